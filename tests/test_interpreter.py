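"""Tracer rules, strength mapping, evidence extraction and the matrix."""

import pytest

from kefed.data import ObservationRow, ObservationTable, RegionExtent
from kefed.errors import DomainError, TracerConfigError
from kefed.fixtures import (
    INJECTION_CHEMICAL,
    INJECTION_LOCATION,
    LABELING_DENSITY,
    LABELING_TYPE,
    MAPPED_LOCATION,
    TAXONOMIC_CLASS,
    CorpusSpec,
    random_corpus,
)
from kefed.interpreter import (
    DENSITY_LEVELS,
    PRESENT_UNKNOWN,
    Strength,
    StrengthScale,
    TracerRegistry,
    build_matrix,
    density_to_strength,
    evidence_for_connection,
    evidence_report,
)


def make_row(exp, pub, chem, inj, mapped, ltype, density):
    return ObservationRow(experiment_id=exp, publication=pub, values={
        TAXONOMIC_CLASS: "Rattus norvegicus",
        INJECTION_CHEMICAL: chem,
        INJECTION_LOCATION: RegionExtent(((inj[0], inj[1]),)),
        MAPPED_LOCATION: RegionExtent(((mapped[0], mapped[1]),)),
        LABELING_TYPE: ltype,
        LABELING_DENSITY: density,
    })


def table_of(*rows):
    return ObservationTable(model_id="tract-tracing", rows=list(rows))


class TestStrengthScale:
    def test_default_map_endpoints_and_midpoints(self, default_scale):
        assert density_to_strength("no label", default_scale) == Strength.NONE
        assert density_to_strength("very sparse label", default_scale) == Strength.WEAK
        assert density_to_strength("moderate label", default_scale) == Strength.MODERATE
        assert density_to_strength("dense label", default_scale) == Strength.STRONG
        assert density_to_strength(PRESENT_UNKNOWN, default_scale) == Strength.WEAK

    def test_unknown_label_is_a_domain_error(self, default_scale):
        with pytest.raises(DomainError):
            density_to_strength("super dense", default_scale)

    def test_non_monotone_map_rejected(self, default_scale):
        broken = {k: v.label for k, v in default_scale.density_map.items()}
        broken["sparse label"] = "strong"
        with pytest.raises(DomainError):
            StrengthScale(density_map=broken)

    def test_incomplete_map_rejected(self):
        with pytest.raises(DomainError):
            StrengthScale(density_map={"no label": "none"})

    def test_map_covers_the_whole_density_scale(self, default_scale):
        assert set(default_scale.density_map) == set(DENSITY_LEVELS) | {PRESENT_UNKNOWN}


class TestRules:
    def test_retrograde_row_with_fiber_label_contributes_nothing(
            self, demo_atlas, default_registry, default_scale):
        t = table_of(make_row("e1", "p1", "HRP", ("coextensive_with", "ENT"),
                              ("coextensive_with", "CA1"), "fibers", PRESENT_UNKNOWN))
        assert evidence_for_connection("CA1", "ENT", t, demo_atlas,
                                       default_registry, default_scale) == []

    def test_anterograde_row_with_cellular_label_contributes_nothing(
            self, demo_atlas, default_registry, default_scale):
        t = table_of(make_row("e1", "p1", "PHAL", ("coextensive_with", "CA1"),
                              ("coextensive_with", "ENT"), "cellular", PRESENT_UNKNOWN))
        assert evidence_for_connection("CA1", "ENT", t, demo_atlas,
                                       default_registry, default_scale) == []

    def test_negative_reports_yield_no_evidence(
            self, demo_atlas, default_registry, default_scale):
        t = table_of(make_row("e1", "p1", "PHAL", ("coextensive_with", "CA1"),
                              ("coextensive_with", "ENT"), "terminals", "no label"))
        assert evidence_for_connection("CA1", "ENT", t, demo_atlas,
                                       default_registry, default_scale) == []

    def test_empty_table_yields_no_evidence(self, demo_atlas, default_registry, default_scale):
        assert evidence_for_connection("CA1", "ENT", table_of(), demo_atlas,
                                       default_registry, default_scale) == []

    def test_subregion_injection_matches_via_part(
            self, demo_atlas, default_registry, default_scale):
        t = table_of(make_row("e1", "p1", "PHAL", ("coextensive_with", "RSPv-a"),
                              ("coextensive_with", "POST"), "terminals", "dense label"))
        [ev] = evidence_for_connection("RSP", "POST", t, demo_atlas,
                                       default_registry, default_scale)
        assert ev.directness == "via_part"
        assert ev.injection_trail.verdict == "contained"
        assert ev.strength == Strength.STRONG

    def test_unregistered_chemical_is_named(self, demo_atlas, default_scale):
        t = table_of(make_row("e1", "p1", "mystery-dye", ("coextensive_with", "CA1"),
                              ("coextensive_with", "ENT"), "terminals", PRESENT_UNKNOWN))
        with pytest.raises(TracerConfigError) as err:
            evidence_for_connection("CA1", "ENT", t, demo_atlas,
                                    TracerRegistry(), default_scale)
        assert "mystery-dye" in str(err.value)

    def test_direct_only_drops_overlap_matches(
            self, worked_example, demo_atlas, default_scale):
        table, registry = worked_example
        full = evidence_for_connection("CA1", "ENT", table, demo_atlas, registry,
                                       default_scale)
        direct = evidence_for_connection("CA1", "ENT", table, demo_atlas, registry,
                                         default_scale, direct_only=True)
        assert {e.directness for e in full} == {"direct", "via_part", "via_overlap"}
        assert all(e.directness != "via_overlap" for e in direct)
        assert len(full) - len(direct) == 3


class TestMatrix:
    def test_no_data_means_all_cells_none_zero(
            self, demo_atlas, default_registry, default_scale):
        mat = build_matrix(["CA1", "ENT", "POST"], table_of(), demo_atlas,
                           default_registry, default_scale)
        for o in mat.regions:
            for t in mat.regions:
                if o != t:
                    assert mat.cell(o, t) == (Strength.NONE, 0)

    def test_cell_is_max_strength_with_count(
            self, demo_atlas, default_registry, default_scale):
        t = table_of(
            make_row("e1", "p1", "PHAL", ("coextensive_with", "CA1"),
                     ("coextensive_with", "ENT"), "terminals", "sparse label"),
            make_row("e2", "p2", "PHAL", ("coextensive_with", "CA1"),
                     ("coextensive_with", "ENT"), "terminals", "dense label"))
        mat = build_matrix(["CA1", "ENT"], t, demo_atlas, default_registry, default_scale)
        assert mat.cell("CA1", "ENT") == (Strength.STRONG, 2)
        assert mat.cell("ENT", "CA1") == (Strength.NONE, 0)

    def test_cell_strength_equals_max_of_report(
            self, worked_example, demo_atlas, default_scale):
        table, registry = worked_example
        mat = build_matrix(["CA1", "ENT"], table, demo_atlas, registry, default_scale)
        ev = evidence_for_connection("CA1", "ENT", table, demo_atlas, registry,
                                     default_scale)
        s, n = mat.cell("CA1", "ENT")
        assert s == max(e.strength for e in ev) and n == len(ev)

    def test_matrix_csv_shape(self, worked_example, demo_atlas, default_scale):
        table, registry = worked_example
        mat = build_matrix(["CA1", "ENT"], table, demo_atlas, registry, default_scale)
        text = mat.to_csv_text()
        lines = text.strip().splitlines()
        assert lines[0] == "origin,CA1,ENT"
        assert lines[1].startswith("CA1,-,weak:10")


class TestReport:
    def test_row_count_matches_evidence(self, worked_example, demo_atlas, default_scale):
        table, registry = worked_example
        ev = evidence_for_connection("CA1", "ENT", table, demo_atlas, registry,
                                     default_scale)
        frame = evidence_report(ev)
        assert len(frame) == len(ev)
        assert list(frame["publication"]) == sorted(frame["publication"])

    def test_empty_report_keeps_header(self):
        frame = evidence_report([])
        assert len(frame) == 0 and "publication" in frame.columns


def _projections(evidence):
    return sorted((e.origin, e.termination, e.strength, e.publication,
                   e.experiment_id, e.directness) for e in evidence)


class TestInvariants:
    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_direction_symmetry(self, seed, default_scale):
        """Swapping tracer direction together with extents and label type
        leaves every pair's evidence unchanged."""
        atlas, table, registry, _ = random_corpus(CorpusSpec(seed=seed, n_experiments=6))
        flipped_rows = []
        flip_type = {"terminals": "cellular", "fibers": "cellular", "cellular": "terminals"}
        flip_chem = {"PHAL": "HRP", "HRP": "PHAL"}
        for r in table.rows:
            values = dict(r.values)
            values[INJECTION_LOCATION], values[MAPPED_LOCATION] = \
                values[MAPPED_LOCATION], values[INJECTION_LOCATION]
            values[LABELING_TYPE] = flip_type[values[LABELING_TYPE]]
            values[INJECTION_CHEMICAL] = flip_chem[values[INJECTION_CHEMICAL]]
            flipped_rows.append(ObservationRow(r.experiment_id, r.publication, values))
        flipped = ObservationTable(table.model_id, flipped_rows)
        roots = sorted({r.abbrev for r in atlas.regions if not atlas.parents(r.abbrev)})
        for o in roots:
            for t in roots:
                if o == t:
                    continue
                a = evidence_for_connection(o, t, table, atlas, registry, default_scale)
                b = evidence_for_connection(o, t, flipped, atlas, registry, default_scale)
                assert _projections(a) == _projections(b)

    def test_coarsening_the_termination_keeps_evidence(
            self, worked_example, demo_atlas, default_scale):
        table, registry = worked_example
        fine = evidence_for_connection("CA1", "ENTl", table, demo_atlas, registry,
                                       default_scale)
        coarse = evidence_for_connection("CA1", "ENT", table, demo_atlas, registry,
                                         default_scale)
        assert {e.row_index for e in fine} <= {e.row_index for e in coarse}
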