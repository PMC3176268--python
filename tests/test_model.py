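"""Workflow-model validation, context derivation and serialization."""

import json

import pytest

from kefed import fixtures as fx
from kefed.errors import (
    DocumentParseError,
    ModelValidationError,
    NodeKindError,
    UnknownNodeError,
)
from kefed.model import (
    KefedEdge,
    KefedModel,
    KefedNode,
    ValueDomain,
    derive_context,
    derive_form,
    model_from_dict,
    model_to_dict,
    read_model,
    validate_model,
    write_model,
)

from _oracles import oracle_context

FREE = ValueDomain(kind="free_text")


def tiny_model(**overrides):
    """One material -> one activity, one parameter, one measurement."""
    nodes = [
        KefedNode("m0", "material"),
        KefedNode("a0", "activity"),
        KefedNode("p0", "parameter", domain=FREE),
        KefedNode("meas0", "measurement", domain=FREE),
    ]
    edges = [
        KefedEdge("m0", "a0", "flow"),
        KefedEdge("p0", "a0", "parameter_of"),
        KefedEdge("a0", "meas0", "measurement_of"),
    ]
    fields = dict(id="tiny", nodes=tuple(nodes), edges=tuple(edges))
    fields.update(overrides)
    return KefedModel(**fields)


class TestValidation:
    def test_tiny_model_is_valid(self):
        assert validate_model(tiny_model()).ok

    def test_flow_cycle_is_one_acyclicity_violation(self):
        m = tiny_model(edges=(
            KefedEdge("m0", "a0", "flow"),
            KefedEdge("a0", "m0", "flow"),
            KefedEdge("p0", "a0", "parameter_of"),
            KefedEdge("a0", "meas0", "measurement_of"),
        ))
        report = validate_model(m)
        assert report.codes().count("flow-cycle") == 1

    def test_measurement_with_two_attachments_is_cardinality_violation(self):
        base = tiny_model()
        m = KefedModel(id="t", nodes=base.nodes + (KefedNode("a1", "activity"), KefedNode("m1", "material")),
                       edges=base.edges + (KefedEdge("m1", "a1", "flow"),
                                           KefedEdge("a1", "meas0", "measurement_of")))
        assert validate_model(m).codes().count("measurement-cardinality") == 1

    def test_unattached_parameter_and_missing_domain(self):
        m = KefedModel(id="t", nodes=(
            KefedNode("m0", "material"),
            KefedNode("a0", "activity"),
            KefedNode("p0", "parameter"),  # no domain, no attachment
        ), edges=(KefedEdge("m0", "a0", "flow"),))
        codes = validate_model(m).codes()
        assert "missing-domain" in codes and "unattached-variable" in codes

    def test_flow_alternation_and_endpoint_kinds(self):
        m = KefedModel(id="t", nodes=(
            KefedNode("m0", "material"), KefedNode("m1", "material"),
            KefedNode("p0", "parameter", domain=FREE), KefedNode("a0", "activity"),
        ), edges=(
            KefedEdge("m0", "m1", "flow"),       # material -> material
            KefedEdge("p0", "a0", "flow"),       # variable in the flow graph
            KefedEdge("p0", "a0", "parameter_of"),
        ))
        codes = validate_model(m).codes()
        assert "flow-alternation" in codes and "flow-endpoint-kind" in codes

    def test_alternation_is_checked_through_control_nodes(self):
        m = KefedModel(id="t", nodes=(
            KefedNode("m0", "material"), KefedNode("m1", "material"),
            KefedNode("f0", "fork"),
        ), edges=(
            KefedEdge("m0", "f0", "flow"),
            KefedEdge("f0", "m1", "flow"),
        ))
        assert "flow-alternation" in validate_model(m).codes()

    def test_dangling_edge_and_bad_curie(self):
        m = KefedModel(id="t", nodes=(
            KefedNode("m0", "material", ontology_term="not a curie"),
            KefedNode("a0", "activity"),
        ), edges=(KefedEdge("m0", "ghost", "flow"), KefedEdge("m0", "a0", "flow")))
        codes = validate_model(m).codes()
        assert "dangling-edge" in codes and "bad-curie" in codes

    def test_degenerate_ordinal_domain(self):
        m = tiny_model(nodes=(
            KefedNode("m0", "material"),
            KefedNode("a0", "activity"),
            KefedNode("p0", "parameter", domain=ValueDomain(kind="ordinal", levels=("only",))),
            KefedNode("meas0", "measurement", domain=FREE),
        ))
        assert "degenerate-ordinal" in validate_model(m).codes()


class TestDeriveContext:
    def test_single_activity_single_parameter(self):
        ctx = derive_context(tiny_model(), "meas0")
        assert ctx.context_ids == ("p0",)

    def test_unknown_and_wrong_kind_errors(self):
        m = tiny_model()
        with pytest.raises(UnknownNodeError):
            derive_context(m, "nope")
        with pytest.raises(NodeKindError):
            derive_context(m, "p0")

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_path_enumeration(self, seed):
        m = fx.random_design(seed)
        assert validate_model(m).ok
        for meas in m.measurements:
            got = derive_context(m, meas.id)
            assert set(got.context_ids) == oracle_context(m, meas.id)
            assert len(set(got.context_ids)) == len(got.context_ids)

    @pytest.mark.parametrize("seed", range(10))
    def test_invariant_under_reserialized_node_order(self, seed):
        m = fx.random_design(seed)
        shuffled = KefedModel(id=m.id, name=m.name, description=m.description,
                              nodes=tuple(reversed(m.nodes)), edges=tuple(reversed(m.edges)))
        for meas in m.measurements:
            assert derive_context(m, meas.id) == derive_context(shuffled, meas.id)

    def test_off_path_parameter_leaves_context_unchanged(self):
        base = tiny_model()
        before = derive_context(base, "meas0")
        # a second, disconnected activity with its own parameter
        m = KefedModel(id="t", nodes=base.nodes + (
            KefedNode("mX", "material"), KefedNode("aX", "activity"),
            KefedNode("pX", "parameter", domain=FREE)),
            edges=base.edges + (KefedEdge("mX", "aX", "flow"),
                                KefedEdge("pX", "aX", "parameter_of")))
        assert derive_context(m, "meas0") == before
        assert set(derive_context(m, "meas0").context_ids) <= {n.id for n in m.nodes}


class TestDeriveForm:
    def test_no_measurements_means_no_columns(self):
        m = KefedModel(id="t", nodes=(KefedNode("m0", "material"), KefedNode("a0", "activity")),
                       edges=(KefedEdge("m0", "a0", "flow"),))
        assert derive_form(m).columns == ()

    def test_shared_parameters_appear_once(self):
        base = tiny_model()
        m = KefedModel(id="t", nodes=base.nodes + (
            KefedNode("meas1", "measurement", domain=FREE),),
            edges=base.edges + (KefedEdge("a0", "meas1", "measurement_of"),))
        form = derive_form(m)
        assert [c.node_id for c in form.columns] == ["p0", "meas0", "meas1"]

    def test_invalid_model_raises_with_report(self):
        m = tiny_model(edges=(KefedEdge("m0", "a0", "flow"),
                              KefedEdge("a0", "m0", "flow"),
                              KefedEdge("p0", "a0", "parameter_of"),
                              KefedEdge("a0", "meas0", "measurement_of")))
        with pytest.raises(ModelValidationError) as err:
            derive_form(m)
        assert "flow-cycle" in err.value.report.codes()

    def test_constants_are_flagged_fixed(self, reference_form):
        fixed = {c.node_id for c in reference_form.columns if c.fixed}
        assert fixed == {"taxonomic-class"}


class TestSerialization:
    def test_roundtrip_identity(self, tmp_path, reference_model):
        path = tmp_path / "model.json"
        write_model(reference_model, path)
        assert read_model(path) == reference_model

    def test_permuted_document_order_reads_equal(self, tmp_path, reference_model):
        path = tmp_path / "model.json"
        write_model(reference_model, path)
        doc = json.loads(path.read_text())
        doc["nodes"].reverse()
        doc["edges"].reverse()
        path.write_text(json.dumps(doc))
        assert read_model(path) == reference_model

    def test_missing_edges_key_reports_pointer(self):
        with pytest.raises(DocumentParseError) as err:
            model_from_dict({"id": "x", "nodes": []})
        assert err.value.location == "/edges"

    def test_bad_node_entry_reports_pointer(self):
        with pytest.raises(DocumentParseError) as err:
            model_from_dict({"id": "x", "nodes": [{"kind": "material"}], "edges": []})
        assert err.value.location == "/nodes/0/id"

    def test_write_refuses_invalid_model(self, tmp_path):
        m = tiny_model(edges=(KefedEdge("m0", "a0", "flow"),
                              KefedEdge("a0", "m0", "flow"),
                              KefedEdge("p0", "a0", "parameter_of"),
                              KefedEdge("a0", "meas0", "measurement_of")))
        with pytest.raises(ModelValidationError):
            write_model(m, tmp_path / "m.json")

    def test_dict_roundtrip(self, reference_model):
        assert model_from_dict(model_to_dict(reference_model)) == reference_model
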