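import numpy as np
import pandas as pd
import pytest

from secpath.extremes import (
    build_network,
    consensus,
    detect_extreme_genes,
    family_share,
    subsystem_tissue_table,
)
from secpath.io_formats import load_pathway_annotation
from secpath.simulate import SimulationPlan, simulate, spike_recovery_plan
from secpath.types import ExpressionMatrix, ExtremeCall, ValidationError


def _matrix(values, genes, tissues):
    return ExpressionMatrix(
        "m", pd.DataFrame(values, index=genes, columns=tissues))


def _annotation(tmp_path, fam_members):
    lines = ["gene\tmodule\tsubsystem\tfamily"]
    for fam, genes in fam_members.items():
        lines += [f"{g}\tM\tS\t{fam}" for g in genes]
    p = tmp_path / "ann.tsv"
    p.write_text("\n".join(lines) + "\n")
    return load_pathway_annotation(p)


class TestFamilyShare:
    def test_two_gene_shares(self):
        m = _matrix([[3.0], [1.0]], ["a", "b"], ["t"])
        sh = family_share(m, ["a", "b"])
        assert sh.loc["a", "t"] == 0.75
        assert sh.loc["b", "t"] == 0.25

    def test_columns_sum_to_one(self, default_sim):
        fams = default_sim.annotation.families(min_size=3)
        members = next(iter(fams.values()))
        sh = family_share(default_sim.primary, members)
        np.testing.assert_allclose(sh.sum(axis=0), 1.0)

    def test_per_tissue_scaling_invariance(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        m1 = _matrix(vals, list("abc"), ["t1", "t2"])
        m2 = _matrix(vals * np.array([10.0, 0.5]), list("abc"), ["t1", "t2"])
        pd.testing.assert_frame_equal(
            family_share(m1, list("abc")), family_share(m2, list("abc")))

    def test_zero_total_tissue_missing(self):
        m = _matrix([[0.0, 1.0], [0.0, 3.0]], ["a", "b"], ["t1", "t2"])
        sh = family_share(m, ["a", "b"])
        assert sh["t1"].isna().all()
        assert sh.loc["b", "t2"] == 0.75


class TestDetection:
    def test_uniform_matrix_no_calls(self, tmp_path):
        m = _matrix(np.full((4, 10), 5.0), list("abcd"), [f"t{i}" for i in range(10)])
        ann = _annotation(tmp_path, {"F": list("abcd")})
        above, below = detect_extreme_genes(m, ann)
        assert above == [] and below == []

    def test_alpha_zero_no_calls(self, default_sim):
        above, _ = detect_extreme_genes(
            default_sim.primary, default_sim.annotation, alpha=0.0)
        assert above == []

    def test_planted_spike_called_with_fold_change(self, tmp_path, rng):
        genes = [f"g{i}" for i in range(6)]
        tissues = [f"t{i}" for i in range(20)]
        vals = np.exp(rng.normal(1.0, 0.2, size=(6, 20)))
        vals[3, 7] *= 10
        m = _matrix(vals, genes, tissues)
        ann = _annotation(tmp_path, {"F": genes})
        above, _ = detect_extreme_genes(m, ann)
        assert [(c.gene, c.tissue) for c in above] == [("g3", "t7")]
        assert above[0].fold_change > 5
        assert above[0].direction == "above"

    def test_library_size_rescaling_invariance(self, tmp_path, rng):
        genes = [f"g{i}" for i in range(6)]
        tissues = [f"t{i}" for i in range(15)]
        vals = np.exp(rng.normal(1.0, 0.3, size=(6, 15)))
        vals[2, 4] *= 12
        scale = rng.uniform(0.2, 5.0, size=15)
        ann = _annotation(tmp_path, {"F": genes})
        a1, _ = detect_extreme_genes(_matrix(vals, genes, tissues), ann)
        a2, _ = detect_extreme_genes(_matrix(vals * scale, genes, tissues), ann)
        assert [(c.gene, c.tissue, pytest.approx(c.G)) for c in a1] == \
               [(c.gene, c.tissue, pytest.approx(c.G)) for c in a2]

    def test_iterative_masking_finds_second_tissue(self, tmp_path, rng):
        genes = [f"g{i}" for i in range(6)]
        tissues = [f"t{i}" for i in range(20)]
        vals = np.exp(rng.normal(1.0, 0.15, size=(6, 20)))
        vals[1, 3] *= 30
        vals[1, 11] *= 20
        m = _matrix(vals, genes, tissues)
        ann = _annotation(tmp_path, {"F": genes})
        single, _ = detect_extreme_genes(m, ann, iterate=False)
        iterated, _ = detect_extreme_genes(m, ann, iterate=True, max_depth=2)
        g1_single = {c.tissue for c in single if c.gene == "g1"}
        g1_iter = {c.tissue for c in iterated if c.gene == "g1"}
        assert g1_single == {"t3"}
        assert g1_iter == {"t3", "t11"}

    def test_validated_false_calls_bounded_under_null(self):
        # the consensus step is what controls the family-wise false-call
        # rate: shares are non-normal, so per-dataset calls run above
        # alpha, but validated pairs stay within alpha * family size
        total_validated = 0.0
        n_seeds = 20
        for seed in range(n_seeds):
            plan = spike_recovery_plan(seed)
            plan.n_spikes = 0
            r = simulate(plan)
            a1, _ = detect_extreme_genes(r.primary, r.annotation)
            a2, _ = detect_extreme_genes(r.validation, r.annotation)
            val = [c for c in consensus(a1, a2) if c.validated]
            total_validated += len(val)
        fams = simulate(spike_recovery_plan(0)).annotation.families(min_size=3)
        bound = sum(0.05 * len(m) for m in fams.values())
        assert total_validated / n_seeds <= bound


class TestConsensus:
    def _call(self, gene, tissue, dataset="primary"):
        return ExtremeCall(gene=gene, family="F", tissue=tissue, G=3.0,
                           p=0.01, fold_change=5.0, dataset_id=dataset)

    def test_identical_sets_all_validated(self):
        a = [self._call("g1", "liver"), self._call("g2", "brain")]
        b = [self._call("g1", "liver", "v"), self._call("g2", "brain", "v")]
        out = consensus(a, b)
        assert all(c.validated for c in out)

    def test_disjoint_sets_none_validated(self):
        out = consensus([self._call("g1", "liver")],
                        [self._call("g2", "brain", "v")])
        assert not any(c.validated for c in out)

    def test_same_gene_different_tissue_not_validated(self):
        out = consensus([self._call("g1", "liver")],
                        [self._call("g1", "brain", "v")])
        assert not out[0].validated

    def test_case_insensitive_and_alias(self):
        out = consensus([self._call("g1", "Skeletal Muscle")],
                        [self._call("g1", "muscle", "v")],
                        alias_map={"muscle": "skeletal muscle"})
        assert out[0].validated

    def test_disjoint_vocabularies_error(self):
        with pytest.raises(ValidationError, match="alias map"):
            consensus([self._call("g1", "liver")],
                      [self._call("g1", "hepar", "v")],
                      tissues_primary=["liver", "brain"],
                      tissues_validation=["hepar", "cerebrum"])


class TestNetwork:
    def _calls(self):
        return [
            ExtremeCall(gene="g1", family="F", tissue="liver", G=3, p=0.01,
                        fold_change=8, dataset_id="d", validated=True,
                        subsystem="ERAD"),
            ExtremeCall(gene="g1", family="F", tissue="brain", G=3, p=0.02,
                        fold_change=6, dataset_id="d", validated=True,
                        subsystem="ERAD"),
        ]

    def test_shared_gene_degree(self, default_sim):
        net = build_network(self._calls(), default_sim.annotation)
        assert net.degree["g1"] == 2
        assert net.nodes["g1"]["kind"] == "gene"
        assert net.nodes["liver"]["kind"] == "tissue"
        # strictly bipartite
        for u, v in net.edges:
            assert {net.nodes[u]["kind"], net.nodes[v]["kind"]} == \
                   {"gene", "tissue"}

    def test_subsystem_tissue_aggregation(self):
        tab = subsystem_tissue_table(self._calls())
        assert tab.loc["ERAD", "liver"] == 1
        assert tab.loc["ERAD", "brain"] == 1

    def test_empty_calls_warns(self, default_sim, caplog):
        with caplog.at_level("WARNING"):
            net = build_network([], default_sim.annotation)
        assert net.number_of_nodes() == 0
        assert "zero extreme calls" in caplog.text
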