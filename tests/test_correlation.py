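import itertools

import numpy as np
import pandas as pd
import pytest

from secpath.correlation import (
    cluster_tissues,
    cross_tissue_correlation,
    family_correlation_profiles,
    low_group_permutation_test,
    profiles_table,
)
from secpath.io_formats import load_pathway_annotation
from secpath.types import ExpressionMatrix, ValidationError


def _matrix(values, genes, tissues, dataset="m"):
    return ExpressionMatrix(
        dataset, pd.DataFrame(values, index=genes, columns=tissues))


class TestCrossTissueCorrelation:
    def test_identical_profiles_rho_one(self):
        v = np.array([[1.0, 1.0], [4.0, 4.0], [9.0, 9.0]])
        c = cross_tissue_correlation(_matrix(v, list("abc"), ["t1", "t2"]))
        assert c.rho.loc["t1", "t2"] == pytest.approx(1.0)

    def test_reflected_profile_rho_minus_one(self):
        a = np.array([1.0, 2.0, 3.0])
        v = np.column_stack([a, -a + 10.0])
        c = cross_tissue_correlation(
            _matrix(v, list("abc"), ["t1", "t2"]), log_transform=False)
        assert c.rho.loc["t1", "t2"] == pytest.approx(-1.0)

    def test_linear_raw_profiles(self):
        v = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        c = cross_tissue_correlation(
            _matrix(v, list("abc"), ["A", "B"]), log_transform=False)
        assert c.rho.loc["A", "B"] == pytest.approx(1.0)

    def test_symmetry_and_unit_diagonal(self, default_sim):
        c = cross_tissue_correlation(default_sim.primary)
        r = c.rho.to_numpy()
        assert np.allclose(r, r.T, atol=1e-12)
        assert np.allclose(np.diag(r), 1.0)
        assert np.nanmax(np.abs(r)) <= 1 + 1e-12

    def test_too_few_genes_error(self):
        m = _matrix([[1.0, 2.0]], ["a"], ["t1", "t2"])
        with pytest.raises(ValidationError, match=">= 2"):
            cross_tissue_correlation(m)

    def test_zero_variance_tissue_gives_missing(self, caplog):
        v = np.array([[1.0, 5.0], [1.0, 9.0], [1.0, 2.0]])
        with caplog.at_level("WARNING"):
            c = cross_tissue_correlation(
                _matrix(v, list("abc"), ["flat", "ok"]), log_transform=False)
        assert np.isnan(c.rho.loc["flat", "ok"])


class TestClusterTissues:
    def _block_matrix(self):
        tissues = [f"t{i}" for i in range(5)]
        r = np.full((5, 5), 0.3)
        r[:3, :3] = 0.95
        r[3:, 3:] = 0.95
        np.fill_diagonal(r, 1.0)
        return pd.DataFrame(r, index=tissues, columns=tissues)

    def test_two_group_split_recovers_blocks_vs_brute_force(self):
        from secpath.correlation import TissueCorrelationMatrix

        rho = self._block_matrix()
        res = cluster_tissues(TissueCorrelationMatrix(rho, "toy"))
        split = frozenset(map(frozenset, [res.group_members(1),
                                          res.group_members(2)]))
        # brute force: the 2-partition minimising mean between-group rho
        tissues = list(rho.index)
        best, best_val = None, np.inf
        for k in range(1, 3):
            for combo in itertools.combinations(tissues, k):
                a, b = set(combo), set(tissues) - set(combo)
                val = np.mean([rho.loc[x, y] for x in a for y in b])
                if val < best_val:
                    best, best_val = frozenset(map(frozenset, [a, b])), val
        assert split == best

    def test_degenerate_all_ones(self, caplog):
        from secpath.correlation import TissueCorrelationMatrix

        tissues = ["a", "b", "c"]
        rho = pd.DataFrame(np.ones((3, 3)), index=tissues, columns=tissues)
        with caplog.at_level("WARNING"):
            res = cluster_tissues(TissueCorrelationMatrix(rho, "ones"))
        assert res.degenerate

    def test_tissue_order_invariance(self, default_sim):
        m = default_sim.primary
        c1 = cross_tissue_correlation(m, genes=default_sim.truth.target_genes)
        perm = list(reversed(m.tissues))
        m2 = ExpressionMatrix("p", m.values[perm])
        c2 = cross_tissue_correlation(m2, genes=default_sim.truth.target_genes)
        s1 = frozenset(map(frozenset, [cluster_tissues(c1).group_members(1),
                                       cluster_tissues(c1).group_members(2)]))
        s2 = frozenset(map(frozenset, [cluster_tissues(c2).group_members(1),
                                       cluster_tissues(c2).group_members(2)]))
        assert s1 == s2

    def test_missing_entries_instruct(self):
        from secpath.correlation import TissueCorrelationMatrix

        rho = self._block_matrix()
        rho.iloc[0, 1] = np.nan
        with pytest.raises(ValidationError, match="impute"):
            cluster_tissues(TissueCorrelationMatrix(rho, "x"))

    def test_newick_contains_all_tissues(self, default_sim):
        c = cross_tissue_correlation(default_sim.primary)
        res = cluster_tissues(c)
        for t in default_sim.primary.tissues:
            assert t in res.newick


class TestPermutationTest:
    def test_planted_low_group_significant(self, default_sim):
        med, p = low_group_permutation_test(
            default_sim.primary, default_sim.truth.target_genes,
            default_sim.truth.low_corr_group, n_perm=199, seed=1)
        assert p <= 0.05
        assert med < 0.75

    def test_all_genes_uninformative(self, default_sim):
        _, p = low_group_permutation_test(
            default_sim.primary, default_sim.primary.genes,
            default_sim.truth.low_corr_group, n_perm=199, seed=1)
        assert p > 0.05  # target equals the null pool: nothing special

    def test_determinism(self, default_sim):
        args = (default_sim.primary, default_sim.truth.target_genes,
                default_sim.truth.low_corr_group)
        r1 = low_group_permutation_test(*args, n_perm=149, seed=5)
        r2 = low_group_permutation_test(*args, n_perm=149, seed=5)
        assert r1 == r2

    def test_p_never_zero(self, default_sim):
        _, p = low_group_permutation_test(
            default_sim.primary, default_sim.truth.target_genes,
            default_sim.truth.low_corr_group, n_perm=149, seed=2)
        assert 0 < p <= 1
        assert p >= 1.0 / 150

    def test_group_equal_to_all_tissues_error(self, default_sim):
        with pytest.raises(ValidationError, match="proper"):
            low_group_permutation_test(
                default_sim.primary, default_sim.truth.target_genes,
                default_sim.primary.tissues, n_perm=149, seed=0)

    def test_low_n_perm_warns(self, default_sim, caplog):
        with caplog.at_level("WARNING"):
            low_group_permutation_test(
                default_sim.primary, default_sim.truth.target_genes,
                default_sim.truth.low_corr_group, n_perm=99, seed=0)
        assert "n_perm" in caplog.text


class TestFamilyProfiles:
    def test_scaled_members_rho_one(self, tmp_path):
        tissues = [f"t{i}" for i in range(5)]
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        vals = np.vstack([base, 2 * base, 5 * base])
        m = _matrix(vals, ["a", "b", "c"], tissues)
        p = tmp_path / "ann.tsv"
        p.write_text("gene\tmodule\tsubsystem\tfamily\n" +
                     "\n".join(f"{g}\tM\tS\tF" for g in "abc") + "\n")
        ann = load_pathway_annotation(p)
        profs = family_correlation_profiles(m, ann, log_transform=False)
        assert all(pr.rho == pytest.approx(1.0) for pr in profs)
        assert len(profs) == 10  # all tissue pairs

    def test_spiked_member_depresses_spike_tissue_pairs(self):
        # removing a planted extreme member raises the family rho for
        # the pairs involving its spike tissue, on average and for a
        # clear majority of pairs (per-pair rho is noisy over a handful
        # of members, so the strict per-pair version is not attainable)
        from secpath.simulate import SimulationPlan, simulate

        diffs = []
        for seed in range(5):
            plan = SimulationPlan(
                seed=seed, n_tissues=20, families=[("FAMA", 10)],
                spikes=[("FAMA_03", "T05", 10.0)], n_low_corr_tissues=0,
                category_plants={}, enzyme_family=None, n_secretome=0,
                n_unconventional=0, n_background=20, n_other=0)
            r = simulate(plan)
            members = [f"FAMA_{i + 1:02d}" for i in range(10)]
            logv = np.log10(r.primary.values.loc[members] + 1.0)
            drop = logv.drop(index="FAMA_03")
            for t in [x for x in r.primary.tissues if x != "T05"]:
                w = np.corrcoef(logv["T05"], logv[t])[0, 1]
                wo = np.corrcoef(drop["T05"], drop[t])[0, 1]
                diffs.append(wo - w)
        diffs = np.asarray(diffs)
        assert diffs.mean() > 0.03
        assert (diffs > 0).mean() > 0.6

    def test_small_family_skipped(self, tmp_path, caplog):
        m = _matrix(np.ones((2, 3)) * [[1.0], [2.0]], ["a", "b"],
                    ["t1", "t2", "t3"])
        p = tmp_path / "ann.tsv"
        p.write_text("gene\tmodule\tsubsystem\tfamily\n"
                     "a\tM\tS\tF\nb\tM\tS\tF\n")
        ann = load_pathway_annotation(p)
        with caplog.at_level("INFO"):
            profs = family_correlation_profiles(m, ann)
        assert profs == []

    def test_reference_tissue_mode(self, default_sim):
        profs = family_correlation_profiles(
            default_sim.primary, default_sim.annotation,
            reference_tissue="T01")
        tab = profiles_table(profs)
        assert set(tab["tissue1"]) == {"T01"}
        n_fams = len(default_sim.annotation.families(min_size=3))
        assert len(tab) == n_fams * (len(default_sim.primary.tissues) - 1)
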