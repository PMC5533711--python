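import numpy as np
import pandas as pd
import pytest

from goiseek.deca import (
    DecaConfig,
    rank_candidates,
    reduce_comparisons,
    run_deca,
    seed_profile,
    select_candidates,
)
from goiseek.errors import ValidationError
from goiseek.types import DEMatrix


def de_matrix(de_rows, p_rows, genes=None, comps=None):
    de_rows = np.asarray(de_rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(de_rows.shape[0])]
    comps = comps or [f"c{j}" for j in range(de_rows.shape[1])]
    de = pd.DataFrame(de_rows, index=genes, columns=comps)
    p = pd.DataFrame(np.asarray(p_rows, dtype=float), index=genes, columns=comps)
    return DEMatrix(de, p)


class TestReduceComparisons:
    def test_significant_comparisons_selected(self):
        m = de_matrix(
            [[1, 2, 3, 4]], [[0.005, 0.5, 0.009, 1.0]]
        )
        got = reduce_comparisons(m, "g0", 0.01, min_reduced_comparisons=2)
        assert got == ["c0", "c2"]

    def test_nowhere_significant_errors(self):
        m = de_matrix([[1, 2, 3]], [[0.5, 0.5, 0.5]])
        with pytest.raises(ValidationError, match="choose another seed"):
            reduce_comparisons(m, "g0")

    def test_exact_alpha_excluded(self):
        m = de_matrix([[1, 2, 3]], [[0.01, 0.009, 0.001]])
        got = reduce_comparisons(m, "g0", 0.01, min_reduced_comparisons=2)
        assert got == ["c1", "c2"]

    def test_missing_de_value_excluded(self):
        m = de_matrix([[np.nan, 2, 3]], [[0.001, 0.002, 0.003]])
        got = reduce_comparisons(m, "g0", 0.01, min_reduced_comparisons=2)
        assert got == ["c1", "c2"]

    def test_absent_seed(self):
        m = de_matrix([[1, 2, 3]], [[0.001, 0.002, 0.003]])
        with pytest.raises(ValidationError, match="gX"):
            reduce_comparisons(m, "gX")


class TestSeedProfile:
    def _matrix(self):
        de = [
            [1.0, 2.0, 3.0, 4.0],  # seed, significant everywhere
            [1.0, 2.0, 3.0, 4.0],  # identical to seed
            [4.0, 3.0, 2.0, 1.0],  # anti-correlated
            [1.0, 1.0, 2.0, 2.0],
        ]
        p = [
            [0.001] * 4,
            [0.001, 0.5, 0.001, 0.5],
            [1.0] * 4,
            [0.001, 0.001, 0.001, 0.5],
        ]
        return de_matrix(de, p)

    def test_identical_gene_correlation_one(self):
        prof = seed_profile(self._matrix(), "g0")
        assert prof.correlation["g1"] == pytest.approx(1.0)
        assert prof.correlation["g2"] == pytest.approx(-1.0)

    def test_significance_fraction_counts(self):
        prof = seed_profile(self._matrix(), "g0")
        assert prof.significance_fraction["g1"] == pytest.approx(0.5)
        assert prof.significance_fraction["g3"] == pytest.approx(0.75)

    def test_imputed_pvalues_never_significant(self):
        prof = seed_profile(self._matrix(), "g0")
        assert prof.significance_fraction["g2"] == 0.0

    def test_seed_excluded(self):
        prof = seed_profile(self._matrix(), "g0")
        assert "g0" not in prof.correlation.index


class TestSelect:
    def _profiles(self, corr, frac):
        from goiseek.deca import SeedProfile

        genes = list(corr.keys())
        return [
            SeedProfile(
                seed="s",
                reduced_comparisons=["c0"],
                correlation=pd.Series(corr),
                significance_fraction=pd.Series(frac),
            )
        ]

    def test_correlation_above_threshold(self):
        profs = self._profiles({"A": 0.65}, {"A": 0.2})
        assert select_candidates(profs) == ["A"]

    def test_exact_threshold_not_selected(self):
        profs = self._profiles({"A": 0.6}, {"A": 0.6})
        assert select_candidates(profs) == []

    def test_negative_correlation_absolute(self):
        profs = self._profiles({"A": -0.7}, {"A": 0.0})
        assert select_candidates(profs) == ["A"]

    def test_threshold_monotone(self, rng):
        from goiseek.deca import SeedProfile

        genes = [f"g{i}" for i in range(30)]
        profs = [
            SeedProfile(
                "s",
                ["c0"],
                pd.Series(rng.uniform(-1, 1, 30), index=genes),
                pd.Series(rng.uniform(0, 1, 30), index=genes),
            )
        ]
        prev = None
        for t in (0.2, 0.4, 0.6, 0.8):
            sel = set(select_candidates(profs, DecaConfig(selection_threshold=t)))
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_every_seed_mode(self):
        from goiseek.deca import SeedProfile

        p1 = SeedProfile(
            "s1", ["c0"],
            pd.Series({"A": 0.9, "B": 0.9}),
            pd.Series({"A": 0.0, "B": 0.0}),
        )
        p2 = SeedProfile(
            "s2", ["c0"],
            pd.Series({"A": 0.9, "B": 0.1}),
            pd.Series({"A": 0.0, "B": 0.0}),
        )
        assert select_candidates([p1, p2]) == ["A", "B"]
        cfg = DecaConfig(selection_mode="every_seed")
        assert select_candidates([p1, p2], cfg) == ["A"]


class TestRank:
    def _profiles(self, corr_by_seed, frac_by_seed):
        from goiseek.deca import SeedProfile

        profs = []
        for seed in corr_by_seed:
            profs.append(
                SeedProfile(
                    seed,
                    ["c0"],
                    pd.Series(corr_by_seed[seed]),
                    pd.Series(frac_by_seed[seed]),
                )
            )
        return profs

    def test_simple_two_gene(self):
        profs = self._profiles(
            {"s": {"A": 0.9, "B": 0.7}}, {"s": {"A": 0.9, "B": 0.7}}
        )
        component, final, ordering = rank_candidates(profs, ["A", "B"])
        assert list(component.loc["A"]) == [1.0, 1.0]
        assert final["A"] == pytest.approx(1.0)
        assert final["B"] == pytest.approx(2.0)
        assert ordering == ["A", "B"]

    def test_two_seed_geometric_mean_oracle(self):
        corr = {
            "s1": {"A": 0.9, "B": 0.5, "C": 0.7},
            "s2": {"A": 0.2, "B": 0.8, "C": 0.6},
        }
        frac = {
            "s1": {"A": 0.1, "B": 0.9, "C": 0.5},
            "s2": {"A": 0.6, "B": 0.3, "C": 0.9},
        }
        profs = self._profiles(corr, frac)
        _, final, _ = rank_candidates(profs, ["A", "B", "C"])

        def rank_of(d, g):
            vals = sorted(d.values(), reverse=True)
            return vals.index(d[g]) + 1

        for g in "ABC":
            ranks = [
                rank_of(corr["s1"], g),
                rank_of(frac["s1"], g),
                rank_of(corr["s2"], g),
                rank_of(frac["s2"], g),
            ]
            assert final[g] == pytest.approx(float(np.prod(ranks)) ** 0.25)

    def test_ties_get_average_rank(self):
        profs = self._profiles(
            {"s": {"A": 0.5, "B": 0.5, "C": 0.5}},
            {"s": {"A": 0.9, "B": 0.8, "C": 0.7}},
        )
        component, _, _ = rank_candidates(profs, ["A", "B", "C"])
        assert set(component["s|corr_rank"]) == {2.0}  # (m + 1) / 2


class TestRunDeca:
    def _matrix(self, rng, n_genes=12, n_comps=8):
        de = rng.normal(size=(n_genes, n_comps))
        p = rng.uniform(size=(n_genes, n_comps))
        p[:3, :5] = 0.001  # first three genes usable as seeds
        return de_matrix(de, p)

    def test_two_n_ranks(self, rng):
        m = self._matrix(rng)
        cfg = DecaConfig(selection_threshold=0.2)
        res = run_deca(m, ["g0", "g1", "g2"], cfg)
        assert res.component_ranks.shape[1] == 6
        res2 = run_deca(m, ["g0", "g1"], cfg)
        assert res2.component_ranks.shape[1] == 4

    def test_seeds_not_in_ranking(self, rng):
        m = self._matrix(rng)
        res = run_deca(m, ["g0", "g1"], DecaConfig(selection_threshold=0.2))
        assert not ({"g0", "g1"} & set(res.ordering))
        assert set(res.universe) == set(m.gene_ids) - {"g0", "g1"}

    def test_failing_seed_named(self, rng):
        m = self._matrix(rng)
        with pytest.raises(ValidationError, match="g11"):
            run_deca(m, ["g0", "g11"])

    def test_rank_sums_and_bounds(self, rng):
        m = self._matrix(rng)
        res = run_deca(m, ["g0", "g1", "g2"], DecaConfig(selection_threshold=0.2))
        mm = len(res.selected_genes)
        assert mm > 0
        for col in res.component_ranks.columns:
            assert res.component_ranks[col].sum() == pytest.approx(mm * (mm + 1) / 2)
        assert ((res.final_ranks >= 1) & (res.final_ranks <= mm)).all()
        assert sorted(res.ordering) == sorted(res.selected_genes)

    def test_permutation_invariance(self, rng):
        m = self._matrix(rng)
        cfg = DecaConfig(selection_threshold=0.2)
        res = run_deca(m, ["g0", "g1", "g2"], cfg)
        gene_perm = list(rng.permutation(m.gene_ids))
        comp_perm = list(rng.permutation(m.comparison_ids))
        shuffled = DEMatrix(
            m.de.loc[gene_perm, comp_perm], m.p.loc[gene_perm, comp_perm]
        )
        res2 = run_deca(shuffled, ["g0", "g1", "g2"], cfg)
        assert res.ordering == res2.ordering
        assert set(res.selected_genes) == set(res2.selected_genes)
        pd.testing.assert_series_equal(
            res.final_ranks.sort_index(), res2.final_ranks.sort_index()
        )


def test_config_validation():
    with pytest.raises(ValidationError):
        DecaConfig(sig_alpha=0.0)
    with pytest.raises(ValidationError):
        DecaConfig(selection_threshold=1.0)
    with pytest.raises(ValidationError):
        DecaConfig(selection_mode="some")
    assert DecaConfig().selection_threshold == 0.6
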