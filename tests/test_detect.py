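"""Tests for diallel dominance ordination and ASE reversal calling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from domrev.detect import (
    AseGeneCounts,
    DiallelData,
    array_covariance,
    array_covariances,
    ase_imbalance_test,
    classify_ase_reversal,
    dominance_ordination,
)
from domrev.synthdata import DiallelSimSpec, preset_fixtures, simulate_diallel


def _diallel_from_matrix(values: dict, context="A") -> pd.DataFrame:
    rows = []
    for (a, b), v in values.items():
        rows.append((a, b, context, 1, v))
    return pd.DataFrame(
        rows, columns=["strain_a", "strain_b", "context", "replicate", "phenotype"]
    )


def additive_diallel(selfs: dict, contexts=("A", "B")) -> DiallelData:
    frames = []
    for ctx in contexts:
        vals = {
            (a, b): 0.5 * (va + vb)
            for a, va in selfs.items()
            for b, vb in selfs.items()
        }
        frames.append(_diallel_from_matrix(vals, ctx))
    return DiallelData(pd.concat(frames, ignore_index=True))


class TestDiallelData:
    def test_missing_selfs_rejected(self):
        tbl = _diallel_from_matrix({("a", "b"): 1.0, ("b", "c"): 2.0, ("a", "c"): 1.5,
                                    ("a", "a"): 0.0, ("b", "b"): 2.0})
        with pytest.raises(ValueError, match="selfs missing"):
            DiallelData(tbl)

    def test_fewer_than_three_strains_rejected(self):
        tbl = _diallel_from_matrix({("a", "a"): 0.0, ("b", "b"): 1.0, ("a", "b"): 0.5})
        with pytest.raises(ValueError, match="3 strains"):
            DiallelData(tbl)

    def test_cross_means_average_reciprocals_and_replicates(self):
        rows = [
            ("a", "b", "A", 1, 1.0),
            ("b", "a", "A", 1, 3.0),
            ("a", "b", "A", 2, 2.0),
            ("a", "a", "A", 1, 0.0),
            ("b", "b", "A", 1, 0.0),
            ("c", "c", "A", 1, 0.0),
            ("a", "c", "A", 1, 1.0),
            ("b", "c", "A", 1, 1.0),
        ]
        data = DiallelData(pd.DataFrame(rows, columns=["strain_a", "strain_b", "context", "replicate", "phenotype"]))
        mat = data.cross_means("A")
        assert mat.loc["a", "b"] == pytest.approx(2.0)
        assert mat.loc["b", "a"] == pytest.approx(2.0)

    def test_tsv_round_trip(self, tmp_path):
        data = additive_diallel({"a": 0.0, "b": 2.0, "c": 6.0})
        path = tmp_path / "diallel.tsv"
        data.to_tsv(path)
        back = DiallelData.from_tsv(path)
        pd.testing.assert_frame_equal(back.table, data.table)


class TestArrayCovariance:
    def test_additive_diallel_gives_half_self_variance(self):
        """Under pure additivity every array covariance equals half the
        variance of the self values (brute-force checked)."""
        selfs = {"a": 0.0, "b": 2.0, "c": 6.0, "d": 3.0}
        data = additive_diallel(selfs)
        expected = 0.5 * np.var(list(selfs.values()), ddof=1)
        W = array_covariances(data, "A")
        for r in selfs:
            assert W[r] == pytest.approx(expected)
        # brute-force oracle for one strain
        v = selfs
        arr = [0.5 * (v["b"] + v[s]) for s in sorted(v)]
        sv = [v[s] for s in sorted(v)]
        assert W["b"] == pytest.approx(np.cov(arr, sv, ddof=1)[0, 1])

    def test_shift_invariance(self):
        data = additive_diallel({"a": 0.0, "b": 2.0, "c": 6.0})
        shifted = DiallelData(
            data.table.assign(phenotype=data.table.phenotype + 100.0)
        )
        pd.testing.assert_series_equal(
            array_covariances(data, "A"), array_covariances(shifted, "A")
        )

    def test_fully_dominant_strain_has_zero_covariance(self):
        """If strain 1 dominates every cross, its array is constant and
        W_1 = 0."""
        selfs = {"s1": 5.0, "s2": 1.0, "s3": 9.0}
        vals = {}
        for a, b in itertools.product(selfs, repeat=2):
            if "s1" in (a, b) :
                vals[(a, b)] = selfs["s1"]
            else:
                vals[(a, b)] = 0.5 * (selfs[a] + selfs[b])
        data = DiallelData(_diallel_from_matrix(vals))
        assert array_covariance(data, "s1", "A") == pytest.approx(0.0, abs=1e-12)

    def test_unknown_strain_rejected(self):
        data = additive_diallel({"a": 0.0, "b": 2.0, "c": 6.0})
        with pytest.raises(KeyError, match="unknown strain"):
            array_covariance(data, "zz", "A")


class TestDominanceOrdination:
    def test_identical_w_vectors_correlate_perfectly(self, rng):
        spec = DiallelSimSpec(n_strains=8, dominance_mode="unconditional",
                              noise_sd=0.0, replicates=1, seed=5)
        data, _ = simulate_diallel(spec)
        # duplicate one context's phenotypes into the other
        tbl = data.table.copy()
        a = tbl[tbl.context == "A"].copy()
        b = a.copy()
        b["context"] = "B"
        dup = DiallelData(pd.concat([a, b], ignore_index=True))
        res = dominance_ordination(dup, n_perm=200, rng=rng)
        assert res.correlation == pytest.approx(1.0)

    def test_reversed_dominance_correlates_negatively(self, rng):
        """Context-reversed dominance orders the strains oppositely in the
        two contexts, so the W vectors anticorrelate."""
        spec = DiallelSimSpec(
            n_strains=12,
            dominance_mode="dominance_reversed",
            noise_sd=0.0,
            replicates=1,
            seed=5,
        )
        data, _ = simulate_diallel(spec)
        res = dominance_ordination(data, n_perm=200, rng=rng)
        assert res.correlation < -0.5

    def test_additive_data_flagged_degenerate(self, rng):
        data = additive_diallel({"a": 0.0, "b": 2.0, "c": 6.0, "d": 1.0})
        res = dominance_ordination(data, n_perm=100, rng=rng)
        assert res.degenerate
        assert np.isnan(res.correlation)

    def test_affine_rescaling_per_context_leaves_result_unchanged(self, rng):
        spec = DiallelSimSpec(n_strains=10, seed=3)
        data, _ = simulate_diallel(spec)
        tbl = data.table.copy()
        tbl.loc[tbl.context == "A", "phenotype"] = (
            3.0 * tbl.loc[tbl.context == "A", "phenotype"] + 7.0
        )
        tbl.loc[tbl.context == "B", "phenotype"] = (
            0.25 * tbl.loc[tbl.context == "B", "phenotype"] - 2.0
        )
        r0 = dominance_ordination(data, n_perm=50, rng=np.random.default_rng(0))
        r1 = dominance_ordination(
            DiallelData(tbl), n_perm=50, rng=np.random.default_rng(0)
        )
        assert r1.correlation == pytest.approx(r0.correlation)
        assert r1.p_value == pytest.approx(r0.p_value)

    def test_permutation_p_within_bounds(self, rng):
        spec = DiallelSimSpec(n_strains=8, seed=1)
        data, _ = simulate_diallel(spec)
        res = dominance_ordination(data, n_perm=500, rng=rng)
        assert 0.0 < res.p_value <= 1.0


class TestAseImbalanceTest:
    def test_balanced_counts(self):
        est, p = ase_imbalance_test(50, 50)
        assert est == 0.5
        assert p == 1.0

    def test_zero_depth_missing(self):
        est, p = ase_imbalance_test(0, 0)
        assert np.isnan(est) and np.isnan(p)

    def test_extreme_imbalance_against_pmf_oracle(self):
        est, p = ase_imbalance_test(90, 10)
        # two-sided exact binomial tail by direct pmf summation
        pmf = stats.binom.pmf(np.arange(101), 100, 0.5)
        oracle = pmf[pmf <= pmf[90] * (1 + 1e-12)].sum()
        assert p == pytest.approx(oracle, rel=1e-9)
        assert p < 1e-10

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ase_imbalance_test(-1, 5)


def ase_table(rows):
    recs = []
    for gene, (a1c1, a2c1, a1c2, a2c2) in rows.items():
        recs.append((gene, "context1", a1c1, a2c1))
        recs.append((gene, "context2", a1c2, a2c2))
    return AseGeneCounts(
        pd.DataFrame(recs, columns=["gene", "context", "allele1_count", "allele2_count"])
    )


class TestClassifyAseReversal:
    def test_spec_examples(self):
        counts = ase_table(
            {
                "rev": (90, 10, 10, 90),
                "ctx": (90, 10, 55, 45),
                "cons": (90, 10, 90, 10),
            }
        )
        calls = classify_ase_reversal(counts, alpha=0.05, mt_method="none")
        got = calls.table.set_index("gene")["classification"]
        assert got["rev"] == "reversal"
        assert got["ctx"] == "context_dependent"
        assert got["cons"] == "consistent_imbalance"

    def test_same_direction_never_reversal_exhaustive(self):
        """Hard rule: same-side imbalance estimates are never a reversal,
        whatever the p-values -- enumerated over a full small count grid."""
        depth = 20
        rows = {}
        i = 0
        for a1 in range(depth + 1):
            for b1 in range(depth + 1):
                rows[f"g{i}"] = (a1, depth - a1, b1, depth - b1)
                i += 1
        calls = classify_ase_reversal(ase_table(rows), alpha=0.5, mt_method="none")
        t = calls.table
        same_side = ((t.est_c1 - 0.5) * (t.est_c2 - 0.5)) >= 0
        assert (t.loc[same_side, "classification"] != "reversal").all()
        # and opposite significant imbalances are called
        strong = (t.est_c1 > 0.9) & (t.est_c2 < 0.1)
        assert (t.loc[strong, "classification"] == "reversal").all()

    def test_zero_depth_gene_skipped_with_reason(self):
        counts = ase_table({"ok": (30, 10, 10, 30), "empty": (0, 0, 20, 20)})
        calls = classify_ase_reversal(counts, mt_method="none")
        assert "empty" in set(calls.skipped["gene"])
        assert "zero depth" in calls.skipped.iloc[0]["reason"]
        assert set(calls.table["gene"]) == {"ok"}

    def test_missing_context_gene_skipped(self):
        tbl = pd.DataFrame(
            [
                ("g1", "context1", 30, 10),
                ("g1", "context2", 10, 30),
                ("g2", "context1", 30, 10),
            ],
            columns=["gene", "context", "allele1_count", "allele2_count"],
        )
        calls = classify_ase_reversal(AseGeneCounts(tbl))
        assert "g2" in set(calls.skipped["gene"])

    def test_bh_adjustment_within_context(self):
        counts = ase_table({f"null{i}": (50, 50, 50, 50) for i in range(20)} | {"hot": (95, 5, 5, 95)})
        calls = classify_ase_reversal(counts, alpha=0.05, mt_method="bh")
        t = calls.table.set_index("gene")
        assert t.loc["hot", "classification"] == "reversal"
        assert (t.drop("hot").classification == "none").all()

    def test_invalid_method_rejected(self):
        with pytest.raises(ValueError, match="mt_method"):
            classify_ase_reversal(ase_table({"g": (1, 1, 1, 1)}), mt_method="holm")


class TestPresetFixtures:
    def test_ase_fixture_classifies_to_truth(self):
        counts = preset_fixtures("ase_10gene")
        calls = classify_ase_reversal(counts, alpha=0.05, mt_method="none")
        truth = counts.table.drop_duplicates("gene").set_index("gene")["truth"]
        got = calls.table.set_index("gene")["classification"]
        for gene in truth.index:
            assert got[gene] == truth[gene]

    def test_additive_diallel_fixture_degenerate(self):
        data = preset_fixtures("diallel_additive_3strain")
        res = dominance_ordination(data, n_perm=50, rng=np.random.default_rng(1))
        assert res.degenerate

    def test_unknown_fixture_lists_available(self):
        with pytest.raises(KeyError, match="available"):
            preset_fixtures("nope")
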