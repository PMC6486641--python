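"""Beta-binomial Wald testing, DMR aggregation and gene-distance analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hapmet.dmr import (  # noqa: test_sites aliased to avoid pytest collection
    CONTRASTS,
    DMRParams,
    build_count_matrix,
    call_dmrs,
    distance_to_nearest_dmr,
    estimate_dispersion,
    run_contrasts,
    test_sites as wald_test_sites,
)

SAMPLES = ("b6_mat", "cast_mat", "cast_pat", "b6_pat")
G1, G2 = ("b6_mat", "cast_mat"), ("cast_pat", "b6_pat")


def count_matrix(N, X, start_step=100):
    """N, X: arrays (sites, 4) ordered as SAMPLES."""
    N, X = np.atleast_2d(N), np.atleast_2d(X)
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "group_start": np.arange(N.shape[0]) * start_step,
            "group_end": np.arange(N.shape[0]) * start_step + 2,
        }
    )
    for j, s in enumerate(SAMPLES):
        df[f"N_{s}"] = N[:, j]
        df[f"X_{s}"] = X[:, j]
    return df


def beta_binomial(rng, n, p, phi, size):
    if phi <= 0:
        return rng.binomial(n, p, size=size)
    ab = 1.0 / phi - 1.0
    pk = rng.beta(p * ab, (1 - p) * ab, size=size)
    return rng.binomial(n, pk)


class TestCountMatrix:
    def _summaries(self, beta_sum=7.4, n_reads=10):
        return pd.DataFrame(
            {
                "chrom": ["chr1"],
                "group_start": [100],
                "group_end": [105],
                "sample": ["b6_mat"],
                "n_reads": [n_reads],
                "beta_sum": [beta_sum],
            }
        )

    def test_rounding(self):
        m = build_count_matrix(self._summaries(7.4, 10))
        assert m["N_b6_mat"].iloc[0] == 10 and m["X_b6_mat"].iloc[0] == 7

    def test_saturated(self):
        m = build_count_matrix(self._summaries(10.0, 10))
        assert m["X_b6_mat"].iloc[0] == 10

    def test_clamped(self):
        m = build_count_matrix(self._summaries(10.6, 10))
        assert m["X_b6_mat"].iloc[0] == 10

    def test_absent_sample_zero(self):
        m = build_count_matrix(self._summaries())
        assert m["N_cast_pat"].iloc[0] == 0


class TestSiteTest:
    def test_identical_groups_null(self):
        N = np.full((1, 4), 20)
        X = np.full((1, 4), 10)
        res = wald_test_sites(count_matrix(N, X), G1, G2)
        assert res["wald_stat"].iloc[0] == pytest.approx(0.0)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)
        assert res["effect"].iloc[0] == 0.0

    def test_hand_computed_wald(self):
        # group1 fully methylated, group2 fully unmethylated, phi = 0
        N = np.array([[30, 30, 30, 30]])
        X = np.array([[30, 30, 0, 0]])
        res = wald_test_sites(count_matrix(N, X), G1, G2, dispersion=np.array([0.0]))
        # independent evaluation of the stated formulas
        y_hi = np.arcsin(2 * 30.5 / 31 - 1)
        y_lo = np.arcsin(2 * 0.5 / 31 - 1)
        var = (1 + 29 * 0.0) / 30
        se = np.sqrt(2 * var / 4 + 2 * var / 4)
        expected = (y_hi - y_lo) / se
        assert res["wald_stat"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert res["effect"].iloc[0] == pytest.approx(1.0)

    def test_label_swap_negates(self, rng):
        N = rng.integers(5, 30, size=(50, 4))
        X = rng.binomial(N, 0.4)
        m = count_matrix(N, X)
        a = wald_test_sites(m, G1, G2)
        b = wald_test_sites(m, G2, G1)
        np.testing.assert_allclose(a["wald_stat"], -b["wald_stat"], rtol=1e-12)
        np.testing.assert_allclose(a["effect"], -b["effect"], rtol=1e-12)
        np.testing.assert_allclose(a["p_value"], b["p_value"], rtol=1e-12)

    def test_uncovered_group_skipped(self):
        N = np.array([[10, 10, 0, 0], [10, 10, 10, 10]])
        X = np.array([[5, 5, 0, 0], [5, 5, 5, 5]])
        res = wald_test_sites(count_matrix(N, X), G1, G2)
        assert len(res) == 1
        assert res["group_start"].iloc[0] == 100

    def test_dispersion_increases_pvalue(self):
        N = np.array([[10, 10, 10, 10]])
        X = np.array([[9, 9, 2, 2]])
        p0 = wald_test_sites(count_matrix(N, X), G1, G2,
                        dispersion=np.array([0.0]))["p_value"].iloc[0]
        p1 = wald_test_sites(count_matrix(N, X), G1, G2,
                        dispersion=np.array([0.3]))["p_value"].iloc[0]
        assert p1 > p0

    def test_null_calibration_quick(self, rng):
        # small-scale check; the full-size calibration lives in acceptance
        N = np.full((4000, 4), 10)
        X = beta_binomial(rng, 10, 0.5, 0.1, size=(4000, 4))
        res = wald_test_sites(count_matrix(N, X), G1, G2)
        frac = float((res["p_value"] < 0.05).mean())
        assert 0.02 < frac < 0.09

    def test_dispersion_moments_recover_truth(self, rng):
        # with many samples per group the MoM estimate should land near phi
        n_samp, phi = 40, 0.15
        N = np.full((2000, n_samp), 30)
        X = beta_binomial(rng, 30, 0.5, phi, size=(2000, n_samp))
        est = estimate_dispersion(N, X, groups=[np.arange(n_samp)])
        assert np.median(est) == pytest.approx(phi, rel=0.25)


def results_frame(p_values, starts=None, effects=None, wald=None):
    n = len(p_values)
    starts = np.arange(n) * 80 if starts is None else np.asarray(starts)
    p = np.asarray(p_values, dtype=float)
    if wald is None:
        wald = np.abs(stats.norm.isf(p / 2))
        wald = wald * (np.ones(n) if effects is None else np.sign(effects))
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "group_start": starts,
            "group_end": starts + 2,
            "effect": effects if effects is not None else np.full(n, 0.5),
            "wald_stat": wald,
            "p_value": p,
        }
    )


class TestCallDmrs:
    def test_no_significant_sites(self):
        res = results_frame([0.5] * 10)
        assert len(call_dmrs(res)) == 0

    def test_five_adjacent_sites(self):
        res = results_frame([1e-8] * 5)
        dmrs = call_dmrs(res)
        assert len(dmrs) == 1
        d = dmrs.iloc[0]
        assert d["n_sites"] == 5
        assert (d["start"], d["end"]) == (0, 322)

    def test_min_sites_rejected(self):
        res = results_frame([1e-8, 1e-8, 0.5, 0.5, 0.5])
        assert len(call_dmrs(res)) == 0

    def test_min_len_rejected(self):
        res = results_frame([1e-8] * 3, starts=np.array([0, 10, 20]))
        assert len(call_dmrs(res)) == 0  # span 22 bp < 50

    def test_merge_gap_splits(self):
        starts = np.array([0, 60, 120, 500, 560, 620])
        res = results_frame([1e-8] * 6, starts=starts)
        dmrs = call_dmrs(res)
        assert len(dmrs) == 2  # 120->500 gap exceeds 100 bp

    def test_sign_change_splits(self):
        effects = np.array([0.5, 0.5, 0.5, -0.5, -0.5, -0.5])
        res = results_frame([1e-8] * 6, effects=effects)
        dmrs = call_dmrs(res)
        assert len(dmrs) == 2
        assert set(np.sign(dmrs["mean_diff"])) == {-1.0, 1.0}

    def test_frac_significant_rule(self):
        # 3 significant of 7 spanning sites: fraction < 0.5 -> rejected
        p = [1e-8, 0.5, 0.5, 0.5, 0.5, 1e-8, 1e-8]
        assert len(call_dmrs(results_frame(p))) == 0

    def test_area_stat_and_rank(self, rng):
        p = np.concatenate([[1e-9] * 4, [0.9] * 5, [1e-6] * 3])
        res = results_frame(p)
        dmrs = call_dmrs(res)
        assert len(dmrs) == 2
        # ranked by |area| descending; area equals recomputed member sum
        assert list(dmrs["rank"]) == [1, 2]
        for row in dmrs.itertuples():
            members = res[
                (res["group_start"] >= row.start) & (res["group_end"] <= row.end)
            ]
            assert row.area_stat == pytest.approx(members["wald_stat"].sum())
        assert dmrs["area_stat"].abs().is_monotonic_decreasing


class TestContrasts:
    def _matrix_with_block(self, rng, kind):
        n = 60
        N = np.full((n, 4), 30)
        X = beta_binomial(rng, 30, 0.5, 0.01, size=(n, 4))
        block = slice(20, 40)
        hi, lo = 0.95, 0.05
        if kind == "poo":  # maternal high in both crosses
            X[block, 0] = beta_binomial(rng, 30, hi, 0.01, size=20)  # b6_mat
            X[block, 1] = beta_binomial(rng, 30, hi, 0.01, size=20)  # cast_mat
            X[block, 2] = beta_binomial(rng, 30, lo, 0.01, size=20)
            X[block, 3] = beta_binomial(rng, 30, lo, 0.01, size=20)
        else:  # B6 allele high in both crosses
            X[block, 0] = beta_binomial(rng, 30, hi, 0.01, size=20)  # b6_mat
            X[block, 3] = beta_binomial(rng, 30, hi, 0.01, size=20)  # b6_pat
            X[block, 1] = beta_binomial(rng, 30, lo, 0.01, size=20)
            X[block, 2] = beta_binomial(rng, 30, lo, 0.01, size=20)
        return count_matrix(N, X, start_step=60)

    def test_parent_of_origin_block(self, rng):
        out = run_contrasts(self._matrix_with_block(rng, "poo"))
        assert len(out["parent_of_origin"]) >= 1
        assert len(out["strain"]) == 0
        d = out["parent_of_origin"].iloc[0]
        assert d["start"] < 40 * 60 and d["end"] > 20 * 60
        assert d["mean_diff"] > 0

    def test_strain_block(self, rng):
        out = run_contrasts(self._matrix_with_block(rng, "strain"))
        assert len(out["strain"]) >= 1
        assert len(out["parent_of_origin"]) == 0

    def test_missing_sample_fatal(self, rng):
        m = self._matrix_with_block(rng, "poo").drop(columns=["N_b6_pat"])
        with pytest.raises(ValueError, match="b6_pat"):
            run_contrasts(m)


class TestDistance:
    def _dmrs(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [12_000, 50_000, 1_000],
                "end": [12_500, 51_000, 2_000],
                "rank": [1, 2, 3],
            }
        )

    def test_overlap_zero(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [12_200], "end": [13_000],
             "name": ["g"], "gene_class": ["biased"]}
        )
        table, _ = distance_to_nearest_dmr(genes, self._dmrs())
        assert table["distance"].iloc[0] == 0

    def test_gap_distance(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [10_000], "end": [11_000],
             "name": ["g"], "gene_class": ["biased"]}
        )
        table, _ = distance_to_nearest_dmr(genes, self._dmrs())
        assert table["distance"].iloc[0] == 1_000

    def test_chromosome_without_dmr(self):
        genes = pd.DataFrame(
            {"chrom": ["chrX"], "start": [0], "end": [100],
             "name": ["g"], "gene_class": ["biased"]}
        )
        table, medians = distance_to_nearest_dmr(genes, self._dmrs())
        assert np.isinf(table["distance"].iloc[0])
        assert medians == {}

    def test_matches_all_pairs_oracle(self, rng):
        genes = pd.DataFrame(
            {
                "chrom": ["chr1"] * 5,
                "start": rng.integers(0, 100_000, 5),
                "name": [f"g{i}" for i in range(5)],
                "gene_class": ["biased", "biased", "unbiased", "unbiased",
                               "unbiased"],
            }
        )
        genes["end"] = genes["start"] + 2_000
        dmrs = self._dmrs()
        table, medians = distance_to_nearest_dmr(genes, dmrs)
        for row in table.itertuples():
            best = np.inf
            for d in dmrs[dmrs["chrom"] == row.chrom].itertuples():
                if d.start < row.end and d.end > row.start:
                    best = 0
                else:
                    best = min(best, max(d.start - row.end, row.start - d.end))
            assert row.distance == best
        expected = table.groupby("gene_class")["distance"].median().to_dict()
        assert medians == expected

    def test_top_k_restriction(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [49_000], "end": [49_500],
             "name": ["g"], "gene_class": ["biased"]}
        )
        # with K=1 only the rank-1 DMR at 12k remains
        table, _ = distance_to_nearest_dmr(genes, self._dmrs(), top_k=1)
        assert table["distance"].iloc[0] == 49_000 - 12_500
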