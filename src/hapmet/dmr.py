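"""Differentially methylated region detection between haplotype-samples.

A reciprocal F1 cross yields four haplotype-samples (maternal and paternal
allele of each cross).  Comparing {maternal, maternal} vs {paternal,
paternal} isolates parent-of-origin effects; {strain A alleles} vs {strain B
alleles} isolates strain effects.  Per CpG call group, methylated and total
read counts per sample feed a two-group beta-binomial test in the spirit of
DSS: the methylation proportion is variance-stabilised with the arcsine
transform

    Y = arcsin(2 * (X + 0.5) / (N + 1) - 1),

whose delta-method variance under beta-binomial counts is
(1 + (N - 1) * phi) / N with dispersion phi.  A Wald statistic on the
difference of group means of Y, with phi estimated per site by method of
moments and shrunk toward the genome-wide mean, gives a two-sided normal
p-value.  Runs of significant sites are merged into regions and ranked by
the area statistic (sum of member Wald statistics).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

P_THRESHOLD = 1e-5
MIN_SITES = 3
MIN_LEN = 50
MERGE_GAP = 100
MIN_FRAC_SIGNIFICANT = 0.5
TOP_K_DMRS = 400

#: Sample names of the standard reciprocal-cross design, as
#: (cross, parent, strain) -> column label.
STANDARD_SAMPLES = ("b6_mat", "cast_pat", "cast_mat", "b6_pat")
PARENT_OF_ORIGIN = "parent_of_origin"
STRAIN = "strain"
CONTRASTS = {
    PARENT_OF_ORIGIN: (("b6_mat", "cast_mat"), ("cast_pat", "b6_pat")),
    STRAIN: (("b6_mat", "b6_pat"), ("cast_pat", "cast_mat")),
}


def build_count_matrix(
    summaries: pd.DataFrame, samples: tuple[str, ...] = STANDARD_SAMPLES
) -> pd.DataFrame:
    """Pivot per-(group, sample) summaries into a count matrix.

    ``summaries`` needs columns chrom, group_start, group_end, sample,
    n_reads, beta_sum.  Per entry, N is the read count and X the rounded
    sum of per-read betas, clamped to [0, N] — the rounding preserves the
    probabilistic methylation mass rather than thresholding each read.
    Missing (group, sample) entries become N = X = 0.
    """
    df = summaries.copy()
    df["X"] = np.clip(np.round(df["beta_sum"]), 0, df["n_reads"]).astype(int)
    idx = ["chrom", "group_start", "group_end"]
    n = df.pivot_table(index=idx, columns="sample", values="n_reads", fill_value=0)
    x = df.pivot_table(index=idx, columns="sample", values="X", fill_value=0)
    out = pd.DataFrame(index=n.index)
    for s in samples:
        out[f"N_{s}"] = n[s].astype(int) if s in n.columns else 0
        out[f"X_{s}"] = x[s].astype(int) if s in x.columns else 0
    return out.reset_index().sort_values(idx, kind="mergesort").reset_index(drop=True)


def _arcsine(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.arcsin(2.0 * (x + 0.5) / (n + 1.0) - 1.0)


def estimate_dispersion(
    N: np.ndarray,
    X: np.ndarray,
    groups: list[np.ndarray] | None = None,
    shrink_weight_scale: float = 4.0,
) -> np.ndarray:
    """Per-site beta-binomial dispersion, method of moments with shrinkage.

    Pooled *within-group* residual variance of the arcsine values (residuals
    around each group's mean, so a genuine between-group difference does not
    inflate the estimate) is equated to its expectation
    mean_k[(1 + (N_k - 1) phi) / N_k] and solved for phi.  Raw estimates
    from a handful of samples are unusable alone, so each is shrunk toward
    the genome-wide mean with weight w = n / (n + c), n the number of
    covered samples at the site and c = ``shrink_weight_scale``.
    """
    N = np.asarray(N, dtype=float)
    X = np.asarray(X, dtype=float)
    if groups is None:
        groups = [np.arange(N.shape[1])]
    covered = N > 0
    n_cov = covered.sum(axis=1)
    Y = _arcsine(X, N)
    Y = np.where(covered, Y, np.nan)
    ss = np.zeros(N.shape[0])
    df = np.zeros(N.shape[0])
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN group slices
        for g in groups:
            resid = Y[:, g] - np.nanmean(Y[:, g], axis=1, keepdims=True)
            ss += np.nansum(resid**2, axis=1)
            df += np.maximum(covered[:, g].sum(axis=1) - 1, 0)
    v_hat = ss / np.maximum(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_n = np.where(covered, 1.0 / N, np.nan)
        slope = np.where(covered, (N - 1.0) / N, np.nan)
    mean_inv_n = np.nanmean(inv_n, axis=1)
    mean_slope = np.nanmean(slope, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_raw = (v_hat - mean_inv_n) / mean_slope
    phi_raw = np.clip(np.nan_to_num(phi_raw, nan=0.0), 0.0, 0.999)
    phi_bar = float(phi_raw[df > 0].mean()) if (df > 0).any() else 0.0
    w = n_cov / (n_cov + shrink_weight_scale)
    return w * phi_raw + (1.0 - w) * phi_bar


def test_sites(
    matrix: pd.DataFrame,
    group1: tuple[str, ...],
    group2: tuple[str, ...],
    dispersion: np.ndarray | None = None,
) -> pd.DataFrame:
    """Two-group Wald test per call group (vectorised over sites).

    The coefficient is the difference of group means of the arcsine-
    transformed proportions; its standard error combines the per-sample
    variances (1 + (N - 1) phi) / N.  Sites lacking a covered sample in
    either group are skipped.  Returns chrom, group_start, group_end,
    effect (proportion scale, group1 - group2), wald_stat, p_value,
    dispersion.
    """
    samples = list(group1) + list(group2)
    N = matrix[[f"N_{s}" for s in samples]].to_numpy(dtype=float)
    X = matrix[[f"X_{s}" for s in samples]].to_numpy(dtype=float)
    g1 = np.arange(len(group1))
    g2 = np.arange(len(group1), len(samples))
    if dispersion is None:
        dispersion = estimate_dispersion(N, X, groups=[g1, g2])
    phi = np.asarray(dispersion, dtype=float)
    covered = N > 0
    ok = covered[:, g1].any(axis=1) & covered[:, g2].any(axis=1)
    keep_idx = np.flatnonzero(ok)
    N, X, phi, covered = N[ok], X[ok], phi[ok], covered[ok]

    Y = np.where(covered, _arcsine(X, N), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.where(covered, (1.0 + (N - 1.0) * phi[:, None]) / N, np.nan)
        mu1 = np.nanmean(Y[:, g1], axis=1)
        mu2 = np.nanmean(Y[:, g2], axis=1)
        m1 = covered[:, g1].sum(axis=1)
        m2 = covered[:, g2].sum(axis=1)
        se = np.sqrt(
            np.nansum(var[:, g1], axis=1) / m1**2
            + np.nansum(var[:, g2], axis=1) / m2**2
        )
        wald = (mu1 - mu2) / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    # Effect on the proportion scale from pooled counts per group.
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = X[:, g1].sum(axis=1) / N[:, g1].sum(axis=1)
        p2 = X[:, g2].sum(axis=1) / N[:, g2].sum(axis=1)
    out = matrix.loc[keep_idx, ["chrom", "group_start", "group_end"]].copy()
    out["effect"] = p1 - p2
    out["wald_stat"] = wald
    out["p_value"] = np.clip(p, np.nextafter(0, 1), 1.0)
    out["dispersion"] = phi
    return out.reset_index(drop=True)


@dataclass
class DMRParams:
    p_threshold: float = P_THRESHOLD
    min_sites: int = MIN_SITES
    min_len: int = MIN_LEN
    merge_gap: int = MERGE_GAP
    min_frac_significant: float = MIN_FRAC_SIGNIFICANT


def call_dmrs(
    results: pd.DataFrame,
    params: DMRParams | None = None,
    contrast: str = "",
) -> pd.DataFrame:
    """Aggregate significant sites into ranked regions.

    Significant sites (p < threshold) sharing an effect sign are clustered
    while consecutive significant sites lie within ``merge_gap`` of each
    other; a cluster spans from its first to last significant site and
    includes the intervening non-significant sites.  Clusters survive when
    they hold at least ``min_sites`` sites, span at least ``min_len`` bp and
    at least ``min_frac_significant`` of their member sites are significant.
    The area statistic sums the Wald statistics of all member sites; regions
    are ranked genome-wide by |area statistic|, descending.
    """
    params = params or DMRParams()
    regions = []
    for chrom, sub in results.groupby("chrom", sort=True):
        sub = sub.sort_values("group_start").reset_index(drop=True)
        sig = (sub["p_value"] < params.p_threshold).to_numpy()
        if not sig.any():
            continue
        idx = np.flatnonzero(sig)
        starts = sub["group_start"].to_numpy()
        ends = sub["group_end"].to_numpy()
        signs = np.sign(sub["effect"].to_numpy())
        # Break between consecutive significant sites on distance or sign flip.
        brk = np.flatnonzero(
            (starts[idx[1:]] - ends[idx[:-1]] > params.merge_gap)
            | (signs[idx[1:]] != signs[idx[:-1]])
        ) + 1
        for chunk in np.split(idx, brk):
            lo, hi = chunk[0], chunk[-1]
            member = slice(lo, hi + 1)
            n_sites = hi - lo + 1
            frac_sig = sig[member].sum() / n_sites
            start, end = int(starts[lo]), int(ends[hi])
            if (
                n_sites < params.min_sites
                or end - start < params.min_len
                or frac_sig < params.min_frac_significant
            ):
                continue
            regions.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_sites": int(n_sites),
                    "n_significant": int(sig[member].sum()),
                    "area_stat": float(sub["wald_stat"].to_numpy()[member].sum()),
                    "mean_diff": float(sub["effect"].to_numpy()[member].mean()),
                    "contrast": contrast,
                }
            )
    cols = ["chrom", "start", "end", "n_sites", "n_significant", "area_stat",
            "mean_diff", "contrast", "rank"]
    if not regions:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(regions)
    df = df.sort_values("area_stat", key=lambda s: s.abs(), ascending=False,
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[cols]


def run_contrasts(
    matrix: pd.DataFrame,
    params: DMRParams | None = None,
    contrasts: dict | None = None,
) -> dict[str, pd.DataFrame]:
    """Site tests + region calling for the parent-of-origin and strain contrasts."""
    contrasts = contrasts or CONTRASTS
    for g1, g2 in contrasts.values():
        for s in list(g1) + list(g2):
            if f"N_{s}" not in matrix.columns:
                raise ValueError(
                    f"sample column {s!r} missing from count matrix; have "
                    f"{[c[2:] for c in matrix.columns if c.startswith('N_')]}"
                )
    out = {}
    for name, (g1, g2) in contrasts.items():
        res = test_sites(matrix, g1, g2)
        out[name] = call_dmrs(res, params, contrast=name)
    return out


def distance_to_nearest_dmr(
    genes: pd.DataFrame, dmrs: pd.DataFrame, top_k: int = TOP_K_DMRS
) -> tuple[pd.DataFrame, dict]:
    """Distance from each gene to its nearest top-K DMR, with class medians.

    ``genes``: chrom, start, end, name and optionally ``gene_class`` (e.g.
    allelically biased vs unbiased).  Distance is 0 for overlap, else the
    gap between closest edges.  Genes on chromosomes without any DMR get
    +inf and are excluded from the medians (with a warning).
    """
    top = dmrs.nsmallest(top_k, "rank") if "rank" in dmrs.columns else dmrs
    rows = []
    for row in genes.itertuples(index=False):
        sub = top[top["chrom"] == row.chrom]
        if len(sub) == 0:
            rows.append(np.inf)
            continue
        gap_left = row.start - sub["end"].to_numpy()
        gap_right = sub["start"].to_numpy() - row.end
        d = np.maximum(np.maximum(gap_left, gap_right), 0)
        rows.append(float(d.min()))
    out = genes.copy()
    out["distance"] = rows
    n_inf = int(np.isinf(out["distance"]).sum())
    if n_inf:
        log.warning("%d genes on chromosomes without DMRs excluded from medians",
                    n_inf)
    finite = out[np.isfinite(out["distance"])]
    if "gene_class" in finite.columns:
        medians = finite.groupby("gene_class")["distance"].median().to_dict()
    else:
        medians = {"all": float(finite["distance"].median())}
    return out, medians
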