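"""Probabilistic per-read CpG methylation calls and bisulfite concordance.

Signal-space methylation callers emit, per read and per CpG *call group*, a
pair of likelihoods for the methylated (M) and unmethylated (C) state.  A
call group chains consecutive CpG sites closer than 11 bp — their 6-mer
contexts overlap, so they share one call.  Bayes' rule with a prior p0 on
methylation converts the likelihood pair into a posterior probability

    beta = 1 / (1 + ((1 - p0)/p0) * L_C / L_M),

computed in log space.  The default prior is 0.5, appropriate for tissues
whose global CpG methylation sits near 50% (e.g. mouse placenta).  Group
averages over reads give a bisulfite-comparable per-group beta; comparison
against per-site bisulfite calls requires splitting each group back into
its member cytosines on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_PRIOR = 0.5
MAX_GAP = 11  # adjacent CpG cytosines closer than this share a call group

NANOPORE_THRESHOLD = 0.36  # binary cutoff for nanopore beta values
BISULFITE_THRESHOLD = 0.5  # binary cutoff for bisulfite beta values


@dataclass(frozen=True)
class CpGCallGroup:
    chromosome: str
    sites: tuple  # ordered 0-based positions of the CpG cytosines

    @property
    def span(self) -> tuple[int, int]:
        return self.sites[0], self.sites[-1] + 1


@dataclass(frozen=True)
class MethylationPrior:
    p0: float = DEFAULT_PRIOR

    def __post_init__(self):
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("prior must lie strictly inside (0, 1)")


def beta_from_likelihoods(
    log_lik_methylated,
    log_lik_unmethylated,
    prior: MethylationPrior | float = DEFAULT_PRIOR,
):
    """Posterior methylation probability from a log-likelihood pair.

    Vectorised; works entirely in log space so |llr| > 700 cannot overflow,
    and infinite ratios map exactly to 0 or 1.  The logistic is evaluated
    as (1 + tanh(x/2))/2, whose odd symmetry makes beta(llr) + beta(-llr)
    exactly 1 at an even prior.
    """
    p0 = prior.p0 if isinstance(prior, MethylationPrior) else float(prior)
    if not 0.0 < p0 < 1.0:
        raise ValueError("prior must lie strictly inside (0, 1)")
    llr = np.asarray(log_lik_methylated, dtype=float) - np.asarray(
        log_lik_unmethylated, dtype=float
    )
    x = llr - np.log((1.0 - p0) / p0)
    out = 0.5 * (1.0 + np.tanh(0.5 * x))
    return float(out) if out.ndim == 0 else out


def add_beta(records: pd.DataFrame, prior=DEFAULT_PRIOR) -> pd.DataFrame:
    """Fill the ``beta`` column of a methylation record frame."""
    records = records.copy()
    records["beta"] = beta_from_likelihoods(
        records["log_lik_methylated"].to_numpy(),
        records["log_lik_unmethylated"].to_numpy(),
        prior,
    )
    return records


def chain_call_groups(
    cpg_positions, chromosome: str = "", max_gap: int = MAX_GAP
) -> list[CpGCallGroup]:
    """Greedy left-to-right chaining of sorted CpG positions into call groups.

    Adjacent sites at distance < ``max_gap`` join one group; the result is
    maximal (appending the next genomic CpG to any group would violate the
    gap rule), which makes greedy chaining equal to transitive closure.
    """
    positions = np.asarray(sorted(set(int(p) for p in cpg_positions)))
    if len(positions) == 0:
        return []
    breaks = np.where(np.diff(positions) >= max_gap)[0] + 1
    return [
        CpGCallGroup(chromosome, tuple(chunk))
        for chunk in np.split(positions, breaks)
    ]


@dataclass
class CallGroupSummary:
    chromosome: str
    group_start: int
    group_end: int
    haplotype: str  # maternal | paternal | all
    n_reads: int
    beta_mean: float
    beta_sum: float = field(default=0.0)


def aggregate_group(records: pd.DataFrame, haplotype: str = "all"):
    """Mean beta across the reads covering one call group.

    ``records`` must all share a group span; returns None for zero records
    (no summary is emitted for uncovered groups).
    """
    if records is None or len(records) == 0:
        return None
    spans = set(zip(records["group_start"], records["group_end"]))
    if len(spans) != 1:
        raise ValueError("records span multiple call groups")
    (start, end), = spans
    betas = records["beta"].to_numpy(dtype=float)
    return CallGroupSummary(
        chromosome=str(records["chrom"].iloc[0]),
        group_start=int(start),
        group_end=int(end),
        haplotype=haplotype,
        n_reads=len(betas),
        beta_mean=float(betas.mean()),
        beta_sum=float(betas.sum()),
    )


def aggregate_by_haplotype(
    records: pd.DataFrame, read_haplotypes: pd.DataFrame,
    maternal_is_ref: bool = True,
) -> pd.DataFrame:
    """Per-group, per-haplotype aggregation across reads.

    ``read_haplotypes`` maps read_id to H (+1 reference allele, -1
    alternate, 0 unassigned).  ``maternal_is_ref`` states which parent
    carries the reference-strain genome in this cross (True for a
    reference-strain dam).  H=0 reads contribute to "all" but to neither
    parent.  Returns one row per (group, haplotype) with n_reads, beta_mean
    and beta_sum.
    """
    merged = records.merge(
        read_haplotypes[["read_id", "H"]], on="read_id", how="left"
    )
    merged["H"] = merged["H"].fillna(0).astype(int)
    h_mat = 1 if maternal_is_ref else -1
    frames = []
    for hap, sel in (
        ("maternal", merged["H"] == h_mat),
        ("paternal", merged["H"] == -h_mat),
        ("all", pd.Series(True, index=merged.index)),
    ):
        sub = merged[sel]
        if len(sub) == 0:
            continue
        g = sub.groupby(["chrom", "group_start", "group_end"], sort=True)["beta"].agg(
            ["count", "mean", "sum"]
        )
        g = g.reset_index().rename(
            columns={"count": "n_reads", "mean": "beta_mean", "sum": "beta_sum"}
        )
        g["haplotype"] = hap
        frames.append(g)
    return pd.concat(frames, ignore_index=True)


def split_groups_to_sites(
    summaries: pd.DataFrame, groups: list[CpGCallGroup]
) -> pd.DataFrame:
    """Explode call-group betas to per-cytosine rows for bisulfite comparison.

    Each CpG contributes its forward-strand cytosine and the reverse-strand
    cytosine of the same dinucleotide (position + 1), all inheriting the
    group beta.  ``summaries`` rows are matched to ``groups`` on (chrom,
    span).
    """
    span_to_sites = {(g.chromosome, *g.span): g.sites for g in groups}
    rows = []
    for row in summaries.itertuples(index=False):
        sites = span_to_sites.get((row.chrom, row.group_start, row.group_end))
        if sites is None:
            raise KeyError(
                f"no call group for {row.chrom}:{row.group_start}-{row.group_end}"
            )
        for s in sites:
            rows.append((row.chrom, s, row.beta_mean))
            rows.append((row.chrom, s + 1, row.beta_mean))
    return pd.DataFrame(rows, columns=["chrom", "pos", "beta"]).sort_values(
        ["chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)


def regroup_sites(sites: pd.DataFrame, max_gap: int = MAX_GAP) -> list[CpGCallGroup]:
    """Inverse of :func:`split_groups_to_sites`.

    Split output lists both cytosines of every CpG, so each maximal run of
    consecutive positions is a tiling of {p, p+1} pairs: the forward-strand
    cytosines sit at even offsets from the run start.  Recovering them and
    re-chaining reproduces the original groups.
    """
    groups = []
    for chrom, sub in sites.groupby("chrom", sort=True):
        pos = np.array(sorted(set(sub["pos"])))
        run_breaks = np.where(np.diff(pos) > 1)[0] + 1
        forward = []
        for run in np.split(pos, run_breaks):
            forward.extend(run[::2])
        groups.extend(chain_call_groups(forward, chrom, max_gap))
    return groups


@dataclass(frozen=True)
class ConcordanceSummary:
    n_sites: int
    median_absolute_deviation: float
    quadrant_fractions: tuple  # (both_high, nano_high_only, bs_high_only, both_low)
    binary_agreement: float


def compare_with_bisulfite(
    nanopore_sites: pd.DataFrame,
    bisulfite_sites: pd.DataFrame,
    nanopore_threshold: float = NANOPORE_THRESHOLD,
    bisulfite_threshold: float = BISULFITE_THRESHOLD,
) -> ConcordanceSummary:
    """Concordance between per-site nanopore and bisulfite beta values.

    Only sites present in both inputs are compared.  A site is binary-
    methylated when its beta reaches the technology's threshold; the
    thresholds differ because nanopore betas are biased toward intermediate
    values.  Reports the median absolute deviation of (nanopore −
    bisulfite), the four quadrant fractions and the concordant-quadrant
    fraction.
    """
    merged = nanopore_sites.merge(
        bisulfite_sites, on=["chrom", "pos"], suffixes=("_nano", "_bs")
    )
    if len(merged) == 0:
        raise ValueError("no CpG site shared between nanopore and bisulfite input")
    nano = merged["beta_nano"].to_numpy(dtype=float)
    bs = merged["beta_bs"].to_numpy(dtype=float)
    mad = float(np.median(np.abs(nano - bs)))
    nano_high = nano >= nanopore_threshold
    bs_high = bs >= bisulfite_threshold
    n = len(merged)
    quad = (
        float((nano_high & bs_high).sum()) / n,
        float((nano_high & ~bs_high).sum()) / n,
        float((~nano_high & bs_high).sum()) / n,
        float((~nano_high & ~bs_high).sum()) / n,
    )
    return ConcordanceSummary(
        n_sites=n,
        median_absolute_deviation=mad,
        quadrant_fractions=quad,
        binary_agreement=quad[0] + quad[3],
    )
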