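"""Resolve grand-parental recombination on the maternal genome.

The maternal line carries an FVB-strain contribution one generation back, so
contiguous stretches of the maternal chromosome may derive from FVB rather
than the reference (B6) background.  Reads are haplotyped three ways
(reference/mm10, FVB, CAST); among maternal (non-CAST) reads the fraction
haplotyped to FVB is computed in 100 kb tiling windows and fitted with a
CART-style recursive partition (piecewise-constant, anova splitting,
minsplit=5, cp=0.1).  Segments whose fitted FVB proportion exceeds 50% have
their maternal alleles replaced with the FVB alleles for all further
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotyping import (
    MIN_SNPS,
    aggregate_evidence,
    collect_basecall_observations,
    _sign,
)

log = logging.getLogger(__name__)

WINDOW_SIZE = 100_000
MINSPLIT = 5
CP = 0.1

MM10, FVB, CAST, UNASSIGNED = "mm10", "FVB", "CAST", "unassigned"


@dataclass(frozen=True)
class PartitionSegment:
    chromosome: str
    start: int
    end: int
    mean_fvb: float

    @property
    def label(self) -> str:
        return FVB if self.mean_fvb > 0.5 else "B6"


def three_way_haplotype(
    read, snps_cast: pd.DataFrame, snps_fvb: pd.DataFrame, min_snps: int = MIN_SNPS
) -> str:
    """Label a read mm10 / FVB / CAST / unassigned.

    The two-way scorer runs once per strain table.  A read is CAST when its
    CAST-vs-reference call is alternate; among non-CAST (maternal) reads it
    is FVB when the FVB-vs-reference call is alternate, mm10 when either
    call is confidently reference, and unassigned when neither table yields
    the minimum SNP support.
    """
    ev_cast = aggregate_evidence(
        collect_basecall_observations(read, snps_cast), "basecall"
    )
    ev_fvb = aggregate_evidence(
        collect_basecall_observations(read, snps_fvb), "basecall"
    )
    call_cast = _sign(ev_cast.h) if ev_cast.n >= min_snps else 0
    call_fvb = _sign(ev_fvb.h) if ev_fvb.n >= min_snps else 0
    if call_cast == -1:
        return CAST
    if call_fvb == -1:
        return FVB
    if call_cast == 1 or call_fvb == 1:
        return MM10
    return UNASSIGNED


def window_fvb_fractions(
    labels: pd.DataFrame, window_size: int = WINDOW_SIZE
) -> pd.DataFrame:
    """Per-window FVB fraction among maternal (non-CAST) reads.

    ``labels`` needs columns chrom, start, end, label; reads are binned by
    alignment midpoint into tiling windows from the chromosome start.
    Windows without maternal reads carry NaN and are skipped by the fit.
    Output columns: chrom, window_start, n_maternal_reads, fvb_fraction.
    """
    maternal = labels[labels["label"].isin([MM10, FVB])].copy()
    rows = []
    for chrom, sub in labels.groupby("chrom", sort=True):
        last = int(sub["end"].max())
        n_windows = int(np.ceil(last / window_size)) if last > 0 else 1
        mat = maternal[maternal["chrom"] == chrom]
        mid = ((mat["start"].to_numpy() + mat["end"].to_numpy()) // 2)
        win = np.minimum(mid // window_size, n_windows - 1).astype(int)
        is_fvb = (mat["label"] == FVB).to_numpy()
        n_mat = np.bincount(win, minlength=n_windows)
        n_fvb = np.bincount(win, weights=is_fvb, minlength=n_windows)
        for w in range(n_windows):
            frac = n_fvb[w] / n_mat[w] if n_mat[w] > 0 else np.nan
            rows.append((chrom, w * window_size, int(n_mat[w]), frac))
    return pd.DataFrame(
        rows, columns=["chrom", "window_start", "n_maternal_reads", "fvb_fraction"]
    )


def _best_split(y: np.ndarray) -> tuple[int, float]:
    """Best binary split of ``y`` by within-segment sum of squares.

    Returns (k, gain): split between indices k-1 and k, and the reduction in
    SS relative to the unsplit node.  Vectorised over all breakpoints.
    """
    n = len(y)
    cs = np.cumsum(y)
    cs2 = np.cumsum(y**2)
    ss_node = cs2[-1] - cs[-1] ** 2 / n
    k = np.arange(1, n)
    ss_left = cs2[k - 1] - cs[k - 1] ** 2 / k
    right_sum = cs[-1] - cs[k - 1]
    ss_right = (cs2[-1] - cs2[k - 1]) - right_sum**2 / (n - k)
    gains = ss_node - (ss_left + ss_right)
    i = int(np.argmax(gains))
    return int(k[i]), float(gains[i])


def fit_partition(
    windows: pd.DataFrame,
    minsplit: int = MINSPLIT,
    cp: float = CP,
    window_size: int = WINDOW_SIZE,
    chrom_end: int | None = None,
) -> list[PartitionSegment]:
    """Piecewise-constant fit of window FVB fractions by recursive splitting.

    A node is considered for splitting only if it holds at least ``minsplit``
    windows, and a split is kept only if it reduces the total sum of squares
    by more than ``cp`` times the root sum of squares (rpart's anova
    complexity rule).  Windows with undefined fraction are excluded from the
    fit; segments extend across them.  Segment boundaries fall midway
    between adjacent retained window starts; the outer boundaries cover the
    chromosome extent.
    """
    windows = windows.dropna(subset=["fvb_fraction"])
    if len(windows) == 0:
        raise ValueError("no window with a defined FVB fraction")
    segments: list[PartitionSegment] = []
    for chrom, sub in windows.groupby("chrom", sort=True):
        sub = sub.sort_values("window_start")
        y = sub["fvb_fraction"].to_numpy(dtype=float)
        starts = sub["window_start"].to_numpy(dtype=int)
        root_ss = float(np.sum((y - y.mean()) ** 2))
        # absolute guard so float noise on constant input cannot fake a gain
        tiny = 1e-12 * max(1.0, float(np.sum(y**2)))
        threshold = cp * root_ss + tiny

        leaves: list[tuple[int, int]] = []

        def recurse(lo: int, hi: int) -> None:
            if hi - lo >= minsplit and hi - lo >= 2:
                k, gain = _best_split(y[lo:hi])
                if gain > threshold:
                    recurse(lo, lo + k)
                    recurse(lo + k, hi)
                    return
            leaves.append((lo, hi))

        recurse(0, len(y))
        leaves.sort()
        chrom_hi = chrom_end if chrom_end is not None else int(starts[-1]) + window_size
        for j, (lo, hi) in enumerate(leaves):
            seg_start = 0 if j == 0 else (starts[lo - 1] + starts[lo] + window_size) // 2
            seg_end = (
                chrom_hi
                if j == len(leaves) - 1
                else (starts[hi - 1] + starts[hi] + window_size) // 2
            )
            segments.append(
                PartitionSegment(chrom, seg_start, seg_end, float(y[lo:hi].mean()))
            )
    return segments


def swap_snps(
    snps_maternal: pd.DataFrame,
    snps_fvb: pd.DataFrame,
    segments: list[PartitionSegment],
) -> pd.DataFrame:
    """Patch the maternal SNP table inside FVB-labelled segments.

    Within each segment whose mean FVB proportion exceeds 50%, the maternal
    alleles are taken from the FVB table; outside, the input table passes
    through unchanged.
    """
    fvb_segments = [s for s in segments if s.label == FVB]
    if not fvb_segments:
        return snps_maternal.copy()
    keep = np.ones(len(snps_maternal), dtype=bool)
    take = np.zeros(len(snps_fvb), dtype=bool)
    for seg in fvb_segments:
        in_seg_m = (
            (snps_maternal["chrom"] == seg.chromosome)
            & (snps_maternal["pos"] >= seg.start)
            & (snps_maternal["pos"] < seg.end)
        ).to_numpy()
        keep &= ~in_seg_m
        in_seg_f = (
            (snps_fvb["chrom"] == seg.chromosome)
            & (snps_fvb["pos"] >= seg.start)
            & (snps_fvb["pos"] < seg.end)
        ).to_numpy()
        if not in_seg_f.any():
            log.warning(
                "FVB segment %s:%d-%d contains no FVB SNP record",
                seg.chromosome, seg.start, seg.end,
            )
        take |= in_seg_f
    out = pd.concat([snps_maternal[keep], snps_fvb[take]], ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def segments_to_frame(segments: list[PartitionSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chromosome for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "label": [s.label for s in segments],
            "mean_fvb": [s.mean_fvb for s in segments],
        }
    )
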