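"""Loess-smoothed per-read methylation tracks for haplotype-split plots.

Single-read methylation calls are noisy; for visualization each read's beta
values are smoothed along the genome with degree-1 loess (tricube weights).
The span adapts to read length L so short reads are smoothed harder:

    alpha(L) = 0.1 + 8e-11 * max(1e5 - L, 0)^2

i.e. 0.9 for very short reads, falling to a floor of 0.1 from 100 kb up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

ALPHA_FLOOR = 0.1
ALPHA_COEF = 8e-11
ALPHA_PIVOT = 1e5


def loess_alpha(read_length: float) -> float:
    """Smoothing span as a function of read length in bases."""
    return ALPHA_FLOOR + ALPHA_COEF * max(ALPHA_PIVOT - read_length, 0.0) ** 2


@dataclass
class SmoothedReadTrack:
    read_id: str
    haplotype: str
    read_length: int
    alpha: float
    positions: np.ndarray
    smoothed_beta: np.ndarray


def smooth_read(
    records: pd.DataFrame, read_length: int | None = None, haplotype: str = "all"
) -> SmoothedReadTrack:
    """Smooth one read's call-group betas against genomic position.

    ``records``: the methylation records of a single read with a ``beta``
    column.  Evaluated at call-group midpoints; with fewer than two groups
    the raw points are returned unsmoothed.  The span is clamped to at
    least 2/n so every local fit sees two points, and fitted values are
    clipped to [0, 1].
    """
    read_ids = records["read_id"].unique()
    if len(read_ids) != 1:
        raise ValueError("smooth_read expects records of exactly one read")
    records = records.sort_values("group_start")
    x = ((records["group_start"] + records["group_end"]) / 2).to_numpy(dtype=float)
    y = records["beta"].to_numpy(dtype=float)
    if read_length is None:
        read_length = int(records["group_end"].max() - records["group_start"].min())
    alpha = loess_alpha(read_length)
    if len(x) < 2:
        fitted = y.copy()
    else:
        frac = min(max(alpha, 2.0 / len(x)), 1.0)
        fitted = lowess(y, x, frac=frac, it=0, xvals=x)
        fitted = np.clip(fitted, 0.0, 1.0)
    return SmoothedReadTrack(
        read_id=str(read_ids[0]),
        haplotype=haplotype,
        read_length=int(read_length),
        alpha=alpha,
        positions=x,
        smoothed_beta=fitted,
    )


def tracks_to_frame(tracks: list[SmoothedReadTrack]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for pos, b in zip(t.positions, t.smoothed_beta):
            rows.append((t.read_id, t.haplotype, t.read_length, t.alpha, pos, b))
    return pd.DataFrame(
        rows,
        columns=["read_id", "haplotype", "read_length", "alpha", "pos", "beta"],
    )
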