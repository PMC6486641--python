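"""Per-read haplotype assignment for nanopore long reads.

Each read aligned over known strain SNPs is scored twice: once from the
basecalled sequence (``basecall`` evidence, Phred qualities) and once from
signal-space genotype calls produced by an HMM re-alignment of the raw
current (``signal`` evidence, whose scores live on a shifted scale).  Both
streams share a single empirical score model mapping a quality ``q`` to the
probability that the observed allele is correct,

    S(q) = 1 - exp(-0.6927 - 0.1203 q),

and a read's aggregate haplotype value ``h`` is the mean of ``S`` over
reference-agreeing observations and ``1 - S`` over alternate-agreeing ones,
so ``h > 0.5`` favours the reference (first) haplotype.  The two streams are
reconciled by an ordered rule table requiring at least five informative SNPs
on at least one stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Empirical score-model coefficients, fitted on successfully haplotyped reads.
SCORE_COEF_INTERCEPT = 0.6927
SCORE_COEF_SLOPE = 0.1203

#: Shift applied to signal-space (HMM) quality scores before scoring, so they
#: exhibit the same relationship to correctness as basecall Phred scores.
SIGNAL_QUALITY_OFFSET = 35.0

#: Minimum informative SNP count for a stream to assign a haplotype alone.
MIN_SNPS = 5

#: Dominance factor for the count and confidence tie-break rules.
RATIO_FACTOR = 3.0

REF, ALT, NEITHER, DELETION = "ref", "alt", "neither", "deletion"


@dataclass(frozen=True)
class SNPObservation:
    """One aligned base over a known strain SNP."""

    snp_position: int
    match: str  # ref | alt | neither | deletion
    q: float | None = None
    S: float | None = None

    @property
    def informative(self) -> bool:
        return self.match in (REF, ALT)


@dataclass(frozen=True)
class HaplotypeEvidence:
    """Aggregate per-read evidence from one stream (basecall or signal)."""

    n: int
    h: float | None
    source: str  # basecall | signal

    @classmethod
    def empty(cls, source: str) -> "HaplotypeEvidence":
        return cls(n=0, h=None, source=source)


@dataclass
class HaplotypeAssignment:
    read_id: str
    n_base: int
    h_base: float | None
    n_signal: int
    h_signal: float | None
    H_base: int
    H_signal: int
    H: int  # +1 reference haplotype, -1 alternate, 0 unassigned
    rule_fired: int  # 1..7


def score_snp(q):
    """Probability that an observed allele with quality ``q`` is correct.

    Vectorised over ``q``; ``q`` must be non-negative (apply any offset and
    floor before calling).
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("quality must be >= 0 after offset/flooring")
    out = 1.0 - np.exp(-SCORE_COEF_INTERCEPT - SCORE_COEF_SLOPE * q)
    return float(out) if out.ndim == 0 else out


def collect_basecall_observations(read, snps: pd.DataFrame) -> list[SNPObservation]:
    """Classify every SNP overlapped by ``read`` against ref/alt alleles.

    ``read`` is a pysam AlignedSegment; ``snps`` a SNP table (columns
    ``chrom, pos, ref, alt``) already restricted to the read's chromosome.
    Bases matching neither allele and deletions at the SNP are classified but
    carry no score — the aggregation step excludes them.
    """
    sel = (snps["pos"].values >= read.reference_start) & (
        snps["pos"].values < read.reference_end
    )
    if not sel.any():
        return []
    ref2query: dict[int, int | None] = {}
    for qpos, rpos in read.get_aligned_pairs():
        if rpos is not None:
            ref2query[rpos] = qpos
    seq = read.query_sequence
    quals = read.query_qualities
    out = []
    for pos, ref_allele, alt_allele in zip(
        snps["pos"].values[sel], snps["ref"].values[sel], snps["alt"].values[sel]
    ):
        pos = int(pos)
        qpos = ref2query.get(pos)
        if qpos is None:
            out.append(SNPObservation(pos, DELETION))
            continue
        base = seq[qpos].upper()
        q = float(quals[qpos]) if quals is not None else 0.0
        if base == ref_allele:
            out.append(SNPObservation(pos, REF, q=q, S=score_snp(q)))
        elif base == alt_allele:
            out.append(SNPObservation(pos, ALT, q=q, S=score_snp(q)))
        else:
            out.append(SNPObservation(pos, NEITHER, q=q))
    return out


def aggregate_evidence(
    observations: Iterable[SNPObservation], source: str = "basecall"
) -> HaplotypeEvidence:
    """Mean haplotype value over informative observations.

    Reference-agreeing observations contribute ``S``, alternate-agreeing ones
    ``1 - S``; neither/deletion observations are excluded.  With no
    informative observation, ``h`` is undefined (None).
    """
    contrib = [
        o.S if o.match == REF else 1.0 - o.S
        for o in observations
        if o.informative
    ]
    if not contrib:
        return HaplotypeEvidence.empty(source)
    return HaplotypeEvidence(n=len(contrib), h=float(np.mean(contrib)), source=source)


def signal_evidence(
    records: pd.DataFrame, offset: float = SIGNAL_QUALITY_OFFSET
) -> HaplotypeEvidence:
    """Evidence from signal-space genotype calls of a single read.

    ``records`` needs columns ``allele`` (ref|alt) and ``quality`` (HMM
    scale).  Qualities are shifted by ``-offset`` and floored at 0: the score
    model returns anti-informative values (<0.5) for negative arguments,
    which a correctness score should not do, so sub-offset calls count as
    uninformative-at-worst (S = S(0) ~ 0.5).
    """
    if records is None or len(records) == 0:
        return HaplotypeEvidence.empty("signal")
    q = np.maximum(records["quality"].to_numpy(dtype=float) - offset, 0.0)
    s = score_snp(q)
    is_ref = records["allele"].to_numpy() == REF
    contrib = np.where(is_ref, s, 1.0 - s)
    return HaplotypeEvidence(n=len(contrib), h=float(contrib.mean()), source="signal")


def _sign(h: float | None) -> int:
    """sgn(h - 0.5) with sgn(0) = 0; undefined h maps to 0."""
    if h is None:
        return 0
    if h > 0.5:
        return 1
    if h < 0.5:
        return -1
    return 0


def combine_calls(
    base: HaplotypeEvidence,
    signal: HaplotypeEvidence,
    read_id: str = "",
    min_snps: int = MIN_SNPS,
    ratio: float = RATIO_FACTOR,
) -> HaplotypeAssignment:
    """Combine basecall and signal evidence by the ordered rule table.

    Rules, applied in order (H_x = sgn(h_x - 0.5)):

    1. both n < min_snps                          -> 0
    2. H_base = H_signal (both nonzero)           -> H_base
    3. n_base > ratio * n_signal                  -> H_base
    4. n_signal > ratio * n_base                  -> H_signal
    5. |h_base - 0.5| > ratio * |h_signal - 0.5|  -> H_base
    6. |h_signal - 0.5| > ratio * |h_base - 0.5|  -> H_signal
    7. otherwise                                  -> 0

    Agreement of two uninformative calls (both H = 0) is not treated as
    agreement: rule 2 requires a nonzero shared sign.
    """
    nb, ns = base.n, signal.n
    hb, hs = base.h, signal.h
    Hb, Hs = _sign(hb), _sign(hs)
    db = abs(hb - 0.5) if hb is not None else 0.0
    ds = abs(hs - 0.5) if hs is not None else 0.0

    if nb < min_snps and ns < min_snps:
        H, rule = 0, 1
    elif Hb == Hs and Hb != 0:
        H, rule = Hb, 2
    elif nb > ratio * ns:
        H, rule = Hb, 3
    elif ns > ratio * nb:
        H, rule = Hs, 4
    elif db > ratio * ds:
        H, rule = Hb, 5
    elif ds > ratio * db:
        H, rule = Hs, 6
    else:
        H, rule = 0, 7

    return HaplotypeAssignment(
        read_id=read_id,
        n_base=nb,
        h_base=hb,
        n_signal=ns,
        h_signal=hs,
        H_base=Hb,
        H_signal=Hs,
        H=H,
        rule_fired=rule,
    )


def haplotype_read(
    read,
    snps: pd.DataFrame,
    signal_records: pd.DataFrame | None = None,
    min_snps: int = MIN_SNPS,
    ratio: float = RATIO_FACTOR,
) -> HaplotypeAssignment:
    """Full per-read pipeline: observe, aggregate both streams, combine."""
    base = aggregate_evidence(collect_basecall_observations(read, snps))
    sig = signal_evidence(signal_records) if signal_records is not None else (
        HaplotypeEvidence.empty("signal")
    )
    return combine_calls(
        base, sig, read_id=read.query_name, min_snps=min_snps, ratio=ratio
    )


def assignments_to_frame(assignments: Sequence[HaplotypeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [a.read_id for a in assignments],
            "n_base": [a.n_base for a in assignments],
            "h_base": [a.h_base for a in assignments],
            "n_signal": [a.n_signal for a in assignments],
            "h_signal": [a.h_signal for a in assignments],
            "H": [a.H for a in assignments],
            "rule_fired": [a.rule_fired for a in assignments],
        }
    )


def evaluate_assignments(
    assignments: Sequence[HaplotypeAssignment], truth: Sequence[int]
) -> dict:
    """Benchmark assignments against known labels (+1/-1 per read).

    Returns accuracy on called reads (H != 0), the fraction of reads called,
    the misassignment rate (wrongly called / all reads), and AUROCs for the
    continuous scores h_base, h_signal (where present) and the combined
    discrete call.
    """
    if len(assignments) != len(truth):
        raise ValueError("assignments and truth labels differ in length")
    truth = np.asarray(truth, dtype=int)
    H = np.array([a.H for a in assignments])
    called = H != 0
    n_called = int(called.sum())
    correct = int((H[called] == truth[called]).sum())
    metrics = {
        "n_reads": len(truth),
        "n_called": n_called,
        "fraction_called": n_called / len(truth) if len(truth) else 0.0,
        "accuracy": correct / n_called if n_called else float("nan"),
        "misassignment_rate": (n_called - correct) / len(truth) if len(truth) else 0.0,
    }
    from sklearn.metrics import roc_auc_score

    for key, scores in (
        ("auroc_basecall", [a.h_base for a in assignments]),
        ("auroc_signal", [a.h_signal for a in assignments]),
    ):
        mask = np.array([s is not None for s in scores])
        y = truth[mask] == 1
        if mask.sum() and 0 < y.sum() < mask.sum():
            metrics[key] = float(
                roc_auc_score(y, np.asarray(scores, dtype=object)[mask].astype(float))
            )
        else:
            metrics[key] = float("nan")
    # Discrete combined call as a 3-level score: -1 < 0 < +1.
    y = truth == 1
    if 0 < y.sum() < len(y):
        from sklearn.metrics import roc_auc_score as _auc

        metrics["auroc_combined"] = float(_auc(y, H))
    else:
        metrics["auroc_combined"] = float("nan")
    return metrics
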