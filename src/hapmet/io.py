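"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open.  Conversions happen at the
boundary: VCF positions (1-based) are shifted on entry, methylation TSVs in
the nanopolish ``call-methylation`` dialect (0-based inclusive start/end of
the first/last CpG cytosine) have their end incremented on entry and
decremented on write, and BED passes through unchanged.  Readers emit
streams sorted by (chromosome, start).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

SNP_COLUMNS = ["chrom", "pos", "ref", "alt", "strain"]


class FormatError(RuntimeError):
    """Fatal input problem: unreadable file or no usable records."""


def read_snp_table(vcf_path, strain_label: str) -> pd.DataFrame:
    """Load biallelic SNVs from a VCF into a SNP table.

    Multi-allelic records, indels and symbolic alleles are dropped.  Output
    columns: chrom, pos (0-based), ref, alt, strain; sorted by (chrom, pos).
    Raises FormatError when the file is unreadable or contains no usable
    record.
    """
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read VCF {vcf_path}: {exc}") from exc
    rows, n_total = [], 0
    with vf:
        for rec in vf:
            n_total += 1
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                continue
            if ref not in "ACGT" or alt not in "ACGT":
                continue
            rows.append((rec.chrom, rec.pos - 1, ref, alt))
    if not rows:
        raise FormatError(
            f"{vcf_path}: no biallelic SNV among {n_total} records"
        )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    df["strain"] = strain_label
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def write_snp_table_vcf(snps: pd.DataFrame, path) -> None:
    """Write a SNP table as minimal VCF 4.2 (0-based pos converted back)."""
    chroms = snps["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\n")


def read_alignments(path, region: tuple[str, int, int] | None = None):
    """Yield primary alignments with a skip counter for the rest.

    Accepts BAM (indexed; the index is built if missing) or plain SAM for
    sequential iteration.  Region queries require BAM.  Yields pysam
    AlignedSegment objects; unmapped, secondary and supplementary records are
    skipped and counted on the generator's ``.counters`` attribute after
    exhaustion via :func:`iter_primary`.
    """
    path = str(path)
    is_bam = path.endswith(".bam")
    if is_bam and not Path(path + ".bai").exists() and not Path(
        path.replace(".bam", ".bai")
    ).exists():
        try:
            pysam.index(path)
        except pysam.SamtoolsError as exc:  # pragma: no cover - samtools detail
            raise FormatError(
                f"{path}: missing index and `samtools index` failed: {exc}"
            ) from exc
    if region is not None and not is_bam:
        raise FormatError("region queries require an indexed BAM")
    mode = "rb" if is_bam else "r"
    af = pysam.AlignmentFile(path, mode)
    if region is not None:
        it = af.fetch(region[0], region[1], region[2])
    else:
        it = af
    return af, it


def iter_primary(path, region=None, counters: dict | None = None):
    """Generator over primary mapped alignments; optional skip counters."""
    af, it = read_alignments(path, region)
    with af:
        for read in it:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                if counters is not None:
                    counters["skipped"] = counters.get("skipped", 0) + 1
                continue
            yield read


# nanopolish call-methylation column set; only a subset is required.
_METH_REQUIRED = ["chromosome", "start", "end", "read_name"]


def read_methylation_tsv(path) -> pd.DataFrame:
    """Read a methylation TSV (nanopolish ``call-methylation`` dialect).

    Requires columns chromosome/start/end/read_name plus either the pair
    log_lik_methylated + log_lik_unmethylated or a single log_lik_ratio
    (stored as methylated minus unmethylated, with the unmethylated term 0).
    ``num_motifs`` defaults to 1 when absent.  Malformed rows are skipped
    with a warning.  Returns columns chrom, group_start, group_end (half-
    open), read_id, log_lik_methylated, log_lik_unmethylated, num_cpgs,
    strand — sorted by (chrom, group_start).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in _METH_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    has_pair = {"log_lik_methylated", "log_lik_unmethylated"} <= set(df.columns)
    if not has_pair and "log_lik_ratio" not in df.columns:
        raise FormatError(f"{path}: need log_lik_ratio or the two log-likelihoods")
    numeric = ["start", "end"] + (
        ["log_lik_methylated", "log_lik_unmethylated"] if has_pair else ["log_lik_ratio"]
    )
    before = len(df)
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=numeric)
    if len(df) < before:
        log.warning("%s: skipped %d malformed rows", path, before - len(df))
    out = pd.DataFrame(
        {
            "chrom": df["chromosome"].astype(str),
            "group_start": df["start"].astype(int),
            "group_end": df["end"].astype(int) + 1,  # inclusive -> half-open
            "read_id": df["read_name"].astype(str),
        }
    )
    if has_pair:
        out["log_lik_methylated"] = df["log_lik_methylated"].astype(float)
        out["log_lik_unmethylated"] = df["log_lik_unmethylated"].astype(float)
    else:
        out["log_lik_methylated"] = df["log_lik_ratio"].astype(float)
        out["log_lik_unmethylated"] = 0.0
    out["num_cpgs"] = (
        pd.to_numeric(df["num_motifs"], errors="coerce").fillna(1).astype(int)
        if "num_motifs" in df.columns
        else 1
    )
    out["strand"] = df["strand"].astype(str) if "strand" in df.columns else "+"
    return out.sort_values(["chrom", "group_start"], kind="mergesort").reset_index(
        drop=True
    )


def write_methylation_tsv(records: pd.DataFrame, path) -> None:
    """Write records back in the call-methylation dialect (inclusive end)."""
    out = pd.DataFrame(
        {
            "chromosome": records["chrom"],
            "strand": records.get("strand", "+"),
            "start": records["group_start"],
            "end": records["group_end"] - 1,
            "read_name": records["read_id"],
            "log_lik_ratio": records["log_lik_methylated"]
            - records["log_lik_unmethylated"],
            "log_lik_methylated": records["log_lik_methylated"],
            "log_lik_unmethylated": records["log_lik_unmethylated"],
            "num_motifs": records["num_cpgs"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_signal_scores(path) -> pd.DataFrame:
    """Read a per-read per-SNP signal-score TSV (phase-reads-like dialect).

    Required columns: read_name, chromosome, position (0-based), allele
    (ref|alt), quality (HMM scale; the -35 offset is applied downstream).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = ["read_name", "chromosome", "position", "allele", "quality"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    bad = ~df["allele"].isin(["ref", "alt"])
    if bad.any():
        log.warning("%s: dropped %d rows with allele not in {ref,alt}", path, bad.sum())
        df = df[~bad]
    out = pd.DataFrame(
        {
            "read_id": df["read_name"].astype(str),
            "chrom": df["chromosome"].astype(str),
            "pos": df["position"].astype(int),
            "allele": df["allele"].astype(str),
            "quality": df["quality"].astype(float),
        }
    )
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_signal_scores(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "read_name": df["read_id"],
            "chromosome": df["chrom"],
            "position": df["pos"],
            "allele": df["allele"],
            "quality": df["quality"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_bisulfite_sites(path) -> pd.DataFrame:
    """Per-site bisulfite calls: TSV with chrom, pos (0-based), beta[, coverage]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos", "beta"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col}")
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def write_bedgraph(df: pd.DataFrame, path, value_col: str = "beta") -> None:
    """bedGraph (0-based half-open) of a per-interval value column."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            start = getattr(row, "start", None)
            if start is None:
                start = row.group_start
                end = row.group_end
            else:
                end = row.end
            fh.write(f"{row.chrom}\t{start}\t{end}\t{getattr(row, value_col):.6g}\n")


DMR_BED_COLUMNS = [
    "chrom",
    "start",
    "end",
    "rank",
    "area_stat",
    "strand",
    "contrast",
    "n_sites",
    "mean_diff",
]


def write_dmrs_bed(dmrs: pd.DataFrame, path) -> None:
    """Ranked DMRs as BED6+ (name = rank, score = area statistic).

    Extra columns: contrast label, number of member sites, mean methylation
    difference.  Overlapping regions within a contrast are legal and only
    warned about.
    """
    with open(path, "w") as fh:
        if len(dmrs) == 0:
            return
        for (chrom, contrast), sub in dmrs.groupby(["chrom", "contrast"]):
            sub = sub.sort_values("start")
            overlap = (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1])
            if overlap.any():
                log.warning("%d overlapping DMR pairs on %s (%s)",
                            int(overlap.sum()), chrom, contrast)
        dmrs = dmrs.sort_values("rank")
        for row in dmrs.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.rank}\t"
                f"{row.area_stat:.6g}\t.\t{row.contrast}\t{row.n_sites}\t"
                f"{row.mean_diff:.6g}\n"
            )


def read_dmrs_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=DMR_BED_COLUMNS, dtype={"chrom": str}
    )
    return df


def read_intervals_bed(path) -> pd.DataFrame:
    """Generic BED3+ reader: chrom, start, end[, name[, score[, strand]]]."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = names[: df.shape[1]]
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
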