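"""Synthetic data with known truth for every input the pipeline consumes.

The generator emulates the study design the pipeline targets: reciprocal F1
crosses of two inbred strains (B6-like reference and CAST-like alternate,
with an optional FVB-like grand-parental block recombined into the maternal
genome), sequenced with long error-prone reads at ~10x genomic coverage.
It emits the exact dialects the io module reads — SAM alignments, VCF SNP
tables, nanopolish-style methylation and signal-score TSVs, per-site
bisulfite calls and gene BED — plus truth tables, so every module is
testable without external data.

Phred qualities are exact transforms of the simulated per-base error rate
(q = -10 log10 e), so the empirical haplotype score model operates in the
calibrated regime it presumes.  The signal stream is a second, independent
noisy observation of the same truth on the shifted (+35) quality scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import io as hio
from .dmr import PARENT_OF_ORIGIN, STRAIN
from .methylation import MAX_GAP, CpGCallGroup, chain_call_groups

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MATERNAL, PATERNAL = "maternal", "paternal"
B6, CAST, FVB = "B6", "CAST", "FVB"


def phred(error_rate: float) -> int:
    return int(round(-10.0 * np.log10(error_rate))) if error_rate > 0 else 60


@dataclass(frozen=True)
class PlantedDMR:
    """A region with a planted methylation difference.

    ``contrast`` is parent_of_origin (maternal allele at ``p_high``,
    paternal at ``p_low``, in both crosses) or strain (B6 allele high,
    CAST allele low, in both crosses).  ICR-like defaults: near-complete
    allelic difference, as at real imprinting control regions.
    """

    chrom: str
    start: int
    end: int
    contrast: str = PARENT_OF_ORIGIN
    p_high: float = 0.95
    p_low: float = 0.05


def _default_dmrs():
    return [
        PlantedDMR("chr1", 300_000, 302_000, PARENT_OF_ORIGIN),
        PlantedDMR("chr1", 900_000, 902_000, PARENT_OF_ORIGIN),
        PlantedDMR("chr1", 1_500_000, 1_502_000, STRAIN),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 1
    chrom_length: int = 2_000_000
    snp_density: float = 1e-3  # CAST-vs-reference SNVs per bp
    fvb_snp_density: float = 5e-4  # FVB-vs-reference SNVs per bp
    cpg_density: float = 0.01  # CpG dinucleotides per bp (genome background)
    dmr_cpg_density: float = 0.02  # CpG-island-like density inside planted DMRs
    mean_read_length: float = 15_000.0
    sd_read_length: float = 8_000.0
    min_read_length: int = 500
    per_base_error: float = 0.10
    deletion_rate: float = 0.01
    coverage: float = 10.0
    # Genome-wide methylation averages ~50% in placenta but is bimodal:
    # methylated domains interleaved with unmethylated island-like domains.
    p_background: float = 0.5
    domain_length: int = 50_000
    domain_amplitude: float = 0.3  # domains at p_background +/- amplitude
    planted_dmrs: list = field(default_factory=_default_dmrs)
    planted_fvb_segment: tuple | None = None  # (chrom, start, end)
    llr_mu: float = 4.0  # mean |log-likelihood ratio| of a confident call
    llr_noise_sd: float = 2.0
    signal_detect_prob: float = 0.8  # fraction of SNPs the HMM scores
    signal_error: float = 0.05
    signal_quality_base: float = 35.0
    bisulfite_coverage: float = 30.0

    def chrom_names(self):
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    sequences: dict  # chrom -> np.uint8 array
    cpg_positions: dict  # chrom -> sorted int array (forward C of each CpG)
    groups: dict  # chrom -> list[CpGCallGroup]
    snps_cast: pd.DataFrame
    snps_fvb: pd.DataFrame


def simulate_genome_and_snps(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedGenome:
    """Random reference with planted CpGs and two non-overlapping SNP tables.

    CpG dinucleotides are written into the sequence at the configured
    densities (denser inside planted DMRs, CpG-island-like); SNP positions
    avoid CpGs and each other, so the two strain tables are disjoint.
    Deterministic under the config seed.
    """
    rng = rng or np.random.default_rng(config.seed)
    total_density = (
        config.snp_density
        + config.fvb_snp_density
        + 2 * max(config.cpg_density, config.dmr_cpg_density)
    )
    if total_density > 0.3:
        raise ValueError("densities too high: sites would be forced to overlap")
    sequences, cpgs, groups = {}, {}, {}
    cast_rows, fvb_rows = [], []
    for chrom in config.chrom_names():
        L = config.chrom_length
        seq = _BASES[rng.integers(0, 4, size=L)].copy()
        dens = np.full(L, config.cpg_density)
        for d in config.planted_dmrs:
            if d.chrom == chrom:
                dens[d.start:d.end] = config.dmr_cpg_density
        cpg_pos = np.flatnonzero(rng.random(L - 1) < dens[:-1])
        # Enforce >=2 bp spacing so CG pairs cannot collide.
        keep = np.ones(len(cpg_pos), dtype=bool)
        last = -10
        for i, p in enumerate(cpg_pos):
            if p - last < 2:
                keep[i] = False
            else:
                last = p
        cpg_pos = cpg_pos[keep]
        seq[cpg_pos] = ord("C")
        seq[cpg_pos + 1] = ord("G")
        blocked = np.zeros(L, dtype=bool)
        blocked[cpg_pos] = True
        blocked[cpg_pos + 1] = True
        for density, rows, strain in (
            (config.snp_density, cast_rows, CAST),
            (config.fvb_snp_density, fvb_rows, FVB),
        ):
            pos = np.flatnonzero(rng.random(L) < density)
            pos = pos[~blocked[pos]]
            blocked[pos] = True
            ref = seq[pos]
            alt = _BASES[
                (np.searchsorted(_BASES, ref) + rng.integers(1, 4, size=len(pos))) % 4
            ]
            for p, r, a in zip(pos, ref, alt):
                rows.append((chrom, int(p), chr(r), chr(a), strain))
        sequences[chrom] = seq
        cpgs[chrom] = cpg_pos
        groups[chrom] = chain_call_groups(cpg_pos, chrom, MAX_GAP)
    cols = hio.SNP_COLUMNS
    return SimulatedGenome(
        config=config,
        sequences=sequences,
        cpg_positions=cpgs,
        groups=groups,
        snps_cast=pd.DataFrame(cast_rows, columns=cols),
        snps_fvb=pd.DataFrame(fvb_rows, columns=cols),
    )


@dataclass
class SimRead:
    read_id: str
    chrom: str
    start: int
    end: int  # reference end (half-open)
    cigar: list  # [(op, length)]; 0 = M, 2 = D
    seq: str
    quality: int
    parent: str  # maternal | paternal
    strain: str  # B6 | CAST (allele carried at CAST-table SNPs: B6 = ref)

    @property
    def truth_label(self) -> int:
        """+1 when the read carries reference (B6) alleles, else -1."""
        return 1 if self.strain == B6 else -1


def _parent_strain(cross: int, parent: str) -> str:
    if cross == 1:  # B6 dam x CAST sire
        return B6 if parent == MATERNAL else CAST
    return CAST if parent == MATERNAL else B6


def simulate_reads(
    genome: SimulatedGenome,
    rng: np.random.Generator,
    n_reads: int | None = None,
    cross: int = 1,
    force_strain: str | None = None,
) -> list[SimRead]:
    """Error-prone long reads carrying haplotype-consistent SNP alleles.

    Each read draws a parent (maternal/paternal, balanced), copies the
    reference, substitutes the parental alleles at SNPs (including FVB
    alleles inside a planted maternal FVB block), then applies substitution
    errors at ``per_base_error`` and deletions at ``deletion_rate``.  All
    bases carry the Phred quality exactly matching the error rate.
    ``force_strain`` simulates pure-strain (non-F1) sequencing runs.
    """
    cfg = genome.config
    chroms = cfg.chrom_names()
    total = cfg.chrom_length * len(chroms)
    if n_reads is None:
        n_reads = int(round(cfg.coverage * total / cfg.mean_read_length))
    q = phred(cfg.per_base_error)
    # lognormal parameterised to the requested mean/sd
    m, s = cfg.mean_read_length, cfg.sd_read_length
    sigma2 = np.log(1.0 + (s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0

    # Per-chromosome allele patches for each strain role.
    patches: dict = {}
    for chrom in chroms:
        cast = genome.snps_cast[genome.snps_cast["chrom"] == chrom]
        fvb = genome.snps_fvb[genome.snps_fvb["chrom"] == chrom]
        cast_pos = cast["pos"].to_numpy()
        cast_alt = np.frombuffer("".join(cast["alt"]).encode(), dtype=np.uint8)
        fvb_sel = np.zeros(len(fvb), dtype=bool)
        if cfg.planted_fvb_segment is not None:
            fc, fs, fe = cfg.planted_fvb_segment
            if fc == chrom:
                fvb_sel = (fvb["pos"].to_numpy() >= fs) & (fvb["pos"].to_numpy() < fe)
        fvb_pos = fvb["pos"].to_numpy()[fvb_sel]
        fvb_alt = np.frombuffer(
            "".join(fvb["alt"][fvb_sel]).encode(), dtype=np.uint8
        ) if fvb_sel.any() else np.array([], dtype=np.uint8)
        empty = (np.array([], dtype=int), np.array([], dtype=np.uint8))
        patches[chrom] = {
            CAST: (cast_pos, cast_alt),
            B6: empty,  # pure B6 parent: reference alleles everywhere
            # B6-derived *maternal* genome carries the grand-parental FVB block
            (B6, MATERNAL): (fvb_pos, fvb_alt),
        }

    reads = []
    chrom_idx = rng.integers(0, len(chroms), size=n_reads)
    lengths = np.maximum(
        rng.lognormal(mu, np.sqrt(sigma2), size=n_reads), cfg.min_read_length
    ).astype(int)
    for i in range(n_reads):
        chrom = chroms[chrom_idx[i]]
        L = min(int(lengths[i]), cfg.chrom_length)
        start = int(rng.integers(0, cfg.chrom_length - L + 1))
        parent = MATERNAL if rng.random() < 0.5 else PATERNAL
        strain = force_strain or _parent_strain(cross, parent)
        seg = genome.sequences[chrom][start:start + L].copy()
        key = (B6, MATERNAL) if (strain == B6 and parent == MATERNAL) else strain
        pos, alt = patches[chrom][key]
        lo, hi = np.searchsorted(pos, [start, start + L])
        seg[pos[lo:hi] - start] = alt[lo:hi]
        # substitution errors (shift to a different base uniformly)
        err = np.flatnonzero(rng.random(L) < cfg.per_base_error)
        if len(err):
            shift = rng.integers(1, 4, size=len(err))
            seg[err] = _BASES[(np.searchsorted(_BASES, seg[err]) + shift) % 4]
        # deletions
        if cfg.deletion_rate > 0:
            keep = rng.random(L) >= cfg.deletion_rate
        else:
            keep = np.ones(L, dtype=bool)
        cigar = _mask_to_cigar(keep)
        reads.append(
            SimRead(
                read_id=f"read_{cross}_{i:06d}",
                chrom=chrom,
                start=start,
                end=start + L,
                cigar=cigar,
                seq=seg[keep].tobytes().decode(),
                quality=q,
                parent=parent,
                strain=strain,
            )
        )
    reads.sort(key=lambda r: (r.chrom, r.start, r.read_id))
    return reads


def _mask_to_cigar(keep: np.ndarray) -> list:
    """Run-length encode a keep mask into M/D CIGAR tuples."""
    ops = np.where(keep, 0, 2)
    brk = np.flatnonzero(np.diff(ops)) + 1
    out = []
    for chunk in np.split(ops, brk):
        out.append((int(chunk[0]), len(chunk)))
    return out


def write_sam(reads: list[SimRead], genome: SimulatedGenome, path) -> None:
    """Coordinate-sorted SAM with per-base qualities."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": c, "LN": genome.config.chrom_length}
            for c in genome.config.chrom_names()
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.seq
            a.flag = 0
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigartuples = r.cigar
            a.query_qualities = pysam.qualitystring_to_array(
                chr(r.quality + 33) * len(r.seq)
            )
            out.write(a)


def simulate_signal_scores(
    reads: list[SimRead], genome: SimulatedGenome, rng: np.random.Generator
) -> pd.DataFrame:
    """Independent signal-space genotype calls at CAST-table SNPs.

    Each overlapped SNP is scored with probability ``signal_detect_prob``;
    the called allele is the read's true allele flipped with probability
    ``signal_error``; qualities sit at base + Phred(signal_error), i.e. on
    the shifted HMM scale the haplotyper expects.
    """
    cfg = genome.config
    rows = []
    quality = cfg.signal_quality_base + phred(cfg.signal_error)
    for chrom in cfg.chrom_names():
        snp_pos = genome.snps_cast[genome.snps_cast["chrom"] == chrom][
            "pos"
        ].to_numpy()
        for r in reads:
            if r.chrom != chrom:
                continue
            lo, hi = np.searchsorted(snp_pos, [r.start, r.end])
            pos = snp_pos[lo:hi]
            det = rng.random(len(pos)) < cfg.signal_detect_prob
            pos = pos[det]
            true_is_ref = r.strain == B6
            flip = rng.random(len(pos)) < cfg.signal_error
            for p, f in zip(pos, flip):
                is_ref = true_is_ref ^ bool(f)
                rows.append(
                    (r.read_id, chrom, int(p), "ref" if is_ref else "alt", quality)
                )
    return pd.DataFrame(
        rows, columns=["read_id", "chrom", "pos", "allele", "quality"]
    )


def _true_methylation_p(
    cfg: SimulationConfig, chrom: str, group: CpGCallGroup, parent: str, strain: str
) -> float:
    pos = group.sites[0]
    for d in cfg.planted_dmrs:
        if d.chrom == chrom and d.start <= pos < d.end:
            if d.contrast == PARENT_OF_ORIGIN:
                return d.p_high if parent == MATERNAL else d.p_low
            return d.p_high if strain == B6 else d.p_low
    # alternating methylated / unmethylated domains, shared by both alleles
    sign = 1.0 if (pos // cfg.domain_length) % 2 else -1.0
    p = cfg.p_background + sign * cfg.domain_amplitude
    return min(max(p, 0.0), 1.0)


def simulate_methylation(
    reads: list[SimRead], genome: SimulatedGenome, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-read per-call-group log-likelihood records with planted truth.

    For every call group fully contained in a read, the true state is
    Bernoulli(p) with p from the read's haplotype and the planted profile;
    the emitted log-likelihood ratio is (2*state - 1) * llr_mu + Normal(0,
    llr_noise_sd).  Returns the internal methylation record frame (write
    with io.write_methylation_tsv for the on-disk dialect).
    """
    cfg = genome.config
    rows = []
    for chrom in cfg.chrom_names():
        groups = genome.groups[chrom]
        g_start = np.array([g.span[0] for g in groups])
        g_end = np.array([g.span[1] for g in groups])
        p_cache: dict = {}
        for r in reads:
            if r.chrom != chrom:
                continue
            lo = np.searchsorted(g_start, r.start)
            hi = np.searchsorted(g_end, r.end, side="right")
            for gi in range(lo, hi):
                key = (gi, r.parent, r.strain)
                p = p_cache.get(key)
                if p is None:
                    p = _true_methylation_p(cfg, chrom, groups[gi], r.parent, r.strain)
                    p_cache[key] = p
                state = rng.random() < p
                llr = (2.0 * state - 1.0) * cfg.llr_mu + rng.normal(
                    0.0, cfg.llr_noise_sd
                )
                rows.append(
                    (
                        chrom,
                        int(g_start[gi]),
                        int(g_end[gi]),
                        r.read_id,
                        float(llr),
                        0.0,
                        len(groups[gi].sites),
                        "+",
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "group_start",
            "group_end",
            "read_id",
            "log_lik_methylated",
            "log_lik_unmethylated",
            "num_cpgs",
            "strand",
        ],
    )


def simulate_bisulfite(
    genome: SimulatedGenome, rng: np.random.Generator
) -> pd.DataFrame:
    """Bulk (unhaplotyped) per-site bisulfite calls.

    Coverage is Poisson; the per-site methylation probability is the mean of
    the maternal and paternal truth, as bulk bisulfite averages alleles.
    """
    cfg = genome.config
    rows = []
    for chrom in cfg.chrom_names():
        for g in genome.groups[chrom]:
            p = 0.5 * (
                _true_methylation_p(cfg, chrom, g, MATERNAL, B6)
                + _true_methylation_p(cfg, chrom, g, PATERNAL, CAST)
            )
            for site in g.sites:
                cov = rng.poisson(cfg.bisulfite_coverage)
                if cov == 0:
                    continue
                x = rng.binomial(cov, p)
                rows.append((chrom, int(site), x / cov, int(cov)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "beta", "coverage"])


def simulate_genes(
    genome: SimulatedGenome, rng: np.random.Generator, n_unbiased: int = 20
) -> pd.DataFrame:
    """Gene intervals: one 'biased' gene adjacent to each parent-of-origin
    DMR plus unbiased genes scattered at random."""
    cfg = genome.config
    rows = []
    for i, d in enumerate(cfg.planted_dmrs):
        if d.contrast != PARENT_OF_ORIGIN:
            continue
        start = d.end + int(rng.integers(1_000, 10_000))
        rows.append((d.chrom, start, start + 5_000, f"biased_{i}", "biased"))
    for i in range(n_unbiased):
        chrom = cfg.chrom_names()[int(rng.integers(0, cfg.n_chromosomes))]
        start = int(rng.integers(0, cfg.chrom_length - 5_000))
        rows.append((chrom, start, start + 5_000, f"unbiased_{i}", "unbiased"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "gene_class"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def simulate_dataset(config: SimulationConfig, outdir, crosses=(1, 2)) -> dict:
    """Write a complete synthetic input set (both crosses) plus truth JSON.

    Emits, per cross: sorted SAM, signal TSV, methylation TSV; plus shared
    CAST/FVB VCFs, bisulfite TSV, gene BED and truth.json.  Returns the
    file manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome_and_snps(config, rng)
    hio.write_snp_table_vcf(genome.snps_cast, outdir / "cast.vcf")
    hio.write_snp_table_vcf(genome.snps_fvb, outdir / "fvb.vcf")
    manifest = {
        "cast_vcf": str(outdir / "cast.vcf"),
        "fvb_vcf": str(outdir / "fvb.vcf"),
    }
    truth: dict = {"config_seed": config.seed, "reads": {}}
    for cross in crosses:
        reads = simulate_reads(genome, rng, cross=cross)
        write_sam(reads, genome, outdir / f"cross{cross}.sam")
        sig = simulate_signal_scores(reads, genome, rng)
        hio.write_signal_scores(sig, outdir / f"cross{cross}.signal.tsv")
        meth = simulate_methylation(reads, genome, rng)
        hio.write_methylation_tsv(meth, outdir / f"cross{cross}.methylation.tsv")
        manifest[f"cross{cross}_sam"] = str(outdir / f"cross{cross}.sam")
        manifest[f"cross{cross}_signal"] = str(outdir / f"cross{cross}.signal.tsv")
        manifest[f"cross{cross}_methylation"] = str(
            outdir / f"cross{cross}.methylation.tsv"
        )
        truth["reads"][str(cross)] = {
            r.read_id: {"parent": r.parent, "strain": r.strain} for r in reads
        }
    bs = simulate_bisulfite(genome, rng)
    bs.to_csv(outdir / "bisulfite.tsv", sep="\t", index=False)
    genes = simulate_genes(genome, rng)
    genes.to_csv(outdir / "genes.bed", sep="\t", index=False, header=False)
    manifest["bisulfite"] = str(outdir / "bisulfite.tsv")
    manifest["genes_bed"] = str(outdir / "genes.bed")
    truth["planted_dmrs"] = [
        {
            "chrom": d.chrom, "start": d.start, "end": d.end,
            "contrast": d.contrast, "p_high": d.p_high, "p_low": d.p_low,
        }
        for d in config.planted_dmrs
    ]
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    manifest["truth"] = str(outdir / "truth.json")
    return manifest
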