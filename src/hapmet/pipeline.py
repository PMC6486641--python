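"""End-to-end orchestration: simulated or on-disk inputs to ranked DMRs.

These functions tie the stage modules together the same way the CLI does,
but return in-memory frames, which makes whole-pipeline evaluation against
simulation truth convenient.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import dmr as dmr_mod
from . import io as hio
from . import methylation as meth_mod
from .config import PipelineConfig
from .haplotyping import haplotype_read
from .simulate import (
    B6,
    SimulationConfig,
    simulate_dataset,
)


def haplotype_alignments(
    sam_path, snps: pd.DataFrame, signal: pd.DataFrame | None,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Haplotype every primary alignment in a SAM/BAM file."""
    cfg = cfg or PipelineConfig()
    by_read = dict(tuple(signal.groupby("read_id"))) if signal is not None else {}
    snps_by_chrom = dict(tuple(snps.groupby("chrom")))
    rows = []
    for read in hio.iter_primary(sam_path):
        chrom_snps = snps_by_chrom.get(
            read.reference_name, snps.iloc[0:0]
        )
        a = haplotype_read(
            read, chrom_snps, by_read.get(read.query_name),
            min_snps=cfg.min_snps, ratio=cfg.ratio_factor,
        )
        rows.append(
            (a.read_id, read.reference_name, read.reference_start,
             read.reference_end, a.n_base, a.h_base, a.n_signal, a.h_signal,
             a.H, a.rule_fired)
        )
    return pd.DataFrame(
        rows,
        columns=["read_id", "chrom", "start", "end", "n_base", "h_base",
                 "n_signal", "h_signal", "H", "rule_fired"],
    )


def summaries_for_cross(
    methylation_tsv, haplotypes: pd.DataFrame, maternal_is_ref: bool,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    cfg = cfg or PipelineConfig()
    records = meth_mod.add_beta(
        hio.read_methylation_tsv(methylation_tsv), cfg.prior_p0
    )
    return meth_mod.aggregate_by_haplotype(records, haplotypes, maternal_is_ref)


def label_samples(summaries: pd.DataFrame, maternal_strain: str) -> pd.DataFrame:
    """Attach haplotype-sample names (e.g. b6_mat / cast_pat) for one cross."""
    df = summaries[summaries["haplotype"].isin(["maternal", "paternal"])].copy()
    paternal_strain = "CAST" if maternal_strain == B6 else "B6"
    df["sample"] = np.where(
        df["haplotype"] == "maternal",
        f"{maternal_strain.lower()}_mat",
        f"{paternal_strain.lower()}_pat",
    )
    return df


def run_synthetic_pipeline(
    sim_config: SimulationConfig,
    workdir=None,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Simulate both crosses and run haplotyping, methylation and DMR calling.

    Returns a dict with the simulated manifest, per-cross haplotype frames,
    the count matrix, both DMR lists and haplotyping metrics against truth.
    """
    import json

    cfg = cfg or PipelineConfig()
    ctx = (
        tempfile.TemporaryDirectory() if workdir is None else _nullcontext(workdir)
    )
    with ctx as wd:
        manifest = simulate_dataset(sim_config, wd)
        truth = json.load(open(manifest["truth"]))
        labelled = []
        haplotype_frames = {}
        for cross, maternal_strain in ((1, "B6"), (2, "CAST")):
            snps = hio.read_snp_table(manifest["cast_vcf"], "CAST")
            signal = hio.read_signal_scores(manifest[f"cross{cross}_signal"])
            haps = haplotype_alignments(
                manifest[f"cross{cross}_sam"], snps, signal, cfg
            )
            haplotype_frames[cross] = haps
            summaries = summaries_for_cross(
                manifest[f"cross{cross}_methylation"], haps,
                maternal_is_ref=(maternal_strain == B6), cfg=cfg,
            )
            labelled.append(label_samples(summaries, maternal_strain))
        matrix = dmr_mod.build_count_matrix(pd.concat(labelled, ignore_index=True))
        params = dmr_mod.DMRParams(
            p_threshold=cfg.p_threshold, min_sites=cfg.min_sites,
            min_len=cfg.min_len, merge_gap=cfg.merge_gap,
            min_frac_significant=cfg.min_frac_significant,
        )
        dmrs = dmr_mod.run_contrasts(matrix, params)
        metrics = _haplotyping_metrics(haplotype_frames, truth)
    return {
        "matrix": matrix,
        "dmrs": dmrs,
        "haplotypes": haplotype_frames,
        "truth": truth,
        "haplotyping_metrics": metrics,
    }


def _haplotyping_metrics(haplotype_frames: dict, truth: dict) -> dict:
    n_called = n_correct = n_total = 0
    for cross, haps in haplotype_frames.items():
        t = truth["reads"][str(cross)]
        lab = haps["read_id"].map(lambda r: 1 if t[r]["strain"] == B6 else -1)
        called = haps["H"] != 0
        n_total += len(haps)
        n_called += int(called.sum())
        n_correct += int((haps["H"][called] == lab[called]).sum())
    return {
        "n_reads": n_total,
        "fraction_called": n_called / n_total if n_total else 0.0,
        "accuracy": n_correct / n_called if n_called else float("nan"),
        "misassignment_rate": (n_called - n_correct) / n_total if n_total else 0.0,
    }


def recovered_fraction(dmrs: pd.DataFrame, planted: list[dict]) -> float:
    """Fraction of planted regions overlapped (>=1 bp) by a called DMR."""
    if not planted:
        return float("nan")
    hit = 0
    for d in planted:
        sel = (
            (dmrs["chrom"] == d["chrom"])
            & (dmrs["start"] < d["end"])
            & (dmrs["end"] > d["start"])
        )
        hit += bool(len(dmrs) and sel.any())
    return hit / len(planted)


class _nullcontext:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        Path(self.value).mkdir(parents=True, exist_ok=True)
        return self.value

    def __exit__(self, *exc):
        return False
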