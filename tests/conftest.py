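import numpy as np
import pandas as pd
import pysam
import pytest

from hapmet.simulate import SimulationConfig, simulate_genome_and_snps


def make_read(
    name="r1",
    chrom="chr1",
    start=0,
    seq="ACGT",
    quals=None,
    cigar=None,
    flag=0,
    header=None,
):
    """Build a pysam AlignedSegment for unit tests."""
    header = header or pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": 10_000_000}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_name = chrom
    a.reference_start = start
    a.mapping_quality = 60
    a.cigartuples = cigar or [(0, len(seq))]
    a.query_qualities = quals if quals is not None else [30] * len(seq)
    return a


def snp_frame(rows):
    """rows: (chrom, pos, ref, alt)"""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    df["strain"] = "CAST"
    return df


@pytest.fixture(scope="session")
def small_genome():
    cfg = SimulationConfig(seed=42, chrom_length=200_000, coverage=5)
    return simulate_genome_and_snps(cfg, np.random.default_rng(42))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
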