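"""Shared fixtures: tiny hand-written VCF/GTF inputs and a small simulated
dataset reused across pipeline-level tests."""

from __future__ import annotations

import numpy as np
import pytest

import sweepscan as sw

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1,length=1000000>\n"
    "##contig=<ID=2,length=1000000>\n"
    "##contig=<ID=X,length=1000000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
)

GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(path, samples, records, with_dp=True):
    """records: (chrom, pos, ref, alt, dosages[, depths])."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fmt = "GT:DP" if with_dp else "GT"
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for rec in records:
            chrom, pos, ref, alt, dosages = rec[:5]
            depths = rec[5] if len(rec) > 5 else [16] * len(dosages)
            if with_dp:
                cells = [f"{GT[d]}:{dp}" for d, dp in zip(dosages, depths)]
            else:
                cells = [GT[d] for d in dosages]
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells) + "\n"
            )
    return path


@pytest.fixture
def four_sample_map():
    return sw.SampleMap([("a1", "P1"), ("a2", "P1"), ("b1", "P2"), ("b2", "P2")])


@pytest.fixture
def toy_vcf(tmp_path, four_sample_map):
    """Five biallelic SNPs, four samples, two populations."""
    samples = ["a1", "a2", "b1", "b2"]
    records = [
        ("1", 100, "A", "G", [0, 1, 1, 2]),
        ("1", 200, "C", "T", [1, 1, 0, 0]),
        ("1", 300, "G", "A", [2, 2, 0, 0]),
        ("2", 150, "T", "C", [0, 0, 1, 1]),
        ("2", 250, "A", "C", [1, -1, 1, 0]),
    ]
    return write_vcf(tmp_path / "toy.vcf", samples, records)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small two-chromosome simulation with two planted sweeps."""
    out = tmp_path_factory.mktemp("sim")
    cfg = sw.SimConfig(
        seed=7,
        n_chrom=2,
        chrom_length=2_000_000,
        snp_count=2_000,
        sweeps=(
            sw.Sweep("1", 500_000, 600_000, "AB"),
            sw.Sweep("2", 1_200_000, 1_300_000, "AB"),
        ),
    )
    return cfg, sw.simulate(cfg, out)
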