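"""Synthetic two-population diploid data with planted selective sweeps.

The generator emulates the data structure a two-population sweep scan
consumes: a multi-sample VCF of biallelic SNPs with genotypes and per-sample
depth, a sample-to-population map, a gene annotation, and a truth BED of the
planted sweep intervals.

Model
-----
Allele frequencies are simulated at the frequency level (no linkage):

* per SNP an ancestral ALT frequency ``q ~ Beta(a, b)``;
* each population drifts independently under a Balding-Nichols model —
  its frequency is drawn from ``Beta(q(1-F)/F, (1-q)(1-F)/F)``, which has
  mean ``q`` and variance ``F q (1-q)`` for drift parameter ``F``;
* inside a planted sweep the swept population's frequency is replaced so
  that its locally major allele sits at ``target_freq`` (near 1), collapsing
  heterozygosity there while the other population keeps its drifted
  frequency (elevated differentiation);
* genotypes are ``Binomial(2, p)`` per diploid individual, calls are dropped
  at ``missing_rate``, and per-sample depth is ``Poisson(depth_mean)``.

The same configuration and seed always produce byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .scan_stats import Window
from .variant_io import SampleMap

__all__ = [
    "Sweep",
    "SimConfig",
    "SweepTruth",
    "SimOutput",
    "RecoveryReport",
    "default_sweeps",
    "simulate",
    "truth_recovery_report",
    "make_filter_demo",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class Sweep:
    """A planted sweep: the swept population's major allele is pushed to
    ``target_freq`` over [start, end) (0-based half-open)."""

    chrom: str
    start: int
    end: int
    population: str
    target_freq: float = 0.98

    def __post_init__(self) -> None:
        if not 0.5 < self.target_freq <= 1.0:
            raise ValueError("target_freq must be in (0.5, 1]")
        if self.end <= self.start or self.start < 0:
            raise ValueError("invalid sweep interval")


def default_sweeps(population: str = "AB") -> list[Sweep]:
    """Five window-aligned 100-kb sweeps spread over two 5-Mb chromosomes."""
    spans = [
        ("1", 1_000_000, 1_100_000),
        ("1", 2_500_000, 2_600_000),
        ("1", 4_000_000, 4_100_000),
        ("2", 1_500_000, 1_600_000),
        ("2", 3_500_000, 3_600_000),
    ]
    return [Sweep(c, s, e, population) for c, s, e in spans]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults model a small resequencing panel: two populations of 12 and 11
    diploids, two 5-Mb chromosomes carrying 5,000 SNPs each, uniform
    ancestral frequencies, drift F = 0.05, a 2 % missing-call rate, and a
    mean depth of 16 reads. Five 100-kb sweeps are planted in the first
    population at target frequency 0.98.
    """

    seed: int
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    snp_count: int = 5_000  # per chromosome
    populations: tuple[str, str] = ("AB", "BG")
    n_per_pop: tuple[int, int] = (12, 11)
    background_beta: tuple[float, float] = (1.0, 1.0)
    divergence_f: float = 0.05
    sweeps: tuple[Sweep, ...] = field(
        default_factory=lambda: tuple(default_sweeps())
    )
    missing_rate: float = 0.02
    depth_mean: float = 16.0

    def __post_init__(self) -> None:
        if self.snp_count > self.chrom_length:
            raise ValueError("more SNPs requested than available positions")
        if not 0.0 <= self.divergence_f < 1.0:
            raise ValueError("divergence_f must be in [0, 1)")
        chroms = {str(i + 1) for i in range(self.n_chrom)}
        for sw in self.sweeps:
            if sw.chrom not in chroms:
                raise ValueError(f"sweep on unknown chromosome {sw.chrom!r}")
            if sw.end > self.chrom_length:
                raise ValueError("sweep interval outside chromosome bounds")
            if sw.population not in self.populations:
                raise ValueError(f"sweep in unknown population {sw.population!r}")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(str(i + 1) for i in range(self.n_chrom))

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}


@dataclass
class SweepTruth:
    """The planted sweep intervals, writable as BED."""

    sweeps: tuple[Sweep, ...]

    def to_bed(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for sw in self.sweeps:
                fh.write(
                    f"{sw.chrom}\t{sw.start}\t{sw.end}\t"
                    f"{sw.population}:{sw.target_freq}\n"
                )

    def __len__(self) -> int:
        return len(self.sweeps)


@dataclass
class SimOutput:
    """Paths to the generated files plus the in-memory ground truth."""

    vcf: str
    popmap: str
    truth_bed: str
    gtf: str
    truth: SweepTruth
    sample_map: SampleMap
    chrom_lengths: dict[str, int]
    positions: dict[str, np.ndarray]  # 1-based SNP positions per chromosome
    true_freq: dict[str, dict[str, np.ndarray]]  # pop -> chrom -> ALT freq


@dataclass
class RecoveryReport:
    """Window-level recovery of planted sweeps by jointly flagged windows."""

    sensitivity: float  # fraction of sweeps overlapped by >=1 joint window
    fdr: float  # fraction of joint windows overlapping no sweep
    n_truth: int
    n_joint: int
    recovered: tuple[bool, ...]  # per planted sweep, in truth order


def _gt_string(d: int, dp: int) -> str:
    if d < 0:
        return f"./.:{dp}"
    return ("0/0", "0/1", "1/1")[d] + f":{dp}"


def simulate(cfg: SimConfig, outdir: str | os.PathLike) -> SimOutput:
    """Generate VCF + population map + truth BED + toy GTF under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    pops = cfg.populations
    n1, n2 = cfg.n_per_pop
    samples = [f"{pops[0]}{i + 1:02d}" for i in range(n1)] + [
        f"{pops[1]}{i + 1:02d}" for i in range(n2)
    ]
    pop_of = [pops[0]] * n1 + [pops[1]] * n2
    sample_map = SampleMap(list(zip(samples, pop_of)))

    a, b = cfg.background_beta
    F = cfg.divergence_f
    positions: dict[str, np.ndarray] = {}
    true_freq: dict[str, dict[str, np.ndarray]] = {p: {} for p in pops}
    vcf_path = os.path.join(outdir, "sim.vcf")

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan-simulate\n")
        for c in cfg.chrom_names:
            fh.write(f"##contig=<ID={c},length={cfg.chrom_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom in cfg.chrom_names:
            S = cfg.snp_count
            pos = np.sort(
                rng.choice(cfg.chrom_length, size=S, replace=False)
            ) + 1  # 1-based
            positions[chrom] = pos
            q = np.clip(rng.beta(a, b, size=S), 1e-9, 1 - 1e-9)
            freqs = {}
            for pop in pops:
                if F > 0:
                    p = rng.beta(q * (1 - F) / F, (1 - q) * (1 - F) / F)
                else:
                    p = q.copy()
                freqs[pop] = np.clip(p, 0.0, 1.0)
            # Plant sweeps: push the locally major allele to target_freq.
            for sw in cfg.sweeps:
                if sw.chrom != chrom:
                    continue
                in_sw = (pos - 1 >= sw.start) & (pos - 1 < sw.end)
                p = freqs[sw.population]
                p[in_sw] = np.where(
                    p[in_sw] >= 0.5, sw.target_freq, 1.0 - sw.target_freq
                )
            for pop in pops:
                true_freq[pop][chrom] = freqs[pop]

            pmat = np.concatenate(
                [
                    np.repeat(freqs[pops[0]][:, None], n1, axis=1),
                    np.repeat(freqs[pops[1]][:, None], n2, axis=1),
                ],
                axis=1,
            )
            gt = rng.binomial(2, pmat).astype(np.int8)
            miss = rng.random(gt.shape) < cfg.missing_rate
            gt[miss] = -1
            dp = rng.poisson(cfg.depth_mean, size=gt.shape)
            ref_idx = rng.integers(0, 4, size=S)
            alt_idx = (ref_idx + rng.integers(1, 4, size=S)) % 4

            for i in range(S):
                row = "\t".join(
                    _gt_string(int(gt[i, j]), int(dp[i, j]))
                    for j in range(gt.shape[1])
                )
                fh.write(
                    f"{chrom}\t{pos[i]}\t.\t{_BASES[ref_idx[i]]}\t"
                    f"{_BASES[alt_idx[i]]}\t.\tPASS\t.\tGT:DP\t{row}\n"
                )

    popmap_path = os.path.join(outdir, "popmap.tsv")
    sample_map.to_tsv(popmap_path)

    truth = SweepTruth(tuple(cfg.sweeps))
    truth_path = os.path.join(outdir, "truth.bed")
    truth.to_bed(truth_path)

    gtf_path = os.path.join(outdir, "genes.gtf")
    _write_toy_gtf(cfg, gtf_path)

    return SimOutput(
        vcf=vcf_path,
        popmap=popmap_path,
        truth_bed=truth_path,
        gtf=gtf_path,
        truth=truth,
        sample_map=sample_map,
        chrom_lengths=cfg.chrom_lengths,
        positions=positions,
        true_freq=true_freq,
    )


def _write_toy_gtf(cfg: SimConfig, path: str | os.PathLike) -> None:
    """One gene centered in each sweep plus >=3 background genes outside."""
    genes: list[tuple[str, int, int, str]] = []  # chrom, start0, end0, name
    for i, sw in enumerate(cfg.sweeps, 1):
        width = min(40_000, sw.end - sw.start)
        mid = (sw.start + sw.end) // 2
        genes.append((sw.chrom, mid - width // 2, mid - width // 2 + width, f"SWG{i}"))

    width = max(1000, min(40_000, cfg.chrom_length // 20))
    n_bg = 0
    for chrom in cfg.chrom_names:
        for k in range(1, 8):
            start = k * cfg.chrom_length // 8
            end = start + width
            if end > cfg.chrom_length:
                continue
            clash = any(
                sw.chrom == chrom and sw.start < end + 50_000 and start - 50_000 < sw.end
                for sw in cfg.sweeps
            )
            if clash:
                continue
            n_bg += 1
            genes.append((chrom, start, end, f"BGG{n_bg}"))
            if n_bg >= 4:
                break
        if n_bg >= 4:
            break

    genes.sort(key=lambda g: (g[0], g[1]))
    with open(path, "w") as fh:
        for chrom, s0, e0, name in genes:
            attrs = f'gene_id "{name}"; gene_name "{name}";'
            fh.write(
                f"{chrom}\tsweepscan_sim\tgene\t{s0 + 1}\t{e0}\t.\t+\t.\t{attrs}\n"
            )


def truth_recovery_report(
    joint_windows: Sequence[Window], truth: SweepTruth
) -> RecoveryReport:
    """Window-level sensitivity and false-discovery fraction.

    Sensitivity is the fraction of planted sweeps overlapped (>= 1 bp) by at
    least one jointly flagged window; FDR is the fraction of joint windows
    overlapping no sweep. With no joint windows FDR is reported as 0.
    """
    recovered = tuple(
        any(w.overlaps(sw.chrom, sw.start, sw.end) for w in joint_windows)
        for sw in truth.sweeps
    )
    n_joint = len(joint_windows)
    false = sum(
        1
        for w in joint_windows
        if not any(w.overlaps(sw.chrom, sw.start, sw.end) for sw in truth.sweeps)
    )
    sensitivity = (sum(recovered) / len(truth)) if len(truth) else 1.0
    fdr = (false / n_joint) if n_joint else 0.0
    return RecoveryReport(
        sensitivity=sensitivity,
        fdr=fdr,
        n_truth=len(truth),
        n_joint=n_joint,
        recovered=recovered,
    )


def make_filter_demo(outdir: str | os.PathLike) -> tuple[str, str, dict[str, int]]:
    """Write a 100-site demonstration VCF with known filter failures.

    Ten diploid samples in two populations. Eighty-eight sites pass the
    default filters; twelve fail, by construction: 3 multiallelic, 2 on a
    non-autosome (X), 3 by mean depth (2, exactly 3, and exactly 30 reads),
    2 by pooled MAF (exactly 0.05, and monomorphic), 2 by missingness
    (exactly 0.1, and 0.3). Returns (vcf path, popmap path, expected counts).
    """
    os.makedirs(outdir, exist_ok=True)
    samples = [f"s{i:02d}" for i in range(1, 11)]
    pop_of = ["P1"] * 5 + ["P2"] * 5
    sample_map = SampleMap(list(zip(samples, pop_of)))
    popmap_path = os.path.join(outdir, "demo_popmap.tsv")
    sample_map.to_tsv(popmap_path)

    def gts(dosages: Sequence[int], dp: int | Sequence[int]) -> str:
        dps = [dp] * 10 if isinstance(dp, int) else list(dp)
        return "\t".join(_gt_string(d, dpv) for d, dpv in zip(dosages, dps))

    def het_pattern(n_het: int) -> list[int]:
        return [1] * n_het + [0] * (10 - n_het)

    lines: list[str] = []
    pos = 0

    def add(chrom: str, ref: str, alt: str, gt_field: str) -> None:
        nonlocal pos
        pos += 1000
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP\t{gt_field}"
        )

    for k in range(88):  # passing sites: MAF 0.1-0.4, no missing, depth 16
        add("1", "A", "G", gts(het_pattern(2 + k % 7), 16))
    for _ in range(3):  # multiallelic
        add("1", "A", "G,T", gts(het_pattern(4), 16))
    for dp in (2, 3, 30):  # depth failures (boundaries are strict)
        add("1", "A", "G", gts(het_pattern(4), dp))
    add("1", "A", "G", gts([1] + [0] * 9, 16))  # MAF exactly 1/20 = 0.05
    add("1", "A", "G", gts([0] * 10, 16))  # monomorphic, MAF 0
    add("1", "A", "G", gts([-1] + [1, 1, 1] + [0] * 6, 16))  # missing 0.1
    add("1", "A", "G", gts([-1, -1, -1] + [1] * 4 + [0] * 3, 16))  # missing 0.3
    xpos = 0
    for _ in range(2):  # non-autosomal
        xpos += 1000
        lines.append(
            f"X\t{xpos}\t.\tA\tG\t.\tPASS\t.\tGT:DP\t{gts(het_pattern(4), 16)}"
        )

    vcf_path = os.path.join(outdir, "filter_demo.vcf")
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1,length=200000>\n")
        fh.write("##contig=<ID=X,length=200000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        fh.write("\n".join(lines) + "\n")

    expected = {
        "retained": 88,
        "non_snp_multiallelic": 3,
        "non_autosomal": 2,
        "depth": 3,
        "maf": 2,
        "missingness": 2,
    }
    return vcf_path, popmap_path, expected
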