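"""Candidate-gene calling: intersect outlier windows from the two statistics
and name genes overlapping both.

A gene is a candidate iff its body (optionally extended by a flank) shares at
least 1 bp with some ZFST-flagged window AND at least 1 bp with some
ZHp-flagged window. The two supporting windows need not coincide; when no
single window carries both flags the candidate is marked "split support".
Reported per-gene statistics come from the most extreme supporting window of
each statistic (highest ZFST, lowest ZHp), giving one row per gene.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import pyranges as pr
from intervaltree import IntervalTree

from .scan_stats import OutlierSet, WindowStatRecord

__all__ = [
    "GeneModel",
    "CandidateGene",
    "read_gtf",
    "intersect_outlier_sets",
    "candidate_genes",
    "write_candidates_tsv",
    "write_candidates_bed",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene with its 1-based inclusive GTF span (min start / max end over
    all of the gene's features)."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def interval0(self) -> tuple[int, int]:
        """0-based half-open span."""
        return self.start - 1, self.end


@dataclass
class CandidateGene:
    """A gene supported by outlier windows under both statistics."""

    gene: GeneModel
    fst_windows: list[WindowStatRecord]
    hp_windows: list[WindowStatRecord]
    hp_pop: str  # population label of the Hp outlier set
    split_support: bool

    @property
    def best_fst(self) -> WindowStatRecord:
        return max(self.fst_windows, key=lambda r: r.zfst)

    @property
    def best_hp(self) -> WindowStatRecord:
        return min(self.hp_windows, key=lambda r: r.zhp[self.hp_pop])

    def __post_init__(self) -> None:
        if not self.fst_windows or not self.hp_windows:
            raise ValueError("candidate requires support from both statistics")


def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    """Read a GTF/GFF2 annotation into one :class:`GeneModel` per gene_id.

    Any feature type contributes: the gene span is the min start / max end
    over all features sharing a gene_id, so exon-only files work. gene_name
    falls back to gene_id when absent.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        df = pr.read_gtf(path).df
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse GTF: {exc}") from exc
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: no gene_id attribute found")
    genes: list[GeneModel] = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        name = gene_id
        if "gene_name" in grp.columns:
            named = grp["gene_name"].dropna()
            if len(named):
                name = str(named.iloc[0])
        genes.append(
            GeneModel(
                gene_id=str(gene_id),
                gene_name=name,
                chrom=str(grp["Chromosome"].iloc[0]),
                start=int(grp["Start"].min()) + 1,  # pyranges stores 0-based
                end=int(grp["End"].max()),
                strand=str(grp["Strand"].iloc[0]) if "Strand" in grp else ".",
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _window_trees(records: Sequence[WindowStatRecord]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rec in records:
        w = rec.window
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, rec)
    return trees


def intersect_outlier_sets(
    fst_out: OutlierSet, hp_out: OutlierSet
) -> list[tuple[WindowStatRecord, WindowStatRecord]]:
    """All (FST window, Hp window) pairs sharing >= 1 bp.

    Symmetric in its arguments; half-open coordinates, so abutting windows do
    not pair.
    """
    trees = _window_trees(hp_out.records)
    pairs: list[tuple[WindowStatRecord, WindowStatRecord]] = []
    for rec in fst_out.records:
        w = rec.window
        for hit in sorted(trees.get(w.chrom, IntervalTree()).overlap(w.start, w.end)):
            pairs.append((rec, hit.data))
    pairs.sort(
        key=lambda p: (
            p[0].window.chrom,
            p[0].window.start,
            p[1].window.start,
        )
    )
    return pairs


def candidate_genes(
    genes: Sequence[GeneModel],
    fst_out: OutlierSet,
    hp_out: OutlierSet,
    flank: int = 0,
) -> list[CandidateGene]:
    """Genes overlapping >= 1 bp of an outlier window under each statistic.

    ``flank`` extends the gene body symmetrically (bp) before testing
    overlap; the default 0 uses the gene body alone. Output is sorted by
    (chrom, start). ``split_support`` records whether no single window
    carries both flags over the gene.
    """
    fst_trees = _window_trees(fst_out.records)
    hp_trees = _window_trees(hp_out.records)
    out: list[CandidateGene] = []
    for gene in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        g0, g1 = gene.interval0
        g0 = max(0, g0 - flank)
        g1 = g1 + flank
        fhits = [
            h.data for h in sorted(fst_trees.get(gene.chrom, IntervalTree()).overlap(g0, g1))
        ]
        hhits = [
            h.data for h in sorted(hp_trees.get(gene.chrom, IntervalTree()).overlap(g0, g1))
        ]
        if not fhits or not hhits:
            continue
        fst_keys = {(r.window.chrom, r.window.start, r.window.end) for r in fhits}
        hp_keys = {(r.window.chrom, r.window.start, r.window.end) for r in hhits}
        out.append(
            CandidateGene(
                gene=gene,
                fst_windows=fhits,
                hp_windows=hhits,
                hp_pop=hp_out.label,
                split_support=not (fst_keys & hp_keys),
            )
        )
    return out


def write_candidates_tsv(
    candidates: Sequence[CandidateGene], path: str | os.PathLike
) -> None:
    """One row per candidate gene with its most extreme supporting windows."""
    with open(path, "w") as fh:
        fh.write(
            "gene\tchrom\tstart_mb\tend_mb\tfst\tzfst\thp\tzhp\tsupport\n"
        )
        for c in candidates:
            bf, bh = c.best_fst, c.best_hp
            fh.write(
                f"{c.gene.gene_name}\t{c.gene.chrom}\t"
                f"{(c.gene.start - 1) / 1e6:.2f}\t{c.gene.end / 1e6:.2f}\t"
                f"{bf.fst_mean:.4f}\t{bf.zfst:.4f}\t"
                f"{bh.hp[c.hp_pop]:.4f}\t{bh.zhp[c.hp_pop]:.4f}\t"
                f"{'split' if c.split_support else 'joint'}\n"
            )


def write_candidates_bed(
    candidates: Sequence[CandidateGene], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            s0, e0 = c.gene.interval0
            fh.write(f"{c.gene.chrom}\t{s0}\t{e0}\t{c.gene.gene_name}\n")
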