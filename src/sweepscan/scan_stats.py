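"""Sliding-window selection-scan statistics: per-SNP FST, windowed pooled
heterozygosity, Z-transforms, and outlier calling.

Two complementary signals of a recent positive-selection sweep are computed
over a tiling of overlapping genomic windows (default 100 kb advanced in
50-kb steps):

* **FST** — allele-frequency differentiation between two populations. For a
  biallelic SNP with population frequencies ``p1`` and ``p2``,

  .. math:: F_{ST} = \\frac{s^2}{\\bar p(1-\\bar p) + s^2/r}

  with :math:`\\bar p` the mean frequency across the ``r = 2`` populations
  and :math:`s^2 = \\sum_i (p_i-\\bar p)^2/(r-1)` the between-population
  sampling variance of frequency (so a fixed difference gives exactly 1).
  Per-SNP values are averaged, unweighted, within each window.

* **Pooled heterozygosity** ``Hp`` — within one population, major and minor
  allele counts are summed over a window's SNPs and combined as
  ``Hp = 2*S_maj*S_min / (S_maj + S_min)**2`` ∈ [0, 0.5]. Windows near
  fixation (a swept haplotype) give Hp near 0.

Both window statistics are Z-transformed against their genome-wide mean and
standard deviation; outliers are the top fraction of ZFST windows (default
1 %) and windows with ZHp at or below a fixed threshold (default −4).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import VariantTable

__all__ = [
    "Window",
    "FstResult",
    "WindowStatRecord",
    "OutlierSet",
    "make_windows",
    "per_snp_fst",
    "fst_series",
    "window_fst",
    "window_hp",
    "z_transform",
    "scan_windows",
    "call_fst_outliers",
    "call_hp_outliers",
    "records_to_frame",
    "write_windows_tsv",
    "write_outliers_bed",
]


@dataclass(frozen=True, order=True)
class Window:
    """Half-open genomic interval [start, end), 0-based."""

    chrom: str
    start: int
    end: int
    index: int = 0  # rank along the chromosome

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class FstResult:
    """Per-SNP FST with its components; ``evaluable`` is False when the site
    is monomorphic in both populations (zero denominator)."""

    fst: float
    s2: float
    pbar: float
    r: int = 2

    @property
    def evaluable(self) -> bool:
        return not math.isnan(self.fst)


@dataclass
class WindowStatRecord:
    """All per-window statistics. NaN marks an unevaluable entry."""

    window: Window
    n_snps: int  # sites falling in the window
    n_fst: int  # FST-evaluable sites
    fst_mean: float
    zfst: float
    n_typed: dict[str, int] = field(default_factory=dict)
    hp: dict[str, float] = field(default_factory=dict)
    zhp: dict[str, float] = field(default_factory=dict)


@dataclass
class OutlierSet:
    """Windows flagged by one statistic, with the rule that produced them."""

    statistic: str  # "ZFST" | "ZHP"
    rule: str  # "top-fraction" | "threshold"
    parameter: float
    label: str  # comparison "P1-P2" or population name
    records: list[WindowStatRecord]

    @property
    def windows(self) -> list[Window]:
        return [r.window for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def make_windows(
    chrom_lengths: Mapping[str, int],
    window_size: int = 100_000,
    step: int = 50_000,
) -> list[Window]:
    """Tile each chromosome from 0 with fixed-size windows and step.

    A trailing window is emitted iff its start lies before the chromosome
    end; its end is truncated to the chromosome length.
    """
    if step <= 0 or window_size <= 0:
        raise ValueError("window_size and step must be positive")
    if step > window_size:
        raise ValueError("step must not exceed window_size")
    windows: list[Window] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom!r}")
        for idx, start in enumerate(range(0, length, step)):
            windows.append(
                Window(chrom, start, min(start + window_size, length), idx)
            )
    return windows


def per_snp_fst(p1: float, p2: float, r: int = 2) -> FstResult:
    """Variance-based FST for one biallelic SNP from two ALT frequencies.

    Sites monomorphic in both populations (``p1 == p2`` in {0, 1}) have a
    zero denominator and are returned with ``fst = NaN`` (unevaluable).
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"allele frequency outside [0, 1]: {p}")
    pbar = (p1 + p2) / 2.0
    s2 = ((p1 - pbar) ** 2 + (p2 - pbar) ** 2) / (r - 1)
    denom = pbar * (1.0 - pbar) + s2 / r
    fst = s2 / denom if denom > 0 else float("nan")
    return FstResult(fst=fst, s2=s2, pbar=pbar, r=r)


def fst_series(p1: np.ndarray, p2: np.ndarray, r: int = 2) -> np.ndarray:
    """Vectorized :func:`per_snp_fst`; NaN where unevaluable (either because
    the denominator is zero or because a frequency is itself NaN/untyped)."""
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        bad = (p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)
    if bad.any():
        raise ValueError("allele frequency outside [0, 1]")
    pbar = (p1 + p2) / 2.0
    s2 = ((p1 - pbar) ** 2 + (p2 - pbar) ** 2) / (r - 1)
    denom = pbar * (1.0 - pbar) + s2 / r
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, s2 / np.where(denom > 0, denom, 1.0), np.nan)


def window_hp(sum_n_maj: int, sum_n_min: int) -> float:
    """Pooled heterozygosity from window-summed major/minor allele counts.

    Integer arithmetic up to the final division, so the result is the
    correctly rounded value of ``2*S_maj*S_min / (S_maj+S_min)**2``.
    """
    if sum_n_maj < 0 or sum_n_min < 0:
        raise ValueError("allele-count sums must be non-negative")
    total = sum_n_maj + sum_n_min
    if total == 0:
        raise ValueError("no typed sites: Hp undefined")
    return (2 * sum_n_maj * sum_n_min) / (total * total)


def window_fst(
    pos0: np.ndarray,
    fst: np.ndarray,
    windows: Sequence[Window],
    min_snps: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted per-window mean of evaluable per-SNP FST values.

    ``pos0`` are sorted 0-based positions on one chromosome; ``fst`` the
    matching per-SNP values (NaN = unevaluable). With a step smaller than the
    window size a SNP contributes to every window covering it. Windows with
    fewer than ``min_snps`` evaluable SNPs get NaN. Returns
    ``(means, n_evaluable)`` aligned with ``windows``.
    """
    pos0 = np.asarray(pos0)
    fst = np.asarray(fst, dtype=np.float64)
    means = np.full(len(windows), np.nan)
    counts = np.zeros(len(windows), dtype=int)
    for i, (lo, hi) in enumerate(_window_slices(pos0, windows)):
        vals = fst[lo:hi]
        n = int(np.isfinite(vals).sum())
        counts[i] = n
        if n >= max(min_snps, 1):
            means[i] = float(np.nanmean(vals))
    return means, counts


def z_transform(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Center/scale a genome-wide statistic to mean 0, unit SD.

    NaN entries (unevaluable windows) are ignored in the moments and
    propagated. The sample standard deviation (``ddof=1``) is the default
    convention. A degenerate (constant) distribution raises ``ValueError``.
    """
    values = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise ValueError("need at least 2 evaluable windows to Z-transform")
    mu = values[finite].mean()
    sigma = values[finite].std(ddof=ddof)
    if sigma == 0 or not np.isfinite(sigma):
        raise ValueError("degenerate statistic distribution (sigma = 0)")
    out = np.full_like(values, np.nan)
    out[finite] = (values[finite] - mu) / sigma
    return out


def _window_slices(
    pos0: np.ndarray, windows: Sequence[Window]
) -> list[tuple[int, int]]:
    """Half-open index ranges of sorted 0-based positions per window."""
    lo = np.searchsorted(pos0, [w.start for w in windows], side="left")
    hi = np.searchsorted(pos0, [w.end for w in windows], side="left")
    return list(zip(lo.tolist(), hi.tolist()))


def scan_windows(
    vt: VariantTable,
    fst_pops: tuple[str, str],
    hp_pops: Sequence[str] | None = None,
    window_size: int = 100_000,
    step: int = 50_000,
    min_snps: int = 10,
    chrom_lengths: Mapping[str, int] | None = None,
    ddof: int = 1,
    r_divisor: int = 2,
) -> list[WindowStatRecord]:
    """Run the two-statistic window scan over a filtered variant table.

    Per window: the unweighted mean of evaluable per-SNP FST values between
    ``fst_pops``, and pooled heterozygosity per population in ``hp_pops``
    from window-summed major/minor counts. Windows with fewer than
    ``min_snps`` contributing sites for a statistic are unevaluable for that
    statistic (NaN) and excluded from its Z-transform. VCF positions are
    mapped to 0-based half-open coordinates internally.
    """
    if len(fst_pops) != 2 or fst_pops[0] == fst_pops[1]:
        raise ValueError("fst_pops must name exactly 2 distinct populations")
    hp_pops = list(hp_pops) if hp_pops is not None else list(fst_pops)

    if chrom_lengths is None:
        chrom_lengths = dict(vt.contig_lengths)
    chrom_lengths = dict(chrom_lengths)
    for chrom in dict.fromkeys(vt.chrom.astype(str)):
        if chrom not in chrom_lengths or chrom_lengths[chrom] <= 0:
            chrom_lengths[chrom] = int(vt.pos[vt.chrom.astype(str) == chrom].max())
    windows = make_windows(chrom_lengths, window_size, step)

    # Per-population allele counts at every site.
    freqs: dict[str, np.ndarray] = {}
    majmin: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for pop in dict.fromkeys(list(fst_pops) + hp_pops):
        ac, an = vt.pop_allele_matrix(pop)
        typed = an > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(typed, ac / np.maximum(an, 1), np.nan)
        freqs[pop] = p
        n_maj = np.where(typed, np.maximum(ac, an - ac), 0)
        n_min = np.where(typed, np.minimum(ac, an - ac), 0)
        majmin[pop] = (n_maj, n_min, typed)

    fst = fst_series(
        np.where(np.isnan(freqs[fst_pops[0]]), 0.5, freqs[fst_pops[0]]),
        np.where(np.isnan(freqs[fst_pops[1]]), 0.5, freqs[fst_pops[1]]),
        r=r_divisor,
    )
    # A site untyped in either population contributes no FST value.
    fst[np.isnan(freqs[fst_pops[0]]) | np.isnan(freqs[fst_pops[1]])] = np.nan

    chrom_arr = vt.chrom.astype(str)
    records: list[WindowStatRecord] = []
    for chrom in dict.fromkeys(w.chrom for w in windows):
        cmask = chrom_arr == chrom
        pos0 = vt.pos[cmask] - 1  # VCF 1-based -> 0-based
        cwindows = [w for w in windows if w.chrom == chrom]
        cfst = fst[cmask]
        cmaj = {p: (m[0][cmask], m[1][cmask], m[2][cmask]) for p, m in majmin.items()}
        fst_means, fst_counts = window_fst(pos0, cfst, cwindows, min_snps)
        for wi, (w, (i0, i1)) in enumerate(
            zip(cwindows, _window_slices(pos0, cwindows))
        ):
            sl = slice(i0, i1)
            n_snps = i1 - i0
            n_fst = int(fst_counts[wi])
            fst_mean = float(fst_means[wi])
            n_typed: dict[str, int] = {}
            hp: dict[str, float] = {}
            for pop in hp_pops:
                n_maj, n_min, typed = cmaj[pop]
                nt = int(typed[sl].sum())
                n_typed[pop] = nt
                if nt >= max(min_snps, 1):
                    hp[pop] = window_hp(
                        int(n_maj[sl].sum()), int(n_min[sl].sum())
                    )
                else:
                    hp[pop] = float("nan")
            records.append(
                WindowStatRecord(
                    window=w,
                    n_snps=n_snps,
                    n_fst=n_fst,
                    fst_mean=fst_mean,
                    zfst=float("nan"),
                    n_typed=n_typed,
                    hp=hp,
                    zhp={p: float("nan") for p in hp_pops},
                )
            )

    # Genome-wide Z-transforms over evaluable windows.
    zfst = z_transform(np.array([r.fst_mean for r in records]), ddof=ddof)
    for rec, z in zip(records, zfst):
        rec.zfst = float(z)
    for pop in hp_pops:
        zhp = z_transform(np.array([r.hp[pop] for r in records]), ddof=ddof)
        for rec, z in zip(records, zhp):
            rec.zhp[pop] = float(z)
    return records


def call_fst_outliers(
    records: Sequence[WindowStatRecord],
    fraction: float = 0.01,
    label: str = "",
) -> OutlierSet:
    """Flag the top ``ceil(fraction * N_evaluable)`` windows by ZFST.

    Ties at the cutoff are broken by (chrom, start) ascending so exactly
    ``k`` windows are flagged, deterministically.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    evaluable = [r for r in records if np.isfinite(r.zfst)]
    if not evaluable:
        raise ValueError("no evaluable windows to call FST outliers from")
    k = math.ceil(fraction * len(evaluable))
    ranked = sorted(
        evaluable, key=lambda r: (-r.zfst, r.window.chrom, r.window.start)
    )
    return OutlierSet(
        statistic="ZFST",
        rule="top-fraction",
        parameter=fraction,
        label=label,
        records=ranked[:k],
    )


def call_hp_outliers(
    records: Sequence[WindowStatRecord],
    population: str,
    threshold: float = -4.0,
) -> OutlierSet:
    """Flag windows with ``ZHp <= threshold`` for one population.

    The boundary is inclusive; an empty result is legal.
    """
    known = {p for r in records for p in r.zhp}
    if population not in known:
        raise KeyError(f"population {population!r} has no ZHp values")
    flagged = [
        r
        for r in records
        if np.isfinite(r.zhp[population]) and r.zhp[population] <= threshold
    ]
    flagged.sort(key=lambda r: (r.window.chrom, r.window.start))
    return OutlierSet(
        statistic="ZHP",
        rule="threshold",
        parameter=threshold,
        label=population,
        records=flagged,
    )


def records_to_frame(records: Sequence[WindowStatRecord]) -> pd.DataFrame:
    """BED-compatible table of per-window statistics."""
    pops = list(records[0].hp) if records else []
    rows = []
    for r in records:
        row = {
            "chrom": r.window.chrom,
            "start": r.window.start,
            "end": r.window.end,
            "n_snps": r.n_snps,
            "n_fst": r.n_fst,
            "fst_mean": r.fst_mean,
            "zfst": r.zfst,
        }
        for p in pops:
            row[f"hp_{p}"] = r.hp.get(p, float("nan"))
            row[f"zhp_{p}"] = r.zhp.get(p, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def write_windows_tsv(
    records: Sequence[WindowStatRecord], path: str | os.PathLike
) -> None:
    records_to_frame(records).to_csv(
        path, sep="\t", index=False, float_format="%.6g", na_rep="NA"
    )


def write_outliers_bed(outliers: OutlierSet, path: str | os.PathLike) -> None:
    """Flagged windows as BED4 with the Z score in the name column."""
    with open(path, "w") as fh:
        for r in sorted(
            outliers.records, key=lambda r: (r.window.chrom, r.window.start)
        ):
            z = r.zfst if outliers.statistic == "ZFST" else r.zhp[outliers.label]
            fh.write(
                f"{r.window.chrom}\t{r.window.start}\t{r.window.end}\t"
                f"{outliers.statistic}={z:.4f}\n"
            )
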