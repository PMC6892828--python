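"""VCF input, SNP quality filtering, and per-population allele counts.

This module turns a multi-sample VCF plus a sample-to-population map into a
:class:`VariantTable`: a column-oriented container of biallelic SNP sites with
per-sample ALT-dosage genotypes. Filtering follows the usual resequencing
conventions for a two-population scan: biallelic autosomal SNPs with a mean
per-site sequencing depth inside an accepted window, a pooled minor allele
frequency above a floor, and a missing-call fraction below a cap.

All boundary comparisons are strict (``depth_min < depth < depth_max``,
``MAF > maf_min``, ``missing < max_missing``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

__all__ = [
    "DEFAULT_AUTOSOMES",
    "FILTER_CRITERIA",
    "SampleMap",
    "VariantSite",
    "VariantTable",
    "FilterConfig",
    "FilterReport",
    "PopAlleleCounts",
    "read_vcf",
    "filter_variants",
    "allele_counts",
]

#: Goat-style autosome names 1-29, accepting both bare and ``chr``-prefixed
#: spellings. Configurable through :class:`FilterConfig`.
DEFAULT_AUTOSOMES = frozenset(str(i) for i in range(1, 30)) | frozenset(
    f"chr{i}" for i in range(1, 30)
)

#: Removal-attribution order: each excluded site is counted once, under the
#: first criterion it fails. Cheap structural checks come first so the report
#: is deterministic.
FILTER_CRITERIA = (
    "non_snp_multiallelic",
    "non_autosomal",
    "depth",
    "maf",
    "missingness",
)

_MISSING = -1  # genotype dosage sentinel


class SampleMap:
    """Ordered mapping from sample id to population label.

    Parameters
    ----------
    pairs
        Iterable of ``(sample_id, population)`` tuples. Each sample may appear
        at most once, and every population must contain at least two samples.
    """

    def __init__(self, pairs: Sequence[tuple[str, str]]):
        self._pop_of: dict[str, str] = {}
        for sample, pop in pairs:
            if sample in self._pop_of:
                raise ValueError(f"duplicate sample in population map: {sample!r}")
            self._pop_of[sample] = pop
        counts: dict[str, int] = {}
        for pop in self._pop_of.values():
            counts[pop] = counts.get(pop, 0) + 1
        small = sorted(p for p, c in counts.items() if c < 2)
        if small:
            raise ValueError(
                f"populations with fewer than 2 samples: {', '.join(small)}"
            )
        if not self._pop_of:
            raise ValueError("empty population map")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "SampleMap":
        """Read a headerless two-column TSV of ``sample_id<TAB>population``."""
        pairs = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, "
                        f"got {len(parts)}"
                    )
                pairs.append((parts[0], parts[1]))
        return cls(pairs)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for sample, pop in self._pop_of.items():
                fh.write(f"{sample}\t{pop}\n")

    @property
    def populations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for pop in self._pop_of.values():
            seen.setdefault(pop)
        return tuple(seen)

    def samples(self, population: str | None = None) -> tuple[str, ...]:
        if population is None:
            return tuple(self._pop_of)
        return tuple(s for s, p in self._pop_of.items() if p == population)

    def population_of(self, sample: str) -> str:
        return self._pop_of[sample]

    def __contains__(self, sample: str) -> bool:
        return sample in self._pop_of

    def __len__(self) -> int:
        return len(self._pop_of)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleMap) and self._pop_of == other._pop_of


@dataclass(frozen=True)
class VariantSite:
    """One VCF record: position, alleles, and per-sample ALT dosages.

    ``genotypes`` holds the ALT-allele dosage per sample (0, 1, 2) with -1 for
    a missing call, in the order given by ``samples``.
    """

    chrom: str
    pos: int  # 1-based, as read from the VCF
    ref: str
    alt: tuple[str, ...]
    genotypes: np.ndarray
    samples: tuple[str, ...]
    mean_depth: float  # NaN if DP was absent

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alt) == 1
            and len(self.ref) == 1
            and len(self.alt[0]) == 1
            and self.ref in "ACGT"
            and self.alt[0] in "ACGT"
        )


@dataclass(frozen=True)
class PopAlleleCounts:
    """Major/minor allele counts and ALT frequency within one population.

    ``n_maj + n_min`` equals twice the number of non-missing diploid calls.
    On a within-population tie the two counts are equal and the major/minor
    assignment is immaterial. ``typed`` is False when the population has no
    non-missing call at the site.
    """

    n_maj: int
    n_min: int
    p: float  # ALT-allele frequency among non-missing calls
    n_called: int

    @property
    def typed(self) -> bool:
        return self.n_called > 0

    def __post_init__(self) -> None:
        if self.n_maj < self.n_min:
            raise ValueError("n_maj must be >= n_min")
        if self.n_maj + self.n_min != 2 * self.n_called:
            raise ValueError("allele counts must sum to twice the call count")


@dataclass(frozen=True)
class FilterConfig:
    """Site-retention thresholds.

    depth_min, depth_max : reads
        Accepted open interval for the mean per-site depth over called
        samples. Defaults 3 and 30.
    maf_min : frequency
        Pooled minor allele frequency must strictly exceed this (default 0.05).
    max_missing : fraction
        Missing-call fraction must be strictly below this (default 0.1).
    autosomes
        Chromosome names accepted as autosomal.
    """

    depth_min: float = 3.0
    depth_max: float = 30.0
    maf_min: float = 0.05
    max_missing: float = 0.1
    autosomes: frozenset[str] = field(default_factory=lambda: DEFAULT_AUTOSOMES)

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if not 0 <= self.max_missing <= 1:
            raise ValueError("max_missing must be in [0, 1]")
        if not self.depth_min < self.depth_max:
            raise ValueError("depth_min must be < depth_max")


@dataclass
class FilterReport:
    """Per-criterion removal counts, in attribution order."""

    n_input: int
    n_retained: int
    removed: dict[str, int]
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.removed.values())
        if total != self.n_input - self.n_retained:
            raise ValueError("removal counts do not sum to input - retained")

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("criterion\tremoved_count\n")
            for crit in FILTER_CRITERIA:
                fh.write(f"{crit}\t{self.removed.get(crit, 0)}\n")
            fh.write(f"retained\t{self.n_retained}\n")


class VariantTable:
    """Column-oriented table of variant sites for a fixed sample set.

    Sites are kept sorted by ``(chrom, pos)``. Genotypes are stored as an
    ``(n_sites, n_samples)`` int8 matrix of ALT dosages with -1 for missing.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        ref: np.ndarray,
        alt: Sequence[tuple[str, ...]],
        gt: np.ndarray,
        mean_depth: np.ndarray,
        samples: Sequence[str],
        sample_map: SampleMap,
        has_dp: bool = True,
        contig_lengths: Mapping[str, int] | None = None,
    ):
        order = np.lexsort((pos, chrom.astype(str)))
        self.chrom = chrom[order]
        self.pos = pos[order]
        self.ref = ref[order]
        self.alt = [tuple(alt[i]) for i in order]
        self.gt = gt[order]
        self.mean_depth = mean_depth[order]
        self.samples = tuple(samples)
        self.sample_map = sample_map
        self.has_dp = has_dp
        self.contig_lengths = dict(contig_lengths or {})

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def site(self, i: int) -> VariantSite:
        return VariantSite(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            ref=str(self.ref[i]),
            alt=self.alt[i],
            genotypes=self.gt[i],
            samples=self.samples,
            mean_depth=float(self.mean_depth[i]),
        )

    def sites(self) -> Iterator[VariantSite]:
        for i in range(len(self)):
            yield self.site(i)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        idx = np.flatnonzero(mask)
        return VariantTable(
            self.chrom[idx],
            self.pos[idx],
            self.ref[idx],
            [self.alt[i] for i in idx],
            self.gt[idx],
            self.mean_depth[idx],
            self.samples,
            self.sample_map,
            self.has_dp,
            self.contig_lengths,
        )

    def pop_columns(self, population: str) -> np.ndarray:
        cols = [
            i
            for i, s in enumerate(self.samples)
            if s in self.sample_map and self.sample_map.population_of(s) == population
        ]
        if not cols:
            raise KeyError(f"population {population!r} has no samples in the table")
        return np.asarray(cols, dtype=int)

    def pop_allele_matrix(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-site ALT count and total allele number for one population.

        Returns ``(ac, an)`` where ``an`` is twice the non-missing call count;
        sites with ``an == 0`` are untyped for the population.
        """
        g = self.gt[:, self.pop_columns(population)]
        called = g != _MISSING
        ac = np.where(called, g, 0).sum(axis=1).astype(np.int64)
        an = 2 * called.sum(axis=1).astype(np.int64)
        return ac, an

    def pooled_alt_frequency(self) -> np.ndarray:
        """ALT frequency over all mapped samples; NaN where no call."""
        called = self.gt != _MISSING
        ac = np.where(called, self.gt, 0).sum(axis=1)
        an = 2 * called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, ac / np.maximum(an, 1), np.nan)


def read_vcf(path: str | os.PathLike, sample_map: SampleMap) -> VariantTable:
    """Read a VCF (plain or bgzipped) into a :class:`VariantTable`.

    Only samples present in ``sample_map`` are retained; genotypes of unmapped
    samples are ignored in all downstream counts. Multi-allelic and non-SNP
    records are kept (flagged for removal by :func:`filter_variants`) so that
    the filter report can attribute them. Positions stay 1-based as in the VCF.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    header = VCF(path)
    present = set(header.samples)
    header.close()
    missing = [s for s in sample_map.samples() if s not in present]
    if missing:
        raise ValueError(
            f"samples in population map absent from VCF header: {', '.join(missing)}"
        )
    keep = [s for s in sample_map.samples() if s in present]
    vcf = VCF(path, gts012=True, samples=keep)
    samples = list(vcf.samples)

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    gts: list[np.ndarray] = []
    depths: list[float] = []
    has_dp = False
    dosage_of = np.array([0, 1, 2, _MISSING], dtype=np.int8)  # gts012 order

    for lineno, rec in enumerate(vcf, 1):
        try:
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            refs.append(rec.REF)
            alts.append(tuple(rec.ALT))
            g = dosage_of[rec.gt_types]
            gts.append(g)
            dp = rec.format("DP")
            if dp is None:
                depths.append(np.nan)
            else:
                has_dp = True
                dp = dp.reshape(-1).astype(np.float64)
                ok = (dp >= 0) & (g != _MISSING)
                depths.append(float(dp[ok].mean()) if ok.any() else np.nan)
        except Exception as exc:  # pragma: no cover - malformed input path
            raise ValueError(f"{path}: malformed record #{lineno}: {exc}") from exc
    contig_lengths = {
        name: int(length)
        for name, length in zip(vcf.seqnames, vcf.seqlens or [])
        if length
    }
    vcf.close()

    n = len(poss)
    gt = (
        np.vstack(gts)
        if n
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return VariantTable(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=alts,
        gt=gt,
        mean_depth=np.asarray(depths, dtype=np.float64),
        samples=samples,
        sample_map=sample_map,
        has_dp=has_dp,
        contig_lengths=contig_lengths,
    )


def filter_variants(
    vt: VariantTable, cfg: FilterConfig | None = None
) -> tuple[VariantTable, FilterReport]:
    """Apply the SNP retention criteria and report per-criterion removals.

    A site is retained iff it is a biallelic SNP, lies on a configured
    autosome, has ``depth_min < mean depth < depth_max`` (sites without DP
    pass, with a note), pooled ``MAF > maf_min``, and missing fraction
    ``< max_missing``. Each removed site is attributed to the first failed
    criterion in :data:`FILTER_CRITERIA` order. Filtering is idempotent.
    """
    cfg = cfg or FilterConfig()
    n = len(vt)
    notes: list[str] = []

    snp_ok = np.fromiter(
        (vt.site(i).is_biallelic_snp for i in range(n)), dtype=bool, count=n
    )
    auto_ok = np.isin(vt.chrom.astype(str), list(cfg.autosomes))

    if vt.has_dp:
        with np.errstate(invalid="ignore"):
            depth_ok = (vt.mean_depth > cfg.depth_min) & (vt.mean_depth < cfg.depth_max)
        # A site with no called-sample DP has NaN mean depth and already fails
        # genotype-based criteria; let it pass depth so attribution is stable.
        depth_ok |= np.isnan(vt.mean_depth)
    else:
        depth_ok = np.ones(n, dtype=bool)
        if n:
            notes.append("DP absent from VCF; depth filter not applied")

    p = vt.pooled_alt_frequency()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(p, 1.0 - p)
    # Sites with zero calls have undefined MAF; they fall through to the
    # missingness criterion, which they necessarily fail.
    maf_ok = np.where(np.isnan(maf), True, maf > cfg.maf_min)

    if vt.gt.shape[1]:
        miss_frac = (vt.gt == _MISSING).mean(axis=1)
    else:
        miss_frac = np.ones(n)
    miss_ok = miss_frac < cfg.max_missing

    removed: dict[str, int] = {}
    alive = np.ones(n, dtype=bool)
    for crit, ok in zip(
        FILTER_CRITERIA, (snp_ok, auto_ok, depth_ok, maf_ok, miss_ok)
    ):
        fails = alive & ~ok
        removed[crit] = int(fails.sum())
        alive &= ok

    out = vt.subset(alive)
    report = FilterReport(
        n_input=n, n_retained=len(out), removed=removed, notes=notes
    )
    return out, report


def allele_counts(
    site: VariantSite, sample_map: SampleMap, population: str
) -> PopAlleleCounts:
    """Major/minor allele counts for one population at one site.

    Counts run over non-missing diploid calls only. The major allele is the
    more frequent allele within the population's calls; on a tie the counts
    are equal. ``p`` is the ALT-allele frequency.
    """
    if population not in sample_map.populations:
        raise KeyError(f"unknown population {population!r}")
    cols = [
        i
        for i, s in enumerate(site.samples)
        if s in sample_map and sample_map.population_of(s) == population
    ]
    g = site.genotypes[cols]
    g = g[g != _MISSING]
    n_called = int(len(g))
    if n_called == 0:
        return PopAlleleCounts(n_maj=0, n_min=0, p=float("nan"), n_called=0)
    ac = int(g.sum())
    an = 2 * n_called
    return PopAlleleCounts(
        n_maj=max(ac, an - ac),
        n_min=min(ac, an - ac),
        p=ac / an,
        n_called=n_called,
    )
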