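"""End-to-end orchestration: filter -> window scan -> outliers -> candidates.

`run_scan` is deterministic given its inputs: the same VCF, population map,
annotation and configuration always produce byte-identical TSV/BED outputs.
The run log records every threshold and convention toggle (window geometry,
SD divisor, boundary inclusiveness) plus site/window counts at each stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import yaml

from . import overlap_annotate as oa
from . import scan_stats as ss
from .variant_io import (
    FilterConfig,
    FilterReport,
    SampleMap,
    VariantTable,
    filter_variants,
    read_vcf,
)

__all__ = [
    "RunConfig",
    "RunResult",
    "run_scan",
    "plot_tracks",
    "load_windows_tsv",
    "records_from_frame",
]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything one scan run needs.

    ``fst_pops`` must name exactly two populations; ``hp_pops`` defaults to
    the same pair. ``gtf`` may be None, in which case candidate-gene calling
    is skipped.
    """

    vcf: str
    popmap: str
    outdir: str
    gtf: str | None = None
    fst_pops: tuple[str, str] = ()
    hp_pops: tuple[str, ...] | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    window_size: int = 100_000
    step: int = 50_000
    min_snps: int = 10
    fst_fraction: float = 0.01
    zhp_threshold: float = -4.0
    ddof: int = 1
    flank: int = 0

    def __post_init__(self) -> None:
        if self.hp_pops is None and self.fst_pops:
            self.hp_pops = tuple(self.fst_pops)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fcfg = raw.pop("filter", None)
        if fcfg:
            if "autosomes" in fcfg:
                fcfg["autosomes"] = frozenset(str(c) for c in fcfg["autosomes"])
            raw["filter"] = FilterConfig(**fcfg)
        for key in ("fst_pops", "hp_pops"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if len(self.fst_pops) != 2 or self.fst_pops[0] == self.fst_pops[1]:
            raise ConfigError(
                "exactly 2 distinct populations must be selected for FST, "
                f"got {self.fst_pops!r}"
            )
        for path, name in ((self.vcf, "vcf"), (self.popmap, "popmap")):
            if not os.path.exists(path):
                raise ConfigError(f"{name} path does not exist: {path}")
        if self.gtf is not None and not os.path.exists(self.gtf):
            raise ConfigError(f"gtf path does not exist: {self.gtf}")


@dataclass
class RunResult:
    records: list[ss.WindowStatRecord]
    fst_out: ss.OutlierSet
    hp_outs: dict[str, ss.OutlierSet]
    joint_windows: dict[str, list[ss.Window]]
    candidates: dict[str, list[oa.CandidateGene]]
    filter_report: FilterReport
    table: VariantTable
    paths: dict[str, str]


def _joint_windows(
    fst_out: ss.OutlierSet, hp_out: ss.OutlierSet
) -> list[ss.Window]:
    """Windows flagged simultaneously by ZFST and by ZHp (same window)."""
    hp_keys = {(w.chrom, w.start, w.end) for w in hp_out.windows}
    return sorted(
        w for w in fst_out.windows if (w.chrom, w.start, w.end) in hp_keys
    )


def run_scan(cfg: RunConfig) -> RunResult:
    """Run the full scan and write all artifacts under ``cfg.outdir``."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    paths: dict[str, str] = {}
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    log(f"config: window_size={cfg.window_size} step={cfg.step} "
        f"min_snps={cfg.min_snps} fst_fraction={cfg.fst_fraction} "
        f"zhp_threshold={cfg.zhp_threshold} (inclusive) sd_ddof={cfg.ddof} "
        f"flank={cfg.flank}")
    log(f"filter: {cfg.filter.depth_min} < depth < {cfg.filter.depth_max}, "
        f"MAF > {cfg.filter.maf_min}, missing < {cfg.filter.max_missing} "
        f"(all strict)")

    sample_map = stage("popmap", SampleMap.from_tsv, cfg.popmap)
    log(f"popmap: {len(sample_map)} samples, "
        f"populations {','.join(sample_map.populations)}")

    vt = stage("read_vcf", read_vcf, cfg.vcf, sample_map)
    log(f"read_vcf: {len(vt)} records, {len(vt.samples)} mapped samples")

    vt_f, report = stage("filter", filter_variants, vt, cfg.filter)
    for crit, n in report.removed.items():
        log(f"filter: removed {n} by {crit}")
    log(f"filter: retained {report.n_retained} of {report.n_input}")
    paths["filter_report"] = os.path.join(cfg.outdir, "filter_report.tsv")
    report.to_tsv(paths["filter_report"])

    hp_pops = tuple(cfg.hp_pops or cfg.fst_pops)
    records = stage(
        "scan",
        ss.scan_windows,
        vt_f,
        tuple(cfg.fst_pops),
        hp_pops,
        window_size=cfg.window_size,
        step=cfg.step,
        min_snps=cfg.min_snps,
        ddof=cfg.ddof,
    )
    n_eval = int(np.sum([np.isfinite(r.zfst) for r in records]))
    log(f"scan: {len(records)} windows, {n_eval} FST-evaluable")
    paths["windows"] = os.path.join(cfg.outdir, "windows.tsv")
    ss.write_windows_tsv(records, paths["windows"])

    fst_out = stage(
        "fst_outliers",
        ss.call_fst_outliers,
        records,
        cfg.fst_fraction,
        label="-".join(cfg.fst_pops),
    )
    log(f"fst_outliers: {len(fst_out)} windows in top {cfg.fst_fraction:g}")
    paths["outliers_zfst"] = os.path.join(cfg.outdir, "outliers_zfst.bed")
    ss.write_outliers_bed(fst_out, paths["outliers_zfst"])

    hp_outs: dict[str, ss.OutlierSet] = {}
    joint: dict[str, list[ss.Window]] = {}
    candidates: dict[str, list[oa.CandidateGene]] = {}
    genes = stage("read_gtf", oa.read_gtf, cfg.gtf) if cfg.gtf else None
    if genes is not None:
        log(f"read_gtf: {len(genes)} genes")

    for pop in hp_pops:
        hp_out = stage(
            "hp_outliers", ss.call_hp_outliers, records, pop, cfg.zhp_threshold
        )
        hp_outs[pop] = hp_out
        log(f"hp_outliers[{pop}]: {len(hp_out)} windows at ZHp <= "
            f"{cfg.zhp_threshold:g}")
        key = f"outliers_zhp_{pop}"
        paths[key] = os.path.join(cfg.outdir, f"{key}.bed")
        ss.write_outliers_bed(hp_out, paths[key])

        joint[pop] = _joint_windows(fst_out, hp_out)
        log(f"joint[{pop}]: {len(joint[pop])} windows flagged by both")

        if genes is not None:
            cands = stage(
                "candidates", oa.candidate_genes, genes, fst_out, hp_out,
                flank=cfg.flank,
            )
            candidates[pop] = cands
            log(f"candidates[{pop}]: {len(cands)} genes")
            tsv = os.path.join(cfg.outdir, f"candidates_{pop}.tsv")
            bed = os.path.join(cfg.outdir, f"candidates_{pop}.bed")
            oa.write_candidates_tsv(cands, tsv)
            oa.write_candidates_bed(cands, bed)
            paths[f"candidates_{pop}"] = tsv
            paths[f"candidates_{pop}_bed"] = bed

    paths["log"] = os.path.join(cfg.outdir, "run.log")
    with open(paths["log"], "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    return RunResult(
        records=records,
        fst_out=fst_out,
        hp_outs=hp_outs,
        joint_windows=joint,
        candidates=candidates,
        filter_report=report,
        table=vt_f,
        paths=paths,
    )


def load_windows_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA", dtype={"chrom": str})
    if df.empty:
        raise ValueError(f"{path}: empty window table")
    return df


def records_from_frame(df: pd.DataFrame) -> list[ss.WindowStatRecord]:
    """Rebuild window records from a windows TSV (inverse of
    :func:`sweepscan.scan_stats.records_to_frame`)."""
    pops = [c[3:] for c in df.columns if c.startswith("hp_")]
    records = []
    idx_by_chrom: dict[str, int] = {}
    for _, row in df.iterrows():
        chrom = str(row["chrom"])
        idx = idx_by_chrom.get(chrom, 0)
        idx_by_chrom[chrom] = idx + 1
        records.append(
            ss.WindowStatRecord(
                window=ss.Window(chrom, int(row["start"]), int(row["end"]), idx),
                n_snps=int(row["n_snps"]),
                n_fst=int(row["n_fst"]),
                fst_mean=float(row["fst_mean"]),
                zfst=float(row["zfst"]),
                n_typed={},
                hp={p: float(row[f"hp_{p}"]) for p in pops},
                zhp={p: float(row[f"zhp_{p}"]) for p in pops},
            )
        )
    return records


def plot_tracks(
    windows_tsv: str | os.PathLike,
    out_path: str | os.PathLike,
    zhp_threshold: float = -4.0,
) -> str:
    """Manhattan-style per-chromosome Z tracks: one panel for ZFST and one
    per population for ZHp, with a dashed line at the active cut-off."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = load_windows_tsv(windows_tsv)
    pops = [c[4:] for c in df.columns if c.startswith("zhp_")]
    chroms = list(dict.fromkeys(df["chrom"].astype(str)))
    offsets: dict[str, int] = {}
    run = 0
    for c in chroms:
        offsets[c] = run
        run += int(df.loc[df["chrom"].astype(str) == c, "end"].max())
    mid = (df["start"] + df["end"]) / 2
    x = mid + df["chrom"].astype(str).map(offsets)
    palette = ("#33557a", "#e0862c")
    colors = df["chrom"].astype(str).map(
        {c: palette[i % 2] for i, c in enumerate(chroms)}
    )

    n_panels = 1 + len(pops)
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(10, 2.6 * n_panels), sharex=True, squeeze=False
    )
    axes = axes.ravel()
    axes[0].scatter(x, df["zfst"], s=6, c=colors)
    axes[0].axhline(abs(zhp_threshold), ls="--", c="grey", lw=1)
    axes[0].set_ylabel("ZFst")
    for ax, pop in zip(axes[1:], pops):
        ax.scatter(x, df[f"zhp_{pop}"], s=6, c=colors)
        ax.axhline(zhp_threshold, ls="--", c="grey", lw=1)
        ax.set_ylabel(f"ZHp ({pop})")
    ticks = [offsets[c] + df.loc[df["chrom"].astype(str) == c, "end"].max() / 2
             for c in chroms]
    axes[-1].set_xticks(ticks)
    axes[-1].set_xticklabels(chroms)
    axes[-1].set_xlabel("chromosome")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return os.fspath(out_path)
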