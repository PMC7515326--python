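"""Study orchestration: cohort -> band maps -> group and correlation CBPT.

Mirrors the analysis flow of a source-space complexity study: band-limit the
epochs, compute one epoch-averaged PLZC value per subject and source, test
the female-minus-male contrast per band with a cluster-based permutation
test, then correlate complexity with ICV-normalized regional volumes (whole
sample first, then within each sex).  Every stage is seeded from a single
master seed through named substreams, so a fixed configuration reproduces
the report byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cluster_stats import ClusterResult, cbpt
from .complexity import ComplexityParams, plzc_array
from .grid import SourceGrid
from .preprocessing import (CANONICAL_BANDS, BandSpec, SourceEpochData,
                            band_decompose, get_band)
from .synthetic import Cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComplexityMap:
    """Per-subject, per-source PLZC values for one band."""

    values: np.ndarray            # (n_subjects, n_sources)
    band: BandSpec
    subject_ids: tuple[str, ...]
    grid: SourceGrid


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of the full study analysis."""

    bands: tuple[str, ...] = ("broadband", "theta", "alpha", "low_beta",
                              "high_beta", "gamma")
    complexity: ComplexityParams = field(default_factory=ComplexityParams)
    alpha: float = 0.05
    n_perm: int = 10_000
    correlation_band: str = "high_beta"
    correlation_regions: tuple[str, ...] = ("hipp_right", "hipp_left")
    filter_order: int | None = None   # None -> 2000 scaled by fs/1000
    pad_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [b for b in self.bands if b not in CANONICAL_BANDS]
        if unknown:
            raise ValueError(f"unknown bands {unknown}; canonical: {sorted(CANONICAL_BANDS)}")
        if self.correlation_band not in CANONICAL_BANDS:
            raise ValueError(f"unknown correlation band {self.correlation_band!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class BandGroupResult:
    band: str
    clusters: list[ClusterResult]


@dataclass
class CorrelationResult:
    scope: str        # "all", "F" or "M"
    region: str
    band: str
    clusters: list[ClusterResult]


@dataclass
class StudyReport:
    group_results: list[BandGroupResult]
    correlation_results: list[CorrelationResult]
    region_means: pd.DataFrame
    meta: dict


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed and stage name."""
    return int(np.random.SeedSequence(
        [int(master), zlib.crc32(stage.encode())]).generate_state(1)[0])


# ---------------------------------------------------------------------------
# complexity maps
# ---------------------------------------------------------------------------

def subject_band_plzc(data: SourceEpochData, params: ComplexityParams) -> np.ndarray:
    """Per-source, epoch-averaged PLZC of one subject's band-filtered data."""
    per_epoch = plzc_array(np.asarray(data.core(), dtype=float), params)
    return per_epoch.mean(axis=1)


def compute_band_maps(cohort: Cohort, cfg: AnalysisConfig,
                      bands: Sequence[str] | None = None) -> dict[str, ComplexityMap]:
    """Band-filter every subject and compute [subject, source] PLZC maps."""
    bands = tuple(bands) if bands is not None else cfg.bands
    ids = cohort.subject_ids
    per_band: dict[str, list[np.ndarray]] = {b: [] for b in bands}
    t0 = time.perf_counter()
    for sid in ids:
        filtered = band_decompose(cohort.data[sid], list(bands),
                                  order=cfg.filter_order, pad_s=cfg.pad_s)
        for b in bands:
            per_band[b].append(subject_band_plzc(filtered[b], cfg.complexity))
    logger.info("complexity maps for %d subjects x %d bands in %.1f s",
                len(ids), len(bands), time.perf_counter() - t0)
    return {
        b: ComplexityMap(values=np.vstack(per_band[b]), band=get_band(b),
                         subject_ids=tuple(ids), grid=cohort.grid)
        for b in bands
    }


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def _aligned_groups(cohort: Cohort, subject_ids: Sequence[str]) -> np.ndarray:
    table = cohort.table.set_index("subject_id")
    return table.loc[list(subject_ids), "group"].to_numpy()


def run_group_analysis(cohort: Cohort, cfg: AnalysisConfig,
                       maps: Mapping[str, ComplexityMap] | None = None
                       ) -> list[BandGroupResult]:
    """Per-band group CBPT (F vs M); every band is reported, significant or not."""
    if maps is None:
        maps = compute_band_maps(cohort, cfg)
    results = []
    for band in cfg.bands:
        cmap = maps[band]
        groups = _aligned_groups(cohort, cmap.subject_ids)
        clusters = cbpt(cmap.values, groups, cmap.grid, mode="group",
                        alpha=cfg.alpha, n_perm=cfg.n_perm,
                        seed=stage_seed(cfg.seed, f"group:{band}"))
        logger.info("band %s: %d cluster(s), %d significant", band,
                    len(clusters), sum(c.significant for c in clusters))
        results.append(BandGroupResult(band=band, clusters=clusters))
    return results


def normalized_volume(table: pd.DataFrame, region: str) -> pd.Series:
    """Region volume divided by intracranial volume (dimensionless)."""
    col = f"{region}_mm3"
    if col not in table.columns:
        raise ValueError(f"region {region!r}: column {col!r} missing from covariates")
    vol = table[col]
    missing = table.loc[vol.isna() | table["icv_mm3"].isna(), "subject_id"].tolist()
    if missing:
        raise ValueError(f"missing volumes for subjects: {missing}")
    return vol / table["icv_mm3"]


def run_correlation_analysis(cohort: Cohort, cfg: AnalysisConfig, group: str,
                             region: str,
                             maps: Mapping[str, ComplexityMap] | None = None
                             ) -> CorrelationResult:
    """Correlation CBPT of the analysis band's map against an ICV-normalized volume.

    ``group`` is "F", "M" or "all" (whole sample).  The covariate is shuffled
    across the analyzed subjects to build the permutation null.
    """
    if group not in ("F", "M", "all"):
        raise ValueError(f"group must be 'F', 'M' or 'all', got {group!r}")
    if maps is None:
        maps = compute_band_maps(cohort, cfg, bands=[cfg.correlation_band])
    cmap = maps[cfg.correlation_band]
    table = cohort.table.set_index("subject_id").loc[list(cmap.subject_ids)].reset_index()
    covariate = normalized_volume(table, region).to_numpy()
    keep = np.ones(len(table), dtype=bool) if group == "all" \
        else (table["group"] == group).to_numpy()
    clusters = cbpt(cmap.values[keep], covariate[keep], cmap.grid,
                    mode="correlation", alpha=cfg.alpha, n_perm=cfg.n_perm,
                    seed=stage_seed(cfg.seed, f"correlation:{group}:{region}"))
    return CorrelationResult(scope=group, region=region,
                             band=cfg.correlation_band, clusters=clusters)


def sensor_style_summary(cmap: ComplexityMap, groups: Sequence[str]) -> pd.DataFrame:
    """Mean PLZC per atlas region and group (flat stand-in for a topographic map)."""
    groups = np.asarray(groups)
    rows = []
    for rid, name in enumerate(cmap.grid.region_names):
        src = np.flatnonzero(cmap.grid.region_id == rid)
        for g in sorted(set(groups.tolist())):
            sel = cmap.values[np.ix_(groups == g, src)]
            rows.append({"region": name, "group": g,
                         "mean_plzc": float(sel.mean()), "n_sources": int(src.size)})
    return pd.DataFrame(rows)


def run_study(cohort: Cohort, cfg: AnalysisConfig) -> StudyReport:
    """The full analysis flow on one cohort."""
    maps = compute_band_maps(cohort, cfg)
    group_results = run_group_analysis(cohort, cfg, maps=maps)

    corr_band = cfg.correlation_band
    if corr_band not in maps:
        maps.update(compute_band_maps(cohort, cfg, bands=[corr_band]))
    correlation_results = []
    for region in cfg.correlation_regions:
        for scope in ("all", "F", "M"):
            correlation_results.append(
                run_correlation_analysis(cohort, cfg, scope, region, maps=maps))

    summary_band = "broadband" if "broadband" in maps else cfg.bands[0]
    groups = _aligned_groups(cohort, maps[summary_band].subject_ids)
    region_means = sensor_style_summary(maps[summary_band], groups)

    meta = {
        "package_version": __version__,
        "analysis_config": _config_dict(cfg),
        "n_subjects": cohort.n_subjects,
        "n_sources": cohort.grid.n_sources,
        "summary_band": summary_band,
        "stage_seeds": {
            **{f"group:{b}": stage_seed(cfg.seed, f"group:{b}") for b in cfg.bands},
            **{f"correlation:{s}:{r}": stage_seed(cfg.seed, f"correlation:{s}:{r}")
               for r in cfg.correlation_regions for s in ("all", "F", "M")},
        },
    }
    return StudyReport(group_results=group_results,
                       correlation_results=correlation_results,
                       region_means=region_means, meta=meta)


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

def _config_dict(cfg: AnalysisConfig) -> dict:
    d = asdict(cfg)
    d["complexity"] = asdict(cfg.complexity)
    return d


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def _region_breakdown(sources: np.ndarray, grid: SourceGrid) -> str:
    rid = grid.region_id[sources]
    parts = []
    for r in sorted(set(int(x) for x in rid)):
        parts.append(f"{grid.region_names[r]}:{int((rid == r).sum())}")
    return ";".join(parts)


def _cluster_rows(clusters: list[ClusterResult], grid: SourceGrid,
                  prefix: dict) -> list[dict]:
    rows = []
    for cid, c in enumerate(clusters):
        rows.append({
            **prefix, "cluster_id": cid, "n_sources": c.n_sources,
            "cluster_stat": _fmt(c.cluster_stat), "p_value": _fmt(c.p_value),
            "sign": "+" if c.sign > 0 else "-",
            "significant": int(c.significant),
            "effect_size": _fmt(c.effect_size) if c.effect_size is not None else "",
            "region_breakdown": _region_breakdown(c.sources, grid),
        })
    return rows


def write_report(report: StudyReport, out_dir: str | Path, grid: SourceGrid) -> None:
    """Write the report as TSV tables plus run metadata (deterministic bytes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    g_rows, g_members = [], []
    for res in report.group_results:
        g_rows += _cluster_rows(res.clusters, grid, {"band": res.band})
        for cid, c in enumerate(res.clusters):
            g_members += [{"band": res.band, "cluster_id": cid, "source_idx": int(s)}
                          for s in c.sources]
    _write_tsv(out / "group_clusters.tsv", g_rows,
               ["band", "cluster_id", "n_sources", "cluster_stat", "p_value",
                "sign", "significant", "effect_size", "region_breakdown"])
    _write_tsv(out / "group_membership.tsv", g_members,
               ["band", "cluster_id", "source_idx"])

    c_rows, c_members = [], []
    for res in report.correlation_results:
        prefix = {"scope": res.scope, "region": res.region, "band": res.band}
        c_rows += _cluster_rows(res.clusters, grid, prefix)
        for cid, c in enumerate(res.clusters):
            c_members += [{**prefix, "cluster_id": cid, "source_idx": int(s)}
                          for s in c.sources]
    _write_tsv(out / "correlation_clusters.tsv", c_rows,
               ["scope", "region", "band", "cluster_id", "n_sources",
                "cluster_stat", "p_value", "sign", "significant", "effect_size",
                "region_breakdown"])
    _write_tsv(out / "correlation_membership.tsv", c_members,
               ["scope", "region", "band", "cluster_id", "source_idx"])

    rm = report.region_means.copy()
    rm["mean_plzc"] = rm["mean_plzc"].map(_fmt)
    rm.to_csv(out / "region_means.tsv", sep="\t", index=False)

    with open(out / "run_meta.json", "w") as fh:
        json.dump(report.meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _write_tsv(path: Path, rows: list[dict], columns: list[str]) -> None:
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)
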