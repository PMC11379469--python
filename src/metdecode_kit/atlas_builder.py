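"""Marker-atlas construction.

Builds a reference atlas of differentially methylated marker regions
from per-entity genome-wide CpG counts:

1. replicates of one tissue are aggregated by summing CpG counts,
   after dropping CpGs whose methylation ratio varies strongly across
   replicates;
2. differentially methylated sites (DMS) are called one-versus-all: a
   CpG marks entity *t* when its methylation ratio differs from every
   other entity's ratio by at least a margin (default 30 percentage
   points), hyper- or hypomethylated relative to all the rest;
3. same-entity, same-direction DMS are chained downstream into regions
   when consecutive sites lie within a maximum gap (default 500 bp);
   regions must contain a minimum number of CpGs (default 4) and reach
   a minimum length (default 100 bp);
4. each candidate region is scored with Fisher's exact test comparing
   the target entity's region-summed methylated/unmethylated CpG
   counts against the pooled counts of all remaining entities, with
   optional Bonferroni correction;
5. markers are selected either unfiltered, by corrected significance,
   or "balanced" (the top-k most significant regions per entity).

Region-level CpG count matrices for the selected markers are then
emitted for the deconvolution step; every CpG inside a region
contributes its full counts (a CpG covered by many reads counts once
per read).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    CountAtlas,
    CpGSiteTable,
    MarkerRegion,
    Region,
    RegionBed,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtlasConfig",
    "MarkerRegionStats",
    "aggregate_replicates",
    "detect_dms",
    "extend_to_regions",
    "fisher_test_region",
    "score_regions",
    "select_markers",
    "build_count_atlas",
]


@dataclasses.dataclass
class AtlasConfig:
    """Tunable parameters of atlas construction.

    margin
        Minimum one-vs-all methylation-ratio difference for a DMS, as a
        fraction (0.30 = 30 percentage points).
    min_cpgs
        Minimum number of DMS a region must chain together.
    max_gap
        Maximum distance in bp between consecutive chained DMS.
    min_region_len
        Minimum region length in bp (the reference sets explored are
        50, 100 and 250; 100 is the default trade-off).
    alpha
        Significance cutoff applied to (corrected) Fisher p-values.
    correction
        "bonferroni" (multiply by the number of candidates, global
        across entities) or "none".
    top_k
        Number of most-significant regions kept per entity in
        "balanced" marker mode.
    replicate_variance_cutoff
        CpGs whose per-replicate ratio range exceeds this value (among
        replicates with depth >= ``min_replicate_depth``) are dropped
        before aggregation.
    margin_mode
        "each": the margin must hold against every other entity
        individually (default). "pooled": against the count-pooled
        ratio of all other entities.
    """

    margin: float = 0.30
    min_cpgs: int = 4
    max_gap: int = 500
    min_region_len: int = 100
    alpha: float = 0.001
    correction: Literal["bonferroni", "none"] = "bonferroni"
    top_k: int = 23
    replicate_variance_cutoff: float = 0.25
    min_replicate_depth: int = 5
    margin_mode: Literal["each", "pooled"] = "each"
    fisher_alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0 < self.margin < 1:
            raise ValidationError(f"margin must be in (0,1), got {self.margin}")
        if self.min_cpgs < 2:
            raise ValidationError(f"min_cpgs must be >= 2, got {self.min_cpgs}")
        if self.min_region_len <= 0:
            raise ValidationError("min_region_len must be positive")
        if not 0 < self.alpha <= 1:
            raise ValidationError(f"alpha must be in (0,1], got {self.alpha}")


@dataclasses.dataclass
class MarkerRegionStats:
    """A candidate marker region with its per-entity counts and p-values."""

    region: MarkerRegion
    meth: np.ndarray  # per-entity region-summed methylated counts
    total: np.ndarray  # per-entity region-summed total counts
    fisher_p: float
    corrected_p: float = 1.0

    def __post_init__(self) -> None:
        if self.corrected_p < self.fisher_p - 1e-15:
            raise ValidationError("corrected_p must be >= fisher_p")


def aggregate_replicates(
    tables: Sequence[CpGSiteTable],
    cutoff: float = 0.25,
    min_depth: int = 5,
    entity_name: str | None = None,
) -> CpGSiteTable:
    """Merge replicate CpG tables of one tissue by summing counts.

    CpGs whose methylation-ratio range across replicates exceeds
    ``cutoff`` are dropped first; the range is computed over replicates
    with total >= ``min_depth`` only (shallow replicates are too noisy
    to judge variability). CpGs absent from some replicates are summed
    over the replicates that cover them.
    """
    if not tables:
        raise ValidationError("aggregate_replicates requires at least one replicate")
    if entity_name is None:
        entity_name = tables[0].entity_name
    if len(tables) == 1:
        return CpGSiteTable(entity_name, tables[0].records.copy())

    frames = []
    for i, t in enumerate(tables):
        df = t.records.copy()
        df["rep"] = i
        frames.append(df)
    allrec = pd.concat(frames, ignore_index=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        allrec["ratio"] = allrec["meth"] / allrec["total"]

    deep = allrec[allrec["total"] >= min_depth]
    rng = deep.groupby(["chrom", "pos"])["ratio"].agg(lambda r: r.max() - r.min())
    variable = set(rng[rng > cutoff].index)
    if variable:
        logger.info(
            "%s: dropping %d highly variant CpGs across replicates", entity_name, len(variable)
        )
        keep = ~allrec.set_index(["chrom", "pos"]).index.isin(variable)
        allrec = allrec[keep]

    summed = (
        allrec.groupby(["chrom", "pos"], as_index=False)[["meth", "total"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return CpGSiteTable(entity_name, summed)


def _joint_ratio_frame(entity_tables: Sequence[CpGSiteTable]) -> tuple[pd.DataFrame, list[str]]:
    """Inner-join all entities on (chrom, pos), keeping sites with total>0 everywhere."""
    names = [t.entity_name for t in entity_tables]
    if len(set(names)) != len(names):
        raise ValidationError("entity names must be unique")
    joined: pd.DataFrame | None = None
    for t in entity_tables:
        df = t.records[t.records["total"] > 0].copy()
        df[f"r_{t.entity_name}"] = df["meth"] / df["total"]
        df = df[["chrom", "pos", f"r_{t.entity_name}", "meth", "total"]].rename(
            columns={"meth": f"m_{t.entity_name}", "total": f"d_{t.entity_name}"}
        )
        joined = df if joined is None else joined.merge(df, on=["chrom", "pos"], how="inner")
    assert joined is not None
    n_union = len(set().union(*(set(zip(t.records["chrom"], t.records["pos"])) for t in entity_tables)))
    skipped = n_union - len(joined)
    if skipped:
        logger.info("detect_dms: skipped %d CpGs not covered in all entities", skipped)
    return joined, names


def detect_dms(
    entity_tables: Sequence[CpGSiteTable],
    margin: float = 0.30,
    margin_mode: str = "each",
) -> pd.DataFrame:
    """Call differentially methylated sites one-versus-all.

    Returns a DataFrame with columns ``entity, chrom, pos, direction``
    sorted by (entity, direction, chrom, pos). A CpG is a DMS for
    entity *t* when its ratio differs by at least ``margin`` from every
    other entity's ratio ("each" mode) or from the pooled-count ratio
    of the rest ("pooled" mode); ``direction`` records whether the
    target is above (hyper) or below (hypo) all the others. CpGs not
    covered (total > 0) in every entity are skipped.
    """
    if len(entity_tables) < 2:
        raise ValidationError("detect_dms needs at least two entities")
    joined, names = _joint_ratio_frame(entity_tables)
    if joined.empty:
        return pd.DataFrame(columns=["entity", "chrom", "pos", "direction"])

    R = np.vstack([joined[f"r_{n}"].to_numpy() for n in names])  # entities x sites
    Msum = np.vstack([joined[f"m_{n}"].to_numpy() for n in names])
    Dsum = np.vstack([joined[f"d_{n}"].to_numpy() for n in names])
    eps = 1e-12
    out = []
    for ti, name in enumerate(names):
        others = np.delete(R, ti, axis=0)
        if margin_mode == "each":
            passed = (np.abs(R[ti] - others) >= margin - eps).all(axis=0)
        elif margin_mode == "pooled":
            rest = np.delete(Msum, ti, axis=0).sum(axis=0) / np.delete(Dsum, ti, axis=0).sum(axis=0)
            passed = np.abs(R[ti] - rest) >= margin - eps
        else:
            raise ValidationError(f"unknown margin_mode {margin_mode!r}")
        hyper = R[ti] > others.max(axis=0)
        for idx in np.nonzero(passed)[0]:
            out.append(
                (
                    name,
                    joined["chrom"].iat[idx],
                    int(joined["pos"].iat[idx]),
                    "hyper" if hyper[idx] else "hypo",
                )
            )
    df = pd.DataFrame(out, columns=["entity", "chrom", "pos", "direction"])
    return df.sort_values(["entity", "direction", "chrom", "pos"], kind="mergesort").reset_index(drop=True)


def extend_to_regions(
    dms: pd.DataFrame,
    min_cpgs: int = 4,
    max_gap: int = 500,
    min_region_len: int = 100,
) -> RegionBed:
    """Chain DMS into marker regions by greedy downstream extension.

    Consecutive sites of the same (entity, direction, chrom) with an
    inter-site gap <= ``max_gap`` form one maximal region; a region is
    kept iff it contains >= ``min_cpgs`` sites and spans at least
    ``min_region_len`` bp. The region interval is
    ``[first_pos, last_pos + 1)``.
    """
    regions: list[MarkerRegion] = []
    if dms.empty:
        return RegionBed([])
    for (entity, direction, chrom), grp in dms.groupby(
        ["entity", "direction", "chrom"], sort=True
    ):
        pos = np.sort(grp["pos"].to_numpy())
        breaks = np.nonzero(np.diff(pos) > max_gap)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(pos) - 1]))
        for s, e in zip(starts, ends):
            n_sites = e - s + 1
            lo, hi = int(pos[s]), int(pos[e]) + 1
            if n_sites >= min_cpgs and hi - lo >= min_region_len:
                regions.append(
                    MarkerRegion(
                        chrom, lo, hi,
                        f"{entity}_{direction}_{chrom}_{lo}",
                        entity, direction,
                    )
                )
    return RegionBed(regions).sorted_by_coordinate()


def fisher_test_region(
    meth: np.ndarray,
    total: np.ndarray,
    target_index: int,
    alternative: str = "two-sided",
) -> float:
    """Fisher's exact p-value for one region, target vs pooled rest.

    The 2x2 table is ``[[m_t, u_t], [sum_j m_j, sum_j u_j]]`` over the
    other entities j, with u = total - meth. An all-zero table returns
    p = 1 by convention.
    """
    meth = np.asarray(meth, dtype=np.int64)
    total = np.asarray(total, dtype=np.int64)
    if (meth > total).any():
        raise ValidationError("meth > total in region counts")
    m_t = int(meth[target_index])
    u_t = int(total[target_index] - meth[target_index])
    m_r = int(meth.sum() - m_t)
    u_r = int((total - meth).sum() - u_t)
    if m_t + u_t + m_r + u_r == 0:
        return 1.0
    _, p = stats.fisher_exact([[m_t, u_t], [m_r, u_r]], alternative=alternative)
    return float(p)


def score_regions(
    entity_tables: Sequence[CpGSiteTable],
    bed: RegionBed,
    alternative: str = "two-sided",
    correction: str = "bonferroni",
) -> list[MarkerRegionStats]:
    """Sum CpG counts per region per entity and attach Fisher p-values.

    The Bonferroni divisor is the number of candidate regions entering
    the test, global across entities.
    """
    names = [t.entity_name for t in entity_tables]
    M, D = _region_counts(entity_tables, bed)
    n = len(bed)
    out: list[MarkerRegionStats] = []
    for k, region in enumerate(bed):
        ti = names.index(region.target_entity)
        p = fisher_test_region(M[:, k], D[:, k], ti, alternative=alternative)
        if correction == "bonferroni":
            cp = min(1.0, p * n)
        elif correction == "none":
            cp = p
        else:
            raise ValidationError(f"unknown correction {correction!r}")
        out.append(MarkerRegionStats(region, M[:, k], D[:, k], p, cp))
    return out


def select_markers(
    stats_list: Sequence[MarkerRegionStats],
    alpha: float = 0.001,
    mode: Literal["all", "significant", "balanced"] = "significant",
    top_k: int = 23,
) -> RegionBed:
    """Select the final marker list.

    Modes: ``all`` keeps every candidate; ``significant`` keeps
    regions with corrected p <= alpha; ``balanced`` keeps, per target
    entity, the ``top_k`` smallest-p regions (ties broken by longer
    region, then genomic coordinate). The output is coordinate-sorted.
    """
    if mode == "all":
        chosen = list(stats_list)
    elif mode == "significant":
        chosen = [s for s in stats_list if s.corrected_p <= alpha]
    elif mode == "balanced":
        chosen = []
        by_entity: dict[str, list[MarkerRegionStats]] = {}
        for s in stats_list:
            by_entity.setdefault(s.region.target_entity, []).append(s)
        for entity, cand in sorted(by_entity.items()):
            if len(cand) < top_k:
                logger.warning(
                    "balanced mode: %s has only %d candidates (< top_k=%d); keeping all",
                    entity, len(cand), top_k,
                )
            ranked = sorted(
                cand,
                key=lambda s: (
                    s.fisher_p,
                    -s.region.length,
                    s.region.chrom,
                    s.region.start,
                ),
            )
            chosen.extend(ranked[:top_k])
    else:
        raise ValidationError(f"unknown marker mode {mode!r}")
    return RegionBed([s.region for s in chosen]).sorted_by_coordinate()


def _region_counts(
    tables: Sequence[CpGSiteTable], bed: RegionBed
) -> tuple[np.ndarray, np.ndarray]:
    """Region-summed (M, D) count matrices, rows = tables, cols = regions.

    Every CpG inside the final region interval contributes, whether or
    not it was one of the seed DMS.
    """
    n_rows, n_regions = len(tables), len(bed)
    M = np.zeros((n_rows, n_regions), dtype=np.int64)
    D = np.zeros((n_rows, n_regions), dtype=np.int64)
    for j, t in enumerate(tables):
        by_chrom = {c: g for c, g in t.records.groupby("chrom")}
        for k, region in enumerate(bed):
            grp = by_chrom.get(region.chrom)
            if grp is None:
                continue
            pos = grp["pos"].to_numpy()
            lo = np.searchsorted(pos, region.start, side="left")
            hi = np.searchsorted(pos, region.end, side="left")
            if hi > lo:
                M[j, k] = grp["meth"].to_numpy()[lo:hi].sum()
                D[j, k] = grp["total"].to_numpy()[lo:hi].sum()
            else:
                logger.debug(
                    "region %s has no CpGs in %s", region.name, t.entity_name
                )
    return M, D


def build_count_atlas(
    entity_tables: Sequence[CpGSiteTable],
    bed: RegionBed,
    condensed: bool = True,
    tissue_labels: Sequence[str] | None = None,
) -> CountAtlas:
    """Build the region-level count atlas from CpG tables.

    With ``condensed=True`` each table is one replicate-aggregated
    tissue. With ``condensed=False`` (full atlas) each table is one
    replicate and ``tissue_labels`` maps each row to its tissue.
    """
    if not condensed and tissue_labels is None:
        raise ValidationError("full atlas requires tissue_labels per replicate")
    M, D = _region_counts(entity_tables, bed)
    names = [t.entity_name for t in entity_tables]
    tissues = list(tissue_labels) if tissue_labels is not None else list(names)
    regions = [Region(r.chrom, r.start, r.end) for r in bed]
    return CountAtlas(entities=names, regions=regions, D=D, M=M, tissues=tissues)
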