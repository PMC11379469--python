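"""On-disk formats and in-memory containers.

Three plain-text dialects are supported, all tab-separated:

* **bedGraph** (MethylDackel dialect, read-only): per-CpG methylation
  calls with columns ``chrom, start, end, ratio, meth, unmeth``.
  Coordinates are 0-based half-open and the CpG position is the
  ``start`` field; the ratio column is ignored and recomputed
  downstream from the counts.
* **region BED**: BED6-compatible marker-region files with two extra
  annotation columns, ``target_entity`` and ``direction``
  (``hyper``/``hypo``).
* **count matrices**: one row per marker region
  (``chrom, start, end``) followed by paired integer count columns
  named ``<name>_meth`` / ``<name>_total``, one pair per atlas entity
  or cfDNA sample.

Counts are CpG counts, not read counts: a CpG spanned by several reads
contributes once per read, so region totals can exceed the number of
fragments. Strand is assumed pre-collapsed upstream (both strands of a
CpG merged by the methylation caller); no strand column is read.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ValidationError",
    "SchemaError",
    "Region",
    "MarkerRegion",
    "CpGSiteTable",
    "RegionBed",
    "CountAtlas",
    "MixtureCounts",
    "read_bedgraph",
    "read_region_bed",
    "write_region_bed",
    "read_count_matrix",
    "write_count_matrix",
    "write_proportions",
    "read_proportions",
]


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a format invariant (e.g. meth > total)."""


class SchemaError(ValueError):
    """A file header does not declare the expected column structure."""


class Region(NamedTuple):
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int


class MarkerRegion(NamedTuple):
    """A marker region annotated with its target entity and direction."""

    chrom: str
    start: int
    end: int
    name: str
    target_entity: str
    direction: str  # "hyper" or "hypo"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def region(self) -> Region:
        return Region(self.chrom, self.start, self.end)


@dataclasses.dataclass
class CpGSiteTable:
    """One entity's genome-wide per-CpG methylated/total counts.

    ``records`` is a DataFrame with columns ``chrom`` (str), ``pos``
    (int, 0-based), ``meth`` (int), ``total`` (int), sorted by
    (chrom, pos) with no duplicate positions and ``meth <= total``.
    """

    entity_name: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = ["chrom", "pos", "meth", "total"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"CpGSiteTable missing columns: {missing}")
        df = df[required].reset_index(drop=True)
        if len(df):
            if (df["meth"] < 0).any() or (df["total"] < 0).any():
                raise ValidationError("negative CpG counts")
            if (df["meth"] > df["total"]).any():
                bad = df.index[df["meth"] > df["total"]][0]
                raise ValidationError(
                    f"meth > total at {df.at[bad, 'chrom']}:{df.at[bad, 'pos']}"
                )
            df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
            if df.duplicated(["chrom", "pos"]).any():
                dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
                raise ValidationError(
                    f"duplicate CpG record at {dup['chrom']}:{dup['pos']}"
                )
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ratios(self) -> pd.Series:
        """Methylation ratio per CpG; NaN where total is 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.records["meth"] / self.records["total"]
        return r

    @classmethod
    def from_records(
        cls,
        entity_name: str,
        records: Iterable[tuple[str, int, int, int]],
    ) -> "CpGSiteTable":
        df = pd.DataFrame(records, columns=["chrom", "pos", "meth", "total"])
        if df.empty:
            df = pd.DataFrame(
                {"chrom": pd.Series(dtype=str)}
                | {c: pd.Series(dtype=np.int64) for c in ("pos", "meth", "total")}
            )
        return cls(entity_name, df)


@dataclasses.dataclass
class RegionBed:
    """An ordered collection of marker regions with unique names."""

    regions: list[MarkerRegion]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate region name: {dup}")
        for r in self.regions:
            if r.start >= r.end:
                raise ValidationError(f"empty/inverted region {r.name}: {r.start}>={r.end}")
            if r.direction not in ("hyper", "hypo"):
                raise ValidationError(f"bad direction {r.direction!r} for {r.name}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    def sorted_by_coordinate(self) -> "RegionBed":
        return RegionBed(sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end)))


def _check_paired_counts(D: np.ndarray, M: np.ndarray, rows: Sequence[str]) -> None:
    if D.shape != M.shape:
        raise ValidationError(f"D shape {D.shape} != M shape {M.shape}")
    if len(rows) != D.shape[0]:
        raise ValidationError("row-name count does not match matrix rows")
    if (D < 0).any() or (M < 0).any():
        raise ValidationError("negative counts")
    if (M > D).any():
        i, k = np.argwhere(M > D)[0]
        raise ValidationError(f"meth > total for row {rows[i]!r}, region index {k}")


@dataclasses.dataclass
class CountAtlas:
    """Paired (total, methylated) CpG count matrices, entities x regions.

    In a *condensed* atlas each row is a replicate-aggregated tissue and
    ``tissues`` equals ``entities``. In a *full* atlas each row is one
    replicate and ``tissues[j]`` names the tissue that replicate j
    belongs to.
    """

    entities: list[str]
    regions: list[Region]
    D: np.ndarray
    M: np.ndarray
    tissues: list[str] | None = None

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=np.int64)
        self.M = np.asarray(self.M, dtype=np.int64)
        _check_paired_counts(self.D, self.M, self.entities)
        if self.D.shape[1] != len(self.regions):
            raise ValidationError("region count does not match matrix columns")
        if self.tissues is None:
            self.tissues = list(self.entities)
        elif len(self.tissues) != len(self.entities):
            raise ValidationError("tissues length != entities length")

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_regions(self) -> int:
        return len(self.regions)


@dataclasses.dataclass
class MixtureCounts:
    """Paired (total, methylated) CpG count matrices, samples x regions."""

    samples: list[str]
    regions: list[Region]
    D: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=np.int64)
        self.M = np.asarray(self.M, dtype=np.int64)
        _check_paired_counts(self.D, self.M, self.samples)
        if self.D.shape[1] != len(self.regions):
            raise ValidationError("region count does not match matrix columns")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_regions(self) -> int:
        return len(self.regions)


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path, entity_name: str | None = None) -> CpGSiteTable:
    """Read a MethylDackel-dialect bedGraph into a :class:`CpGSiteTable`.

    Expects >= 6 tab-separated columns per line: chrom, start, end,
    ratio, methylated count, unmethylated count. ``total`` is computed
    as meth + unmeth; the ratio column is ignored. Track/header lines
    starting with ``track`` or ``#`` are skipped.
    """
    path = Path(path)
    if entity_name is None:
        entity_name = path.stem
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    totals: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >=6 tab-separated fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                pos = int(fields[1])
                meth = int(fields[4])
                unmeth = int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if meth < 0 or unmeth < 0:
                raise ValidationError(
                    f"{path}:{lineno}: negative count (meth={meth}, unmeth={unmeth})"
                )
            chroms.append(chrom)
            poss.append(pos)
            meths.append(meth)
            totals.append(meth + unmeth)
    return CpGSiteTable.from_records(
        entity_name, zip(chroms, poss, meths, totals)
    )


# ---------------------------------------------------------------------------
# region BED


def write_region_bed(bed: RegionBed, path: str | Path) -> None:
    """Write marker regions as BED6 + target_entity + direction columns."""
    with open(path, "w") as fh:
        for r in bed:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t.\t"
                f"{r.target_entity}\t{r.direction}\n"
            )


def read_region_bed(path: str | Path) -> RegionBed:
    path = Path(path)
    regions: list[MarkerRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(
                    f"{path}:{lineno}: expected 8 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            regions.append(
                MarkerRegion(fields[0], start, end, fields[3], fields[6], fields[7])
            )
    return RegionBed(regions)


# ---------------------------------------------------------------------------
# count matrices

_REGION_COLS = ["chrom", "start", "end"]


def write_count_matrix(
    counts: CountAtlas | MixtureCounts, path: str | Path
) -> None:
    """Write a paired count matrix as TSV, one row per region."""
    names = counts.entities if isinstance(counts, CountAtlas) else counts.samples
    data: dict[str, list | np.ndarray] = {
        "chrom": [r.chrom for r in counts.regions],
        "start": [r.start for r in counts.regions],
        "end": [r.end for r in counts.regions],
    }
    for j, name in enumerate(names):
        data[f"{name}_meth"] = counts.M[j]
        data[f"{name}_total"] = counts.D[j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def _parse_count_header(columns: Sequence[str]) -> list[str]:
    if list(columns[:3]) != _REGION_COLS:
        raise SchemaError(
            f"count matrix must start with columns {_REGION_COLS}, got {list(columns[:3])}"
        )
    meth_names = [c[: -len("_meth")] for c in columns[3:] if c.endswith("_meth")]
    total_names = [c[: -len("_total")] for c in columns[3:] if c.endswith("_total")]
    if set(meth_names) != set(total_names):
        odd = set(meth_names) ^ set(total_names)
        raise SchemaError(f"unpaired count columns for: {sorted(odd)}")
    extra = [
        c
        for c in columns[3:]
        if not (c.endswith("_meth") or c.endswith("_total"))
    ]
    if extra:
        raise SchemaError(f"unrecognized columns: {extra}")
    return meth_names  # in header (meth) order


def read_count_matrix(
    path: str | Path, kind: str = "atlas"
) -> CountAtlas | MixtureCounts:
    """Read a paired count matrix TSV.

    ``kind`` selects the returned container: ``"atlas"`` ->
    :class:`CountAtlas`, ``"mixture"`` -> :class:`MixtureCounts`.
    """
    df = pd.read_csv(path, sep="\t")
    names = _parse_count_header(df.columns)
    regions = [
        Region(str(c), int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]
    M = np.vstack([df[f"{n}_meth"].to_numpy(dtype=np.int64) for n in names]) if names else np.zeros((0, len(regions)), dtype=np.int64)
    D = np.vstack([df[f"{n}_total"].to_numpy(dtype=np.int64) for n in names]) if names else np.zeros((0, len(regions)), dtype=np.int64)
    if kind == "atlas":
        return CountAtlas(entities=list(names), regions=regions, D=D, M=M)
    if kind == "mixture":
        return MixtureCounts(samples=list(names), regions=regions, D=D, M=M)
    raise ValueError(f"kind must be 'atlas' or 'mixture', got {kind!r}")


# ---------------------------------------------------------------------------
# proportions


def write_proportions(result, path: str | Path) -> None:
    """Write estimated proportions as TSV: sample id + one column per entity.

    ``result`` needs ``samples``, ``column_labels`` and ``proportions``
    attributes (see :class:`metdecode_kit.deconvolution.DeconvolutionResult`).
    """
    A = np.asarray(result.proportions, dtype=float)
    if len(result.samples) and not np.allclose(A.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("proportion rows must sum to 1 within 1e-6")
    df = pd.DataFrame(A, columns=result.column_labels)
    df.insert(0, "sample", result.samples)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_proportions(path: str | Path) -> pd.DataFrame:
    """Read a proportions TSV back into a DataFrame indexed by sample."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise SchemaError("proportions file must have a 'sample' column")
    return df.set_index("sample")
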