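"""Evaluation: accuracy metrics, tissue-of-origin calling and LOD.

Covers four needs downstream of deconvolution:

* agreement metrics between estimated and true proportions (Pearson r,
  MSE) and between predicted and true class labels (accuracy, Cohen's
  kappa);
* tissue-of-origin (TOO) assignment: per cancer entity, estimated
  proportions in cases are normalized by the maximum estimate observed
  across a panel of healthy controls, the highest normalized cancer
  contributor is called as the putative TOO, and a sample whose raw
  cancer contributions are all zero is called "normal";
* aggregation of blood-cell proportions into the three complete-blood-
  count classes (neutrophils, lymphocytes, monocytes);
* limit-of-detection (LOD) estimation on a tumor-fraction dilution
  series: scanning fractions from high to low, the LOD is the
  smallest fraction down to which the true tumor entity keeps a
  positive estimate and stays the top cancer contributor.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TooCall",
    "LodResult",
    "SUBTYPE_GROUPS",
    "LYMPHOCYTE_ENTITIES",
    "pearson",
    "mse",
    "accuracy",
    "cohens_kappa",
    "normalize_by_controls",
    "assign_too",
    "aggregate_to_cbc_classes",
    "limit_of_detection",
]

#: Cancer-subtype grouping used when reporting TOO calls: cervical
#: adeno/squamous subtypes collapse to cervical carcinoma, colon and
#: rectum adenocarcinoma to colorectal carcinoma.
SUBTYPE_GROUPS: dict[str, str] = {
    "CEAD": "CERCA",
    "CESC": "CERCA",
    "COAD": "COLCA",
    "READ": "COLCA",
}

#: Blood entities summed into the CBC "lymphocytes" class.
LYMPHOCYTE_ENTITIES: tuple[str, ...] = ("B", "CD4T", "CD8T", "NK")


@dataclasses.dataclass
class TooCall:
    """One sample's tissue-of-origin call."""

    sample: str
    normalized: dict[str, float]  # per cancer entity, control-normalized
    label: str  # a cancer entity (possibly grouped) or "normal"


@dataclasses.dataclass
class LodResult:
    """Limit-of-detection scan over a dilution series."""

    per_replicate: pd.DataFrame  # columns: tumor_entity, replicate, lod, detected
    mean_lod: float


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation; 0 (with a warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("pearson needs at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("pearson undefined for constant vector; returning 0")
        return 0.0
    return float(stats.pearsonr(x, y).statistic)


def mse(x: Sequence[float], y: Sequence[float]) -> float:
    """Mean squared error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 1:
        raise ValidationError("mse needs at least 1 point")
    return float(np.mean((x - y) ** 2))


def accuracy(predicted: Sequence[str], true: Sequence[str]) -> float:
    """Fraction of exactly matching labels."""
    if len(predicted) != len(true):
        raise ValidationError("label lists differ in length")
    if len(predicted) == 0:
        raise ValidationError("accuracy of an empty label list is undefined")
    return sum(p == t for p, t in zip(predicted, true)) / len(predicted)


def cohens_kappa(predicted: Sequence[str], true: Sequence[str]) -> float:
    """Cohen's kappa: chance-corrected multi-class agreement.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement p_e from
    the marginal label frequencies. When p_e = 1 (a single shared
    label), kappa is defined as 1 for perfect agreement and 0
    otherwise, with a warning.
    """
    if len(predicted) != len(true):
        raise ValidationError("label lists differ in length")
    if len(predicted) == 0:
        raise ValidationError("kappa of an empty label list is undefined")
    n = len(predicted)
    labels = sorted(set(predicted) | set(true))
    pred = list(predicted)
    tr = list(true)
    p_o = sum(p == t for p, t in zip(pred, tr)) / n
    p_e = sum((pred.count(l) / n) * (tr.count(l) / n) for l in labels)
    if math.isclose(p_e, 1.0):
        logger.warning("kappa degenerate (p_e = 1); returning %s", 1.0 if p_o == 1.0 else 0.0)
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def normalize_by_controls(
    A_cases: pd.DataFrame,
    A_controls: pd.DataFrame,
    cancer_entities: Sequence[str],
) -> pd.DataFrame:
    """Divide case proportions by the per-entity maximum across controls.

    Establishes, per cancer entity, the reference range of healthy
    samples; a case's normalized contribution > 1 means it exceeds
    every control. A control maximum of 0 maps a positive case value
    to +inf (detected above any finite competitor) and a zero case
    value to 0.
    """
    missing = [c for c in cancer_entities if c not in A_cases.columns or c not in A_controls.columns]
    if missing:
        raise ValidationError(f"entities missing from proportions: {missing}")
    if len(A_controls) < 1:
        raise ValidationError("need at least one control sample")
    out = {}
    for c in cancer_entities:
        cmax = float(A_controls[c].max())
        vals = A_cases[c].to_numpy(dtype=float)
        if cmax > 0:
            out[c] = vals / cmax
        else:
            out[c] = np.where(vals > 0, np.inf, 0.0)
    return pd.DataFrame(out, index=A_cases.index)


def assign_too(
    normalized: Mapping[str, float],
    raw: Mapping[str, float],
    group_subtypes: bool = True,
    group_before_argmax: bool = False,
    sample: str = "",
) -> TooCall:
    """Call the tissue of origin from normalized cancer contributions.

    The label is the argmax of the normalized cancer contributions
    (ties broken by raw contribution, then lexicographic name); it is
    "normal" iff every raw cancer contribution is 0. With
    ``group_subtypes``, the subtype-to-group mapping (CEAD/CESC ->
    CERCA, COAD/READ -> COLCA) is applied after the argmax by default,
    or before it (summing group members) if ``group_before_argmax``.
    """
    if not normalized:
        raise ValidationError("no cancer entities supplied")
    if set(normalized) != set(raw):
        raise ValidationError("normalized and raw entity sets differ")
    if all(raw[c] == 0 for c in raw):
        return TooCall(sample=sample, normalized=dict(normalized), label="normal")
    if group_subtypes and group_before_argmax:
        grouped_norm: dict[str, float] = {}
        grouped_raw: dict[str, float] = {}
        for c in normalized:
            g = SUBTYPE_GROUPS.get(c, c)
            grouped_norm[g] = grouped_norm.get(g, 0.0) + normalized[c]
            grouped_raw[g] = grouped_raw.get(g, 0.0) + raw[c]
        normalized, raw = grouped_norm, grouped_raw
    best = min(normalized, key=lambda c: (-normalized[c], -raw[c], c))
    label = SUBTYPE_GROUPS.get(best, best) if group_subtypes else best
    return TooCall(sample=sample, normalized=dict(normalized), label=label)


def aggregate_to_cbc_classes(proportions: Mapping[str, float]) -> dict[str, float]:
    """Collapse blood entities to CBC classes and renormalize.

    lymphocytes = B + CD4T + CD8T + NK; neutrophils and monocytes pass
    through. The three classes are renormalized to sum to 1;
    erythroblasts (not counted by a differential CBC) are excluded
    from the renormalization.
    """
    needed = set(LYMPHOCYTE_ENTITIES) | {"neutrophils", "monocytes"}
    missing = sorted(needed - set(proportions))
    if missing:
        raise ValidationError(f"missing blood entities: {missing}")
    lymph = sum(proportions[e] for e in LYMPHOCYTE_ENTITIES)
    raw = {
        "neutrophils": float(proportions["neutrophils"]),
        "lymphocytes": float(lymph),
        "monocytes": float(proportions["monocytes"]),
    }
    s = sum(raw.values())
    if s == 0:
        raise ValidationError("all CBC-class proportions are zero")
    return {k: v / s for k, v in raw.items()}


def limit_of_detection(
    results: pd.DataFrame,
    true_entity: str,
    fraction_grid: Sequence[float] | None = None,
) -> LodResult:
    """Scan a dilution series for the limit of detection.

    ``results`` must have one row per (fraction, replicate) with
    columns ``fraction``, ``replicate``, ``est_true`` (estimated
    contribution of the true tumor entity) and ``top_label`` (the top
    cancer contributor's label). Scanning fractions in descending
    order, a replicate's LOD is the smallest fraction f such that at
    every fraction >= f the true entity has a positive estimate and is
    the top cancer contributor. If detection already fails at the
    highest fraction, the LOD is recorded as that highest fraction and
    flagged (``detected = False``). ``mean_lod`` averages the
    replicate LODs.
    """
    required = {"fraction", "replicate", "est_true", "top_label"}
    missing = required - set(results.columns)
    if missing:
        raise ValidationError(f"results table missing columns: {sorted(missing)}")
    if fraction_grid is None:
        fraction_grid = sorted(results["fraction"].unique(), reverse=True)
    else:
        fraction_grid = sorted(fraction_grid, reverse=True)

    rows = []
    for rep, grp in results.groupby("replicate"):
        by_frac = grp.set_index("fraction")
        lod = None
        detected_any = False
        for f in fraction_grid:
            if f not in by_frac.index:
                raise ValidationError(f"replicate {rep}: missing fraction {f}")
            row = by_frac.loc[f]
            ok = (row["est_true"] > 0) and (row["top_label"] == true_entity)
            if ok:
                lod = f
                detected_any = True
            else:
                break
        if lod is None:
            lod = fraction_grid[0]
            logger.warning(
                "replicate %s: detection fails at the highest fraction %g", rep, lod
            )
        rows.append({"tumor_entity": true_entity, "replicate": rep, "lod": lod, "detected": detected_any})
    per_rep = pd.DataFrame(rows)
    return LodResult(per_replicate=per_rep, mean_lod=float(per_rep["lod"].mean()))
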