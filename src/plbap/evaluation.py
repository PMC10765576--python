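"""Scoring metrics, masking-based interpretability and enrichment analysis.

Scoring power is summarized by Pearson's correlation (PC) and the
root-mean-squared error (RMSE) between predicted and experimental
affinities.  Post-hoc feature importance follows a dataset-level masking
scheme: a feature group is zeroed across every complex, the model is
re-evaluated, and the signed changes

    dPC_i  = PC_i  - PC_0      (a drop is negative)
    dRMSE_i = RMSE_i - RMSE_0   (an increase is positive)

flag important groups.  Screening power is summarized by the enrichment
factor EF^X over the top X% of score-ranked ligands, in two conventions:

* ``precision``  -- the fraction of actives among the top n_top;
* ``normalized`` -- precision divided by the dataset base rate (default;
  reported EF magnitudes of 10-20 only make sense in this convention).

Decoy subsampling at fixed decoy-to-active ratios with repeated draws
averages out selection noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .complex_model import ValidationError

__all__ = [
    "ScoreTable",
    "FeatureGroup",
    "pearson",
    "rmse",
    "mask_feature_group",
    "masking_importance",
    "enrichment_factor",
    "enrichment_sweep",
    "ratio_and_counts",
]


@dataclass
class ScoreTable:
    """Per-complex true/predicted affinities, optionally with active flags."""

    frame: pd.DataFrame  # columns: id, y_true, y_pred[, is_active]

    def __post_init__(self) -> None:
        required = {"id", "y_true", "y_pred"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"score table missing columns {sorted(missing)}")
        if self.frame["id"].duplicated().any():
            raise ValidationError("score table ids must be unique")
        for col in ("y_true", "y_pred"):
            if not np.all(np.isfinite(self.frame[col].to_numpy(float))):
                raise ValidationError(f"non-finite values in {col}")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_records(cls, ids: Sequence, y_true: Sequence[float],
                     y_pred: Sequence[float],
                     is_active: Sequence[bool] | None = None) -> "ScoreTable":
        data = {"id": list(ids), "y_true": list(y_true), "y_pred": list(y_pred)}
        if is_active is not None:
            data["is_active"] = [bool(v) for v in is_active]
        return cls(pd.DataFrame(data))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScoreTable":
        return cls(pd.read_csv(path))


def pearson(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Pearson's correlation coefficient; undefined for constant inputs."""
    yt = np.asarray(y_true, float)
    yp = np.asarray(y_pred, float)
    if yt.size < 2:
        raise ValidationError("pearson needs at least two samples")
    if np.std(yt) == 0 or np.std(yp) == 0:
        raise ValidationError("pearson undefined for zero-variance input")
    from scipy.stats import pearsonr

    return float(pearsonr(yt, yp).statistic)


def rmse(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    yt = np.asarray(y_true, float)
    yp = np.asarray(y_pred, float)
    return float(np.sqrt(np.mean((yt - yp) ** 2)))


# ---------------------------------------------------------------------------
# masking interpretability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureGroup:
    """A named selector into the per-complex feature array.

    ``indices`` indexes the feature axes (everything after the leading
    complex axis); entries may be integers or ``slice(None)`` to span an
    axis, e.g. ``(3, 7)`` for one contact-matrix cell, ``(j, k, l,
    slice(None))`` for one voxel across channels, ``(..., c)`` for a whole
    channel.
    """

    name: str
    indices: tuple


def mask_feature_group(features: np.ndarray, group: FeatureGroup) -> np.ndarray:
    """Zero the selected entries for every complex; everything else is
    copied bit-identically.  An empty selector masks nothing (identity)."""
    features = np.asarray(features)
    out = features.copy()
    if group.indices == ():
        return out
    for axis, ind in enumerate(group.indices):
        if isinstance(ind, int) and not (-features.shape[axis + 1]
                                         <= ind < features.shape[axis + 1]):
            raise ValidationError(
                f"group {group.name}: index {ind} out of range on axis {axis}")
    out[(slice(None),) + tuple(group.indices)] = 0
    return out


def masking_importance(score_fn: Callable[[np.ndarray], np.ndarray],
                       features: np.ndarray, y_true: Sequence[float],
                       groups: Sequence[FeatureGroup]) -> pd.DataFrame:
    """Dataset-level masking report.

    Evaluates ``score_fn`` on the unmasked features (baseline PC_0/RMSE_0),
    then once per group with that group zeroed.  Returns one row per group
    with the signed deltas (dPC = PC_i - PC_0, dRMSE = RMSE_i - RMSE_0) and
    the positive-means-important ``pc_drop = PC_0 - PC_i`` convenience
    column; the baseline appears as the first row with zero deltas.
    """
    y_true = np.asarray(y_true, float)
    baseline_pred = np.asarray(score_fn(features), float)
    pc0 = pearson(y_true, baseline_pred)
    rmse0 = rmse(y_true, baseline_pred)
    rows = [{"group": "__baseline__", "pc": pc0, "rmse": rmse0,
             "delta_pc": 0.0, "delta_rmse": 0.0, "pc_drop": 0.0}]
    for group in groups:
        masked = mask_feature_group(features, group)
        pred = np.asarray(score_fn(masked), float)
        # a mask can silence the model entirely; a constant prediction has
        # no correlation, recorded as pc_i = 0 (the maximal drop)
        pc_i = pearson(y_true, pred) if np.std(pred) > 0 else 0.0
        rmse_i = rmse(y_true, pred)
        rows.append({"group": group.name, "pc": pc_i, "rmse": rmse_i,
                     "delta_pc": pc_i - pc0, "delta_rmse": rmse_i - rmse0,
                     "pc_drop": pc0 - pc_i})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enrichment analysis
# ---------------------------------------------------------------------------

def enrichment_factor(table: ScoreTable, top_percent: float,
                      definition: str = "normalized") -> float:
    """EF over the top ``top_percent`` % of ligands ranked by descending
    predicted score (ties broken by id for determinism)."""
    if definition not in ("normalized", "precision"):
        raise ValidationError(f"unknown EF definition {definition!r}")
    frame = table.frame
    if "is_active" not in frame.columns:
        raise ValidationError("enrichment needs an is_active column")
    n_total = len(frame)
    n_top = math.ceil(top_percent / 100.0 * n_total)
    if n_top == 0:
        raise ValidationError("top fraction selects zero ligands")
    ranked = frame.sort_values(["y_pred", "id"],
                               ascending=[False, True], kind="mergesort")
    hits = int(ranked["is_active"].to_numpy()[:n_top].sum())
    precision = hits / n_top
    if definition == "precision":
        return precision
    n_actives = int(frame["is_active"].sum())
    if n_actives == 0:
        raise ValidationError("no actives in table")
    return precision / (n_actives / n_total)


def enrichment_sweep(actives: ScoreTable, decoy_pool: ScoreTable,
                     ratios: Sequence[float], top_percents: Sequence[float],
                     repeats: int = 10, seed: int = 0,
                     definition: str = "normalized") -> pd.DataFrame:
    """EF^X per decoy-to-active ratio, averaged over repeated uniform decoy
    draws (without replacement) from the pool.

    Returns a tidy frame with per-repeat EF values and, per (ratio, X),
    the mean over repeats; fully reproducible from ``seed``.
    """
    n_actives = len(actives)
    n_pool = len(decoy_pool)
    max_ratio = max(ratios)
    needed = math.ceil(max_ratio * n_actives)
    if needed > n_pool:
        feasible = n_pool / n_actives
        raise ValidationError(
            f"decoy pool too small for ratio {max_ratio} "
            f"(max feasible ratio {feasible:.2f})")
    rng = np.random.default_rng(seed)
    rows = []
    for ratio in ratios:
        n_decoys = round(ratio * n_actives)
        for rep in range(repeats):
            chosen = rng.choice(n_pool, size=n_decoys, replace=False)
            frame = pd.concat([actives.frame, decoy_pool.frame.iloc[chosen]],
                              ignore_index=True)
            table = ScoreTable(frame)
            for x in top_percents:
                rows.append({"ratio": ratio, "top_percent": x, "repeat": rep,
                             "ef": enrichment_factor(table, x, definition)})
    result = pd.DataFrame(rows)
    means = (result.groupby(["ratio", "top_percent"], as_index=False)["ef"]
             .mean().rename(columns={"ef": "ef_mean"}))
    return result.merge(means, on=["ratio", "top_percent"])


def ratio_and_counts(n_actives: int, n_decoys: int) -> tuple[int, float]:
    """Total ligand-pair count and the decoy-to-active ratio r_DTA."""
    if n_actives <= 0:
        raise ValidationError("n_actives must be positive")
    return n_actives + n_decoys, n_decoys / n_actives
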