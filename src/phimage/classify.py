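"""Decide per pixel whether a response reflects a real pH change.

Two methods, mirroring the two analyses applied to the in-vivo maps:

* **CI threshold** — pool every finite per-pixel, per-angle response value
  from the buffered-saline (HEPES) null runs and take the 95% normal
  interval of that pixel distribution, mean +/- 1.96 SD.  A brain pixel
  whose response exceeds the upper threshold is labeled alkaline, below
  the lower acidic.  By construction ~5% of null pixels exceed the
  thresholds, so the null runs themselves estimate the false-positive
  rate.  (The standard-error interval of the grand mean would be
  vanishingly narrow with thousands of pooled pixels; it is available
  behind ``method='se'`` for completeness.)

* **Per-pixel t-test** — for each (pixel, angle), a two-sided one-sample
  t-test of the angle's per-trial responses against zero, alpha 0.05, no
  multiple-testing correction.  Note that the per-trial response subtracts
  the grand mean over all trials, which includes the angle's own trials;
  under the null this makes the test conservative (true type-I rate
  ~3.8% with 8 angles rather than the nominal 5%).

Group-level comparison: per-run, per-angle significant-pixel counts go
into a two-way ANOVA (condition x angle) plus an unpaired t-test on
counts pooled across angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .response import ResponseMaps
from .types import InvalidParameterError

__all__ = [
    "NullThresholds",
    "ClassificationMap",
    "GroupComparison",
    "compute_null_thresholds",
    "classify_by_threshold",
    "classify_by_ttest",
    "count_table",
    "compare_brain_vs_null",
    "LABEL_ACIDIC",
    "LABEL_NONE",
    "LABEL_ALKALINE",
]

LABEL_ACIDIC, LABEL_NONE, LABEL_ALKALINE = -1, 0, 1


@dataclass(frozen=True)
class NullThresholds:
    """Null-derived decision thresholds in pH units (lower < upper)."""

    lower: float
    upper: float
    n_values: int
    method: str = "normal_interval"
    source: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.lower < self.upper:
            raise InvalidParameterError("degenerate interval: lower must be < upper")


@dataclass
class ClassificationMap:
    """Per (pixel, angle) labels: -1 acidic, 0 none, +1 alkaline."""

    labels: np.ndarray  # int8, (n_rows, n_cols, n_angles); masked pixels 0
    valid: np.ndarray  # bool, pixels actually classified
    angles_deg: np.ndarray
    method: str  # 'ci_threshold' or 't_test'
    alpha: float | None = None
    thresholds: NullThresholds | None = None

    def per_angle_counts(self) -> pd.DataFrame:
        """Labeled-pixel counts and proportions per angle over the valid region."""
        rows = []
        n_valid = int(self.valid.sum())
        for k, angle in enumerate(self.angles_deg):
            lab = self.labels[:, :, k][self.valid]
            n_alk = int((lab == LABEL_ALKALINE).sum())
            n_acid = int((lab == LABEL_ACIDIC).sum())
            rows.append(
                {
                    "angle_deg": float(angle),
                    "n_valid": n_valid,
                    "n_alkaline": n_alk,
                    "n_acidic": n_acid,
                    "n_labeled": n_alk + n_acid,
                    "prop_labeled": (n_alk + n_acid) / n_valid if n_valid else np.nan,
                }
            )
        return pd.DataFrame(rows)

    @property
    def labeled_fraction(self) -> float:
        lab = self.labels[self.valid]
        return float((lab != LABEL_NONE).mean())


def compute_null_thresholds(
    hepes_maps: Sequence[ResponseMaps],
    method: str = "normal_interval",
    sources: Sequence[str] = (),
) -> NullThresholds:
    """Pool null-run response values into one global threshold pair.

    Thresholds are pooled over all runs and all angles (one pair reused
    across angles).  ``method='normal_interval'`` gives mean +/- 1.96 SD of
    the pooled pixel distribution; ``'se'`` the standard-error interval of
    the pooled mean.
    """
    if not hepes_maps:
        raise InvalidParameterError("no HEPES response maps supplied")
    pooled = np.concatenate([m.delta_delta_ph.ravel() for m in hepes_maps])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise InvalidParameterError("no finite null values to pool")
    mu = float(pooled.mean())
    sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    if sd == 0.0:
        raise InvalidParameterError("degenerate null pool (SD = 0)")
    if method == "normal_interval":
        half = 1.96 * sd
    elif method == "se":
        half = 1.96 * sd / np.sqrt(pooled.size)
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    return NullThresholds(
        lower=mu - half,
        upper=mu + half,
        n_values=int(pooled.size),
        method=method,
        source=tuple(sources),
    )


def _valid_region(values: np.ndarray, region_mask: np.ndarray | None) -> np.ndarray:
    valid = np.all(np.isfinite(values), axis=2)
    if region_mask is not None:
        valid &= region_mask
    if not valid.any():
        raise InvalidParameterError("all pixels masked out: nothing to classify")
    return valid


def classify_by_threshold(
    maps: ResponseMaps,
    thresholds: NullThresholds,
    region_mask: np.ndarray | None = None,
) -> ClassificationMap:
    """Label each (pixel, angle) by comparing its response to the null interval."""
    vals = maps.delta_delta_ph
    valid = _valid_region(vals, region_mask)
    labels = np.zeros(vals.shape, dtype=np.int8)
    labels[vals > thresholds.upper] = LABEL_ALKALINE
    labels[vals < thresholds.lower] = LABEL_ACIDIC
    labels[~valid] = LABEL_NONE
    return ClassificationMap(
        labels=labels,
        valid=valid,
        angles_deg=maps.angles_deg.copy(),
        method="ci_threshold",
        thresholds=thresholds,
    )


def classify_by_ttest(
    maps: ResponseMaps,
    alpha: float = 0.05,
    region_mask: np.ndarray | None = None,
) -> ClassificationMap:
    """Per (pixel, angle) one-sample t-test of the trial responses against 0.

    Uses the per-trial responses stored on ``maps`` (grouped by angle).
    Zero-variance trial sets are defined as not significant.  No
    multiple-testing correction is applied.
    """
    if maps.delta_delta_ph_trial is None:
        raise InvalidParameterError(
            "per-trial responses missing: run compute_trial_responses first"
        )
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    ddt = maps.delta_delta_ph_trial
    angles = maps.angles_deg
    valid = _valid_region(maps.delta_delta_ph, region_mask)
    labels = np.zeros(maps.delta_delta_ph.shape, dtype=np.int8)
    for k, angle in enumerate(angles):
        idx = np.where(maps.trial_angles == angle)[0]
        if idx.size < 2:
            raise InvalidParameterError(f"angle {angle} has fewer than 2 trials")
        vals = ddt[:, :, idx]
        import warnings as _warnings

        with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
            _warnings.filterwarnings("ignore", message="Precision loss occurred")
            t_stat, p_val = stats.ttest_1samp(vals, 0.0, axis=2)
        mean = vals.mean(axis=2)
        # zero-variance trial sets are defined as not significant (with a
        # relative floor: a numerically constant set is constant)
        sd = vals.std(axis=2)
        has_var = sd > 1e-9 * np.maximum(np.abs(mean), 1e-6)
        sig = np.isfinite(p_val) & (p_val < alpha) & has_var
        labels[:, :, k][sig & (mean > 0)] = LABEL_ALKALINE
        labels[:, :, k][sig & (mean < 0)] = LABEL_ACIDIC
    labels[~valid] = LABEL_NONE
    return ClassificationMap(
        labels=labels,
        valid=valid,
        angles_deg=angles.copy(),
        method="t_test",
        alpha=alpha,
    )


def count_table(
    classification: ClassificationMap, run: str, condition: str
) -> pd.DataFrame:
    """Per-angle significant-pixel counts for one run, for group comparison."""
    df = classification.per_angle_counts()
    df.insert(0, "run", run)
    df.insert(1, "condition", condition)
    return df[["run", "condition", "angle_deg", "n_labeled", "n_valid"]].rename(
        columns={"n_labeled": "count"}
    )


@dataclass
class GroupComparison:
    """Two-way ANOVA (condition x angle) on counts plus a pooled t-test."""

    anova: pd.DataFrame  # index: C(condition), C(angle), interaction, Residual
    t_stat: float
    t_p: float
    pooled_counts: pd.DataFrame  # per-run totals

    def effect(self, name: str) -> tuple[float, float]:
        row = self.anova.loc[name]
        return float(row["F"]), float(row["PR(>F)"])


def compare_brain_vs_null(count_tables: Sequence[pd.DataFrame]) -> GroupComparison:
    """Compare per-angle significant-pixel counts between conditions.

    Expects one table per run from :func:`count_table`.  Fits
    ``count ~ C(condition) * C(angle)`` and reports type-II F tests for
    the main effects and the interaction, plus an unpaired two-sample
    t-test on per-run counts pooled (summed) across angles.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = pd.concat(count_tables, ignore_index=True)
    conditions = data["condition"].unique()
    if len(conditions) != 2:
        raise InvalidParameterError("need exactly 2 conditions to compare")
    for cond in conditions:
        if data.loc[data["condition"] == cond, "run"].nunique() < 2:
            raise InvalidParameterError(f"condition {cond!r} has fewer than 2 runs")
    model = smf.ols("count ~ C(condition) * C(angle_deg)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(
        index={
            "C(condition)": "condition",
            "C(angle_deg)": "angle",
            "C(condition):C(angle_deg)": "interaction",
        }
    )
    pooled = data.groupby(["run", "condition"], as_index=False)["count"].sum()
    groups = [pooled.loc[pooled["condition"] == c, "count"].to_numpy() for c in conditions]
    t_stat, t_p = stats.ttest_ind(*groups)
    return GroupComparison(
        anova=anova, t_stat=float(t_stat), t_p=float(t_p), pooled_counts=pooled
    )
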