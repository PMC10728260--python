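"""Accuracy and precision statistics for quantified iodine concentration.

Implements the standard quantitative-imaging-biomarker metrics:

* bias — measured minus nominal C_I, per replicate and averaged per level;
* linearity — first- and second-order polynomial fits of measured on
  nominal C_I; linearity holds when the quadratic coefficient is small
  (|β₂| criterion β₂ < 0.5), the first-order slope is near one
  (0.95 < β₁ < 1.05) and the first-order fit has R² > 0.9;
* repeatability — within-subject SD of replicates per level (wSD), its
  coefficient of variation (wCV = wSD/mean) and the repeatability
  coefficient RC = 2.77·wSD (the 95% limit for the difference of two
  repeated measurements under normality);
* reproducibility — Pearson correlation between paired measurements from
  two scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RC_FACTOR", "ReplicateSet", "LinearityReport",
           "RepeatabilityReport", "compute_bias", "assess_linearity",
           "compute_repeatability", "compute_reproducibility"]

#: RC = RC_FACTOR * wSD; 2.77 = 1.96 * sqrt(2).
RC_FACTOR = 2.77

_COLUMNS = ["scenario", "nominal_ci", "replicate", "session", "measured_ci"]


@dataclass
class ReplicateSet:
    """Replicate C_I measurements as a tidy table.

    Columns: ``scenario`` (FBP/fFBP/SIRT/fSIRT or any label), ``nominal_ci``
    (mg I/ml), ``replicate`` (index within session), ``session`` (test vs
    retest acquisition session), ``measured_ci`` (mg I/ml).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"ReplicateSet missing columns: {missing}")
        counts = self.df.groupby(["scenario", "nominal_ci"]).size()
        if (counts < 2).any():
            raise ValueError("need >= 2 replicates per (scenario, level)")

    def scenario(self, name: str) -> pd.DataFrame:
        sub = self.df[self.df["scenario"] == name]
        if sub.empty:
            raise ValueError(f"no measurements for scenario {name!r}")
        return sub

    def scenarios(self) -> list[str]:
        return sorted(self.df["scenario"].unique())


@dataclass(frozen=True)
class LinearityReport:
    beta1: float
    beta2: float
    r_squared: float
    passes: bool


@dataclass
class RepeatabilityReport:
    """Per-level wSD/wCV/RC plus the RMS-pooled wSD.

    ``per_level`` columns: nominal_ci, mean, wsd, wcv, rc; wCV is NaN
    (flagged, not an error) at a zero-mean level.
    """

    per_level: pd.DataFrame
    pooled_wsd: float

    @property
    def pooled_rc(self) -> float:
        return RC_FACTOR * self.pooled_wsd


def compute_bias(measured, nominal: float) -> tuple[np.ndarray, float]:
    """Per-replicate bias (measured − nominal) and its mean."""
    measured = np.asarray(measured, dtype=np.float64)
    if measured.size == 0:
        raise ValueError("empty measurement list")
    bias = measured - nominal
    return bias, float(bias.mean())


def assess_linearity(reps: ReplicateSet, scenario: str) -> LinearityReport:
    """Fit measured C_I on nominal C_I (orders 1 and 2, replicates pooled)
    and apply the three linearity criteria."""
    sub = reps.scenario(scenario)
    x = sub["nominal_ci"].to_numpy(dtype=np.float64)
    y = sub["measured_ci"].to_numpy(dtype=np.float64)
    if len(np.unique(x)) < 3:
        raise ValueError("linearity assessment requires >= 3 nominal levels")
    b1, a1 = np.polyfit(x, y, 1)
    b2 = np.polyfit(x, y, 2)[0]
    pred = b1 * x + a1
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    passes = (abs(b2) < 0.5) and (0.95 < b1 < 1.05) and (r2 > 0.9)
    return LinearityReport(beta1=float(b1), beta2=float(b2),
                           r_squared=float(r2), passes=bool(passes))


def compute_repeatability(reps: ReplicateSet,
                          scenario: str) -> RepeatabilityReport:
    """Per-level wSD (sample SD of replicates, n−1), wCV and RC = 2.77·wSD.

    All replicates of a level are pooled across sessions; pooled wSD is the
    root-mean-square of the per-level wSDs.
    """
    sub = reps.scenario(scenario)
    rows = []
    for level, grp in sub.groupby("nominal_ci"):
        vals = grp["measured_ci"].to_numpy(dtype=np.float64)
        if len(vals) < 2:
            raise ValueError(f"level {level}: < 2 replicates")
        wsd = float(vals.std(ddof=1))
        mean = float(vals.mean())
        wcv = wsd / mean if mean != 0 else float("nan")
        rows.append({"nominal_ci": float(level), "mean": mean, "wsd": wsd,
                     "wcv": wcv, "rc": RC_FACTOR * wsd})
    per_level = pd.DataFrame(rows).sort_values("nominal_ci",
                                               ignore_index=True)
    pooled = float(np.sqrt(np.mean(per_level["wsd"].to_numpy() ** 2)))
    return RepeatabilityReport(per_level=per_level, pooled_wsd=pooled)


def compute_reproducibility(x, y) -> tuple[float, float]:
    """Pearson correlation and two-sided p-value for paired measurements
    from two scenarios (paired by (level, replicate, session))."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("length mismatch between paired measurement vectors")
    if x.size < 3:
        raise ValueError("need >= 3 paired measurements")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the measurement vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
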