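"""Algorithm-level accuracy evaluation: bias, regression metrics, one-way
ANOVA, and per-category robustness analysis.

*Bias* is the signed mean of (predicted - measured) over a set of images;
positive bias means over-estimation.  Regression accuracy is the R^2 of the
OLS fit of predicted on measured, with RMSE computed on identity residuals
(predicted - measured), i.e. against ground truth rather than the fitted
line.  Robustness is tested with a one-way ANOVA on per-image residuals
grouped by a category factor (flower color, petal display, or capture
distance); the residual formulation gives the conventional degrees of
freedom (k - 1, n - k) over the pooled images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betainc

from .errors import DegenerateRegressionError, ParameterError, SchemaError

EVAL_COLUMNS = (
    "image_id",
    "predicted_cm2",
    "measured_cm2",
    "color_category",
    "petal_category",
    "distance_cm",
)

FACTOR_COLUMNS = {
    "color": "color_category",
    "petal": "petal_category",
    "distance": "distance_cm",
}

DEFAULT_ALPHA = 0.05


@dataclass
class BiasResult:
    bias: float  # cm^2, positive = over-estimation
    n: int
    group: Optional[str] = None


def bias(
    predicted: Sequence[float], measured: Sequence[float], group: Optional[str] = None
) -> BiasResult:
    """Mean of (predicted_i - measured_i)."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise ParameterError("predicted and measured must have equal length")
    if predicted.size == 0:
        raise ParameterError("bias requires at least one pair")
    return BiasResult(bias=float(np.mean(predicted - measured)), n=int(predicted.size), group=group)


@dataclass
class RegressionResult:
    r2: float
    rmse: float  # cm^2, on identity residuals
    slope: float
    intercept: float
    n: int


def regression_metrics(predicted: Sequence[float], measured: Sequence[float]) -> RegressionResult:
    """OLS of predicted on measured (slope, intercept, R^2) plus identity RMSE."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise ParameterError("predicted and measured must have equal length")
    n = predicted.size
    if n < 2:
        raise DegenerateRegressionError("regression requires at least two points")
    if np.ptp(measured) == 0:
        raise DegenerateRegressionError("measured values are constant; slope is undefined")
    fit = stats.linregress(measured, predicted)
    fitted = fit.intercept + fit.slope * measured
    ss_res = float(np.sum((predicted - fitted) ** 2))
    ss_tot = float(np.sum((predicted - np.mean(predicted)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((predicted - measured) ** 2)))
    return RegressionResult(
        r2=float(r2), rmse=rmse, slope=float(fit.slope), intercept=float(fit.intercept), n=int(n)
    )


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict = field(default_factory=dict)
    ss_between: float = 0.0
    ss_within: float = 0.0
    ss_total: float = 0.0
    flag: Optional[str] = None  # 'degenerate' | 'infinite-f' | None


def f_upper_tail(f: float, df1: int, df2: int) -> float:
    """P(F >= f) via the regularized incomplete beta function."""
    if f <= 0:
        return 1.0
    x = df2 / (df2 + df1 * f)
    return float(betainc(df2 / 2.0, df1 / 2.0, x))


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Fixed-effects one-way ANOVA from the sum-of-squares decomposition.

    SS_total = SS_between + SS_within about the grand mean;
    F = MS_between / MS_within on (k - 1, n - k) degrees of freedom.
    Degenerate cases: all values identical everywhere -> F = 0 with a
    'degenerate' flag; zero within-group variance with distinct group means
    -> infinite F with an 'infinite-f' flag.
    """
    arrays = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    k = len(arrays)
    if k < 2:
        raise ParameterError("ANOVA requires at least two groups")
    if any(a.size == 0 for a in arrays.values()):
        raise ParameterError("every ANOVA group must be non-empty")
    n = sum(a.size for a in arrays.values())
    df_between = k - 1
    df_within = n - k
    if df_within < 1:
        raise ParameterError("ANOVA requires n - k >= 1 residual degrees of freedom")
    grand = sum(a.sum() for a in arrays.values()) / n
    group_means = {key: float(a.mean()) for key, a in arrays.items()}
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values()))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays.values()))
    ss_total = float(sum(((a - grand) ** 2).sum() for a in arrays.values()))
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ms_between == 0.0:
            return AnovaResult(
                0.0, df_between, df_within, 1.0, group_means,
                ss_between, ss_within, ss_total, flag="degenerate",
            )
        return AnovaResult(
            float("inf"), df_between, df_within, 0.0, group_means,
            ss_between, ss_within, ss_total, flag="infinite-f",
        )
    f = float(ms_between / ms_within)
    return AnovaResult(
        f, df_between, df_within, f_upper_tail(f, df_between, df_within),
        group_means, ss_between, ss_within, ss_total,
    )


# ---------------------------------------------------------------------------
# Evaluation tables
# ---------------------------------------------------------------------------

def validate_eval_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"evaluation table is missing column(s): {', '.join(missing)}")
    if (pd.to_numeric(table["measured_cm2"], errors="coerce") < 0).any():
        raise SchemaError("measured_cm2 must be non-negative")
    return table


def read_eval_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a predicted-vs-measured CSV with category labels."""
    return validate_eval_table(pd.read_csv(path))


def write_eval_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    validate_eval_table(table).to_csv(path, index=False)


@dataclass
class CategoryReport:
    """Per-category bias plus the ANOVA over per-image residuals."""

    factor: str
    biases: list[BiasResult]
    anova: AnovaResult
    alpha: float = DEFAULT_ALPHA

    @property
    def rejects(self) -> bool:
        return self.anova.p_value < self.alpha


def evaluate_by_category(table: pd.DataFrame, factor: str) -> CategoryReport:
    """Group per-image residuals by one factor; report bias per group and the
    one-way ANOVA across groups.

    Rows with a missing factor label are an error (named by image_id); rows
    are never silently dropped.
    """
    validate_eval_table(table)
    if factor not in FACTOR_COLUMNS:
        raise ParameterError(f"unknown factor {factor!r}; expected one of {sorted(FACTOR_COLUMNS)}")
    col = FACTOR_COLUMNS[factor]
    labels = table[col]
    missing_mask = labels.isna() | (labels.astype(str).str.strip() == "")
    if missing_mask.any():
        bad = table.loc[missing_mask, "image_id"].tolist()
        raise SchemaError(f"rows missing {col}: {bad}")
    residuals = table["predicted_cm2"].to_numpy(float) - table["measured_cm2"].to_numpy(float)
    groups: dict[str, np.ndarray] = {}
    biases: list[BiasResult] = []
    for key in sorted(labels.astype(str).unique()):
        idx = (labels.astype(str) == key).to_numpy()
        groups[key] = residuals[idx]
        biases.append(BiasResult(bias=float(residuals[idx].mean()), n=int(idx.sum()), group=key))
    anova = one_way_anova(groups)
    return CategoryReport(factor=factor, biases=biases, anova=anova)
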