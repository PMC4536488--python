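"""Statistical layer for transfer experiments.

Per-donor-cell integrated transfer intensities are heavily right-skewed, so
the analysis pipeline is: normalize every condition to the control condition
(whose median is set to 100%), transform to the natural logarithm, then test
on the transformed data — one-way ANOVA followed by Dunnett's many-to-one
post-hoc test against the control for multiple conditions, or a two-sided
Student's t-test for a single comparison. Significance is called at
alpha = 0.05. Dot-plot summaries report medians of the untransformed,
normalized data.

Normality of the log-transformed data is checked with a chi-square
goodness-of-fit test against a normal with the sample mean and SD, using
equal-probability bins (``ceil(n/5)`` bins, capped at 20) and
``bins - 3`` degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .errors import StatisticsError

ALPHA = 0.05


@dataclass(frozen=True)
class ConditionDataset:
    """Per-donor-cell integrated transfer intensities for one condition."""

    label: str
    values: np.ndarray
    is_control: bool = False
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise StatisticsError(f"{self.label}: values must be 1D")
        if np.any(vals < 0):
            raise StatisticsError(f"{self.label}: negative transfer intensities")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class ConditionResult:
    label: str
    n: int
    median_pct: float
    dunnett_p: float | None
    t_test_p: float | None
    significant: bool


@dataclass(frozen=True)
class StatReport:
    """Output of :func:`compare_conditions`."""

    control_label: str
    conditions: tuple[ConditionResult, ...]
    anova_F: float | None
    anova_p: float | None
    normality_stat: float | None
    normality_p: float | None
    zeros_replaced: int = 0


def _control(datasets: list[ConditionDataset]) -> ConditionDataset:
    ctrl = [d for d in datasets if d.is_control]
    if len(ctrl) != 1:
        raise StatisticsError(f"need exactly one control condition, got {len(ctrl)}")
    return ctrl[0]


def normalize_to_control(datasets: list[ConditionDataset]) -> list[ConditionDataset]:
    """Express every value in percent of the control condition's median.

    The control median becomes exactly 100 by construction; the operation is
    idempotent and invariant to a common positive rescaling of raw values.
    """
    ctrl = _control(datasets)
    med = float(np.median(ctrl.values))
    if not math.isfinite(med) or med <= 0:
        raise StatisticsError(f"control median must be positive, got {med}")
    factor = 100.0 / med
    return [replace(d, values=d.values * factor,
                    background=None if d.background is None else np.asarray(d.background) * factor)
            for d in datasets]


def log_transform(
    values: np.ndarray, zero_pseudocount: float | None = 1.0
) -> tuple[np.ndarray, int]:
    """Natural-log transform; returns (transformed, number of zeros replaced).

    Fully inhibited donors can yield exactly zero transfer; ln(0) is avoided
    by substituting a configurable pseudo-count (default 1 grayscale*voxel on
    the raw scale) before transforming. Pass ``zero_pseudocount=None`` to
    make nonpositive values an error instead.
    """
    vals = np.asarray(values, dtype=float)
    if np.any(vals < 0):
        raise StatisticsError("negative values cannot be log-transformed")
    n_zero = int(np.count_nonzero(vals == 0))
    if n_zero:
        if zero_pseudocount is None:
            raise StatisticsError(f"{n_zero} zero values and no pseudo-count configured")
        vals = np.where(vals == 0, zero_pseudocount, vals)
    return np.log(vals), n_zero


def test_normality(values: np.ndarray) -> tuple[float, float]:
    """Chi-square goodness-of-fit of a sample against a fitted normal.

    Equal-probability binning under the fitted normal (``ceil(n/5)`` bins,
    at most 20), degrees of freedom = bins - 3 (two estimated parameters).
    Requires n >= 30 and a nonzero sample SD.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if n < 30:
        raise StatisticsError(f"normality test needs n >= 30, got {n}")
    mu = vals.mean()
    sd = vals.std(ddof=1)
    if sd == 0:
        raise StatisticsError("normality test undefined for a constant sample")
    k = min(20, math.ceil(n / 5))
    edges = sps.norm.ppf(np.linspace(0, 1, k + 1), loc=mu, scale=sd)
    observed, _ = np.histogram(vals, bins=edges)
    expected = np.full(k, n / k)
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = k - 3
    p = float(sps.chi2.sf(stat, df))
    return stat, p


def summarize_medians(datasets: list[ConditionDataset]) -> dict[str, float]:
    """Per-condition medians of untransformed (normalized) values."""
    return {d.label: float(np.median(d.values)) for d in datasets}


def compare_conditions(
    datasets: list[ConditionDataset],
    zero_pseudocount: float | None = 1.0,
    equal_var: bool = True,
    normalize: bool = True,
    random_state: int | np.random.Generator | None = None,
) -> StatReport:
    """Normalize, log-transform and test conditions against the control.

    With exactly two datasets a two-sided Student's t-test is used (Welch's
    variant with ``equal_var=False``); with more, one-way ANOVA on the
    log-transformed values followed by Dunnett's test of every condition
    against the control. The control's log-transformed sample is additionally
    checked for normality when large enough.
    """
    if len(datasets) < 2:
        raise StatisticsError("need at least two conditions to compare")
    for d in datasets:
        if d.values.size < 2:
            raise StatisticsError(f"{d.label}: need n >= 2, got {d.values.size}")
    if normalize:
        datasets = normalize_to_control(datasets)
    ctrl = _control(datasets)
    others = [d for d in datasets if not d.is_control]

    transformed: dict[str, np.ndarray] = {}
    zeros = 0
    for d in datasets:
        t, nz = log_transform(d.values, zero_pseudocount)
        transformed[d.label] = t
        zeros += nz

    norm_stat = norm_p = None
    if ctrl.values.size >= 30:
        norm_stat, norm_p = test_normality(transformed[ctrl.label])

    results: list[ConditionResult] = []
    medians = summarize_medians(datasets)
    if len(datasets) == 2:
        other = others[0]
        t_p = float(
            sps.ttest_ind(
                transformed[other.label], transformed[ctrl.label], equal_var=equal_var
            ).pvalue
        )
        anova_F = anova_p = None
        results.append(
            ConditionResult(other.label, other.values.size, medians[other.label],
                            dunnett_p=None, t_test_p=t_p, significant=t_p < ALPHA)
        )
    else:
        groups = [transformed[d.label] for d in datasets]
        f_res = sps.f_oneway(*groups)
        anova_F, anova_p = float(f_res.statistic), float(f_res.pvalue)
        dunnett = sps.dunnett(
            *[transformed[d.label] for d in others],
            control=transformed[ctrl.label],
            rng=random_state,
        )
        for d, p in zip(others, dunnett.pvalue):
            results.append(
                ConditionResult(d.label, d.values.size, medians[d.label],
                                dunnett_p=float(p), t_test_p=None,
                                significant=float(p) < ALPHA)
            )
    ctrl_res = ConditionResult(ctrl.label, ctrl.values.size, medians[ctrl.label],
                               dunnett_p=None, t_test_p=None, significant=False)
    return StatReport(
        control_label=ctrl.label,
        conditions=(ctrl_res, *results),
        anova_F=anova_F,
        anova_p=anova_p,
        normality_stat=norm_stat,
        normality_p=norm_p,
        zeros_replaced=zeros,
    )
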