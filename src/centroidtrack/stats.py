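"""Reproducibility and agreement statistics for the validation study:
Shapiro-Wilk normality, the paired t-test comparing planned against
measured translations, ICC(A,1) reliability between replicate runs,
Bland-Altman limits of agreement, and the paired-design sample-size
computation via exact noncentral-t power.

Distribution machinery comes from scipy/statsmodels; the ICC is computed
directly from the two-way ANOVA mean squares (McGraw & Wong's A,1 form —
absolute agreement, single measurement) because the scientific question is
whether two examiners' *absolute* measurements are interchangeable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.power import TTestPower

from .errors import CentroidTrackError

LOA_MULTIPLIER = 1.96  # 95 % limits of agreement


@dataclass
class PairedSeries:
    """Two paired measurement sequences (mm)."""

    values_a: np.ndarray
    values_b: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values_a = np.asarray(self.values_a, dtype=np.float64).ravel()
        self.values_b = np.asarray(self.values_b, dtype=np.float64).ravel()
        if len(self.values_a) != len(self.values_b):
            raise ValueError("paired series must have equal length")
        if len(self.values_a) < 2:
            raise ValueError("paired series needs n >= 2")
        if not (np.isfinite(self.values_a).all()
                and np.isfinite(self.values_b).all()):
            raise ValueError("paired series contains missing values")

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b

    @property
    def n(self) -> int:
        return len(self.values_a)


@dataclass
class PairedTResult:
    mean: float
    sd: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    df: int
    degenerate: bool = False  # zero-variance, nonzero-mean differences

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def paired_t(series: PairedSeries) -> PairedTResult:
    """Two-sided paired t-test on d = a - b, df = n - 1.

    Zero-variance differences with nonzero mean are reported with a
    ``degenerate`` flag (t infinite) rather than raising.
    """
    d = series.differences
    n = series.n
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    tcrit = float(sps.t.ppf(0.975, df))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, df)
        return PairedTResult(mean, 0.0, 0.0, mean, mean,
                             math.inf if mean > 0 else -math.inf, 0.0, df,
                             degenerate=True)
    se = sd / math.sqrt(n)
    t = mean / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PairedTResult(mean, sd, se, mean - tcrit * se, mean + tcrit * se,
                         float(t), p, df)


def shapiro_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p; requires 3 <= n <= 5000 and nonconstant data."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if not 3 <= len(values) <= 5000:
        raise CentroidTrackError(
            f"Shapiro-Wilk requires 3 <= n <= 5000, got n={len(values)}")
    if np.ptp(values) == 0:
        raise CentroidTrackError("Shapiro-Wilk undefined for constant input")
    w, p = sps.shapiro(values)
    return float(w), float(p)


@dataclass
class ICCResult:
    icc: float
    ms_rows: float    # between-subject mean square
    ms_cols: float    # between-rater mean square
    ms_error: float   # residual mean square
    n_subjects: int
    k_raters: int
    degenerate: bool = False  # no between-subject variance

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def icc_agreement(ratings) -> ICCResult:
    """Two-way absolute-agreement single-measurement ICC — ICC(A,1).

    ``ratings`` is an (n_subjects, k_raters) table.  Computed from the
    standard two-way ANOVA mean squares::

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    and clipped to the [-1, 1] reporting range.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an (n >= 2, k >= 2) table")
    if not np.isfinite(x).all():
        raise ValueError("ratings table must be complete")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_error = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if ss_rows == 0.0:
        return ICCResult(0.0, msr, msc, mse, n, k, degenerate=True)
    icc = float(np.clip((msr - mse) / denom, -1.0, 1.0))
    return ICCResult(icc, float(msr), float(msc), float(mse), n, k)


@dataclass
class BlandAltmanResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    coverage: float               # fraction of differences inside the LoA
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)

    def to_dict(self, include_points: bool = True) -> dict:
        out = {"mean_diff": self.mean_diff, "loa_low": self.loa_low,
               "loa_high": self.loa_high, "coverage": self.coverage}
        if include_points:
            out["means"] = np.asarray(self.means).tolist()
            out["diffs"] = np.asarray(self.diffs).tolist()
        return out


def bland_altman(series: PairedSeries) -> BlandAltmanResult:
    """Bland-Altman agreement: mean difference, mean +/- 1.96 SD limits,
    and the plot data (pairwise means vs differences)."""
    d = series.differences
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - LOA_MULTIPLIER * sd, mean + LOA_MULTIPLIER * sd
    coverage = float(((d >= lo) & (d <= hi)).mean())
    return BlandAltmanResult(mean, lo, hi, coverage,
                             means=(series.values_a + series.values_b) / 2.0,
                             diffs=d)


def required_n_paired(delta: float, sd: float, power: float = 0.95,
                      alpha: float = 0.05) -> int:
    """Smallest n for which a two-sided paired t-test at level ``alpha``
    detects a true mean difference ``delta`` (SD of differences ``sd``)
    with the requested power; exact noncentral-t evaluation."""
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be positive")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must be in (0, 1)")
    solver = TTestPower()
    effect = delta / sd
    n = int(math.ceil(solver.solve_power(effect_size=effect, nobs=None,
                                         alpha=alpha, power=power,
                                         alternative="two-sided")))
    n = max(n, 2)
    while n > 2 and solver.power(effect, n - 1, alpha) >= power:
        n -= 1
    while solver.power(effect, n, alpha) < power:
        n += 1
    return n


# ---------------------------------------------------------------------------
# Study-level report


@dataclass
class ValidationReport:
    """Accuracy table per replicate plus reproducibility (ICC + Bland-
    Altman) between the first two replicate runs, per ROI and axis."""

    accuracy: pd.DataFrame
    reproducibility: pd.DataFrame
    bland_altman_points: dict

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy.to_dict(orient="records"),
            "reproducibility":
                self.reproducibility.to_dict(orient="records"),
            "bland_altman_points": self.bland_altman_points,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def build_validation_report(cases: pd.DataFrame) -> ValidationReport:
    """Build the study report from a long per-case table.

    Expects columns ``roi, axis, replicate, planned, measured`` (use
    :func:`cases_to_long` for the study driver's wide table).  Accuracy
    rows give, per replicate and ROI/axis, the paired t-test of measured
    against planned plus normality of the differences; reproducibility
    rows give ICC(A,1) and Bland-Altman limits between replicates 0 and 1.
    """
    required = {"roi", "axis", "replicate", "planned", "measured"}
    missing = required - set(cases.columns)
    if missing:
        raise ValueError(f"cases table missing columns: {sorted(missing)}")

    acc_rows = []
    for (rep, roi, axis), grp in cases.groupby(["replicate", "roi", "axis"]):
        series = PairedSeries(grp["measured"].to_numpy(),
                              grp["planned"].to_numpy(),
                              label=f"rep{rep}_{roi}_{axis}")
        res = paired_t(series)
        d = series.differences
        try:
            _, shapiro_p = shapiro_normality(d)
        except CentroidTrackError:
            shapiro_p = np.nan
        acc_rows.append({"replicate": rep, "roi": roi, "axis": axis,
                         "n": series.n, "mean_diff": res.mean,
                         "sd": res.sd, "se": res.se,
                         "ci_low": res.ci_low, "ci_high": res.ci_high,
                         "t": res.t, "p": res.p, "shapiro_p": shapiro_p})

    rep_rows, ba_points = [], {}
    reps = sorted(cases["replicate"].unique())
    if len(reps) >= 2:
        r0, r1 = reps[0], reps[1]
        for (roi, axis), grp in cases.groupby(["roi", "axis"]):
            sort_cols = [c for c in ("patient",) if c in grp.columns]
            ga = grp[grp["replicate"] == r0]
            gb = grp[grp["replicate"] == r1]
            if sort_cols:
                ga, gb = ga.sort_values(sort_cols), gb.sort_values(sort_cols)
            a = ga["measured"].to_numpy()
            b = gb["measured"].to_numpy()
            if len(a) != len(b) or len(a) < 2:
                continue
            icc = icc_agreement(np.column_stack([a, b]))
            ba = bland_altman(PairedSeries(a, b, label=f"{roi}_{axis}"))
            rep_rows.append({"roi": roi, "axis": axis, "n": len(a),
                             "icc_a1": icc.icc,
                             "ba_mean_diff": ba.mean_diff,
                             "ba_loa_low": ba.loa_low,
                             "ba_loa_high": ba.loa_high,
                             "ba_coverage": ba.coverage})
            ba_points[f"{roi}_{axis}"] = ba.to_dict(include_points=True)
    return ValidationReport(accuracy=pd.DataFrame(acc_rows),
                            reproducibility=pd.DataFrame(rep_rows),
                            bland_altman_points=ba_points)


def cases_to_long(cases: pd.DataFrame) -> pd.DataFrame:
    """Reshape the study driver's wide per-case table (planned_x,
    measured_x, ...) into the long format build_validation_report expects."""
    frames = []
    ok = cases[cases["ok"]] if "ok" in cases.columns else cases
    for axis in ("x", "y", "z"):
        frames.append(pd.DataFrame({
            "patient": ok["patient"], "roi": ok["roi"],
            "replicate": ok["replicate"], "axis": axis,
            "planned": ok[f"planned_{axis}"],
            "measured": ok[f"measured_{axis}"]}))
    return pd.concat(frames, ignore_index=True)
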