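"""Calibration of the image-intensity statistic against dry cell weight.

The biomass model is a simple linear regression

    DCW = beta0 + beta1 * MII + eps,    eps ~ N(0, sigma^2)

with the microscopic image intensity (MII) as the single predictor and
dry cell weight (DCW, mg/L) as the response.  :class:`MIICalibration` is
the model object (built from samples or a DataFrame); ``fit()`` returns a
:class:`CalibrationResults` carrying the coefficient estimates, their
standard errors, the standardized coefficient (equal to Pearson r in the
simple-regression case), t and F statistics with two-sided p-values, R²,
residuals and 95% confidence intervals, plus ``predict`` and a
``summary()`` table in the layout of a standard ANOVA verification report.

The fit uses the closed-form normal equations; inference uses the exact
t(n-2) and F(1, n-2) reference distributions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class InsufficientDataError(ValueError):
    """Fewer samples than the model can be identified from (n < 3)."""


class DegenerateDesignError(ValueError):
    """All MII values identical: the calibration line is unidentifiable."""


@dataclass(frozen=True)
class CalibrationSample:
    """One culture sample: measured intensity and (optionally) its DCW."""

    sample_id: str
    mii: float
    dcw: float | None = None
    dilution_factor: float | None = None
    time_h: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.mii <= 255.0):
            raise ValueError(f"mii must lie in [0, 255], got {self.mii}")
        if self.dcw is not None and self.dcw < 0:
            raise ValueError(f"dcw must be non-negative, got {self.dcw}")
        if self.dilution_factor is not None and self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be positive")


class MIICalibration:
    """Simple linear regression model of DCW on MII.

    Parameters
    ----------
    mii, dcw : array-like
        Paired observations; both length n >= 3 with at least two
        distinct MII values.
    sample_ids : sequence of str, optional
    """

    def __init__(self, mii, dcw, sample_ids=None):
        self.mii = np.asarray(mii, dtype=np.float64)
        self.dcw = np.asarray(dcw, dtype=np.float64)
        if self.mii.shape != self.dcw.shape or self.mii.ndim != 1:
            raise ValueError("mii and dcw must be 1-D arrays of equal length")
        self.sample_ids = (
            list(sample_ids) if sample_ids is not None
            else [f"S{i}" for i in range(len(self.mii))]
        )
        if len(self.sample_ids) != len(self.mii):
            raise ValueError("sample_ids length mismatch")

    @classmethod
    def from_samples(cls, samples: Iterable[CalibrationSample]) -> "MIICalibration":
        samples = [s for s in samples if s.dcw is not None]
        return cls([s.mii for s in samples], [s.dcw for s in samples],
                   [s.sample_id for s in samples])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MIICalibration":
        """Build from a sample table with ``mii`` and ``dcw`` columns."""
        sub = df.dropna(subset=["mii", "dcw"])
        ids = sub["sample_id"].astype(str).tolist() if "sample_id" in sub else None
        return cls(sub["mii"].to_numpy(), sub["dcw"].to_numpy(), ids)

    def fit(self) -> "CalibrationResults":
        x, y = self.mii, self.dcw
        n = len(x)
        if n < 3:
            raise InsufficientDataError(f"need at least 3 samples, got {n}")
        sxx = float(np.sum((x - x.mean()) ** 2))
        if sxx == 0.0:
            raise DegenerateDesignError("all MII values identical; slope unidentifiable")
        sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
        sst = float(np.sum((y - y.mean()) ** 2))

        beta1 = sxy / sxx
        beta0 = float(y.mean()) - beta1 * float(x.mean())
        fitted = beta0 + beta1 * x
        resid = y - fitted
        sse = float(np.sum(resid ** 2))
        df_resid = n - 2
        mse = sse / df_resid
        ssr = sst - sse

        beta1_se = math.sqrt(mse / sxx)
        beta0_se = math.sqrt(mse * (1.0 / n + x.mean() ** 2 / sxx))
        t_slope = beta1 / beta1_se if beta1_se > 0 else math.inf
        t_intercept = beta0 / beta0_se if beta0_se > 0 else math.inf
        f_stat = (ssr / 1.0) / mse if mse > 0 else math.inf
        r_squared = 1.0 - sse / sst if sst > 0 else 0.0
        sd_x = math.sqrt(sxx / (n - 1))
        sd_y = math.sqrt(sst / (n - 1)) if sst > 0 else 0.0
        beta_std = beta1 * sd_x / sd_y if sd_y > 0 else 0.0

        tdist = stats.t(df_resid)
        p_slope = 2.0 * tdist.sf(abs(t_slope))
        p_intercept = 2.0 * tdist.sf(abs(t_intercept))
        p_f = stats.f(1, df_resid).sf(f_stat)
        tcrit = tdist.ppf(0.975)

        return CalibrationResults(
            model=self,
            beta0=beta0, beta0_se=beta0_se,
            beta1=beta1, beta1_se=beta1_se,
            beta_std=beta_std,
            t_intercept=t_intercept, t_slope=t_slope,
            p_intercept=p_intercept, p_slope=p_slope,
            f_stat=f_stat, p_f=p_f,
            r_squared=r_squared,
            df_resid=df_resid, n=n,
            residuals=resid,
            ci95_beta0=(beta0 - tcrit * beta0_se, beta0 + tcrit * beta0_se),
            ci95_beta1=(beta1 - tcrit * beta1_se, beta1 + tcrit * beta1_se),
        )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CalibrationResults:
    """Fitted calibration line with its verification statistics."""

    model: MIICalibration | None
    beta0: float
    beta0_se: float
    beta1: float
    beta1_se: float
    beta_std: float
    t_intercept: float
    t_slope: float
    p_intercept: float
    p_slope: float
    f_stat: float
    p_f: float
    r_squared: float
    df_resid: int
    n: int
    residuals: np.ndarray = field(repr=False, default=None)
    ci95_beta0: tuple[float, float] = (math.nan, math.nan)
    ci95_beta1: tuple[float, float] = (math.nan, math.nan)

    def predict(self, mii) -> np.ndarray | float:
        """Predicted DCW (mg/L) at the given MII value(s).

        Extrapolated negative predictions are returned as-is; callers can
        detect them with ``predicted < 0``.
        """
        mii = np.asarray(mii, dtype=np.float64)
        out = self.beta0 + self.beta1 * mii
        return float(out) if out.ndim == 0 else out

    @property
    def equation(self) -> str:
        return f"Y = {self.beta0:.3f} + {self.beta1:.3f}X"

    def summary(self) -> str:
        """Verification table: coefficients, SEs, standardized
        coefficient, t, F (with significance stars) and R²."""
        lines = [
            "Calibration model verification (simple linear regression)",
            "=" * 74,
            f"{'Variable':<12}{'B':>10}{'SE':>10}{'Beta':>8}{'t':>10}"
            f"{'F':>12}{'R^2':>8}",
            "-" * 74,
            f"{'(Constant)':<12}{self.beta0:>10.3f}{self.beta0_se:>10.3f}{'':>8}"
            f"{self.t_intercept:>7.3f}{_stars(self.p_intercept):<4}"
            f"{self.f_stat:>9.3f}{_stars(self.p_f):<4}{self.r_squared:>6.3f}",
            f"{'MII':<12}{self.beta1:>10.3f}{self.beta1_se:>10.3f}{self.beta_std:>8.3f}"
            f"{self.t_slope:>7.3f}{_stars(self.p_slope):<4}",
            "-" * 74,
            f"n = {self.n}, residual df = {self.df_resid}, {self.equation}",
            "*p < 0.05, **p < 0.01, ***p < 0.001",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0, "beta0_se": self.beta0_se,
            "beta1": self.beta1, "beta1_se": self.beta1_se,
            "beta_std": self.beta_std,
            "t_intercept": self.t_intercept, "t_slope": self.t_slope,
            "p_intercept": self.p_intercept, "p_slope": self.p_slope,
            "f_stat": self.f_stat, "p_f": self.p_f,
            "r_squared": self.r_squared,
            "df_resid": self.df_resid, "n": self.n,
            "ci95_beta0": list(self.ci95_beta0),
            "ci95_beta1": list(self.ci95_beta1),
            "residuals": None if self.residuals is None else list(map(float, self.residuals)),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationResults":
        with open(path) as fh:
            d = json.load(fh)
        resid = d.pop("residuals", None)
        d["ci95_beta0"] = tuple(d["ci95_beta0"])
        d["ci95_beta1"] = tuple(d["ci95_beta1"])
        return cls(model=None,
                   residuals=None if resid is None else np.asarray(resid), **d)


# ---------------------------------------------------------------------------
# functional surface

def fit_simple_regression(samples: Iterable[CalibrationSample]) -> CalibrationResults:
    """Fit the MII -> DCW line from calibration samples."""
    return MIICalibration.from_samples(samples).fit()


def predict_dcw(fit: CalibrationResults, mii: float) -> float:
    """Predicted DCW (mg/L) at one MII value."""
    return float(fit.predict(mii))


def accuracy_pct(predicted: float, actual: float) -> float:
    """Degree of accuracy between predicted and measured DCW.

    Defined as ``100 * min(predicted, actual) / max(predicted, actual)``:
    symmetric in its arguments, equal to 100 only at perfect agreement,
    and expressing the agreement of the smaller value with the larger as
    a percentage.
    """
    if predicted <= 0 or actual <= 0:
        raise ValueError("accuracy is defined for positive quantities only")
    return 100.0 * min(predicted, actual) / max(predicted, actual)


def verification_table(fit: CalibrationResults) -> str:
    return fit.summary()


@dataclass
class DilutionGroup:
    dilution_label: str
    n: int
    r_squared: float | None  # None when the group is too small to fit


@dataclass
class DilutionReport:
    groups: list[DilutionGroup]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"dilution_label": g.dilution_label, "n": g.n, "r_squared": g.r_squared}
             for g in self.groups]
        )


def dilution_analysis(samples: Sequence[CalibrationSample],
                      grouping: Mapping[float, str]) -> DilutionReport:
    """Per-dilution-group calibration quality.

    ``grouping`` maps each dilution factor to a group label (several
    factors may share a label, e.g. 2 and 5 pooled).  A separate simple
    regression is fitted per group; groups with fewer than 3 usable
    samples are reported with an undefined R² rather than raising.
    Group order follows first appearance of each label in ``grouping``.
    """
    by_label: dict[str, list[CalibrationSample]] = {}
    for factor, label in grouping.items():
        by_label.setdefault(label, [])
    for s in samples:
        if s.dilution_factor is None or s.dilution_factor not in grouping:
            raise ValueError(
                f"sample {s.sample_id!r} has dilution factor {s.dilution_factor!r} "
                "not covered by the grouping")
        by_label[grouping[s.dilution_factor]].append(s)
    groups = []
    for label, members in by_label.items():
        usable = [s for s in members if s.dcw is not None]
        if len(usable) < 3:
            groups.append(DilutionGroup(label, len(usable), None))
            continue
        try:
            fit = fit_simple_regression(usable)
            groups.append(DilutionGroup(label, fit.n, fit.r_squared))
        except DegenerateDesignError:
            groups.append(DilutionGroup(label, len(usable), None))
    return DilutionReport(groups)
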