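"""Probit dose-mortality analysis for rice-stem-dip bioassays.

The classic quantal-response workflow (Finney): mortality proportions
are corrected for control mortality with Abbott's formula, a probit
regression of corrected mortality on log10 concentration is fitted by
maximum likelihood (Fisher scoring), and the median lethal
concentration LC50 = 10**(-intercept/slope) is reported with a 95%
confidence interval from Fieller's theorem (delta method available for
comparison).  A Pearson chi-square over dose groups measures goodness
of fit; when it signals significant lack of fit (alpha = 0.05) the
parameter covariance is inflated by the heterogeneity factor
h = chi2/df before intervals are formed (Finney's convention).

An assay is discarded outright when control mortality exceeds 10%,
mirroring standard bioassay quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist, norm

__all__ = [
    "BioassayTable",
    "ProbitFit",
    "AssayDiscardedError",
    "SeparationError",
    "FitError",
    "UnboundedIntervalError",
    "validate_assay",
    "abbott_correct",
    "fit_probit",
    "lc50_ci",
]

_Z95 = norm.ppf(0.975)
_PCLIP = 1e-10


class AssayDiscardedError(ValueError):
    """Control mortality above the acceptance threshold."""


class SeparationError(ValueError):
    """All-dead or all-alive responses: the dose-response is not identifiable."""


class FitError(RuntimeError):
    """Maximum-likelihood fit failed to converge."""


class UnboundedIntervalError(ValueError):
    """Fieller interval is unbounded (slope indistinguishable from zero)."""


@dataclass
class BioassayTable:
    """Pooled dose-mortality data for one site x insecticide assay.

    ``concentrations`` are in mg/L; ``n_exposed``/``n_dead`` are pooled
    over replicates per concentration.  ``control_n``/``control_dead``
    describe the untreated (distilled water) control.
    """

    site_id: str
    insecticide: str
    concentrations: np.ndarray
    n_exposed: np.ndarray
    n_dead: np.ndarray
    control_n: int = 0
    control_dead: int = 0
    scoring_time_h: float | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.n_exposed = np.asarray(self.n_exposed, dtype=float)
        self.n_dead = np.asarray(self.n_dead, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(np.unique(self.concentrations)) < 2:
            raise ValueError("at least 2 distinct concentrations required")
        if np.any(self.n_dead < 0) or np.any(self.n_dead > self.n_exposed):
            raise ValueError("need 0 <= n_dead <= n_exposed at every dose")
        if not (0 <= self.control_dead <= max(self.control_n, 0)):
            raise ValueError("need 0 <= control_dead <= control_n")
        order = np.argsort(self.concentrations)
        self.concentrations = self.concentrations[order]
        self.n_exposed = self.n_exposed[order]
        self.n_dead = self.n_dead[order]

    @property
    def control_mortality(self) -> float:
        if self.control_n <= 0:
            return 0.0
        return self.control_dead / self.control_n

    @classmethod
    def from_frame(cls, df: pd.DataFrame, site_id: str, insecticide: str) -> "BioassayTable":
        """Build a table from long-format rows, pooling replicates.

        Expected columns: site_id, insecticide, conc_mg_L, n_exposed,
        n_dead, is_control.
        """
        sub = df[(df["site_id"] == site_id) & (df["insecticide"] == insecticide)]
        if sub.empty:
            raise KeyError(f"no rows for site {site_id!r} / {insecticide!r}")
        ctrl = sub[sub["is_control"].astype(bool)]
        trt = sub[~sub["is_control"].astype(bool)]
        pooled = trt.groupby("conc_mg_L")[["n_exposed", "n_dead"]].sum().reset_index()
        return cls(
            site_id=site_id,
            insecticide=insecticide,
            concentrations=pooled["conc_mg_L"].to_numpy(),
            n_exposed=pooled["n_exposed"].to_numpy(),
            n_dead=pooled["n_dead"].to_numpy(),
            control_n=int(ctrl["n_exposed"].sum()),
            control_dead=int(ctrl["n_dead"].sum()),
        )


@dataclass
class ProbitFit:
    """Fitted probit line probit(p) = intercept + slope * log10(conc)."""

    intercept: float
    slope: float
    slope_se: float
    lc50: float
    ci95: tuple[float, float]
    chi2: float
    df: int
    heterogeneity: float
    converged: bool
    vcov: np.ndarray  # 2x2 covariance of (intercept, slope), uninflated
    n_total: float

    @property
    def log10_lc50(self) -> float:
        return -self.intercept / self.slope


def validate_assay(table: BioassayTable, max_control_mortality: float = 0.10) -> bool:
    """True unless control mortality *exceeds* the threshold (10% passes)."""
    return table.control_mortality <= max_control_mortality


def abbott_correct(p_obs: float, p_control: float):
    """Abbott's control-mortality correction, clipped to [0, 1].

    corrected = (p_obs - p_control) / (1 - p_control)
    """
    p_control = np.asarray(p_control, dtype=float)
    if np.any(p_control < 0) or np.any(p_control >= 1):
        raise ValueError("control mortality must lie in [0, 1)")
    corrected = (np.asarray(p_obs, dtype=float) - p_control) / (1.0 - p_control)
    return np.clip(corrected, 0.0, 1.0)


def _fisher_scoring(x, n, y, max_iter=100, gtol=1e-8):
    """ML probit fit of y/n on x; returns (theta, vcov, converged)."""
    # starting values from least squares on empirical probits
    p_emp = (y + 0.5) / (n + 1.0)
    z_emp = norm.ppf(np.clip(p_emp, 1e-6, 1 - 1e-6))
    A = np.column_stack([np.ones_like(x), x])
    theta, *_ = np.linalg.lstsq(A, z_emp, rcond=None)
    converged = False
    info = np.eye(2)
    for _ in range(max_iter):
        eta = theta[0] + theta[1] * x
        p = np.clip(norm.cdf(eta), _PCLIP, 1 - _PCLIP)
        phi = norm.pdf(eta)
        w = n * phi**2 / (p * (1 - p))
        resid = (y - n * p) * phi / (p * (1 - p))
        score = A.T @ resid
        info = A.T @ (w[:, None] * A)
        if np.max(np.abs(score)) < gtol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix: {exc}") from exc
        # step halving keeps the likelihood finite for extreme starts
        for _ in range(20):
            cand = theta + step
            eta_c = cand[0] + cand[1] * x
            p_c = np.clip(norm.cdf(eta_c), _PCLIP, 1 - _PCLIP)
            ll_c = np.sum(y * np.log(p_c) + (n - y) * np.log1p(-p_c))
            ll_0 = np.sum(y * np.log(p) + (n - y) * np.log1p(-p))
            if ll_c >= ll_0 - 1e-12:
                break
            step = step / 2.0
        theta = theta + step
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular information matrix at optimum: {exc}") from exc
    return theta, vcov, converged


def fit_probit(table: BioassayTable, apply_abbott: bool = True) -> ProbitFit:
    """Maximum-likelihood probit fit of an assay table.

    Replicates are pooled per concentration; Abbott's correction is
    applied whenever the control shows non-zero mortality (tables with
    control mortality above 10% must be discarded beforehand and raise
    :class:`AssayDiscardedError` here).
    """
    if not validate_assay(table):
        raise AssayDiscardedError(
            f"control mortality {table.control_mortality:.1%} exceeds 10%; assay discarded"
        )
    x = np.log10(table.concentrations)
    n = table.n_exposed.astype(float)
    p_obs = table.n_dead / n
    p_ctrl = table.control_mortality
    abbott_used = apply_abbott and p_ctrl > 0
    if abbott_used:
        p_use = abbott_correct(p_obs, p_ctrl)
    else:
        p_use = p_obs
    y = p_use * n
    if np.all(y <= 0) or np.all(y >= n):
        raise SeparationError(
            "all-0% or all-100% corrected mortality: LC50 not identifiable"
        )
    theta, vcov, converged = _fisher_scoring(x, n, y)
    if not converged:
        raise FitError(
            f"probit fit did not converge for {table.site_id}/{table.insecticide} "
            f"(theta={theta})"
        )
    a, b = float(theta[0]), float(theta[1])
    eta = a + b * x
    p_hat = np.clip(norm.cdf(eta), _PCLIP, 1 - _PCLIP)
    if abbott_used and table.control_n > 0:
        # The control rate is itself estimated; the plug-in Abbott
        # correction shifts every corrected response coherently, an
        # error source the binomial information does not see.  Add its
        # delta-method contribution so intervals keep nominal coverage.
        dy_dc = np.where(p_use > 0, n * (p_obs - 1.0) / (1.0 - p_ctrl) ** 2, 0.0)
        phi = norm.pdf(eta)
        s = phi / (p_hat * (1 - p_hat)) * dy_dc
        A = np.column_stack([np.ones_like(x), x])
        g = vcov @ (A.T @ s)
        var_c = p_ctrl * (1 - p_ctrl) / table.control_n
        vcov = vcov + var_c * np.outer(g, g)
    expected = n * p_hat
    chi2 = float(np.sum((y - expected) ** 2 / (expected * (1 - expected / n))))
    df = len(x) - 2
    # Finney's convention: inflate only on *significant* lack of fit,
    # else on-model data would be systematically overcovered.
    if df > 0 and chi2 > chi2_dist.ppf(0.95, df):
        h = chi2 / df
    else:
        h = 1.0
    fit = ProbitFit(
        intercept=a,
        slope=b,
        slope_se=float(np.sqrt(vcov[1, 1])),
        lc50=10.0 ** (-a / b),
        ci95=(np.nan, np.nan),
        chi2=chi2,
        df=df,
        heterogeneity=h,
        converged=converged,
        vcov=vcov,
        n_total=float(np.sum(n)),
    )
    fit.ci95 = lc50_ci(fit)
    return fit


def lc50_ci(fit: ProbitFit, level: float = 0.95, method: str = "fieller") -> tuple[float, float]:
    """Confidence interval for LC50 in mg/L.

    ``fieller`` solves the exact-ratio quadratic for m = -a/b on the
    log10 scale; ``delta`` linearises.  When the fit is heterogeneous
    (chi2/df > 1) the covariance is inflated by h before either method.
    """
    if not fit.converged:
        raise FitError("cannot form an interval from a non-converged fit")
    if fit.slope <= 0:
        raise ValueError("interval requires a positive fitted slope")
    z = norm.ppf(0.5 + level / 2.0)
    a, b = fit.intercept, fit.slope
    v = fit.heterogeneity * fit.vcov
    v11, v12, v22 = v[0, 0], v[0, 1], v[1, 1]
    m = -a / b
    if method == "delta":
        var_m = (v11 + 2 * m * v12 + m**2 * v22) / b**2
        lo, hi = m - z * np.sqrt(var_m), m + z * np.sqrt(var_m)
        return 10.0**lo, 10.0**hi
    if method != "fieller":
        raise ValueError(f"unknown CI method {method!r}")
    g = z**2 * v22 / b**2
    if g >= 1:
        raise UnboundedIntervalError(
            f"slope not distinguishable from zero at this level (g={g:.3f} >= 1)"
        )
    # roots of (a + b m)^2 = z^2 (v11 + 2 m v12 + m^2 v22)
    qa = b**2 - z**2 * v22
    qb = 2 * (a * b - z**2 * v12)
    qc = a**2 - z**2 * v11
    disc = qb**2 - 4 * qa * qc
    if disc < 0:
        raise UnboundedIntervalError("Fieller quadratic has no real roots")
    root = np.sqrt(disc)
    lo = (-qb - root) / (2 * qa)
    hi = (-qb + root) / (2 * qa)
    return 10.0**lo, 10.0**hi


def fit_all(df: pd.DataFrame, apply_abbott: bool = True) -> pd.DataFrame:
    """Fit every (site, insecticide) assay in a long-format frame.

    Returns one row per assay mirroring the usual toxicity-table layout
    (LC50, CI bounds, slope +/- SE, chi2).
    """
    rows = []
    for (site, ins), _ in df.groupby(["site_id", "insecticide"], sort=False):
        table = BioassayTable.from_frame(df, site, ins)
        fit = fit_probit(table, apply_abbott=apply_abbott)
        rows.append(
            {
                "site_id": site,
                "insecticide": ins,
                "lc50_mg_L": fit.lc50,
                "ci_lower": fit.ci95[0],
                "ci_upper": fit.ci95[1],
                "slope": fit.slope,
                "slope_se": fit.slope_se,
                "chi2": fit.chi2,
                "df": fit.df,
                "heterogeneity": fit.heterogeneity,
            }
        )
    return pd.DataFrame(rows)
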