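"""Constrained Hill fits of irradiance-response series under adapting backgrounds.

To test whether a chromatic background desensitizes a cone signal, the
single-wavelength irradiance-response data recorded under each background
are fit jointly with Hill functions

    V(I) = Vmax * I^n / (I^n + sigma^n)

sharing one maximal amplitude Vmax and one exponent n across backgrounds
while the semi-saturation sigma is free per background.  A background that
bleaches the driving opsin shifts log sigma upward (desensitization); a
background the opsin does not absorb leaves log sigma unchanged.  The
shift is assessed by a t test on the fitted log sigma values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "AdaptationSeries",
    "SharedHillFit",
    "fit_shared_hill",
    "compare_semisaturation",
]


@dataclass
class AdaptationSeries:
    """Irradiance-response points at one wavelength under one background."""

    wavelength_nm: float
    background: str
    log_irradiance: np.ndarray
    amplitude: np.ndarray
    se: np.ndarray | None = None
    n: np.ndarray | None = None

    def __post_init__(self):
        self.log_irradiance = np.asarray(self.log_irradiance, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.log_irradiance.size != self.amplitude.size:
            raise ValueError("column lengths differ")
        if self.log_irradiance.size < 4:
            raise ValueError("need at least 4 irradiance levels per series")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.size != self.amplitude.size:
                raise ValueError("se length mismatch")


@dataclass
class SharedHillFit:
    vmax: float
    vmax_se: float
    exponent: float
    exponent_se: float
    log_sigma: dict[str, float]
    log_sigma_se: dict[str, float]
    r2: dict[str, float]
    df_residual: int
    converged: bool
    overlap_warning: bool = False


def _hill_log(log_i: np.ndarray, vmax: float, n_h: float, log_sigma: float) -> np.ndarray:
    # V = Vmax / (1 + 10^(n*(log sigma - log I))), numerically stable form
    z = n_h * (log_sigma - log_i)
    return vmax / (1.0 + np.power(10.0, np.clip(z, -300, 300)))


def fit_shared_hill(series: list[AdaptationSeries]) -> SharedHillFit:
    """Joint Hill fit over backgrounds with shared Vmax and exponent.

    Weighted least squares with weights 1/se when every series carries
    per-point standard errors, unweighted otherwise.  Parameter standard
    errors come from the residual-variance-scaled inverse normal-equations
    matrix of the joint fit; the residual df is pooled over backgrounds.
    """
    if len(series) < 2:
        raise ValueError("need at least two backgrounds")
    backgrounds = [s.background for s in series]
    if len(set(backgrounds)) != len(backgrounds):
        raise ValueError("duplicate background labels")

    # warn (flag) when the log-irradiance ranges do not overlap
    lo = max(s.log_irradiance.min() for s in series)
    hi = min(s.log_irradiance.max() for s in series)
    overlap_warning = bool(lo > hi)

    weighted = all(s.se is not None and np.all(s.se > 0) for s in series)
    amp_all = np.concatenate([s.amplitude for s in series])
    vmax0 = float(amp_all.max()) if amp_all.max() > 0 else 1.0
    theta0 = [vmax0, 1.0]
    for s in series:
        half = 0.5 * vmax0
        j = int(np.argmin(np.abs(s.amplitude - half)))
        theta0.append(float(s.log_irradiance[j]))
    theta0 = np.asarray(theta0)

    def residual(theta):
        vmax, n_h = theta[0], theta[1]
        out = []
        for i, s in enumerate(series):
            pred = _hill_log(s.log_irradiance, vmax, n_h, theta[2 + i])
            r = pred - s.amplitude
            if weighted:
                r = r / s.se
            out.append(r)
        return np.concatenate(out)

    n_params = 2 + len(series)
    lo_b = np.array([0.0, 1e-3] + [-5.0] * len(series))
    hi_b = np.array([np.inf, 20.0] + [15.0] * len(series))
    res = optimize.least_squares(
        residual,
        np.clip(theta0, lo_b + 1e-9, hi_b - 1e-9),
        bounds=(lo_b, hi_b),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        max_nfev=2000,
    )
    theta = res.x
    n_total = amp_all.size
    df = n_total - n_params
    if df < 1:
        raise ValueError("not enough points for the joint fit")
    ss_res = float(2.0 * res.cost)
    res_var = ss_res / df
    jac = res.jac
    try:
        cov = np.linalg.inv(jac.T @ jac) * res_var
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        degenerate = False
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jac.T @ jac) * res_var
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        degenerate = True

    r2 = {}
    for i, s in enumerate(series):
        pred = _hill_log(s.log_irradiance, theta[0], theta[1], theta[2 + i])
        ss = float(np.sum((s.amplitude - pred) ** 2))
        tot = float(np.sum((s.amplitude - s.amplitude.mean()) ** 2))
        r2[s.background] = 1.0 - ss / tot if tot > 0 else np.nan

    return SharedHillFit(
        vmax=float(theta[0]),
        vmax_se=float(se[0]),
        exponent=float(theta[1]),
        exponent_se=float(se[1]),
        log_sigma={s.background: float(theta[2 + i]) for i, s in enumerate(series)},
        log_sigma_se={s.background: float(se[2 + i]) for i, s in enumerate(series)},
        r2=r2,
        df_residual=int(df),
        converged=bool(res.status > 0 and not degenerate),
        overlap_warning=overlap_warning,
    )


def compare_semisaturation(fit: SharedHillFit, bg_a: str, bg_b: str) -> dict:
    """Two-sample t test on the fitted log semi-saturations of two backgrounds.

    Returns ``{"delta_log_sigma", "t", "df", "p"}`` with
    delta = log sigma(A) - log sigma(B); a positive delta means background A
    desensitized the signal relative to background B.
    """
    for bg in (bg_a, bg_b):
        if bg not in fit.log_sigma:
            raise KeyError(f"background {bg!r} not in fit")
    delta = fit.log_sigma[bg_a] - fit.log_sigma[bg_b]
    se = float(np.hypot(fit.log_sigma_se[bg_a], fit.log_sigma_se[bg_b]))
    df = fit.df_residual
    if se == 0:
        p = 0.0 if delta != 0 else 1.0
        t = np.inf if delta != 0 else 0.0
    else:
        t = delta / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    return {"delta_log_sigma": float(delta), "t": float(t), "df": int(df), "p": p}
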