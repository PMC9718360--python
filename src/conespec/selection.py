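"""Exhaustive cone-subset model selection for cumulative spectral datasets.

All 255 nonempty subsets of the eight-cone catalog are fitted to the
dataset by bounded Levenberg–Marquardt-style nonlinear least squares
(scipy trust-region-reflective with analytic Jacobian, multi-started over
a deterministic grid of semi-saturation initializations).  The best model
must satisfy four constraints:

1. the fit converged;
2. every fitted Vm is significantly greater than zero (t test, p <= 0.05);
3. every Vm is below the amplitude cap (2.0 in dataset-normalized units);
4. its r^2 is maximal among admissible models.

Models whose residual variance is statistically indistinguishable from the
best model's (variance-ratio F test, two-sided p >= 0.95) are reported as
an equivalence class.

Model ids are a bitmask over the catalog order: bit i set means cone i
(ascending peak wavelength, UV = bit 0) is included, so the full model of
an 8-cone catalog is id 255 and e.g. {UV, B1, B2, G1, G4, R2} is id 111.

F-test convention: for residual variances (v_A, df_A) vs (v_B, df_B) we
report the cumulative probability cdf = P(F <= v_A/v_B), the one-sided
upper-tail p, and a two-sided p = 2*min(cdf, 1-cdf).  Equivalence is
declared on the two-sided p (near-unity variance ratios give p close to 1);
a large ratio drives the two-sided p toward 0 (inferiority).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataset import SpectralDataset
from .model import ModelParams
from .templates import ConeCatalog

__all__ = [
    "ConeModelSpec",
    "FitOptions",
    "FitResult",
    "SelectionReport",
    "enumerate_models",
    "spec_from_id",
    "fit_model",
    "vm_significance",
    "compare_models_F",
    "select",
    "cross_fit",
]

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class ConeModelSpec:
    """A candidate cone combination, identified by its bitmask id."""

    model_id: int
    subset: tuple[str, ...]

    @property
    def n_cones(self) -> int:
        return len(self.subset)


def spec_from_id(model_id: int, catalog: ConeCatalog) -> ConeModelSpec:
    n = len(catalog)
    if not (1 <= model_id < 2**n):
        raise ValueError(f"model_id must be in [1, {2**n - 1}]")
    subset = tuple(
        lbl for i, lbl in enumerate(catalog.labels) if model_id & (1 << i)
    )
    return ConeModelSpec(model_id=model_id, subset=subset)


def enumerate_models(catalog: ConeCatalog) -> list[ConeModelSpec]:
    """All 2^n - 1 nonempty cone subsets in deterministic id order."""
    return [spec_from_id(mid, catalog) for mid in range(1, 2 ** len(catalog))]


@dataclass(frozen=True)
class FitOptions:
    """Optimizer and acceptance settings for subset fitting and selection."""

    vm_bounds: tuple[float, float] = (0.0, 10.0)
    log_k_bounds: tuple[float, float] = (2.0, 8.0)
    multistart_log_k: tuple[float, ...] = (3.5, 4.0, 4.5, 5.0, 5.5)
    alpha: float = 0.05
    vm_cap: float = 2.0
    equivalence_p: float = 0.95
    one_sided_vm_test: bool = False
    seed: int = 0
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int = 400


@dataclass
class FitResult:
    spec: ConeModelSpec
    vm: dict[str, float]
    vm_se: dict[str, float]
    log_k_uv: float
    log_k_uv_se: float
    r2: float
    ss_res: float
    residual_variance: float
    df_residual: int
    n_points: int
    converged: bool
    vm_p: dict[str, float] = field(default_factory=dict)
    constraint_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def admissible(self) -> bool:
        return all(self.constraint_flags.values())

    def params(self) -> ModelParams:
        return ModelParams(subset=self.spec.subset, vm=dict(self.vm), log_k_uv=self.log_k_uv)


@dataclass
class SelectionReport:
    best: FitResult | None
    equivalents: list[FitResult]
    results: list[FitResult]
    options: FitOptions
    n_points: int

    @property
    def no_admissible_model(self) -> bool:
        return self.best is None

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "model_id": r.spec.model_id,
                    "subset": "+".join(r.spec.subset),
                    "n_cones": r.spec.n_cones,
                    "r2": r.r2,
                    "residual_variance": r.residual_variance,
                    "df_residual": r.df_residual,
                    "converged": r.converged,
                    "all_vm_significant": r.constraint_flags.get("all_vm_significant", False),
                    "all_vm_below_cap": r.constraint_flags.get("all_vm_below_cap", False),
                    "admissible": r.admissible,
                    "is_best": self.best is not None and r.spec.model_id == self.best.spec.model_id,
                    "is_equivalent": any(
                        e.spec.model_id == r.spec.model_id for e in self.equivalents
                    ),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics


def vm_significance(vm: float, se: float, df: int, one_sided: bool = False) -> float:
    """p-value of the t test that a fitted saturation amplitude exceeds zero.

    Default is the two-sided p of t = vm/se with a positivity requirement
    (a negative estimate can never count as a significant cone signal);
    ``one_sided=True`` gives the upper-tail p directly.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if se < 0:
        raise ValueError("se must be nonnegative")
    if se == 0:
        return 0.0 if vm > 0 else 1.0
    t = vm / se
    if one_sided:
        return float(stats.t.sf(t, df))
    if t <= 0:
        return 1.0
    return float(2.0 * stats.t.sf(abs(t), df))


def compare_models_F(res_var_a: float, df_a: int, res_var_b: float, df_b: int) -> dict:
    """Variance-ratio F test between two model fits.

    Returns ``{"F", "cdf", "p_one_sided", "p_two_sided"}`` where
    ``cdf = P(F <= res_var_a/res_var_b)`` under equal true variances,
    ``p_one_sided`` is the upper tail, and ``p_two_sided = 2*min(cdf, 1-cdf)``.
    Equivalence corresponds to a two-sided p >= 0.95 (variance ratio near 1).
    """
    if res_var_a < 0 or res_var_b < 0:
        raise ValueError("residual variances must be nonnegative")
    if df_a < 1 or df_b < 1:
        raise ValueError("dfs must be >= 1")
    if res_var_b == 0:
        if res_var_a == 0:
            return {"F": 1.0, "cdf": 0.5, "p_one_sided": 0.5, "p_two_sided": 1.0}
        return {"F": np.inf, "cdf": 1.0, "p_one_sided": 0.0, "p_two_sided": 0.0}
    f = res_var_a / res_var_b
    cdf = float(stats.f.cdf(f, df_a, df_b))
    sf = float(stats.f.sf(f, df_a, df_b))
    return {
        "F": float(f),
        "cdf": cdf,
        "p_one_sided": sf,
        "p_two_sided": float(2.0 * min(cdf, sf)),
    }


# ---------------------------------------------------------------------------
# fitting machinery


class _SubsetProblem:
    """Residuals/Jacobian of one cone subset on a fixed dataset.

    The absorbance matrix and linear irradiances are precomputed once per
    dataset (see :func:`_prepare`); a problem instance just slices them.
    """

    def __init__(self, x_full: np.ndarray, delta: np.ndarray, y: np.ndarray, idx: list[int]):
        self.x = x_full[:, idx]  # I * A_i per point/cone
        self.delta = delta[idx]
        self.y = y
        self.m = len(idx)

    def hill(self, log_k_uv: float) -> np.ndarray:
        k = 10.0 ** (log_k_uv + self.delta)
        return self.x / (self.x + k)

    def residual(self, theta: np.ndarray) -> np.ndarray:
        vm, log_k = theta[:-1], theta[-1]
        return self.hill(log_k) @ vm - self.y

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        vm, log_k = theta[:-1], theta[-1]
        k = 10.0 ** (log_k + self.delta)
        denom = self.x + k
        h = self.x / denom
        dh_dlogk = -self.x * k * _LN10 / (denom * denom)
        return np.column_stack([h, dh_dlogk @ vm])


def _prepare(dataset: SpectralDataset, catalog: ConeCatalog):
    a = catalog.absorbance_matrix(dataset.wavelength_nm)
    irr = np.power(10.0, dataset.log_irradiance)
    x_full = irr[:, None] * a
    return x_full, catalog.delta_log_k, dataset.amplitude.copy()


def _fit_subset(problem: _SubsetProblem, options: FitOptions):
    """Multi-start bounded least squares; returns (theta, ss_res, converged)."""
    m = problem.m
    lo = np.array([options.vm_bounds[0]] * m + [options.log_k_bounds[0]])
    hi = np.array([options.vm_bounds[1]] * m + [options.log_k_bounds[1]])
    best = None
    for log_k0 in options.multistart_log_k:
        h0 = problem.hill(log_k0)
        try:
            vm0, _ = optimize.nnls(h0, problem.y)
        except RuntimeError:
            vm0 = np.zeros(m)
        theta0 = np.clip(
            np.append(vm0, log_k0), lo + 1e-12, hi - 1e-12
        )
        res = optimize.least_squares(
            problem.residual,
            theta0,
            jac=problem.jacobian,
            bounds=(lo, hi),
            method="trf",
            xtol=options.xtol,
            ftol=options.ftol,
            gtol=options.gtol,
            max_nfev=options.max_nfev,
        )
        ss = float(2.0 * res.cost)
        if best is None or ss < best[1]:
            best = (res.x.copy(), ss, res.status > 0)
    return best


def _fit_result(
    spec: ConeModelSpec,
    problem: _SubsetProblem,
    theta: np.ndarray,
    ss_res: float,
    converged: bool,
    ss_tot: float,
    n: int,
    options: FitOptions,
) -> FitResult:
    m = problem.m
    n_params = m + 1
    df = n - n_params
    if df <= 0:
        raise ValueError("insufficient points for this model")
    res_var = ss_res / df
    # standard errors from the approximated normal-equations matrix
    jac = problem.jacobian(theta)
    jtj = jac.T @ jac
    se = np.full(n_params, np.nan)
    ill_conditioned = False
    try:
        cond = np.linalg.cond(jtj)
        if not np.isfinite(cond) or cond > 1e12:
            ill_conditioned = True
            cov = np.linalg.pinv(jtj) * res_var
        else:
            cov = np.linalg.inv(jtj) * res_var
        diag = np.clip(np.diag(cov), 0.0, None)
        se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        ill_conditioned = True
    converged = bool(converged and not ill_conditioned)

    labels = spec.subset
    vm = {lbl: float(theta[i]) for i, lbl in enumerate(labels)}
    vm_se = {lbl: float(se[i]) for i, lbl in enumerate(labels)}
    vm_p = {
        lbl: (
            vm_significance(vm[lbl], vm_se[lbl], df, options.one_sided_vm_test)
            if np.isfinite(vm_se[lbl])
            else 1.0
        )
        for lbl in labels
    }
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    flags = {
        "converged": converged,
        "all_vm_significant": all(p <= options.alpha for p in vm_p.values()),
        "all_vm_below_cap": all(v < options.vm_cap for v in vm.values()),
    }
    return FitResult(
        spec=spec,
        vm=vm,
        vm_se=vm_se,
        log_k_uv=float(theta[-1]),
        log_k_uv_se=float(se[-1]),
        r2=float(r2) if np.isfinite(r2) else np.nan,
        ss_res=float(ss_res),
        residual_variance=float(res_var),
        df_residual=int(df),
        n_points=int(n),
        converged=converged,
        vm_p=vm_p,
        constraint_flags=flags,
    )


def fit_model(
    dataset: SpectralDataset,
    spec: ConeModelSpec,
    catalog: ConeCatalog,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit one cone-subset model to a spectral dataset.

    Free parameters are the included Vm values and the shared log10 UV
    semi-saturation.  Multi-start initialization: each start fixes the
    semi-saturation on a deterministic grid and seeds the Vm from a
    nonnegative-least-squares pass; the best local optimum is kept.
    """
    options = options or FitOptions()
    n = dataset.n_points
    if n <= len(spec.subset) + 1:
        raise ValueError("dataset has too few points for this model")
    x_full, delta, y = _prepare(dataset, catalog)
    idx = [catalog.index(lbl) for lbl in spec.subset]
    problem = _SubsetProblem(x_full, delta, y, idx)
    theta, ss_res, converged = _fit_subset(problem, options)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return _fit_result(spec, problem, theta, ss_res, converged, ss_tot, n, options)


def select(
    dataset: SpectralDataset,
    catalog: ConeCatalog,
    options: FitOptions | None = None,
) -> SelectionReport:
    """Fit every cone subset and pick the best admissible model.

    Admissibility: converged, every Vm significant at ``options.alpha``,
    every Vm below ``options.vm_cap``.  Among admissible models the one
    with maximal r^2 wins; exact ties go to the smaller subset (parsimony),
    then the smaller id.  Admissible models indistinguishable from the best
    by the two-sided variance-ratio F test at ``options.equivalence_p`` are
    reported as equivalents.
    """
    options = options or FitOptions()
    n = dataset.n_points
    if n == 0:
        raise ValueError("empty dataset")
    x_full, delta, y = _prepare(dataset, catalog)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    results: list[FitResult] = []
    for spec in enumerate_models(catalog):
        if n <= len(spec.subset) + 1:
            continue
        idx = [catalog.index(lbl) for lbl in spec.subset]
        problem = _SubsetProblem(x_full, delta, y, idx)
        theta, ss_res, converged = _fit_subset(problem, options)
        results.append(
            _fit_result(spec, problem, theta, ss_res, converged, ss_tot, n, options)
        )
    admissible = [r for r in results if r.admissible and np.isfinite(r.r2)]
    if not admissible:
        return SelectionReport(None, [], results, options, n)
    best = max(admissible, key=lambda r: (r.r2, -r.spec.n_cones, -r.spec.model_id))
    equivalents = []
    for r in admissible:
        if r.spec.model_id == best.spec.model_id:
            continue
        cmp = compare_models_F(
            r.residual_variance, r.df_residual, best.residual_variance, best.df_residual
        )
        if cmp["p_two_sided"] >= options.equivalence_p:
            equivalents.append(r)
    return SelectionReport(best, equivalents, results, options, n)


def cross_fit(
    dataset_b: SpectralDataset,
    spec_a: ConeModelSpec,
    catalog: ConeCatalog,
    options: FitOptions | None = None,
    best_b: FitResult | None = None,
) -> tuple[FitResult, dict]:
    """Fit dataset B with model A's cone combination and compare to B's own best.

    Used for between-genotype comparisons: a large variance ratio (two-sided
    p near 0) means combination A does not represent dataset B.  If
    ``best_b`` is not supplied, a full selection on B is run to obtain it.
    """
    options = options or FitOptions()
    fit_a_on_b = fit_model(dataset_b, spec_a, catalog, options)
    if best_b is None:
        report = select(dataset_b, catalog, options)
        if report.best is None:
            raise ValueError("dataset B has no admissible model to compare against")
        best_b = report.best
    comparison = compare_models_F(
        fit_a_on_b.residual_variance,
        fit_a_on_b.df_residual,
        best_b.residual_variance,
        best_b.df_residual,
    )
    comparison["best_b_model_id"] = best_b.spec.model_id
    return fit_a_on_b, comparison
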