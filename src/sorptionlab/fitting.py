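"""Parameter estimation for sorption isotherm models.

Estimation minimizes the residual mean square

    RMS = sum((y_exp - y_cal)^2) / N

by nonlinear ordinary least squares.  Initialization follows two routes:

* GAB: rearranging the isotherm into a second-order polynomial in ``aw``
  (``aw/xe`` regressed on ``1, aw, aw^2``) and inverting algebraically.
* empirical models: a real-coded genetic algorithm searching inside
  per-parameter bounds.

A global (all-temperature, all-covariate) fit links temperature through the
Arrhenius laws (GAB) or per-coefficient linear laws (empirical), plus the
two additive dummy coefficients ``b1``/``b2``.  Both a ``"joint"`` strategy
(one simultaneous RMS minimization, the default) and a ``"sequential"``
strategy (per-temperature fits, temperature-law linkage, then a b-only
refit) are available.

Residuals are always stored in the canonical record order
(method, branch, temperature, ascending aw) so that order-sensitive
diagnostics (Ljung-Box) are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .errors import (
    BoundsError,
    EvaluationDomainError,
    InitializationError,
    UnidentifiableError,
)
from .models import ModelSpec, ParameterVector, celsius_to_kelvin, evaluate_model
from .synthetic import IsothermDataset

__all__ = [
    "GAConfig",
    "FitResult",
    "canonical_order",
    "default_bounds",
    "init_gab_quadratic",
    "ga_initialize",
    "fit_ols",
    "linearize_arrhenius",
    "confidence_intervals",
    "fit_global",
]

_PENALTY = 1e6


@dataclass(frozen=True)
class GAConfig:
    """Settings for the genetic-algorithm initializer (seed is mandatory)."""

    population: int = 60
    generations: int = 150
    bounds: dict[str, tuple[float, float]] | None = None
    seed: int = 0
    tournament_k: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.15
    elite: int = 2

    def __post_init__(self):
        if self.population < 2:
            raise BoundsError("GA population must be >= 2")
        if self.generations < 1:
            raise BoundsError("GA needs at least one generation")


@dataclass
class FitResult:
    """Converged parameters, RMS and residuals for one model on one dataset."""

    spec: ModelSpec
    params: ParameterVector
    rms: float
    n_obs: int
    converged: bool
    residuals: np.ndarray
    iterations: int
    message: str = ""
    jac: np.ndarray | None = field(default=None, repr=False)
    internal: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "temp_mode": self.spec.temp_mode,
            "uses_dummies": self.spec.uses_dummies,
            "params": self.params.to_dict(),
            "rms": float(self.rms),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "message": self.message,
        }


def canonical_order(frame):
    """Sort records by (method, branch, temperature, ascending aw, replicate)."""
    return frame.sort_values(
        ["method", "branch", "temperature_c", "aw", "replicate"],
        kind="mergesort",
    ).reset_index(drop=True)


def _arrays(dataset: IsothermDataset):
    df = canonical_order(dataset.frame)
    return (
        df["aw"].to_numpy(float),
        df["temperature_c"].to_numpy(float),
        (df["method"].to_numpy() == "semidry").astype(float),
        (df["branch"].to_numpy() == "adsorption").astype(float),
        df["xe"].to_numpy(float),
    )


def default_bounds(spec: ModelSpec) -> dict[str, tuple[float, float]]:
    """Shipped search bounds per parameter; every entry overridable."""
    bounds: dict[str, tuple[float, float]] = {}
    for p in spec.param_names:
        if p == "Xm":
            bounds[p] = (1e-3, 0.5)
        elif p == "C":
            bounds[p] = (1e-2, 1e3)
        elif p == "K":
            bounds[p] = (1e-2, 0.99)
        elif p == "C0":
            bounds[p] = (1e-12, 1e2)
        elif p == "K0":
            bounds[p] = (1e-3, 1e3)
        elif p in ("Hm", "Hn"):
            bounds[p] = (0.0, 1e4)
        elif p in ("b1", "b2"):
            bounds[p] = (-0.1, 0.1)
        elif p.endswith("_1"):
            bounds[p] = (-0.5, 0.5)  # per-Kelvin slopes
        else:
            bounds[p] = (-10.0, 10.0)
    return bounds


# ---------------------------------------------------------------------------
# internal parameterization: positive Arrhenius prefactors are optimized in
# log space for conditioning; everything else is identity.

def _transforms(spec: ModelSpec) -> tuple[str, ...]:
    return tuple(
        "log" if (spec.temp_mode == "arrhenius" and p in ("C0", "K0")) else "id"
        for p in spec.param_names
    )


def _to_internal(spec: ModelSpec, params: ParameterVector) -> np.ndarray:
    out = []
    for name, tr in zip(spec.param_names, _transforms(spec)):
        v = params[name]
        if tr == "log":
            if v <= 0:
                raise EvaluationDomainError(f"{name} must be positive (got {v})")
            out.append(np.log(v))
        else:
            out.append(v)
    return np.array(out, dtype=float)


def _from_internal(spec: ModelSpec, x: np.ndarray) -> ParameterVector:
    vals = {}
    for name, tr, v in zip(spec.param_names, _transforms(spec), x):
        vals[name] = float(np.exp(v)) if tr == "log" else float(v)
    return ParameterVector(vals)


def _rms_of(spec, params, aw, temp, d1, d2, y) -> float:
    try:
        pred = evaluate_model(spec, params, aw, temperature_c=temp, d1=d1, d2=d2)
    except EvaluationDomainError:
        return np.inf
    return float(np.mean((y - pred) ** 2))


def init_gab_quadratic(aw, xe=None) -> tuple[float, float, float]:
    """Initialize (Xm, C, K) by the quadratic rearrangement of the GAB law.

    ``aw/xe`` is regressed on ``(1, aw, aw^2)`` by OLS; the three
    coefficients are inverted algebraically into the GAB parameters.  The
    inversion solves ``K^2 + f*K + g = 0`` with ``f = beta1/beta0`` and
    ``g = beta2/beta0``, then ``C = f/K + 2`` and ``Xm = 1/(beta0*C*K)``.

    Accepts either ``(aw_array, xe_array)`` or a single-temperature
    :class:`IsothermDataset`.

    Raises
    ------
    InitializationError
        When the quadratic is underdetermined or the inversion yields no
        positive real triple (callers fall back to GA initialization).
    """
    if xe is None:
        if not isinstance(aw, IsothermDataset):
            raise TypeError("pass (aw, xe) arrays or an IsothermDataset")
        df = aw.frame
        if df["temperature_c"].nunique() != 1:
            raise InitializationError("quadratic init needs a single-temperature subset")
        aw, xe = df["aw"].to_numpy(float), df["xe"].to_numpy(float)
    aw = np.asarray(aw, dtype=float)
    xe = np.asarray(xe, dtype=float)
    if len(np.unique(aw)) < 3:
        raise InitializationError("quadratic init needs >= 3 distinct aw values")
    if np.any(xe <= 0):
        raise InitializationError("quadratic init needs all xe > 0")
    design = np.column_stack([np.ones_like(aw), aw, aw ** 2])
    beta, *_ = np.linalg.lstsq(design, aw / xe, rcond=None)
    b0, b1, b2 = beta
    if b0 == 0:
        raise InitializationError("degenerate quadratic (beta0 = 0)")
    f, g = b1 / b0, b2 / b0
    disc = f * f - 4.0 * g
    if disc < 0:
        raise InitializationError("complex roots in GAB quadratic inversion")
    roots = [(-f + np.sqrt(disc)) / 2.0, (-f - np.sqrt(disc)) / 2.0]
    candidates = []
    for k in roots:
        if k <= 0:
            continue
        c = f / k + 2.0
        if c <= 0:
            continue
        xm = 1.0 / (b0 * c * k)
        if xm <= 0:
            continue
        candidates.append((xm, c, k))
    if not candidates:
        raise InitializationError("no positive (Xm, C, K) root in GAB inversion")
    # prefer the physically usual multilayer factor K < 1
    candidates.sort(key=lambda t: (not (0 < t[2] < 1), t[2]))
    return candidates[0]


def ga_initialize(spec: ModelSpec, dataset: IsothermDataset,
                  config: GAConfig) -> ParameterVector:
    """Genetic-algorithm search for a starting parameter vector.

    Real-coded GA with tournament selection, blend crossover, Gaussian
    mutation and elitism, minimizing RMS inside the configured bounds.
    Deterministic given the seed.
    """
    bounds_map = dict(default_bounds(spec))
    if config.bounds:
        bounds_map.update(config.bounds)
    names = spec.param_names
    missing = [p for p in names if p not in bounds_map]
    if missing:
        raise BoundsError(f"missing GA bounds for parameters: {missing}")
    lo = np.array([bounds_map[p][0] for p in names], dtype=float)
    hi = np.array([bounds_map[p][1] for p in names], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))) or np.any(hi < lo):
        raise BoundsError("GA bounds must be finite with hi >= lo")

    aw, temp, d1, d2, y = _arrays(dataset)
    rng = np.random.default_rng(config.seed)

    def fitness(x: np.ndarray) -> float:
        return _rms_of(spec, ParameterVector(dict(zip(names, x))), aw, temp, d1, d2, y)

    pop = rng.uniform(lo, hi, size=(config.population, len(names)))
    fit = np.array([fitness(x) for x in pop])
    if not np.any(np.isfinite(fit)):
        raise BoundsError("all GA individuals infeasible; widen the bounds")

    span = hi - lo
    for _ in range(config.generations):
        order = np.argsort(fit)
        pop, fit = pop[order], fit[order]
        new = [pop[i].copy() for i in range(min(config.elite, len(pop)))]
        while len(new) < config.population:
            idx = rng.integers(0, config.population, size=config.tournament_k)
            p1 = pop[idx[np.argmin(fit[idx])]]
            idx = rng.integers(0, config.population, size=config.tournament_k)
            p2 = pop[idx[np.argmin(fit[idx])]]
            if rng.random() < config.crossover_rate:
                u = rng.uniform(-0.25, 1.25, size=len(names))
                child = u * p1 + (1.0 - u) * p2
            else:
                child = p1.copy()
            mask = rng.random(len(names)) < config.mutation_rate
            child = np.where(mask, child + rng.normal(0.0, 0.1 * span + 1e-300), child)
            new.append(np.clip(child, lo, hi))
        pop = np.array(new)
        fit = np.array([fitness(x) for x in pop])

    best = pop[np.argmin(fit)]
    if not np.isfinite(fit.min()):
        raise BoundsError("GA failed to find a feasible individual")
    return ParameterVector(dict(zip(names, best)))


def _numeric_jacobian(spec, x, aw, temp, d1, d2):
    """Central-difference Jacobian of predictions w.r.t. internal parameters."""
    n = len(x)
    cols = []
    for j in range(n):
        h = 1e-6 * max(1.0, abs(x[j]))
        xp, xm_ = x.copy(), x.copy()
        xp[j] += h
        xm_[j] -= h
        fp = evaluate_model(spec, _from_internal(spec, xp), aw, temperature_c=temp, d1=d1, d2=d2)
        fm = evaluate_model(spec, _from_internal(spec, xm_), aw, temperature_c=temp, d1=d1, d2=d2)
        cols.append((np.asarray(fp) - np.asarray(fm)) / (2.0 * h))
    # residual = y - f, so d(residual)/dx = -df/dx
    return -np.column_stack(cols)


def fit_ols(spec: ModelSpec, dataset: IsothermDataset, init: ParameterVector,
            tol: float = 1e-10, max_iter: int = 2000) -> FitResult:
    """Nonlinear least squares (RMS minimization) from a given start.

    The start must be evaluable on every record; a domain violation at the
    initial point raises before any iteration.  Divergence or a singular
    Jacobian yields ``converged=False`` with diagnostics rather than a
    silent success.
    """
    aw, temp, d1, d2, y = _arrays(dataset)
    if len(y) == 0:
        raise ValueError("empty dataset")
    # precondition: the initial point must be inside the evaluation domain
    evaluate_model(spec, init, aw, temperature_c=temp, d1=d1, d2=d2)
    x0 = _to_internal(spec, init)

    def resid(x):
        try:
            pred = evaluate_model(spec, _from_internal(spec, x), aw,
                                  temperature_c=temp, d1=d1, d2=d2)
        except EvaluationDomainError:
            return np.full_like(y, _PENALTY)
        return y - pred

    method = "lm" if len(y) >= len(x0) else "trf"
    res = least_squares(resid, x0, method=method, xtol=tol, ftol=tol,
                        gtol=1e-14, max_nfev=max_iter)
    params = _from_internal(spec, res.x)
    residuals = resid(res.x)
    converged = bool(res.success) and np.all(np.abs(residuals) < _PENALTY)
    rms = float(np.mean(residuals ** 2))
    jac = _numeric_jacobian(spec, res.x, aw, temp, d1, d2) if converged else None
    return FitResult(
        spec=spec, params=params, rms=rms, n_obs=len(y), converged=converged,
        residuals=residuals, iterations=int(res.nfev), message=str(res.message),
        jac=jac, internal=res.x,
    )


def linearize_arrhenius(temps_c, c_values, k_values, lambda_: float,
                        r_w: float = 0.4615) -> tuple[float, float, float, float]:
    """Recover (C0, K0, Hm, Hn) from per-temperature (C, K) estimates.

    ``ln C`` is regressed on ``1/T_K`` (slope ``(Hm - Hn)/R_w``, intercept
    ``ln C0``); ``ln K`` likewise (slope ``(lambda - Hn)/R_w``), after which
    ``Hn = lambda - slope_K * R_w`` and ``Hm = Hn + slope_C * R_w``.
    """
    temps_c = np.asarray(temps_c, dtype=float)
    c_values = np.asarray(c_values, dtype=float)
    k_values = np.asarray(k_values, dtype=float)
    if np.any(c_values <= 0) or np.any(k_values <= 0):
        raise EvaluationDomainError("Arrhenius linearization needs positive C and K")
    if len(np.unique(temps_c)) < 2:
        raise UnidentifiableError("need >= 2 distinct temperatures")
    inv_t = 1.0 / celsius_to_kelvin(temps_c)
    slope_c, intercept_c = np.polyfit(inv_t, np.log(c_values), 1)
    slope_k, intercept_k = np.polyfit(inv_t, np.log(k_values), 1)
    c0 = float(np.exp(intercept_c))
    k0 = float(np.exp(intercept_k))
    hn = float(lambda_ - slope_k * r_w)
    hm = float(hn + slope_c * r_w)
    return c0, k0, hm, hn


def confidence_intervals(fit: FitResult, level: float = 0.95) -> ParameterVector:
    """Asymptotic (linearized) confidence intervals at the optimum.

    Based on the residual variance and the Jacobian at the solution;
    intervals are symmetric about the point estimates.  Log-space internal
    parameters are mapped back by the delta method.
    """
    if not fit.converged or fit.jac is None:
        raise UnidentifiableError("confidence intervals require a converged fit")
    jac = fit.jac
    n, m = jac.shape
    if n <= m:
        raise UnidentifiableError("more parameters than observations")
    _, s, vt = np.linalg.svd(jac, full_matrices=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-10:
        raise UnidentifiableError(
            "rank-deficient Jacobian: at least one parameter is not identifiable"
        )
    sse = float(np.sum(fit.residuals ** 2))
    s2 = sse / (n - m)
    cov = (vt.T * (s2 / s ** 2)) @ vt
    se_int = np.sqrt(np.maximum(np.diag(cov), 0.0))
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - m)
    names = fit.spec.param_names
    trans = _transforms(fit.spec)
    ci = {}
    for name, tr, se in zip(names, trans, se_int):
        v = fit.params[name]
        half = tcrit * (se * abs(v) if tr == "log" else se)
        ci[name] = (v - half, v + half)
    fit.params.ci = ci
    return fit.params


def _fit_dummies_ols(spec_nod, params, dataset):
    """Closed-form OLS for the additive b1/b2 offsets given base parameters."""
    aw, temp, d1, d2, y = _arrays(dataset)
    base = evaluate_model(spec_nod, params, aw, temperature_c=temp, d1=0, d2=0)
    design = np.column_stack([d1, d2])
    b, *_ = np.linalg.lstsq(design, y - base, rcond=None)
    return float(b[0]), float(b[1])


def _sequential_estimate(spec: ModelSpec, dataset: IsothermDataset,
                         ga_config: GAConfig | None) -> ParameterVector:
    """Per-temperature fits, temperature-law linkage, then b-only OLS refit."""
    df = dataset.frame
    if spec.uses_dummies:
        ref = dataset.subset((df["method"] == "wet") & (df["branch"] == "desorption"))
    else:
        ref = dataset
    temps = sorted(ref.frame["temperature_c"].unique())
    base_spec = ModelSpec(spec.name, temp_mode="fixed", uses_dummies=False,
                          dlp_reduced=spec.dlp_reduced,
                          lambda_=spec.lambda_, r_w=spec.r_w)
    ga = ga_config or GAConfig(population=40, generations=60, seed=0)
    per_t: dict[float, ParameterVector] = {}
    for i, t in enumerate(temps):
        sub = ref.subset(ref.frame["temperature_c"] == t)
        if spec.name == "GAB":
            try:
                xm, c, k = init_gab_quadratic(
                    sub.frame["aw"].to_numpy(float), sub.frame["xe"].to_numpy(float))
                init_t = ParameterVector({"Xm": xm, "C": c, "K": k})
            except InitializationError:
                init_t = ga_initialize(base_spec, sub,
                                       GAConfig(population=ga.population,
                                                generations=ga.generations,
                                                bounds=ga.bounds, seed=ga.seed + i))
        else:
            init_t = ga_initialize(base_spec, sub,
                                   GAConfig(population=ga.population,
                                            generations=ga.generations,
                                            bounds=ga.bounds, seed=ga.seed + i))
        per_t[t] = fit_ols(base_spec, sub, init_t).params

    values: dict[str, float] = {}
    if spec.temp_mode == "arrhenius":
        c0, k0, hm, hn = linearize_arrhenius(
            temps,
            [per_t[t]["C"] for t in temps],
            [per_t[t]["K"] for t in temps],
            spec.lambda_, spec.r_w,
        )
        values.update(Xm=float(np.mean([per_t[t]["Xm"] for t in temps])),
                      C0=c0, K0=k0, Hm=hm, Hn=hn)
    elif spec.temp_mode == "linear":
        t_k = celsius_to_kelvin(np.array(temps))
        for a in spec.base_coeffs:
            vals = np.array([per_t[t][a] for t in temps])
            if spec.dlp_reduced and spec.name == "DLP" and a == "a2":
                values[f"{a}_1"] = float(np.sum(vals * t_k) / np.sum(t_k ** 2))
            else:
                slope, intercept = np.polyfit(t_k, vals, 1)
                values[f"{a}_1"] = float(slope)
                values[f"{a}_2"] = float(intercept)
    else:  # fixed: single temperature expected
        values.update({k: v for k, v in per_t[temps[0]].values.items()})

    if spec.uses_dummies:
        spec_nod = ModelSpec(spec.name, temp_mode=spec.temp_mode, uses_dummies=False,
                             dlp_reduced=spec.dlp_reduced,
                             lambda_=spec.lambda_, r_w=spec.r_w)
        b1, b2 = _fit_dummies_ols(spec_nod, ParameterVector(values), dataset)
        values["b1"], values["b2"] = b1, b2
    return ParameterVector(values)


def _evaluate_fit(spec: ModelSpec, dataset: IsothermDataset,
                  params: ParameterVector) -> FitResult:
    """Build a FitResult at fixed parameters (no optimization)."""
    aw, temp, d1, d2, y = _arrays(dataset)
    pred = evaluate_model(spec, params, aw, temperature_c=temp, d1=d1, d2=d2)
    residuals = y - pred
    x = _to_internal(spec, params)
    jac = _numeric_jacobian(spec, x, aw, temp, d1, d2)
    return FitResult(spec=spec, params=params, rms=float(np.mean(residuals ** 2)),
                     n_obs=len(y), converged=True, residuals=residuals,
                     iterations=0, message="sequential estimate", jac=jac, internal=x)


def fit_global(spec: ModelSpec, dataset: IsothermDataset,
               strategy: str = "joint", init: ParameterVector | None = None,
               ga_config: GAConfig | None = None, tol: float = 1e-10,
               max_iter: int = 2000) -> FitResult:
    """Fit the temperature-parameterized model plus dummy offsets.

    ``strategy="joint"`` (default): one simultaneous RMS minimization of all
    coefficients, started from the sequential estimate (or ``init``).
    ``strategy="sequential"``: the staged estimate itself, no joint polish.
    """
    if strategy not in ("joint", "sequential"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if spec.uses_dummies:
        df = dataset.frame
        if "semidry" not in set(df["method"]) or "wet" not in set(df["method"]):
            present = sorted(set(df["method"]))
            raise UnidentifiableError(
                f"b1 unidentifiable: method has only level(s) {present}; "
                "both 'wet' and 'semidry' are required"
            )
        if "adsorption" not in set(df["branch"]) or "desorption" not in set(df["branch"]):
            present = sorted(set(df["branch"]))
            raise UnidentifiableError(
                f"b2 unidentifiable: branch has only level(s) {present}; "
                "both 'desorption' and 'adsorption' are required"
            )
    start = init if init is not None else _sequential_estimate(spec, dataset, ga_config)
    if strategy == "sequential":
        return _evaluate_fit(spec, dataset, start)
    return fit_ols(spec, dataset, start, tol=tol, max_iter=max_iter)
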