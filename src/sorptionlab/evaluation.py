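"""Model evaluation: metrics, repeated splits, residual screening, ranking.

The protocol: the dataset is randomly partitioned ``n_iterations`` times
(default 100) into 75% training / 25% validation; every model is refit per
iteration and scored on both subsets with the mean relative error (MRE, %)
and the adjusted coefficient of determination (R2adj, %).  Residuals of the
full-training fits are screened for independence (Ljung-Box) and
homoscedasticity (Levene/Brown-Forsythe).  A two-factor ANOVA
(model x iteration) with Fisher LSD pairwise comparisons ranks the models
per metric and assigns compact letter groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import acorr_ljungbox

from .errors import DegenerateInputError, SchemaError, UnidentifiableError
from .fitting import FitResult, canonical_order, fit_global
from .ml import ML_NAMES, MLConfig, train_ml
from .models import MODEL_NAMES, evaluate_model, get_spec
from .synthetic import IsothermDataset

__all__ = [
    "SplitPlan",
    "EvalConfig",
    "RankingTable",
    "make_splits",
    "mre",
    "r2_adj",
    "ljung_box",
    "levene",
    "aw_tercile_groups",
    "compact_letters",
    "anova_lsd",
    "anova_residual_checks",
    "run_pipeline",
]


@dataclass
class SplitPlan:
    """Reproducible repeated train/validation partitions."""

    n_iterations: int
    train_fraction: float
    splits: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    stratified: bool = True

    def __iter__(self):
        return iter(self.splits)


@dataclass
class EvalConfig:
    """Thresholds and knobs for the evaluation stage (single config block)."""

    alpha: float = 0.05
    lb_lags: int | None = None  # default min(10, N // 5)
    levene_grouping: str = "aw_terciles"  # or "temperature"
    r2_denominator: str = "standard"  # or "as_printed"
    ml_config: MLConfig = field(default_factory=MLConfig)
    fit_strategy: str = "joint"
    unstable_threshold: float = 0.2


@dataclass
class RankingTable:
    """Per-model metric means +/- SE with LSD letters and final ordering."""

    table: pd.DataFrame  # one row per model
    anova: dict  # omnibus F/p per metric and factor
    lsd: dict  # LSD half-interval per metric
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "anova": self.anova,
            "lsd": self.lsd,
            "models": self.table.to_dict(orient="records"),
        }


def make_splits(dataset: IsothermDataset, n_iterations: int = 100,
                train_fraction: float = 0.75, seed: int = 0,
                stratify: bool = True) -> SplitPlan:
    """Repeated random 75/25-style partitions of the record set.

    By default sampling is stratified on the (method, branch, temperature)
    cell so every factor level stays represented in every training set
    (the dummy coefficients are unidentifiable otherwise); plain uniform
    sampling is available with ``stratify=False``.
    """
    n = len(dataset)
    if n < 8:
        raise SchemaError("dataset too small to partition (need >= 8 records)")
    if not 0 < train_fraction < 1:
        raise SchemaError("train_fraction must lie in (0, 1)")
    df = canonical_order(dataset.frame)
    rng = np.random.default_rng(seed)
    if stratify:
        groups = [idx.to_numpy() for _, idx in
                  df.groupby(["method", "branch", "temperature_c"], sort=True).groups.items()]
        groups = [np.sort(np.asarray(g)) for g in groups]
    else:
        groups = [np.arange(n)]
    splits = []
    for _ in range(n_iterations):
        train_parts, val_parts = [], []
        for g in groups:
            perm = rng.permutation(g)
            k = int(round(train_fraction * len(g)))
            k = min(max(k, 1), len(g) - 1) if len(g) > 1 else len(g)
            train_parts.append(perm[:k])
            val_parts.append(perm[k:])
        train_idx = np.sort(np.concatenate(train_parts))
        val_idx = np.sort(np.concatenate(val_parts))
        if len(val_idx) == 0:
            raise SchemaError("train_fraction leaves an empty validation set")
        splits.append((train_idx, val_idx))
    return SplitPlan(n_iterations, train_fraction, splits, seed, stratify)


def mre(y_exp, y_cal) -> float:
    """Mean relative error in percent: (100/N) * sum |y_exp - y_cal| / y_exp."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    if y_exp.shape != y_cal.shape:
        raise SchemaError("y_exp and y_cal must have equal length")
    if np.any(y_exp == 0):
        raise DegenerateInputError("MRE undefined: y_exp contains zeros")
    return float(100.0 / len(y_exp) * np.sum(np.abs(y_exp - y_cal) / np.abs(y_exp)))


def r2_adj(y_exp, y_pred, m: int,
           denominator: str = "standard") -> tuple[float, float]:
    """Coefficient of determination and its parameter-count-adjusted form (%).

    ``denominator="standard"`` uses the total sum of squares about the mean
    of ``y_exp``; ``"as_printed"`` reproduces an alternative form in which
    the denominator is ``sum((mean(y_exp) - y_pred)^2)``.  Returns
    ``(r2, r2_adj)``, both in percent:
    ``r2_adj = 100 - ((N-1)/(N-M)) * (100 - r2)``.
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = len(y_exp)
    if n <= m:
        raise DegenerateInputError(f"need N > M for adjusted R2 (N={n}, M={m})")
    if np.allclose(y_exp, y_exp[0]):
        raise DegenerateInputError("R2 undefined for constant y_exp")
    sse = float(np.sum((y_exp - y_pred) ** 2))
    if denominator == "standard":
        sst = float(np.sum((y_exp - y_exp.mean()) ** 2))
    elif denominator == "as_printed":
        sst = float(np.sum((y_exp.mean() - y_pred) ** 2))
    else:
        raise SchemaError(f"unknown r2 denominator {denominator!r}")
    if sst == 0:
        raise DegenerateInputError("zero total sum of squares")
    r2 = 100.0 * (1.0 - sse / sst)
    adj = 100.0 - (n - 1) / (n - m) * (100.0 - r2)
    return r2, adj


def ljung_box(residuals, lags: int | None = None) -> float:
    """Ljung-Box p-value for residual independence.

    Residuals must already be in the canonical record order.  Default lag
    count is ``min(10, N // 5)``.
    """
    residuals = np.asarray(residuals, dtype=float)
    n = len(residuals)
    if lags is None:
        lags = max(1, min(10, n // 5))
    if not 1 <= lags < n:
        raise DegenerateInputError(f"need N > lags >= 1 (N={n}, lags={lags})")
    if np.allclose(residuals, residuals[0]):
        raise DegenerateInputError("constant residual vector")
    out = acorr_ljungbox(residuals, lags=[lags], return_df=True)
    return float(out["lb_pvalue"].iloc[0])


def levene(residuals, groups) -> float:
    """Brown-Forsythe (median-centered Levene) p-value for homoscedasticity."""
    residuals = np.asarray(residuals, dtype=float)
    groups = np.asarray(groups)
    if residuals.shape != groups.shape:
        raise SchemaError("residuals and groups must align")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise DegenerateInputError("Levene's test needs >= 2 groups")
    samples = [residuals[groups == lab] for lab in labels]
    if any(len(s) < 2 for s in samples):
        raise DegenerateInputError("every group needs >= 2 residuals")
    return float(stats.levene(*samples, center="median").pvalue)


def aw_tercile_groups(aw) -> np.ndarray:
    """Default Levene grouping: low/mid/high water-activity terciles."""
    aw = np.asarray(aw, dtype=float)
    q1, q2 = np.quantile(aw, [1 / 3, 2 / 3])
    return np.where(aw <= q1, "low", np.where(aw <= q2, "mid", "high"))


def compact_letters(means: np.ndarray, significant: np.ndarray,
                    order: np.ndarray) -> list[str]:
    """Compact letter display from a pairwise-significance matrix.

    ``order`` ranks treatments best-first.  For LSD with equal replication
    the non-significance relation is an interval graph on the sorted means,
    so maximal non-significant runs are the letter groups.
    """
    k = len(means)
    letters = ["" for _ in range(k)]
    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and not any(
            significant[order[a], order[b]]
            for a in range(i, j + 2) for b in range(a + 1, j + 2)
        ):
            j += 1
        runs.append((i, j))
    # keep maximal runs only
    maximal = [r for r in runs if not any(
        (o[0] <= r[0] and r[1] <= o[1] and o != r) for o in runs)]
    maximal.sort()
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for li, (i, j) in enumerate(maximal):
        ch = alphabet[li % len(alphabet)] * (li // len(alphabet) + 1)
        for pos in range(i, j + 1):
            letters[order[pos]] += ch
    return letters


def _two_way_anova(values: np.ndarray):
    """Balanced two-factor ANOVA without interaction (rows x columns).

    Returns (F_row, p_row, F_col, p_col, mse, df_error) for a matrix of
    observations with one row per level of factor A and one column per level
    of factor B.
    """
    a, b = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_a = b * float(np.sum((row_means - grand) ** 2))
    ss_b = a * float(np.sum((col_means - grand) ** 2))
    resid = values - row_means[:, None] - col_means[None, :] + grand
    ss_e = float(np.sum(resid ** 2))
    df_a, df_b, df_e = a - 1, b - 1, (a - 1) * (b - 1)
    ms_a = ss_a / df_a if df_a else np.nan
    ms_b = ss_b / df_b if df_b else np.nan
    ms_e = ss_e / df_e if df_e else np.nan
    # sums of squares that are pure rounding error count as exact zeros
    floor = 1e-12 * float(np.mean(values ** 2)) + 1e-300
    ms_a = 0.0 if ms_a < floor else ms_a
    ms_b = 0.0 if ms_b < floor else ms_b
    ms_e = 0.0 if ms_e < floor else ms_e

    def _f_p(ms_f, df_f):
        if ms_e > 0:
            f = ms_f / ms_e
            return f, float(stats.f.sf(f, df_f, df_e))
        # zero error variance: any factor effect is infinitely significant
        return (np.inf, 0.0) if ms_f > 0 else (0.0, 1.0)

    f_a, p_a = _f_p(ms_a, df_a)
    f_b, p_b = _f_p(ms_b, df_b)
    return f_a, p_a, f_b, p_b, ms_e, df_e, resid


def anova_lsd(metrics: pd.DataFrame, alpha: float = 0.05,
              validity: dict[str, bool] | None = None) -> RankingTable:
    """Two-factor ANOVA (model x iteration) with Fisher LSD letter groups.

    ``metrics`` is the long-format validation metric table with columns
    ``model, iteration, mre_pct, r2adj_pct``; the design must be balanced.
    Rank order follows ascending mean MRE; ties in letters are broken by
    mean MRE.
    """
    required = {"model", "iteration", "mre_pct", "r2adj_pct"}
    missing = required - set(metrics.columns)
    if missing:
        raise SchemaError(f"metrics table missing columns: {sorted(missing)}")
    model_names = list(pd.unique(metrics["model"]))
    if len(model_names) < 2:
        raise SchemaError("ranking needs at least two models")
    counts = metrics.groupby(["model", "iteration"]).size()
    if counts.nunique() != 1 or counts.iloc[0] != 1:
        raise SchemaError("unbalanced model x iteration design")
    n_models = len(model_names)
    iters = sorted(pd.unique(metrics["iteration"]))
    if metrics.groupby("model")["iteration"].nunique().nunique() != 1:
        raise SchemaError("models observed on differing iteration sets")

    pivoted = {
        metric: metrics.pivot(index="model", columns="iteration", values=metric)
        .loc[model_names, iters].to_numpy(dtype=float)
        for metric in ("mre_pct", "r2adj_pct")
    }
    rows = {name: {} for name in model_names}
    anova_report, lsd_report = {}, {}
    n_rep = len(iters)
    tcrit = None
    for metric, values in pivoted.items():
        f_m, p_m, f_i, p_i, mse, df_e, _ = _two_way_anova(values)
        anova_report[metric] = {
            "model_F": f_m, "model_p": p_m,
            "iteration_F": f_i, "iteration_p": p_i,
            "mse": mse, "df_error": df_e,
        }
        tcrit = stats.t.ppf(1 - alpha / 2, df_e)
        lsd = float(tcrit * np.sqrt(2.0 * mse / n_rep))
        lsd_report[metric] = lsd
        means = values.mean(axis=1)
        ses = values.std(axis=1, ddof=1) / np.sqrt(n_rep)
        significant = np.abs(means[:, None] - means[None, :]) > lsd
        np.fill_diagonal(significant, False)
        ascending = metric == "mre_pct"  # best = smallest MRE, largest R2adj
        order = np.argsort(means if ascending else -means, kind="mergesort")
        letters = compact_letters(means, significant, order)
        for i, name in enumerate(model_names):
            rows[name][f"{metric}_mean"] = float(means[i])
            rows[name][f"{metric}_se"] = float(ses[i])
            rows[name][f"{metric}_letter"] = letters[i]

    table = pd.DataFrame([
        {"model": name, **rows[name],
         "residuals_valid": bool(validity.get(name, True)) if validity else True}
        for name in model_names
    ])
    table = table.sort_values("mre_pct_mean", kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return RankingTable(table=table, anova=anova_report, lsd=lsd_report, alpha=alpha)


def anova_residual_checks(resid: np.ndarray, alpha: float = 0.05,
                          factors: pd.DataFrame | None = None) -> dict:
    """Normality, independence and heteroscedasticity screens on ANOVA residuals.

    Shapiro-Wilk on the residuals, Ljung-Box on their sequence, and an OLS
    regression of the squared residuals on the design factors (overall F) as
    the heteroscedasticity screen.
    """
    resid = np.asarray(resid, dtype=float).ravel()
    if len(resid) < 3:
        raise DegenerateInputError("Shapiro-Wilk needs at least 3 residuals")
    sw_p = float(stats.shapiro(resid).pvalue)
    lb_p = ljung_box(resid)
    report = {
        "shapiro_p": sw_p, "normal_ok": sw_p > alpha,
        "ljung_box_p": lb_p, "independent_ok": lb_p > alpha,
    }
    if factors is not None:
        sq = resid ** 2
        design = [np.ones_like(sq)]
        for col in factors.columns:
            vals = factors[col]
            if vals.dtype.kind in "if":
                design.append(vals.to_numpy(float))
            else:
                levels = pd.unique(vals)
                for lev in levels[1:]:
                    design.append((vals == lev).to_numpy(float))
        x = np.column_stack(design)
        n, p = x.shape
        beta, *_ = np.linalg.lstsq(x, sq, rcond=None)
        fitted = x @ beta
        ss_res = float(np.sum((sq - fitted) ** 2))
        ss_tot = float(np.sum((sq - sq.mean()) ** 2))
        df1, df2 = p - 1, n - p
        if ss_tot > 0 and df1 > 0 and df2 > 0 and ss_res > 0:
            f_stat = ((ss_tot - ss_res) / df1) / (ss_res / df2)
            mlr_p = float(stats.f.sf(f_stat, df1, df2))
        else:
            f_stat, mlr_p = np.nan, 1.0
        report.update(mlr_F=f_stat, mlr_p=mlr_p, homoscedastic_ok=mlr_p > alpha)
    return report


def _conventional_spec(name: str):
    return get_spec(name, uses_dummies=True)


def _score(y, pred, m, config):
    out = {"mre_pct": mre(y, pred)}
    r2, adj = r2_adj(y, pred, m, denominator=config.r2_denominator)
    out["r2_pct"] = r2
    out["r2adj_pct"] = adj
    return out


def run_pipeline(dataset: IsothermDataset, models: list[str],
                 plan: SplitPlan, config: EvalConfig | None = None) -> dict:
    """Fit, score, screen and rank a list of models on one dataset.

    ``models`` may mix conventional names (GAB, Oswin, ...) and ML names
    (RT, RF, KNN, SVM); duplicates get ``#2``-style labels.  Per iteration,
    every model is (re)fit on the training subset and scored on both
    subsets.  Full-training-set residuals feed the Ljung-Box and Levene
    screens; validation metrics feed the ANOVA/LSD ranking.  Models whose
    fits fail in more than ``unstable_threshold`` of iterations are flagged
    unstable instead of aborting the run.

    Returns a dict with keys ``ranking`` (RankingTable), ``metrics``
    (long-format DataFrame), ``fits``, ``diagnostics``, ``unstable``.
    """
    config = config or EvalConfig()
    labels = []
    seen: dict[str, int] = {}
    for name in models:
        if name not in MODEL_NAMES and name not in ML_NAMES:
            raise SchemaError(
                f"unknown model {name!r}; valid: {', '.join(MODEL_NAMES + ML_NAMES)}")
        seen[name] = seen.get(name, 0) + 1
        labels.append(name if seen[name] == 1 else f"{name}#{seen[name]}")

    df = canonical_order(dataset.frame)
    ordered = IsothermDataset(df, provenance=dataset.provenance,
                              truth=dataset.truth, seed=dataset.seed)

    fits: dict[str, object] = {}
    diagnostics: dict[str, dict] = {}
    full_params: dict[str, object] = {}
    for label, name in zip(labels, models):
        if name in ML_NAMES:
            reg = train_ml(name, ordered, config.ml_config)
            resid = df["xe"].to_numpy(float) - reg.predict(df)
            fits[label] = reg
        else:
            spec = _conventional_spec(name)
            fit = fit_global(spec, ordered, strategy=config.fit_strategy)
            resid = fit.residuals
            fits[label] = fit
            full_params[label] = fit.params
        if config.levene_grouping == "temperature":
            groups = df["temperature_c"].to_numpy()
        else:
            groups = aw_tercile_groups(df["aw"].to_numpy(float))
        try:
            # exact (noise-free) fits give constant-zero residuals: nothing
            # to screen, so the model passes by construction
            lb_p = ljung_box(resid, lags=config.lb_lags)
            lv_p = levene(resid, groups)
        except DegenerateInputError:
            lb_p = lv_p = float("nan")
        random_ok = not (lb_p <= config.alpha)
        homosc_ok = not (lv_p <= config.alpha)
        diagnostics[label] = {
            "ljung_box_p": lb_p, "levene_p": lv_p,
            "random_ok": random_ok,
            "homoscedastic_ok": homosc_ok,
            "valid": random_ok and homosc_ok,
        }

    records = []
    failures = {label: 0 for label in labels}
    for it, (train_idx, val_idx) in enumerate(plan):
        train = ordered.subset(ordered.frame.index.isin(train_idx))
        val = ordered.subset(ordered.frame.index.isin(val_idx))
        y_tr = train.frame["xe"].to_numpy(float)
        y_va = val.frame["xe"].to_numpy(float)
        for label, name in zip(labels, models):
            try:
                if name in ML_NAMES:
                    ml_cfg = MLConfig(**{**config.ml_config.__dict__,
                                         "seed": config.ml_config.seed + it})
                    reg = train_ml(name, train, ml_cfg)
                    pred_tr, pred_va = reg.predict(train.frame), reg.predict(val.frame)
                    m = 1
                else:
                    spec = _conventional_spec(name)
                    fit = fit_global(spec, train, strategy=config.fit_strategy,
                                     init=full_params.get(label))
                    if not fit.converged:
                        raise RuntimeError(f"fit did not converge: {fit.message}")
                    aw_t, t_t = train.frame["aw"].to_numpy(float), train.frame["temperature_c"].to_numpy(float)
                    aw_v, t_v = val.frame["aw"].to_numpy(float), val.frame["temperature_c"].to_numpy(float)
                    pred_tr = evaluate_model(spec, fit.params, aw_t, temperature_c=t_t,
                                             d1=train.d1(), d2=train.d2())
                    pred_va = evaluate_model(spec, fit.params, aw_v, temperature_c=t_v,
                                             d1=val.d1(), d2=val.d2())
                    m = spec.n_params
            except Exception:
                failures[label] += 1
                continue
            for subset_name, y, pred in (("train", y_tr, pred_tr),
                                         ("validation", y_va, pred_va)):
                records.append({
                    "model": label, "iteration": it, "subset": subset_name,
                    **_score(y, pred, m, config), "n": len(y), "m": m,
                })

    metrics = pd.DataFrame(records)
    unstable = {label: failures[label] / plan.n_iterations > config.unstable_threshold
                for label in labels}
    # keep the ANOVA balanced: use iterations where every model produced metrics
    val_metrics = metrics[metrics["subset"] == "validation"]
    ok_iters = [
        it for it, grp in val_metrics.groupby("iteration")
        if set(grp["model"]) == set(labels)
    ]
    val_metrics = val_metrics[val_metrics["iteration"].isin(ok_iters)]
    if len(ok_iters) < 2 or len(labels) < 2:
        raise UnidentifiableError(
            "not enough complete iterations (or models) for the ANOVA ranking")
    validity = {label: diagnostics[label]["valid"] for label in labels}
    ranking = anova_lsd(val_metrics, alpha=config.alpha, validity=validity)
    ranking.table["unstable"] = ranking.table["model"].map(unstable)
    return {
        "ranking": ranking,
        "metrics": metrics,
        "fits": fits,
        "diagnostics": diagnostics,
        "unstable": unstable,
    }
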