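"""Synthetic dynamic-dewpoint-style sorption datasets with known ground truth.

The generator mimics the measurement protocol of a dynamic dewpoint
instrument: a desorption sweep from aw 0.60 down to 0.10 and an adsorption
sweep from 0.60 up to 0.85, on a 0.01 aw grid, at several temperatures, for
two postharvest methods, in replicates.  Ground truth is any registered
isotherm model; additive or proportional Gaussian noise stands in for
instrument scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import (
    BoundsError,
    InvalidProtocolError,
    InvalidTruthError,
    SchemaError,
)
from .models import ModelSpec, ParameterVector, evaluate_model, gab_k_of_t

__all__ = [
    "METHODS",
    "BRANCHES",
    "DESORPTION_RANGE",
    "ADSORPTION_RANGE",
    "DEFAULT_TEMPERATURES",
    "DEFAULT_NOISE_SD",
    "NoiseModel",
    "Design",
    "IsothermDataset",
    "ddi_grid",
    "generate_isotherm",
    "make_crossing_scenario",
    "default_truth",
    "sigmoid_truth",
]

METHODS = ("wet", "semidry")
BRANCHES = ("desorption", "adsorption")
DESORPTION_RANGE = (0.60, 0.10)  # start, end (descending sweep)
ADSORPTION_RANGE = (0.60, 0.85)  # start, end (ascending sweep)
DEFAULT_TEMPERATURES = (25.0, 35.0, 45.0)

#: Stand-in for instrument scatter; not a measured quantity.  Configurable.
DEFAULT_NOISE_SD = 0.002

COLUMNS = ("aw", "temperature_c", "method", "branch", "replicate", "xe")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for synthetic datasets."""

    kind: str = "gaussian-additive"  # none | gaussian-additive | gaussian-proportional
    sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "gaussian-additive", "gaussian-proportional"):
            raise SchemaError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise SchemaError("noise sd must be >= 0")

    def apply(self, xe: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return xe
        eps = rng.normal(0.0, self.sd, size=xe.shape)
        if self.kind == "gaussian-additive":
            return xe + eps
        return xe * (1.0 + eps)


@dataclass(frozen=True)
class Design:
    """Factorial measurement design: temperatures x methods x branches x replicates."""

    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    methods: tuple[str, ...] = METHODS
    branches: tuple[str, ...] = BRANCHES
    replicates: int = 1
    step: float = 0.01

    def __post_init__(self):
        if not self.temperatures or not self.methods or not self.branches:
            raise SchemaError("design must be nonempty")
        for m in self.methods:
            if m not in METHODS:
                raise SchemaError(f"unknown method {m!r}; valid: {METHODS}")
        for b in self.branches:
            if b not in BRANCHES:
                raise SchemaError(f"unknown branch {b!r}; valid: {BRANCHES}")
        if self.replicates < 1:
            raise SchemaError("replicates must be >= 1")


@dataclass
class IsothermDataset:
    """An ordered collection of sorption measurements plus provenance.

    The canonical container is a pandas DataFrame with columns
    ``aw, temperature_c, method, branch, replicate, xe``.  Synthetic datasets
    always carry their ground truth (model spec, parameters, noise) and seed.
    """

    frame: pd.DataFrame
    provenance: str = "synthetic"  # synthetic | measured
    truth: dict | None = None
    seed: int | None = None

    def __post_init__(self):
        df = self.frame
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"dataset missing columns: {missing}")
        self.frame = df = df.reset_index(drop=True)
        if np.any(df["aw"] <= 0) or np.any(df["aw"] >= 1):
            raise SchemaError("aw values must lie strictly inside (0, 1)")
        if np.any(df["xe"] < 0):
            raise SchemaError("xe values must be non-negative")
        bad_method = set(df["method"]) - set(METHODS)
        if bad_method:
            raise SchemaError(f"unknown method labels: {sorted(bad_method)}")
        bad_branch = set(df["branch"]) - set(BRANCHES)
        if bad_branch:
            raise SchemaError(f"unknown branch labels: {sorted(bad_branch)}")
        key = ["aw", "temperature_c", "method", "branch", "replicate"]
        if df.duplicated(subset=key).any():
            raise SchemaError("duplicate (aw, temperature_c, method, branch, replicate) keys")
        if self.provenance == "synthetic" and (self.truth is None or self.seed is None):
            raise SchemaError("synthetic datasets must carry truth and seed")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> pd.DataFrame:
        return self.frame

    def d1(self) -> np.ndarray:
        """Indicator for the semidry postharvest method."""
        return (self.frame["method"].to_numpy() == "semidry").astype(float)

    def d2(self) -> np.ndarray:
        """Indicator for the adsorption branch."""
        return (self.frame["branch"].to_numpy() == "adsorption").astype(float)

    def subset(self, mask) -> "IsothermDataset":
        return IsothermDataset(
            self.frame.loc[mask].reset_index(drop=True),
            provenance=self.provenance, truth=self.truth, seed=self.seed,
        )


def ddi_grid(branch: str, step: float = 0.01) -> np.ndarray:
    """Water-activity grid of a dynamic-dewpoint sweep.

    Desorption sweeps 0.60 down to 0.10; adsorption sweeps 0.60 up to 0.85,
    both endpoints inclusive when ``step`` divides the range.
    """
    if branch not in BRANCHES:
        raise InvalidProtocolError(f"unknown branch {branch!r}; valid: {BRANCHES}")
    if not step > 0:
        raise InvalidProtocolError("step must be positive")
    start, end = DESORPTION_RANGE if branch == "desorption" else ADSORPTION_RANGE
    span = abs(end - start)
    if step > span + 1e-12:
        raise InvalidProtocolError(
            f"step {step} exceeds the {branch} range of {span:.2f} aw"
        )
    n = int(np.floor(span / step + 1e-9)) + 1
    sign = -1.0 if branch == "desorption" else 1.0
    grid = start + sign * step * np.arange(n)
    return np.round(grid, 10)


def generate_isotherm(truth_spec: ModelSpec, truth_params: ParameterVector,
                      design: Design | None = None,
                      noise: NoiseModel | None = None) -> IsothermDataset:
    """Generate a full factorial DDI-style dataset from a known truth.

    One record per grid point x design cell x replicate;
    ``xe = evaluate_model(...) + noise``.  Regeneration with the same seed is
    bit-identical.
    """
    design = design or Design()
    noise = noise or NoiseModel(kind="none", sd=0.0, seed=0)
    rng = np.random.default_rng(noise.seed)
    rows = []
    for method in design.methods:
        for branch in design.branches:
            grid = ddi_grid(branch, design.step)
            d1 = float(method == "semidry")
            d2 = float(branch == "adsorption")
            for temp in design.temperatures:
                try:
                    clean = evaluate_model(truth_spec, truth_params, grid,
                                           temperature_c=temp, d1=d1, d2=d2)
                except Exception as exc:
                    raise InvalidTruthError(
                        f"truth evaluation failed for {truth_spec.name} at "
                        f"T={temp}, method={method}, branch={branch}: {exc}"
                    ) from exc
                clean = np.asarray(clean, dtype=float)
                if np.any(clean < 0) or not np.all(np.isfinite(clean)):
                    raise InvalidTruthError(
                        f"truth produces negative or non-finite xe at T={temp}, "
                        f"method={method}, branch={branch}"
                    )
                for rep in range(1, design.replicates + 1):
                    xe = noise.apply(clean, rng)
                    rows.append(pd.DataFrame({
                        "aw": grid,
                        "temperature_c": temp,
                        "method": method,
                        "branch": branch,
                        "replicate": rep,
                        "xe": xe,
                    }))
    frame = pd.concat(rows, ignore_index=True)
    truth = {
        "model": truth_spec.name,
        "temp_mode": truth_spec.temp_mode,
        "uses_dummies": truth_spec.uses_dummies,
        "dlp_reduced": truth_spec.dlp_reduced,
        "lambda_": truth_spec.lambda_,
        "r_w": truth_spec.r_w,
        "params": dict(truth_params.values),
        "noise": {"kind": noise.kind, "sd": noise.sd, "seed": noise.seed},
    }
    return IsothermDataset(frame, provenance="synthetic", truth=truth, seed=noise.seed)


def default_truth(b1: float = -0.016, b2: float = 0.002,
                  lambda_: float = 2406.0) -> tuple[ModelSpec, ParameterVector]:
    """A plausible GAB global (Arrhenius + dummies) ground truth.

    Magnitudes chosen to give a type-II sigmoid in the 0.10-0.35 decimal
    dry-basis range, equilibrium moisture decreasing with temperature, a
    negative semidry offset and a small positive adsorption offset.
    """
    spec = ModelSpec("GAB", temp_mode="arrhenius", uses_dummies=True, lambda_=lambda_)
    params = ParameterVector({
        "Xm": 0.102,
        "C0": 1.4e-8,
        "K0": 10.5,
        "Hm": 6099.0,
        "Hn": 2895.0,
        "b1": b1,
        "b2": b2,
    })
    return spec, params


def sigmoid_truth(b1: float = -0.016, b2: float = 0.002,
                  lambda_: float = 2406.0) -> tuple[ModelSpec, ParameterVector]:
    """A well-conditioned GAB global truth with a pronounced type-II sigmoid.

    Moderate energy constant (C about 20 at 35 degC) and a high multilayer
    factor (K about 0.75) give xe spanning roughly 0.05-0.31 decimal d.b.
    over the DDI range, with every parameter direction well identified --
    the preferred ground truth for estimator calibration studies.
    """
    r_w, t_ref = 0.4615, 308.15
    dh_c, dh_k = 1000.0, -300.0
    c0 = 20.0 / np.exp(dh_c / (r_w * t_ref))
    k0 = 0.75 / np.exp(dh_k / (r_w * t_ref))
    hn = lambda_ - dh_k
    spec = ModelSpec("GAB", temp_mode="arrhenius", uses_dummies=True, lambda_=lambda_)
    params = ParameterVector({"Xm": 0.102, "C0": c0, "K0": k0,
                              "Hm": hn + dh_c, "Hn": hn, "b1": b1, "b2": b2})
    return spec, params


def make_crossing_scenario(cross_aw: float,
                           k_ref: float = 0.70,
                           xm: float = 0.102,
                           dh_c: float = 3204.0,
                           b1: float = -0.016,
                           b2: float = 0.002,
                           lambda_: float = 2406.0,
                           r_w: float = 0.4615) -> tuple[ModelSpec, ParameterVector]:
    """Construct a GAB ground truth whose 25/45 degC adsorption curves cross.

    The crossing mechanism: C decreases with temperature (depressing xe at
    low aw) while K increases with temperature (raising xe at high aw where
    ``K*aw`` approaches 1).  The K-law enthalpy gap is tuned numerically so
    that the two curves intersect at ``cross_aw``; construction verifies the
    intersection lies within +/-0.05 of the request.

    Returns a (spec, params) pair intended as a semidry ground truth.
    """
    lo, hi = ADSORPTION_RANGE
    if not (0.6 < cross_aw < 0.85):
        raise InvalidProtocolError(
            f"cross_aw must lie inside the adsorption range ({0.6}, {0.85}); got {cross_aw}"
        )
    t_lo, t_hi = 25.0, 45.0
    t_ref_k = 35.0 + 273.15

    def build(dh_k: float) -> tuple[ModelSpec, ParameterVector]:
        # anchor C and K at the 35 degC midpoint, then solve back C0/K0
        hn = lambda_ - dh_k
        hm = hn + dh_c
        c_ref = 60.0
        c0 = c_ref / np.exp(dh_c / (r_w * t_ref_k))
        k0 = k_ref / np.exp(dh_k / (r_w * t_ref_k))
        spec = ModelSpec("GAB", temp_mode="arrhenius", uses_dummies=True,
                         lambda_=lambda_, r_w=r_w)
        params = ParameterVector({"Xm": xm, "C0": c0, "K0": k0,
                                  "Hm": hm, "Hn": hn, "b1": b1, "b2": b2})
        return spec, params

    def diff_at(dh_k: float, aw: float) -> float:
        spec, params = build(dh_k)
        hi_v = evaluate_model(spec, params, aw, temperature_c=t_hi, d1=1, d2=1)
        lo_v = evaluate_model(spec, params, aw, temperature_c=t_lo, d1=1, d2=1)
        return hi_v - lo_v

    # dh_k < 0 makes K grow with temperature; bound so K(45degC)*0.85 stays < 1
    dh_min = -2000.0
    while True:
        spec, params = build(dh_min)
        if gab_k_of_t(params["K0"], lambda_, params["Hn"], r_w, t_hi) * hi < 0.995:
            break
        dh_min *= 0.7
        if dh_min > -10.0:
            raise BoundsError("could not bound the crossing search")
    f_lo, f_hi = diff_at(dh_min, cross_aw), diff_at(-1e-6, cross_aw)
    if f_lo * f_hi > 0:
        raise BoundsError(
            f"no crossing achievable at aw={cross_aw} with the given shape settings"
        )
    dh_star = brentq(lambda d: diff_at(d, cross_aw), dh_min, -1e-6, xtol=1e-10)
    spec, params = build(dh_star)

    # verify numerically: sign change of the curve difference within +/-0.05
    grid = ddi_grid("adsorption")
    window = grid[(grid >= cross_aw - 0.05) & (grid <= cross_aw + 0.05)]
    diffs = np.array([diff_at(dh_star, a) for a in window])
    if not np.any(np.sign(diffs[:-1]) != np.sign(diffs[1:])):
        raise InvalidTruthError(
            f"constructed scenario does not cross within +/-0.05 of aw={cross_aw}"
        )
    return spec, params
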