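"""Closed-form water sorption isotherm models.

Twelve conventional equations relating equilibrium moisture content ``xe``
(decimal dry basis, kg water per kg dry solid) to water activity ``aw``, with
three temperature parameterizations:

``fixed``
    Raw coefficients, valid at a single temperature.
``linear``
    Every empirical coefficient depends linearly on absolute temperature,
    ``a_i = a_i_1 * T_K + a_i_2`` (empirical models only).
``arrhenius``
    GAB only: the energy constant ``C`` and multilayer factor ``K`` follow
    exponential (Arrhenius-type) temperature laws driven by sorption
    enthalpies.

Two optional dummy covariates enter additively: ``d1`` encodes the
postharvest method contrast (0 = wet reference, 1 = semidry) and ``d2`` the
sorption branch (0 = desorption reference, 1 = adsorption), with regression
coefficients ``b1`` and ``b2``.

All temperature-dependent expressions use Kelvin internally.  The gas
constant is the water-specific value ``R_WATER`` because the sorption
enthalpies are expressed per kg of water, and the latent heat of
vaporization defaults to its value near 35 degC; both are configurable on
:class:`ModelSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EvaluationDomainError, InvalidParameterError

__all__ = [
    "MODEL_NAMES",
    "R_WATER",
    "LAMBDA_DEFAULT",
    "ModelSpec",
    "ParameterVector",
    "evaluate_model",
    "gab_c_of_t",
    "gab_k_of_t",
    "linear_param",
    "celsius_to_kelvin",
    "get_spec",
]

#: Water-specific gas constant, kJ kg^-1 K^-1 (8.314 J mol^-1 K^-1 / 18.015 g mol^-1).
R_WATER = 0.4615

#: Latent heat of water vaporization near 35 degC, kJ kg^-1.
LAMBDA_DEFAULT = 2406.0

_KELVIN_OFFSET = 273.15

# Base (fixed-temperature) coefficient names per model.
_BASE_COEFFS: dict[str, tuple[str, ...]] = {
    "GAB": ("Xm", "C", "K"),
    "Peleg": ("a0", "a1", "a2", "a3"),
    "Smith": ("a1", "a2"),
    "Kuhn": ("a1", "a2"),
    "DLP": ("a0", "a1", "a2", "a3"),
    "ChungPfost": ("a1", "a2"),
    "Caurie": ("a1", "a2"),
    "IglesiasChirife": ("a1", "a2"),
    "WhiteEiring": ("a1", "a2"),
    "Polynomial": ("a0", "a1", "a2", "a3"),
    "Oswin": ("a1", "a2"),
    "YanniotisBlahovec": ("a0", "a1", "a2", "a3"),
}

MODEL_NAMES: tuple[str, ...] = tuple(_BASE_COEFFS)

_ML_NAMES = ("RT", "RF", "KNN", "SVM")


def celsius_to_kelvin(temperature_c):
    """Convert Celsius to Kelvin (array-aware)."""
    return np.asarray(temperature_c, dtype=float) + _KELVIN_OFFSET


@dataclass
class ParameterVector:
    """Named parameter values with optional 95% confidence bounds."""

    values: dict[str, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def get(self, name: str, default: float = 0.0) -> float:
        return self.values.get(name, default)

    def as_array(self, names) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)

    def copy(self) -> "ParameterVector":
        return ParameterVector(dict(self.values), dict(self.ci))

    def to_dict(self) -> dict:
        out = {"values": dict(self.values)}
        if self.ci:
            out["ci95"] = {k: list(v) for k, v in self.ci.items()}
        return out


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one sorption model: equation, temperature mode, covariates.

    Parameters
    ----------
    name
        One of :data:`MODEL_NAMES`.
    temp_mode
        ``"fixed"``, ``"linear"`` (empirical models) or ``"arrhenius"``
        (GAB only).
    uses_dummies
        Whether the additive ``b1*d1 + b2*d2`` term is part of the model.
    dlp_reduced
        For DLP in linear mode: fix the quadratic coefficient's intercept to
        zero (``a2_2 = 0``), i.e. slope-only temperature dependence for
        ``a2``.  Both behaviors are supported.
    lambda_, r_w
        Physical constants used by the GAB Arrhenius laws; never estimated.
    """

    name: str
    temp_mode: str = "fixed"
    uses_dummies: bool = False
    dlp_reduced: bool = False
    lambda_: float = LAMBDA_DEFAULT
    r_w: float = R_WATER

    def __post_init__(self):
        if self.name not in _BASE_COEFFS:
            raise InvalidParameterError(
                f"unknown model {self.name!r}; valid names: {', '.join(MODEL_NAMES)}"
            )
        if self.temp_mode not in ("fixed", "linear", "arrhenius"):
            raise InvalidParameterError(f"unknown temp_mode {self.temp_mode!r}")
        if self.temp_mode == "arrhenius" and self.name != "GAB":
            raise InvalidParameterError("arrhenius temperature mode is GAB-only")
        if self.temp_mode == "linear" and self.name == "GAB":
            raise InvalidParameterError("GAB uses arrhenius, not linear, temperature mode")
        if self.r_w <= 0:
            raise InvalidParameterError("r_w must be positive")

    @property
    def base_coeffs(self) -> tuple[str, ...]:
        return _BASE_COEFFS[self.name]

    @property
    def param_names(self) -> tuple[str, ...]:
        names: list[str] = []
        if self.temp_mode == "fixed":
            names.extend(self.base_coeffs)
        elif self.temp_mode == "arrhenius":
            names.extend(("Xm", "C0", "K0", "Hm", "Hn"))
        else:  # linear
            for a in self.base_coeffs:
                names.append(f"{a}_1")
                if not (self.dlp_reduced and self.name == "DLP" and a == "a2"):
                    names.append(f"{a}_2")
        if self.uses_dummies:
            names.extend(("b1", "b2"))
        return tuple(names)

    @property
    def n_params(self) -> int:
        """Number of free parameters M (for adjusted R^2)."""
        return len(self.param_names)


def get_spec(name: str, temp_mode: str | None = None, uses_dummies: bool = False,
             **kwargs) -> ModelSpec:
    """Registry lookup: build the conventional ModelSpec for a model name.

    With ``temp_mode=None`` the global mode is chosen: arrhenius for GAB,
    linear otherwise.
    """
    if temp_mode is None:
        temp_mode = "arrhenius" if name == "GAB" else "linear"
    return ModelSpec(name=name, temp_mode=temp_mode, uses_dummies=uses_dummies, **kwargs)


def gab_c_of_t(c0, hm, hn, r_w, temperature_c):
    """GAB energy constant C at a given temperature (Arrhenius form)."""
    if np.any(np.asarray(c0) <= 0):
        raise InvalidParameterError("C0 must be positive")
    t_k = celsius_to_kelvin(temperature_c)
    return c0 * np.exp((hm - hn) / (r_w * t_k))


def gab_k_of_t(k0, lambda_, hn, r_w, temperature_c):
    """GAB multilayer factor K at a given temperature (Arrhenius form)."""
    if np.any(np.asarray(k0) <= 0):
        raise InvalidParameterError("K0 must be positive")
    t_k = celsius_to_kelvin(temperature_c)
    return k0 * np.exp((lambda_ - hn) / (r_w * t_k))


def linear_param(a_i1, a_i2, temperature_c):
    """Empirical coefficient with linear absolute-temperature dependence."""
    return a_i1 * celsius_to_kelvin(temperature_c) + a_i2


# ---------------------------------------------------------------------------
# Base formulas (fixed-temperature coefficients).  Each returns xe and raises
# EvaluationDomainError on a domain violation -- no silent clamping.

def _gab(aw, c):
    xm, cc, k = c["Xm"], c["C"], c["K"]
    if np.any(cc <= 0):
        raise EvaluationDomainError("GAB requires C > 0")
    kaw = k * aw
    if np.any(kaw >= 1.0) or np.any(kaw <= 0.0):
        raise EvaluationDomainError("GAB requires 0 < K*aw < 1")
    denom = (1.0 - kaw) * (1.0 + (cc - 1.0) * kaw)
    if np.any(denom <= 0):
        raise EvaluationDomainError("GAB denominator not positive")
    return xm * cc * kaw / denom

def _peleg(aw, c):
    return c["a0"] * aw ** c["a1"] + c["a2"] * aw ** c["a3"]

def _smith(aw, c):
    return c["a1"] - c["a2"] * np.log(1.0 - aw)

def _kuhn(aw, c):
    return c["a1"] / np.log(aw) + c["a2"]

def _dlp_x(aw):
    return np.log(-np.log(aw))

def _dlp(aw, c):
    x = _dlp_x(aw)
    return c["a0"] + c["a1"] * x + c["a2"] * x ** 2 + c["a3"] * x ** 3

def _chung_pfost(aw, c):
    return c["a1"] - c["a2"] * np.log(-np.log(aw))

def _caurie(aw, c):
    return np.exp(c["a1"] + c["a2"] * aw)

def _iglesias_chirife(aw, c):
    return c["a1"] + c["a2"] * (aw / (1.0 - aw))

def _white_eiring(aw, c):
    denom = c["a1"] + c["a2"] * aw
    if np.any(denom <= 0):
        raise EvaluationDomainError("WhiteEiring requires a1 + a2*aw > 0")
    return 1.0 / denom

def _polynomial(aw, c):
    return c["a0"] + c["a1"] * aw + c["a2"] * aw ** 2 + c["a3"] * aw ** 3

def _oswin(aw, c):
    return c["a1"] * (aw / (1.0 - aw)) ** c["a2"]

def _yanniotis_blahovec(aw, c):
    d1 = c["a0"] + c["a1"] * aw
    d2 = c["a2"] + c["a3"] * aw
    if np.any(d1 == 0) or np.any(d2 == 0):
        raise EvaluationDomainError("YanniotisBlahovec denominator is zero")
    return aw / d1 + aw / d2


_FORMULAS = {
    "GAB": _gab,
    "Peleg": _peleg,
    "Smith": _smith,
    "Kuhn": _kuhn,
    "DLP": _dlp,
    "ChungPfost": _chung_pfost,
    "Caurie": _caurie,
    "IglesiasChirife": _iglesias_chirife,
    "WhiteEiring": _white_eiring,
    "Polynomial": _polynomial,
    "Oswin": _oswin,
    "YanniotisBlahovec": _yanniotis_blahovec,
}


def _resolve_coeffs(spec: ModelSpec, params: ParameterVector, temperature_c):
    """Collapse the temperature parameterization to fixed-T coefficients."""
    if spec.temp_mode == "fixed":
        return {a: params[a] for a in spec.base_coeffs}
    if spec.temp_mode == "arrhenius":
        return {
            "Xm": params["Xm"],
            "C": gab_c_of_t(params["C0"], params["Hm"], params["Hn"], spec.r_w, temperature_c),
            "K": gab_k_of_t(params["K0"], spec.lambda_, params["Hn"], spec.r_w, temperature_c),
        }
    coeffs = {}
    for a in spec.base_coeffs:
        slope = params[f"{a}_1"]
        if spec.dlp_reduced and spec.name == "DLP" and a == "a2":
            intercept = 0.0
        else:
            intercept = params[f"{a}_2"]
        coeffs[a] = linear_param(slope, intercept, temperature_c)
    return coeffs


def evaluate_model(spec: ModelSpec, params: ParameterVector, aw,
                   temperature_c=None, d1=0, d2=0):
    """Evaluate equilibrium moisture content for a model.

    Parameters
    ----------
    aw
        Water activity, scalar or array, strictly inside (0, 1).
    temperature_c
        Required for ``linear``/``arrhenius`` temperature modes.
    d1, d2
        Dummy indicators (method contrast / branch contrast); only used when
        ``spec.uses_dummies``.

    Returns
    -------
    float or ndarray
        ``xe`` in decimal dry basis, with the additive dummy offsets applied.
    """
    aw_arr = np.asarray(aw, dtype=float)
    scalar = aw_arr.ndim == 0 and np.ndim(temperature_c) == 0 and np.ndim(d1) == 0 and np.ndim(d2) == 0
    if np.any(aw_arr <= 0.0) or np.any(aw_arr >= 1.0):
        raise EvaluationDomainError("aw must lie strictly inside (0, 1)")
    if spec.temp_mode != "fixed":
        if temperature_c is None:
            raise EvaluationDomainError(f"temp_mode={spec.temp_mode!r} requires temperature_c")
        temperature_c = np.asarray(temperature_c, dtype=float)

    coeffs = _resolve_coeffs(spec, params, temperature_c)
    xe = _FORMULAS[spec.name](aw_arr, coeffs)
    if spec.uses_dummies:
        xe = xe + params["b1"] * np.asarray(d1, dtype=float) + params["b2"] * np.asarray(d2, dtype=float)
    if not np.all(np.isfinite(xe)):
        raise EvaluationDomainError(f"{spec.name} evaluation produced non-finite values")
    if scalar:
        return float(xe)
    return np.asarray(xe, dtype=float)
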