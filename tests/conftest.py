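"""Shared fixtures and independent reference implementations.

The reference formulas below are deliberately separate, literal
transcriptions of each model equation (scalar math module only); the package
implementation is never imported into them.  They serve as the oracle for
the equation-equivalence checks.
"""

from __future__ import annotations

import math
import zlib

import numpy as np
import pytest

import sorptionlab as sl
from sorptionlab.models import ModelSpec, ParameterVector

# --------------------------------------------------------------------------
# independent scalar transcriptions (oracle)

REFERENCE_FORMULAS = {
    "GAB": lambda aw, p: (p["Xm"] * p["C"] * p["K"] * aw)
    / ((1 - p["K"] * aw) * (1 + (p["C"] - 1) * p["K"] * aw)),
    "Peleg": lambda aw, p: p["a0"] * aw ** p["a1"] + p["a2"] * aw ** p["a3"],
    "Smith": lambda aw, p: p["a1"] - p["a2"] * math.log(1 - aw),
    "Kuhn": lambda aw, p: p["a1"] / math.log(aw) + p["a2"],
    "DLP": lambda aw, p: p["a0"]
    + p["a1"] * math.log(-math.log(aw))
    + p["a2"] * math.log(-math.log(aw)) ** 2
    + p["a3"] * math.log(-math.log(aw)) ** 3,
    "ChungPfost": lambda aw, p: p["a1"] - p["a2"] * math.log(-math.log(aw)),
    "Caurie": lambda aw, p: math.exp(p["a1"] + p["a2"] * aw),
    "IglesiasChirife": lambda aw, p: p["a1"] + p["a2"] * (aw / (1 - aw)),
    "WhiteEiring": lambda aw, p: 1.0 / (p["a1"] + p["a2"] * aw),
    "Polynomial": lambda aw, p: p["a0"] + p["a1"] * aw + p["a2"] * aw ** 2
    + p["a3"] * aw ** 3,
    "Oswin": lambda aw, p: p["a1"] * (aw / (1 - aw)) ** p["a2"],
    "YanniotisBlahovec": lambda aw, p: aw / (p["a0"] + p["a1"] * aw)
    + aw / (p["a2"] + p["a3"] * aw),
}


def random_valid_params(name: str, rng: np.random.Generator) -> dict:
    """Draw fixed-temperature coefficients inside each model's valid domain."""
    if name == "GAB":
        return {"Xm": rng.uniform(0.02, 0.3), "C": rng.uniform(1.5, 80),
                "K": rng.uniform(0.1, 0.95)}
    if name == "Peleg":
        return {"a0": rng.uniform(0.05, 0.5), "a1": rng.uniform(0.2, 3.0),
                "a2": rng.uniform(0.05, 0.5), "a3": rng.uniform(3.5, 12.0)}
    if name == "Kuhn":
        return {"a1": rng.uniform(-0.2, -0.01), "a2": rng.uniform(0.01, 0.3)}
    if name == "Caurie":
        return {"a1": rng.uniform(-4, -1), "a2": rng.uniform(0.5, 3)}
    if name == "WhiteEiring":
        # keep a1 + a2*aw > 0 on (0, 1)
        return {"a1": rng.uniform(3, 12), "a2": rng.uniform(-2.5, 4)}
    if name == "Oswin":
        return {"a1": rng.uniform(0.05, 0.4), "a2": rng.uniform(0.1, 1.2)}
    if name == "YanniotisBlahovec":
        # both denominators positive on (0, 1)
        return {"a0": rng.uniform(0.5, 4), "a1": rng.uniform(0.1, 3),
                "a2": rng.uniform(0.5, 4), "a3": rng.uniform(0.1, 3)}
    if name in ("Smith", "ChungPfost", "IglesiasChirife"):
        return {"a1": rng.uniform(0.01, 0.4), "a2": rng.uniform(0.01, 0.3)}
    if name in ("DLP", "Polynomial"):
        return {"a0": rng.uniform(-0.3, 0.5), "a1": rng.uniform(-0.2, 0.2),
                "a2": rng.uniform(-0.1, 0.1), "a3": rng.uniform(-0.05, 0.05)}
    raise KeyError(name)


def stable_seed(name: str) -> int:
    """Deterministic per-name seed (builtin hash() is process-randomized)."""
    return zlib.crc32(name.encode())


#: One fixed, plausible truth per model guaranteed to give xe > 0 on the
#: DDI desorption grid (used by the self-recovery smoke suite).
RECOVERY_TRUTHS = {
    "GAB": {"Xm": 0.102, "C": 15.0, "K": 0.75},
    "Peleg": {"a0": 0.3, "a1": 0.6, "a2": 0.4, "a3": 6.0},
    "Smith": {"a1": 0.05, "a2": 0.12},
    "Kuhn": {"a1": -0.08, "a2": 0.05},
    "DLP": {"a0": 0.15, "a1": -0.07, "a2": 0.02, "a3": -0.005},
    "ChungPfost": {"a1": 0.12, "a2": 0.05},
    "Caurie": {"a1": -2.5, "a2": 1.8},
    "IglesiasChirife": {"a1": 0.06, "a2": 0.1},
    "WhiteEiring": {"a1": 8.0, "a2": -4.0},
    "Polynomial": {"a0": 0.05, "a1": 0.3, "a2": -0.2, "a3": 0.25},
    "Oswin": {"a1": 0.15, "a2": 0.45},
    "YanniotisBlahovec": {"a0": 2.0, "a1": 1.5, "a2": 3.0, "a3": 0.8},
}


# --------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def gab_fixed():
    spec = ModelSpec("GAB", temp_mode="fixed")
    params = ParameterVector({"Xm": 0.102, "C": 15.0, "K": 0.75})
    return spec, params


@pytest.fixture(scope="session")
def sigmoid_truth():
    return sl.sigmoid_truth()


@pytest.fixture(scope="session")
def clean_dataset(sigmoid_truth):
    """Noise-free full factorial DDI dataset (462 records)."""
    spec, params = sigmoid_truth
    return sl.generate_isotherm(spec, params)


@pytest.fixture(scope="session")
def noisy_dataset(sigmoid_truth):
    spec, params = sigmoid_truth
    noise = sl.NoiseModel(kind="gaussian-additive", sd=0.002, seed=42)
    return sl.generate_isotherm(spec, params, noise=noise)
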