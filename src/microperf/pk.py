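"""Pharmacokinetics of the antibody-drug conjugate (T-DM1).

Holds the kinetic constants, the exponential plasma-decay model, the
six-timescale analysis that justifies the quasi-steady-state model
reduction, and the resulting effective uptake rate.

The six physical processes and their characteristic timescales are

* diffusion            t_diff = h_l^2 / D             (h_l inter-vessel distance)
* extravasation        t_ev   = h_l^2 / (pi d_l P)
* plasma depletion     t_pd   = 1 / b
* receptor binding     t_on   = eps / (k_on C_r)
* unbinding            t_off  = 1 / k_off
* internalisation      t_int  = 1 / k_int

When the slow transport group ``min{t_diff, t_ev, t_pd}`` is well
separated from the fast kinetic group ``max{t_on, t_off, t_int}``, bound
drug tracks free drug quasi-statically and the three-phase model reduces
to a single linear reaction-diffusion equation with effective uptake rate
``k_eff = t_off / (t_on (t_off + t_int))``.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

__all__ = [
    "PKParams",
    "Timescales",
    "load_default_pk",
    "load_parameter_table",
    "plasma_concentration",
    "compute_timescales",
    "effective_uptake_rate",
    "fit_plasma_decay",
]


@dataclass(frozen=True)
class PKParams:
    """Drug transport and kinetic constants (units: um, day, nM)."""

    D: float = 4233.6            # free-drug diffusivity, um^2/day
    P: float = 241.92            # vessel permeability, um/day
    epsilon: float = 0.24        # effective void fraction
    C_r: float = 100.0           # receptor concentration, nM
    k_on: float = 3.125          # 1/(nM day)
    k_off: float = 12787.723785166240   # 1/day
    k_int: float = 75.75757575757576    # 1/day
    C_plasma_initial: float = 810.0     # nM
    b: float = 0.2105            # plasma decay rate, 1/day

    def __post_init__(self):
        for name in ("D", "P", "epsilon", "C_r", "k_on", "k_off", "k_int",
                     "C_plasma_initial", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PKParams.{name} must be positive")


def load_parameter_table() -> Dict[str, Dict[str, dict]]:
    """Raw shipped parameter table (values with unit tags and notes)."""
    text = importlib.resources.files("microperf.data").joinpath(
        "parameters.yaml").read_text()
    return yaml.safe_load(text)


def load_default_pk() -> PKParams:
    tab = load_parameter_table()["drug"]
    return PKParams(
        D=tab["D"]["value"],
        P=tab["P"]["value"],
        epsilon=tab["epsilon"]["value"],
        C_r=tab["C_r"]["value"],
        k_on=tab["k_on"]["value"],
        k_off=tab["k_off"]["value"],
        k_int=tab["k_int"]["value"],
        C_plasma_initial=tab["C_plasma_initial"]["value"],
        b=tab["b"]["value"],
    )


def plasma_concentration(t, pk: PKParams):
    """Plasma drug concentration C0 * exp(-b t) in nM; t in days, >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = pk.C_plasma_initial * np.exp(-pk.b * t)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Timescales:
    """Characteristic timescales in days; ranges as (min, max) tuples."""

    t_diff: Tuple[float, float]
    t_ev: Tuple[float, float]
    t_pd: float
    t_on: float
    t_off: float
    t_int: float
    t_eff: float
    separation_ratio: float     # min(slow) / max(fast)
    qss_valid: bool

    def as_table(self) -> "pd.DataFrame":  # noqa: F821 - optional import
        import pandas as pd

        rows = [
            ("t_diff", self.t_diff[0], self.t_diff[1], "diffusion"),
            ("t_ev", self.t_ev[0], self.t_ev[1], "extravasation"),
            ("t_pd", self.t_pd, self.t_pd, "plasma depletion"),
            ("t_on", self.t_on, self.t_on, "binding"),
            ("t_off", self.t_off, self.t_off, "unbinding"),
            ("t_int", self.t_int, self.t_int, "internalisation"),
            ("t_eff", self.t_eff, self.t_eff, "effective uptake"),
        ]
        return pd.DataFrame(rows, columns=["timescale", "min_day", "max_day", "process"])


def compute_timescales(
    pk: PKParams,
    h_range: Tuple[float, float] = (100.0, 1000.0),
    d_range: Tuple[float, float] = (15.0, 110.0),
    ratio_threshold: float = 10.0,
) -> Timescales:
    """Evaluate the six timescales over the network geometry ranges.

    ``h_range`` is the inter-vessel distance range and ``d_range`` the
    vessel diameter range (both um).  ``qss_valid`` reports whether the
    slow transport group exceeds the fast kinetic group by at least
    ``ratio_threshold``.
    """
    h_lo, h_hi = h_range
    d_lo, d_hi = d_range
    if not (0 < h_lo <= h_hi and 0 < d_lo <= d_hi):
        raise ValueError("ranges must be positive and ordered")
    t_diff = (h_lo ** 2 / pk.D, h_hi ** 2 / pk.D)
    # t_ev = h^2 / (pi d P): minimal at (h_lo, d_hi), maximal at (h_hi, d_lo)
    t_ev = (h_lo ** 2 / (math.pi * d_hi * pk.P),
            h_hi ** 2 / (math.pi * d_lo * pk.P))
    t_pd = 1.0 / pk.b
    t_on = pk.epsilon / (pk.k_on * pk.C_r)
    t_off = 1.0 / pk.k_off
    t_int = 1.0 / pk.k_int
    t_eff = t_on * (1.0 + t_int / t_off)
    slow = min(t_diff[0], t_ev[0], t_pd)
    fast = max(t_on, t_off, t_int)
    ratio = slow / fast
    return Timescales(
        t_diff=t_diff,
        t_ev=t_ev,
        t_pd=t_pd,
        t_on=t_on,
        t_off=t_off,
        t_int=t_int,
        t_eff=t_eff,
        separation_ratio=ratio,
        qss_valid=ratio >= ratio_threshold,
    )


def effective_uptake_rate(pk: PKParams) -> float:
    """Effective linear uptake rate k_eff (1/day) of the reduced model.

    Computed as t_off / (t_on (t_off + t_int)) and cross-checked against
    the algebraically identical form (k_on C_r / eps) k_int / (k_off + k_int).
    """
    t_on = pk.epsilon / (pk.k_on * pk.C_r)
    t_off = 1.0 / pk.k_off
    t_int = 1.0 / pk.k_int
    k1 = t_off / (t_on * (t_off + t_int))
    k2 = (pk.k_on * pk.C_r / pk.epsilon) * pk.k_int / (pk.k_off + pk.k_int)
    if not math.isclose(k1, k2, rel_tol=1e-10):
        raise AssertionError(f"inconsistent k_eff forms: {k1} vs {k2}")
    return k1


def fit_plasma_decay(
    times,
    concentrations,
    method: str = "loglinear",
) -> Tuple[float, float]:
    """Fit C(t) = C0 exp(-b t) to measured plasma concentrations.

    ``loglinear`` (default) does ordinary least squares on log C vs t;
    ``nls`` does nonlinear least squares on the original scale.  Returns
    (C0 in nM, b in 1/day).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("times and concentrations must be matching 1D arrays")
    if t.size < 2:
        raise ValueError("at least two samples required to fit a decay")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    slope, intercept = np.polyfit(t, np.log(c), 1)
    c0, b = float(np.exp(intercept)), float(-slope)
    if method == "loglinear":
        return c0, b
    if method == "nls":
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(
            lambda tt, a, r: a * np.exp(-r * tt), t, c, p0=(c0, b), maxfev=10000
        )
        return float(popt[0]), float(popt[1])
    raise ValueError(f"unknown fit method '{method}'")
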