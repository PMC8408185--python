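"""Imino-proton solvent-exchange analysis from water magnetization transfer.

After selective inversion of the water resonance, water magnetization
is transferred to a base-paired imino proton at the solvent exchange
rate k_ex.  The imino peak volume as a function of the exchange delay
follows

    W(t) = W0 - E W0 k_ex / (R1w - R1n) (exp(-R1n t) - exp(-R1w t))

where E is the water-inversion efficiency, R1w the water proton R1 and
R1n the sum of the imino proton R1 and k_ex.  R1w and E are fixed from
prior measurements; k_ex and R1n are fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IminoTrace",
    "IminoFit",
    "WaterR1Fit",
    "InversionEfficiency",
    "inversion_efficiency",
    "imino_recovery",
    "fit_imino_exchange",
    "fit_water_r1",
]


@dataclass
class IminoTrace:
    """Delays (s) and imino peak volumes with fixed W0, E, R1w."""

    delays: np.ndarray
    volumes: np.ndarray
    W0: float
    E: float
    R1w: float

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if np.any(self.delays < 0):
            raise ValueError("delays must be >= 0")
        if not 0 <= self.E <= 1:
            raise ValueError("inversion efficiency must lie in [0, 1]")
        if self.R1w <= 0:
            raise ValueError("water R1 must be positive")


class InversionEfficiency(NamedTuple):
    E: float
    out_of_range: bool


def inversion_efficiency(W_inv: float, W_eq: float) -> InversionEfficiency:
    """E = 1 - W_inv/W_eq from water peak volumes with/without inversion.

    As printed this gives E = 1 for complete saturation (W_inv = 0) and
    would give E = 2 for a perfect inversion (W_inv = -W_eq); values
    outside [0, 1] are returned as-is with a warning flag.
    """
    if W_eq == 0:
        raise ValueError("W_eq must be nonzero")
    E = 1.0 - W_inv / W_eq
    return InversionEfficiency(float(E), not (0.0 <= E <= 1.0))


def imino_recovery(t, W0: float, E: float, k_ex: float, R1w: float, R1n: float):
    """Imino peak volume W(t); analytic limit at R1w = R1n."""
    t = np.asarray(t, dtype=float)
    if abs(R1w - R1n) < 1e-9 * max(abs(R1w), abs(R1n), 1.0):
        # l'Hopital limit of (e^{-R1n t} - e^{-R1w t})/(R1w - R1n)
        return W0 - E * W0 * k_ex * t * np.exp(-R1n * t)
    return W0 - E * W0 * k_ex / (R1w - R1n) * (
        np.exp(-R1n * t) - np.exp(-R1w * t)
    )


class IminoFit(NamedTuple):
    k_ex: float
    R1n: float
    k_ex_sd: float
    R1n_sd: float


def fit_imino_exchange(trace: IminoTrace) -> IminoFit:
    """Two-parameter (k_ex, R1n) fit of the exchange-transfer trace.

    Standard errors are the square roots of the diagonal of the
    covariance matrix.
    """
    if trace.delays.size < 6:
        raise ValueError("need >= 6 delays to fit the exchange trace")

    def model(t, k_ex, R1n):
        return imino_recovery(t, trace.W0, trace.E, k_ex, trace.R1w, R1n)

    dip = trace.W0 - trace.volumes.min()
    k0 = max(dip / max(trace.W0, 1e-300) * 50.0, 1.0)
    popt, pcov = curve_fit(
        model,
        trace.delays,
        trace.volumes,
        p0=(k0, 30.0),
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=20000,
    )
    sd = np.sqrt(np.diag(pcov))
    return IminoFit(float(popt[0]), float(popt[1]), float(sd[0]), float(sd[1]))


class WaterR1Fit(NamedTuple):
    R1w: float
    I_inf: float
    R1w_sd: float
    non_recovering: bool


def fit_water_r1(delays, intensities) -> WaterR1Fit:
    """Saturation-recovery fit I(t) = I_inf (1 - exp(-R1w t))."""
    t = np.asarray(delays, dtype=float)
    I = np.asarray(intensities, dtype=float)
    if t.size < 5:
        raise ValueError("need >= 5 delays for saturation recovery")

    def model(tt, r1, iinf):
        return iinf * (1.0 - np.exp(-r1 * tt))

    iinf0 = float(I.max()) if I.max() > 0 else 1.0
    try:
        popt, pcov = curve_fit(
            model, t, I, p0=(0.3, iinf0), maxfev=20000
        )
        sd = np.sqrt(np.diag(pcov))
        non_rec = popt[0] <= 0
        return WaterR1Fit(float(popt[0]), float(popt[1]), float(sd[0]), bool(non_rec))
    except RuntimeError:
        return WaterR1Fit(float("nan"), float("nan"), float("nan"), True)
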