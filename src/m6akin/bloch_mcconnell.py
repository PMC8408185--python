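"""N-site Bloch-McConnell simulation of CEST and off-resonance R1rho.

The magnetization of N exchanging states is propagated under the
combined action of chemical exchange, relaxation, and a continuous RF
field applied along x.  For a piecewise-constant RF field the
generator is time independent, so propagation is exact via its
eigendecomposition (no stepwise integration).

Sign conventions follow the acquisition conventions of the dispersion
experiments exactly as recorded in the profile metadata:

* CEST offsets are ``Omega = omega_rf - omega_obs`` (Hz), so the minor
  dip of an excited state with shift ``dw`` appears at ``Omega = +dw``.
* R1rho offsets are ``Omega_eff = omega_obs - omega_rf`` (Hz), so the
  dispersion peak appears at ``Omega_eff = -dw``.

A single conversion layer (:func:`state_offsets_rad`) applies these,
preventing double negation.

Relaxation is homogeneous (decay toward zero, no thermal-recovery
term), consistent with intensities normalized to the zero-delay signal
over short relaxation delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import curve_fit

from .constants import B1_GRID_POINTS, B1_GRID_SPAN_SIGMA
from .exchange_models import ExchangeModel, NucleusContext, build_rate_matrix

__all__ = [
    "CESTProfile",
    "R1rhoProfile",
    "MonoExpFit",
    "bm_generator",
    "propagate",
    "state_offsets_rad",
    "simulate_cest",
    "simulate_r1rho",
    "monoexp_rate",
]


def _as_points(b1, offsets):
    b1 = np.atleast_1d(np.asarray(b1, dtype=float))
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    if b1.shape != offsets.shape:
        raise ValueError("b1 and offset arrays must have identical shapes")
    return b1, offsets


@dataclass
class CESTProfile:
    """CEST acquisition grid and (optionally) measured intensities.

    ``b1_hz`` and ``offset_hz`` are parallel per-point arrays; use
    :meth:`from_grid` to build the cross product of a few RF powers
    with an offset ladder.  ``init_mode`` is ``"gs_only"`` (no
    equilibration of magnetization before the relaxation delay; the
    default for non-methyl probes) or ``"equilibrated"`` (z
    magnetization distributed by state populations; methyl probes).
    """

    probe: str = "C"
    b1_hz: np.ndarray = field(default_factory=lambda: np.array([25.0]))
    offset_hz: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    trelax: float = 0.2
    intensities: np.ndarray | None = None
    sigma: np.ndarray | None = None
    init_mode: str = "gs_only"
    b1_inhomogeneity: float = 0.0

    def __post_init__(self) -> None:
        self.b1_hz, self.offset_hz = _as_points(self.b1_hz, self.offset_hz)
        if self.trelax <= 0:
            raise ValueError("trelax must be positive")
        if self.init_mode not in ("gs_only", "equilibrated"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities, dtype=float)
            if not np.all(np.isfinite(self.intensities)):
                raise ValueError("intensities must be finite")

    @classmethod
    def from_grid(
        cls,
        b1_powers: Sequence[float],
        offsets: Sequence[float],
        **kwargs,
    ) -> "CESTProfile":
        b1 = np.repeat(np.asarray(b1_powers, dtype=float), len(offsets))
        off = np.tile(np.asarray(offsets, dtype=float), len(b1_powers))
        return cls(b1_hz=b1, offset_hz=off, **kwargs)

    @property
    def n_points(self) -> int:
        return self.b1_hz.size


@dataclass
class R1rhoProfile:
    """Off-resonance R1rho grid and (optionally) measured rates."""

    probe: str = "C"
    b1_hz: np.ndarray = field(default_factory=lambda: np.array([150.0]))
    offset_hz: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    r1rho: np.ndarray | None = None
    sigma: np.ndarray | None = None
    alignment: str = "auto"

    def __post_init__(self) -> None:
        self.b1_hz, self.offset_hz = _as_points(self.b1_hz, self.offset_hz)
        if self.alignment not in ("auto", "gs", "avg"):
            raise ValueError(f"unknown alignment {self.alignment!r}")
        if self.r1rho is not None:
            self.r1rho = np.asarray(self.r1rho, dtype=float)
            if np.any(self.r1rho <= 0):
                raise ValueError("r1rho values must be positive")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")

    @classmethod
    def from_grid(cls, b1_powers, offsets, **kwargs) -> "R1rhoProfile":
        b1 = np.repeat(np.asarray(b1_powers, dtype=float), len(offsets))
        off = np.tile(np.asarray(offsets, dtype=float), len(b1_powers))
        return cls(b1_hz=b1, offset_hz=off, **kwargs)

    @property
    def n_points(self) -> int:
        return self.b1_hz.size


# ---------------------------------------------------------------------------
# generator construction and exact propagation
# ---------------------------------------------------------------------------


def state_offsets_rad(
    model: ExchangeModel,
    ctx: NucleusContext,
    offset_hz,
    kind: str,
    probe: str | None = None,
) -> np.ndarray:
    """Resonance offset of every state in the RF rotating frame (rad/s).

    ``kind="cest"`` uses Omega = omega_rf - omega_obs; ``kind="r1rho"``
    uses Omega_eff = omega_obs - omega_rf (both referenced to the
    ground-state resonance).  Output shape is (n_offsets, n_states).
    """
    dw_rad = np.array([ctx.ppm_to_rad_s(s.dw_ppm(probe)) for s in model.states])
    omega = 2.0 * np.pi * np.atleast_1d(np.asarray(offset_hz, dtype=float))
    if kind == "cest":
        return dw_rad[None, :] - omega[:, None]
    if kind == "r1rho":
        return dw_rad[None, :] + omega[:, None]
    raise ValueError(f"unknown experiment kind {kind!r}")


def bm_generator(
    model: ExchangeModel,
    omega1_rad: np.ndarray,
    delta_rad: np.ndarray,
) -> np.ndarray:
    """Bloch-McConnell generators, one per grid point.

    Magnetization is ordered (Mx_1..Mx_N, My_1..My_N, Mz_1..Mz_N).
    ``omega1_rad`` has shape (P,), ``delta_rad`` shape (P, N); the
    result has shape (P, 3N, 3N).
    """
    K = build_rate_matrix(model)
    n = K.shape[0]
    R1 = np.array([s.R1 for s in model.states])
    R2 = np.array([s.R2 for s in model.states])
    omega1 = np.atleast_1d(np.asarray(omega1_rad, dtype=float))
    delta = np.atleast_2d(np.asarray(delta_rad, dtype=float))
    P = omega1.size
    L = np.zeros((P, 3 * n, 3 * n))
    sl = slice
    x, y, z = sl(0, n), sl(n, 2 * n), sl(2 * n, 3 * n)
    Kx = K - np.diag(R2)
    Kz = K - np.diag(R1)
    L[:, x, x] = Kx
    L[:, y, y] = Kx
    L[:, z, z] = Kz
    idx = np.arange(n)
    L[:, idx, n + idx] = delta
    L[:, n + idx, idx] = -delta
    L[:, n + idx, 2 * n + idx] = omega1[:, None]
    L[:, 2 * n + idx, n + idx] = -omega1[:, None]
    return L


def propagate(L: np.ndarray, M0: np.ndarray, times) -> np.ndarray:
    """Evolve magnetization under exp(L t) exactly.

    ``L`` has shape (P, m, m) or (m, m); ``M0`` shape (m,) or (P, m);
    ``times`` is a scalar or 1-D array.  Returns shape (P, n_times, m)
    (leading axes squeezed to match the inputs only in the sense that a
    2-D ``L`` yields (n_times, m)).
    """
    single = L.ndim == 2
    L = L[None] if single else L
    P, m, _ = L.shape
    M0 = np.broadcast_to(np.asarray(M0, dtype=float), (P, m))
    t = np.atleast_1d(np.asarray(times, dtype=float))

    try:
        w, V = np.linalg.eig(L)
        cond = np.linalg.cond(V)
        if np.any(~np.isfinite(cond)) or np.max(cond) > 1e10:
            raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        c = np.linalg.solve(V, M0[..., None])  # (P, m, 1)
        phases = np.exp(w[:, None, :] * t[None, :, None])  # (P, T, m)
        out = np.einsum("pij,ptj,pj...->pti", V, phases, c[..., 0])
        out = np.real(out)
    except np.linalg.LinAlgError:
        out = np.empty((P, t.size, m))
        for p in range(P):
            for k, tk in enumerate(t):
                out[p, k] = expm(L[p] * tk) @ M0[p]
    if not np.all(np.isfinite(out)):
        bad = np.argwhere(~np.isfinite(out))
        raise FloatingPointError(
            f"non-finite magnetization during propagation at point index "
            f"{bad[0][0]}"
        )
    return out[0] if single else out


def _b1_weights(b1_inhomogeneity: float):
    """Scale factors and weights of the discrete Gaussian B1 distribution."""
    if b1_inhomogeneity <= 0:
        return np.array([1.0]), np.array([1.0])
    span = B1_GRID_SPAN_SIGMA * b1_inhomogeneity
    scales = 1.0 + np.linspace(-span, span, B1_GRID_POINTS)
    weights = np.exp(-0.5 * ((scales - 1.0) / b1_inhomogeneity) ** 2)
    keep = scales > 0
    return scales[keep], weights[keep] / weights[keep].sum()


# ---------------------------------------------------------------------------
# CEST
# ---------------------------------------------------------------------------


def simulate_cest(
    model: ExchangeModel,
    ctx: NucleusContext,
    grid: CESTProfile,
    probe: str | None = None,
) -> np.ndarray:
    """Normalized ground-state intensity for every (power, offset) point.

    Magnetization starts according to ``grid.init_mode``, evolves for
    ``grid.trelax`` under the Bloch-McConnell generator, and the
    ground-state z magnetization is reported normalized to its
    zero-delay value.  A non-zero ``grid.b1_inhomogeneity`` averages
    the profile over a discrete Gaussian distribution of RF amplitudes.
    """
    if np.any(grid.b1_hz <= 0):
        raise ValueError("CEST B1 power must be positive for every point")
    n = len(model.states)
    Mz0 = np.zeros(n)
    if grid.init_mode == "equilibrated":
        Mz0[:] = model.populations
    else:
        Mz0[0] = 1.0
    M0 = np.concatenate([np.zeros(2 * n), Mz0])
    delta = state_offsets_rad(model, ctx, grid.offset_hz, "cest", probe)

    scales, weights = _b1_weights(grid.b1_inhomogeneity)
    signal = np.zeros(grid.n_points)
    for s, wgt in zip(scales, weights):
        omega1 = 2.0 * np.pi * grid.b1_hz * s
        L = bm_generator(model, omega1, delta)
        M = propagate(L, M0, grid.trelax)  # (P, 1, 3n)
        signal += wgt * M[:, 0, 2 * n]
    return signal / Mz0[0]


# ---------------------------------------------------------------------------
# R1rho
# ---------------------------------------------------------------------------


class MonoExpFit(NamedTuple):
    rate: float
    amplitude: float
    non_decaying: bool


def monoexp_rate(times, values) -> MonoExpFit:
    """Least-squares fit of A * exp(-R t); returns (R, A, warning flag)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points for a monoexponential fit")
    if np.any(v <= 0):
        raise ValueError("values must be positive for a monoexponential fit")
    # log-linear initial guess
    slope, intercept = np.polyfit(t, np.log(v), 1)
    p0 = (max(-slope, 1e-12), np.exp(intercept))
    try:
        popt, _ = curve_fit(
            lambda tt, r, a: a * np.exp(-r * tt), t, v, p0=p0, maxfev=10000
        )
        rate, amp = float(popt[0]), float(popt[1])
    except RuntimeError:
        rate, amp = float(-slope), float(np.exp(intercept))
    return MonoExpFit(rate, amp, non_decaying=rate <= 0)


def _alignment_for(
    model: ExchangeModel, ctx: NucleusContext, alignment: str, probe: str | None
) -> str:
    if alignment != "auto":
        return alignment
    pops = model.populations
    dw = np.array([ctx.ppm_to_rad_s(s.dw_ppm(probe)) for s in model.states])
    es = [i for i in range(len(pops)) if i != 0]
    major = max(es, key=lambda i: pops[i])
    dw_major = dw[major]
    if dw_major == 0:
        raise ValueError(
            "alignment='auto' undefined: the major excited state has zero "
            "chemical-shift offset"
        )
    names = model.names
    k_ex = model.rate(names[0], names[major]) + model.rate(names[major], names[0])
    return "gs" if k_ex / abs(dw_major) <= 1.0 else "avg"


def simulate_r1rho(
    model: ExchangeModel,
    ctx: NucleusContext,
    grid: R1rhoProfile,
    probe: str | None = None,
    n_delays: int = 12,
) -> np.ndarray:
    """R1rho (s^-1) per (spin-lock power, offset) point.

    Magnetization is initialized along the ground-state effective field
    (``gs`` alignment) or along the population-averaged effective field
    (``avg``); ``auto`` chooses by the k_ex/|dw_major| rule (<= 1: GS,
    > 1: averaged).  The magnetization is propagated over a ladder of
    delays and the rate extracted by a monoexponential fit of the
    projection onto the effective field.
    """
    if np.any(grid.b1_hz <= 0):
        raise ValueError("spin-lock power must be positive for every point")
    mode = _alignment_for(model, ctx, grid.alignment, probe)
    n = len(model.states)
    pops = model.populations
    delta = state_offsets_rad(model, ctx, grid.offset_hz, "r1rho", probe)
    omega1 = 2.0 * np.pi * grid.b1_hz
    L = bm_generator(model, omega1, delta)

    R1_bar = float(pops @ np.array([s.R1 for s in model.states]))
    R2_bar = float(pops @ np.array([s.R2 for s in model.states]))

    rates = np.empty(grid.n_points)
    for p in range(grid.n_points):
        if mode == "gs":
            theta = np.arctan2(omega1[p], delta[p, 0])
            M0 = np.zeros(3 * n)
            M0[0] = np.sin(theta)
            M0[2 * n] = np.cos(theta)
        else:
            delta_avg = float(pops @ delta[p])
            theta = np.arctan2(omega1[p], delta_avg)
            M0 = np.concatenate(
                [pops * np.sin(theta), np.zeros(n), pops * np.cos(theta)]
            )
        unit = np.zeros(3 * n)
        if mode == "gs":
            unit[0], unit[2 * n] = np.sin(theta), np.cos(theta)
        else:
            unit[:n] = np.sin(theta)
            unit[2 * n :] = np.cos(theta)

        r_est = max(R1_bar * np.cos(theta) ** 2 + R2_bar * np.sin(theta) ** 2, 1e-2)
        fit = None
        for _ in range(3):
            tmax = 1.2 / r_est
            delays = np.linspace(0.0, tmax, n_delays)
            traj = propagate(L[p], M0, delays)  # (T, 3n)
            proj = traj @ unit
            if np.any(proj <= 0):
                # decay too fast for the ladder; shorten and retry
                r_est *= 4.0
                continue
            fit = monoexp_rate(delays, proj)
            if 0.3 < fit.rate / r_est < 3.0:
                rates[p] = fit.rate
                break
            r_est = max(fit.rate, 1e-2)
        else:
            if fit is None:
                raise FloatingPointError(
                    f"R1rho extraction failed at point {p} "
                    f"(b1={grid.b1_hz[p]} Hz, offset={grid.offset_hz[p]} Hz)"
                )
            rates[p] = fit.rate
    return rates
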