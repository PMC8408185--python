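"""CS / IF / CS+IF kinetic simulation and the m6A-impact predictor.

The four-state conformational-selection + induced-fit scheme couples
methylamino isomerization in the single strand (k1 / k_m1) and in the
duplex (k2 / k_m2) to bimolecular annealing through the anti
(Watson-Crick-competent) and syn (mismatch-like) isomer pathways.
This module integrates the mass-action ODE systems, extracts apparent
two-state annealing/melting rate constants from the relaxation of the
total duplex concentration, decomposes the equilibrium reactive flux
into the CS and IF pathways, and predicts how methylation changes the
apparent rate constants of an arbitrary duplex (or of a unimolecular
conformational transition) from its unmethylated reference rates and
thermodynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .constants import (
    DEFAULT_DDG_M6A,
    R_KCAL,
    SYN_KOFF_ACCELERATION,
    SYN_KON_PENALTY,
)
from .exchange_models import (
    HybridizationSystem,
    RateSet,
    equilibrium_populations,
)

__all__ = [
    "TimeCourse",
    "ApparentRates",
    "FluxReport",
    "integrate_cs",
    "integrate_if",
    "integrate_cs_if",
    "apparent_rates",
    "flux",
    "predict_m6a_impact",
    "predict_table",
    "duplex_rates_from_exchange",
    "default_time_grid",
]

CS_SPECIES = ("ss_syn", "ss_anti", "ds_anti", "ss2")
IF_SPECIES = ("ss_syn", "ds_syn", "ds_anti", "ss2")
CS_IF_SPECIES = ("ss_syn", "ss_anti", "ds_syn", "ds_anti", "ss2")


@dataclass
class TimeCourse:
    """Concentration trajectories (M) per species over ``times`` (s)."""

    times: np.ndarray
    concentrations: dict[str, np.ndarray]
    system: HybridizationSystem
    conservation_residual: float = 0.0

    @property
    def duplex_total(self) -> np.ndarray:
        total = np.zeros_like(self.times, dtype=float)
        for name in ("ds_syn", "ds_anti"):
            if name in self.concentrations:
                total = total + self.concentrations[name]
        return total


@dataclass
class ApparentRates:
    """Effective two-state rates extracted from a multi-state time course."""

    kon_app: float | None = None  # M^-1 s^-1 (bimolecular)
    koff_app: float | None = None  # s^-1
    k_forward: float | None = None  # s^-1 (unimolecular)
    k_backward: float | None = None
    k_ex: float | None = None
    fold_kon: float | None = None  # kon_ref / kon_app
    fold_koff: float | None = None  # koff_ref / koff_app
    rms_residual: float = float("nan")
    warning: str | None = None


class FluxReport(NamedTuple):
    F_CS: float
    F_IF: float
    fraction_CS: float
    fraction_IF: float


# ---------------------------------------------------------------------------
# ODE integration
# ---------------------------------------------------------------------------


def _integrate(rhs, y0, times, system: HybridizationSystem, species) -> TimeCourse:
    times = np.asarray(times, dtype=float)
    atol = 1e-12 * system.Ct
    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        np.asarray(y0, dtype=float),
        t_eval=times,
        method="LSODA",
        rtol=1e-8,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    conc = {name: sol.y[i] for i, name in enumerate(species)}
    strand1 = sum(
        conc[n] for n in species if n != "ss2"
    )
    resid = float(np.max(np.abs(strand1 - strand1[0])))
    if resid > 1e-9 * system.Ct:
        raise RuntimeError(
            f"strand mass conservation violated ({resid:.3e} M drift)"
        )
    for name in species:
        conc[name] = np.clip(conc[name], 0.0, None)
    return TimeCourse(times, conc, system, resid)


def _default_init(system: HybridizationSystem, species) -> np.ndarray:
    """100% single strand in the syn isomer at t = 0."""
    y0 = np.zeros(len(species))
    y0[species.index("ss_syn")] = system.Ct
    if "ss2" in species and system.bimolecular:
        y0[species.index("ss2")] = system.ss2_total
    return y0


def integrate_cs(
    rates: RateSet,
    system: HybridizationSystem,
    init: Sequence[float] | None = None,
    times: np.ndarray | None = None,
) -> TimeCourse:
    """Conformational-selection pathway: ss_syn <-> ss_anti <-> ds_anti."""
    bi = system.bimolecular
    if times is None:
        times = default_time_grid(rates, system)
    y0 = _default_init(system, CS_SPECIES) if init is None else np.asarray(init)
    if np.any(np.asarray(y0) < 0):
        raise ValueError("initial concentrations must be nonnegative")

    def rhs(t, y):
        ss_syn, ss_anti, ds_anti, ss2 = y
        anneal = rates.kon_anti * ss_anti * (ss2 if bi else 1.0)
        melt = rates.koff_anti * ds_anti
        iso_f = rates.k1 * ss_syn
        iso_b = rates.k_m1 * ss_anti
        return [
            -iso_f + iso_b,
            iso_f - iso_b - anneal + melt,
            anneal - melt,
            (-anneal + melt) if bi else 0.0,
        ]

    return _integrate(rhs, y0, times, system, CS_SPECIES)


def integrate_if(
    rates: RateSet,
    system: HybridizationSystem,
    init: Sequence[float] | None = None,
    times: np.ndarray | None = None,
) -> TimeCourse:
    """Induced-fit pathway: ss_syn <-> ds_syn <-> ds_anti."""
    bi = system.bimolecular
    if times is None:
        times = default_time_grid(rates, system)
    y0 = _default_init(system, IF_SPECIES) if init is None else np.asarray(init)
    if np.any(np.asarray(y0) < 0):
        raise ValueError("initial concentrations must be nonnegative")

    def rhs(t, y):
        ss_syn, ds_syn, ds_anti, ss2 = y
        anneal = rates.kon_syn * ss_syn * (ss2 if bi else 1.0)
        melt = rates.koff_syn * ds_syn
        iso_f = rates.k_m2 * ds_syn  # ds_syn -> ds_anti
        iso_b = rates.k2 * ds_anti
        return [
            -anneal + melt,
            anneal - melt - iso_f + iso_b,
            iso_f - iso_b,
            (-anneal + melt) if bi else 0.0,
        ]

    return _integrate(rhs, y0, times, system, IF_SPECIES)


def integrate_cs_if(
    rates: RateSet,
    system: HybridizationSystem,
    init: Sequence[float] | None = None,
    times: np.ndarray | None = None,
) -> TimeCourse:
    """Full four-state CS+IF system (five concentration variables)."""
    bi = system.bimolecular
    if times is None:
        times = default_time_grid(rates, system)
    y0 = _default_init(system, CS_IF_SPECIES) if init is None else np.asarray(init)
    if np.any(np.asarray(y0) < 0):
        raise ValueError("initial concentrations must be nonnegative")

    def rhs(t, y):
        ss_syn, ss_anti, ds_syn, ds_anti, ss2 = y
        s = ss2 if bi else 1.0
        iso_ss_f = rates.k1 * ss_syn
        iso_ss_b = rates.k_m1 * ss_anti
        anneal_syn = rates.kon_syn * ss_syn * s
        melt_syn = rates.koff_syn * ds_syn
        anneal_anti = rates.kon_anti * ss_anti * s
        melt_anti = rates.koff_anti * ds_anti
        iso_ds_f = rates.k2 * ds_anti  # anti -> syn
        iso_ds_b = rates.k_m2 * ds_syn
        return [
            -iso_ss_f + iso_ss_b - anneal_syn + melt_syn,
            iso_ss_f - iso_ss_b - anneal_anti + melt_anti,
            anneal_syn - melt_syn + iso_ds_f - iso_ds_b,
            anneal_anti - melt_anti - iso_ds_f + iso_ds_b,
            (-anneal_syn + melt_syn - anneal_anti + melt_anti) if bi else 0.0,
        ]

    return _integrate(rhs, y0, times, system, CS_IF_SPECIES)


def _relaxation_time_estimate(rates: RateSet, system: HybridizationSystem) -> float:
    """Crude inverse of the slowest relevant rate, for grid construction."""
    candidates = []
    s = system.ss2_total if system.bimolecular else 1.0
    if rates.kon_anti > 0 or rates.koff_anti > 0:
        candidates.append(rates.kon_anti * s + rates.koff_anti)
    if rates.kon_syn > 0 or rates.koff_syn > 0:
        candidates.append(rates.kon_syn * s + rates.koff_syn)
    if rates.k1 > 0 or rates.k_m1 > 0:
        candidates.append(rates.k1 + rates.k_m1)
    if rates.k2 > 0 or rates.k_m2 > 0:
        candidates.append(rates.k2 + rates.k_m2)
    candidates = [c for c in candidates if c > 0]
    if not candidates:
        raise ValueError("cannot build a time grid: all rates are zero")
    return 1.0 / min(candidates)


def default_time_grid(
    rates: RateSet,
    system: HybridizationSystem,
    n_points: int = 60,
    decades_below: float = 3.0,
    decades_above: float = 3.0,
) -> np.ndarray:
    """Log-spaced grid spanning 1e-3 to 1e+3 relaxation times, with t=0."""
    tau = _relaxation_time_estimate(rates, system)
    grid = np.logspace(
        math.log10(tau) - decades_below,
        math.log10(tau) + decades_above,
        n_points,
    )
    return np.concatenate([[0.0], grid])


# ---------------------------------------------------------------------------
# apparent two-state rates
# ---------------------------------------------------------------------------


def _two_state_duplex(
    kon: float, koff: float, system: HybridizationSystem, times: np.ndarray
) -> np.ndarray:
    """Exact solution of the apparent two-state hybridization model.

    d[ds]/dt = kon (Ct - ds)(S - ds) - koff ds with ds(0) = 0 is a
    Riccati equation whose solution is rational in exp; the closed form
    is used so the fit model is exact and robust for any trial rates.
    """
    Ct, S = system.Ct, system.ss2_total
    a = kon
    b = -(kon * (Ct + S) + koff)
    c = kon * Ct * S
    disc = math.sqrt(max(b * b - 4.0 * a * c, 0.0))
    r1 = (-b - disc) / (2.0 * a)  # equilibrium duplex concentration
    r2 = (-b + disc) / (2.0 * a)
    if r2 <= 0:
        return np.zeros_like(times)
    Q = (r1 / r2) * np.exp(a * (r1 - r2) * times)
    return (r1 - Q * r2) / (1.0 - Q)


def apparent_rates(
    tc: TimeCourse,
    system: HybridizationSystem | None = None,
    kon_ref: float | None = None,
    koff_ref: float | None = None,
) -> ApparentRates:
    """Effective two-state rate constants from a simulated time course.

    Bimolecular systems: the total duplex trajectory is fit by least
    squares to the numerical two-state hybridization model
    (d[ds]/dt = kon*[ss1][ss2] - koff*[ds]).  Unimolecular systems: the
    product ("ES") trajectory is fit to A(1 - exp(-k_ex t)) and k_ex is
    split by the equilibrium product fraction.

    Fold-changes are reported as reference/apparent when reference
    rates are supplied.
    """
    system = system or tc.system
    times = tc.times
    span = times[times > 0]
    if span.size >= 2 and span.max() / span.min() < 1e3:
        raise ValueError(
            "time course must span at least three decades around the "
            "relaxation time"
        )

    if not system.bimolecular:
        product = tc.duplex_total
        p_eq = product[-1] / system.Ct

        def resid_uni(x):
            kex, amp = x
            return product / system.Ct - amp * (1.0 - np.exp(-kex * times))

        kex0 = 1.0 / max(times[np.searchsorted(product, 0.632 * product[-1])], 1e-12)
        res = least_squares(
            resid_uni, [kex0, p_eq], bounds=([1e-12, 0.0], [np.inf, 1.0])
        )
        kex, amp = res.x
        kf = kex * p_eq
        kb = kex * (1.0 - p_eq)
        out = ApparentRates(
            k_forward=float(kf),
            k_backward=float(kb),
            k_ex=float(kex),
            rms_residual=float(np.sqrt(np.mean(res.fun**2))),
        )
        if kon_ref is not None:
            out.fold_kon = kon_ref / kf if kf > 0 else float("inf")
        if koff_ref is not None:
            out.fold_koff = koff_ref / kb if kb > 0 else float("inf")
        return out

    duplex = tc.duplex_total
    ds_eq = duplex[-1]
    if ds_eq <= 0:
        raise ValueError("no duplex formed; apparent rates undefined")

    warning = None
    if "ds_syn" in tc.concentrations:
        syn_frac = tc.concentrations["ds_syn"][-1] / ds_eq
        if syn_frac > 0.10:
            warning = (
                f"syn duplex is {syn_frac:.1%} of total duplex at equilibrium; "
                "the apparent two-state approximation is strained"
            )

    # initial guesses from the equilibrium and the half-rise time
    ss2_eq = system.ss2_total - ds_eq
    ss1_eq = system.Ct - ds_eq
    K_eq = ds_eq / max(ss1_eq * ss2_eq, 1e-300)
    i_half = int(np.searchsorted(duplex, 0.5 * ds_eq))
    t_half = times[min(max(i_half, 1), times.size - 1)]
    koff0 = max(math.log(2.0) / t_half / max(K_eq * ss2_eq, 1.0), 1e-6)
    kon0 = koff0 * K_eq

    def resid(x):
        kon, koff = np.exp(x)
        model = _two_state_duplex(kon, koff, system, times)
        return (model - duplex) / system.Ct

    # bounds keep the (possibly data-unconstrained) melting rate finite
    lo = np.log([kon0, koff0]) - 30.0
    hi = np.log([kon0, koff0]) + 30.0
    res = least_squares(resid, np.log([kon0, koff0]), bounds=(lo, hi),
                        method="trf")
    kon, koff = np.exp(res.x)
    out = ApparentRates(
        kon_app=float(kon),
        koff_app=float(koff),
        rms_residual=float(np.sqrt(np.mean(res.fun**2))),
        warning=warning,
    )
    if kon_ref is not None:
        out.fold_kon = float(kon_ref / kon)
    if koff_ref is not None:
        out.fold_koff = float(koff_ref / koff)
    return out


def duplex_rates_from_exchange(
    k_ex: float, p_ss: float, Ct: float, ss2_total: float | None = None
) -> tuple[float, float]:
    """(kon, koff) from a two-state dispersion fit of duplex melting.

    The forward (melting) rate is k_ex * p_ss and the backward
    (annealing) pseudo-first-order rate k_ex (1 - p_ss) = kon * [ss2],
    with [ss2] = Ct * p_ss for a two-state fit of a 1:1 duplex.
    """
    if not 0 < p_ss < 1:
        raise ValueError("p_ss must lie strictly between 0 and 1")
    ss2 = Ct * p_ss if ss2_total is None else ss2_total - Ct * (1.0 - p_ss)
    if ss2 <= 0:
        raise ValueError("free complementary strand concentration is not positive")
    koff = k_ex * p_ss
    kon = k_ex * (1.0 - p_ss) / ss2
    return kon, koff


# ---------------------------------------------------------------------------
# pathway flux
# ---------------------------------------------------------------------------


def flux(rates: RateSet, system: HybridizationSystem) -> FluxReport:
    """Equilibrium reactive flux through the CS and IF pathways.

    Each pathway flux is the harmonic mean of its sequential forward
    rates evaluated at the equilibrium concentrations:
    CS: isomerization of the free strand then annealing of the anti
    isomer; IF: annealing of the syn isomer then isomerization within
    the duplex.
    """
    eq = equilibrium_populations(rates, system)
    c = eq.concentrations
    s = c["ss2"] if system.bimolecular else 1.0

    cs_steps = [rates.k1 * c["ss_syn"], rates.kon_anti * c["ss_anti"] * s]
    if_steps = [rates.kon_syn * c["ss_syn"] * s, rates.k_m2 * c["ds_syn"]]

    def harmonic(steps):
        if any(x <= 0 for x in steps):
            return 0.0
        return 1.0 / sum(1.0 / x for x in steps)

    f_cs = harmonic(cs_steps)
    f_if = harmonic(if_steps)
    total = f_cs + f_if
    if total == 0:
        raise ValueError("both pathway fluxes are zero")
    return FluxReport(f_cs, f_if, f_cs / total, f_if / total)


# ---------------------------------------------------------------------------
# the m6A-impact predictor
# ---------------------------------------------------------------------------


def build_predicted_rateset(
    kon_ref: float,
    koff_ref: float,
    dG_anneal_ref: float,
    iso_ss: tuple[float, float],
    iso_ds: tuple[float, float],
    temperature: float,
    ddG_m6A: float = DEFAULT_DDG_M6A,
    closure: str = "kon_syn_ratio",
    syn_kon_penalty: float = SYN_KON_PENALTY,
    syn_koff_acceleration: float = SYN_KOFF_ACCELERATION,
) -> RateSet:
    """Assemble the full CS+IF rate set for a methylated duplex.

    * anti pathway: ``koff_anti = koff_ref``; ``kon_anti`` closes the
      thermodynamic cycle against the annealing free energy of the anti
      single strand (apparent methylated annealing free energy minus
      the single-strand isomerization penalty).
    * syn pathway, ``closure="kon_syn_ratio"``: ``kon_syn = kon_ref /
      syn_kon_penalty`` and ``koff_syn`` from the cycle;
      ``closure="koff_syn_ratio"``: ``koff_syn = koff_ref *
      syn_koff_acceleration`` and ``kon_syn`` from the cycle.
    """
    if closure not in ("kon_syn_ratio", "koff_syn_ratio"):
        raise ValueError(f"unknown closure {closure!r}")
    k1, k_m1 = iso_ss
    k2, k_m2 = iso_ds
    RT = R_KCAL * temperature
    dG_iso_ss = -RT * math.log(k1 / k_m1)
    dG_iso_ds = -RT * math.log(k_m2 / k2)
    dG_app = dG_anneal_ref + ddG_m6A
    dG_anneal_anti = dG_app - dG_iso_ss
    dG_anneal_syn = dG_app - dG_iso_ds

    koff_anti = koff_ref
    kon_anti = koff_anti * math.exp(-dG_anneal_anti / RT)
    if closure == "kon_syn_ratio":
        kon_syn = kon_ref / syn_kon_penalty
        koff_syn = kon_syn / math.exp(-dG_anneal_syn / RT)
    else:
        koff_syn = koff_ref * syn_koff_acceleration
        kon_syn = koff_syn * math.exp(-dG_anneal_syn / RT)

    rates = RateSet(
        k1=k1,
        k_m1=k_m1,
        k2=k2,
        k_m2=k_m2,
        kon_anti=kon_anti,
        koff_anti=koff_anti,
        kon_syn=kon_syn,
        koff_syn=koff_syn,
        kon_ref=kon_ref,
        koff_ref=koff_ref,
    )
    rates.check_cycle_closure(1e-6)
    return rates


def predict_m6a_impact(
    kon_ref: float,
    koff_ref: float | None,
    dG_anneal_ref: float,
    iso_ss: tuple[float, float],
    iso_ds: tuple[float, float],
    system: HybridizationSystem,
    ddG_m6A: float = DEFAULT_DDG_M6A,
    closure: str = "kon_syn_ratio",
    times: np.ndarray | None = None,
) -> ApparentRates:
    """Predicted apparent rates for a methylated duplex or transition.

    ``koff_ref`` may be omitted, in which case it is derived from
    ``kon_ref`` and the unmethylated annealing free energy.  The full
    rate set is built by thermodynamic-cycle closure, the CS+IF system
    integrated from 100% syn single strand, and the apparent two-state
    rates extracted from the duplex relaxation.  Fold-changes are
    reference/apparent.
    """
    RT = R_KCAL * system.temperature
    if koff_ref is None:
        koff_ref = kon_ref / math.exp(-dG_anneal_ref / RT)
    rates = build_predicted_rateset(
        kon_ref,
        koff_ref,
        dG_anneal_ref,
        iso_ss,
        iso_ds,
        system.temperature,
        ddG_m6A=ddG_m6A,
        closure=closure,
    )
    tc = integrate_cs_if(rates, system, times=times)
    return apparent_rates(tc, system, kon_ref=kon_ref, koff_ref=koff_ref)


REQUIRED_TABLE_COLUMNS = ("id", "kon_ref", "dG_anneal_ref")


def predict_table(
    records: pd.DataFrame,
    iso_ss: tuple[float, float],
    iso_ds: tuple[float, float],
    system: HybridizationSystem,
    ddG_m6A: float = DEFAULT_DDG_M6A,
    closure: str = "kon_syn_ratio",
) -> pd.DataFrame:
    """Row-wise m6A-impact prediction for a per-sequence table.

    ``records`` requires columns ``id``, ``kon_ref`` (M^-1 s^-1) and
    ``dG_anneal_ref`` (kcal/mol, annealing free energy of the
    unmethylated duplex).  The melting reference is derived per record
    as koff_ref = kon_ref / exp(-dG/RT).
    """
    missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table is missing columns: {missing}")
    rows = []
    RT = R_KCAL * system.temperature
    for rec in records.itertuples(index=False):
        kon_ref = float(rec.kon_ref)
        if kon_ref <= 0:
            raise ValueError(f"record {rec.id!r}: kon_ref must be positive")
        dg = float(rec.dG_anneal_ref)
        koff_ref = kon_ref / math.exp(-dg / RT)
        pred = predict_m6a_impact(
            kon_ref,
            koff_ref,
            dg,
            iso_ss,
            iso_ds,
            system,
            ddG_m6A=ddG_m6A,
            closure=closure,
        )
        rows.append(
            {
                "id": rec.id,
                "kon_ref": kon_ref,
                "koff_ref": koff_ref,
                "dG_anneal_ref": dg,
                "kon_app": pred.kon_app,
                "koff_app": pred.koff_app,
                "fold_kon": pred.fold_kon,
                "fold_koff": pred.fold_koff,
            }
        )
    return pd.DataFrame(rows)
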