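"""Free-energy bookkeeping for hybridization and isomerization.

Rate <-> free-energy conversions, the decomposition of the apparent
annealing free energy of a methylated duplex into single-strand
isomerization plus annealing of the anti isomer, thermodynamic-cycle
closure of the syn (induced-fit) pathway, modified van't Hoff analysis
of temperature-dependent rate constants, and two-state UV melting-curve
fitting with linear baselines.

Sign convention: annealing free energies are negative when favorable.
All temperatures are Kelvin internally; R = 1.9872e-3 kcal/mol/K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .constants import KB_OVER_H, R_KCAL

__all__ = [
    "ThermoRecord",
    "VantHoffFit",
    "MeltingCurve",
    "MeltingFit",
    "dg_from_rates",
    "k_ratio_from_dg",
    "decompose_annealing",
    "dg_app_from_populations",
    "close_cycle_syn",
    "vant_hoff_fit",
    "fit_melting_curve",
    "two_state_pss",
]


@dataclass(frozen=True)
class ThermoRecord:
    """A dG/dH/dS/Tm bundle for one reaction step at temperature T."""

    label: str
    T: float
    dG: float | None = None  # kcal/mol
    dH: float | None = None  # kcal/mol
    dS: float | None = None  # kcal/mol/K
    Tm: float | None = None  # K

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive (Kelvin)")
        if None not in (self.dG, self.dH, self.dS):
            if abs(self.dG - (self.dH - self.T * self.dS)) > 1e-6:
                raise ValueError(
                    f"{self.label}: dG != dH - T dS "
                    f"({self.dG} vs {self.dH - self.T * self.dS})"
                )


def dg_from_rates(kf: float, kb: float, T: float) -> float:
    """Standard free energy -RT ln(kf/kb) in kcal/mol."""
    if kf <= 0 or kb <= 0:
        raise ValueError("rate constants must be positive")
    return -R_KCAL * T * math.log(kf / kb)


def k_ratio_from_dg(dG: float, T: float) -> float:
    """Equilibrium constant exp(-dG/RT) (inverse of dg_from_rates)."""
    return math.exp(-dG / (R_KCAL * T))


class AnnealingDecomposition(NamedTuple):
    dG_anneal_anti: float
    ddG_anti: float | None


def decompose_annealing(
    dG_app: float,
    dG_iso_ss: float,
    dG_ref: float | None = None,
    T: float | None = None,
) -> AnnealingDecomposition:
    """Split the apparent annealing free energy of a methylated duplex.

    The overall annealing of the methylated strand proceeds through
    syn -> anti isomerization of the single strand followed by
    annealing of the anti isomer, so
    dG_anneal_anti = dG_app - dG_iso_ss, and the methyl-group effect on
    the annealing step itself is ddG_anti = dG_anneal_anti - dG_ref
    relative to the unmethylated reference.
    """
    dg_anti = dG_app - dG_iso_ss
    ddg = None if dG_ref is None else dg_anti - dG_ref
    return AnnealingDecomposition(dg_anti, ddg)


def dg_app_from_populations(
    p_ss: float,
    p_gs: float,
    k1: float,
    k_m1: float,
    Ct: float,
    ss2_total: float,
    T: float,
    p_es_duplex: float = 0.0,
) -> float:
    """Apparent annealing free energy from dispersion-fit populations.

    Concentrations follow the strand bookkeeping of a two- or
    three-state dispersion fit: the single-strand pool splits into
    syn/anti by the isomerization rates, the ground state is the anti
    duplex, and (in the three-state case) ``p_es_duplex`` is the
    population of the syn duplex intermediate, which is included in the
    complementary-strand mass balance.

    dG = -RT ln([ss_syn][ss2] / [ds_anti]).
    """
    if not (0 < p_ss < 1) or not (0 < p_gs <= 1):
        raise ValueError("populations must lie in (0, 1)")
    if k1 <= 0 or k_m1 <= 0:
        raise ValueError("isomerization rates must be positive")
    ss_total = Ct * p_ss
    ss_syn = ss_total * k_m1 / (k1 + k_m1)
    ds_anti = Ct * p_gs
    ds_syn = Ct * p_es_duplex
    ss2 = ss2_total - ds_anti - ds_syn
    if ds_anti <= 0:
        raise ValueError("zero duplex concentration; annealing dG undefined")
    if ss2 <= 0:
        raise ValueError("complementary-strand mass balance gives [ss2] <= 0")
    if p_ss >= 1.0 - 1e-12:
        return float("inf")
    return -R_KCAL * T * math.log(ss_syn * ss2 / ds_anti)


class SynCycleClosure(NamedTuple):
    kon_syn: float
    koff_syn: float
    dG_iso_ds: float  # syn -> anti direction, -RT ln(k_m2 / k2)
    dG_anneal_syn: float


def close_cycle_syn(
    dG_app: float,
    k2: float,
    k_m2: float,
    T: float,
    kon_syn: float | None = None,
    koff_syn: float | None = None,
) -> SynCycleClosure:
    """Complete the syn-pathway rates by thermodynamic-cycle closure.

    Given the apparent annealing free energy, the duplex isomerization
    rates (k2: anti -> syn, k_m2: syn -> anti) and exactly one of the
    syn annealing/melting rate constants, the other follows from
    dG_anneal_syn = dG_app - dG_iso_ds with
    dG_iso_ds = -RT ln(k_m2 / k2) and
    koff_syn = kon_syn / exp(-dG_anneal_syn / RT).
    """
    if (kon_syn is None) == (koff_syn is None):
        raise ValueError("supply exactly one of kon_syn / koff_syn")
    if k2 <= 0 or k_m2 <= 0:
        raise ValueError("duplex isomerization rates must be positive")
    RT = R_KCAL * T
    dG_iso_ds = -RT * math.log(k_m2 / k2)
    dG_anneal_syn = dG_app - dG_iso_ds
    K_syn = math.exp(-dG_anneal_syn / RT)
    if kon_syn is not None:
        if kon_syn <= 0:
            raise ValueError("kon_syn must be positive")
        koff_syn = kon_syn / K_syn
    else:
        if koff_syn <= 0:
            raise ValueError("koff_syn must be positive")
        kon_syn = koff_syn * K_syn

    # full-cycle identity: K_anneal_syn * K_iso(syn->anti) must reproduce
    # the apparent annealing equilibrium
    residual = (kon_syn / koff_syn) * (k_m2 / k2) / math.exp(-dG_app / RT) - 1.0
    if abs(residual) > 1e-6:
        raise ValueError(f"thermodynamic cycle residual {residual:.3e} exceeds 1e-6")
    return SynCycleClosure(float(kon_syn), float(koff_syn), dG_iso_ds, dG_anneal_syn)


# ---------------------------------------------------------------------------
# modified van't Hoff analysis
# ---------------------------------------------------------------------------


@dataclass
class VantHoffFit:
    """Transition-state parameters from ln(k/T) vs 1/T regression.

    The modified van't Hoff form referenced to the harmonic-mean
    temperature T_hm decorrelates the activation free energy and
    enthalpy:

    ln(k(T)/T) = ln(kB kappa / h) - dG(T_hm)/(R T_hm) - dH/R (1/T - 1/T_hm)

    with transmission coefficient kappa fixed at 1.
    """

    dG_act: float  # kcal/mol at T_hm
    dH_act: float  # kcal/mol
    T_hm: float
    dG_sd: float
    dH_sd: float
    r_squared: float
    temperatures: np.ndarray
    extrapolated: bool = False

    def extrapolate(self, T: float) -> float:
        """Rate constant k(T); flags extrapolation beyond the fit span."""
        if not (self.temperatures.min() <= T <= self.temperatures.max()):
            self.extrapolated = True
        lnk_over_T = (
            math.log(KB_OVER_H)
            - self.dG_act / (R_KCAL * self.T_hm)
            - (self.dH_act / R_KCAL) * (1.0 / T - 1.0 / self.T_hm)
        )
        return T * math.exp(lnk_over_T)


def harmonic_mean_temperature(temperatures: Sequence[float]) -> float:
    t = np.asarray(temperatures, dtype=float)
    return float(t.size / np.sum(1.0 / t))


def vant_hoff_fit(
    temperatures: Sequence[float],
    rates: Sequence[float],
    rate_err: Sequence[float] | None = None,
) -> VantHoffFit:
    """Fit one direction's k(T) to the modified van't Hoff equation.

    Linear least squares of ln(k/T) against (1/T - 1/T_hm), unweighted
    unless per-point rate uncertainties are supplied.
    """
    T = np.asarray(temperatures, dtype=float)
    k = np.asarray(rates, dtype=float)
    if T.size < 3:
        raise ValueError("need rates at >= 3 temperatures")
    if np.any(k <= 0) or np.any(T <= 0):
        raise ValueError("temperatures and rates must be positive")
    T_hm = harmonic_mean_temperature(T)
    x = 1.0 / T - 1.0 / T_hm
    y = np.log(k / T)
    if rate_err is not None:
        w = k / np.asarray(rate_err, dtype=float)  # sigma_lnk = err/k
    else:
        w = np.ones_like(y)
    A = np.vstack([np.ones_like(x), x]).T * w[:, None]
    b = y * w
    coef, _, _, _ = np.linalg.lstsq(A, b, rcond=None)
    intercept, slope = coef
    resid = (A @ coef) - b
    dof = max(y.size - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(A.T @ A)

    dH = -slope * R_KCAL
    dG = (math.log(KB_OVER_H) - intercept) * R_KCAL * T_hm
    dH_sd = math.sqrt(cov[1, 1]) * R_KCAL
    dG_sd = math.sqrt(cov[0, 0]) * R_KCAL * T_hm

    k_fit = T * np.exp(intercept + slope * x)
    ss_res = float(np.sum((k_fit - k) ** 2))
    ss_tot = float(np.sum((k - k.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return VantHoffFit(
        dG_act=float(dG),
        dH_act=float(dH),
        T_hm=T_hm,
        dG_sd=float(dG_sd),
        dH_sd=float(dH_sd),
        r_squared=r2,
        temperatures=T,
    )


# ---------------------------------------------------------------------------
# UV melting curves
# ---------------------------------------------------------------------------


@dataclass
class MeltingCurve:
    """A260 vs temperature for a non-self-complementary 1:1 duplex."""

    temperatures: np.ndarray  # K, strictly increasing
    a260: np.ndarray
    Ct: float  # total duplex strand concentration (M)
    self_complementary: bool = False

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.a260 = np.asarray(self.a260, dtype=float)
        if self.self_complementary:
            raise ValueError(
                "self-complementary duplexes are not supported; the Ct/2 "
                "entropy convention applies to non-self-complementary strands"
            )
        if self.temperatures.size < 20:
            raise ValueError("need >= 20 points spanning the transition")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.Ct <= 0:
            raise ValueError("Ct must be positive")


def two_state_pss(T, Tm: float, dH: float) -> np.ndarray:
    """Single-strand fraction of a 1:1 duplex melting transition.

    Derived from the two-state equilibrium with total strand
    concentration folded into Tm; evaluates to exactly 0.5 at T = Tm.
    """
    T = np.asarray(T, dtype=float)
    e = np.exp((1.0 / Tm - 1.0 / T) * dH / R_KCAL)
    return 1.0 - (1.0 + 4.0 * e - np.sqrt(1.0 + 8.0 * e)) / (4.0 * e)


@dataclass
class MeltingFit:
    Tm: float  # K
    dH: float  # kcal/mol
    dS: float  # kcal/mol/K
    baselines: dict[str, float]  # m_ss, b_ss, m_ds, b_ds
    Tm_sd: float
    dH_sd: float
    converged: bool

    def dG(self, T: float) -> float:
        return self.dH - T * self.dS


def fit_melting_curve(curve: MeltingCurve) -> MeltingFit:
    """Six-parameter two-state fit with linear ss/ds baselines.

    A260(T) = (m_ss T + b_ss) p_ss + (m_ds T + b_ds)(1 - p_ss) with
    p_ss the two-state single-strand fraction.  The entropy follows
    from dS = dH/Tm - R ln(Ct/2) (non-self-complementary convention)
    and dG(T) = dH - T dS.
    """
    T = curve.temperatures
    A = curve.a260

    def model(Tv, Tm, dH, m_ss, b_ss, m_ds, b_ds):
        pss = two_state_pss(Tv, Tm, dH)
        return (m_ss * Tv + b_ss) * pss + (m_ds * Tv + b_ds) * (1.0 - pss)

    # initial guesses: Tm at the steepest rise, baselines from the ends
    dAdT = np.gradient(A, T)
    Tm0 = float(T[np.argmax(dAdT)])
    n_edge = max(3, T.size // 10)
    m_ds0, b_ds0 = np.polyfit(T[:n_edge], A[:n_edge], 1)
    m_ss0, b_ss0 = np.polyfit(T[-n_edge:], A[-n_edge:], 1)
    p0 = (Tm0, -60.0, m_ss0, b_ss0, m_ds0, b_ds0)
    try:
        popt, pcov = curve_fit(model, T, A, p0=p0, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((6, 6), np.nan)
        converged = False
    Tm, dH, m_ss, b_ss, m_ds, b_ds = popt
    if not (T.min() <= Tm <= T.max()):
        converged = False
    dS = dH / Tm - R_KCAL * math.log(curve.Ct / 2.0)
    sd = np.sqrt(np.abs(np.diag(pcov)))
    return MeltingFit(
        Tm=float(Tm),
        dH=float(dH),
        dS=float(dS),
        baselines={
            "m_ss": float(m_ss),
            "b_ss": float(b_ss),
            "m_ds": float(m_ds),
            "b_ds": float(b_ds),
        },
        Tm_sd=float(sd[0]),
        dH_sd=float(sd[1]),
        converged=converged,
    )
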