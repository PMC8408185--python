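"""Synthetic-data generators with known ground truth.

Every generator is a pure function of (parameters, seed): identical
inputs reproduce identical outputs.  Generated uncertainty columns are
set to the true noise sigma so that reduced chi^2 is ~1 for a
well-specified fit.

Named scenarios bundle datasets emulating the systems the kinetic
model was developed on: millisecond methylamino isomerization in an
unpaired strand (~9% anti population, ~600 s^-1 exchange), a
low-populated syn-duplex excited state in a stable hairpin (~1%, ~500
s^-1, 2.5 ppm C2 shift), and a full four-state CS+IF rate set at
55 C-like conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bloch_mcconnell import (
    CESTProfile,
    R1rhoProfile,
    simulate_cest,
    simulate_r1rho,
)
from .exchange_models import (
    ExchangeModel,
    HybridizationSystem,
    NucleusContext,
    RateSet,
    two_state_model,
)
from .fitting import Dataset
from .imino_exchange import IminoTrace, imino_recovery
from .thermodynamics import MeltingCurve, two_state_pss

__all__ = [
    "NoiseSpec",
    "ScenarioBundle",
    "gen_cest",
    "gen_r1rho",
    "gen_melting",
    "gen_imino",
    "gen_scenario",
    "available_scenarios",
]

#: default CEST noise: 0.5% of the zero-delay (unit-normalized) intensity,
#: the order of a triplicate zero-delay standard deviation
DEFAULT_CEST_SIGMA = 0.005


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise of width ``sigma``, absolute or fractional."""

    sigma: float = DEFAULT_CEST_SIGMA
    fractional: bool = False
    seed: int = 0
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind != "gaussian":
            raise ValueError("only gaussian noise is supported")

    def apply(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (noisy values, per-point sigma column)."""
        rng = np.random.default_rng(self.seed)
        if self.fractional:
            sigma = self.sigma * np.abs(values)
        else:
            sigma = np.full_like(values, self.sigma, dtype=float)
        if self.sigma == 0:
            return values.copy(), np.maximum(sigma, 1e-12)
        return values + rng.normal(0.0, sigma), sigma


def gen_cest(
    model: ExchangeModel,
    ctx: NucleusContext,
    grid: CESTProfile,
    noise: NoiseSpec = NoiseSpec(),
    probe: str | None = None,
) -> CESTProfile:
    """Forward-simulated CEST profile plus Gaussian noise."""
    clean = simulate_cest(model, ctx, grid, probe=probe)
    noisy, sigma = noise.apply(clean)
    return CESTProfile(
        probe=probe or grid.probe,
        b1_hz=grid.b1_hz.copy(),
        offset_hz=grid.offset_hz.copy(),
        trelax=grid.trelax,
        intensities=noisy,
        sigma=sigma,
        init_mode=grid.init_mode,
        b1_inhomogeneity=grid.b1_inhomogeneity,
    )


def gen_r1rho(
    model: ExchangeModel,
    ctx: NucleusContext,
    grid: R1rhoProfile,
    noise: NoiseSpec = NoiseSpec(sigma=0.02, fractional=True),
    probe: str | None = None,
) -> R1rhoProfile:
    """Forward-simulated R1rho profile plus Gaussian noise."""
    clean = simulate_r1rho(model, ctx, grid, probe=probe)
    noisy, sigma = noise.apply(clean)
    return R1rhoProfile(
        probe=probe or grid.probe,
        b1_hz=grid.b1_hz.copy(),
        offset_hz=grid.offset_hz.copy(),
        r1rho=noisy,
        sigma=sigma,
        alignment=grid.alignment,
    )


def gen_melting(
    Tm: float,
    dH: float,
    Ct: float,
    baselines: Mapping[str, float] | None = None,
    T_grid: Sequence[float] | None = None,
    noise: NoiseSpec = NoiseSpec(sigma=0.002),
) -> MeltingCurve:
    """Two-state melting curve with linear baselines (temperatures in K)."""
    if T_grid is None:
        T_grid = np.linspace(288.15, 368.15, 81)
    T = np.asarray(T_grid, dtype=float)
    bl = {"m_ss": 1.5e-3, "b_ss": 0.45, "m_ds": 5e-4, "b_ds": 0.30}
    if baselines:
        bl.update(baselines)
    pss = two_state_pss(T, Tm, dH)
    a260 = (bl["m_ss"] * T + bl["b_ss"]) * pss + (bl["m_ds"] * T + bl["b_ds"]) * (
        1.0 - pss
    )
    noisy, _ = noise.apply(a260)
    return MeltingCurve(temperatures=T, a260=noisy, Ct=Ct)


def gen_imino(
    k_ex: float,
    R1n: float,
    W0: float = 1.0,
    E: float = 0.9,
    R1w: float = 0.3,
    delays: Sequence[float] | None = None,
    noise: NoiseSpec = NoiseSpec(sigma=0.02, fractional=True),
) -> IminoTrace:
    """Water-magnetization-transfer trace from the exchange model."""
    if delays is None:
        delays = np.array(
            [0.0, 0.005, 0.01, 0.02, 0.03, 0.05, 0.08, 0.12, 0.18, 0.25, 0.4, 0.6]
        )
    t = np.asarray(delays, dtype=float)
    clean = imino_recovery(t, W0, E, k_ex, R1w, R1n)
    noisy, _ = noise.apply(clean)
    return IminoTrace(delays=t, volumes=noisy, W0=W0, E=E, R1w=R1w)


# ---------------------------------------------------------------------------
# named scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioBundle:
    name: str
    datasets: list[Dataset]
    ground_truth: dict
    seed: int
    rates: RateSet | None = None
    system: HybridizationSystem | None = None


def _scenario_ss_isomerization(seed: int) -> ScenarioBundle:
    """Unpaired-strand methylamino isomerization (ssGGACU-like).

    Two-state exchange, anti population ~9%, k_ex ~600 s^-1 at 25 C;
    C10 shows a +3 ppm excited-state shift, C2 a -0.6 ppm shift.
    """
    truth = {"p_es": 0.09, "k_ex": 600.0, "dw_ES_C10": 3.0, "dw_ES_C2": -0.6,
             "R1": 2.0, "R2": 20.0}
    ctx = NucleusContext("13C", 600.0)
    model = two_state_model(
        truth["p_es"],
        truth["k_ex"],
        {"C10": truth["dw_ES_C10"], "C2": truth["dw_ES_C2"]},
        R1_gs=truth["R1"],
        R2_gs=truth["R2"],
    )
    offsets = ctx.ppm_to_hz(np.linspace(-9.0, 9.0, 75))
    datasets = []
    for i, probe in enumerate(("C10", "C2")):
        grid = CESTProfile.from_grid(
            [15.0, 30.0], offsets, trelax=0.2,
            init_mode="equilibrated" if probe == "C10" else "gs_only",
        )
        prof = gen_cest(model, ctx, grid, NoiseSpec(seed=seed + i), probe=probe)
        datasets.append(Dataset(prof, ctx, probe))
    return ScenarioBundle("ss_isomerization", datasets, truth, seed)


def _scenario_duplex_syn_es(seed: int) -> ScenarioBundle:
    """Hairpin-duplex syn excited state (hpGGACU-like).

    Two-state exchange with a ~1% excited state, k_ex ~500 s^-1 and a
    +2.5 ppm C2 shift at 55 C.
    """
    truth = {"p_es": 0.01, "k_ex": 500.0, "dw_ES_C2": 2.5, "dw_ES_C10": 4.0,
             "R1": 1.8, "R2": 18.0}
    ctx = NucleusContext("13C", 600.0)
    model = two_state_model(
        truth["p_es"],
        truth["k_ex"],
        {"C2": truth["dw_ES_C2"], "C10": truth["dw_ES_C10"]},
        R1_gs=truth["R1"],
        R2_gs=truth["R2"],
    )
    offsets = ctx.ppm_to_hz(np.linspace(-7.0, 7.0, 75))
    datasets = []
    for i, probe in enumerate(("C2", "C10")):
        grid = CESTProfile.from_grid(
            [15.0, 30.0], offsets, trelax=0.2,
            init_mode="equilibrated" if probe == "C10" else "gs_only",
        )
        prof = gen_cest(model, ctx, grid, NoiseSpec(seed=seed + i), probe=probe)
        datasets.append(Dataset(prof, ctx, probe))
    return ScenarioBundle("duplex_syn_es", datasets, truth, seed)


def _scenario_cs_if_55c(seed: int) -> ScenarioBundle:
    """Four-state CS+IF rate set at 55 C-like conditions.

    Single-strand isomerization with ~9% anti and k_ex ~600 s^-1,
    duplex isomerization with ~1% syn and k_ex ~500 s^-1, annealing of
    the anti isomer twice as fast as a 1e5 M^-1 s^-1 reference, and a
    syn (mismatch-like) pathway 20-fold slower on / ~80-fold faster off.
    """
    kon_ref, koff_ref = 1e5, 20.0
    rates = RateSet(
        k1=54.0,
        k_m1=546.0,
        k2=5.0,
        k_m2=495.0,
        kon_anti=2.0 * kon_ref,
        koff_anti=koff_ref,
        kon_syn=kon_ref / 20.0,
        koff_syn=0.0,  # closed below
        kon_ref=kon_ref,
        koff_ref=koff_ref,
    )
    # close the thermodynamic cycle for koff_syn
    koff_syn = (
        rates.kon_syn
        * (rates.k_m1 / rates.k1)
        * (rates.koff_anti / rates.kon_anti)
        * (rates.k_m2 / rates.k2)
    )
    rates = RateSet(**{**rates.__dict__, "koff_syn": koff_syn})
    rates.check_cycle_closure()
    system = HybridizationSystem(Ct=2e-4, ss2_total=2e-4, temperature=328.15)
    truth = {
        "kon_ref": kon_ref,
        "koff_ref": koff_ref,
        "p_anti_ss": 0.09,
        "p_syn_ds": 0.01,
    }
    return ScenarioBundle("cs_if_55c", [], truth, seed, rates=rates, system=system)


_SCENARIOS = {
    "ss_isomerization": _scenario_ss_isomerization,
    "duplex_syn_es": _scenario_duplex_syn_es,
    "cs_if_55c": _scenario_cs_if_55c,
}


def available_scenarios() -> list[str]:
    return sorted(_SCENARIOS)


def gen_scenario(name: str, seed: int = 0) -> ScenarioBundle:
    """Deterministic named dataset bundle with ground truth."""
    try:
        factory = _SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {available_scenarios()}"
        ) from None
    return factory(seed)
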