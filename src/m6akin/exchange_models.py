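"""Exchange-model data structures and equilibrium solvers.

An :class:`ExchangeModel` is a set of spectroscopic states (populations,
chemical-shift offsets, relaxation rates) connected by first-order
exchange rate constants.  It is the object the Bloch-McConnell
simulator propagates and the dispersion fitter optimizes.

The four-state conformational-selection + induced-fit (CS+IF) scheme for
a methylated strand hybridizing with its complement is::

    dsNA(anti)  <-- k_m2 / k2 -->  dsNA(syn)
        ^                             ^
   kon_anti*[ss2] / koff_anti    kon_syn*[ss2] / koff_syn
        |                             |
    ssNA(anti)  <-- k_m1 / k1 -->  ssNA(syn)

State ordering is fixed as (dsNA_anti = ground state, dsNA_syn,
ssNA_syn, ssNA_anti); all chemical-shift offsets are stored relative to
the ground state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .constants import (
    DEFAULT_PROTON_FIELD_MHZ,
    GAMMA_RATIOS,
    POPULATION_FLOOR,
)

__all__ = [
    "SpectroState",
    "ExchangeModel",
    "RateSet",
    "HybridizationSystem",
    "NucleusContext",
    "EquilibriumState",
    "EsPopulationEstimate",
    "CS_IF_STATE_ORDER",
    "build_rate_matrix",
    "stationary_distribution",
    "equilibrium_populations",
    "pseudo_first_order",
    "es_population_from_shift",
    "two_state_model",
    "save_model",
    "load_model",
]

#: fixed state ordering of the four-state CS+IF scheme
CS_IF_STATE_ORDER = ("ds_anti", "ds_syn", "ss_syn", "ss_anti")

#: undirected edges (by state index) allowed for each topology
TOPOLOGY_EDGES = {
    "two_state": {(0, 1)},
    "linear3": {(0, 1), (1, 2)},
    "star3": {(0, 1), (0, 2)},
    "triangular3": {(0, 1), (0, 2), (1, 2)},
    # cycle ds_anti - ds_syn - ss_syn - ss_anti - ds_anti
    "four_state_cs_if": {(0, 1), (1, 2), (2, 3), (0, 3)},
}


@dataclass(frozen=True)
class SpectroState:
    """One spectroscopic state of an exchange model.

    Parameters
    ----------
    name:
        State label.
    population:
        Equilibrium fractional population (0-1).
    dw:
        Chemical-shift offset of this state relative to the ground
        state, in ppm.  Either a scalar (single probe) or a mapping
        ``{probe_label: ppm}`` for multi-probe models.
    R1, R2:
        Longitudinal and transverse relaxation rates (s^-1).
    """

    name: str
    population: float
    dw: float | Mapping[str, float] = 0.0
    R1: float = 0.0
    R2: float = 0.0

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.population <= 1.0 + 1e-12):
            raise ValueError(
                f"state {self.name!r}: population {self.population} not in [0, 1]"
            )
        if self.R1 < 0 or self.R2 < 0:
            raise ValueError(f"state {self.name!r}: relaxation rates must be >= 0")

    def dw_ppm(self, probe: str | None = None) -> float:
        """Chemical-shift offset (ppm) for one probe."""
        if isinstance(self.dw, Mapping):
            if probe is None:
                if len(self.dw) != 1:
                    raise KeyError(
                        f"state {self.name!r} has multiple probes; specify one of "
                        f"{sorted(self.dw)}"
                    )
                return next(iter(self.dw.values()))
            return float(self.dw[probe])
        return float(self.dw)


@dataclass(frozen=True)
class NucleusContext:
    """Probe nucleus and spectrometer field, for ppm <-> Hz conversion."""

    nucleus: str = "13C"
    proton_field_MHz: float = DEFAULT_PROTON_FIELD_MHZ

    def __post_init__(self) -> None:
        if self.nucleus not in GAMMA_RATIOS:
            raise ValueError(
                f"unknown nucleus {self.nucleus!r}; supported: {sorted(GAMMA_RATIOS)}"
            )
        if self.proton_field_MHz <= 0:
            raise ValueError("proton_field_MHz must be positive")

    @property
    def larmor_MHz(self) -> float:
        return self.proton_field_MHz * GAMMA_RATIOS[self.nucleus]

    def ppm_to_hz(self, ppm):
        return np.asarray(ppm, dtype=float) * self.larmor_MHz

    def hz_to_ppm(self, hz):
        return np.asarray(hz, dtype=float) / self.larmor_MHz

    def ppm_to_rad_s(self, ppm):
        return self.ppm_to_hz(ppm) * 2.0 * np.pi


@dataclass(frozen=True)
class HybridizationSystem:
    """Strand concentrations and temperature of a hybridization system.

    ``bimolecular=False`` describes intramolecular conformational
    transitions (hairpins, TAR-like switches) where the complementary
    strand concentration plays no role.
    """

    Ct: float
    ss2_total: float = 0.0
    temperature: float = 298.15
    bimolecular: bool = True

    def __post_init__(self) -> None:
        if self.Ct <= 0:
            raise ValueError("Ct must be positive")
        if self.ss2_total < 0:
            raise ValueError("ss2_total must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")


@dataclass(frozen=True)
class RateSet:
    """The eight CS+IF rate constants plus the unmethylated reference.

    ``k1``/``k_m1`` are forward/backward methylamino isomerization in
    the single strand (syn -> anti / anti -> syn); ``k2``/``k_m2`` the
    same in the duplex (anti -> syn / syn -> anti).  ``kon_*`` are
    bimolecular annealing rates (M^-1 s^-1) and ``koff_*`` first-order
    melting rates (s^-1) for the anti and syn pathways.  ``kon_ref`` /
    ``koff_ref`` are the unmethylated reference rates.
    """

    k1: float = 0.0
    k_m1: float = 0.0
    k2: float = 0.0
    k_m2: float = 0.0
    kon_anti: float = 0.0
    koff_anti: float = 0.0
    kon_syn: float = 0.0
    koff_syn: float = 0.0
    kon_ref: float = 0.0
    koff_ref: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"rate {name} must be >= 0, got {value}")

    def cycle_ratio(self) -> float:
        """Product of equilibrium-constant ratios around the CS+IF cycle.

        Thermodynamic consistency (microscopic reversibility) requires
        the product to equal 1.
        """
        try:
            return (
                (self.k1 / self.k_m1)
                * (self.kon_anti / self.koff_anti)
                * (self.k2 / self.k_m2)
                * (self.koff_syn / self.kon_syn)
            )
        except ZeroDivisionError as exc:
            raise ValueError("cycle ratio undefined: a backward rate is zero") from exc

    def check_cycle_closure(self, tol: float = 1e-6) -> None:
        ratio = self.cycle_ratio()
        if abs(ratio - 1.0) > tol:
            raise ValueError(
                f"thermodynamic cycle not closed: ratio {ratio:.6g} differs "
                f"from 1 by more than {tol}"
            )


@dataclass
class ExchangeModel:
    """States plus pairwise first-order exchange rates.

    ``rates`` maps ordered state-name pairs ``(from, to)`` to rate
    constants (s^-1).  Rates may exist only on edges of the declared
    ``topology``.  On construction the stationary distribution of the
    rate matrix is checked against the stored populations; pass
    ``populations=None``-style construction via :meth:`from_rates` to
    have populations computed instead.
    """

    states: Sequence[SpectroState]
    rates: Mapping[tuple[str, str], float]
    topology: str = "two_state"
    detailed_balance: bool = False
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGY_EDGES:
            raise ValueError(f"unknown topology {self.topology!r}")
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValueError("state names must be unique")
        expected = max(max(e) for e in TOPOLOGY_EDGES[self.topology]) + 1
        if len(self.states) != expected:
            raise ValueError(
                f"topology {self.topology!r} requires {expected} states, "
                f"got {len(self.states)}"
            )
        index = {n: i for i, n in enumerate(names)}
        edges = TOPOLOGY_EDGES[self.topology]
        for (a, b), rate in self.rates.items():
            if a not in index or b not in index:
                raise ValueError(f"rate references unknown state ({a!r}, {b!r})")
            if rate < 0:
                raise ValueError(f"rate {a}->{b} must be >= 0")
            i, j = index[a], index[b]
            if (min(i, j), max(i, j)) not in edges:
                raise ValueError(
                    f"rate {a}->{b} not allowed for topology {self.topology!r}"
                )
        total = sum(s.population for s in self.states)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"populations sum to {total}, expected 1")
        if self._validate and any(k > 0 for k in self.rates.values()):
            pi = stationary_distribution(build_rate_matrix(self))
            stored = np.array([s.population for s in self.states])
            if np.max(np.abs(pi - stored)) > 1e-6:
                raise ValueError(
                    "stored populations do not match the stationary distribution "
                    f"of the rate matrix: stored {stored}, stationary {pi}"
                )
            if self.detailed_balance:
                self._check_detailed_balance()

    def _check_detailed_balance(self, tol: float = 1e-6) -> None:
        """For cyclic topologies, forward/backward products must close."""
        if self.topology not in ("triangular3", "four_state_cs_if"):
            return
        names = [s.name for s in self.states]
        n = len(names)
        cycle = list(range(n)) + [0]
        ratio = 1.0
        for a, b in zip(cycle[:-1], cycle[1:]):
            kf = self.rates.get((names[a], names[b]), 0.0)
            kb = self.rates.get((names[b], names[a]), 0.0)
            if kf == 0 or kb == 0:
                return  # open cycle: nothing to close
            ratio *= kf / kb
        if abs(ratio - 1.0) > tol:
            raise ValueError(
                f"detailed balance requested but cycle ratio is {ratio:.6g}"
            )

    # -- convenience ---------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.states]

    @property
    def populations(self) -> np.ndarray:
        return np.array([s.population for s in self.states])

    def rate(self, a: str, b: str) -> float:
        return float(self.rates.get((a, b), 0.0))

    @classmethod
    def from_rates(
        cls,
        states: Sequence[SpectroState],
        rates: Mapping[tuple[str, str], float],
        topology: str,
        detailed_balance: bool = False,
    ) -> "ExchangeModel":
        """Build a model computing populations from the rates."""
        probe = cls(
            states=states,
            rates=rates,
            topology=topology,
            detailed_balance=False,
            _validate=False,
        )
        pi = stationary_distribution(build_rate_matrix(probe))
        new_states = [replace(s, population=float(p)) for s, p in zip(states, pi)]
        return cls(
            states=new_states,
            rates=rates,
            topology=topology,
            detailed_balance=detailed_balance,
        )

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "topology": self.topology,
            "detailed_balance": self.detailed_balance,
            "states": [
                {
                    "name": s.name,
                    "population": s.population,
                    "dw": dict(s.dw) if isinstance(s.dw, Mapping) else s.dw,
                    "R1": s.R1,
                    "R2": s.R2,
                }
                for s in self.states
            ],
            "rates": [
                {"from": a, "to": b, "k": k} for (a, b), k in self.rates.items()
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ExchangeModel":
        states = [
            SpectroState(
                name=d["name"],
                population=d["population"],
                dw=d.get("dw", 0.0),
                R1=d.get("R1", 0.0),
                R2=d.get("R2", 0.0),
            )
            for d in data["states"]
        ]
        rates = {(r["from"], r["to"]): float(r["k"]) for r in data["rates"]}
        return cls(
            states=states,
            rates=rates,
            topology=data["topology"],
            detailed_balance=bool(data.get("detailed_balance", False)),
        )


def save_model(model: ExchangeModel, path) -> None:
    """Serialize a model to YAML or JSON, chosen by file extension."""
    text_path = str(path)
    data = model.to_dict()
    if text_path.endswith(".json"):
        with open(text_path, "w") as fh:
            json.dump(data, fh, indent=2)
    else:
        with open(text_path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def load_model(path) -> ExchangeModel:
    text_path = str(path)
    with open(text_path) as fh:
        data = json.load(fh) if text_path.endswith(".json") else yaml.safe_load(fh)
    return ExchangeModel.from_dict(data)


# ---------------------------------------------------------------------------
# rate matrix and stationary distribution
# ---------------------------------------------------------------------------


def build_rate_matrix(model: ExchangeModel) -> np.ndarray:
    """First-order kinetic matrix K with K[i, j] = rate j -> i (s^-1).

    Columns sum to zero (probability conservation).  Raises if the
    positive-rate graph has more than one closed communicating class,
    naming the states that cannot equilibrate with the ground state.
    """
    names = model.names
    n = len(names)
    index = {name: i for i, name in enumerate(names)}
    K = np.zeros((n, n))
    for (a, b), k in model.rates.items():
        if k > 0:
            K[index[b], index[a]] += k
    np.fill_diagonal(K, 0.0)
    K[np.diag_indices(n)] = -K.sum(axis=0)
    if np.any(K > 0):
        _check_single_closed_class(K, names)
    return K


def _closed_classes(K: np.ndarray) -> list[set[int]]:
    """Closed communicating classes of the positive-rate digraph."""
    n = K.shape[0]
    adj = [set(np.nonzero(K[:, j] > 0)[0]) - {j} for j in range(n)]

    # reachability closure
    reach = [set(a) | {i} for i, a in enumerate(adj)]
    changed = True
    while changed:
        changed = False
        for i in range(n):
            extra = set()
            for j in reach[i]:
                extra |= reach[j]
            if not extra <= reach[i]:
                reach[i] |= extra
                changed = True
    classes: list[set[int]] = []
    seen: set[int] = set()
    for i in range(n):
        if i in seen:
            continue
        scc = {j for j in reach[i] if i in reach[j]}
        seen |= scc
        if all(reach[j] <= scc for j in scc):
            classes.append(scc)
    return classes


def _isolated_states(K: np.ndarray) -> list[int]:
    """States with neither incoming nor outgoing rates (spectators)."""
    n = K.shape[0]
    off = K - np.diag(np.diag(K))
    return [
        i
        for i in range(n)
        if not np.any(off[i, :] > 0) and not np.any(off[:, i] > 0)
    ]


def _check_single_closed_class(K: np.ndarray, names: Sequence[str]) -> None:
    isolated = set(_isolated_states(K))
    classes = [c for c in _closed_classes(K) if not c <= isolated]
    if len(classes) > 1:
        groups = [" /".join(names[i] for i in sorted(c)) for c in classes]
        raise ValueError(
            "disconnected exchange topology: states cannot equilibrate between "
            f"closed groups {groups}"
        )
    if len(classes) == 0:
        raise ValueError("no equilibration possible: all rates are zero")


def stationary_distribution(K: np.ndarray) -> np.ndarray:
    """Normalized stationary vector of a kinetic matrix (K pi = 0).

    Fully isolated states (no rates in or out) carry zero population.
    """
    n = K.shape[0]
    isolated = _isolated_states(K)
    if isolated:
        keep = [i for i in range(n) if i not in isolated]
        if not keep:
            raise ValueError("no equilibration possible: all rates are zero")
        pi = np.zeros(n)
        pi[keep] = stationary_distribution(K[np.ix_(keep, keep)])
        return pi
    A = np.vstack([K, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.where(np.abs(pi) < POPULATION_FLOOR, 0.0, pi)
    if np.any(pi < -1e-9):
        raise ValueError(f"stationary solve produced negative populations: {pi}")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# equilibrium of the CS+IF hybridization system
# ---------------------------------------------------------------------------


class EquilibriumState(NamedTuple):
    """Equilibrium concentrations (M) and strand-1 fractional populations."""

    concentrations: dict[str, float]  # ss_syn, ss_anti, ds_syn, ds_anti, ss2
    populations: dict[str, float]  # fractions of strand 1 summing to 1
    ss2_free: float


def _first_order_matrix(rates: RateSet, ss2: float, bimolecular: bool) -> np.ndarray:
    """4-state kinetic matrix in CS_IF_STATE_ORDER with linearized annealing."""
    anneal = ss2 if bimolecular else 1.0
    ds_anti, ds_syn, ss_syn, ss_anti = 0, 1, 2, 3
    K = np.zeros((4, 4))

    def add(i, j, k):  # j -> i
        K[i, j] += k

    add(ds_syn, ds_anti, rates.k2)
    add(ds_anti, ds_syn, rates.k_m2)
    add(ss_anti, ss_syn, rates.k1)
    add(ss_syn, ss_anti, rates.k_m1)
    add(ds_anti, ss_anti, rates.kon_anti * anneal)
    add(ss_anti, ds_anti, rates.koff_anti)
    add(ds_syn, ss_syn, rates.kon_syn * anneal)
    add(ss_syn, ds_syn, rates.koff_syn)
    K[np.diag_indices(4)] = 0.0
    K[np.diag_indices(4)] -= K.sum(axis=0)
    return K


def equilibrium_populations(
    rates: RateSet, system: HybridizationSystem
) -> EquilibriumState:
    """Equilibrium concentrations of the four strand-1 species and free ss2.

    For bimolecular systems the steady state of the nonlinear network is
    found exactly by solving the scalar mass balance for the free
    complementary-strand concentration: at fixed [ss2] the strand-1
    species form a first-order network whose stationary distribution is
    computed analytically, and [ss2] is bracketed by conservation of the
    second strand.
    """
    all_rates = [
        rates.k1, rates.k_m1, rates.k2, rates.k_m2,
        rates.kon_anti, rates.koff_anti, rates.kon_syn, rates.koff_syn,
    ]
    if all(r == 0 for r in all_rates):
        raise ValueError("no equilibration possible: all rates are zero")

    if not system.bimolecular:
        K = _first_order_matrix(rates, 1.0, bimolecular=False)
        _check_single_closed_class(K, CS_IF_STATE_ORDER)
        pi = stationary_distribution(K)
        conc = {n: float(system.Ct * p) for n, p in zip(CS_IF_STATE_ORDER, pi)}
        conc["ss2"] = 0.0
        pops = {n: float(p) for n, p in zip(CS_IF_STATE_ORDER, pi)}
        return EquilibriumState(conc, pops, 0.0)

    def duplex_fraction(ss2: float) -> float:
        K = _first_order_matrix(rates, ss2, bimolecular=True)
        pi = stationary_distribution(K)
        return float(pi[0] + pi[1])

    if system.ss2_total == 0 or not (rates.kon_anti > 0 or rates.kon_syn > 0):
        ss2 = system.ss2_total
    else:
        def balance(ss2: float) -> float:
            return ss2 + system.Ct * duplex_fraction(ss2) - system.ss2_total

        lo, hi = 0.0, system.ss2_total
        if balance(hi) <= 0:
            ss2 = hi
        else:
            ss2 = brentq(balance, lo, hi, xtol=1e-16, rtol=1e-14)

    K = _first_order_matrix(rates, ss2, bimolecular=True)
    _check_single_closed_class(K, CS_IF_STATE_ORDER)
    pi = stationary_distribution(K)
    conc = {n: float(system.Ct * p) for n, p in zip(CS_IF_STATE_ORDER, pi)}
    conc["ss2"] = float(ss2)
    pops = {n: float(p) for n, p in zip(CS_IF_STATE_ORDER, pi)}

    # mass conservation of strand 1 (exact by construction) and strand 2
    duplex = conc["ds_anti"] + conc["ds_syn"]
    if abs(ss2 + duplex - system.ss2_total) > 1e-9 * max(system.Ct, 1e-30):
        raise RuntimeError("strand-2 mass balance violated in equilibrium solve")
    return EquilibriumState(conc, pops, float(ss2))


def pseudo_first_order(
    rates: RateSet,
    system: HybridizationSystem,
    nmr_params: Mapping[str, Mapping[str, float]] | None = None,
    detailed_balance: bool = False,
) -> ExchangeModel:
    """Linearize the bimolecular annealing steps at the equilibrium [ss2].

    Returns a four-state :class:`ExchangeModel` in the fixed state order
    whose stationary populations equal :func:`equilibrium_populations`.
    ``nmr_params`` optionally supplies ``dw`` (ppm), ``R1`` and ``R2``
    per state name; they default to zero.
    """
    eq = equilibrium_populations(rates, system)
    if system.bimolecular:
        ss2 = eq.ss2_free
        if ss2 <= 0 and (rates.kon_anti > 0 or rates.kon_syn > 0):
            raise ValueError(
                "equilibrium free complementary strand concentration is zero; "
                "annealing direction undefined"
            )
        kon_anti_fo = rates.kon_anti * ss2
        kon_syn_fo = rates.kon_syn * ss2
    else:
        kon_anti_fo = rates.kon_anti
        kon_syn_fo = rates.kon_syn

    nmr_params = nmr_params or {}
    states = []
    for name in CS_IF_STATE_ORDER:
        p = nmr_params.get(name, {})
        states.append(
            SpectroState(
                name=name,
                population=eq.populations[name],
                dw=p.get("dw", 0.0),
                R1=p.get("R1", 0.0),
                R2=p.get("R2", 0.0),
            )
        )
    model_rates = {
        ("ds_anti", "ds_syn"): rates.k2,
        ("ds_syn", "ds_anti"): rates.k_m2,
        ("ss_syn", "ss_anti"): rates.k1,
        ("ss_anti", "ss_syn"): rates.k_m1,
        ("ss_anti", "ds_anti"): kon_anti_fo,
        ("ds_anti", "ss_anti"): rates.koff_anti,
        ("ss_syn", "ds_syn"): kon_syn_fo,
        ("ds_syn", "ss_syn"): rates.koff_syn,
    }
    model_rates = {k: v for k, v in model_rates.items() if v > 0}
    return ExchangeModel(
        states=states,
        rates=model_rates,
        topology="four_state_cs_if",
        detailed_balance=detailed_balance,
    )


# ---------------------------------------------------------------------------
# chemical-shift-perturbation population estimate
# ---------------------------------------------------------------------------


class EsPopulationEstimate(NamedTuple):
    population: float  # clipped to [0, 1]
    raw: float
    out_of_range: bool


def es_population_from_shift(
    w_obs: float, w_gs: float, w_es: float
) -> EsPopulationEstimate:
    """Excited-state population from a fast-exchange-averaged shift.

    The observed shift is the population-weighted average of the ground
    and excited-state shifts, so p_ES = (w_obs - w_GS)/(w_ES - w_GS).
    Values outside [0, 1] are clipped and flagged.
    """
    if w_gs == w_es:
        raise ValueError("w_GS equals w_ES; population is undetermined")
    raw = (w_obs - w_gs) / (w_es - w_gs)
    out = not (0.0 <= raw <= 1.0)
    return EsPopulationEstimate(float(min(max(raw, 0.0), 1.0)), float(raw), out)


# ---------------------------------------------------------------------------
# convenience constructors
# ---------------------------------------------------------------------------


def two_state_model(
    p_es: float,
    k_ex: float,
    dw_ppm: float | Mapping[str, float],
    R1_gs: float = 1.5,
    R2_gs: float = 15.0,
    R1_es: float | None = None,
    R2_es: float | None = None,
) -> ExchangeModel:
    """Ground state + one excited state exchanging at ``k_ex`` (s^-1)."""
    if not 0 < p_es < 1:
        raise ValueError("p_es must lie strictly between 0 and 1")
    if k_ex <= 0:
        raise ValueError("k_ex must be positive")
    kf = k_ex * p_es
    kb = k_ex * (1.0 - p_es)
    states = [
        SpectroState("GS", 1.0 - p_es, dw=0.0, R1=R1_gs, R2=R2_gs),
        SpectroState(
            "ES",
            p_es,
            dw=dw_ppm,
            R1=R1_gs if R1_es is None else R1_es,
            R2=R2_gs if R2_es is None else R2_es,
        ),
    ]
    return ExchangeModel(
        states=states,
        rates={("GS", "ES"): kf, ("ES", "GS"): kb},
        topology="two_state",
    )
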