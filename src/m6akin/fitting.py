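"""Fitting exchange models to CEST / R1rho dispersion data.

A :class:`FitSpec` pairs a parameter table with a builder that turns a
parameter dictionary into an :class:`~m6akin.exchange_models.ExchangeModel`.
Every non-linked parameter is shared across all datasets of a global
fit; per-probe chemical-shift offsets are separate named parameters
(``dw_<probe>``) feeding the model's per-probe shift table.

Optimization is bounded trust-region nonlinear least squares with a
configurable number of multi-starts drawn log-uniformly around the
initial guess.  Parameter uncertainties come either from the Jacobian
covariance at the optimum (always reported) or from a Monte Carlo
resampling of the best-fit curve with Gaussian noise
(:func:`monte_carlo_errors`, 500 iterations by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .bloch_mcconnell import (
    CESTProfile,
    R1rhoProfile,
    simulate_cest,
    simulate_r1rho,
)
from .exchange_models import (
    ExchangeModel,
    NucleusContext,
    SpectroState,
    two_state_model,
)

__all__ = [
    "Parameter",
    "FitSpec",
    "FitResult",
    "Dataset",
    "fit_profiles",
    "monte_carlo_errors",
    "reduced_chi2",
    "compare_topologies",
    "TopologyComparison",
    "two_state_fitspec",
    "three_state_fitspec",
]


@dataclass
class Parameter:
    """One model parameter: free (vary within bounds), or frozen.

    A "frozen with window" parameter (the constrained-fit idiom where a
    predetermined value may float by its experimental uncertainty) is
    expressed as ``vary=True`` with ``lower/upper = value -/+ sd``.
    """

    value: float
    vary: bool = True
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.vary and not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("free parameters require finite bounds")
        if self.vary and not (self.lower <= self.value <= self.upper):
            raise ValueError(
                f"initial value {self.value} outside bounds "
                f"[{self.lower}, {self.upper}]"
            )

    @classmethod
    def frozen_with_window(cls, value: float, sd: float) -> "Parameter":
        return cls(value=value, vary=True, lower=value - sd, upper=value + sd)


@dataclass
class FitSpec:
    """Parameters plus a builder mapping them to an exchange model."""

    topology: str
    params: dict[str, Parameter]
    builder: Callable[[Mapping[str, float]], ExchangeModel]
    linked: dict[str, Callable[[Mapping[str, float]], float]] = field(
        default_factory=dict
    )
    n_starts: int = 8
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.params) & set(self.linked)
        if overlap:
            raise ValueError(f"parameters both free/frozen and linked: {overlap}")

    @property
    def free_names(self) -> list[str]:
        return [n for n, p in self.params.items() if p.vary]

    def full_params(self, free_values: Mapping[str, float]) -> dict[str, float]:
        out = {n: p.value for n, p in self.params.items()}
        out.update(free_values)
        for n, fn in self.linked.items():
            out[n] = float(fn(out))
        return out


class Dataset(NamedTuple):
    """One dispersion dataset: profile with data, context, probe label."""

    profile: CESTProfile | R1rhoProfile
    ctx: NucleusContext
    probe: str | None = None


@dataclass
class FitResult:
    params: dict[str, float]
    sd: dict[str, float]  # covariance-based, free parameters only
    mc_sd: dict[str, float] | None
    chi2_red: float
    n_points: int
    n_free: int
    residuals: np.ndarray
    converged: bool
    seed: int
    log: list[str] = field(default_factory=list)


def reduced_chi2(obs, calc, sigma, n_free: int) -> float:
    """Sum of squared sigma-normalized residuals over (N - n_free)."""
    obs = np.asarray(obs, dtype=float)
    calc = np.asarray(calc, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if not (obs.shape == calc.shape == sigma.shape):
        raise ValueError("obs, calc and sigma must have identical shapes")
    n = obs.size
    if n <= n_free:
        raise ValueError(f"need more points ({n}) than free parameters ({n_free})")
    return float(np.sum(((calc - obs) / sigma) ** 2) / (n - n_free))


def _dataset_arrays(ds: Dataset):
    prof = ds.profile
    if isinstance(prof, CESTProfile):
        obs, sigma = prof.intensities, prof.sigma
    else:
        obs, sigma = prof.r1rho, prof.sigma
    if obs is None or sigma is None:
        raise ValueError("dataset profile carries no data/uncertainty columns")
    return np.asarray(obs, float), np.asarray(sigma, float)


def _simulate_dataset(model: ExchangeModel, ds: Dataset) -> np.ndarray:
    if isinstance(ds.profile, CESTProfile):
        return simulate_cest(model, ds.ctx, ds.profile, probe=ds.probe)
    return simulate_r1rho(model, ds.ctx, ds.profile, probe=ds.probe)


def _residuals(spec: FitSpec, datasets: Sequence[Dataset], free: Mapping[str, float]):
    params = spec.full_params(free)
    model = spec.builder(params)
    parts = []
    for ds in datasets:
        obs, sigma = _dataset_arrays(ds)
        calc = _simulate_dataset(model, ds)
        parts.append((calc - obs) / sigma)
    return np.concatenate(parts)


def _pack(spec: FitSpec):
    """Internal optimization coordinates: log10 for strictly positive params."""
    names = spec.free_names
    logs = [spec.params[n].lower > 0 for n in names]

    def to_internal(values):
        return np.array(
            [math.log10(v) if lg else v for v, lg in zip(values, logs)]
        )

    def to_external(x):
        return {
            n: (10.0 ** xi if lg else float(xi))
            for n, xi, lg in zip(names, x, logs)
        }

    lo = to_internal([spec.params[n].lower for n in names])
    hi = to_internal([spec.params[n].upper for n in names])
    x0 = to_internal([spec.params[n].value for n in names])
    return names, to_external, x0, lo, hi


def fit_profiles(
    datasets: Sequence[Dataset] | Dataset,
    spec: FitSpec,
    max_nfev: int | None = None,
) -> FitResult:
    """Global bounded least-squares fit of one or more profiles.

    Minimizes the sum over all datasets of ((obs - calc)/sigma)^2 with
    all parameters shared and linked constraints re-evaluated at every
    iterate.  Runs ``spec.n_starts`` trust-region solves from
    log-uniformly perturbed initial guesses and keeps the best.
    """
    if isinstance(datasets, Dataset):
        datasets = [datasets]
    names, to_external, x0, lo, hi = _pack(spec)
    if not names:
        raise ValueError("no free parameters to fit")
    rng = np.random.default_rng(spec.seed)
    log: list[str] = []

    def fun(x):
        return _residuals(spec, datasets, to_external(x))

    best = None
    n_converged = 0
    for start in range(spec.n_starts):
        if start == 0:
            xs = x0.copy()
        else:
            span = np.minimum(hi - lo, 1.0)
            xs = np.clip(x0 + rng.uniform(-0.5, 0.5, size=x0.size) * span, lo, hi)
        try:
            res = least_squares(
                fun, xs, bounds=(lo, hi), method="trf", max_nfev=max_nfev
            )
        except (FloatingPointError, np.linalg.LinAlgError) as exc:
            log.append(f"start {start}: solver failure ({exc})")
            continue
        if res.status > 0:
            n_converged += 1
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimization starts failed")

    converged = n_converged > 0
    if not converged:
        log.append("no start converged within the budget; best point reported")

    free = to_external(best.x)
    params = spec.full_params(free)
    n_points = best.fun.size
    n_free = len(names)
    chi2 = reduced_chi2(
        np.zeros(n_points), best.fun, np.ones(n_points), n_free
    )  # residuals are already sigma-scaled

    # covariance in external coordinates via the internal Jacobian and the
    # chain rule d(external)/d(internal) = ln(10) * value for log params
    sd = {}
    try:
        JTJ = best.jac.T @ best.jac
        cov = np.linalg.pinv(JTJ)
        scale = np.array(
            [
                params[n] * math.log(10.0) if spec.params[n].lower > 0 else 1.0
                for n in names
            ]
        )
        sd = {
            n: float(np.sqrt(max(cov[i, i], 0.0)) * scale[i])
            for i, n in enumerate(names)
        }
    except np.linalg.LinAlgError:
        log.append("covariance estimation failed")

    # record constraint satisfaction at the optimum
    for lname, fn in spec.linked.items():
        log.append(f"linked {lname} = {params[lname]:.6g} at optimum")

    return FitResult(
        params=params,
        sd=sd,
        mc_sd=None,
        chi2_red=chi2,
        n_points=n_points,
        n_free=n_free,
        residuals=best.fun,
        converged=converged,
        seed=spec.seed,
        log=log,
    )


def monte_carlo_errors(
    datasets: Sequence[Dataset] | Dataset,
    spec: FitSpec,
    best: FitResult,
    n_iter: int = 500,
    seed: int | None = None,
) -> dict[str, float]:
    """Monte Carlo parameter uncertainties.

    The best-fit curve is resampled ``n_iter`` times with Gaussian noise
    of the per-point sigma, refit, and the standard deviation of the
    refit parameters returned.  Results are stored on ``best.mc_sd``.
    """
    if isinstance(datasets, Dataset):
        datasets = [datasets]
    if not best.converged:
        raise ValueError("Monte Carlo errors require a converged best fit")
    rng = np.random.default_rng(best.seed if seed is None else seed)
    model = spec.builder(best.params)
    curves = [_simulate_dataset(model, ds) for ds in datasets]
    sigmas = [_dataset_arrays(ds)[1] for ds in datasets]

    samples: dict[str, list[float]] = {n: [] for n in spec.free_names}
    n_failed = 0
    for _ in range(n_iter):
        resampled = []
        for ds, curve, sigma in zip(datasets, curves, sigmas):
            noisy = curve + rng.normal(0.0, sigma)
            prof = _replace_data(ds.profile, noisy)
            resampled.append(Dataset(prof, ds.ctx, ds.probe))
        mc_spec = FitSpec(
            topology=spec.topology,
            params={
                n: Parameter(
                    value=best.params[n] if p.vary else p.value,
                    vary=p.vary,
                    lower=p.lower,
                    upper=p.upper,
                )
                for n, p in spec.params.items()
            },
            builder=spec.builder,
            linked=spec.linked,
            n_starts=1,
            seed=int(rng.integers(2**31 - 1)),
        )
        try:
            res = fit_profiles(resampled, mc_spec)
        except (RuntimeError, FloatingPointError):
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        for n in samples:
            samples[n].append(res.params[n])

    if n_failed > 0.2 * n_iter:
        best.log.append(
            f"Monte Carlo: {n_failed}/{n_iter} refits failed to converge"
        )
    mc_sd = {
        n: float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        for n, vals in samples.items()
    }
    best.mc_sd = mc_sd
    return mc_sd


def _replace_data(profile, values):
    if isinstance(profile, CESTProfile):
        return CESTProfile(
            probe=profile.probe,
            b1_hz=profile.b1_hz,
            offset_hz=profile.offset_hz,
            trelax=profile.trelax,
            intensities=values,
            sigma=profile.sigma,
            init_mode=profile.init_mode,
            b1_inhomogeneity=profile.b1_inhomogeneity,
        )
    return R1rhoProfile(
        probe=profile.probe,
        b1_hz=profile.b1_hz,
        offset_hz=profile.offset_hz,
        r1rho=values,
        sigma=profile.sigma,
        alignment=profile.alignment,
    )


# ---------------------------------------------------------------------------
# topology selection
# ---------------------------------------------------------------------------


class TopologyComparison(NamedTuple):
    table: list[dict]
    best: str | None
    indistinguishable: bool
    notes: list[str]


def compare_topologies(
    datasets: Sequence[Dataset],
    candidates: Sequence[FitSpec],
) -> TopologyComparison:
    """Fit every candidate topology and rank by information criteria.

    AIC/BIC with Gaussian likelihood (chi^2 + penalty) stand in for the
    Bayesian information-criterion weights of full posterior model
    selection; Akaike-style relative weights are reported and the model
    with the largest weight flagged.  Weight differences below 0.01 are
    reported as indistinguishable rather than broken.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate specs")
    notes: list[str] = []
    rows = []
    for spec in candidates:
        label = spec.name or spec.topology
        try:
            res = fit_profiles(datasets, spec)
        except RuntimeError as exc:
            notes.append(f"{label}: excluded (failed: {exc})")
            continue
        if not res.converged:
            notes.append(f"{label}: excluded (non-converged)")
            continue
        chi2_total = float(np.sum(res.residuals**2))
        k = res.n_free
        n = res.n_points
        rows.append(
            {
                "name": label,
                "topology": spec.topology,
                "chi2": chi2_total,
                "chi2_red": res.chi2_red,
                "n_free": k,
                "aic": chi2_total + 2 * k,
                "bic": chi2_total + k * math.log(n),
                "result": res,
            }
        )
    if not rows:
        raise RuntimeError("no candidate converged")
    aic_min = min(r["aic"] for r in rows)
    raw = [math.exp(-0.5 * (r["aic"] - aic_min)) for r in rows]
    total = sum(raw)
    for r, w in zip(rows, raw):
        r["weight"] = w / total
    rows.sort(key=lambda r: -r["weight"])
    indist = len(rows) > 1 and rows[0]["weight"] - rows[1]["weight"] < 0.01
    best = None if indist else rows[0]["name"]
    return TopologyComparison(rows, best, indist, notes)


# ---------------------------------------------------------------------------
# spec factories for the standard topologies
# ---------------------------------------------------------------------------


def _dw_map(params: Mapping[str, float], state_tag: str, probes) -> dict | float:
    if len(probes) == 1:
        return params[f"dw_{state_tag}_{probes[0]}"]
    return {p: params[f"dw_{state_tag}_{p}"] for p in probes}


def two_state_fitspec(
    p_es: float = 0.02,
    k_ex: float = 500.0,
    dw: Mapping[str, float] | float = 2.0,
    R1: float = 1.5,
    R2: float = 15.0,
    equal_r2: bool = True,
    R2_es: float | None = None,
    seed: int = 0,
    n_starts: int = 8,
    frozen: Sequence[str] = (),
) -> FitSpec:
    """FitSpec for ground state + one excited state.

    ``dw`` may be a scalar (single probe ``"C"``) or a mapping of probe
    label to initial shift offset.  Names in ``frozen`` are held fixed.
    """
    dw_init = dict(dw) if isinstance(dw, Mapping) else {"C": float(dw)}
    probes = tuple(dw_init)
    params = {
        "p_es": Parameter(p_es, lower=1e-4, upper=0.5),
        "k_ex": Parameter(k_ex, lower=1.0, upper=1e5),
        "R1": Parameter(R1, lower=0.01, upper=20.0),
        "R2": Parameter(R2, lower=0.1, upper=300.0),
    }
    for probe, val in dw_init.items():
        params[f"dw_ES_{probe}"] = Parameter(val, lower=-15.0, upper=15.0)
    if not equal_r2:
        params["R2_es"] = Parameter(
            R2 if R2_es is None else R2_es, lower=0.1, upper=300.0
        )
    for name in frozen:
        params[name].vary = False

    def builder(p: Mapping[str, float]) -> ExchangeModel:
        return two_state_model(
            p_es=p["p_es"],
            k_ex=p["k_ex"],
            dw_ppm=_dw_map(p, "ES", probes),
            R1_gs=p["R1"],
            R2_gs=p["R2"],
            R2_es=p.get("R2_es"),
        )

    return FitSpec(
        topology="two_state",
        params=params,
        builder=builder,
        seed=seed,
        n_starts=n_starts,
        name="two_state",
    )


def _pairwise_rates(kex: float, pa: float, pb: float):
    """Split an exchange rate over one edge by the two populations."""
    tot = pa + pb
    return kex * pb / tot, kex * pa / tot


def three_state_fitspec(
    topology: str,
    p1: float = 0.02,
    p2: float = 0.05,
    k_ex_a: float = 500.0,
    k_ex_b: float = 1000.0,
    k_ex_c: float = 200.0,
    dw1: Mapping[str, float] | float = 2.0,
    dw2: Mapping[str, float] | float = 4.0,
    R1: float = 1.5,
    R2: float = 15.0,
    seed: int = 0,
    n_starts: int = 8,
    frozen: Sequence[str] = (),
) -> FitSpec:
    """FitSpec for the three-state topologies.

    ``linear3``: GS <-> ES1 <-> ES2 (edge a: GS-ES1, edge b: ES1-ES2).
    ``star3``:   ES1 <-> GS <-> ES2 (edge a: GS-ES1, edge b: GS-ES2).
    ``triangular3``: both plus a direct ES1-ES2 edge (edge c); the
    populations-plus-edge-rate parameterization satisfies detailed
    balance edge-wise by construction.
    """
    if topology not in ("linear3", "star3", "triangular3"):
        raise ValueError(f"not a three-state topology: {topology!r}")
    dw1m = dict(dw1) if isinstance(dw1, Mapping) else {"C": float(dw1)}
    dw2m = dict(dw2) if isinstance(dw2, Mapping) else {"C": float(dw2)}
    if tuple(dw1m) != tuple(dw2m):
        raise ValueError("dw1 and dw2 must cover the same probes")
    probes = tuple(dw1m)
    params = {
        "p1": Parameter(p1, lower=1e-4, upper=0.5),
        "p2": Parameter(p2, lower=1e-4, upper=0.5),
        "k_ex_a": Parameter(k_ex_a, lower=1.0, upper=1e5),
        "k_ex_b": Parameter(k_ex_b, lower=1.0, upper=1e5),
        "R1": Parameter(R1, lower=0.01, upper=20.0),
        "R2": Parameter(R2, lower=0.1, upper=300.0),
    }
    if topology == "triangular3":
        params["k_ex_c"] = Parameter(k_ex_c, lower=1.0, upper=1e5)
    for probe, val in dw1m.items():
        params[f"dw_ES1_{probe}"] = Parameter(val, lower=-15.0, upper=15.0)
    for probe, val in dw2m.items():
        params[f"dw_ES2_{probe}"] = Parameter(val, lower=-15.0, upper=15.0)
    for name in frozen:
        params[name].vary = False

    def builder(p: Mapping[str, float]) -> ExchangeModel:
        pg = 1.0 - p["p1"] - p["p2"]
        if pg <= 0:
            raise FloatingPointError("excited-state populations exceed 1")
        pops = {"GS": pg, "ES1": p["p1"], "ES2": p["p2"]}
        rates: dict[tuple[str, str], float] = {}
        if topology == "linear3":
            edges = [("GS", "ES1", "k_ex_a"), ("ES1", "ES2", "k_ex_b")]
        elif topology == "star3":
            edges = [("GS", "ES1", "k_ex_a"), ("GS", "ES2", "k_ex_b")]
        else:
            edges = [
                ("GS", "ES1", "k_ex_a"),
                ("GS", "ES2", "k_ex_b"),
                ("ES1", "ES2", "k_ex_c"),
            ]
        for a, b, key in edges:
            kf, kb = _pairwise_rates(p[key], pops[a], pops[b])
            rates[(a, b)] = kf
            rates[(b, a)] = kb
        states = [
            SpectroState("GS", pops["GS"], dw=0.0, R1=p["R1"], R2=p["R2"]),
            SpectroState(
                "ES1", pops["ES1"], dw=_dw_map(p, "ES1", probes),
                R1=p["R1"], R2=p["R2"],
            ),
            SpectroState(
                "ES2", pops["ES2"], dw=_dw_map(p, "ES2", probes),
                R1=p["R1"], R2=p["R2"],
            ),
        ]
        return ExchangeModel(states=states, rates=rates, topology=topology)

    return FitSpec(
        topology=topology,
        params=params,
        builder=builder,
        seed=seed,
        n_starts=n_starts,
        name=topology,
    )
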