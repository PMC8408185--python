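import numpy as np
import pytest

from m6akin import (
    CESTProfile,
    HybridizationSystem,
    NucleusContext,
    RateSet,
    two_state_model,
)


@pytest.fixture
def ctx13c() -> NucleusContext:
    return NucleusContext("13C", 600.0)


@pytest.fixture
def ss_iso_model():
    """Unpaired-strand isomerization: 9% anti, k_ex 600 s^-1, +3 ppm C10."""
    return two_state_model(0.09, 600.0, {"C10": 3.0, "C2": -0.6},
                           R1_gs=2.0, R2_gs=20.0)


@pytest.fixture
def cs_if_rates() -> RateSet:
    """A thermodynamically closed four-state CS+IF rate set.

    High-temperature duplex-hybridization conditions: ~9% anti isomer
    in the single strand with millisecond isomerization, ~1% syn
    duplex, annealing of the anti isomer twice the reference rate and a
    20-fold-penalized syn pathway closed through the cycle.
    """
    kon_ref, koff_ref = 1e5, 20.0
    k1, k_m1 = 540.0, 5460.0
    k2, k_m2 = 5.0, 495.0
    kon_syn = kon_ref / 20.0
    koff_syn = kon_syn * (k_m1 / k1) * (koff_ref / (2 * kon_ref)) * (k_m2 / k2)
    return RateSet(
        k1=k1, k_m1=k_m1, k2=k2, k_m2=k_m2,
        kon_anti=2 * kon_ref, koff_anti=koff_ref,
        kon_syn=kon_syn, koff_syn=koff_syn,
        kon_ref=kon_ref, koff_ref=koff_ref,
    )


@pytest.fixture
def duplex_system() -> HybridizationSystem:
    return HybridizationSystem(Ct=2e-4, ss2_total=2e-4, temperature=328.15)


def make_cest_dataset(model, ctx, sigma=0.005, seed=0, n_offsets=50,
                      powers=(20.0,), span_ppm=6.0, probe=None):
    """Synthetic CEST dataset with Gaussian noise (helper for fit tests)."""
    from m6akin import Dataset, simulate_cest

    offsets = ctx.ppm_to_hz(np.linspace(-span_ppm, span_ppm, n_offsets))
    grid = CESTProfile.from_grid(list(powers), offsets, trelax=0.2)
    clean = simulate_cest(model, ctx, grid, probe=probe)
    rng = np.random.default_rng(seed)
    grid.intensities = clean + rng.normal(0.0, sigma, clean.shape)
    grid.sigma = np.full(clean.shape, sigma)
    return Dataset(grid, ctx, probe)
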