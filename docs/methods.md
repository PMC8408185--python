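# Methods

`m6akin` models how N6-methyladenosine (m6A) reshapes the kinetics of
nucleic-acid hybridization and conformational transitions, and provides
the NMR machinery (chemical exchange saturation transfer, CEST, and
off-resonance rotating-frame relaxation, R1rho) used to measure the
underlying exchange processes. This note records the models, the
numerical choices, and the limits of what the synthetic-data tests can
show.

## The four-state CS+IF kinetic scheme

The methylamino group of m6A interconverts between a *syn* isomer
(dominant when the base is unpaired, incompatible with Watson-Crick
pairing) and an *anti* isomer (dominant in the duplex, pairing
competent). Hybridization of a methylated strand with its complement
therefore couples two isomerization equilibria to two annealing steps:

```
ds(anti)  <-- k_m2 / k2 -->   ds(syn)
   ^                             ^
kon_anti*[ss2] / koff_anti   kon_syn*[ss2] / koff_syn
   |                             |
ss(anti)  <-- k_m1 / k1 -->   ss(syn)
```

* conformational selection (CS): the single strand first isomerizes to
  *anti* (k1/k_m1), then anneals (kon_anti/koff_anti);
* induced fit (IF): the *syn* strand anneals first to a singly
  H-bonded, mismatch-like duplex intermediate (kon_syn/koff_syn), which
  then isomerizes (k_m2/k2; k2 is the anti->syn direction).

Setting `bimolecular=False` removes the `[ss2]` factors and the same
scheme describes unimolecular conformational transitions (hairpin or
apical-loop switches) where the "duplex" states are the paired
conformation.

Mass-action ODEs for the CS, IF and full CS+IF species sets are
integrated with LSODA at rtol 1e-8 and atol 1e-12·Ct; strand mass
conservation is asserted at every output time to 1e-9·Ct.

**Equilibria.** At fixed free complement concentration `[ss2]` the four
strand-1 species form a first-order network whose stationary
distribution is computed analytically (null space of the rate matrix).
The bimolecular steady state is found exactly by bracketing the scalar
mass-balance equation for `[ss2]` with Brent's method (xtol 1e-16)
rather than by iterating rates and concentrations to a fixed point;
the two formulations share the same solution, the root solve just
reaches it directly. Populations below 1e-12 are flattened to exactly
zero to keep stationary solves well conditioned, and states with no
rates in or out are treated as zero-population spectators (this is how
a pure-CS rate set embeds in the four-state container).

**Apparent rates.** The effective two-state annealing/melting constants
are extracted by least squares on the total-duplex time course against
the two-state hybridization model d[ds]/dt = kon·[ss1][ss2] − koff·[ds].
That model is a Riccati equation with a closed-form solution, which is
used as the fit model (exact, and robust for extreme trial rates; the
fitted melting rate is additionally bounded within e±30 of its initial
guess because a trajectory that runs to completion contains almost no
melting information). The fitting grid is 60 log-spaced points spanning
1e-3 to 1e3 estimated relaxation times plus t = 0. Simulations start
from 100% *syn* single strand; starting instead from pre-equilibrated
isomer populations changes the extracted rates by <1% whenever
isomerization is fast relative to the pseudo-first-order annealing
rate, which is the regime the model targets. When the syn duplex
intermediate exceeds 10% of the duplex pool at equilibrium the
apparent two-state description degrades and the extraction attaches a
warning instead of failing.

For unimolecular transitions the product trajectory is fit to
A(1 − exp(−k_ex·t)) and k_ex is split into forward/backward rates by
the equilibrium product fraction.

**Flux.** The equilibrium reactive throughput of each pathway is the
harmonic mean of its sequential forward rates evaluated at equilibrium
concentrations — CS: k1·[ss_syn] and kon_anti·[ss_anti]·[ss2]; IF:
kon_syn·[ss_syn]·[ss2] and k_m2·[ds_syn].

## The m6A-impact predictor

Given the unmethylated reference rates (kon, koff) and annealing free
energy, the predictor assumes:

* methylation destabilizes the duplex by ΔΔG (default 1.0 kcal/mol);
* the *anti* isomer hybridizes like unmethylated A: koff_anti = koff,
  and kon_anti follows from closing the thermodynamic cycle against
  ΔG_anneal,anti = ΔG_app − ΔG_iso,ss;
* the *syn* isomer hybridizes like a mismatch: kon_syn = kon/20, with
  koff_syn closed through the cycle (or, alternatively,
  koff_syn = 80·koff with kon_syn closed). The 20 and 80 are named
  constants in `constants.py`.

Isomerization rates (k1, k_m1, k2, k_m2) at the prediction temperature
are explicit inputs; temperature extrapolation is done separately with
the van't Hoff module so the predictor never extrapolates silently.

Two properties of this construction are worth stating plainly, because
they constrain what the predictor can and cannot show:

1. The two closure variants describe the same physical assumption and
   produce *identical* rate sets exactly when
   ΔΔG = RT·ln(20·80) + ΔG_iso,ds(syn→anti). With inputs consistent to
   within ±0.3 kcal/mol of that identity the predicted fold-changes
   agree to better than 10%; with strongly inconsistent inputs (e.g. a
   1 kcal/mol ΔΔG combined with a 3 kcal/mol duplex-isomer penalty)
   the syn-pathway rates differ ~3-fold between variants and apparent
   predictions can diverge by ~30% in IF-heavy regimes. The robustness
   test therefore samples inputs near consistency.
2. Because kon_anti is set by cycle closure,
   kon_anti/kon = exp((ΔG_iso,ss − ΔΔG)/RT) is independent of duplex
   stability. At fixed ΔΔG the predicted annealing slowdown is
   therefore nearly flat across ΔG_anneal; slowdowns beyond the
   anti-population deficit arise when hybridization (or an
   intramolecular transition) is fast enough that isomerization becomes
   rate-limiting — the regime probed by the fast-transition tests,
   where the forward-rate reduction exceeds the equilibrium isomer
   deficit several-fold.

## Bloch-McConnell simulation

Magnetization of N exchanging states (3N Cartesian components) evolves
under a time-independent generator combining exchange (the first-order
rate matrix applied to each component), relaxation (R1 on z, R2 on
x/y, decay toward zero — no thermal-recovery term, consistent with
intensities normalized to the zero-delay signal over sub-second
delays), and a continuous RF field along x with offset-dependent z
rotation. Propagation is exact: a batched eigendecomposition of the
generator per (power, offset) point, with a scipy `expm` fallback if
the eigenbasis is ill-conditioned (degenerate-eigenvalue corner
cases).

Sign conventions are applied in a single layer: CEST offsets are
Ω = ω_rf − ω_obs (minor dip of a state with shift Δω appears at +Δω);
R1rho offsets are Ω_eff = ω_obs − ω_rf (dispersion peak at −Δω). Shift
offsets are stored in ppm relative to the ground state and converted
through the probe nucleus Larmor frequency (default 600 MHz proton
field; frequency ratios 0.25145020 for 13C and 0.10136767 for 15N).

* **CEST**: magnetization starts either entirely on the ground state
  (`gs_only`, the default for non-methyl probes, matching acquisition
  without pre-equilibration) or distributed by populations
  (`equilibrated`, methyl probes); the ground-state z magnetization
  after the relaxation delay (default 200 ms) is reported normalized
  to its zero-delay value. RF-amplitude inhomogeneity is modelled as a
  discrete Gaussian over B1 (11 points spanning ±2.5σ, default σ = 10%
  of nominal when enabled, disabled at σ = 0); this is a declared
  choice, not a reproduction of any instrument's measured distribution.
* **R1rho**: magnetization is initialized along the ground-state
  effective field or the population-averaged effective field; `auto`
  chooses GS alignment when k_ex/|Δω_major| ≤ 1 and averaged alignment
  otherwise. The magnetization is propagated over a ladder of 12
  delays whose span is adapted (up to three attempts) to give an
  order-unity decay, and the rate is a monoexponential fit of the
  projection onto the alignment direction.

Not modelled: pulse shapes, proton-proton cross-relaxation, scalar
couplings, and TROSY spin-state selection; a spin-state-selective
proton CEST difference profile is handled as an ordinary two-state fit
of the supplied difference data.

## Fitting and model selection

Profiles are fit by bounded trust-region least squares on
σ-normalized residuals, with strictly positive parameters optimized in
log10 coordinates. Multi-start (default 8 starts, log-uniform
perturbations of the initial guess, seeded) guards against local
minima. All non-linked parameters are shared across the datasets of a
global fit; per-probe shift offsets are distinct named parameters
(`dw_<probe>`). Linked parameters are arbitrary callables evaluated at
every iterate — this is how a kon/koff ratio is pinned to a free
energy while the absolute scale floats. "Frozen within ±1 s.d."
constrained-fit parameters are free parameters with tight bounds.

Uncertainties: covariance-based standard errors from the Jacobian at
the optimum are always reported; Monte Carlo errors (resample the
best-fit curve with Gaussian noise of the per-point σ and refit;
default 500 iterations, seeded) are computed on request. Reduced χ² is
Σ((calc−obs)/σ)²/(N − n_free); the degrees-of-freedom divisor is used
so that a well-specified fit sits near 1.

Topology selection among two-state, linear, star-like and triangular
three-state models uses AIC/BIC with Akaike weights as a
Gaussian-likelihood stand-in for fully Bayesian information-criterion
weights; candidates that fail to converge are excluded with a note,
and weight ties below 0.01 are reported as indistinguishable. In the
provided three-state parameterization (populations plus per-edge
exchange rates) the triangular model satisfies detailed balance
edge-wise by construction; the `ExchangeModel` container itself also
accepts unconstrained triangular rate sets built directly from six
rates, and only enforces cycle closure when the `detailed_balance`
flag is set.

## Thermodynamics

* ΔG° = −RT·ln(kf/kb), R = 1.9872e-3 kcal/mol/K; annealing free
  energies are negative when favorable. Temperatures are Kelvin
  internally, Celsius at the CLI boundary.
* Decomposition: ΔG_anneal,anti = ΔG_app − ΔG_iso,ss; the methyl
  effect on the annealing step is ΔΔG = ΔG_anneal,anti − ΔG_ref.
* Cycle closure of the syn pathway: ΔG_iso,ds = −RT·ln(k_m2/k2)
  (the syn→anti direction, negative when anti is favored — its
  magnitude is the "destabilization of the syn duplex" quoted in the
  anti→syn direction), ΔG_anneal,syn = ΔG_app − ΔG_iso,ds, and the
  missing syn rate follows from the equilibrium constant. The
  full-cycle product is asserted to 1 within 1e-6.
* Modified van't Hoff analysis: ln(k/T) is regressed on
  (1/T − 1/T_hm) with T_hm the harmonic mean of the measurement
  temperatures, transmission coefficient fixed at 1; this form
  decorrelates ΔG‡(T_hm) and ΔH‡. Unweighted unless per-point rate
  errors are supplied (weights k/σ_k in log space). Extrapolation
  beyond the fitted span is allowed but flagged.
* UV melting: six-parameter fit (linear single- and double-strand
  baselines, Tm, ΔH°) of the two-state 1:1-duplex melting transition;
  the single-strand fraction is exactly 0.5 at Tm by construction.
  ΔS° = ΔH°/Tm − R·ln(Ct/2) (non-self-complementary convention;
  self-complementary duplexes are rejected with a message), and
  ΔG°(T) = ΔH° − TΔS°.
* Imino solvent exchange: the water-inversion transfer trace
  W(t) = W0 − E·W0·k_ex/(R1w−R1n)·(e^(−R1n·t) − e^(−R1w·t)) is fit for
  (k_ex, R1n) with W0, E, R1w fixed; the degenerate R1w = R1n case
  switches to the analytic limit t·e^(−R1n·t). The inversion
  efficiency is computed as E = 1 − W_inv/W_eq, which yields 1 for
  complete saturation and 2 for a perfect inversion; values outside
  [0, 1] are returned with a warning flag rather than rescaled, since
  the intended normalization of the printed convention is ambiguous.

## Synthetic data

Every generator is a pure function of (parameters, seed); generated σ
columns equal the true noise width so reduced χ² calibrates to ~1.
Default CEST noise is 0.5% of the zero-delay intensity, the order of a
triplicate zero-delay standard deviation. Offset grids span about ±3×
the largest shift offset at 75 points and 2 RF powers.

Named scenarios pin the study conditions: `ss_isomerization` (9% anti
single-strand isomer, k_ex 600 s⁻¹, +3 ppm methyl-carbon and −0.6 ppm
C2 excited-state shifts, 25 °C-like), `duplex_syn_es` (1% syn-duplex
excited state, k_ex 500 s⁻¹, +2.5 ppm C2 shift, 55 °C-like), and
`cs_if_55c` (a thermodynamically closed four-state rate set with the
anti strand annealing at twice a 1e5 M⁻¹s⁻¹ reference and a 20-fold
penalized syn pathway; single-strand isomerization at its
high-temperature-extrapolated speed, k_ex 6000 s⁻¹).

What the synthetic tests do **not** show: the generators draw from the
same forward models the fitters invert, so passing recovery tests
demonstrates numerical correctness and calibration of the machinery,
not the adequacy of two-/four-state exchange models for real nucleic
acids (peak overlap, baseline artifacts, B1 miscalibration, and
non-Gaussian intensity errors are all absent).

## Problem sizes

Test and acceptance runs use deliberately small problem sizes chosen
to exercise every code path at full numerical fidelity: dispersion
grids of 50-150 points, 100-replicate recovery sweeps, Monte Carlo
error estimates of 10-100 refits in tests (the production default
stays at 500), and kinetic time grids of 61 points over six decades.

## Known limitations

* No more than four exchange states; no scalar-coupling evolution.
* Nearest-neighbor ΔG prediction and sequence-based kon prediction are
  out of scope — genome-scale prediction tables take per-sequence kon
  and ΔG as inputs.
* No position-dependence of the methyl site within the duplex; the
  modular Watson-Crick/mismatch treatment of the two isomers assumes a
  central, fully stacked site.
* No Mg²⁺ model: salt effects enter only through user-supplied free
  energies and rates.
* The apparent-rate extraction presumes a dominant single relaxation of
  total duplex; regimes with heavy syn-duplex accumulation are flagged,
  not resolved.
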