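# m6akin

Kinetic and spectroscopic modelling of how N6-methyladenosine (m6A)
reshapes nucleic-acid hybridization and conformational transitions.

The methylamino group of m6A flips between a *syn* isomer that blocks
Watson-Crick pairing (favored ~10:1 when the base is unpaired) and an
*anti* isomer that pairs normally (favored ~100:1 in a duplex). A
methylated strand therefore hybridizes through two competing pathways:
**conformational selection** (CS: isomerize first, k1/k_m1, then anneal,
kon_anti/koff_anti) and **induced fit** (IF: anneal first into a singly
H-bonded, mismatch-like duplex, kon_syn/koff_syn, then isomerize,
k2/k_m2). This four-state scheme explains why m6A slows apparent
annealing ~5-20-fold while barely touching melting, and predicts even
larger slowdowns for fast intramolecular transitions where
isomerization becomes rate-limiting.

The package is aimed at NMR spectroscopists and kineticists working on
chemical exchange in nucleic acids. It provides:

* `exchange_models` — exchange-model containers (states, populations,
  rate matrices), equilibrium solvers for the CS+IF hybridization
  system, and pseudo-first-order linearization of the bimolecular step;
* `bloch_mcconnell` — exact N-site Bloch-McConnell simulation of CEST
  intensity profiles and off-resonance R1rho;
* `fitting` — bounded multi-start least-squares fitting of dispersion
  profiles (global, constrained, linked-ratio), Monte Carlo
  uncertainties, reduced chi-square, and AIC/BIC topology selection;
* `hybridization_kinetics` — CS / IF / CS+IF ODE integration, apparent
  two-state rate extraction, pathway-flux decomposition, and the
  forward predictor of m6A-induced rate changes (single duplexes,
  unimolecular transitions, and per-sequence tables);
* `thermodynamics` — free-energy bookkeeping, thermodynamic-cycle
  closure, modified van't Hoff analysis, UV melting-curve fits;
* `imino_exchange` — imino-proton solvent-exchange fitting;
* `synthetic_data` — seeded generators for every input, with named
  ground-truth scenarios;
* a `m6akin` command-line interface wrapping all of the above.

## Worked example

Predict how methylating a central adenosine changes the apparent
annealing and melting rates of a duplex with unmethylated annealing
rate 1e5 M⁻¹s⁻¹ and annealing free energy −6.5 kcal/mol at 55 °C,
200 µM strands:

```python
from m6akin import HybridizationSystem, predict_m6a_impact

system = HybridizationSystem(Ct=2e-4, ss2_total=2e-4, temperature=328.15)
pred = predict_m6a_impact(
    kon_ref=1e5, koff_ref=None, dG_anneal_ref=-6.5,
    iso_ss=(540.0, 5460.0),   # ss isomerization: syn->anti / anti->syn (s^-1)
    iso_ds=(5.0, 495.0),      # ds isomerization: anti->syn / syn->anti (s^-1)
    system=system,
)
print(f"apparent kon: {pred.kon_app:.3g} M^-1 s^-1")
print(f"apparent koff: {pred.koff_app:.3g} s^-1")
print(f"annealing slowdown (unmethylated/methylated): {pred.fold_kon:.2f}")
print(f"melting fold-change: {pred.fold_koff:.2f}")
```

```
apparent kon: 2.33e+04 M^-1 s^-1
apparent koff: 5.5 s^-1
annealing slowdown (unmethylated/methylated): 4.30
melting fold-change: 0.85
```

The predictor builds the full eight-rate CS+IF set by thermodynamic
cycle closure (the *anti* isomer melts like unmethylated A; the *syn*
isomer anneals 20-fold slower, like a mismatch), integrates the
four-state kinetics from 100% *syn* single strand, and fits the total
duplex time course to an apparent two-state model. Annealing slows
~4-fold — driven by the ~10-fold-rarer annealing-competent *anti*
single strand — while melting is essentially unchanged, because *anti*
dominates the duplex.

The same machinery runs from the shell, e.g.

```bash
m6akin gen-synthetic --scenario duplex_syn_es --seed 5 --outdir bundle
m6akin fit-rd bundle/duplex_syn_es_C2.csv bundle/duplex_syn_es_C10.csv \
    --out fit.json --seed 1
```

which generates a hairpin-duplex CEST scenario with a 1%-populated
syn-duplex excited state (k_ex = 500 s⁻¹, Δω_C2 = +2.5 ppm) and
recovers those parameters by a global two-probe Bloch-McConnell fit.

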