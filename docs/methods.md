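# Methods

## Reaction scheme

The base model is a single well-mixed compartment with 16 chemical species
and 16 reactions, integrated as mass-action ODEs (µM, s).  RII regulatory
subunits are treated as independent monomers occupying one of two binding
squares:

| id | species | id | species | id | species | id | species |
|----|---------|----|---------|----|---------|----|---------|
| 1 | pRII | 5 | RII·C | 9 | C | 13 | CN·pRII·cAMP |
| 2 | pRII·C | 6 | RII·cAMP·C | 10 | cAMP | 14 | AKAR4 |
| 3 | pRII·cAMP | 7 | RII·cAMP | 11 | CN | 15 | AKAR4·C |
| 4 | pRII·cAMP·C | 8 | RII | 12 | CN·pRII | 16 | pAKAR4 |

Reactions: 8 reversible binding edges (4 per square), 2 irreversible
autophosphorylation steps (RII·C → pRII·C, RII·cAMP·C → pRII·cAMP·C), CN
dephosphorylation of the two C-free phospho-species as explicit
binding + catalysis (4 reactions), and the reporter module
(AKAR4 + C ⇌ AKAR4·C → pAKAR4 + C).  The numbering is fixed so that the
RII·C + cAMP edge carries K_D56 and the RII·cAMP + C edge K_D76; K_D keys
pair the RII-containing reactant's index with the complex index.

Structural assumptions (deliberate simplifications):

1. no RII-dimer cooperativity — RII protomers are independent;
2. one lumped cAMP binding event per RII (no two-site CNB domain detail);
3. CN kinetic parameters identical for pRII and pRII·cAMP;
4. autophosphorylation rates identical with and without bound cAMP;
5. a single RII parameterisation in the base model (the α/β split reuses
   it);
6. CN acts only on C-free phospho-species — the unique assignment
   consistent with the 16-species/16-reaction scheme and three-step
   enzymatic reactions;
7. CN is constitutively active (Ca²⁺/CaM are saturating and not modeled);
8. AKAP79 is a rate regime, not a species: anchoring switches the CN
   reaction constants between a high-affinity (`_wA`) and a low-affinity
   (`_nA`) set.  Which regime applies is a property of the simulated
   condition, and both sets are part of the sampled parameter vector.

Five conservation laws (total RII, C, CN, cAMP, reporter) are emitted as
left null vectors of the stoichiometric matrix and monitored along every
trajectory (relative drift < 1e-6).

The extended model splits every RII-containing species and reaction into
α and β copies (26 species, 30 reactions) sharing C, cAMP, CN and the
reporter; the default α fraction is 0.85.  Parameters are duplicated, so
isoform-specific mutations are expressible:

* **S98A** (non-phosphorylatable inhibitor sequence): both α-pool
  autophosphorylation rate constants set to 0 — the α pool is confined to
  the unphosphorylated square.
* **S98E** (phospho-mimetic): both α-pool CN turnover numbers set to 0 in
  both AKAP regimes, and the α pool starts fully phosphorylated,
  partitioned between pRIIα and pRIIα·C.

## Default rate constants

The published supplement carrying the original table is not part of this
package's inputs, so the defaults are assembled from the quantities the
study itself measures plus a one-time qualitative calibration against its
summary statistics, then frozen:

| parameter | value | origin |
|---|---|---|
| CN·pRII (with AKAP79) kf, kr, kcat | 1.0 µM⁻¹s⁻¹, 0.91 s⁻¹, 0.45 s⁻¹ | measured K_m 1.36 µM, k_cat 0.45 s⁻¹ |
| CN·pRII (no anchor) kf, kr, kcat | 0.01, 0.74, 0.2 | K_m 94 µM; activity < 0.03 s⁻¹ at ≤ 5 µM |
| RII + C kf | 0.2 µM⁻¹s⁻¹ | fast recapture; 50× the pRII rate |
| pRII + C kf | 0.004 µM⁻¹s⁻¹ | measured 50-fold on-rate contrast |
| kr (RII·C) | 2e-4 s⁻¹ | sub-nM holoenzyme affinity |
| kr (pRII·C) | 0.02 s⁻¹ | sets the basal (0-cAMP) reporter rise |
| cAMP + RII / pRII kf, kr | 0.1, 1.0 | K_D 10 µM on free subunits |
| cAMP + holo kf, kr | 1.0, 0.1 | K_D56 = K_D24 = 0.1 µM (low) |
| C + RII·cAMP kf, kr | 1.0, 10.0 | K_D76 = 10 µM (high) |
| C + pRII·cAMP kf, kr | 0.02, 0.5 | slow capture square |
| kphos | 5 s⁻¹ | fast intramolecular step |
| AKAR4 kf, kr, kcat | 0.1, 0.9, 0.12 | K_m ≈ 10 µM; maps ~0.3 µM free C to ~19 %/min |

The cAMP affinities implement the identifiability finding that a low
K_D56 paired with a high K_D76 lets sub-stoichiometric cAMP liberate C
subunits: cAMP binds holoenzyme well and the resulting R·cAMP·C complex
releases C readily, while free R subunits do not soak up the dose.  Note
that this pattern makes the binding squares thermodynamically
inconsistent (the product of K_Ds around a square cycle differs by
direction).  That is intentional and inherited from the independent
mass-action parameterisation being fitted; with catalysis disabled the
system then relaxes to a non-equilibrium steady state with a circulating
flux, and per-edge [A][B]/[AB] = K_D holds only for Wegscheider-consistent
parameter sets (the test suite checks the equilibrium oracle on such a
set, and isolated binding pairs against the closed-form quadratic).

## Simulation and readout

Initial conditions reflect the pre-stimulus mixture: all RII
unphosphorylated and C equilibrated over the cAMP-free pools — free C is
the bracketed root of c + Σᵢ Tᵢ·c/(Kᵢ + c) = C_total (Brent's method,
xtol 1e-15; single pool reduces to the standard quadratic), the cAMP dose
enters as free cAMP at t = 0, and CN/AKAR4 start free.  For S98E the α
pool instead equilibrates through the pRII·C edge.

Integration uses LSODA (stiff/non-stiff switching) with an analytic
Jacobian, rtol 1e-6, atol 1e-10 µM, over 0–605 s sampled every 5 s.
Rate constants drawn from wide priors span orders of magnitude, hence the
stiff-capable default.  Concentrations below −1e-9 µM trigger a warning;
small negatives are clipped to zero.

The reporter readout maps the phospho-fraction
f = pAKAR4/(AKAR4 + AKAR4·C + pAKAR4) to a 520/485 emission ratio
baseline × (1 + 0.72·f); three baseline samples (f = 0) are prepended at
−15, −10, −5 s.  Peak rates are least-squares slopes of the
percent-of-full-scale signal over 30–90 s, or 30–330 s for doses
≤ 0.1 µM where the response is slow, reported per minute.  Under the
linear 72% gain map this equals percent phosphorylated reporter per
minute.

## Parameter estimation

Distance: ρ = Σᵢ(yᵢ_exp − yᵢ_sim)²/n on the 5-s grid over 0–605 s, after
min–max normalising each experimental dataset to [0, 1] and applying the
recorded transform unchanged to the simulation.  Acceptance requires
ρ < 0.01.  Two rules are available: per-dataset gating (every dataset must
pass; default) and a pooled mean-ρ variant.  The conjunctive default is
the stricter reading of "only accept parameter sets whose simulated
curves reproduce the measurements"; the original copula-based machinery
for merging datasets is out of scope.

Two stages mirror the experimental design:

1. **Reporter calibration** — the three AKAR4 constants are fitted by
   nonlinear least squares (log10 space, Levenberg–Marquardt) against six
   C-subunit-only traces spanning 0–0.4 µM C, then frozen.
2. **Rejection sampling** — the remaining 30 constants (including both CN
   regimes) are drawn from independent log-uniform priors spanning three
   orders of magnitude centred on the defaults ([d·10^-1.5, d·10^1.5];
   the symmetric reading of "three orders of magnitude around a default",
   configurable), simulated against all 12 condition datasets
   (3 mixtures × cAMP doses 0, 0.2, 1, 2 µM), and accepted or rejected.
   Failing datasets short-circuit the remaining simulations for a draw.
   Integrator failures count as rejections and are reported.

**Desk scale.**  The original estimation accepted ~15,000 parameter sets
using cluster-scale sequential machinery.  Plain rejection from the full
three-decade prior has a vanishing acceptance probability at desk scale,
so the package's recovery experiment — generate the 12 datasets from a
known parameter set with additive ratio noise σ = 0.005 (≈0.7% of full
scale, which keeps the generating set itself inside the acceptance
region), then sample — uses a prior span of 0.5 decades and 10⁴ draws
(≈1% acceptance, minutes on one CPU).  The recovery claims checked at
this scale are scale-free: every accepted set re-simulates all datasets
within threshold, the accepted ensemble's pointwise trace envelope
brackets the generating curves, and acceptance is monotone in the
threshold under a fixed draw stream.

Accepted ensembles are projected onto the extended model (base parameters
copied into both pools) to predict mutant behaviour, classified
fits-/misfits-mutant by whether every mutant-condition ρ passes 0.01, and
summarised through the eight binding K_Ds including the (K_D56, K_D76)
rank correlation.

## Assay analytics

* ³²P release: fraction = cpm_sup/(cpm_sup + cpm_pellet); per-enzyme
  activity = fraction × [S]/([E]·t), flagged outside the <10%-released
  initial-rate regime.
* Michaelis–Menten fits are unweighted nonlinear least squares (replicate
  structure is small — triplicates); standard errors from the covariance.
  Low-affinity data use a through-origin linear fit whose slope estimates
  k_cat/K_m, reporting the largest tested concentration as a lower bound
  on K_m when the relation stays linear.
* Immunoblot reference curves: Hill fits I = Imax·c^h/(K^h + c^h) by
  iterative least squares; extract lanes are inverted through the curve
  only within the reference range (extrapolation above it is refused,
  inversions below the lowest reference warn).
* Molar conversion assumes protein is 8% of tissue wet weight, density
  1.04 g/mL, and sequence molar masses of the human subunits (RIIα
  45,518 Da; RIIβ 46,303 Da; Cβ 40,623 Da) — none of these constants is
  dictated by the measurements themselves, so all are configurable; the
  defaults reproduce 5.9 µM RIIα / 1.03 µM RIIβ within ~5% and an
  RIIα:C molar ratio of ≈8.9–9.4 depending on the mass table.
* The free-C calibration maps AKAR4 rates to C concentration
  linear-through-origin up to 0.4 µM (the observed near-linear range);
  the functional form beyond it is not constrained by the package's
  inputs, so inversion above the calibrated range is refused.

## Synthetic data

Generators emit every input the pipeline consumes with the generating
truth attached: AKAR4 condition traces (5-s sampling, 605 s, 3 baseline
points, 72% gain, additive Gaussian ratio noise σ = 0.005 by default),
C-only calibration traces, Michaelis–Menten velocity tables
(multiplicative 5% noise, triplicates, 0.25–5 µM grid), Poisson-split
³²P count records, and Hill-shaped immunoblot series (multiplicative 2%
noise; 15 µg extract lanes, 48 ng band at the default 0.32%).  All
generators are deterministic under a seed.

What they do not emulate: instrument drift, injection transients,
photobleaching, well cross-talk, heteroscedastic or temporally correlated
trace noise, and image-analysis artefacts in band intensities.  Passing
recovery tests on this synthetic data therefore demonstrates the
correctness and internal consistency of the estimation machinery, not
robustness to real-instrument noise structure.

## Known limitations

* No Ca²⁺/CaM activation kinetics of CN, no RI subunits, no spatial or
  stochastic effects, no membrane geometry.
* The default rate table is a package choice consistent with the measured
  constraints, not the published supplement's table; ensemble inferences
  should be read relative to these defaults and the stated priors.
* Reporter-depletion curvature makes window-averaged rates mildly
  sublinear in free C near the top of the calibration range; the
  calibration object treats the relation as linear only inside 0.4 µM.
* Rejection ABC with conjunctive gating is conservative; at full
  three-decade prior span it needs far more draws than a desktop budget
  provides (hence the documented desk-scale protocol).
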