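# Methods

## Overview

`statescape` implements energy-landscape analysis (ELA) of multichannel
brain-activity recordings. The chain is:

1. **Binarization.** Each region-of-interest (ROI) signal is thresholded at
   its mean: active (1) above, inactive (0) at or below. A timepoint's
   activation pattern over n ROIs is one of 2^n *brain states*, encoded as an
   integer with ROI i at bit weight 2^i.
2. **Group model.** Participants of a group are concatenated and the state
   sequence is fitted with a pairwise maximum-entropy (Ising) model: the
   distribution of maximum entropy whose single-ROI and pairwise activation
   moments match the data. Its energy is
   `E(σ) = −Σ_i h_i σ_i − ½ Σ_{i≠j} J_ij σ_i σ_j` with `σ ∈ {0,1}^n`, and
   `P(σ) ∝ exp(−E(σ))`.
3. **Landscape.** States form a hypercube graph (neighbors differ in one
   ROI). Local energy minima are *basins*; steepest descent attributes every
   state to a basin's cluster; minimax path energies (Dijkstra with
   `new_cost = max(cost, E(neighbor))`) give saddles and the asymmetric
   barriers `saddle(a,b) − E(a)`; single-linkage agglomeration on saddle
   levels gives the disconnectivity dendrogram.
4. **Dynamics.** On a fixed partition with major (two lowest-energy) basins
   A1, A2 and clusters P1, P2, each participant's series yields transition
   rates TR(A→A′), TR(P→P′) and staying rates SR(A→A′), SR(P→P′), all
   normalized by the series length T, and the derived *traveling* score
   TR(A→A′)/TR(P→P′) (ease of switching; undefined, not zero, when
   TR(P→P′)=0) and *lingering* score SR(A→A′)+SR(P→P′) (tendency to stay).
5. **Statistics.** One-way ANOVA with Bonferroni-corrected pairwise Welch
   t-tests (Kruskal–Wallis alongside), chi-squared for categorical factors,
   two-way ANOVA (group × site, type-II), and OLS regression of symptom
   scores on basin characteristics.

## Assumptions

The Ising fit treats timepoints as exchangeable draws from a stationary
distribution; temporal order only matters to the dynamics layer. This is the
standard equilibrium assumption of ELA and is the reason group-level pooling
is used to reach adequate T. The fit enumerates all 2^n states, so n is
guarded at ≤ 20; the target use case is functional networks of 4–10 ROIs.
The maximum-likelihood problem is concave; the optimum is unique whenever no
ROI (or ROI pair) is constantly on/off, and the fit refuses boundary data
with an explicit error rather than diverging.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `threshold_mode` | `participant_mean` | per-ROI binarization threshold; each participant's own mean avoids inter-participant intensity bias. `group_mean` (pooled mean) is also available; both conventions are used in the ELA literature and can disagree slightly. |
| `fit tol` | 1e-6 | convergence threshold on the largest absolute moment mismatch (dimensionless activation moments). |
| `fit step` | 0.2 | gradient-ascent step; halved on likelihood decrease, regrown ×1.05 (concavity makes this safe). |
| `dynamics mode` | `direct` | consecutive-pair counting. `first_passage` counts episodes (next visit to {A1,A2} after a visit) for the transition rates; staying rates are pair counts in both modes, which keeps traveling and lingering on the same footing. |
| rate denominator | T | series length, as defined; T vs T−1 is immaterial for group contrasts. |

Tie-breaking is everywhere by lower state code (lexicographic (energy, code)
order), so basin search, descent and major-basin selection are fully
deterministic; exact energy ties have measure zero for models fitted to
real-valued data. Under this rule a flat landscape has exactly one basin
(code 0). Values exactly at threshold binarize to 0. Empirical energies
−log p are undefined (NaN + mask) for unobserved states; landscapes are
always built from model energies, with empirical energies as a diagnostic.

## Synthetic cohorts

The generator plants a known landscape: Hopfield-style storage of one binary
pattern in the ±1 spin convention (`K_ij = c·ε_i ε_j / n`, `ε = 2p−1`) plus
a small field `δ·ε/n` that makes the pattern strictly deeper than its
complement, converted exactly to the {0,1} convention (`J = 4K`,
`h_i = 2b_i − 2Σ_{j≠i}K_ij`). Full enumeration verifies the pattern and its
complement are the two lowest-energy states — the antisynchronized major
basin pair characteristic of group-level functional-network landscapes.
Defaults `c = 1.2`, `δ = 0.1` give two basins with ~58/42% cluster mass at
n = 6.

Binary sequences are drawn either i.i.d. from the exact Boltzmann
distribution or by single-flip Metropolis (burn-in 10·2^n attempts, one
recorded state per n attempts). BOLD-like signals are
`baseline + amplitude·(2σ−1) + N(0, noise_sd)` per ROI (defaults 100, 1,
0.2), so mean-thresholding recovers the states up to Gaussian tail errors.
Cohorts default to 160 timepoints per participant (~ one 5-minute
resting-state run) and 2 scanning sites assigned round-robin. Symptom-like
scores are `10 + 2·f + N(0, 0.05)` where f is the participant's realized
frequency of the deepest basin's cluster — a linear planted effect the
regression stage can recover. All randomness descends from one integer seed
via `numpy.random.SeedSequence.spawn`, making cohorts byte-reproducible.

What the generator does **not** emulate: hemodynamic response convolution
and autocorrelated scanner noise, head motion, site-dependent intensity
profiles, and inter-individual model variability beyond isotropic Gaussian
parameter perturbation. Passing tests therefore certify the machinery —
estimator correctness, search correctness, calibration of the statistics on
their own assumptions — not robustness to fMRI artifacts.

## Numerical choices

- Boltzmann normalization via log-sum-exp; probabilities renormalized to
  kill last-ulp drift so conservation checks hold at 1e-12.
- Gradient ascent from `h = logit(mean activation)`, `J = 0` with exact
  enumerated model moments; moment gap is the convergence measure because it
  is the defining property of the maximum-entropy fit. Parameter accuracy at
  a given gap depends on the Fisher conditioning of the model (at gap 1e-6 a
  planted n=6 model is recovered to ~1e-4).
- Steepest descent implemented by pointer-jumping over the best-neighbor
  map; fixed points are asserted to equal the enumerated local minima.
- Minimax Dijkstra (widest-path variant) is exact for the bottleneck
  objective; saddle matrices satisfy `saddle(a,c) ≤ max(saddle(a,b),
  saddle(b,c))`, which single-linkage agglomeration exploits.
- Pairs straddling participant-concatenation joins are excluded from every
  transition/staying count (no physical transition exists there).
- SR(P→P′) excludes pairs already counted in SR(A→A′), so the two staying
  rates never double-count; a conservation identity (staying + crossing +
  minor-cluster categories = (T−1−#joins)/T) is asserted in tests.

## Design choices that were genuinely open

- **Cluster assignment** (descent vs barrier-based): steepest descent to the
  nearest basin, the reading consistent with attributing every state to the
  basin whose domain of attraction contains it.
- **Basin frequency** counts cluster membership by default (frequencies sum
  to 1 across basins); exact basin-state visits are an option.
- **Group comparison of basin frequencies across separately fitted
  landscapes** adds a group-level random effect: all participants of a group
  share their landscape's boundary-estimation noise, which inflates one-way
  ANOVA type-I error far above nominal (≈0.4 observed at 3×20 participants,
  T=150). Calibration is nominal (≈0.04 over 200 null cohorts) when all
  participants are evaluated on one shared fitted partition. The pipeline
  defaults to own-group landscapes for fidelity to common ELA practice, but
  the calibration suite evaluates the shared-partition configuration, and
  cross-partition evaluation is the recommended sensitivity analysis for any
  real group contrast.
- **Simulation sizes** in tests and the acceptance script: exact-recovery at
  n=6; finite-sample recovery at T=1e5; oracle equivalence on 100 (descent)
  and 50 (saddle) random n=4 landscapes; calibration on 200 null cohorts and
  power on 50 contrast cohorts of 3 groups × 20 participants × T=150, the
  power contrast being couplings 1.2 vs 1.5 with Metropolis sampling (mixing
  speed, not just occupancy, carries lingering differences).

## Limitations

- Exact enumeration limits n to ~20 ROIs; no pseudo-likelihood or MCMC
  approximations for larger networks.
- No image-space preprocessing, scrubbing, or atlas handling: inputs are
  gap-free ROI-by-time tables.
- Dynamics summaries are those defined above; no dwell-time distributions or
  Markov spectral analysis.
- Landscape topology is reported numerically (tables, Newick dendrograms,
  radial profiles); no 3-D rendering.
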