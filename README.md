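# statescape

Energy-landscape analysis (ELA) of multichannel brain-activity recordings:
pairwise maximum-entropy (Ising) model fitting, basin/barrier landscape
mapping, and brain-state transition dynamics, with the group statistics used
to compare clinical populations (e.g. melancholic vs non-melancholic
depression vs healthy controls on resting-state fMRI functional networks).

## What it computes

Continuous region-of-interest (ROI) signals are binarized at each ROI's mean,
giving at every timepoint a binary *brain state* σ ∈ {0,1}^n. A group's
concatenated state sequence is fitted by maximum likelihood with the pairwise
maximum-entropy model

    E(σ) = − Σᵢ hᵢσᵢ − ½ Σᵢ≠ⱼ Jᵢⱼσᵢσⱼ,    P(σ) = e^(−E(σ)) / Σ_σ' e^(−E(σ')),

whose parameters h (ROI activity) and J (pairwise interaction) reproduce the
data's first and second activation moments exactly. The energy function over
the n-dimensional hypercube of states is then analyzed as a landscape:

- **basins** — states below all single-flip neighbors — and each basin's
  **cluster** (domain of attraction under steepest descent);
- **saddles and barriers** between basins via minimax-path Dijkstra, and the
  disconnectivity **dendrogram** (Newick export);
- per-participant **basin frequencies** and, on the two lowest-energy
  ("major") basins A1, A2 with clusters P1, P2, transition and staying rates

      TR(A→A′) = [n(A1→A2)+n(A2→A1)]/T     SR(A→A′) = [n(A1→A1)+n(A2→A2)]/T
      TR(P→P′) = [n(P1→P2)+n(P2→P1)]/T     SR(P→P′) = [n(P1→P1)+n(P2→P2)]/T

  giving the **traveling score** TR(A→A′)/TR(P→P′) and **lingering score**
  SR(A→A′)+SR(P→P′);
- group comparisons (one-way ANOVA + Bonferroni pairwise, Kruskal–Wallis,
  chi-squared, two-way group×site ANOVA) and symptom-score regressions.

Because suitable clinical recordings are rarely shareable, the package ships
a first-class synthetic-cohort generator with *planted* landscapes (a stored
activation pattern and its complement as the two deepest, antisynchronized
basins) so every stage is testable against known ground truth. See
`docs/methods.md` for the model, conventions and design choices.

## Worked example

```python
from statescape import (PlantedLandscapeSpec, make_planted_model,
                        boltzmann_distribution, assign_to_basins,
                        saddle_energies, build_dendrogram)

model = make_planted_model(PlantedLandscapeSpec(
    n_rois=6, pattern=(1, 1, 1, 0, 0, 0), coupling_strength=1.2))
table = boltzmann_distribution(model)
part = assign_to_basins(table)
saddles = saddle_energies(table, part.basin_codes)
```

Running `python examples/02_energy_landscape.py` (which does the above)
prints:

```
basins (energy ascending):
  state  7 (111000)  E = -3.700  cluster 42/64 states (65.6%)  [major]
  state 56 (000111)  E = -3.500  cluster 22/64 states (34.4%)  [major]
saddle between major basins: E = -0.000
barrier 7->56: 3.700   barrier 56->7: 3.500
dendrogram: (S7:3.7,S56:3.5);
```

The planted pattern 111000 and its complement are the two major basins; every
one of the 64 states drains into one of them; crossing from the deeper basin
costs 3.7 energy units against 3.5 the other way — the asymmetry equals the
depth difference. `examples/03_transition_dynamics.py` then scores simulated
participants on this landscape (a temporally correlated walker lingers at
0.827 vs 0.519 for an i.i.d. sampler), and
`examples/04_cohort_group_statistics.py` detects a planted coupling contrast
between groups (lingering 0.87 vs 0.79–0.81, ANOVA p ≈ 3e-10).

## Command line

The same stages are scriptable: `statescape simulate | binarize | fit |
landscape | dynamics | stats | run`, with `run` executing every stage for
every network × group from one YAML config and writing TSV/JSON/Newick
artifacts plus a manifest. Outputs are byte-identical across reruns with the
same config and seed.

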