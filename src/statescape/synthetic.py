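"""Synthetic cohorts with planted energy landscapes.

Real resting-state recordings for this analysis are not publicly deposited, so
every downstream stage is exercised on synthetic cohorts whose ground truth is
known exactly:

* a *planted* Ising model whose two lowest-energy states are a chosen
  activation pattern and its bitwise complement — the antisynchronized
  major-basin pair that group-level landscapes of functional networks exhibit;
* binary state sequences drawn from that model's Boltzmann distribution
  (i.i.d. exact sampling, or a single-flip Metropolis chain when temporal
  autocorrelation matters);
* BOLD-like continuous signals whose per-region mean-thresholding recovers the
  binary states (up to Gaussian noise), closing the loop with the binarization
  stage;
* per-group parameter perturbations and symptom-like covariates generated as a
  linear function of each participant's realized major-basin frequency, so the
  symptom-regression stage has a recoverable planted effect.

All randomness flows from one integer seed through ``numpy``'s SeedSequence
spawning, so cohorts are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import ising
from .ising import IsingModel, boltzmann_distribution, from_spin_parameters
from .landscape import assign_to_basins
from .preprocess import BinaryStateSeries, ParticipantSeries, encode_state


class PlantedLandscapeError(ValueError):
    """The requested planted minima are not the two lowest-energy states."""


@dataclass
class PlantedLandscapeSpec:
    """Recipe for an Ising model with a chosen deep-basin pattern.

    ``coupling_strength`` scales the Hopfield-style stored-pattern couplings
    (dimensionless; ~1 gives well-separated basins for n <= 12).
    ``field_strength`` is a small symmetry-breaking field making the pattern
    strictly deeper than its complement.
    """

    n_rois: int
    pattern: tuple[int, ...]
    coupling_strength: float = 1.2
    field_strength: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.pattern = tuple(int(b) for b in self.pattern)
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if len(self.pattern) != self.n_rois:
            raise ValueError("pattern length must equal n_rois")
        if any(b not in (0, 1) for b in self.pattern):
            raise ValueError("pattern must be binary")
        if self.coupling_strength <= 0:
            raise PlantedLandscapeError(
                "coupling_strength must be > 0 (zero coupling gives a flat "
                "landscape with no planted minima)"
            )


@dataclass
class CohortSpec:
    """Study-level design: groups, series length, noise, sampler.

    ``groups`` entries are (label, n_participants, perturbation_scale): each
    group's model is the base planted model plus Gaussian parameter
    perturbations of that scale (0 = identical landscapes across groups).
    ``timepoints_per_participant`` defaults to 160, the order of a single
    ~5-minute resting-state run.  Symptom-like scores are
    ``symptom_intercept + symptom_slope * f(major cluster) + N(0, symptom_noise_sd)``.
    """

    groups: list[tuple[str, int, float]]
    timepoints_per_participant: int = 160
    noise_sd: float = 0.2
    sampler: str = "exact"
    seed: int = 0
    n_sites: int = 2
    symptom_name: str = "symptom"
    symptom_slope: float = 2.0
    symptom_intercept: float = 10.0
    symptom_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("need at least one group")
        for label, n_p, scale in self.groups:
            if n_p < 1:
                raise ValueError(f"group {label!r} needs n_participants >= 1")
            if scale < 0:
                raise ValueError("perturbation scale must be >= 0")
        if self.timepoints_per_participant < 2:
            raise ValueError("timepoints_per_participant must be >= 2")
        if self.sampler not in ("exact", "metropolis"):
            raise ValueError("sampler must be 'exact' or 'metropolis'")


def make_planted_model(spec: PlantedLandscapeSpec) -> IsingModel:
    """Build an Ising model whose two deepest states are pattern & complement.

    The construction stores the pattern Hopfield-style in the +/-1 spin
    convention (K_ij = c * eps_i eps_j / n with eps = 2*pattern - 1, plus a
    small field delta * eps breaking the pattern/complement tie in the
    pattern's favor) and converts exactly to the {0,1} (h, J) convention.
    Full enumeration then verifies the planted pair really are the two
    lowest-energy states; if not (couplings too weak relative to fields), a
    :class:`PlantedLandscapeError` asks the caller to raise coupling_strength.
    """
    n = spec.n_rois
    eps = 2.0 * np.asarray(spec.pattern, dtype=float) - 1.0
    K = spec.coupling_strength * np.outer(eps, eps) / n
    np.fill_diagonal(K, 0.0)
    b = spec.field_strength * eps / n
    h, J = from_spin_parameters(b, K)
    roi_names = [f"ROI{i}" for i in range(n)]
    model = IsingModel(h=h, J=J, roi_names=roi_names)

    e = ising.all_energies(model)
    order = np.lexsort((np.arange(2**n), e))
    pattern_code = encode_state(spec.pattern)
    complement_code = pattern_code ^ (2**n - 1)
    lowest_two = set(int(c) for c in order[:2])
    if lowest_two != {pattern_code, complement_code}:
        raise PlantedLandscapeError(
            "planted pattern and complement are not the two lowest-energy "
            "states; increase coupling_strength or decrease field_strength"
        )
    if e[pattern_code] >= e[complement_code]:
        raise PlantedLandscapeError(
            "symmetry-breaking field failed to make the pattern strictly "
            "deeper than its complement"
        )
    return model


def sample_states(
    model: IsingModel,
    T: int,
    sampler: str = "exact",
    seed: int | np.random.SeedSequence = 0,
    burn_in: Optional[int] = None,
    thin: Optional[int] = None,
    origin: str = "synthetic",
) -> BinaryStateSeries:
    """Draw a length-T state sequence from the model's Boltzmann distribution.

    ``sampler='exact'`` draws i.i.d. from the fully enumerated distribution;
    ``'metropolis'`` runs a single-flip Metropolis chain (temporally
    correlated), with ``burn_in`` defaulting to 10 * 2^n flip attempts and one
    state recorded every ``thin`` (default n) attempts.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    n = model.n
    if sampler == "exact":
        table = boltzmann_distribution(model)
        if not np.isfinite(table.energies).all():
            raise ValueError("non-finite energies")
        states = rng.choice(2**n, size=T, p=table.probabilities)
    elif sampler == "metropolis":
        e = ising.all_energies(model)
        if not np.isfinite(e).all():
            raise ValueError("non-finite energies")
        burn = 10 * 2**n if burn_in is None else burn_in
        thin = n if thin is None else thin
        total = burn + T * thin
        flips = rng.integers(0, n, size=total)
        us = rng.random(size=total)
        cur = int(rng.integers(0, 2**n))
        states = np.empty(T, dtype=np.int64)
        k = 0
        for t in range(total):
            prop = cur ^ (1 << int(flips[t]))
            if us[t] < np.exp(min(0.0, e[cur] - e[prop])):
                cur = prop
            if t >= burn and (t - burn) % thin == thin - 1:
                states[k] = cur
                k += 1
        assert k == T
    else:
        raise ValueError("sampler must be 'exact' or 'metropolis'")
    return BinaryStateSeries(
        states=states, n=n, roi_names=model.roi_names, origin=origin
    )


def states_to_bold(
    series: BinaryStateSeries,
    baseline: Sequence[float] | float = 100.0,
    amplitude: Sequence[float] | float = 1.0,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    participant_id: str = "synthetic",
    group: str = "",
    site: str = "",
) -> ParticipantSeries:
    """Render a binary state sequence as noisy BOLD-like continuous signals.

    signal[t, i] = baseline_i + amplitude_i * (2*sigma[t, i] - 1) + N(0, noise_sd).
    With zero noise and balanced up/down occupancy, per-region mean
    thresholding recovers sigma exactly.
    """
    rng = np.random.default_rng(seed)
    n = series.n
    baseline = np.broadcast_to(np.asarray(baseline, dtype=float), (n,))
    amplitude = np.broadcast_to(np.asarray(amplitude, dtype=float), (n,))
    if (amplitude <= 0).any():
        raise ValueError("amplitudes must be > 0")
    bits = ((series.states[:, None] >> np.arange(n)) & 1).astype(float)
    signals = baseline + amplitude * (2.0 * bits - 1.0)
    if noise_sd > 0:
        signals = signals + rng.normal(0.0, noise_sd, size=signals.shape)
    roi_names = series.roi_names or [f"ROI{i}" for i in range(n)]
    return ParticipantSeries(
        participant_id=participant_id,
        signals=signals,
        roi_names=list(roi_names),
        group=group,
        site=site,
    )


def _perturb_model(
    model: IsingModel, scale: float, rng: np.random.Generator
) -> IsingModel:
    """Add symmetric Gaussian noise of the given scale to h and J."""
    if scale == 0:
        return model
    n = model.n
    dh = rng.normal(0.0, scale, size=n)
    dJ = rng.normal(0.0, scale, size=(n, n))
    dJ = (dJ + dJ.T) / 2.0
    np.fill_diagonal(dJ, 0.0)
    return IsingModel(h=model.h + dh, J=model.J + dJ, roi_names=model.roi_names)


def make_cohort(
    spec: CohortSpec, base: PlantedLandscapeSpec
) -> tuple[list[ParticipantSeries], pd.DataFrame, dict]:
    """Generate a full multi-group cohort with known ground truth.

    Returns (participants, metadata, truth): one :class:`ParticipantSeries`
    per participant; a metadata table (participant_id, group, site, symptom
    score); and the ground-truth dict holding the base and per-group models,
    the planted pattern, and the symptom-model coefficients.

    Each group's model is the base planted model plus Gaussian perturbations
    at that group's scale; participants are sampled independently.  The
    symptom score is a linear function of the participant's *realized*
    frequency of the deepest basin's cluster (under the participant's own
    group landscape), plus Gaussian noise.
    """
    base_model = make_planted_model(base)
    root = np.random.SeedSequence(spec.seed)
    ss_groups, ss_parts, ss_symptoms = root.spawn(3)
    group_seeds = ss_groups.spawn(len(spec.groups))

    group_models: dict[str, IsingModel] = {}
    group_partitions = {}
    for (label, _, scale), ss in zip(spec.groups, group_seeds):
        g_model = _perturb_model(base_model, scale, np.random.default_rng(ss))
        group_models[label] = g_model
        group_partitions[label] = assign_to_basins(boltzmann_distribution(g_model))

    n_total = sum(n_p for _, n_p, _ in spec.groups)
    part_seeds = iter(ss_parts.spawn(n_total))
    symptom_rng = np.random.default_rng(ss_symptoms)

    participants: list[ParticipantSeries] = []
    meta_rows = []
    pid = 0
    for label, n_p, _ in spec.groups:
        model = group_models[label]
        partition = group_partitions[label]
        deepest = partition.basin_codes[0]
        for k in range(n_p):
            ss = next(part_seeds)
            ss_sample, ss_bold = ss.spawn(2)
            series = sample_states(
                model,
                spec.timepoints_per_participant,
                sampler=spec.sampler,
                seed=ss_sample,
            )
            participant_id = f"sub-{pid:03d}"
            site = f"site{pid % spec.n_sites}"
            p = states_to_bold(
                series,
                noise_sd=spec.noise_sd,
                seed=ss_bold,
                participant_id=participant_id,
                group=label,
                site=site,
            )
            freq = np.count_nonzero(
                partition.assignment[series.states] == deepest
            ) / series.T
            score = (
                spec.symptom_intercept
                + spec.symptom_slope * freq
                + symptom_rng.normal(0.0, spec.symptom_noise_sd)
            )
            p.symptom_scores[spec.symptom_name] = float(score)
            participants.append(p)
            meta_rows.append(
                {
                    "participant_id": participant_id,
                    "group": label,
                    "site": site,
                    spec.symptom_name: float(score),
                    "true_deepest_basin_freq": freq,
                }
            )
            pid += 1

    metadata = pd.DataFrame(meta_rows)
    truth = {
        "pattern": list(base.pattern),
        "base_model": base_model.to_dict(),
        "group_models": {g: m.to_dict() for g, m in group_models.items()},
        "symptom_model": {
            "name": spec.symptom_name,
            "intercept": spec.symptom_intercept,
            "slope": spec.symptom_slope,
            "noise_sd": spec.symptom_noise_sd,
            "predictor": "frequency of deepest basin cluster (own group landscape)",
        },
    }
    return participants, metadata, truth
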