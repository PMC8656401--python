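"""Participant-level dynamics on a fixed group energy landscape.

Given a participant's binary state sequence and the group's basin partition,
this module computes the occurrence frequency of each basin's cluster and the
transition/staying rates defined on the two *major* (lowest-energy) basins
A1, A2 and their clusters P1, P2:

    TR(A->A') = [n(A1->A2) + n(A2->A1)] / T      (major transition rate)
    TR(P->P') = [n(P1->P2) + n(P2->P1)] / T      (peripheral transition rate)
    SR(A->A') = [n(A1->A1) + n(A2->A2)] / T      (major staying rate)
    SR(P->P') = [n(P1->P1) + n(P2->P2)] / T      (peripheral staying rate)

    traveling score = TR(A->A') / TR(P->P')      (a.k.a. efficiency score)
    lingering score = SR(A->A') + SR(P->P')

Counts are over consecutive timepoint pairs (t, t+1) that do not straddle a
participant-concatenation boundary; the denominator is the series length T.
SR(P->P') counts pairs staying within the same major cluster *excluding* the
pairs already counted in SR(A->A') (both timepoints sitting exactly on the
basin state), so the two staying rates never double-count a pair.

``mode='first_passage'`` replaces the transition counts by episode counts: a
transition A1->A2 is scored when the series visits A1 and its next visit to
{A1, A2} is A2 (likewise at the cluster level for TR(P->P')).  Staying rates
are direct pair counts in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .landscape import BasinPartition
from .preprocess import BinaryStateSeries


@dataclass
class DynamicsMetrics:
    """Per-participant basin frequencies and transition/staying scores.

    ``traveling`` is None (undefined) when TR(P->P') = 0 — no peripheral
    transitions at all — never silently 0 or NaN.
    """

    participant_id: str
    basin_frequency: dict[int, float]
    tr_major: float
    tr_peripheral: float
    sr_major: float
    sr_peripheral: float
    traveling: Optional[float]
    lingering: float
    n_valid_pairs: int = 0


def _valid_pair_mask(series: BinaryStateSeries) -> np.ndarray:
    """Boolean mask over pairs (t, t+1): True unless the pair crosses a join."""
    T = series.T
    mask = np.ones(max(T - 1, 0), dtype=bool)
    for b in series.segment_boundaries:
        mask[b - 1] = False
    return mask


def basin_frequency(
    series: BinaryStateSeries,
    partition: BasinPartition,
    count: str = "cluster",
) -> dict[int, float]:
    """Fraction of timepoints spent in each basin's cluster.

    ``count='cluster'`` (default) attributes a timepoint to the basin whose
    attraction domain contains its state; frequencies then sum to 1 over all
    basins (major and minor).  ``count='exact'`` counts only timepoints sitting
    exactly on the basin state itself.
    """
    if series.n != partition.n:
        raise ValueError("series and partition have different n")
    T = series.T
    if count == "cluster":
        assigned = partition.assignment[series.states]
        return {
            b: float(np.count_nonzero(assigned == b)) / T
            for b in partition.basin_codes
        }
    if count == "exact":
        return {
            b: float(np.count_nonzero(series.states == b)) / T
            for b in partition.basin_codes
        }
    raise ValueError(f"unknown count mode {count!r}")


def _first_passage_count(visits: np.ndarray, a: int, b: int) -> tuple[int, int]:
    """Episode counts (a->b, b->a): next visit within {a, b} after each visit."""
    seq = visits[np.isin(visits, (a, b))]
    ab = int(np.count_nonzero((seq[:-1] == a) & (seq[1:] == b)))
    ba = int(np.count_nonzero((seq[:-1] == b) & (seq[1:] == a)))
    return ab, ba


def transition_and_staying_rates(
    series: BinaryStateSeries,
    partition: BasinPartition,
    mode: str = "direct",
    first_passage_strict: bool = False,
) -> DynamicsMetrics:
    """Transition and staying rates on the two major basins, plus the scores.

    ``first_passage_strict`` only affects first-passage mode: when True, a
    visit to a minor cluster breaks the episode, so excursions through minor
    territory are not scored as transitions.
    """
    if series.n != partition.n:
        raise ValueError("series and partition have different n")
    if len(partition.major) < 2:
        raise ValueError("need two major basins to define transition dynamics")
    if mode not in ("direct", "first_passage"):
        raise ValueError(f"unknown mode {mode!r}")
    a1, a2 = partition.major[0], partition.major[1]
    T = series.T
    s = series.states
    cl = partition.assignment[s]  # cluster (basin code) of each timepoint
    mask = _valid_pair_mask(series)
    u, v = s[:-1][mask], s[1:][mask]
    cu, cv = cl[:-1][mask], cl[1:][mask]

    n_sa = np.count_nonzero((u == v) & ((u == a1) | (u == a2)))
    same_major_cluster = (cu == cv) & ((cu == a1) | (cu == a2))
    n_sp = np.count_nonzero(same_major_cluster) - n_sa

    if mode == "direct":
        n_ta = np.count_nonzero(((u == a1) & (v == a2)) | ((u == a2) & (v == a1)))
        n_tp = np.count_nonzero(((cu == a1) & (cv == a2)) | ((cu == a2) & (cv == a1)))
    else:
        # episode counting on the (possibly boundary-split) visit sequences
        n_ta = n_tp = 0
        edges = (0,) + series.segment_boundaries + (T,)
        for lo, hi in zip(edges, edges[1:]):
            seg_s, seg_cl = s[lo:hi], cl[lo:hi]
            if first_passage_strict:
                # truncate episodes at minor-cluster visits: split on them
                in_major = (seg_cl == a1) | (seg_cl == a2)
                breaks = np.flatnonzero(~in_major)
                pieces = np.split(np.arange(hi - lo), breaks)
            else:
                pieces = [np.arange(hi - lo)]
            for idx in pieces:
                idx = idx[(seg_cl[idx] == a1) | (seg_cl[idx] == a2)]
                ab, ba = _first_passage_count(seg_s[idx], a1, a2)
                n_ta += ab + ba
                ab, ba = _first_passage_count(seg_cl[idx], a1, a2)
                n_tp += ab + ba

    tr_major = n_ta / T
    tr_peripheral = n_tp / T
    sr_major = n_sa / T
    sr_peripheral = n_sp / T
    traveling = tr_major / tr_peripheral if tr_peripheral > 0 else None
    return DynamicsMetrics(
        participant_id=series.origin,
        basin_frequency=basin_frequency(series, partition),
        tr_major=tr_major,
        tr_peripheral=tr_peripheral,
        sr_major=sr_major,
        sr_peripheral=sr_peripheral,
        traveling=traveling,
        lingering=sr_major + sr_peripheral,
        n_valid_pairs=int(mask.sum()),
    )


def pair_count_conservation(
    series: BinaryStateSeries, partition: BasinPartition
) -> dict[str, float]:
    """Decompose all valid pairs into mutually exclusive categories (sums to
    (T - 1 - #boundary pairs)/T); used as an internal accounting check."""
    a1, a2 = partition.major[0], partition.major[1]
    s = series.states
    cl = partition.assignment[s]
    mask = _valid_pair_mask(series)
    u, v = s[:-1][mask], s[1:][mask]
    cu, cv = cl[:-1][mask], cl[1:][mask]
    T = series.T
    is_major_u = (cu == a1) | (cu == a2)
    is_major_v = (cv == a1) | (cv == a2)
    n_sa = np.count_nonzero((u == v) & ((u == a1) | (u == a2)))
    n_same_major = np.count_nonzero((cu == cv) & is_major_u)
    n_cross_major = np.count_nonzero(is_major_u & is_major_v & (cu != cv))
    n_within_minor = np.count_nonzero((cu == cv) & ~is_major_u)
    n_minor_cross = np.count_nonzero((cu != cv) & (~is_major_u | ~is_major_v))
    return {
        "sr_major": n_sa / T,
        "sr_peripheral": (n_same_major - n_sa) / T,
        "tr_peripheral": n_cross_major / T,
        "minor_cross": n_minor_cross / T,
        "within_minor": n_within_minor / T,
        "total": mask.sum() / T,
    }


def cohort_dynamics(
    series_list: Sequence[BinaryStateSeries],
    partition: BasinPartition,
    mode: str = "direct",
    metadata: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """One row of dynamics metrics per participant, against a shared partition.

    If ``metadata`` (indexed or keyed by participant_id) is given, its columns
    (group, site, symptom scores, ...) are merged onto the result.
    """
    rows = []
    for series in series_list:
        m = transition_and_staying_rates(series, partition, mode=mode)
        row = {
            "participant_id": m.participant_id,
            "tr_major": m.tr_major,
            "tr_peripheral": m.tr_peripheral,
            "sr_major": m.sr_major,
            "sr_peripheral": m.sr_peripheral,
            "traveling": m.traveling,
            "lingering": m.lingering,
        }
        for b, f in m.basin_frequency.items():
            row[f"freq_basin_{b}"] = f
        rows.append(row)
    out = pd.DataFrame(rows)
    if metadata is not None:
        meta = metadata.reset_index() if metadata.index.name == "participant_id" else metadata
        out = out.merge(meta, on="participant_id", how="left")
    return out
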