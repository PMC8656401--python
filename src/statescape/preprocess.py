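"""Binarize continuous region-of-interest (ROI) signals into brain states.

Each timepoint of an n-ROI recording is reduced to a binary activation
pattern: ROI i is "active" (1) when its signal exceeds a per-ROI threshold
(by default that ROI's own temporal mean), "inactive" (0) otherwise.  The
pattern is encoded as an integer state code with ROI i at bit weight 2**i
(0-based, in `roi_names` order), giving 2^n possible states.

Participants of a group are concatenated into one long state sequence for
group-level model fitting; the join positions are recorded so transition
counting can skip the non-physical pairs straddling two participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class ParticipantSeries:
    """One participant's continuous ROI x time signals plus metadata.

    ``signals`` is T x n (rows = timepoints, columns = ROIs, matching
    ``roi_names``).  ``symptom_scores`` carries questionnaire-style covariates
    (e.g. depression-severity or anhedonia scores) keyed by instrument name.
    """

    participant_id: str
    signals: np.ndarray
    roi_names: list[str]
    group: str = ""
    site: str = ""
    symptom_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.signals, pd.DataFrame):
            self.roi_names = list(self.signals.columns)
            self.signals = self.signals.to_numpy(dtype=np.float64)
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a T x n matrix")
        T, n = self.signals.shape
        if T < 2:
            raise ValueError("need at least 2 timepoints")
        if len(self.roi_names) != n:
            raise ValueError("roi_names must match signal columns")
        if len(set(self.roi_names)) != n:
            raise ValueError("roi_names must be unique")
        if not np.isfinite(self.signals).all():
            raise ValueError("signals must be finite (gap-free input required)")

    @property
    def n(self) -> int:
        return self.signals.shape[1]

    @property
    def T(self) -> int:
        return self.signals.shape[0]

    def subset(self, roi_names: Sequence[str]) -> "ParticipantSeries":
        """Restrict to the named ROIs, in the given order (e.g. one network)."""
        missing = [r for r in roi_names if r not in self.roi_names]
        if missing:
            raise KeyError(f"ROI(s) not present: {missing}")
        idx = [self.roi_names.index(r) for r in roi_names]
        return ParticipantSeries(
            participant_id=self.participant_id,
            signals=self.signals[:, idx],
            roi_names=list(roi_names),
            group=self.group,
            site=self.site,
            symptom_scores=dict(self.symptom_scores),
        )


@dataclass
class BinaryStateSeries:
    """Time-ordered integer state codes for one participant or a group.

    ``segment_boundaries`` holds the start index of every participant after the
    first in a concatenation; the pair (b-1, b) then crosses participants and
    must not be counted as a transition.
    """

    states: np.ndarray
    n: int
    roi_names: Optional[list[str]] = None
    origin: str = ""
    segment_boundaries: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1:
            raise ValueError("states must be 1-D")
        if (self.states < 0).any() or (self.states >= 2**self.n).any():
            raise ValueError("state code out of range for n")
        b = tuple(int(x) for x in self.segment_boundaries)
        if any(x2 <= x1 for x1, x2 in zip(b, b[1:])) or any(
            not (0 < x < len(self.states)) for x in b
        ):
            raise ValueError("segment_boundaries must be strictly increasing, in (0, T)")
        self.segment_boundaries = b

    @property
    def T(self) -> int:
        return len(self.states)


def encode_state(bits: Sequence[int]) -> int:
    """Bit vector -> integer code; ROI at position i contributes 2**i."""
    bits = np.asarray(bits)
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("bits must be 0/1")
    return int((bits.astype(np.int64) << np.arange(len(bits))).sum())


def decode_state(code: int, n: int) -> np.ndarray:
    """Integer code -> length-n bit vector (inverse of :func:`encode_state`)."""
    if not 0 <= code < 2**n:
        raise ValueError(f"code {code} out of range for n={n}")
    return (np.int64(code) >> np.arange(n)) & 1


def encode_states(bits: np.ndarray) -> np.ndarray:
    """Row-wise encoding of a T x n {0,1} matrix into T state codes."""
    bits = np.asarray(bits, dtype=np.int64)
    return (bits << np.arange(bits.shape[1])).sum(axis=1)


def binarize(
    ts: ParticipantSeries,
    threshold_mode: str = "participant_mean",
    group_means: Optional[Mapping[str, float] | Sequence[float]] = None,
    strict: bool = False,
) -> BinaryStateSeries:
    """Threshold each ROI at its mean signal and encode states.

    ``threshold_mode='participant_mean'`` (default) uses each ROI's mean over
    this participant's own timepoints; ``'group_mean'`` uses caller-supplied
    per-ROI means computed over the combined group data.  A value exactly equal
    to its threshold maps to inactive (0).

    In group_mean mode a zero-variance ROI raises if ``strict`` else warns
    (its column binarizes to a constant).
    """
    if threshold_mode == "participant_mean":
        thresholds = ts.signals.mean(axis=0)
    elif threshold_mode == "group_mean":
        if group_means is None:
            raise ValueError("group_mean mode requires group_means for every ROI")
        if isinstance(group_means, Mapping):
            missing = [r for r in ts.roi_names if r not in group_means]
            if missing:
                raise ValueError(f"group_means missing ROI(s): {missing}")
            thresholds = np.array([group_means[r] for r in ts.roi_names], dtype=float)
        else:
            thresholds = np.asarray(group_means, dtype=float)
            if thresholds.shape != (ts.n,):
                raise ValueError("group_means must supply one value per ROI")
        flat = ts.signals.std(axis=0) == 0.0
        if flat.any():
            names = [ts.roi_names[i] for i in np.flatnonzero(flat)]
            msg = f"zero-variance ROI(s) {names} binarize to a constant column"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    bits = (ts.signals > thresholds).astype(np.int64)
    return BinaryStateSeries(
        states=encode_states(bits),
        n=ts.n,
        roi_names=list(ts.roi_names),
        origin=ts.participant_id,
    )


def group_roi_means(series_list: Iterable[ParticipantSeries]) -> np.ndarray:
    """Per-ROI means over the combined timepoints of all participants."""
    series_list = list(series_list)
    _require_matching_rois([s.roi_names for s in series_list])
    stacked = np.vstack([s.signals for s in series_list])
    return stacked.mean(axis=0)


def _require_matching_rois(roi_lists) -> None:
    first = roi_lists[0]
    for other in roi_lists[1:]:
        if list(other) != list(first):
            raise ValueError(f"ROI name/order mismatch: {other} vs {first}")


def concatenate_group(
    series_list: Sequence[BinaryStateSeries], label: str = ""
) -> BinaryStateSeries:
    """Join participants' state sequences, recording the join positions."""
    if not series_list:
        raise ValueError("need at least one series")
    if any(s.n != series_list[0].n for s in series_list):
        raise ValueError("all series must have the same n")
    if series_list[0].roi_names is not None:
        _require_matching_rois([s.roi_names for s in series_list])
    states = np.concatenate([s.states for s in series_list])
    boundaries: list[int] = []
    offset = 0
    for s in series_list[:-1]:
        # carry any existing internal boundaries along, then mark the join
        boundaries.extend(b + offset for b in s.segment_boundaries)
        offset += s.T
        boundaries.append(offset)
    boundaries.extend(b + offset for b in series_list[-1].segment_boundaries)
    return BinaryStateSeries(
        states=states,
        n=series_list[0].n,
        roi_names=series_list[0].roi_names,
        origin=f"group:{label}" if label else "group",
        segment_boundaries=tuple(boundaries),
    )
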