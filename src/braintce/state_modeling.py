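"""Network-dominance state modeling of a parcellated recording.

A z-scored region x time recording is aggregated to one time series per
intrinsic network; at each timepoint the network with the highest mean
activity "dominates", provided that mean clears an amplitude threshold
(default half a standard deviation — timepoints where no network does are
discarded as noise). Averaging the full-resolution activity over the
timepoints each network dominates yields one continuous state coefficient
map per network: the subject-specific, signed representation of that
network used as a point in state space by the control computations.

Multi-run recordings are standardized and labelled per run; state maps pool
dominated timepoints across runs, and downstream transition counting never
bridges a run boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ActivityRecording",
    "DominanceSequence",
    "StateMaps",
    "DISCARDED",
    "standardize",
    "network_average",
    "dominance_sequence",
    "state_maps",
]

DISCARDED = "DISCARDED"
DEFAULT_THRESHOLD = 0.5

#: canonical ordering of the seven intrinsic networks
CANONICAL_ORDER = ("VIS", "SMN", "DAN", "SAL", "LIM", "FPN", "DMN")


@dataclass
class ActivityRecording:
    """Column-standardized region x time activity (z-units)."""

    values: np.ndarray  # (T, N)
    region_ids: list[str]
    run_boundaries: list[int] | None = None  # run start indices; first is 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("recording must be a T x N matrix")
        if len(self.region_ids) != self.values.shape[1]:
            raise ValueError("region ids do not match recording columns")
        if self.run_boundaries is None:
            self.run_boundaries = [0]
        if self.run_boundaries[0] != 0:
            raise ValueError("first run must start at index 0")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    def run_slices(self) -> list[slice]:
        starts = list(self.run_boundaries) + [self.n_timepoints]
        return [slice(a, b) for a, b in zip(starts[:-1], starts[1:])]


@dataclass
class DominanceSequence:
    """Per-timepoint winning-network labels with discards."""

    labels: list[str]
    threshold: float
    winning_means: np.ndarray  # (T,) mean activity of the winning network
    run_boundaries: list[int]

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero([lab != DISCARDED for lab in self.labels])

    def retained_pairs(self) -> list[tuple[str, str]]:
        """Consecutive retained label pairs, never bridging run boundaries.

        Within each run the retained subsequence is treated as contiguous:
        a discarded gap does not break a transition, a run boundary does.
        Self-pairs (same label twice) count as transitions.
        """
        pairs: list[tuple[str, str]] = []
        starts = list(self.run_boundaries) + [len(self.labels)]
        for a, b in zip(starts[:-1], starts[1:]):
            kept = [lab for lab in self.labels[a:b] if lab != DISCARDED]
            pairs.extend(zip(kept[:-1], kept[1:]))
        return pairs


@dataclass
class StateMaps:
    """One coefficient map per network state, with occupancy bookkeeping."""

    maps: np.ndarray  # (K, N)
    state_names: list[str]
    occupancy: np.ndarray  # (K,) dominated-timepoint counts
    total_timepoints: int
    region_ids: list[str]

    def map_of(self, name: str) -> np.ndarray:
        return self.maps[self.state_names.index(name)]


def standardize(
    raw: np.ndarray | pd.DataFrame,
    region_ids: list[str] | None = None,
    run_boundaries: list[int] | None = None,
) -> ActivityRecording:
    """Z-score each region's time series (sample SD), per run.

    Constant columns are rejected by name: a zero-variance region carries no
    dominance information and would divide by zero.
    """
    if isinstance(raw, pd.DataFrame):
        region_ids = [str(c) for c in raw.columns]
        raw = raw.to_numpy(dtype=float)
    raw = np.asarray(raw, dtype=float)
    if raw.shape[0] < 2:
        raise ValueError("need at least two timepoints to standardize")
    if region_ids is None:
        region_ids = [f"r{i}" for i in range(raw.shape[1])]
    boundaries = run_boundaries or [0]
    out = np.empty_like(raw)
    starts = list(boundaries) + [raw.shape[0]]
    for a, b in zip(starts[:-1], starts[1:]):
        block = raw[a:b]
        sd = block.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"constant region in run [{a}:{b}): {region_ids[bad[0]]}")
        out[a:b] = (block - block.mean(axis=0)) / sd
    return ActivityRecording(values=out, region_ids=region_ids, run_boundaries=boundaries)


def network_average(
    rec: ActivityRecording, partition: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Aggregate the recording to one mean time series per network.

    ``partition`` maps region id -> network label; every region must be
    assigned. Returns a (K networks x T) DataFrame whose row order follows
    the canonical network ordering where applicable, then alphabetical.
    """
    if isinstance(partition, pd.Series):
        partition = partition.to_dict()
    missing = [r for r in rec.region_ids if r not in partition]
    if missing:
        raise ValueError(f"regions without network assignment: {missing[:5]}")
    networks = sorted(
        {partition[r] for r in rec.region_ids},
        key=lambda n: (CANONICAL_ORDER.index(n) if n in CANONICAL_ORDER else len(CANONICAL_ORDER), n),
    )
    series = np.empty((len(networks), rec.n_timepoints))
    for k, net in enumerate(networks):
        cols = [i for i, r in enumerate(rec.region_ids) if partition[r] == net]
        series[k] = rec.values[:, cols].mean(axis=1)
    return pd.DataFrame(series, index=networks)


def dominance_sequence(
    network_series: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    run_boundaries: list[int] | None = None,
) -> DominanceSequence:
    """Label each timepoint with its dominating network.

    The winner is the network with the highest mean activity, retained only
    if that mean is at least ``threshold`` (in SD units); otherwise, and on
    exact ties (order-dependence would be irreproducible), the timepoint is
    DISCARDED.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    vals = network_series.to_numpy()
    names = [str(i) for i in network_series.index]
    T = vals.shape[1]
    winners = vals.argmax(axis=0)
    winning_means = vals[winners, np.arange(T)]
    tied = (vals == winning_means[None, :]).sum(axis=0) > 1
    labels = [
        DISCARDED if (winning_means[t] < threshold or tied[t]) else names[winners[t]]
        for t in range(T)
    ]
    return DominanceSequence(
        labels=labels,
        threshold=threshold,
        winning_means=winning_means,
        run_boundaries=run_boundaries or [0],
    )


def state_maps(rec: ActivityRecording, seq: DominanceSequence) -> StateMaps:
    """Average the full-resolution activity over each network's dominated timepoints.

    Networks that never dominate are dropped from the state set (their
    occupancy would be zero and no transition can involve them).
    """
    if len(seq.labels) != rec.n_timepoints:
        raise ValueError("sequence length does not match recording")
    present = [lab for lab in dict.fromkeys(seq.labels) if lab != DISCARDED]
    if not present:
        raise ValueError("no states detected: every timepoint was discarded")
    order = sorted(
        present,
        key=lambda n: (CANONICAL_ORDER.index(n) if n in CANONICAL_ORDER else len(CANONICAL_ORDER), n),
    )
    labels_arr = np.asarray(seq.labels, dtype=object)
    maps = np.empty((len(order), rec.values.shape[1]))
    occupancy = np.empty(len(order), dtype=int)
    for k, name in enumerate(order):
        rows = labels_arr == name
        occupancy[k] = int(rows.sum())
        maps[k] = rec.values[rows].mean(axis=0)
    return StateMaps(
        maps=maps,
        state_names=order,
        occupancy=occupancy,
        total_timepoints=rec.n_timepoints,
        region_ids=list(rec.region_ids),
    )
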