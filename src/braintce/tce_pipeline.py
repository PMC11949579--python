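"""Time-averaged control energy (TCE) over a dominance sequence.

For every ordered pair of network states (including self-pairs) the optimal
control energy per region is computed once, filling an asymmetric K x K x N
tensor — asymmetric because the structural connectome imposes a directional
flow on state space, so moving from state i to j generally costs a
different amount than the reverse. The empirical dominance sequence then
selects which transitions actually occurred; averaging the corresponding
per-region energy maps over all P consecutive transitions gives the TCE
map,

    TCE = (E*_{0->1} + E*_{1->2} + ... + E*_{P-1->P}) / P,

a per-region estimate of the average control effort exerted across the
recording, comparable across recording lengths.

Hierarchy summaries re-express the same transitions at the coarser
unimodal (sensory: VIS, SMN) versus heteromodal (associative: DAN, SAL,
LIM, FPN, DMN) level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome_io import NormalizedSystem
from .control_core import ControlProblem, solve_optimal_control
from .state_modeling import DominanceSequence, StateMaps

__all__ = [
    "TransitionEnergy",
    "TCEMap",
    "HierarchySummary",
    "DEFAULT_HIERARCHY",
    "transition_energy_matrix",
    "tce",
    "hierarchy_summary",
    "occurrence_weighted_map",
]

#: canonical network -> hierarchy class mapping for the seven-network partition
DEFAULT_HIERARCHY = {
    "VIS": "U",
    "SMN": "U",
    "DAN": "H",
    "SAL": "H",
    "LIM": "H",
    "FPN": "H",
    "DMN": "H",
}


@dataclass
class TransitionEnergy:
    """Per-region control energies for every ordered state pair."""

    node_tensor: np.ndarray  # (K, K, N): [source, target, region]
    state_order: list[str]
    region_ids: list[str]

    @property
    def totals(self) -> np.ndarray:
        """K x K whole-brain energy per ordered pair (sum over regions)."""
        return self.node_tensor.sum(axis=2)

    def slice(self, source: str, target: str) -> np.ndarray:
        i = self.state_order.index(source)
        j = self.state_order.index(target)
        return self.node_tensor[i, j]


@dataclass
class TCEMap:
    """Transition-averaged per-region control energy for one recording."""

    values: np.ndarray  # (N,)
    transition_count: int
    region_ids: list[str]
    subject_id: str = ""


@dataclass
class HierarchySummary:
    """Within/between-hierarchy transition counts and mean costs."""

    counts: pd.DataFrame  # 2x2 int, index=source class, columns=target class
    mean_energy: pd.DataFrame  # 2x2 float, whole-brain mean energy per class
    within_fraction: float
    transition_count: int


def transition_energy_matrix(
    states: StateMaps,
    system: NormalizedSystem,
    horizon_T: float = 1.0,
    rho: float = 1.0,
    n_steps: int = 1000,
    endpoint_tol: float = 1e-6,
) -> TransitionEnergy:
    """Solve the optimal control problem for all K^2 ordered state pairs.

    With K = 7 networks this is the full set of 49 per-region energy maps.
    Solver infeasibility propagates with the offending pair named.
    """
    if states.maps.shape[1] != system.n_regions:
        raise ValueError("state maps not aligned to system regions")
    K = len(states.state_names)
    N = system.n_regions
    tensor = np.empty((K, K, N))
    for i, src in enumerate(states.state_names):
        for j, tgt in enumerate(states.state_names):
            problem = ControlProblem(
                system=system,
                x0=states.maps[i],
                xT=states.maps[j],
                horizon_T=horizon_T,
                rho=rho,
                n_steps=n_steps,
                endpoint_tol=endpoint_tol,
            )
            result = solve_optimal_control(problem)
            if not result.feasible:
                raise RuntimeError(
                    f"infeasible control solution for transition {src}->{tgt} "
                    f"(endpoint error {result.endpoint_error:.3e})"
                )
            tensor[i, j] = result.node_energy
    return TransitionEnergy(
        node_tensor=tensor,
        state_order=list(states.state_names),
        region_ids=list(states.region_ids),
    )


def tce(seq: DominanceSequence, te: TransitionEnergy, subject_id: str = "") -> TCEMap:
    """Average per-region energies over the recording's transitions.

    Transitions are consecutive retained label pairs (self-pairs included,
    runs never bridged); P is their count. Raises if the sequence contains
    no transition.
    """
    pairs = seq.retained_pairs()
    if not pairs:
        raise ValueError("no transitions in sequence (P = 0)")
    index = {name: k for k, name in enumerate(te.state_order)}
    # accumulate per unique ordered pair: scaling the whole transition
    # multiset then leaves the weighted mean bit-identical
    counts: dict[tuple[str, str], int] = {}
    for pair in pairs:
        counts[pair] = counts.get(pair, 0) + 1
    acc = np.zeros(te.node_tensor.shape[2])
    for (src, tgt), count in sorted(counts.items()):
        acc += (count / len(pairs)) * te.node_tensor[index[src], index[tgt]]
    return TCEMap(
        values=acc,
        transition_count=len(pairs),
        region_ids=list(te.region_ids),
        subject_id=subject_id,
    )


def hierarchy_summary(
    seq: DominanceSequence,
    te: TransitionEnergy,
    hierarchy: dict[str, str] | None = None,
) -> HierarchySummary:
    """Aggregate transitions into the 2x2 unimodal/heteromodal table.

    ``mean_energy`` holds, per source/target class pair, the mean
    whole-brain energy (sum over regions) of the transitions in that cell;
    cells with no transition are NaN.
    """
    hierarchy = dict(DEFAULT_HIERARCHY if hierarchy is None else hierarchy)
    pairs = seq.retained_pairs()
    if not pairs:
        raise ValueError("no transitions in sequence (P = 0)")
    unmapped = {lab for pair in pairs for lab in pair if lab not in hierarchy}
    if unmapped:
        raise ValueError(f"networks without hierarchy label: {sorted(unmapped)}")

    classes = ("U", "H")
    index = {name: k for k, name in enumerate(te.state_order)}
    totals = te.totals
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    sums = pd.DataFrame(0.0, index=classes, columns=classes)
    for src, tgt in pairs:
        cs, ct = hierarchy[src], hierarchy[tgt]
        counts.loc[cs, ct] += 1
        sums.loc[cs, ct] += totals[index[src], index[tgt]]
    mean_energy = sums / counts.replace(0, np.nan)
    P = len(pairs)
    within = int(counts.loc["U", "U"] + counts.loc["H", "H"])
    return HierarchySummary(
        counts=counts,
        mean_energy=mean_energy,
        within_fraction=within / P,
        transition_count=P,
    )


def occurrence_weighted_map(
    seq: DominanceSequence,
    states: StateMaps,
    denominator: str = "total",
) -> np.ndarray:
    """State-frequency-weighted sum of coefficient maps.

    Each state's map is scaled by the fraction of timepoints it dominated
    (``denominator="total"`` divides by all timepoints, the default
    reading; ``"retained"`` divides by non-discarded timepoints only) and
    the scaled maps are summed.
    """
    counts = np.array([seq.labels.count(name) for name in states.state_names])
    if denominator == "total":
        denom = len(seq.labels)
    elif denominator == "retained":
        denom = len(seq.retained_indices)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0 or counts.sum() == 0:
        return np.zeros(states.maps.shape[1])
    ratios = counts / denom
    return ratios @ states.maps
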