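"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover everything the pipeline consumes, so every module is
testable without any neuroimaging download:

* modular symmetric weighted connectomes with planted within-module >
  between-module block weight means (emulating tractography-derived
  streamline-weight matrices);
* raw region x time recordings with a planted network-dominance sequence:
  at each timepoint the dominating network's template (positive amplitude
  on its regions) plus iid Gaussian noise, and pure noise at timepoints
  planted as DISCARDED — so the true dominance labels and templates are
  known exactly;
* spatially autocorrelated scalar maps drawn from a Gaussian process with
  squared-exponential covariance over region coordinates (emulating smooth
  reference maps such as metabolic uptake).

Every generator is a pure function of its spec and seed, and each returns
a ground-truth ledger sufficient to verify downstream results without
re-deriving them. Default scale: 60 regions in 4 networks (2 unimodal, 2
heteromodal), 200 timepoints — enough for nontrivial transition structure
at seconds-level test runtimes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome_io import Connectome, RegionMeta
from .state_modeling import DISCARDED

__all__ = [
    "SynthSpec",
    "default_spec",
    "seven_network_spec",
    "synth_connectome",
    "synth_recording",
    "synth_spatial_field",
    "region_coordinates",
    "lookup_frame",
    "write_fixture_dir",
]


@dataclass
class SynthSpec:
    """Parameters of one synthetic dataset."""

    n_regions: int
    networks: dict[str, tuple[int, str]]  # name -> (size, 'U'|'H')
    seed: int
    within_mean: float = 1.0
    between_mean: float = 0.5
    density: float = 0.3
    n_timepoints: int = 200
    discard_prob: float = 0.15
    template_amplitude: float = 1.0
    noise_sd: float = 0.1
    lengthscale: float = 20.0
    box_size: float = 100.0
    planted_sequence: list[str] | None = None

    def __post_init__(self) -> None:
        sizes = sum(size for size, _ in self.networks.values())
        if sizes != self.n_regions:
            raise ValueError(f"network sizes sum to {sizes}, expected {self.n_regions}")
        if any(w < 0 for w in (self.within_mean, self.between_mean)):
            raise ValueError("block weight means must be nonnegative")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def region_ids(self) -> list[str]:
        return [f"r{i:03d}" for i in range(self.n_regions)]

    @property
    def network_of_region(self) -> list[str]:
        out: list[str] = []
        for name, (size, _) in self.networks.items():
            out.extend([name] * size)
        return out

    @property
    def hierarchy_of_network(self) -> dict[str, str]:
        return {name: h for name, (_, h) in self.networks.items()}


def default_spec(seed: int = 0, **overrides) -> SynthSpec:
    """Standard test-scale spec: 60 regions, 4 networks (2 U, 2 H), T=200."""
    params = dict(
        n_regions=60,
        networks={"VIS": (15, "U"), "SMN": (15, "U"), "FPN": (15, "H"), "DMN": (15, "H")},
        seed=seed,
    )
    params.update(overrides)
    return SynthSpec(**params)


def seven_network_spec(seed: int = 0, n_regions: int = 400, **overrides) -> SynthSpec:
    """Seven-network spec mirroring the canonical intrinsic-network partition."""
    base, extra = divmod(n_regions, 7)
    names = ["VIS", "SMN", "DAN", "SAL", "LIM", "FPN", "DMN"]
    hier = {"VIS": "U", "SMN": "U"}
    networks = {
        name: (base + (1 if i < extra else 0), hier.get(name, "H"))
        for i, name in enumerate(names)
    }
    params = dict(n_regions=n_regions, networks=networks, seed=seed)
    params.update(overrides)
    return SynthSpec(**params)


def region_coordinates(spec: SynthSpec) -> np.ndarray:
    """Uniform 3D coordinates in a cube, deterministic under the spec seed."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    return rng.uniform(0.0, spec.box_size, size=(spec.n_regions, 3))


def synth_connectome(spec: SynthSpec) -> Connectome:
    """Modular symmetric nonnegative weight matrix with zero diagonal.

    Each unordered region pair carries an edge with probability
    ``density``; edge weights are exponential with mean ``within_mean``
    inside a network block and ``between_mean`` across blocks.
    """
    if not (0 < spec.density <= 1):
        raise ValueError(f"infeasible density {spec.density}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 12]))
    nets = spec.network_of_region
    n = spec.n_regions
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].size) < spec.density
    same = np.array([nets[i] == nets[j] for i, j in zip(*iu)])
    means = np.where(same, spec.within_mean, spec.between_mean)
    weights = rng.exponential(scale=np.maximum(means, 1e-300)) * present
    weights[means == 0] = 0.0
    W[iu] = weights
    W = W + W.T
    return Connectome(weights=W, region_ids=spec.region_ids, region_meta=_meta(spec))


def _meta(spec: SynthSpec) -> RegionMeta:
    df = lookup_frame(spec).set_index("region_id")
    return RegionMeta(
        network=df["network"],
        hierarchy=df["hierarchy"],
        hemisphere=df["hemisphere"],
        coordinates=df[["x", "y", "z"]].astype(float),
    )


def lookup_frame(spec: SynthSpec) -> pd.DataFrame:
    """Region lookup table (region_id, network, hierarchy, hemisphere, x, y, z)."""
    coords = region_coordinates(spec)
    nets = spec.network_of_region
    hier = spec.hierarchy_of_network
    return pd.DataFrame(
        {
            "region_id": spec.region_ids,
            "network": nets,
            "hierarchy": [hier[n] for n in nets],
            "hemisphere": ["L" if i % 2 == 0 else "R" for i in range(spec.n_regions)],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    )


def planted_sequence(spec: SynthSpec) -> list[str]:
    """The planted dominance labels: explicit if given, else random."""
    if spec.planted_sequence is not None:
        if len(spec.planted_sequence) != spec.n_timepoints:
            raise ValueError("planted sequence length must equal n_timepoints")
        return list(spec.planted_sequence)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 13]))
    names = list(spec.networks)
    labels = []
    for _ in range(spec.n_timepoints):
        if rng.random() < spec.discard_prob:
            labels.append(DISCARDED)
        else:
            labels.append(names[rng.integers(len(names))])
    # guarantee every network appears so no region column is constant
    for k, name in enumerate(names):
        if name not in labels:
            labels[k] = name
    return labels


def synth_recording(spec: SynthSpec) -> tuple[np.ndarray, dict]:
    """Raw T x N recording with planted dominance, plus ground-truth ledger.

    The ledger carries the true labels, the K x N templates, the region ->
    network map and independent transition bookkeeping (retained pairs and
    their hierarchy-class counts), sufficient for every downstream oracle.
    """
    labels = planted_sequence(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 14]))
    names = list(spec.networks)
    nets = np.asarray(spec.network_of_region)
    templates = np.zeros((len(names), spec.n_regions))
    for k, name in enumerate(names):
        templates[k, nets == name] = spec.template_amplitude
    raw = rng.normal(0.0, spec.noise_sd, size=(spec.n_timepoints, spec.n_regions))
    for t, lab in enumerate(labels):
        if lab != DISCARDED:
            raw[t] += templates[names.index(lab)]

    kept = [lab for lab in labels if lab != DISCARDED]
    pairs = list(zip(kept[:-1], kept[1:]))
    hier = spec.hierarchy_of_network
    class_counts = {("U", "U"): 0, ("U", "H"): 0, ("H", "U"): 0, ("H", "H"): 0}
    for a, b in pairs:
        class_counts[(hier[a], hier[b])] += 1
    ledger = {
        "labels": labels,
        "templates": templates,
        "template_names": names,
        "network_of_region": nets.tolist(),
        "hierarchy_of_network": hier,
        "retained_pairs": pairs,
        "class_counts": class_counts,
    }
    return raw, ledger


def synth_spatial_field(
    coordinates: np.ndarray, lengthscale: float, seed: int
) -> np.ndarray:
    """Gaussian-process draw with squared-exponential covariance.

    ``lengthscale = 0`` degenerates to iid standard normal values (a flat
    variogram at the field variance). A small diagonal jitter is added for
    Cholesky stability, escalated once before giving up.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    if lengthscale < 0:
        raise ValueError("lengthscale must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 15]))
    n = coordinates.shape[0]
    if lengthscale == 0:
        return rng.standard_normal(n)
    d2 = np.sum((coordinates[:, None, :] - coordinates[None, :, :]) ** 2, axis=-1)
    K = np.exp(-d2 / (2.0 * lengthscale**2))
    for jitter in (1e-10, 1e-6):
        try:
            L = np.linalg.cholesky(K + jitter * np.eye(n))
            return L @ rng.standard_normal(n)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance not positive definite even with jitter")


def write_fixture_dir(spec: SynthSpec, outdir: str | Path) -> Path:
    """Write a complete fixture directory: connectome, recording, lookup, ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conn = synth_connectome(spec)
    raw, ledger = synth_recording(spec)
    pd.DataFrame(conn.weights, index=conn.region_ids, columns=conn.region_ids).to_csv(
        outdir / "connectome.tsv", sep="\t"
    )
    pd.DataFrame(raw, columns=spec.region_ids).to_csv(
        outdir / "recording.tsv", sep="\t", index=False
    )
    lookup_frame(spec).to_csv(outdir / "lookup.tsv", sep="\t", index=False)
    serializable = dict(ledger)
    serializable["templates"] = ledger["templates"].tolist()
    serializable["retained_pairs"] = [list(p) for p in ledger["retained_pairs"]]
    serializable["class_counts"] = {
        f"{a}->{b}": v for (a, b), v in ledger["class_counts"].items()
    }
    (outdir / "ledger.json").write_text(json.dumps(serializable, indent=1))
    return outdir
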