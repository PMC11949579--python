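"""Reading, validation and spectral normalization of structural connectomes.

A connectome is an N x N symmetric nonnegative weight matrix over labelled
brain regions (e.g. streamline weights from tractography), accompanied by a
region lookup table assigning each region to an intrinsic network, a
hierarchy class (unimodal ``U`` / heteromodal ``H``), a hemisphere and a 3D
coordinate.

Before any control computation the adjacency matrix ``A`` is stabilized as

    A_norm = A / (lambda_max + c) - I

where ``lambda_max`` is the largest eigenvalue of ``A`` and ``c > 0`` an
offset pushing all eigenvalues of ``A_norm`` strictly below zero, so the
uncontrolled linear dynamics ``dx/dt = A_norm x`` decay instead of growing
without bound.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "NormalizedSystem",
    "RegionMeta",
    "load_connectome",
    "load_region_lookup",
    "normalize_adjacency",
    "write_connectome",
]

#: relative Frobenius tolerance below which a weight matrix counts as symmetric
SYMMETRY_RTOL = 1e-8

LOOKUP_COLUMNS = ("region_id", "network", "hierarchy", "hemisphere", "x", "y", "z")


@dataclass(frozen=True)
class RegionMeta:
    """Per-region annotations from the lookup table."""

    network: pd.Series  # region_id -> network label
    hierarchy: pd.Series  # region_id -> 'U' | 'H'
    hemisphere: pd.Series  # region_id -> 'L' | 'R'
    coordinates: pd.DataFrame  # region_id -> (x, y, z) in mm

    def network_of(self, region_id: str) -> str:
        return str(self.network.loc[region_id])


@dataclass
class Connectome:
    """Weighted symmetric structural network over labelled regions."""

    weights: np.ndarray
    region_ids: list[str]
    region_meta: RegionMeta | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        validate_weights(self.weights)
        if len(self.region_ids) != self.weights.shape[0]:
            raise ValueError(
                f"{len(self.region_ids)} region ids for a "
                f"{self.weights.shape[0]}-region matrix"
            )
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("duplicate region id in connectome")
        if self.region_meta is not None:
            missing = [r for r in self.region_ids if r not in self.region_meta.network.index]
            if missing:
                raise ValueError(f"regions missing from lookup table: {missing[:5]}")
            _check_network_hierarchy_consistency(self.region_meta)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class NormalizedSystem:
    """Stabilized system matrix ``A_norm`` with its normalization constants."""

    a_norm: np.ndarray
    lambda_max: float
    c: float

    @property
    def n_regions(self) -> int:
        return self.a_norm.shape[0]


def validate_weights(weights: np.ndarray) -> None:
    """Raise ``ValueError`` unless ``weights`` is a valid connectome matrix."""
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {weights.shape}")
    if not np.all(np.isfinite(weights)):
        raise ValueError("NaN/Inf entry in weight matrix")
    if np.any(weights < 0):
        raise ValueError("negative weight in connectome")
    denom = max(np.linalg.norm(weights), 1.0)
    if np.linalg.norm(weights - weights.T) > SYMMETRY_RTOL * denom:
        raise ValueError("weight matrix is not symmetric within tolerance")
    if np.any(np.abs(np.diag(weights)) > 0):
        raise ValueError("nonzero diagonal in connectome weights")


def _check_network_hierarchy_consistency(meta: RegionMeta) -> None:
    mapping = pd.DataFrame({"network": meta.network, "hierarchy": meta.hierarchy})
    counts = mapping.groupby("network")["hierarchy"].nunique()
    bad = counts[counts > 1]
    if len(bad):
        raise ValueError(
            f"networks mapped to more than one hierarchy label: {list(bad.index)}"
        )


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text().splitlines()[0]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def load_connectome(
    path: str | Path,
    symmetrize_policy: str = "average",
    lookup_path: str | Path | None = None,
) -> Connectome:
    """Load a dense weight matrix from CSV/TSV.

    The file may carry a header row and/or a first column of region ids;
    both are detected. ``symmetrize_policy`` is ``"average"`` (store
    ``(W + W.T)/2``; the default, tolerant to float-noisy tractography
    output) or ``"strict"`` (reject asymmetric input). Self-weights on the
    diagonal are discarded: self-dynamics enter through the ``-I`` term of
    the normalization, and a separate self-loop weight has no role in the
    model.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str)
    has_header = not _is_numeric(raw.iloc[0, 1])
    has_index = not _is_numeric(raw.iloc[1 if has_header else 0, 0])
    df = pd.read_csv(
        path,
        sep=sep,
        header=0 if has_header else None,
        index_col=0 if has_index else None,
    )
    weights = df.to_numpy(dtype=float)
    if weights.shape[0] != weights.shape[1]:
        raise ValueError(f"non-square connectome matrix {weights.shape} in {path}")
    if has_header:
        region_ids = [str(c) for c in df.columns]
    elif has_index:
        region_ids = [str(i) for i in df.index]
    else:
        region_ids = [f"r{i}" for i in range(weights.shape[0])]

    if symmetrize_policy == "average":
        weights = (weights + weights.T) / 2.0
    elif symmetrize_policy != "strict":
        raise ValueError(f"unknown symmetrize policy {symmetrize_policy!r}")
    np.fill_diagonal(weights, 0.0)

    meta = load_region_lookup(lookup_path) if lookup_path is not None else None
    return Connectome(weights=weights, region_ids=region_ids, region_meta=meta)


def _is_numeric(token: object) -> bool:
    try:
        float(token)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def load_region_lookup(path: str | Path) -> RegionMeta:
    """Load the region lookup TSV (region_id, network, hierarchy, hemisphere, x, y, z)."""
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    missing = [c for c in LOOKUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lookup table missing columns {missing}")
    if df["region_id"].duplicated().any():
        raise ValueError("duplicate region id in lookup table")
    df = df.set_index("region_id")
    meta = RegionMeta(
        network=df["network"].astype(str),
        hierarchy=df["hierarchy"].astype(str),
        hemisphere=df["hemisphere"].astype(str),
        coordinates=df[["x", "y", "z"]].astype(float),
    )
    bad = set(meta.hierarchy.unique()) - {"U", "H"}
    if bad:
        raise ValueError(f"hierarchy labels must be U or H, got {sorted(bad)}")
    _check_network_hierarchy_consistency(meta)
    return meta


def write_connectome(conn: Connectome, path: str | Path, sep: str = ",") -> None:
    """Write the weight matrix with region ids as header and index."""
    df = pd.DataFrame(conn.weights, index=conn.region_ids, columns=conn.region_ids)
    df.to_csv(path, sep=sep)


def normalize_adjacency(conn: Connectome | np.ndarray, c: float = 1.0) -> NormalizedSystem:
    """Stabilize the adjacency: ``A_norm = A/(lambda_max + c) - I``.

    ``lambda_max`` is the largest eigenvalue of the symmetric weight matrix.
    For any ``c > 0`` the spectrum of ``A_norm`` is the spectrum of ``A``
    scaled by ``1/(lambda_max + c)`` and shifted by ``-1``, so its largest
    eigenvalue is ``-c/(lambda_max + c) < 0``. An all-zero matrix is allowed
    (``lambda_max = 0``, ``A_norm = -I``).
    """
    if c <= 0:
        raise ValueError(f"stability offset c must be positive, got {c}")
    weights = conn.weights if isinstance(conn, Connectome) else np.asarray(conn, float)
    validate_weights(weights)
    lambda_max = float(np.linalg.eigvalsh(weights)[-1]) if weights.any() else 0.0
    a_norm = weights / (lambda_max + c) - np.eye(weights.shape[0])
    return NormalizedSystem(a_norm=a_norm, lambda_max=lambda_max, c=float(c))
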