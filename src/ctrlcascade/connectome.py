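"""Structural connectomes and network-control metrics.

The dynamical model is the noise-free linear discrete-time system

    x(t+1) = A x(t) + B_K u_K(t)

where ``A`` is the (stabilized) structural connectivity matrix. Modal
controllability of node *i* is

    phi_i = sum_j (1 - lambda_j(A)^2) * V_ij^2

over the eigenvalues ``lambda_j`` and orthonormal eigenvectors ``V`` of the
normalized adjacency. Single-node controllability is summarized by the
discrete controllability Gramian ``W = sum_tau A^tau B B' (A^tau)'``, the
fixed point of the Lyapunov equation ``W = A W A' + B B'``.

Edge weights are mean quantitative anisotropy (QA); connections with
QA <= 0.001 are treated as noise and removed before normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

SYMMETRY_TOL = 1e-10

#: The ten canonical networks used to summarize node-level controllability.
CANONICAL_NETWORKS = ("MF", "FP", "DMN", "Mot", "VisI", "VisII", "Vas", "SAL", "SC", "CBL")


@dataclass
class StructuralConnectome:
    """Per-subject symmetric nonnegative edge-weight matrix."""

    subject_id: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if np.isnan(w).any():
            i, j = np.argwhere(np.isnan(w))[0]
            raise ValueError(f"NaN entry at row {i + 1}, column {j + 1}")
        if (w < 0).any():
            raise ValueError("negative edge weights are not allowed")
        asym = np.abs(w - w.T).max() if w.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL:g}")
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class NetworkPartition:
    """Assignment of 1-based node indices to canonical network labels."""

    node_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.node_ids.shape != self.labels.shape:
            raise ValueError("node_ids and labels must align")
        n = len(self.node_ids)
        if sorted(self.node_ids) != list(range(1, n + 1)):
            raise ValueError("node_ids must cover 1..N exactly once")
        order = np.argsort(self.node_ids)
        self.node_ids = self.node_ids[order]
        self.labels = self.labels[order]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def networks(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab), None)
        return list(seen)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NetworkPartition":
        df = pd.read_csv(path)
        return cls(df["node_id"].to_numpy(), df["network_label"].to_numpy())

    @classmethod
    def contiguous(cls, sizes: Mapping[str, int]) -> "NetworkPartition":
        """Partition with contiguous blocks of the given sizes."""
        labels = np.concatenate([[lab] * n for lab, n in sizes.items()])
        return cls(np.arange(1, len(labels) + 1), labels)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"node_id": self.node_ids, "network_label": self.labels}).to_csv(
            path, index=False
        )


@dataclass
class NormalizedAdjacency:
    """Stabilized adjacency with spectral radius strictly below one."""

    matrix: np.ndarray
    spectral_radius: float


@dataclass
class ControllabilityProfile:
    """Eigen-spectrum, node-level modal controllability, and network means."""

    eigenvalues: np.ndarray  # sorted descending
    modal: np.ndarray  # phi_i per node
    network_means: dict[str, float] = field(default_factory=dict)


@dataclass
class GramianResult:
    control_node: int  # 1-based
    gramian: np.ndarray
    min_eigenvalue: float


def read_connectome(
    path: str | Path, dialect: str = "dense-matrix-csv", subject_id: str | None = None
) -> StructuralConnectome:
    """Read a dense square connectivity matrix from a text file.

    ``dialect`` is ``"dense-matrix-csv"`` (comma-separated) or
    ``"dense-matrix-whitespace"``. Small asymmetries (<= 1e-10) are
    symmetrized by averaging; NaN or negative entries raise.
    """
    path = Path(path)
    delim = "," if dialect == "dense-matrix-csv" else None
    w = np.loadtxt(path, delimiter=delim, ndmin=2)
    return StructuralConnectome(subject_id or path.stem, w)


def write_connectome(c: StructuralConnectome, path: str | Path, dialect: str = "dense-matrix-csv") -> None:
    delim = "," if dialect == "dense-matrix-csv" else " "
    np.savetxt(path, c.weights, delimiter=delim, fmt="%.17g")


def apply_qa_threshold(
    c: StructuralConnectome, threshold: float = 0.001
) -> tuple[StructuralConnectome, int]:
    """Zero out edges with weight <= threshold (strict ``>`` retained).

    Returns the filtered connectome and the number of retained edges
    (unordered node pairs with nonzero weight).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    w = c.weights.copy()
    w[w <= threshold] = 0.0
    out = StructuralConnectome(c.subject_id, w)
    n_edges = int(np.count_nonzero(np.triu(out.weights, k=1)))
    return out, n_edges


def normalize_adjacency(c: StructuralConnectome | np.ndarray) -> NormalizedAdjacency:
    """Divide A by ``1 + lambda_max(A)`` so the spectral radius is < 1.

    For a symmetric nonnegative matrix the largest eigenvalue equals the
    spectral radius, so the normalized matrix has spectral radius
    ``lambda_max / (1 + lambda_max) < 1`` and the zero matrix is fixed.
    """
    a = c.weights if isinstance(c, StructuralConnectome) else np.asarray(c, dtype=float)
    if a.size == 0:
        return NormalizedAdjacency(a.copy(), 0.0)
    lam_max = float(np.linalg.eigvalsh(a)[-1])
    if lam_max <= 0:  # zero matrix (nonnegative symmetric => lam_max >= 0)
        return NormalizedAdjacency(a.copy(), 0.0)
    m = a / (1.0 + lam_max)
    return NormalizedAdjacency(m, lam_max / (1.0 + lam_max))


def _check_stable_symmetric(a: NormalizedAdjacency | np.ndarray) -> np.ndarray:
    m = a.matrix if isinstance(a, NormalizedAdjacency) else np.asarray(a, dtype=float)
    if np.abs(m - m.T).max(initial=0.0) > 1e-8:
        raise ValueError("matrix must be symmetric")
    if m.size and np.abs(np.linalg.eigvalsh(m)).max() >= 1.0:
        raise ValueError("spectral radius must be < 1; normalize the adjacency first")
    return m


def modal_controllability(a: NormalizedAdjacency | np.ndarray) -> ControllabilityProfile:
    """Node-level modal controllability phi_i = sum_j (1 - lambda_j^2) V_ij^2.

    Uses the orthonormal eigenvectors of the symmetric normalized adjacency;
    phi is invariant to eigenvector sign because V enters squared. The
    conservation identity ``sum_i phi_i = N - ||A||_F^2`` holds exactly in
    this basis.
    """
    m = _check_stable_symmetric(a)
    lam, vec = np.linalg.eigh(m)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    phi = (vec**2) @ (1.0 - lam**2)
    return ControllabilityProfile(eigenvalues=lam, modal=phi)


def controllability_gramian(
    a: NormalizedAdjacency | np.ndarray, control_node: int
) -> GramianResult:
    """Infinite-horizon Gramian for a single control node (1-based index).

    Solves the discrete Lyapunov fixed point ``W = A W A' + B B'`` with B the
    indicator column of ``control_node``; equivalent to the convergent series
    ``sum_tau A^tau B B' (A^tau)'`` because the spectral radius is < 1.
    """
    m = _check_stable_symmetric(a)
    n = m.shape[0]
    if not 1 <= control_node <= n:
        raise ValueError(f"control_node must be in 1..{n}")
    b = np.zeros((n, 1))
    b[control_node - 1, 0] = 1.0
    w = linalg.solve_discrete_lyapunov(m, b @ b.T)
    w = 0.5 * (w + w.T)
    min_eig = float(np.linalg.eigvalsh(w)[0])
    return GramianResult(control_node=control_node, gramian=w, min_eigenvalue=min_eig)


def aggregate_to_networks(
    profile: ControllabilityProfile | np.ndarray, partition: NetworkPartition
) -> dict[str, float]:
    """Unweighted per-network mean of node-level modal controllability."""
    phi = profile.modal if isinstance(profile, ControllabilityProfile) else np.asarray(profile)
    if len(phi) != partition.n_nodes:
        raise ValueError(
            f"profile has {len(phi)} nodes but partition covers {partition.n_nodes}"
        )
    means: dict[str, float] = {}
    for lab in partition.networks:
        mask = partition.labels == lab
        means[lab] = float(phi[mask].mean())
    if isinstance(profile, ControllabilityProfile):
        profile.network_means = means
    return means


class ModalControllability(BaseEstimator, TransformerMixin):
    """Transformer from structural connectomes to modal-controllability values.

    Parameters
    ----------
    qa_threshold : float, default 0.001
        Edges with mean QA <= this value are removed before normalization.
    partition : NetworkPartition or None
        If given, :meth:`network_table` aggregates node values to per-network
        means.

    The transform is stateless: ``fit`` only validates parameters.
    """

    def __init__(self, qa_threshold: float = 0.001, partition: NetworkPartition | None = None):
        self.qa_threshold = qa_threshold
        self.partition = partition

    def fit(self, X: Sequence[StructuralConnectome | np.ndarray], y=None):
        if self.qa_threshold < 0:
            raise ValueError("qa_threshold must be >= 0")
        self.n_features_in_ = len(X) if hasattr(X, "__len__") else None
        return self

    def transform(self, X: Iterable[StructuralConnectome | np.ndarray]) -> np.ndarray:
        """Return an (n_subjects, n_nodes) array of node-level phi."""
        rows = []
        for item in X:
            c = item if isinstance(item, StructuralConnectome) else StructuralConnectome("", item)
            c, _ = apply_qa_threshold(c, self.qa_threshold)
            rows.append(modal_controllability(normalize_adjacency(c)).modal)
        return np.asarray(rows)

    def network_table(self, X: Iterable[StructuralConnectome | np.ndarray]) -> pd.DataFrame:
        """Per-subject per-network mean phi as a tidy DataFrame."""
        if self.partition is None:
            raise ValueError("a partition is required for network aggregation")
        records = []
        ids = []
        for item in X:
            c = item if isinstance(item, StructuralConnectome) else StructuralConnectome("", item)
            ids.append(c.subject_id)
            c, _ = apply_qa_threshold(c, self.qa_threshold)
            prof = modal_controllability(normalize_adjacency(c))
            records.append(aggregate_to_networks(prof, self.partition))
        df = pd.DataFrame(records)
        df.insert(0, "subject_id", ids)
        return df
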