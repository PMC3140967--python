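"""Tirion elastic networks: spring lists, Hessians, and normal modes.

The potential is the pairwise Hookean form
``E = (C/2) * sum over springs (|r_ij| - |r0_ij|)**2`` where springs join
every node pair within a distance cutoff of the reference geometry.  Nodes
carry unit mass, so eigenvalues are in units of C/Å² and frequencies
``ω = sqrt(λ)`` are in arbitrary units; both cancel in downstream
similarity weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "ElasticNetwork", "ModeSet", "build_network", "tirion_energy",
    "hessian", "normal_modes", "compute_modes",
]


class NetworkError(ValueError):
    pass


@dataclass
class ElasticNetwork:
    """Springs between reference-structure nodes within a cutoff."""

    node_coords: np.ndarray          # (N, 3) reference positions, Å
    springs: np.ndarray              # (S, 2) int pairs, i < j
    rest_lengths: np.ndarray         # (S,) Å
    cutoff: float                    # Å
    spring_constant: float = 1.0     # phenomenological C, energy/Å²
    n_components: int = 1

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_springs(self) -> int:
        return self.springs.shape[0]

    @property
    def is_connected(self) -> bool:
        return self.n_components == 1


@dataclass
class ModeSet:
    """Ascending internal (non-rigid) normal modes of an elastic network."""

    eigenvalues: np.ndarray      # (K,) ascending, λ ≥ 0
    eigenvectors: np.ndarray     # (3N, K) orthonormal columns
    n_rigid: int
    frequencies: np.ndarray = field(default=None)  # ω = sqrt(max(λ, 0))

    def __post_init__(self):
        if self.frequencies is None:
            self.frequencies = np.sqrt(np.clip(self.eigenvalues, 0.0, None))

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def dim(self) -> int:
        return self.eigenvectors.shape[0]

    def save(self, path: str) -> None:
        """Plain-text serialization; round-trips exactly at 1e-12."""
        with open(path, "w") as fh:
            fh.write(f"# n_rigid {self.n_rigid}\n")
            fh.write(f"# dim {self.dim} n_modes {self.n_modes}\n")
            for k in range(self.n_modes):
                fh.write(f"{k} {float(self.eigenvalues[k])!r} "
                         f"{float(self.frequencies[k])!r}\n")
            for k in range(self.n_modes):
                fh.write(" ".join(repr(float(v)) for v in self.eigenvectors[:, k]))
                fh.write("\n")

    @classmethod
    def load(cls, path: str) -> "ModeSet":
        with open(path) as fh:
            lines = fh.read().splitlines()
        n_rigid = int(lines[0].split()[2])
        dim = int(lines[1].split()[2])
        n_modes = int(lines[1].split()[4])
        evals = np.array(
            [float(lines[2 + k].split()[1]) for k in range(n_modes)])
        freqs = np.array(
            [float(lines[2 + k].split()[2]) for k in range(n_modes)])
        vecs = np.empty((dim, n_modes))
        for k in range(n_modes):
            vecs[:, k] = np.fromstring(lines[2 + n_modes + k], sep=" ")
        return cls(eigenvalues=evals, eigenvectors=vecs,
                   n_rigid=n_rigid, frequencies=freqs)


def build_network(nodes: np.ndarray, cutoff: float,
                  spring_constant: float = 1.0) -> ElasticNetwork:
    """Connect every node pair within ``cutoff`` Å of the reference geometry.

    A disconnected network raises a warning (modes remain computable, but
    each extra component contributes 6 more rigid modes).
    """
    nodes = np.asarray(nodes, dtype=float)
    if nodes.ndim != 2 or nodes.shape[1] != 3:
        raise NetworkError("nodes must be (N, 3)")
    n = nodes.shape[0]
    if n < 2:
        raise NetworkError("need at least 2 nodes")
    if cutoff <= 0:
        raise NetworkError("cutoff must be positive")
    tree = cKDTree(nodes)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        pairs = np.empty((0, 2), dtype=int)
    order = np.lexsort((pairs[:, 1], pairs[:, 0])) if len(pairs) else []
    pairs = pairs[order] if len(pairs) else pairs
    rest = (np.linalg.norm(nodes[pairs[:, 0]] - nodes[pairs[:, 1]], axis=1)
            if len(pairs) else np.empty(0))
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"elastic network is disconnected ({n_comp} components); "
            f"expect {6 * n_comp} rigid modes")
    return ElasticNetwork(node_coords=nodes, springs=pairs,
                          rest_lengths=rest, cutoff=float(cutoff),
                          spring_constant=float(spring_constant),
                          n_components=int(n_comp))


def tirion_energy(net: ElasticNetwork, coords: np.ndarray) -> float:
    """Harmonic spring energy ``(C/2) Σ (|r_ij| − |r⁰_ij|)²`` at ``coords``."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != net.node_coords.shape:
        raise NetworkError(
            f"coords shape {coords.shape} does not match network "
            f"{net.node_coords.shape}")
    if net.n_springs == 0:
        return 0.0
    d = np.linalg.norm(
        coords[net.springs[:, 0]] - coords[net.springs[:, 1]], axis=1)
    return float(0.5 * net.spring_constant *
                 np.sum((d - net.rest_lengths) ** 2))


def hessian(net: ElasticNetwork) -> np.ndarray:
    """Analytic 3N×3N Hessian of the spring energy at the reference.

    Each spring contributes the rank-one block ``C · û ûᵀ`` on its unit
    bond vector û: subtracted on the (i, j)/(j, i) off-diagonal blocks and
    accumulated on the (i, i) and (j, j) diagonal blocks.
    """
    n = net.n_nodes
    h = np.zeros((3 * n, 3 * n))
    if net.n_springs and np.any(net.rest_lengths <= 0):
        bad = net.springs[net.rest_lengths <= 0][0]
        raise NetworkError(
            f"coincident nodes {bad[0]} and {bad[1]} share a spring")
    for (i, j), r0 in zip(net.springs, net.rest_lengths):
        u = (net.node_coords[j] - net.node_coords[i]) / r0
        block = net.spring_constant * np.outer(u, u)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        h[si, si] += block
        h[sj, sj] += block
        h[si, sj] -= block
        h[sj, si] -= block
    return h


def normal_modes(h: np.ndarray, n_modes: int | None = None,
                 n_components: int = 1,
                 rigid_rtol: float = 1e-8) -> ModeSet:
    """Diagonalize a Hessian and return the lowest internal modes.

    Rigid modes (λ below ``rigid_rtol × λ_max``) are discarded; a connected
    3-D network must yield exactly 6, and exactly 6 are always removed for
    connected input.  Eigenvector signs are solver-dependent; consumers
    must use absolute overlaps.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise NetworkError("Hessian must be square")
    if not np.allclose(h, h.T, atol=1e-10 * max(1.0, np.abs(h).max())):
        raise NetworkError("Hessian must be symmetric")
    evals, evecs = eigh((h + h.T) / 2.0)
    lam_max = float(np.abs(evals).max()) if evals.size else 0.0
    near_zero = int(np.sum(np.abs(evals) < rigid_rtol * max(lam_max, 1e-300)))
    expected = 6 * n_components
    if near_zero < expected:
        raise NetworkError(
            f"found {near_zero} near-zero modes but connectivity implies "
            f"{expected}; Hessian assembly is suspect")
    if near_zero > expected:
        warnings.warn(
            f"{near_zero} near-zero modes for {n_components} component(s); "
            f"treating the {near_zero} smallest as rigid")
    n_rigid = near_zero
    internal_evals = np.clip(evals[n_rigid:], 0.0, None)
    internal_evecs = evecs[:, n_rigid:]
    if n_modes is not None:
        if n_modes > internal_evals.size:
            raise NetworkError(
                f"requested {n_modes} modes but only "
                f"{internal_evals.size} internal modes exist")
        internal_evals = internal_evals[:n_modes]
        internal_evecs = internal_evecs[:, :n_modes]
    return ModeSet(eigenvalues=internal_evals, eigenvectors=internal_evecs,
                   n_rigid=n_rigid)


def compute_modes(net_or_coords, cutoff: float | None = None,
                  n_modes: int | None = None,
                  spring_constant: float = 1.0) -> ModeSet:
    """Convenience: build network (if needed), assemble Hessian, diagonalize."""
    if isinstance(net_or_coords, ElasticNetwork):
        net = net_or_coords
    else:
        if cutoff is None:
            raise NetworkError("cutoff required when passing raw coordinates")
        net = build_network(net_or_coords, cutoff, spring_constant)
    return normal_modes(hessian(net), n_modes=n_modes,
                        n_components=net.n_components)
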