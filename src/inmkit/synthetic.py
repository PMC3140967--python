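"""Synthetic fixtures: hinge proteins, transition trajectories, Gaussians.

These generators stand in for molecular-dynamics data: two-domain bead
proteins whose open and closed conformers differ by a rigid rotation of
the second domain about a hinge, trajectories that dwell in one state or
switch between them under Gaussian positional noise, and multivariate
normal ensembles whose entropy has an analytic truth.  Everything is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from inmkit.enm import ModeSet
from inmkit.structures import ATOMIC_MASSES, Structure, Trajectory

__all__ = [
    "HingeSpec", "make_hinge_protein", "make_backbone_chain",
    "make_transition_trajectory", "sample_gaussian_ensemble",
    "covariance_from_modes",
]

# idealized backbone internal coordinates (Å / degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 116.6, 121.7
HELIX_PHI, HELIX_PSI = -57.0, -47.0


@dataclass
class HingeSpec:
    """Parameters of the two-domain hinge fixture."""

    n_per_domain: int = 30
    open_angle: float = 120.0       # inter-domain angle, degrees
    closed_angle: float = 60.0
    hinge_residues: int = 2
    spacing: float = 3.8            # consecutive CA-CA distance, Å
    seed: int = 0

    def __post_init__(self):
        if self.n_per_domain < 10:
            raise ValueError("need at least 10 residues per domain")
        if abs(self.open_angle - self.closed_angle) < 10.0:
            raise ValueError("open/closed angles must differ by >= 10 degrees")


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _helix_ca_trace(n: int, spacing: float) -> np.ndarray:
    """CA positions of an idealized helix along +z with given CA spacing."""
    rise = 1.5
    twist = np.radians(100.0)
    chord = np.sqrt(max(spacing ** 2 - rise ** 2, 1e-9))
    radius = chord / (2.0 * np.sin(twist / 2.0))
    i = np.arange(n)
    return np.column_stack((radius * np.cos(twist * i),
                            radius * np.sin(twist * i),
                            rise * i))


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to a-b-c."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(ang),
                   bond * np.sin(ang) * np.cos(tor),
                   bond * np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def make_backbone_chain(phis: np.ndarray, psis: np.ndarray,
                        omegas: np.ndarray | float = 180.0,
                        resname: str = "ALA", chain: str = "A") -> Structure:
    """Ideal N/CA/C backbone built from torsions by chain extension.

    ``phis[i]`` is the φ torsion of residue i+1 (the first is unused) and
    ``psis[i]`` the ψ of residue i+1 (the last is unused).  A constant
    (−57, −47) gives an α-helix; (180, 180) a planar trans zigzag.
    """
    phis = np.asarray(phis, dtype=float)
    psis = np.asarray(psis, dtype=float)
    n_res = len(phis)
    if len(psis) != n_res:
        raise ValueError("phis and psis must have equal length")
    omegas = (np.full(n_res, float(omegas))
              if np.isscalar(omegas) else np.asarray(omegas, dtype=float))
    coords = np.empty((3 * n_res, 3))
    coords[0] = (0.0, 0.0, 0.0)                       # N1
    coords[1] = (_B_N_CA, 0.0, 0.0)                   # CA1
    ang = np.radians(_A_N_CA_C)
    coords[2] = coords[1] + _B_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])             # C1
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[3 * i - 3: 3 * i]
        n_i = _nerf(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psis[i - 1])
        ca_i = _nerf(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, omegas[i - 1])
        c_i = _nerf(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phis[i])
        coords[3 * i: 3 * i + 3] = (n_i, ca_i, c_i)
    names = np.tile(["N", "CA", "C"], n_res)
    elements = np.tile(["N", "C", "C"], n_res)
    resids = np.repeat(np.arange(1, n_res + 1), 3)
    return Structure(
        names=names, elements=elements, resids=resids,
        icodes=np.array([""] * 3 * n_res),
        resnames=np.array([resname] * 3 * n_res),
        chains=np.array([chain] * 3 * n_res),
        coords=coords,
        masses=np.array([ATOMIC_MASSES[e] for e in elements]),
        provenance={"generator": "make_backbone_chain"},
    )


def make_hinge_protein(spec: HingeSpec, state: str,
                       backbone: bool = False) -> Structure:
    """Two compact domains joined at a short hinge, in one of two states.

    The chain is built straight, then every atom past the hinge pivot is
    rigidly rotated about an axis through the pivot CA perpendicular to
    the chain direction, so the two states differ only by a rigid rotation
    of domain 2 and domain 1 is bit-identical between them.
    """
    if state not in ("open", "closed"):
        raise ValueError("state must be 'open' or 'closed'")
    n_total = 2 * spec.n_per_domain + spec.hinge_residues
    if backbone:
        phis = np.full(n_total, HELIX_PHI)
        psis = np.full(n_total, HELIX_PSI)
        s = make_backbone_chain(phis, psis)
        ca_indices = np.where(s.names == "CA")[0]
        pivot_res = spec.n_per_domain + spec.hinge_residues  # 1-based resid
        pivot_atom = ca_indices[pivot_res - 1]
        pivot = s.coords[pivot_atom]
        chain_dir = (s.coords[ca_indices[-1]] - s.coords[ca_indices[0]])
    else:
        ca = _helix_ca_trace(n_total, spec.spacing)
        names = np.array(["CA"] * n_total)
        s = Structure(
            names=names, elements=np.array(["C"] * n_total),
            resids=np.arange(1, n_total + 1),
            icodes=np.array([""] * n_total),
            resnames=np.array(["ALA"] * n_total),
            chains=np.array(["A"] * n_total),
            coords=ca,
            masses=np.full(n_total, ATOMIC_MASSES["C"]),
            provenance={"generator": "make_hinge_protein"},
        )
        pivot_res = spec.n_per_domain + spec.hinge_residues
        pivot_atom = pivot_res - 1
        pivot = s.coords[pivot_atom]
        chain_dir = s.coords[-1] - s.coords[0]
    chain_dir = chain_dir / np.linalg.norm(chain_dir)
    # bend axis: perpendicular to the chain direction, deterministic
    trial = np.array([1.0, 0.0, 0.0])
    axis = np.cross(chain_dir, trial)
    if np.linalg.norm(axis) < 1e-6:
        axis = np.cross(chain_dir, np.array([0.0, 1.0, 0.0]))
    axis /= np.linalg.norm(axis)
    angle = spec.open_angle if state == "open" else spec.closed_angle
    bend = 180.0 - angle
    rot = _rotation_about_axis(axis, bend)
    coords = s.coords.copy()
    moving = np.arange(s.n_atoms) > pivot_atom
    coords[moving] = (coords[moving] - pivot) @ rot.T + pivot
    out = s.copy_with_coords(coords)
    out.provenance.update({
        "state": state, "hinge_pivot_resid": int(pivot_res),
        "seed": spec.seed,
        "spec": {
            "n_per_domain": spec.n_per_domain,
            "open_angle": spec.open_angle,
            "closed_angle": spec.closed_angle,
            "hinge_residues": spec.hinge_residues,
            "spacing": spec.spacing,
        },
    })
    return out


def make_transition_trajectory(open_s: Structure, closed_s: Structure,
                               n_frames: int, switch_frame: int | None = None,
                               noise_sigma: float = 0.0, seed: int = 0,
                               dt_ps: float = 10.0,
                               interp_frames: int = 10) -> Trajectory:
    """Dwell-or-switch trajectory between two conformers with noise.

    Frames before ``switch_frame`` sit at the open conformer; from the
    switch on, the base geometry interpolates linearly to the closed
    conformer over ``interp_frames`` frames and stays there.
    ``switch_frame=None`` gives a pure open-state dwell.  Isotropic
    Gaussian noise of the stated sigma is added per coordinate.
    """
    if open_s.n_atoms != closed_s.n_atoms:
        raise ValueError("open/closed structures must share topology")
    if switch_frame is not None and not (0 <= switch_frame < n_frames):
        raise ValueError(
            f"switch_frame {switch_frame} outside [0, {n_frames})")
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, open_s.n_atoms, 3))
    for f in range(n_frames):
        if switch_frame is None or f < switch_frame:
            t = 0.0
        else:
            t = min(1.0, (f - switch_frame + 1) / interp_frames)
        base = (1.0 - t) * open_s.coords + t * closed_s.coords
        frames[f] = base
    if noise_sigma > 0:
        frames += rng.normal(0.0, noise_sigma, size=frames.shape)
    return Trajectory(
        topology=open_s, frames=frames,
        times=dt_ps * np.arange(n_frames),
        metadata={"switch_frame": switch_frame, "noise_sigma": noise_sigma,
                  "seed": seed, "interp_frames": interp_frames},
    )


def sample_gaussian_ensemble(mean: Structure, covariance: np.ndarray,
                             n_frames: int, seed: int = 0,
                             dt_ps: float = 1.0) -> Trajectory:
    """I.i.d. multivariate-normal frames about a mean structure.

    The generator covariance is stored in ``metadata['generator_covariance']``
    so estimators can be checked against the analytic truth.
    """
    cov = np.asarray(covariance, dtype=float)
    n3 = 3 * mean.n_atoms
    if cov.shape != (n3, n3):
        raise ValueError(f"covariance must be ({n3}, {n3})")
    evals = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if evals[0] < -1e-8 * max(evals[-1], 1e-300):
        raise ValueError("covariance is not positive semidefinite")
    rng = np.random.default_rng(seed)
    flat = rng.multivariate_normal(mean.coords.reshape(-1), cov,
                                   size=n_frames, method="eigh")
    return Trajectory(
        topology=mean, frames=flat.reshape(n_frames, mean.n_atoms, 3),
        times=dt_ps * np.arange(n_frames),
        metadata={"generator_covariance": cov, "seed": seed},
    )


def covariance_from_modes(modes: ModeSet, kt: float = 1.0) -> np.ndarray:
    """Harmonic positional covariance ``kT Σ_k λ_k⁻¹ v_k v_kᵀ`` over
    internal modes (a pseudo-inverse of the Hessian in its internal
    subspace), suitable as a structured PSD generator covariance."""
    lam = modes.eigenvalues
    if np.any(lam <= 0):
        raise ValueError("all internal eigenvalues must be positive")
    v = modes.eigenvectors
    return kt * (v / lam) @ v.T
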