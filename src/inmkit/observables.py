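"""Ensemble observables: quasi-harmonic entropy, SASA, backbone dihedrals.

The configurational entropy follows Schlitter's covariance-matrix upper
bound

    S_conf = (k_B/2) ln det( 1 + (k_B T e^2 / hbar^2) M sigma )

evaluated in the numerically symmetric form with M^(1/2) sigma M^(1/2),
where sigma is the positional fluctuation covariance of the aligned
ensemble and M the diagonal atomic mass matrix (each mass on 3 consecutive
coordinates).  Output is molar (J/mol/K or kJ/mol/K).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import constants
from scipy.spatial import cKDTree

from inmkit.structures import (
    Structure, StructureError, Trajectory, select_atoms, superpose,
    apply_transform,
)

__all__ = [
    "CovarianceModel", "EntropyReport", "SASAProfile", "DihedralSeries",
    "build_covariance", "schlitter_entropy", "region_entropy",
    "sasa", "sasa_profile", "backbone_dihedrals", "dihedral_density",
    "DEFAULT_RADII", "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C")

# van der Waals radii (Å) used for SASA
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}

_AMU = constants.atomic_mass          # kg
_KB = constants.k                     # J/K
_HBAR = constants.hbar                # J s
_R = constants.R                      # J/mol/K
_A2 = 1e-20                           # Å² -> m²


@dataclass
class CovarianceModel:
    """Aligned-ensemble mean, positional covariance and masses."""

    mean_coords: np.ndarray       # (N, 3) Å
    sigma: np.ndarray             # (3N, 3N) Å²
    masses: np.ndarray            # (N,) amu
    temperature: float            # K
    n_frames: int

    def __post_init__(self):
        n3 = 3 * self.mean_coords.shape[0]
        if self.sigma.shape != (n3, n3):
            raise ValueError("sigma must be (3N, 3N)")
        if not np.allclose(self.sigma, self.sigma.T,
                           atol=1e-10 * max(1.0, np.abs(self.sigma).max())):
            raise ValueError("sigma must be symmetric")

    @property
    def n_atoms(self) -> int:
        return self.mean_coords.shape[0]

    def mass_vector(self) -> np.ndarray:
        """3N-vector with each atomic mass repeated on 3 coordinates (amu)."""
        return np.repeat(self.masses, 3)


@dataclass
class EntropyReport:
    """Per-region per-atom configurational entropies with block stds."""

    rows: list[dict] = field(default_factory=list)
    units: str = "J/mol/K"
    n_blocks: int = 3
    temperature: float = 300.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


@dataclass
class SASAProfile:
    resids: np.ndarray
    mean: np.ndarray     # Å² per residue
    std: np.ndarray
    probe: float
    n_points: int

    def __post_init__(self):
        if np.any(self.mean < 0) or np.any(self.std < 0):
            raise ValueError("SASA means/stds must be nonnegative")


@dataclass
class DihedralSeries:
    """Per-residue per-frame (φ, ψ) in degrees, range (−180, 180]."""

    resids: list[int]
    phi: np.ndarray          # (F, R), NaN where undefined
    psi: np.ndarray
    omitted: dict = field(default_factory=dict)   # resid -> reason


# ---------------------------------------------------------------------------
# Covariance & entropy
# ---------------------------------------------------------------------------

def _align_frames(frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
    out = np.empty_like(frames)
    for i, fr in enumerate(frames):
        rot, trans, _ = superpose(ref, fr)
        out[i] = apply_transform(fr, rot, trans)
    return out


def build_covariance(traj: Trajectory,
                     residue_ranges: Sequence[tuple[int, int]] | None = None,
                     atom_names: Sequence[str] = BACKBONE_ATOMS,
                     temperature: float = 300.0,
                     align: bool = True) -> CovarianceModel:
    """Positional fluctuation covariance of an aligned sub-ensemble.

    Frames are superposed onto the ensemble mean, iterated twice: align to
    the first frame, compute the mean, then re-align the original frames to
    that mean.  The covariance uses the 1/n normalization.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for a covariance")
    topo = traj.topology
    if residue_ranges is None:
        residue_ranges = [(int(topo.resids.min()), int(topo.resids.max()))]
    sel = select_atoms(topo, residue_ranges,
                       set(atom_names) if atom_names else None)
    mask = np.zeros(topo.n_atoms, dtype=bool)
    keyset = {(str(c), int(r), str(ic), str(nm))
              for c, r, ic, nm in zip(sel.chains, sel.resids, sel.icodes,
                                      sel.names)}
    for i in range(topo.n_atoms):
        key = (str(topo.chains[i]), int(topo.resids[i]),
               str(topo.icodes[i]), str(topo.names[i]))
        mask[i] = key in keyset
    idx = np.where(mask)[0]
    frames = traj.frames[:, idx, :]
    if align:
        if len(idx) < 3:
            raise ValueError("alignment requires at least 3 atoms")
        aligned = _align_frames(frames, frames[0])
        mean1 = aligned.mean(axis=0)
        aligned = _align_frames(frames, mean1)
        mean = aligned.mean(axis=0)
    else:
        aligned = frames
        mean = frames.mean(axis=0)
    flat = aligned.reshape(traj.n_frames, -1)
    dev = flat - mean.reshape(-1)
    sigma = dev.T @ dev / traj.n_frames
    return CovarianceModel(mean_coords=mean, sigma=sigma,
                           masses=topo.masses[idx],
                           temperature=float(temperature),
                           n_frames=traj.n_frames)


def schlitter_entropy(cov: CovarianceModel,
                      units: str = "J/mol/K") -> float:
    """Schlitter configurational entropy of a covariance model (molar).

    Evaluated as ``(R/2) Σ ln(1 + α λ_k)`` over the eigenvalues of
    ``M^(1/2) σ M^(1/2)`` with ``α = k_B T e² / ħ²`` in SI units; the
    result is an upper bound on the true configurational entropy and is
    nonnegative.
    """
    if cov.temperature <= 0:
        raise ValueError("temperature must be positive")
    sig = (cov.sigma + cov.sigma.T) / 2.0
    evals_sigma = np.linalg.eigvalsh(sig)
    if evals_sigma.size and evals_sigma[0] < -1e-8 * max(
            evals_sigma[-1], 1e-300):
        raise ValueError("covariance is not positive semidefinite")
    m_sqrt = np.sqrt(cov.mass_vector() * _AMU)            # kg^(1/2)
    core = (m_sqrt[:, None] * sig * _A2) * m_sqrt[None, :]  # kg m²
    alpha = _KB * cov.temperature * np.e ** 2 / _HBAR ** 2  # 1/(kg m²)
    lam = np.linalg.eigvalsh((core + core.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    s = 0.5 * _R * float(np.sum(np.log1p(alpha * lam)))   # J/mol/K
    if units == "J/mol/K":
        return s
    if units == "kJ/mol/K":
        return s / 1000.0
    raise ValueError(f"unknown units {units!r}")


def region_entropy(traj: Trajectory, regions: dict,
                   n_blocks: int = 3, temperature: float = 300.0,
                   units: str = "J/mol/K",
                   atom_names: Sequence[str] = BACKBONE_ATOMS) -> EntropyReport:
    """Per-atom Schlitter entropy for named residue regions, with block stds.

    ``regions`` maps a name to an interval list ``[(lo, hi), ...]``.  The
    per-atom value is the full-ensemble entropy divided by the number of
    selected atoms; the std is over ``n_blocks`` contiguous equal-length
    frame blocks.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    report = EntropyReport(units=units, n_blocks=n_blocks,
                           temperature=temperature)
    f = traj.n_frames
    block_edges = np.linspace(0, f, n_blocks + 1).astype(int)
    for name, intervals in regions.items():
        intervals = [tuple(iv) for iv in intervals]
        cov = build_covariance(traj, intervals, atom_names,
                               temperature=temperature)
        n_atoms = cov.n_atoms
        if n_atoms == 0:
            raise StructureError(f"region {name!r} selects no backbone atoms")
        total = schlitter_entropy(cov, units=units)
        block_vals = []
        for b in range(n_blocks):
            lo, hi = block_edges[b], block_edges[b + 1]
            sub = Trajectory(topology=traj.topology,
                             frames=traj.frames[lo:hi],
                             times=traj.times[lo:hi])
            bc = build_covariance(sub, intervals, atom_names,
                                  temperature=temperature)
            block_vals.append(schlitter_entropy(bc, units=units) / n_atoms)
        report.rows.append({
            "region": name,
            "intervals": intervals,
            "n_atoms": n_atoms,
            "per_atom_entropy": total / n_atoms,
            "block_std": float(np.std(block_vals, ddof=1)),
            "blocks": block_vals,
        })
    return report


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack((np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)))


def sasa(structure: Structure, radii: dict | None = None,
         probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley.

    For each atom, the fraction of ``n_points`` quasi-uniform test points
    on the probe-expanded sphere not buried inside any neighbor's expanded
    sphere, times the expanded-sphere area.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    radii = DEFAULT_RADII if radii is None else radii
    elements = [str(e) for e in structure.elements]
    missing = sorted({e for e in elements if e not in radii})
    if missing:
        raise ValueError(f"no radius for element(s): {missing}")
    r = np.array([radii[e] for e in elements]) + probe
    xyz = structure.coords
    unit = _sphere_points(n_points)
    tree = cKDTree(xyz)
    rmax = r.max()
    out = np.empty(structure.n_atoms)
    for i in range(structure.n_atoms):
        pts = xyz[i] + r[i] * unit
        neighbors = [j for j in tree.query_ball_point(xyz[i], r[i] + rmax)
                     if j != i]
        if neighbors:
            nb_xyz = xyz[neighbors]
            nb_r = r[neighbors]
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < nb_r[None, :] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * np.pi * r[i] ** 2
    return out


def sasa_profile(traj: Trajectory, residue_range: tuple[int, int],
                 probe: float = 1.4, n_points: int = 960,
                 radii: dict | None = None) -> SASAProfile:
    """Per-residue mean and std of summed atomic SASA over frames.

    The whole structure participates in burial; only residues inside
    ``residue_range`` are reported.  Population std (duplicating every
    frame leaves both mean and std unchanged).
    """
    topo = traj.topology
    lo, hi = residue_range
    report_resids = [ri for ri in topo.residue_ids() if lo <= ri <= hi]
    if not report_resids:
        raise StructureError(
            f"no residues in range {lo}-{hi}; available "
            f"{int(topo.resids.min())}-{int(topo.resids.max())}")
    per_frame = np.empty((traj.n_frames, len(report_resids)))
    res_masks = [(topo.resids == ri) for ri in report_resids]
    for f in range(traj.n_frames):
        frame_s = topo.copy_with_coords(traj.frames[f])
        atom_sasa = sasa(frame_s, radii=radii, probe=probe, n_points=n_points)
        for k, mask in enumerate(res_masks):
            per_frame[f, k] = atom_sasa[mask].sum()
    return SASAProfile(resids=np.array(report_resids),
                       mean=per_frame.mean(axis=0),
                       std=per_frame.std(axis=0),
                       probe=probe, n_points=n_points)


# ---------------------------------------------------------------------------
# Backbone dihedrals
# ---------------------------------------------------------------------------

def dihedral_angles(p0, p1, p2, p3) -> np.ndarray:
    """Torsion angle(s) in degrees, IUPAC sign, range (−180, 180].

    Accepts (..., 3) arrays; broadcasts over leading axes.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return ang


def backbone_dihedrals(traj: Trajectory,
                       residues: Sequence[int]) -> DihedralSeries:
    """φ/ψ per frame for each listed residue (degrees, (−180, 180]).

    φ needs C of the preceding residue, ψ the N of the following one;
    chain-terminal residues yield only the defined angle.  Residues with
    missing atoms are recorded in ``omitted`` rather than silently dropped.
    """
    topo = traj.topology
    atom_of: dict[tuple[int, str], int] = {}
    for i in range(topo.n_atoms):
        atom_of.setdefault((int(topo.resids[i]), str(topo.names[i])), i)
    ordered = topo.residue_ids()
    pos = {r: k for k, r in enumerate(ordered)}
    chain_of = {}
    for i in range(topo.n_atoms):
        chain_of.setdefault(int(topo.resids[i]), str(topo.chains[i]))

    resids = [int(r) for r in residues]
    f = traj.n_frames
    phi = np.full((f, len(resids)), np.nan)
    psi = np.full((f, len(resids)), np.nan)
    omitted: dict[int, str] = {}
    for k, r in enumerate(resids):
        if r not in pos:
            omitted[r] = "residue absent"
            continue
        core = [(r, "N"), (r, "CA"), (r, "C")]
        if any(key not in atom_of for key in core):
            omitted[r] = "missing backbone atom"
            continue
        i_n, i_ca, i_c = (atom_of[key] for key in core)
        p = pos[r]
        prev_r = ordered[p - 1] if p > 0 else None
        next_r = ordered[p + 1] if p + 1 < len(ordered) else None
        if prev_r is not None and chain_of.get(prev_r) == chain_of[r] and \
                (prev_r, "C") in atom_of:
            i_cprev = atom_of[(prev_r, "C")]
            phi[:, k] = dihedral_angles(
                traj.frames[:, i_cprev], traj.frames[:, i_n],
                traj.frames[:, i_ca], traj.frames[:, i_c])
        if next_r is not None and chain_of.get(next_r) == chain_of[r] and \
                (next_r, "N") in atom_of:
            i_nnext = atom_of[(next_r, "N")]
            psi[:, k] = dihedral_angles(
                traj.frames[:, i_n], traj.frames[:, i_ca],
                traj.frames[:, i_c], traj.frames[:, i_nnext])
        if np.all(np.isnan(phi[:, k])) and np.all(np.isnan(psi[:, k])):
            omitted[r] = "no dihedral defined (isolated residue)"
    return DihedralSeries(resids=resids, phi=phi, psi=psi, omitted=omitted)


def dihedral_density(series: DihedralSeries, bins: int = 72) -> dict:
    """Per-residue normalized 2-D (φ, ψ) histogram on (−180, 180]².

    Binning is periodic: angles are wrapped onto [0, 360) before binning,
    so +180 and −180 coincide.  Each residue's histogram sums to 1 (over
    frames where both angles are defined).  Returns
    ``{resid: (bins, bins) array}`` plus ``"edges"`` with the bin edges in
    degrees on the wrapped axis.
    """
    edges = np.linspace(0.0, 360.0, bins + 1)
    out: dict = {"edges": edges - 180.0}
    for k, r in enumerate(series.resids):
        ph = series.phi[:, k]
        ps = series.psi[:, k]
        ok = ~(np.isnan(ph) | np.isnan(ps))
        hist = np.zeros((bins, bins))
        if ok.any():
            wph = np.mod(ph[ok] + 180.0, 360.0)
            wps = np.mod(ps[ok] + 180.0, 360.0)
            hist, _, _ = np.histogram2d(wph, wps, bins=[edges, edges])
            hist = hist / hist.sum()
        out[r] = hist
    return out
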