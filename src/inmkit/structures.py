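"""Structures, trajectories, residue mappings and rigid superposition.

Conventions: coordinates in Å throughout; residue identifiers are the
author-assigned PDB numbers (never serial indices); residue intervals are
inclusive on both ends.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Structure", "Trajectory", "ResidueMapping",
    "read_structure", "read_trajectory", "write_pdb", "write_trajectory",
    "select_atoms", "map_residues", "superpose", "rmsd", "rmsd_trace",
    "node_coords",
]

# Standard atomic masses (amu), keyed by upper-case element symbol.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45,
    "BR": 79.904, "I": 126.904, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "MN": 54.938, "CA": 40.078, "NA": 22.990, "K": 39.098, "CU": 63.546,
}

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


class StructureError(ValueError):
    """Raised for malformed input or invalid selections."""


@dataclass
class Structure:
    """A set of atoms with coordinates and identity metadata.

    Attributes
    ----------
    names : array of atom names (e.g. ``"CA"``).
    elements : array of element symbols (upper case).
    resids : array of author-assigned residue numbers.
    icodes : array of PDB insertion codes (``""`` when absent).
    resnames : array of residue names.
    chains : array of chain identifiers.
    coords : (N, 3) positions in Å.
    masses : per-atom masses in amu.
    provenance : free-form record of how the structure was obtained.
    """

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    icodes: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    masses: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coords must be an (N, 3) array")
        self.validate()

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def validate(self) -> None:
        n = self.n_atoms
        if n < 1:
            raise StructureError("structure must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("coordinates must be finite")
        if not np.all(self.masses > 0):
            raise StructureError("all masses must be positive")
        for arr in (self.names, self.elements, self.resids, self.icodes,
                    self.resnames, self.chains, self.masses):
            if len(arr) != n:
                raise StructureError("per-atom arrays must share one length")
        # residue ids unique within a chain: a residue block may not recur
        seen: set = set()
        prev = None
        for ch, ri, ic in zip(self.chains, self.resids, self.icodes):
            key = (ch, int(ri), ic)
            if key != prev:
                if key in seen:
                    raise StructureError(
                        f"residue {ri}{ic} recurs non-contiguously in chain {ch}"
                    )
                seen.add(key)
                prev = key

    def residue_ids(self) -> list[int]:
        """Ordered unique residue numbers (insertion codes must be blank)."""
        out: list[int] = []
        prev = None
        for ri, ic in zip(self.resids, self.icodes):
            key = (int(ri), ic)
            if key != prev:
                out.append(int(ri))
                prev = key
        return out

    def sequence(self) -> str:
        """One-letter sequence over unique residues, ``X`` for unknowns."""
        seq = []
        prev = None
        for ri, ic, rn in zip(self.resids, self.icodes, self.resnames):
            key = (int(ri), ic)
            if key != prev:
                seq.append(AA3TO1.get(str(rn).upper(), "X"))
                prev = key
        return "".join(seq)

    def subset(self, idx: np.ndarray) -> "Structure":
        return Structure(
            names=self.names[idx], elements=self.elements[idx],
            resids=self.resids[idx], icodes=self.icodes[idx],
            resnames=self.resnames[idx], chains=self.chains[idx],
            coords=self.coords[idx], masses=self.masses[idx],
            provenance=dict(self.provenance),
        )

    def copy_with_coords(self, coords: np.ndarray) -> "Structure":
        s = self.subset(np.arange(self.n_atoms))
        s.coords = np.asarray(coords, dtype=float)
        return s


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing one topology."""

    topology: Structure
    frames: np.ndarray          # (F, N, 3) Å
    times: np.ndarray           # (F,) ps, strictly increasing
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must be (F, N, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"frames have {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if len(self.times) != len(self.frames):
            raise StructureError("times and frames must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.copy_with_coords(self.frames[i])


@dataclass
class ResidueMapping:
    """One-to-one ordered pairing of residue numbers between two structures."""

    pairs: list[tuple[int, int]]
    provenance: str = "explicit"
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        a_ids = [p[0] for p in self.pairs]
        b_ids = [p[1] for p in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise StructureError("residue mapping must be one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def a_ids(self) -> list[int]:
        return [p[0] for p in self.pairs]

    def b_ids(self) -> list[int]:
        return [p[1] for p in self.pairs]

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# provenance: {self.provenance}\n")
            for note in self.notes:
                fh.write(f"# {note}\n")
            for a, b in self.pairs:
                fh.write(f"{a} {b}\n")

    @classmethod
    def read(cls, path: str) -> "ResidueMapping":
        pairs = []
        provenance = "explicit"
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("# provenance:"):
                        provenance = line.split(":", 1)[1].strip()
                    continue
                a, b = line.split()
                pairs.append((int(a), int(b)))
        return cls(pairs=pairs, provenance=provenance)


# ---------------------------------------------------------------------------
# PDB parsing / writing
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    # in the 4-char field, two-letter elements occupy the first two columns
    if len(name) >= 2 and name[0] not in " 0123456789":
        cand = name[:2].strip().upper()
        if cand in ATOMIC_MASSES:
            return cand
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16]
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        resid = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise StructureError(
            f"malformed ATOM record at line {lineno}: {exc}"
        ) from exc
    if not element:
        element = _element_from_name(name)
    return {
        "name": name.strip(), "altloc": altloc.strip(), "resname": resname,
        "chain": chain, "resid": resid, "icode": icode,
        "xyz": (x, y, z), "occupancy": occupancy, "element": element,
    }


def _split_models(lines: Iterable[str]):
    """Split PDB lines into per-model lists of (lineno, atom-line)."""
    models: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    in_model = False
    for i, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec == "MODEL ":
            if current:
                models.append(current)
                current = []
            in_model = True
        elif rec == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec == "ATOM  ":
            current.append((i, line))
        # HETATM, TER, everything else dropped
    if current:
        models.append(current)
    if not models:
        models = [[]]
    _ = in_model
    return models


def _as_text(pdb_source) -> str:
    if hasattr(pdb_source, "read"):
        return pdb_source.read()
    text = str(pdb_source)
    if "\n" not in text and os.path.exists(text):
        with open(text) as fh:
            return fh.read()
    return text


def _atoms_to_structure(atoms: list[dict], provenance: dict) -> Structure:
    # altloc policy: per (chain, resid, icode, name) keep highest occupancy,
    # ties broken by lexicographically smallest altloc (blank sorts first)
    best: dict[tuple, dict] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a["chain"], a["resid"], a["icode"], a["name"])
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a["occupancy"], -ord(a["altloc"] or "A")) > (
                    b["occupancy"], -ord(b["altloc"] or "A")):
                best[key] = a
    kept = [best[k] for k in order]
    masses = []
    for a in kept:
        el = a["element"]
        if el not in ATOMIC_MASSES:
            raise StructureError(f"unknown element {el!r} for atom {a['name']}")
        masses.append(ATOMIC_MASSES[el])
    prov = dict(provenance)
    prov["altloc_policy"] = "highest-occupancy, ties -> altloc A"
    return Structure(
        names=np.array([a["name"] for a in kept]),
        elements=np.array([a["element"] for a in kept]),
        resids=np.array([a["resid"] for a in kept], dtype=int),
        icodes=np.array([a["icode"] for a in kept]),
        resnames=np.array([a["resname"] for a in kept]),
        chains=np.array([a["chain"] for a in kept]),
        coords=np.array([a["xyz"] for a in kept], dtype=float),
        masses=np.array(masses, dtype=float),
        provenance=prov,
    )


def read_structure(pdb_source, model_index: int = 0,
                   chain_id: str | None = None) -> Structure:
    """Read one model / one chain from PDB text or a PDB file path.

    Only ``ATOM`` records are kept (HETATM dropped); insertion codes are
    preserved.  ``model_index`` counts MODEL blocks from 0; single-model
    files have exactly one block.
    """
    text = _as_text(pdb_source)
    models = _split_models(text.splitlines())
    if not (0 <= model_index < len(models)):
        raise StructureError(
            f"model index {model_index} not available; file has "
            f"{len(models)} model(s) (indices 0..{len(models) - 1})"
        )
    atoms = [_parse_atom_line(line, no) for no, line in models[model_index]]
    if chain_id is not None:
        available = sorted({a["chain"] for a in atoms})
        atoms = [a for a in atoms if a["chain"] == chain_id]
        if not atoms:
            raise StructureError(
                f"chain {chain_id!r} not found; available chains: {available}"
            )
    if not atoms:
        raise StructureError("no ATOM records found in the requested model")
    prov = {"model_index": model_index, "chain_id": chain_id}
    return _atoms_to_structure(atoms, prov)


def _format_atom_line(serial, name, resname, chain, resid, icode, xyz, element):
    if len(name) < 4:
        name = " " + name
    return (
        f"ATOM  {serial % 100000:5d} {name:<4s} {resname:<3s} {chain:1s}"
        f"{resid:4d}{icode or ' ':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


def pdb_text(structure: Structure, coords: np.ndarray | None = None) -> str:
    """Render a Structure (optionally with replacement coords) as PDB text."""
    xyz = structure.coords if coords is None else np.asarray(coords)
    lines = []
    for i in range(structure.n_atoms):
        lines.append(_format_atom_line(
            i + 1, str(structure.names[i]), str(structure.resnames[i]),
            str(structure.chains[i]), int(structure.resids[i]),
            str(structure.icodes[i]), xyz[i], str(structure.elements[i]),
        ))
    lines.append("END\n")
    return "".join(lines)


def write_pdb(structure: Structure, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(pdb_text(structure))


def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write a trajectory as a multi-model PDB (text baseline format)."""
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"MODEL     {i + 1:4d}\n")
            body = pdb_text(traj.topology, traj.frames[i])
            fh.write(body[: body.rindex("END")])
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory(source, topology: Structure | None = None,
                    dt_ps: float = 1.0, t0_ps: float = 0.0,
                    times: Sequence[float] | None = None) -> Trajectory:
    """Read a trajectory from a multi-model PDB (baseline) or, for other
    file extensions, via MDAnalysis when it is installed.

    Frame times are ``t0 + i*dt`` unless ``times`` is given explicitly.
    """
    if isinstance(source, str) and not source.lower().endswith(
            (".pdb", ".ent")) and "\n" not in source and os.path.exists(source):
        return _read_trajectory_mda(source, topology, dt_ps, t0_ps)
    text = _as_text(source)
    models = _split_models(text.splitlines())
    frames = []
    topo = topology
    for mi, model in enumerate(models):
        atoms = [_parse_atom_line(line, no) for no, line in model]
        if not atoms:
            raise StructureError(f"model {mi} contains no ATOM records")
        s = _atoms_to_structure(atoms, {"model_index": mi})
        if topo is None:
            topo = s
        elif s.n_atoms != topo.n_atoms:
            raise StructureError(
                f"model {mi} has {s.n_atoms} atoms, expected {topo.n_atoms}"
            )
        frames.append(s.coords)
    if times is None:
        times = t0_ps + dt_ps * np.arange(len(frames))
    return Trajectory(topology=topo, frames=np.array(frames),
                      times=np.asarray(times, dtype=float))


def _read_trajectory_mda(path, topology, dt_ps, t0_ps) -> Trajectory:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise StructureError(
            f"cannot read {path!r}: not a PDB and MDAnalysis is unavailable"
        ) from exc
    u = mda.Universe(path)
    if topology is None:
        raise StructureError("a topology Structure is required for MD formats")
    frames, times = [], []
    for ts in u.trajectory:
        frames.append(ts.positions.astype(float).copy())
        times.append(float(ts.time) if ts.time is not None else
                     t0_ps + dt_ps * len(times))
    return Trajectory(topology=topology, frames=np.array(frames),
                      times=np.array(times))


# ---------------------------------------------------------------------------
# Selection and mapping
# ---------------------------------------------------------------------------

def parse_ranges(spec: str) -> list[tuple[int, int]]:
    """Parse ``"27-71,76-175"`` into inclusive (lo, hi) intervals."""
    out = []
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part[1:]:
            split_at = part.index("-", 1)
            lo, hi = int(part[:split_at]), int(part[split_at + 1:])
        else:
            lo = hi = int(part)
        out.append((lo, hi))
    return out


def select_atoms(s: Structure,
                 residue_ranges: Sequence[tuple[int, int]],
                 atom_names: set | Sequence | None = None) -> Structure:
    """Filter atoms by inclusive residue-number intervals and atom names.

    Order is preserved.  An empty selection is an error, never an empty
    result.
    """
    if not residue_ranges:
        raise StructureError("residue_ranges must be nonempty")
    mask = np.zeros(s.n_atoms, dtype=bool)
    for lo, hi in residue_ranges:
        mask |= (s.resids >= lo) & (s.resids <= hi)
    if atom_names is not None:
        names = set(atom_names)
        mask &= np.isin(s.names, list(names))
    if not mask.any():
        avail = (int(s.resids.min()), int(s.resids.max()))
        raise StructureError(
            f"selection {list(residue_ranges)}"
            f"{'' if atom_names is None else ' with names ' + str(sorted(set(atom_names)))}"
            f" matched no atoms; available residue range {avail[0]}-{avail[1]}"
        )
    return s.subset(np.where(mask)[0])


def _needleman_wunsch(a: str, b: str, match: int = 1, mismatch: int = -1,
                      gap: int = -2) -> list[tuple[int, int]]:
    """Global alignment; returns aligned (index_a, index_b) column pairs."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(np.frombuffer(a[i - 1].encode() * m, dtype="S1") ==
                       np.frombuffer(b.encode(), dtype="S1"), match, mismatch)
        for j in range(1, m + 1):
            score[i, j] = max(score[i - 1, j - 1] + sub[j - 1],
                              score[i - 1, j] + gap,
                              score[i, j - 1] + gap)
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        s_diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1]
                                        else mismatch)
        if score[i, j] == s_diag:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif score[i, j] == score[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def map_residues(a: Structure, b: Structure, spec) -> ResidueMapping:
    """Build a one-to-one residue correspondence between two structures.

    ``spec`` is one of:

    * an explicit list of ``(resid_a, resid_b)`` pairs,
    * ``"offset K"`` / ``("offset", K)`` — residue k in *a* maps to k+K in *b*,
    * ``"align"`` — built-in global alignment (match +1 / mismatch −1 /
      gap −2) of the one-letter sequences; explicit pairs always override.
    """
    ids_a = a.residue_ids()
    ids_b = b.residue_ids()
    set_a, set_b = set(ids_a), set(ids_b)
    notes: list[str] = []

    if isinstance(spec, (list, tuple)) and spec and \
            isinstance(spec[0], (list, tuple)) and not (
                isinstance(spec[0], str)):
        pairs = [(int(x), int(y)) for x, y in spec]
        for x, y in pairs:
            if x not in set_a:
                raise StructureError(f"residue {x} absent from structure A")
            if y not in set_b:
                raise StructureError(f"residue {y} absent from structure B")
        return ResidueMapping(pairs=pairs, provenance="explicit")

    if isinstance(spec, (list, tuple)) and len(spec) == 2 and \
            spec[0] == "offset":
        spec = f"offset {spec[1]}"
    if isinstance(spec, str) and spec.strip().lower().startswith("offset"):
        k = int(spec.replace(":", " ").split()[1])
        pairs = [(r, r + k) for r in ids_a if r + k in set_b]
        dropped = len(ids_a) - len(pairs)
        if not pairs:
            raise StructureError(f"offset {k} maps no residues")
        if dropped:
            notes.append(f"{dropped} residue(s) of A had no partner at offset {k}")
        return ResidueMapping(pairs=pairs, provenance="offset", notes=notes)

    if spec == "align":
        seq_a, seq_b = a.sequence(), b.sequence()
        cols = _needleman_wunsch(seq_a, seq_b)
        pairs = [(ids_a[i], ids_b[j]) for i, j in cols]
        frac = len(pairs) / max(1, min(len(ids_a), len(ids_b)))
        if frac < 0.5:
            msg = f"alignment paired only {frac:.0%} of residues"
            warnings.warn(msg)
            notes.append(msg)
        return ResidueMapping(pairs=pairs, provenance="aligned", notes=notes)

    raise StructureError(f"unrecognized mapping spec: {spec!r}")


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def rmsd(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


def _check_nondegenerate(pts: np.ndarray, label: str) -> None:
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] <= 1e-8 * max(1.0, s[0]):
        raise StructureError(f"{label} point cloud is degenerate (collinear)")


def superpose(x: np.ndarray, y: np.ndarray):
    """Least-squares rigid superposition of ``y`` onto ``x`` (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``y @ rotation.T + translation`` best fits ``x``; the rotation is
    proper (det = +1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StructureError(
            f"point counts differ: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 3:
        raise StructureError("superposition needs at least 3 points")
    _check_nondegenerate(x, "reference")
    _check_nondegenerate(y, "mobile")
    cx = x.mean(axis=0)
    cy = y.mean(axis=0)
    h = (y - cy).T @ (x - cx)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cx - rot @ cy
    fitted = y @ rot.T + trans
    return rot, trans, rmsd(x, fitted)


def apply_transform(coords: np.ndarray, rot: np.ndarray,
                    trans: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ rot.T + trans


def node_coords(s: Structure, resids: Sequence[int],
                atom_name: str = "CA") -> np.ndarray:
    """Coordinates of one named atom per residue, in the order of ``resids``."""
    index: dict[int, int] = {}
    for i in range(s.n_atoms):
        if str(s.names[i]) == atom_name:
            index.setdefault(int(s.resids[i]), i)
    missing = [r for r in resids if r not in index]
    if missing:
        raise StructureError(
            f"atom {atom_name} missing for residues {missing[:8]}"
            f"{'...' if len(missing) > 8 else ''}"
        )
    return s.coords[[index[r] for r in resids]]


def node_indices(s: Structure, resids: Sequence[int],
                 atom_name: str = "CA") -> np.ndarray:
    """Atom indices of one named atom per residue, ordered like ``resids``."""
    index: dict[int, int] = {}
    for i in range(s.n_atoms):
        if str(s.names[i]) == atom_name:
            index.setdefault(int(s.resids[i]), i)
    missing = [r for r in resids if r not in index]
    if missing:
        raise StructureError(
            f"atom {atom_name} missing for residues {missing[:8]}"
            f"{'...' if len(missing) > 8 else ''}"
        )
    return np.array([index[r] for r in resids], dtype=int)


def rmsd_trace(traj: Trajectory, ref: Structure,
               mapping: ResidueMapping | None = None,
               atom_name: str = "CA") -> np.ndarray:
    """Per-frame superposed RMSD against a reference on mapped nodes.

    Returns an (F, 2) array of ``(time_ps, rmsd_Å)`` rows.  With no
    mapping, residues are matched by identical residue number.
    """
    if mapping is None:
        common = [r for r in traj.topology.residue_ids()
                  if r in set(ref.residue_ids())]
        mapping = ResidueMapping([(r, r) for r in common],
                                 provenance="identity")
    if len(mapping) < 3:
        raise StructureError("mapping resolves fewer than 3 nodes")
    traj_idx = node_indices(traj.topology, mapping.a_ids(), atom_name)
    ref_xyz = node_coords(ref, mapping.b_ids(), atom_name)
    out = np.empty((traj.n_frames, 2))
    for f in range(traj.n_frames):
        mob = traj.frames[f][traj_idx]
        _, _, r = superpose(ref_xyz, mob)
        out[f] = (traj.times[f], r)
    return out
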