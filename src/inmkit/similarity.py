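"""Mode matching, frequency-weighted structural similarity, and state calls.

The similarity between two conformations is computed from their elastic
networks: the n lowest-frequency internal modes of the query are each
matched to the template mode (within a low-frequency pool) of maximal
absolute overlap, and the similarity is the template-frequency-weighted
mean of those absolute overlaps:

    S = Σ_i ω_{m(i)} |<v_i, v_{m(i)}>| / Σ_i ω_{m(i)}      ∈ [0, 1]

Trajectory snapshots are treated instantaneously: every frame is its own
elastic-network reference structure, rigidly superposed onto the template
before comparison.  Note S(a, b) need not equal S(b, a); the convention
throughout is query = snapshot, template = reference structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Sequence

import numpy as np
import pandas as pd

from inmkit.enm import ModeSet, compute_modes
from inmkit.structures import (
    ResidueMapping, Structure, StructureError, Trajectory, node_coords,
    node_indices, superpose, apply_transform,
)

__all__ = [
    "Template", "SimilarityTrace", "StateCall",
    "match_modes", "inm_similarity", "compare_structures",
    "similarity_trace",
    "classify_trajectory", "tabulate_transitions",
]

DEFAULT_POOL = 10


@dataclass
class Template:
    """A reference structure with the residue mapping used to extract nodes.

    ``mapping`` pairs are (trajectory/query resid, template resid); ``None``
    means identical residue numbering.
    """

    structure: Structure
    mapping: ResidueMapping | None = None
    name: str = "template"
    atom_name: str = "CA"

    def query_resids(self, query: Structure) -> list[int]:
        if self.mapping is not None:
            return self.mapping.a_ids()
        own = set(self.structure.residue_ids())
        return [r for r in query.residue_ids() if r in own]

    def template_resids(self, query: Structure) -> list[int]:
        if self.mapping is not None:
            return self.mapping.b_ids()
        return self.query_resids(query)

    def node_xyz(self, query: Structure) -> np.ndarray:
        return node_coords(self.structure, self.template_resids(query),
                           self.atom_name)


@dataclass
class SimilarityTrace:
    """Per-frame similarity of a trajectory to open and closed templates."""

    times: np.ndarray
    s_open: np.ndarray
    s_closed: np.ndarray
    n_modes: int
    open_id: str = "open"
    closed_id: str = "closed"
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.s_open = np.asarray(self.s_open, dtype=float)
        self.s_closed = np.asarray(self.s_closed, dtype=float)
        if not (len(self.times) == len(self.s_open) == len(self.s_closed)):
            raise ValueError("trace arrays must share one length")
        for arr in (self.s_open, self.s_closed):
            if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
                raise ValueError("similarities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def to_tsv(self, path_or_buf) -> None:
        buf = StringIO()
        buf.write(f"# n_modes={self.n_modes}\n")
        buf.write(f"# open={self.open_id} closed={self.closed_id}\n")
        for k in sorted(self.config):
            buf.write(f"# {k}={self.config[k]}\n")
        buf.write("time_ps\ts_open\ts_closed\n")
        for t, so, sc in zip(self.times, self.s_open, self.s_closed):
            buf.write(f"{float(t)!r}\t{float(so)!r}\t{float(sc)!r}\n")
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "SimilarityTrace":
        if hasattr(path_or_buf, "read"):
            lines = path_or_buf.read().splitlines()
        else:
            with open(path_or_buf) as fh:
                lines = fh.read().splitlines()
        n_modes, open_id, closed_id, config = 2, "open", "closed", {}
        rows = []
        for line in lines:
            if line.startswith("#"):
                body = line[1:].strip()
                for tok in body.split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        if k == "n_modes":
                            n_modes = int(v)
                        elif k == "open":
                            open_id = v
                        elif k == "closed":
                            closed_id = v
                        else:
                            config[k] = v
            elif line and not line.startswith("time_ps"):
                rows.append([float(x) for x in line.split("\t")])
        arr = np.array(rows) if rows else np.empty((0, 3))
        return cls(times=arr[:, 0], s_open=arr[:, 1], s_closed=arr[:, 2],
                   n_modes=n_modes, open_id=open_id, closed_id=closed_id,
                   config=config)


@dataclass
class StateCall:
    """Frame labels, dwell segments and transition events for one trace."""

    labels: list[str]                       # open | closed | intermediate
    segments: list[tuple[str, int, int, int]]   # (state, first, last, n_frames)
    transitions: list[tuple[int, str]]      # (frame index, "open->closed" ...)
    high: float
    low: float
    dwell: int

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    @property
    def has_transition(self) -> bool:
        return self.n_transitions > 0

    @property
    def start_state(self) -> str:
        return self.segments[0][0] if self.segments else "none"

    @property
    def end_state(self) -> str:
        return self.segments[-1][0] if self.segments else "none"


def match_modes(query: ModeSet, template: ModeSet, n: int,
                pool: int = DEFAULT_POOL) -> list[tuple[int, int, float]]:
    """Match the n lowest query modes to template modes by max |overlap|.

    Query modes are taken in fixed ascending-frequency order; for each, the
    template mode among the ``pool`` lowest maximizing the absolute inner
    product is selected.  Duplicate template hits are allowed.  Returns
    ``(query_index, template_index, |overlap|)`` triples.
    """
    if query.dim != template.dim:
        raise ValueError(
            f"mode dimensionality differs: {query.dim} vs {template.dim}")
    if query.n_modes < n:
        raise ValueError(f"query has {query.n_modes} modes, need {n}")
    pool = min(pool, template.n_modes)
    if pool < n:
        raise ValueError(
            f"template pool of {pool} modes is smaller than n={n}")
    overlaps = np.abs(query.eigenvectors[:, :n].T @
                      template.eigenvectors[:, :pool])
    out = []
    for i in range(n):
        m = int(np.argmax(overlaps[i]))
        out.append((i, m, float(overlaps[i, m])))
    return out


def inm_similarity(query: ModeSet, template: ModeSet, n: int,
                   pool: int = DEFAULT_POOL) -> float:
    """Frequency-weighted mean absolute overlap of matched modes, in [0, 1].

    Weights are the frequencies of the matched template ("target") modes.
    The query structure must already be rigidly superposed onto the
    template's mapped nodes before its modes are computed.
    """
    matches = match_modes(query, template, n, pool=pool)
    w = np.array([template.frequencies[m] for _, m, _ in matches])
    ov = np.array([o for _, _, o in matches])
    if np.all(w == 0):
        w = np.ones_like(w)
    return float(np.sum(w * ov) / np.sum(w))


def _rotate_modes(modes: ModeSet, rot: np.ndarray) -> ModeSet:
    """Apply one rigid rotation to every per-node 3-vector of each mode."""
    dim = modes.dim
    v = modes.eigenvectors.reshape(dim // 3, 3, -1)
    rotated = np.einsum("ab,nbk->nak", rot, v).reshape(dim, -1)
    return ModeSet(eigenvalues=modes.eigenvalues, eigenvectors=rotated,
                   n_rigid=modes.n_rigid, frequencies=modes.frequencies)


def _template_modes(template: Template, query_topology: Structure,
                    cutoff: float, pool_modes: int) -> tuple[np.ndarray, ModeSet]:
    xyz = template.node_xyz(query_topology)
    modes = compute_modes(xyz, cutoff=cutoff, n_modes=pool_modes)
    return xyz, modes


def compare_structures(query: Structure, template: Structure,
                       mapping: ResidueMapping, n: int = 2,
                       cutoff: float = 13.0, pool: int = DEFAULT_POOL,
                       atom_name: str = "CA") -> dict:
    """Single-shot INM similarity and superposed RMSD between two structures.

    ``mapping`` pairs are (query resid, template resid).  The query's
    mapped nodes are rigidly superposed onto the template's before the
    query network is built.  Returns ``{"similarity", "rmsd", "n_nodes"}``.
    """
    q_xyz = node_coords(query, mapping.a_ids(), atom_name)
    t_xyz = node_coords(template, mapping.b_ids(), atom_name)
    rot, trans, r = superpose(t_xyz, q_xyz)
    fitted = apply_transform(q_xyz, rot, trans)
    q_modes = compute_modes(fitted, cutoff=cutoff, n_modes=n)
    t_modes = compute_modes(t_xyz, cutoff=cutoff, n_modes=max(pool, n))
    return {
        "similarity": inm_similarity(q_modes, t_modes, n, pool=pool),
        "rmsd": r,
        "n_nodes": len(mapping),
    }


def similarity_trace(traj: Trajectory, open_template: Template,
                     closed_template: Template, n: int = 2,
                     cutoff: float = 13.0, stride_ps: float | None = None,
                     pool: int = DEFAULT_POOL) -> SimilarityTrace:
    """Instantaneous-normal-mode similarity of each snapshot to two templates.

    Per retained snapshot: extract mapped nodes, rigidly superpose onto
    each template, rebuild the elastic network at the snapshot geometry,
    diagonalize, and compute the similarity with the same ``n`` against
    both templates.
    """
    topo = traj.topology
    open_resids = open_template.query_resids(topo)
    closed_resids = closed_template.query_resids(topo)
    if len(open_resids) != len(closed_resids):
        raise StructureError(
            f"templates resolve different node counts: "
            f"{len(open_resids)} vs {len(closed_resids)}")
    idx_open = node_indices(topo, open_resids, open_template.atom_name)
    idx_closed = node_indices(topo, closed_resids, closed_template.atom_name)

    pool_modes = max(pool, n)
    open_xyz, open_modes = _template_modes(open_template, topo, cutoff,
                                           pool_modes)
    closed_xyz, closed_modes = _template_modes(closed_template, topo, cutoff,
                                               pool_modes)

    if stride_ps is not None and traj.n_frames > 1:
        dt = float(traj.times[1] - traj.times[0])
        if stride_ps < dt - 1e-9:
            raise ValueError(
                f"stride {stride_ps} ps is finer than frame spacing {dt} ps")
        step = max(1, int(round(stride_ps / dt)))
        keep = np.arange(0, traj.n_frames, step)
    else:
        keep = np.arange(traj.n_frames)

    same_nodes = np.array_equal(idx_open, idx_closed)
    times, s_open, s_closed = [], [], []
    for f in keep:
        frame = traj.frames[f]
        try:
            # The spring set is rotation-invariant, so the snapshot's modes
            # are computed once and their eigenvectors rotated onto each
            # template's frame (exactly equivalent to recomputing after
            # superposition).
            if same_nodes:
                q_xyz = frame[idx_open]
                q_modes = compute_modes(q_xyz, cutoff=cutoff, n_modes=n)
                for t_xyz, t_modes, sink in (
                        (open_xyz, open_modes, s_open),
                        (closed_xyz, closed_modes, s_closed)):
                    rot, _, _ = superpose(t_xyz, q_xyz)
                    sink.append(inm_similarity(
                        _rotate_modes(q_modes, rot), t_modes, n, pool=pool))
            else:
                pairs = ((frame[idx_open], open_xyz, open_modes, s_open),
                         (frame[idx_closed], closed_xyz, closed_modes,
                          s_closed))
                for q_xyz, t_xyz, t_modes, sink in pairs:
                    rot, trans, _ = superpose(t_xyz, q_xyz)
                    fitted = apply_transform(q_xyz, rot, trans)
                    q_modes = compute_modes(fitted, cutoff=cutoff, n_modes=n)
                    sink.append(inm_similarity(q_modes, t_modes, n,
                                               pool=pool))
        except (ValueError, StructureError) as exc:
            raise StructureError(f"frame {f}: {exc}") from exc
        times.append(traj.times[f])
    return SimilarityTrace(
        times=np.array(times), s_open=np.array(s_open),
        s_closed=np.array(s_closed), n_modes=n,
        open_id=open_template.name, closed_id=closed_template.name,
        config={"cutoff": cutoff, "pool": pool, "stride_ps": stride_ps},
    )


def classify_trajectory(trace: SimilarityTrace, high: float = 0.95,
                        low: float = 0.85, dwell: int = 5) -> StateCall:
    """Label frames open/closed/intermediate and count dwell transitions.

    A frame is *open* when ``s_open >= high`` and ``s_closed <= low``;
    *closed* when the converse holds; otherwise *intermediate*.  Dwell
    segments are maximal runs of one state; intermediate frames never
    terminate a run, only an opposing-state frame does.  A transition is
    recorded between consecutive qualifying segments (>= ``dwell`` state
    frames each) of different states.
    """
    if not (0 <= low < high <= 1):
        raise ValueError("thresholds must satisfy 0 <= low < high <= 1")
    if dwell < 1:
        raise ValueError("dwell must be >= 1")
    labels = []
    for so, sc in zip(trace.s_open, trace.s_closed):
        if so >= high and sc <= low:
            labels.append("open")
        elif sc >= high and so <= low:
            labels.append("closed")
        else:
            labels.append("intermediate")
    runs: list[dict] = []
    for f, lab in enumerate(labels):
        if lab == "intermediate":
            continue
        if runs and runs[-1]["state"] == lab:
            runs[-1]["frames"].append(f)
        else:
            runs.append({"state": lab, "frames": [f]})
    segments = [(r["state"], r["frames"][0], r["frames"][-1],
                 len(r["frames"])) for r in runs]
    qualifying = [s for s in segments if s[3] >= dwell]
    transitions = []
    for prev, cur in zip(qualifying, qualifying[1:]):
        if prev[0] != cur[0]:
            transitions.append((cur[1], f"{prev[0]}->{cur[0]}"))
    return StateCall(labels=labels, segments=qualifying,
                     transitions=transitions, high=high, low=low, dwell=dwell)


def _round_half_up_pct(count: int, total: int) -> int:
    return int(np.floor(100.0 * count / total + 0.5))


def tabulate_transitions(calls: Sequence[tuple], ) -> pd.DataFrame:
    """Tabulate transition percentages grouped by (protein tag, start state).

    ``calls`` is a sequence of ``(protein, start_state, call)`` where
    ``call`` is a :class:`StateCall` or anything with a boolean
    ``has_transition`` attribute (a plain bool also works).  Percentages
    are rounded to the nearest integer, half away from zero.
    """
    if not calls:
        raise ValueError("no calls to tabulate")
    groups: dict[tuple[str, str], list] = {}
    order: list[tuple[str, str]] = []
    for protein, start_state, call in calls:
        key = (str(protein), str(start_state))
        if key not in groups:
            groups[key] = []
            order.append(key)
        flag = call if isinstance(call, (bool, np.bool_)) else bool(
            call.has_transition)
        groups[key].append(flag)
    rows = []
    for protein, start_state in order:
        flags = groups[(protein, start_state)]
        total = len(flags)
        n_trans = sum(flags)
        rows.append({
            "protein": protein,
            "start_state": start_state,
            "total": total,
            "no_transition_pct": _round_half_up_pct(total - n_trans, total),
            "transition_pct": _round_half_up_pct(n_trans, total),
        })
    return pd.DataFrame(rows)
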