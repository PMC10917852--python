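"""Branch decomposition of tree-structured traces, and reassembly.

A neuron trace is a rooted tree of knots; the mapping machinery operates on
non-bifurcating *branches*, each an arc-length-parameterized polyline. The
decomposition recursively removes the root-to-leaf path with the longest arc
length, so the first branch is the longest root-to-leaf path and every
remaining subtree is processed the same way from the junction node where it
hangs off an already-extracted branch. Junction nodes are copied into every
branch that passes through them; reassembly fuses those copies back together,
which preserves the topology of the original tree.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .errors import JunctionConsistencyError
from .swc_io import NeuronTrace, TraceNode

__all__ = ["Branch", "BranchDecomposition", "decompose_branches", "reassemble"]

#: Mapped copies of a junction node must agree to this (microns); they are
#: produced by evaluating the same function at the same point, so anything
#: larger signals a non-function transformation or a bug.
JUNCTION_TOLERANCE = 1e-9


@dataclass
class Branch:
    """A non-bifurcating polyline with cumulative-arc-length timestamps.

    ``timestamps[i] - timestamps[i-1]`` equals the Euclidean length of the
    i-th segment and ``timestamps[0] == 0``, i.e. the polyline is
    parameterized by arc length. ``origin_ids`` keeps the trace node id of
    each knot so junction copies can be matched during reassembly.
    """

    knots: np.ndarray  # (n, 3) microns
    timestamps: np.ndarray  # (n,)
    origin_ids: list[int]

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.knots.ndim != 2 or self.knots.shape[1] != 3:
            raise ValueError("knots must be an (n, 3) array")
        n = len(self.knots)
        if n < 2:
            raise ValueError("a branch needs at least 2 knots")
        if self.timestamps.shape != (n,) or len(self.origin_ids) != n:
            raise ValueError("knots, timestamps and origin_ids must align")
        seglens = np.linalg.norm(np.diff(self.knots, axis=0), axis=1)
        dts = np.diff(self.timestamps)
        if np.any(dts <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.timestamps[0] != 0.0 or not np.allclose(dts, seglens, atol=1e-9):
            raise ValueError("timestamps must be cumulative arc length from 0")

    @classmethod
    def from_knots(cls, knots: np.ndarray, origin_ids: Sequence[int]) -> "Branch":
        knots = np.asarray(knots, dtype=float)
        seglens = np.linalg.norm(np.diff(knots, axis=0), axis=1)
        ts = np.concatenate([[0.0], np.cumsum(seglens)])
        return cls(knots, ts, list(origin_ids))

    @property
    def arc_length(self) -> float:
        return float(self.timestamps[-1])

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    def point_at(self, t: float) -> np.ndarray:
        """Position on the polyline at arc-length parameter ``t``."""
        t = float(np.clip(t, 0.0, self.arc_length))
        i = int(np.searchsorted(self.timestamps, t, side="right")) - 1
        i = min(max(i, 0), self.n_knots - 2)
        dt = self.timestamps[i + 1] - self.timestamps[i]
        w = (t - self.timestamps[i]) / dt
        return (1 - w) * self.knots[i] + w * self.knots[i + 1]


@dataclass
class BranchDecomposition:
    """Branches of a trace plus the bookkeeping needed to reassemble them."""

    branches: list[Branch]
    #: trace node id -> [(branch index, knot index)] for ids in >= 2 branches
    junction_map: dict[int, list[tuple[int, int]]]
    trace: NeuronTrace = field(repr=False)

    @property
    def total_arc_length(self) -> float:
        return float(sum(b.arc_length for b in self.branches))


def _downstream_stats(
    trace: NeuronTrace,
) -> dict[int, tuple[float, int]]:
    """For each node: (max arc length to a descendant leaf, leaf id achieving
    it, smaller leaf id on ties)."""
    pos = {n.id: n.position for n in trace.nodes}
    stats: dict[int, tuple[float, int]] = {}
    # iterative post-order
    stack = [(trace.root.id, False)]
    while stack:
        nid, processed = stack.pop()
        kids = trace.children_ids(nid)
        if not processed:
            stack.append((nid, True))
            stack.extend((k, False) for k in kids)
            continue
        if not kids:
            stats[nid] = (0.0, nid)
            continue
        best: tuple[float, int] | None = None
        for k in kids:
            d = float(np.linalg.norm(pos[k] - pos[nid]))
            length, leaf = stats[k]
            cand = (d + length, leaf)
            if best is None or cand[0] > best[0] or (
                cand[0] == best[0] and cand[1] < best[1]
            ):
                best = cand
        stats[nid] = best
    return stats


def decompose_branches(trace: NeuronTrace) -> BranchDecomposition:
    """Split ``trace`` into non-bifurcating branches.

    The first branch is the root-to-leaf path with the longest arc length
    (ties broken toward the smaller leaf id); each remaining subtree is
    extracted the same way, rooted at its junction node on an
    already-extracted branch, with that junction copied as the new branch's
    first knot. Every tree edge lands in exactly one branch.
    """
    stats = _downstream_stats(trace)
    pos = {n.id: n.position for n in trace.nodes}
    used_children: set[int] = set()  # child ids whose incoming edge is consumed

    def descend(start: int) -> list[int]:
        """Longest path downward from ``start`` through unconsumed edges."""
        path = [start]
        cur = start
        while True:
            kids = [k for k in trace.children_ids(cur) if k not in used_children]
            if not kids:
                return path
            best_k = None
            best = None
            for k in kids:
                d = float(np.linalg.norm(pos[k] - pos[cur]))
                length, leaf = stats[k]
                cand = (d + length, leaf, k)
                if (
                    best is None
                    or cand[0] > best[0]
                    or (cand[0] == best[0] and cand[1] < best[1])
                    or (cand[0] == best[0] and cand[1] == best[1] and cand[2] < best[2])
                ):
                    best, best_k = cand, k
            used_children.add(best_k)
            path.append(best_k)
            cur = best_k

    branches: list[Branch] = []
    occurrences: dict[int, list[tuple[int, int]]] = {}
    queue: deque[int] = deque()

    def emit(path_ids: list[int]) -> None:
        bi = len(branches)
        knots = np.array([pos[i] for i in path_ids])
        branches.append(Branch.from_knots(knots, path_ids))
        for ki, nid in enumerate(path_ids):
            occurrences.setdefault(nid, []).append((bi, ki))
        queue.extend(path_ids)

    emit(descend(trace.root.id))
    while queue:
        nid = queue.popleft()
        # each unconsumed child of a node already on a branch spawns a new
        # branch starting at the (copied) junction node
        while True:
            kids = [k for k in trace.children_ids(nid) if k not in used_children]
            if not kids:
                break
            emit(descend(nid))

    junction_map = {
        nid: occ for nid, occ in occurrences.items() if len(occ) >= 2
    }
    return BranchDecomposition(branches, junction_map, trace)


# replacement for one branch: either an (n_knots, 3) array (knot-level) or a
# (points, knot_sample_indices) pair for dense/upsampled output
Replacement = Union[np.ndarray, tuple[np.ndarray, np.ndarray]]


def _normalize_replacement(
    branch: Branch, repl: Replacement
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(repl, tuple):
        points, knot_idx = repl
        points = np.asarray(points, dtype=float)
        knot_idx = np.asarray(knot_idx, dtype=int)
    else:
        points = np.asarray(repl, dtype=float)
        knot_idx = np.arange(len(points))
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("replacement points must be (m, 3)")
    if knot_idx.shape != (branch.n_knots,):
        raise ValueError(
            f"knot index list must have one entry per original knot "
            f"({branch.n_knots}), got {knot_idx.shape}"
        )
    if knot_idx[0] != 0 or knot_idx[-1] != len(points) - 1:
        raise ValueError("replacement must start/end at the branch endpoints")
    return points, knot_idx


def reassemble(
    decomposition: BranchDecomposition,
    replacements: Sequence[Replacement],
    tolerance: float = JUNCTION_TOLERANCE,
) -> NeuronTrace:
    """Rebuild a tree-structured trace from per-branch replacement knots.

    Knot-level replacements (one point per original knot) preserve the
    original node ids, order and per-node metadata, so the identity mapping
    reproduces the input trace node-for-node. Dense replacements
    ``(points, knot_sample_indices)`` produce a renumbered trace whose
    interpolated nodes inherit ``structure_id``/``radius`` from the
    downstream original knot of their segment.

    Junction copies must land within ``tolerance`` microns of each other;
    they are fused into a single output node.
    """
    trace = decomposition.trace
    branches = decomposition.branches
    if len(replacements) != len(branches):
        raise ValueError(
            f"{len(branches)} branches but {len(replacements)} replacements"
        )
    normalized = [
        _normalize_replacement(b, r) for b, r in zip(branches, replacements)
    ]
    dense = any(len(p) != b.n_knots for b, (p, _) in zip(branches, normalized))

    # junction fusion consistency check
    for nid, occ in decomposition.junction_map.items():
        pts = [normalized[bi][0][normalized[bi][1][ki]] for bi, ki in occ]
        spread = max(
            float(np.linalg.norm(p - pts[0])) for p in pts[1:]
        ) if len(pts) > 1 else 0.0
        if spread > tolerance:
            raise JunctionConsistencyError(
                f"junction node {nid} maps to positions {spread:.3g} um apart "
                f"(> {tolerance} um)"
            )

    if not dense:
        # Preserve original ids/order: every output node is an original node
        # with a replaced position.
        new_pos: dict[int, np.ndarray] = {}
        for (points, knot_idx), branch in zip(normalized, branches):
            for ki, nid in enumerate(branch.origin_ids):
                new_pos.setdefault(nid, points[knot_idx[ki]])
        nodes = [
            TraceNode(n.id, n.structure_id, new_pos[n.id], n.radius, n.parent_id)
            for n in trace.nodes
        ]
        return NeuronTrace(nodes, list(trace.metadata))

    # Dense output: renumber sequentially in branch order, fusing junctions.
    nodes: list[TraceNode] = []
    next_id = 1
    # original node id -> output node id of its first (fused) copy
    fused: dict[int, int] = {}

    for bi, ((points, knot_idx), branch) in enumerate(zip(normalized, branches)):
        # per-sample metadata donor: the downstream original knot of the segment
        donors: list[TraceNode] = []
        ki = 0
        for si in range(len(points)):
            while ki < branch.n_knots - 1 and si > knot_idx[ki]:
                ki += 1
            # sample si lies at or before original knot ki
            donors.append(trace.node_by_id(branch.origin_ids[ki]))
        knot_sample = set(int(k) for k in knot_idx)

        start = 0
        if branch.origin_ids[0] in fused:
            parent_out = fused[branch.origin_ids[0]]
            start = 1  # skip the junction copy itself
        else:
            parent_out = -1
        for si in range(start, len(points)):
            donor = donors[si]
            node = TraceNode(next_id, donor.structure_id, points[si], donor.radius,
                             parent_out)
            nodes.append(node)
            parent_out = next_id
            if si in knot_sample:
                oid = branch.origin_ids[int(np.searchsorted(knot_idx, si))]
                fused.setdefault(oid, next_id)
            next_id += 1
    return NeuronTrace(nodes, list(trace.metadata))
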