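"""Reading, writing and validating neuron traces in SWC format.

SWC is the de-facto standard plain-text format for neuron reconstructions:
``#`` comment lines followed by whitespace-separated rows of
``id type x y z radius parent``, whose parent pointers form a rooted tree.
Positions are in microns throughout this package; no unit conversion is
performed. The SWC type code (``structure_id``) and radius are passed
through untouched — mapping is radius-free.

Traces containing *repeat nodes* (connected nodes closer than
``MIN_SEGMENT_LENGTH``) are rejected at read time: a zero-length segment
breaks the arc-length parameterization every downstream operation relies on.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

import numpy as np

from .errors import RepeatNodeError, SWCParseError, SWCStructureError

__all__ = [
    "TraceNode",
    "NeuronTrace",
    "read_swc",
    "write_swc",
    "MIN_SEGMENT_LENGTH",
]

#: Connected nodes closer than this (in microns) are treated as repeats.
MIN_SEGMENT_LENGTH = 1e-6


@dataclass
class TraceNode:
    """One SWC row: a sampled 3D point (a *knot*) of a neuron trace."""

    id: int
    structure_id: int
    position: np.ndarray  # shape (3,), microns
    radius: float
    parent_id: int  # -1 for the root

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got {self.position.shape}")
        if self.id <= 0:
            raise SWCStructureError(f"node id must be positive, got {self.id}")
        if self.radius < 0:
            raise SWCStructureError(f"node {self.id}: negative radius {self.radius}")


@dataclass
class NeuronTrace:
    """A validated rooted tree of :class:`TraceNode` (SWC semantics).

    ``metadata`` holds the verbatim comment header lines (leading ``#``
    included); they are preserved on write.
    """

    nodes: list[TraceNode]
    metadata: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------

    def node_by_id(self, node_id: int) -> TraceNode:
        return self._index[node_id]

    @property
    def root(self) -> TraceNode:
        return self._root

    def children_ids(self, node_id: int) -> list[int]:
        return self._children.get(node_id, [])

    def positions(self) -> np.ndarray:
        """All node positions as an (n, 3) array, in node order."""
        return np.array([n.position for n in self.nodes], dtype=float)

    def edges(self) -> Iterable[tuple[int, int]]:
        """(parent_id, child_id) pairs, in node order."""
        for n in self.nodes:
            if n.parent_id != -1:
                yield (n.parent_id, n.id)

    def __len__(self) -> int:
        return len(self.nodes)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if not self.nodes:
            raise SWCStructureError("trace has no nodes")
        index: dict[int, TraceNode] = {}
        for n in self.nodes:
            if n.id in index:
                raise SWCStructureError(f"duplicate node id {n.id}")
            index[n.id] = n

        roots = [n for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise SWCStructureError(
                f"trace must have exactly one root, found {len(roots)}"
            )
        children: dict[int, list[int]] = {}
        for n in self.nodes:
            if n.parent_id == -1:
                continue
            if n.parent_id not in index:
                raise SWCStructureError(
                    f"node {n.id} references missing parent {n.parent_id}"
                )
            if n.parent_id == n.id:
                raise SWCStructureError(f"node {n.id} is its own parent")
            children.setdefault(n.parent_id, []).append(n.id)
            d = float(np.linalg.norm(n.position - index[n.parent_id].position))
            if d < MIN_SEGMENT_LENGTH:
                raise RepeatNodeError(
                    f"nodes {n.parent_id} and {n.id} are {d:.3g} um apart "
                    f"(< {MIN_SEGMENT_LENGTH} um): repeat trace nodes are not supported"
                )

        # Reachability from the root proves acyclicity: every node has one
        # parent pointer, so any cycle would be disconnected from the root.
        reached = set()
        stack = [roots[0].id]
        while stack:
            nid = stack.pop()
            reached.add(nid)
            stack.extend(children.get(nid, []))
        if len(reached) != len(self.nodes):
            orphans = sorted(set(index) - reached)
            raise SWCStructureError(
                f"nodes {orphans} are not reachable from the root (cycle?)"
            )

        self._index = index
        self._root = roots[0]
        self._children = children


def _open_source(source: Union[str, os.PathLike, IO[str]]) -> tuple[IO[str], bool]:
    if isinstance(source, (str, os.PathLike)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_swc(source: Union[str, os.PathLike, IO[str]]) -> NeuronTrace:
    """Parse SWC text into a validated :class:`NeuronTrace`.

    Parameters
    ----------
    source
        Path or open text stream. Any column whitespace is accepted; node
        order and comment header are preserved.

    Raises
    ------
    SWCParseError
        On a malformed row (names the line number).
    SWCStructureError, RepeatNodeError
        When the node table violates the tree invariants.
    """
    stream, should_close = _open_source(source)
    try:
        metadata: list[str] = []
        nodes: list[TraceNode] = []
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                metadata.append(line)
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(
                    f"line {lineno}: expected 7 columns, got {len(parts)}: {line!r}"
                )
            try:
                nid = int(parts[0])
                stype = int(parts[1])
                xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
                radius = float(parts[5])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"line {lineno}: {exc}") from exc
            if not np.all(np.isfinite(xyz)) or not np.isfinite(radius):
                raise SWCParseError(f"line {lineno}: non-finite coordinate or radius")
            try:
                nodes.append(TraceNode(nid, stype, xyz, radius, parent))
            except (SWCStructureError, ValueError) as exc:
                raise SWCParseError(f"line {lineno}: {exc}") from exc
        return NeuronTrace(nodes, metadata)
    finally:
        if should_close:
            stream.close()


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def write_swc(trace: NeuronTrace, sink: Union[str, os.PathLike, IO[str]]) -> None:
    """Write ``trace`` as SWC text; re-parsing reproduces the node table.

    Positions and radii are printed with Python's shortest round-tripping
    float representation (always >= 6 significant digits where needed), so
    ``read_swc(write_swc(t))`` is the identity on the parsed node table.
    """
    trace.validate()
    if isinstance(sink, (str, os.PathLike)):
        with open(sink, "w", encoding="utf-8") as fh:
            write_swc(trace, fh)
        return
    for line in trace.metadata:
        sink.write(line if line.startswith("#") else "# " + line)
        sink.write("\n")
    for n in trace.nodes:
        x, y, z = n.position
        sink.write(
            f"{n.id} {n.structure_id} {_fmt(x)} {_fmt(y)} {_fmt(z)} "
            f"{_fmt(n.radius)} {n.parent_id}\n"
        )


def dumps_swc(trace: NeuronTrace) -> str:
    """Return the SWC text for ``trace`` as a string."""
    buf = io.StringIO()
    write_swc(trace, buf)
    return buf.getvalue()
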