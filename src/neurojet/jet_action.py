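"""k-jets of curves and the group action of diffeomorphisms on them.

A k-jet at parameter t bundles a curve's position with its first k
derivatives. Diffeomorphisms act on jets so that acting on the jet of a
curve equals taking the jet of the composed curve: position moves through
the map, the first derivative through the Jacobian, and the second
derivative through the Jacobian plus a Hessian correction,

    phi . (t, x0, x1, x2) = (t, phi(x0), Dphi(x0) x1,
                             Dphi(x0) x2 + D2phi(x0)(x1, x1)).

Orders are capped at k = 2 (mapping uses k = 1). One-sided derivatives on
arc-length-parameterized polylines are the unit chords of the segments; the
action generally breaks unit norm, and the mapped tangent is used as-is by
Hermite interpolation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateSegmentError
from .neuron_tree import Branch
from .swc_io import MIN_SEGMENT_LENGTH

__all__ = ["Jet", "JetSequence", "prolong", "act", "act_sequence", "MAX_ORDER"]

MAX_ORDER = 2


@dataclass
class Jet:
    """Position and first k derivatives of a curve at parameter ``t``."""

    t: float
    xs: tuple[np.ndarray, ...]  # (x0, ..., xk), each a 3-vector

    def __post_init__(self) -> None:
        self.xs = tuple(np.asarray(x, dtype=float) for x in self.xs)
        if not self.xs or any(x.shape != (3,) for x in self.xs):
            raise ValueError("jet components must be 3-vectors")
        if self.order > MAX_ORDER:
            raise ValueError(f"jet order {self.order} exceeds supported {MAX_ORDER}")

    @property
    def order(self) -> int:
        return len(self.xs) - 1

    @property
    def position(self) -> np.ndarray:
        return self.xs[0]


@dataclass
class JetSequence:
    """Time-stamped jets with strictly increasing t and a shared order."""

    jets: list[Jet]

    def __post_init__(self) -> None:
        if not self.jets:
            raise ValueError("empty jet sequence")
        orders = {j.order for j in self.jets}
        if len(orders) != 1:
            raise ValueError(f"jets must share one order, got {sorted(orders)}")
        ts = np.array([j.t for j in self.jets])
        if np.any(np.diff(ts) <= 0):
            raise ValueError("jet timestamps must be strictly increasing")

    @property
    def order(self) -> int:
        return self.jets[0].order

    def __len__(self) -> int:
        return len(self.jets)


def prolong(branch: Branch, k: int) -> list[tuple[Jet, Jet]]:
    """Extend a polyline branch to per-segment jet pairs of order ``k``.

    For k = 0 the jets carry positions only. For k = 1 both endpoint
    derivatives of segment [x_i, x_{i+1}] equal the unit chord
    (x_{i+1} - x_i) / |x_{i+1} - x_i|, i.e. one-sided derivatives: an
    interior knot carries a (generally different) derivative on each side,
    which permits tangent discontinuity at the knots — the piecewise-linear
    reading of an SWC trace.
    """
    if k not in (0, 1):
        raise ValueError(f"prolongation supports k in {{0, 1}}, got {k}")
    pairs: list[tuple[Jet, Jet]] = []
    for i in range(branch.n_knots - 1):
        x0, x1 = branch.knots[i], branch.knots[i + 1]
        t0, t1 = branch.timestamps[i], branch.timestamps[i + 1]
        L = float(np.linalg.norm(x1 - x0))
        if L < MIN_SEGMENT_LENGTH:
            raise DegenerateSegmentError(
                f"segment {i} of branch has length {L:.3g} um"
            )
        if k == 0:
            pairs.append((Jet(t0, (x0,)), Jet(t1, (x1,))))
        else:
            u = (x1 - x0) / L
            pairs.append((Jet(t0, (x0, u)), Jet(t1, (x1, u))))
    return pairs


def act(phi, jet: Jet) -> Jet:
    """Apply the jet-space action of ``phi`` to one jet.

    Requires derivatives of ``phi`` up to the jet's order: the Jacobian for
    k >= 1 (analytic or finite-difference) and the Hessian for k = 2
    (raises :class:`~neurojet.errors.CapabilityError` when unavailable).
    The timestamp is unchanged.
    """
    x0 = jet.xs[0]
    ys = [np.asarray(phi(x0), dtype=float)]
    if jet.order >= 1:
        J = phi.jacobian_at(x0)
        ys.append(J @ jet.xs[1])
    if jet.order >= 2:
        H = phi.hessian_at(x0)  # (3,3,3), symmetric in last two axes
        x1, x2 = jet.xs[1], jet.xs[2]
        ys.append(J @ x2 + np.einsum("abc,b,c->a", H, x1, x1))
    return Jet(jet.t, tuple(ys))


def act_sequence(phi, seq: JetSequence) -> JetSequence:
    """Act on every jet of a sequence; timestamps are preserved."""
    return JetSequence([act(phi, j) for j in seq.jets])
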