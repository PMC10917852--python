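"""Quantitative comparison of mapped traces.

Discrete Frechet distance between polylines (and its max over matched
branches for whole traces), the four standard morphometric quantities (path
angle, branch angle, tortuosity, segment length), and the two-sample
Kolmogorov-Smirnov statistic used to compare morphometric distributions.
Wilcoxon signed-rank with Bonferroni correction is exposed as a thin
convenience wrapper over scipy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import BranchCorrespondenceError, DegenerateSegmentError
from .neuron_tree import decompose_branches
from .swc_io import NeuronTrace

__all__ = [
    "discrete_frechet",
    "trace_frechet",
    "MorphometrySummary",
    "morphometry",
    "ks_statistic",
    "mean_sampling_period",
    "wilcoxon_signed_rank",
    "bonferroni",
]


def discrete_frechet(P: np.ndarray, Q: np.ndarray) -> float:
    """Discrete Frechet distance between two polylines (microns).

    Minimum over monotone couplings of the two point sequences of the
    maximum pairwise distance, via the standard dynamic program (rolling
    rows, O(|P| |Q|) time, O(|Q|) memory). Symmetric; an upper bound to the
    continuous Frechet distance.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.size == 0 or Q.size == 0:
        raise ValueError("discrete_frechet needs non-empty polylines")
    n, m = len(P), len(Q)
    d0 = np.linalg.norm(Q - P[0], axis=1)
    row = np.maximum.accumulate(d0).tolist()
    for i in range(1, n):
        di = np.linalg.norm(Q - P[i], axis=1).tolist()
        new = [max(row[0], di[0])]
        for j in range(1, m):
            reach = min(row[j], row[j - 1], new[j - 1])
            new.append(reach if reach > di[j] else di[j])
        row = new
    return float(row[-1])


def trace_frechet(A: NeuronTrace, B: NeuronTrace) -> float:
    """Max discrete Frechet distance over matched branches of two traces.

    ``A`` and ``B`` must be mappings of the same source trace; branches are
    paired in decomposition-extraction order, which coincides for mappings of
    a common source. Differing branch counts raise
    :class:`~neurojet.errors.BranchCorrespondenceError`.
    """
    da, db = decompose_branches(A), decompose_branches(B)
    if len(da.branches) != len(db.branches):
        raise BranchCorrespondenceError(
            f"traces decompose into {len(da.branches)} vs {len(db.branches)} branches"
        )
    return max(
        discrete_frechet(ba.knots, bb.knots)
        for ba, bb in zip(da.branches, db.branches)
    )


@dataclass
class MorphometrySummary:
    """Per-trace morphometric samples (units: degrees, ratios, microns)."""

    path_angles: np.ndarray
    branch_angles: np.ndarray
    tortuosities: np.ndarray
    segment_lengths: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "path_angle": self.path_angles,
            "branch_angle": self.branch_angles,
            "tortuosity": self.tortuosities,
            "segment_length": self.segment_lengths,
        }


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateSegmentError("zero-length vector in angle computation")
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def morphometry(trace: NeuronTrace) -> MorphometrySummary:
    """Compute the four standard morphometric quantities of a trace.

    * path angle, at each non-root node with exactly one child: the angle
      between the directions toward its parent and toward its child, so a
      straight continuation scores 180 degrees;
    * branch angle, at each bifurcation: the angle between the two (pairwise,
      if more) child directions;
    * tortuosity, per decomposed branch: arc length over endpoint Euclidean
      distance (>= 1);
    * segment length: Euclidean length of every parent-child edge.
    """
    path_angles: list[float] = []
    branch_angles: list[float] = []
    seg_lengths: list[float] = []
    for node in trace.nodes:
        kids = trace.children_ids(node.id)
        if node.parent_id != -1:
            seg_lengths.append(
                float(
                    np.linalg.norm(
                        node.position - trace.node_by_id(node.parent_id).position
                    )
                )
            )
        if len(kids) == 1 and node.parent_id != -1:
            parent = trace.node_by_id(node.parent_id)
            child = trace.node_by_id(kids[0])
            path_angles.append(
                _angle_deg(
                    parent.position - node.position, child.position - node.position
                )
            )
        elif len(kids) >= 2:
            for a, b in itertools.combinations(kids, 2):
                va = trace.node_by_id(a).position - node.position
                vb = trace.node_by_id(b).position - node.position
                branch_angles.append(_angle_deg(va, vb))

    tortuosities: list[float] = []
    for br in decompose_branches(trace).branches:
        chord = float(np.linalg.norm(br.knots[-1] - br.knots[0]))
        if chord > 0:
            tortuosities.append(br.arc_length / chord)
    return MorphometrySummary(
        np.asarray(path_angles),
        np.asarray(branch_angles),
        np.asarray(tortuosities),
        np.asarray(seg_lengths),
    )


def ks_statistic(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic: sup |ECDF_a - ECDF_b|."""
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_statistic needs non-empty samples")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def mean_sampling_period(trace: NeuronTrace) -> float:
    """Average distance between connected trace nodes (microns)."""
    dists = [
        float(np.linalg.norm(trace.node_by_id(c).position - trace.node_by_id(p).position))
        for p, c in trace.edges()
    ]
    if not dists:
        raise ValueError("trace has no edges")
    return float(np.mean(dists))


def wilcoxon_signed_rank(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples (scipy).

    Convenience only; returns (statistic, p-value).
    """
    res = stats.wilcoxon(sample_a, sample_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values, n_comparisons: int | None = None) -> np.ndarray:
    """Bonferroni-corrected p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    k = n_comparisons if n_comparisons is not None else p.size
    return np.minimum(p * k, 1.0)
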