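"""Worst-case error bounds for zeroth- and first-order mapping.

For a piecewise-linear, arc-length-parameterized curve c with knots t_i and a
diffeomorphism phi, write f = phi o c for the exactly transformed curve and
g0 / g1 for the zeroth- / first-order reconstructions.

* The **Jacobian bound** (zeroth order, C^1 maps) controls the linear-spline
  error per knot interval through how far Dphi strays from the identity and
  how much the displacement eps_i = c(t_i) - phi(c(t_i)) changes between
  consecutive knots:

      max_t |f - g0| <= max_{i, t in [t_{i-1}, t_i]}
          (|Dphi(c(t)) - I| |t_i - t_{i-1}| + |eps_i - eps_{i-1}|) / 2

  with the spectral norm for matrices. The supremum over t is approximated
  by dense probing (``n_probe`` per interval), making the computed value a
  lower estimate of the true supremum.

* The **derivative bounds** (C^4 maps, knot spacing delta = max gap) are
  classical interpolation bounds on the coordinate functions f_j:

      |f - g0| <= (3/4)  M4 (d/2)^4 + (3/2)(d/2)^2 M3 (d/2) + (3/2)(d/2)^2 M2
      |f - g1| <= (3/4!) M4 (d/2)^4,          d = delta

  where Mk = max |d^k f_j / dt^k|. The first-order bound is always the
  tighter of the two; their ratio tends to (3/4!)/(3/4) = 1/6 as M2, M3 -> 0.

The derivative maxima are estimated with central finite differences on a
dense probe grid per segment (each segment of a piecewise-linear source is a
piecewise-C^4 piece of f). M2 and M3 enter the zeroth-order bound evaluated
at the knots; reporting grid-wide maxima instead is an upper estimate and
keeps the computed bound conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffeo import Diffeomorphism
from .neuron_tree import Branch

__all__ = [
    "BoundReport",
    "jacobian_bound",
    "derivative_bounds",
    "estimate_f_derivative_maxima",
    "branch_sup_error",
]


@dataclass
class BoundReport:
    """A computed error bound plus the ingredients that produced it."""

    bound_value: float  # microns
    per_interval_terms: np.ndarray  # maximized summand per knot interval
    knot_spacing_delta: float  # max |t_i - t_{i-1}|
    inputs_descriptor: dict

    def __post_init__(self) -> None:
        if self.bound_value < 0:
            raise ValueError("a bound cannot be negative")


def jacobian_bound(
    branch: Branch, phi: Diffeomorphism, n_probe: int = 100
) -> BoundReport:
    """Zeroth-order (Jacobian) error bound for a piecewise-linear branch.

    For each knot interval the bracketed quantity is maximized over
    ``n_probe`` equispaced probe parameters; the report's ``bound_value`` is
    the max over intervals.
    """
    if n_probe < 2:
        raise ValueError("n_probe must be >= 2")
    eye = np.eye(3)
    knots = branch.knots
    ts = branch.timestamps
    eps = knots - phi(knots)  # eps_i = c(t_i) - phi(c(t_i))
    terms = np.empty(branch.n_knots - 1)
    for i in range(1, branch.n_knots):
        dt = float(ts[i] - ts[i - 1])
        w = np.linspace(0.0, 1.0, n_probe)[:, None]
        probes = (1 - w) * knots[i - 1] + w * knots[i]
        jac_dev = max(
            float(np.linalg.norm(phi.jacobian_at(p) - eye, 2)) for p in probes
        )
        deps = float(np.linalg.norm(eps[i] - eps[i - 1]))
        terms[i - 1] = 0.5 * (jac_dev * dt + deps)
    return BoundReport(
        bound_value=float(terms.max()),
        per_interval_terms=terms,
        knot_spacing_delta=float(np.diff(ts).max()),
        inputs_descriptor={
            "n_probe": n_probe,
            "n_knots": branch.n_knots,
            "phi": phi.descriptor,
        },
    )


def derivative_bounds(M2: float, M3: float, M4: float, delta: float) -> tuple[float, float]:
    """Derivative-based bounds for zeroth- and first-order mapping.

    Pure arithmetic on user-supplied coordinate-wise derivative maxima
    M2, M3, M4 and the maximum knot spacing ``delta``; returns
    ``(bound0, bound1)`` with ``bound1 <= bound0`` always.
    """
    if min(M2, M3, M4) < 0 or delta <= 0:
        raise ValueError("derivative maxima must be >= 0 and delta > 0")
    h = delta / 2.0
    bound0 = 0.75 * M4 * h**4 + 1.5 * h**2 * M3 * h + 1.5 * h**2 * M2
    bound1 = (3.0 / 24.0) * M4 * h**4
    return float(bound0), float(bound1)


def estimate_f_derivative_maxima(
    branch: Branch, phi: Diffeomorphism, probe_spacing: float = 0.5
) -> tuple[float, float, float]:
    """Estimate max |d^k f_j / dt^k|, k = 2, 3, 4, for f = phi o c.

    Central finite differences on a uniform probe grid along each segment
    (at least 7 probes per segment); maxima are taken over probes,
    coordinates and segments.
    """
    if probe_spacing <= 0:
        raise ValueError("probe_spacing must be positive")
    m2 = m3 = m4 = 0.0
    for i in range(branch.n_knots - 1):
        x0, x1 = branch.knots[i], branch.knots[i + 1]
        L = float(np.linalg.norm(x1 - x0))
        n = max(int(np.ceil(L / probe_spacing)) + 1, 7)
        t = np.linspace(0.0, 1.0, n)[:, None]
        h = L / (n - 1)
        f = phi((1 - t) * x0 + t * x1)  # (n, 3)
        d2 = (f[:-2] - 2 * f[1:-1] + f[2:]) / h**2
        d3 = (-f[:-4] + 2 * f[1:-3] - 2 * f[3:-1] + f[4:]) / (2 * h**3)
        d4 = (f[:-4] - 4 * f[1:-3] + 6 * f[2:-2] - 4 * f[3:-1] + f[4:]) / h**4
        m2 = max(m2, float(np.abs(d2).max()))
        m3 = max(m3, float(np.abs(d3).max()))
        m4 = max(m4, float(np.abs(d4).max()))
    return m2, m3, m4


def branch_sup_error(
    branch: Branch,
    phi: Diffeomorphism,
    method: str,
    n_probe: int = 200,
    fd_step: float | None = None,
) -> float:
    """Measured max deviation of a mapped branch from f = phi o c.

    Probes every segment densely; the companion quantity the bounds above
    are checked against.
    """
    from .mapping import segment_sup_error

    return max(
        segment_sup_error(
            branch.knots[i], branch.knots[i + 1], phi, method, n_probe, fd_step
        )
        for i in range(branch.n_knots - 1)
    )
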