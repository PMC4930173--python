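"""Co-attraction: chemotaxis toward a secreted, rapidly equilibrating field.

Every cell secretes a molecule c that diffuses and degrades much faster
than the cells move, so the field is slaved to the instantaneous cell
positions.  In two dimensions each point source contributes a screened
(Yukawa-type) profile K0(r/ell), where ell is the degradation length, and
the gradient it exerts at another cell is along the separation with
magnitude K1(r/ell).  Overall secretion/diffusion prefactors are absorbed
into the chemotaxis strength chi, because the polarity response normalizes
the gradient to a unit vector:

    bias = chi * grad_c / |grad_c|       if |grad_c| > g0, else 0.

The threshold g0 exists to avoid dividing by zero for vanishing gradients;
the response strength is otherwise independent of gradient magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import k0, k1

from .mechanics import DegenerateOverlapError, pairwise_geometry

__all__ = [
    "CoattractionParams",
    "coattract_gradient",
    "chemotaxis_bias",
    "coattract_field",
]

#: Distances below this are treated as coincident (kernel diverges).
_MIN_DISTANCE = 1e-12


@dataclass
class CoattractionParams:
    """Co-attraction parameters.

    chi : polarity bias strength (same units as polarity rate).
    ell : degradation length of the secreted field, in cell diameters.
    g0  : gradient-magnitude threshold below which the response is off.
    """

    chi: float = 0.0
    ell: float = 5.0
    g0: float = 1e-5

    def __post_init__(self) -> None:
        if self.ell <= 0:
            raise ValueError("ell must be positive")
        if self.g0 < 0 or self.chi < 0:
            raise ValueError("chi and g0 must be non-negative")


def coattract_gradient(positions: np.ndarray, i: int | None = None, ell: float = 5.0):
    """Gradient of the secreted field at cell positions (prefactor 1).

    grad c(r_i) = - sum_{j != i} K1(|r_i - r_j| / ell) rhat_ij

    pointing from each cell toward its secreting neighbors.  Returns the
    (N, 2) array of gradients, or a single vector when ``i`` is given.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 2:
        grads = np.zeros_like(pos)
    else:
        _, dist, rhat = pairwise_geometry(pos)
        if np.any(dist < _MIN_DISTANCE):
            raise DegenerateOverlapError("cells too close for kernel evaluation")
        kern = k1(dist / ell)  # diagonal distance is inf -> kernel 0
        grads = -np.einsum("ij,ijk->ik", kern, rhat)
    if i is None:
        return grads
    return grads[i]


def chemotaxis_bias(grad_c: np.ndarray, chi: float, g0: float = 1e-5) -> np.ndarray:
    """Polarity-rate contribution chi * grad_c/|grad_c| above threshold.

    Accepts a single vector or an (N, 2) array; the output magnitude is
    exactly chi wherever |grad_c| > g0 and zero elsewhere.
    """
    g = np.asarray(grad_c, dtype=float)
    single = g.ndim == 1
    g = np.atleast_2d(g)
    mag = np.sqrt(np.einsum("ik,ik->i", g, g))
    active = mag > g0
    out = np.zeros_like(g)
    if np.any(active):
        out[active] = chi * g[active] / mag[active, None]
    return out[0] if single else out


def coattract_field(
    positions: np.ndarray, query_points: np.ndarray, ell: float = 5.0
) -> np.ndarray:
    """Secreted-field values c(r) = ell * sum_j K0(|r - r_j| / ell).

    The ell factor makes the analytic gradient of this field exactly the
    K1 kernel sum of :func:`coattract_gradient` (both share the same
    arbitrary overall prefactor convention).
    """
    pos = np.asarray(positions, dtype=float)
    q = np.atleast_2d(np.asarray(query_points, dtype=float))
    diff = q[:, None, :] - pos[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if np.any(dist < _MIN_DISTANCE):
        raise DegenerateOverlapError("query point coincides with a cell")
    vals = ell * k0(dist / ell).sum(axis=1)
    return vals if np.asarray(query_points).ndim > 1 else float(vals[0])


def rasterize_field(
    positions: np.ndarray,
    extent: tuple[float, float, float, float],
    resolution: int = 100,
    ell: float = 5.0,
):
    """Sample c on a regular grid for plotting; returns (x, y, c) columns."""
    x0, x1, y0, y1 = extent
    xs = np.linspace(x0, x1, resolution)
    ys = np.linspace(y0, y1, resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    c = coattract_field(positions, pts, ell)
    return pts[:, 0], pts[:, 1], c
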