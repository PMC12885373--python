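"""Composition-dependent bias surfaces on the three-part simplex.

PCR bias is not uniform: how much a diversity metric shifts after ``x``
cycles depends on where the community sits in the simplex.  These sweeps
evaluate an alpha-metric bias at every point of a regular simplex lattice
(or a beta-metric bias between a fixed reference and every point), producing
a surface that can be rendered as a ternary diagram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bias import alpha_bias, beta_bias
from .compositions import ContrastMatrix, as_composition, make_contrast_matrix, phi, phi_inverse
from .diversity import MetricSpec, _as_metric

__all__ = [
    "BiasSurface",
    "perturbation_arrow",
    "render_ternary",
    "simplex_grid",
    "sweep_alpha",
    "sweep_beta",
    "ternary_coords",
]


def simplex_grid(step: float, floor: float = 1e-6) -> list[np.ndarray]:
    """Regular lattice on the 3-part simplex with every part >= ``floor``.

    Lattice points are ``(i, j, m - i - j) / m`` with ``m = round(1/step)``,
    so the grid is exact in floating point and the barycenter is included
    whenever 3 divides ``m``.  The boundary is excluded because log-ratio
    metrics need strictly positive parts.
    """
    if not 0 < step < 1:
        raise ValueError("step must lie in (0, 1)")
    if floor <= 0:
        raise ValueError("floor must be positive")
    m = int(round(1.0 / step))
    pts = []
    for i in range(m + 1):
        for j in range(m + 1 - i):
            p = np.array([i, j, m - i - j], dtype=float) / m
            if p.min() >= floor:
                pts.append(p)
    return pts


def ternary_coords(c) -> tuple[float, float]:
    """Barycentric-to-Cartesian map onto the unit triangle.

    ``x = p2 + p3/2``, ``y = (sqrt(3)/2) p3``: vertices map to (0,0), (1,0)
    and (1/2, sqrt(3)/2).
    """
    p = np.asarray(c, dtype=float)
    if p.ndim != 1 or p.size != 3:
        raise ValueError("ternary coordinates are defined for 3-part compositions")
    return float(p[1] + p[2] / 2.0), float(np.sqrt(3.0) / 2.0 * p[2])


@dataclass
class BiasSurface:
    """Grid of 3-part compositions with one metric-bias value per point."""

    points: list[np.ndarray]
    bias_values: np.ndarray
    metric: MetricSpec
    beta: np.ndarray
    cycles: float
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bias_values = np.asarray(self.bias_values, dtype=float)
        if len(self.points) != self.bias_values.size:
            raise ValueError("one bias value per grid point required")
        self.points = [as_composition(p) for p in self.points]

    def to_frame(self) -> pd.DataFrame:
        xy = np.array([ternary_coords(p) for p in self.points])
        arr = np.array(self.points)
        return pd.DataFrame(
            {
                "p1": arr[:, 0],
                "p2": arr[:, 1],
                "p3": arr[:, 2],
                "tern_x": xy[:, 0],
                "tern_y": xy[:, 1],
                "bias": self.bias_values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def _psi3(psi: ContrastMatrix | None) -> ContrastMatrix:
    if psi is None:
        return make_contrast_matrix("alr", 3)
    if psi.D != 3:
        raise ValueError("simplex sweeps are defined on 3 taxa")
    return psi


def sweep_alpha(
    metric,
    beta,
    x: float = 35.0,
    step: float = 0.01,
    floor: float = 1e-6,
    psi: ContrastMatrix | None = None,
) -> BiasSurface:
    """Alpha-metric bias at every grid point of the 3-part simplex."""
    psi = _psi3(psi)
    b = np.asarray(beta, dtype=float)
    if b.shape != (2,):
        raise ValueError("beta must be a 2-vector in the 3-taxon basis")
    spec = _as_metric(metric)
    pts = simplex_grid(step, floor)
    vals = np.array([alpha_bias(phi(p, psi), b, x, spec, psi) for p in pts])
    return BiasSurface(pts, vals, spec, b, float(x))


def sweep_beta(
    metric,
    reference,
    beta,
    x: float = 35.0,
    step: float = 0.01,
    floor: float = 1e-6,
    psi: ContrastMatrix | None = None,
    tree=None,
    taxon_ids=None,
) -> BiasSurface:
    """Beta-metric bias between a fixed reference and every grid point."""
    psi = _psi3(psi)
    ref = as_composition(reference)
    if ref.size != 3:
        raise ValueError("reference must be a 3-part composition")
    b = np.asarray(beta, dtype=float)
    if b.shape != (2,):
        raise ValueError("beta must be a 2-vector in the 3-taxon basis")
    spec = _as_metric(metric)
    alpha_ref = phi(ref, psi)
    pts = simplex_grid(step, floor)
    vals = np.array(
        [
            beta_bias(alpha_ref, phi(p, psi), b, x, spec, psi, tree=tree, taxon_ids=taxon_ids)
            for p in pts
        ]
    )
    return BiasSurface(pts, vals, spec, b, float(x), reference=ref)


def perturbation_arrow(beta, x: float, psi: ContrastMatrix | None = None):
    """Ternary endpoints of the bias arrow: barycenter -> perturbed barycenter."""
    psi = _psi3(psi)
    origin = np.full(3, 1.0 / 3.0)
    tip = phi_inverse(phi(origin, psi) + x * np.asarray(beta, dtype=float), psi)
    return ternary_coords(origin), ternary_coords(tip)


def render_ternary(surface: BiasSurface, path, title: str | None = None) -> None:
    """Render a bias surface as a ternary scatter (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = surface.to_frame()
    fig, ax = plt.subplots(figsize=(6, 5.5))
    lim = max(np.abs(frame["bias"]).max(), 1e-12)
    sc = ax.scatter(
        frame["tern_x"], frame["tern_y"], c=frame["bias"],
        cmap="RdBu_r", vmin=-lim, vmax=lim, s=6, linewidths=0,
    )
    tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0, 0]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    (ox, oy), (tx, ty) = perturbation_arrow(surface.beta, surface.cycles)
    ax.annotate("", xy=(tx, ty), xytext=(ox, oy),
                arrowprops={"color": "darkorange", "arrowstyle": "->", "lw": 2})
    ax.plot([ox], [oy], "o", color="green", ms=6)
    if surface.reference is not None:
        rx, ry = ternary_coords(surface.reference)
        ax.plot([rx], [ry], "o", mfc="none", mec="grey", ms=10, mew=2)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title or f"{surface.metric.name} bias after {surface.cycles:g} cycles")
    fig.colorbar(sc, ax=ax, shrink=0.8, label="bias")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
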