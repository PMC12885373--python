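"""Log-ratio geometry of the compositional simplex.

A *composition* is a vector of strictly positive relative abundances that
sums to one — a point on the (D-1)-simplex.  PCR amplification acts on
compositions multiplicatively, which becomes an additive shift
("perturbation") once compositions are mapped to log-ratio coordinates by a
contrast matrix Psi.  This module provides that algebra:

* :func:`make_contrast_matrix` — ALR and ILR contrast matrices,
* :func:`phi` / :func:`phi_inverse` — the log-ratio transform and its inverse,
* :func:`clr` — the centered log-ratio transform,
* :func:`perturb` — the simplex group operation in log-ratio coordinates.

All logarithms are natural.  Compositions are plain 1-D numpy arrays;
:func:`as_composition` validates them.  Zero parts are rejected here — the
algebra is exact on the open simplex, and pseudo-count zero handling lives
with count-table I/O (see :meth:`ampbias.synthetic.CountMatrix.compositions`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "SUM_ATOL",
    "ContrastMatrix",
    "as_composition",
    "close",
    "clr",
    "make_contrast_matrix",
    "perturb",
    "phi",
    "phi_inverse",
    "validate_efficiencies",
]

#: absolute tolerance for "sums to one" and round-trip checks
SUM_ATOL = 1e-12


def close(parts) -> np.ndarray:
    """Closure operation: rescale a positive vector to sum to one."""
    x = np.asarray(parts, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("a composition needs at least 2 parts in a 1-D vector")
    if not np.all(np.isfinite(x)) or np.any(x <= 0.0):
        raise ValueError("composition parts must be finite and strictly positive")
    return x / x.sum()


def as_composition(parts, *, atol: float = SUM_ATOL) -> np.ndarray:
    """Validate ``parts`` as a composition and return it as a float array.

    Raises ``ValueError`` when any part is non-positive, the vector has
    fewer than two parts, or the parts do not sum to one within ``atol``.
    """
    x = np.asarray(parts, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("a composition needs at least 2 parts in a 1-D vector")
    if not np.all(np.isfinite(x)) or np.any(x <= 0.0):
        raise ValueError("composition parts must be finite and strictly positive")
    if abs(x.sum() - 1.0) > atol:
        raise ValueError(f"composition parts must sum to 1 within {atol}, got {x.sum()!r}")
    return x


@dataclass(frozen=True)
class ContrastMatrix:
    """A (D-1) x D full-row-rank matrix whose rows sum to zero.

    Rows define the log-contrasts used by :func:`phi`; ``basis_kind`` records
    whether the matrix is the additive-log-ratio block ``[I, -1]``, an
    orthonormal isometric basis, or user supplied.
    """

    matrix: np.ndarray
    basis_kind: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] - 1 or m.shape[1] < 2:
            raise ValueError("contrast matrix must be (D-1) x D with D >= 2")
        if np.max(np.abs(m.sum(axis=1))) > SUM_ATOL:
            raise ValueError("each contrast-matrix row must sum to zero")
        if np.max(np.abs(m)) > 1.0 + SUM_ATOL:
            raise ValueError("contrast-matrix entries must lie in [-1, 1]")
        sv = np.linalg.svd(m, compute_uv=False)
        if sv[-1] <= m.shape[1] * np.finfo(float).eps * sv[0]:
            raise ValueError("contrast matrix must have rank D-1")
        object.__setattr__(self, "matrix", m)

    @property
    def D(self) -> int:
        """Number of parts the basis applies to."""
        return self.matrix.shape[1]

    @cached_property
    def pinv(self) -> np.ndarray:
        """Moore-Penrose pseudoinverse (D x (D-1)), cached."""
        return np.linalg.pinv(self.matrix)


_ALR_NAMES = {"alr", "additive-log-ratio"}
_ILR_NAMES = {"ilr", "isometric", "isometric-log-ratio"}


def make_contrast_matrix(kind: str, D: int) -> ContrastMatrix:
    """Build a named contrast matrix for ``D`` parts.

    ``kind='alr'`` gives the additive-log-ratio block ``[I_{D-1}, -1]``
    (log of each part relative to the last).  ``kind='ilr'`` gives an
    orthonormal (Helmert-type) isometric basis, in which Euclidean norms of
    coordinates equal clr norms.
    """
    if D < 2:
        raise ValueError(f"need at least 2 parts, got D={D}")
    key = str(kind).lower()
    if key in _ALR_NAMES:
        m = np.hstack([np.eye(D - 1), -np.ones((D - 1, 1))])
        return ContrastMatrix(m, basis_kind="additive-log-ratio")
    if key in _ILR_NAMES:
        m = np.zeros((D - 1, D))
        for i in range(1, D):
            scale = np.sqrt(i / (i + 1.0))
            m[i - 1, :i] = scale / i
            m[i - 1, i] = -scale
        return ContrastMatrix(m, basis_kind="isometric")
    raise ValueError(f"unknown contrast-matrix kind {kind!r}; use 'alr' or 'ilr'")


def phi(c, psi: ContrastMatrix) -> np.ndarray:
    """Log-ratio transform: ``psi @ log(c)`` — a (D-1)-vector of contrasts."""
    x = as_composition(c)
    if x.size != psi.D:
        raise ValueError(f"composition has {x.size} parts but basis expects {psi.D}")
    return psi.matrix @ np.log(x)


def phi_inverse(eta, psi: ContrastMatrix) -> np.ndarray:
    """Invert :func:`phi`: the unique composition with ``phi(c) == eta``.

    Because the rows of Psi sum to zero, the solution of ``Psi log c = eta``
    is unique up to a multiple of the all-ones vector, which the closure
    removes: ``c = close(exp(pinv(Psi) @ eta))``.
    """
    e = np.asarray(eta, dtype=float)
    if e.ndim != 1 or e.size != psi.D - 1:
        raise ValueError(f"log-ratio vector must have length {psi.D - 1}, got shape {e.shape}")
    if not np.all(np.isfinite(e)):
        raise ValueError("log-ratio coordinates must be finite")
    v = psi.pinv @ e
    v -= v.max()  # guard exp overflow; closure removes the shift
    p = np.exp(v)
    return p / p.sum()


def clr(c) -> np.ndarray:
    """Centered log-ratio transform: ``log(c) - mean(log(c))``; sums to zero."""
    x = as_composition(c)
    lx = np.log(x)
    return lx - lx.mean()


def perturb(eta, gamma) -> np.ndarray:
    """Perturbation in log-ratio coordinates: coordinate-wise sum.

    Both vectors must be expressed in the same basis; a length mismatch is
    treated as a basis mismatch and rejected.
    """
    e = np.asarray(eta, dtype=float)
    g = np.asarray(gamma, dtype=float)
    if e.ndim != 1 or g.ndim != 1 or e.size != g.size:
        raise ValueError("basis mismatch: perturb needs two log-ratio vectors of equal length")
    if not (np.all(np.isfinite(e)) and np.all(np.isfinite(g))):
        raise ValueError("log-ratio coordinates must be finite")
    return e + g


def validate_efficiencies(b) -> np.ndarray:
    """Validate a per-taxon, per-cycle amplification-efficiency vector.

    Efficiencies live in [1, 2]: 1 means no amplification, 2 perfect
    doubling each cycle.
    """
    x = np.asarray(b, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("efficiency vector must be 1-D with at least 2 taxa")
    if np.any(x < 1.0) or np.any(x > 2.0) or not np.all(np.isfinite(x)):
        raise ValueError("amplification efficiencies must lie in [1, 2]")
    return x
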