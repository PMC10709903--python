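"""Triple scoring functions f : X^3 -> R (higher = more plausible).

Three geometries are provided:

* translation in R^n  (``transe``):   f = -|| h + r - t ||_p
* bilinear product in C^n (``complex``): f = Re <h, r, conj(t)>
* rotation in C^n (``rotate``):       f = -|| h o r - t ||_p  with |r_i| = 1

Complex vectors of dimension n are stored as 2n reals: the first n entries
are the real parts, the last n the imaginary parts.  Rotation relations are
parameterized by n unconstrained phase angles theta, r_i = exp(i * theta_i),
so the unit-modulus constraint holds by construction under gradient updates.

Each scorer exposes a batched ``score`` (inputs broadcast over the leading
axes) and a ``grad`` returning the partial derivatives of the score with
respect to the three embeddings, used by the training loop's hand-rolled
backward pass.  The subgradient of |x| at 0 is taken as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EmbeddingSpaceSpec:
    """The embedding space X: real R^n or complex C^n (stored as 2n reals)."""

    field: str  # "real" | "complex"
    dimension: int

    def __post_init__(self) -> None:
        if self.field not in ("real", "complex"):
            raise ValueError(f"unknown field {self.field!r}")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")

    @property
    def storage_dim(self) -> int:
        """Number of reals used to store one vector of X."""
        return self.dimension * (2 if self.field == "complex" else 1)


def _check_last_dim(*arrays: np.ndarray) -> None:
    dims = {a.shape[-1] for a in arrays}
    if len(dims) != 1:
        raise ValueError(f"dimension mismatch: {sorted(dims)}")


def _split_complex(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[-1]
    if n % 2:
        raise ValueError("complex storage requires an even number of reals")
    return x[..., : n // 2], x[..., n // 2 :]


def _neg_norm(d: np.ndarray, p: int) -> np.ndarray:
    if p == 1:
        return -np.sum(np.abs(d), axis=-1)
    if p == 2:
        return -np.sqrt(np.sum(d * d, axis=-1))
    raise ValueError(f"norm must be 1 or 2, got {p}")


def _neg_norm_grad(d: np.ndarray, p: int) -> np.ndarray:
    """d(-||d||_p)/dd, with the subgradient at 0 taken as 0."""
    if p == 1:
        return -np.sign(d)
    nrm = np.sqrt(np.sum(d * d, axis=-1, keepdims=True))
    return -np.divide(d, nrm, out=np.zeros_like(d), where=nrm > 0)


# ---------------------------------------------------------------------------
# Functional forms
# ---------------------------------------------------------------------------

def score_transe(h: np.ndarray, r: np.ndarray, t: np.ndarray, norm: int = 2) -> np.ndarray:
    """Translational score -||h + r - t||_norm; 0 iff t is the exact translation."""
    h, r, t = np.asarray(h, float), np.asarray(r, float), np.asarray(t, float)
    _check_last_dim(h, r, t)
    return _neg_norm(h + r - t, norm)


def score_complex(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Re(sum_i h_i r_i conj(t_i)), on the 2n-real storage convention."""
    h, r, t = np.asarray(h, float), np.asarray(r, float), np.asarray(t, float)
    _check_last_dim(h, r, t)
    hr, hi = _split_complex(h)
    rr, ri = _split_complex(r)
    tr, ti = _split_complex(t)
    return np.sum((hr * rr - hi * ri) * tr + (hr * ri + hi * rr) * ti, axis=-1)


def score_rotate(
    h: np.ndarray, r_phase: np.ndarray, t: np.ndarray, norm: int = 2
) -> np.ndarray:
    """-||h o exp(i*theta) - t||_norm; invariant under theta -> theta + 2*pi."""
    h, t = np.asarray(h, float), np.asarray(t, float)
    theta = np.asarray(r_phase, float)
    _check_last_dim(h, t)
    hr, hi = _split_complex(h)
    if theta.shape[-1] != hr.shape[-1]:
        raise ValueError(
            f"phase dimension {theta.shape[-1]} != complex dimension {hr.shape[-1]}"
        )
    tr, ti = _split_complex(t)
    c, s = np.cos(theta), np.sin(theta)
    d_re = hr * c - hi * s - tr
    d_im = hr * s + hi * c - ti
    return _neg_norm(np.concatenate([d_re, d_im], axis=-1), norm)


# ---------------------------------------------------------------------------
# Scorer objects (score + gradients, used by training)
# ---------------------------------------------------------------------------

class Scorer:
    """Interface: batched score plus partial derivatives of the score."""

    name: str
    space: EmbeddingSpaceSpec

    @property
    def entity_dim(self) -> int:
        return self.space.storage_dim

    @property
    def relation_dim(self) -> int:
        return self.space.storage_dim

    def score(self, h, r, t):  # pragma: no cover - interface
        raise NotImplementedError

    def grad(self, h, r, t):  # pragma: no cover - interface
        raise NotImplementedError


class TransEScorer(Scorer):
    name = "transe"

    def __init__(self, dimension: int, norm: int = 2):
        self.space = EmbeddingSpaceSpec("real", dimension)
        self.norm = norm

    def score(self, h, r, t):
        return score_transe(h, r, t, self.norm)

    def grad(self, h, r, t):
        h, r, t = np.asarray(h, float), np.asarray(r, float), np.asarray(t, float)
        g = _neg_norm_grad(h + r - t, self.norm)
        return g, g, -g


class ComplExScorer(Scorer):
    name = "complex"

    def __init__(self, dimension: int):
        self.space = EmbeddingSpaceSpec("complex", dimension)

    def score(self, h, r, t):
        return score_complex(h, r, t)

    def grad(self, h, r, t):
        h, r, t = np.asarray(h, float), np.asarray(r, float), np.asarray(t, float)
        hr, hi = _split_complex(h)
        rr, ri = _split_complex(r)
        tr, ti = _split_complex(t)
        gh = np.concatenate([rr * tr + ri * ti, -ri * tr + rr * ti], axis=-1)
        gr = np.concatenate([hr * tr + hi * ti, -hi * tr + hr * ti], axis=-1)
        gt = np.concatenate([hr * rr - hi * ri, hr * ri + hi * rr], axis=-1)
        return gh, gr, gt


class RotatEScorer(Scorer):
    """Relation = elementwise rotation; relation rows store phase angles."""

    name = "rotate"

    def __init__(self, dimension: int, norm: int = 2):
        self.space = EmbeddingSpaceSpec("complex", dimension)
        self.norm = norm

    @property
    def relation_dim(self) -> int:
        return self.space.dimension  # n phases, not 2n reals

    def score(self, h, r, t):
        return score_rotate(h, r, t, self.norm)

    def grad(self, h, r, t):
        h, t = np.asarray(h, float), np.asarray(t, float)
        theta = np.asarray(r, float)
        hr, hi = _split_complex(h)
        tr, ti = _split_complex(t)
        c, s = np.cos(theta), np.sin(theta)
        d_re = hr * c - hi * s - tr
        d_im = hr * s + hi * c - ti
        gd = _neg_norm_grad(np.concatenate([d_re, d_im], axis=-1), self.norm)
        g_re, g_im = _split_complex(gd)
        gh = np.concatenate([g_re * c + g_im * s, -g_re * s + g_im * c], axis=-1)
        gtheta = g_re * (-hr * s - hi * c) + g_im * (hr * c - hi * s)
        gt = -gd
        return gh, gtheta, gt


def make_scorer(name: str, dimension: int, norm: int = 2) -> Scorer:
    """Build a scorer from a config key ``transe|complex|rotate``."""
    if name == "transe":
        return TransEScorer(dimension, norm)
    if name == "complex":
        return ComplExScorer(dimension)
    if name == "rotate":
        return RotatEScorer(dimension, norm)
    raise ValueError(f"unknown scorer {name!r}")
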