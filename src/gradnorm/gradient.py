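"""Connectivity gradients: diffusion map embedding, templates, alignment.

The principal gradient is the first non-trivial component of a diffusion
map embedding of the connectivity affinity matrix; it spans the cortical
hierarchy from unimodal sensory parcels to the transmodal default-mode
apex. Individual embeddings carry arbitrary sign/rotation, so they are
aligned to a group template (built from the group-averaged connectivity
matrix, not averaged embeddings) by orthogonal Procrustes rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from .atlas import ParcelAtlas
from .connectome import (ConnectivityMatrix, normalized_angle_affinity,
                         row_threshold)

_DEGENERATE_GAP = 1e-10


@dataclass(frozen=True)
class GradientSet:
    """P x k embedding plus its eigenvalues and alignment state."""

    components: np.ndarray
    eigenvalues: np.ndarray
    aligned: bool = False
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if self.components.ndim != 2 or self.components.shape[1] < 1:
            raise ValueError("components must be P x k with k >= 1")
        if not np.all(np.isfinite(self.components)):
            raise ValueError("non-finite gradient components")
        ev = self.eigenvalues
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("eigenvalues must be nonincreasing")

    @property
    def k(self) -> int:
        return self.components.shape[1]

    @property
    def g1(self) -> np.ndarray:
        """Principal gradient (component 1)."""
        return self.components[:, 0]


@dataclass(frozen=True)
class TemplateGradient:
    """Template embedding derived from a group-mean connectivity matrix."""

    components: np.ndarray
    eigenvalues: np.ndarray
    source: str = "group-mean connectivity"


def diffusion_embedding(affinity: np.ndarray, k: int = 10, alpha: float = 0.5,
                        diffusion_time: float = 0.0) -> GradientSet:
    """Diffusion map embedding of a symmetric nonnegative affinity matrix.

    The affinity is density-normalized by row sums to the power ``alpha``
    (0.5 = Fokker-Planck convention), turned into a row-stochastic Markov
    operator, and eigendecomposed through its symmetric conjugate. The
    trivial constant eigenvector is dropped; the next ``k`` eigenvectors
    are scaled by ``lambda/(1 - lambda)`` when ``diffusion_time == 0`` or
    by ``lambda**t`` otherwise. Component signs are deterministic (first
    element of largest magnitude is positive).
    """
    W = np.asarray(affinity, dtype=float)
    P = W.shape[0]
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("affinity must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if np.any(W < 0):
        raise ValueError("affinity entries must be nonnegative")
    if not 1 <= k < P:
        raise ValueError(f"k must satisfy 1 <= k < P, got k={k}, P={P}")
    n_comp, labels = connected_components(W > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"affinity graph is disconnected ({n_comp} components, "
            f"sizes {sizes.tolist()})")

    d = W.sum(axis=1)
    Wn = W / np.outer(d, d) ** alpha if alpha != 0 else W
    d1 = Wn.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d1)
    M = Wn * np.outer(inv_sqrt, inv_sqrt)  # symmetric conjugate of the Markov operator
    M = (M + M.T) / 2.0
    evals, evecs = eigh(M)
    order = np.argsort(evals)[::-1]
    evals = evals[order][: k + 1]
    evecs = evecs[:, order][:, : k + 1]

    # right eigenvectors of the Markov operator, normalized so the trivial
    # one is constant
    psi = evecs * inv_sqrt[:, None]
    psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
    lam = evals[1:]
    if np.any(np.abs(np.diff(evals)) < _DEGENERATE_GAP):
        warnings.warn("degenerate eigenvalue spectrum; components are "
                      "defined only up to rotation within degenerate blocks",
                      stacklevel=2)
    if diffusion_time == 0:
        denom = np.where(np.abs(1.0 - lam) < 1e-15, 1e-15, 1.0 - lam)
        scale = lam / denom
    else:
        scale = lam ** diffusion_time
    comps = psi[:, 1:] * scale
    comps = _fix_signs(comps)
    return GradientSet(components=comps, eigenvalues=lam)


def _fix_signs(comps: np.ndarray) -> np.ndarray:
    out = comps.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            out[:, j] = -col
    return out


def build_template(fc_list, k: int = 10, density: float = 0.10,
                   alpha: float = 0.5, diffusion_time: float = 0.0,
                   orient_atlas: ParcelAtlas | None = None) -> TemplateGradient:
    """Template gradient from the element-wise mean connectivity matrix.

    The mean z-matrix is row-thresholded, converted to a normalized-angle
    affinity and embedded. When ``orient_atlas`` is given, the sign of
    component 1 is fixed so DMN parcels have positive mean loading
    (sensory parcels at the negative pole), the conventional orientation
    of the cortical hierarchy axis.
    """
    fc_list = list(fc_list)
    if not fc_list:
        raise ValueError("need at least one connectivity matrix")
    mats = [m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
            for m in fc_list]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent matrix shapes: {sorted(shapes)}")
    mean_z = np.mean(mats, axis=0)
    np.fill_diagonal(mean_z, 0.0)
    aff = normalized_angle_affinity(row_threshold(mean_z, density))
    emb = diffusion_embedding(aff, k=k, alpha=alpha, diffusion_time=diffusion_time)
    comps = emb.components
    if orient_atlas is not None:
        dmn = orient_atlas.indices("DMN")
        if comps[dmn, 0].mean() < 0:
            comps = comps.copy()
            comps[:, 0] = -comps[:, 0]
    return TemplateGradient(components=comps, eigenvalues=emb.eigenvalues)


def procrustes_align(individual: GradientSet, template: TemplateGradient | GradientSet,
                     scaling: bool = False) -> GradientSet:
    """Align an individual embedding to a template by orthogonal rotation.

    Finds the orthogonal matrix R minimizing ``||individual @ R -
    template||_F`` (rotation/reflection only; optional single global scale
    when ``scaling``), and returns the rotated embedding flagged as
    aligned.
    """
    A = individual.components
    B = template.components
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: individual {A.shape} vs template {B.shape}")
    R, s = orthogonal_procrustes(A, B)
    out = A @ R
    if scaling:
        out = out * (s / np.sum(A**2))
    return replace(individual, components=out, aligned=True,
                   reference_id=getattr(template, "source", "template"))


def subject_gradients(fc: ConnectivityMatrix, template: TemplateGradient,
                      k: int = 10, density: float = 0.10, alpha: float = 0.5,
                      diffusion_time: float = 0.0) -> GradientSet:
    """Convenience: threshold, affinity, embed and align one subject."""
    aff = normalized_angle_affinity(row_threshold(fc, density))
    emb = diffusion_embedding(aff, k=k, alpha=alpha, diffusion_time=diffusion_time)
    return procrustes_align(emb, template)
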