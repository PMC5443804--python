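"""Dihedral PCA and free-energy landscapes.

Backbone dihedral angles are mapped to the (cos, sin) circle to remove
the periodic discontinuity, terminal-residue angles are excluded, and a
principal component analysis of the resulting features yields the
collective coordinates V1, V2.  The conformational free-energy surface is

    dG(V1, V2) = -kB*T * ln( P(V1, V2) / Pmax )

reported in kBT units (so the global minimum is 0 by construction).
Minima are located by topographic persistence so that shallow sampling
ripples below a depth threshold are not reported as states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .errors import AnalysisError, ParameterError

__all__ = [
    "DihedralTrajectory",
    "FEPGrid",
    "Minimum",
    "featurize",
    "project",
    "free_energy",
    "find_minima",
    "DihedralPCA",
]


@dataclass
class DihedralTrajectory:
    """Frames x angles matrix of backbone dihedrals in degrees (-180, 180]."""

    angles: np.ndarray
    labels: list[tuple[int, str]]      # (residue index, angle name)
    terminal_mask: np.ndarray          # True = terminal residue angle, excluded

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.terminal_mask = np.asarray(self.terminal_mask, dtype=bool)
        if self.angles.ndim != 2:
            raise ParameterError("angles must be frames x n_angles")
        n_angles = self.angles.shape[1]
        if len(self.labels) != n_angles or self.terminal_mask.size != n_angles:
            raise ParameterError("labels/terminal_mask length must match n_angles")
        if np.any(self.angles <= -180.0) or np.any(self.angles > 180.0):
            raise ParameterError("angles must lie in (-180, 180] degrees")


@dataclass
class FEPGrid:
    """2-D free-energy surface over (V1, V2) in kBT units.

    Empty bins carry the sentinel ``empty_value`` (+inf) rather than a
    capped number, so that minima searches only ever see populated bins.
    """

    v1_edges: np.ndarray
    v2_edges: np.ndarray
    deltaG: np.ndarray
    pmax_bin: tuple[int, int]
    counts: np.ndarray | None = None
    empty_value: float = np.inf

    @property
    def populated(self) -> np.ndarray:
        return np.isfinite(self.deltaG)


@dataclass
class Minimum:
    bin: tuple[int, int]
    deltaG: float
    persistence: float


def featurize(traj: DihedralTrajectory) -> np.ndarray:
    """Map kept dihedrals to (cos, sin) pairs: frames x 2*n_kept."""
    if traj.angles.shape[0] < 2:
        raise ParameterError("need at least 2 frames")
    kept = ~traj.terminal_mask
    if not np.any(kept):
        raise ParameterError("no dihedrals left after excluding terminal residues")
    theta = np.deg2rad(traj.angles[:, kept])
    feats = np.empty((theta.shape[0], 2 * theta.shape[1]))
    feats[:, 0::2] = np.cos(theta)
    feats[:, 1::2] = np.sin(theta)
    return feats


class DihedralPCA(BaseEstimator, TransformerMixin):
    """PCA on circular dihedral features with a deterministic sign convention.

    Components are orientation-fixed by making the largest-magnitude loading
    of each component positive.  Fitted attributes: ``components_``,
    ``explained_variance_``, ``explained_variance_ratio_``, ``mean_``.
    """

    def __init__(self, n_components=2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 3:
            raise ParameterError("need at least 3 frames for PCA")
        if np.allclose(np.var(X, axis=0), 0.0):
            raise AnalysisError("zero-variance features: landscape undefined")
        pca = PCA(n_components=self.n_components)
        pca.fit(X)
        comps = pca.components_.copy()
        for k in range(comps.shape[0]):
            j = np.argmax(np.abs(comps[k]))
            if comps[k, j] < 0:
                comps[k] = -comps[k]
        self._pca = pca
        self.components_ = comps
        self.mean_ = pca.mean_
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T


def project(features) -> tuple[np.ndarray, np.ndarray]:
    """Top-2 principal components of the features.

    Returns ``(V, explained_variance_ratio)`` with ``V`` of shape
    (frames, 2).
    """
    est = DihedralPCA(n_components=2).fit(features)
    return est.transform(features), est.explained_variance_ratio_


def free_energy(v1, v2, grid_bins=50, padding=0.05) -> FEPGrid:
    """Histogram the (V1, V2) projections and convert to dG in kBT.

    dG = -ln(P/Pmax); the factor kB*T is carried as the unit, so the
    returned surface is dimensionless in kBT.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.size != v2.size or v1.size == 0:
        raise ParameterError("V1 and V2 must be equal-length, nonempty")

    def _edges(v):
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo if hi > lo else max(abs(hi), 1.0)
        pad = padding * span
        return np.linspace(lo - pad, hi + pad, grid_bins + 1)

    e1, e2 = _edges(v1), _edges(v2)
    counts, _, _ = np.histogram2d(v1, v2, bins=[e1, e2])
    pmax = counts.max()
    if pmax <= 0:
        raise AnalysisError("empty histogram")
    with np.errstate(divide="ignore"):
        dg = -np.log(counts / pmax)
    dg[counts == 0] = np.inf
    if np.count_nonzero(counts) == 1:
        warnings.warn("all frames fall in a single bin: degenerate landscape")
    i, j = np.unravel_index(np.argmax(counts), counts.shape)
    return FEPGrid(v1_edges=e1, v2_edges=e2, deltaG=dg,
                   pmax_bin=(int(i), int(j)), counts=counts)


def find_minima(fep: FEPGrid, depth_threshold: float = 0.5,
                min_count: int = 5) -> list[Minimum]:
    """Local minima of the landscape, filtered by topographic persistence.

    Populated bins are processed in order of increasing dG (a watershed
    flooding): a bin with no previously-seen 8-neighbor starts a new basin;
    when two basins meet, the meeting level is the saddle and the shallower
    basin's persistence is saddle - birth.  Only minima with persistence
    >= ``depth_threshold`` (kBT) are returned; the global minimum has
    infinite persistence and is therefore always reported, with dG = 0.

    Bins visited by fewer than ``min_count`` frames are sampling noise, not
    landscape features, and do not participate in the search (without this
    cutoff every isolated tail bin would count as a spurious minimum).
    """
    dg = fep.deltaG
    if fep.counts is not None and min_count > 1:
        dg = np.where(fep.counts >= min_count, dg, np.inf)
    pop = np.argwhere(np.isfinite(dg))
    if pop.size == 0:
        return []
    order = np.argsort(dg[pop[:, 0], pop[:, 1]], kind="stable")
    cells = [tuple(c) for c in pop[order]]

    parent: dict[tuple[int, int], tuple[int, int]] = {}
    birth: dict[tuple[int, int], float] = {}

    def find(c):
        root = c
        while parent[root] != root:
            root = parent[root]
        while parent[c] != root:
            parent[c], c = root, parent[c]
        return root

    minima: list[Minimum] = []
    seen = set()
    for c in cells:
        i, j = c
        roots = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                nb = (i + di, j + dj)
                if nb != c and nb in seen:
                    roots.add(find(nb))
        if not roots:
            parent[c] = c
            birth[c] = float(dg[c])
        else:
            # merge into the deepest basin; others die at this saddle level
            deepest = min(roots, key=lambda r: birth[r])
            for r in roots:
                if r is not deepest and r != deepest:
                    persistence = float(dg[c]) - birth[r]
                    if persistence >= depth_threshold:
                        minima.append(Minimum(bin=r, deltaG=birth[r],
                                              persistence=persistence))
                    parent[r] = deepest
            parent[c] = deepest
        seen.add(c)

    # Surviving roots are basins that never merged into a deeper one: the
    # global minimum, plus any basin disconnected from it (its barrier was
    # never sampled, i.e. is effectively infinite).  The min_count cutoff has
    # already removed sparse noise patches, so survivors are real features.
    survivors = {find(c) for c in seen}
    for r in survivors:
        minima.append(Minimum(bin=r, deltaG=birth[r], persistence=np.inf))
    minima.sort(key=lambda m: m.deltaG)
    return minima
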