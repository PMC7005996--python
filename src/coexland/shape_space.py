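"""PCA landscape shape-space: fitting, projection, archetypes.

Treating every model of a sweep as a replicate and every (n_x, n_y)
grid cell as a feature, a mean-centered PCA (raw covariance, no
feature scaling) of a landscape library yields a small set of
orthonormal components that span the dominant landscape shapes. The
scores of a landscape along these components are its shape
coordinates; empirical landscapes projected into a model-trained
("theory-driven") space inherit the same coordinates, making model
and data directly comparable.

Eigenvectors are sign-invariant, so a convention is frozen: the
components are flipped so that the hi/hi archetype (both genes fully
on) scores nonnegatively on components 1 and 2; deeper components get
their largest-magnitude loading made positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy.stats import poisson
from sklearn.decomposition import PCA

from .steady_state import DEFAULT_FLOOR, CoexpressionLandscape, quasipotential
from .sweep import LandscapeLibrary

__all__ = [
    "ShapeSpace",
    "ShapeCoordinates",
    "fit_shape_space",
    "project",
    "project_features",
    "motif_occupancy",
    "archetype_landscape",
]

ARCHETYPES = ("lo/lo", "hi/hi", "antagonistic", "asymmetric")


@dataclass(frozen=True)
class ShapeCoordinates:
    """Scores of one landscape along the shape components."""

    scores: np.ndarray

    def __getitem__(self, i: int) -> float:
        return float(self.scores[i])

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class ShapeSpace:
    """Fitted PCA basis over landscape feature vectors.

    ``components`` is (n_components, M^2) with orthonormal rows;
    ``explained_variance_ratio`` is nonincreasing. ``sign_flips``
    records which raw PCA components were negated by the sign
    convention.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    representation: str
    M: int
    sign_flips: np.ndarray
    floor: float = DEFAULT_FLOOR

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("mean", data=self.mean)
            f.create_dataset("components", data=self.components)
            f.create_dataset("explained_variance_ratio",
                             data=self.explained_variance_ratio)
            f.create_dataset("sign_flips", data=self.sign_flips)
            f.attrs["representation"] = self.representation
            f.attrs["M"] = self.M
            f.attrs["floor"] = self.floor

    @classmethod
    def load(cls, path) -> "ShapeSpace":
        with h5py.File(path, "r") as f:
            return cls(
                mean=f["mean"][:], components=f["components"][:],
                explained_variance_ratio=f["explained_variance_ratio"][:],
                sign_flips=f["sign_flips"][:],
                representation=str(f.attrs["representation"]),
                M=int(f.attrs["M"]), floor=float(f.attrs["floor"]))


def _truncated_poisson(mean: float, M: int) -> np.ndarray:
    pmf = poisson.pmf(np.arange(M), mean)
    return pmf / pmf.sum()


def archetype_landscape(kind: str, M: int = 21, g_hi: float = 1.4,
                        g_lo: float = 0.001, k: float = 0.2,
                        representation: str = "probability",
                        floor: float = DEFAULT_FLOOR) -> CoexpressionLandscape:
    """Hand-built reference landscapes for the canonical shapes.

    Products and mixtures of truncated Poisson marginals with means
    g/k: 'lo/lo' (both off), 'hi/hi' (both on), 'antagonistic' (equal
    mixture of hi/lo and lo/hi) and 'asymmetric' (X on, Y off). Used
    for the component sign convention and for interpretability checks.
    """
    lo = _truncated_poisson(g_lo / k, M)
    hi = _truncated_poisson(g_hi / k, M)
    if kind == "lo/lo":
        grid = np.outer(lo, lo)
    elif kind == "hi/hi":
        grid = np.outer(hi, hi)
    elif kind == "antagonistic":
        grid = 0.5 * np.outer(hi, lo) + 0.5 * np.outer(lo, hi)
    elif kind == "asymmetric":
        grid = np.outer(hi, lo)
    else:
        raise ValueError(f"unknown archetype {kind!r}; one of {ARCHETYPES}")
    land = CoexpressionLandscape(grid=grid, representation="probability",
                                 provenance="model")
    if representation == "quasipotential":
        land = quasipotential(land, floor=floor)
    return land


def fit_shape_space(library: LandscapeLibrary, n_components: int = 3) -> ShapeSpace:
    """Mean-centered PCA of a landscape library.

    Requires at least n_components rows with nonzero total variance;
    a library of identical rows is degenerate and rejected. Components
    are sign-fixed against the hi/hi archetype (see module docstring).
    """
    X = library.data
    if X.shape[0] < n_components:
        raise ValueError("library has fewer rows than requested components")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate library: zero variance across rows")
    pca = PCA(n_components=n_components)
    pca.fit(X)

    hihi = archetype_landscape(
        "hi/hi", M=library.M, representation=library.representation,
        floor=library.floor).features()
    flips = np.ones(n_components)
    for c in range(n_components):
        if c < 2:
            score = pca.components_[c] @ (hihi - pca.mean_)
            if score < 0:
                flips[c] = -1
        else:
            lead = pca.components_[c][np.argmax(np.abs(pca.components_[c]))]
            if lead < 0:
                flips[c] = -1
    return ShapeSpace(
        mean=pca.mean_, components=pca.components_ * flips[:, None],
        explained_variance_ratio=pca.explained_variance_ratio_,
        representation=library.representation, M=library.M,
        sign_flips=flips, floor=library.floor)


def project_features(features: np.ndarray, space: ShapeSpace) -> np.ndarray:
    """Scores of feature rows (R x M^2 or length M^2) in the shape-space."""
    features = np.atleast_2d(np.asarray(features, float))
    if features.shape[1] != space.mean.size:
        raise ValueError(
            f"feature length {features.shape[1]} does not match the "
            f"space's M^2 = {space.mean.size}")
    return (features - space.mean) @ space.components.T


def project(landscape: CoexpressionLandscape, space: ShapeSpace) -> ShapeCoordinates:
    """Shape coordinates of a single landscape."""
    if landscape.representation != space.representation:
        raise ValueError(
            f"landscape representation {landscape.representation!r} does not "
            f"match the space's training representation {space.representation!r}")
    return ShapeCoordinates(project_features(landscape.features(), space)[0])


def motif_occupancy(space: ShapeSpace, library: LandscapeLibrary
                    ) -> dict[str, np.ndarray]:
    """Shape coordinates grouped by motif class.

    Returns {motif class -> (rows, n_components) score array}; every
    library row must carry a motif-class label.
    """
    if library.representation != space.representation:
        raise ValueError("library/space representation mismatch")
    if "motif_class" not in library.descriptors.columns or \
            library.descriptors["motif_class"].isna().any():
        raise ValueError("library rows lack motif-class labels")
    scores = project_features(library.data, space)
    out: dict[str, np.ndarray] = {}
    for cls, idx in library.descriptors.groupby("motif_class").groups.items():
        out[str(cls)] = scores[np.asarray(idx)]
    return out
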