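"""Conformational landscapes: embedding, free energy, averages, RMSF.

Aligned conformers are flattened to Cartesian feature vectors and reduced to
a low-dimensional landscape (PCA by default — deterministic; UMAP behind the
same interface for non-linear structure, seed-pinned).  Point density in the
landscape converts to free-energy differences by Boltzmann inversion,
ΔG/kBT = −ln(n/n0) with n0 the most populated bin, so energies are always in
kBT units and zeroed at the densest region.  Regions of the landscape select
particles for cluster-average structures and per-residue RMSF profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .ensemble_io import ConformerEnsemble

__all__ = [
    "Embedding",
    "FreeEnergySurface",
    "RegionSelection",
    "embed",
    "free_energy_surface",
    "select_region",
    "cluster_average",
    "rmsf",
    "two_cluster_partition",
    "suggest_density_peaks",
]

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    """Low-dimensional coordinates of an ensemble plus the fitted model."""

    points: np.ndarray
    method: str
    particle_ids: np.ndarray
    seed: int | None = None
    params: dict[str, Any] = field(default_factory=dict)
    model: Any = field(default=None, repr=False)
    # squared reconstruction residual per particle (PCA only): variance that
    # falls outside the retained basis, the Q-statistic of multivariate
    # monitoring; None for non-linear embeddings
    residual_sq: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_dimensions(self) -> int:
        return self.points.shape[1]

    def __len__(self) -> int:
        return self.points.shape[0]

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Re-project new conformers (N, A, 3) with the fitted model."""
        x = np.asarray(coords, dtype=float).reshape(coords.shape[0], -1)
        return self.model.transform(x)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"c{i + 1}": self.points[:, i] for i in range(self.n_dimensions)}
        return pd.DataFrame({"particle_id": self.particle_ids, **cols})


def embed(
    ensemble: ConformerEnsemble,
    method: str = "pca",
    n_dimensions: int = 10,
    seed: int | None = 0,
    **kwargs: Any,
) -> Embedding:
    """Embed an aligned ensemble into ``n_dimensions`` landscape coordinates.

    Each conformer is flattened to a 3A-vector and centred; ``pca`` is the
    deterministic default, ``umap`` captures non-linear structure and is
    reproducible at a fixed seed (hyperparameters are recorded on the
    returned object).  Warns if the ensemble carries no alignment report,
    because rigid-body pose then leaks into the landscape.
    """
    n = len(ensemble)
    if n < n_dimensions:
        raise ValueError(
            f"need at least n_dimensions={n_dimensions} conformers, got {n}"
        )
    if ensemble.alignment is None:
        warnings.warn(
            "ensemble has no alignment report; embedding unaligned conformers "
            "mixes pose into the conformational landscape",
            stacklevel=2,
        )
    x = ensemble.coords.reshape(n, -1)
    residual_sq = None
    if method == "pca":
        from sklearn.decomposition import PCA

        model = PCA(n_components=n_dimensions, random_state=seed, **kwargs)
        points = model.fit_transform(x)
        centered_sq = ((x - x.mean(axis=0)) ** 2).sum(axis=1)
        residual_sq = np.maximum(centered_sq - (points**2).sum(axis=1), 0.0)
        params = {"n_components": n_dimensions}
    elif method == "umap":
        import umap

        params = {
            "n_components": n_dimensions,
            "n_neighbors": kwargs.pop("n_neighbors", 15),
            "min_dist": kwargs.pop("min_dist", 0.1),
        }
        model = umap.UMAP(random_state=seed, **params, **kwargs)
        points = model.fit_transform(x)
        logger.info("umap fitted with %s", params)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return Embedding(
        points=np.asarray(points, dtype=float),
        method=method,
        particle_ids=ensemble.particle_ids.copy(),
        seed=seed,
        params=params,
        model=model,
        residual_sq=residual_sq,
    )


@dataclass
class FreeEnergySurface:
    """2D occupancy histogram with Boltzmann-inverted energies.

    ``dg_kt`` is −ln(n/n0) on occupied bins and NaN on empty bins (empty
    bins are reported via ``occupied``, never as infinities).
    """

    axes: tuple[int, int]
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    n0: int

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    @property
    def dg_kt(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            dg = -np.log(self.counts / self.n0)
        dg[~self.occupied] = np.nan
        return dg

    def to_frame(self) -> pd.DataFrame:
        xi, yi = np.nonzero(self.occupied)
        return pd.DataFrame(
            {
                "x_center": 0.5 * (self.x_edges[xi] + self.x_edges[xi + 1]),
                "y_center": 0.5 * (self.y_edges[yi] + self.y_edges[yi + 1]),
                "count": self.counts[xi, yi].astype(int),
                "dg_kt": self.dg_kt[xi, yi],
            }
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mesh = ax.pcolormesh(self.x_edges, self.y_edges, self.dg_kt.T, **kwargs)
        ax.figure.colorbar(mesh, ax=ax, label=r"$\Delta G / k_B T$")
        ax.set_xlabel(f"component {self.axes[0] + 1}")
        ax.set_ylabel(f"component {self.axes[1] + 1}")
        return ax


def free_energy_surface(
    embedding: Embedding, axes: tuple[int, int] = (0, 1), n_bins: int = 60
) -> FreeEnergySurface:
    """Boltzmann-inverted 2D histogram over a pair of landscape axes."""
    if len(embedding) == 0:
        raise ValueError("cannot build a surface from an empty embedding")
    if max(axes) >= embedding.n_dimensions:
        raise ValueError(f"axes {axes} exceed embedding dimension")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = embedding.points[:, axes[0]]
    y = embedding.points[:, axes[1]]
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=n_bins)
    return FreeEnergySurface(
        axes=tuple(axes),
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        n0=int(counts.max()),
    )


@dataclass
class RegionSelection:
    """A labelled set of particle ids, usually cut from the landscape."""

    particle_ids: np.ndarray
    label: str = ""
    bounds: dict[int, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if len(self.particle_ids) == 0:
            raise ValueError(f"region {self.label!r} selected no particles")

    def __len__(self) -> int:
        return len(self.particle_ids)

    def union(self, other: "RegionSelection") -> "RegionSelection":
        return RegionSelection(
            particle_ids=np.union1d(self.particle_ids, other.particle_ids),
            label=f"{self.label}|{other.label}",
        )

    def intersection(self, other: "RegionSelection") -> "RegionSelection":
        return RegionSelection(
            particle_ids=np.intersect1d(self.particle_ids, other.particle_ids),
            label=f"{self.label}&{other.label}",
        )


def select_region(
    embedding: Embedding,
    bounds: dict[int, tuple[float, float]] | None = None,
    particle_ids: Sequence[int] | None = None,
    label: str = "",
) -> RegionSelection:
    """Select particles by axis-aligned landscape bounds or an explicit list.

    ``bounds`` maps axis index to an inclusive (low, high) interval; axes
    not listed are unconstrained.  Raises (echoing the bounds) if nothing
    falls inside.
    """
    if (bounds is None) == (particle_ids is None):
        raise ValueError("give exactly one of bounds or particle_ids")
    if particle_ids is not None:
        ids = np.asarray(particle_ids)
        missing = np.setdiff1d(ids, embedding.particle_ids)
        if missing.size:
            raise ValueError(f"ids not in embedding: {missing[:5].tolist()}...")
        return RegionSelection(particle_ids=ids, label=label)
    mask = np.ones(len(embedding), dtype=bool)
    for axis, (lo, hi) in bounds.items():
        mask &= (embedding.points[:, axis] >= lo) & (embedding.points[:, axis] <= hi)
    if not mask.any():
        raise ValueError(f"empty selection for bounds {bounds}")
    return RegionSelection(
        particle_ids=embedding.particle_ids[mask], label=label, bounds=dict(bounds)
    )


def cluster_average(
    ensemble: ConformerEnsemble, selection: RegionSelection
) -> np.ndarray:
    """Arithmetic mean of the aligned coordinates over the selected particles."""
    idx = ensemble.index_of(selection.particle_ids)
    return ensemble.coords[idx].mean(axis=0)


def rmsf(
    ensemble: ConformerEnsemble,
    selection: RegionSelection,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the cluster average.

    RMSF_i = sqrt(mean_n ‖x_ni − ref_i‖²) over the selected conformers; the
    reference defaults to the selection's own average structure.
    """
    idx = ensemble.index_of(selection.particle_ids)
    coords = ensemble.coords[idx]
    if reference is None:
        reference = coords.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != coords.shape[1:]:
        raise ValueError("reference topology does not match ensemble")
    return np.sqrt(np.mean(np.sum((coords - reference) ** 2, axis=2), axis=0))


def two_cluster_partition(
    embedding: Embedding,
    seed: int | None = 0,
    alpha: float = 0.01,
    min_minor_fraction: float = 0.001,
) -> dict[str, Any]:
    """Major/minor partition of the landscape by robust outlier detection.

    A minority population that differs from the consensus by a global
    deformation can be smeared over symmetry-related directions (the ring
    register is unresolved), so its centroid coincides with the main mode
    and centroid-based clustering fails.  It remains far from the main mode
    point-wise, in the retained landscape coordinates or in the part of its
    deformation the truncated basis drops.  The partition therefore scores
    every particle by robust Mahalanobis distance (minimum covariance
    determinant fit) over the landscape coordinates augmented with the
    reconstruction-residual norm, and flags particles beyond the
    Bonferroni-corrected chi-square quantile (``alpha`` expected false
    positives per run) as the minor cluster.

    Returns labels (0 = major, 1 = minor), the minor fraction, and
    ``separation`` = the smallest flagged distance over the threshold
    (≫1 for a genuinely distinct minor population).  ``n_clusters`` is 1
    when fewer than ``min_minor_fraction`` (or 5) particles are flagged.
    """
    from scipy.stats import chi2
    from sklearn.covariance import MinCovDet

    feats = embedding.points
    if embedding.residual_sq is not None:
        feats = np.column_stack([feats, np.sqrt(embedding.residual_sq)])
    n, d = feats.shape
    mcd = MinCovDet(random_state=seed).fit(feats)
    d2 = mcd.mahalanobis(feats)
    threshold = chi2.ppf(1.0 - alpha / n, d)
    labels = (d2 > threshold).astype(int)
    n_minor = int(labels.sum())
    minor_fraction = float(n_minor / n)
    separation = float(d2[labels == 1].min() / threshold) if n_minor else 0.0
    is_two = n_minor >= max(5, int(np.ceil(min_minor_fraction * n)))
    return {
        "labels": labels,
        "minor_fraction": minor_fraction,
        "separation": separation,
        "n_clusters": 2 if is_two else 1,
        "minor_ids": embedding.particle_ids[labels == 1],
        "major_ids": embedding.particle_ids[labels == 0],
        "mahalanobis_sq": d2,
        "threshold": float(threshold),
    }


def suggest_density_peaks(
    surface: FreeEnergySurface, min_count: int = 1, size: int = 3
) -> pd.DataFrame:
    """Local maxima of the 2D histogram — scriptable stand-ins for the
    interactive picking of dense landscape regions."""
    from scipy.ndimage import maximum_filter

    peaks = (
        (surface.counts == maximum_filter(surface.counts, size=size))
        & (surface.counts >= min_count)
    )
    xi, yi = np.nonzero(peaks)
    frame = pd.DataFrame(
        {
            "x_center": 0.5 * (surface.x_edges[xi] + surface.x_edges[xi + 1]),
            "y_center": 0.5 * (surface.y_edges[yi] + surface.y_edges[yi + 1]),
            "count": surface.counts[xi, yi].astype(int),
        }
    )
    return frame.sort_values("count", ascending=False).reset_index(drop=True)
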