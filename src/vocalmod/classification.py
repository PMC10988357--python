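"""Unsupervised classification of responsive units into response types.

Features per responsive unit are the first three principal components of
the 25-dim auROC response vectors plus log10 of the baseline firing rate,
z-scored. The 4-dim features are embedded in 2-D with t-SNE, a Gaussian-
smoothed 2-D density of units is computed on a grid, and a watershed
transform segments the density into basins; each unit is labeled by its
basin. Basins are then named E (excitatory), I (inhibitory) or O (other)
from the mean post-onset auROC deviation of their units, with E/I subtypes
ordered by response duration (sustained before transient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
from skimage.morphology import h_maxima
from skimage.segmentation import watershed
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .responses import FIRST_SLICE, SUBSEQUENT_SLICE

__all__ = [
    "FeatureMatrix", "TypeMap",
    "build_features", "embed_2d", "density_watershed", "name_types",
    "classify_population",
]

MIN_BASELINE_RATE = 0.01  # spikes/s floor guarding log10(0)
NAMING_DELTA = 0.05  # |mean post-onset auROC - 0.5| threshold for E/I naming


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (n_units, 4) z-scored
    pca: PCA
    explained_variance_ratio: np.ndarray


@dataclass
class TypeMap:
    coords: np.ndarray  # (n_units, 2) embedding
    labels: np.ndarray  # (n_units,) basin label, contiguous ints from 0
    type_names: dict  # basin label -> type name
    density: np.ndarray  # smoothed grid density
    grid_extent: tuple  # (x0, x1, y0, y1)

    @property
    def names(self) -> np.ndarray:
        return np.array([self.type_names[l] for l in self.labels])


def build_features(vectors25: np.ndarray, baseline_rates: np.ndarray) -> FeatureMatrix:
    """PC1-3 of the response vectors + log10 baseline rate, z-scored."""
    x = np.asarray(vectors25, dtype=float)
    rates = np.asarray(baseline_rates, dtype=float)
    if x.ndim != 2 or x.shape[1] != 25:
        raise ValueError("vectors25 must be (n_units, 25)")
    if x.shape[0] < 4:
        raise ValueError("need at least 4 responsive units for 3 components")
    pca = PCA(n_components=3).fit(x)
    scores = pca.transform(x)
    logrates = np.log10(np.maximum(rates, MIN_BASELINE_RATE))
    feats = np.column_stack([scores, logrates])
    sd = feats.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature column; population is degenerate")
    z = (feats - feats.mean(axis=0)) / sd
    return FeatureMatrix(values=z, pca=pca,
                         explained_variance_ratio=pca.explained_variance_ratio_)


def embed_2d(features: FeatureMatrix | np.ndarray, perplexity: float = 30.0,
             seed: int = 0, n_iter: int = 1000) -> np.ndarray:
    """Deterministic (fixed-seed, PCA-initialized) t-SNE to 2-D."""
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if x.shape[0] < 3 * perplexity:
        raise ValueError("perplexity too large for the number of units")
    ts = TSNE(
        n_components=2, perplexity=perplexity, init="pca",
        max_iter=n_iter, random_state=seed,
    )
    return ts.fit_transform(x)


def density_watershed(coords: np.ndarray, grid_size: int = 100,
                      sigma_bins: float = 2.0, marker_sigma_mult: float = 2.0,
                      prominence_frac: float = 0.1) -> np.ndarray:
    """Label each unit by its watershed basin of the smoothed 2-D density.

    A ``grid_size`` x ``grid_size`` histogram over the 5%-padded bounding
    box is Gaussian-smoothed (``sigma_bins``) and segmented by a watershed
    of the negated density. Markers (one per basin) are the regional maxima
    of a more heavily smoothed copy (``sigma_bins * marker_sigma_mult``)
    with prominence at least ``prominence_frac`` of its peak: marker
    detection on the coarser scale keeps sampling noise in sparse histogram
    cells from seeding spurious basins, while basin boundaries still follow
    the finer density. Each unit inherits the label of its grid cell.
    Returns contiguous labels 0..k-1; coincident points give one label.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n_units, 2)")
    if len(coords) < 2:
        raise ValueError("need at least 2 units")
    mins, maxs = coords.min(axis=0), coords.max(axis=0)
    span = np.where(maxs - mins > 0, maxs - mins, 1.0)
    lo = mins - 0.05 * span
    hi = maxs + 0.05 * span
    hist, xe, ye = np.histogram2d(
        coords[:, 0], coords[:, 1], bins=grid_size,
        range=[[lo[0], hi[0]], [lo[1], hi[1]]],
    )
    density = scipy.ndimage.gaussian_filter(hist, sigma_bins)
    marker_density = scipy.ndimage.gaussian_filter(
        hist, sigma_bins * marker_sigma_mult)
    h = max(prominence_frac * marker_density.max(), 1e-12)
    markers, n_markers = scipy.ndimage.label(h_maxima(marker_density, h))
    if n_markers == 0:  # flat density (all points coincident)
        return np.zeros(len(coords), dtype=int)
    basins = watershed(-density, markers=markers)

    ix = np.clip(np.searchsorted(xe, coords[:, 0], side="right") - 1, 0, grid_size - 1)
    iy = np.clip(np.searchsorted(ye, coords[:, 1], side="right") - 1, 0, grid_size - 1)
    labels = basins[ix, iy]
    if np.any(labels == 0):  # ridge cells: assign to nearest basin centroid
        cents = np.array([
            coords[labels == k].mean(axis=0) if np.any(labels == k)
            else [np.inf, np.inf]
            for k in range(1, basins.max() + 1)
        ])
        for i in np.flatnonzero(labels == 0):
            d = np.linalg.norm(cents - coords[i], axis=1)
            labels[i] = int(np.argmin(d)) + 1
    # contiguous 0-based labels
    uniq = np.unique(labels)
    remap = {old: new for new, old in enumerate(uniq)}
    return np.array([remap[l] for l in labels], dtype=int)


def _post_onset_deviation(mean_vec: np.ndarray) -> tuple[float, int]:
    """Mean deviation from 0.5 of the post-onset entries of a 25-dim mean
    response vector, and the count of post-onset entries deviating by more
    than the naming threshold (a response-duration proxy)."""
    first = mean_vec[:15]  # bins -0.5..+0.25 s; post-onset = last 5
    sub = mean_vec[15:]  # bins -0.25..+0.25 s; post-onset = last 5
    post = np.concatenate([first[10:], sub[5:]])
    dev = float(post.mean() - 0.5)
    n_mod = int(np.sum(np.abs(post - 0.5) > NAMING_DELTA))
    return dev, n_mod


def name_types(labels: np.ndarray, vectors25: np.ndarray,
               delta: float = NAMING_DELTA) -> dict:
    """Name each basin E/I/O from its mean response vector.

    E if the mean post-onset auROC exceeds 0.5 + delta, I if below
    0.5 - delta, else O. E and I subtypes are numbered by decreasing
    response duration (sustained first): E1, E2, ..., I1, I2, ...
    """
    labels = np.asarray(labels)
    vectors25 = np.asarray(vectors25, dtype=float)
    stats = {}
    for lab in np.unique(labels):
        mean_vec = vectors25[labels == lab].mean(axis=0)
        dev, n_mod = _post_onset_deviation(mean_vec)
        if dev > delta:
            cls = "E"
        elif dev < -delta:
            cls = "I"
        else:
            cls = "O"
        stats[lab] = (cls, n_mod, abs(dev))
    names = {}
    for cls in ("E", "I"):
        members = [l for l, s in stats.items() if s[0] == cls]
        members.sort(key=lambda l: (-stats[l][1], -stats[l][2]))
        for rank, lab in enumerate(members, start=1):
            names[lab] = f"{cls}{rank}"
    for lab, s in stats.items():
        if s[0] == "O":
            names[lab] = "O"
    return names


def classify_population(vectors25, baseline_rates, perplexity: float = 30.0,
                        seed: int = 0, grid_size: int = 100,
                        sigma_bins: float = 2.0) -> TypeMap:
    """Full feature -> embedding -> watershed -> naming chain."""
    feats = build_features(vectors25, baseline_rates)
    coords = embed_2d(feats, perplexity=perplexity, seed=seed)
    labels = density_watershed(coords, grid_size=grid_size, sigma_bins=sigma_bins)
    names = name_types(labels, vectors25)
    mins, maxs = coords.min(axis=0), coords.max(axis=0)
    return TypeMap(coords=coords, labels=labels, type_names=names,
                   density=np.array([]),
                   grid_extent=(mins[0], maxs[0], mins[1], maxs[1]))
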