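"""Spatial eigenfunctions (PCNM), environmental standardisation and PCA.

PCNM axes are the positive-eigenvalue eigenvectors of the double-centred,
truncated geographic distance matrix; they serve as orthogonal spatial
predictors ("spatial factors") in Mantel tests and variance partitioning.
Climate and soil variable families are reduced by correlation-matrix PCA,
keeping axes that explain more than a retention threshold of the variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .core import Coordinates, DistanceMatrix, ValidationError

logger = logging.getLogger("multidiv")

EARTH_RADIUS_KM = 6371.0


def geo_distance(coords: Coordinates, method: str = "auto") -> DistanceMatrix:
    """Pairwise site distances: great-circle (km) or planar Euclidean.

    ``method="auto"`` picks haversine for geographic coordinates and
    Euclidean for planar ones; requesting haversine on planar-flagged
    coordinates is an error.
    """
    if method == "auto":
        method = "haversine" if coords.crs == "geographic" else "euclidean"
    xy = coords.xy()
    if method == "euclidean":
        d = squareform(pdist(xy))
    elif method == "haversine":
        if coords.crs != "geographic":
            raise ValidationError("haversine requires geographic coordinates")
        lon = np.radians(xy[:, 0])
        lat = np.radians(xy[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = (
            np.sin(dlat / 2) ** 2
            + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        )
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    else:
        raise ValidationError(f"unknown distance method {method!r}")
    return DistanceMatrix(coords.site_ids, d)


@dataclass
class EigenBasis:
    """Retained spatial eigenvectors with their eigenvalues."""

    site_ids: list[str]
    vectors: np.ndarray  # (n_sites, n_axes)
    eigenvalues: np.ndarray
    truncation: float
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCNM{i + 1}" for i in range(self.vectors.shape[1])]
        df = pd.DataFrame(self.vectors, index=self.site_ids, columns=cols)
        df.index.name = "site"
        return df


def pcnm(
    geo_dist: DistanceMatrix,
    truncation: float | str = "auto",
    tol: float = 1e-9,
    keep_negative: bool = False,
) -> EigenBasis:
    """Principal coordinates of the neighbour matrix.

    Distances above the truncation threshold t (default: largest edge of
    the minimum spanning tree of the distance graph) are replaced by 4t;
    the modified matrix is double-centred as in PCoA and eigendecomposed.
    Positive-eigenvalue axes are retained, ordered by eigenvalue.
    """
    n = geo_dist.n
    if n < 3:
        raise ValidationError("PCNM needs at least 3 sites")
    d = geo_dist.values.copy()
    if truncation == "auto":
        mst = minimum_spanning_tree(d).toarray()
        t = float(mst.max())
    else:
        t = float(truncation)
    if t <= 0:
        raise ValidationError("non-positive truncation distance")
    d[d > t] = 4.0 * t
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = np.abs(w) > tol if keep_negative else w > tol
    return EigenBasis(
        site_ids=list(geo_dist.labels),
        vectors=v[:, keep],
        eigenvalues=w[keep],
        truncation=t,
        n_retained=int(keep.sum()),
    )


def standardize(table: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Centre and scale every numeric column to mean 0, SD 1.

    Uses the population SD convention by default; constant columns are
    dropped with a warning.  Idempotent.
    """
    num = table.select_dtypes(include=[np.number])
    out = {}
    for col in num.columns:
        x = num[col].to_numpy(dtype=float)
        sd = x.std(ddof=ddof)
        if sd <= 0:
            logger.warning("constant column %r dropped in standardisation", col)
            continue
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=table.index)


@dataclass
class ReducedEnv:
    """Retained PCA axes of one environmental variable family."""

    site_ids: list[str]
    scores: pd.DataFrame  # e.g. columns Soil_PC1..Soil_PC4
    loadings: pd.DataFrame  # variables x axes
    proportions: np.ndarray
    threshold: float
    passthrough: bool = False
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = self.scores.copy()
        df.index.name = "site"
        return df


def env_pca(
    env_subset: pd.DataFrame,
    retain_threshold: float = 0.10,
    prefix: str = "PC",
) -> ReducedEnv:
    """Correlation-matrix PCA of one variable family, keeping axes whose
    variance proportion exceeds ``retain_threshold``.

    Variables are standardised first; axis signs are fixed so the
    largest-magnitude loading on each axis is positive.  With fewer than
    two variables the (standardised) input passes through unchanged.
    """
    z = standardize(env_subset)
    if z.shape[1] < 2:
        return ReducedEnv(
            site_ids=list(env_subset.index),
            scores=z.rename(columns={c: f"{prefix}1" for c in z.columns}),
            loadings=pd.DataFrame(np.ones((z.shape[1], z.shape[1])),
                                  index=z.columns, columns=[f"{prefix}1"]),
            proportions=np.array([1.0] * z.shape[1]),
            threshold=retain_threshold,
            passthrough=True,
            notes=["fewer than 2 variables; passed through standardised"],
        )
    x = z.to_numpy()
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / n  # population-variance convention matches standardize()
    props = eig / eig.sum()
    # sign convention: largest |loading| positive per axis
    for i in range(vt.shape[0]):
        jmax = np.argmax(np.abs(vt[i]))
        if vt[i, jmax] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    keep = props > retain_threshold
    scores = (u * s)[:, keep]
    cols = [f"{prefix}{i + 1}" for i in range(int(keep.sum()))]
    return ReducedEnv(
        site_ids=list(env_subset.index),
        scores=pd.DataFrame(scores, index=env_subset.index, columns=cols),
        loadings=pd.DataFrame(vt[keep].T, index=z.columns, columns=cols),
        proportions=props[keep],
        threshold=retain_threshold,
    )


def env_distance(table: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between site rows of a (standardised) table."""
    d = squareform(pdist(table.to_numpy(dtype=float)))
    return DistanceMatrix([str(i) for i in table.index], d)
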