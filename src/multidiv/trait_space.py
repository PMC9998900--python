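"""Mixed-type trait distances and representations of functional space.

Gower dissimilarity handles categorical, ordinal and continuous traits with
pairwise deletion of missing values.  Principal coordinates (with optional
Lingoes / Cailliez corrections) and a deterministic UPGMA dendrogram provide
the continuous-space and branch-length representations of the functional
space used by the beta-diversity machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import DistanceMatrix, Phylogeny, TraitTable, ValidationError

logger = logging.getLogger("multidiv")


# ---------------------------------------------------------------------------
# Gower distance
# ---------------------------------------------------------------------------


def gower_distance(
    traits: TraitTable, weights: dict[str, float] | None = None
) -> DistanceMatrix:
    """Gower dissimilarity among species over mixed-type traits.

    Per-trait dissimilarity is a 0/1 mismatch for categorical traits and a
    range-normalised absolute difference for continuous traits; ordinal
    traits are converted to (average) ranks first and then range-normalised.
    The pairwise distance is the weighted mean over traits non-missing in
    both species (pairwise deletion with weight renormalisation).  Values
    lie in [0, 1].

    Raises
    ------
    ValidationError
        If some species pair shares no non-missing trait.  Continuous
        traits with zero range over the pool are dropped with a warning.
    """
    species = traits.species_ids
    n = len(species)
    if weights is None:
        weights = {}
    cols = []
    for name in traits.trait_names:
        kind = traits.kinds[name]
        col = traits.data[name]
        w = float(weights.get(name, 1.0))
        if w < 0:
            raise ValidationError(f"negative weight for trait {name!r}")
        valid = col.notna().to_numpy()
        if kind == "categorical":
            codes = pd.factorize(col)[0].astype(float)  # NaN -> -1
            diff = (codes[:, None] != codes[None, :]).astype(float)
        else:
            x = col.to_numpy(dtype=float)
            if kind == "ordinal":
                r = np.full(n, np.nan)
                r[valid] = rankdata(x[valid])
                x = r
            rng = np.nanmax(x) - np.nanmin(x) if valid.any() else 0.0
            if rng <= 0:
                logger.warning("trait %r constant over pool; dropped", name)
                continue
            diff = np.abs(x[:, None] - x[None, :]) / rng
        both = valid[:, None] & valid[None, :]
        cols.append((w, diff, both))

    if not cols:
        raise ValidationError("no usable traits for Gower distance")

    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for w, diff, both in cols:
        num += np.where(both, w * diff, 0.0)
        den += np.where(both, w, 0.0)
    if np.any(den == 0):
        i, j = np.argwhere(den == 0)[0]
        raise ValidationError(
            f"species pair ({species[i]}, {species[j]}) shares no "
            "non-missing trait"
        )
    d = num / den
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(species, d)


# ---------------------------------------------------------------------------
# Principal coordinates
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """Axis scores of an eigen-ordination, ordered by decreasing eigenvalue."""

    labels: list[str]
    scores: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,)
    proportions: np.ndarray  # (k,) fraction of (positive) variance
    method: str  # "pcoa" or "pca"
    n_negative: int = 0

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.scores.shape[1])]
        df = pd.DataFrame(self.scores, index=self.labels, columns=cols)
        df.index.name = "id"
        return df


def _center_gower(d2: np.ndarray) -> np.ndarray:
    """Double-centred -0.5*D2 (Gower's matrix)."""
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def pcoa(
    dist: DistanceMatrix, correction: str = "none", tol: float = 1e-9
) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    ``correction="lingoes"`` adds the smallest constant to the squared
    distances, and ``"cailliez"`` to the distances themselves, that makes
    the matrix fully Euclidean; with ``"none"`` axes with eigenvalue below
    ``tol`` are dropped and the count of negative eigenvalues reported.
    """
    if correction not in ("none", "lingoes", "cailliez"):
        raise ValidationError(f"unknown correction {correction!r}")
    n = dist.n
    if n < 2:
        raise ValidationError("PCoA needs at least 2 objects")
    d = dist.values.copy()

    if correction != "none":
        b = _center_gower(d**2)
        w = np.linalg.eigvalsh(b)
        if w[0] < -tol:
            if correction == "lingoes":
                c1 = -w[0]
                d2 = d**2 + 2.0 * c1
                np.fill_diagonal(d2, 0.0)
                d = np.sqrt(d2)
            else:  # cailliez
                delta1 = _center_gower(d**2)
                delta2 = _center_gower(d)
                top = np.hstack([np.zeros((n, n)), 2.0 * delta1])
                bot = np.hstack([-np.eye(n), -4.0 * delta2])
                c2 = float(np.max(np.linalg.eigvals(np.vstack([top, bot])).real))
                d = d + c2
                np.fill_diagonal(d, 0.0)

    b = _center_gower(d**2)
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    n_neg = int(np.sum(w < -tol))
    keep = w > tol
    wk, vk = w[keep], v[:, keep]
    scores = vk * np.sqrt(wk)[None, :]
    pos_total = w[w > 0].sum()
    props = wk / pos_total if pos_total > 0 else np.zeros_like(wk)
    return OrdinationResult(
        labels=list(dist.labels),
        scores=scores,
        eigenvalues=wk,
        proportions=props,
        method="pcoa",
        n_negative=n_neg,
    )


# ---------------------------------------------------------------------------
# UPGMA dendrogram
# ---------------------------------------------------------------------------


def upgma_dendrogram(dist: DistanceMatrix) -> Phylogeny:
    """Average-linkage (UPGMA) dendrogram as an ultrametric rooted tree.

    Agglomeration is written out explicitly so that merge ties are broken
    deterministically by lexicographic label order, making branch-based
    functional beta diversity reproducible bit-for-bit.
    """
    labels = list(dist.labels)
    n = len(labels)
    if n == 1:
        return Phylogeny.from_newick(f"({labels[0]}:0.0);")

    # active clusters: key -> (newick, height, size, lexicographically
    # smallest member label used for tie-breaks)
    clusters: dict[int, tuple[str, float, int, str]] = {
        i: (labels[i], 0.0, 1, labels[i]) for i in range(n)
    }
    d = {
        (i, j): float(dist.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }

    next_id = n
    while len(clusters) > 1:
        # choose the minimum-distance pair; ties by (label_i, label_j)
        best = None
        for (i, j), dij in d.items():
            li = min(clusters[i][3], clusters[j][3])
            lj = max(clusters[i][3], clusters[j][3])
            key = (dij, li, lj)
            if best is None or key < best[0]:
                best = (key, (i, j))
        (dij, _, _), (i, j) = best
        ni, hi, si, mi = clusters[i]
        nj, hj, sj, mj = clusters[j]
        h = dij / 2.0
        if mi > mj:  # deterministic child order
            ni, nj, hi, hj = nj, ni, hj, hi
            mi = mj
        newick = f"({ni}:{h - hi:.12g},{nj}:{h - hj:.12g})"
        # UPGMA update: size-weighted average distance to the new cluster
        new_d = {}
        for k in clusters:
            if k in (i, j):
                continue
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            new_d[k] = (si * dik + sj * djk) / (si + sj)
        del clusters[i], clusters[j]
        d = {
            (a, b): v
            for (a, b), v in d.items()
            if a not in (i, j) and b not in (i, j)
        }
        for k, v in new_d.items():
            d[(min(k, next_id), max(k, next_id))] = v
        clusters[next_id] = (newick, h, si + sj, mi)
        next_id += 1

    (newick, _, _, _) = next(iter(clusters.values()))
    return Phylogeny.from_newick(newick + ";")
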