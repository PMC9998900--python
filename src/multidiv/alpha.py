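"""Per-site taxonomic, phylogenetic and functional alpha diversity.

Taxonomic and functional diversity use Rao's quadratic entropy Q = sum_ij
d_ij p_i p_j (with d_ij = 1 for i != j it reduces to Gini-Simpson);
phylogenetic diversity uses Faith's PD and the mean pairwise (MPD) and mean
nearest-taxon (MNTD) distances on the tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CommunityMatrix, DataBundle, DistanceMatrix, Phylogeny, ValidationError
from .trait_space import gower_distance


def rao_q(abundances: np.ndarray, dist: DistanceMatrix | None = None) -> float:
    """Rao quadratic entropy of one community.

    ``abundances`` is a vector over the species of ``dist`` (any positive
    scale; it is renormalised to relative abundances).  With ``dist=None``
    the taxonomic convention d_ij = 1 (i != j) is used, giving Gini-Simpson.
    """
    p = np.asarray(abundances, dtype=float)
    if np.any(p < 0):
        raise ValidationError("negative abundance")
    total = p.sum()
    if total <= 0:
        raise ValidationError("all-zero abundance vector")
    p = p / total
    if dist is None:
        return float(1.0 - np.sum(p**2))
    d = dist.values
    if d.shape[0] != p.shape[0]:
        raise ValidationError("abundance vector does not match distance matrix")
    return float(p @ d @ p)


def faith_pd(present: np.ndarray, tree: Phylogeny, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of the species flagged in ``present``.

    Sum of branch lengths of the subtree spanning the present tips; with
    ``include_root=True`` (default) the path from the subtree to the tree
    root is included, so a single-species community has PD equal to its
    root-to-tip distance.
    """
    present = np.asarray(present, dtype=bool)
    if present.shape[0] != len(tree.tip_labels):
        raise ValidationError("presence vector does not match tree tips")
    if not present.any():
        raise ValidationError("empty community has no PD")
    X = tree.branch_incidence
    L = tree.branch_lengths
    counts = X[:, present].sum(axis=1)
    on = counts > 0
    if not include_root:
        on &= counts < present.sum()
    return float(L[on].sum())


def mpd(present: np.ndarray, dist: DistanceMatrix) -> float:
    """Mean pairwise distance among present species (unweighted).

    Returns NaN for communities with fewer than two species.
    """
    idx = np.flatnonzero(np.asarray(present, dtype=bool))
    if idx.size < 2:
        return float("nan")
    sub = dist.values[np.ix_(idx, idx)]
    k = idx.size
    return float(sub.sum() / (k * (k - 1)))


def mntd(present: np.ndarray, dist: DistanceMatrix) -> float:
    """Mean nearest-taxon distance among present species (unweighted)."""
    idx = np.flatnonzero(np.asarray(present, dtype=bool))
    if idx.size < 2:
        return float("nan")
    sub = dist.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


@dataclass
class AlphaTable:
    """Per-site alpha diversity indices with their provenance."""

    data: pd.DataFrame  # index site, columns raoq_td/raoq_fd/faith_pd/mpd/mntd
    mode: str
    functional_distance: str = "gower"

    def to_frame(self) -> pd.DataFrame:
        df = self.data.copy()
        df.index.name = "site"
        return df


def alpha_pipeline(
    bundle: DataBundle,
    functional_dist: DistanceMatrix | None = None,
    include_root: bool = True,
) -> AlphaTable:
    """Compute all alpha indices for every site of a validated bundle.

    Functional metrics use Gower distances over the trait table (or a
    pre-computed ``functional_dist``); phylogenetic MPD/MNTD use cophenetic
    tree distances.  Presence-mode data use equal relative abundances.
    """
    cm: CommunityMatrix = bundle.community
    if functional_dist is None:
        if bundle.traits is None:
            raise ValidationError("bundle has no traits for functional metrics")
        functional_dist = gower_distance(bundle.traits)
    functional_dist = functional_dist.submatrix(cm.species_ids)
    if bundle.tree is None:
        raise ValidationError("bundle has no tree for phylogenetic metrics")
    coph = bundle.tree.cophenetic().submatrix(cm.species_ids)

    # presence re-expressed in tree tip order for Faith's PD
    tip_pos = {t: i for i, t in enumerate(bundle.tree.tip_labels)}
    order = np.array([tip_pos[s] for s in cm.species_ids])
    pres = cm.presence()
    pres_tree = np.zeros((cm.n_sites, len(bundle.tree.tip_labels)), dtype=bool)
    pres_tree[:, order] = pres

    rows = []
    for i, site in enumerate(cm.site_ids):
        ab = cm.values[i] if cm.mode == "abundance" else pres[i].astype(float)
        rows.append(
            {
                "raoq_td": rao_q(ab),
                "raoq_fd": rao_q(ab, functional_dist),
                "faith_pd": faith_pd(pres_tree[i], bundle.tree, include_root=include_root),
                "mpd": mpd(pres[i], coph),
                "mntd": mntd(pres[i], coph),
            }
        )
    df = pd.DataFrame(rows, index=cm.site_ids)
    return AlphaTable(df, mode=cm.mode)
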