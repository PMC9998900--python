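"""Sorensen-family beta diversity partitioned into turnover and nestedness.

Pairwise and multiple-site dissimilarity are decomposed after Baselga's
framework: total dissimilarity (sor) = turnover (sim, species replacement)
+ nestedness-resultant (sne, richness-difference) components.  The same
algebra runs in three currencies: species counts (taxonomic), branch
lengths of the phylogeny (phylogenetic) and branch lengths of a functional
dendrogram or convex-hull volumes in trait-ordination space (functional).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CommunityMatrix, DataBundle, DistanceMatrix, Phylogeny, ValidationError
from .trait_space import gower_distance, pcoa, upgma_dendrogram


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def abc_counts(site_i: np.ndarray, site_j: np.ndarray) -> tuple[int, int, int]:
    """Shared (a) and unique (b, c) species counts of two presence vectors."""
    pi = np.asarray(site_i, dtype=bool)
    pj = np.asarray(site_j, dtype=bool)
    a = int((pi & pj).sum())
    b = int((pi & ~pj).sum())
    c = int((~pi & pj).sum())
    return a, b, c


def pairwise_partition(a: float, b: float, c: float) -> tuple[float, float, float]:
    """Sorensen dissimilarity and its turnover/nestedness components.

    sor = (b+c)/(2a+b+c); sim = min(b,c)/(a+min(b,c)); sne = sor - sim.
    """
    if a + b + c <= 0:
        raise ValidationError("both communities empty")
    sor = (b + c) / (2 * a + b + c)
    m = min(b, c)
    sim = m / (a + m) if (a + m) > 0 else 0.0
    return sor, sim, sor - sim


def _spanning_presence(tree: Phylogeny, present: np.ndarray, include_root: bool) -> np.ndarray:
    """Boolean branch mask of the subtree spanning ``present`` tips."""
    X = tree.branch_incidence
    counts = X[:, present].sum(axis=1)
    on = counts > 0
    if not include_root:
        on &= counts < int(np.sum(present))
    return on


def shared_branch_abc(
    tree: Phylogeny,
    site_i: np.ndarray,
    site_j: np.ndarray,
    include_root: bool = True,
) -> tuple[float, float, float]:
    """Branch-length analogue of ``abc_counts`` on the two spanning subtrees.

    a is the branch length shared by both subtrees; b and c are the lengths
    unique to each, so a + b = PD(i) and a + c = PD(j).  Presence vectors
    are in the tree's tip order.
    """
    L = tree.branch_lengths
    on_i = _spanning_presence(tree, np.asarray(site_i, bool), include_root)
    on_j = _spanning_presence(tree, np.asarray(site_j, bool), include_root)
    a = float(L[on_i & on_j].sum())
    b = float(L[on_i & ~on_j].sum())
    c = float(L[~on_i & on_j].sum())
    return a, b, c


# ---------------------------------------------------------------------------
# Convex-hull functional components
# ---------------------------------------------------------------------------


def _hull_volume(points: np.ndarray) -> tuple[object, float]:
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(points)
    except QhullError as e:
        raise ValidationError(
            "degenerate point set for convex hull; use dendrogram mode"
        ) from e
    return hull, float(hull.volume)


def _intersection_volume(hull_i, hull_j, k: int) -> float:
    """Volume of the intersection of two convex hulls via halfspaces."""
    from scipy.optimize import linprog
    from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

    halfspaces = np.vstack([hull_i.equations, hull_j.equations])
    # Chebyshev centre: maximise margin r with A x + |A_row| r <= -b
    norm = np.linalg.norm(halfspaces[:, :-1], axis=1, keepdims=True)
    c = np.zeros(k + 1)
    c[-1] = -1.0
    A_ub = np.hstack([halfspaces[:, :-1], norm])
    b_ub = -halfspaces[:, -1]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * k + [(0, None)])
    if not res.success or res.x[-1] <= 1e-12:
        return 0.0
    interior = res.x[:-1]
    try:
        hs = HalfspaceIntersection(halfspaces, interior)
        return float(ConvexHull(hs.intersections).volume)
    except QhullError:
        return 0.0


def functional_abc(
    scores: np.ndarray,
    site_i: np.ndarray,
    site_j: np.ndarray,
    k: int = 2,
) -> tuple[float, float, float]:
    """Hull-mode functional components in the first ``k`` ordination axes.

    a = intersection volume of the two community hulls, b/c = volumes
    unique to each.  Every community needs at least k+1 species.
    """
    pi = np.flatnonzero(np.asarray(site_i, bool))
    pj = np.flatnonzero(np.asarray(site_j, bool))
    if len(pi) < k + 1 or len(pj) < k + 1:
        raise ValidationError(
            f"hull mode needs > {k} species per site; use dendrogram mode"
        )
    if scores.shape[1] < k:
        raise ValidationError(f"ordination has fewer than {k} axes")
    hi, vi = _hull_volume(scores[pi, :k])
    hj, vj = _hull_volume(scores[pj, :k])
    a = _intersection_volume(hi, hj, k)
    a = min(a, vi, vj)  # guard tiny numerical overshoot
    return a, vi - a, vj - a


# ---------------------------------------------------------------------------
# Partition over a site set
# ---------------------------------------------------------------------------


@dataclass
class BetaPartition:
    """Pairwise matrices and multiple-site decomposition for one dimension."""

    dimension: str
    sor: DistanceMatrix
    sim: DistanceMatrix
    sne: DistanceMatrix
    multisite: dict[str, float]
    mean_pairwise: dict[str, float]
    meta: dict = field(default_factory=dict)

    def multisite_frame(self):
        import pandas as pd

        rows = [
            {"component": "sor", "multisite": self.multisite["SOR"],
             "mean_pairwise": self.mean_pairwise["sor"]},
            {"component": "sim", "multisite": self.multisite["SIM"],
             "mean_pairwise": self.mean_pairwise["sim"]},
            {"component": "sne", "multisite": self.multisite["SNE"],
             "mean_pairwise": self.mean_pairwise["sne"]},
        ]
        return pd.DataFrame(rows).set_index("component")


def _partition_from_components(
    site_ids: list[str],
    A: np.ndarray,
    totals: np.ndarray,
    pooled_total: float,
    dimension: str,
    meta: dict,
) -> BetaPartition:
    """Assemble pairwise matrices and multi-site scalars from shared-unit
    matrix ``A`` (a_ij), per-site totals and the pooled total."""
    n = len(site_ids)
    B = totals[:, None] - A  # units unique to the row site
    C = B.T
    with np.errstate(divide="ignore", invalid="ignore"):
        sor = (B + C) / (2 * A + B + C)
        m = np.minimum(B, C)
        sim = np.where(A + m > 0, m / (A + m), 0.0)
    np.fill_diagonal(sor, 0.0)
    np.fill_diagonal(sim, 0.0)
    sne = sor - sim

    iu = np.triu_indices(n, k=1)
    sum_min = float(np.minimum(B, C)[iu].sum())
    sum_max = float(np.maximum(B, C)[iu].sum())
    K = float(totals.sum() - pooled_total)
    SOR = (sum_min + sum_max) / (2 * K + sum_min + sum_max) if (2 * K + sum_min + sum_max) > 0 else 0.0
    SIM = sum_min / (K + sum_min) if (K + sum_min) > 0 else 0.0
    SNE = SOR - SIM
    turnover_pct = 100.0 * SIM / SOR if SOR > 0 else float("nan")
    nestedness_pct = 100.0 * SNE / SOR if SOR > 0 else float("nan")

    return BetaPartition(
        dimension=dimension,
        sor=DistanceMatrix(site_ids, sor),
        sim=DistanceMatrix(site_ids, sim),
        sne=DistanceMatrix(site_ids, sne),
        multisite={
            "SOR": SOR,
            "SIM": SIM,
            "SNE": SNE,
            "turnover_pct": turnover_pct,
            "nestedness_pct": nestedness_pct,
        },
        mean_pairwise={
            "sor": float(sor[iu].mean()),
            "sim": float(sim[iu].mean()),
            "sne": float(sne[iu].mean()),
        },
        meta=meta,
    )


def _check_no_empty(cm: CommunityMatrix) -> np.ndarray:
    pres = cm.presence()
    if np.any(pres.sum(axis=1) == 0):
        raise ValidationError("empty site in beta-diversity input")
    return pres


def taxonomic_beta(cm: CommunityMatrix) -> BetaPartition:
    """Taxonomic turnover/nestedness partition over all sites."""
    pres = _check_no_empty(cm)
    P = pres.astype(float)
    A = P @ P.T
    totals = P.sum(axis=1)
    pooled = float((pres.any(axis=0)).sum())
    return _partition_from_components(
        cm.site_ids, A, totals, pooled, "taxonomic", {"units": "species"}
    )


def _branch_beta(
    cm: CommunityMatrix, tree: Phylogeny, dimension: str, include_root: bool, meta: dict
) -> BetaPartition:
    pres = _check_no_empty(cm)
    tip_pos = {t: i for i, t in enumerate(tree.tip_labels)}
    order = np.array([tip_pos[s] for s in cm.species_ids])
    pres_tree = np.zeros((cm.n_sites, len(tree.tip_labels)), dtype=bool)
    pres_tree[:, order] = pres

    X = tree.branch_incidence.astype(float)  # (E, S)
    L = tree.branch_lengths
    counts = X @ pres_tree.T  # (E, n_sites)
    on = counts > 0
    if not include_root:
        on &= counts < pres_tree.sum(axis=1)[None, :]
    onf = on.astype(float)
    A = (onf * L[:, None]).T @ onf  # shared branch length per pair
    totals = on.T @ L  # PD per site
    pooled = float(L[on.any(axis=1)].sum())
    return _partition_from_components(cm.site_ids, A, totals, pooled, dimension, meta)


def phylogenetic_beta(
    cm: CommunityMatrix, tree: Phylogeny, include_root: bool = True
) -> BetaPartition:
    """Branch-length (PhyloSor-family) turnover/nestedness partition."""
    return _branch_beta(
        cm, tree, "phylogenetic", include_root,
        {"units": "branch length", "include_root": include_root},
    )


def functional_beta(
    cm: CommunityMatrix,
    functional_dist: DistanceMatrix | None = None,
    traits=None,
    mode: str = "dendrogram",
    k: int = 2,
    include_root: bool = True,
) -> BetaPartition:
    """Functional turnover/nestedness partition.

    ``mode="dendrogram"`` (default) runs the branch-length algebra on the
    UPGMA dendrogram of the Gower distances — deterministic and valid for
    mixed trait types.  ``mode="hull"`` uses convex-hull volumes of each
    community in the first ``k`` PCoA axes of Gower space (pairwise
    matrices only; the multi-site summary requires dendrogram mode).
    """
    if functional_dist is None:
        if traits is None:
            raise ValidationError("functional_beta needs a distance matrix or traits")
        functional_dist = gower_distance(traits)
    functional_dist = functional_dist.submatrix(cm.species_ids)

    if mode == "dendrogram":
        dendro = upgma_dendrogram(functional_dist)
        return _branch_beta(
            cm, dendro, "functional", include_root,
            {"units": "dendrogram branch length", "mode": "dendrogram"},
        )
    if mode != "hull":
        raise ValidationError(f"unknown functional mode {mode!r}")
    if k > 3:
        raise ValidationError("hull mode supports k <= 3 axes")

    pres = _check_no_empty(cm)
    ord_res = pcoa(functional_dist, correction="lingoes")
    scores = ord_res.scores
    n = cm.n_sites
    sor = np.zeros((n, n))
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b, c = functional_abc(scores, pres[i], pres[j], k=k)
            s, t, _ = pairwise_partition(a, b, c)
            sor[i, j] = sor[j, i] = s
            sim[i, j] = sim[j, i] = t
    sne = sor - sim
    iu = np.triu_indices(n, k=1)
    return BetaPartition(
        dimension="functional",
        sor=DistanceMatrix(cm.site_ids, sor),
        sim=DistanceMatrix(cm.site_ids, sim),
        sne=DistanceMatrix(cm.site_ids, sne),
        multisite={k_: float("nan") for k_ in
                   ("SOR", "SIM", "SNE", "turnover_pct", "nestedness_pct")},
        mean_pairwise={
            "sor": float(sor[iu].mean()),
            "sim": float(sim[iu].mean()),
            "sne": float(sne[iu].mean()),
        },
        meta={"units": f"hull volume ({k} axes)", "mode": "hull", "k": k},
    )


def multisite_partition(partition: BetaPartition) -> tuple[float, float, float, float, float]:
    """(SOR, SIM, SNE, turnover%, nestedness%) of a computed partition."""
    m = partition.multisite
    return m["SOR"], m["SIM"], m["SNE"], m["turnover_pct"], m["nestedness_pct"]


def beta_all(
    bundle: DataBundle,
    functional_mode: str = "dendrogram",
    k: int = 2,
    include_root: bool = True,
) -> dict[str, BetaPartition]:
    """Taxonomic, phylogenetic and functional partitions of one bundle."""
    cm = bundle.community
    out = {"taxonomic": taxonomic_beta(cm)}
    if bundle.tree is not None:
        out["phylogenetic"] = phylogenetic_beta(cm, bundle.tree, include_root)
    if bundle.traits is not None:
        out["functional"] = functional_beta(
            cm, traits=bundle.traits, mode=functional_mode, k=k,
            include_root=include_root,
        )
    return out
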