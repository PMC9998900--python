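"""Richness-preserving null models and standardised effect sizes.

The null model shuffles species labels on the distance matrix (equivalently,
tree tips) while holding the occurrence matrix fixed, so the observed
richness of every community is preserved.  SES = (obs - mean_null)/sd_null;
negative values indicate clustering, positive values overdispersion, with
|SES| > 1.96 conventionally taken as a significant departure from random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataBundle, DistanceMatrix, ValidationError
from .alpha import mntd, mpd
from .trait_space import gower_distance

_DEGENERATE_SD = 1e-12


def shuffle_labels(dist: DistanceMatrix, rng: np.random.Generator) -> DistanceMatrix:
    """Jointly permute rows/columns of a distance matrix by one random
    permutation of its labels; the off-diagonal value multiset is unchanged."""
    perm = rng.permutation(dist.n)
    return DistanceMatrix(dist.labels, dist.values[np.ix_(perm, perm)])


def _null_metrics(
    site_idx: list[np.ndarray],
    dist_values: np.ndarray,
    metric: str,
    n_null: int,
    rng: np.random.Generator,
    shared_permutation: bool = True,
) -> np.ndarray:
    """(n_null, n_sites) null metric values under the label shuffle.

    Sites are grouped by richness so each replicate is a handful of
    vectorised gathers instead of a per-site Python loop.
    """
    n_species = dist_values.shape[0]
    n_sites = len(site_idx)
    out = np.full((n_null, n_sites), np.nan)
    groups: dict[int, list[int]] = {}
    for s, idx in enumerate(site_idx):
        groups.setdefault(len(idx), []).append(s)

    for r in range(n_null):
        if shared_permutation:
            perm = rng.permutation(n_species)
        for k, members in groups.items():
            if k < 2:
                continue
            I = np.stack([site_idx[s] for s in members])  # (m, k)
            if shared_permutation:
                J = perm[I]
            else:
                J = np.stack(
                    [rng.choice(n_species, size=k, replace=False) for _ in members]
                )
            sub = dist_values[J[:, :, None], J[:, None, :]]  # (m, k, k)
            if metric == "mpd":
                vals = sub.sum(axis=(1, 2)) / (k * (k - 1))
            else:  # mntd
                sub[:, np.arange(k), np.arange(k)] = np.inf
                vals = sub.min(axis=2).mean(axis=1)
            out[r, members] = vals
    return out


@dataclass
class SESTable:
    """Per-site standardised effect sizes for one metric/dimension."""

    data: pd.DataFrame
    metric: str  # mpd | mntd
    dimension: str  # phylo | func
    n_null: int
    seed: int
    null_algorithm: str = "taxa_label_shuffle_shared"

    def to_frame(self) -> pd.DataFrame:
        df = self.data.copy()
        df.index.name = "site"
        return df


def ses(
    bundle: DataBundle,
    metric: str = "mntd",
    dimension: str = "phylo",
    n_null: int = 1000,
    seed: int = 0,
    functional_dist: DistanceMatrix | None = None,
    shared_permutation: bool = True,
) -> SESTable:
    """Standardised effect size of MPD or MNTD against the label-shuffle null.

    Sites with fewer than two species are reported with missing values (a
    single species has no pairwise structure).  A null with zero standard
    deviation (e.g. a site containing the whole pool) is flagged degenerate
    rather than yielding an infinite SES.  ``p_rank`` is the proportion of
    null values at or below the observation, with the (r+1)/(n+1)
    convention.
    """
    if metric not in ("mpd", "mntd"):
        raise ValidationError(f"unknown metric {metric!r}")
    if dimension not in ("phylo", "func"):
        raise ValidationError(f"unknown dimension {dimension!r}")
    cm = bundle.community
    if dimension == "phylo":
        if bundle.tree is None:
            raise ValidationError("bundle has no tree")
        dist = bundle.tree.cophenetic().submatrix(cm.species_ids)
    else:
        if functional_dist is None:
            if bundle.traits is None:
                raise ValidationError("bundle has no traits")
            functional_dist = gower_distance(bundle.traits)
        dist = functional_dist.submatrix(cm.species_ids)

    pres = cm.presence()
    site_idx = [np.flatnonzero(pres[i]) for i in range(cm.n_sites)]
    fn = mpd if metric == "mpd" else mntd
    obs = np.array([fn(pres[i], dist) for i in range(cm.n_sites)])

    rng = np.random.default_rng(seed)
    null = _null_metrics(
        site_idx, dist.values, metric, n_null, rng, shared_permutation
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN small sites
        null_mean = np.nanmean(null, axis=0)
        null_sd = np.nanstd(null, axis=0, ddof=1)
    degenerate = null_sd <= _DEGENERATE_SD
    with np.errstate(invalid="ignore", divide="ignore"):
        ses_vals = np.where(
            degenerate | np.isnan(obs), np.nan, (obs - null_mean) / null_sd
        )
    with np.errstate(invalid="ignore"):
        p_rank = (np.nansum(null <= obs[None, :], axis=0) + 1) / (n_null + 1)
    p_rank = np.where(np.isnan(obs), np.nan, p_rank)

    df = pd.DataFrame(
        {
            "obs": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "ses": ses_vals,
            "p_rank": p_rank,
            "degenerate": degenerate,
            "richness": [len(i) for i in site_idx],
        },
        index=cm.site_ids,
    )
    algo = "taxa_label_shuffle_" + ("shared" if shared_permutation else "per_site")
    return SESTable(df, metric, dimension, n_null, seed, algo)


def classify_structure(
    ses_table: SESTable | pd.DataFrame,
    zones: pd.Series,
    threshold: float = 1.96,
    zone_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-zone counts of clustered / overdispersed communities.

    ``zones`` maps site id to zone label; every site in the SES table must
    have a zone.  Returns one row per zone with counts (and proportions) of
    negative, positive, significantly negative and significantly positive
    SES values.
    """
    df = ses_table.data if isinstance(ses_table, SESTable) else ses_table
    zones = zones.astype(str)
    missing = set(df.index) - set(zones.index)
    if missing:
        raise ValidationError(f"sites without zone label: {sorted(missing)[:5]}")
    z = zones.loc[df.index]
    if zone_order is None:
        from .core import ZONE_LABELS

        zone_order = (
            list(ZONE_LABELS)
            if set(z) <= set(ZONE_LABELS)
            else sorted(set(z))
        )
    unknown = set(z) - set(zone_order)
    if unknown:
        raise ValidationError(f"unknown zone label(s): {sorted(unknown)}")

    rows = []
    for zone in zone_order:
        s = df.loc[(z == zone).to_numpy(), "ses"].dropna()
        n = len(s)
        rows.append(
            {
                "zone": zone,
                "n": n,
                "clustered": int((s < 0).sum()),
                "overdispersed": int((s > 0).sum()),
                "sig_clustered": int((s < -threshold).sum()),
                "sig_overdispersed": int((s > threshold).sum()),
                "prop_clustered": (s < 0).mean() if n else 0.0,
                "prop_sig_clustered": (s < -threshold).mean() if n else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("zone")
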