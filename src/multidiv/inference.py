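"""Matrix-correlation tests and variance partitioning of beta diversity.

Mantel and partial Mantel tests correlate the off-diagonal elements of two
site-by-site distance matrices, with significance from joint row/column
permutations.  Variance partitioning regresses the principal coordinates of
a beta-diversity matrix (db-RDA style) on up to four predictor sets
(inundation gradient, climate, soil, spatial eigenvectors) and decomposes
the adjusted R-squared into unique and shared Venn fractions by
inclusion-exclusion.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DistanceMatrix, ValidationError
from .trait_space import pcoa

logger = logging.getLogger("multidiv")


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    n: int
    partial: str | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "r": self.r,
                    "p": self.p,
                    "n_perm": self.n_perm,
                    "n": self.n,
                    "partial": self.partial or "",
                }
            ]
        )


def _check_aligned(*mats: DistanceMatrix) -> None:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise ValidationError("distance matrices have mismatched labels")


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0:
        return 0.0
    return float((xc @ yc) / den)


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation over the n(n-1)/2 off-diagonal pairs; the
    null distribution jointly permutes rows and columns of ``dy``; p is
    one-tailed for positive association with the (r+1)/(n+1) convention.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be at least 99")
    _check_aligned(dx, dy)
    n = dx.n
    iu = np.triu_indices(n, k=1)
    x = dx.values[iu]
    r_obs = _corr(x, dy.values[iu])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = dy.values[np.ix_(perm, perm)][iu]
        if _corr(x, yp) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, n=n, seed=seed)


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residuals of a simple linear regression of v on z (with intercept).

    Residuals that are pure floating-point noise (v collinear with z) are
    zeroed so they cannot masquerade as signal after normalisation.
    """
    A = np.column_stack([np.ones_like(z), z])
    coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    r = v - A @ coef
    scale = np.linalg.norm(v - v.mean())
    if np.linalg.norm(r) <= 1e-10 * max(scale, 1e-300):
        return np.zeros_like(r)
    return r


def partial_mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    dz: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Partial Mantel correlation of dx and dy controlling for dz.

    Off-diagonal elements of dx and dy are each regressed on those of dz;
    r is the correlation of the residuals.  The null permutes the raw
    ``dy`` matrix (Legendre's method 1) and recomputes the residual
    correlation.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be at least 99")
    _check_aligned(dx, dy, dz)
    n = dx.n
    iu = np.triu_indices(n, k=1)
    z = dz.values[iu]
    rx = _residualize(dx.values[iu], z)
    r_obs = _corr(rx, _residualize(dy.values[iu], z))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = dy.values[np.ix_(perm, perm)][iu]
        if _corr(rx, _residualize(yp, z)) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(
        r=r_obs, p=p, n_perm=n_perm, n=n, partial="dz", seed=seed
    )


# ---------------------------------------------------------------------------
# Redundancy analysis pieces
# ---------------------------------------------------------------------------


def _r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Trace R-squared of a multivariate least-squares fit with intercept."""
    Yc = Y - Y.mean(axis=0)
    A = np.column_stack([np.ones(X.shape[0]), X])
    coef, *_ = np.linalg.lstsq(A, Yc, rcond=None)
    fitted = A @ coef
    ss_tot = float(np.sum(Yc**2))
    if ss_tot == 0:
        return 0.0
    ss_res = float(np.sum((Yc - fitted) ** 2))
    return 1.0 - ss_res / ss_tot


def rda_adj_r2(response_axes: np.ndarray, predictors: np.ndarray) -> float:
    """Ezekiel-adjusted trace R-squared: 1 - (1-R2)(n-1)/(n-m-1)."""
    Y = np.asarray(response_axes, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    if n - m - 1 <= 0:
        raise ValidationError("saturated model: n - m - 1 <= 0")
    r2 = _r2(Y, X)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def forward_select(
    response_axes: np.ndarray,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> list[str]:
    """Greedy forward selection of predictors for a multivariate response.

    At each step the candidate with the largest adjusted-R2 gain is tested
    by permuting response rows; selection stops when the added term's
    permutation p exceeds ``alpha`` or the cumulative adjusted R2 exceeds
    the global (all-candidate) adjusted R2 (double stopping rule).  An
    empty selection is a valid outcome.
    """
    Y = np.asarray(response_axes, dtype=float)
    n = Y.shape[0]
    names = list(candidates.columns)
    Xall = candidates.to_numpy(dtype=float)
    try:
        global_adj = rda_adj_r2(Y, Xall)
    except ValidationError:
        global_adj = np.inf  # saturated global model: skip that stop rule
    rng = np.random.default_rng(seed)

    selected: list[str] = []
    cur_cols: list[int] = []
    while True:
        remaining = [j for j in range(len(names)) if j not in cur_cols]
        if not remaining:
            break
        best_j, best_adj = None, -np.inf
        for j in remaining:
            cols = cur_cols + [j]
            if n - len(cols) - 1 <= 0:
                continue
            adj = rda_adj_r2(Y, Xall[:, cols])
            if adj > best_adj:
                best_adj, best_j = adj, j
        if best_j is None:
            break
        cols = cur_cols + [best_j]
        cur_r2 = _r2(Y, Xall[:, cur_cols]) if cur_cols else 0.0
        gain_obs = _r2(Y, Xall[:, cols]) - cur_r2
        count = 0
        for _ in range(n_perm):
            Yp = Y[rng.permutation(n)]
            gain = _r2(Yp, Xall[:, cols]) - (
                _r2(Yp, Xall[:, cur_cols]) if cur_cols else 0.0
            )
            if gain >= gain_obs:
                count += 1
        p = (count + 1) / (n_perm + 1)
        if p > alpha:
            break
        # scope rule: beyond the first term, stop once the cumulative
        # adjusted R2 would exceed the global (all-candidate) model's --
        # the first significant term is always eligible, otherwise a lone
        # strong predictor among pure noise could never be selected
        if selected and best_adj > global_adj:
            break
        selected.append(names[best_j])
        cur_cols.append(best_j)
    return selected


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------


@dataclass
class VarPartResult:
    """Venn decomposition of adjusted R-squared over predictor sets.

    ``fractions`` maps a frozenset of set labels (the exact Venn region) to
    its adjusted-R2 share; negative values are an expected adjusted-R2
    artefact and are reported as-is.
    """

    set_labels: list[str]
    union_adj_r2: dict[frozenset, float]
    fractions: dict[frozenset, float]
    residual: float
    response_description: str
    meta: dict = field(default_factory=dict)

    @property
    def unique(self) -> dict[str, float]:
        return {s: self.fractions[frozenset([s])] for s in self.set_labels}

    @property
    def total_adj_r2(self) -> float:
        return self.union_adj_r2[frozenset(self.set_labels)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subset, frac in sorted(
            self.fractions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
        ):
            rows.append(
                {
                    "sets": "+".join(sorted(subset)),
                    "n_sets": len(subset),
                    "fraction": frac,
                    "union_adj_r2": self.union_adj_r2[subset],
                }
            )
        rows.append(
            {"sets": "residual", "n_sets": 0, "fraction": self.residual,
             "union_adj_r2": np.nan}
        )
        return pd.DataFrame(rows).set_index("sets")


def variance_partition(
    beta_dist: DistanceMatrix,
    sets: dict[str, pd.DataFrame],
    n_axes_rule: str = "positive",
) -> VarPartResult:
    """Partition beta-diversity variation among predictor sets.

    The response is the positive-eigenvalue PCoA axes of ``beta_dist``
    (db-RDA style).  Adjusted R2 is computed for all non-empty unions of
    the predictor sets and the exclusive Venn fractions recovered by
    solving the inclusion-exclusion system; the residual is
    1 - adjR2(all sets).  Empty predictor sets degrade the partition to the
    remaining sets with a warning.
    """
    usable: dict[str, pd.DataFrame] = {}
    for name, df in sets.items():
        if df is None or df.shape[1] == 0:
            logger.warning("predictor set %r is empty; dropped from partition", name)
            continue
        if list(map(str, df.index)) != beta_dist.labels:
            df = df.loc[beta_dist.labels]
        usable[name] = df
    if not usable:
        raise ValidationError("no non-empty predictor sets")

    ord_res = pcoa(beta_dist)
    Y = ord_res.scores
    if n_axes_rule != "positive":
        raise ValidationError(f"unknown n_axes_rule {n_axes_rule!r}")

    labels = sorted(usable)
    subsets = [
        frozenset(c)
        for k in range(1, len(labels) + 1)
        for c in itertools.combinations(labels, k)
    ]
    union_adj: dict[frozenset, float] = {}
    for sub in subsets:
        X = np.column_stack([usable[s].to_numpy(dtype=float) for s in sorted(sub)])
        union_adj[sub] = rda_adj_r2(Y, X)

    # solve M f = r where M[S, T] = 1 iff T intersects S
    m = len(subsets)
    M = np.zeros((m, m))
    r = np.zeros(m)
    for i, S in enumerate(subsets):
        r[i] = union_adj[S]
        for j, T in enumerate(subsets):
            M[i, j] = 1.0 if S & T else 0.0
    f = np.linalg.solve(M, r)
    fractions = {subsets[j]: float(f[j]) for j in range(m)}
    residual = 1.0 - union_adj[frozenset(labels)]

    return VarPartResult(
        set_labels=labels,
        union_adj_r2=union_adj,
        fractions=fractions,
        residual=residual,
        response_description=(
            f"PCoA of beta matrix ({Y.shape[1]} positive axes, "
            f"{beta_dist.n} sites)"
        ),
        meta={"n_axes": Y.shape[1]},
    )
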