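"""Core domain types, file readers/writers and cross-dataset validation.

The central objects are a site-by-species :class:`CommunityMatrix`, a species
:class:`TraitTable`, a rooted :class:`Phylogeny` with branch lengths, a site
:class:`EnvTable`, site :class:`Coordinates`, and a generic labelled
:class:`DistanceMatrix`.  :func:`validate_bundle` reconciles them into a
:class:`DataBundle` that downstream metrics consume.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("multidiv")

TRAIT_KINDS = ("categorical", "ordinal", "continuous")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric, non-negative pairwise distances with a fixed label order."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(self.values < -1e-12):
            raise ValidationError("distance matrix has negative entries")
        np.fill_diagonal(self.values, 0.0)
        self.values = np.maximum(self.values, 0.0)
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, labels: Sequence[str]) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([pos[l] for l in labels], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"label {e} not in distance matrix") from e

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = self.index(labels)
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) values, row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Community matrix
# ---------------------------------------------------------------------------


@dataclass
class CommunityMatrix:
    """Sites x species occurrence or abundance table.

    Parameters
    ----------
    site_ids, species_ids
        Unique ordered labels.
    values
        Non-negative matrix, shape ``(n_sites, n_species)``.  In
        ``presence`` mode every entry is 0 or 1.
    mode
        ``"presence"`` or ``"abundance"``.
    """

    site_ids: list[str]
    species_ids: list[str]
    values: np.ndarray
    mode: str = "presence"
    coerced_cells: int = 0

    def __post_init__(self) -> None:
        self.site_ids = [str(s).strip() for s in self.site_ids]
        self.species_ids = [str(s).strip() for s in self.species_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("presence", "abundance"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValidationError("duplicate site label")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValidationError("duplicate species label")
        if self.values.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValidationError("community values shape mismatch")
        if np.any(self.values < 0):
            raise ValidationError("negative abundance in community matrix")
        if self.mode == "presence":
            bad = ~np.isin(self.values, (0.0, 1.0))
            if bad.any():
                raise ValidationError("presence-mode matrix has non-0/1 entries")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def presence(self) -> np.ndarray:
        """Boolean occurrence matrix regardless of mode."""
        return self.values > 0

    def richness(self) -> np.ndarray:
        return self.presence().sum(axis=1)

    def drop_empty_sites(self) -> "CommunityMatrix":
        keep = self.richness() > 0
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning("dropping %d site(s) with zero richness", n_drop)
        return CommunityMatrix(
            [s for s, k in zip(self.site_ids, keep) if k],
            self.species_ids,
            self.values[keep],
            mode=self.mode,
            coerced_cells=self.coerced_cells,
        )

    def select_species(self, species: Sequence[str]) -> "CommunityMatrix":
        pos = {s: i for i, s in enumerate(self.species_ids)}
        idx = [pos[s] for s in species]
        return CommunityMatrix(
            self.site_ids,
            list(species),
            self.values[:, idx],
            mode=self.mode,
            coerced_cells=self.coerced_cells,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.site_ids, columns=self.species_ids)
        df.index.name = "site"
        return df


# ---------------------------------------------------------------------------
# Trait table
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Species trait values with each column tagged by kind.

    ``kinds`` maps trait name to one of ``categorical``, ``ordinal``,
    ``continuous``; ``units`` optionally annotates continuous traits.
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = [str(i).strip() for i in self.data.index]
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate species label in trait table")
        unknown = set(self.data.columns) - set(self.kinds)
        if unknown:
            raise ValidationError(f"traits without declared kind: {sorted(unknown)}")
        for t, k in self.kinds.items():
            if k not in TRAIT_KINDS:
                raise ValidationError(f"trait {t!r} has unknown kind {k!r}")
        all_missing = self.data.isna().all(axis=1)
        if all_missing.any():
            raise ValidationError(
                "species with no non-missing trait: "
                f"{list(self.data.index[all_missing])}"
            )

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    def select_species(self, species: Sequence[str]) -> "TraitTable":
        return TraitTable(self.data.loc[list(species)], dict(self.kinds), dict(self.units))


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """Rooted tree with non-negative branch lengths over a species pool.

    Thin wrapper around a :class:`dendropy.Tree` exposing the vectorised
    branch-incidence representation used by the diversity metrics: each
    branch is a row of a boolean matrix over tips (True where the tip
    descends from the branch), paired with the branch length.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        if len(set(tips)) != len(tips):
            raise ValidationError("duplicate tip labels in tree")
        self.tip_labels: list[str] = tips
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue  # root edge length may be absent
            if edge.length is None:
                raise ValidationError("branch lengths required")
            if edge.length < 0:
                raise ValidationError("negative branch length")
        root = tree.seed_node
        if len(root.child_nodes()) > 2:
            logger.warning("tree root is multifurcating; accepted as rooted")
        self._incidence: np.ndarray | None = None
        self._lengths: np.ndarray | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        """Parse a Newick tree from a path or a literal string."""
        text = str(source)
        if not text.lstrip().startswith("(") and Path(text).exists():
            text = Path(text).read_text()
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- branch incidence ---------------------------------------------

    def _build_incidence(self) -> None:
        tips = self.tip_labels
        pos = {t: i for i, t in enumerate(tips)}
        rows, lens = [], []
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                mask = np.zeros(len(tips), dtype=bool)
                mask[pos[node.taxon.label]] = True
            else:
                mask = np.zeros(len(tips), dtype=bool)
                for ch in node.child_nodes():
                    mask |= ch._md_mask
            node._md_mask = mask
            length = node.edge.length
            if node is self._tree.seed_node:
                length = length or 0.0
            if length is None:
                length = 0.0
            rows.append(mask)
            lens.append(float(length))
        self._incidence = np.array(rows, dtype=bool)
        self._lengths = np.array(lens, dtype=float)

    @property
    def branch_incidence(self) -> np.ndarray:
        """Boolean (n_branches, n_tips) matrix of tip descent."""
        if self._incidence is None:
            self._build_incidence()
        return self._incidence

    @property
    def branch_lengths(self) -> np.ndarray:
        if self._lengths is None:
            self._build_incidence()
        return self._lengths

    # -- derived quantities -------------------------------------------

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    def cophenetic(self) -> DistanceMatrix:
        """Tip-to-tip path-length distances."""
        X = self.branch_incidence.astype(float)
        L = self.branch_lengths
        shared = (X * L[:, None]).T @ X  # shared root-path length
        depth = np.diag(shared)
        d = depth[:, None] + depth[None, :] - 2.0 * shared
        return DistanceMatrix(self.tip_labels, np.maximum(d, 0.0))

    def prune(self, keep: Iterable[str]) -> "Phylogeny":
        """Subtree over ``keep`` tips; path lengths between kept tips preserved."""
        keep = list(keep)
        missing = set(keep) - set(self.tip_labels)
        if missing:
            raise ValidationError(f"tips not in tree: {sorted(missing)}")
        sub = self._tree.extract_tree_with_taxa_labels(
            labels=keep, suppress_unifurcations=True
        )
        return Phylogeny(sub)


# ---------------------------------------------------------------------------
# Environment and coordinates
# ---------------------------------------------------------------------------

ZONE_LABELS = ("I", "II", "III", "IV")
#: days of continuous inundation per elevation zone (shortest to longest)
ZONE_INUNDATION_DAYS = {"I": 68, "II": 112, "III": 152, "IV": 204}


@dataclass
class EnvTable:
    """Per-site environment: inundation zone/days, soil, climate, topography."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = [str(i).strip() for i in self.data.index]
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate site label in environment table")
        num = self.data.select_dtypes(include=[np.number])
        if not np.isfinite(num.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite numeric value in environment table")
        if "zone" in self.data.columns:
            bad = set(self.data["zone"].astype(str)) - set(ZONE_LABELS)
            if bad:
                raise ValidationError(f"unknown inundation zone label(s): {sorted(bad)}")

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    def select_sites(self, sites: Sequence[str]) -> "EnvTable":
        return EnvTable(self.data.loc[list(sites)])

    def columns_matching(self, prefix: str) -> list[str]:
        return [c for c in self.data.columns if c.startswith(prefix)]


@dataclass
class Coordinates:
    """Per-site x/y location, geographic (lon/lat degrees) or planar."""

    data: pd.DataFrame  # columns x, y
    crs: str = "planar"  # "geographic" or "planar"

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = [str(i).strip() for i in self.data.index]
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate site label in coordinates")
        if not {"x", "y"} <= set(self.data.columns):
            raise ValidationError("coordinates need columns 'x' and 'y'")
        if self.crs not in ("geographic", "planar"):
            raise ValidationError(f"unknown crs flag {self.crs!r}")
        if self.crs == "geographic":
            lat = self.data["y"].to_numpy(dtype=float)
            if np.any(np.abs(lat) > 90):
                raise ValidationError("latitude outside [-90, 90]")

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def select_sites(self, sites: Sequence[str]) -> "Coordinates":
        return Coordinates(self.data.loc[list(sites)], crs=self.crs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = [str(i).strip() for i in df.index]
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_community(path: str | Path, mode: str = "presence") -> CommunityMatrix:
    """Read a site-by-species table (first column = site id).

    In presence mode any positive value is coerced to 1 and the number of
    coerced cells recorded; zero stays zero.  Sites with zero richness are
    dropped with a warning.
    """
    df = _read_delimited(path)
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValidationError("negative value in community file")
    coerced = 0
    if mode == "presence":
        pos = values > 0
        coerced = int(np.sum(pos & (values != 1)))
        values = pos.astype(float)
    cm = CommunityMatrix(
        list(df.index), list(df.columns), values, mode=mode, coerced_cells=coerced
    )
    return cm.drop_empty_sites()


def read_tree(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree; branch lengths are mandatory."""
    return Phylogeny.from_newick(path)


def read_traits(
    path: str | Path,
    kinds: Mapping[str, str] | str | Path,
    units: Mapping[str, str] | None = None,
) -> TraitTable:
    """Read a trait table; ``kinds`` is a mapping or a YAML sidecar path."""
    df = _read_delimited(path)
    if not isinstance(kinds, Mapping):
        import yaml

        with open(kinds) as fh:
            side = yaml.safe_load(fh)
        kinds = side.get("kinds", side)
        units = units or side.get("units", {})
    return TraitTable(df, dict(kinds), dict(units or {}))


def read_env(path: str | Path) -> EnvTable:
    return EnvTable(_read_delimited(path))


def read_coords(path: str | Path, crs: str = "planar") -> Coordinates:
    df = _read_delimited(path)
    return Coordinates(df, crs=crs)


def write_table(result, path: str | Path, float_precision: int = 12) -> None:
    """Write any tabular result as CSV with a deterministic column order.

    Accepts a DataFrame or any object exposing ``to_frame()``.
    """
    if hasattr(result, "to_frame") and not isinstance(result, pd.DataFrame):
        df = result.to_frame()
    elif isinstance(result, pd.DataFrame):
        df = result
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot write object of type {type(result).__name__}")
    df.to_csv(path, float_format=f"%.{float_precision}g")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    return DistanceMatrix.from_frame(_read_delimited(path))


# ---------------------------------------------------------------------------
# Bundle validation
# ---------------------------------------------------------------------------


@dataclass
class DataBundle:
    """Reconciled datasets over common species and site sets."""

    community: CommunityMatrix
    traits: TraitTable | None
    tree: Phylogeny | None
    env: EnvTable | None
    coords: Coordinates | None
    species: list[str]
    sites: list[str]
    report: dict[str, int] = field(default_factory=dict)


def validate_bundle(
    community: CommunityMatrix,
    traits: TraitTable | None = None,
    tree: Phylogeny | None = None,
    env: EnvTable | None = None,
    coords: Coordinates | None = None,
    policy: str = "drop",
) -> DataBundle:
    """Reconcile species across community/traits/tree and sites across
    community/env/coords.

    ``policy="error"`` rejects any mismatch; ``policy="drop"`` intersects
    label sets, prunes the tree and reports per-source drop counts.
    Matching is by exact (whitespace-trimmed) label.
    """
    if policy not in ("error", "drop"):
        raise ValidationError(f"unknown policy {policy!r}")

    species = list(community.species_ids)
    sources: dict[str, set[str]] = {}
    if traits is not None:
        sources["traits"] = set(traits.species_ids)
    if tree is not None:
        sources["tree"] = set(tree.tip_labels)

    common = set(species)
    for s in sources.values():
        common &= s
    if not common:
        raise ValidationError("no common species across community/traits/tree")

    report: dict[str, int] = {}
    report["community_species_dropped"] = len(set(species) - common)
    for name, s in sources.items():
        report[f"{name}_species_dropped"] = len(s - common)
    if policy == "error" and (
        report["community_species_dropped"]
        or any(report[f"{n}_species_dropped"] for n in sources)
    ):
        raise ValidationError(f"species label mismatch: {report}")

    kept_species = [s for s in species if s in common]
    community = community.select_species(kept_species)
    community = community.drop_empty_sites()
    if traits is not None:
        traits = traits.select_species(kept_species)
    if tree is not None and set(tree.tip_labels) != common:
        tree = tree.prune(kept_species)

    # sites
    sites = list(community.site_ids)
    site_sources: dict[str, set[str]] = {}
    if env is not None:
        site_sources["env"] = set(env.site_ids)
    if coords is not None:
        site_sources["coords"] = set(coords.site_ids)
    common_sites = set(sites)
    for s in site_sources.values():
        common_sites &= s
    if not common_sites:
        raise ValidationError("no common sites across community/env/coords")
    report["community_sites_dropped"] = len(set(sites) - common_sites)
    for name, s in site_sources.items():
        report[f"{name}_sites_dropped"] = len(s - common_sites)
    if policy == "error" and (
        report["community_sites_dropped"]
        or any(report[f"{n}_sites_dropped"] for n in site_sources)
    ):
        raise ValidationError(f"site label mismatch: {report}")

    kept_sites = [s for s in sites if s in common_sites]
    if kept_sites != sites:
        pos = {s: i for i, s in enumerate(community.site_ids)}
        idx = [pos[s] for s in kept_sites]
        community = CommunityMatrix(
            kept_sites,
            community.species_ids,
            community.values[idx],
            mode=community.mode,
            coerced_cells=community.coerced_cells,
        )
    if env is not None:
        env = env.select_sites(kept_sites)
    if coords is not None:
        coords = coords.select_sites(kept_sites)

    return DataBundle(
        community=community,
        traits=traits,
        tree=tree,
        env=env,
        coords=coords,
        species=kept_species,
        sites=kept_sites,
        report=report,
    )
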