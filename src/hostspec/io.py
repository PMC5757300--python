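"""Core data containers and plain-text readers/writers.

Everything on disk is plain text: Newick for trees and CSV (comma separated,
UTF-8, ``.`` decimal, empty cell = missing) for trait tables, host-parasite
association tables and labelled distance matrices.

Species labels are matched exactly after trimming surrounding whitespace,
collapsing internal runs of spaces and treating underscores and spaces as
interchangeable (the Newick convention), so ``Rattus_rattus`` and
``Rattus rattus`` refer to the same host.
"""

from __future__ import annotations

import io as _io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("hostspec")

__all__ = [
    "ValidationError",
    "FormatError",
    "normalize_label",
    "HostTree",
    "read_newick",
    "write_newick",
    "TraitTable",
    "read_trait_table",
    "write_trait_table",
    "AssociationTable",
    "read_associations",
    "write_associations",
    "DistanceMatrix",
    "read_matrix",
    "write_matrix",
    "AnalysisConfig",
    "DEFAULT_LINKAGE_METHODS",
    "intersect_species",
]


class ValidationError(ValueError):
    """An input violates a structural invariant (no silent coercion)."""


class FormatError(ValueError):
    """A file could not be parsed in the expected dialect."""


_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Canonicalise a species label: underscores -> spaces, collapse runs of
    whitespace, strip the ends."""
    return _WS.sub(" ", str(label).replace("_", " ")).strip()


# ---------------------------------------------------------------------------
# Host phylogeny
# ---------------------------------------------------------------------------


class HostTree:
    """A rooted host phylogeny with branch lengths.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the invariants
    the downstream analyses rely on: unique non-empty tip labels, every
    non-root branch carries a non-negative length, and at least two tips.
    Polytomies are preserved.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        tree.is_rooted = True
        for taxon in tree.taxon_namespace:
            if taxon.label is not None:
                taxon.label = normalize_label(taxon.label)
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "HostTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                rooting="default-rooted",
            )
        except Exception as exc:  # dendropy raises several parse error types
            msg = str(exc).lower()
            if "duplicate" in msg or "multiple occurrences" in msg:
                raise ValidationError(f"duplicate tip labels: {exc}") from exc
            pos = ""
            line = getattr(exc, "line_num", None)
            col = getattr(exc, "col_num", None)
            if line is not None:
                pos = f" (line {line}, column {col})"
            raise FormatError(f"could not parse Newick{pos}: {exc}") from exc
        return cls(tree)

    @classmethod
    def read(cls, path) -> "HostTree":
        text = Path(path).read_text(encoding="utf-8").strip()
        if not text:
            raise FormatError(f"{path}: empty Newick file")
        return cls.from_newick(text)

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        leaves = self._tree.leaf_nodes()
        if len(leaves) < 2:
            raise ValidationError("tree must have at least 2 tips")
        labels = [lf.taxon.label if lf.taxon else "" for lf in leaves]
        if any(not lab for lab in labels):
            raise ValidationError("tree has unlabelled tips")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise ValidationError(
                    "missing branch length on a non-root edge"
                )
            if node.edge.length < 0:
                raise ValidationError("negative branch length")

    # -- basic queries ------------------------------------------------------

    @property
    def tips(self) -> list[str]:
        """Sorted tip labels."""
        return sorted(lf.taxon.label for lf in self._tree.leaf_nodes())

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def n_edges(self) -> int:
        """Number of edges excluding the root edge."""
        return sum(1 for n in self._tree.preorder_node_iter()) - 1

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    # -- output -------------------------------------------------------------

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def write(self, path) -> None:
        Path(path).write_text(self.to_newick() + "\n", encoding="utf-8")

    def prune_to(self, labels: Iterable[str]) -> "HostTree":
        """Return a copy restricted to ``labels`` (all must be tips)."""
        keep = {normalize_label(l) for l in labels}
        missing = keep - set(self.tips)
        if missing:
            raise ValidationError(f"labels not in tree: {sorted(missing)}")
        tree = self._tree.clone(depth=1)
        tree.retain_taxa_with_labels(sorted(keep))
        return HostTree(tree)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<HostTree with {self.n_tips} tips>"


def read_newick(path) -> HostTree:
    """Read a single-tree Newick file into a :class:`HostTree`."""
    return HostTree.read(path)


def write_newick(tree: HostTree, path) -> None:
    tree.write(path)


# ---------------------------------------------------------------------------
# Trait table
# ---------------------------------------------------------------------------

_TRAIT_TYPES = ("continuous", "binary", "categorical", "fuzzy")


@dataclass
class TraitTable:
    """Per-species typed trait columns with missingness.

    ``types`` maps every data column to one of ``continuous``, ``binary``,
    ``categorical`` or ``fuzzy``; ``fuzzy_groups`` groups the fuzzy columns
    into named compositions (e.g. the 10 diet-category proportions) whose
    non-missing rows must sum to 1.
    """

    data: pd.DataFrame
    types: dict
    fuzzy_groups: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = self.data.copy()
        self.data.index = [normalize_label(s) for s in self.data.index]
        self.data.index.name = "species"
        self.validate()

    def validate(self) -> None:
        idx = list(self.data.index)
        if len(set(idx)) != len(idx):
            dupes = sorted({s for s in idx if idx.count(s) > 1})
            raise ValidationError(f"duplicate species labels: {dupes}")
        unknown = set(self.data.columns) - set(self.types)
        if unknown:
            raise ValidationError(f"columns missing from schema: {sorted(unknown)}")
        for col, typ in self.types.items():
            if typ not in _TRAIT_TYPES:
                raise ValidationError(f"unknown trait type {typ!r} for {col!r}")
            if col not in self.data.columns:
                raise ValidationError(f"schema column {col!r} absent from table")
            vals = self.data[col]
            if typ in ("continuous", "fuzzy"):
                arr = pd.to_numeric(vals, errors="coerce")
                bad = vals.notna() & arr.isna()
                if bad.any():
                    raise ValidationError(
                        f"non-numeric values in {typ} column {col!r}: "
                        f"{sorted(self.data.index[bad])}"
                    )
                if np.isinf(arr.to_numpy(dtype=float, na_value=np.nan)).any():
                    raise ValidationError(f"non-finite values in column {col!r}")
                if typ == "fuzzy" and (arr.dropna() < 0).any():
                    raise ValidationError(f"negative proportions in {col!r}")
                self.data[col] = arr.astype(float)
            elif typ == "binary":
                arr = pd.to_numeric(vals, errors="coerce")
                ok = arr.isna() | arr.isin([0, 1])
                if not ok.all():
                    raise ValidationError(
                        f"binary column {col!r} has values outside {{0,1}}: "
                        f"{sorted(self.data.index[~ok])}"
                    )
                self.data[col] = arr.astype(float)
        for group, cols in self.fuzzy_groups.items():
            for c in cols:
                if self.types.get(c) != "fuzzy":
                    raise ValidationError(
                        f"fuzzy group {group!r} member {c!r} is not typed fuzzy"
                    )
            block = self.data[list(cols)]
            complete = block.notna().all(axis=1)
            sums = block[complete].sum(axis=1)
            bad = sums.index[(sums - 1.0).abs() > 1e-8]
            if len(bad):
                raise ValidationError(
                    f"fuzzy group {group!r} rows do not sum to 1: {sorted(bad)}"
                )

    @property
    def species(self) -> list:
        return list(self.data.index)

    def copy(self) -> "TraitTable":
        return TraitTable(self.data.copy(), dict(self.types), dict(self.fuzzy_groups))


def _parse_schema(schema: Mapping[str, str]):
    """Split a column->type map; fuzzy entries may read ``fuzzy:<group>``."""
    types, groups = {}, {}
    for col, typ in schema.items():
        if typ.startswith("fuzzy"):
            _, _, group = typ.partition(":")
            group = group or "fuzzy"
            types[col] = "fuzzy"
            groups.setdefault(group, []).append(col)
        else:
            types[col] = typ
    return types, groups


def read_trait_table(path, schema: Mapping[str, str]) -> TraitTable:
    """Read a trait CSV whose first column is ``species``; ``schema`` names
    every other column's type (``continuous``, ``binary``, ``categorical``
    or ``fuzzy:<group>``)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "species":
        raise FormatError(f"{path}: first column must be 'species'")
    df = df.replace("", np.nan).set_index("species")
    extra = set(df.columns) - set(schema)
    if extra:
        raise FormatError(f"{path}: columns not named in schema: {sorted(extra)}")
    types, groups = _parse_schema(schema)
    return TraitTable(df, types, groups)


def write_trait_table(table: TraitTable, path) -> None:
    table.data.to_csv(path, na_rep="")


# ---------------------------------------------------------------------------
# Host-parasite associations
# ---------------------------------------------------------------------------


@dataclass
class AssociationTable:
    """Long-format host x parasite presence records.

    Duplicate ``(host, parasite)`` rows are aggregated by logical OR of
    presence and summation of any sampling counts; presence is forced to 1
    whenever ``n_infested > 0``.
    """

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records.copy()
        required = {"host", "parasite", "present"}
        if not required.issubset(df.columns):
            raise ValidationError(f"association table needs columns {sorted(required)}")
        df["host"] = df["host"].map(normalize_label)
        df["parasite"] = df["parasite"].map(normalize_label)
        df["present"] = pd.to_numeric(df["present"], errors="raise")
        if not df["present"].isin([0, 1]).all():
            raise ValidationError("present must be 0 or 1")
        for col in ("n_sampled", "n_infested"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="coerce")
            else:
                df[col] = np.nan
        agg = (
            df.groupby(["host", "parasite"], as_index=False)
            .agg(
                present=("present", "max"),
                n_sampled=("n_sampled", lambda s: s.sum(min_count=1)),
                n_infested=("n_infested", lambda s: s.sum(min_count=1)),
            )
            .sort_values(["parasite", "host"], ignore_index=True)
        )
        counts = agg["n_sampled"].notna() & agg["n_infested"].notna()
        bad = counts & (agg["n_infested"] > agg["n_sampled"])
        if bad.any():
            pairs = agg.loc[bad, ["host", "parasite"]].to_records(index=False)
            raise ValidationError(f"n_infested > n_sampled for {list(pairs)}")
        agg.loc[agg["n_infested"] > 0, "present"] = 1
        agg["present"] = agg["present"].astype(int)
        self.records = agg

    @property
    def parasites(self) -> list:
        return sorted(self.records["parasite"].unique())

    @property
    def hosts(self) -> list:
        return sorted(self.records["host"].unique())

    def hosts_of(self, parasite: str) -> list:
        """Hosts recorded as infested by ``parasite`` (sorted)."""
        parasite = normalize_label(parasite)
        sub = self.records
        sel = (sub["parasite"] == parasite) & (sub["present"] == 1)
        return sorted(sub.loc[sel, "host"])

    def presence_vector(self, parasite: str, species: Sequence[str]) -> np.ndarray:
        """0/1 response over ``species`` (absent == never recorded present)."""
        infested = set(self.hosts_of(parasite))
        return np.array([1 if s in infested else 0 for s in species], dtype=int)


def read_associations(path) -> AssociationTable:
    df = pd.read_csv(path)
    return AssociationTable(df)


def write_associations(table: AssociationTable, path) -> None:
    out = table.records.copy()
    out.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """A labelled symmetric non-negative distance matrix.

    ``scaled`` records whether the entries were divided by the maximum, so
    that off-diagonal values span [0, 1].
    """

    labels: list
    values: np.ndarray
    scaled: bool = False

    def __post_init__(self):
        self.labels = [normalize_label(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if n == 0:
            raise ValidationError("empty label list")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite distances")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValidationError("matrix is not symmetric")
        if np.abs(np.diag(self.values)).max() > 0:
            raise ValidationError("diagonal must be zero")
        if self.values.min() < 0:
            raise ValidationError("negative distances")
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.labels)

    def max_scaled(self) -> "DistanceMatrix":
        """Divide all entries by the maximum distance so values span [0, 1]."""
        m = self.values.max()
        vals = self.values / m if m > 0 else self.values.copy()
        return DistanceMatrix(list(self.labels), vals, scaled=True)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        labels = [normalize_label(l) for l in labels]
        pos = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in pos]
        if missing:
            raise ValidationError(f"labels absent from matrix: {missing}")
        ix = np.array([pos[l] for l in labels])
        return DistanceMatrix(labels, self.values[np.ix_(ix, ix)], self.scaled)

    # alias: restriction to a subset of labels is just a reorder
    submatrix = reorder

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def write_matrix(matrix: DistanceMatrix, path) -> None:
    """Write a labelled square CSV that round-trips through
    :func:`read_matrix` to < 1e-12."""
    df = matrix.to_frame()
    df.index.name = "species"
    df.to_csv(path, float_format="%.17g")


def read_matrix(path, scaled: bool = False) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float), scaled=scaled)


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

DEFAULT_LINKAGE_METHODS = (
    "single",
    "complete",
    "average",
    "weighted",
    "centroid",
    "median",
    "ward",
    "ward_squared",
)


@dataclass
class AnalysisConfig:
    """Knobs shared across the specificity and regression stages.

    The defaults reproduce the reference analysis schedule: 10,000 null
    iterations with alpha ~ U(0,1), squared-Euclidean blending (p = 2), the
    eight-member dendrogram ensemble, and a two-chain MCMC run of 2,000,000
    iterations with 1,000,000 burn-in thinned by 1,000.
    """

    seed: int = 0
    n_null_iterations: int = 10_000
    alpha_mode: str = "uniform"
    p_exponent: float = 2.0
    linkage_methods: tuple = DEFAULT_LINKAGE_METHODS
    n_chains: int = 2
    n_iter: int = 2_000_000
    burn_in: int = 1_000_000
    thin: int = 1_000
    subsample_size: int | None = None

    def __post_init__(self):
        if self.n_null_iterations < 1:
            raise ValidationError("n_null_iterations must be >= 1")
        if self.p_exponent <= 0:
            raise ValidationError("p_exponent must be > 0")
        if self.alpha_mode not in ("uniform", "grid"):
            raise ValidationError("alpha_mode must be 'uniform' or 'grid'")
        if not self.burn_in < self.n_iter:
            raise ValidationError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.subsample_size is not None and self.subsample_size < 2:
            raise ValidationError("subsample_size must be >= 2")

    @property
    def retained_draws(self) -> int:
        """chains x (iterations - burn-in) / thin."""
        return self.n_chains * ((self.n_iter - self.burn_in) // self.thin)


# ---------------------------------------------------------------------------
# Alignment across inputs
# ---------------------------------------------------------------------------


def intersect_species(
    tree: HostTree,
    traits: TraitTable,
    associations: AssociationTable | None = None,
    min_species: int = 4,
) -> list:
    """Species shared by all supplied inputs (sorted); drops are logged.

    Analyses run on the intersection, mirroring the complete-data subset of
    a compiled database; nothing is silently renamed or guessed.
    """
    sets = {"tree": set(tree.tips), "traits": set(traits.species)}
    if associations is not None:
        sets["associations"] = set(associations.hosts)
    shared = set.intersection(*sets.values())
    for name, s in sets.items():
        dropped = len(s - shared)
        if dropped:
            logger.info("intersect_species: dropping %d species only in %s", dropped, name)
    if len(shared) < min_species:
        raise ValidationError(
            f"only {len(shared)} species shared across inputs (need >= {min_species})"
        )
    return sorted(shared)
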