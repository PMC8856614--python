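"""Binary glomerular innervation profiles: data model, I/O and statistics.

A labeled neuron's innervation profile is the binary vector recording which
antennal-lobe glomeruli its processes enter. Collections of such profiles
(one row per labeled neuron, with brain/hemisphere/sex/mating metadata)
support pattern counting, innervation-frequency tables, frequency-class
assignment and hierarchical clustering with a correlation distance.
"""
from __future__ import annotations

import warnings
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConfigError, IntegrityError, SchemaError
from .glomeruli import GlomerulusMap, default_map

#: Metadata columns preceding the per-glomerulus 0/1 columns in profile tables.
METADATA_COLUMNS = ("brain_id", "hemisphere", "sex", "mating_status",
                    "genotype", "condition")

HEMISPHERES = ("L", "R")
#: Empirically observed range of innervated-glomerulus counts per neuron;
#: profiles outside it load with a warning, never an error.
TYPICAL_COUNT_RANGE = (6, 24)

#: Maximal correlation distance, assigned to zero-variance profiles.
MAX_CORR_DISTANCE = 2.0


@dataclass
class InnervationProfile:
    """One labeled neuron's binary innervation vector plus metadata.

    ``hemisphere`` follows the observer-view convention: a neuron labeled
    "R" sits in the fly's anatomical *left* hemisphere (the assignment is
    made looking at the mounted brain from the front).
    """

    brain_id: str
    hemisphere: str
    innervation: np.ndarray
    map: GlomerulusMap = field(default_factory=default_map)
    sex: str = "unknown"
    mating_status: str = "unknown"
    genotype: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        vec = np.asarray(self.innervation)
        if not np.isin(vec, (0, 1)).all():
            raise ValueError(
                f"profile ({self.brain_id}, {self.hemisphere}): innervation "
                "entries must be 0 or 1")
        if vec.shape != (len(self.map),):
            raise SchemaError(
                f"profile ({self.brain_id}, {self.hemisphere}): vector length "
                f"{vec.size} does not match map length {len(self.map)}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        self.innervation = vec.astype(np.uint8)

    def innervated_set(self) -> frozenset[str]:
        """Names of the glomeruli with value 1."""
        return frozenset(np.asarray(self.map.names)[self.innervation == 1])


class ProfileCollection:
    """A validated set of innervation profiles aligned to one glomerulus map.

    Stored as a metadata :class:`~pandas.DataFrame` plus an ``(n, G)`` uint8
    matrix; rows keep their input order. ``(brain_id, hemisphere)`` must be
    unique across the collection.
    """

    def __init__(self, map: GlomerulusMap, meta: pd.DataFrame,
                 matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix)
        if not np.isin(matrix, (0, 1)).all():
            raise ValueError("innervation matrix entries must be 0 or 1")
        if matrix.shape != (len(meta), len(map)):
            raise SchemaError("matrix shape does not match metadata/map")
        missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
        if missing:
            raise SchemaError(f"missing metadata columns: {missing}")
        key = meta[["brain_id", "hemisphere"]].astype(str)
        dup = key.duplicated()
        if dup.any():
            bad = key[dup].iloc[0]
            raise IntegrityError(
                f"duplicate (brain_id, hemisphere) = "
                f"({bad['brain_id']}, {bad['hemisphere']})")
        self.map = map
        self.meta = meta.reset_index(drop=True)
        self.matrix = matrix.astype(np.uint8)

    @classmethod
    def from_profiles(cls, profiles: Sequence[InnervationProfile],
                      map: GlomerulusMap | None = None) -> "ProfileCollection":
        if not profiles:
            raise ValueError("cannot build a collection from zero profiles")
        map = map or profiles[0].map
        meta = pd.DataFrame(
            [{c: getattr(p, c) for c in METADATA_COLUMNS} for p in profiles])
        matrix = np.stack([p.innervation for p in profiles])
        return cls(map, meta, matrix)

    def __len__(self) -> int:
        return len(self.meta)

    def __iter__(self) -> Iterator[InnervationProfile]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> InnervationProfile:
        row = self.meta.iloc[i]
        return InnervationProfile(
            brain_id=str(row["brain_id"]), hemisphere=row["hemisphere"],
            innervation=self.matrix[i], map=self.map, sex=row["sex"],
            mating_status=row["mating_status"], genotype=row["genotype"],
            condition=row["condition"])

    def subset(self, mask: np.ndarray) -> "ProfileCollection":
        mask = np.asarray(mask)
        return ProfileCollection(self.map, self.meta.loc[mask],
                                 self.matrix[mask])

    def to_frame(self) -> pd.DataFrame:
        """Long table: metadata columns then one 0/1 column per glomerulus."""
        mat = pd.DataFrame(self.matrix, columns=list(self.map.names))
        return pd.concat([self.meta.reset_index(drop=True), mat], axis=1)

    def write(self, path: str | Path) -> None:
        """Write the collection as CSV (``.tsv`` extension selects tabs)."""
        sep = "\t" if str(path).endswith(".tsv") else ","
        self.to_frame().to_csv(path, sep=sep, index=False)


def read_profiles(path: str | Path,
                  map: GlomerulusMap | None = None) -> ProfileCollection:
    """Read a profile table (CSV/TSV) into a validated collection.

    The header must contain the metadata columns plus one 0/1 column per
    glomerulus. Unknown glomerulus columns raise :class:`SchemaError`;
    non-binary cells raise ``ValueError``; duplicated (brain_id, hemisphere)
    raises :class:`IntegrityError`. Row order is preserved.
    """
    map = map or default_map()
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep, dtype={"brain_id": str})
    missing_meta = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_meta:
        raise SchemaError(f"missing metadata columns: {missing_meta}")
    glom_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    unknown = [c for c in glom_cols if c not in map]
    if unknown:
        raise SchemaError(f"columns not in glomerulus map: {unknown}")
    absent = [n for n in map.names if n not in glom_cols]
    if absent:
        raise SchemaError(f"glomerulus columns missing from table: {absent}")
    matrix = df[list(map.names)].to_numpy()
    if not np.isin(matrix, (0, 1)).all():
        raise ValueError("innervation cells must be 0 or 1")
    coll = ProfileCollection(map, df[list(METADATA_COLUMNS)], matrix)
    counts = coll.matrix.sum(axis=1)
    lo, hi = TYPICAL_COUNT_RANGE
    n_out = int(((counts < lo) | (counts > hi)).sum())
    if n_out:
        warnings.warn(
            f"{n_out} profile(s) innervate outside the typical "
            f"{lo}-{hi} glomerulus range", stacklevel=2)
    return coll


def innervation_count(profile: InnervationProfile | np.ndarray) -> int:
    """Number of innervated glomeruli (1-entries) in a profile."""
    vec = profile.innervation if isinstance(profile, InnervationProfile) \
        else np.asarray(profile)
    return int(vec.sum())


def frequency_table(collection: ProfileCollection,
                    group_by: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-glomerulus innervation frequencies, optionally stratified.

    Returns one row per (group, glomerulus) with columns ``group_label``,
    ``glomerulus``, ``count_innervated``, ``n`` and ``frequency``
    (= count/n exactly). Row order is invariant to the input row order.
    """
    if len(collection) == 0:
        raise ValueError("empty collection")
    frames = []
    if group_by:
        grouped = collection.meta.groupby(list(group_by), sort=True,
                                          observed=True).indices
        groups = [("/".join(map(str, k)) if isinstance(k, tuple) else str(k),
                   idx) for k, idx in sorted(grouped.items(), key=lambda t: str(t[0]))]
    else:
        groups = [("all", np.arange(len(collection)))]
    for label, idx in groups:
        if len(idx) == 0:
            raise ValueError(f"empty group {label!r}")
        counts = collection.matrix[idx].sum(axis=0)
        frames.append(pd.DataFrame({
            "group_label": label,
            "glomerulus": list(collection.map.names),
            "count_innervated": counts.astype(int),
            "n": len(idx),
            "frequency": counts / len(idx),
        }))
    return pd.concat(frames, ignore_index=True)


def distinct_patterns(collection: ProfileCollection
                      ) -> tuple[int, pd.DataFrame]:
    """Count unique binary innervation vectors and their multiplicities.

    Returns ``(count, table)`` where ``table`` has one row per distinct
    pattern (``pattern`` as a '0'/'1' string in map order, ``multiplicity``),
    sorted by decreasing multiplicity. Multiplicities sum to the collection
    size.
    """
    if len(collection) == 0:
        raise ValueError("empty collection")
    patterns = ["".join(map(str, row)) for row in collection.matrix]
    counts = pd.Series(patterns).value_counts()
    table = counts.rename_axis("pattern").reset_index(name="multiplicity")
    return len(table), table


#: Default frequency-class boundaries. The descriptive bins used in the
#: study (always innervated; >95%; 10-84%) do not tile [0,1], so the gaps
#: get explicit classes rather than being silently widened.
DEFAULT_CLASS_EDGES = {"rare_max": 0.10, "variable_max": 0.84,
                       "high_min": 0.95}


def classify_frequency(freq: float,
                       edges: Mapping[str, float] | None = None) -> str:
    """Assign one frequency class: always / high / variable / rare / other.

    always: f == 1; high: high_min < f < 1; variable: rare_max <= f <=
    variable_max; rare: f < rare_max; other: the (variable_max, high_min]
    gap. Edges must satisfy 0 < rare_max <= variable_max <= high_min < 1.
    """
    e = dict(DEFAULT_CLASS_EDGES, **(edges or {}))
    if not (0.0 < e["rare_max"] <= e["variable_max"] <= e["high_min"] < 1.0):
        raise ConfigError(f"overlapping or out-of-range class edges: {e}")
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency {freq} outside [0, 1]")
    if freq == 1.0:
        return "always"
    if freq > e["high_min"]:
        return "high"
    if freq < e["rare_max"]:
        return "rare"
    if freq <= e["variable_max"]:
        return "variable"
    return "other"


def classify_glomeruli(freqs: pd.DataFrame,
                       edges: Mapping[str, float] | None = None
                       ) -> dict[str, str]:
    """Frequency class per glomerulus from a :func:`frequency_table` output."""
    return {row.glomerulus: classify_frequency(row.frequency, edges)
            for row in freqs.itertuples()}


@dataclass
class ClusterResult:
    """Agglomerative clustering of profiles (or glomeruli).

    ``linkage`` is a SciPy linkage matrix over ``labels``; ``leaf_order``
    is the dendrogram leaf sequence (optimized to minimize the sum of
    adjacent-leaf distances when requested).
    """

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[int]
    distance: np.ndarray  # condensed distance vector

    def to_newick(self, digits: int = 6) -> str:
        """Export the merge tree as a Newick string; branch lengths are the
        differences between parent and child merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = round(parent_height - node.dist, digits)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length}"
            inner = ",".join(rec(c, node.dist)
                             for c in (node.left, node.right))
            return f"({inner}):{length}"

        return rec(tree, tree.dist) + ";"


def correlation_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r between rows of a binary matrix.

    Zero-variance rows (all-0 or all-1 vectors) have undefined correlation;
    they are assigned the maximal distance (2.0) to every other row, with a
    warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    degenerate = matrix.var(axis=1) == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance profile(s) assigned "
            "maximal correlation distance", stacklevel=2)
    dist = np.full((n, n), MAX_CORR_DISTANCE)
    ok = ~degenerate
    if ok.sum() >= 2:
        r = np.corrcoef(matrix[ok])
        d = np.clip(1.0 - r, 0.0, MAX_CORR_DISTANCE)
        dist[np.ix_(ok, ok)] = d
    elif ok.sum() == 1:
        i = int(np.flatnonzero(ok)[0])
        dist[i, i] = 0.0
    np.fill_diagonal(dist, 0.0)
    return dist


def cluster_profiles(collection: ProfileCollection,
                     axis: str = "profiles",
                     optimize_leaf_order: bool = False) -> ClusterResult:
    """Complete-linkage hierarchical clustering under correlation distance.

    ``axis='profiles'`` clusters neurons (rows); ``axis='glomeruli'``
    clusters glomeruli (columns). Merge heights are non-decreasing
    (complete linkage); the SciPy nearest-neighbor-chain agglomeration is
    deterministic for a fixed distance matrix.
    """
    if axis == "profiles":
        matrix = collection.matrix
        labels = [f"{b}_{h}" for b, h in zip(
            collection.meta["brain_id"], collection.meta["hemisphere"])]
    elif axis == "glomeruli":
        matrix = collection.matrix.T
        labels = list(collection.map.names)
    else:
        raise ConfigError("axis must be 'profiles' or 'glomeruli'")
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least two vectors")
    dist = correlation_distance_matrix(matrix)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    if optimize_leaf_order:
        Z = hierarchy.optimal_leaf_ordering(Z, condensed)
    order = hierarchy.leaves_list(Z)
    return ClusterResult(linkage=Z, labels=labels,
                         leaf_order=[int(i) for i in order],
                         distance=condensed)
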