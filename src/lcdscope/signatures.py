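"""Whole-proteome LCD-content signatures and organism comparison.

A proteome's LCD content is summarized as a 400-component vector of
per-residue occupancy percentages, one per LCD class, in a fixed key order
(20 primary classes then 380 secondary classes, lexicographic). Signatures
are compared by percentile rank within a cohort (midrank convention),
componentwise raw difference, and Manhattan distance — by default over the
380 secondary classes only — with group-mean distance matrices and
complete-linkage agglomerative clustering on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classes import ALL_CLASS_LABELS, secondary_class_labels
from .errors import ConsistencyError
from .stats import ClassCountTable, per_residue_occupancy

SECONDARY_LABELS = tuple(secondary_class_labels())


@dataclass
class OccupancySignature:
    """400-component per-residue-occupancy vector for one proteome."""

    proteome_id: str
    values: pd.Series  # index = ALL_CLASS_LABELS, percentages in [0, 100]
    domain_of_life: str = "Unknown"
    clade: str = ""

    def __post_init__(self) -> None:
        if tuple(self.values.index) != ALL_CLASS_LABELS:
            raise ConsistencyError("signature keys must follow the canonical "
                                   "400-class order")


def build_signature(table: ClassCountTable) -> OccupancySignature:
    """Per-class per-residue occupancy vector; absent classes are 0."""
    vals = pd.Series(
        [per_residue_occupancy(table, lbl) for lbl in ALL_CLASS_LABELS],
        index=list(ALL_CLASS_LABELS), name=table.proteome_id, dtype=float,
    )
    return OccupancySignature(table.proteome_id, vals,
                              table.domain_of_life, table.clade)


def percentile_ranks(
    sig: OccupancySignature,
    cohort: Sequence[OccupancySignature],
) -> pd.Series:
    """Per-class percentile rank of ``sig`` within ``cohort`` (self included).

    Midrank convention: 100 · (#below + 0.5 · #equal) / cohort size.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if not any(s.proteome_id == sig.proteome_id for s in cohort):
        raise ConsistencyError("signature's organism must belong to the cohort")
    mat = np.vstack([s.values.to_numpy() for s in cohort])
    v = sig.values.to_numpy()
    below = (mat < v).sum(axis=0)
    equal = (mat == v).sum(axis=0)
    ranks = 100.0 * (below + 0.5 * equal) / len(cohort)
    return pd.Series(ranks, index=list(ALL_CLASS_LABELS), name=sig.proteome_id)


def signature_difference(a: OccupancySignature, b: OccupancySignature) -> pd.Series:
    """Componentwise raw occupancy difference a − b (antisymmetric)."""
    if tuple(a.values.index) != tuple(b.values.index):
        raise ConsistencyError("signature key order mismatch")
    return a.values - b.values


def manhattan_distance(
    a: OccupancySignature,
    b: OccupancySignature,
    keys: Sequence[str] = SECONDARY_LABELS,
) -> float:
    """Manhattan distance over ``keys`` (default: the 380 secondary classes)."""
    if tuple(a.values.index) != tuple(b.values.index):
        raise ConsistencyError("signature key order mismatch")
    keys = list(keys)
    return float(np.abs(a.values[keys].to_numpy() - b.values[keys].to_numpy()).sum())


def distance_matrix(
    signatures: Sequence[OccupancySignature],
    keys: Sequence[str] = SECONDARY_LABELS,
) -> pd.DataFrame:
    """Symmetric pairwise Manhattan distance matrix over organisms."""
    ids = [s.proteome_id for s in signatures]
    mat = np.vstack([s.values[list(keys)].to_numpy() for s in signatures])
    dist = np.abs(mat[:, None, :] - mat[None, :, :]).sum(axis=2)
    return pd.DataFrame(dist, index=ids, columns=ids)


def group_mean_distances(
    signatures: Sequence[OccupancySignature],
    labels: Mapping[str, str],
    keys: Sequence[str] = SECONDARY_LABELS,
) -> pd.DataFrame:
    """Group×group mean pairwise distance; within-group means exclude
    self-pairs (NaN for singleton groups)."""
    dist = distance_matrix(signatures, keys)
    groups = sorted({labels[s.proteome_id] for s in signatures})
    members = {
        g: [s.proteome_id for s in signatures if labels[s.proteome_id] == g]
        for g in groups
    }
    out = pd.DataFrame(index=groups, columns=groups, dtype=float)
    for g1 in groups:
        for g2 in groups:
            if g1 == g2:
                ids = members[g1]
                if len(ids) < 2:
                    out.loc[g1, g2] = math.nan
                    continue
                vals = [dist.loc[i, j] for k, i in enumerate(ids)
                        for j in ids[k + 1:]]
            else:
                vals = [dist.loc[i, j] for i in members[g1] for j in members[g2]]
            out.loc[g1, g2] = float(np.mean(vals))
    return out


def complete_linkage_cluster(dist: np.ndarray | pd.DataFrame) -> list[tuple[int, int, float]]:
    """Agglomerative complete-linkage merge list.

    Input: symmetric non-negative matrix with zero diagonal over n items.
    Returns n−1 merges ``(i, j, height)`` where items are 0..n−1 and the
    cluster formed by merge k gets id n+k (scipy-style ids). Cluster-pair
    distance is the maximum over cross pairs; ties break on the smallest
    (i, j) id pair. Heights are non-decreasing.
    """
    if isinstance(dist, pd.DataFrame):
        dist = dist.to_numpy(dtype=float)
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T, atol=1e-9):
        raise ConsistencyError("distance matrix must be square and symmetric")
    if np.any(np.diag(dist) != 0) or np.any(dist < 0):
        raise ConsistencyError("distance matrix must be non-negative with a "
                               "zero diagonal")
    # cluster id -> set of leaf indices
    active: dict[int, set[int]] = {i: {i} for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        ids = sorted(active)
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                i, j = ids[x], ids[y]
                d = max(dist[a, b] for a in active[i] for b in active[j])
                key = (d, i, j)
                if best is None or key < best:
                    best = key
        d, i, j = best
        merges.append((i, j, float(d)))
        active[next_id] = active.pop(i) | active.pop(j)
        next_id += 1
    return merges


def merges_to_newick(
    merges: Sequence[tuple[int, int, float]],
    leaf_names: Sequence[str],
) -> str:
    """Render a merge list as a Newick string with ultrametric-style branch
    lengths (child branch = parent height/2 − child height/2)."""
    n = len(leaf_names)
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: str(leaf_names[i]) for i in range(n)}
    next_id = n
    for i, j, h in merges:
        bi = h / 2 - height[i] / 2
        bj = h / 2 - height[j] / 2
        node[next_id] = f"({node[i]}:{bi:.6g},{node[j]}:{bj:.6g})"
        height[next_id] = h
        next_id += 1
    return node[next_id - 1] + ";"


def signatures_to_frame(signatures: Sequence[OccupancySignature]) -> pd.DataFrame:
    """Organism × 400-class occupancy matrix with domain/clade columns."""
    rows = {s.proteome_id: s.values for s in signatures}
    df = pd.DataFrame(rows).T
    df.insert(0, "clade", [s.clade for s in signatures])
    df.insert(0, "domain_of_life", [s.domain_of_life for s in signatures])
    df.index.name = "proteome_id"
    return df
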