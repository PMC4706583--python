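"""Pairwise p-distances and taxon-level diversity summaries.

The p-distance between two aligned protein sequences is the proportion of
amino-acid sites at which they differ, among the sites that are comparable
under the gap policy.  Under *pairwise deletion* (the default) a site is
comparable for a pair iff both sequences carry a standard amino acid there —
neither a gap ``-`` nor an undetermined ``X``.  Under *complete deletion*
only columns comparable in every sequence are used for all pairs.

Diversity in a clan (a named taxon at some rank) is summarised by the
per-sequence average p-distance: for each member, the mean of its p-distances
to the other members.  The clan's record is the mean and sample SD of those
per-sequence averages — this is the quantity plotted per rank in
taxonomy-stratified heatmaps, and the observation unit fed to the variance
partition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import AlignmentShapeError, InputError
from .seqio import (
    GAP,
    MISSING_RESIDUE,
    AnnotatedSequence,
    Taxonomy,
    TaxonomyNode,
)

logger = logging.getLogger(__name__)

GapPolicy = Literal["pairwise", "complete"]


@dataclass
class PDistanceMatrix:
    """Symmetric matrix of pairwise p-distances with comparable-site counts.

    ``p[i, j]`` is NaN for pairs with zero comparable sites; such pairs are
    also listed in ``flagged_pairs``.
    """

    ids: list[str]
    p: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if self.p.shape != (n, n) or self.comparable_sites.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        self._index = {acc: i for i, acc in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def flagged_pairs(self) -> list[tuple[str, str]]:
        iu, ju = np.triu_indices(self.n, k=1)
        bad = np.isnan(self.p[iu, ju])
        return [(self.ids[i], self.ids[j]) for i, j in zip(iu[bad], ju[bad])]

    def loc(self, a: str, b: str) -> float:
        return float(self.p[self._index[a], self._index[b]])

    def submatrix(self, members: Sequence[str]) -> "PDistanceMatrix":
        idx = [self._index[m] for m in members]
        return PDistanceMatrix(
            list(members),
            self.p[np.ix_(idx, idx)],
            self.comparable_sites[np.ix_(idx, idx)],
        )

    def to_phylip(self, path: str | Path) -> None:
        """Write a PHYLIP-style square distance file (tab-delimited)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, acc in enumerate(self.ids):
                row = "\t".join(f"{v:.6f}" for v in self.p[i])
                fh.write(f"{acc}\t{row}\n")

    @classmethod
    def from_phylip(cls, path: str | Path) -> "PDistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1 : n + 1]])
        p = np.asarray(rows, dtype=float)
        return cls(ids, p, np.full((n, n), -1, dtype=int))


@dataclass(frozen=True)
class GroupSummary:
    """Diversity record for one clan: n, mean and SD of per-sequence averages."""

    rank: str
    taxon: str
    n: int
    mean_p: float | None
    sd_p: float | None

    @property
    def available(self) -> bool:
        return self.mean_p is not None


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t comparison of two clans' per-sequence average distances."""

    t: float
    df: float
    p_value: float
    method: Literal["welch", "pooled"]


# ---------------------------------------------------------------------------
# Core distance computation

_GAP_ORD = ord(GAP)
_X_ORD = ord(MISSING_RESIDUE)


def _encode(residues: Iterable[str]) -> np.ndarray:
    """Encode aligned residue strings as a (n, L) uint8 matrix."""
    seqs = list(residues)
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


def _valid_mask(arr: np.ndarray) -> np.ndarray:
    return (arr != _GAP_ORD) & (arr != _X_ORD)


def p_distance(
    a: str, b: str, policy: GapPolicy = "pairwise"
) -> tuple[float, int]:
    """p-distance between two aligned sequences.

    Returns ``(p, m)`` where ``m`` is the comparable-site count.  When
    ``m == 0`` the distance is undefined and ``p`` is NaN (no exception).
    """
    if len(a) != len(b):
        raise AlignmentShapeError(
            f"sequences have unequal lengths {len(a)} and {len(b)}"
        )
    arr = _encode([a.upper(), b.upper()])
    valid = _valid_mask(arr)
    both = valid[0] & valid[1]
    m = int(both.sum())
    if m == 0:
        return float("nan"), 0
    diffs = int(((arr[0] != arr[1]) & both).sum())
    return diffs / m, m


def distance_matrix(
    seqs: Sequence[AnnotatedSequence], policy: GapPolicy = "pairwise"
) -> PDistanceMatrix:
    """All-pairs p-distance matrix under the given gap policy."""
    if len(seqs) < 2:
        raise InputError("distance_matrix needs at least 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentShapeError(f"mixed aligned lengths: {sorted(lengths)}")
    if policy not in ("pairwise", "complete"):
        raise InputError(f"unknown gap policy {policy!r}")

    arr = _encode(s.residues for s in seqs)
    valid = _valid_mask(arr)
    if policy == "complete":
        cols = valid.all(axis=0)
        arr, valid = arr[:, cols], valid[:, cols]

    n = arr.shape[0]
    m = valid.astype(np.int64) @ valid.T.astype(np.int64)
    diffs = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        diffs[i] = ((arr[i] != arr) & valid[i] & valid).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(m > 0, diffs / np.maximum(m, 1), np.nan)
    np.fill_diagonal(p, 0.0)

    out = PDistanceMatrix([s.accession for s in seqs], p, m)
    if out.flagged_pairs:
        logger.warning(
            "%d sequence pairs have no comparable sites", len(out.flagged_pairs)
        )
    return out


# ---------------------------------------------------------------------------
# Group summaries


def per_sequence_average(
    matrix: PDistanceMatrix, members: Iterable[str]
) -> dict[str, float]:
    """Mean p-distance of each member against the other members.

    Pairs with undefined distance are excluded from the mean with a warning.
    A member set smaller than 2 yields an empty result (the "blank" cells of
    per-rank heatmaps).
    """
    members = sorted(members)
    if len(members) < 2:
        logger.warning("per_sequence_average: fewer than 2 members, no averages")
        return {}
    sub = matrix.submatrix(members).p.copy()
    np.fill_diagonal(sub, np.nan)
    n_undef = int(np.isnan(sub).sum() - len(members))
    if n_undef > 0:
        logger.warning(
            "per_sequence_average: excluding %d undefined pairs", n_undef // 2
        )
    with np.errstate(invalid="ignore"):
        avgs = np.nanmean(sub, axis=1)
    return {acc: float(v) for acc, v in zip(members, avgs) if not math.isnan(v)}


def group_summary(matrix: PDistanceMatrix, node: TaxonomyNode) -> GroupSummary:
    """Diversity summary of one clan (mean ± SD of per-sequence averages)."""
    averages = per_sequence_average(matrix, node.members)
    n = len(node.members)
    if not averages:
        return GroupSummary(node.rank, node.name, n, None, None)
    vals = np.array(list(averages.values()))
    sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
    return GroupSummary(node.rank, node.name, n, float(vals.mean()), sd)


def rank_table(
    matrix: PDistanceMatrix, taxonomy: Taxonomy, rank: str
) -> list[GroupSummary]:
    """One :class:`GroupSummary` per clan at the given rank.

    Clans with fewer than 2 members are emitted with blank statistics so that
    every rank partitions the full dataset.
    """
    return [group_summary(matrix, node) for node in taxonomy.nodes_at_rank(rank)]


def rank_tables_frame(
    matrix: PDistanceMatrix, taxonomy: Taxonomy, ranks: Iterable[str]
) -> pd.DataFrame:
    """Stack rank tables for several ranks into one tidy DataFrame."""
    rows = [
        {
            "rank": s.rank.rstrip("_"),
            "taxon": s.taxon,
            "n": s.n,
            "mean_p": s.mean_p,
            "sd_p": s.sd_p,
        }
        for rank in ranks
        for s in rank_table(matrix, taxonomy, rank)
    ]
    return pd.DataFrame(rows, columns=["rank", "taxon", "n", "mean_p", "sd_p"])


# ---------------------------------------------------------------------------
# Group comparison


def compare_groups(
    s1: GroupSummary, s2: GroupSummary, method: Literal["welch", "pooled"] = "welch"
) -> GroupComparison:
    """Two-sample t test from clan summary statistics.

    Welch (default) uses the Satterthwaite degrees of freedom; the pooled
    variant assumes equal variances.  With zero variance in both groups and
    equal means the result is t=0, p=1.
    """
    for s in (s1, s2):
        if s.n < 2 or s.mean_p is None or s.sd_p is None:
            raise InputError("compare_groups needs n >= 2 and defined mean/sd")
    diff = s1.mean_p - s2.mean_p
    v1, v2 = s1.sd_p**2, s2.sd_p**2
    if method == "welch":
        se2 = v1 / s1.n + v2 / s2.n
        if se2 == 0:
            return GroupComparison(0.0, float(s1.n + s2.n - 2), 1.0, method)
        df = se2**2 / (
            (v1 / s1.n) ** 2 / (s1.n - 1) + (v2 / s2.n) ** 2 / (s2.n - 1)
        )
    elif method == "pooled":
        df = s1.n + s2.n - 2
        sp2 = ((s1.n - 1) * v1 + (s2.n - 1) * v2) / df
        se2 = sp2 * (1 / s1.n + 1 / s2.n)
        if se2 == 0:
            return GroupComparison(0.0, float(df), 1.0, method)
    else:
        raise InputError(f"unknown method {method!r}")
    t = diff / math.sqrt(se2)
    p = 2 * float(stats.t.sf(abs(t), df))
    return GroupComparison(t, float(df), p, method)
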