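"""Inter-/intra-clan variance partitioning by unequal-size model II ANOVA.

The model
---------

At a taxonomy bifurcation, the member sequences of a node split into k clans
(its child taxa) with sizes n_1..n_k, N = Σ n_i.  Each sequence carries one
observation y_ij — by default its average p-distance to the other members of
the node.  The one-way random-effects (model II) layout

    y_ij = μ + A_i + e_ij,   A_i ~ (0, σ²_A),  e_ij ~ (0, σ²_W)

treats the clans as a random sample of taxa.  With unequal sizes the
among-clan mean square estimates σ²_W + n0·σ²_A where

    n0 = (N − Σ n_i²/N) / (k − 1)

so the variance components are

    σ²_W = MS_within,    σ²_A = max(0, (MS_among − MS_within) / n0)

and the partition reported per node is

    inter-clan % = 100·σ²_A / (σ²_A + σ²_W),   intra-clan % = 100 − inter.

A large inter-clan share means diversity accumulates *across* the taxonomic
boundary at that node — the signature read as horizontal transfer propensity —
while a large intra-clan share means diversity stays within clans (vertical
descent).

The entry point is :class:`ClanVarianceModel`, a statsmodels-style model:
build it from observations and clan labels (or a DataFrame), call
:meth:`~ClanVarianceModel.fit`, and read the components off the returned
:class:`ClanVarianceResults` (or print ``results.summary()``).
:func:`partition_lineage` fits one model per eligible taxonomy bifurcation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import InputError
from .distances import PDistanceMatrix, per_sequence_average
from .seqio import Taxonomy, TaxonomyNode

logger = logging.getLogger(__name__)

#: Ranks at which bifurcations are partitioned (children: phylum .. genus).
DEFAULT_PARTITION_RANKS = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class_",
    "order",
    "family",
)


class ClanVarianceModel:
    """One-way random-effects ANOVA of clan-structured observations.

    Parameters
    ----------
    values:
        Observations y_ij, one per sequence.
    clans:
        Clan label for each observation, aligned with ``values``.

    Preconditions (checked at ``fit``): at least two clans, N > k, and at
    least one clan with two or more members so the within mean square has
    degrees of freedom.  Violations raise :class:`InputError`; pipeline
    callers catch this and record the node as "not available".
    """

    def __init__(self, values: Sequence[float], clans: Sequence[str]):
        self.values = np.asarray(values, dtype=float)
        self.clans = np.asarray(clans, dtype=object)
        if self.values.shape != self.clans.shape or self.values.ndim != 1:
            raise InputError("values and clans must be equal-length 1-D")
        if np.isnan(self.values).any():
            raise InputError("NaN observations are not allowed")

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, value_col: str = "value", clan_col: str = "clan"
    ) -> "ClanVarianceModel":
        return cls(data[value_col].to_numpy(), data[clan_col].to_numpy())

    @classmethod
    def from_mappings(
        cls, values: Mapping[str, float], clans: Mapping[str, str]
    ) -> "ClanVarianceModel":
        """Build from accession-keyed maps, as the pipeline stages produce."""
        keys = sorted(values)
        missing = [k for k in keys if k not in clans]
        if missing:
            raise InputError(f"no clan label for {missing[:5]}")
        return cls([values[k] for k in keys], [clans[k] for k in keys])

    def fit(self) -> "ClanVarianceResults":
        labels, inverse = np.unique(self.clans, return_inverse=True)
        k = len(labels)
        sizes = np.bincount(inverse)
        N = int(sizes.sum())
        if k < 2:
            raise InputError("need at least 2 clans")
        if N <= k:
            raise InputError("need N > k observations")
        if (sizes < 2).all():
            raise InputError("need at least one clan with n_i >= 2")

        grand = self.values.mean()
        group_means = np.array(
            [self.values[inverse == i].mean() for i in range(k)]
        )
        ss_among = float(np.sum(sizes * (group_means - grand) ** 2))
        ss_within = float(
            np.sum((self.values - group_means[inverse]) ** 2)
        )
        df_among, df_within = k - 1, N - k
        ms_among = ss_among / df_among
        ms_within = ss_within / df_within
        n0 = (N - float(np.sum(sizes**2)) / N) / (k - 1)
        sigma2_among = max(0.0, (ms_among - ms_within) / n0)
        sigma2_within = ms_within
        total = sigma2_among + sigma2_within
        pct_inter = 100.0 * sigma2_among / total if total > 0 else 0.0
        return ClanVarianceResults(
            clan_labels=[str(x) for x in labels],
            sizes=[int(s) for s in sizes],
            k=k,
            N=N,
            ss_among=ss_among,
            ss_within=ss_within,
            df_among=df_among,
            df_within=df_within,
            ms_among=ms_among,
            ms_within=ms_within,
            n0=n0,
            sigma2_among=sigma2_among,
            sigma2_within=sigma2_within,
            pct_inter=pct_inter,
            pct_intra=100.0 - pct_inter,
        )


@dataclass(frozen=True)
class ClanVarianceResults:
    """Fitted variance components of a :class:`ClanVarianceModel`."""

    clan_labels: list[str]
    sizes: list[int]
    k: int
    N: int
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    ms_among: float
    ms_within: float
    n0: float
    sigma2_among: float
    sigma2_within: float
    pct_inter: float
    pct_intra: float

    def summary(self) -> str:
        lines = [
            "Inter-/intra-clan variance partition (model II ANOVA)",
            "=" * 56,
            f"clans (k): {self.k}    observations (N): {self.N}",
            f"clan sizes: {self.sizes}",
            f"{'source':<12}{'df':>6}{'SS':>14}{'MS':>14}",
            f"{'among':<12}{self.df_among:>6}{self.ss_among:>14.6f}"
            f"{self.ms_among:>14.6f}",
            f"{'within':<12}{self.df_within:>6}{self.ss_within:>14.6f}"
            f"{self.ms_within:>14.6f}",
            f"n0 (effective clan size): {self.n0:.4f}",
            f"sigma2 among: {self.sigma2_among:.6f}    "
            f"sigma2 within: {self.sigma2_within:.6f}",
            f"inter-clan: {self.pct_inter:.2f} %    "
            f"intra-clan: {self.pct_intra:.2f} %",
        ]
        return "\n".join(lines)


def partition(
    values: Mapping[str, float] | Sequence[float],
    clans: Mapping[str, str] | Sequence[str],
) -> ClanVarianceResults:
    """Functional wrapper: fit a :class:`ClanVarianceModel` in one call."""
    if isinstance(values, Mapping):
        model = ClanVarianceModel.from_mappings(values, clans)
    else:
        model = ClanVarianceModel(values, clans)
    return model.fit()


@dataclass(frozen=True)
class NodePartition:
    """Variance partition (or the reason it is unavailable) at one node."""

    rank: str
    taxon: str
    child_rank: str
    results: ClanVarianceResults | None
    status: str  # "ok" or the reason the node was skipped


def partition_lineage(
    matrix: PDistanceMatrix,
    taxonomy: Taxonomy,
    ranks: Iterable[str] = DEFAULT_PARTITION_RANKS,
    observation: Literal["per_sequence_average", "pairwise"] = (
        "per_sequence_average"
    ),
) -> list[NodePartition]:
    """Fit the variance partition at every eligible taxonomy bifurcation.

    For each node at the given ranks with >= 2 children, the clans are the
    node's children and the default observation for each member sequence is
    its average p-distance within the node's member set (computed node-
    locally).  The non-default ``observation="pairwise"`` uses the raw
    within-clan/among-clan pairwise structure's per-pair distances, labelling
    each unordered within-node pair that falls inside a single clan by that
    clan — pairs spanning two clans are dropped; such pairwise observations
    are not independent, which is why this variant is not the default.
    Nodes failing the model preconditions are reported with their reason.
    """
    from .seqio import RANKS

    wanted = {r if r in RANKS else r + "_" for r in ranks}
    out: list[NodePartition] = []
    for node in taxonomy.walk():
        if node.rank not in wanted:
            continue
        children = node.child_list()
        child_rank = children[0].rank.rstrip("_") if children else "?"
        if len(children) < 2:
            out.append(
                NodePartition(
                    node.rank.rstrip("_"), node.name, child_rank, None,
                    "fewer than 2 clans",
                )
            )
            continue
        try:
            if observation == "per_sequence_average":
                values = per_sequence_average(matrix, node.members)
                if len(values) < len(node.members):
                    raise InputError("undefined per-sequence averages")
                clan_of = {
                    acc: child.name
                    for child in children
                    for acc in child.members
                }
                results = ClanVarianceModel.from_mappings(values, clan_of).fit()
            elif observation == "pairwise":
                vals, labs = [], []
                for child in children:
                    sub = matrix.submatrix(sorted(child.members)).p
                    iu, ju = np.triu_indices(sub.shape[0], k=1)
                    for v in sub[iu, ju]:
                        if not np.isnan(v):
                            vals.append(float(v))
                            labs.append(child.name)
                results = ClanVarianceModel(vals, labs).fit()
            else:
                raise InputError(f"unknown observation unit {observation!r}")
            out.append(
                NodePartition(
                    node.rank.rstrip("_"), node.name, child_rank, results, "ok"
                )
            )
        except InputError as exc:
            logger.debug("skipping node %s (%s): %s", node.name, node.rank, exc)
            out.append(
                NodePartition(
                    node.rank.rstrip("_"), node.name, child_rank, None, str(exc)
                )
            )
    return out


def partitions_frame(parts: list[NodePartition]) -> pd.DataFrame:
    """Tidy table of per-node partitions (one row per taxonomy node)."""
    rows = []
    for p in parts:
        r = p.results
        rows.append(
            {
                "rank": p.rank,
                "taxon": p.taxon,
                "child_rank": p.child_rank,
                "status": p.status,
                "k": r.k if r else None,
                "N": r.N if r else None,
                "sizes": ",".join(map(str, r.sizes)) if r else None,
                "n0": r.n0 if r else None,
                "ms_among": r.ms_among if r else None,
                "ms_within": r.ms_within if r else None,
                "sigma2_among": r.sigma2_among if r else None,
                "pct_inter": r.pct_inter if r else None,
                "pct_intra": r.pct_intra if r else None,
            }
        )
    cols = [
        "rank", "taxon", "child_rank", "status", "k", "N", "sizes", "n0",
        "ms_among", "ms_within", "sigma2_among", "pct_inter", "pct_intra",
    ]
    return pd.DataFrame(rows, columns=cols)
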