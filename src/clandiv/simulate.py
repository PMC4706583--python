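"""Synthetic aligned protein families over a known taxonomy.

The generator grows a taxonomy (superkingdom → ... → genus → organisms) with
configurable, possibly uneven, branching, then evolves a root protein
sequence down that tree under a 20-state equal-rates substitution model (the
amino-acid analogue of Jukes–Cantor): along a branch carrying d expected
substitutions per site, each site differs from its parent with probability

    P(diff | d) = (19/20) (1 − exp(−(20/19) d))

and a differing site takes a uniformly chosen other residue.  Because this is
the exact transition kernel of the model, expected pairwise p-distance between
two leaves is ``expected_p`` of their total path length — the closed form the
calibration tests lean on.  The model has no indels, no rate heterogeneity
and no selection; gaps for exercising the pairwise-deletion policy are
introduced afterwards by :func:`mask_gaps`.

Optional horizontal-transfer events replace a recipient leaf's sequence with
a copy of a donor from a different clan plus a little extra divergence,
planting the mixed-clan signal that depresses inter-clan variance and
entangles clans in the tree.

Default configuration
---------------------

:func:`SimulationConfig.default` emulates a small prokaryote-like protein
family: one superkingdom, two phyla, uneven numbers of classes through
genera, and per-rank divergences placed so that clan-mean p-distances fall
in roughly the 0.3–0.8 band typical of deep protein-family datasets.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._errors import ConfigError
from .seqio import RANKS, AnnotatedSequence, Lineage

AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

#: Ranks below superkingdom on which branching/divergence are configured.
BRANCH_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "organism")


def expected_p(d: float) -> float:
    """Expected p-distance after d substitutions/site under the 20-state model.

    Strictly increasing in d, asymptote 19/20.
    """
    if d < 0:
        raise ConfigError(f"divergence must be >= 0, got {d}")
    return (19.0 / 20.0) * (1.0 - math.exp(-(20.0 / 19.0) * d))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic family.

    ``branching[rank]`` is the (min, max) number of children per node at that
    rank (inclusive range; equal values mean a fixed count); for "organism"
    it is the number of leaf sequences per genus.  ``rate_per_rank[rank]``
    is the expected substitutions per site d on branches leading *into*
    nodes of that rank; the leaf branch uses the "organism" entry.
    """

    seq_length: int = 600
    branching: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "kingdom": (1, 1),
            "phylum": (2, 2),
            "class": (2, 4),
            "order": (1, 3),
            "family": (1, 2),
            "genus": (1, 3),
            "organism": (1, 4),
        }
    )
    rate_per_rank: dict[str, float] = field(
        default_factory=lambda: {
            "kingdom": 0.0,
            "phylum": 0.25,
            "class": 0.15,
            "order": 0.10,
            "family": 0.10,
            "genus": 0.08,
            "organism": 0.15,
        }
    )
    hgt_events: int = 0
    hgt_rank: str = "phylum"
    hgt_extra_divergence: float = 0.02
    superkingdom: str = "Synthibacteria"
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0) -> "SimulationConfig":
        return cls(seed=seed)

    def validate(self) -> None:
        if self.seq_length < 1:
            raise ConfigError("seq_length must be >= 1")
        for rank in BRANCH_RANKS:
            if rank not in self.branching:
                raise ConfigError(f"branching missing rank {rank!r}")
            lo, hi = self.branching[rank]
            if not (1 <= lo <= hi):
                raise ConfigError(f"bad branching range for {rank!r}: {lo, hi}")
            if rank not in self.rate_per_rank:
                raise ConfigError(f"rate_per_rank missing rank {rank!r}")
            if self.rate_per_rank[rank] < 0:
                raise ConfigError(f"negative divergence at rank {rank!r}")
        if self.hgt_events < 0:
            raise ConfigError("hgt_events must be >= 0")
        if self.hgt_rank not in BRANCH_RANKS[:-1]:
            raise ConfigError(f"bad hgt_rank {self.hgt_rank!r}")


@dataclass
class TruthRecord:
    """What the generator actually did: branch divergences and HGT events."""

    config: SimulationConfig
    n_sequences: int
    branch_divergence: dict[str, float]
    hgt: list[dict[str, str]]
    clan_counts: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "n_sequences": self.n_sequences,
            "branch_divergence": self.branch_divergence,
            "hgt": self.hgt,
            "clan_counts": self.clan_counts,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _evolve(parent: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of the 20-state equal-rates model (exact transition kernel)."""
    child = parent.copy()
    if d == 0:
        return child
    p_diff = expected_p(d)
    hit = rng.random(parent.shape[0]) < p_diff
    idx = np.nonzero(hit)[0]
    if idx.size:
        # uniformly one of the 19 other residues
        cur = np.searchsorted(AMINO_ACIDS, parent[idx])
        offset = rng.integers(1, 20, size=idx.size)
        child[idx] = AMINO_ACIDS[(cur + offset) % 20]
    return child


def simulate_family(
    cfg: SimulationConfig,
) -> tuple[list[AnnotatedSequence], dict[str, Lineage], TruthRecord]:
    """Generate an aligned family, its lineage table and a truth record.

    Fully deterministic for a fixed ``cfg.seed``: taxonomy sampling, sequence
    evolution and HGT placement all derive from one seeded generator.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    root = rng.choice(AMINO_ACIDS, size=cfg.seq_length)
    seqs: list[AnnotatedSequence] = []
    lineages: dict[str, Lineage] = {}
    branch_div: dict[str, float] = {}
    clan_counts: dict[str, int] = {}

    def descend(rank_idx: int, parent_seq: np.ndarray, names: list[str]) -> None:
        rank = BRANCH_RANKS[rank_idx]
        lo, hi = cfg.branching[rank]
        n_children = int(rng.integers(lo, hi + 1))
        for c in range(1, n_children + 1):
            d = cfg.rate_per_rank[rank]
            child_seq = _evolve(parent_seq, d, rng)
            if rank == "organism":
                acc = f"SYN{len(seqs) + 1:05d}"
                organism = f"{names[-1]} sp. {c}"
                fields = dict(zip(RANKS, [cfg.superkingdom] + names + [organism]))
                # prokaryote-style lineage: drop the kingdom rank when the
                # config does not actually branch on it
                if cfg.branching["kingdom"] == (1, 1):
                    fields["kingdom"] = None
                lineages[acc] = Lineage(**fields)
                seqs.append(
                    AnnotatedSequence(
                        acc, child_seq.tobytes().decode("ascii"), lineages[acc]
                    )
                )
                branch_div[acc] = d
            else:
                name = f"{names[-1]}.{rank[0].upper()}{c}" if names else f"K{c}"
                branch_div[name] = d
                clan_counts[rank] = clan_counts.get(rank, 0) + 1
                descend(rank_idx + 1, child_seq, names + [name])

    descend(0, root, [])

    hgt_log: list[dict[str, str]] = []
    if cfg.hgt_events:
        clan_idx = BRANCH_RANKS.index(cfg.hgt_rank)
        clan_of = {
            s.accession: s.lineage.as_tuple()[clan_idx + 1] for s in seqs
        }
        distinct = sorted(set(clan_of.values()))
        if len(distinct) < 2:
            raise ConfigError(
                f"hgt needs >= 2 clans at rank {cfg.hgt_rank!r}, found {len(distinct)}"
            )
        accs = [s.accession for s in seqs]
        touched: set[str] = set()  # recipients so far (their sequences changed)
        for _ in range(cfg.hgt_events):
            # distinct recipients, and donors untouched by earlier events, so
            # every logged event stays verifiable on the final alignment
            candidates = [a for a in accs if a not in touched]
            if not candidates:
                raise ConfigError("too many hgt_events for the family size")
            recipient = candidates[int(rng.integers(len(candidates)))]
            donors = [
                a
                for a in accs
                if clan_of[a] != clan_of[recipient] and a not in touched
            ]
            if not donors:
                raise ConfigError("no untouched donor clan member left")
            donor = donors[int(rng.integers(len(donors)))]
            touched.add(recipient)
            donor_seq = next(s for s in seqs if s.accession == donor)
            arr = np.frombuffer(
                donor_seq.residues.encode("ascii"), dtype=np.uint8
            )
            transferred = _evolve(arr, cfg.hgt_extra_divergence, rng)
            for i, s in enumerate(seqs):
                if s.accession == recipient:
                    seqs[i] = AnnotatedSequence(
                        recipient,
                        transferred.tobytes().decode("ascii"),
                        s.lineage,
                    )
                    break
            hgt_log.append({"donor": donor, "recipient": recipient})

    truth = TruthRecord(cfg, len(seqs), branch_div, hgt_log, clan_counts)
    return seqs, lineages, truth


def mask_gaps(
    seqs: Sequence[AnnotatedSequence], fraction: float, seed: int = 0
) -> list[AnnotatedSequence]:
    """Replace a seeded random subset of residues with gaps.

    Each residue independently becomes '-' with probability ``fraction``, so
    a pair's expected comparable-site count is L(1 − fraction)².
    """
    if not 0 <= fraction < 1:
        raise ConfigError("gap fraction must be in [0, 1)")
    if fraction == 0:
        return list(seqs)
    rng = np.random.default_rng(seed)
    out = []
    for s in seqs:
        arr = np.frombuffer(s.residues.encode("ascii"), dtype=np.uint8).copy()
        arr[rng.random(arr.size) < fraction] = ord("-")
        out.append(
            AnnotatedSequence(s.accession, arr.tobytes().decode("ascii"), s.lineage)
        )
    return out
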