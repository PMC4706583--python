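"""Aligned-FASTA and taxonomic-lineage I/O, deduplication and taxonomy building.

The data model is a flat list of :class:`AnnotatedSequence` records — one
aligned protein sequence plus its eight-rank taxonomic lineage (superkingdom,
kingdom, phylum, class, order, family, genus, organism) — and a
:class:`Taxonomy` tree built from those lineages, whose internal nodes are the
"clans" (named taxa at a given rank) that downstream diversity summaries and
variance partitions operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._errors import AlignmentShapeError, InputError

logger = logging.getLogger(__name__)

#: Canonical rank names, outermost first.  "class_" avoids the keyword; the
#: external (TSV header) spelling is "class".
RANKS = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class_",
    "order",
    "family",
    "genus",
    "organism",
)

#: Header spellings used in lineage TSV files, same order as RANKS.
RANK_HEADERS = tuple(r.rstrip("_") for r in RANKS)

#: Values in a lineage TSV cell that mean "rank not documented".
MISSING_TOKENS = frozenset({"", "NA"})

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
MISSING_RESIDUE = "X"


@dataclass(frozen=True)
class Lineage:
    """One eight-rank taxonomic path; absent ranks are ``None``."""

    superkingdom: str | None = None
    kingdom: str | None = None
    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None
    organism: str | None = None

    def rank(self, name: str) -> str | None:
        return getattr(self, name if name in RANKS else name + "_")

    def as_tuple(self) -> tuple[str | None, ...]:
        return tuple(getattr(self, r) for r in RANKS)

    def is_complete(self, require_kingdom: bool | None = None) -> bool:
        """Whether every rank is documented.

        UniProt-style lineages give no kingdom for archaea and bacteria, so by
        default the kingdom rank is required only when the superkingdom is
        Eukaryota.  ``require_kingdom=True`` demands all eight ranks;
        ``require_kingdom=False`` never requires kingdom.
        """
        for r in RANKS:
            if r == "kingdom":
                continue
            if not getattr(self, r):
                return False
        if require_kingdom is None:
            require_kingdom = (self.superkingdom or "").lower() == "eukaryota"
        return bool(self.kingdom) or not require_kingdom


@dataclass(frozen=True)
class AnnotatedSequence:
    """An aligned protein sequence with its accession and lineage."""

    accession: str
    residues: str
    lineage: Lineage | None = None

    def __post_init__(self):
        if not self.residues:
            raise InputError(f"{self.accession}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def with_lineage(self, lineage: Lineage) -> "AnnotatedSequence":
        return replace(self, lineage=lineage)


@dataclass
class TaxonomyNode:
    """A clan: a named taxon at a given rank, with child clans and members."""

    rank: str
    name: str
    parent: "TaxonomyNode | None" = None
    children: dict[str, "TaxonomyNode"] = field(default_factory=dict)
    members: set[str] = field(default_factory=set)

    @property
    def path(self) -> tuple[str, ...]:
        node, parts = self, []
        while node is not None:
            parts.append(node.name)
            node = node.parent
        return tuple(reversed(parts))

    def child_list(self) -> list["TaxonomyNode"]:
        return [self.children[k] for k in sorted(self.children)]

    def walk(self) -> Iterator["TaxonomyNode"]:
        yield self
        for child in self.child_list():
            yield from child.walk()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TaxonomyNode({self.rank}={self.name!r}, n={len(self.members)})"


@dataclass
class Taxonomy:
    """Forest of per-superkingdom taxonomy trees."""

    roots: list[TaxonomyNode]

    def walk(self) -> Iterator[TaxonomyNode]:
        for root in self.roots:
            yield from root.walk()

    def nodes_at_rank(self, rank: str) -> list[TaxonomyNode]:
        rank = rank if rank in RANKS else rank + "_"
        return [n for n in self.walk() if n.rank == rank]

    @property
    def size(self) -> int:
        return sum(len(r.members) for r in self.roots)


# ---------------------------------------------------------------------------
# Alignment I/O


def read_alignment(path: str | Path) -> list[AnnotatedSequence]:
    """Read an aligned FASTA file into :class:`AnnotatedSequence` records.

    Gap characters are retained and record order is preserved.  Raises
    :class:`AlignmentShapeError` when records have unequal lengths and
    :class:`InputError` on duplicate accessions or an empty file.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records")
    seqs: list[AnnotatedSequence] = []
    seen: set[str] = set()
    length = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != length:
            raise AlignmentShapeError(
                f"{path}: record {rec.id} has length {len(rec.seq)}, "
                f"expected {length}"
            )
        if rec.id in seen:
            raise InputError(f"{path}: duplicate accession {rec.id}")
        seen.add(rec.id)
        seqs.append(AnnotatedSequence(rec.id, str(rec.seq).upper()))
    return seqs


def write_alignment(seqs: Iterable[AnnotatedSequence], path: str | Path) -> None:
    """Write aligned sequences as normalized FASTA (one line per sequence)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.accession, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# Lineage tables


def read_lineages(path: str | Path) -> dict[str, Lineage]:
    """Read a tab-separated lineage table into a map accession -> Lineage.

    The header must contain an ``accession`` column; rank columns use the
    spellings in :data:`RANK_HEADERS`.  Empty cells and ``NA`` are absent
    ranks; unknown columns are ignored with a warning.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise InputError(f"{path}: empty lineage table")
        header = header_line.split("\t")
        if "accession" not in header:
            raise InputError(f"{path}: lineage table lacks an accession column")
        known = {"accession", *RANK_HEADERS}
        for col in header:
            if col not in known:
                logger.warning("%s: ignoring unknown lineage column %r", path, col)
        idx = {col: i for i, col in enumerate(header) if col in known}

        out: dict[str, Lineage] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")

            def cell(col: str) -> str | None:
                i = idx.get(col)
                if i is None or i >= len(cells):
                    return None
                value = cells[i].strip()
                return None if value in MISSING_TOKENS else value

            acc = cell("accession")
            if acc is None:
                raise InputError(f"{path}:{lineno}: row without accession")
            out[acc] = Lineage(
                **{r: cell(h) for r, h in zip(RANKS, RANK_HEADERS)}
            )
    return out


def write_lineages(lineages: dict[str, Lineage], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\t" + "\t".join(RANK_HEADERS) + "\n")
        for acc in lineages:
            vals = [v or "" for v in lineages[acc].as_tuple()]
            fh.write(acc + "\t" + "\t".join(vals) + "\n")


def attach_lineages(
    seqs: Iterable[AnnotatedSequence], lineages: dict[str, Lineage]
) -> list[AnnotatedSequence]:
    """Attach lineages by accession; sequences without an entry keep ``None``."""
    return [
        s.with_lineage(lineages[s.accession]) if s.accession in lineages else s
        for s in seqs
    ]


# ---------------------------------------------------------------------------
# Filters


def dedup_identical(seqs: list[AnnotatedSequence]) -> list[AnnotatedSequence]:
    """Drop sequences whose full residue string (gaps included) repeats.

    The first occurrence wins and input order is preserved, so the operation
    is idempotent and stable.
    """
    seen: set[str] = set()
    kept = []
    for s in seqs:
        key = s.residues.upper()
        if key not in seen:
            seen.add(key)
            kept.append(s)
    if len(kept) < len(seqs):
        logger.info("dedup_identical: %d -> %d sequences", len(seqs), len(kept))
    return kept


def filter_complete_lineage(
    seqs: list[AnnotatedSequence], require_kingdom: bool | None = None
) -> tuple[list[AnnotatedSequence], list[AnnotatedSequence]]:
    """Split sequences into (complete lineage, incomplete lineage).

    ``require_kingdom`` follows :meth:`Lineage.is_complete`: by default the
    kingdom rank is mandatory only for eukaryotes, mirroring how public
    protein databases document prokaryotic lineages.
    """
    kept, dropped = [], []
    for s in seqs:
        if s.lineage is not None and s.lineage.is_complete(require_kingdom):
            kept.append(s)
        else:
            dropped.append(s)
    for sk, n in sorted(superkingdom_counts(kept).items()):
        logger.info("complete lineages in %s: %d", sk, n)
    return kept, dropped


def superkingdom_counts(seqs: Iterable[AnnotatedSequence]) -> dict[str, int]:
    """Bookkeeping: number of sequences per superkingdom."""
    counts: dict[str, int] = {}
    for s in seqs:
        sk = (s.lineage.superkingdom if s.lineage else None) or "<none>"
        counts[sk] = counts.get(sk, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Taxonomy


def build_taxonomy(seqs: list[AnnotatedSequence]) -> Taxonomy:
    """Build the per-superkingdom taxonomy forest from complete lineages.

    Every sequence is attached to the member set of each node along its
    lineage path, so each node's members are exactly the union of its
    children's members.  A missing kingdom collapses into a placeholder node
    named after the superkingdom so prokaryote paths keep eight levels.
    """
    roots: dict[str, TaxonomyNode] = {}
    organism_parent: dict[tuple[str, ...], tuple[str, str]] = {}
    for s in seqs:
        lin = s.lineage
        if lin is None or not lin.is_complete():
            raise InputError(f"{s.accession}: incomplete lineage in build_taxonomy")
        names = list(lin.as_tuple())
        if names[1] is None:  # prokaryotes: no kingdom rank documented
            names[1] = names[0]
        sk = names[0]
        node = roots.setdefault(sk, TaxonomyNode("superkingdom", sk))
        node.members.add(s.accession)
        for rank, name in zip(RANKS[1:], names[1:]):
            child = node.children.get(name)
            if child is None:
                child = TaxonomyNode(rank, name, parent=node)
                node.children[name] = child
            node = child
            node.members.add(s.accession)
        key = (sk, lin.organism)
        parent = (lin.genus, lin.family)
        prev = organism_parent.setdefault(key, parent)
        if prev != parent:
            raise InputError(
                f"conflicting lineage for organism {lin.organism!r}: "
                f"{prev} vs {parent} (accession {s.accession})"
            )
    return Taxonomy([roots[k] for k in sorted(roots)])
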