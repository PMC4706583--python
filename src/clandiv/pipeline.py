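"""End-to-end orchestration: alignment + lineages in, report artifacts out.

Stages: dedup -> lineage filter -> taxonomy -> distance matrix -> per-rank
diversity tables -> variance partitions -> NJ tree with bootstrap.  Every
output is a plain-text file (TSV / PHYLIP-style matrix / Newick / JSON) and a
run is fully reproducible from the config echoed into its output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from ._errors import ClandivError, InputError
from .anova import DEFAULT_PARTITION_RANKS, partition_lineage, partitions_frame
from .distances import GapPolicy, distance_matrix, rank_tables_frame
from .njtree import bootstrap_supports, write_newick
from .seqio import (
    attach_lineages,
    build_taxonomy,
    dedup_identical,
    filter_complete_lineage,
    read_alignment,
    read_lineages,
    superkingdom_counts,
)

logger = logging.getLogger(__name__)

SUMMARY_RANKS = ("phylum", "class_", "order", "family", "genus")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    alignment: str
    lineages: str
    out_dir: str
    gap_policy: GapPolicy = "pairwise"
    ranks: tuple[str, ...] = SUMMARY_RANKS
    partition_ranks: tuple[str, ...] = DEFAULT_PARTITION_RANKS
    bootstrap: int = 100
    seed: int = 0
    require_kingdom: bool | None = None
    plots: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


class StageError(ClandivError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    On any stage error, partial outputs are removed and a
    :class:`StageError` naming the stage propagates.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}

    def stage(name: str):
        logger.info("stage: %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    shutil.rmtree(out, ignore_errors=True)
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("read_inputs"):
        seqs = read_alignment(cfg.alignment)
        lineages = read_lineages(cfg.lineages)
        seqs = attach_lineages(seqs, lineages)
        manifest["stages"]["read_inputs"] = {"n_sequences": len(seqs)}

    with stage("dedup_identical"):
        seqs = dedup_identical(seqs)
        manifest["stages"]["dedup_identical"] = {"n_sequences": len(seqs)}

    with stage("filter_complete_lineage"):
        kept, dropped = filter_complete_lineage(seqs, cfg.require_kingdom)
        if not kept:
            raise InputError("no sequences with complete lineage remain")
        manifest["stages"]["filter_complete_lineage"] = {
            "n_kept": len(kept),
            "n_dropped": len(dropped),
            "superkingdom_counts": superkingdom_counts(kept),
        }

    with stage("build_taxonomy"):
        taxonomy = build_taxonomy(kept)
        manifest["stages"]["build_taxonomy"] = {
            "n_superkingdoms": len(taxonomy.roots),
            "n_nodes": sum(1 for _ in taxonomy.walk()),
        }

    with stage("distance_matrix"):
        matrix = distance_matrix(kept, cfg.gap_policy)
        matrix.to_phylip(out / "pdistance.phylip.tsv")
        manifest["stages"]["distance_matrix"] = {
            "n": matrix.n,
            "n_flagged_pairs": len(matrix.flagged_pairs),
            "gap_policy": cfg.gap_policy,
        }

    with stage("rank_tables"):
        table = rank_tables_frame(matrix, taxonomy, cfg.ranks)
        table.to_csv(out / "rank_summary.tsv", sep="\t", index=False)
        manifest["stages"]["rank_tables"] = {"n_rows": len(table)}

    with stage("variance_partition"):
        parts = partition_lineage(matrix, taxonomy, cfg.partition_ranks)
        pframe = partitions_frame(parts)
        pframe.to_csv(out / "variance_partition.tsv", sep="\t", index=False)
        manifest["stages"]["variance_partition"] = {
            "n_nodes": len(parts),
            "n_computed": int((pframe["status"] == "ok").sum()),
            "skipped": {
                f"{p.rank}:{p.taxon}": p.status
                for p in parts
                if p.status != "ok"
            },
        }

    with stage("nj_bootstrap"):
        tree = bootstrap_supports(
            kept, b=cfg.bootstrap, seed=cfg.seed, policy=cfg.gap_policy
        )
        write_newick(tree, out / "tree.nwk")
        manifest["stages"]["nj_bootstrap"] = {
            "n_leaves": len(tree.leaf_labels),
            "bootstrap": cfg.bootstrap,
            "dropped_replicates": tree.dropped_replicates,
        }

    if cfg.plots:
        with stage("plots"):
            from .plots import rank_heatmap, partition_pies

            rank_heatmap(table, out / "rank_heatmap.png")
            partition_pies(pframe, out / "partition_pies.png")
            manifest["stages"]["plots"] = {"written": 2}

    (out / "config.json").write_text(cfg.to_json())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
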