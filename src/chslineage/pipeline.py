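"""End-to-end orchestration: annotate -> trees -> reconcile -> summarize.

Every stage writes plain TSV/newick/JSON intermediates so any stage can be
re-run in isolation, and every report number is a pure function of those
intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import annotation as ann
from . import reconcile as rec
from . import trees

log = logging.getLogger("chslineage")

__all__ = ["PipelineConfig", "Report", "run_pipeline", "chromosomes_with_genes"]


@dataclass
class PipelineConfig:
    """Paths and flags for one pipeline run; round-trips through YAML."""

    gene_tree: str | None = None
    species_tree: str | None = None
    species_map: str | None = None  # TSV; falls back to the delimiter rule
    fasta: str | None = None
    gff: str | None = None
    outgroup: list[str] = field(default_factory=list)
    include_pseudogenes: bool = False
    annotation: dict[str, Any] = field(default_factory=dict)
    outdir: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class Report:
    """Structured pipeline output; `summary` is the machine-readable core."""

    annotation_table: pd.DataFrame | None
    reconciliation_table: pd.DataFrame | None
    lineage_table: pd.DataFrame
    retention: rec.RetentionSummary | None
    summary: dict[str, Any]

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        if self.annotation_table is not None:
            self.annotation_table.to_csv(
                os.path.join(outdir, "annotation.tsv"), sep="\t", index=False
            )
        if self.reconciliation_table is not None:
            self.reconciliation_table.to_csv(
                os.path.join(outdir, "reconciliation.tsv"), sep="\t", index=False
            )
        self.lineage_table.to_csv(
            os.path.join(outdir, "lineages.tsv"), sep="\t", index=False
        )
        if self.retention is not None:
            self.retention.matrix.to_csv(
                os.path.join(outdir, "retention_matrix.tsv"), sep="\t"
            )
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
        with open(os.path.join(outdir, "report.txt"), "w") as fh:
            fh.write(self.render_text())

    def render_text(self) -> str:
        s = self.summary
        lines = ["chslineage pipeline report", "=" * 26, ""]
        if "per_species_functional" in s:
            lines.append("Putatively functional genes per species:")
            for sp, n in sorted(s["per_species_functional"].items()):
                lines.append(f"  {sp:<14} {n}")
            lines.append("")
        lines.append(f"Ancestral lineages at the species root: {s['n_lineages']}")
        if s["n_lineages"]:
            lines.append(
                f"Species retaining >=2 lineages: {s['n_multi']}; "
                f"exactly 1: {s['n_single']}"
            )
            lines.append("")
            lines.append("lineage_id  n_copies  n_species  n_losses")
            for row in s["lineages"]:
                lines.append(
                    f"{row['lineage_id']:<11} {row['n_copies']:>8}  "
                    f"{row['n_species']:>9}  {row['n_losses']:>8}"
                )
        return "\n".join(lines) + "\n"


def chromosomes_with_genes(annotation_table: pd.DataFrame) -> pd.Series:
    """Distinct chromosomes bearing functional genes, per species."""
    func = annotation_table[annotation_table["status"] == ann.FUNCTIONAL]
    return func.groupby("species")["chromosome"].nunique()


def _lineage_table(
    lineages: list[rec.AncestralLineage],
) -> pd.DataFrame:
    rows = []
    for lin in lineages:
        rows.append(
            {
                "lineage_id": lin.lineage_id,
                "n_copies": lin.n_copies,
                "n_species": lin.n_species,
                "n_losses": lin.n_losses,
                "n_losses_unconstrained": lin.n_losses_unconstrained,
                "lost_edges": ";".join(
                    sorted(rec.node_signature(n) for n in lin.losses)
                ),
                "members": ";".join(sorted(lin.members)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lineage_id",
            "n_copies",
            "n_species",
            "n_losses",
            "n_losses_unconstrained",
            "lost_edges",
            "members",
        ],
    )


def summarize(
    gene_tree,
    species_tree,
    species_map: dict[str, str],
    annotation_table: pd.DataFrame | None = None,
) -> Report:
    """Reconcile one gene tree and assemble the report (no file IO)."""
    species = [l.taxon.label for l in species_tree.leaf_node_iter()]
    if gene_tree is None or not any(gene_tree.leaf_node_iter()):
        summary: dict[str, Any] = {
            "n_lineages": 0,
            "n_multi": 0,
            "n_single": 0,
            "lineages": [],
        }
        report = Report(annotation_table, None, _lineage_table([]), None, summary)
    else:
        result = rec.reconcile(gene_tree, species_tree, species_map)
        lineages = rec.decompose_lineages(result)
        retention = rec.retention_summary(lineages, species)
        table = _lineage_table(lineages)
        summary = {
            "n_lineages": len(lineages),
            "n_multi": retention.n_multi,
            "n_single": retention.n_single,
            "lineages": table.drop(columns=["members"]).to_dict("records"),
            "per_species_copies": {
                sp: int(retention.matrix.loc[sp].sum()) for sp in species
            },
            "lineages_per_species": {
                sp: int(retention.lineages_per_species[sp]) for sp in species
            },
        }
        report = Report(
            annotation_table, result.to_frame(), table, retention, summary
        )
    if annotation_table is not None:
        counts = annotation_table.groupby(["species", "status"]).size()
        summary["per_species_functional"] = {
            sp: int(n)
            for (sp, st), n in counts.items()
            if st == ann.FUNCTIONAL
        }
        summary["per_species_pseudogene"] = {
            sp: int(n)
            for (sp, st), n in counts.items()
            if st == ann.PSEUDOGENE
        }
        summary["chromosomes_with_genes"] = {
            sp: int(n) for sp, n in chromosomes_with_genes(annotation_table).items()
        }
    return report


def run_pipeline(config: PipelineConfig) -> Report:
    """Run annotate -> trees -> reconcile -> summarize from a config.

    Any stage failure raises with the stage name prefixed.
    """
    logging.basicConfig(level=config.log_level)
    import dendropy as _dendropy
    import numpy as _np

    from . import __version__

    log.info(
        "pipeline start (config %s; chslineage %s, numpy %s, dendropy %s)",
        config.digest(),
        __version__,
        _np.__version__,
        _dendropy.__version__,
    )

    annotation_table = None
    pseudo_ids: set[str] = set()
    if config.fasta and config.gff:
        try:
            sequences = ann.read_fasta(config.fasta)
            records = ann.read_gene_models(config.gff)
            cfg = ann.AnnotationConfig(**config.annotation)
            annotated = ann.annotate(records, sequences, cfg)
            annotation_table = ann.annotation_frame(annotated)
            pseudo_ids = {
                r.gene_id for r in annotated if r.status == ann.PSEUDOGENE
            }
        except Exception as exc:
            raise RuntimeError(f"annotation stage failed: {exc}") from exc

    try:
        if config.species_tree is None:
            raise ValueError("species_tree path is required")
        species_tree = trees.load_tree(config.species_tree)
        gene_tree = (
            trees.load_tree(config.gene_tree) if config.gene_tree else None
        )
        if gene_tree is not None and config.outgroup:
            gene_tree = trees.root_with_outgroup(gene_tree, config.outgroup)
        if gene_tree is not None and pseudo_ids and not config.include_pseudogenes:
            keep_out = sorted(
                set(trees.leaf_labels(gene_tree)) & pseudo_ids
            )
            if keep_out:
                gene_tree.prune_taxa_with_labels(
                    keep_out, suppress_unifurcations=True
                )
        table = (
            trees.read_species_map(config.species_map)
            if config.species_map
            else None
        )
        species_map = (
            trees.build_species_map(
                trees.leaf_labels(gene_tree),
                table=table,
                valid_species=[
                    l.taxon.label for l in species_tree.leaf_node_iter()
                ],
            )
            if gene_tree is not None
            else {}
        )
    except Exception as exc:
        raise RuntimeError(f"tree stage failed: {exc}") from exc

    try:
        report = summarize(gene_tree, species_tree, species_map, annotation_table)
    except Exception as exc:
        raise RuntimeError(f"reconciliation stage failed: {exc}") from exc

    if config.outdir:
        report.write(config.outdir)
        log.info("report written to %s", config.outdir)
    return report
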