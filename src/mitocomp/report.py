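"""Comparative report over one or more genomes.

Assembles the per-genome region-composition rows, per-gene start/stop
tables, junction tables, codon/RSCU tables, gene-order comparison and
(when structures are supplied) tRNA summaries into one object with TSV and
JSON writers. Rounding (one decimal for percentages, three for skews)
happens only at the presentation layer; machine outputs keep full
precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import architecture, codon_analysis, composition, trna
from .architecture import ANCESTRAL_GENE_ORDER
from .mito_io import MitoGenome


@dataclass
class ComparativeReport:
    """All comparative tables for a set of genomes, in input order."""

    genome_ids: List[str]
    region_table: pd.DataFrame
    gene_table: pd.DataFrame
    junction_tables: Dict[str, pd.DataFrame]
    codon_table: pd.DataFrame
    order_table: pd.DataFrame
    trna_table: Optional[pd.DataFrame] = None
    warnings_log: List[str] = field(default_factory=list)

    def write_tsv(self, outdir) -> List[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in self._named_tables():
            path = outdir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            written.append(path)
        return written

    def write_json(self, path) -> Path:
        payload = {name: df.to_dict(orient="records")
                   for name, df in self._named_tables()}
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1, default=str))
        return path

    def _named_tables(self):
        yield "region_composition", self.region_table
        yield "gene_start_stop", self.gene_table
        for gid, table in self.junction_tables.items():
            yield f"junctions_{gid}", table
        yield "codon_usage_rscu", self.codon_table
        yield "gene_order", self.order_table
        if self.trna_table is not None:
            yield "trna_summary", self.trna_table


def compare_genomes(
    genomes: Sequence[MitoGenome],
    structures: Optional[Dict[str, Sequence[trna.CloverleafStructure]]] = None,
    reference_order=ANCESTRAL_GENE_ORDER,
) -> ComparativeReport:
    """Build the full comparative report; sections degrade gracefully for
    partially annotated genomes (with entries in ``warnings_log``)."""
    if not genomes:
        raise ValueError("at least one genome required")
    log: List[str] = []
    region_rows = []
    gene_rows = []
    junction_tables: Dict[str, pd.DataFrame] = {}
    codon_rows = []
    order_rows = []
    trna_frames = []

    for g in genomes:
        summary = composition.summaries_to_table(composition.region_summary(g))
        summary.insert(0, "genome", g.record_id)
        region_rows.append(summary)

        if g.features_of_class("PCG"):
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                profile = codon_analysis.codon_usage(g)
            log.extend(f"{g.record_id}: {w.message}" for w in caught)
            codon_analysis.rscu(profile)
            gtab = codon_analysis.gene_reports_table(profile.gene_reports())
            gtab.insert(0, "genome", g.record_id)
            gene_rows.append(gtab)
            ctab = codon_analysis.profile_to_table(profile)
            ctab.insert(0, "genome", g.record_id)
            codon_rows.append(ctab)
        else:
            log.append(f"{g.record_id}: no PCGs annotated; codon sections "
                       "skipped")

        if len(g.features) >= 2:
            junction_tables[g.record_id] = architecture.junction_table(g)
            try:
                order = architecture.gene_order(g)
                rep = architecture.detect_rearrangement(order, reference_order)
                order_rows.append({
                    "genome": g.record_id,
                    "n_genes": len(order),
                    "breakpoint_distance": rep.distance,
                    "rearranged": rep.rearranged,
                    "displaced_genes": ",".join(rep.displaced_genes),
                })
            except ValueError as exc:
                log.append(f"{g.record_id}: gene-order comparison skipped "
                           f"({exc})")
        else:
            log.append(f"{g.record_id}: too few features for junction "
                       "analysis")

        if structures and g.record_id in structures:
            tab = trna.summarize_trnas(g, structures[g.record_id])
            tab.insert(0, "genome", g.record_id)
            trna_frames.append(tab)

    return ComparativeReport(
        genome_ids=[g.record_id for g in genomes],
        region_table=pd.concat(region_rows, ignore_index=True)
        if region_rows else pd.DataFrame(),
        gene_table=pd.concat(gene_rows, ignore_index=True)
        if gene_rows else pd.DataFrame(),
        junction_tables=junction_tables,
        codon_table=pd.concat(codon_rows, ignore_index=True)
        if codon_rows else pd.DataFrame(),
        order_table=pd.DataFrame(order_rows),
        trna_table=pd.concat(trna_frames, ignore_index=True)
        if trna_frames else None,
        warnings_log=log,
    )


def render_text(report: ComparativeReport) -> str:
    """Human-readable rendering with table-style rounding (AT% to one
    decimal, skews to three)."""
    region = report.region_table.copy()
    if not region.empty:
        region["at_percent"] = region["at_percent"].round(1)
        for col in ("at_skew", "gc_skew"):
            region[col] = region[col].round(3)
    parts = [
        "# Region composition", region.to_string(index=False),
        "", "# Protein-coding genes", report.gene_table.to_string(index=False),
        "", "# Gene order vs reference", report.order_table.to_string(index=False),
    ]
    if report.warnings_log:
        parts += ["", "# Warnings"] + [f"- {w}" for w in report.warnings_log]
    return "\n".join(parts)


__all__ = ["ComparativeReport", "compare_genomes", "render_text"]
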