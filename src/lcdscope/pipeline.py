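"""End-to-end survey orchestration over a directory of proteome FASTAs.

Stages: scan → per-organism counts/statistics → scrambled-proteome
enrichment → optional GO enrichment → signatures and clustering. Outputs are
per-organism TSVs plus domain-level summaries under a fixed layout, with a
JSON manifest recording every parameter so a run can be reproduced from the
manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classes import ALL_CLASS_LABELS, all_class_specs, spec_from_label
from .enrichment import domain_enrichment_summary, enrichment_analysis, results_to_frame
from .errors import ConfigurationError
from .ontology import class_go_enrichment, load_annotations, load_ontology, shared_pair_summary
from .proteome import read_fasta, read_metadata
from .scanner import scan_proteome
from .signatures import (build_signature, complete_linkage_cluster,
                         distance_matrix, merges_to_newick, signatures_to_frame)
from .stats import count_class_table, organism_level_frequency

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one survey run (all scan defaults printed):
    window 20, primary 40%, secondary 20%, dispersion 0.5, alpha 0.05,
    min_depth 4."""

    input_dir: str
    out_dir: str
    metadata: str | None = None
    classes: str | list[str] = "all"
    window_size: int = 20
    primary_threshold: float = 0.40
    secondary_threshold: float = 0.20
    dispersion_threshold: float = 0.5
    seed: int = 42
    alpha: float = 0.05
    min_depth: int = 4
    run_enrichment: bool = True
    obo: str | None = None
    gaf_dir: str | None = None
    exclude: list[str] = field(default_factory=list)
    exclude_domains_from_clustering: list[str] = field(
        default_factory=lambda: ["Viruses"])

    def class_specs(self):
        labels = (list(ALL_CLASS_LABELS) if self.classes == "all"
                  else list(self.classes))
        return [
            spec_from_label(lbl, self.window_size, self.primary_threshold,
                            self.secondary_threshold, self.dispersion_threshold)
            for lbl in labels
        ]


def run_survey(config: RunConfig) -> Path:
    """Run every stage over the configured proteome directory.

    Returns the output directory. Reruns with the same config are
    bit-identical except manifest timestamps are deliberately omitted.
    """
    in_dir = Path(config.input_dir)
    out = Path(config.out_dir)
    if not in_dir.is_dir():
        raise ConfigurationError(f"input directory {in_dir} does not exist")
    out.mkdir(parents=True, exist_ok=True)
    (out / "per_organism").mkdir(exist_ok=True)
    specs = config.class_specs()
    meta = read_metadata(config.metadata) if config.metadata else {}

    fastas = sorted(p for p in in_dir.glob("*.fasta")
                    if p.stem not in set(config.exclude))
    proteomes = []
    for fp in fastas:
        proteome = read_fasta(fp)
        if proteome.proteome_id in meta:
            proteome.domain_of_life, proteome.clade = meta[proteome.proteome_id]
        proteomes.append(proteome)

    ontology = load_ontology(config.obo) if config.obo else None
    tables, signatures = [], []
    results_by_org, go_by_org = {}, {}
    row_counts = {}
    for i, proteome in enumerate(proteomes):
        pid = proteome.proteome_id
        lcds = scan_proteome(proteome, specs)
        lcds.to_csv(out / "per_organism" / f"{pid}.lcds.tsv",
                    sep="\t", index=False)
        table = count_class_table(lcds, proteome)
        tables.append(table)
        signatures.append(build_signature(table))
        if config.run_enrichment:
            org_seed = config.seed * 100003 + i
            results = enrichment_analysis(proteome, lcds, org_seed, specs,
                                          config.alpha)
            results_by_org[pid] = results
            results_to_frame(results).to_csv(
                out / "per_organism" / f"{pid}.enrichment.tsv",
                sep="\t", index=False)
        if ontology is not None and config.gaf_dir:
            gaf = Path(config.gaf_dir) / f"{pid}.gaf"
            if gaf.exists():
                ann = load_annotations(str(gaf), proteome)
                go_recs = class_go_enrichment(lcds, proteome, ann, ontology,
                                              config.alpha, config.min_depth)
                go_by_org[pid] = go_recs
                pd.DataFrame([r.__dict__ for r in go_recs]).to_csv(
                    out / "per_organism" / f"{pid}.go.tsv",
                    sep="\t", index=False)
        row_counts[pid] = int(len(lcds))
        logger.info("organism=%s stage=scan lcds=%d", pid, len(lcds))

    # organism x class count matrix (Table S1 shape)
    counts = pd.DataFrame(
        {t.proteome_id: {lbl: t.count(lbl, "n_proteins_with_lcd")
                         for lbl in ALL_CLASS_LABELS} for t in tables}
    ).T.sort_index()
    counts.index.name = "proteome_id"
    counts.to_csv(out / "protein_counts.tsv", sep="\t")

    domains = sorted({t.domain_of_life for t in tables})
    freq_rows = {}
    for dom in domains:
        group = [t for t in tables if t.domain_of_life == dom]
        freq_rows[dom] = organism_level_frequency(group)
    pd.DataFrame(freq_rows).T.to_csv(out / "organism_level_frequency.tsv",
                                     sep="\t")

    if results_by_org:
        for dom in domains:
            group = [t.proteome_id for t in tables if t.domain_of_life == dom]
            if group:
                domain_enrichment_summary(results_by_org, group).to_csv(
                    out / f"enrichment_summary.{dom}.tsv", sep="\t")

    if go_by_org:
        for dom in domains:
            group = [t.proteome_id for t in tables
                     if t.domain_of_life == dom and t.proteome_id in go_by_org]
            if group:
                shared_pair_summary(go_by_org, group).to_csv(
                    out / f"go_shared_pairs.{dom}.tsv", sep="\t", index=False)

    signatures_to_frame(signatures).to_csv(out / "signatures.tsv", sep="\t")
    cluster_sigs = [s for s in signatures
                    if s.domain_of_life not in
                    set(config.exclude_domains_from_clustering)]
    if len(cluster_sigs) >= 2:
        dist = distance_matrix(cluster_sigs)
        dist.to_csv(out / "distance_matrix.tsv", sep="\t")
        merges = complete_linkage_cluster(dist)
        (out / "clustering.nwk").write_text(
            merges_to_newick(merges, list(dist.index)) + "\n")

    manifest = {
        "lcdscope_version": __version__,
        "n_organisms": len(proteomes),
        "parameters": {
            "classes": config.classes if config.classes == "all"
            else list(config.classes),
            "window_size": config.window_size,
            "primary_threshold": config.primary_threshold,
            "secondary_threshold": config.secondary_threshold,
            "dispersion_threshold": config.dispersion_threshold,
            "seed": config.seed,
            "alpha": config.alpha,
            "min_depth": config.min_depth,
            "exclude": sorted(config.exclude),
            "rng": "numpy PCG64 (Fisher-Yates via Generator.shuffle)",
        },
        "lcd_counts": row_counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
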