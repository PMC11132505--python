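"""GO-term enrichment of LCD-containing protein sets.

The ontology is read from OBO (is_a edges only; obsolete terms skipped) and
term *depth* is the longest is_a path to the namespace root. Annotations come
from GAF 2.x files, restricted to the proteome under study, with optional
ancestor propagation (off by default). For each LCD class, the proteins
carrying ≥1 LCD of that class form the study set, tested term-by-term
against the proteome background with a one-sided (enrichment) Fisher's exact
test and single-step Šidák correction across all tested terms; reported
records are filtered to a minimum depth (default 4) to drop non-specific
terms, without altering the correction family. Pairs (LCD class, GO term)
significant in at least one organism are summarized as the percentage of a
group's organisms sharing the enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom

from .errors import ConsistencyError, FormatError
from .proteome import Proteome

logger = logging.getLogger(__name__)

_NAMESPACE_ABBREV = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}


@dataclass
class OntologyTerm:
    go_id: str
    name: str
    namespace: str  # BP | CC | MF
    parents: frozenset[str]
    depth: int


@dataclass
class Ontology:
    terms: dict[str, OntologyTerm]

    def __contains__(self, go_id: str) -> bool:
        return go_id in self.terms

    def depth(self, go_id: str) -> int:
        return self.terms[go_id].depth

    def ancestors(self, go_id: str) -> set[str]:
        out: set[str] = set()
        stack = [go_id]
        while stack:
            for parent in self.terms[stack.pop()].parents:
                if parent not in out and parent in self.terms:
                    out.add(parent)
                    stack.append(parent)
        return out


@dataclass
class GOEnrichmentRecord:
    class_label: str
    go_id: str
    name: str
    namespace: str
    depth: int
    study_count: int
    study_n: int
    pop_count: int
    pop_n: int
    p_raw: float
    p_adj: float
    significant: bool


def load_ontology(obo_path: str) -> Ontology:
    """Load [Term] stanzas from an OBO file; compute longest-path depths.

    is_a edges pointing at undefined terms are dropped with a warning; a
    cyclic ontology raises :class:`FormatError`.
    """
    graph = obonet.read_obo(obo_path, ignore_obsolete=True)
    nodes = {n for n, d in graph.nodes(data=True) if d.get("name") is not None}
    terms: dict[str, dict] = {}
    dag = nx.DiGraph()  # edges parent -> child for depth DP
    for node in nodes:
        data = graph.nodes[node]
        ns = _NAMESPACE_ABBREV.get(data.get("namespace", ""), data.get("namespace", ""))
        parents = set()
        for parent in data.get("is_a", []):
            if parent not in nodes:
                logger.warning("dropping dangling is_a edge %s -> %s", node, parent)
                continue
            parents.add(parent)
            dag.add_edge(parent, node)
        dag.add_node(node)
        terms[node] = {"name": data.get("name", ""), "namespace": ns,
                       "parents": frozenset(parents)}
    if not nx.is_directed_acyclic_graph(dag):
        raise FormatError(f"cycle detected in is_a graph of {obo_path}")
    depth: dict[str, int] = {}
    for node in nx.topological_sort(dag):
        preds = [depth[p] for p in dag.predecessors(node)]
        depth[node] = 1 + max(preds) if preds else 0
    return Ontology({
        go_id: OntologyTerm(go_id, t["name"], t["namespace"], t["parents"],
                            depth[go_id])
        for go_id, t in terms.items()
    })


def load_annotations(
    gaf_path: str,
    proteome: Proteome,
    propagate: bool = False,
    ontology: Ontology | None = None,
) -> dict[str, set[str]]:
    """Read a GAF 2.x file into {accession: GO id set}.

    Only direct annotations of accessions present in the proteome are kept;
    NOT-qualified rows are skipped; malformed rows are skipped with a
    warning. With ``propagate=True`` (requires ``ontology``), is_a ancestors
    are added to each protein's term set.
    """
    keep = set(proteome.accessions)
    annotations: dict[str, set[str]] = {}
    with open(gaf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 15:
                logger.warning("skipping malformed GAF row %d in %s",
                               lineno, gaf_path)
                continue
            accession, qualifier, go_id = fields[1], fields[3], fields[4]
            if "NOT" in qualifier.split("|"):
                continue
            if accession not in keep or not go_id.startswith("GO:"):
                continue
            annotations.setdefault(accession, set()).add(go_id)
    if propagate:
        if ontology is None:
            raise ValueError("ancestor propagation requires an ontology")
        for acc, terms in annotations.items():
            extra: set[str] = set()
            for t in terms:
                if t in ontology:
                    extra |= ontology.ancestors(t)
            terms |= extra
    return annotations


def go_enrich(
    study: set[str],
    population: set[str],
    annotations: Mapping[str, set[str]],
    ontology: Ontology,
    alpha: float = 0.05,
    min_depth: int = 4,
    two_sided: bool = False,
) -> list[GOEnrichmentRecord]:
    """Per-term enrichment of ``study`` against ``population``.

    One-sided (enrichment) Fisher's exact test by default; Šidák-corrected
    over *all* tested terms (every term annotating ≥1 population protein),
    then filtered to ``depth ≥ min_depth`` for reporting. The depth filter
    never changes p-values, only which records are returned.
    """
    if not study <= population:
        raise ConsistencyError("study set must be a subset of the population")
    pop_n, study_n = len(population), len(study)
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for acc in population:
        for t in annotations.get(acc, ()):
            term_pop[t] = term_pop.get(t, 0) + 1
    for acc in study:
        for t in annotations.get(acc, ()):
            term_study[t] = term_study.get(t, 0) + 1
    tested = sorted(term_pop)
    m = len(tested)
    records = []
    for t in tested:
        k = term_study.get(t, 0)
        K = term_pop[t]
        if two_sided:
            from .enrichment import fisher_exact_2x2
            p = fisher_exact_2x2(k, study_n - k, K - k,
                                 (pop_n - study_n) - (K - k))
        else:
            p = float(hypergeom.sf(k - 1, pop_n, K, study_n))
        p = min(1.0, max(p, 0.0))
        p_adj = float(-math.expm1(m * math.log1p(-min(p, 1.0 - 1e-16))))
        p_adj = min(1.0, p_adj)
        if t in ontology:
            term = ontology.terms[t]
            depth, name, ns = term.depth, term.name, term.namespace
        else:
            depth, name, ns = -1, "", ""
        if depth < min_depth:
            continue
        records.append(GOEnrichmentRecord(
            class_label="", go_id=t, name=name, namespace=ns, depth=depth,
            study_count=k, study_n=study_n, pop_count=K, pop_n=pop_n,
            p_raw=p, p_adj=p_adj, significant=p_adj < alpha,
        ))
    return records


def class_go_enrichment(
    lcds: pd.DataFrame,
    proteome: Proteome,
    annotations: Mapping[str, set[str]],
    ontology: Ontology,
    alpha: float = 0.05,
    min_depth: int = 4,
) -> list[GOEnrichmentRecord]:
    """GO enrichment for every LCD class detected in one organism.

    Study set per class = proteins with ≥1 LCD of that class; background =
    all proteins of the proteome.
    """
    population = set(proteome.accessions)
    records: list[GOEnrichmentRecord] = []
    if not len(lcds):
        return records
    for lbl, sub in lcds.groupby("class_label", sort=True):
        study = set(sub["accession"])
        for rec in go_enrich(study, population, annotations, ontology,
                             alpha=alpha, min_depth=min_depth):
            rec.class_label = lbl
            records.append(rec)
    return records


def shared_pair_summary(
    per_organism_records: Mapping[str, Sequence[GOEnrichmentRecord]],
    group: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Percentage of a group's organisms sharing each significant
    (LCD class, GO term) pair.

    Only pairs significant in ≥1 organism are emitted; the denominator is
    the whole group.
    """
    orgs = list(group) if group is not None else list(per_organism_records)
    if not orgs:
        raise ValueError("organism group is empty")
    counts: dict[tuple[str, str], int] = {}
    names: dict[tuple[str, str], tuple[str, str, int]] = {}
    for org in orgs:
        for rec in per_organism_records[org]:
            if rec.significant:
                key = (rec.class_label, rec.go_id)
                counts[key] = counts.get(key, 0) + 1
                names[key] = (rec.name, rec.namespace, rec.depth)
    n = len(orgs)
    rows = [
        {
            "class_label": cls, "go_id": go, "name": names[(cls, go)][0],
            "namespace": names[(cls, go)][1], "depth": names[(cls, go)][2],
            "n_significant": cnt, "pct_organisms": 100.0 * cnt / n,
        }
        for (cls, go), cnt in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["class_label", "go_id", "name", "namespace", "depth",
                       "n_significant", "pct_organisms"],
    )
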