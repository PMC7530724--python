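"""Cross-species GO annotation transfer and gene-set construction.

Species without a curated ontology annotation inherit GO terms from a
reference proteome through best BLAST hits (primary reference, with a
secondary reference as fallback), the inherited terms are completed with
their full ancestral history in the ontology graph, and terms are turned
into measured-gene sets bounded in size for enrichment testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from .errors import AnnotationMismatchError, ConfigError, ParseError

__all__ = [
    "BLAST_COLUMNS",
    "load_obo",
    "read_blast_table",
    "assign_homologues",
    "ancestral_closure",
    "ancestor_cache",
    "close_annotation",
    "transfer_annotation",
    "build_gene_sets",
    "TransferResult",
]

#: NCBI BLAST tabular layout (outfmt 6).
BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

DEFAULT_RELATIONS = ("is_a", "part_of")


def load_obo(path, relations: Iterable[str] = DEFAULT_RELATIONS) -> nx.DiGraph:
    """Read an OBO ontology into a child→parent DiGraph.

    Only edges of the requested relation types (default ``is_a`` and
    ``part_of``) are kept; node attributes ``name`` and ``namespace`` are
    preserved.
    """
    multi = obonet.read_obo(path)
    relations = set(relations)
    dag = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        dag.add_node(node, name=data.get("name", ""), namespace=data.get("namespace", ""))
    for child, parent, key in multi.edges(keys=True):
        if key in relations:
            dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        raise ParseError("ontology graph contains a cycle")
    return dag


def read_blast_table(path) -> pd.DataFrame:
    """Parse a BLAST outfmt-6 TSV; malformed rows raise with their line number."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(BLAST_COLUMNS):
                raise ParseError(
                    f"expected {len(BLAST_COLUMNS)} tab-separated fields, got {len(parts)}",
                    line=i,
                )
            try:
                parts[10] = float(parts[10])  # evalue
                parts[11] = float(parts[11])  # bitscore
            except ValueError as exc:
                raise ParseError(f"non-numeric evalue/bitscore: {exc}", line=i) from exc
            rows.append(parts)
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


def assign_homologues(hits: pd.DataFrame, e_max: float = 1e-5) -> dict[str, str]:
    """Best-hit homologue per query, subject to an E-value ceiling.

    For each query the hit with the smallest E-value wins (ties broken by
    highest bit score, then lexicographically smallest subject id); queries
    whose best E-value exceeds ``e_max`` get no homologue.
    """
    if len(hits) == 0:
        return {}
    ok = hits.loc[pd.to_numeric(hits["evalue"]) <= e_max]
    if len(ok) == 0:
        return {}
    ranked = ok.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).drop_duplicates("qseqid")
    return dict(zip(ranked["qseqid"], ranked["sseqid"]))


def ancestral_closure(dag: nx.DiGraph, terms: Iterable[str]) -> frozenset[str]:
    """Terms plus every term reachable through child→parent edges."""
    out: set[str] = set()
    for t in terms:
        if t not in dag:
            raise AnnotationMismatchError(f"term {t!r} not in ontology")
        out.add(t)
        out.update(nx.descendants(dag, t))  # graph edges point child→parent
    return frozenset(out)


def ancestor_cache(dag: nx.DiGraph) -> dict[str, frozenset[str]]:
    """Precompute term → {term and all its ancestors} for every term.

    Single pass in reverse topological order (parents first), so each term's
    closure is the union of its parents' closures plus itself.
    """
    cache: dict[str, frozenset[str]] = {}
    for node in reversed(list(nx.topological_sort(dag))):
        anc: set[str] = {node}
        for parent in dag.successors(node):
            anc |= cache[parent]
        cache[node] = frozenset(anc)
    return cache


def close_annotation(
    dag: nx.DiGraph, annot: Mapping[str, Iterable[str]]
) -> dict[str, frozenset[str]]:
    """Apply ancestral closure to every gene's term set."""
    cache = ancestor_cache(dag)
    out: dict[str, frozenset[str]] = {}
    for gene, terms in annot.items():
        closed: set[str] = set()
        for t in terms:
            if t not in cache:
                raise AnnotationMismatchError(f"term {t!r} not in ontology")
            closed |= cache[t]
        out[gene] = frozenset(closed)
    return out


@dataclass
class TransferResult:
    """Closed annotation per gene plus the reference each gene came from."""

    annotation: dict[str, frozenset[str]]
    provenance: dict[str, str]  # gene → "primary" | "secondary"


def transfer_annotation(
    primary_map: Mapping[str, str],
    secondary_map: Mapping[str, str],
    primary_annot: Mapping[str, Iterable[str]],
    secondary_annot: Mapping[str, Iterable[str]],
    dag: nx.DiGraph,
    primary_terms: frozenset[str] | None = None,
    namespace: str = "biological_process",
) -> TransferResult:
    """Transfer reference GO terms onto species genes via homologues.

    A gene inherits the terms of its primary-reference homologue; if it has
    none, those of its secondary-reference homologue; otherwise it stays
    unannotated.  Terms outside the requested namespace are dropped, the
    ancestral closure is applied, and (after closure) terms absent from the
    primary reference's own term universe are removed so that all species
    are described in one comparable vocabulary.  Genes left without any term
    do not appear in the result.
    """
    cache = ancestor_cache(dag)
    ns_ok = {t for t, d in dag.nodes(data=True) if d.get("namespace", namespace) == namespace}

    def _close(terms: Iterable[str]) -> frozenset[str]:
        closed: set[str] = set()
        for t in terms:
            if t not in cache:
                raise AnnotationMismatchError(f"term {t!r} not in ontology")
            if t in ns_ok:
                closed |= cache[t]
        return frozenset(closed & ns_ok)

    if primary_terms is None:
        universe: set[str] = set()
        for terms in primary_annot.values():
            universe |= set(_close(terms))
        primary_terms = frozenset(universe)

    annotation: dict[str, frozenset[str]] = {}
    provenance: dict[str, str] = {}
    genes = set(primary_map) | set(secondary_map)
    for gene in sorted(genes):
        if gene in primary_map:
            terms = _close(primary_annot.get(primary_map[gene], ()))
            source = "primary"
        else:
            terms = _close(secondary_annot.get(secondary_map[gene], ()))
            terms = frozenset(terms & primary_terms)
            source = "secondary"
        if terms:
            annotation[gene] = terms
            provenance[gene] = source
    return TransferResult(annotation=annotation, provenance=provenance)


def build_gene_sets(
    annot: Mapping[str, Iterable[str]],
    measured_genes: Iterable[str],
    min_size: int = 3,
    max_size: int = 1500,
) -> dict[str, frozenset[str]]:
    """Invert the annotation into term → measured-gene sets, size-bounded.

    Only genes present in ``measured_genes`` count toward a set, and only
    sets with between ``min_size`` and ``max_size`` genes (inclusive) are
    retained — small sets carry no testable signal and huge ones are
    uninformative catch-alls.
    """
    if min_size < 1 or max_size < min_size:
        raise ConfigError("need 1 <= min_size <= max_size")
    measured = set(measured_genes)
    sets: dict[str, set[str]] = {}
    for gene, terms in annot.items():
        if gene not in measured:
            continue
        for t in terms:
            sets.setdefault(t, set()).add(gene)
    return {
        t: frozenset(genes)
        for t, genes in sorted(sets.items())
        if min_size <= len(genes) <= max_size
    }
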