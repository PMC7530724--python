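"""Plain-text readers and writers for every pipeline artifact.

All tables are TSV.  Expression and control-spot tables have one id column
followed by one column per sample; designs are sample/treatment/pair;
homology hits follow the BLAST tabular (outfmt 6) layout; annotations are
two-column gene/term tables; gene sets are term/size/comma-joined genes;
the ontology is a minimal OBO subset (id, name, namespace, is_a).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import ParseError

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_probe_map_tsv",
    "write_probe_map_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_gene_sets_tsv",
    "write_gene_sets_tsv",
    "write_blast_tsv",
    "write_obo",
    "write_enrichment_tsv",
    "read_enrichment_tsv",
    "write_study",
]


def read_matrix_tsv(path) -> pd.DataFrame:
    """Rows × samples table; first column is the row (probe/gene/spot) id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ParseError(f"duplicate row ids in {path}")
    return df


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_design_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    if "treatment" not in df.columns:
        raise ParseError(f"design {path} lacks a 'treatment' column")
    return df


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t")


def read_probe_map_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"probe map {path} needs two columns (probe, gene)")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="gene")


def write_probe_map_tsv(probe_map: pd.Series, path) -> None:
    pd.DataFrame({"probe": probe_map.index, "gene": probe_map.values}).to_csv(
        path, sep="\t", index=False
    )


def read_annotation_tsv(path) -> dict[str, frozenset[str]]:
    """GAF-like two-column table: gene id, GO term id (one pair per row)."""
    annot: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        annot.setdefault(gene, set()).add(term)
    return {g: frozenset(t) for g, t in annot.items()}


def write_annotation_tsv(
    annot: Mapping[str, Iterable[str]], path, provenance: Mapping[str, str] | None = None
) -> None:
    rows = []
    for gene in sorted(annot):
        for term in sorted(annot[gene]):
            row = {"gene": gene, "term": term}
            if provenance is not None:
                row["provenance"] = provenance.get(gene, "")
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_sets_tsv(path) -> dict[str, frozenset[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, frozenset[str]] = {}
    for _, row in df.iterrows():
        genes = frozenset(g for g in str(row["genes"]).split(",") if g)
        out[row["term"]] = genes
    return out


def write_gene_sets_tsv(gene_sets: Mapping[str, frozenset], path) -> None:
    rows = [
        {"term": t, "size": len(genes), "genes": ",".join(sorted(genes))}
        for t, genes in sorted(gene_sets.items())
    ]
    pd.DataFrame(rows, columns=["term", "size", "genes"]).to_csv(path, sep="\t", index=False)


def write_blast_tsv(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False, header=False)


def write_obo(dag: nx.DiGraph, path) -> None:
    """Minimal OBO export: [Term] stanzas with id/name/namespace/is_a."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for term in sorted(dag.nodes):
            data = dag.nodes[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {data.get('name', term)}\n")
            fh.write(f"namespace: {data.get('namespace', 'biological_process')}\n")
            for parent in sorted(dag.successors(term)):
                fh.write(f"is_a: {parent} ! {dag.nodes[parent].get('name', parent)}\n")


def write_enrichment_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_enrichment_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_study(study, outdir) -> dict[str, str]:
    """Write every artifact of a synthetic study; returns a path manifest."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_obo(study.dag, _p("go.obo"))
    write_annotation_tsv(study.ref_annotation, _p("primary_annot.tsv"))
    write_annotation_tsv(study.secondary_annotation, _p("secondary_annot.tsv"))
    for sp in study.species:
        d = os.path.join(outdir, sp.name)
        os.makedirs(d, exist_ok=True)
        write_matrix_tsv(sp.expression.signals, os.path.join(d, "expression.tsv"))
        write_matrix_tsv(sp.expression.control_spots, os.path.join(d, "controls.tsv"))
        write_design_tsv(sp.expression.design, os.path.join(d, "design.tsv"))
        write_probe_map_tsv(sp.universe.probe_map, os.path.join(d, "probe_map.tsv"))
        write_blast_tsv(sp.universe.primary_hits, os.path.join(d, "primary_hits.tsv"))
        write_blast_tsv(sp.universe.secondary_hits, os.path.join(d, "secondary_hits.tsv"))
        paths[sp.name] = d
    truth_rows = []
    for direction, planted in (("up", study.truth.planted_up), ("down", study.truth.planted_down)):
        for contrast, terms in planted.items():
            for t in sorted(terms):
                truth_rows.append({"contrast": contrast, "direction": direction, "term": t})
    pd.DataFrame(truth_rows, columns=["contrast", "direction", "term"]).to_csv(
        _p("planted_terms.tsv"), sep="\t", index=False
    )
    return paths
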