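"""End-to-end orchestration: preprocess → annotate → enrich → compare.

A single structured config describes every combination (its expression,
control-spot and design files per time point, plus homology hit tables),
the shared ontology and reference annotations, the contrasts to test and
the k-of-n conformability rule per contrast.  Every filtering decision is
logged so the stage counts in the run report are auditable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import annotate, compare, enrich, io, preprocess
from .errors import ConfigError, PipelineError

__all__ = [
    "RunConfig",
    "run_pipeline",
    "analyze_study",
    "export_heatmap_matrix",
    "read_heatmap_matrix",
]

NA_SENTINEL = "NA"


@dataclass
class CombinationSpec:
    id: str
    probe_map: str
    primary_hits: str
    secondary_hits: str | None
    paired: bool
    timepoints: list[dict]  # each: {id, expression, controls, design}


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    outdir: str
    obo: str
    primary_annot: str
    secondary_annot: str | None
    contrasts: list[str]
    rules: dict[str, compare.ConformabilityRule]
    combinations: list[CombinationSpec]
    preprocess: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig
    )
    alpha: float = 0.05
    min_set_size: int = 3
    max_set_size: int = 1500

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        try:
            combos = [
                CombinationSpec(
                    id=c["id"],
                    probe_map=c["probe_map"],
                    primary_hits=c["primary_hits"],
                    secondary_hits=c.get("secondary_hits"),
                    paired=bool(c.get("paired", False)),
                    timepoints=list(c["timepoints"]),
                )
                for c in raw["combinations"]
            ]
            alpha = float(raw.get("alpha", 0.05))
            rules = {
                contrast: compare.ConformabilityRule(
                    k=int(params["k"]), n=int(params["n"]), alpha=alpha,
                    timepoint_mode=params.get("timepoint_mode", "any"),
                )
                for contrast, params in raw.get("rules", {}).items()
            }
            pp = preprocess.PreprocessConfig(**raw.get("preprocess", {}))
            cfg = cls(
                outdir=raw["outdir"],
                obo=raw["annotation"]["obo"],
                primary_annot=raw["annotation"]["primary_annot"],
                secondary_annot=raw["annotation"].get("secondary_annot"),
                contrasts=list(raw["contrasts"]),
                rules=rules,
                combinations=combos,
                preprocess=pp,
                alpha=alpha,
                min_set_size=int(raw.get("min_set_size", 3)),
                max_set_size=int(raw.get("max_set_size", 1500)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid run config: {exc!r}") from exc
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    def validate(self) -> None:
        """Check file existence and contrast arms before any computation."""
        files = [self.obo, self.primary_annot]
        if self.secondary_annot:
            files.append(self.secondary_annot)
        for c in self.combinations:
            files += [c.probe_map, c.primary_hits]
            if c.secondary_hits:
                files.append(c.secondary_hits)
            if not c.timepoints:
                raise ConfigError(f"combination {c.id} has no time points")
            for tp in c.timepoints:
                files += [tp["expression"], tp["controls"], tp["design"]]
        for f in files:
            if not os.path.exists(f):
                raise ConfigError(f"input file does not exist: {f}")
        for c in self.combinations:
            for tp in c.timepoints:
                design = io.read_design_tsv(tp["design"])
                arms = set(design["treatment"])
                for name in self.contrasts:
                    ct = enrich.Contrast.from_name(name)
                    missing = {ct.treatment, ct.reference} - arms
                    if missing:
                        raise ConfigError(
                            f"combination {c.id}/{tp['id']}: design lacks arms "
                            f"{sorted(missing)} needed by {name}"
                        )
        for name, rule in self.rules.items():
            if rule.n != len(self.combinations):
                raise ConfigError(
                    f"rule for {name} expects n={rule.n}, config has "
                    f"{len(self.combinations)} combinations"
                )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts under cfg.outdir.

    Returns the run report (stage counts per combination/time point and the
    significant/conformable/analogous summary per contrast and direction).
    A stage failure raises :class:`PipelineError` naming the stage; the
    MANIFEST file lists which stages had completed.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest_path = os.path.join(cfg.outdir, "MANIFEST")
    completed: list[str] = []

    def _done(stage: str) -> None:
        completed.append(stage)
        with open(manifest_path, "w") as fh:
            fh.write("\n".join(completed) + "\n")

    report: dict = {"combinations": {}, "contrasts": {}}

    try:
        stage = "load-annotation"
        dag = annotate.load_obo(cfg.obo)
        primary_annot = io.read_annotation_tsv(cfg.primary_annot)
        secondary_annot = (
            io.read_annotation_tsv(cfg.secondary_annot) if cfg.secondary_annot else {}
        )
        _done(stage)

        results: list[compare.CombinationResult] = []
        for combo in cfg.combinations:
            stage = f"annotate:{combo.id}"
            primary_map = annotate.assign_homologues(
                annotate.read_blast_table(combo.primary_hits)
            )
            secondary_map = (
                annotate.assign_homologues(annotate.read_blast_table(combo.secondary_hits))
                if combo.secondary_hits
                else {}
            )
            secondary_map = {q: s for q, s in secondary_map.items() if q not in primary_map}
            transfer = annotate.transfer_annotation(
                primary_map, secondary_map, primary_annot, secondary_annot, dag
            )
            combo_dir = os.path.join(cfg.outdir, combo.id)
            os.makedirs(combo_dir, exist_ok=True)
            io.write_annotation_tsv(
                transfer.annotation,
                os.path.join(combo_dir, "annotation.tsv"),
                provenance=transfer.provenance,
            )
            _done(stage)

            probe_map = io.read_probe_map_tsv(combo.probe_map)
            tables: dict[str, dict[str, pd.DataFrame]] = {}
            combo_report: dict = {"timepoints": {}}
            for tp in combo.timepoints:
                stage = f"preprocess:{combo.id}:{tp['id']}"
                ds = preprocess.ExpressionDataset(
                    signals=io.read_matrix_tsv(tp["expression"]),
                    design=io.read_design_tsv(tp["design"]),
                    control_spots=io.read_matrix_tsv(tp["controls"]),
                )
                pre = preprocess.preprocess_dataset(ds, probe_map, cfg.preprocess)
                tp_dir = os.path.join(combo_dir, str(tp["id"]))
                os.makedirs(tp_dir, exist_ok=True)
                io.write_matrix_tsv(pre.matrix, os.path.join(tp_dir, "processed.tsv"))
                pre.removed.to_csv(
                    os.path.join(tp_dir, "filter_report.tsv"), sep="\t", index=False
                )
                _done(stage)

                stage = f"enrich:{combo.id}:{tp['id']}"
                gene_sets = annotate.build_gene_sets(
                    transfer.annotation,
                    pre.matrix.index,
                    min_size=cfg.min_set_size,
                    max_size=cfg.max_set_size,
                )
                io.write_gene_sets_tsv(gene_sets, os.path.join(tp_dir, "gene_sets.tsv"))
                log2 = pre.log2_matrix
                design = ds.design
                tp_tables: dict[str, pd.DataFrame] = {}
                for name in cfg.contrasts:
                    contrast = enrich.Contrast.from_name(name, paired=combo.paired)
                    table = enrich.run_gage(log2, gene_sets, contrast, design)
                    io.write_enrichment_tsv(
                        table, os.path.join(tp_dir, f"enrichment_{name}.tsv")
                    )
                    tp_tables[name] = table
                tables[str(tp["id"])] = tp_tables
                counts = dict(pre.counts)
                counts["gene_sets"] = len(gene_sets)
                combo_report["timepoints"][str(tp["id"])] = counts
                _done(stage)
            report["combinations"][combo.id] = combo_report
            results.append(compare.CombinationResult(combination=combo.id, tables=tables))

        stage = "compare"
        conformable: dict[str, dict[str, frozenset[str]]] = {}
        for name in cfg.contrasts:
            rule = cfg.rules.get(name)
            if rule is None:
                continue
            universe = compare.common_universe(results, name)
            contrast_report: dict = {"universe": len(universe), "directions": {}}
            conformable[name] = {}
            for direction in ("up", "down"):
                sig_any, conf = compare.classify_conformable(results, name, direction, rule)
                conformable[name][direction] = conf
                mat = compare.fdr_matrix(results, name, direction)
                cdir = os.path.join(cfg.outdir, "compare", name)
                os.makedirs(cdir, exist_ok=True)
                mat.to_csv(os.path.join(cdir, f"fdr_matrix_{direction}.tsv"), sep="\t")
                flags = pd.DataFrame(
                    {
                        "term": sorted(universe),
                        "significant_any": [t in sig_any for t in sorted(universe)],
                        "conformable": [t in conf for t in sorted(universe)],
                    }
                )
                flags.to_csv(
                    os.path.join(cdir, f"conformability_{direction}.tsv"),
                    sep="\t",
                    index=False,
                )
                contrast_report["directions"][direction] = {
                    "significant_any": len(sig_any),
                    "conformable": len(conf),
                }
            report["contrasts"][name] = contrast_report
        _done(stage)

        stage = "overlap"
        if {"E_vs_C", "F_vs_C", "EF_vs_F"} <= set(conformable):
            report["overlap"] = {}
            for direction in ("up", "down"):
                res = compare.overlap_analysis(
                    conformable["E_vs_C"][direction],
                    conformable["F_vs_C"][direction],
                    conformable["EF_vs_F"][direction],
                    direction=direction,
                )
                odir = os.path.join(cfg.outdir, "compare")
                pd.DataFrame([res.venn]).to_csv(
                    os.path.join(odir, f"venn_{direction}.tsv"), sep="\t", index=False
                )
                report["overlap"][direction] = {
                    "analogous": len(res.analogous),
                    "enhanced_core": len(res.enhanced_core),
                    "enhanced_of_analogous_pct": res.enhanced_of_analogous_pct,
                    "analogous_of_f_pct": res.analogous_of_f_pct,
                }
        _done(stage)

        with open(os.path.join(cfg.outdir, "report.yaml"), "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=True)
        _done("report")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return report


def analyze_study(
    study,
    contrasts: Sequence[str],
    pre_cfg: preprocess.PreprocessConfig | None = None,
    min_set_size: int = 3,
    max_set_size: int = 1500,
) -> tuple[list[compare.CombinationResult], dict]:
    """In-memory preprocess → annotate → enrich for a synthetic study.

    Convenience equivalent of :func:`run_pipeline` that skips file I/O:
    each species is processed with the default chain, annotation is
    transferred through its hit tables, and every requested contrast is
    tested (paired for block-paired species).  Returns one
    :class:`~xgage.compare.CombinationResult` per species plus per-species
    stage counts.
    """
    pre_cfg = pre_cfg or preprocess.PreprocessConfig()
    results: list[compare.CombinationResult] = []
    counts: dict[str, dict] = {}
    for sp in study.species:
        pre = preprocess.preprocess_dataset(sp.expression, sp.universe.probe_map, pre_cfg)
        primary_map = annotate.assign_homologues(sp.universe.primary_hits)
        secondary_map = {
            q: s
            for q, s in annotate.assign_homologues(sp.universe.secondary_hits).items()
            if q not in primary_map
        }
        transfer = annotate.transfer_annotation(
            primary_map,
            secondary_map,
            study.ref_annotation,
            study.secondary_annotation,
            study.dag,
        )
        gene_sets = annotate.build_gene_sets(
            transfer.annotation, pre.matrix.index, min_set_size, max_set_size
        )
        log2 = pre.log2_matrix
        tables = {
            name: enrich.run_gage(
                log2,
                gene_sets,
                enrich.Contrast.from_name(name, paired=sp.paired),
                sp.expression.design,
            )
            for name in contrasts
        }
        results.append(
            compare.CombinationResult(combination=sp.name, tables={"t1": tables})
        )
        counts[sp.name] = dict(pre.counts, gene_sets=len(gene_sets))
    return results, counts


def export_heatmap_matrix(
    results: Sequence[compare.CombinationResult],
    contrast: str,
    direction: str,
    ordering: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Wide signed-FDR matrix for heatmap rendering.

    Rows are gene sets (the supplied ordering first, remaining universe
    terms appended alphabetically), columns combination/time-point; down-
    regulation FDRs are written negative so one matrix can carry both
    directions, and missing results become the ``NA`` sentinel.
    """
    universe = sorted(compare.common_universe(results, contrast)) if len(results) >= 2 else sorted(
        t for res in results for tp in res.timepoints for t in res.terms(contrast, tp)
    )
    if ordering:
        unknown = [t for t in ordering if t not in set(universe)]
        if unknown:
            raise ConfigError(f"ordering contains terms outside the result: {unknown[:5]}")
        rest = sorted(set(universe) - set(ordering))
        terms = list(ordering) + rest
    else:
        terms = universe
    mat = compare.fdr_matrix(results, contrast, direction, terms=terms)
    sign = -1.0 if direction == "down" else 1.0
    out = mat.map(lambda v: NA_SENTINEL if v is None or pd.isna(v) else sign * float(v))
    return out


def read_heatmap_matrix(path) -> pd.DataFrame:
    """Read a signed-FDR export back to absolute FDR values (NaN for NA)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_SENTINEL])
    return df.abs()
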