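"""Synthetic multi-species expression studies with known planted structure.

Stands in for the study's public microarray/RNA-seq datasets: several
species share a reference gene universe related by best-hit homology, carry
microarray-like positive signals with dark-corner control spots, and receive
treatment effects (insect eggs E, larval feeding F, and their combination
EF against controls C) planted into designated GO terms.  Every downstream
stage — detection filtering, annotation transfer, enrichment, conformability
classification — can therefore be checked against a ground truth.

Treatment effects are planted per contrast and applied to treatment arms as
follows: terms planted for E_vs_C shift the E arm (the egg effect is local
to the egg phase); terms planted for F_vs_C shift both the F and the EF arm
(feeding damage is present in both); terms planted for EF_vs_F shift only
the EF arm (the egg-primed amplification of the feeding response).

Randomness is split into one independent stream per output artifact, keyed
on the master seed plus the artifact's identity, so adding a species never
perturbs another species' data and identical configurations are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .annotate import BLAST_COLUMNS, close_annotation
from .errors import ConfigError
from .preprocess import ExpressionDataset

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SpeciesUniverse",
    "SpeciesData",
    "Study",
    "generate_go_dag",
    "generate_reference_annotation",
    "sample_planted_terms",
    "generate_species_universe",
    "simulate_expression",
    "simulate_study",
]

# artifact codes for per-stream seeding
_DAG, _REF_ANNOT, _SEC_ANNOT, _PLANT, _HITS, _EXPR = range(6)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, key))))


# effect of planting a term for a contrast lands on these treatment arms
_EFFECT_ARMS: dict[str, tuple[str, ...]] = {
    "E_vs_C": ("E",),
    "F_vs_C": ("F", "EF"),
    "EF_vs_C": ("EF",),
    "EF_vs_F": ("EF",),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic multi-species experiment.

    Defaults emulate the real study's layout: four plant–insect
    combinations (one of them block-paired with three replicate blocks, as
    in the *S. dulcamara* design), a full C/E/F/EF factorial with three
    replicates per arm, log-normal one-colour intensities with dark-corner
    control spots sitting well below gene signals, and best-hit homology to
    a primary reference proteome with a secondary-reference fallback.
    """

    seed: int = 0
    n_species: int = 4
    n_ref_genes: int = 4000
    homology_hit_rate: float = 0.9
    secondary_hit_rate: float = 0.5
    subthreshold_hit_rate: float = 0.3
    decoy_hits: int = 2
    n_probes_per_gene: int = 2
    n_replicates: int = 3
    paired: bool = False
    paired_species: tuple[int, ...] = (3,)
    treatments: tuple[str, ...] = ("C", "E", "F", "EF")
    planted_terms_up: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    planted_terms_down: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    effect_size: float = 2.0
    noise_sd: float = 0.25
    pair_sd: float = 0.5
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    n_control_spots: int = 100
    control_spot_log2_mean: float = 4.0
    control_spot_log2_sd: float = 0.5
    dropout_fraction: float = 0.02
    n_go_terms: int = 800
    n_secondary_only_terms: int = 10
    max_parents: int = 3
    terms_per_gene: int = 3

    def __post_init__(self) -> None:
        for name in (
            "homology_hit_rate",
            "secondary_hit_rate",
            "subthreshold_hit_rate",
            "dropout_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be non-negative")
        if self.n_go_terms < 2:
            raise ConfigError("need at least two GO terms")
        if "C" not in self.treatments:
            raise ConfigError("treatments must include the control arm C")
        for planted in (self.planted_terms_up, self.planted_terms_down):
            for contrast in planted:
                if contrast not in _EFFECT_ARMS:
                    raise ConfigError(f"unknown contrast {contrast!r}")
                for arm in (contrast.split("_vs_")[0],):
                    if arm not in self.treatments:
                        raise ConfigError(
                            f"contrast {contrast} references treatment {arm!r} "
                            "absent from the design"
                        )


@dataclass
class GroundTruth:
    """What was planted and which genes truly map to which reference genes."""

    planted_up: dict[str, frozenset[str]]
    planted_down: dict[str, frozenset[str]]
    gene_maps: dict[str, dict[str, str]]  # species → species gene → primary ref gene
    secondary_maps: dict[str, dict[str, str]]  # species → species gene → secondary ref gene


def generate_go_dag(
    n_terms: int,
    max_parents: int = 3,
    seed: int = 0,
    namespace: str = "biological_process",
) -> nx.DiGraph:
    """A rooted random DAG of GO-like terms with child→parent edges.

    The first term is the single root; every later term attaches to between
    one and ``max_parents`` earlier terms, which guarantees acyclicity and
    a single connected root.
    """
    if n_terms < 2:
        raise ConfigError("a DAG needs at least two terms")
    if max_parents < 1:
        raise ConfigError("max_parents must be at least 1")
    rng = _rng(seed, _DAG)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    dag = nx.DiGraph()
    for i, t in enumerate(terms):
        dag.add_node(t, name=f"synthetic process {i + 1}", namespace=namespace)
    for i in range(1, n_terms):
        k = int(rng.integers(1, max_parents + 1))
        parents = rng.choice(i, size=min(k, i), replace=False)
        for p in sorted(parents):
            dag.add_edge(terms[i], terms[p])
    return dag


def generate_reference_annotation(
    dag: nx.DiGraph,
    n_genes: int,
    terms_per_gene: int = 3,
    seed: int = 0,
    excluded_terms: Iterable[str] = (),
    gene_prefix: str = "REF",
) -> dict[str, frozenset[str]]:
    """Direct (pre-closure) term assignments for the reference gene universe.

    Each gene draws between one and ``terms_per_gene`` distinct non-root
    terms; the root is reached through closure only.
    """
    rng = _rng(seed, _REF_ANNOT)
    order = list(nx.topological_sort(dag))
    root = order[-1] if dag.out_degree(order[-1]) == 0 else None
    excluded = set(excluded_terms)
    candidates = sorted(t for t in dag.nodes if dag.out_degree(t) > 0 and t not in excluded)
    if not candidates:
        raise ConfigError("no non-root terms available for annotation")
    annot: dict[str, frozenset[str]] = {}
    for j in range(n_genes):
        k = int(rng.integers(1, terms_per_gene + 1))
        picks = rng.choice(len(candidates), size=min(k, len(candidates)), replace=False)
        annot[f"{gene_prefix}{j:05d}"] = frozenset(candidates[i] for i in picks)
    return annot


def sample_planted_terms(
    dag: nx.DiGraph,
    ref_annotation: Mapping[str, Iterable[str]],
    n: int,
    seed: int = 0,
    size_range: tuple[int, int] = (8, 150),
    exclude: Iterable[str] = (),
    member_disjoint_from: Iterable[str] = (),
) -> tuple[str, ...]:
    """Pick terms to plant effects into, constrained to a workable set size.

    Sizes are counted on the closed reference annotation so that a planted
    term keeps at least the minimum gene-set size after annotation transfer
    and measurement filtering downstream.  ``member_disjoint_from`` rejects
    candidates whose gene membership intersects that of the listed terms —
    planted groups that are meant to move in opposite directions must not
    share genes, or their shifts cancel and the ground truth becomes
    incoherent.
    """
    closed = close_annotation(dag, dict(ref_annotation))
    members: dict[str, set[str]] = {}
    for gene, terms in closed.items():
        for t in terms:
            members.setdefault(t, set()).add(gene)
    lo, hi = size_range
    excluded = set(exclude)
    blocked_genes: set[str] = set()
    for t in member_disjoint_from:
        blocked_genes |= members.get(t, set())
    eligible = sorted(
        t
        for t, genes in members.items()
        if lo <= len(genes) <= hi and t not in excluded and not (genes & blocked_genes)
    )
    if len(eligible) < n:
        raise ConfigError(
            f"only {len(eligible)} terms have closed size in {size_range} "
            f"and are disjoint from the blocked terms, need {n}"
        )
    rng = _rng(seed, _PLANT)
    picks = rng.choice(len(eligible), size=n, replace=False)
    return tuple(sorted(eligible[i] for i in picks))


@dataclass
class SpeciesUniverse:
    """Probe layout and homology-hit tables of one species."""

    species: str
    probe_map: pd.Series  # probe id → species gene id
    primary_hits: pd.DataFrame
    secondary_hits: pd.DataFrame
    gene_map: dict[str, str]  # species gene → primary ref gene (truth)
    secondary_map: dict[str, str]  # species gene → secondary ref gene (truth)


def _hit_row(q: str, s: str, evalue: float, bitscore: float, rng: np.random.Generator) -> list:
    length = int(rng.integers(80, 500))
    pident = round(float(rng.uniform(40, 99)), 2)
    mismatch = int(length * (100 - pident) / 100)
    return [q, s, pident, length, mismatch, int(rng.integers(0, 5)),
            1, length, 1, length, evalue, round(bitscore, 1)]


def generate_species_universe(
    cfg: SimulationConfig,
    dag: nx.DiGraph,
    ref_annotation: Mapping[str, Iterable[str]],
    species_index: int,
) -> SpeciesUniverse:
    """One species' genes, probes and synthetic BLAST hit tables.

    Each species gene corresponds one-to-one to a reference gene.  With
    probability ``homology_hit_rate`` it receives a best hit to its true
    primary-reference gene (E-value ≤ 1e-5) plus optional decoy hits with
    strictly worse E-values; otherwise it may receive a secondary-reference
    hit (probability ``secondary_hit_rate``) and/or a sub-threshold primary
    hit that the E-value ceiling must reject.
    """
    if not ref_annotation:
        raise ConfigError("reference annotation must be non-empty")
    rng = _rng(cfg.seed, _HITS, species_index)
    ref_genes = sorted(ref_annotation)
    species = f"sp{species_index + 1}"
    p_rows: list[list] = []
    s_rows: list[list] = []
    gene_map: dict[str, str] = {}
    secondary_map: dict[str, str] = {}
    probe_ids: list[str] = []
    probe_genes: list[str] = []

    def _add_hits(rows: list[list], q: str, subject: str, subjects_pool: list[str]) -> None:
        true_e = 10.0 ** -float(rng.uniform(6, 50))
        true_bit = float(rng.uniform(80, 400))
        rows.append(_hit_row(q, subject, true_e, true_bit, rng))
        for _ in range(int(rng.integers(0, cfg.decoy_hits + 1))):
            decoy = subjects_pool[int(rng.integers(0, len(subjects_pool)))]
            if decoy == subject:
                continue
            decoy_e = min(true_e * 10.0 ** float(rng.uniform(1, 6)), 10.0)
            rows.append(_hit_row(q, decoy, decoy_e, true_bit * float(rng.uniform(0.2, 0.8)), rng))

    alt_genes = [f"ALT{j:05d}" for j in range(len(ref_genes))]
    for j, ref in enumerate(ref_genes):
        gene = f"S{species_index + 1}G{j:05d}"
        for k in range(cfg.n_probes_per_gene):
            probe_ids.append(f"{gene}_p{k + 1}")
            probe_genes.append(gene)
        if rng.random() < cfg.homology_hit_rate:
            gene_map[gene] = ref
            _add_hits(p_rows, gene, ref, ref_genes)
        else:
            if rng.random() < cfg.subthreshold_hit_rate:
                weak_e = 10.0 ** -float(rng.uniform(0.0, 4.9))
                p_rows.append(_hit_row(gene, ref, weak_e, float(rng.uniform(20, 45)), rng))
            if rng.random() < cfg.secondary_hit_rate:
                alt = alt_genes[j]
                secondary_map[gene] = alt
                _add_hits(s_rows, gene, alt, alt_genes)
    return SpeciesUniverse(
        species=species,
        probe_map=pd.Series(probe_genes, index=pd.Index(probe_ids, name="probe"), name="gene"),
        primary_hits=pd.DataFrame(p_rows, columns=BLAST_COLUMNS),
        secondary_hits=pd.DataFrame(s_rows, columns=BLAST_COLUMNS),
        gene_map=gene_map,
        secondary_map=secondary_map,
    )


def _planted_deltas(
    cfg: SimulationConfig,
    annotation: Mapping[str, frozenset[str]],
    genes: list[str],
    gene_map: Mapping[str, str],
) -> dict[str, np.ndarray]:
    """Per-treatment log2 shift vector over species genes."""
    all_terms: set[str] = set()
    for terms in annotation.values():
        all_terms |= set(terms)
    delta = {t: np.zeros(len(genes)) for t in cfg.treatments}
    for planted, sign in ((cfg.planted_terms_up, +1.0), (cfg.planted_terms_down, -1.0)):
        for contrast, terms in planted.items():
            terms = frozenset(terms)
            missing = terms - all_terms
            if missing:
                raise ConfigError(f"planted terms absent from annotation: {sorted(missing)}")
            affected = np.array(
                [bool(annotation.get(gene_map.get(g, ""), frozenset()) & terms) for g in genes]
            )
            for arm in _EFFECT_ARMS[contrast]:
                if arm in delta:
                    delta[arm] = delta[arm] + sign * cfg.effect_size * affected
    return delta


def simulate_expression(
    cfg: SimulationConfig,
    annotation: Mapping[str, frozenset[str]],
    truth: GroundTruth,
    species_index: int = 0,
) -> ExpressionDataset:
    """Microarray-like signals for one species under the planted effects.

    log2 signal = gene baseline + treatment effect + block shift (paired
    designs) + N(0, noise_sd), exponentiated to positive intensities.
    Control spots are drawn from their own (lower) log-normal distribution,
    and a ``dropout_fraction`` of probes is forced below the detection
    threshold in every sample of one randomly chosen treatment.
    """
    species = f"sp{species_index + 1}"
    gene_map = truth.gene_maps[species]
    genes = sorted(set(gene_map) | set(truth.secondary_maps.get(species, {})))
    if not genes:
        raise ConfigError(f"no genes for species {species}")
    # full species gene list from the map domains may miss homologue-less
    # genes; regenerate the complete list from the reference universe size
    n_genes = max(int(g.split("G")[-1]) for g in genes) + 1
    genes = [f"S{species_index + 1}G{j:05d}" for j in range(n_genes)]

    rng = _rng(cfg.seed, _EXPR, species_index)
    samples = [f"{t}{r + 1}" for t in cfg.treatments for r in range(cfg.n_replicates)]
    design = pd.DataFrame(
        {
            "treatment": [t for t in cfg.treatments for _ in range(cfg.n_replicates)],
            "pair": [str(r + 1) if cfg.paired else "" for _ in cfg.treatments
                     for r in range(cfg.n_replicates)],
        },
        index=pd.Index(samples, name="sample"),
    )

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=len(genes))
    delta = _planted_deltas(cfg, annotation, genes, gene_map)
    pair_shift = rng.normal(0.0, cfg.pair_sd, size=cfg.n_replicates) if cfg.paired else None

    probe_ids = [f"{g}_p{k + 1}" for g in genes for k in range(cfg.n_probes_per_gene)]
    gene_idx = np.repeat(np.arange(len(genes)), cfg.n_probes_per_gene)
    log2 = np.empty((len(probe_ids), len(samples)))
    for s_i, s in enumerate(samples):
        t = design.at[s, "treatment"]
        mu = baseline[gene_idx] + delta[t][gene_idx]
        if pair_shift is not None:
            mu = mu + pair_shift[int(design.at[s, "pair"]) - 1]
        log2[:, s_i] = mu + rng.normal(0.0, cfg.noise_sd, size=len(probe_ids))
    signals = pd.DataFrame(2.0 ** log2, index=pd.Index(probe_ids, name="probe"), columns=samples)

    spots = 2.0 ** rng.normal(
        cfg.control_spot_log2_mean,
        cfg.control_spot_log2_sd,
        size=(cfg.n_control_spots, len(samples)),
    )
    control = pd.DataFrame(
        spots, index=pd.Index([f"CTRL{i:04d}" for i in range(cfg.n_control_spots)], name="spot"),
        columns=samples,
    )

    n_drop = int(round(cfg.dropout_fraction * len(probe_ids)))
    if n_drop > 0:
        thresholds = 1.5 * control.quantile(0.9, axis=0)
        drop_idx = rng.choice(len(probe_ids), size=n_drop, replace=False)
        for p_i in drop_idx:
            t = cfg.treatments[int(rng.integers(0, len(cfg.treatments)))]
            for s in design.index[design["treatment"] == t]:
                signals.iloc[p_i, signals.columns.get_loc(s)] = float(
                    thresholds[s] * rng.uniform(0.05, 0.8)
                )
    return ExpressionDataset(signals=signals, design=design, control_spots=control)


@dataclass
class SpeciesData:
    """One plant–insect combination: its universe and expression dataset."""

    name: str
    universe: SpeciesUniverse
    expression: ExpressionDataset
    paired: bool


@dataclass
class Study:
    """A complete synthetic multi-species study with its ground truth."""

    config: SimulationConfig
    dag: nx.DiGraph
    ref_annotation: dict[str, frozenset[str]]  # direct terms, primary reference
    ref_annotation_closed: dict[str, frozenset[str]]
    secondary_annotation: dict[str, frozenset[str]]  # direct terms, secondary reference
    species: list[SpeciesData]
    truth: GroundTruth


def simulate_study(cfg: SimulationConfig) -> Study:
    """Generate the whole study: ontology, references, species, signals.

    The ontology carries ``n_go_terms`` shared terms plus a handful of
    secondary-only terms that never occur in the primary reference
    annotation (they exercise the comparability rule that removes
    secondary-specific terms during transfer).  One combination (by default
    the fourth) is simulated with a block-paired design.
    """
    n_terms_total = cfg.n_go_terms + cfg.n_secondary_only_terms
    dag = generate_go_dag(n_terms_total, cfg.max_parents, cfg.seed)
    all_terms = [f"GO:{i + 1:07d}" for i in range(n_terms_total)]
    secondary_only = set(all_terms[cfg.n_go_terms:])

    ref_annot = generate_reference_annotation(
        dag, cfg.n_ref_genes, cfg.terms_per_gene, cfg.seed, excluded_terms=secondary_only
    )
    ref_closed = close_annotation(dag, ref_annot)

    sec_rng = _rng(cfg.seed, _SEC_ANNOT)
    sec_only_sorted = sorted(secondary_only)
    secondary_annot: dict[str, frozenset[str]] = {}
    for j, ref in enumerate(sorted(ref_annot)):
        terms = set(ref_annot[ref])
        if sec_only_sorted and sec_rng.random() < 0.1:
            terms.add(sec_only_sorted[int(sec_rng.integers(0, len(sec_only_sorted)))])
        secondary_annot[f"ALT{j:05d}"] = frozenset(terms)

    universes = [
        generate_species_universe(cfg, dag, ref_annot, i) for i in range(cfg.n_species)
    ]
    truth = GroundTruth(
        planted_up={c: frozenset(t) for c, t in cfg.planted_terms_up.items()},
        planted_down={c: frozenset(t) for c, t in cfg.planted_terms_down.items()},
        gene_maps={u.species: dict(u.gene_map) for u in universes},
        secondary_maps={u.species: dict(u.secondary_map) for u in universes},
    )
    # effects are biological: driven by the gene's true reference identity,
    # known for every gene (homology detection only affects annotation)
    full_maps = {
        f"sp{i + 1}": {
            f"S{i + 1}G{j:05d}": f"REF{j:05d}" for j in range(cfg.n_ref_genes)
        }
        for i in range(cfg.n_species)
    }
    truth_full = GroundTruth(
        planted_up=truth.planted_up,
        planted_down=truth.planted_down,
        gene_maps=full_maps,
        secondary_maps=truth.secondary_maps,
    )

    species_data = []
    for i, uni in enumerate(universes):
        paired = i in cfg.paired_species
        cfg_i = replace(cfg, paired=paired)
        ds = simulate_expression(cfg_i, ref_closed, truth_full, species_index=i)
        species_data.append(SpeciesData(name=uni.species, universe=uni, expression=ds, paired=paired))
    return Study(
        config=cfg,
        dag=dag,
        ref_annotation=ref_annot,
        ref_annotation_closed=ref_closed,
        secondary_annotation=secondary_annot,
        species=species_data,
        truth=truth,
    )
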