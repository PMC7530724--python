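"""Meta-classification of enrichment results across plant–insect combinations.

Enrichment tables from several species × insect combinations (each possibly
observed at several harvest time points) are restricted to the gene sets
tested in *all* of them, flagged significant per combination at a strict
FDR cut-off, and classified as *conformable* when significant in at least
k of the n combinations.  Conformable sets of the egg and the feeding
contrasts intersect to the *analogous* response, and analogous sets that are
additionally conformable in the egg-modified feeding contrast (EF vs F) form
the egg-enhanced core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, UndefinedFractionError

__all__ = [
    "CombinationResult",
    "ConformabilityRule",
    "ConformabilityResult",
    "common_universe",
    "significant_in_combination",
    "classify_conformable",
    "overlap_fraction",
    "overlap_analysis",
    "fdr_matrix",
]


@dataclass
class CombinationResult:
    """All enrichment tables of one plant–insect combination.

    ``tables`` maps time-point id → contrast name → enrichment table (the
    DataFrame produced by :func:`xgage.enrich.run_gage`).  Single-harvest
    combinations simply use one time point.
    """

    combination: str
    tables: dict[str, dict[str, pd.DataFrame]]

    def __post_init__(self) -> None:
        if not self.tables:
            raise ConfigError(f"combination {self.combination!r} has no time points")

    @property
    def timepoints(self) -> list[str]:
        return list(self.tables)

    def table(self, timepoint: str, contrast: str) -> pd.DataFrame:
        return self.tables[timepoint][contrast]

    def terms(self, contrast: str, timepoint: str) -> frozenset[str]:
        tab = self.tables[timepoint].get(contrast)
        if tab is None or len(tab) == 0:
            return frozenset()
        return frozenset(tab["term"])

    def fdr(self, term: str, contrast: str, direction: str, timepoint: str) -> float | None:
        tab = self.tables[timepoint].get(contrast)
        if tab is None:
            return None
        rows = tab.loc[(tab["term"] == term) & (tab["direction"] == direction), "fdr"]
        if len(rows) == 0:
            return None
        return float(rows.iloc[0])


@dataclass(frozen=True)
class ConformabilityRule:
    """k-of-n significance rule with its FDR cut-off.

    ``timepoint_mode`` decides whether a multi-time-point combination counts
    as significant when *any* of its time points is (default) or only when
    all are.
    """

    k: int
    n: int
    alpha: float = 0.05
    timepoint_mode: str = "any"

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.n:
            raise ConfigError(f"need 1 <= k <= n, got k={self.k}, n={self.n}")
        if self.timepoint_mode not in ("any", "all"):
            raise ConfigError("timepoint_mode must be 'any' or 'all'")


def common_universe(results: Sequence[CombinationResult], contrast: str) -> frozenset[str]:
    """Gene sets tested in every combination and every time point."""
    if len(results) < 2:
        raise ConfigError("common universe needs at least two combinations")
    universe: frozenset[str] | None = None
    for res in results:
        for tp in res.timepoints:
            terms = res.terms(contrast, tp)
            universe = terms if universe is None else universe & terms
    return universe if universe is not None else frozenset()


def significant_in_combination(
    result: CombinationResult,
    term: str,
    contrast: str,
    direction: str,
    alpha: float = 0.05,
    timepoint_mode: str = "any",
) -> bool:
    """Strict FDR < alpha, across time points per ``timepoint_mode``."""
    flags = []
    for tp in result.timepoints:
        fdr = result.fdr(term, contrast, direction, tp)
        flags.append(fdr is not None and fdr < alpha)
    return any(flags) if timepoint_mode == "any" else all(flags)


def classify_conformable(
    results: Sequence[CombinationResult],
    contrast: str,
    direction: str,
    rule: ConformabilityRule,
) -> tuple[frozenset[str], frozenset[str]]:
    """Significant-in-any and conformable (k-of-n) gene sets for a contrast.

    Both sets are drawn from the common universe; a set is conformable when
    significant in at least ``rule.k`` of the ``rule.n`` combinations.
    """
    if rule.n != len(results):
        raise ConfigError(f"rule expects n={rule.n} combinations, got {len(results)}")
    universe = common_universe(results, contrast)
    significant_any: set[str] = set()
    conformable: set[str] = set()
    for term in universe:
        votes = sum(
            significant_in_combination(
                res, term, contrast, direction, rule.alpha, rule.timepoint_mode
            )
            for res in results
        )
        if votes >= 1:
            significant_any.add(term)
        if votes >= rule.k:
            conformable.add(term)
    return frozenset(significant_any), frozenset(conformable)


def overlap_fraction(subset_count: int, total_count: int) -> int:
    """Integer percentage, rounded half away from zero."""
    if total_count <= 0:
        raise UndefinedFractionError("total count must be positive")
    if not 0 <= subset_count <= total_count:
        raise ValueError("need 0 <= subset_count <= total_count")
    return int(math.floor(100.0 * subset_count / total_count + 0.5))


@dataclass
class ConformabilityResult:
    """Analogous/enhanced classification of conformable gene sets.

    ``venn`` holds the seven exclusive region counts of the E, F and
    EF-vs-F conformable sets; fraction metrics are integer percentages and
    ``None`` when their denominator is empty.
    """

    direction: str
    conformable_e: frozenset[str]
    conformable_f: frozenset[str]
    conformable_ef_vs_f: frozenset[str]
    analogous: frozenset[str]
    enhanced_core: frozenset[str]
    venn: dict[str, int] = field(default_factory=dict)
    enhanced_of_analogous_pct: int | None = None
    analogous_of_f_pct: int | None = None


def overlap_analysis(
    conformable_e: Iterable[str],
    conformable_f: Iterable[str],
    conformable_ef_vs_f: Iterable[str],
    direction: str = "up",
) -> ConformabilityResult:
    """Intersect the three conformable sets into analogous and enhanced cores.

    ``analogous`` = conformable in both E vs C and F vs C; ``enhanced_core``
    = analogous sets also conformable in EF vs F (feeding response amplified
    by prior egg deposition).  Also reports all exclusive Venn region counts
    of the three sets.
    """
    e = frozenset(conformable_e)
    f = frozenset(conformable_f)
    ef = frozenset(conformable_ef_vs_f)
    analogous = e & f
    enhanced = analogous & ef
    venn = {
        "E_only": len(e - f - ef),
        "F_only": len(f - e - ef),
        "EFvsF_only": len(ef - e - f),
        "E_and_F_only": len((e & f) - ef),
        "E_and_EFvsF_only": len((e & ef) - f),
        "F_and_EFvsF_only": len((f & ef) - e),
        "E_and_F_and_EFvsF": len(e & f & ef),
    }
    return ConformabilityResult(
        direction=direction,
        conformable_e=e,
        conformable_f=f,
        conformable_ef_vs_f=ef,
        analogous=analogous,
        enhanced_core=enhanced,
        venn=venn,
        enhanced_of_analogous_pct=(
            overlap_fraction(len(enhanced), len(analogous)) if analogous else None
        ),
        analogous_of_f_pct=(overlap_fraction(len(analogous), len(f)) if f else None),
    )


def fdr_matrix(
    results: Sequence[CombinationResult],
    contrast: str,
    direction: str,
    terms: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Wide FDR table: rows = gene sets, columns = combination/time point."""
    if terms is None:
        terms = sorted(common_universe(results, contrast))
    else:
        terms = list(terms)
    data: dict[str, list[float | None]] = {}
    for res in results:
        for tp in res.timepoints:
            col = f"{res.combination}:{tp}" if len(res.timepoints) > 1 else res.combination
            data[col] = [res.fdr(t, contrast, direction, tp) for t in terms]
    out = pd.DataFrame(data, index=pd.Index(terms, name="term"))
    return out
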