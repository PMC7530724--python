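"""Raw-signal processing for one-colour microarray-like intensity data.

The processing chain mirrors common limma-style workflows on single-channel
arrays: a detection filter anchored on structural dark-corner control spots,
array background correction, between-array quantile normalisation, probe →
gene averaging, and a coefficient-of-variation filter that keeps the most
variable fraction of genes.  All steps operate on raw (positive) intensities;
downstream statistics work on log2 of the normalised gene matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .errors import DesignError, MissingControlsError

__all__ = [
    "ExpressionDataset",
    "PreprocessConfig",
    "PreprocessResult",
    "detection_threshold",
    "detection_thresholds",
    "filter_undetected",
    "background_correct",
    "quantile_normalize",
    "average_by_gene",
    "variance_filter",
    "preprocess_dataset",
]


@dataclass
class ExpressionDataset:
    """A probes × samples intensity matrix with its treatment design.

    Parameters
    ----------
    signals
        Non-negative intensities, rows indexed by probe id, columns by
        sample id.  Control spots are *not* part of this matrix; they live
        in ``control_spots``.
    design
        One row per sample (index = sample id) with a ``treatment`` column
        (labels such as C/E/F/EF) and an optional ``pair`` column for
        block-paired designs.
    control_spots
        Structural control-spot signals: a DataFrame (spots × samples, one
        column per array) or a Series (pooled across arrays).
    """

    signals: pd.DataFrame
    design: pd.DataFrame
    control_spots: pd.DataFrame | pd.Series | None = None

    def __post_init__(self) -> None:
        if "treatment" not in self.design.columns:
            raise DesignError("design must have a 'treatment' column")
        if list(self.signals.columns) != list(self.design.index):
            missing = set(self.signals.columns) ^ set(self.design.index)
            if missing:
                raise DesignError(f"samples in matrix and design differ: {sorted(missing)}")
            self.design = self.design.loc[self.signals.columns]
        if (self.signals.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")
        if "pair" in self.design.columns:
            pair = self.design["pair"]
            has = pair.notna() & (pair.astype(str) != "")
            if has.any() and not has.all():
                raise DesignError("either all samples carry a pair label or none")

    @property
    def treatments(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.design["treatment"]:
            seen.setdefault(t, None)
        return list(seen)

    def samples_for(self, treatment: str) -> list[str]:
        return list(self.design.index[self.design["treatment"] == treatment])

    @property
    def paired(self) -> bool:
        if "pair" not in self.design.columns:
            return False
        pair = self.design["pair"]
        return bool((pair.notna() & (pair.astype(str) != "")).all())


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable knobs of the signal-processing chain.

    ``detect_factor`` × Q(``detect_quantile``) of the control spots defines
    the per-array detection threshold (defaults 1.5 × 90 % quantile);
    ``keep_fraction`` is the fraction of genes kept by the CV filter.
    """

    detect_factor: float = 1.5
    detect_quantile: float = 0.90
    keep_fraction: float = 0.40
    log_base: int = 2
    background_offset: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.detect_quantile < 1.0:
            raise ValueError("detect_quantile must be in (0, 1)")
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.background_offset <= 0:
            raise ValueError("background_offset must be positive")


def detection_threshold(
    control_spots: np.ndarray | pd.Series,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> float:
    """Detection threshold from one array's control spots.

    Returns ``detect_factor`` times the ``detect_quantile`` quantile of the
    control-spot signals, the quantile computed by linear interpolation of
    order statistics (position ``1 + (n-1) q``; numpy's default).
    """
    spots = np.asarray(control_spots, dtype=float)
    if spots.size == 0:
        raise MissingControlsError("no control-spot signals supplied")
    return float(cfg.detect_factor * np.quantile(spots, cfg.detect_quantile))


def detection_thresholds(ds: ExpressionDataset, cfg: PreprocessConfig = PreprocessConfig()) -> pd.Series:
    """Per-sample detection thresholds (per array when per-array spots exist).

    Falls back to one pooled threshold applied to every sample when only a
    pooled control-spot vector is available.
    """
    if ds.control_spots is None:
        raise MissingControlsError("dataset has no control spots")
    if isinstance(ds.control_spots, pd.DataFrame):
        return pd.Series(
            {s: detection_threshold(ds.control_spots[s], cfg) for s in ds.signals.columns},
            name="threshold",
        )
    pooled = detection_threshold(ds.control_spots, cfg)
    return pd.Series(pooled, index=ds.signals.columns, name="threshold")


def filter_undetected(
    ds: ExpressionDataset, thresholds: pd.Series
) -> tuple[ExpressionDataset, pd.Index]:
    """Drop probes undetected in every sample of at least one treatment.

    A probe is removed iff there is a treatment group in which each sample's
    signal is strictly below that sample's threshold.  Returns the filtered
    dataset and the index of removed probes.
    """
    thresholds = thresholds.reindex(ds.signals.columns)
    if thresholds.isna().any():
        raise DesignError("thresholds missing for some samples")
    below = ds.signals.lt(thresholds, axis=1)
    removed_mask = pd.Series(False, index=ds.signals.index)
    for treatment in ds.treatments:
        cols = ds.samples_for(treatment)
        removed_mask |= below[cols].all(axis=1)
    removed = ds.signals.index[removed_mask]
    kept = ds.signals.loc[~removed_mask]
    return replace(ds, signals=kept), removed


def background_correct(
    ds: ExpressionDataset,
    cfg: PreprocessConfig = PreprocessConfig(),
    corrector: Callable[[pd.DataFrame, pd.DataFrame | pd.Series], pd.DataFrame] | None = None,
) -> ExpressionDataset:
    """Subtract a per-array background estimate, flooring at a small offset.

    The default estimate is the median control-spot signal of each array;
    subtraction preserves the within-array ordering of probes and the floor
    keeps every output strictly positive (so log transforms stay finite).
    A ``corrector`` callable may be supplied to plug in a different model
    (e.g. a normexp-style fit); it receives the signal matrix and the
    control spots and must return a corrected matrix.
    """
    if corrector is not None:
        corrected = corrector(ds.signals, ds.control_spots)
    else:
        if ds.control_spots is None:
            background = pd.Series(0.0, index=ds.signals.columns)
        elif isinstance(ds.control_spots, pd.DataFrame):
            background = ds.control_spots.median(axis=0).reindex(ds.signals.columns)
        else:
            background = pd.Series(
                float(np.median(np.asarray(ds.control_spots, dtype=float))),
                index=ds.signals.columns,
            )
        corrected = ds.signals.sub(background, axis=1)
    corrected = corrected.clip(lower=cfg.background_offset)
    return replace(ds, signals=corrected)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to share the same value distribution.

    Classic quantile normalisation: each column's i-th order statistic is
    replaced by the mean of all columns' i-th order statistics, preserving
    within-column rank order.  Idempotent.
    """
    a = matrix.to_numpy(dtype=float)
    if a.size == 0:
        return matrix.copy()
    order = np.argsort(a, axis=0, kind="stable")
    sorted_ = np.take_along_axis(a, order, axis=0)
    row_means = sorted_.mean(axis=1)
    out = np.empty_like(a)
    np.put_along_axis(out, order, np.broadcast_to(row_means[:, None], a.shape), axis=0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def average_by_gene(matrix: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse probes to genes by arithmetic mean per sample.

    ``probe_to_gene`` maps probe id → gene id; probes without a mapping are
    dropped, and a probe may map to at most one gene.
    """
    probe_to_gene = pd.Series(probe_to_gene)
    if probe_to_gene.index.has_duplicates:
        dupes = probe_to_gene.index[probe_to_gene.index.duplicated()].unique()
        raise ValueError(f"probes map to more than one gene: {list(dupes[:5])}")
    mapped = matrix.index.intersection(probe_to_gene.index)
    sub = matrix.loc[mapped]
    genes = probe_to_gene.loc[mapped]
    out = sub.groupby(genes).mean()
    out.index.name = "gene"
    return out.sort_index()


def cv_scores(matrix: pd.DataFrame) -> pd.Series:
    """Coefficient of variation (sd / mean) per row across all samples."""
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    scores = sd / mean
    scores = scores.where(mean != 0, 0.0)
    return scores.fillna(0.0)


def variance_filter(
    matrix: pd.DataFrame, cfg: PreprocessConfig = PreprocessConfig()
) -> tuple[pd.DataFrame, pd.Series]:
    """Keep the most variable fraction of genes by coefficient of variation.

    Retains the ``ceil(keep_fraction × n)`` genes with the highest sd/mean
    across all samples; ties are broken by gene id so the result is
    deterministic.  Returns the filtered matrix (original row order) and the
    CV score of every input gene.
    """
    if matrix.shape[0] < 1:
        raise ValueError("variance filter needs at least one gene")
    scores = cv_scores(matrix)
    n_keep = math.ceil(cfg.keep_fraction * matrix.shape[0])
    ranked = sorted(matrix.index, key=lambda g: (-scores[g], g))
    keep = set(ranked[:n_keep])
    return matrix.loc[matrix.index.isin(keep)], scores


@dataclass
class PreprocessResult:
    """Outcome of the full processing chain for one dataset."""

    matrix: pd.DataFrame  # genes × samples, normalised raw-scale intensities
    removed: pd.DataFrame  # probe/gene id with removal reason
    counts: dict = field(default_factory=dict)

    @property
    def log2_matrix(self) -> pd.DataFrame:
        return np.log2(self.matrix)


def preprocess_dataset(
    ds: ExpressionDataset,
    probe_to_gene: pd.Series,
    cfg: PreprocessConfig = PreprocessConfig(),
    skip_array_steps: bool = False,
) -> PreprocessResult:
    """Run the fixed processing chain on one dataset.

    Order: detection filter → background correction → quantile
    normalisation → probe averaging → CV filter.  ``skip_array_steps``
    enters the chain at probe averaging for data that arrive already
    normalised (e.g. pre-processed RNA-seq matrices).
    """
    removed_records: list[tuple[str, str]] = []
    counts: dict[str, int] = {"probes_in": int(ds.signals.shape[0])}

    if skip_array_steps:
        work = ds
        counts["probes_detected"] = int(work.signals.shape[0])
    else:
        thresholds = detection_thresholds(ds, cfg)
        work, dropped = filter_undetected(ds, thresholds)
        removed_records += [(p, "detection") for p in dropped]
        counts["probes_detected"] = int(work.signals.shape[0])
        work = background_correct(work, cfg)
        work = replace(work, signals=quantile_normalize(work.signals))

    genes = average_by_gene(work.signals, probe_to_gene)
    unmapped = work.signals.index.difference(pd.Series(probe_to_gene).index)
    removed_records += [(p, "unmapped") for p in unmapped]
    counts["genes_after_averaging"] = int(genes.shape[0])

    filtered, scores = variance_filter(genes, cfg)
    removed_records += [(g, "variance") for g in genes.index.difference(filtered.index)]
    counts["genes_after_variance_filter"] = int(filtered.shape[0])

    removed = pd.DataFrame(removed_records, columns=["id", "reason"])
    return PreprocessResult(matrix=filtered, removed=removed, counts=counts)
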