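"""GAGE-style gene-set enrichment on per-comparison fold changes.

For a pairwise treatment contrast, per-gene log2 fold changes are formed for
every one-on-one combination of a treatment and a reference sample (or for
each matched block in a paired design).  For every gene set and every
fold-change column, a Welch two-sample t statistic compares the set's fold
changes against the all-gene background; the resulting one-sided p-values
(tested separately for up- and for down-regulation) are combined across
columns with Stouffer's method and corrected across gene sets with
Benjamini–Hochberg FDR, separately per direction.

One-on-one fold-change columns built from the same replicates are not
independent: two columns sharing a treatment (or reference) sample have
correlation 1/2 under the null.  ``run_gage`` therefore standardises the
Stouffer z-sum by its exact design-implied null variance by default
(``correlation_adjust=True``), which keeps null p-values uniform for
unpaired designs and reduces to the plain 1/sqrt(k) scaling whenever the
columns are disjoint (e.g. paired designs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.sparse import csr_matrix
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, InvalidInputError

__all__ = [
    "Contrast",
    "FoldChangeMatrix",
    "pairwise_fold_changes",
    "set_t_statistic",
    "stouffer_combine",
    "bh_fdr",
    "run_gage",
]

P_CLAMP = 1e-15

#: Enrichment table column layout.
TABLE_COLUMNS = ["term", "direction", "size", "mean_t", "z", "p", "fdr", "n_pairs"]


@dataclass(frozen=True)
class Contrast:
    """A pairwise treatment comparison, e.g. E vs C."""

    name: str
    treatment: str
    reference: str
    paired: bool = False

    @classmethod
    def from_name(cls, name: str, paired: bool = False) -> "Contrast":
        try:
            treatment, reference = name.split("_vs_")
        except ValueError as exc:
            raise DesignError(f"contrast name {name!r} is not of the form ARM_vs_REF") from exc
        return cls(name=name, treatment=treatment, reference=reference, paired=paired)


@dataclass
class FoldChangeMatrix:
    """Per-gene log2 fold changes, one column per comparison.

    ``pairs`` records, per column, which (treatment sample, reference
    sample) produced it; for paired designs both entries of a pair are the
    block's own samples and the columns are mutually disjoint.
    """

    values: pd.DataFrame
    pairs: list[tuple[str, str]]
    paired: bool

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def null_z_variance(self) -> float:
        """Null variance of the sum of per-column z-scores.

        Columns ``t_i - r_j`` and ``t_i' - r_j'`` have correlation
        ``([i==i'] + [j==j'])/2`` under iid gene noise; disjoint columns are
        independent.  Returns ``k + 2 * sum of pairwise correlations``.
        """
        k = self.n_columns
        if self.paired:
            return float(k)
        var = float(k)
        for a in range(k):
            ta, ra = self.pairs[a]
            for b in range(a + 1, k):
                tb, rb = self.pairs[b]
                rho = (0.5 if ta == tb else 0.0) + (0.5 if ra == rb else 0.0)
                var += 2.0 * rho
        return var


def pairwise_fold_changes(
    matrix: pd.DataFrame, contrast: Contrast, design: pd.DataFrame
) -> FoldChangeMatrix:
    """Log2 fold-change columns for a contrast.

    ``matrix`` is the genes × samples log2 expression matrix.  Unpaired
    contrasts enumerate every ordered (treatment sample, reference sample)
    combination; paired contrasts form one column per pair label, each the
    within-block difference.
    """
    treat = [s for s in design.index if design.at[s, "treatment"] == contrast.treatment]
    ref = [s for s in design.index if design.at[s, "treatment"] == contrast.reference]
    if not treat or not ref:
        raise DesignError(
            f"contrast {contrast.name}: need samples in both arms "
            f"({contrast.treatment}: {len(treat)}, {contrast.reference}: {len(ref)})"
        )
    cols: dict[str, np.ndarray] = {}
    pairs: list[tuple[str, str]] = []
    if contrast.paired:
        if "pair" not in design.columns:
            raise DesignError("paired contrast requires a 'pair' column in the design")
        t_by_pair = {str(design.at[s, "pair"]): s for s in treat}
        r_by_pair = {str(design.at[s, "pair"]): s for s in ref}
        if len(t_by_pair) != len(treat) or len(r_by_pair) != len(ref):
            raise DesignError("duplicate pair labels within one arm")
        if set(t_by_pair) != set(r_by_pair):
            raise DesignError(
                f"pair labels do not form complete blocks: "
                f"{sorted(set(t_by_pair) ^ set(r_by_pair))}"
            )
        for label in sorted(t_by_pair):
            t, r = t_by_pair[label], r_by_pair[label]
            cols[f"pair:{label}"] = matrix[t].to_numpy() - matrix[r].to_numpy()
            pairs.append((t, r))
    else:
        for t in treat:
            for r in ref:
                cols[f"{t}|{r}"] = matrix[t].to_numpy() - matrix[r].to_numpy()
                pairs.append((t, r))
    values = pd.DataFrame(cols, index=matrix.index)
    return FoldChangeMatrix(values=values, pairs=pairs, paired=contrast.paired)


def _membership(genes: pd.Index, gene_sets: Mapping[str, frozenset]) -> tuple[list[str], csr_matrix]:
    """Sparse set × gene indicator matrix over the matrix's gene order."""
    pos = {g: i for i, g in enumerate(genes)}
    terms = sorted(gene_sets)
    rows, cols_idx = [], []
    for i, t in enumerate(terms):
        for g in gene_sets[t]:
            j = pos.get(g)
            if j is not None:
                rows.append(i)
                cols_idx.append(j)
    data = np.ones(len(rows))
    member = csr_matrix((data, (rows, cols_idx)), shape=(len(terms), len(genes)))
    return terms, member


def _welch_vs_background(
    fc: np.ndarray, member: csr_matrix, set_vs_complement: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch t of each set's fold changes against the background, per column.

    Returns (t, df, n_set); shapes (n_sets, k).  Background is all genes by
    default (the set included), or the set's complement when requested.
    """
    n = fc.shape[0]
    n_s = np.asarray(member.sum(axis=1)).ravel()  # genes per set
    s_sum = member @ fc
    s_sumsq = member @ (fc * fc)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_s = s_sum / n_s[:, None]
        var_s = (s_sumsq - s_sum * mean_s) / (n_s[:, None] - 1)
    var_s = np.clip(var_s, 0.0, None)

    col_sum = fc.sum(axis=0)
    col_sumsq = (fc * fc).sum(axis=0)
    if set_vs_complement:
        n_b = (n - n_s)[:, None]
        b_sum = col_sum[None, :] - s_sum
        b_sumsq = col_sumsq[None, :] - s_sumsq
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_b = b_sum / n_b
            var_b = np.clip((b_sumsq - b_sum * mean_b) / (n_b - 1), 0.0, None)
    else:
        n_b = np.full((len(n_s), 1), float(n))
        mean_b = (col_sum / n)[None, :]
        var_b = (np.clip((col_sumsq - col_sum * (col_sum / n)), 0.0, None) / (n - 1))[None, :]

    a = var_s / n_s[:, None]
    b = var_b / n_b
    se2 = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean_s - mean_b) / np.sqrt(se2)
        df = se2 * se2 / (a * a / (n_s[:, None] - 1) + b * b / (n_b - 1))
    zero = se2 == 0
    t = np.where(zero | ~np.isfinite(t), 0.0, t)
    df = np.where(~np.isfinite(df) | (df <= 0), 1.0, df)
    return t, df, n_s


def _one_sided_p(t: np.ndarray, df: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clamped upper- and lower-tail p-values of t under Student's t(df)."""
    p_up = special.stdtr(df, -t)
    p_down = special.stdtr(df, t)
    clip = lambda p: np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    return clip(p_up), clip(p_down)


def set_t_statistic(
    fc_column: pd.Series, set_genes: Sequence[str] | frozenset
) -> tuple[float, float, float]:
    """Welch t (and one-sided p-values) of one set against the background.

    Compares the fold changes of ``set_genes`` with those of *all* genes in
    the column.  Returns (t, p_up, p_down); a degenerate comparison (zero
    variance everywhere) yields (0, 0.5, 0.5).
    """
    set_genes = frozenset(set_genes)
    if len(set_genes) < 2:
        raise InvalidInputError("set_t_statistic needs at least two set genes")
    fc = fc_column.to_numpy(dtype=float)[:, None]
    terms, member = _membership(fc_column.index, {"set": set_genes})
    t, df, _ = _welch_vs_background(fc, member)
    p_up, p_down = _one_sided_p(t, df)
    return float(t[0, 0]), float(p_up[0, 0]), float(p_down[0, 0])


def stouffer_combine(p_values: Sequence[float] | np.ndarray) -> float:
    """Combine one-sided p-values: z_i = Phi^-1(1-p_i), z = sum(z_i)/sqrt(k)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InvalidInputError("no p-values to combine")
    if not np.isfinite(p).all() or (p <= 0).any() or (p >= 1).any():
        raise InvalidInputError("p-values must lie strictly in (0, 1)")
    z = stats.norm.isf(p)
    return float(stats.norm.sf(z.sum() / np.sqrt(p.size)))


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_gage(
    matrix: pd.DataFrame,
    gene_sets: Mapping[str, frozenset],
    contrast: Contrast,
    design: pd.DataFrame,
    correlation_adjust: bool = True,
    set_vs_complement: bool = False,
) -> pd.DataFrame:
    """Gene-set enrichment table for one contrast.

    Per fold-change column each set is Welch-tested against the all-gene
    background; one-sided p-values are Stouffer-combined across columns
    (standardised by the design-implied null variance of the z-sum unless
    ``correlation_adjust`` is off) and BH-corrected across sets, separately
    for the up and down directions.

    Returns a DataFrame with columns term, direction, size, mean_t, z, p,
    fdr, n_pairs.
    """
    if not gene_sets:
        warnings.warn("no gene sets to test; returning an empty table", stacklevel=2)
        return pd.DataFrame(columns=TABLE_COLUMNS)
    fcm = pairwise_fold_changes(matrix, contrast, design)
    fc = fcm.values.to_numpy(dtype=float)
    terms, member = _membership(matrix.index, gene_sets)
    t, df, n_s = _welch_vs_background(fc, member, set_vs_complement=set_vs_complement)
    p_up, p_down = _one_sided_p(t, df)

    k = fcm.n_columns
    denom = np.sqrt(fcm.null_z_variance() if correlation_adjust else float(k))
    blocks = []
    for direction, p_mat in (("up", p_up), ("down", p_down)):
        z = stats.norm.isf(p_mat).sum(axis=1) / denom
        p_comb = stats.norm.sf(z)
        blocks.append(
            pd.DataFrame(
                {
                    "term": terms,
                    "direction": direction,
                    "size": n_s.astype(int),
                    "mean_t": t.mean(axis=1),
                    "z": z,
                    "p": p_comb,
                    "fdr": bh_fdr(p_comb),
                    "n_pairs": k,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)
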