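"""Single-gene and mean-signature statistics linking expression to response.

The core statistic is the rank-based ROC AUC with the resistant class as
positive and expression as score.  Raw AUC times the two group sizes equals
the Mann-Whitney U statistic of the resistant group (midrank convention), so
the AUC's p-value is the two-sided Mann-Whitney p.  Reported AUCs are folded
to >= 0.5 with an explicit direction flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datastore import ExpressionMatrix
from .errors import ValidationError
from .response import RESISTANT, SENSITIVE, ResponseLabeling

HIGHER_IN_RESISTANT = "higher_in_resistant"
HIGHER_IN_SENSITIVE = "higher_in_sensitive"
NO_DIRECTION = "none"


@dataclass
class BiomarkerStat:
    """Per-gene association statistics for one compound in one dataset."""

    gene: str
    n_sensitive: int
    n_resistant: int
    auc: float
    direction: str
    mw_p: float
    spearman_rho: float | None = None
    spearman_p: float | None = None
    fdr_q: float | None = None


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for x, p).

    Exact p when both groups have <= 20 observations and there are no ties,
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError(f"each group needs >= 2 values, got {len(x)} and {len(y)}")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:  # all values identical: U at its null mean
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def rank_u(scores_positive, scores_negative) -> float:
    """Midrank Mann-Whitney U of the positive group (no p-value)."""
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float(ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0)


def raw_auc(scores_positive, scores_negative) -> float:
    """P(score_positive > score_negative) + 0.5 * P(equal), via midranks.

    Equals U / (n_pos * n_neg) for the midrank U of the positive group.
    """
    return rank_u(scores_positive, scores_negative) / (
        len(scores_positive) * len(scores_negative))


def roc_auc(expression: dict[str, float], labeling: ResponseLabeling,
            gene: str = "") -> BiomarkerStat:
    """Folded ROC AUC + direction + Mann-Whitney p for one gene.

    Resistant is the positive class and expression the score; cell lines
    lacking expression are dropped with a warning unless they exceed half the
    labeled lines, which is an error.
    """
    labeled = [cl for cl, lab in labeling.labels.items() if lab in (SENSITIVE, RESISTANT)]
    with_expr = [cl for cl in labeled if cl in expression]
    n_missing = len(labeled) - len(with_expr)
    if labeled and n_missing > len(labeled) / 2:
        raise ValidationError(
            f"expression missing for {n_missing}/{len(labeled)} labeled cell lines"
        )
    if n_missing:
        warnings.warn(f"{n_missing} labeled cell line(s) without expression dropped")
    sens = [expression[cl] for cl in with_expr if labeling.labels[cl] == SENSITIVE]
    res = [expression[cl] for cl in with_expr if labeling.labels[cl] == RESISTANT]
    if len(sens) < 2 or len(res) < 2:
        raise ValidationError(
            f"need >= 2 cell lines per class with expression, got "
            f"{len(sens)} sensitive / {len(res)} resistant"
        )
    a = raw_auc(res, sens)
    _, p = mann_whitney(res, sens)
    if a > 0.5:
        direction = HIGHER_IN_RESISTANT
    elif a < 0.5:
        direction = HIGHER_IN_SENSITIVE
    else:
        direction = NO_DIRECTION
    return BiomarkerStat(gene=gene, n_sensitive=len(sens), n_resistant=len(res),
                         auc=max(a, 1.0 - a), direction=direction, mw_p=p)


def spearman_vs_response(expression: dict[str, float],
                         audrc: dict[str, float]) -> tuple[float, float]:
    """Spearman rho/p between expression and response over all shared cell
    lines (not only the tertile-labeled ones)."""
    shared = sorted(set(expression) & set(audrc))
    if len(shared) < 4:
        raise ValidationError(f"need >= 4 shared cell lines, got {len(shared)}")
    x = [expression[cl] for cl in shared]
    y = [audrc[cl] for cl in shared]
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def mean_signature(genes: list[str], m: ExpressionMatrix) -> dict[str, float]:
    """Per-cell-line arithmetic mean of the listed genes' expression.

    Genes absent from the matrix are skipped with a warning; an entirely
    absent list is an error naming the misses.
    """
    present = [g for g in genes if g in set(m.genes)]
    missing = [g for g in genes if g not in set(m.genes)]
    if not present:
        raise ValidationError(f"none of the listed genes are in the matrix: {missing}")
    if missing:
        warnings.warn(f"genes absent from matrix skipped: {missing}")
    idx = [m.genes.index(g) for g in present]
    means = m.values[idx].mean(axis=0)
    return dict(zip(m.cell_lines, means))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_screen(m: ExpressionMatrix, labeling: ResponseLabeling,
                audrc: dict[str, float] | None = None,
                genes: list[str] | None = None) -> list[BiomarkerStat]:
    """Screen genes against a labeling: folded AUC, direction, Mann-Whitney p,
    Spearman rho vs response, and BH q over the screened set.

    Returns stats sorted by AUC descending, ties broken by gene symbol.
    """
    labeled = {cl for cl, lab in labeling.labels.items() if lab in (SENSITIVE, RESISTANT)}
    if len(labeled & set(m.cell_lines)) < 6:
        raise ValidationError("labeling and matrix share fewer than 6 labeled cell lines")
    if genes is None:
        screened = list(m.genes)
    else:
        in_matrix = set(m.genes)
        screened = [g for g in genes if g in in_matrix]
        absent = [g for g in genes if g not in in_matrix]
        if absent:
            warnings.warn(f"genes absent from matrix skipped: {absent}")
        if not screened:
            raise ValidationError(f"no requested gene is in the matrix: {absent}")

    idx = {g: i for i, g in enumerate(m.genes)}
    stats_out: list[BiomarkerStat] = []
    for g in screened:
        expr = dict(zip(m.cell_lines, m.values[idx[g]]))
        stat = roc_auc(expr, labeling, gene=g)
        if audrc is not None and len(set(expr) & set(audrc)) >= 4:
            stat.spearman_rho, stat.spearman_p = spearman_vs_response(expr, audrc)
        stats_out.append(stat)
    qvals = bh_fdr([s.mw_p for s in stats_out])
    for s, q in zip(stats_out, qvals):
        s.fdr_q = float(q)
    stats_out.sort(key=lambda s: (-s.auc, s.gene))
    return stats_out


def correlation_matrix(m: ExpressionMatrix, screen: list[BiomarkerStat],
                       audrc: dict[str, float],
                       ic50: dict[str, float] | None = None,
                       rho_threshold: float = 0.20,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlation matrix over response metrics and retained genes.

    A gene is retained when its screen Mann-Whitney p < ``alpha`` and its
    |Spearman rho vs AUDRC| >= ``rho_threshold``.
    """
    retained = [s.gene for s in screen
                if s.mw_p < alpha and s.spearman_rho is not None
                and abs(s.spearman_rho) >= rho_threshold]
    if not retained:
        warnings.warn("no gene passes the significance and correlation filters")
        return pd.DataFrame()
    cols: dict[str, dict[str, float]] = {"AUDRC": audrc}
    if ic50:
        cols["IC50"] = ic50
    idx = {g: i for i, g in enumerate(m.genes)}
    for g in retained:
        cols[g] = dict(zip(m.cell_lines, m.values[idx[g]]))
    df = pd.DataFrame(cols)
    corr = df.corr(method="spearman")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def stats_to_frame(screen: list[BiomarkerStat]) -> pd.DataFrame:
    """Screen results as a tidy table (the CLI's stats TSV layout)."""
    return pd.DataFrame(
        [{"gene": s.gene, "n_sensitive": s.n_sensitive, "n_resistant": s.n_resistant,
          "auc": s.auc, "direction": s.direction, "mw_p": s.mw_p,
          "spearman_rho": s.spearman_rho, "spearman_p": s.spearman_p, "fdr_q": s.fdr_q}
         for s in screen]
    )
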