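"""Per-sample EMT scoring via the signed two-sample Kolmogorov-Smirnov statistic.

Within one sample, every gene is ranked by expression (ascending, mid-ranks
for ties). The empirical cumulative distribution functions of the Epi and the
Mes signature genes are compared on this shared rank axis. The EMT score is
the signed supremum deviation:

    score = +sup(ECDF_Epi - ECDF_Mes)   if that supremum dominates,
            -sup(ECDF_Mes - ECDF_Epi)   otherwise (exact tie -> 0).

Highly expressed Mes genes sit at high ranks, so ECDF_Epi rises first and the
score is positive: positive = mesenchymal-like, negative = epithelial-like,
with |score| equal to the classical two-sample KS statistic D. Samples are
segregated four ways by the sign and the KS test p-value: Mes (score > 0,
p < threshold), intermediate-Mes (score > 0, p >= threshold), and
symmetrically on the Epi side; a score of exactly 0 is intermediate-Epi
(documented tie rule).
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import CoverageError, EMTSignature, ExpressionMatrix, ScoreResult

logger = logging.getLogger("emtscore")

DEFAULT_P_THRESHOLD = 0.05
STRICT_P_THRESHOLD = 0.001  # stricter segregation threshold also in use
MIN_GENES_DEFAULT = 3
EXACT_P_MAX_TOTAL = 20  # exhaustive permutation null only for small sets


def rank_sample(matrix: ExpressionMatrix, sample_id: str) -> pd.Series:
    """Within-sample expression ranks (1 = lowest; ties get mid-ranks).

    Genes with a missing value in this sample are excluded from its ranking.
    """
    col = matrix.sample(sample_id).dropna()
    if len(col) < 2:
        raise ValueError(f"sample {sample_id!r} has <2 genes with values")
    ranks = stats.rankdata(col.to_numpy(), method="average")
    return pd.Series(ranks, index=col.index, name=sample_id)


def signed_ks(epi_positions: np.ndarray, mes_positions: np.ndarray
              ) -> tuple[float, float]:
    """Signed supremum ECDF deviation and the unsigned KS statistic D.

    Returns ``(score, d)`` where ``score = sup(ECDF_Epi - ECDF_Mes)`` when
    that supremum is strictly the larger one, the negated opposite supremum
    when it is not, and 0.0 on an exact tie; ``d = max`` of the two suprema.
    """
    e = np.sort(np.asarray(epi_positions, dtype=float))
    m = np.sort(np.asarray(mes_positions, dtype=float))
    if e.size == 0 or m.size == 0:
        raise ValueError("both gene sets must be non-empty")
    grid = np.concatenate([e, m])
    grid.sort(kind="mergesort")
    cdf_e = np.searchsorted(e, grid, side="right") / e.size
    cdf_m = np.searchsorted(m, grid, side="right") / m.size
    diff = cdf_e - cdf_m
    d_plus = float(diff.max())   # sup(ECDF_Epi - ECDF_Mes)
    d_minus = float(-diff.min())  # sup(ECDF_Mes - ECDF_Epi)
    d = max(d_plus, d_minus, 0.0)
    if math.isclose(d_plus, d_minus, rel_tol=0.0, abs_tol=1e-12):
        return 0.0, d
    return (d_plus if d_plus > d_minus else -d_minus), d


def ks_pvalue(d_stat: float, n_epi: int, n_mes: int, exact: bool = False) -> float:
    """Two-sided p-value for a two-sample KS statistic.

    Default: asymptotic Kolmogorov distribution at effective size
    ``n_epi * n_mes / (n_epi + n_mes)``. With ``exact=True`` (only for
    ``n_epi + n_mes <= 20``), the exhaustive permutation distribution of D
    over all label assignments of distinct ranks is used.
    """
    if not 0.0 <= d_stat <= 1.0:
        raise ValueError(f"d_stat {d_stat} outside [0, 1]")
    if n_epi < 1 or n_mes < 1:
        raise ValueError("n_epi and n_mes must be >= 1")
    if exact:
        total = n_epi + n_mes
        if total > EXACT_P_MAX_TOTAL:
            raise ValueError(
                f"exact p-value limited to n_epi+n_mes <= {EXACT_P_MAX_TOTAL}"
            )
        positions = np.arange(1, total + 1, dtype=float)
        count = 0
        n_total = 0
        for combo in combinations(range(total), n_epi):
            epi = positions[list(combo)]
            mask = np.ones(total, dtype=bool)
            mask[list(combo)] = False
            _, d = signed_ks(epi, positions[mask])
            n_total += 1
            if d >= d_stat - 1e-12:
                count += 1
        return count / n_total
    en = n_epi * n_mes / (n_epi + n_mes)
    return float(np.clip(special.kolmogorov(d_stat * math.sqrt(en)), 0.0, 1.0))


def classify(emt_score: float, ks_p: float,
             p_threshold: float = DEFAULT_P_THRESHOLD) -> str:
    """Four-way Epi / intermediate-Epi / intermediate-Mes / Mes segregation."""
    if not 0.0 < p_threshold < 1.0:
        raise ValueError(f"p_threshold {p_threshold} outside (0, 1)")
    if emt_score > 0:
        return "Mes" if ks_p < p_threshold else "intermediate-Mes"
    if emt_score < 0:
        return "Epi" if ks_p < p_threshold else "intermediate-Epi"
    return "intermediate-Epi"  # score exactly 0: Epi-side tie rule


def emt_score(matrix: ExpressionMatrix, sample_id: str, signature: EMTSignature,
              p_threshold: float = DEFAULT_P_THRESHOLD,
              min_genes: int = MIN_GENES_DEFAULT,
              exact_p: bool = False) -> ScoreResult:
    """Signed 2KS EMT score of one sample against an Epi/Mes signature."""
    ranks = rank_sample(matrix, sample_id)
    epi_r = ranks.reindex([g for g in signature.epi_genes if g in ranks.index])
    mes_r = ranks.reindex([g for g in signature.mes_genes if g in ranks.index])
    n_epi, n_mes = len(epi_r), len(mes_r)
    if n_epi < min_genes or n_mes < min_genes:
        raise CoverageError(
            f"sample {sample_id!r}: only {n_epi} Epi and {n_mes} Mes signature "
            f"genes present (floor {min_genes} each)"
        )
    for side, found, total in (("Epi", n_epi, len(signature.epi_genes)),
                               ("Mes", n_mes, len(signature.mes_genes))):
        if found < 0.5 * total:
            logger.warning("sample %r: only %d/%d %s signature genes found",
                           sample_id, found, total, side)
    score, d = signed_ks(epi_r.to_numpy(), mes_r.to_numpy())
    p = ks_pvalue(d, n_epi, n_mes, exact=exact_p)
    return ScoreResult(
        sample_id=sample_id,
        emt_score=score,
        ks_pvalue=p,
        klass=classify(score, p, p_threshold),
        n_epi_used=n_epi,
        n_mes_used=n_mes,
    )


def score_matrix(matrix: ExpressionMatrix, signature: EMTSignature,
                 p_threshold: float = DEFAULT_P_THRESHOLD,
                 min_genes: int = MIN_GENES_DEFAULT,
                 exact_p: bool = False) -> list[ScoreResult]:
    """Score every sample; coverage failures yield flagged records, not aborts."""
    results: list[ScoreResult] = []
    for sid in matrix.sample_ids:
        try:
            results.append(emt_score(matrix, sid, signature,
                                     p_threshold=p_threshold,
                                     min_genes=min_genes, exact_p=exact_p))
        except (CoverageError, ValueError) as exc:
            logger.warning("sample %r flagged: %s", sid, exc)
            results.append(ScoreResult(sample_id=sid, emt_score=None,
                                       ks_pvalue=None, klass=None,
                                       n_epi_used=0, n_mes_used=0,
                                       error=str(exc)))
    return results


def scores_to_frame(results: Sequence[ScoreResult]) -> pd.DataFrame:
    """Tabulate ScoreResults (one row per sample, order preserved)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "emt_score": [r.emt_score for r in results],
            "ks_pvalue": [r.ks_pvalue for r in results],
            "class": [r.klass for r in results],
            "n_epi_used": [r.n_epi_used for r in results],
            "n_mes_used": [r.n_mes_used for r in results],
            "error": [r.error for r in results],
        }
    )


def spearman_association(scores: Sequence[float], covariate: Sequence[float]
                         ) -> tuple[float, float]:
    """Spearman rho (two-sided p) between scores and a per-sample covariate.

    Pairs with a missing value on either side are dropped; >=3 complete pairs
    are required. This is the association used to relate EMT scores to drug
    IC50 values or other continuous phenotypes.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape:
        raise ValueError("scores and covariate must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    if keep.sum() < 3:
        raise ValueError(f"need >=3 complete pairs, got {int(keep.sum())}")
    rho, p = stats.spearmanr(x[keep], y[keep])
    return float(rho), float(p)


def mannwhitney_groups(scores: Sequence[float], labels: Sequence[object]
                       ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing scores between two label groups.

    Used e.g. to compare spindle- vs non-spindle-morphology score
    distributions. With identical values in both groups the statistic is
    degenerate and the maximal p-value 1.0 is returned.
    """
    x = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    levels = pd.unique(lab)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    a, b = x[lab == levels[0]], x[lab == levels[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        return float(a.size * b.size / 2.0), 1.0
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(u), float(min(p, 1.0))
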