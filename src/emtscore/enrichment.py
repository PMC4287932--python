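"""Single-sample gene-set enrichment (ssGSEA) scores.

Genes are ordered by descending expression within one sample. Two running
cumulative distributions are walked down that list: ``P_in`` accumulates
weighted mass over in-set genes (weight = within-sample ascending mid-rank
raised to the exponent ``alpha``, normalized to sum to 1) and ``P_out``
accumulates uniform mass over out-of-set genes. The enrichment score is the
sum of ``P_in - P_out`` over all positions, positive when the set's genes
concentrate at high expression. With ``alpha = 0`` the score is a pure rank
statistic (invariant under any strictly increasing transform of expression).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSet
from .scoring import spearman_association

DEFAULT_ALPHA = 0.25


@dataclass(frozen=True)
class EnrichmentResult:
    sample_id: str
    set_name: str
    es: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.es):
            raise ValueError(f"non-finite enrichment score for {self.sample_id!r}")


def ssgsea_es(matrix: ExpressionMatrix, sample_id: str, gene_set: GeneSet,
              alpha: float = DEFAULT_ALPHA) -> EnrichmentResult:
    """ssGSEA enrichment score of one gene set in one sample."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha {alpha} outside [0, 1]")
    col = matrix.sample(sample_id).dropna()
    values = col.to_numpy(dtype=float)
    n = values.size
    in_mask = col.index.isin(gene_set.genes)
    k = int(in_mask.sum())
    if k == 0:
        raise ValueError(f"set {gene_set.name!r} has no genes in the matrix")
    if k == n:
        raise ValueError(f"set {gene_set.name!r} covers every gene (empty complement)")
    asc_ranks = stats.rankdata(values, method="average")
    # descending expression; ties broken by gene position for determinism
    order = np.lexsort((np.arange(n), -values))
    in_ord = in_mask[order]
    w = np.where(in_ord, asc_ranks[order] ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_ord) / (n - k)
    return EnrichmentResult(sample_id=sample_id, set_name=gene_set.name,
                            es=float(np.sum(p_in - p_out)))


def ssgsea_matrix(matrix: ExpressionMatrix, gene_sets: Sequence[GeneSet],
                  alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Enrichment scores for every (sample, set) pair: samples x sets frame."""
    if not gene_sets:
        raise ValueError("no gene sets given")
    out = pd.DataFrame(index=pd.Index(matrix.sample_ids, name="sample_id"),
                       columns=[gs.name for gs in gene_sets], dtype=float)
    for sid in matrix.sample_ids:
        for gs in gene_sets:
            out.loc[sid, gs.name] = ssgsea_es(matrix, sid, gs, alpha=alpha).es
    return out


def marker_correlation(es_per_sample: pd.Series, matrix: ExpressionMatrix,
                       markers: Iterable[str]) -> pd.DataFrame:
    """Spearman correlation of an enrichment-score profile with marker genes.

    Returns a frame indexed by marker with columns ``rho``, ``pvalue`` and
    ``present``; markers absent from the matrix are reported as missing
    (NaN statistics), not errors. Raises only when every marker is absent.
    """
    markers = list(markers)
    if len(es_per_sample) < 3:
        raise ValueError("need >=3 samples for marker correlation")
    rows = []
    n_present = 0
    for m in markers:
        if m in matrix.data.index:
            expr = matrix.data.loc[m, es_per_sample.index]
            rho, p = spearman_association(es_per_sample.to_numpy(),
                                          expr.to_numpy(dtype=float))
            rows.append((m, rho, p, True))
            n_present += 1
        else:
            rows.append((m, np.nan, np.nan, False))
    if n_present == 0:
        raise ValueError("none of the marker genes are present in the matrix")
    return pd.DataFrame(rows, columns=["marker", "rho", "pvalue", "present"]
                        ).set_index("marker")
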