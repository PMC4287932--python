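"""Cross-cancer combination of disease-specific signatures.

Each gene is given a weighted sum over the diseases whose signature contains
it:

    w_g = sum_d |fc_gd| * (1 - q_gd/100) * 2*|ROC_gd - 0.5| * sqrt(n_d)

so the weight grows with fold-change, shrinks with the SAM q-value%, grows
with the ROC distance from chance, and grows (damped, sqrt) with cohort
size. Weights are z-transformed over every gene appearing in at least one
disease signature and genes are kept when they satisfy the membership rule
(default: present in all D diseases), have z > 3.09 (the upper 0.001
standard-normal quantile) and carry a consistent Epi/Mes direction across
diseases.

The algebraic form of the weight is this package's reconstruction from the
stated qualitative requirements; swapping in a different form only requires
changing :func:`gene_weight`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .derivation import DiseaseGeneStats
from .io import EMTSignature

logger = logging.getLogger("emtscore")

Z_THRESHOLD_DEFAULT = 3.09


def z_threshold_for_p(p: float = 0.001) -> float:
    """Upper-tail standard-normal quantile matching an inclusion p-value."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"p {p} outside (0, 1)")
    return float(sps.norm.isf(p))


@dataclass(frozen=True)
class GeneWeight:
    gene: str
    w: float                   # non-negative weighted sum over diseases
    z: float | None            # z-transformed weight (None before combination)
    diseases_present: int
    direction_consensus: Literal["Epi", "Mes", "conflict"]

    def __post_init__(self) -> None:
        if not self.w >= 0:
            raise ValueError(f"negative weight for {self.gene!r}")


def _disease_contribution(row: pd.Series, n_samples: int) -> float:
    fc = abs(float(row["fc_log2"]))
    q = float(row["q_pct"])
    roc = float(row["roc"])
    return fc * (1.0 - q / 100.0) * 2.0 * abs(roc - 0.5) * np.sqrt(n_samples)


def gene_weight(stats_by_disease: Sequence[DiseaseGeneStats], gene: str
                ) -> GeneWeight:
    """Weighted sum over the diseases whose signature contains the gene."""
    w = 0.0
    directions: set[str] = set()
    present = 0
    for ds in stats_by_disease:
        if gene not in ds.table.index:
            continue
        present += 1
        row = ds.table.loc[gene]
        w += _disease_contribution(row, ds.n_samples)
        directions.add(str(row["direction"]))
    if present == 0:
        raise ValueError(f"gene {gene!r} appears in no disease signature")
    consensus: Literal["Epi", "Mes", "conflict"]
    consensus = directions.pop() if len(directions) == 1 else "conflict"
    return GeneWeight(gene=gene, w=w, z=None, diseases_present=present,
                      direction_consensus=consensus)


def weight_table(stats_by_disease: Sequence[DiseaseGeneStats]) -> pd.DataFrame:
    """Per-gene weights over the union of all disease signatures.

    Columns: ``w``, ``z`` (population z-transform, ddof=0), ``n_diseases``,
    ``direction``. The z population is every gene present in >=1 signature.
    """
    if not stats_by_disease:
        raise ValueError("no disease statistics given")
    universe = sorted(set().union(*(set(ds.table.index) for ds in stats_by_disease)))
    rows = [gene_weight(stats_by_disease, g) for g in universe]
    w = np.array([r.w for r in rows])
    sd = w.std(ddof=0)
    if sd == 0:
        raise ValueError("weight standard deviation is zero; z-transform undefined")
    z = (w - w.mean()) / sd
    return pd.DataFrame({
        "w": w,
        "z": z,
        "n_diseases": [r.diseases_present for r in rows],
        "direction": [r.direction_consensus for r in rows],
    }, index=pd.Index(universe, name="gene"))


def combine_signatures(stats_by_disease: Sequence[DiseaseGeneStats],
                       z_threshold: float = Z_THRESHOLD_DEFAULT,
                       membership: Literal["all", "at_least_k"] = "all",
                       k: int | None = None) -> EMTSignature:
    """Generic signature: membership rule AND z > threshold AND direction consensus."""
    n_dis = len(stats_by_disease)
    if n_dis < 2:
        raise ValueError("need stats from >=2 diseases")
    tab = weight_table(stats_by_disease)
    if membership == "all":
        member_ok = tab["n_diseases"] == n_dis
    elif membership == "at_least_k":
        if k is None or not 1 <= k <= n_dis:
            raise ValueError(f"membership='at_least_k' needs 1 <= k <= {n_dis}")
        member_ok = tab["n_diseases"] >= k
    else:
        raise ValueError(f"unknown membership rule {membership!r}")
    conflict = tab["direction"] == "conflict"
    if conflict.any():
        logger.warning("combine_signatures: %d gene(s) with conflicting "
                       "directions excluded: %s", int(conflict.sum()),
                       list(tab.index[conflict])[:5])
    selected = tab[member_ok & (tab["z"] > z_threshold) & ~conflict]
    if selected.empty:
        raise ValueError(
            "no gene passes the combination thresholds; consider "
            "membership='at_least_k' with k < D or a lower z_threshold"
        )
    epi = tuple(selected.index[selected["direction"] == "Epi"])
    mes = tuple(selected.index[selected["direction"] == "Mes"])
    if not epi or not mes:
        raise ValueError(
            f"one-sided generic signature (Epi: {len(epi)}, Mes: {len(mes)}); "
            "consider relaxing the thresholds"
        )
    weights = {g: float(selected.loc[g, "w"]) for g in selected.index}
    diseases = ",".join(ds.disease for ds in stats_by_disease)
    return EMTSignature(epi_genes=epi, mes_genes=mes, weights=weights,
                        source=f"generic({diseases})")


def signature_overlap_report(signatures: Sequence[EMTSignature],
                             names: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise shared-gene counts between signatures.

    One row per unordered pair with counts of shared Epi genes, shared Mes
    genes, and genes assigned discordant directions by the two signatures.
    """
    if len(signatures) < 2:
        raise ValueError("need >=2 signatures")
    if names is None:
        names = [s.source or f"sig{i}" for i, s in enumerate(signatures)]
    rows = []
    for i, j in combinations(range(len(signatures)), 2):
        a, b = signatures[i], signatures[j]
        shared_epi = len(set(a.epi_genes) & set(b.epi_genes))
        shared_mes = len(set(a.mes_genes) & set(b.mes_genes))
        discordant = len(set(a.epi_genes) & set(b.mes_genes)) + \
            len(set(a.mes_genes) & set(b.epi_genes))
        rows.append((names[i], names[j], shared_epi, shared_mes, discordant))
    return pd.DataFrame(rows, columns=["signature_a", "signature_b",
                                       "shared_epi", "shared_mes", "discordant"])
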