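"""Cancer-specific EMT signature derivation.

The six-stage scheme implemented by :func:`derive_cancer_signature`:

1. score every published EMT gene set per sample by ssGSEA;
2. correlate each set's enrichment profile with canonical Epi/Mes marker
   genes and keep the best-oriented set;
3. rank samples by that set's (oriented) enrichment score and train a
   metagene probit classifier on the 10-20 most extreme samples per side;
4. predict a mesenchymal-phenotype probability for every sample (steps 1-3
   may be iterated until the extreme-sample membership stabilizes);
5. take the extreme samples of the probability ranking (25% per side for
   cell-line cohorts, 100 per side for tumour cohorts) and select genes by
   SAM (permutation q-value% = 0) together with per-gene ROC
   (AUC > 0.8 or < 0.2);
6. record per-gene statistics (log2 fold-change, q%, ROC, cohort size) for
   downstream cross-cancer combination.

The phenotype classifier is a deterministic stand-in for Bayesian binary
probit regression on metagenes: genes are standardized on the training
samples, the top-k left singular vectors define metagene loadings, and a
ridge-penalized probit is fitted by iteratively reweighted least squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import DEFAULT_ALPHA, marker_correlation, ssgsea_matrix
from .io import EMTSignature, ExpressionMatrix, GeneSet

logger = logging.getLogger("emtscore")

# canonical EMT marker transcripts used to orient published gene sets
MES_MARKERS: tuple[str, ...] = ("TWIST1", "SNAI1", "SNAI2", "VIM", "CDH2", "ZEB1")
EPI_MARKERS: tuple[str, ...] = ("CDH1", "DDR1", "ERBB2", "ERBB3", "KRT19")


# ---------------------------------------------------------------------------
# Extreme-sample selection
# ---------------------------------------------------------------------------


def select_extremes(ranking: pd.Series,
                    mode: Literal["cell_line", "tumour"] = "cell_line",
                    frac: float = 0.25, n_each: int = 100
                    ) -> tuple[list[str], list[str]]:
    """Pick the most-Epi and most-Mes samples from a ranking.

    ``ranking`` maps sample id -> score where larger means more mesenchymal.
    Cell-line cohorts take the extreme ``frac`` (default 25%) of each end;
    tumour cohorts take ``min(n_each, n//2)`` per end. Returns
    ``(epi_ids, mes_ids)``; the groups never overlap.
    """
    n = len(ranking)
    if n < 4:
        raise ValueError(f"need >=4 ranked samples, got {n}")
    if mode == "cell_line":
        if not 0.0 < frac <= 0.5:
            raise ValueError(f"frac {frac} outside (0, 0.5]")
        m = math.ceil(frac * n)
    elif mode == "tumour":
        if n_each < 1:
            raise ValueError("n_each must be >= 1")
        m = min(n_each, n // 2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if 2 * m > n:
        raise ValueError(f"cannot take {m} samples per end from {n} samples")
    # deterministic tie-break: secondary sort on sample id
    srt = ranking.sort_index().sort_values(kind="mergesort")
    epi_ids = list(srt.index[:m])
    mes_ids = list(srt.index[-m:])
    return epi_ids, mes_ids


# ---------------------------------------------------------------------------
# SAM (significance analysis of microarrays)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamResult:
    """Moderated d-statistics and permutation q-value% per gene."""

    d: pd.Series          # (mean_Mes - mean_Epi) / (s + s0)
    q_pct: pd.Series      # q-value in percent, [0, 100]
    fold_change: pd.Series  # mean_Mes - mean_Epi on the log2 scale
    s0: float
    n_perm_used: int
    exhaustive: bool
    seed: int | None

    def __post_init__(self) -> None:
        q = self.q_pct.to_numpy()
        if ((q < 0) | (q > 100)).any():
            raise ValueError("q-values outside [0, 100]")


def _group_stats(x: np.ndarray, mes_mask: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene mean difference, pooled standard error and fold change."""
    n_mes = int(mes_mask.sum())
    n_epi = x.shape[1] - n_mes
    xm, xe = x[:, mes_mask], x[:, ~mes_mask]
    mean_m, mean_e = xm.mean(axis=1), xe.mean(axis=1)
    sse = ((xm - mean_m[:, None]) ** 2).sum(axis=1) + \
          ((xe - mean_e[:, None]) ** 2).sum(axis=1)
    a = (1.0 / n_mes + 1.0 / n_epi) / (n_mes + n_epi - 2)
    s = np.sqrt(a * sse)
    fc = mean_m - mean_e
    return fc, s, fc


def _tusher_s0(d_num: np.ndarray, s: np.ndarray) -> float:
    """Tusher coefficient-of-variation minimization over s-percentile candidates."""
    qs = np.percentile(s, np.arange(0, 101, 5))
    windows = np.percentile(s, np.arange(0, 101, 1))
    best, best_cv = 0.0, np.inf
    for s0 in qs:
        d = d_num / (s + s0)
        vs = []
        for lo, hi in zip(windows[:-1], windows[1:]):
            sel = (s >= lo) & (s <= hi)
            if sel.sum() >= 2:
                vs.append(stats.median_abs_deviation(d[sel], scale="normal"))
        vs = np.asarray(vs)
        if len(vs) < 2 or vs.mean() == 0:
            continue
        cv = vs.std() / vs.mean()
        if cv < best_cv:
            best_cv, best = cv, float(s0)
    return best


def sam(matrix: ExpressionMatrix, epi_ids: Sequence[str], mes_ids: Sequence[str],
        n_perm: int = 1000, seed: int | None = 0,
        s0_method: Literal["percentile", "tusher"] = "percentile",
        s0_percentile: float = 5.0) -> SamResult:
    """SAM moderated statistics with permutation q-value%.

    ``d_g = (mean_Mes - mean_Epi) / (s_g + s0)`` with the pooled standard
    error ``s_g`` and fudge factor ``s0`` (default: 5th percentile of the
    ``s_g`` distribution; ``s0_method="tusher"`` runs the coefficient-of-
    variation minimization instead). The q-value% of a gene is the median
    permutation false-call count at its |d| cut divided by the observed call
    count, x100, capped at 100 and made monotone non-increasing in |d|.
    If ``n_perm`` meets or exceeds the number of distinct label assignments,
    the permutation null is enumerated exhaustively.
    """
    epi_ids, mes_ids = list(epi_ids), list(mes_ids)
    if len(epi_ids) < 2 or len(mes_ids) < 2:
        raise ValueError("both groups need >=2 samples")
    if set(epi_ids) & set(mes_ids):
        raise ValueError("epi_ids and mes_ids overlap")
    cols = epi_ids + mes_ids
    sub = matrix.data[cols]
    keep = sub.notna().all(axis=1)
    if not keep.all():
        logger.warning("sam: dropped %d gene(s) with missing values",
                       int((~keep).sum()))
        sub = sub.loc[keep]
    if sub.shape[0] < 2:
        raise ValueError("need >=2 genes with complete values")
    x = sub.to_numpy(dtype=float)
    genes = sub.index
    n_epi, n_mes = len(epi_ids), len(mes_ids)
    n = n_epi + n_mes
    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[n_epi:] = True

    fc, s, _ = _group_stats(x, obs_mask)
    if s0_method == "tusher":
        s0 = _tusher_s0(fc, s)
    else:
        s0 = float(np.percentile(s, s0_percentile))
    denom = s + s0
    d_obs = np.divide(fc, denom, out=np.zeros_like(fc), where=denom > 0)

    n_distinct = math.comb(n, n_mes)
    exhaustive = n_perm >= n_distinct
    if exhaustive:
        masks = np.zeros((n_distinct, n), dtype=bool)
        for i, combo in enumerate(combinations(range(n), n_mes)):
            masks[i, list(combo)] = True
        n_used = n_distinct
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_perm, n), dtype=bool)
        for i in range(n_perm):
            masks[i, rng.permutation(n)[:n_mes]] = True
        n_used = n_perm

    # vectorized permutation d-statistics (same s0 across permutations)
    m = masks.T.astype(float)               # n x P
    e = 1.0 - m
    sum_m, sum_e = x @ m, x @ e
    ssq_m, ssq_e = (x ** 2) @ m, (x ** 2) @ e
    mean_m, mean_e = sum_m / n_mes, sum_e / n_epi
    sse = (ssq_m - n_mes * mean_m ** 2) + (ssq_e - n_epi * mean_e ** 2)
    a = (1.0 / n_mes + 1.0 / n_epi) / (n - 2)
    s_perm = np.sqrt(np.maximum(a * sse, 0.0))
    num = mean_m - mean_e
    den = s_perm + s0
    d_perm = np.divide(num, den, out=np.zeros_like(num), where=den > 0)

    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="mergesort")
    cuts = abs_obs[order]
    called = np.searchsorted(-cuts, -cuts, side="right")  # ties share a count
    perm_sorted = np.sort(np.abs(d_perm), axis=0)         # ascending per perm
    g = x.shape[0]
    false_counts = np.empty((n_used, g))
    for p in range(n_used):
        false_counts[p] = g - np.searchsorted(perm_sorted[:, p], cuts, side="left")
    med_false = np.median(false_counts, axis=0)
    q_raw = np.minimum(100.0, 100.0 * med_false / called)
    # monotone non-increasing in |d|: running min from the least significant end
    q_mono = np.minimum.accumulate(q_raw[::-1])[::-1]
    q = np.empty(g)
    q[order] = q_mono

    return SamResult(
        d=pd.Series(d_obs, index=genes, name="d"),
        q_pct=pd.Series(q, index=genes, name="q_pct"),
        fold_change=pd.Series(fc, index=genes, name="fc_log2"),
        s0=s0, n_perm_used=n_used, exhaustive=exhaustive, seed=seed,
    )


# ---------------------------------------------------------------------------
# Per-gene ROC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    """Per-gene AUC for Mes-vs-Epi discrimination (ties credited 1/2)."""

    auc: pd.Series

    def __post_init__(self) -> None:
        v = self.auc.to_numpy()
        if ((v < 0) | (v > 1)).any():
            raise ValueError("AUC outside [0, 1]")


def roc_per_gene(matrix: ExpressionMatrix, epi_ids: Sequence[str],
                 mes_ids: Sequence[str]) -> RocResult:
    """AUC = P(random Mes value > random Epi value) + 1/2 P(tie), per gene."""
    epi_ids, mes_ids = list(epi_ids), list(mes_ids)
    if not epi_ids or not mes_ids:
        raise ValueError("both groups must be non-empty")
    sub = matrix.data[epi_ids + mes_ids]
    sub = sub.loc[sub.notna().all(axis=1)]
    x = sub.to_numpy(dtype=float)
    n_epi, n_mes = len(epi_ids), len(mes_ids)
    ranks = stats.rankdata(x, method="average", axis=1)
    rank_sum_mes = ranks[:, n_epi:].sum(axis=1)
    u = rank_sum_mes - n_mes * (n_mes + 1) / 2.0
    return RocResult(auc=pd.Series(u / (n_epi * n_mes), index=sub.index, name="auc"))


# ---------------------------------------------------------------------------
# Threshold-based gene selection
# ---------------------------------------------------------------------------


def select_signature_genes(sam_result: SamResult, roc_result: RocResult,
                           q_max_pct: float = 0.0,
                           roc_hi: float = 0.8, roc_lo: float = 0.2,
                           source: str = "derived") -> EMTSignature:
    """Select Epi/Mes genes jointly passing the SAM q and ROC thresholds.

    Mes: ``q <= q_max_pct`` and ``ROC > roc_hi`` and ``d > 0``;
    Epi: ``q <= q_max_pct`` and ``ROC < roc_lo`` and ``d < 0``.
    Genes whose d and ROC directions conflict are excluded with a warning.
    """
    common = sam_result.d.index.intersection(roc_result.auc.index)
    if len(common) != len(sam_result.d) or len(common) != len(roc_result.auc):
        raise ValueError("SAM and ROC results cover different gene universes")
    d = sam_result.d[common]
    q = sam_result.q_pct[common]
    auc = roc_result.auc[common]
    pass_q = q <= q_max_pct
    mes = pass_q & (auc > roc_hi) & (d > 0)
    epi = pass_q & (auc < roc_lo) & (d < 0)
    conflict = pass_q & (((auc > roc_hi) & (d <= 0)) | ((auc < roc_lo) & (d >= 0)))
    if conflict.any():
        logger.warning("select_signature_genes: %d gene(s) with conflicting "
                       "d/ROC directions excluded: %s",
                       int(conflict.sum()), list(common[conflict])[:5])
    epi_genes = tuple(common[epi])
    mes_genes = tuple(common[mes])
    if not epi_genes or not mes_genes:
        raise ValueError(
            f"empty signature side (Epi: {len(epi_genes)}, Mes: {len(mes_genes)}); "
            f"consider relaxing q_max_pct/roc thresholds"
        )
    return EMTSignature(epi_genes=epi_genes, mes_genes=mes_genes, source=source)


# ---------------------------------------------------------------------------
# Metagene probit phenotype prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetageneProbitModel:
    """Fitted SVD-metagene + ridge-probit phenotype classifier."""

    genes: pd.Index
    train_mean: np.ndarray
    train_sd: np.ndarray
    loadings: np.ndarray      # genes x k metagene loadings (left singular vectors)
    beta: np.ndarray          # intercept + k coefficients
    k: int
    ridge: float
    train_probabilities: pd.Series


@dataclass(frozen=True)
class PhenotypeProbability:
    probabilities: pd.Series  # per-sample P(Mes), in [0, 1]
    loadings: np.ndarray
    k: int

    def __post_init__(self) -> None:
        p = self.probabilities.to_numpy()
        if ((p < 0) | (p > 1)).any():
            raise ValueError("phenotype probabilities outside [0, 1]")


def _probit_irls(design: np.ndarray, y: np.ndarray, ridge: float,
                 max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Ridge-penalized probit fit by Newton/IRLS with step halving.

    The intercept is unpenalized. Raises on non-convergence.
    """
    n, p = design.shape
    pen = ridge * np.eye(p)
    pen[0, 0] = 0.0
    beta = np.zeros(p)

    def nll(b: np.ndarray) -> float:
        eta = design @ b
        ll = np.sum(np.where(y == 1, stats.norm.logcdf(eta),
                             stats.norm.logcdf(-eta)))
        return -ll + 0.5 * ridge * float(b[1:] @ b[1:])

    current = nll(beta)
    for _ in range(max_iter):
        eta = design @ beta
        mu = np.clip(stats.norm.cdf(eta), 1e-10, 1 - 1e-10)
        phi = stats.norm.pdf(eta)
        w = phi ** 2 / (mu * (1 - mu))
        z = eta + (y - mu) / np.maximum(phi, 1e-300)
        xtw = design.T * w
        new = np.linalg.solve(xtw @ design + pen, xtw @ z)
        step, prev = new - beta, current
        for _ in range(30):  # halve until the penalized objective improves
            cand = beta + step
            val = nll(cand)
            if val <= prev + 1e-12:
                break
            step = step / 2.0
        else:
            raise RuntimeError("probit IRLS: step halving failed to improve "
                               f"objective (nll={prev:.6g})")
        delta = float(np.max(np.abs(cand - beta)))
        beta, current = cand, val
        if delta < tol:
            return beta
    raise RuntimeError(f"probit IRLS did not converge in {max_iter} iterations "
                       f"(last step {delta:.3g}, nll {current:.6g})")


def fit_metagene_probit(matrix: ExpressionMatrix, epi_ids: Sequence[str],
                        mes_ids: Sequence[str], k: int = 2,
                        ridge: float = 1e-3) -> MetageneProbitModel:
    """Fit the metagene probit on labelled extreme samples.

    Genes are standardized over the pooled training samples; the top-k left
    singular vectors of the standardized matrix define the metagenes, each
    sign-fixed so its loading on the Mes-group mean is positive; phenotype
    (Mes=1) is regressed on the metagene coordinates by ridge probit.
    """
    epi_ids, mes_ids = list(epi_ids), list(mes_ids)
    if len(epi_ids) < k + 1 or len(mes_ids) < k + 1:
        raise ValueError(f"both training groups need >= k+1 = {k + 1} samples")
    if set(epi_ids) & set(mes_ids):
        raise ValueError("training groups overlap")
    cols = epi_ids + mes_ids
    sub = matrix.data[cols]
    sub = sub.loc[sub.notna().all(axis=1)]
    x = sub.to_numpy(dtype=float)
    if k > min(x.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(x.shape)}")
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mean[:, None]) / sd[:, None]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    if s[k - 1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError(f"k={k} exceeds the numerical rank of the training data")
    u_k = u[:, :k]
    mes_mean = z[:, len(epi_ids):].mean(axis=1)
    sign = np.where(u_k.T @ mes_mean >= 0, 1.0, -1.0)
    u_k = u_k * sign[None, :]
    coords = z.T @ u_k  # samples x k
    y = np.concatenate([np.zeros(len(epi_ids)), np.ones(len(mes_ids))])
    design = np.column_stack([np.ones(len(cols)), coords])
    beta = _probit_irls(design, y, ridge)
    probs = stats.norm.cdf(design @ beta)
    return MetageneProbitModel(
        genes=sub.index, train_mean=mean, train_sd=sd, loadings=u_k,
        beta=beta, k=k, ridge=ridge,
        train_probabilities=pd.Series(probs, index=cols, name="p_mes"),
    )


def predict_phenotype(model: MetageneProbitModel, matrix: ExpressionMatrix,
                      sample_ids: Sequence[str] | None = None
                      ) -> PhenotypeProbability:
    """Mes-phenotype probability for new samples under a fitted model.

    Genes absent from the matrix are imputed at the training mean (zero after
    standardization) with a warning; more than 50% missing is an error.
    """
    if sample_ids is None:
        sample_ids = matrix.sample_ids
    sample_ids = list(sample_ids)
    present = model.genes.isin(matrix.data.index)
    n_missing = int((~present).sum())
    if n_missing > 0.5 * len(model.genes):
        raise ValueError(f"{n_missing}/{len(model.genes)} model genes missing "
                         "from the matrix")
    if n_missing:
        logger.warning("predict_phenotype: %d model gene(s) missing, imputed "
                       "at training mean", n_missing)
    z = np.zeros((len(model.genes), len(sample_ids)))
    sub = matrix.data.reindex(index=model.genes, columns=sample_ids)
    vals = sub.to_numpy(dtype=float)
    std = (vals - model.train_mean[:, None]) / model.train_sd[:, None]
    z = np.where(np.isfinite(std), std, 0.0)  # missing gene/value -> train mean
    coords = z.T @ model.loadings
    eta = model.beta[0] + coords @ model.beta[1:]
    probs = stats.norm.cdf(eta)
    return PhenotypeProbability(
        probabilities=pd.Series(probs, index=sample_ids, name="p_mes"),
        loadings=model.loadings, k=model.k,
    )


# ---------------------------------------------------------------------------
# Per-disease gene statistics (consumed by the generic combination)
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class DiseaseGeneStats:
    """Per-gene SAM/ROC statistics of one disease's signature.

    ``table`` is indexed by gene with columns ``fc_log2`` (mean_Mes -
    mean_Epi on the log2 scale), ``q_pct``, ``roc`` and ``direction``
    (Epi/Mes); ``n_samples`` is the cohort size.
    """

    disease: str
    table: pd.DataFrame
    n_samples: int

    def __post_init__(self) -> None:
        missing = {"fc_log2", "q_pct", "roc", "direction"} - set(self.table.columns)
        if missing:
            raise ValueError(f"stats table missing columns {sorted(missing)}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        q = self.table["q_pct"].to_numpy(dtype=float)
        r = self.table["roc"].to_numpy(dtype=float)
        if ((q < 0) | (q > 100)).any():
            raise ValueError("q_pct outside [0, 100]")
        if ((r < 0) | (r > 1)).any():
            raise ValueError("roc outside [0, 1]")
        if not self.table["direction"].isin(["Epi", "Mes"]).all():
            raise ValueError("direction must be 'Epi' or 'Mes'")


def write_stats(statistics: DiseaseGeneStats, path: str | Path) -> None:
    out = statistics.table.copy()
    out["n_samples"] = statistics.n_samples
    out.to_csv(path, sep="\t", index_label="gene")


def read_stats(path: str | Path, disease: str | None = None) -> DiseaseGeneStats:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    n = int(df["n_samples"].iloc[0])
    return DiseaseGeneStats(
        disease=disease if disease is not None else Path(path).stem,
        table=df.drop(columns="n_samples"),
        n_samples=n,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeriveConfig:
    """Tunable parameters of the six-stage derivation."""

    disease: str = "disease"
    mode: Literal["cell_line", "tumour"] = "cell_line"
    n_seed: int = 15          # extreme samples per side for probit training
    frac: float = 0.25        # cell-line extreme fraction for SAM/ROC
    n_each: int = 100         # tumour extreme count per side for SAM/ROC
    q_max_pct: float = 0.0
    roc_hi: float = 0.8
    roc_lo: float = 0.2
    k: int = 2
    ridge: float = 1e-3
    n_perm: int = 1000
    seed: int = 0
    max_iter: int = 1
    alpha: float = DEFAULT_ALPHA
    mes_markers: tuple[str, ...] = MES_MARKERS
    epi_markers: tuple[str, ...] = EPI_MARKERS


@dataclass(frozen=True, eq=False)
class DeriveResult:
    signature: EMTSignature
    stats: DiseaseGeneStats
    chosen_set: str
    orientation: int               # +1 if higher ES of the chosen set = more Mes
    probabilities: pd.Series       # final per-sample P(Mes)
    epi_ids: list[str]
    mes_ids: list[str]
    sam_result: SamResult
    roc_result: RocResult
    n_iterations: int


def _orientation_score(es: pd.Series, matrix: ExpressionMatrix,
                       mes_markers: Sequence[str], epi_markers: Sequence[str]
                       ) -> float:
    """Mean marker rho difference: positive when high ES tracks Mes markers."""
    corr = marker_correlation(es, matrix, list(mes_markers) + list(epi_markers))
    mes_rho = corr.loc[corr.index.isin(mes_markers) & corr["present"], "rho"]
    epi_rho = corr.loc[corr.index.isin(epi_markers) & corr["present"], "rho"]
    parts = []
    if len(mes_rho):
        parts.append(mes_rho.mean())
    if len(epi_rho):
        parts.append(-epi_rho.mean())
    return float(np.mean(parts))


def derive_cancer_signature(matrix: ExpressionMatrix,
                            published_sets: Sequence[GeneSet],
                            config: DeriveConfig = DeriveConfig()
                            ) -> DeriveResult:
    """Run the full six-stage derivation on one cohort."""
    if not published_sets:
        raise ValueError("published_sets must contain at least one gene set")
    if matrix.n_samples < 30:
        logger.warning("derive_cancer_signature: only %d samples (>=30 "
                       "recommended)", matrix.n_samples)
    if not 2 <= config.n_seed <= matrix.n_samples // 2:
        raise ValueError(f"n_seed {config.n_seed} infeasible for "
                         f"{matrix.n_samples} samples")
    if not 10 <= config.n_seed <= 20:
        logger.warning("n_seed %d outside the customary 10-20 range",
                       config.n_seed)

    # steps 1-2: ssGSEA on published sets, oriented by marker correlation
    try:
        es = ssgsea_matrix(matrix, published_sets, alpha=config.alpha)
    except ValueError as exc:
        raise ValueError(f"step 1 (ssGSEA) failed: {exc}") from exc
    best_name, best_score = None, 0.0
    for gs in published_sets:
        try:
            sc = _orientation_score(es[gs.name], matrix,
                                    config.mes_markers, config.epi_markers)
        except ValueError as exc:
            raise ValueError(f"step 2 (marker correlation) failed: {exc}") from exc
        if best_name is None or abs(sc) > abs(best_score):
            best_name, best_score = gs.name, sc
    orientation = 1 if best_score >= 0 else -1
    if best_score == 0:
        logger.warning("step 2: chosen set %r has zero marker orientation; "
                       "assuming higher ES = Mes", best_name)
    ranking = orientation * es[best_name]

    # steps 3-4 (optionally recursive): probit training on seed extremes,
    # phenotype prediction on all samples
    prev_membership: tuple[frozenset, frozenset] | None = None
    model = None
    probs = ranking
    n_iter = 0
    for it in range(max(1, config.max_iter)):
        n_iter = it + 1
        try:
            seed_epi, seed_mes = select_extremes(
                probs if it else ranking, mode="tumour", n_each=config.n_seed)
            model = fit_metagene_probit(matrix, seed_epi, seed_mes,
                                        k=config.k, ridge=config.ridge)
            probs = predict_phenotype(model, matrix).probabilities
        except (ValueError, RuntimeError) as exc:
            raise type(exc)(f"step 3-4 (metagene probit) failed: {exc}") from exc
        membership = (frozenset(seed_epi), frozenset(seed_mes))
        if membership == prev_membership:
            break
        prev_membership = membership

    # step 5: SAM/ROC on the extreme samples of the probability ranking
    try:
        epi_ids, mes_ids = select_extremes(probs, mode=config.mode,
                                           frac=config.frac, n_each=config.n_each)
        sam_result = sam(matrix, epi_ids, mes_ids, n_perm=config.n_perm,
                         seed=config.seed)
        roc_result = roc_per_gene(matrix, epi_ids, mes_ids)
        signature = select_signature_genes(
            sam_result, roc_result, q_max_pct=config.q_max_pct,
            roc_hi=config.roc_hi, roc_lo=config.roc_lo,
            source=f"derived:{config.disease}")
    except ValueError as exc:
        raise ValueError(f"step 5 (SAM/ROC selection) failed: {exc}") from exc

    # step 6: per-gene statistics for the cross-cancer combination
    sig_genes = list(signature.epi_genes) + list(signature.mes_genes)
    direction = pd.Series(
        ["Epi"] * len(signature.epi_genes) + ["Mes"] * len(signature.mes_genes),
        index=sig_genes)
    table = pd.DataFrame({
        "fc_log2": sam_result.fold_change[sig_genes],
        "q_pct": sam_result.q_pct[sig_genes],
        "roc": roc_result.auc[sig_genes],
        "direction": direction,
    })
    statistics = DiseaseGeneStats(disease=config.disease, table=table,
                                  n_samples=matrix.n_samples)
    return DeriveResult(
        signature=signature, stats=statistics, chosen_set=best_name,
        orientation=orientation, probabilities=probs,
        epi_ids=epi_ids, mes_ids=mes_ids,
        sam_result=sam_result, roc_result=roc_result, n_iterations=n_iter,
    )
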