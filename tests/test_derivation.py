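"""Signature derivation: extremes, SAM, ROC, probit and the full pipeline."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import emtscore as es


# ---------------------------------------------------------------------------
# select_extremes
# ---------------------------------------------------------------------------


def _ranking(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(size=n), index=[f"s{i:04d}" for i in range(n)])


def test_cell_line_mode_takes_quarter_per_end():
    epi, mes = es.select_extremes(_ranking(40), mode="cell_line", frac=0.25)
    assert len(epi) == len(mes) == 10
    assert not set(epi) & set(mes)


def test_tumour_mode_takes_hundred_per_end():
    r = _ranking(1000)
    epi, mes = es.select_extremes(r, mode="tumour", n_each=100)
    assert len(epi) == len(mes) == 100
    assert max(r[epi]) < min(r[mes])


def test_too_few_samples_is_error():
    with pytest.raises(ValueError, match=">=4"):
        es.select_extremes(_ranking(3))


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _two_group_matrix(n_genes, n_epi, n_mes, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(7, 1, size=(n_genes, n_epi + n_mes))
    vals[: n_genes // 2, n_epi:] += effect  # first half of genes shifted in Mes
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"e{i}" for i in range(n_epi)] + [f"m{i}" for i in range(n_mes)]
    m = es.matrix_from_arrays(genes, samples, vals)
    return m, samples[:n_epi], samples[n_epi:]


def test_sam_identical_groups_null():
    genes = [f"g{i}" for i in range(5)]
    vals = np.tile(np.arange(5, dtype=float)[:, None], (1, 6))
    m = es.matrix_from_arrays(genes, [f"s{i}" for i in range(6)], vals)
    out = es.sam(m, [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)],
                 n_perm=1000)
    assert (out.d == 0).all()
    assert (out.q_pct == 100.0).all()


def test_sam_label_swap_negates_d_keeps_q():
    m, epi, mes = _two_group_matrix(12, 4, 4, effect=2.0, seed=3)
    a = es.sam(m, epi, mes, n_perm=10_000)  # C(8,4)=70 -> exhaustive
    b = es.sam(m, mes, epi, n_perm=10_000)
    assert a.exhaustive and b.exhaustive
    assert np.allclose(a.d, -b.d)
    assert np.allclose(a.q_pct, b.q_pct)


def brute_force_sam_q(x, n_epi, n_mes, s0):
    """Exhaustive-permutation q-value oracle, explicit loops throughout."""
    g, n = x.shape

    def dstat(mes_cols):
        mes_cols = set(mes_cols)
        d = np.empty(g)
        for gi in range(g):
            xm = [x[gi, j] for j in range(n) if j in mes_cols]
            xe = [x[gi, j] for j in range(n) if j not in mes_cols]
            mm, me = np.mean(xm), np.mean(xe)
            sse = sum((v - mm) ** 2 for v in xm) + sum((v - me) ** 2 for v in xe)
            s = math.sqrt((1 / len(xm) + 1 / len(xe)) / (n - 2) * sse)
            d[gi] = (mm - me) / (s + s0)
        return d

    obs = dstat(range(n_epi, n))
    perm_abs = [np.abs(dstat(c)) for c in combinations(range(n), n_mes)]
    q = np.empty(g)
    order = np.argsort(-np.abs(obs))
    for rank_pos, gi in enumerate(order):
        cut = abs(obs[gi])
        called = sum(abs(obs[gj]) >= cut - 1e-12 for gj in range(g))
        falses = [sum(v >= cut - 1e-12 for v in pa) for pa in perm_abs]
        q[gi] = min(100.0, 100.0 * np.median(falses) / called)
    # monotone non-increasing in |d|
    for i in range(len(order) - 2, -1, -1):
        q[order[i]] = min(q[order[i]], q[order[i + 1]])
    return obs, q


def test_sam_q_matches_exhaustive_oracle():
    """3v3 toy with all C(6,3) label assignments against a loop oracle."""
    m, epi, mes = _two_group_matrix(5, 3, 3, effect=3.0, seed=11)
    out = es.sam(m, epi, mes, n_perm=100)  # C(6,3)=20 -> exhaustive
    assert out.exhaustive
    x = m.data[epi + mes].to_numpy()
    obs, q = brute_force_sam_q(x, 3, 3, out.s0)
    assert np.allclose(out.d.to_numpy(), obs)
    assert np.allclose(out.q_pct.to_numpy(), q)


def test_sam_planted_effect_gets_low_q_high_d():
    m, epi, mes = _two_group_matrix(40, 10, 10, effect=4.0, seed=5)
    out = es.sam(m, epi, mes, n_perm=500, seed=1)
    shifted = [f"g{i:03d}" for i in range(20)]
    rest = [f"g{i:03d}" for i in range(20, 40)]
    assert (out.q_pct[shifted] == 0.0).all()
    assert out.d[shifted].min() > out.d[rest].max()


def test_sam_group_size_validation(small_matrix):
    with pytest.raises(ValueError, match=">=2"):
        es.sam(small_matrix, ["s1"], ["s2", "s3"])


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def test_roc_trivial_cases():
    genes = ["up", "const"]
    vals = np.array([[1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
                     [5.0, 5.0, 5.0, 5.0, 5.0, 5.0]])
    m = es.matrix_from_arrays(genes, [f"s{i}" for i in range(6)], vals)
    roc = es.roc_per_gene(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    assert roc.auc["up"] == 1.0
    assert roc.auc["const"] == 0.5


def test_roc_label_swap_complement(rng):
    vals = rng.normal(size=(6, 7))
    m = es.matrix_from_arrays([f"g{i}" for i in range(6)],
                              [f"s{i}" for i in range(7)], vals)
    a = es.roc_per_gene(m, ["s0", "s1", "s2"], ["s3", "s4", "s5", "s6"])
    b = es.roc_per_gene(m, ["s3", "s4", "s5", "s6"], ["s0", "s1", "s2"])
    assert np.allclose(a.auc + b.auc, 1.0)


def test_roc_matches_pair_counting_oracle(rng):
    """AUC equals explicit pair counting on random instances up to 20x20."""
    for _ in range(30):
        n_epi = int(rng.integers(1, 21))
        n_mes = int(rng.integers(1, 21))
        vals = np.round(rng.normal(size=(3, n_epi + n_mes)), 1)  # induce ties
        m = es.matrix_from_arrays(
            ["a", "b", "c"], [f"s{i}" for i in range(n_epi + n_mes)], vals)
        epi = [f"s{i}" for i in range(n_epi)]
        mes = [f"s{i}" for i in range(n_epi, n_epi + n_mes)]
        roc = es.roc_per_gene(m, epi, mes)
        for gi, g in enumerate(["a", "b", "c"]):
            wins = ties = 0
            for i in range(n_epi):
                for j in range(n_epi, n_epi + n_mes):
                    if vals[gi, j] > vals[gi, i]:
                        wins += 1
                    elif vals[gi, j] == vals[gi, i]:
                        ties += 1
            assert roc.auc[g] == pytest.approx(
                (wins + 0.5 * ties) / (n_epi * n_mes), abs=1e-12)


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------


def _fake_sam(d, q):
    genes = pd.Index([f"g{i}" for i in range(len(d))])
    return es.SamResult(d=pd.Series(d, index=genes),
                        q_pct=pd.Series(q, index=genes),
                        fold_change=pd.Series(d, index=genes),
                        s0=0.1, n_perm_used=10, exhaustive=True, seed=0)


def _fake_roc(auc):
    return es.RocResult(auc=pd.Series(auc, index=[f"g{i}" for i in range(len(auc))]))


def test_select_signature_genes_thresholds():
    sam_r = _fake_sam(d=[3.0, 2.5, -3.0, 0.5, -0.2],
                      q=[0.0, 5.0, 0.0, 0.0, 0.0])
    roc_r = _fake_roc([0.9, 0.9, 0.1, 0.5, 0.5])
    sig = es.select_signature_genes(sam_r, roc_r)
    assert set(sig.mes_genes) == {"g0"}   # g1 fails q, g3 fails ROC
    assert set(sig.epi_genes) == {"g2"}


def test_conflicting_direction_excluded():
    sam_r = _fake_sam(d=[3.0, -1.0, -3.0], q=[0.0, 0.0, 0.0])
    roc_r = _fake_roc([0.9, 0.95, 0.1])  # g1: high ROC but negative d
    sig = es.select_signature_genes(sam_r, roc_r)
    assert "g1" not in sig.mes_genes + sig.epi_genes


def test_selection_monotone_in_thresholds(rng):
    """Relaxing q_max or roc_hi never removes a selected gene."""
    d = rng.normal(scale=2, size=30)
    q = rng.uniform(0, 10, size=30).round()
    q[np.abs(d) > 2] = 0.0
    auc = np.clip(0.5 + d / 6 + rng.normal(scale=0.05, size=30), 0, 1)
    sam_r, roc_r = _fake_sam(d, q), _fake_roc(auc)
    strict = es.select_signature_genes(sam_r, roc_r, q_max_pct=0, roc_hi=0.85,
                                       roc_lo=0.15)
    loose = es.select_signature_genes(sam_r, roc_r, q_max_pct=5, roc_hi=0.8,
                                      roc_lo=0.2)
    assert set(strict.mes_genes) <= set(loose.mes_genes)
    assert set(strict.epi_genes) <= set(loose.epi_genes)


def test_empty_side_raises_with_advice():
    sam_r = _fake_sam(d=[3.0, 2.0], q=[0.0, 0.0])
    roc_r = _fake_roc([0.9, 0.9])
    with pytest.raises(ValueError, match="relaxing"):
        es.select_signature_genes(sam_r, roc_r)


# ---------------------------------------------------------------------------
# metagene probit
# ---------------------------------------------------------------------------


def _labelled_cohort(n_each=8, n_genes=30, gap=3.0, seed=0):
    rng = np.random.default_rng(seed)
    phi = np.array([-1.0] * n_each + [1.0] * n_each)
    beta = np.concatenate([np.full(n_genes // 2, -gap / 2),
                           np.full(n_genes - n_genes // 2, gap / 2)])
    vals = rng.normal(7, 1, size=(n_genes, 1)) + beta[:, None] * phi[None, :] \
        + rng.normal(0, 0.3, size=(n_genes, 2 * n_each))
    genes = [f"g{i:02d}" for i in range(n_genes)]
    samples = [f"e{i}" for i in range(n_each)] + [f"m{i}" for i in range(n_each)]
    m = es.matrix_from_arrays(genes, samples, vals)
    return m, samples[:n_each], samples[n_each:]


def test_separable_training_groups_split_at_half():
    m, epi, mes = _labelled_cohort()
    model = es.fit_metagene_probit(m, epi, mes, k=2)
    probs = model.train_probabilities
    assert (probs[mes] > 0.5).all()
    assert (probs[epi] < 0.5).all()
    assert probs[mes].mean() > probs[epi].mean()


def test_centroid_sample_probability_near_half():
    m, epi, mes = _labelled_cohort()
    model = es.fit_metagene_probit(m, epi, mes, k=2)
    centroid = m.data[epi + mes].mean(axis=1)
    m2 = es.ExpressionMatrix(m.data.assign(centroid=centroid))
    p = es.predict_phenotype(model, m2, ["centroid"]).probabilities["centroid"]
    assert abs(p - 0.5) < 0.05


def test_k1_probabilities_match_closed_form_probit():
    m, epi, mes = _labelled_cohort()
    model = es.fit_metagene_probit(m, epi, mes, k=1)
    # recompute the metagene coordinate and apply Phi(b0 + b1 x) directly
    sub = m.data[epi + mes]
    z = (sub.to_numpy() - model.train_mean[:, None]) / model.train_sd[:, None]
    coords = z.T @ model.loadings
    expected = sps.norm.cdf(model.beta[0] + model.beta[1] * coords[:, 0])
    assert np.allclose(model.train_probabilities.to_numpy(), expected)


def test_prediction_idempotent_and_duplicate_consistent():
    m, epi, mes = _labelled_cohort()
    model = es.fit_metagene_probit(m, epi, mes, k=2)
    pred = es.predict_phenotype(model, m, epi + mes).probabilities
    assert np.allclose(pred.to_numpy(), model.train_probabilities.to_numpy())
    dup = es.ExpressionMatrix(m.data.assign(copy0=m.data[epi[0]]))
    p2 = es.predict_phenotype(model, dup).probabilities
    assert p2["copy0"] == pytest.approx(p2[epi[0]], rel=1e-9)


def test_missing_gene_handling():
    m, epi, mes = _labelled_cohort()
    model = es.fit_metagene_probit(m, epi, mes, k=2)
    reduced = es.ExpressionMatrix(m.data.iloc[: m.n_genes // 3])
    with pytest.raises(ValueError, match="missing"):
        es.predict_phenotype(model, reduced)


def test_probit_recovers_planted_axis():
    m, truth = es.generate_cohort(n_samples=80, n_background=100, n_epi=20,
                                  n_mes=20, seed=4)
    order = truth.phi.sort_values()
    epi, mes = list(order.index[:12]), list(order.index[-12:])
    model = es.fit_metagene_probit(m, epi, mes, k=2)
    probs = es.predict_phenotype(model, m).probabilities
    rho, _ = es.spearman_association(probs[truth.phi.index].to_numpy(),
                                     truth.phi.to_numpy())
    assert rho >= 0.9


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def test_derive_recovers_planted_signature():
    matrix, truth = es.generate_cohort(seed=1)
    cfg = es.DeriveConfig(disease="synthetic", seed=7,
                          mes_markers=truth.mes_genes[:3],
                          epi_markers=truth.epi_genes[:3])
    res = es.derive_cancer_signature(matrix, truth.gene_sets(), cfg)
    selected = set(res.signature.epi_genes) | set(res.signature.mes_genes)
    planted = set(truth.epi_genes) | set(truth.mes_genes)
    recall = len(selected & planted) / len(planted)
    fp = len(selected & set(truth.background_genes))
    assert recall >= 0.9
    assert fp == 0
    assert set(res.signature.mes_genes) <= set(truth.mes_genes)
    assert res.stats.n_samples == matrix.n_samples
    assert (res.stats.table.loc[list(res.signature.mes_genes), "fc_log2"] > 0).all()


def test_derive_n_seed_controls_training_extremes():
    matrix, truth = es.generate_cohort(n_samples=40, n_background=60, n_epi=15,
                                       n_mes=15, phi_dist="two_cluster", seed=2)
    cfg = es.DeriveConfig(disease="d", n_seed=10, seed=5,
                          mes_markers=truth.mes_genes[:3],
                          epi_markers=truth.epi_genes[:3])
    res = es.derive_cancer_signature(matrix, truth.gene_sets(), cfg)
    assert len(res.epi_ids) == len(res.mes_ids) == 10  # ceil(0.25*40)


def test_derive_requires_published_sets(small_matrix):
    with pytest.raises(ValueError, match="published_sets"):
        es.derive_cancer_signature(small_matrix, [])


def test_stats_round_trip(tmp_path):
    table = pd.DataFrame({
        "fc_log2": [2.0, -1.5], "q_pct": [0.0, 0.0], "roc": [0.95, 0.05],
        "direction": ["Mes", "Epi"],
    }, index=pd.Index(["m1", "e1"], name="gene"))
    stats = es.DiseaseGeneStats(disease="toy", table=table, n_samples=50)
    path = tmp_path / "toy.tsv"
    es.write_stats(stats, path)
    back = es.read_stats(path, disease="toy")
    pd.testing.assert_frame_equal(back.table, stats.table)
    assert back.n_samples == 50
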