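"""Pearson, Granger and phase-transfer-entropy estimators."""

import numpy as np
import pytest
from scipy import stats

from qeegconn.connectivity import (
    ConnMatrix,
    PTEParams,
    fit_var,
    granger_pairwise,
    interhemispheric_summary,
    pearson_connectivity,
    pte_connectivity,
    threshold_directed,
)
from qeegconn.errors import (
    ContractError,
    DegenerateChannelError,
    ParameterError,
    QeegError,
)
from qeegconn.synthetic_data import simulate_phase_coupled_pair

from conftest import make_epochs


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------


def test_pearson_duplicate_and_negated_channels(rng):
    x = rng.normal(size=5000)
    es = make_epochs(np.vstack([x, x, -x]), rate=250.0,
                     labels=["C3", "C4", "P3"], n_epochs=2)
    r = pearson_connectivity(es, (8.0, 13.0))
    assert r.values[0, 1] == pytest.approx(1.0, abs=1e-9)
    assert r.values[0, 2] == pytest.approx(-1.0, abs=1e-9)
    assert np.array_equal(r.values, r.values.T)
    assert np.all(np.diag(r.values) == 1.0)


def test_pearson_independent_noise_near_zero(rng):
    x = rng.normal(size=(2, 10_000))
    es = make_epochs(x, rate=250.0, labels=["C3", "C4"])
    r = pearson_connectivity(es, (1.0, 40.0))
    # oracle: the direct product-moment formula on the filtered traces
    from qeegconn.signal_io import bandpass_filter

    xf = bandpass_filter(x, (1.0, 40.0), 250.0)
    a, b = xf - xf.mean(axis=1, keepdims=True)
    direct = (a @ b) / np.sqrt((a @ a) * (b @ b))
    assert r.values[0, 1] == pytest.approx(direct, abs=1e-9)
    assert abs(r.values[0, 1]) < 0.05


def test_pearson_constant_channel_error():
    x = np.vstack([np.ones(2000), np.random.default_rng(0).normal(size=2000)])
    es = make_epochs(x, rate=250.0, labels=["C3", "C4"])
    with pytest.raises(DegenerateChannelError, match="C3"):
        pearson_connectivity(es, (8.0, 13.0))


def test_pearson_amplitude_invariance(rng):
    x = rng.normal(size=(3, 4000))
    es1 = make_epochs(x, rate=250.0, n_epochs=2)
    es2 = make_epochs(x * np.array([[1.0], [50.0], [0.01]]), rate=250.0, n_epochs=2)
    r1 = pearson_connectivity(es1, (4.0, 30.0))
    r2 = pearson_connectivity(es2, (4.0, 30.0))
    np.testing.assert_allclose(r1.values, r2.values, atol=1e-12)


# ---------------------------------------------------------------------------
# VAR fitting / Granger
# ---------------------------------------------------------------------------

# a clearly-order-2 stable bivariate VAR (companion radius ~0.8)
A1 = np.array([[0.5, 0.10], [0.0, 0.40]])
A2 = np.array([[-0.30, 0.0], [0.30, -0.30]])


def _simulate_var2(n, seed, burn=200):
    rng = np.random.default_rng(seed)
    x = np.zeros((2, n + burn))
    e = rng.normal(size=(2, n + burn))
    for t in range(2, n + burn):
        x[:, t] = A1 @ x[:, t - 1] + A2 @ x[:, t - 2] + e[:, t]
    return x[:, burn:]


def test_var_order_recovery_bic():
    """BIC picks the true order 2 for >= 90% of VAR(2) realizations."""
    hits = 0
    n_seeds = 100
    for seed in range(n_seeds):
        es = make_epochs(_simulate_var2(5000, seed), rate=250.0)
        model = fit_var(es, ("C3", "C4"), max_order=6)
        hits += model.order == 2
    assert hits >= 0.90 * n_seeds


def test_var_white_noise_residual_cov(rng):
    x = rng.normal(size=(2, 5000)) * np.array([[1.0], [2.0]])
    es = make_epochs(x, rate=250.0)
    model = fit_var(es, (0, 1), max_order=3)
    sample_cov = np.cov(x, bias=True)
    np.testing.assert_allclose(model.residual_cov, sample_cov, rtol=0.05)


def test_var_stability_reported(rng):
    es = make_epochs(_simulate_var2(3000, 7), rate=250.0)
    model = fit_var(es, (0, 1))
    assert model.spectral_radius() < 1.0


def test_var_short_epoch_precondition():
    es = make_epochs(np.random.default_rng(1).normal(size=(2, 50)), rate=250.0)
    with pytest.raises(ParameterError):
        fit_var(es, (0, 1), max_order=6)


def test_granger_detects_lagged_driving(rng):
    """y driven by x's past: GC decision x->y on, y->x off."""
    n = 5000
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    y = np.zeros(n)
    y[1:] = 0.8 * x[:-1]
    y += e
    es = make_epochs(np.vstack([x, y]), rate=250.0, labels=["C3", "C4"])
    gc, dec = granger_pairwise(es, max_order=6, alpha=0.05)
    assert dec.values[0, 1] == 1.0
    assert dec.values[1, 0] == 0.0
    assert gc.values[0, 1] > gc.values[1, 0]


def test_granger_analytic_value():
    """GC estimate approaches ln(1 + b^2) for y[t] = b x[t-1] + e."""
    rng = np.random.default_rng(99)
    n = 100_000
    b = 0.8
    x = rng.normal(size=n)
    y = np.zeros(n)
    y[1:] = b * x[:-1]
    y += rng.normal(size=n)
    es = make_epochs(np.vstack([x, y]), rate=250.0, labels=["C3", "C4"])
    gc, _ = granger_pairwise(es, max_order=6)
    analytic = np.log(1 + b * b)  # restricted var (b^2+1) over full var 1
    assert gc.values[0, 1] == pytest.approx(analytic, rel=0.20)


def test_granger_matches_statsmodels_oracle(rng):
    """The exclusion F statistic agrees with an independent implementation."""
    from statsmodels.tsa.stattools import grangercausalitytests

    x = _simulate_var2(2000, 42)
    es = make_epochs(x, rate=250.0, labels=["C3", "C4"])
    p = 2
    gc, dec = granger_pairwise(es, max_order=p, alpha=0.05)
    # statsmodels tests column 2 -> column 1 of data arranged (target, source)
    res = grangercausalitytests(np.column_stack([x[1], x[0]]), maxlag=[p])
    f_sm, p_sm, *_ = res[p][0]["ssr_ftest"]
    # recompute our F from the published matrices: invert decision logic
    # by re-deriving the statistic through identical nested regressions
    from qeegconn.connectivity import _lag_stacks, _ols_rss

    targets, lags = _lag_stacks(es, [0, 1], p)
    N = targets.shape[0]
    ones = np.ones((N, 1))
    Xf = np.hstack([lags[0][:, :p], lags[1][:, :p], ones])
    _, rss_f = _ols_rss(Xf, targets[:, [1]])
    Xr = np.hstack([lags[1][:, :p], ones])
    _, rss_r = _ols_rss(Xr, targets[:, [1]])
    f_ours = ((rss_r[0] - rss_f[0]) / p) / (rss_f[0] / (N - 2 * p - 1))
    assert f_ours == pytest.approx(f_sm, rel=5e-3)
    assert gc.values[0, 1] == pytest.approx(np.log(rss_r[0] / rss_f[0]), abs=1e-12)


def test_granger_duplicated_channel_reported_missing(rng):
    x = rng.normal(size=3000)
    es = make_epochs(np.vstack([x, x]), rate=250.0, labels=["C3", "C4"])
    gc, dec = granger_pairwise(es, max_order=3)
    assert np.isnan(gc.values[0, 1]) and np.isnan(dec.values[1, 0])
    assert len(gc.params["failed_pairs"]) == 1


def test_granger_scale_invariance(rng):
    x = _simulate_var2(4000, 5)
    es1 = make_epochs(x, rate=250.0)
    es2 = make_epochs(x * np.array([[100.0], [0.2]]), rate=250.0)
    gc1, _ = granger_pairwise(es1, max_order=4)
    gc2, _ = granger_pairwise(es2, max_order=4)
    np.testing.assert_allclose(gc1.values, gc2.values, rtol=1e-8, atol=1e-12)


# ---------------------------------------------------------------------------
# PTE
# ---------------------------------------------------------------------------


def test_pte_diagonal_and_nonnegativity(rng):
    es = make_epochs(rng.normal(size=(3, 5000)), rate=250.0, n_epochs=5)
    m = pte_connectivity(es, (8.0, 13.0))
    assert np.all(np.diag(m.values) == 0.0)
    assert np.all(m.values >= 0.0)
    assert m.directed


def test_pte_detects_delayed_phase_coupling():
    rec = simulate_phase_coupled_pair(250.0, 30.0, (8.0, 13.0), delay=10,
                                      kappa=1.0, seed=11)
    es = make_epochs(rec.samples, rate=250.0, labels=rec.labels, n_epochs=15)
    m = pte_connectivity(es, (8.0, 13.0))
    assert m.values[0, 1] > m.values[1, 0]


def test_pte_amplitude_invariance(rng):
    x = rng.normal(size=(2, 4000))
    es1 = make_epochs(x, rate=250.0, n_epochs=4)
    es2 = make_epochs(x * np.array([[3.0], [0.01]]), rate=250.0, n_epochs=4)
    m1 = pte_connectivity(es1, (8.0, 13.0))
    m2 = pte_connectivity(es2, (8.0, 13.0))
    np.testing.assert_allclose(m1.values, m2.values, atol=1e-12)


def test_pte_parameter_errors(rng):
    es = make_epochs(rng.normal(size=(2, 500)), rate=250.0)
    with pytest.raises(ParameterError):
        pte_connectivity(es, (8.0, 13.0), params=PTEParams(delay=500))
    with pytest.raises(ParameterError):
        pte_connectivity(es, (8.0, 13.0), params=PTEParams(bins=1))
    with pytest.raises(DegenerateChannelError):
        es0 = make_epochs(np.vstack([np.zeros(500), rng.normal(size=500)]),
                          rate=250.0)
        pte_connectivity(es0, (8.0, 13.0))


def test_pte_default_delay_tracks_band():
    # half a mean-period at 250 Hz: alpha ~ 12 samples, delta ~ 62 samples
    p_alpha = PTEParams().resolved((8.0, 13.0), 250.0, 500)
    p_delta = PTEParams().resolved((1.0, 3.0), 250.0, 500)
    assert p_alpha.delay == round(250.0 / 10.5 / 2)
    assert p_delta.delay == round(250.0 / 2.0 / 2)
    assert p_alpha.bins == int(np.ceil(np.sqrt(500)))


def test_pte_no_preferred_direction_when_uncoupled():
    """Across independent uncoupled oscillator pairs the estimator favors
    neither direction (paired sign test over 100 realizations)."""
    diffs = []
    for seed in range(100):
        rec = simulate_phase_coupled_pair(250.0, 8.0, (8.0, 13.0), delay=10,
                                          kappa=0.0, seed=seed)
        es = make_epochs(rec.samples, rate=250.0, labels=rec.labels, n_epochs=4)
        m = pte_connectivity(es, (8.0, 13.0))
        diffs.append(m.values[0, 1] - m.values[1, 0])
    n_pos = int(np.sum(np.array(diffs) > 0))
    p = stats.binomtest(n_pos, len(diffs), 0.5).pvalue
    assert p > 0.01


def test_uncoupled_pair_within_surrogate_null():
    """|PTE(x->y) - PTE(y->x)| of uncoupled pairs stays below the 95%
    quantile of their own time-shift surrogate null (200 surrogates).
    A 95% bound fails ~1 realization in 20 by construction, so the check
    runs five independent realizations and tolerates one exceedance."""
    rng = np.random.default_rng(5)
    passes = 0
    for seed in range(5):
        rec = simulate_phase_coupled_pair(250.0, 20.0, (8.0, 13.0), delay=10,
                                          kappa=0.0, seed=seed)
        es = make_epochs(rec.samples, rate=250.0, labels=rec.labels, n_epochs=10)
        m = pte_connectivity(es, (8.0, 13.0))
        observed = abs(m.values[0, 1] - m.values[1, 0])
        null = []
        n = rec.samples.shape[1]
        for _ in range(200):
            shift = int(rng.integers(n // 4, 3 * n // 4))
            x_s = np.roll(rec.samples[0], shift)
            es_s = make_epochs(np.vstack([x_s, rec.samples[1]]), rate=250.0,
                               labels=rec.labels, n_epochs=10)
            m_s = pte_connectivity(es_s, (8.0, 13.0))
            null.append(abs(m_s.values[0, 1] - m_s.values[1, 0]))
        passes += observed <= np.quantile(null, 0.95)
    assert passes >= 4


# ---------------------------------------------------------------------------
# Thresholding and hemispheric partition
# ---------------------------------------------------------------------------


def _toy_directed(values, labels):
    v = np.asarray(values, dtype=float)
    np.fill_diagonal(v, 0.0)
    return ConnMatrix(values=v, metric="pte", band="alpha", directed=True,
                      node_labels=labels)


def test_threshold_edge_selection():
    m = _toy_directed([[0, 0.1, 0.5], [0.9, 0, 0.0], [0.0, 0.0, 0]],
                      ["C3", "C4", "Cz"])
    assert threshold_directed(m, 1.0).n_edges == 0
    assert threshold_directed(m, 0.05).n_edges == 3
    es = threshold_directed(m, 0.4)
    assert sorted((s, t) for s, t, _ in es.edges) == [("C3", "Cz"), ("C4", "C3")]
    assert es.total_intensity == pytest.approx(1.4)


def test_threshold_negative_warns():
    m = _toy_directed(np.zeros((2, 2)), ["C3", "C4"])
    with pytest.warns(UserWarning):
        threshold_directed(m, -0.5)


def test_threshold_requires_directed():
    m = ConnMatrix(values=np.eye(2), metric="pearson", band="alpha",
                   directed=False, node_labels=["C3", "C4"])
    with pytest.raises(ParameterError):
        threshold_directed(m, 0.1)


def test_interhemispheric_partition():
    m = _toy_directed(np.zeros((4, 4)), ["C3", "F3", "C4", "Cz"])
    m.values[0, 1] = 0.5  # C3 -> F3, intra-left
    m.values[0, 2] = 0.7  # C3 -> C4, cross
    m.values[3, 0] = 0.2  # Cz -> C3, midline
    summary = interhemispheric_summary(threshold_directed(m, 0.1))
    assert summary["intra_left"]["count"] == 1
    assert summary["cross"]["count"] == 1
    assert summary["cross"]["intensity"] == pytest.approx(0.7)
    assert summary["midline_involved"]["count"] == 1
    assert summary["intra_right"]["count"] == 0


def test_interhemispheric_unmapped_label_error():
    from qeegconn.connectivity import EdgeSet
    from qeegconn.errors import LabelError

    edges = EdgeSet(edges=[("EKG", "C3", 1.0)], threshold=0.0,
                    metric="pte", band="alpha")
    with pytest.raises(LabelError):
        interhemispheric_summary(edges)


def test_connmatrix_invariant_enforcement():
    with pytest.raises(ContractError):
        ConnMatrix(values=np.array([[0.0, -0.2], [0.1, 0.0]]), metric="pte",
                   band="alpha", directed=True, node_labels=["C3", "C4"])
    asym = np.array([[1.0, 0.3], [0.2, 1.0]])
    with pytest.raises(ContractError):
        ConnMatrix(values=asym, metric="pearson", band="alpha",
                   directed=False, node_labels=["C3", "C4"])
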