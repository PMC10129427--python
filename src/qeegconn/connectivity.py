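"""Channel-pair connectivity: Pearson r, pairwise Granger causality, PTE.

Three estimators with a common output container (:class:`ConnMatrix`):

* **Pearson** — band-limited product-moment correlation, epoch-averaged;
  undirected, diagonal 1.
* **Granger causality** — for each ordered pair (i, j), the log ratio of
  restricted to full innovation variance, GC(i->j) = ln(s2_r / s2_f), from
  nested least-squares autoregressions; the model order is chosen per pair
  by BIC up to a maximum lag (default 6).  A binary companion matrix holds
  the F-test decision for the lag-exclusion restriction.
* **Phase transfer entropy** — transfer entropy between instantaneous
  phases of the band-limited analytic signal, estimated from binned phase
  histograms: PTE(x->y) = sum p(y+, y, x) ln[p(y+|y,x) / p(y+|y)] with the
  future taken ``delay`` samples ahead.  Directed, non-negative, diagonal 0.

All estimators average over artifact-free epochs treated as independent
realizations; epochs are never concatenated, so no spurious cross-boundary
lags enter the estimates.  Pairs that fail (singular designs, degenerate
channels) are reported as missing values, never silently as zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import hilbert

from .errors import (
    ContractError,
    DegenerateChannelError,
    DegeneracyError,
    InstabilityError,
    ParameterError,
    QeegError,
)
from .signal_io import EpochSet, RegionMap, bandpass_filter

__all__ = [
    "ConnMatrix",
    "VARModel",
    "PTEParams",
    "EdgeSet",
    "pearson_connectivity",
    "fit_var",
    "granger_pairwise",
    "pte_connectivity",
    "threshold_directed",
    "interhemispheric_summary",
]

_METRICS = {"pearson", "granger", "granger_binary", "pte"}


@dataclass
class ConnMatrix:
    """One connectivity metric's channel x channel values for one band.

    For directed metrics entry (i, j) is the influence i -> j.  NaN marks a
    pair whose estimation failed.
    """

    values: np.ndarray
    metric: str
    band: str
    directed: bool
    node_labels: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.node_labels)
        if self.values.shape != (n, n):
            raise ContractError("values must be square and match node_labels")
        if self.metric not in _METRICS:
            raise ContractError(f"unknown metric {self.metric!r}")
        finite = self.values[np.isfinite(self.values)]
        if self.metric == "pearson":
            if self.directed:
                raise ContractError("pearson matrices are undirected")
            if not np.array_equal(self.values, self.values.T):
                raise ContractError("pearson matrix must equal its transpose")
            if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
                raise ContractError("pearson entries must lie in [-1, 1]")
        else:
            if finite.size and finite.min() < -1e-12:
                raise ContractError(f"{self.metric} entries must be non-negative")
            if not np.allclose(np.diag(self.values), 0.0):
                raise ContractError(f"{self.metric} diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def offdiag_values(self) -> np.ndarray:
        """Finite off-diagonal entries (upper triangle only if undirected)."""
        n = self.n_nodes
        if self.directed:
            mask = ~np.eye(n, dtype=bool)
        else:
            mask = np.triu(np.ones((n, n), dtype=bool), k=1)
        vals = self.values[mask]
        return vals[np.isfinite(vals)]


def _check_band(band: tuple[float, float], rate: float) -> tuple[float, float]:
    lo, hi = float(band[0]), float(band[1])
    if not (0 < lo < hi < rate / 2):
        raise ParameterError(f"band {band} outside (0, Nyquist={rate / 2})")
    return lo, hi


def pearson_connectivity(epochs: EpochSet, band: tuple[float, float],
                         band_name: str | None = None) -> ConnMatrix:
    """Epoch-averaged Pearson correlation on band-limited signals."""
    if epochs.n_channels < 2:
        raise ParameterError("need at least 2 channels")
    lo, hi = _check_band(band, epochs.rate)
    acc = np.zeros((epochs.n_channels, epochs.n_channels))
    for k, ep in enumerate(epochs.epochs):
        x = bandpass_filter(ep, (lo, hi), epochs.rate)
        sd = x.std(axis=1)
        dead = np.where(sd <= 1e-12 * (1.0 + np.abs(x).max()))[0]
        if dead.size:
            raise DegenerateChannelError(
                f"zero-variance channel(s) {[epochs.labels[d] for d in dead]} "
                f"in epoch {k} after {band} Hz filtering"
            )
        acc += np.corrcoef(x)
    r = acc / epochs.n_epochs
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnMatrix(
        values=r, metric="pearson",
        band=band_name or f"{lo:g}-{hi:g}Hz", directed=False,
        node_labels=list(epochs.labels), params={"band_hz": [lo, hi]},
    )


# ---------------------------------------------------------------------------
# Granger causality
# ---------------------------------------------------------------------------


@dataclass
class VARModel:
    """A bivariate least-squares VAR fit with BIC-selected order."""

    order: int
    coefficients: list[np.ndarray]  # per-lag 2x2 matrices, [target, source]
    intercept: np.ndarray
    residual_cov: np.ndarray
    criterion_value: float
    resid_ss: np.ndarray  # per-equation residual sum of squares
    nobs: int

    def spectral_radius(self) -> float:
        return _companion_radius(self.coefficients)


def _companion_radius(coefs: list[np.ndarray]) -> float:
    p = len(coefs)
    m = coefs[0].shape[0]
    comp = np.zeros((m * p, m * p))
    comp[:m, :] = np.hstack(coefs)
    if p > 1:
        comp[m:, :-m] = np.eye(m * (p - 1))
    return float(np.abs(np.linalg.eigvals(comp)).max())


def _lag_stacks(epochs: EpochSet, idx: list[int], max_order: int):
    """Pooled targets and per-channel lag regressor blocks.

    All candidate orders are fitted on the common sample t in
    [max_order, L) of every epoch so their BIC values are comparable.
    Returns (targets: N x m, lags: list of N x max_order per channel).
    """
    tgt_parts = [[] for _ in idx]
    lag_parts = [[] for _ in idx]
    for ep in epochs.epochs:
        for c, ch in enumerate(idx):
            x = ep[ch]
            tgt_parts[c].append(x[max_order:])
            lag_parts[c].append(
                np.column_stack([x[max_order - k : len(x) - k] for k in range(1, max_order + 1)])
            )
    targets = np.column_stack([np.concatenate(t) for t in tgt_parts])
    lags = [np.vstack(l) for l in lag_parts]
    return targets, lags


def _ols_rss(X: np.ndarray, Y: np.ndarray):
    """Least squares via normal equations; returns (coeffs, rss per column)."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegeneracyError("singular regressor matrix (collinear channels?)")
    gram = X.T @ X
    beta = np.linalg.solve(gram, X.T @ Y)
    resid = Y - X @ beta
    return beta, np.einsum("ij,ij->j", resid, resid)


def fit_var(epochs: EpochSet, channels: tuple, max_order: int = 6) -> VARModel:
    """Fit a bivariate VAR on a channel pair, order selected by BIC.

    Epochs are pooled as separate realizations sharing coefficients.  The
    BIC is ``ln det(Sigma_hat) + k ln(N) / N`` with k the number of
    estimated coefficients; only stable models (companion spectral radius
    < 1) are eligible.
    """
    if max_order < 1:
        raise ParameterError("max_order must be >= 1")
    if epochs.n_samples <= 10 * max_order:
        raise ParameterError(
            f"epochs of {epochs.n_samples} samples too short for max_order "
            f"{max_order} (need > {10 * max_order})"
        )
    idx = [c if isinstance(c, (int, np.integer)) else epochs.labels.index(c)
           for c in channels]
    if len(idx) != 2:
        raise ParameterError("fit_var operates on exactly one channel pair")
    targets, lags = _lag_stacks(epochs, idx, max_order)
    N = targets.shape[0]
    ones = np.ones((N, 1))

    best = None
    last_err: QeegError | None = None
    for p in range(1, max_order + 1):
        X = np.hstack([lags[0][:, :p], lags[1][:, :p], ones])
        try:
            beta, rss = _ols_rss(X, targets)
        except DegeneracyError as exc:
            last_err = exc
            continue
        sigma = _residual_cov(X, targets, beta, N)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            last_err = DegeneracyError("singular innovation covariance")
            continue
        k = 2 * (2 * p + 1)
        bic = logdet + k * math.log(N) / N
        # rows of beta are [i lags 1..p, j lags 1..p, intercept];
        # A_k[target, source] = coefficient of source's lag k on target
        coefs = []
        for k_ in range(1, p + 1):
            a = np.zeros((2, 2))
            a[:, 0] = beta[k_ - 1]
            a[:, 1] = beta[p + k_ - 1]
            coefs.append(a)
        if _companion_radius(coefs) >= 1.0:
            last_err = InstabilityError(f"order-{p} fit unstable")
            continue
        model = VARModel(
            order=p, coefficients=coefs, intercept=beta[-1].copy(),
            residual_cov=sigma, criterion_value=bic, resid_ss=rss, nobs=N,
        )
        if best is None or bic < best.criterion_value:
            best = model
    if best is None:
        raise last_err or InstabilityError("no stable VAR order found")
    return best


def _residual_cov(X, Y, beta, N):
    resid = Y - X @ beta
    return resid.T @ resid / N


def granger_pairwise(
    epochs: EpochSet,
    max_order: int = 6,
    alpha: float = 0.05,
    band_name: str = "broadband",
) -> tuple[ConnMatrix, ConnMatrix]:
    """Pairwise Granger causality for every ordered channel pair.

    GC(i->j) = ln(RSS_restricted / RSS_full) for predicting j, where the
    restricted model omits i's lags; both models share the BIC-selected
    bivariate order.  The binary matrix holds the F-test decision for the
    exclusion restriction at level ``alpha``.  Failed pairs are NaN in both
    matrices and listed in ``params["failed_pairs"]``.
    """
    n = epochs.n_channels
    if n < 2:
        raise ParameterError("need at least 2 channels")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    gc = np.zeros((n, n))
    binary = np.zeros((n, n))
    failed: list[str] = []
    orders: dict[str, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            try:
                model = fit_var(epochs, (i, j), max_order=max_order)
            except ParameterError:
                raise
            except QeegError as exc:
                gc[i, j] = gc[j, i] = np.nan
                binary[i, j] = binary[j, i] = np.nan
                failed.append(f"{epochs.labels[i]}->{epochs.labels[j]}: {exc}")
                continue
            p = model.order
            orders[f"{epochs.labels[i]}|{epochs.labels[j]}"] = p
            targets, lags = _lag_stacks(epochs, [i, j], max_order)
            N = targets.shape[0]
            ones = np.ones((N, 1))
            df2 = N - 2 * p - 1
            for (src, tgt), lt, col in (((i, j), 1, 1), ((j, i), 0, 0)):
                rss_f = model.resid_ss[col]
                Xr = np.hstack([lags[lt][:, :p], ones])
                _, rss_r = _ols_rss(Xr, targets[:, [col]])
                rss_r = rss_r[0]
                gc[src, tgt] = max(0.0, math.log(rss_r / rss_f))
                F = ((rss_r - rss_f) / p) / (rss_f / df2)
                pval = stats.f.sf(max(F, 0.0), p, df2)
                binary[src, tgt] = 1.0 if pval < alpha else 0.0
    params = {"max_order": max_order, "alpha": alpha,
              "failed_pairs": failed, "orders": orders}
    labels = list(epochs.labels)
    return (
        ConnMatrix(values=gc, metric="granger", band=band_name, directed=True,
                   node_labels=labels, params=params),
        ConnMatrix(values=binary, metric="granger_binary", band=band_name,
                   directed=True, node_labels=labels, params=params),
    )


# ---------------------------------------------------------------------------
# Phase transfer entropy
# ---------------------------------------------------------------------------


@dataclass
class PTEParams:
    """Estimator settings for phase transfer entropy.

    ``delay`` defaults to half the average oscillation period of the band
    in samples (minimum 1); ``bins`` defaults to ceil(sqrt(epoch samples))
    capped at 64.  ``epoch_mode`` selects how epochs combine:
    ``"pooled_counts"`` (default) accumulates the phase histograms over all
    epochs before forming one transfer-entropy estimate — the plug-in bias
    shrinks with the pooled sample count, so weak true phase flow is not
    drowned by per-epoch bias; ``"epoch_mean"`` estimates TE per epoch and
    averages.  Neither mode ever forms lags across an epoch boundary.
    """

    delay: int | None = None
    bins: int | None = None
    band: str | None = None
    epoch_mode: str = "pooled_counts"

    def resolved(self, band: tuple[float, float], rate: float, n_samples: int) -> "PTEParams":
        if self.epoch_mode not in ("pooled_counts", "epoch_mean"):
            raise ParameterError(f"unknown epoch_mode {self.epoch_mode!r}")
        delay = self.delay
        if delay is None:
            f_mean = (band[0] + band[1]) / 2.0
            delay = max(1, int(round(rate / f_mean / 2.0)))
        bins = self.bins
        if bins is None:
            bins = min(64, int(math.ceil(math.sqrt(n_samples))))
        if delay < 1:
            raise ParameterError("PTE delay must be >= 1 sample")
        if bins < 2:
            raise ParameterError("PTE needs at least 2 phase bins")
        if delay >= n_samples:
            raise ParameterError(
                f"delay {delay} >= epoch length {n_samples} samples"
            )
        return PTEParams(delay=delay, bins=bins, band=self.band,
                         epoch_mode=self.epoch_mode)


def _phase_bin_indices(x: np.ndarray, band: tuple[float, float], rate: float,
                       bins: int, labels: list[str]) -> np.ndarray:
    """Band-filter, extract instantaneous phase, and bin it into [0, bins)."""
    xf = bandpass_filter(x, band, rate)
    sd = xf.std(axis=1)
    dead = np.where(sd <= 1e-12 * (1.0 + np.abs(x).max()))[0]
    if dead.size:
        raise DegenerateChannelError(
            f"constant-phase channel(s) {[labels[d] for d in dead]} "
            f"after {band} Hz filtering"
        )
    phases = np.angle(hilbert(xf, axis=-1))
    idx = np.floor((phases + np.pi) / (2 * np.pi) * bins).astype(np.intp)
    return np.clip(idx, 0, bins - 1)


def _te_counts(n3: np.ndarray, n_y: np.ndarray, n_yfy: np.ndarray,
               n_yx: np.ndarray, B: int, M: int) -> float:
    """Plug-in transfer entropy from joint/marginal histogram counts (nats)."""
    nz = np.nonzero(n3)[0]
    yf = nz // (B * B)
    y = (nz // B) % B
    x = nz % B
    num = n3[nz].astype(float) * n_y[y]
    den = n_yfy[yf * B + y].astype(float) * n_yx[y * B + x]
    return float(np.sum(n3[nz] * np.log(num / den)) / M)


def pte_connectivity(
    epochs: EpochSet,
    band: tuple[float, float],
    params: PTEParams | None = None,
    band_name: str | None = None,
) -> ConnMatrix:
    """Phase transfer entropy between every ordered channel pair, per band.

    Phases come from the analytic signal of the zero-phase band-filtered
    trace and are discretized into equal-width bins.  By default the phase
    histograms are pooled over all epochs before one transfer entropy is
    computed per ordered pair (see :class:`PTEParams`); lags never span an
    epoch boundary.  The plug-in estimate is a conditional mutual
    information and thus non-negative; tiny negative rounding is clipped
    (counted in ``params["n_clipped"]``).  PTE(x->x) is 0 by convention.
    """
    lo, hi = _check_band(band, epochs.rate)
    resolved = (params or PTEParams()).resolved((lo, hi), epochs.rate,
                                                epochs.n_samples)
    delay, B = resolved.delay, resolved.bins
    n = epochs.n_channels
    pooled = resolved.epoch_mode == "pooled_counts"
    acc = np.zeros((n, n))
    n_clipped = 0

    if pooled:
        need = n * n * B**3 * 8
        if need > 1.5e9:
            raise ParameterError(
                f"pooled phase histograms would need ~{need / 1e9:.1f} GB "
                f"({n} channels, {B} bins); reduce bins or use epoch_mean"
            )
        c_y = np.zeros((n, B), dtype=np.int64)
        c_yfy = np.zeros((n, B * B), dtype=np.int64)
        c_yx = np.zeros((n, n, B * B), dtype=np.int64)
        c3 = np.zeros((n, n, B * B * B), dtype=np.int64)
        m_total = 0
    for ep in epochs.epochs:
        idx = _phase_bin_indices(ep, (lo, hi), epochs.rate, B, epochs.labels)
        M = epochs.n_samples - delay
        past = idx[:, :-delay]
        fut = idx[:, delay:]
        # per-channel marginals that do not depend on the source channel
        n_y = [np.bincount(past[j], minlength=B) for j in range(n)]
        n_yfy = [np.bincount(fut[j] * B + past[j], minlength=B * B) for j in range(n)]
        if pooled:
            m_total += M
            c_y += np.asarray(n_y)
            c_yfy += np.asarray(n_yfy)
        for j in range(n):
            code_fy = fut[j] * B + past[j]
            for i in range(n):
                if i == j:
                    continue
                n_yx = np.bincount(past[j] * B + past[i], minlength=B * B)
                n3 = np.bincount(code_fy * B + past[i], minlength=B * B * B)
                if pooled:
                    c_yx[i, j] += n_yx
                    c3[i, j] += n3
                else:
                    te = _te_counts(n3, n_y[j], n_yfy[j], n_yx, B, M)
                    if te < 0:
                        n_clipped += 1
                        te = 0.0
                    acc[i, j] += te
    if pooled:
        for j in range(n):
            for i in range(n):
                if i == j:
                    continue
                te = _te_counts(c3[i, j], c_y[j], c_yfy[j], c_yx[i, j], B, m_total)
                if te < 0:
                    n_clipped += 1
                    te = 0.0
                acc[i, j] = te
        values = acc
    else:
        values = acc / epochs.n_epochs
    np.fill_diagonal(values, 0.0)
    return ConnMatrix(
        values=values, metric="pte",
        band=band_name or f"{lo:g}-{hi:g}Hz", directed=True,
        node_labels=list(epochs.labels),
        params={"band_hz": [lo, hi], "delay": delay, "bins": B,
                "epoch_mode": resolved.epoch_mode, "n_clipped": n_clipped},
    )


# ---------------------------------------------------------------------------
# Edge thresholding and hemispheric partition
# ---------------------------------------------------------------------------


@dataclass
class EdgeSet:
    """Directed edges surviving a threshold, with their weights."""

    edges: list[tuple[str, str, float]]
    threshold: float
    metric: str
    band: str

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_intensity(self) -> float:
        return float(sum(w for _, _, w in self.edges))


def threshold_directed(conn: ConnMatrix, threshold: float) -> EdgeSet:
    """Retain directed edges with value strictly above ``threshold``."""
    if not conn.directed:
        raise ParameterError("threshold_directed requires a directed matrix")
    if threshold < 0 and conn.metric in ("granger", "granger_binary", "pte"):
        warnings.warn(
            f"negative threshold on non-negative metric {conn.metric}; "
            f"all present edges will be retained",
            stacklevel=2,
        )
    edges = []
    n = conn.n_nodes
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            v = conn.values[i, j]
            if np.isfinite(v) and v > threshold:
                edges.append((conn.node_labels[i], conn.node_labels[j], float(v)))
    return EdgeSet(edges=edges, threshold=float(threshold),
                   metric=conn.metric, band=conn.band)


def interhemispheric_summary(edges: EdgeSet,
                             regions: RegionMap | None = None) -> dict[str, dict]:
    """Partition retained edges by endpoint hemispheres.

    Categories: ``intra_left``, ``intra_right``, ``cross`` (one endpoint in
    each hemisphere) and ``midline_involved`` (either endpoint on the
    midline; takes precedence).  Each category reports edge count and
    summed intensity.
    """
    regions = regions or RegionMap.default()
    out = {k: {"count": 0, "intensity": 0.0}
           for k in ("intra_left", "intra_right", "cross", "midline_involved")}
    for src, tgt, w in edges.edges:
        hs, ht = regions.hemisphere_of(src), regions.hemisphere_of(tgt)
        if "midline" in (hs, ht):
            cat = "midline_involved"
        elif hs == ht:
            cat = f"intra_{hs}"
        else:
            cat = "cross"
        out[cat]["count"] += 1
        out[cat]["intensity"] += w
    return out
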