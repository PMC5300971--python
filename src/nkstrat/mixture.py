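"""Per-sample finite-mixture clustering of gated NK events.

EM-fitted Gaussian mixtures with full covariance on the 5 maturation
markers (a Student-t family with fixed degrees of freedom is available
behind an option), k-means++ initialisation with restarts, and component-
count selection by BIC and ICL. Conventions:

* BIC = 2*loglik - p*log(n) — larger is better;
* ICL = BIC - 2*H where H is the total entropy of the posterior
  responsibilities (penalises overlapping, poorly separated components).

A fit "fails" (mirroring samples that cannot be computed in practice)
when every restart ends with a non-finite likelihood, a component weight
below 1/(10n), or a covariance condition number above 1e12.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .io_gating import NK_MARKERS, EventMatrix

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


class MixtureFitError(RuntimeError):
    """All restarts failed for a sample; carries the sample id."""

    def __init__(self, message: str, sample_id: str = ""):
        super().__init__(message)
        self.sample_id = sample_id


@dataclass
class MixtureOptions:
    family: str = "gaussian"  # or "student-t"
    dof: float = 4.0  # Student-t degrees of freedom (fixed, not estimated)
    max_iter: int = 150
    tol: float = 1e-6  # convergence: |delta loglik| per event
    n_init: int = 3
    seed: int = 0
    reg: float = 1e-6  # covariance ridge, times trace(global cov)/d
    max_condition: float = 1e12

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "student-t"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class MixtureModel:
    K: int
    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)
    family: str
    dof: float
    loglik_trace: list[float]  # total loglik per EM iteration
    converged: bool
    channels: list[str]

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def n_params(self) -> int:
        d = self.means.shape[1]
        return (self.K - 1) + self.K * d + self.K * d * (d + 1) // 2


def _as_array(events, channels: Sequence[str] | None) -> tuple[np.ndarray, list[str], str]:
    if isinstance(events, EventMatrix):
        cols = list(channels) if channels is not None else [
            c for c in NK_MARKERS if c in events.channels
        ] or events.channels
        return events.values(cols), cols, events.sample_id
    X = np.asarray(events, dtype=float)
    if X.ndim != 2:
        raise ValueError("events must be a 2-D array or EventMatrix")
    cols = list(channels) if channels is not None else [
        f"ch{i}" for i in range(X.shape[1])
    ]
    return X, cols, ""


def _component_logpdf(
    X: np.ndarray, mean: np.ndarray, cov: np.ndarray, family: str, dof: float
) -> tuple[np.ndarray, float]:
    """Log density of one component; returns (logpdf, condition number)."""
    d = X.shape[1]
    chol = np.linalg.cholesky(cov)
    diag = np.diag(chol)
    logdet = 2.0 * float(np.log(diag).sum())
    solved = solve_triangular(chol, (X - mean).T, lower=True)
    maha = np.einsum("ij,ij->j", solved, solved)
    cond = float((diag.max() / diag.min()) ** 2)
    if family == "gaussian":
        lp = -0.5 * (d * _LOG_2PI + logdet + maha)
    else:
        lp = (
            lgamma((dof + d) / 2.0)
            - lgamma(dof / 2.0)
            - 0.5 * d * np.log(dof * np.pi)
            - 0.5 * logdet
            - 0.5 * (dof + d) * np.log1p(maha / dof)
        )
    return lp, cond


def _weighted_log_prob(X, weights, means, covs, family, dof):
    K = len(weights)
    out = np.empty((X.shape[0], K))
    max_cond = 1.0
    for k in range(K):
        lp, cond = _component_logpdf(X, means[k], covs[k], family, dof)
        out[:, k] = np.log(weights[k]) + lp
        max_cond = max(max_cond, cond)
    return out, max_cond


def _m_step(X, resp, ridge, u=None):
    """Weighted parameter update; ``u`` carries the gamma-scale weights of
    the Student-t model (None for the Gaussian family)."""
    n, d = X.shape
    nk = resp.sum(axis=0)
    weights = nk / n
    w = resp if u is None else resp * u
    denom = w.sum(axis=0)
    means = (w.T @ X) / denom[:, None]
    K = resp.shape[1]
    covs = np.empty((K, d, d))
    eye = np.eye(d)
    for k in range(K):
        Xc = X - means[k]
        covs[k] = (Xc.T * w[:, k]) @ Xc / max(nk[k], 1e-12) + ridge * eye
    return weights, means, covs


def _em_once(
    X: np.ndarray, K: int, opts: MixtureOptions, init_seed: int
) -> tuple[MixtureModel, np.ndarray, bool]:
    """One EM run from a k-means++ start. Returns (model, resp, degenerate)."""
    n, d = X.shape
    global_cov = np.cov(X.T) if n > 1 else np.zeros((d, d))
    ridge = opts.reg * float(np.trace(np.atleast_2d(global_cov))) / d
    centers, _ = kmeans_plusplus(X, n_clusters=K, random_state=init_seed)
    # hard assignment to the nearest start defines the initial responsibilities
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    resp = np.zeros((n, K))
    resp[np.arange(n), d2.argmin(axis=1)] = 1.0

    weights, means, covs = _m_step(X, resp, ridge)
    trace: list[float] = []
    converged = False
    max_cond = 1.0
    for _ in range(opts.max_iter):
        log_prob, max_cond = _weighted_log_prob(
            X, weights, means, covs, opts.family, opts.dof
        )
        log_norm = logsumexp(log_prob, axis=1)
        total = float(log_norm.sum())
        trace.append(total)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < opts.tol * n:
            converged = True
            break
        resp = np.exp(log_prob - log_norm[:, None])
        if opts.family == "student-t":
            u = np.empty((n, K))
            for k in range(K):
                chol = np.linalg.cholesky(covs[k])
                solved = solve_triangular(chol, (X - means[k]).T, lower=True)
                maha = np.einsum("ij,ij->j", solved, solved)
                u[:, k] = (opts.dof + d) / (opts.dof + maha)
            weights, means, covs = _m_step(X, resp, ridge, u=u)
        else:
            weights, means, covs = _m_step(X, resp, ridge)

    model = MixtureModel(
        K=K, weights=weights, means=means, covariances=covs,
        family=opts.family, dof=opts.dof, loglik_trace=trace,
        converged=converged, channels=[],
    )
    degenerate = (
        not np.isfinite(trace[-1])
        or weights.min() < 1.0 / (10.0 * n)
        or max_cond > opts.max_condition
    )
    return model, resp, degenerate


def fit_mixture(
    events,
    K: int,
    opts: MixtureOptions | None = None,
    channels: Sequence[str] | None = None,
) -> MixtureModel:
    """EM-fit a K-component mixture; best of ``n_init`` restarts by loglik.

    Raises :class:`MixtureFitError` when the sample has fewer events than
    components or every restart is degenerate.
    """
    opts = opts or MixtureOptions()
    X, cols, sample_id = _as_array(events, channels)
    n = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < K:
        raise MixtureFitError(
            f"sample {sample_id or '<array>'}: {n} events < K={K}", sample_id
        )
    best: MixtureModel | None = None
    for r in range(opts.n_init):
        init_seed = int((opts.seed + 7919 * r) % (2**31 - 1))
        try:
            model, _, degenerate = _em_once(X, K, opts, init_seed)
        except np.linalg.LinAlgError:
            continue
        if degenerate:
            continue
        if best is None or model.loglik > best.loglik:
            best = model
    if best is None:
        raise MixtureFitError(
            f"sample {sample_id or '<array>'}: all {opts.n_init} restarts degenerate",
            sample_id,
        )
    best.channels = cols
    return best


def assign_events(
    model: MixtureModel, events, channels: Sequence[str] | None = None
) -> np.ndarray:
    """MAP cluster labels (argmax posterior responsibility; ties break to
    the lowest cluster id)."""
    X, cols, _ = _as_array(events, channels or (model.channels or None))
    if model.channels and cols != model.channels:
        raise ValueError(
            f"channel mismatch: model fitted on {model.channels}, got {cols}"
        )
    if X.shape[1] != model.means.shape[1]:
        raise ValueError("event dimensionality does not match the model")
    log_prob, _ = _weighted_log_prob(
        X, model.weights, model.means, model.covariances, model.family, model.dof
    )
    return log_prob.argmax(axis=1)


def _posterior_entropy(model: MixtureModel, X: np.ndarray) -> float:
    log_prob, _ = _weighted_log_prob(
        X, model.weights, model.means, model.covariances, model.family, model.dof
    )
    log_resp = log_prob - logsumexp(log_prob, axis=1)[:, None]
    resp = np.exp(log_resp)
    return float(-(resp * np.where(resp > 0, log_resp, 0.0)).sum())


def bic(model: MixtureModel, n: int) -> float:
    return 2.0 * model.loglik - model.n_params() * float(np.log(n))


@dataclass
class ModelSelectionTable:
    """BIC/ICL per scanned component count; failed fits carry NaN scores."""

    table: pd.DataFrame  # columns: K, loglik, n_params, bic, icl, converged, failed

    def _argmax(self, col: str) -> int:
        ok = self.table[~self.table["failed"]]
        if ok.empty:
            raise MixtureFitError("every K in the scanned range failed")
        return int(ok.loc[ok[col].idxmax(), "K"])

    @property
    def best_k_bic(self) -> int:
        return self._argmax("bic")

    @property
    def best_k_icl(self) -> int:
        return self._argmax("icl")

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def select_K(
    events,
    K_range: Sequence[int],
    opts: MixtureOptions | None = None,
    channels: Sequence[str] | None = None,
) -> ModelSelectionTable:
    """Scan component counts and score each fit by BIC and ICL."""
    if len(K_range) == 0:
        raise ValueError("K_range must be non-empty")
    opts = opts or MixtureOptions()
    X, cols, _ = _as_array(events, channels)
    rows = []
    for K in K_range:
        try:
            model = fit_mixture(X, K, opts, channels=cols)
        except MixtureFitError:
            rows.append(
                {"K": K, "loglik": np.nan, "n_params": np.nan, "bic": np.nan,
                 "icl": np.nan, "converged": False, "failed": True}
            )
            continue
        b = bic(model, X.shape[0])
        icl = b - 2.0 * _posterior_entropy(model, X)
        rows.append(
            {"K": K, "loglik": model.loglik, "n_params": model.n_params(),
             "bic": b, "icl": icl, "converged": model.converged, "failed": False}
        )
    return ModelSelectionTable(pd.DataFrame(rows))


CLUSTER_TABLE_COLUMNS = ("sample_id", "cluster_id") + NK_MARKERS + ("event_count",)


def cluster_cohort(
    samples: Sequence[EventMatrix],
    K: int,
    opts: MixtureOptions | None = None,
    channels: Sequence[str] = NK_MARKERS,
) -> tuple[pd.DataFrame, list[str]]:
    """Fit every sample with a fixed K and pool the cluster records.

    Per-sample failures are collected, not fatal; the returned table has
    (#samples - #failures) * K rows with columns
    (sample_id, cluster_id, <markers...>, event_count).
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    opts = opts or MixtureOptions()
    channels = list(channels)
    rows = []
    failed: list[str] = []
    for i, sample in enumerate(samples):
        sample_opts = MixtureOptions(
            **{**opts.__dict__, "seed": int((opts.seed + i) % (2**31 - 1))}
        )
        try:
            model = fit_mixture(sample, K, sample_opts, channels=channels)
        except MixtureFitError:
            logger.warning("sample %s failed to be computed", sample.sample_id)
            failed.append(sample.sample_id)
            continue
        labels = assign_events(model, sample, channels=channels)
        counts = np.bincount(labels, minlength=K)
        for k in range(K):
            rows.append(
                (sample.sample_id, k, *model.means[k], int(counts[k]))
            )
    if not rows:
        raise MixtureFitError("all samples failed to be computed")
    table = pd.DataFrame(
        rows, columns=["sample_id", "cluster_id", *channels, "event_count"]
    )
    return table, failed


__all__ = [
    "MixtureOptions", "MixtureModel", "MixtureFitError", "ModelSelectionTable",
    "fit_mixture", "assign_events", "select_K", "bic", "cluster_cohort",
    "CLUSTER_TABLE_COLUMNS",
]
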