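"""Left-truncated mixture Gaussian (LTMG) modelling of per-gene expression.

Each gene's expression across cells is modelled as a mixture of k Gaussians
whose components stand for discrete transcriptional regulatory states.
Values at or below a truncation point (zeros and near-zero noise on the log
scale) are treated as left-censored: they contribute the left-tail mass
``alpha_i * Phi((T - mu_i) / sigma_i)`` to the likelihood instead of a
density value.  Parameters are estimated by a censored-data EM; the component
count is chosen by BIC.  The per-cell argmax-posterior component index is the
transcriptional regulatory signal (TRS) used as an element-wise loss weight
in the autoencoders.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numba
import numpy as np
from scipy.special import ndtr
from scipy.stats import norm

_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _normpdf(x, mean, sd):
    z = (x - mean) / sd
    return np.exp(-0.5 * z * z) * (_INV_SQRT2PI / sd)

__all__ = ["LTMGFit", "TRSMatrix", "fit_ltmg_gene", "assign_trs", "build_trs_matrix"]

_SIGMA_FLOOR = 1e-3
_TINY = 1e-300


@dataclass
class LTMGFit:
    """Converged mixture fit for one gene.

    ``weights``/``means``/``sds`` are stored with means sorted ascending so
    component 1 is always the lowest-expression state.  ``flagged`` marks
    degenerate fits (constant gene, EM failure) that fell back to k=1.
    """

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    bic: float
    truncation_point: float
    log_likelihood: float = float("nan")
    flagged: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-8):
            raise ValueError("mixing weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("component SDs must be positive")
        order = np.argsort(self.means, kind="stable")
        self.weights = self.weights[order]
        self.means = self.means[order]
        self.sds = self.sds[order]


@dataclass
class TRSMatrix:
    """Discrete regulatory-signal labels (cells x genes) plus per-gene fits."""

    labels: np.ndarray  # int, entries in 1..k_g per gene g
    fits: list[LTMGFit]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def to_weights(self, mode: str = "minmax") -> np.ndarray:
        """Loss-weight view of the labels.

        ``minmax`` rescales labels per gene to [0, 1] via (label-1)/(k-1) so
        the regularizer strength alpha means the same thing whatever k a gene
        selected; single-component genes get weight 0.  ``expressed`` is the
        binary reading — the lowest (censored) state weighs 0 and every
        expressed state weighs 1 — which treats all technical zeros as
        equally unreliable regardless of how many states a gene has.
        ``raw`` keeps the integer labels.
        """
        if mode == "raw":
            return self.labels.astype(float)
        if mode == "expressed":
            return (self.labels > 1).astype(float)
        if mode != "minmax":
            raise ValueError(f"unknown TRS weight mode {mode!r}")
        w = np.zeros(self.labels.shape, dtype=float)
        for g, fit in enumerate(self.fits):
            k = fit.n_components
            if k > 1:
                w[:, g] = (self.labels[:, g] - 1) / (k - 1)
        return w


def _censored_loglik(obs, n_cens, T, weights, means, sds):
    if len(obs):
        dens = weights * _normpdf(obs[:, None], means[None, :], sds[None, :])
        ll = float(np.log(np.maximum(dens.sum(axis=1), _TINY)).sum())
    else:
        ll = 0.0
    if n_cens:
        tail = float(np.maximum((weights * ndtr((T - means) / sds)).sum(), _TINY))
        ll += n_cens * np.log(tail)
    return ll


@numba.njit(cache=False, fastmath=False)
def _em_kernel(obs, n_cens, T, weights, means, sds, tol, max_iter, sigma_floor):  # pragma: no cover
    """Censored-data EM from one initialisation (compiled inner loop)."""
    k = len(weights)
    n_obs = len(obs)
    n = n_obs + n_cens
    trace = np.empty(max_iter)
    n_done = 0
    prev_ll = -np.inf
    inv_sqrt2pi = 0.3989422804014327
    sqrt2 = 1.4142135623730951
    tiny = 1e-300
    r_obs = np.empty((n_obs, k))
    for _ in range(max_iter):
        # E-step: responsibilities of observed points (densities) and of the
        # censored block (left-tail masses).
        for j in range(n_obs):
            s = 0.0
            for i in range(k):
                z = (obs[j] - means[i]) / sds[i]
                d = weights[i] * np.exp(-0.5 * z * z) * inv_sqrt2pi / sds[i]
                r_obs[j, i] = d
                s += d
            if s < tiny:
                s = tiny
            for i in range(k):
                r_obs[j, i] /= s
        r_cens = np.zeros(k)
        m1 = np.zeros(k)
        m2 = np.zeros(k)
        if n_cens > 0:
            tails = np.empty(k)
            tot = 0.0
            for i in range(k):
                z = (T - means[i]) / sds[i]
                # erfc keeps the far-left tail representable (erf saturates
                # at |z| ~ 8 and would zero the CDF)
                cdf = 0.5 * math.erfc(-z / sqrt2)
                t = weights[i] * cdf
                if t < tiny:
                    t = tiny
                tails[i] = t
                tot += t
                # conditional moments of N(mu, sd) truncated to (-inf, T]
                pdf = np.exp(-0.5 * z * z) * inv_sqrt2pi
                if cdf > 0.0 and pdf / cdf < 1e12:
                    ratio = pdf / cdf
                else:
                    ratio = -z  # asymptotic hazard phi/Phi ~ -z as z -> -inf
                m1[i] = means[i] - sds[i] * ratio
                var = sds[i] * sds[i] * max(1.0 - z * ratio - ratio * ratio, 0.0)
                m2[i] = var + m1[i] * m1[i]
            for i in range(k):
                r_cens[i] = tails[i] / tot

        # M-step
        for i in range(k):
            n_i = n_cens * r_cens[i]
            sx = n_cens * r_cens[i] * m1[i]
            for j in range(n_obs):
                n_i += r_obs[j, i]
                sx += r_obs[j, i] * obs[j]
            if n_i < tiny:
                n_i = tiny
            weights[i] = n_i / n
            mu = sx / n_i
            means[i] = mu
            sq = n_cens * r_cens[i] * (m2[i] - 2.0 * mu * m1[i] + mu * mu)
            for j in range(n_obs):
                diff = obs[j] - mu
                sq += r_obs[j, i] * diff * diff
            v = sq / n_i
            if v < sigma_floor * sigma_floor:
                v = sigma_floor * sigma_floor
            sds[i] = np.sqrt(v)

        # log-likelihood
        ll = 0.0
        for j in range(n_obs):
            s = 0.0
            for i in range(k):
                z = (obs[j] - means[i]) / sds[i]
                s += weights[i] * np.exp(-0.5 * z * z) * inv_sqrt2pi / sds[i]
            ll += np.log(max(s, tiny))
        if n_cens > 0:
            tail = 0.0
            for i in range(k):
                z = (T - means[i]) / sds[i]
                tail += weights[i] * 0.5 * math.erfc(-z / sqrt2)
            ll += n_cens * np.log(max(tail, tiny))
        trace[n_done] = ll
        n_done += 1
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * (1.0 + abs(ll)):
            break
        prev_ll = ll
    return weights, means, sds, trace[:n_done]


def _em_once(obs, n_cens, T, k, weights, means, sds, tol, max_iter, sigma_floor):
    """Censored-data EM from one initialisation; returns params + loglik trace."""
    w, m, s, trace = _em_kernel(
        np.ascontiguousarray(obs, dtype=np.float64),
        int(n_cens),
        float(T),
        weights.astype(np.float64).copy(),
        means.astype(np.float64).copy(),
        sds.astype(np.float64).copy(),
        float(tol),
        int(max_iter),
        float(sigma_floor),
    )
    return w, m, s, list(trace)


def _degenerate_fit(x, T, sigma_floor):
    mu = float(np.mean(x)) if len(x) else T
    n = max(len(x), 1)
    ll = _censored_loglik(
        x[x > T], int((x <= T).sum()), T, np.array([1.0]), np.array([mu]), np.array([sigma_floor])
    )
    return LTMGFit(
        n_components=1,
        weights=np.array([1.0]),
        means=np.array([mu]),
        sds=np.array([sigma_floor]),
        bic=2 * np.log(n) - 2 * ll,
        truncation_point=T,
        log_likelihood=ll,
        flagged=True,
    )


def fit_ltmg_gene(
    expr: np.ndarray,
    max_components: int = 5,
    truncation_point: float = 0.0,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 300,
    sigma_floor: float = _SIGMA_FLOOR,
    min_samples: int = 10,
    seed: int | None = None,
) -> LTMGFit:
    """Fit the left-truncated mixture to one gene, choosing k by BIC.

    Runs censored EM for each k in 1..max_components with k-means-style
    initialisation and ``n_restarts`` random restarts, and returns the fit
    minimising ``BIC = (3k - 1) ln n - 2 logL`` (weights live on a simplex,
    hence 3k - 1 free parameters).
    """
    x = np.asarray(expr, dtype=float).ravel()
    if len(x) < min_samples:
        raise ValueError(f"need at least {min_samples} cells, got {len(x)}")
    T = float(truncation_point)
    obs = x[x > T]
    n_cens = int((x <= T).sum())
    n = len(x)
    if len(np.unique(obs)) <= 1:
        return _degenerate_fit(x, T, sigma_floor)

    rng = np.random.default_rng(seed)
    best: LTMGFit | None = None
    for k in range(1, max_components + 1):
        if len(obs) < 2 * k:
            break
        restarts = 1 if k == 1 else n_restarts
        best_ll, best_params = -np.inf, None
        for r in range(restarts):
            # quantile/k-means-flavoured init on the observed values
            if r == 0:
                qs = np.quantile(obs, (np.arange(k) + 0.5) / k)
            else:
                qs = np.sort(rng.choice(obs, size=k, replace=False))
            means0 = qs.astype(float)
            sds0 = np.full(k, max(np.std(obs) / max(k, 1), sigma_floor))
            weights0 = np.full(k, 1.0 / k)
            try:
                w, m, s, trace = _em_once(
                    obs, n_cens, T, k, weights0, means0, sds0, tol, max_iter, sigma_floor
                )
            except FloatingPointError:
                continue
            if trace and trace[-1] > best_ll:
                best_ll, best_params = trace[-1], (w, m, s)
        if best_params is None:
            continue
        w, m, s = best_params
        bic = (3 * k - 1) * np.log(n) - 2 * best_ll
        fit = LTMGFit(k, w, m, s, bic, T, log_likelihood=best_ll)
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        return _degenerate_fit(x, T, sigma_floor)
    return best


def assign_trs(expr: np.ndarray, fit: LTMGFit) -> np.ndarray:
    """Label each cell with its argmax-posterior component (1-based).

    The posterior is proportional to ``alpha_i * phi(x; mu_i, sigma_i)``;
    ties break toward the smaller component index, and censored values
    (x <= truncation point) go to the lowest-mean component.
    """
    x = np.asarray(expr, dtype=float).ravel()
    k = fit.n_components
    if k == 1:
        return np.ones(len(x), dtype=int)
    score = fit.weights * norm.pdf(x[:, None], fit.means[None, :], fit.sds[None, :])
    labels = np.argmax(score, axis=1) + 1  # argmax returns first max: low-index tie-break
    labels[x <= fit.truncation_point] = 1  # means sorted ascending
    return labels.astype(int)


def build_trs_matrix(
    x,
    max_components: int = 5,
    truncation_point: float = 0.0,
    seed: int | None = 0,
    **fit_kwargs,
) -> TRSMatrix:
    """Fit LTMG gene-by-gene on a preprocessed matrix and assemble the TRS.

    A failing gene never aborts the matrix: it falls back to a flagged k=1
    fit with all labels 1.
    """
    values = x.values if hasattr(x, "values") else np.asarray(x, dtype=float)
    n, m = values.shape
    labels = np.ones((n, m), dtype=int)
    fits: list[LTMGFit] = []
    base = 0 if seed is None else int(seed)
    for g in range(m):
        try:
            fit = fit_ltmg_gene(
                values[:, g],
                max_components=max_components,
                truncation_point=truncation_point,
                seed=(base + g) % (2**31 - 1),
                **fit_kwargs,
            )
        except ValueError:
            fit = _degenerate_fit(values[:, g], float(truncation_point), _SIGMA_FLOOR)
        fits.append(fit)
        labels[:, g] = assign_trs(values[:, g], fit)
    return TRSMatrix(labels=labels, fits=fits)
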