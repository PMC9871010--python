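"""Estimation of the cell-type-of-interest proportion in bulk tissue.

A bulk expression value for a signature gene g in sample i is modeled as a
mixture ``w_i^g = pi_i * s_i^g + (1 - pi_i) * t_i^g`` of unobserved
expression in the cell type of interest (s, e.g. epithelium) and in all
other cells (t, e.g. stroma), with ``s ~ N(mu_S, sigma_S^2)`` and
``t ~ N(mu_T, sigma_T^2)`` per gene.  Marginally

    w_i^g ~ N(pi_i mu_S + (1-pi_i) mu_T,  pi_i^2 sigma_S^2 + (1-pi_i)^2 sigma_T^2),

so the likelihood of pi is available in closed form per gene.  A prior
proportion h_i (for instance a rescaled xCell enrichment score) enters
through ``h_i ~ Beta(pi_i * delta, (1 - pi_i) * delta)``, which makes h an
unbiased but noisy estimate of pi with concentration delta estimated from
the data.  Both sources are combined in a single log likelihood that is
maximized by block coordinate ascent over per-gene Gaussian parameters,
per-sample proportions and delta.  Initializing pi at the prior anchors the
"S" component to the cell type the prior describes and resolves the label
switching inherent to two-component mixtures.

Robustness comes from bagging: the model is refit on bootstrap draws of the
samples, every sample is re-scored under each fitted parameter set, and the
final estimate is a per-sample tail-trimmed mean across bootstraps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "PriorScoreVector",
    "SignatureExpressionMatrix",
    "SignatureMixtureParams",
    "CellProportionEstimate",
    "rescale_prior",
    "signature_log_likelihood",
    "fit_signature_mixture",
    "estimate_pi_bagged",
]

PI_LO, PI_HI = 0.01, 0.99
DELTA_LO, DELTA_HI = 0.1, 1e4
DELTA_INIT = 10.0
_ASCENT_SLACK = 1e-8  # numerical slack on the monotonicity assertion


@dataclass
class PriorScoreVector:
    """Per-sample prior proportions h in (0,1) with Beta concentration delta."""

    sample_ids: np.ndarray
    h: np.ndarray
    delta: float | None = None

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.h.shape[0] != self.sample_ids.shape[0]:
            raise ValueError("sample_ids and h lengths differ")
        if not np.all((self.h > 0) & (self.h < 1)):
            raise ValueError("prior scores must lie strictly in (0, 1)")

    def flipped(self) -> "PriorScoreVector":
        """Prior for the complementary cell type (h -> 1 - h)."""
        return PriorScoreVector(self.sample_ids, 1.0 - self.h, self.delta)


@dataclass
class SignatureExpressionMatrix:
    """Samples x signature-genes matrix of normalized expression."""

    W: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D (samples x genes)")
        if self.W.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("W shape inconsistent with ids")
        if self.W.shape[1] < 2:
            raise ValueError("need at least 2 signature genes")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W contains non-finite entries")


@dataclass
class SignatureMixtureParams:
    """Per-gene Gaussian parameters (mu_S, mu_T, sigma_S, sigma_T)."""

    mu_S: np.ndarray
    mu_T: np.ndarray
    sigma_S: np.ndarray
    sigma_T: np.ndarray

    def __post_init__(self) -> None:
        for name in ("mu_S", "mu_T", "sigma_S", "sigma_T"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.sigma_S <= 0) or np.any(self.sigma_T <= 0):
            raise ValueError("sigmas must be strictly positive")

    def swapped(self) -> "SignatureMixtureParams":
        return SignatureMixtureParams(self.mu_T.copy(), self.mu_S.copy(),
                                      self.sigma_T.copy(), self.sigma_S.copy())


@dataclass
class CellProportionEstimate:
    """Bagged per-sample proportion estimates with bootstrap provenance."""

    sample_ids: np.ndarray
    pi_hat: np.ndarray
    n_boot: int
    trim_frac: float
    per_sample_boot_spread: np.ndarray
    delta_hat: float
    boot_estimates: np.ndarray | None = field(default=None, repr=False)


def rescale_prior(raw_scores, sample_ids=None, eps: float = 0.01) -> PriorScoreVector:
    """Min-max rescale raw enrichment scores to (0,1), clipped to [eps, 1-eps].

    Raises if all scores are identical: a constant prior carries no ranking
    information and must be supplied explicitly by the caller instead.
    """
    s = np.asarray(raw_scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    lo, hi = s.min(), s.max()
    if hi == lo:
        raise ValueError("all prior scores identical; prior is uninformative")
    h = np.clip((s - lo) / (hi - lo), eps, 1.0 - eps)
    if sample_ids is None:
        sample_ids = np.arange(s.size)
    return PriorScoreVector(sample_ids=np.asarray(sample_ids), h=h)


def _gauss_loglik_matrix(W, pi, params) -> np.ndarray:
    """N x G matrix of marginal Gaussian log densities of w given pi."""
    pi = pi[:, None]
    mean = pi * params.mu_S[None, :] + (1 - pi) * params.mu_T[None, :]
    var = pi**2 * params.sigma_S[None, :] ** 2 + (1 - pi) ** 2 * params.sigma_T[None, :] ** 2
    return -0.5 * (np.log(2 * np.pi * var) + (W - mean) ** 2 / var)


def _beta_loglik(h, pi, delta) -> np.ndarray:
    return stats.beta.logpdf(h, pi * delta, (1 - pi) * delta)


def signature_log_likelihood(
    W: SignatureExpressionMatrix,
    pi: np.ndarray,
    params: SignatureMixtureParams,
    prior: PriorScoreVector,
) -> float:
    """Joint log likelihood of signature expression and the prior given pi.

    Sum over samples of (a) marginal Gaussian log densities of each
    signature gene under the mixture mean/variance and (b) the Beta log
    density of the prior score.  Deterministic given its inputs.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any((pi <= 0) | (pi >= 1)):
        raise ValueError("pi must lie strictly in (0, 1)")
    if prior.delta is None:
        raise ValueError("prior.delta must be set")
    ll_w = _gauss_loglik_matrix(W.W, pi, params)
    if not np.all(np.isfinite(ll_w)):
        i, g = np.argwhere(~np.isfinite(ll_w))[0]
        raise FloatingPointError(
            f"non-finite expression log-likelihood at sample {i}, gene {g}")
    ll_h = _beta_loglik(prior.h, pi, prior.delta)
    if not np.all(np.isfinite(ll_h)):
        i = int(np.argwhere(~np.isfinite(ll_h))[0])
        raise FloatingPointError(f"non-finite prior log-likelihood at sample {i}")
    return float(ll_w.sum() + ll_h.sum())


def _gene_negloglik_and_grad(theta, w_g, pi):
    """Negative per-gene log likelihood and gradient in (mu_S, mu_T, log sig_S, log sig_T)."""
    mu_s, mu_t, ls, lt = theta
    sig_s, sig_t = np.exp(ls), np.exp(lt)
    q = 1.0 - pi
    mean = pi * mu_s + q * mu_t
    var = pi**2 * sig_s**2 + q**2 * sig_t**2
    r = w_g - mean
    nll = 0.5 * np.sum(np.log(2 * np.pi * var) + r**2 / var)
    dL_dmean = r / var                      # of +loglik
    dL_dvar = -0.5 / var + r**2 / (2 * var**2)
    g_mu_s = np.sum(dL_dmean * pi)
    g_mu_t = np.sum(dL_dmean * q)
    g_ls = np.sum(dL_dvar * 2 * pi**2 * sig_s**2)   # d var/d log sig_s = 2 pi^2 sig_s^2
    g_lt = np.sum(dL_dvar * 2 * q**2 * sig_t**2)
    return nll, -np.array([g_mu_s, g_mu_t, g_ls, g_lt])


def _update_genes(W, pi, params) -> SignatureMixtureParams:
    mu_S, mu_T = params.mu_S.copy(), params.mu_T.copy()
    sig_S, sig_T = params.sigma_S.copy(), params.sigma_T.copy()
    bounds = [(None, None), (None, None), (-7.0, 7.0), (-7.0, 7.0)]
    for g in range(W.shape[1]):
        x0 = np.array([mu_S[g], mu_T[g], np.log(sig_S[g]), np.log(sig_T[g])])
        f0, _ = _gene_negloglik_and_grad(x0, W[:, g], pi)
        res = optimize.minimize(
            _gene_negloglik_and_grad, x0, args=(W[:, g], pi),
            jac=True, method="L-BFGS-B", bounds=bounds,
        )
        if np.isfinite(res.fun) and res.fun <= f0:  # never accept a worse point
            mu_S[g], mu_T[g] = res.x[0], res.x[1]
            sig_S[g], sig_T[g] = np.exp(res.x[2]), np.exp(res.x[3])
    return SignatureMixtureParams(mu_S, mu_T, sig_S, sig_T)


def _score_pi_one(w_i, h_i, params, delta) -> float:
    """Maximize the single-sample log likelihood over pi in [PI_LO, PI_HI]."""

    def neg(p):
        mean = p * params.mu_S + (1 - p) * params.mu_T
        var = p**2 * params.sigma_S**2 + (1 - p) ** 2 * params.sigma_T**2
        ll = -0.5 * np.sum(np.log(2 * np.pi * var) + (w_i - mean) ** 2 / var)
        ll += (
            special.gammaln(delta)
            - special.gammaln(p * delta)
            - special.gammaln((1 - p) * delta)
            + (p * delta - 1) * np.log(h_i)
            + ((1 - p) * delta - 1) * np.log1p(-h_i)
        )
        return -ll

    res = optimize.minimize_scalar(neg, bounds=(PI_LO, PI_HI), method="bounded",
                                   options={"xatol": 1e-7})
    return float(res.x), float(-res.fun), neg


def _update_pi(W, h, pi, params, delta) -> np.ndarray:
    out = pi.copy()
    for i in range(W.shape[0]):
        x, fmax, neg = _score_pi_one(W[i], h[i], params, delta)
        if fmax >= -neg(pi[i]):
            out[i] = x
    return out


def _update_delta(h, pi, delta) -> float:
    def neg(logd):
        d = np.exp(logd)
        return -float(np.sum(_beta_loglik(h, pi, d)))

    res = optimize.minimize_scalar(
        neg, bounds=(np.log(DELTA_LO), np.log(DELTA_HI)), method="bounded",
        options={"xatol": 1e-8},
    )
    if -res.fun >= float(np.sum(_beta_loglik(h, pi, delta))):
        return float(np.exp(res.x))
    return delta


def _init_params(W, pi) -> SignatureMixtureParams:
    # least-squares on [pi, 1-pi] per gene for means; pooled residual SD
    A = np.column_stack([pi, 1 - pi])
    coef, *_ = np.linalg.lstsq(A, W, rcond=None)
    resid = W - A @ coef
    sd = np.maximum(resid.std(axis=0), 1e-2)
    return SignatureMixtureParams(coef[0], coef[1], sd.copy(), sd.copy())


def fit_signature_mixture(
    W: SignatureExpressionMatrix,
    prior: PriorScoreVector,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> tuple[np.ndarray, SignatureMixtureParams, float, dict]:
    """Block coordinate ascent on the joint signature/prior log likelihood.

    Alternates per-gene Gaussian parameter updates, per-sample bounded 1-D
    maximization of pi, and a 1-D update of the prior concentration delta,
    starting from pi = h (which anchors component labels to the prior) and
    delta = 10.  Each block update is accepted only if it does not decrease
    the objective, so the trace is non-decreasing by construction; a
    decrease beyond numerical slack raises.  Returns the proportion vector,
    gene parameters, delta, and an info dict with the objective trace and a
    convergence flag.
    """
    h = np.clip(prior.h, PI_LO, PI_HI)
    pi = h.copy()
    delta = DELTA_INIT
    params = _init_params(W.W, pi)
    pv = PriorScoreVector(prior.sample_ids, prior.h, delta)
    obj = signature_log_likelihood(W, pi, params, pv)
    trace = [obj]
    converged = False
    for _ in range(max_iter):
        params = _update_genes(W.W, pi, params)
        pi = _update_pi(W.W, np.clip(prior.h, 1e-12, 1 - 1e-12), pi, params, delta)
        delta = _update_delta(np.clip(prior.h, 1e-12, 1 - 1e-12), pi, delta)
        pv.delta = delta
        new_obj = signature_log_likelihood(W, pi, params, pv)
        if new_obj < obj - _ASCENT_SLACK * (1.0 + abs(obj)):
            raise RuntimeError("coordinate ascent objective decreased")
        trace.append(new_obj)
        if abs(new_obj - obj) <= tol * (1.0 + abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if not converged:
        warnings.warn("proportion estimation did not converge; best iterate returned")
    return pi, params, delta, {"trace": np.asarray(trace), "converged": converged}


def _trimmed_stats(col: np.ndarray, trim: float) -> tuple[float, float]:
    x = np.sort(col)
    k = int(np.floor(trim * x.size))
    kept = x[k: x.size - k] if k > 0 else x
    return float(kept.mean()), float(kept.std())


def aggregate_bootstrap(estimates: np.ndarray, trim: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample tail-trimmed mean and SD across bootstrap estimates.

    ``estimates`` is (n_boot, n_samples); ``trim`` is the per-tail fraction
    of bootstrap estimates dropped before averaging.
    """
    if not 0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    out = np.array([_trimmed_stats(estimates[:, j], trim)
                    for j in range(estimates.shape[1])])
    return out[:, 0], out[:, 1]


def estimate_pi_bagged(
    W: SignatureExpressionMatrix,
    prior: PriorScoreVector,
    n_boot: int = 100,
    frac: float = 0.8,
    trim: float = 0.05,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> CellProportionEstimate:
    """Bagged proportion estimation.

    Each bootstrap refits the mixture on ``ceil(frac * N)`` samples drawn
    with replacement, then scores all N samples by per-sample 1-D
    maximization under that bootstrap's gene parameters and delta.  The
    final estimate is the per-sample mean after dropping the ``trim``
    fraction of bootstrap estimates in each tail.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    N = W.W.shape[0]
    m = int(np.ceil(frac * N))
    ests, deltas = [], []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.choice(N, size=m, replace=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Wb = SignatureExpressionMatrix(W.W[idx], W.gene_ids, W.sample_ids[idx])
                pb = PriorScoreVector(prior.sample_ids[idx], prior.h[idx])
                _, params, delta, _ = fit_signature_mixture(
                    Wb, pb, max_iter=max_iter, tol=tol)
        except Exception as exc:  # noqa: BLE001 - logged and skipped by contract
            n_failed += 1
            warnings.warn(f"bootstrap fit failed and was skipped: {exc}")
            continue
        h_all = np.clip(prior.h, 1e-12, 1 - 1e-12)
        pi_all = np.array([_score_pi_one(W.W[i], h_all[i], params, delta)[0]
                           for i in range(N)])
        ests.append(pi_all)
        deltas.append(delta)
    if n_failed > 0.5 * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap fits failed")
    ests = np.asarray(ests)
    pi_hat, spread = aggregate_bootstrap(ests, trim)
    return CellProportionEstimate(
        sample_ids=W.sample_ids, pi_hat=pi_hat, n_boot=len(ests),
        trim_frac=trim, per_sample_boot_spread=spread,
        delta_hat=float(np.mean(deltas)), boot_estimates=ests,
    )
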