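"""Model-implied moments and full-information ML likelihood.

The casewise (FIML) log-likelihood retains subjects with incomplete data:
each case contributes the Gaussian log-density of its observed subvector
under the corresponding submatrix of the model-implied moments,

    l_i = -1/2 [ k_i log 2*pi + log|Sigma_i| + (y_i - mu_i)' Sigma_i^{-1} (y_i - mu_i) ].

Cases are grouped by missingness pattern for efficiency; the grouped result
is identical to the casewise sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

LOG2PI = float(np.log(2.0 * np.pi))

__all__ = [
    "MissingPatterns", "implied_moments", "fiml_loglik", "fiml_loglik_grad",
    "saturated_fiml", "independence_loglik",
]


@dataclass
class _Pattern:
    obs: np.ndarray      # indices of observed columns
    n: int
    ybar: np.ndarray     # pattern mean of observed columns
    scatter: np.ndarray  # centered cross-product about ybar


class MissingPatterns:
    """Missingness-pattern summary of a data matrix with NaN for missing."""

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, float)
        if y.ndim != 2:
            raise ValueError("expected a 2-D data matrix")
        mask = np.isnan(y)
        if mask.all(axis=1).any():
            raise ValueError("cases with no observed values are not allowed")
        pats, inverse = np.unique(mask, axis=0, return_inverse=True)
        self.n, self.p = y.shape
        self.patterns: list[_Pattern] = []
        for k in range(pats.shape[0]):
            rows = np.where(inverse == k)[0]
            obs = np.where(~pats[k])[0]
            sub = y[np.ix_(rows, obs)]
            ybar = sub.mean(axis=0)
            dev = sub - ybar
            self.patterns.append(_Pattern(obs, len(rows), ybar, dev.T @ dev))
        self.rows_by_pattern = [np.where(inverse == k)[0]
                                for k in range(pats.shape[0])]
        self._y = y


def implied_moments(mats: dict):
    """(mu, Sigma) plus intermediates reused by gradient and factor scores."""
    lam, beta, psi = mats["lam"], mats["beta"], mats["psi"]
    theta, nu, alpha = mats["theta"], mats["nu"], mats["alpha"]
    m = beta.shape[0]
    imb = np.eye(m) - beta
    try:
        g = np.linalg.inv(imb)
    except np.linalg.LinAlgError as err:  # pragma: no cover - guarded upstream
        raise np.linalg.LinAlgError("singular (I - B)") from err
    a = g @ alpha                  # latent means
    v = g @ psi @ g.T              # latent covariance
    lam_g = lam @ g
    lam_v = lam @ v                # Cov(y, eta) up to Theta-free part
    mu = nu + lam @ a
    sigma = lam_v @ lam.T + theta
    sigma = 0.5 * (sigma + sigma.T)
    cache = {"g": g, "a": a, "v": v, "lam_g": lam_g, "lam_v": lam_v}
    return mu, sigma, cache


def _pattern_terms(mu, sigma, pat: _Pattern):
    o = pat.obs
    sub = sigma[np.ix_(o, o)]
    c, low = cho_factor(sub, lower=True)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    ainv = cho_solve((c, low), np.eye(len(o)))
    d = pat.ybar - mu[o]
    return o, ainv, logdet, d


def fiml_loglik(mu, sigma, patterns: MissingPatterns) -> float:
    ll = 0.0
    for pat in patterns.patterns:
        o, ainv, logdet, d = _pattern_terms(mu, sigma, pat)
        quad = float(np.einsum("ij,ji->", ainv, pat.scatter)) \
            + pat.n * float(d @ ainv @ d)
        ll += -0.5 * (pat.n * len(o) * LOG2PI + pat.n * logdet + quad)
    return ll


def fiml_loglik_grad(mats: dict, patterns: MissingPatterns):
    """Log-likelihood and its gradient with respect to the six matrices.

    Returns ``(ll, grads)`` where ``grads`` maps matrix name to an array of
    the same shape.  Raises ``np.linalg.LinAlgError`` when a pattern
    submatrix is not positive definite.
    """
    mu, sigma, cache = implied_moments(mats)
    p = len(mu)
    gmu = np.zeros(p)
    gsig = np.zeros((p, p))
    ll = 0.0
    for pat in patterns.patterns:
        o, ainv, logdet, d = _pattern_terms(mu, sigma, pat)
        w = pat.scatter + pat.n * np.outer(d, d)
        quad = float(np.einsum("ij,ji->", ainv, w))
        ll += -0.5 * (pat.n * len(o) * LOG2PI + pat.n * logdet + quad)
        gmu[o] += pat.n * (ainv @ d)
        gsig[np.ix_(o, o)] += -0.5 * (pat.n * ainv - ainv @ w @ ainv)

    lam, g, a = mats["lam"], cache["g"], cache["a"]
    v, lam_g, lam_v = cache["v"], cache["lam_g"], cache["lam_v"]
    u = lam_g.T @ gmu
    grads = {
        "nu": gmu,
        "alpha": u,
        "lam": np.outer(gmu, a) + 2.0 * gsig @ lam_v,
        "theta": gsig,
        "psi": lam_g.T @ gsig @ lam_g,
        "beta": np.outer(u, a) + 2.0 * (lam_g.T @ gsig @ lam_v),
    }
    return ll, grads


def fisher_diag(mats: dict, n: int) -> dict:
    """Complete-data Fisher-information diagonal per matrix entry.

    Used to precondition the quasi-Newton search: free parameters of a
    structural model live on wildly different scales (variances in squared
    questionnaire units next to loadings of a binary indicator), and an
    unscaled L-BFGS start matrix makes convergence slow.  Closed forms per
    entry follow from I = n/2 tr(P dSigma P dSigma) + n dmu' P dmu with
    P = Sigma^{-1}.
    """
    mu, sigma, cache = implied_moments(mats)
    lam = mats["lam"]
    g, a, v = cache["g"], cache["a"], cache["v"]
    l = cache["lam_g"]
    c = cache["lam_v"]          # Lambda V = Cov(y, eta)
    p = np.linalg.inv(sigma)
    pl = p @ l                  # p x m
    pc = p @ c                  # p x m
    m_mat = l.T @ pl            # m x m
    q = c.T @ pc                # m x m
    nmat = l.T @ pc             # m x m
    pd = np.diag(p)
    md = np.diag(m_mat)
    qd = np.diag(q)
    out = {}
    out["nu"] = n * pd
    out["alpha"] = n * md
    out["psi"] = n * (m_mat ** 2 + np.outer(md, md))
    np.fill_diagonal(out["psi"], 0.5 * n * md ** 2)
    out["theta"] = n * (p ** 2 + np.outer(pd, pd))
    np.fill_diagonal(out["theta"], 0.5 * n * pd ** 2)
    out["lam"] = n * ((pc) ** 2 + np.outer(pd, qd)) \
        + n * np.outer(pd, a ** 2)
    out["beta"] = n * (nmat ** 2 + np.outer(md, qd)) \
        + n * np.outer(md, a ** 2)
    return out


def saturated_fiml(y: np.ndarray, tol: float = 1e-10, max_iter: int = 1000):
    """ML estimates of an unstructured (mu, Sigma) under MAR missingness.

    EM for the multivariate normal with missing values; reduces to the sample
    mean and ML (denominator n) covariance for complete data.  Returns
    ``(mu, sigma, loglik, n_iter)``.
    """
    y = np.asarray(y, float)
    n, p = y.shape
    patterns = MissingPatterns(y)
    # start: available-case means / variances, zero covariances
    mu = np.nanmean(y, axis=0)
    var = np.nanvar(y, axis=0)
    var[~np.isfinite(var) | (var <= 0)] = 1.0
    sigma = np.diag(var)
    if not np.isnan(y).any():
        dev = y - mu
        sigma = dev.T @ dev / n
        sigma = 0.5 * (sigma + sigma.T)
        evals, evecs = np.linalg.eigh(sigma)
        floor = 1e-8 * max(float(evals.max()), 1e-12)
        if evals.min() < floor:
            sigma = (evecs * np.clip(evals, floor, None)) @ evecs.T
        return mu, sigma, fiml_loglik(mu, sigma, patterns), 0

    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        t1 = np.zeros(p)
        t2 = np.zeros((p, p))
        ll = 0.0
        for pat, rows in zip(patterns.patterns, patterns.rows_by_pattern):
            o = pat.obs
            mis = np.setdiff1d(np.arange(p), o)
            sub = sigma[np.ix_(o, o)]
            c, low = cho_factor(sub, lower=True)
            ainv = cho_solve((c, low), np.eye(len(o)))
            yo = patterns._y[np.ix_(rows, o)]
            dev = yo - mu[o]
            ll += -0.5 * (pat.n * len(o) * LOG2PI
                          + pat.n * 2.0 * np.log(np.diag(c)).sum()
                          + float(np.einsum("ij,ij->", dev @ ainv, dev)))
            filled = np.empty((pat.n, p))
            filled[:, o] = yo
            t2_pat = np.zeros((p, p))
            if len(mis):
                b = sigma[np.ix_(mis, o)] @ ainv
                cond_mu = mu[mis] + dev @ b.T
                cond_cov = sigma[np.ix_(mis, mis)] - b @ sigma[np.ix_(o, mis)]
                filled[:, mis] = cond_mu
                t2_pat[np.ix_(mis, mis)] += pat.n * cond_cov
            t1 += filled.sum(axis=0)
            t2 += filled.T @ filled + t2_pat
        mu = t1 / n
        sigma = t2 / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        # keep the update usable when n < p (rank-deficient sample moments)
        evals, evecs = np.linalg.eigh(sigma)
        floor = 1e-8 * max(float(evals.max()), 1e-12)
        if evals.min() < floor:
            sigma = (evecs * np.clip(evals, floor, None)) @ evecs.T
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    ll = fiml_loglik(mu, sigma, patterns)
    return mu, sigma, ll, it


def independence_loglik(y: np.ndarray) -> tuple[float, int]:
    """Log-likelihood and free-parameter count of the independence model.

    Per-variable univariate normal ML (mean and variance over the observed
    cases of that variable); the closed-form baseline used by the CFI.
    """
    y = np.asarray(y, float)
    ll = 0.0
    for j in range(y.shape[1]):
        col = y[:, j]
        col = col[~np.isnan(col)]
        m, v = col.mean(), col.var()
        ll += -0.5 * len(col) * (LOG2PI + np.log(v)) - 0.5 * ((col - m) ** 2).sum() / v
    return ll, 2 * y.shape[1]
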