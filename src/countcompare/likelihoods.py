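"""Log-likelihoods for the four count-regression families.

The count part always uses a log link, mu_i = exp(x_i' beta).  The
negative binomial is the NB2 parameterization with conditional variance
mu (1 + alpha mu); alpha -> 0 recovers the Poisson.  The zero-inflated
families mix a degenerate point mass at zero (probability phi_i, the
"structural" zeros) with a Poisson or NB count component; phi_i comes
from a binary link applied to the zero-part linear predictor z_i' gamma.

All functions are vectorized over observations and use log-gamma /
log-sum-exp arithmetic throughout, so they remain finite for large
counts and extreme mixture weights.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, expit, gammaln

FAMILIES = ("poisson", "nb", "zip", "zinb")

__all__ = [
    "FAMILIES",
    "poisson_logpmf",
    "nb_logpmf",
    "zip_logpmf",
    "zinb_logpmf",
    "log_pmf",
    "conditional_mean_variance",
    "loglik_poisson",
    "loglik_nb",
    "loglik_zip",
    "loglik_zinb",
]


def _validate_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.size and (np.any(y < 0) or np.any(y != np.floor(y))):
        bad = np.where((y < 0) | (y != np.floor(y)))[0]
        raise ValueError(f"y must contain nonnegative integers; offending rows: {bad[:10].tolist()}")
    return np.asarray(y, dtype=float)


# ---------------------------------------------------------------------------
# per-observation log pmfs


def poisson_logpmf(y, mu):
    """log P(Y=y) for Poisson(mu), elementwise."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = y * np.log(mu) - mu - gammaln(y + 1.0)
    # mu == 0: point mass at zero
    out = np.where((mu == 0) & (y == 0), 0.0, out)
    out = np.where((mu == 0) & (y > 0), -np.inf, out)
    return out


def nb_logpmf(y, mu, alpha):
    """log P(Y=y) for NB2(mu, alpha), elementwise.

    Gamma-Poisson mixture with heterogeneity tau ~ gamma(theta, theta),
    theta = 1/alpha; uses log-gamma arithmetic only.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0; for the alpha -> 0 limit use poisson_logpmf")
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = 1.0 / alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1.0)
            + theta * np.log(theta)
            + y * np.log(mu)
            - (y + theta) * np.log(theta + mu)
        )
    out = np.where((mu == 0) & (y == 0), 0.0, out)
    out = np.where((mu == 0) & (y > 0), -np.inf, out)
    return out


def _zero_inflate(log_g, log_g0, y, phi):
    """Mix a count-component log pmf with a point mass at zero."""
    phi = np.asarray(phi, dtype=float)
    if np.any(~np.isfinite(phi)) or np.any(phi < 0) or np.any(phi >= 1):
        bad = np.where(~((phi >= 0) & (phi < 1)))[0]
        raise ValueError(f"phi must lie in [0, 1); offending rows: {bad[:10].tolist()}")
    with np.errstate(divide="ignore"):
        log_phi = np.log(phi)
        log_1mphi = np.log1p(-phi)
    zero_branch = np.logaddexp(log_phi, log_1mphi + log_g0)
    pos_branch = log_1mphi + log_g
    return np.where(np.asarray(y) == 0, zero_branch, pos_branch)


def zip_logpmf(y, mu, phi):
    """log P(Y=y) for the zero-inflated Poisson mixture."""
    mu = np.asarray(mu, dtype=float)
    return _zero_inflate(poisson_logpmf(y, mu), -mu, y, phi)


def zinb_logpmf(y, mu, alpha, phi):
    """log P(Y=y) for the zero-inflated NB2 mixture."""
    mu = np.asarray(mu, dtype=float)
    theta = 1.0 / alpha
    log_g0 = theta * (np.log(theta) - np.log(theta + mu))
    return _zero_inflate(nb_logpmf(y, mu, alpha), log_g0, y, phi)


def log_pmf(family: str, y, mu, alpha=None, phi=None):
    """Dispatch to the family log pmf (phi defaults to 0 for zi families)."""
    if family == "poisson":
        return poisson_logpmf(y, mu)
    if family == "nb":
        return nb_logpmf(y, mu, alpha)
    if family == "zip":
        return zip_logpmf(y, mu, 0.0 if phi is None else phi)
    if family == "zinb":
        return zinb_logpmf(y, mu, alpha, 0.0 if phi is None else phi)
    raise ValueError(f"unknown family {family!r}")


def conditional_mean_variance(family: str, mu, alpha=None, phi=None):
    """(E, V) of Y given covariates under the stated family.

    poisson: E = V = mu
    nb:      E = mu,            V = mu (1 + alpha mu)
    zip:     E = mu (1 - phi),  V = E (1 + phi mu)
    zinb:    E = mu (1 - phi),  V = E (1 + (alpha + phi) mu)
    """
    mu = np.asarray(mu, dtype=float)
    if family == "poisson":
        return mu, mu
    if family == "nb":
        return mu, mu * (1.0 + alpha * mu)
    phi = np.asarray(0.0 if phi is None else phi, dtype=float)
    e = mu * (1.0 - phi)
    if family == "zip":
        return e, e * (1.0 + phi * mu)
    if family == "zinb":
        return e, e * (1.0 + (alpha + phi) * mu)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# regression log-likelihoods


def _linpred(X, beta, what="beta"):
    eta = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    if np.any(eta >= 700.0):
        bad = np.where(eta >= 700.0)[0]
        raise OverflowError(
            f"linear predictor for {what} reaches exp overflow (>= 700); offending rows: {bad[:10].tolist()}"
        )
    return eta


def loglik_poisson(beta, y, X):
    """Poisson log-likelihood and its score X'(y - mu)."""
    y = _validate_counts(y)
    eta = _linpred(X, beta)
    mu = np.exp(eta)
    ll = float(np.sum(y * eta - mu - gammaln(y + 1.0)))
    score = np.asarray(X).T @ (y - mu)
    return ll, score


def loglik_nb(beta, alpha, y, X):
    """NB2 log-likelihood and its score with respect to (beta, alpha)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0; use loglik_poisson for the alpha -> 0 limit")
    y = _validate_counts(y)
    eta = _linpred(X, beta)
    mu = np.exp(eta)
    theta = 1.0 / alpha
    ll = float(np.sum(nb_logpmf(y, mu, alpha)))
    score_beta = np.asarray(X).T @ ((y - mu) / (1.0 + alpha * mu))
    dl_dtheta = np.sum(
        digamma(y + theta) - digamma(theta) + np.log(theta) + 1.0
        - np.log(theta + mu) - (y + theta) / (theta + mu)
    )
    score_alpha = -(theta**2) * dl_dtheta  # d theta / d alpha = -theta^2
    return ll, np.concatenate([score_beta, [score_alpha]])


def _phi_from_link(Z, gamma, link="logit"):
    eta_z = _linpred(Z, gamma, what="gamma")
    if link == "logit":
        return expit(eta_z)
    if link == "probit":
        from scipy.stats import norm

        return norm.cdf(eta_z)
    if link == "cloglog":
        return -np.expm1(-np.exp(np.clip(eta_z, None, 30.0)))
    raise ValueError(f"unknown zero link {link!r}")


def loglik_zip(beta, gamma, y, X, Z, link="logit"):
    """Zero-inflated Poisson log-likelihood (zero part via `link`)."""
    y = _validate_counts(y)
    mu = np.exp(_linpred(X, beta))
    phi = _phi_from_link(Z, gamma, link)
    ll = zip_logpmf(y, mu, phi)
    if np.any(~np.isfinite(ll)):
        bad = np.where(~np.isfinite(ll))[0]
        raise FloatingPointError(f"non-finite ZIP likelihood contribution at rows {bad[:10].tolist()}")
    return float(np.sum(ll))


def loglik_zinb(beta, gamma, alpha, y, X, Z, link="logit"):
    """Zero-inflated NB2 log-likelihood (zero part via `link`)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0; use loglik_zip for the alpha -> 0 limit")
    y = _validate_counts(y)
    mu = np.exp(_linpred(X, beta))
    phi = _phi_from_link(Z, gamma, link)
    ll = zinb_logpmf(y, mu, alpha, phi)
    if np.any(~np.isfinite(ll)):
        bad = np.where(~np.isfinite(ll))[0]
        raise FloatingPointError(f"non-finite ZINB likelihood contribution at rows {bad[:10].tolist()}")
    return float(np.sum(ll))
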