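"""Empirical-Bayes variance shrinkage (scaled inverse-chi-square prior).

Gene-wise sample variances s_g^2 on df degrees of freedom are shrunk toward
a common prior variance s0^2 with prior degrees of freedom d0:

    s_tilde_g^2 = (d0 * s0^2 + df * s_g^2) / (d0 + df)

(d0, s0^2) are estimated by moment matching on log variances: under the
model, log s_g^2 follows a shifted log-F distribution whose mean and
variance involve digamma/trigamma terms, so d0 comes from inverting the
trigamma function on the excess variance of log s_g^2, Newton iteration.
Genes with zero sample variance are excluded from the fit and assigned the
prior variance by the callers.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, polygamma

from .exceptions import ValidationError

__all__ = ["trigamma_inverse", "fit_variance_prior", "squeeze_variances"]


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        raise ValidationError("trigamma_inverse requires a positive argument")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-10:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) from gene-wise variances on ``df`` df each.

    Returns ``d0 = inf`` (complete shrinkage to a common variance) when the
    observed spread of log variances does not exceed what sampling alone
    explains.  Zero/non-finite variances must be removed by the caller.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        # nothing to fit a spread from: behave as "no moderation"
        return 0.0, float(s2.mean()) if s2.size else 1.0
    if df <= 0:
        raise ValidationError("residual degrees of freedom must be positive")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = z.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(e.mean())
    return float(d0), float(s0_sq)


def squeeze_variances(
    s2: np.ndarray, df: float, prior_df: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Shrink gene-wise variances toward the fitted (or forced) prior.

    Parameters
    ----------
    s2
        Gene-wise sample variances; zeros allowed (they take the prior).
    df
        Residual degrees of freedom of each s2.
    prior_df
        Force d0 instead of fitting it; ``0`` disables moderation and
        reproduces the ordinary t-test.

    Returns
    -------
    (s2_post, d0, s0_sq) with s2_post the moderated variances.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if prior_df is None:
        if not ok.any():
            raise ValidationError("all gene variances are zero; cannot fit a prior")
        d0, s0_sq = fit_variance_prior(s2[ok], df)
    else:
        d0 = float(prior_df)
        if d0 < 0:
            raise ValidationError("prior_df must be >= 0")
        s0_sq = float(np.exp(np.log(s2[ok]).mean())) if ok.any() else 1.0
    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        post = np.where(ok, s2, s0_sq)
    else:
        post = (d0 * s0_sq + df * np.where(ok, s2, 0.0)) / (d0 + df)
        post[~ok] = s0_sq
    return post, d0, s0_sq
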