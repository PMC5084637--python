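"""Multivariable MR: the exposure's direct effect conditional on covariates.

When instruments also affect correlated traits (here LDL cholesterol and
triglycerides), the univariable IVW estimate mixes the exposure's effect with
theirs.  Regressing the outcome betas jointly on the exposure betas and the
covariate betas (no intercept, outcome-precision weights) isolates the
exposure coefficient as its direct causal effect.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .estimators import CausalEstimate, Z95, _two_sided_p
from .exceptions import ConfigurationError, SingularDesignError, ValidationError
from .instruments import InstrumentSet

logger = logging.getLogger(__name__)

#: condition number above which the weighted design is treated as collinear
CONDITION_NUMBER_LIMIT = 1e10


def multivariable_mr(
    s: InstrumentSet,
    covariates: Sequence[str] = (),
    *,
    weighted: bool = True,
) -> tuple[CausalEstimate, dict[str, CausalEstimate]]:
    """Joint weighted linear model of outcome betas on exposure + covariate betas.

    Returns the exposure coefficient as the headline :class:`CausalEstimate`
    (method ``multivariable``) plus one estimate per covariate trait.  With no
    covariates this reduces exactly to fixed-effects IVW.  Weights are
    ``se_outcome**-2`` (covariate measurement error ignored, the first-order
    summarized-data convention); ``weighted=False`` fits ordinary least
    squares instead.  SEs use the weighted normal equations with a
    multiplicative residual-variance floor of 1.
    """
    covariates = list(covariates)
    n = len(s)
    k = 1 + len(covariates)
    if n <= k:
        raise ValidationError(f"need more instruments ({n}) than coefficients ({k})")
    missing_traits = [c for c in covariates if f"beta_cov_{c}" not in s.data.columns]
    if missing_traits:
        raise ConfigurationError(f"no covariate effects for trait(s): {missing_traits}")
    for c in covariates:
        col = s.data[f"beta_cov_{c}"]
        if col.isna().any():
            bad = list(s.data.loc[col.isna(), "rsid"])
            raise ValidationError(f"missing beta for covariate {c!r} at rsids: {bad}")

    # orient to the exposure-increasing allele; all betas flip together so the
    # fit is invariant to effect-allele labelling
    sign = np.where(s.data["beta_exposure"].to_numpy(dtype=float) < 0, -1.0, 1.0)
    X = np.column_stack(
        [s.data["beta_exposure"].to_numpy(dtype=float)]
        + [s.data[f"beta_cov_{c}"].to_numpy(dtype=float) for c in covariates]
    ) * sign[:, None]
    y = s.data["beta_outcome"].to_numpy(dtype=float) * sign
    w = s.data["se_outcome"].to_numpy(dtype=float) ** -2 if weighted else np.ones(n)

    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    # collinearity check on norm-scaled nonzero columns; an all-zero covariate
    # column is harmless (its coefficient is pinned to 0 by the pseudoinverse)
    norms = np.linalg.norm(Xw, axis=0)
    live = norms > 0
    if np.linalg.cond(Xw[:, live] / norms[live]) > CONDITION_NUMBER_LIMIT:
        raise SingularDesignError(
            f"collinear design (condition number > {CONDITION_NUMBER_LIMIT:g})"
        )
    import statsmodels.api as sm

    fit = sm.WLS(y, X, weights=w).fit()
    scale_used = max(1.0, float(fit.scale))
    se = np.sqrt(np.diag(fit.normalized_cov_params) * scale_used)
    params = np.asarray(fit.params)

    def make(method: str, i: int) -> CausalEstimate:
        p = float(_two_sided_p(params[i] / se[i])) if se[i] > 0 else 1.0
        return CausalEstimate(
            method=method, beta=float(params[i]), se=float(se[i]), p_value=p, n_snps=n
        )

    headline = make("multivariable", 0)
    per_covariate = {c: make(f"multivariable[{c}]", i + 1) for i, c in enumerate(covariates)}
    return headline, per_covariate
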