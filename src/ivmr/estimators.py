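"""Causal-effect estimators for summarized-data Mendelian randomization.

All estimators consume a harmonized :class:`~ivmr.instruments.InstrumentSet`
of independent SNPs.  The per-SNP building block is the Wald ratio
``beta_outcome / beta_exposure``; estimators differ in how the ratios are
pooled and which instrument-validity assumptions they relax:

* ``ivw`` — inverse-variance-weighted pooling (equivalently a zero-intercept
  weighted regression of outcome betas on exposure betas).  Consistent only
  if every instrument is valid.  Fixed-effects, multiplicative random-effects
  (SE inflated by sqrt(Q/df), point estimate unchanged) and additive
  DerSimonian–Laird random-effects flavours.
* ``mr_egger`` — the same regression with a free intercept.  The intercept
  estimates average directional pleiotropy; the slope remains a consistent
  causal estimate under the InSIDE assumption (direct effects independent of
  instrument strength).
* ``weighted_median`` — the weight-0.5 quantile of the ordered Wald ratios;
  consistent while valid instruments carry a majority of the weight.
* ``correct_for_overlap`` — first-order adjustment for participant overlap
  between the exposure and outcome samples, which pulls a two-sample estimate
  toward the observational association in proportion to overlap and inverse
  instrument strength.

Heterogeneity of the Wald ratios is quantified by Cochran's Q; excess Q
signals invalid (pleiotropic) instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import SingularDesignError, ValidationError
from .instruments import InstrumentSet

logger = logging.getLogger(__name__)

Z95 = 1.96  # normal 95% CI multiplier


@dataclass(frozen=True)
class CausalEstimate:
    """One MR result: method label, estimate, uncertainty, heterogeneity."""

    method: str
    beta: float
    se: float
    p_value: float
    n_snps: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    q_statistic: float | None = None
    p_heterogeneity: float | None = None
    i_squared: float | None = None

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            object.__setattr__(self, "ci_low", self.beta - Z95 * self.se)
        if np.isnan(self.ci_high):
            object.__setattr__(self, "ci_high", self.beta + Z95 * self.se)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = (
            f"{self.method}: beta={self.beta:.4f} "
            f"(95% CI {self.ci_low:.4f} to {self.ci_high:.4f}), "
            f"p={self.p_value:.4g}, n_snps={self.n_snps}"
        )
        if self.q_statistic is not None:
            s += f", Q={self.q_statistic:.2f} (p_het={self.p_heterogeneity:.3g})"
        return s


@dataclass(frozen=True)
class WaldRatio:
    """Per-SNP causal estimate: outcome effect divided by exposure effect."""

    rsid: str
    ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        return self.se_ratio**-2


def _two_sided_p(z: np.ndarray | float) -> np.ndarray | float:
    return 2.0 * stats.norm.sf(np.abs(z))


def _oriented_betas(s: InstrumentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """beta_exposure, beta_outcome, se_outcome with all exposure betas >= 0.

    Orienting every SNP to its exposure-increasing allele removes the
    arbitrariness of effect-allele labelling; IVW is invariant to it, MR-Egger
    requires it.
    """
    bx = s.data["beta_exposure"].to_numpy(dtype=float)
    by = s.data["beta_outcome"].to_numpy(dtype=float)
    sy = s.data["se_outcome"].to_numpy(dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign, sy


def wald_ratios(s: InstrumentSet, se_order: str = "first") -> list[WaldRatio]:
    """Per-SNP Wald ratios with delta-method standard errors.

    First-order SEs (``se_outcome / |beta_exposure|``) treat the exposure beta
    as known — the standard choice for genome-wide-significant instruments.
    Second-order SEs add the exposure-error term and are never smaller.
    SNPs with ``beta_exposure == 0`` are excluded with a warning.
    """
    if se_order not in ("first", "second"):
        raise ValidationError(f"se_order must be 'first' or 'second', got {se_order!r}")
    out = []
    for _, row in s.data.iterrows():
        bx = float(row["beta_exposure"])
        if bx == 0:
            logger.warning("wald_ratios: beta_exposure=0 for %s; excluded", row["rsid"])
            continue
        by, sy = float(row["beta_outcome"]), float(row["se_outcome"])
        if se_order == "first":
            se = sy / abs(bx)
        else:
            sx = float(row["se_exposure"])
            se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
        out.append(WaldRatio(rsid=row["rsid"], ratio=by / bx, se_ratio=se))
    return out


def cochran_q(
    ratios: Sequence[WaldRatio], center: float
) -> tuple[float, int, float, dict[str, float]]:
    """Cochran's Q heterogeneity statistic of Wald ratios about ``center``.

    Returns (Q, df, p_heterogeneity, per-SNP contributions).  ``df = n - 1``
    because the center is in practice estimated from the same ratios.  Large
    per-SNP contributions identify candidate pleiotropic instruments.
    """
    if len(ratios) < 2:
        raise ValidationError("cochran_q needs at least 2 ratios")
    contrib = {r.rsid: r.weight * (r.ratio - center) ** 2 for r in ratios}
    q = float(sum(contrib.values()))
    df = len(ratios) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p, contrib


def _ivw_point(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    """Closed-form IVW point estimate and fixed-effects SE."""
    w = sy**-2
    denom = float(np.sum(bx**2 * w))
    if denom == 0:
        raise SingularDesignError("all exposure betas are zero")
    beta = float(np.sum(bx * by * w)) / denom
    se_fixed = denom**-0.5
    return beta, se_fixed


def ivw(s: InstrumentSet, effects_model: str = "random_multiplicative") -> CausalEstimate:
    """Inverse-variance-weighted causal estimate.

    The point estimate is the zero-intercept weighted regression slope of
    outcome betas on exposure betas with weights ``se_outcome**-2`` —
    algebraically the precision-weighted mean of the Wald ratios.

    ``fixed`` and ``random_multiplicative`` share this point estimate; the
    latter inflates the SE by ``sqrt(max(1, Q / (n - 1)))`` when the ratios
    are overdispersed.  ``random_additive`` is a DerSimonian–Laird
    meta-analysis of the Wald ratios (moment estimator of the between-SNP
    variance tau^2) and may shift the point estimate.
    """
    if effects_model not in ("fixed", "random_multiplicative", "random_additive"):
        raise ValidationError(f"unknown effects_model {effects_model!r}")
    if len(s) == 0:
        raise ValidationError("empty instrument set")
    ratios = wald_ratios(s)
    n = len(ratios)
    if n == 0:
        raise ValidationError("no usable instruments (all beta_exposure zero)")
    if n == 1 and effects_model != "fixed":
        logger.warning("ivw: single instrument; falling back to fixed effects")
        effects_model = "fixed"

    bx, by, sy = _oriented_betas(s.subset([r.rsid for r in ratios]))
    beta, se_fixed = _ivw_point(bx, by, sy)

    q = df = p_het = i2 = None
    if n >= 2:
        q, df, p_het, _ = cochran_q(ratios, beta)
        i2 = max(0.0, (q - df) / q) if q > 0 else 0.0

    method = f"ivw_{effects_model}"
    if effects_model == "fixed":
        se = se_fixed
    elif effects_model == "random_multiplicative":
        se = se_fixed * float(np.sqrt(max(1.0, q / df)))
    else:  # random_additive: DerSimonian-Laird on the Wald ratios
        r = np.array([x.ratio for x in ratios])
        w = np.array([x.weight for x in ratios])
        tau2 = max(0.0, (q - df) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
        w_star = 1.0 / (1.0 / w + tau2)
        beta = float(np.sum(w_star * r) / np.sum(w_star))
        se = float(np.sum(w_star) ** -0.5)

    return CausalEstimate(
        method=method,
        beta=beta,
        se=se,
        p_value=float(_two_sided_p(beta / se)),
        n_snps=n,
        q_statistic=q,
        p_heterogeneity=p_het,
        i_squared=i2,
    )


def mr_egger(s: InstrumentSet) -> tuple[CausalEstimate, CausalEstimate]:
    """MR-Egger regression: returns (slope, intercept) estimates.

    Weighted regression of outcome betas on exposure betas with a free
    intercept (weights ``se_outcome**-2``), after orienting every SNP to its
    exposure-increasing allele.  A nonzero intercept indicates average
    directional pleiotropy; the slope is the pleiotropy-robust causal estimate
    under InSIDE.  SEs use multiplicative random effects: the WLS covariance
    scaled by ``max(1, residual mean square)`` so they never drop below the
    fixed-effects level.
    """
    if len(s) < 3:
        raise ValidationError("mr_egger needs at least 3 instruments")
    bx, by, sy = _oriented_betas(s)
    if np.ptp(bx) == 0:
        raise SingularDesignError("no spread in exposure betas after orientation")
    import statsmodels.api as sm

    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=sy**-2).fit()
    scale_used = max(1.0, float(fit.scale))
    se = np.sqrt(np.diag(fit.normalized_cov_params) * scale_used)
    inter_b, slope_b = float(fit.params[0]), float(fit.params[1])
    inter_se, slope_se = float(se[0]), float(se[1])
    n = len(bx)
    slope = CausalEstimate(
        method="egger_slope",
        beta=slope_b,
        se=slope_se,
        p_value=float(_two_sided_p(slope_b / slope_se)),
        n_snps=n,
    )
    intercept = CausalEstimate(
        method="egger_intercept",
        beta=inter_b,
        se=inter_se,
        p_value=float(_two_sided_p(inter_b / inter_se)),
        n_snps=n,
    )
    return slope, intercept


def weighted_median_point(ratios: Sequence[float], weights: Sequence[float]) -> float:
    """Weight-0.5 quantile of the ratios with linear interpolation.

    Ratios are sorted; with normalized weights ``w'`` the cumulative midpoint
    grid is ``s_i = sum_{j<=i} w'_j - w'_i / 2`` and the estimate interpolates
    between the two ratios bracketing s = 0.5.
    """
    r = np.asarray(ratios, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(r)
    r, w = r[order], w[order]
    wn = w / w.sum()
    s_grid = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s_grid, r))


def weighted_median(
    s: InstrumentSet, n_bootstrap: int = 10_000, seed: int = 20_170_520
) -> CausalEstimate:
    """Weighted median causal estimate with parametric-bootstrap SE.

    The point estimate uses inverse-variance weights on the Wald ratios and no
    randomness; only the SE is bootstrapped (exposure and outcome betas
    resampled from their reported sampling distributions, seeded).
    Consistent as long as valid instruments hold > 50% of the weight.
    """
    if len(s) < 3:
        raise ValidationError("weighted_median needs at least 3 instruments")
    if n_bootstrap < 100:
        raise ValidationError("n_bootstrap must be >= 100 for a stable SE")
    ratios = wald_ratios(s)
    point = weighted_median_point([r.ratio for r in ratios], [r.weight for r in ratios])

    d = s.subset([r.rsid for r in ratios]).data
    bx = d["beta_exposure"].to_numpy(dtype=float)
    sx = d["se_exposure"].to_numpy(dtype=float)
    by = d["beta_outcome"].to_numpy(dtype=float)
    sy = d["se_outcome"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    bx_rep = rng.normal(bx, sx, size=(n_bootstrap, bx.size))
    by_rep = rng.normal(by, sy, size=(n_bootstrap, by.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        r_rep = by_rep / bx_rep
        w_rep = (bx_rep / sy) ** 2
    boots = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        ok = np.isfinite(r_rep[i])
        boots[i] = weighted_median_point(r_rep[i][ok], w_rep[i][ok])
    se = float(np.std(boots, ddof=1))
    return CausalEstimate(
        method="weighted_median",
        beta=point,
        se=se,
        p_value=float(_two_sided_p(point / se)),
        n_snps=len(ratios),
    )


def correct_for_overlap(
    est: CausalEstimate,
    overlap_fraction: float,
    observational_estimate: float,
    mean_f: float,
) -> CausalEstimate:
    """First-order sample-overlap correction of a two-sample MR estimate.

    With fraction ``c`` of outcome-sample participants shared with the
    exposure sample, weak-instrument bias pulls the estimate toward the
    observational exposure–outcome association instead of toward zero; the
    expected bias is approximately ``c * observational_estimate / mean_f``.
    That bias is subtracted; the SE is carried over unchanged.  The correction
    vanishes for disjoint samples (c = 0) or infinitely strong instruments.
    """
    if not (0 <= overlap_fraction <= 1):
        raise ValidationError(f"overlap_fraction={overlap_fraction} outside [0, 1]")
    if mean_f <= 1:
        raise ValidationError(f"mean_f must exceed 1, got {mean_f}")
    bias = overlap_fraction * observational_estimate / mean_f
    beta = est.beta - bias
    return replace(
        est,
        method="ivw_overlap_corrected",
        beta=beta,
        ci_low=beta - Z95 * est.se,
        ci_high=beta + Z95 * est.se,
        p_value=float(_two_sided_p(beta / est.se)),
    )
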