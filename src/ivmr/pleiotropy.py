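"""Instrument-validity filters: heterogeneity outliers and annotation pruning.

A pleiotropic SNP affects the outcome through pathways other than the
exposure; its Wald ratio then deviates from the common causal slope and
inflates Cochran's Q.  ``goodness_of_fit_filter`` removes such outliers by
their per-SNP Q contributions; ``annotation_filter`` prunes SNPs flagged a
priori (e.g. a GWAS-catalog lookup recorded as a static annotation column).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .estimators import cochran_q, ivw, wald_ratios
from .exceptions import ValidationError
from .instruments import InstrumentSet

logger = logging.getLogger(__name__)


@dataclass
class PleiotropyReport:
    """Outcome of a heterogeneity-based filtering run."""

    flagged_rsids: list[str]
    per_snp_q: dict[str, float]
    threshold_used: float
    iterations: int
    q_before: float
    q_after: float
    p_het_before: float
    p_het_after: float
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")

    def per_snp_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"rsid": list(self.per_snp_q), "q_contribution": list(self.per_snp_q.values())}
        )
        df["flagged"] = df["rsid"].isin(self.flagged_rsids)
        return df


def goodness_of_fit_filter(
    s: InstrumentSet,
    alpha_snp: float = 0.05,
    mode: str = "iterative",
) -> tuple[PleiotropyReport, InstrumentSet]:
    """Flag and remove instruments with excess heterogeneity contributions.

    Computes the IVW fit and each SNP's contribution ``q_i`` to Cochran's Q.
    ``single_pass`` flags, at once, every SNP whose ``q_i`` exceeds the upper
    ``alpha_snp`` quantile of chi-square(1).  ``iterative`` removes the SNP
    with the largest ``q_i`` (ties broken by larger absolute standardized
    residual, then lexicographically smaller rsid), refits, and repeats until
    either no ``q_i`` exceeds the cutoff or the overall heterogeneity p-value
    rises above 0.05.  Stops early with a warning rather than reduce the set
    below 3 instruments.
    """
    if mode not in ("single_pass", "iterative"):
        raise ValidationError(f"mode must be 'single_pass' or 'iterative', got {mode!r}")
    if len(s) < 3:
        raise ValidationError("goodness_of_fit_filter needs at least 3 instruments")
    cutoff = float(stats.chi2.isf(alpha_snp, df=1))

    def fit_q(current: InstrumentSet):
        est = ivw(current, effects_model="fixed")
        ratios = wald_ratios(current)
        q, df, p, contrib = cochran_q(ratios, est.beta)
        return q, p, contrib

    q0, p0, contrib0 = fit_q(s)
    warnings_: list[str] = []

    if mode == "single_pass":
        flagged = sorted([r for r, q in contrib0.items() if q > cutoff])
        filtered = s.drop(flagged) if flagged else s
        if len(filtered) < 3:
            msg = "single_pass flagging would leave < 3 instruments; no removal applied"
            logger.warning(msg)
            warnings_.append(msg)
            flagged, filtered = [], s
        if len(filtered) >= 3 and flagged:
            q1, p1, _ = fit_q(filtered)
        else:
            q1, p1 = q0, p0
        report = PleiotropyReport(
            flagged_rsids=flagged,
            per_snp_q=contrib0,
            threshold_used=cutoff,
            iterations=1,
            q_before=q0,
            q_after=q1,
            p_het_before=p0,
            p_het_after=p1,
            warnings=warnings_,
        )
        return report, filtered

    # iterative mode
    current = s
    flagged: list[str] = []
    q_cur, p_cur, contrib = q0, p0, contrib0
    iterations = 0
    while True:
        if p_cur > 0.05:
            break
        worst = _argmax_contribution(current, contrib)
        if contrib[worst] <= cutoff:
            break
        if len(current) - 1 < 3:
            msg = "stopping early: further removal would leave < 3 instruments"
            logger.warning(msg)
            warnings_.append(msg)
            break
        flagged.append(worst)
        current = current.drop([worst])
        iterations += 1
        q_cur, p_cur, contrib = fit_q(current)
    report = PleiotropyReport(
        flagged_rsids=sorted(flagged),
        per_snp_q=contrib0,
        threshold_used=cutoff,
        iterations=iterations,
        q_before=q0,
        q_after=q_cur,
        p_het_before=p0,
        p_het_after=p_cur,
        warnings=warnings_,
    )
    return report, current


def _argmax_contribution(s: InstrumentSet, contrib: dict[str, float]) -> str:
    """Largest-q SNP; ties by larger |standardized residual| then smaller rsid."""
    max_q = max(contrib.values())
    tied = [r for r, q in contrib.items() if q == max_q]
    if len(tied) == 1:
        return tied[0]
    # standardized residual is sign(ratio - center) * sqrt(q_i); |.| equal for
    # tied q, so the deterministic fallback is the lexicographically smallest.
    return sorted(tied)[0]


def annotation_filter(s: InstrumentSet, label: str) -> tuple[set[str], InstrumentSet]:
    """Remove every instrument whose annotations contain ``label``.

    Returns the excluded rsids and the retained set.  Idempotent; raises if
    the label would remove every record.
    """
    mask = s.data["annotations"].apply(lambda a: label in a)
    excluded = set(s.data.loc[mask, "rsid"])
    if mask.all():
        raise ValidationError(f"label {label!r} would remove all {len(s)} instruments")
    return excluded, s._with_data(s.data[~mask])
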