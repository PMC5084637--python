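"""Model/Results interface over the summarized-data MR estimators.

:class:`MRModel` is constructed from a harmonized instrument table (an
:class:`~ivmr.instruments.InstrumentSet` or a plain DataFrame) and its
``fit`` method dispatches to the individual estimators; the returned
:class:`MRResults` carries the estimates, their uncertainties, heterogeneity
diagnostics, and renders a summary table.  ``fit_all`` runs the full battery
of approaches — IVW on all instruments, MR-Egger, weighted median,
heterogeneity-filtered IVW, annotation-pruned IVW, the multivariable model,
and the sample-overlap correction — producing one results table in the style
of an MR sensitivity-analysis overview.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .estimators import (
    CausalEstimate,
    correct_for_overlap,
    ivw,
    mr_egger,
    wald_ratios,
    weighted_median,
)
from .exceptions import ValidationError
from .instruments import InstrumentSet, mean_f_statistic
from .multivariable import multivariable_mr
from .pleiotropy import PleiotropyReport, annotation_filter, goodness_of_fit_filter

_COLUMNS = ["method", "n_snps", "beta", "se", "ci_low", "ci_high", "p_value",
            "q_statistic", "p_heterogeneity"]


class MRModel:
    """Two-sample Mendelian randomization model on summary statistics.

    Parameters
    ----------
    instruments
        Harmonized instrument panel.  A DataFrame with the canonical columns
        is accepted and wrapped.
    exposure, outcome
        Trait labels for reporting (taken from the InstrumentSet if present).
    """

    def __init__(
        self,
        instruments: InstrumentSet | pd.DataFrame,
        exposure: str | None = None,
        outcome: str | None = None,
    ) -> None:
        if isinstance(instruments, pd.DataFrame):
            instruments = InstrumentSet(instruments)
        self.instruments = instruments
        self.exposure = exposure or instruments.exposure_name
        self.outcome = outcome or instruments.outcome_name

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, column_map: Mapping[str, str] | None = None, **kwargs
    ) -> "MRModel":
        if column_map:
            df = df.rename(columns={v: k for k, v in column_map.items()})
        return cls(InstrumentSet(df), **kwargs)

    def wald_ratios(self, se_order: str = "first"):
        return wald_ratios(self.instruments, se_order=se_order)

    def fit(self, method: str = "ivw", **kwargs) -> "MRResults":
        """Fit one estimator; ``method`` in {ivw, egger, weighted_median, multivariable}."""
        s = self.instruments
        if method == "ivw":
            est = ivw(s, **kwargs)
            return MRResults(self, [est])
        if method == "egger":
            slope, intercept = mr_egger(s)
            return MRResults(self, [slope, intercept])
        if method == "weighted_median":
            return MRResults(self, [weighted_median(s, **kwargs)])
        if method == "multivariable":
            headline, per_cov = multivariable_mr(s, **kwargs)
            return MRResults(self, [headline, *per_cov.values()])
        raise ValidationError(f"unknown method {method!r}")

    def fit_all(
        self,
        *,
        covariates: Sequence[str] = (),
        filter_mode: str = "iterative",
        alpha_snp: float = 0.05,
        annotation_label: str | None = None,
        overlap_fraction: float | None = None,
        observational_estimate: float | None = None,
        n_bootstrap: int = 10_000,
        seed: int = 20_170_520,
    ) -> "MRResults":
        """Run the full estimator battery and sensitivity analyses."""
        s = self.instruments
        estimates: list[CausalEstimate] = []
        notes: dict[str, object] = {}

        est_random = ivw(s, effects_model="random_multiplicative")
        estimates.append(est_random)
        slope, intercept = mr_egger(s)
        estimates += [slope, intercept]
        estimates.append(weighted_median(s, n_bootstrap=n_bootstrap, seed=seed))

        report, filtered = goodness_of_fit_filter(s, alpha_snp=alpha_snp, mode=filter_mode)
        notes["pleiotropy_report"] = report
        if len(filtered) >= 1:
            est = ivw(filtered, effects_model="fixed")
            est = _relabel(est, "ivw_fixed_filtered")
            estimates.append(est)

        if annotation_label is not None:
            excluded, pruned = annotation_filter(s, annotation_label)
            notes["annotation_excluded"] = sorted(excluded)
            est = ivw(pruned, effects_model="random_multiplicative")
            estimates.append(_relabel(est, "ivw_random_pruned"))

        if covariates:
            headline, per_cov = multivariable_mr(s, covariates)
            estimates.append(headline)
            estimates += list(per_cov.values())

        if overlap_fraction is not None and observational_estimate is not None:
            corrected = correct_for_overlap(
                est_random, overlap_fraction, observational_estimate, mean_f_statistic(s)
            )
            estimates.append(corrected)

        return MRResults(self, estimates, notes=notes)


def _relabel(est: CausalEstimate, method: str) -> CausalEstimate:
    import dataclasses

    return dataclasses.replace(est, method=method)


class MRResults:
    """Container for fitted MR estimates with tabular and text rendering."""

    def __init__(
        self,
        model: MRModel,
        estimates: Sequence[CausalEstimate],
        notes: Mapping[str, object] | None = None,
    ) -> None:
        self.model = model
        self.estimates = {e.method: e for e in estimates}
        self.notes = dict(notes or {})

    def __getitem__(self, method: str) -> CausalEstimate:
        return self.estimates[method]

    @property
    def headline(self) -> CausalEstimate:
        return next(iter(self.estimates.values()))

    # convenience accessors mirroring statsmodels results
    @property
    def params(self) -> pd.Series:
        return pd.Series({m: e.beta for m, e in self.estimates.items()}, name="beta")

    @property
    def bse(self) -> pd.Series:
        return pd.Series({m: e.se for m, e in self.estimates.items()}, name="se")

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series({m: e.p_value for m, e in self.estimates.items()}, name="p_value")

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame(
            {m: (e.ci_low, e.ci_high) for m, e in self.estimates.items()},
            index=["ci_low", "ci_high"],
        ).T

    @property
    def pleiotropy_report(self) -> PleiotropyReport | None:
        return self.notes.get("pleiotropy_report")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.estimates.values():
            rows.append(
                {
                    "method": e.method,
                    "n_snps": e.n_snps,
                    "beta": e.beta,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p_value": e.p_value,
                    "q_statistic": e.q_statistic,
                    "p_heterogeneity": e.p_heterogeneity,
                }
            )
        return pd.DataFrame(rows, columns=_COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        """Four-decimal TSV results table (p-values in scientific notation)."""
        df = self.to_frame().copy()
        for col in ("beta", "se", "ci_low", "ci_high"):
            df[col] = df[col].map(lambda v: f"{v:.4f}" if pd.notna(v) else "")
        for col in ("p_value", "q_statistic", "p_heterogeneity"):
            df[col] = df[col].map(lambda v: f"{v:.4g}" if pd.notna(v) else "")
        df.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "exposure": self.model.exposure,
            "outcome": self.model.outcome,
            "estimates": [e.__dict__ for e in self.estimates.values()],
        }
        text = json.dumps(payload, indent=2, default=str) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        """Human-readable overview of all fitted approaches."""
        lines = [
            f"Mendelian randomization: {self.model.exposure} -> {self.model.outcome}",
            f"Instruments: {len(self.model.instruments)} SNPs",
            "-" * 78,
            f"{'method':<24}{'n':>4}{'beta':>10}{'se':>9}{'95% CI':>20}{'p':>10}",
        ]
        for e in self.estimates.values():
            ci = f"[{e.ci_low:.4f}, {e.ci_high:.4f}]"
            lines.append(
                f"{e.method:<24}{e.n_snps:>4}{e.beta:>10.4f}{e.se:>9.4f}{ci:>20}{e.p_value:>10.3g}"
            )
        het = [e for e in self.estimates.values() if e.q_statistic is not None]
        if het:
            e = het[0]
            lines.append("-" * 78)
            lines.append(
                f"Heterogeneity ({e.method}): Q={e.q_statistic:.2f}, "
                f"p={e.p_heterogeneity:.3g}, I^2={100 * (e.i_squared or 0):.1f}%"
            )
        report = self.pleiotropy_report
        if report is not None:
            lines.append(
                f"Heterogeneity filter: {len(report.flagged_rsids)} SNPs flagged "
                f"(p_het {report.p_het_before:.2g} -> {report.p_het_after:.2g})"
            )
        return "\n".join(lines)
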