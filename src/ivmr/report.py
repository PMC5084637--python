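"""End-to-end pipeline orchestration and figure rendering.

``run_pipeline`` drives the full analysis from raw instrument tables to a
results bundle on disk: read, harmonize, select, enrichment lookup, the MR
estimator battery with pleiotropy filtering and sensitivity analyses, and the
figures (p-value histogram, effect scatter with the MR slope).  Every stage
logs its instrument counts so the bookkeeping is auditable, and a fixed seed
makes the bundle reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .enrichment import binomial_enrichment, direction_consistency, pvalue_histogram
from .estimators import CausalEstimate
from .exceptions import IVMRError
from .instruments import (
    InstrumentSet,
    explained_variance,
    harmonize,
    mean_f_statistic,
    read_instruments,
    select_instruments,
)
from .model import MRModel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs; mirrors the CLI flags."""

    input_path: str | Path
    outcome_path: str | Path | None = None  # separate outcome table to harmonize in
    output_dir: str | Path = "ivmr_results"
    column_map: Mapping[str, str] = field(default_factory=dict)
    covariate_columns: Mapping[str, str] = field(default_factory=dict)
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    selection_threshold: float | None = 5e-8
    alpha: float = 0.05
    expected_direction: str = "positive"
    filter_mode: str = "iterative"
    alpha_snp: float = 0.05
    annotation_label: str | None = None
    overlap_fraction: float | None = None
    observational_estimate: float | None = None
    palindromic_policy: str = "keep"
    n_bootstrap: int = 10_000
    seed: int = 20_170_520
    exposure_sample_size: float | None = None
    make_plots: bool = True

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of in-memory results.

    Stage failures are logged with the stage name; independent downstream
    stages still run.  On-disk bundle: harmonized instrument TSV, enrichment
    JSON + histogram TSV, Table-2-style results TSV/JSON, per-SNP Q-contribution
    TSV, figures, and a plain-text run log.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ivmr")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    results: dict = {"config": dataclasses.asdict(cfg)}
    try:
        # ---- read + harmonize + select
        s = read_instruments(
            cfg.input_path,
            cfg.column_map,
            exposure_name=cfg.exposure_name,
            outcome_name=cfg.outcome_name,
            covariate_columns=cfg.covariate_columns,
        )
        logger.info("read %d instruments from %s", len(s), cfg.input_path)
        if cfg.outcome_path is not None:
            outcome = read_instruments(cfg.outcome_path, cfg.column_map)
            s = harmonize(s, outcome, palindromic_policy=cfg.palindromic_policy)
            logger.info("harmonized to %d shared instruments", len(s))
        if cfg.selection_threshold is not None:
            s = select_instruments(s, cfg.selection_threshold)
            logger.info("selected %d instruments at p < %g", len(s), cfg.selection_threshold)
        s.to_tsv(out / "instruments.harmonized.tsv")
        results["instruments"] = s

        # ---- instrument strength
        results["mean_f_statistic"] = mean_f_statistic(s)
        logger.info("mean F statistic: %.1f", results["mean_f_statistic"])
        if cfg.exposure_sample_size:
            results["explained_variance"] = explained_variance(
                s, per_snp_n=cfg.exposure_sample_size
            )
            logger.info("explained variance: %.4f", results["explained_variance"])

        # ---- enrichment lookup
        try:
            enr = binomial_enrichment(s.data["p_outcome"].tolist(), cfg.alpha)
            n_inconsistent, flags = direction_consistency(s, cfg.expected_direction)
            enr = dataclasses.replace(enr, n_direction_inconsistent=n_inconsistent)
            results["enrichment"] = enr
            (out / "enrichment.json").write_text(
                json.dumps(dataclasses.asdict(enr), indent=2) + "\n"
            )
            counts, edges, expected = pvalue_histogram(
                s.data["p_outcome"].tolist(),
                20,
                plot_path=(out / "pvalue_histogram") if cfg.make_plots else None,
            )
            with open(out / "pvalue_histogram.tsv", "w") as fh:
                fh.write("bin_start\tbin_end\tcount\texpected\n")
                for i, c in enumerate(counts):
                    fh.write(f"{edges[i]:.4f}\t{edges[i + 1]:.4f}\t{c}\t{expected:.4f}\n")
            logger.info("enrichment: %s (direction-inconsistent: %d)", enr, n_inconsistent)
        except IVMRError as exc:
            logger.error("stage 'enrichment' failed: %s", exc)

        # ---- MR estimator battery
        model = MRModel(s)
        fit = model.fit_all(
            covariates=sorted(cfg.covariate_columns),
            filter_mode=cfg.filter_mode,
            alpha_snp=cfg.alpha_snp,
            annotation_label=cfg.annotation_label,
            overlap_fraction=cfg.overlap_fraction,
            observational_estimate=cfg.observational_estimate,
            n_bootstrap=cfg.n_bootstrap,
            seed=cfg.seed,
        )
        results["mr"] = fit
        fit.to_tsv(out / "mr_results.tsv")
        fit.to_json(out / "mr_results.json")
        report = fit.pleiotropy_report
        if report is not None:
            report.to_json(out / "pleiotropy_report.json")
            report.per_snp_table().to_csv(out / "per_snp_q.tsv", sep="\t", index=False)
            logger.info(
                "goodness-of-fit filter flagged %d SNPs; p_het %.3g -> %.3g",
                len(report.flagged_rsids), report.p_het_before, report.p_het_after,
            )
        for line in fit.summary().splitlines():
            logger.info("%s", line)

        # ---- figures
        if cfg.make_plots:
            try:
                flagged = set(report.flagged_rsids) if report else set()
                scatter_plot(
                    s, list(fit.estimates.values()), flagged, path=out / "effect_scatter"
                )
            except IVMRError as exc:
                logger.error("stage 'scatter_plot' failed: %s", exc)
        return results
    finally:
        root.removeHandler(handler)
        handler.close()


def scatter_plot(
    s: InstrumentSet,
    estimates: Sequence[CausalEstimate],
    flagged: set[str] | None = None,
    *,
    path: str | Path,
) -> None:
    """Per-SNP effect scatter with the MR slope and its 95% CI band.

    x: exposure betas +/- 1.96 SE; y: outcome betas +/- 1.96 SE.  The solid
    line through the origin has the first estimate's slope, dashed lines its
    CI bounds.  Flagged (pleiotropy-suspect) SNPs are drawn in red with their
    gene-name annotation when present.
    """
    if len(s) == 0:
        raise IVMRError("cannot plot an empty instrument set")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    flagged = flagged or set()
    d = s.data
    sign = np.where(d["beta_exposure"].to_numpy(float) < 0, -1.0, 1.0)
    bx = d["beta_exposure"].to_numpy(float) * sign
    by = d["beta_outcome"].to_numpy(float) * sign
    sx = d["se_exposure"].to_numpy(float)
    sy = d["se_outcome"].to_numpy(float)
    is_flagged = d["rsid"].isin(flagged).to_numpy()

    fig, ax = plt.subplots(figsize=(7, 5))
    for mask, color in ((~is_flagged, "#30608a"), (is_flagged, "#c03030")):
        if mask.any():
            ax.errorbar(
                bx[mask], by[mask], xerr=1.96 * sx[mask], yerr=1.96 * sy[mask],
                fmt="o", ms=4, color=color, ecolor=color, elinewidth=0.7, alpha=0.8,
            )
    for i, row in d.iterrows():
        if row["rsid"] in flagged:
            genes = [a for a in row["annotations"] if not a.startswith("gwas_catalog")]
            if genes:
                ax.annotate(
                    ",".join(sorted(genes)), (bx[i], by[i]),
                    fontsize=7, xytext=(3, 3), textcoords="offset points",
                )
    slope_est = next((e for e in estimates if e.method.startswith("ivw")), None)
    if slope_est is not None:
        xs = np.linspace(0, float(bx.max()) * 1.05, 50)
        ax.plot(xs, slope_est.beta * xs, "k-", lw=1.5)
        ax.plot(xs, slope_est.ci_low * xs, "k--", lw=1)
        ax.plot(xs, slope_est.ci_high * xs, "k--", lw=1)
    else:
        logger.warning("scatter_plot: no IVW estimate supplied; slope omitted")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"SNP effect on {s.exposure_name} (SD)")
    ax.set_ylabel(f"SNP effect on {s.outcome_name}")
    fig.tight_layout()
    p = Path(path)
    if p.suffix:
        fig.savefig(p, dpi=150)
    else:
        fig.savefig(p.with_suffix(".png"), dpi=150)
        fig.savefig(p.with_suffix(".svg"))
    plt.close(fig)
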