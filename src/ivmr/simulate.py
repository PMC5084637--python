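"""Synthetic GWAS summary statistics with known ground truth.

Emulates the study design downstream code targets: a panel of independent
SNPs selected for genome-wide-significant association with a standardized
exposure (HDL cholesterol, SD units), looked up against an outcome (log
eGFR) measured in a second, partially overlapping sample.  Ground truth —
the per-SNP true effects and which instruments are valid — is returned
alongside the observed table, so estimator bias, filter recovery and power
can all be measured exactly.

The generative model per SNP i:

* true exposure effect ``b_i`` drawn from a folded normal with scale
  ``exposure_beta_scale`` (effect sizes span a wide range, like a panel of
  GWAS lead SNPs);
* true outcome effect ``a_i + beta * b_i`` where ``beta`` is the causal
  effect and ``a_i`` a direct (pleiotropic) effect, nonzero for a random
  ``pleiotropy_fraction`` of SNPs, drawn Normal(pleiotropy_mean,
  pleiotropy_sd) — mean 0 gives balanced pleiotropy, nonzero directional;
  with ``inside_violated`` the direct effect is proportional to ``b_i``;
* observed betas add bivariate Gaussian noise with SDs ``1/sqrt(n_exposure)``
  and ``1/sqrt(n_outcome)`` and correlation ``overlap_correlation``
  (participant overlap correlates the two sampling errors);
* genome-wide selection (p_exposure < ``selection_threshold``) is applied to
  the *observed* exposure statistics, so winner's curse is present by
  construction, as in real lookups.

Each SNP draws from its own deterministic substream, so enlarging ``n_snps``
never reshuffles earlier SNPs and identical seeds give bit-identical tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import ivw
from .exceptions import ValidationError
from .instruments import InstrumentSet

logger = logging.getLogger(__name__)

#: attempts to redraw a panel when selection leaves < 3 SNPs
RETRY_LIMIT = 10


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters; defaults mirror the target study design."""

    n_snps: int = 68
    true_causal_beta: float = 0.0
    exposure_beta_scale: float = 0.05
    n_exposure: int = 188_000
    n_outcome: int = 133_413
    pleiotropy_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.015
    inside_violated: bool = False
    overlap_correlation: float = 0.0
    selection_threshold: float | None = 5e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pleiotropy_fraction <= 1):
            raise ValidationError("pleiotropy_fraction must be in [0, 1]")
        if not (-1 <= self.overlap_correlation <= 1):
            raise ValidationError("overlap_correlation must be in [-1, 1]")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ValidationError("sample sizes must be >= 2")
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        if self.selection_threshold is not None and not (0 < self.selection_threshold <= 1):
            raise ValidationError("selection_threshold must be in (0, 1] or None")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Read a flat key-value config file (YAML syntax, keys = field names)."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def exposure_scale_for_survival(
    fraction: float,
    se_exposure: float,
    threshold: float = 5e-8,
) -> float:
    """Folded-normal scale at which ``fraction`` of draws pass selection.

    Solves for the scale ``s`` such that P(|N(0, s)| > z_crit * se) =
    ``fraction``, with ``z_crit`` the two-sided normal quantile of the
    selection threshold.  Useful for constructing panels with a target
    survival rate.
    """
    if not (0 < fraction < 1):
        raise ValidationError("fraction must be in (0, 1)")
    z_crit = stats.norm.isf(threshold / 2)
    # |N(0,s)| > c  <=>  fraction = 2 * sf(c / s)
    return float(z_crit * se_exposure / stats.norm.isf(fraction / 2))


def _draw_panel(cfg: SimulationConfig, attempt: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    se_x = cfg.n_exposure**-0.5
    se_y = cfg.n_outcome**-0.5
    root = np.random.SeedSequence(cfg.seed, spawn_key=(attempt,))
    children = root.spawn(cfg.n_snps + 1)
    # panel-level stream decides which SNPs carry direct effects
    panel_rng = np.random.default_rng(children[-1])
    n_invalid = int(round(cfg.pleiotropy_fraction * cfg.n_snps))
    invalid_idx = set(
        panel_rng.choice(cfg.n_snps, size=n_invalid, replace=False).tolist()
    ) if n_invalid else set()

    cov = np.array(
        [
            [se_x**2, cfg.overlap_correlation * se_x * se_y],
            [cfg.overlap_correlation * se_x * se_y, se_y**2],
        ]
    )
    chol = np.linalg.cholesky(cov)

    rows, truth_rows = [], []
    alleles = ("A", "G")  # non-palindromic pair; allele identity is inert here
    for i in range(cfg.n_snps):
        rng = np.random.default_rng(children[i])
        b_true = abs(rng.normal(0.0, cfg.exposure_beta_scale))
        direct = 0.0
        if i in invalid_idx:
            if cfg.inside_violated:
                # direct effect scales with instrument strength: InSIDE broken
                direct = b_true * rng.normal(
                    cfg.pleiotropy_mean / max(cfg.exposure_beta_scale, 1e-12),
                    cfg.pleiotropy_sd / max(cfg.exposure_beta_scale, 1e-12),
                )
            else:
                direct = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd)
        y_true = cfg.true_causal_beta * b_true + direct
        noise = chol @ rng.standard_normal(2)
        bx_obs = b_true + noise[0]
        by_obs = y_true + noise[1]
        p_x = 2 * stats.norm.sf(abs(bx_obs) / se_x)
        p_y = 2 * stats.norm.sf(abs(by_obs) / se_y)
        rows.append(
            {
                "rsid": f"rs{i + 1:06d}",
                "effect_allele": alleles[0],
                "other_allele": alleles[1],
                "beta_exposure": bx_obs,
                "se_exposure": se_x,
                "p_exposure": max(p_x, 5e-324),
                "beta_outcome": by_obs,
                "se_outcome": se_y,
                "p_outcome": max(p_y, 5e-324),
            }
        )
        truth_rows.append(
            {
                "rsid": f"rs{i + 1:06d}",
                "true_beta_exposure": b_true,
                "true_direct_effect": direct,
                "true_beta_outcome": y_true,
                "valid_instrument": i not in invalid_idx,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_instruments(cfg: SimulationConfig) -> tuple[InstrumentSet, pd.DataFrame]:
    """Generate one instrument panel plus its ground-truth table.

    Returns the post-selection :class:`InstrumentSet` and a truth DataFrame
    covering every drawn SNP (columns ``true_beta_exposure``,
    ``true_direct_effect``, ``true_beta_outcome``, ``valid_instrument``,
    ``selected``).  If selection leaves fewer than 3 SNPs the whole panel is
    redrawn from a fresh substream, up to ``RETRY_LIMIT`` times.
    """
    for attempt in range(RETRY_LIMIT):
        table, truth = _draw_panel(cfg, attempt)
        if cfg.selection_threshold is not None:
            selected = table["p_exposure"] < cfg.selection_threshold
        else:
            selected = pd.Series(True, index=table.index)
        truth["selected"] = selected.to_numpy()
        if cfg.selection_threshold is None or selected.sum() >= 3:
            s = InstrumentSet(
                table[selected],
                exposure_name="HDL",
                outcome_name="log_eGFR",
                selection_pvalue_threshold=cfg.selection_threshold,
                assumed_ld_independent=True,
            )
            return s, truth
        logger.warning(
            "simulate_instruments: selection left %d SNPs (attempt %d); redrawing",
            int(selected.sum()), attempt + 1,
        )
    raise ValidationError(
        f"selection left < 3 SNPs in {RETRY_LIMIT} attempts; "
        "raise exposure_beta_scale or relax selection_threshold"
    )


def power_curve(
    cfg: SimulationConfig,
    causal_grid: Sequence[float],
    n_replicates: int = 500,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Monte-Carlo power of the random-effects IVW test across causal effects.

    For each grid value, simulates ``n_replicates`` panels (replicate seeds
    derived deterministically from ``cfg.seed``), runs IVW with multiplicative
    random effects, and reports the rejection fraction at level ``alpha``.
    At a true effect of zero this is the empirical type-I error rate.
    """
    causal_grid = list(causal_grid)
    if not causal_grid:
        raise ValidationError("causal_grid must be nonempty")
    if n_replicates < 100:
        raise ValidationError("n_replicates must be >= 100")
    rows = []
    for gi, beta in enumerate(causal_grid):
        hits = 0
        for rep in range(n_replicates):
            rep_seed = int(
                np.random.SeedSequence(cfg.seed, spawn_key=(7, gi, rep)).generate_state(1)[0]
                % (2**31)
            )
            rep_cfg = dataclasses.replace(cfg, true_causal_beta=float(beta), seed=rep_seed)
            panel, _ = simulate_instruments(rep_cfg)
            est = ivw(panel, effects_model="random_multiplicative")
            hits += est.p_value < alpha
        rows.append({"causal_beta": float(beta), "power": hits / n_replicates})
    return pd.DataFrame(rows)


def write_simulation(
    cfg: SimulationConfig, out_prefix: str | Path
) -> tuple[InstrumentSet, pd.DataFrame]:
    """Simulate and write the instrument TSV (+ metadata sidecar) and truth TSV."""
    panel, truth = simulate_instruments(cfg)
    prefix = Path(out_prefix)
    panel.to_tsv(prefix.with_suffix(".instruments.tsv"))
    truth.to_csv(prefix.with_suffix(".truth.tsv"), sep="\t", index=False)
    return panel, truth
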