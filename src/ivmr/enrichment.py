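"""Single-SNP lookup analysis: over-representation of small outcome p-values.

If the exposure has no effect on the outcome and the instruments are valid,
outcome-association p-values across the instrument panel are uniform on
(0, 1].  An excess of small p-values is tested with a one-sided exact
binomial tail; per-SNP significance uses a Bonferroni-corrected threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .instruments import InstrumentSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """Counts and test results of the single-SNP outcome lookup."""

    n_total: int
    n_below: int
    alpha: float
    expected_fraction: float
    p_binomial: float
    bonferroni_threshold: float
    n_bonferroni_significant: int
    n_direction_inconsistent: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.n_below}/{self.n_total} SNPs with p < {self.alpha} "
            f"(expected {self.expected_fraction * self.n_total:.1f}); "
            f"binomial p = {self.p_binomial:.3g}; "
            f"{self.n_bonferroni_significant} below Bonferroni threshold "
            f"{self.bonferroni_threshold:.3g}"
        )


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValidationError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def binomial_enrichment(p_values: Sequence[float], alpha: float = 0.05) -> EnrichmentResult:
    """Exact one-sided binomial test for an excess of p-values below ``alpha``.

    With ``k`` of ``n`` p-values strictly below ``alpha``, reports
    P(X >= k) for X ~ Binomial(n, alpha) — the probability of observing at
    least this many small p-values if all nulls were true.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("p_values must be nonempty")
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha={alpha} outside (0, 1)")
    n = int(p.size)
    k = int(np.sum(p < alpha))
    # exact upper tail P(X >= k) = sf(k - 1)
    p_binom = float(stats.binom.sf(k - 1, n, alpha))
    bonf = bonferroni_threshold(n, alpha)
    return EnrichmentResult(
        n_total=n,
        n_below=k,
        alpha=alpha,
        expected_fraction=alpha,
        p_binomial=p_binom,
        bonferroni_threshold=bonf,
        n_bonferroni_significant=int(np.sum(p < bonf)),
    )


def direction_consistency(
    s: InstrumentSet, expected_sign: str = "positive"
) -> tuple[int, dict[str, bool]]:
    """Count SNPs whose outcome effect contradicts the expected direction.

    Every record is first oriented to its exposure-increasing allele (both
    betas flipped where beta_exposure < 0), so the count is invariant to how
    the effect allele was labelled.  Returns the count of inconsistent SNPs
    and a per-rsid flag map (True = inconsistent).  Records with
    beta_exposure exactly zero are skipped with a warning.
    """
    if expected_sign not in ("positive", "negative"):
        raise ValidationError(f"expected_sign must be 'positive' or 'negative', got {expected_sign!r}")
    want = 1.0 if expected_sign == "positive" else -1.0
    flags: dict[str, bool] = {}
    for _, row in s.data.iterrows():
        bx, by = float(row["beta_exposure"]), float(row["beta_outcome"])
        if bx == 0:
            logger.warning("direction_consistency: beta_exposure=0 for %s; skipped", row["rsid"])
            continue
        oriented_by = by if bx > 0 else -by
        flags[row["rsid"]] = (oriented_by * want) < 0
    return sum(flags.values()), flags


def pvalue_histogram(
    p_values: Sequence[float],
    n_bins: int = 20,
    *,
    plot_path: str | Path | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Equal-width histogram of p-values on [0, 1] with the uniform reference.

    Returns (counts, bin_edges, expected_per_bin).  Under the global null the
    counts fluctuate around ``len(p_values) / n_bins``.  If ``plot_path`` is
    given, a bar plot with the uniform reference line is written there (both
    PNG and SVG when the suffix is omitted).
    """
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    p = np.asarray(p_values, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(p, bins=edges)
    expected = p.size / n_bins
    if plot_path is not None:
        _render_histogram(counts, edges, expected, Path(plot_path))
    return counts, edges, expected


def _render_histogram(counts: np.ndarray, edges: np.ndarray, expected: float, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    widths = np.diff(edges)
    ax.bar(edges[:-1], counts, width=widths, align="edge", color="#4878a8", edgecolor="white")
    ax.axhline(expected, linestyle="--", color="black", label="uniform expectation")
    ax.set_xlabel("outcome association p-value")
    ax.set_ylabel("number of SNPs")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path.suffix:
        fig.savefig(path, dpi=150)
    else:
        fig.savefig(path.with_suffix(".png"), dpi=150)
        fig.savefig(path.with_suffix(".svg"))
    plt.close(fig)
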