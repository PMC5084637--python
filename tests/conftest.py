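import numpy as np
import pandas as pd
import pytest

from ivmr import InstrumentSet


def make_set(
    beta_exposure,
    beta_outcome,
    se_exposure=None,
    se_outcome=None,
    rsids=None,
    annotations=None,
    **extra,
):
    """Build a small InstrumentSet from parallel arrays with sane defaults."""
    bx = np.asarray(beta_exposure, dtype=float)
    by = np.asarray(beta_outcome, dtype=float)
    n = bx.size
    sx = np.full(n, 0.01) if se_exposure is None else np.asarray(se_exposure, float)
    sy = np.full(n, 0.005) if se_outcome is None else np.asarray(se_outcome, float)
    df = pd.DataFrame(
        {
            "rsid": rsids or [f"rs{i + 1}" for i in range(n)],
            "effect_allele": ["A"] * n,
            "other_allele": ["G"] * n,
            "beta_exposure": bx,
            "se_exposure": sx,
            "p_exposure": np.clip(2 * _norm_sf(np.abs(bx) / sx), 5e-324, 1.0),
            "beta_outcome": by,
            "se_outcome": sy,
            "p_outcome": np.clip(2 * _norm_sf(np.abs(by) / sy), 5e-324, 1.0),
        }
    )
    if annotations is not None:
        df["annotations"] = annotations
    for k, v in extra.items():
        df[k] = v
    return InstrumentSet(df)


def _norm_sf(z):
    from scipy.stats import norm

    return norm.sf(z)


@pytest.fixture
def three_snp_set():
    """The 3-SNP hand case used for closed-form oracle checks."""
    return make_set(
        beta_exposure=[0.1, 0.2, 0.05],
        beta_outcome=[0.002, 0.003, 0.0005],
        se_outcome=[0.001, 0.001, 0.002],
    )


@pytest.fixture
def replicate_seeds():
    """Deterministic per-replicate seeds below 2**31."""

    def _seeds(master, n):
        return [
            int(np.random.SeedSequence(master, spawn_key=(i,)).generate_state(1)[0] % 2**31)
            for i in range(n)
        ]

    return _seeds
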