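"""Genetic-instrument containers, I/O, harmonization and strength diagnostics.

The working unit is the :class:`InstrumentSet`: a table of independent SNPs,
each with a per-allele effect estimate and standard error on an exposure
(e.g. HDL cholesterol in SD units) and on an outcome (e.g. log eGFR), plus
optional covariate effects (LDL, TG), allele frequencies and free-text
annotations.  Everything downstream — enrichment tests, MR estimators,
pleiotropy filters — consumes this container.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: columns every instrument table must provide (possibly via a column map)
MANDATORY_COLUMNS = (
    "rsid",
    "effect_allele",
    "other_allele",
    "beta_exposure",
    "se_exposure",
    "p_exposure",
    "beta_outcome",
    "se_outcome",
    "p_outcome",
)

NUMERIC_COLUMNS = (
    "beta_exposure",
    "se_exposure",
    "p_exposure",
    "beta_outcome",
    "se_outcome",
    "p_outcome",
    "eaf",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    return _COMPLEMENT.get(allele.upper(), allele)


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T or C/G pairs are strand-ambiguous ('palindromic')."""
    return _complement(a1.upper()) == a2.upper()


@dataclass(frozen=True)
class InstrumentRecord:
    """One harmonized SNP instrument.

    ``beta_exposure``/``se_exposure`` are per effect allele in exposure SD
    units; ``beta_outcome``/``se_outcome`` in outcome units (log eGFR here).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    p_exposure: float
    beta_outcome: float
    se_outcome: float
    p_outcome: float
    beta_covariates: Mapping[str, float] = field(default_factory=dict)
    eaf: float | None = None
    annotations: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValidationError(
                f"{self.rsid}: standard errors must be positive "
                f"(se_exposure={self.se_exposure}, se_outcome={self.se_outcome})"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele identical")
        for name, p in (("p_exposure", self.p_exposure), ("p_outcome", self.p_outcome)):
            if not (0 < p <= 1):
                raise ValidationError(f"{self.rsid}: {name}={p} outside (0, 1]")


class InstrumentSet:
    """Ordered collection of instruments with provenance metadata.

    Thin wrapper around a :class:`pandas.DataFrame` (one row per SNP) carrying
    the trait names, the selection p-value threshold applied (if any), and a
    flag recording that LD independence (r^2 < 0.1) is assumed of the input
    rather than computed.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
        selection_pvalue_threshold: float | None = None,
        assumed_ld_independent: bool = True,
    ) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in data.columns]
        if missing:
            raise ConfigurationError(f"missing mandatory column(s): {', '.join(missing)}")
        data = data.reset_index(drop=True).copy()
        dup = data["rsid"][data["rsid"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate rsid(s): {sorted(set(dup))}")
        if (data["se_exposure"] <= 0).any() or (data["se_outcome"] <= 0).any():
            bad = data.loc[(data["se_exposure"] <= 0) | (data["se_outcome"] <= 0), "rsid"]
            raise ValidationError(f"non-positive standard error for: {list(bad)}")
        for col in ("p_exposure", "p_outcome"):
            if ((data[col] <= 0) | (data[col] > 1)).any():
                bad = data.loc[(data[col] <= 0) | (data[col] > 1), "rsid"]
                raise ValidationError(f"{col} outside (0, 1] for: {list(bad)}")
        if "annotations" not in data.columns:
            data["annotations"] = [frozenset() for _ in range(len(data))]
        else:
            data["annotations"] = [_as_annotation_set(a) for a in data["annotations"]]
        self.data = data
        self.exposure_name = exposure_name
        self.outcome_name = outcome_name
        self.selection_pvalue_threshold = selection_pvalue_threshold
        self.assumed_ld_independent = assumed_ld_independent

    # ------------------------------------------------------------------ basics
    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self) -> Iterator[InstrumentRecord]:
        return iter(self.records)

    @property
    def rsids(self) -> list[str]:
        return list(self.data["rsid"])

    @property
    def covariate_names(self) -> list[str]:
        return [c[len("beta_cov_"):] for c in self.data.columns if c.startswith("beta_cov_")]

    @property
    def records(self) -> list[InstrumentRecord]:
        covs = self.covariate_names
        out = []
        for _, row in self.data.iterrows():
            beta_cov = {
                c: float(row[f"beta_cov_{c}"])
                for c in covs
                if pd.notna(row[f"beta_cov_{c}"])
            }
            eaf = float(row["eaf"]) if "eaf" in row.index and pd.notna(row["eaf"]) else None
            out.append(
                InstrumentRecord(
                    rsid=row["rsid"],
                    effect_allele=row["effect_allele"],
                    other_allele=row["other_allele"],
                    beta_exposure=float(row["beta_exposure"]),
                    se_exposure=float(row["se_exposure"]),
                    p_exposure=float(row["p_exposure"]),
                    beta_outcome=float(row["beta_outcome"]),
                    se_outcome=float(row["se_outcome"]),
                    p_outcome=float(row["p_outcome"]),
                    beta_covariates=beta_cov,
                    eaf=eaf,
                    annotations=row["annotations"],
                )
            )
        return out

    def _with_data(self, data: pd.DataFrame, **meta) -> "InstrumentSet":
        kwargs = dict(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            selection_pvalue_threshold=self.selection_pvalue_threshold,
            assumed_ld_independent=self.assumed_ld_independent,
        )
        kwargs.update(meta)
        return InstrumentSet(data, **kwargs)

    def subset(self, rsids: Sequence[str]) -> "InstrumentSet":
        keep = set(rsids)
        return self._with_data(self.data[self.data["rsid"].isin(keep)])

    def drop(self, rsids: Sequence[str]) -> "InstrumentSet":
        out = set(rsids)
        return self._with_data(self.data[~self.data["rsid"].isin(out)])

    # --------------------------------------------------------------------- I/O
    def to_tsv(self, path: str | Path, *, sidecar: bool = True) -> None:
        """Write the instrument table as TSV plus a JSON metadata sidecar."""
        df = self.data.copy()
        df["annotations"] = [";".join(sorted(a)) for a in df["annotations"]]
        df.to_csv(path, sep="\t", index=False)
        if sidecar:
            meta = {
                "exposure_name": self.exposure_name,
                "outcome_name": self.outcome_name,
                "selection_pvalue_threshold": self.selection_pvalue_threshold,
                "assumed_ld_independent": self.assumed_ld_independent,
                "n_snps": len(self),
            }
            Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def _as_annotation_set(value) -> frozenset[str]:
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(str(v) for v in value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    text = str(value).strip()
    if not text:
        return frozenset()
    return frozenset(t.strip() for t in text.split(";") if t.strip())


# -------------------------------------------------------------------- reading

def read_instruments(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    covariate_columns: Mapping[str, str] | None = None,
) -> InstrumentSet:
    """Read a tab-separated instrument table.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Maps canonical field names (``rsid``, ``beta_exposure``, ...) to the
        column names actually present in the file.  Fields not mentioned are
        assumed to use their canonical name.
    covariate_columns
        Maps covariate trait names (e.g. ``"LDL"``) to the file columns that
        hold the per-allele effects on that trait.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, sep="\t", dtype=str)
    rename = {}
    for canonical in MANDATORY_COLUMNS + ("eaf", "annotations"):
        source = column_map.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical in MANDATORY_COLUMNS:
            raise ConfigurationError(
                f"missing mandatory column '{canonical}' (looked for '{source}') in {path}"
            )
    df = raw.rename(columns=rename)
    for trait, source in (covariate_columns or {}).items():
        if source not in raw.columns:
            raise ConfigurationError(f"missing covariate column '{source}' for trait '{trait}'")
        df[f"beta_cov_{trait}"] = raw[source]
    keep = [c for c in df.columns if c in MANDATORY_COLUMNS + ("eaf", "annotations")
            or c.startswith("beta_cov_")]
    df = df[keep]
    for col in df.columns:
        if col in NUMERIC_COLUMNS or col.startswith("beta_cov_"):
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = parsed.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"non-numeric value {df[col].iloc[row]!r} in column '{col}', "
                    f"data row {row + 1}"
                )
            df[col] = parsed
    return InstrumentSet(df, exposure_name=exposure_name, outcome_name=outcome_name)


# --------------------------------------------------------------- harmonization

def harmonize(
    exposure_table: InstrumentSet,
    outcome_table: InstrumentSet,
    palindromic_policy: str = "keep",
) -> InstrumentSet:
    """Merge exposure and outcome summary statistics on a shared effect allele.

    Takes the rsid intersection of the two tables.  Where the outcome table
    reports its effect for the exposure table's *other* allele (directly or
    after A<->T / C<->G strand complementation), the outcome beta is negated so
    both traits refer to the same effect allele.  Palindromic SNPs (A/T, C/G)
    are kept or dropped per ``palindromic_policy``; irreconcilable allele pairs
    are excluded with a log message.  The operation is idempotent.
    """
    if palindromic_policy not in ("keep", "drop"):
        raise ValidationError(f"palindromic_policy must be 'keep' or 'drop', got {palindromic_policy!r}")
    exp = exposure_table.data.set_index("rsid")
    out = outcome_table.data.set_index("rsid")
    shared = [r for r in exposure_table.rsids if r in out.index]
    if not shared:
        raise ValidationError("no shared rsids between exposure and outcome tables")

    rows = []
    for rsid in shared:
        e = exp.loc[rsid]
        o = out.loc[rsid]
        ea, oa = e["effect_allele"].upper(), e["other_allele"].upper()
        if palindromic_policy == "drop" and is_palindromic(ea, oa):
            logger.info("harmonize: dropping palindromic SNP %s (%s/%s)", rsid, ea, oa)
            continue
        o_ea, o_oa = o["effect_allele"].upper(), o["other_allele"].upper()
        if (o_ea, o_oa) in ((ea, oa), (_complement(ea), _complement(oa))):
            flip = False
        elif (o_ea, o_oa) in ((oa, ea), (_complement(oa), _complement(ea))):
            flip = True
        else:
            logger.warning(
                "harmonize: irreconcilable alleles for %s (exposure %s/%s, outcome %s/%s); excluded",
                rsid, ea, oa, o_ea, o_oa,
            )
            continue
        row = e.to_dict()
        row["rsid"] = rsid
        row["beta_outcome"] = -float(o["beta_outcome"]) if flip else float(o["beta_outcome"])
        row["se_outcome"] = float(o["se_outcome"])
        row["p_outcome"] = float(o["p_outcome"])
        rows.append(row)
    if not rows:
        raise ValidationError("harmonization excluded every shared SNP")
    df = pd.DataFrame(rows)
    return InstrumentSet(
        df,
        exposure_name=exposure_table.exposure_name,
        outcome_name=outcome_table.outcome_name,
        selection_pvalue_threshold=exposure_table.selection_pvalue_threshold,
        assumed_ld_independent=exposure_table.assumed_ld_independent
        and outcome_table.assumed_ld_independent,
    )


# ------------------------------------------------------------------- selection

def select_instruments(s: InstrumentSet, p_threshold: float = 5e-8) -> InstrumentSet:
    """Keep SNPs genome-wide significant for the exposure (p_exposure < threshold)."""
    if not (0 < p_threshold <= 1):
        raise ValidationError(f"p_threshold={p_threshold} outside (0, 1]")
    kept = s.data[s.data["p_exposure"] < p_threshold]
    return s._with_data(kept, selection_pvalue_threshold=p_threshold)


# ----------------------------------------------------------------- diagnostics

def f_statistics(s: InstrumentSet) -> np.ndarray:
    """Per-SNP instrument-strength F statistic, (beta_exposure / se_exposure)^2."""
    if len(s) == 0:
        raise ValidationError("empty instrument set")
    z = s.data["beta_exposure"].to_numpy() / s.data["se_exposure"].to_numpy()
    return z**2


def mean_f_statistic(s: InstrumentSet) -> float:
    """Mean instrument F statistic across the set (weak-instrument diagnostic)."""
    return float(np.mean(f_statistics(s)))


def explained_variance(
    s: InstrumentSet,
    per_snp_n: float | None = None,
    method: str = "beta_se_n",
) -> float:
    """Total exposure variance explained (R^2) by the instrument panel.

    ``beta_se_n`` uses r2_i = z_i^2 / (z_i^2 + n - 2) from the per-SNP z score
    and sample size.  ``af_weighted`` uses r2_i = 2 f_i (1 - f_i) beta_i^2 with
    the exposure standardised to unit variance (needs allele frequencies).
    The sum over SNPs is clipped to [0, 1].
    """
    if len(s) == 0:
        raise ValidationError("empty instrument set")
    if method == "beta_se_n":
        if per_snp_n is None:
            raise ConfigurationError("method 'beta_se_n' requires per_snp_n (sample size)")
        z2 = f_statistics(s)
        r2 = z2 / (z2 + per_snp_n - 2)
    elif method == "af_weighted":
        if "eaf" not in s.data.columns or s.data["eaf"].isna().any():
            raise ConfigurationError("method 'af_weighted' requires allele frequencies (eaf)")
        f = s.data["eaf"].to_numpy(dtype=float)
        beta = s.data["beta_exposure"].to_numpy(dtype=float)
        r2 = 2.0 * f * (1.0 - f) * beta**2
    else:
        raise ConfigurationError(f"unknown explained-variance method {method!r}")
    return float(np.clip(np.sum(r2), 0.0, 1.0))
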