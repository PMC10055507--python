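"""GWAS summary-statistic I/O and genetic-instrument selection.

Summary statistics are held as pandas DataFrames with a canonical column
schema (one row per variant). Instrument selection applies the usual
two-sample MR filters: genome-wide significance, a minor-allele-frequency
floor, an instrument-strength (F-statistic) floor, and greedy LD pruning
against a user-supplied pairwise r-squared matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order for summary-statistic tables.
CANONICAL_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

_NUMERIC_COLUMNS = ["eaf", "beta", "se", "pvalue", "n"]
_VALID_BASES = frozenset("ACGT")
TRAIT_TYPES = ("continuous", "binary")


def _check_trait_type(trait_type: str) -> None:
    if trait_type not in TRAIT_TYPES:
        raise ValueError(f"trait_type must be one of {TRAIT_TYPES}, got {trait_type!r}")


@dataclass
class SummaryStatTable:
    """Per-variant association records for a single trait.

    Parameters
    ----------
    trait_id
        Identifier of the trait the statistics describe.
    trait_type
        ``"continuous"`` (beta in SD units) or ``"binary"`` (beta is a log
        odds ratio).
    df
        DataFrame with (at least) the :data:`CANONICAL_COLUMNS`.
    provenance
        Free-text source label.
    n_rejected
        Rows dropped during parsing for violating record invariants.
    """

    trait_id: str
    trait_type: str
    df: pd.DataFrame
    provenance: str = ""
    n_rejected: int = 0

    def __post_init__(self) -> None:
        _check_trait_type(self.trait_type)
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"summary-statistic table missing columns: {missing}")
        dup = self.df["variant_id"].duplicated()
        if dup.any():
            dups = sorted(self.df.loc[dup, "variant_id"].unique())
            raise ValueError(f"duplicate variant_id values: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class InstrumentSet:
    """Variants retained as instruments for one exposure trait.

    ``df`` carries the canonical columns plus ``f_stat``; every row satisfies
    the selection filters it was produced under.
    """

    trait_id: str
    trait_type: str
    df: pd.DataFrame
    filters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)


def _valid_allele(series: pd.Series) -> pd.Series:
    return series.fillna("").map(
        lambda a: len(a) >= 1 and set(a) <= _VALID_BASES
    )


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    trait_type: str = "continuous",
    trait_id: str | None = None,
    provenance: str | None = None,
) -> SummaryStatTable:
    """Read a delimited summary-statistics file into a :class:`SummaryStatTable`.

    The file is tab-separated with a header (gzip is handled transparently by
    extension). ``column_map`` maps canonical field names to source column
    names, e.g. ``{"variant_id": "SNP", "pvalue": "P"}``; unmapped canonical
    names are taken verbatim. Rows violating record invariants
    (unparseable beta/se, se <= 0, p outside (0, 1], non-ACGT or identical
    alleles, non-positive n) are rejected and counted, never silently kept;
    out-of-range allele frequencies are set to missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    column_map = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise KeyError(f"column {src!r} (for field {canon!r}) not in header of {path}")
        rename[src] = canon
    df = raw.rename(columns=rename)[CANONICAL_COLUMNS].copy()

    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("variant_id", "effect_allele", "other_allele"):
        df[col] = df[col].astype("string").str.strip()
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()

    bad_eaf = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    if bad_eaf.any():
        logger.warning("%s: %d out-of-range eaf values set to missing", path.name, bad_eaf.sum())
        df.loc[bad_eaf, "eaf"] = np.nan

    ok = (
        df["variant_id"].notna()
        & (df["variant_id"] != "")
        & _valid_allele(df["effect_allele"])
        & _valid_allele(df["other_allele"])
        & (df["effect_allele"] != df["other_allele"])
        & np.isfinite(df["beta"])
        & np.isfinite(df["se"])
        & (df["se"] > 0)
        & df["pvalue"].notna()
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
        & df["n"].notna()
        & (df["n"] > 0)
    )
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.info("%s: rejected %d malformed rows", path.name, n_rejected)
    df = df.loc[ok].reset_index(drop=True)
    df["variant_id"] = df["variant_id"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str)
    df["other_allele"] = df["other_allele"].astype(str)

    return SummaryStatTable(
        trait_id=trait_id if trait_id is not None else path.name.split(".")[0],
        trait_type=trait_type,
        df=df,
        provenance=provenance if provenance is not None else str(path),
        n_rejected=n_rejected,
    )


def write_sumstats(table: SummaryStatTable, path: str | Path) -> Path:
    """Write a table to tab-separated text (gzip by ``.gz`` extension)."""
    path = Path(path)
    table.df[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def f_statistic(beta, se):
    """Per-variant instrument-strength F-statistic, (beta / se)^2.

    For a single-SNP regression this equals the square of the Wald z and is
    the quantity conventionally screened at F >= 10 against weak-instrument
    bias. Accepts scalars or arrays.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def _greedy_ld_prune(df: pd.DataFrame, ld_r2: pd.DataFrame, r2_max: float) -> list[str]:
    """Greedy pruning: keep the strongest remaining variant, drop its LD partners.

    Strength order: smallest p-value, then largest ``|beta|``, then
    lexicographic variant id — deterministic output.
    """
    order = df.assign(_absbeta=df["beta"].abs()).sort_values(
        ["pvalue", "_absbeta", "variant_id"], ascending=[True, False, True]
    )["variant_id"].tolist()
    removed: set[str] = set()
    kept: list[str] = []
    candidates = set(order)
    for vid in order:
        if vid in removed:
            continue
        kept.append(vid)
        partners = ld_r2.loc[vid]
        hits = partners.index[(partners.values > r2_max)]
        removed.update(h for h in hits if h != vid and h in candidates)
    return kept


def select_instruments(
    table: SummaryStatTable,
    p_max: float = 5e-8,
    maf_min: float = 0.01,
    ld_r2: pd.DataFrame | None = None,
    r2_max: float = 0.01,
    f_min: float = 10.0,
    *,
    allow_missing_eaf: bool = False,
) -> InstrumentSet:
    """Select genetic instruments for a trait.

    Filters, in order: association p-value < ``p_max`` (genome-wide
    significance, default 5e-8); minor-allele frequency
    ``min(eaf, 1 - eaf) >= maf_min`` (records with missing eaf pass only if
    ``allow_missing_eaf``); F-statistic >= ``f_min``; then greedy LD pruning
    so no retained pair has r^2 > ``r2_max``, always retaining the variant
    with the strongest association.

    ``ld_r2`` is a symmetric DataFrame indexed/columned by variant id covering
    every variant that passes the marginal filters; omit it for independent
    variants (no pruning). An empty result is returned with a warning, not an
    error.
    """
    if not (0 < p_max <= 1):
        raise ValueError("p_max must be in (0, 1]")
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0 <= r2_max <= 1):
        raise ValueError("r2_max must be in [0, 1]")

    df = table.df.copy()
    keep = df["pvalue"] < p_max
    maf = np.minimum(df["eaf"], 1 - df["eaf"])
    maf_ok = maf >= maf_min
    if allow_missing_eaf:
        maf_ok = maf_ok | df["eaf"].isna()
    keep &= maf_ok.fillna(False) if not allow_missing_eaf else maf_ok
    df = df.loc[keep].copy()
    df["f_stat"] = f_statistic(df["beta"].to_numpy(), df["se"].to_numpy()) if len(df) else np.array([])
    df = df.loc[df["f_stat"] >= f_min].copy()

    if ld_r2 is not None and len(df):
        missing = set(df["variant_id"]) - set(ld_r2.index)
        if missing:
            raise ValueError(f"ld_r2 matrix does not cover variants: {sorted(missing)[:5]}")
        kept = _greedy_ld_prune(df, ld_r2, r2_max)
        df = df.loc[df["variant_id"].isin(kept)].copy()

    df = df.reset_index(drop=True)
    if len(df) == 0:
        logger.warning("trait %s: no variants pass instrument filters", table.trait_id)
    logger.info("trait %s: %d/%d variants retained as instruments", table.trait_id, len(df), len(table))
    return InstrumentSet(
        trait_id=table.trait_id,
        trait_type=table.trait_type,
        df=df,
        filters={
            "p_max": p_max,
            "maf_min": maf_min,
            "r2_max": r2_max,
            "f_min": f_min,
            "allow_missing_eaf": allow_missing_eaf,
        },
    )
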