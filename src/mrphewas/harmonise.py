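"""Allele harmonisation of exposure and outcome summary statistics.

Two-sample MR requires the exposure and outcome effect estimates for each
instrument to reference the same effect allele. This module aligns an
outcome table onto an exposure instrument set, flipping effect signs where
the allele labels are swapped, resolving strand flips by complementing, and
treating palindromic (A/T, C/G) variants via allele-frequency orientation:
a palindrome is kept only when both frequencies fall outside a window around
0.5 and is dropped otherwise, since strand cannot then be inferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import InstrumentSet, SummaryStatTable

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Statuses under which an instrument is retained for analysis.
RETAINED_STATUSES = ("aligned", "flipped", "palindromic_kept")
DROPPED_STATUSES = ("dropped_palindromic", "dropped_incompatible", "dropped_missing_outcome")


def complement(allele: str) -> str:
    """Reverse complement of an allele string (simple complement for SNPs)."""
    return allele.translate(_COMPLEMENT)[::-1]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for strand-ambiguous allele pairs (A/T or C/G)."""
    return complement(effect_allele) == other_allele


@dataclass
class HarmonisedSet:
    """Allele-aligned exposure/outcome instrument pairs for one analysis.

    ``df`` has one row per retained instrument with columns ``variant_id``,
    ``beta_exp``, ``se_exp``, ``beta_out``, ``se_out``, ``eaf_exp``,
    ``eaf_out`` and ``status``; ``log`` additionally records every dropped
    instrument with its reason. ``lifetime_risk`` is the outcome's population
    lifetime risk K, used for liability-scale variance conversion.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    log: pd.DataFrame | None = None
    n_exp: float | None = None
    n_cases: float | None = None
    n_controls: float | None = None
    exposure_type: str = "continuous"
    lifetime_risk: float | None = None
    drops: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lifetime_risk is not None and not (0 < self.lifetime_risk < 1):
            raise ValueError("lifetime_risk must be in (0, 1)")
        retained = self.df["status"].isin(RETAINED_STATUSES) if len(self.df) else pd.Series(dtype=bool)
        if len(self.df) and not retained.all():
            raise ValueError("HarmonisedSet.df may only hold retained instruments")
        if len(self.df) and not ((self.df["se_exp"] > 0).all() and (self.df["se_out"] > 0).all()):
            raise ValueError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        eaf_exp=None,
        eaf_out=None,
        *,
        exposure_id: str = "exposure",
        outcome_id: str = "outcome",
        variant_ids=None,
        **kwargs,
    ) -> "HarmonisedSet":
        """Build a set directly from effect arrays (simulation/test helper)."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        n = len(beta_exp)
        if variant_ids is None:
            variant_ids = [f"rs{i + 1:06d}" for i in range(n)]
        df = pd.DataFrame(
            {
                "variant_id": variant_ids,
                "beta_exp": beta_exp,
                "se_exp": np.broadcast_to(np.asarray(se_exp, dtype=float), (n,)).copy(),
                "beta_out": np.asarray(beta_out, dtype=float),
                "se_out": np.broadcast_to(np.asarray(se_out, dtype=float), (n,)).copy(),
                "eaf_exp": np.broadcast_to(np.asarray(eaf_exp, dtype=float), (n,)).copy()
                if eaf_exp is not None
                else np.nan,
                "eaf_out": np.broadcast_to(np.asarray(eaf_out, dtype=float), (n,)).copy()
                if eaf_out is not None
                else np.nan,
                "status": "aligned",
            }
        )
        return cls(exposure_id=exposure_id, outcome_id=outcome_id, df=df, **kwargs)


def _harmonise_one(row: pd.Series, window: float) -> tuple[str, float, float]:
    """Return (status, beta_out, eaf_out) for one merged instrument row.

    ``beta_out``/``eaf_out`` are re-oriented to the exposure effect allele;
    they are NaN when the instrument is dropped.
    """
    ea_x, oa_x = row["effect_allele_exp"], row["other_allele_exp"]
    ea_y, oa_y = row["effect_allele_out"], row["other_allele_out"]
    beta_y, eaf_y = row["beta_out_raw"], row["eaf_out_raw"]

    pal = is_palindromic(ea_x, oa_x)
    pair_x = {ea_x, oa_x}
    if {ea_y, oa_y} == pair_x:
        swapped = ea_y != ea_x
    elif not pal and {complement(ea_y), complement(oa_y)} == pair_x:
        swapped = complement(ea_y) != ea_x
    else:
        return "dropped_incompatible", np.nan, np.nan

    if swapped:
        beta_y = -beta_y
        eaf_y = 1 - eaf_y if np.isfinite(eaf_y) else np.nan

    if not pal:
        return ("flipped" if swapped else "aligned"), beta_y, eaf_y

    # Palindrome: allele letters cannot distinguish strands, so orientation
    # must come from the allele frequencies on both sides.
    eaf_x = row["eaf_exp"]
    if not (np.isfinite(eaf_x) and np.isfinite(eaf_y)):
        return "dropped_palindromic", np.nan, np.nan
    if abs(eaf_x - 0.5) < window or abs(eaf_y - 0.5) < window:
        return "dropped_palindromic", np.nan, np.nan
    if (eaf_x - 0.5) * (eaf_y - 0.5) < 0:  # opposite orientation: flip again
        beta_y, eaf_y = -beta_y, 1 - eaf_y
    return "palindromic_kept", beta_y, eaf_y


def harmonise(
    exposure: InstrumentSet,
    outcome: SummaryStatTable,
    palindrome_eaf_window: float = 0.08,
    *,
    n_cases: float | None = None,
    n_controls: float | None = None,
    lifetime_risk: float | None = None,
) -> HarmonisedSet:
    """Align outcome effects onto the exposure instruments' effect alleles.

    Instruments absent from the outcome table are dropped and counted
    (no proxy search). ``palindrome_eaf_window`` is the half-width w of the
    ambiguity window: palindromic variants are kept only when both allele
    frequencies lie outside (0.5 - w, 0.5 + w). All drops are logged with
    reason codes; retained + dropped always equals the input instrument
    count.
    """
    if not (0 <= palindrome_eaf_window <= 0.5):
        raise ValueError("palindrome_eaf_window must be in [0, 0.5]")
    if len(exposure) == 0:
        raise ValueError("exposure instrument set is empty")

    exp = exposure.df.rename(
        columns={
            "effect_allele": "effect_allele_exp",
            "other_allele": "other_allele_exp",
            "eaf": "eaf_exp",
            "beta": "beta_exp",
            "se": "se_exp",
            "n": "n_exp",
        }
    )
    out = outcome.df.rename(
        columns={
            "effect_allele": "effect_allele_out",
            "other_allele": "other_allele_out",
            "eaf": "eaf_out_raw",
            "beta": "beta_out_raw",
            "se": "se_out",
        }
    )[["variant_id", "effect_allele_out", "other_allele_out", "eaf_out_raw", "beta_out_raw", "se_out"]]

    merged = exp.merge(out, on="variant_id", how="left")

    statuses, betas, eafs = [], [], []
    for _, row in merged.iterrows():
        if pd.isna(row["effect_allele_out"]):
            statuses.append("dropped_missing_outcome")
            betas.append(np.nan)
            eafs.append(np.nan)
            continue
        s, b, e = _harmonise_one(row, palindrome_eaf_window)
        statuses.append(s)
        betas.append(b)
        eafs.append(e)

    log = merged[["variant_id", "beta_exp", "se_exp", "eaf_exp"]].copy()
    log["beta_out"] = betas
    log["se_out"] = merged["se_out"]
    log["eaf_out"] = eafs
    log["status"] = statuses

    retained = log.loc[log["status"].isin(RETAINED_STATUSES)].reset_index(drop=True)
    retained = retained[
        ["variant_id", "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp", "eaf_out", "status"]
    ]
    drops = {
        s: int((log["status"] == s).sum()) for s in DROPPED_STATUSES if (log["status"] == s).any()
    }
    if drops:
        logger.info(
            "%s vs %s: retained %d/%d instruments (drops: %s)",
            exposure.trait_id, outcome.trait_id, len(retained), len(merged), drops,
        )
    assert len(retained) + sum(drops.values()) == len(merged)

    n_exp = float(exp["n_exp"].median()) if "n_exp" in exp else None
    return HarmonisedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        df=retained,
        log=log,
        n_exp=n_exp,
        n_cases=n_cases,
        n_controls=n_controls,
        exposure_type=exposure.trait_type,
        lifetime_risk=lifetime_risk,
        drops=drops,
    )
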