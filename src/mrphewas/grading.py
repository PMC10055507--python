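"""Four-tier evidence grading of MR associations and summary counting.

Continuous exposures are graded a priori into hierarchical tiers:

* ``robust`` — IVW-RE p below the family-wise (Bonferroni) threshold, a
  sensitivity estimator (WME or MBE) p < 0.05, true causal direction and
  more than one instrument;
* ``probable`` — as robust but IVW-RE p < 0.05;
* ``suggestive`` — IVW-RE p < 0.05 (multi-instrument) or Wald p < 0.05
  (single instrument);
* ``non_significant`` — otherwise.

Binary exposures, where two-sample MR effect sizes are unreliable, are
classified only as ``supported`` (p < 0.05) or ``not_supported``. All
threshold comparisons are strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

TIERS = ("robust", "probable", "suggestive", "non_significant")
BINARY_LABELS = ("supported", "not_supported")


def round_sig(x: float, sig_figs: int) -> float:
    """Round to a number of significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig_figs - 1)


def bonferroni_threshold(alpha: float, n_tests: int, *, sig_figs: int | None = None) -> float:
    """Per-test threshold ``alpha / n_tests`` controlling the family-wise rate.

    ``sig_figs`` additionally rounds the reported threshold (e.g. 0.05/3,500
    at two significant figures is 1.4e-5).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    thr = alpha / n_tests
    return round_sig(thr, sig_figs) if sig_figs is not None else thr


def grade_continuous(
    *,
    p_ivw: float | None = None,
    p_wald: float | None = None,
    p_wme: float | None = None,
    p_mbe: float | None = None,
    direction_true: bool | None = None,
    n_iv: int,
    robust_threshold: float,
) -> str:
    """Tier for a continuous-exposure association (strict inequalities).

    Tiers are evaluated robust -> probable -> suggestive and the first
    satisfied is returned. ``direction_true=None`` (direction not assessed)
    fails the robust/probable gates. A single-instrument association must
    supply ``p_wald``; a multi-instrument one must supply ``p_ivw``.
    """
    if n_iv < 1:
        raise ValueError("n_iv must be >= 1")
    multi = n_iv > 1
    if multi and p_ivw is None:
        raise ValueError("multi-instrument association requires p_ivw")
    if not multi and p_wald is None:
        raise ValueError("single-instrument association requires p_wald")

    sensitivity_ok = (p_wme is not None and p_wme < 0.05) or (
        p_mbe is not None and p_mbe < 0.05
    )
    if multi and sensitivity_ok and direction_true is True:
        if p_ivw < robust_threshold:
            return "robust"
        if p_ivw < 0.05:
            return "probable"
    if (multi and p_ivw < 0.05) or (not multi and p_wald < 0.05):
        return "suggestive"
    return "non_significant"


def grade_binary(p: float) -> str:
    """Binary-exposure classification: ``supported`` iff p < 0.05 (strict)."""
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    return "supported" if p < 0.05 else "not_supported"


@dataclass
class GradedAssociation:
    """One exposure-cancer pair with its tier and supporting statistics.

    Exactly one of ``tier`` / ``binary_support`` is populated, matching the
    exposure's trait type.
    """

    exposure_id: str
    outcome_id: str
    exposure_type: str = "continuous"
    tier: str | None = None
    binary_support: str | None = None
    p_ivw: float | None = None
    p_wald: float | None = None
    p_wme: float | None = None
    p_mbe: float | None = None
    n_iv: int = 0
    direction_true: bool | None = None
    estimates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.tier is None) == (self.binary_support is None):
            raise ValueError("exactly one of tier / binary_support must be set")
        if self.tier is not None and self.exposure_type != "continuous":
            raise ValueError("tier applies to continuous exposures only")
        if self.binary_support is not None and self.exposure_type != "binary":
            raise ValueError("binary_support applies to binary exposures only")
        if self.tier is not None and self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.binary_support is not None and self.binary_support not in BINARY_LABELS:
            raise ValueError(f"unknown binary_support {self.binary_support!r}")

    @property
    def label(self) -> str:
        return self.tier if self.tier is not None else self.binary_support


@dataclass
class GradingSummary:
    """Counts and percentages per evidence label across graded associations."""

    total: int
    counts: dict
    percentages: dict
    per_outcome_robust: dict


def _as_label_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "label" not in df.columns:
            tier = df["tier"] if "tier" in df else pd.Series(index=df.index, dtype=object)
            bins = df["binary_support"] if "binary_support" in df else pd.Series(index=df.index, dtype=object)
            df["label"] = tier.where(tier.notna(), bins)
        return df
    return pd.DataFrame(
        {
            "exposure_id": [r.exposure_id for r in records],
            "outcome_id": [r.outcome_id for r in records],
            "label": [r.label for r in records],
        }
    )


def summarise_grading(records, rounding: dict | None = None) -> GradingSummary:
    """Per-label counts, rounded percentages, and per-outcome robust counts.

    ``records`` is a sequence of :class:`GradedAssociation` or a DataFrame
    with ``tier``/``binary_support`` (or ``label``) and ``outcome_id``
    columns. ``rounding`` maps label -> decimal places for its percentage
    (default 1 everywhere); percentages are ``100 * count / total``.
    """
    df = _as_label_frame(records)
    if len(df) == 0:
        raise ValueError("no graded associations to summarise")
    rounding = rounding or {}
    counts = df["label"].value_counts().to_dict()
    total = int(len(df))
    percentages = {}
    for label, c in counts.items():
        dec = int(rounding.get(label, 1))
        pct = round(100.0 * c / total, dec)
        percentages[label] = int(pct) if dec == 0 else pct
    robust = df.loc[df["label"] == "robust"]
    per_outcome = (
        robust.groupby("outcome_id").size().sort_values(ascending=False).to_dict()
        if "outcome_id" in df and len(robust)
        else {}
    )
    assert sum(counts.values()) == total
    return GradingSummary(
        total=total, counts=counts, percentages=percentages, per_outcome_robust=per_outcome
    )
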