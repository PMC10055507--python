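"""End-to-end orchestration: estimators per pair, and a full PheWAS run.

:func:`analyse_pair` runs the requested estimators on one harmonised
exposure-cancer pair and returns a tidy one-row-per-method table.
:func:`run_phewas` drives the whole chain — instrument selection,
harmonisation, estimation, Steiger directionality, and evidence grading —
over a file tree as written by :func:`mrphewas.simulate.simulate_phewas`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimators as est
from .grading import bonferroni_threshold, grade_binary, grade_continuous
from .harmonise import HarmonisedSet, harmonise
from .inference import pve_binary_outcome, pve_continuous, steiger
from .sumstats import read_sumstats, select_instruments

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw", "wme", "mbe", "egger", "wald")

_RESULT_COLUMNS = [
    "exposure_id", "outcome_id", "method", "estimate", "se", "ci_low", "ci_high",
    "pvalue", "or_sd", "n_snp", "Q", "Q_pvalue", "egger_intercept",
    "egger_intercept_se", "egger_intercept_pvalue",
]


def analyse_pair(
    hset: HarmonisedSet,
    methods=DEFAULT_METHODS,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the requested estimators on one harmonised set.

    Methods needing more instruments than available are skipped (logged).
    ``wald`` is reported for single-instrument sets only, where it is the
    primary estimate. Heterogeneity (Q) accompanies the IVW row and the
    Egger intercept its slope row.
    """
    n = len(hset)
    if n == 0:
        raise ValueError("harmonised set has no instruments")
    rows = []

    def _row(method, r: est.MRResult, **extra):
        d = {
            "exposure_id": hset.exposure_id,
            "outcome_id": hset.outcome_id,
            "method": method,
            "estimate": r.estimate,
            "se": r.se,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "pvalue": r.pvalue,
            "or_sd": r.or_sd,
            "n_snp": r.n_snp,
        }
        d.update(extra)
        rows.append(d)

    if "wald" in methods and n == 1:
        r = hset.df.iloc[0]
        _row("wald", est.wald_ratio(r["beta_exp"], r["beta_out"], r["se_out"], r["se_exp"]))
    if "ivw" in methods and n >= 2:
        r, het = est.ivw(hset)
        _row("ivw_re", r, Q=het.Q, Q_pvalue=het.pvalue)
    if "wme" in methods:
        if n >= 3:
            _row("wme", est.weighted_median(hset, n_boot=n_boot, seed=seed))
        else:
            logger.info("%s: skipping WME (<3 instruments)", hset.exposure_id)
    if "mbe" in methods:
        if n >= 3:
            _row("mbe", est.mode_based(hset, n_boot=n_boot, seed=seed + 1))
        else:
            logger.info("%s: skipping MBE (<3 instruments)", hset.exposure_id)
    if "egger" in methods and n >= 3:
        er = est.egger(hset)
        _row(
            "egger_slope", er.slope,
            egger_intercept=er.intercept,
            egger_intercept_se=er.intercept_se,
            egger_intercept_pvalue=er.intercept_pvalue,
        )
    return pd.DataFrame(rows).reindex(columns=_RESULT_COLUMNS)


@dataclass
class PheWASResult:
    """Everything a run produces: per-method results and graded pairs."""

    results: pd.DataFrame
    graded: pd.DataFrame
    robust_threshold: float


def run_phewas(
    data_dir: str | Path,
    *,
    p_max: float = 5e-8,
    maf_min: float = 0.01,
    f_min: float = 10.0,
    alpha: float = 0.05,
    n_tests: int | None = None,
    lifetime_risk: float = 0.04,
    methods=DEFAULT_METHODS,
    n_boot: int = 200,
    seed: int = 0,
    palindrome_eaf_window: float = 0.08,
) -> PheWASResult:
    """Run the full MR-PheWAS chain over a simulated (or equivalent) file tree.

    ``data_dir`` must hold ``exposures/<trait>.tsv``, ``outcomes/<trait>.tsv``
    and a ``truth.tsv`` manifest with ``trait_id``, ``exposure_type``,
    ``n_cases``, ``n_controls`` columns. The robust tier threshold is
    ``alpha / n_tests``; ``n_tests`` defaults to the number of continuous
    traits in the run. Record counts are conserved: every manifest trait
    appears exactly once in the graded table (traits with no surviving
    instruments are graded from nothing and reported as such).
    """
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "truth.tsv", sep="\t")
    n_cont = int((manifest["exposure_type"] == "continuous").sum())
    robust_thr = bonferroni_threshold(alpha, n_tests if n_tests is not None else max(1, n_cont))

    all_results, graded_rows = [], []
    for i, m in manifest.iterrows():
        label = m["trait_id"]
        exposure = read_sumstats(
            data_dir / "exposures" / f"{label}.tsv",
            trait_type=m["exposure_type"], trait_id=label,
        )
        outcome = read_sumstats(
            data_dir / "outcomes" / f"{label}.tsv", trait_type="binary",
        )
        instruments = select_instruments(exposure, p_max=p_max, maf_min=maf_min, f_min=f_min)
        base = {"exposure_id": label, "outcome_id": outcome.trait_id,
                "exposure_type": m["exposure_type"]}
        if len(instruments) == 0:
            graded_rows.append({**base, "tier": None, "binary_support": None,
                                "n_iv": 0, "direction_true": None, "note": "no_instruments"})
            continue
        hset = harmonise(
            instruments, outcome, palindrome_eaf_window,
            n_cases=float(m["n_cases"]), n_controls=float(m["n_controls"]),
            lifetime_risk=lifetime_risk,
        )
        if len(hset) == 0:
            graded_rows.append({**base, "tier": None, "binary_support": None,
                                "n_iv": 0, "direction_true": None, "note": "no_harmonised"})
            continue
        res = analyse_pair(hset, methods=methods, n_boot=n_boot, seed=seed + int(i))
        all_results.append(res)

        def _p(method):
            sel = res.loc[res["method"] == method, "pvalue"]
            return float(sel.iloc[0]) if len(sel) else None

        n_iv = len(hset)
        p_primary = _p("ivw_re") if n_iv > 1 else _p("wald")
        direction = None
        if m["exposure_type"] == "continuous":
            pve_x = pve_continuous(
                hset.df.rename(columns={"eaf_exp": "eaf", "beta_exp": "beta"})
            )
            pve_y = pve_binary_outcome(hset)
            st = steiger(pve_x, hset.n_exp, pve_y, hset.n_cases + hset.n_controls)
            direction = st.direction_true
            tier = grade_continuous(
                p_ivw=_p("ivw_re"), p_wald=_p("wald"), p_wme=_p("wme"), p_mbe=_p("mbe"),
                direction_true=direction, n_iv=n_iv, robust_threshold=robust_thr,
            )
            graded_rows.append({**base, "tier": tier, "binary_support": None,
                                "n_iv": n_iv, "direction_true": direction, "note": ""})
        else:
            support = grade_binary(p_primary)
            graded_rows.append({**base, "tier": None, "binary_support": support,
                                "n_iv": n_iv, "direction_true": None, "note": ""})

    results = (
        pd.concat(all_results, ignore_index=True)
        if all_results
        else pd.DataFrame(columns=_RESULT_COLUMNS)
    )
    graded = pd.DataFrame(graded_rows)
    assert len(graded) == len(manifest), "row conservation violated"
    logger.info("run_phewas: %d traits in, %d graded, %d result rows",
                len(manifest), len(graded), len(results))
    return PheWASResult(results=results, graded=graded, robust_threshold=robust_thr)
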