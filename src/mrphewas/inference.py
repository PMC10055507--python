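"""Directionality (Steiger) and a-priori power, via variance explained.

The Steiger test asks whether the instruments explain more variance in the
exposure than in the outcome — the pattern expected when causation runs
exposure -> outcome rather than the reverse. For a binary (case-control)
outcome the log-OR effects are first converted to the liability scale using
the population lifetime risk K, so that the two R^2 values are comparable.

Power uses the standard normal-approximation for a two-sample MR test of a
binary outcome: the non-centrality is
``log(OR_sd) * sqrt(N * R^2 * phi * (1 - phi))`` with ``phi`` the case
fraction, i.e. the Wald z expected at the hypothesised effect given the
asymptotic variance of the IVW estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonise import HarmonisedSet
from .sumstats import InstrumentSet


@dataclass
class SteigerResult:
    """Direction-of-causality assessment from instrument R^2 on each trait."""

    pve_exposure: float
    pve_outcome: float
    direction_true: bool
    pvalue: float


@dataclass
class PowerEstimate:
    """A-priori power of the MR test at a hypothesised OR per SD."""

    alpha: float
    power: float
    n_cases: float
    n_controls: float
    pve: float
    or_sd: float


def _eaf_beta(obj) -> pd.DataFrame:
    if isinstance(obj, InstrumentSet):
        return obj.df
    return obj


def pve_continuous(instruments) -> float:
    """Proportion of trait variance explained by the instruments.

    For a trait in SD units, each biallelic variant with effect-allele
    frequency p and per-allele effect beta contributes ``2 p (1 - p) beta^2``;
    contributions sum under linkage equilibrium and the total is capped at 1.
    Accepts an :class:`InstrumentSet` or a DataFrame with ``eaf`` and
    ``beta`` columns. Missing eaf is an error naming the offending variants.
    """
    df = _eaf_beta(instruments)
    if len(df) == 0:
        return 0.0
    missing = df["eaf"].isna()
    if missing.any():
        ids = df.loc[missing, "variant_id"].tolist() if "variant_id" in df else list(df.index[missing])
        raise ValueError(f"missing eaf for variants: {ids[:5]}")
    p = df["eaf"].to_numpy(float)
    b = df["beta"].to_numpy(float)
    return float(min(1.0, np.sum(2 * p * (1 - p) * b**2)))


def pve_binary_outcome(
    hset: HarmonisedSet,
    lifetime_risk: float | None = None,
    *,
    method: str = "liability",
) -> float:
    """Liability-scale variance in a binary outcome explained by instruments.

    Each per-allele log-OR is converted to a liability-scale effect and the
    per-variant contributions ``2 p (1 - p) b_liab^2`` summed (capped at 1).
    The default ``"liability"`` conversion uses the population lifetime risk
    K: the log-OR approximates a risk difference ``b K (1 - K)`` which maps
    to the liability scale on division by the normal density at the
    threshold ``Phi^{-1}(1 - K)``. The ``"probit"`` flag instead treats
    ``b * sqrt(3) / pi`` (log-odds rescaled by the logistic SD) as the
    liability coefficient directly, ignoring K.
    """
    K = lifetime_risk if lifetime_risk is not None else hset.lifetime_risk
    if K is None or not (0 < K < 1):
        raise ValueError("lifetime_risk K must be in (0, 1)")
    df = hset.df
    if len(df) == 0:
        return 0.0
    missing = df["eaf_out"].isna()
    if missing.any():
        ids = df.loc[missing, "variant_id"].tolist()
        raise ValueError(f"missing eaf_out for variants: {ids[:5]}")
    p = df["eaf_out"].to_numpy(float)
    b = df["beta_out"].to_numpy(float)
    if method == "liability":
        t = stats.norm.ppf(1 - K)
        b_liab = b * K * (1 - K) / stats.norm.pdf(t)
    elif method == "probit":
        b_liab = b * np.sqrt(3) / np.pi
    else:
        raise ValueError("method must be 'liability' or 'probit'")
    return float(min(1.0, np.sum(2 * p * (1 - p) * b_liab**2)))


def steiger(pve_x: float, n_x: float, pve_y: float, n_y: float) -> SteigerResult:
    """Steiger directionality test comparing instrument R^2 on two traits.

    The square roots of the R^2 values are Fisher z-transformed and compared
    with a two-sample z test using variances ``1 / (n - 3)``.
    ``direction_true`` is the claim that causation runs x -> y, i.e.
    ``pve_x > pve_y``; equal R^2 gives p = 1 (direction indeterminate).
    """
    for name, v in (("pve_x", pve_x), ("pve_y", pve_y)):
        if not (0 <= v < 1):
            raise ValueError(f"{name} must be in [0, 1)")
    for name, v in (("n_x", n_x), ("n_y", n_y)):
        if v < 10:
            raise ValueError(f"{name} must be >= 10")
    zx = np.arctanh(np.sqrt(pve_x))
    zy = np.arctanh(np.sqrt(pve_y))
    z = (zx - zy) / np.sqrt(1.0 / (n_x - 3) + 1.0 / (n_y - 3))
    return SteigerResult(
        pve_exposure=float(pve_x),
        pve_outcome=float(pve_y),
        direction_true=bool(pve_x > pve_y),
        pvalue=float(2 * stats.norm.sf(abs(z))),
    )


def power(
    alpha: float,
    n_cases: float,
    n_controls: float,
    pve: float,
    or_sd: float,
) -> PowerEstimate:
    """A-priori power of a two-sample MR test for a binary outcome.

    Non-centrality ``ncp = log(or_sd) * sqrt(N * pve * phi * (1 - phi))``
    (``phi`` = case fraction, ``N * phi * (1 - phi)`` = case/control
    harmonic mean), with
    ``power = Phi(ncp - z_{1-a/2}) + Phi(-ncp - z_{1-a/2})``.
    At ``or_sd = 1`` power equals ``alpha`` exactly, and power is symmetric
    in ``log(or_sd)``; ``pve = 0`` returns ``alpha`` with a warning.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be > 0")
    if not (0 <= pve < 1):
        raise ValueError("pve must be in [0, 1)")
    if or_sd <= 0:
        raise ValueError("or_sd must be > 0")
    if pve == 0:
        warnings.warn("pve = 0: power equals the test size", stacklevel=2)
        return PowerEstimate(alpha, float(alpha), n_cases, n_controls, pve, or_sd)

    N = n_cases + n_controls
    phi = n_cases / N
    ncp = np.log(or_sd) * np.sqrt(N * pve * phi * (1 - phi))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    pw = float(stats.norm.cdf(ncp - zcrit) + stats.norm.cdf(-ncp - zcrit))
    return PowerEstimate(alpha, pw, n_cases, n_controls, pve, or_sd)


def power_curve(
    alpha: float,
    n_cases: float,
    n_controls: float,
    pve: float,
    or_grid,
) -> pd.DataFrame:
    """Power across a grid of hypothesised ORs (one row per OR)."""
    rows = [power(alpha, n_cases, n_controls, pve, float(r)) for r in or_grid]
    return pd.DataFrame(
        {"or_sd": [r.or_sd for r in rows], "power": [r.power for r in rows],
         "alpha": alpha, "n_cases": n_cases, "n_controls": n_controls, "pve": pve}
    )
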