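"""Two-sample MR causal-effect estimators and sensitivity diagnostics.

All estimators consume a :class:`~mrphewas.harmonise.HarmonisedSet` whose
exposure effects are in SD units and outcome effects are log odds ratios, so
every estimate is a causal log-OR per SD of exposure (``or_sd = exp(estimate)``
is the odds ratio per SD).

Estimators
----------
* :func:`wald_ratio` — single-instrument ratio estimate.
* :func:`ivw` — inverse-variance-weighted regression through the origin,
  with multiplicative random-effects overdispersion (primary estimator).
* :func:`weighted_median` — consistent when >= 50% of instrument weight
  comes from valid instruments; bootstrap SE.
* :func:`mode_based` — mode of the kernel-smoothed ratio density; consistent
  when the largest group of instruments sharing a ratio is valid.
* :func:`egger` — regression with a free intercept; a non-zero intercept is
  evidence of directional pleiotropy.
* :func:`leave_one_out` — IVW refits omitting each instrument in turn.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .harmonise import HarmonisedSet

logger = logging.getLogger(__name__)

#: Normal CI multiplier used by wald/ivw/wme/mbe intervals.
CI_MULT = 1.96


@dataclass
class MRResult:
    """One estimator's causal estimate with uncertainty.

    ``estimate`` is the causal log-OR per SD of exposure; ``or_sd`` its
    exponential. ``fallback`` marks results produced by a degenerate-input
    fallback (e.g. IVW with a single instrument reduces to the Wald ratio).
    """

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    fallback: bool = False

    @property
    def or_sd(self) -> float:
        return float(np.exp(self.estimate))

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


@dataclass
class HeterogeneityResult:
    """Cochran's Q heterogeneity statistic across instrument ratios."""

    Q: float
    df: int
    pvalue: float


@dataclass
class EggerResult:
    """MR-Egger slope (causal estimate) and intercept (pleiotropy test)."""

    slope: MRResult
    intercept: float
    intercept_se: float
    intercept_pvalue: float


@dataclass
class LeaveOneOutResult:
    """Per-instrument-omitted IVW refits plus the largest estimate shift."""

    results: "object"  # pandas.DataFrame: dropped, estimate, se, pvalue, n_snp
    full: MRResult
    max_shift: float
    max_shift_variant: str


def _norm_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def _arrays(hset: HarmonisedSet):
    df = hset.df
    return (
        df["beta_exp"].to_numpy(float),
        df["se_exp"].to_numpy(float),
        df["beta_out"].to_numpy(float),
        df["se_out"].to_numpy(float),
    )


def wald_ratio(
    beta_exp: float,
    beta_out: float,
    se_out: float,
    se_exp: float = 0.0,
    *,
    second_order: bool = False,
) -> MRResult:
    """Single-instrument Wald ratio ``beta_out / beta_exp``.

    The default standard error is the first-order delta approximation
    ``se_out / |beta_exp|``; ``second_order`` adds the exposure-uncertainty
    term ``beta_out^2 se_exp^2 / beta_exp^4``.
    """
    if beta_exp == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    if se_out <= 0:
        raise ValueError("se_out must be > 0")
    est = beta_out / beta_exp
    var = se_out**2 / beta_exp**2
    if second_order:
        var += beta_out**2 * se_exp**2 / beta_exp**4
    se = float(np.sqrt(var))
    return MRResult(
        method="wald",
        estimate=float(est),
        se=se,
        ci_low=float(est - CI_MULT * se),
        ci_high=float(est + CI_MULT * se),
        pvalue=_norm_p(est / se),
        n_snp=1,
    )


def ivw(
    hset: HarmonisedSet,
    *,
    random_effects: bool = True,
    method: str = "multiplicative",
) -> tuple[MRResult, HeterogeneityResult]:
    """Inverse-variance-weighted estimate with random-effects allowance.

    Weighted regression of outcome on exposure effects through the origin
    with weights ``1 / se_out^2``. Heterogeneity is Cochran's Q on
    ``n - 1`` df. Under the default multiplicative random-effects model the
    standard error is inflated by ``sqrt(max(1, Q / (n - 1)))``; the additive
    variant applies a DerSimonian–Laird tau^2 to the per-instrument ratio
    variances. With one instrument the function falls back to the Wald ratio
    (flagged); it errors on an empty set.
    """
    bx, sx, by, so = _arrays(hset)
    n = len(bx)
    if n == 0:
        raise ValueError("no instruments")
    if n == 1:
        logger.warning("%s vs %s: single instrument, falling back to Wald ratio",
                       hset.exposure_id, hset.outcome_id)
        res = wald_ratio(bx[0], by[0], so[0], sx[0])
        res.fallback = True
        return res, HeterogeneityResult(Q=0.0, df=0, pvalue=float("nan"))
    if method not in ("multiplicative", "additive"):
        raise ValueError("method must be 'multiplicative' or 'additive'")

    w = 1.0 / so**2
    sw_xx = float(np.sum(w * bx * bx))
    est = float(np.sum(w * bx * by) / sw_xx)
    Q = float(np.sum(w * (by - est * bx) ** 2))
    df = n - 1
    q_p = float(stats.chi2.sf(Q, df))

    if method == "additive" and random_effects:
        # DL estimate on the per-instrument Wald ratios.
        ratios = by / bx
        vr = so**2 / bx**2
        wr = 1.0 / vr
        s1, s2 = float(wr.sum()), float((wr**2).sum())
        tau2 = max(0.0, (Q - df) / (s1 - s2 / s1))
        w_star = 1.0 / (vr + tau2)
        est = float(np.sum(w_star * ratios) / w_star.sum())
        se = float(np.sqrt(1.0 / w_star.sum()))
    else:
        se = float(np.sqrt(1.0 / sw_xx))
        if random_effects:
            se *= float(np.sqrt(max(1.0, Q / df)))

    result = MRResult(
        method="ivw_re" if random_effects else "ivw_fe",
        estimate=est,
        se=se,
        ci_low=est - CI_MULT * se,
        ci_high=est + CI_MULT * se,
        pvalue=_norm_p(est / se),
        n_snp=n,
    )
    return result, HeterogeneityResult(Q=Q, df=df, pvalue=q_p)


def _wme_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(hset: HarmonisedSet, n_boot: int = 1000, seed: int | None = None) -> MRResult:
    """Weighted-median estimate (WME) with parametric-bootstrap SE.

    Per-instrument Wald ratios are ordered and weighted by the inverse of
    their first-order variances; the estimate is the ratio at cumulative
    weight 0.5 (linear interpolation). The SE is the standard deviation of
    the estimate over ``n_boot`` parametric resamples of
    ``(beta_exp, beta_out)`` from their sampling normals; ``seed`` is
    mandatory for reproducibility.
    """
    if seed is None:
        raise ValueError("seed is required for the bootstrap")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives an unstable bootstrap SE", stacklevel=2)
    bx, sx, by, so = _arrays(hset)
    n = len(bx)
    if n < 3:
        raise ValueError("weighted median requires >= 3 instruments")

    weights = bx**2 / so**2  # inverse first-order ratio variance
    est = _wme_point(by / bx, weights)

    rng = np.random.default_rng(seed)
    bxs = bx + sx * rng.standard_normal((n_boot, n))
    bys = by + so * rng.standard_normal((n_boot, n))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _wme_point(bys[i] / bxs[i], bxs[i] ** 2 / so**2)
    se = float(np.std(boots, ddof=1))

    return MRResult(
        method="wme",
        estimate=est,
        se=se,
        ci_low=est - CI_MULT * se,
        ci_high=est + CI_MULT * se,
        pvalue=_norm_p(est / se) if se > 0 else 1.0 if est == 0 else 0.0,
        n_snp=n,
    )


def _mbe_point(ratios: np.ndarray, weights: np.ndarray, phi: float, grid_size: int) -> float:
    """Argmax of the weighted normal-kernel density over Wald ratios.

    Bandwidth is ``phi`` times the modified Silverman rule
    ``0.9 min(sd, normalised MAD) n^(-1/5)`` over the ratio dispersion.
    Degenerate zero dispersion returns the common ratio.
    """
    n = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if n > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    candidates = [s for s in (sd, mad) if s > 0]
    if not candidates:
        return float(ratios[0])
    h = phi * 0.9 * min(candidates) * n ** (-0.2)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_size)
    dens = (weights[None, :] * stats.norm.pdf((grid[:, None] - ratios[None, :]) / h)).sum(axis=1) / h
    return float(grid[int(np.argmax(dens))])


def mode_based(
    hset: HarmonisedSet,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    weighted: bool = False,
    grid_size: int = 512,
) -> MRResult:
    """Mode-based estimate (MBE): mode of the smoothed Wald-ratio density.

    The default is the simple mode (equal instrument weights);
    ``weighted=True`` uses inverse-variance weights. ``phi`` multiplies the
    bandwidth. The point estimate is deterministic (a fixed density grid);
    only the bootstrap SE depends on ``seed``, which is mandatory.
    """
    if seed is None:
        raise ValueError("seed is required for the bootstrap")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives an unstable bootstrap SE", stacklevel=2)
    bx, sx, by, so = _arrays(hset)
    n = len(bx)
    if n < 3:
        raise ValueError("mode-based estimate requires >= 3 instruments")

    def _weights(b):
        return b**2 / so**2 if weighted else np.full(n, 1.0 / n)

    est = _mbe_point(by / bx, _weights(bx), phi, grid_size)

    rng = np.random.default_rng(seed)
    bxs = bx + sx * rng.standard_normal((n_boot, n))
    bys = by + so * rng.standard_normal((n_boot, n))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _mbe_point(bys[i] / bxs[i], _weights(bxs[i]), phi, grid_size)
    se = float(np.std(boots, ddof=1))

    return MRResult(
        method="mbe",
        estimate=est,
        se=se,
        ci_low=est - CI_MULT * se,
        ci_high=est + CI_MULT * se,
        pvalue=_norm_p(est / se) if se > 0 else 1.0 if est == 0 else 0.0,
        n_snp=n,
    )


def egger(hset: HarmonisedSet) -> EggerResult:
    """MR-Egger regression: slope = causal estimate, intercept = pleiotropy.

    Instruments are re-oriented so all exposure effects are non-negative,
    then outcome effects are regressed on exposure effects with a free
    intercept and weights ``1 / se_out^2``. Standard errors carry the same
    multiplicative overdispersion factor as IVW (never deflated below the
    fixed-effect SE); p-values and CIs use t on ``n - 2`` df, appropriate for
    small instrument counts.
    """
    bx, sx, by, so = _arrays(hset)
    n = len(bx)
    if n < 3:
        raise ValueError("MR-Egger requires >= 3 instruments")

    sign = np.where(bx < 0, -1.0, 1.0)
    bxo, byo = bx * sign, by * sign
    res = sm.WLS(byo, sm.add_constant(bxo), weights=1.0 / so**2).fit()

    # statsmodels scales bse by the residual scale; recompute the unit-scale
    # SEs from the normal equations and re-apply the scale floored at 1 so
    # heterogeneity can only widen the interval (noiseless data gives
    # scale ~ 0, where dividing bse by sqrt(scale) would blow up).
    scale = float(res.scale)
    infl = np.sqrt(max(1.0, scale))
    w = 1.0 / so**2
    xtwx = np.array(
        [[w.sum(), np.sum(w * bxo)], [np.sum(w * bxo), np.sum(w * bxo**2)]]
    )
    se_unit = np.sqrt(np.diag(np.linalg.inv(xtwx)))
    se_int, se_slope = float(se_unit[0] * infl), float(se_unit[1] * infl)
    b_int, b_slope = float(res.params[0]), float(res.params[1])
    tdist = stats.t(df=n - 2)
    tcrit = float(tdist.ppf(0.975))

    def _tp(z):
        return float(2 * tdist.sf(abs(z))) if np.isfinite(z) else 1.0

    slope = MRResult(
        method="egger_slope",
        estimate=b_slope,
        se=se_slope,
        ci_low=b_slope - tcrit * se_slope,
        ci_high=b_slope + tcrit * se_slope,
        pvalue=_tp(b_slope / se_slope) if se_slope > 0 else (1.0 if b_slope == 0 else 0.0),
        n_snp=n,
    )
    return EggerResult(
        slope=slope,
        intercept=b_int,
        intercept_se=se_int,
        intercept_pvalue=_tp(b_int / se_int) if se_int > 0 else (1.0 if b_int == 0 else 0.0),
    )


def leave_one_out(hset: HarmonisedSet) -> LeaveOneOutResult:
    """IVW refit omitting each instrument in turn.

    Flags the instrument whose omission shifts the estimate most — a simple
    screen for single outlying or pleiotropic variants driving the result.
    """
    import pandas as pd

    bx, sx, by, so = _arrays(hset)
    n = len(bx)
    if n < 3:
        raise ValueError("leave-one-out requires >= 3 instruments")
    full, _ = ivw(hset)

    rows = []
    for i in range(n):
        mask = np.arange(n) != i
        sub = HarmonisedSet.from_arrays(
            bx[mask], sx[mask], by[mask], so[mask],
            exposure_id=hset.exposure_id, outcome_id=hset.outcome_id,
            variant_ids=hset.df["variant_id"].to_numpy()[mask],
        )
        res, _ = ivw(sub)
        rows.append(
            {
                "dropped": hset.df["variant_id"].iloc[i],
                "estimate": res.estimate,
                "se": res.se,
                "pvalue": res.pvalue,
                "n_snp": res.n_snp,
            }
        )
    results = pd.DataFrame(rows)
    shifts = (results["estimate"] - full.estimate).abs()
    imax = int(shifts.idxmax())
    return LeaveOneOutResult(
        results=results,
        full=full,
        max_shift=float(shifts.iloc[imax]),
        max_shift_variant=str(results["dropped"].iloc[imax]),
    )
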