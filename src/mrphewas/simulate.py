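"""Synthetic two-sample GWAS summary statistics and literature-triple fixtures.

Statistics are generated directly at the summary level under the standard
two-sample MR generative model: independent biallelic instruments with
effect-allele frequencies p, true per-allele exposure effects b (SD units),
and true outcome effects ``beta_causal * b + alpha`` where ``alpha`` is a
per-variant pleiotropic effect (zero for valid instruments, drawn from a
balanced or directional normal for the invalid fraction). Observed effects
add sampling noise with the asymptotic standard errors

* exposure (continuous, SD units): ``se = 1 / sqrt(2 p (1 - p) n_exp)``
* outcome (case-control log-OR):  ``se = 1 / sqrt(2 p (1 - p) N phi (1 - phi))``

with ``phi`` the case fraction — the same formulas the power module inverts,
so a-priori power predictions and empirical rejection rates close the loop.
Instruments are independent, consistent with post-LD-pruning data.

Default sizes mirror a large-biobank exposure GWAS (n = 300,000) paired
with the colorectal-cancer GWAS of the study design (73,673 cases /
86,854 controls); default per-SNP effects (normal, sd 0.05) give 30
instruments a total PVE of ~3%, matching the median instrument strength
reported for real trait panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .litspace import TripleSet, triple_set, write_triples
from .sumstats import CANONICAL_COLUMNS, SummaryStatTable, write_sumstats

_P_FLOOR = 1e-320  # keep p-values in (0, 1] under extreme z

_PREDICATES = ("stimulates", "inhibits", "associated_with", "affects", "predisposes")


@dataclass
class PleiotropyConfig:
    """Direct instrument-outcome effects violating the exclusion restriction.

    ``mode``: ``"none"``, ``"balanced"`` (mean-zero alpha) or
    ``"directional"`` (mean ``mean``); ``fraction_invalid`` is the share of
    instruments receiving a pleiotropic effect.
    """

    mode: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    fraction_invalid: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.mode!r}")
        if not (0 <= self.fraction_invalid <= 1):
            raise ValueError("fraction_invalid must be in [0, 1]")
        if self.mode == "balanced" and self.mean != 0:
            raise ValueError("balanced pleiotropy must have mean 0")


@dataclass
class SimConfig:
    """Conditions of one simulated exposure-cancer analysis (seed mandatory)."""

    seed: int
    n_instruments: int = 30
    beta_causal: float = 0.0
    exposure_effect_dist: dict = field(
        default_factory=lambda: {"name": "normal", "mean": 0.0, "sd": 0.05}
    )
    eaf_dist: dict = field(default_factory=lambda: {"name": "uniform", "low": 0.05, "high": 0.5})
    n_exposure: int = 300_000
    n_cases: int = 73_673
    n_controls: int = 86_854
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    exposure_type: str = "continuous"

    def __post_init__(self) -> None:
        if isinstance(self.pleiotropy, Mapping):
            self.pleiotropy = PleiotropyConfig(**self.pleiotropy)
        for name in ("n_instruments", "n_exposure", "n_cases", "n_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.exposure_type not in ("continuous", "binary"):
            raise ValueError("exposure_type must be 'continuous' or 'binary'")


@dataclass
class SimTruth:
    """Generative ground truth backing one simulated dataset."""

    beta_causal: float
    beta_exp: np.ndarray
    pleiotropy: np.ndarray
    eaf: np.ndarray
    pve_exposure: float
    variant_ids: list


def _draw(spec: Mapping, size: int, rng: np.random.Generator) -> np.ndarray:
    name = spec.get("name", "normal")
    if name == "normal":
        return rng.normal(spec.get("mean", 0.0), spec["sd"], size)
    if name == "uniform":
        return rng.uniform(spec["low"], spec["high"], size)
    if name == "fixed":
        return np.full(size, float(spec["value"]))
    raise ValueError(f"unknown distribution {name!r}")


def draw_truth(config: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Draw the latent truth (frequencies, true effects, pleiotropy)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_instruments
    eaf = np.clip(_draw(config.eaf_dist, n, rng), 0.01, 0.99)
    beta = _draw(config.exposure_effect_dist, n, rng)
    alpha = np.zeros(n)
    pl = config.pleiotropy
    if pl.mode != "none" and pl.fraction_invalid > 0:
        n_invalid = int(round(pl.fraction_invalid * n))
        idx = rng.choice(n, size=n_invalid, replace=False)
        alpha[idx] = rng.normal(pl.mean, pl.sd, n_invalid)
    pve = float(np.sum(2 * eaf * (1 - eaf) * beta**2))
    return SimTruth(
        beta_causal=config.beta_causal,
        beta_exp=beta,
        pleiotropy=alpha,
        eaf=eaf,
        pve_exposure=pve,
        variant_ids=[f"rs{i + 1:06d}" for i in range(n)],
    )


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2 * stats.norm.sf(np.abs(beta / se)), _P_FLOOR)


def sample_tables(
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    trait_id: str = "sim_exposure",
    outcome_id: str = "sim_cancer",
) -> tuple[SummaryStatTable, SummaryStatTable]:
    """Add sampling noise to a fixed truth and emit exposure/outcome tables.

    Separating this from :func:`draw_truth` lets callers re-noise the same
    latent truth repeatedly (e.g. to measure empirical power conditional on
    an instrument panel).
    """
    p = truth.eaf
    var_g = 2 * p * (1 - p)
    se_exp = 1.0 / np.sqrt(var_g * config.n_exposure)
    beta_exp_hat = truth.beta_exp + se_exp * rng.standard_normal(len(p))

    N = config.n_cases + config.n_controls
    phi = config.n_cases / N
    se_out = 1.0 / np.sqrt(var_g * N * phi * (1 - phi))
    beta_out_true = truth.beta_causal * truth.beta_exp + truth.pleiotropy
    beta_out_hat = beta_out_true + se_out * rng.standard_normal(len(p))

    base = {
        "variant_id": truth.variant_ids,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": p,
    }
    exp_df = pd.DataFrame(
        {**base, "beta": beta_exp_hat, "se": se_exp,
         "pvalue": _pvalues(beta_exp_hat, se_exp), "n": float(config.n_exposure)}
    )[CANONICAL_COLUMNS]
    out_df = pd.DataFrame(
        {**base, "beta": beta_out_hat, "se": se_out,
         "pvalue": _pvalues(beta_out_hat, se_out), "n": float(N)}
    )[CANONICAL_COLUMNS]
    exposure = SummaryStatTable(
        trait_id=trait_id, trait_type=config.exposure_type, df=exp_df, provenance="simulated"
    )
    outcome = SummaryStatTable(
        trait_id=outcome_id, trait_type="binary", df=out_df, provenance="simulated"
    )
    return exposure, outcome


def simulate_two_sample(
    config: SimConfig,
    *,
    trait_id: str = "sim_exposure",
    outcome_id: str = "sim_cancer",
) -> tuple[SummaryStatTable, SummaryStatTable, SimTruth]:
    """Generate one exposure/outcome summary-statistic pair plus its truth.

    Fully reproducible: the same config (including seed) yields identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    truth = draw_truth(config, rng)
    exposure, outcome = sample_tables(truth, config, rng, trait_id=trait_id, outcome_id=outcome_id)
    return exposure, outcome, truth


def simulate_phewas(configs: Mapping[str, SimConfig], out_dir: str | Path) -> pd.DataFrame:
    """Write a pipeline-ready file tree for a batch of simulated traits.

    ``configs`` maps trait label -> :class:`SimConfig`. Produces
    ``exposures/<label>.tsv`` and ``outcomes/<label>.tsv`` under ``out_dir``
    plus a ``truth.tsv`` manifest (one row per trait with the generative
    effect and instrument strength); returns the manifest.
    """
    if len(configs) == 0:
        raise ValueError("empty simulation batch")
    labels = list(configs)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate trait labels")
    out_dir = Path(out_dir)
    (out_dir / "exposures").mkdir(parents=True, exist_ok=True)
    (out_dir / "outcomes").mkdir(parents=True, exist_ok=True)

    rows = []
    for label, cfg in configs.items():
        exposure, outcome, truth = simulate_two_sample(cfg, trait_id=label)
        write_sumstats(exposure, out_dir / "exposures" / f"{label}.tsv")
        write_sumstats(outcome, out_dir / "outcomes" / f"{label}.tsv")
        rows.append(
            {
                "trait_id": label,
                "exposure_type": cfg.exposure_type,
                "beta_causal": truth.beta_causal,
                "n_instruments": cfg.n_instruments,
                "pve_exposure": truth.pve_exposure,
                "n_exposure": cfg.n_exposure,
                "n_cases": cfg.n_cases,
                "n_controls": cfg.n_controls,
                "fraction_invalid": cfg.pleiotropy.fraction_invalid,
                "seed": cfg.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return manifest


def simulate_triples(
    n_exposure_triples: int,
    n_cancer_triples: int,
    n_shared_mediators: int,
    seed: int,
    *,
    exposure_term: str = "igf-1",
    cancer_term: str = "colorectal cancer",
    out_dir: str | Path | None = None,
) -> tuple[TripleSet, TripleSet]:
    """Construct two literature spaces sharing an exact number of mediators.

    The shared terms form directed chains exposure -> mediator -> cancer;
    filler triples use disjoint term namespaces so the directed overlap is
    exactly ``n_shared_mediators``. With ``out_dir`` set, the two spaces are
    also written as ``<exposure>.tsv`` / ``<cancer>.tsv``.
    """
    for name, v in (
        ("n_exposure_triples", n_exposure_triples),
        ("n_cancer_triples", n_cancer_triples),
        ("n_shared_mediators", n_shared_mediators),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if n_shared_mediators > min(n_exposure_triples, n_cancer_triples):
        raise ValueError("n_shared_mediators cannot exceed either space size")

    rng = np.random.default_rng(seed)

    def _pred():
        return _PREDICATES[rng.integers(len(_PREDICATES))]

    mediators = [f"mediator {i + 1}" for i in range(n_shared_mediators)]
    exp_rows = [(exposure_term, _pred(), m) for m in mediators]
    exp_rows += [
        (exposure_term, _pred(), f"exposure pathway {j + 1}")
        for j in range(n_exposure_triples - n_shared_mediators)
    ]
    can_rows = [(m, _pred(), cancer_term) for m in mediators]
    can_rows += [
        (f"cancer pathway {j + 1}", _pred(), cancer_term)
        for j in range(n_cancer_triples - n_shared_mediators)
    ]
    exposure_space = triple_set(exp_rows, anchor=exposure_term)
    cancer_space = triple_set(can_rows, anchor=cancer_term)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_triples(exposure_space, out_dir / "exposure_triples.tsv")
        write_triples(cancer_space, out_dir / "cancer_triples.tsv")
    return exposure_space, cancer_space


def config_to_dict(config: SimConfig) -> dict:
    """Plain-dict form of a config (YAML-friendly)."""
    return asdict(config)
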