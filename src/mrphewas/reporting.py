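"""Results assembly: Z-statistic matrix, clustering, and app-table export.

The Z matrix mirrors the familiar PheWAS heatmap: rows are exposure traits
with at least one suggestive-or-better (or supported) association, columns
are cancer outcomes, and cells hold the signed Z statistic
(estimate / se) of the primary estimator. Rows/columns are ordered by
hierarchical agglomerative clustering (Euclidean distance, complete
linkage — the defaults of the R ``pheatmap`` heatmap tool).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

#: Labels counting as "showing an association" for matrix inclusion.
SIGNIFICANT_LABELS = ("robust", "probable", "suggestive", "supported")

#: Cap applied to -log10(p) in exports, for numeric stability downstream.
NEG_LOG10_P_CAP = 300.0

APP_TABLE_COLUMNS = [
    "exposure_id", "outcome_id", "method", "estimate", "se", "or_sd",
    "or_ci_low", "or_ci_high", "pvalue", "neg_log10_p", "n_snp", "label",
]

APP_TABLE_SCHEMA_VERSION = "1.0"


@dataclass
class ResultsMatrix:
    """Signed Z statistics (rows: traits, cols: outcomes) with tier labels."""

    z: pd.DataFrame
    tiers: pd.DataFrame


@dataclass
class ClusterResult:
    """Row/column leaf orderings plus the linkage matrices behind them."""

    row_order: list
    col_order: list
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def _primary_rows(results: pd.DataFrame) -> pd.DataFrame:
    """One row per pair: the IVW result where present, else Wald."""
    primary = results.loc[results["method"].isin(["ivw_re", "wald"])].copy()
    primary["_rank"] = (primary["method"] == "wald").astype(int)
    primary = primary.sort_values("_rank").drop_duplicates(
        subset=["exposure_id", "outcome_id"], keep="first"
    )
    return primary.drop(columns="_rank")


def _labels(graded: pd.DataFrame) -> pd.Series:
    tier = graded["tier"] if "tier" in graded else pd.Series(index=graded.index, dtype=object)
    bins = (
        graded["binary_support"]
        if "binary_support" in graded
        else pd.Series(index=graded.index, dtype=object)
    )
    return tier.where(tier.notna(), bins)


def build_zmatrix(results: pd.DataFrame, graded: pd.DataFrame) -> ResultsMatrix:
    """Assemble the trait x outcome Z matrix from per-method results.

    Only traits with at least one suggestive-or-better (or supported)
    association anywhere are kept as rows; cells without a result stay
    missing. Z is ``estimate / se`` of the primary (IVW-RE, else Wald)
    result, so its sign always matches the estimate's.
    """
    graded = graded.copy()
    graded["label"] = _labels(graded)
    keep = graded.loc[graded["label"].isin(SIGNIFICANT_LABELS), "exposure_id"].unique()
    primary = _primary_rows(results)
    primary = primary.loc[primary["exposure_id"].isin(keep)].copy()
    primary["z"] = primary["estimate"] / primary["se"]
    z = primary.pivot(index="exposure_id", columns="outcome_id", values="z").sort_index()
    lab = graded.loc[graded["exposure_id"].isin(keep)]
    tiers = (
        lab.pivot(index="exposure_id", columns="outcome_id", values="label")
        .reindex(index=z.index, columns=z.columns)
    )
    return ResultsMatrix(z=z, tiers=tiers)


def _pairwise_complete_dist(x: np.ndarray) -> np.ndarray:
    """Euclidean distance over shared non-missing dims, rescaled to p dims."""
    n, p = x.shape
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(x[i]) & np.isfinite(x[j])
            if not ok.any():
                d[i, j] = d[j, i] = np.nan
                continue
            ss = np.sum((x[i, ok] - x[j, ok]) ** 2) * (p / ok.sum())
            d[i, j] = d[j, i] = np.sqrt(ss)
    if np.isnan(d).any():
        d[np.isnan(d)] = np.nanmax(d) * 2 if np.isfinite(np.nanmax(d)) else 1.0
    return squareform(d, checks=False)


def cluster_matrix(matrix: ResultsMatrix, *, missing: str = "zero") -> ClusterResult:
    """Order the Z matrix by hierarchical clustering of rows and columns.

    Complete-linkage agglomeration on Euclidean distances. Missing cells are
    imputed as 0 for the distance computation only (``missing="zero"``,
    neutral evidence) or handled by pairwise-complete distances
    (``missing="pairwise"``). All-missing rows are excluded with a warning.
    Input order never affects the dendrogram topology; labels are pre-sorted
    so ties break deterministically.
    """
    if missing not in ("zero", "pairwise"):
        raise ValueError("missing must be 'zero' or 'pairwise'")
    z = matrix.z.sort_index().sort_index(axis=1)
    all_missing = z.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(f"excluding all-missing rows: {list(z.index[all_missing])}", stacklevel=2)
        z = z.loc[~all_missing]
    if len(z) < 2:
        raise ValueError("clustering requires >= 2 rows")

    def _linkage(frame: pd.DataFrame) -> np.ndarray:
        x = frame.to_numpy(float)
        if missing == "zero":
            dvec = pdist(np.nan_to_num(x, nan=0.0), metric="euclidean")
        else:
            dvec = _pairwise_complete_dist(x)
        return hierarchy.linkage(dvec, method="complete")

    row_link = _linkage(z)
    row_order = [z.index[i] for i in hierarchy.leaves_list(row_link)]
    if z.shape[1] >= 2:
        col_link = _linkage(z.T)
        col_order = [z.columns[i] for i in hierarchy.leaves_list(col_link)]
    else:
        col_link, col_order = None, list(z.columns)
    return ClusterResult(
        row_order=row_order, col_order=col_order, row_linkage=row_link, col_linkage=col_link
    )


def _sig6(x: float) -> float:
    return float(f"{x:.6g}")


def export_app_table(results: pd.DataFrame, graded: pd.DataFrame, path) -> pd.DataFrame:
    """Write the per-(trait, outcome, method) table consumed by the viewer app.

    One row per estimator result with the OR per SD (6 significant figures),
    its CI, p-value, capped -log10 p, and the pair's evidence label. Empty
    results give a header-only file. Returns the exported frame.
    """
    graded = graded.copy()
    graded["label"] = _labels(graded)
    out = results.copy()
    if len(out):
        out["or_sd"] = np.exp(out["estimate"]).map(_sig6)
        out["or_ci_low"] = np.exp(out["ci_low"]).map(_sig6)
        out["or_ci_high"] = np.exp(out["ci_high"]).map(_sig6)
        out["neg_log10_p"] = np.minimum(-np.log10(out["pvalue"]), NEG_LOG10_P_CAP)
        out = out.merge(
            graded[["exposure_id", "outcome_id", "label"]],
            on=["exposure_id", "outcome_id"], how="left",
        )
    out = out.reindex(columns=APP_TABLE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# mrphewas app table schema v{APP_TABLE_SCHEMA_VERSION}\n")
        out.to_csv(fh, sep="\t", index=False)
    logger.info("exported %d result rows to %s", len(out), path)
    return out


def read_app_table(path) -> pd.DataFrame:
    """Re-import an exported app table."""
    return pd.read_csv(path, sep="\t", comment="#")
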