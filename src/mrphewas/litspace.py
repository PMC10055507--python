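"""Literature-triple triangulation of MR findings.

A *literature space* is the set of subject-predicate-object assertions
("triples") mined from published abstracts around an anchor term (an
exposure or a cancer). Overlapping an exposure space with a cancer space
nominates candidate mediators: terms reached from the exposure that also
lead into the cancer, suggesting a causal pathway exposure -> mediator ->
cancer. Spaces with more than a configurable number of triples (default 50)
are considered viable for triangulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

TRIPLE_COLUMNS = ["subject", "predicate", "object"]


def normalise_term(term: str) -> str:
    """Lowercase, trim, and collapse internal whitespace."""
    return " ".join(str(term).strip().lower().split())


@dataclass
class TripleSet:
    """A literature space: de-duplicated triples around one anchor term."""

    anchor: str | None
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRIPLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"triple table missing columns: {missing}")
        if self.anchor is not None:
            self.anchor = normalise_term(self.anchor)

    @property
    def size(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class OverlapReport:
    """Mediator candidates shared between an exposure and a cancer space.

    ``mediators`` has one row per common term with the number of supporting
    triples on each side, ranked by ``min(support_exposure, support_cancer)``
    descending (ties alphabetical); ``sankey`` is the corresponding
    exposure -> mediator -> cancer edge list. ``viable`` reports whether both
    spaces individually pass the viability rule.
    """

    pair: tuple
    mediators: pd.DataFrame
    viable: bool
    sankey: pd.DataFrame


def _clean(df: pd.DataFrame, source_id: str | None) -> tuple[pd.DataFrame, int]:
    df = df.copy()
    for c in TRIPLE_COLUMNS:
        df[c] = df[c].map(lambda v: normalise_term(v) if pd.notna(v) else "")
    bad = (df["subject"] == "") | (df["object"] == "")
    n_bad = int(bad.sum())
    df = df.loc[~bad]
    df = df.drop_duplicates(subset=TRIPLE_COLUMNS).reset_index(drop=True)
    if "source_id" not in df.columns:
        df["source_id"] = source_id if source_id is not None else ""
    return df[TRIPLE_COLUMNS + ["source_id"]], n_bad


def read_triples(path: str | Path, anchor: str | None = None) -> TripleSet:
    """Read a TSV of subject/predicate/object rows into a TripleSet.

    Terms are case-normalised; duplicates on (subject, predicate, object)
    are collapsed; rows with an empty subject or object are logged and
    skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TRIPLE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df, n_bad = _clean(raw, source_id=anchor or path.stem)
    if n_bad:
        logger.warning("%s: skipped %d malformed triple rows", path.name, n_bad)
    return TripleSet(anchor=anchor, df=df)


def triple_set(rows, anchor: str | None = None) -> TripleSet:
    """Build a TripleSet from an iterable of (subject, predicate, object)."""
    df = pd.DataFrame(rows, columns=TRIPLE_COLUMNS)
    df, _ = _clean(df, source_id=anchor)
    return TripleSet(anchor=anchor, df=df)


def write_triples(ts: TripleSet, path: str | Path) -> Path:
    path = Path(path)
    ts.df[TRIPLE_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def viability(space: TripleSet, min_triples: int = 50) -> bool:
    """A space is viable iff it holds strictly more than ``min_triples``."""
    if min_triples < 0:
        raise ValueError("min_triples must be >= 0")
    return space.size > min_triples


def overlap(
    exposure_space: TripleSet,
    cancer_space: TripleSet,
    *,
    symmetric: bool = False,
    min_triples: int = 50,
) -> OverlapReport:
    """Intersect two literature spaces to nominate mediators.

    Directed join (default): a mediator is a term appearing as the *object*
    of an exposure triple and the *subject* of a cancer triple, forming the
    chain exposure -> mediator -> cancer. With ``symmetric=True`` a mediator
    is any term appearing in either position on both sides. The anchor terms
    themselves are never reported as mediators. Empty spaces give an empty
    mediator list.
    """
    exp_df, can_df = exposure_space.df, cancer_space.df
    anchors = {a for a in (exposure_space.anchor, cancer_space.anchor) if a}

    if symmetric:
        # any-position join; each triple supports a term once even if the
        # term fills both slots
        def _counts(df):
            terms = [t for _, r in df.iterrows() for t in {r["subject"], r["object"]}]
            return pd.Series(terms, dtype=object).value_counts()

        sup_e, sup_c = _counts(exp_df), _counts(can_df)
    else:
        sup_e = exp_df["object"].value_counts()
        sup_c = can_df["subject"].value_counts()

    common = sorted((set(sup_e.index) & set(sup_c.index)) - anchors)
    rows = [
        {
            "term": t,
            "support_exposure": int(sup_e[t]),
            "support_cancer": int(sup_c[t]),
            "score": int(min(sup_e[t], sup_c[t])),
        }
        for t in common
    ]
    mediators = pd.DataFrame(rows, columns=["term", "support_exposure", "support_cancer", "score"])
    if len(mediators):
        mediators = mediators.sort_values(
            ["score", "term"], ascending=[False, True]
        ).reset_index(drop=True)

    exp_anchor = exposure_space.anchor or "exposure"
    can_anchor = cancer_space.anchor or "cancer"
    edges = []
    for _, m in mediators.iterrows():
        edges.append({"source": exp_anchor, "target": m["term"], "weight": m["support_exposure"]})
        edges.append({"source": m["term"], "target": can_anchor, "weight": m["support_cancer"]})
    sankey = pd.DataFrame(edges, columns=["source", "target", "weight"])

    return OverlapReport(
        pair=(exp_anchor, can_anchor),
        mediators=mediators,
        viable=viability(exposure_space, min_triples) and viability(cancer_space, min_triples),
        sankey=sankey,
    )
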