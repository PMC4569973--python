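"""Pathway / process / organismal-system enrichment of promiscuous vs.
selective compounds.

Each annotation term defines a 2x2 table (promiscuous/selective x
in-term/not-in-term) over the compounds mapped in that term's category;
a two-sided Fisher exact test gives p, and Benjamini-Hochberg correction
is applied within each (category, ontology level) family, mirroring
separate collective/detailed result tables.  Both enrichment and
depletion are reported (odds ratio above or below 1).  Compounds mapped
to a category but to none of its terms at a given level form a testable
"Not assigned" pseudo-term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

NOT_ASSIGNED = "Not assigned"
MIN_COMPOUNDS_PER_CATEGORY = 20


@dataclass
class EnrichmentRow:
    term: str
    level: str       # "collective" | "detailed"
    category: str    # e.g. Metabolism
    a: int           # promiscuous, in term
    b: int           # promiscuous, not in term
    c: int           # selective, in term
    d: int           # selective, not in term
    odds_ratio: float
    p: float
    p_fdr: float


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_p(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact p and sample odds ratio for a 2x2 table."""
    odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p), float(odds)


def fisher_enrichment(membership: pd.DataFrame, labels,
                      min_compounds: int = MIN_COMPOUNDS_PER_CATEGORY,
                      global_correction: bool = False,
                      ) -> list[EnrichmentRow]:
    """Term-wise enrichment of promiscuous vs. selective compounds.

    `membership` is a table with columns compound_id, category, level,
    term (one row per compound-term assignment; a compound may appear
    with term = NaN to mark it as mapped in a category without a term).
    `labels` maps compound_id -> "promiscuous"/"selective" (dict or list
    of objects with those attributes).  Categories with fewer than
    `min_compounds` labelled compounds are skipped.  BH correction is per
    (category, level) family unless `global_correction`.
    """
    if isinstance(labels, dict):
        label_of = dict(labels)
    else:
        label_of = {l.compound_id: l.label for l in labels}

    df = membership.copy()
    required = {"compound_id", "category", "level", "term"}
    if not required.issubset(df.columns):
        raise ValueError(f"membership table needs columns {sorted(required)}")
    df = df[df["compound_id"].isin(label_of)]
    if df.empty:
        raise ValueError("no membership rows for labelled compounds")

    # the background universe is the full mapped compound set (every
    # labelled compound appearing anywhere in the membership table), so a
    # compound mapped in one category but not another still counts in the
    # "Not assigned" pseudo-term of the latter
    universe = sorted(df["compound_id"].unique())
    prom = {cid for cid in universe if label_of[cid] == "promiscuous"}
    n_prom, n_sel = len(prom), len(universe) - len(prom)

    rows: list[EnrichmentRow] = []
    for category in sorted(df["category"].unique()):
        cat_df = df[df["category"] == category]
        if cat_df["compound_id"].nunique() < min_compounds:
            continue
        for level in sorted(cat_df["level"].unique()):
            lvl_df = cat_df[(cat_df["level"] == level) & cat_df["term"].notna()]
            term_members = {
                term: set(grp["compound_id"])
                for term, grp in lvl_df.groupby("term")
            }
            assigned = set().union(*term_members.values()) if term_members else set()
            unassigned = set(universe) - assigned
            if unassigned:
                term_members[NOT_ASSIGNED] = unassigned
            for term in sorted(term_members):
                members = term_members[term]
                a = len(members & prom)
                c = len(members) - a
                b = n_prom - a
                d = n_sel - c
                p, odds = fisher_p(a, b, c, d)
                rows.append(EnrichmentRow(term, level, category,
                                          a, b, c, d, odds, p, math.nan))

    if not rows:
        raise ValueError("no testable categories (all below min_compounds)")

    if global_correction:
        adj = bh_correct([r.p for r in rows])
        for r, q in zip(rows, adj):
            r.p_fdr = float(q)
    else:
        families: dict[tuple[str, str], list[int]] = {}
        for i, r in enumerate(rows):
            families.setdefault((r.category, r.level), []).append(i)
        for idx in families.values():
            adj = bh_correct([rows[i].p for i in idx])
            for i, q in zip(idx, adj):
                rows[i].p_fdr = float(q)
    return rows


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "category": r.category, "level": r.level, "term": r.term,
        "promiscuous_in": r.a, "promiscuous_out": r.b,
        "selective_in": r.c, "selective_out": r.d,
        "odds_ratio": r.odds_ratio, "p": r.p, "p_fdr": r.p_fdr,
    } for r in rows])
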