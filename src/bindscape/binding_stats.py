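"""Promiscuity propensity profiles and pocket amino-acid composition
propensities.

For a descriptor t and compound class c, the observed values are split
into equal-count intervals and each interval i receives the propensity

    P_i = f_i / g_i,   f_i = q_i / sum(q),  g_i = s_i / sum(s),

where q_i and s_i count promiscuous and selective compounds in interval i.
Propensities are reported log10-transformed (symmetric about 0); the
standard error of P_i is

    se_i = (1/g_i) * sqrt(f_i (1 - f_i) / sum(q)).

The same ratio applied to residue-type counts inside vs. outside binding
pockets yields the compositional propensity of each amino-acid type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._aa import AA_ORDER

log = logging.getLogger(__name__)

DEFAULT_N_BINS = 10
PSEUDO_COUNT = 0.5


@dataclass
class PropensityBin:
    lo: float
    hi: float
    q: float
    s: float
    f: float
    g: float
    propensity: float
    log10_propensity: float
    se: float
    pseudo_counted: bool = False


@dataclass
class PropensityProfile:
    property_name: str
    compound_class: str
    bins: list[PropensityBin]


@dataclass
class CompositionPropensity:
    res_type: str
    q: float
    s: float
    propensity: float
    log10_propensity: float
    se: float
    pseudo_counted: bool = False


def equal_count_bins(values, n_bins: int) -> list[tuple[float, float]]:
    """Quantile-style interval edges giving near-equal occupancy.

    On tie-free data, bin occupancies differ by at most one.  Duplicate
    edges arising from ties are merged (yielding fewer bins) with a
    warning.  Intervals are [lo, hi) with the final interval closed.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(values) < n_bins:
        raise ValueError("fewer values than bins")
    distinct = np.unique(values)
    if len(distinct) < n_bins:
        raise ValueError(
            f"{n_bins} bins requested but only {len(distinct)} distinct values")
    v = np.sort(values)
    n = len(v)
    cut_positions = [round(n * j / n_bins) for j in range(1, n_bins)]
    inner = [v[p] for p in cut_positions]
    merged = []
    for e in inner:
        if not merged or e > merged[-1]:
            merged.append(e)
    if len(merged) < len(inner):
        warnings.warn("duplicate bin edges merged; fewer bins than requested")
    edges = [v[0]] + merged + [v[-1]]
    # guard against a first edge equal to the minimum (all mass in bin 0)
    edges = [edges[0]] + [e for e in edges[1:-1] if e > edges[0]] + [edges[-1]]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def assign_bins(values, intervals) -> np.ndarray:
    """Index of the [lo, hi) interval containing each value; the final
    interval also contains its upper edge.  Values outside all intervals
    are clipped into the nearest one."""
    values = np.asarray(values, dtype=float)
    inner_edges = np.array([hi for _, hi in intervals[:-1]])
    return np.searchsorted(inner_edges, values, side="right").clip(
        0, len(intervals) - 1)


def _propensity_from_counts(q: np.ndarray, s: np.ndarray
                            ) -> tuple[np.ndarray, ...]:
    """Shared propensity/SE arithmetic; applies a 0.5 pseudo-count to every
    cell when any count is zero (log10 otherwise undefined)."""
    q = np.asarray(q, dtype=float)
    s = np.asarray(s, dtype=float)
    pseudo = bool(np.any(q == 0) or np.any(s == 0))
    if pseudo:
        q = q + PSEUDO_COUNT
        s = s + PSEUDO_COUNT
    f = q / q.sum()
    g = s / s.sum()
    p = f / g
    se = (1.0 / g) * np.sqrt(f * (1.0 - f) / q.sum())
    return q, s, f, g, p, np.log10(p), se, pseudo


def propensity_profile(values, labels, property_name: str = "",
                       compound_class: str = "all",
                       n_bins: int = DEFAULT_N_BINS,
                       intervals=None) -> PropensityProfile:
    """Per-interval promiscuity propensities for one descriptor.

    `values` are descriptor values, `labels` the matching promiscuity
    labels ("promiscuous"/"selective" strings or booleans).  Intervals are
    computed on the pooled values of both groups (equal-count binning)
    unless supplied.  Missing descriptor values are excluded pairwise with
    a logged count.
    """
    values = np.asarray(values, dtype=float)
    lab = np.asarray([
        l if isinstance(l, (bool, np.bool_)) else l == "promiscuous"
        for l in labels])
    if len(values) != len(lab):
        raise ValueError("values and labels differ in length")
    keep = ~np.isnan(values)
    if not keep.all():
        log.info("propensity_profile(%s): %d missing values excluded",
                 property_name, int((~keep).sum()))
    values, lab = values[keep], lab[keep]
    if not lab.any() or lab.all():
        raise ValueError("both promiscuous and selective compounds required")
    if intervals is None:
        intervals = equal_count_bins(values, n_bins)
    idx = assign_bins(values, intervals)
    nb = len(intervals)
    q = np.bincount(idx[lab], minlength=nb).astype(float)
    s = np.bincount(idx[~lab], minlength=nb).astype(float)
    q, s, f, g, p, logp, se, pseudo = _propensity_from_counts(q, s)
    bins = [PropensityBin(lo, hi, q[i], s[i], f[i], g[i], p[i], logp[i],
                          se[i], pseudo)
            for i, (lo, hi) in enumerate(intervals)]
    return PropensityProfile(property_name, compound_class, bins)


def composition_propensity(pocket_counts, background_counts,
                           res_types=AA_ORDER) -> list[CompositionPropensity]:
    """Amino-acid compositional propensities of binding pockets.

    `pocket_counts` (q_i) aggregate residue-type counts over pockets;
    `background_counts` (s_i) count residues outside any pocket.  Types
    absent from both are omitted.  Same ratio and standard error as the
    descriptor profiles, with n = number of residue types.
    """
    q_all = np.asarray(pocket_counts, dtype=float)
    s_all = np.asarray(background_counts, dtype=float)
    if q_all.sum() == 0 or s_all.sum() == 0:
        raise ValueError("need at least one pocket and one non-pocket residue")
    present = (q_all + s_all) > 0
    types = [t for t, keep in zip(res_types, present) if keep]
    q, s, f, g, p, logp, se, pseudo = _propensity_from_counts(
        q_all[present], s_all[present])
    return [CompositionPropensity(t, q[i], s[i], p[i], logp[i], se[i], pseudo)
            for i, t in enumerate(types)]


def pocket_background_counts(pockets, chains) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate (q, s): residue-type counts inside pockets and in chain
    regions outside every pocket.

    Pocket membership is resolved per (structure, chain, seq_number) so a
    residue participating in any pocket never also counts as background.
    """
    from ._aa import AA_INDEX

    q = np.zeros(len(AA_ORDER), dtype=float)
    in_pocket: set[tuple[str, str, str]] = set()
    for p in pockets:
        q += p.composition
        for seq_number, _ in p.residues:
            in_pocket.add((p.structure_id, p.chain_id, seq_number))
    s = np.zeros(len(AA_ORDER), dtype=float)
    for ch in chains:
        for res in ch.residues:
            if (ch.structure_id, ch.chain_id, res.seq_number) in in_pocket:
                continue
            idx = AA_INDEX.get(res.res_type)
            if idx is not None:
                s[idx] += 1
    return q, s
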