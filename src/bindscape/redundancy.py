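"""Redundancy reduction of pockets and targets, and promiscuity labelling.

Two levels of redundancy are collapsed before any compound is called
promiscuous or selective:

* pockets of one compound on one protein (chains with identical sequence)
  are clustered by complete linkage on Bray-Curtis dissimilarity of their
  amino-acid compositions, cut at 0.3, keeping one representative each;
* the protein targets of one compound are clustered at 30% pairwise
  sequence identity (single linkage over the identity graph, a reproducible
  stand-in for score-based Blastclust), keeping pockets from one member
  chain per cluster.

A compound with three or more surviving pockets is promiscuous; with one
or two, selective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_io import TargetChain
from .pockets import BindingPocket

log = logging.getLogger(__name__)

BC_CUTOFF = 0.3
IDENTITY_CUTOFF = 0.30
LENGTH_COVERAGE = 0.95
PROMISCUITY_MIN_POCKETS = 3


class UndefinedDissimilarityError(ValueError):
    """Bray-Curtis is undefined when both count vectors are zero."""


@dataclass
class TargetCluster:
    members: list[TargetChain]
    representative: TargetChain


@dataclass(frozen=True)
class PromiscuityLabel:
    compound_id: str
    n_pockets: int
    label: str  # "promiscuous" | "selective"


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity ``sum|a_i - b_i| / sum(a_i + b_i)`` between
    two non-negative count vectors; symmetric, in [0, 1], zero iff equal."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    total = float(np.sum(a) + np.sum(b))
    if total == 0:
        raise UndefinedDissimilarityError("both count vectors are zero")
    return float(np.sum(np.abs(a - b)) / total)


def _pocket_sort_key(p: BindingPocket):
    # larger pockets first, then lexicographic (structure, chain) for ties
    return (-p.n_residues, p.structure_id, p.chain_id)


def dedup_pockets(pockets: list[BindingPocket],
                  cutoff: float = BC_CUTOFF) -> list[BindingPocket]:
    """One representative pocket per complete-linkage cluster at `cutoff`.

    All inputs must share one compound and one target protein.  Clusters
    are the maximal sets whose complete-linkage merge height is <= cutoff
    (the tree is cut strictly above it).  The representative is the pocket
    with the most residues, ties broken by (structure_id, chain_id).
    """
    if len(pockets) <= 1:
        return list(pockets)
    n = len(pockets)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = bray_curtis(pockets[i].composition,
                                                  pockets[j].composition)
    labels = fcluster(linkage(squareform(dmat, checks=False), method="complete"),
                      t=cutoff, criterion="distance")
    reps = []
    for cl in np.unique(labels):
        members = [pockets[i] for i in np.flatnonzero(labels == cl)]
        reps.append(min(members, key=_pocket_sort_key))
    reps.sort(key=_pocket_sort_key)
    return reps


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(seq_a: str, seq_b: str,
                      aligner: Align.PairwiseAligner | None = None,
                      ) -> tuple[float, float, float]:
    """Global-alignment identity and per-sequence coverage.

    Returns ``(identity, coverage_a, coverage_b)`` where identity is
    identical positions over total alignment length (gap columns included)
    and coverage of a sequence is the fraction of its residues falling in
    aligned (residue-residue) columns.
    """
    if not seq_a or not seq_b:
        return 0.0, 0.0, 0.0
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned_cols += a1 - a0
        for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]):
            if x == y:
                matches += 1
    aln_len = aln.length
    identity = matches / aln_len if aln_len else 0.0
    return identity, aligned_cols / len(seq_a), aligned_cols / len(seq_b)


def cluster_targets(chains: list[TargetChain],
                    identity_cutoff: float = IDENTITY_CUTOFF,
                    length_coverage: float = LENGTH_COVERAGE,
                    ) -> list[TargetCluster]:
    """Single-linkage clusters of chains over the sequence-identity graph.

    Two chains are joined when pairwise identity >= identity_cutoff and
    the alignment covers >= length_coverage of at least one of them.
    Identical sequences are grouped before any alignment.  The cluster
    representative is the longest chain, ties broken by (structure_id,
    chain_id).
    """
    if not chains:
        raise ValueError("no chains to cluster")
    # group exact-duplicate sequences so each distinct sequence aligns once
    seq_groups: dict[str, list[TargetChain]] = {}
    for ch in chains:
        seq_groups.setdefault(ch.sequence, []).append(ch)
    seqs = sorted(seq_groups)

    parent = list(range(len(seqs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    aligner = _make_aligner()
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ident, cov_a, cov_b = pairwise_identity(seqs[i], seqs[j], aligner)
            if ident >= identity_cutoff and max(cov_a, cov_b) >= length_coverage:
                union(i, j)

    comp: dict[int, list[TargetChain]] = {}
    for i, seq in enumerate(seqs):
        comp.setdefault(find(i), []).extend(seq_groups[seq])
    clusters = []
    for members in comp.values():
        rep = min(members, key=lambda c: (-len(c.sequence), c.structure_id,
                                          c.chain_id))
        members = sorted(members, key=lambda c: (c.structure_id, c.chain_id))
        clusters.append(TargetCluster(members, rep))
    clusters.sort(key=lambda cl: (cl.representative.structure_id,
                                  cl.representative.chain_id))
    return clusters


def _chain_key(structure_id: str, chain_id: str) -> tuple[str, str]:
    return (structure_id, chain_id)


def nonredundant_events(pockets_by_compound: dict[str, list[BindingPocket]],
                        chains: list[TargetChain],
                        identity_cutoff: float = IDENTITY_CUTOFF,
                        length_coverage: float = LENGTH_COVERAGE,
                        ) -> dict[str, list[BindingPocket]]:
    """Non-redundant, non-homologous binding events per compound.

    For each compound the set of its target chains is clustered at the
    identity cutoff; within each target cluster, pockets from a single
    member chain survive (the chain chosen by the cluster-representative
    rule among the chains actually carrying pockets).  Pocket-level
    deduplication (:func:`dedup_pockets`) is expected to have been applied
    per (compound, protein) beforehand.
    """
    chain_lookup = {_chain_key(c.structure_id, c.chain_id): c for c in chains}
    out: dict[str, list[BindingPocket]] = {}
    for compound_id in sorted(pockets_by_compound):
        plist = pockets_by_compound[compound_id]
        if not plist:
            continue
        target_chains = []
        seen = set()
        for p in plist:
            key = _chain_key(p.structure_id, p.chain_id)
            if key in seen:
                continue
            seen.add(key)
            if key not in chain_lookup:
                raise KeyError(f"pocket references unknown chain {key}")
            target_chains.append(chain_lookup[key])
        clusters = cluster_targets(target_chains, identity_cutoff,
                                   length_coverage)
        kept: list[BindingPocket] = []
        for cl in clusters:
            member_keys = {_chain_key(c.structure_id, c.chain_id)
                           for c in cl.members}
            candidates = [p for p in plist
                          if _chain_key(p.structure_id, p.chain_id) in member_keys]
            # keep pockets of the representative chain only
            rep_chain = min(
                {_chain_key(p.structure_id, p.chain_id) for p in candidates} | set(),
                key=lambda k: (-len(chain_lookup[k].sequence), k),
            )
            kept.extend(p for p in candidates
                        if _chain_key(p.structure_id, p.chain_id) == rep_chain)
        kept.sort(key=_pocket_sort_key)
        out[compound_id] = kept
    return out


def classify_promiscuity(events: dict[str, list[BindingPocket]] | dict[str, int],
                         min_pockets: int = PROMISCUITY_MIN_POCKETS,
                         ) -> list[PromiscuityLabel]:
    """Label each compound promiscuous (>= `min_pockets` non-redundant
    pockets) or selective (fewer).  Compounds with zero events are excluded
    with a logged count."""
    labels = []
    n_skipped = 0
    for compound_id in sorted(events):
        v = events[compound_id]
        n = v if isinstance(v, int) else len(v)
        if n < 1:
            n_skipped += 1
            continue
        labels.append(PromiscuityLabel(
            compound_id, n,
            "promiscuous" if n >= min_pockets else "selective"))
    if n_skipped:
        log.info("classify_promiscuity: %d compounds without events excluded",
                 n_skipped)
    return labels
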