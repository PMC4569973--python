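"""Per-compound target-diversity measures.

EC entropy quantifies how broadly a compound's protein targets spread
over the six top-level Enzyme Commission classes (oxidoreductases,
transferases, hydrolases, lyases, isomerases, ligases) plus a "None"
category for targets without an EC assignment.  Class counts are weighted
by the inverse background size of each class before normalizing to
probabilities, so an over-represented class in the target bank does not
dominate; entropy is Shannon entropy in nats (max ln 7).

Pocket variability (PV) is the sum over residue types of the
variance-to-mean ratio of composition counts across a compound's pocket
set; PV = 0 iff all pockets share one composition, and PV is independent
of compound size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import TargetChain
from .pockets import BindingPocket

log = logging.getLogger(__name__)

EC_CATEGORIES = ("EC1", "EC2", "EC3", "EC4", "EC5", "EC6", "None")
MIN_TARGETS = 3
MIN_POCKETS = 3


@dataclass
class ECEntropyResult:
    compound_id: str
    probabilities: np.ndarray  # over EC_CATEGORIES, sums to 1
    entropy: float             # nats, in [0, ln 7]
    n_targets: int


@dataclass
class PocketVariabilityResult:
    compound_id: str
    variances: np.ndarray  # per residue type with mean > 0
    means: np.ndarray
    pv: float
    n_pockets: int


def ec_class_counts(targets: list[TargetChain]) -> np.ndarray:
    """Counts over the 7 categories.  A chain with several top-level EC
    numbers contributes one count to each; a chain without any counts
    under "None"."""
    counts = np.zeros(7, dtype=float)
    for ch in targets:
        classes = sorted({e for e in ch.ec_numbers if 1 <= e <= 6})
        if not classes:
            counts[6] += 1
        else:
            for e in classes:
                counts[e - 1] += 1
    return counts


def background_class_sizes(chains: list[TargetChain]) -> np.ndarray:
    """EC category sizes over a full target set, for the entropy weighting."""
    sizes = ec_class_counts(chains)
    return sizes


def ec_entropy(targets: list[TargetChain], background_sizes,
               compound_id: str = "", min_targets: int = MIN_TARGETS,
               weighted: bool = True) -> ECEntropyResult | None:
    """Background-weighted EC entropy of one compound's target set.

    Raw category counts c_i are divided by the background class sizes N_i
    (``weighted=False`` skips this step) and normalized to probabilities;
    H = -sum p_i ln p_i.  Compounds with fewer than `min_targets` targets
    are skipped (returns None) with a log entry; the target count is a
    protein count, not a pocket count.
    """
    if len(targets) < min_targets:
        log.info("ec_entropy(%s): only %d targets (< %d), skipped",
                 compound_id, len(targets), min_targets)
        return None
    counts = ec_class_counts(targets)
    if weighted:
        n_bg = np.asarray(background_sizes, dtype=float)
        if n_bg.shape != (7,) or np.any(n_bg < 0):
            raise ValueError("background_sizes must be 7 non-negative numbers")
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(n_bg > 0, counts / np.where(n_bg > 0, n_bg, 1.0), 0.0)
    else:
        w = counts
    total = w.sum()
    if total == 0:
        raise ValueError("all observed classes have zero background size")
    p = w / total
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return ECEntropyResult(compound_id, p, h, len(targets))


def pocket_variability(pockets: list[BindingPocket], compound_id: str = "",
                       min_pockets: int = MIN_POCKETS,
                       ) -> PocketVariabilityResult | None:
    """PV = sum over residue types of sample variance / mean of counts.

    Sample variance uses the n-1 denominator.  The sum runs over residue
    types with nonzero mean across the pocket set.  Compounds with fewer
    than `min_pockets` pockets are skipped (returns None).
    """
    if len(pockets) < min_pockets:
        log.info("pocket_variability(%s): only %d pockets (< %d), skipped",
                 compound_id, len(pockets), min_pockets)
        return None
    counts = np.array([p.composition for p in pockets], dtype=float)
    means = counts.mean(axis=0)
    variances = counts.var(axis=0, ddof=1)
    present = means > 0
    pv = float((variances[present] / means[present]).sum())
    return PocketVariabilityResult(compound_id, variances[present],
                                   means[present], pv, len(pockets))
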