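"""Binding-pocket definition by heavy-atom contact geometry.

A pocket is the set of protein residues on one chain with at least one
heavy atom within 5 Angstrom (inclusive) of any ligand heavy atom; only
contact sets of three or more residues qualify as pockets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._aa import AA_INDEX, AA_ORDER
from .core_io import LigandInstance, StructureModel

CONTACT_CUTOFF = 5.0
MIN_POCKET_RESIDUES = 3


class DegenerateLigandError(ValueError):
    """Ligand without heavy atoms cannot define contacts."""


@dataclass
class BindingPocket:
    compound_id: str
    structure_id: str
    chain_id: str
    residues: list[tuple[str, str]]   # (seq_number, res_type), sequence order
    composition: np.ndarray           # 20-dim count vector over AA_ORDER

    @property
    def n_residues(self) -> int:
        return len(self.residues)


def composition_from_types(res_types) -> np.ndarray:
    """20-dim count vector over the standard residue types.

    Nonstandard (``OTHER``) residues contribute nothing; the vector is
    invariant to residue ordering.
    """
    comp = np.zeros(len(AA_ORDER), dtype=int)
    for t in res_types:
        idx = AA_INDEX.get(t)
        if idx is not None:
            comp[idx] += 1
    return comp


def pocket_composition(pocket: BindingPocket) -> np.ndarray:
    return composition_from_types(t for _, t in pocket.residues)


def extract_pockets(model: StructureModel, ligand: LigandInstance,
                    cutoff: float = CONTACT_CUTOFF,
                    min_residues: int = MIN_POCKET_RESIDUES,
                    ) -> list[BindingPocket]:
    """Pockets of `ligand` on each chain of `model`.

    Emits one pocket per chain on which at least `min_residues` residues
    have a heavy atom within `cutoff` (inclusive) of any ligand heavy atom.
    Nonstandard residues count toward the residue threshold but contribute
    nothing to the 20-dim composition.  Chains are treated independently: a
    ligand wedged between two chains yields up to two pockets.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_coords = ligand.heavy_coords
    if len(lig_coords) == 0:
        raise DegenerateLigandError(
            f"ligand {ligand.compound_id} in {ligand.structure_id} has no heavy atoms")
    tree = cKDTree(lig_coords)

    pockets: list[BindingPocket] = []
    for chain in model.chains:
        contact = []
        for res in chain.residues:
            coords = res.heavy_coords
            if len(coords) == 0:
                continue
            d, _ = tree.query(coords, k=1)
            if np.min(d) <= cutoff:
                contact.append(res)
        if len(contact) >= min_residues:
            residues = [(r.seq_number, r.res_type) for r in contact]
            pockets.append(BindingPocket(
                compound_id=ligand.compound_id,
                structure_id=model.structure_id,
                chain_id=chain.chain_id,
                residues=residues,
                composition=composition_from_types(t for _, t in residues),
            ))
    return pockets
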