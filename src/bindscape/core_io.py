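"""Parsing of complex structures and compound libraries, plus admission filters.

Structures (PDB or mmCIF) are read through :mod:`gemmi` into lightweight
domain objects; compound libraries (SDF) through RDKit.  The admission
filters mirror the study design for structurally resolved binding events:
X-ray resolution of 2 Angstrom or better, ligand molecular weight between
30 and 1000 Da, no common ions/solvents/cryo-agents, and no covalently
attached ligands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from ._aa import OTHER, res_type_from_3letter

log = logging.getLogger(__name__)

#: heavy-atom distance below which a ligand atom is considered covalently
#: bonded to the protein (standard upper bound for a covalent bond length)
COVALENT_CUTOFF = 1.9

#: default component codes excluded as ions, solvents, buffers and cryo
#: agents.  The set is an approximation of the study's (unpublished) list and
#: is user-overridable in :func:`identify_ligands`.
DEFAULT_EXCLUSIONS = frozenset({
    # water / heavy water
    "HOH", "DOD", "WAT",
    # buffers and solvents
    "MES", "DMS", "GOL", "BME", "EDO", "PEG", "PG4", "PGE", "1PE",
    "TRS", "EPE", "MPD", "IPA", "EOH", "MOH", "ACT", "ACY", "FMT",
    "NO3", "NH4", "AZI", "SCN", "CIT", "TLA", "MLI",
    # common ions
    "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "FE2", "CU", "CU1",
    "NI", "CO", "CD", "HG", "BR", "IOD", "F", "CS", "LI", "SR", "BA",
    "SO4", "PO4", "CO3", "OH", "SE",
})

_HYDROGEN = {"H", "D", "T"}


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed or contains no chains."""


class EmptyLibraryError(ValueError):
    """Raised when an SDF file yields zero parsable molecules."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    is_heavy: bool

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_number: str  # residue number + insertion code, e.g. "42" or "42A"
    res_type: str    # one-letter code or OTHER
    atoms: list[Atom]

    @property
    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], float)


@dataclass
class TargetChain:
    structure_id: str
    chain_id: str
    residues: list[Residue]
    ec_numbers: list[int] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        """One-letter sequence over the standard amino-acid residues;
        nonstandard residues are represented as 'X'."""
        return "".join(r.res_type if r.res_type != OTHER else "X"
                       for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LigandInstance:
    compound_id: str   # 3-letter chemical component code
    structure_id: str
    chain_id: str
    seq_number: str
    atoms: list[Atom]
    molecular_weight: float
    covalent_flag: bool = False

    @property
    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], float)


@dataclass
class StructureModel:
    structure_id: str
    resolution: float | None
    chains: list[TargetChain]
    ligands: list[LigandInstance]


@dataclass
class CompoundRecord:
    """A small molecule: identity, molecular graph, weight and fingerprint."""
    compound_id: str
    mol: object            # rdkit.Chem.Mol over the largest fragment
    molecular_weight: float
    smiles: str | None
    fingerprint: "Fingerprint"


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length hashed bit set for a molecular graph."""
    bits: frozenset
    size: int

    def __len__(self):
        return self.size


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: keep the highest-occupancy conformer per
    atom name, ties broken by file order."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        key = atom.name
        if key not in best:
            best[key] = atom
            order.append(key)
        elif atom.occ > best[key].occ:
            best[key] = atom
    return [best[k] for k in order]


def _to_atom(a: gemmi.Atom) -> Atom:
    el = a.element.name
    return Atom(
        name=a.name,
        element=el,
        coords=np.array([a.pos.x, a.pos.y, a.pos.z], float),
        is_heavy=el.upper() not in _HYDROGEN,
    )


def _ligand_weight(atoms: list[Atom]) -> float:
    """Molecular weight summed over the atoms present in the model.

    Crystal structures omit hydrogens, so this slightly underestimates the
    true compound weight; the 30-1000 Da admission window is wide enough
    that the distinction is immaterial for filtering.
    """
    return float(sum(gemmi.Element(a.element).weight for a in atoms))


def read_structure(path: str | Path, dialect: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of multi-model files is used.  Hydrogens are
    retained but flagged ``is_heavy=False``.  Every non-water, non-polymer
    HETATM residue becomes one :class:`LigandInstance`; admission filtering
    is left to :func:`identify_ligands`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb(str(path))
        elif dialect == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0 or len(st[0]) == 0:
        raise StructureFormatError(f"{path}: no chains found")

    structure_id = st.name.strip() or path.stem
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None

    model = st[0]
    chains: list[TargetChain] = []
    ligands: list[LigandInstance] = []
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            atoms = [_to_atom(a) for a in _pick_altlocs(res)]
            if not atoms:
                continue
            seq_number = f"{res.seqid.num}{res.seqid.icode}".strip()
            et = res.entity_type
            if et == gemmi.EntityType.Unknown:
                info = gemmi.find_tabulated_residue(res.name)
                is_polymer = ((info.is_amino_acid() if info else False)
                              or res.het_flag == "A")
            else:
                is_polymer = et == gemmi.EntityType.Polymer
            if is_polymer:
                residues.append(Residue(chain.name, seq_number,
                                        res_type_from_3letter(res.name), atoms))
            else:
                ligands.append(LigandInstance(res.name, structure_id, chain.name,
                                              seq_number, atoms,
                                              _ligand_weight(atoms)))
        if residues:
            chains.append(TargetChain(structure_id, chain.name, residues))

    if not chains:
        raise StructureFormatError(f"{path}: no protein chains")

    model_out = StructureModel(structure_id, resolution, chains, ligands)
    _flag_covalent(model_out)
    return model_out


def _flag_covalent(model: StructureModel, cutoff: float = COVALENT_CUTOFF) -> None:
    """Mark ligands with any heavy atom closer than `cutoff` to a protein
    heavy atom as covalently bound."""
    coords = [r.heavy_coords for ch in model.chains for r in ch.residues]
    coords = [c for c in coords if len(c)]
    if not coords:
        return
    tree = cKDTree(np.vstack(coords))
    for lig in model.ligands:
        hv = lig.heavy_coords
        if len(hv) == 0:
            continue
        d, _ = tree.query(hv, k=1)
        lig.covalent_flag = bool(np.min(d) < cutoff)


def filter_structures(models: list[StructureModel],
                      max_resolution: float = 2.0) -> list[StructureModel]:
    """Keep X-ray models with a reported resolution of `max_resolution`
    (inclusive) or better; models without a resolution record are dropped."""
    return [m for m in models
            if m.resolution is not None and m.resolution <= max_resolution]


def identify_ligands(model: StructureModel,
                     min_mw: float = 30.0,
                     max_mw: float = 1000.0,
                     exclusion_list: frozenset | set | None = None,
                     ) -> list[LigandInstance]:
    """Ligands passing the compound admission filters.

    Keeps ligand instances with ``min_mw <= MW <= max_mw`` whose component
    code is not on the ion/solvent exclusion list and that are not
    covalently attached to the protein.
    """
    if exclusion_list is None:
        exclusion_list = DEFAULT_EXCLUSIONS
    out = []
    for lig in model.ligands:
        if lig.compound_id.upper() in exclusion_list:
            continue
        if not (min_mw <= lig.molecular_weight <= max_mw):
            continue
        if lig.covalent_flag:
            continue
        out.append(lig)
    return out


def _largest_fragment(mol):
    from rdkit import Chem
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def compute_fingerprint(mol, n_bits: int = 1024) -> Fingerprint:
    """Hashed path-based fingerprint (RDKit linear fingerprint, 1024 bits)."""
    from rdkit.Chem import rdmolops
    bv = rdmolops.RDKFingerprint(mol, fpSize=n_bits)
    return Fingerprint(frozenset(bv.GetOnBits()), n_bits)


def read_compound_library(path: str | Path, id_property: str | None = None,
                          ) -> list[CompoundRecord]:
    """Read an SDF compound library into :class:`CompoundRecord` objects.

    The largest covalently connected fragment defines each molecule
    (salts/counter-ions dropped).  Entries with R-group placeholders
    (dummy atoms) or without a computable SMILES are skipped with a logged
    count.  Raises :class:`EmptyLibraryError` if nothing parses.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    path = Path(path)
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    except OSError as exc:
        raise EmptyLibraryError(f"{path}: {exc}") from exc
    records: list[CompoundRecord] = []
    n_dropped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            n_dropped += 1
            continue
        mol = _largest_fragment(mol)
        if any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
            n_dropped += 1  # R-group / dummy-atom placeholder
            continue
        try:
            smiles = Chem.MolToSmiles(mol)
        except Exception:
            n_dropped += 1
            continue
        if id_property and mol.HasProp(id_property):
            cid = mol.GetProp(id_property)
        elif mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            cid = mol.GetProp("_Name").strip()
        else:
            cid = f"MOL{i:05d}"
        records.append(CompoundRecord(
            compound_id=cid,
            mol=mol,
            molecular_weight=float(Descriptors.MolWt(mol)),
            smiles=smiles,
            fingerprint=compute_fingerprint(mol),
        ))
    if n_dropped:
        log.info("read_compound_library(%s): dropped %d unusable entries",
                 path.name, n_dropped)
    if not records:
        raise EmptyLibraryError(f"{path}: no parsable molecules")
    return records
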