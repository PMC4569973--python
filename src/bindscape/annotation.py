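"""Compound classification against drug/metabolite libraries and
physicochemical descriptors.

A structure-bank compound is assigned to a library compound when their
molecular weights agree within 1 Da and their fingerprints exceed 0.95
Tanimoto similarity (strict).  Compounds matching both a drug and a
metabolite library are "overlapping"; unmatched compounds remain
unassigned.

Graph-based descriptors (Wiener, Platt, Balaban indices, ring/rotatable
counts, donor/acceptor counts) are computed from the heavy-atom molecular
graph; experimental-style descriptors (pKa, pI, logP, TPSA, ASA) are
expected from a supplied table, with crude built-in approximations for
synthetic use only.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .core_io import CompoundRecord, Fingerprint

log = logging.getLogger(__name__)

MW_TOLERANCE = 1.0
TANIMOTO_MIN = 0.95

CLASS_DRUG = "drug"
CLASS_METABOLITE = "metabolite"
CLASS_OVERLAPPING = "overlapping"
CLASS_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ClassAssignment:
    compound_id: str
    compound_class: str
    drug_matches: tuple = ()
    metabolite_matches: tuple = ()


@dataclass
class DescriptorVector:
    """Per-compound physicochemical descriptors; any field may be missing
    (NaN)."""
    molecular_weight: float = math.nan        # Da
    atom_count: float = math.nan              # heavy atoms
    ring_atom_count: float = math.nan
    relative_ring_atom_count: float = math.nan
    accessible_surface_area: float = math.nan  # A^2
    tpsa: float = math.nan                     # A^2
    logp: float = math.nan
    strongest_acidic_pka: float = math.nan
    strongest_basic_pka: float = math.nan
    isoelectric_point: float = math.nan
    h_bond_donor_count: float = math.nan
    h_bond_acceptor_count: float = math.nan
    relative_h_bond_donor_count: float = math.nan
    relative_h_bond_acceptor_count: float = math.nan
    relative_rotatable_bond_count: float = math.nan
    relative_sp3_carbons: float = math.nan
    balaban_index: float = math.nan
    wiener_index: float = math.nan
    relative_platt_index: float = math.nan
    vertex_adjacency_information: float = math.nan

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


DESCRIPTOR_NAMES = tuple(f.name for f in fields(DescriptorVector))


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto similarity |a&b| / |a|b| of two equal-length bit sets.

    Two empty fingerprints are defined as similarity 1 with a warning.
    """
    if len(fp_a) != len(fp_b):
        raise ValueError(f"fingerprint length mismatch: {len(fp_a)} vs {len(fp_b)}")
    union = len(fp_a.bits | fp_b.bits)
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 1.0")
        return 1.0
    return len(fp_a.bits & fp_b.bits) / union


def map_compound(pdb_compound: CompoundRecord,
                 drug_lib: list[CompoundRecord],
                 metabolite_libs: list[list[CompoundRecord]],
                 mw_tol: float = MW_TOLERANCE,
                 t_min: float = TANIMOTO_MIN) -> ClassAssignment:
    """Classify a structure-bank compound by library matching.

    A library compound matches iff |delta MW| <= mw_tol and Tanimoto
    similarity strictly exceeds t_min.  Matching in a drug library only ->
    drug; metabolite libraries only -> metabolite; both -> overlapping;
    neither -> unassigned.  The result is invariant to library ordering.
    """
    def matches(libs):
        hits = []
        for lib in libs:
            for rec in lib:
                if abs(rec.molecular_weight - pdb_compound.molecular_weight) > mw_tol:
                    continue
                if tanimoto(rec.fingerprint, pdb_compound.fingerprint) > t_min:
                    hits.append(rec.compound_id)
        return tuple(sorted(set(hits)))

    drug_hits = matches([drug_lib])
    met_hits = matches(metabolite_libs)
    if drug_hits and met_hits:
        cls = CLASS_OVERLAPPING
    elif drug_hits:
        cls = CLASS_DRUG
    elif met_hits:
        cls = CLASS_METABOLITE
    else:
        cls = CLASS_UNASSIGNED
    return ClassAssignment(pdb_compound.compound_id, cls, drug_hits, met_hits)


# ---------------------------------------------------------------------------
# graph descriptors

def _heavy_graph(mol):
    """Heavy-atom adjacency as (n, edge list, degree array)."""
    n = mol.GetNumHeavyAtoms()
    edges = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((i, j))
    deg = np.zeros(n, dtype=int)
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    return n, edges, deg


def _distance_matrix(n, edges) -> np.ndarray:
    """All-pairs shortest paths by BFS over the unweighted heavy-atom graph."""
    adj = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if np.isinf(dist[s, v]):
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def wiener_index(n, edges) -> float:
    """Half-sum of all-pairs shortest-path lengths over heavy atoms."""
    if n < 2:
        return 0.0
    dist = _distance_matrix(n, edges)
    finite = dist[np.isfinite(dist)]
    return float(finite.sum() / 2.0)


def platt_index(edges, deg) -> float:
    """Sum of edge degrees: for each bond, (deg(u)-1) + (deg(v)-1)."""
    return float(sum(deg[i] + deg[j] - 2 for i, j in edges))


def balaban_index(n, edges) -> float:
    """Balaban J index: (m / (mu + 1)) * sum over edges of 1/sqrt(s_i s_j),
    where s_i are distance sums and mu the cyclomatic number."""
    m = len(edges)
    if m == 0 or n < 2:
        return 0.0
    dist = _distance_matrix(n, edges)
    if not np.all(np.isfinite(dist)):
        # computed per connected component is meaningless for J; use the
        # largest component via caller; here guard by treating as 0
        return 0.0
    s = dist.sum(axis=1)
    mu = m - n + 1
    total = sum(1.0 / math.sqrt(s[i] * s[j]) for i, j in edges)
    return float(m / (mu + 1.0) * total)


def vertex_adjacency_information(edges) -> float:
    """Conventional magnitude form 1 + log2(b) over the bond count b."""
    m = len(edges)
    return 1.0 + math.log2(m) if m > 0 else 0.0


def compute_graph_descriptors(compound: CompoundRecord) -> DescriptorVector:
    """Descriptors derivable from the heavy-atom molecular graph.

    Non-graph fields (pKa, pI, logP, TPSA, ASA) are left missing; see
    :func:`approximate_descriptors` and :func:`load_descriptor_table`.
    A disconnected graph is reduced to its largest fragment with a warning.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors, Lipinski

    mol = compound.mol
    if len(Chem.GetMolFrags(mol)) > 1:
        warnings.warn(f"{compound.compound_id}: disconnected graph, "
                      "descriptors computed on largest fragment")
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())

    n, edges, deg = _heavy_graph(mol)
    if n == 0:
        raise ValueError(f"{compound.compound_id}: empty molecular graph")

    ring_atoms = sum(1 for a in mol.GetAtoms() if a.IsInRing())
    rotatable = Lipinski.NumRotatableBonds(mol)
    donors = Lipinski.NumHDonors(mol)
    acceptors = Lipinski.NumHAcceptors(mol)
    sp3_c = sum(1 for a in mol.GetAtoms()
                if a.GetAtomicNum() == 6
                and a.GetHybridization() == Chem.HybridizationType.SP3)

    return DescriptorVector(
        molecular_weight=float(Descriptors.MolWt(mol)),
        atom_count=float(n),
        ring_atom_count=float(ring_atoms),
        relative_ring_atom_count=ring_atoms / n,
        h_bond_donor_count=float(donors),
        h_bond_acceptor_count=float(acceptors),
        relative_h_bond_donor_count=donors / n,
        relative_h_bond_acceptor_count=acceptors / n,
        relative_rotatable_bond_count=rotatable / n,
        relative_sp3_carbons=sp3_c / n,
        balaban_index=balaban_index(n, edges),
        wiener_index=wiener_index(n, edges),
        relative_platt_index=platt_index(edges, deg) / n,
        vertex_adjacency_information=vertex_adjacency_information(edges),
    )


def approximate_descriptors(compound: CompoundRecord) -> DescriptorVector:
    """Graph descriptors plus crude estimates of the physicochemical fields.

    The logP (Crippen atomic contributions), TPSA, ASA (Labute) and the
    SMARTS-group pKa/pI estimates here are rough approximations intended
    for synthetic data and tests; real analyses should supply a descriptor
    table instead.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    vec = compute_graph_descriptors(compound)
    mol = compound.mol
    vec.logp = float(Crippen.MolLogP(mol))
    vec.tpsa = float(Descriptors.TPSA(mol))
    vec.accessible_surface_area = float(rdMolDescriptors.CalcLabuteASA(mol))

    # crude group-based pKa assignment
    acid_pkas, base_pkas = [], []
    groups = [
        ("C(=O)[OH]", 4.2, None),        # carboxylic acid
        ("[SX4](=O)(=O)[OH]", -1.0, None),  # sulfonic acid
        ("P(=O)([OH])", 2.0, None),      # phosphate/phosphonate first pKa
        ("c[OH]", 10.0, None),           # phenol
        ("[SH]", 10.5, None),            # thiol
        ("[NX3;H2,H1,H0;!$(NC=O);!$(N=*);!a]", None, 10.0),  # aliphatic amine
        ("c1ccncc1", None, 5.2),         # pyridine-like
        ("[NX3][CX3](=[NX3])", None, 12.5),  # guanidine/amidine
    ]
    for smarts, a_pka, b_pka in groups:
        patt = Chem.MolFromSmarts(smarts)
        nhits = len(mol.GetSubstructMatches(patt))
        if nhits:
            if a_pka is not None:
                acid_pkas.extend([a_pka] * nhits)
            if b_pka is not None:
                base_pkas.extend([b_pka] * nhits)
    if acid_pkas:
        vec.strongest_acidic_pka = float(min(acid_pkas))
    if base_pkas:
        vec.strongest_basic_pka = float(max(base_pkas))
    if acid_pkas and base_pkas:
        vec.isoelectric_point = (min(acid_pkas) + max(base_pkas)) / 2.0
    elif acid_pkas:
        vec.isoelectric_point = min(acid_pkas) - 2.0
    elif base_pkas:
        vec.isoelectric_point = max(base_pkas) + 2.0
    return vec


def load_descriptor_table(path, compounds: dict[str, DescriptorVector],
                          key_column: str = "compound_id",
                          ) -> dict[str, DescriptorVector]:
    """Overlay a TSV descriptor table onto computed descriptor vectors.

    Supplied columns override computed fields; rows for unknown compounds
    are logged and skipped.  A supplied molecular weight deviating by more
    than 1 Da from the computed one triggers a consistency warning.
    """
    table = pd.read_csv(path, sep="\t")
    if key_column not in table.columns:
        raise ValueError(f"descriptor table lacks key column {key_column!r}")
    table[key_column] = table[key_column].astype(str)
    known_cols = [c for c in table.columns
                  if c in DESCRIPTOR_NAMES]
    n_unknown = 0
    for _, row in table.iterrows():
        cid = str(row[key_column])
        if cid not in compounds:
            n_unknown += 1
            continue
        vec = compounds[cid]
        for col in known_cols:
            value = row[col]
            if pd.isna(value):
                continue
            if (col == "molecular_weight"
                    and not math.isnan(vec.molecular_weight)
                    and abs(vec.molecular_weight - float(value)) > MW_TOLERANCE):
                warnings.warn(
                    f"{cid}: supplied MW {value} differs from computed "
                    f"{vec.molecular_weight:.2f} by more than {MW_TOLERANCE} Da")
            setattr(vec, col, float(value))
    if n_unknown:
        log.info("load_descriptor_table: %d rows for unknown compounds skipped",
                 n_unknown)
    return compounds
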