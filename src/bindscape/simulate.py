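"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates, at desk scale, the kind of data the analysis was
designed for: protein-ligand complex structures whose binding pockets are
known by construction, compound libraries with class-conditional
descriptor distributions (location parameters anchored to the observed
drug/metabolite medians, e.g. molecular-weight medians of 330.2 vs.
238.7 Da), per-compound binding-event counts whose log-rate is linear in
chosen descriptors, per-target EC labels with controllable diversity,
pocket composition vectors with controllable dispersion, and pathway
annotations with planted enrichment among promiscuous compounds.

Geometry and molecular graphs only need to satisfy the pipeline's
contracts; no attempt is made at physically realistic folds or
synthesizable chemistry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._aa import AA_ORDER, ONE_TO_THREE

# ---------------------------------------------------------------------------
# configuration

#: class-conditional descriptor distributions: name -> kind, per-class
#: location (drug, metabolite, overlapping) and scale.  Locations are the
#: observed class medians where known; "lognormal" scale is the sigma of
#: log values, "normal" scale the standard deviation.
DESCRIPTOR_PARAMS: dict[str, dict] = {
    "molecular_weight": {"kind": "lognormal",
                         "loc": (330.2, 238.7, 255.0), "scale": 0.45},
    "logp": {"kind": "normal", "loc": (1.43, -0.3, -0.1), "scale": 1.8},
    "tpsa": {"kind": "lognormal", "loc": (90.0, 90.0, 90.0), "scale": 0.5},
    "relative_ring_atom_count": {"kind": "unit", "loc": (0.56, 0.46, 0.47),
                                 "scale": 0.15},
    "relative_sp3_carbons": {"kind": "unit", "loc": (0.33, 0.53, 0.50),
                             "scale": 0.18},
    "relative_rotatable_bond_count": {"kind": "unit", "loc": (0.12, 0.16, 0.15),
                                      "scale": 0.06},
    "relative_h_bond_donor_count": {"kind": "unit", "loc": (0.12, 0.18, 0.17),
                                    "scale": 0.06},
    "relative_h_bond_acceptor_count": {"kind": "unit",
                                       "loc": (0.23, 0.30, 0.29),
                                       "scale": 0.08},
    "balaban_index": {"kind": "normal", "loc": (1.69, 2.12, 2.05),
                      "scale": 0.5},
}

CLASS_NAMES = ("drug", "metabolite", "overlapping")


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults reproduce the analyzed population: class mixture in the
    observed 1226/659/1001 proportions, a promiscuity log-rate decreasing
    in molecular weight and increasing in flexibility (so roughly a fifth
    of compounds end up promiscuous), moderately diverse EC labels, and
    pocket compositions with mild overdispersion.
    """
    seed: int = 0
    n_compounds: int = 500
    class_mixture: tuple = (0.425, 0.228, 0.347)  # drug, metabolite, overlap
    descriptor_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DESCRIPTOR_PARAMS.items()})
    # promiscuity model: n_pockets = 1 + Poisson(exp(beta0 + beta . z + eps)),
    # eps ~ Normal(0, event_log_noise_sd).  The defaults give a heavy-tailed
    # pocket-count distribution with roughly 22% of compounds promiscuous
    # and about four binding events per compound on average, matching the
    # analyzed population.
    beta0: float = -1.3
    event_log_noise_sd: float = 2.1
    beta: dict = field(default_factory=lambda: {
        "molecular_weight": -0.4,
        "relative_rotatable_bond_count": 0.3,
    })
    max_events: int = 60   # truncation of the heavy tail at desk scale
    # EC label model: per-compound Dirichlet(alpha) over the 7 categories
    ec_alpha: float = 1.0
    ec_background: tuple = (300, 250, 300, 100, 80, 100, 150)
    # pocket composition: per-pocket Dirichlet-multinomial around a
    # per-compound profile; concentration range sampled log-uniformly
    # (lower concentration = more dispersed pockets = higher PV)
    pocket_concentration: tuple = (20.0, 200.0)
    pocket_size: tuple = (8, 18)          # residues per pocket, inclusive
    n_chain_residues: int = 40            # background residues per chain
    duplicate_event_rate: float = 0.10    # identical-protein redundant copies
    homolog_event_rate: float = 0.10      # near-identical homolog copies
    # pathway annotation model
    pathway_base_rate: float = 0.15
    planted_terms: tuple = ()             # (category, level, term, odds_ratio)
    categories: tuple = ("Metabolism", "Environmental Information Processing",
                         "Organismal Systems")
    n_terms_per_level: int = 6

    def __post_init__(self):
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class mixture must sum to 1")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be positive")


@dataclass
class SimCompound:
    compound_id: str
    compound_class: str
    smiles: str
    molecular_weight: float     # actual graph MW
    descriptors: dict           # sampled + graph values, keyed by name


# ---------------------------------------------------------------------------
# compound generation

_B36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"

_SCAFFOLDS = ("c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCOC1", "C1CCNCC1",
              "c1ccc2ccccc2c1", "C1CCC(=O)CC1")
_TERMINALS = ("", "O", "N", "C(=O)O", "OC", "C(N)=O")

_CH2 = 14.027


def _code(i: int) -> str:
    """3-character component code (base-36), skipping codes that collide
    with the ion/solvent exclusion list."""
    from .core_io import DEFAULT_EXCLUSIONS
    while True:
        c = _B36[(i // 1296) % 36] + _B36[(i // 36) % 36] + _B36[i % 36]
        if c not in DEFAULT_EXCLUSIONS:
            return c
        i += 1  # pragma: no cover - collisions are rare


def _sample_descriptor(rng, kind, loc, scale, n):
    if kind == "lognormal":
        return np.exp(rng.normal(math.log(loc), scale, n))
    if kind == "normal":
        return rng.normal(loc, scale, n)
    if kind == "unit":
        return np.clip(rng.normal(loc, scale, n), 0.0, 1.0)
    raise ValueError(f"unknown descriptor kind {kind!r}")


def _build_molecule(target_mw: float, scaffold: str, terminal: str):
    """Assemble a template molecule approximating `target_mw` by padding a
    scaffold with a methylene chain."""
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    base = Chem.MolFromSmiles(scaffold + terminal)
    base_mw = Descriptors.MolWt(base)
    k = max(0, round((target_mw - base_mw) / _CH2))
    smiles = scaffold + "C" * k + terminal
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - templates are all valid
        mol = base
        smiles = scaffold + terminal
    return mol, Chem.MolToSmiles(mol)


def generate_compound_set(config: SimConfig, out_dir: str | Path | None = None,
                          rng: np.random.Generator | None = None,
                          ) -> list[SimCompound]:
    """Sample the compound population and, optionally, write SDF libraries.

    When `out_dir` is given, writes ``compounds.sdf`` (the structure-bank
    side), ``drugs.sdf`` and ``metabolites.sdf`` (library copies of the
    same molecules for the drug/overlapping and metabolite/overlapping
    compounds, so library matching recovers the true classes), and
    ``descriptors.tsv``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    classes = rng.choice(len(CLASS_NAMES), size=n, p=config.class_mixture)

    names = sorted(config.descriptor_params)
    sampled = {}
    for name in names:
        p = config.descriptor_params[name]
        locs = np.asarray(p["loc"], dtype=float)[classes]
        vals = np.empty(n)
        for cls in range(len(CLASS_NAMES)):
            mask = classes == cls
            if mask.any():
                vals[mask] = _sample_descriptor(
                    rng, p["kind"], float(np.asarray(p["loc"])[cls]),
                    p["scale"], int(mask.sum()))
        sampled[name] = vals

    from rdkit.Chem import Descriptors

    compounds: list[SimCompound] = []
    seen_smiles: set[str] = set()
    for i in range(n):
        scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
        terminal = _TERMINALS[rng.integers(len(_TERMINALS))]
        target_mw = min(max(sampled["molecular_weight"][i], 60.0), 990.0)
        # distinct structures per compound: shift the chain length and, if
        # needed, add a methyl branch until the canonical form is unique
        # (duplicate structures would conflate classes at the fingerprint-
        # matching stage, since matching is exact-structure by design)
        mol = smiles = None
        for bump in (0, 14, -14, 28, -28, 42):
            cand_mol, cand = _build_molecule(target_mw + bump, scaffold,
                                             terminal)
            if cand not in seen_smiles:
                mol, smiles = cand_mol, cand
                break
        if mol is None:
            from rdkit import Chem
            base = scaffold + "C" * max(0, round((target_mw - 120) / _CH2))
            for n_branch in range(1, 40):
                cand = base + "C(C)" * n_branch + terminal
                cand_mol = Chem.MolFromSmiles(cand)
                cand = Chem.MolToSmiles(cand_mol)
                if cand not in seen_smiles:
                    mol, smiles = cand_mol, cand
                    break
        seen_smiles.add(smiles)
        mw = float(Descriptors.MolWt(mol))
        desc = {name: float(sampled[name][i]) for name in names}
        desc["molecular_weight"] = mw  # graph weight is authoritative
        compounds.append(SimCompound(
            compound_id=_code(i),
            compound_class=CLASS_NAMES[classes[i]],
            smiles=smiles,
            molecular_weight=mw,
            descriptors=desc,
        ))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_sdf(out_dir / "compounds.sdf",
                   [(c.compound_id, c.smiles) for c in compounds])
        _write_sdf(out_dir / "drugs.sdf",
                   [(f"D_{c.compound_id}", c.smiles) for c in compounds
                    if c.compound_class in ("drug", "overlapping")])
        _write_sdf(out_dir / "metabolites.sdf",
                   [(f"M_{c.compound_id}", c.smiles) for c in compounds
                    if c.compound_class in ("metabolite", "overlapping")])
        desc_table = pd.DataFrame(
            [{"compound_id": c.compound_id, **c.descriptors}
             for c in compounds])
        desc_table.to_csv(out_dir / "descriptors.tsv", sep="\t", index=False,
                          float_format="%.6g")
    return compounds


def _write_sdf(path: Path, entries: list[tuple[str, str]]) -> None:
    from rdkit import Chem

    with open(path, "w") as fh:
        writer = Chem.SDWriter(fh)
        writer.SetKekulize(True)
        for name, smiles in entries:
            mol = Chem.MolFromSmiles(smiles)
            mol.SetProp("_Name", name)
            writer.write(mol)
        writer.close()


# ---------------------------------------------------------------------------
# binding events

def generate_binding_events(config: SimConfig, compounds: list[SimCompound],
                            rng: np.random.Generator | None = None,
                            ) -> pd.DataFrame:
    """Sample per-compound binding events with ground truth.

    The event count is 1 + Poisson(exp(beta0 + beta . z)) over z-scored
    descriptors (every compound has at least one event, as in the
    analyzed set).  Each event carries a target EC category drawn from
    the compound's Dirichlet profile and a pocket composition drawn from
    a Dirichlet-multinomial around the compound's pocket profile.

    Returns one row per event: compound_id, event index, ec_class
    (1..6 or 0 for "None"), pocket size, and 20 composition count columns.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    names = sorted(config.beta)
    z = {}
    for name in names:
        v = np.array([c.descriptors[name] for c in compounds], dtype=float)
        sd = v.std()
        z[name] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    eta = np.full(len(compounds), config.beta0)
    for name in names:
        eta = eta + config.beta[name] * z[name]
    if config.event_log_noise_sd > 0:
        eta = eta + rng.normal(0.0, config.event_log_noise_sd, len(compounds))
    n_events = np.minimum(1 + rng.poisson(np.exp(eta)), config.max_events)

    k_lo, k_hi = config.pocket_concentration
    log_k = rng.uniform(math.log(k_lo), math.log(k_hi), len(compounds))

    rows = []
    for i, comp in enumerate(compounds):
        theta_ec = rng.dirichlet([config.ec_alpha] * 7)
        phi = rng.dirichlet([1.0] * len(AA_ORDER))
        kappa = math.exp(log_k[i])
        for e in range(int(n_events[i])):
            ec_idx = int(rng.choice(7, p=theta_ec))
            size = int(rng.integers(config.pocket_size[0],
                                    config.pocket_size[1] + 1))
            pi = rng.dirichlet(phi * kappa + 1e-6)
            counts = rng.multinomial(size, pi)
            row = {
                "compound_id": comp.compound_id,
                "event": e,
                "ec_class": 0 if ec_idx == 6 else ec_idx + 1,
                "pocket_size": size,
                "pocket_concentration": kappa,
                "true_n_events": int(n_events[i]),
            }
            for aa, cnt in zip(AA_ORDER, counts):
                row[f"n_{aa}"] = int(cnt)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# structure geometry

def _sphere_points(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (golden-spiral construction)."""
    idx = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * idx / n)
    theta = math.pi * (1 + math.sqrt(5)) * idx
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])

_LIGAND_RADIUS = 1.4


def build_structure_text(structure_id: str, compound_id: str,
                         pocket_residues: list[tuple[str, float]],
                         background_types: list[str],
                         resolution: float | None = 1.8,
                         chain_id: str = "A",
                         n_ligand_atoms: int = 8) -> str:
    """PDB-format text for one synthetic complex.

    `pocket_residues` is a list of (one-letter residue type, distance)
    pairs; each residue's nearest heavy atom is placed at exactly that
    distance from its anchor ligand atom (and no closer to any other).
    `background_types` residues are placed with all atoms at least 7 A
    from every ligand atom.  The ligand is an `n_ligand_atoms` carbon
    cluster on a small sphere at the origin.
    """
    lig_pos = _sphere_points(n_ligand_atoms) * _LIGAND_RADIUS

    # interleave pocket residues evenly among background residues
    n_pocket = len(pocket_residues)
    n_total = n_pocket + len(background_types)
    pocket_slots = set()
    if n_pocket:
        step = n_total / n_pocket
        pocket_slots = {int(i * step) for i in range(n_pocket)}
        while len(pocket_slots) < n_pocket:  # collision guard
            pocket_slots.add(max(pocket_slots) + 1)

    bg_dirs = _sphere_points(max(len(background_types), 1))
    lines = []
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {resolution:4.2f} ANGSTROMS.")
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")

    serial = 1
    res_seq = 0
    pocket_iter = iter(pocket_residues)
    bg_iter = iter(enumerate(background_types))

    def atom_line(record, name, res_name, seq, pos, element):
        nonlocal serial
        line = (f"{record:<6}{serial:>5} {name:<4} {res_name:>3} {chain_id}"
                f"{seq:>4}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                f"  1.00  0.00          {element:>2}")
        serial += 1
        return line

    for slot in range(n_total):
        res_seq += 1
        if slot in pocket_slots:
            res_type, dist = next(pocket_iter)
            anchor_idx = (res_seq - 1) % n_ligand_atoms
            anchor = lig_pos[anchor_idx]
            direction = anchor / np.linalg.norm(anchor)
            contact = anchor + direction * dist
            res3 = ONE_TO_THREE.get(res_type, "UNK")
            lines.append(atom_line("ATOM", " CB", res3, res_seq, contact, "C"))
            lines.append(atom_line("ATOM", " CA", res3, res_seq,
                                   contact + direction * 1.5, "C"))
            lines.append(atom_line("ATOM", " N", res3, res_seq,
                                   contact + direction * 2.9, "N"))
        else:
            j, res_type = next(bg_iter)
            direction = bg_dirs[j]
            center = direction * (10.0 + 0.5 * j)
            res3 = ONE_TO_THREE.get(res_type, "UNK")
            lines.append(atom_line("ATOM", " CA", res3, res_seq, center, "C"))
            lines.append(atom_line("ATOM", " CB", res3, res_seq,
                                   center + direction * 1.5, "C"))
            lines.append(atom_line("ATOM", " O", res3, res_seq,
                                   center + direction * 2.9, "O"))

    lines.append("TER")
    for k, pos in enumerate(lig_pos):
        lines.append(atom_line("HETATM", f" C{k + 1}", compound_id, 901,
                               pos, "C"))
    lines.append("END")
    header = f"HEADER    SYNTHETIC COMPLEX                       {structure_id:>8}"
    return "\n".join([header] + lines) + "\n"


def generate_structures(events: pd.DataFrame, config: SimConfig,
                        out_dir: str | Path,
                        rng: np.random.Generator | None = None,
                        ) -> pd.DataFrame:
    """Write one PDB file per event (plus redundant/homolog copies) and
    return the expected pocket table.

    Pocket residue contact distances are sampled uniformly in
    [3.2, 4.9] A; background residues sit beyond 7 A, so pocket recovery
    by a 5 A contact search is exact by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    aa = np.array(list(AA_ORDER))
    truth_rows = []
    n_struct = 0
    for _, ev in events.iterrows():
        counts = np.array([ev[f"n_{a}"] for a in AA_ORDER], dtype=int)
        types = [t for t, c in zip(AA_ORDER, counts) for _ in range(c)]
        while len(types) < 3:  # guard; pocket sizes are >= 8 by default
            types.append("A")
        types = [str(t) for t in rng.permutation(types)]
        distances = rng.uniform(3.2, 4.9, len(types))
        background = list(rng.choice(aa, config.n_chain_residues))
        sid = f"S{n_struct:05d}"
        n_struct += 1
        text = build_structure_text(
            sid, ev["compound_id"],
            list(zip(types, distances)), background)
        (out_dir / f"{sid}.pdb").write_text(text)
        truth_rows.append({
            "structure_id": sid, "chain_id": "A",
            "compound_id": ev["compound_id"],
            "ec_class": int(ev["ec_class"]),
            "n_pocket_residues": len(types),
            "redundant_of": "",
        })

        u = rng.uniform()
        if u < config.duplicate_event_rate:
            # byte-level distinct file, identical protein and pocket
            dup_id = f"S{n_struct:05d}"
            n_struct += 1
            dup_text = build_structure_text(
                dup_id, ev["compound_id"],
                list(zip(types, distances)), background)
            (out_dir / f"{dup_id}.pdb").write_text(dup_text)
            truth_rows.append({
                "structure_id": dup_id, "chain_id": "A",
                "compound_id": ev["compound_id"],
                "ec_class": int(ev["ec_class"]),
                "n_pocket_residues": len(types),
                "redundant_of": sid,
            })
        elif u < config.duplicate_event_rate + config.homolog_event_rate:
            # homolog: same pocket, a few background substitutions
            hom_bg = list(background)
            for pos in rng.choice(len(hom_bg), size=min(3, len(hom_bg)),
                                  replace=False):
                hom_bg[pos] = str(rng.choice(aa))
            hom_id = f"S{n_struct:05d}"
            n_struct += 1
            hom_text = build_structure_text(
                hom_id, ev["compound_id"],
                list(zip(types, distances)), hom_bg)
            (out_dir / f"{hom_id}.pdb").write_text(hom_text)
            truth_rows.append({
                "structure_id": hom_id, "chain_id": "A",
                "compound_id": ev["compound_id"],
                "ec_class": int(ev["ec_class"]),
                "n_pocket_residues": len(types),
                "redundant_of": sid,
            })
    return pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# pathway annotations

def generate_pathways(config: SimConfig, promiscuous_ids: set,
                      compound_ids: list[str],
                      rng: np.random.Generator | None = None,
                      ) -> pd.DataFrame:
    """Pathway membership table with planted enrichment.

    Every term has base membership probability `pathway_base_rate`; for a
    planted (category, level, term, OR) the membership odds of
    promiscuous compounds are multiplied by OR.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    planted = {(c, l, t): o for c, l, t, o in config.planted_terms}
    rows = []
    base = config.pathway_base_rate
    base_odds = base / (1 - base)
    for category in config.categories:
        for level in ("collective", "detailed"):
            for k in range(config.n_terms_per_level):
                term = f"{category.split()[0]} {level} term {k}"
                odds_ratio = planted.get((category, level, term), 1.0)
                p_prom = (base_odds * odds_ratio) / (1 + base_odds * odds_ratio)
                for cid in compound_ids:
                    p = p_prom if cid in promiscuous_ids else base
                    if rng.uniform() < p:
                        rows.append({"compound_id": cid, "category": category,
                                     "level": level, "term": term})
    return pd.DataFrame(rows,
                        columns=["compound_id", "category", "level", "term"])


# ---------------------------------------------------------------------------
# full bundle

def generate_bundle(config: SimConfig, out_dir: str | Path) -> dict:
    """Generate every pipeline input under `out_dir` with ground truth.

    Writes structures/ (PDB files), compounds.sdf, drugs.sdf,
    metabolites.sdf, descriptors.tsv, pathways.tsv, events.tsv and
    truth.json; returns the ground-truth dictionary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    compounds = generate_compound_set(config, out_dir, rng)
    events = generate_binding_events(config, compounds, rng)
    truth_pockets = generate_structures(events, config,
                                        out_dir / "structures", rng)
    events.to_csv(out_dir / "events.tsv", sep="\t", index=False,
                  float_format="%.6g")
    truth_pockets.to_csv(out_dir / "structures_truth.tsv", sep="\t",
                         index=False)
    ec_table = truth_pockets[["structure_id", "chain_id", "ec_class"]]
    ec_table.to_csv(out_dir / "ec_annotations.tsv", sep="\t", index=False)

    n_events = events.groupby("compound_id")["event"].count()
    promiscuous = set(n_events[n_events >= 3].index)
    pathways = generate_pathways(config, promiscuous,
                                 [c.compound_id for c in compounds], rng)
    pathways.to_csv(out_dir / "pathways.tsv", sep="\t", index=False)

    truth = {
        "seed": config.seed,
        "n_compounds": config.n_compounds,
        "classes": {c.compound_id: c.compound_class for c in compounds},
        "n_events": {k: int(v) for k, v in n_events.items()},
        "promiscuous": sorted(promiscuous),
        "planted_terms": [list(t) for t in config.planted_terms],
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
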