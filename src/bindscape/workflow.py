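"""End-to-end orchestration: ingest -> pockets -> redundancy reduction ->
annotation -> promiscuity labels -> propensity statistics -> target
diversity -> prediction models -> pathway enrichment.

Every stage writes a flat TSV with a header so any stage is independently
re-runnable and auditable; the consolidated report records every
dropped-record count, so each ingested compound is accounted for exactly
once (classified, unassigned, or dropped with a reason).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, binding_stats, diversity, enrichment, models
from . import core_io, pockets as pockets_mod, redundancy
from ._aa import AA_ORDER

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    structures_dir: str
    compounds_sdf: str
    drug_libs: list = field(default_factory=list)
    metabolite_libs: list = field(default_factory=list)
    descriptor_table: str | None = None
    pathway_table: str | None = None
    ec_table: str | None = None
    out_dir: str = "bindscape_out"
    max_resolution: float = 2.0
    min_mw: float = 30.0
    max_mw: float = 1000.0
    contact_cutoff: float = 5.0
    min_pocket_residues: int = 3
    bc_cutoff: float = 0.3
    identity_cutoff: float = 0.30
    length_coverage: float = 0.95
    mw_tolerance: float = 1.0
    tanimoto_min: float = 0.95
    promiscuity_min_pockets: int = 3
    n_bins: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("max_resolution", "contact_cutoff", "bc_cutoff",
                     "identity_cutoff", "mw_tolerance", "tanimoto_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.promiscuity_min_pockets < 2:
            raise ValueError("promiscuity threshold must be >= 2")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _ingest(config: PipelineConfig, report: dict):
    sdir = Path(config.structures_dir)
    paths = sorted(list(sdir.glob("*.pdb")) + list(sdir.glob("*.cif")))
    if not paths:
        raise StageError("ingest", f"no structure files in {sdir}")
    models_all = []
    n_unparsable = 0
    for p in paths:
        try:
            models_all.append(core_io.read_structure(p))
        except core_io.StructureFormatError:
            n_unparsable += 1
    kept = core_io.filter_structures(models_all, config.max_resolution)
    report["structures_total"] = len(paths)
    report["structures_unparsable"] = n_unparsable
    report["structures_resolution_filtered"] = len(models_all) - len(kept)
    report["structures_kept"] = len(kept)
    return kept


def _extract_all_pockets(config: PipelineConfig, structures, report: dict):
    all_pockets = []
    n_ligands = 0
    for model in structures:
        ligands = core_io.identify_ligands(model, config.min_mw,
                                           config.max_mw)
        n_ligands += len(ligands)
        for lig in ligands:
            all_pockets.extend(pockets_mod.extract_pockets(
                model, lig, config.contact_cutoff,
                config.min_pocket_residues))
    report["ligand_instances_admitted"] = n_ligands
    report["pockets_extracted"] = len(all_pockets)
    return all_pockets


def _reduce_redundancy(config: PipelineConfig, structures, all_pockets,
                       report: dict):
    chains = [ch for m in structures for ch in m.chains]
    seq_of = {(ch.structure_id, ch.chain_id): ch.sequence for ch in chains}
    # pocket dedup within (compound, protein); proteins are chains with
    # identical sequences
    groups: dict[tuple[str, str], list] = {}
    for p in all_pockets:
        key = (p.compound_id, seq_of[(p.structure_id, p.chain_id)])
        groups.setdefault(key, []).append(p)
    deduped_by_compound: dict[str, list] = {}
    for (cid, _), plist in sorted(groups.items()):
        deduped_by_compound.setdefault(cid, []).extend(
            redundancy.dedup_pockets(plist, config.bc_cutoff))
    report["pockets_after_dedup"] = sum(map(len, deduped_by_compound.values()))
    events = redundancy.nonredundant_events(
        deduped_by_compound, chains, config.identity_cutoff,
        config.length_coverage)
    report["pockets_nonredundant"] = sum(map(len, events.values()))
    return chains, events


def _annotate(config: PipelineConfig, report: dict):
    pdb_compounds = core_io.read_compound_library(config.compounds_sdf)
    drug_lib = []
    for p in config.drug_libs:
        drug_lib.extend(core_io.read_compound_library(p))
    met_libs = [core_io.read_compound_library(p)
                for p in config.metabolite_libs]
    assignments = {}
    for rec in pdb_compounds:
        assignments[rec.compound_id] = annotation.map_compound(
            rec, drug_lib, met_libs, config.mw_tolerance,
            config.tanimoto_min)
    report["compounds_in_library"] = len(pdb_compounds)
    return pdb_compounds, assignments


def _descriptors(config: PipelineConfig, pdb_compounds):
    vectors = {rec.compound_id: annotation.compute_graph_descriptors(rec)
               for rec in pdb_compounds}
    if config.descriptor_table:
        annotation.load_descriptor_table(config.descriptor_table, vectors)
    rows = [{"compound_id": cid, **vec.as_dict()}
            for cid, vec in sorted(vectors.items())]
    return pd.DataFrame(rows)


def _attach_ec(config: PipelineConfig, chains) -> None:
    if not config.ec_table:
        return
    table = pd.read_csv(config.ec_table, sep="\t")
    ec_of: dict[tuple[str, str], list[int]] = {}
    for _, row in table.iterrows():
        cls = int(row["ec_class"])
        key = (str(row["structure_id"]), str(row["chain_id"]))
        if 1 <= cls <= 6:
            ec_of.setdefault(key, []).append(cls)
    for ch in chains:
        ch.ec_numbers = ec_of.get((ch.structure_id, ch.chain_id), [])


def _summary_table(labels, assignments, events) -> pd.DataFrame:
    """Compounds with >= k non-redundant pockets per class, k = 1..5,
    with the total pocket count in parentheses-style columns."""
    classes = ("drug", "metabolite", "overlapping", "unassigned", "all")
    rows = []
    for k in range(1, 6):
        row = {"min_pockets": k}
        for cls in classes:
            sel = [l for l in labels
                   if l.n_pockets >= k
                   and (cls == "all"
                        or (assignments[l.compound_id].compound_class == cls
                            if l.compound_id in assignments else
                            cls == "unassigned"))]
            row[f"{cls}_compounds"] = len(sel)
            row[f"{cls}_pockets"] = sum(l.n_pockets for l in sel)
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dictionary and writes
    all stage tables under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    try:
        structures = _ingest(config, report)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("ingest", str(exc)) from exc

    try:
        all_pockets = _extract_all_pockets(config, structures, report)
        chains, events = _reduce_redundancy(config, structures, all_pockets,
                                            report)
    except Exception as exc:
        raise StageError("pockets", str(exc)) from exc

    try:
        pdb_compounds, assignments = _annotate(config, report)
        desc_df = _descriptors(config, pdb_compounds)
    except Exception as exc:
        raise StageError("annotate", str(exc)) from exc

    labels = redundancy.classify_promiscuity(
        events, config.promiscuity_min_pockets)
    label_of = {l.compound_id: l.label for l in labels}

    # record conservation over the compound library
    with_events = {l.compound_id for l in labels}
    classified = {cid for cid, a in assignments.items()
                  if a.compound_class != annotation.CLASS_UNASSIGNED}
    report["compounds_with_events"] = len(with_events)
    report["compounds_classified"] = len(classified)
    report["compounds_unassigned"] = len(assignments) - len(classified)
    report["compounds_dropped_no_events"] = len(
        set(assignments) - with_events)

    # ---- stage tables -----------------------------------------------------
    pocket_rows = []
    for cid in sorted(events):
        for p in events[cid]:
            row = {"compound_id": cid, "structure_id": p.structure_id,
                   "chain_id": p.chain_id,
                   "residues": ";".join(f"{s}:{t}" for s, t in p.residues)}
            for aa, c in zip(AA_ORDER, p.composition):
                row[f"n_{aa}"] = int(c)
            pocket_rows.append(row)
    _write(pd.DataFrame(pocket_rows), out / "pockets.tsv")

    label_df = pd.DataFrame([
        {"compound_id": l.compound_id, "n_pockets": l.n_pockets,
         "label": l.label,
         "compound_class": (assignments[l.compound_id].compound_class
                            if l.compound_id in assignments else "unknown")}
        for l in labels])
    _write(label_df, out / "labels.tsv")

    assign_df = pd.DataFrame([
        {"compound_id": cid, "compound_class": a.compound_class,
         "drug_matches": ";".join(a.drug_matches),
         "metabolite_matches": ";".join(a.metabolite_matches)}
        for cid, a in sorted(assignments.items())])
    _write(assign_df, out / "class_assignments.tsv")
    _write(desc_df, out / "descriptors_computed.tsv")

    summary = _summary_table(labels, assignments, events)
    _write(summary, out / "summary.tsv")
    report["summary"] = summary.to_dict(orient="records")

    # ---- propensity profiles ---------------------------------------------
    desc_idx = desc_df.set_index("compound_id")
    prop_rows = []
    analyzed = label_df[label_df["compound_id"].isin(desc_idx.index)]
    for cls in ("all", "drug", "metabolite", "overlapping"):
        sel = analyzed if cls == "all" else analyzed[
            analyzed["compound_class"] == cls]
        if len(sel) < 2 * config.n_bins:
            continue
        lab = sel["label"].to_numpy()
        if (lab == "promiscuous").sum() == 0 or (lab == "selective").sum() == 0:
            continue
        for prop in annotation.DESCRIPTOR_NAMES:
            vals = desc_idx.loc[sel["compound_id"], prop].to_numpy(float)
            ok = ~np.isnan(vals)
            if ok.sum() < 2 * config.n_bins:
                continue
            try:
                profile = binding_stats.propensity_profile(
                    vals[ok], lab[ok], prop, cls, config.n_bins)
            except ValueError:
                continue
            for b in profile.bins:
                prop_rows.append({
                    "property": prop, "compound_class": cls,
                    "lo": b.lo, "hi": b.hi, "q": b.q, "s": b.s,
                    "propensity": b.propensity,
                    "log10_propensity": b.log10_propensity, "se": b.se})
    _write(pd.DataFrame(prop_rows), out / "propensity_profiles.tsv")

    # ---- composition propensities ----------------------------------------
    comp_rows = []
    flat_pockets = [p for cid in sorted(events) for p in events[cid]]
    groupings = {"all": flat_pockets,
                 "promiscuous": [p for p in flat_pockets
                                 if label_of.get(p.compound_id) == "promiscuous"],
                 "selective": [p for p in flat_pockets
                               if label_of.get(p.compound_id) == "selective"]}
    for cls in ("drug", "metabolite", "overlapping"):
        groupings[cls] = [
            p for p in flat_pockets
            if p.compound_id in assignments
            and assignments[p.compound_id].compound_class == cls]
    for group, plist in groupings.items():
        if not plist:
            continue
        q, s = binding_stats.pocket_background_counts(plist, chains)
        if q.sum() == 0 or s.sum() == 0:
            continue
        for cp in binding_stats.composition_propensity(q, s):
            comp_rows.append({
                "grouping": group, "res_type": cp.res_type, "q": cp.q,
                "s": cp.s, "log10_propensity": cp.log10_propensity,
                "se": cp.se})
    _write(pd.DataFrame(comp_rows), out / "composition_propensities.tsv")

    # ---- target diversity -------------------------------------------------
    _attach_ec(config, chains)
    chain_of = {(ch.structure_id, ch.chain_id): ch for ch in chains}
    bg_sizes = diversity.background_class_sizes(chains)
    div_rows = []
    for cid in sorted(events):
        plist = events[cid]
        targets = []
        seen = set()
        for p in plist:
            key = (p.structure_id, p.chain_id)
            if key not in seen:
                seen.add(key)
                targets.append(chain_of[key])
        ec_res = diversity.ec_entropy(targets, bg_sizes, cid)
        pv_res = diversity.pocket_variability(plist, cid)
        if ec_res is None and pv_res is None:
            continue
        div_rows.append({
            "compound_id": cid,
            "ec_entropy": ec_res.entropy if ec_res else math.nan,
            "pocket_variability": pv_res.pv if pv_res else math.nan,
            "n_targets": len(targets), "n_pockets": len(plist)})
    div_df = pd.DataFrame(div_rows)
    _write(div_df, out / "diversity.tsv")

    # ---- prediction models ------------------------------------------------
    model_rows = []
    feature_cols = [c for c in desc_idx.columns
                    if desc_idx[c].notna().all()]
    model_df = label_df[label_df["compound_id"].isin(desc_idx.index)].copy()
    X = desc_idx.loc[model_df["compound_id"], feature_cols]
    y_logn = np.log10(model_df["n_pockets"].to_numpy(float))
    try:
        fit = models.fit_plsr(X, y_logn, "log10_pocket_count",
                              seed=config.seed)
        model_rows.append({"model": "plsr", "target": "log10_pocket_count",
                           "n_components": fit.n_components, "r": fit.r,
                           "n": fit.n_samples})
    except ValueError as exc:
        log.info("PLSR pocket count skipped: %s", exc)
    if len(div_df) and div_df["ec_entropy"].notna().sum() >= 20:
        sub = div_df[div_df["ec_entropy"].notna()]
        try:
            fit = models.fit_plsr(
                desc_idx.loc[sub["compound_id"], feature_cols],
                sub["ec_entropy"].to_numpy(float), "ec_entropy",
                seed=config.seed)
            model_rows.append({"model": "plsr", "target": "ec_entropy",
                               "n_components": fit.n_components,
                               "r": fit.r, "n": fit.n_samples})
        except ValueError as exc:
            log.info("PLSR EC entropy skipped: %s", exc)
    try:
        svm_fit = models.fit_svm_promiscuity(
            X, model_df["label"].to_numpy(), seed=config.seed)
        model_rows.append({"model": "svm", "target": "promiscuity",
                           "cv_error": svm_fit.cv_error,
                           "setting": svm_fit.description,
                           "n": len(model_df)})
    except ValueError as exc:
        log.info("SVM skipped: %s", exc)
    cls_df = model_df[model_df["compound_class"].isin(
        ("drug", "metabolite", "overlapping"))]
    if cls_df["compound_class"].nunique() >= 2:
        try:
            cart_fit = models.fit_cart_class(
                desc_idx.loc[cls_df["compound_id"], feature_cols],
                cls_df["compound_class"].to_numpy(), seed=config.seed)
            model_rows.append({"model": "cart", "target": "compound_class",
                               "cv_error": cart_fit.cv_error,
                               "setting": cart_fit.description,
                               "n": len(cls_df)})
        except ValueError as exc:
            log.info("CART skipped: %s", exc)
    _write(pd.DataFrame(model_rows), out / "models.tsv")
    report["models"] = model_rows

    # ---- enrichment --------------------------------------------------------
    if config.pathway_table:
        membership = pd.read_csv(config.pathway_table, sep="\t")
        membership["compound_id"] = membership["compound_id"].astype(str)
        try:
            rows = enrichment.fisher_enrichment(membership, labels)
            _write(enrichment.enrichment_table(rows), out / "enrichment.tsv")
            report["enrichment_terms_tested"] = len(rows)
        except ValueError as exc:
            log.info("enrichment skipped: %s", exc)
            report["enrichment_terms_tested"] = 0

    report["n_promiscuous"] = int((label_df["label"] == "promiscuous").sum())
    report["n_selective"] = int((label_df["label"] == "selective").sum())
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    return report
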