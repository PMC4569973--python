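# Methods

`bindscape` implements a desk-scale, fully testable version of a
structure-based survey of compound–protein binding promiscuity: which
physicochemical properties of small molecules (metabolites, drugs, and
compounds that are both) go along with binding many distinct protein
pockets rather than one or two, and how diverse the targets of
promiscuous compounds are.

## Binding events and pockets

A *binding event* is one co-crystallized, non-covalently bound compound
on one protein chain. Structures are admitted when an X-ray resolution
record is present and ≤ 2.0 Å (the bound is read inclusively). Ligands
are admitted when 30 Da ≤ MW ≤ 1000 Da, the component code is not on the
ion/solvent exclusion list, and no ligand heavy atom lies within 1.9 Å
of a protein heavy atom (the covalency heuristic; 1.9 Å is a standard
ceiling for covalent bond lengths). The shipped exclusion list (water,
MES, DMSO, glycerol, 2-mercaptoethanol, common ions, cryo-agents, …) is
an approximation and user-overridable. Ligand weights are summed over
the atoms present in the model; crystal structures omit hydrogens, so
these weights underestimate the true compound weight by a few percent,
immaterial against the 30–1000 Da window.

The *binding pocket* of a ligand on a chain is the set of residues with
at least one heavy atom within 5.0 Å (closed ball) of any ligand heavy
atom; only contact sets of ≥ 3 residues count as pockets. Pockets are
per-chain: a ligand wedged between two chains yields up to two pockets.
No crystallographic symmetry expansion is applied. Alternate locations
are resolved to the highest-occupancy conformer (ties: file order); only
the first model of multi-model files is read. Nonstandard residues count
toward the 3-residue threshold but contribute nothing to the 20-dim
amino-acid composition vector.

## Redundancy reduction and the promiscuity call

Pockets of one compound on one protein (protein = chains with identical
sequence) are clustered by complete linkage on Bray–Curtis dissimilarity
of their composition vectors,

    d_BC(a, b) = Σ_i |a_i − b_i| / Σ_i (a_i + b_i),   i = 1..20,

cutting the tree at 0.3 (clusters are maximal sets with merge height
≤ 0.3) and keeping one representative per cluster — the pocket with the
most residues, ties broken lexicographically by (structure, chain), so
output is deterministic.

The protein targets of each compound are then clustered at 30% sequence
identity. In place of score-based Blastclust we use global pairwise
alignment (match 2, mismatch −1, gap open −10, extend −1); identity is
identical positions over alignment length, and an edge additionally
requires the aligned region to cover ≥ 95% of at least one partner.
Single-linkage components of this graph are the target clusters; within
each cluster, only the pockets of one member chain (the longest
sequence, ties by identifier) survive. This identity approximation can
split or merge borderline clusters relative to Blastclust's score
coverage; the cutoff semantics are otherwise the same.

A compound with ≥ 3 surviving (non-redundant, non-homologous) pockets is
*promiscuous*; with 1–2, *selective*.

## Propensity statistics

For a descriptor t and compound class c, observed values are split into
equal-count intervals (default 10; quantile-style edges, duplicate edges
merged with a warning). With q_i promiscuous and s_i selective counts in
interval i,

    P_i = f_i / g_i,   f_i = q_i / Σq,   g_i = s_i / Σs,
    se_i = (1/g_i) · sqrt( f_i (1 − f_i) / Σq ),

reported as log₁₀ P_i. The standard-error expression follows the
Levitt-style grouping (1/g_i outside the square root). Binning is
computed on the pooled promiscuous ∪ selective values, so intervals
contain nearly equal compound counts. If any cell of a profile is zero,
0.5 is added to every q_i and s_i (Haldane–Anscombe), flagged per bin;
otherwise the counts are used as observed. Missing descriptor values are
excluded pairwise per property with logged counts.

The same ratio applied to residue-type counts inside pockets (q_i) vs.
chain residues outside every pocket (s_i) gives the amino-acid
compositional propensity of binding pockets, computed for groupings by
compound class and by promiscuity label.

## Target diversity

**EC entropy.** Each target chain contributes one count to each of its
top-level EC classes (1–6), or to "None" if unannotated. Counts c_i are
divided by the background class sizes N_i (sizes of the EC categories
over the full ingested target set, configurable) and normalized to
probabilities; H = −Σ p_i ln p_i. The natural logarithm is used (base
only rescales H; the maximum over 7 categories is ln 7 ≈ 1.95). An
unweighted variant (p_i = c_i/Σc) is available behind a flag. The
target count is a protein count, not a pocket count, and compounds with
fewer than 3 targets are skipped.

**Pocket variability.** For a compound with ≥ 3 pockets,
PV = Σ_i σ_i²/μ_i over residue types with nonzero mean, where σ_i²
(sample variance, n−1 denominator) and μ_i are taken over the pocket
composition counts. PV = 0 iff all pockets share one composition, and
the variance-to-mean form makes PV insensitive to compound size.

## Prediction models

PLSR is fit to log₁₀ pocket count, PV, or EC entropy with standardized
predictors (descriptors span orders of magnitude; standardization is a
declared choice). The component count (≤ 10) minimizes the 10-fold
cross-validated RMSEP; the reported r comes from leave-one-out
predictions at that component count. Components are re-oriented so each
score vector correlates positively with the response; the underlying
NIPALS sign convention is otherwise arbitrary and would make loading
signs meaningless. The SVM promiscuity classifier reports stratified
5-fold CV error per kernel (linear, RBF, polynomial) and the best
kernel. The CART compound-class tree is grown at 3–10 splits
(`max_leaf_nodes` = splits + 1) and the split count with lowest 5-fold
CV error reported. Fold assignment uses a recorded seed.

## Pathway enrichment

Annotation terms live in (category × level) families — categories such
as Metabolism, Environmental Information Processing, Organismal Systems;
levels collective and detailed. The background universe is the full
mapped compound set (every labelled compound appearing anywhere in the
membership table); categories mapping fewer than 20 compounds are
skipped. Per term, a 2×2 table (promiscuous/selective × in/out) is
tested two-sided by Fisher's exact test; Benjamini–Hochberg correction
is applied within each (category, level) family (a global-correction
flag exists). Compounds mapped in a category but to none of its terms
at a given level form a testable "Not assigned" pseudo-term — with the
global universe this is the only reading under which that pseudo-term
has non-empty counts. Enrichment and depletion are both reported via
the odds ratio.

## Synthetic data generator

The generator produces every input the pipeline consumes, with ground
truth, so all stages are testable without external downloads:

* **Compounds** — class mixture 0.425/0.228/0.347
  (drug/metabolite/overlapping, the observed 1226/659/1001 proportions).
  Descriptors are drawn from class-conditional distributions anchored to
  the observed medians (drug MW median 330.2 Da vs. metabolite 238.7 Da,
  logP 1.43 vs. −0.3, relative ring atom count 0.56 vs. 0.46, …);
  size-like quantities are log-normal, indices normal, unit-interval
  descriptors clipped normal. Molecules are assembled from scaffold +
  methylene-chain + terminal templates sized to the sampled weight, with
  a uniqueness pass (chain-length shifts, then methyl branches) because
  exact-structure fingerprint matching would conflate classes across
  duplicate structures. Library SDFs contain copies of the same
  molecules so class mapping recovers the ground truth.
* **Binding events** — pocket count = 1 + Poisson(exp(β₀ + β·z + ε)),
  z the standardized descriptors, ε ~ N(0, σ). Defaults β₀ = −1.3,
  σ = 2.1, β = (MW −0.4, relative rotatable bonds +0.3) reproduce the
  analyzed population: ≈ 22% promiscuous compounds and ≈ 4 binding
  events per compound with a heavy right tail (truncated at 60 events
  per compound as a desk-scale choice). Promiscuity odds fall with
  molecular weight and rise with flexibility.
* **Targets** — per-compound EC profiles from a symmetric Dirichlet(α)
  over the 7 categories (α → 0 concentrates, α large approaches
  uniform); pocket compositions from a Dirichlet–multinomial around a
  per-compound profile, with the concentration sampled log-uniformly per
  compound (lower concentration ⇒ more dispersed pockets ⇒ larger PV).
* **Structures** — one PDB file per event: the ligand is a small carbon
  cluster at the origin; each pocket residue's nearest heavy atom is
  placed at an exact sampled distance (3.2–4.9 Å) from its anchor ligand
  atom along the outward radial direction, which guarantees the nearest
  distance analytically; background residues sit beyond 7 Å. Pocket
  recovery by the 5 Å contact search is therefore exact by construction.
  A fraction of events is duplicated as identical-protein copies
  (exercising pocket dedup) or as homologs with a few background
  substitutions (exercising target clustering); ground-truth event
  counts are invariant to both.
* **Pathways** — every term has a base membership rate; planted terms
  multiply the membership odds of promiscuous compounds by a chosen
  odds ratio.

Everything is driven by one seed and is byte-identical across runs.

What the generator does **not** emulate: real protein folds and packing
(residues are 3-atom clusters on analytic positions), chemically
meaningful ligand poses, sequence families with realistic homology
structure (homologs are point-substituted copies; unrelated chains are
i.i.d. random sequences), correlated descriptors, or database-specific
identifier quirks. Passing tests therefore demonstrate correctness of
the pipeline's logic and calibration of its statistics under known
models — not that the biological conclusions transfer to any particular
structure bank snapshot.

## Numerical choices and degenerate inputs

Distance and dissimilarity boundaries are closed (≤ 5.0 Å contacts,
≤ 0.3 cluster heights, ≤ 2.0 Å resolution). Bray–Curtis on two zero
vectors, empty structure files, empty SDF libraries, single-class model
inputs, constant predictor matrices and sub-threshold target/pocket
counts all raise or skip with logged counts rather than returning
silent values. Tanimoto of two empty fingerprints is defined as 1 with
a warning. Equal-count binning requires at least as many distinct
values as bins. All stage tables are written as TSV with fixed float
formatting, so a rerun under the same seed is byte-identical.

## Problem sizes

The shipped test-suite and acceptance runs use 40–500 compounds with
roughly 2–4 binding events per compound (≈ 100–2,300 structures),
2,000-compound draws for the statistical calibration checks, and
10–50 seed replicates for the stochastic properties; these sizes give
stable pass/fail behaviour for every check while keeping a full run in
minutes on one CPU.

## Known limitations

* The 30%-identity clustering approximates Blastclust's score-based
  coverage; borderline clusters may differ.
* pKa, pI, logP, TPSA and ASA should come from a curated descriptor
  table; the built-in estimators (Crippen logP, RDKit TPSA, Labute ASA,
  SMARTS-group pKa/pI) are crude and intended for synthetic tests only.
* The hashed path fingerprint (1024-bit RDKit linear fingerprint) is a
  stand-in for CDK extended fingerprints; matching behaviour, not
  bit-exactness, is the goal, and isomers can still be conflated — as
  with any 2-D fingerprint matching.
* The "vertex adjacency information" descriptor uses the conventional
  1 + log₂(bond count) magnitude form.
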