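# Methods

## Problem setting

`pcmscreen` implements a proteochemometric (PCM) virtual-screening pipeline
for SGLT-family transporters (solute carrier family 5). The scientific
obstacle it addresses is data heterogeneity: public bioactivity extracts
carry pChEMBL values (−log10 molar potency from Ki/IC50/EC50/Kd), while a
typical in-house single-concentration screen reports percent activity versus
negative control at 50 µM (100 = no inhibition). The two units cannot be
interconverted, so the pipeline classifies instead of regressing, and the
pair of activity cutoffs — one per dialect — becomes a modeling decision
made by grid search.

## Curation

Structures are standardized with RDKit's `rdMolStandardize`: cleanup, then
largest organic fragment (salt stripping), then charge neutralization
(acids protonated, bases deprotonated), then canonical SMILES. The order is
fixed as listed; the whole map is idempotent, which the tests assert on a
fixture panel. Stereo annotations are retained as given — downstream
descriptors are 2-D, so stereoisomer enumeration would add nothing.

Public-dialect records are kept only with curation confidence 7 or 9;
records without a confidence score are dropped, not imputed. Duplicate
(compound, target) measurements are resolved by activity-unit ranking
Ki > IC50 > EC50 > Kd, averaging pChEMBL values within the winning unit.
When the merged dataset carries both dialects for one (compound, target)
pair, the in-house record wins: model validation lives in the in-house
chemical space, so its label is the relevant one. Merging identifies
compounds by canonical SMILES.

## Descriptors

Ligands: 512 FCFP-style fingerprint bits — circular neighborhoods of
diameter 6 (radius 3) over RDKit's pharmacophoric feature invariants
(H-bond donor/acceptor, positive/negative ionizability, aromaticity,
halogen) — folded by hash modulo 512, plus seven physicochemical
properties: molecular weight (Da), ALogP, H-bond acceptors, H-bond donors,
rotatable bonds, bridge bonds (bonds shared by ≥ 2 SSSR rings), and
aromatic rings. ALogP is RDKit's Crippen atom-contribution logP; small
parameterization differences versus other vendors' ALogP implementations
are accepted and not corrected for.

Proteins: the first three Z-scales (z1 lipophilicity, z2 size/bulk, z3
polarity) per residue, from the packaged 20-entry table. Two modes exist:
`per_position_variable` (default) emits (z1, z2, z3) for every alignment
column that is not conserved across the panel, with gaps encoded as
(0, 0, 0) — a deterministic choice preferred over column means;
`sequence_mean` averages the three scales over the non-gap positions.
The pipeline consumes a precomputed alignment (aligned FASTA or Clustal);
it does not run an aligner.

A PCM row is ligand block ∥ protein block for one measured
(compound, target) pair; a QSAR row is the 519-column ligand block alone.

## Labeling and threshold grid search

A record is active iff pChEMBL > cutoff (public) or % control < cutoff
(in-house); both inequalities strict. The default grid spans
pChEMBL ∈ {6.5 … 9.0} × percent ∈ {50 … 90} in steps of 0.5 and 5. For each
cell, a ligand-only random forest is trained on the public primary-target
records plus 70% of the in-house primary-target compounds, labeled by that
cell, and scored by MCC on the held-out 30%. One split, fixed by seed, is
reused for every cell; it is stratified on quartile bins of the continuous
%-control values rather than on labels, so the same split stays balanced
under every candidate cutoff. Ties prefer a higher pChEMBL cutoff, then a
lower percent cutoff (stricter actives). A cell whose training labels
collapse to one class is recorded as degenerate with MCC 0.

## Models and validation

Classifiers are 500-tree random forests (scikit-learn), mtry =
floor(√n_features), other hyperparameters at library defaults and recorded
in a manifest. mtry is computed from the actual column count rather than
hard-coded; a config override exists. The reported class probability is the
fraction of trees voting active (each tree's majority leaf class), the
classical vote semantics; ties at a probability cutoff classify active
(≥). No class weighting is applied; imbalance is logged.

Three CV designs share one set of 5 folds over the in-house primary-target
compounds (stratified random over compounds, not rows, so a compound never
straddles train and test): training on public data only, in-house only, or
both, always excluding every record of a test-fold compound. A fourth
design, `qsar_holdout`, is the single 70/30 ligand-only benchmark used by
the grid search. Metrics are computed with the 0-convention for empty
marginals; `mcc_from_rates` implements the identity
MCC = √(sens·spec·PPV·NPV) − √((1−sens)(1−spec)(1−PPV)(1−NPV)),
exact whenever no marginal is zero (verified against count-form MCC by
exhaustive enumeration of all confusion matrices with total ≤ 30).

## Screening and selection

A trained ensemble scores a standardized library in batches with the
protein block fixed to the target. Candidates pass the prefilter with
probability ≥ 0.8 and molecular weight strictly > 300 Da ("≤ 300 removed"
excludes fragment-like hits). The Diverse set is the k = 40 medoids of a
PAM-style k-medoids clustering (greedy BUILD initialization, alternating
refinement) under 1 − Tanimoto on the fingerprints; medoids are real
compounds, matching the idea of selecting "cluster centers". Analog
(Cluster-set) picks are the top-n survivors by Tanimoto similarity to each
reference inhibitor, ties broken by compound id; analog picks exclude
compounds already taken (Diverse set first, then earlier references), so
the combined pick list is duplicate-free — with the campaign configuration
of 40 + 10 + 10 + 10 + 7 that is 77 unique compounds.

## Chemical-space diagnostics

t-SNE (scikit-learn, PCA initialization, seeded) embeds fingerprints folded
to 2048 bits into two components (CSNE1, CSNE2); perplexity defaults to 30
and requires n > 3·perplexity. Per-source physchem summaries report
mean ± sd of MW, ALogP, HBD, HBA. Binding-mode exploration clusters the
primary-target actives into k = 10 k-medoid clusters; actives here use the
inclusive public cutoff pChEMBL ≥ 6.5 — deliberately weaker than the 8.5
modeling cutoff, to include weak binders — together with % control < 70.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study, not SGLT
pharmacology. An 8-member protein panel is one random root sequence
(default length 500) with i.i.d. substitutions at rate 0.05 per member,
emitted pre-aligned; member-versus-root differences are Binomial(L, rate)
by construction. Compounds come from two fragment grammars:
`glycoside_like` (polyol pyranose and oxopyrrolidine-carboxamide scaffolds;
HBD/HBA-rich, narrow chemotype — the public-set caricature) and `diverse`
(assorted drug-like scaffolds spanning roughly MW 180–450 — the in-house
caricature). Generated SMILES are standardized at generation, so they
survive re-standardization unchanged, and are unique within a dataset.

Activity is planted through substructure rules so fingerprint models can
legitimately learn it: latent potency = baseline 4.3 + matched rule
contributions + a small target modifier (fixed weight · the target's mean
Z-scales) + Gaussian noise. The default rules are an aryl-ethoxy motif
(+4.6, present only in the glycoside grammar, prevalence 0.20) and a
sulfonamide motif (+3.2, only in the diverse grammar, prevalence 0.15 for
the screen, 0.10 for the library). Rule patterns are disjoint from the
grammars' common scaffold atoms, so labels cannot leak through gross
composition alone. The public dialect reports pChEMBL = clip(latent + ε,
4, 10) with ε ~ N(0, 0.3) and confidence 9, on two random panel targets per
compound; the in-house dialect reports % control = clip(100 − g(latent + ε))
on the first two panel targets, ε ~ N(0, 0.8), with g a logistic scaled to
(0, 100) with slope 0.8 latent units — a monotone, bounded link mirroring a
single-concentration readout.

The logistic midpoint realizes the configured planted threshold t (default
70): the mean active-class latent maps to percent t − 5, half a default
grid step below t, which makes t the tightest cutoff enclosing the active
class. Cutoffs above t relabel nothing (the inactive class sits far above),
so they tie with t and the tie-break resolves to t; the cutoff below t
truncates the active class and scores strictly worse. At the default noise
(sd 0.8) the active class deliberately straddles the threshold — labels
carry realistic single-concentration noise, and cross-validated MCC on
default data lands near 0.3–0.6, the regime the method actually operates
in; the threshold-recovery test instead uses a low-noise planting
(sd 0.05) where the planted cutoff is sharply identified. Passing tests on
these data show the pipeline recovers substructure-driven signal and
rejects out-of-domain transfer; they do not show anything about real SGLT
assay data, whose noise structure, chemotype overlap and activity cliffs
are not modeled.

## Problem sizes and numerics

Default synthetic conditions: 300 public compounds (600 records over 8
targets), 750 in-house compounds (1,500 records over 2 targets), 500-
compound library. Recovery tests run 10 seeds at these sizes with the full
500-tree forests; the threshold grid search inside tests uses 100-tree
benchmark forests, a deliberate benchmark-size choice that only adds vote
noise to the quantity under test. k-medoids is deterministic given its
seed (randomness only breaks exact cost ties); t-SNE coordinates are
bit-reproducible for a fixed seed and library version, which the run
manifest records. Degenerate inputs fail loudly and early: single-class
training raises, perplexity too large for n raises, unresolvable references
are listed by id, unparseable library structures are logged, counted and
skipped.

## Known limitations

- The fragment grammars cover a narrow slice of chemistry; absolute
  descriptor distributions are not representative of vendor libraries.
- The %-control link g is a convenience; real single-concentration
  readouts saturate and have compound-specific artifacts (aggregation,
  fluorescence interference) that are not modeled.
- k-medoids with BUILD + alternation is a heuristic; it does not guarantee
  the PAM swap optimum, only a deterministic, well-spread medoid set.
- Protein descriptors assume a trusted alignment; alignment errors
  propagate silently into the positional Z-scale block.
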