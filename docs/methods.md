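# Methods

## Problem and scope

`cdk9screen` implements a ligand-based virtual-screening workflow for
CDK9 inhibitor discovery as a tested, reusable pipeline.  The workflow
is classification-based: heterogeneous bioactivity records are curated
into labeled, class-balanced train/test datasets; compounds are encoded
in seven molecular representations; a zoo of 35 models per labeling
scheme (5 algorithms x 7 representations) is tuned and ranked by the
Matthews correlation coefficient; the best model assigns a probability
score (PS) to every compound of a screening library; and hits are
reduced to a structurally diverse purchase list by average-linkage
Tanimoto clustering.  A synthetic-data module supplies all inputs, so
the full pipeline runs and is validated without any external database.

## Structure standardization

All compounds — training, test, decoy and screening — pass one
protocol (`standardize`):

1. **Salt stripping.** The parent is the fragment with the most heavy
   atoms; ties break by molecular weight, then by lexicographically
   smallest canonical SMILES.
2. **Ionization at pH 7.4** by an explicit rule table: carboxylic,
   sulfonic and phosphonic acids and tetrazoles are deprotonated;
   aliphatic primary/secondary/tertiary amines, amidines and guanidines
   are protonated; anilines, amides, sulfonamides and aromatic
   N-heterocycles stay neutral.  Phosphonic/phosphoric centers lose a
   single proton (the second pKa sits near 7.4, so the mono-anion is
   the representative species); centers already carrying an anionic
   oxygen are skipped, which makes the transform idempotent.  The table
   reproduces the dominant pH-7.4 species for drug-like chemistry and
   is fully testable; it does not attempt pKa prediction or tautomer
   canonicalization.
3. **Canonicalization.** The canonical SMILES of the ionized parent is
   the deduplication key (`std_key`).  Stereochemistry is retained, so
   enantiomers remain distinct records.

Unparseable or empty structures are rejected with a reason code and
written to a reject log; nothing is dropped silently.

## Curation funnel

`datasets` turns an activity table (compound, SMILES, activity type,
relation, value, unit) into balanced datasets:

* Only exact ("=") IC50/EC50/Ki/Kd records with known units
  ({nM, uM, M} — anything else is a reject, not a guess) enter the
  measured pool; censored (">") records go to a side pool.
  pActivity = -log10(molar value).
* IC50 records train; EC50/Ki/Kd records test.  A compound measured
  both ways keeps only its IC50 record, enriching the training set.
* One record per `std_key`; multiple exact values collapse to the
  **median** pActivity (robust to outliers, order-independent).
  Structures appearing in both pools stay in training only.
* Two labeling schemes: Lead-Oriented (active pActivity >= 6.0,
  inactive <= 5.30) and Potency-Oriented (active >= 7.5, inactive
  <= 5.5).  Both boundaries are inclusive; the exclusion window between
  them is dropped to avoid boundary ambiguity.
* Censored records certify inactivity when the reported bound reaches
  the scheme's inactivity concentration (5 uM for LO, 3.2 uM for PO,
  inclusive).
* Decoys (presumed-inactive, drug-like) are standardized identically,
  deduplicated against measured compounds, and sampled uniformly
  without replacement — train first, then test from the remainder —
  until classes are exactly balanced.  A pool too small is a hard
  error naming the stage.  Should a split carry an inactive majority
  before balancing (possible by sampling noise near the class
  boundary), the excess inactives are uniformly down-sampled (seeded)
  to the active count and the drop is recorded in the funnel report,
  so every emitted dataset is perfectly balanced either way.

A funnel report accounts for every input record (retained, rejected,
window-excluded, censored-used/discarded), and conservation is asserted
in tests on every synthetic run.

## Molecular representations

| kind        | length | content                                        |
|-------------|--------|------------------------------------------------|
| path_fp     | 1024   | hashed atom-bond-path (subgraph) fingerprint   |
| morgan_fp   | 1024   | radius-2 hashed circular fingerprint           |
| dict_fp     | 881    | substructure-key dictionary fingerprint        |
| descriptors | 208    | physicochemical descriptors, min-max scaled    |
| hybridRR    | 1232   | path_fp ++ scaled descriptors                  |
| hybridMR    | 1232   | morgan_fp ++ scaled descriptors                |
| hybridPR    | 1089   | dict_fp ++ scaled descriptors                  |

The 881-key dictionary is a package convention shipped as a versioned
TSV (`data/substructure_keys.tsv`), mixing element-count thresholds,
ring-count thresholds (size, aromaticity, heteroatom content) and SMARTS
substructure keys (curated functional groups, bonded element pairs and
triples), generated deterministically by `cdk9screen._keygen`.  The 208
descriptors are pinned in `data/descriptor_manifest.txt`; the loader
fails loudly if the installed toolkit drifts from the manifest.
Non-finite descriptor values are imputed with the training median.

The min-max scaler is **fitted on the training split only** and frozen
for test and screening compounds (values outside the training range
clip to [0,1]; constant training features map to 0).  Fitting on the
full dataset would leak test information into the representation.

Tanimoto similarity T = s/(a+b-s) applies to binary fingerprints
(T = 0 when both vectors are empty); the inner-product generalization
K = <x,y>/(<x,x>+<y,y>-<x,y>) serves as the SVM kernel and reduces to T
on binary input.

## Model zoo

Hyperparameter grids (cardinalities 6/5/14/5/12):

* **RF** — trees in {100, 500} x features-per-split in {all, sqrt, log2}
* **SVM** — kernel in {linear, poly, rbf, sigmoid, Tanimoto}
* **KNN** — k in {3,5,...,15} x weighting in {uniform, distance}
* **GP** — kernel in {DotProduct, RationalQuadratic, Matern,
  WhiteKernel, RBF}
* **MLP** — {2,3} layers x uniform width {100,200,1000} x batch
  {100,200}, ReLU activation

Design choices where the design was open: the MLP architecture grid is
read as a uniform width per network (the smallest grid consistent with
"combinations of layers and widths"); MLP training uses the adam
optimizer with a fixed 150-epoch cap; the Tanimoto kernel is offered to
the SVM only; SVM probability scores come from Platt-style sigmoid
calibration fitted within training folds (support vector machines are
not natively probabilistic); GP scores are the posterior class
probability.

Grid search evaluates every point by stratified 5-fold CV (80/20
splits) on the training set only, with a tuning seed independent of the
assessment folds, and maximizes mean MCC.  Exact ties resolve to the
earlier grid point; grids are declared in increasing complexity order,
so ties go to fewer trees / smaller k / narrower networks.  The winning
configuration is assessed by a second 5-fold CV, refit on the complete
training set, and evaluated once on the held-out test set.  Grid search
and CV never see the test split.  Degenerate folds (a class smaller
than the fold count) are refused with a message.

## Evaluation

MCC, precision and recall are computed from the confusion matrix at
the strict active call PS > t (a score exactly at threshold is called
inactive).  Degenerate denominators: MCC = 0 when any factor under the
root is zero; precision/recall = 0 on 0/0.  The threshold sweep runs
t = 0.50 to 0.90 in steps of 0.05 (the grid granularity is an artifact
default) and reports the smallest threshold with perfect precision.
Models are ranked by test MCC, ties by precision, recall, then
lexicographic name, so the table is independent of input order.

## Screening and diversity selection

Libraries are standardized with the training protocol (rejects logged,
never fatal), scored in batches (batching is memory-only; results are
batch-size-invariant), and filtered with the **inclusive** comparator
PS >= 0.8 — the evaluation sweep uses strict >, the hit filter uses >=,
and both comparators are explicit configuration.  Hits are clustered by
agglomerative average linkage on d = 1 - T over path fingerprints with
the dendrogram cut at 0.30.  The agglomerator is written out explicitly
(Lance-Williams update) so that exact-tie merges are deterministic —
lowest-index pair first — independent of input order; it is checked in
tests against an exhaustive reference agglomerator on all small
instances and against scipy's implementation on tie-free ones.  Average
linkage is monotone, so merging until the closest pair exceeds the
cutoff equals cutting the full dendrogram at that height.  Each cluster
contributes its highest-PS commercially available member (ties by
compound id); clusters with no available member are logged and skipped,
which is why representatives can be fewer than clusters.

## Synthetic study conditions

The generator emulates a ChEMBL-like extract, a ZINC-like decoy set and
a vendor catalogue.  Compounds are assembled from a fixed
scaffold-decoration grammar (8 ring cores, 6 linkers, 12 substituents);
a configurable fraction carry one of three planted "pharmacophores"
(4-aminoquinazoline, 2-aminobenzothiazole, morpholine-4-sulfonyl) that
the plain grammar cannot produce, so carrier status is
substructure-checkable and decoys are guaranteed carrier-free.

Defaults (the package's study conditions): 60% carriers; carrier
potency ~ Normal(8.0, 0.6) on the pActivity scale (~10 nM, a typical
potent-inhibitor series), non-carriers ~ Normal(4.5, 0.6) (~32 uM),
i.e. a separation of ~5.8 sigma; ~80% IC50 records, the rest split over
EC50/Ki/Kd; 10% of weak compounds censored as "> 10 uM"; 10% salt
forms; 5% duplicate entries under a second activity type; ~30% of
records reported in uM.  The carrier mean is set high enough that both
schemes keep actives in the majority before decoy balancing; at very
small library sizes (n around 100) sampling noise can still violate
that precondition, which the funnel reports as a hard error.

What the generator does *not* emulate: real medicinal-chemistry SAR,
activity cliffs, correlated assay noise, inter-lab variability, or the
actual chemical space of public databases.  Passing the acceptance
suite therefore demonstrates that the pipeline recovers a clean planted
structure-activity signal and that every bookkeeping invariant holds —
not that the models would reach comparable MCC on real bioactivity
data.

## Problem sizes and numerical choices

The acceptance computations use a 2000-compound activity library with a
2500-compound decoy pool for signal recovery (full RF and GP grids),
and a 600-compound library with single-point reduced grids for the
end-to-end campaign over a 10,000-compound screening library — sizes
chosen so the whole suite runs comfortably on a single CPU while the
derived datasets stay in the regime where a 5-fold stratified split is
well-defined for every grid point.  Tolerances: metric-formula
equivalence to independent oracles is asserted at 1e-12; Tanimoto
kernel PSD at -1e-8 on the smallest eigenvalue; scaler inverse
round-trip at 1e-9.  All stochastic components (generator, decoy
sampling, fold shuffling, RF bootstrap, MLP init) consume named seeds,
and every pipeline output is a deterministic function of them.

## Known limitations

* The ionization rule table covers dominant drug-like chemistry only;
  it is not a pKa model (no zwitterion equilibria beyond rule
  composition, no tautomers).
* The 881-key dictionary is a stand-in convention: lengths and
  semantics match the substructure-key fingerprint family, but key
  identities differ from any database's canonical list.
* The naive O(n^3) agglomerator is intended for hit lists (hundreds to
  a few thousand compounds), not whole libraries.
* GP with the WhiteKernel grid point is a null model (constant 0.5
  scores); it exists to keep the declared grid complete and is never
  selected on separable data.
* Model persistence uses Python pickle; registries are trusted local
  artifacts, not an exchange format.
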