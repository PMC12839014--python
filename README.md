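# cdk9screen

A ligand-based virtual-screening pipeline for CDK9 inhibitor discovery,
built for computational chemists who want the full workflow — from raw
bioactivity records to a diverse, purchasable hit list — as tested,
reusable, seed-reproducible code.

CDK9, in complex with cyclin T1, drives transcriptional elongation and
is a prominent oncology target.  Finding new chemotypes for it by
machine learning means: curating heterogeneous potency measurements
(IC50/EC50/Ki/Kd) into defensible active/inactive labels, encoding
molecules numerically, selecting a classifier that actually
generalizes, and turning hundreds of high-scoring screening compounds
into a short, structurally diverse purchase list.  `cdk9screen`
implements each of those steps behind a small, composable API.

## The method

**Curation.**  Exact ("=") records are kept, pActivity = −log10(molar
value) is computed, IC50 records train while EC50/Ki/Kd records test,
duplicates collapse to the median pActivity per standardized structure,
and two labeling schemes apply: Lead-Oriented (active pActivity ≥ 6,
inactive ≤ 5.30) and Potency-Oriented (active ≥ 7.5, inactive ≤ 5.5),
with the window between thresholds excluded.  Censored ("> value")
records certify inactivity when the bound reaches the scheme's
inactivity cutoff, and drug-like decoys balance the classes exactly.
All structures pass one standardization protocol (salt stripping,
pH-7.4 ionization by an explicit rule table, canonical-SMILES keys).

**Models.**  Seven representations (path, circular and
substructure-key fingerprints; 208 scaled physicochemical descriptors;
three fingerprint+descriptor hybrids) × five algorithms (RF, SVM with a
Tanimoto kernel option, KNN, GP, MLP), each tuned by exhaustive grid
search under stratified 5-fold cross-validation maximizing the
Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

then refit on the full training set and ranked by test-set MCC.

**Screening.**  The selected model assigns a probability score (PS) to
every library compound; hits with PS ≥ 0.8 are clustered by
average-linkage agglomeration on the Tanimoto distance d = 1 − T
between path fingerprints, cut at 0.30, and each cluster contributes
its highest-scoring commercially available member.

A synthetic-data module generates ChEMBL-like activity tables, decoy
libraries and vendor catalogues with a planted substructure–potency
signal, so the entire pipeline runs and validates offline.  See
`docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from cdk9screen import models, pipeline

cfg = pipeline.CampaignConfig(
    n_compounds=300, n_decoys=600, library_size=2000,
    seed=7, grids=models.REDUCED_GRIDS,
)
res = pipeline.run_campaign(cfg)

print(res.ranking.head(5)[
    ["algorithm", "representation", "scheme", "cv_mean_mcc", "mcc", "precision", "recall"]
].round(3).to_string())
best = res.best.record
print(f"\nbest model: {best['algorithm']}-{best['representation']} ({best['scheme']})")
print(f"perfect precision from threshold: {res.curve.perfect_precision_threshold}")
print(f"hits (PS >= 0.8): {len(res.hits)}")
print(f"clusters (cut 0.30): {res.assignment.n_clusters}")
print(f"representatives: {len(res.representatives)}")
```

prints

```
     algorithm representation scheme  cv_mean_mcc  mcc  precision  recall
rank
1           GP    descriptors     LO          1.0  1.0        1.0     1.0
2           GP    descriptors     PO          1.0  1.0        1.0     1.0
3           GP        dict_fp     LO          1.0  1.0        1.0     1.0
4           GP        dict_fp     PO          1.0  1.0        1.0     1.0
5           GP       hybridMR     LO          1.0  1.0        1.0     1.0

best model: GP-descriptors (LO)
perfect precision from threshold: 0.5
hits (PS >= 0.8): 33
clusters (cut 0.30): 17
representatives: 13
```

The planted signal is deliberately clean (≈5.8σ separation between
carrier and non-carrier potency), so many models reach MCC 1.0 on the
held-out test set and the threshold sweep achieves perfect precision
already at 0.5.  Of the 2000 screening compounds, 33 score PS ≥ 0.8;
they collapse into 17 structural clusters, 13 of which have a
commercially available member to purchase (the other 4 are logged and
skipped).

The same campaign is available from the shell:

```sh
cdk9screen run --n-compounds 300 --library-size 2000 --seed 7 --out campaign/
cdk9screen synth --n-compounds 1000 --out synth_out/       # raw inputs only
cdk9screen curate --activity synth_out/activity.csv --decoys synth_out/decoys.smi
cdk9screen screen --model campaign/best_model --library synth_out/library.csv
```

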