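# editcode

Structure-aware prediction of A-to-I RNA editing levels for
saturation-mutagenesis variant libraries.

Given an RNA substrate (sequence + editing site + folding constraint
strings) and a library of designed variants, the pipeline

1. **folds** every variant under a simplified, fully verifiable pair-energy
   model (MFE structure, partition function, base-pair probabilities,
   MFE frequency, ensemble diversity) and computes the constrained-ensemble
   **probability of the active conformation**
   `exp(-E_wt/kT) / Z / max(1, noncanonical core pairs)` with `kT = 0.6` kcal
   (37 °C) by default;
2. **annotates** each MFE structure into bpRNA-style elements (stems,
   hairpins, bulges, internal loops, multiloops, exterior) and scores
   structure similarity to WT via normalized tree-edit distance
   (1 = identical);
3. **quantifies** editing from amplicon reads by exact signature matching
   (editing site masked; level = G/(A+G)) and standardizes levels into
   library Z-scores (WT Z = 0 by construction);
4. classifies every single substitution into the six
   transition/transversion × none/break/shift categories;
5. builds a **per-mutated-base feature matrix** (nine feature groups:
   global structure, num_mutations, mutation sequence/structure/other,
   editing-site sequence/structure, upstream, downstream contexts);
6. **trains gradient-boosted trees** with leakage-free position-based
   70/15/15 splits (co-mutated positions share a split), max 1000 rounds,
   early stopping after 10 rounds without validation-RMSE improvement, and
   interprets them with exact tree-Shapley attributions (per feature, per
   group, additive to the prediction);
7. **clusters** variants by structure-tree distance (average linkage,
   Newick dendrogram output).

A seeded synthetic-data module generates hairpin substrates, variant
libraries (singles, transversion doubles, compensatory stem rewrites,
small indels), editing levels from a planted logistic function of
structural features, and binomial reads — so every stage is testable
offline.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance gates (folding-oracle
equivalence on 200 random sequences, annotation round-trips on 500
structures, quantifier recovery at coverage 2000, end-to-end planted-signal
recovery with test R² ≥ 0.8 and the planted features in the top-5 Shapley
ranking across seeds, cross-family generalization failure, no-leakage).

## CLI

```sh
editcode fold --seq GGGAAAACCC [--constraint ... --reference ... --backend builtin|vienna]
editcode annotate --structure "((.((...)).))" --seq GGAGGAAACCCCC --site 3
editcode simulate --spec spec.json --out sim/          # FASTA + TSV + FASTQ + truth
editcode quantify --substrate sim/substrate.json --library sim/library.tsv \
                  --fastq sim/reads.fastq --out quant.tsv
editcode design   --substrate sub.json --region 3:12 --out designed.tsv
editcode featurize --substrate sub.json --library lib.tsv --out features.csv
editcode run      --config cfg.json --out run/         # full pipeline + manifest
editcode explain  --config cfg.json --out run/ --top 20
editcode crosseval --train-config a.json --test-config b.json --out out/
editcode cluster  --substrate sub.json --library lib.tsv --k 2 --out out/
```

Pipeline config (JSON or YAML):

```json
{
  "synth": {"seed": 5, "n_singles": 24, "n_doubles": 6},
  "split_seed": 2,
  "train": {"seed": 7, "max_rounds": 1000, "patience": 10}
}
```

(or `"substrate": "sub.json", "library": "lib.tsv"` to use real inputs).
Every run writes `manifest.json` (config, seeds, registry version, input
digests, stage timings); reruns with the builtin backend are bit-identical.

## Layout

```
src/editcode/
  fold.py        energy model, MFE/partition DP, constraints, active conformation
  annotate.py    pair tables, element annotation, site context, tree similarity
  library.py     substrates, variants, reads→editing, Z-scores, mutation classes
  features.py    feature registry and per-mutated-base matrix
  model.py       position splits, GBT training, metrics, Shapley reports
  shap_trees.py  exact Shapley values for sklearn tree ensembles
  synth.py       seeded substrate/library/editing/read generators
  pipeline.py    orchestration, manifests, structure clustering
  cli.py         `editcode` command group
```
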