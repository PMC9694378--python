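# ppisasa

Post-docking rescoring toolkit for protein–ligand virtual screening built
around buried-surface-area descriptors:

- **Shrake–Rupley SASA** with a deterministic golden-spiral point set,
  computed in three states per docking pose: bound complex, unbound
  receptor, unbound ligand (identical coordinates, no relaxation).
- **Pharmacophoric atom typing** — every atom gets exactly one of seven
  categories (Hydrophobic, Aromatic, Donor, Acceptor, Positive, Negative,
  Other) via a SMARTS cascade for ligands and a residue/atom-name table
  for receptors, so category SASA sums always partition the total.
- **80 SASA descriptors per pose** — for each category and role
  (receptor/ligand/both): unbound, bound, delta (buried) and relative
  (bound/unbound) surface area.
- **Rank-by-rank consensus rescoring** — min–max score normalization,
  fractional ranking, and mean-rank aggregation over any number of
  scoring-function columns.
- **Screening metrics** — ROC AUC (Mann–Whitney), enrichment factors at
  arbitrary fractions (ceil convention, deterministic tie handling), and
  BEDROC (α = 20 default, exact min/max normalization).
- **Eight classifier families** (single Gini tree, bagged forest, random
  forest, naive Bayes, RBF SVM, logistic regression, SGD neural net,
  bagged neural net) with by-class weighting, stratified 70/30 split,
  stratified 10-fold CV, confusion statistics (sensitivity, specificity,
  precision, concordance, Youden J, MCC, F1, Cohen's κ), test-set
  enrichment and permutation descriptor importance.
- **Synthetic fixtures** — parametric pocket–ligand complexes with
  controllable burial depth, two-class descriptor tables with stated
  effect sizes/imbalance, and correlated multi-function score tables.

## CLI

```sh
# end-to-end pipeline from a YAML config (real or synthetic inputs)
ppisasa run --config run.yaml

# descriptor table from a receptor PDB + docked poses (SDF/MOL2)
ppisasa descriptors --receptor rec.pdb --poses poses.sdf \
    --score-field docking_score --out descriptors.csv

# consensus rescoring of a per-pose score table
ppisasa consensus --scores scores.csv \
    --orient surflex=higher,goldscore=higher,chemscore=lower \
    --best-pose-by surflex --out consensus.csv

# AUC / EF1% / EF5% / BEDROC per score column
ppisasa vs-eval --scores consensus.csv --labels labels.csv --out metrics.csv

# train + cross-validate + test one classifier family
ppisasa ml-run --table descriptors.csv --family random_forest --out report.json

# generate synthetic inputs
ppisasa fixtures --kind pocket --seed 1 --out fixtures/
```

A minimal synthetic pipeline config:

```yaml
outdir: out
seed: 1
fixture_pockets:
  - {burial_depth: 0.3}
  - {burial_depth: 0.7}
fixture_scores: {n_compounds: 200, k: 6, signal: 1.5}
families: [random_forest]
```

Score tables are CSV with `compound_id`, `pose_id` and one column per
scoring function; labels are CSV with `compound_id`, `label` (0/1).

## Defaults worth knowing

- SASA: probe 1.4 Å, 960 sphere points, Bondi vdW radii (unknown
  elements: 1.80 Å with a warning). Hydrogens are used if present, never
  added.
- Binding site: whole residues with any heavy atom within 5 Å of a ligand
  heavy atom.
- Typing cascade order: Negative > Positive > Donor > Acceptor > Aromatic
  > Hydrophobic > Other; hydrogens inherit their heavy atom's category;
  His ring nitrogens default to Positive (`his_positive=False` gives
  Donor/Acceptor).
- Relative descriptors with a zero unbound denominator are imputed to 1.0
  and flagged (`n_imputed` column).
- ML: descriptors are min–max normalized on the training partition only;
  classification threshold 0.5; neural-net families handle class
  imbalance by seeded balanced oversampling (they accept no class
  weights).
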