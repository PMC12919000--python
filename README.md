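# ubiqpair

Structure-guided analysis of ubiquitin–E2–E3 ternary complexes and prediction
of functional E2–E3 ligase pairs.

The package covers the full desk-side pipeline:

* **`structure_model`** — PDB/mmCIF parsing into a uniform chain/residue/atom
  model, sequence-identity role assignment (ubiquitin / E2 / E3 / other)
  against a reference registry, and grouping of chains into ternary-complex
  copies within an asymmetric unit.
* **`conformation_analysis`** — crossover-helix and catalytic-cysteine
  location, the two diagnostic distances (ubiquitin Ile44 Cα → helix Cα,
  ubiquitin C-terminal carbonyl → Cys Cα), and Closed/Open classification
  (10 Å / 12 Å cutoffs; the tail criterion applies to predicted structures
  only, distances are averaged over copies).
* **`interface_analysis`** — 8 Å Cα interface residues, distance-only
  hydrogen-bond detection (N/O pairs ≤ 3.5 Å), E2 binding-loop and E3
  loop-engagement statistics, linchpin (bridging E3 residue) detection, and
  crossover-helix-anchored interface RMSD between complexes.
* **`confidence_scores`** — mean interface PAE, ipSAE, pDockQ2, pDockQ and
  chain-pair ipTM from AF3-style or ColabFold-style confidence JSON.
* **`dataset_builder`** — E3 classification by domain content (RING / U-box /
  HECT / RBR / atypical), RING/U-box truncation spans, and pair / non-pair
  set construction from a physical-interaction edge table (experimental
  score ≥ 400 for pairs; no evidence at any level for non-pairs).
* **`energetics_ingest`** — TSV contract for externally computed interface
  energetics (binding energy, SASA components, hydrogen-bond counts).
* **`pair_classifier`** — 38-column feature assembly, nested stratified
  cross-validation of a gradient-boosted classifier with leakage-free feature
  selection, F(β = 0.75) threshold choice, model persistence, and per-E3
  partner prediction behind a structural prefilter.
* **`synthetic_fixtures`** — deterministic generators for every input:
  toy ternary complexes with tunable geometry and planted linchpin bridges,
  confidence JSON in both dialects, energetics tables, edge tables, and
  labeled feature tables with planted effect directions.

## CLI

```bash
ubiqpair synth complex --out fixtures/            # toy structure + manifest
ubiqpair parse fixtures/toy.pdb --registry registry.tsv
ubiqpair conformation fixtures/toy.pdb --registry registry.tsv --mode predicted
ubiqpair features fixtures/toy.pdb --registry registry.tsv
ubiqpair irmsd --ref ref.pdb --model model.pdb --registry registry.tsv
ubiqpair confidence --structure toy.pdb --json toy.af3.json --dialect af3
ubiqpair dataset --edges edges.tsv --domains domains.tsv --e2 e2.tsv --e3 e3.tsv \
    --min-score 400 --seed 1 --out dataset/
ubiqpair train --features features.tsv --seed 0 --out model/
ubiqpair predict --model model/ --features candidates.tsv --out predictions/
```

A registry TSV (columns: gene, kind, sequence, catalytic_cys, helix_start,
helix_end) supplies reference sequences, curated crossover-helix spans and
catalytic cysteines; `ubiqpair.structure_model.write_registry` emits one for
the synthetic toy system.

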