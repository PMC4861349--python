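# confdiv

Conformational-diversity-aware assessment of protein structure models.

Proteins populate their native state as an ensemble of conformers, but
model quality assessment usually compares decoys against a single target
structure. `confdiv` takes the two most structurally distant experimentally
determined conformers of a target plus a population of decoys, ranks the
decoys against *both* conformers under three similarity measures (C-alpha
RMSD, GDT_TS, TM-score), quantifies how much the two rankings diverge
(Spearman rank correlation), cross-compares the best decoys, and classifies
each target by whether the decoy population resolves one or two members of
the native ensemble (`SAME_BEST` / `DIFFERENT_BEST`).

A first-class synthetic-data module generates hinge-motion conformer pairs
and noisy decoy clouds with ground-truth labels, so the entire pipeline is
testable without downloading anything.

## Layout

| module | role |
| --- | --- |
| `confdiv.structure_io` | PDB reading/writing, C-alpha traces, multi-model splitting, residue-number correspondences, coverage |
| `confdiv.metrics` | Kabsch superposition, RMSD, GDT_TS and TM-score (fragment-seeded iterative search), per-position deviation/z-score profiles, coarse Shrake–Rupley rASA |
| `confdiv.diversity` | maximally distant conformer-pair selection and per-group diversity summaries |
| `confdiv.assessment` | decoy filtering (coverage ≥ 0.8, missing run ≤ 5), dual-reference ranking, Spearman correlation, best-decoy cross-comparison, target classification, cohort reports |
| `confdiv.synthetic` | self-avoiding backbone generator, hinge motion, labelled decoy clouds, dataset writer |
| `confdiv.pipeline` / `confdiv.cli` | end-to-end orchestration, manifests in / TSV+JSON reports out |

## CLI

```bash
# generate a synthetic dataset (PDB files + manifests)
confdiv synth --n-targets 5 --n-residues 40 --hinge-angle 30 \
    --n-decoys-a 50 --n-decoys-b 50 --seed 1 --out data/

# conformer-pair selection and diversity summary only
confdiv diversity --manifest data/conformers.tsv --out div/

# full dual-reference assessment
confdiv assess --manifest data/conformers.tsv --decoys data/decoys.tsv \
    --metric-set rmsd,gdt_ts,tm --min-significant 3 --out results/

# re-aggregate per-target JSONs into a cohort report
confdiv report --assessments results/targets --out report/
```

`assess` accepts a flat `key = value` config file via `--config`;
command-line flags override file values. Outputs are TSV/JSON with a
sidecar `schema.json` for units, plus `run_log.json` recording the tool
version, configuration hash and per-stage counts. Reruns with identical
inputs and config are byte-identical.

Manifest formats (tab-separated):

* `conformers.tsv`: `target_id  pdb_id  model_number  chain  cause  method  path`
* `decoys.tsv`: `target_id  decoy_id  group_label  chain  path`

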