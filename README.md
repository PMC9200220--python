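# vscreen

Structure-free virtual screening toolkit. A protein binding pocket (defined
as all residues within 1 nm of a reference bound ligand) and each candidate
compound are rendered as 300-dimensional substructure-embedding vectors; a
densely connected feed-forward classifier scores the concatenated
pocket++ligand vector as a binding probability in (0, 1). The package covers
the full pipeline plus the evaluation statistics used for large-scale
screening benchmarks, and ships synthetic generators with planted ground
truth so every stage can be tested end to end without external data.

## Modules

| module | what it does |
| --- | --- |
| `vscreen.chem_features` | Morgan-environment "sentences", skip-gram embedding training, molecule/pocket vectors, `.smi`/SDF/TSV I/O |
| `vscreen.pocket_extract` | PDB parsing, distance-based pocket extraction, pocket-to-pseudo-molecule conversion |
| `vscreen.dfcnn_core` | the densely connected classifier (NumPy forward/backward, Adam) and a 1-D CNN alternative (RMSprop); input normalization; persistence |
| `vscreen.synthetic_data` | planted-signal binding worlds, cross-combination pair sets, toy PDB complexes, fragment-grammar SMILES libraries, labeled active/decoy sets |
| `vscreen.screening_engine` | streaming library scoring, ranking, cutoff/top-fraction selection, recall@top-f, Lipinski filtering |
| `vscreen.eval_metrics` | confusion metrics (accuracy/TPR/precision/MCC), rank AUC, prediction-vs-random enrichment ratios, summary-table aggregation and count reconstruction |
| `vscreen.hit_clustering` | Morgan fingerprints, Tanimoto distances, average-linkage clustering into k groups, medoid representatives |

## CLI

```sh
vscreen simulate library --n 2000 --seed 1 --out corpus.smi
vscreen train-embedding --smi corpus.smi --dim 300 --seed 1 --out table.tsv
vscreen featurize --smi corpus.smi --table table.tsv --out vectors.tsv

vscreen simulate complex --n-residues 8 --n-near 4 --out toy.pdb
vscreen pocket --pdb toy.pdb --ligand LIG:A:900 --radius 10 --table table.tsv --out pocket_vec.tsv

vscreen simulate world --n-pockets 30 --n-ligands 200 --seed 1 --out pairs.tsv
vscreen train --pairs pairs.tsv --arch dfcnn --seed 1 --out model/
vscreen screen --model model/model.npz --pocket-vec pocket_vec.tsv \
    --table table.tsv --smi corpus.smi --cutoff 0.99 --out run/
vscreen evaluate --scores run/scores.tsv --labels labels.tsv --cutoffs 0.9,0.99 --out report.json
vscreen cluster --smi hits.smi --k 6 --out clusters.tsv
```

## Notes

* No GPU or deep-learning framework is required; both networks are plain
  NumPy and fully deterministic for a fixed seed.
* Screening streams the library with constant memory apart from the ranked
  result rows and is invariant to batch size.
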