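# modelrank

Ligand-guided selection of GPCR homology models by charged-contact scoring.

## The problem

Homology modeling of a G-protein-coupled receptor (GPCR) typically yields
hundreds to thousands of plausible structures that standard stereochemical
checks cannot tell apart, yet only a few have a binding pocket good enough
for structure-based ligand discovery. For aminergic receptors there is a
strong functional prior: active ligands carry a protonated amine that forms
a salt bridge with the conserved aspartate D3.32 (Ballesteros–Weinstein
numbering). `modelrank` turns that prior into a model-selection score:

* dock a small set of known ligands into every model (docking itself is
  external; `modelrank` consumes the pose files),
* score each model by the fraction of poses whose cationic atom lies within
  **6.0 Å (inclusive) of the carboxyl carbon** of the anchor residue
  (CG of Asp, CD of Glu):

  `score(model) = #{poses : d(C_carboxyl, cation) ≤ 6 Å} / #poses`,

* average over replicate docking runs, rank the models, and
* compare the 10 best against the 10 worst models atom by atom — after a
  backbone superposition onto the pooled mean, the per-atom difference of
  group mean positions `Δ_j = ‖⟨x_j⟩_best − ⟨x_j⟩_worst‖` nominates the
  side-chain conformations (e.g. the E5.46 carboxylate orientation) that
  separate good from bad pockets.

It also implements the accompanying bioactivity data curation used to pick
the guiding ligands: ChEMBL-style filters (MW ≤ 500 Da, confidence 9,
Ki/Kd/IC50/EC50, relation "=", value ≤ 10 nM, unambiguous stereochemistry),
binding-over-functional / newer-over-older deduplication, Morgan-feature
(diameter 4) MaxMin diversity picking, and Cheng–Prusoff conversion
Ki = IC50 / (1 + [L]/Kd) with pKi = −log10 Ki.

A synthetic fixture generator stands in for the modeling/docking/database
engines so the complete workflow is runnable and testable offline; see
`docs/methods.md` for what it does and does not emulate.

## Worked example

```
modelrank fixtures --out demo/fx --n-models 50 --seed 7
modelrank rank --manifest demo/fx/manifest.tsv --bwmap demo/fx/bwmap.tsv \
               --site demo/fx/site.yaml --k 10 --out-dir demo/rank
modelrank diff --manifest demo/fx/manifest.tsv \
               --extremes demo/rank/extremes.json \
               --bwmap demo/fx/bwmap.tsv --out-dir demo/diff
```

`demo/rank/scores.csv` starts:

```
model_id,rank,score_run1,score_run2,aggregate,discrepancy,pooled
m17,1,0.83333333333333337,0.83333333333333337,0.83333333333333337,0,0.83333333333333337
m09,2,0.82222222222222219,0.82222222222222219,0.82222222222222219,0,0.82222222222222219
```

Model `m17` ranks first: 75 of its 90 poses (83.3%) form the charged
contact with the D3.32 anchor in both replicate runs. `demo/diff/diff.tsv`
starts:

```
atom_name  residue_name  residue_number  chain  subset     delta     residue_max_delta  bw_label  in_site
OE1        GLU           546             A      sidechain  5.148606  5.148606           5.46      True
CD2        PHE           739             A      sidechain  2.067192  2.067192           7.39      True
```

The atom whose mean position differs most between the 10 best and 10 worst
models (here 5.1 Å, planted at 4.7 Å plus side-chain noise at this small
ensemble size) is a carboxyl oxygen of the glutamate at BW position 5.46 —
the side chain whose orientation discriminates scoring from non-scoring
pockets. Other subcommands: `contacts` (per-pose interaction records as
JSON lines), `rmsd` (ensemble RMSD decomposed into backbone/side chains),
`curate` and `pick` (activity-table pipeline).

To use your own data instead of fixtures, provide PDB models, SDF/MOL2 pose
files with formal charges, a `manifest.tsv` (model_id, run_id, model_path,
pose_path), a BW map TSV (bw_label, chain, resnum, resname) and optionally
a site YAML; residue 7.39 (Pro vs Phe differs between conventions) is
whatever your map declares.

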