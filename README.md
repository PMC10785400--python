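# voxsite

Consensus binding-site prediction for blind docking, on a voxel grid.

## The problem

Blind docking — docking a ligand against a whole protein surface without
knowing the binding site — is unreliable when any single program's top pose
is trusted. Individual docking programs (AutoDock Vina, PLANTS, GalaxyDock3,
ZDOCK) and cavity-detection tools (Fpocket, P2Rank) each make characteristic
mistakes, but they tend to *agree* at the true site far more often than at
any other pocket. `voxsite` turns that agreement into a prediction:

1. draw a 10 Å cubic grid over the protein and assign every predicted pose
   and cavity to the grid box containing its mass centre;
2. featurize each occupied box: per program *P* the pose count
   `sampled_pose_number_P_at_location`, the minimum pose-to-box-centre
   distance `P_distance` and the best native score `P_best_score`; per
   cavity tool *T* the best cavity rank `T_min_pose_id`, its centroid
   distance, and the tool's descriptor columns; missing values get
   training-set mean imputation;
3. select informative features by the Boruta shadow-feature procedure
   (real importances vs. column-shuffled copies, binomial hit test);
4. score each box with a stacked classifier — bagged gradient-boosted
   trees, random forest and logistic model whose out-of-fold predictions
   feed a logistic meta-learner — yielding a binding-site probability in
   [0, 1];
5. report the detected cavity nearest the top-scoring box as the binding
   site, and emit a 15 Å local-docking box around it (fallback order
   PLANTS → Vina → GalaxyDock3) for the user's own docking run.

Evaluation uses the field's standard metrics: a site prediction is a hit
when its centroid lies within 8 Å of the crystal ligand's mass centre, and
a pose is a hit when its **symmetry-corrected RMSD** — the minimum of
`sqrt(Σᵢ‖xᵢ − xᵢ,ref‖²/N)` over all automorphisms of the element- and
bond-labelled molecular graph — is below 2 Å.

No external docking binary is ever executed: adapters normalize real
program outputs (Vina PDBQT, fpocket directories, P2Rank CSVs, generic
multi-entry molecule files) into a versioned JSON interchange, and a
synthetic scenario generator produces statistically realistic corpora so
the whole pipeline trains and tests offline.

## Worked example

Train on 15 synthetic targets and predict the site of a 16th
(`examples/03_train_and_predict_site.py`):

```text
Boruta confirmed 15/21 features, e.g. sampled_pose_number_vina_at_location, vina_distance, vina_best_score
validation report: {'n_validation_targets': 3, 'n_validation_rows': 80, 'auroc': 0.983, 'log_loss': 0.265, 'top1_site_hit_rate': 0.333}
predicted site [  1.1    6.86 -23.7 ] via p2rank:4 (voxel score 0.996)
distance to true site: 1.28 Å -> HIT at the 8 Å criterion
```

Boruta keeps the pose-count/distance/score features and drops
uninformative descriptor columns; the model's held-out AUROC says the voxel
classifier separates site from non-site boxes; the prediction maps the top
voxel to a P2Rank cavity 1.28 Å from the true site — a hit at the 8 Å
criterion. The other examples cover scenario generation, voxelization,
symmetric RMSD (`plain 1.400 Å → symmetric 0.000 Å` for a renumbered
benzene ring) and docking-plan emission.

The same pipeline is scriptable from a shell:

```bash
voxsite e2e --out run/ --seed 0 --n-train 60 --n-eval 20
voxsite simulate|featurize|train|predict|evaluate ...   # individual stages
```

## Layout

- `src/voxsite/` — library: `structmodel` (structures, cleaning, centroids),
  `adapters` (program-output parsers + interchange), `voxelizer`,
  `selector` (Boruta + ANOVA F), `scorer` (stacked ensemble), `sitepredict`
  (ranking, cavity mapping, docking plans), `evaluate` (metrics incl.
  symmetric RMSD), `synthetic` (scenario generator), `pipeline`, `cli`.
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — model assumptions, parameter meanings, numerical
  choices and limitations.
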