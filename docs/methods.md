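# Methods

## Model

`voxsite` treats blind-docking site prediction as binary classification of
grid boxes. A 10 Å axis-aligned cubic lattice is drawn over the padded
bounding box of the protein's heavy atoms (`dims = ceil((extent +
2·padding)/resolution)` per axis, default padding 5 Å so surface-adjacent
poses stay in bounds). Each predicted pose and cavity is assigned to the box
containing its mass centre under floor indexing with half-open intervals;
points on or past the outer boundary clamp to the nearest boundary box, so
assignment is a true partition — per-program pose counts over boxes always
sum to the program's pose count. 10 Å is coarse enough that a binding site
concentrates in one or a few boxes and fine enough that distinct pockets
rarely share one.

Mass centres are computed over heavy atoms only, with standard atomic
weights. Hydrogens are excluded because docking outputs and the RMSD
convention are heavy-atom based; a geometric (unweighted) centroid is
available as an option. No protonation or pKa assignment is performed
anywhere — docking inputs are expected pre-protonated by the user's own
preparation pipeline, and the emitted docking plans record this.

A box is labelled positive iff it contains the crystal ligand's mass
centre — one positive per labelled target, even when the ligand spans
several boxes (the centre-containing box is the single positive). If that
box was filtered out as empty it is re-inserted with missing features so
the positive example survives; mean imputation then fills it.

### Features

Per docking program *P*: `sampled_pose_number_P_at_location` (count),
`P_distance` (minimum pose-centroid → box-centre distance, Å),
`P_best_score` (program units; *minimum* for the energy-like scores of
Vina/PLANTS/GalaxyDock3, *maximum* for ZDOCK — the registry carries the
polarity, since score direction is never normalized). Per cavity tool *T*:
`T_min_pose_id` (best = lowest cavity rank in the box), `T_distance`, and
the descriptor columns of the best-ranked cavity (e.g.
`Fpocket_druggability_score`, `P2Rank_probability`). A program that ran but
placed nothing in a box contributes a count of 0 there; a program that
failed outright contributes *missing* for all its columns — the distinction
matters, and upstream failure rates of 0–2 % per program are why the
interchange tracks failures explicitly. Missing cells are replaced by
training-set column means (inference-time imputation always uses the
training means; a never-observed column imputes to 0 and is flagged).

### Feature selection

Canonical Boruta: each iteration appends one column-shuffled shadow copy
per undecided feature, fits a random forest (impurity importance, balanced
class weights, default 200 trees), and credits a feature with a hit when
its importance exceeds the *maximum* shadow importance. Cumulative hits are
tested two-sided against Binomial(trials, ½) at α = 0.05: significantly
above chance → confirmed, below → rejected, undecided at the iteration cap
(default 100) → tentative (dropped by default, keepable by flag). No
multiple-testing correction across features, matching the canonical
algorithm. Deterministic given the seed. ANOVA F-scores are computed for
interpretability only; a zero-variance feature scores 0 and an infinite F
(zero within-group variance) is reported as a 1e12 sentinel.

### Classifier

Bagged multi-layer stacking with an explicit, seedable procedure. Layer 1
fits each base learner — histogram gradient-boosted trees, random forest,
and a standardized logistic model; the roster is a registry and
configurable — on `bags_per_learner` bootstrap resamples (a single bag fits
the full data, degenerating to a plain classifier) and averages the bags.
Out-of-fold predictions, computed with *target-grouped* K-folds so no voxel
of a target ever informs a prediction on that target, feed the next layer
(concatenated with the original features); the final meta-learner is a
logistic model on the last layer's predictions, so the output is a
calibrated probability in [0, 1] without a separate calibration stage. The
≈1 positive : dozens of negatives imbalance is handled by balanced class
weights in every learner, never by resampling. Train/validation splitting
is at target granularity (default 20 % of targets held out for the training
report: AUROC, log-loss, top-1 site hit rate). An optional dedup drops
training targets whose precomputed structural similarity (e.g. TM-score) to
any benchmark target strictly exceeds 0.5; a score of exactly 0.5 is kept,
and similarity computation itself is external input.

### Site prediction and docking plans

Voxels are ranked by descending score, ties broken by greater total pose
count then lexicographic index. The top voxel maps to the nearest cavity by
Euclidean centroid distance over the *union* of both tools' lists; ties
break by smaller cavity rank then tool name, so the result is invariant to
input order. With no cavities at all the voxel centre itself is reported,
flagged "voxel-only". Requesting k sites walks the ranking and reports each
cavity once. The emitted local-docking plan is a 15 Å box centred on the
site with fallback order PLANTS → Vina → GalaxyDock3 (Vina-dialect config
text plus JSON stubs); nothing is executed, and the final pose selection
simply takes the best-scoring pose (polarity-aware) from the first program
in the order that returned any.

### Metrics

Site: Euclidean distance predicted-centroid → crystal-ligand mass centre;
hit iff < 8 Å (strict). Pose: heavy-atom RMSD in the receptor frame with
*no* superposition, `sqrt(Σᵢ (Δxᵢ² + Δyᵢ² + Δzᵢ²)/N)`; hit iff < 2 Å
(strict). The symmetric RMSD is the minimum plain RMSD over all
isomorphisms between the two molecules' element- and bond-order-labelled
graphs, found by VF2 search; the recorded automorphism count is the group
order. Bond connectivity comes from file connectivity when present,
otherwise distance-based perception (covalent-radius sum + 0.45 Å, all
orders 1, flagged). Beyond 10⁶ isomorphisms the result is the best of the
enumerated mappings and the identity correspondence — an upper bound,
flagged `capped`. Benchmark summaries report per-dataset accuracy, mean and
median, plus an *unweighted* cross-dataset average (each dataset counts
once regardless of size).

## Synthetic scenarios

The generator emulates the statistical structure consensus relies on, not
physics. A target is a minimum-spacing carbon point cloud inside a 25 Å
sphere; the true site and 4 decoys sit on the surface, pairwise ≥ 12 Å
apart so an 8 Å hit is unambiguous. Each program's poses land near the true
site with probability `program_accuracy` (default 0.6 easy, 0.3 hard) with
Gaussian scatter σ = 2.5 Å, otherwise near a random decoy; pose counts
default to Vina 9, PLANTS 10, GalaxyDock3 20, ZDOCK 100 (mirroring each
program's output character). True-site poses score ≈2 units better on
average (unit-variance normals, polarity per program). Cavity tools report
all five sites perturbed by σ = 2 Å, ranking the true site first with
probability 0.5, with plausible descriptor distributions that overlap
between true and decoy pockets. Whole-program failures occur at rate 0.02
(scalar or per-program map); if a draw would silence every producer, one
program is forced to run. The crystal ligand is a rigid 7-heavy-atom
para-substituted ring whose mass centre sits exactly on the true site.
Everything is deterministic given (seed, target index).

What passing tests on this family do **not** show: robustness to real
score scales, correlated program errors, flexible ligands, multi-site
proteins, or crystal-structure artefacts. They do show that the
aggregation, selection, stacking and mapping machinery recovers a planted
consensus signal and degrades to the decoy baseline when the signal is
destroyed.

## Numerical and design choices

- Grid: `dims` uses a 1e-9 relative guard against float noise at exact
  multiples; atoms exactly on the outer face clamp into the last box.
- Ranking/mapping tie-breaks (pose count → lexicographic; rank → tool
  name) make every pipeline stage deterministic; a single global seed fans
  out to per-stage seeds via a seed sequence, so stages are independently
  reproducible.
- Problem sizes in the test suite and the acceptance script: training on
  60 synthetic targets with 20 held out (the scale at which the recovery
  statistics are stable), Boruta property checks at n = 400 with 50-tree
  forests and the pipeline run with 100-tree forests and a 30-iteration
  cap — on this corpus every feature is decided well before the cap.
- The fpocket parser reads the `*_info.txt` + per-pocket PQR dialect;
  unparseable descriptor lines degrade to missing values with a logged
  warning rather than aborting a run.
- ZDOCK poses are accepted only as pre-extracted coordinate files; its
  native rigid-body transformation output is out of scope.
- The interchange JSON (`voxsite-interchange/1`) is the tested contract;
  native-format parsers are best-effort conveniences.

## Limitations

Single-positive labelling under-credits ligands genuinely spanning
several boxes. Grid alignment is bounding-box derived, so predictions are
not strictly invariant to protein rotation (only to translation). The
stacked ensemble's learner roster is a pragmatic default, not a tuned
optimum. Symmetric RMSD assumes the two inputs are the same molecule; it
refuses otherwise rather than attempting partial matching.
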