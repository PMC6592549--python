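# Methods

## Scoring model

For one receptor model and one docking run, the charged-interaction score is
the fraction of docked poses satisfying the ionic-contact criterion: the
Euclidean distance from the carboxyl carbon of the anchor residue (atom CG
for aspartate, CD for glutamate — the carbon, not the oxygens) to the
nearest formally cationic ligand atom is at most `max_distance` (default
6.0 Å, boundary inclusive). "Cationic" is any atom with formal charge ≥ +1
regardless of element, because file dialects place the charge of
guanidinium or quaternary-ammonium groups on different atoms; an optional
heuristic flags protonatable amine nitrogens (bonded only to C/H, not
amide, not aromatic) for inputs without formal charges, and is used only on
request. A pose with no cationic atom scores negative with an undefined
(infinite) minimum distance.

Scores are exact rationals k/n alongside their float value. Replicate
docking runs are aggregated as the arithmetic mean of run-level fractions —
not by pooling poses — so a two-run model with run scores 0.84 and 0.83
reports 0.835; the pooled fraction and the absolute run discrepancy are
reported for transparency. Ranking is by descending aggregate; ties break
by smaller run discrepancy, then lexical model id (a reproducibility
convention with no scientific content), giving dense ranks 1..n. Models
whose pose files are missing are excluded and logged rather than scored 0:
absent data is not evidence of a missing interaction.

## Superposition and RMSD

Rigid superposition uses the closed-form Kabsch solution (SVD with a
determinant correction, proper rotations only); inputs need ≥ 3
non-collinear paired points. Ensemble RMSD fits every model on backbone
heavy atoms (N, CA, C, O, OXT) to a mean reference obtained by one round of
iterative fitting: fit all models to a canonical first model, average,
refit once onto that average, and average again. Processing order inside
the ensemble is canonicalized by model id so the reference is invariant to
input order. One fit per model is reused for all atom subsets, which makes
the decomposition identity

    n_all · RMSD_all² = n_bb · RMSD_bb² + n_sc · RMSD_sc²

hold exactly. Whether an ensemble spread should be quoted as RMSD-to-mean
or as the all-pairs average is a genuine convention choice; the headline is
RMSD-to-mean, and the all-pairs average (≈ √2 larger for independent noise)
is computed on request (`include_pairwise`), since it costs O(n²) fits.
Hydrogens are excluded from every geometric analysis. Receptor coordinates
are stored single-precision (the PDB container's native width); all
computation is double-precision, so geometric invariances hold to ~1e-6 Å,
not machine epsilon.

## Best-vs-worst group differences

The k best and k worst ranked models (default k = 10, requiring n ≥ 2k for
disjoint groups) are pooled and superposed onto the pooled-ensemble mean
with a backbone fit; the report lists, per heavy atom of the chosen subset
(default: side chains), the distance between the two group mean positions,
sorted descending with ties broken by residue number then atom name. The
superposition target is deliberately the pooled mean with a backbone-only
fit so that reported deltas reflect side-chain rearrangement rather than
global rigid motion — other choices (fit each group separately, all-atom
fit) are defensible and would shift deltas slightly. The report is
per-atom; a per-residue max-delta rollup column is included for
convenience. Annotated reports carry Ballesteros–Weinstein labels and a
binding-site membership flag, and the pooled mean structure can be written
as PDB with each atom's delta in the B-factor column for visualization.

## Residue numbering and the binding site

BW labels resolve through a user-supplied table (bw_label, chain, resnum,
resname); the expected residue name is validated against the structure to
catch mis-specified maps. Mapping is never inferred from sequence
alignment. The default site specification is the canonical aminergic
orthosteric pocket (3.32 anchor, 3.33, 4.56, 5.46, 6.48, 6.51, 7.39), with
the anchor required to resolve to Asp or Glu. Position 7.39 is left
entirely to the user's map — conventions differ on whether it is a proline
or a phenylalanine in some receptors — and the shipped fixture map uses
phenylalanine so the aromatic interaction code path is exercisable.

## Extended interaction fingerprint

For pose inspection only (never part of the score), geometric rules emit
hydrogen-bond (ligand N/O to residue N/O ≤ 3.5 Å), pi-cation (cation to
aromatic-ring centroid ≤ 6.0 Å, restricted to Phe/Tyr/Trp/His — some
perception tools also report "pi-cation" contacts to carboxylates, which
this package deliberately does not) and hydrophobic (ligand C to side-chain
C ≤ 4.5 Å) annotations. These thresholds are conventional defaults, are
configurable, and carry no claim of equivalence to any particular
pharmacophore package.

## Bioactivity curation

Filters apply in a fixed order — MW ≤ 500 Da, confidence = 9, activity type
∈ {Ki, Kd, IC50, EC50}, relation "=", value ≤ 10 (with unit filter "nM"
this is ≤ 10 nM; both thresholds are exposed because export column
conventions vary), unit "nM", unambiguous stereochemistry — and every
dropped record is charged to its first failing stage. The kept set is
order-invariant (filters are per-record), so stage order only shapes the
attribution of drops. Records with missing molecular weight are dropped at
the MW stage, since the filter cannot be verified for them.
Stereo-ambiguity is a boolean column on synthetic tables; when SMILES are
available, unassigned stereocenter detection is delegated to RDKit and
cached into that column. Deduplication keeps one record per ligand:
binding (Ki/Kd) beats functional (IC50/EC50), then the most recent year,
then the lowest value, then stable input order. Tanimoto similarity and
MaxMin picking operate on abstract feature sets (two empty fingerprints are
defined as identical, with a warning); Morgan feature fingerprints use
diameter 4 (radius 2), 2048 bits. MaxMin draws its first pick from the
seeded RNG and then greedily maximizes the minimum Tanimoto distance to the
picked set, ties to the lowest index. Cheng–Prusoff is
Ki = IC50/(1 + [L]/Kd) with positive inputs required.

## Synthetic fixtures: what they emulate and what they don't

The generator stands in for three external engines. Receptor ensembles are
noisy copies of a hand-built seven-helix bundle (23 residues, 161 heavy
atoms) whose side chains point into a central pocket; isotropic Gaussian
noise is applied per coordinate with σ_bb = 0.4 Å on backbone and σ_sc =
1.6 Å on side-chain atoms, emulating the empirical pattern that side chains
vary several-fold more than the backbone across a homology-model ensemble.
Note the resulting RMSD-to-mean is √3·σ·√((n−1)/n) per subset (≈ 0.69 Å
backbone, ≈ 2.77 Å side chain), since σ is per coordinate. Models planted
as low-scoring (planted fraction ≤ 0.1) additionally have one E5.46
carboxyl oxygen displaced 4.7 Å outward from the pocket, mimicking the
outward-pointing glutamate conformation of poorly-scoring pockets. Pose
sets place a three-heavy-atom protonated-amine fragment so that exactly k
of 90 poses per run sit 4.0–5.5 Å from the anchor carboxyl carbon and the
rest 7–12 Å — a ≥ 0.5 Å constructed margin around the 6 Å cutoff, so
scoring recovers k/90 exactly and rank recovery is noise-free by
construction. The default planted-score distribution gives a unique top
model at 75/90 ≈ 0.833, one quarter of models at or below 0.1, and ~0.7% at
exactly 0 (7 of 1000). Planted fractions are identical across the two
replicate runs, so run discrepancy is zero on fixtures; discrepancy
handling is tested on synthetic score pairs directly.

No random rigid body motion is applied per model (so zero-noise
configurations yield byte-identical structures); superposition correctness
is exercised by applying explicit rigid motions in tests. The fixtures are
not physically realistic: no force field, no sterics (poses may overlap the
receptor), minimal ligand topology, idealized helix geometry. Passing tests
therefore certify the measurement and ranking machinery — contact
detection, exact fractions, superposition, group statistics, curation
logic — not docking accuracy or model quality on real receptors. Activity
tables are generated with a failure profile assigning each failing record
exactly one failing stage, making kept counts exact by construction;
duplicate groups are generated with random type/year/value for comparison
against a brute-force preference comparator.

## Numerical and degenerate-input choices

Kabsch rejects < 3 points and collinear sets (rank < 2 after centering).
Empty atom subsets (e.g. side chains of an all-glycine selection) report
NaN RMSD with n = 0 and are excluded from averages. Alternate locations in
PDB input reduce to the highest-occupancy conformer (ties resolve to the
first encountered, i.e. altloc A); homology models normally contain none.
Elements missing from PDB columns 77–78 are inferred from atom names. SDF
formal charges (`M  CHG`) are preserved exactly; MOL2 carries partial
charges only, so formal charges for MOL2 input come from RDKit valence
perception during sanitization — SDF is the recommended pose format.
Scores are exact rationals; CSV output serializes floats at full precision
(`%.17g`) so reruns are byte-identical. All CLI outputs embed the tool
version, seed and a parameter digest (paths excluded, so outputs are
location-independent).

## Problem sizes

The default study conditions are 1000 models × 2 runs × 90 poses. The
acceptance script runs them in full, in memory; the end-to-end CLI test
writes and re-reads the complete bundle (1000 PDBs, 2000 SDF files, ~80 MB)
twice to verify byte-identical reruns. Property tests use 100-seed
replications at 10–100 models, chosen so the whole suite stays fast while
estimates (e.g. displacement recovery within ±0.4 Å) are well inside their
stated bands.

## Known limitations

Single-chain, single-conformer receptor handling; no protonation-state
assignment of the receptor; no sequence alignment or BW-label inference; no
docking, pharmacophore perception or decoy generation. The ionic-contact
criterion is a geometric proxy — it does not verify hydrogen positions or
salt-bridge energetics. Curation thresholds mirror one specific export
convention (ChEMBL-like columns); other schemas need the column-mapping
config.
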