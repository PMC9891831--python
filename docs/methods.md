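# Methods

## Scope and model

`fegsnet` implements a sequence-only binary protein classifier in three
parts: (i) a graphical featurizer that turns a protein into one scalar per
physicochemical property via a 3D curve and a distance-quotient matrix,
concatenated with amino-acid and dipeptide compositions; (ii) baseline
descriptors (AAC, DPC, amphiphilic pseudo-AAC); (iii) a cascade deep-forest
classifier with a cross-validated evaluation harness. A seeded synthetic
generator stands in for curated positive/negative sequence sets so the whole
pipeline is testable offline; the `benchmark` command runs the identical
pipeline on user-supplied FASTA files.

## Graphical featurization

For a property that orders the 20 residues (lowest value = rank 1, ties
broken alphabetically; a property with 20 identical values carries no
ordering information and is rejected at table load), residues sit at
Φ(A_i) = (cos(2πi/20), sin(2πi/20), 1) and ordered pairs at
Φ(A_iA_j) = Φ(A_i) + Φ(A_j)/4. Rank i enters the angle directly, so rank 20
coincides with angle 0. The curve of S = s₁…s_N starts at the origin; the
first step adds the vertex point of s₁ and step i ≥ 2 adds the pair point of
the trailing dipeptide s_{i−1}s_i. This incremental rule is the unique
reading of the cumulative construction that yields exactly one new point per
residue.

The N residue points (the synthetic origin is excluded, so the matrix size
equals the sequence length) fill M_ij = ‖P_i − P_j‖ / path(i, j) with zero
diagonal, where path is the summed length of the curve edges between the two
points — the classic Euclidean/graph-distance quotient, dimensionless and in
(0, 1]. The combining operation of the two distances is a design choice
(the quotient is the standard construction in the graphical-representation
literature); it is cross-checked in the tests by brute-force edge summation.
The per-property scalar is the leading eigenvalue of M divided by N: for a
nonnegative symmetric matrix this is the spectral radius, and the 1/N
normalization removes the linear growth of the eigenvalue with sequence
length so that proteins of different sizes are comparable. Matrices up to
32×32 use a dense symmetric eigensolver; larger ones use Lanczos iteration
for the single largest eigenvalue. Memory is O(N²) per curve — the intended
regime is proteins up to a few thousand residues.

Feature layout is fixed and written into every output header: P eigen
columns in table order, then AAC in alphabetical residue order, then DPC in
lexicographic pair order. Identical inputs give bit-identical vectors.

## The property table

The original selection of 158 indices behind this construction was never
published, so the bundled table
(`src/fegsnet/data/physchem_indices_synthetic.tsv`) is a documented
synthetic stand-in: five well-known published scales (Tanford-style
hydrophobicity, Hopp-Woods hydrophilicity, Kyte-Doolittle hydropathy,
side-chain mass, isoelectric point) followed by 153 seeded pseudo-random
rows. Only the induced residue ordering of each property enters the
geometry, so random rows exercise the machinery exactly as real indices do;
they are not claims about amino-acid chemistry. Any user table with ≥ 1
non-degenerate property is accepted (`--table`); every downstream dimension
is P + 420 and the effective P (after dropping degenerate rows) is logged.

## APAAC

The amphiphilic pseudo-composition follows the standard definition:
hydrophobicity and hydrophilicity scales standardized to zero mean and unit
(population) variance over the 20 residues, correlation factors
τ_{2k−1} = Σᵢ H1(sᵢ)H1(s_{i+k})/(N−k) and τ_{2k} likewise for H2,
k = 1..λ, and the (20+2λ)-vector (f‖w·τ)/(1 + w Στ). Defaults λ = 5,
w = 0.05 (the classic settings; the reference experiments never state
theirs, so APAAC results are not an exact reproduction surface). The vector
always sums to 1; because the standardized scales are signed, the τ tail can
be negative — only the composition block is guaranteed nonnegative. A
sequence must be longer than λ.

## Cascade deep forest

Layer = 6 XGBoost + 6 random-forest + 6 extra-trees learners, 20
trees/boosting rounds each (boosted learners: depth-3 trees, learning rate
0.3). During training each learner is cross-fitted on an internal stratified
3-fold split, so the 36 augmentation probabilities appended to the features
are out-of-fold — naive in-sample probabilities saturate to 0/1 and kill the
cascade. The layer's validation score is the accuracy of the out-of-fold
mean-probability vote; growth stops when a layer fails to beat the best
score so far (patience 1) or at `max_layers` (default 10), and the model is
truncated at the best layer. Prediction propagates through the kept layers
(augmenting with full-fit probabilities) and averages the last layer's 18
probability vectors; the sum and the mean give the same argmax, and ties go
to the positive class.

Within a layer the six copies of each learner type differ only by seed.
Forests randomize feature subsets per split, so seeds suffice; XGBoost's
histogram algorithm is deterministic on full data, so the boosted learners
use 80% row and column subsampling to make their seeds effective. All seeds
derive from the config seed through a fixed-order generator, making training
and prediction bit-reproducible on a fixed software stack. Multiclass
problems and the multi-grained-scanning stage of the wider deep-forest
literature are out of scope; concatenating several encodings into one input
block is possible by stacking feature matrices, but every reported
experiment uses one encoding at a time.

## Evaluation

Threshold metrics come from the confusion counts with the convention that a
zero denominator defines the metric (SN, SP, MCC, F1) as 0 — the formulas
are undefined there and a fixed convention keeps degenerate folds
comparable. AUC uses midranks (Mann–Whitney), is undefined on a single-class
sample, and is reported as null for such folds. Cross-validation is
stratified (class imbalance at a few hundred samples makes unstratified
folds noisy); the headline report is the per-fold average, with pooled
confusion counts available behind `pooled=True` — both modes exist because
published summaries rarely say which they used. `k = n` falls back to
unstratified leave-one-out, where single-sample folds cannot be stratified.
The independent-test protocol fits once on the training set and refuses
overlapping sequence ids (`allow_overlap` exists for resubstitution smoke
tests only).

## Synthetic generator

Negative-class sequences are i.i.d. draws from a fixed background
composition (typical proteome frequencies) expressed as a first-order Markov
chain; the positive class mixes each transition row toward a uniform law
over a frozen 40-pair signature dipeptide set with weight `effect`
(rows without a signature pair keep the background law). `effect = 0` makes
the classes identically distributed — the null case used to verify
chance-level performance — and `effect` near 0.5 gives a strong, learnable
order signal. A first-order chain (rather than i.i.d. residues with
composition shifts) was chosen deliberately: the signal lives in residue
*order*, which DPC and the curve features can see but AAC largely cannot.
Lengths are uniform on [50, 400] residues, the scale of
immunoglobulin-domain proteins, which also keeps the O(N²) quotient matrices
small. Defaults: effect 0.5 for "strong" separation, matching the
simulation checks.

What the generator does not emulate: homology and family structure, domain
architecture, length/composition correlation, or any real immunoglobulin
biology. Passing tests therefore demonstrate that the pipeline extracts
dipeptide-order signal correctly and that the cascade learns it — not that
the default table or classifier settings reach any particular accuracy on
curated immunoglobulin data. For real data, redundancy reduction (e.g.
CD-HIT at 60%) must be done externally before training.

## Problem sizes and numerical choices

The simulation checks use 500+500 null sequences (DPC features, one-layer
cascade — the null conclusion is classifier-independent, so the cheapest
configuration is used) and 200+200 strong-effect sequences with full
5-fold cascade cross-validation on both the graphical and DPC features;
these sizes give stable estimates (binomial s.e. ≈ 0.016 on the null AUC)
while keeping a full run to minutes on one CPU. Tolerances: probability
rows sum to 1 within 1e−9; the Lanczos eigenvalue agrees with power
iteration to 1e−8; APAAC agrees with a brute-force double loop to 1e−10;
goodness-of-fit of generated dipeptide frequencies is judged at 5 binomial
standard errors per transition cell.

## Known limitations

- The bundled property table is a stand-in; results with it are not
  comparable to runs using the (unpublished) original index selection.
- O(N²) memory per curve; no approximate eigensolver for very long
  sequences.
- Binary classification only; no feature selection; no web service.
- Sequences shorter than 2 residues after cleaning are dropped, and
  sequences that are fragments of other proteins are not detected (no
  operational rule exists for that filter).
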