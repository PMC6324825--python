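# Methods

## Model overview and assumptions

`cdpred` treats inter-residue geometry prediction as a set of binary
classification problems over residue pairs of a query protein. The truth
label of a pair is the interval containing its Cβ–Cβ distance (Cα for
glycine, or where the Cβ is unresolved): contact (0, 8] Å, then (8, 13],
(13, 18] and (18, 23] Å; half-open-left, closed-right throughout, so
d = 8.0 Å is a contact and d = 8.01 Å belongs to 8–13. Pairs whose
distance is trivially implied by the chain are removed before training
and evaluation alike: all pairs with |i−j| ≤ 5; for the distance bins,
pairs below bin-specific separations (8, 13, 15 residues) and pairs on
the same predicted helix or strand element (maximal run of identical H
or E labels; each coil residue is its own element). The contact class
keeps same-element pairs. Using *predicted* secondary structure for the
filter, for training and test alike, keeps the pair universe computable
without a solved structure.

The classifier input is evolutionary: given a deep alignment of
homologs, directly coupled column pairs — dependencies that survive
after transitive correlation is removed — are strong contact evidence.

## Coevolution stage

Columns are 21-state categoricals (20 amino acids + gap; unknown
residues are pooled with the gap state). Each row is weighted by
1/(number of rows ≥ 80% identical to it, inclusive); pairwise identity
excludes columns gapped in both rows and counts gap-versus-residue as a
mismatch. Weighted single- and pair-site frequencies are mixed toward
uniform with fraction pc/(pc + total weight), pc = 1 by default, chosen
so the pair tables still marginalise exactly to the single-site tables.
The sample covariance C[(i,a),(j,b)] = f_ij(a,b) − f_i(a)f_j(b) is
shrunk toward its diagonal — (1−s)C + s·diag(C) with the smallest s on a
0.05 grid giving a minimum eigenvalue above 1e−8 — and passed to the
graphical lasso,

    min_Θ  −log det Θ + tr(SΘ) + ρ‖Θ‖₁(off-diagonal),

solved through scikit-learn's coordinate-descent implementation. The
penalty convention keeps the empirical diagonal of the working
covariance (the diagonal of Θ is unpenalised); the package's own
block-coordinate-descent reference solver (`cdpred.reference`) uses the
same convention and serves as an independent correctness oracle in the
tests — the two routes agree in penalised objective to ~1e−12 on random
SPD instances up to p = 50.

Pair scores are the L1 norm of the 20×20 inter-position block of Θ (gap
state excluded, the PSICOV convention), with the average product
correction raw(i,j) − rowmean_i·rowmean_j/grandmean applied by default
to remove per-position background coupling.

ρ defaults to 0.02, a free parameter of the method; 0.02
gives heavily sparse off-diagonal blocks on the synthetic benchmark
(median off-block occupancy a few percent) while recovering planted
couplings with top-L/5 precision 1.0 at the benchmark conditions. Both ρ
and the pseudocount are exposed parameters.

## Feature vector (733 dimensions)

The canonical dimension is 733; the block-level composition is fixed
only qualitatively (local predicted properties, whole-sequence
properties, coevolution scores), so the layout here is a documented,
configurable reconstruction that realises that composition at exactly
733 dimensions:

* per-residue windows (half-width 3, 7 positions) around i and around j,
  each position contributing 46 values: 21 weighted profile
  frequencies, 20-state query identity, 3-state secondary structure,
  accessibility, and a boundary flag — out-of-chain window slots are
  all-zero except the flag, so edge pairs are distinguishable from
  genuine zeros; 2 × 7 × 46 = 644;
* pair blocks: 5×5 windows (half-width 2) of APC couplings, raw
  couplings and mutual information centred on (i, j), plus sequence
  separation (normalised and log2) and three gap-fraction values;
  3 × 25 + 5 = 80;
* global block: scaled L, log L, log(1+M_eff), scaled N_f, log(1+N_f),
  H/E/C composition, mean accessibility; 9.

644 + 80 + 9 = 733. The layout is serialisable to YAML and identified by
a content hash; trained networks refuse vectors built under a different
schema. Vectors are computable without any structure coordinates, so
label leakage is structurally impossible.

## Networks and training

All seven networks share one architecture: input, eight rectifier hidden
layers of 120, 50 and six of 30 units, and a single logistic output
(100,341 parameters at input 733). Contacts are scored by the mean of
four networks trained on nested intervals (0, 7.9], (0, 8.0], (0, 8.1],
(0, 8.2] Å; each distance bin has one network. The architecture, the
logistic output and early stopping are the method's contract; the
optimiser is an implementation choice, here Adam (lr 1e−3, batch 64) on binary cross-entropy, with a seeded 15%
validation split, stopping after 10 evaluations without improvement and
returning the best-validation-loss weights. Because ~92% of pairs are
non-contacting, negatives are subsampled to at most 5 per positive
(seeded) before training. All randomness — initialisation, splits, batch
order, subsampling — flows from explicit seeds; training is bit
reproducible on one platform, and models serialise exactly to npz.

Distance bins whose assembled training set contains a single class (a
real possibility on very small toys) are skipped with a warning and
recorded on the results object rather than trained vacuously.

## Selection rules and constraint emission

From the scored pairs: the ⌊3L/2⌋ top contacts regardless of score, and
per distance bin the pairs scoring at least 0.6 / 0.6 / 0.7 capped at
⌊1.5L⌋ / ⌊L⌋ / ⌊0.5L⌋ for 8–13 / 13–18 / 18–23 Å. Ties are broken score
descending, then (i, j) ascending, making selection deterministic; fractional
caps always floor. Eligibility filtering happens before ranking.

Selected pairs serialise to the Rosetta `AtomPair` grammar, CB atoms
with CA for glycine, contacts first then bins by distance, each in rank
order; identical inputs give byte-identical files. Default potentials — a
FADE well spanning the contact range and flat-bottomed BOUNDED functions
over each bin interval — are configurable per bin via YAML; the
grammar and per-bin parameterisation are the contract, the numeric
defaults are this package's own.
BOUNDED lines carry numeric parameters only (lb, ub, sd, rswitch); the
optional Rosetta tag token is omitted so lines round-trip as floats.
Folding itself is out of scope; the package consumes an energy-annotated
model pool and returns the lowest-total-energy entry (ties by
identifier).

## Evaluation

Only positive predictions are emitted, so TN = FN = 0 and accuracy
(correct/all × 100) coincides with PPV; the identity is asserted
programmatically on every report. Top-fraction curves evaluate the best
⌊f·L⌋ predictions at fractions of L. Residue-type propensities follow
the O/E construction: per structure and bin, E is the type distribution
of the bin's true pairs and O that of the correctly predicted pairs with
score ≥ 0.7 (each sums to 1 per structure); the reported table is
log2 of O/E averaged over structures where the type occurs in the truth
(E > 0), with contributing-structure counts alongside, and a pooled
variant behind a flag for comparison. Per-type precision pools correct
over predicted counts across structures. Pair types are unordered, so
all tables are symmetric under type exchange.

## Synthetic data

The generator supplies the desk-scale stand-in for a real training
corpus. Toy structures are compact self-avoiding chains: bond length
3.8 Å between consecutive Cα, non-bonded minimum 4.0 Å, a centripetal
bias that increases deterministically on retry until the fold has at
least 0.5 L contacts at separation ≥ 6 on the representative-atom map,
pseudo-Cβ 1.5 Å from the Cα pointing away from the chain neighbours, and
~8% glycine so the Cα fallback is always exercised. Tracks are
plausible: helix/strand runs of 4–12 residues separated by 2–5 coil,
accessibility a monotone decreasing rescaling of per-residue contact
count.

Alignments are sampled column-independently from per-column Dirichlet(2)
backgrounds, except at planted pairs — a subset of genuine long-range
contacts, each residue used once — which are drawn jointly from
P(a,b) ∝ p_i(a)p_j(b)exp(s·[b = σ(a)]) with a per-pair random bijection
σ and strength s (default 2.5); s = 0 reduces exactly to independence.
Row 0 is the query sequence; a 3% uniform gap overlay is applied. A
reduced alphabet (e.g. 4 letters) is available for fast unit tests.

What this does *not* emulate: phylogenetic correlation between rows,
entropy variation of real columns, indel structure, and couplings that
share residues or chain through the contact network. Synthetic recovery
is therefore easier than on real alignments — passing tests demonstrate
the machinery is correct and well-calibrated at the stated conditions,
not that real-protein accuracy matches externally reported figures, which would
require external structure sets, database-built alignments, external SS
predictors and folding runs.

## Numerical choices and problem sizes

Distance intervals are (low, high]; identity clustering is greedy
single-linkage in row order; shrinkage grid step 0.05; glasso tolerance
1e−3 (1e−7 in oracle comparisons); MI is clamped at 0 and computed from
the same weighted frequency tables as the covariance. Finite-sample MI
estimates carry a positive bias ≈ (q−1)²/(2M ln 2) bits, which the tests
account for by using the reduced alphabet or percentile-based
comparisons rather than absolute thresholds at q = 21.

Test and verification sizes, chosen to exercise every code path in a
couple of minutes: unit fixtures L = 30, M = 300; planted-coupling
recovery L = 50, M = 2000 over 5 seeds (top-L/5 precision 1.0 against a
base rate ≈ 0.011); end-to-end training/prediction/constraint emission
L = 60, M = 1000 over 3 seeds (top-L/10 contact precision ≈ 0.9–1.0
against base ≈ 0.05).

## Known limitations

* The 733-feature layout is this package's own reconstruction of the
  qualitative composition; trained weights are not comparable to any
  externally trained model's.
* M_eff by cluster counting is the literal reading of its definition; a
  summed-inverse-weight variant is available (`method="weights"`).
* Secondary-structure dihedral restraints are not emitted; only
  `AtomPair` restraints are produced.
* The PDB reader handles single-model ATOM records with altloc blank/A
  and renumbers sequentially; mmCIF and biological assemblies are out of
  scope.
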