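# cdpred

Residue–residue **contact** and **distance-bin** prediction from multiple
sequence alignments, with emission of Rosetta restraints for de novo
structure modelling.

## The problem and the method

For a globular protein roughly 92% of residue pairs are non-contacting,
so even a modest number of correctly predicted inter-residue distances
adds substantial information for structure prediction. `cdpred`
classifies each residue pair (i, j) of a query protein into a contact
class or one of three distance bins, measured between Cβ atoms (Cα for
glycine):

| bin | interval (Å) | min \|i−j\| | same-SS pairs | selection rule |
|---|---|---|---|---|
| contact | (0, 8]   | 6  | kept    | top ⌊3L/2⌋ by score, no threshold |
| 8–13    | (8, 13]  | 8  | removed | score ≥ 0.6, ≤ ⌊1.5L⌋ |
| 13–18   | (13, 18] | 13 | removed | score ≥ 0.6, ≤ ⌊L⌋ |
| 18–23   | (18, 23] | 15 | removed | score ≥ 0.7, ≤ ⌊0.5L⌋ |

Pairs on the same predicted helix or strand, and pairs closer than each
bin's minimum separation, are excluded for the distance bins because
their distance is trivially implied by local geometry.

The pipeline is:

1. **Alignment statistics** — effective sequence count
   M_eff (greedy clustering at 80% identity) and normalised depth
   N_f = M_eff / √L.
2. **Coevolution** — sequence-weighted 21-state frequencies with a
   pseudocount, the (21L)×(21L) sample covariance shrunk to positive
   definiteness, a sparse precision matrix Θ from the graphical lasso
   (min −log det Θ + tr(SΘ) + ρ‖Θ‖₁ off-diagonal), and per-pair coupling
   scores ‖Θ_ij‖₁ over the 20×20 amino-acid block with the average
   product correction.
3. **Features** — a 733-dimensional vector per pair: windowed profile /
   secondary-structure / accessibility blocks around i and j, windowed
   coupling and mutual-information blocks around (i, j), sequence
   separation and gap statistics, and global L / M_eff / N_f terms.
4. **Networks** — seven feed-forward networks sharing one architecture
   (input, hidden layers 120–50–30×6, logistic output): four contact
   networks trained on nested cutoffs (0,7.9]…(0,8.2] Å whose mean is the
   contact score, and one network per distance bin. Training is Adam on
   binary cross-entropy with early stopping on a validation split.
5. **Constraints** — selected pairs become Rosetta `AtomPair` lines
   (FADE well for contacts, BOUNDED for the bins; CA for glycine), and
   the final model of a folded pool is the lowest-total-energy entry.

Predicted secondary structure and solvent accessibility are consumed as
input tracks (produced externally); the `synthetic` module fabricates
consistent toy structures, coupled alignments and tracks so the entire
pipeline runs offline.

## Worked example

Generate a synthetic protein (L = 60) with a deep coupled alignment,
inspect its depth, and compute couplings:

```bash
$ cdpred simulate --length 60 --depth 1000 --seed 7 --out fx/
wrote synthetic fixture (L=60, M=1000) to fx/

$ cdpred msa-stats fx/toy.aln --format aln
M       Meff    Nf
1000    1000    129.0994

$ cdpred couplings fx/toy.aln --format aln --out fx/couplings.tsv
wrote couplings for L=60 to fx/couplings.tsv
```

All 1000 sampled rows are mutually <80% identical, so M_eff = 1000 and
N_f = 1000/√60 ≈ 129 — a very deep alignment by real-protein standards.
The couplings TSV holds raw and APC-corrected scores per pair; planted
coupled pairs rank at the top.

Training and prediction from Python:

```python
from cdpred import ContactDistanceModel, TrainingProtein, TrainConfig
from cdpred.synthetic import make_toy_protein, sample_coupled_msa

toy = make_toy_protein(L=60, seed=1)
msa = sample_coupled_msa(toy, M=1000, seed=2)
model = ContactDistanceModel([TrainingProtein.from_toy(toy, msa)])
results = model.fit(TrainConfig(max_epochs=30, patience=5, seed=0))
print(results.summary())
```

```
Contact/distance-bin network training summary
========================================================================
network           n_train   n_pos  best epoch   val loss  early stop
------------------------------------------------------------------------
contact<=7.9          258      43           9     0.2092        True
contact<=8.0          270      45           7     0.2476        True
contact<=8.1          288      48           6     0.1363        True
contact<=8.2          306      51           3     0.3043        True
8-13                  840     140           5     0.3783        True
13-18                1002     167           5     0.2648        True
18-23                1035     187           5     0.3534        True
------------------------------------------------------------------------
feature dimension: 733   networks: 7   parameters each: 100341
```

Each row is one network: its training-set size after 5:1
negative:positive balancing, positive count, the epoch whose validation
loss was lowest (those weights are returned), and that loss.
`results.predict_protein(...)` then scores every eligible pair of every
bin, and the selection rules above turn the scores into a constraint
file (`cdpred constraints`).

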