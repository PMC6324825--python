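"""Desk-scale synthetic fixtures: toy folds, coupled alignments, tracks.

Real training data for contact/distance networks needs solved structures
and deep alignments. This module fabricates both at toy scale so the
whole pipeline is exercisable offline:

* compact self-avoiding 3D chains with realistic Cα spacing (3.8 Å) and
  pseudo-Cβ atoms, guaranteeing a usable number of long-range contacts;
* alignments whose columns are sampled independently from per-column
  background distributions except at a planted set of contacting residue
  pairs, which are sampled jointly from a pairwise energy model — the
  idealised coevolutionary signal that covariance methods look for;
* consistent secondary-structure and accessibility tracks (helix/strand
  runs of realistic lengths; accessibility decreasing with burial).

The planted-pair sampler is a deliberate simplification of evolutionary
covariance: pairs are coupled independently of each other and there is
no phylogeny, so recovering them is easier than on real alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import Residue, SsTrack, StructureModel, cb_distance_map, ss_elements
from .msa import ALPHABET, AMINO_ACIDS, GAP, Msa

_BOND = 3.8       # consecutive Cα spacing, Å
_CLASH = 4.0      # minimum non-bonded Cα distance, Å
_CB_OFFSET = 1.5  # pseudo-Cβ offset from Cα, Å


@dataclass
class ToyProtein:
    """A synthetic protein: structure, truth, planted couplings, tracks."""

    structure: StructureModel
    contact_map: np.ndarray                       # bool L x L, d <= 8 Å
    planted: list[tuple[tuple[int, int], float]]  # ((i, j) 1-based, strength)
    ss: SsTrack
    acc: np.ndarray
    seed: int

    @property
    def L(self) -> int:
        return self.structure.L

    @property
    def sequence(self) -> str:
        return self.structure.sequence


def _grow_chain(L: int, rng: np.random.Generator, bias: float) -> np.ndarray | None:
    """One attempt at a compact self-avoiding chain; None on failure."""
    coords = np.zeros((L, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for k in range(1, L):
        placed = False
        for _ in range(60):
            centroid = coords[:k].mean(axis=0)
            pull = centroid - coords[k - 1]
            norm = np.linalg.norm(pull)
            pull = pull / norm if norm > 1e-9 else np.zeros(3)
            step = 0.9 * direction + bias * pull + rng.normal(0.0, 1.0, 3)
            step /= np.linalg.norm(step)
            cand = coords[k - 1] + _BOND * step
            if k >= 2:
                d = np.linalg.norm(coords[: k - 1] - cand, axis=1)
                if d.min() < _CLASH:
                    continue
            coords[k] = cand
            direction = step
            placed = True
            break
        if not placed:
            return None
    return coords


def make_toy_structure(L: int, seed: int) -> StructureModel:
    """A compact self-avoiding chain with Cα/pseudo-Cβ coordinates.

    Consecutive Cα atoms are 3.8 Å apart; each non-glycine residue gets a
    pseudo-Cβ 1.5 Å from its Cα pointing away from the chain neighbours.
    The generator retries (deterministically, from the one seed) until
    the fold has at least 0.5 L contacts with sequence separation >= 6.
    """
    if not 20 <= L <= 400:
        raise ValueError("L must be in [20, 400]")
    rng = np.random.default_rng(seed)
    for attempt in range(200):
        bias = 0.5 + 0.05 * (attempt // 10)
        coords = _grow_chain(L, rng, bias)
        if coords is None:
            continue
        # ~8% glycine so the Cα fallback path is always exercised
        seq = [
            "G" if rng.random() < 0.08 else AMINO_ACIDS[rng.integers(0, 20)]
            for _ in range(L)
        ]
        residues = []
        for k in range(L):
            aa = seq[k]
            cb = None
            if aa != "G":
                away = np.zeros(3)
                if k > 0:
                    away += coords[k] - coords[k - 1]
                if k < L - 1:
                    away += coords[k] - coords[k + 1]
                norm = np.linalg.norm(away)
                if norm < 1e-9:
                    away = np.array([0.0, 0.0, 1.0])
                    norm = 1.0
                cb = coords[k] + _CB_OFFSET * away / norm
            residues.append(Residue(index=k + 1, aa=aa, ca=coords[k], cb=cb))
        structure = StructureModel(residues=residues, chain_id="A")
        # the contact guarantee is on the representative-atom (Cβ/Cα) map,
        # the same geometry every downstream consumer sees
        dmap = cb_distance_map(structure)
        n_contacts = sum(
            1 for i in range(L) for j in range(i + 6, L) if dmap[i, j] <= 8.0
        )
        if n_contacts >= 0.5 * L:
            return structure
    raise RuntimeError(
        f"could not grow a compact self-avoiding chain for L={L}, "
        f"seed={seed}; try another seed"
    )


def make_tracks(structure: StructureModel, seed: int) -> tuple[SsTrack, np.ndarray]:
    """Plausible predicted SS labels and accessibility for a toy fold.

    Secondary structure alternates coil runs (2-5 residues) with helix or
    strand runs (4-12). Accessibility decreases monotonically with the
    residue's contact count, rescaled to [0, 1].
    """
    rng = np.random.default_rng(seed)
    L = structure.L
    labels: list[str] = []
    while len(labels) < L:
        labels.extend("C" * int(rng.integers(2, 6)))
        kind = "H" if rng.random() < 0.5 else "E"
        labels.extend(kind * int(rng.integers(4, 13)))
    labels = labels[:L]
    # guarantee the trailing run is still a valid (possibly short) element
    ss = ss_elements("".join(labels))

    dmap = cb_distance_map(structure)
    counts = ((dmap <= 8.0).sum(axis=1) - 1).astype(float)
    span = counts.max() - counts.min()
    if span < 1e-9:
        acc = np.full(L, 0.5)
    else:
        acc = (counts.max() - counts) / span
    return ss, acc


def make_toy_protein(
    L: int = 60,
    seed: int = 0,
    n_planted: int | None = None,
    coupling_strength: float = 2.5,
) -> ToyProtein:
    """Bundle a toy structure, tracks and planted contacting couplings.

    Planted pairs are drawn from the contacting (d <= 8 Å) pairs with
    sequence separation >= 6, each residue used at most once, so every
    planted coupling corresponds to a genuine long-range contact.
    """
    structure = make_toy_structure(L, seed)
    rng = np.random.default_rng(seed + 1)
    dmap = cb_distance_map(structure)
    contact_map = dmap <= 8.0
    np.fill_diagonal(contact_map, False)
    candidates = [
        (i, j)
        for i in range(1, L + 1)
        for j in range(i + 6, L + 1)
        if contact_map[i - 1, j - 1]
    ]
    if n_planted is None:
        n_planted = max(4, L // 4)
    order = rng.permutation(len(candidates))
    used: set[int] = set()
    planted: list[tuple[tuple[int, int], float]] = []
    for k in order:
        i, j = candidates[k]
        if i in used or j in used:
            continue
        used.update((i, j))
        planted.append(((i, j), coupling_strength))
        if len(planted) >= n_planted:
            break
    ss, acc = make_tracks(structure, seed + 2)
    return ToyProtein(
        structure=structure, contact_map=contact_map, planted=planted,
        ss=ss, acc=acc, seed=seed,
    )


def sample_coupled_msa(
    toy: ToyProtein,
    M: int,
    coupling_strength: float | None = None,
    seed: int = 0,
    n_aa_states: int = 20,
    gap_fraction: float = 0.03,
) -> Msa:
    """Sample an alignment with couplings planted at contacting pairs.

    Non-planted columns are sampled independently from per-column
    Dirichlet background distributions over the first ``n_aa_states``
    amino acids. Each planted pair (i, j) is sampled jointly from
    P(a, b) ∝ p_i(a) p_j(b) exp(strength · [b = σ(a)]) for a seeded
    random bijection σ, i.e. a pairwise energy model favouring a fixed
    set of state combinations. Strength 0 reduces to full independence.
    Row 0 is the toy protein's own sequence (the query). A small uniform
    gap fraction is overlaid afterwards.

    A reduced ``n_aa_states`` (e.g. 4) makes unit tests fast; the full
    20 letters are the realistic default.
    """
    if M < 50:
        raise ValueError("need at least 50 rows for a meaningful alignment")
    rng = np.random.default_rng(seed)
    L = toy.L
    q = n_aa_states
    probs = rng.dirichlet(np.full(q, 2.0), size=L)
    codes = np.empty((M - 1, L), dtype=np.int64)
    for c in range(L):
        codes[:, c] = rng.choice(q, size=M - 1, p=probs[c])
    for (i, j), strength in toy.planted:
        s = coupling_strength if coupling_strength is not None else strength
        sigma = rng.permutation(q)
        P = np.outer(probs[i - 1], probs[j - 1])
        P[np.arange(q), sigma] *= np.exp(s)
        P = P / P.sum()
        flat = rng.choice(q * q, size=M - 1, p=P.ravel())
        codes[:, i - 1] = flat // q
        codes[:, j - 1] = flat % q
    if gap_fraction > 0:
        gaps = rng.random(codes.shape) < gap_fraction
    else:
        gaps = np.zeros(codes.shape, dtype=bool)
    rows = [toy.sequence]
    for r in range(M - 1):
        chars = [
            GAP if gaps[r, c] else ALPHABET[codes[r, c]]
            for c in range(L)
        ]
        rows.append("".join(chars))
    return Msa(query_id=f"toy_L{L}_seed{toy.seed}", rows=rows)


def write_fixture_dir(toy: ToyProtein, msa: Msa, directory: str | Path) -> None:
    """Write PDB, aln, SS/accessibility TSVs and truth labels to a directory."""
    from .geometry import DEFAULT_BINS, pair_labels
    from .msa import write_msa

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_pdb(toy.structure, directory / "toy.pdb")
    write_msa(msa, directory / "toy.aln", format="aln")
    with (directory / "ss.tsv").open("w") as fh:
        for k, lab in enumerate(toy.ss.labels, start=1):
            fh.write(f"{k}\t{lab}\n")
    with (directory / "acc.tsv").open("w") as fh:
        for k, a in enumerate(toy.acc, start=1):
            fh.write(f"{k}\t{a:.4f}\n")
    labels = pair_labels(toy.structure, DEFAULT_BINS)
    with (directory / "truth.tsv").open("w") as fh:
        fh.write("i\tj\tbin\n")
        for (i, j), lab in sorted(labels.items()):
            fh.write(f"{i}\t{j}\t{lab or 'none'}\n")


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write Cα/Cβ coordinates as a minimal single-chain PDB file."""
    from Bio.PDB import PDBIO, StructureBuilder

    from .geometry import ONE_TO_THREE

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("toy")
    builder.init_model(0)
    builder.init_chain(structure.chain_id)
    builder.init_seg("    ")
    for res in structure.residues:
        resname = ONE_TO_THREE.get(res.aa, "UNK")
        builder.init_residue(resname, " ", res.index, " ")
        builder.init_atom("CA", res.ca.astype(np.float32), 0.0, 1.0, " ", " CA ",
                          element="C")
        if res.cb is not None:
            builder.init_atom("CB", res.cb.astype(np.float32), 0.0, 1.0, " ",
                              " CB ", element="C")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))
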