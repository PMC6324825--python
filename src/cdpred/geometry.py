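"""Structure geometry: Cβ distance maps, distance bins, eligibility filters.

Inter-residue distances are measured between Cβ atoms, falling back to Cα
for glycine (which has no Cβ) or where the Cβ is unresolved. Pairs are
classified into half-open distance intervals: contact (0, 8] Å, then
(8, 13], (13, 18] and (18, 23] Å.

Each bin carries its own eligibility filter. Pairs closer than 6 residues
in sequence are trivially close in space and are excluded everywhere.
The distance bins additionally use larger minimum separations (8, 13 and
15 residues) — below those, sequence separation alone pins down the
distance range — and exclude pairs lying on the same predicted helix or
strand, whose distance follows from local geometry. The contact bin keeps
same-element pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

#: canonical 3-letter -> 1-letter residue codes
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class Residue:
    index: int                      # sequential, 1-based
    aa: str                         # one-letter code ('X' if non-standard)
    ca: np.ndarray                  # Cα coordinates, Å
    cb: np.ndarray | None = None    # Cβ coordinates, Å; None for glycine


@dataclass
class StructureModel:
    """Ordered residues of one chain with Cα/Cβ coordinates."""

    residues: list[Residue]
    chain_id: str = "A"

    @property
    def L(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def representative_atom(self, k: int) -> tuple[str, np.ndarray]:
        """Name and coordinates of the distance atom of residue k (0-based)."""
        r = self.residues[k]
        if r.cb is not None:
            return "CB", r.cb
        return "CA", r.ca


@dataclass(frozen=True)
class BinSpec:
    """One distance bin's interval, filters and selection rule."""

    name: str
    low: float                  # Å, exclusive
    high: float                 # Å, inclusive
    min_sep: int                # minimum |i - j|
    score_threshold: float      # selection threshold on network score
    cap_factor: float           # selection cap as a multiple of L
    exclude_same_ss: bool       # drop pairs on one helix/strand element

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"bin {self.name}: low must be < high")
        if self.min_sep < 6:
            raise ValueError(f"bin {self.name}: min_sep must be >= 6")
        if self.cap_factor <= 0:
            raise ValueError(f"bin {self.name}: cap_factor must be positive")


CONTACT_BIN = BinSpec("contact", 0.0, 8.0, 6, 0.0, 1.5, False)
DEFAULT_BINS: tuple[BinSpec, ...] = (
    CONTACT_BIN,
    BinSpec("8-13", 8.0, 13.0, 8, 0.6, 1.5, True),
    BinSpec("13-18", 13.0, 18.0, 13, 0.6, 1.0, True),
    BinSpec("18-23", 18.0, 23.0, 15, 0.7, 0.5, True),
)

#: training intervals of the four contact-ensemble members (Å upper bounds)
CONTACT_ENSEMBLE_CUTOFFS = (7.9, 8.0, 8.1, 8.2)


def validate_bins(bins: list[BinSpec] | tuple[BinSpec, ...]) -> None:
    """Reject overlapping distance intervals."""
    ordered = sorted(bins, key=lambda b: b.low)
    for a, b in zip(ordered, ordered[1:]):
        if b.low < a.high:
            raise ValueError(f"bins {a.name} and {b.name} overlap")


@dataclass
class SsTrack:
    """Per-residue 3-state secondary structure with element identifiers.

    Residues in one maximal run of identical H or E labels share an
    element id; every coil residue is its own element.
    """

    labels: str
    element_id: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        bad = set(self.labels) - set("HEC")
        if bad:
            raise ValueError(f"unknown secondary-structure labels: {sorted(bad)}")
        if self.element_id is None:
            self.element_id = _element_ids(self.labels)

    @property
    def L(self) -> int:
        return len(self.labels)


def _element_ids(labels: str) -> np.ndarray:
    ids = np.empty(len(labels), dtype=int)
    current = 0
    for k, lab in enumerate(labels):
        if k == 0:
            ids[k] = current
            continue
        prev = labels[k - 1]
        if lab == prev and lab in "HE":
            ids[k] = ids[k - 1]
        else:
            current += 1
            ids[k] = current
    return ids + 1  # 1-based ids


def ss_elements(labels: str) -> SsTrack:
    """Segment an H/E/C label string into secondary-structure elements."""
    return SsTrack(labels=labels)


def read_structure(path: str | Path, chain: str = "A") -> StructureModel:
    """Read one chain from a PDB file into a StructureModel.

    ATOM records only; altloc blank or 'A' kept; residues are renumbered
    sequentially 1..L in file order. Residues missing a Cα are dropped
    with a warning.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} not in {path}; available chains: {sorted(chains)}"
        )
    residues: list[Residue] = []
    for res in chains[chain].get_residues():
        if res.id[0] != " ":       # skip HETATM / water
            continue
        name = res.get_resname().strip()
        aa = THREE_TO_ONE.get(name, "X")
        ca = cb = None
        for atom in res.get_atoms():
            if atom.get_altloc() not in (" ", "A"):
                continue
            if atom.get_name() == "CA":
                ca = atom.get_coord().astype(float)
            elif atom.get_name() == "CB":
                cb = atom.get_coord().astype(float)
        if ca is None:
            warnings.warn(
                f"residue {res.id[1]}{name} in chain {chain} has no CA; dropped",
                stacklevel=2,
            )
            continue
        residues.append(Residue(index=len(residues) + 1, aa=aa, ca=ca, cb=cb))
    return StructureModel(residues=residues, chain_id=chain)


def cb_distance_map(structure: StructureModel) -> np.ndarray:
    """L x L Euclidean distances between representative (Cβ/Cα) atoms."""
    coords = np.array(
        [structure.representative_atom(k)[1] for k in range(structure.L)]
    )
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def assign_bin(d: float, bins: list[BinSpec] | tuple[BinSpec, ...] = DEFAULT_BINS) -> str | None:
    """Name of the bin whose (low, high] interval contains d, else None."""
    validate_bins(bins)
    for b in bins:
        if b.low < d <= b.high:
            return b.name
    return None


def eligible_pairs(
    L: int, bin: BinSpec, ss: SsTrack | None = None
) -> list[tuple[int, int]]:
    """All 1-based pairs (i, j), i < j, passing the bin's filters.

    Separation filter: j - i >= the bin's minimum separation. If the bin
    excludes same-secondary-structure pairs, pairs whose residues share a
    helix/strand element id are removed (requires an SS track).
    """
    if bin.exclude_same_ss and ss is None:
        raise ValueError(f"bin {bin.name} excludes same-SS pairs; SS track required")
    pairs = []
    for i in range(1, L + 1):
        for j in range(i + bin.min_sep, L + 1):
            if bin.exclude_same_ss and ss.element_id[i - 1] == ss.element_id[j - 1]:
                continue
            pairs.append((i, j))
    return pairs


def pair_labels(
    structure: StructureModel,
    bins: list[BinSpec] | tuple[BinSpec, ...] = DEFAULT_BINS,
) -> dict[tuple[int, int], str | None]:
    """Bin label of every i < j pair from the structure's distance map."""
    dmap = cb_distance_map(structure)
    L = structure.L
    validate_bins(bins)
    out: dict[tuple[int, int], str | None] = {}
    for i in range(1, L + 1):
        for j in range(i + 1, L + 1):
            d = dmap[i - 1, j - 1]
            label = None
            for b in bins:
                if b.low < d <= b.high:
                    label = b.name
                    break
            out[(i, j)] = label
    return out
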