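"""Selection of scored pairs and Rosetta constraint-file emission.

Scored pairs become structure-modelling restraints under bin-specific
rules: the top 3L/2 contacts by score regardless of threshold, and for
the 8-13 / 13-18 / 18-23 Å bins pairs scoring at least 0.6 / 0.6 / 0.7
capped at 1.5L / L / 0.5L pairs respectively. Selected pairs serialize
to the Rosetta ``AtomPair`` constraint grammar (one line per restraint,
Cβ atoms, Cα for glycine), ready for a fragment-assembly folding run;
the folded pool's final model is the entry with the lowest total energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .geometry import BinSpec, StructureModel

#: default restraint potentials per bin: FADE well over the contact range,
#: flat-bottomed bounded potentials over each distance interval
DEFAULT_POTENTIALS: dict[str, tuple[str, tuple[float, ...]]] = {
    "contact": ("FADE", (-10.0, 19.0, 10.0, -15.0, 0.0)),
    "8-13": ("BOUNDED", (8.0, 13.0, 1.0, 0.5)),
    "13-18": ("BOUNDED", (13.0, 18.0, 1.0, 0.5)),
    "18-23": ("BOUNDED", (18.0, 23.0, 1.0, 0.5)),
}


@dataclass(frozen=True)
class PairPrediction:
    """One scored candidate pair from a bin's network."""

    i: int
    j: int
    bin: str
    score: float

    def __post_init__(self) -> None:
        if not self.i < self.j:
            raise ValueError(f"require i < j; got ({self.i}, {self.j})")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1]; got {self.score}")


def _ranked(preds: list[PairPrediction]) -> list[PairPrediction]:
    # score descending, then i ascending, then j ascending — deterministic
    return sorted(preds, key=lambda p: (-p.score, p.i, p.j))


def select_contacts(preds: list[PairPrediction], L: int) -> list[PairPrediction]:
    """The floor(3L/2) top-scoring contacts, irrespective of score."""
    for p in preds:
        if p.bin != "contact":
            raise ValueError(f"non-contact prediction in contact selection: {p}")
    return _ranked(preds)[: math.floor(3 * L / 2)]


def select_distance_pairs(
    preds: list[PairPrediction], bin: BinSpec, L: int
) -> list[PairPrediction]:
    """Pairs scoring >= the bin threshold, capped at floor(cap_factor L)."""
    if bin.name == "contact":
        raise ValueError("contact bin uses select_contacts (no score threshold)")
    for p in preds:
        if p.bin != bin.name:
            raise ValueError(f"prediction for bin {p.bin!r} passed to {bin.name!r}")
    passing = [p for p in preds if p.score >= bin.score_threshold]
    return _ranked(passing)[: math.floor(bin.cap_factor * L)]


@dataclass(frozen=True)
class ConstraintRecord:
    """One AtomPair restraint serializable to the Rosetta grammar."""

    atom_i: str
    res_i: int
    atom_j: str
    res_j: int
    function: str
    parameters: tuple[float, ...]

    def to_line(self) -> str:
        params = " ".join(_fmt(p) for p in self.parameters)
        return (
            f"AtomPair {self.atom_i} {self.res_i} {self.atom_j} {self.res_j} "
            f"{self.function} {params}"
        )

    @classmethod
    def from_line(cls, line: str) -> "ConstraintRecord":
        tokens = line.split()
        if len(tokens) < 7 or tokens[0] != "AtomPair":
            raise ValueError(f"not an AtomPair constraint line: {line!r}")
        return cls(
            atom_i=tokens[1],
            res_i=int(tokens[2]),
            atom_j=tokens[3],
            res_j=int(tokens[4]),
            function=tokens[5],
            parameters=tuple(float(t) for t in tokens[6:]),
        )


def _fmt(x: float) -> str:
    return f"{x:g}"


def _atom_for(structure: StructureModel | None, res: int, sequence: str | None) -> str:
    if structure is not None:
        aa = structure.residues[res - 1].aa
    elif sequence is not None:
        aa = sequence[res - 1]
    else:
        return "CB"
    return "CA" if aa == "G" else "CB"


def build_constraints(
    selections: dict[str, list[PairPrediction]],
    sequence: str | None = None,
    structure: StructureModel | None = None,
    potentials: dict[str, tuple[str, tuple[float, ...]]] | None = None,
    bin_order: tuple[str, ...] = ("contact", "8-13", "13-18", "18-23"),
) -> list[ConstraintRecord]:
    """Turn per-bin selections into ordered ConstraintRecords.

    Glycine positions (known from the query sequence or a structure) use
    the CA atom. Ordering is stable: contacts first, then bins by
    increasing distance, each in selection rank order.
    """
    pots = dict(DEFAULT_POTENTIALS)
    if potentials:
        pots.update(potentials)
    records: list[ConstraintRecord] = []
    for bin_name in bin_order:
        if bin_name not in selections:
            continue
        func, params = pots[bin_name]
        for p in selections[bin_name]:
            records.append(
                ConstraintRecord(
                    atom_i=_atom_for(structure, p.i, sequence),
                    res_i=p.i,
                    atom_j=_atom_for(structure, p.j, sequence),
                    res_j=p.j,
                    function=func,
                    parameters=params,
                )
            )
    return records


def write_constraint_file(
    records: list[ConstraintRecord], path: str | Path
) -> None:
    """One AtomPair line per record; trailing newline; byte-stable."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_constraint_file(path: str | Path) -> list[ConstraintRecord]:
    """Parse a constraint file written by :func:`write_constraint_file`."""
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        records.append(ConstraintRecord.from_line(line))
    return records


@dataclass(frozen=True)
class ModelPoolEntry:
    """A candidate folded model with its total energy."""

    identifier: str
    energy: float
    similarity: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise ValueError(f"model {self.identifier}: energy must be finite")


def select_lowest_energy(pool: list[ModelPoolEntry]) -> ModelPoolEntry:
    """Entry with minimal total energy; ties broken by identifier order."""
    if not pool:
        raise ValueError("empty model pool")
    return min(pool, key=lambda e: (e.energy, e.identifier))
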