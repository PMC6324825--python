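"""Multiple sequence alignment I/O and redundancy statistics.

An alignment is held as a list of equal-length uppercase strings over the
20 amino acids, ``-`` (gap) and ``X`` (unknown). Row 0 is the query. The
depth statistics Meff (number of sequence clusters at an identity cutoff)
and Nf (Meff normalised by sqrt of query length) quantify how much
non-redundant evolutionary information an alignment carries; contact
prediction accuracy rises with Nf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: residue alphabet used throughout: 20 amino acids then the gap state
ALPHABET = AMINO_ACIDS + GAP
N_STATES = len(ALPHABET)  # 21
_AA_SET = set(AMINO_ACIDS)

_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE["X"] = N_STATES - 1  # unknown residues are pooled with the gap state


class MsaFormatError(ValueError):
    """Raised when an alignment file cannot be parsed."""


@dataclass
class Msa:
    """An aligned set of homologous sequences with a designated query.

    Parameters
    ----------
    query_id:
        Identifier of the query sequence (row 0).
    rows:
        Aligned sequences, all the same length, uppercase, over the 20
        amino acids plus ``-`` and ``X``.
    """

    query_id: str
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise MsaFormatError("alignment has no rows")
        width = len(self.rows[0])
        for k, row in enumerate(self.rows):
            if len(row) != width:
                raise MsaFormatError(
                    f"row {k} ({self.query_id!r} alignment) has length "
                    f"{len(row)}, expected {width}"
                )
        allowed = _AA_SET | {GAP, "X"}
        bad = set("".join(self.rows)) - allowed
        if bad:
            raise MsaFormatError(f"unexpected characters in alignment: {sorted(bad)}")

    @property
    def M(self) -> int:
        """Number of rows."""
        return len(self.rows)

    @property
    def width(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0])

    @property
    def L(self) -> int:
        """Query length: number of non-gap columns of row 0."""
        return sum(1 for c in self.rows[0] if c != GAP)

    def encoded(self) -> np.ndarray:
        """Integer codes, shape (M, width); amino acids 0..19, gap/X = 20."""
        out = np.empty((self.M, self.width), dtype=np.int32)
        for k, row in enumerate(self.rows):
            out[k] = [_CODE[c] for c in row]
        return out

    def query_columns(self) -> list[int]:
        """Alignment-column indices where the query has a residue."""
        return [k for k, c in enumerate(self.rows[0]) if c != GAP]

    def to_query_columns(self) -> "Msa":
        """Restrict the alignment to the query's non-gap columns (width L)."""
        cols = self.query_columns()
        return Msa(
            query_id=self.query_id,
            rows=["".join(row[c] for c in cols) for row in self.rows],
        )

    def __iter__(self) -> Iterator[str]:
        return iter(self.rows)


@dataclass
class MsaStats:
    """Redundancy statistics of one alignment."""

    meff: float
    nf: float
    identity_threshold: float
    cluster_assignments: np.ndarray = field(repr=False, default=None)


def read_msa(path: str | Path, format: Literal["fasta", "a3m", "aln"] = "fasta") -> Msa:
    """Read an alignment in FASTA, A3M or one-row-per-line (aln) dialect.

    A3M lowercase columns are insertions relative to the query and are
    removed; remaining residues are uppercased and unknown letters mapped
    to ``X``. The first sequence is taken as the query.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise MsaFormatError(f"{path}: empty alignment file")
    if format in ("fasta", "a3m"):
        ids, seqs = _parse_fasta_like(text, path)
        if format == "a3m":
            seqs = [_strip_inserts(s) for s in seqs]
        rows = [_sanitize(s) for s in seqs]
        widths = {len(r) for r in rows}
        if len(widths) > 1:
            offender = next(i for i, r in enumerate(rows) if len(r) != len(rows[0]))
            raise MsaFormatError(
                f"{path}: ragged alignment; row {offender} ({ids[offender]!r}) has "
                f"length {len(rows[offender])}, query has {len(rows[0])}"
            )
        return Msa(query_id=ids[0], rows=rows)
    elif format == "aln":
        rows = [_sanitize(line.strip()) for line in text.splitlines() if line.strip()]
        return Msa(query_id=path.stem, rows=rows)
    raise ValueError(f"unknown alignment format: {format!r}")


def _parse_fasta_like(text: str, path: Path) -> tuple[list[str], list[str]]:
    ids: list[str] = []
    seqs: list[str] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if ids:
                seqs.append("".join(current))
            ids.append(line[1:].split()[0] if line[1:].split() else "")
            current = []
        elif line.strip():
            if not ids:
                raise MsaFormatError(f"{path}: sequence data before first header")
            current.append(line.strip())
    if ids:
        seqs.append("".join(current))
    if not ids:
        raise MsaFormatError(f"{path}: no FASTA records found")
    return ids, seqs


def _strip_inserts(seq: str) -> str:
    # a3m convention: lowercase letters are insertions w.r.t. the query
    return "".join(c for c in seq if not c.islower())


def _sanitize(seq: str) -> str:
    seq = seq.upper().replace(".", GAP)
    return "".join(c if c in _AA_SET or c == GAP else "X" for c in seq)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns between two aligned sequences.

    Columns gapped in both sequences are excluded from the comparison;
    a gap aligned against a residue counts as a mismatch.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length: {len(a)} vs {len(b)}")
    matches = 0
    compared = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        compared += 1
        if x == y:
            matches += 1
    if compared == 0:
        return 0.0
    return matches / compared


def identity_matrix(msa: Msa) -> np.ndarray:
    """All-against-all pairwise identity, vectorised; shape (M, M).

    Uses the same column rule as :func:`pairwise_identity`.
    """
    codes = msa.encoded()
    M, W = codes.shape
    p = N_STATES
    onehot = np.zeros((M, W * p), dtype=np.float32)
    flat = np.arange(W) * p + codes
    for k in range(M):
        onehot[k, flat[k]] = 1.0
    same_state = onehot @ onehot.T  # columns with identical state (incl. gap-gap)
    gaps = (codes == p - 1).astype(np.float32)
    shared_gaps = gaps @ gaps.T
    matches = same_state - shared_gaps
    denom = W - shared_gaps
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(denom > 0, matches / denom, 0.0)
    return ident.astype(float)


def compute_meff(
    msa: Msa,
    identity_threshold: float = 0.8,
    method: Literal["cluster", "weights"] = "cluster",
    _identity: np.ndarray | None = None,
) -> MsaStats:
    """Effective number of sequences at an identity cutoff, and Nf.

    ``method="cluster"`` (default) greedily clusters rows in input order
    with single linkage at >= ``identity_threshold`` identity and reports
    the number of clusters. ``method="weights"`` instead sums inverse
    neighbourhood sizes (the weighting used when estimating coupled
    frequencies), provided as an alternative reading of the same
    redundancy notion.
    """
    ident = identity_matrix(msa) if _identity is None else _identity
    M = msa.M
    if method == "weights":
        neighbours = (ident >= identity_threshold).sum(axis=1)
        meff = float(np.sum(1.0 / neighbours))
        assignments = np.arange(M)
    elif method == "cluster":
        assignments = np.full(M, -1, dtype=int)
        n_clusters = 0
        members: list[list[int]] = []
        for k in range(M):
            placed = False
            for ci, rows in enumerate(members):
                if np.any(ident[k, rows] >= identity_threshold):
                    assignments[k] = ci
                    rows.append(k)
                    placed = True
                    break
            if not placed:
                assignments[k] = n_clusters
                members.append([k])
                n_clusters += 1
        meff = float(n_clusters)
    else:
        raise ValueError(f"unknown meff method {method!r}")
    nf = compute_nf(meff, msa.L)
    return MsaStats(
        meff=meff,
        nf=nf,
        identity_threshold=identity_threshold,
        cluster_assignments=assignments,
    )


def compute_nf(meff: float | MsaStats, L: int) -> float:
    """Normalised alignment depth: Meff / sqrt(L)."""
    if isinstance(meff, MsaStats):
        meff = meff.meff
    if L < 1:
        raise ValueError("query length must be >= 1")
    return float(meff) / float(np.sqrt(L))


def subsample_to_nf(
    msa: Msa,
    target_nf: float,
    seed: int,
    identity_threshold: float = 0.8,
) -> Msa:
    """Randomly drop non-query rows until Nf falls to ``target_nf`` or below.

    The query row is always retained. Rows are removed uniformly at
    random, one at a time, recomputing Nf after each removal; the result
    is deterministic for a fixed seed. If even the query-alone alignment
    exceeds the target, that single-row alignment is returned with a
    warning.
    """
    if target_nf <= 0:
        raise ValueError("target_nf must be positive")
    rng = np.random.default_rng(seed)
    ident = identity_matrix(msa)
    keep = list(range(msa.M))
    L = msa.L

    def current_nf(rows: list[int]) -> float:
        sub = Msa(query_id=msa.query_id, rows=[msa.rows[i] for i in rows])
        stats = compute_meff(
            sub, identity_threshold, _identity=ident[np.ix_(rows, rows)]
        )
        return compute_nf(stats.meff, L)

    nf = current_nf(keep)
    while nf > target_nf and len(keep) > 1:
        victim = int(rng.integers(1, len(keep)))  # never index 0 (query)
        keep.pop(victim)
        nf = current_nf(keep)
    if nf > target_nf:
        warnings.warn(
            f"target Nf {target_nf} unreachable: query-alone alignment has "
            f"Nf {nf:.3f}",
            stacklevel=2,
        )
    return Msa(query_id=msa.query_id, rows=[msa.rows[i] for i in keep])


def write_msa(msa: Msa, path: str | Path, format: Literal["fasta", "aln"] = "fasta") -> None:
    """Write an alignment as FASTA or one-row-per-line text."""
    path = Path(path)
    with path.open("w") as fh:
        if format == "fasta":
            for k, row in enumerate(msa.rows):
                name = msa.query_id if k == 0 else f"seq{k}"
                fh.write(f">{name}\n{row}\n")
        elif format == "aln":
            for row in msa.rows:
                fh.write(row + "\n")
        else:
            raise ValueError(f"unknown format {format!r}")
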