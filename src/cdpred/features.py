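"""Per-pair input feature vectors for the prediction networks.

Every candidate residue pair (i, j) is described by a 733-dimensional
vector combining three kinds of information, mirroring the composition
used across the MetaPSICOV lineage of predictors:

* local blocks — a sequence window around each of i and j carrying the
  weighted amino-acid profile, the query identity, predicted secondary
  structure and solvent accessibility per position, with an explicit
  boundary flag for window slots falling outside the chain;
* pair blocks — windowed direct-coupling scores (raw and APC-corrected),
  windowed mutual information, sequence separation and gap statistics;
* global blocks — chain length, alignment depth (Meff, Nf), mean
  secondary-structure composition and mean accessibility.

The exact block layout is data (a :class:`FeatureSchema`), serialisable
to YAML and identified by a content hash so that trained networks can
refuse mismatched inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .coevolution import CouplingMatrix, FrequencyTables, weighted_frequencies
from .geometry import SsTrack
from .msa import Msa, MsaStats, N_STATES

_SS_INDEX = {"H": 0, "E": 1, "C": 2}


@dataclass(frozen=True)
class FeatureSchema:
    """Block layout of the pair feature vector."""

    residue_window: int = 3      # half-width of the per-residue window
    pair_window: int = 2         # half-width of the windowed pair matrices
    per_position_width: int = 46  # profile 21 + query one-hot 20 + SS 3 + acc 1 + boundary 1
    pair_scalars: int = 5        # sep/L, log2 sep, joint gap, gap_i, gap_j
    global_width: int = 9

    @property
    def n_window_positions(self) -> int:
        return 2 * self.residue_window + 1

    @property
    def residue_block_width(self) -> int:
        return self.n_window_positions * self.per_position_width

    @property
    def pair_matrix_width(self) -> int:
        return (2 * self.pair_window + 1) ** 2

    @property
    def pair_block_width(self) -> int:
        return 3 * self.pair_matrix_width + self.pair_scalars

    @property
    def total_dim(self) -> int:
        return 2 * self.residue_block_width + self.pair_block_width + self.global_width

    @property
    def blocks(self) -> list[tuple[str, int]]:
        """Ordered (name, width) layout of the vector."""
        w = self.pair_matrix_width
        return [
            ("residue_i_window", self.residue_block_width),
            ("residue_j_window", self.residue_block_width),
            ("coupling_apc_window", w),
            ("coupling_raw_window", w),
            ("mutual_information_window", w),
            ("pair_scalars", self.pair_scalars),
            ("global", self.global_width),
        ]

    def to_dict(self) -> dict:
        return {
            "residue_window": self.residue_window,
            "pair_window": self.pair_window,
            "per_position_width": self.per_position_width,
            "pair_scalars": self.pair_scalars,
            "global_width": self.global_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(**d)

    @property
    def schema_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_schema() -> FeatureSchema:
    """The default 733-feature layout."""
    schema = FeatureSchema()
    assert schema.total_dim == 733
    return schema


@dataclass
class PairFeatures:
    i: int
    j: int
    vector: np.ndarray
    schema_id: str


@dataclass
class ProteinFeatureContext:
    """Per-protein quantities from which any pair's vector is assembled."""

    L: int
    stats: MsaStats
    couplings: CouplingMatrix
    profile: np.ndarray        # (L, 21) weighted AA frequencies
    query_onehot: np.ndarray   # (L, 20)
    mi: np.ndarray             # (L, L) mutual information, bits
    gap_fraction: np.ndarray   # (L,) per-column gap fraction
    ss: SsTrack
    acc: np.ndarray            # (L,) accessibility in [0, 1]

    @classmethod
    def build(
        cls,
        msa: Msa,
        stats: MsaStats,
        couplings: CouplingMatrix,
        ss: SsTrack,
        acc: np.ndarray,
        freqs: FrequencyTables | None = None,
        pseudocount: float = 1.0,
    ) -> "ProteinFeatureContext":
        qmsa = msa.to_query_columns()
        L = qmsa.L
        if freqs is None:
            freqs = weighted_frequencies(qmsa, pseudocount=pseudocount)
        profile = freqs.f1.copy()
        codes = qmsa.encoded()[0]
        query_onehot = np.zeros((L, 20))
        for k, c in enumerate(codes):
            if c < 20:
                query_onehot[k, c] = 1.0
        mi = mi_matrix(freqs)
        gap_fraction = profile[:, N_STATES - 1].copy()
        acc = np.asarray(acc, dtype=float)
        if not (len(ss.labels) == L == acc.size == couplings.L):
            raise ValueError("track/coupling lengths do not match the query length")
        return cls(
            L=L, stats=stats, couplings=couplings, profile=profile,
            query_onehot=query_onehot, mi=mi, gap_fraction=gap_fraction,
            ss=ss, acc=acc,
        )


def mi_matrix(freqs: FrequencyTables) -> np.ndarray:
    """Mutual information (bits) between all column pairs."""
    q = freqs.n_states
    L = freqs.n_columns
    mi = np.zeros((L, L))
    f1 = freqs.f1
    for i in range(L):
        bi = slice(i * q, (i + 1) * q)
        for j in range(i + 1, L):
            bj = slice(j * q, (j + 1) * q)
            fij = freqs.f2[bi, bj]
            outer = np.outer(f1[i], f1[j])
            mask = fij > 0
            val = float(np.sum(fij[mask] * np.log2(fij[mask] / outer[mask])))
            mi[i, j] = mi[j, i] = max(val, 0.0)
    return mi


def mutual_information(
    msa: Msa, i: int, j: int, pseudocount: float = 0.0
) -> float:
    """Mutual information between query columns i and j (1-based), in bits."""
    qmsa = msa.to_query_columns()
    freqs = weighted_frequencies(qmsa, pseudocount=pseudocount)
    q = freqs.n_states
    fij = freqs.f2[(i - 1) * q : i * q, (j - 1) * q : j * q]
    outer = np.outer(freqs.f1[i - 1], freqs.f1[j - 1])
    mask = fij > 0
    return max(float(np.sum(fij[mask] * np.log2(fij[mask] / outer[mask]))), 0.0)


def _residue_window_block(
    ctx: ProteinFeatureContext, center: int, schema: FeatureSchema
) -> np.ndarray:
    """Windowed per-position features around 1-based position ``center``."""
    w = schema.residue_window
    width = schema.per_position_width
    out = np.zeros((schema.n_window_positions, width))
    for slot, pos in enumerate(range(center - w, center + w + 1)):
        if pos < 1 or pos > ctx.L:
            out[slot, -1] = 1.0  # boundary flag; all else zero
            continue
        k = pos - 1
        out[slot, 0:21] = ctx.profile[k]
        out[slot, 21:41] = ctx.query_onehot[k]
        out[slot, 41 + _SS_INDEX[ctx.ss.labels[k]]] = 1.0
        out[slot, 44] = ctx.acc[k]
    return out.ravel()


def _pair_window_block(
    mat: np.ndarray, i: int, j: int, w: int, L: int
) -> np.ndarray:
    """(2w+1)^2 values of ``mat`` around 1-based (i, j); out-of-range -> 0."""
    out = np.zeros((2 * w + 1, 2 * w + 1))
    for a, pi in enumerate(range(i - w, i + w + 1)):
        if pi < 1 or pi > L:
            continue
        for b, pj in enumerate(range(j - w, j + w + 1)):
            if pj < 1 or pj > L or pi == pj:
                continue
            out[a, b] = mat[pi - 1, pj - 1]
    return out.ravel()


def build_pair_features(
    ctx: ProteinFeatureContext,
    i: int,
    j: int,
    schema: FeatureSchema | None = None,
) -> PairFeatures:
    """Assemble the feature vector of the 1-based pair (i, j), i < j."""
    if schema is None:
        schema = default_schema()
    if not (1 <= i < j <= ctx.L):
        raise ValueError(f"need 1 <= i < j <= L; got i={i}, j={j}, L={ctx.L}")
    pw = schema.pair_window
    sep = j - i
    raw = ctx.couplings.raw_scores
    apc = ctx.couplings.scores
    parts = [
        _residue_window_block(ctx, i, schema),
        _residue_window_block(ctx, j, schema),
        _pair_window_block(apc, i, j, pw, ctx.L),
        _pair_window_block(raw, i, j, pw, ctx.L),
        _pair_window_block(ctx.mi, i, j, pw, ctx.L),
        np.array([
            sep / ctx.L,
            np.log2(sep),
            0.5 * (ctx.gap_fraction[i - 1] + ctx.gap_fraction[j - 1]),
            ctx.gap_fraction[i - 1],
            ctx.gap_fraction[j - 1],
        ]),
        _global_block(ctx),
    ]
    vec = np.concatenate(parts)
    if vec.size != schema.total_dim:
        raise AssertionError("schema/block width mismatch")
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"non-finite feature values for pair ({i}, {j})")
    return PairFeatures(i=i, j=j, vector=vec, schema_id=schema.schema_hash)


def _global_block(ctx: ProteinFeatureContext) -> np.ndarray:
    labels = ctx.ss.labels
    L = ctx.L
    return np.array([
        L / 1000.0,
        np.log10(L),
        np.log10(1.0 + ctx.stats.meff),
        ctx.stats.nf / 100.0,
        np.log10(1.0 + ctx.stats.nf),
        labels.count("H") / L,
        labels.count("E") / L,
        labels.count("C") / L,
        float(np.mean(ctx.acc)),
    ])


def feature_matrix(
    ctx: ProteinFeatureContext,
    pairs: list[tuple[int, int]],
    schema: FeatureSchema | None = None,
) -> np.ndarray:
    """Stack feature vectors for many pairs; shape (n_pairs, total_dim)."""
    if schema is None:
        schema = default_schema()
    out = np.empty((len(pairs), schema.total_dim))
    for k, (i, j) in enumerate(pairs):
        out[k] = build_pair_features(ctx, i, j, schema).vector
    return out
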