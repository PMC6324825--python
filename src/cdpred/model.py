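"""High-level modelling interface: build, fit, predict, summarise.

:class:`ContactDistanceModel` is constructed from training proteins
(alignment + structure + predicted SS/accessibility tracks), assembles
the per-bin training sets under the bin eligibility filters, and
``fit()`` trains the seven networks — the four-member contact ensemble
plus one network per distance bin — returning a
:class:`ContactDistanceResults` carrying the trained networks, their
training logs and a ``summary()`` table. Prediction on a new protein
goes through the same feature pipeline and returns one scored row per
eligible pair per bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coevolution import CouplingMatrix, msa_couplings
from .constraints import PairPrediction
from .features import (
    FeatureSchema,
    ProteinFeatureContext,
    default_schema,
    feature_matrix,
)
from .geometry import (
    BinSpec,
    CONTACT_ENSEMBLE_CUTOFFS,
    DEFAULT_BINS,
    SsTrack,
    StructureModel,
    cb_distance_map,
    eligible_pairs,
)
from .msa import Msa, compute_meff
from .networks import (
    ContactEnsemble,
    NetworkModel,
    TrainConfig,
    TrainingLog,
    balance_classes,
    init_network,
    predict_bin,
    predict_contact,
    train_network,
)


@dataclass
class TrainingProtein:
    """One training example: alignment, structure and predicted tracks."""

    msa: Msa
    structure: StructureModel
    ss: SsTrack
    acc: np.ndarray
    couplings: CouplingMatrix | None = None

    @classmethod
    def from_toy(cls, toy, msa: Msa) -> "TrainingProtein":
        return cls(msa=msa, structure=toy.structure, ss=toy.ss, acc=toy.acc)


def build_context(
    protein: TrainingProtein,
    rho: float = 0.02,
    pseudocount: float = 1.0,
) -> ProteinFeatureContext:
    """Alignment statistics, couplings and tracks for one protein."""
    qmsa = protein.msa.to_query_columns()
    stats = compute_meff(qmsa)
    couplings = protein.couplings
    if couplings is None:
        couplings = msa_couplings(qmsa, rho=rho, pseudocount=pseudocount)
    return ProteinFeatureContext.build(
        qmsa, stats, couplings, protein.ss, protein.acc,
        pseudocount=pseudocount,
    )


class ContactDistanceModel:
    """Contact/distance-bin predictor over a set of training proteins.

    Parameters
    ----------
    proteins:
        Training examples with alignments, structures and tracks.
    bins:
        Distance-bin definitions (interval, separation filter, same-SS
        exclusion, selection rule). Defaults to contact + 8-13, 13-18,
        18-23 Å.
    schema:
        Feature layout; defaults to the 733-dimensional layout.
    negative_ratio:
        Per-network cap on negatives per positive in the training set.
    """

    def __init__(
        self,
        proteins: list[TrainingProtein],
        bins: tuple[BinSpec, ...] = DEFAULT_BINS,
        schema: FeatureSchema | None = None,
        negative_ratio: float = 5.0,
        rho: float = 0.02,
    ) -> None:
        if not proteins:
            raise ValueError("need at least one training protein")
        self.proteins = proteins
        self.bins = bins
        self.schema = schema or default_schema()
        self.negative_ratio = negative_ratio
        self.rho = rho
        self._datasets: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # ------------------------------------------------------------------
    def _assemble(self, seed: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-network (features, labels) stacked over training proteins."""
        tasks: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        contact_bin = next(b for b in self.bins if b.name == "contact")
        for protein in self.proteins:
            ctx = build_context(protein, rho=self.rho)
            dmap = cb_distance_map(protein.structure)
            for bin_spec in self.bins:
                pairs = eligible_pairs(ctx.L, bin_spec, protein.ss)
                if not pairs:
                    continue
                X = feature_matrix(ctx, pairs, self.schema)
                d = np.array([dmap[i - 1, j - 1] for i, j in pairs])
                if bin_spec.name == "contact":
                    for cutoff in CONTACT_ENSEMBLE_CUTOFFS:
                        y = (d <= cutoff).astype(float)
                        tasks.setdefault(f"contact<={cutoff}", []).append((X, y))
                else:
                    y = ((d > bin_spec.low) & (d <= bin_spec.high)).astype(float)
                    tasks.setdefault(bin_spec.name, []).append((X, y))
        datasets = {}
        for name, parts in tasks.items():
            X = np.vstack([x for x, _ in parts])
            y = np.concatenate([y for _, y in parts])
            idx = balance_classes(y, self.negative_ratio, seed)
            datasets[name] = (X[idx], y[idx])
        return datasets

    def fit(self, config: TrainConfig | None = None) -> "ContactDistanceResults":
        """Train the four contact networks and one network per distance bin."""
        cfg = config or TrainConfig()
        datasets = self._assemble(cfg.seed)
        members: list[NetworkModel] = []
        logs: dict[str, TrainingLog] = {}
        for k, cutoff in enumerate(CONTACT_ENSEMBLE_CUTOFFS):
            key = f"contact<={cutoff}"
            X, y = datasets[key]
            net = init_network(
                self.schema.total_dim, seed=cfg.seed + k,
                trained_interval=(0.0, cutoff), schema_id=self.schema.schema_hash,
            )
            trained, log = train_network(net, X, y, cfg)
            members.append(trained)
            logs[key] = log
        ensemble = ContactEnsemble(members=members)
        bin_networks: dict[str, NetworkModel] = {}
        skipped: list[str] = []
        for bk, b in enumerate(self.bins):
            if b.name == "contact":
                continue
            X, y = datasets.get(b.name, (np.empty((0, 1)), np.empty(0)))
            if np.unique(y).size < 2:
                warnings.warn(
                    f"bin {b.name}: training data has a single class; "
                    "network skipped", stacklevel=2,
                )
                skipped.append(b.name)
                continue
            net = init_network(
                self.schema.total_dim, seed=cfg.seed + 10 + bk,
                trained_interval=(b.low, b.high), schema_id=self.schema.schema_hash,
            )
            trained, log = train_network(net, X, y, cfg)
            bin_networks[b.name] = trained
            logs[b.name] = log
        return ContactDistanceResults(
            model=self, contact_ensemble=ensemble, bin_networks=bin_networks,
            logs=logs, config=cfg,
            dataset_sizes={k: (v[0].shape[0], int(v[1].sum())) for k, v in datasets.items()},
            skipped_bins=skipped,
        )


@dataclass
class ContactDistanceResults:
    """Trained networks with training diagnostics and prediction methods."""

    model: ContactDistanceModel
    contact_ensemble: ContactEnsemble
    bin_networks: dict[str, NetworkModel]
    logs: dict[str, TrainingLog]
    config: TrainConfig
    dataset_sizes: dict[str, tuple[int, int]] = field(default_factory=dict)
    skipped_bins: list[str] = field(default_factory=list)

    def predict_protein(
        self,
        protein: TrainingProtein,
        ctx: ProteinFeatureContext | None = None,
    ) -> pd.DataFrame:
        """Score every eligible pair of every bin; columns i, j, bin, score."""
        if ctx is None:
            ctx = build_context(protein, rho=self.model.rho)
        rows = []
        for b in self.model.bins:
            if b.name != "contact" and b.name not in self.bin_networks:
                continue
            pairs = eligible_pairs(ctx.L, b, protein.ss)
            if not pairs:
                continue
            X = feature_matrix(ctx, pairs, self.model.schema)
            if b.name == "contact":
                scores = predict_contact(
                    self.contact_ensemble, X, self.model.schema.schema_hash
                )
            else:
                scores = predict_bin(
                    self.bin_networks[b.name], X, self.model.schema.schema_hash
                )
            for (i, j), s in zip(pairs, scores):
                rows.append({"i": i, "j": j, "bin": b.name, "score": float(s)})
        return pd.DataFrame(rows, columns=["i", "j", "bin", "score"])

    def predictions(self, frame: pd.DataFrame) -> list[PairPrediction]:
        """Convert a prediction frame into PairPrediction records."""
        return [
            PairPrediction(int(r.i), int(r.j), str(r.bin), float(r.score))
            for r in frame.itertuples()
        ]

    # ---- persistence -------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.contact_ensemble.save(directory)
        for name, net in self.bin_networks.items():
            net.save(directory / f"bin_{name}.npz")

    def summary(self) -> str:
        """Human-readable training summary, one row per network."""
        lines = [
            "Contact/distance-bin network training summary",
            "=" * 72,
            f"{'network':<16}{'n_train':>9}{'n_pos':>8}{'best epoch':>12}"
            f"{'val loss':>11}{'early stop':>12}",
            "-" * 72,
        ]
        for name, log in self.logs.items():
            n, npos = self.dataset_sizes.get(name, (0, 0))
            lines.append(
                f"{name:<16}{n:>9}{npos:>8}{log.best_epoch:>12}"
                f"{log.best_val_loss:>11.4f}{str(log.stopped_early):>12}"
            )
        lines.append("-" * 72)
        lines.append(
            f"feature dimension: {self.model.schema.total_dim}   "
            f"networks: {4 + len(self.bin_networks)}   "
            f"parameters each: {self.contact_ensemble.members[0].n_parameters}"
        )
        return "\n".join(lines)
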