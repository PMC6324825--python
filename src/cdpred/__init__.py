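"""cdpred: residue contact and distance-bin prediction from alignments.

Couples a PSICOV-style sparse-inverse-covariance coevolution stage with
small feed-forward networks that classify residue pairs into a contact
class ((0, 8] Å between Cβ atoms, Cα for glycine) and three distance
bins ((8, 13], (13, 18], (18, 23] Å), then turns the scored pairs into
Rosetta AtomPair restraints for structure modelling.
"""

from .msa import Msa, MsaStats, compute_meff, compute_nf, read_msa, subsample_to_nf
from .coevolution import (
    CouplingMatrix,
    coupling_scores,
    glasso_precision,
    msa_couplings,
    sample_covariance,
    shrink_to_spd,
    weighted_frequencies,
)
from .geometry import (
    BinSpec,
    CONTACT_ENSEMBLE_CUTOFFS,
    DEFAULT_BINS,
    SsTrack,
    StructureModel,
    assign_bin,
    cb_distance_map,
    eligible_pairs,
    read_structure,
    ss_elements,
)
from .features import (
    FeatureSchema,
    ProteinFeatureContext,
    build_pair_features,
    default_schema,
    mutual_information,
)
from .networks import (
    ContactEnsemble,
    NetworkModel,
    TrainConfig,
    init_network,
    predict_bin,
    predict_contact,
    train_network,
)
from .constraints import (
    ConstraintRecord,
    ModelPoolEntry,
    PairPrediction,
    build_constraints,
    read_constraint_file,
    select_contacts,
    select_distance_pairs,
    select_lowest_energy,
    write_constraint_file,
)
from .evaluation import (
    AccuracyReport,
    PropensityTable,
    StructureEvaluation,
    accuracy,
    positive_predictive_value,
    propensity,
    topk_curve,
)
from .model import ContactDistanceModel, ContactDistanceResults, TrainingProtein
from .synthetic import ToyProtein, make_toy_protein, make_toy_structure, make_tracks, sample_coupled_msa

__version__ = "0.1.0"
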