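"""oodeval: out-of-distribution detection scores for image classifiers.

Implements three extrusive OOD confidence scores — maximum softmax
probability, class-conditional Mahalanobis confidence, and the energy
score — together with the data-split protocol, ROC-based metrics (AUROC,
FPR95, Youden threshold) and synthetic benchmarks for studying how detector
performance depends on classifier accuracy, distributional shift, and
class imbalance in the detector-fitting set.
"""

__version__ = "0.1.0"

from .classifier_adapter import (
    Checkpoint,
    ClassifierAdapter,
    LinearAdapter,
    MLPAdapter,
    SplitSpec,
    TrainingResult,
    linear_adapter,
    load_adapter,
    save_adapter,
    split_dataset,
    train_reference_classifier,
)
from .evaluation import (
    FiveNumberSummary,
    ROCResult,
    accuracy_at_threshold,
    best_threshold,
    equalize_sizes,
    five_number_summary,
    fpr_at_tpr,
    roc_curve,
)
from .ood_scores import (
    ConfidenceSet,
    EnergyConfig,
    EnergyDetector,
    GaussianClassModel,
    MahalanobisDetector,
    MSPDetector,
    energy,
    energy_confidence,
    fit_gaussian_model,
    mahalanobis_confidence,
    msp_confidence,
    score_dataset,
)
from .records import FeatureTable
from .synthetic_data import (
    ClassSizeProfile,
    FeatureSpaceSpec,
    OODShiftSpec,
    ToyImageSpec,
    generate_id_features,
    generate_ood_features,
    generate_toy_images,
    generate_toy_ood_images,
    load_image_directory,
    make_class_size_profile,
)

__all__ = [
    "__version__",
    "Checkpoint",
    "ClassifierAdapter",
    "ClassSizeProfile",
    "ConfidenceSet",
    "EnergyConfig",
    "EnergyDetector",
    "FeatureSpaceSpec",
    "FeatureTable",
    "FiveNumberSummary",
    "GaussianClassModel",
    "LinearAdapter",
    "MahalanobisDetector",
    "MLPAdapter",
    "MSPDetector",
    "OODShiftSpec",
    "ROCResult",
    "SplitSpec",
    "ToyImageSpec",
    "TrainingResult",
    "accuracy_at_threshold",
    "best_threshold",
    "energy",
    "energy_confidence",
    "equalize_sizes",
    "fit_gaussian_model",
    "five_number_summary",
    "fpr_at_tpr",
    "generate_id_features",
    "generate_ood_features",
    "generate_toy_images",
    "generate_toy_ood_images",
    "linear_adapter",
    "load_adapter",
    "load_image_directory",
    "mahalanobis_confidence",
    "make_class_size_profile",
    "msp_confidence",
    "roc_curve",
    "save_adapter",
    "score_dataset",
    "split_dataset",
    "train_reference_classifier",
]
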