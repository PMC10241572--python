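"""slicefuse: 2.5D RGB slice superposition for CT lesion classification.

Fuses three consecutive axial CT slice crops into the R/G/B channels of one
image so a 2D classifier can exploit inter-slice structure, and provides the
full evaluation protocol around it: DICOM/ROI I/O, patient-grouped k-fold
cross-validation, pooled confusion-matrix metrics with Wilson CIs, ROC/AUC
with the paired DeLong test, Grad-CAM, and synthetic lesion phantoms whose
class signal lives only in the cross-slice evolution of the lesion.
"""

from .io import (
    BoxAnnotation,
    CTVolume,
    WindowSpec,
    raw_to_hu,
    read_annotation_table,
    read_dicom_series,
    read_imagej_roi,
    window_to_uint8,
    write_dicom_series,
)
from .superpose import (
    AugmentParams,
    SuperpositionImage,
    augment_image,
    balance_classes,
    extract_triplet,
    make_single_slice,
    make_superposition,
)
from .cohort import Manifest, ManifestRecord, assign_patient_folds, split_fold
from .nnet import ReferenceCNN
from .train import TrainConfig, early_stop_check, grad_cam, learning_rate_at, train_classifier
from .stats import (
    ConfusionMatrix,
    MetricReport,
    RocResult,
    auc_mann_whitney,
    confusion_from_scores,
    delong_paired_test,
    metrics_from_confusion,
    pool_confusions,
    reconstruct_confusion_from_printed,
    roc_result,
)
from .phantom import PhantomSpec, generate_cohort, generate_phantom_volume
from .experiment import FusionExperiment, FusionResults

__version__ = "0.1.0"

__all__ = [
    "BoxAnnotation",
    "CTVolume",
    "WindowSpec",
    "raw_to_hu",
    "read_annotation_table",
    "read_dicom_series",
    "read_imagej_roi",
    "window_to_uint8",
    "write_dicom_series",
    "AugmentParams",
    "SuperpositionImage",
    "augment_image",
    "balance_classes",
    "extract_triplet",
    "make_single_slice",
    "make_superposition",
    "Manifest",
    "ManifestRecord",
    "assign_patient_folds",
    "split_fold",
    "ReferenceCNN",
    "TrainConfig",
    "early_stop_check",
    "grad_cam",
    "learning_rate_at",
    "train_classifier",
    "ConfusionMatrix",
    "MetricReport",
    "RocResult",
    "auc_mann_whitney",
    "confusion_from_scores",
    "delong_paired_test",
    "metrics_from_confusion",
    "pool_confusions",
    "reconstruct_confusion_from_printed",
    "roc_result",
    "PhantomSpec",
    "generate_cohort",
    "generate_phantom_volume",
    "FusionExperiment",
    "FusionResults",
]
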