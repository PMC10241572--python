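"""The two-arm cross-validation experiment as a Model/Results pair.

:class:`FusionExperiment` is built from a cohort (volumes + box
annotations); :meth:`FusionExperiment.fit` runs the full protocol for both
input encodings —

* ``superposition``: prev/current/next slice crops fused as R/G/B, and
* ``original``: the current-slice crop replicated across the 3 channels —

over patient-grouped k-fold cross-validation with a fresh classifier per
arm and fold, pools the per-fold test confusion matrices, and returns a
:class:`FusionResults` carrying pooled accuracy/precision/recall with
Wilson CIs, ROC/AUC with DeLong variance per arm, and the paired DeLong
comparison of the two arms' AUCs on the identical pooled test cases.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Manifest, ManifestRecord, assign_patient_folds, split_fold
from .io import POSITIVE_LABEL, BoxAnnotation, CTVolume, WindowSpec, read_annotation_table, read_dicom_series
from .nnet import ReferenceCNN
from .stats import (
    ConfusionMatrix,
    DeLongComparison,
    MetricReport,
    RocResult,
    confusion_from_scores,
    delong_paired_test,
    metrics_from_confusion,
    pool_confusions,
    roc_result,
)
from .superpose import (
    AugmentParams,
    SuperpositionImage,
    augment_image,
    balance_classes,
    make_single_slice,
    make_superposition,
)
from .train import TrainConfig, train_classifier

__all__ = ["FusionExperiment", "FusionResults", "ArmResult", "ARMS"]

ARMS = ("original", "superposition")

#: Desk-scale schedule for the from-scratch reference CNN (the full-scale
#: transfer-learning schedule is the TrainConfig default). A from-scratch
#: batch-normalized net wants a higher base rate than a pretrained backbone.
DESK_TRAIN_CONFIG = TrainConfig(
    max_epochs=50,
    batch_size=64,
    base_lr=3e-3,
    reduced_lr=3e-4,
    lr_switch_epoch=40,
    early_stop_patience=12,
    seed=0,
    resolution=32,
)

#: Training-set augmentation for the desk-scale experiment. Full-circle
#: rotations are appropriate because axial in-plane orientation is arbitrary;
#: shifts and zoom mimic annotation-box jitter.
DESK_AUGMENT = AugmentParams(
    rotation_deg_range=(-180.0, 180.0),
    shift_frac_range=(-0.08, 0.08),
    zoom_range=(0.9, 1.1),
)


@dataclass(frozen=True)
class ArmResult:
    """Pooled evaluation of one input-encoding arm."""

    arm: str
    per_fold: list[ConfusionMatrix]
    confusion: ConfusionMatrix
    metrics: MetricReport
    roc: RocResult

    @property
    def accuracy(self) -> float:
        return float(self.metrics.accuracy.value)

    @property
    def auc(self) -> float:
        return self.roc.auc


class FusionResults:
    """Results of a fitted :class:`FusionExperiment`.

    ``arms`` maps arm name to :class:`ArmResult`; ``comparison`` is the
    paired DeLong test of superposition vs original AUC; ``config`` embeds
    the fully resolved configuration and seeds; ``histories`` the per-arm,
    per-fold training curves.
    """

    def __init__(
        self,
        arms: dict[str, ArmResult],
        comparison: DeLongComparison,
        config: dict,
        histories: dict[str, list[pd.DataFrame]],
    ):
        self.arms = arms
        self.comparison = comparison
        self.config = config
        self.histories = histories

    def summary(self) -> str:
        """Plain-text results table in the style of a published metrics table."""
        lines = [
            "Two-arm slice-fusion cross-validation",
            "=" * 78,
            f"{'Arm':<14}{'N':>6}{'Accuracy % (95% CI)':>24}"
            f"{'Precision %':>13}{'Recall %':>11}{'AUC (95% CI)':>20}",
            "-" * 78,
        ]
        def fmt(metric, width):
            return f"{metric.value:>{width}.2f}" if metric.defined else f"{'n/a':>{width}}"

        for name in ARMS:
            a = self.arms[name]
            m = a.metrics
            acc = f"{m.accuracy.value:.2f} ({m.accuracy.ci_low:.2f}-{m.accuracy.ci_high:.2f})"
            auc = f"{a.auc:.3f} ({a.roc.ci95[0]:.3f}-{a.roc.ci95[1]:.3f})"
            lines.append(
                f"{name:<14}{a.confusion.n:>6}{acc:>24}"
                f"{fmt(m.precision, 13)}{fmt(m.recall, 11)}{auc:>20}"
            )
        c = self.comparison
        lines += [
            "-" * 78,
            f"DeLong paired test (superposition - original): "
            f"dAUC={c.delta:+.4f}, z={c.z:.3f}, p={c.p_value:.4g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def cm_dict(cm: ConfusionMatrix) -> dict:
            return {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn}

        out: dict = {"config": self.config, "arms": {}, "comparison": {}}
        for name, a in self.arms.items():
            m = a.metrics
            out["arms"][name] = {
                "confusion": cm_dict(a.confusion),
                "per_fold": [cm_dict(cm) for cm in a.per_fold],
                "accuracy": m.accuracy.value,
                "accuracy_ci": [m.accuracy.ci_low, m.accuracy.ci_high],
                "precision": m.precision.value,
                "recall": m.recall.value,
                "auc": a.auc,
                "auc_ci": list(a.roc.ci95),
                "auc_delong_variance": a.roc.delong_variance,
            }
        c = self.comparison
        out["comparison"] = {
            "auc_superposition": c.auc_a,
            "auc_original": c.auc_b,
            "delta_auc": c.delta,
            "z": c.z,
            "p_value": c.p_value,
        }
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass
class FusionExperiment:
    """The two-arm experiment model, built from volumes and annotations.

    Parameters
    ----------
    volumes : patient_id -> CTVolume.
    annotations : one box per annotated slice; labels already canonical.
    window : HU display window applied before fusion.
    resolution : square classifier input side (32 for the reference CNN).
    k : number of patient-grouped folds.
    train_config : epoch schedule (defaults to the desk-scale schedule).
    channels : reference CNN widths.
    seed : master seed; folds, balancing and per-fold classifier seeds all
        derive from it.
    balance : oversample the training minority class to parity (fakes are
        created after splitting, from train-fold records only).
    augment_copies : stochastically augmented copies of every training
        record added before fitting (both arms identically); 0 disables.
    val_fraction : fraction of training *patients* held out (grouped) for
        the early-stopping validation loss.
    """

    volumes: dict[str, CTVolume]
    annotations: list[BoxAnnotation]
    window: WindowSpec = field(default_factory=WindowSpec)
    resolution: int = 32
    k: int = 2
    train_config: TrainConfig = field(default_factory=lambda: DESK_TRAIN_CONFIG)
    channels: tuple[int, int, int] = (12, 24, 48)
    seed: int = 0
    balance: bool = True
    augment: AugmentParams = field(default_factory=lambda: DESK_AUGMENT)
    augment_copies: int = 2
    val_fraction: float = 0.2

    @classmethod
    def from_phantom(
        cls, n_patients_per_class: int, spec=None, seed: int = 0, **kwargs
    ) -> "FusionExperiment":
        """Build the experiment on a freshly generated phantom cohort."""
        from .phantom import PhantomSpec, generate_cohort

        spec = PhantomSpec() if spec is None else spec
        volumes, annotations, _ = generate_cohort(n_patients_per_class, spec, seed=seed)
        return cls(volumes=volumes, annotations=annotations, seed=seed, **kwargs)

    @classmethod
    def from_cohort_dir(cls, path: str | Path, **kwargs) -> "FusionExperiment":
        """Load a cohort written to disk (DICOM series + annotations.csv)."""
        path = Path(path)
        annotations = read_annotation_table(path / "annotations.csv")
        volumes = {
            d.name: read_dicom_series(d) for d in sorted((path / "dicom").iterdir()) if d.is_dir()
        }
        return cls(volumes=volumes, annotations=annotations, **kwargs)

    # ------------------------------------------------------------------

    def _build_images(self) -> tuple[dict[str, list[SuperpositionImage]], Manifest]:
        """Render both arms' images for every annotation, plus the manifest."""
        images: dict[str, list[SuperpositionImage]] = {arm: [] for arm in ARMS}
        records = []
        for ann in self.annotations:
            volume = self.volumes[ann.patient_id]
            images["superposition"].append(
                make_superposition(volume, ann, self.window, self.resolution)
            )
            images["original"].append(
                make_single_slice(volume, ann, self.window, self.resolution)
            )
            records.append(
                ManifestRecord(
                    image_ref=f"{ann.patient_id}:{ann.slice_index}",
                    patient_id=ann.patient_id,
                    label=ann.label,
                )
            )
        return images, Manifest(records)

    def _val_split(
        self, train_idx: list[int], manifest: Manifest, fold: int
    ) -> tuple[list[int], list[int]]:
        """Patient-grouped split of the training records for early stopping."""
        patients = sorted({manifest.records[i].patient_id for i in train_idx})
        rng = np.random.default_rng((self.seed, fold, 17))
        rng.shuffle(patients)
        n_val = max(1, int(round(self.val_fraction * len(patients))))
        val_patients = set(patients[:n_val])
        tr = [i for i in train_idx if manifest.records[i].patient_id not in val_patients]
        va = [i for i in train_idx if manifest.records[i].patient_id in val_patients]
        return tr, va

    def fit(self) -> FusionResults:
        """Run both arms over all folds and assemble the pooled results."""
        images, manifest = self._build_images()
        manifest = assign_patient_folds(manifest, self.k, seed=self.seed)
        index_of = {id(r): i for i, r in enumerate(manifest.records)}

        labels_by_fold: dict[int, np.ndarray] = {}
        scores: dict[str, dict[int, np.ndarray]] = {arm: {} for arm in ARMS}
        per_fold_cm: dict[str, list[ConfusionMatrix]] = {arm: [] for arm in ARMS}
        histories: dict[str, list[pd.DataFrame]] = {arm: [] for arm in ARMS}

        for fold in range(self.k):
            train_records, test_records = split_fold(manifest, fold)
            train_idx = [index_of[id(r)] for r in train_records]
            test_idx = [index_of[id(r)] for r in test_records]
            tr_idx, va_idx = self._val_split(train_idx, manifest, fold)
            y_test = np.array(
                [1 if manifest.records[i].label == POSITIVE_LABEL else 0 for i in test_idx]
            )
            labels_by_fold[fold] = y_test

            for arm_i, arm in enumerate(ARMS):
                train_imgs = [images[arm][i] for i in tr_idx]
                val_imgs = [images[arm][i] for i in va_idx]
                if self.balance:
                    counts = {}
                    for im in train_imgs:
                        counts[im.label] = counts.get(im.label, 0) + 1
                    if len(counts) == 2 and len(set(counts.values())) == 2:
                        train_imgs = balance_classes(
                            train_imgs,
                            self.augment,
                            seed=self.seed * 1000 + fold * 10 + arm_i,
                        )
                if self.augment_copies > 0:
                    rng = np.random.default_rng((self.seed, fold, arm_i, 23))
                    extra = []
                    for _ in range(self.augment_copies):
                        for im in train_imgs:
                            extra.append(
                                replace(
                                    im,
                                    pixels=augment_image(im.pixels, draw=self.augment.draw(rng)),
                                    fake=True,
                                )
                            )
                    train_imgs = train_imgs + extra
                clf = ReferenceCNN(
                    resolution=self.resolution,
                    channels=self.channels,
                    seed=self.seed * 1000 + fold * 10 + arm_i,
                )
                cfg = TrainConfig(
                    **{
                        **asdict(self.train_config),
                        "seed": self.seed * 1000 + fold * 10 + arm_i,
                        "resolution": self.resolution,
                    }
                )
                clf, history = train_classifier(clf, train_imgs, val_imgs, cfg)
                histories[arm].append(history)
                test_pixels = np.stack([images[arm][i].pixels for i in test_idx])
                s = clf.predict_scores(test_pixels)
                scores[arm][fold] = s
                per_fold_cm[arm].append(confusion_from_scores(y_test, s))

        pooled_labels = np.concatenate([labels_by_fold[f] for f in range(self.k)])
        arms: dict[str, ArmResult] = {}
        pooled_scores: dict[str, np.ndarray] = {}
        for arm in ARMS:
            pooled_scores[arm] = np.concatenate([scores[arm][f] for f in range(self.k)])
            confusion = pool_confusions(per_fold_cm[arm])
            arms[arm] = ArmResult(
                arm=arm,
                per_fold=per_fold_cm[arm],
                confusion=confusion,
                metrics=metrics_from_confusion(confusion),
                roc=roc_result(pooled_labels, pooled_scores[arm]),
            )
        comparison = delong_paired_test(
            pooled_labels, pooled_scores["superposition"], pooled_scores["original"]
        )
        config = {
            "k": self.k,
            "seed": self.seed,
            "resolution": self.resolution,
            "window": {"level": self.window.level, "width": self.window.width},
            "channels": list(self.channels),
            "balance": self.balance,
            "val_fraction": self.val_fraction,
            "augment_copies": self.augment_copies,
            "train_config": asdict(self.train_config),
            "n_patients": len(self.volumes),
            "n_images": len(self.annotations),
        }
        return FusionResults(arms, comparison, config, histories)
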