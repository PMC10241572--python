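"""Dataset manifest and patient-grouped k-fold assignment.

Folds are assigned at the patient level so no patient's images can appear in
both the train and test side of any fold — the grouping that prevents a
classifier from recognizing a patient instead of a disease. Within each
class, patients are distributed greedily (largest image count first) to keep
per-fold image counts close to equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ManifestRecord", "Manifest", "assign_patient_folds", "split_fold"]


@dataclass(frozen=True)
class ManifestRecord:
    """One image entry: a reference, its patient, label, fold, and fake flag."""

    image_ref: str
    patient_id: str
    label: str
    fold: int | None = None
    fake: bool = False


@dataclass
class Manifest:
    """An ordered collection of image records with optional fold assignment."""

    records: list[ManifestRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_ref": r.image_ref,
                    "patient_id": r.patient_id,
                    "label": r.label,
                    "fold": -1 if r.fold is None else r.fold,
                    "fake": r.fake,
                }
                for r in self.records
            ],
            columns=["image_ref", "patient_id", "label", "fold", "fake"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Manifest":
        df = pd.read_csv(path)
        records = [
            ManifestRecord(
                image_ref=str(row.image_ref),
                patient_id=str(row.patient_id),
                label=str(row.label),
                fold=None if int(row.fold) < 0 else int(row.fold),
                fake=bool(row.fake),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records)


def _patient_class(records: list[ManifestRecord], patient: str) -> str:
    """A patient's class for stratification: the majority label of its records."""
    labels = [r.label for r in records if r.patient_id == patient]
    uniq, counts = np.unique(labels, return_counts=True)
    return str(uniq[np.argmax(counts)])


def assign_patient_folds(manifest: Manifest, k: int, seed: int = 0) -> Manifest:
    """Assign every record a fold by partitioning *patients* into ``k`` groups.

    Within each class, patients sorted by descending image count (ties
    shuffled by ``seed``) are assigned greedily to the fold currently holding
    the fewest of that class's images (ties broken by lowest fold index).
    Every image inherits its patient's fold. Requires at least ``k`` patients
    per class.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts: dict[str, int] = {}
    for r in manifest.records:
        counts[r.patient_id] = counts.get(r.patient_id, 0) + 1
    by_class: dict[str, list[str]] = {}
    for p in counts:
        by_class.setdefault(_patient_class(manifest.records, p), []).append(p)
    for label, patients in by_class.items():
        if len(patients) < k:
            raise ValueError(
                f"class {label!r} has {len(patients)} patients; need >= {k} for {k}-fold"
            )

    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for label in sorted(by_class):
        patients = sorted(by_class[label])
        rng.shuffle(patients)  # randomizes count ties via the stable sort below
        patients.sort(key=lambda p: -counts[p])
        weights = [0] * k
        for p in patients:
            fold = int(np.argmin(weights))  # argmin takes the lowest index on ties
            assignment[p] = fold
            weights[fold] += counts[p]

    return Manifest([replace(r, fold=assignment[r.patient_id]) for r in manifest.records])


def split_fold(
    manifest: Manifest, fold_index: int
) -> tuple[list[ManifestRecord], list[ManifestRecord]]:
    """Split into (train, test) for one fold.

    Test = the real (non-fake) records of ``fold_index``; train = everything
    else. Train and test never share a patient.
    """
    folds = {r.fold for r in manifest.records}
    if None in folds:
        raise ValueError("folds not assigned; call assign_patient_folds first")
    if fold_index not in folds:
        raise ValueError(f"unknown fold index {fold_index}; have {sorted(folds)}")
    test = [r for r in manifest.records if r.fold == fold_index and not r.fake]
    train = [r for r in manifest.records if r.fold != fold_index]
    return train, test
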