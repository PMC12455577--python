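"""Study artifact IO and the shared in-memory data model.

On-disk layout written by :func:`write_study` (one directory per study):

    design.csv                      subject_id,group
    labels.nii.gz                   integer ROI label map
    labels_legend.json              label -> region name
    mask.nii.gz                     brain mask
    truth_amplitudes.csv            ground-truth pool amplitudes (if synthetic)
    b0_truth.nii.gz                 ground-truth field (if synthetic)
    sub-XX_cest.nii.gz              (x, y, offset) saturation stack
    sub-XX_wassr.nii.gz             WASSR stack
    sub-XX_ref.nii.gz               unsaturated reference S0
    cest_schedule.json              offsets sidecar (offsets_ppm, b1_uT, t_sat_s)
    wassr_schedule.json             WASSR sidecar

Offsets are stored in ppm, positive downfield of water at 0 ppm; voxel
grids are index-addressed (0-based, row-major).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .spectra import SaturationSchedule
from .synthetic import StudyBundle

logger = logging.getLogger(__name__)

REQUIRED_REGIONS = ("cortex", "hippocampus", "piriform_cortex", "thalamus")
KNOWN_GROUPS = ("vehicle", "ART", "nicotine", "cotreat")

__all__ = [
    "ZSpectrumStack",
    "RoiLabelMap",
    "StudyDesign",
    "StudyLoadError",
    "read_cest_study",
    "read_study",
    "normalize_stack",
    "write_study",
]


class StudyLoadError(RuntimeError):
    """Raised when study artifacts fail validation on load."""


@dataclass
class ZSpectrumStack:
    """Per-voxel saturation signal over offsets.

    ``signal`` has shape ``(h, w, n_offsets)``; it is normalized
    (dimensionless Z) after :func:`normalize_stack`, raw before.
    Masked-out voxels are ignored by every downstream stage.
    """

    signal: np.ndarray
    offsets_ppm: np.ndarray
    mask: np.ndarray
    reference: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.signal.ndim != 3:
            raise StudyLoadError("signal must be 3-D (x, y, offset)")
        if self.signal.shape[-1] != self.offsets_ppm.size:
            raise StudyLoadError(
                f"stack has {self.signal.shape[-1]} volumes but sidecar lists "
                f"{self.offsets_ppm.size} offsets"
            )
        if self.mask.shape != self.signal.shape[:2]:
            raise StudyLoadError(
                f"mask shape {self.mask.shape} does not match grid {self.signal.shape[:2]}"
            )
        diffs = np.diff(self.offsets_ppm)
        if np.any(diffs == 0):
            raise StudyLoadError("duplicate offsets in sidecar")
        if np.any(diffs < 0):
            if np.all(diffs < 0):  # fully descending: reverse consistently
                self.offsets_ppm = self.offsets_ppm[::-1].copy()
                self.signal = self.signal[..., ::-1].copy()
            else:
                raise StudyLoadError("offsets must be monotonic")
        if not np.all(np.isfinite(self.signal[self.mask])):
            raise StudyLoadError("non-finite signal inside mask")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.signal.shape[:2]


@dataclass
class RoiLabelMap:
    """Integer label image plus a legend of region names.  The whole
    brain is always derived as the union of labeled voxels, never stored
    as its own label."""

    labels: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if "whole_brain" in self.legend.values():
            raise StudyLoadError("whole_brain must be derived, not stored as a label")
        missing = set(REQUIRED_REGIONS) - set(self.legend.values())
        if missing:
            raise StudyLoadError(f"label legend missing regions: {sorted(missing)}")

    def region_mask(self, region: str) -> np.ndarray:
        if region == "whole_brain":
            return self.labels > 0
        for value, name in self.legend.items():
            if name == region:
                return self.labels == value
        raise KeyError(f"unknown region {region!r}")

    @property
    def region_names(self) -> list[str]:
        return sorted(self.legend.values()) + ["whole_brain"]


@dataclass
class StudyDesign:
    """Subject-to-group assignment."""

    table: pd.DataFrame  # columns subject_id, group

    def __post_init__(self) -> None:
        required = {"subject_id", "group"}
        if not required <= set(self.table.columns):
            raise StudyLoadError(f"design table needs columns {sorted(required)}")
        if self.table["subject_id"].duplicated().any():
            raise StudyLoadError("duplicate subject_ids in design table")
        counts = self.table["group"].value_counts()
        if (counts < 1).any():
            raise StudyLoadError("every group must be non-empty")

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def subjects_in(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "subject_id"].tolist()


def _save_nii(path: Path, array: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float64), np.eye(4)), str(path))


def _save_nii_int(path: Path, array: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.int16), np.eye(4)), str(path))


def _load_nii(path: Path) -> np.ndarray:
    if not path.exists():
        raise StudyLoadError(f"missing file: {path}")
    return np.asarray(nib.load(str(path)).dataobj)


def write_study(bundle: StudyBundle, out_dir: str | Path) -> list[Path]:
    """Write a synthetic study bundle to ``out_dir``; returns the file list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def record(path: Path) -> Path:
        written.append(path)
        return path

    _save_nii_int(record(out / "labels.nii.gz"), bundle.labels)
    _save_nii_int(record(out / "mask.nii.gz"), bundle.mask.astype(np.int16))
    _save_nii(record(out / "b0_truth.nii.gz"), bundle.b0_truth)
    (record(out / "labels_legend.json")).write_text(
        json.dumps({str(k): v for k, v in bundle.legend.items()}, indent=1)
    )
    (record(out / "cest_schedule.json")).write_text(
        json.dumps(bundle.config.schedule.to_dict())
    )
    (record(out / "wassr_schedule.json")).write_text(
        json.dumps(bundle.config.wassr_schedule.to_dict())
    )
    pd.DataFrame(bundle.design, columns=["subject_id", "group"]).to_csv(
        record(out / "design.csv"), index=False
    )
    truth_rows = []
    for s in bundle.subjects:
        _save_nii(record(out / f"{s.subject_id}_cest.nii.gz"), s.cest)
        _save_nii(record(out / f"{s.subject_id}_wassr.nii.gz"), s.wassr)
        _save_nii(record(out / f"{s.subject_id}_ref.nii.gz"), s.reference)
        for pool_name, amp_map in s.truth_amplitude.items():
            inside = amp_map[bundle.mask]
            truth_rows.append(
                {"subject_id": s.subject_id, "group": s.group, "pool": pool_name,
                 "mean_amplitude": float(inside.mean()) if inside.size else np.nan}
            )
    pd.DataFrame(truth_rows).to_csv(record(out / "truth_amplitudes.csv"), index=False)
    return written


def read_cest_study(
    stack_path: str | Path,
    sidecar_path: str | Path,
    mask_path: str | Path,
    reference_path: str | Path | None = None,
) -> tuple[ZSpectrumStack, SaturationSchedule]:
    """Load one subject's saturation stack with its offsets sidecar.

    Validates grid-shape agreement and sidecar/volume counts; offsets
    are returned ascending with the signal reordered to match."""
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise StudyLoadError(f"missing offsets sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    raw_offsets = np.asarray(sidecar["offsets_ppm"], dtype=float)
    signal = _load_nii(Path(stack_path)).astype(float)
    mask = _load_nii(Path(mask_path)).astype(bool)
    reference = None
    if reference_path is not None:
        reference = _load_nii(Path(reference_path)).astype(float)
        if reference.shape != signal.shape[:2]:
            raise StudyLoadError(
                f"reference shape {reference.shape} does not match grid {signal.shape[:2]}"
            )
    stack = ZSpectrumStack(
        signal=signal, offsets_ppm=raw_offsets, mask=mask, reference=reference
    )
    schedule = SaturationSchedule(
        offsets_ppm=stack.offsets_ppm,
        b1_uT=float(sidecar["b1_uT"]),
        t_sat_s=float(sidecar["t_sat_s"]),
    )
    return stack, schedule


def read_study(root: str | Path):
    """Load a full study directory: per-subject stacks, design, labels.

    Returns ``(subjects, design, label_map, cest_schedule, wassr_schedule)``
    where ``subjects`` maps subject_id to a dict with ``cest`` and
    ``wassr`` ZSpectrumStacks."""
    root = Path(root)
    design = StudyDesign(pd.read_csv(root / "design.csv"))
    legend = {int(k): v for k, v in json.loads((root / "labels_legend.json").read_text()).items()}
    label_map = RoiLabelMap(_load_nii(root / "labels.nii.gz").astype(np.int16), legend)
    mask = _load_nii(root / "mask.nii.gz").astype(bool)
    subjects: dict[str, dict] = {}
    cest_schedule = wassr_schedule = None
    for sid in design.table["subject_id"]:
        cest_path = root / f"{sid}_cest.nii.gz"
        wassr_path = root / f"{sid}_wassr.nii.gz"
        if not wassr_path.exists():
            raise StudyLoadError(f"subject {sid}: missing WASSR stack at {wassr_path}")
        cest, cest_schedule = read_cest_study(
            cest_path, root / "cest_schedule.json", root / "mask.nii.gz",
            root / f"{sid}_ref.nii.gz",
        )
        wassr, wassr_schedule = read_cest_study(
            wassr_path, root / "wassr_schedule.json", root / "mask.nii.gz",
            root / f"{sid}_ref.nii.gz",
        )
        subjects[sid] = {"cest": cest, "wassr": wassr}
    if label_map.labels.shape != mask.shape:
        raise StudyLoadError("label map and mask shapes disagree")
    return subjects, design, label_map, cest_schedule, wassr_schedule


def normalize_stack(stack: ZSpectrumStack, pre_normalized: bool = False) -> ZSpectrumStack:
    """Divide the signal by the per-voxel unsaturated reference S0.

    Voxels with non-positive S0 are removed from the mask (counted and
    logged).  If no reference is attached, the data must be declared
    pre-normalized explicitly."""
    if stack.normalized:
        return stack
    if stack.reference is None:
        if pre_normalized:
            return replace(stack, normalized=True)
        raise StudyLoadError(
            "no reference image attached; pass pre_normalized=True if the data "
            "is already normalized"
        )
    bad = stack.mask & ~(stack.reference > 0)
    n_bad = int(bad.sum())
    mask = stack.mask & (stack.reference > 0)
    if n_bad:
        logger.warning("normalize_stack: dropped %d voxels with S0 <= 0", n_bad)
    ref = np.where(stack.reference > 0, stack.reference, 1.0)
    signal = stack.signal / ref[..., None]
    return ZSpectrumStack(
        signal=signal, offsets_ppm=stack.offsets_ppm, mask=mask,
        reference=stack.reference, normalized=True,
    )
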