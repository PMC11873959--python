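"""Manifest I/O, subject-wise splitting, pair construction and curriculum.

Longitudinal data arrive as a CSV manifest (one row per acquisition) with
columns ``subject_id``, ``time``, ``path``, optionally ``target`` (a scalar
such as a clinical score), ``group`` (0/1 case-control label) and any number
of ``meta_*`` covariate columns.  Images are loaded lazily from ``path``
(TIFF/PNG for 2D, NIfTI for 3D) unless an in-memory array was attached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ImageRecord",
    "LongitudinalPair",
    "read_manifest",
    "split_subjects",
    "make_pairs",
    "curriculum_filter",
    "load_image",
    "minmax_normalize",
]


def load_image(path: str | Path) -> np.ndarray:
    """Read a single-channel image or volume from disk as float32."""
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float32)
    if suffix.endswith((".tif", ".tiff")):
        import tifffile

        return np.asarray(tifffile.imread(str(path)), dtype=np.float32)
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)), dtype=np.float32)
    if arr.ndim == 3:  # collapse an RGB(A) axis if present
        arr = arr.mean(axis=-1)
    return arr


def minmax_normalize(img: np.ndarray) -> np.ndarray:
    """Per-image min-max rescaling to [0, 1] (constant images map to 0)."""
    img = np.asarray(img, dtype=np.float32)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


@dataclass
class ImageRecord:
    """One timepoint of one subject."""

    subject_id: str
    time: float
    path: str | None = None
    image: np.ndarray | None = None
    target: float | None = None
    metadata: np.ndarray | None = None
    group: int | None = None

    def load(self) -> np.ndarray:
        if self.image is None:
            if self.path is None:
                raise ValueError(
                    f"record ({self.subject_id}, t={self.time}) has neither an "
                    "in-memory image nor a path")
            self.image = load_image(self.path)
        return self.image


@dataclass
class LongitudinalPair:
    """Two timepoints of the same subject, in presentation order.

    ``order_label`` is 1 iff the presented order is chronological, which by
    construction is equivalent to ``delta_time > 0``.
    """

    first: ImageRecord
    second: ImageRecord
    order_label: int = field(init=False)
    delta_time: float = field(init=False)
    delta_target: float | None = field(init=False)

    def __post_init__(self) -> None:
        if self.first.subject_id != self.second.subject_id:
            raise ValueError("pair members must share a subject")
        self.delta_time = float(self.second.time - self.first.time)
        self.order_label = int(self.delta_time > 0)
        if self.first.target is not None and self.second.target is not None:
            self.delta_target = float(self.second.target - self.first.target)
        else:
            self.delta_target = None

    @property
    def subject_id(self) -> str:
        return self.first.subject_id

    def delta_metadata(self) -> np.ndarray | None:
        if self.first.metadata is None:
            return None
        return np.asarray(self.second.metadata, float) - np.asarray(self.first.metadata, float)

    def reversed(self) -> "LongitudinalPair":
        return LongitudinalPair(self.second, self.first)

    def chronological(self) -> "LongitudinalPair":
        """The same unordered pair presented earlier-first."""
        return self if self.delta_time > 0 else self.reversed()


def read_manifest(path: str | Path, check_paths: bool = True) -> list[ImageRecord]:
    """Parse a manifest CSV into records sorted by (subject, time).

    Metadata covariates are taken from columns named ``meta_*`` in their
    manifest order.  Duplicate (subject, time) rows and non-numeric times are
    rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "time", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    try:
        df["time"] = pd.to_numeric(df["time"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"manifest {path}: non-numeric 'time' values") from exc
    dup = df.duplicated(subset=["subject_id", "time"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"manifest {path}: duplicate (subject, time) row "
            f"({row['subject_id']}, t={row['time']})")
    meta_cols = [c for c in df.columns if c.startswith("meta_")]
    df = df.sort_values(["subject_id", "time"], kind="mergesort").reset_index(drop=True)
    records = []
    for _, row in df.iterrows():
        img_path = Path(row["path"])
        if not img_path.is_absolute():
            img_path = path.parent / img_path
        if check_paths and not img_path.exists():
            raise ValueError(f"manifest {path}: image not found: {img_path}")
        target = row["target"] if "target" in df.columns and pd.notna(row["target"]) else None
        group = int(row["group"]) if "group" in df.columns and pd.notna(row["group"]) else None
        meta = np.array([float(row[c]) for c in meta_cols]) if meta_cols else None
        records.append(ImageRecord(
            subject_id=str(row["subject_id"]), time=float(row["time"]),
            path=str(img_path), target=None if target is None else float(target),
            metadata=meta, group=group))
    return records


def split_subjects(records: list[ImageRecord],
                   fractions: tuple[float, ...] = (0.6, 0.2, 0.2),
                   seed: int = 0) -> tuple[list[ImageRecord], ...]:
    """Subject-wise split: every subject's records land wholly in one split.

    Subject counts follow the fractions by largest-remainder rounding, so
    10 subjects at (0.6, 0.2, 0.2) give 6/2/2.
    """
    fracs = np.asarray(fractions, float)
    if (fracs <= 0).any() or abs(fracs.sum() - 1.0) > 1e-8:
        raise ValueError("fractions must be positive and sum to 1")
    subjects = sorted({r.subject_id for r in records})
    if len(subjects) < len(fracs):
        raise ValueError(
            f"{len(subjects)} subjects cannot fill {len(fracs)} splits")
    order = np.random.default_rng(seed).permutation(len(subjects))
    shuffled = [subjects[i] for i in order]
    ideal = fracs * len(subjects)
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for i in np.argsort(-remainder)[: len(subjects) - counts.sum()]:
        counts[i] += 1
    out, start = [], 0
    for c in counts:
        chosen = set(shuffled[start:start + c])
        out.append([r for r in records if r.subject_id in chosen])
        start += c
    return tuple(out)


def make_pairs(records: list[ImageRecord], task: str = "ordering",
               rng: np.random.Generator | None = None,
               both_orders: bool = False,
               max_pairs_per_subject: int | None = None) -> list[LongitudinalPair]:
    """Enumerate within-subject pairs with randomized presentation order.

    Each unordered pair is emitted once with a coin-flip orientation (labels
    balanced 1:1 in expectation), or twice — once per orientation — when
    ``both_orders`` is set.  Subjects with a single timepoint are skipped
    with a warning.  ``max_pairs_per_subject`` caps combinations per subject
    by random subsampling.
    """
    if task not in ("ordering", "interval", "score"):
        raise ValueError(f"unknown task {task!r}")
    rng = rng or np.random.default_rng()
    by_subject: dict[str, list[ImageRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    pairs: list[LongitudinalPair] = []
    for sid in sorted(by_subject):
        recs = sorted(by_subject[sid], key=lambda r: r.time)
        if len(recs) < 2:
            warnings.warn(f"subject {sid} has a single timepoint; skipped")
            continue
        combos = list(combinations(range(len(recs)), 2))
        if max_pairs_per_subject is not None and len(combos) > max_pairs_per_subject:
            idx = rng.choice(len(combos), size=max_pairs_per_subject, replace=False)
            combos = [combos[i] for i in sorted(idx)]
        for i, j in combos:  # i < j, so (recs[i], recs[j]) is chronological
            if both_orders:
                pairs.append(LongitudinalPair(recs[i], recs[j]))
                pairs.append(LongitudinalPair(recs[j], recs[i]))
            elif rng.random() < 0.5:
                pairs.append(LongitudinalPair(recs[i], recs[j]))
            else:
                pairs.append(LongitudinalPair(recs[j], recs[i]))
    return pairs


def curriculum_filter(pairs: list[LongitudinalPair], epoch: int,
                      start_threshold: float, step_epochs: int = 2,
                      warmup_epochs: int = 10) -> list[LongitudinalPair]:
    """Warm-up schedule: admit only widely separated pairs early in training.

    The |Δt| threshold starts at ``start_threshold``, decays linearly to 0 by
    one step every ``step_epochs`` epochs, and vanishes at ``warmup_epochs``,
    after which every pair passes.
    """
    if start_threshold <= 0:
        return list(pairs)
    if step_epochs < 1:
        raise ValueError("step_epochs must be >= 1")
    frac = min(1.0, (epoch // step_epochs) * step_epochs / warmup_epochs)
    threshold = start_threshold * (1.0 - frac)
    return [p for p in pairs if abs(p.delta_time) > threshold]


def max_interval_pairs(pairs: list[LongitudinalPair]) -> list[LongitudinalPair]:
    """One pair per subject: the one with the largest |Δt| (first-last scans)."""
    best: dict[str, LongitudinalPair] = {}
    for p in pairs:
        cur = best.get(p.subject_id)
        if cur is None or abs(p.delta_time) > abs(cur.delta_time):
            best[p.subject_id] = p
    return [best[s] for s in sorted(best)]
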