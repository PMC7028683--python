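"""Three-stage labeling and sliding-window segmentation.

A fall recording is divided into three stages: non-fall (ordinary activity),
pre-impact fall (the descent between loss of balance and ground contact, the
interval in which a protective device can still deploy) and fall (the impact
and the state transition around it).  Everything after the fall stage is cut
off before labeling.  Trials are then cut into fixed-length overlapping
windows, each carrying one class label:

    0 = non-fall, 1 = pre-impact fall, 2 = fall

The default labeling rule assigns a window the stage of its final sample —
causal semantics: at inference time the window's end is "now".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError, ConfigError
from .sisfall import RecordingTrial

__all__ = [
    "NON_FALL",
    "PRE_IMPACT",
    "FALL",
    "LABEL_NAMES",
    "StageAnnotation",
    "WindowSet",
    "truncate_post_fall",
    "segment_windows",
    "stage_of_sample",
    "assign_window_label",
    "build_dataset",
]

logger = logging.getLogger(__name__)

NON_FALL, PRE_IMPACT, FALL = 0, 1, 2
LABEL_NAMES = {NON_FALL: "non-fall", PRE_IMPACT: "pre-impact", FALL: "fall"}

LABEL_RULES = ("final_sample", "majority")


@dataclass(frozen=True)
class StageAnnotation:
    """Half-open, 0-based sample intervals delimiting the three stages.

    Non-fall is ``[0, pre_impact_start)``, pre-impact fall is
    ``[pre_impact_start, pre_impact_end)`` and fall is
    ``[pre_impact_end, fall_end)``.  For a pure-ADL trial all three indices
    equal the trial length (no pre-impact or fall interval exists).
    """

    pre_impact_start: int
    pre_impact_end: int
    fall_end: int

    def validate(self, n_samples: int) -> None:
        a, b, c = self.pre_impact_start, self.pre_impact_end, self.fall_end
        if not (0 <= a <= b <= c <= n_samples):
            raise AnnotationError(
                f"annotation ({a}, {b}, {c}) inconsistent with trial length {n_samples}"
            )
        if a != b and a == c:
            raise AnnotationError("pre-impact interval without a fall interval")

    @property
    def is_adl(self) -> bool:
        """True when the trial contains no pre-impact/fall interval."""
        return self.pre_impact_start == self.pre_impact_end == self.fall_end

    @classmethod
    def adl(cls, n_samples: int) -> "StageAnnotation":
        return cls(n_samples, n_samples, n_samples)


def truncate_post_fall(trial: RecordingTrial, ann: StageAnnotation) -> RecordingTrial:
    """Drop everything at or after ``fall_end`` (post-incident data).

    ADL trials (``fall_end == T``) are returned unchanged.  ``fall_end == 0``
    yields an empty trial, which downstream segmentation skips.
    """
    if ann.fall_end > trial.n_samples:
        raise AnnotationError(
            f"fall_end {ann.fall_end} beyond trial length {trial.n_samples}"
        )
    if ann.fall_end == trial.n_samples:
        return trial
    return replace(trial, samples=trial.samples[: ann.fall_end].copy())


def segment_windows(n_samples: int, window_len: int, stride: int) -> list[tuple[int, int]]:
    """Spans ``[s, s+window_len)`` for ``s = 0, stride, 2*stride, ...``

    A trial shorter than one window yields an empty list (the trial is
    skipped with a warning by :func:`build_dataset`).
    """
    if window_len < 1:
        raise ConfigError("window_len must be >= 1")
    if not 1 <= stride <= window_len:
        raise ConfigError("stride must satisfy 1 <= stride <= window_len")
    if n_samples < window_len:
        return []
    n = (n_samples - window_len) // stride + 1
    return [(s * stride, s * stride + window_len) for s in range(n)]


def stage_of_sample(i: int, ann: StageAnnotation) -> int:
    """Stage of one sample index within a truncated trial."""
    if i < ann.pre_impact_start:
        return NON_FALL
    if i < ann.pre_impact_end:
        return PRE_IMPACT
    if i < ann.fall_end:
        return FALL
    # samples at/after fall_end only occur for ADL trials, where every
    # index is non-fall by definition
    return NON_FALL


def assign_window_label(
    span: tuple[int, int], ann: StageAnnotation, rule: str = "final_sample"
) -> int:
    """Label one window span under the configured rule.

    ``final_sample`` (default): the stage containing the last sample of the
    window.  ``majority``: the stage covering the most samples of the span,
    ties broken toward the later (more severe) stage.
    """
    start, end = span
    if rule == "final_sample":
        return stage_of_sample(end - 1, ann)
    if rule == "majority":
        def overlap(lo: int, hi: int) -> int:
            return max(0, min(end, hi) - max(start, lo))

        counts = [
            # non-fall: before pre-impact onset, plus anything past fall_end
            overlap(0, ann.pre_impact_start) + overlap(ann.fall_end, end),
            overlap(ann.pre_impact_start, ann.pre_impact_end),
            overlap(ann.pre_impact_end, ann.fall_end),
        ]
        best = max(counts)
        # ties break toward the later (more severe) stage
        return max(c for c in (NON_FALL, PRE_IMPACT, FALL) if counts[c] == best)
    raise ConfigError(f"unknown labeling rule {rule!r}; known: {LABEL_RULES}")


@dataclass
class WindowSet:
    """Fixed-length labeled windows ready for model consumption.

    ``windows``: float array [N × L × C]; ``labels``: int array [N] with
    values in {0, 1, 2}; ``provenance``: one row per window with subject,
    activity, trial and start index, so subject-wise splits can be enforced
    at window granularity.
    """

    windows: np.ndarray
    labels: np.ndarray
    provenance: pd.DataFrame
    window_len: int = 256
    stride: int = 128
    rule: str = "final_sample"

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.windows.ndim != 3:
            raise ConfigError("windows must be [N x L x C]")
        if len(self.labels) != len(self.windows) or len(self.provenance) != len(self.windows):
            raise ConfigError("windows, labels and provenance must align")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            LABEL_NAMES[c]: int((self.labels == c).sum()) for c in (0, 1, 2)
        }

    def subset(self, mask: np.ndarray) -> "WindowSet":
        mask = np.asarray(mask)
        return WindowSet(
            self.windows[mask],
            self.labels[mask],
            self.provenance[mask].reset_index(drop=True),
            self.window_len,
            self.stride,
            self.rule,
        )

    def for_subjects(self, subject_ids: Iterable[str]) -> "WindowSet":
        ids = set(subject_ids)
        return self.subset(self.provenance["subject_id"].isin(ids).to_numpy())

    def save(self, path: str | Path) -> Path:
        """Persist arrays + provenance + a JSON manifest next to them."""
        path = Path(path)
        np.savez(
            path,
            windows=self.windows.astype(np.float32),
            labels=self.labels,
            **{
                # fixed-width unicode for string columns so the container
                # stays loadable without pickle
                f"prov_{c}": np.asarray(
                    self.provenance[c].to_numpy(),
                    dtype=None if self.provenance[c].dtype != object else str,
                )
                for c in self.provenance.columns
            },
        )
        manifest = {
            "window_len": self.window_len,
            "stride": self.stride,
            "rule": self.rule,
            "label_map": {str(k): v for k, v in LABEL_NAMES.items()},
            "class_counts": self.class_counts,
            "n_windows": len(self),
        }
        mpath = path.with_suffix(".manifest.json")
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "WindowSet":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        data = np.load(path, allow_pickle=False)
        prov_cols = {
            k[len("prov_"):]: data[k] for k in data.files if k.startswith("prov_")
        }
        manifest = json.loads(path.with_suffix("").with_suffix(".manifest.json").read_text())
        return cls(
            data["windows"].astype(np.float64),
            data["labels"],
            pd.DataFrame(prov_cols),
            window_len=manifest["window_len"],
            stride=manifest["stride"],
            rule=manifest["rule"],
        )


def build_dataset(
    trials: Sequence[tuple[RecordingTrial, StageAnnotation]],
    window_len: int = 256,
    stride: int = 128,
    rule: str = "final_sample",
) -> WindowSet:
    """Truncate, segment and label a collection of annotated trials."""
    if rule not in LABEL_RULES:
        raise ConfigError(f"unknown labeling rule {rule!r}; known: {LABEL_RULES}")
    arrays: list[np.ndarray] = []
    labels: list[int] = []
    prov: list[tuple] = []
    for trial, ann in trials:
        ann.validate(trial.n_samples)
        cut = truncate_post_fall(trial, ann)
        spans = segment_windows(cut.n_samples, window_len, stride)
        if not spans:
            logger.warning(
                "skipping trial %s_%s_R%02d: %d samples < window length %d",
                trial.activity_code, trial.subject_id, trial.trial_index,
                cut.n_samples, window_len,
            )
            continue
        for start, end in spans:
            arrays.append(cut.samples[start:end])
            labels.append(assign_window_label((start, end), ann, rule))
            prov.append((trial.subject_id, trial.subject_group,
                         trial.activity_code, trial.trial_index, start))
    if not arrays:
        windows = np.zeros((0, window_len, 0))
    else:
        windows = np.stack(arrays)
    ws = WindowSet(
        windows,
        np.asarray(labels, dtype=np.int64),
        pd.DataFrame(
            prov,
            columns=["subject_id", "subject_group", "activity_code",
                     "trial_index", "start"],
        ),
        window_len=window_len,
        stride=stride,
        rule=rule,
    )
    logger.info("built %d windows; class counts %s", len(ws), ws.class_counts)
    return ws
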