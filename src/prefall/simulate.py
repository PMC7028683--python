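"""Synthetic annotated IMU cohorts with the three-stage fall structure.

The generator produces 6-channel recordings (tri-axial accelerometer in g,
tri-axial gyroscope in °/s, 200 Hz) from piecewise kinematic phase templates
plus per-subject random effects and white Gaussian sensor noise.  It is a
statistical stand-in for instrumented fall/ADL protocols, not a biomechanical
simulation: its purpose is controllable, exactly-annotated structure so the
whole pipeline is testable without any external download.

A fall trial concatenates three phases:

1. an ADL prefix (walking) — the non-fall stage;
2. a descent — the pre-impact stage: acceleration magnitude decays from 1 g
   toward a free-fall floor (< 0.8 g) while the gyroscope shows a fast-onset
   rotation burst (100–300 °/s peak), as the body pivots after losing
   balance;
3. impact and settling — the fall stage: a multi-g spike (> 2 g) followed by
   damped ringing around a new, lying-down gravity orientation.

A short post-fall tail (lying still) follows the fall stage so that the
post-incident truncation step has something to remove.  Annotation indices
coincide exactly with the generative phase switches.

Per-subject effects (amplitude gain, walking cadence, phase-duration jitter)
are drawn once per subject, which makes subjects real statistical units and
subject-wise cross-validation meaningful.  Elderly subjects walk slower with
lower amplitude.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .sisfall import (
    SIM_SCHEMA,
    RecordingTrial,
    trial_filename,
    write_annotations,
    write_trial,
)
from .windows import StageAnnotation

__all__ = [
    "FallTemplate",
    "AdlTemplate",
    "SubjectParams",
    "SimCohortConfig",
    "Cohort",
    "simulate_adl_trial",
    "simulate_fall_trial",
    "simulate_cohort",
    "write_cohort",
    "load_cohort",
]

logger = logging.getLogger(__name__)

GRAVITY = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class FallTemplate:
    """One fall scenario: direction of toppling and descent timing."""

    name: str
    code: str                      # activity code, e.g. "F01"
    descent_ms: tuple[float, float] = (400.0, 700.0)
    gyro_axis: int = 1             # dominant rotation axis (0=x roll, 1=y pitch)
    gyro_sign: float = 1.0
    # unit gravity direction after the body comes to rest
    rest_direction: tuple[float, float, float] = (1.0, 0.0, 0.15)

    def __post_init__(self) -> None:
        lo, hi = self.descent_ms
        if not (200.0 <= lo <= hi <= 800.0):
            raise ConfigError(
                f"fall template {self.name!r}: descent range {self.descent_ms} "
                "must lie within [200, 800] ms"
            )


@dataclass(frozen=True)
class AdlTemplate:
    """One activity of daily living."""

    name: str                      # {"walk", "sit_down", "stand", "jog"}
    code: str                      # activity code, e.g. "D01"
    duration_s: float = 4.0


DEFAULT_FALL_TEMPLATES: tuple[FallTemplate, ...] = (
    FallTemplate("forward", "F01", (400.0, 700.0), gyro_axis=1, gyro_sign=+1.0,
                 rest_direction=(1.0, 0.0, 0.15)),
    FallTemplate("backward", "F02", (400.0, 700.0), gyro_axis=1, gyro_sign=-1.0,
                 rest_direction=(-1.0, 0.0, 0.15)),
    FallTemplate("lateral", "F03", (300.0, 600.0), gyro_axis=0, gyro_sign=+1.0,
                 rest_direction=(0.0, 1.0, 0.15)),
    FallTemplate("vertical", "F04", (400.0, 800.0), gyro_axis=0, gyro_sign=-1.0,
                 rest_direction=(0.3, -0.9, 0.3)),
)

DEFAULT_ADL_TEMPLATES: tuple[AdlTemplate, ...] = (
    AdlTemplate("walk", "D01", 4.0),
    AdlTemplate("sit_down", "D02", 4.0),
    AdlTemplate("stand", "D03", 4.0),
    AdlTemplate("jog", "D04", 4.0),
)


@dataclass
class SubjectParams:
    """Per-subject random effects, drawn once per subject."""

    subject_id: str
    group: str                     # {"young", "elderly"}
    gain: float = 1.0              # movement amplitude multiplier
    cadence_hz: float = 1.8        # walking step frequency
    jitter: float = 0.0            # fractional timing jitter, in [-0.15, 0.15]


@dataclass
class SimCohortConfig:
    """The study conditions the generator emulates, at desk scale.

    Defaults: 11 subjects (6 young, 5 elderly — five elderly so the default
    cohort supports 5-fold subject-wise splits with at least one elderly
    subject per test fold), 4 fall + 4 ADL templates, 3 trials per subject
    per template.
    """

    n_young: int = 6
    n_elderly: int = 5
    trials_per_subject: int = 3
    fall_templates: tuple[FallTemplate, ...] = DEFAULT_FALL_TEMPLATES
    adl_templates: tuple[AdlTemplate, ...] = DEFAULT_ADL_TEMPLATES
    rate_hz: float = 200.0
    noise_sd_acc: float = 0.03     # g
    noise_sd_gyro: float = 3.0     # °/s
    impact_peak_range: tuple[float, float] = (3.0, 6.0)   # g
    freefall_floor_range: tuple[float, float] = (0.25, 0.6)  # g
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 0 or self.n_elderly < 0 or self.trials_per_subject < 0:
            raise ConfigError("counts must be >= 0")
        if self.impact_peak_range[0] <= 2.0:
            raise ConfigError("impact_peak_range minimum must exceed 2 g")
        if self.freefall_floor_range[1] >= 0.8:
            raise ConfigError("freefall_floor_range maximum must stay below 0.8 g")
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fall_templates"] = [dataclasses.asdict(t) for t in self.fall_templates]
        d["adl_templates"] = [dataclasses.asdict(t) for t in self.adl_templates]
        return d


@dataclass
class Cohort:
    """Subjects and their annotated trials, in memory."""

    subjects: list[SubjectParams]
    trials: list[tuple[RecordingTrial, StageAnnotation]]
    config: SimCohortConfig

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def ids_by_group(self, group: str) -> list[str]:
        return [s.subject_id for s in self.subjects if s.group == group]


# ---------------------------------------------------------------------------
# signal building blocks

def _noise(rng: np.random.Generator, n: int, cfg: SimCohortConfig) -> np.ndarray:
    out = np.empty((n, 6))
    out[:, :3] = rng.normal(0.0, cfg.noise_sd_acc, size=(n, 3))
    out[:, 3:] = rng.normal(0.0, cfg.noise_sd_gyro, size=(n, 3))
    return out


def _walk_segment(n: int, sp: SubjectParams, rng: np.random.Generator,
                  rate: float, amp: float = 0.22) -> np.ndarray:
    """Walking: vertical oscillation around 1 g at the subject's cadence."""
    t = np.arange(n) / rate
    phase = rng.uniform(0, 2 * np.pi)
    c = sp.cadence_hz
    sig = np.zeros((n, 6))
    a = amp * sp.gain
    sig[:, 2] = 1.0 + a * np.sin(2 * np.pi * c * t + phase) \
        + 0.3 * a * np.sin(4 * np.pi * c * t + 2 * phase)
    sig[:, 0] = 0.4 * a * np.sin(2 * np.pi * c * t + phase + 0.8)
    sig[:, 1] = 0.3 * a * np.sin(np.pi * c * t + phase)
    sig[:, 4] = 18.0 * sp.gain * np.sin(2 * np.pi * c * t + phase)   # pitch sway
    sig[:, 3] = 10.0 * sp.gain * np.sin(np.pi * c * t + phase + 1.2)  # roll sway
    return sig


def _stand_segment(n: int) -> np.ndarray:
    sig = np.zeros((n, 6))
    sig[:, :3] = GRAVITY
    return sig


def _jog_segment(n: int, sp: SubjectParams, rng: np.random.Generator,
                 rate: float) -> np.ndarray:
    t = np.arange(n) / rate
    phase = rng.uniform(0, 2 * np.pi)
    c = min(1.55 * sp.cadence_hz, 3.2)
    sig = np.zeros((n, 6))
    a = min(0.45 * sp.gain, 0.45)  # keep |a| above the 0.5 g ADL floor
    sig[:, 2] = 1.0 + a * np.sin(2 * np.pi * c * t + phase)
    sig[:, 0] = 0.35 * a * np.sin(2 * np.pi * c * t + phase + 1.0)
    sig[:, 4] = 30.0 * sp.gain * np.sin(2 * np.pi * c * t + phase)
    return sig


def _sit_down_segment(n: int, sp: SubjectParams, rng: np.random.Generator,
                      rate: float) -> np.ndarray:
    """Quiet stance, one smooth sit-down transient, then sitting still."""
    sig = _stand_segment(n)
    dur = int(0.8 * rate)
    t0 = int(rng.uniform(0.25, 0.5) * (n - dur))
    tau = np.linspace(0.0, 1.0, dur)
    # dip below 1 g while descending, brief overshoot on seat contact
    bump = -0.18 * sp.gain * np.sin(np.pi * tau) + 0.45 * sp.gain * np.sin(np.pi * tau) ** 8
    sig[t0:t0 + dur, 2] += bump
    sig[t0:t0 + dur, 1] += 0.08 * sp.gain * np.sin(np.pi * tau)
    sig[t0:t0 + dur, 4] += 45.0 * sp.gain * np.sin(np.pi * tau)  # trunk pitch
    return sig


_ADL_BUILDERS = {
    "walk": lambda n, sp, rng, rate: _walk_segment(n, sp, rng, rate),
    "stand": lambda n, sp, rng, rate: _stand_segment(n),
    "jog": _jog_segment,
    "sit_down": _sit_down_segment,
}


def simulate_adl_trial(
    template: AdlTemplate,
    subject: SubjectParams,
    rng: np.random.Generator,
    config: SimCohortConfig | None = None,
    trial_index: int = 1,
) -> tuple[RecordingTrial, StageAnnotation]:
    """One non-fall trial; the annotation marks the whole trial non-fall."""
    cfg = config if config is not None else SimCohortConfig()
    if template.name not in _ADL_BUILDERS:
        raise ConfigError(f"unknown ADL template {template.name!r}")
    rate = cfg.rate_hz
    n = int(round(template.duration_s * rate * (1.0 + subject.jitter * rng.uniform(-1, 1))))
    n = max(n, 1)
    sig = _ADL_BUILDERS[template.name](n, subject, rng, rate)
    sig = sig + _noise(rng, n, cfg)
    trial = RecordingTrial(
        samples=sig, rate_hz=rate, subject_id=subject.subject_id,
        subject_group=subject.group, activity_code=template.code,
        trial_index=trial_index, is_fall_activity=False,
    )
    return trial, StageAnnotation.adl(n)


def simulate_fall_trial(
    template: FallTemplate,
    subject: SubjectParams,
    rng: np.random.Generator,
    config: SimCohortConfig | None = None,
    trial_index: int = 1,
) -> tuple[RecordingTrial, StageAnnotation]:
    """One fall trial: walk prefix → descent → impact + settling → lying tail.

    Annotation indices mark the generative phase boundaries exactly; the
    lying tail lies beyond ``fall_end`` and is removed by truncation.
    """
    cfg = config if config is not None else SimCohortConfig()
    rate = cfg.rate_hz

    prefix_n = int(round(rng.uniform(2.2, 2.9) * rate * (1.0 + subject.jitter)))
    descent_ms = rng.uniform(*template.descent_ms)
    descent_n = max(int(round(descent_ms / 1000.0 * rate)), 2)
    fall_n = int(round(1.2 * rate))        # impact + settling
    tail_n = int(round(1.0 * rate))        # post-fall lying, truncated later

    prefix = _walk_segment(prefix_n, subject, rng, rate)

    # descent: gravity direction swings toward the rest orientation while
    # the magnitude decays to the free-fall floor
    floor = rng.uniform(*cfg.freefall_floor_range)
    tau = np.linspace(0.0, 1.0, descent_n, endpoint=False)
    mag = floor + (1.0 - floor) * 0.5 * (1.0 + np.cos(np.pi * tau))
    rest = np.asarray(template.rest_direction, dtype=float)
    rest = rest / np.linalg.norm(rest)
    frac = tau[:, None]
    direction = (1 - frac) * GRAVITY + frac * rest
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    descent = np.zeros((descent_n, 6))
    descent[:, :3] = mag[:, None] * direction
    # slip perturbation right at loss of balance
    jerk_n = min(int(0.06 * rate), descent_n)
    descent[:jerk_n, 0] += 0.3 * np.sin(np.pi * np.linspace(0, 1, jerk_n))
    # rotation burst with abrupt onset: the body pivots as soon as balance
    # is lost, reaching peak angular velocity within ~40 ms and sustaining
    # it through the descent (trunk angular velocity is the classic early
    # pre-impact trigger precisely because its onset is fast)
    peak = rng.uniform(100.0, 300.0)
    attack_n = max(int(round(0.04 * rate)), 1)
    ramp = np.sin(0.5 * np.pi * np.minimum(np.arange(descent_n) / attack_n, 1.0)) ** 2
    descent[:, 3 + template.gyro_axis] += template.gyro_sign * peak * ramp

    # impact + settling around the rest orientation
    t_fall = np.arange(fall_n) / rate
    fall = np.zeros((fall_n, 6))
    fall[:, :3] = rest
    peak_g = rng.uniform(*cfg.impact_peak_range)
    spike_n = max(int(0.04 * rate), 1)
    spike = (peak_g - 1.0) * np.sin(np.pi * np.linspace(0, 1, spike_n)) ** 2
    fall[:spike_n, :3] += spike[:, None] * rest
    ring = 0.5 * np.exp(-t_fall / 0.18) * np.sin(2 * np.pi * 8.0 * t_fall)
    fall[:, :3] += ring[:, None] * rest
    gyro_decay = template.gyro_sign * peak * np.exp(-t_fall / 0.12)
    fall[:, 3 + template.gyro_axis] += gyro_decay

    tail = np.zeros((tail_n, 6))
    tail[:, :3] = rest

    sig = np.concatenate([prefix, descent, fall, tail], axis=0)
    sig += _noise(rng, len(sig), cfg)
    trial = RecordingTrial(
        samples=sig, rate_hz=rate, subject_id=subject.subject_id,
        subject_group=subject.group, activity_code=template.code,
        trial_index=trial_index, is_fall_activity=True,
    )
    ann = StageAnnotation(
        pre_impact_start=prefix_n,
        pre_impact_end=prefix_n + descent_n,
        fall_end=prefix_n + descent_n + fall_n,
    )
    return trial, ann


def _draw_subject(sid: str, group: str, rng: np.random.Generator) -> SubjectParams:
    slow = 1.0 if group == "young" else 0.82
    return SubjectParams(
        subject_id=sid,
        group=group,
        gain=float(np.clip(rng.normal(1.0, 0.08), 0.78, 1.22)) * slow,
        cadence_hz=float(rng.normal(1.85 * slow, 0.12)),
        jitter=float(rng.uniform(-0.12, 0.12)),
    )


def simulate_cohort(config: SimCohortConfig | None = None) -> Cohort:
    """Generate the full cohort; deterministic under ``config.seed``."""
    cfg = config if config is not None else SimCohortConfig()
    rng = np.random.default_rng(cfg.seed)
    subjects: list[SubjectParams] = []
    for i in range(cfg.n_young):
        subjects.append(_draw_subject(f"SA{i + 1:02d}", "young", rng))
    for i in range(cfg.n_elderly):
        subjects.append(_draw_subject(f"SE{i + 1:02d}", "elderly", rng))
    if not subjects:
        logger.warning("empty cohort: no subjects configured")
    trials: list[tuple[RecordingTrial, StageAnnotation]] = []
    for sp in subjects:
        for tpl in cfg.adl_templates:
            for r in range(cfg.trials_per_subject):
                trials.append(simulate_adl_trial(tpl, sp, rng, cfg, trial_index=r + 1))
        for tpl in cfg.fall_templates:
            for r in range(cfg.trials_per_subject):
                trials.append(simulate_fall_trial(tpl, sp, rng, cfg, trial_index=r + 1))
    return Cohort(subjects=subjects, trials=trials, config=cfg)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write the cohort in the SisFall dialect + annotation CSV + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann_rows: dict[str, tuple[int, int, int]] = {}
    for trial, ann in cohort.trials:
        fname = trial_filename(trial)
        write_trial(trial, out_dir / fname, schema=SIM_SCHEMA)
        ann_rows[Path(fname).stem] = (
            ann.pre_impact_start, ann.pre_impact_end, ann.fall_end
        )
    write_annotations(ann_rows, out_dir / "annotations.csv")
    manifest = {
        "seed": cohort.config.seed,
        "config": cohort.config.to_dict(),
        "n_subjects": len(cohort.subjects),
        "n_trials": len(cohort.trials),
        "subjects": [dataclasses.asdict(s) for s in cohort.subjects],
    }
    (out_dir / "cohort.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out_dir


def load_cohort(in_dir: str | Path) -> Cohort:
    """Read back a cohort written by :func:`write_cohort`."""
    from .sisfall import read_annotations, read_trial

    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "cohort.json").read_text())
    cfg_d = dict(manifest["config"])
    cfg_d["fall_templates"] = tuple(FallTemplate(**t) for t in cfg_d["fall_templates"])
    cfg_d["adl_templates"] = tuple(AdlTemplate(**t) for t in cfg_d["adl_templates"])
    for key in ("impact_peak_range", "freefall_floor_range"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = SimCohortConfig(**cfg_d)
    subjects = [SubjectParams(**s) for s in manifest["subjects"]]
    anns = read_annotations(in_dir / "annotations.csv")
    trials = []
    for stem, (a, b, c) in sorted(anns.items()):
        trial = read_trial(in_dir / f"{stem}.txt", schema=SIM_SCHEMA, rate_hz=cfg.rate_hz)
        trials.append((trial, StageAnnotation(a, b, c)))
    return Cohort(subjects=subjects, trials=trials, config=cfg)
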