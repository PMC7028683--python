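#!/usr/bin/env python
"""Run the full cross-validation experiment on a real SisFall download.

The public SisFall corpus (9-channel raw trials at 200 Hz) is not shipped
with this package; point this script at a local copy plus a stage-annotation
CSV (columns: trial_id, pre_impact_start, pre_impact_end, fall_end) and it
will reproduce the subject-wise five-fold experiment for one model family
with the canonical hyperparameters (batch 64, 200 epochs, lr 0.0005, focal
loss).  Expect a long run on CPU.

Usage:
    python scripts/run_sisfall.py --data-dir SisFall/ \
        --annotations annotations.csv --family convlstm --out results/sisfall/
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from prefall.cli import _model_config
from prefall.evaluation import cross_validate
from prefall.simulate import Cohort, SimCohortConfig, SubjectParams
from prefall.sisfall import (
    DEFAULT_CHANNELS,
    SISFALL_SCHEMA,
    read_annotations,
    read_trial,
    select_channels,
)
from prefall.training import TrainConfig
from prefall.windows import StageAnnotation


def load_sisfall(data_dir: Path, annotations: Path) -> Cohort:
    anns = read_annotations(annotations)
    trials = []
    subjects: dict[str, SubjectParams] = {}
    for stem, (a, b, c) in sorted(anns.items()):
        path = data_dir / f"{stem}.txt"
        trial = read_trial(path, schema=SISFALL_SCHEMA)
        trial = select_channels(trial, DEFAULT_CHANNELS)
        trials.append((trial, StageAnnotation(a, b, c)))
        subjects.setdefault(
            trial.subject_id,
            SubjectParams(subject_id=trial.subject_id, group=trial.subject_group),
        )
    return Cohort(subjects=list(subjects.values()), trials=trials,
                  config=SimCohortConfig())


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--annotations", type=Path, required=True)
    parser.add_argument("--family", default="convlstm",
                        choices=["cnn", "lstm", "convlstm"])
    parser.add_argument("--epochs", type=int, default=200)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    cohort = load_sisfall(args.data_dir, args.annotations)
    report = cross_validate(
        cohort,
        _model_config({}, args.family),
        TrainConfig(n_epochs=args.epochs, seed=args.seed),
        fold_seed=args.seed,
        cache_dir=str(args.out / "folds"),
    )
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    print(json.dumps(report["mean"], indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
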