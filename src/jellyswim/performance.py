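"""Summary quantities: enhancement factors, speed-frequency tables, and
theory-versus-experiment comparison statistics.

A SpeedRecord row is one (animal, condition) mean vertical speed, either
measured from field video or predicted by the hydrodynamic model. The
enhancement factor normalises a driven condition's speed by the same
animal's unstimulated (0 Hz controller) baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import SimulationConfig, mean_speed, simulate
from .geometry import Environment, Morphology
from .kinematics import PulseProgram

__all__ = [
    "SpeedRecord",
    "enhancement_factor",
    "baseline_speed",
    "predict_speed_table",
    "compare_theory_experiment",
    "records_to_frame",
    "frame_to_records",
]

_CSV_COLUMNS = [
    "animal_id",
    "controller_freq_hz",
    "measured_freq_hz",
    "mean_speed_cm_s",
    "speed_err_cm_s",
    "source",
]


@dataclass(frozen=True)
class SpeedRecord:
    """One mean-vertical-speed observation or prediction.

    controller_freq is the externally commanded stimulation rate (0 for the
    control case, NaN when not applicable, e.g. model predictions);
    measured_freq is the realised pulse rate including endogenous pulses.
    """

    animal_id: str
    measured_freq: float
    mean_speed: float
    controller_freq: float = float("nan")
    speed_err: float = 0.0
    source: str = "experimental"

    def __post_init__(self) -> None:
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be non-negative")
        if self.speed_err < 0:
            raise ValueError("speed_err must be non-negative")
        if self.source not in ("experimental", "theoretical"):
            raise ValueError("source must be 'experimental' or 'theoretical'")


def enhancement_factor(speed: float, baseline: float) -> float:
    """Swimming speed normalised by the same animal's 0 Hz control speed."""
    if baseline <= 0:
        raise ValueError("baseline speed must be positive")
    return speed / baseline


def baseline_speed(records: Sequence[SpeedRecord]) -> float:
    """Mean speed of the control (controller_freq = 0) records of one animal.

    Field protocols took two control measurements per animal; their
    arithmetic mean is the baseline.
    """
    animals = {r.animal_id for r in records}
    if len(animals) > 1:
        raise ValueError(f"records mix animals: {sorted(animals)}")
    controls = [r.mean_speed for r in records if r.controller_freq == 0]
    if not controls:
        raise ValueError("no control (0 Hz) record for baseline")
    return float(np.mean(controls))


def predict_speed_table(
    morph: Morphology,
    pulse_template: PulseProgram,
    freqs: Iterable[float],
    env: Environment | None = None,
    cfg: SimulationConfig | None = None,
    animal_id: str = "animal",
) -> list[SpeedRecord]:
    """Run the hydrodynamic model at each measured frequency.

    Morphology and contraction/relaxation timings are held fixed at the
    values estimated from one video; only the drive frequency varies.
    Deterministic: repeated frequencies give identical speeds.
    """
    records = []
    for f in freqs:
        if not 0 < f <= 1.4:
            raise ValueError(
                f"frequency {f} Hz outside the biological range (0, 1.4]"
            )
        pulse = replace(pulse_template, f=f)
        traj = simulate(morph, pulse, env, cfg)
        records.append(
            SpeedRecord(
                animal_id=animal_id,
                measured_freq=f,
                mean_speed=max(mean_speed(traj), 0.0),
                source="theoretical",
            )
        )
    return records


def compare_theory_experiment(
    theoretical: Sequence[SpeedRecord],
    experimental: Sequence[SpeedRecord],
    freq_tol: float = 1e-6,
) -> tuple[float, float, pd.DataFrame]:
    """Mean and sample SD of |theory - experiment| over matched pairs.

    Records are matched on (animal_id, measured_freq); unmatched records
    appear in the returned table with NaN partners rather than being
    silently dropped. With a single matched pair the SD is reported as 0.
    """
    pairs = []
    used = set()
    for th in theoretical:
        match = None
        for j, ex in enumerate(experimental):
            if j in used:
                continue
            if ex.animal_id == th.animal_id and math.isclose(
                ex.measured_freq, th.measured_freq, abs_tol=freq_tol
            ):
                match = (j, ex)
                break
        if match is None:
            pairs.append((th, None))
        else:
            used.add(match[0])
            pairs.append((th, match[1]))
    for j, ex in enumerate(experimental):
        if j not in used:
            pairs.append((None, ex))

    rows = []
    for th, ex in pairs:
        rows.append(
            {
                "animal_id": (th or ex).animal_id,
                "measured_freq_hz": (th or ex).measured_freq,
                "theory_cm_s": th.mean_speed if th else float("nan"),
                "experiment_cm_s": ex.mean_speed if ex else float("nan"),
                "abs_diff_cm_s": abs(th.mean_speed - ex.mean_speed)
                if th and ex
                else float("nan"),
                "matched": bool(th and ex),
            }
        )
    table = pd.DataFrame(rows)
    diffs = table.loc[table["matched"], "abs_diff_cm_s"].to_numpy()
    if len(diffs) == 0:
        raise ValueError("no matched (animal, frequency) pairs to compare")
    mean_abs = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    return mean_abs, sd, table


def records_to_frame(records: Sequence[SpeedRecord]) -> pd.DataFrame:
    """SpeedRecords -> DataFrame in the CSV column dialect."""
    return pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "controller_freq_hz": r.controller_freq,
                "measured_freq_hz": r.measured_freq,
                "mean_speed_cm_s": r.mean_speed,
                "speed_err_cm_s": r.speed_err,
                "source": r.source,
            }
            for r in records
        ],
        columns=_CSV_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[SpeedRecord]:
    """DataFrame in the CSV column dialect -> SpeedRecords."""
    missing = set(_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return [
        SpeedRecord(
            animal_id=str(row.animal_id),
            controller_freq=float(row.controller_freq_hz),
            measured_freq=float(row.measured_freq_hz),
            mean_speed=float(row.mean_speed_cm_s),
            speed_err=float(row.speed_err_cm_s),
            source=str(row.source),
        )
        for row in frame.itertuples()
    ]
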