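"""Experiment design: stimulus sampling, unit conversion, and trial-table I/O.

The experiment presents auditory stimuli through 7 hidden speakers at
{0, ±5, ±10, ±15} degrees and visual stimuli (Gaussian luminance spots at three
reliability levels) uniformly on [-20, 20] degrees.  Five tasks are run per
participant: UV, UA (unisensory localization), BC (same/different causal
judgment), and BV/BA (bisensory localization of one modality).  On bisensory
trials the two stimuli share a location with probability 0.5.  Localization
responses live on the [-45, 45] degree response range; the small fraction of
clicks landing outside it is discarded at load time.

Degrees of visual angle are the canonical unit throughout the package; screen
pixels only appear through :class:`UnitConversion`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TASKS = ("UV", "UA", "BC", "BV", "BA")
RELIABILITIES = ("high", "med", "low")

#: Columns of the canonical trial table, in order.
TRIAL_COLUMNS = [
    "participant",
    "task",
    "s_V",
    "s_A",
    "reliability",
    "response_loc",
    "response_cat",
]

RESPONSE_HALF_RANGE = 45.0
RESPONSE_RANGE_WIDTH = 90.0


@dataclass(frozen=True)
class UnitConversion:
    """Linear map between screen pixels and degrees of visual angle.

    The default anchors reproduce the experimental apparatus: the visual
    stimulus range [-20, 20] degrees spans pixels 283 to 731 on a 1024-pixel
    projector, giving 0.08928 degrees per pixel.
    """

    degrees_per_pixel: float = 0.08928
    pixel_origin: float = 507.0  # screen pixel corresponding to 0 degrees

    def __post_init__(self) -> None:
        if self.degrees_per_pixel <= 0:
            raise ValueError("degrees_per_pixel must be positive")

    @classmethod
    def from_anchors(cls, pixel_span: float, degree_span: float, pixel_origin: float = 507.0) -> "UnitConversion":
        return cls(degrees_per_pixel=degree_span / pixel_span, pixel_origin=pixel_origin)


def pixels_to_degrees(px, conv: UnitConversion | None = None):
    """Convert an absolute pixel coordinate (or pixel span) to degrees."""
    conv = conv or UnitConversion()
    return (np.asarray(px, dtype=float) - conv.pixel_origin) * conv.degrees_per_pixel


def degrees_to_pixels(deg, conv: UnitConversion | None = None):
    conv = conv or UnitConversion()
    return np.asarray(deg, dtype=float) / conv.degrees_per_pixel + conv.pixel_origin


def pixel_span_to_degrees(px_span, conv: UnitConversion | None = None):
    """Convert a pixel distance (no origin) to a degree distance."""
    conv = conv or UnitConversion()
    return np.asarray(px_span, dtype=float) * conv.degrees_per_pixel


@dataclass(frozen=True)
class ExperimentDesign:
    """Stimulus-generation scheme of the five-task experiment."""

    n_participants: int = 15
    trials_per_task: dict = field(
        default_factory=lambda: {"UV": 500, "UA": 500, "B": 1000, "BC": 1000}
    )
    auditory_locations: tuple = (-15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0)
    visual_range: tuple = (-20.0, 20.0)
    p_same_location: float = 0.5
    reliability_levels: tuple = RELIABILITIES
    response_range: tuple = (-RESPONSE_HALF_RANGE, RESPONSE_HALF_RANGE)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_same_location <= 1.0:
            raise ValueError("p_same_location must lie in [0, 1]")
        if not self.auditory_locations:
            raise ValueError("auditory_locations must be non-empty")
        for task, n in self.trials_per_task.items():
            if n <= 0:
                raise ValueError(f"trial count for task {task!r} must be positive")
        lo, hi = self.response_range
        if not all(lo <= a <= hi for a in self.auditory_locations):
            raise ValueError("auditory locations must lie within the response range")
        if not (lo <= self.visual_range[0] and self.visual_range[1] <= hi):
            raise ValueError("visual range must lie within the response range")

    @property
    def trials_per_participant(self) -> int:
        return sum(self.trials_per_task.values())

    @property
    def response_range_width(self) -> float:
        return self.response_range[1] - self.response_range[0]


def default_design(**overrides) -> ExperimentDesign:
    """The experiment as run: 15 participants x 3000 trials."""
    return ExperimentDesign(**overrides)


def _sample_participant(design: ExperimentDesign, participant, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    aud = np.asarray(design.auditory_locations)
    vlo, vhi = design.visual_range

    n_uv = design.trials_per_task.get("UV", 0)
    rows.append(
        pd.DataFrame(
            {
                "participant": participant,
                "task": "UV",
                "s_V": rng.uniform(vlo, vhi, n_uv),
                "s_A": np.nan,
                "reliability": rng.choice(RELIABILITIES, n_uv),
                "response_loc": np.nan,
                "response_cat": np.nan,
            }
        )
    )
    n_ua = design.trials_per_task.get("UA", 0)
    rows.append(
        pd.DataFrame(
            {
                "participant": participant,
                "task": "UA",
                "s_V": np.nan,
                "s_A": rng.choice(aud, n_ua),
                "reliability": np.nan,
                "response_loc": np.nan,
                "response_cat": np.nan,
            }
        )
    )

    def bisensory(task_labels: np.ndarray) -> pd.DataFrame:
        n = len(task_labels)
        s_a = rng.choice(aud, n)
        same = rng.random(n) < design.p_same_location
        s_v = np.where(same, s_a, rng.uniform(vlo, vhi, n))
        return pd.DataFrame(
            {
                "participant": participant,
                "task": task_labels,
                "s_V": s_v,
                "s_A": s_a,
                "reliability": rng.choice(RELIABILITIES, n),
                "response_loc": np.nan,
                "response_cat": np.nan,
            }
        )

    n_b = design.trials_per_task.get("B", 0)
    if n_b:
        # BV/BA response type assigned with equal probability, independent of stimuli
        labels = np.where(rng.random(n_b) < 0.5, "BV", "BA")
        rows.append(bisensory(labels))
    n_bc = design.trials_per_task.get("BC", 0)
    if n_bc:
        rows.append(bisensory(np.full(n_bc, "BC")))

    return pd.concat(rows, ignore_index=True)


def sample_experiment(design: ExperimentDesign, seed: int) -> pd.DataFrame:
    """Sample the stimuli (no responses) of a full experiment.

    Returns a trial table with one row per trial and NaN responses.
    Bit-reproducible for a fixed ``(design, seed)``.
    """
    rng = np.random.default_rng(seed)
    tables = [
        _sample_participant(design, p, np.random.default_rng(rng.integers(2**31)))
        for p in range(design.n_participants)
    ]
    table = pd.concat(tables, ignore_index=True)
    return table[TRIAL_COLUMNS]


def validate_trials(table: pd.DataFrame) -> None:
    """Check the task/field invariants of a trial table; raise ValueError on violation."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad_task = set(table["task"]) - set(TASKS)
    if bad_task:
        raise ValueError(f"unknown task labels: {sorted(bad_task)}")
    uv = table["task"] == "UV"
    ua = table["task"] == "UA"
    bi = table["task"].isin(("BC", "BV", "BA"))
    if table.loc[uv, "s_V"].isna().any() or table.loc[uv, "s_A"].notna().any():
        raise ValueError("UV trials must carry s_V and no s_A")
    if table.loc[uv, "reliability"].isna().any():
        raise ValueError("UV trials must carry a reliability level")
    if table.loc[ua, "s_A"].isna().any() or table.loc[ua, "s_V"].notna().any():
        raise ValueError("UA trials must carry s_A and no s_V")
    if table.loc[bi, ["s_V", "s_A"]].isna().any().any():
        raise ValueError("bisensory trials must carry both stimuli")
    if table.loc[bi, "reliability"].isna().any():
        raise ValueError("bisensory trials must carry a reliability level")
    bc = table["task"] == "BC"
    loc_tasks = table["task"].isin(("UV", "UA", "BV", "BA"))
    if table.loc[bc, "response_loc"].notna().any():
        raise ValueError("BC trials must not carry a location response")
    if table.loc[loc_tasks, "response_cat"].notna().any():
        raise ValueError("localization trials must not carry a categorical response")
    cat = table.loc[bc, "response_cat"].dropna()
    if not cat.isin((1, 2)).all():
        raise ValueError("BC categorical responses must be 1 (same) or 2 (different)")


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table to CSV (lossless roundtrip with :func:`read_trials`)."""
    validate_trials(table)
    table.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Unparseable degree fields are reported with their (1-based, data) row number.
    """
    raw = pd.read_csv(path, dtype={"task": str, "reliability": str})
    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"trial file missing columns: {missing}")
    for col in ("s_V", "s_A", "response_loc", "response_cat"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"unparseable value in column {col!r} at data row {row}")
        raw[col] = coerced
    table = raw[TRIAL_COLUMNS]
    validate_trials(table)
    return table


def filter_valid_responses(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop localization responses outside the response range.

    Mirrors the preprocessing of the experiment, where a handful of clicks
    landed off the response monitor.  BC (categorical) trials are never
    removed.  Returns ``(kept_table, discarded_count)``.
    """
    loc = table["response_loc"]
    out = loc.notna() & ((loc < -RESPONSE_HALF_RANGE) | (loc > RESPONSE_HALF_RANGE))
    return table.loc[~out].reset_index(drop=True), int(out.sum())


def write_design(design: ExperimentDesign, path) -> None:
    """Persist an experiment design as a YAML config mirroring its fields."""
    import yaml
    payload = {
        "n_participants": design.n_participants,
        "trials_per_task": {k: int(v) for k, v in design.trials_per_task.items()},
        "auditory_locations": [float(a) for a in design.auditory_locations],
        "visual_range": [float(v) for v in design.visual_range],
        "p_same_location": float(design.p_same_location),
        "reliability_levels": list(design.reliability_levels),
        "response_range": [float(v) for v in design.response_range],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_design(path) -> ExperimentDesign:
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("auditory_locations", "visual_range", "reliability_levels",
                "response_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ExperimentDesign(**raw)


def trials_to_csv_string(table: pd.DataFrame) -> str:
    buf = io.StringIO()
    write_trials(table, buf)
    return buf.getvalue()
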