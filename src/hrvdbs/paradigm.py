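"""Block-design stimulation schedules and Pre/On/Post epoching.

A session day runs four 30-min stimulation blocks separated by 90 min of
off time inside a 10:00-18:00 window.  For each block, three 3-min analysis
windows are taken: Pre (immediately before onset), On (end of the on
period, capturing the steady-state response) and Post (immediately after
offset).  Per-subject delta features contrast phases and aggregate over
blocks and stimulation-frequency days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg_rr import RRISeries, segment_quality
from .hrv_core import INDEX_NAMES, BandDefinition, compute_indices

__all__ = [
    "StimulationSchedule",
    "PhaseWindow",
    "PHASES",
    "build_schedule",
    "phase_windows",
    "extract_phase_segments",
    "phase_indices",
    "delta_features",
]

PHASES = ("Pre", "On", "Post")
STANDARD_FREQUENCIES = (25.0, 50.0, 100.0)


@dataclass
class StimulationSchedule:
    """On-blocks of one session day at a single stimulation frequency."""

    frequency: float  # Hz
    blocks: list[tuple[float, float]]  # (on_start, on_end) seconds
    day: str = ""

    def __post_init__(self) -> None:
        self.blocks = [(float(a), float(b)) for a, b in self.blocks]
        for a, b in self.blocks:
            if b <= a:
                raise ValueError(f"empty or inverted block ({a}, {b})")
        for (_, e0), (s1, _) in zip(self.blocks, self.blocks[1:]):
            if s1 < e0:
                raise ValueError("blocks must be chronological and non-overlapping")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def to_dict(self) -> dict:
        return {"frequency": self.frequency, "day": self.day,
                "blocks": [list(b) for b in self.blocks]}

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationSchedule":
        return cls(frequency=float(d["frequency"]),
                   blocks=[tuple(b) for b in d["blocks"]],
                   day=str(d.get("day", "")))


@dataclass(frozen=True)
class PhaseWindow:
    phase: str  # Pre | On | Post
    start: float  # seconds
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def build_schedule(
    day_start: float = 10 * 3600.0,
    frequency: float = 100.0,
    n_blocks: int = 4,
    on_s: float = 30 * 60.0,
    off_s: float = 90 * 60.0,
    day: str = "",
) -> StimulationSchedule:
    """Blocks at a fixed on+off pitch starting at ``day_start`` (seconds of day)."""
    if frequency not in STANDARD_FREQUENCIES:
        warnings.warn(
            f"non-standard stimulation frequency {frequency} Hz "
            f"(standard: {STANDARD_FREQUENCIES})", stacklevel=2,
        )
    if n_blocks != 4:
        warnings.warn(f"non-standard block count {n_blocks}", stacklevel=2)
    pitch = on_s + off_s
    blocks = [(day_start + i * pitch, day_start + i * pitch + on_s) for i in range(n_blocks)]
    return StimulationSchedule(frequency=frequency, blocks=blocks, day=day)


def phase_windows(
    block: tuple[float, float], duration: float = 180.0
) -> dict[str, PhaseWindow]:
    """Pre/On/Post windows for one block.

    Pre ends exactly at stimulation onset, On occupies the last ``duration``
    seconds of the on period, Post starts exactly at stimulation offset.
    """
    on_start, on_end = block
    if duration > on_end - on_start:
        raise ValueError("window duration exceeds the on period")
    return {
        "Pre": PhaseWindow("Pre", on_start - duration, on_start),
        "On": PhaseWindow("On", on_end - duration, on_end),
        "Post": PhaseWindow("Post", on_end, on_end + duration),
    }


def extract_phase_segments(
    rr: RRISeries,
    schedule: StimulationSchedule,
    duration: float = 180.0,
) -> list[dict[str, tuple[PhaseWindow, RRISeries | None, bool]]]:
    """Per-block Pre/On/Post RR segments with quality verdicts.

    A window not covered by the recording yields ``(window, None, False)``
    (missing) instead of raising.  Covered windows carry one padding beat on
    each side so downstream spline resampling never extrapolates.
    """
    out = []
    t0 = rr.beat_times[0] if len(rr) else np.inf
    t1 = rr.beat_times[-1] if len(rr) else -np.inf
    for block in schedule.blocks:
        windows = phase_windows(block, duration=duration)
        row: dict[str, tuple[PhaseWindow, RRISeries | None, bool]] = {}
        for phase, win in windows.items():
            if win.start < t0 - 3.0 or win.end > t1 + 3.0:
                row[phase] = (win, None, False)
                continue
            seg = rr.window(win.start, win.end, pad_beats=1)
            usable, _ = segment_quality(rr, win.start, win.end)
            row[phase] = (win, seg if len(seg) else None, usable and len(seg) > 0)
        out.append(row)
    return out


def phase_indices(
    cohort: dict[str, dict[str, tuple[RRISeries, StimulationSchedule]]],
    duration: float = 180.0,
    ar_order: int = 19,
    lam: float = 500.0,
    bands: BandDefinition = BandDefinition(),
) -> pd.DataFrame:
    """Tidy long table of HRV indices per (subject, day, block, phase).

    ``cohort`` maps subject -> day -> (RR series, schedule).  Unusable or
    missing segments contribute no rows (missing data stay missing).
    """
    rows = []
    for subject, days in cohort.items():
        for day, (rr, schedule) in days.items():
            segments = extract_phase_segments(rr, schedule, duration=duration)
            for block_idx, row in enumerate(segments):
                for phase in PHASES:
                    win, seg, usable = row[phase]
                    if not usable or seg is None:
                        continue
                    try:
                        idx = compute_indices(
                            seg, ar_order=ar_order, lam=lam, bands=bands,
                            start=win.start, end=win.end,
                        )
                    except ValueError:
                        continue
                    for name, value in idx.as_dict().items():
                        rows.append(
                            {
                                "subject": subject,
                                "day": day,
                                "frequency": schedule.frequency,
                                "block": block_idx,
                                "phase": phase,
                                "index": name,
                                "value": value,
                            }
                        )
    return pd.DataFrame(
        rows,
        columns=["subject", "day", "frequency", "block", "phase", "index", "value"],
    )


def delta_features(
    table: pd.DataFrame,
    contrast: str = "post_minus_pre",
    aggregate: str = "mean_over_frequencies",
) -> pd.DataFrame:
    """Per-subject delta features from a :func:`phase_indices` table.

    ``contrast`` is ``post_minus_pre`` (default) or ``on_minus_pre``; the
    block-level delta is averaged over each day's usable blocks, then either
    averaged across frequency days (8 features per subject) or kept per
    frequency (columns suffixed ``@<freq>``, 24 features).  Subjects with no
    usable block pair are dropped with a warning.
    """
    if contrast == "post_minus_pre":
        hi, lo = "Post", "Pre"
    elif contrast == "on_minus_pre":
        hi, lo = "On", "Pre"
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    if aggregate not in ("mean_over_frequencies", "per_frequency"):
        raise ValueError(f"unknown aggregate {aggregate!r}")

    wide = table.pivot_table(
        index=["subject", "frequency", "block"],
        columns=["index", "phase"],
        values="value",
        aggfunc="first",
    )
    deltas = {}
    for name in INDEX_NAMES:
        if (name, hi) in wide.columns and (name, lo) in wide.columns:
            deltas[name] = wide[(name, hi)] - wide[(name, lo)]
        else:
            deltas[name] = pd.Series(np.nan, index=wide.index)
    delta_df = pd.DataFrame(deltas)

    per_freq = delta_df.groupby(level=["subject", "frequency"]).mean()
    if aggregate == "mean_over_frequencies":
        feat = per_freq.groupby(level="subject").mean()
    else:
        feat = per_freq.unstack("frequency")
        feat.columns = [f"{name}@{freq:g}" for name, freq in feat.columns]

    dropped = feat.index[feat.isna().all(axis=1)]
    if len(dropped):
        warnings.warn(f"subjects dropped (no usable blocks): {list(dropped)}", stacklevel=2)
        feat = feat.drop(index=dropped)
    return feat
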