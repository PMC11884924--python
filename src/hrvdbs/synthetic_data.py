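"""Synthetic cohort generator with known autonomic spectral structure.

Beat trains come from an integral pulse frequency modulation (IPFM) model:
a beat is emitted whenever the running integral of ``(1 + m(t)) / T0``
crosses a successive integer, where ``m(t)`` carries a low-frequency and a
high-frequency sinusoid plus band-limited broadband noise.  Stimulation
effects are injected into the IPFM parameters over the scheduled on-blocks
(with a configurable carryover into the post period) so they propagate
through the true generative model.  A Mexican-hat QRS template turns beat
trains into synthetic ECG for exercising the detection front end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .ecg_rr import ECGRecord, RRISeries, write_ecg, write_rr
from .paradigm import StimulationSchedule, build_schedule

__all__ = [
    "IPFMParams",
    "EffectWindow",
    "FrequencyEffect",
    "EffectModel",
    "CohortSpec",
    "SubjectRecord",
    "Cohort",
    "simulate_rr_ipfm",
    "synthesize_ecg",
    "mexican_hat_template",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class IPFMParams:
    """Parameters of the IPFM beat generator.

    The modulation ``m(t) = a_LF sin(2 pi f_LF t + phase_LF)
    + a_HF sin(2 pi f_HF t + phase_HF) + noise + wander`` must keep the
    instantaneous rate positive: ``a_LF + a_HF + 3 (noise_sd + wander_sd)
    < 1``.  ``wander_sd`` drives a very-low-frequency baseline drift
    (below ~0.025 Hz): it contributes to SDNN but is removed by
    smoothness-priors detrending, so it leaves the analysis-band powers
    essentially untouched.
    """

    base_interval_T0: float = 1.0  # seconds (mean RR)
    a_LF: float = 0.05
    a_HF: float = 0.05
    f_LF: float = 0.095  # Hz, centred in the 0.04-0.15 band
    f_HF: float = 0.275  # Hz, centred in the 0.15-0.4 band
    phase_LF: float = 0.0
    phase_HF: float = 0.0
    noise_sd: float = 0.02
    wander_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_interval_T0 <= 0:
            raise ValueError("base_interval_T0 must be positive")
        if not (0 <= self.a_LF < 0.5 and 0 <= self.a_HF < 0.5):
            raise ValueError("modulation amplitudes must lie in [0, 0.5)")
        if self.noise_sd < 0 or self.wander_sd < 0:
            raise ValueError("noise_sd and wander_sd must be non-negative")
        if self.a_LF + self.a_HF + 3 * (self.noise_sd + self.wander_sd) >= 1:
            raise ValueError("a_LF + a_HF + 3*(noise_sd + wander_sd) must be < 1")
        if not (0.04 <= self.f_LF < 0.15):
            raise ValueError("f_LF must lie in [0.04, 0.15)")
        if not (0.15 <= self.f_HF < 0.4):
            raise ValueError("f_HF must lie in [0.15, 0.4)")


@dataclass(frozen=True)
class EffectWindow:
    """Piecewise parameter modifier active on [start, end) seconds."""

    start: float
    end: float
    delta_T0_ms: float = 0.0  # added to the base interval
    gain_LF: float = 1.0  # multiplies a_LF
    gain_HF: float = 1.0  # multiplies a_HF


@dataclass(frozen=True)
class FrequencyEffect:
    """Stimulation-locked effect at one stimulation frequency."""

    delta_mRRI: float = 0.0  # ms, applied during On
    gain_LF: float = 1.0
    gain_HF: float = 1.0

    def __post_init__(self) -> None:
        if self.gain_LF <= 0 or self.gain_HF <= 0:
            raise ValueError("gains must be positive")


def _default_effects() -> dict[float, FrequencyEffect]:
    # dose-ordered: mRRI down, LF up, HF down, all stronger at higher frequency
    return {
        25.0: FrequencyEffect(delta_mRRI=-20.0, gain_LF=1.3, gain_HF=0.9),
        50.0: FrequencyEffect(delta_mRRI=-40.0, gain_LF=1.7, gain_HF=0.75),
        100.0: FrequencyEffect(delta_mRRI=-60.0, gain_LF=2.1, gain_HF=0.6),
    }


@dataclass(frozen=True)
class EffectModel:
    """Per-frequency stimulation effects plus the outcome-group modifier.

    ``outcome_effect`` multiplies both spectral amplitudes for subjects in
    the improved group (amplitudes scale by its square root so band powers
    scale by the factor itself); applying the same factor to LF and HF
    leaves nLF/nHF/LF-HF unchanged, mirroring a response confined to the
    absolute powers.  ``carryover`` scales the effect persisting after
    stimulation offset for ``carryover_s`` seconds.
    """

    per_frequency: dict[float, FrequencyEffect] = field(default_factory=_default_effects)
    outcome_effect: float = 1.0
    carryover: float = 0.6
    carryover_s: float = 600.0

    def __post_init__(self) -> None:
        if self.outcome_effect <= 0:
            raise ValueError("outcome_effect must be positive")
        if not 0 <= self.carryover <= 1:
            raise ValueError("carryover must lie in [0, 1]")

    @classmethod
    def null(cls) -> "EffectModel":
        return cls(per_frequency={f: FrequencyEffect() for f in (25.0, 50.0, 100.0)})

    def windows(
        self, schedule: StimulationSchedule, improved: bool = False
    ) -> list[EffectWindow]:
        """Effect timeline for one session day."""
        eff = self.per_frequency.get(schedule.frequency, FrequencyEffect())
        pow_gain = self.outcome_effect if improved else 1.0
        amp_gain = float(np.sqrt(pow_gain))
        g_lf = 1.0 + (eff.gain_LF * amp_gain - 1.0)
        g_hf = 1.0 + (eff.gain_HF * amp_gain - 1.0)
        out = []
        for on_start, on_end in schedule.blocks:
            out.append(
                EffectWindow(on_start, on_end, eff.delta_mRRI, g_lf, g_hf)
            )
            c = self.carryover
            if c > 0 and self.carryover_s > 0:
                out.append(
                    EffectWindow(
                        on_end,
                        on_end + self.carryover_s,
                        c * eff.delta_mRRI,
                        1.0 + c * (g_lf - 1.0),
                        1.0 + c * (g_hf - 1.0),
                    )
                )
        return out


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 8
    n_improved: int = 3
    ipfm_defaults: IPFMParams = IPFMParams(wander_sd=0.1)
    effect: EffectModel = EffectModel()
    frequencies: tuple[float, ...] = (25.0, 50.0, 100.0)
    n_blocks: int = 4
    day_start: float = 10 * 3600.0
    ecg_sampling_rate: float = 500.0
    subject_variability: float = 0.05  # sd of per-subject log-scale jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.n_improved <= self.n_subjects:
            raise ValueError("n_improved must lie in [0, n_subjects]")
        if self.ecg_sampling_rate < 100:
            raise ValueError("ecg_sampling_rate must be >= 100 Hz")


@dataclass
class SubjectRecord:
    subject_id: str
    improved: bool
    crs_r_baseline: int
    crs_r_followup: int
    days: dict[str, tuple[RRISeries, StimulationSchedule]]  # day label -> data


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SubjectRecord]

    def rr_map(self) -> dict[str, dict[str, tuple[RRISeries, StimulationSchedule]]]:
        return {s.subject_id: s.days for s in self.subjects}

    def labels(self) -> dict[str, bool]:
        return {s.subject_id: s.improved for s in self.subjects}


def amplitudes_for_band_ratio(
    target_lf_hf: float,
    a_HF: float = 0.04,
    f_LF: float = 0.095,
    f_HF: float = 0.275,
    T0: float = 1.0,
) -> tuple[float, float]:
    """Modulation amplitudes whose RR spectrum has a given LF/HF ratio.

    Beat-by-beat sampling of the modulation attenuates each tone roughly by
    ``sinc(f T0)`` in amplitude, so the naive ``sqrt(ratio)`` amplitude rule
    is corrected by the sinc factors before the generator is parameterized.
    """
    h_lf = float(np.sinc(f_LF * T0))
    h_hf = float(np.sinc(f_HF * T0))
    a_LF = a_HF * np.sqrt(target_lf_hf) * h_hf / h_lf
    return float(a_LF), float(a_HF)


# ---------------------------------------------------------------------------
# IPFM generator


def _modulation(
    params: IPFMParams,
    t: np.ndarray,
    rng: np.random.Generator,
    effect_timeline: list[EffectWindow] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous modulation m(t) and base interval T0(t) on the grid."""
    g_lf = np.ones_like(t)
    g_hf = np.ones_like(t)
    t0 = np.full_like(t, params.base_interval_T0)
    for w in effect_timeline or []:
        mask = (t >= w.start) & (t < w.end)
        g_lf[mask] = w.gain_LF
        g_hf[mask] = w.gain_HF
        t0[mask] = params.base_interval_T0 + w.delta_T0_ms / 1000.0
    m = g_lf * params.a_LF * np.sin(2 * np.pi * params.f_LF * t + params.phase_LF)
    m += g_hf * params.a_HF * np.sin(2 * np.pi * params.f_HF * t + params.phase_HF)
    if params.noise_sd > 0:
        # band-limited broadband noise: white at 4 Hz, linearly interpolated
        n_coarse = int(np.ceil((t[-1] - t[0]) * 4.0)) + 2
        coarse_t = t[0] + np.arange(n_coarse) / 4.0
        coarse = rng.standard_normal(n_coarse) * params.noise_sd
        m += np.interp(t, coarse_t, coarse)
    if params.wander_sd > 0:
        # very-low-frequency drift: white at 0.05 Hz, linearly interpolated
        n_coarse = int(np.ceil((t[-1] - t[0]) * 0.05)) + 2
        coarse_t = t[0] + np.arange(n_coarse) / 0.05
        coarse = rng.standard_normal(n_coarse) * params.wander_sd
        m += np.interp(t, coarse_t, coarse)
    return m, t0


def simulate_rr_ipfm(
    params: IPFMParams,
    duration: float,
    effect_timeline: list[EffectWindow] | None = None,
    t_start: float = 0.0,
    dt: float = 0.01,
    rng: np.random.Generator | None = None,
) -> RRISeries:
    """Simulate a beat train by integral pulse frequency modulation.

    Beats are emitted when the running integral of ``(1 + m(t)) / T0(t)``
    crosses successive integers; crossing times are located by linear
    interpolation of the cumulative integral on a ``dt`` grid (sub-ms
    accuracy for physiological modulation rates).
    """
    if duration <= 10 * params.base_interval_T0:
        raise ValueError("duration must exceed 10 base intervals")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = int(np.ceil(duration / dt)) + 1
    t = t_start + np.arange(n) * dt
    m, t0 = _modulation(params, t, rng, effect_timeline)
    rate = (1.0 + m) / t0
    integral = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0) * dt])
    n_beats = int(np.floor(integral[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    idx = np.searchsorted(integral, targets)
    frac = (targets - integral[idx - 1]) / (integral[idx] - integral[idx - 1])
    beat_times = t[idx - 1] + frac * dt
    return RRISeries.from_beat_times(beat_times)


# ---------------------------------------------------------------------------
# ECG synthesis


def mexican_hat_template(
    sampling_rate: float, width_s: float = 0.08, amplitude: float = 1.0
) -> np.ndarray:
    """Second Gaussian derivative QRS stand-in of total width ``width_s``."""
    half = width_s / 2.0
    t = np.arange(-half, half + 1.0 / sampling_rate / 2, 1.0 / sampling_rate)
    sigma = width_s / 8.0
    shape = (1.0 - (t / sigma) ** 2) * np.exp(-(t**2) / (2 * sigma**2))
    return amplitude * shape


def synthesize_ecg(
    rr: RRISeries,
    sampling_rate: float = 500.0,
    qrs_template: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    subject_id: str = "",
) -> ECGRecord:
    """One QRS template instance centred at each beat time, plus noise."""
    if sampling_rate < 100:
        raise ValueError("sampling_rate must be >= 100 Hz")
    if qrs_template is None:
        qrs_template = mexican_hat_template(sampling_rate)
    qrs_template = np.asarray(qrs_template, dtype=float)
    if rr.beat_times.size == 0:
        return ECGRecord(np.zeros(0), sampling_rate, 0.0, subject_id)
    if len(rr) and qrs_template.size / sampling_rate * 1000.0 > rr.intervals.min():
        raise ValueError("QRS template longer than the shortest RR interval")

    margin = qrs_template.size / sampling_rate
    start = rr.beat_times[0] - margin
    end = rr.beat_times[-1] + margin
    n = int(np.ceil((end - start) * sampling_rate)) + 1
    samples = np.zeros(n)
    half = qrs_template.size // 2
    centers = np.round((rr.beat_times - start) * sampling_rate).astype(int)
    for c in centers:
        lo = c - half
        hi = lo + qrs_template.size
        samples[max(lo, 0) : min(hi, n)] += qrs_template[
            max(-lo, 0) : qrs_template.size - max(hi - n, 0)
        ]
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        samples = samples + rng.standard_normal(n) * noise_sd
    return ECGRecord(samples, sampling_rate, start, subject_id)


# ---------------------------------------------------------------------------
# Cohort simulation


def _simulate_day(
    params: IPFMParams,
    schedule: StimulationSchedule,
    effects: list[EffectWindow],
    rng: np.random.Generator,
    margin_s: float = 420.0,
    dt: float = 0.01,
) -> RRISeries:
    """RR series covering each block's analysis span, chunk by chunk.

    Off-time between blocks (beyond ``margin_s`` around each on period) is
    not simulated; the analysis windows never reach into those gaps.
    """
    beat_times: list[np.ndarray] = []
    for on_start, on_end in schedule.blocks:
        t0 = on_start - margin_s
        dur = (on_end + margin_s) - t0
        chunk = simulate_rr_ipfm(
            params, dur, effect_timeline=effects, t_start=t0, dt=dt, rng=rng
        )
        beat_times.append(chunk.beat_times)
    return RRISeries.from_beat_times(np.concatenate(beat_times))


def simulate_cohort(spec: CohortSpec, include_ecg: bool = False) -> Cohort:
    """Deterministically simulate a full cohort from its spec and seed.

    The first ``n_improved`` subjects (by index) are assigned to the
    improved outcome group; their follow-up CRS-R gain is drawn from
    [3, 6] and everyone else's from [0, 2], so exactly ``n_improved``
    subjects cross the 3-point responder threshold.
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    subjects = []
    for i in range(spec.n_subjects):
        improved = i < spec.n_improved
        sub_rng = np.random.default_rng(subject_seeds[i])
        jitter = float(np.exp(spec.subject_variability * sub_rng.standard_normal()))
        phase_lf, phase_hf = sub_rng.uniform(0, 2 * np.pi, size=2)
        params = replace(
            spec.ipfm_defaults,
            base_interval_T0=spec.ipfm_defaults.base_interval_T0 * jitter,
            phase_LF=float(phase_lf),
            phase_HF=float(phase_hf),
        )
        days = {}
        for freq in spec.frequencies:
            schedule = build_schedule(
                day_start=spec.day_start, frequency=freq,
                n_blocks=spec.n_blocks, day=f"{freq:g}Hz",
            )
            effects = spec.effect.windows(schedule, improved=improved)
            rr = _simulate_day(params, schedule, effects, sub_rng)
            days[schedule.day] = (rr, schedule)
        baseline = int(sub_rng.integers(5, 11))
        gain = int(sub_rng.integers(3, 7)) if improved else int(sub_rng.integers(0, 3))
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:02d}",
                improved=improved,
                crs_r_baseline=baseline,
                crs_r_followup=min(baseline + gain, 23),
                days=days,
            )
        )
    cohort = Cohort(spec=spec, subjects=subjects)
    if include_ecg:
        for sub in cohort.subjects:
            ecg_rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 7, int(sub.subject_id[1:])])
            )
            for day, (rr, schedule) in sub.days.items():
                sub.__dict__.setdefault("ecg", {})[day] = synthesize_ecg(
                    rr, spec.ecg_sampling_rate, noise_sd=0.05,
                    rng=ecg_rng, subject_id=sub.subject_id,
                )
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path, include_ecg: bool = False) -> Path:
    """Write RR files, schedules, outcome labels and the spec to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = []
    for sub in cohort.subjects:
        sdir = out_dir / sub.subject_id
        sdir.mkdir(exist_ok=True)
        for day, (rr, schedule) in sub.days.items():
            write_rr(rr, sdir / f"rr_{day}.csv")
            (sdir / f"schedule_{day}.yaml").write_text(yaml.safe_dump(schedule.to_dict()))
            ecg = getattr(sub, "ecg", {}).get(day) if include_ecg else None
            if ecg is not None:
                write_ecg(ecg, sdir / f"ecg_{day}.csv")
        labels.append(
            {
                "subject": sub.subject_id,
                "crs_r_baseline": sub.crs_r_baseline,
                "crs_r_followup": sub.crs_r_followup,
                "improved": sub.improved,
            }
        )
    import pandas as pd  # local: keep module import surface small

    pd.DataFrame(labels).to_csv(out_dir / "labels.csv", index=False)
    (out_dir / "cohort_spec.json").write_text(
        json.dumps(
            {
                "n_subjects": cohort.spec.n_subjects,
                "n_improved": cohort.spec.n_improved,
                "frequencies": list(cohort.spec.frequencies),
                "seed": cohort.spec.seed,
            },
            indent=2,
        )
    )
    return out_dir
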