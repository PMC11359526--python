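"""Synthetic cohorts of wearable stress recordings.

Generates multi-channel (EDA in microsiemens, skin temperature in deg C)
4 Hz recordings of laboratory stress sessions: 10 audio stressors at random
inter-stimulus intervals, phasic skin-conductance responses (SCRs) with
latency/rise/recovery structure, non-responder subjects, spurious
between-stimulus peaks, tonic drift and measurement noise.  Every recording
carries its stimulus protocol so the ground truth is available downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Seconds of relaxation before the first stressor may occur.
BASELINE_S = 60.0

#: Device sampling rate (Hz).
RAW_RATE_HZ = 4.0

__all__ = [
    "BASELINE_S",
    "RAW_RATE_HZ",
    "StimulusProtocol",
    "SubjectPhenotype",
    "PhenotypeRanges",
    "Recording",
    "gen_protocol",
    "gen_scr_kernel",
    "gen_recording",
    "gen_cohort",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Ground-truth stressor schedule of one session."""

    session_duration: float  # seconds
    stressor_times: tuple[float, ...]  # seconds from session start, increasing

    def __post_init__(self) -> None:
        times = np.asarray(self.stressor_times, dtype=float)
        if times.size and not np.all(np.diff(times) > 0):
            raise ValueError("stressor_times must be strictly increasing")
        if times.size and (times[0] < BASELINE_S or times[-1] > self.session_duration):
            raise ValueError(
                "stressor_times must lie within "
                f"[{BASELINE_S}, {self.session_duration}]"
            )

    @property
    def n_stressors(self) -> int:
        return len(self.stressor_times)

    def to_json(self, subject_id: str = "") -> str:
        return json.dumps(
            {
                "subject_id": subject_id,
                "session_duration_s": self.session_duration,
                "stressor_times_s": list(self.stressor_times),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusProtocol":
        obj = json.loads(text)
        return cls(
            session_duration=float(obj["session_duration_s"]),
            stressor_times=tuple(float(t) for t in obj["stressor_times_s"]),
        )


@dataclass(frozen=True)
class SubjectPhenotype:
    """Per-subject signal-generation parameters.

    ``responder_prob`` is the probability that a stressor elicits an SCR
    (non-responders have values well below 1); ``spurious_rate`` places
    stimulus-unrelated SCRs as a Poisson process (events per minute).
    """

    responder_prob: float = 1.0
    scr_amplitude: float = 1.0  # microsiemens
    scr_latency: float = 1.5  # seconds
    scr_rise: float = 2.5  # seconds
    scr_recovery: float = 3.0  # seconds
    spurious_rate: float = 0.0  # events / minute
    tonic_level: float = 2.0  # microsiemens
    tonic_drift: float = 0.0  # microsiemens / minute
    st_baseline: float = 33.0  # deg C
    st_response_slope: float = 0.0  # deg C / s, effect size of stress on ST
    noise_sd: float = 0.0  # signal units

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_prob <= 1.0:
            raise ValueError("responder_prob must be in [0, 1]")
        for name in ("scr_latency", "scr_rise", "scr_recovery"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class PhenotypeRanges:
    """Uniform sampling ranges, one ``(lo, hi)`` pair per phenotype field.

    A degenerate pair ``(v, v)`` pins the field to ``v``.
    """

    responder_prob: tuple[float, float] = (1.0, 1.0)
    scr_amplitude: tuple[float, float] = (0.6, 1.4)
    scr_latency: tuple[float, float] = (1.0, 2.0)
    scr_rise: tuple[float, float] = (2.0, 3.0)
    scr_recovery: tuple[float, float] = (2.5, 4.0)
    spurious_rate: tuple[float, float] = (0.0, 0.0)
    tonic_level: tuple[float, float] = (1.0, 4.0)
    tonic_drift: tuple[float, float] = (0.0, 0.0)
    st_baseline: tuple[float, float] = (32.0, 34.0)
    st_response_slope: tuple[float, float] = (0.0, 0.0)
    noise_sd: tuple[float, float] = (0.0, 0.0)
    session_duration: tuple[float, float] = (900.0, 1320.0)  # 15 to 22 min

    def sample(self, rng: np.random.Generator) -> tuple[SubjectPhenotype, float]:
        values = {}
        for f in dataclasses.fields(self):
            lo, hi = getattr(self, f.name)
            if lo > hi:
                raise ValueError(f"empty range for {f.name}: ({lo}, {hi})")
            values[f.name] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        duration = values.pop("session_duration")
        return SubjectPhenotype(**values), duration


@dataclass(frozen=True)
class Recording:
    """One subject's raw multi-channel trace plus its stimulus protocol."""

    subject_id: str
    sampling_rate: float  # Hz
    eda: np.ndarray  # microsiemens
    st: np.ndarray  # deg C
    protocol: StimulusProtocol
    # ground-truth bookkeeping, used only by tests and the manifest
    responded_times: tuple[float, ...] = field(default=())
    spurious_times: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        n_expected = int(round(self.protocol.session_duration * self.sampling_rate))
        if len(self.eda) != len(self.st):
            raise ValueError("eda and st must have identical length")
        if len(self.eda) != n_expected:
            raise ValueError(
                f"signal length {len(self.eda)} != "
                f"session_duration * sampling_rate = {n_expected}"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.eda)) / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "eda_uS": self.eda, "st_C": self.st}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, protocol: StimulusProtocol, subject_id: str = "") -> "Recording":
        df = pd.read_csv(path)
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
        return cls(
            subject_id=subject_id,
            sampling_rate=1.0 / dt,
            eda=df["eda_uS"].to_numpy(dtype=float),
            st=df["st_C"].to_numpy(dtype=float),
            protocol=protocol,
        )


def gen_protocol(
    duration: float,
    n_stressors: int = 10,
    gap_min: float = 52.0,
    gap_max: float = 125.0,
    rng_seed: int | np.random.Generator = 0,
    baseline_s: float = BASELINE_S,
) -> StimulusProtocol:
    """Draw a stressor schedule with i.i.d. uniform inter-stimulus gaps.

    The first stressor falls at ``baseline_s`` plus one gap draw; consecutive
    gaps are drawn uniformly from ``[gap_min, gap_max]``.  Sequences whose
    last stressor would overrun ``duration`` are rejected and redrawn, which
    leaves the per-gap distribution essentially uniform for feasible
    configurations.
    """
    if n_stressors < 1:
        raise ValueError("n_stressors must be >= 1")
    if not gap_min < gap_max:
        raise ValueError("gap_min must be < gap_max")
    min_duration = baseline_s + n_stressors * gap_min
    if duration < min_duration:
        raise ValueError(
            f"duration {duration} s cannot hold {n_stressors} stressors; "
            f"minimum required duration is {min_duration} s"
        )
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, int) else rng_seed
    for _ in range(10_000):
        gaps = rng.uniform(gap_min, gap_max, size=n_stressors)
        times = baseline_s + np.cumsum(gaps)
        if times[-1] <= duration:
            return StimulusProtocol(
                session_duration=float(duration),
                stressor_times=tuple(float(t) for t in times),
            )
    raise ValueError(
        f"could not place {n_stressors} stressors with gaps in "
        f"[{gap_min}, {gap_max}] inside {duration} s after 10000 attempts"
    )


def gen_scr_kernel(
    latency: float,
    rise: float,
    recovery: float,
    amplitude: float,
    sampling_rate: float = RAW_RATE_HZ,
    n_recovery_constants: float = 4.0,
) -> np.ndarray:
    """Canonical skin-conductance-response waveform on a sampling grid.

    Zero until ``latency``, smooth monotone (raised-cosine) rise to the
    single peak at ``latency + rise``, then exponential decay with time
    constant ``recovery``.  Normalized so the sampled maximum equals
    ``amplitude`` exactly.
    """
    for name, v in (("latency", latency), ("rise", rise), ("recovery", recovery)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    support = latency + rise + n_recovery_constants * recovery
    t = np.arange(int(np.ceil(support * sampling_rate)) + 1) / sampling_rate
    w = np.zeros_like(t)
    rising = (t >= latency) & (t <= latency + rise)
    w[rising] = 0.5 * (1.0 - np.cos(np.pi * (t[rising] - latency) / rise))
    decaying = t > latency + rise
    w[decaying] = np.exp(-(t[decaying] - latency - rise) / recovery)
    if amplitude == 0.0:
        return np.zeros_like(w)
    return w * (amplitude / w.max())


def _add_kernel(signal: np.ndarray, kernel: np.ndarray, onset_idx: int) -> None:
    stop = min(onset_idx + len(kernel), len(signal))
    if stop > onset_idx >= 0:
        signal[onset_idx:stop] += kernel[: stop - onset_idx]


def gen_recording(
    protocol: StimulusProtocol,
    phenotype: SubjectPhenotype,
    rng_seed: int | np.random.Generator = 0,
    subject_id: str = "S00",
    sampling_rate: float = RAW_RATE_HZ,
) -> Recording:
    """Synthesize one subject's EDA/ST trace for a stimulus protocol.

    EDA = tonic level + linear drift + one SCR per responded stressor +
    Poisson-placed spurious SCRs + white Gaussian noise.  ST = baseline +
    a small post-stressor slope excursion (zero by default) + noise.
    """
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, int) else rng_seed
    n = int(round(protocol.session_duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    p = phenotype

    eda = p.tonic_level + p.tonic_drift * (t / 60.0)
    kernel = gen_scr_kernel(p.scr_latency, p.scr_rise, p.scr_recovery,
                            p.scr_amplitude, sampling_rate)

    responded = []
    for ts in protocol.stressor_times:
        if rng.uniform() < p.responder_prob:
            responded.append(ts)
            _add_kernel(eda, kernel, int(round(ts * sampling_rate)))

    # spurious SCRs: homogeneous Poisson process over the session
    spurious = []
    n_spurious = rng.poisson(p.spurious_rate * protocol.session_duration / 60.0)
    if n_spurious:
        sp_times = np.sort(rng.uniform(0.0, protocol.session_duration, n_spurious))
        sp_kernel = gen_scr_kernel(p.scr_latency, p.scr_rise, p.scr_recovery,
                                   0.7 * p.scr_amplitude if p.scr_amplitude > 0 else 0.0,
                                   sampling_rate)
        for ts in sp_times:
            spurious.append(float(ts))
            _add_kernel(eda, sp_kernel, int(round(ts * sampling_rate)))

    st = np.full(n, p.st_baseline, dtype=float)
    if p.st_response_slope != 0.0:
        # triangular excursion: ramp over the 16 s analysis horizon, then back
        ramp_s = 16.0
        half = int(round(ramp_s * sampling_rate))
        exc = np.concatenate([
            np.arange(half) / sampling_rate,
            np.maximum(ramp_s - np.arange(half + 1) / sampling_rate, 0.0),
        ]) * p.st_response_slope
        for ts in protocol.stressor_times:
            _add_kernel(st, exc, int(round(ts * sampling_rate)))

    if p.noise_sd > 0:
        eda = eda + rng.normal(0.0, p.noise_sd, n)
        st = st + rng.normal(0.0, p.noise_sd, n)

    return Recording(
        subject_id=subject_id,
        sampling_rate=sampling_rate,
        eda=eda,
        st=st,
        protocol=protocol,
        responded_times=tuple(responded),
        spurious_times=tuple(spurious),
    )


def gen_cohort(
    n_subjects: int = 28,
    phenotype_ranges: PhenotypeRanges | None = None,
    rng_seed: int = 0,
    n_stressors: int = 10,
    gap_min: float = 52.0,
    gap_max: float = 125.0,
) -> tuple[list[Recording], list[dict]]:
    """Generate a cohort of recordings with per-subject phenotype draws.

    Returns ``(recordings, manifest)`` where the manifest lists each
    subject's true phenotype, session duration and child seed — enough to
    reproduce any single recording in isolation.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ranges = phenotype_ranges or PhenotypeRanges()
    root = np.random.SeedSequence(rng_seed)
    children = root.spawn(n_subjects)

    recordings: list[Recording] = []
    manifest: list[dict] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        phenotype, duration = ranges.sample(rng)
        duration = float(round(duration))
        subject_id = f"S{i:02d}"
        protocol = gen_protocol(duration, n_stressors, gap_min, gap_max, rng_seed=rng)
        rec = gen_recording(protocol, phenotype, rng_seed=rng, subject_id=subject_id)
        recordings.append(rec)
        manifest.append(
            {
                "subject_id": subject_id,
                "seed_spawn_key": list(child.spawn_key),
                "root_seed": rng_seed,
                "session_duration_s": duration,
                "phenotype": dataclasses.asdict(phenotype),
                "stressor_times_s": list(protocol.stressor_times),
            }
        )
    return recordings, manifest


def easy_ranges(noise_sd: float = 0.02) -> PhenotypeRanges:
    """Fully responding, spurious-free cohort with mild measurement noise."""
    return PhenotypeRanges(
        responder_prob=(1.0, 1.0),
        spurious_rate=(0.0, 0.0),
        noise_sd=(noise_sd, noise_sd),
    )


def hard_ranges(responder_prob: float = 0.4, spurious_per_min: float = 0.5,
                noise_sd: float = 0.05) -> PhenotypeRanges:
    """Non-responder phenotype: most stressors leave no trace in the signal."""
    return PhenotypeRanges(
        responder_prob=(responder_prob, responder_prob),
        spurious_rate=(spurious_per_min, spurious_per_min),
        noise_sd=(noise_sd, noise_sd),
    )


def save_cohort(recordings: Sequence[Recording], manifest: list[dict], outdir) -> None:
    """Write per-subject CSV + protocol JSON and the cohort manifest."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        rec.to_csv(out / f"{rec.subject_id}.csv")
        (out / f"{rec.subject_id}.protocol.json").write_text(
            rec.protocol.to_json(rec.subject_id)
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
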