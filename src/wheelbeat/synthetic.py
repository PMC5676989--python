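"""Synthetic driving-style ECG with ground truth.

Real steering-wheel ECG collections are not publicly available, so this
module provides the data the rest of the pipeline is developed and tested
against: multi-subject single-lead ECG with per-subject morphology, heart
rate variability, and the contaminations characteristic of in-vehicle
acquisition — baseline wander, 50 Hz powerline pickup, broadband (EMG-like)
noise, amplifier-saturation episodes and contact-loss gaps.

The clean generator follows the well-known limit-cycle dynamical ECG model
(three coupled ODEs whose attractor is the unit circle, with the P-QRS-T
waves produced by Gaussian angular events).  On the attractor the (x, y)
subsystem reduces exactly to a phase variable theta(t) advancing at the
instantaneous angular heart rate, and the z (voltage) equation becomes a
linear first-order ODE driven by a known forcing; we integrate that
reduction with an exponential-Euler recursion, which is fast, exact in the
relaxation term, and bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "SubjectMorphology",
    "NoiseProfile",
    "AnnotatedStream",
    "simulate_clean_ecg",
    "contaminate",
    "simulate_cohort",
    "draw_morphology",
    "write_stream_csv",
]

_WAVES = ("P", "Q", "R", "S", "T")

# Textbook Lead-I-like defaults: event angles (radians, R at 0), Gaussian
# angular widths (radians) and peak amplitudes (mV).
_DEF_ANGLES = np.deg2rad([-70.0, -15.0, 0.0, 15.0, 100.0])
_DEF_WIDTHS = np.array([0.25, 0.10, 0.10, 0.10, 0.40])
_DEF_AMPS = np.array([0.12, -0.10, 1.00, -0.15, 0.30])


@dataclass(frozen=True)
class SubjectMorphology:
    """Per-subject wave geometry and heart-rate statistics.

    Parameters
    ----------
    amplitudes : peak amplitude of each of the P, Q, R, S, T waves, mV.
    widths : Gaussian angular width of each wave, radians.
    angles : angular position of each wave within one cycle (R at 0), radians;
        must be strictly increasing.
    mean_hr_bpm : mean heart rate, beats per minute, in [40, 180].
    hrv : fractional standard deviation of the beat-to-beat (RR) interval.
    """

    amplitudes: tuple[float, ...] = tuple(_DEF_AMPS)
    widths: tuple[float, ...] = tuple(_DEF_WIDTHS)
    angles: tuple[float, ...] = tuple(_DEF_ANGLES)
    mean_hr_bpm: float = 70.0
    hrv: float = 0.05

    def __post_init__(self) -> None:
        if not (len(self.amplitudes) == len(self.widths) == len(self.angles) == 5):
            raise ValueError("morphology needs exactly five (P,Q,R,S,T) waves")
        if self.amplitudes[2] <= 0:
            raise ValueError("R amplitude must be positive")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("wave angles must be strictly increasing")
        if not 40.0 <= self.mean_hr_bpm <= 180.0:
            raise ValueError("mean heart rate must lie in [40, 180] bpm")
        if any(w <= 0 for w in self.widths):
            raise ValueError("wave widths must be positive")
        if self.hrv < 0:
            raise ValueError("hrv must be non-negative")


@dataclass(frozen=True)
class NoiseProfile:
    """Contamination model for in-vehicle acquisition.

    Amplitudes are in mV; event rates in events/min; durations are the means
    of exponential duration distributions, in seconds.  ``sat_rail_mv`` is
    the amplifier rail: the recorded signal can never exceed it in absolute
    value, and saturation episodes pin the signal to it with a slow
    exponential recovery afterwards.
    """

    baseline_mv: float = 0.2
    baseline_cutoff_hz: float = 0.5
    powerline_mv: float = 0.05
    powerline_hz: float = 50.0
    broadband_sd_mv: float = 0.05
    sat_rate_per_min: float = 2.0
    sat_mean_duration_s: float = 1.0
    sat_rail_mv: float = 2.5
    sat_recovery_s: float = 0.5
    loss_rate_per_min: float = 2.0
    loss_mean_duration_s: float = 2.0

    def __post_init__(self) -> None:
        for name in ("baseline_mv", "powerline_mv", "broadband_sd_mv",
                     "sat_rate_per_min", "sat_mean_duration_s",
                     "loss_rate_per_min", "loss_mean_duration_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sat_rail_mv <= 0:
            raise ValueError("sat_rail_mv must be positive")
        if not 0 < self.baseline_cutoff_hz < 1.0:
            raise ValueError("baseline_cutoff_hz must lie in (0, 1) Hz")

    @classmethod
    def silent(cls) -> "NoiseProfile":
        """A profile that leaves the signal untouched."""
        return cls(baseline_mv=0.0, powerline_mv=0.0, broadband_sd_mv=0.0,
                   sat_rate_per_min=0.0, loss_rate_per_min=0.0)


@dataclass
class AnnotatedStream:
    """A simulated recording with full ground truth.

    ``noisy`` is what an acquisition device would record; ``clean`` the
    noise-free reference; ``rpeaks`` the true R-peak sample indices (only
    those inside lead-on runs); ``mask`` the per-sample lead-on indicator.
    """

    noisy: np.ndarray
    clean: np.ndarray
    fs: float
    rpeaks: np.ndarray
    mask: np.ndarray
    subject: str = "S0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.noisy = np.asarray(self.noisy, dtype=float)
        self.clean = np.asarray(self.clean, dtype=float)
        self.rpeaks = np.asarray(self.rpeaks, dtype=int)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.noisy.shape == self.clean.shape == self.mask.shape):
            raise ValueError("noisy, clean and mask must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.rpeaks.size and np.any(np.diff(self.rpeaks) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")
        if self.rpeaks.size and not self.mask[self.rpeaks].all():
            raise ValueError("every R-peak must lie inside a lead-on run")

    @property
    def is_clean(self) -> bool:
        return bool(np.array_equal(self.noisy, self.clean))

    def to_stream(self):
        from wheelbeat.stream_prep import EcgStream

        return EcgStream(samples=self.noisy, fs=self.fs, mask=self.mask)


def _rr_series(morph: SubjectMorphology, n_beats: int, rng: np.random.Generator
               ) -> np.ndarray:
    """Beat-to-beat intervals (s) with Mayer-wave and respiratory modulation."""
    rr_mean = 60.0 / morph.mean_hr_bpm
    t = np.cumsum(np.full(n_beats, rr_mean)) - rr_mean
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    # two oscillatory components (~0.1 Hz sympathetic, ~0.25 Hz respiratory)
    # plus white jitter; combined to unit variance before scaling by hrv
    mod = (np.sin(2 * np.pi * 0.1 * t + ph1)
           + np.sin(2 * np.pi * 0.25 * t + ph2)) / np.sqrt(1.0)
    mod = 0.9 * mod + 0.45 * rng.standard_normal(n_beats)
    rr = rr_mean * (1.0 + morph.hrv * mod)
    return np.clip(rr, 60.0 / 180.0 / 1.1, 60.0 / 40.0 * 1.1)


def simulate_clean_ecg(morph: SubjectMorphology, duration: float, fs: float,
                       seed: int, subject: str = "S0") -> AnnotatedStream:
    """Simulate a clean single-lead ECG with ground-truth R-peaks.

    Integrates the limit-cycle model on its attractor: the phase advances at
    2*pi / RR(t) and the voltage obeys ``dz/dt = F(theta) - z`` where F is a
    sum of Gaussian-derivative angular events.  Event gains are rescaled per
    beat so that ``morph.amplitudes`` are realised in mV regardless of heart
    rate.  A 2 s burn-in absorbs the initial transient.

    Returns an :class:`AnnotatedStream` with ``noisy == clean``.
    """
    if duration <= 2.0:
        raise ValueError("duration must exceed 2 s")
    if fs < 250.0:
        raise ValueError("sampling rate must be at least 250 Hz")
    rng = np.random.default_rng(seed)
    burn = 2.0
    total = duration + burn
    n = int(round(total * fs))
    dt = 1.0 / fs

    n_beats = int(np.ceil(total * morph.mean_hr_bpm / 60.0 * 1.5)) + 4
    rr = _rr_series(morph, n_beats, rng)
    beat_edges = np.concatenate([[0.0], np.cumsum(rr)])  # phase = -pi here

    t = np.arange(n) * dt
    # unwrapped phase: phi(beat_edges[k]) = 2*pi*k - pi, R-peaks at phi = 2*pi*k
    k = np.searchsorted(beat_edges, t, side="right") - 1
    phi = 2 * np.pi * k - np.pi + 2 * np.pi * (t - beat_edges[k]) / rr[k]
    omega = 2 * np.pi / rr[k]

    amps = np.asarray(morph.amplitudes)
    widths = np.asarray(morph.widths)
    angles = np.asarray(morph.angles)
    forcing = np.zeros(n)
    for a, b, th in zip(amps, widths, angles):
        dth = np.mod(phi - th + np.pi, 2 * np.pi) - np.pi
        # gain a*omega/b^2 makes the integrated bump peak ~= a (mV)
        forcing += -(a * omega / b**2) * dth * np.exp(-dth**2 / (2 * b**2))

    # exponential-Euler for dz/dt = forcing - z
    decay = np.exp(-dt)
    z = sps.lfilter([1.0 - decay], [1.0, -decay], forcing)

    i0 = int(round(burn * fs))
    z = z[i0:i0 + int(round(duration * fs))]
    nz = z.size

    # R-peaks sit at phase 0, i.e. mid-beat between consecutive edges
    r_times = beat_edges[:-1] + rr / 2.0 - burn
    half = int(round(0.04 * fs))
    rpeaks = []
    for rt in r_times:
        idx = int(round(rt * fs))
        if idx - half < 0 or idx + half + 1 > nz:
            continue
        w = z[idx - half:idx + half + 1]
        rpeaks.append(idx - half + int(np.argmax(w)))
    rpeaks = np.asarray(sorted(set(rpeaks)), dtype=int)

    return AnnotatedStream(
        noisy=z.copy(), clean=z, fs=fs, rpeaks=rpeaks,
        mask=np.ones(nz, dtype=bool), subject=subject,
        meta={"seed": int(seed), "duration_s": float(duration)},
    )


def _episodes(rate_per_min: float, mean_dur_s: float, total_s: float,
              rng: np.random.Generator) -> list[tuple[float, float]]:
    """Poisson-process episode (start, duration) pairs within [0, total_s)."""
    lam = rate_per_min * total_s / 60.0
    count = rng.poisson(lam)
    out = []
    for _ in range(count):
        start = rng.uniform(0.0, total_s)
        dur = rng.exponential(mean_dur_s)
        out.append((start, dur))
    return sorted(out)


def contaminate(stream: AnnotatedStream, noise: NoiseProfile, seed: int,
                sat_episodes: list[tuple[float, float]] | None = None,
                loss_episodes: list[tuple[float, float]] | None = None,
                ) -> AnnotatedStream:
    """Contaminate a clean stream with the driving-noise model.

    Adds baseline wander (lowpass-filtered noise below ``baseline_cutoff_hz``),
    powerline pickup, broadband noise, amplifier-saturation episodes (signal
    pinned at the rail, then exponential recovery with time constant
    ``sat_recovery_s``) and contact-loss gaps (lead-on mask cleared).  The
    whole record is clipped at the rail, as a real front-end would.

    ``sat_episodes`` / ``loss_episodes`` override the Poisson draws with
    explicit (start_s, duration_s) lists, which the tests use for exact
    bookkeeping.  The ``clean`` reference and ground-truth R-peaks are
    preserved; R-peaks falling inside a contact-loss gap are dropped (they
    are unobservable).
    """
    if not stream.is_clean:
        raise ValueError("contaminate expects a clean stream (noisy == clean)")
    rng = np.random.default_rng(seed)
    fs = stream.fs
    n = stream.clean.size
    total_s = n / fs
    t = np.arange(n) / fs
    x = stream.clean.copy()

    if noise.baseline_mv > 0:
        white = rng.standard_normal(n)
        sos = sps.butter(2, noise.baseline_cutoff_hz, fs=fs, output="sos")
        bw = sps.sosfiltfilt(sos, white)
        sd = bw.std()
        if sd > 0:
            x = x + noise.baseline_mv * bw / sd
    if noise.powerline_mv > 0:
        x = x + noise.powerline_mv * np.sin(
            2 * np.pi * noise.powerline_hz * t + rng.uniform(0, 2 * np.pi))
    if noise.broadband_sd_mv > 0:
        x = x + noise.broadband_sd_mv * rng.standard_normal(n)

    if sat_episodes is None:
        sat_episodes = _episodes(noise.sat_rate_per_min,
                                 noise.sat_mean_duration_s, total_s, rng)
    rail = noise.sat_rail_mv
    for start, dur in sat_episodes:
        i0 = int(round(start * fs))
        i1 = min(int(round((start + dur) * fs)), n)
        if i1 <= i0 or i0 >= n:
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        x[i0:i1] = sign * rail
        # exponential drift back to the signal after the episode
        tail = np.arange(i1, min(i1 + int(5 * noise.sat_recovery_s * fs), n))
        if tail.size:
            rec = sign * rail * np.exp(-(tail - i1) / fs / noise.sat_recovery_s)
            x[tail] = x[tail] * (1 - np.exp(-(tail - i1) / fs / noise.sat_recovery_s)) + rec

    x = np.clip(x, -rail, rail)

    mask = stream.mask.copy()
    if loss_episodes is None:
        loss_episodes = _episodes(noise.loss_rate_per_min,
                                  noise.loss_mean_duration_s, total_s, rng)
    for start, dur in loss_episodes:
        i0 = int(round(start * fs))
        i1 = min(i0 + int(round(dur * fs)), n)
        if i1 <= i0 or i0 >= n:
            continue
        mask[i0:i1] = False
        # floating electrode: low-amplitude noise around zero
        x[i0:i1] = 0.01 * rng.standard_normal(i1 - i0)

    rpeaks = stream.rpeaks[mask[stream.rpeaks]] if stream.rpeaks.size else stream.rpeaks
    meta = dict(stream.meta)
    meta.update({"noise_seed": int(seed),
                 "sat_episodes": [(float(s), float(d)) for s, d in sat_episodes],
                 "loss_episodes": [(float(s), float(d)) for s, d in loss_episodes]})
    return AnnotatedStream(noisy=x, clean=stream.clean.copy(), fs=fs,
                           rpeaks=rpeaks, mask=mask, subject=stream.subject,
                           meta=meta)


def draw_morphology(rng: np.random.Generator) -> SubjectMorphology:
    """Draw a subject morphology uniformly within +/-20% of textbook values.

    Heart rate is drawn in [55, 90] bpm; the angular order of the five waves
    is preserved by construction (20% jitter cannot reorder them given the
    default spacing, and the draw is rejected otherwise).
    """
    for _ in range(100):
        amps = _DEF_AMPS * rng.uniform(0.8, 1.2, size=5)
        widths = _DEF_WIDTHS * rng.uniform(0.8, 1.2, size=5)
        angles = _DEF_ANGLES + np.deg2rad(rng.uniform(-6.0, 6.0, size=5))
        angles[2] = 0.0  # R anchors the cycle
        hr = rng.uniform(55.0, 90.0)
        hrv = rng.uniform(0.03, 0.08)
        if np.all(np.diff(angles) > 0):
            return SubjectMorphology(tuple(amps), tuple(widths), tuple(angles),
                                     float(hr), float(hrv))
    raise RuntimeError("could not draw a valid morphology")  # pragma: no cover


def simulate_cohort(n_subjects: int, trips_per_subject: int,
                    trip_duration: float = 120.0, fs: float = 1000.0,
                    seed: int = 0,
                    noise: NoiseProfile | None = None,
                    ) -> list[AnnotatedStream]:
    """Simulate a cohort of drivers, several trips each.

    Each subject gets a distinct morphology drawn by :func:`draw_morphology`;
    each trip gets its own recorded sub-seed.  If ``noise`` is given, every
    trip is contaminated with it (fresh noise per trip); otherwise trips are
    returned clean.
    """
    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    if trips_per_subject < 1:
        raise ValueError("need at least one trip per subject")
    master = np.random.default_rng(seed)
    streams: list[AnnotatedStream] = []
    for s in range(n_subjects):
        morph = draw_morphology(master)
        label = f"S{s:02d}"
        for trip in range(trips_per_subject):
            sub_seed = int(master.integers(0, 2**31 - 1))
            st = simulate_clean_ecg(morph, trip_duration, fs, sub_seed, label)
            st.meta.update({"trip": trip, "trip_seed": sub_seed})
            if noise is not None:
                st = contaminate(st, noise, seed=sub_seed + 1)
                st.meta.update({"trip": trip, "trip_seed": sub_seed})
            streams.append(st)
    return streams


def _mask_runlengths(mask: np.ndarray) -> list[list[int]]:
    """[value, length] run-length encoding of the boolean mask."""
    runs = []
    i = 0
    n = mask.size
    while i < n:
        j = i
        while j < n and mask[j] == mask[i]:
            j += 1
        runs.append([int(mask[i]), j - i])
        i = j
    return runs


def write_stream_csv(stream: AnnotatedStream, path: str | Path) -> Path:
    """Write (time_s, amplitude_mV) CSV plus a JSON ground-truth sidecar."""
    path = Path(path)
    t = np.arange(stream.noisy.size) / stream.fs
    arr = np.column_stack([t, stream.noisy])
    header = "time_s,amplitude_mV"
    np.savetxt(path, arr, delimiter=",", header=header, comments="",
               fmt="%.6f")
    sidecar = {
        "fs": stream.fs,
        "subject": stream.subject,
        "rpeaks": stream.rpeaks.tolist(),
        "mask_runs": _mask_runlengths(stream.mask),
        "meta": {k: v for k, v in stream.meta.items()
                 if isinstance(v, (int, float, str, list))},
    }
    side = path.with_suffix(path.suffix + ".json")
    side.write_text(json.dumps(sidecar))
    return path
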