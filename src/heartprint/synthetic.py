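"""Synthetic two-session ECG cohorts with per-subject heartbeat morphology.

Each heartbeat is modelled as the sum of five Gaussian bumps (P, Q, R, S, T)
placed around jittered R times.  A cohort draws a distinct morphology per
subject, perturbs it between the two acquisition sessions (inter-session
drift), and overlays baseline wander, 50 Hz powerline interference and
broadband noise.  Every record carries ground-truth R-peak indices so the
downstream detector, segmenter and matchers can be validated exactly.

Reproducibility contract: every random draw comes from a stream keyed by
``(seed, subject index, session index)``, so regenerating a cohort — or any
subset of it — with the same seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

WAVES = ("P", "Q", "R", "S", "T")

#: Baseline PQRST morphology: per-wave (amplitude [mV], offset from R [s],
#: width [s]).  Amplitudes are arbitrary units on a mV-like scale; the
#: pipeline min-max normalizes downstream so the scale is immaterial.
DEFAULT_WAVE_PARAMS = {
    "P": (0.12, -0.220, 0.045),
    "Q": (-0.12, -0.032, 0.011),
    "R": (1.00, 0.000, 0.014),
    "S": (-0.18, 0.035, 0.012),
    "T": (0.35, 0.280, 0.080),
}


class ConfigurationError(ValueError):
    """Raised when a cohort or morphology specification is invalid."""


@dataclass(frozen=True)
class MorphologyParams:
    """One subject-session heartbeat shape plus heart-rate statistics.

    ``amplitudes``/``offsets``/``widths`` map wave name -> value; offsets are
    seconds relative to the R center (R fixed at 0), widths are Gaussian
    standard deviations in seconds.
    """

    amplitudes: dict[str, float]
    offsets: dict[str, float]
    widths: dict[str, float]
    heart_rate_bpm: float = 72.0
    hrv_sd_bpm: float = 3.0

    def validate(self) -> None:
        for w in WAVES:
            if w not in self.amplitudes or w not in self.offsets or w not in self.widths:
                raise ConfigurationError(f"missing wave {w!r} in morphology")
            if self.widths[w] <= 0:
                raise ConfigurationError(f"wave {w} width must be > 0")
        amp = self.amplitudes
        if not (amp["R"] > abs(amp["Q"]) and amp["R"] > abs(amp["S"])):
            raise ConfigurationError("R amplitude must dominate |Q| and |S|")
        off = self.offsets
        if not (off["P"] < off["Q"] < off["R"] == 0.0 < off["S"] < off["T"]):
            raise ConfigurationError("wave centers must be ordered P < Q < R(=0) < S < T")
        if not (40.0 <= self.heart_rate_bpm <= 180.0):
            raise ConfigurationError("mean heart rate must lie in [40, 180] bpm")
        if self.hrv_sd_bpm < 0:
            raise ConfigurationError("heart-rate variability sd must be >= 0")


def default_morphology() -> MorphologyParams:
    """The population-mean morphology from which subjects are drawn."""
    return MorphologyParams(
        amplitudes={w: DEFAULT_WAVE_PARAMS[w][0] for w in WAVES},
        offsets={w: DEFAULT_WAVE_PARAMS[w][1] for w in WAVES},
        widths={w: DEFAULT_WAVE_PARAMS[w][2] for w in WAVES},
    )


@dataclass(frozen=True)
class CohortSpec:
    """Study design of a synthetic cohort.

    Defaults emulate the acquisition layout of the off-the-person finger-ECG
    database the pipeline targets: 63 subjects, two sessions, 2 min per
    record at 1 kHz, European 50 Hz mains.
    """

    n_subjects: int = 63
    sessions: int = 2
    duration_s: float = 120.0
    fs: float = 1000.0
    between_subject_sd: float = 0.15
    session_drift: float = 0.05
    baseline_wander_amp: float = 0.10
    powerline_amp: float = 0.05
    broadband_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.sessions != 2:
            raise ConfigurationError("cohorts are two-session by design")
        if self.fs <= 60.0:
            raise ConfigurationError("fs must exceed twice the 30 Hz band edge")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        for name in ("between_subject_sd", "session_drift", "baseline_wander_amp",
                     "powerline_amp", "broadband_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class ECGRecord:
    """One subject-session signal with metadata and optional ground truth."""

    subject_id: str
    session_id: int
    fs: float
    signal: np.ndarray
    true_r_peaks: np.ndarray | None = None

    def validate(self) -> None:
        if self.true_r_peaks is not None:
            rp = np.asarray(self.true_r_peaks)
            if rp.size and (np.any(np.diff(rp) <= 0) or rp[0] < 0 or rp[-1] >= len(self.signal)):
                raise ConfigurationError("true_r_peaks must be strictly increasing and in range")


def _subject_id(i: int) -> str:
    return f"S{i + 1:03d}"


def _perturb(morph: MorphologyParams, scale: float, rng: np.random.Generator) -> MorphologyParams:
    """Multiplicative zero-mean perturbation of every morphology parameter.

    Draws are truncated at +/-3 sd and the result is clipped back into the
    validity region (widths floored, HR clipped, wave order preserved by the
    multiplicative form since offsets keep their sign).
    """
    def jitter() -> float:
        return float(np.clip(rng.standard_normal(), -3.0, 3.0)) * scale

    amps = {w: morph.amplitudes[w] * (1.0 + jitter()) for w in WAVES}
    offs = {w: morph.offsets[w] * (1.0 + 0.5 * jitter()) for w in WAVES}
    wids = {w: max(morph.widths[w] * (1.0 + 0.5 * jitter()), 0.004) for w in WAVES}
    # keep R dominant even at extreme draws
    cap = 0.8 * abs(amps["R"])
    amps["Q"] = float(np.clip(amps["Q"], -cap, -0.01))
    amps["S"] = float(np.clip(amps["S"], -cap, -0.01))
    hr = float(np.clip(morph.heart_rate_bpm * (1.0 + 0.5 * jitter()), 45.0, 170.0))
    out = MorphologyParams(amps, offs, wids, hr, morph.hrv_sd_bpm)
    out.validate()
    return out


def sample_cohort_morphologies(spec: CohortSpec) -> dict[str, tuple[MorphologyParams, ...]]:
    """Draw per-subject morphologies for both sessions.

    Session 1 is the population morphology perturbed at ``between_subject_sd``;
    session 2 is session 1 perturbed again at ``session_drift``.  With zero
    drift the two sessions are identical objects field-for-field.
    """
    spec.validate()
    base = default_morphology()
    out: dict[str, tuple[MorphologyParams, ...]] = {}
    for i in range(spec.n_subjects):
        rng1 = np.random.default_rng([spec.seed, i, 101])
        m1 = _perturb(base, spec.between_subject_sd, rng1)
        if spec.session_drift == 0.0:
            m2 = dataclasses.replace(m1)
        else:
            rng2 = np.random.default_rng([spec.seed, i, 102])
            m2 = _perturb(m1, spec.session_drift, rng2)
        out[_subject_id(i)] = (m1, m2)
    return out


def synthesize_ecg(
    morph: MorphologyParams,
    spec: CohortSpec,
    rng: np.random.Generator,
    subject_id: str = "S001",
    session_id: int = 1,
) -> ECGRecord:
    """Render one record: place R times, sum Gaussian bumps, add noise.

    Inter-beat intervals are Gaussian around 60/HR seconds (sd derived from
    the bpm-scale HRV sd), truncated at +/-3 sd so consecutive beats never
    overlap.  With all noise amplitudes zero the inter-beat signal is ~0 and
    the value at each true R index equals the R amplitude to within ~1%.
    """
    morph.validate()
    n = int(round(spec.duration_s * spec.fs))
    mean_rr = 60.0 / morph.heart_rate_bpm
    if spec.duration_s < 2.0 * mean_rr:
        raise ConfigurationError("duration too short for two beats at this heart rate")
    sd_rr = morph.hrv_sd_bpm * 60.0 / morph.heart_rate_bpm**2

    t0 = mean_rr * (0.3 + 0.4 * rng.random())
    r_times = [t0]
    while True:
        rr = mean_rr + float(np.clip(rng.standard_normal(), -3.0, 3.0)) * sd_rr
        nxt = r_times[-1] + rr
        if nxt >= spec.duration_s:
            break
        r_times.append(nxt)

    signal = np.zeros(n)
    t = np.arange(n) / spec.fs
    for tr in r_times:
        for w in WAVES:
            a = morph.amplitudes[w]
            c = tr + morph.offsets[w]
            s = morph.widths[w]
            lo = max(int((c - 5 * s) * spec.fs), 0)
            hi = min(int((c + 5 * s) * spec.fs) + 1, n)
            if lo < hi:
                signal[lo:hi] += a * np.exp(-((t[lo:hi] - c) ** 2) / (2 * s * s))

    if spec.baseline_wander_amp > 0:
        n_sin = int(rng.integers(2, 4))
        for _ in range(n_sin):
            f = 0.05 + 0.35 * rng.random()  # below 0.4 Hz: inside filter stopband
            phase = 2 * np.pi * rng.random()
            signal += (spec.baseline_wander_amp / n_sin) * np.sin(2 * np.pi * f * t + phase)
    if spec.powerline_amp > 0:
        signal += spec.powerline_amp * np.sin(2 * np.pi * 50.0 * t + 2 * np.pi * rng.random())
    if spec.broadband_sd > 0:
        signal += spec.broadband_sd * rng.standard_normal(n)

    peaks = np.round(np.asarray(r_times) * spec.fs).astype(int)
    peaks = peaks[(peaks >= 0) & (peaks < n)]
    rec = ECGRecord(subject_id, session_id, spec.fs, signal, peaks)
    rec.validate()
    return rec


def record_rng(spec: CohortSpec, subject_index: int, session_id: int) -> np.random.Generator:
    """Per-record stream keyed by (seed, subject index, session) — stable
    under cohort subsetting."""
    return np.random.default_rng([spec.seed, subject_index, session_id])


def generate_cohort(spec: CohortSpec) -> list[ECGRecord]:
    """Generate the full cohort: one record per subject per session."""
    spec.validate()
    morphs = sample_cohort_morphologies(spec)
    records = []
    for i, (sid, (m1, m2)) in enumerate(morphs.items()):
        for session_id, m in ((1, m1), (2, m2)):
            rng = record_rng(spec, i, session_id)
            records.append(synthesize_ecg(m, spec, rng, subject_id=sid, session_id=session_id))
    return records
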