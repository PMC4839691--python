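"""Target nonwords, trial-unique white noise, and SNR-controlled mixtures.

The four targets are /aCCa/ nonwords -- a continuant consonant (/l/ or
/R/) followed by a stop (/d/ or /g/): *alda*, *alga*, *aRda*, *aRga*.
They are built here by additive formant synthesis (sum of AM sinusoids
following F1-F4 trajectories) rather than recorded speech, with the
trajectories chosen so that the known cue regions of the task are
acoustically meaningful: the /da/ variants carry an F2 onset near
1380 Hz and an F3 onset near 2557 Hz at the start of the second
syllable, while the /ga/ variants show the characteristic F2/F3 "pinch"
near 1977 Hz.  All targets share a 680 ms total duration with a 328 ms
first syllable, sampled at 48 kHz, and are power-normalized to unit RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

SAMPLE_RATE = 48_000
TOTAL_DURATION_MS = 680.0
SYLLABLE1_DURATION_MS = 328.0

#: labels of the four targets; last-consonant class is 'da' or 'ga'
TARGET_LABELS = ("alda", "alga", "aRda", "aRga")

FormantTracks = dict[str, dict[str, list[tuple[float, float]]]]


def n_samples(duration_ms: float = TOTAL_DURATION_MS,
              sample_rate: int = SAMPLE_RATE) -> int:
    return int(round(duration_ms / 1000.0 * sample_rate))


@dataclass
class TargetSet:
    """The four task targets with their formant trajectories.

    All waveforms have identical length ``round(total_duration/1000 *
    sample_rate)`` and identical RMS (unit, to 1e-9).
    """

    labels: tuple[str, ...]
    waveforms: dict[str, np.ndarray]
    sample_rate: int
    total_duration_ms: float
    syllable1_duration_ms: float
    formant_tracks: FormantTracks = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.labels) != 4:
            raise ValueError("a TargetSet holds exactly 4 targets")
        n = n_samples(self.total_duration_ms, self.sample_rate)
        for lab in self.labels:
            w = self.waveforms[lab]
            if w.shape != (n,):
                raise ValueError(
                    f"waveform {lab!r} has {w.shape[0]} samples, expected {n}")
        rms = np.array([_rms(self.waveforms[lab]) for lab in self.labels])
        if np.any(np.abs(rms / rms[0] - 1.0) > 1e-9):
            raise ValueError("target waveforms are not power-equalized")

    def consonant_class(self, label: str) -> str:
        """'da' or 'ga' -- the class the listener must report."""
        return label[-2:]

    def is_ga(self, label: str) -> bool:
        return self.consonant_class(label) == "ga"


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x, dtype=np.float64))))


# ---------------------------------------------------------------------------
# formant trajectories
# ---------------------------------------------------------------------------

def default_formant_tracks() -> FormantTracks:
    """Breakpoint (time ms, frequency Hz) trajectories for F1-F4.

    Layout per target: /a/ vowel, continuant consonant (/l/ or /R/),
    stop closure around 328-395 ms, then the second /Ca/ syllable whose
    formant onsets carry the place-of-articulation cue:

    * /da/ (alveolar): F1 onset 665 Hz, F2 onset 1380 Hz, F3 onset
      2557 Hz, relaxing to the /a/ steady state.
    * /ga/ (velar): F2 and F3 converge ("pinch") near 1977 Hz at onset
      before separating.
    """
    a = {"F1": 700.0, "F2": 1200.0, "F3": 2500.0, "F4": 3500.0}
    # continuant consonants, reached by 240 ms and held to the closure
    cons = {
        "l": {"F1": 420.0, "F2": 1150.0, "F3": 2600.0, "F4": 3600.0},
        "R": {"F1": 560.0, "F2": 1350.0, "F3": 2100.0, "F4": 3400.0},
    }
    # second-syllable onsets at ~400 ms (stop release)
    onset = {
        "da": {"F1": 665.0, "F2": 1380.0, "F3": 2557.0, "F4": 3500.0},
        "ga": {"F1": 665.0, "F2": 1900.0, "F3": 2060.0, "F4": 3500.0},
    }
    tracks: FormantTracks = {}
    for label in TARGET_LABELS:
        c, stop = label[1], label[-2:]
        per_formant: dict[str, list[tuple[float, float]]] = {}
        for f in ("F1", "F2", "F3", "F4"):
            per_formant[f] = [
                (0.0, a[f]),
                (180.0, a[f]),
                (240.0, cons[c][f]),
                (328.0, cons[c][f]),
                # closure: hold the consonant locus through the gap
                (395.0, onset[stop][f]),
                (400.0, onset[stop][f]),
                (470.0, a[f]),
                (680.0, a[f]),
            ]
        tracks[label] = per_formant
    return tracks


def _interp_track(track: list[tuple[float, float]], t_ms: np.ndarray) -> np.ndarray:
    pts = np.asarray(track, dtype=float)
    if pts[0, 0] > 0.0 or pts[-1, 0] < TOTAL_DURATION_MS - 1e-9:
        raise ValueError("formant track must cover [0, 680] ms")
    return np.interp(t_ms, pts[:, 0], pts[:, 1])


def _amplitude_envelope(t_ms: np.ndarray, syllable1_ms: float) -> np.ndarray:
    """Voicing envelope: two syllables separated by the stop closure."""
    env = np.zeros_like(t_ms)
    closure_end = 395.0

    def ramp(lo, hi, rise, fall):
        seg = np.clip((t_ms - lo) / rise, 0.0, 1.0) * \
            np.clip((hi - t_ms) / fall, 0.0, 1.0)
        return np.clip(seg, 0.0, 1.0)

    env += ramp(0.0, syllable1_ms, 15.0, 25.0)
    env += ramp(closure_end, TOTAL_DURATION_MS, 12.0, 30.0)
    return np.clip(env, 0.0, 1.0)


def synthesize_targets(
    tracks: FormantTracks | None = None,
    formant_amplitudes: tuple[float, float, float, float] = (1.0, 0.63, 0.40, 0.25),
    sample_rate: int = SAMPLE_RATE,
    total_duration_ms: float = TOTAL_DURATION_MS,
    syllable1_duration_ms: float = SYLLABLE1_DURATION_MS,
) -> TargetSet:
    """Build the 4 power-normalized targets by additive formant synthesis.

    Each formant contributes an AM sinusoid whose instantaneous frequency
    follows the (linearly interpolated) track; a shared voicing envelope
    imposes the two-syllable structure with a stop closure.  Waveforms
    are normalized to unit RMS.

    Raises
    ------
    ValueError
        If formant ordering F1<F2<F3<F4 is violated anywhere, a track
        does not cover the full duration, or a synthesized waveform is
        silent (zero RMS cannot be power-normalized).
    """
    if tracks is None:
        tracks = default_formant_tracks()
    n = n_samples(total_duration_ms, sample_rate)
    t_ms = np.arange(n) / sample_rate * 1000.0
    env = _amplitude_envelope(t_ms, syllable1_duration_ms)
    waveforms: dict[str, np.ndarray] = {}
    for label in TARGET_LABELS:
        freqs = np.stack([_interp_track(tracks[label][f], t_ms)
                          for f in ("F1", "F2", "F3", "F4")])
        if np.any(np.diff(freqs, axis=0) <= 0.0):
            raise ValueError(
                f"target {label!r}: formant ordering F1<F2<F3<F4 violated")
        phase = 2.0 * np.pi * np.cumsum(freqs, axis=1) / sample_rate
        amps = np.asarray(formant_amplitudes, dtype=float)[:, None]
        w = np.sum(amps * np.sin(phase), axis=0) * env
        r = _rms(w)
        if r == 0.0:
            raise ValueError(
                f"target {label!r} is silent; cannot power-normalize")
        waveforms[label] = w / r
    return TargetSet(
        labels=TARGET_LABELS,
        waveforms=waveforms,
        sample_rate=sample_rate,
        total_duration_ms=total_duration_ms,
        syllable1_duration_ms=syllable1_duration_ms,
        formant_tracks=tracks,
    )


# ---------------------------------------------------------------------------
# noise and mixing
# ---------------------------------------------------------------------------

def generate_noise(seed: int,
                   duration_ms: float = TOTAL_DURATION_MS,
                   sample_rate: int = SAMPLE_RATE) -> np.ndarray:
    """One trial-unique Gaussian white noise token, RMS-normalized to 1.

    The seed uniquely identifies the realization: the same seed always
    returns a bit-identical waveform.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_samples(duration_ms, sample_rate))
    return x / _rms(x)


def mix_at_snr(target: np.ndarray, noise: np.ndarray, snr_db: float,
               normalize: bool = True) -> np.ndarray:
    """Mix ``target + g*noise`` at the requested broadband SNR.

    The noise gain is ``g = RMS(target)/RMS(noise) * 10**(-snr_db/20)``
    so that, before the final normalization, the target-to-noise RMS
    ratio equals ``snr_db`` exactly.  The mixture is then re-normalized
    to unit RMS (absolute level carries no information in the task).
    """
    target = np.asarray(target, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if target.shape != noise.shape:
        raise ValueError("target and noise must have equal length")
    rt, rn = _rms(target), _rms(noise)
    if rt == 0.0 or rn == 0.0:
        raise ValueError("target and noise must both have nonzero RMS")
    g = rt / rn * 10.0 ** (-snr_db / 20.0)
    mix = target + g * noise
    if not normalize:
        return mix
    return mix / _rms(mix)


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

def write_wav(path, waveform: np.ndarray, sample_rate: int,
              subtype: str = "float32") -> None:
    """Write a mono waveform as RIFF WAV (float32 by default, or pcm16).

    ``pcm16`` clips to [-1, 1] and quantizes to 16 bits; use it only for
    signals already scaled into that range.
    """
    w = np.asarray(waveform, dtype=np.float64)
    if subtype == "float32":
        wavfile.write(path, sample_rate, w.astype(np.float32))
    elif subtype == "pcm16":
        q = np.clip(w, -1.0, 1.0)
        wavfile.write(path, sample_rate,
                      (q * 32767.0).round().astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a WAV file to float64 in [-1, 1] (PCM) or native float scale.

    Returns ``(waveform, sample_rate)``.  Raises ``ValueError`` naming
    the path for unreadable or foreign files.
    """
    try:
        sample_rate, data = wavfile.read(path)
    except Exception as exc:  # wavfile raises assorted exception types
        raise ValueError(f"cannot read WAV file {path!r}: {exc}") from exc
    if data.dtype == np.int16:
        x = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2147483647.0
    elif data.dtype in (np.float32, np.float64):
        x = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format in {path!r}: "
                         f"{data.dtype}")
    return x, int(sample_rate)
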