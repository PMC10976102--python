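"""Synthetic multichannel EEG-like data with controllable phase coupling.

The generator produces datasets whose class structure is planted in
exactly the two feature families the pipeline extracts:

* **phase coupling** — designated channel pairs share a common carrier
  oscillation whose phase is mixed with a per-channel independent phase
  at weight ``1 - kappa``, so the phase-locking value between the pair
  interpolates smoothly from near-chance (kappa = 0) to exactly 1
  (kappa = 1, noise-free);
* **band power** — every channel carries one narrowband component per
  canonical EEG band (delta/theta/alpha/beta/gamma), and the "high"
  class multiplies selected band amplitudes by sqrt(gain) so the band
  *power* ratio between classes equals the requested gain.

Trials are labelled through ordinal scores that binarize to the intended
class under the dataset threshold: high-class trials score exactly the
threshold, low-class trials score one below — deliberately exercising
the "score < threshold -> low, otherwise high" boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import Recording
from .features import BAND_NAMES

__all__ = ["SyntheticSpec", "generate_dataset"]

#: centre frequency (Hz) of the planted narrowband component per band;
#: even values land on exact FFT bins for both 0.5 s and 1 s windows at 128 Hz
BAND_COMPONENT_HZ = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 22.0, "gamma": 38.0}

#: baseline amplitude of each per-band component (carrier amplitude is 1)
BAND_COMPONENT_AMP = 0.5

#: per-sample sd (radians) of the slow phase random walk
PHASE_WALK_SD = 0.1


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Attributes
    ----------
    n_subjects, n_trials_per_subject:
        Dataset extent.
    trial_duration:
        Trial length in seconds.
    fs:
        Sampling rate, Hz; must exceed twice the carrier band's upper edge.
    n_channels:
        Channel count (arbitrary; 32 mimics a DEAP montage, 14 DREAMER).
    coupled_channel_pairs:
        Channel index pairs that phase-lock in the high class.
    coupling_strength:
        kappa in [0, 1]; weight of the shared carrier phase for
        high-class trials (low-class trials always use kappa = 0).
    carrier_band:
        (low, high) Hz interval the carrier frequency is drawn from,
        uniformly per trial (default: alpha, 8-13 Hz).
    band_power_offsets:
        Map band name -> multiplicative *power* gain applied to that
        band's component in high-class trials (e.g. ``{"beta": 2.0}``).
    noise_sd:
        Additive white Gaussian noise sd, signal units.
    class_balance:
        Fraction of trials in the high class.
    threshold:
        Score threshold of the emulated rating scale (5 for a 1-9 scale).
    seed:
        Root seed; each subject gets an RNG stream derived from
        (seed, subject index), so any single subject is reproducible
        independently of the others.
    """

    n_subjects: int = 5
    n_trials_per_subject: int = 25
    trial_duration: float = 8.0
    fs: float = 128.0
    n_channels: int = 8
    coupled_channel_pairs: tuple[tuple[int, int], ...] = ((0, 1), (2, 3))
    coupling_strength: float = 1.0
    carrier_band: tuple[float, float] = (8.0, 13.0)
    band_power_offsets: dict[str, float] = field(default_factory=lambda: {"beta": 2.0})
    noise_sd: float = 0.1
    class_balance: float = 0.5
    threshold: float = 5.0
    seed: int = 0
    dimension_names: tuple[str, ...] = ("arousal", "valence", "dominance")

    def validate(self) -> None:
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError(
                f"coupling_strength must be in [0, 1], got {self.coupling_strength}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.trial_duration <= 0:
            raise ValueError(f"trial_duration must be positive, got {self.trial_duration}")
        if self.fs <= 2.0 * self.carrier_band[1]:
            raise ValueError(
                f"fs={self.fs} must exceed twice the carrier band upper edge "
                f"({self.carrier_band[1]} Hz)"
            )
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError(f"class_balance must be in [0, 1], got {self.class_balance}")
        for a, b in self.coupled_channel_pairs:
            if not (0 <= a < self.n_channels and 0 <= b < self.n_channels) or a == b:
                raise ValueError(f"invalid coupled pair ({a}, {b}) for {self.n_channels} channels")
        unknown = set(self.band_power_offsets) - set(BAND_NAMES)
        if unknown:
            raise ValueError(f"unknown bands in band_power_offsets: {sorted(unknown)}")


def _phase_walk(rng: np.random.Generator, n: int) -> np.ndarray:
    """Slowly drifting phase: random start plus a Gaussian random walk."""
    start = rng.uniform(0.0, 2.0 * np.pi)
    return start + np.cumsum(rng.normal(0.0, PHASE_WALK_SD, size=n))


def _indep_phase(
    rng: np.random.Generator, n: int, t: np.ndarray, f_pair: float, band: tuple[float, float]
) -> np.ndarray:
    """Independent phase: an in-band frequency detuning plus a slow walk.

    Redrawing the channel's effective frequency uniformly inside the
    carrier band makes uncoupled phase differences sweep linearly, so
    windowed PLV decoheres toward chance without the heavy spectral
    tails a fast random walk would spray into neighbouring bands.
    """
    f_own = rng.uniform(*band)
    return 2.0 * np.pi * (f_own - f_pair) * t + _phase_walk(rng, n)


def _trial_signal(
    spec: SyntheticSpec, rng: np.random.Generator, is_high: bool
) -> np.ndarray:
    """One trial: channels x samples."""
    n = int(round(spec.trial_duration * spec.fs))
    t = np.arange(n) / spec.fs
    kappa = spec.coupling_strength if is_high else 0.0
    sig = np.zeros((spec.n_channels, n))

    # carrier oscillation; coupled pairs share frequency and common phase
    pair_of: dict[int, int] = {}
    for pi, (a, b) in enumerate(spec.coupled_channel_pairs):
        pair_of[a] = pi
        pair_of[b] = pi
    pair_freq = rng.uniform(*spec.carrier_band, size=max(len(spec.coupled_channel_pairs), 1))
    pair_common = [
        _phase_walk(rng, n) for _ in range(max(len(spec.coupled_channel_pairs), 1))
    ]
    for ch in range(spec.n_channels):
        if ch in pair_of:
            pi = pair_of[ch]
            f = pair_freq[pi]
            indep = _indep_phase(rng, n, t, f, spec.carrier_band)
            phase = kappa * pair_common[pi] + (1.0 - kappa) * indep
        else:
            f = rng.uniform(*spec.carrier_band)
            phase = _phase_walk(rng, n)
        sig[ch] = np.cos(2.0 * np.pi * f * t + phase)

    # narrowband components per canonical band; members of a coupled pair
    # share component phases so kappa=1 + zero noise means identical signals
    gains = {
        band: (spec.band_power_offsets.get(band, 1.0) if is_high else 1.0)
        for band in BAND_NAMES
    }
    comp_phase_for_pair = [
        {band: rng.uniform(0.0, 2.0 * np.pi) for band in BAND_NAMES}
        for _ in range(max(len(spec.coupled_channel_pairs), 1))
    ]
    for ch in range(spec.n_channels):
        if ch in pair_of:
            phases = comp_phase_for_pair[pair_of[ch]]
        else:
            phases = {band: rng.uniform(0.0, 2.0 * np.pi) for band in BAND_NAMES}
        for band in BAND_NAMES:
            amp = BAND_COMPONENT_AMP * np.sqrt(gains[band])
            sig[ch] += amp * np.sin(
                2.0 * np.pi * BAND_COMPONENT_HZ[band] * t + phases[band]
            )

    if spec.noise_sd > 0:
        sig += rng.normal(0.0, spec.noise_sd, size=sig.shape)
    return sig


def generate_dataset(spec: SyntheticSpec) -> list[Recording]:
    """Generate ``spec.n_subjects`` recordings with planted class structure.

    Identical spec + seed gives bit-identical output.  Class assignment is
    exact: ``round(class_balance * n_trials)`` trials per subject are high,
    the rest low, in an order shuffled per subject.
    """
    spec.validate()
    n_trials = spec.n_trials_per_subject
    n_high = int(round(spec.class_balance * n_trials))
    recordings: list[Recording] = []
    for s in range(spec.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, s)))
        is_high = np.zeros(n_trials, dtype=bool)
        is_high[:n_high] = True
        rng.shuffle(is_high)
        trials = np.stack([_trial_signal(spec, rng, h) for h in is_high])
        score = np.where(is_high, spec.threshold, spec.threshold - 1.0)
        scores = np.tile(score[:, None], (1, len(spec.dimension_names)))
        recordings.append(
            Recording(
                subject_id=f"synth{s:02d}",
                signal=trials,
                fs=spec.fs,
                scores=scores,
                dimension_names=spec.dimension_names,
            )
        )
    return recordings
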