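"""Auditory stimulus synthesis and binaural spatialization.

The stimulus is a 500 ms band-limited (100-4000 Hz) pink-noise burst,
sinusoidally amplitude-modulated at 6 Hz with 3 dB depth and gated by 25 ms
raised-cosine ramps.  Azimuth and distance are rendered by convolving the
stimulus with (a) a room impulse response built with the 2-D image-source
method for a 4.2 x 5.2 m room (listener 1.5 m from the back wall on the
mid-line, sources on a 2.5 m arc, wall absorbance 0.2, reflections up to
order 5) and (b) a per-azimuth binaural head-related impulse response —
either a built-in spherical-head model or a measured set loaded from WAV or
SOFA files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import fftconvolve

__all__ = [
    "NoiseSpec",
    "RoomSpec",
    "ImpulseResponse",
    "HRIRSet",
    "synth_pink_noise",
    "apply_am",
    "apply_ramps",
    "make_stimulus",
    "image_sources",
    "build_room_ir",
    "spherical_head_hrir",
    "spherical_head_hrir_set",
    "load_hrir_wavs",
    "load_hrir_sofa",
    "spatialize",
    "write_wav",
]

SPEED_OF_SOUND_MPS = 343.0


@dataclass(frozen=True)
class NoiseSpec:
    """Pink-noise burst parameters."""

    duration_s: float = 0.5
    band_hz: tuple[float, float] = (100.0, 4000.0)
    fs_hz: int = 44100
    am_rate_hz: float = 6.0
    am_depth_db: float = 3.0
    ramp_s: float = 0.025

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi < self.fs_hz / 2):
            raise ValueError(
                f"band {self.band_hz} must satisfy 0 < lo < hi < Nyquist ({self.fs_hz/2})")
        if self.am_depth_db < 0:
            raise ValueError("am_depth_db must be >= 0")
        if 2 * self.ramp_s > self.duration_s:
            raise ValueError("ramps longer than the stimulus")


@dataclass(frozen=True)
class RoomSpec:
    """Rectangular-room geometry for the image-source model.

    The floor plan is ``width_m`` (x) by ``depth_m`` (y) with the origin at
    the front-left corner; the listener sits on the horizontal centre line,
    ``listener_from_back_m`` from the back wall, facing the front wall (+y).
    Sound sources lie on a ``source_radius_m`` arc in front of the listener.
    """

    width_m: float = 4.2
    depth_m: float = 5.2
    listener_from_back_m: float = 1.5
    source_radius_m: float = 2.5
    absorbance: float = 0.2
    max_reflections: int = 5
    speed_of_sound_mps: float = SPEED_OF_SOUND_MPS

    def __post_init__(self) -> None:
        if not (0.0 <= self.absorbance <= 1.0):
            raise ValueError("absorbance must lie in [0, 1]")
        if self.max_reflections < 0:
            raise ValueError("max_reflections must be >= 0")
        lx, ly = self.listener_xy
        if not (0 < lx < self.width_m and 0 < ly < self.depth_m):
            raise ValueError("listener outside room")
        # note: with the default geometry the source arc leaves the room
        # beyond ~57 degrees; source positions are validated per request.

    @property
    def listener_xy(self) -> tuple[float, float]:
        return (self.width_m / 2.0, self.listener_from_back_m)

    def source_xy(self, azimuth_deg: float) -> tuple[float, float]:
        """Source position for an azimuth (0 = straight ahead, + = right)."""
        lx, ly = self.listener_xy
        az = math.radians(azimuth_deg)
        return (lx + self.source_radius_m * math.sin(az),
                ly + self.source_radius_m * math.cos(az))

    @property
    def reflection_coefficient(self) -> float:
        # pressure coefficient from energy absorbance: r = sqrt(1 - a)
        return math.sqrt(1.0 - self.absorbance)


@dataclass
class ImpulseResponse:
    """Sparse room reflection pulse train and its sampled rendering."""

    fs_hz: int
    pulses: list[tuple[float, float]]  # (delay_s, amplitude), sorted by delay

    @property
    def taps(self) -> np.ndarray:
        """Pulse train rendered by nearest-sample placement."""
        n = int(round(self.pulses[-1][0] * self.fs_hz)) + 1
        out = np.zeros(n)
        for delay, amp in self.pulses:
            out[int(round(delay * self.fs_hz))] += amp
        return out

    @property
    def energy(self) -> float:
        return float(sum(a * a for _, a in self.pulses))


@dataclass
class HRIRSet:
    """Per-azimuth binaural impulse responses on a sorted azimuth grid."""

    azimuths: np.ndarray
    left: list[np.ndarray]
    right: list[np.ndarray]
    fs_hz: int
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        order = np.argsort(self.azimuths)
        self.azimuths = np.asarray(self.azimuths, dtype=float)[order]
        self.left = [self.left[i] for i in order]
        self.right = [self.right[i] for i in order]
        if len(np.unique(self.azimuths)) != len(self.azimuths):
            raise ValueError("duplicate azimuths in HRIR set")
        for l, r in zip(self.left, self.right):
            if len(l) != len(r):
                raise ValueError("left/right HRIR length mismatch")

    def __getitem__(self, azimuth_deg: float) -> tuple[np.ndarray, np.ndarray]:
        """HRIR pair at the grid azimuth nearest to the request."""
        i = int(np.argmin(np.abs(self.azimuths - azimuth_deg)))
        return self.left[i], self.right[i]


def synth_pink_noise(spec: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Band-limited pink-noise burst (mono, unit peak scale applied later).

    White Gaussian noise is shaped in the frequency domain by 1/sqrt(f)
    (power density proportional to 1/f) with brick-wall limits at the band
    edges, then normalized to unit RMS.
    """
    n = int(round(spec.duration_s * spec.fs_hz))
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / spec.fs_hz)
    lo, hi = spec.band_hz
    shape = np.zeros_like(f)
    inband = (f >= lo) & (f <= hi)
    shape[inband] = 1.0 / np.sqrt(f[inband])
    wave = np.fft.irfft(spectrum * shape, n=n)
    return wave / np.sqrt(np.mean(wave ** 2))


def apply_am(wave: np.ndarray, rate_hz: float, depth_db: float,
             fs_hz: int = 44100) -> np.ndarray:
    """Sinusoidal amplitude modulation with a peak-to-trough depth in dB.

    The envelope oscillates in linear amplitude between 1 and
    ``10**(-depth_db/20)`` so that ``20*log10(max/min)`` equals ``depth_db``;
    the envelope starts at its peak.
    """
    if depth_db < 0:
        raise ValueError("depth_db must be >= 0")
    if depth_db == 0:
        return wave.copy()
    t = np.arange(len(wave)) / fs_hz
    emin = 10.0 ** (-depth_db / 20.0)
    env = (1 + emin) / 2 + (1 - emin) / 2 * np.cos(2 * np.pi * rate_hz * t)
    return wave * env


def apply_ramps(wave: np.ndarray, ramp_s: float, fs_hz: int) -> np.ndarray:
    """Gate on/off with raised-cosine half-windows of length ``ramp_s``.

    Ramp length in samples is ``round(ramp_s * fs_hz)``; the gain runs from 0
    at the first sample to 1, leaving the interior untouched.
    """
    n_ramp = int(round(ramp_s * fs_hz))
    if 2 * n_ramp > len(wave):
        raise ValueError("ramps longer than the waveform")
    out = wave.copy()
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    out[:n_ramp] *= ramp
    out[-n_ramp:] *= ramp[::-1]
    return out


def make_stimulus(spec: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Full mono stimulus chain: pink noise -> AM -> ramps, peak-normalized."""
    w = synth_pink_noise(spec, rng)
    w = apply_am(w, spec.am_rate_hz, spec.am_depth_db, spec.fs_hz)
    w = apply_ramps(w, spec.ramp_s, spec.fs_hz)
    return 0.9 * w / np.max(np.abs(w))


def image_sources(
    room: RoomSpec,
    source_xy: tuple[float, float],
    listener_xy: tuple[float, float],
    max_order: int,
) -> list[tuple[tuple[float, float], int]]:
    """Mirror-image source positions up to ``max_order`` total reflections.

    2-D (floor-plan) variant: images of a source at (x, y) in a W x D room
    form the lattice (±x + 2 m W, ±y + 2 n D); the reflection count of image
    (m, parity_x, n, parity_y) is |2m - px| + |2n - py| in the standard
    image-source indexing.  Order 0 is the direct source.
    """
    sx, sy = source_xy
    lx, ly = listener_xy
    for x, y, what in ((sx, sy, "source"), (lx, ly, "listener")):
        if not (0 <= x <= room.width_m and 0 <= y <= room.depth_m):
            raise ValueError(f"{what} position ({x}, {y}) outside room")
    W, D = room.width_m, room.depth_m
    images: list[tuple[tuple[float, float], int]] = []
    # p in {0,1} selects the unreflected/reflected coordinate; m counts wall pairs
    half = max_order // 2 + 1
    for px in (0, 1):
        for py in (0, 1):
            for m in range(-half, half + 1):
                for n in range(-half, half + 1):
                    order = abs(2 * m - px) + abs(2 * n - py)
                    if order > max_order:
                        continue
                    ix = (-sx if px else sx) + 2 * m * W
                    iy = (-sy if py else sy) + 2 * n * D
                    images.append(((ix, iy), order))
    return images


def build_room_ir(room: RoomSpec, azimuth_deg: float,
                  fs_hz: int = 44100) -> ImpulseResponse:
    """Room impulse response at the listener for a source at ``azimuth_deg``.

    Each image source contributes one pulse with delay = distance / c and
    amplitude = r**order / distance, where r is the pressure reflection
    coefficient derived from the wall absorbance (r = sqrt(1 - a)).  Pulses
    are sorted by delay; the direct path arrives first.
    """
    if abs(azimuth_deg) > 90:
        raise ValueError(f"azimuth {azimuth_deg} outside +/-90 degrees")
    src = room.source_xy(azimuth_deg)
    lis = room.listener_xy
    r = room.reflection_coefficient
    pulses = []
    for (ix, iy), order in image_sources(room, src, lis, room.max_reflections):
        gain = r ** order
        if gain == 0.0 and order > 0:
            continue
        dist = math.hypot(ix - lis[0], iy - lis[1])
        pulses.append((dist / room.speed_of_sound_mps, gain / dist))
    pulses.sort()
    return ImpulseResponse(fs_hz=fs_hz, pulses=pulses)


def _woodworth_itd(azimuth_deg: float, head_radius_m: float,
                   c: float = SPEED_OF_SOUND_MPS) -> float:
    """Interaural time difference, positive when the right ear leads."""
    az = math.radians(azimuth_deg)
    return (head_radius_m / c) * (az + math.sin(az))


def spherical_head_hrir(
    azimuth_deg: float,
    fs_hz: int = 44100,
    head_radius_m: float = 0.0875,
    n_taps: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic binaural impulse response from a rigid-sphere head model.

    ITD follows the Woodworth formula tau(az) = (a/c)(az + sin az); ILD is a
    first-order low-pass head-shadow on the contralateral ear (corner
    frequency c / (2 pi a) scaled down with increasing incidence angle).
    Mirror symmetric: left(az) == right(-az).
    """
    if abs(azimuth_deg) > 90:
        raise ValueError(f"azimuth {azimuth_deg} outside +/-90 degrees")
    itd = _woodworth_itd(azimuth_deg, head_radius_m)
    base_delay_s = (n_taps // 4) / fs_hz
    # right ear leads (earlier, shorter delay) for positive azimuth
    delay_r = base_delay_s - itd / 2
    delay_l = base_delay_s + itd / 2

    f = np.fft.rfftfreq(n_taps, d=1.0 / fs_hz)
    w0 = SPEED_OF_SOUND_MPS / (2 * np.pi * head_radius_m)

    def ear(delay_s: float, shadow: float) -> np.ndarray:
        # shadow in [0, 1]: 0 = ipsilateral (flat), 1 = full contralateral
        # low-pass.  The shadow is applied zero-phase (magnitude only) so the
        # interaural delay is carried entirely by the Woodworth ITD term.
        h = np.exp(-2j * np.pi * f * delay_s)
        if shadow > 0:
            fc = w0 / (1 + 3 * shadow)  # corner frequency drops into the shadow
            h = h / np.abs(1 + 1j * f / fc)
        return np.fft.irfft(h, n=n_taps)

    s = abs(math.sin(math.radians(azimuth_deg)))
    if azimuth_deg >= 0:
        right = ear(delay_r, 0.0)
        left = ear(delay_l, s)
    else:
        right = ear(delay_r, s)
        left = ear(delay_l, 0.0)
    return left, right


def spherical_head_hrir_set(
    fs_hz: int = 44100,
    step_deg: int = 5,
    head_radius_m: float = 0.0875,
) -> HRIRSet:
    """Spherical-head HRIRs on the paradigm's ±90 degree, 5 degree grid."""
    azimuths = np.arange(-90, 90 + step_deg, step_deg, dtype=float)
    left, right = [], []
    for az in azimuths:
        l, r = spherical_head_hrir(az, fs_hz, head_radius_m)
        left.append(l)
        right.append(r)
    return HRIRSet(azimuths=azimuths, left=left, right=right,
                   fs_hz=fs_hz, provenance="synthetic")


def load_hrir_wavs(directory: str | Path, pattern: str = "az{az:+d}.wav") -> HRIRSet:
    """Load a measured HRIR set from per-azimuth stereo WAV files.

    Files are matched by substituting each grid azimuth into ``pattern``;
    azimuths present in the directory define the grid.
    """
    directory = Path(directory)
    azimuths, left, right = [], [], []
    fs = None
    for az in range(-90, 95, 5):
        path = directory / pattern.format(az=az)
        if not path.exists():
            continue
        fs_i, data = wavfile.read(path)
        if data.ndim != 2 or data.shape[1] != 2:
            raise ValueError(f"{path} is not a stereo WAV")
        if data.dtype.kind == "i":
            data = data / np.iinfo(data.dtype).max
        if fs is None:
            fs = fs_i
        elif fs != fs_i:
            raise ValueError(f"{path}: sample rate {fs_i} != {fs}")
        azimuths.append(float(az))
        left.append(np.asarray(data[:, 0], dtype=float))
        right.append(np.asarray(data[:, 1], dtype=float))
    if not azimuths:
        raise FileNotFoundError(f"no HRIR WAV files matching {pattern!r} in {directory}")
    return HRIRSet(azimuths=np.array(azimuths), left=left, right=right,
                   fs_hz=int(fs), provenance="loaded")


def load_hrir_sofa(path: str | Path) -> HRIRSet:
    """Load an HRIR set from a SOFA (HDF5) file, horizontal plane only."""
    import h5py

    with h5py.File(path, "r") as f:
        ir = np.asarray(f["Data.IR"])           # (M, 2, N)
        pos = np.asarray(f["SourcePosition"])   # (M, 3): az, el, r
        fs = int(np.asarray(f["Data.SamplingRate"]).ravel()[0])
    horiz = np.abs(pos[:, 1]) < 1e-6
    az = pos[horiz, 0]
    az = np.where(az > 180, az - 360, az)  # SOFA convention: CCW 0..360
    keep = np.abs(az) <= 90
    idx = np.flatnonzero(horiz)[keep]
    return HRIRSet(
        azimuths=-az[keep],  # SOFA azimuth is counter-clockwise positive
        left=[ir[i, 0] for i in idx],
        right=[ir[i, 1] for i in idx],
        fs_hz=fs,
        provenance="loaded",
    )


def spatialize(
    wave: np.ndarray,
    azimuth_deg: float,
    hrirs: HRIRSet,
    room: RoomSpec,
) -> np.ndarray:
    """Render a mono waveform at an azimuth: wave (*) room IR (*) HRIR per ear.

    The room IR is computed for the requested azimuth and convolved with the
    same-azimuth HRIR (reflections share the direct-path HRIR), reproducing
    the construction of a distance-cueing 'reverberant HRTF'.  Returns an
    (n, 2) float array.
    """
    if abs(azimuth_deg) > 90:
        raise ValueError(f"azimuth {azimuth_deg} outside +/-90 degrees")
    ir = build_room_ir(room, azimuth_deg, hrirs.fs_hz).taps
    left, right = hrirs[azimuth_deg]
    wl = fftconvolve(fftconvolve(wave, ir), left)
    wr = fftconvolve(fftconvolve(wave, ir), right)
    return np.column_stack([wl, wr])


def write_wav(path: str | Path, stereo: np.ndarray, fs_hz: int = 44100,
              dtype: str = "float32") -> None:
    """Write a waveform to WAV (float32 by default, or PCM16)."""
    if dtype == "float32":
        wavfile.write(path, fs_hz, stereo.astype(np.float32))
    elif dtype == "pcm16":
        peak = np.max(np.abs(stereo))
        scaled = stereo / peak * 0.999 if peak > 1 else stereo
        wavfile.write(path, fs_hz, (scaled * 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
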