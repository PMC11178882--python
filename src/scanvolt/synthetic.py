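"""Seeded synthetic scanless-2P voltage-imaging movies with ground truth.

Emulates camera recordings of a negative-going, membrane-localised voltage
indicator under sculpted two-photon illumination: soma-sized fluorescent
annuli, voltage-dependent dimming (defaults calibrated to ~43% -dF/F0 per
100 mV), quadratic scaling of baseline fluorescence with excitation power
density, Poisson shot noise, photobleaching to ~0.80 of the initial
fluorescence over 3 s of continuous illumination with ~0.97 recovery after
2.5 s in the dark, and the five electrophysiology command protocols used to
characterise the approach (voltage steps, AP-like pulse trains, frequency
trains, sub-threshold steps and random spiking over 30 s).

All randomness derives from one master seed through named substreams, so a
(configuration, seed) pair reproduces a movie bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AcquisitionConfig",
    "CellModel",
    "IlluminationSpec",
    "ProtocolSpec",
    "GroundTruth",
    "Movie",
    "BleachModel",
    "max_rows_at_rate",
    "make_protocol",
    "voltage_to_fluorescence",
    "bleach_profile",
    "render_movie",
    "make_multi_target_scene",
    "simulate_counts_trace",
]

WAVEFORM_RATE_HZ = 10_000.0      # command-voltage sampling (ephys digitiser)
_SENSOR_MAX_ROWS = 3200          # full sensor height, rows

# substream keys (mixed with the master seed)
_STREAM_SCENE, _STREAM_SHOT, _STREAM_SPIKES, _STREAM_SPECKLE = 11, 13, 17, 19


def max_rows_at_rate(frame_rate_hz: float) -> int:
    """Camera row budget at a given frame rate (266 rows at 1 kHz,
    scaling inversely with rate, e.g. 532 rows at 500 Hz)."""
    return int(min(math.floor(266 * 1000.0 / frame_rate_hz), _SENSOR_MAX_ROWS))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera acquisition settings."""

    frame_rate_hz: float = 500.0
    exposure_ms: float | None = None     # defaults to the full frame period
    pixel_size_um: float = 0.1625
    roi_shape: tuple[int, int] = (64, 64)   # (rows, cols)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not (0 < self.frame_rate_hz):
            raise ValueError("frame rate must be positive")
        period_ms = 1000.0 / self.frame_rate_hz
        if self.exposure_ms is not None and self.exposure_ms > period_ms + 1e-9:
            raise ValueError("exposure must not exceed the frame period")
        if self.roi_shape[0] > max_rows_at_rate(self.frame_rate_hz):
            raise ValueError(
                f"{self.roi_shape[0]} rows exceeds the "
                f"{max_rows_at_rate(self.frame_rate_hz)}-row limit at "
                f"{self.frame_rate_hz:g} Hz (266 rows at 1 kHz)")

    @property
    def effective_exposure_ms(self) -> float:
        return (self.exposure_ms if self.exposure_ms is not None
                else 1000.0 / self.frame_rate_hz)

    @property
    def fov_um(self) -> tuple[float, float]:
        return (self.roi_shape[0] * self.pixel_size_um,
                self.roi_shape[1] * self.pixel_size_um)


@dataclass(frozen=True)
class CellModel:
    """Geometry and photophysics of one fluorescent cell.

    ``expression_F0`` is the mean baseline photon count per membrane pixel
    per frame at the reference power density.  ``sensitivity`` is the
    fractional fluorescence *decrease* per 100 mV of depolarisation.
    """

    centroid_um: tuple[float, float] = (0.0, 0.0)
    soma_diameter_um: float = 14.0
    membrane_annulus_width_um: float = 1.0
    expression_F0: float = 100.0
    sensitivity: float = 0.43
    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.soma_diameter_um <= 0:
            raise ValueError("soma diameter must be positive")
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValueError("sensitivity must lie in [0, 1]")
        if self.expression_F0 < 0:
            raise ValueError("F0 must be non-negative")


@dataclass(frozen=True)
class IlluminationSpec:
    """Excitation spot and temporal schedule.

    ``power_per_target_mw`` is tied to the power density through the spot
    area convention  P = power_density * pi * (FWHM/2)^2  (top-hat of the
    stated FWHM diameter).  Baseline fluorescence scales as
    (power_density / reference_power_density)^2 (two-photon excitation).
    """

    spot_fwhm_um: float = 12.0
    power_density_mw_um2: float = 0.88
    reference_power_density_mw_um2: float = 0.88
    wavelength_nm: float = 940.0
    epochs_ms: tuple[tuple[float, float], ...] | None = None  # None: protocol's
    speckle_sigma: float = 0.0    # log-normal static gain field (0 = off)

    def __post_init__(self) -> None:
        if self.spot_fwhm_um <= 0 or self.power_density_mw_um2 < 0:
            raise ValueError("invalid illumination parameters")
        if self.epochs_ms is not None:
            prev = -math.inf
            for on, off in self.epochs_ms:
                if off <= on or on < prev:
                    raise ValueError("epochs must be chronological and "
                                     "non-overlapping")
                prev = off

    @property
    def spot_area_um2(self) -> float:
        return math.pi * (self.spot_fwhm_um / 2.0) ** 2

    @property
    def power_per_target_mw(self) -> float:
        return self.power_density_mw_um2 * self.spot_area_um2

    @property
    def power_scale(self) -> float:
        """Quadratic 2P baseline-fluorescence factor relative to reference."""
        return (self.power_density_mw_um2 /
                self.reference_power_density_mw_um2) ** 2


@dataclass(frozen=True)
class BleachModel:
    """Single-exponential photobleaching with a floor, plus dark recovery.

    Calibrated so that 3 s of continuous illumination at the reference
    power density bleaches to ``end_fraction_3s`` of the initial
    fluorescence, and a 2.5 s dark interval recovers to
    ``recovery_fraction`` of the previous epoch-start value.  The bleach
    rate scales quadratically with power density (two-photon excitation).
    """

    end_fraction_3s: float = 0.80
    floor: float = 0.5
    recovery_fraction: float = 0.97
    recovery_tau_s: float = 0.55

    @property
    def tau_s(self) -> float:
        frac = (self.end_fraction_3s - self.floor) / (1.0 - self.floor)
        return 3.0 / math.log(1.0 / frac)


@dataclass(frozen=True)
class ProtocolSpec:
    """Command-voltage waveform plus the protocol's illumination schedule."""

    protocol_id: int
    waveform_mv: np.ndarray            # sampled at WAVEFORM_RATE_HZ
    holding_mv: float
    spike_times_ms: tuple[float, ...]
    illumination_epochs_ms: tuple[tuple[float, float], ...]
    step_amplitudes_mv: tuple[float, ...] = ()
    seed: int | None = None

    @property
    def duration_ms(self) -> float:
        return len(self.waveform_mv) / WAVEFORM_RATE_HZ * 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.waveform_mv)) / WAVEFORM_RATE_HZ * 1000.0

    @property
    def delta_v_mv(self) -> np.ndarray:
        """Depolarisation relative to holding."""
        return self.waveform_mv - self.holding_mv


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis should recover."""

    protocol: ProtocolSpec
    spike_times_ms: dict[int, tuple[float, ...]]   # per cell id
    bleach: BleachModel
    seed: int
    cell_masks: list[np.ndarray] = field(default_factory=list)
    relative_fluorescence: np.ndarray | None = None  # per-frame ideal, (T, n_cells)


@dataclass
class Movie:
    """Photon-count stack with acquisition metadata."""

    data: np.ndarray                   # (T, Y, X) uint16
    frame_rate_hz: float
    pixel_size_um: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_times_ms(self) -> np.ndarray:
        """Timestamps at exposure start."""
        return np.arange(self.n_frames) * 1000.0 / self.frame_rate_hz


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def _steps_waveform(duration_ms, holding, onsets, durations, amplitudes):
    n = int(round(duration_ms * WAVEFORM_RATE_HZ / 1000.0))
    w = np.full(n, float(holding))
    for on, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(on * WAVEFORM_RATE_HZ / 1000.0))
        i1 = int(round((on + dur) * WAVEFORM_RATE_HZ / 1000.0))
        if i0 < 0 or dur < 0:
            raise ValueError("negative onset or duration")
        w[i0:i1] = holding + amp
    return w


def make_protocol(protocol_id: int, *, step_amplitude_mv: float = 100.0,
                  seed: int = 0, spike_rate_hz: float = 5.0 / 3.0,
                  refractory_ms: float = 20.0,
                  duration_ms: float | None = None,
                  train_hz: float = 20.0, n_pulses: int = 10) -> ProtocolSpec:
    """Build one of the five stimulus protocols.

    1: three 100 ms steps of ``step_amplitude_mv`` (default 100 mV) from a
       -55 mV holding potential under 3 s of continuous illumination.
    2: the same three steps under strobed illumination (200 ms pulses
       centred on each step, steps 2.5 s apart).
    3: a 20 Hz train of ten 3 ms, 100 mV AP-like pulses within a 500 ms
       illuminated window (-75 mV holding); ``train_hz`` / ``n_pulses``
       generalise it to the 25-125 Hz frequency-train recordings.
    4: six 20 ms sub-threshold steps, 0 to 2.5 mV in 0.5 mV increments,
       30 ms apart, each under a 40 ms strobe.
    5: random (Poisson, refractory-constrained) AP-like pulses over a 30 s
       continuously illuminated recording, drawn from ``seed``
       (``duration_ms`` overrides the recording length).
    """
    if protocol_id == 1:
        onsets = (500.0, 1500.0, 2500.0)
        w = _steps_waveform(3000.0, -55.0, onsets, [100.0] * 3,
                            [step_amplitude_mv] * 3)
        return ProtocolSpec(1, w, -55.0, (), ((0.0, 3000.0),),
                            (step_amplitude_mv,) * 3)
    if protocol_id == 2:
        onsets = tuple(1250.0 + 2500.0 * k for k in range(3))
        w = _steps_waveform(7500.0, -55.0, onsets, [100.0] * 3,
                            [step_amplitude_mv] * 3)
        epochs = tuple((on - 50.0, on + 150.0) for on in onsets)
        return ProtocolSpec(2, w, -55.0, (), epochs,
                            (step_amplitude_mv,) * 3)
    if protocol_id == 3:
        if train_hz <= 0 or n_pulses < 1:
            raise ValueError("train frequency and pulse count must be positive")
        period = 1000.0 / train_hz
        onsets = tuple(25.0 + period * k for k in range(n_pulses))
        dur = max(500.0, onsets[-1] + 25.0)
        w = _steps_waveform(dur, -75.0, onsets, [3.0] * n_pulses,
                            [100.0] * n_pulses)
        return ProtocolSpec(3, w, -75.0, onsets, ((0.0, dur),))
    if protocol_id == 4:
        amps = tuple(0.5 * k for k in range(6))
        onsets = tuple(20.0 + 50.0 * k for k in range(6))
        w = _steps_waveform(320.0, -75.0, onsets, [20.0] * 6, amps)
        epochs = tuple((on - 10.0, on + 30.0) for on in onsets)
        return ProtocolSpec(4, w, -75.0, (), epochs, amps)
    if protocol_id == 5:
        duration = 30_000.0 if duration_ms is None else float(duration_ms)
        rng = np.random.default_rng([seed, _STREAM_SPIKES])
        times, t = [], 0.0
        while True:
            t += rng.exponential(1000.0 / spike_rate_hz)
            t = max(t, (times[-1] + refractory_ms) if times else 0.0)
            if t >= duration - 10.0:
                break
            times.append(t)
        onsets = tuple(times)
        w = _steps_waveform(duration, -75.0, onsets, [3.0] * len(onsets),
                            [100.0] * len(onsets))
        return ProtocolSpec(5, w, -75.0, onsets, ((0.0, duration),),
                            seed=seed)
    raise ValueError(f"unknown protocol id {protocol_id!r} (must be 1-5)")


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _kinetic_kernel(cell: CellModel) -> np.ndarray:
    """Unit-area rise/decay kernel at the waveform rate."""
    dt_ms = 1000.0 / WAVEFORM_RATE_HZ
    t = np.arange(0.0, 10.0 * cell.tau_decay_ms + dt_ms, dt_ms)
    k = np.exp(-t / cell.tau_decay_ms) - np.exp(-t / cell.tau_rise_ms)
    s = k.sum()
    if s <= 0:
        raise ValueError("degenerate kinetic kernel")
    return k / s


def voltage_to_fluorescence(protocol: ProtocolSpec, cell: CellModel,
                            fv_curve=None) -> np.ndarray:
    """Ideal relative fluorescence (1 = baseline) at the waveform rate.

    Linear negative-going response by default, F/F0 = 1 - s * dV / 100 mV,
    convolved with the cell's unit-area kinetic kernel (so steady-state
    amplitudes are preserved).  ``fv_curve`` replaces the linear F-V
    relation with an arbitrary map from depolarisation (mV) to fractional
    fluorescence decrease, e.g. :func:`sigmoid_fv` for a saturating
    response.
    """
    if fv_curve is None:
        drive = cell.sensitivity * protocol.delta_v_mv / 100.0
    else:
        drive = np.asarray(fv_curve(protocol.delta_v_mv), dtype=float)
    kern = _kinetic_kernel(cell)
    filtered = np.convolve(drive, kern)[:len(drive)]
    return 1.0 - filtered


def sigmoid_fv(max_response: float = 0.6, v_half_mv: float = 60.0,
               slope_mv: float = 30.0):
    """Saturating F-V relation: fractional dimming vs depolarisation.

    Normalised to pass through zero at rest; approaches ``max_response``
    for large depolarisations.
    """
    def curve(dv_mv):
        dv = np.asarray(dv_mv, dtype=float)
        rest = 1.0 / (1.0 + np.exp(v_half_mv / slope_mv))
        val = 1.0 / (1.0 + np.exp(-(dv - v_half_mv) / slope_mv))
        return max_response * (val - rest) / (1.0 - rest)
    return curve


def bleach_profile(times_s: np.ndarray,
                   epochs_s: Sequence[tuple[float, float]],
                   bleach: BleachModel = BleachModel(),
                   power_scale: float = 1.0) -> np.ndarray:
    """Bleach factor b(t) for an illumination schedule.

    During illumination b decays exponentially toward the floor with the
    calibrated time constant (rate scaled by ``power_scale``, the squared
    power-density ratio); during dark intervals b recovers toward
    ``recovery_fraction`` times the previous epoch-start value with time
    constant ``recovery_tau_s``.  Recovery never reduces b.
    """
    times = np.asarray(times_s, dtype=float)
    out = np.ones_like(times)
    rate = power_scale / bleach.tau_s
    b, epoch_start_b = 1.0, 1.0
    prev_off = None
    for on, off in epochs_s:
        if prev_off is not None and on > prev_off:
            target = max(bleach.recovery_fraction * epoch_start_b, b)
            dark = np.clip(times - prev_off, 0.0, on - prev_off)
            in_dark = (times >= prev_off)
            out[in_dark] = target - (target - b) * np.exp(
                -dark[in_dark] / bleach.recovery_tau_s)
            b = target - (target - b) * math.exp(
                -(on - prev_off) / bleach.recovery_tau_s)
        epoch_start_b = b
        amp = b - bleach.floor
        dt_on = np.clip(times - on, 0.0, off - on)
        lit = times >= on
        out[lit] = bleach.floor + amp * np.exp(-rate * dt_on[lit])
        b = bleach.floor + amp * math.exp(-rate * (off - on))
        prev_off = off
    return out


def _frame_average(x_10k: np.ndarray, acq: AcquisitionConfig,
                   n_frames: int) -> np.ndarray:
    """Average a waveform-rate signal over each frame's exposure window."""
    samples_per_frame = WAVEFORM_RATE_HZ / acq.frame_rate_hz
    exp_samples = max(int(round(acq.effective_exposure_ms
                                * WAVEFORM_RATE_HZ / 1000.0)), 1)
    spf = int(round(samples_per_frame))
    if abs(samples_per_frame - spf) < 1e-9 and n_frames * spf <= len(x_10k):
        blocks = x_10k[:n_frames * spf].reshape(n_frames, spf)
        return blocks[:, :exp_samples].mean(axis=1)
    out = np.empty(n_frames)
    for i in range(n_frames):
        i0 = int(round(i * samples_per_frame))
        seg = x_10k[i0:i0 + exp_samples]
        out[i] = seg.mean() if seg.size else x_10k[-1]
    return out


def _gate_profile(epochs_ms, times_ms):
    gate = np.zeros_like(times_ms)
    for on, off in epochs_ms:
        gate[(times_ms >= on) & (times_ms < off)] = 1.0
    return gate


def _annulus_mask(cell: CellModel, acq: AcquisitionConfig) -> np.ndarray:
    rows, cols = acq.roi_shape
    y = (np.arange(rows) + 0.5) * acq.pixel_size_um
    x = (np.arange(cols) + 0.5) * acq.pixel_size_um
    X, Y = np.meshgrid(x, y)
    r = np.hypot(X - cell.centroid_um[0], Y - cell.centroid_um[1])
    r_out = cell.soma_diameter_um / 2.0
    return (r <= r_out) & (r >= r_out - cell.membrane_annulus_width_um)


def render_movie(cells: Sequence[CellModel], protocol: ProtocolSpec,
                 illum: IlluminationSpec, acq: AcquisitionConfig,
                 seed: int, background: float = 10.0,
                 bleach: BleachModel = BleachModel(),
                 crosstalk_gain: float = 0.0,
                 spike_jitter_ms: float = 0.0) -> tuple[Movie, GroundTruth]:
    """Render a Poisson photon-count movie plus its ground truth.

    Per-pixel expected counts are
    ``background + annulus * F0 * power_scale * relF(t) * bleach(t) * gate(t)``
    with ``power_scale`` the quadratic 2P power-density factor.  Realised
    counts are Poisson draws from a seed-derived substream, so the stack is
    bit-identical for a fixed (configuration, seed).

    ``crosstalk_gain`` adds a voltage-modulated component to the background
    (out-of-target fluorescence), for signal-to-background studies.
    ``spike_jitter_ms`` jitters each cell's spike train independently so
    multi-cell movies are not perfectly synchronous.
    """
    rows, cols = acq.roi_shape
    n_frames = int(protocol.duration_ms / 1000.0 * acq.frame_rate_hz)
    if n_frames <= 0:
        raise ValueError("protocol too short for one frame")
    fov = acq.fov_um
    for c in cells:
        x, y = c.centroid_um
        if not (0 <= x <= fov[1] and 0 <= y <= fov[0]):
            raise ValueError(f"cell centroid {c.centroid_um} outside FOV "
                             f"{fov}")

    epochs = (illum.epochs_ms if illum.epochs_ms is not None
              else protocol.illumination_epochs_ms)
    t10k_ms = protocol.times_ms
    gate_10k = _gate_profile(epochs, t10k_ms)
    bleach_10k = bleach_profile(t10k_ms / 1000.0,
                                [(a / 1000.0, b / 1000.0) for a, b in epochs],
                                bleach, illum.power_scale)
    gate_f = _frame_average(gate_10k, acq, n_frames)
    bleach_f = _frame_average(bleach_10k, acq, n_frames)

    rng_spikes = np.random.default_rng([seed, _STREAM_SPIKES, 101])
    rng_shot = np.random.default_rng([seed, _STREAM_SHOT])
    rng_speckle = np.random.default_rng([seed, _STREAM_SPECKLE])

    expected = np.full((n_frames, rows, cols), float(background))
    truth_spikes: dict[int, tuple[float, ...]] = {}
    masks, rel_frames = [], []
    for ci, cell in enumerate(cells):
        proto_c = protocol
        if spike_jitter_ms > 0 and protocol.spike_times_ms:
            jit = tuple(np.sort(np.asarray(protocol.spike_times_ms)
                                + rng_spikes.uniform(-spike_jitter_ms,
                                                     spike_jitter_ms,
                                                     len(protocol.spike_times_ms))))
            w = _steps_waveform(protocol.duration_ms, protocol.holding_mv,
                                jit, [3.0] * len(jit), [100.0] * len(jit))
            proto_c = replace(protocol, waveform_mv=w, spike_times_ms=jit)
        truth_spikes[ci] = proto_c.spike_times_ms
        rel_10k = voltage_to_fluorescence(proto_c, cell)
        rel_f = _frame_average(rel_10k, acq, n_frames)
        rel_frames.append(rel_f)

        mask = _annulus_mask(cell, acq)
        masks.append(mask)
        gain = np.ones(int(mask.sum()))
        if illum.speckle_sigma > 0:
            gain = rng_speckle.lognormal(
                -illum.speckle_sigma ** 2 / 2, illum.speckle_sigma,
                int(mask.sum()))
        f0 = cell.expression_F0 * illum.power_scale
        signal_t = f0 * rel_f * bleach_f * gate_f          # (T,)
        expected[:, mask] += signal_t[:, None] * gain[None, :]
        if crosstalk_gain > 0:
            # out-of-target fluorescence that shares the cell's voltage
            # modulation (scattered/out-of-focus light)
            bg_fluor = crosstalk_gain * f0 * rel_f * bleach_f * gate_f
            expected[:, ~mask] += bg_fluor[:, None]

    counts = rng_shot.poisson(np.maximum(expected, 0.0))
    counts = np.minimum(counts, 2 ** acq.bit_depth - 1).astype(np.uint16)
    movie = Movie(counts, acq.frame_rate_hz, acq.pixel_size_um,
                  metadata={"seed": seed, "protocol": protocol.protocol_id,
                            "power_density_mw_um2": illum.power_density_mw_um2,
                            "n_cells": len(cells)})
    truth = GroundTruth(protocol, truth_spikes, bleach, seed, masks,
                        np.column_stack(rel_frames) if rel_frames else None)
    return movie, truth


def make_multi_target_scene(n_targets: int, fov_um: float = 300.0,
                            min_separation_um: float = 25.0,
                            seed: int = 0,
                            soma_diameter_um: float = 14.0,
                            max_tries: int = 10_000) -> list[CellModel]:
    """Uniformly place cells in the field with a minimum pairwise distance.

    Simple dart-throwing (rejection) sampling with a bounded retry budget;
    raises if the requested packing is infeasible within that budget.
    """
    rng = np.random.default_rng([seed, _STREAM_SCENE])
    margin = soma_diameter_um / 2.0
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n_targets:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_targets} targets with separation "
                f">= {min_separation_um} um in {fov_um} um after "
                f"{max_tries} tries")
        tries += 1
        x, y = rng.uniform(margin, fov_um - margin, 2)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_separation_um ** 2
               for px, py in pts):
            pts.append((float(x), float(y)))
    return [CellModel(centroid_um=p, soma_diameter_um=soma_diameter_um)
            for p in pts]


def simulate_counts_trace(protocol: ProtocolSpec, cell: CellModel,
                          acq: AcquisitionConfig, seed: int,
                          photons_per_frame: float = 10_000.0,
                          illum: IlluminationSpec | None = None,
                          bleach: BleachModel = BleachModel()
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Trace-level shortcut: summed photon counts per frame for one cell.

    Skips the spatial rendering (equivalent to the weighted sum over the
    membrane pixels collecting ``photons_per_frame`` at baseline); useful
    for detection/averaging studies where only the temporal statistics
    matter.  Returns (times_ms, counts).
    """
    illum = illum or IlluminationSpec()
    n_frames = int(protocol.duration_ms / 1000.0 * acq.frame_rate_hz)
    epochs = (illum.epochs_ms if illum.epochs_ms is not None
              else protocol.illumination_epochs_ms)
    t10k = protocol.times_ms
    rel = voltage_to_fluorescence(protocol, cell)
    gate = _gate_profile(epochs, t10k)
    bl = bleach_profile(t10k / 1000.0,
                        [(a / 1000.0, b / 1000.0) for a, b in epochs],
                        bleach, illum.power_scale)
    expect = photons_per_frame * illum.power_scale * _frame_average(
        rel * gate * bl, acq, n_frames)
    rng = np.random.default_rng([seed, _STREAM_SHOT, 7])
    counts = rng.poisson(np.maximum(expect, 0.0)).astype(float)
    times_ms = np.arange(n_frames) * 1000.0 / acq.frame_rate_hz
    return times_ms, counts
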