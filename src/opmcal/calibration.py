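"""Matrix-coil array calibration: reference fields, demodulation, solvers.

The calibration imposes eight simultaneous reference fields on the array —
three uniform fields (nominally 0.2 nT along x, y, z at 3, 4, 5 Hz) and the
five independent field gradients (nominally 2 nT/m at 6–10 Hz) — and recovers
every channel's sensitive orientation, gain and position from the signed
in-phase response at each drive frequency:

* orientation/gain: b = Bu g, solved as g = Bu⁺ b; the direction of g is the
  channel orientation and |g| its gain.
* position: bg = BG r with row k of BG equal to gain·uᵀ·G_k, solved by
  least squares, r = BG⁺ bg.

A sensor's position is reported as the mean of its three channel positions.

The amplitudes (0.2 nT, 2 nT/m) keep the superposed field below 1 nT at every
cell so open-loop sensors stay in their linear regime; the 3–10 Hz frequency
comb makes a 1-s rectangular window contain an integer number of cycles of
every component, so the eight demodulated estimates are exactly orthogonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrays import SensorArray, channel_matrices
from .errors import (
    DeadChannelError,
    DegenerateOrientationError,
    InvalidArgumentError,
    InvalidDesignError,
)
from .fields import gradient_basis_tensors
from .timeseries import TimeSeries

UNIFORM_AMPLITUDE = 0.2e-9  # tesla
GRADIENT_AMPLITUDE = 2.0e-9  # tesla / metre
DEFAULT_SAMPLE_RATE = 375.0  # Hz
DEFAULT_DURATION = 4.0  # s
DEFAULT_WINDOW_START = 0.5  # s, settle margin before the 1-s analysis window
DEFAULT_WINDOW_LENGTH = 1.0  # s
DEAD_GAIN_THRESHOLD = 1e-6


@dataclass(frozen=True)
class CalibrationComponent:
    kind: str  # "uniform" | "gradient"
    pattern: int  # axis index 0..2 (uniform) or gradient index 0..4
    amplitude: float  # tesla or tesla/metre
    frequency: float  # Hz


@dataclass(frozen=True)
class CalibrationProtocol:
    """The eight frequency-multiplexed reference-field components."""

    components: tuple[CalibrationComponent, ...]
    duration: float = DEFAULT_DURATION
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self):
        kinds = [c.kind for c in self.components]
        if kinds.count("uniform") != 3 or kinds.count("gradient") != 5:
            raise InvalidArgumentError("protocol needs exactly 3 uniform + 5 gradient components")
        freqs = [c.frequency for c in self.components]
        if len(set(freqs)) != len(freqs):
            raise InvalidArgumentError("component frequencies must be distinct")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([c.frequency for c in self.components])

    @property
    def uniform_components(self) -> list[CalibrationComponent]:
        return [c for c in self.components if c.kind == "uniform"]

    @property
    def gradient_components(self) -> list[CalibrationComponent]:
        return [c for c in self.components if c.kind == "gradient"]


def default_protocol() -> CalibrationProtocol:
    """3, 4, 5 Hz uniform x/y/z at 0.2 nT; 6–10 Hz gradients at 2 nT/m; 4 s at 375 Hz."""
    comps = [
        CalibrationComponent("uniform", axis, UNIFORM_AMPLITUDE, 3.0 + axis)
        for axis in range(3)
    ] + [
        CalibrationComponent("gradient", k, GRADIENT_AMPLITUDE, 6.0 + k)
        for k in range(5)
    ]
    return CalibrationProtocol(components=tuple(comps))


@dataclass
class CalibrationDesign:
    """Known reference-field patterns in solver-ready form.

    ``uniform_matrix`` rows are the three uniform field vectors (tesla), so
    the nominal axis-aligned protocol yields the diagonal Bu matrix;
    ``gradient_tensors`` is (5,3,3) with each G_k at protocol amplitude.
    Arbitrary (e.g. rigidly rotated) patterns are supported, which is what
    makes the calibration's rotational equivariance testable.
    """

    uniform_matrix: np.ndarray
    gradient_tensors: np.ndarray

    def __post_init__(self):
        self.uniform_matrix = np.asarray(self.uniform_matrix, dtype=float)
        self.gradient_tensors = np.asarray(self.gradient_tensors, dtype=float)
        if self.uniform_matrix.shape != (3, 3):
            raise InvalidDesignError("uniform_matrix must be 3x3")
        if self.gradient_tensors.shape != (5, 3, 3):
            raise InvalidDesignError("gradient_tensors must be (5,3,3)")
        for G in self.gradient_tensors:
            if not np.allclose(G, G.T, atol=1e-20):
                raise InvalidDesignError("gradient tensors must be symmetric")
            scale = max(np.abs(G).max(), 1e-30)
            if abs(np.trace(G)) > 1e-12 * scale:
                raise InvalidDesignError("gradient tensors must be traceless")

    @classmethod
    def from_protocol(cls, protocol: CalibrationProtocol) -> "CalibrationDesign":
        U = np.zeros((3, 3))
        for j, c in enumerate(protocol.uniform_components):
            U[j, c.pattern] = c.amplitude
        basis = gradient_basis_tensors(1.0)
        G = np.stack([c.amplitude * basis[c.pattern] for c in protocol.gradient_components])
        return cls(uniform_matrix=U, gradient_tensors=G)

    def rotated(self, R: np.ndarray) -> "CalibrationDesign":
        """The same patterns rigidly rotated by R (fields R·B, tensors R·G·Rᵀ)."""
        return CalibrationDesign(
            uniform_matrix=self.uniform_matrix @ R.T,
            gradient_tensors=np.einsum("ab,kbc,dc->kad", R, self.gradient_tensors, R),
        )


@dataclass
class DemodulatedResponse:
    """Signed in-phase amplitudes per channel: b (N,3) and bg (N,5), tesla."""

    b: np.ndarray
    bg: np.ndarray


def component_amplitudes(
    array_geometry, protocol: CalibrationProtocol, design: CalibrationDesign | None = None
) -> np.ndarray:
    """Noise-free per-channel signed amplitude of each protocol component (N,8)."""
    if design is None:
        design = CalibrationDesign.from_protocol(protocol)
    positions, orientations, gains = (
        array_geometry.channel_matrices()
        if hasattr(array_geometry, "channel_matrices")
        else array_geometry
    )
    n = positions.shape[0]
    amps = np.empty((n, 8))
    col = 0
    for j, _c in enumerate(protocol.uniform_components):
        amps[:, col] = gains * (orientations @ design.uniform_matrix[j])
        col += 1
    for k, _c in enumerate(protocol.gradient_components):
        Bk = positions @ design.gradient_tensors[k].T
        amps[:, col] = gains * np.einsum("ij,ij->i", Bk, orientations)
        col += 1
    return amps


def superposed_field_max(
    slots_or_positions, protocol: CalibrationProtocol | None = None,
    design: CalibrationDesign | None = None,
) -> float:
    """Max |B| of the superposed eight-component field over cells and time (tesla).

    Deterministic safety check: the OPMs only stay linear in open loop if the
    total reference field never exceeds ~1 nT anywhere in the helmet.
    """
    if protocol is None:
        protocol = default_protocol()
    if design is None:
        design = CalibrationDesign.from_protocol(protocol)
    pos = np.asarray(
        [s.cell_position for s in slots_or_positions]
        if hasattr(slots_or_positions[0], "cell_position")
        else slots_or_positions,
        dtype=float,
    )
    t = np.arange(int(round(protocol.duration * protocol.sample_rate))) / protocol.sample_rate
    drives = np.sin(2.0 * np.pi * protocol.frequencies[:, None] * t[None, :])  # (8,T)
    # per-position field vector of each component: (8, P, 3)
    comp_fields = np.empty((8, pos.shape[0], 3))
    for j in range(3):
        comp_fields[j] = design.uniform_matrix[j]
    for k in range(5):
        comp_fields[3 + k] = pos @ design.gradient_tensors[k].T
    total = np.einsum("kpc,kt->ptc", comp_fields, drives)
    return float(np.linalg.norm(total, axis=2).max())


def simulate_calibration_recording(
    array: SensorArray,
    protocol: CalibrationProtocol | None = None,
    seed: int = 0,
    design: CalibrationDesign | None = None,
) -> TimeSeries:
    """Simulate the array's response to the eight simultaneous reference fields.

    Channel i at time t measures the sum over components of its signed
    amplitude times sin(2π f_k t), plus white Gaussian noise with per-sample
    sigma = noise_density·sqrt(sample_rate/2).  Deterministic given ``seed``.
    """
    if protocol is None:
        protocol = default_protocol()
    rng = np.random.default_rng(seed)
    n_samp = int(round(protocol.duration * protocol.sample_rate))
    t = np.arange(n_samp) / protocol.sample_rate
    drives = np.sin(2.0 * np.pi * protocol.frequencies[:, None] * t[None, :])
    amps = component_amplitudes(array, protocol, design)
    data = amps @ drives
    sigma = array.noise_densities() * 1e-15 * np.sqrt(protocol.sample_rate / 2.0)
    data += rng.normal(size=data.shape) * sigma[:, None]
    ids = [f"s{c.sensor_id:03d}{c.axis_label}" for c in array.channels]
    return TimeSeries(data=data, sample_rate=protocol.sample_rate, channel_ids=ids,
                      events=[("stimulus_on", 0)])


def demodulate(
    ts: TimeSeries,
    protocol: CalibrationProtocol,
    window_start: float = DEFAULT_WINDOW_START,
    window_length: float = DEFAULT_WINDOW_LENGTH,
) -> DemodulatedResponse:
    """Signed in-phase amplitude of every protocol component for every channel.

    amplitude at f_k = (2/N) Σ_t x(t)·sin(2π f_k t), over a rectangular window
    containing an integer number of cycles of every component; the reference
    sine has zero phase at stimulus onset (sample 0), so signs are relative to
    the drive.  Integer-cycle windows make distinct components exactly
    orthogonal (no spectral leakage).
    """
    freqs = protocol.frequencies
    for f in freqs:
        cycles = f * window_length
        if abs(cycles - round(cycles)) > 1e-9:
            raise InvalidArgumentError(
                f"window_length {window_length} s is not an integer number of "
                f"cycles at {f} Hz"
            )
    fs = ts.sample_rate
    i0 = int(round(window_start * fs))
    n = int(round(window_length * fs))
    if i0 < 0 or i0 + n > ts.n_samples:
        raise InvalidArgumentError("demodulation window outside the recording")
    t_abs = (i0 + np.arange(n)) / fs
    refs = np.sin(2.0 * np.pi * freqs[:, None] * t_abs[None, :])  # (8, n)
    amps = (2.0 / n) * ts.data[:, i0:i0 + n] @ refs.T  # (N, 8)
    n_uniform = len(protocol.uniform_components)
    return DemodulatedResponse(b=amps[:, :n_uniform], bg=amps[:, n_uniform:])


def solve_orientation_gain(b, design: CalibrationDesign) -> tuple[np.ndarray, float]:
    """Solve b = Bu g for one channel: orientation = g/|g|, gain = |g|."""
    U = design.uniform_matrix
    if np.linalg.matrix_rank(U) < 3:
        raise InvalidDesignError("uniform-field design matrix is singular")
    g = np.linalg.pinv(U) @ np.asarray(b, dtype=float)
    norm = np.linalg.norm(g)
    if norm < DEAD_GAIN_THRESHOLD:
        raise DeadChannelError("channel shows no response to the uniform fields")
    return g / norm, float(norm)


def solve_position(bg, orientation, gain: float, design: CalibrationDesign) -> np.ndarray:
    """Solve bg = BG r for one channel's position by least squares.

    Row k of BG is gain·orientationᵀ·G_k — the gradient field this channel
    would report per metre of displacement along each axis.
    """
    if gain <= 0:
        raise InvalidArgumentError("gain must be positive")
    g_vec = gain * np.asarray(orientation, dtype=float)
    BG = np.einsum("j,kjl->kl", g_vec, design.gradient_tensors)  # (5,3)
    if np.linalg.matrix_rank(BG, tol=1e-12 * max(np.abs(BG).max(), 1e-30)) < 3:
        raise DegenerateOrientationError("gradient design rows span < 3 dimensions")
    r, *_ = np.linalg.lstsq(BG, np.asarray(bg, dtype=float), rcond=None)
    return r


class ArrayCalibrationModel:
    """Per-channel calibration model for a matrix-coil reference recording.

    Parameters
    ----------
    recording : TimeSeries
        The multichannel response to the eight simultaneous reference fields.
    protocol : CalibrationProtocol
        Frequencies and amplitudes of the reference components.
    sensor_ids : array-like of int
        Owning sensor id per channel (the array topology); used to average the
        three channel positions of each sensor into a sensor position.
    design : CalibrationDesign, optional
        Override the patterns implied by the protocol (e.g. rotated fields).
    """

    def __init__(self, recording: TimeSeries, protocol: CalibrationProtocol,
                 sensor_ids, design: CalibrationDesign | None = None):
        self.recording = recording
        self.protocol = protocol
        self.sensor_ids = np.asarray(sensor_ids, dtype=int)
        if self.sensor_ids.shape != (recording.n_channels,):
            raise InvalidArgumentError("sensor_ids must give one sensor per channel")
        self.design = design if design is not None else CalibrationDesign.from_protocol(protocol)

    @classmethod
    def from_array(cls, array: SensorArray, seed: int = 0,
                   protocol: CalibrationProtocol | None = None,
                   design: CalibrationDesign | None = None) -> "ArrayCalibrationModel":
        """Simulate the reference recording for ``array`` and wrap it in a model."""
        if protocol is None:
            protocol = default_protocol()
        rec = simulate_calibration_recording(array, protocol, seed=seed, design=design)
        return cls(rec, protocol, array.sensor_ids, design=design)

    def fit(self, window_start: float = DEFAULT_WINDOW_START,
            window_length: float = DEFAULT_WINDOW_LENGTH) -> "ArrayCalibrationResults":
        """Demodulate and solve orientation/gain then position for every channel.

        Channels whose solve fails (dead, degenerate) are flagged and excluded
        from sensor-position averaging; calibration completes for the rest.
        """
        demod = demodulate(self.recording, self.protocol, window_start, window_length)
        n = self.recording.n_channels
        orientations = np.full((n, 3), np.nan)
        gains = np.full(n, np.nan)
        positions = np.full((n, 3), np.nan)
        residuals = np.full(n, np.nan)
        ok = np.zeros(n, dtype=bool)
        messages: dict[int, str] = {}
        for i in range(n):
            try:
                u, gain = solve_orientation_gain(demod.b[i], self.design)
                r = solve_position(demod.bg[i], u, gain, self.design)
            except (DeadChannelError, DegenerateOrientationError, InvalidDesignError) as e:
                messages[i] = str(e)
                continue
            orientations[i] = u
            gains[i] = gain
            positions[i] = r
            g_vec = gain * u
            BG = np.einsum("j,kjl->kl", g_vec, self.design.gradient_tensors)
            residuals[i] = np.linalg.norm(BG @ r - demod.bg[i])
            ok[i] = True

        sensor_positions: dict[int, np.ndarray] = {}
        for sid in np.unique(self.sensor_ids):
            mask = (self.sensor_ids == sid) & ok
            if mask.any():
                sensor_positions[int(sid)] = positions[mask].mean(axis=0)
        return ArrayCalibrationResults(
            model=self, demod=demod, orientations=orientations, gains=gains,
            positions=positions, residuals=residuals, ok=ok,
            sensor_positions=sensor_positions, flagged=messages,
            window=(window_start, window_length),
        )


@dataclass
class ArrayCalibrationResults:
    """Estimated per-channel orientation, gain and position, with diagnostics."""

    model: ArrayCalibrationModel
    demod: DemodulatedResponse
    orientations: np.ndarray  # (N,3), NaN rows where flagged
    gains: np.ndarray  # (N,)
    positions: np.ndarray  # (N,3) m
    residuals: np.ndarray  # (N,) tesla, gradient-equation residual norm
    ok: np.ndarray  # (N,) bool
    sensor_positions: dict[int, np.ndarray]  # sensor id -> mean of 3 channel positions
    flagged: dict[int, str]
    window: tuple[float, float]

    @property
    def n_channels(self) -> int:
        return self.gains.shape[0]

    def channel_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Calibrated geometry in the same layout the forward code consumes."""
        return self.positions, self.orientations, self.gains

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sensor_id": self.model.sensor_ids,
                "gain": self.gains,
                "x_m": self.positions[:, 0],
                "y_m": self.positions[:, 1],
                "z_m": self.positions[:, 2],
                "ux": self.orientations[:, 0],
                "uy": self.orientations[:, 1],
                "uz": self.orientations[:, 2],
                "residual_T": self.residuals,
                "ok": self.ok,
            }
        )
        df.index.name = "channel"
        return df

    def compare_to_truth(self, array: SensorArray) -> "CalibrationErrorReport":
        return compare_to_truth(self, array)


@dataclass
class CalibrationErrorReport:
    """Per-channel calibration error versus a ground-truth array."""

    angle_error_deg: np.ndarray
    gain_ratio: np.ndarray
    position_error_mm: np.ndarray
    axis_labels: np.ndarray

    def summary(self) -> pd.DataFrame:
        """Mean ± sd per casing axis, mirroring per-axis histogram panels."""
        df = pd.DataFrame(
            {
                "axis": self.axis_labels,
                "angle_error_deg": self.angle_error_deg,
                "gain_ratio": self.gain_ratio,
                "position_error_mm": self.position_error_mm,
            }
        )
        return df.groupby("axis").agg(["mean", "std"])


def compare_to_truth(results: ArrayCalibrationResults, array: SensorArray) -> CalibrationErrorReport:
    """Angle error (deg), gain ratio and position error (mm) per channel."""
    if results.n_channels != array.n_channels:
        raise InvalidArgumentError("calibration and array channel counts differ")
    true_pos, true_ori, true_gain = channel_matrices(array)
    dots = np.abs(np.einsum("ij,ij->i", results.orientations, true_ori))
    angle = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
    gain_ratio = results.gains / true_gain
    pos_err = np.linalg.norm(results.positions - true_pos, axis=1) * 1e3
    labels = np.array([c.axis_label for c in array.channels])
    return CalibrationErrorReport(angle, gain_ratio, pos_err, labels)


def calibrate_array(recording: TimeSeries, protocol: CalibrationProtocol,
                    sensor_ids, window_start: float = DEFAULT_WINDOW_START,
                    window_length: float = DEFAULT_WINDOW_LENGTH,
                    design: CalibrationDesign | None = None) -> ArrayCalibrationResults:
    """Functional wrapper: build the model and fit in one call."""
    return ArrayCalibrationModel(recording, protocol, sensor_ids, design=design).fit(
        window_start, window_length
    )
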