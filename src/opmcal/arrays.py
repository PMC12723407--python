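"""Synthetic triaxial OPM arrays with ground-truth geometry, gains and noise.

A helmet is modelled as a spherical cap carrying approximately evenly spaced
sensor slots.  Each occupied slot holds one triaxial sensor contributing three
channels whose *true* sensitive orientations deviate from the casing axes by
per-axis angular offsets, and whose gains deviate from the nominal factory
value of one.  These ground truths are what the matrix-coil calibration is
later asked to recover.

Units are SI internally (metres, tesla); noise densities are carried in
fT/sqrt(Hz) because that is the unit practitioners quote sensor noise in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from ._utils import rotation_about_axis, perpendicular_unit, spawn_seeds
from .errors import InvalidArgumentError

AXIS_LABELS = ("X", "Y", "Z")

#: per-axis (mean, sd) angular offsets in degrees between the sensitive axis
#: and the casing axis, as measured for triaxial OPMs
DEFAULT_ANGLE_OFFSETS: dict[str, tuple[float, float]] = {
    "X": (18.7, 7.3),
    "Y": (4.5, 2.0),
    "Z": (9.3, 5.4),
}
DEFAULT_GAIN_RANGE = (0.8, 1.4)
DEFAULT_NOISE_DENSITY_FT = 17.0  # fT/sqrt(Hz), median empty-room channel noise
DEFAULT_SCALP_RADIUS = 0.09  # m
DEFAULT_OFFSET_MEAN = 0.0062  # m, cell-to-scalp standoff
DEFAULT_OFFSET_SD = 0.0050  # m
OFFSET_TRUNCATION = (0.001, 0.030)  # m; the printed distribution has negative mass
CAP_AREA_FRACTION = 0.7  # slots cover the upper ~70% of the sphere


@dataclass(frozen=True)
class SensorSlot:
    """One helmet slot: a cell position and the casing axis triad."""

    slot_id: int
    cell_position: np.ndarray  # (3,) m, helmet frame
    casing_axes: np.ndarray  # (3,3), rows = casing X, Y, Z unit vectors

    def __post_init__(self):
        R = np.asarray(self.casing_axes, dtype=float)
        if R.shape != (3, 3):
            raise InvalidArgumentError("casing_axes must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise InvalidArgumentError("casing_axes must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise InvalidArgumentError("casing_axes must be right-handed (det +1)")


@dataclass(frozen=True)
class TrueChannel:
    """Ground truth for one measurement axis of one sensor."""

    sensor_id: int
    axis_label: str  # "X" | "Y" | "Z"
    true_orientation: np.ndarray  # unit 3-vector
    true_gain: float
    noise_density: float  # fT/sqrt(Hz)

    def __post_init__(self):
        if self.axis_label not in AXIS_LABELS:
            raise InvalidArgumentError(f"axis_label must be one of {AXIS_LABELS}")
        if abs(np.linalg.norm(self.true_orientation) - 1.0) > 1e-12:
            raise InvalidArgumentError("true_orientation must be unit length")
        if self.true_gain <= 0:
            raise InvalidArgumentError("true_gain must be positive")
        if self.noise_density < 0:
            raise InvalidArgumentError("noise_density must be non-negative")


@dataclass
class SensorArray:
    """A triaxial array: slots plus three true channels per occupied slot."""

    slots: list[SensorSlot]
    channels: list[TrueChannel]
    frame_label: str = "helmet"

    def __post_init__(self):
        occupied = {c.sensor_id for c in self.channels}
        slot_ids = {s.slot_id for s in self.slots}
        if not occupied <= slot_ids:
            raise InvalidArgumentError("every channel must map to an existing slot")
        if len(self.channels) != 3 * len(occupied):
            raise InvalidArgumentError("expected exactly 3 channels per occupied slot")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_sensors(self) -> int:
        return len({c.sensor_id for c in self.channels})

    @property
    def sensor_ids(self) -> np.ndarray:
        """Per-channel owning sensor id, in channel declaration order."""
        return np.array([c.sensor_id for c in self.channels], dtype=int)

    def slot_by_id(self, slot_id: int) -> SensorSlot:
        for s in self.slots:
            if s.slot_id == slot_id:
                return s
        raise KeyError(slot_id)

    def channel_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return channel_matrices(self)

    def noise_densities(self) -> np.ndarray:
        """Per-channel noise density, fT/sqrt(Hz)."""
        return np.array([c.noise_density for c in self.channels])

    def cad_geometry(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CAD-file geometry: casing axes as orientations, unit gains.

        This is the 'uncalibrated' description used as the comparison arm in
        phantom QA: channel orientations are assumed orthogonal and parallel
        to the sensor casing and all gains are assumed to be one.
        """
        pos = np.empty((self.n_channels, 3))
        ori = np.empty((self.n_channels, 3))
        for i, ch in enumerate(self.channels):
            slot = self.slot_by_id(ch.sensor_id)
            pos[i] = slot.cell_position
            ori[i] = slot.casing_axes[AXIS_LABELS.index(ch.axis_label)]
        return pos, ori, np.ones(self.n_channels)


def make_helmet_slots(
    n_slots: int = 163,
    scalp_radius: float = DEFAULT_SCALP_RADIUS,
    offset_mean: float = DEFAULT_OFFSET_MEAN,
    offset_sd: float = DEFAULT_OFFSET_SD,
    seed: int = 0,
) -> list[SensorSlot]:
    """Place ``n_slots`` approximately evenly spaced slots on a head-like cap.

    Slots are laid out with a Fibonacci spiral over the upper ~70% of a sphere
    of radius ``scalp_radius``; each cell sits at ``scalp_radius + offset``
    with the offset drawn from a normal truncated to [1 mm, 30 mm].  The
    casing long axis points radially outward; the other two axes are
    tangential.
    """
    if n_slots <= 0:
        raise InvalidArgumentError("n_slots must be >= 1")
    if scalp_radius <= 0:
        raise InvalidArgumentError("scalp_radius must be positive")
    if offset_mean <= 0:
        raise InvalidArgumentError("offset_mean must be positive")
    rng = np.random.default_rng(seed)

    lo, hi = OFFSET_TRUNCATION
    if offset_sd > 0:
        a, b = (lo - offset_mean) / offset_sd, (hi - offset_mean) / offset_sd
        offsets = truncnorm.rvs(a, b, loc=offset_mean, scale=offset_sd,
                                size=n_slots, random_state=rng)
    else:
        offsets = np.full(n_slots, np.clip(offset_mean, lo, hi))

    golden = np.pi * (3.0 - np.sqrt(5.0))
    ks = np.arange(n_slots)
    # z uniform over the cap keeps area density constant
    z = 1.0 - (ks + 0.5) * (2.0 * CAP_AREA_FRACTION / n_slots)
    phi = golden * ks
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    normals = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    slots = []
    for k in range(n_slots):
        n = normals[k]
        ref = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.999 else np.array([1.0, 0.0, 0.0])
        x = np.cross(ref, n)
        x /= np.linalg.norm(x)
        y = np.cross(n, x)
        slots.append(
            SensorSlot(
                slot_id=k,
                cell_position=(scalp_radius + offsets[k]) * n,
                casing_axes=np.vstack([x, y, n]),
            )
        )
    return slots


def make_synthetic_array(
    slots: list[SensorSlot] | None = None,
    n_sensors: int = 128,
    angle_offset_params: dict[str, tuple[float, float]] | None = None,
    gain_range: tuple[float, float] = DEFAULT_GAIN_RANGE,
    noise_density: float = DEFAULT_NOISE_DENSITY_FT,
    seed: int = 0,
) -> SensorArray:
    """Populate a helmet with triaxial sensors carrying realistic defects.

    Each channel's true orientation is its casing axis rotated by an angle
    drawn from the per-axis folded normal |N(mean, sd)| about a uniformly
    random axis perpendicular to the casing axis.  Gains are uniform over
    ``gain_range``.  Deterministic given ``seed``.
    """
    if slots is None:
        slots = make_helmet_slots(seed=seed)
    if n_sensors > len(slots):
        raise InvalidArgumentError(
            f"n_sensors={n_sensors} exceeds available slots ({len(slots)})"
        )
    g_lo, g_hi = gain_range
    if not (0.0 < g_lo <= g_hi < 5.0):
        raise InvalidArgumentError("gain_range must lie within (0, 5)")
    params = dict(DEFAULT_ANGLE_OFFSETS if angle_offset_params is None else angle_offset_params)

    rng = np.random.default_rng(seed)
    # even selection of occupied slots along the spiral ordering
    occupied = np.floor(np.arange(n_sensors) * len(slots) / n_sensors).astype(int)

    channels = []
    for idx in occupied:
        slot = slots[idx]
        for a, label in enumerate(AXIS_LABELS):
            mean, sd = params[label]
            angle = abs(rng.normal(mean, sd)) if sd > 0 else abs(mean)
            casing_axis = slot.casing_axes[a]
            if angle == 0.0:
                orientation = casing_axis.copy()
            else:
                perp = perpendicular_unit(casing_axis, rng)
                orientation = rotation_about_axis(perp, np.deg2rad(angle)) @ casing_axis
            orientation /= np.linalg.norm(orientation)
            gain = rng.uniform(g_lo, g_hi)
            channels.append(
                TrueChannel(
                    sensor_id=slot.slot_id,
                    axis_label=label,
                    true_orientation=orientation,
                    true_gain=float(gain),
                    noise_density=float(noise_density),
                )
            )
    return SensorArray(slots=list(slots), channels=channels)


def default_array(seed: int = 0, n_sensors: int = 128) -> SensorArray:
    """The study-condition array: 163-slot helmet, 128 triaxial sensors."""
    slot_seed, arr_seed = spawn_seeds(seed, 2)
    slots = make_helmet_slots(seed=slot_seed)
    return make_synthetic_array(slots, n_sensors=n_sensors, seed=arr_seed)


def channel_matrices(array: SensorArray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-channel positions (N,3), orientations (N,3) and gains (N,).

    Row i corresponds to channel i in declaration order; all three channels of
    a sensor share the slot's cell position.
    """
    n = array.n_channels
    positions = np.empty((n, 3))
    orientations = np.empty((n, 3))
    gains = np.empty(n)
    slot_map = {s.slot_id: s for s in array.slots}
    for i, ch in enumerate(array.channels):
        positions[i] = slot_map[ch.sensor_id].cell_position
        orientations[i] = ch.true_orientation
        gains[i] = ch.true_gain
    return positions, orientations, gains
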