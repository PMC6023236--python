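"""Force-plate channel reduction and force-defined gait events.

A piezoelectric plate reports eight channels: four vertical components
``fz1..fz4`` at sensors embedded near the plate corners, and two paired
shear channels per horizontal axis (``fx12``, ``fx34`` along lateral X;
``fy14``, ``fy23`` along anterior Y).  The net ground reaction force
(GRF, reaction convention: force on the foot, Z up) and the center of
pressure (COP, point of application of the vertical force at the plate
surface) follow from moment balance about the sensor plane.

Sensor layout (plate-center coordinates, top view)::

        y=+b   1 (-a,+b) ---- 2 (+a,+b)
                  |               |
        y=-b   4 (-a,-b) ---- 3 (+a,-b)

so channel pair 2,3 sits at x=+a, pair 1,2 at y=+b, matching the pairing
implied by the shear channel names.  The sensors sit a depth ``az0``
below the top surface, which couples shear force into the vertical
moment balance; the COP formulas below invert that coupling exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import EventNotFoundError, InputError, NoContactError

__all__ = [
    "PlateGeometry",
    "ChannelRecord",
    "GRFSeries",
    "reduce_channels",
    "detect_contact_onset",
    "detect_impact_peak",
]

#: sentinel written into COP columns where the vertical force is too small
#: for the COP quotient to be meaningful
COP_SENTINEL = np.nan

CHANNEL_NAMES = ("fx12", "fx34", "fy14", "fy23", "fz1", "fz2", "fz3", "fz4")


@dataclass(frozen=True)
class PlateGeometry:
    """Sensor geometry of a four-sensor force plate.

    Parameters
    ----------
    a, b:
        Half-spacing of the sensors along plate X and Y (m); sensors sit
        at (+/-a, +/-b) from the plate center.
    az0:
        Depth of the sensor plane below the top surface (m, >= 0).
    origin_offset:
        3-vector from the global origin to the plate center at the top
        surface (m).  A corner-origin convention is expressed by setting
        this to the corner-to-center vector; the default (0,0,0) puts
        the global origin at the plate center.
    force_rate:
        Nominal sampling rate of the force channels (Hz).
    """

    a: float
    b: float
    az0: float = 0.0
    origin_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    force_rate: float = 3000.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise InputError(f"sensor offsets must be positive, got a={self.a}, b={self.b}")
        if self.az0 < 0:
            raise InputError(f"sensor depth az0 must be >= 0, got {self.az0}")
        if self.force_rate <= 0:
            raise InputError(f"force_rate must be positive, got {self.force_rate}")

    @property
    def sensor_xy(self) -> np.ndarray:
        """Sensor (x, y) positions in plate-center coordinates, rows 1..4."""
        a, b = self.a, self.b
        return np.array([[-a, b], [a, b], [a, -b], [-a, -b]])


@dataclass
class ChannelRecord:
    """Raw 8-channel force-plate record on its own time base (s, N)."""

    time: np.ndarray
    fx12: np.ndarray
    fx34: np.ndarray
    fy14: np.ndarray
    fy23: np.ndarray
    fz1: np.ndarray
    fz2: np.ndarray
    fz3: np.ndarray
    fz4: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in CHANNEL_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.time.shape:
                raise InputError(
                    f"channel {name} has length {arr.size}, expected {self.time.size}"
                )
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise InputError("force time base must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class GRFSeries:
    """Net GRF on the foot and surface COP in the global frame.

    ``cop_valid`` is False (and COP is NaN) wherever the vertical force
    is below the threshold used at reduction time: the COP quotient is
    ill-conditioned as F_Z -> 0.
    """

    time: np.ndarray
    F_X: np.ndarray
    F_Y: np.ndarray
    F_Z: np.ndarray
    cop_X: np.ndarray
    cop_Y: np.ndarray
    cop_valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("F_X", "F_Y", "F_Z", "cop_X", "cop_Y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.cop_valid is None:
            self.cop_valid = np.isfinite(self.cop_X) & np.isfinite(self.cop_Y)
        self.cop_valid = np.asarray(self.cop_valid, dtype=bool)
        n = self.time.size
        for name in ("F_X", "F_Y", "F_Z", "cop_X", "cop_Y", "cop_valid"):
            if getattr(self, name).size != n:
                raise InputError(f"GRF field {name} length mismatch")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise InputError("GRF time base must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size


def reduce_channels(
    rec: ChannelRecord,
    geom: PlateGeometry,
    cop_force_threshold: float = 10.0,
) -> GRFSeries:
    """Reduce raw channels to net GRF and global-frame COP.

    Net force: ``F_X = fx12 + fx34``, ``F_Y = fy14 + fy23``,
    ``F_Z = fz1 + fz2 + fz3 + fz4``.  Plate-frame COP from moment
    balance about the sensor plane::

        x_cop = (sum_i x_i fz_i + az0 * F_X) / F_Z
        y_cop = (sum_i y_i fz_i + az0 * F_Y) / F_Z

    then shifted by the plate origin offset into the global frame.
    COP is emitted as NaN with ``cop_valid = False`` wherever
    ``F_Z < cop_force_threshold`` (N).
    """
    F_X = rec.fx12 + rec.fx34
    F_Y = rec.fy14 + rec.fy23
    fz = np.stack([rec.fz1, rec.fz2, rec.fz3, rec.fz4])
    F_Z = fz.sum(axis=0)

    xy = geom.sensor_xy
    valid = F_Z >= cop_force_threshold
    with np.errstate(divide="ignore", invalid="ignore"):
        x_cop = (xy[:, 0] @ fz + geom.az0 * F_X) / F_Z
        y_cop = (xy[:, 1] @ fz + geom.az0 * F_Y) / F_Z
    x_cop = np.where(valid, x_cop + geom.origin_offset[0], COP_SENTINEL)
    y_cop = np.where(valid, y_cop + geom.origin_offset[1], COP_SENTINEL)

    return GRFSeries(
        time=rec.time.copy(),
        F_X=F_X,
        F_Y=F_Y,
        F_Z=F_Z,
        cop_X=x_cop,
        cop_Y=y_cop,
        cop_valid=valid,
    )


def detect_contact_onset(
    grf: GRFSeries,
    rise_threshold: float = 10.0,
    floor_threshold: float = 2.0,
) -> float:
    """Contact onset t0: last quiet sample before the vertical force rises.

    The onset is the time of the last sample with ``F_Z <= floor_threshold``
    preceding the first sample with ``F_Z > rise_threshold``.  The
    floor-then-rise rule approximates "the instant at which GRF is zero"
    robustly on channels with a noise floor.
    """
    above = np.nonzero(grf.F_Z > rise_threshold)[0]
    if above.size == 0:
        raise NoContactError(
            f"vertical force never exceeds rise threshold {rise_threshold} N"
        )
    first_rise = above[0]
    quiet = np.nonzero(grf.F_Z[:first_rise] <= floor_threshold)[0]
    if quiet.size == 0:
        # signal starts already loaded right at the rise; fall back to the
        # sample before the rise
        idx = max(first_rise - 1, 0)
    else:
        idx = quiet[-1]
    return float(grf.time[idx])


def detect_impact_peak(
    grf: GRFSeries,
    t0: float,
    search_window: float = 0.060,
    min_prominence_fraction: float = 0.05,
) -> float:
    """Impact-transient peak time t_p.

    The first local maximum of the vertical force in ``(t0, t0 + window]``
    whose prominence is at least ``min_prominence_fraction`` of the
    window maximum; if no local maximum qualifies (e.g. the force is
    monotone through the window), the window argmax is used.
    """
    sel = (grf.time > t0) & (grf.time <= t0 + search_window)
    if not sel.any():
        raise InputError(f"empty impact-peak search window after t0={t0}")
    idx = np.nonzero(sel)[0]
    fz = grf.F_Z[idx]
    peaks, _ = find_peaks(fz, prominence=min_prominence_fraction * fz.max())
    if peaks.size:
        return float(grf.time[idx[peaks[0]]])
    return float(grf.time[idx[int(np.argmax(fz))]])
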