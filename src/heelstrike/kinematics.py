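"""Marker processing: local tibia frame, heel point, deformation track.

Two LEDs on the medial tibia define a local right-handed frame: the
local z axis points from the lower LED (the local origin L) to the
upper LED; the local y axis is the unit vector orthogonal to z lying in
the plane of progression (zero global-X component, positive anterior
component); x = y cross z completes the frame.

The heel point H is bone-fixed: its local position ``r_H`` is constant
over a trial and is estimated as the component-wise median of the
center-of-pressure samples transformed into the local frame over a
window centred on the impact force peak.  The global heel trajectory
``R_H(t) = L(t) + R(t) r_H`` then yields the foot-ankle deformation
``S(t) = R_H(t) - R_H(t0)`` and the vertical heel velocity by central
differences.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import (
    EventNotFoundError,
    GeometryError,
    InputError,
    InsufficientDataError,
    SynchronizationError,
)
from .forceplate import GRFSeries

__all__ = [
    "MarkerSeries",
    "FrameSeries",
    "LocalCOP",
    "HeelTrack",
    "zero_phase_lowpass",
    "filter_markers",
    "build_local_frames",
    "localize_cop",
    "estimate_heel_point",
    "reconstruct_heel_track",
    "detect_deformation_end",
]


@dataclass
class MarkerSeries:
    """Two-LED marker record: positions (m) on the kinematic time base (s).

    ``led1`` is the lower marker (local frame origin), ``led2`` the upper.
    Warns if the inter-marker distance varies by more than 1 mm over the
    trial — the cluster is assumed rigid at the 0.1 mm level.
    """

    time: np.ndarray
    led1: np.ndarray  # (n, 3)
    led2: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.led1 = np.asarray(self.led1, dtype=float)
        self.led2 = np.asarray(self.led2, dtype=float)
        n = self.time.size
        for name in ("led1", "led2"):
            if getattr(self, name).shape != (n, 3):
                raise InputError(f"{name} must have shape ({n}, 3)")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise InputError("marker time base must be strictly increasing")
        d = np.linalg.norm(self.led2 - self.led1, axis=1)
        if n and (d.max() - d.min()) > 1e-3:
            warnings.warn(
                f"inter-marker distance varies by {(d.max() - d.min()) * 1e3:.2f} mm "
                "(> 1 mm); marker cluster may not be rigid",
                stacklevel=2,
            )

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def inter_marker_distance(self) -> np.ndarray:
        return np.linalg.norm(self.led2 - self.led1, axis=1)


@dataclass
class FrameSeries:
    """Per-sample local-to-global rotation and local origin (= led1)."""

    time: np.ndarray
    rotation: np.ndarray  # (n, 3, 3), columns are local x, y, z in global coords
    origin: np.ndarray  # (n, 3)

    def __len__(self) -> int:
        return self.time.size


@dataclass
class LocalCOP:
    """COP samples transformed into the local tibia frame."""

    time: np.ndarray
    xyz: np.ndarray  # (n, 3)
    valid: np.ndarray  # boolean


@dataclass
class HeelTrack:
    """Heel-point trajectory and foot-ankle deformation for one trial.

    Attributes
    ----------
    r_H:
        Constant local heel-point position (m).
    R_H:
        Global heel position per kinematic sample (m).
    S:
        Deformation ``R_H(t) - R_H(t0)`` (m); zero at t0 by construction.
    Zdot_H:
        Vertical heel velocity, central differences of ``R_H[:, 2]`` (m/s).
    """

    time: np.ndarray
    r_H: np.ndarray
    R_H: np.ndarray
    S: np.ndarray
    Zdot_H: np.ndarray
    t0: float

    def zdot_at(self, t: float | np.ndarray) -> np.ndarray:
        """Vertical heel velocity at arbitrary times (linear interpolation)."""
        return np.interp(t, self.time, self.Zdot_H)

    def z_at(self, t: float | np.ndarray) -> np.ndarray:
        """Global heel height at arbitrary times (linear interpolation)."""
        return np.interp(t, self.time, self.R_H[:, 2])


def zero_phase_lowpass(
    signal: np.ndarray,
    cutoff: float = 100.0,
    rate: float = 1295.0,
    order: int = 2,
) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero net phase lag).

    A causal Butterworth of the given order is applied forward then
    backward, doubling the effective order and cancelling phase.  Edges
    are handled by odd-reflection padding of three filter lengths.
    Works on 1-D series or (n, k) columns.
    """
    signal = np.asarray(signal, dtype=float)
    if rate <= 2 * cutoff:
        raise InputError(f"rate {rate} Hz must exceed twice the cutoff {cutoff} Hz")
    b, a = butter(order, cutoff, fs=rate)
    padlen = 3 * max(len(a), len(b))
    if signal.shape[0] <= padlen:
        raise InputError(
            f"series of length {signal.shape[0]} too short for padding {padlen}"
        )
    return filtfilt(b, a, signal, axis=0, padlen=padlen)


def filter_markers(
    markers: MarkerSeries, cutoff: float = 100.0, order: int = 2
) -> MarkerSeries:
    """Low-pass both LED trajectories coordinate-wise (zero phase)."""
    rate = markers.rate
    return MarkerSeries(
        time=markers.time.copy(),
        led1=zero_phase_lowpass(markers.led1, cutoff, rate, order),
        led2=zero_phase_lowpass(markers.led2, cutoff, rate, order),
    )


def build_local_frames(markers: MarkerSeries, y_sign: float = 1.0) -> FrameSeries:
    """Construct the per-sample local tibia frame from the two LEDs.

    local z = unit(led2 - led1); local y = the unit vector orthogonal to
    z with zero global-X component, signed so its global-Y (anterior)
    component is positive (``y_sign=-1`` flips this); local x = y x z.
    """
    dz = markers.led2 - markers.led1
    norms = np.linalg.norm(dz, axis=1)
    bad = np.nonzero(norms < 1e-9)[0]
    if bad.size:
        raise GeometryError(f"coincident LEDs at sample index {bad[0]}")
    z = dz / norms[:, None]

    # y = unit(0, z_z, -z_y): orthogonal to z within the global YZ plane
    yz_norm = np.hypot(z[:, 1], z[:, 2])
    bad = np.nonzero(yz_norm < 1e-9)[0]
    if bad.size:
        raise GeometryError(
            f"local z parallel to global X at sample index {bad[0]}; y undefined"
        )
    y = np.zeros_like(z)
    y[:, 1] = z[:, 2] / yz_norm
    y[:, 2] = -z[:, 1] / yz_norm
    sign = np.where(y[:, 1] >= 0, 1.0, -1.0) * float(y_sign)
    y *= sign[:, None]

    x = np.cross(y, z)
    rotation = np.stack([x, y, z], axis=-1)  # columns: x, y, z
    return FrameSeries(time=markers.time.copy(), rotation=rotation, origin=markers.led1.copy())


def localize_cop(
    frames: FrameSeries,
    grf: GRFSeries,
    surface_z: float = 0.0,
) -> LocalCOP:
    """Transform the global COP into the local tibia frame.

    The COP (global Z = plate surface height) is linearly interpolated
    from the force base onto the kinematic timestamps, avoiding
    interpolation of rotations; the local position is
    ``r(t) = R(t)^T (COP(t) - L(t))``.  Kinematic samples outside the
    valid-COP time range are marked invalid.
    """
    valid_idx = np.nonzero(grf.cop_valid)[0]
    if valid_idx.size == 0:
        raise SynchronizationError("no valid COP samples to localize")
    t_cop = grf.time[valid_idx]
    if t_cop[-1] < frames.time[0] or t_cop[0] > frames.time[-1]:
        raise SynchronizationError(
            f"COP time range [{t_cop[0]:.4f}, {t_cop[-1]:.4f}] s does not overlap "
            f"kinematic frames [{frames.time[0]:.4f}, {frames.time[-1]:.4f}] s"
        )
    tk = frames.time
    in_range = (tk >= t_cop[0]) & (tk <= t_cop[-1])
    cop_g = np.full((tk.size, 3), np.nan)
    cop_g[:, 0] = np.interp(tk, t_cop, grf.cop_X[valid_idx])
    cop_g[:, 1] = np.interp(tk, t_cop, grf.cop_Y[valid_idx])
    cop_g[:, 2] = surface_z

    rel = cop_g - frames.origin
    local = np.einsum("nij,nj->ni", np.transpose(frames.rotation, (0, 2, 1)), rel)
    local[~in_range] = np.nan
    return LocalCOP(time=tk.copy(), xyz=local, valid=in_range)


def estimate_heel_point(
    local_cop: LocalCOP,
    grf: GRFSeries,
    t_p: float,
    peak_fraction: float = 0.25,
    median_kind: str = "marginal",
    min_window_duration: float = 0.005,
) -> np.ndarray:
    """Estimate the constant local heel point ``r_H``.

    The window starts at the first force sample whose vertical force
    reaches ``peak_fraction`` of the impact-peak force and ends so that
    the peak sample is the window midpoint; the window, defined on the
    force base, is mapped to kinematic timestamps and the component-wise
    median of the local COP over it is returned.  ``median_kind``
    "geometric" uses Weiszfeld's algorithm instead of the marginal
    median.

    When the impact peak sits at the very first loaded sample (heavily
    damped contact: the force decays monotonically from touchdown) the
    peak-centred rule degenerates; the window is then extended forward
    to span at least ``min_window_duration`` seconds, over which the
    COP is equally stationary under the heel.
    """
    p = int(np.argmin(np.abs(grf.time - t_p)))
    fz_peak = grf.F_Z[p]
    above = np.nonzero(grf.F_Z[: p + 1] >= peak_fraction * fz_peak)[0]
    if above.size == 0:
        raise InsufficientDataError("no force sample reaches the window threshold")
    s = above[0]
    e = min(2 * p - s, len(grf.time) - 1)
    if grf.time[e] - grf.time[s] < min_window_duration:
        e = int(np.searchsorted(grf.time, grf.time[s] + min_window_duration))
        e = min(e, len(grf.time) - 1)
    t_start, t_end = grf.time[s], grf.time[e]

    sel = (local_cop.time >= t_start) & (local_cop.time <= t_end) & local_cop.valid
    sel &= np.isfinite(local_cop.xyz).all(axis=1)
    if sel.sum() < 3:
        raise InsufficientDataError(
            f"heel-point window [{t_start:.4f}, {t_end:.4f}] s holds "
            f"{int(sel.sum())} local COP samples (< 3)"
        )
    pts = local_cop.xyz[sel]
    if median_kind == "marginal":
        return np.median(pts, axis=0)
    if median_kind == "geometric":
        return _geometric_median(pts)
    raise InputError(f"unknown median_kind {median_kind!r}")


def _geometric_median(pts: np.ndarray, tol: float = 1e-10, maxiter: int = 200) -> np.ndarray:
    """Weiszfeld iteration; falls back to the marginal median on stall."""
    x = np.median(pts, axis=0)
    for _ in range(maxiter):
        d = np.linalg.norm(pts - x, axis=1)
        if (d < tol).any():
            return x
        w = 1.0 / d
        x_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(x_new - x) < tol:
            return x_new
        x = x_new
    return x


def reconstruct_heel_track(
    frames: FrameSeries, r_H: np.ndarray, t0: float
) -> HeelTrack:
    """Reconstruct the global heel trajectory and deformation.

    ``R_H(t) = L(t) + R(t) r_H`` on the kinematic base; the reference
    position ``R_H(t0)`` is linearly interpolated to the (force-defined)
    contact onset; ``Zdot_H`` is the central-difference gradient of the
    vertical component.
    """
    r_H = np.asarray(r_H, dtype=float)
    if not (frames.time[0] <= t0 <= frames.time[-1]):
        raise SynchronizationError(
            f"t0={t0:.4f} s outside kinematic range "
            f"[{frames.time[0]:.4f}, {frames.time[-1]:.4f}] s"
        )
    R_H = frames.origin + np.einsum("nij,j->ni", frames.rotation, r_H)
    ref = np.array([np.interp(t0, frames.time, R_H[:, k]) for k in range(3)])
    S = R_H - ref
    Zdot = np.gradient(R_H[:, 2], frames.time)
    return HeelTrack(time=frames.time.copy(), r_H=r_H, R_H=R_H, S=S, Zdot_H=Zdot, t0=t0)


def detect_deformation_end(
    track: HeelTrack, t0: float, max_wait: float = 0.100
) -> float:
    """End of heel strike t_e: first upward zero crossing of Zdot_H after t0.

    The crossing is located to sub-sample resolution by linear
    interpolation between the bracketing kinematic samples.  The heel
    must still be descending at t0.
    """
    v0 = float(track.zdot_at(t0))
    if v0 >= 0:
        raise EventNotFoundError(f"heel not descending at t0 (Zdot={v0:.3f} m/s)")
    after = track.time > t0
    t = track.time[after]
    v = track.Zdot_H[after]
    crossings = np.nonzero((v[:-1] < 0) & (v[1:] >= 0))[0]
    for i in crossings:
        if t[i] - t0 > max_wait:
            break
        # linear interpolation for the sub-sample zero
        frac = -v[i] / (v[i + 1] - v[i])
        t_e = t[i] + frac * (t[i + 1] - t[i])
        if t_e - t0 <= max_wait:
            return float(t_e)
    raise EventNotFoundError(
        f"no upward zero crossing of heel velocity within {max_wait * 1e3:.0f} ms of t0"
    )
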