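"""Heel-strike energy absorption: force-integral work and effective-mass models.

Two independent estimates of the mechanical energy absorbed by the
foot-ankle system between contact onset t0 and the end of heel strike
t_e (zero vertical heel velocity):

* the force-integral method — the work done by the ground reaction
  force over the foot-ankle deformation,
  ``W = int F . dS = W_X + W_Y + W_Z``, evaluated by the trapezoidal
  rule on the force time base with the deformation interpolated up;

* the effective-foot-mass model — a point mass M_eff decelerated by the
  vertical GRF, identified from the impulse-momentum balance

      int_{t0}^{t} F_Z dt = M_eff (Zdot_H(t) - Zdot_H(t0)) + M_eff g (t - t0)

  and its energy change ``dE = 1/2 M (v_end^2 - v_start^2) + M g dz``.
  Evaluated to t_e with Zdot_H(t_e)=0 this gives M_e / dE_e; evaluated
  to the impact-force peak t_p with the measured Zdot_H(t_p) it gives
  M_p / dE_p; and with the classical assumption Zdot_H(t_p)=0 (used
  when force and kinematics are not synchronized) it gives M_p_CS /
  dE_p_CS.

Sign convention: dE is the energy change OF the effective mass, so a
negative value means energy absorbed by the heel pad, foot and ankle —
matching the sign of the force-integral work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import forceplate as fp
from . import kinematics as kin
from .config import PipelineConfig
from .errors import (
    HeelstrikeError,
    InputError,
    ModelAssumptionError,
    SynchronizationError,
)
from .forceplate import ChannelRecord, GRFSeries
from .kinematics import HeelTrack, MarkerSeries

__all__ = [
    "EventTimes",
    "TrialEnergetics",
    "work_by_grf",
    "effective_mass",
    "effective_mass_energy",
    "process_records",
    "process_trial",
]

G_DEFAULT = 9.81


@dataclass(frozen=True)
class EventTimes:
    """Contact onset, impact-force peak, and end of heel strike (s)."""

    t0: float
    t_p: float
    t_e: float

    def __post_init__(self) -> None:
        if not (self.t0 < self.t_p):
            raise InputError(f"event order violated: t0={self.t0} >= t_p={self.t_p}")
        if self.t_p > self.t_e:
            warnings.warn(
                f"impact peak t_p={self.t_p:.4f} s after deformation end "
                f"t_e={self.t_e:.4f} s (undamped limit or detection jitter)",
                stacklevel=2,
            )


@dataclass
class TrialEnergetics:
    """All per-trial heel-strike quantities (SI units)."""

    # force-integral method
    W: float
    W_X: float
    W_Y: float
    W_Z: float
    # effective-mass models
    M_e: float
    M_p: float
    M_p_CS: float
    dE_e: float
    dE_p: float
    dE_p_CS: float
    # deformation and kinematic descriptors
    S_te: np.ndarray
    S_te_mag: float
    Zdot_t0: float
    Zdot_tp: float
    # events
    t0: float
    t_p: float
    t_e: float
    t_p_ms: float
    t_e_ms: float
    # context
    walking_speed: float
    body_mass: float | None = None
    g: float = G_DEFAULT
    subject_id: str | None = None
    trial_id: str | None = None
    flags: list[str] = field(default_factory=list)

    SCALAR_FIELDS = (
        "W", "W_X", "W_Y", "W_Z",
        "M_e", "M_p", "M_p_CS", "dE_e", "dE_p", "dE_p_CS",
        "S_te_mag", "Zdot_t0", "Zdot_tp", "t_p_ms", "t_e_ms", "walking_speed",
    )

    def mass_pct(self, which: str = "M_e") -> float:
        """Effective mass as percent of body mass (NaN without body mass)."""
        if self.body_mass is None or not self.body_mass > 0:
            return float("nan")
        return 100.0 * getattr(self, which) / self.body_mass

    def to_dict(self) -> dict:
        d = {k: float(getattr(self, k)) for k in self.SCALAR_FIELDS}
        d.update(
            t0=float(self.t0), t_p=float(self.t_p), t_e=float(self.t_e),
            S_te=[float(v) for v in self.S_te],
            body_mass=self.body_mass, g=self.g,
            subject_id=self.subject_id, trial_id=self.trial_id,
            flags=list(self.flags),
        )
        d["M_e_pct"] = self.mass_pct("M_e")
        d["M_p_pct"] = self.mass_pct("M_p")
        d["M_p_CS_pct"] = self.mass_pct("M_p_CS")
        d["t_e_over_t_p"] = float(self.t_e_ms / self.t_p_ms) if self.t_p_ms > 0 else float("nan")
        return d


def _segment_on_force_base(
    grf: GRFSeries, track: HeelTrack, t_start: float, t_end: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Force samples in (t_start, t_end) plus interpolated exact endpoints.

    Returns (t, F (n,3), S (n,3)) with the deformation interpolated from
    the kinematic base up to the force base.
    """
    if t_end <= t_start:
        raise InputError(f"event order: t_end={t_end} <= t_start={t_start}")
    if t_start < track.time[0] or t_end > track.time[-1]:
        raise SynchronizationError(
            "deformation track does not cover the heel-strike interval"
        )
    if t_start < grf.time[0] or t_end > grf.time[-1]:
        raise SynchronizationError("force record does not cover the heel-strike interval")
    inside = (grf.time > t_start) & (grf.time < t_end)
    t = np.concatenate([[t_start], grf.time[inside], [t_end]])
    F = np.column_stack(
        [np.interp(t, grf.time, comp) for comp in (grf.F_X, grf.F_Y, grf.F_Z)]
    )
    S = np.column_stack([np.interp(t, track.time, track.S[:, k]) for k in range(3)])
    return t, F, S


def work_by_grf(
    grf: GRFSeries, track: HeelTrack, t0: float, t_e: float
) -> tuple[float, float, float, float]:
    """Work done by the GRF over the foot-ankle deformation on [t0, t_e].

    Each component is the trapezoidal path integral of F_k dS_k on the
    force time base; W is their sum.  Negative work = energy absorbed.
    """
    _, F, S = _segment_on_force_base(grf, track, t0, t_e)
    comps = [float(np.trapezoid(F[:, k], x=S[:, k])) for k in range(3)]
    return sum(comps), comps[0], comps[1], comps[2]


def vertical_impulse(grf: GRFSeries, t_start: float, t_end: float) -> float:
    """Trapezoidal time integral of F_Z over [t_start, t_end] (N s)."""
    if t_end <= t_start:
        raise InputError(f"event order: t_end={t_end} <= t_start={t_start}")
    inside = (grf.time > t_start) & (grf.time < t_end)
    t = np.concatenate([[t_start], grf.time[inside], [t_end]])
    fz = np.interp(t, grf.time, grf.F_Z)
    return float(np.trapezoid(fz, x=t))


def effective_mass(
    grf: GRFSeries,
    v_start: float,
    v_end: float,
    t_start: float,
    t_end: float,
    g: float = G_DEFAULT,
) -> float:
    """Effective foot mass from the impulse-momentum balance (kg).

    ``M = int F_Z dt / (v_end - v_start + g (t_end - t_start))``.
    With v_end = 0 at t_e this is M_e; with the measured heel velocity
    at the impact peak it is M_p; forcing v_end = 0 at t_p gives the
    classical M_p_CS.
    """
    denom = v_end - v_start + g * (t_end - t_start)
    if not denom > 0:
        raise ModelAssumptionError(
            f"effective-mass denominator {denom:.4g} <= 0 "
            f"(v_start={v_start:.3f}, v_end={v_end:.3f}, dt={t_end - t_start:.4f})"
        )
    return vertical_impulse(grf, t_start, t_end) / denom


def effective_mass_energy(
    M: float,
    v_start: float,
    v_end: float,
    z_start: float,
    z_end: float,
    g: float = G_DEFAULT,
) -> float:
    """Energy change of the effective mass (J); negative = absorbed.

    ``dE = 1/2 M (v_end^2 - v_start^2) + M g (z_end - z_start)``.
    """
    if not M > 0:
        raise InputError(f"effective mass must be positive, got {M}")
    return 0.5 * M * (v_end**2 - v_start**2) + M * g * (z_end - z_start)


def _model_quantities(
    grf: GRFSeries,
    track: HeelTrack,
    events: EventTimes,
    g: float,
    flags: list[str],
) -> dict[str, float]:
    """All three effective-mass variants; failures flagged, not fatal."""
    v0 = float(track.zdot_at(events.t0))
    vp = float(track.zdot_at(events.t_p))
    z0 = float(track.z_at(events.t0))
    zp = float(track.z_at(events.t_p))
    ze = float(track.z_at(events.t_e))
    out = dict(Zdot_t0=v0, Zdot_tp=vp)
    variants = {
        "e": (0.0, events.t_e, ze),      # improved model to t_e
        "p": (vp, events.t_p, zp),       # improved model to t_p
        "p_CS": (0.0, events.t_p, zp),   # classical assumption at t_p
    }
    for tag, (v_end, t_end, z_end) in variants.items():
        m_key = "M_e" if tag == "e" else ("M_p" if tag == "p" else "M_p_CS")
        e_key = "dE_" + tag
        try:
            M = effective_mass(grf, v0, v_end, events.t0, t_end, g)
            out[m_key] = M
            out[e_key] = effective_mass_energy(M, v0, v_end, z0, z_end, g)
        except ModelAssumptionError as exc:
            flags.append(f"{m_key}: {exc}")
            out[m_key] = float("nan")
            out[e_key] = float("nan")
    return out


def process_records(
    rec: ChannelRecord | GRFSeries,
    markers: MarkerSeries,
    config: PipelineConfig | None = None,
    subject_id: str | None = None,
    trial_id: str | None = None,
    r_H_offset: np.ndarray | None = None,
    return_intermediates: bool = False,
) -> TrialEnergetics | tuple[TrialEnergetics, dict]:
    """Run the full per-trial chain on in-memory records.

    Stages: channel reduction -> contact onset -> impact peak -> marker
    filtering -> local frames -> COP localization -> heel-point median
    -> heel track -> deformation end -> work integral -> effective-mass
    models.  Stage errors are re-raised annotated with the stage name;
    model-assumption failures are flagged on the result instead.
    ``r_H_offset`` displaces the estimated heel point in the local frame
    (used by the sensitivity analysis).
    """
    cfg = config or PipelineConfig()
    stage = "forceplate"
    try:
        if isinstance(rec, GRFSeries):
            grf = rec
        else:
            if cfg.energetics.filter_force:
                # optional channel-level low-pass before COP computation
                rate = cfg.plate.force_rate
                rec = ChannelRecord(time=rec.time, **{
                    name: kin.zero_phase_lowpass(
                        getattr(rec, name), cfg.kinematics.cutoff_hz, rate,
                        cfg.kinematics.filter_order)
                    for name in fp.CHANNEL_NAMES
                })
            geom = fp.PlateGeometry(
                a=cfg.plate.a, b=cfg.plate.b, az0=cfg.plate.az0,
                origin_offset=cfg.plate.origin_offset, force_rate=cfg.plate.force_rate,
            )
            grf = fp.reduce_channels(rec, geom, cfg.events.cop_force_threshold)
        t0 = fp.detect_contact_onset(
            grf, cfg.events.rise_threshold, cfg.events.floor_threshold
        )
        t_p = fp.detect_impact_peak(
            grf, t0, cfg.events.peak_window, cfg.events.min_prominence_fraction
        )

        stage = "kinematics"
        filtered = kin.filter_markers(
            markers, cfg.kinematics.cutoff_hz, cfg.kinematics.filter_order
        )
        frames = kin.build_local_frames(filtered, cfg.kinematics.y_sign)
        local_cop = kin.localize_cop(frames, grf, cfg.kinematics.surface_z)
        r_H = kin.estimate_heel_point(
            local_cop, grf, t_p, cfg.events.peak_fraction, cfg.kinematics.median_kind
        )
        if r_H_offset is not None:
            r_H = r_H + np.asarray(r_H_offset, dtype=float)
        track = kin.reconstruct_heel_track(frames, r_H, t0)
        t_e = kin.detect_deformation_end(track, t0, cfg.events.max_wait)
        events = EventTimes(t0=t0, t_p=t_p, t_e=t_e)

        stage = "energetics"
        W, W_X, W_Y, W_Z = work_by_grf(grf, track, t0, t_e)
        flags: list[str] = []
        mq = _model_quantities(grf, track, events, cfg.energetics.g, flags)

        S_te = np.array([np.interp(t_e, track.time, track.S[:, k]) for k in range(3)])
        duration = markers.time[-1] - markers.time[0]
        walking_speed = float(
            (markers.led1[-1, 1] - markers.led1[0, 1]) / duration
        )
    except HeelstrikeError as exc:
        if not getattr(exc, "_stage_annotated", False):
            exc._stage_annotated = True  # type: ignore[attr-defined]
            exc.args = (f"[{stage}] {exc}",)
        raise

    result = TrialEnergetics(
        W=W, W_X=W_X, W_Y=W_Y, W_Z=W_Z,
        M_e=mq["M_e"], M_p=mq["M_p"], M_p_CS=mq["M_p_CS"],
        dE_e=mq["dE_e"], dE_p=mq["dE_p"], dE_p_CS=mq["dE_p_CS"],
        S_te=S_te, S_te_mag=float(np.linalg.norm(S_te)),
        Zdot_t0=mq["Zdot_t0"], Zdot_tp=mq["Zdot_tp"],
        t0=t0, t_p=t_p, t_e=t_e,
        t_p_ms=1e3 * (t_p - t0), t_e_ms=1e3 * (t_e - t0),
        walking_speed=walking_speed,
        body_mass=cfg.body_mass, g=cfg.energetics.g,
        subject_id=subject_id, trial_id=trial_id, flags=flags,
    )
    if return_intermediates:
        return result, dict(
            grf=grf, frames=frames, local_cop=local_cop, r_H=r_H,
            track=track, events=events,
        )
    return result


def process_trial(
    force_file: str | Path,
    marker_file: str | Path,
    config: PipelineConfig | None = None,
    subject_id: str | None = None,
    trial_id: str | None = None,
) -> TrialEnergetics:
    """Process one trial from its force and marker CSV files."""
    from .io import read_force_csv, read_marker_csv

    rec = read_force_csv(force_file)
    markers = read_marker_csv(marker_file)
    return process_records(rec, markers, config, subject_id, trial_id)
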