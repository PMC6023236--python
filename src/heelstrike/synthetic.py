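"""Synthetic heel-strike trials with known ground truth.

A point mass (the effective foot mass) touches down with a downward
velocity and is decelerated by a viscoelastic ground contact,

    M z'' = -M g + F_c,   F_c = max(0, k d^n + c d' d^(n-1)),  d = max(0, -z)

(Kelvin-Voigt for the default exponent n = 1; Hertz-like for n > 1;
the contact force never pulls).  The trajectory is integrated with a
fixed-step fourth-order Runge-Kutta scheme, and the solution is
rendered both as raw 8-channel force-plate CSV data and as a two-LED
marker record of a rigid shank segment carrying the heel point — the
same file dialects the analysis pipeline reads — together with a
:class:`SimTruth` ledger of true events and energies.

Default parameters (M = 8.5 kg, k = 15 kN/m, c = 250 N s/m, i.e. a
damping ratio of about 0.35, v0 = -0.57 m/s) produce impact-transient
timing, deformation magnitude and absorbed energy of the order seen in
barefoot walking at preferred speed: t_p ~ 20 ms, t_e/t_p ~ 1.8,
S_Z(t_e) ~ -13 mm, dE_e ~ -2.4 J.

Geometry of the rendered trial: the heel point touches down at a fixed
plate location; the plate-surface COP sits at the heel's horizontal
position (plus optional shear-driven drift).  Because the bone-fixed
heel point penetrates the surface by d(t) while the COP stays on it,
the local-frame COP carries the penetration in its z coordinate — a
property shared with real data, see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, RenderError
from .forceplate import ChannelRecord, PlateGeometry
from .kinematics import MarkerSeries

__all__ = [
    "SimConfig",
    "SimSolution",
    "SimTruth",
    "simulate_heel_impact",
    "render_plate_channels",
    "render_markers",
    "render_trial",
    "make_fixture_study",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic heel-strike trial (SI units)."""

    mass: float = 8.5            # effective foot mass M_true (kg)
    k: float = 15e3              # contact stiffness (N/m^n)
    c: float = 250.0             # contact damping (N s/m^n)
    n: float = 1.0               # contact exponent (1 = Kelvin-Voigt)
    damper_ramp_depth: float = 0.002  # damper ramp-in depth (m); 0 = pure KV
    v0: float = -0.57            # vertical touchdown velocity (m/s, < 0)
    v_horiz: tuple[float, float] = (0.0, 0.0)  # post-contact heel drift (m/s)
    drift_tau: float = 0.020     # horizontal drift decay time constant (s)
    shear_stiffness: float = 20e3
    shear_damping: float = 200.0
    cop_local: tuple[float, float, float] = (0.012, -0.055, -0.150)
    led_separation: float = 0.16
    marker_offsets: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None
    tilt_deg: float = 5.0        # constant segment tilt about global X (deg)
    tilt_ramp: float = 0.0       # additional tilt rate during contact (deg/s)
    noise_marker_sd: float = 1e-4
    noise_channel_sd: float = 0.0
    sync_jitter: float = 0.0     # force-clock offset vs kinematics (s, |.| <= 1 ms)
    force_rate: float = 3000.0
    kin_rate: float = 1295.0
    ode_step: float = 1e-5
    lead_in: float = 0.060       # pre-contact record length (s)
    sim_duration: float = 0.150  # max simulated contact duration (s)
    touchdown_xy: tuple[float, float] = (0.02, 0.05)
    seed: int = 0
    plate: PlateGeometry = field(default_factory=lambda: PlateGeometry(a=0.12, b=0.20, az0=0.006))
    body_mass: float | None = None

    def __post_init__(self) -> None:
        if not (self.mass > 0 and self.k > 0):
            raise ConfigError("mass and stiffness must be positive")
        if self.c < 0:
            raise ConfigError("damping must be non-negative")
        if self.v0 >= 0:
            raise ConfigError(f"touchdown velocity must be downward (v0 < 0), got {self.v0}")
        if not (self.force_rate > 0 and self.kin_rate > 0):
            raise ConfigError("sampling rates must be positive")
        if self.ode_step > 1.0 / (10.0 * self.force_rate):
            raise ConfigError(
                f"ode_step {self.ode_step} too coarse for force_rate {self.force_rate}"
            )
        if abs(self.sync_jitter) > 1e-3:
            raise ConfigError("sync_jitter must be at most 1 ms")

    @property
    def damping_ratio(self) -> float:
        """c / (2 sqrt(k M)) — meaningful for the linear contact (n = 1)."""
        return self.c / (2.0 * np.sqrt(self.k * self.mass))

    def led_offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """Heel-to-LED vectors in the segment frame."""
        if self.marker_offsets is not None:
            return (np.asarray(self.marker_offsets[0], dtype=float),
                    np.asarray(self.marker_offsets[1], dtype=float))
        o1 = -np.asarray(self.cop_local, dtype=float)
        o2 = o1 + np.array([0.0, 0.0, self.led_separation])
        return o1, o2


@dataclass
class SimSolution:
    """Fine-grid contact solution, time measured from touchdown."""

    t: np.ndarray       # (n,) fine time grid, t[0] = 0 at touchdown
    z: np.ndarray       # vertical heel/mass position (m, <= 0 in contact)
    v: np.ndarray       # vertical velocity (m/s)
    F: np.ndarray       # vertical contact force on the foot (N, >= 0)
    config: SimConfig

    def horizontal_path(self) -> tuple[np.ndarray, np.ndarray]:
        """Post-contact heel drift displacement and velocity, shape (n, 2)."""
        cfg = self.config
        vh = np.asarray(cfg.v_horiz, dtype=float)
        tau = cfg.drift_tau
        decay = 1.0 - np.exp(-self.t / tau)
        disp = vh[None, :] * tau * decay[:, None]
        vel = vh[None, :] * np.exp(-self.t / tau)[:, None]
        in_contact = (self.z < 0)[:, None]
        return disp, np.where(in_contact, vel, 0.0)

    def shear_force(self) -> np.ndarray:
        """Ground shear force on the foot (n, 2); zero out of contact."""
        cfg = self.config
        disp, vel = self.horizontal_path()
        f = -(cfg.shear_stiffness * disp + cfg.shear_damping * vel)
        return np.where((self.F > 0)[:, None], f, 0.0)


@dataclass
class SimTruth:
    """Ground-truth ledger on the fine grid (times from touchdown)."""

    t: np.ndarray
    deformation: np.ndarray       # d(t) = max(0, -z) (m)
    dissipated_energy: np.ndarray  # cumulative damper dissipation (J, >= 0)
    stored_elastic: np.ndarray     # elastic potential of the contact (J)
    work_by_contact: np.ndarray    # cumulative vertical contact work on the mass (J)
    shear_work: np.ndarray         # cumulative shear work on the foot (J)
    z: np.ndarray
    v: np.ndarray
    touchdown_time: float          # on the rendered timeline (= lead_in)
    t_p_true: float                # rendered-timeline instant of peak contact force
    t_e_true: float                # rendered-timeline instant of zero vertical velocity
    mass: float
    g: float = 9.81

    def energy_change(self, t_a: float, t_b: float) -> float:
        """True dKE + dPE of the mass between rendered-timeline times (J)."""
        ta = t_a - self.touchdown_time
        tb = t_b - self.touchdown_time
        z_a, z_b = np.interp([ta, tb], self.t, self.z)
        v_a, v_b = np.interp([ta, tb], self.t, self.v)
        return float(
            0.5 * self.mass * (v_b**2 - v_a**2) + self.mass * self.g * (z_b - z_a)
        )

    def shear_work_between(self, t_a: float, t_b: float) -> float:
        ta = t_a - self.touchdown_time
        tb = t_b - self.touchdown_time
        w_a, w_b = np.interp([ta, tb], self.t, self.shear_work)
        return float(w_b - w_a)

    def total_work_between(self, t_a: float, t_b: float) -> float:
        """Vertical dKE + dPE plus shear work — the force-integral target."""
        return self.energy_change(t_a, t_b) + self.shear_work_between(t_a, t_b)

    def state_at(self, t_rendered: float) -> tuple[float, float]:
        ts = t_rendered - self.touchdown_time
        return (
            float(np.interp(ts, self.t, self.z)),
            float(np.interp(ts, self.t, self.v)),
        )

    def audit_residual(self) -> float:
        """Max |dKE + dPE - work_by_contact| over the grid (J)."""
        ke = 0.5 * self.mass * self.v**2
        pe = self.mass * self.g * self.z
        lhs = (ke + pe) - (ke[0] + pe[0])
        return float(np.max(np.abs(lhs - self.work_by_contact)))

    def summary(self) -> dict:
        i_e = int(np.searchsorted(self.t, self.t_e_true - self.touchdown_time))
        i_e = min(i_e, self.t.size - 1)
        return dict(
            touchdown_time=self.touchdown_time,
            t_p_true=self.t_p_true,
            t_e_true=self.t_e_true,
            mass=self.mass,
            deformation_te=float(np.interp(
                self.t_e_true - self.touchdown_time, self.t, self.deformation
            )),
            work_by_contact_te=float(self.work_by_contact[i_e]),
            dissipated_te=float(self.dissipated_energy[i_e]),
            stored_elastic_te=float(self.stored_elastic[i_e]),
        )


def _contact_force(z: float, v: float, cfg: SimConfig) -> float:
    # Damping ramps in over the first damper_ramp_depth of penetration
    # (Hunt-Crossley-style), so the contact force is continuous at
    # touchdown; beyond that depth the law is plain Kelvin-Voigt.  A pure
    # KV damper would jump to c|v0| at first contact — a step no finite
    # sampling rate can integrate to the tolerances this package holds
    # itself to, and one real heel pads do not exhibit.
    d = -z
    if d <= 0.0:
        return 0.0
    ramp = min(1.0, d / cfg.damper_ramp_depth) if cfg.damper_ramp_depth > 0 else 1.0
    if cfg.n == 1.0:
        f = cfg.k * d + cfg.c * (-v) * ramp
    else:
        f = cfg.k * d**cfg.n + cfg.c * (-v) * d ** (cfg.n - 1.0) * ramp
    return f if f > 0.0 else 0.0


def simulate_heel_impact(cfg: SimConfig) -> tuple[SimSolution, SimTruth]:
    """Integrate the contact dynamics and build the truth ledger.

    Fixed-step RK4 at ``cfg.ode_step`` from z(0) = 0, zdot(0) = v0 for
    ``cfg.sim_duration``; after rebound lift-off the mass continues in
    free flight (zero contact force).  Energies are accumulated by the
    trapezoidal rule on the same fine grid; the ledger's audit residual
    |dKE + dPE - work_by_contact| stays at the quadrature level.
    """
    M, g, h = cfg.mass, 9.81, cfg.ode_step
    n_steps = int(round(cfg.sim_duration / h))

    z = np.empty(n_steps + 1)
    v = np.empty(n_steps + 1)
    z[0], v[0] = 0.0, cfg.v0

    def acc(zz: float, vv: float) -> float:
        return -g + _contact_force(zz, vv, cfg) / M

    zi, vi = 0.0, cfg.v0
    for i in range(n_steps):
        a1 = acc(zi, vi)
        k1z, k1v = vi, a1
        a2 = acc(zi + 0.5 * h * k1z, vi + 0.5 * h * k1v)
        k2z, k2v = vi + 0.5 * h * k1v, a2
        a3 = acc(zi + 0.5 * h * k2z, vi + 0.5 * h * k2v)
        k3z, k3v = vi + 0.5 * h * k2v, a3
        a4 = acc(zi + h * k3z, vi + h * k3v)
        k4z, k4v = vi + h * k3v, a4
        zi += h / 6.0 * (k1z + 2 * k2z + 2 * k3z + k4z)
        vi += h / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        z[i + 1], v[i + 1] = zi, vi

    t = np.arange(n_steps + 1) * h
    F = np.array([_contact_force(zz, vv, cfg) for zz, vv in zip(z, v)])
    d = np.maximum(0.0, -z)

    # cumulative trapezoidal integrals on the fine grid
    def cumtrapz(y: np.ndarray) -> np.ndarray:
        out = np.zeros_like(y)
        out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(t))
        return out

    work_by_contact = cumtrapz(F * v)
    if cfg.damper_ramp_depth > 0:
        ramp = np.minimum(1.0, d / cfg.damper_ramp_depth)
    else:
        ramp = np.ones_like(d)
    damper_power = np.where(
        F > 0, cfg.c * v**2 * ramp * np.where(d > 0, d, 0.0) ** (cfg.n - 1.0), 0.0
    )
    dissipated = cumtrapz(damper_power)
    stored = cfg.k * d ** (cfg.n + 1.0) / (cfg.n + 1.0)

    sol = SimSolution(t=t, z=z, v=v, F=F, config=cfg)
    _, vel = sol.horizontal_path()
    shear_power = np.einsum("ni,ni->n", sol.shear_force(), vel)
    shear_work = cumtrapz(shear_power)

    # true events: peak contact force; first upward zero crossing of v
    i_p = int(np.argmax(F))
    t_p_true = t[i_p]
    up = np.nonzero((v[:-1] < 0) & (v[1:] >= 0))[0]
    if up.size:
        i = up[0]
        t_e_true = t[i] + (-v[i] / (v[i + 1] - v[i])) * h
    else:
        t_e_true = t[-1]

    truth = SimTruth(
        t=t, deformation=d, dissipated_energy=dissipated, stored_elastic=stored,
        work_by_contact=work_by_contact, shear_work=shear_work, z=z, v=v,
        touchdown_time=cfg.lead_in,
        t_p_true=cfg.lead_in + t_p_true, t_e_true=cfg.lead_in + t_e_true,
        mass=M,
    )
    return sol, truth


def _heel_global(sol: SimSolution, t_rendered: np.ndarray) -> np.ndarray:
    """Global heel-point trajectory on the rendered timeline, shape (n, 3)."""
    cfg = sol.config
    ts = t_rendered - cfg.lead_in  # time from touchdown
    x0, y0 = cfg.touchdown_xy
    out = np.empty((t_rendered.size, 3))
    disp, _ = sol.horizontal_path()
    pre = ts < 0
    # pre-contact: constant-velocity descent at v0, no horizontal motion
    out[pre, 0] = x0
    out[pre, 1] = y0
    out[pre, 2] = cfg.v0 * ts[pre]
    post = ~pre
    out[post, 0] = x0 + np.interp(ts[post], sol.t, disp[:, 0])
    out[post, 1] = y0 + np.interp(ts[post], sol.t, disp[:, 1])
    out[post, 2] = np.interp(ts[post], sol.t, sol.z)
    return out


def _tilt_angle(cfg: SimConfig, t_rendered: np.ndarray) -> np.ndarray:
    """Segment tilt about global X (rad): constant, ramping after contact."""
    ts = np.maximum(0.0, t_rendered - cfg.lead_in)
    return np.deg2rad(cfg.tilt_deg + cfg.tilt_ramp * ts)


def _rot_x(theta: np.ndarray) -> np.ndarray:
    """(n, 3, 3) rotation matrices about the global X axis."""
    c, s = np.cos(theta), np.sin(theta)
    R = np.zeros((theta.size, 3, 3))
    R[:, 0, 0] = 1.0
    R[:, 1, 1] = c
    R[:, 1, 2] = -s
    R[:, 2, 1] = s
    R[:, 2, 2] = c
    return R


def channels_for_load(
    F_X: np.ndarray,
    F_Y: np.ndarray,
    F_Z: np.ndarray,
    cop_x: np.ndarray,
    cop_y: np.ndarray,
    geom: PlateGeometry,
) -> dict[str, np.ndarray]:
    """Forward-render plate channels for a net load at a global-frame COP.

    The vertical load splits bilinearly among the four sensors at the
    sensor-plane projection of the COP (the surface COP shifted by the
    shear lever ``az0 F_xy / F_Z``); shear splits evenly between its
    paired channels.  Exact inverse of the pipeline channel reduction.
    """
    F_X, F_Y, F_Z = (np.atleast_1d(np.asarray(a, float)) for a in (F_X, F_Y, F_Z))
    cx = np.atleast_1d(np.asarray(cop_x, float)) - geom.origin_offset[0]
    cy = np.atleast_1d(np.asarray(cop_y, float)) - geom.origin_offset[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        xs = np.where(F_Z > 0, cx - geom.az0 * F_X / F_Z, 0.0)
        ys = np.where(F_Z > 0, cy - geom.az0 * F_Y / F_Z, 0.0)
    loaded = F_Z > 0
    if np.any((np.abs(xs[loaded]) > geom.a) | (np.abs(ys[loaded]) > geom.b)):
        raise RenderError("COP outside the sensor rectangle")
    out = dict(fx12=F_X / 2.0, fx34=F_X / 2.0, fy14=F_Y / 2.0, fy23=F_Y / 2.0)
    for i, (sx, sy) in enumerate(geom.sensor_xy):
        w = 0.25 * (1.0 + np.sign(sx) * xs / geom.a) * (1.0 + np.sign(sy) * ys / geom.b)
        out[f"fz{i + 1}"] = w * F_Z
    return out


def render_plate_channels(sol: SimSolution, cfg: SimConfig | None = None,
                          rng: np.random.Generator | None = None) -> ChannelRecord:
    """Render the contact force as a raw 8-channel plate record.

    The vertical load is split bilinearly among the four sensors at the
    sensor-plane projection of the COP (surface COP minus the az0 shear
    lever); shear splits evenly between its paired channels.  The force
    clock is offset by ``sync_jitter`` relative to the kinematic
    timeline, and seeded Gaussian channel noise is added if configured.
    This forward model is the exact inverse of the pipeline's channel
    reduction.
    """
    cfg = cfg or sol.config
    rng = rng or np.random.default_rng(cfg.seed)
    geom = cfg.plate
    n = int(np.floor((cfg.lead_in + sol.t[-1]) * cfg.force_rate))
    t_stamp = np.arange(n + 1) / cfg.force_rate
    t_phys = t_stamp + cfg.sync_jitter  # what the plate actually samples

    ts = t_phys - cfg.lead_in
    F_Z = np.interp(ts, sol.t, sol.F, left=0.0, right=0.0)
    shear = sol.shear_force()
    F_X = np.interp(ts, sol.t, shear[:, 0], left=0.0, right=0.0)
    F_Y = np.interp(ts, sol.t, shear[:, 1], left=0.0, right=0.0)

    heel = _heel_global(sol, t_phys)
    channels = channels_for_load(F_X, F_Y, F_Z, heel[:, 0], heel[:, 1], geom)
    if cfg.noise_channel_sd > 0:
        for key in channels:
            channels[key] = channels[key] + rng.normal(
                0.0, cfg.noise_channel_sd, t_stamp.size
            )
    return ChannelRecord(time=t_stamp, **channels)


def render_markers(sol: SimSolution, cfg: SimConfig | None = None,
                   rng: np.random.Generator | None = None) -> MarkerSeries:
    """Render the two-LED marker record of the rigid shank segment.

    LEDs sit at fixed segment-frame offsets from the heel point; the
    segment translates with the simulated mass (plus prescribed
    horizontal drift) and tilts about global X by the configured
    constant angle plus optional slow ramp.  Seeded Gaussian noise of
    ``noise_marker_sd`` is added per coordinate.
    """
    cfg = cfg or sol.config
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n = int(np.floor((cfg.lead_in + sol.t[-1]) * cfg.kin_rate))
    t = np.arange(n + 1) / cfg.kin_rate

    heel = _heel_global(sol, t)
    R = _rot_x(_tilt_angle(cfg, t))
    o1, o2 = cfg.led_offsets()
    led1 = heel + np.einsum("nij,j->ni", R, o1)
    led2 = heel + np.einsum("nij,j->ni", R, o2)
    if cfg.noise_marker_sd > 0:
        led1 = led1 + rng.normal(0.0, cfg.noise_marker_sd, led1.shape)
        led2 = led2 + rng.normal(0.0, cfg.noise_marker_sd, led2.shape)
    return MarkerSeries(time=t, led1=led1, led2=led2)


def render_trial(cfg: SimConfig) -> tuple[ChannelRecord, MarkerSeries, SimTruth]:
    """Simulate and render one complete trial (deterministic given seed)."""
    sol, truth = simulate_heel_impact(cfg)
    rng = np.random.default_rng(cfg.seed)
    rec = render_plate_channels(sol, cfg, rng)
    markers = render_markers(sol, cfg, rng)
    return rec, markers, truth


# ---------------------------------------------------------------------------
# fixture study


DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    # study-like conditions: effective mass ~9-13% of a 76.7 +/- 15 kg body,
    # stiffness/damping giving t_p ~ 12-25 ms and t_e/t_p ~ 1.5-2.3,
    # touchdown velocity spanning the observed -0.78..-0.39 m/s subject means
    "body_mass": (55.0, 95.0),
    "mass_fraction": (0.09, 0.13),
    "k": (12e3, 18e3),
    "damping_ratio": (0.30, 0.45),
    "v0": (-0.70, -0.45),
    "tilt_deg": (0.0, 8.0),
    "tilt_ramp": (5.0, 20.0),
}

#: trial-to-trial scatter of the touchdown velocity within a subject (m/s)
V0_TRIAL_SD = 0.03


def make_fixture_study(
    n_subjects: int = 12,
    n_trials: int = 10,
    parameter_ranges: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    noisy: bool = True,
) -> list[dict]:
    """Generate a study's worth of synthetic trials with a truth manifest.

    Per subject, body mass, effective-mass fraction, contact stiffness,
    damping ratio, touchdown velocity and segment tilt are drawn from
    ``parameter_ranges`` (uniform); per trial the touchdown velocity is
    jittered.  With ``noisy`` the rendered records carry 0.1 mm marker
    noise, 0.25 N channel noise and a +/-1 ms force-clock offset.

    Returns a list of trial dicts with keys ``subject_id``,
    ``trial_id``, ``config``, ``truth``, ``channels``, ``markers``;
    when ``out_dir`` is given the records are additionally written as
    CSV pairs plus a ``truth.json`` manifest.  Deterministic given the
    seed.
    """
    ranges = {**DEFAULT_RANGES, **(parameter_ranges or {})}
    rng = np.random.default_rng(seed)
    trials: list[dict] = []

    for si in range(n_subjects):
        u = lambda key: float(rng.uniform(*ranges[key]))  # noqa: E731
        body_mass = u("body_mass")
        mass = body_mass * u("mass_fraction")
        k = u("k")
        c = u("damping_ratio") * 2.0 * np.sqrt(k * mass)
        v0_subj = u("v0")
        tilt = u("tilt_deg")
        ramp = u("tilt_ramp")
        subject_id = f"S{si + 1:02d}"
        for ti in range(n_trials):
            v0 = min(-0.05, v0_subj + float(rng.normal(0.0, V0_TRIAL_SD)))
            jitter = float(rng.uniform(-1e-3, 1e-3)) if noisy else 0.0
            cfg = SimConfig(
                mass=mass, k=k, c=c, v0=v0,
                tilt_deg=tilt, tilt_ramp=ramp,
                noise_marker_sd=1e-4 if noisy else 0.0,
                noise_channel_sd=0.25 if noisy else 0.0,
                sync_jitter=jitter,
                seed=int(rng.integers(0, 2**31 - 1)),
                body_mass=body_mass,
            )
            rec, markers, truth = render_trial(cfg)
            trials.append(dict(
                subject_id=subject_id, trial_id=f"T{ti + 1:02d}",
                config=cfg, truth=truth, channels=rec, markers=markers,
            ))

    if out_dir is not None:
        from .io import write_force_csv, write_marker_csv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {}
        for tr in trials:
            stem = f"{tr['subject_id']}_{tr['trial_id']}"
            write_force_csv(tr["channels"], out / f"{stem}_force.csv")
            write_marker_csv(tr["markers"], out / f"{stem}_markers.csv")
            cfg = tr["config"]
            manifest[stem] = dict(
                subject_id=tr["subject_id"], trial_id=tr["trial_id"],
                force_file=f"{stem}_force.csv", marker_file=f"{stem}_markers.csv",
                body_mass=cfg.body_mass,
                mass=cfg.mass, k=cfg.k, c=cfg.c, v0=cfg.v0,
                damping_ratio=cfg.damping_ratio,
                truth=tr["truth"].summary(),
            )
        with open(out / "truth.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return trials
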