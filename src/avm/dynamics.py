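"""Overdamped active dynamics of cell centres and polarity angles.

Each interior cell carries a unit polarity n_i = (cos theta_i, sin theta_i)
and self-propels with force f_a n_i.  The equations of motion are

    gamma   dr_i/dt     = f_a n_i + F_i + nu_i(t)
    gamma_r dtheta_i/dt = tau_i + nu_i^r(t)

with F_i the vertex-model + soft-core + boundary-line force, tau_i the
z-component of the alignment torque, and Gaussian white noises of strength
2D and 2D_r.  Integration is plain Euler-Maruyama; after every step the
Delaunay property is restored by equiangulation and any flips between four
interior cells are logged as T1 events.

Boundary ghosts move under passive forces only (free mode) or not at all
(fixed mode); they carry no polarity, activity or noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import boundary as bnd
from . import mechanics as mech
from .tissue import Tissue, FLAG_INTERIOR, FLAG_BOUNDARY

__all__ = [
    "ActiveParams",
    "StepEvents",
    "shape_tensor",
    "shape_axis_angle",
    "alignment_torque",
    "assemble_forces",
    "step",
    "free_particle_msd_trajectories",
    "free_polarity_angles",
]


@dataclass
class ActiveParams:
    """Activity, noise and alignment parameters.

    ``alignment`` is a tuple drawn from {"polar", "velocity", "shape"};
    multiple mechanisms are additive.  ``tau_r_inv`` is an alternative way to
    set the rotational noise: D_r = tau_r_inv / 2 per the decorrelation time
    tau_r = gamma_r / (2 D_r).
    """

    f_a: float = 0.0
    gamma: float = 1.0
    gamma_r: float = 1.0
    D: float = 0.0
    D_r: float = 0.0
    J_p: float = 0.0
    J_v: float = 0.0
    J_s: float = 0.0
    alignment: tuple[str, ...] = ()
    dt: float = 0.01

    def __post_init__(self):
        if self.gamma <= 0 or self.gamma_r <= 0 or self.dt <= 0:
            raise ValueError("gamma, gamma_r and dt must be positive")
        if self.D < 0 or self.D_r < 0:
            raise ValueError("noise magnitudes must be non-negative")
        unknown = set(self.alignment) - {"polar", "velocity", "shape"}
        if unknown:
            raise ValueError(f"unknown alignment model(s): {sorted(unknown)}")

    @classmethod
    def with_tau_r_inv(cls, tau_r_inv: float, **kw) -> "ActiveParams":
        return cls(D_r=tau_r_inv / 2.0, **kw)

    @property
    def v0(self) -> float:
        """Free-cell active speed f_a / gamma."""
        return self.f_a / self.gamma


@dataclass
class StepEvents:
    t1: list[tuple[int, int, int, int]] = field(default_factory=list)  # site ids
    flips: int = 0


# ---------------------------------------------------------------------------
# shape tensor and torques
# ---------------------------------------------------------------------------

def shape_tensor(vertices: np.ndarray) -> np.ndarray:
    """2x2 cell shape tensor from ordered polygon vertices.

    Built from coordinate differences of consecutive vertices, normalised by
    the vertex count; symmetric positive semi-definite, with the dominant
    eigenvector along the cell's long axis.
    """
    d = np.roll(vertices, -1, axis=0) - vertices
    M = d.T @ d / len(vertices)
    return M


def shape_axis_angle(vertices: np.ndarray) -> float:
    """Angle of the principal (largest-eigenvalue) axis of the shape tensor.

    The eigenvector sign is arbitrary; callers disambiguate against the
    polarity (nematic convention).
    """
    M = shape_tensor(vertices)
    w, v = np.linalg.eigh(M)
    axis = v[:, int(np.argmax(w))]
    return float(np.arctan2(axis[1], axis[0]))


def alignment_torque(
    tissue: Tissue,
    params: ActiveParams,
    velocities: np.ndarray | None = None,
) -> np.ndarray:
    """Alignment torque (z-component) per site; zero for non-interior sites.

    polar:    tau_i = J_p sum_j sin(theta_j - theta_i) over Delaunay
              neighbour cells j,
    velocity: tau_i = J_v sin(theta_v - theta_i) with theta_v the direction
              of the previous-step velocity (zero torque for zero velocity),
    shape:    tau_i = J_s sin(theta_p - theta_i) with theta_p the principal
              axis of the cell shape tensor, sign chosen so n . p >= 0.
    """
    tau = np.zeros(tissue.n_sites)
    if not params.alignment:
        return tau
    theta = tissue.theta
    if "polar" in params.alignment and params.J_p != 0.0:
        edges = tissue.mesh.edges()
        ii = tissue.interior
        cc = edges[ii[edges[:, 0]] & ii[edges[:, 1]]]
        dth = theta[cc[:, 1]] - theta[cc[:, 0]]
        s = np.sin(dth)
        np.add.at(tau, cc[:, 0], params.J_p * s)
        np.add.at(tau, cc[:, 1], -params.J_p * s)
    if "velocity" in params.alignment and params.J_v != 0.0 and velocities is not None:
        # (no velocity history yet, e.g. the first step, is the zero-velocity
        # limit: zero torque)
        speed = np.linalg.norm(velocities, axis=1)
        moving = (speed > 1e-14) & tissue.interior
        tv = np.arctan2(velocities[moving, 1], velocities[moving, 0])
        tau[moving] += params.J_v * np.sin(tv - theta[moving])
    if "shape" in params.alignment and params.J_s != 0.0:
        geo = mech.cell_geometry(tissue)
        cx = geo["cells"]
        for ci in range(cx.n_cells):
            sl = slice(cx.ptr[ci], cx.ptr[ci + 1])
            i = int(cx.owners[ci])
            tp = shape_axis_angle(geo["V"][sl])
            # nematic: fold the axis into the half-plane around theta_i
            if np.cos(tp - theta[i]) < 0:
                tp += np.pi
            tau[i] += params.J_s * np.sin(tp - theta[i])
    return tau


# ---------------------------------------------------------------------------
# forces and the integration step
# ---------------------------------------------------------------------------

def assemble_forces(
    tissue: Tissue,
    mparams: mech.MechanicalParams,
    bparams: bnd.BoundaryParams | None = None,
) -> np.ndarray:
    """Total passive force: vertex model + soft core + boundary line."""
    F = mech.vm_forces(tissue, mparams)
    F += mech.soft_core_forces(tissue, mparams)
    if bparams is not None and (bparams.lam != 0.0 or bparams.zeta != 0.0):
        F += bnd.boundary_forces(tissue, bparams)
    return F


def _mobile_mask(tissue: Tissue, bparams: bnd.BoundaryParams | None) -> np.ndarray:
    mobile = np.ones(tissue.n_sites, dtype=bool)
    mobile[tissue.flags == 2] = False  # walls never move
    for loop, fixed in zip(tissue.loops, tissue.loop_fixed):
        if fixed:
            mobile[loop] = False
    if bparams is not None and bparams.mode == "fixed":
        mobile[tissue.flags == FLAG_BOUNDARY] = False
    return mobile


def step(
    tissue: Tissue,
    aparams: ActiveParams,
    mparams: mech.MechanicalParams,
    bparams: bnd.BoundaryParams | None,
    rng: np.random.Generator,
    velocities: np.ndarray | None = None,
    max_disp: float = 0.5,
):
    """One Euler-Maruyama step; returns (events, velocities).

    The returned ``velocities`` array (displacement / dt) feeds the velocity
    alignment torque at the next step.  A displacement larger than
    ``max_disp`` (in units of the soft-core range) aborts with an error: the
    time step is too large for the current forces.
    """
    dt = aparams.dt
    F = assemble_forces(tissue, mparams, bparams)
    interior = tissue.interior
    n = np.stack([np.cos(tissue.theta), np.sin(tissue.theta)], axis=1)
    drive = np.zeros_like(F)
    drive[interior] = aparams.f_a * n[interior]
    disp = (dt / aparams.gamma) * (F + drive)
    if aparams.D > 0:
        xi = rng.standard_normal((tissue.n_sites, 2))
        noise = (np.sqrt(2.0 * aparams.D * dt) / aparams.gamma) * xi
        disp[interior] += noise[interior]
    mobile = _mobile_mask(tissue, bparams)
    disp[~mobile] = 0.0
    dmax = float(np.max(np.linalg.norm(disp, axis=1))) if len(disp) else 0.0
    if dmax > max_disp:
        raise RuntimeError(
            f"per-step displacement {dmax:.3g} exceeds {max_disp}: reduce dt"
        )
    tissue.pos += disp
    tissue.mark_moved()

    # polarity update
    if aparams.alignment or aparams.D_r > 0:
        tau = alignment_torque(tissue, aparams, velocities) if aparams.alignment else 0.0
        dtheta = (dt / aparams.gamma_r) * tau
        if aparams.D_r > 0:
            xir = rng.standard_normal(tissue.n_sites)
            dtheta = dtheta + (np.sqrt(2.0 * aparams.D_r * dt) / aparams.gamma_r) * xir
        tissue.theta[interior] = tissue.theta[interior] + (
            dtheta[interior] if np.ndim(dtheta) else dtheta
        )

    flips, quads = tissue.equiangulate()
    events = StepEvents(flips=flips)
    for a, b, c, d in quads:
        if interior[a] and interior[b] and interior[c] and interior[d]:
            events.t1.append(
                (
                    int(tissue.ids[a]),
                    int(tissue.ids[b]),
                    int(tissue.ids[c]),
                    int(tissue.ids[d]),
                )
            )
    return events, disp / dt


# ---------------------------------------------------------------------------
# free-particle validation utilities
# ---------------------------------------------------------------------------

def free_particle_msd_trajectories(
    params: ActiveParams, n_particles: int, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Positions (n_steps+1, n_particles, 2) of force-free cells under Eq. of
    motion noise only — the analytic benchmark MSD = 4 (D/gamma^2) t."""
    pos = np.zeros((n_steps + 1, n_particles, 2))
    scale = np.sqrt(2.0 * params.D * params.dt) / params.gamma
    for s in range(n_steps):
        pos[s + 1] = pos[s] + scale * rng.standard_normal((n_particles, 2))
    return pos


def free_polarity_angles(
    params: ActiveParams, n_particles: int, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Torque-free polarity angles (n_steps+1, n_particles); the benchmark
    autocorrelation is <cos(dtheta)> = exp(-D_r t / gamma_r^2 ... )."""
    th = np.zeros((n_steps + 1, n_particles))
    scale = np.sqrt(2.0 * params.D_r * params.dt) / params.gamma_r
    for s in range(n_steps):
        th[s + 1] = th[s] + scale * rng.standard_normal(n_particles)
    return th
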