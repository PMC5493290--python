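"""Run orchestration: configuration, the main loop, sweeps and experiments.

The per-step loop follows the model's flow: passive forces (vertex model +
soft core + boundary line) and alignment torques are evaluated on the
current Delaunay mesh; positions and polarities advance by one
Euler-Maruyama step; equiangulation restores the Delaunay property (logging
T1 flips); population events (growth every step, division/death checks at
a fixed cadence) and boundary refinement trigger full triangulation
rebuilds.  Snapshots, the event log and a run manifest are written to a
trajectory directory when requested.
"""

from __future__ import annotations

import dataclasses
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boundary as bnd
from . import dynamics as dyn
from . import mechanics as mech
from . import observables as obs
from . import population as pop
from . import scenarios, trajio
from .tissue import Tissue

__all__ = ["RunConfig", "RunResult", "run", "relax", "sweep", "sorting_experiment"]

INSTABILITY_THRESHOLD = 0.05  # boundary-length growth marking the unstable phase


@dataclass
class RunConfig:
    """Everything needed to reproduce one run bit-for-bit."""

    scenario: scenarios.ScenarioSpec = field(default_factory=scenarios.ScenarioSpec)
    mechanics: mech.MechanicalParams = field(default_factory=mech.MechanicalParams)
    active: dyn.ActiveParams = field(default_factory=dyn.ActiveParams)
    boundary: bnd.BoundaryParams = field(default_factory=bnd.BoundaryParams)
    population: pop.PopulationParams = field(default_factory=pop.PopulationParams)
    n_steps: int = 1000
    snapshot_every: int = 100
    refine_every: int = 10
    pre_relax_steps: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, dict):
                return {clean(k): clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            if isinstance(x, np.ndarray):
                return clean(x.tolist())
            if isinstance(x, (np.floating,)):
                return float(x)
            if isinstance(x, (np.integer,)):
                return int(x)
            if isinstance(x, (np.bool_,)):
                return bool(x)
            return x

        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sc = d.get("scenario", {})
        if "type_fractions" in sc:
            sc["type_fractions"] = {int(k): float(v) for k, v in sc["type_fractions"].items()}
        me = dict(d.get("mechanics", {}))
        if isinstance(me.get("Lambda"), list):
            me["Lambda"] = np.asarray(me["Lambda"], dtype=float)
        ac = dict(d.get("active", {}))
        if "alignment" in ac:
            ac["alignment"] = tuple(ac["alignment"])
        return cls(
            scenario=scenarios.ScenarioSpec(**sc),
            mechanics=mech.MechanicalParams(**me),
            active=dyn.ActiveParams(**ac),
            boundary=bnd.BoundaryParams(**d.get("boundary", {})),
            population=pop.PopulationParams(**d.get("population", {})),
            **{
                k: d[k]
                for k in ("n_steps", "snapshot_every", "refine_every", "pre_relax_steps", "seed")
                if k in d
            },
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunResult:
    config: RunConfig
    tissue: Tissue
    times: np.ndarray
    frames: list  # list of (ids, interior positions) per snapshot
    events: list  # list of event dicts
    boundary_lengths: np.ndarray
    tau_inst: float
    n_cells_series: np.ndarray

    def scattering(self, **kw) -> obs.ScatteringResult:
        ids, P = trajio.aligned_positions(self.frames)
        return obs.self_intermediate(self.times, P, **kw)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self.times) else 0.0

    def t1_rate(self) -> float:
        mean_n = float(np.mean(self.n_cells_series))
        rate, _ = obs.t1_statistics(self.events, int(mean_n), max(self.duration, 1e-300))
        return rate

    def phase(self) -> obs.PhaseMetrics:
        sc = self.scattering()
        return obs.classify_phase(self.t1_rate(), sc.tau_alpha, self.duration, self.tau_inst)


def run(
    config: RunConfig,
    outdir: str | Path | None = None,
    tissue: Tissue | None = None,
    rng: np.random.Generator | None = None,
    start_step: int = 0,
) -> RunResult:
    """Execute a run; optionally continue from an existing tissue/rng state."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if tissue is None:
        tissue = scenarios.init_packing(config.scenario, rng)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "start_step": start_step,
            "wall_start": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)

    n_loops = len(tissue.loops)

    # optional passive pre-relaxation (no activity, no noise, no events)
    if config.pre_relax_steps > 0 and start_step == 0:
        quiet = dataclasses.replace(
            config.active, f_a=0.0, D=0.0, D_r=0.0, alignment=()
        )
        for _ in range(config.pre_relax_steps):
            dyn.step(tissue, quiet, config.mechanics, config.boundary, rng)

    dt = config.active.dt
    times = []
    frames = []
    events: list[dict] = []
    blens = []
    n_series = []
    velocities = None
    ref_blen = bnd.boundary_length(tissue)
    tau_inst = np.inf

    def record(step):
        times.append(step * dt)
        frames.append(trajio.interior_table(tissue))
        n_series.append(tissue.n_cells)
        if out is not None:
            trajio.write_snapshot(tissue, out / f"frame_{step:08d}.tsv")

    record(start_step)
    blens.append(ref_blen)
    last_check_step = start_step

    def one_step(vel):
        """One dt of dynamics; violent transients (fresh divisions in a
        crowded region) are integrated with temporary sub-steps."""
        try:
            return dyn.step(
                tissue, config.active, config.mechanics, config.boundary, rng, vel
            )
        except RuntimeError:
            n_sub = 50
            sub = dataclasses.replace(config.active, dt=config.active.dt / n_sub)
            ev_all = dyn.StepEvents()
            for _ in range(n_sub):
                ev_s, vel = dyn.step(tissue, sub, config.mechanics, config.boundary, rng, vel)
                ev_all.t1.extend(ev_s.t1)
                ev_all.flips += ev_s.flips
            return ev_all, vel

    for step in range(start_step, start_step + config.n_steps):
        ev, velocities = one_step(velocities)
        now = (step + 1) * dt
        for quad in ev.t1:
            events.append({"step": step + 1, "time": now, "event": "T1", "ids": quad})
        pop.grow(tissue, config.population, dt)
        if (
            (config.population.chi > 0.0 or config.population.enable_death)
            and (step + 1 - last_check_step) >= config.population.check_every
        ):
            interval = (step + 1 - last_check_step) * dt
            for rec in pop.population_update(tissue, config.population, rng, interval):
                events.append(
                    {"step": step + 1, "time": now, "event": rec[0], "ids": rec[1:]}
                )
            last_check_step = step + 1
            velocities = None  # indices changed; velocity memory is void
        if (
            config.boundary.mode == "free"
            and config.refine_every > 0
            and (step + 1) % config.refine_every == 0
        ):
            for rec in bnd.refine(tissue, config.boundary):
                events.append(
                    {"step": step + 1, "time": now, "event": rec[0], "ids": (rec[1],)}
                )
                velocities = None
        blen = bnd.boundary_length(tissue)
        blens.append(blen)
        ref_blen = min(ref_blen, blen)
        if not np.isfinite(tau_inst) and blen > (1.0 + INSTABILITY_THRESHOLD) * ref_blen:
            tau_inst = now
        bnd.topology_guard(tissue, expected_loops=n_loops)
        if (step + 1) % config.snapshot_every == 0 or step + 1 == start_step + config.n_steps:
            record(step + 1)

    if out is not None:
        trajio.write_events(events, out / "events.tsv")
        trajio.save_rng_state(rng, out / "rng_state.json")
        trajio.write_snapshot(tissue, out / "final.tsv")
        diag = pd.DataFrame({"time": np.arange(len(blens)) * dt, "boundary_length": blens})
        diag.to_csv(out / "boundary_length.tsv", sep="\t", index=False)
    return RunResult(
        config=config,
        tissue=tissue,
        times=np.asarray(times),
        frames=frames,
        events=events,
        boundary_lengths=np.asarray(blens),
        tau_inst=tau_inst,
        n_cells_series=np.asarray(n_series),
    )


def relax(
    tissue: Tissue,
    mparams: mech.MechanicalParams,
    bparams: bnd.BoundaryParams | None = None,
    gtol: float = 1e-10,
    maxiter: int = 5000,
) -> float:
    """Drive the tissue to a local energy minimum (zero-activity ground state).

    Minimises the total passive energy over all mobile sites with L-BFGS,
    re-equiangulating at every evaluation so T1 topology changes are allowed
    along the way.  Returns the final maximum force magnitude.
    """
    from scipy.optimize import minimize

    from .geometry import MeshError

    mobile = dyn._mobile_mask(tissue, bparams)
    idx = np.nonzero(mobile)[0]
    best = {"e": np.inf, "x": tissue.pos[idx].copy()}

    def fg(x):
        tissue.pos[idx] = x.reshape(-1, 2)
        tissue.mark_moved()
        try:
            # full rebuild: validates the trial configuration (flip passes
            # alone cannot detect a cell thrown past the ghost ring)
            tissue.remesh()
            e = mech.vm_energy(tissue, mparams).total + mech.soft_core_energy(
                tissue, mparams
            )
            if bparams is not None:
                e += sum(bnd.boundary_energy(tissue, bparams))
            F = dyn.assemble_forces(tissue, mparams, bparams)
        except MeshError:
            # wild line-search step (e.g. a cell thrown past the ghost ring):
            # reject with a huge energy so the search backtracks
            return 1e20, np.zeros(2 * len(idx))
        if e < best["e"]:
            best["e"] = e
            best["x"] = tissue.pos[idx].copy()
        return e, (-F[idx]).ravel()

    minimize(
        fg,
        tissue.pos[idx].ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 0.0},
    )
    tissue.pos[idx] = best["x"]
    tissue.mark_moved()
    tissue.remesh()
    # L-BFGS line searches stall once energy differences reach the rounding
    # floor; a gradient-only overdamped descent keeps reducing the force
    lr = 0.05
    cap = 0.1  # max per-iteration displacement, units of a
    maxF = np.inf
    for _ in range(20000):
        F = dyn.assemble_forces(tissue, mparams, bparams)
        maxF = float(np.max(np.linalg.norm(F[mobile], axis=1)))
        if maxF < gtol:
            break
        disp = lr * F[mobile]
        m = float(np.max(np.linalg.norm(disp, axis=1)))
        if m > cap:
            disp *= cap / m
        tissue.pos[mobile] += disp
        tissue.mark_moved()
        tissue.equiangulate()
    return maxF


# ---------------------------------------------------------------------------
# experiment suites
# ---------------------------------------------------------------------------

def sweep(
    p0_values,
    f_a_values,
    base: RunConfig,
    replicates: int = 1,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Phase scan over the (p0, f_a) grid.

    The uniform junction tension is set from p0 by Lambda = -p0 Gamma
    sqrt(A0).  One run per (p0, f_a, seed); failures are recorded and the
    sweep continues.  Returns one row per run with tau_alpha, t1_rate,
    tau_inst and the phase classification.
    """
    rows = []
    for p0 in p0_values:
        for f_a in f_a_values:
            for rep in range(replicates):
                seed = int(base.seed + 1000 * rep + hash((round(p0, 6), round(f_a, 6))) % 997)
                cfg = dataclasses.replace(
                    base,
                    mechanics=dataclasses.replace(
                        base.mechanics,
                        Lambda=mech.p0_to_lambda(
                            p0, np.asarray(base.mechanics.Gamma).item(), base.scenario.A0
                        ),
                    ),
                    active=dataclasses.replace(base.active, f_a=f_a),
                    seed=seed,
                )
                row = {"p0": p0, "f_a": f_a, "seed": seed}
                try:
                    sub = Path(outdir) / f"p0_{p0:.3f}_fa_{f_a:.3f}_{rep}" if outdir else None
                    res = run(cfg, outdir=sub)
                    ph = res.phase()
                    sc_tau = ph.tau_alpha
                    row.update(
                        tau_alpha=(
                            sc_tau
                            if np.isfinite(sc_tau)
                            else res.duration * obs.CENSOR_FACTOR
                        ),
                        censored=not np.isfinite(sc_tau),
                        t1_rate=ph.t1_rate,
                        t1_count=sum(1 for e in res.events if e["event"] == "T1"),
                        tau_inst=ph.tau_inst if np.isfinite(ph.tau_inst) else np.inf,
                        classification=ph.classification,
                        error="",
                    )
                except Exception as exc:  # keep sweeping
                    row.update(
                        tau_alpha=np.nan,
                        censored=True,
                        t1_rate=np.nan,
                        t1_count=-1,
                        tau_inst=np.nan,
                        classification="failed",
                        error=str(exc),
                    )
                rows.append(row)
    df = pd.DataFrame(rows)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(outdir) / "sweep.tsv", sep="\t", index=False)
    return df


def sorting_experiment(config: RunConfig, sample_every: int | None = None):
    """Two-type sorting run; returns (times, demixing-index series, result).

    The demixing index is the fraction of cell-cell junction length joining
    same-type cells; it rises during sorting (Lambda_rb above the mean of
    the like-type tensions) and falls towards a checkerboard when the
    inequality is reversed.
    """
    from . import observables as obs_mod

    if sample_every is None:
        sample_every = config.snapshot_every
    rng = np.random.default_rng(config.seed)
    tissue = scenarios.init_packing(config.scenario, rng)
    dt = config.active.dt
    times = [0.0]
    series = [obs_mod.demixing_index(tissue)]
    velocities = None
    for step in range(config.n_steps):
        _, velocities = dyn.step(
            tissue, config.active, config.mechanics, config.boundary, rng, velocities
        )
        if (step + 1) % sample_every == 0:
            times.append((step + 1) * dt)
            series.append(obs_mod.demixing_index(tissue))
    return np.asarray(times), np.asarray(series), tissue
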