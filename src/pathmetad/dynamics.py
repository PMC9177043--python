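"""Overdamped Langevin propagation and the multiple-path metadynamics engine.

The engine is a desk-scale surrogate for the all-atom protocol: walkers move
by overdamped (Brownian) dynamics on an analytic CV-space potential; each
path carries a shared metadynamics bias on its progress coordinate s, a tube
potential on the perpendicular component z, and attractor walkers holding the
path through chosen intermediate states; paths adapt from the restrained
cumulative sampling density.

Time bookkeeping: one engine "ps" is 100 Langevin steps at dt = 0.01, so the
reference schedule (1 ps hill/update pace, 20 ps steering, analysis windows)
carries over by the same ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bias import (
    BiasGrid,
    Hill,
    HillList,
    RestraintSchedule,
    Walker,
    WalkerEnsemble,
    wrap_s,
    write_hills,
)
from .cvspace import plane_space
from .errors import ParameterError, PropagationError
from .pathcv import (
    PathCurve,
    PathUpdateState,
    init_cyclic_path,
    reparameterize,
    smooth_lambda,
    smooth_path_cv,
    update_path,
    write_path,
)
from .potentials import KT_300K, AnalyticPotential
from .reference import rolling_embed

__all__ = [
    "LangevinConfig",
    "langevin_step",
    "PathProtocol",
    "MultiPMDConfig",
    "PathRunResult",
    "RunResult",
    "run_multipmd",
    "rotor_flip_protocol",
    "double_channel_protocol",
]


@dataclass(frozen=True)
class LangevinConfig:
    """Overdamped Langevin parameters.

    kT defaults to 0.596 kcal/mol (300 K) in the same energy units as the
    bias force constants.  Equal seeds give bit-identical trajectories.
    """

    kT: float = KT_300K
    friction: float = 1.0
    dt: float = 0.01
    seed: int = 0
    n_steps: int = 1000

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ParameterError("dt must be > 0")
        if not self.friction > 0:
            raise ParameterError("friction must be > 0")


def _wrap_axes(x: np.ndarray, periodic_axes) -> np.ndarray:
    for j in periodic_axes:
        x[..., j] = (x[..., j] + np.pi) % (2.0 * np.pi) - np.pi
    return x


def langevin_step(
    pos: np.ndarray,
    potential: AnalyticPotential,
    bias_force,
    config: LangevinConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One overdamped Euler-Maruyama step.

    x <- x - (grad V - F_bias) dt / gamma + sqrt(2 kT dt / gamma) eta,
    with eta standard normal per axis from the supplied seeded generator.
    Periodic axes of the potential are wrapped to [-pi, pi).
    ``bias_force`` is an additional force array (or None).
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    grad = np.atleast_2d(potential.gradient(pos))
    if not np.all(np.isfinite(grad)):
        raise PropagationError("non-finite potential gradient")
    force = -grad
    if bias_force is not None:
        bias_force = np.atleast_2d(np.asarray(bias_force, dtype=float))
        if not np.all(np.isfinite(bias_force)):
            raise PropagationError("non-finite bias force")
        force = force + bias_force
    g = config.friction
    new = pos + force * (config.dt / g)
    if config.kT > 0:
        new = new + np.sqrt(2.0 * config.kT * config.dt / g) * rng.standard_normal(pos.shape)
    return _wrap_axes(new, potential.periodic_axes)


# ---------------------------------------------------------------------------
# engine configuration


@dataclass
class PathProtocol:
    """Per-path protocol: discretization, flexibility and walker roles.

    The reference arrangement is 9 standard walkers plus 3 attractors: one
    harmonically restrained at the second stable state (force constant 50)
    and two steered to s = +/-0.5 (force constant 5000 per squared path unit
    over the first 20 ps) carrying a harmonic restraint on the opening axis
    (force constant 5000) at ``attractor_theta`` -- 0 for inside paths,
    -pi/2 for outside paths.
    """

    mechanism: str = "inside"
    n_nodes: int = 11
    half_life: float = np.inf
    n_standard: int = 9
    attractor_theta: float | None = 0.0
    with_hg_attractor: bool = True
    with_steered_attractors: bool = True


@dataclass
class MultiPMDConfig:
    """Full engine configuration for one multiple-path run."""

    potential: AnalyticPotential
    paths: list
    wcf: tuple = (1.5, 0.0)
    hg: tuple = (-1.5, 0.0)
    embedding: str = "rolling"  # "rolling" (chi', theta) or "identity" (2D)
    total_time: float = 1400.0  # ps
    dt: float = 0.01
    kT: float = KT_300K
    friction: float = 1.0
    hill_width: float = 0.1
    hill_height: float = 0.05
    hill_pace: float = 1.0  # ps
    hill_start: float = 40.0  # ps; deposition begins after path establishment
    update_pace: float = 1.0  # ps
    tube_k: float = 50.0
    path_smoothing: float = 0.2  # neighbor-averaging fraction per path update
    path_move_cap: float = 0.5  # node move cap per update (node spacings)
    steer_k: float = 5000.0
    steer_window: float = 20.0  # ps
    theta_k: float = 5000.0
    hg_k: float = 50.0
    traj_stride: int = 10  # steps between trajectory records
    snapshot_pace: float = 10.0  # ps between stored path snapshots
    bounds_margin: float = 3.0
    sample_stride: int = 1  # steps between path-update samples

    @property
    def steps_per_ps(self) -> int:
        return int(round(1.0 / self.dt))  # 100 steps per ps at dt=0.01

    @property
    def n_steps(self) -> int:
        return int(round(self.total_time * self.steps_per_ps))


def rotor_flip_protocol(
    potential: AnalyticPotential | None = None,
    total_time: float = 1400.0,
    **overrides,
) -> MultiPMDConfig:
    """The reference two-path protocol on the rotor-flip landscape.

    One inside path (11 nodes, infinite half-life, attractors restrained at
    theta = 0) and one outside path (39 nodes, 20 ps half-life, attractors at
    theta = -pi/2), each with 9 standard walkers and 3 attractors.
    """
    from .potentials import RotorFlipPotential

    potential = potential or RotorFlipPotential()
    p = potential.params
    cfg = MultiPMDConfig(
        potential=potential,
        paths=[
            PathProtocol("inside", 11, np.inf, 9, 0.0),
            PathProtocol("outside", 39, 20.0, 9, -np.pi / 2),
        ],
        wcf=(p.chi_wcf, 0.0),
        hg=(p.chi_hg, 0.0),
        embedding="rolling",
        total_time=total_time,
    )
    return replace(cfg, **overrides) if overrides else cfg


def double_channel_protocol(
    potential: AnalyticPotential | None = None,
    total_time: float = 300.0,
    n_nodes: int = 33,
    **overrides,
) -> MultiPMDConfig:
    """Single cyclic path on the generic 2D double-channel landscape.

    Used for minimum-energy-path convergence checks against the
    zero-temperature string oracle, so the default temperature is cold
    (kT = 0.25, a quarter of the saddle height): the sampled density ridge
    then coincides with the MFEP to within the node resolution, while the
    metadynamics bias still drives full loops.
    """
    from .potentials import DoubleChannel2D

    potential = potential or DoubleChannel2D()
    cfg = MultiPMDConfig(
        potential=potential,
        paths=[
            PathProtocol(
                "loop", n_nodes, np.inf, 9,
                attractor_theta=None,
                with_hg_attractor=False,
                with_steered_attractors=False,
            )
        ],
        wcf=(-1.0, 0.0),
        hg=(1.0, 0.0),
        embedding="identity",
        total_time=total_time,
        kT=0.25,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# run artifacts


@dataclass
class PathRunResult:
    """Artifacts of one path: shared hills, adapted path, trajectories."""

    mechanism: str
    path: PathCurve
    hills: HillList
    snapshots: list  # (time, nodes) pairs
    traj_time: np.ndarray
    traj_pos: np.ndarray  # (n_records, n_walkers, ndim)
    traj_s: np.ndarray  # (n_records, n_walkers)
    traj_z: np.ndarray
    traj_bias: np.ndarray
    roles: list
    ensemble: WalkerEnsemble
    update_state: PathUpdateState

    def standard_indices(self):
        return [i for i, r in enumerate(self.roles) if r == "standard"]


@dataclass
class RunResult:
    config: MultiPMDConfig
    seed: int
    paths: list

    def __getitem__(self, mechanism: str) -> PathRunResult:
        for p in self.paths:
            if p.mechanism == mechanism:
                return p
        raise KeyError(mechanism)


# ---------------------------------------------------------------------------
# engine


def _initial_path(cfg: MultiPMDConfig, proto: PathProtocol) -> PathCurve:
    if cfg.embedding == "rolling":
        wcf_e = rolling_embed(np.asarray(cfg.wcf))[0]
        hg_e = rolling_embed(np.asarray(cfg.hg))[0]
        return init_cyclic_path(wcf_e, hg_e, proto.n_nodes, proto.mechanism)
    # identity embedding: circle with the wcf-hg segment as diameter
    wcf = np.asarray(cfg.wcf, dtype=float)
    hg = np.asarray(cfg.hg, dtype=float)
    center = 0.5 * (wcf + hg)
    radius = 0.5 * np.linalg.norm(hg - wcf)
    a0 = np.arctan2(wcf[1] - center[1], wcf[0] - center[0])
    ang = a0 + 2.0 * np.pi * np.linspace(0.0, 1.0, proto.n_nodes)
    nodes = np.column_stack([center[0] + radius * np.cos(ang),
                             center[1] + radius * np.sin(ang)])
    nodes[0] = wcf
    nodes[-1] = wcf
    return PathCurve(nodes, plane_space(), cyclic=True, mechanism=proto.mechanism)


def _build_walkers(cfg: MultiPMDConfig, proto: PathProtocol) -> WalkerEnsemble:
    walkers = []
    for i in range(proto.n_standard):
        walkers.append(Walker("standard", np.asarray(cfg.wcf, dtype=float), [], i))
    idx = proto.n_standard
    if proto.with_hg_attractor:
        r = RestraintSchedule("point", cfg.hg_k, np.asarray(cfg.hg, dtype=float))
        walkers.append(Walker("attractor", np.asarray(cfg.hg, dtype=float), [r], idx))
        idx += 1
    if proto.with_steered_attractors:
        for s_target, s_start in ((0.5, 1.0), (-0.5, -1.0)):
            rs = [
                RestraintSchedule(
                    "s", cfg.steer_k, s_target,
                    start=s_start, window=cfg.steer_window, periodic=2.0,
                )
            ]
            if proto.attractor_theta is not None:
                rs.append(RestraintSchedule("theta", cfg.theta_k, proto.attractor_theta))
            walkers.append(Walker("attractor", np.asarray(cfg.wcf, dtype=float), rs, idx))
            idx += 1
    return WalkerEnsemble(walkers)


def _run_one_path(cfg: MultiPMDConfig, proto: PathProtocol, seed_seq) -> PathRunResult:
    rng = np.random.default_rng(seed_seq)
    pot = cfg.potential
    embed = rolling_embed if cfg.embedding == "rolling" else (lambda x: np.atleast_2d(x))
    ndim = 2

    path = _initial_path(cfg, proto)
    state = PathUpdateState(path.n_nodes, path.nodes.shape[1],
                            half_life=proto.half_life, update_pace=cfg.update_pace,
                            smoothing=cfg.path_smoothing, move_cap=cfg.path_move_cap)
    ens = _build_walkers(cfg, proto)
    roles = [w.role for w in ens.walkers]
    nw = len(ens.walkers)
    pos = np.array([w.position for w in ens.walkers], dtype=float)
    std_idx = np.array([i for i, r in enumerate(roles) if r == "standard"], dtype=int)

    hills = HillList()
    grid = BiasGrid()
    lcfg = LangevinConfig(kT=cfg.kT, friction=cfg.friction, dt=cfg.dt)

    steps_per_ps = cfg.steps_per_ps
    hill_every = max(1, int(round(cfg.hill_pace * steps_per_ps)))
    update_every = max(1, int(round(cfg.update_pace * steps_per_ps)))
    snap_every = max(1, int(round(cfg.snapshot_pace * steps_per_ps)))
    n_steps = cfg.n_steps

    # embedding Jacobian d(emb)/d(chi, theta) applied to embedded gradients
    def pull_back(grad_emb, x):
        if cfg.embedding != "rolling":
            return grad_emb
        out = np.empty((grad_emb.shape[0], 2))
        out[:, 0] = (-np.sin(x[:, 0]) * grad_emb[:, 0]
                     + np.cos(x[:, 0]) * grad_emb[:, 1])
        out[:, 1] = grad_emb[:, 2]
        return out

    n_rec = n_steps // cfg.traj_stride + 1
    traj_time = np.empty(n_rec)
    traj_pos = np.empty((n_rec, nw, ndim))
    traj_s = np.empty((n_rec, nw))
    traj_z = np.empty((n_rec, nw))
    traj_bias = np.empty((n_rec, nw))
    rec = 0

    snapshots = [(0.0, path.nodes.copy())]
    sample_buf_pts: list[np.ndarray] = []
    sample_buf_t: list[float] = []

    # declared CV bounds for the runaway diagnostic (non-periodic axes)
    lo = np.full(ndim, -np.inf)
    hi = np.full(ndim, np.inf)
    for j in range(ndim):
        if j not in pot.periodic_axes:
            ref = [cfg.wcf[j], cfg.hg[j]]
            lo[j] = min(ref) - np.pi - cfg.bounds_margin
            hi[j] = max(ref) + np.pi + cfg.bounds_margin

    lam = smooth_lambda(path)

    for step in range(n_steps + 1):
        t = step * cfg.dt  # ps

        # --- smooth path CV of all walkers with exact gradients ----------
        emb = embed(pos)
        s, z2, gs_emb, gz2_emb = smooth_path_cv(emb, path, lam)
        z = np.sqrt(np.maximum(z2, 0.0))
        ds = pull_back(gs_emb, pos)  # (nw, 2)
        dz2 = pull_back(gz2_emb, pos)

        # --- forces ------------------------------------------------------
        bias_f = np.zeros((nw, ndim))
        e_bias = np.zeros(nw)
        # shared metadynamics bias: standard walkers only
        if len(std_idx) and len(hills):
            e_b, dEds = grid.evaluate(s[std_idx])
            e_bias[std_idx] = e_b
            bias_f[std_idx] -= dEds[:, None] * ds[std_idx]
        # tube on everyone: E = 1/2 k z^2 (upper wall at z = 0)
        wall = (z2 > 0.0).astype(float)
        bias_f -= (0.5 * cfg.tube_k * wall)[:, None] * dz2
        # restraints (attractors); stiff harmonic terms are applied with an
        # implicit-Euler damping factor 1/(1 + k |grad q|^2 dt/gamma) along
        # the restrained coordinate q, which keeps the overdamped integrator
        # stable for the large reference force constants (k = 5000)
        dt_g = cfg.dt / cfg.friction
        for i, w in enumerate(ens.walkers):
            for r in w.restraints:
                k_r = r.force_constant
                if r.target_cv == "s":
                    d = float(wrap_s(s[i] - r.center_at(t)))
                    g2 = float(ds[i] @ ds[i])
                    bias_f[i] -= (k_r * d / (1.0 + k_r * g2 * dt_g)) * ds[i]
                elif r.target_cv == "theta":
                    d = pos[i, 1] - r.center_at(t)
                    bias_f[i, 1] -= k_r * d / (1.0 + k_r * dt_g)
                elif r.target_cv == "point":
                    d = pos[i] - np.asarray(r.center_at(t), dtype=float)
                    for j in pot.periodic_axes:
                        d[j] = (d[j] + np.pi) % (2.0 * np.pi) - np.pi
                    bias_f[i] -= k_r * d / (1.0 + k_r * dt_g)

        # --- record ------------------------------------------------------
        if step % cfg.traj_stride == 0:
            traj_time[rec] = t
            traj_pos[rec] = pos
            traj_s[rec] = s
            traj_z[rec] = z
            traj_bias[rec] = e_bias
            rec += 1

        # --- hill deposition (synchronized, walker-index order) ----------
        if step > 0 and step % hill_every == 0 and t >= cfg.hill_start:
            for i in std_idx:
                hill = Hill(float(wrap_s(s[i])), cfg.hill_width, cfg.hill_height, t)
                hills.append(hill)
                grid.add_hill(hill)

        # --- path-update sampling & update -------------------------------
        if step % cfg.sample_stride == 0:
            sample_buf_pts.append(embed(pos).copy())
            sample_buf_t.append(t)
        if step > 0 and step % update_every == 0 and sample_buf_pts:
            pts = np.concatenate(sample_buf_pts, axis=0)
            times = np.repeat(sample_buf_t, nw)
            path = update_path(path, (pts, times), state)
            if cfg.embedding == "rolling":
                # sampled configurations live on the unit cylinder
                # cos^2 + sin^2 = 1; keep the path on that manifold
                nodes = path.nodes.copy()
                r = np.sqrt(nodes[:, 0] ** 2 + nodes[:, 1] ** 2)
                nodes[:, :2] /= np.where(r > 0.1, r, 1.0)[:, None]
                path = reparameterize(
                    PathCurve(nodes, path.space, path.cyclic, path.mechanism)
                )
            lam = smooth_lambda(path)
            sample_buf_pts.clear()
            sample_buf_t.clear()

        if step > 0 and step % snap_every == 0:
            snapshots.append((t, path.nodes.copy()))

        if step == n_steps:
            break

        # --- propagate ----------------------------------------------------
        pos = langevin_step(pos, pot, bias_f, lcfg, rng)
        if not np.all(np.isfinite(pos)):
            raise PropagationError("non-finite walker position")
        if np.any(pos < lo) or np.any(pos > hi):
            bad = int(np.argmax(np.any((pos < lo) | (pos > hi), axis=1)))
            raise PropagationError(
                f"walker {bad} left the declared CV bounds at t={t:.2f} ps: "
                f"position {pos[bad]}"
            )

    for i, w in enumerate(ens.walkers):
        w.position = pos[i]
    if snapshots[-1][0] < n_steps * cfg.dt:
        snapshots.append((n_steps * cfg.dt, path.nodes.copy()))

    return PathRunResult(
        mechanism=proto.mechanism,
        path=path,
        hills=hills,
        snapshots=snapshots,
        traj_time=traj_time[:rec],
        traj_pos=traj_pos[:rec],
        traj_s=traj_s[:rec],
        traj_z=traj_z[:rec],
        traj_bias=traj_bias[:rec],
        roles=roles,
        ensemble=ens,
        update_state=state,
    )


def restraint_force_s(r: RestraintSchedule, s: float, t: float):
    """Energy and dE/ds of an s-restraint with period-2 minimum image."""
    c = r.center_at(t)
    d = float(wrap_s(s - c))
    return 0.5 * r.force_constant * d * d, r.force_constant * d


def run_multipmd(cfg: MultiPMDConfig, seed: int = 0, out_dir=None) -> RunResult:
    """Run all paths of a configuration; optionally write artifacts.

    Every artifact is a pure function of (config, seed): each path draws from
    its own stream spawned deterministically from the root seed.

    Output files per path (plain text): ``HILLS.<mechanism>``,
    ``PATH.<mechanism>`` (final nodes) and ``COLVAR.<mechanism>`` with one
    block of columns per walker (time, coordinates, s, z, bias energy).
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(cfg.paths))
    results = []
    for proto, child in zip(cfg.paths, children):
        results.append(_run_one_path(cfg, proto, child))
    run = RunResult(cfg, seed, results)
    if out_dir is not None:
        write_run(run, out_dir)
    return run


def write_run(run: RunResult, out_dir) -> None:
    """Write HILLS / PATH / COLVAR tables for every path of a run."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for pr in run.paths:
        write_hills(pr.hills, os.path.join(out_dir, f"HILLS.{pr.mechanism}"))
        write_path(pr.path, os.path.join(out_dir, f"PATH.{pr.mechanism}"))
        cols = os.path.join(out_dir, f"COLVAR.{pr.mechanism}")
        nw = len(pr.roles)
        with open(cols, "w") as fh:
            names = []
            for i, role in enumerate(pr.roles):
                names += [f"w{i}.{c}" for c in ("x0", "x1", "s", "z", "bias")]
            fh.write("# time " + " ".join(names) + "\n")
            fh.write("# roles: " + " ".join(pr.roles) + "\n")
            for k in range(pr.traj_time.shape[0]):
                row = [f"{pr.traj_time[k]:.17g}"]
                for i in range(nw):
                    row += [
                        f"{pr.traj_pos[k, i, 0]:.17g}",
                        f"{pr.traj_pos[k, i, 1]:.17g}",
                        f"{pr.traj_s[k, i]:.17g}",
                        f"{pr.traj_z[k, i]:.17g}",
                        f"{pr.traj_bias[k, i]:.17g}",
                    ]
                fh.write(" ".join(row) + "\n")
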