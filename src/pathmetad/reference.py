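"""Independent reference calculations.

These routines share no code path with the sampling engine: free-energy
profiles by dense 2D grid quadrature, minimum (free-)energy paths by a
zero-temperature string method, and channel barriers by grid minimax search.
They serve as oracles that the metadynamics estimates and adapted paths are
validated against.
"""

from __future__ import annotations

import numpy as np

from .errors import AccuracyError
from .pathcv import PathCurve, _project_batch, reparameterize
from .potentials import AnalyticPotential, KT_300K

__all__ = [
    "rolling_embed",
    "reference_fes_quadrature",
    "string_mfep",
    "channel_barriers",
]


def rolling_embed(x: np.ndarray) -> np.ndarray:
    """Map (chi', theta) configurations to the embedded [cos, sin, theta] space."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return np.column_stack([np.cos(x[:, 0]), np.sin(x[:, 0]), x[:, 1]])


def _default_domain(potential: AnalyticPotential):
    if 0 in potential.periodic_axes:
        return ((-np.pi, np.pi), (-3.2, 2.2))
    return ((-2.0, 2.0), (-2.0, 2.0))


def reference_fes_quadrature(
    potential: AnalyticPotential,
    path: PathCurve,
    tube_k: float = 50.0,
    kT: float = KT_300K,
    domain=None,
    grid=(480, 480),
    s_bins: int = 200,
    embed=None,
    cv: str = "smooth",
    refine_check: bool = False,
    refine_tol_kT: float = 0.05,
):
    """Free-energy profile F(s) by dense 2D grid quadrature.

    F(s) = -kT ln sum over the slab of configurations projecting to each s
    bin of exp(-[V + 1/2 k z^2] / kT) dA, anchored so the WCF (edge) bins
    average to zero.  Returns (s_centers, F).

    ``cv`` selects the path coordinate: ``"smooth"`` (the differentiable
    soft-min path CV the engine biases -- the default, so quadrature profiles
    are directly comparable with metadynamics estimates) or ``"projection"``
    (piecewise-linear nearest-segment projection).

    With ``refine_check`` the quadrature is repeated on a 2x finer grid and an
    :class:`AccuracyError` is raised if the extracted barrier heights (the
    maxima of the anchored profile on each half of the cycle) change by more
    than ``refine_tol_kT`` kT.  Individual nearly-empty bins far up the
    barrier walls are not required to converge bin-by-bin.
    """
    from .pathcv import smooth_path_cv

    def compute(nx, ny):
        (x0, x1), (y0, y1) = domain
        xs = x0 + (x1 - x0) * (np.arange(nx) + 0.5) / nx
        ys = y0 + (y1 - y0) * (np.arange(ny) + 0.5) / ny
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        v = np.asarray(potential.energy(pts), dtype=float)
        emb = embed(pts)
        # chunk the path-CV evaluation to bound memory
        s = np.empty(pts.shape[0])
        z2 = np.empty(pts.shape[0])
        chunk = max(1, 4_000_000 // max(path.n_nodes, 1))
        for i in range(0, pts.shape[0], chunk):
            if cv == "smooth":
                si, z2i, _, _ = smooth_path_cv(emb[i : i + chunk], path)
                z2i = np.maximum(z2i, 0.0)
            else:
                si, zi, _, _ = _project_batch(emb[i : i + chunk], path.nodes)
                z2i = zi**2
            s[i : i + chunk] = si
            z2[i : i + chunk] = z2i
        w = np.exp(-(v + 0.5 * tube_k * z2) / kT)
        edges = np.linspace(-1.0, 1.0, s_bins + 1)
        idx = np.clip(np.digitize(s, edges) - 1, 0, s_bins - 1)
        mass = np.bincount(idx, weights=w, minlength=s_bins)
        dA = (x1 - x0) / nx * (y1 - y0) / ny
        with np.errstate(divide="ignore"):
            F = -kT * np.log(mass * dA)
        F = F - 0.5 * (F[0] + F[-1])
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, F

    if domain is None:
        domain = _default_domain(potential)
    if embed is None:
        embed = rolling_embed if path.nodes.shape[1] == 3 else (lambda p: np.atleast_2d(p))

    centers, F = compute(*grid)
    if refine_check:
        _, F2 = compute(2 * grid[0], 2 * grid[1])

        def barriers(prof):
            out = []
            for mask in (centers < 0, centers > 0):
                vals = prof[mask & np.isfinite(prof)]
                out.append(vals.max() if vals.size else np.nan)
            return np.asarray(out)

        delta = np.abs(barriers(F) - barriers(F2))
        if np.any(~np.isfinite(delta)) or np.max(delta) > refine_tol_kT * kT:
            raise AccuracyError(
                "quadrature grid too coarse: barrier estimates change by more "
                f"than {refine_tol_kT} kT on 2x refinement"
            )
        F = F2
    return centers, F


def string_mfep(
    potential: AnalyticPotential,
    init_path: PathCurve,
    step: float = 5e-3,
    max_iter: int = 20000,
    tol: float = 1e-10,
) -> PathCurve:
    """Zero-temperature string method: steepest descent + reparameterization.

    Interior nodes follow -grad V; endpoints stay fixed; nodes are
    redistributed to equal arc length each iteration.  Converges to the
    minimum-energy path homotopic to the initial guess.
    """
    path = init_path.copy()
    for _ in range(max_iter):
        g = np.atleast_2d(potential.gradient(path.nodes))
        new = path.nodes - step * g
        new[0] = init_path.nodes[0]
        new[-1] = init_path.nodes[-1]
        moved = PathCurve(new, path.space, path.cyclic, path.mechanism)
        moved = reparameterize(moved)
        delta = np.max(np.linalg.norm(moved.nodes - path.nodes, axis=1))
        path = moved
        if delta < tol:
            break
    return path


def channel_barriers(
    potential: AnalyticPotential,
    chi_wcf: float = 1.5,
    chi_hg: float = -1.5,
    theta_inside=(-0.6, 0.4),
    theta_outside=(-2.4, -0.8),
    n_chi: int = 600,
    n_theta: int = 400,
):
    """Barriers of the four rolling channels by grid minimax search.

    For each channel (inside/outside gate window in theta, crossed with the
    3'/5' half of the rolling circle) the channel floor is min over theta of
    V at each chi' column, and the barrier is the max of that floor over the
    half, referenced to the WCF minimum.  Returns a dict keyed by
    ("inside"|"outside", "3p"|"5p") with barrier heights and saddle chi'.
    """
    margin = 0.15  # exclude the immediate vicinity of the stable states
    halves = {
        "3p": np.linspace(chi_hg + margin, chi_wcf - margin, n_chi),
        "5p": np.linspace(chi_wcf + margin, chi_hg + 2 * np.pi - margin, n_chi),
    }
    windows = {"inside": theta_inside, "outside": theta_outside}
    v_ref = float(np.min(potential.energy(
        np.column_stack([np.full(200, chi_wcf),
                         np.linspace(-0.5, 0.5, 200)]))))
    out = {}
    for wname, (t0, t1) in windows.items():
        thetas = np.linspace(t0, t1, n_theta)
        for hname, chis in halves.items():
            cc, tt = np.meshgrid(chis, thetas, indexing="ij")
            pts = np.column_stack([cc.ravel(), tt.ravel()])
            v = np.asarray(potential.energy(pts)).reshape(n_chi, n_theta)
            floor = v.min(axis=1)
            k = int(np.argmax(floor))
            out[(wname, hname)] = {
                "barrier": float(floor[k] - v_ref),
                "chi_saddle": float(chis[k]),
                "theta_saddle": float(thetas[int(np.argmin(v[k]))]),
            }
    return out
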