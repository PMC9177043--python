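"""Cyclic adaptive path collective variables.

A path is an ordered string of nodes in an embedded, purely linear CV space.
For the base-rolling problem the space is [cos(chi'), sin(chi'), theta] and
the path is *cyclic*: it starts and ends at the Watson-Crick-Franklin (WCF)
anchor point, describing a full revolution of the rolling base through the
Hoogsteen (HG) state and back.

The progress coordinate ``s`` along a cyclic path grows from -1 to +1 and is
periodic on that range, so the WCF anchor sits at s = +/-1 and the HG state
near s = 0.  By the sign convention used throughout, -1 < s < 0 is the
rotation with the purine 6-ring pointing in the 5' direction of the chain and
0 < s < +1 the rotation in the 3' direction.  ``z`` is the perpendicular
(Euclidean) distance from a configuration to the path.

Two coordinate definitions are provided.  The piecewise-linear
nearest-segment projection (``project_point``) is geometrically exact and
testable against a dense-resampling oracle, with gradients by central finite
differences (``projection_gradients``, step 1e-5 per axis) or in closed form
(``project_points_with_grad``); it serves analysis.  The differentiable
soft-min path CV (``smooth_path_cv``) is C1 everywhere, including around
path corners where the projection is not, and is what the sampling engine
biases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cvspace import CVSpace, DimensionalError, rolling_space
from .errors import ParameterError, StateError

__all__ = [
    "PathCurve",
    "Projection",
    "PathUpdateState",
    "init_cyclic_path",
    "project_point",
    "project_points",
    "project_points_with_grad",
    "projection_gradients",
    "smooth_path_cv",
    "smooth_lambda",
    "update_path",
    "reparameterize",
    "write_path",
    "read_path",
]


@dataclass(frozen=True)
class Projection:
    """Projection of a CV point onto a path: progress ``s`` and distance ``z``."""

    s: float
    z: float


@dataclass
class PathCurve:
    """An ordered string of nodes in an embedded CV space.

    Attributes
    ----------
    nodes : (n, d) ndarray
        Node coordinates.  For a cyclic path the first and last node coincide
        at the fixed anchor (the WCF state).
    space : CVSpace
        The embedded space the nodes live in.
    cyclic : bool
        Whether ``s`` is periodic on [-1, +1].
    """

    nodes: np.ndarray
    space: CVSpace
    cyclic: bool = True
    mechanism: str | None = None

    def __post_init__(self) -> None:
        self.nodes = np.array(self.nodes, dtype=float)
        if self.nodes.ndim != 2:
            raise ParameterError("nodes must be a 2D (n, d) array")
        if self.nodes.shape[0] < 3:
            raise ParameterError("a path needs at least 3 nodes")
        self.space.check_point(self.nodes[0])

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def fixed_endpoint(self) -> np.ndarray:
        return self.nodes[0].copy()

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)

    def total_length(self) -> float:
        return float(self.segment_lengths().sum())

    def copy(self) -> "PathCurve":
        return PathCurve(self.nodes.copy(), self.space, self.cyclic, self.mechanism)


def init_cyclic_path(
    wcf_point,
    hg_point,
    n_nodes: int,
    mechanism: str = "inside",
    space: CVSpace | None = None,
) -> PathCurve:
    """Initial guess for a cyclic rolling path.

    The curve describes a full revolution of the rolling angle chi' from the
    WCF anchor through the HG state and back, traced along the chi' circle at
    the WCF opening angle theta (i.e. with no base flipping), and embedded as
    [cos(chi'), sin(chi'), theta].  Node 0 and node n-1 coincide at the WCF
    anchor; nodes are equidistant.

    The revolution runs in the direction of increasing chi', which places the
    5' intermediate (chi' near +/-pi) in the first half (s < 0) and the 3'
    intermediate (chi' near 0) in the second half (s > 0), matching the sign
    convention of the progress coordinate.
    """
    space = space or rolling_space()
    wcf_point = np.asarray(wcf_point, dtype=float)
    hg_point = np.asarray(hg_point, dtype=float)
    space.check_point(wcf_point)
    if hg_point.shape != wcf_point.shape:
        raise DimensionalError("WCF and HG points have different dimensionality")
    if n_nodes < 3:
        raise ParameterError("n_nodes must be >= 3")

    chi_wcf = float(np.arctan2(wcf_point[1], wcf_point[0]))
    theta_wcf = float(wcf_point[2])
    u = np.linspace(0.0, 1.0, n_nodes)
    chi = chi_wcf + 2.0 * np.pi * u
    nodes = np.column_stack([np.cos(chi), np.sin(chi), np.full(n_nodes, theta_wcf)])
    # exact closure at the anchor (cos/sin of chi_wcf +/- 2 pi differ in the lsb)
    nodes[0] = wcf_point
    nodes[-1] = wcf_point
    return PathCurve(nodes, space, cyclic=True, mechanism=mechanism)


def _project_batch(points: np.ndarray, nodes: np.ndarray):
    """Nearest-segment projection of many points onto a polyline.

    Returns (s, z, seg_index, t) where s is arc-length progress in [-1, 1].
    Ties between equidistant segments resolve to the lower segment index.
    """
    a = nodes[:-1]  # (m, d)
    d = nodes[1:] - nodes[:-1]  # (m, d)
    seg_len2 = np.einsum("md,md->m", d, d)
    seg_len2 = np.where(seg_len2 > 0, seg_len2, 1.0)
    diff = points[:, None, :] - a[None, :, :]  # (p, m, d)
    t = np.einsum("pmd,md->pm", diff, d) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist2 = np.einsum("pmd,pmd->pm", points[:, None, :] - proj, points[:, None, :] - proj)
    k = np.argmin(dist2, axis=1)
    rows = np.arange(points.shape[0])
    z = np.sqrt(dist2[rows, k])
    seg_len = np.sqrt(np.einsum("md,md->m", nodes[1:] - nodes[:-1], nodes[1:] - nodes[:-1]))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total <= 0:
        raise StateError("degenerate path: zero total length")
    arc = cum[k] + t[rows, k] * seg_len[k]
    s = -1.0 + 2.0 * arc / total
    return s, z, k, t[rows, k]


def project_points(points, path: PathCurve):
    """Vectorized projection; returns (s, z) arrays."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    path.space.check_point(points[0])
    if path.n_nodes == 0:
        raise StateError("empty path")
    s, z, _, _ = _project_batch(points, path.nodes)
    return s, z


def project_point(p, path: PathCurve) -> Projection:
    """Project one CV point onto the path."""
    s, z = project_points(np.asarray(p, dtype=float)[None, :], path)
    return Projection(float(s[0]), float(z[0]))


def project_points_with_grad(points, path: PathCurve):
    """Projection plus exact gradients of (s, z) in the embedded space.

    For the piecewise-linear projection the gradients are closed-form: within
    a segment, grad s = (2 / L_total) t_hat along the segment tangent and
    grad z points from the projection to the point; in the wedge regions
    beyond a segment end (projection clipped to a node), s is locally
    constant so grad s = 0.  These one-sided expressions are well defined
    arbitrarily close to the medial-axis discontinuities of the projection,
    where finite differences across the jump are not.

    Returns (s, z, grad_s, grad_z) with gradient arrays shaped like points.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    nodes = path.nodes
    s, z, k, t = _project_batch(points, nodes)
    d = nodes[1:] - nodes[:-1]
    seg_len = np.linalg.norm(d, axis=1)
    total = seg_len.sum()
    t_hat = d / np.where(seg_len > 0, seg_len, 1.0)[:, None]
    proj = nodes[k] + t[:, None] * d[k]
    interior = (t > 0.0) & (t < 1.0)
    grad_s = np.where(interior[:, None], (2.0 / total) * t_hat[k], 0.0)
    dvec = points - proj
    with np.errstate(invalid="ignore", divide="ignore"):
        grad_z = np.where(z[:, None] > 0, dvec / z[:, None], 0.0)
    return s, z, grad_s, grad_z


def smooth_lambda(path: PathCurve, factor: float = 1.0) -> float:
    """Default soft-min sharpness for the smooth path CV: lambda such that
    lambda * (mean node spacing)^2 = ``factor``.

    A unit product keeps s smooth across node-scale path corners (sharper
    choices starve the corner-apex bins of sampling); softer choices blur
    genuine barrier structure."""
    seg = path.segment_lengths()
    return float(factor / np.mean(seg) ** 2)


def smooth_path_cv(points, path: PathCurve, lam: float | None = None):
    """Differentiable cyclic path CV: progress s, squared distance z^2, and
    their exact gradients.

    Node i (the duplicate cyclic endpoint excluded) is assigned the phase
    phi_i = pi + 2 pi arc_i / L, so the anchor sits at s = +/-1 and the
    midpoint of the cycle at s ~ 0.  With soft-min weights
    w_i = exp(-lambda d_i^2),

        s   = atan2(sum w sin phi, sum w cos phi) / pi
        z^2 = softmin_i d_i^2 = -ln(sum w) / lambda ,

    both C^1 everywhere -- unlike the piecewise-linear projection, whose
    clipped corner wedges have exactly zero s-gradient and therefore cannot
    transmit a bias force around path corners.  grad z^2 reduces to
    2 (x - nbar) with nbar the weighted node mean.

    Returns (s, z2, grad_s, grad_z2); gradients have the shape of points.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    nodes = path.nodes[:-1] if path.cyclic else path.nodes
    seg = path.segment_lengths()
    arc = np.concatenate([[0.0], np.cumsum(seg)])[: nodes.shape[0]]
    total = float(seg.sum())
    if total <= 0:
        raise StateError("degenerate path: zero total length")
    if lam is None:
        lam = smooth_lambda(path)
    phi = np.pi + 2.0 * np.pi * arc / total

    diff = points[:, None, :] - nodes[None, :, :]  # (p, m, d)
    d2 = np.einsum("pmd,pmd->pm", diff, diff)
    d2min = d2.min(axis=1, keepdims=True)
    w = np.exp(-lam * (d2 - d2min))  # stabilized; common factor cancels in s
    wsum = w.sum(axis=1)
    C = w @ np.cos(phi)
    S = w @ np.sin(phi)
    s = np.arctan2(S, C) / np.pi

    # z^2 = d2min - ln(sum w)/lambda; grad z^2 = 2 (x - weighted node mean)
    z2 = (d2min[:, 0] - np.log(wsum) / lam)
    nbar = (w[:, :, None] * nodes[None, :, :]).sum(axis=1) / wsum[:, None]
    grad_z2 = 2.0 * (points - nbar)

    # grad s: common factors of w cancel in the atan2 quotient
    dw = -2.0 * lam * w[:, :, None] * diff  # (p, m, d)
    dS = np.einsum("m,pmd->pd", np.sin(phi), dw)
    dC = np.einsum("m,pmd->pd", np.cos(phi), dw)
    denom = np.pi * (S**2 + C**2)
    grad_s = (C[:, None] * dS - S[:, None] * dC) / denom[:, None]
    return s, z2, grad_s, grad_z2


def projection_gradients(p, path: PathCurve, step: float = 1e-5):
    """Central finite-difference gradients of (s, z) wrt the embedded axes.

    The difference in s is taken with period-2 minimum-image wrapping for
    cyclic paths so the gradient is continuous across s = +/-1.
    """
    p = np.asarray(p, dtype=float)
    d = p.shape[0]
    pts = np.repeat(p[None, :], 2 * d, axis=0)
    for j in range(d):
        pts[2 * j, j] += step
        pts[2 * j + 1, j] -= step
    s, z = project_points(pts, path)
    ds = s[0::2] - s[1::2]
    if path.cyclic:
        ds = (ds + 1.0) % 2.0 - 1.0
    grad_s = ds / (2.0 * step)
    grad_z = (z[0::2] - z[1::2]) / (2.0 * step)
    return grad_s, grad_z


def reparameterize(path: PathCurve, rtol: float = 1e-6, max_iter: int = 200) -> PathCurve:
    """Redistribute nodes to equal arc length along the current polyline.

    Node count and endpoints are preserved.  New node positions always lie on
    the ORIGINAL polyline: the iteration adjusts arc-length positions along
    it until the consecutive chord lengths of the new node set are equal
    within ``rtol`` of their mean, so repeated reparameterization never
    erodes the curve geometry.
    """
    nodes = path.nodes
    n = nodes.shape[0]
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise StateError("degenerate path: all nodes identical")
    cum = np.concatenate([[0.0], np.cumsum(seg)])

    def place(arcs):
        idx = np.clip(np.searchsorted(cum, arcs, side="right") - 1, 0, n - 2)
        t = (arcs - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
        out = nodes[idx] + t[:, None] * (nodes[idx + 1] - nodes[idx])
        out[0] = nodes[0]
        out[-1] = nodes[-1]
        return out

    arcs = np.linspace(0.0, total, n)
    new = place(arcs)
    for _ in range(max_iter):
        chords = np.linalg.norm(np.diff(new, axis=0), axis=1)
        mean = chords.mean()
        if mean <= 0 or np.max(np.abs(chords - mean)) <= rtol * mean:
            break
        # remap arc positions through the chord-length parameterization
        ccum = np.concatenate([[0.0], np.cumsum(chords)])
        arcs = np.interp(np.linspace(0.0, ccum[-1], n), ccum, arcs)
        new = place(arcs)
    return PathCurve(new, path.space, path.cyclic, path.mechanism)


@dataclass
class PathUpdateState:
    """Fading-memory accumulators driving adaptive path updates.

    Each node keeps the weighted sum of the positions of the samples assigned
    to it (nearest node in the embedded space, ties toward the lower index)
    and the corresponding weight sum; the node's drive is the perpendicular
    component of the displacement from the node to that weighted mean, i.e.
    the fading-memory weighted mean perpendicular displacement of its
    samples.  A sample's weight halves every ``half_life`` of simulation
    time; with an infinite half-life weights never decay, so the accumulated
    mean -- and with it the path -- becomes progressively more rigid as
    sampling accumulates.
    """

    n_nodes: int
    ndim: int
    half_life: float = np.inf
    update_pace: float = 1.0
    smoothing: float = 0.0  # neighbor-averaging fraction per update (anti-kink)
    move_cap: float = 0.5  # max node move per update, in units of node spacing
    pos_sum: np.ndarray = field(init=False)
    weight_sum: np.ndarray = field(init=False)
    last_time: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not (self.half_life > 0):
            raise ParameterError("half_life must be positive (may be inf)")
        self.pos_sum = np.zeros((self.n_nodes, self.ndim))
        self.weight_sum = np.zeros(self.n_nodes)

    def decay_factor(self, dt: float) -> float:
        if np.isinf(self.half_life):
            return 1.0
        return float(2.0 ** (-dt / self.half_life))

    def sample_weight(self, age: float) -> float:
        """Weight of a sample of the given age (in simulation time)."""
        if np.isinf(self.half_life):
            return 1.0
        return float(2.0 ** (-age / self.half_life))


def update_path(path: PathCurve, samples, state: PathUpdateState) -> PathCurve:
    """Move interior nodes toward the fading-memory mean perpendicular
    displacement of the samples assigned to them.

    ``samples`` is a pair (points, times) or a sequence of (point, time).
    Endpoint nodes never move.  Per-update node displacement is capped at half
    the mean node spacing to prevent oscillation.  The returned path is
    reparameterized.  With no samples the path is returned unchanged.
    """
    if isinstance(samples, tuple) and len(samples) == 2:
        pts, times = samples
    else:
        seq = list(samples)
        if not seq:
            return path
        pts = np.array([p for p, _ in seq], dtype=float)
        times = np.array([t for _, t in seq], dtype=float)
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if pts.shape[0] == 0:
        return path

    t_now = float(times.max())
    fade = state.decay_factor(max(t_now - state.last_time, 0.0))
    state.pos_sum *= fade
    state.weight_sum *= fade
    state.last_time = t_now

    nodes = path.nodes
    n = path.n_nodes
    # nearest-node assignment (argmin resolves ties toward the lower index)
    d2 = np.einsum("pnd,pnd->pn", pts[:, None, :] - nodes[None, :, :],
                   pts[:, None, :] - nodes[None, :, :])
    assign = np.argmin(d2, axis=1)
    if np.isinf(state.half_life):
        w = np.ones_like(times)
    else:
        w = 2.0 ** (-(t_now - times) / state.half_life)

    np.add.at(state.pos_sum, assign, pts * w[:, None])
    np.add.at(state.weight_sum, assign, w)

    # unit tangents at nodes (central differences in node index)
    tang = np.empty_like(nodes)
    tang[1:-1] = nodes[2:] - nodes[:-2]
    tang[0] = nodes[1] - nodes[0]
    tang[-1] = nodes[-1] - nodes[-2]
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    tang = tang / np.where(norm > 0, norm, 1.0)

    new_nodes = nodes.copy()
    cap = state.move_cap * path.total_length() / (n - 1)
    interior = np.arange(1, n - 1)
    active = interior[state.weight_sum[interior] > 0]
    if active.size:
        mean_pos = state.pos_sum[active] / state.weight_sum[active][:, None]
        move = mean_pos - nodes[active]
        move -= np.einsum("pd,pd->p", move, tang[active])[:, None] * tang[active]
        mag = np.linalg.norm(move, axis=1)
        scale = np.where(mag > cap, cap / np.where(mag > 0, mag, 1.0), 1.0)
        new_nodes[active] = nodes[active] + move * scale[:, None]
    if state.smoothing > 0:
        # damp node-scale kinks: pull each interior node a fraction toward
        # the midpoint of its neighbors (string-method stabilization)
        mid = 0.5 * (new_nodes[:-2] + new_nodes[2:])
        new_nodes[1:-1] += state.smoothing * (mid - new_nodes[1:-1])
    out = PathCurve(new_nodes, path.space, path.cyclic, path.mechanism)
    return reparameterize(out)


# ---------------------------------------------------------------------------
# plain-text path files


def write_path(path: PathCurve, filename) -> None:
    """Write a path as a plain-text table, one node per line.

    The header names the CV axes and records the cyclic flag; values are
    written with 17 significant digits so a read/write round trip is bit-exact
    on the decimal representation.
    """
    with open(filename, "w") as fh:
        fh.write(f"# axes: {' '.join(path.space.names)}\n")
        fh.write(f"# cyclic: {int(path.cyclic)}\n")
        if path.mechanism:
            fh.write(f"# mechanism: {path.mechanism}\n")
        for row in path.nodes:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_path(filename, space: CVSpace | None = None) -> PathCurve:
    """Read a path written by :func:`write_path`."""
    cyclic = True
    mechanism = None
    names = None
    rows = []
    with open(filename) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("axes:"):
                    names = body.split(":", 1)[1].split()
                elif body.startswith("cyclic:"):
                    cyclic = bool(int(body.split(":", 1)[1]))
                elif body.startswith("mechanism:"):
                    mechanism = body.split(":", 1)[1].strip()
                continue
            rows.append([float(v) for v in line.split()])
    nodes = np.array(rows, dtype=float)
    if space is None:
        if names is not None and list(names) == list(rolling_space().names):
            space = rolling_space()
        else:
            from .cvspace import Axis

            space = CVSpace(tuple(Axis(n or f"cv{i}") for i, n in
                                  enumerate(names or [f"cv{i}" for i in range(nodes.shape[1])])))
    return PathCurve(nodes, space, cyclic, mechanism)
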