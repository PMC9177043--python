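"""Free-energy profiles from metadynamics hill lists.

The running free-energy estimate of plain metadynamics is the negative of the
sum of the deposited Gaussians.  Profiles are taken as snapshots at regular
intervals, each independently shifted so its minimum is zero (metadynamics
determines F only up to an additive constant, and the overall fill level
grows without bound for non-tempered hills), then averaged per bin; the
per-bin standard deviation over snapshots is the error bar.  The averaged
profile is anchored to F = 0 at the WCF bin (s = +/-1).

Direction convention on the cyclic progress axis: -1 < s < 0 is the rotation
with the purine 6-ring in the 5' direction, 0 < s < +1 the 3' direction; the
HG state sits near s = 0 (its exact position is located, not assumed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bias import HillList, bias_energy_force
from .errors import ParameterError, StatisticsError

__all__ = [
    "FreeEnergyProfile",
    "BarrierSummary",
    "profile_from_hills",
    "averaged_profile",
    "extract_barriers",
    "diffusion_check",
    "linear_trend_fit",
    "write_profile",
    "read_profile",
]

DEFAULT_BINS = 200


def s_grid(n_bins: int = DEFAULT_BINS) -> np.ndarray:
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class FreeEnergyProfile:
    """F(s) on a grid with per-bin mean and std over time snapshots."""

    s: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    snapshot_times: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.std < 0):
            raise ParameterError("std must be >= 0")


@dataclass
class BarrierSummary:
    """Direction-resolved barriers and the WCF-to-HG free-energy difference.

    barrier_5p is the maximum of F on -1 < s < 0 relative to F(WCF); likewise
    barrier_3p on 0 < s < 1.  delta_f is F at the HG minimum (the lowest F in
    |s| < 0.5) minus F(WCF); NaN with a topology warning when no interior
    minimum exists.
    """

    barrier_5p: float
    barrier_3p: float
    delta_f: float
    ts_5p: float
    ts_3p: float
    s_hg: float


def profile_from_hills(hills: HillList, t: float, n_bins: int = DEFAULT_BINS):
    """One snapshot F(s) = -sum of hills deposited up to time t.

    Shifted so min F = 0.  Returns (s, F); with no hills the profile is zero.
    """
    s = s_grid(n_bins)
    if len(hills) == 0:
        return s, np.zeros_like(s)
    e, _ = bias_energy_force(s, hills, t_max=t)
    e = np.atleast_1d(e)
    F = -e
    return s, F - F.min()


def averaged_profile(
    hills: HillList,
    t_start: float,
    t_end: float,
    interval: float,
    n_bins: int = DEFAULT_BINS,
) -> FreeEnergyProfile:
    """Mean and std of min-shifted snapshots taken every ``interval``.

    Snapshots are taken at t_start, t_start + interval, ..., t_end
    (inclusive).  Each snapshot is min-shifted before averaging so the spread
    reflects profile shape, not fill level; the averaged profile is then
    anchored to zero at the WCF (edge) bins.
    """
    if not t_start < t_end:
        raise ParameterError("t_start must be < t_end")
    if not interval > 0:
        raise ParameterError("interval must be > 0")
    times = np.arange(t_start, t_end + 1e-9 * interval, interval)
    if times.size < 2:
        raise StatisticsError("fewer than 2 snapshots in the analysis window")
    s = s_grid(n_bins)
    snaps = np.empty((times.size, n_bins))
    for k, t in enumerate(times):
        _, snaps[k] = profile_from_hills(hills, t, n_bins)
    mean = snaps.mean(axis=0)
    std = snaps.std(axis=0)
    mean = mean - 0.5 * (mean[0] + mean[-1])
    return FreeEnergyProfile(s, mean, std, times)


def _anchored(profile: FreeEnergyProfile) -> np.ndarray:
    f = profile.mean
    return f - 0.5 * (f[0] + f[-1])


def extract_barriers(profile: FreeEnergyProfile, hg_window: float = 0.5) -> BarrierSummary:
    """Direction-resolved barriers and Delta F from an anchored profile.

    The HG minimum is searched in |s| < ``hg_window`` (its exact progress
    value cannot be known a priori); if the lowest interior point is not a
    genuine local minimum a topology warning is emitted and Delta F is NaN.
    """
    s, F = profile.s, _anchored(profile)
    m5 = (s > -1.0) & (s < 0.0)
    m3 = (s > 0.0) & (s < 1.0)
    i5 = np.flatnonzero(m5)[np.argmax(F[m5])]
    i3 = np.flatnonzero(m3)[np.argmax(F[m3])]
    mh = np.abs(s) < hg_window
    ih = np.flatnonzero(mh)[np.argmin(F[mh])]
    interior = 0 < ih < len(s) - 1
    is_min = interior and F[ih] <= F[ih - 1] and F[ih] <= F[ih + 1] and (
        F[ih] < max(F[i5], F[i3])
    )
    if not is_min:
        warnings.warn("no interior HG minimum found; Delta F undefined",
                      category=UserWarning, stacklevel=2)
        delta_f = np.nan
        s_hg = np.nan
    else:
        delta_f = float(F[ih])
        s_hg = float(s[ih])
    return BarrierSummary(
        barrier_5p=float(F[i5]),
        barrier_3p=float(F[i3]),
        delta_f=delta_f,
        ts_5p=float(s[i5]),
        ts_3p=float(s[i3]),
        s_hg=s_hg,
    )


def diffusion_check(
    times: np.ndarray,
    s_traj: np.ndarray,
    window: float,
    wcf_tol: float = 0.2,
    hg_tol: float = 0.2,
):
    """Earliest onset of the free-diffusion regime along s.

    ``s_traj`` is (n_records, n_walkers) (or 1D for a single walker).  A full
    end-to-end traversal is a walker excursion from the WCF region
    (|s| > 1 - wcf_tol) through the HG region (|s| < hg_tol) and back.  The
    flag is True at the earliest time after which every subsequent window of
    length ``window`` contains at least one completed traversal by the
    ensemble; returns (flag, onset) with onset None if never reached.
    """
    times = np.asarray(times, dtype=float)
    s_traj = np.asarray(s_traj, dtype=float)
    if s_traj.ndim == 1:
        s_traj = s_traj[:, None]
    events = []
    for w in range(s_traj.shape[1]):
        s = s_traj[:, w]
        stage = 0  # 0: seek WCF, 1: seek HG, 2: seek WCF again
        for k in range(s.size):
            in_wcf = abs(s[k]) > 1.0 - wcf_tol
            in_hg = abs(s[k]) < hg_tol
            if stage == 0 and in_wcf:
                stage = 1
            elif stage == 1 and in_hg:
                stage = 2
            elif stage == 2 and in_wcf:
                events.append(times[k])
                stage = 1
    if not events:
        return False, None
    events = np.sort(np.asarray(events))
    t_end = times[-1]
    # candidate onsets: scan from each event; onset must leave >= 1 window
    for t0 in events:
        if t0 > t_end - window:
            break
        edges = np.arange(t0, t_end + 1e-12, window)
        if edges[-1] < t_end:
            pass  # trailing partial window is not required
        counts = np.histogram(events, bins=edges)[0] if edges.size > 1 else []
        if len(counts) and np.all(counts >= 1):
            return True, float(t0)
    return False, None


def linear_trend_fit(descriptor, barriers):
    """Ordinary least squares of barrier against a structural descriptor.

    Returns (slope, intercept, residuals).  Raises for n < 2 or a descriptor
    with zero variance (degenerate design).
    """
    x = np.asarray(descriptor, dtype=float)
    y = np.asarray(barriers, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("descriptor and barriers must be equal-length 1D")
    if x.size < 2:
        raise ParameterError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ParameterError("zero descriptor variance: fit is degenerate")
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    residuals = y - (slope * x + intercept)
    return slope, intercept, residuals


# ---------------------------------------------------------------------------
# plain-text FES files


def write_profile(profile: FreeEnergyProfile, filename) -> None:
    with open(filename, "w") as fh:
        fh.write("# s F_mean F_std\n")
        for s, m, sd in zip(profile.s, profile.mean, profile.std):
            fh.write(f"{s:.17g} {m:.17g} {sd:.17g}\n")


def read_profile(filename) -> FreeEnergyProfile:
    data = np.loadtxt(filename)
    return FreeEnergyProfile(data[:, 0], data[:, 1], data[:, 2], np.array([]))


def write_summary(summary: BarrierSummary, filename) -> None:
    with open(filename, "w") as fh:
        fh.write("# quantity value\n")
        fh.write(f"barrier_5p {summary.barrier_5p:.6f}\n")
        fh.write(f"barrier_3p {summary.barrier_3p:.6f}\n")
        fh.write(f"delta_f {summary.delta_f:.6f}\n")
        fh.write(f"ts_5p {summary.ts_5p:.6f}\n")
        fh.write(f"ts_3p {summary.ts_3p:.6f}\n")
        fh.write(f"s_hg {summary.s_hg:.6f}\n")
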