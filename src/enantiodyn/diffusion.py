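"""Mean-square displacement and Einstein-relation diffusion estimation.

The estimator chain mirrors standard practice for translational diffusion from
MD trajectories: unwrap periodic coordinates, compute the molecule
centre-of-mass MSD over all time origins, average the per-replicate curves,
and fit the linear regime by ordinary least squares; in three dimensions
MSD(t) = 6 D t, so D = slope / 6.

Units: MSD curves carry lag times in ns and MSD in nm^2; diffusion
coefficients are reported in 1e-10 m^2/s (slope in nm^2/ns corresponds to
10 x 1e-10 m^2/s).

Statistical error: when per-replicate curves are available, the quoted error
of the averaged estimate is the standard error of the mean (SEM) of the
per-replicate D values; otherwise the OLS slope standard error is propagated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from enantiodyn.core_io import NM2_PER_NS_TO_1E10_M2_S, SpeciesMap, Trajectory

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "unwrap",
    "msd",
    "average_msd",
    "fit_einstein",
    "convergence_report",
]


@dataclass
class MSDCurve:
    """Ensemble- and origin-averaged mean-square displacement.

    ``lag_times`` in ns, ``msd`` in nm^2, ``n_origins`` the number of
    (molecule, time-origin) pairs entering each lag, ``duration_ns`` the time
    span of the underlying trajectory (used for default fit windows).
    """

    lag_times: np.ndarray
    msd: np.ndarray
    n_origins: np.ndarray
    species_selector: str = ""
    duration_ns: float = 0.0

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_origins = np.asarray(self.n_origins, dtype=int)
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag_times must be increasing")
        if abs(self.msd[0]) > 1e-12 or np.any(self.msd < -1e-12):
            raise ValueError("msd must start at 0 and be non-negative")


@dataclass
class DiffusionEstimate:
    """Einstein-relation fit result. D and stderr in 1e-10 m^2/s."""

    D: float
    stderr: float
    r_squared: float
    fit_window: tuple
    per_replicate_D: np.ndarray | None = None
    stderr_kind: str = "slope"  # "sem_replicates" when per-replicate Ds exist

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


def unwrap(traj: Trajectory, max_step_fraction: float = 0.5) -> Trajectory:
    """Remove periodic wrapping by minimum-image continuity.

    Assumes no particle moves more than half a box edge between saved frames
    (the minimum-image criterion); an apparent min-imaged step at or beyond
    ``max_step_fraction * box`` raises, citing frame and particle, as the
    sampling is then too sparse to unwrap reliably.  Already-unwrapped input
    is returned unchanged (identity).
    """
    if not traj.wrapped:
        return traj
    box = traj.box[None, None, :]
    diffs = np.diff(traj.frames, axis=0)
    diffs -= box * np.round(diffs / box)
    limit = max_step_fraction * traj.box * (1 - 1e-9)
    too_big = np.abs(diffs) >= limit[None, None, :]
    if too_big.any():
        f, p, _ = np.argwhere(too_big)[0]
        raise ValueError(
            f"unwrap: jump of >= {max_step_fraction} box edges between frames "
            f"{f} and {f + 1} for particle {p}; trajectory sampled too sparsely"
        )
    frames = np.empty_like(traj.frames)
    frames[0] = traj.frames[0]
    np.cumsum(diffs, axis=0, out=diffs)
    frames[1:] = traj.frames[0][None] + diffs
    return Trajectory(times=traj.times.copy(), frames=frames, box=traj.box.copy(), wrapped=False)


def _msd_fft(r: np.ndarray) -> np.ndarray:
    """All-time-origin MSD of one walker path r (N, 3) via the FFT
    autocorrelation identity msd(m) = S1(m) - 2*S2(m)."""
    n = len(r)
    nfft = 1 << (2 * n - 1).bit_length()
    fr = np.fft.rfft(r, n=nfft, axis=0)
    s2 = np.fft.irfft(fr * np.conj(fr), n=nfft, axis=0)[:n].sum(axis=1)
    s2 /= n - np.arange(n)
    d = np.square(r).sum(axis=1)
    d_ext = np.append(d, 0.0)
    q = 2.0 * d.sum()
    s1 = np.empty(n)
    for m in range(n):
        q -= d_ext[m - 1] + d_ext[n - m]
        s1[m] = q / (n - m)
    return s1 - 2.0 * s2


def _molecule_coms(traj: Trajectory, species_map: SpeciesMap, mol_ids: np.ndarray) -> np.ndarray:
    """(n_frames, n_molecules, 3) unweighted-centroid paths."""
    coms = np.empty((traj.n_frames, len(mol_ids), 3))
    for k, mid in enumerate(mol_ids):
        parts = species_map.particles_of(int(mid))
        coms[:, k, :] = traj.frames[:, parts, :].mean(axis=1)
    return coms


def _select_molecules(species_map: SpeciesMap, selector) -> np.ndarray:
    if isinstance(selector, dict):
        return species_map.molecule_ids(
            species=selector.get("species"), chirality=selector.get("chirality")
        )
    return np.asarray(list(selector), dtype=int)


def msd(
    traj: Trajectory,
    species_map: SpeciesMap,
    selector,
    max_lag_fraction: float = 0.9,
    origin_stride: int = 1,
) -> MSDCurve:
    """Centre-of-mass MSD averaged over the selected molecules and over all
    time origins (overlapping windows).

    ``selector`` is either a dict ({"species": ..., "chirality": ...}) or an
    explicit iterable of molecule ids.  The trajectory must be unwrapped.
    ``origin_stride`` > 1 subsamples time origins for speed (the FFT path is
    used only for stride 1).
    """
    if traj.wrapped:
        raise ValueError("msd requires an unwrapped trajectory; call unwrap() first")
    mol_ids = _select_molecules(species_map, selector)
    if len(mol_ids) == 0:
        raise ValueError(f"selector {selector!r} matches no molecules")
    coms = _molecule_coms(traj, species_map, mol_ids)
    n = traj.n_frames
    n_lags = max(2, int(np.floor(max_lag_fraction * (n - 1))) + 1)
    n_lags = min(n_lags, n)

    if origin_stride == 1:
        acc = np.zeros(n)
        for k in range(coms.shape[1]):
            acc += _msd_fft(coms[:, k, :])
        curve = acc[:n_lags] / coms.shape[1]
        n_origins = (n - np.arange(n_lags)) * coms.shape[1]
    else:
        curve = np.zeros(n_lags)
        n_origins = np.zeros(n_lags, dtype=int)
        for m in range(n_lags):
            disp = coms[m:, :, :] - coms[: n - m, :, :]
            disp = disp[::origin_stride]
            sq = np.square(disp).sum(axis=2)
            curve[m] = sq.mean()
            n_origins[m] = sq.size
    curve[0] = 0.0

    label = str(selector) if not isinstance(selector, dict) else ",".join(
        f"{k}={v}" for k, v in selector.items() if v is not None
    )
    return MSDCurve(
        lag_times=(traj.times[:n_lags] - traj.times[0]) / 1000.0,
        msd=curve,
        n_origins=n_origins,
        species_selector=label,
        duration_ns=traj.duration_ns,
    )


def average_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Pointwise mean of replicate MSD curves (identical lag grids required);
    origin counts are summed."""
    if not curves:
        raise ValueError("no curves to average")
    ref = curves[0]
    for c in curves[1:]:
        if c.lag_times.shape != ref.lag_times.shape or not np.allclose(
            c.lag_times, ref.lag_times, rtol=1e-9
        ):
            raise ValueError("mismatched lag grids")
    return MSDCurve(
        lag_times=ref.lag_times.copy(),
        msd=np.mean([c.msd for c in curves], axis=0),
        n_origins=np.sum([c.n_origins for c in curves], axis=0),
        species_selector=ref.species_selector,
        duration_ns=ref.duration_ns,
    )


def _default_window(curve: MSDCurve) -> tuple:
    t = curve.duration_ns if curve.duration_ns > 0 else float(curve.lag_times[-1])
    return (0.1 * t, 0.9 * t)


def fit_einstein(
    curve: MSDCurve,
    window: tuple | None = None,
    per_replicate_curves: list[MSDCurve] | None = None,
) -> DiffusionEstimate:
    """Ordinary least-squares fit of MSD versus lag over ``window`` (ns);
    D = slope/6 converted to 1e-10 m^2/s.

    The default window spans 10% to 90% of the trajectory duration (the
    standard linear-regime choice for runs whose MSD is fitted between
    one-tenth and nine-tenths of their length).  When ``per_replicate_curves``
    are given, the quoted stderr is the SEM of the per-replicate D values.
    """
    if window is None:
        window = _default_window(curve)
    t_min, t_max = window
    mask = (curve.lag_times >= t_min) & (curve.lag_times <= t_max)
    if mask.sum() < 10:
        raise ValueError(f"fit window {window} contains {mask.sum()} points; need >= 10")
    x = curve.lag_times[mask]
    y = curve.msd[mask]
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in fit window")
    res = stats.linregress(x, y)
    d = res.slope / 6.0 * NM2_PER_NS_TO_1E10_M2_S

    per_rep = None
    if per_replicate_curves:
        per_rep = np.array(
            [fit_einstein(c, window=window).D for c in per_replicate_curves]
        )
        stderr = float(np.std(per_rep, ddof=1) / np.sqrt(len(per_rep))) if len(per_rep) > 1 else 0.0
        kind = "sem_replicates"
    else:
        stderr = res.stderr / 6.0 * NM2_PER_NS_TO_1E10_M2_S
        kind = "slope"
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return DiffusionEstimate(
        D=float(d),
        stderr=float(stderr),
        r_squared=min(r2, 1.0),
        fit_window=(float(t_min), float(t_max)),
        per_replicate_D=per_rep,
        stderr_kind=kind,
    )


def convergence_report(per_replicate_curves: list[MSDCurve], window: tuple | None = None):
    """Fit on the running average of the first n replicate curves, n = 1..N
    in supplied order (no reordering).  Returns a DataFrame with columns
    (n_replicates, D, stderr, r_squared); stderr is the SEM over the first n
    per-replicate D values (NaN at n = 1)."""
    import pandas as pd

    if len(per_replicate_curves) < 2:
        raise ValueError("need >= 2 replicates for a convergence report")
    if window is None:
        window = _default_window(per_replicate_curves[0])
    single_d = np.array([fit_einstein(c, window=window).D for c in per_replicate_curves])
    rows = []
    for n in range(1, len(per_replicate_curves) + 1):
        avg = average_msd(per_replicate_curves[:n])
        est = fit_einstein(avg, window=window)
        sem = np.std(single_d[:n], ddof=1) / np.sqrt(n) if n > 1 else np.nan
        rows.append((n, est.D, sem, est.r_squared))
    return pd.DataFrame(rows, columns=["n_replicates", "D", "stderr", "r_squared"])
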