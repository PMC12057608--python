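"""Detection and statistics of transient tracer-CRA (analyte - chiral
resolving agent) complexes.

Contact definition: a tracer-CRA pair is *bound* while the minimum
inter-particle distance between the two molecules (minimum-image convention)
is below a hysteresis pair of cutoffs - the pair enters the bound state when
the distance drops to ``r_on`` and leaves it when the distance exceeds
``r_off`` (``r_off >= r_on`` suppresses rattling at the cutoff).  Unbound gaps
shorter than ``gap_tolerance`` are bridged into one event.  All cutoffs are in
Angstrom, gap_tolerance in ps; every result table carries these choices.

Event time convention: a bound run of frames [f0 .. f1] maps to the half-open
interval [t(f0), t(f1+1)) clipped at the final frame time, so that per pair the
bound and unbound durations exactly partition the trajectory span when
gap_tolerance = 0, and a pair bound throughout yields one event of the full
duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from enantiodyn.core_io import ANGSTROM_PER_NM, SpeciesMap, Trajectory

__all__ = [
    "ComplexEvent",
    "DistanceHistogram",
    "detect_complexes",
    "bound_state_matrix",
    "lifetimes",
    "replicate_lifetimes",
    "lifetime_difference",
    "stoichiometry_census",
    "average_census",
    "excess_heterochiral",
    "chiral_distance_histogram",
    "average_histograms",
    "select_frames",
]

STATE_LABELS = ["1:1", "1:2", "1:3", "1:4+", "unbound"]


@dataclass(frozen=True)
class ComplexEvent:
    """One continuous bound interval of a tracer-CRA pair (times in ns)."""

    tracer_id: int
    cra_id: int
    t_start: float
    t_end: float
    pairing: str

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class DistanceHistogram:
    """Chiral-H to CRA centre-of-mass distance histogram (Angstrom).

    ``mean_frequency`` is the per-bin count (single trajectory) or the
    replicate mean; ``error`` the SEM across replicates (zeros for a single
    trajectory)."""

    bin_edges: np.ndarray
    mean_frequency: np.ndarray
    error: np.ndarray
    pairing: str

    def __post_init__(self) -> None:
        if np.any(self.mean_frequency < 0):
            raise ValueError("frequencies must be non-negative")
        if len(self.bin_edges) != len(self.mean_frequency) + 1:
            raise ValueError("bin_edges must have one more entry than frequencies")

    @property
    def total_mass(self) -> float:
        return float(self.mean_frequency.sum())


def _minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _molecule_com(frames: np.ndarray, particles: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image-consistent unweighted centroid of one molecule, per frame."""
    ref = frames[:, particles[0], :]
    rel = _minimum_image(frames[:, particles, :] - ref[:, None, :], box)
    return ref + rel.mean(axis=1)


def _pair_distances(traj: Trajectory, species_map: SpeciesMap):
    """Minimum inter-particle distance (Angstrom) for every tracer-CRA pair.

    Returns (dist[frames, tracers, cras], tracer_ids, cra_ids)."""
    tracer_ids = species_map.molecule_ids(species="MA")
    cra_ids = species_map.molecule_ids(species="CRA")
    box = traj.box
    n_f = traj.n_frames
    dist = np.full((n_f, len(tracer_ids), len(cra_ids)), np.inf)
    cra_parts = [species_map.particles_of(int(c)) for c in cra_ids]
    for ti, tid in enumerate(tracer_ids):
        t_parts = species_map.particles_of(int(tid))
        for ci, c_parts in enumerate(cra_parts):
            best = np.full(n_f, np.inf)
            for tp in t_parts:
                d = _minimum_image(
                    traj.frames[:, [tp], :] - traj.frames[:, c_parts, :], box
                )
                best = np.minimum(best, np.linalg.norm(d, axis=-1).min(axis=1))
            dist[:, ti, ci] = best
    return dist * ANGSTROM_PER_NM, tracer_ids, cra_ids


def bound_state_matrix(
    traj: Trajectory, species_map: SpeciesMap, r_on: float, r_off: float
):
    """Hysteresis bound-state booleans per frame and tracer-CRA pair.

    Returns (state[frames, tracers, cras], tracer_ids, cra_ids).  A pair
    enters the bound state when its minimum inter-particle distance <= r_on
    (Angstrom) and leaves when it exceeds r_off."""
    if r_off < r_on:
        raise ValueError("r_off must be >= r_on")
    if r_on <= 0:
        raise ValueError("r_on must be positive")
    dist, tracer_ids, cra_ids = _pair_distances(traj, species_map)
    below_on = dist <= r_on
    above_off = dist > r_off
    state = np.zeros_like(below_on)
    state[0] = below_on[0]
    for f in range(1, traj.n_frames):
        state[f] = below_on[f] | (state[f - 1] & ~above_off[f])
    return state, tracer_ids, cra_ids


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop is exclusive."""
    padded = np.diff(np.concatenate(([False], mask, [False])).astype(int))
    starts = np.where(padded == 1)[0]
    stops = np.where(padded == -1)[0]
    return list(zip(starts, stops))


def detect_complexes(
    traj: Trajectory,
    species_map: SpeciesMap,
    r_on: float = 4.0,
    r_off: float = 5.0,
    gap_tolerance: float = 100.0,
) -> list[ComplexEvent]:
    """Detect bound events for every tracer-CRA pair.

    ``r_on``/``r_off`` in Angstrom, ``gap_tolerance`` in ps.  The defaults
    (4.0 / 5.0 A, 100 ps) treat brief separations as part of one residence
    event, appropriate when complex lifetimes are orders of magnitude longer
    than the contact-breaking timescale.
    """
    state, tracer_ids, cra_ids = bound_state_matrix(traj, species_map, r_on, r_off)
    times_ns = traj.times / 1000.0
    gap_ns = gap_tolerance / 1000.0
    n_frames = traj.n_frames
    events: list[ComplexEvent] = []
    for ti, tid in enumerate(tracer_ids):
        t_chir = species_map.chirality_of(int(tid))
        for ci, cid in enumerate(cra_ids):
            runs = _runs(state[:, ti, ci])
            if not runs:
                continue
            # bridge unbound gaps shorter than gap_tolerance
            merged = [list(runs[0])]
            for start, stop in runs[1:]:
                gap = times_ns[start] - times_ns[merged[-1][1]] if merged[-1][1] < n_frames else 0.0
                if gap < gap_ns - 1e-12:
                    merged[-1][1] = stop
                else:
                    merged.append([start, stop])
            c_chir = species_map.chirality_of(int(cid))
            pairing = "homochiral" if t_chir == c_chir else "heterochiral"
            for start, stop in merged:
                t_start = times_ns[start]
                t_end = times_ns[stop] if stop < n_frames else times_ns[-1]
                if t_end > t_start:
                    events.append(
                        ComplexEvent(int(tid), int(cid), float(t_start), float(t_end), pairing)
                    )
    return events


def lifetimes(events: list[ComplexEvent]) -> pd.DataFrame:
    """Mean and SEM of event durations per pairing class (durations pooled
    over all supplied events).  Classes with no events are absent from the
    table, not reported as zero."""
    rows = []
    by_class: dict[str, list[float]] = {}
    for ev in events:
        by_class.setdefault(ev.pairing, []).append(ev.duration)
    for pairing, durs in sorted(by_class.items()):
        arr = np.asarray(durs)
        sem = float(np.std(arr, ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        rows.append((pairing, float(arr.mean()), sem, len(arr)))
    return pd.DataFrame(rows, columns=["pairing", "mean_lifetime", "stderr", "n_events"])


def replicate_lifetimes(event_lists: list[list[ComplexEvent]]) -> pd.DataFrame:
    """Per-pairing mean lifetime with SEM across replicates (each replicate
    contributes its own mean), the error convention used for replicate-based
    lifetime tables."""
    per_rep: dict[str, list[float]] = {}
    for events in event_lists:
        tab = lifetimes(events)
        for _, row in tab.iterrows():
            per_rep.setdefault(row["pairing"], []).append(row["mean_lifetime"])
    rows = []
    for pairing, means in sorted(per_rep.items()):
        arr = np.asarray(means)
        sem = float(np.std(arr, ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else np.nan
        rows.append((pairing, float(arr.mean()), sem, len(arr)))
    return pd.DataFrame(rows, columns=["pairing", "mean_lifetime", "stderr", "n_replicates"])


def lifetime_difference(
    hetero: tuple[float, float], homo: tuple[float, float]
) -> tuple[float, float]:
    """Heterochiral minus homochiral mean lifetime with quadrature-propagated
    error: (t_het - t_homo, sqrt(e_het^2 + e_homo^2)).  Rounding happens only
    at presentation."""
    (t1, e1), (t2, e2) = hetero, homo
    if e1 < 0 or e2 < 0:
        raise ValueError("errors must be non-negative")
    return t1 - t2, float(np.hypot(e1, e2))


def stoichiometry_census(
    traj: Trajectory,
    species_map: SpeciesMap,
    r_on: float = 4.0,
    r_off: float = 5.0,
) -> pd.DataFrame:
    """Per-frame stoichiometry census: each tracer's simultaneous bound-CRA
    count k defines its 1:k state for that frame (a tracer within the cutoff
    of two CRAs counts as one 1:2 frame, not two 1:1 frames).

    Returns a tidy DataFrame (tracer_chirality, pairing, state, frames) where
    ``frames`` sums over all tracers of that chirality; states are
    {1:1, 1:2, 1:3, 1:4+, unbound} and partition every (frame, tracer) cell.
    """
    state, tracer_ids, cra_ids = bound_state_matrix(traj, species_map, r_on, r_off)
    counts = state.sum(axis=2)  # (frames, tracers)
    cra_chir = species_map.chirality_of(int(cra_ids[0])) if len(cra_ids) else "none"
    rows = []
    for ti, tid in enumerate(tracer_ids):
        chir = species_map.chirality_of(int(tid))
        pairing = "homochiral" if chir == cra_chir else "heterochiral"
        c = counts[:, ti]
        binned = {
            "1:1": int((c == 1).sum()),
            "1:2": int((c == 2).sum()),
            "1:3": int((c == 3).sum()),
            "1:4+": int((c >= 4).sum()),
            "unbound": int((c == 0).sum()),
        }
        for label, n in binned.items():
            rows.append((chir, pairing, label, n))
    df = pd.DataFrame(rows, columns=["tracer_chirality", "pairing", "state", "frames"])
    return df.groupby(["tracer_chirality", "pairing", "state"], as_index=False)["frames"].sum()


def average_census(censuses: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean and SEM of per-replicate census frame counts."""
    cat = pd.concat(censuses, keys=range(len(censuses)), names=["replicate"]).reset_index(
        level=0
    )
    g = cat.groupby(["tracer_chirality", "pairing", "state"])["frames"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "frames_mean", "sem": "frames_sem", "count": "n_replicates"})


def excess_heterochiral(censuses: list[pd.DataFrame]) -> tuple[float, float]:
    """Excess of heterochiral over homochiral 1:1 frame counts: per replicate,
    total heterochiral 1:1 frames minus total homochiral 1:1 frames; returns
    (mean, SEM across replicates).  With a single replicate the error is
    undefined (NaN)."""
    diffs = []
    for census in censuses:
        ones = census[census["state"] == "1:1"]
        het = ones.loc[ones["pairing"] == "heterochiral", "frames"].sum()
        hom = ones.loc[ones["pairing"] == "homochiral", "frames"].sum()
        if not len(ones):
            raise ValueError("census lacks 1:1 states")
        diffs.append(float(het - hom))
    arr = np.asarray(diffs)
    sem = float(np.std(arr, ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan")
    return float(arr.mean()), sem


def _one_to_one_distances(
    traj: Trajectory,
    species_map: SpeciesMap,
    r_on: float,
    r_off: float,
) -> pd.DataFrame:
    """Chiral-H -> bound-CRA centre-of-mass distance (Angstrom) for every
    (frame, tracer) in a 1:1 state."""
    state, tracer_ids, cra_ids = bound_state_matrix(traj, species_map, r_on, r_off)
    counts = state.sum(axis=2)
    box = traj.box
    cra_chir = species_map.chirality_of(int(cra_ids[0])) if len(cra_ids) else "none"
    cra_coms = {
        int(cid): _molecule_com(traj.frames, species_map.particles_of(int(cid)), box)
        for cid in cra_ids
    }
    rows = []
    for ti, tid in enumerate(tracer_ids):
        sel = counts[:, ti] == 1
        if not sel.any():
            continue
        h_part = species_map.chiral_h_particle(int(tid))
        chir = species_map.chirality_of(int(tid))
        pairing = "homochiral" if chir == cra_chir else "heterochiral"
        partner_idx = np.argmax(state[:, ti, :], axis=1)
        for f in np.where(sel)[0]:
            cid = int(cra_ids[partner_idx[f]])
            d = _minimum_image(traj.frames[f, h_part] - cra_coms[cid][f], box)
            rows.append(
                (int(f), float(traj.times[f] / 1000.0), int(tid), cid, pairing,
                 float(np.linalg.norm(d) * ANGSTROM_PER_NM))
            )
    return pd.DataFrame(
        rows, columns=["frame", "time_ns", "tracer_id", "cra_id", "pairing", "distance_A"]
    )


def chiral_distance_histogram(
    traj: Trajectory,
    species_map: SpeciesMap,
    r_on: float = 4.0,
    r_off: float = 5.0,
    bin_width: float = 0.5,
    distance_range: tuple[float, float] = (2.5, 15.0),
) -> dict[str, DistanceHistogram]:
    """Histogram of chiral-H to CRA centre-of-mass distances over all
    (frame, tracer) observations in a 1:1 state, one histogram per pairing
    class.  Bins are left-closed right-open, default 0.5 A over [2.5, 15.0] A.
    Raises when no 1:1 frames exist."""
    obs = _one_to_one_distances(traj, species_map, r_on, r_off)
    if len(obs) == 0:
        raise ValueError("no 1:1 complex frames; nothing to histogram")
    lo, hi = distance_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    out = {}
    for pairing, grp in obs.groupby("pairing"):
        counts, _ = np.histogram(grp["distance_A"], bins=edges)
        out[pairing] = DistanceHistogram(
            bin_edges=edges,
            mean_frequency=counts.astype(float),
            error=np.zeros_like(counts, dtype=float),
            pairing=str(pairing),
        )
    return out


def average_histograms(per_replicate: list[dict[str, DistanceHistogram]]) -> dict[str, DistanceHistogram]:
    """Replicate mean and SEM per bin, per pairing class."""
    pairings = sorted({p for rep in per_replicate for p in rep})
    out = {}
    for pairing in pairings:
        stacks = [rep[pairing].mean_frequency for rep in per_replicate if pairing in rep]
        edges = next(rep[pairing].bin_edges for rep in per_replicate if pairing in rep)
        arr = np.stack(stacks)
        sem = (
            arr.std(axis=0, ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else np.zeros(arr.shape[1])
        )
        out[pairing] = DistanceHistogram(
            bin_edges=edges, mean_frequency=arr.mean(axis=0), error=sem, pairing=pairing
        )
    return out


def select_frames(
    traj: Trajectory,
    species_map: SpeciesMap,
    d_min: float,
    d_max: float,
    stride: int = 1,
    r_on: float = 4.0,
    r_off: float = 5.0,
) -> pd.DataFrame:
    """Select 1:1-complex observations whose chiral-H to CRA centre-of-mass
    distance lies in [d_min, d_max] Angstrom, subsampled by ``stride`` over
    observations; each row is tagged with frame, tracer, CRA, pairing and
    distance.  An empty selection returns an empty table (with a warning from
    the caller's side if desired)."""
    if not d_max > d_min:
        raise ValueError("d_max must exceed d_min")
    obs = _one_to_one_distances(traj, species_map, r_on, r_off)
    sel = obs[(obs["distance_A"] >= d_min) & (obs["distance_A"] <= d_max)]
    return sel.iloc[::stride].reset_index(drop=True)


def write_selected_frames(
    traj: Trajectory, selection: pd.DataFrame, path
) -> None:
    """Export the full-system coordinates of the selected frames as a
    multi-model PDB for external refinement.  Frame order follows the
    selection table (times are re-indexed; the table is the provenance)."""
    from enantiodyn.core_io import write_trajectory, Trajectory as _T

    frames = traj.frames[selection["frame"].unique()]
    sub = _T(
        times=np.arange(len(frames), dtype=float),
        frames=frames,
        box=traj.box.copy(),
        wrapped=traj.wrapped,
    )
    write_trajectory(sub, path, format_hint="pdb")
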