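"""End-to-end orchestration: simulate -> diffusion -> complexation -> report.

A run is fully specified by a :class:`RunConfig`; the config (including the
master seed and every cutoff) is embedded verbatim in the report so any output
can be reproduced bit-identically.  Per-replicate seeds are derived
deterministically from the master seed with ``numpy.random.SeedSequence``
spawning, so replicate k of a run is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from enantiodyn import complexation, diffusion, dosyfit, synthgen

__all__ = ["RunConfig", "run_all", "replicate_seeds"]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with defaults.  Serializable to/from
    plain dicts (YAML/JSON)."""

    preset: str = "production-ci"
    n_replicates: int = 15
    seed: int = 0
    r_on_A: float | None = None  # default: capture radius of the preset
    r_off_A: float | None = None
    gap_tolerance_ps: float = 0.0
    fit_window_ns: tuple | None = None  # default: 10-90% of run length
    histogram_bin_A: float = 0.5
    histogram_range_A: tuple = (2.5, 15.0)
    out_dir: str | None = None
    preset_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("fit_window_ns", "histogram_range_A"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate integer seeds spawned from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _significance(value: float, err: float, n_sigma: float = 3.0) -> str:
    if not np.isfinite(err) or err == 0:
        return "undetermined"
    return "significant" if abs(value) > n_sigma * err else "not significant"


def run_all(config: RunConfig) -> dict:
    """Execute the full chain on synthetic replicates and assemble the report.

    Stages: simulate each replicate; per-enantiomer diffusion (replicate MSDs,
    averaged fit, SEM across replicates); complex detection, lifetimes by
    pairing with replicate errors, lifetime difference, stoichiometry census,
    heterochiral-excess statistic, chiral-H distance histograms.  Any stage
    error propagates with the stage name; previously computed sections of the
    report are retained in the exception's ``partial`` attribute.
    """
    report: dict = {"config": config.to_dict()}
    seeds = replicate_seeds(config.seed, config.n_replicates)
    report["replicate_seeds"] = seeds

    stage = "simulate"
    try:
        runs = []
        for s in seeds:
            spec = synthgen.preset(config.preset, seed=s, **config.preset_overrides)
            runs.append(synthgen.simulate(spec))
        spec0 = runs[0][2].spec
        r_on = config.r_on_A if config.r_on_A is not None else spec0.capture_radius * 10.0
        r_off = config.r_off_A if config.r_off_A is not None else r_on

        stage = "diffusion"
        diff_section = {}
        curves_by_chir = {}
        for chir in ("R", "S"):
            curves = []
            for traj, smap, _ in runs:
                unwrapped = diffusion.unwrap(traj)
                curves.append(
                    diffusion.msd(unwrapped, smap, {"species": "MA", "chirality": chir})
                )
            curves_by_chir[chir] = curves
            avg = diffusion.average_msd(curves)
            est = diffusion.fit_einstein(
                avg, window=config.fit_window_ns, per_replicate_curves=curves
            )
            diff_section[chir] = {
                "D": est.D,
                "stderr": est.stderr,
                "r_squared": est.r_squared,
                "fit_window_ns": list(est.fit_window),
                "stderr_kind": est.stderr_kind,
                "per_replicate_D": [float(x) for x in est.per_replicate_D],
            }
        dd, dd_err = dosyfit.delta_D(
            (diff_section["R"]["D"], diff_section["R"]["stderr"]),
            (diff_section["S"]["D"], diff_section["S"]["stderr"]),
        )
        diff_section["delta_D"] = {
            "value": dd,
            "stderr": dd_err,
            "convention": "D(R-MA) - D(S-MA)",
            "significance_3sigma": _significance(dd, dd_err),
        }
        report["diffusion"] = diff_section

        stage = "complexation"
        cutoffs = {"r_on_A": r_on, "r_off_A": r_off, "gap_tolerance_ps": config.gap_tolerance_ps}
        event_lists = [
            complexation.detect_complexes(
                traj, smap, r_on=r_on, r_off=r_off, gap_tolerance=config.gap_tolerance_ps
            )
            for traj, smap, _ in runs
        ]
        life = complexation.replicate_lifetimes(event_lists)
        section = {"cutoffs": cutoffs, "lifetimes": life.to_dict(orient="records")}
        by_pairing = {row["pairing"]: row for _, row in life.iterrows()}
        if {"homochiral", "heterochiral"} <= set(by_pairing):
            het = by_pairing["heterochiral"]
            hom = by_pairing["homochiral"]
            diff, err = complexation.lifetime_difference(
                (het["mean_lifetime"], het["stderr"]), (hom["mean_lifetime"], hom["stderr"])
            )
            section["lifetime_difference_ns"] = {
                "value": diff,
                "stderr": err,
                "convention": "heterochiral - homochiral",
                "significance_3sigma": _significance(diff, err),
            }
        censuses = [
            complexation.stoichiometry_census(traj, smap, r_on=r_on, r_off=r_off)
            for traj, smap, _ in runs
        ]
        section["census"] = complexation.average_census(censuses).to_dict(orient="records")
        excess, excess_err = complexation.excess_heterochiral(censuses)
        section["excess_heterochiral_1to1_frames"] = {"value": excess, "stderr": excess_err}
        try:
            hists = [
                complexation.chiral_distance_histogram(
                    traj, smap, r_on=r_on, r_off=r_off,
                    bin_width=config.histogram_bin_A,
                    distance_range=config.histogram_range_A,
                )
                for traj, smap, _ in runs
            ]
            avg_h = complexation.average_histograms(hists)
            section["distance_histograms"] = {
                pairing: {
                    "bin_edges_A": h.bin_edges.tolist(),
                    "mean_frequency": h.mean_frequency.tolist(),
                    "sem": h.error.tolist(),
                }
                for pairing, h in avg_h.items()
            }
        except ValueError:
            section["distance_histograms"] = None
        report["complexation"] = section
    except Exception as exc:
        exc.partial = report  # type: ignore[attr-defined]
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as f:
            json.dump(report, f, indent=2, sort_keys=True)
    return report
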