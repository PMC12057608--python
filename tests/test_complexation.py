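import numpy as np
import pytest

from enantiodyn import complexation, synthgen
from enantiodyn.complexation import ComplexEvent, _runs, bound_state_matrix
from enantiodyn.dosyfit import round_printed

from conftest import make_species_map, make_trajectory


def pair_map(cra_chirality="R"):
    return make_species_map(
        [
            (0, 0, "MA", "R", "heavy"),
            (1, 0, "MA", "R", "chiral_H"),
            (2, 1, "CRA", cra_chirality, "heavy"),
        ]
    )


def held_pair_trajectory(n_frames=20, bead_cra_nm=0.25, h_cra_nm=0.625, box=10.0):
    """Tracer bead, chiral_H, and CRA bead at fixed mutual distances.

    Defaults use binary-exact coordinates so constructed distances carry no
    floating-point surprises at histogram bin edges."""
    frames = np.zeros((n_frames, 3, 3))
    frames[:, 0] = [5.0, 5.0, 5.0]
    frames[:, 2] = [5.0 + bead_cra_nm, 5.0, 5.0]
    # place H on the line through the CRA at the requested distance
    frames[:, 1] = [5.0 + bead_cra_nm - h_cra_nm, 5.0, 5.0]
    return make_trajectory(frames, box=box, wrapped=True)


class TestDetectComplexes:
    def test_pair_held_in_contact_yields_one_full_event(self):
        traj = held_pair_trajectory()
        events = complexation.detect_complexes(traj, pair_map(), r_on=4.0, r_off=5.0,
                                               gap_tolerance=0.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.t_start == 0.0
        assert ev.t_end == pytest.approx(traj.duration_ns)
        assert ev.pairing == "homochiral"

    def test_pair_beyond_cutoff_yields_no_events(self):
        traj = held_pair_trajectory(bead_cra_nm=2.0, h_cra_nm=2.2)
        events = complexation.detect_complexes(traj, pair_map(), r_on=4.0, r_off=5.0)
        assert events == []

    def test_detection_reproduces_simulator_telegraph_exactly(self, bias_run):
        """With r_on = r_off = capture radius and no gap bridging, detected
        events equal the simulator's ground-truth bound intervals exactly."""
        spec, traj, smap, truth = bias_run
        events = complexation.detect_complexes(
            traj, smap, r_on=spec.capture_radius * 10, r_off=spec.capture_radius * 10,
            gap_tolerance=0.0,
        )
        detected = sorted((e.tracer_id, e.cra_id, e.t_start, e.t_end, e.pairing) for e in events)
        expected = sorted(truth.bound_intervals())
        assert len(detected) == len(expected)
        for d, g in zip(detected, expected):
            assert d[0] == g[0] and d[1] == g[1] and d[4] == g[4]
            assert d[2] == pytest.approx(g[2], abs=1e-12)
            assert d[3] == pytest.approx(g[3], abs=1e-12)

    def test_gap_bridging_merges_brief_separations(self):
        """A 2-frame excursion beyond r_off inside gap_tolerance is bridged
        into a single event; with zero tolerance it splits the event."""
        frames = np.zeros((20, 3, 3))
        frames[:, 0] = [5.0, 5.0, 5.0]
        frames[:, 1] = [4.8, 5.0, 5.0]
        frames[:, 2] = [5.3, 5.0, 5.0]
        frames[8:10, 2] = [6.5, 5.0, 5.0]  # 12 A away: clearly unbound
        traj = make_trajectory(frames, box=10.0, wrapped=True)
        split = complexation.detect_complexes(traj, pair_map(), r_on=4.0, r_off=5.0,
                                              gap_tolerance=0.0)
        merged = complexation.detect_complexes(traj, pair_map(), r_on=4.0, r_off=5.0,
                                               gap_tolerance=3.0)
        assert len(split) == 2
        assert len(merged) == 1
        assert merged[0].duration == pytest.approx(traj.duration_ns)

    def test_hysteresis_keeps_pair_bound_between_cutoffs(self):
        """Once bound at r_on, the pair stays bound while the distance sits
        between r_on and r_off."""
        frames = np.zeros((10, 3, 3))
        frames[:, 0] = [5.0, 5.0, 5.0]
        frames[:, 1] = [4.75, 5.0, 5.0]
        frames[:, 2] = [5.35, 5.0, 5.0]  # 3.5 A: binds at r_on = 4
        frames[5:, 2] = [5.45, 5.0, 5.0]  # 4.5 A: beyond r_on, inside r_off
        traj = make_trajectory(frames, box=10.0, wrapped=True)
        events = complexation.detect_complexes(traj, pair_map(), r_on=4.0, r_off=5.0,
                                               gap_tolerance=0.0)
        assert len(events) == 1
        assert events[0].t_end == pytest.approx(traj.duration_ns)

    def test_invalid_cutoffs_rejected(self, bias_run):
        _, traj, smap, _ = bias_run
        with pytest.raises(ValueError, match="r_off"):
            complexation.detect_complexes(traj, smap, r_on=5.0, r_off=4.0)

    def test_bound_and_unbound_durations_partition_trajectory(self, bias_run):
        """With gap_tolerance = 0, bound plus unbound interval durations per
        pair telescope exactly to the trajectory time span."""
        spec, traj, smap, _ = bias_run
        state, tracer_ids, cra_ids = bound_state_matrix(
            traj, smap, spec.capture_radius * 10, spec.capture_radius * 10
        )
        times_ns = traj.times / 1000.0
        span = times_ns[-1] - times_ns[0]
        n = traj.n_frames
        for ti in range(len(tracer_ids)):
            for ci in range(len(cra_ids)):
                total = 0.0
                for mask in (state[:, ti, ci], ~state[:, ti, ci]):
                    for start, stop in _runs(mask):
                        t_end = times_ns[stop] if stop < n else times_ns[-1]
                        total += t_end - times_ns[start]
                assert total == pytest.approx(span, abs=1e-9)

    def test_resolving_agent_chirality_swap_mirrors_pairing_labels(self, bias_run):
        """Relabelling the resolving agent's chirality (R agent -> S agent,
        analytes unchanged) swaps the homochiral and heterochiral outputs
        exactly; relabelling *everything* (the full mirror system) leaves the
        pairing labels invariant."""
        from enantiodyn.core_io import SpeciesMap

        spec, traj, smap, _ = bias_run
        r = spec.capture_radius * 10
        ev = complexation.detect_complexes(traj, smap, r_on=r, r_off=r, gap_tolerance=0.0)

        cra_swapped_table = smap.table.copy()
        is_cra = cra_swapped_table["species"] == "CRA"
        cra_swapped_table.loc[is_cra, "chirality"] = cra_swapped_table.loc[
            is_cra, "chirality"
        ].map({"R": "S", "S": "R"})
        ev_swapped = complexation.detect_complexes(
            traj, SpeciesMap(cra_swapped_table), r_on=r, r_off=r, gap_tolerance=0.0
        )
        flip = {"homochiral": "heterochiral", "heterochiral": "homochiral"}
        expected = sorted((e.tracer_id, e.cra_id, e.t_start, e.t_end, flip[e.pairing]) for e in ev)
        got = sorted((e.tracer_id, e.cra_id, e.t_start, e.t_end, e.pairing) for e in ev_swapped)
        assert got == expected

        ev_full = complexation.detect_complexes(
            traj, smap.swap_chirality(), r_on=r, r_off=r, gap_tolerance=0.0
        )
        unchanged = sorted((e.tracer_id, e.cra_id, e.t_start, e.t_end, e.pairing) for e in ev_full)
        assert unchanged == sorted(
            (e.tracer_id, e.cra_id, e.t_start, e.t_end, e.pairing) for e in ev
        )


class TestLifetimes:
    def test_two_point_mean_and_sem(self):
        events = [
            ComplexEvent(0, 1, 0.0, 2.0, "heterochiral"),
            ComplexEvent(0, 1, 3.0, 7.0, "heterochiral"),
        ]
        tab = complexation.lifetimes(events)
        row = tab.iloc[0]
        assert row["mean_lifetime"] == pytest.approx(3.0)
        assert row["stderr"] == pytest.approx(1.0)

    def test_single_full_length_event(self):
        events = [ComplexEvent(0, 1, 0.0, 1.0, "homochiral")]
        row = complexation.lifetimes(events).iloc[0]
        assert row["mean_lifetime"] == pytest.approx(1.0)
        assert row["stderr"] == 0.0

    def test_absent_class_not_reported_as_zero(self):
        events = [ComplexEvent(0, 1, 0.0, 1.0, "homochiral")]
        tab = complexation.lifetimes(events)
        assert list(tab["pairing"]) == ["homochiral"]

    def test_exponential_residence_oracle(self):
        """Detected mean lifetime converges to 1/k_off for kinetically
        generated events (here a quick, modest-precision check; the long-run
        convergence test lives in the acceptance suite)."""
        spec = synthgen.SimulationSpec(
            n_R_MA=5, n_S_MA=5, n_CRA=10, box_edge=5.0, dt=1.0, n_steps=20000,
            save_interval=2, D_free={"MA": 12.0, "CRA": 7.0}, D_bound=5.0,
            k_on=1000.0, k_off={("R", "R"): 2.0, ("S", "R"): 2.0},
            capture_radius=0.6, seed=13,
        )
        _, _, truth = synthgen.simulate(spec)
        durs = np.array([b - a for _, _, a, b, _ in truth.bound_intervals()])
        interior = durs  # censoring negligible: runs are 40x the mean lifetime
        assert len(interior) > 150
        sem = interior.std(ddof=1) / np.sqrt(len(interior))
        assert abs(interior.mean() - 0.5) < 4 * max(sem, 0.01)


class TestLifetimeDifference:
    @pytest.mark.parametrize(
        "hetero,homo,expected",
        [
            ((86.04, 0.46), (84.46, 0.38), (1.58, 0.60)),
            ((85.48, 0.39), (83.11, 0.49), (2.37, 0.63)),
        ],
    )
    def test_published_table_arithmetic(self, hetero, homo, expected):
        """Heterochiral-minus-homochiral lifetime differences and quadrature
        errors reproduce the published values at printed precision."""
        diff, err = complexation.lifetime_difference(hetero, homo)
        assert round_printed(diff, 2) == expected[0]
        assert round_printed(err, 2) == expected[1]

    def test_zero_errors_propagate_to_zero(self):
        assert complexation.lifetime_difference((5.0, 0.0), (5.0, 0.0)) == (0.0, 0.0)

    def test_negative_errors_rejected(self):
        with pytest.raises(ValueError):
            complexation.lifetime_difference((1.0, -0.1), (1.0, 0.1))


class TestCensus:
    def test_tracer_with_two_partners_counts_once_as_1_2(self):
        """A tracer inside the cutoff of two CRAs is in a single 1:2 state,
        not two 1:1 states."""
        frames = np.zeros((5, 4, 3))
        frames[:, 0] = [5.0, 5.0, 5.0]
        frames[:, 1] = [4.75, 5.0, 5.0]
        frames[:, 2] = [5.3, 5.0, 5.0]
        frames[:, 3] = [5.0, 5.3, 5.0]
        traj = make_trajectory(frames, box=10.0, wrapped=True)
        smap = make_species_map(
            [
                (0, 0, "MA", "R", "heavy"),
                (1, 0, "MA", "R", "chiral_H"),
                (2, 1, "CRA", "R", "heavy"),
                (3, 2, "CRA", "R", "heavy"),
            ]
        )
        census = complexation.stoichiometry_census(traj, smap, r_on=4.0, r_off=5.0)
        by_state = census.set_index("state")["frames"]
        assert by_state["1:2"] == 5
        assert by_state["1:1"] == 0

    def test_states_partition_all_frames(self, bias_run):
        spec, traj, smap, _ = bias_run
        census = complexation.stoichiometry_census(
            traj, smap, r_on=spec.capture_radius * 10, r_off=spec.capture_radius * 10
        )
        per_chir = census.groupby("tracer_chirality")["frames"].sum()
        n_tracers_per_chir = 5
        assert (per_chir == traj.n_frames * n_tracers_per_chir).all()

    def test_one_to_one_dominates_at_low_density(self, bias_run):
        """At dilute CRA occupancy the census falls off monotonically with
        stoichiometry."""
        spec, traj, smap, _ = bias_run
        census = complexation.stoichiometry_census(
            traj, smap, r_on=spec.capture_radius * 10, r_off=spec.capture_radius * 10
        )
        totals = census.groupby("state")["frames"].sum()
        assert totals["1:1"] > totals["1:2"] >= totals["1:3"]


class TestExcess:
    def test_symmetric_kinetics_show_no_significant_excess(self):
        """With chirality-independent dissociation rates the heterochiral
        1:1 excess is statistically indistinguishable from zero."""
        censuses = []
        for seed in range(60, 65):
            spec = synthgen.preset(
                "symmetric-kinetic", seed=seed, n_steps=1500, save_interval=3
            )
            traj, smap, _ = synthgen.simulate(spec)
            censuses.append(
                complexation.stoichiometry_census(
                    traj, smap, r_on=spec.capture_radius * 10, r_off=spec.capture_radius * 10
                )
            )
        excess, sem = complexation.excess_heterochiral(censuses)
        assert abs(excess) < 3 * sem

    def test_single_replicate_error_is_undefined(self, bias_run):
        spec, traj, smap, _ = bias_run
        census = complexation.stoichiometry_census(
            traj, smap, r_on=spec.capture_radius * 10, r_off=spec.capture_radius * 10
        )
        excess, sem = complexation.excess_heterochiral([census])
        assert np.isnan(sem)


class TestDistanceHistogram:
    def test_rigid_geometry_lands_in_left_closed_bin(self):
        """A chiral-H held at 6.25 A from the CRA centre of mass (an exactly
        representable distance) puts all mass in the [6.0, 6.5) bin
        (left-closed edges)."""
        traj = held_pair_trajectory(n_frames=8, bead_cra_nm=0.25, h_cra_nm=0.625)
        hists = complexation.chiral_distance_histogram(
            traj, pair_map(), r_on=4.0, r_off=5.0
        )
        h = hists["homochiral"]
        idx = np.digitize(6.25, h.bin_edges) - 1
        assert h.bin_edges[idx] == pytest.approx(6.0)
        assert h.bin_edges[idx + 1] == pytest.approx(6.5)
        assert h.mean_frequency[idx] == 8
        assert h.total_mass == 8

    def test_total_mass_counts_observations(self, bias_run):
        spec, traj, smap, _ = bias_run
        r = spec.capture_radius * 10
        hists = complexation.chiral_distance_histogram(
            traj, smap, r_on=r, r_off=r, distance_range=(0.0, 20.0)
        )
        state, _, _ = bound_state_matrix(traj, smap, r, r)
        n_one_to_one = int((state.sum(axis=2) == 1).sum())
        assert sum(h.total_mass for h in hists.values()) == n_one_to_one

    def test_no_complexes_raises(self):
        traj = held_pair_trajectory(bead_cra_nm=2.0, h_cra_nm=2.2)
        with pytest.raises(ValueError, match="no 1:1"):
            complexation.chiral_distance_histogram(traj, pair_map(), r_on=4.0, r_off=5.0)


class TestSelectFrames:
    def test_full_window_selects_all_one_to_one_frames(self, bias_run):
        spec, traj, smap, _ = bias_run
        r = spec.capture_radius * 10
        sel = complexation.select_frames(traj, smap, d_min=0.0, d_max=50.0, r_on=r, r_off=r)
        hists = complexation.chiral_distance_histogram(
            traj, smap, r_on=r, r_off=r, distance_range=(0.0, 50.0)
        )
        assert len(sel) == sum(h.total_mass for h in hists.values())

    def test_window_fraction_matches_histogram_mass(self, bias_run):
        """The selected fraction in a distance window equals the histogram
        mass inside that window (internal consistency)."""
        spec, traj, smap, _ = bias_run
        r = spec.capture_radius * 10
        lo, hi = 2.5, 5.0
        sel = complexation.select_frames(traj, smap, d_min=lo, d_max=hi, r_on=r, r_off=r)
        hists = complexation.chiral_distance_histogram(
            traj, smap, r_on=r, r_off=r, bin_width=0.5, distance_range=(0.0, 50.0)
        )
        mass = 0.0
        for h in hists.values():
            centers = (h.bin_edges[:-1] + h.bin_edges[1:]) / 2
            mass += h.mean_frequency[(centers > lo) & (centers < hi)].sum()
        # bin-edge effects allow off-by-a-few; windows align to bin edges here
        assert len(sel) == pytest.approx(mass, abs=2)

    def test_disjoint_window_is_empty(self, bias_run):
        spec, traj, smap, _ = bias_run
        r = spec.capture_radius * 10
        sel = complexation.select_frames(traj, smap, d_min=40.0, d_max=45.0, r_on=r, r_off=r)
        assert len(sel) == 0

    def test_export_multi_model_pdb(self, tmp_path, bias_run):
        spec, traj, smap, _ = bias_run
        r = spec.capture_radius * 10
        sel = complexation.select_frames(traj, smap, d_min=0.0, d_max=50.0, r_on=r, r_off=r)
        out = tmp_path / "selected.pdb"
        complexation.write_selected_frames(traj, sel.head(20), out)
        text = out.read_text()
        assert text.count("MODEL") == len(sel.head(20)["frame"].unique())
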