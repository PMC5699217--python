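"""Surface distances, dwell fractions, and ensemble summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import chelax as cx
from chelax.analysis import IonSurfaceSeries, surface_distances


def brute_force_surface_distance(ion, coords, radii, box=None):
    """Independent oracle: exhaustive double loop with explicit wrapping."""
    best = math.inf
    for atom, radius in zip(coords, radii):
        acc = 0.0
        for k in range(3):
            d = ion[k] - atom[k]
            if box is not None:
                d -= box[k] * round(d / box[k])
            acc += d * d
        best = min(best, math.sqrt(acc) - radius)
    return best


class TestIonSurfaceDistance:
    def test_single_atom(self, one_atom_structure):
        d = cx.ion_surface_distance([5.0, 0.0, 0.0], one_atom_structure)
        assert d == pytest.approx(3.5)

    def test_on_surface_is_zero(self, one_atom_structure):
        d = cx.ion_surface_distance([0.0, 1.5, 0.0], one_atom_structure)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_overlap_is_negative(self, one_atom_structure):
        assert cx.ion_surface_distance([0.5, 0.0, 0.0], one_atom_structure) < 0

    def test_periodic_image_is_nearer(self, one_atom_structure):
        s = one_atom_structure.translated([1.0, 10.0, 10.0])
        # ion near the far face is close to the atom through the boundary
        d = cx.ion_surface_distance([19.0, 10.0, 10.0], s, box=[20.0] * 3)
        assert d == pytest.approx(2.0 - 1.5)

    @pytest.mark.parametrize("use_box", [False, True])
    def test_matches_brute_force_oracle(self, use_box):
        rng = np.random.default_rng(123 + use_box)
        for _ in range(30):
            n_atoms = rng.integers(1, 50)
            box = rng.uniform(15.0, 40.0, 3) if use_box else None
            s = cx.Structure(
                elements=["C"] * n_atoms,
                coords=rng.uniform(0, 15.0, (n_atoms, 3)),
                radii=rng.uniform(1.0, 2.5, n_atoms),
                charges=np.zeros(n_atoms),
            )
            ions = rng.uniform(-5.0, 20.0, (5, 3))
            got = surface_distances(ions, s, box)
            for i, ion in enumerate(ions):
                want = brute_force_surface_distance(ion, s.coords, s.radii, box)
                assert got[i] == pytest.approx(want, abs=1e-9)


class TestDistanceSeries:
    def test_series_from_frames(self, one_atom_structure):
        frames = np.array(
            [[[5.0, 0, 0]], [[3.0, 0, 0]], [[10.0, 0, 0]]]
        )
        traj = cx.Trajectory(
            species=["Ca"], frames=frames, box=np.array([50.0] * 3),
            times=np.arange(3.0),
        )
        series = cx.distance_series(traj, one_atom_structure)
        np.testing.assert_allclose(series.distances[0], [3.5, 1.5, 8.5])

    def test_missing_species_names_available(self, one_atom_structure):
        traj = cx.Trajectory(
            species=["Na"], frames=np.zeros((2, 1, 3)), box=np.array([50.0] * 3),
            times=np.arange(2.0),
        )
        with pytest.raises(ValueError, match="Na"):
            cx.distance_series(traj, one_atom_structure, "Ca")

    def test_species_filter_bookkeeping(self, one_atom_structure):
        rng = np.random.default_rng(0)
        labels = ["Ca"] * 3 + ["Na"] * 5
        traj = cx.Trajectory(
            species=labels, frames=rng.uniform(0, 50, (4, 8, 3)),
            box=np.array([50.0] * 3), times=np.arange(4.0),
        )
        series = cx.distance_series(traj, one_atom_structure, "Na")
        assert series.n_ions == 5
        assert set(series.species) == {"Na"}


class TestDwellFraction:
    def test_inclusive_boundary(self):
        assert cx.dwell_fraction([2.0, 4.0, 2.5, 3.0, 10.0], 3.0) == pytest.approx(0.6)

    def test_all_bound(self):
        assert cx.dwell_fraction([1.0, 2.0, 0.5], 3.0) == 1.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            cx.dwell_fraction([], 3.0)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            cx.dwell_fraction([1.0], 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        series=hnp.arrays(
            float, st.integers(min_value=1, max_value=30),
            elements=st.floats(min_value=-1.0, max_value=20.0),
        ),
        t1=st.floats(min_value=0.1, max_value=10.0),
        t2=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_monotone_in_threshold(self, series, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        assert cx.dwell_fraction(series, lo) <= cx.dwell_fraction(series, hi)


class TestSummarize:
    def _run(self, per_ion_rows, run_id="r"):
        return IonSurfaceSeries(
            distances=np.array(per_ion_rows, dtype=float),
            species=["Ca"] * len(per_ion_rows),
            run_id=run_id,
        )

    def test_identical_ions_have_zero_spread(self):
        run = self._run([[1.0, 3.0], [1.0, 3.0]])
        stats = cx.summarize(run).species["Ca"]
        assert stats.avg_distance == pytest.approx(2.0)
        assert stats.sd_distance == 0.0
        assert stats.avg_min_distance == pytest.approx(1.0)

    def test_pooled_vs_per_run_hand_fixture(self):
        """Per-ion means {2, 4} in run 1 and {6, 8} in run 2: pooled SD is
        the population SD of {2,4,6,8} = sqrt(5); per-run SD is the
        population SD of the run means {3, 7} = 2."""
        runs = [
            self._run([[2.0, 2.0], [4.0, 4.0]], "a"),
            self._run([[6.0, 6.0], [8.0, 8.0]], "b"),
        ]
        pooled = cx.summarize(runs, mode="pooled").species["Ca"]
        assert pooled.avg_distance == pytest.approx(5.0)
        assert pooled.sd_distance == pytest.approx(math.sqrt(5.0))
        per_run = cx.summarize(runs, mode="per_run").species["Ca"]
        assert per_run.avg_distance == pytest.approx(5.0)
        assert per_run.sd_distance == pytest.approx(2.0)

    def test_min_never_exceeds_mean(self):
        rng = np.random.default_rng(5)
        run = self._run(rng.uniform(0, 20, (6, 40)))
        stats = cx.summarize(run).species["Ca"]
        assert stats.avg_min_distance <= stats.avg_distance

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            cx.summarize(self._run([[1.0]]), mode="median")

    def test_ragged_series_rejected(self):
        with pytest.raises(ValueError):
            IonSurfaceSeries(
                distances=np.array([[1.0, 2.0], [3.0]], dtype=object),
                species=["Ca", "Ca"],
            )

    def test_dwell_rises_with_attraction(self, one_atom_structure):
        """Mean dwell fraction is non-decreasing in the well depth."""
        from chelax.builder import IonSet

        s = one_atom_structure.translated([15.0] * 3)
        means = []
        for depth in (0.0, 6.0):
            well = cx.BindingWell(site_index=0, radius=4.5, depth=depth)
            rng = np.random.default_rng(2)
            ions = IonSet(
                labels=["Ca"] * 4, positions=rng.uniform(0, 30, (4, 3)),
                charges=np.zeros(4), diffusion=np.full(4, 1.0),
            )
            traj = cx.simulate(
                s, ions,
                cx.BDParams(
                    box_edges=[30.0] * 3, n_steps=20_000, timestep=0.02,
                    save_interval=10, lj_epsilon=0.0, binding_well=well, seed=8,
                ),
            )
            stats = cx.summarize(cx.distance_series(traj, s))
            means.append(stats.species["Ca"].avg_dwell_fraction)
        assert means[1] > means[0]
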