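"""Radial distribution functions: normalisation, averaging, convergence."""

import numpy as np
import pytest

import chelax as cx


def _static_trajectory(positions, box, n_frames, species=None):
    pos = np.asarray(positions, dtype=float)
    return cx.Trajectory(
        species=species or ["Ca"] * pos.shape[0],
        frames=np.repeat(pos[None, :, :], n_frames, axis=0),
        box=np.asarray(box, dtype=float),
        times=np.arange(float(n_frames)),
    )


@pytest.fixture
def point_reference():
    return cx.Structure(
        elements=["X"], coords=[[20.0] * 3], radii=[1.0], charges=[0.0]
    )


class TestComputeRdf:
    def test_frozen_ion_hand_normalisation(self, point_reference):
        """One ion fixed at distance d for 100 frames: all counts fall in
        d's bin and g equals counts * V / (frames * ions * shell volume)."""
        d, bin_width, L = 7.3, 0.5, 40.0
        traj = _static_trajectory([[20.0 + d, 20.0, 20.0]], [L] * 3, 100)
        result = cx.compute_rdf(
            traj, point_reference, "Ca", bin_width=bin_width, r_max=15.0
        )
        idx = int(d / bin_width)
        assert result.counts[idx] == 100
        assert result.counts.sum() == 100
        r_c = result.bin_centers[idx]
        expected = (100 * L**3) / (100 * 1 * 4 * np.pi * r_c**2 * bin_width)
        assert result.g[idx] == pytest.approx(expected)

    def test_empty_species_selection(self, point_reference):
        traj = _static_trajectory([[1.0, 1.0, 1.0]], [40.0] * 3, 3)
        with pytest.raises(ValueError, match="available"):
            cx.compute_rdf(traj, point_reference, "Na")

    def test_r_max_beyond_half_box_rejected(self, point_reference):
        traj = _static_trajectory([[1.0, 1.0, 1.0]], [40.0] * 3, 3)
        with pytest.raises(ValueError, match="half"):
            cx.compute_rdf(traj, point_reference, "Ca", r_max=25.0)

    def test_reference_modes_differ_for_offset_solute(self):
        s = cx.Structure(
            elements=["X", "X"],
            coords=[[15.0, 20.0, 20.0], [25.0, 20.0, 20.0]],
            radii=[1.0, 1.0],
            charges=[0.0, 0.0],
        )
        traj = _static_trajectory([[28.0, 20.0, 20.0]], [40.0] * 3, 10)
        com = cx.compute_rdf(traj, s, "Ca", bin_width=0.5, r_max=15.0)
        near = cx.compute_rdf(
            traj, s, "Ca", bin_width=0.5, r_max=15.0, reference="nearest-atom"
        )
        assert com.counts[int(8.0 / 0.5)] == 10  # 8 A from the centroid
        assert near.counts[int(3.0 / 0.5)] == 10  # 3 A from the nearer atom
        assert com.reference == "com" and near.reference == "nearest-atom"


class TestAverageRdf:
    def _result(self, g, n_frames=10):
        edges = np.arange(0.0, 5.5, 0.5)
        g_arr = np.full(len(edges) - 1, float(g))
        return cx.RDFResult(
            bin_edges=edges, g=g_arr, counts=np.ones(len(edges) - 1, dtype=int),
            reference="com", n_frames=n_frames, species=("Ca",),
        )

    def test_idempotent_on_identical_inputs(self):
        avg = cx.average_rdf([self._result(1.5), self._result(1.5)])
        np.testing.assert_allclose(avg.g, 1.5)
        assert avg.n_frames == 20

    def test_arithmetic_mean(self):
        avg = cx.average_rdf([self._result(0.0), self._result(2.0)])
        np.testing.assert_allclose(avg.g, 1.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        results = [self._result(g) for g in rng.uniform(0, 3, 4)]
        a = cx.average_rdf(results)
        b = cx.average_rdf(results[::-1])
        np.testing.assert_allclose(a.g, b.g)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_mismatched_bins_rejected(self):
        other = cx.RDFResult(
            bin_edges=np.arange(0.0, 5.25, 0.25),
            g=np.ones(20), counts=np.ones(20, dtype=int),
            reference="com", n_frames=10, species=("Ca",),
        )
        with pytest.raises(ValueError):
            cx.average_rdf([self._result(1.0), other])

    def test_replicate_average_reduces_variance(self, point_reference):
        """Averaging three seeded replicates lowers the per-bin scatter of
        g around its flat ideal value."""
        from chelax.builder import IonSet

        runs = []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(100 + seed)
            ions = IonSet(
                labels=["Na"] * 64, positions=rng.uniform(0, 40, (64, 3)),
                charges=np.zeros(64), diffusion=np.full(64, 1.0),
            )
            traj = cx.simulate(
                point_reference, ions,
                cx.BDParams(
                    box_edges=[40.0] * 3, n_steps=12_000, timestep=0.02,
                    save_interval=8, lj_epsilon=0.0, seed=seed,
                ),
            )
            runs.append(
                cx.compute_rdf(traj, point_reference, "Na", bin_width=0.5, r_max=18.0)
            )
        avg = cx.average_rdf(runs)
        sel = avg.bin_centers >= 6.0
        # the replicate average deviates from the flat ideal value by less
        # than the typical (mean) single-run deviation
        single_dev = np.mean([np.abs(r.g[sel] - 1.0).mean() for r in runs])
        assert np.abs(avg.g[sel] - 1.0).mean() < single_dev


class TestWindowConvergence:
    def test_identical_windows_have_zero_divergence(self, point_reference):
        traj = _static_trajectory([[26.0, 20.0, 20.0]], [40.0] * 3, 30)
        res = cx.window_convergence(
            traj, point_reference, "Ca",
            windows=[(0, 30), (0, 30)], bin_width=0.5, r_max=15.0,
        )
        assert res.divergences == [0.0, 0.0]
        assert res.converged

    def test_outward_drift_detected(self, point_reference):
        """Ions drifting radially outward give window-dependent RDFs."""
        n_frames, n_ions = 300, 4
        frames = np.empty((n_frames, n_ions, 3))
        for f in range(n_frames):
            r = 4.0 + 8.0 * f / n_frames  # 4 A -> 12 A
            for i in range(n_ions):
                angle = 2 * np.pi * i / n_ions
                frames[f, i] = [
                    20.0 + r * np.cos(angle), 20.0 + r * np.sin(angle), 20.0,
                ]
        traj = cx.Trajectory(
            species=["Ca"] * n_ions, frames=frames, box=np.array([40.0] * 3),
            times=np.arange(float(n_frames)),
        )
        res = cx.window_convergence(
            traj, point_reference, "Ca", bin_width=0.5, r_max=15.0
        )
        assert not res.converged
        assert res.divergences[-2] > res.tolerance

    def test_window_outside_trajectory_rejected(self, point_reference):
        traj = _static_trajectory([[26.0, 20.0, 20.0]], [40.0] * 3, 10)
        with pytest.raises(ValueError, match="outside"):
            cx.window_convergence(
                traj, point_reference, "Ca", windows=[(0, 5), (0, 20)],
                bin_width=0.5, r_max=15.0,
            )
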