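import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shoalnoise import (
    centroid_distance,
    compute_kinematics,
    heading_difference_summary,
    modal_nnd,
    nearest_neighbour_geometry,
    relative_position_map,
)

from conftest import make_dataset


def moving_dataset(offsets, heading_deg=90.0, T=30, speed=1.0):
    """Fish at fixed relative offsets, all translating along a common heading.

    ``heading_deg`` measured counter-clockwise from +x (90 = +y).
    """
    offsets = np.asarray(offsets, dtype=float)
    h = np.array([np.cos(np.radians(heading_deg)), np.sin(np.radians(heading_deg))])
    base = np.arange(T)[:, None] * h[None, :] * speed
    pos = base[:, None, :] + offsets[None, :, :]
    pos = pos - pos.mean(axis=(0, 1))
    return make_dataset(pos)


class TestCentroidDistance:
    def test_unit_square_symmetry(self):
        ds = moving_dataset([[0, 0], [1, 0], [1, 1], [0, 1]])
        _, means, n_skip = centroid_distance(ds)
        np.testing.assert_allclose(means, np.sqrt(2) / 2, atol=1e-12)
        assert n_skip == 0

    def test_coincident_fish_zero(self):
        ds = moving_dataset([[0, 0], [0, 0], [0, 0], [0, 0]])
        _, means, _ = centroid_distance(ds)
        np.testing.assert_allclose(means, 0.0, atol=1e-12)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(-30, 30, (40, 4, 2))
        ds = make_dataset(pos)
        dist, means, _ = centroid_distance(ds)
        for t in range(40):
            c = pos[t].mean(axis=0)
            for j in range(4):
                assert dist[t, j] == pytest.approx(
                    np.linalg.norm(pos[t, j] - c), abs=1e-12
                )

    def test_sparse_frames_skipped(self):
        pos = np.full((10, 3, 2), np.nan)
        pos[:, 0] = 0.0
        pos[:5, 1, 0] = 1.0
        pos[:5, 1, 1] = 0.0
        ds = make_dataset(pos)
        _, _, n_skip = centroid_distance(ds)
        assert n_skip == 5


class TestNearestNeighbourGeometry:
    def geometry(self, offsets, heading_deg=90.0):
        ds = moving_dataset(offsets, heading_deg=heading_deg)
        ks = compute_kinematics(ds, smoothing_window=1)
        return ds, ks, nearest_neighbour_geometry(ds, ks)

    def test_neighbour_dead_ahead(self):
        # focal fish moving along +y, neighbour 5 cm ahead
        _, _, pgs = self.geometry([[0, 0], [0, 5]])
        pg = pgs[0]
        t = 10
        assert pg.bearing[t] == pytest.approx(0.0, abs=1e-9)
        assert pg.side[t] == "front"
        assert pg.perp_offset[t] == pytest.approx(0.0, abs=1e-9)
        assert pg.para_offset[t] == pytest.approx(5.0)

    def test_neighbour_directly_beside(self):
        _, _, pgs = self.geometry([[0, 0], [3, 0]])
        pg = pgs[0]
        t = 10
        assert pg.bearing[t] == pytest.approx(90.0)
        assert pg.side[t] == "behind"  # boundary convention: front is < 90
        assert pg.perp_offset[t] == pytest.approx(3.0)
        assert pg.para_offset[t] == pytest.approx(0.0, abs=1e-9)

    def test_bearing_43_degrees(self):
        # neighbour placed where shoals most often keep them: 43 deg off the
        # travel axis, here at 5 cm range ahead-right of the focal fish
        off = 5.0 * np.array([np.sin(np.radians(43.0)), np.cos(np.radians(43.0))])
        _, _, pgs = self.geometry([[0, 0], off.tolist()])
        assert pgs[0].bearing[10] == pytest.approx(43.0, abs=1e-9)
        assert pgs[0].side[10] == "front"

    def test_nearest_tie_lower_id(self):
        _, _, pgs = self.geometry([[0, 0], [2, 0], [-2, 0]])
        assert pgs[0].neighbour_id[10] == 1

    def test_pythagoras_every_frame(self):
        rng = np.random.default_rng(8)
        pos = np.cumsum(rng.normal(0, 0.6, (50, 4, 2)), axis=0)
        ds = make_dataset(pos)
        ks = compute_kinematics(ds, smoothing_window=1)
        for pg in nearest_neighbour_geometry(ds, ks):
            ok = np.isfinite(pg.bearing)
            lhs = pg.perp_offset[ok] ** 2 + pg.para_offset[ok] ** 2
            np.testing.assert_allclose(lhs, pg.nnd[ok] ** 2, atol=1e-6)

    def test_heading_diff_symmetric_under_swap(self):
        rng = np.random.default_rng(9)
        pos = np.cumsum(rng.normal(0, 0.6, (50, 2, 2)), axis=0)
        ds = make_dataset(pos)
        ks = compute_kinematics(ds, smoothing_window=1)
        pgs = nearest_neighbour_geometry(ds, ks)
        both = np.isfinite(pgs[0].heading_diff) & np.isfinite(pgs[1].heading_diff)
        np.testing.assert_allclose(
            pgs[0].heading_diff[both], pgs[1].heading_diff[both], atol=1e-9
        )
        np.testing.assert_allclose(pgs[0].nnd, pgs[1].nnd, atol=1e-12)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(theta=st.floats(0, 2 * np.pi),
           shift=st.tuples(st.floats(-15, 15), st.floats(-15, 15)))
    def test_rigid_motion_invariance(self, theta, shift):
        """All pairwise measures are invariant under global rigid motions."""
        rng = np.random.default_rng(11)
        pos = np.cumsum(rng.normal(0, 0.7, (40, 4, 2)), axis=0)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        ds = make_dataset(pos)
        ds_rot = make_dataset(pos @ R.T + np.asarray(shift))
        ks = compute_kinematics(ds, smoothing_window=1)
        ks_rot = compute_kinematics(ds_rot, smoothing_window=1)
        for pg, pgr in zip(
            nearest_neighbour_geometry(ds, ks),
            nearest_neighbour_geometry(ds_rot, ks_rot),
        ):
            np.testing.assert_allclose(pgr.nnd, pg.nnd, atol=1e-9)
            ok = np.isfinite(pg.bearing)
            np.testing.assert_allclose(pgr.bearing[ok], pg.bearing[ok], atol=1e-9)
            np.testing.assert_allclose(pgr.perp_offset[ok], pg.perp_offset[ok], atol=1e-9)
            np.testing.assert_allclose(pgr.para_offset[ok], pg.para_offset[ok], atol=1e-9)
            both = np.isfinite(pg.heading_diff)
            np.testing.assert_allclose(
                pgr.heading_diff[both], pg.heading_diff[both], atol=1e-9
            )


class TestModalNND:
    def test_constant_series(self):
        x = np.full(100, 5.0)
        assert abs(modal_nnd(x, bin_width=0.5) - 5.0) <= 0.25

    def test_dominant_mode(self):
        x = np.concatenate([np.full(60, 2.0), np.full(18, 8.0)])
        assert modal_nnd(x, bin_width=1.0, min_frames=50) == pytest.approx(2.5)

    def test_tie_goes_to_smaller_distance(self):
        x = np.concatenate([np.full(30, 2.2), np.full(30, 8.2)])
        assert modal_nnd(x, bin_width=1.0, min_frames=50) == pytest.approx(2.5)

    def test_large_sample_mixture_mode(self):
        # histogram oracle: dominant mixture mode recovered within one bin
        rng = np.random.default_rng(17)
        x = np.concatenate([
            rng.normal(4.0, 0.6, 70_000),
            rng.normal(9.0, 1.2, 30_000),
        ])
        x = np.abs(x)
        assert abs(modal_nnd(x, bin_width=0.5) - 4.0) <= 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            modal_nnd(np.array([]), bin_width=0.5)


class TestHeadingDifference:
    def test_parallel_and_antiparallel(self):
        ds = moving_dataset([[0, 0], [3, 0]])
        ks = compute_kinematics(ds, smoothing_window=1)
        pg = nearest_neighbour_geometry(ds, ks)[0]
        assert heading_difference_summary(pg) == pytest.approx(0.0, abs=1e-9)
        # antiparallel: two fish passing each other on straight tracks
        T = 30
        pos = np.zeros((T, 2, 2))
        pos[:, 0, 0] = np.arange(T) - T / 2
        pos[:, 0, 1] = 0.0
        pos[:, 1, 0] = T / 2 - np.arange(T, dtype=float)
        pos[:, 1, 1] = 1.0
        ds2 = make_dataset(pos)
        ks2 = compute_kinematics(ds2, smoothing_window=1)
        pg2 = nearest_neighbour_geometry(ds2, ks2)[0]
        assert heading_difference_summary(pg2) == pytest.approx(180.0, abs=1e-9)

    def test_independent_headings_mean_90(self):
        # Monte-Carlo oracle: unsigned angle between two independent uniform
        # headings has mean 90 deg; tolerance 3 standard errors
        rng = np.random.default_rng(23)
        n = 4000
        # two fish on random-walk headings far apart -> independent directions
        th1 = rng.uniform(0, 2 * np.pi, n)
        th2 = rng.uniform(0, 2 * np.pi, n)
        diff = np.degrees(np.arccos(np.cos(th1 - th2)))
        se = diff.std() / np.sqrt(n)
        assert abs(diff.mean() - 90.0) < 3 * se + 1e-9


class TestRelativePositionMap:
    def make_pgs(self, ds):
        ks = compute_kinematics(ds, smoothing_window=1)
        return nearest_neighbour_geometry(ds, ks)

    def test_all_mass_dead_ahead(self):
        ds = moving_dataset([[0, 0], [0, 5.5]])
        rp = relative_position_map(self.make_pgs(ds)[:1], bin_size=1.0, sigma=0)
        iy, ix = np.unravel_index(np.argmax(rp.grid), rp.grid.shape)
        assert abs(rp.edges[iy] + 0.5 - 5.5) <= 0.5   # ahead ~ +5.5 cm
        assert abs(rp.edges[ix] + 0.5) <= 0.5          # right ~ 0 cm
        assert rp.grid.max() == pytest.approx(1.0)     # single occupied cell
        assert rp.grid.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mirror_symmetric_input(self):
        # fish 1 and 2 sit at mirrored offsets around fish 0; their maps
        # (both pointing at fish 0) are mirror images about the travel axis
        ds = moving_dataset([[0, 0], [2.5, 1.25], [-2.5, 1.25]])
        pgs = self.make_pgs(ds)
        rp = relative_position_map(pgs[1:3], bin_size=1.0, sigma=0)
        np.testing.assert_allclose(rp.grid, rp.grid[:, ::-1], atol=1e-12)

    def test_smoothing_conserves_mass(self):
        rng = np.random.default_rng(29)
        pos = np.cumsum(rng.normal(0, 0.7, (200, 4, 2)), axis=0)
        ds = make_dataset(pos)
        rp0 = relative_position_map(self.make_pgs(ds), sigma=0)
        rp6 = relative_position_map(self.make_pgs(ds), sigma=6.0)
        assert rp0.grid.sum() == pytest.approx(1.0, abs=1e-9)
        assert rp6.grid.sum() == pytest.approx(1.0, abs=1e-9)
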