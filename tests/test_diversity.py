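"""FDis/FRic metrics against analytic and Monte-Carlo hull oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull

from traitdiv import (
    Community,
    ExtirpationRecord,
    extinction_impact,
    fd_table,
    functional_dispersion,
    functional_richness,
    species_pool_richness,
    unweighted_dispersion_variants,
    weighted_dispersion,
)
from traitdiv.ordination import OrdinationSpace


def space_from_points(points: np.ndarray, m_fric: int | None = None) -> OrdinationSpace:
    """Wrap explicit coordinates as an ordination space for metric tests."""
    points = np.atleast_2d(np.asarray(points, float))
    coords = pd.DataFrame(
        points,
        index=[f"s{i}" for i in range(len(points))],
        columns=[f"axis_{j + 1}" for j in range(points.shape[1])],
    )
    return OrdinationSpace(
        coordinates=coords,
        eigenvalues=np.ones(points.shape[1]),
        correction="none",
        m_fric=m_fric or points.shape[1],
    )


def hit_or_miss_volume(points: np.ndarray, n_samples: int, rng) -> float:
    """Rejection-sampling estimate of a convex hull volume (independent oracle)."""
    hull = ConvexHull(points)
    lo, hi = points.min(axis=0), points.max(axis=0)
    box = np.prod(hi - lo)
    draws = rng.uniform(lo, hi, size=(n_samples, points.shape[1]))
    # inside iff all hull facet inequalities A x + b <= 0 hold
    inside = (draws @ hull.equations[:, :-1].T + hull.equations[:, -1] <= 1e-12).all(axis=1)
    return box * inside.mean()


class TestDispersion:
    def test_single_species_is_zero_with_warning(self):
        sp = space_from_points([[1.0, 2.0]])
        comm = Community("s", ["s0"], pd.Series({"s0": 1.0}))
        with pytest.warns(UserWarning, match="single-member"):
            assert functional_dispersion(sp, comm) == 0.0

    def test_symmetric_pair_equal_weights(self):
        sp = space_from_points([[-1.0], [1.0]])
        comm = Community("s", ["s0", "s1"], pd.Series({"s0": 0.5, "s1": 0.5}))
        assert functional_dispersion(sp, comm) == pytest.approx(1.0)

    def test_occupancy_weighted_worked_example(self):
        # a = (0.9, 0.1) at coordinates (-1, +1): centroid -0.8,
        # FDis = 0.9*0.2 + 0.1*1.8 = 0.36
        sp = space_from_points([[-1.0], [1.0]])
        comm = Community("s", ["s0", "s1"], pd.Series({"s0": 0.9, "s1": 0.1}))
        assert functional_dispersion(sp, comm, use_weights=True) == pytest.approx(0.36)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_centroid_computation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        coords = rng.normal(size=(n, 3))
        w = rng.uniform(0.05, 1.0, n)
        centroid = (w[:, None] * coords).sum(axis=0) / w.sum()
        expected = float(
            (w * np.sqrt(((coords - centroid) ** 2).sum(axis=1))).sum() / w.sum()
        )
        assert weighted_dispersion(coords, w) == pytest.approx(expected, abs=1e-10)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(7, 3))
        w = rng.uniform(0.1, 1.0, 7)
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = coords @ rot.T + np.array([3.0, -2.0, 0.5])
        assert weighted_dispersion(moved, w) == pytest.approx(
            weighted_dispersion(coords, w), abs=1e-10
        )

    def test_weights_are_relative(self, rng):
        coords = rng.normal(size=(6, 2))
        w = rng.uniform(0.1, 1.0, 6)
        assert weighted_dispersion(coords, 7.3 * w) == pytest.approx(
            weighted_dispersion(coords, w), abs=1e-12
        )

    def test_uniform_occupancy_equals_unweighted(self):
        sp = space_from_points(np.random.default_rng(1).normal(size=(5, 2)))
        members = [f"s{i}" for i in range(5)]
        comm = Community("s", members, pd.Series(0.7, index=members))
        assert functional_dispersion(sp, comm, use_weights=True) == pytest.approx(
            functional_dispersion(sp, comm, use_weights=False)
        )


class TestRichness:
    def test_triangle_area(self):
        sp = space_from_points([[0, 0], [1, 0], [0, 1]], m_fric=2)
        assert functional_richness(sp, ["s0", "s1", "s2"]) == pytest.approx(0.5)

    def test_unit_tetrahedron_volume(self):
        sp = space_from_points(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], m_fric=3
        )
        assert functional_richness(sp, ["s0", "s1", "s2", "s3"]) == pytest.approx(1 / 6)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_rejection_sampling_estimate(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 2))
        sp = space_from_points(pts, m_fric=2)
        vol = functional_richness(sp, [f"s{i}" for i in range(8)])
        mc = hit_or_miss_volume(pts, 200_000, rng)
        assert vol == pytest.approx(mc, rel=0.01)

    def test_too_few_species_error_instructs_lower_m(self):
        sp = space_from_points([[0, 0, 0], [1, 0, 0], [0, 1, 0]], m_fric=3)
        with pytest.raises(ValueError, match="lower m"):
            functional_richness(sp, ["s0", "s1", "s2"])

    def test_coplanar_points_report_zero_with_warning(self):
        pts = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
        sp = space_from_points(pts, m_fric=3)
        with pytest.warns(UserWarning, match="degenerate"):
            assert functional_richness(sp, ["s0", "s1", "s2", "s3"]) == 0.0

    def test_duplicate_coordinates_deduplicated(self):
        sp = space_from_points([[0, 0], [1, 0], [0, 1], [0, 1]], m_fric=2)
        assert functional_richness(sp, ["s0", "s1", "s2", "s3"]) == pytest.approx(0.5)

    def test_hull_monotone_under_species_addition(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            pts = rng.normal(size=(9, 3))
            sp = space_from_points(pts, m_fric=3)
            all_ids = [f"s{i}" for i in range(9)]
            sub = all_ids[:5]
            assert functional_richness(sp, all_ids) >= functional_richness(sp, sub) - 1e-12

    def test_pool_richness_same_function_and_monotone(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        sp = space_from_points(pts, m_fric=2)
        ids = [f"s{i}" for i in range(10)]
        assert species_pool_richness(sp, ids[:6]) == functional_richness(sp, ids[:6])
        assert species_pool_richness(sp, ids) >= functional_richness(sp, ids[:6])

    def test_outside_point_strictly_increases_hull(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [5.0, 5.0]])
        sp = space_from_points(pts, m_fric=2)
        assert functional_richness(sp, ["s0", "s1", "s2", "s3"]) > functional_richness(
            sp, ["s0", "s1", "s2"]
        )


class TestExtinctionImpact:
    def test_interior_extirpation_has_no_impact(self):
        pts = [[0, 0], [4, 0], [0, 4], [4, 4], [2.0, 2.0]]
        sp = space_from_points(pts, m_fric=2)
        comm = Community("k", ["s0", "s1", "s2", "s3"], pd.Series(0.5, index=["s0", "s1", "s2", "s3"]))
        delta, pct = extinction_impact(sp, comm, ExtirpationRecord("k", ["s4"]))
        assert delta == 0.0 and pct == 0.0

    def test_square_losing_one_corner(self):
        pts = [[0, 0], [1, 0], [0, 1], [1, 1]]
        sp = space_from_points(pts, m_fric=2)
        comm = Community("k", ["s0", "s1", "s2"], pd.Series(0.5, index=["s0", "s1", "s2"]))
        delta, pct = extinction_impact(sp, comm, ExtirpationRecord("k", ["s3"]))
        assert delta == pytest.approx(0.5)
        assert pct == pytest.approx(50.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_configuration_matches_hull_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        pts = rng.normal(size=(10, 2))
        sp = space_from_points(pts, m_fric=2)
        ids = [f"s{i}" for i in range(10)]
        members, lost = ids[:7], ids[7:]
        comm = Community("k", members, pd.Series(0.5, index=members))
        delta, pct = extinction_impact(sp, comm, ExtirpationRecord("k", lost))
        whole = hit_or_miss_volume(pts, 300_000, rng)
        now = hit_or_miss_volume(pts[:7], 300_000, rng)
        assert delta == pytest.approx(max(whole - now, 0.0), abs=0.02 * whole)
        assert pct == pytest.approx(100 * max(whole - now, 0) / whole, abs=2.0)

    def test_empty_extirpation_scores_zero(self, shared_space):
        members = list(shared_space.species[:5])
        comm = Community("k", members, pd.Series(0.5, index=members))
        assert extinction_impact(shared_space, comm, ExtirpationRecord("k", [])) == (0.0, 0.0)

    def test_extirpated_member_overlap_rejected(self, shared_space):
        members = list(shared_space.species[:5])
        comm = Community("k", members, pd.Series(0.5, index=members))
        with pytest.raises(ValueError, match="still listed"):
            extinction_impact(shared_space, comm, ExtirpationRecord("k", members[:1]))

    def test_site_mismatch_rejected(self, shared_space):
        members = list(shared_space.species[:5])
        comm = Community("k", members, pd.Series(0.5, index=members))
        with pytest.raises(ValueError, match="mismatch"):
            extinction_impact(shared_space, comm, ExtirpationRecord("other", []))


class TestVariantsAndTable:
    def test_pool_equals_realized_gives_equal_variants(self, shared_space):
        members = list(shared_space.species[:6])
        comm = Community("s", members, pd.Series(0.4, index=members))
        a, b = unweighted_dispersion_variants(shared_space, comm, members)
        assert a == pytest.approx(b)

    def test_outlying_pool_species_raises_pool_variant(self):
        pts = np.vstack([np.random.default_rng(0).normal(size=(6, 2)), [[40.0, 40.0]]])
        sp = space_from_points(pts, m_fric=2)
        members = [f"s{i}" for i in range(6)]
        comm = Community("s", members, pd.Series(0.4, index=members))
        a, b = unweighted_dispersion_variants(sp, comm, members + ["s6"])
        assert b > a

    def test_fd_table_columns_and_invariants(self, study):
        fd = study.fd
        expected = {
            "region",
            "fdis_weighted",
            "fdis_unweighted_realized",
            "fdis_unweighted_pool",
            "fric",
            "pool_fric",
            "fric_with_extirpated",
            "delta_fric",
            "percent_loss",
            "m_axes",
            "flags",
        }
        assert expected <= set(fd.columns)
        assert (fd["fric"] >= 0).all()
        assert (fd["pool_fric"] >= fd["fric"] - 1e-12).all()
        assert (fd["fric_with_extirpated"] >= fd["fric"] - 1e-12).all()
        assert ((fd["percent_loss"] >= 0) & (fd["percent_loss"] <= 100)).all()
        # percent loss is delta over the pre-extirpation volume
        nonzero = fd[fd["delta_fric"] > 0]
        assert np.allclose(
            nonzero["percent_loss"],
            100 * nonzero["delta_fric"] / nonzero["fric_with_extirpated"],
        )

    def test_community_occupancy_validation(self):
        with pytest.raises(ValueError, match="\\(0, 1\\]"):
            Community("s", ["a"], pd.Series({"a": 1.2}))
        with pytest.raises(ValueError, match="\\(0, 1\\]"):
            Community("s", ["a"], pd.Series({"a": 0.0}))
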