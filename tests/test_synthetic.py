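"""Synthetic-study generator: structural constraints, reproducibility,
left-skewed responses and the targeted-extirpation regime."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gamma as gamma_fn

from traitdiv import (
    build_shared_space,
    simulate_communities,
    simulate_response,
    simulate_study,
    simulate_traits,
)
from traitdiv.simulate import COMMUNITY_SIZE_RANGE, DEFAULT_TRUTH, RESPONSES
from traitdiv.traits import ACTIVITY_PERIODS, DIET_CATEGORIES


class TestTraits:
    def test_structural_constraints(self, traits80):
        df = traits80.data
        assert (df["mass"] > 1.0).all()  # terrestrial mammals above 1 kg
        assert (df[[f"diet_{c}" for c in DIET_CATEGORIES]].sum(axis=1) >= 1).all()
        assert (df[[f"activity_{p}" for p in ACTIVITY_PERIODS]].sum(axis=1) >= 1).all()
        assert (df["litter_size"] >= 1).all()

    def test_seed_reproducibility(self):
        a = simulate_traits(30, seed=3).data
        b = simulate_traits(30, seed=3).data
        pd.testing.assert_frame_equal(a, b)
        c = simulate_traits(30, seed=4).data
        assert not a.equals(c)

    def test_minimum_species_enforced(self):
        with pytest.raises(ValueError, match="at least 5"):
            simulate_traits(3)


class TestCommunities:
    def test_structure(self, study):
        sizes = []
        for comm in study.communities:
            pool = set(study.pools[comm.site_id])
            assert set(comm.members) <= pool
            a = comm.occupancy.to_numpy()
            assert ((a > 0) & (a <= 1)).all()
            sizes.append(len(comm.members))
        lo, hi = COMMUNITY_SIZE_RANGE
        assert min(sizes) >= lo and max(sizes) <= hi

    def test_extirpated_disjoint_from_members_and_in_space(self, study):
        members = {c.site_id: set(c.members) for c in study.communities}
        n_ext_sites = 0
        for e in study.extirpations:
            assert not (set(e.extirpated) & members[e.site_id])
            assert set(e.extirpated) <= set(study.space.species)
            n_ext_sites += bool(e.extirpated)
        assert n_ext_sites >= 2

    def test_too_few_sites_rejected(self, traits80):
        space = build_shared_space(traits80)
        with pytest.raises(ValueError, match="at least 2 sites"):
            simulate_communities(traits80, space, n_sites=1, seed=0)

    def test_hull_targeted_extirpations_cost_more_than_random(self, traits80):
        """Losing hull-vertex (outlying) species shrinks FRic more than
        losing random species — the top-predator-loss regime."""
        from traitdiv.diversity import fd_table

        space = build_shared_space(traits80)
        losses = {}
        for mode in ("hull", "random"):
            pct = []
            for seed in range(6):
                comms, pools, exts = simulate_communities(
                    traits80, space, n_sites=10, seed=seed, extirpation_mode=mode,
                    n_extirpation_sites=5,
                )
                fd = fd_table(space, comms, pools, exts)
                pct.extend(fd.loc[fd["delta_fric"] >= 0, "percent_loss"])
            losses[mode] = np.mean(pct)
        assert losses["hull"] > losses["random"]


class TestResponses:
    def test_mean_matches_law_of_large_numbers(self):
        # beta = 0, offsets = 0: E[y] = exp(intercept)
        design = pd.DataFrame(
            {
                "pool_fric": np.zeros(10_000),
                "habitat_H": 0.0,
                "ndvi": 0.0,
                "human_density": 0.0,
                "extinction_delta": 0.0,
                "region_Africa": 0.0,
                "region_Asia": 0.0,
                "region_Madagascar": 0.0,
            }
        )
        truth = {
            "intercept": -1.4,
            "beta": {k: 0.0 for k in DEFAULT_TRUTH["beta"]},
            "region_offsets": {k: 0.0 for k in DEFAULT_TRUTH["region_offsets"]},
            "shape": 5.0,
        }
        y = simulate_response(design, truth, seed=0)
        assert y.mean() == pytest.approx(np.exp(-1.4), rel=0.01)
        assert (y > 0).all()

    def test_large_shape_shrinks_coefficient_of_variation(self):
        design = pd.DataFrame({k: np.zeros(5000) for k in
                               list(DEFAULT_TRUTH["beta"]) +
                               [f"region_{r}" for r in DEFAULT_TRUTH["region_offsets"]]})
        base = {**DEFAULT_TRUTH, "shape": 2.0}
        tight = {**DEFAULT_TRUTH, "shape": 50.0}
        cv = lambda y: y.std() / y.mean()
        assert cv(simulate_response(design, tight, seed=1)) < 0.1 * cv(
            simulate_response(design, base, seed=1)
        )

    def test_nonpositive_shape_rejected(self, study):
        with pytest.raises(ValueError, match="shape"):
            simulate_response(study.design, {**DEFAULT_TRUTH, "shape": 0.0}, seed=0)

    def test_default_responses_left_skewed(self, study):
        """Weibull shape k = 5 with the Madagascar deficit yields the
        left-skewed positive diversity responses the likelihood assumes."""
        for name in RESPONSES:
            y = study.responses[name]
            assert (y > 0).all()
        pooled = stats.skew(
            np.concatenate(
                [
                    (study.responses[n] / study.responses[n].mean()).to_numpy()
                    for n in RESPONSES
                ]
            )
        )
        assert pooled < 0


class TestStudy:
    def test_bitwise_reproducible(self):
        a = simulate_study(n_sites=8, n_species=40, seed=9)
        b = simulate_study(n_sites=8, n_species=40, seed=9)
        pd.testing.assert_frame_equal(a.fd, b.fd)
        pd.testing.assert_frame_equal(a.design, b.design)
        pd.testing.assert_frame_equal(a.responses, b.responses)

    def test_design_is_standardized_with_region_dummies(self, study):
        for col in ("pool_fric", "habitat_H", "ndvi", "human_density", "extinction_delta"):
            assert abs(study.design[col].mean()) < 1e-10
            assert abs(study.design[col].std(ddof=1) - 1) < 1e-10
        assert {"region_Africa", "region_Asia", "region_Madagascar"} <= set(study.design.columns)

    def test_all_referenced_species_exist(self, study):
        referenced = set()
        for c in study.communities:
            referenced |= set(c.members)
        for pool in study.pools.values():
            referenced |= set(pool)
        for e in study.extirpations:
            referenced |= set(e.extirpated)
        assert referenced <= set(study.traits.species)

    def test_truth_records_generator_parameters(self, study):
        assert study.truth["beta"]["ndvi"] == 0.07
        assert study.truth["beta"]["extinction_delta"] == -0.18
        assert study.truth["region_offsets"]["Madagascar"] == -2.60
        assert "scaling" in study.truth
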