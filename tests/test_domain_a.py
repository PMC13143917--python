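"""Social-communication submodels: depletion rate, reciprocity decay,
nonverbal effectiveness and relationship growth."""

import dataclasses
import math

import numpy as np
import pytest

from asdyn import (NonverbalChannel, ReciprocityParams, RelationshipParams,
                   SocialContextSignal, effective_depletion_rate,
                   nonverbal_effectiveness, reciprocity_trajectory,
                   relationship_quality)


def _bare_reciprocity(**kw):
    defaults = dict(R0=0.85, alpha=1.0, beta_base=0.3, M_social=0.0,
                    Pr_env=0.0, I_align=0.0)
    defaults.update(kw)
    return ReciprocityParams(**defaults)


class TestDepletionRate:
    def test_identity_case_returns_baseline(self):
        p = _bare_reciprocity()
        assert effective_depletion_rate(p, 0, 0, 0) == pytest.approx(p.beta_base)

    def test_hand_evaluated_modulation(self):
        # 0.3 * (1 + 0.4 + 0.2 + 0.5) / (1 + 0.6 + 0 + 0.3) computed by hand
        p = ReciprocityParams(beta_base=0.3, M_social=0.6, Pr_env=0.0, I_align=0.3)
        expected = 0.3 * 2.1 / 1.9
        assert effective_depletion_rate(p, 0.4, 0.2, 0.5) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.33158, abs=5e-6)

    def test_protective_terms_strictly_decrease_rate(self):
        p = ReciprocityParams(beta_base=0.3, M_social=0.6, Pr_env=0.2, I_align=0.3)
        base = effective_depletion_rate(p, 0.4, 0.2, 0.5)
        for name in ("M_social", "Pr_env", "I_align"):
            doubled = dataclasses.replace(p, **{name: 2 * getattr(p, name)})
            assert effective_depletion_rate(doubled, 0.4, 0.2, 0.5) < base

    def test_monotone_in_loads_and_protection(self, rng):
        # finite differences over a random parameter grid
        for _ in range(50):
            p = ReciprocityParams(beta_base=rng.uniform(0.05, 0.5),
                                  M_social=rng.uniform(0, 1),
                                  Pr_env=rng.uniform(0, 1),
                                  I_align=rng.uniform(0, 1))
            loads = rng.uniform(0, 1, 3)
            f0 = effective_depletion_rate(p, *loads)
            for i in range(3):
                bumped = loads.copy()
                bumped[i] += 0.1
                assert effective_depletion_rate(p, *bumped) >= f0

    def test_negative_load_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            effective_depletion_rate(ReciprocityParams(), -0.1, 0, 0)


class TestReciprocityTrajectory:
    def test_initial_value_is_capacity_times_r0(self):
        p = _bare_reciprocity(alpha=0.9, R0=0.8)
        ctx = SocialContextSignal.constant(np.linspace(0, 2, 5))
        R = reciprocity_trajectory(p, ctx)
        assert R[0] == pytest.approx(0.9 * 0.8, abs=1e-15)

    def test_constant_rate_matches_closed_form_everywhere(self):
        p = _bare_reciprocity(beta_base=0.5)
        t = np.linspace(0, 4, 257)
        R = reciprocity_trajectory(p, SocialContextSignal.constant(t))
        assert np.max(np.abs(R - 0.85 * np.exp(-0.5 * t))) < 1e-12
        # direct evaluation oracle at t = 1 h
        assert R[64] == pytest.approx(0.85 * math.exp(-0.5), abs=1e-12)
        assert 0.85 * math.exp(-0.5) == pytest.approx(0.51555, abs=5e-6)

    def test_non_increasing_and_grid_refinement_stable(self):
        p = _bare_reciprocity()
        t1 = np.linspace(0, 3, 301)
        t2 = np.linspace(0, 3, 601)
        load = lambda t: 0.5 + 0.5 * np.sin(t)
        R1 = reciprocity_trajectory(p, SocialContextSignal(t1, load(t1), 0 * t1, 0 * t1))
        R2 = reciprocity_trajectory(p, SocialContextSignal(t2, load(t2), 0 * t2, 0 * t2))
        assert np.all(np.diff(R1) <= 0)
        assert abs(R1[-1] - R2[-1]) < 1e-5

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            SocialContextSignal(np.array([]), np.array([]), np.array([]), np.array([]))


class TestNonverbal:
    def test_hand_summation(self):
        chans = [NonverbalChannel("gaze", 0.3, 0.5, 1.0),
                 NonverbalChannel("gesture", 0.2, 1.0, 0.5)]
        assert nonverbal_effectiveness(chans) == pytest.approx(0.25, abs=1e-15)

    def test_zero_efficiency_contributes_nothing(self):
        base = [NonverbalChannel("a", 0.5, 1.0, 0.7)]
        with_dead = base + [NonverbalChannel("b", 9.0, 0.0, 1.0)]
        assert nonverbal_effectiveness(with_dead) == nonverbal_effectiveness(base)

    def test_linear_in_cue_scores_and_permutation_invariant(self, rng):
        chans = [NonverbalChannel(f"c{i}", rng.uniform(0, 1), rng.uniform(0, 1),
                                  rng.uniform(0, 1)) for i in range(6)]
        n = nonverbal_effectiveness(chans)
        perm = [chans[i] for i in rng.permutation(6)]
        assert nonverbal_effectiveness(perm) == pytest.approx(n, abs=1e-14)
        doubled = [dataclasses.replace(c, x=2 * c.x) for c in chans]
        assert nonverbal_effectiveness(doubled) == pytest.approx(2 * n, abs=1e-13)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            nonverbal_effectiveness([])


class TestRelationships:
    def test_half_maximum_at_inflection(self):
        r = RelationshipParams(a_max=1.2, M_soc=0.8, M_norm=1.0, t_infl=6.0)
        C, comps = relationship_quality([r], 6.0)
        assert C == pytest.approx(1.2 * 0.8 / 2, abs=1e-12)

    def test_maximal_uncertainty_freezes_growth(self):
        r = RelationshipParams(P_var=1.0)
        for t in (-5.0, 0.0, 30.0):
            C, _ = relationship_quality([r], t)
            assert C == pytest.approx(r.a_max * r.M_soc / r.M_norm / 2, abs=1e-12)

    def test_asymptote(self):
        rels = [RelationshipParams(a_max=1.0, t_infl=3.0, k_base=0.8, P_var=0.1),
                RelationshipParams(a_max=0.6, t_infl=9.0, k_base=0.5, P_var=0.0)]
        total_a = sum(r.a_max * r.M_soc / r.M_norm for r in rels)
        k_min = min(r.k_base * (r.R_sal / r.R_norm) * (1 - r.P_var) for r in rels)
        t_far = max(r.t_infl for r in rels) + 50 / k_min
        C, _ = relationship_quality(rels, t_far)
        assert C == pytest.approx(total_a, abs=1e-9)

    def test_additivity_over_relationships(self, rng):
        rels = [RelationshipParams(a_max=rng.uniform(0.5, 2), t_infl=rng.uniform(0, 12),
                                   k_base=rng.uniform(0.1, 1)) for _ in range(4)]
        t = rng.uniform(0, 24, size=7)
        C_all, _ = relationship_quality(rels, t)
        C_sum = sum(relationship_quality([r], t)[0] for r in rels)
        assert np.allclose(C_all, C_sum, atol=1e-13)

    def test_non_decreasing_in_time(self):
        rels = [RelationshipParams(), RelationshipParams(t_infl=12.0)]
        t = np.linspace(-10, 40, 200)
        C, _ = relationship_quality(rels, t)
        assert np.all(np.diff(C) >= 0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="M_norm"):
            relationship_quality([RelationshipParams(M_norm=0.0)], 1.0)
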