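"""Structure extraction, outcome classification, optimality and payoffs."""

import itertools

import numpy as np
import pytest

from coordsig import (
    PopulationState,
    PreferenceType,
    ScenarioConfig,
    SignalSpace,
    StrategyProfile,
    classify,
    expected_payoffs,
    extract_structure,
    interaction_payoff,
    is_optimal,
    named_structure,
    preset,
    render_structure,
)
from coordsig.structures import GroupStructure, TypeBehaviour, _behavioural_check


def monomorphic_pop(cfg, profiles):
    counts = cfg.type_counts()
    return PopulationState.from_profiles(
        cfg, {k: {profiles[k]: float(counts[k])} for k in range(len(cfg.types))}
    )


class TestExtractStructure:
    def test_monomorphic_population_reproduces_profiles(self):
        cfg = preset("three-type-cost")
        ref = named_structure(cfg, "optimal-favouring-umma")
        pop = monomorphic_pop(cfg, ref.profiles())
        st = extract_structure(pop, cfg)
        assert not st.any_mixed()
        assert [b.signal for b in st.behaviours] == [b.signal for b in ref.behaviours]
        assert st.resolved_actions().tolist() == ref.resolved_actions().tolist()

    def test_majority_ignores_pattern_recovered(self):
        """Ummians silent, Kishus and Akkadians signalling, only Kishus
        conditioning actions -- the prominent suboptimal three-type outcome."""
        cfg = preset("three-type-cost")
        ref = named_structure(cfg, "majority-ignores")
        pop = monomorphic_pop(cfg, ref.profiles())
        st = extract_structure(pop, cfg)
        assert st.behaviours[0].attended == ()
        assert st.behaviours[1].attended == (0,)
        assert st.behaviours[2].attended == (0,)
        # only Kishus condition: their resolved action varies with partner
        R = st.resolved_actions()
        assert len(set(R[1])) == 3
        assert len(set(R[0])) == 1 and len(set(R[2])) == 1

    def test_same_signals_different_actions_distinct_structures(self):
        cfg = preset("intersectional")
        a = named_structure(cfg, "intersectional")
        b = named_structure(cfg, "conjunction-umma")
        assert a.signalling_system == b.signalling_system
        assert a.resolved_actions().tolist() != b.resolved_actions().tolist()

    def test_subthreshold_signal_flagged_mixed(self):
        cfg = preset("two-type-base", {"V": 2.0, "d": 0.5})
        space = cfg.space
        p1 = StrategyProfile(space, (1,), (0, 0, 0))
        p2 = StrategyProfile(space, (2,), (0, 0, 0))
        pop = PopulationState.from_profiles(
            cfg, {0: {p1: 250.0, p2: 250.0}, 1: {p1: 500.0}}
        )
        st = extract_structure(pop, cfg)
        assert st.behaviours[0].mixed_signal
        assert not st.behaviours[1].mixed_signal


class TestClassify:
    def test_uniform_norm_majority(self):
        cfg = preset("two-type-base", {"V": 2.0, "d": 0.6})
        umma_always = StrategyProfile(cfg.space, (0,), (0, 0, 0))
        pop = monomorphic_pop(cfg, [umma_always, umma_always])
        lab = classify(extract_structure(pop, cfg), cfg)
        assert lab.label == "uniform-norm-majority"

    def test_uniform_norm_minority(self):
        cfg = preset("two-type-base", {"V": 2.0, "d": 0.6})
        kish_always = StrategyProfile(cfg.space, (0,), (1, 1, 1))
        pop = monomorphic_pop(cfg, [kish_always, kish_always])
        lab = classify(extract_structure(pop, cfg), cfg)
        assert lab.label == "uniform-norm-minority"

    def test_both_preferred_miscoordination(self):
        cfg = preset("two-type-base", {"signal_alphabet": [], "V": 3.0, "d": 0.5})
        umma = StrategyProfile(cfg.space, (), (0,))
        kish = StrategyProfile(cfg.space, (), (1,))
        pop = monomorphic_pop(cfg, [umma, kish])
        lab = classify(extract_structure(pop, cfg), cfg)
        assert lab.label == "both-preferred-miscoordination"

    def test_intersectional_vs_conjunctive_merger(self):
        cfg = preset("intersectional")
        inter = named_structure(cfg, "intersectional")
        assert classify(inter, cfg).label == "intersectional"
        cfg_mc = preset("intersectional", {"VK": 0.0})
        merger = named_structure(cfg_mc, "conjunction-umma")
        lab = classify(merger, cfg_mc)
        assert lab.label == "conjunctive-merger"
        assert "umma" in lab.category

    def test_majority_ignores_label(self):
        cfg = preset("three-type-cost")
        st = named_structure(cfg, "majority-ignores")
        lab = classify(st, cfg)
        assert lab.label == "majority-ignores-signals-suboptimal"
        assert "Ummian" in lab.category

    def test_optimal_favouring_labels(self):
        cfg = preset("three-type-cost")
        for name, action in (
            ("optimal-favouring-umma", "umma"),
            ("optimal-favouring-kish", "kish"),
        ):
            lab = classify(named_structure(cfg, name), cfg)
            assert lab.label == f"optimal-favouring-{action}"

    def test_relabelling_invariance(self):
        """Swapping the two real signals consistently leaves the label alone."""
        cfg = preset("three-type-cost")
        st = named_structure(cfg, "optimal-favouring-umma")
        base = classify(st, cfg).label
        swapped_profiles = []
        swap = {0: 0, 1: 2, 2: 1}
        for prof in st.profiles():
            sig = (swap[prof.signal[0]],)
            combos = cfg.space.combinations
            acts = tuple(
                prof.actions[cfg.space.vector_index((swap[c[0]],))] for c in combos
            )
            swapped_profiles.append(StrategyProfile(cfg.space, sig, acts))
        pop = monomorphic_pop(cfg, swapped_profiles)
        assert classify(extract_structure(pop, cfg), cfg).label == base

    def test_embedding_labels(self):
        cfg = preset("disjoint-double")
        assert classify(named_structure(cfg, "disjoint"), cfg).label == (
            "disjoint-double-embedding"
        )
        cfg_h = preset("hierarchical-double")
        assert classify(named_structure(cfg_h, "hierarchical"), cfg_h).label == (
            "hierarchical-double-embedding"
        )


class TestIsOptimal:
    def test_two_dim_single_embedding_structure_optimal(self):
        cfg = preset("single-embedding")
        st = named_structure(cfg, "optimal-two-dim")
        cert = is_optimal(st, cfg)
        assert cert.optimal, cert.violations

    def test_majority_ignores_fails_clause_i(self):
        """Ummians and Akkadians fail to coordinate despite a mutually
        beneficial greeting existing."""
        cfg = preset("three-type-cost")
        cert = is_optimal(named_structure(cfg, "majority-ignores"), cfg)
        assert not cert.optimal
        assert cert.status == "violates-i"
        assert any("Ummian-Akkadian" in v for v in cert.violations)

    def test_single_type_preferred_action_no_signals_optimal(self):
        cfg = preset("two-type-base", {"d": 1.0, "V": 2.0})
        umma = StrategyProfile(cfg.space, (0,), (0, 0, 0))
        pop = monomorphic_pop(cfg, [umma, umma])
        cert = is_optimal(extract_structure(pop, cfg), cfg)
        assert cert.optimal
        assert cert.structure_cost == 0.0

    def test_agrees_with_brute_force_enumeration_small_space(self):
        """Exhaustive comparison on a two-type, one-dimension, one-signal
        space: every assignment of full profiles to types."""
        space = SignalSpace((1,))
        types = [
            PreferenceType(0, "A", (2.0, 1.0), 0.5),
            PreferenceType(1, "B", (1.0, 2.0), 0.5),
        ]
        cfg = ScenarioConfig(
            types=types, action_labels=("x", "y"), space=space, signal_cost=0.1, N=10
        ).validate()
        all_profiles = [
            StrategyProfile(space, (s,), acts)
            for s in range(2)
            for acts in itertools.product(range(2), repeat=2)
        ]
        # brute-force: all structures satisfying clauses (i)+(ii), their costs
        def clauses_ok(pa, pb):
            for (ti, pi), (tj, pj) in itertools.combinations_with_replacement(
                [(types[0], pa), (types[1], pb)], 2
            ):
                ai, aj = pi.action_against(pj), pj.action_against(pi)
                mp = [a for a in range(2) if ti.payoffs[a] > 0 and tj.payoffs[a] > 0]
                if mp:
                    if ai != aj or ai not in mp:
                        return False
                    best = max(ti.payoffs[a] + tj.payoffs[a] for a in mp)
                    if ti.payoffs[ai] + tj.payoffs[ai] < best:
                        return False
            return True

        feasible_costs = [
            0.05 * (pa.attended_dims + pb.attended_dims)
            for pa, pb in itertools.product(all_profiles, repeat=2)
            if clauses_ok(pa, pb)
        ]
        min_cost = min(feasible_costs)
        for pa, pb in itertools.product(all_profiles, repeat=2):
            pop = monomorphic_pop(cfg, [pa, pb])
            st = extract_structure(pop, cfg)
            cert = is_optimal(st, cfg)
            expected = clauses_ok(pa, pb) and (
                0.05 * (pa.attended_dims + pb.attended_dims) <= min_cost + 1e-12
            )
            assert cert.optimal == expected, (pa, pb, cert)

    def test_optimal_structure_exists_when_all_dyads_share_positive_action(self):
        """Constructive check: for every shipped preset whose dyads all admit
        a mutually beneficial action, some structure passes the certificate."""
        for name in ("two-type-base", "three-type-cost", "single-embedding"):
            cfg = preset(name)
            mats = [
                [
                    any(
                        t1.payoffs[a] > 0 and t2.payoffs[a] > 0
                        for a in range(cfg.n_actions)
                    )
                    for t2 in cfg.types
                ]
                for t1 in cfg.types
            ]
            if not all(all(row) for row in mats):
                continue
            names = {
                "three-type-cost": "optimal-favouring-umma",
                "single-embedding": "optimal-two-dim",
            }
            if name == "two-type-base":
                # cross-cultural competence: each type signals, own greeting
                # within type, the umma greeting between types
                u = StrategyProfile(cfg.space, (1,), (0, 0, 0))
                k = StrategyProfile(cfg.space, (2,), (1, 0, 1))
                st = extract_structure(monomorphic_pop(cfg, [u, k]), cfg)
            else:
                st = named_structure(cfg, names[name])
            assert not _behavioural_check(st.resolved_actions(), cfg)


class TestExpectedPayoffs:
    def test_single_type_preferred_norm_pays_v(self):
        cfg = preset("two-type-base", {"d": 1.0, "V": 3.0, "signal_alphabet": []})
        umma = StrategyProfile(cfg.space, (), (0,))
        pop = monomorphic_pop(cfg, [umma, umma])
        pay = expected_payoffs(extract_structure(pop, cfg), cfg)
        assert pay["Ummian"] == pytest.approx(3.0)

    def test_three_type_matches_pair_enumeration_oracle(self):
        """Equal-thirds population in the optimal-favouring-Ummians structure,
        V=2, c=0: per-type payoffs from exhaustive dyad enumeration."""
        cfg = preset("three-type-cost", {"V": 2.0, "d": 0.5, "c": 0.0})
        st = named_structure(cfg, "optimal-favouring-umma")
        profiles = st.profiles()
        pay = expected_payoffs(st, cfg)
        for i, t in enumerate(cfg.types):
            oracle = sum(
                cfg.types[j].proportion
                * interaction_payoff(t, profiles[i], profiles[j], cfg.signal_cost)
                for j in range(3)
            )
            assert pay[t.label] == pytest.approx(oracle)

    def test_optimal_structure_still_unequal(self):
        """In the structure favouring Ummians, Ummians strictly out-earn
        Kishus: optimality does not imply equity."""
        cfg = preset("three-type-cost", {"V": 2.0, "d": 0.5})
        pay = expected_payoffs(named_structure(cfg, "optimal-favouring-umma"), cfg)
        assert pay["Ummian"] > pay["Kishu"]


class TestRender:
    def test_render_mentions_types_and_null_underscore(self):
        cfg = preset("three-type-cost")
        text = render_structure(named_structure(cfg, "majority-ignores"), cfg)
        assert "Ummian" in text and "Kishu" in text
        assert "_" in text
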