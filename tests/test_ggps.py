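import numpy as np
import pytest

from kinforge.cm_model import RelationshipClass, default_table
from kinforge.gedcom_io import parse_gedcom
from kinforge.ggps import (ExitEvent, GGPSConfig, Hypothesis, _trace, apply_filters,
                           enumerate_exit_events, intersect_events, run_ggps,
                           score_hypotheses, transition_probability, workload)
from kinforge.pedigree_graph import Match, build_graph
from kinforge.synthetic_fixtures import SimConfig, make_ggps_case

from conftest import TWO_BRANCH_GED, make_gedcom


@pytest.fixture(scope="module")
def table():
    return default_table()


def trace_events(g, match, cls, p_rel=0.5, config=None):
    events = {}
    _trace(g, match, cls, p_rel, config or GGPSConfig(), events)
    return sorted(events.values(), key=lambda e: -e.remaining_moves_r)


# match @I3@ with one recorded parent couple, nobody deeper
CHAIN_GED = make_gedcom(
    indis=[(1, "A //", "M", 1900, (), ("@F1@",)),
           (2, "B //", "F", 1900, (), ("@F1@",)),
           (3, "C //", "M", 1930, ("@F1@",), ())],
    fams=[(1, "@I1@", "@I2@", ("@I3@",))])


class TestTrace:
    def test_chain_class_2_1(self):
        g = build_graph(parse_gedcom(CHAIN_GED)[0])
        events = trace_events(g, Match("@I3@", 500.0), RelationshipClass(g_up=2, g_down=1))
        by_r = {}
        for e in events:
            by_r.setdefault(e.remaining_moves_r, set()).add(e.node_v)
        assert by_r[6] == {"@I3@"}
        assert by_r[5] == {"@F1@"}
        assert by_r[4] == {"@I1@", "@I2@"}
        assert set(by_r) == {6, 5, 4}  # grandparent frontier: nothing deeper

    def test_r_invariant(self):
        g = build_graph(parse_gedcom(TWO_BRANCH_GED)[0])
        for cls in (RelationshipClass(g_up=2, g_down=2), RelationshipClass(g_up=1, g_down=3)):
            for e in trace_events(g, Match("@I7@", 400.0), cls):
                penalty = 1 if g.is_family(e.node_v) and e.remaining_moves_r % 2 else 0
                assert e.remaining_moves_r == \
                    2 * e.remaining_up + 2 * e.remaining_down - penalty

    def test_founder_match_stops_at_frontier(self):
        g = build_graph(parse_gedcom(CHAIN_GED)[0])
        events = trace_events(g, Match("@I1@", 2600.0),
                              RelationshipClass(g_up=1, g_down=1),
                              config=GGPSConfig(trace_descent=False))
        assert [(e.node_v, e.remaining_moves_r) for e in events] == [("@I1@", 4)]

    def test_descent_through_verified_relatives(self):
        g = build_graph(parse_gedcom(TWO_BRANCH_GED)[0])
        events = trace_events(g, Match("@I7@", 866.0), RelationshipClass(g_up=2, g_down=2))
        nodes_at = {(e.node_v, e.remaining_moves_r) for e in events}
        # descent passes the apex family again, then uncle Edwin and his family
        assert ("@F1@", 3) in nodes_at
        assert ("@I5@", 2) in nodes_at
        assert ("@F4@", 1) in nodes_at


class TestEnumerate:
    def test_p_min_one_yields_nothing(self, table):
        g = build_graph(parse_gedcom(CHAIN_GED)[0])
        events = enumerate_exit_events(g, Match("@I3@", 400.0),
                                       GGPSConfig(p_min=1.0), table)
        assert events == []

    def test_match_must_exist(self, table):
        g = build_graph(parse_gedcom(CHAIN_GED)[0])
        with pytest.raises(KeyError):
            enumerate_exit_events(g, Match("@I99@", 400.0), GGPSConfig(), table)

    def test_events_filtered_by_p_min(self, table):
        g = build_graph(parse_gedcom(TWO_BRANCH_GED)[0])
        events = enumerate_exit_events(g, Match("@I7@", 430.0),
                                       GGPSConfig(p_min=0.05), table)
        assert events
        assert all(e.p_rel >= 0.05 for e in events)


class TestIntersect:
    def test_two_cousin_matches_converge_at_family(self, table):
        g = build_graph(parse_gedcom(TWO_BRANCH_GED)[0])
        config = GGPSConfig()
        matches = [Match("@I7@", 866.0), Match("@I8@", 820.0)]
        events = {m.individual_id: enumerate_exit_events(g, m, config, table)
                  for m in matches}
        hyps = intersect_events(events, config)
        at_grandparents = [h for h in hyps if h.node_v == "@F1@"
                           and set(h.match_ids) == {"@I7@", "@I8@"}]
        assert at_grandparents
        assert {h.remaining_moves_r for h in at_grandparents} >= {3}

    def test_single_match_insufficient(self, table):
        g = build_graph(parse_gedcom(TWO_BRANCH_GED)[0])
        config = GGPSConfig(min_converging_matches=2)
        events = {"@I7@": enumerate_exit_events(g, Match("@I7@", 866.0), config, table)}
        assert intersect_events(events, config) == []

    def test_min_one_makes_every_event_a_hypothesis(self, table):
        g = build_graph(parse_gedcom(CHAIN_GED)[0])
        config = GGPSConfig(min_converging_matches=1, include_identity_hypotheses=True)
        events = {"@I3@": enumerate_exit_events(g, Match("@I3@", 430.0), config, table)}
        hyps = intersect_events(events, config)
        assert len(hyps) == len({(e.node_v, e.remaining_moves_r)
                                 for e in events["@I3@"]})


def _hyp(node_v, r, events=()):
    return Hypothesis(node_v=node_v, remaining_moves_r=r, events=list(events))


def _event(match_id, p_rel, ru=0, rd=1, node="@F1@", r=1):
    return ExitEvent(match_id=match_id, rel_class=RelationshipClass(g_up=2, g_down=2),
                     node_v=node, remaining_moves_r=r, consumed_up=2,
                     remaining_up=ru, remaining_down=rd, p_rel=p_rel)


class TestWorkload:
    def test_r_zero(self, nuclear_graph):
        assert workload(_hyp("@I3@", 0), nuclear_graph) == 0.0

    def test_single_down_half_edge_from_family(self, nuclear_graph):
        # family exists, the hypothetical child is one whole individual
        assert workload(_hyp("@F1@", 1), nuclear_graph) == 1.0

    def test_alternation_from_individual(self, nuclear_graph):
        # INDI -> fam(0.5) -> indi(1.0) -> fam(0.5) -> indi(1.0)
        assert workload(_hyp("@I3@", 4), nuclear_graph) == 3.0

    def test_two_match_convergence_fixture(self, two_branch_graph, table):
        config = GGPSConfig()
        matches = [Match("@I7@", 866.0), Match("@I8@", 820.0)]
        events = {m.individual_id: enumerate_exit_events(g := two_branch_graph, m, config, table)
                  for m in matches}
        hyps = intersect_events(events, config)
        target = next(h for h in hyps if (h.node_v, h.remaining_moves_r) == ("@F1@", 3))
        # suffix from the family node: child(1.0) + family(0.5) + child(1.0)
        assert workload(target, two_branch_graph) == 2.5


class TestTransitionProbability:
    def test_empty_product(self):
        assert transition_probability(0, 0, GGPSConfig()) == 1.0

    def test_direct_arithmetic(self):
        assert transition_probability(2, 1, GGPSConfig(qa=0.9, qd=0.8)) == \
            pytest.approx(0.648)

    def test_qa_one_boundary(self):
        cfg = GGPSConfig(qa=1.0, qd=0.8)
        for g_up in range(6):
            assert transition_probability(g_up, 0, cfg) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transition_probability(-1, 0, GGPSConfig())


class TestScoring:
    def test_score_arithmetic(self, nuclear_graph, table):
        # W=3, alpha=1, Pc=0.5, Pt=0.648, Q=1 -> 4 / 0.324 = 12.3457
        cfg = GGPSConfig(qa=0.9, qd=0.8, alpha=1.0)
        h = _hyp("@I3@", 4, [_event("@M1@", 0.5, ru=2, rd=1), _event("@M2@", 0.5, ru=2, rd=1)])
        out = score_hypotheses([h], nuclear_graph, cfg, table)[0]
        assert out.W_eff == 3.0
        assert out.P_t == pytest.approx(0.648)
        assert out.P_combined == pytest.approx(0.5)
        assert out.Q_factor == 1.0
        assert out.score == pytest.approx(4.0 / 0.324, rel=1e-6)

    def test_higher_p_combined_ranks_first(self, nuclear_graph, table):
        cfg = GGPSConfig()
        h1 = _hyp("@F1@", 1, [_event("@M1@", 0.6), _event("@M2@", 0.6)])
        h2 = _hyp("@I3@", 1, [_event("@M1@", 0.3, node="@I3@"), _event("@M2@", 0.3, node="@I3@")])
        ranked = score_hypotheses([h2, h1], nuclear_graph, cfg, table)
        assert ranked[0].node_v == "@F1@"

    def test_score_monotonicity(self, nuclear_graph, table):
        cfg = GGPSConfig()
        base = score_hypotheses(
            [_hyp("@F1@", 1, [_event("@M1@", 0.5), _event("@M2@", 0.5)])],
            nuclear_graph, cfg, table)[0]
        worse_p = score_hypotheses(
            [_hyp("@F1@", 1, [_event("@M1@", 0.4), _event("@M2@", 0.4)])],
            nuclear_graph, cfg, table)[0]
        longer = score_hypotheses(
            [_hyp("@F1@", 3, [_event("@M1@", 0.5, rd=2, r=3), _event("@M2@", 0.5, rd=2, r=3)])],
            nuclear_graph, cfg, table)[0]
        assert base.score < worse_p.score
        assert base.score < longer.score

    def test_random_component_algebra(self, nuclear_graph, table):
        rng = np.random.default_rng(7)
        cfg = GGPSConfig(alpha=float(rng.uniform(0.1, 2.0)))
        for _ in range(200):
            ps = rng.uniform(0.05, 1.0, size=2)
            ru, rd = int(rng.integers(0, 4)), int(rng.integers(0, 4))
            h = _hyp("@F1@", 2 * (ru + rd) or 1,
                     [_event("@M1@", ps[0], ru=ru, rd=rd), _event("@M2@", ps[1], ru=ru, rd=rd)])
            out = score_hypotheses([h], nuclear_graph, cfg, table)[0]
            direct = (out.W_eff + cfg.alpha) / (out.P_combined * out.P_t * out.Q_factor)
            assert out.score == pytest.approx(direct, rel=1e-12)


class TestFilters:
    def test_age_filter_drops_implausible(self, two_branch_graph):
        cfg = GGPSConfig(age_tolerance_years=20)
        # node @F1@ partners born 1900/1902 -> implied ~1901 + offset
        h = _hyp("@F1@", 1, [_event("@M1@", 0.5, rd=1)])
        kept = apply_filters([h], two_branch_graph, cfg, target_birth_year=1929)
        assert kept == [h]
        dropped = apply_filters([h], two_branch_graph, cfg, target_birth_year=1990)
        assert dropped == []

    def test_infinite_tolerance_keeps_all(self, two_branch_graph):
        cfg = GGPSConfig(age_tolerance_years=10_000)
        h = _hyp("@F1@", 1, [_event("@M1@", 0.5)])
        assert apply_filters([h], two_branch_graph, cfg, 1800) == [h]

    def test_missing_estimate_warns_and_skips(self, two_branch_graph):
        cfg = GGPSConfig()
        h = _hyp("@F1@", 1, [_event("@M1@", 0.5)])
        with pytest.warns(UserWarning):
            assert apply_filters([h], two_branch_graph, cfg, None) == [h]


class TestPipeline:
    def test_recovery_on_simulated_case(self, table):
        case = make_ggps_case(SimConfig(seed=1, founders=6, generations=4,
                                        mean_children=2.5), 3, table)
        g = build_graph(case.document)
        hyps = run_ggps(g, case.matches, GGPSConfig(min_converging_matches=3, p_min=0.02))
        assert (case.truth.true_exit in
                [(h.node_v, h.remaining_moves_r) for h in hyps])

    def test_deterministic(self, table):
        case = make_ggps_case(SimConfig(seed=2, founders=6, generations=4), 3, table)
        g = build_graph(case.document)
        a = run_ggps(g, case.matches)
        b = run_ggps(g, case.matches)
        assert [(h.node_v, h.remaining_moves_r, h.score) for h in a] == \
               [(h.node_v, h.remaining_moves_r, h.score) for h in b]

    def test_adding_consistent_match_never_hurts_rank(self, table):
        g = build_graph(parse_gedcom(TWO_BRANCH_GED)[0])
        cfg = GGPSConfig()
        two = run_ggps(g, [Match("@I7@", 866.0), Match("@I8@", 866.0)], cfg)
        three = run_ggps(g, [Match("@I7@", 866.0), Match("@I8@", 866.0),
                             Match("@I5@", 1741.0)], cfg)

        def rank_of(hyps, key):
            scores = {(h.node_v, h.remaining_moves_r): h.score for h in hyps}
            if key not in scores:
                return None
            return 1 + sum(1 for s in scores.values() if s < scores[key] - 1e-12)

        key = ("@F4@", 1)  # unknown as child of Edwin: supported by all three
        r2, r3 = rank_of(two, key), rank_of(three, key)
        assert r2 is not None and r3 is not None
        assert r3 <= r2

    def test_completability_invariant(self, table):
        # every hypothesis attaches only new nodes: r >= 1 and the remaining
        # split is consistent with the half-edge accounting
        case = make_ggps_case(SimConfig(seed=4, founders=6, generations=4), 3, table)
        g = build_graph(case.document)
        for h in run_ggps(g, case.matches):
            assert h.remaining_moves_r >= 1
            for e in h.events:
                penalty = 1 if g.is_family(h.node_v) and h.remaining_moves_r % 2 else 0
                assert h.remaining_moves_r == \
                    2 * e.remaining_up + 2 * e.remaining_down - penalty
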