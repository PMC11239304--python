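"""Frontier construction: dominance, extended dominance, hulls vs brute force."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from daive import (
    CostOutcomePoint,
    NetHealthPoint,
    evaluate_equity,
    net_health_equity_frontier,
    net_health_value,
    quadrant,
    representative_wtp,
    value_efficiency_frontier,
)

# ---------------------------------------------------------------------------
# Independent brute-force oracles (segment/dominance enumeration, no hull code)
# ---------------------------------------------------------------------------


def brute_force_value_frontier(points):
    """Members of the cost-gain frontier by exhaustive dominance checks.

    A point is a member iff it is the (unique, tie-broken) cheapest anchor or
    (a) no other point weakly dominates it (cost <=, gain >=, one strict) and
    (b) it lies strictly above every segment joining two other points that
    bracket its cost (otherwise it is extended-dominated or collinear).
    """
    anchor = min(points, key=lambda p: (p.cost, -p.gain, p.condition))
    members = []
    for p in points:
        if p is anchor:
            members.append(p)
            continue
        if p.cost <= anchor.cost or p.gain <= anchor.gain:
            continue  # dominated by or behind the anchor
        dominated = any(
            q is not p and q.cost <= p.cost and q.gain >= p.gain
            and (q.cost < p.cost or q.gain > p.gain)
            for q in points
        )
        if dominated:
            continue
        extended = False
        for a, b in itertools.permutations([q for q in points if q is not p], 2):
            if a.cost <= p.cost <= b.cost and a.cost < b.cost and a.gain < b.gain:
                frac = (p.cost - a.cost) / (b.cost - a.cost)
                seg = a.gain + frac * (b.gain - a.gain)
                if p.gain <= seg + 1e-12:
                    extended = True
                    break
        if not extended:
            members.append(p)
    return sorted({m.condition for m in members})


def brute_force_equity_frontier(points):
    """Members of the upper-right (Q, NHV) hull by exhaustive enumeration."""
    def dominated(p):
        return any(
            q is not p
            and q.equitability >= p.equitability and q.nhv >= p.nhv
            and (q.equitability > p.equitability or q.nhv > p.nhv
                 or q.condition < p.condition)
            for q in points
        )

    members = []
    for p in points:
        if dominated(p):
            continue
        under_chord = False
        for a, b in itertools.combinations([q for q in points if q is not p], 2):
            lo, hi = sorted((a, b), key=lambda r: r.equitability)
            if lo.equitability <= p.equitability <= hi.equitability \
                    and lo.equitability < hi.equitability:
                frac = (p.equitability - lo.equitability) / (
                    hi.equitability - lo.equitability
                )
                seg = lo.nhv + frac * (hi.nhv - lo.nhv)
                if p.nhv <= seg + 1e-12:
                    under_chord = True
                    break
        if not under_chord:
            members.append(p)
    return sorted({m.condition for m in members})


# ---------------------------------------------------------------------------
# Net health value and representative willingness-to-pay
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "gain, cost, wtp, expected",
    [(0.5, 250, 580, 40.0), (0.0, 0.0, 170, 0.0), (0.75, 100, 170, 27.5)],
)
def test_net_health_value(gain, cost, wtp, expected):
    assert net_health_value(gain, cost, wtp) == pytest.approx(expected)


def test_net_health_value_requires_positive_wtp():
    with pytest.raises(ValueError, match="positive"):
        net_health_value(1.0, 0.0, 0.0)


class TestRepresentativeWtp:
    def test_explicit_list_passes_through(self, wtp_set):
        assert representative_wtp(values=wtp_set) == tuple(sorted(wtp_set))

    def test_single_icer_brackets(self):
        assert representative_wtp([100.0]) == (50.0, 150.0)

    def test_bracketing_interleaves_icers(self):
        icers = (400 / 3, 250.0, 400.0, 500.0)
        lam = representative_wtp(icers)
        assert len(lam) == 5
        assert lam[0] < icers[0] < lam[1] < icers[1] < lam[2] < icers[2] \
            < lam[3] < icers[3] < lam[4]

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            representative_wtp(None, None)


# ---------------------------------------------------------------------------
# Value efficiency frontier
# ---------------------------------------------------------------------------


class TestValueEfficiencyFrontier:
    def test_analytic_case_study_frontier(self, analytic_points):
        frontier = value_efficiency_frontier(analytic_points)
        assert frontier.labels == ("Min", "A", "AB", "ABC", "ABCD")
        np.testing.assert_allclose(frontier.icers, [400 / 3, 250, 400, 500],
                                   atol=1e-6)

    def test_icers_strictly_increase(self, analytic_points):
        frontier = value_efficiency_frontier(analytic_points)
        assert all(a < b for a, b in zip(frontier.icers, frontier.icers[1:]))

    def test_single_point(self):
        p = CostOutcomePoint("X", 10, 1)
        assert value_efficiency_frontier([p]).labels == ("X",)

    def test_equal_cost_keeps_higher_gain(self):
        pts = [CostOutcomePoint("low", 100, 1.0), CostOutcomePoint("high", 100, 2.0)]
        assert value_efficiency_frontier(pts).labels == ("high",)

    def test_collinear_middle_point_dropped_by_default(self):
        pts = [
            CostOutcomePoint("a", 0, 0.0),
            CostOutcomePoint("b", 50, 0.5),
            CostOutcomePoint("c", 100, 1.0),
        ]
        strict = value_efficiency_frontier(pts)
        assert strict.labels == ("a", "c") and strict.icers == (100.0,)
        kept = value_efficiency_frontier(pts, include_collinear=True)
        assert kept.labels == ("a", "b", "c")

    @settings(derandomize=True, max_examples=150)
    @given(
        coords=st.lists(
            st.tuples(st.integers(0, 100), st.integers(-50, 50)),
            min_size=1,
            max_size=16,
            unique=True,
        )
    )
    def test_matches_brute_force_dominance_enumeration(self, coords):
        pts = [
            CostOutcomePoint(f"p{i}", c, g, i) for i, (c, g) in enumerate(coords)
        ]
        frontier = value_efficiency_frontier(pts)
        assert sorted(frontier.labels) == brute_force_value_frontier(pts)

    @settings(derandomize=True, max_examples=100)
    @given(
        coords=st.lists(
            st.tuples(st.integers(0, 100), st.integers(-50, 50)),
            min_size=2,
            max_size=16,
            unique=True,
        )
    )
    def test_nonmembers_weakly_below_hull(self, coords):
        pts = [CostOutcomePoint(f"p{i}", c, g, i) for i, (c, g) in enumerate(coords)]
        frontier = value_efficiency_frontier(pts)
        members = sorted(frontier.members, key=lambda p: p.cost)
        for p in pts:
            if p.condition in frontier.labels:
                continue
            # interpolate the hull's gain at p.cost (hull extends flat at ends)
            costs = [m.cost for m in members]
            gains = [m.gain for m in members]
            hull_gain = np.interp(p.cost, costs, gains)
            assert p.gain <= hull_gain + 1e-9


# ---------------------------------------------------------------------------
# Net health equity frontier and quadrants
# ---------------------------------------------------------------------------


def analytic_nh_points(true_mean_gains, true_group_gain_table, condition_costs, lam):
    equity = evaluate_equity(true_group_gain_table)
    return [
        NetHealthPoint(
            t,
            r.equitability,
            net_health_value(true_mean_gains[t], condition_costs[t], lam),
            len(t) if t != "Min" else 0,
        )
        for t, r in equity.items()
        if not r.excluded
    ]


class TestNetHealthEquityFrontier:
    @pytest.mark.parametrize(
        "lam, expected",
        [
            (170.0, ("A", "D")),
            (330.0, ("AB", "ABC", "D")),
            (580.0, ("ABCD", "D")),
            (830.0, ("ABCD", "D")),
        ],
    )
    def test_analytic_case_study_hulls(
        self, true_mean_gains, true_group_gain_table, condition_costs, lam, expected
    ):
        pts = analytic_nh_points(
            true_mean_gains, true_group_gain_table, condition_costs, lam
        )
        frontier = net_health_equity_frontier(pts, lam)
        assert frontier.labels == expected
        assert sorted(frontier.labels) == brute_force_equity_frontier(pts)

    def test_members_ordered_highest_nhv_to_highest_q(
        self, true_mean_gains, true_group_gain_table, condition_costs
    ):
        pts = analytic_nh_points(
            true_mean_gains, true_group_gain_table, condition_costs, 830.0
        )
        f = net_health_equity_frontier(pts, 830.0)
        nhv = [m.nhv for m in f.members]
        q = [m.equitability for m in f.members]
        assert nhv == sorted(nhv, reverse=True) and q == sorted(q)

    def test_single_point_is_its_own_frontier(self):
        p = NetHealthPoint("X", 0.1, 5.0)
        assert net_health_equity_frontier([p], 100.0).labels == ("X",)

    def test_exact_tie_broken_toward_fewer_components(self):
        pts = [NetHealthPoint("CD", 0.32, -35.0, 2), NetHealthPoint("D", 0.32, -35.0, 1)]
        assert net_health_equity_frontier(pts, 830.0).labels == ("D",)

    @settings(derandomize=True, max_examples=150)
    @given(
        coords=st.lists(
            st.tuples(st.integers(-100, 100), st.integers(-100, 100)),
            min_size=1,
            max_size=16,
            unique=True,
        )
    )
    def test_matches_brute_force_enumeration(self, coords):
        pts = [NetHealthPoint(f"p{i:02d}", q, v, i) for i, (q, v) in enumerate(coords)]
        frontier = net_health_equity_frontier(pts, 100.0)
        assert sorted(frontier.labels) == brute_force_equity_frontier(pts)

    @settings(derandomize=True, max_examples=100)
    @given(
        coords=st.lists(
            st.tuples(st.integers(-100, 100), st.integers(-100, 100)),
            min_size=2,
            max_size=16,
            unique=True,
        )
    )
    def test_hull_slopes_decrease_and_nonmembers_below(self, coords):
        pts = [NetHealthPoint(f"p{i:02d}", q, v, i) for i, (q, v) in enumerate(coords)]
        f = net_health_equity_frontier(pts, 100.0)
        m = list(f.members)
        slopes = [
            (b.nhv - a.nhv) / (b.equitability - a.equitability)
            for a, b in zip(m, m[1:])
            if b.equitability > a.equitability
        ]
        assert all(s2 < s1 + 1e-9 for s1, s2 in zip(slopes, slopes[1:]))
        qs = [p.equitability for p in m]
        vs = [p.nhv for p in m]
        for p in f.dominated:
            if qs[0] <= p.equitability <= qs[-1] and len(m) > 1:
                hull_v = np.interp(p.equitability, qs, vs)
                assert p.nhv <= hull_v + 1e-9


class TestQuadrant:
    @pytest.mark.parametrize(
        "q, nhv, label",
        [
            (0.32, -165.0, "lower-right"),
            (-0.107, 27.5, "upper-left"),
            (0.0356, 1192.5, "upper-right"),
            (-0.2, -10.0, "lower-left"),
            (0.0, 0.0, "on-axis"),
            (0.0, 5.0, "on-axis"),
        ],
    )
    def test_labels(self, q, nhv, label):
        assert quadrant(q, nhv) == label

    def test_tolerance_widens_axes(self):
        assert quadrant(0.01, 5.0, tolerance=0.02) == "on-axis"
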