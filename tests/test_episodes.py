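import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ucclaims.catalog import DrugSpec, default_catalog, refill_interval_days
from ucclaims.episodes import (
    GRACE_DAYS,
    build_all_episodes,
    build_episodes,
    classify_prescription_novelty,
    combination_flag,
    count_mtd_lines,
    episodes_to_frame,
    first_mtd,
)

ORIGIN = pd.Timestamp("2018-01-01")


def day(n):
    return ORIGIN + pd.Timedelta(days=int(n))


# ---------------------------------------------------------------------------
# independent oracle: a day-by-day scan that re-derives episode boundaries
# directly from the refill-gap discontinuation rule

def day_scan_episodes(rxs, spec, censor_day):
    """Walk calendar days one at a time, tracking coverage and gap status."""
    merged = {}
    for d, q in rxs:
        merged[d] = merged.get(d, 0) + q
    rx_map = dict(sorted(merged.items()))
    episodes = []
    active = None  # [start, last, sched, n]
    d = min(rx_map)
    while d <= censor_day:
        if active is not None and d == active[2] + GRACE_DAYS + 1:
            episodes.append((active[0], active[1], active[2], active[2],
                             "discontinued", active[3]))
            active = None
        if d in rx_map:
            sched = d + refill_interval_days(spec, rx_map[d])
            if active is None:
                active = [d, d, sched, 1]
            else:
                active[1], active[2] = d, sched
                active[3] += 1
        d += 1
    if active is not None:
        if censor_day > active[2] + GRACE_DAYS:
            episodes.append((active[0], active[1], active[2], active[2],
                             "discontinued", active[3]))
        else:
            episodes.append((active[0], active[1], active[2], censor_day,
                             "ongoing_at_censor", active[3]))
    return episodes


def day_scan_covered(rxs, spec, start_day, end_day, censor_day):
    """Count covered days in [start, min(end, censor)] by marking a day grid."""
    merged = {}
    for d, q in rxs:
        merged[d] = merged.get(d, 0) + q
    hi = min(end_day, censor_day)
    covered = np.zeros(hi - start_day + 1, dtype=bool)
    for d, q in merged.items():
        for dd in range(d, d + refill_interval_days(spec, q)):
            if start_day <= dd <= hi:
                covered[dd - start_day] = True
    return int(covered.sum())


RULE_SPECS = [
    DrugSpec("uste_like", "u", "biologic", "sc", "fixed_weeks", 12),
    DrugSpec("ifx_like", "i", "biologic", "iv", "fixed_weeks", 8),
    DrugSpec("ada_like", "a", "biologic", "sc", "count_times_14"),
    DrugSpec("oral_like", "o", "systemic_steroid", "po", "prescription_days"),
]


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    spec_idx=st.integers(0, len(RULE_SPECS) - 1),
    days=st.lists(st.integers(0, 600), min_size=1, max_size=5),
    qty_seed=st.integers(0, 2**31 - 1),
    censor_gap=st.integers(0, 250),
)
def test_build_episodes_matches_day_scan(spec_idx, days, qty_seed, censor_gap):
    """The episode engine agrees with a brute-force day-by-day scanner."""
    spec = RULE_SPECS[spec_idx]
    rng = np.random.default_rng(qty_seed)
    qmax = 3 if spec.rule != "prescription_days" else 120
    rxs = sorted((d, int(rng.integers(1, qmax + 1))) for d in days)
    censor_day = max(d for d, _ in rxs) + censor_gap

    got = build_episodes([(day(d), q) for d, q in rxs], spec, day(censor_day))
    expected = day_scan_episodes(rxs, spec, censor_day)

    assert len(got) == len(expected)
    for ep, (start, last, sched, end, status, n_rx) in zip(got, expected):
        assert ep.start_date == day(start)
        assert ep.last_rx_date == day(last)
        assert ep.scheduled_next == day(sched)
        assert ep.end_date == day(end)
        assert ep.status == status
        assert ep.n_prescriptions == n_rx
        episode_rxs = [(d, q) for d, q in rxs if start <= d <= last]
        assert ep.covered_days == day_scan_covered(
            episode_rxs, spec, start, end, censor_day
        )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    spec_idx=st.integers(0, len(RULE_SPECS) - 1),
    days=st.lists(st.integers(0, 600), min_size=1, max_size=5),
    censor_gap=st.integers(0, 250),
)
def test_episode_invariants(spec_idx, days, censor_gap):
    """Episodes are ordered, non-overlapping, and never credit time past censor."""
    spec = RULE_SPECS[spec_idx]
    rxs = sorted((d, 1 if spec.rule != "prescription_days" else 30) for d in set(days))
    censor_day = max(d for d, _ in rxs) + censor_gap
    eps = build_episodes([(day(d), q) for d, q in rxs], spec, day(censor_day))
    assert eps, "at least one episode from >=1 prescription"
    for ep in eps:
        assert ep.start_date <= ep.last_rx_date <= ep.scheduled_next
        if ep.status == "discontinued":
            assert ep.end_date == ep.scheduled_next
    for a, b in zip(eps, eps[1:]):
        assert a.end_date < b.start_date
    total_covered = sum(ep.covered_days for ep in eps)
    assert total_covered <= censor_day - min(d for d, _ in rxs) + 1


class TestNovelty:
    def test_empty_history_is_new(self):
        assert classify_prescription_novelty([], day(100)) == "new"

    @pytest.mark.parametrize(
        "gap, expected",
        [(200, "new"), (183, "new"), (182, "new"), (181, "old"), (100, "old"), (1, "old")],
    )
    def test_washout_window_boundaries(self, gap, expected):
        """26-week washout is half-open: exactly 182 days prior stays new."""
        assert classify_prescription_novelty([day(300 - gap)], day(300)) == expected

    def test_history_must_precede_rx(self):
        with pytest.raises(ValueError):
            classify_prescription_novelty([day(300)], day(300))


class TestBuildEpisodes:
    def test_single_rx_discontinued_at_scheduled_date(self, catalog):
        # 12-week drug, one dose, censored at day 400: 400 > 84 + 91
        eps = build_episodes([(day(0), 1)], catalog.get("ustekinumab"), day(400))
        (ep,) = eps
        assert ep.status == "discontinued"
        assert ep.end_date == day(84)
        assert ep.covered_days == 84

    def test_ongoing_within_grace(self, catalog):
        eps = build_episodes(
            [(day(0), 1), (day(56), 1)], catalog.get("infliximab"), day(150)
        )
        (ep,) = eps
        assert ep.status == "ongoing_at_censor"
        assert ep.n_prescriptions == 2
        assert ep.end_date == day(150)

    def test_gap_of_exactly_91_days_does_not_discontinue(self, catalog):
        # 30-day supply at day 0: scheduled day 30; refill at day 121 = 30 + 91
        eps = build_episodes(
            [(day(0), 30), (day(121), 30)], catalog.get("prednisolone_po"), day(200)
        )
        assert len(eps) == 1
        assert eps[0].n_prescriptions == 2

    def test_gap_of_92_days_discontinues(self, catalog):
        eps = build_episodes(
            [(day(0), 30), (day(122), 30)], catalog.get("prednisolone_po"), day(200)
        )
        assert len(eps) == 2
        assert eps[0].status == "discontinued"
        assert eps[0].end_date == day(30)

    def test_same_day_lines_merged(self, catalog):
        eps = build_episodes(
            [(day(0), 15), (day(0), 15)], catalog.get("prednisolone_po"), day(40)
        )
        (ep,) = eps
        assert ep.n_prescriptions == 1
        assert ep.scheduled_next == day(30)

    def test_unsorted_input_rejected(self, catalog):
        with pytest.raises(ValueError):
            build_episodes([(day(10), 30), (day(0), 30)],
                           catalog.get("prednisolone_po"), day(100))

    def test_censor_before_last_rx_rejected(self, catalog):
        with pytest.raises(ValueError):
            build_episodes([(day(10), 30)], catalog.get("prednisolone_po"), day(5))

    def test_no_prescriptions_no_episodes(self, catalog):
        assert build_episodes([], catalog.get("prednisolone_po"), day(5)) == []


class TestFirstMtdAndFlags:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["patient_id", "drug_id", "start_date", "last_rx_date",
                     "scheduled_next", "end_date", "status", "covered_days",
                     "n_prescriptions"],
        )

    def test_earliest_episode_wins(self, catalog):
        eps = self._frame([
            ("p1", "vedolizumab", day(100), day(100), day(156), day(400),
             "ongoing_at_censor", 56, 1),
            ("p1", "tacrolimus", day(300), day(300), day(330), day(400),
             "ongoing_at_censor", 30, 1),
        ])
        res = first_mtd(eps, catalog)
        assert res.iloc[0]["drug_id"] == "vedolizumab"

    def test_tie_broken_lexicographically(self, catalog, caplog):
        eps = self._frame([
            ("p1", "tacrolimus", day(100), day(100), day(130), day(400),
             "ongoing_at_censor", 30, 1),
            ("p1", "infliximab", day(100), day(100), day(156), day(400),
             "ongoing_at_censor", 56, 1),
        ])
        with caplog.at_level("INFO", logger="ucclaims.episodes"):
            res = first_mtd(eps, catalog)
        assert res.iloc[0]["drug_id"] == "infliximab"
        assert any("tie" in rec.message for rec in caplog.records)

    def test_no_mtd_episodes_empty(self, catalog):
        eps = self._frame([
            ("p1", "mesalazine", day(0), day(0), day(189), day(400),
             "ongoing_at_censor", 189, 1),
        ])
        assert len(first_mtd(eps, catalog)) == 0

    @pytest.mark.parametrize(
        "aza_start, aza_end, ifx_start, expected",
        [
            (0, 300, 100, True),    # active across the start
            (150, 300, 100, False), # not yet started
            (0, 90, 100, False),    # already discontinued
            (100, 300, 100, True),  # starting the same day counts
        ],
    )
    def test_combination_flag(self, aza_start, aza_end, ifx_start, expected):
        aza = self._frame([
            ("p1", "azathioprine", day(aza_start), day(aza_start), day(aza_end),
             day(aza_end), "discontinued", 1, 1),
        ])
        assert combination_flag(day(ifx_start), aza) is expected

    def test_count_mtd_lines_counts_distinct_drugs(self, catalog):
        eps = self._frame([
            ("p1", "infliximab", day(0), day(0), day(56), day(56), "discontinued", 56, 1),
            ("p1", "infliximab", day(300), day(300), day(356), day(400),
             "ongoing_at_censor", 56, 1),
            ("p1", "tacrolimus", day(500), day(500), day(530), day(600),
             "ongoing_at_censor", 30, 1),
            ("p1", "mesalazine", day(0), day(0), day(189), day(600),
             "ongoing_at_censor", 189, 1),
        ])
        assert count_mtd_lines(eps, catalog) == 2  # two distinct MTDs, not 3 episodes


def test_build_all_episodes_groups_per_patient_drug(catalog):
    rx = pd.DataFrame(
        {
            "patient_id": ["a", "a", "b"],
            "drug_id": ["infliximab", "infliximab", "tacrolimus"],
            "date": [day(0), day(56), day(10)],
            "quantity": [1, 1, 30],
        }
    )
    censor = pd.Series({"a": day(150), "b": day(300)})
    eps = build_all_episodes(rx, catalog, censor)
    assert len(eps) == 2
    assert set(eps["patient_id"]) == {"a", "b"}
    b_row = eps[eps["patient_id"] == "b"].iloc[0]
    assert b_row["status"] == "discontinued"


def test_episodes_to_frame_empty():
    assert episodes_to_frame([]).empty
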