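"""Adaptive administration: selection, stopping, routing, imputation."""

import numpy as np
import pytest

from pcmcat import (
    CatSession,
    Item,
    ItemBank,
    PersonEstimate,
    PoolExhaustedError,
    StopRules,
    impute_unanswered,
    make_model_respondent,
    route_next_item,
    run_cat,
    select_next_item,
    session_trace,
    should_stop,
)
from pcmcat.pcm import score_moments


def _fake_session(thetas, sems, n_pool=24, administered=None):
    administered = administered or list(range(1, len(thetas) + 1))
    return CatSession(
        administered=administered,
        responses={i: 0 for i in administered},
        theta_history=list(thetas),
        sem_history=list(sems),
        pool_size=n_pool,
    )


class TestSelectNextItem:
    def test_maximal_information_item_chosen(self, bank):
        # at theta = 2, the 1-step item at 2.17 is near its information peak
        administered = [i for i in bank.pool_ids if i not in (15, 18)]
        assert score_moments(2.0, bank[15])[1] > score_moments(2.0, bank[18])[1]
        assert select_next_item(2.0, administered, bank) == 15

    def test_tie_broken_by_lowest_item_id(self):
        twins = ItemBank(
            [Item.from_difficulty(5, 0.4, 2), Item.from_difficulty(3, 0.4, 2)]
        )
        assert select_next_item(0.0, [], twins) == 3

    def test_first_item_random_but_seeded(self, bank):
        picks = {
            select_next_item(0.0, [], bank, np.random.default_rng(99), first=True)
            for _ in range(5)
        }
        assert len(picks) == 1
        other = select_next_item(0.0, [], bank, np.random.default_rng(100), first=True)
        assert other in bank.pool_ids

    def test_exhausted_pool_raises(self, bank):
        with pytest.raises(PoolExhaustedError):
            select_next_item(0.0, list(bank.pool_ids), bank)


class TestShouldStop:
    def test_reliability_rule_has_no_min_item_gate(self):
        session = _fake_session([0.1] * 4, [0.5, 0.4, 0.3, 0.05])
        stop, reason = should_stop(session, StopRules())
        assert stop and reason == "reliability"

    def test_residual_rule_arithmetic(self):
        # last-5 changes (0.04, 0.03, 0.02, 0.06, 0.05): mean 0.04 < 0.05
        thetas = [1.00, 1.04, 1.07, 1.09, 1.15, 1.20]
        session = _fake_session(thetas, [0.9] * 6)
        stop, reason = should_stop(session, StopRules())
        assert stop and reason == "residual"

    def test_residual_rule_gated_by_min_items(self):
        thetas = [1.00, 1.04, 1.07, 1.09, 1.15, 1.20]
        session = _fake_session(thetas, [0.9] * 6)
        stop, reason = should_stop(session, StopRules(min_items=7))
        assert not stop and reason is None

    def test_residual_above_threshold_keeps_going(self):
        thetas = [0.0, 0.3, 0.6, 0.9, 1.2, 1.5]
        session = _fake_session(thetas, [0.9] * 6)
        stop, reason = should_stop(session, StopRules())
        assert not stop

    def test_pool_exhaustion(self):
        session = _fake_session([0.0, 0.5, 0.7], [0.9, 0.8, 0.8], n_pool=3)
        stop, reason = should_stop(session, StopRules())
        assert stop and reason == "pool_exhausted"

    def test_max_items_cap(self):
        session = _fake_session([0.0, 0.5, 0.7], [0.9, 0.8, 0.8], n_pool=24)
        stop, reason = should_stop(session, StopRules(max_items=3))
        assert stop and reason == "max_items"


class TestRunCat:
    def test_session_contract(self, bank):
        respondent = make_model_respondent(0.0, bank, seed=4)
        session = run_cat(respondent, bank, seed=4)
        n = len(session.administered)
        assert 1 <= n <= 24
        assert len(set(session.administered)) == n
        assert set(session.administered) <= set(bank.pool_ids)
        assert len(session.theta_history) == n == len(session.sem_history)
        assert session.stop_reason in {
            "reliability", "residual", "pool_exhausted", "max_items",
        }
        assert isinstance(session.final, PersonEstimate)
        assert session.fit is not None

    def test_deterministic_given_seed(self, bank):
        a = run_cat(make_model_respondent(0.5, bank, seed=8), bank, seed=8)
        b = run_cat(make_model_respondent(0.5, bank, seed=8), bank, seed=8)
        assert a.administered == b.administered
        assert a.theta_history == b.theta_history
        assert a.stop_reason == b.stop_reason

    def test_shorter_than_full_form_on_average(self, bank):
        lengths = []
        for i in range(100):
            theta = np.random.default_rng([30, i]).standard_normal()
            session = run_cat(
                make_model_respondent(theta, bank, seed=[30, i]), bank, seed=[30, i]
            )
            lengths.append(len(session.administered))
        assert np.mean(lengths) < 24

    def test_sem_non_increasing_while_theta_stable(self, bank):
        session = run_cat(make_model_respondent(0.3, bank, seed=12), bank, seed=12)
        theta = np.array(session.theta_history)
        sem = np.array(session.sem_history)
        stable = np.abs(np.diff(theta)) < 0.2
        assert (np.diff(sem)[stable] <= 1e-12).all()

    def test_invalid_answer_reported_with_item(self, bank):
        with pytest.raises(ValueError, match="item"):
            run_cat(lambda iid: 99, bank, seed=1)

    def test_trace_has_one_row_per_step(self, bank):
        session = run_cat(make_model_respondent(0.0, bank, seed=2), bank, seed=2)
        trace = session_trace(session)
        assert list(trace["step"]) == list(range(1, len(session.administered) + 1))
        assert trace["residual"].iloc[:5].isna().all()
        if len(trace) >= 6:
            assert np.isfinite(trace["residual"].iloc[5:]).all()


class TestRouting:
    def test_skip_item_follows_route_map(self, routing_bank):
        assert route_next_item(routing_bank, 39, 1) == 40
        assert route_next_item(routing_bank, 39, 2) == 41

    def test_ordinary_item_falls_through_sequentially(self, routing_bank):
        assert route_next_item(routing_bank, 15, 0) == 16
        assert route_next_item(routing_bank, 40, 1) == 41

    def test_end_of_questionnaire_returns_none(self, routing_bank):
        assert route_next_item(routing_bank, 41, 0) is None

    def test_invalid_answer_rejected(self, routing_bank):
        with pytest.raises(ValueError):
            route_next_item(routing_bank, 15, 5)

    def test_every_path_strictly_increasing(self, routing_bank):
        """All answer paths traverse the questionnaire in increasing order."""
        def walk(current, answers):
            path = [current]
            for a in answers:
                nxt = route_next_item(routing_bank, current, a)
                if nxt is None:
                    break
                path.append(nxt)
                current = nxt
            return path

        rng = np.random.default_rng(0)
        for _ in range(20):
            answers = [int(rng.integers(0, 2)) for _ in range(30)]
            path = walk(15, answers)
            assert (np.diff(path) > 0).all()


class TestImputation:
    def test_fully_administered_session_unchanged(self, bank):
        rules = StopRules(max_items=24, reliability_target=0.999,
                          residual_threshold=1e-9)
        session = run_cat(make_model_respondent(0.0, bank, seed=6), bank, rules, seed=6)
        assert len(session.administered) == 24
        assert impute_unanswered(session, bank) == session.responses

    def test_high_ability_imputes_max_categories(self, bank):
        session = _fake_session([4.0], [0.3], administered=[15])
        session.final = PersonEstimate(10.0, 0.3, 0.5, 1, True, True)
        session.responses = {15: 1}
        completed = impute_unanswered(session, bank)
        for item in bank.pool_items():
            if item.item_id != 15:
                assert completed[item.item_id] == item.n_steps

    def test_midpoint_rounds_half_up(self):
        # unanswered 1-step item at theta = difficulty: expected score 0.5 -> 1
        target = Item.from_difficulty(2, 0.0, 1)
        solo = ItemBank([Item.from_difficulty(1, 0.0, 1), target])
        session = CatSession(
            administered=[1], responses={1: 1}, theta_history=[0.0],
            sem_history=[1.0], pool_size=2,
        )
        session.final = PersonEstimate(0.0, 1.0, 0.0, 1, True, False)
        assert impute_unanswered(session, solo)[2] == 1

    def test_unfinished_session_rejected(self, bank):
        with pytest.raises(ValueError):
            impute_unanswered(_fake_session([0.0], [1.0]), bank)


def test_stop_rule_validation():
    with pytest.raises(ValueError):
        StopRules(min_items=0)
    with pytest.raises(ValueError):
        StopRules(reliability_target=1.5)
    with pytest.raises(ValueError):
        StopRules(residual_threshold=0.0)
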