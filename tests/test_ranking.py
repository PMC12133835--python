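import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exsel.corpus import Demonstration, Explanation
from exsel.ranking import (
    RankingConfig,
    RelevanceProfile,
    err_contribution,
    err_score,
    hybrid_select,
    mmr_score,
    relevance_probabilities,
)

probs_strategy = st.lists(st.floats(0, 1), min_size=0, max_size=8)


class TestErrScore:
    def test_single_fully_relevant_item(self):
        assert err_score([1.0], 1.0) == pytest.approx(1.0)

    def test_all_zero_probabilities(self):
        assert err_score([0.0, 0.0, 0.0], 0.5) == 0.0

    def test_hand_expanded_two_item_case(self):
        # 0.85*0.5 + (1/2)*(1-0.425)*0.425
        assert err_score([0.5, 0.5], 0.85) == pytest.approx(0.5471875, abs=1e-12)

    def test_empty_list_scores_zero(self):
        assert err_score([], 0.85) == 0.0

    def test_rejects_out_of_range_inputs(self):
        with pytest.raises(ValueError):
            err_score([1.2], 0.85)
        with pytest.raises(ValueError):
            err_score([0.5], 0.0)

    @given(probs_strategy)
    def test_bounded_by_harmonic_number(self, probs):
        n = len(probs)
        h_n = sum(1.0 / k for k in range(1, n + 1))
        s = err_score(probs, 0.85)
        assert 0.0 <= s <= h_n + 1e-12

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=6), st.data())
    def test_promoting_higher_probability_never_decreases_err(self, probs, data):
        i = data.draw(st.integers(0, len(probs) - 2))
        lo, hi = sorted(probs[i : i + 2])
        worse = probs[:i] + [lo, hi] + probs[i + 2 :]
        better = probs[:i] + [hi, lo] + probs[i + 2 :]
        assert err_score(better, 0.85) >= err_score(worse, 0.85) - 1e-12


class TestErrContribution:
    def test_first_position_identity(self):
        assert err_contribution(1.0, [], 1.0) == pytest.approx(1.0)

    def test_second_term_of_worked_example(self):
        assert err_contribution(0.5, [0.5], 0.85) == pytest.approx(0.1221875, abs=1e-12)

    def test_contributions_sum_to_err_score(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            probs = rng.random(int(rng.integers(1, 8))).tolist()
            gamma = float(rng.uniform(0.05, 1.0))
            total = sum(
                err_contribution(p, probs[:i], gamma) for i, p in enumerate(probs)
            )
            assert total == pytest.approx(err_score(probs, gamma), abs=1e-12)


class TestMmrScore:
    def test_pure_relevance_limit(self):
        assert mmr_score(0.73, [0.9, 0.2], 1.0) == pytest.approx(0.73)

    def test_empty_selected_set_max_is_zero(self):
        assert mmr_score(0.8, [], 0.5) == pytest.approx(0.4)

    def test_worked_example(self):
        assert mmr_score(0.9, [0.7, 0.2], 0.5) == pytest.approx(0.10)

    def test_rejects_unclipped_similarities(self):
        with pytest.raises(ValueError):
            mmr_score(-0.2, [], 0.5)
        with pytest.raises(ValueError):
            mmr_score(0.5, [1.3], 0.5)


class TestRelevanceProbabilities:
    def test_single_candidate_gets_probability_one(self, backend, criteria):
        cands = [Explanation(expl_id="e0", text="feeling hopeless and sad", demo_id="d0")]
        prof = relevance_probabilities(cands, "why so sad", [], criteria, backend)
        assert prof.probs == (1.0,)

    def test_identical_candidates_split_evenly(self, backend, criteria):
        cands = [
            Explanation(expl_id="e0", text="same words here", demo_id="d0"),
            Explanation(expl_id="e1", text="same words here", demo_id="d0"),
        ]
        prof = relevance_probabilities(cands, "the query text", [], criteria, backend)
        assert prof.probs[0] == pytest.approx(prof.probs[1])
        assert sum(prof.probs) == pytest.approx(1.0, abs=1e-9)

    def test_query_overlap_raises_probability(self, backend, criteria):
        cands = [
            Explanation(expl_id="hit", text="shared tokens with query words", demo_id="d0"),
            Explanation(expl_id="miss", text="entirely unrelated vocabulary list", demo_id="d0"),
        ]
        prof = relevance_probabilities(
            cands, "shared tokens with query please", [], criteria, backend
        )
        assert prof.prob_of("hit") > prof.prob_of("miss")

    def test_empty_candidates_rejected(self, backend, criteria):
        with pytest.raises(ValueError):
            relevance_probabilities([], "query", [], criteria, backend)

    def test_criteria_required_when_weighted(self, backend):
        cands = [Explanation(expl_id="e0", text="some rationale", demo_id="d0")]
        with pytest.raises(ValueError, match="criteria"):
            relevance_probabilities(cands, "q", [], [], backend, RankingConfig())
        # weight 0 works without criteria
        prof = relevance_probabilities(
            cands, "q words", [], [], backend, RankingConfig(criteria_weight=0.0)
        )
        assert prof.probs == (1.0,)


class TestRankingConfig:
    def test_defaults(self):
        cfg = RankingConfig()
        assert (cfg.gamma, cfg.lam, cfg.k) == (0.85, 0.5, 2)

    @pytest.mark.parametrize(
        "kwargs", [{"gamma": 1.5}, {"gamma": 0.0}, {"lam": -0.1}, {"k": 0}, {"criteria_weight": 2.0}]
    )
    def test_rejects_out_of_range(self, kwargs):
        with pytest.raises(ValueError):
            RankingConfig(**kwargs)


class TestHybridSelect:
    def _profile(self, cands, probs):
        return RelevanceProfile(
            candidate_ids=tuple(c.expl_id for c in cands), probs=tuple(probs)
        )

    def test_k1_pure_relevance_picks_most_query_similar(self, backend):
        cands = [
            Explanation(expl_id="far", text="totally different topic entirely", demo_id="d0"),
            Explanation(expl_id="near", text="query words appear here exactly", demo_id="d0"),
        ]
        prof = self._profile(cands, [0.3, 0.7])
        cfg = RankingConfig(lam=1.0, k=1)
        sel = hybrid_select(cands, prof, "query words appear here exactly", backend, cfg)
        assert [i.expl_id for i in sel.selected] == ["near"]

    def test_duplicate_is_never_selected_over_distinct_candidate(self, backend):
        cands = [
            Explanation(expl_id="A", text="sad lonely evening thoughts", demo_id="d0"),
            Explanation(expl_id="Adup", text="sad lonely evening thoughts", demo_id="d0"),
            Explanation(expl_id="B", text="worried about sleepless nights", demo_id="d0"),
        ]
        prof = self._profile(cands, [1 / 3] * 3)
        sel = hybrid_select(cands, prof, "sad and sleepless", backend, RankingConfig(k=2))
        assert {i.expl_id for i in sel.selected} == {"A", "B"}

    def test_pool_exhaustion_returns_everything(self, backend):
        cands = [
            Explanation(expl_id=f"e{i}", text=f"candidate number {i} text", demo_id="d0")
            for i in range(3)
        ]
        prof = self._profile(cands, [0.2, 0.5, 0.3])
        sel = hybrid_select(cands, prof, "candidate text", backend, RankingConfig(k=10))
        assert len(sel.selected) == 3
        assert sel.pool_size == 3

    def test_profile_must_cover_candidates(self, backend):
        cands = [Explanation(expl_id="e0", text="words here", demo_id="d0")]
        prof = RelevanceProfile(candidate_ids=("other",), probs=(1.0,))
        with pytest.raises(ValueError):
            hybrid_select(cands, prof, "q", backend, RankingConfig())

    def test_greedy_scores_reproduced_by_bruteforce_rescoring(self, backend, criteria):
        """Independent re-scoring of the greedy-chosen prefix reproduces S_comb."""
        from exsel.embeddings import clip01, cosine_similarity
        from exsel.ranking import err_contribution as errc, mmr_score as mmr

        rng = np.random.default_rng(11)
        vocab = "apple river stone cloud letter garden mirror candle".split()
        for trial in range(10):
            n = int(rng.integers(2, 7))
            cands = [
                Explanation(
                    expl_id=f"e{i}",
                    text=" ".join(rng.choice(vocab, size=3, replace=False)),
                    demo_id="d0",
                )
                for i in range(n)
            ]
            query = " ".join(rng.choice(vocab, size=3, replace=False))
            cfg = RankingConfig(k=min(3, n))
            prof = relevance_probabilities(cands, query, [], criteria, backend, cfg)
            sel = hybrid_select(cands, prof, query, backend, cfg)

            # brute-force: recompute each position's score from raw parts
            q_vec = backend.embed(query)
            vecs = {c.expl_id: backend.embed(c.text) for c in cands}
            chosen_probs, chosen_ids = [], []
            for item in sel.selected:
                p = prof.prob_of(item.expl_id)
                sims_sel = [
                    clip01(cosine_similarity(vecs[item.expl_id], vecs[cid]))
                    for cid in chosen_ids
                ]
                s_q = clip01(cosine_similarity(vecs[item.expl_id], q_vec))
                expected = errc(p, chosen_probs, cfg.gamma) + mmr(s_q, sims_sel, cfg.lam)
                assert item.s_comb == pytest.approx(expected, abs=1e-12)
                chosen_probs.append(p)
                chosen_ids.append(item.expl_id)

    def test_lambda_zero_second_pick_prefers_dissimilar(self, backend):
        cands = [
            Explanation(expl_id="top", text="alpha beta gamma delta", demo_id="d0"),
            Explanation(expl_id="redundant", text="alpha beta gamma epsilon", demo_id="d0"),
            Explanation(expl_id="diverse", text="zeta eta theta iota", demo_id="d0"),
        ]
        prof = self._profile(cands, [0.4, 0.3, 0.3])
        sel = hybrid_select(
            cands, prof, "alpha beta gamma delta", backend, RankingConfig(lam=0.0, k=2)
        )
        assert [i.expl_id for i in sel.selected][1] == "diverse"
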