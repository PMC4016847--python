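"""Ellman-assay statistics: inhibition, replicate summaries, ANOVA/LSD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import saposcreen as sp
from saposcreen.bioassay import AssayError, anova_lsd, inhibition_percent, rank_agents, summarize


class TestInhibitionPercent:
    def test_sample_equal_to_control_is_zero(self):
        assert inhibition_percent(1.0, 1.0, 0.1) == pytest.approx(0.0)

    def test_sample_equal_to_blank_is_full_inhibition(self):
        assert inhibition_percent(0.1, 1.0, 0.1) == pytest.approx(100.0)

    def test_halfway_sample(self):
        assert inhibition_percent(0.55, 1.00, 0.10) == pytest.approx(50.0)

    def test_control_not_above_blank_is_assay_failure(self):
        with pytest.raises(AssayError):
            inhibition_percent(0.5, 0.1, 0.1)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=0.0, max_value=2.0),
        st.floats(min_value=0.5, max_value=3.0),
        st.floats(min_value=0.0, max_value=0.4),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_affine_invariance(self, sample, control_extra, blank, k):
        control = blank + control_extra
        a = inhibition_percent(sample, control, blank)
        b = inhibition_percent(k * sample, k * control, k * blank)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-7)


class TestSummarize:
    def test_constant_replicates(self):
        r = summarize([50, 50, 50])
        assert (r.mean_inhibition, r.sem, r.n) == (50.0, 0.0, 3)

    def test_sem_is_sd_over_sqrt_n(self):
        r = summarize([40, 50, 60])
        assert r.mean_inhibition == pytest.approx(50.0)
        assert r.sem == pytest.approx(10.0 / math.sqrt(3), abs=1e-9)

    def test_fewer_than_three_replicates_rejected(self):
        with pytest.raises(AssayError):
            summarize([50.0])


class TestAnovaLSD:
    def test_identical_groups_show_no_significant_pairs(self):
        rng = np.random.default_rng(0)
        g = {k: (50 + rng.normal(0, 1, 6)).tolist() for k in "abc"}
        g["b"] = g["a"]  # literally identical pair
        res = anova_lsd(g)
        assert not any(
            c.significant for c in res.pairs if {c.agent_a, c.agent_b} == {"a", "b"}
        )

    def test_separated_groups_are_significant(self):
        rng = np.random.default_rng(1)
        res = anova_lsd(
            {
                "low": (0 + rng.normal(0, 0.5, 5)).tolist(),
                "high": (100 + rng.normal(0, 0.5, 5)).tolist(),
            }
        )
        assert res.p < 0.05
        assert res.significant_pairs() == [("low", "high")]

    def test_degenerate_variance_is_an_error(self):
        with pytest.raises(AssayError):
            anova_lsd({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})

    def test_flags_match_permutation_oracle(self):
        """LSD significance flags agree with a permutation-test oracle.

        Three groups with one clearly shifted mean; both routes are run
        over independent seeds and must agree in >= 95% of them.
        """

        def permutation_flags(groups, alpha=0.05, n_perm=400, seed=0):
            rng = np.random.default_rng(seed)
            names = list(groups)
            arrays = {k: np.asarray(v) for k, v in groups.items()}
            # omnibus: permutation F
            pooled = np.concatenate(list(arrays.values()))
            sizes = [arrays[k].size for k in names]

            def fstat(values):
                parts, i = [], 0
                for s in sizes:
                    parts.append(values[i : i + s])
                    i += s
                grand = values.mean()
                ssb = sum(p.size * (p.mean() - grand) ** 2 for p in parts)
                ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
                return (ssb / (len(parts) - 1)) / (ssw / (values.size - len(parts)))

            f_obs = fstat(pooled)
            f_null = [
                fstat(rng.permutation(pooled)) for _ in range(n_perm)
            ]
            omnibus = (1 + sum(f >= f_obs for f in f_null)) / (1 + n_perm) < alpha
            flags = {}
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    x, y = arrays[a], arrays[b]
                    obs = abs(x.mean() - y.mean())
                    both = np.concatenate([x, y])
                    null = []
                    for _ in range(n_perm):
                        p = rng.permutation(both)
                        null.append(abs(p[: x.size].mean() - p[x.size :].mean()))
                    p_pair = (1 + sum(d >= obs for d in null)) / (1 + n_perm)
                    flags[(a, b)] = omnibus and p_pair < alpha
            return flags

        agree = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            groups = {
                "a": (40 + rng.normal(0, 5, 6)).tolist(),
                "b": (60 + rng.normal(0, 5, 6)).tolist(),
                "c": (41 + rng.normal(0, 5, 6)).tolist(),
            }
            res = anova_lsd(groups)
            lsd_flags = {(c.agent_a, c.agent_b): c.significant for c in res.pairs}
            oracle = permutation_flags(groups, seed=seed)
            agree += lsd_flags == oracle
        assert agree >= 0.95 * n_seeds


class TestRanking:
    def test_extract_screen_top_agent(self):
        df = sp.read_screen_table("extract_screen")
        ranked = rank_agents(sp.screen_results(df, "BuChE"))
        assert ranked[0].agent_id == "Ethyl acetate/ultrasonic"
        assert ranked[0].mean_inhibition == pytest.approx(44.1)

    def test_compound_screen_top_agent(self):
        df = sp.read_screen_table("compound_screen")
        ranked = rank_agents(sp.screen_results(df, "BuChE"))
        assert ranked[0].agent_id == "3"
        assert ranked[0].mean_inhibition == pytest.approx(75.8)

    def test_not_detected_entries_are_excluded_not_zero(self):
        df = sp.read_screen_table("extract_screen")
        ache = sp.screen_results(df, "AChE")
        assert ache == []  # no extract showed AChE inhibition

    def test_reference_inhibitor_not_ranked_by_default(self):
        df = sp.read_screen_table("compound_screen")
        agents = {r.agent_id for r in sp.screen_results(df, "BuChE")}
        assert "Donepezil" not in agents
        with_ref = sp.screen_results(df, "BuChE", include_reference=True)
        assert rank_agents(with_ref)[0].agent_id == "Donepezil"

    def test_tie_breaks_by_sem_then_name(self):
        mk = lambda agent, mean, sem: sp.InhibitionResult(agent, "BuChE", mean, sem, 3)
        ranked = rank_agents([mk("b", 40, 0.5), mk("a", 40, 0.5), mk("c", 40, 0.2)])
        assert [r.agent_id for r in ranked] == ["c", "a", "b"]

    def test_single_agent_ranks_itself(self):
        r = sp.InhibitionResult("only", "AChE", 10.0, 0.1, 3)
        assert rank_agents([r]) == [r]

    def test_empty_and_mixed_enzyme_inputs_rejected(self):
        with pytest.raises(AssayError):
            rank_agents([])
        with pytest.raises(AssayError):
            rank_agents(
                [
                    sp.InhibitionResult("a", "AChE", 10, 0.1, 3),
                    sp.InhibitionResult("b", "BuChE", 10, 0.1, 3),
                ]
            )
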