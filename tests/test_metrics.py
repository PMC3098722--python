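import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evls import (
    MetricError,
    accumulation_curve,
    auac,
    bedroc,
    enrichment_factor,
    max_enrichment_factor,
    metric_report,
    rie,
    roc_auc,
    roc_from_auac,
    truncate_decimals,
)

from conftest import ranking_from_binder_positions


# ---------------------------------------------------------------------------
# Naive reference implementations (pure-python enumeration; kept independent
# of the production code paths)
# ---------------------------------------------------------------------------

def naive_metrics(binder_positions, n_total, chi=None, alpha=20.0):
    positions = sorted(binder_positions)
    n = len(positions)
    fa = [sum(1 for p in positions if p <= k) for k in range(1, n_total + 1)]
    out = {"auac": sum(fa) / (n * n_total)}
    decoys = [k for k in range(1, n_total + 1) if k not in set(positions)]
    wins = sum(1 for b in positions for d in decoys if b < d)
    out["roc"] = wins / (n * len(decoys)) if decoys else None
    if chi is not None:
        k = math.floor(chi * n_total)
        out["ef"] = fa[k - 1] / (n * chi)
    num = sum(math.exp(-alpha * p / n_total) for p in positions)
    den = (n / n_total) * (1 - math.exp(-alpha)) / (math.exp(alpha / n_total) - 1)
    out["rie"] = num / den
    ideal = sum(math.exp(-alpha * p / n_total) for p in range(1, n + 1)) / den
    worst = sum(math.exp(-alpha * p / n_total)
                for p in range(n_total - n + 1, n_total + 1)) / den
    out["bedroc"] = (out["rie"] - worst) / (ideal - worst) if n < n_total else None
    return out


class TestAccumulationCurve:
    @pytest.mark.parametrize(
        "positions, n_total, expected",
        [
            ({1, 3}, 4, [1, 1, 2, 2]),
            ({1, 2, 3}, 6, [1, 2, 3, 3, 3, 3]),  # ideal: F_a(k) = min(k, n)
            ({1, 4, 7}, 10, [1, 1, 1, 2, 2, 2, 3, 3, 3, 3]),
        ],
    )
    def test_counts_binders_at_or_above_rank(self, positions, n_total, expected):
        ranked, lib = ranking_from_binder_positions(positions, len(positions), n_total)
        curve = accumulation_curve(ranked, lib)
        assert curve.values.tolist() == expected
        assert curve.values[-1] == curve.n_binders

    def test_no_actives_is_an_error(self):
        ranked, lib = ranking_from_binder_positions({1}, 1, 3)
        decoys_only = lib.subset([l for l in lib.ligand_ids if l.startswith("D")])
        from evls import RankedList

        sub = RankedList("T", "x", [e for e in ranked.entries
                                    if e.ligand_id.startswith("D")])
        with pytest.raises(MetricError, match="without actives"):
            accumulation_curve(sub, decoys_only)


class TestAuac:
    @pytest.mark.parametrize(
        "positions, n_total, expected",
        [
            ({1}, 2, 1.0),          # ideal with n=1: 1 - (n-1)/(2N)
            ({2}, 2, 0.5),          # worst: (n+1)/(2N)
            ({1, 4, 7}, 10, 0.70),  # 21/30
        ],
    )
    def test_known_values(self, positions, n_total, expected):
        ranked, lib = ranking_from_binder_positions(positions, len(positions), n_total)
        assert auac(accumulation_curve(ranked, lib)) == pytest.approx(expected)


class TestRocAuc:
    def test_pair_enumeration_value(self):
        ranked, lib = ranking_from_binder_positions({1, 4, 7}, 3, 10)
        assert roc_auc(ranked, lib) == pytest.approx(15 / 21)

    def test_matches_linear_transform_of_auac(self):
        ranked, lib = ranking_from_binder_positions({1, 4, 7}, 3, 10)
        a = auac(accumulation_curve(ranked, lib))
        assert roc_from_auac(a, 3, 10) == pytest.approx(15 / 21)
        assert roc_auc(ranked, lib) == pytest.approx(roc_from_auac(a, 3, 10))

    def test_all_scores_tied_gives_half_credit(self):
        from evls import RankedList, RankEntry

        entries = [RankEntry(l, -10.0, 0.0) for l in ["B0", "D0", "B1", "D1"]]
        ranked = RankedList("T", "x", entries)
        from conftest import make_library

        lib = make_library(2, 2)
        assert roc_auc(ranked, lib) == pytest.approx(0.5)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(5, 60), st.data())
    def test_linear_transform_identity_for_tie_free_rankings(self, n_total, data):
        n = data.draw(st.integers(1, n_total - 1))
        positions = data.draw(
            st.sets(st.integers(1, n_total), min_size=n, max_size=n))
        ranked, lib = ranking_from_binder_positions(positions, n, n_total)
        a = auac(accumulation_curve(ranked, lib))
        assert roc_auc(ranked, lib) == pytest.approx(
            roc_from_auac(a, n, n_total), abs=1e-12)


class TestEnrichmentFactor:
    def test_ideal_rankings_match_closed_form(self):
        # ideal EF_1% for (n=8, N=163) and (n=32, N=2617)
        for n, n_total, expected in [(8, 163, 12.5), (32, 2617, 81.25)]:
            ranked, lib = ranking_from_binder_positions(
                set(range(1, n + 1)), n, n_total)
            ef = enrichment_factor(accumulation_curve(ranked, lib), 0.01)
            assert ef == pytest.approx(expected)
            assert ef == pytest.approx(max_enrichment_factor(n, n_total, 0.01))

    def test_whole_list_fraction_gives_ef_one(self):
        ranked, lib = ranking_from_binder_positions({2, 5}, 2, 10)
        assert enrichment_factor(accumulation_curve(ranked, lib), 1.0) == 1.0

    def test_direct_evaluation(self):
        ranked, lib = ranking_from_binder_positions({1, 4, 7}, 3, 10)
        ef = enrichment_factor(accumulation_curve(ranked, lib), 0.2)
        assert ef == pytest.approx(1 / 0.6)

    def test_too_small_fraction_is_an_error(self):
        ranked, lib = ranking_from_binder_positions({1}, 1, 10)
        with pytest.raises(MetricError, match="too small"):
            enrichment_factor(accumulation_curve(ranked, lib), 0.01)


class TestRieBedroc:
    def test_ideal_ranking_equals_direct_formula_at_top_ranks(self):
        n, n_total, alpha = 5, 50, 20.0
        expected = naive_metrics(range(1, n + 1), n_total, alpha=alpha)["rie"]
        assert rie(np.arange(1, n + 1), n, n_total, alpha) == pytest.approx(expected)

    def test_all_actives_gives_rie_one(self):
        assert rie(np.arange(1, 11), 10, 10, 20.0) == pytest.approx(1.0)

    def test_bedroc_endpoints(self):
        n, n_total = 8, 163
        ideal = bedroc(np.arange(1, n + 1), n, n_total, 20.0)
        worst = bedroc(np.arange(n_total - n + 1, n_total + 1), n, n_total, 20.0)
        assert ideal == pytest.approx(1.0)
        assert worst == pytest.approx(0.0)


class TestTruncation:
    @pytest.mark.parametrize("x, expected", [
        (81.25, 81.2), (77.7777, 77.7), (46.15, 46.1), (12.5, 12.5), (0.978, 0.9),
    ])
    def test_truncates_not_rounds(self, x, expected):
        assert truncate_decimals(x, 1) == pytest.approx(expected)


class TestProperties:
    @settings(max_examples=60, deadline=None)
    @given(st.integers(6, 40), st.data())
    def test_moving_a_binder_up_never_decreases_any_metric(self, n_total, data):
        n = data.draw(st.integers(1, n_total // 2))
        positions = sorted(data.draw(
            st.sets(st.integers(2, n_total), min_size=n, max_size=n)))
        # move the worst-ranked binder strictly up to a free position
        free = [k for k in range(1, positions[-1]) if k not in set(positions)]
        if not free:
            return
        better = positions[:-1] + [free[0]]
        before = full_report(positions, n_total)
        after = full_report(better, n_total)
        for key in before:
            assert after[key] >= before[key] - 1e-12

    def test_metrics_depend_only_on_binder_positions(self):
        a = full_report([2, 5, 9], 12)
        b = full_report([2, 5, 9], 12)
        assert a == b

    @settings(max_examples=40, deadline=None)
    @given(st.integers(2, 8), st.data())
    def test_oracle_equivalence_small_libraries(self, n_total, data):
        n = data.draw(st.integers(1, n_total - 1))
        positions = data.draw(
            st.sets(st.integers(1, n_total), min_size=n, max_size=n))
        ranked, lib = ranking_from_binder_positions(positions, n, n_total)
        ref = naive_metrics(positions, n_total, chi=1.0)
        curve = accumulation_curve(ranked, lib)
        assert auac(curve) == pytest.approx(ref["auac"], abs=1e-12)
        assert roc_auc(ranked, lib) == pytest.approx(ref["roc"], abs=1e-12)
        ranks = ranked.binder_ranks(lib)
        assert rie(ranks, n, n_total) == pytest.approx(ref["rie"], abs=1e-12)
        assert bedroc(ranks, n, n_total) == pytest.approx(ref["bedroc"], abs=1e-12)


def full_report(positions, n_total):
    ranked, lib = ranking_from_binder_positions(set(positions), len(positions), n_total)
    rep = metric_report(ranked, lib, chi_values=(1 / n_total + 1e-9,))
    return {"auac": rep.auac, "roc": rep.roc_auc, "rie": rep.rie,
            "bedroc": rep.bedroc, "ef": list(rep.ef.values())[0]}


class TestMetricReport:
    def test_ideal_and_worst_rankings(self):
        n, n_total = 3, 30
        ideal, lib = ranking_from_binder_positions(set(range(1, n + 1)), n, n_total)
        rep = metric_report(ideal, lib, chi_values=(0.10,))
        assert rep.auac == pytest.approx(1 - (n - 1) / (2 * n_total))
        assert rep.roc_auc == 1.0
        assert rep.bedroc == pytest.approx(1.0)
        assert rep.ef[0.10] == pytest.approx(max_enrichment_factor(n, n_total, 0.10))
        worst, lib = ranking_from_binder_positions(
            set(range(n_total - n + 1, n_total + 1)), n, n_total)
        rep = metric_report(worst, lib, chi_values=(0.10,))
        assert rep.roc_auc == 0.0
        assert rep.bedroc == pytest.approx(0.0)
        assert rep.ef[0.10] == 0.0
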