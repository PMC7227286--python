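import random

import numpy as np
import pytest

from burdenalign import (
    FieldYearBaseline,
    IncomeGroup,
    JournalEntry,
    JournalTable,
    PublicationRecord,
    Quartile,
    QuartileIndex,
    assign_quartiles,
    field_year_baselines,
    income_group_weights,
    mncs,
    pp_top10,
    publication_shares,
    q1_share,
    relative_research_effort,
)
from burdenalign.errors import UndefinedRatioError, UndefinedShareError


def journal_table(ifs, year=2012, category="F01"):
    t = JournalTable()
    for i, impact in enumerate(ifs):
        t.add(
            JournalEntry(
                journal_id=f"J{i:03d}",
                year=year,
                subject_categories=frozenset({category}),
                impact_factor=impact,
            )
        )
    return t


def rec(pub_id="p", journal_id="J000", citations=0, year=2012):
    return PublicationRecord(
        pub_id=pub_id, year=year, doc_type="article",
        journal_id=journal_id, citations=citations,
    )


class TestQuartiles:
    def test_eight_distinct_ifs_give_two_q1(self):
        q = assign_quartiles(journal_table([8, 7, 6, 5, 4, 3, 2, 1]), "F01", 2012)
        assert sum(1 for v in q.values() if v is Quartile.Q1) == 2
        assert q["J000"] is Quartile.Q1 and q["J001"] is Quartile.Q1

    def test_hundred_distinct_ifs_give_25_per_quartile(self):
        q = assign_quartiles(journal_table(list(range(100, 0, -1))), "F01", 2012)
        counts = {v: 0 for v in Quartile}
        for v in q.values():
            counts[v] += 1
        assert all(c == 25 for c in counts.values())

    def test_single_journal_is_q1(self):
        q = assign_quartiles(journal_table([1.0]), "F01", 2012)
        assert q == {"J000": Quartile.Q1}

    def test_empty_category_year_is_empty(self):
        assert assign_quartiles(journal_table([1.0]), "F99", 2012) == {}

    def test_ties_share_best_quartile_of_block(self):
        # 4 journals, IFs [5, 3, 3, 1]: the tied block spans ranks 2-3,
        # whose best rank 2 gives Q2 to both
        q = assign_quartiles(journal_table([5, 3, 3, 1]), "F01", 2012)
        assert q["J001"] is Quartile.Q2 and q["J002"] is Quartile.Q2
        assert q["J000"] is Quartile.Q1 and q["J003"] is Quartile.Q4

    def test_invariant_under_monotone_transform_of_ifs(self):
        rng = random.Random(8)
        ifs = [round(rng.uniform(0.1, 20), 3) for _ in range(37)]
        q1 = assign_quartiles(journal_table(ifs), "F01", 2012)
        q2 = assign_quartiles(journal_table([x**3 + 1 for x in ifs]), "F01", 2012)
        assert q1 == q2

    def test_best_quartile_across_categories(self):
        t = JournalTable()
        # JA is bottom of F01 (Q4 of 8) but the only journal of F02 (Q1)
        for i, impact in enumerate([8, 7, 6, 5, 4, 3, 2]):
            t.add(JournalEntry(f"J{i}", 2012, frozenset({"F01"}), impact))
        t.add(JournalEntry("JA", 2012, frozenset({"F01", "F02"}), 1.0))
        assert QuartileIndex(t).best_quartile("JA", 2012) is Quartile.Q1

    def test_nearest_year_fallback(self):
        t = journal_table([4, 3, 2, 1], year=2011)
        assert QuartileIndex(t).best_quartile("J000", 2014) is Quartile.Q1


class TestFieldYearBaselines:
    def test_skewed_field_gives_zero_threshold(self):
        """Nine uncited papers and one at 10: t=0, no tie credit, top pub full."""
        t = journal_table([1.0] * 1)
        records = [rec(pub_id=f"p{i}", citations=0) for i in range(9)]
        records.append(rec(pub_id="p9", citations=10))
        base = field_year_baselines(records, t)[("F01", 2012)]
        assert base.mean_citations == pytest.approx(1.0)
        assert base.top10_threshold == 0
        assert base.tie_fraction == pytest.approx(0.0)
        assert pp_top10(records, [1.0] * 10, {("F01", 2012): base}, t) == pytest.approx(0.1)

    def test_all_equal_citations_share_tie_credit(self):
        t = journal_table([1.0])
        records = [rec(pub_id=f"p{i}", citations=5) for i in range(10)]
        base = field_year_baselines(records, t)[("F01", 2012)]
        assert base.top10_threshold == 5
        assert base.tie_fraction == pytest.approx(0.1)

    def test_threshold_and_tie_match_exhaustive_scan(self):
        rng = np.random.default_rng(13)
        t = journal_table([1.0])
        for trial in range(20):
            n = int(rng.integers(5, 200))
            cites = rng.negative_binomial(1.5, 0.2, size=n)
            records = [rec(pub_id=f"p{i}", citations=int(c)) for i, c in enumerate(cites)]
            base = field_year_baselines(records, t)[("F01", 2012)]
            # exhaustive scan over candidate thresholds
            best = min(
                (v for v in set(cites) if (cites > v).sum() <= 0.1 * n),
            )
            assert base.top10_threshold == best
            above = (cites > best).sum()
            ties = (cites == best).sum()
            assert base.tie_fraction == pytest.approx((0.1 * n - above) / ties)
            assert above <= 0.1 * n


class TestCitationIndicators:
    def test_records_at_field_mean_score_one(self):
        t = journal_table([1.0])
        records = [rec(pub_id=f"p{i}", citations=4) for i in range(8)]
        base = field_year_baselines(records, t)
        assert mncs(records, [1.0] * 8, base, t) == pytest.approx(1.0)

    def test_uncited_subset_scores_zero(self):
        t = journal_table([1.0])
        records = [rec(pub_id=f"p{i}", citations=i) for i in range(10)]
        base = field_year_baselines(records, t)
        assert mncs(records[:1], [1.0], base, t) == pytest.approx(0.0)

    def test_whole_corpus_identities(self):
        """World MNCS = 1 and PPtop10 = 10% over a single-category reference set."""
        rng = np.random.default_rng(21)
        t = journal_table([1.0])
        records = [
            rec(pub_id=f"p{i}", citations=int(c))
            for i, c in enumerate(rng.negative_binomial(1.2, 0.12, size=500))
        ]
        base = field_year_baselines(records, t)
        w = [1.0] * len(records)
        assert mncs(records, w, base, t) == pytest.approx(1.0, abs=1e-9)
        assert pp_top10(records, w, base, t) == pytest.approx(0.1, abs=1e-9)

    def test_all_above_threshold_gives_one(self):
        t = journal_table([1.0])
        records = [rec(pub_id=f"p{i}", citations=c) for i, c in enumerate([0] * 18 + [50, 60])]
        base = field_year_baselines(records, t)
        top = [r for r in records if r.citations >= 50]
        assert pp_top10(top, [1.0, 1.0], base, t) == pytest.approx(1.0)

    def test_multi_category_scores_average_equally(self):
        t = JournalTable()
        t.add(JournalEntry("J0", 2012, frozenset({"A", "B"}), 1.0))
        base = {
            ("A", 2012): FieldYearBaseline("A", 2012, 2.0, 5, 0.0, 10),
            ("B", 2012): FieldYearBaseline("B", 2012, 8.0, 20, 0.0, 10),
        }
        r = rec(journal_id="J0", citations=8)
        # (8/2 + 8/8) / 2 = 2.5
        assert mncs([r], [1.0], base, t) == pytest.approx(2.5)

    def test_random_subsets_match_credit_sum_oracle(self):
        rng = np.random.default_rng(17)
        t = journal_table([1.0])
        records = [
            rec(pub_id=f"p{i}", citations=int(c))
            for i, c in enumerate(rng.negative_binomial(2, 0.2, size=120))
        ]
        base = field_year_baselines(records, t)
        b = base[("F01", 2012)]
        for _ in range(10):
            idx = rng.choice(len(records), size=30, replace=False)
            sub = [records[i] for i in idx]
            credits = [
                1.0 if r.citations > b.top10_threshold
                else (b.tie_fraction if r.citations == b.top10_threshold else 0.0)
                for r in sub
            ]
            assert pp_top10(sub, [1.0] * 30, base, t) == pytest.approx(
                sum(credits) / 30
            )


class TestSharesAndEffort:
    def test_single_record_full_share(self):
        assert publication_shares([{"k": 1.0}]) == {"k": 1.0}

    def test_symmetric_weights_equal_shares(self):
        shares = publication_shares([{"a": 0.5, "b": 0.5}, {"b": 0.5, "a": 0.5}])
        assert shares == {"a": pytest.approx(0.5), "b": pytest.approx(0.5)}

    def test_matches_weighted_crosstab_oracle(self):
        rng = random.Random(23)
        keymaps = []
        for _ in range(500):
            keys = rng.sample(["a", "b", "c", "d"], rng.randint(1, 3))
            w = 1.0 / len(keys)
            keymaps.append({k: w for k in keys})
        shares = publication_shares(keymaps)
        totals: dict[str, float] = {}
        for km in keymaps:
            for k, w in km.items():
                totals[k] = totals.get(k, 0.0) + w
        grand = sum(totals.values())
        for k in totals:
            assert shares[k] == pytest.approx(totals[k] / grand, abs=1e-12)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_scope_is_undefined(self):
        with pytest.raises(UndefinedShareError):
            publication_shares([])

    def test_effort_ratio_worked_examples(self):
        assert relative_research_effort(0.34, 0.13) == pytest.approx(2.615, abs=1e-3)
        assert relative_research_effort(0.04, 0.14) == pytest.approx(0.286, abs=1e-3)
        assert relative_research_effort(0.2, 0.2) == pytest.approx(1.0)

    def test_effort_with_zero_daly_share_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            relative_research_effort(0.1, 0.0)


class TestQ1Share:
    def test_all_q1_gives_one_and_none_gives_zero(self):
        t = journal_table([8, 7, 6, 5, 4, 3, 2, 1])
        qi = QuartileIndex(t)
        q1_recs = [rec(journal_id="J000"), rec(journal_id="J001")]
        q4_recs = [rec(journal_id="J007")]
        assert q1_share(q1_recs, [1.0, 1.0], qi) == pytest.approx(1.0)
        assert q1_share(q4_recs, [1.0], qi) == pytest.approx(0.0)

    def test_mixed_subset_matches_weighted_count(self):
        t = journal_table([8, 7, 6, 5, 4, 3, 2, 1])
        qi = QuartileIndex(t)
        recs = [rec(journal_id=f"J{i:03d}") for i in range(8)]
        weights = [0.5, 1.0, 0.25, 1.0, 1.0, 0.5, 1.0, 0.75]
        expected = (0.5 + 1.0) / sum(weights)  # J000, J001 are Q1
        assert q1_share(recs, weights, qi) == pytest.approx(expected)

    def test_unmatched_journals_excluded_from_denominator(self):
        t = journal_table([4, 3, 2, 1])
        qi = QuartileIndex(t)
        recs = [rec(journal_id="J000"), rec(journal_id="NOPE")]
        assert q1_share(recs, [1.0, 1.0], qi) == pytest.approx(1.0)

    def test_empty_denominator_is_undefined(self):
        qi = QuartileIndex(journal_table([1.0]))
        with pytest.raises(UndefinedShareError):
            q1_share([rec(journal_id="NOPE")], [1.0], qi)


def test_income_group_weights_aggregation(tiny_income):
    w = {"NLD": 0.5, "ESP": 0.25, "CHN": 0.25}
    gw = income_group_weights(w, tiny_income)
    assert gw[IncomeGroup.HIC] == pytest.approx(0.75)
    assert gw[IncomeGroup.UMIC] == pytest.approx(0.25)


def test_income_group_weights_drop_unclassified(tiny_income):
    gw = income_group_weights(
        {"NLD": 0.5, "XXX": 0.5}, tiny_income, unknown="unclassified"
    )
    assert gw == {IncomeGroup.HIC: pytest.approx(0.5)}
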