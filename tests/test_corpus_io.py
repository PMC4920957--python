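import json
from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsetopics.corpus_io import (
    PeriodSplit,
    QuerySpec,
    count_mentions,
    filter_by_query,
    match_groups,
    read_corpus,
    split_periods,
    write_corpus,
)
from sparsetopics.errors import CorpusFormatError, DuplicateIdError

QUERY = QuerySpec.from_dict({"pap": ["pap smear", "pap test"], "cervical cancer": ["cervical cancer"]})


def _rec(text, id, ts="2012-02-01T12:00:00Z"):
    from datetime import datetime, timezone

    from sparsetopics.corpus_io import TweetRecord

    when = datetime.fromisoformat(ts.replace("Z", "+00:00")).astimezone(timezone.utc)
    return TweetRecord(id=id, timestamp=when, text=text, lang="en")


def _write_jsonl(path, rows):
    path.write_text("".join(json.dumps(r) + "\n" for r in rows), encoding="utf-8")


class TestReadCorpus:
    def test_jsonl_identity_read_preserves_order(self, tmp_path):
        rows = [
            {"id": f"t{i}", "timestamp": "2012-01-05T00:00:00Z", "text": f"msg {i}", "lang": "en"}
            for i in range(3)
        ]
        p = tmp_path / "c.jsonl"
        _write_jsonl(p, rows)
        records = read_corpus(p)
        assert [r.id for r in records] == ["t0", "t1", "t2"]
        assert records[1].text == "msg 1"

    def test_duplicate_id_rejected_with_id_named(self, tmp_path):
        rows = [
            {"id": "t1", "timestamp": "2012-01-05T00:00:00Z", "text": "a"},
            {"id": "t1", "timestamp": "2012-01-06T00:00:00Z", "text": "b"},
        ]
        p = tmp_path / "c.jsonl"
        _write_jsonl(p, rows)
        with pytest.raises(DuplicateIdError, match="t1"):
            read_corpus(p)

    def test_missing_field_names_line_and_field(self, tmp_path):
        p = tmp_path / "c.jsonl"
        _write_jsonl(p, [{"id": "t1", "text": "no timestamp"}])
        with pytest.raises(CorpusFormatError, match="line 1.*timestamp"):
            read_corpus(p)

    def test_csv_timestamp_lands_in_followup_period(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "id,timestamp,text,lang,retweet_of\n"
            't1,2012-03-14T00:00:00Z,"pap test news",en,\n',
            encoding="utf-8",
        )
        (rec,) = read_corpus(p)
        assert PeriodSplit.default().period_of(rec.utc_date) == "followup"

    def test_missing_lang_mapped_to_unknown(self, tmp_path):
        p = tmp_path / "c.jsonl"
        _write_jsonl(p, [{"id": "t1", "timestamp": "2012-01-05T00:00:00Z", "text": "x"}])
        assert read_corpus(p)[0].lang == "und"

    def test_round_trip(self, tmp_path, make_record):
        records = [make_record("pap smear a"), make_record("b", retweet_of="t0001")]
        p = tmp_path / "c.jsonl"
        write_corpus(records, p)
        assert read_corpus(p) == records


class TestQueryFilter:
    def test_hashtag_collapsed_matching_on_promotion_tweet(self, make_record):
        rec = make_record("Get Tested For Cervical Cancer #cancer #cervicalcancer #paptest")
        (m,) = filter_by_query([rec], QUERY)
        assert m.groups == {"cervical cancer", "pap"}

    def test_no_phrase_dropped(self, make_record):
        assert filter_by_query([make_record("Smead Slash/Jacket, Letter, 11 Point")], QUERY) == []

    def test_case_insensitive_substring_scan(self, make_record):
        records = [make_record("pap smear x"), make_record("PAP TEST y"), make_record("unrelated")]
        kept = filter_by_query(records, QUERY)
        # brute-force oracle: lowercase substring scan
        expected = [
            r for r in records if any(p in r.text.lower() for ps in QUERY.groups.values() for p in ps)
        ]
        assert [m.record for m in kept] == expected
        assert len(kept) == 2

    def test_collapse_off_misses_hashtag_only_match(self, make_record):
        rec = make_record("#paptest only")
        assert filter_by_query([rec], QUERY, collapse_hashtags=False) == []
        assert len(filter_by_query([rec], QUERY, collapse_hashtags=True)) == 1

    @given(st.lists(st.sampled_from(["pap smear now", "CERVICAL CANCER info", "nothing here", "#paptest"]), max_size=12))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_filter_idempotent(self, texts):
        records = [_rec(t, id=f"h{i}") for i, t in enumerate(texts)]
        once = [m.record for m in filter_by_query(records, QUERY)]
        twice = [m.record for m in filter_by_query(once, QUERY)]
        assert once == twice

    def test_phrase_in_two_groups_rejected(self):
        with pytest.raises(ValueError, match="appears in groups"):
            QuerySpec.from_dict({"a": ["pap test"], "b": ["pap test"]})

    def test_default_query_includes_misspellings(self):
        q = QuerySpec.default()
        assert match_groups("got my pap smeer done", q) == {"pap"}


class TestSplitPeriods:
    SPLIT = PeriodSplit.default()

    @pytest.mark.parametrize(
        "ts,where",
        [
            ("2012-03-13T23:59:59Z", "baseline"),
            ("2012-03-14T00:00:00Z", "followup"),
            ("2011-12-31T23:59:00Z", None),
            ("2012-07-01T00:00:00Z", None),
        ],
    )
    def test_boundary_dates(self, make_record, ts, where):
        rec = make_record(ts=ts)
        baseline, followup, oor = split_periods([rec], self.SPLIT)
        got = "baseline" if baseline else "followup" if followup else None
        assert got == where

    def test_partition_sizes(self, make_record):
        recs = (
            [make_record(ts="2012-02-01T00:00:00Z") for _ in range(4)]
            + [make_record(ts="2012-04-01T00:00:00Z") for _ in range(5)]
            + [make_record(ts="2011-06-01T00:00:00Z")]
        )
        b, f, o = split_periods(recs, self.SPLIT)
        assert (len(b), len(f), len(o)) == (4, 5, 1)

    @given(
        st.lists(
            st.sampled_from(["2011-12-01", "2012-01-01", "2012-03-13", "2012-03-14", "2012-06-30", "2012-12-01"]),
            max_size=20,
        )
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_partition_property(self, days):
        recs = [_rec("x", id=f"p{i}", ts=f"{d}T10:00:00Z") for i, d in enumerate(days)]
        b, f, o = split_periods(recs, self.SPLIT)
        assert len(b) + len(f) + len(o) == len(recs)
        assert sorted(r.id for part in (b, f, o) for r in part) == sorted(r.id for r in recs)

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            PeriodSplit(date(2012, 1, 1), date(2012, 3, 14), date(2012, 3, 14), date(2012, 6, 30))


class TestCountMentions:
    def test_record_matching_two_groups_counts_once_per_group(self, make_record):
        rec = make_record("pap smear and cervical cancer together")
        series = count_mentions([rec], QUERY)
        assert {s.group: s.total for s in series} == {"pap": 1, "cervical cancer": 1}

    def test_empty_corpus_all_zero(self):
        series = count_mentions([], QUERY)
        assert all(s.total == 0 and s.bins == () for s in series)

    def test_bins_contiguous_and_totals_match_filter(self, make_record):
        recs = [
            make_record("pap test a", ts="2012-01-01T01:00:00Z"),
            make_record("pap test b", ts="2012-01-04T01:00:00Z"),
            make_record("cervical cancer c", ts="2012-01-02T01:00:00Z"),
            make_record("nothing", ts="2012-01-03T01:00:00Z"),
        ]
        series = {s.group: s for s in count_mentions(recs, QUERY)}
        pap = series["pap"]
        assert [d.isoformat() for d, _ in pap.bins] == ["2012-01-01", "2012-01-02", "2012-01-03", "2012-01-04"]
        assert [c for _, c in pap.bins] == [1, 0, 0, 1]
        only_pap = QuerySpec.from_dict({"pap": ["pap smear", "pap test"]})
        assert pap.total == len(filter_by_query(recs, only_pap))

    def test_weekly_bins(self, make_record):
        recs = [
            make_record("pap test", ts="2012-01-02T01:00:00Z"),  # Monday
            make_record("pap test", ts="2012-01-08T01:00:00Z"),  # Sunday same ISO week
            make_record("pap test", ts="2012-01-09T01:00:00Z"),  # next week
        ]
        (pap,) = [s for s in count_mentions(recs, QUERY, "week") if s.group == "pap"]
        assert [c for _, c in pap.bins] == [2, 1]
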