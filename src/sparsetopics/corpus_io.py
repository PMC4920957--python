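"""Reading, filtering and time-slicing of tweet corpora.

A corpus is a flat list of :class:`TweetRecord`, read from JSON-lines or CSV.
Keyword filtering works on case-insensitive phrase matching with optional
hashtag collapsing, so "#cervicalcancer" matches the phrase "cervical cancer".
Period splitting partitions records around an event date on UTC calendar
dates, and mention counting produces per-group daily or weekly time series.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .errors import CorpusFormatError, DuplicateIdError

__all__ = [
    "TweetRecord",
    "QuerySpec",
    "QueryMatch",
    "PeriodSplit",
    "MentionSeries",
    "read_corpus",
    "write_corpus",
    "filter_by_query",
    "split_periods",
    "count_mentions",
    "mention_series_to_csv",
]

UNKNOWN_LANG = "und"

_REQUIRED_FIELDS = ("id", "timestamp", "text")


@dataclass(frozen=True, slots=True)
class TweetRecord:
    """One raw message: id, UTC timestamp, raw text, language tag, retweet link.

    The classic 140-character limit is *not* enforced; modern corpora exceed
    it and nothing downstream depends on message length.
    """

    id: str
    timestamp: datetime
    text: str
    lang: str = UNKNOWN_LANG
    retweet_of: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("TweetRecord.id must be non-empty")
        if self.timestamp.tzinfo is None:
            raise ValueError("TweetRecord.timestamp must be timezone-aware")
        if self.retweet_of is not None and not self.retweet_of:
            raise ValueError("TweetRecord.retweet_of must be non-empty when present")

    @property
    def utc_date(self) -> date:
        return self.timestamp.astimezone(timezone.utc).date()


def _parse_timestamp(value: str, *, line: int | None = None) -> datetime:
    try:
        ts = pd.Timestamp(value)
    except (ValueError, TypeError) as exc:
        raise CorpusFormatError(f"unparseable timestamp {value!r}", line=line, field="timestamp") from exc
    if pd.isna(ts):
        raise CorpusFormatError(f"unparseable timestamp {value!r}", line=line, field="timestamp")
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    return ts.tz_convert("UTC").to_pydatetime()


def _record_from_mapping(raw: Mapping, line: int) -> TweetRecord:
    for name in _REQUIRED_FIELDS:
        value = raw.get(name)
        if value is None or (isinstance(value, str) and value == "" and name != "text"):
            raise CorpusFormatError(f"missing required field {name!r}", line=line, field=name)
    lang = raw.get("lang") or UNKNOWN_LANG
    retweet_of = raw.get("retweet_of") or None
    return TweetRecord(
        id=str(raw["id"]),
        timestamp=_parse_timestamp(str(raw["timestamp"]), line=line),
        text=str(raw["text"]),
        lang=str(lang).lower(),
        retweet_of=str(retweet_of) if retweet_of is not None else None,
    )


def read_corpus(path: str | Path, fmt: Literal["jsonl", "csv"] | None = None) -> list[TweetRecord]:
    """Read a corpus file, preserving record order and rejecting duplicate ids.

    ``fmt`` defaults to the file extension (``.jsonl``/``.json`` vs ``.csv``).
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    records: list[TweetRecord] = []
    seen: set[str] = set()

    def _add(rec: TweetRecord, line: int) -> None:
        if rec.id in seen:
            raise DuplicateIdError(rec.id, line=line)
        seen.add(rec.id)
        records.append(rec)

    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    raw = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"invalid JSON: {exc.msg}", line=line_no) from exc
                if not isinstance(raw, dict):
                    raise CorpusFormatError("record is not a JSON object", line=line_no)
                _add(_record_from_mapping(raw, line_no), line_no)
    elif fmt == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for line_no, raw in enumerate(reader, start=2):  # header is line 1
                _add(_record_from_mapping(raw, line_no), line_no)
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    return records


def write_corpus(records: Iterable[TweetRecord], path: str | Path) -> None:
    """Serialize records as JSON-lines (the package's canonical dialect)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            obj = {
                "id": rec.id,
                "timestamp": rec.timestamp.astimezone(timezone.utc).isoformat().replace("+00:00", "Z"),
                "text": rec.text,
                "lang": rec.lang,
            }
            if rec.retweet_of is not None:
                obj["retweet_of"] = rec.retweet_of
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Query filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuerySpec:
    """Named groups of case-insensitive match phrases (including misspellings).

    The default query mirrors a cervical-cancer screening collection:
    group "pap" = {"pap smear", "pap test", common misspellings} and group
    "cervical cancer" = {"cervical cancer", common misspellings}. The shipped
    phrase list is an editable JSON config (``data/default_query.json``).
    """

    groups: Mapping[str, tuple[str, ...]]

    def __post_init__(self):
        if not self.groups:
            raise ValueError("QuerySpec needs at least one phrase group")
        norm: dict[str, tuple[str, ...]] = {}
        seen: dict[str, str] = {}
        for name, phrases in self.groups.items():
            cleaned = tuple(p.strip().lower() for p in phrases)
            if not cleaned:
                raise ValueError(f"query group {name!r} is empty")
            for p in cleaned:
                if not p:
                    raise ValueError(f"query group {name!r} contains an empty phrase")
                if p in seen and seen[p] != name:
                    raise ValueError(f"phrase {p!r} appears in groups {seen[p]!r} and {name!r}")
                seen[p] = name
            norm[name] = cleaned
        object.__setattr__(self, "groups", norm)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Sequence[str]]) -> "QuerySpec":
        return cls(groups={k: tuple(v) for k, v in mapping.items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "QuerySpec":
        with Path(path).open(encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "QuerySpec":
        text = resources.files("sparsetopics.data").joinpath("default_query.json").read_text("utf-8")
        return cls.from_dict(json.loads(text))


_SQUASH_RE = re.compile(r"[\s#]+")


def _squash(text: str) -> str:
    """Lowercase and drop whitespace and '#' so hashtag-run phrases compare."""
    return _SQUASH_RE.sub("", text.lower())


def match_groups(text: str, query: QuerySpec, *, collapse_hashtags: bool = True) -> frozenset[str]:
    """Names of query groups with at least one phrase occurring in ``text``."""
    lowered = text.lower()
    squashed = _squash(text) if collapse_hashtags else ""
    hits = set()
    for name, phrases in query.groups.items():
        for phrase in phrases:
            if phrase in lowered or (collapse_hashtags and _squash(phrase) in squashed):
                hits.add(name)
                break
    return frozenset(hits)


@dataclass(frozen=True, slots=True)
class QueryMatch:
    record: TweetRecord
    groups: frozenset[str]


def filter_by_query(
    records: Iterable[TweetRecord],
    query: QuerySpec,
    *,
    collapse_hashtags: bool = True,
) -> list[QueryMatch]:
    """Retain records whose text matches >=1 phrase; annotate matched groups."""
    out = []
    for rec in records:
        groups = match_groups(rec.text, query, collapse_hashtags=collapse_hashtags)
        if groups:
            out.append(QueryMatch(record=rec, groups=groups))
    return out


# ---------------------------------------------------------------------------
# Period split
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class PeriodSplit:
    """Inclusive UTC calendar-date bounds for the baseline and follow-up windows."""

    baseline_start: date
    baseline_end: date
    followup_start: date
    followup_end: date

    def __post_init__(self):
        if not (self.baseline_start <= self.baseline_end):
            raise ValueError("baseline period is empty")
        if not (self.followup_start <= self.followup_end):
            raise ValueError("follow-up period is empty")
        if not (self.baseline_end < self.followup_start):
            raise ValueError("baseline must end strictly before follow-up starts")

    @classmethod
    def default(cls) -> "PeriodSplit":
        """Six-month window split at the March 2012 screening-guideline change."""
        return cls(date(2012, 1, 1), date(2012, 3, 13), date(2012, 3, 14), date(2012, 6, 30))

    def period_of(self, when: datetime | date) -> str | None:
        d = when.astimezone(timezone.utc).date() if isinstance(when, datetime) else when
        if self.baseline_start <= d <= self.baseline_end:
            return "baseline"
        if self.followup_start <= d <= self.followup_end:
            return "followup"
        return None


def split_periods(
    records: Iterable[TweetRecord], split: PeriodSplit
) -> tuple[list[TweetRecord], list[TweetRecord], list[TweetRecord]]:
    """Partition records into (baseline, followup, out_of_range) by UTC date."""
    baseline: list[TweetRecord] = []
    followup: list[TweetRecord] = []
    out_of_range: list[TweetRecord] = []
    for rec in records:
        period = split.period_of(rec.utc_date)
        if period == "baseline":
            baseline.append(rec)
        elif period == "followup":
            followup.append(rec)
        else:
            out_of_range.append(rec)
    return baseline, followup, out_of_range


# ---------------------------------------------------------------------------
# Mention counting
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class MentionSeries:
    """Contiguous binned counts of messages matching one query group.

    Counts messages, not phrase occurrences: a tweet containing a phrase twice
    counts once, and a tweet matching two groups counts once in each group's
    series.
    """

    group: str
    bins: tuple[tuple[date, int], ...]
    bin_width: Literal["day", "week"] = "day"

    @property
    def total(self) -> int:
        return sum(c for _, c in self.bins)


def _bin_start(d: date, bin_width: str) -> date:
    if bin_width == "day":
        return d
    if bin_width == "week":  # ISO week, Monday start
        return d - timedelta(days=d.weekday())
    raise ValueError(f"unknown bin width {bin_width!r}")


def count_mentions(
    records: Sequence[TweetRecord],
    query: QuerySpec,
    bin_width: Literal["day", "week"] = "day",
    *,
    collapse_hashtags: bool = True,
) -> list[MentionSeries]:
    """Per-group binned mention counts; applies its own phrase matching."""
    matched: dict[str, list[date]] = {name: [] for name in query.groups}
    all_dates: list[date] = []
    for rec in records:
        groups = match_groups(rec.text, query, collapse_hashtags=collapse_hashtags)
        if groups:
            d = _bin_start(rec.utc_date, bin_width)
            all_dates.append(d)
            for g in groups:
                matched[g].append(d)
    series = []
    if all_dates:
        lo, hi = min(all_dates), max(all_dates)
        step = timedelta(days=1 if bin_width == "day" else 7)
        grid = []
        d = lo
        while d <= hi:
            grid.append(d)
            d += step
    else:
        grid = []
    for name in query.groups:
        counts = pd.Series(matched[name], dtype="object").value_counts().to_dict()
        series.append(
            MentionSeries(
                group=name,
                bins=tuple((d, int(counts.get(d, 0))) for d in grid),
                bin_width=bin_width,
            )
        )
    return series


def mention_series_to_csv(series: Iterable[MentionSeries], path: str | Path) -> None:
    """Write tidy CSV with columns group,date,count."""
    rows = [(s.group, d.isoformat(), c) for s in series for d, c in s.bins]
    pd.DataFrame(rows, columns=["group", "date", "count"]).to_csv(path, index=False)
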