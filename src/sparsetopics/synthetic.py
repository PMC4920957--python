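"""Synthetic tweet corpora with planted topic structure and exact bookkeeping.

The generator emulates an already-collected health-discourse stream: each
on-topic message draws most of its tokens from a single planted keyword set
(single-topic assumption, no mixtures) plus background filler; a
contamination fraction of messages is pure background, occasionally carrying
a collection query phrase (how irrelevant content enters a keyword-collected
corpus); a small fraction is mislabeled non-English (scrambled tokens from a
disjoint pseudo-vocabulary, tagged "en"); some messages are duplicated as
retweets; and timestamps straddle an event date with a configurable
follow-up volume multiplier. Ground truth records every planted fact for
downstream testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .corpus_io import TweetRecord
from .errors import SynthSpecError

__all__ = ["SynthSpec", "DocLabel", "GroundTruth", "generate_corpus", "describe_truth", "DEFAULT_THEMES"]

# Disjoint five-word keyword themes used when no explicit sets are given.
# None of these words is a stop-word or a collection query token.
DEFAULT_THEMES: tuple[tuple[str, ...], ...] = (
    ("screening", "tested", "clinic", "appointment", "reminder"),
    ("guidelines", "uspstf", "recommendation", "interval", "panel"),
    ("vaccine", "hpv", "doses", "teens", "prevention"),
    ("abnormal", "colposcopy", "biopsy", "nervous", "waiting"),
    ("valentine", "awkward", "hilarious", "giggle", "story"),
    ("survival", "boosts", "study", "experts", "regular"),
    ("awareness", "ribbon", "month", "donate", "campaign"),
    ("insurance", "coverage", "lowcost", "community", "outreach"),
)

_NONENGLISH_VOCAB_SIZE = 50


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic corpus.

    Defaults plant 5 disjoint 5-keyword topics with 40 documents each, 20%
    background-only contamination, 5% mislabeled non-English content, retweet
    duplication with a geometric per-document duplicate count of mean 1.5,
    and a two-period timestamp structure with twice the baseline volume after
    the event date.
    """

    n_topics: int = 5
    keywords_per_topic: int = 5
    docs_per_topic: int = 40
    background_vocab_size: int = 100
    tokens_per_doc: tuple[int, int] = (6, 12)
    keyword_frac: float = 0.8
    contamination_frac: float = 0.20
    nonenglish_frac: float = 0.05
    retweet_mean: float = 1.5
    query_phrases: tuple[str, ...] = ("pap smear", "pap test", "cervical cancer")
    ontopic_query_frac: float = 0.0
    offtopic_query_frac: float = 0.5
    baseline: tuple[date, date] = (date(2012, 1, 1), date(2012, 3, 13))
    followup: tuple[date, date] = (date(2012, 3, 14), date(2012, 6, 30))
    volume_multiplier: float = 2.0
    followup_only_topics: tuple[int, ...] = ()
    topic_keywords: tuple[tuple[str, ...], ...] | None = None
    mention_frac: float = 0.3
    url_frac: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_topics < 1:
            raise SynthSpecError("n_topics", "must be >= 1")
        if self.keywords_per_topic < 1:
            raise SynthSpecError("keywords_per_topic", "must be >= 1")
        if self.docs_per_topic < 1:
            raise SynthSpecError("docs_per_topic", "must be >= 1")
        if not (0.0 <= self.contamination_frac < 1.0):
            raise SynthSpecError("contamination_frac", "must be in [0, 1)")
        if not (0.0 <= self.nonenglish_frac < 1.0):
            raise SynthSpecError("nonenglish_frac", "must be in [0, 1)")
        if self.contamination_frac + self.nonenglish_frac >= 1.0:
            raise SynthSpecError("contamination_frac", "contamination + non-English fractions must sum below 1")
        if self.contamination_frac > 0 and self.background_vocab_size < 1:
            raise SynthSpecError("background_vocab_size", "contamination requires a background vocabulary")
        lo, hi = self.tokens_per_doc
        if lo < 1 or hi < lo:
            raise SynthSpecError("tokens_per_doc", "must be a non-empty (low, high) range")
        if not (0.0 < self.keyword_frac <= 1.0):
            raise SynthSpecError("keyword_frac", "must be in (0, 1]")
        if self.retweet_mean < 0:
            raise SynthSpecError("retweet_mean", "must be >= 0")
        if not (0.0 <= self.ontopic_query_frac <= 1.0):
            raise SynthSpecError("ontopic_query_frac", "must be in [0, 1]")
        if not (0.0 <= self.offtopic_query_frac <= 1.0):
            raise SynthSpecError("offtopic_query_frac", "must be in [0, 1]")
        if self.volume_multiplier <= 0:
            raise SynthSpecError("volume_multiplier", "must be > 0")
        if any(t < 0 or t >= self.n_topics for t in self.followup_only_topics):
            raise SynthSpecError("followup_only_topics", "topic index out of range")
        if self.baseline[1] >= self.followup[0]:
            raise SynthSpecError("baseline", "baseline must end before follow-up starts")
        sets = self.keyword_sets()
        flat = [w for s in sets for w in s]
        if len(set(flat)) != len(flat):
            raise SynthSpecError("topic_keywords", "keyword sets must be pairwise disjoint")
        background = set(self._background_vocab())
        if background & set(flat):
            raise SynthSpecError("topic_keywords", "keyword sets must be disjoint from the background vocabulary")

    def keyword_sets(self) -> tuple[tuple[str, ...], ...]:
        if self.topic_keywords is not None:
            if len(self.topic_keywords) != self.n_topics:
                raise SynthSpecError("topic_keywords", "one keyword set per topic required")
            return tuple(tuple(s) for s in self.topic_keywords)
        if self.n_topics <= len(DEFAULT_THEMES) and self.keywords_per_topic <= len(DEFAULT_THEMES[0]):
            return tuple(theme[: self.keywords_per_topic] for theme in DEFAULT_THEMES[: self.n_topics])
        return tuple(
            tuple(f"topic{t}kw{i}" for i in range(self.keywords_per_topic)) for t in range(self.n_topics)
        )

    def _background_vocab(self) -> tuple[str, ...]:
        return tuple(f"filler{i:03d}" for i in range(self.background_vocab_size))

    def _nonenglish_vocab(self) -> tuple[str, ...]:
        return tuple(f"kata{i:03d}" for i in range(_NONENGLISH_VOCAB_SIZE))


@dataclass(frozen=True, slots=True)
class DocLabel:
    """Planted provenance of one tweet id."""

    kind: str  # "topic" | "contamination" | "nonenglish"
    topic: int | None
    period: str  # "baseline" | "followup"
    is_retweet: bool = False
    parent: str | None = None


@dataclass(frozen=True)
class GroundTruth:
    """Exact bookkeeping for every generated tweet id."""

    labels: Mapping[str, DocLabel]
    keyword_sets: tuple[tuple[str, ...], ...]
    duplicate_groups: Mapping[str, tuple[str, ...]]  # original id -> retweet ids

    def multiplicity_histogram(self) -> dict[int, int]:
        """Histogram of duplicate-group sizes (1 + retweet count per original)."""
        hist: dict[int, int] = {}
        for rts in self.duplicate_groups.values():
            size = 1 + len(rts)
            hist[size] = hist.get(size, 0) + 1
        return dict(sorted(hist.items()))

    def period_counts(self) -> dict[str, int]:
        counts = {"baseline": 0, "followup": 0}
        for lab in self.labels.values():
            counts[lab.period] += 1
        return counts

    def topic_of(self, tweet_id: str) -> int | None:
        return self.labels[tweet_id].topic

    def to_json(self, path: str | Path) -> None:
        obj = {
            "keyword_sets": [list(s) for s in self.keyword_sets],
            "labels": {
                tid: {
                    "kind": lab.kind,
                    "topic": lab.topic,
                    "period": lab.period,
                    "is_retweet": lab.is_retweet,
                    "parent": lab.parent,
                }
                for tid, lab in self.labels.items()
            },
            "duplicate_groups": {k: list(v) for k, v in self.duplicate_groups.items()},
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text("utf-8"))
        return cls(
            labels={
                tid: DocLabel(
                    kind=l["kind"],
                    topic=l["topic"],
                    period=l["period"],
                    is_retweet=l["is_retweet"],
                    parent=l["parent"],
                )
                for tid, l in obj["labels"].items()
            },
            keyword_sets=tuple(tuple(s) for s in obj["keyword_sets"]),
            duplicate_groups={k: tuple(v) for k, v in obj["duplicate_groups"].items()},
        )


def _category_counts(spec: SynthSpec) -> tuple[int, int]:
    """(n_contamination, n_nonenglish) from the fractions of total base docs."""
    n_on = spec.n_topics * spec.docs_per_topic
    denom = 1.0 - spec.contamination_frac - spec.nonenglish_frac
    n_total = round(n_on / denom)
    return round(spec.contamination_frac * n_total), round(spec.nonenglish_frac * n_total)


def _followup_count(n: int, multiplier: float) -> int:
    """Deterministic rounding of the follow-up share under the volume multiplier."""
    return round(n * multiplier / (1.0 + multiplier))


def _random_datetime(rng: np.random.Generator, lo: date, hi: date) -> datetime:
    days = (hi - lo).days
    d = lo + timedelta(days=int(rng.integers(0, days + 1)))
    sec = int(rng.integers(0, 86400))
    return datetime(d.year, d.month, d.day, tzinfo=timezone.utc) + timedelta(seconds=sec)


def generate_corpus(spec: SynthSpec) -> tuple[list[TweetRecord], GroundTruth]:
    """Deterministically generate (records, ground truth) from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    keyword_sets = spec.keyword_sets()
    background = spec._background_vocab()
    nonenglish = spec._nonenglish_vocab()
    n_contam, n_noneng = _category_counts(spec)

    # plan: (kind, topic) per base doc, grouped by category for period assignment
    plan: list[tuple[str, int | None]] = []
    for t in range(spec.n_topics):
        plan.extend(("topic", t) for _ in range(spec.docs_per_topic))
    plan.extend(("contamination", None) for _ in range(n_contam))
    plan.extend(("nonenglish", None) for _ in range(n_noneng))

    # period assignment per category, exact under the volume multiplier
    periods: list[str] = []
    for kind, topic in (("topic", t) for t in range(spec.n_topics)):
        n = spec.docs_per_topic
        if topic in spec.followup_only_topics:
            periods.extend("followup" for _ in range(n))
        else:
            nf = _followup_count(n, spec.volume_multiplier)
            periods.extend("baseline" for _ in range(n - nf))
            periods.extend("followup" for _ in range(nf))
    for n in (n_contam, n_noneng):
        nf = _followup_count(n, spec.volume_multiplier)
        periods.extend("baseline" for _ in range(n - nf))
        periods.extend("followup" for _ in range(nf))

    lo_tok, hi_tok = spec.tokens_per_doc
    records: list[TweetRecord] = []
    labels: dict[str, DocLabel] = {}
    duplicate_groups: dict[str, tuple[str, ...]] = {}
    counter = 0

    def _next_id() -> str:
        nonlocal counter
        counter += 1
        return f"t{counter:06d}"

    p_retweet = 1.0 / (1.0 + spec.retweet_mean) if spec.retweet_mean > 0 else 1.0

    for (kind, topic), period in zip(plan, periods):
        n_tok = int(rng.integers(lo_tok, hi_tok + 1))
        words: list[str] = []
        if kind == "topic":
            kws = keyword_sets[topic]
            for _ in range(n_tok):
                if spec.background_vocab_size == 0 or rng.random() < spec.keyword_frac:
                    words.append(kws[int(rng.integers(len(kws)))])
                else:
                    words.append(background[int(rng.integers(len(background)))])
        elif kind == "contamination":
            words = [background[int(rng.integers(len(background)))] for _ in range(n_tok)]
        else:  # nonenglish
            words = [nonenglish[int(rng.integers(len(nonenglish)))] for _ in range(n_tok)]

        # Off-topic and mislabeled non-English messages occasionally carry a
        # collection query phrase (how irrelevant content enters a keyword-
        # collected corpus); on-topic injection is off by default.
        q_frac = spec.ontopic_query_frac if kind == "topic" else spec.offtopic_query_frac
        if spec.query_phrases and rng.random() < q_frac:
            phrase = spec.query_phrases[int(rng.integers(len(spec.query_phrases)))]
            pos = int(rng.integers(len(words) + 1))
            words = words[:pos] + phrase.split() + words[pos:]
        if rng.random() < spec.mention_frac:
            words.insert(0, f"@user{int(rng.integers(500))}")
        if rng.random() < spec.url_frac:
            suffix = "".join(chr(97 + int(c)) for c in rng.integers(0, 26, size=6))
            words.append(f"http://t.co/{suffix}")
        text = " ".join(words)

        p_lo, p_hi = spec.baseline if period == "baseline" else spec.followup
        ts = _random_datetime(rng, p_lo, p_hi)
        tid = _next_id()
        records.append(TweetRecord(id=tid, timestamp=ts, text=text, lang="en"))
        labels[tid] = DocLabel(kind=kind, topic=topic, period=period)

        # retweet duplication: geometric number of duplicates per base doc
        n_rt = int(rng.geometric(p_retweet) - 1) if spec.retweet_mean > 0 else 0
        rt_ids = []
        period_end = datetime(p_hi.year, p_hi.month, p_hi.day, 23, 59, 59, tzinfo=timezone.utc)
        for _ in range(n_rt):
            rid = _next_id()
            span = max(1.0, (period_end - ts).total_seconds())
            rt_ts = ts + timedelta(seconds=float(rng.random() * span))
            records.append(
                TweetRecord(
                    id=rid,
                    timestamp=rt_ts,
                    text=f"RT @user{int(rng.integers(500))}: {text}",
                    lang="en",
                    retweet_of=tid,
                )
            )
            labels[rid] = DocLabel(kind=kind, topic=topic, period=period, is_retweet=True, parent=tid)
            rt_ids.append(rid)
        duplicate_groups[tid] = tuple(rt_ids)

    truth = GroundTruth(labels=labels, keyword_sets=keyword_sets, duplicate_groups=duplicate_groups)
    return records, truth


def describe_truth(truth: GroundTruth) -> pd.DataFrame:
    """Per-class summary table: base docs, retweets, records, period totals."""
    rows = []
    classes: dict[str, dict[str, int]] = {}
    for lab in truth.labels.values():
        name = f"topic {lab.topic}" if lab.kind == "topic" else lab.kind
        c = classes.setdefault(name, {"base_docs": 0, "retweets": 0, "baseline": 0, "followup": 0})
        if lab.is_retweet:
            c["retweets"] += 1
        else:
            c["base_docs"] += 1
        c[lab.period] += 1
    for name in sorted(classes):
        c = classes[name]
        rows.append(
            {
                "class": name,
                "base_docs": c["base_docs"],
                "retweets": c["retweets"],
                "records": c["base_docs"] + c["retweets"],
                "baseline": c["baseline"],
                "followup": c["followup"],
            }
        )
    return pd.DataFrame(rows, columns=["class", "base_docs", "retweets", "records", "baseline", "followup"])
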