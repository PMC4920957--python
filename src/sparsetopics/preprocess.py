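"""Twitter-aware text normalization and duplicate/retweet collapsing.

Normalization lowercases, strips a leading "RT" marker, removes @-mentions
and URL-shaped tokens, drops stop-words and single-character tokens, and
keeps hashtags verbatim (with their leading "#"). Retweets and exact
normalized duplicates collapse into a single weighted :class:`Document`
whose multiplicity records how often the message appeared; downstream the
term matrix scales each row by the square root of that multiplicity.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import TweetRecord, UNKNOWN_LANG, _parse_timestamp

__all__ = [
    "StopwordPolicy",
    "Document",
    "normalize_text",
    "filter_language",
    "collapse_duplicates",
    "documents_to_jsonl",
    "documents_from_jsonl",
]

_LEADING_PUNCT = ".,;:!?\"'()[]{}<>«»“”‘’…-–—*~"
_URL_RE = re.compile(r"(?:https?://|www\.)\S+|\S+\.\S+/\S*", re.IGNORECASE)
_TOKEN_RE = re.compile(r"#?[0-9a-z_']+")
_RT_RE = re.compile(r"^rt$", re.IGNORECASE)


def _load_default_stopwords() -> frozenset[str]:
    text = resources.files("sparsetopics.data").joinpath("stopwords_en.txt").read_text("utf-8")
    words = [w.strip() for w in text.splitlines()]
    return frozenset(w for w in words if w and not w.startswith("#"))


@dataclass(frozen=True)
class StopwordPolicy:
    """Stop-word list plus the Twitter-specific normalization switches.

    ``extra_stopwords`` defaults to {"rt"} so bare retweet markers never reach
    the vocabulary. Hashtags are exempt from stop-word removal because the tag
    itself is topical content.
    """

    stopwords: frozenset[str] = field(default_factory=_load_default_stopwords)
    extra_stopwords: frozenset[str] = frozenset({"rt"})
    drop_mentions: bool = True
    drop_urls: bool = True
    keep_hashtags: bool = True

    def __post_init__(self):
        object.__setattr__(self, "stopwords", frozenset(w.lower() for w in self.stopwords))
        object.__setattr__(self, "extra_stopwords", frozenset(w.lower() for w in self.extra_stopwords))

    @property
    def all_stopwords(self) -> frozenset[str]:
        return self.stopwords | self.extra_stopwords

    @classmethod
    def default(cls) -> "StopwordPolicy":
        return cls()

    @classmethod
    def from_file(cls, path: str | Path) -> "StopwordPolicy":
        """Parse a plain-text config: stop tokens one per line, optional
        ``[extra]`` and ``[flags]`` sections (``flag = true/false``)."""
        stop: set[str] = set()
        extra: set[str] = set()
        flags = {"drop_mentions": True, "drop_urls": True, "keep_hashtags": True}
        section = "stopwords"
        for raw in Path(path).read_text("utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1].strip().lower()
                continue
            if section == "flags":
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in flags:
                    raise ValueError(f"unknown stop-word policy flag {key!r}")
                flags[key] = value.strip().lower() in ("1", "true", "yes", "on")
            elif section == "extra":
                extra.add(line.lower())
            else:
                stop.add(line.lower())
        return cls(stopwords=frozenset(stop), extra_stopwords=frozenset(extra or {"rt"}), **flags)


def normalize_text(text: str, policy: StopwordPolicy | None = None) -> tuple[list[str], bool]:
    """Normalize raw tweet text into tokens; flag a leading "RT" marker.

    Returns ``(tokens, was_retweet_marked)``. Idempotent on its own output:
    re-normalizing ``" ".join(tokens)`` yields the same tokens.
    """
    if policy is None:
        policy = StopwordPolicy.default()
    chunks = text.split()
    was_rt = False
    if chunks and _RT_RE.match(chunks[0].strip(_LEADING_PUNCT)):
        was_rt = True
        chunks = chunks[1:]
    stop = policy.all_stopwords
    tokens: list[str] = []
    for chunk in chunks:
        lowered = chunk.lower()
        core = lowered.lstrip(_LEADING_PUNCT)
        if policy.drop_mentions and core.startswith("@"):
            continue
        if policy.drop_urls and _URL_RE.match(core):
            continue
        for tok in _TOKEN_RE.findall(lowered):
            tok = tok.strip("'")
            if not tok:
                continue
            if tok.startswith("#"):
                body = tok.lstrip("#")
                if not body:
                    continue
                if policy.keep_hashtags:
                    tokens.append("#" + body)
                    continue
                tok = body
            if len(tok) < 2:
                continue
            if tok in stop:
                continue
            tokens.append(tok)
    return tokens, was_rt


def filter_language(
    records: Iterable[TweetRecord],
    keep: str = "en",
    *,
    keep_unknown: bool = True,
) -> tuple[list[TweetRecord], list[TweetRecord]]:
    """Split records into (kept, excluded) by language tag.

    The tag is taken at face value even though platform language tags are
    imperfect — mislabeled content survives this filter and is handled (or
    surfaced) downstream, so ``keep_unknown`` defaults to True.
    """
    kept: list[TweetRecord] = []
    excluded: list[TweetRecord] = []
    for rec in records:
        lang = rec.lang or UNKNOWN_LANG
        if lang == keep or (keep_unknown and lang == UNKNOWN_LANG):
            kept.append(rec)
        else:
            excluded.append(rec)
    return kept, excluded


@dataclass(frozen=True, slots=True)
class Document:
    """A normalized, weighted message.

    ``multiplicity`` is 1 plus the number of collapsed duplicates/retweets;
    ``doc_id`` and ``timestamp`` come from the earliest contributing record.
    """

    doc_id: str
    tokens: tuple[str, ...]
    multiplicity: int
    source_ids: tuple[str, ...]
    timestamp: datetime

    def __post_init__(self):
        if self.multiplicity != len(self.source_ids) or self.multiplicity < 1:
            raise ValueError("multiplicity must equal len(source_ids) >= 1")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the smaller index as root so first-appearance order is easy
            lo, hi = min(ra, rb), max(ra, rb)
            self.parent[hi] = lo


def collapse_duplicates(
    records: Sequence[TweetRecord],
    policy: StopwordPolicy | None = None,
) -> list[Document]:
    """Collapse retweets and exact normalized duplicates into weighted Documents.

    Two records merge when (a) one is a retweet whose original is present
    (followed transitively), or (b) their normalized token sequences are
    identical and non-empty. Dangling retweet parents are tolerated: such a
    retweet stands as its own original. Empty token sequences are never merged
    by content (they carry no evidence of sameness).
    """
    if policy is None:
        policy = StopwordPolicy.default()
    norm: list[list[str]] = []
    for rec in records:
        tokens, _ = normalize_text(rec.text, policy)
        norm.append(tokens)

    uf = _UnionFind(len(records))
    index_of = {rec.id: i for i, rec in enumerate(records)}
    token_first: dict[tuple[str, ...], int] = {}
    for i, rec in enumerate(records):
        if rec.retweet_of is not None and rec.retweet_of in index_of:
            uf.union(i, index_of[rec.retweet_of])
        key = tuple(norm[i])
        if key:
            if key in token_first:
                uf.union(i, token_first[key])
            else:
                token_first[key] = i

    groups: dict[int, list[int]] = {}
    for i in range(len(records)):
        groups.setdefault(uf.find(i), []).append(i)

    docs: list[Document] = []
    for root in sorted(groups):  # root is the smallest index => first appearance
        members = groups[root]
        earliest = min(members, key=lambda i: (records[i].timestamp, i))
        docs.append(
            Document(
                doc_id=records[earliest].id,
                tokens=tuple(norm[earliest]),
                multiplicity=len(members),
                source_ids=tuple(records[i].id for i in members),
                timestamp=records[earliest].timestamp,
            )
        )
    return docs


def documents_to_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "tokens": list(doc.tokens),
                        "multiplicity": doc.multiplicity,
                        "source_ids": list(doc.source_ids),
                        "timestamp": doc.timestamp.astimezone(timezone.utc).isoformat().replace("+00:00", "Z"),
                    },
                    ensure_ascii=False,
                    sort_keys=True,
                )
                + "\n"
            )


def documents_from_jsonl(path: str | Path) -> list[Document]:
    docs = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            docs.append(
                Document(
                    doc_id=obj["doc_id"],
                    tokens=tuple(obj["tokens"]),
                    multiplicity=int(obj["multiplicity"]),
                    source_ids=tuple(obj["source_ids"]),
                    timestamp=_parse_timestamp(obj["timestamp"]),
                )
            )
    return docs
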