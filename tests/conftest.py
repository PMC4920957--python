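from datetime import datetime, timezone

import pytest

from sparsetopics.corpus_io import TweetRecord


@pytest.fixture
def make_record():
    """Factory for TweetRecords with compact defaults."""

    counter = {"n": 0}

    def _make(text="hello world", *, id=None, ts="2012-02-01T12:00:00Z", lang="en", retweet_of=None):
        counter["n"] += 1
        when = datetime.fromisoformat(ts.replace("Z", "+00:00")).astimezone(timezone.utc)
        return TweetRecord(
            id=id or f"t{counter['n']:04d}",
            timestamp=when,
            text=text,
            lang=lang,
            retweet_of=retweet_of,
        )

    return _make
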