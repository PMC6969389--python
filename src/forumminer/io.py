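"""Post records and JSONL input/output.

The on-disk dialect is one JSON object per line with fields ``post_id``,
``thread_id``, ``subforum``, ``timestamp`` (ISO-8601 date) and ``text``.
Synthetic corpora may additionally carry ``true_sentiment`` / ``true_cuis``,
but the generator in this package writes ground truth to a sidecar file
instead so the pipeline can never read labels by accident.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

__all__ = ["Post", "read_posts", "write_posts"]


@dataclass(frozen=True)
class Post:
    """A timestamped forum message.

    ``timestamp`` may be None for malformed records; downstream year
    stratification excludes such posts and reports the exclusion tally.
    """

    post_id: str
    thread_id: str = ""
    subforum: str = ""
    timestamp: _dt.date | None = None
    text: str = ""
    true_sentiment: str | None = None
    true_cuis: tuple[str, ...] | None = None

    def with_text(self, text: str) -> "Post":
        return replace(self, text=text)

    def to_record(self) -> dict:
        rec = {
            "post_id": self.post_id,
            "thread_id": self.thread_id,
            "subforum": self.subforum,
            "timestamp": self.timestamp.isoformat() if self.timestamp else None,
            "text": self.text,
        }
        if self.true_sentiment is not None:
            rec["true_sentiment"] = self.true_sentiment
        if self.true_cuis is not None:
            rec["true_cuis"] = list(self.true_cuis)
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "Post":
        ts = rec.get("timestamp")
        timestamp = _dt.date.fromisoformat(ts[:10]) if ts else None
        cuis = rec.get("true_cuis")
        return cls(
            post_id=str(rec["post_id"]),
            thread_id=str(rec.get("thread_id", "")),
            subforum=str(rec.get("subforum", "")),
            timestamp=timestamp,
            text=rec.get("text", ""),
            true_sentiment=rec.get("true_sentiment"),
            true_cuis=tuple(cuis) if cuis is not None else None,
        )


def read_posts(path: str | Path) -> Iterator[Post]:
    """Stream posts from a JSONL file, one object per line."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield Post.from_record(json.loads(line))


def write_posts(posts: Iterable[Post], path: str | Path) -> int:
    """Write posts as JSONL; returns the number of records written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for post in posts:
            fh.write(json.dumps(post.to_record(), sort_keys=True) + "\n")
            n += 1
    return n
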