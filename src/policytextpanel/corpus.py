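"""Document filtering and TF-IDF keyword extraction.

Documents are pre-tokenized: each record carries a title token sequence and a
body token sequence.  Tokens are opaque strings; no language-specific
segmentation happens here.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence


class CorpusError(ValueError):
    """Raised on invalid corpus-level input (empty corpus, misaligned keyword sets)."""


@dataclass(frozen=True)
class PolicyDocument:
    """One policy document: identifier, issuing prefecture, year, tokens."""

    doc_id: str
    prefecture_id: str
    year: int
    title_tokens: tuple[str, ...]
    body_tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "title_tokens", tuple(self.title_tokens))
        object.__setattr__(self, "body_tokens", tuple(self.body_tokens))

    @property
    def tokens(self) -> tuple[str, ...]:
        """Title and body pooled, in order.  Term frequencies are counted here."""
        return self.title_tokens + self.body_tokens

    def to_json(self) -> str:
        return json.dumps(
            {
                "doc_id": self.doc_id,
                "prefecture_id": self.prefecture_id,
                "year": self.year,
                "title_tokens": list(self.title_tokens),
                "body_tokens": list(self.body_tokens),
            },
            sort_keys=False,
            separators=(",", ":"),
        )

    @classmethod
    def from_json(cls, line: str) -> "PolicyDocument":
        d = json.loads(line)
        return cls(
            doc_id=d["doc_id"],
            prefecture_id=d["prefecture_id"],
            year=int(d["year"]),
            title_tokens=tuple(d["title_tokens"]),
            body_tokens=tuple(d["body_tokens"]),
        )


@dataclass(frozen=True)
class KeywordSet:
    """Top keywords extracted for one document, scores non-increasing."""

    doc_id: str
    keywords: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "keywords", tuple((str(t), float(s)) for t, s in self.keywords)
        )
        scores = [s for _, s in self.keywords]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError(f"keyword scores must be non-increasing: {self.doc_id}")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.keywords)

    def to_json(self) -> str:
        return json.dumps(
            {"doc_id": self.doc_id, "keywords": [[t, s] for t, s in self.keywords]},
            separators=(",", ":"),
        )

    @classmethod
    def from_json(cls, line: str) -> "KeywordSet":
        d = json.loads(line)
        return cls(doc_id=d["doc_id"], keywords=tuple((t, s) for t, s in d["keywords"]))


def read_corpus_jsonl(handle: IO[str] | str) -> Iterator[PolicyDocument]:
    """Stream documents from a JSONL file path or open handle, one per line."""
    if isinstance(handle, str):
        with open(handle, encoding="utf-8") as fh:
            yield from read_corpus_jsonl(fh)
        return
    for line in handle:
        line = line.strip()
        if line:
            yield PolicyDocument.from_json(line)


def write_corpus_jsonl(docs: Iterable[PolicyDocument], handle: IO[str] | str) -> None:
    if isinstance(handle, str):
        with open(handle, "w", encoding="utf-8") as fh:
            write_corpus_jsonl(docs, fh)
        return
    for doc in docs:
        handle.write(doc.to_json())
        handle.write("\n")


def filter_relevant(
    docs: Iterable[PolicyDocument], relevance_tokens: Iterable[str]
) -> list[PolicyDocument]:
    """Keep documents whose title shares at least one token with ``relevance_tokens``.

    Order is preserved; an empty result is valid.
    """
    relevance = frozenset(relevance_tokens)
    if not relevance:
        raise CorpusError("relevance token set must be non-empty")
    return [d for d in docs if relevance.intersection(d.title_tokens)]


def tfidf_keywords(
    docs: Sequence[PolicyDocument], k: int = 5, *, idf_smooth: bool = False
) -> list[KeywordSet]:
    """Extract the top-``k`` TF-IDF keywords for every document.

    score(t, d) = tf(t, d) * ln(N / df(t)), with raw term counts over the pooled
    title+body token stream, N the corpus size and df(t) the number of documents
    containing t.  Terms present in every document score zero and are excluded,
    unless fewer than k positive-score terms exist, in which case zero-score
    terms fill the remaining slots ranked by raw term frequency.  Ties break
    lexicographically by token so output is fully deterministic.

    With ``idf_smooth`` the idf becomes ln(1 + N/df) and never vanishes; this is
    a sensitivity switch, not the default.
    """
    docs = list(docs)
    if not docs:
        raise CorpusError("cannot extract keywords from an empty corpus")
    if k < 1:
        raise CorpusError(f"k must be >= 1, got {k}")

    n_docs = len(docs)
    doc_counts = [Counter(d.tokens) for d in docs]
    df: Counter[str] = Counter()
    for counts in doc_counts:
        df.update(counts.keys())

    if idf_smooth:
        idf = {t: math.log(1.0 + n_docs / d) for t, d in df.items()}
    else:
        idf = {t: math.log(n_docs / d) for t, d in df.items()}

    out = []
    for doc, counts in zip(docs, doc_counts):
        scored = [(t, counts[t] * idf[t]) for t in counts]
        positive = sorted(
            ((t, s) for t, s in scored if s > 0.0), key=lambda ts: (-ts[1], ts[0])
        )
        top = positive[:k]
        if len(top) < k:
            # idf-degenerate fill: rank ubiquitous terms by raw tf, score 0
            zeros = sorted(
                ((t, s) for t, s in scored if s <= 0.0),
                key=lambda ts: (-counts[ts[0]], ts[0]),
            )
            top.extend((t, 0.0) for t, _ in zeros[: k - len(top)])
        out.append(KeywordSet(doc_id=doc.doc_id, keywords=tuple(top)))
    return out


def identify_uebmi_docs(
    docs: Sequence[PolicyDocument],
    keyword_sets: Sequence[KeywordSet],
    uebmi_token: str,
) -> list[PolicyDocument]:
    """Select documents mentioning the scheme token in the title or among
    their extracted keywords.  A body-only mention that did not make the
    keyword list is not sufficient."""
    by_id = {ks.doc_id: ks for ks in keyword_sets}
    selected = []
    for doc in docs:
        ks = by_id.get(doc.doc_id)
        if ks is None:
            raise CorpusError(f"no keyword set for document {doc.doc_id!r}")
        if uebmi_token in doc.title_tokens or uebmi_token in ks.tokens:
            selected.append(doc)
    return selected
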