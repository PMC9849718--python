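"""Categorized keyword counting and prefecture-year cumulative exposure scores.

The measurement chain is: per-document category counts (only keywords that were
extracted for that document contribute, and semantically neutral keywords only
count when a collocation word appears nearby), summed to prefecture-year totals,
then cumulated from each prefecture's scheme launch year onward.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .corpus import KeywordSet, PolicyDocument

CATEGORIES = (
    "benefit_expansion",
    "cost_containment",
    "service_delivery",
    "pharmaceutical",
)


class LexiconError(ValueError):
    """Invalid lexicon configuration."""


class ExposureError(ValueError):
    """Inconsistent counting input (corrupt keyword set, missing launch year)."""


@dataclass(frozen=True)
class CategoryLexicon:
    """Keyword -> category map with neutral-keyword collocation rules.

    Keys of ``keyword_to_category`` may be multi-token phrases (whitespace
    separated); those match as contiguous token n-grams.  A keyword listed in
    ``neutral_keywords`` still maps to a category but an occurrence only counts
    when one of ``collocation_words`` appears within ``collocation_window``
    tokens on either side, within the same token stream.
    """

    keyword_to_category: Mapping[str, str]
    neutral_keywords: frozenset[str] = frozenset()
    collocation_words: frozenset[str] = frozenset()
    collocation_window: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "keyword_to_category", dict(self.keyword_to_category))
        object.__setattr__(self, "neutral_keywords", frozenset(self.neutral_keywords))
        object.__setattr__(self, "collocation_words", frozenset(self.collocation_words))
        if self.collocation_window < 1:
            raise LexiconError("collocation_window must be >= 1")
        for kw, cat in self.keyword_to_category.items():
            if cat not in CATEGORIES:
                raise LexiconError(f"unknown category {cat!r} for keyword {kw!r}")
        unmapped = self.neutral_keywords - set(self.keyword_to_category)
        if unmapped:
            raise LexiconError(f"neutral keywords missing a category: {sorted(unmapped)}")

    def to_yaml(self, handle: IO[str] | str) -> None:
        payload = {
            "categories": {
                cat: sorted(k for k, c in self.keyword_to_category.items() if c == cat)
                for cat in CATEGORIES
            },
            "neutral_keywords": sorted(self.neutral_keywords),
            "collocation_words": sorted(self.collocation_words),
            "collocation_window": self.collocation_window,
        }
        if isinstance(handle, str):
            with open(handle, "w", encoding="utf-8") as fh:
                yaml.safe_dump(payload, fh, sort_keys=True)
        else:
            yaml.safe_dump(payload, handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, handle: IO[str] | str) -> "CategoryLexicon":
        if isinstance(handle, str):
            with open(handle, encoding="utf-8") as fh:
                payload = yaml.safe_load(fh)
        else:
            payload = yaml.safe_load(handle)
        mapping: dict[str, str] = {}
        for cat, words in (payload.get("categories") or {}).items():
            for w in words or []:
                mapping[str(w)] = str(cat)
        return cls(
            keyword_to_category=mapping,
            neutral_keywords=frozenset(payload.get("neutral_keywords") or []),
            collocation_words=frozenset(payload.get("collocation_words") or []),
            collocation_window=int(payload.get("collocation_window", 5)),
        )


def demo_lexicon() -> CategoryLexicon:
    """Small built-in lexicon with transliterated keyword names.

    Ships so that the pipeline and the synthetic generator run without any
    external configuration; real analyses supply their own inventory.
    """
    mapping = {
        # benefit expansion
        "reimbursement_rate": "benefit_expansion",
        "maximum_payment": "benefit_expansion",
        "supplementary_program": "benefit_expansion",
        "medicine_catalogue": "benefit_expansion",
        # cost containment
        "per_diem_payment": "cost_containment",
        "global_budget": "cost_containment",
        "designated_facility_management": "cost_containment",
        "fund_expense_control": "cost_containment",
        "price_negotiation": "cost_containment",
        # supply side
        "referral_system": "service_delivery",
        "service_efficiency": "service_delivery",
        "drug_pricing": "pharmaceutical",
        "essential_medicines": "pharmaceutical",
    }
    return CategoryLexicon(
        keyword_to_category=mapping,
        neutral_keywords=frozenset({"reimbursement_rate", "maximum_payment"}),
        collocation_words=frozenset({"increase", "improve", "enhance", "expand"}),
        collocation_window=5,
    )


def _ngram_positions(stream: Sequence[str], phrase: tuple[str, ...]) -> list[int]:
    n = len(phrase)
    return [
        i
        for i in range(len(stream) - n + 1)
        if tuple(stream[i : i + n]) == phrase
    ]


def _qualified_occurrences(
    stream: Sequence[str],
    phrase: tuple[str, ...],
    neutral: bool,
    collocation_words: frozenset[str],
    window: int,
) -> int:
    """Count occurrences of ``phrase`` in one token stream.

    Neutral phrases require a collocation word within ``window`` tokens on
    either side of the occurrence span.
    """
    positions = _ngram_positions(stream, phrase)
    if not neutral:
        return len(positions)
    n = len(phrase)
    count = 0
    for pos in positions:
        lo = max(0, pos - window)
        hi = min(len(stream), pos + n + window)
        context = list(stream[lo:pos]) + list(stream[pos + n : hi])
        if collocation_words.intersection(context):
            count += 1
    return count


def count_document_categories(
    doc: PolicyDocument,
    keyword_set: KeywordSet,
    lexicon: CategoryLexicon,
    *,
    extracted_only: bool = True,
) -> dict[str, int]:
    """Per-category qualified keyword occurrence counts for one document.

    Only keywords that were extracted for the document contribute (a multi-token
    lexicon phrase contributes when any of its constituent tokens was
    extracted); set ``extracted_only=False`` to count every lexicon keyword
    regardless, for sensitivity analysis.  Occurrences are counted over the
    title and body streams separately so collocation windows never span the
    title/body boundary.
    """
    if keyword_set.doc_id != doc.doc_id:
        raise ExposureError(
            f"keyword set {keyword_set.doc_id!r} does not belong to document {doc.doc_id!r}"
        )
    doc_tokens = set(doc.tokens)
    missing = [t for t in keyword_set.tokens if t not in doc_tokens]
    if missing:
        raise ExposureError(
            f"keyword(s) {missing} not present in document {doc.doc_id!r}: corrupt keyword set"
        )

    extracted = set(keyword_set.tokens)
    counts = {cat: 0 for cat in CATEGORIES}
    for keyword, category in lexicon.keyword_to_category.items():
        phrase = tuple(keyword.split())
        if extracted_only and not extracted.intersection(phrase):
            continue
        neutral = keyword in lexicon.neutral_keywords
        occurrences = 0
        for stream in (doc.title_tokens, doc.body_tokens):
            occurrences += _qualified_occurrences(
                stream, phrase, neutral, lexicon.collocation_words, lexicon.collocation_window
            )
        counts[category] += occurrences
    return counts


@dataclass(frozen=True)
class DocCategoryCounts:
    doc_id: str
    prefecture_id: str
    year: int
    counts: Mapping[str, int]


def aggregate_prefecture_year(doc_counts: Iterable[DocCategoryCounts]) -> pd.DataFrame:
    """Sum per-document category counts to prefecture-year totals.

    Returns a frame with columns prefecture_id, year and one column per
    category, sorted by (prefecture_id, year).  Order of input documents is
    irrelevant.
    """
    rows = [
        {"prefecture_id": dc.prefecture_id, "year": dc.year}
        | {cat: int(dc.counts.get(cat, 0)) for cat in CATEGORIES}
        for dc in doc_counts
    ]
    if not rows:
        return pd.DataFrame(columns=["prefecture_id", "year", *CATEGORIES])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["prefecture_id", "year"], as_index=False)[list(CATEGORIES)]
        .sum()
        .sort_values(["prefecture_id", "year"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


@dataclass(frozen=True)
class ExposureTable:
    """Prefecture-year cumulative category scores plus launch years.

    ``data`` columns: prefecture_id, year, launch_year, then one column per
    category.  ``divisor`` records any rescaling applied to the category
    columns (raw integer counts have divisor 1).
    """

    data: pd.DataFrame
    divisor: float = 1.0

    def __post_init__(self) -> None:
        expected = ["prefecture_id", "year", "launch_year", *CATEGORIES]
        missing = [c for c in expected if c not in self.data.columns]
        if missing:
            raise ExposureError(f"exposure table missing columns: {missing}")

    def validate(self) -> None:
        """Assert the structural invariants: zeros before launch, cumulative
        series non-decreasing within prefecture, non-negative values."""
        df = self.data.sort_values(["prefecture_id", "year"])
        pre_launch = df[df["year"] < df["launch_year"]]
        for cat in CATEGORIES:
            if (df[cat] < 0).any():
                raise ExposureError(f"negative exposure in column {cat}")
            if not pre_launch.empty and (pre_launch[cat] != 0).any():
                raise ExposureError(f"nonzero {cat} before launch year")
            diffs = df.groupby("prefecture_id")[cat].diff().dropna()
            post = df["year"] >= df["launch_year"]
            # only post-launch differences must be non-decreasing; the step
            # into the launch year is a jump from structural zeros
            decreasing = diffs[diffs < -1e-12]
            if not decreasing.empty and post.loc[decreasing.index].any():
                raise ExposureError(f"cumulative series decreases in column {cat}")

    def to_csv(self, handle: IO[str] | str) -> None:
        if isinstance(handle, str):
            with open(handle, "w", encoding="utf-8", newline="\n") as fh:
                self.to_csv(fh)
            return
        handle.write(f"# divisor={self.divisor!r}\n")
        self.data.to_csv(handle, index=False, lineterminator="\n")

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, handle: IO[str] | str) -> "ExposureTable":
        if isinstance(handle, str):
            with open(handle, encoding="utf-8") as fh:
                return cls.from_csv(fh)
        first = handle.readline()
        divisor = 1.0
        if first.startswith("# divisor="):
            divisor = float(first.split("=", 1)[1])
            data = pd.read_csv(handle)
        else:
            data = pd.read_csv(io.StringIO(first + handle.read()))
        return cls(data=data, divisor=divisor)

    def lookup(self, prefecture_id: str, year: int) -> pd.Series:
        rows = self.data[
            (self.data["prefecture_id"] == prefecture_id) & (self.data["year"] == year)
        ]
        if rows.empty:
            raise ExposureError(f"no exposure row for ({prefecture_id!r}, {year})")
        return rows.iloc[0]


def cumulate(
    yearly: pd.DataFrame,
    launch_years: Mapping[str, int],
    years: Iterable[int] | None = None,
) -> ExposureTable:
    """Build the cumulative exposure table from yearly prefecture counts.

    value(p, t) = sum of yearly counts from launch(p) through t for
    t >= launch(p), and exactly 0 for years before the launch — counts dated
    before a prefecture's launch never enter the cumulative series.
    """
    present = sorted(set(yearly["prefecture_id"])) if len(yearly) else []
    missing = [p for p in present if p not in launch_years]
    if missing:
        raise ExposureError(f"launch year unknown for prefecture(s): {missing}")

    prefectures = sorted(launch_years)
    if years is None:
        candidates = list(launch_years.values())
        if len(yearly):
            candidates += [int(yearly["year"].min()), int(yearly["year"].max())]
        years = range(min(candidates), max(candidates) + 1)
    years = sorted(set(int(y) for y in years))

    indexed = (
        yearly.set_index(["prefecture_id", "year"])[list(CATEGORIES)]
        if len(yearly)
        else pd.DataFrame(columns=list(CATEGORIES))
    )
    rows = []
    for pref in prefectures:
        launch = int(launch_years[pref])
        running = {cat: 0 for cat in CATEGORIES}
        for year in years:
            if year >= launch and (pref, year) in getattr(indexed, "index", ()):
                row = indexed.loc[(pref, year)]
                for cat in CATEGORIES:
                    running[cat] += int(row[cat])
            values = dict(running) if year >= launch else {cat: 0 for cat in CATEGORIES}
            rows.append(
                {"prefecture_id": pref, "year": year, "launch_year": launch} | values
            )
    table = ExposureTable(data=pd.DataFrame(rows), divisor=1.0)
    table.validate()
    return table


def rescale(table: ExposureTable, divisor: float) -> ExposureTable:
    """Divide all category columns by ``divisor`` (a pure units choice; the
    divisor is recorded in the table metadata)."""
    if not (isinstance(divisor, (int, float)) and math.isfinite(divisor) and divisor > 0):
        raise ExposureError(f"divisor must be a positive finite number, got {divisor!r}")
    data = table.data.copy()
    for cat in CATEGORIES:
        data[cat] = data[cat] / divisor
    return replace(table, data=data, divisor=table.divisor * divisor)
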