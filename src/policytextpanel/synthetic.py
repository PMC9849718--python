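"""Synthetic corpus and panel generators with fully known ground truth.

Every downstream stage is testable against the truth objects returned here:
per-document planted category counts, the cumulative exposure table, the
spending-equation coefficients and the enrolment instruments.

Determinism: each generator call derives one RNG stream per prefecture from
the spec seed, so adding prefectures never perturbs existing ones and the same
seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import PolicyDocument
from .exposure import CATEGORIES, ExposureTable, demo_lexicon

RELEVANCE_TOKENS = ("medical", "medicine", "health", "hospital")
UEBMI_TOKEN = "uebmi"

_LEX = demo_lexicon()
_EXPANSION_NEUTRAL = tuple(
    sorted(
        k
        for k, c in _LEX.keyword_to_category.items()
        if c == "benefit_expansion" and k in _LEX.neutral_keywords
    )
)
_EXPANSION_PLAIN = tuple(
    sorted(
        k
        for k, c in _LEX.keyword_to_category.items()
        if c == "benefit_expansion" and k not in _LEX.neutral_keywords
    )
)
_CONTAINMENT = tuple(
    sorted(k for k, c in _LEX.keyword_to_category.items() if c == "cost_containment")
)
_SUPPLY = tuple(
    sorted(
        (k, c)
        for k, c in _LEX.keyword_to_category.items()
        if c in ("service_delivery", "pharmaceutical")
    )
)
_COLLOCATIONS = tuple(sorted(_LEX.collocation_words))

# separator between planted units; strictly larger than the lexicon's
# collocation window so units never qualify each other
_SEPARATION = _LEX.collocation_window + 1


class ConfigError(ValueError):
    pass


class CoverageError(ValueError):
    """The exposure table does not cover a needed prefecture-year."""


def _check_unit_interval(**named: float) -> None:
    for name, value in named.items():
        if not (0.0 <= value <= 1.0):
            raise ConfigError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class CorpusSpec:
    """Configuration of the document-corpus generator.

    ``docs_per_year_rate`` is the Poisson mean of scheme documents per
    prefecture-year after launch; ``noise_docs_per_year_rate`` governs
    non-scheme documents (a ``relevant_fraction`` of which pass the
    health-relevance title filter).  Propensities control how often a scheme
    document plants a keyword of each category.
    """

    n_prefectures: int = 50
    years: tuple[int, int] = (1997, 2015)
    launch_year_range: tuple[int, int] = (1998, 2003)
    docs_per_year_rate: float = 1.5
    expansion_propensity: float = 0.55
    containment_propensity: float = 0.45
    neutral_keyword_rate: float = 0.30
    vocab_size: int = 150
    seed: int = 0
    noise_docs_per_year_rate: float = 1.0
    relevant_fraction: float = 0.4
    supply_rate: float = 0.5
    supply_in_noise_docs: bool = False
    collocated_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.n_prefectures < 1:
            raise ConfigError("n_prefectures must be >= 1")
        if self.years[0] > self.years[1]:
            raise ConfigError(f"empty year range {self.years}")
        lo, hi = self.launch_year_range
        if lo > hi or lo < self.years[0] or hi > self.years[1]:
            raise ConfigError(
                f"launch_year_range {self.launch_year_range} not within years {self.years}"
            )
        if self.docs_per_year_rate < 0 or self.noise_docs_per_year_rate < 0:
            raise ConfigError("document rates must be >= 0")
        if self.vocab_size < 30:
            raise ConfigError("vocab_size must be >= 30")
        _check_unit_interval(
            expansion_propensity=self.expansion_propensity,
            containment_propensity=self.containment_propensity,
            neutral_keyword_rate=self.neutral_keyword_rate,
            relevant_fraction=self.relevant_fraction,
            supply_rate=self.supply_rate,
            collocated_fraction=self.collocated_fraction,
        )


@dataclass(frozen=True)
class CorpusTruth:
    """Ground truth emitted alongside the synthetic corpus.

    ``doc_truth`` has one row per document with relevance/scheme tags and the
    countable (collocation-qualified) keyword occurrences planted per category.
    ``exposure`` is the cumulative table the pipeline should reproduce.
    """

    doc_truth: pd.DataFrame
    yearly: pd.DataFrame
    exposure: ExposureTable
    launch_years: dict[str, int]
    propensities: pd.DataFrame


def _draw_propensity(rng: np.random.Generator, mean: float) -> float:
    # Beta with mean exactly `mean`; degenerate at the endpoints.  The
    # concentration keeps cross-prefecture heterogeneity moderate so exposure
    # leverage is not dominated by a handful of prefectures.
    if mean <= 0.0:
        return 0.0
    if mean >= 1.0:
        return 1.0
    return float(rng.beta(8.0 * mean, 8.0 * (1.0 - mean)))


def _keyword_unit(
    rng: np.random.Generator, keyword: str, count: int, collocated: bool
) -> list[str]:
    """A contiguous run of `count` keyword occurrences; collocated units place
    a collocation word directly before every occurrence."""
    if collocated:
        unit: list[str] = []
        for _ in range(count):
            unit.append(_COLLOCATIONS[int(rng.integers(len(_COLLOCATIONS)))])
            unit.append(keyword)
        return unit
    return [keyword] * count


def _filler(rng: np.random.Generator, vocab_size: int, n_units: int) -> list[str]:
    # each filler token appears at most once per document, keeping its term
    # frequency at 1 so planted keywords (tf >= 2) dominate the TF-IDF ranking
    m = min(int(18 + rng.poisson(8)), vocab_size)
    m = max(m, _SEPARATION * n_units)
    picks = rng.choice(vocab_size, size=m, replace=False)
    return [f"w{i}" for i in picks]


def _assemble_body(rng: np.random.Generator, units: list[list[str]], vocab_size: int) -> list[str]:
    filler = _filler(rng, vocab_size, len(units))
    body: list[str] = []
    idx = 0
    for unit in units:
        body.extend(unit)
        body.extend(filler[idx : idx + _SEPARATION])
        idx += _SEPARATION
    body.extend(filler[idx:])
    return body


def generate_corpus(spec: CorpusSpec) -> tuple[list[PolicyDocument], CorpusTruth]:
    """Emit a synthetic policy corpus plus its exact ground truth.

    Scheme documents exist only from the prefecture's launch year onward and
    always carry the scheme token in the title; documents dated before launch
    never contain scheme-category keywords.
    """
    docs: list[PolicyDocument] = []
    truth_rows: list[dict] = []
    launch_years: dict[str, int] = {}
    prop_rows: list[dict] = []
    y0, y1 = spec.years

    for pidx in range(spec.n_prefectures):
        pref = f"p{pidx:03d}"
        rng = np.random.default_rng([spec.seed, pidx])
        launch = int(rng.integers(spec.launch_year_range[0], spec.launch_year_range[1] + 1))
        launch_years[pref] = launch
        prop_exp = _draw_propensity(rng, spec.expansion_propensity)
        prop_cont = _draw_propensity(rng, spec.containment_propensity)
        prop_rows.append(
            {"prefecture_id": pref, "expansion": prop_exp, "containment": prop_cont}
        )

        for year in range(y0, y1 + 1):
            n_uebmi = int(rng.poisson(spec.docs_per_year_rate)) if year >= launch else 0
            for serial in range(n_uebmi):
                units: list[list[str]] = []
                counts = dict.fromkeys(CATEGORIES, 0)
                if rng.random() < prop_exp:
                    count = int(3 + rng.poisson(2.0))
                    if _EXPANSION_NEUTRAL and rng.random() < spec.neutral_keyword_rate:
                        kw = _EXPANSION_NEUTRAL[int(rng.integers(len(_EXPANSION_NEUTRAL)))]
                        collocated = bool(rng.random() < spec.collocated_fraction)
                        units.append(_keyword_unit(rng, kw, count, collocated))
                        if collocated:
                            counts["benefit_expansion"] += count
                    else:
                        kw = _EXPANSION_PLAIN[int(rng.integers(len(_EXPANSION_PLAIN)))]
                        units.append(_keyword_unit(rng, kw, count, False))
                        counts["benefit_expansion"] += count
                if rng.random() < prop_cont:
                    count = int(3 + rng.poisson(2.0))
                    kw = _CONTAINMENT[int(rng.integers(len(_CONTAINMENT)))]
                    units.append(_keyword_unit(rng, kw, count, False))
                    counts["cost_containment"] += count
                if rng.random() < spec.supply_rate:
                    count = int(2 + rng.poisson(1.0))
                    kw, cat = _SUPPLY[int(rng.integers(len(_SUPPLY)))]
                    units.append(_keyword_unit(rng, kw, count, False))
                    counts[cat] += count
                title = (
                    RELEVANCE_TOKENS[int(rng.integers(len(RELEVANCE_TOKENS)))],
                    UEBMI_TOKEN,
                    "policy",
                )
                body = _assemble_body(rng, units, spec.vocab_size)
                doc_id = f"{pref}-{year}-u{serial}"
                docs.append(
                    PolicyDocument(doc_id, pref, year, title, tuple(body))
                )
                truth_rows.append(
                    {
                        "doc_id": doc_id,
                        "prefecture_id": pref,
                        "year": year,
                        "is_relevant": True,
                        "is_uebmi": True,
                    }
                    | counts
                )

            n_noise = int(rng.poisson(spec.noise_docs_per_year_rate))
            for serial in range(n_noise):
                relevant = bool(rng.random() < spec.relevant_fraction)
                counts = dict.fromkeys(CATEGORIES, 0)
                units = []
                if relevant and spec.supply_in_noise_docs and rng.random() < spec.supply_rate:
                    count = int(2 + rng.poisson(1.0))
                    kw, cat = _SUPPLY[int(rng.integers(len(_SUPPLY)))]
                    units.append(_keyword_unit(rng, kw, count, False))
                    counts[cat] += count
                if relevant:
                    title = (
                        RELEVANCE_TOKENS[int(rng.integers(len(RELEVANCE_TOKENS)))],
                        "circular",
                    )
                else:
                    title = ("road", "construction", "circular")
                body = _assemble_body(rng, units, spec.vocab_size)
                doc_id = f"{pref}-{year}-n{serial}"
                docs.append(PolicyDocument(doc_id, pref, year, title, tuple(body)))
                truth_rows.append(
                    {
                        "doc_id": doc_id,
                        "prefecture_id": pref,
                        "year": year,
                        "is_relevant": relevant,
                        "is_uebmi": False,
                    }
                    | counts
                )

    columns = ["doc_id", "prefecture_id", "year", "is_relevant", "is_uebmi", *CATEGORIES]
    doc_truth = pd.DataFrame(truth_rows, columns=columns)

    yearly = (
        doc_truth.groupby(["prefecture_id", "year"], as_index=False)[list(CATEGORIES)].sum()
        if len(doc_truth)
        else pd.DataFrame(columns=["prefecture_id", "year", *CATEGORIES])
    )

    # independent cumulation (not exposure.cumulate), zero before launch
    yearly_idx = (
        yearly.set_index(["prefecture_id", "year"]) if len(yearly) else pd.DataFrame()
    )
    exp_rows = []
    for pref in sorted(launch_years):
        launch = launch_years[pref]
        running = dict.fromkeys(CATEGORIES, 0)
        for year in range(y0, y1 + 1):
            if year >= launch:
                if len(yearly_idx) and (pref, year) in yearly_idx.index:
                    row = yearly_idx.loc[(pref, year)]
                    for cat in CATEGORIES:
                        running[cat] += int(row[cat])
                values = dict(running)
            else:
                values = dict.fromkeys(CATEGORIES, 0)
            exp_rows.append(
                {"prefecture_id": pref, "year": year, "launch_year": launch} | values
            )
    exposure = ExposureTable(data=pd.DataFrame(exp_rows), divisor=1.0)

    return docs, CorpusTruth(
        doc_truth=doc_truth,
        yearly=yearly,
        exposure=exposure,
        launch_years=launch_years,
        propensities=pd.DataFrame(prop_rows),
    )


# ---------------------------------------------------------------------------
# panel generator


@dataclass(frozen=True)
class Beta:
    """Ground-truth coefficients of the spending equation."""

    b0: float = 5.0
    b1_enroll: float = -0.3
    b2_expansion: float = 0.25
    b3_containment: float = 0.20
    b4_enroll_expansion: float = 0.15
    b5_enroll_containment: float = -0.20
    b6_expansion_containment: float = -0.55
    b7_threeway: float = -0.50
    lambda_service: float = 0.05
    lambda_pharma: float = -0.05
    delta: Mapping[str, float] = field(
        default_factory=lambda: {
            "days_unable": 0.05,
            "severity": 0.8,
            "chronic": 0.1,
            "utilization": 1.5,
            "age": 0.01,
            "schooling_years": -0.01,
            "household_size": 0.0,
            "log_income": 0.02,
        }
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", dict(self.delta))

    @classmethod
    def zeros(cls) -> "Beta":
        return cls(
            b0=0.0,
            b1_enroll=0.0,
            b2_expansion=0.0,
            b3_containment=0.0,
            b4_enroll_expansion=0.0,
            b5_enroll_containment=0.0,
            b6_expansion_containment=0.0,
            b7_threeway=0.0,
            lambda_service=0.0,
            lambda_pharma=0.0,
            delta={},
        )


@dataclass(frozen=True)
class Alpha:
    """Enrolment-equation (logit) coefficients."""

    a0: float = -2.2
    a_uebmi_pen: float = 5.5
    a_gmi_pen: float = -2.0
    a_confounder: float = 0.8


@dataclass(frozen=True)
class PanelSpec:
    """Configuration of the individual-panel generator.

    ``p_spend_intercept`` is the baseline probability of any positive spending
    (probit link, default 1.0 so the default process is purely log-linear; set
    below 1 to exercise the two-part structure).  ``gamma_confounder`` loads a
    time-varying latent confounder into the spending equation; the same latent
    enters the enrolment equation via ``alpha.a_confounder``, creating the
    endogeneity the instruments must fix.
    """

    n_individuals_per_prefecture_wave: int = 17
    waves: tuple[int, ...] = (1997, 2000, 2004, 2006, 2009, 2011, 2015)
    beta: Beta = field(default_factory=Beta)
    alpha: Alpha = field(default_factory=Alpha)
    gamma_confounder: float = 0.6
    sigma_individual_fe: float = 0.8
    sigma_noise: float = 1.0
    p_spend_intercept: float = 1.0
    attrition_rate: float = 0.45
    year_effect_per_wave: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "waves", tuple(int(w) for w in self.waves))
        if self.n_individuals_per_prefecture_wave < 1:
            raise ConfigError("n_individuals_per_prefecture_wave must be >= 1")
        if list(self.waves) != sorted(set(self.waves)):
            raise ConfigError("waves must be strictly ascending")
        if self.sigma_individual_fe < 0 or self.sigma_noise < 0:
            raise ConfigError("sigma values must be >= 0")
        _check_unit_interval(
            p_spend_intercept=self.p_spend_intercept, attrition_rate=self.attrition_rate
        )


@dataclass(frozen=True)
class PanelTruth:
    beta: Beta
    alpha: Alpha
    gamma_confounder: float
    individual_effects: pd.DataFrame  # person_id, fe
    instruments: pd.DataFrame  # prefecture_id, year, uebmi_penetration, gmi_penetration
    year_effects: dict[int, float]


_MIN_LOG_SPEND = 0.01  # floor on positive log spending; negligible mass at defaults


def generate_panel(
    spec: PanelSpec, exposure: ExposureTable
) -> tuple[pd.DataFrame, PanelTruth]:
    """Simulate an unbalanced individual panel over the exposure table's
    prefectures.

    Enrolment is Bernoulli with a logit linear in the two prefecture-level
    instruments (and the latent confounder); spending is two-part, with the log
    of positive spending following the three-way-interaction linear predictor
    plus an individual effect and noise.  The exposure table must cover every
    prefecture-wave; column values enter the spending equation as given (apply
    any rescaling before calling).
    """
    exp_df = exposure.data
    prefectures = sorted(exp_df["prefecture_id"].unique())
    exp_idx = exp_df.set_index(["prefecture_id", "year"])
    missing = [
        (p, w) for p in prefectures for w in spec.waves if (p, w) not in exp_idx.index
    ]
    if missing:
        raise CoverageError(f"exposure table missing prefecture-years: {missing[:10]}")

    launch = {
        p: int(exp_df.loc[exp_df["prefecture_id"] == p, "launch_year"].iloc[0])
        for p in prefectures
    }

    b = spec.beta
    a = spec.alpha
    year_effects = {w: spec.year_effect_per_wave * i for i, w in enumerate(spec.waves)}
    z_spend = stats.norm.ppf(spec.p_spend_intercept) if spec.p_spend_intercept < 1.0 else np.inf

    rows: list[pd.DataFrame] = []
    fe_rows: list[pd.DataFrame] = []
    instrument_rows: list[dict] = []
    n = spec.n_individuals_per_prefecture_wave

    for pidx, pref in enumerate(prefectures):
        rng = np.random.default_rng([spec.seed, 104729, pidx])

        pens = {}
        for w in spec.waves:
            if w >= launch[pref]:
                upen = float(
                    np.clip(0.12 + 0.05 * (w - launch[pref]) + rng.normal(0, 0.10), 0.02, 0.90)
                )
            else:
                upen = 0.0
            gpen = float(np.clip(0.35 - 0.45 * upen + rng.normal(0, 0.07), 0.0, 0.90))
            pens[w] = (upen, gpen)
            instrument_rows.append(
                {
                    "prefecture_id": pref,
                    "year": w,
                    "uebmi_penetration": upen,
                    "gmi_penetration": gpen,
                }
            )

        # person registry for this prefecture
        next_person = 0
        active: list[int] = []
        person_fe: dict[int, float] = {}
        person_age0: dict[int, float] = {}
        person_school: dict[int, float] = {}
        person_hh: dict[int, int] = {}
        person_chronic: dict[int, int] = {}
        person_entry: dict[int, int] = {}

        for widx, w in enumerate(spec.waves):
            if widx > 0:
                keep = rng.random(len(active)) >= spec.attrition_rate
                active = [p for p, k in zip(active, keep) if k]
            n_new = max(0, n - len(active))
            for _ in range(n_new):
                pid = next_person
                next_person += 1
                person_fe[pid] = float(rng.normal(0.0, spec.sigma_individual_fe))
                person_age0[pid] = float(rng.integers(20, 56))
                person_school[pid] = float(np.clip(round(rng.normal(9.5, 3.5)), 0, 18))
                person_hh[pid] = int(1 + rng.poisson(2.7))
                person_chronic[pid] = int(rng.random() < 0.05)
                person_entry[pid] = w
                active.append(pid)

            m = len(active)
            ids = np.array(active)
            upen, gpen = pens[w]
            exp_row = exp_idx.loc[(pref, w)]
            expansion = float(exp_row["benefit_expansion"])
            containment = float(exp_row["cost_containment"])
            service = float(exp_row["service_delivery"])
            pharma = float(exp_row["pharmaceutical"])

            severity = rng.choice(4, size=m, p=[0.85, 0.06, 0.07, 0.02])
            days = np.where(severity > 0, rng.poisson(2.0 * severity), 0).astype(float)
            utilization = (
                rng.random(m) < (0.06 + 0.25 * (severity > 0))
            ).astype(float)
            log_income = rng.normal(8.5, 1.2, size=m)
            # reported age jitters by up to a year so it is not exactly
            # collinear with the year dummies after demeaning
            age = np.array(
                [person_age0[p] + (w - person_entry[p]) for p in active]
            ) + rng.integers(-1, 2, size=m)
            schooling = np.array([person_school[p] for p in active])
            household = np.array([person_hh[p] for p in active], dtype=float)
            chronic = np.array([person_chronic[p] for p in active], dtype=float)
            fe = np.array([person_fe[p] for p in active])

            conf = rng.normal(0.0, 1.0, size=m)
            if w >= launch[pref]:
                logit = a.a0 + a.a_uebmi_pen * upen + a.a_gmi_pen * gpen + a.a_confounder * conf
                p_enroll = 1.0 / (1.0 + np.exp(-logit))
                enrolled = (rng.random(m) < p_enroll).astype(float)
            else:
                enrolled = np.zeros(m)

            covars = {
                "days_unable": days,
                "severity": severity.astype(float),
                "chronic": chronic,
                "utilization": utilization,
                "age": age.astype(float),
                "schooling_years": schooling,
                "household_size": household,
                "log_income": log_income,
            }
            predictor = (
                b.b0
                + b.b1_enroll * enrolled
                + b.b2_expansion * expansion
                + b.b3_containment * containment
                + b.b4_enroll_expansion * enrolled * expansion
                + b.b5_enroll_containment * enrolled * containment
                + b.b6_expansion_containment * expansion * containment
                + b.b7_threeway * enrolled * expansion * containment
                + b.lambda_service * service
                + b.lambda_pharma * pharma
                + year_effects[w]
                + fe
                + spec.gamma_confounder * conf
                + rng.normal(0.0, spec.sigma_noise, size=m)
            )
            for name, value in b.delta.items():
                predictor = predictor + value * covars[name]

            if np.isinf(z_spend):
                spender = np.ones(m, dtype=bool)
            else:
                spender = rng.random(m) < stats.norm.cdf(z_spend)
            log_oop = np.where(spender, np.maximum(predictor, _MIN_LOG_SPEND), 0.0)
            oop_raw = np.expm1(log_oop)

            rows.append(
                pd.DataFrame(
                    {
                        "person_id": [f"{pref}-i{p}" for p in ids],
                        "prefecture_id": pref,
                        "year": w,
                        "uebmi_enrolled": enrolled,
                        "oop_raw": oop_raw,
                        "log_oop": log_oop,
                        **covars,
                        "uebmi_penetration": upen,
                        "gmi_penetration": gpen,
                    }
                )
            )

        fe_rows.append(
            pd.DataFrame(
                {
                    "person_id": [f"{pref}-i{p}" for p in sorted(person_fe)],
                    "fe": [person_fe[p] for p in sorted(person_fe)],
                }
            )
        )

    panel = pd.concat(rows, ignore_index=True)
    truth = PanelTruth(
        beta=b,
        alpha=a,
        gamma_confounder=spec.gamma_confounder,
        individual_effects=pd.concat(fe_rows, ignore_index=True),
        instruments=pd.DataFrame(instrument_rows),
        year_effects=year_effects,
    )
    return panel, truth


def write_panel_csv(panel: pd.DataFrame, path: str) -> None:
    panel.to_csv(path, index=False, lineterminator="\n")
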