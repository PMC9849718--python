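"""End-to-end orchestration: simulate/load -> extract -> score -> merge -> fit.

Every stage writes a text artifact into the run directory; the manifest records
a content hash and row counts for each, so identical config + seed yields
identical hashes and no stage ever mutates an upstream artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import corpus as corpus_mod
from . import estimators, exposure as exposure_mod, panel as panel_mod, synthetic

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = (
    "days_unable",
    "severity",
    "chronic",
    "utilization",
    "age",
    "schooling_years",
    "household_size",
    "log_income",
)

DEFAULT_MODELS: tuple[dict, ...] = (
    {
        "name": "macro_interaction_fe",
        "outcome": "log_oop",
        "regressors": [
            "benefit_expansion",
            "cost_containment",
            "benefit_expansion:cost_containment",
            "service_delivery",
            "pharmaceutical",
            *DEFAULT_COVARIATES,
        ],
    },
    {
        "name": "micro_threeway_fe",
        "outcome": "log_oop",
        "regressors": [
            "uebmi_enrolled",
            "benefit_expansion",
            "cost_containment",
            "uebmi_enrolled:benefit_expansion",
            "uebmi_enrolled:cost_containment",
            "benefit_expansion:cost_containment",
            "uebmi_enrolled:benefit_expansion:cost_containment",
            "service_delivery",
            "pharmaceutical",
            *DEFAULT_COVARIATES,
        ],
        "lincoms": [
            "uebmi_enrolled + uebmi_enrolled:benefit_expansion",
            "uebmi_enrolled + uebmi_enrolled:cost_containment",
            "uebmi_enrolled + uebmi_enrolled:benefit_expansion"
            " + uebmi_enrolled:cost_containment"
            " + uebmi_enrolled:benefit_expansion:cost_containment",
        ],
    },
    {
        "name": "micro_iv",
        "outcome": "log_oop",
        "regressors": [
            "service_delivery",
            "pharmaceutical",
            *DEFAULT_COVARIATES,
        ],
        "endogenous": "uebmi_enrolled",
        "instruments": ["uebmi_penetration", "gmi_penetration"],
    },
)


class ConfigValidationError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration.

    In ``simulate`` mode the corpus and panel are generated from the embedded
    spec blocks; in ``files`` mode all referenced input files must exist before
    any computation starts.
    """

    mode: str = "simulate"
    out_dir: str = "run_output"
    seed: int = 0
    corpus_spec: Mapping = field(default_factory=dict)
    panel_spec: Mapping = field(default_factory=dict)
    corpus_path: str | None = None
    lexicon_path: str | None = None
    panel_path: str | None = None
    launch_years_path: str | None = None
    deflator_path: str | None = None
    base_year: int = 2015
    relevance_tokens: tuple[str, ...] = synthetic.RELEVANCE_TOKENS
    uebmi_token: str = synthetic.UEBMI_TOKEN
    k_keywords: int = 5
    divisor: float = 100.0
    models: tuple[Mapping, ...] = DEFAULT_MODELS
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ConfigValidationError(f"unknown mode {self.mode!r}")
        if self.divisor <= 0:
            raise ConfigValidationError("divisor must be positive")
        if self.mode == "files":
            for label in ("corpus_path", "lexicon_path", "panel_path", "launch_years_path"):
                path = getattr(self, label)
                if path is None:
                    raise ConfigValidationError(f"files mode requires {label}")
                if not os.path.exists(path):
                    raise ConfigValidationError(f"{label} does not exist: {path}")
        elif self.lexicon_path is not None and not os.path.exists(self.lexicon_path):
            raise ConfigValidationError(f"lexicon_path does not exist: {self.lexicon_path}")
        object.__setattr__(self, "relevance_tokens", tuple(self.relevance_tokens))
        object.__setattr__(self, "models", tuple(dict(m) for m in self.models))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _parse_spec(block: Mapping, cls):
    block = dict(block)
    if cls is synthetic.PanelSpec:
        if isinstance(block.get("beta"), Mapping):
            block["beta"] = synthetic.Beta(**block["beta"])
        if isinstance(block.get("alpha"), Mapping):
            block["alpha"] = synthetic.Alpha(**block["alpha"])
    return cls(**block)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.out_dir, exist_ok=True)
    artifacts: dict[str, str] = {}
    counts: dict[str, int] = {}

    def save(name: str, writer) -> str:
        path = os.path.join(config.out_dir, name)
        writer(path)
        artifacts[name] = _sha256(path)
        return path

    # ---- stage: inputs
    if config.mode == "simulate":
        try:
            cspec = _parse_spec(
                {"seed": config.seed, **dict(config.corpus_spec)}, synthetic.CorpusSpec
            )
            docs, corpus_truth = synthetic.generate_corpus(cspec)
        except Exception as exc:  # noqa: BLE001
            raise StageError("simulate_corpus", exc) from exc
        save("corpus.jsonl", lambda p: corpus_mod.write_corpus_jsonl(docs, p))
        save(
            "truth_doc_categories.csv",
            lambda p: corpus_truth.doc_truth.to_csv(p, index=False, lineterminator="\n"),
        )
        save("truth_exposure.csv", corpus_truth.exposure.to_csv)
        launch_years = corpus_truth.launch_years
        save(
            "launch_years.csv",
            lambda p: pd.DataFrame(
                sorted(launch_years.items()), columns=["prefecture_id", "launch_year"]
            ).to_csv(p, index=False, lineterminator="\n"),
        )
        lexicon = (
            exposure_mod.CategoryLexicon.from_yaml(config.lexicon_path)
            if config.lexicon_path
            else exposure_mod.demo_lexicon()
        )
    else:
        docs = list(corpus_mod.read_corpus_jsonl(config.corpus_path))
        lexicon = exposure_mod.CategoryLexicon.from_yaml(config.lexicon_path)
        ly = pd.read_csv(config.launch_years_path)
        launch_years = dict(zip(ly["prefecture_id"].astype(str), ly["launch_year"].astype(int)))
    counts["documents_in"] = len(docs)

    # ---- stage: relevance filter
    try:
        relevant = corpus_mod.filter_relevant(docs, config.relevance_tokens)
    except Exception as exc:  # noqa: BLE001
        raise StageError("filter_relevant", exc) from exc
    counts["documents_relevant"] = len(relevant)

    # ---- stage: keyword extraction
    try:
        keyword_sets = corpus_mod.tfidf_keywords(relevant, k=config.k_keywords)
    except Exception as exc:  # noqa: BLE001
        raise StageError("tfidf_keywords", exc) from exc
    save(
        "keywords.jsonl",
        lambda p: open(p, "w", encoding="utf-8").write(
            "".join(ks.to_json() + "\n" for ks in keyword_sets)
        ),
    )

    # ---- stage: scheme-document identification
    try:
        uebmi_docs = corpus_mod.identify_uebmi_docs(relevant, keyword_sets, config.uebmi_token)
    except Exception as exc:  # noqa: BLE001
        raise StageError("identify_uebmi_docs", exc) from exc
    uebmi_ids = {d.doc_id for d in uebmi_docs}
    counts["documents_uebmi"] = len(uebmi_docs)

    # ---- stage: category counting + exposure table
    # scheme categories are counted only over scheme documents; supply-side
    # categories over every relevant document
    try:
        ks_by_id = {ks.doc_id: ks for ks in keyword_sets}
        doc_counts = []
        for doc in relevant:
            c = exposure_mod.count_document_categories(doc, ks_by_id[doc.doc_id], lexicon)
            if doc.doc_id not in uebmi_ids:
                c["benefit_expansion"] = 0
                c["cost_containment"] = 0
            doc_counts.append(
                exposure_mod.DocCategoryCounts(doc.doc_id, doc.prefecture_id, doc.year, c)
            )
        yearly = exposure_mod.aggregate_prefecture_year(doc_counts)
        years = None
        if config.mode == "simulate":
            years = range(cspec.years[0], cspec.years[1] + 1)
        table = exposure_mod.cumulate(yearly, launch_years, years=years)
        table = exposure_mod.rescale(table, config.divisor)
    except Exception as exc:  # noqa: BLE001
        raise StageError("exposure", exc) from exc
    save("exposure.csv", table.to_csv)
    counts["exposure_rows"] = len(table.data)

    # ---- stage: panel
    try:
        if config.mode == "simulate":
            pspec = _parse_spec(
                {"seed": config.seed, **dict(config.panel_spec)}, synthetic.PanelSpec
            )
            panel, _ = synthetic.generate_panel(pspec, table)
            panel = panel.drop(columns=["log_oop"])
            deflator = {int(y): 1.0 for y in panel["year"].unique()} | {config.base_year: 1.0}
        else:
            panel = pd.read_csv(config.panel_path)
            if config.deflator_path:
                dd = pd.read_csv(config.deflator_path)
                deflator = dict(zip(dd["year"].astype(int), dd["index"].astype(float)))
            else:
                deflator = {int(y): 1.0 for y in panel["year"].unique()} | {config.base_year: 1.0}
        panel["log_oop"] = panel_mod.deflate_and_log(
            panel["oop_raw"], panel["year"], deflator, config.base_year
        )
        save("panel.csv", lambda p: panel.to_csv(p, index=False, lineterminator="\n"))
        counts["panel_rows"] = len(panel)

        merged = panel_mod.merge_exposures(panel, table, strict=(config.mode == "simulate"))
        counts["merged_rows"] = len(merged.data)
        counts["merge_dropped"] = merged.n_unmatched
        analysis, dropped = panel_mod.drop_missing(
            merged.data, ["log_oop", *DEFAULT_COVARIATES]
        )
        counts["missing_dropped"] = dropped
        save("analysis.csv", lambda p: analysis.to_csv(p, index=False, lineterminator="\n"))
        summary = panel_mod.panel_summary(analysis)
        save("summary.tsv", lambda p: open(p, "w", encoding="utf-8").write(summary.to_tsv()))
    except Exception as exc:  # noqa: BLE001
        raise StageError("panel", exc) from exc

    # ---- stage: models
    results = {}
    for block in config.models:
        block = dict(block)
        name = block.pop("name", block.get("outcome", "model"))
        lincoms = block.pop("lincoms", [])
        try:
            spec = estimators.ModelSpec.from_dict(block)
            if spec.endogenous:
                fit = estimators.fit_fe_2sls(analysis, spec)
            else:
                fit = estimators.fit_twoway_fe(analysis, spec)
            if lincoms:
                fit = estimators.with_lincoms(fit, lincoms)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"fit:{name}", exc) from exc
        results[name] = fit.to_dict()
        save(f"fit_{name}.tsv", lambda p, f=fit: open(p, "w", encoding="utf-8").write(f.summary_tsv()))
    save(
        "results.json",
        lambda p: open(p, "w", encoding="utf-8").write(
            json.dumps(results, indent=2, sort_keys=True)
        ),
    )

    manifest = {
        "seed": config.seed,
        "mode": config.mode,
        "divisor": config.divisor,
        "counts": counts,
        "artifacts": artifacts,
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
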