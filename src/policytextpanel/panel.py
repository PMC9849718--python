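"""Analysis-panel construction: outcome transform, exposure merge, summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure import CATEGORIES, ExposureTable

logger = logging.getLogger(__name__)


class PanelError(ValueError):
    pass


def deflate_and_log(
    oop_raw: pd.Series | np.ndarray | float,
    years: pd.Series | np.ndarray | int,
    deflator: Mapping[int, float],
    base_year: int,
) -> pd.Series | np.ndarray | float:
    """log(1 + spending deflated to base-year prices).

    log_oop = ln(oop_raw * index(base_year)/index(year) + 1); zero spending maps
    to exactly zero.  The +1 keeps zero-spending observations in the sample.
    """
    if base_year not in deflator:
        raise PanelError(f"deflator missing base year {base_year}")
    scalar = np.isscalar(oop_raw) and np.isscalar(years)
    oop = np.asarray(oop_raw, dtype=float)
    yrs = np.atleast_1d(np.asarray(years))
    missing = sorted(set(int(y) for y in yrs) - set(deflator))
    if missing:
        raise PanelError(f"deflator missing year(s): {missing}")
    index = np.array([deflator[int(y)] for y in yrs], dtype=float)
    if (index <= 0).any() or deflator[base_year] <= 0:
        raise PanelError("deflator indices must be positive")
    result = np.log1p(oop * (deflator[base_year] / index))
    if scalar:
        return float(result[0]) if result.ndim else float(result)
    if isinstance(oop_raw, pd.Series):
        return pd.Series(result, index=oop_raw.index, name="log_oop")
    return result


@dataclass(frozen=True)
class MergeResult:
    data: pd.DataFrame
    n_unmatched: int


def merge_exposures(
    panel: pd.DataFrame, exposure: ExposureTable, *, strict: bool = True
) -> MergeResult:
    """Left-join exposure columns onto the panel by (prefecture_id, year).

    With ``strict`` any unmatched prefecture-year aborts with the offending
    keys; otherwise unmatched rows are dropped and counted.
    Outcome and covariate columns are never modified.
    """
    for col in ("prefecture_id", "year"):
        if col not in panel.columns:
            raise PanelError(f"panel missing merge key column {col!r}")
    exp_cols = ["prefecture_id", "year", "launch_year", *CATEGORIES]
    merged = panel.merge(
        exposure.data[exp_cols], on=["prefecture_id", "year"], how="left", indicator=True
    )
    unmatched = merged["_merge"] == "left_only"
    n_unmatched = int(unmatched.sum())
    if n_unmatched and strict:
        keys = (
            merged.loc[unmatched, ["prefecture_id", "year"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        raise PanelError(
            "unmatched prefecture-years in exposure table: "
            + ", ".join(f"({k.prefecture_id!r}, {k.year})" for k in keys)
        )
    if n_unmatched:
        logger.warning("merge_exposures dropped %d unmatched rows", n_unmatched)
        merged = merged[~unmatched]
    return MergeResult(
        data=merged.drop(columns="_merge").reset_index(drop=True),
        n_unmatched=n_unmatched,
    )


def drop_missing(
    panel: pd.DataFrame, columns: Sequence[str]
) -> tuple[pd.DataFrame, int]:
    """Listwise deletion on ``columns``; the dropped count is returned and
    logged so estimation sample sizes are always explicit."""
    before = len(panel)
    out = panel.dropna(subset=[c for c in columns if c in panel.columns])
    dropped = before - len(out)
    if dropped:
        logger.info("drop_missing removed %d of %d rows", dropped, before)
    return out.reset_index(drop=True), dropped


@dataclass(frozen=True)
class PanelSummary:
    variables: pd.DataFrame  # per-variable n, mean, sd
    n_observations: int
    n_persons: int
    mean_obs_per_person: float

    def to_tsv(self) -> str:
        lines = ["variable\tn\tmean\tsd"]
        for row in self.variables.itertuples():
            sd = "" if pd.isna(row.sd) else f"{row.sd:.3f}"
            lines.append(f"{row.Index}\t{row.n}\t{row.mean:.3f}\t{sd}")
        lines.append(f"observations\t{self.n_observations}\t\t")
        lines.append(f"persons\t{self.n_persons}\t\t")
        lines.append(f"mean_obs_per_person\t{self.mean_obs_per_person:.3f}\t\t")
        return "\n".join(lines) + "\n"


def panel_summary(
    panel: pd.DataFrame,
    person_col: str = "person_id",
    variables: Sequence[str] | None = None,
) -> PanelSummary:
    """Per-variable n/mean/SD plus person-level panel structure.

    SD uses the n-1 denominator and is reported missing for a single
    observation; mean observations per person = rows / distinct persons.
    """
    if panel.empty:
        raise PanelError("cannot summarize an empty panel")
    if person_col not in panel.columns:
        raise PanelError(f"panel missing person column {person_col!r}")
    if variables is None:
        variables = [
            c
            for c in panel.columns
            if c != person_col and pd.api.types.is_numeric_dtype(panel[c])
        ]
    records = {}
    for var in variables:
        col = pd.to_numeric(panel[var], errors="coerce").dropna()
        records[var] = {
            "n": int(col.size),
            "mean": float(col.mean()) if col.size else np.nan,
            "sd": float(col.std(ddof=1)) if col.size > 1 else np.nan,
        }
    n_obs = len(panel)
    n_persons = int(panel[person_col].nunique())
    return PanelSummary(
        variables=pd.DataFrame.from_dict(records, orient="index"),
        n_observations=n_obs,
        n_persons=n_persons,
        mean_obs_per_person=n_obs / n_persons,
    )
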