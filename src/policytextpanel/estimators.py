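"""Panel estimators: two-way fixed effects, FE-2SLS, contrasts, two-part model.

All linear estimators share a within-transformation backbone: variables are
demeaned within individual and year dummies (also demeaned) are appended, which
reproduces least-squares-dummy-variables coefficients without materializing the
individual dummies.  Standard errors are heteroskedasticity-robust (HC1) or
cluster-robust (CR1) depending on the model spec.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats


class RankError(ValueError):
    """Regressors collinear after the within transformation."""


class SpecError(ValueError):
    """Invalid model specification."""


_CLUSTER_COLS = {"prefecture": "prefecture_id", "individual": "person_id"}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression.

    Regressor names containing ``:`` denote interaction terms and are built as
    products of the referenced columns if not already present in the data.
    ``sample_filter`` selects all rows, enrollees only or the uninsured only,
    based on the enrolment dummy column.
    """

    outcome: str
    regressors: tuple[str, ...]
    endogenous: str | None = None
    instruments: tuple[str, ...] = ()
    fe: frozenset[str] = frozenset({"individual", "year"})
    cluster: str = "prefecture"
    sample_filter: str = "all"
    person_col: str = "person_id"
    year_col: str = "year"
    enroll_col: str = "uebmi_enrolled"

    def __post_init__(self) -> None:
        object.__setattr__(self, "regressors", tuple(self.regressors))
        object.__setattr__(self, "instruments", tuple(self.instruments))
        object.__setattr__(self, "fe", frozenset(self.fe))
        if bool(self.endogenous) != bool(self.instruments):
            raise SpecError("instruments must be set iff an endogenous regressor is set")
        if self.cluster not in ("none", *_CLUSTER_COLS):
            raise SpecError(f"unknown cluster level {self.cluster!r}")
        if self.sample_filter not in ("all", "enrolled", "uninsured"):
            raise SpecError(f"unknown sample filter {self.sample_filter!r}")
        unknown_fe = self.fe - {"individual", "year"}
        if unknown_fe:
            raise SpecError(f"unknown fixed effects: {sorted(unknown_fe)}")
        if self.endogenous and self.endogenous in self.instruments:
            # the self-instrument case is legal (2SLS collapses to OLS) but the
            # instrument must then not also appear among structural regressors
            pass

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        kwargs = dict(d)
        for key in ("regressors", "instruments"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if "fe" in kwargs and kwargs["fe"] is not None:
            kwargs["fe"] = frozenset(kwargs["fe"])
        return cls(**kwargs)


@dataclass(frozen=True)
class LincomResult:
    expression: str
    estimate: float
    se: float
    stat: float
    p: float


@dataclass(frozen=True)
class FitResult:
    """Coefficients, covariance and diagnostics for one estimated model."""

    params: pd.Series
    vcov: pd.DataFrame
    n_obs: int
    df_resid: int
    r2_within: float | None = None
    diagnostics: dict = field(default_factory=dict)
    lincom_results: tuple[LincomResult, ...] = ()
    unidentified: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()
    data_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    df_inference: int | None = None  # None -> normal reference

    def se(self, name: str) -> float:
        return float(np.sqrt(self.vcov.loc[name, name]))

    def pvalue(self, name: str) -> float:
        z = self.params[name] / self.se(name)
        if self.df_inference is not None:
            return float(2 * stats.t.sf(abs(z), self.df_inference))
        return float(2 * stats.norm.sf(abs(z)))

    def summary_tsv(self) -> str:
        """Coefficient table: estimate, SE in parentheses, stars at 0.10/0.05/0.01."""
        lines = ["term\testimate\tse\tp"]
        for name in self.params.index:
            p = self.pvalue(name)
            stars = "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.10 else ""
            lines.append(f"{name}\t{self.params[name]:.4f}{stars}\t({self.se(name):.4f})\t{p:.4f}")
        lines.append(f"n_obs\t{self.n_obs}\t\t")
        if self.r2_within is not None:
            lines.append(f"r2_within\t{self.r2_within:.4f}\t\t")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "se": {k: self.se(k) for k in self.params.index},
            "n_obs": self.n_obs,
            "df_resid": self.df_resid,
            "r2_within": self.r2_within,
            "diagnostics": {
                k: (v if v is None or isinstance(v, str) else float(v))
                for k, v in self.diagnostics.items()
            },
            "unidentified": list(self.unidentified),
            "flags": list(self.flags),
            "lincom": [
                {"expression": lc.expression, "estimate": lc.estimate, "se": lc.se, "p": lc.p}
                for lc in self.lincom_results
            ],
        }


# ---------------------------------------------------------------------------
# design construction


def build_interactions(df: pd.DataFrame, names: Iterable[str]) -> pd.DataFrame:
    """Materialize product columns for every ``a:b[:c]`` name not yet present.

    Products are taken over the raw (level) columns; demeaning is applied to
    the constructed interaction afterwards, matching dummy-variable semantics.
    """
    df = df.copy()
    for name in names:
        if name in df.columns or ":" not in name:
            continue
        parts = name.split(":")
        missing = [p for p in parts if p not in df.columns]
        if missing:
            raise SpecError(f"interaction {name!r} references unknown columns {missing}")
        col = df[parts[0]].astype(float).copy()
        for p in parts[1:]:
            col = col * df[p].astype(float)
        df[name] = col
    return df


def _apply_sample_filter(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    if spec.sample_filter == "all":
        return df
    if spec.enroll_col not in df.columns:
        raise SpecError(f"sample filter needs column {spec.enroll_col!r}")
    want = 1 if spec.sample_filter == "enrolled" else 0
    return df[df[spec.enroll_col] == want]


def _prepare(df: pd.DataFrame, spec: ModelSpec, extra_cols: Sequence[str] = ()):
    """Common within-transform plumbing.

    Returns (data, y, X, D, n_persons) where X holds the demeaned identified
    regressors, D the demeaned year dummies (or a constant when no individual
    FE is requested), and ``unidentified`` regressors have been removed.
    """
    df = _apply_sample_filter(df, spec)
    df = build_interactions(df, list(spec.regressors) + list(extra_cols))
    needed = [spec.outcome, *spec.regressors, *extra_cols]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SpecError(f"data missing columns: {missing}")
    df = df.dropna(subset=list(dict.fromkeys(needed))).reset_index(drop=True)
    if df.empty:
        raise SpecError("no observations left after filtering")

    # year dummies, reference = earliest year
    dummies = pd.DataFrame(index=df.index)
    if "year" in spec.fe:
        years = sorted(df[spec.year_col].unique())
        for y in years[1:]:
            dummies[f"year_{y}"] = (df[spec.year_col] == y).astype(float)

    value_cols = list(dict.fromkeys([spec.outcome, *spec.regressors, *extra_cols]))
    values = df[value_cols].astype(float)
    if "individual" in spec.fe:
        group = df[spec.person_col]
        values = values - values.groupby(group).transform("mean")
        if not dummies.empty:
            dummies = dummies - dummies.groupby(group).transform("mean")
        n_absorbed = group.nunique()
    else:
        dummies.insert(0, "const", 1.0)
        n_absorbed = 0

    return df, values, dummies, n_absorbed


def _split_identified(values: pd.DataFrame, names: Sequence[str]):
    """Separate regressors annihilated by the within transform."""
    unidentified, kept = [], []
    for name in names:
        if np.max(np.abs(values[name].to_numpy())) < 1e-10:
            unidentified.append(name)
        else:
            kept.append(name)
    return kept, unidentified


def _check_rank(Z: np.ndarray, names: Sequence[str], n_protect: int) -> list[int]:
    """QR-based rank check.  Columns beyond the first ``n_protect`` (year
    dummies / constant) may be dropped silently; collinearity among the first
    ``n_protect`` columns (the substantive regressors) is an error."""
    if Z.shape[1] == 0:
        return []
    _, R, piv = scipy.linalg.qr(Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(Z.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    dropped = sorted(piv[rank:])
    bad = [names[i] for i in dropped if i < n_protect]
    if bad:
        raise RankError(f"regressors collinear after demeaning: {bad}")
    return dropped


def _robust_vcov(
    Zk: np.ndarray,
    resid: np.ndarray,
    bread: np.ndarray,
    clusters: np.ndarray | None,
) -> np.ndarray:
    """HC1 / CR1 sandwich covariance.

    Small-sample corrections use k = explicit design columns only: absorbed
    individual effects are nested within either cluster level, so following
    the usual nested-fixed-effects convention they are not counted, and with
    singleton clusters CR1 collapses exactly to HC1.
    """
    n, k = Zk.shape
    if clusters is None:
        meat = (Zk * (resid**2)[:, None]).T @ Zk
        scale = n / (n - k)  # HC1
    else:
        codes, _ = pd.factorize(clusters)
        n_g = codes.max() + 1
        scores = np.zeros((n_g, k))
        np.add.at(scores, codes, Zk * resid[:, None])
        meat = scores.T @ scores
        scale = (n_g / (n_g - 1)) * ((n - 1) / (n - k))  # CR1
    return scale * bread @ meat @ bread


def _cluster_values(df: pd.DataFrame, spec: ModelSpec) -> np.ndarray | None:
    if spec.cluster == "none":
        return None
    col = _CLUSTER_COLS[spec.cluster]
    if col not in df.columns:
        raise SpecError(f"cluster column {col!r} not in data")
    return df[col].to_numpy()


def _data_ranges(df: pd.DataFrame, names: Iterable[str]) -> dict:
    out = {}
    for name in names:
        if name in df.columns:
            col = df[name].astype(float)
            out[name] = (float(col.min()), float(col.max()))
    return out


# ---------------------------------------------------------------------------
# estimators


def fit_twoway_fe(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Two-way fixed-effects OLS via within-individual demeaning plus year
    dummies; coefficients equal the explicit dummy-variable (LSDV) estimates.

    Regressors with no within-individual variation are flagged unidentified and
    excluded; genuine collinearity among the remaining regressors raises
    :class:`RankError`.
    """
    if spec.endogenous:
        raise SpecError("spec has an endogenous regressor; use fit_fe_2sls")
    data, values, dummies, n_absorbed = _prepare(df, spec)
    kept, unidentified = _split_identified(values, spec.regressors)

    names = list(kept) + list(dummies.columns)
    Z = np.column_stack([values[kept].to_numpy(), dummies.to_numpy()]) if names else np.empty((len(data), 0))
    drop_idx = _check_rank(Z, names, n_protect=len(kept))
    keep_idx = [i for i in range(Z.shape[1]) if i not in drop_idx]
    Zk = Z[:, keep_idx]
    names_k = [names[i] for i in keep_idx]

    y = values[spec.outcome].to_numpy()
    beta, *_ = np.linalg.lstsq(Zk, y, rcond=None)
    resid = y - Zk @ beta
    n = len(y)
    df_resid = n - Zk.shape[1] - n_absorbed
    if df_resid <= 0:
        raise SpecError("non-positive residual degrees of freedom")

    tss = float(y @ y)
    rss = float(resid @ resid)
    r2_within = 1.0 - rss / tss if tss > 0 else float("nan")

    bread = np.linalg.inv(Zk.T @ Zk)
    V = _robust_vcov(Zk, resid, bread, _cluster_values(data, spec))

    return FitResult(
        params=pd.Series(beta, index=names_k),
        vcov=pd.DataFrame(V, index=names_k, columns=names_k),
        n_obs=n,
        df_resid=df_resid,
        r2_within=r2_within,
        unidentified=tuple(unidentified),
        data_ranges=_data_ranges(data, set(spec.regressors)),
    )


def fit_fe_2sls(df: pd.DataFrame, spec: ModelSpec, *, force_plugin: bool = False) -> FitResult:
    """Fixed-effects two-stage least squares with a linear first stage.

    All variables are within-transformed, the endogenous regressor is projected
    onto the excluded instruments plus every exogenous regressor (including the
    year dummies), and 2SLS coefficients are computed on the projected design.
    Diagnostics: first-stage F on the excluded instruments, Hansen J
    overidentification test (needs >= 2 instruments, otherwise reported as not
    applicable) and a regression-based Wu-Hausman endogeneity test.

    ``force_plugin`` exists only to acknowledge the forbidden-regression guard:
    nonlinear fitted-probability plug-ins are rejected by construction, the
    first stage here is always linear.
    """
    if not spec.endogenous:
        raise SpecError("fit_fe_2sls requires an endogenous regressor and instruments")
    if force_plugin:
        raise SpecError("fitted-probability plug-in first stages are not supported")
    overlap = set(spec.instruments) & set(spec.regressors)
    if overlap:
        raise SpecError(f"instruments also listed as structural regressors: {sorted(overlap)}")

    extra = [spec.endogenous] + [c for c in spec.instruments if c != spec.endogenous]
    data, values, dummies, n_absorbed = _prepare(df, spec, extra_cols=extra)
    kept_exog, unidentified = _split_identified(values, spec.regressors)

    x_endog = values[spec.endogenous].to_numpy()
    if np.max(np.abs(x_endog)) < 1e-10:
        raise RankError(f"endogenous regressor {spec.endogenous!r} has no within variation")
    W = np.column_stack([values[kept_exog].to_numpy(), dummies.to_numpy()]) if (
        kept_exog or not dummies.empty
    ) else np.empty((len(data), 0))
    w_names = list(kept_exog) + list(dummies.columns)
    drop_idx = _check_rank(W, w_names, n_protect=len(kept_exog))
    keep_idx = [i for i in range(W.shape[1]) if i not in drop_idx]
    W = W[:, keep_idx]
    w_names = [w_names[i] for i in keep_idx]

    Zx = values[list(spec.instruments)].to_numpy()
    H = np.column_stack([Zx, W]) if W.size else Zx
    if np.linalg.matrix_rank(H) < H.shape[1]:
        raise RankError("first-stage design is rank deficient")

    n = len(data)
    y = values[spec.outcome].to_numpy()

    # first stage
    gamma, *_ = np.linalg.lstsq(H, x_endog, rcond=None)
    x_hat = H @ gamma
    v_hat = x_endog - x_hat

    # first-stage F on excluded instruments (classical, nested-RSS form)
    df_first = n - H.shape[1] - n_absorbed
    rss_u = float(v_hat @ v_hat)
    if W.size:
        gr, *_ = np.linalg.lstsq(W, x_endog, rcond=None)
        rss_r = float(np.sum((x_endog - W @ gr) ** 2))
    else:
        rss_r = float(x_endog @ x_endog)
    q = len(spec.instruments)
    first_stage_F = (
        ((rss_r - rss_u) / q) / (rss_u / df_first) if df_first > 0 and rss_u > 0 else float("inf")
    )

    # second stage on projected design
    X = np.column_stack([x_endog, W]) if W.size else x_endog[:, None]
    Xhat = np.column_stack([x_hat, W]) if W.size else x_hat[:, None]
    names_k = [spec.endogenous] + w_names
    XtX = Xhat.T @ Xhat
    beta = np.linalg.solve(XtX, Xhat.T @ y)
    resid = y - X @ beta  # structural residuals use the actual regressor

    k = X.shape[1]
    df_resid = n - k - n_absorbed
    if df_resid <= 0:
        raise SpecError("non-positive residual degrees of freedom")
    bread = np.linalg.inv(XtX)
    clusters = _cluster_values(data, spec)
    V = _robust_vcov(Xhat, resid, bread, clusters)

    tss = float(y @ y)
    r2_within = 1.0 - float(resid @ resid) / tss if tss > 0 else float("nan")

    # Hansen J (overidentification); just-identified -> not applicable
    if q >= 2:
        g = H * resid[:, None]
        if clusters is None:
            S = g.T @ g
        else:
            codes, _ = pd.factorize(clusters)
            sums = np.zeros((codes.max() + 1, H.shape[1]))
            np.add.at(sums, codes, g)
            S = sums.T @ sums
        gbar = g.sum(axis=0)
        J = float(gbar @ np.linalg.pinv(S) @ gbar)
        overid_df = q - 1
        overid_p = float(stats.chi2.sf(J, overid_df))
    else:
        J, overid_p = None, None

    # Wu-Hausman: augment the structural equation with the first-stage residual
    A = np.column_stack([X, v_hat])
    alpha, *_ = np.linalg.lstsq(A, y, rcond=None)
    res_a = y - A @ alpha
    df_a = n - A.shape[1] - n_absorbed
    bread_a = np.linalg.inv(A.T @ A)
    V_a = _robust_vcov(A, res_a, bread_a, clusters)
    t_endog = alpha[-1] / math.sqrt(V_a[-1, -1])
    endog_p = float(2 * stats.norm.sf(abs(t_endog)))

    return FitResult(
        params=pd.Series(beta, index=names_k),
        vcov=pd.DataFrame(V, index=names_k, columns=names_k),
        n_obs=n,
        df_resid=df_resid,
        r2_within=r2_within,
        diagnostics={
            "first_stage_F": float(first_stage_F),
            "overid_stat": J,
            "overid_p": overid_p,
            "endogeneity_stat": float(t_endog),
            "endogeneity_p": endog_p,
        },
        unidentified=tuple(unidentified),
        data_ranges=_data_ranges(data, set(spec.regressors) | {spec.endogenous}),
    )


# ---------------------------------------------------------------------------
# contrasts and marginal effects

_TERM_RE = re.compile(r"[+-]")


def _parse_contrast(expression: str, names: Sequence[str]) -> dict[str, float]:
    """Parse 'b1 + 0.5*b2 - b3' into {name: weight}.

    ``*`` multiplies a numeric literal with a coefficient name; coefficient
    names themselves may contain ``:`` (interaction terms).
    """
    weights: dict[str, float] = {}
    expr = expression.replace("-", "+-")
    for raw in expr.split("+"):
        term = raw.strip()
        if not term:
            continue
        sign = 1.0
        if term.startswith("-"):
            sign, term = -1.0, term[1:].strip()
        weight, name = sign, None
        for part in (p.strip() for p in term.split("*")):
            try:
                weight *= float(part)
            except ValueError:
                if name is not None:
                    raise SpecError(f"multiple coefficient names in term {raw!r}")
                name = part
        if name is None:
            raise SpecError(f"term {raw!r} has no coefficient name")
        if name not in names:
            raise SpecError(f"unknown coefficient {name!r} in contrast {expression!r}")
        weights[name] = weights.get(name, 0.0) + weight
    return weights


def lincom(fit: FitResult, expression: str | Mapping[str, float]) -> LincomResult:
    """Estimate, delta-method SE and p-value for a linear combination c'beta."""
    names = list(fit.params.index)
    if isinstance(expression, str):
        weights = _parse_contrast(expression, names)
        label = expression
    else:
        unknown = [k for k in expression if k not in names]
        if unknown:
            raise SpecError(f"unknown coefficient(s) {unknown}")
        weights = dict(expression)
        label = " + ".join(f"{w}*{k}" for k, w in weights.items())
    c = np.array([weights.get(nm, 0.0) for nm in names])
    est = float(c @ fit.params.to_numpy())
    var = float(c @ fit.vcov.to_numpy() @ c)
    se = math.sqrt(max(var, 0.0))
    stat = est / se if se > 0 else float("nan")
    if fit.df_inference is not None:
        p = float(2 * stats.t.sf(abs(stat), fit.df_inference))
    else:
        p = float(2 * stats.norm.sf(abs(stat)))
    return LincomResult(expression=label, estimate=est, se=se, stat=stat, p=p)


def with_lincoms(fit: FitResult, expressions: Iterable[str]) -> FitResult:
    return replace(fit, lincom_results=tuple(lincom(fit, e) for e in expressions))


def _interaction_name(names: Sequence[str], parts: Sequence[str]) -> str | None:
    want = sorted(parts)
    for nm in names:
        if ":" in nm and sorted(nm.split(":")) == want:
            return nm
    return None


def marginal_effects(
    fit: FitResult,
    focal: str,
    moderator: str,
    grid: Sequence[float],
    level: float = 0.95,
    fixed: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Effect of ``focal`` at each moderator value, with confidence band.

    effect(m) = b_focal + b_{focal x moderator} * m, plus, for every second
    moderator held fixed at value v, b_{focal x other} * v and the three-way
    term b_{focal x moderator x other} * m * v.  The CI comes from the same
    contrast-vector delta method as :func:`lincom`.
    """
    names = list(fit.params.index)
    if focal not in names:
        raise SpecError(f"focal regressor {focal!r} not in fit")
    inter = _interaction_name(names, [focal, moderator])
    if inter is None:
        raise SpecError(f"fit lacks a {focal!r} x {moderator!r} interaction")
    fixed = dict(fixed or {})

    lo, hi = fit.data_ranges.get(moderator, (-np.inf, np.inf))
    grid = [float(m) for m in grid]
    if any(m < lo or m > hi for m in grid):
        warnings.warn(
            f"moderator grid extends outside observed range [{lo}, {hi}]",
            UserWarning,
            stacklevel=2,
        )

    V = fit.vcov.to_numpy()
    beta = fit.params.to_numpy()
    C = np.zeros((len(grid), len(names)))
    for row, m in enumerate(sorted(grid)):
        C[row, names.index(focal)] = 1.0
        C[row, names.index(inter)] += m
        for other, val in fixed.items():
            two = _interaction_name(names, [focal, other])
            if two is not None:
                C[row, names.index(two)] += val
            three = _interaction_name(names, [focal, moderator, other])
            if three is not None:
                C[row, names.index(three)] += m * val
    effects = C @ beta
    ses = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, V, C), 0.0))
    if fit.df_inference is not None:
        crit = stats.t.ppf(0.5 + level / 2, fit.df_inference)
    else:
        crit = stats.norm.ppf(0.5 + level / 2)
    return pd.DataFrame(
        {
            "moderator_value": sorted(grid),
            "effect": effects,
            "se": ses,
            "ci_low": effects - crit * ses,
            "ci_high": effects + crit * ses,
        }
    )


# ---------------------------------------------------------------------------
# two-part model


def fit_two_part(
    df: pd.DataFrame, spec: ModelSpec, *, prefecture_col: str = "prefecture_id"
) -> tuple[FitResult, FitResult | None]:
    """Two-part expenditure model.

    Part 1: probit of any-spending on the spec regressors with year and
    prefecture dummies (individual fixed effects in a probit are
    incidental-parameters-inconsistent, so the absorbing level is coarsened).
    Part 2: within-estimator OLS of log positive spending on the
    positive-spending subsample, with the spec's own FE treatment.

    ``spec.outcome`` must hold raw (deflated) spending levels.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    data = _apply_sample_filter(df, spec)
    data = build_interactions(data, spec.regressors)
    data = data.dropna(subset=[spec.outcome, *spec.regressors]).reset_index(drop=True)
    if data.empty:
        raise SpecError("no observations left after filtering")
    spend = data[spec.outcome].astype(float)
    if (spend < 0).any():
        raise SpecError("two-part outcome must be non-negative spending levels")
    any_spend = (spend > 0).astype(float)

    # ---- part 1
    if any_spend.nunique() < 2:
        part1 = FitResult(
            params=pd.Series(dtype=float),
            vcov=pd.DataFrame(),
            n_obs=len(data),
            df_resid=0,
            flags=("degenerate_binary_part",),
        )
    else:
        Xp = data[list(spec.regressors)].astype(float)
        if "year" in spec.fe:
            Xp = pd.concat(
                [Xp, pd.get_dummies(data[spec.year_col], prefix="year", drop_first=True, dtype=float)],
                axis=1,
            )
        if prefecture_col in data.columns:
            Xp = pd.concat(
                [Xp, pd.get_dummies(data[prefecture_col], prefix="pref", drop_first=True, dtype=float)],
                axis=1,
            )
        Xp = sm.add_constant(Xp, has_constant="add")
        # drop all-constant dummies (e.g. a year absent from the subsample)
        keep = ["const"] + [c for c in Xp.columns if c != "const" and Xp[c].nunique() > 1]
        Xp = Xp[keep]
        flags: tuple[str, ...] = ()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=PerfectSeparationWarning)
                warnings.simplefilter("ignore", category=ConvergenceWarning)
                warnings.simplefilter("error", category=RuntimeWarning)
                res = sm.Probit(any_spend, Xp).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            finite = bool(np.isfinite(res.params).all() and np.isfinite(res.bse).all())
            big = bool(np.max(np.abs(res.params)) > 1e3)
            if not converged or not finite or big:
                raise PerfectSeparationError("probit did not identify finite coefficients")
            part1 = FitResult(
                params=pd.Series(res.params, index=Xp.columns),
                vcov=pd.DataFrame(res.cov_params(), index=Xp.columns, columns=Xp.columns),
                n_obs=int(res.nobs),
                df_resid=int(res.df_resid),
            )
        except (
            PerfectSeparationError,
            PerfectSeparationWarning,
            np.linalg.LinAlgError,
            RuntimeWarning,
        ):
            flags = ("separation",)
            part1 = FitResult(
                params=pd.Series(dtype=float),
                vcov=pd.DataFrame(),
                n_obs=len(data),
                df_resid=0,
                flags=flags,
            )

    # ---- part 2: log positive spending, within estimator
    pos = data[spend > 0].copy()
    if pos.empty:
        return part1, None
    log_col = "__log_positive_spend"
    pos[log_col] = np.log(pos[spec.outcome].astype(float))
    spec2 = replace(spec, outcome=log_col, endogenous=None, instruments=())
    part2 = fit_twoway_fe(pos, spec2)
    return part1, part2
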