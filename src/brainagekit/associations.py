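"""Covariate-adjusted association battery for the brain-age delta.

Linear models of delta on each validation variable with chronological age
and sex as covariates (age only within sex strata), ANCOVA-style adjusted
contrasts for categorical predictors with Cohen's d, Cohen's f^2 for
continuous predictors, sex/age interaction tests, Benjamini-Hochberg FDR
over the whole battery, and the extreme-percentile subject selection.

Standardization recipe for the reported standardized beta: the outcome and
continuous predictors are z-scored on the analysis sample before fitting;
dummy-coded categorical levels are left unscaled, so their betas are in
outcome-SD units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import sex_to_code

__all__ = [
    "TestSpec",
    "fit_association",
    "ancova_categorical",
    "cohens_f2",
    "interaction_test",
    "fdr_correct",
    "select_extreme_deltas",
    "run_battery",
    "default_battery",
    "apoe_group",
]

_CONDITION_LIMIT = 1e8


@dataclass(frozen=True)
class TestSpec:
    __test__ = False  # not a pytest class despite the name

    predictor: str
    kind: str = "continuous"  # 'continuous' | 'categorical'
    reference: str | None = None  # reference level for categorical predictors
    outcome: str = "delta"
    covariates: tuple = ("age", "sex")
    interaction: str | None = None  # moderator for a product-term test

    def __post_init__(self) -> None:
        if self.predictor in self.covariates:
            raise ValueError("predictor must not appear among the covariates")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


def _covariate_columns(data: pd.DataFrame, covariates) -> dict[str, np.ndarray]:
    cols = {}
    for cov in covariates:
        if cov == "sex":
            cols["sex"] = sex_to_code(data["sex"]).to_numpy(dtype=float)
        else:
            cols[cov] = data[cov].to_numpy(dtype=float)
    return cols


def _ols(y: np.ndarray, cols: dict[str, np.ndarray]):
    X = pd.DataFrame(cols)
    X.insert(0, "const", 1.0)
    cond = np.linalg.cond(X.to_numpy())
    if cond > _CONDITION_LIMIT:
        raise ValueError(f"collinear design (condition number {cond:.3g})")
    return sm.OLS(y, X.to_numpy()).fit(), list(X.columns)


def _complete_cases(data: pd.DataFrame, columns) -> pd.DataFrame:
    missing = [c for c in columns if c not in data.columns]
    if missing:
        raise ValueError(f"columns absent from the data: {missing}")
    sub = data[list(columns)].dropna()
    return data.loc[sub.index]


def fit_association(spec: TestSpec, data: pd.DataFrame) -> dict:
    """Standardized linear association of a continuous predictor with delta.

    Complete-case analysis; outcome and predictor are z-scored on the
    analysis sample.  Returns a result row (dict) with beta, SE, p, CI95,
    N and Cohen's f^2 as the effect size.
    """
    if spec.kind != "continuous":
        raise ValueError("use ancova_categorical for categorical predictors")
    needed = [spec.outcome, spec.predictor, *spec.covariates]
    d = _complete_cases(data, needed)
    if len(d) == 0:
        raise ValueError("empty stratum after complete-case filtering")
    n_terms = 2 + len(spec.covariates)
    if len(d) <= n_terms:
        raise ValueError("too few complete cases for the model")
    y = _zscore(d[spec.outcome].to_numpy(dtype=float))
    cols = {"predictor": _zscore(d[spec.predictor].to_numpy(dtype=float))}
    cols.update(_covariate_columns(d, spec.covariates))
    res, names = _ols(y, cols)
    j = names.index("predictor")
    ci = res.conf_int()[j]
    red, _ = _ols(y, _covariate_columns(d, spec.covariates)) if spec.covariates else (None, None)
    r2_red = red.rsquared if red is not None else 0.0
    r2_full = min(res.rsquared, 1.0)
    if r2_full >= 1.0 - 1e-12:
        f2 = float("inf")  # perfect fit: unbounded local effect size
    else:
        f2 = cohens_f2(r2_full, min(r2_red, r2_full))
    return {
        "predictor": spec.predictor,
        "level": "",
        "beta": float(res.params[j]),
        "se": float(res.bse[j]),
        "p": float(res.pvalues[j]),
        "ci_lo": float(ci[0]),
        "ci_hi": float(ci[1]),
        "n": int(len(d)),
        "effect_size": float(f2),
        "effect_kind": "f2",
    }


def ancova_categorical(spec: TestSpec, data: pd.DataFrame) -> list[dict]:
    """Adjusted contrasts of each predictor level against the reference.

    One-way ANCOVA-style OLS of the z-scored delta on level dummies plus the
    covariates.  Cohen's d per contrast is the adjusted difference divided
    by the model residual SD (the 'estimated standard deviation').
    """
    if spec.kind != "categorical":
        raise ValueError("spec is not categorical")
    needed = [spec.outcome, spec.predictor, *spec.covariates]
    d = _complete_cases(data, needed)
    if len(d) == 0:
        raise ValueError("empty stratum after complete-case filtering")
    levels = d[spec.predictor].astype(str)
    counts = levels.value_counts()
    ref = spec.reference if spec.reference is not None else counts.index[0]
    if ref not in counts.index:
        raise ValueError(f"reference level {ref!r} absent from the data")
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"levels with < 2 subjects: {list(small.index)}")
    y = _zscore(d[spec.outcome].to_numpy(dtype=float))
    other = [lv for lv in counts.index if lv != ref]
    cols = {f"level[{lv}]": (levels == lv).to_numpy(dtype=float) for lv in other}
    cols.update(_covariate_columns(d, spec.covariates))
    res, names = _ols(y, cols)
    resid_sd = float(np.sqrt(res.scale))
    rows = []
    for lv in other:
        j = names.index(f"level[{lv}]")
        ci = res.conf_int()[j]
        rows.append(
            {
                "predictor": spec.predictor,
                "level": f"{lv} (ref: {ref})",
                "beta": float(res.params[j]),
                "se": float(res.bse[j]),
                "p": float(res.pvalues[j]),
                "ci_lo": float(ci[0]),
                "ci_hi": float(ci[1]),
                "n": int(len(d)),
                "effect_size": float(res.params[j] / resid_sd),
                "effect_kind": "d",
            }
        )
    return rows


def cohens_f2(r2_full: float, r2_reduced: float) -> float:
    """Local effect size ``(R2_full - R2_reduced) / (1 - R2_full)``."""
    if not 0.0 <= r2_reduced <= r2_full:
        raise ValueError("require 0 <= R2_reduced <= R2_full")
    if r2_full >= 1.0:
        raise ValueError("R2_full must be < 1")
    return (r2_full - r2_reduced) / (1.0 - r2_full)


def interaction_test(spec: TestSpec, data: pd.DataFrame) -> dict:
    """Product-term test for moderation of the association by sex or age.

    Continuous variables are mean-centered before forming the product; main
    effects are always included.  Returns the product term's row.
    """
    mod = spec.interaction
    if mod is None:
        raise ValueError("spec has no interaction moderator")
    needed = [spec.outcome, spec.predictor, mod, *[c for c in spec.covariates if c != mod]]
    d = _complete_cases(data, list(dict.fromkeys(needed)))
    if len(d) == 0:
        raise ValueError("empty stratum after complete-case filtering")
    y = _zscore(d[spec.outcome].to_numpy(dtype=float))
    x = d[spec.predictor].to_numpy(dtype=float)
    x = x - x.mean()
    if mod == "sex":
        m = sex_to_code(d["sex"]).to_numpy(dtype=float)
        if np.ptp(m) == 0:
            raise ValueError("moderator constant within stratum")
    else:
        m = d[mod].to_numpy(dtype=float)
        if np.ptp(m) == 0:
            raise ValueError("moderator constant within stratum")
        m = m - m.mean()
    cols = {"predictor": x, "moderator": m, "product": x * m}
    for cov in spec.covariates:
        if cov == mod:
            continue
        cols.update(_covariate_columns(d, (cov,)))
    res, names = _ols(y, cols)
    j = names.index("product")
    ci = res.conf_int()[j]
    return {
        "predictor": f"{spec.predictor} x {mod}",
        "level": "",
        "beta": float(res.params[j]),
        "se": float(res.bse[j]),
        "p": float(res.pvalues[j]),
        "ci_lo": float(ci[0]),
        "ci_hi": float(ci[1]),
        "n": int(len(d)),
        "effect_size": float("nan"),
        "effect_kind": "",
    }


def fdr_correct(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_extreme_deltas(
    deltas: pd.Series,
    cohort: pd.Series | None = None,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
) -> pd.Index:
    """Subjects in the tails of the per-cohort delta distribution.

    Percentiles use linear interpolation (numpy default); a subject is
    selected when delta <= P(lower) or delta >= P(upper).  Degenerate
    cohorts (all deltas equal) contribute no subjects and emit a warning.
    """
    deltas = pd.Series(deltas, dtype=float)
    groups = (
        {"all": deltas.index}
        if cohort is None
        else cohort.loc[deltas.index].groupby(cohort).groups
    )
    selected = []
    for name, idx in groups.items():
        block = deltas.loc[idx]
        if len(block) < 10:
            raise ValueError(f"cohort {name!r} has fewer than 10 subjects")
        if block.nunique() == 1:
            warnings.warn(f"cohort {name!r}: all deltas equal; both tails empty")
            continue
        lo = np.percentile(block, lower_pct)
        hi = np.percentile(block, upper_pct)
        tails = block[(block <= lo) | (block >= hi)]
        if tails.empty:
            warnings.warn(f"cohort {name!r}: percentile ties collapsed a tail")
        selected.append(tails.index)
    if not selected:
        return pd.Index([])
    out = selected[0]
    for idx in selected[1:]:
        out = out.union(idx)
    return out


def apoe_group(genotypes: pd.Series) -> pd.Series:
    """Collapse APOE genotypes to the four-level contrast coding.

    e33 is the reference group; e22/e23 -> e2; e34/e44 -> e4; e24 separate.
    Already-grouped labels pass through.
    """
    mapping = {
        "e33": "e33", "e22": "e2", "e23": "e2", "e34": "e4", "e44": "e4",
        "e24": "e24", "e2": "e2", "e4": "e4",
    }
    s = pd.Series(genotypes).map(mapping)
    if s.isna().any() and pd.Series(genotypes).notna().any():
        bad = sorted(set(pd.Series(genotypes).dropna()[s.isna()].astype(str)))
        if bad:
            raise ValueError(f"unknown APOE genotypes: {bad}")
    return s


def default_battery() -> list[TestSpec]:
    """Validation-variable specs mirroring the published battery structure."""
    specs = [
        TestSpec("abeta_status", kind="categorical", reference="A-"),
        TestSpec("at_stage", kind="categorical", reference="A-T-"),
        TestSpec("apoe", kind="categorical", reference="e33"),
        TestSpec("wmh_prepared"),
        TestSpec("csf_nfl_z"),
        TestSpec("plasma_nfl_z"),
        TestSpec("signature_change"),
    ]
    for var in ("wmh_prepared", "csf_nfl_z", "plasma_nfl_z", "signature_change"):
        specs.append(TestSpec(var, interaction="sex"))
        specs.append(TestSpec(var, interaction="age"))
    return specs


@dataclass
class BatteryResult:
    table: pd.DataFrame
    family_size: int
    skipped: list = field(default_factory=list)


def run_battery(
    data: pd.DataFrame,
    specs: list[TestSpec] | None = None,
    strata: list[tuple[str, str]] | None = None,
) -> BatteryResult:
    """Run every spec across the strata and FDR-correct the whole family.

    ``data`` needs columns delta, age, sex, diagnosis plus the predictors.
    ``strata`` is a list of (diagnosis, sex) pairs where either entry may be
    'all'.  Failures of individual tests are recorded and the battery
    continues.  The returned table satisfies q >= p row-wise; the family
    size used for the correction is reported so the published family count
    can be replicated.
    """
    specs = specs if specs is not None else default_battery()
    if strata is None:
        strata = [
            (dx, sx)
            for dx in ("CU", "MCI")
            for sx in ("all", "female", "male")
        ]
    rows = []
    skipped = []
    for dx, sx in strata:
        d = data
        if dx != "all":
            d = d[d["diagnosis"] == dx]
        if sx != "all":
            d = d[d["sex"] == sx]
        for spec in specs:
            if spec.interaction == "sex" and sx != "all":
                continue  # sex interaction undefined within a sex stratum
            covs = ("age",) if sx != "all" else spec.covariates
            s = TestSpec(
                spec.predictor, kind=spec.kind, reference=spec.reference,
                outcome=spec.outcome, covariates=covs, interaction=spec.interaction,
            )
            try:
                if spec.interaction is not None:
                    results = [interaction_test(s, d)]
                elif spec.kind == "categorical":
                    results = ancova_categorical(s, d)
                else:
                    results = [fit_association(s, d)]
            except ValueError as err:
                skipped.append({"diagnosis": dx, "sex": sx,
                                "predictor": spec.predictor, "reason": str(err)})
                continue
            for row in results:
                rows.append({"diagnosis": dx, "sex": sx, **row})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q"] = fdr_correct(table["p"].to_numpy())
    return BatteryResult(table=table, family_size=len(table), skipped=skipped)
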