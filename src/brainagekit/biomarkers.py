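"""Biomarker transforms, amyloid/tau (AT) staging, WMH preparation, and the
ageing-signature thickness composite.

Cut-offs ship as a versioned YAML (``data/cutoffs.yaml``) and are editable;
the boundary convention is that abnormality requires a strict inequality
past the cut-off (a value exactly at the cut-off is normal).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CutoffTable",
    "load_default_cutoffs",
    "abeta_status",
    "at_stage",
    "exclude_non_ad_change",
    "SignatureDefinition",
    "default_signature",
    "aging_signature",
    "signature_zscore",
    "signature_change",
    "transform_nfl",
    "prepare_wmh",
]


@dataclass
class CutoffTable:
    """Per-cohort biomarker cut-offs and amyloid modality."""

    cohorts: dict
    version: int = 1

    def __post_init__(self) -> None:
        for name, cfg in self.cohorts.items():
            if cfg.get("abeta_modality") not in ("csf", "pet"):
                raise ValueError(f"cohort {name!r}: exactly one abeta modality required")
            for key, val in cfg.items():
                if key != "abeta_modality" and val <= 0:
                    raise ValueError(f"cohort {name!r}: cut-off {key} must be positive")

    def for_cohort(self, cohort: str) -> dict:
        try:
            return self.cohorts[cohort]
        except KeyError:
            raise ValueError(f"unknown cohort {cohort!r} in cut-off table") from None

    @classmethod
    def from_yaml(cls, path) -> "CutoffTable":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(cohorts=d["cohorts"], version=d.get("version", 1))


def load_default_cutoffs() -> CutoffTable:
    text = resources.files("brainagekit").joinpath("data/cutoffs.yaml").read_text()
    d = yaml.safe_load(text)
    return CutoffTable(cohorts=d["cohorts"], version=d.get("version", 1))


def abeta_status(value, cohort: str, cutoffs: CutoffTable | None = None):
    """Classify amyloid status ('A+'/'A-') in the cohort's modality units.

    CSF abeta42 strictly below the cut-off is abnormal (A+); Centiloid
    strictly above the cut-off is abnormal.  Negative Centiloids pass
    through; negative CSF concentrations are rejected.
    """
    cutoffs = cutoffs or load_default_cutoffs()
    cfg = cutoffs.for_cohort(cohort)
    v = pd.Series(value, dtype=float) if not np.isscalar(value) else value
    if cfg["abeta_modality"] == "csf":
        cut = cfg["csf_abeta42"]
        if np.isscalar(v):
            if v < 0:
                raise ValueError("negative CSF concentration")
            return "A+" if v < cut else "A-"
        if (v.dropna() < 0).any():
            raise ValueError("negative CSF concentration")
        out = pd.Series(pd.NA, index=v.index, dtype="object")
        out[v < cut] = "A+"
        out[v >= cut] = "A-"
        return out
    cut = cfg["centiloid"]
    if np.isscalar(v):
        return "A+" if v > cut else "A-"
    out = pd.Series(pd.NA, index=v.index, dtype="object")
    out[v > cut] = "A+"
    out[(v <= cut) & v.notna()] = "A-"
    return out


def at_stage(abeta, ptau_value, cohort: str, cutoffs: CutoffTable | None = None):
    """Cross amyloid status with tau status (T+ iff p-tau strictly above cut-off).

    Missing p-tau yields the explicit missing code ``pd.NA`` (stage
    undefined), never a sentinel number.
    """
    cutoffs = cutoffs or load_default_cutoffs()
    cfg = cutoffs.for_cohort(cohort)
    cut = cfg.get("csf_ptau")
    if cut is None:
        raise ValueError(f"cohort {cohort!r} has no p-tau cut-off")

    def one(a, p):
        if pd.isna(a) or pd.isna(p):
            return pd.NA
        t = "T+" if p > cut else "T-"
        return f"{a}{t}"

    if np.isscalar(ptau_value) or ptau_value is None or (
        not isinstance(ptau_value, (pd.Series, np.ndarray, list))
    ):
        return one(abeta, ptau_value)
    a = pd.Series(abeta)
    p = pd.Series(ptau_value, dtype=float)
    return pd.Series([one(x, y) for x, y in zip(a, p)], index=a.index, dtype="object")


def exclude_non_ad_change(
    table: pd.DataFrame, stage_col: str = "at_stage", cohort_col: str = "cohort"
) -> tuple[pd.DataFrame, dict]:
    """Drop A-T+ rows (non-AD pathologic change); report counts per cohort."""
    mask = table[stage_col] == "A-T+"
    if cohort_col in table.columns:
        report = table.loc[mask, cohort_col].value_counts().to_dict()
    else:
        report = {"all": int(mask.sum())}
    return table.loc[~mask.fillna(False)].copy(), {"A-T+": report}


@dataclass
class SignatureDefinition:
    """ROI list with per-ROI surface-area weights for the thickness composite.

    The published ROI list (calcarine, caudal fusiform, caudal insula,
    cuneus, inferior frontal gyrus, medial superior frontal, precentral)
    lacks exact Desikan-Killiany labels for two entries; the default mapping
    below is an interpretation, not a verbatim label list, and is
    user-overridable: calcarine -> pericalcarine, caudal fusiform ->
    fusiform, caudal insula -> insula, inferior frontal gyrus ->
    parsopercularis + parstriangularis, medial superior frontal ->
    superiorfrontal.
    """

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("signature weights must be >= 0")
        if sum(self.weights.values()) <= 0:
            raise ValueError("signature weights must not all be zero")


#: Template relative surface areas (arbitrary units) for the default mapping.
_SIGNATURE_TEMPLATE = {
    "pericalcarine": 1.4,
    "fusiform": 3.4,
    "insula": 2.3,
    "cuneus": 1.5,
    "parsopercularis": 1.6,
    "parstriangularis": 1.4,
    "superiorfrontal": 7.0,
    "precentral": 5.0,
}


def default_signature() -> SignatureDefinition:
    weights = {}
    for label, w in _SIGNATURE_TEMPLATE.items():
        for hemi in ("lh", "rh"):
            weights[f"{hemi}_{label}_thickness"] = w
    return SignatureDefinition(weights=weights)


def aging_signature(thickness, definition: SignatureDefinition | None = None):
    """Surface-area-weighted mean cortical thickness over the signature ROIs.

    ``thickness`` is a Series (one subject) or DataFrame (subjects x
    features) containing every ROI named in the definition.  Per-subject
    measured areas may be used by passing a custom definition.
    """
    definition = definition or default_signature()
    rois = list(definition.weights)
    w = np.array([definition.weights[r] for r in rois], dtype=float)
    if isinstance(thickness, pd.DataFrame):
        missing = [r for r in rois if r not in thickness.columns]
        if missing:
            raise ValueError(f"missing signature ROIs: {missing[:4]}")
        t = thickness[rois].to_numpy(dtype=float)
        return pd.Series(t @ w / w.sum(), index=thickness.index, name="aging_signature")
    t = pd.Series(thickness)
    missing = [r for r in rois if r not in t.index]
    if missing:
        raise ValueError(f"missing signature ROIs: {missing[:4]}")
    return float(t[rois].to_numpy(dtype=float) @ w / w.sum())


def signature_zscore(values, reference_mean: float, reference_sd: float):
    """Z-score against a reference (e.g. cognitively unimpaired) mean and SD."""
    if reference_sd <= 0:
        raise ValueError("reference SD must be > 0")
    return (np.asarray(values, dtype=float) - reference_mean) / reference_sd


def signature_change(v1, v2, interval: float):
    """Annualized change (visit2 - visit1) / interval; interval in years."""
    if interval <= 0:
        raise ValueError("interval must be > 0 years")
    return (np.asarray(v2, dtype=float) - np.asarray(v1, dtype=float)) / interval


def transform_nfl(values: pd.Series, cohort_labels: pd.Series) -> pd.Series:
    """Natural-log transform, then z-score within cohort (pooling across assays)."""
    v = pd.Series(values, dtype=float)
    if (v.dropna() <= 0).any():
        raise ValueError("NfL values must be positive")
    logs = np.log(v)
    out = pd.Series(np.nan, index=v.index, dtype=float)
    for _, idx in cohort_labels.loc[v.index].groupby(cohort_labels).groups.items():
        block = logs.loc[idx].dropna()
        if len(block) < 2:
            out.loc[block.index] = np.nan
            continue
        out.loc[block.index] = (block - block.mean()) / block.std(ddof=1)
    return out


def prepare_wmh(wmh_volumes, tiv) -> np.ndarray:
    """Natural-log transform WMH volumes then residualize on TIV (with intercept)."""
    v = np.asarray(wmh_volumes, dtype=float)
    if np.any(v[~np.isnan(v)] <= 0):
        raise ValueError("WMH volumes must be positive")
    t = np.asarray(tiv, dtype=float)
    logs = np.log(v)
    ok = ~(np.isnan(logs) | np.isnan(t))
    X = np.column_stack([np.ones(ok.sum()), t[ok]])
    beta, *_ = np.linalg.lstsq(X, logs[ok], rcond=None)
    out = np.full_like(logs, np.nan)
    out[ok] = logs[ok] - X @ beta
    return out
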