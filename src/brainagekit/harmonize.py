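"""Feature preprocessing: covariate residualization and within-cohort z-scoring.

Volumes are replaced by least-squares residuals on TIV plus site indicators;
cortical thicknesses by residuals on site indicators only.  Features are then
z-scored feature-wise within each cohort (sample SD, denominator n-1).
Residualization models are fit within cohort and can be frozen and applied
to new subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FeatureMatrix

__all__ = ["HarmonizationModel", "residualize", "zscore_within_cohort", "harmonize"]


@dataclass
class HarmonizationModel:
    """Fitted residualization recipes and z-scoring statistics.

    ``recipes`` maps (cohort, feature) -> dict with the covariate design
    description and fitted coefficients; ``zstats`` maps (cohort, feature)
    -> (mean, sd).  ``constant_features`` lists (cohort, feature) pairs whose
    within-cohort SD was ~0 (their z-scores are set to 0).
    """

    recipes: dict = field(default_factory=dict)
    zstats: dict = field(default_factory=dict)
    constant_features: list = field(default_factory=list)
    pooled_sites: dict = field(default_factory=dict)  # cohort -> sites pooled

    def to_json(self, path) -> None:
        payload = {
            "recipes": {f"{c}\t{f}": r for (c, f), r in self.recipes.items()},
            "zstats": {f"{c}\t{f}": list(v) for (c, f), v in self.zstats.items()},
            "constant_features": [list(cf) for cf in self.constant_features],
            "pooled_sites": self.pooled_sites,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def _site_design(site: pd.Series, pooled: set[str]) -> tuple[np.ndarray, list[str]]:
    """One-hot site indicators against the most frequent site as reference.

    Sites in ``pooled`` (singleton sites) are merged into the reference level.
    """
    s = site.where(~site.isin(pooled), other="__ref__")
    counts = s.value_counts()
    ref = counts.index[0]
    levels = [lv for lv in counts.index if lv != ref]
    cols = [(s == lv).to_numpy(dtype=float) for lv in levels]
    X = np.column_stack(cols) if cols else np.empty((len(s), 0))
    return X, levels


def _fit_residuals(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS residuals of every column of Y on design X (with intercept)."""
    Xi = np.column_stack([np.ones(len(Y)), X])
    beta, *_ = np.linalg.lstsq(Xi, Y, rcond=None)
    return Y - Xi @ beta, beta


def residualize(
    features: FeatureMatrix,
    covariates: pd.DataFrame,
    model: HarmonizationModel | None = None,
) -> tuple[FeatureMatrix, HarmonizationModel]:
    """Residualize volumes on TIV + site and thicknesses on site, per cohort.

    Parameters
    ----------
    features:
        Raw feature matrix.
    covariates:
        Subject table aligned on index; must contain ``cohort``, ``site`` and
        (for volume features) ``tiv``.
    model:
        A previously fitted :class:`HarmonizationModel` to apply frozen to
        new subjects.  When None (default) a model is fit per cohort.
    """
    sub = covariates.loc[features.data.index]
    if "site" not in sub.columns or "cohort" not in sub.columns:
        raise ValueError("covariates must contain 'cohort' and 'site' columns")
    vol_cols = features.features_by_measure("volume")
    thick_cols = features.features_by_measure("thickness")
    if vol_cols:
        if "tiv" not in sub.columns or sub["tiv"].isna().any():
            raise ValueError("TIV missing for one or more subjects with volume features")
    out = features.data.copy()
    fitted = model if model is not None else HarmonizationModel()
    freeze = model is not None

    for cohort, block in sub.groupby("cohort", sort=True):
        idx = block.index
        pooled = set()
        site_counts = block["site"].value_counts()
        singles = [s for s, n in site_counts.items() if n < 2]
        if singles and len(site_counts) > 1:
            pooled = set(singles)
        if not freeze:
            fitted.pooled_sites[cohort] = sorted(pooled)
        Xsite, levels = _site_design(block["site"], pooled)
        tiv = block["tiv"].to_numpy(dtype=float) if vol_cols else None

        for cols, use_tiv in ((thick_cols, False), (vol_cols, True)):
            if not cols:
                continue
            Y = out.loc[idx, cols].to_numpy(dtype=float)
            X = np.column_stack([tiv, Xsite]) if use_tiv else Xsite
            if freeze:
                for j, f in enumerate(cols):
                    rec = fitted.recipes.get((cohort, f))
                    if rec is None:
                        raise ValueError(
                            f"no fitted recipe for cohort={cohort!r} feature={f!r}"
                        )
                    beta = np.asarray(rec["beta"])
                    Xi = np.column_stack([np.ones(len(Y)), X])
                    Y[:, j] = Y[:, j] - Xi @ beta
                out.loc[idx, cols] = Y
            else:
                resid, beta = _fit_residuals(Y, X)
                out.loc[idx, cols] = resid
                covs = (["tiv"] if use_tiv else []) + [f"site[{lv}]" for lv in levels]
                for j, f in enumerate(cols):
                    fitted.recipes[(cohort, f)] = {
                        "covariates": covs,
                        "beta": beta[:, j].tolist(),
                    }
    result = FeatureMatrix(
        data=out, meta=features.meta, harmonized=features.harmonized,
        flags=dict(features.flags),
    )
    return result, fitted


def zscore_within_cohort(
    features: FeatureMatrix,
    cohort_labels: pd.Series,
    model: HarmonizationModel | None = None,
) -> tuple[FeatureMatrix, HarmonizationModel]:
    """Z-score each feature within each cohort (sample SD, n-1 denominator).

    Constant features are set to 0 and flagged.  Raises on cohorts with a
    single subject.
    """
    labels = cohort_labels.loc[features.data.index]
    out = features.data.copy()
    fitted = model if model is not None else HarmonizationModel()
    freeze = model is not None
    for cohort, idx in labels.groupby(labels).groups.items():
        block = out.loc[idx]
        if len(block) < 2 and not freeze:
            raise ValueError(f"cohort {cohort!r} has a single subject; cannot z-score")
        if freeze:
            for f in block.columns:
                mean, sd = fitted.zstats[(cohort, f)]
                out.loc[idx, f] = 0.0 if sd == 0 else (block[f] - mean) / sd
        else:
            mean = block.mean(axis=0)
            sd = block.std(axis=0, ddof=1)
            const = sd <= 1e-12
            z = (block - mean) / sd.where(~const, other=1.0)
            z.loc[:, const] = 0.0
            out.loc[idx] = z
            for f in block.columns:
                s = 0.0 if const[f] else float(sd[f])
                fitted.zstats[(cohort, f)] = (float(mean[f]), s)
                if const[f]:
                    fitted.constant_features.append((cohort, f))
    result = FeatureMatrix(
        data=out, meta=features.meta, harmonized=True, flags=dict(features.flags)
    )
    result.flags["constant_features"] = list(fitted.constant_features)
    return result, fitted


def harmonize(
    features: FeatureMatrix, covariates: pd.DataFrame
) -> tuple[FeatureMatrix, HarmonizationModel]:
    """Full preprocessing: residualize, then z-score within cohort."""
    resid, model = residualize(features, covariates)
    z, zmodel = zscore_within_cohort(resid, covariates["cohort"])
    model.zstats = zmodel.zstats
    model.constant_features = zmodel.constant_features
    return z, model
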