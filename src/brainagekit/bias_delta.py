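"""Age-bias correction of raw brain-age predictions and the brain-age delta.

Raw predictions regress to the mean of the training age distribution, so the
predicted age Y is first regressed on chronological age (Y = alpha * age +
beta).  The correction adds back the age-dependent shortfall:

    corrected = predicted + (age - (alpha * age + beta))
    delta     = corrected - age

When the bias line is fit on the same sample it corrects, OLS orthogonality
makes the delta uncorrelated with age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BiasModel", "fit_age_bias", "correct_and_delta", "delta_per_cohort"]


@dataclass(frozen=True)
class BiasModel:
    alpha: float  # slope of predicted on chronological age
    beta: float  # intercept
    alpha_se: float
    beta_se: float
    n: int
    sample: str = ""  # identifier of the fitting sample


def fit_age_bias(age, predicted, sample: str = "") -> BiasModel:
    """OLS of predicted age on chronological age.

    Requires at least two paired observations with non-constant age; with
    exactly two points the fit is exact and the SEs are NaN.
    """
    age = np.asarray(age, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if age.shape != predicted.shape:
        raise ValueError("age and predicted must have the same shape")
    if age.size < 2:
        raise ValueError("need at least two subjects to fit the age bias")
    if np.ptp(age) == 0:
        raise ValueError("age is constant; bias slope is not identifiable")
    res = stats.linregress(age, predicted)
    return BiasModel(
        alpha=float(res.slope),
        beta=float(res.intercept),
        alpha_se=float(res.stderr) if age.size > 2 else float("nan"),
        beta_se=float(res.intercept_stderr) if age.size > 2 else float("nan"),
        n=int(age.size),
        sample=sample,
    )


def correct_and_delta(predicted, age, bias: BiasModel):
    """Apply the age-bias correction and compute the brain-age delta (years)."""
    predicted = np.asarray(predicted, dtype=float)
    age = np.asarray(age, dtype=float)
    if predicted.shape != age.shape:
        raise ValueError("predicted and age must have the same shape")
    corrected = predicted + (age - (bias.alpha * age + bias.beta))
    delta = corrected - age
    return corrected, delta


def delta_per_cohort(
    predictions: pd.Series,
    age: pd.Series,
    cohort: pd.Series,
    bias: BiasModel | None = None,
) -> pd.DataFrame:
    """Bias-correct predictions and compute deltas, one bias fit per cohort.

    Pass a frozen ``bias`` model to apply reference-sample coefficients to
    every cohort instead of refitting within each cohort.
    """
    idx = predictions.index
    out = pd.DataFrame(
        {
            "predicted_age": predictions,
            "age": age.loc[idx],
            "cohort": cohort.loc[idx],
        }
    )
    corrected = np.empty(len(out))
    delta = np.empty(len(out))
    alphas = {}
    for name, block in out.groupby("cohort", sort=True):
        b = bias if bias is not None else fit_age_bias(
            block["age"], block["predicted_age"], sample=str(name)
        )
        c, d = correct_and_delta(block["predicted_age"], block["age"], b)
        pos = out.index.get_indexer(block.index)
        corrected[pos] = c
        delta[pos] = d
        alphas[name] = (b.alpha, b.beta)
    out["corrected_age"] = corrected
    out["delta"] = delta
    out.attrs["bias_coefficients"] = alphas
    return out
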