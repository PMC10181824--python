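"""Multi-cohort synthetic dataset generator with known ground truth.

The generator emulates the statistical structure of multi-site ageing
cohorts: uniform chronological age within a configurable range, sex- and
site-structured ROI features with linear age trajectories and sex x age
interactions, TIV effects on volumes, a latent per-subject ageing
acceleration ``delta`` (years), and a biomarker panel whose (log) values
load on ``delta``, on age and on a shared latent pathology score with
configurable standardized effects.

Every generated feature follows

    x[i, r] = a_r + b_r * (age_i + delta_i) + c_r * sex_i
              + d_r * (age_i + delta_i) * sex_i + s[site_i, r]
              + k_r * tiv_i          (volumes only)
              + shared_r * u_i + eps[i, r]

with ``delta_i ~ Normal(0, sigma_delta)`` plus additive APOE-genotype and
diagnosis shifts.  Each biomarker ``m`` is generated from a unit-variance
latent

    z_m = e_delta * dstd + e_age * astd + e_path * path + resid

where ``dstd``/``astd`` are ``delta``/age standardized by their theoretical
moments, ``path`` is a unit-variance pathology score with correlation
``pathology_delta_corr`` to ``dstd``, and ``resid`` takes up the remaining
variance.  Log-normal biomarkers are ``exp(mu + scale * z_m)``; Centiloids
are linear in ``z_m`` (and may be negative).

All randomness derives from ``SimulationConfig.seed`` through named
``numpy`` seed sequences, so regeneration with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import FeatureMatrix, region_table

__all__ = [
    "CohortSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_followup",
    "theoretical_delta_moments",
    "write_dataset",
]

#: Default standardized effect of delta on each biomarker latent.
DEFAULT_DELTA_EFFECTS = {
    "csf_abeta42": -0.35,
    "csf_ptau": 0.30,
    "csf_nfl": 0.30,
    "plasma_nfl": 0.30,
    "wmh_volume": 0.25,
    "centiloid": 0.35,
}

#: Default standardized effect of (standardized) age on each biomarker latent.
DEFAULT_AGE_EFFECTS = {
    "csf_abeta42": -0.15,
    "csf_ptau": 0.20,
    "csf_nfl": 0.35,
    "plasma_nfl": 0.35,
    "wmh_volume": 0.35,
    "centiloid": 0.20,
}

#: Default loading of the shared pathology score (AD-specific markers only).
DEFAULT_PATHOLOGY_EFFECTS = {
    "csf_abeta42": -0.60,
    "csf_ptau": 0.55,
    "csf_nfl": 0.0,
    "plasma_nfl": 0.0,
    "wmh_volume": 0.0,
    "centiloid": 0.60,
}

#: Location/scale of each biomarker's measurement model.  Log-normal markers
#: use (mu, scale) on the natural-log scale; Centiloid is linear.
BIOMARKER_SCALES = {
    "csf_abeta42": ("lognormal", np.log(1250.0), 0.42),
    "csf_ptau": ("lognormal", np.log(16.5), 0.45),
    "csf_nfl": ("lognormal", np.log(85.0), 0.35),
    "plasma_nfl": ("lognormal", np.log(11.0), 0.35),
    "wmh_volume": ("lognormal", np.log(4.0), 0.80),
    "centiloid": ("linear", 12.0, 25.0),
}

_CSF_PANEL = ("csf_abeta42", "csf_ptau", "csf_nfl", "plasma_nfl", "wmh_volume")
_PET_PANEL = ("centiloid",)

DEFAULT_APOE_FREQUENCIES = {"e33": 0.58, "e2": 0.11, "e4": 0.27, "e24": 0.04}
DEFAULT_APOE_DELTA_SHIFTS = {"e33": 0.0, "e2": -0.3, "e4": 1.0, "e24": 0.5}


@dataclass
class CohortSpec:
    """Size and biomarker modality of one synthetic cohort."""

    n: int
    abeta_modality: str = "csf"  # 'csf' or 'pet'
    fraction_mci: float = 0.0
    panel: tuple[str, ...] | None = None  # None -> modality default
    csf_abeta_cutoff: float = 1098.0
    ptau_cutoff: float = 24.0
    centiloid_cutoff: float = 17.0

    def resolved_panel(self) -> tuple[str, ...]:
        if self.panel is not None:
            return tuple(self.panel)
        return _CSF_PANEL if self.abeta_modality == "csf" else _PET_PANEL


@dataclass
class SimulationConfig:
    cohorts: Mapping[str, CohortSpec] = field(
        default_factory=lambda: {"DISCOVERY": CohortSpec(n=500)}
    )
    age_range: tuple[float, float] = (44.0, 81.0)
    fraction_female: float = 0.52
    n_sites: int = 3
    n_regions: int = 183
    sigma_delta: float = 3.0
    biomarker_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DELTA_EFFECTS)
    )
    biomarker_age_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_EFFECTS)
    )
    pathology_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATHOLOGY_EFFECTS)
    )
    pathology_delta_corr: float = 0.3
    apoe_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_APOE_FREQUENCIES)
    )
    apoe_delta_shifts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_APOE_DELTA_SHIFTS)
    )
    mci_delta_shift: float = 1.5
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"thickness": 0.08, "volume": 150.0}
    )
    site_sd: dict[str, float] = field(
        default_factory=lambda: {"thickness": 0.05, "volume": 100.0}
    )
    shared_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"thickness": 0.0, "volume": 0.0}
    )
    follow_up_interval: float = 3.0
    followup_delta_gain: float = 0.1  # g in interval * (1 + g * delta)
    slopes: Sequence[float] | None = None  # optional b_r override
    sex_slopes: Sequence[float] | None = None  # optional d_r override
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.cohorts, Mapping):
            self.cohorts = {
                name: (spec if isinstance(spec, CohortSpec) else CohortSpec(**spec))
                for name, spec in self.cohorts.items()
            }
        self.age_range = tuple(float(a) for a in self.age_range)

    def validate(self) -> None:
        for name, spec in self.cohorts.items():
            if spec.n < 1:
                raise ValueError(f"cohort {name!r}: n must be positive")
            if spec.abeta_modality not in ("csf", "pet"):
                raise ValueError(f"cohort {name!r}: unknown abeta modality")
            for m in spec.resolved_panel():
                if m not in self.biomarker_effects:
                    raise ValueError(
                        f"cohort {name!r} requests biomarker {m!r} with no entry "
                        "in the effect map"
                    )
                if m not in BIOMARKER_SCALES:
                    raise ValueError(f"unknown biomarker {m!r}")
        if not 0.0 <= self.fraction_female <= 1.0:
            raise ValueError("fraction_female must lie in [0, 1]")
        if self.sigma_delta < 0:
            raise ValueError("sigma_delta must be >= 0")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        if self.n_sites < 1 or self.n_regions < 1:
            raise ValueError("n_sites and n_regions must be positive")
        for d in (self.noise_sd, self.site_sd, self.shared_noise_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("all noise SDs must be >= 0")
        if not -1.0 < self.pathology_delta_corr < 1.0:
            raise ValueError("pathology_delta_corr must lie in (-1, 1)")
        fsum = sum(self.apoe_frequencies.values())
        if not np.isclose(fsum, 1.0):
            raise ValueError("apoe_frequencies must sum to 1")

    # -- (de)serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["cohorts"] = {k: dataclasses.asdict(v) for k, v in self.cohorts.items()}
        for key in ("slopes", "sex_slopes"):
            if d[key] is not None:
                d[key] = [float(v) for v in d[key]]
        d["age_range"] = list(d["age_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["cohorts"] = {k: CohortSpec(**v) for k, v in d["cohorts"].items()}
        d["age_range"] = tuple(d["age_range"])
        return cls(**d)


def theoretical_delta_moments(config: SimulationConfig) -> tuple[float, float]:
    """Mean and SD of delta implied by the config (base + APOE + diagnosis).

    The three contributions are independent: a Normal(0, sigma_delta) base,
    a discrete APOE-genotype shift, and a per-cohort Bernoulli MCI shift.
    The MCI mixture is taken across cohorts weighted by cohort size.
    """
    freqs = config.apoe_frequencies
    shifts = config.apoe_delta_shifts
    m_apoe = sum(freqs[g] * shifts.get(g, 0.0) for g in freqs)
    v_apoe = sum(freqs[g] * (shifts.get(g, 0.0) - m_apoe) ** 2 for g in freqs)
    n_total = sum(s.n for s in config.cohorts.values())
    f_mci = sum(s.n * s.fraction_mci for s in config.cohorts.values()) / n_total
    m_mci = f_mci * config.mci_delta_shift
    v_mci = f_mci * (1 - f_mci) * config.mci_delta_shift**2
    mean = m_apoe + m_mci
    sd = float(np.sqrt(config.sigma_delta**2 + v_apoe + v_mci))
    return float(mean), sd


@dataclass
class GroundTruth:
    """Per-subject latents and generating coefficients of a synthetic dataset."""

    delta: pd.Series  # true ageing acceleration, years
    pathology: pd.Series  # shared latent pathology score (unit variance)
    true_abeta_positive: pd.Series  # bool (may be NA when modality absent)
    true_tau_positive: pd.Series
    coefficients: pd.DataFrame  # per feature: a, b, c, d, k
    site_effects: pd.DataFrame  # n_sites x n_features
    biomarker_params: dict  # per biomarker: kind, mu, scale, loadings
    delta_moments: tuple[float, float]
    config: SimulationConfig

    def to_json(self, path) -> None:
        payload = {
            "delta": self.delta.to_dict(),
            "pathology": self.pathology.to_dict(),
            "true_abeta_positive": {
                k: (None if pd.isna(v) else bool(v))
                for k, v in self.true_abeta_positive.items()
            },
            "true_tau_positive": {
                k: (None if pd.isna(v) else bool(v))
                for k, v in self.true_tau_positive.items()
            },
            "coefficients": self.coefficients.to_dict(orient="index"),
            "site_effects": self.site_effects.to_dict(orient="index"),
            "biomarker_params": self.biomarker_params,
            "delta_moments": list(self.delta_moments),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def _draw_region_coefficients(
    config: SimulationConfig, meta: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample per-feature trajectory coefficients and site offsets."""
    n = len(meta)
    is_thick = (meta["measure"] == "thickness").to_numpy()
    a = np.where(is_thick, rng.normal(2.5, 0.25, n), rng.uniform(2000.0, 20000.0, n))
    b = np.where(
        is_thick,
        -rng.uniform(0.004, 0.020, n),
        -rng.uniform(5.0, 40.0, n),
    )
    c = np.where(is_thick, rng.normal(0.0, 0.03, n), rng.normal(0.0, 200.0, n))
    d = np.where(is_thick, rng.normal(0.0, 0.001, n), rng.normal(0.0, 2.0, n))
    k = np.where(is_thick, 0.0, rng.uniform(0.5, 5.0, n))
    if config.slopes is not None:
        b = np.asarray(config.slopes, dtype=float)
        if b.shape != (n,):
            raise ValueError("slopes override must have length n_regions")
    if config.sex_slopes is not None:
        d = np.asarray(config.sex_slopes, dtype=float)
        if d.shape != (n,):
            raise ValueError("sex_slopes override must have length n_regions")
    site_scale = np.where(
        is_thick, config.site_sd["thickness"], config.site_sd["volume"]
    )
    site_effects = rng.normal(0.0, 1.0, (config.n_sites, n)) * site_scale
    coefs = pd.DataFrame(
        {"a": a, "b": b, "c": c, "d": d, "k": k}, index=meta.index
    )
    return coefs, pd.DataFrame(site_effects, columns=meta.index)


def _feature_values(
    meta: pd.DataFrame,
    coefs: pd.DataFrame,
    site_effects: pd.DataFrame,
    effective_age: np.ndarray,
    sex: np.ndarray,
    site: np.ndarray,
    tiv: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    is_thick = (meta["measure"] == "thickness").to_numpy()
    a = coefs["a"].to_numpy()
    b = coefs["b"].to_numpy()
    c = coefs["c"].to_numpy()
    d = coefs["d"].to_numpy()
    k = coefs["k"].to_numpy()
    X = (
        a[None, :]
        + np.outer(effective_age, b)
        + np.outer(sex, c)
        + np.outer(effective_age * sex, d)
        + site_effects.to_numpy()[site, :]
        + np.outer(tiv, k)
    )
    shared = np.where(
        is_thick, config.shared_noise_sd["thickness"], config.shared_noise_sd["volume"]
    )
    if np.any(shared > 0):
        u = rng.normal(0.0, 1.0, len(effective_age))
        X = X + np.outer(u, shared)
    noise = np.where(is_thick, config.noise_sd["thickness"], config.noise_sd["volume"])
    if np.any(noise > 0):
        X = X + rng.normal(0.0, 1.0, X.shape) * noise[None, :]
    return X


def _biomarker_latent_params(config: SimulationConfig, marker: str) -> dict:
    e_d = float(config.biomarker_effects[marker])
    e_a = float(config.biomarker_age_effects.get(marker, 0.0))
    e_p = float(config.pathology_effects.get(marker, 0.0))
    rho = config.pathology_delta_corr
    explained = e_d**2 + e_a**2 + e_p**2 + 2.0 * e_d * e_p * rho
    resid_var = 1.0 - explained
    if resid_var < -1e-9:
        raise ValueError(
            f"biomarker {marker!r}: configured effects imply latent variance > 1"
        )
    kind, mu, scale = BIOMARKER_SCALES[marker]
    return {
        "kind": kind,
        "mu": mu,
        "scale": scale,
        "e_delta": e_d,
        "e_age": e_a,
        "e_path": e_p,
        "resid_sd": float(np.sqrt(max(resid_var, 0.0))),
    }


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, FeatureMatrix, pd.DataFrame, GroundTruth]:
    """Generate subjects, ROI features, biomarker panel and ground truth.

    Returns
    -------
    subjects : DataFrame indexed by subject_id with columns cohort, age, sex
        (labels), site, diagnosis, apoe, tiv.
    features : FeatureMatrix (raw, unharmonized).
    panel : DataFrame indexed by subject_id, one column per biomarker
        (NaN where the cohort's panel does not include it).
    truth : GroundTruth
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_coef, ss_subj, ss_feat, ss_bio, _ss_follow = root.spawn(5)
    meta = region_table(config.n_regions)
    coefs, site_effects = _draw_region_coefficients(
        config, meta, np.random.default_rng(ss_coef)
    )

    rng_s = np.random.default_rng(ss_subj)
    age_lo, age_hi = config.age_range
    delta_mean, delta_sd = theoretical_delta_moments(config)
    age_mu = 0.5 * (age_lo + age_hi)
    age_sigma = (age_hi - age_lo) / np.sqrt(12.0)

    genotypes = sorted(config.apoe_frequencies)
    probs = np.array([config.apoe_frequencies[g] for g in genotypes])
    probs = probs / probs.sum()

    frames = []
    for name, spec in config.cohorts.items():
        n = spec.n
        age = rng_s.uniform(age_lo, age_hi, n)
        sex = (rng_s.uniform(size=n) < config.fraction_female).astype(int)
        site = rng_s.integers(0, config.n_sites, n)
        apoe = np.array(genotypes)[rng_s.choice(len(genotypes), size=n, p=probs)]
        mci = rng_s.uniform(size=n) < spec.fraction_mci
        delta = np.zeros(n)
        if config.sigma_delta > 0:
            delta = rng_s.normal(0.0, config.sigma_delta, n)
        delta = (
            delta
            + np.array([config.apoe_delta_shifts.get(g, 0.0) for g in apoe])
            + np.where(mci, config.mci_delta_shift, 0.0)
        )
        tiv = np.where(
            sex == 1, rng_s.normal(1350.0, 100.0, n), rng_s.normal(1550.0, 110.0, n)
        )
        frames.append(
            pd.DataFrame(
                {
                    "cohort": name,
                    "age": age,
                    "sex": np.where(sex == 1, "female", "male"),
                    "sex_code": sex,
                    "site": [f"{name}_site{int(s)}" for s in site],
                    "site_idx": site,
                    "diagnosis": np.where(mci, "MCI", "CU"),
                    "apoe": apoe,
                    "tiv": tiv,
                    "delta": delta,
                },
                index=[f"{name}_{i:05d}" for i in range(n)],
            )
        )
    subj = pd.concat(frames)
    subj.index.name = "subject_id"

    rng_f = np.random.default_rng(ss_feat)
    X = _feature_values(
        meta,
        coefs,
        site_effects,
        (subj["age"] + subj["delta"]).to_numpy(),
        subj["sex_code"].to_numpy(dtype=float),
        subj["site_idx"].to_numpy(),
        subj["tiv"].to_numpy(),
        config,
        rng_f,
    )
    features = FeatureMatrix(
        data=pd.DataFrame(X, index=subj.index, columns=meta.index),
        meta=meta,
        harmonized=False,
    )

    # biomarkers -----------------------------------------------------------
    rng_b = np.random.default_rng(ss_bio)
    dstd = np.zeros(len(subj))
    if delta_sd > 0:
        dstd = (subj["delta"].to_numpy() - delta_mean) / delta_sd
    astd = (subj["age"].to_numpy() - age_mu) / age_sigma
    rho = config.pathology_delta_corr
    path = rho * dstd + np.sqrt(1.0 - rho**2) * rng_b.normal(0.0, 1.0, len(subj))

    all_markers = sorted(
        {m for spec in config.cohorts.values() for m in spec.resolved_panel()}
    )
    params = {m: _biomarker_latent_params(config, m) for m in all_markers}
    panel = pd.DataFrame(index=subj.index, columns=all_markers, dtype=float)
    for m in all_markers:
        p = params[m]
        z = (
            p["e_delta"] * dstd
            + p["e_age"] * astd
            + p["e_path"] * path
            + p["resid_sd"] * rng_b.normal(0.0, 1.0, len(subj))
        )
        if p["kind"] == "lognormal":
            values = np.exp(p["mu"] + p["scale"] * z)
        else:
            values = p["mu"] + p["scale"] * z
        panel[m] = values
    for name, spec in config.cohorts.items():
        absent = set(all_markers) - set(spec.resolved_panel())
        if absent:
            panel.loc[subj["cohort"] == name, sorted(absent)] = np.nan

    # true biomarker statuses from the cohort's modality and cut-offs
    abeta = pd.Series(pd.NA, index=subj.index, dtype="boolean")
    tau = pd.Series(pd.NA, index=subj.index, dtype="boolean")
    for name, spec in config.cohorts.items():
        mask = (subj["cohort"] == name).to_numpy()
        if spec.abeta_modality == "csf" and "csf_abeta42" in panel:
            abeta[mask] = panel.loc[mask, "csf_abeta42"] < spec.csf_abeta_cutoff
        elif spec.abeta_modality == "pet" and "centiloid" in panel:
            abeta[mask] = panel.loc[mask, "centiloid"] > spec.centiloid_cutoff
        if "csf_ptau" in panel.columns:
            vals = panel.loc[mask, "csf_ptau"]
            tau[mask] = (vals > spec.ptau_cutoff).where(vals.notna(), pd.NA)

    truth = GroundTruth(
        delta=subj["delta"].copy(),
        pathology=pd.Series(path, index=subj.index, name="pathology"),
        true_abeta_positive=abeta,
        true_tau_positive=tau,
        coefficients=coefs,
        site_effects=site_effects,
        biomarker_params={"rho": rho, "markers": params},
        delta_moments=(delta_mean, delta_sd),
        config=config,
    )
    subjects = subj.drop(columns=["delta"])
    return subjects, features, panel, truth


def generate_followup(
    subjects: pd.DataFrame,
    features: FeatureMatrix,
    truth: GroundTruth,
    interval: float | None = None,
) -> FeatureMatrix:
    """Second-visit feature matrix, ``interval`` years after visit 1.

    Each subject's features are advanced along their own trajectory by
    ``interval * (1 + g * delta)`` effective years (``g`` from the config),
    with the same site and TIV and fresh measurement noise.  ``interval=0``
    with zero noise reproduces visit 1 exactly.
    """
    config = truth.config
    if interval is None:
        interval = config.follow_up_interval
    if interval < 0:
        raise ValueError("interval must be >= 0 years")
    if "site_idx" not in subjects.columns:
        raise ValueError("subjects table must come from generate_cohort (site_idx)")
    root = np.random.SeedSequence(config.seed)
    ss_follow = root.spawn(5)[4]
    rng = np.random.default_rng(ss_follow)
    g = config.followup_delta_gain
    sub = subjects.loc[features.data.index]
    delta = truth.delta.loc[features.data.index].to_numpy()
    eff_age = sub["age"].to_numpy() + delta + interval * (1.0 + g * delta)
    X = _feature_values(
        features.meta,
        truth.coefficients,
        truth.site_effects,
        eff_age,
        sub["sex_code"].to_numpy(dtype=float),
        sub["site_idx"].to_numpy(),
        sub["tiv"].to_numpy(),
        config,
        rng,
    )
    return FeatureMatrix(
        data=pd.DataFrame(X, index=features.data.index, columns=features.meta.index),
        meta=features.meta,
        harmonized=False,
    )


def write_dataset(
    outdir,
    subjects: pd.DataFrame,
    features: FeatureMatrix,
    panel: pd.DataFrame,
    truth: GroundTruth,
) -> None:
    """Write all tables to ``outdir`` as CSV/JSON/YAML plus an aparc TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(outdir / "subjects.csv")
    features.to_csv(outdir / "features.csv")
    panel.to_csv(outdir / "biomarkers.csv", index_label="subject_id")
    truth.to_json(outdir / "ground_truth.json")
    truth.config.to_yaml(outdir / "config.yaml")
    features.to_aparcstats_tsv(outdir / "aparc_thickness.tsv", "thickness")
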