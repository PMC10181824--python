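"""Shared tabular containers and region metadata.

The package moves three tables around:

* a subject table (demographics, cohort, site, diagnosis, APOE, TIV),
* a :class:`FeatureMatrix` of subjects x ROI features with per-feature
  metadata (measure kind, hemisphere, region), and
* a biomarker panel (one row per subject).

All of them are plain :class:`pandas.DataFrame` objects except the feature
matrix, which carries metadata and a raw/harmonized state flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Desikan-Killiany cortical parcellation labels (34 per hemisphere).
DESIKAN_KILLIANY = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)

_ASEG_BILATERAL = (
    "Lateral-Ventricle", "Inf-Lat-Vent", "Cerebellum-White-Matter",
    "Cerebellum-Cortex", "Thalamus-Proper", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Amygdala", "Accumbens-area", "VentralDC", "vessel",
    "choroid-plexus", "Cerebral-White-Matter", "WM-hypointensities",
    "non-WM-hypointensities",
)

_ASEG_MIDLINE = (
    "3rd-Ventricle", "4th-Ventricle", "5th-Ventricle", "Brain-Stem", "CSF",
    "WM-hypointensities-total", "non-WM-hypointensities-total", "Optic-Chiasm",
    "CC_Posterior", "CC_Mid_Posterior", "CC_Central", "CC_Mid_Anterior",
    "CC_Anterior",
)


def region_table(n_regions: int = 183) -> pd.DataFrame:
    """Build the feature metadata table for ``n_regions`` ROI features.

    The default 183 features are: for each Desikan-Killiany label, lh/rh
    cortical thickness and lh/rh cortical volume (34 x 4 = 136), followed by
    47 aseg-style subcortical volumes.  Smaller ``n_regions`` take a prefix
    of this ordering (so both thickness and volume features are present for
    any ``n_regions >= 4``); larger values append generic volume features.

    Returns a DataFrame indexed by feature name with columns
    ``measure`` ('thickness'|'volume'), ``hemisphere`` ('lh'|'rh'|'midline')
    and ``region``.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be a positive integer")
    rows: list[tuple[str, str, str, str]] = []
    for label in DESIKAN_KILLIANY:
        for hemi in ("lh", "rh"):
            rows.append((f"{hemi}_{label}_thickness", "thickness", hemi, label))
        for hemi in ("lh", "rh"):
            rows.append((f"{hemi}_{label}_volume", "volume", hemi, label))
    for name in _ASEG_BILATERAL:
        rows.append((f"Left-{name}", "volume", "lh", name))
        rows.append((f"Right-{name}", "volume", "rh", name))
    for name in _ASEG_MIDLINE:
        rows.append((name, "volume", "midline", name))
    i = 0
    while len(rows) < n_regions:
        rows.append((f"extra{i:03d}_volume", "volume", "midline", f"extra{i:03d}"))
        i += 1
    rows = rows[:n_regions]
    meta = pd.DataFrame(rows, columns=["feature", "measure", "hemisphere", "region"])
    return meta.set_index("feature")


@dataclass
class FeatureMatrix:
    """Subjects x ROI features with per-feature metadata.

    Parameters
    ----------
    data:
        DataFrame indexed by subject id, one column per feature.
    meta:
        DataFrame indexed by feature name, columns ``measure``,
        ``hemisphere``, ``region``; must cover every column of ``data``.
    harmonized:
        Whether the features have been residualized/z-scored.
    flags:
        Free-form per-feature flags set by processing steps (e.g. features
        found constant during z-scoring).
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    harmonized: bool = False
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"features missing from metadata: {sorted(missing)[:5]}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def measure_of(self, feature: str) -> str:
        return str(self.meta.loc[feature, "measure"])

    def features_by_measure(self, measure: str) -> list[str]:
        sel = self.meta.loc[self.meta["measure"] == measure].index
        return [f for f in self.data.columns if f in set(sel)]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            data=self.data.copy(),
            meta=self.meta.copy(),
            harmonized=self.harmonized,
            flags=dict(self.flags),
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="subject_id")

    def to_aparcstats_tsv(self, path, measure: str = "thickness") -> None:
        """Write a FreeSurfer ``aparcstats2table``-style TSV (one measure)."""
        cols = self.features_by_measure(measure)
        out = self.data[cols].copy()
        out.index.name = f"{measure}-subject"
        out.to_csv(path, sep="\t")


SUBJECT_COLUMNS = (
    "subject_id", "cohort", "age", "sex", "site", "diagnosis", "apoe", "tiv",
)

SEX_LABELS = {0: "male", 1: "female"}
SEX_CODES = {"male": 0, "female": 1, "M": 0, "F": 1, 0: 0, 1: 1}


def sex_to_code(values) -> pd.Series:
    """Map sex labels to the internal 0/1 (male/female) coding."""
    s = pd.Series(values)
    try:
        return s.map(SEX_CODES).astype(int)
    except (ValueError, TypeError) as err:  # unmapped labels become NaN
        bad = sorted(set(s[~s.isin(SEX_CODES)].astype(str)))
        raise ValueError(f"unknown sex labels: {bad}") from err
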