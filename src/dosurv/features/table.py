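"""Assembly of patient x feature tables.

A feature group is extracted per region (whole heart, or each of the five
subparts) and concatenated with the clinical and chemotherapy covariates.
Dosimetric column counts per group and scale:

===============  ============  =========
group            whole_heart   subparts
===============  ============  =========
mean_dose        1             5
dose_volume      24            120
firstorder       18            90
dosiomics_full   93            465
===============  ============  =========
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..cohort import PatientRecord, clinical_frame
from ..volume import SUBPARTS, WHOLE_HEART, DoseVolume
from .discretize import discretize
from .dvh import dose_volume_indicators, mean_dose
from .firstorder import first_order_features
from .texture import glcm_features, gldm_features, glrlm_features, glszm_features, ngtdm_features

FEATURE_GROUPS = ("mean_dose", "dose_volume", "firstorder", "dosiomics_full")
SCALES = ("whole_heart", "subparts")

#: Default dose bin width (Gy) for the discretization behind texture features.
DEFAULT_BIN_WIDTH_GY = 0.5


@dataclass
class FeatureTable:
    """Patient x feature matrix with per-column (kind, region, family) tags."""

    data: pd.DataFrame
    column_meta: dict[str, dict]  # column -> {"kind", "region", "family"}

    @property
    def p(self) -> int:
        return self.data.shape[1]

    def dosimetric_columns(self) -> list[str]:
        return [c for c, m in self.column_meta.items() if m["kind"] == "dosimetric"]

    def clinical_columns(self) -> list[str]:
        return [c for c, m in self.column_meta.items() if m["kind"] == "clinical"]

    def diagnosis_columns(self) -> list[str]:
        return [c for c, m in self.column_meta.items() if m["kind"] == "diagnosis"]

    def subset(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(
            data=self.data[columns].copy(),
            column_meta={c: self.column_meta[c] for c in columns},
        )

    def to_csv(self, path, meta_path=None) -> None:
        self.data.to_csv(path, float_format="%.10g")
        if meta_path is not None:
            import json

            with open(meta_path, "w") as fh:
                json.dump(self.column_meta, fh, indent=1)


def extract_region_features(
    volume: DoseVolume, region: str, group: str, bin_width: float = DEFAULT_BIN_WIDTH_GY
) -> dict[str, float]:
    """Ordered feature-name -> value map for one region and group."""
    if group == "mean_dose":
        return {"mean_dose": mean_dose(volume, region)}
    if group == "dose_volume":
        return dose_volume_indicators(volume, region)
    disc = discretize(volume, region, bin_width=bin_width)
    out = {f"firstorder_{k}": v for k, v in first_order_features(disc, volume, region).items()}
    if group == "firstorder":
        return out
    if group == "dosiomics_full":
        for prefix, fn in (
            ("glcm", glcm_features),
            ("glrlm", glrlm_features),
            ("glszm", glszm_features),
            ("ngtdm", ngtdm_features),
            ("gldm", gldm_features),
        ):
            out.update({f"{prefix}_{k}": v for k, v in fn(disc).items()})
        return out
    raise ValueError(f"unknown feature group {group!r}; expected one of {FEATURE_GROUPS}")


def regions_for_scale(scale: str) -> tuple[str, ...]:
    if scale == "whole_heart":
        return (WHOLE_HEART,)
    if scale == "subparts":
        return SUBPARTS
    raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")


def patient_feature_row(
    volume: DoseVolume, group: str, scale: str, bin_width: float = DEFAULT_BIN_WIDTH_GY
) -> dict[str, float]:
    """Dosimetric features of one preprocessed patient volume."""
    row: dict[str, float] = {}
    for region in regions_for_scale(scale):
        feats = extract_region_features(volume, region, group, bin_width=bin_width)
        row.update({f"{region}__{k}": v for k, v in feats.items()})
    return row


def extract_feature_table(
    records: list[PatientRecord],
    volumes: dict[str, DoseVolume],
    group: str,
    scale: str = "whole_heart",
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> FeatureTable:
    """Clinical + chemotherapy + dosimetric design matrix for a cohort.

    ``volumes`` maps patient id to the preprocessed (session-summed,
    outlier-clipped) dose volume; every patient must carry the masks the
    requested scale needs.
    """
    clin = clinical_frame(records)
    dose_rows = []
    for r in records:
        try:
            vol = volumes[r.patient_id]
        except KeyError:
            raise KeyError(f"no dose volume for patient {r.patient_id!r}") from None
        dose_rows.append(patient_feature_row(vol, group, scale, bin_width=bin_width))
    dose = pd.DataFrame(dose_rows, index=clin.index)
    data = pd.concat([clin, dose], axis=1)
    if data.isna().any().any():
        bad = data.columns[data.isna().any()].tolist()
        raise ValueError(f"non-finite feature values in columns {bad}")

    meta: dict[str, dict] = {}
    for c in clin.columns:
        kind = "diagnosis" if c.startswith("diag_") else "clinical"
        meta[c] = {"kind": kind, "region": None, "family": None}
    for c in dose.columns:
        region, name = c.split("__", 1)
        family = name.split("_", 1)[0] if name.startswith(("glcm", "glrlm", "glszm", "ngtdm", "gldm")) else (
            "firstorder" if name.startswith("firstorder") else "dvh"
        )
        meta[c] = {"kind": "dosimetric", "region": region, "family": family}
    return FeatureTable(data=data, column_meta=meta)
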