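"""Theory-driven composite ROIs and regional -> composite SUVR aggregation.

The four built-in composites follow the Braak-motivated scheme used across
the tau-PET literature:

* ``entorhinal``       — bilateral entorhinal cortex (stage I/II)
* ``early_tau``        — entorhinal + inferior temporal + fusiform +
  parahippocampal (regions accumulating tau earliest)
* ``temporal_meta``    — entorhinal + amygdala + inferior/middle temporal +
  fusiform + parahippocampal (approximating Braak I-IV)
* ``neocortical_meta`` — widespread neocortex (approximating Braak V/VI);
  here every cortical label except the temporal-meta members and the
  cingulate (limbic) labels, overridable by passing custom definitions.

Composites are volume-weighted means by default (the convention for
published meta-ROIs); unweighted arithmetic means are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import RegionAtlas

WEIGHTINGS = ("volume_weighted", "unweighted")

_TEMPORAL_META_REGIONS = (
    "entorhinal",
    "amygdala",
    "inferiortemporal",
    "middletemporal",
    "fusiform",
    "parahippocampal",
)
_EARLY_TAU_REGIONS = ("entorhinal", "inferiortemporal", "fusiform", "parahippocampal")
_LIMBIC_EXCLUDE = (
    "caudalanteriorcingulate",
    "isthmuscingulate",
    "posteriorcingulate",
    "rostralanteriorcingulate",
)


@dataclass(frozen=True)
class CompositeROIDefinition:
    name: str
    member_labels: tuple[str, ...]
    weighting: str = "volume_weighted"

    def __post_init__(self) -> None:
        if not self.member_labels:
            raise ValueError(f"ROI {self.name!r} has no member labels")
        if len(set(self.member_labels)) != len(self.member_labels):
            raise ValueError(f"ROI {self.name!r} has duplicate member labels")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(
                f"ROI {self.name!r}: weighting must be one of {WEIGHTINGS}"
            )

    def validate_against(self, atlas: RegionAtlas) -> None:
        missing = [lab for lab in self.member_labels if lab not in atlas.stage_class]
        if missing:
            raise ValueError(f"ROI {self.name!r}: labels missing from atlas: {missing}")


def builtin_rois(
    atlas: RegionAtlas, weighting: str = "volume_weighted"
) -> list[CompositeROIDefinition]:
    """The four theory-driven composite ROI definitions, bilateral."""

    def bilateral(regions) -> tuple[str, ...]:
        labs: list[str] = []
        for region in regions:
            labs.extend(atlas.bilateral(region))
        return tuple(labs)

    temporal = bilateral(_TEMPORAL_META_REGIONS)
    early = bilateral(_EARLY_TAU_REGIONS)
    exclude = set(temporal) | set(bilateral(_LIMBIC_EXCLUDE))
    neocortical = tuple(
        lab for lab in atlas.cortical_labels() if lab not in exclude
    )
    rois = [
        CompositeROIDefinition("entorhinal", bilateral(("entorhinal",)), weighting),
        CompositeROIDefinition("early_tau", early, weighting),
        CompositeROIDefinition("temporal_meta", temporal, weighting),
        CompositeROIDefinition("neocortical_meta", neocortical, weighting),
    ]
    for roi in rois:
        roi.validate_against(atlas)
    return rois


def aggregate(cohort: pd.DataFrame, roi: CompositeROIDefinition) -> pd.Series:
    """Per-subject composite SUVR for one ROI over a wide cohort table."""
    suvr_cols = [f"suvr_{lab}" for lab in roi.member_labels]
    missing = [c for c in suvr_cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"ROI {roi.name!r}: cohort is missing columns {missing}")
    suvr = cohort[suvr_cols].to_numpy(dtype=float)
    if roi.weighting == "unweighted":
        values = suvr.mean(axis=1)
    else:
        vol_cols = [f"vol_{lab}" for lab in roi.member_labels]
        missing = [c for c in vol_cols if c not in cohort.columns]
        if missing:
            raise ValueError(f"ROI {roi.name!r}: cohort is missing columns {missing}")
        vols = cohort[vol_cols].to_numpy(dtype=float)
        total = vols.sum(axis=1)
        if np.any(total <= 0):
            row = int(np.argmax(total <= 0))
            raise ValueError(f"ROI {roi.name!r}: zero total volume at row {row}")
        values = (vols * suvr).sum(axis=1) / total
    return pd.Series(values, index=cohort.index, name=roi.name)


def build_roi_table(
    cohort: pd.DataFrame, rois: list[CompositeROIDefinition]
) -> pd.DataFrame:
    """Composite SUVR table: metadata columns + one column per composite ROI."""
    meta_cols = [
        c
        for c in ("subject_id", "tracer", "diagnosis", "subtype", "abeta_status")
        if c in cohort.columns
    ]
    out = cohort[meta_cols].copy()
    for roi in rois:
        out[roi.name] = aggregate(cohort, roi)
    return out
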