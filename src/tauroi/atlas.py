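"""Region atlas: the label universe over which regional SUVR values are defined.

The default atlas mimics a FreeSurfer Desikan-Killiany cortical parcellation
(31 bilateral cortical regions, i.e. 62 labels) plus the bilateral amygdala,
each label carrying a nominal volume and a coarse Braak stage class used by
the synthetic cohort generator:

* ``I_II``   — entorhinal cortex (earliest neurofibrillary involvement)
* ``III_IV`` — limbic / medial-inferior temporal spread (amygdala,
  parahippocampal, fusiform, inferior and middle temporal)
* ``V_VI``   — remaining neocortex (late involvement)
* ``off_target`` — labels whose signal is dominated by non-specific binding;
  none in the default atlas, but supported so tracer models can attach an
  additive off-target shift to specific label sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STAGE_CLASSES = ("I_II", "III_IV", "V_VI", "off_target")

# Desikan-Killiany-style cortical region names (per hemisphere) with nominal
# volumes in mm^3 (round numbers; only relative sizes matter downstream).
_CORTICAL_VOLUMES: dict[str, float] = {
    "bankssts": 2500.0,
    "caudalanteriorcingulate": 2000.0,
    "caudalmiddlefrontal": 6000.0,
    "cuneus": 3000.0,
    "entorhinal": 1800.0,
    "fusiform": 9000.0,
    "inferiorparietal": 13000.0,
    "inferiortemporal": 11000.0,
    "isthmuscingulate": 2500.0,
    "lateraloccipital": 11000.0,
    "lateralorbitofrontal": 7000.0,
    "lingual": 6000.0,
    "medialorbitofrontal": 5000.0,
    "middletemporal": 12000.0,
    "parahippocampal": 2200.0,
    "paracentral": 3500.0,
    "parsopercularis": 4500.0,
    "parsorbitalis": 2000.0,
    "parstriangularis": 3500.0,
    "pericalcarine": 2000.0,
    "postcentral": 10000.0,
    "posteriorcingulate": 3000.0,
    "precentral": 13000.0,
    "precuneus": 10000.0,
    "rostralanteriorcingulate": 2500.0,
    "rostralmiddlefrontal": 9000.0,
    "superiorfrontal": 22000.0,
    "superiorparietal": 13000.0,
    "superiortemporal": 11000.0,
    "supramarginal": 10000.0,
    "transversetemporal": 1000.0,
}

_SUBCORTICAL_VOLUMES: dict[str, float] = {"amygdala": 1700.0}

# Coarse Braak stage grouping; everything cortical not listed here is V_VI.
_STAGE_I_II = {"entorhinal"}
_STAGE_III_IV = {
    "amygdala",
    "parahippocampal",
    "fusiform",
    "inferiortemporal",
    "middletemporal",
}


@dataclass(frozen=True)
class RegionAtlas:
    """A set of region labels with stage classes and nominal volumes.

    Parameters
    ----------
    labels
        Unique region identifiers, e.g. ``"lh_entorhinal"``.
    stage_class
        Mapping from label to one of :data:`STAGE_CLASSES`.
    nominal_volume
        Mapping from label to a strictly positive volume (mm^3; arbitrary
        units are fine since only relative weights are used).
    """

    labels: tuple[str, ...]
    stage_class: dict[str, str] = field(repr=False)
    nominal_volume: dict[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atlas labels must be unique")
        for lab in self.labels:
            cls = self.stage_class.get(lab)
            if cls not in STAGE_CLASSES:
                raise ValueError(
                    f"label {lab!r} has invalid stage class {cls!r}; "
                    f"expected one of {STAGE_CLASSES}"
                )
            vol = self.nominal_volume.get(lab)
            if vol is None or not np.isfinite(vol) or vol <= 0:
                raise ValueError(f"label {lab!r} must have a finite positive volume")

    def __len__(self) -> int:
        return len(self.labels)

    def volumes(self, labels: list[str] | tuple[str, ...]) -> np.ndarray:
        return np.asarray([self.nominal_volume[lab] for lab in labels], dtype=float)

    def cortical_labels(self) -> tuple[str, ...]:
        """Labels belonging to cortical regions (amygdala is subcortical)."""
        return tuple(lab for lab in self.labels if not lab.endswith("amygdala"))

    def bilateral(self, region: str) -> tuple[str, str]:
        """Return the left/right label pair for a region name, validating presence."""
        pair = (f"lh_{region}", f"rh_{region}")
        for lab in pair:
            if lab not in self.stage_class:
                raise KeyError(f"atlas is missing required label {lab!r}")
        return pair


def default_atlas() -> RegionAtlas:
    """The built-in 64-label bilateral atlas (62 cortical labels + amygdalae)."""
    labels: list[str] = []
    stage: dict[str, str] = {}
    vols: dict[str, float] = {}
    for hemi in ("lh", "rh"):
        for region, vol in {**_CORTICAL_VOLUMES, **_SUBCORTICAL_VOLUMES}.items():
            lab = f"{hemi}_{region}"
            labels.append(lab)
            vols[lab] = vol
            if region in _STAGE_I_II:
                stage[lab] = "I_II"
            elif region in _STAGE_III_IV:
                stage[lab] = "III_IV"
            else:
                stage[lab] = "V_VI"
    return RegionAtlas(labels=tuple(labels), stage_class=stage, nominal_volume=vols)
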