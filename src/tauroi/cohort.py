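"""Synthetic multi-tracer regional-SUVR cohort generator.

The generative model is a single latent tau-burden severity per subject.
A subject in stratum (group, amyloid status) draws a latent severity

    z ~ Normal(latent_mean, latent_sd^2)

and each atlas region ``r`` with stage class ``c(r)`` accumulates burden
through a logistic dose-response with a class-specific onset:

    burden_r = 1 / (1 + exp(-(z - theta_{c(r)}) / tau))

so that early-stage regions (lower onset theta) saturate before late-stage
regions, emulating Braak-ordered spread.  A tracer maps burden to SUVR
through an affine model with additive Gaussian measurement noise:

    suvr_r = a_t + b_t * burden_r + shift_{c(r)} + eps,   eps ~ N(0, sigma_t^2)

truncated below at 0.05 SUVR.  Amyloid status within each group is assigned
as an exact count (round(n * fraction), order shuffled by the seeded RNG),
so configured stratum sizes are reproduced deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import STAGE_CLASSES, RegionAtlas, default_atlas

DIAGNOSES = ("CU", "AD", "nonAD")

_META_COLS = ["subject_id", "tracer", "diagnosis", "subtype", "abeta_status"]

SUVR_FLOOR = 0.05


def _check_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class TracerModel:
    """Affine latent-burden -> SUVR map for one tracer.

    ``offset`` and ``gain`` are in SUVR units (gain per unit burden, burden
    in [0, 1]); ``noise_sd`` is per-region measurement noise in SUVR units;
    ``offtarget_shift`` adds a constant SUVR shift per stage class (e.g. to
    model meningeal spill-in on off-target labels).
    """

    name: str
    offset: float
    gain: float
    noise_sd: float
    offtarget_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fname in ("offset", "gain", "noise_sd"):
            _check_finite(f"tracer {self.name!r}: {fname}", getattr(self, fname))
        if self.gain <= 0:
            raise ValueError(f"tracer {self.name!r}: gain must be > 0")
        if self.noise_sd <= 0:
            raise ValueError(f"tracer {self.name!r}: noise_sd must be > 0")
        for cls, val in self.offtarget_shift.items():
            if cls not in STAGE_CLASSES:
                raise ValueError(
                    f"tracer {self.name!r}: unknown stage class {cls!r} in offtarget_shift"
                )
            _check_finite(f"tracer {self.name!r}: offtarget_shift[{cls!r}]", val)

    def shift(self, stage_class: str) -> float:
        return self.offtarget_shift.get(stage_class, 0.0)


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group (optionally a single subtype) in a cohort.

    Latent severity can differ between amyloid-negative and -positive strata
    (``latent_mean``/``latent_sd`` for Abeta-, ``latent_mean_pos``/
    ``latent_sd_pos`` for Abeta+; the positive stratum defaults to the
    negative one).
    """

    diagnosis: str
    n: int
    latent_mean: float
    latent_sd: float
    subtype: str = ""
    abeta_pos_fraction: float = 0.0
    latent_mean_pos: float | None = None
    latent_sd_pos: float | None = None

    def __post_init__(self) -> None:
        label = f"group {self.diagnosis}/{self.subtype or '-'}"
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"{label}: diagnosis must be one of {DIAGNOSES}")
        if not isinstance(self.n, (int, np.integer)) or self.n < 1:
            raise ValueError(f"{label}: n must be a positive integer, got {self.n!r}")
        if not 0.0 <= self.abeta_pos_fraction <= 1.0:
            raise ValueError(f"{label}: abeta_pos_fraction must be in [0, 1]")
        _check_finite(f"{label}: latent_mean", self.latent_mean)
        _check_finite(f"{label}: latent_sd", self.latent_sd)
        if self.latent_sd <= 0:
            raise ValueError(f"{label}: latent_sd must be > 0")
        if self.latent_mean_pos is not None:
            _check_finite(f"{label}: latent_mean_pos", self.latent_mean_pos)
        if self.latent_sd_pos is not None:
            _check_finite(f"{label}: latent_sd_pos", self.latent_sd_pos)
            if self.latent_sd_pos <= 0:
                raise ValueError(f"{label}: latent_sd_pos must be > 0")

    @property
    def pos_mean(self) -> float:
        return self.latent_mean if self.latent_mean_pos is None else self.latent_mean_pos

    @property
    def pos_sd(self) -> float:
        return self.latent_sd if self.latent_sd_pos is None else self.latent_sd_pos

    @property
    def n_abeta_pos(self) -> int:
        return int(round(self.n * self.abeta_pos_fraction))


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one tracer cohort."""

    tracer: TracerModel
    groups: tuple[GroupSpec, ...]
    atlas: RegionAtlas = field(default_factory=default_atlas)
    stage_onsets: dict[str, float] = field(
        default_factory=lambda: {"I_II": 0.0, "III_IV": 0.8, "V_VI": 1.8}
    )
    stage_slope: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        for cls in ("I_II", "III_IV", "V_VI"):
            if cls not in self.stage_onsets:
                raise ValueError(f"stage_onsets missing class {cls!r}")
            _check_finite(f"stage_onsets[{cls!r}]", self.stage_onsets[cls])
        o = self.stage_onsets
        if not (o["I_II"] <= o["III_IV"] <= o["V_VI"]):
            raise ValueError("stage onsets must be ordered I_II <= III_IV <= V_VI")
        _check_finite("stage_slope", self.stage_slope)
        if self.stage_slope <= 0:
            raise ValueError("stage_slope must be > 0")
        used = {self.atlas.stage_class[lab] for lab in self.atlas.labels}
        missing = used - set(self.stage_onsets) - {"off_target"}
        if missing:
            raise ValueError(f"stage_onsets missing classes {sorted(missing)}")

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)

    def onset(self, stage_class: str) -> float:
        # off-target labels do not track tau burden: infinite onset => burden 0
        if stage_class == "off_target":
            return np.inf
        return self.stage_onsets[stage_class]


def region_burden(z: np.ndarray, onset: float, slope: float) -> np.ndarray:
    """Logistic latent-severity -> burden response, saturating at 1."""
    z = np.asarray(z, dtype=float)
    if np.isinf(onset):
        return np.zeros_like(z)
    return 1.0 / (1.0 + np.exp(-(z - onset) / slope))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one wide table of subjects for a cohort configuration.

    Returns a DataFrame with columns ``subject_id, tracer, diagnosis,
    subtype, abeta_status`` followed by ``suvr_<label>`` and ``vol_<label>``
    for every atlas label, one row per subject.  Identical configs (same
    seed) give identical tables.
    """
    rng = np.random.default_rng(config.seed)
    atlas = config.atlas
    tracer = config.tracer
    onsets = np.asarray([config.onset(atlas.stage_class[lab]) for lab in atlas.labels])
    shifts = np.asarray([tracer.shift(atlas.stage_class[lab]) for lab in atlas.labels])
    vols = atlas.volumes(atlas.labels)

    frames: list[pd.DataFrame] = []
    counter = 0
    for group in config.groups:
        n = group.n
        k_pos = group.n_abeta_pos
        status = np.array(["neg"] * (n - k_pos) + ["pos"] * k_pos)
        rng.shuffle(status)
        is_pos = status == "pos"
        z = np.empty(n)
        z[~is_pos] = rng.normal(group.latent_mean, group.latent_sd, size=int((~is_pos).sum()))
        z[is_pos] = rng.normal(group.pos_mean, group.pos_sd, size=int(is_pos.sum()))

        burden = 1.0 / (1.0 + np.exp(-(z[:, None] - onsets[None, :]) / config.stage_slope))
        burden[:, np.isinf(onsets)] = 0.0
        noise = rng.normal(0.0, tracer.noise_sd, size=burden.shape)
        suvr = tracer.offset + tracer.gain * burden + shifts[None, :] + noise
        np.maximum(suvr, SUVR_FLOOR, out=suvr)

        ids = [
            f"{tracer.name}_{group.diagnosis}{('_' + group.subtype) if group.subtype else ''}_{counter + i:05d}"
            for i in range(n)
        ]
        counter += n
        meta = pd.DataFrame(
            {
                "subject_id": ids,
                "tracer": tracer.name,
                "diagnosis": group.diagnosis,
                "subtype": group.subtype,
                "abeta_status": status,
            }
        )
        suvr_df = pd.DataFrame(suvr, columns=[f"suvr_{lab}" for lab in atlas.labels])
        vol_df = pd.DataFrame(
            np.tile(vols, (n, 1)), columns=[f"vol_{lab}" for lab in atlas.labels]
        )
        frames.append(pd.concat([meta, suvr_df, vol_df], axis=1))

    out = pd.concat(frames, axis=0, ignore_index=True)
    return out


def save_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as UTF-8 CSV (round-trips through load_cohort)."""
    table.to_csv(path, index=False, float_format="%.12g")


def _infer_labels(columns) -> list[str]:
    seen: dict[str, None] = {}
    for c in columns:
        if c.startswith("suvr_"):
            seen.setdefault(c[len("suvr_"):])
        elif c.startswith("vol_"):
            seen.setdefault(c[len("vol_"):])
    return list(seen)


def load_cohort(path, atlas: RegionAtlas | None = None) -> pd.DataFrame:
    """Load and validate a wide cohort CSV.

    Raises ``ValueError`` naming the offending column/row on schema
    violations: missing metadata or per-label columns, duplicate subject
    ids, non-positive SUVR values, or an empty file.
    """
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"cohort file {path} is empty") from exc
    if table.empty:
        raise ValueError(f"cohort file {path} contains no rows")
    missing_meta = [c for c in _META_COLS if c not in table.columns]
    if missing_meta:
        raise ValueError(f"cohort file {path} missing required columns {missing_meta}")
    labels = _infer_labels(table.columns) if atlas is None else list(atlas.labels)
    if not labels:
        raise ValueError(f"cohort file {path} has no suvr_* columns")
    for lab in labels:
        for col in (f"suvr_{lab}", f"vol_{lab}"):
            if col not in table.columns:
                raise ValueError(f"cohort file {path} missing required column {col!r}")
    dup = table["subject_id"][table["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicated subject_id values: {sorted(dup.unique())[:5]}")
    value_cols = [f"{p}_{lab}" for lab in labels for p in ("suvr", "vol")]
    table[value_cols] = table[value_cols].astype(float)
    suvr_cols = [f"suvr_{lab}" for lab in labels]
    bad = table[suvr_cols].le(0) | ~np.isfinite(table[suvr_cols])
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = int(bad[col].idxmax())
        raise ValueError(
            f"non-positive or non-finite SUVR in column {col!r}, row {row}"
        )
    table["subtype"] = table["subtype"].fillna("")
    return table
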