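"""Composite ROI definitions and regional -> composite aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tauroi import CompositeROIDefinition, aggregate, build_roi_table, builtin_rois


def _members(rois, name):
    return set(next(r for r in rois if r.name == name).member_labels)


def test_builtin_roi_membership(atlas):
    rois = builtin_rois(atlas)
    assert [r.name for r in rois] == [
        "entorhinal", "early_tau", "temporal_meta", "neocortical_meta",
    ]
    assert _members(rois, "entorhinal") == {"lh_entorhinal", "rh_entorhinal"}
    expected_temporal = {
        f"{h}_{reg}"
        for h in ("lh", "rh")
        for reg in ("entorhinal", "amygdala", "inferiortemporal",
                    "middletemporal", "fusiform", "parahippocampal")
    }
    assert _members(rois, "temporal_meta") == expected_temporal
    expected_early = {
        f"{h}_{reg}"
        for h in ("lh", "rh")
        for reg in ("entorhinal", "inferiortemporal", "fusiform", "parahippocampal")
    }
    assert _members(rois, "early_tau") == expected_early
    # temporal meta = early tau plus bilateral amygdala and middle temporal
    assert _members(rois, "temporal_meta") == expected_early | {
        "lh_amygdala", "rh_amygdala", "lh_middletemporal", "rh_middletemporal",
    }
    neo = _members(rois, "neocortical_meta")
    assert neo.isdisjoint(expected_temporal)
    assert not any("cingulate" in lab or "amygdala" in lab for lab in neo)


def _frame(suvrs: dict[str, float], vols: dict[str, float]) -> pd.DataFrame:
    cols = {f"suvr_{k}": [v] for k, v in suvrs.items()}
    cols.update({f"vol_{k}": [v] for k, v in vols.items()})
    return pd.DataFrame(cols)


def test_volume_weighted_two_member_example():
    roi = CompositeROIDefinition("toy", ("a", "b"), "volume_weighted")
    frame = _frame({"a": 1.0, "b": 1.6}, {"a": 2.0, "b": 1.0})
    assert aggregate(frame, roi).iloc[0] == pytest.approx(1.2)


@pytest.mark.parametrize("weighting", ["volume_weighted", "unweighted"])
def test_constant_members_identity(weighting):
    roi = CompositeROIDefinition("toy", ("a", "b", "c"), weighting)
    frame = _frame({"a": 1.37, "b": 1.37, "c": 1.37}, {"a": 3.0, "b": 1.0, "c": 2.0})
    assert aggregate(frame, roi).iloc[0] == pytest.approx(1.37, abs=1e-15)


def test_matches_explicit_loop_oracle(rng):
    labels = tuple(f"m{i}" for i in range(6))
    suvrs = dict(zip(labels, rng.uniform(0.8, 3.0, 6)))
    vols = dict(zip(labels, rng.uniform(500, 9000, 6)))
    frame = _frame(suvrs, vols)
    num = den = 0.0
    for lab in labels:
        num += vols[lab] * suvrs[lab]
        den += vols[lab]
    roi = CompositeROIDefinition("toy", labels, "volume_weighted")
    assert aggregate(frame, roi).iloc[0] == pytest.approx(num / den, rel=1e-14)
    roi_u = CompositeROIDefinition("toy", labels, "unweighted")
    assert aggregate(frame, roi_u).iloc[0] == pytest.approx(
        np.mean(list(suvrs.values())), rel=1e-14
    )


@settings(deadline=None, max_examples=50)
@given(
    suvrs=st.lists(st.floats(0.1, 5.0), min_size=2, max_size=8),
    shift=st.floats(-0.5, 0.5),
    data=st.data(),
)
def test_bounding_and_shift_equivariance(suvrs, shift, data):
    labels = tuple(f"m{i}" for i in range(len(suvrs)))
    vols = data.draw(
        st.lists(st.floats(1.0, 100.0), min_size=len(suvrs), max_size=len(suvrs))
    )
    frame = _frame(dict(zip(labels, suvrs)), dict(zip(labels, vols)))
    for weighting in ("volume_weighted", "unweighted"):
        roi = CompositeROIDefinition("toy", labels, weighting)
        val = aggregate(frame, roi).iloc[0]
        assert min(suvrs) - 1e-9 <= val <= max(suvrs) + 1e-9
        shifted = _frame(
            {k: v + shift for k, v in zip(labels, suvrs)}, dict(zip(labels, vols))
        )
        assert aggregate(shifted, roi).iloc[0] == pytest.approx(val + shift, abs=1e-9)


def test_equal_volumes_match_unweighted(rng):
    labels = tuple(f"m{i}" for i in range(5))
    suvrs = dict(zip(labels, rng.uniform(0.5, 3.0, 5)))
    frame = _frame(suvrs, {lab: 7.0 for lab in labels})
    vw = aggregate(frame, CompositeROIDefinition("t", labels, "volume_weighted"))
    uw = aggregate(frame, CompositeROIDefinition("t", labels, "unweighted"))
    assert abs(vw.iloc[0] - uw.iloc[0]) < 1e-12


def test_roi_table_carries_metadata_and_bounds(small_cohort, atlas):
    rois = builtin_rois(atlas)
    table = build_roi_table(small_cohort, rois)
    assert len(table) == len(small_cohort)
    assert {"subject_id", "diagnosis", "abeta_status"} <= set(table.columns)
    for roi in rois:
        member_vals = small_cohort[[f"suvr_{l}" for l in roi.member_labels]]
        assert (table[roi.name] >= member_vals.min(axis=1) - 1e-9).all()
        assert (table[roi.name] <= member_vals.max(axis=1) + 1e-9).all()


def test_errors_named(atlas):
    with pytest.raises(ValueError, match="duplicate"):
        CompositeROIDefinition("bad", ("a", "a"))
    with pytest.raises(ValueError, match="no member"):
        CompositeROIDefinition("bad", ())
    roi = CompositeROIDefinition("bad", ("lh_entorhinal", "lh_nowhere"))
    with pytest.raises(ValueError, match="lh_nowhere"):
        roi.validate_against(atlas)
    frame = _frame({"a": 1.0}, {"a": 1.0})
    with pytest.raises(ValueError, match="suvr_b"):
        aggregate(frame, CompositeROIDefinition("bad", ("a", "b")))
    zero = _frame({"a": 1.0, "b": 2.0}, {"a": 0.0, "b": 0.0})
    with pytest.raises(ValueError, match="zero total volume"):
        aggregate(zero, CompositeROIDefinition("bad", ("a", "b")))
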