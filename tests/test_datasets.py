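"""Tidy I/O, validation, control normalization, aggregation."""

import math

import numpy as np
import pytest

import respcurve as rc


def _write(tmp_path, text, name="data.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_read_dr_csv(tmp_path):
    p = _write(tmp_path,
               "treatment,replicate,dose,response\n"
               "A,1,0,100\nA,1,1,80\nA,1,10,45\nA,1,100,8\n")
    ds = rc.read_tidy_table(p, "DR")
    assert len(ds.records) == 4
    assert len(ds.distinct_doses()) == 4
    assert ds.factor_names == ("treatment",)


def test_read_dr_missing_column(tmp_path):
    p = _write(tmp_path, "replicate,dose\n1,0\n")
    with pytest.raises(rc.SchemaError, match="response"):
        rc.read_tidy_table(p, "DR")


def test_read_dr_na_dose(tmp_path):
    p = _write(tmp_path, "replicate,dose,response\n1,0,10\n1,NA,20\n")
    with pytest.raises(rc.ValidationError, match="row 1"):
        rc.read_tidy_table(p, "DR")


def test_read_te_synthesizes_censored_remainder(tmp_path):
    p = _write(tmp_path,
               "replicate,time_before,time_after,count,total\n"
               "1,0,2,20,100\n1,2,4,30,100\n")
    ds = rc.read_tidy_table(p, "TE")
    cens = [r for r in ds.records if math.isinf(r.time_after)]
    assert len(cens) == 1
    assert cens[0].count == 50
    assert cens[0].time_before == 4.0
    total = sum(r.count for r in ds.records)
    assert total == 100


def test_te_overlapping_intervals_rejected():
    recs = [rc.TERecord(("a",), 1, 0.0, 3.0, 5),
            rc.TERecord(("a",), 1, 2.0, 4.0, 5)]
    with pytest.raises(rc.ValidationError, match="overlap"):
        rc.TimeToEventDataset(recs)


def test_te_counts_exceeding_total_rejected():
    recs = [rc.TERecord(("a",), 1, 0.0, 2.0, 80)]
    with pytest.raises(rc.ValidationError, match="group_total"):
        rc.TimeToEventDataset(recs, {(("a",), 1): 50})


def test_roundtrip_dr(tmp_path):
    recipe = rc.DRRecipe("LL.4", (2.0, 5.0, 95.0, 3.0), noise_sd=4.0, seed=5)
    ds = rc.simulate_dose_response(recipe)
    p = tmp_path / "rt.csv"
    rc.write_tidy_table(ds, p)
    back = rc.read_tidy_table(p, "DR", shape=ds.shape)
    np.testing.assert_allclose(back.doses, ds.doses)
    np.testing.assert_allclose(back.responses, ds.responses)


def test_roundtrip_te(tmp_path, te_toy):
    p = tmp_path / "rt.csv"
    rc.write_tidy_table(te_toy, p)
    back = rc.read_tidy_table(p, "TE")
    assert back.pooled_intervals() == te_toy.pooled_intervals()


def test_normalize_to_control():
    recs = [rc.DRRecord((), 1, 0.0, 2.0), rc.DRRecord((), 2, 0.0, 2.0),
            rc.DRRecord((), 1, 1.0, 1.0), rc.DRRecord((), 1, 10.0, 0.5)]
    ds = rc.DoseResponseDataset(recs)
    out = rc.normalize_to_control(ds)
    assert out.response_scale == "percent"
    vals = {r.dose: r.response for r in out.records if r.replicate == 1}
    assert vals[0.0] == pytest.approx(100.0)
    assert vals[1.0] == pytest.approx(50.0)
    assert vals[10.0] == pytest.approx(25.0)


def test_normalize_is_idempotent():
    recs = [rc.DRRecord((), 1, 0.0, 2.0), rc.DRRecord((), 1, 1.0, 1.0),
            rc.DRRecord((), 1, 10.0, 0.4)]
    once = rc.normalize_to_control(rc.DoseResponseDataset(recs))
    twice = rc.normalize_to_control(once)
    np.testing.assert_allclose(twice.responses, once.responses)


def test_normalize_without_control_errors():
    recs = [rc.DRRecord((), 1, 1.0, 1.0), rc.DRRecord((), 1, 10.0, 0.5)]
    with pytest.raises(rc.ValidationError, match="relative"):
        rc.normalize_to_control(rc.DoseResponseDataset(recs))


def test_aggregate_by_dose():
    recs = [rc.DRRecord((), 1, 1.0, 40.0), rc.DRRecord((), 2, 1.0, 60.0),
            rc.DRRecord((), 1, 10.0, 20.0)]
    agg = rc.aggregate_by_dose(rc.DoseResponseDataset(recs))
    row1 = agg[agg["dose"] == 1.0].iloc[0]
    assert row1["mean"] == pytest.approx(50.0)
    assert row1["sd"] == pytest.approx(np.sqrt(200.0))  # two-point SD
    assert row1["n"] == 2
    row2 = agg[agg["dose"] == 10.0].iloc[0]
    assert math.isnan(row2["sd"]) and row2["n"] == 1


def test_aggregate_empty():
    agg = rc.aggregate_by_dose(rc.DoseResponseDataset([]))
    assert agg.empty


def test_dataset_invariants():
    with pytest.raises(rc.ValidationError):
        rc.DoseResponseDataset([rc.DRRecord((), 1, -1.0, 5.0)])
    ds = rc.DoseResponseDataset([rc.DRRecord((), 1, 0.0, 1.0),
                                 rc.DRRecord((), 1, 1.0, 1.0)])
    with pytest.raises(rc.ValidationError, match="3 distinct"):
        ds.validate_for_fitting()


def test_config_validation():
    with pytest.raises(rc.ValidationError):
        rc.AnalysisConfig(ed_method="magic")
    cfg = rc.AnalysisConfig()
    assert cfg.resolve_absolute_level("percent") == 50.0
    assert cfg.resolve_absolute_level("proportion") == 0.5
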