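import numpy as np
import pandas as pd
import pytest

from jellydiet.curation import (
    CurationConfig,
    apply_reassignments,
    blank_correct,
    curate,
    drop_low_depth_samples,
    filter_regional,
    filter_taxonomy,
    remove_predator_reads,
    zero_low_cells,
)
from jellydiet.io import ContractError
from jellydiet.synthio import simulate_dataset

from conftest import feature_table, make_metadata, make_taxonomy, small_config


@pytest.fixture
def two_stomach_meta():
    return make_metadata(
        stomachs=[("S1", "Gadus morhua", "Gadiformes", "west"),
                  ("S2", "Argentina silus", "Argentiniformes", "east")],
        blanks=["B1"],
    )


# ---------------------------------------------------------------------------
# blank correction
# ---------------------------------------------------------------------------


def test_blank_share_strictly_greater(two_stomach_meta):
    """11/100 reads in blanks removes a feature; exactly 10/100 retains it."""
    t = feature_table("COI", {
        "over": [50, 39, 11],   # share 0.11
        "edge": [60, 30, 10],   # share 0.10 exactly
        "clean": [70, 30, 0],
    }, ["S1", "S2", "B1"])
    out, rec = blank_correct(t, two_stomach_meta, 0.10)
    assert rec.features_removed == ["over"]
    assert rec.reads_removed == 100
    assert set(out.feature_ids) == {"edge", "clean"}


def test_blank_rule_skipped_without_controls():
    meta = make_metadata([("S1", "Gadus morhua", "Gadiformes", "west")])
    t = feature_table("COI", {"f": [10]}, ["S1"])
    out, rec = blank_correct(t, meta, 0.10)
    assert not rec.applied and out.counts.equals(t.counts)


def test_blank_rule_optionally_pools_pcr_negatives():
    meta = make_metadata([("S1", "Gadus morhua", "Gadiformes", "west")],
                         blanks=["B1"], negatives=["N1"])
    t = feature_table("COI", {"f": [89, 6, 5]}, ["S1", "B1", "N1"])
    out, _ = blank_correct(t, meta, 0.10)                              # 6/100
    assert out.feature_ids == ["f"]
    out, _ = blank_correct(t, meta, 0.10, include_pcr_negatives=True)  # 11/100
    assert out.feature_ids == []


# ---------------------------------------------------------------------------
# taxonomy filters
# ---------------------------------------------------------------------------


def test_coi_identity_threshold_is_strict(two_stomach_meta):
    t = feature_table("COI", {"a": [10, 0, 0], "b": [10, 0, 0], "c": [10, 0, 0],
                              "d": [10, 0, 0]}, ["S1", "S2", "B1"])
    tax = make_taxonomy("COI", {
        "a": {"kingdom": "Animalia", "best_identity": 0.84},
        "b": {"kingdom": "Animalia", "best_identity": 0.85},
        "c": {"kingdom": "Animalia", "best_identity": 0.99, "is_terrestrial": True},
        "d": {"kingdom": "Fungi", "best_identity": 0.99, "excluded_group": True},
    })
    out, rec = filter_taxonomy(t, tax, CurationConfig(), "COI")
    assert rec.detail["reasons"] == {"a": "identity", "c": "terrestrial",
                                     "d": "excluded_group"}
    assert out.feature_ids == ["b"]


def test_18s_bootstrap_and_animalia(two_stomach_meta):
    t = feature_table("18S", {"a": [10, 0, 0], "b": [10, 0, 0], "c": [10, 0, 0]},
                      ["S1", "S2", "B1"])
    tax = make_taxonomy("18S", {
        "a": {"kingdom": "Animalia", "phylum_bootstrap": 69},
        "b": {"kingdom": "Animalia", "phylum_bootstrap": 70},  # equality retains
        "c": {"kingdom": "Chromista", "phylum_bootstrap": 99},
    })
    out, rec = filter_taxonomy(t, tax, CurationConfig(), "18S")
    assert rec.detail["reasons"] == {"a": "bootstrap", "c": "non_animalia"}
    assert out.feature_ids == ["b"]


def test_missing_confidence_score_is_error(two_stomach_meta):
    t = feature_table("COI", {"a": [10, 0, 0]}, ["S1", "S2", "B1"])
    tax = make_taxonomy("COI", {"a": {"kingdom": "Animalia"}})
    with pytest.raises(ContractError, match="best_identity"):
        filter_taxonomy(t, tax, CurationConfig(), "COI")


# ---------------------------------------------------------------------------
# cell zeroing
# ---------------------------------------------------------------------------


def test_zero_low_cells_boundary():
    t = feature_table("COI", {"f": [4, 5, 0]}, ["a", "b", "c"])
    out, rec = zero_low_cells(t, 5)
    assert out.counts.loc["f"].tolist() == [0, 5, 0]
    assert rec.cells_zeroed == 1 and rec.reads_removed == 4


def test_zero_low_cells_drops_emptied_feature():
    t = feature_table("COI", {"gone": [4, 4, 4], "kept": [9, 0, 0]},
                      ["a", "b", "c"])
    out, rec = zero_low_cells(t, 5)
    assert rec.features_removed == ["gone"]
    assert out.feature_ids == ["kept"]
    assert rec.reads_removed == 12


def test_zero_low_cells_all_zero_table_unchanged():
    t = feature_table("COI", {"f": [0, 0]}, ["a", "b"])
    out, rec = zero_low_cells(t, 5)
    assert out.counts.loc["f"].tolist() == [0, 0]
    assert rec.reads_removed == 0 and rec.cells_zeroed == 0


# ---------------------------------------------------------------------------
# predator removal
# ---------------------------------------------------------------------------


@pytest.fixture
def predator_setup():
    meta = make_metadata(
        stomachs=[("GM1", "Gadus morhua", "Gadiformes", "west"),
                  ("AS1", "Argentina silus", "Argentiniformes", "east")],
        blanks=["B1"],
    )
    t = feature_table("COI", {
        "gadus": [100, 50, 0],
        "prey": [200, 200, 0],
    }, ["GM1", "AS1", "B1"])
    tax = make_taxonomy("COI", {
        "gadus": {"kingdom": "Animalia", "order": "Gadiformes",
                  "species": "Gadus morhua", "best_identity": 0.98},
        "prey": {"kingdom": "Animalia", "order": "Euphausiacea",
                 "species": "Meganyctiphanes norvegica", "best_identity": 0.98},
    })
    return t, tax, meta


def test_species_mode_zeroes_only_own_stomachs(predator_setup):
    t, tax, meta = predator_setup
    out, rec = remove_predator_reads(t, tax, meta, "species")
    assert out.counts.loc["gadus"].tolist() == [0, 50, 0]  # kept in A. silus stomach
    assert rec.reads_removed == 100
    assert rec.detail["reads_removed_per_sample"] == {"GM1": 100}


def test_order_mode_zeroes_all_samples(predator_setup):
    t, tax, meta = predator_setup
    out, rec = remove_predator_reads(t, tax, meta, "order")
    assert "gadus" not in out.feature_ids  # emptied everywhere, dropped
    assert rec.reads_removed == 150
    assert out.counts.loc["prey"].tolist() == [200, 200, 0]


def test_order_mode_requires_order_list(predator_setup):
    t, tax, meta = predator_setup
    with pytest.raises(ContractError, match="order list"):
        remove_predator_reads(t, tax, meta, "order", predator_orders=())


def test_no_predator_features_unchanged(predator_setup):
    t, tax, meta = predator_setup
    sub = feature_table("COI", {"prey": [200, 200, 0]}, ["GM1", "AS1", "B1"])
    out, rec = remove_predator_reads(sub, tax, meta, "species")
    assert out.counts.equals(sub.counts) and rec.reads_removed == 0


# ---------------------------------------------------------------------------
# regional filter / depth filter
# ---------------------------------------------------------------------------


def test_filter_regional(two_stomach_meta):
    t = feature_table("COI", {"ok": [10, 0, 0], "alien": [5, 0, 0]},
                      ["S1", "S2", "B1"])
    tax = make_taxonomy("COI", {
        "ok": {"kingdom": "Animalia", "best_identity": 0.9},
        "alien": {"kingdom": "Animalia", "best_identity": 0.9,
                  "regionally_plausible": False},
    })
    out, rec = filter_regional(t, tax)
    assert rec.features_removed == ["alien"] and out.feature_ids == ["ok"]


def test_depth_filter_at_least_1000():
    t = feature_table("COI", {"f": [999, 1000, 1500]}, ["a", "b", "c"])
    out, rec = drop_low_depth_samples(t, 1000)
    assert rec.samples_dropped == ["a"] and rec.reads_removed == 999
    assert out.sample_ids == ["b", "c"]


# ---------------------------------------------------------------------------
# reassignments
# ---------------------------------------------------------------------------


def test_reassignments(predator_setup):
    _, tax, _ = predator_setup
    assert apply_reassignments(tax, {}) is tax
    out = apply_reassignments(tax, {"prey": {"kingdom": "Animalia",
                                             "family": "Euphausiidae"}})
    assert out.table.loc["prey", "family"] == "Euphausiidae"
    assert out.table.loc["prey", "species"] == ""  # demoted below family
    assert out.table.loc["gadus", "species"] == "Gadus morhua"
    with pytest.raises(ContractError, match="ghost"):
        apply_reassignments(tax, {"ghost": {"family": "X"}})


def test_reassignment_demotion_moves_metric_rank(predator_setup):
    """Demoting a species call to family removes it from species-level
    aggregation but keeps its reads at family level."""
    from jellydiet.dietmetrics import aggregate_rank
    t, tax, meta = predator_setup
    demoted = apply_reassignments(
        tax, {"prey": {"kingdom": "Animalia", "family": "Euphausiidae"}})
    sp_table, _ = aggregate_rank(t, demoted, "species")
    assert "Meganyctiphanes norvegica" not in sp_table.feature_ids
    assert "Euphausiidae (family)" in sp_table.feature_ids
    fam_table, _ = aggregate_rank(t, demoted, "family")
    assert int(fam_table.counts.loc["Euphausiidae"].sum()) == 400


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------


def test_cascade_matches_hand_computation(cascade_fixture):
    """The surviving (feature, sample) set and the per-rule audit counts of
    the full cascade equal a straight-line hand computation."""
    table, tax, meta = cascade_fixture
    curated, report = curate(table, tax, meta, CurationConfig())

    assert curated.sample_ids == ["S1", "S2", "S3"]
    assert set(curated.feature_ids) == {"cont_b", "prey1", "pred_gm", "prey2"}
    expected = pd.DataFrame(
        {"S1": [40, 600, 300, 400], "S2": [30, 0, 200, 970],
         "S3": [10, 500, 0, 400]},
        index=pd.Index(["cont_b", "prey1", "pred_gm", "prey2"], name="feature_id"),
    )
    # hand-derived: blank rule removes cont_a (share 0.11); identity filter
    # removes lowid; the 4-read cells (prey1@S2, cont_b@B2) are zeroed;
    # G. morhua reads leave its own stomachs S1+S2 only; S4 ends at 999 reads
    # and is dropped together with both blanks.
    expected.loc["pred_gm"] = [0, 0, 100]
    pd.testing.assert_frame_equal(curated.counts.loc[expected.index], expected)

    by_rule = {r.rule: r for r in report.rules}
    assert by_rule["blank_correct"].features_removed == ["cont_a"]
    assert by_rule["blank_correct"].reads_removed == 100
    assert by_rule["filter_taxonomy"].reads_removed == 50
    assert by_rule["zero_low_cells"].cells_zeroed == 2
    assert by_rule["zero_low_cells"].reads_removed == 8
    assert by_rule["remove_predator_reads"].reads_removed == 500
    assert by_rule["drop_low_depth_samples"].samples_dropped == ["S4", "B1", "B2"]
    assert by_rule["drop_low_depth_samples"].reads_removed == 1005
    assert report.reads_in == 4713 and report.reads_out == 3050
    report.check_conservation()


@pytest.mark.parametrize("marker", ["COI", "18S"])
def test_cascade_conservation_and_idempotence_on_synthetic(marker):
    ds = simulate_dataset(small_config(seed=21))
    table, tax = ds.tables[marker], ds.taxonomies[marker]
    curated, report = curate(table, tax, ds.metadata)
    report.check_conservation()
    removed = sum(r.reads_removed for r in report.rules)
    assert report.reads_in - removed == report.reads_out
    again, report2 = curate(curated, tax, ds.metadata)
    assert again.counts.equals(curated.counts)
    assert report2.reads_in == report2.reads_out


def test_cascade_monotone_total_reads():
    ds = simulate_dataset(small_config(seed=30))
    _, report = curate(ds.tables["COI"], ds.taxonomies["COI"], ds.metadata)
    running = report.reads_in
    for rule in report.rules:
        assert rule.reads_removed >= 0
        running -= rule.reads_removed
        assert running >= 0
    assert running == report.reads_out


def test_blank_rule_recovers_seeded_contaminants():
    """Seeded contaminants (heavy blank loads) are exactly the features whose
    blank share exceeds the threshold; prey features are untouched."""
    ds = simulate_dataset(small_config(seed=8, n_contaminants=3,
                                       contaminant_blank_load=300.0,
                                       contaminant_sample_load=1.0,
                                       tag_switch_rate=0.0))
    t = ds.tables["COI"]
    _, rec = blank_correct(t, ds.metadata, 0.10)
    assert set(rec.features_removed) == set(ds.truth.contaminant_ids)


def test_empty_dataset_empty_report():
    t = feature_table("COI", {}, ["S1"])
    meta = make_metadata([("S1", "Gadus morhua", "Gadiformes", "west")])
    tax = make_taxonomy("COI", {})
    curated, report = curate(t, tax, meta)
    assert curated.feature_ids == []
    assert report.reads_in == report.reads_out == 0
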