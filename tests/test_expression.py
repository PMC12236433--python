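import numpy as np
import pandas as pd
import pytest

from eddyomics import (
    AbsoluteAbundanceTable,
    AbundanceTable,
    ExpressionDifferentialModel,
    ExpressionRecord,
    RunConfig,
    SampleMetadata,
    ValidationError,
    summarize_by_category,
    within_taxon_normalize,
)


def _diel(n=4):
    ids = [f"C{i}" for i in range(n)] + [f"A{i}" for i in range(n)]
    return SampleMetadata(pd.DataFrame(dict(
        sample_id=ids, eddy=["cyclone"] * n + ["anticyclone"] * n,
        volume_ml=[1500.0] * 2 * n)))


def test_within_taxon_fractions_arithmetic():
    t = AbundanceTable(pd.DataFrame({"s1": [20.0, 60.0, 5.0]}, index=["t1", "t2", "u1"]),
                       "transcript_per_ml")
    out, excluded = within_taxon_normalize(t, {"t1": "T", "t2": "T", "u1": "U"})
    assert out.values.at["t1", "s1"] == pytest.approx(0.25)
    assert out.values.at["u1", "s1"] == 1.0  # single-transcript taxon
    assert excluded == {}


def test_within_taxon_fractions_sum_to_one_per_taxon():
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(rng.uniform(0.1, 10, size=(12, 5)),
                        index=[f"t{i}" for i in range(12)],
                        columns=[f"s{j}" for j in range(5)])
    taxon_map = {f"t{i}": f"T{i % 3}" for i in range(12)}
    out, _ = within_taxon_normalize(AbundanceTable(vals, "transcript_per_ml"), taxon_map)
    for taxon in ("T0", "T1", "T2"):
        members = [t for t, x in taxon_map.items() if x == taxon]
        np.testing.assert_allclose(out.values.loc[members].sum(axis=0), 1.0, atol=1e-9)


def test_within_taxon_zero_total_sample_excluded_and_reported():
    vals = pd.DataFrame({"s1": [2.0, 2.0], "s2": [0.0, 0.0]}, index=["t1", "t2"])
    out, excluded = within_taxon_normalize(AbundanceTable(vals, "transcript_per_ml"),
                                           {"t1": "T", "t2": "T"})
    assert excluded == {"T": ["s2"]}
    assert (out.values["s2"] == 0.0).all()


def test_below_detection_entries_zeroed_before_fractions():
    vals = pd.DataFrame({"s1": [6.0, 2.0]}, index=["t1", "t2"])
    flags = pd.DataFrame({"s1": [False, True]}, index=["t1", "t2"])
    table = AbsoluteAbundanceTable(vals, "transcript_per_ml", below_detection=flags)
    out, _ = within_taxon_normalize(table, {"t1": "T", "t2": "T"})
    assert out.values.at["t1", "s1"] == 1.0
    assert out.values.at["t2", "s1"] == 0.0


def _annotated_table(meta, values, taxa):
    ann = pd.DataFrame({"taxon": taxa}, index=values.index)
    return AbundanceTable(values, "transcript_per_ml", ann)


def test_identical_groups_yield_no_sides():
    meta = _diel()
    vals = pd.DataFrame(
        np.tile([[0.1, 0.2, 0.15, 0.12]], (3, 2)).reshape(3, 8),
        index=["t1", "t2", "t3"], columns=meta.sample_ids)
    table = _annotated_table(meta, vals, ["T"] * 3)
    res = ExpressionDifferentialModel(table, meta).fit()
    assert all(r.side == "none" for r in res.records)


def test_label_swap_negates_every_log2fc(per_ml, diel_meta, dataset):
    taxa = sorted({t for t, fc in dataset.truth.taxon_fc.items() if fc < 1})[:2]
    res = ExpressionDifferentialModel(per_ml, diel_meta, taxa=taxa).fit()
    swapped = diel_meta.frame.copy()
    swapped["eddy"] = swapped["eddy"].map({"cyclone": "anticyclone", "anticyclone": "cyclone"})
    res_swap = ExpressionDifferentialModel(
        per_ml, SampleMetadata(swapped.reset_index()), taxa=taxa).fit()
    a = {r.transcript_id: r for r in res.records}
    for r in res_swap.records:
        assert r.log2_fold_change == pytest.approx(-a[r.transcript_id].log2_fold_change, abs=1e-12)
        assert r.p_value == pytest.approx(a[r.transcript_id].p_value, rel=1e-9)


def test_recovery_of_planted_de_transcripts(dataset, per_ml, diel_meta):
    focal = sorted({t for t in dataset.truth.de_transcripts})[0].split("|")[0]
    res = ExpressionDifferentialModel(per_ml, diel_meta, taxa=[focal]).fit()
    rec = {r.transcript_id: r for r in res.records}
    hits = sum(
        1 for t, l2 in dataset.truth.de_transcripts.items()
        if rec[t].side == ("anticyclone" if l2 > 0 else "cyclone"))
    false_sides = sum(1 for r in res.records
                      if r.side != "none" and r.transcript_id not in dataset.truth.de_transcripts)
    assert hits >= 4
    assert false_sides <= 2


def _rec(tid, eggnog, cog, l2, side):
    return ExpressionRecord(tid, "T", eggnog, "K00001", cog, l2, 1e-6, 1e-4, side)


def test_both_sides_eggnog_rule_drops_ambiguous_annotations():
    records = [
        _rec("t1", "E1", "J", 3.0, "anticyclone"),
        _rec("t2", "E1", "J", -3.0, "cyclone"),
        _rec("t3", "E2", "J", -4.0, "cyclone"),
    ]
    out = summarize_by_category(records, "cog")
    assert len(out) == 1
    assert out[0].n_cyclone == 1 and out[0].n_anticyclone == 0


def test_both_sides_exclusion_is_idempotent():
    records = [
        _rec("t1", "E1", "J", 3.0, "anticyclone"),
        _rec("t2", "E1", "J", -3.0, "cyclone"),
        _rec("t3", "E2", "P", -4.0, "cyclone"),
        _rec("t4", "E3", "P", -2.5, "cyclone"),
    ]
    once = summarize_by_category(records, "cog")
    # rebuild records from the survivors and summarize again
    survivors = [r for r in records if r.eggnog_id != "E1"]
    twice = summarize_by_category(survivors, "cog")
    assert [(s.category_id, s.n_cyclone, s.n_anticyclone) for s in once] == [
        (s.category_id, s.n_cyclone, s.n_anticyclone) for s in twice]


def test_cog_counting_matches_hand_tally():
    records = [_rec(f"tj{i}", f"EJ{i}", "J", -3.0, "cyclone") for i in range(4)]
    records += [_rec(f"tp{i}", f"EP{i}", "P", 3.0, "anticyclone") for i in range(2)]
    out = {s.category_id: s for s in summarize_by_category(records, "cog")}
    assert (out["J"].n_cyclone, out["J"].n_anticyclone) == (4, 0)
    assert (out["P"].n_cyclone, out["P"].n_anticyclone) == (0, 2)


def test_category_counts_conserved_for_single_letter_annotations():
    records = [_rec(f"t{i}", f"E{i}", "JKLMNP"[i], (-1) ** i * 3.0,
                    "cyclone" if i % 2 == 0 else "anticyclone") for i in range(6)]
    out = summarize_by_category(records, "cog")
    assert sum(s.n_cyclone + s.n_anticyclone for s in out) == 6


def test_pathway_retention_needs_more_than_two_transcripts():
    pathways = pd.Series({
        "t1": "mapA", "t2": "mapA", "t3": "mapB", "t4": "mapB", "t5": "mapB"})
    records = [_rec(t, f"E{t}", "J", -3.0, "cyclone") for t in pathways.index]
    out = summarize_by_category(records, "pathway", pathway_annotations=pathways)
    assert [s.category_id for s in out] == ["mapB"]  # 2 members dropped, 3 kept


def test_pathway_merge_map_applied_before_retention():
    pathways = pd.Series({"t1": "mapA", "t2": "mapB", "t3": "mapB"})
    records = [_rec(t, f"E{t}", "J", -3.0, "cyclone") for t in pathways.index]
    none_kept = summarize_by_category(records, "pathway", pathway_annotations=pathways)
    assert none_kept == []
    merged = summarize_by_category(
        records, "pathway", pathway_annotations=pathways, merge_map={"mapA": "mapB"})
    assert len(merged) == 1 and merged[0].n_cyclone == 3


def test_unknown_summary_mode_rejected():
    with pytest.raises(ValidationError, match="mode"):
        summarize_by_category([], "kegg")


def test_null_side_rate_below_one_percent():
    """Without true differential expression, fewer than 1% of transcripts
    acquire a side (q < 0.05 and |log2FC| > 2) at n = 18/18."""
    from eddyomics import ErccCalibrationModel
    from eddyomics.simulate import (GroundTruth, diel_ids, load_ercc_reference,
                                    simulate_design, simulate_transcriptomes)
    meta = simulate_design(29)
    diel = meta.subset(diel_ids(meta))
    truth = GroundTruth(taxon_fc={"T": 1.0})
    counts, spikes = simulate_transcriptomes(
        diel, truth, load_ercc_reference(), seed=29, transcripts_per_taxon=1000)
    cal = ErccCalibrationModel(spikes, load_ercc_reference()).fit()
    per_ml = cal.normalize(counts, diel)
    res = ExpressionDifferentialModel(per_ml, diel).fit()
    assert len(res.sided()) / len(res.records) < 0.01


def test_sides_match_thresholds(dataset, per_ml, diel_meta):
    focal = sorted({t for t in dataset.truth.de_transcripts})[0].split("|")[0]
    res = ExpressionDifferentialModel(per_ml, diel_meta, taxa=[focal]).fit()
    thr = res.model.config.thresholds
    for r in res.records:
        sided = r.q_value < thr.q_max and abs(r.log2_fold_change) > thr.log2fc_flag
        assert (r.side != "none") == sided
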