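import math

import numpy as np
import pytest

from toxconcord.concordance import (
    ConcordanceResult,
    ContingencyTable,
    EmptyStratumError,
    MetricSet,
    Stratum,
    bonferroni_within_soc,
    build_contingency,
    compute_metrics,
    run_identical_concordance,
)
from toxconcord.records import validate_pt_soc_unique

from conftest import frame, rec


def T(tp, fp, fn, tn):
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


# --- contingency construction ------------------------------------------------


def test_four_cell_classification(four_drug_frame, gi_soc):
    t = build_contingency(
        four_drug_frame, set("ABCD"), Stratum(species_sel="dog"), "Vomiting", "Vomiting"
    )
    assert (t.tp, t.fp, t.fn, t.tn) == (1, 1, 1, 1)
    assert t.n_universe == 4


def test_all_species_union_rule(gi_soc):
    rows = [
        rec("A", "human", gi_soc, "Vomiting"),
        rec("A", "rat", gi_soc, "Vomiting"),  # rat-only preclinical finding
        rec("B", "human", gi_soc, "Vomiting"),
        rec("B", "dog", gi_soc, "Diarrhoea"),
    ]
    f = frame(*rows)
    t_all = build_contingency(f, {"A", "B"}, Stratum(species_sel="all"), "Vomiting", "Vomiting")
    assert (t_all.tp, t_all.fn) == (1, 1)  # A counted preclinical-present
    t_dog = build_contingency(f, {"A", "B"}, Stratum(species_sel="dog"), "Vomiting", "Vomiting")
    # in the dog stratum only B has a dog record; A leaves the universe
    assert t_dog.n_universe == 1 and t_dog.tp == 0


def test_empty_stratum_universe_is_an_error(gi_soc):
    f = frame(rec("A", "human", gi_soc, "Vomiting"), rec("A", "rat", gi_soc, "Vomiting"))
    with pytest.raises(EmptyStratumError):
        build_contingency(f, {"A"}, Stratum(species_sel="dog"), "Vomiting", "Vomiting")


def test_modality_slice_excludes_unknown_modality(four_drug_frame):
    modalities = {"A": "SM", "B": "SM", "C": "unknown", "D": "Bio"}
    t = build_contingency(
        four_drug_frame,
        set("ABCD"),
        Stratum(species_sel="dog", modality_sel="SM"),
        "Vomiting",
        "Vomiting",
        modalities=modalities,
    )
    assert t.n_universe == 2  # A and B only; C (unknown) and D (Bio) out


def test_cells_always_sum_to_universe(four_drug_frame):
    rng = np.random.default_rng(0)
    for _ in range(20):
        pts = rng.choice(["Vomiting", "Nope"], size=2)
        t = build_contingency(
            four_drug_frame, set("ABCD"), Stratum(species_sel="dog"), pts[0], pts[1]
        )
        assert t.tp + t.fp + t.fn + t.tn == t.n_universe == 4


# --- metrics ----------------------------------------------------------------


def test_metric_reference_values():
    m = compute_metrics(T(8, 2, 4, 86))
    assert m.sensitivity == pytest.approx(8 / 12)
    assert m.specificity == pytest.approx(86 / 88)
    assert m.lr_plus == pytest.approx(29.333, rel=1e-3)
    assert m.ilr_minus == pytest.approx(2.932, rel=1e-3)
    assert m.ppv == pytest.approx(0.800)
    assert m.npv == pytest.approx(86 / 90)
    assert not m.low_tp_flag


def test_zero_fp_with_signal_gives_infinite_lr_plus():
    m = compute_metrics(T(127, 0, 30, 100))
    assert m.lr_plus == math.inf


def test_no_information_table_gives_unit_ratios():
    m = compute_metrics(T(5, 5, 5, 5))
    assert m.lr_plus == 1.0 and m.ilr_minus == 1.0


def test_undefined_metrics_are_flagged_not_zeroed():
    m = compute_metrics(T(0, 0, 3, 7))
    assert math.isnan(m.ppv) and "ppv" in m.undefined
    m2 = compute_metrics(T(0, 3, 0, 7))  # no clinically positive drug
    assert math.isnan(m2.sensitivity) and "sensitivity" in m2.undefined
    assert "lr_plus" in m2.undefined


def test_low_tp_flag_threshold_is_configurable():
    assert compute_metrics(T(4, 1, 1, 4)).low_tp_flag
    assert not compute_metrics(T(4, 1, 1, 4), low_tp=3).low_tp_flag


def test_odds_identity_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(300):
        tp, fp, fn, tn = (int(v) + 1 for v in rng.integers(0, 50, size=4))
        m = compute_metrics(T(tp, fp, fn, tn))
        prev = (tp + fn) / (tp + fp + fn + tn)
        post_odds = m.ppv / (1 - m.ppv)
        assert post_odds == pytest.approx(prev / (1 - prev) * m.lr_plus, rel=1e-9)


def test_lr_plus_monotone_in_tp_fn_exchange():
    rng = np.random.default_rng(1)
    for _ in range(200):
        tp, fp, tn = (int(v) for v in rng.integers(1, 40, size=3))
        fn = int(rng.integers(1, 40))
        a = compute_metrics(T(tp, fp, fn, tn)).lr_plus
        b = compute_metrics(T(tp + 1, fp, fn - 1, tn)).lr_plus
        assert b >= a


# --- Bonferroni families -----------------------------------------------------


def _result(p_raw, soc="S", stratum=None, mode="identical"):
    return ConcordanceResult(
        stratum=stratum or Stratum(),
        preclin_pt="p",
        clin_pt="p",
        soc=soc,
        mode=mode,
        table=T(1, 1, 1, 1),
        p_raw=p_raw,
        metrics=MetricSet(),
    )


def test_bonferroni_multiplies_by_family_size_and_thresholds():
    results = [_result(0.004)] + [_result(0.5) for _ in range(9)]
    bonferroni_within_soc(results)
    assert results[0].p_adj == pytest.approx(0.04) and results[0].significant


def test_bonferroni_clamps_at_one():
    results = [_result(0.3) for _ in range(5)]
    bonferroni_within_soc(results)
    assert all(r.p_adj == 1.0 for r in results)


def test_single_test_family_keeps_raw_p():
    results = [_result(0.049)]
    bonferroni_within_soc(results)
    assert results[0].p_adj == pytest.approx(0.049) and results[0].significant


def test_families_split_by_soc_stratum_and_mode():
    results = [
        _result(0.01, soc="S1"),
        _result(0.01, soc="S2"),
        _result(0.01, soc="S1", mode="cross_term"),
        _result(0.01, soc="S1", stratum=Stratum(species_sel="rat")),
    ]
    bonferroni_within_soc(results)
    assert all(r.family_size == 1 for r in results)


# --- identical-term runner ---------------------------------------------------


def _three_pt_frame(gi_soc):
    rows = []
    for d in "ABCDEF":
        rows.append(rec(d, "human", "Investigations", "Clinical finding present"))
        rows.append(rec(d, "dog", "Investigations", "Animal finding present"))
    for pt in ("Vomiting", "Diarrhoea", "Gastric ulcer"):
        rows.append(rec("A", "human", gi_soc, pt))
        rows.append(rec("A", "dog", gi_soc, pt))
        rows.append(rec("B", "dog", gi_soc, pt))
    rows.append(rec("C", "human", gi_soc, "Nausea"))  # clinical-only PT
    return frame(*rows)


def test_identical_run_tests_every_dual_observed_pt(gi_soc):
    f = _three_pt_frame(gi_soc)
    res = run_identical_concordance(
        f, set("ABCDEF"), [Stratum(species_sel="dog")], validate_pt_soc_unique(f)
    )
    pts = {r.preclin_pt for r in res}
    assert {"Vomiting", "Diarrhoea", "Gastric ulcer"} <= pts
    assert "Nausea" not in pts  # observed clinically only
    assert all(r.p_adj >= r.p_raw - 1e-15 for r in res)
    assert all(r.identical_term for r in res)
    # deterministic sort order
    keys = [(r.stratum.label(), r.soc, r.preclin_pt) for r in res]
    assert keys == sorted(keys)


def test_identical_run_recovers_planted_signal(planted_cohort):
    cohort, prof = planted_cohort
    from toxconcord.prepare import deduplicate, filter_records, restrict_to_dual_reported

    records, _ = filter_records(cohort.ae_records)
    records = deduplicate(records)
    records, universe = restrict_to_dual_reported(records)
    res = run_identical_concordance(
        records, universe, [Stratum(species_sel="rat")], validate_pt_soc_unique(records)
    )
    target = [r for r in res if r.preclin_pt == prof.pt]
    assert len(target) == 1
    r = target[0]
    assert r.significant
    assert 9.0 <= r.metrics.lr_plus <= 15.0  # planted LR+ = 12
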