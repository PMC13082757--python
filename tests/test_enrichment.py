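import math
from fractions import Fraction

import numpy as np
import pytest

from toxconcord.concordance import Stratum
from toxconcord.enrichment import (
    annotate_tp_drugs,
    bh_adjust,
    hypergeometric_enrichment,
    hypergeometric_tail_p,
)
from toxconcord.records import TargetAnnotation, TargetRelation

from conftest import frame, rec


def exact_tail(overlap, background, set_size, query):
    """Independent oracle: exact rational upper-tail sum."""
    total = math.comb(background, query)
    acc = Fraction(0)
    for k in range(overlap, min(set_size, query) + 1):
        acc += Fraction(math.comb(set_size, k) * math.comb(background - set_size, query - k), total)
    return float(acc)


def test_hypergeometric_reference_value():
    # background 50, set 10, query 5, overlap 4: (8400 + 252) / 2,118,760
    assert hypergeometric_tail_p(4, 50, 10, 5) == pytest.approx(
        (8400 + 252) / math.comb(50, 5), rel=1e-12
    )


def test_zero_overlap_gives_p_one():
    assert hypergeometric_tail_p(0, 50, 10, 5) == 1.0


def test_tail_matches_exact_enumeration_on_small_backgrounds():
    rng = np.random.default_rng(0)
    for _ in range(200):
        bg = int(rng.integers(5, 61))
        set_size = int(rng.integers(1, bg + 1))
        query = int(rng.integers(1, bg + 1))
        overlap = int(rng.integers(0, min(set_size, query) + 1))
        got = hypergeometric_tail_p(overlap, bg, set_size, query)
        assert got == pytest.approx(exact_tail(overlap, bg, set_size, query), abs=1e-12)


def bh_oracle(ps):
    """Independent step-up: adj_i = min over j >= i (sorted) of p_j * m / j."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * m / rank)
        adj[i] = running
    return adj


@pytest.mark.parametrize(
    "ps,expected",
    [
        ([0.01], [0.01]),
        ([0.05, 0.05, 0.05], [0.05, 0.05, 0.05]),
        ([0.001, 0.01, 0.04], [0.003, 0.015, 0.04]),
    ],
)
def test_bh_reference_vectors(ps, expected):
    assert bh_adjust(ps) == pytest.approx(expected)


def test_bh_matches_independent_step_up_on_random_vectors():
    rng = np.random.default_rng(1)
    for _ in range(100):
        ps = list(rng.random(int(rng.integers(1, 40))))
        assert bh_adjust(ps) == pytest.approx(bh_oracle(ps), abs=1e-12)


def test_bh_output_dominates_input_and_caps_at_one():
    rng = np.random.default_rng(2)
    ps = list(rng.random(50))
    adj = bh_adjust(ps)
    assert all(0 <= a <= 1 and a >= p - 1e-15 for p, a in zip(ps, adj))


def test_bh_rejects_out_of_range_values():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_enrichment_requires_query_within_background():
    with pytest.raises(ValueError, match="subset"):
        hypergeometric_enrichment({"X"}, {"s": {"X"}}, {"Y"})
    with pytest.raises(ValueError, match="background"):
        hypergeometric_enrichment(set(), {"s": {"X"}}, set())


def test_enrichment_intersects_sets_with_background():
    res = hypergeometric_enrichment(
        {"A"}, {"s": {"A", "Z"}}, {"A", "B", "C"}
    )
    assert res[0].set_size == 1  # Z is outside the background


def test_annotate_tp_drugs_unions_targets(four_drug_frame, gi_soc):
    targets = [
        TargetAnnotation(drug_id="A", target_symbol="T1", relation=TargetRelation.on_target),
        TargetAnnotation(drug_id="A", target_symbol="T2", relation=TargetRelation.off_target),
        TargetAnnotation(drug_id="B", target_symbol="T3", relation=TargetRelation.on_target),
    ]
    from toxconcord.concordance import build_contingency
    from toxconcord.stats import fisher_exact_two_tailed
    from toxconcord.concordance import ConcordanceResult, MetricSet

    stratum = Stratum(species_sel="dog")
    table = build_contingency(four_drug_frame, set("ABCD"), stratum, "Vomiting", "Vomiting")
    result = ConcordanceResult(
        stratum=stratum,
        preclin_pt="Vomiting",
        clin_pt="Vomiting",
        soc=gi_soc,
        mode="identical",
        table=table,
        p_raw=1.0,
        metrics=MetricSet(),
    )
    tp_drugs, query = annotate_tp_drugs(result, four_drug_frame, set("ABCD"), targets)
    assert tp_drugs == {"A"}  # only A has the PT on both sides
    assert query == {"T1", "T2"}
    _, on_only = annotate_tp_drugs(
        result, four_drug_frame, set("ABCD"), targets, relation=TargetRelation.on_target
    )
    assert on_only == {"T1"}


def test_empty_tp_set_gives_empty_query_not_error(four_drug_frame, gi_soc):
    from toxconcord.concordance import ConcordanceResult, ContingencyTable, MetricSet

    result = ConcordanceResult(
        stratum=Stratum(species_sel="dog"),
        preclin_pt="Nope",
        clin_pt="Nope",
        soc=gi_soc,
        mode="identical",
        table=ContingencyTable(tp=0, fp=0, fn=0, tn=4),
        p_raw=1.0,
        metrics=MetricSet(),
    )
    tp_drugs, query = annotate_tp_drugs(result, four_drug_frame, set("ABCD"), [])
    assert tp_drugs == set() and query == set()


def test_planted_causal_target_reaches_the_query_set(planted_cohort):
    """Generator truth propagation: the targets linked to a planted AE
    appear in the query set built from that AE's true-positive drugs."""
    cohort, prof = planted_cohort
    from toxconcord.concordance import (
        ConcordanceResult,
        MetricSet,
        build_contingency,
    )
    from toxconcord.prepare import deduplicate, filter_records, restrict_to_dual_reported

    records, _ = filter_records(cohort.ae_records)
    records = deduplicate(records)
    records, universe = restrict_to_dual_reported(records)
    stratum = Stratum(species_sel="rat")
    table = build_contingency(records, universe, stratum, prof.pt, prof.pt)
    result = ConcordanceResult(
        stratum=stratum,
        preclin_pt=prof.pt,
        clin_pt=prof.pt,
        soc=prof.soc,
        mode="identical",
        table=table,
        p_raw=0.0,
        metrics=MetricSet(),
    )
    targets = [
        TargetAnnotation(
            drug_id=r.drug_id, target_symbol=r.target_symbol, relation=TargetRelation(r.relation)
        )
        for r in cohort.targets.itertuples(index=False)
    ]
    _, query = annotate_tp_drugs(result, records, universe, targets)
    assert prof.linked_targets <= query


def test_causal_sets_rank_below_random_sets_in_p(planted_cohort):
    """Across resampled random sets of equal size, the planted causal
    set's p is smaller than the median random-set p."""
    cohort, prof = planted_cohort
    rng = np.random.default_rng(3)
    all_targets = set(cohort.targets["target_symbol"])
    tp_like = set(
        cohort.targets.loc[cohort.targets["relation"] == "on_target", "target_symbol"]
    )
    query = tp_like | set(
        rng.choice(sorted(all_targets - tp_like), size=60, replace=False)
    )
    causal = set(prof.linked_targets)
    p_causal = hypergeometric_enrichment(query, {"causal": causal}, all_targets)[0].p_raw
    randoms = []
    pool = sorted(all_targets)
    for _ in range(50):
        s = set(rng.choice(pool, size=len(causal), replace=False))
        randoms.append(hypergeometric_enrichment(query, {"r": s}, all_targets)[0].p_raw)
    assert p_causal < np.median(randoms)
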