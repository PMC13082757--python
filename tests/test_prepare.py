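import random

import pytest

from toxconcord.prepare import (
    IDENTITY_TIERS,
    canonical_id_map,
    deduplicate,
    filter_records,
    first_matching_tier,
    resolve_drug_identity,
    restrict_to_dual_reported,
)
from toxconcord.records import DrugEntity

from conftest import frame, rec


# --- filtering ---------------------------------------------------------------


def test_filter_removes_post_marketing_and_refuted():
    rows = [rec(f"d{i}", "dog", "S", "P") for i in range(5)]
    rows += [rec(f"p{i}", "dog", "S", "P", post_marketing=True) for i in range(3)]
    rows += [rec(f"r{i}", "dog", "S", "P", refuted=True) for i in range(2)]
    kept, report = filter_records(frame(*rows))
    assert len(kept) == 5
    assert (report.post_marketing, report.refuted, report.both) == (3, 2, 0)


def test_filter_counts_doubly_flagged_record_under_both_reasons():
    rows = [
        rec("a", "dog", "S", "P"),
        rec("b", "dog", "S", "P"),
        rec("c", "dog", "S", "P"),
        rec("x", "dog", "S", "P", post_marketing=True, refuted=True),
    ]
    kept, report = filter_records(frame(*rows))
    assert len(kept) == 3
    assert (report.post_marketing, report.refuted, report.both) == (1, 1, 1)


def test_filter_on_empty_input_is_identity():
    kept, report = filter_records(frame())
    assert kept.empty and report.kept == 0


# --- deduplication -----------------------------------------------------------


def test_dedup_key_is_drug_species_pt():
    rows = [
        rec("d", "dog", "S", "Vomiting", source="pp"),
        rec("d", "dog", "S", "Vomiting", source="offx"),
        rec("d", "rat", "S", "Vomiting"),
    ]
    out = deduplicate(frame(*rows))
    assert len(out) == 2
    # first instance in input order is retained
    assert out.loc[out["species"] == "dog", "source"].item() == "pp"


def test_dedup_collapses_all_identical_keys_to_one():
    rows = [rec("d", "dog", "S", "P", source=str(i)) for i in range(6)]
    out = deduplicate(frame(*rows))
    assert len(out) == 1 and out["source"].item() == "0"


# --- dual-reporting restriction ----------------------------------------------


def test_dual_reporting_drops_single_sided_drugs():
    rows = [
        rec("A", "human", "S", "P1"),
        rec("A", "rat", "S", "P2"),
        rec("B", "human", "S", "P1"),
        rec("C", "mouse", "S", "P2"),
    ]
    out, universe = restrict_to_dual_reported(frame(*rows))
    assert universe == {"A"}
    assert set(out["drug_id"]) == {"A"}


def test_dual_reporting_keeps_fully_dual_input_unchanged():
    rows = [rec("A", "human", "S", "P1"), rec("A", "dog", "S", "P1")]
    f = frame(*rows)
    out, universe = restrict_to_dual_reported(f)
    assert universe == {"A"} and len(out) == len(f)


# --- idempotence / commutation properties ------------------------------------


def _random_frame(seed, flags_constant_per_key=True):
    rng = random.Random(seed)
    rows = []
    keyflags = {}
    for _ in range(rng.randint(5, 60)):
        key = (
            f"d{rng.randint(0, 8)}",
            rng.choice(["human", "dog", "rat"]),
            f"P{rng.randint(0, 5)}",
        )
        if flags_constant_per_key:
            pm, rf = keyflags.setdefault(
                key, (rng.random() < 0.2, rng.random() < 0.2)
            )
        else:
            pm, rf = rng.random() < 0.2, rng.random() < 0.2
        rows.append(rec(key[0], key[1], "S", key[2], post_marketing=pm, refuted=rf))
    return frame(*rows)


@pytest.mark.parametrize("seed", range(10))
def test_prepare_steps_are_idempotent(seed):
    f = _random_frame(seed)
    once, _ = filter_records(f)
    twice, _ = filter_records(once)
    assert once.equals(twice)
    d1 = deduplicate(f)
    assert d1.equals(deduplicate(d1))
    r1, u1 = restrict_to_dual_reported(d1)
    r2, u2 = restrict_to_dual_reported(r1)
    assert r1.equals(r2) and u1 == u2


@pytest.mark.parametrize("seed", range(10))
def test_filter_and_dedup_commute_when_flags_agree_within_key(seed):
    """Exclusion flags are properties of the association, so duplicate
    records of one drug-species-AE key share them; under that condition
    the filter and the deduplication can run in either order."""
    f = _random_frame(seed, flags_constant_per_key=True)
    a = deduplicate(filter_records(f)[0])
    b = filter_records(deduplicate(f))[0]
    assert sorted(map(tuple, a.itertuples(index=False))) == sorted(
        map(tuple, b.itertuples(index=False))
    )


# --- identity resolution -----------------------------------------------------


def E(drug_id, name, synonyms=(), cid=None, cas=None, smiles=None):
    return DrugEntity(
        drug_id=drug_id, main_name=name, synonyms=set(synonyms), cid=cid, cas=cas, smiles=smiles
    )


def test_name_match_is_case_insensitive():
    m = resolve_drug_identity([E("L1", "aspirin")], [E("R1", "Aspirin")])
    assert m[0].tier == "name" and m[0].canonical_id == "L1"


def test_cas_tier_wins_when_names_and_synonyms_differ():
    left = [E("L1", "drugA", cas="50-78-2")]
    right = [E("R1", "acetylsalicylic acid", cas="50-78-2")]
    m = resolve_drug_identity(left, right)
    assert m[0].tier == "cas"


def test_synonym_tier_stops_cascade_before_cid():
    left = [E("L1", "x1", synonyms={"compound-7"})]
    right = [E("R1", "y9", synonyms={"compound-7"}, cid="999")]
    m = resolve_drug_identity(left, right)
    assert m[0].tier == "synonym"


def test_unmatched_right_entity_keeps_its_own_id():
    m = resolve_drug_identity([E("L1", "a")], [E("R1", "b")])
    assert m[0].tier == "unmatched" and m[0].canonical_id == "R1"
    assert canonical_id_map(m) == {"R1": "R1"}


def test_duplicate_drug_id_within_one_side_is_an_error():
    with pytest.raises(ValueError, match="duplicate"):
        resolve_drug_identity([E("L1", "a"), E("L1", "b")], [E("R1", "c")])


def _random_entities(rng, prefix, n):
    names = [f"name{rng.randint(0, 15)}" for _ in range(n)]
    ents = []
    for i, nm in enumerate(names):
        ents.append(
            DrugEntity(
                drug_id=f"{prefix}{i}",
                main_name=nm,
                synonyms={f"syn{rng.randint(0, 20)}" for _ in range(rng.randint(0, 3))},
                cid=f"c{rng.randint(0, 10)}" if rng.random() < 0.5 else None,
                cas=f"cas{rng.randint(0, 10)}" if rng.random() < 0.5 else None,
                smiles=f"S{rng.randint(0, 10)}" if rng.random() < 0.5 else None,
            )
        )
    return ents


def _oracle_resolution(left, right):
    """Brute force: test every tier for every pair, strictly in order."""
    out = {}
    for r in right:
        best = None  # (tier_index, left_id)
        for l in left:
            t = first_matching_tier(l, r)
            if t is None:
                continue
            cand = (IDENTITY_TIERS.index(t), l.drug_id)
            if best is None or cand < best:
                best = cand
        out[r.drug_id] = r.drug_id if best is None else best[1]
    return out


@pytest.mark.parametrize("seed", range(15))
def test_resolution_agrees_with_bruteforce_oracle(seed):
    rng = random.Random(seed)
    left = _random_entities(rng, "L", rng.randint(1, 200))
    right = _random_entities(rng, "R", rng.randint(1, 50))
    got = canonical_id_map(resolve_drug_identity(left, right))
    assert got == _oracle_resolution(left, right)


def test_each_right_entity_maps_to_exactly_one_canonical_id():
    rng = random.Random(99)
    left = _random_entities(rng, "L", 50)
    right = _random_entities(rng, "R", 50)
    matches = resolve_drug_identity(left, right)
    assert len({m.right_id for m in matches}) == len(matches)
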