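"""Record-level preparation: exclusion filters, deduplication, the
dual-reporting restriction, and cross-source drug-identity resolution.

The preparation mirrors standard pharmacovigilance curation practice:
post-marketing reports and refuted associations are excluded, repeated
observations of the same drug-species-AE triple are collapsed to one,
and the analysis universe is restricted to drugs observed at least once
on both the preclinical and the clinical side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .records import DrugEntity, IdentityMatch

log = logging.getLogger(__name__)

#: Deduplication key. Phase is implied by species and SOC is implied by PT,
#: so the triple fully identifies one drug-species-AE observation.
DEDUP_KEY = ["drug_id", "species", "pt"]


@dataclass
class FilterReport:
    """Counts of removed records per exclusion reason.

    A record carrying both flags is counted under BOTH reasons; the
    overlap is reported separately so the reason counts remain
    interpretable as flag totals.
    """

    post_marketing: int = 0
    refuted: int = 0
    both: int = 0
    kept: int = 0


def filter_records(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop post-marketing and refuted records, reporting removal counts."""
    if records.empty:
        return records.copy(), FilterReport()
    pm = records["post_marketing"].astype(bool)
    rf = records["refuted"].astype(bool)
    keep = ~(pm | rf)
    report = FilterReport(
        post_marketing=int(pm.sum()),
        refuted=int(rf.sum()),
        both=int((pm & rf).sum()),
        kept=int(keep.sum()),
    )
    log.info(
        "filter_records: removed %d post-marketing, %d refuted (%d overlapping), kept %d",
        report.post_marketing,
        report.refuted,
        report.both,
        report.kept,
    )
    return records.loc[keep].reset_index(drop=True), report


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per (drug_id, species, pt), first in input order."""
    if records.empty:
        return records.copy()
    out = records.drop_duplicates(subset=DEDUP_KEY, keep="first").reset_index(drop=True)
    dropped = len(records) - len(out)
    if dropped:
        log.info("deduplicate: removed %d duplicate record(s)", dropped)
    return out


def restrict_to_dual_reported(records: pd.DataFrame) -> tuple[pd.DataFrame, set[str]]:
    """Keep only drugs with >=1 preclinical AND >=1 clinical record.

    Returns the restricted records and the retained drug set, which is
    the default universe for true-negative estimation downstream.
    """
    if records.empty:
        return records.copy(), set()
    by_phase = records.groupby("drug_id")["phase"].agg(set)
    universe = {d for d, phases in by_phase.items() if {"preclinical", "clinical"} <= phases}
    out = records[records["drug_id"].isin(universe)].reset_index(drop=True)
    log.info(
        "restrict_to_dual_reported: %d of %d drugs dual-reported",
        len(universe),
        by_phase.shape[0],
    )
    return out, universe


# --- drug identity resolution ------------------------------------------------

#: Cascade order; the first tier that matches wins and is recorded.
IDENTITY_TIERS = ("name", "synonym", "cid", "cas", "smiles")


def _names(e: DrugEntity) -> set[str]:
    return {e.main_name.strip().lower()}


def _name_pool(e: DrugEntity) -> set[str]:
    return _names(e) | {s.strip().lower() for s in e.synonyms}


def match_at_tier(left: DrugEntity, right: DrugEntity, tier: str) -> bool:
    """Whether two entities match at one cascade level (and only that level's
    evidence). Name/synonym comparison is case-insensitive after trimming;
    CID/CAS likewise; SMILES is exact-string after trimming (a cheminformatics
    normalizer can be plugged in upstream)."""
    if tier == "name":
        return _names(left) == _names(right) or bool(_names(left) & _names(right))
    if tier == "synonym":
        return bool(_name_pool(left) & _name_pool(right))
    if tier == "cid":
        return (
            left.cid is not None
            and right.cid is not None
            and left.cid.strip().lower() == right.cid.strip().lower()
        )
    if tier == "cas":
        return (
            left.cas is not None
            and right.cas is not None
            and left.cas.strip().lower() == right.cas.strip().lower()
        )
    if tier == "smiles":
        return (
            left.smiles is not None
            and right.smiles is not None
            and left.smiles.strip() == right.smiles.strip()
        )
    raise ValueError(f"unknown tier {tier!r}")


def first_matching_tier(left: DrugEntity, right: DrugEntity) -> str | None:
    for tier in IDENTITY_TIERS:
        if match_at_tier(left, right, tier):
            return tier
    return None


def _check_unique_ids(entities: list[DrugEntity], side: str) -> None:
    seen: set[str] = set()
    for e in entities:
        if e.drug_id in seen:
            raise ValueError(f"duplicate drug_id {e.drug_id!r} on {side} side")
        seen.add(e.drug_id)


def resolve_drug_identity(
    left: list[DrugEntity], right: list[DrugEntity]
) -> list[IdentityMatch]:
    """Resolve right-side entities against the left (canonical) source.

    The cascade is evaluated strictly in order name -> synonym -> CID ->
    CAS -> SMILES for each right entity against every left entity; the
    first tier with any hit wins. A matched right entity takes the left
    entity's id as canonical; an unmatched right entity keeps its own id
    (mirroring preservation of the original source name). If several left
    entities match at the winning tier, the lexicographically smallest
    left id is taken and a warning is logged.
    """
    _check_unique_ids(left, "left")
    _check_unique_ids(right, "right")
    matches: list[IdentityMatch] = []
    for r in right:
        winning_tier: str | None = None
        candidates: list[str] = []
        for tier in IDENTITY_TIERS:
            candidates = [l.drug_id for l in left if match_at_tier(l, r, tier)]
            if candidates:
                winning_tier = tier
                break
        if winning_tier is None:
            matches.append(
                IdentityMatch(left_id="", right_id=r.drug_id, tier="unmatched", canonical_id=r.drug_id)
            )
            continue
        canonical = min(candidates)
        if len(candidates) > 1:
            log.warning(
                "identity tie for %r at tier %s: %s -> chose %s",
                r.drug_id,
                winning_tier,
                sorted(candidates),
                canonical,
            )
        matches.append(
            IdentityMatch(left_id=canonical, right_id=r.drug_id, tier=winning_tier, canonical_id=canonical)
        )
    return matches


def canonical_id_map(matches: list[IdentityMatch]) -> dict[str, str]:
    """right_id -> canonical_id lookup from a resolution run."""
    return {m.right_id: m.canonical_id for m in matches}
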