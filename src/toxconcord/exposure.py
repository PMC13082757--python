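"""Pharmacokinetic exposure comparability and the exposure-controlled subset.

Animal and human exposures are compared on the log10 scale: a pair is
"comparable" when |delta log10 Cmax| <= threshold OR |delta log10 AUC| <=
threshold (default threshold 1.0, i.e. within one log-unit -- the
conventional 10-fold safety factor). Cmax is in ug/mL and AUC in ug*h/mL;
units must be normalized upstream.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import PKRecord, Species


class ComparisonStatus(str, enum.Enum):
    compared = "compared"
    no_shared_metric = "no_shared_metric"


@dataclass
class ExposureComparison:
    """Outcome of one animal-vs-human exposure comparison.

    ``comparable`` is None when no metric is shared between the two
    records ("incomparable for missing data"), which is distinct from a
    failed comparison (comparable=False).
    """

    comparable: bool | None
    status: ComparisonStatus
    metrics_used: tuple[str, ...]
    delta_log10: dict[str, float]


def exposure_comparable(
    animal: PKRecord, human: PKRecord, threshold: float = 1.0
) -> ExposureComparison:
    """Apply the one-log-unit rule to one animal/human PK record pair.

    The boundary is inclusive (delta exactly equal to the threshold
    passes). Both metrics are evaluated and OR-combined; ``metrics_used``
    lists every metric that satisfied the rule.
    """
    if animal.drug_id != human.drug_id:
        raise ValueError("exposure comparison requires the same drug on both sides")
    if human.species != Species.human or animal.species == Species.human:
        raise ValueError("expected one animal record and one human record")
    deltas: dict[str, float] = {}
    passed: list[str] = []
    for metric in ("cmax", "auc"):
        a, h = getattr(animal, metric), getattr(human, metric)
        if a is None or h is None:
            continue
        d = abs(math.log10(a) - math.log10(h))
        deltas[metric] = d
        if d <= threshold:
            passed.append(metric)
    if not deltas:
        return ExposureComparison(None, ComparisonStatus.no_shared_metric, (), {})
    return ExposureComparison(
        comparable=bool(passed),
        status=ComparisonStatus.compared,
        metrics_used=tuple(passed),
        delta_log10=deltas,
    )


def exposure_pass_table(
    pk_records: list[PKRecord], threshold: float = 1.0
) -> pd.DataFrame:
    """Audit table of (drug, species) exposure comparability.

    A (drug, animal species) pair passes iff at least one of its animal
    PK records is comparable to at least one human PK record of the same
    drug (existential rule over repeated PK studies). Pairs with no
    shared metric against any human record are reported with
    ``status = no_shared_metric``.
    """
    humans: dict[str, list[PKRecord]] = {}
    animals: dict[tuple[str, str], list[PKRecord]] = {}
    for rec in pk_records:
        if rec.species == Species.human:
            humans.setdefault(rec.drug_id, []).append(rec)
        else:
            animals.setdefault((rec.drug_id, rec.species.value), []).append(rec)

    rows = []
    for (drug, species), arecs in sorted(animals.items()):
        best: ExposureComparison | None = None
        for a in arecs:
            for h in humans.get(drug, []):
                cmp_ = exposure_comparable(a, h, threshold)
                if cmp_.status == ComparisonStatus.no_shared_metric:
                    if best is None:
                        best = cmp_
                    continue
                if best is None or best.comparable is None:
                    best = cmp_
                elif cmp_.comparable and not best.comparable:
                    best = cmp_
                elif cmp_.comparable == best.comparable:
                    # keep the smaller delta for the audit trail
                    if min(cmp_.delta_log10.values()) < min(best.delta_log10.values()):
                        best = cmp_
        if best is None:
            rows.append((drug, species, False, "no_pk_data", "", float("nan")))
        elif best.comparable is None:
            rows.append((drug, species, False, "no_shared_metric", "", float("nan")))
        else:
            metric = ";".join(best.metrics_used)
            rows.append(
                (
                    drug,
                    species,
                    bool(best.comparable),
                    "compared",
                    metric,
                    min(best.delta_log10.values()),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["drug_id", "species", "passed", "status", "metric_used", "delta_log10"],
    )


def exposure_controlled_subset(
    records: pd.DataFrame, pk_records: list[PKRecord], threshold: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict records to exposure-comparable (drug, species) pairs.

    Preclinical records outside passing pairs are dropped; human records
    are retained for drugs with at least one passing pair. Drugs with no
    PK data leave the subset entirely. Returns (restricted records, pass
    table).
    """
    passes = exposure_pass_table(pk_records, threshold)
    passing = passes.loc[passes["passed"], ["drug_id", "species"]]
    pass_pairs = set(map(tuple, passing.itertuples(index=False)))
    drugs_with_pass = {d for d, _ in pass_pairs}

    is_human = records["species"] == "human"
    keep_human = is_human & records["drug_id"].isin(drugs_with_pass)
    in_pass = np.fromiter(
        ((d, s) in pass_pairs for d, s in zip(records["drug_id"], records["species"])),
        dtype=bool,
        count=len(records),
    )
    keep_animal = ~is_human & in_pass
    out = records.loc[keep_human | keep_animal].reset_index(drop=True)
    return out, passes
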