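"""Target annotation of true-positive drug sets and hypergeometric
annotation-set enrichment with Benjamini-Hochberg correction.

This is a self-contained, file-based replacement for external enrichment
services: annotation sets arrive as GMT files, the background defaults
to all targets annotated to any drug in the analysis universe, and the
test is the upper-tail hypergeometric P(X >= overlap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .concordance import ConcordanceResult, build_stratum_view
from .records import TargetAnnotation, TargetRelation

log = logging.getLogger(__name__)

ALPHA_ENRICHMENT = 0.01


@dataclass
class EnrichmentResult:
    annotation_set_id: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p_raw: float
    p_adj_bh: float = float("nan")
    significant: bool = False


def annotate_tp_drugs(
    result: ConcordanceResult,
    records: pd.DataFrame,
    universe: Iterable[str],
    targets: Sequence[TargetAnnotation],
    relation: Optional[TargetRelation] = None,
    modalities: Optional[Mapping[str, str]] = None,
) -> tuple[set[str], set[str]]:
    """True-positive drugs for one concordance result, and their targets.

    The TP set contains the stratum-universe drugs with the result's
    preclinical PT present under the stratum species rule AND the
    clinical PT present in humans. The query set is the union of their
    annotated targets, optionally filtered by on/off-target relation.
    An empty TP set yields an empty query with a warning, not an error.
    """
    view = build_stratum_view(records, universe, result.stratum, modalities)
    tp_drugs = view.preclin_drugs.get(result.preclin_pt, set()) & view.clin_drugs.get(
        result.clin_pt, set()
    )
    if not tp_drugs:
        log.warning(
            "no TP drugs for %s -> %s in stratum %s",
            result.preclin_pt,
            result.clin_pt,
            result.stratum.label(),
        )
        return set(), set()
    query = {
        t.target_symbol
        for t in targets
        if t.drug_id in tp_drugs and (relation is None or t.relation == relation)
    }
    return tp_drugs, query


def hypergeometric_tail_p(overlap: int, background: int, set_size: int, query: int) -> float:
    """P(X >= overlap) drawing ``query`` from ``background`` with
    ``set_size`` successes."""
    if overlap == 0:
        return 1.0
    return float(sps.hypergeom.sf(overlap - 1, background, set_size, query))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def hypergeometric_enrichment(
    query: set[str],
    annotation_sets: Mapping[str, set[str]],
    background: set[str],
    alpha: float = ALPHA_ENRICHMENT,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each annotation set.

    Every set is intersected with the background before testing; the
    query must be a subset of the background. BH correction runs across
    all tested sets; significance is p_adj < alpha (default 0.01).
    """
    if not background:
        raise ValueError("empty background")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    results: list[EnrichmentResult] = []
    for set_id in sorted(annotation_sets):
        members = annotation_sets[set_id] & background
        overlap = len(members & query)
        results.append(
            EnrichmentResult(
                annotation_set_id=set_id,
                overlap=overlap,
                set_size=len(members),
                query_size=len(query),
                background_size=len(background),
                p_raw=hypergeometric_tail_p(overlap, len(background), len(members), len(query)),
            )
        )
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adj_bh = float(p_adj)
        r.significant = r.p_adj_bh < alpha
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.annotation_set_id,
                r.overlap,
                r.set_size,
                r.query_size,
                r.background_size,
                r.p_raw,
                r.p_adj_bh,
                r.significant,
            )
            for r in results
        ],
        columns=[
            "annotation_set_id",
            "overlap",
            "set_size",
            "query_size",
            "background_size",
            "p_raw",
            "p_adj_bh",
            "significant",
        ],
    )
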