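"""Cross-term concordance: non-identical preclinical-clinical PT pairs
within each SOC, semantic-similarity scoring, the quartile/Kruskal-Wallis
trend analysis, and unique-endpoint accounting.

Cross-term pairs stay inside their SOC to keep comparisons biologically
coherent; similarity scores are descriptive only and never gate or
weight the statistical inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .concordance import (
    ALPHA_CONCORDANCE,
    LOW_TP_THRESHOLD,
    MODE_CROSS_TERM,
    ConcordanceResult,
    ContingencyTable,
    EmptyStratumError,
    Stratum,
    bonferroni_within_soc,
    build_stratum_view,
    compute_metrics,
    contingency_from_view,
)
from .embeddings import EmbeddingProvider, cosine_similarity, embed_terms
from .stats import fisher_exact_two_tailed, kruskal_wallis

log = logging.getLogger(__name__)


def enumerate_crossterm_pairs(
    preclin_vocab: Mapping[str, Iterable[str]],
    clin_vocab: Mapping[str, Iterable[str]],
) -> list[tuple[str, str, str]]:
    """Full per-SOC cross product of preclinical x clinical PTs.

    Vocabularies map SOC -> PT set as observed in the prepared records.
    Identical pairs are included (they are flagged downstream); no pair
    spans two SOCs.
    """
    pairs: list[tuple[str, str, str]] = []
    for soc in sorted(set(preclin_vocab) & set(clin_vocab)):
        for p_pt in sorted(set(preclin_vocab[soc])):
            for c_pt in sorted(set(clin_vocab[soc])):
                pairs.append((soc, p_pt, c_pt))
    return pairs


def observed_vocabularies(records: pd.DataFrame) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Per-SOC PT sets observed preclinically / clinically."""
    is_human = records["species"] == "human"
    pre, clin = {}, {}
    for out, frame in ((pre, records[~is_human]), (clin, records[is_human])):
        for soc, grp in frame.groupby("soc")["pt"]:
            out[soc] = set(grp)
    return pre, clin


def run_crossterm_concordance(
    records: pd.DataFrame,
    universe: Iterable[str],
    strata: Sequence[Stratum],
    pairs: Sequence[tuple[str, str, str]],
    modalities: Optional[Mapping[str, str]] = None,
    alpha: float = ALPHA_CONCORDANCE,
    low_tp: int = LOW_TP_THRESHOLD,
) -> list[ConcordanceResult]:
    """One test per (stratum, pair); family = (soc, stratum, cross-term).

    Identical pairs are enumerated (so families equal the set of tests
    performed) but carry identical_term = True. A pair with an empty
    margin in a stratum yields p = 1 by the zero-margin convention.
    """
    results: list[ConcordanceResult] = []
    for stratum in strata:
        try:
            view = build_stratum_view(records, universe, stratum, modalities)
        except EmptyStratumError:
            log.warning("skipping empty stratum %s", stratum.label())
            continue
        for soc, p_pt, c_pt in pairs:
            table = contingency_from_view(view, p_pt, c_pt)
            results.append(
                ConcordanceResult(
                    stratum=stratum,
                    preclin_pt=p_pt,
                    clin_pt=c_pt,
                    soc=soc,
                    mode=MODE_CROSS_TERM,
                    table=table,
                    p_raw=fisher_exact_two_tailed(table.tp, table.fp, table.fn, table.tn),
                    metrics=compute_metrics(table, low_tp=low_tp),
                )
            )
    results.sort(key=lambda r: (r.stratum.label(), r.soc, r.preclin_pt, r.clin_pt))
    return bonferroni_within_soc(results, alpha=alpha)


def count_unique_endpoints(
    significant_crossterm: Sequence[ConcordanceResult] | Sequence[tuple[str, str]],
    significant_identical: Iterable[str] = (),
) -> tuple[int, int, int, int]:
    """Unique "additional" endpoints from significant cross-term pairs.

    Terms already significant in identical-term mode are removed from
    both sides first; then n_clin and n_preclin count the remaining
    unique clinical / preclinical PTs, n_shared their intersection, and
    n_total = n_clin + n_preclin - n_shared.
    """
    pairs: list[tuple[str, str]] = []
    for item in significant_crossterm:
        if isinstance(item, ConcordanceResult):
            pairs.append((item.preclin_pt, item.clin_pt))
        else:
            pairs.append((item[0], item[1]))
    identical = set(significant_identical)
    preclin = {p for p, _ in pairs} - identical
    clin = {c for _, c in pairs} - identical
    shared = preclin & clin
    return len(clin), len(preclin), len(shared), len(clin) + len(preclin) - len(shared)


def similarity_table(
    pairs: Sequence[tuple[str, str, str]],
    provider: EmbeddingProvider,
) -> pd.DataFrame:
    """Cosine similarity for each (soc, preclin_pt, clin_pt) pair."""
    terms = sorted({p for _, p, _ in pairs} | {c for _, _, c in pairs})
    vectors = {v.term: v for v in embed_terms(provider, terms)}
    rows = [
        (soc, p, c, cosine_similarity(vectors[p], vectors[c]))
        for soc, p, c in pairs
    ]
    return pd.DataFrame(rows, columns=["soc", "preclin_pt", "clin_pt", "similarity"])


@dataclass
class QuartileSummary:
    """Per-quartile similarity ranges, counts, and median LR+ with the
    Kruskal-Wallis test across the four bins."""

    boundaries: tuple[float, float, float]
    counts: tuple[int, int, int, int]
    similarity_ranges: tuple[tuple[float, float], ...]
    median_lr_plus: tuple[float, float, float, float]
    kw_statistic: float
    kw_p: float


def quartile_lr_analysis(
    similarities: Sequence[float], lr_plus: Sequence[float]
) -> QuartileSummary:
    """Median LR+ across empirical similarity quartiles, plus KW test.

    Bins split at the empirical 25/50/75 percentiles; a value exactly on
    a boundary goes to the lower bin. +inf LR+ values rank above every
    finite value (and push a bin's median to +inf when they dominate).
    Fewer than 8 pairs is an error: quartiles would be unstable.
    """
    sim = np.asarray(similarities, dtype=float)
    lr = np.asarray(lr_plus, dtype=float)
    if sim.shape != lr.shape:
        raise ValueError("similarities and lr_plus must align")
    if sim.size < 8:
        raise ValueError("need at least 8 pairs for a quartile analysis")
    q1, q2, q3 = np.quantile(sim, [0.25, 0.5, 0.75])
    bins = (sim > q1).astype(int) + (sim > q2) + (sim > q3)
    groups = [lr[bins == b] for b in range(4)]
    if any(g.size == 0 for g in groups):
        # heavy boundary ties can empty an upper bin; report it clearly
        raise ValueError("degenerate similarity distribution: empty quartile bin")
    h, p = kruskal_wallis(groups)
    return QuartileSummary(
        boundaries=(float(q1), float(q2), float(q3)),
        counts=tuple(int(g.size) for g in groups),
        similarity_ranges=tuple(
            (float(sim[bins == b].min()), float(sim[bins == b].max())) for b in range(4)
        ),
        median_lr_plus=tuple(float(np.median(g)) for g in groups),
        kw_statistic=h,
        kw_p=p,
    )
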