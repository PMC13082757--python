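"""Per-stratum contingency tables, exact testing, within-SOC Bonferroni
correction, and the likelihood-ratio concordance metrics.

For each (stratum, preclinical PT, clinical PT) pair every drug in the
stratum universe is classified exactly once:

* TP  - AE observed in the preclinical slice AND in humans
* FP  - observed preclinically but not in humans
* FN  - observed in humans but not preclinically
* TN  - observed in neither (an estimate: the remainder of the universe)

Metrics: sensitivity, specificity, LR+ = sens/(1-spec) (how much an
animal finding raises the odds of the human AE), iLR- = spec/(1-sens)
(how much the absence of an animal finding lowers those odds), PPV and
NPV. Phenotypes with zero false positives are retained and yield
LR+ = +inf; such estimates are flagged when the TP count is small.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .records import PRECLINICAL_SPECIES, Modality
from .stats import fisher_exact_two_tailed

log = logging.getLogger(__name__)

ALL = "all"

#: default alpha for the adjusted-p significance call
ALPHA_CONCORDANCE = 0.05
#: default TP count below which estimates are flagged as unstable
LOW_TP_THRESHOLD = 5

MODE_IDENTICAL = "identical"
MODE_CROSS_TERM = "cross_term"


@dataclass(frozen=True)
class Stratum:
    """The (species | all, modality | all, exposure-controlled?) slice.

    Under ``species_sel = "all"`` an AE counts as preclinical-present if
    it was observed in ANY panel species (union rule).
    """

    species_sel: str = ALL
    modality_sel: str = ALL
    exposure_controlled: bool = False

    def __post_init__(self):
        valid_species = {s.value for s in PRECLINICAL_SPECIES} | {ALL}
        if self.species_sel not in valid_species:
            raise ValueError(f"invalid species_sel {self.species_sel!r}")
        if self.modality_sel not in {Modality.SM.value, Modality.Bio.value, ALL}:
            raise ValueError(f"invalid modality_sel {self.modality_sel!r}")

    def label(self) -> str:
        exp = "expctrl" if self.exposure_controlled else "allexp"
        return f"{self.species_sel}|{self.modality_sel}|{exp}"


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cells must be non-negative")
        if self.n_universe <= 0:
            raise ValueError("universe must be positive")

    @property
    def n_universe(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricSet:
    sensitivity: float = math.nan
    specificity: float = math.nan
    lr_plus: float = math.nan
    ilr_minus: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    low_tp_flag: bool = False
    undefined: tuple[str, ...] = ()


@dataclass
class ConcordanceResult:
    """One (stratum, preclinical PT, clinical PT) concordance test."""

    stratum: Stratum
    preclin_pt: str
    clin_pt: str
    soc: str
    mode: str
    table: ContingencyTable
    p_raw: float
    metrics: MetricSet
    p_adj: float = math.nan
    significant: bool = False
    family_size: int = 0

    @property
    def identical_term(self) -> bool:
        return self.preclin_pt == self.clin_pt


def compute_metrics(table: ContingencyTable, low_tp: int = LOW_TP_THRESHOLD) -> MetricSet:
    """Diagnostic metrics from a 2x2 table, with explicit undefined flags.

    LR+ is +inf when FP = 0 and TP > 0 (perfect specificity with signal);
    iLR- is +inf when FN = 0 and TN > 0. A metric whose denominator has
    no observations (e.g. PPV with TP+FP = 0) is NaN and listed in
    ``undefined`` rather than coerced to 0.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    m = MetricSet(low_tp_flag=tp < low_tp)
    undefined: list[str] = []

    pos = tp + fn  # clinically positive drugs
    neg = fp + tn
    if pos >= 1:
        m.sensitivity = tp / pos
    else:
        undefined.append("sensitivity")
    if neg >= 1:
        m.specificity = tn / neg
    else:
        undefined.append("specificity")

    if pos >= 1 and neg >= 1:
        if fp == 0:
            m.lr_plus = math.inf if tp > 0 else math.nan
            if tp == 0:
                undefined.append("lr_plus")
        else:
            m.lr_plus = m.sensitivity / (1.0 - m.specificity)
        if fn == 0:
            m.ilr_minus = math.inf if tn > 0 else math.nan
            if tn == 0:
                undefined.append("ilr_minus")
        else:
            m.ilr_minus = m.specificity / (1.0 - m.sensitivity)
    else:
        undefined.extend(["lr_plus", "ilr_minus"])

    if tp + fp >= 1:
        m.ppv = tp / (tp + fp)
    else:
        undefined.append("ppv")
    if tn + fn >= 1:
        m.npv = tn / (tn + fn)
    else:
        undefined.append("npv")
    m.undefined = tuple(undefined)
    return m


class EmptyStratumError(ValueError):
    """The stratum universe contains no drugs; the stratum is unevaluable."""


@dataclass
class _StratumView:
    """Precomputed presence sets for one stratum."""

    universe: list[str]
    preclin_drugs: dict[str, set[str]]  # pt -> drugs with preclinical finding
    clin_drugs: dict[str, set[str]]  # pt -> drugs with clinical finding


def build_stratum_view(
    records: pd.DataFrame,
    universe: Iterable[str],
    stratum: Stratum,
    modalities: Optional[Mapping[str, str]] = None,
) -> _StratumView:
    """Resolve the stratum universe and per-PT drug presence sets.

    The stratum universe is the set of dual-reported drugs that (a) fall
    in the modality slice (``unknown`` modality drugs stay in the "all"
    aggregate but leave SM/Bio slices), and (b) have at least one
    preclinical record under the stratum's species rule and at least one
    clinical record. Records must already be prepared (filtered,
    deduplicated, dual-reported, and exposure-restricted when the
    stratum is exposure-controlled).
    """
    drugs = set(universe)
    if stratum.modality_sel != ALL:
        if modalities is None:
            raise ValueError("modality-stratified analysis requires a modality map")
        drugs = {d for d in drugs if modalities.get(d, "unknown") == stratum.modality_sel}

    rec = records[records["drug_id"].isin(drugs)]
    is_human = rec["species"] == "human"
    clin = rec[is_human]
    if stratum.species_sel == ALL:
        pre = rec[~is_human]
    else:
        pre = rec[rec["species"] == stratum.species_sel]

    pre_drugs = set(pre["drug_id"])
    clin_drugs_all = set(clin["drug_id"])
    stratum_universe = sorted(pre_drugs & clin_drugs_all)
    if not stratum_universe:
        raise EmptyStratumError(f"stratum {stratum.label()} has an empty universe")
    su = set(stratum_universe)

    def presence(frame: pd.DataFrame) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        sub = frame[frame["drug_id"].isin(su)]
        for pt, grp in sub.groupby("pt")["drug_id"]:
            out[pt] = set(grp)
        return out

    return _StratumView(
        universe=stratum_universe,
        preclin_drugs=presence(pre),
        clin_drugs=presence(clin),
    )


def contingency_from_view(view: _StratumView, preclin_pt: str, clin_pt: str) -> ContingencyTable:
    n = len(view.universe)
    p = view.preclin_drugs.get(preclin_pt, set())
    c = view.clin_drugs.get(clin_pt, set())
    tp = len(p & c)
    fp = len(p) - tp
    fn = len(c) - tp
    tn = n - tp - fp - fn
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def build_contingency(
    records: pd.DataFrame,
    universe: Iterable[str],
    stratum: Stratum,
    preclin_pt: str,
    clin_pt: str,
    modalities: Optional[Mapping[str, str]] = None,
) -> ContingencyTable:
    """2x2 table for one (stratum, preclinical PT, clinical PT) pair.

    Every drug in the stratum universe is classified exactly once, so
    the four cells always sum to the universe size; TN is the estimated
    remainder.
    """
    view = build_stratum_view(records, universe, stratum, modalities)
    return contingency_from_view(view, preclin_pt, clin_pt)


def bonferroni_within_soc(
    results: list[ConcordanceResult], alpha: float = ALPHA_CONCORDANCE
) -> list[ConcordanceResult]:
    """Bonferroni correction with families (soc, stratum, mode), in place.

    Every test actually performed counts toward its family size,
    significant or not. p_adj = min(1, p_raw * family size);
    significant iff p_adj < alpha.
    """
    families: dict[tuple, int] = {}
    for r in results:
        key = (r.soc, r.stratum, r.mode)
        families[key] = families.get(key, 0) + 1
    for r in results:
        m = families[(r.soc, r.stratum, r.mode)]
        r.family_size = m
        r.p_adj = min(1.0, r.p_raw * m)
        r.significant = r.p_adj < alpha
    return results


def run_identical_concordance(
    records: pd.DataFrame,
    universe: Iterable[str],
    strata: Sequence[Stratum],
    pt_to_soc: Mapping[str, str],
    modalities: Optional[Mapping[str, str]] = None,
    alpha: float = ALPHA_CONCORDANCE,
    low_tp: int = LOW_TP_THRESHOLD,
) -> list[ConcordanceResult]:
    """Identical-term concordance over every stratum.

    For each stratum, every PT observed at least once preclinically AND
    at least once clinically within that stratum is tested with
    preclin_pt = clin_pt. Zero-FP phenotypes are retained. Results are
    sorted by (stratum, soc, pt) and corrected within (soc, stratum).
    """
    results: list[ConcordanceResult] = []
    for stratum in strata:
        try:
            view = build_stratum_view(records, universe, stratum, modalities)
        except EmptyStratumError:
            log.warning("skipping empty stratum %s", stratum.label())
            continue
        pts = sorted(set(view.preclin_drugs) & set(view.clin_drugs))
        for pt in pts:
            table = contingency_from_view(view, pt, pt)
            results.append(
                ConcordanceResult(
                    stratum=stratum,
                    preclin_pt=pt,
                    clin_pt=pt,
                    soc=pt_to_soc[pt],
                    mode=MODE_IDENTICAL,
                    table=table,
                    p_raw=fisher_exact_two_tailed(table.tp, table.fp, table.fn, table.tn),
                    metrics=compute_metrics(table, low_tp=low_tp),
                )
            )
    results.sort(key=lambda r: (r.stratum.label(), r.soc, r.preclin_pt))
    return bonferroni_within_soc(results, alpha=alpha)


RESULT_COLUMNS = [
    "stratum_species",
    "stratum_modality",
    "exposure_controlled",
    "mode",
    "soc",
    "preclin_pt",
    "clin_pt",
    "identical_term",
    "tp",
    "fp",
    "fn",
    "tn",
    "n_universe",
    "p_raw",
    "p_adj",
    "family_size",
    "significant",
    "sensitivity",
    "specificity",
    "lr_plus",
    "ilr_minus",
    "ppv",
    "npv",
    "low_tp_flag",
]


def results_to_frame(results: Sequence[ConcordanceResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        m = r.metrics
        rows.append(
            (
                r.stratum.species_sel,
                r.stratum.modality_sel,
                r.stratum.exposure_controlled,
                r.mode,
                r.soc,
                r.preclin_pt,
                r.clin_pt,
                r.identical_term,
                r.table.tp,
                r.table.fp,
                r.table.fn,
                r.table.tn,
                r.table.n_universe,
                r.p_raw,
                r.p_adj,
                r.family_size,
                r.significant,
                m.sensitivity,
                m.specificity,
                m.lr_plus,
                m.ilr_minus,
                m.ppv,
                m.npv,
                m.low_tp_flag,
            )
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
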