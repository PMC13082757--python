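"""Synthetic drug-species-AE cohorts with known planted truth.

The generator emulates the statistical structure of curated
pharmacovigilance extracts: per-AE human prevalence, per-species planted
sensitivity/specificity (hence a planted LR+), a SOC/PT vocabulary with
only partial overlap between the preclinical and clinical sides,
lognormal exposures with a controllable comparable fraction, and
target-AE causal links.

Generative model, per drug and planted AE profile: the human occurrence
is Bernoulli(prevalence); given a human occurrence each panel species
shows the preclinical finding with probability ``sensitivity`` and,
given no human occurrence, with probability ``1 - specificity``
(conditionally independent across species given the human outcome). The
planted positive likelihood ratio is therefore sens / (1 - spec).

Randomness derives from a single root seed with fixed per-component
spawn keys (drugs, PK, targets, then one stream per profile index), so
appending profiles never perturbs earlier draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy import optimize
from scipy import stats as sps

from .records import AE_COLUMNS, PRECLINICAL_SPECIES

SPECIES_PANEL_DEFAULT = tuple(s.value for s in PRECLINICAL_SPECIES)

#: Anchor terms guaranteeing every drug is dual-reported. The anchor PTs
#: are one-sided by construction (preclinical-only / clinical-only), so
#: identical-term tests never see them and their cross-term table has a
#: full margin (p = 1 by the zero-margin convention).
ANCHOR_SOC = "Investigations"
ANCHOR_PRECLIN_PT = "Animal finding present"
ANCHOR_CLIN_PT = "Clinical finding present"


class VocabTerm(BaseModel):
    soc: str
    pt: str
    preclinical_observable: bool = True
    clinical_observable: bool = True


class PlantedAEProfile(BaseModel):
    """Planted per-AE truth: prevalence, per-species sens/spec, targets.

    ``preclin_pt`` lets the preclinical finding surface under a
    different (same-SOC) term than the clinical one, generating
    cross-term concordance from a shared latent human event; it defaults
    to the clinical term. A profile is a no-information null exactly
    when sensitivity = 1 - specificity (planted LR+ = 1).
    """

    pt: str
    soc: str
    prevalence_human: float = Field(ge=0.0, le=1.0)
    sensitivity: Union[float, dict[str, float]]
    specificity: Union[float, dict[str, float]]
    preclin_pt: Optional[str] = None
    linked_targets: set[str] = Field(default_factory=set)

    def sens_for(self, species: str) -> float:
        v = self.sensitivity[species] if isinstance(self.sensitivity, dict) else self.sensitivity
        if not 0.0 <= v <= 1.0:
            raise ValueError("sensitivity must be in [0, 1]")
        return float(v)

    def spec_for(self, species: str) -> float:
        v = self.specificity[species] if isinstance(self.specificity, dict) else self.specificity
        if not 0.0 <= v <= 1.0:
            raise ValueError("specificity must be in [0, 1]")
        return float(v)

    @property
    def preclinical_term(self) -> str:
        return self.preclin_pt or self.pt


class SimConfig(BaseModel):
    n_drugs: int = Field(gt=0)
    modality_fraction_bio: float = Field(default=0.3, ge=0.0, le=1.0)
    species_panel: tuple[str, ...] = SPECIES_PANEL_DEFAULT
    vocab: list[VocabTerm] = Field(min_length=1)
    seed: int = 0
    pk_sigma_log10: float = Field(default=1.0, gt=0.0)
    comparable_fraction_target: float = Field(default=0.5, ge=0.0, le=1.0)
    post_marketing_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    refuted_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    decoy_targets: int = Field(default=1000, ge=0)
    background_targets_per_drug: int = Field(default=2, ge=0)
    #: probability that a drug causing an AE carries any one of the AE's
    #: linked targets (different drugs hit different members of a target family)
    causal_target_prob: float = Field(default=0.6, ge=0.0, le=1.0)
    ensure_dual_reported: bool = True

    @field_validator("species_panel")
    @classmethod
    def _panel_valid(cls, v):
        allowed = set(SPECIES_PANEL_DEFAULT)
        bad = [s for s in v if s not in allowed]
        if bad:
            raise ValueError(f"unknown panel species: {bad}")
        if not v:
            raise ValueError("species_panel must be non-empty")
        return tuple(v)


@dataclass
class PlantedMetrics:
    """Closed-form truth for one (profile, species) at a given prevalence."""

    lr_plus: float
    ilr_minus: float
    tp_frac: float
    fp_frac: float
    fn_frac: float
    tn_frac: float


def planted_truth_metrics(profile: PlantedAEProfile, species: str) -> PlantedMetrics:
    """Closed-form LR+, iLR- and expected cell fractions of the model."""
    sens = profile.sens_for(species)
    spec = profile.spec_for(species)
    prev = profile.prevalence_human
    lr_plus = math.inf if spec == 1.0 else sens / (1.0 - spec)
    ilr_minus = math.inf if sens == 1.0 else spec / (1.0 - sens)
    return PlantedMetrics(
        lr_plus=lr_plus,
        ilr_minus=ilr_minus,
        tp_frac=prev * sens,
        fn_frac=prev * (1.0 - sens),
        fp_frac=(1.0 - prev) * (1.0 - spec),
        tn_frac=(1.0 - prev) * spec,
    )


@dataclass
class SimTruth:
    """Planted ground truth serialized alongside a cohort.

    Never consumed by the inference modules; only tests and validation
    read it back.
    """

    planted: dict  # (preclin_pt -> clin_pt, species) truths, JSON-friendly
    exposure_comparable: dict  # drug -> {species: bool}
    target_links: dict  # target -> [clinical pts]
    designed_to_drop: list[str]
    config: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "planted": self.planted,
                    "exposure_comparable": self.exposure_comparable,
                    "target_links": self.target_links,
                    "designed_to_drop": self.designed_to_drop,
                    "config": self.config,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )


@dataclass
class Cohort:
    drugs: pd.DataFrame
    ae_records: pd.DataFrame
    pk: pd.DataFrame
    targets: pd.DataFrame
    annotation_sets: dict[str, set[str]]
    truth: SimTruth


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _solve_pk_offset(sigma: float, target: float, threshold: float = 1.0) -> float:
    """Mean |offset| of the animal-human log10 exposure gap such that
    P(|delta| <= threshold) equals the target comparable fraction."""

    def frac(d0: float) -> float:
        return sps.norm.cdf((threshold - d0) / sigma) - sps.norm.cdf((-threshold - d0) / sigma)

    f0 = frac(0.0)
    if target > f0 + 1e-12:
        raise ValueError(
            f"comparable_fraction_target {target} unreachable with pk_sigma_log10 {sigma} "
            f"(max {f0:.3f}); reduce the spread or the target"
        )
    if abs(target - f0) <= 1e-12:
        return 0.0
    return float(optimize.brentq(lambda d: frac(d) - target, 0.0, 60.0 * sigma))


def generate_cohort(config: SimConfig, profiles: Sequence[PlantedAEProfile]) -> Cohort:
    """Generate the five input tables plus the planted-truth record.

    Emits drug metadata, AE records, PK measurements, target
    annotations, and target annotation sets, all in the canonical
    loader schemas. A fixed seed gives byte-identical tables.
    """
    vocab_by_pt = {t.pt: t for t in config.vocab}
    for prof in profiles:
        for term, role in ((prof.pt, "clinical"), (prof.preclinical_term, "preclinical")):
            if term not in vocab_by_pt:
                raise ValueError(f"profile references unknown PT {term!r} ({role} side)")
            if vocab_by_pt[term].soc != prof.soc:
                raise ValueError(
                    f"profile SOC {prof.soc!r} disagrees with vocab SOC for {term!r}"
                )

    n = config.n_drugs
    width = max(4, len(str(n)))
    drug_ids = [f"drug_{i:0{width}d}" for i in range(n)]

    # -- drugs (stream 0) -----------------------------------------------------
    rng_drugs = _stream(config.seed, 0)
    is_bio = rng_drugs.random(n) < config.modality_fraction_bio
    drugs = pd.DataFrame(
        {
            "drug_id": drug_ids,
            "main_name": drug_ids,
            "synonyms": [f"syn-{d}" for d in drug_ids],
            "cid": [f"CID{i}" for i in range(n)],
            "cas": ["" for _ in range(n)],
            "smiles": ["" for _ in range(n)],
            "modality": np.where(is_bio, "Bio", "SM"),
        }
    )

    # -- AE occurrences (one stream per profile: keys 100, 101, ...) ----------
    rows: list[tuple] = []
    flagged_rows: list[tuple] = []
    planted: dict = {}
    human_occurrence: dict[str, np.ndarray] = {}
    for i, prof in enumerate(profiles):
        rng = _stream(config.seed, 100 + i)
        human = rng.random(n) < prof.prevalence_human
        human_occurrence[prof.pt] = human_occurrence.get(prof.pt, np.zeros(n, bool)) | human
        clin_term = vocab_by_pt[prof.pt]
        pre_term = vocab_by_pt[prof.preclinical_term]
        if clin_term.clinical_observable:
            for j in np.flatnonzero(human):
                rows.append((drug_ids[j], "human", "clinical", prof.soc, prof.pt, False, False, "sim"))
        for species in config.species_panel:
            sens, spec = prof.sens_for(species), prof.spec_for(species)
            occ = np.where(human, rng.random(n) < sens, rng.random(n) < (1.0 - spec))
            if pre_term.preclinical_observable:
                for j in np.flatnonzero(occ):
                    rows.append(
                        (drug_ids[j], species, "preclinical", prof.soc, prof.preclinical_term, False, False, "sim")
                    )
            truth = planted_truth_metrics(prof, species)
            planted[f"{prof.preclinical_term}->{prof.pt}|{species}"] = {
                "lr_plus": "Inf" if math.isinf(truth.lr_plus) else truth.lr_plus,
                "ilr_minus": "Inf" if math.isinf(truth.ilr_minus) else truth.ilr_minus,
                "prevalence": prof.prevalence_human,
                "sensitivity": sens,
                "specificity": spec,
                "null": abs(sens - (1.0 - spec)) < 1e-12,
            }
        # flagged extras: appended after the clean records so that
        # first-instance deduplication always retains the clean copy
        if config.post_marketing_fraction > 0 and clin_term.clinical_observable:
            for j in np.flatnonzero(human & (rng.random(n) < config.post_marketing_fraction)):
                flagged_rows.append(
                    (drug_ids[j], "human", "clinical", prof.soc, prof.pt, True, False, "sim-postmkt")
                )
        if config.refuted_fraction > 0 and clin_term.clinical_observable:
            for j in np.flatnonzero(human & (rng.random(n) < config.refuted_fraction)):
                flagged_rows.append(
                    (drug_ids[j], "human", "clinical", prof.soc, prof.pt, False, True, "sim-refuted")
                )

    if config.ensure_dual_reported:
        for d in drug_ids:
            rows.append((d, "human", "clinical", ANCHOR_SOC, ANCHOR_CLIN_PT, False, False, "sim-anchor"))
            for species in config.species_panel:
                rows.append((d, species, "preclinical", ANCHOR_SOC, ANCHOR_PRECLIN_PT, False, False, "sim-anchor"))

    ae = pd.DataFrame(rows + flagged_rows, columns=AE_COLUMNS)
    ae = ae.sort_values(
        ["post_marketing", "refuted", "drug_id", "species", "soc", "pt"], kind="mergesort"
    ).reset_index(drop=True)

    dual = ae.groupby("drug_id")["phase"].agg(set)
    designed_to_drop = sorted(
        d for d in drug_ids if not ({"preclinical", "clinical"} <= dual.get(d, set()))
    )

    # -- PK (stream 1) ---------------------------------------------------------
    rng_pk = _stream(config.seed, 1)
    offset = _solve_pk_offset(config.pk_sigma_log10, config.comparable_fraction_target)
    human_log = rng_pk.normal(0.0, 0.5, size=n)  # log10 Cmax in ug/mL
    tau = 10.0 ** rng_pk.normal(0.8, 0.2, size=n)  # exposure-duration factor (h)
    pk_rows = []
    exposure_truth: dict[str, dict[str, bool]] = {d: {} for d in drug_ids}
    for j, d in enumerate(drug_ids):
        h_cmax = 10.0 ** human_log[j]
        pk_rows.append((d, "human", h_cmax, h_cmax * tau[j]))
        for species in config.species_panel:
            delta = rng_pk.normal(offset, config.pk_sigma_log10)
            a_cmax = 10.0 ** (human_log[j] + delta)
            pk_rows.append((d, species, a_cmax, a_cmax * tau[j]))
            exposure_truth[d][species] = bool(abs(delta) <= 1.0)
    pk = pd.DataFrame(pk_rows, columns=["drug_id", "species", "cmax", "auc"])

    # -- targets (stream 2) ----------------------------------------------------
    rng_tg = _stream(config.seed, 2)
    decoys = [f"TGT{k:04d}" for k in range(config.decoy_targets)]
    target_rows: list[tuple] = []
    target_links: dict[str, set[str]] = {}
    for prof in profiles:
        if not prof.linked_targets:
            continue
        human = human_occurrence[prof.pt]
        for tgt in sorted(prof.linked_targets):
            target_links.setdefault(tgt, set()).add(prof.pt)
            carriers = np.flatnonzero(human & (rng_tg.random(n) < config.causal_target_prob))
            for j in carriers:
                target_rows.append((drug_ids[j], tgt, "on_target"))
    if decoys and config.background_targets_per_drug:
        for d in drug_ids:
            picks = rng_tg.choice(
                decoys, size=min(config.background_targets_per_drug, len(decoys)), replace=False
            )
            for tgt in picks:
                target_rows.append((d, tgt, "off_target"))
    targets = (
        pd.DataFrame(target_rows, columns=["drug_id", "target_symbol", "relation"])
        .drop_duplicates()
        .sort_values(["drug_id", "target_symbol", "relation"], kind="mergesort")
        .reset_index(drop=True)
    )

    # -- annotation sets: one causal set per target-linked AE plus decoy sets --
    annotation_sets: dict[str, set[str]] = {}
    for prof in profiles:
        if prof.linked_targets:
            annotation_sets[f"phenotype::{prof.pt}"] = set(prof.linked_targets)
    all_targets = sorted({r[1] for r in target_rows})
    for k in range(5):
        if not all_targets:
            break
        size = min(max(2, len(all_targets) // 6), len(all_targets))
        members = rng_tg.choice(all_targets, size=size, replace=False)
        annotation_sets[f"random::set{k}"] = set(map(str, members))

    truth = SimTruth(
        planted=planted,
        exposure_comparable=exposure_truth,
        target_links={t: sorted(v) for t, v in target_links.items()},
        designed_to_drop=designed_to_drop,
        config=json.loads(config.model_dump_json()),
    )
    return Cohort(
        drugs=drugs,
        ae_records=ae,
        pk=pk,
        targets=targets,
        annotation_sets=annotation_sets,
        truth=truth,
    )


def default_vocab() -> list[VocabTerm]:
    """A compact MedDRA-like vocabulary with partial side overlap."""
    both = [
        ("Gastrointestinal disorders", "Vomiting"),
        ("Gastrointestinal disorders", "Diarrhoea"),
        ("Gastrointestinal disorders", "Gastric ulcer"),
        ("Hepatobiliary disorders", "Hepatocellular injury"),
        ("Hepatobiliary disorders", "Hepatitis"),
        ("Hepatobiliary disorders", "Hyperbilirubinaemia"),
        ("Nervous system disorders", "Seizure"),
        ("Nervous system disorders", "Tremor"),
        ("Blood and lymphatic system disorders", "Neutropenia"),
        ("Blood and lymphatic system disorders", "Anaemia"),
    ]
    preclin_only = [
        ("Gastrointestinal disorders", "Gastrointestinal hypermotility"),
        ("Nervous system disorders", "Hypertonia"),
        ("Hepatobiliary disorders", "Hepatic necrosis"),
    ]
    clin_only = [
        ("Nervous system disorders", "Headache"),
        ("Gastrointestinal disorders", "Nausea"),
    ]
    vocab = [VocabTerm(soc=s, pt=p) for s, p in both]
    vocab += [VocabTerm(soc=s, pt=p, clinical_observable=False) for s, p in preclin_only]
    vocab += [VocabTerm(soc=s, pt=p, preclinical_observable=False) for s, p in clin_only]
    vocab.append(
        VocabTerm(soc=ANCHOR_SOC, pt=ANCHOR_PRECLIN_PT, clinical_observable=False)
    )
    vocab.append(
        VocabTerm(soc=ANCHOR_SOC, pt=ANCHOR_CLIN_PT, preclinical_observable=False)
    )
    return vocab


def planted_similarity_trend(
    n_pairs: int = 1000, seed: int = 0, slope: float = 2.0, noise_sd: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic (similarity, LR+) pairs with a planted increasing trend.

    LR+ = exp(0.5 + slope * similarity + Normal(0, noise_sd)); by
    construction the conditional median of LR+ increases with
    similarity.
    """
    rng = np.random.default_rng(seed)
    sim = rng.random(n_pairs)
    lr = np.exp(0.5 + slope * sim + rng.normal(0.0, noise_sd, size=n_pairs))
    return sim, lr
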