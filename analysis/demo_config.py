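"""Shared configuration for the demonstration analysis.

One synthetic cohort of 400 dual-reported drugs across the five-species
preclinical panel, with planted AE profiles spanning strong, moderate,
null, and cross-term (proxy) concordance, plus causal target links for
the enrichment stage. Every numbered script reads and writes
``results/demo``.
"""

from pathlib import Path

from toxconcord.pipeline import RunConfig
from toxconcord.simulate import default_vocab

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "demo"
SEED = 42

PROFILES = [
    # strongly concordant GI event, dogs more sensitive than rodents
    dict(
        pt="Vomiting",
        soc="Gastrointestinal disorders",
        prevalence_human=0.30,
        sensitivity={"mouse": 0.45, "rat": 0.55, "rabbit": 0.40, "dog": 0.75, "monkey": 0.65},
        specificity=0.95,
        linked_targets=["HTR3A", "HTR3B", "OPRM1", "GLP1R", "GDF15", "CACNA1A"],
    ),
    # hepatic injury with high specificity (near-infinite LR+ expected)
    dict(
        pt="Hepatocellular injury",
        soc="Hepatobiliary disorders",
        prevalence_human=0.15,
        sensitivity=0.6,
        specificity=0.99,
        linked_targets=["CYP2E1", "ABCB11", "NR1I2", "HMOX1"],
    ),
    # moderate haematological signal
    dict(
        pt="Neutropenia",
        soc="Blood and lymphatic system disorders",
        prevalence_human=0.25,
        sensitivity=0.5,
        specificity=0.9,
    ),
    # planted cross-term: preclinical hypertonia proxies clinical seizure
    dict(
        pt="Seizure",
        soc="Nervous system disorders",
        prevalence_human=0.20,
        sensitivity={"mouse": 0.55, "rat": 0.5, "rabbit": 0.4, "dog": 0.7, "monkey": 0.65},
        specificity=0.97,
        preclin_pt="Hypertonia",
        linked_targets=["GRIN2B", "CHRNA4", "CHRNA7", "GRIA1", "DRD2"],
    ),
    # additional moderate GI and hepatic events to populate the
    # within-SOC cross-term pair space
    dict(
        pt="Diarrhoea",
        soc="Gastrointestinal disorders",
        prevalence_human=0.25,
        sensitivity=0.55,
        specificity=0.9,
    ),
    dict(
        pt="Gastric ulcer",
        soc="Gastrointestinal disorders",
        prevalence_human=0.12,
        sensitivity=0.6,
        specificity=0.97,
    ),
    # preclinical hypermotility proxies clinical nausea (pure cross-term:
    # the preclinical term is never reported clinically and vice versa)
    dict(
        pt="Nausea",
        soc="Gastrointestinal disorders",
        prevalence_human=0.18,
        sensitivity=0.5,
        specificity=0.96,
        preclin_pt="Gastrointestinal hypermotility",
    ),
    dict(
        pt="Hepatitis",
        soc="Hepatobiliary disorders",
        prevalence_human=0.18,
        sensitivity=0.5,
        specificity=0.93,
    ),
    dict(
        pt="Hyperbilirubinaemia",
        soc="Hepatobiliary disorders",
        prevalence_human=0.2,
        sensitivity=0.45,
        specificity=0.85,
    ),
    # preclinical necrosis proxies clinical hepatitis (cross-term)
    dict(
        pt="Hepatitis",
        soc="Hepatobiliary disorders",
        prevalence_human=0.15,
        sensitivity=0.55,
        specificity=0.97,
        preclin_pt="Hepatic necrosis",
    ),
    # no-information control (planted LR+ = 1)
    dict(
        pt="Anaemia",
        soc="Blood and lymphatic system disorders",
        prevalence_human=0.30,
        sensitivity=0.5,
        specificity=0.5,
    ),
    # weak signal, expected to stay mostly non-significant
    dict(
        pt="Tremor",
        soc="Nervous system disorders",
        prevalence_human=0.20,
        sensitivity=0.35,
        specificity=0.75,
    ),
]

STRATA = [
    dict(),
    dict(species="rat"),
    dict(species="dog"),
    dict(species="monkey"),
    dict(modality="SM"),
    dict(modality="Bio"),
    dict(exposure_controlled=True),
]


def make_config(outdir: Path = OUTDIR, seed: int = SEED) -> RunConfig:
    vocab = [v.model_dump() for v in default_vocab()]
    return RunConfig.model_validate(
        dict(
            simulate=dict(
                config=dict(
                    n_drugs=400,
                    vocab=vocab,
                    species_panel=["mouse", "rat", "rabbit", "dog", "monkey"],
                    modality_fraction_bio=0.3,
                    comparable_fraction_target=0.5,
                    seed=0,
                ),
                profiles=PROFILES,
            ),
            strata=STRATA,
            quartiles_on="all",  # similarity is descriptive; score every pair
            outdir=str(outdir),
            seed=seed,
        )
    )
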