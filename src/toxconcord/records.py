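"""Domain record types for the concordance analysis.

Adverse events (AEs) are coded with two MedDRA levels: the System Organ
Class (SOC, the organ-system grouping) and the Preferred Term (PT, the
specific phenotype). Terms are treated as opaque labels; the only
structural constraint enforced is that a PT belongs to exactly one SOC
within a dataset, because the within-SOC Bonferroni families downstream
require a unique family per PT.

Records are validated here with pydantic and converted to/from pandas
DataFrames for the bulk computations (see :func:`ae_records_to_frame`).
"""

from __future__ import annotations

import enum
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator


class Species(str, enum.Enum):
    """The clinical species plus the five major preclinical species."""

    human = "human"
    mouse = "mouse"
    rat = "rat"
    rabbit = "rabbit"
    dog = "dog"
    monkey = "monkey"


#: The preclinical panel (every species except human).
PRECLINICAL_SPECIES: tuple[Species, ...] = (
    Species.mouse,
    Species.rat,
    Species.rabbit,
    Species.dog,
    Species.monkey,
)


class Phase(str, enum.Enum):
    preclinical = "preclinical"
    clinical = "clinical"


class Modality(str, enum.Enum):
    """Therapeutic modality: small molecule, biologic, or unlabelled."""

    SM = "SM"
    Bio = "Bio"
    unknown = "unknown"


class AERecord(BaseModel):
    """One drug x species x phase x SOC/PT adverse-event observation.

    ``phase`` is fully determined by ``species``: a human observation is
    clinical and an animal observation is preclinical.
    """

    drug_id: str
    species: Species
    phase: Phase
    soc: str
    pt: str
    post_marketing: bool = False
    refuted: bool = False
    source: str = ""

    @field_validator("soc", "pt")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v or not v.strip():
            raise ValueError("soc and pt must be non-empty")
        return v

    @model_validator(mode="after")
    def _phase_matches_species(self) -> "AERecord":
        expected = Phase.clinical if self.species == Species.human else Phase.preclinical
        if self.phase != expected:
            raise ValueError(
                f"species {self.species.value!r} implies phase {expected.value!r}, "
                f"got {self.phase.value!r}"
            )
        return self

    @classmethod
    def make(cls, drug_id: str, species: Species | str, soc: str, pt: str, **kw) -> "AERecord":
        """Construct with the phase derived from the species."""
        sp = Species(species)
        phase = Phase.clinical if sp == Species.human else Phase.preclinical
        return cls(drug_id=drug_id, species=sp, phase=phase, soc=soc, pt=pt, **kw)


class DrugEntity(BaseModel):
    """One consolidated drug with its identifiers and modality label."""

    drug_id: str
    main_name: str
    synonyms: set[str] = Field(default_factory=set)
    cid: Optional[str] = None
    cas: Optional[str] = None
    smiles: Optional[str] = None
    modality: Modality = Modality.unknown


class IdentityMatch(BaseModel):
    """A resolved cross-source drug identity.

    ``tier`` records the FIRST level of the matching cascade
    (name -> synonym -> cid -> cas -> smiles) that produced the match.
    """

    left_id: str
    right_id: str
    tier: str
    canonical_id: str


class PKRecord(BaseModel):
    """One pharmacokinetic exposure measurement.

    Units: ``cmax`` in ug/mL, ``auc`` in ug*h/mL. At least one of the two
    must be present and positive.
    """

    drug_id: str
    species: Species
    cmax: Optional[float] = None
    auc: Optional[float] = None

    @model_validator(mode="after")
    def _at_least_one_positive(self) -> "PKRecord":
        if self.cmax is None and self.auc is None:
            raise ValueError("PKRecord needs at least one of cmax/auc")
        for name in ("cmax", "auc"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        return self


class TargetRelation(str, enum.Enum):
    on_target = "on_target"
    off_target = "off_target"


class TargetAnnotation(BaseModel):
    drug_id: str
    target_symbol: str
    relation: TargetRelation


AE_COLUMNS = [
    "drug_id",
    "species",
    "phase",
    "soc",
    "pt",
    "post_marketing",
    "refuted",
    "source",
]


def ae_records_to_frame(records: Iterable[AERecord]) -> pd.DataFrame:
    """Convert validated records to the canonical DataFrame layout."""
    rows = [
        (
            r.drug_id,
            r.species.value,
            r.phase.value,
            r.soc,
            r.pt,
            r.post_marketing,
            r.refuted,
            r.source,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=AE_COLUMNS)


def frame_to_ae_records(frame: pd.DataFrame) -> list[AERecord]:
    return [
        AERecord.make(
            drug_id=row.drug_id,
            species=row.species,
            soc=row.soc,
            pt=row.pt,
            post_marketing=bool(row.post_marketing),
            refuted=bool(row.refuted),
            source=str(row.source),
        )
        for row in frame.itertuples(index=False)
    ]


def validate_pt_soc_unique(frame: pd.DataFrame) -> dict[str, str]:
    """Return the PT -> SOC map, raising if any PT sits under two SOCs.

    A PT under two SOCs would make the within-SOC correction family
    ambiguous, so it is a hard load-time error rather than a silent pick.
    """
    mapping = frame[["pt", "soc"]].drop_duplicates()
    dup = mapping[mapping.duplicated("pt", keep=False)]
    if not dup.empty:
        offenders = sorted(dup["pt"].unique())
        raise ValueError(
            "PT(s) mapped to more than one SOC: " + ", ".join(offenders[:10])
        )
    return dict(zip(mapping["pt"], mapping["soc"]))
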