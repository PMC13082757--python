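"""End-to-end orchestration: config, stages, report tables, manifest.

A run is fully specified by a :class:`RunConfig` (YAML or JSON): either
paths to the five input tables or a simulate block, plus the strata
list, thresholds, output directory and seed. Stages communicate through
files in the output directory so each is independently re-runnable, and
identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .concordance import (
    ConcordanceResult,
    Stratum,
    results_to_frame,
    run_identical_concordance,
)
from .crossterm import (
    enumerate_crossterm_pairs,
    observed_vocabularies,
    quartile_lr_analysis,
    run_crossterm_concordance,
    similarity_table,
)
from .embeddings import HashedNgramProvider
from .enrichment import annotate_tp_drugs, enrichment_to_frame, hypergeometric_enrichment
from .exposure import exposure_controlled_subset
from .io import (
    load_ae_records,
    load_drug_entities,
    load_pk_records,
    load_target_annotations,
    parse_float,
    read_gmt,
    write_gmt,
    write_table,
)
from .prepare import deduplicate, filter_records, restrict_to_dual_reported
from .records import validate_pt_soc_unique
from .simulate import PlantedAEProfile, SimConfig, generate_cohort

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


class InputPaths(BaseModel):
    ae: str
    drugs: str
    pk: Optional[str] = None
    targets: Optional[str] = None
    annotation_sets: Optional[str] = None


class SimulateBlock(BaseModel):
    config: SimConfig
    profiles: list[PlantedAEProfile]


class StratumSpec(BaseModel):
    species: str = "all"
    modality: str = "all"
    exposure_controlled: bool = False

    def to_stratum(self) -> Stratum:
        return Stratum(
            species_sel=self.species,
            modality_sel=self.modality,
            exposure_controlled=self.exposure_controlled,
        )


class Thresholds(BaseModel):
    alpha_concordance: float = Field(default=0.05, gt=0)
    alpha_enrichment: float = Field(default=0.01, gt=0)
    exposure_delta: float = Field(default=1.0, gt=0)
    low_tp: int = Field(default=5, gt=0)


class RunConfig(BaseModel):
    inputs: Optional[InputPaths] = None
    simulate: Optional[SimulateBlock] = None
    strata: list[StratumSpec] = Field(default_factory=lambda: [StratumSpec()])
    thresholds: Thresholds = Field(default_factory=Thresholds)
    quartiles_on: str = "significant"  # or "all"
    enrichment_top_k: int = 2
    embedding_dim: int = 64
    outdir: str = "results"
    seed: int = 0

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "RunConfig":
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of 'inputs' or 'simulate' must be given")
        if self.quartiles_on not in {"significant", "all"}:
            raise ValueError("quartiles_on must be 'significant' or 'all'")
        for s in self.strata:
            s.to_stratum()  # validates
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.model_validate(data)

    def config_hash(self) -> str:
        """Hash of the analysis-defining fields (the output location is
        excluded so relocated runs stay comparable)."""
        payload = self.model_dump(mode="json", exclude={"outdir"})
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode("utf-8")
        ).hexdigest()


@dataclass
class PipelineState:
    config: RunConfig
    outdir: Path
    records: Optional[pd.DataFrame] = None
    universe: Optional[set[str]] = None
    modalities: Optional[dict[str, str]] = None
    pt_to_soc: Optional[dict[str, str]] = None
    manifest: Optional[dict] = None


def _outpath(state: PipelineState, name: str) -> Path:
    return state.outdir / name


def stage_simulate(state: PipelineState) -> None:
    cfg = state.config
    assert cfg.simulate is not None
    sim = cfg.simulate.config.model_copy(update={"seed": cfg.seed})
    cohort = generate_cohort(sim, cfg.simulate.profiles)
    write_table(cohort.drugs, _outpath(state, "drugs.csv"), sort_by=["drug_id"])
    write_table(
        cohort.ae_records,
        _outpath(state, "ae_records.csv"),
        sort_by=["post_marketing", "refuted", "drug_id", "species", "soc", "pt"],
    )
    write_table(cohort.pk, _outpath(state, "pk.csv"), sort_by=["drug_id", "species"])
    write_table(
        cohort.targets, _outpath(state, "targets.csv"), sort_by=["drug_id", "target_symbol"]
    )
    write_gmt(cohort.annotation_sets, _outpath(state, "annotation_sets.gmt"))
    cohort.truth.to_json(_outpath(state, "sim_truth.json"))


def _input_path(state: PipelineState, name: str, simulated: str) -> Path:
    cfg = state.config
    if cfg.simulate is not None:
        return _outpath(state, simulated)
    value = getattr(cfg.inputs, name)
    if value is None:
        raise StageError("prepare", "missing_input", f"input '{name}' not configured")
    return Path(value)


def stage_prepare(state: PipelineState) -> None:
    ae_path = _input_path(state, "ae", "ae_records.csv")
    drugs_path = _input_path(state, "drugs", "drugs.csv")
    loaded = load_ae_records(ae_path)
    if loaded.rejected:
        rej = pd.DataFrame(
            [(r.row_index, r.reason) for r in loaded.rejected], columns=["row_index", "reason"]
        )
        write_table(rej, _outpath(state, "rejected_rows.csv"), sort_by=["row_index"])
    records, report = filter_records(loaded.records)
    records = deduplicate(records)
    records, universe = restrict_to_dual_reported(records)
    if records.empty:
        raise StageError("prepare", "no_records", "no records survive preparation")
    entities = load_drug_entities(drugs_path)
    state.records = records
    state.universe = universe
    state.modalities = {e.drug_id: e.modality.value for e in entities}
    state.pt_to_soc = validate_pt_soc_unique(records)
    write_table(
        records,
        _outpath(state, "prepared_records.csv"),
        sort_by=["drug_id", "species", "soc", "pt"],
    )
    write_table(
        pd.DataFrame({"drug_id": sorted(universe)}),
        _outpath(state, "universe.csv"),
        sort_by=["drug_id"],
    )
    state.manifest["filter_report"] = {
        "post_marketing_removed": report.post_marketing,
        "refuted_removed": report.refuted,
        "overlap": report.both,
    }


def _needs_exposure(cfg: RunConfig) -> bool:
    return any(s.exposure_controlled for s in cfg.strata)


def stage_exposure(state: PipelineState) -> None:
    cfg = state.config
    if cfg.simulate is None and (cfg.inputs is None or cfg.inputs.pk is None):
        raise StageError(
            "exposure", "missing_input", "an exposure-controlled stratum requires a 'pk' input table"
        )
    pk = load_pk_records(_input_path(state, "pk", "pk.csv"))
    restricted, passes = exposure_controlled_subset(
        state.records, pk, threshold=cfg.thresholds.exposure_delta
    )
    write_table(passes, _outpath(state, "exposure_pass.csv"), sort_by=["drug_id", "species"])
    write_table(
        restricted,
        _outpath(state, "exposure_records.csv"),
        sort_by=["drug_id", "species", "soc", "pt"],
    )


def _load_exposure_records(state: PipelineState) -> pd.DataFrame:
    path = _outpath(state, "exposure_records.csv")
    if not path.exists():
        raise StageError(
            "concord", "missing_stage", "exposure stage output not found; run exposure first"
        )
    return pd.read_csv(path, dtype={"drug_id": str}, keep_default_na=False)


def _split_strata(cfg: RunConfig) -> tuple[list[Stratum], list[Stratum]]:
    plain = [s.to_stratum() for s in cfg.strata if not s.exposure_controlled]
    expctrl = [s.to_stratum() for s in cfg.strata if s.exposure_controlled]
    return plain, expctrl


def stage_concord(state: PipelineState) -> None:
    cfg = state.config
    plain, expctrl = _split_strata(cfg)
    results: list[ConcordanceResult] = []
    kw = dict(
        pt_to_soc=state.pt_to_soc,
        modalities=state.modalities,
        alpha=cfg.thresholds.alpha_concordance,
        low_tp=cfg.thresholds.low_tp,
    )
    if plain:
        results += run_identical_concordance(state.records, state.universe, plain, **kw)
    if expctrl:
        results += run_identical_concordance(
            _load_exposure_records(state), state.universe, expctrl, **kw
        )
    frame = results_to_frame(results)
    write_table(
        frame,
        _outpath(state, "concordance_identical.csv"),
        sort_by=["stratum_species", "stratum_modality", "exposure_controlled", "soc", "preclin_pt"],
    )
    state.manifest["family_sizes_identical"] = _family_sizes(frame)


def _family_sizes(frame: pd.DataFrame) -> dict[str, int]:
    if frame.empty:
        return {}
    grp = frame.groupby(
        ["soc", "stratum_species", "stratum_modality", "exposure_controlled", "mode"]
    ).size()
    return {"|".join(map(str, key)): int(v) for key, v in grp.items()}


def stage_crossterm(state: PipelineState) -> None:
    cfg = state.config
    pre_vocab, clin_vocab = observed_vocabularies(state.records)
    pairs = enumerate_crossterm_pairs(pre_vocab, clin_vocab)
    plain, expctrl = _split_strata(cfg)
    results: list[ConcordanceResult] = []
    kw = dict(
        modalities=state.modalities,
        alpha=cfg.thresholds.alpha_concordance,
        low_tp=cfg.thresholds.low_tp,
    )
    if plain:
        results += run_crossterm_concordance(state.records, state.universe, plain, pairs, **kw)
    if expctrl:
        results += run_crossterm_concordance(
            _load_exposure_records(state), state.universe, expctrl, pairs, **kw
        )
    frame = results_to_frame(results)
    write_table(
        frame,
        _outpath(state, "concordance_crossterm.csv"),
        sort_by=[
            "stratum_species",
            "stratum_modality",
            "exposure_controlled",
            "soc",
            "preclin_pt",
            "clin_pt",
        ],
    )
    state.manifest["family_sizes_crossterm"] = _family_sizes(frame)


def _read_results(state: PipelineState, name: str) -> pd.DataFrame:
    path = _outpath(state, name)
    if not path.exists():
        raise StageError("semantics", "missing_stage", f"{name} not found; run earlier stages")
    frame = pd.read_csv(path, dtype={"preclin_pt": str, "clin_pt": str}, keep_default_na=False)
    for col in ("p_raw", "p_adj", "lr_plus", "ilr_minus", "sensitivity", "specificity", "ppv", "npv"):
        frame[col] = frame[col].map(parse_float)
    for col in ("significant", "identical_term", "exposure_controlled", "low_tp_flag"):
        frame[col] = frame[col].astype(str).str.lower() == "true"
    for col in ("tp", "fp", "fn", "tn", "n_universe", "family_size"):
        frame[col] = frame[col].astype(int)
    return frame


def stage_semantics(state: PipelineState) -> None:
    cfg = state.config
    cross = _read_results(state, "concordance_crossterm.csv")
    pairs = (
        cross[["soc", "preclin_pt", "clin_pt"]].drop_duplicates().itertuples(index=False)
    )
    pairs = [tuple(p) for p in pairs]
    provider = HashedNgramProvider(dim=cfg.embedding_dim)
    sims = similarity_table(pairs, provider)
    write_table(
        sims, _outpath(state, "similarities.csv"), sort_by=["soc", "preclin_pt", "clin_pt"]
    )
    # the quartile trend is assessed on the combined stratum (all species,
    # all modalities, no exposure restriction) so each pair is scored once
    scored = cross[
        (cross["stratum_species"] == "all")
        & (cross["stratum_modality"] == "all")
        & (~cross["exposure_controlled"])
    ].merge(sims, on=["soc", "preclin_pt", "clin_pt"], how="left")
    if cfg.quartiles_on == "significant":
        scored = scored[scored["significant"]]
    scored = scored[np.isfinite(scored["lr_plus"]) | np.isposinf(scored["lr_plus"])]
    summary_path = _outpath(state, "quartile_summary.json")
    try:
        if len(scored) < 8:
            raise ValueError(f"only {len(scored)} scored pair(s); need >= 8")
        q = quartile_lr_analysis(scored["similarity"].to_numpy(), scored["lr_plus"].to_numpy())
    except ValueError as exc:
        summary = {"skipped": str(exc)}
    else:
        summary = {
            "provider_id": provider.provider_id,
            "n_pairs": int(len(scored)),
            "boundaries": list(q.boundaries),
            "counts": list(q.counts),
            "median_lr_plus": ["Inf" if np.isposinf(m) else m for m in q.median_lr_plus],
            "kw_statistic": q.kw_statistic,
            "kw_p": q.kw_p,
        }
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def stage_enrich(state: PipelineState) -> None:
    cfg = state.config
    if cfg.simulate is None and (cfg.inputs.targets is None or cfg.inputs.annotation_sets is None):
        log.info("enrichment skipped: no targets/annotation_sets configured")
        return
    targets = load_target_annotations(_input_path(state, "targets", "targets.csv"))
    annotation_sets = read_gmt(_input_path(state, "annotation_sets", "annotation_sets.gmt"))
    identical = _read_results(state, "concordance_identical.csv")
    sig = identical[identical["significant"]].copy()
    if sig.empty:
        log.warning("enrichment skipped: no significant identical-term results")
        write_table(
            enrichment_to_frame([]), _outpath(state, "enrichment.csv"), sort_by=[]
        )
        return
    sig = (
        sig.sort_values(
            ["lr_plus", "tp", "soc", "preclin_pt"],
            ascending=[False, False, True, True],
            kind="mergesort",
        )
        .drop_duplicates("preclin_pt")  # distinct exemplar AEs
        .head(cfg.enrichment_top_k)
    )
    background = {
        t.target_symbol for t in targets if t.drug_id in state.universe
    }
    frames = []
    for row in sig.itertuples(index=False):
        stratum = Stratum(
            species_sel=row.stratum_species,
            modality_sel=row.stratum_modality,
            exposure_controlled=bool(row.exposure_controlled),
        )
        result = _result_stub(row, stratum)
        _, query = annotate_tp_drugs(result, state.records, state.universe, targets)
        query &= background
        if not query:
            continue
        res = hypergeometric_enrichment(
            query, annotation_sets, background, alpha=cfg.thresholds.alpha_enrichment
        )
        frame = enrichment_to_frame(res)
        frame.insert(0, "exemplar_pt", row.preclin_pt)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True) if frames else enrichment_to_frame([])
    if "exemplar_pt" not in out.columns:
        out.insert(0, "exemplar_pt", pd.Series(dtype=str))
    write_table(
        out, _outpath(state, "enrichment.csv"), sort_by=["exemplar_pt", "annotation_set_id"]
    )


def _result_stub(row, stratum: Stratum) -> ConcordanceResult:
    from .concordance import ContingencyTable, MetricSet

    return ConcordanceResult(
        stratum=stratum,
        preclin_pt=row.preclin_pt,
        clin_pt=row.clin_pt,
        soc=row.soc,
        mode=row.mode,
        table=ContingencyTable(tp=int(row.tp), fp=int(row.fp), fn=int(row.fn), tn=int(row.tn)),
        p_raw=float(row.p_raw),
        metrics=MetricSet(),
    )


def summarize_significant(results: pd.DataFrame, strata: list[StratumSpec]) -> pd.DataFrame:
    """Per-(stratum, SOC) counts of tested and significant results.

    Emits one TOTAL row per stratum (zeros when the stratum produced no
    tests) so empty strata are visible rather than absent.
    """
    key = ["mode", "stratum_species", "stratum_modality", "exposure_controlled", "soc"]
    rows = []
    if not results.empty:
        grp = results.groupby(key[:-1] + ["soc"])
        for k, sub in grp:
            n = len(sub)
            s = int(sub["significant"].sum())
            rows.append((*k, n, s, 100.0 * s / n))
    frame = pd.DataFrame(
        rows, columns=key + ["n_tested", "n_significant", "pct_significant"]
    )
    totals = []
    for mode in sorted(results["mode"].unique()) if not results.empty else ["identical"]:
        for spec in strata:
            sub = frame[
                (frame["mode"] == mode)
                & (frame["stratum_species"] == spec.species)
                & (frame["stratum_modality"] == spec.modality)
                & (frame["exposure_controlled"] == spec.exposure_controlled)
            ]
            n, s = int(sub["n_tested"].sum()), int(sub["n_significant"].sum())
            totals.append(
                (
                    mode,
                    spec.species,
                    spec.modality,
                    spec.exposure_controlled,
                    "TOTAL",
                    n,
                    s,
                    (100.0 * s / n) if n else 0.0,
                )
            )
    totals_frame = pd.DataFrame(totals, columns=frame.columns)
    if frame.empty:
        return totals_frame
    return pd.concat([frame, totals_frame], ignore_index=True)


def stage_report(state: PipelineState) -> None:
    frames = []
    for name in ("concordance_identical.csv", "concordance_crossterm.csv"):
        path = _outpath(state, name)
        if path.exists():
            frames.append(_read_results(state, name))
    if not frames:
        raise StageError("report", "missing_stage", "no concordance outputs to summarize")
    combined = pd.concat(frames, ignore_index=True)
    summary = summarize_significant(combined, state.config.strata)
    write_table(
        summary,
        _outpath(state, "summary_significant.csv"),
        sort_by=["mode", "stratum_species", "stratum_modality", "exposure_controlled", "soc"],
    )


STAGE_ORDER = [
    ("simulate", stage_simulate),
    ("prepare", stage_prepare),
    ("exposure", stage_exposure),
    ("concord", stage_concord),
    ("crossterm", stage_crossterm),
    ("semantics", stage_semantics),
    ("enrich", stage_enrich),
    ("report", stage_report),
]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; return the manifest (also written to disk).

    Any stage error aborts with the stage name; the manifest marks the
    run incomplete and records the machine-readable error code.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = PipelineState(config=config, outdir=outdir)
    state.manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages_completed": [],
        "incomplete": True,
    }
    has_pk = config.simulate is not None or (config.inputs and config.inputs.pk)
    try:
        for name, fn in STAGE_ORDER:
            if name == "simulate" and config.simulate is None:
                continue
            if name == "exposure" and not (_needs_exposure(config) or has_pk):
                continue
            log.info("stage %s", name)
            fn(state)
            state.manifest["stages_completed"].append(name)
    except StageError as err:
        state.manifest["error"] = {"stage": err.stage, "code": err.code, "message": str(err)}
        _write_manifest(state)
        raise
    state.manifest["incomplete"] = False
    state.manifest["row_counts"] = {
        p.name: sum(1 for _ in open(p, encoding="utf-8")) - 1
        for p in sorted(outdir.glob("*.csv"))
    }
    _write_manifest(state)
    return state.manifest


def _write_manifest(state: PipelineState) -> None:
    (_outpath(state, "manifest.json")).write_text(
        json.dumps(state.manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
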