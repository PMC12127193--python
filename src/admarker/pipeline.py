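"""Pipeline orchestration: configuration, analysis sets, staged execution.

``run_pipeline`` chains simulate/ingest -> quantification QC -> endpoints ->
DEP screening -> single-marker stratum reports -> combination reports ->
exploratory outputs, writing every table as CSV/TSV plus a manifest with a
config hash, per-stage seeds and row counts, and a content hash per output
file.  The run is a pure function of (config, input files): the same config
reproduces byte-identical outputs.

Analysis-set conventions (nested): SAS (>= 1 dose) >= FAS (>= 1 post-dose
efficacy assessment) >= PPS (completed per protocol with adherence >= 80%);
BAS (biomarker consent + data) is a subset of FAS.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import endpoints as ep
from . import explore, io, stratify, synth
from .combos import enumerate_and_report

logger = logging.getLogger("admarker")

__all__ = ["RunConfig", "AnalysisSets", "build_analysis_sets", "run_pipeline", "stage_seed"]


@dataclass(frozen=True)
class AnalysisSets:
    """Membership lists for the four nested analysis sets."""

    sas: tuple[str, ...]
    fas: tuple[str, ...]
    pps: tuple[str, ...]
    bas: tuple[str, ...]


def build_analysis_sets(cohort: pd.DataFrame, adherence_min: float = 80.0) -> AnalysisSets:
    """Apply the analysis-set membership rules to a cohort table.

    SAS: received at least one dose.  FAS: SAS plus at least one post-dose
    efficacy assessment (a week-2 or week-4 EASI).  PPS: FAS plus protocol
    completion and adherence >= ``adherence_min`` percent.  BAS: FAS plus
    biomarker consent.  Contradictory flags (marked completed while the
    week-4 EASI is missing) raise with the offending patient ids.
    """
    dosed = cohort["dosed"].astype(bool)
    assessed = cohort["easi_wk2"].notna() | cohort["easi_wk4"].notna()
    completed = cohort["completed"].astype(bool)

    contradiction = completed & cohort["easi_wk4"].isna()
    if contradiction.any():
        bad = cohort.loc[contradiction, "patient_id"].tolist()
        raise ValueError(f"contradictory completion flags for patients: {bad}")

    sas = dosed
    fas = sas & assessed
    pps = fas & completed & (cohort["adherence_pct"] >= adherence_min)
    bas = fas & cohort["biomarker_consent"].astype(bool)
    ids = cohort["patient_id"]
    return AnalysisSets(
        sas=tuple(ids[sas]),
        fas=tuple(ids[fas]),
        pps=tuple(ids[pps]),
        bas=tuple(ids[bas]),
    )


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    out_dir: str = "admarker_run"
    clinical_csv: str | None = None       # ingest instead of simulating
    proteome_tsv: str | None = None
    gmt_path: str | None = None
    seed: int = 0
    n_proteins: int = 469
    auroc_min: float = 0.7
    r2_min: float = 0.9
    gate_alpha: float = 0.05
    equal_var: bool = True
    adherence_min: float = 80.0
    combo_k: int = 2
    combo_shortlist: int = 5
    n_perm: int = 1000
    active_arm: str = "high_dose"
    placebo_arm: str = "placebo"
    stages: tuple[str, ...] = ("simulate", "endpoints", "strat", "combos", "explore")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of (master seed, stage name)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns a manifest dict (also written as ``manifest.json``).  Stages not
    listed in ``config.stages`` are skipped; a stage whose inputs were not
    produced raises a dependency error naming the missing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {}

    # --- simulate / ingest -------------------------------------------------
    cohort = proteome = None
    if "simulate" in stages and config.clinical_csv is None:
        tc = synth.default_config(
            seed=stage_seed(config.seed, "simulate"), n_proteins=config.n_proteins
        )
        trial = synth.simulate_trial(tc)
        cohort, proteome = trial.cohort, trial.proteome
        io.write_clinical_csv(cohort, out / "clinical.csv")
        io.write_proteome_tsv(proteome, out / "proteome.tsv")
        outputs["clinical"] = out / "clinical.csv"
        outputs["proteome"] = out / "proteome.tsv"
    elif config.clinical_csv is not None:
        cohort = io.read_clinical_csv(config.clinical_csv)
        if config.proteome_tsv is not None:
            proteome = io.read_proteome_tsv(config.proteome_tsv)
    if cohort is None:
        raise RuntimeError("no cohort available: enable 'simulate' or provide clinical_csv")
    counts["cohort"] = len(cohort)

    sets = build_analysis_sets(cohort, adherence_min=config.adherence_min)
    counts.update(sas=len(sets.sas), fas=len(sets.fas), pps=len(sets.pps), bas=len(sets.bas))
    logger.info("analysis sets: SAS=%d FAS=%d PPS=%d BAS=%d",
                len(sets.sas), len(sets.fas), len(sets.pps), len(sets.bas))

    # --- endpoints ---------------------------------------------------------
    endpoints_df = None
    if "endpoints" in stages:
        fas_cohort = cohort[cohort["patient_id"].isin(sets.fas)]
        endpoints_df = ep.compute_endpoints(fas_cohort)
        endpoints_df.to_csv(out / "endpoints.csv", index=False)
        ep.arm_summary(endpoints_df).to_csv(out / "arm_contrasts.csv", index=False)
        outputs["endpoints"] = out / "endpoints.csv"
        outputs["arm_contrasts"] = out / "arm_contrasts.csv"
        counts["endpoints"] = len(endpoints_df)

    def _bas_frames():
        if endpoints_df is None:
            raise RuntimeError("dependency error: stage 'endpoints' did not run")
        if proteome is None:
            raise RuntimeError("dependency error: no proteome (stage 'simulate' "
                               "or proteome_tsv required)")
        bas_ids = [p for p in proteome.index if p in set(sets.bas)]
        mat = proteome.loc[bas_ids]
        epi = endpoints_df.set_index("patient_id").loc[bas_ids]
        complete = epi["easi50_wk4"].notna()
        return mat.loc[complete.to_numpy()], epi.loc[complete.to_numpy()].reset_index()

    # --- single-marker stratification --------------------------------------
    deps = None
    if "strat" in stages:
        mat, epi = _bas_frames()
        act = epi["arm"] == config.active_arm
        flags = epi.loc[act, "easi50_wk4"].astype(bool).to_numpy()
        deps = stratify.select_deps(
            mat.loc[act.to_numpy()], flags, auroc_min=config.auroc_min
        )
        counts["deps"] = len(deps)
        reports = []
        for c in deps:
            if c.direction is None:
                continue
            levels = mat[c.protein_id]
            reports.append(
                stratify.stratum_report(
                    epi, levels, c,
                    active_arm=config.active_arm, placebo_arm=config.placebo_arm,
                    equal_var=config.equal_var,
                )
            )
        stratify.table2_style(reports).to_csv(out / "single_marker_report.csv", index=False)
        pd.DataFrame(
            [
                {"protein_id": c.protein_id, "direction": c.direction,
                 "cutoff": c.cutoff, "j": c.j, "sensitivity": c.sensitivity,
                 "specificity": c.specificity, "auroc": c.auroc}
                for c in deps
            ]
        ).to_csv(out / "deps.csv", index=False)
        outputs["single_marker_report"] = out / "single_marker_report.csv"
        outputs["deps"] = out / "deps.csv"

    # --- combinations ------------------------------------------------------
    if "combos" in stages:
        if deps is None:
            raise RuntimeError("dependency error: stage 'strat' did not run")
        mat, epi = _bas_frames()
        shortlist = [c for c in deps if c.direction is not None][: config.combo_shortlist]
        combo_df = enumerate_and_report(
            mat, shortlist, epi, k=config.combo_k,
            active_arm=config.active_arm, placebo_arm=config.placebo_arm,
            equal_var=config.equal_var,
        )
        combo_df.to_csv(out / "combo_report.csv", index=False)
        outputs["combo_report"] = out / "combo_report.csv"
        counts["combos"] = len(combo_df)

    # --- exploratory -------------------------------------------------------
    if "explore" in stages:
        mat, epi = _bas_frames()
        act = (epi["arm"] == config.active_arm).to_numpy()
        flags = epi.loc[act, "easi50_wk4"].astype(bool).to_numpy()
        vol = explore.volcano(mat.loc[act], flags)
        vol.to_csv(out / "volcano.csv", index=False)
        outputs["volcano"] = out / "volcano.csv"
        scores, evr, _ = explore.pca(mat.loc[act])
        scores.join(pd.Series(flags, index=scores.index, name="responder")).to_csv(
            out / "pca_scores.csv"
        )
        outputs["pca_scores"] = out / "pca_scores.csv"
        counts["explained_pc1_pct"] = int(round(100 * evr.iloc[0]))
        if config.gmt_path:
            sets_gmt = explore.read_gmt(config.gmt_path)
            ranked = vol.dropna(subset=["log2_fc"]).set_index("protein_id")["log2_fc"]
            res = explore.gsea_preranked(
                ranked, sets_gmt, n_perm=config.n_perm,
                seed=stage_seed(config.seed, "gsea"),
            )
            pd.DataFrame(
                [
                    {"set_name": r.set_name, "es": r.es, "nes": r.nes,
                     "p_perm": r.p_perm, "fdr_q": r.fdr_q, "size": r.size,
                     "leading_edge": "|".join(map(str, r.leading_edge))}
                    for r in res
                ]
            ).to_csv(out / "gsea.csv", index=False)
            outputs["gsea"] = out / "gsea.csv"

    # --- manifest ----------------------------------------------------------
    manifest = {
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in sorted(stages)},
        "row_counts": counts,
        "analysis_sets": {"sas": len(sets.sas), "fas": len(sets.fas),
                          "pps": len(sets.pps), "bas": len(sets.bas)},
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
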