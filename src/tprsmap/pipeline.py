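"""End-to-end pipeline: simulate -> QC -> relatedness/MDS -> expression ->
scores -> PLS -> association/mediation -> report.

One structured config drives every stage; a master seed spawns per-stage
seeds by a fixed counter rule (stage i uses generator seed [master, i]) so
any stage can be re-run in isolation and reproduce its outputs. A run
manifest records the config hash, per-stage output checksums and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import estimate_relatedness, mds_components, qc_filter, write_dosage_tsv
from .mediation import (
    adjusted_regression,
    brainscore_symptom_corr,
    mediate,
    multiple_comparison_gate,
)
from .pls import BehavioralPLS, save_pls_result
from .simulate import SimulationConfig, simulate_study, write_study

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "ancestry", "scores", "pls", "associate", "mediate"]

# which earlier stage each stage needs
_REQUIRES = {
    "qc": "simulate",
    "ancestry": "qc",
    "scores": "qc",
    "pls": "scores",
    "associate": "pls",
    "mediate": "pls",
}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    maf_min: float = 0.01
    info_min: float = 0.80
    pihat_max: float = 0.2
    mds_k: int = 10
    n_perm: int = 500
    n_boot: int = 1000
    bsr_threshold: float = 2.5
    min_cluster_size: int = 20
    mediation_n_boot: int = 5000
    n_causal: int = 20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> SimulationConfig:
        if self.mds_k < 1:
            raise ValueError("mds_k must be >= 1")
        for name in ("n_perm", "n_boot", "mediation_n_boot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        return SimulationConfig(**sim)


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    stages: dict  # stage -> {"status", "outputs": {path: sha256}, "elapsed_s"}
    version: str
    started: str
    finished: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksum_dir(paths) -> dict:
    out = {}
    for p in paths:
        p = Path(p)
        if p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    out[str(f)] = _sha256(f)
        elif p.is_file():
            out[str(p)] = _sha256(p)
    return out


def stage_seed(master_seed: int, stage: str) -> list:
    """Counter-based per-stage seed: generator key [master, stage index]."""
    return [int(master_seed) & 0x7FFFFFFF, STAGES.index(stage)]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    sim_cfg = config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = {s: bool(config.stages.get(s, True)) for s in STAGES}
    for stage, need in _REQUIRES.items():
        if enabled[stage] and not enabled[need]:
            raise StageError(stage, f"requires stage {need!r}; run it first")

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            yaml.safe_dump(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        seeds={s: stage_seed(config.seed, s) for s in STAGES},
        stages={},
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    state: dict = {}

    def record(stage, outputs, t0):
        manifest.stages[stage] = {
            "status": "completed",
            "outputs": _checksum_dir(outputs),
            "elapsed_s": round(time.time() - t0, 3),
        }

    try:
        if enabled["simulate"]:
            t0 = time.time()
            study = simulate_study(sim_cfg, n_causal=config.n_causal)
            write_study(study, outdir / "inputs")
            state["study"] = study
            record("simulate", [outdir / "inputs"], t0)

        if enabled["qc"]:
            t0 = time.time()
            study = state["study"]
            g_qc, report = qc_filter(
                study.genotypes, maf_min=config.maf_min, info_min=config.info_min
            )
            report.to_frame().to_csv(outdir / "qc_removed.tsv", sep="\t", index=False)
            write_dosage_tsv(
                g_qc, outdir / "dosages_qc.tsv", outdir / "variants_qc.tsv"
            )
            state["g_qc"] = g_qc
            record("qc", [outdir / "qc_removed.tsv", outdir / "dosages_qc.tsv"], t0)

        if enabled["ancestry"]:
            t0 = time.time()
            g_qc = state["g_qc"]
            rel = estimate_relatedness(g_qc, pihat_max=config.pihat_max)
            pd.DataFrame(
                rel.excluded_subjects, columns=["subject_id", "reason"]
            ).to_csv(outdir / "related_excluded.tsv", sep="\t", index=False)
            keep = [s for s in g_qc.subject_ids if s not in set(rel.excluded_ids)]
            g_final = g_qc.take_subjects(keep)
            anc = mds_components(g_final, k=min(config.mds_k, g_final.n_subjects - 1))
            anc.components.to_csv(outdir / "mds_components.tsv", sep="\t",
                                  index_label="subject_id")
            state["g_final"] = g_final
            state["ancestry"] = anc
            record(
                "ancestry",
                [outdir / "related_excluded.tsv", outdir / "mds_components.tsv"],
                t0,
            )
        elif enabled["scores"]:
            state["g_final"] = state["g_qc"]

        if enabled["scores"]:
            t0 = time.time()
            from .genotypes import harmonize
            from .scoring import compute_pgc_prs, compute_tprs, impute_expression, ld_clump

            study = state["study"]
            g = state["g_final"]
            w_harm, _ = harmonize(g, study.weights)
            expr = impute_expression(g, w_harm)
            tprs = compute_tprs(expr, study.de_table)
            tprs.scores.rename("tprs").to_frame().rename_axis("subject_id").to_csv(
                outdir / "tprs.tsv", sep="\t"
            )
            ss_harm, _ = harmonize(g, study.sumstats)
            clumps = ld_clump(ss_harm, g)
            prs_list = compute_pgc_prs(g, ss_harm, clumps)
            prs_df = pd.DataFrame(
                {f"p_{sv.threshold:g}": sv.scores for sv in prs_list}
            )
            prs_df.rename_axis("subject_id").to_csv(outdir / "pgc_prs.tsv", sep="\t")
            state["tprs"] = tprs
            state["expr"] = expr
            record("scores", [outdir / "tprs.tsv", outdir / "pgc_prs.tsv"], t0)

        if enabled["pls"]:
            t0 = time.time()
            study = state["study"]
            score = state["tprs"].scores
            act = study.activations.take_subjects(list(score.index))
            state["act"] = act
            pls = BehavioralPLS(
                n_perm=config.n_perm, n_boot=config.n_boot,
                bsr_threshold=config.bsr_threshold,
                min_cluster_size=config.min_cluster_size,
                random_state=stage_seed(config.seed, "pls"),
            ).fit(act, score)
            save_pls_result(pls.result_, outdir / "pls")
            state["pls"] = pls
            record("pls", [outdir / "pls"], t0)

        if enabled["associate"]:
            t0 = time.time()
            if "pls" not in state:
                raise StageError("associate", "requires stage 'pls'; run it first")
            study = state["study"]
            pls = state["pls"]
            med_cell = study.config.mediation_cell_resolved
            bs = pls.brainscores_[0][med_cell[1]]
            symptoms = study.symptoms.loc[bs.index]
            rows = []
            for grp in study.config.groups:
                ids = symptoms.index[symptoms["sex"] == grp]
                for col in ("anhedonia", "anxious_arousal",
                            "general_distress_depression", "general_distress_anxiety"):
                    r, r2, p = brainscore_symptom_corr(
                        bs.loc[ids], symptoms.loc[ids, col]
                    )
                    rows.append({"group": grp, "symptom": col, "r": r,
                                 "r2": r2, "p": p})
            pd.DataFrame(rows).to_csv(outdir / "associations.tsv", sep="\t", index=False)
            state["assoc"] = pd.DataFrame(rows)
            record("associate", [outdir / "associations.tsv"], t0)

        if enabled["mediate"]:
            t0 = time.time()
            if "pls" not in state:
                raise StageError("mediate", "requires stage 'pls'; run it first")
            study = state["study"]
            pls = state["pls"]
            med_cell = study.config.mediation_cell_resolved
            bs = pls.brainscores_[0][med_cell[1]]
            symptoms = study.symptoms.loc[bs.index]
            score = state["tprs"].scores.loc[symptoms.index]
            res = mediate(
                score, bs.loc[symptoms.index], symptoms["anhedonia"],
                strata=symptoms["sex"], n_boot=config.mediation_n_boot,
                seed=stage_seed(config.seed, "mediate"),
            )
            rows = []
            for lab, m in res.items():
                if lab == "_moderation":
                    continue
                rows.append(
                    {"stratum": lab, "a": m.a, "b": m.b, "ab": m.ab,
                     "se_ab": m.se_ab, "ci_lo": m.ci_ab[0], "ci_hi": m.ci_ab[1],
                     "n": m.n}
                )
            pd.DataFrame(rows).to_csv(outdir / "mediation.tsv", sep="\t", index=False)
            state["mediation"] = res
            record("mediate", [outdir / "mediation.tsv"], t0)
    except StageError:
        raise
    except Exception as exc:  # annotate with the failing stage
        done = set(manifest.stages)
        current = next((s for s in STAGES if enabled[s] and s not in done), "?")
        raise StageError(current, str(exc)) from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(outdir / "manifest.json")
    state["manifest"] = manifest
    return manifest
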