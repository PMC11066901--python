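"""Pipeline orchestration: extract → profile → essentiality → drugs → rank.

One config drives the full chain.  Per subtype: consensus model
building, exchange profiling, single-gene essentiality and the
single-drug screen; across subtypes: the combination screen with
Bliss classification, subtype specificity, the healthy-control safety
check and evidence-based prioritization.  Every artifact is written
as TSV/JSON under the output directory together with a manifest
(input hashes, thresholds, seed) that suffices to reproduce the run;
identical config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .context import (
    CONSENSUS_Q_DEFAULT,
    P_HI_DEFAULT,
    P_LO_DEFAULT,
    build_consensus_model,
    consensus_assignment,
    discretize_expression,
    map_calls_to_reactions,
    read_expression,
)
from .drugs import (
    BLISS_TOL_DEFAULT,
    HIT_CUTOFF_DEFAULT,
    SAFETY_ETA_DEFAULT,
    read_drug_catalog,
    safety_check,
    screen_combinations,
    screen_single_drugs,
    subtype_specificity,
)
from .essentiality import (
    ESSENTIALITY_CUTOFF_DEFAULT,
    annotate_common_essentials,
    classify_essential,
    read_gene_list,
    single_gene_deletion,
)
from .exchanges import (
    NARROW_RATIO_DEFAULT,
    classify_narrow_bounded,
    compare_exchange_profiles,
    profile_exchanges,
)
from .lp import EPSILON_FLUX, fba
from .network import apply_medium, read_medium, read_network, write_network
from .ranking import RulesConfig, compute_potency, rank_candidates, read_evidence

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # input paths
    network: str = ""
    expression: str = ""
    subtypes: str = ""
    medium: str = ""
    drug_catalog: str = ""
    evidence_dir: str = ""
    common_essentials: str = ""  # optional one-gene-per-line reference list
    control_group: str = "CTRL"
    # thresholds
    fraction: float = 1.0  # FVA optimality fraction
    epsilon: float = EPSILON_FLUX  # flux-consistency threshold
    consensus_q: float = CONSENSUS_Q_DEFAULT
    consensus_mode: str = "agreement"  # or "pooled"
    p_hi: float = P_HI_DEFAULT
    p_lo: float = P_LO_DEFAULT
    cutoff: float = HIT_CUTOFF_DEFAULT  # growth-reduction hit/essentiality cutoff
    bliss_tol: float = BLISS_TOL_DEFAULT
    eta: float = SAFETY_ETA_DEFAULT
    ratio_cutoff: float = NARROW_RATIO_DEFAULT
    # run control
    seed: int = 1
    outdir: str = "pipeline_out"

    def validate(self) -> None:
        checks = [
            ("fraction", self.fraction, 0.0, 1.0),
            ("consensus_q", self.consensus_q, 0.0, 1.0),
            ("cutoff", self.cutoff, 0.0, 1.0),
            ("bliss_tol", self.bliss_tol, 0.0, 1.0),
            ("eta", self.eta, 0.0, 1.0),
            ("ratio_cutoff", self.ratio_cutoff, 0.0, 1.0),
            ("p_hi", self.p_hi, 0.0, 1.0),
            ("p_lo", self.p_lo, 0.0, 1.0),
        ]
        for name, value, lo, hi in checks:
            if not (lo < value <= hi):
                raise ValueError(f"config {name}={value} outside ({lo}, {hi}]")
        if self.epsilon <= 0:
            raise ValueError(f"config epsilon={self.epsilon} must be positive")
        if self.consensus_mode not in {"agreement", "pooled"}:
            raise ValueError(f"unknown consensus_mode {self.consensus_mode!r}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_file(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the full chain and write a report bundle to ``outdir``.

    Returns the in-memory results keyed by stage.  Any stage failure
    raises :class:`PipelineError` naming the stage; outputs written so
    far remain on disk next to a ``FAILED`` marker naming the stage.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {}
    stage = "load"
    try:
        network = read_network(config.network)
        medium = read_medium(config.medium)
        profile = read_expression(config.expression, config.subtypes)
        catalog = read_drug_catalog(config.drug_catalog)
        evidence = read_evidence(config.evidence_dir)
        groups = profile.subtype_names
        tumor_groups = [g for g in groups if g != config.control_group]
        if not tumor_groups:
            raise ValueError("no tumor sample groups found in subtype labels")

        # -- context-specific models -------------------------------------
        stage = "extract"
        calls = discretize_expression(profile, config.p_hi, config.p_lo, seed=config.seed)
        models = {}
        qc_rows = []
        build_groups = list(tumor_groups)
        if config.control_group in groups:
            build_groups.append(config.control_group)
        for group in build_groups:
            samples = profile.samples_of(group)
            assignments = [map_calls_to_reactions(network, calls, s) for s in samples]
            if config.consensus_mode == "pooled":
                # pool calls by per-gene majority before mapping
                pooled = calls.calls[samples].sum(axis=1)
                pooled_calls = pooled.apply(lambda v: 1 if v > 0 else (-1 if v < 0 else 0))
                pooled_df = pooled_calls.to_frame(name="pooled")
                from .context import GeneCalls

                assignments = [
                    map_calls_to_reactions(network, GeneCalls(pooled_df), "pooled")
                ]
            model = build_consensus_model(
                network, assignments, medium,
                q=config.consensus_q, epsilon=config.epsilon, model_id=group,
            )
            models[group] = model
            growth = fba(apply_medium(model, medium))
            qc_rows.append({
                "model": group,
                "selected_samples": len(samples),
                "reactions": len(model.reactions),
                "metabolites": len(model.metabolites),
                "genes": len(model.genes),
                "growth_rate": growth.objective_value,
            })
            write_network(model, out / f"model_{group}.json", "json")
        qc = pd.DataFrame(qc_rows).set_index("model")
        _write_tsv(qc, out / "model_qc.tsv")
        results["models"] = models
        results["model_qc"] = qc

        tumor_models = [models[g] for g in tumor_groups]
        control_model = models.get(config.control_group)

        # -- exchange profiling --------------------------------------------
        stage = "exchanges"
        profiles = {}
        for group in tumor_groups:
            prof = profile_exchanges(models[group], medium, config.fraction,
                                     config.ratio_cutoff)
            profiles[group] = prof
            _write_tsv(prof, out / f"exchanges_{group}.tsv")
        if len(profiles) >= 2:
            comparison = compare_exchange_profiles(list(profiles.values()))
            _write_tsv(comparison, out / "exchange_comparison.tsv", index=False)
            results["exchange_comparison"] = comparison
        results["exchange_profiles"] = profiles
        results["narrow_exchanges"] = {
            g: classify_narrow_bounded(p, config.ratio_cutoff) for g, p in profiles.items()
        }

        # -- essentiality ---------------------------------------------------
        stage = "essentiality"
        reference = read_gene_list(config.common_essentials) if config.common_essentials else []
        essentials = {}
        for group in tumor_groups:
            screen = single_gene_deletion(models[group], medium, cutoff=config.cutoff)
            ess = classify_essential(screen, config.cutoff)
            annotated = annotate_common_essentials(ess, reference)
            screen["common_essential"] = screen.index.map(
                lambda g: bool(annotated["common_essential"].get(g, False))
            )
            essentials[group] = screen
            _write_tsv(screen, out / f"essentiality_{group}.tsv")
        results["essentiality"] = essentials

        # -- drug screens -----------------------------------------------------
        stage = "drugs"
        single = {}
        for group in tumor_groups:
            res = screen_single_drugs(models[group], medium, catalog, config.cutoff)
            single[group] = res
            _write_tsv(res, out / f"drugs_single_{group}.tsv")
        single_long = pd.concat([df.reset_index() for df in single.values()],
                                ignore_index=True)
        single_spec = subtype_specificity(single_long, ["drug"])
        _write_tsv(single_spec, out / "drugs_single_specificity.tsv", index=False)
        results["single_drugs"] = single
        results["single_specificity"] = single_spec

        stage = "combos"
        combos = screen_combinations(
            tumor_models, medium, catalog, config.cutoff, config.bliss_tol,
            single_results=single,
        )
        _write_tsv(combos, out / "drug_combinations.tsv", index=False)
        combo_spec = subtype_specificity(combos, ["drug_a", "drug_b"])
        _write_tsv(combo_spec, out / "drug_combination_specificity.tsv", index=False)
        results["combinations"] = combos
        results["combination_specificity"] = combo_spec

        safety_rows = []
        if control_model is not None:
            reported = combos[combos["hit"]][["drug_a", "drug_b"]].drop_duplicates()
            for _, row in reported.iterrows():
                a = catalog.drugs[row["drug_a"]]
                b = catalog.drugs[row["drug_b"]]
                check = safety_check(control_model, medium,
                                     set(a.targets) | set(b.targets), config.eta)
                safety_rows.append({
                    "drug_a": a.id, "drug_b": b.id,
                    "safety_pass": check["pass"],
                    "biomass_ratio": check["biomass_ratio"],
                    "atp_ratio": check["atp_ratio"],
                })
        safety = pd.DataFrame.from_records(
            safety_rows,
            columns=["drug_a", "drug_b", "safety_pass", "biomass_ratio", "atp_ratio"],
        )
        _write_tsv(safety, out / "combination_safety.tsv", index=False)
        results["combination_safety"] = safety

        # -- prioritization -----------------------------------------------------
        stage = "rank"
        hit_singles = sorted(
            {d for df in single.values() for d in df.index[df["hit"]]}
        )
        hit_pairs = combos[combos["hit"]][["drug_a", "drug_b"]].drop_duplicates()
        combo_members = {
            f"{r.drug_a}+{r.drug_b}": (r.drug_a, r.drug_b)
            for r in hit_pairs.itertuples()
        }
        candidates = hit_singles + sorted(combo_members)
        potency = compute_potency(evidence)
        antibc_ids = [d.id for d in catalog.of_category("AntiBC")]
        antibc_potencies = potency[potency.index.isin(antibc_ids)]
        reference_potency = (
            float(antibc_potencies.median()) if len(antibc_potencies) else None
        )
        ranking, audit = rank_candidates(
            candidates, evidence, RulesConfig(),
            reference_potency=reference_potency, combo_members=combo_members,
        )
        _write_tsv(ranking, out / "drug_ranking.tsv", index=False)
        audit_df = pd.DataFrame.from_records(audit, columns=["drug", "action", "reasons"])
        _write_tsv(audit_df, out / "ranking_audit.tsv", index=False)
        results["ranking"] = ranking
        results["ranking_audit"] = audit_df

        # -- manifest ----------------------------------------------------------
        stage = "manifest"
        input_paths = {
            k: getattr(config, k)
            for k in ("network", "expression", "subtypes", "medium", "drug_catalog")
            if getattr(config, k)
        }
        manifest = {
            "version": __version__,
            "config": dataclasses.asdict(config),
            "input_sha256": {k: _sha256(v) for k, v in input_paths.items()},
            "models": sorted(models),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        results["manifest"] = manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    return results
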