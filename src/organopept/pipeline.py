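"""End-to-end pipeline orchestration with a single YAML config.

Stages run in dependency order — simulate/fixture -> variant filter ->
neoantigen enumeration -> peptidome assembly -> differential analysis
-> funnel — each writing plain-text artifacts stamped with the config
hash and seed.  Rerunning with an identical config is byte-identical
except for timestamps.  All thresholds default to the study protocol
values (tumor VAF 0.10, strong rank 0.5, weak rank 2.0, q 0.05,
fold 2, HLA-II minimum length 12, clonal CCF 0.7) and are surfaced as
named keys so sensitivity analyses are one-line config edits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import differential, funnel as funnel_mod, neoantigens, peptidome, variants
from .synthetic import (
    SimConfig,
    build_binding_model,
    build_reference_fixture,
    generate_expression,
    generate_mutations,
    generate_proteome,
    ifng_gene_set,
    simulate_evidence,
    write_proteome_fasta,
)

logger = logging.getLogger("organopept")


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("[organopept:%(funcName)s] %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run configuration; every study threshold is a named key."""

    out_dir: str = "organopept_out"
    source: str = "simulate"  # simulate | fixture
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {
            "filter": True,
            "enumerate": True,
            "assemble": True,
            "diff": True,
            "funnel": True,
        }
    )
    thresholds: dict = field(
        default_factory=lambda: {
            "tumor_vaf_min": variants.TUMOR_VAF_MIN,
            "strong_rank": funnel_mod.STRONG_RANK_THRESHOLD,
            "weak_rank": funnel_mod.WEAK_RANK_THRESHOLD,
            "q_value": differential.Q_THRESHOLD,
            "fold_change": 2.0,
            "hla2_min_length": peptidome.HLA_II_MIN_LENGTH,
            "ccf_clonal": variants.CCF_CLONAL_THRESHOLD,
        }
    )
    simulation: dict = field(default_factory=dict)
    ifng_gene_list: str | None = None

    def validate(self) -> None:
        if self.source not in ("simulate", "fixture"):
            raise ValueError(f"unknown source {self.source!r}")
        for key, value in self.thresholds.items():
            if value <= 0:
                raise ValueError(f"threshold {key} must be positive")
        if self.source == "simulate" and self.stages.get("diff"):
            conditions = self.simulation.get("conditions", ("untreated",))
            if len(conditions) < 2:
                raise ValueError(
                    "differential stage needs >= 2 conditions in "
                    "simulation.conditions"
                )

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.simulation)
        for key in ("conditions", "allotypes", "protein_length_range",
                    "replicate_design"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        kwargs.setdefault("seed", self.seed)
        return SimConfig(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        base = cls()
        for key, value in data.items():
            if not hasattr(base, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(base, key), dict) and isinstance(value, dict):
                merged = dict(getattr(base, key))
                merged.update(value)
                setattr(base, key, merged)
            else:
                setattr(base, key, value)
        return base

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )


def _fixture_stage(out: Path, seed: int) -> dict:
    fx = build_reference_fixture(seed=seed)
    fx["candidates"].to_csv(out / "candidates.tsv", sep="\t", index=False)
    fx["detected_neoantigens"].to_csv(out / "detected_neoantigens.tsv", sep="\t", index=False)
    fx["mutations"].to_csv(out / "mutations.tsv", sep="\t", index=False)
    write_proteome_fasta(fx["wt_contexts"], out / "wt_contexts.fasta")
    return fx


def run_fixture_funnel(fixture: dict) -> dict:
    """Enumeration + detection matching + funnel on the in-print fixture.

    Builds mutant proteins from the three published missense mutations,
    enumerates their candidate windows, matches the published detected
    ligand list against them, and assembles the funnel across all 612
    candidate mutations.
    """
    proteome = {p.protein_id: p for p in fixture["wt_contexts"]}
    mutants = neoantigens.mutant_records_from_table(
        fixture["mutations"], proteome
    )
    detected_ligands = fixture["detected_neoantigens"]["mut_peptide"].tolist()
    hits = neoantigens.match_detected_to_mutations(
        detected_ligands, list(proteome.values()), mutants
    )
    summary = funnel_mod.funnel_from_flags(
        fixture["candidates"], hits["mutation_id"]
    )
    # per-mutation candidate enumeration check: each published mutant
    # ligand must be among its mutation's candidate windows
    n_candidates = {}
    for rec, (_, mrow) in zip(mutants, fixture["mutations"].iterrows()):
        wt = proteome[rec.protein_id]
        cands = neoantigens.enumerate_candidates(
            wt.sequence, rec.sequence, rec.mutated_positions, rec.mutation_id
        )
        n_candidates[rec.mutation_id] = len(cands)
    return {
        "funnel": summary.to_dict(),
        "detected_hits": hits.to_dict(orient="records"),
        "n_enumerated_per_detected_mutation": n_candidates,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the consolidated report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": 1,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    if config.source == "fixture":
        try:
            fx = _fixture_stage(out, seed=config.seed or 612)
            if config.stages.get("funnel", True):
                report["fixture_funnel"] = run_fixture_funnel(fx)
        except Exception as exc:  # noqa: BLE001
            raise StageError("fixture", exc) from exc
        _write_report(report, out)
        return report

    # ---- simulation source -------------------------------------------
    sim = config.sim_config()
    try:
        proteome = generate_proteome(sim)
        expression = generate_expression(proteome, sim)
        model = build_binding_model(sim.allotypes, sim)
        mutations = generate_mutations(proteome, sim)
        write_proteome_fasta(proteome, out / "proteome.fasta")
        expression.to_csv(out / "expression.tsv", sep="\t", index=False)
        mutations.to_csv(out / "mutations.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc
    logger.info("simulated %d proteins, %d mutations", len(proteome),
                len(mutations))

    retained = mutations
    if config.stages.get("filter", True):
        try:
            retained, rejects = variants.filter_somatic(mutations)
            retained.to_csv(out / "retained_variants.tsv", sep="\t",
                            index=False)
            rejects.to_csv(out / "rejected_variants.tsv", sep="\t",
                           index=False)
            clonal = variants.classify_clonality(retained["ccf"])
            report["variants"] = {
                "n_input": len(mutations),
                "n_retained": len(retained),
                "n_rejected": len(rejects),
                "n_clonal": int((clonal == "clonal").sum()),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("filter", exc) from exc

    candidates = pd.DataFrame(
        columns=["peptide", "mutation_id", "gene_id", "protein_id"]
    )
    mutant_records: list = []
    if config.stages.get("enumerate", True):
        try:
            by_prot = {p.protein_id: p for p in proteome}
            rows = []
            enum_input = retained.rename(
                columns={"variant_id": "mutation_id"}
            )
            mutant_records = neoantigens.mutant_records_from_table(
                enum_input, by_prot
            )
            for rec in mutant_records:
                wt = by_prot[rec.protein_id]
                for c in neoantigens.enumerate_candidates(
                    wt.sequence, rec.sequence, rec.mutated_positions,
                    rec.mutation_id,
                ):
                    rows.append(
                        dict(peptide=c.sequence, mutation_id=rec.mutation_id,
                             gene_id=wt.gene_id, protein_id=wt.protein_id)
                    )
            candidates = pd.DataFrame(
                rows,
                columns=["peptide", "mutation_id", "gene_id", "protein_id"],
            ).drop_duplicates("peptide")
            candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
            report["enumeration"] = {
                "n_candidate_mutations": len(mutant_records),
                "n_candidate_peptides": len(candidates),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("enumerate", exc) from exc

    try:
        # exclude candidate peptides present anywhere in the wild type
        wt_join = "|".join(p.sequence for p in proteome)
        spike = candidates[
            ~candidates["peptide"].map(lambda p: p in wt_join)
        ]
        evidence, truth = simulate_evidence(
            proteome, expression, model, sim, candidates=spike
        )
        evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)
        truth.to_json(out / "ground_truth.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate-evidence", exc) from exc

    presence = None
    if config.stages.get("assemble", True):
        try:
            presence = peptidome.call_presence(evidence)
            presence.to_csv(out / "presence.tsv", sep="\t", index=False)
            counts = peptidome.count_unique_peptides(presence, "I")
            report["assembly"] = {
                "n_present": {
                    f"{s}/{c}": int(n) for (s, c), n in counts.items()
                },
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("assemble", exc) from exc

    if config.stages.get("diff", True) and presence is not None:
        try:
            conditions = sim.conditions
            matrix = differential.build_intensity_matrix(evidence)
            matrix = differential.normalize_matrix(matrix)
            matrix = differential.impute_missing(matrix, seed=sim.seed + 1)
            results = differential.test_differential(
                matrix, treated=conditions[1], untreated=conditions[0]
            )
            gene_map = dict(zip(evidence["peptide"], evidence["gene_id"]))
            if config.ifng_gene_list:
                ifng_genes = funnel_mod.read_gene_list(config.ifng_gene_list)
            else:
                ifng_genes = sorted(ifng_gene_set(proteome, sim))
            annotated, summary = differential.annotate_results(
                results, ifng_genes, gene_map
            )
            annotated.to_csv(out / "differential.tsv", sep="\t", index=False)
            (out / "volcano.json").write_text(
                json.dumps(differential.volcano_data(annotated)[:5000])
            )
            report["differential"] = summary
        except Exception as exc:  # noqa: BLE001
            raise StageError("diff", exc) from exc

    if config.stages.get("funnel", True) and len(candidates):
        try:
            detected_peps = (
                set(presence["peptide"]) if presence is not None else set()
            )
            hits = neoantigens.match_detected_to_mutations(
                detected_peps, proteome, mutant_records
            )
            summary = funnel_mod.build_funnel(
                candidates, model, sim.allotypes, expression, hits
            )
            report["funnel"] = summary.to_dict()
        except Exception as exc:  # noqa: BLE001
            raise StageError("funnel", exc) from exc

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "report.txt").write_text(render_report(report))


def render_report(report: dict) -> str:
    """Human-readable one-page summary of a report bundle."""
    lines = [
        "organopept report",
        f"  config hash: {report.get('config_hash', '-')}",
        f"  seed:        {report.get('seed', '-')}",
    ]
    if "variants" in report:
        v = report["variants"]
        lines.append(
            f"  variants: {v['n_retained']}/{v['n_input']} retained, "
            f"{v['n_clonal']} clonal"
        )
    if "enumeration" in report:
        e = report["enumeration"]
        lines.append(
            f"  candidates: {e['n_candidate_peptides']} peptides from "
            f"{e['n_candidate_mutations']} mutations"
        )
    if "assembly" in report:
        for key, n in report["assembly"]["n_present"].items():
            lines.append(f"  present peptides [{key}]: {n}")
    if "differential" in report:
        d = report["differential"]
        lines.append(
            f"  differential: {d['n_significant']} significant "
            f"({d['n_up']} up / {d['n_down']} down), "
            f"chymo fraction {d['chymo_fraction']:.3f}"
        )
    for key in ("funnel", "fixture_funnel"):
        if key in report:
            f = report[key]["funnel"] if key == "fixture_funnel" else report[key]
            lines.append(
                f"  funnel: {f['n_candidate_mutations']} candidates -> "
                f"{f['n_strong_binder_mutations']} strong -> "
                f"{f['n_expressed_strong_binder_mutations']} expressed -> "
                f"{f['n_ms_detected_mutations']} MS-detected "
                f"({f['pct_detected']:.2f}%)"
            )
    return "\n".join(lines) + "\n"


def write_report(stage_outputs: dict, path: str | Path) -> dict:
    """Aggregate stage outputs into one JSON document + text summary."""
    report = {"schema_version": 1}
    report.update(stage_outputs)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_report(report, path)
    return report
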