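"""End-to-end orchestration: simulate -> preprocess -> network (per
condition) -> correlate -> preserve -> score -> scan.

A :class:`RunConfig` (loadable from YAML) toggles stages and carries their
parameters; :func:`run` executes the enabled stages in order, writes each
stage's artifacts under the output directory, and returns a machine-
readable report.  Any stage failure halts the run with a report naming the
stage; a stage whose upstream output is missing fails with an error naming
the producing stage.

All randomness derives from the single config seed through stable
per-stage sub-seeds, so disabling one stage never shifts another stage's
draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, io, motifscan, preprocess, synthdata
from .network import CoexpressionNetwork
from .preservation import ModulePreservation
from .synthdata import SynthConfig
from .traits import ModuleTraitAnalysis

__all__ = ["RunConfig", "run", "stage_seed"]

STAGES = ("simulate", "preprocess", "network", "correlate", "preserve", "score", "scan")


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2^31, derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Stage toggles and parameters for one pipeline run."""

    outdir: str = "coexnet_run"
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    preprocess: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    preserve: dict = field(default_factory=dict)
    score: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        stages = {s: True for s in STAGES}
        stages.update(cfg.stages or {})
        bad = set(stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        cfg.stages = stages
        return cfg

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _require(outputs: dict, key: str, producer: str):
    if key not in outputs:
        raise RuntimeError(
            f"missing upstream output {key!r}: enable or run the {producer!r} stage first"
        )
    return outputs[key]


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = config.resolved()
    report: dict = {
        "seed": config.seed,
        "parameters": resolved,
        "parameter_hash": hashlib.sha256(
            json.dumps(resolved, sort_keys=True).encode()
        ).hexdigest()[:16],
        "stages": {},
    }
    outputs: dict = {}

    stage = None
    try:
        if config.stages.get("simulate"):
            stage = "simulate"
            info = _stage_simulate(config, outdir, outputs)
            report["stages"][stage] = info
        if config.stages.get("preprocess"):
            stage = "preprocess"
            report["stages"][stage] = _stage_preprocess(config, outdir, outputs)
        if config.stages.get("network"):
            stage = "network"
            report["stages"][stage] = _stage_network(config, outdir, outputs)
        if config.stages.get("correlate"):
            stage = "correlate"
            report["stages"][stage] = _stage_correlate(outdir, outputs)
        if config.stages.get("preserve"):
            stage = "preserve"
            report["stages"][stage] = _stage_preserve(config, outdir, outputs)
        if config.stages.get("score"):
            stage = "score"
            report["stages"][stage] = _stage_score(outdir, outputs)
        if config.stages.get("scan"):
            stage = "scan"
            report["stages"][stage] = _stage_scan(config, outdir, outputs)
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        io.write_json(report, outdir / "report.json")
        raise
    io.write_json(report, outdir / "report.json")
    return report


def _stage_simulate(config: RunConfig, outdir: Path, outputs: dict) -> dict:
    seed = stage_seed(config.seed, "simulate")
    synth_kwargs = dict(config.synth)
    synth_kwargs.setdefault("seed", seed)
    if "module_sizes" in synth_kwargs:
        synth_kwargs["module_sizes"] = tuple(synth_kwargs["module_sizes"])
    scfg = SynthConfig(**synth_kwargs)
    expr, truth = synthdata.generate_expression(scfg)
    traits = synthdata.generate_traits(truth, scfg, seed=seed + 1)
    expr2, truth2 = synthdata.generate_condition2(expr, truth, scfg, seed=seed + 2)
    rng = np.random.default_rng(seed + 3)
    lengths = pd.Series(
        rng.integers(300, 12000, expr.shape[0]).astype(float), index=expr.index, name="length"
    )
    counts = synthdata.generate_counts(expr, lengths, 2e7, seed=seed + 4)
    annotations = synthdata.generate_annotations(truth, n_terms=100, seed=seed + 5)
    interactions = synthdata.generate_interactions(truth, seed=seed + 6)
    pwm = motifscan.pwm_from_counts(synthdata.default_pwm_counts(), name="synthetic_forkhead")
    promoters, offsets = synthdata.generate_promoters(
        pwm, n=200, motif_rate=0.5, seed=seed + 7
    )

    io.write_matrix_tsv(counts, outdir / "counts.tsv")
    io.write_matrix_tsv(expr, outdir / "expr.tsv")
    io.write_matrix_tsv(expr2, outdir / "expr_condition2.tsv")
    lengths.to_frame().to_csv(outdir / "gene_lengths.tsv", sep="\t")
    traits.to_csv(outdir / "traits.tsv", sep="\t")
    annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    interactions.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    io.write_fasta(promoters, outdir / "promoters.fasta")
    truth_payload = {
        "labels": truth.labels.to_dict(),
        "preserved_modules": list(truth.preserved_modules),
        "trait_couplings": {t: list(v) for t, v in truth.trait_couplings.items()},
        "motif_offsets": offsets.to_dict(orient="records"),
    }
    io.write_json(truth_payload, outdir / "truth.json")

    outputs.update(
        expr=expr, expr2=expr2, truth=truth, traits=traits, counts=counts,
        lengths=lengths, annotations=annotations, interactions=interactions,
        promoters=promoters, motif_offsets=offsets, pwm=pwm,
    )
    return {
        "n_genes": int(expr.shape[0]),
        "n_samples": int(expr.shape[1]),
        "n_modules": int(len(scfg.module_sizes)),
        "seed": seed,
    }


def _stage_preprocess(config: RunConfig, outdir: Path, outputs: dict) -> dict:
    counts = _require(outputs, "counts", "simulate")
    lengths = _require(outputs, "lengths", "simulate")
    expr, rep = preprocess.preprocess_counts(counts, lengths, **config.preprocess)
    io.write_matrix_tsv(expr, outdir / "expr_preprocessed.tsv")
    outputs["expr_preprocessed"] = expr
    return rep.to_dict()


def _stage_network(config: RunConfig, outdir: Path, outputs: dict) -> dict:
    expr = _require(outputs, "expr", "simulate")
    res = CoexpressionNetwork(expr, **config.network).fit()
    outputs["network"] = res
    res.gene_table().to_csv(outdir / "modules.tsv", sep="\t")
    res.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
    res.network.edge_list(min_weight=0.1).to_csv(outdir / "edges.tsv", sep="\t", index=False)
    return {
        "power": res.power,
        "n_modules": len(res.modules.module_names),
        "n_assigned": int((res.labels != "grey").sum()),
        "converged": res.converged,
        "grey_per_iteration": res.grey_per_iteration,
    }


def _stage_correlate(outdir: Path, outputs: dict) -> dict:
    net = _require(outputs, "network", "network")
    traits = _require(outputs, "traits", "simulate")
    res = ModuleTraitAnalysis(net.eigengenes, traits).fit()
    res.table.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
    from .traits import gene_significance

    gs = gene_significance(net.expression(), traits)
    gs.to_csv(outdir / "gene_significance.tsv", sep="\t")
    outputs["module_trait"] = res
    outputs["gene_significance"] = gs
    return {
        "n_significant_uncorrected": int((res.table["p"] <= 0.05).sum()),
        "n_pass_fdr": int(res.table["pass"].sum()),
    }


def _stage_preserve(config: RunConfig, outdir: Path, outputs: dict) -> dict:
    net = _require(outputs, "network", "network")
    expr2 = _require(outputs, "expr2", "simulate")
    kwargs = dict(n_perm=100, seed=stage_seed(config.seed, "preserve"))
    kwargs.update(config.preserve)
    res = ModulePreservation(net.expression(), expr2, net.labels, **kwargs).fit()
    res.table.to_csv(outdir / "preservation.tsv", sep="\t", index=False)
    outputs["preservation"] = res
    return {
        "n_modules": len(res.table),
        "preserved": res.preserved(),
        "not_preserved": res.not_preserved(),
    }


def _stage_score(outdir: Path, outputs: dict) -> dict:
    net = _require(outputs, "network", "network")
    annotations = _require(outputs, "annotations", "simulate")
    interactions = _require(outputs, "interactions", "simulate")
    gs = _require(outputs, "gene_significance", "correlate")
    kme_own = net.modules.own_kme()
    terms = annotate.score_terms(
        annotations, net.labels, kme_own, gs_trait=gs.iloc[:, 0]
    )
    terms.to_csv(outdir / "term_scores.tsv", sep="\t", index=False)
    stats = pd.DataFrame(
        {"kIN": net.modules.k["kIN"], "gs": gs.iloc[:, 0].reindex(net.labels.index)}
    )
    ranked = annotate.scale_interactions(interactions, stats, metric=1)
    ranked.to_csv(outdir / "interactions_ranked.tsv", sep="\t", index=False)
    return {"n_term_scores": len(terms), "n_ranked_edges": len(ranked)}


def _stage_scan(config: RunConfig, outdir: Path, outputs: dict) -> dict:
    promoters = _require(outputs, "promoters", "simulate")
    pwm = _require(outputs, "pwm", "simulate")
    kwargs = dict(min_relative=0.80)
    kwargs.update(config.scan)
    hits = motifscan.scan_promoters(promoters, pwm, **kwargs)
    hits.to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
    return {"n_hits": len(hits), "n_promoters_hit": int(hits["seq_id"].nunique())}
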