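"""End-to-end orchestration: profile -> cluster -> ages -> curves ->
enrichment -> losses -> PTM analysis, with a machine-readable manifest.

A run is fully determined by its config (a YAML mapping) and the root
seed; each stage writes one TSV/JSON under the output directory and the
manifest echoes parameters, per-stage status and row counts.  Stages
whose inputs are not configured are skipped and noted as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import DEFAULT_SCALE, GeneAnnotation, load_tree_files
from .enrichment import age_enrichment_report
from .gene_age import (
    age_from_reconstruction,
    ages_table,
    assign_age_oldest_hit,
    dollo_reconstruct,
    emergence_curves,
    wagner_reconstruct,
)
from .profiles import (
    PhyloProfile,
    build_profile,
    cluster_genes,
    detect_model_organism_losses,
    flag_isolated_hits,
    read_hits,
)
from .ptm import AgeCouplingModel, load_ptm_pairs


@dataclass
class PipelineConfig:
    tree: str
    groups: str
    outdir: str
    hits: str | None = None
    genes: str | None = None
    profile: str | None = None
    annotations: str | None = None
    background: str | None = None
    ptm_pairs: str | None = None
    loss_targets: list[str] = field(default_factory=list)
    min_score: float = 0.05
    gain_cost: float = 1.0
    loss_cost: float = 1.0
    discount_isolated: bool = False
    reps: int = 1000
    seed: int = 0
    jump_threshold: int = 3
    reference_species: str = "Hsa"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def read_annotations(path) -> list[GeneAnnotation]:
    """Annotation TSV: gene, subnetworks (|-separated), tiers (|-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        out.append(
            GeneAnnotation(
                gene=r["gene"],
                subnetworks=frozenset(str(r["subnetworks"]).split("|")),
                tiers=frozenset(str(r["tiers"]).split("|")),
            )
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scale = DEFAULT_SCALE
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in vars(config).items() if not isinstance(v, (list,))
        },
        "stages": {},
    }

    def stage(name: str, status: str, rows: int | None = None, output: str | None = None):
        manifest["stages"][name] = {"status": status, "rows": rows, "output": output}

    tree = load_tree_files(config.tree, config.groups, scale=scale)

    # -- profile -----------------------------------------------------------
    if config.profile:
        prof = PhyloProfile.read(config.profile)
    elif config.hits:
        hits = read_hits(config.hits)
        if config.genes:
            genes = [g.strip() for g in open(config.genes) if g.strip()]
        else:
            genes = sorted(set(hits["seed_gene"]))
        prof = build_profile(
            hits, genes, tree, min_score=config.min_score,
            seed_species=config.reference_species,
        )
    else:
        raise ValueError("config needs either 'profile' or 'hits'")
    prof = flag_isolated_hits(prof, tree)
    prof.write(outdir / "profile.tsv", outdir / "profile_flags.tsv")
    stage("profile", "ok", len(prof.genes), "profile.tsv")

    # -- cluster -----------------------------------------------------------
    if len(prof.genes) >= 2:
        order, Z = cluster_genes(prof)
        pd.DataFrame({"gene": order}).to_csv(
            outdir / "cluster_order.tsv", sep="\t", index=False
        )
        stage("cluster", "ok", len(order), "cluster_order.tsv")
    else:
        stage("cluster", "skipped")

    # -- ages (three methods) ---------------------------------------------
    all_ages = {}
    oldest = []
    for g in prof.genes:
        row = prof.matrix.loc[g]
        if row.sum() == 0:
            continue
        oldest.append(
            assign_age_oldest_hit(
                row, tree, scale,
                discount_isolated=config.discount_isolated,
                isolated=prof.isolated.loc[g],
                gene=g,
            )
        )
    all_ages["oldest"] = oldest
    dollo = []
    wagner = []
    for g in prof.genes:
        row = prof.matrix.loc[g]
        if row.sum() == 0:
            continue
        dollo.append(age_from_reconstruction(dollo_reconstruct(tree, row, gene=g), tree, scale))
        wagner.append(
            age_from_reconstruction(
                wagner_reconstruct(
                    tree, row, config.gain_cost, config.loss_cost, gene=g
                ),
                tree, scale, reference=config.reference_species,
            )
        )
    all_ages["dollo"] = dollo
    all_ages["wagner"] = wagner
    frames = [ages_table(v, scale) for v in all_ages.values()]
    ages_df = pd.concat(frames, ignore_index=True)
    ages_df.to_csv(outdir / "ages.tsv", sep="\t", index=False)
    stage("ages", "ok", len(ages_df), "ages.tsv")

    # -- emergence curves --------------------------------------------------
    annotations = read_annotations(config.annotations) if config.annotations else None
    curve_frames = []
    for method, ages in all_ages.items():
        for strat in ("none",) + (("tier", "subnetwork") if annotations else ()):
            for curve in emergence_curves(ages, annotations, scale, stratify_by=strat):
                df = curve.as_frame(scale)
                df.insert(0, "method", method)
                curve_frames.append(df)
    curves_df = pd.concat(curve_frames, ignore_index=True)
    curves_df.to_csv(outdir / "emergence_curves.tsv", sep="\t", index=False)
    stage("curves", "ok", len(curves_df), "emergence_curves.tsv")

    # -- enrichment --------------------------------------------------------
    if config.background:
        bg = pd.read_csv(config.background, sep="\t", dtype={"gene": str})
        report = age_enrichment_report(
            all_ages["oldest"], dict(zip(bg["gene"], bg["age_rank"])), scale
        )
        report.per_group.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        stage("enrichment", "ok", len(report.per_group), "enrichment.tsv")
    else:
        stage("enrichment", "skipped")

    # -- losses ------------------------------------------------------------
    if config.loss_targets:
        records = detect_model_organism_losses(prof, tree, config.loss_targets)
        pd.DataFrame(
            {
                "gene": [r.gene for r in records],
                "species": [r.species for r in records],
                "oldest_present_rank": [r.oldest_present_rank for r in records],
                "note": [r.note for r in records],
            }
        ).to_csv(outdir / "losses.tsv", sep="\t", index=False)
        stage("losses", "ok", len(records), "losses.tsv")
    else:
        stage("losses", "skipped")

    # -- ptm ---------------------------------------------------------------
    if config.ptm_pairs:
        net = load_ptm_pairs(config.ptm_pairs, scale=scale)
        results = AgeCouplingModel(net, config.jump_threshold).fit(
            n_reps=config.reps, seed=config.seed
        )
        results.to_json(outdir / "ptm_report.json")
        stage("ptm", "ok", len(net), "ptm_report.json")
    else:
        stage("ptm", "skipped")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
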