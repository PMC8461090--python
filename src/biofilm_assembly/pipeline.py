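"""Orchestration of the full study-shaped run.

Stages execute in order: rarefaction → alpha diversity → Bray-Curtis +
unweighted UniFrac → PCoA + NMDS → PERMANOVA (one factor at a time) →
assembly-process partitioning. Every stage writes a TSV under the output
directory and is seeded deterministically from one master seed, so a rerun
with the same configuration reproduces every numeric output bit for bit.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, diversity
from .assembly import NullModelConfig, quantify_assembly
from .community import CommunityTable

logger = logging.getLogger(__name__)

#: Factors tested by PERMANOVA, one-way each (the study's four contrasts).
PERMANOVA_FACTORS = ("day", "membrane_type", "surface_character", "flux")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run on one dataset."""

    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    scenario: str | None = None  # alternative to input paths
    depth: int = 4386
    seed: int = 0
    n_permutations: int = 999
    grouping: tuple[str, ...] = ("day",)
    biofilm_only: bool = True
    null_config: NullModelConfig | None = None
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        has_paths = self.table_path is not None
        if has_paths == (self.scenario is not None):
            raise ValueError("set exactly one of input paths or scenario")
        if self.depth < 1:
            raise ValueError("depth must be ≥ 1")


@dataclass
class RunManifest:
    """What a run produced: config echo, seeds, drops, outputs, timings."""

    config: RunConfig
    stage_seeds: dict[str, int] = field(default_factory=dict)
    dropped_samples: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        lines = ["# run manifest"]
        for k, v in vars(self.config).items():
            lines.append(f"config.{k}\t{v}")
        for k, v in self.stage_seeds.items():
            lines.append(f"seed.{k}\t{v}")
        lines.append(f"dropped_samples\t{','.join(self.dropped_samples) or '-'}")
        for k, v in self.stage_seconds.items():
            lines.append(f"seconds.{k}\t{v:.2f}")
        for f in self.outputs:
            lines.append(f"output\t{f}")
        path.write_text("\n".join(lines) + "\n")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed by hashing
    the stage name, so stages can be rerun in isolation."""
    h = hashlib.blake2b(f"{master}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2**31)


def export_top_taxa(
    table: CommunityTable, metadata: pd.DataFrame, n: int = 25, by: list[str] | None = None
) -> pd.DataFrame:
    """Mean relative abundance per metadata group of the ``n`` overall most
    abundant taxa — the tidy table behind a top-taxa heatmap."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if n > len(table.taxon_ids):
        logger.warning("n=%d exceeds %d taxa; truncating", n, len(table.taxon_ids))
        n = len(table.taxon_ids)
    by = by or ["day", "compartment"]
    rel = community.relative_abundance(table)
    overall = rel.mean(axis=0)
    top_idx = np.argsort(-overall)[:n]
    meta = metadata.set_index("sample_id").loc[table.sample_ids]
    groups = meta[by].astype(str).agg("|".join, axis=1).to_numpy()
    rows = []
    for level in pd.unique(groups):
        mask = groups == level
        means = rel[mask].mean(axis=0)
        for i in top_idx:
            rows.append(
                {
                    "group": level,
                    "taxon_id": table.taxon_ids[i],
                    "mean_relative_abundance": means[i],
                }
            )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> RunManifest:
    """Execute every stage of the pipeline and write all outputs.

    Returns the manifest; any stage failure raises with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config)
    stage = "load"
    t0 = time.time()
    try:
        if config.scenario is not None:
            from .simulate import ScenarioConfig, simulate_scenario

            sc_seed = stage_seed(config.seed, "simulate")
            manifest.stage_seeds["simulate"] = sc_seed
            study = simulate_scenario(ScenarioConfig(config.scenario, seed=sc_seed))
            table, tree, metadata = study.table, study.tree, study.metadata
        else:
            table = community.read_count_table(config.table_path)
            tree = community.read_tree(config.tree_path, expected_taxa=table.taxon_ids)
            metadata = community.read_metadata(config.metadata_path)
        community.join_metadata(table, metadata)  # consistency check
        manifest.stage_seconds[stage] = time.time() - t0

        # -- rarefy --------------------------------------------------------
        stage = "rarefy"
        t0 = time.time()
        seed = stage_seed(config.seed, stage)
        manifest.stage_seeds[stage] = seed
        manifest.dropped_samples = community.samples_below_depth(table, config.depth)
        rarefied = community.rarefy(table, config.depth, seed)
        p = out / "rarefied.tsv"
        community.write_count_table(rarefied, p)
        manifest.outputs.append(str(p))
        manifest.stage_seconds[stage] = time.time() - t0

        # -- alpha ---------------------------------------------------------
        stage = "alpha"
        t0 = time.time()
        alpha = diversity.alpha_diversity_table(rarefied)
        p = out / "alpha.tsv"
        alpha.to_csv(p, sep="\t", index=False)
        manifest.outputs.append(str(p))
        manifest.stage_seconds[stage] = time.time() - t0

        # -- beta ----------------------------------------------------------
        stage = "beta"
        t0 = time.time()
        bc = diversity.bray_curtis(rarefied)
        uf = diversity.unweighted_unifrac(rarefied, tree)
        for name, dm in (("bray_curtis", bc), ("unifrac", uf)):
            p = out / f"distance_{name}.tsv"
            dm.to_data_frame().to_csv(p, sep="\t", index_label="sample_id")
            manifest.outputs.append(str(p))
        manifest.stage_seconds[stage] = time.time() - t0

        # -- ordination ----------------------------------------------------
        stage = "ordination"
        t0 = time.time()
        seed = stage_seed(config.seed, stage)
        manifest.stage_seeds[stage] = seed
        nmds_res = diversity.nmds(bc, k=2, seed=seed)
        pcoa_res = diversity.pcoa(uf, k=2)
        ords = []
        for res in (nmds_res, pcoa_res):
            df = res.coordinates.copy()
            df.columns = ["axis1", "axis2"][: df.shape[1]]
            df.insert(0, "method", res.method)
            df.insert(
                1, "stat", res.values[0] if res.method == "nmds" else res.values[:1][0]
            )
            ords.append(df.reset_index(names="sample_id"))
        p = out / "ordination.tsv"
        pd.concat(ords).to_csv(p, sep="\t", index=False)
        manifest.outputs.append(str(p))
        manifest.stage_seconds[stage] = time.time() - t0

        # -- PERMANOVA -----------------------------------------------------
        stage = "permanova"
        t0 = time.time()
        seed = stage_seed(config.seed, stage)
        manifest.stage_seeds[stage] = seed
        meta = metadata.set_index("sample_id").loc[rarefied.sample_ids]
        rows = []
        for factor in PERMANOVA_FACTORS:
            if factor not in meta.columns:
                continue
            labels = meta[factor].astype(str).to_numpy()
            informative = labels != "n/a"
            ids = [s for s, k in zip(rarefied.sample_ids, informative) if k]
            if len(set(labels[informative])) < 2 or len(ids) < 4:
                logger.warning("PERMANOVA factor %r skipped (too few levels)", factor)
                continue
            sub = bc.filter(ids)
            res = diversity.permanova(
                sub, meta.loc[ids, factor].astype(str), config.n_permutations, seed
            )
            rows.append(
                {
                    "factor": factor,
                    "pseudo_F": res.pseudo_f,
                    "R2": res.r2,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                }
            )
        p = out / "permanova.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        manifest.outputs.append(str(p))
        manifest.stage_seconds[stage] = time.time() - t0

        # -- assembly ------------------------------------------------------
        stage = "assembly"
        t0 = time.time()
        seed = stage_seed(config.seed, stage)
        manifest.stage_seeds[stage] = seed
        ncfg = config.null_config or NullModelConfig()
        ncfg = NullModelConfig(
            n_null=ncfg.n_null,
            bnri_threshold=ncfg.bnri_threshold,
            rc_threshold=ncfg.rc_threshold,
            bin_size_min=ncfg.bin_size_min,
            ds_cut=ncfg.ds_cut,
            ds_quantile=ncfg.ds_quantile,
            abundance_weighted=ncfg.abundance_weighted,
            seed=seed,
        )
        atable = rarefied
        if config.biofilm_only and "compartment" in meta.columns:
            keep = [
                s
                for s in rarefied.sample_ids
                if meta.loc[s, "compartment"] == "biofilm"
            ]
            if len(keep) >= 2:
                atable = rarefied.select_samples(keep)
        result = quantify_assembly(atable, tree, metadata, list(config.grouping), ncfg)
        for name, df in (
            ("assembly_groups", result.group_fractions.reset_index()),
            ("assembly_pairs", result.pair_fractions),
            ("pair_bin_scores", result.pair_bin_scores),
            ("bins", result.bins),
        ):
            p = out / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False, float_format="%.10g")
            manifest.outputs.append(str(p))
        manifest.stage_seconds[stage] = time.time() - t0
    except Exception as exc:  # annotate failures with the stage
        partial = out / "manifest.txt"
        manifest.write(partial)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    mpath = out / "manifest.txt"
    manifest.write(mpath)
    manifest.outputs.append(str(mpath))
    missing = [f for f in manifest.outputs if not Path(f).exists()]
    if missing:
        raise RuntimeError(f"manifest lists missing outputs: {missing}")
    return manifest
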