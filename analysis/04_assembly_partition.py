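"""Partition biofilm community turnover into the five assembly processes.

Runs the phylogenetic-bin null-model framework on the rarefied biofilm
samples of each dataset, grouped by sampling day: taxa are binned into
deep clades, each within-day sample pair is scored per bin with βNRI
(phylogenetic null) and modified Raup-Crick (taxonomic null), and the
bin-abundance-weighted process labels are averaged per day group.

The headline pattern mirrors biofilm succession: homogeneous selection
dominates young biofilms (days 1-10) and collapses by day 30, replaced by
drift and dispersal limitation.
"""

import argparse
from pathlib import Path

import pandas as pd

from biofilm_assembly import NullModelConfig, quantify_assembly, rarefy
from biofilm_assembly.community import read_count_table, read_metadata, read_tree
from biofilm_assembly.pipeline import export_top_taxa


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/assembly"))
    ap.add_argument("--depth", type=int, default=4386)
    ap.add_argument("--n-null", type=int, default=1000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    tree = read_tree(args.data / "tree.nwk")
    summaries = []
    for nucleic in ("DNA", "cDNA"):
        table = read_count_table(args.data / f"{nucleic}_table.tsv")
        metadata = read_metadata(args.data / f"{nucleic}_metadata.tsv")
        rarefied = rarefy(table, args.depth, seed=args.seed)
        meta = metadata.set_index("sample_id")
        biofilm = [s for s in rarefied.sample_ids if meta.loc[s, "compartment"] == "biofilm"]
        sub = rarefied.select_samples(biofilm)

        cfg = NullModelConfig(n_null=args.n_null, seed=args.seed)
        result = quantify_assembly(sub, tree, metadata, ["day"], cfg)
        result.group_fractions.reset_index().to_csv(
            args.out / f"{nucleic}_groups.tsv", sep="\t", index=False
        )
        result.pair_fractions.to_csv(
            args.out / f"{nucleic}_pairs.tsv", sep="\t", index=False
        )
        result.pair_bin_scores.to_csv(
            args.out / f"{nucleic}_pair_bin_scores.tsv", sep="\t", index=False
        )
        result.bins.to_csv(args.out / f"{nucleic}_bins.tsv", sep="\t", index=False)

        top = export_top_taxa(rarefied, metadata, n=25, by=["day", "compartment"])
        top.to_csv(args.out / f"{nucleic}_top25_taxa.tsv", sep="\t", index=False)

        g = result.group_fractions
        summaries.append((nucleic, g))
        print(f"== {nucleic}: per-day process fractions (mean over within-day pairs)")
        print(g.round(3).to_string())

    for nucleic, g in summaries:
        hos1, hos30 = g.loc["1", "HoS"], g.loc["30", "HoS"]
        stoch30 = g.loc["30", "DR"] + g.loc["30", "DL"]
        print(
            f"{nucleic}: homogeneous selection {hos1:.0%} at day 1 → {hos30:.0%} at day 30; "
            f"drift + dispersal limitation reach {stoch30:.0%} by day 30"
        )


if __name__ == "__main__":
    main()
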