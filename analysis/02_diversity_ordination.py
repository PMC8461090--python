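"""Rarefaction, alpha diversity, beta diversity and ordination.

Rarefies each dataset to an even depth of 4,386 reads, computes per-sample
alpha indices (observed richness, Shannon, Simpson, Chao1), Bray-Curtis
and unweighted-UniFrac distances, and ordinations (NMDS on Bray-Curtis,
PCoA on UniFrac). Biofilm samples order along the ordination's first axis
by sampling day, and MLSS separates from the biofilms — the succession
signal the assembly analysis explains.
"""

import argparse
from pathlib import Path

import pandas as pd

from biofilm_assembly import nmds, pcoa, rarefy, unweighted_unifrac
from biofilm_assembly.community import (
    read_count_table,
    read_metadata,
    read_tree,
    write_count_table,
)
from biofilm_assembly.diversity import alpha_diversity_table, bray_curtis


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/diversity"))
    ap.add_argument("--depth", type=int, default=4386)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    tree = read_tree(args.data / "tree.nwk")
    for nucleic in ("DNA", "cDNA"):
        table = read_count_table(args.data / f"{nucleic}_table.tsv")
        metadata = read_metadata(args.data / f"{nucleic}_metadata.tsv")
        rarefied = rarefy(table, args.depth, seed=args.seed)
        dropped = set(table.sample_ids) - set(rarefied.sample_ids)
        write_count_table(rarefied, args.out / f"{nucleic}_rarefied.tsv")

        alpha = alpha_diversity_table(rarefied)
        alpha.to_csv(args.out / f"{nucleic}_alpha.tsv", sep="\t", index=False)

        bc = bray_curtis(rarefied)
        uf = unweighted_unifrac(rarefied, tree)
        bc.to_data_frame().to_csv(
            args.out / f"{nucleic}_bray_curtis.tsv", sep="\t", index_label="sample_id"
        )
        uf.to_data_frame().to_csv(
            args.out / f"{nucleic}_unifrac.tsv", sep="\t", index_label="sample_id"
        )

        nm = nmds(bc, k=2, seed=args.seed)
        pc = pcoa(uf, k=2)
        coords = nm.coordinates.join(pc.coordinates)
        coords = coords.join(metadata.set_index("sample_id")[["day", "compartment"]])
        coords.to_csv(args.out / f"{nucleic}_ordination.tsv", sep="\t", index_label="sample_id")

        day_means = coords[coords.compartment == "biofilm"].groupby("day")["NMDS1"].mean()
        print(
            f"{nucleic}: dropped {len(dropped)} sample(s) below depth; "
            f"alpha observed {alpha.observed.min()}-{alpha.observed.max()}, "
            f"Shannon {alpha.shannon.min():.2f}-{alpha.shannon.max():.2f}; "
            f"NMDS stress {nm.values[0]:.2e}; "
            f"day-mean NMDS1 {', '.join(f'{d}:{v:+.3f}' for d, v in day_means.items())}"
        )


if __name__ == "__main__":
    main()
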