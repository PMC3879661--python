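#!/usr/bin/env python
"""Metagene occupancy profiles around polyA sites.

Computes 80-bp-shift nucleosome and 300-bp-shift RNAP II aggregate
profiles over ±1000 bp, grouped by site class and by position class,
and reports where each group's nucleosome occupancy bottoms out (the
NDR) and peaks downstream.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from polyanuc.genome import read_genes_tsv, read_sites_bed
from polyanuc.profiles import aggregate_profile, build_profile_matrix
from polyanuc.sites import classify_sites, load_sites
from polyanuc.tags import TagCollection

DATA = Path("results/analysis/data")
OUT = Path("results/analysis")


def main() -> None:
    genes = read_genes_tsv(DATA / "genes.tsv")
    loaded, _ = load_sites(read_sites_bed(DATA / "sites.bed"), genes)
    classified = classify_sites(loaded, genes)

    libraries = {
        "nucleosome": (TagCollection.from_bed(DATA / "mnase_tags.bed"), 80),
        "rnap2": (TagCollection.from_bed(DATA / "rnap2_tags.bed"), 300),
    }
    for lib_name, (tags, shift) in libraries.items():
        matrix = build_profile_matrix(tags, classified, shift=shift)
        for group_attr in ("site_class", "position_class"):
            frames = []
            for label in sorted({getattr(s, group_attr) for s in classified}):
                ids = [s.site_id for s in classified
                       if getattr(s, group_attr) == label]
                agg = aggregate_profile(matrix.subset(ids))
                f = agg.to_frame()
                f.insert(0, "group", label)
                frames.append(f)
                if lib_name == "nucleosome":
                    near = np.abs(agg.offsets) <= 300
                    trough = agg.offsets[near][np.nanargmin(agg.mean_score[near])]
                    down = (agg.offsets > 0) & near
                    peak = agg.offsets[down][np.nanargmax(agg.mean_score[down])]
                    print(f"nucleosome/{label} (n={agg.n_anchors}): "
                          f"trough at {trough:+d} bp, "
                          f"downstream peak at {peak:+d} bp (within ±300)")
            path = OUT / f"profile_{lib_name}_by_{group_attr}.tsv"
            pd.concat(frames).to_csv(path, sep="\t", index=False)
            print(f"wrote {path}")


if __name__ == "__main__":
    main()
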