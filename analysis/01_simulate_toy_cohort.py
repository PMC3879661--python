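#!/usr/bin/env python
"""Simulate the toy gene cohort all downstream analyses use.

Builds the mixed cohort (single-site and multi-site genes), samples
MNase, RNAP II and RNA-seq libraries at default depth, and writes
everything (plus the generating truth) under results/analysis/data/.
"""

from pathlib import Path

import numpy as np

from polyanuc.simulate import (PRESETS, build_truth, reads_to_bed,
                               simulate_mnase, simulate_rnap2, simulate_rnaseq)

SEED = 11
OUT = Path("results/analysis/data")


def main() -> None:
    truth = build_truth(PRESETS["constitutive_vs_alternative"], seed=SEED)
    truth.write(OUT)
    rng = np.random.default_rng(SEED + 1)
    mnase = simulate_mnase(truth, rng, background_per_base=0.005)
    rnap2 = simulate_rnap2(truth, rng, body_rate_per_read=0.01)
    reads = simulate_rnaseq(truth, rng)
    mnase.to_bed(OUT / "mnase_tags.bed")
    rnap2.to_bed(OUT / "rnap2_tags.bed")
    reads_to_bed(reads, OUT / "rnaseq_reads.bed")

    n_single = sum(1 for s in truth.sites if s.position_class == "single")
    print(f"cohort: {len(truth.genes)} genes, {len(truth.sites)} polyA sites "
          f"({n_single} constitutive)")
    print(f"libraries: {mnase.total_tags} MNase tags, {rnap2.total_tags} RNAP II "
          f"tags, {len(reads)} RNA-seq reads")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
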