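"""Self-contained validation experiments.

Each function sets up its own inputs with the synthetic-data generator
(or tiny closed-form constructions), runs the relevant pipeline
operations, and returns plain measured numbers.  They back both the
validation test suite and the reproduction script, and the analysis
drivers reuse several of them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .expression import compute_rpkm, compute_rud
from .genome import GeneModel, PolyASite, sites_to_frame
from .group_stats import region_summaries, wilcoxon_compare
from .peaks import call_peaks, compare_positioning
from .profiles import aggregate_profile, build_profile_matrix, score_track
from .simulate import (PRESETS, NucleosomeSlot, SyntheticTruth, build_truth,
                       simulate_mnase, simulate_rnaseq)
from .sites import classify_sites, load_sites
from .tags import TagCollection


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, n)


# ---------------------------------------------------------------------------
# scoring


def scoring_oracle_deviation(seed: int, n_instances: int = 50) -> dict:
    """Largest |score_track − naive per-locus count| over random instances.

    The oracle is an explicit per-tag counting loop, independent of the
    binary-search implementation.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_points = 0
    for _ in range(n_instances):
        chrom_len = int(rng.integers(1500, 4000))
        n_tags = int(rng.integers(50, 500))
        shift = int(rng.choice([20, 80, 300]))
        plus = np.sort(rng.integers(0, chrom_len, n_tags // 2))
        minus = np.sort(rng.integers(0, chrom_len, n_tags - n_tags // 2))
        tags = TagCollection.from_positions({"c": plus}, {"c": minus})
        track = score_track(tags, "c", 0, min(chrom_len, 1000), shift=shift)
        for pos, got in zip(track.positions, track.scores):
            n_plus = int(np.sum((plus >= pos - shift) & (plus < pos)))
            n_minus = int(np.sum((minus >= pos) & (minus < pos + shift)))
            worst = max(worst, abs(got - (n_plus + n_minus) / 2.0))
            n_points += 1
    return {"value": worst, "n": n_points}


# ---------------------------------------------------------------------------
# closed forms


def rpkm_closed_form() -> dict:
    """RPKM of 1000 reads on a 2-kb coding region in a 1 M-read library."""
    gene = GeneModel("g", "c", "+", 0, 2000)
    reads = pd.DataFrame({"chrom": ["c"] * 1000,
                          "start": np.arange(1000) % 1980,
                          "end": np.arange(1000) % 1980 + 20,
                          "strand": ["+"] * 1000})
    [rec] = compute_rpkm(reads, [gene], library_total=1_000_000)
    return {"value": rec.rpkm, "n": 1000}


def rud_symmetric() -> dict:
    """RUD of a perfectly symmetric read placement around a site."""
    gene = GeneModel("g", "c", "+", 0, 10_000)
    site = PolyASite("s", "c", "+", 5000, "g")
    d = np.array([30, 60, 90, 120, 150, 180])
    reads = pd.DataFrame({
        "chrom": ["c"] * 12,
        "start": np.concatenate([5000 - d, 5000 + d]),
        "end": np.concatenate([5000 - d, 5000 + d]) + 10,
        "strand": ["+"] * 12,
    })
    rec = compute_rud(reads, site, gene)
    return {"value": rec.rud, "n": 12}


def wilcoxon_exact_triples() -> dict:
    """Two-sided exact rank-sum p for {1,2,3} vs {4,5,6}."""
    res = wilcoxon_compare([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    return {"value": res.p_value, "n": 6}


# ---------------------------------------------------------------------------
# RUD parameter recovery


def rud_recovery(seed: int, n_replicates: int = 100) -> dict:
    """Replicated RUD at a proximal site with true usage 0.7 (expect 0.3).

    One two-site gene per replicate at 20,000 expected gene reads
    (the ``proximal_usage`` scenario).  Returns the mean absolute error
    and the fraction of replicates within 0.05 of 1 − u.
    """
    cfg = PRESETS["proximal_usage"]
    truth_template = build_truth(cfg, seed=0)   # geometry is deterministic
    gene = truth_template.genes[0]
    proximal = next(s for s in truth_template.sites
                    if s.position_class == "proximal")
    true_rud = 1.0 - truth_template.usage[proximal.site_id]
    ruds = []
    for s in _child_seeds(seed, n_replicates):
        reads = simulate_rnaseq(truth_template, int(s))
        rec = compute_rud(reads, proximal, gene, truth_template.sites)
        ruds.append(rec.rud)
    ruds = np.array(ruds, dtype=float)
    return {
        "ruds": ruds,
        "true_rud": true_rud,
        "mean_rud": float(ruds.mean()),
        "mean_abs_error": float(np.abs(ruds - true_rud).mean()),
        "fraction_within_005": float(np.mean(np.abs(ruds - true_rud) < 0.05)),
        "n": n_replicates,
    }


# ---------------------------------------------------------------------------
# NDR contrast


def ndr_contrast(seed: int, region: tuple[int, int] = (-150, 150)) -> dict:
    """Near-site occupancy of deep-NDR (0.1) vs shallow-NDR (0.5) site groups.

    200 single-site genes per group; per-site mean occupancy over the
    region feeds a Wilcoxon rank-sum test.
    """
    truth = build_truth(PRESETS["ndr_contrast"], seed=seed)
    tags = simulate_mnase(truth, seed + 1)
    deep = truth.sites_in_group("deep_ndr")
    shallow = truth.sites_in_group("shallow_ndr")
    matrix = build_profile_matrix(tags, deep + shallow, shift=80,
                                  chrom_sizes=truth.chrom_sizes)
    vals_deep, _ = region_summaries(matrix.subset([s.site_id for s in deep]), region)
    vals_shallow, _ = region_summaries(
        matrix.subset([s.site_id for s in shallow]), region)
    cmp_ = wilcoxon_compare(vals_deep, vals_shallow,
                            labels=("deep_ndr", "shallow_ndr"), region=region)
    return {
        "mean_deep": float(vals_deep.mean()),
        "mean_shallow": float(vals_shallow.mean()),
        "p_value": cmp_.p_value,
        "z_value": cmp_.z_value,
        "n_per_group": len(deep),
    }


# ---------------------------------------------------------------------------
# positioning contrast


def positioning_contrast(seed: int, n_replicates: int = 20) -> dict:
    """Well-positioned (σ=5) vs fuzzy (σ=30) nucleosomes, 200 sites/group.

    Per replicate: simulate, call downstream peaks, run the F test on
    summit dispersion and the Welch t test on fuzziness.  Reports
    detection fractions at p < 1e-3 and mean recovered fuzziness.
    """
    f_hits, t_hits, fuzz_pos, fuzz_fuz = [], [], [], []
    for s in _child_seeds(seed, n_replicates):
        truth = build_truth(PRESETS["positioning_contrast"], seed=int(s))
        tags = simulate_mnase(truth, int(s) + 1)
        peaks_pos = call_peaks(tags, truth.sites_in_group("positioned"), "downstream")
        peaks_fuz = call_peaks(tags, truth.sites_in_group("fuzzy"), "downstream")
        cmp_ = compare_positioning(peaks_pos, peaks_fuz,
                                   labels=("positioned", "fuzzy"))
        f_hits.append(cmp_.f_pvalue < 1e-3)
        t_hits.append(cmp_.t_pvalue < 1e-3)
        fuzz_pos.append(cmp_.mean_fuzziness[0])
        fuzz_fuz.append(cmp_.mean_fuzziness[1])
    return {
        "f_detection_rate": float(np.mean(f_hits)),
        "t_detection_rate": float(np.mean(t_hits)),
        "mean_fuzziness_sd5": float(np.mean(fuzz_pos)),
        "mean_fuzziness_sd30": float(np.mean(fuzz_fuz)),
        "true_sds": (5.0, 30.0),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# profile geometry


def _mirror_tags(tags: TagCollection, length: int) -> TagCollection:
    plus = {c: np.sort(length - 1 - arr) for c, arr in tags.minus.items()}
    minus = {c: np.sort(length - 1 - arr) for c, arr in tags.plus.items()}
    return TagCollection.from_positions(plus, minus)


def profile_geometry(seed: int, n_sites: int = 50, planted_offset: int = 150) -> dict:
    """Dyads planted at a fixed downstream offset of every site.

    The aggregate profile should peak at that offset (plateau centre on
    the 10-bp grid), and reflecting the toy genome while swapping
    strands should leave the aggregate untouched.
    """
    rng = np.random.default_rng(seed)
    length = 40_000 * n_sites // 10
    positions = np.sort(rng.choice(np.arange(3000, length - 3000, 2500), n_sites,
                                   replace=False))
    sites = [PolyASite(f"s{i}", "c", "+" if i % 2 else "-", int(p), f"g{i}")
             for i, p in enumerate(positions)]
    dyads = np.array([
        s.position + (planted_offset if s.strand == "+" else -planted_offset)
        for s in sites for _ in range(20)
    ])
    tags = TagCollection.from_positions({"c": np.sort(dyads - 73)},
                                        {"c": np.sort(dyads + 73)})
    matrix = build_profile_matrix(tags, sites, shift=80)
    agg = aggregate_profile(matrix)
    top = agg.offsets[agg.mean_score == np.nanmax(agg.mean_score)]
    peak_offset = float(top.mean())   # centre of the maximal plateau

    mirrored_sites = [
        PolyASite(s.site_id, s.chrom, "-" if s.strand == "+" else "+",
                  length - s.position, s.gene_id)
        for s in sites
    ]
    agg_m = aggregate_profile(
        build_profile_matrix(_mirror_tags(tags, length), mirrored_sites, shift=80))
    mirror_dev = float(np.nanmax(np.abs(agg.mean_score - agg_m.mean_score)))
    return {"peak_offset": peak_offset, "mirror_deviation": mirror_dev,
            "n_sites": n_sites}


# ---------------------------------------------------------------------------
# classification round trip


def classification_roundtrip(seed: int, n_genes: int = 50) -> dict:
    """Generator-intended labels vs classifier output on random toy genes."""
    cfg = replace(PRESETS["constitutive_vs_alternative"], n_genes=n_genes,
                  site_count_probs={1: 0.3, 2: 0.4, 3: 0.3})
    truth = build_truth(cfg, seed=seed)
    table = sites_to_frame(truth.sites)[["site_id", "chrom", "position", "strand"]]
    loaded, _ = load_sites(table, truth.genes)
    got = {s.site_id: (s.site_class, s.position_class)
           for s in classify_sites(loaded, truth.genes)}
    intended = {s.site_id: (s.site_class, s.position_class) for s in truth.sites}
    mismatches = sum(got.get(sid) != lab for sid, lab in intended.items())
    return {"n_sites": len(intended), "n_mismatches": mismatches,
            "n_minus_strand": sum(s.strand == "-" for s in truth.sites),
            "n_two_site_genes": sum(
                1 for g in truth.genes
                if sum(s.gene_id == g.gene_id for s in truth.sites) == 2)}


# ---------------------------------------------------------------------------
# Wilcoxon null calibration


def wilcoxon_null_calibration(seed: int, n_pairs: int = 10_000,
                              n_per_group: int = 30, alpha: float = 0.05) -> dict:
    """Type-I error of the rank-sum test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_pairs):
        a = rng.normal(0, 1, n_per_group)
        b = rng.normal(0, 1, n_per_group)
        if wilcoxon_compare(a, b).p_value < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_pairs, "n_pairs": n_pairs,
            "alpha": alpha}
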