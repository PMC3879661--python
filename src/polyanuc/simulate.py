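"""Synthetic toy genome with full ground truth.

Generates what the analysis assumes about real data: genes laid out on a
toy chromosome, one or more polyA sites per gene, phased nucleosome
arrays flanking each site with a nucleosome-depleted region (NDR) at the
site itself, RNAP II tag clusters accumulating up- or downstream of
sites, and RNA-seq reads whose density drops past a site in proportion
to the site's usage fraction.  Every stochastic quantity flows from one
seeded :class:`numpy.random.Generator`, so a seed fully determines the
fixture set; the returned :class:`SyntheticTruth` carries the generating
parameters as ground truth for recovery tests.

The dyad→tag model mirrors the strand-shifted scoring geometry: each
sampled dyad emits a + strand tag 73 bp upstream and a − strand tag
73 bp downstream (both ends of the 147-bp nucleosomal fragment); a
single-end mode keeps one random end instead.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, PolyASite, write_genes_tsv, write_sites_bed
from .tags import TagCollection

DYAD_SHIFT = 73


@dataclass(frozen=True)
class NucleosomeSlot:
    chrom: str
    center: int          # expected dyad position
    jitter_sd: float     # positioning noise, bp
    weight: float        # expected dyads sampled at depth 1 (NDR-adjusted)


@dataclass(frozen=True)
class Rnap2Cluster:
    chrom: str
    center: int
    sd: float
    weight: float        # expected tag pairs at depth 1


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Geometry is per gene: the proximal site sits ``tss_to_first_site``
    bp from the TSS, further sites every ``intersite_spacing`` bp, the
    gene ends ``site_to_gene_end`` bp past the last site.  ``variants``
    split genes round-robin into named groups with parameter overrides
    (e.g. two NDR depths, two jitter levels) for contrast scenarios.
    """

    n_genes: int = 50
    site_count_probs: dict[int, float] = field(default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2})
    tss_to_first_site: int = 2000
    intersite_spacing: int = 1000
    site_to_gene_end: int = 500
    intergenic_gap: int = 3000
    margin: int = 2000
    usage_fractions: dict[int, tuple[float, ...]] = field(default_factory=dict)
    expression_rate: float = 2000.0      # expected RNA-seq reads per gene at depth 1
    read_length: int = 20
    nuc_repeat: int = 180
    n_nucs_per_side: int = 5
    jitter_sd: float = 20.0
    slot_placement_sd: float | None = None   # across-site scatter of slot
    # centres; None ties it to jitter_sd (poor positioning shows up both
    # within a site, across cells, and across sites)
    occupancy_weight: float = 20.0       # expected dyads per slot at depth 1
    ndr_halfwidth: int = 100
    ndr_depletion: float = 0.5
    rnap2_upstream_offset: int = -150    # cluster at proximal sites
    rnap2_downstream_offset: int = 200   # cluster at distal/constitutive sites
    rnap2_cluster_sd: float = 30.0
    rnap2_cluster_weight: float = 200.0
    variants: tuple[tuple[str, dict], ...] = ()
    chrom: str = "chrT"

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.tss_to_first_site <= 0 or self.site_to_gene_end <= 0:
            raise ValueError("tss_to_first_site and site_to_gene_end must be positive")
        if self.intersite_spacing <= 0:
            raise ValueError("intersite_spacing must be positive")
        if not self.site_count_probs or any(k < 1 for k in self.site_count_probs):
            raise ValueError("site_count_probs must map positive site counts")
        for k, fr in self.usage_fractions.items():
            if len(fr) != k or abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError(f"usage_fractions[{k}] must have {k} entries summing to 1")


PRESETS: dict[str, ScenarioConfig] = {
    "constitutive_vs_alternative": ScenarioConfig(
        n_genes=60, site_count_probs={1: 0.5, 2: 0.3, 3: 0.2},
    ),
    # one 2-site gene per replicate at 20k reads: RUD at the proximal
    # site estimates 1 − u with sampling sd ≈ 0.017 (see docs/methods.md)
    "proximal_usage": ScenarioConfig(
        n_genes=1, site_count_probs={2: 1.0}, usage_fractions={2: (0.7, 0.3)},
        expression_rate=20000.0,
    ),
    # 200 single-site genes per jitter group, 250 dyads (500 tags) per slot
    "positioning_contrast": ScenarioConfig(
        n_genes=400, site_count_probs={1: 1.0}, occupancy_weight=250.0,
        n_nucs_per_side=2,
        variants=(("positioned", {"jitter_sd": 5.0}), ("fuzzy", {"jitter_sd": 30.0})),
    ),
    # 200 single-site genes per NDR-depth group
    "ndr_contrast": ScenarioConfig(
        n_genes=400, site_count_probs={1: 1.0},
        variants=(("deep_ndr", {"ndr_depletion": 0.1}), ("shallow_ndr", {"ndr_depletion": 0.5})),
    ),
}


@dataclass
class SyntheticTruth:
    """Ground truth behind one synthetic fixture set."""

    genes: list[GeneModel]
    sites: list[PolyASite]               # carrying intended class labels
    expression_rate: dict[str, float]    # gene_id -> expected reads at depth 1
    usage: dict[str, float]              # site_id -> usage fraction
    slots: list[NucleosomeSlot]
    rnap2_clusters: list[Rnap2Cluster]
    chrom_sizes: dict[str, int]
    groups: dict[str, str]               # site_id -> variant group
    seed: int | None = None
    config: ScenarioConfig | None = None

    def sites_in_group(self, group: str) -> list[PolyASite]:
        return [s for s in self.sites if self.groups.get(s.site_id) == group]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genes_tsv(self.genes, outdir / "genes.tsv")
        write_sites_bed(self.sites, outdir / "sites.bed")
        payload = {
            "seed": self.seed,
            "chrom_sizes": self.chrom_sizes,
            "expression_rate": self.expression_rate,
            "usage": self.usage,
            "groups": self.groups,
            "slots": [asdict(s) for s in self.slots],
            "rnap2_clusters": [asdict(c) for c in self.rnap2_clusters],
            "site_labels": {
                s.site_id: {"site_class": s.site_class, "position_class": s.position_class}
                for s in self.sites
            },
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def _position_label(j: int, k: int) -> str:
    if k == 1:
        return "single"
    if j == 0:
        return "proximal"
    if j == k - 1:
        return "distal"
    return "in_between"


def build_truth(config: ScenarioConfig, seed: int | np.random.Generator) -> SyntheticTruth:
    """Lay out the toy genome and all generating parameters."""
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)

    counts = np.array(sorted(config.site_count_probs))
    probs = np.array([config.site_count_probs[k] for k in counts], dtype=float)
    probs = probs / probs.sum()
    variant_names = [v[0] for v in config.variants] or ["all"]
    variant_overrides = {v[0]: v[1] for v in config.variants}

    genes: list[GeneModel] = []
    sites: list[PolyASite] = []
    expression: dict[str, float] = {}
    usage: dict[str, float] = {}
    slots: list[NucleosomeSlot] = []
    clusters: list[Rnap2Cluster] = []
    groups: dict[str, str] = {}

    cursor = config.margin
    for i in range(config.n_genes):
        k = int(rng.choice(counts, p=probs))
        strand = "+" if i % 2 == 0 else "-"
        group = variant_names[i % len(variant_names)]
        local = replace(config, **variant_overrides.get(group, {}))
        length = config.tss_to_first_site + (k - 1) * config.intersite_spacing + config.site_to_gene_end
        start, end = cursor, cursor + length
        cursor = end + config.intergenic_gap
        gene_id = f"g{i:04d}"
        gene = GeneModel(gene_id=gene_id, chrom=config.chrom, strand=strand,
                         start=start, end=end)
        genes.append(gene)
        expression[gene_id] = float(config.expression_rate)

        fractions = config.usage_fractions.get(k) or tuple([1.0 / k] * k)
        for j in range(k):
            d = config.tss_to_first_site + j * config.intersite_spacing
            pos = start + d if strand == "+" else end - d
            site_id = f"{gene_id}_s{j}"
            site = PolyASite(site_id=site_id, chrom=config.chrom, strand=strand,
                             position=pos, gene_id=gene_id,
                             site_class="constitutive" if k == 1 else "alternative",
                             position_class=_position_label(j, k))
            sites.append(site)
            usage[site_id] = float(fractions[j])
            groups[site_id] = group

            sgn = 1 if strand == "+" else -1
            placement_sd = (local.slot_placement_sd
                            if local.slot_placement_sd is not None
                            else local.jitter_sd)
            for m in range(-local.n_nucs_per_side, local.n_nucs_per_side + 1):
                offset = m * local.nuc_repeat
                weight = local.occupancy_weight
                if abs(offset) <= local.ndr_halfwidth:
                    weight *= local.ndr_depletion
                shove = int(np.rint(rng.normal(0, placement_sd))) if placement_sd else 0
                slots.append(NucleosomeSlot(config.chrom, pos + sgn * offset + shove,
                                            local.jitter_sd, weight))
            if site.position_class in ("proximal",):
                clusters.append(Rnap2Cluster(
                    config.chrom, pos + sgn * local.rnap2_upstream_offset,
                    local.rnap2_cluster_sd,
                    local.rnap2_cluster_weight * fractions[j]))
            if site.position_class in ("distal", "single"):
                clusters.append(Rnap2Cluster(
                    config.chrom, pos + sgn * local.rnap2_downstream_offset,
                    local.rnap2_cluster_sd,
                    local.rnap2_cluster_weight * fractions[j]))

    chrom_size = cursor + config.margin
    return SyntheticTruth(
        genes=genes, sites=sites, expression_rate=expression, usage=usage,
        slots=slots, rnap2_clusters=clusters,
        chrom_sizes={config.chrom: int(chrom_size)}, groups=groups,
        seed=seed_val, config=config,
    )


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _emit_dyad_tags(
    dyads: np.ndarray, rng: np.random.Generator, paired: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Tags implied by dyad positions: both fragment ends, or one random end."""
    if paired:
        return dyads - DYAD_SHIFT, dyads + DYAD_SHIFT
    pick = rng.random(len(dyads)) < 0.5
    return dyads[pick] - DYAD_SHIFT, dyads[~pick] + DYAD_SHIFT


def simulate_mnase(
    truth: SyntheticTruth,
    seed: int | np.random.Generator,
    depth: float = 1.0,
    background_per_base: float = 0.0,
    paired_ends: bool = True,
) -> TagCollection:
    """Sample MNase tag 5' ends from the nucleosome slots.

    Each slot contributes Poisson(weight × depth) dyads jittered with
    its positioning sd; dyads become strand-shifted tag pairs (or single
    random ends).  ``background_per_base`` adds uniform tags per base
    per strand on every chromosome.
    """
    rng = _as_rng(seed)
    plus_parts: dict[str, list[np.ndarray]] = {}
    minus_parts: dict[str, list[np.ndarray]] = {}
    by_chrom: dict[str, list[NucleosomeSlot]] = {}
    for slot in truth.slots:
        by_chrom.setdefault(slot.chrom, []).append(slot)
    for chrom, slot_list in by_chrom.items():
        centers = np.array([s.center for s in slot_list], dtype=float)
        sds = np.array([s.jitter_sd for s in slot_list], dtype=float)
        weights = np.array([s.weight for s in slot_list], dtype=float)
        n = rng.poisson(weights * depth)
        centers_rep = np.repeat(centers, n)
        sds_rep = np.repeat(sds, n)
        dyads = np.rint(rng.normal(centers_rep, sds_rep)).astype(np.int64) \
            if len(centers_rep) else np.empty(0, dtype=np.int64)
        plus, minus = _emit_dyad_tags(dyads, rng, paired_ends)
        plus_parts.setdefault(chrom, []).append(plus)
        minus_parts.setdefault(chrom, []).append(minus)
    if background_per_base > 0:
        for chrom, size in truth.chrom_sizes.items():
            lam = background_per_base * size * depth
            for parts in (plus_parts, minus_parts):
                n_bg = rng.poisson(lam)
                parts.setdefault(chrom, []).append(
                    rng.integers(0, size, n_bg).astype(np.int64))
    plus = {c: np.concatenate(p) for c, p in plus_parts.items() if p}
    minus = {c: np.concatenate(p) for c, p in minus_parts.items() if p}
    return TagCollection.from_positions(plus, minus, library_label="mnase_synthetic")


def simulate_rnap2(
    truth: SyntheticTruth,
    seed: int | np.random.Generator,
    depth: float = 1.0,
    body_rate_per_read: float = 0.0,
    pair_span: int = 300,
) -> TagCollection:
    """Sample RNAP II tag 5' ends: accumulation clusters + gene-body background.

    Each cluster draws Poisson(weight × depth) loci around its centre
    and emits a sense/antisense tag pair a uniform-random half-span (up
    to ``pair_span`` bp) to either side, so the ``pair_span``-shifted
    occupancy score rises triangularly to a maximum at the cluster
    centre.  Gene-body background adds Poisson(expression_rate × depth ×
    body_rate_per_read) uniform random-strand tags per gene, tying
    polymerase load to expression.
    """
    rng = _as_rng(seed)
    plus_parts: dict[str, list[np.ndarray]] = {}
    minus_parts: dict[str, list[np.ndarray]] = {}
    for cluster in truth.rnap2_clusters:
        n = rng.poisson(cluster.weight * depth)
        loci = np.rint(rng.normal(cluster.center, cluster.sd, n)).astype(np.int64)
        halfspan = np.rint(rng.uniform(0, pair_span, n)).astype(np.int64)
        plus_parts.setdefault(cluster.chrom, []).append(loci - halfspan)
        minus_parts.setdefault(cluster.chrom, []).append(loci + halfspan)
    if body_rate_per_read > 0:
        for gene in truth.genes:
            lam = truth.expression_rate[gene.gene_id] * depth * body_rate_per_read
            n_bg = rng.poisson(lam)
            pos = rng.integers(gene.start, gene.end, n_bg).astype(np.int64)
            pick = rng.random(n_bg) < 0.5
            plus_parts.setdefault(gene.chrom, []).append(pos[pick])
            minus_parts.setdefault(gene.chrom, []).append(pos[~pick])
    plus = {c: np.concatenate(p) for c, p in plus_parts.items() if p}
    minus = {c: np.concatenate(p) for c, p in minus_parts.items() if p}
    return TagCollection.from_positions(plus, minus, library_label="rnap2_synthetic")


def simulate_rnaseq(
    truth: SyntheticTruth,
    seed: int | np.random.Generator,
    depth: float = 1.0,
    read_length: int | None = None,
) -> pd.DataFrame:
    """Sample RNA-seq read intervals (chrom, start, end, strand).

    Per gene, Poisson(expression_rate × depth) reads are drawn from the
    transcript pool in which a fraction u_i of molecules terminates at
    site *i*: each read lands on an isoform with probability
    proportional to u_i × molecule length (uniform fragmentation of the
    pool), at a position uniform along that molecule, truncated at the
    cleavage site (the 3'-most fragments yield reads ending exactly at
    the site).  The per-base 5'-end density is therefore uniform up to a
    site and drops, immediately past it, by exactly that site's usage
    fraction — the regime in which RUD estimates 1 − u.
    """
    rng = _as_rng(seed)
    rl = read_length if read_length is not None else (
        truth.config.read_length if truth.config else 20)
    per_gene_sites: dict[str, list[PolyASite]] = {}
    for s in truth.sites:
        per_gene_sites.setdefault(s.gene_id, []).append(s)

    chroms, starts, ends, strands = [], [], [], []
    for gene in truth.genes:
        gsites = sorted(per_gene_sites[gene.gene_id],
                        key=lambda s: gene.dist_to_tss(s.position))
        u = np.array([truth.usage[s.site_id] for s in gsites], dtype=float)
        u = u / u.sum()
        n_reads = rng.poisson(truth.expression_rate[gene.gene_id] * depth)
        if n_reads == 0:
            continue
        lengths = np.array([gene.dist_to_tss(s.position) + 1 for s in gsites])
        q = u * lengths
        q = q / q.sum()
        site_idx = rng.choice(len(gsites), size=n_reads, p=q)
        mol_len = lengths[site_idx]
        s_tx = np.floor(rng.random(n_reads) * mol_len).astype(np.int64)  # transcript coord
        span = np.minimum(rl, mol_len - s_tx)
        if gene.strand == "+":
            g_start = gene.start + s_tx
            g_end = g_start + span
        else:
            g5 = gene.end - 1 - s_tx
            g_start = g5 - span + 1
            g_end = g5 + 1
        chroms.append(np.full(n_reads, gene.chrom, dtype=object))
        starts.append(g_start)
        ends.append(g_end)
        strands.append(np.full(n_reads, gene.strand, dtype=object))
    if not chroms:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    return pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "start": np.concatenate(starts),
            "end": np.concatenate(ends),
            "strand": np.concatenate(strands),
        }
    )


def reads_to_bed(reads: pd.DataFrame, path: str | Path, name: str = "read") -> None:
    out = reads.copy()
    out.insert(3, "name", name)
    out.insert(4, "score", 0)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 5], names=["chrom", "start", "end", "strand"],
                     dtype={"chrom": str})
    return df
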