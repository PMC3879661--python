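"""Gene expression (RPKM) and polyA-site usage (RUD) from RNA-seq reads.

RPKM counts reads overlapping a gene's protein-coding intervals, per
kilobase of mappable (coding) length, per million mapped library reads.
RUD — relative usage of the downstream polyA site — is the ratio of
RNA-seq read density downstream of a cleavage site to the density
upstream of it; a transcript pool that mostly terminates at the site
leaves little downstream signal, so low RUD means high usage.  Reads
within ±10 nt of the site are excluded because cleavage is imprecise.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, PolyASite

logger = logging.getLogger(__name__)

RPKM_HIGH = 10.0
RPKM_LOW = 0.1
RPKM_EXPRESSED = 1.0
DEFAULT_RUD_WINDOW = 200
DEFAULT_RUD_EXCLUSION = 10


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    read_count: int
    rpkm: float
    stratum: str  # high (>10) / expressed (>1) / low (<0.1) / other


@dataclass(frozen=True)
class UsageRecord:
    site_id: str
    gene_id: str
    upstream_density: float
    downstream_density: float
    rud: float | None
    usage_label: str = "unlabeled"  # high / low / intermediate / undefined


def _stratum(rpkm: float) -> str:
    if rpkm > RPKM_HIGH:
        return "high"
    if rpkm > RPKM_EXPRESSED:
        return "expressed"
    if rpkm < RPKM_LOW:
        return "low"
    return "other"


def compute_rpkm(
    reads: pd.DataFrame,
    genes: Sequence[GeneModel],
    library_total: int | None = None,
) -> list[ExpressionRecord]:
    """RPKM per gene from aligned-read intervals (columns chrom, start, end).

    A read counts toward a gene when its interval overlaps any coding
    interval; a read overlapping several genes counts toward each.
    ``library_total`` defaults to the number of input reads.
    """
    total = library_total if library_total is not None else len(reads)
    if total <= 0:
        raise ValueError("library_total must be positive")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in reads.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        by_chrom[str(chrom)] = (starts[order], ends[order])

    records = []
    for gene in genes:
        if gene.mappable_length <= 0:
            logger.warning("gene %s: zero-length coding region", gene.gene_id)
            records.append(ExpressionRecord(gene.gene_id, 0, float("nan"), "invalid"))
            continue
        starts, ends = by_chrom.get(gene.chrom, (np.empty(0, np.int64),) * 2)
        mask = np.zeros(len(starts), dtype=bool)
        for s, e in gene.coding_intervals:
            mask |= (starts < e) & (ends > s)
        count = int(mask.sum())
        rpkm = count / (gene.mappable_length / 1e3) / (total / 1e6)
        records.append(ExpressionRecord(gene.gene_id, count, rpkm, _stratum(rpkm)))
    return records


def read_five_prime_ends(reads: pd.DataFrame) -> pd.DataFrame:
    """Reduce read intervals to sorted 5'-end coordinates per chromosome.

    Uses the read's own strand (start for +, end−1 for −); reads without
    a strand column are taken at their left end.
    """
    if "strand" in reads.columns:
        pos = np.where(reads["strand"].to_numpy() == "-",
                       reads["end"].to_numpy() - 1, reads["start"].to_numpy())
    else:
        pos = reads["start"].to_numpy()
    return pd.DataFrame({"chrom": reads["chrom"].to_numpy(), "pos": pos})


class _EndIndex:
    """Sorted per-chromosome 5'-end positions for density counting."""

    def __init__(self, reads: pd.DataFrame):
        ends = read_five_prime_ends(reads)
        self._by_chrom = {
            str(chrom): np.sort(grp["pos"].to_numpy(dtype=np.int64))
            for chrom, grp in ends.groupby("chrom", sort=False)
        }

    def count(self, chrom: str, lo: int, hi: int) -> int:
        """Number of 5' ends in the half-open genomic interval [lo, hi)."""
        arr = self._by_chrom.get(chrom)
        if arr is None or hi <= lo:
            return 0
        return int(np.searchsorted(arr, hi) - np.searchsorted(arr, lo))


def compute_rud(
    reads: pd.DataFrame | _EndIndex,
    site: PolyASite,
    gene: GeneModel,
    gene_sites: Sequence[PolyASite] = (),
    window: int = DEFAULT_RUD_WINDOW,
    exclusion: int = DEFAULT_RUD_EXCLUSION,
) -> UsageRecord:
    """RUD for one site: downstream / upstream read 5'-end density.

    The upstream window covers the ``window − exclusion`` bases ending
    ``exclusion`` bases before the site (transcription direction), the
    downstream window mirrors it; both are clipped at the gene span and
    at neighbouring polyA sites of the same gene, with densities taken
    over the clipped lengths.
    """
    if window <= exclusion:
        raise ValueError("window must exceed exclusion")
    index = reads if isinstance(reads, _EndIndex) else _EndIndex(reads)
    p = site.position
    others = [s.position for s in gene_sites if s.site_id != site.site_id]

    if site.strand == "+":
        up_lo, up_hi = p - window + 1, p - exclusion + 1      # (p-w, p-excl]
        dn_lo, dn_hi = p + exclusion, p + window              # [p+excl, p+w)
        up_lo = max(up_lo, gene.start, *[o + 1 for o in others if o < p] or [up_lo])
        dn_hi = min(dn_hi, gene.end, *[o for o in others if o > p] or [dn_hi])
    else:
        up_lo, up_hi = p + exclusion, p + window              # transcription upstream
        dn_lo, dn_hi = p - window + 1, p - exclusion + 1
        up_hi = min(up_hi, gene.end, *[o for o in others if o > p] or [up_hi])
        dn_lo = max(dn_lo, gene.start, *[o + 1 for o in others if o < p] or [dn_lo])

    up_len, dn_len = up_hi - up_lo, dn_hi - dn_lo
    up_density = index.count(site.chrom, up_lo, up_hi) / up_len if up_len > 0 else 0.0
    dn_density = index.count(site.chrom, dn_lo, dn_hi) / dn_len if dn_len > 0 else 0.0
    rud = dn_density / up_density if up_density > 0 else None
    label = "unlabeled" if rud is not None else "undefined"
    return UsageRecord(site.site_id, site.gene_id or gene.gene_id,
                       up_density, dn_density, rud, label)


def compute_usage_table(
    reads: pd.DataFrame,
    sites: Sequence[PolyASite],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_RUD_WINDOW,
    exclusion: int = DEFAULT_RUD_EXCLUSION,
) -> list[UsageRecord]:
    """RUD for every classified site, sharing one read index."""
    index = _EndIndex(reads)
    gene_by_id = {g.gene_id: g for g in genes}
    per_gene: dict[str, list[PolyASite]] = defaultdict(list)
    for s in sites:
        per_gene[s.gene_id].append(s)
    return [
        compute_rud(index, s, gene_by_id[s.gene_id], per_gene[s.gene_id],
                    window=window, exclusion=exclusion)
        for s in sites
    ]


def assign_usage(
    records: Sequence[UsageRecord],
    expression: Sequence[ExpressionRecord],
    min_rpkm: float = RPKM_EXPRESSED,
) -> list[UsageRecord]:
    """Label each expressed gene's extreme-RUD sites.

    Within a gene with at least two defined RUD values, the lowest-RUD
    site is the high-usage site and the highest-RUD site the low-usage
    site; the rest are intermediate.  Genes below ``min_rpkm`` or with
    fewer than two defined RUDs contribute only undefined labels.  RUD
    ties at an extreme break lexicographically by site_id.
    """
    rpkm_by_gene = {e.gene_id: e.rpkm for e in expression}
    per_gene: dict[str, list[UsageRecord]] = defaultdict(list)
    for r in records:
        per_gene[r.gene_id].append(r)

    out: list[UsageRecord] = []
    for gene_id, recs in per_gene.items():
        defined = sorted((r for r in recs if r.rud is not None),
                         key=lambda r: r.site_id)
        eligible = rpkm_by_gene.get(gene_id, 0.0) > min_rpkm and len(defined) >= 2
        if not eligible:
            out.extend(
                UsageRecord(r.site_id, r.gene_id, r.upstream_density,
                            r.downstream_density, r.rud, "undefined")
                for r in recs
            )
            continue
        ordered = sorted(defined, key=lambda r: (r.rud, r.site_id))
        lo = ordered[0]
        hi_pool = [r for r in ordered if r.rud == ordered[-1].rud and r is not lo]
        hi = hi_pool[0] if hi_pool else ordered[-1]
        if sum(r.rud == lo.rud for r in ordered) > 1 or sum(
            r.rud == hi.rud for r in ordered
        ) > 1:
            logger.warning("gene %s: RUD tie at an extreme; broken by site_id",
                           gene_id)
        for r in recs:
            if r.rud is None:
                label = "undefined"
            elif r is lo:
                label = "high"
            elif r is hi:
                label = "low"
            else:
                label = "intermediate"
            out.append(UsageRecord(r.site_id, r.gene_id, r.upstream_density,
                                   r.downstream_density, r.rud, label))
    return out


def usage_to_frame(records: Sequence[UsageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "upstream_density": [r.upstream_density for r in records],
            "downstream_density": [r.downstream_density for r in records],
            "rud": [np.nan if r.rud is None else r.rud for r in records],
            "usage_label": [r.usage_label for r in records],
        }
    )


def expression_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "read_count": [r.read_count for r in records],
            "rpkm": [r.rpkm for r in records],
            "stratum": [r.stratum for r in records],
        }
    )
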