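"""PolyA-site loading, classification and distance summaries.

Sites are retained only when they fall inside exactly one gene span on
the matching strand ("uniquely mapped").  Retained sites are then split
into the constitutive class (sole site of a one-site gene) and the
alternative class (sites of multi-site genes); alternative sites are
labelled proximal / in_between / distal by strand-aware distance from
the TSS.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneModel, PolyASite

logger = logging.getLogger(__name__)


@dataclass
class LoadReport:
    """Per-reason counts of rejected site records."""

    n_input: int = 0
    n_retained: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1


def load_sites(
    site_table: pd.DataFrame, genes: list[GeneModel]
) -> tuple[list[PolyASite], LoadReport]:
    """Assign each site record to the unique containing gene.

    ``site_table`` needs columns site_id, chrom, position, strand (a
    gene_id column, if present, is ignored in favour of the interval
    assignment).  Sites contained in zero or in more than one same-strand
    gene span are dropped and counted in the report.
    """
    report = LoadReport(n_input=len(site_table))
    by_chrom: dict[tuple[str, str], list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[(g.chrom, g.strand)].append(g)

    retained: list[PolyASite] = []
    for row in site_table.itertuples(index=False):
        try:
            pos = int(row.position)
            strand = str(row.strand)
            chrom = str(row.chrom)
            site_id = str(row.site_id)
        except (ValueError, AttributeError):
            report.reject("malformed_record")
            logger.warning("malformed site record dropped: %r", row)
            continue
        if strand not in ("+", "-"):
            report.reject("malformed_record")
            logger.warning("site %s: bad strand %r", site_id, strand)
            continue
        hits = [g for g in by_chrom.get((chrom, strand), ()) if g.contains(pos)]
        if len(hits) == 0:
            report.reject("no_containing_gene")
            continue
        if len(hits) > 1:
            report.reject("ambiguous_gene_overlap")
            continue
        retained.append(
            PolyASite(site_id=site_id, chrom=chrom, strand=strand, position=pos,
                      gene_id=hits[0].gene_id)
        )
    report.n_retained = len(retained)
    if not retained:
        logger.warning("load_sites: no site survived filtering (%d input)", report.n_input)
    return retained, report


def classify_sites(
    sites: list[PolyASite], genes: list[GeneModel]
) -> list[PolyASite]:
    """Attach site_class and position_class labels.

    Duplicate coordinates within a gene keep only the lexicographically
    smallest site_id (with a warning); a gene reduced to one distinct
    coordinate is classified as a single-site gene.
    """
    if not sites:
        raise ValueError("classify_sites: empty site collection")
    gene_by_id = {g.gene_id: g for g in genes}
    per_gene: dict[str, list[PolyASite]] = defaultdict(list)
    for s in sites:
        if s.gene_id not in gene_by_id:
            raise KeyError(f"site {s.site_id}: unknown gene {s.gene_id}")
        per_gene[s.gene_id].append(s)

    out: list[PolyASite] = []
    for gene_id, gsites in per_gene.items():
        gene = gene_by_id[gene_id]
        # deduplicate identical coordinates deterministically
        by_pos: dict[int, PolyASite] = {}
        for s in sorted(gsites, key=lambda s: s.site_id):
            if s.position in by_pos:
                logger.warning(
                    "gene %s: sites %s and %s share coordinate %d; keeping %s",
                    gene_id, by_pos[s.position].site_id, s.site_id, s.position,
                    by_pos[s.position].site_id,
                )
            else:
                by_pos[s.position] = s
        kept = sorted(by_pos.values(), key=lambda s: (gene.dist_to_tss(s.position), s.site_id))
        if len(kept) == 1:
            out.append(kept[0].classified("constitutive", "single"))
            continue
        proximal = kept[0]
        distal = min(kept, key=lambda s: (gene.dist_to_end(s.position), s.site_id))
        for s in kept:
            if s is proximal:
                out.append(s.classified("alternative", "proximal"))
            elif s is distal:
                out.append(s.classified("alternative", "distal"))
            else:
                out.append(s.classified("alternative", "in_between"))
    return out


def distance_summary(
    sites: list[PolyASite], genes: list[GeneModel], min_sites_per_gene: int = 3
) -> pd.DataFrame:
    """Mean site-to-TSS and site-to-gene-end distances per position class.

    Restricted to genes carrying at least ``min_sites_per_gene`` polyA
    sites (the summary is about how the three alternative classes are
    spaced, so two-site genes — which have no in-between sites — are
    excluded by default).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    counts: dict[str, int] = defaultdict(int)
    for s in sites:
        counts[s.gene_id] += 1
    rows = []
    for cls in ("proximal", "in_between", "distal"):
        d_tss, d_end = [], []
        for s in sites:
            if s.position_class != cls or counts[s.gene_id] < min_sites_per_gene:
                continue
            g = gene_by_id[s.gene_id]
            d_tss.append(g.dist_to_tss(s.position))
            d_end.append(g.dist_to_end(s.position))
        if not d_tss:
            logger.warning("distance_summary: no %s sites in eligible genes", cls)
            continue
        rows.append(
            {
                "position_class": cls,
                "mean_dist_to_tss": float(np.mean(d_tss)),
                "mean_dist_to_gene_end": float(np.mean(d_end)),
                "n_sites": len(d_tss),
            }
        )
    return pd.DataFrame(rows, columns=["position_class", "mean_dist_to_tss",
                                       "mean_dist_to_gene_end", "n_sites"])
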