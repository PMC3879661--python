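"""Gene models and polyadenylation sites.

Coordinates are 0-based, half-open throughout (BED convention).  A gene
occupies the genomic span ``[start, end)``; its transcription start site
(TSS) is ``start`` on the + strand and ``end`` on the − strand, so
strand-aware distances along the direction of transcription are always
non-negative for positions inside the span.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SITE_CLASSES = ("constitutive", "alternative")
POSITION_CLASSES = ("single", "proximal", "in_between", "distal")


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene with the intervals used for expression."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    coding_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: empty gene span [{self.start}, {self.end})")
        ivs = tuple(tuple(iv) for iv in self.coding_intervals)
        if not ivs:
            ivs = ((self.start, self.end),)
        prev_end = None
        for s, e in ivs:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: coding interval ({s}, {e}) outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: coding intervals overlap or are unsorted")
            prev_end = e
        object.__setattr__(self, "coding_intervals", ivs)

    @property
    def tss(self) -> int:
        """Transcription start, strand-aware boundary coordinate."""
        return self.start if self.strand == "+" else self.end

    @property
    def gene_end(self) -> int:
        """3' end of the gene, strand-aware boundary coordinate."""
        return self.end if self.strand == "+" else self.start

    @property
    def mappable_length(self) -> int:
        return sum(e - s for s, e in self.coding_intervals)

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def dist_to_tss(self, position: int) -> int:
        """Distance from the TSS along the direction of transcription."""
        return position - self.start if self.strand == "+" else self.end - position

    def dist_to_end(self, position: int) -> int:
        """Distance from the 3' gene end, against transcription."""
        return self.end - position if self.strand == "+" else position - self.start


@dataclass(frozen=True)
class PolyASite:
    """One cleavage/polyadenylation site with derived class labels.

    ``site_class`` separates the single site of one-site genes
    (constitutive) from the sites of multi-site genes (alternative);
    ``position_class`` orders alternative sites by distance from the TSS
    (proximal nearest the TSS, distal nearest the gene end).
    """

    site_id: str
    chrom: str
    strand: str
    position: int
    gene_id: str | None = None
    site_class: str | None = None
    position_class: str | None = None

    def classified(self, site_class: str, position_class: str) -> "PolyASite":
        if site_class not in SITE_CLASSES or position_class not in POSITION_CLASSES:
            raise ValueError(f"bad labels ({site_class}, {position_class})")
        return replace(self, site_class=site_class, position_class=position_class)


# ---------------------------------------------------------------------------
# I/O


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    """Read gene models from a refFlat-style TSV.

    Required columns: gene_id, chrom, strand, start, end.  An optional
    ``coding_intervals`` column holds comma-separated ``s-e`` pairs.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    genes = []
    for row in df.itertuples(index=False):
        ivs: tuple[tuple[int, int], ...] = ()
        raw = getattr(row, "coding_intervals", "")
        if isinstance(raw, str) and raw:
            ivs = tuple(
                (int(p.split("-")[0]), int(p.split("-")[1])) for p in raw.split(",") if p
            )
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                coding_intervals=ivs,
            )
        )
    return genes


def write_genes_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "start": g.start,
            "end": g.end,
            "coding_intervals": ",".join(f"{s}-{e}" for s, e in g.coding_intervals),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sites_bed(path: str | Path) -> pd.DataFrame:
    """Read polyA sites from BED6 (``name`` is ``site_id|gene_id`` or ``site_id``).

    Returns a tidy frame with columns site_id, gene_id, chrom, position,
    strand; ``gene_id`` is empty when the name carries no gene.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    name = df["name"].fillna("").str.split("|", n=1, expand=True)
    out = pd.DataFrame(
        {
            "site_id": name[0],
            "gene_id": name[1] if name.shape[1] > 1 else "",
            "chrom": df["chrom"],
            # malformed coordinates become NaN and are rejected downstream
            "position": pd.to_numeric(df["start"], errors="coerce"),
            "strand": df["strand"],
        }
    )
    out["gene_id"] = out["gene_id"].fillna("")
    return out


def write_sites_bed(sites: Sequence[PolyASite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            name = f"{s.site_id}|{s.gene_id}" if s.gene_id else s.site_id
            fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\t{name}\t0\t{s.strand}\n")


def sites_to_frame(sites: Sequence[PolyASite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "gene_id": [s.gene_id for s in sites],
            "chrom": [s.chrom for s in sites],
            "position": [s.position for s in sites],
            "strand": [s.strand for s in sites],
            "site_class": [s.site_class for s in sites],
            "position_class": [s.position_class for s in sites],
        }
    )
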