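"""Strand-separated 5'-end tag collections.

MNase-seq and ChIP-seq libraries are reduced to the 5'-end coordinate of
each uniquely mapped read: ``start`` for + strand reads, ``end − 1`` for
− strand reads (BED half-open intervals).  Coordinates are kept sorted
per chromosome and strand so occupancy scoring is a pair of binary
searches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class TagCollection:
    """Sorted tag 5'-end coordinates, separated by chromosome and strand."""

    plus: dict[str, np.ndarray] = field(default_factory=dict)
    minus: dict[str, np.ndarray] = field(default_factory=dict)
    library_label: str = ""
    _warned: set[str] = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        for d in (self.plus, self.minus):
            for chrom, arr in d.items():
                a = np.asarray(arr, dtype=np.int64)
                a.sort()
                d[chrom] = a

    @property
    def total_tags(self) -> int:
        return int(
            sum(len(a) for a in self.plus.values())
            + sum(len(a) for a in self.minus.values())
        )

    @property
    def chroms(self) -> set[str]:
        return set(self.plus) | set(self.minus)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(plus, minus) sorted coordinate arrays for one chromosome."""
        empty = np.empty(0, dtype=np.int64)
        if chrom not in self.plus and chrom not in self.minus:
            if chrom not in self._warned:
                self._warned.add(chrom)
                logger.warning("library %s: chromosome %s has no tags",
                               self.library_label or "?", chrom)
        return self.plus.get(chrom, empty), self.minus.get(chrom, empty)

    @classmethod
    def from_bed(cls, path: str | Path, library_label: str = "") -> "TagCollection":
        """Load a BED6 tag file; each record contributes one 5'-end tag."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 5],
            names=["chrom", "start", "end", "strand"],
            dtype={"chrom": str},
        )
        return cls.from_frame(df, library_label=library_label or Path(path).stem)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, library_label: str = "") -> "TagCollection":
        five = np.where(df["strand"].to_numpy() == "+",
                        df["start"].to_numpy(), df["end"].to_numpy() - 1)
        plus: dict[str, np.ndarray] = {}
        minus: dict[str, np.ndarray] = {}
        frame = pd.DataFrame({"chrom": df["chrom"], "pos": five, "strand": df["strand"]})
        for (chrom, strand), grp in frame.groupby(["chrom", "strand"], sort=False):
            target = plus if strand == "+" else minus
            target[chrom] = np.sort(grp["pos"].to_numpy(dtype=np.int64))
        return cls(plus=plus, minus=minus, library_label=library_label)

    @classmethod
    def from_positions(
        cls,
        plus: dict[str, np.ndarray] | None = None,
        minus: dict[str, np.ndarray] | None = None,
        library_label: str = "",
    ) -> "TagCollection":
        return cls(plus=dict(plus or {}), minus=dict(minus or {}),
                   library_label=library_label)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.chroms):
                for pos in self.plus.get(chrom, ()):
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\ttag\t0\t+\n")
                for pos in self.minus.get(chrom, ()):
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\ttag\t0\t-\n")
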