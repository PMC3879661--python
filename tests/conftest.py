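"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from polyanuc import GeneModel, PolyASite, TagCollection


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def naive_occupancy(plus: np.ndarray, minus: np.ndarray, pos: int, shift: int) -> float:
    """Brute-force strand-shifted score: explicit per-tag counting."""
    n_plus = sum(1 for t in plus if pos - shift <= t < pos)
    n_minus = sum(1 for t in minus if pos <= t < pos + shift)
    return (n_plus + n_minus) / 2.0


def random_tags(
    rng: np.random.Generator, chrom_len: int = 10_000, n: int = 500,
    chrom: str = "chr1",
) -> TagCollection:
    plus = np.sort(rng.integers(0, chrom_len, n // 2))
    minus = np.sort(rng.integers(0, chrom_len, n - n // 2))
    return TagCollection.from_positions({chrom: plus}, {chrom: minus})


def mirror_tags(tags: TagCollection, length: int) -> TagCollection:
    """Reflect the toy genome: base x -> length − 1 − x, strands swapped."""
    plus = {c: np.sort(length - 1 - arr) for c, arr in tags.minus.items()}
    minus = {c: np.sort(length - 1 - arr) for c, arr in tags.plus.items()}
    return TagCollection.from_positions(plus, minus)


def mirror_site(site: PolyASite, length: int) -> PolyASite:
    """Reflect an anchor.  Anchors mirror as boundaries (x -> length − x)
    so the half-open strand-shifted counting windows map onto each other
    exactly."""
    return PolyASite(
        site_id=site.site_id, chrom=site.chrom,
        strand="-" if site.strand == "+" else "+",
        position=length - site.position, gene_id=site.gene_id,
        site_class=site.site_class, position_class=site.position_class,
    )


def make_gene(gene_id="g1", chrom="chr1", strand="+", start=0, end=10_000,
              coding=()) -> GeneModel:
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     start=start, end=end, coding_intervals=tuple(coding))


def make_site(site_id="s1", chrom="chr1", strand="+", position=5000,
              gene_id="g1", **labels) -> PolyASite:
    return PolyASite(site_id=site_id, chrom=chrom, strand=strand,
                     position=position, gene_id=gene_id, **labels)
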