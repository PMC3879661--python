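"""Site loading, classification and distance summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polyanuc import classify_sites, distance_summary, load_sites
from polyanuc.genome import GeneModel

from conftest import make_gene, make_site


def site_table(rows):
    return pd.DataFrame(rows, columns=["site_id", "chrom", "position", "strand"])


class TestLoadSites:
    def test_site_outside_any_gene_is_dropped(self):
        genes = [make_gene(start=1000, end=5000)]
        table = site_table([("a", "chr1", 2000, "+"),
                            ("b", "chr1", 4000, "+"),
                            ("c", "chr1", 9000, "+")])
        sites, report = load_sites(table, genes)
        assert [s.site_id for s in sites] == ["a", "b"]
        assert report.rejected == {"no_containing_gene": 1}

    def test_strand_mismatch_drops_site(self):
        genes = [make_gene(strand="-", start=0, end=10_000)]
        sites, report = load_sites(site_table([("a", "chr1", 5000, "+")]), genes)
        assert sites == []
        assert report.rejected == {"no_containing_gene": 1}

    def test_ambiguous_overlap_drops_site(self):
        genes = [make_gene("g1", start=0, end=6000),
                 make_gene("g2", start=4000, end=10_000)]
        sites, report = load_sites(site_table([("a", "chr1", 5000, "+")]), genes)
        assert sites == []
        assert report.rejected == {"ambiguous_gene_overlap": 1}

    def test_assignment_matches_bruteforce_containment(self, rng):
        genes = [make_gene(f"g{i}", start=i * 20_000, end=i * 20_000 + 8000,
                           strand="+" if i % 2 else "-")
                 for i in range(2)]
        table = site_table([
            (f"s{j}", "chr1", int(rng.integers(0, 45_000)),
             rng.choice(["+", "-"])) for j in range(30)
        ])
        sites, _ = load_sites(table, genes)
        got = {s.site_id: s.gene_id for s in sites}
        # independent loop over every site x gene pair
        expected = {}
        for row in table.itertuples(index=False):
            hits = [g for g in genes
                    if g.strand == row.strand and g.start <= row.position < g.end]
            if len(hits) == 1:
                expected[row.site_id] = hits[0].gene_id
        assert got == expected

    def test_malformed_record_is_rejected_not_fatal(self):
        genes = [make_gene()]
        table = site_table([("a", "chr1", 5000, "+"), ("b", "chr1", 4000, "x")])
        sites, report = load_sites(table, genes)
        assert [s.site_id for s in sites] == ["a"]
        assert report.rejected == {"malformed_record": 1}


class TestClassifySites:
    def test_single_site_gene_is_constitutive(self):
        genes = [make_gene()]
        [site] = classify_sites([make_site(position=1000)], genes)
        assert (site.site_class, site.position_class) == ("constitutive", "single")

    def test_plus_strand_three_sites(self):
        genes = [make_gene(start=0, end=10_000)]
        sites = [make_site(f"s{p}", position=p) for p in (2000, 5000, 9000)]
        labels = {s.position: s.position_class for s in classify_sites(sites, genes)}
        assert labels == {2000: "proximal", 5000: "in_between", 9000: "distal"}

    def test_minus_strand_reverses_absolute_order(self):
        genes = [make_gene(strand="-", start=0, end=10_000)]
        sites = [make_site(f"s{p}", strand="-", position=p)
                 for p in (2000, 5000, 9000)]
        labels = {s.position: s.position_class for s in classify_sites(sites, genes)}
        assert labels == {2000: "distal", 5000: "in_between", 9000: "proximal"}

    def test_two_site_gene_has_no_in_between(self):
        genes = [make_gene()]
        sites = [make_site("a", position=2000), make_site("b", position=8000)]
        classes = sorted(s.position_class for s in classify_sites(sites, genes))
        assert classes == ["distal", "proximal"]

    def test_duplicate_coordinates_collapse_to_single(self, caplog):
        genes = [make_gene()]
        sites = [make_site("b", position=3000), make_site("a", position=3000)]
        out = classify_sites(sites, genes)
        assert len(out) == 1
        assert out[0].site_id == "a"
        assert (out[0].site_class, out[0].position_class) == ("constitutive", "single")

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            classify_sites([], [make_gene()])

    def test_mirror_invariance_of_labels(self, rng):
        """Reflecting all coordinates and flipping all strands leaves the
        proximal/in-between/distal labels of every site unchanged."""
        L = 200_000
        genes, sites = [], []
        cursor = 1000
        for i in range(20):
            strand = "+" if i % 2 else "-"
            length = int(rng.integers(4000, 9000))
            g = make_gene(f"g{i}", strand=strand, start=cursor, end=cursor + length)
            genes.append(g)
            k = int(rng.integers(1, 5))
            offsets = np.sort(rng.choice(np.arange(100, length - 100), k, replace=False))
            for j, d in enumerate(offsets):
                sites.append(make_site(f"g{i}_s{j}", strand=strand,
                                       position=cursor + int(d), gene_id=f"g{i}"))
            cursor += length + 1000
        mirrored_genes = [
            GeneModel(g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
                      L - g.end, L - g.start)
            for g in genes
        ]
        mirrored_sites = [
            make_site(s.site_id, strand="-" if s.strand == "+" else "+",
                      position=L - 1 - s.position, gene_id=s.gene_id)
            for s in sites
        ]
        orig = {s.site_id: (s.site_class, s.position_class)
                for s in classify_sites(sites, genes)}
        mirr = {s.site_id: (s.site_class, s.position_class)
                for s in classify_sites(mirrored_sites, mirrored_genes)}
        assert orig == mirr

    def test_ordering_property(self, rng):
        """Within a gene, distance-to-TSS orders proximal < in_between < distal."""
        genes = [make_gene(strand="-", start=0, end=50_000)]
        positions = rng.choice(np.arange(100, 49_900), 6, replace=False)
        sites = [make_site(f"s{i}", strand="-", position=int(p))
                 for i, p in enumerate(positions)]
        out = classify_sites(sites, genes)
        d = {s.site_id: genes[0].dist_to_tss(s.position) for s in out}
        prox = [d[s.site_id] for s in out if s.position_class == "proximal"]
        mid = [d[s.site_id] for s in out if s.position_class == "in_between"]
        dist = [d[s.site_id] for s in out if s.position_class == "distal"]
        assert max(prox) < min(mid) and max(mid) < min(dist)


class TestDistanceSummary:
    def test_three_site_gene_arithmetic(self):
        genes = [make_gene(start=0, end=10_000)]
        sites = classify_sites(
            [make_site(f"s{p}", position=p) for p in (2000, 5000, 9000)], genes)
        df = distance_summary(sites, genes).set_index("position_class")
        assert df.loc["proximal", "mean_dist_to_tss"] == 2000
        assert df.loc["distal", "mean_dist_to_gene_end"] == 1000
        assert df.loc["in_between", "n_sites"] == 1

    def test_duplicated_gene_doubles_counts_not_means(self):
        genes = [make_gene("g1", start=0, end=10_000),
                 make_gene("g2", start=20_000, end=30_000)]
        sites = []
        for gid, base in (("g1", 0), ("g2", 20_000)):
            sites += [make_site(f"{gid}_{p}", position=base + p, gene_id=gid)
                      for p in (2000, 5000, 9000)]
        df = distance_summary(classify_sites(sites, genes), genes)
        df = df.set_index("position_class")
        assert df.loc["proximal", "mean_dist_to_tss"] == 2000
        assert (df["n_sites"] == 2).all()

    def test_matches_per_site_loop(self, rng):
        genes, sites = [], []
        cursor = 0
        for i in range(20):
            strand = "+" if rng.random() < 0.5 else "-"
            g = make_gene(f"g{i}", strand=strand, start=cursor, end=cursor + 12_000)
            genes.append(g)
            k = int(rng.integers(3, 6))
            for j, d in enumerate(np.sort(rng.choice(np.arange(500, 11_500), k,
                                                     replace=False))):
                pos = cursor + int(d)
                sites.append(make_site(f"g{i}_s{j}", strand=strand, position=pos,
                                       gene_id=f"g{i}"))
            cursor += 15_000
        classified = classify_sites(sites, genes)
        df = distance_summary(classified, genes).set_index("position_class")
        gene_by_id = {g.gene_id: g for g in genes}
        for cls in ("proximal", "in_between", "distal"):
            d_tss = [gene_by_id[s.gene_id].dist_to_tss(s.position)
                     for s in classified if s.position_class == cls]
            assert df.loc[cls, "mean_dist_to_tss"] == pytest.approx(np.mean(d_tss))
            assert df.loc[cls, "n_sites"] == len(d_tss)

    def test_partition_property(self, rng):
        genes = [make_gene()]
        sites = [make_site(f"s{i}", position=1000 + 500 * i) for i in range(5)]
        out = classify_sites(sites, genes)
        assert len(out) == len(sites)
        assert all(s.site_class in ("constitutive", "alternative") for s in out)
        counts = {c: sum(s.position_class == c for s in out)
                  for c in ("proximal", "in_between", "distal")}
        assert counts == {"proximal": 1, "in_between": 3, "distal": 1}
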