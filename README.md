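# polyanuc

Nucleosome and RNA polymerase II occupancy around human polyadenylation
sites: a tested analysis pipeline for epigenomics / regulatory-genomics
work on alternative polyadenylation (APA).

More than half of human protein-coding genes carry several
polyadenylation (polyA) sites, so the choice of cleavage site shapes the
transcriptome.  Chromatin participates in that choice: polyA sites sit
in a nucleosome-depleted region (NDR), flanking nucleosomes can pause
elongating RNA polymerase II (RNAP II), and the strength of these
features tracks how a site is used.  `polyanuc` implements the
computational side of that analysis for anyone with strand-specific tag
files (MNase-seq, ChIP-seq) and RNA-seq alignments in BED form:

* **Site classification** — constitutive (sole site of a gene) vs
  alternative, and proximal / in-between / distal by distance from the
  TSS, with distance summaries.
* **Strand-shifted occupancy scoring** — at locus *p* with shift *s*,

  `score(p) = (#{+ tags in [p−s, p)} + #{− tags in [p, p+s)}) / 2`

  on a 10-bp grid; *s* = 80 bp for nucleosomes (MNase tag 5′ ends flank
  the 147-bp wrapped DNA), *s* = 300 bp for RNAP II.  Site-anchored,
  transcription-oriented profile matrices over ±1000 bp and smoothed
  aggregate (metagene) profiles, moving-average span 5.
* **Expression and usage** — RPKM over coding regions (strata > 10,
  > 1, < 0.1) and the RUD statistic (relative usage of the downstream
  polyA site): downstream / upstream read density with a ±10-nt
  exclusion around the cleavage site.  Lowest RUD in a gene = high-usage
  site, highest = low-usage.
* **Peak positioning** — a simple, fully specified nucleosome peak
  caller within ±300 bp of each site (smoothed-track summit + dyad
  dispersion "fuzziness", dyads implied at tag 5′ end ± 73 bp), with an
  F test on summit dispersion and a Welch t test on fuzziness between
  site groups.
* **Group statistics** — Wilcoxon rank-sum comparisons of per-site mean
  occupancy over a chosen offset region (exact for small tie-free
  samples, tie-corrected normal approximation otherwise).
* **Synthetic data** — a seeded generator producing a toy genome with
  phased nucleosome arrays, NDRs of controllable depth, RNAP II
  clusters and usage-dependent RNA-seq coverage, with full ground truth
  for recovery tests.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Run the numbered analysis scripts in order (each is a thin driver over
the library; outputs land in `results/analysis/`):

```bash
python analysis/01_simulate_toy_cohort.py
python analysis/02_classify_sites.py
python analysis/03_occupancy_profiles.py
python analysis/04_expression_usage.py
python analysis/05_peak_positioning.py
python analysis/06_group_contrasts.py
```

Printed output (abridged):

```
cohort: 60 genes, 91 polyA sites (37 constitutive)
libraries: 41679 MNase tags, 24435 RNAP II tags, 120108 RNA-seq reads

retained 91/91 sites; class counts {'single': 37, 'proximal': 23,
  'distal': 23, 'in_between': 8}; 0 label mismatches vs truth
position_class  mean_dist_to_tss  mean_dist_to_gene_end  n_sites
      proximal            2000.0                 2500.0        8
    in_between            3000.0                 1500.0        8
        distal            4000.0                  500.0        8

nucleosome/constitutive (n=37): trough at -80 bp, downstream peak at +180 bp
nucleosome/alternative (n=54): trough at +0 bp, downstream peak at +160 bp

usage labels: {'undefined': 37, 'low': 23, 'high': 23, 'intermediate': 8}
proximal sites: mean |RUD - (1-u)| = 0.063 over 23 sites

downstream peaks: 37 constitutive / 54 alternative
positioning contrast (σ=5 vs σ=30, 200 peaks/group):
  F test p<1e-3 in 100%, t test in 100% of replicates
  recovered fuzziness 5.0 / 33.9 bp (true 5 / 30)

constitutive vs alternative near-site occupancy: means 6.24 vs 11.47,
  p = 9.64e-14
NDR contrast (depletion 0.1 vs 0.5, 200/group): means 3.72 vs 6.09,
  p = 4.94e-45
```

Reading it: the classifier reproduces the generator's intended labels
exactly; the metagene profile shows the occupancy trough at the polyA
site and the first flanking nucleosome ~180 bp downstream; RUD at
proximal sites recovers 1 − (usage fraction); and both positioning
tests and the occupancy Wilcoxon separate groups that truly differ.

The same steps are available as one command with a manifest:

```bash
polyanuc run-all --preset constitutive_vs_alternative --seed 11 --out results/run
```

plus `simulate`, `classify`, `profile`, `usage`, `peaks` and `compare`
subcommands for individual stages on your own BED/TSV inputs
(`polyanuc --help`).

## Layout

```
src/polyanuc/       library: genome, sites, tags, profiles, expression,
                    peaks, group_stats, simulate, experiments, pipeline, cli
analysis/           numbered narrative drivers over the library
tests/              pytest suite (unit, property, end-to-end validation)
scripts/acceptance.py   from-scratch recomputation of headline numbers
docs/methods.md     models, parameters, design choices, limitations
```
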