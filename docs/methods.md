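# Methods

`polyanuc` implements a metagene analysis of chromatin and transcription
signals around human polyadenylation (polyA) sites: how nucleosome
occupancy and RNA polymerase II (RNAP II) accumulation differ between
constitutive and alternative sites, between proximal and distal sites,
and between highly and lowly used sites.  Because the analysis was
designed against genome-scale MNase-seq / ChIP-seq / RNA-seq data that a
desk-scale package cannot ship, every statistical behaviour is instead
validated on a synthetic toy genome with full ground truth.  This note
records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Site classification

A polyA site is retained when it lies inside exactly one gene span
`[start, end)` on the matching strand; sites hitting zero or several
genes are dropped and counted ("uniquely mapped" is not otherwise
specified for the source data, so containment-in-exactly-one is our
operational definition).  A gene's only site is *constitutive*
(position class *single*); the sites of multi-site genes are
*alternative* and are labelled by strand-aware distance from the
transcription start site: the nearest is *proximal*, the site nearest
the gene end is *distal*, the rest *in_between*.  Two-site genes
therefore have no in-between sites.  Duplicate coordinates within a gene
keep the lexicographically smallest site id (with a warning), and a gene
whose sites collapse to one coordinate reclassifies as single-site.
Distance summaries (mean distance to TSS and to gene end per class) are
restricted to genes with more than two sites, since the summary
describes how the three alternative classes are spaced.

All coordinates are 0-based, half-open (BED).  For a − strand gene the
TSS is the right span boundary and all distances run against the genomic
axis, so every rule is strand-mirror invariant; the test suite checks
this by reflecting whole toy genomes.

## Strand-shifted occupancy score

The occupancy score at a locus *p* with shift *s* is

    score(p) = ( #{+ tags in [p−s, p)} + #{− tags in [p, p+s)} ) / 2,

evaluated on a 10-bp grid.  With *s* = 80 this is the nucleosome score:
MNase-protected fragments place sequenced 5′ ends upstream (+ strand)
and downstream (− strand) of the wrapped DNA, so a nucleosome centred at
*p* contributes to both counts.  With *s* = 300 the same kernel scores
RNAP II ChIP tags.  Window half-openness is our choice (the counting
rule needs an unambiguous boundary); the sum-vs-mean ambiguity of
"average number of reads" is resolved as the mean of the two counts —
the factor 2 cancels in every within-library contrast.  Tags-per-million
scaling is available for cross-library display but is a no-op within
one library, which is where all the statistics run.

Profiles anchor this score at every polyA site over ±1000 bp; − strand
rows are reversed so positive offsets always point downstream in the
direction of transcription.  Offsets whose genomic position falls
outside the chromosome are stored as missing (NaN), not zero — zero-fill
would drag aggregate means down at contig edges.  The aggregate profile
is the per-offset mean over non-missing rows followed by a centred
moving average of span 5 grid points with symmetrically shrinking
windows at the edges (span-5 matching the analysis' smoothing; the
shrinking-window rule keeps the first and last offsets defined).

## Expression and usage

RPKM is reads overlapping a gene's coding intervals, per kb of coding
("mappable") length, per million mapped library reads.  Reads count by
any-overlap, and a read overlapping two genes counts toward both (the
symmetric choice; logged).  Expression strata follow the analysis'
thresholds verbatim: highly expressed RPKM > 10, unexpressed RPKM < 0.1,
expressed RPKM > 1; anything between 0.1 and 1 falls in "other" and is
excluded from those contrasts.

RUD (relative usage of the downstream polyA site) at a site is the ratio
of downstream to upstream RNA-seq read 5′-end density.  Reads within
±10 nt of the site are excluded (cleavage is imprecise).  The window
length is not fixed by the source analysis; we default to 200 bp per
side, clipped so a window never crosses a neighbouring polyA site of the
same gene or the gene boundary, with densities over the clipped lengths
— this keeps one site's windows free of another site's step.  Reads are
assigned by 5′-end position for RUD (density semantics) but by overlap
for RPKM (coverage semantics).  Within an expressed gene (RPKM > 1) with
at least two defined RUDs, the lowest-RUD site is labelled high-usage
and the highest-RUD site low-usage; ties break lexicographically by site
id with a warning.  Low RUD means high usage: a heavily used site
terminates most transcripts, leaving little downstream signal.

## Peak positioning metrics

Within 300 bp upstream or downstream of a site, the peak caller reports
the 10-bp grid point maximising the span-5-smoothed occupancy track.
Tied maxima are grouped into contiguous runs: a smoothed single peak
yields a symmetric plateau whose centre is the summit, while distinct
tied peaks break toward the polyA site.  Peak *fuzziness* is the sample
standard deviation of tag-implied dyad positions (each + tag implies a
dyad 73 bp downstream of its 5′ end, each − tag 73 bp upstream; 73 is
half the 147-bp nucleosomal DNA) within summit ± 80 bp; peaks supported
by fewer than 10 implied dyads are discarded as unstable.  This is a
deliberately simple, fully specified caller — it produces exactly the
two quantities the group contrasts need (summit position and fuzziness)
and nothing else; it is not a reimplementation of any genome-wide
dynamic-nucleosome caller, and its outputs are named accordingly.

Group contrasts: a two-sided F test on summit-offset variances (reported
as larger/smaller variance, so group order is irrelevant) asks whether
summits are more consistently placed in one group; a Welch t test on
fuzziness asks whether individual nucleosomes are better positioned.  A
zero-variance group makes the F test degenerate and is flagged rather
than silently handled.

## Wilcoxon rank-sum comparisons

Occupancy differences between site groups reduce each site to its mean
score over a configurable offset region (default ±150 bp for near-site
claims; `[−300, 0)` / `(0, +300]` for one-sided claims), then compare
the two collections of per-site means with the Wilcoxon rank-sum test:
midrank tie handling; exact null distribution when both groups have
fewer than 20 tie-free observations; otherwise the normal approximation
with tie-corrected variance and a 0.5 continuity correction.  Whether
the original contrasts were computed per-offset or on regional means is
not stated; regional means were chosen (one value per site keeps sites,
not offsets, as the sampling unit).  No multiple-testing correction is
applied, matching the analysis being reproduced.

## Synthetic data generator

The generator is the package's ground-truth instrument, not a fixture:
it emulates exactly the regularities the analysis assumes and nothing
finer.

* **Genome layout.** Genes placed sequentially with a 3-kb intergenic
  gap on one toy chromosome, alternating strands.  The proximal site
  sits 2 kb from the TSS, further sites every 1 kb, the gene ends 500 bp
  past the last site.  These spacings keep RUD windows (200 bp) inside
  single inter-site intervals and metagene windows (±1 kb) inside gene
  neighbourhoods.
* **Nucleosomes.** Phased slot arrays through each site (180-bp repeat,
  a plausible nucleosome repeat length), 5 slots per side by default.
  Slots within ±100 bp of the site (the NDR half-width) have their
  expected occupancy multiplied by the depletion factor, producing the
  trough-and-flanking-peak metagene shape.  Each slot's realised centre
  is displaced once, at layout time, by N(0, placement sd); each
  sequenced dyad is then drawn N(centre, jitter sd) and emits a + tag at
  dyad−73 and a − tag at dyad+73 (both fragment ends; a single-random-end
  mode exists).  The placement sd defaults to the jitter sd: poor
  positioning in a cell population shows up both as within-site spread
  across cells and as across-site variation of the preferred position —
  without the across-site component, summit positions estimated from
  hundreds of tags collapse onto the 10-bp grid in every group and
  summit-dispersion comparisons have nothing to measure.
* **RNAP II.** Gaussian clusters (sd 30 bp) upstream of proximal sites
  and downstream of distal/constitutive sites, weights tied to usage;
  each cluster locus emits a sense/antisense tag pair with a uniform
  half-span up to 300 bp, so the 300-bp-shift score rises triangularly
  to a maximum at the cluster centre.  Gene-body background scales with
  expression.
* **RNA-seq.** Per gene, Poisson(expected reads) reads land on isoforms
  with probability ∝ usage × molecule length (uniform fragmentation of
  the transcript pool), at positions uniform along the molecule,
  truncated at the cleavage site.  The per-base 5′-end density is then
  uniform up to a site and drops by exactly that site's usage fraction
  past it — the regime in which RUD estimates 1 − u.  A
  one-read-per-molecule model would over-weight short isoforms per base
  and bias RUD; a fixed-length, no-truncation read model would leave a
  (read length − exclusion)-bp dead zone for 5′ ends just upstream of
  the site, inflating RUD by a few percent.  Read length defaults to
  20 nt.

All randomness flows from one seeded `numpy` generator; the same seed
reproduces every output file byte-for-byte.

What the generator does **not** model: sequence (no FASTA, no
sequence-dependent nucleosome preference), mappability, duplicate reads,
fragment-length variation, splicing/junction reads, overlapping genes,
or inter-gene expression variability.  Passing recovery tests therefore
demonstrate that the estimators are correct under the stated generative
assumptions — not that real libraries satisfy those assumptions.

## Validation experiments and problem sizes

The validation suite (and `scripts/acceptance.py`) runs each experiment
at a size chosen to make the expected effect at least several standard
errors wide while staying desk-scale:

* scoring: binary-search tracks vs naive per-tag counting on 50 random
  instances (exact equality required);
* closed forms: RPKM(1000 reads, 2 kb, 1 M total) = 500; symmetric-read
  RUD = 1; exact rank-sum p({1,2,3} vs {4,5,6}) = 0.1;
* RUD recovery: 100 replicates of one two-site gene, usage 0.7/0.3,
  20,000 expected reads — ~1.5k upstream / 0.5k downstream window reads
  give a sampling sd of ~0.017, well inside the ±0.05 recovery band;
* NDR contrast: depletion 0.1 vs 0.5, 200 single-site genes per group,
  Wilcoxon on mean occupancy over |offset| ≤ 150;
* positioning contrast: jitter 5 vs 30 bp, 200 peaks per group, 250
  dyads (500 tags) per nucleosome, 20 replicates; fuzziness recovery is
  read off the same runs (the σ=30 estimate sits ~10% high because
  neighbouring array slots bleed into the summit ± 80 bp dyad window);
* profile geometry: dyads planted +150 bp downstream of 50 sites must
  peak the aggregate within one grid step, and genome reflection with
  strand swap must reproduce the aggregate exactly (anchors mirror as
  interval boundaries, x → L − x, which maps the half-open counting
  windows onto each other exactly);
* classification: generator-intended labels must match the classifier on
  50 random genes including − strand and two-site cases;
* calibration: rank-sum type-I error at α = 0.05 within ±0.01 over
  10,000 null pairs (n = 30 per group, exercising the asymptotic
  branch).

## Known limitations

* The peak caller's summit lives on the 10-bp scoring grid; sub-grid
  positioning differences are invisible to the F test.
* Fuzziness is truncated by the summit ± 80 bp dyad window; for spreads
  approaching 30 bp the estimate is mildly biased (truncation shrinks
  it, neighbour bleed-through inflates it; net ≈ +10% at σ = 30 under
  the default 180-bp repeat).
* RUD is undefined where the upstream window is empty, and single-site
  genes never receive usage labels; both are reported, not imputed.
* The Wilcoxon exact branch requires tie-free data; tied small samples
  fall back to the tie-corrected normal approximation.
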