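# Methods

This note records the models implemented in `gpitrio`, their
assumptions, the defaults that matter, and what the synthetic-data
tests do and do not establish.

## Inheritance classification

A candidate genotype configuration at one site must be consistent with
a monoallelic mode (de novo, or dominantly inherited from an affected
parent), a biallelic mode (homozygous, or compound heterozygous in
*trans*) or an X-linked hemizygous mode. The classifier is a pure
truth table over trio genotypes:

- *de novo*: child het or hom-alt with both parents hom-ref. (A hom-alt
  de novo implies two independent events; it is labelled, rarity makes
  it vanishing in practice.)
- *inherited monoallelic*: child het with at least one carrier parent
  able to transmit the allele; the origin is the unique carrier parent,
  or `ambiguous` when both carry (or a parent genotype is missing).
- *hom biallelic*: child hom-alt with both parents carriers.
- A child hom-alt with a hom-ref parent violates transmission and is
  dropped to a violations counter: deletions and uniparental events are
  deliberately not modelled, and genotyping error is handled by an
  upstream QC gate (site PASS status plus optional depth / allele-
  fraction thresholds), not by a probabilistic error model.

Compound-heterozygote pairing is phase-by-parental-origin: within one
gene, every (paternal-only het, maternal-only het) pair is a *trans*
candidate; *cis* pairs are never emitted, and sites carried het by both
parents are phase-ambiguous and excluded by default
(`include_ambiguous_comphet` re-admits them, flagged). Pairing never
crosses gene boundaries.

Dominant transmission: an inherited monoallelic candidate is admitted
only when the transmitting parent is affected (ambiguous origin: any
affected parent). This reproduces the strong dependence of per-trio
candidate counts on parental affected status seen in large trio
cohorts, which the test suite checks qualitatively (strata with two
affected parents carry more exome-wide candidates than strata with
none).

## Filter cascade

Stages run in a fixed order — classify, pair, MAF, consequence,
PolyPhen, homozygote count, panel — so per-stage elimination counts are
reproducible; the output is invariant to input record order.

- **MAF** (strict `<`): monoallelic candidates at 0.1%
  (`maf_threshold_monoallelic = 0.001`), each site of a biallelic or
  X-linked candidate at 1% (`maf_threshold_biallelic = 0.01`). Missing
  frequencies are treated as 0 — absence from the reference cohort is
  precisely the rare case the filters target. An optional strict mode
  (`strict_biallelic_maf`) applies the 0.1% threshold to biallelic
  calls as well; it is off by default because the tighter biallelic
  threshold describes a post-review curation step rather than the
  cohort-wide rule, and both behaviours are wanted as config options.
- **Consequence**: the annotated class must be protein altering
  ({stop gained, frameshift, splice acceptor/donor, missense, in-frame
  indel}). Annotation is a deliberately simplified single-transcript
  dialect carried in INFO keys `GENE`, `CSQCLASS`, `PPH2`, `MAF`,
  `NHOM` (+ optional `CDNA`); re-implementing a full effect predictor
  is out of scope and cross-transcript severity ranking is collapsed
  into the single annotated class.
- **PolyPhen**: inherited missense predicted benign is excluded; de
  novo benign missense and missing predictions pass.
- **Homozygote count**: biallelic calls only — a constituent site with
  MAF inside [0.1%, 1%] that has been observed homozygous at least
  `hom_count_exclusion_min = 2` times in the reference cohort kills the
  call. "Multiple times" is not quantified in the source analyses, so
  the minimum is 2 and config-exposed. Sites below the band never
  trigger the rule; sites above 1% never reach it (already failed MAF).
- **Panel**: gene membership in the config-supplied panel. The default
  ships the 14 named pathway genes (the full 31-gene clinical panel is
  supply-your-own). In the default recessive-focus mode, monoallelic
  survivors inside the panel are logged but not flagged (pathway genes
  with recessive inheritance and low haploinsufficiency sensitivity),
  and off-panel de novo survivors are kept in an incidental lane.

The incidence estimate is `100·(diagnosed families)/(independent
families)` to two decimals, counting families rather than trios so an
affected sibling pair contributes once.

## Autozygosity and inbreeding

Segments are called from allelic ratios (alt depth / total depth) of
QC-passing sites with depth ≥ 10. The caller is a transparent
run-length scanner rather than an HMM: a segment is a maximal run of
homozygous-like markers (ratio ≤ 0.1 or ≥ 0.9), broken at inter-marker
gaps > 3 Mb (exome coverage is uneven), emitted at ≥ 2 Mb span and
≥ 25 markers. Genotype error is tolerated by absorbing isolated
heterozygous markers, with the constraint that absorbed hets must be at
least 1/rate Mb apart (default rate 1/Mb). The local-spacing form was
chosen over a cumulative per-span budget deliberately: a cumulative
budget lets a long clean run bank exceptions and overrun its true
boundary by megabases, while the local rule bounds boundary blur to the
first few flanking markers. The commercial segment caller used in
practice is replaced by this testable stand-in; an HMM backend could be
added behind the same interface. Copy-neutral LOH is not distinguished
from deletion (no coverage modelling); both count as
homozygosity-by-descent for F.

Observed F is the autosomal fraction covered by segments (GRCh37
chr1–22 lengths, config-overridable); X is excluded. The pedigree
expectation is the recursive kinship coefficient of the parents
(founders: φ = 1/2 with self, 0 pairwise), giving 1/16 for first-cousin
matings. Gene containment in a shared segment requires containment (not
overlap) in one segment per affected individual, and reports the
intersected interval.

Chance homozygosity inflates caller-based F slightly relative to the
true autozygous fraction (flanking extension plus bridging of short
non-autozygous gaps between true tracts). The recovery tests therefore
check (i) the mean true autozygous fraction of simulated first-cousin
offspring against the 1/16 expectation, (ii) that caller-based F on
non-consanguineous genomes stays below 0.02 in ≥95% of replicates, and
(iii) exact boundary recovery (within one marker interval) on
error-free marker data.

## Co-segregation statistic

For a biallelic candidate with two heterozygous carrier parents, an
additional sibling inherits both risk alleles with probability 1/4
under Mendelian transmission unlinked to disease — whatever the
sibling's affected status. A tested affected carrier sibling therefore
contributes 1/4 and a tested unaffected non-carrier 3/4; families
multiply over tested siblings, untested siblings and families
contribute nothing (NA), and the cohort value is the product of
informative families, kept as an exact `Fraction` and reported rounded
to three decimals. Homozygous-model families use the same 1/4–3/4
values (both parents are het carriers). The statistic is one-sided,
purely combinatorial and uncorrected — descriptive evidence of
co-segregation, not a calibrated hypothesis test.

## Exon-skip consequences

`TranscriptModel` is an abstract exon table (lengths, CDS offsets,
optional spliced sequence); real genomic coordinates are unnecessary.
The skipped amplicon is the full RT-PCR product minus the skipped exon
length (the exon must lie strictly between the primer exons); a skip
shifts the frame iff the exon's coding length is not divisible by 3.
Protein notation comes from translating the intact and skip-modified
CDS and scanning for the first altered residue: frameshifts are
reported `p.Xn fs*N` with N the distance to the new stop (`fs*1` for an
immediate junction stop, `*?` with a warning when no stop is reached),
in-frame skips as `p.(Xi_Yj del)` with the end clamped to the last
residue when the removed block spans the stop codon. The notation is
loose HGVS by design — no grammar validation. A skip matching a known
alternative isoform raises an interpretation-caveat flag only; it is
not a pathogenicity call.

The shipped synthetic transcript encodes the structure of the analysed
splice case: a 91 bp exon 3 beginning at c.336 whose skip makes residue
113 (Asp) a Trp followed immediately by a stop (`p.D113fs*2`), with
exon 5 as a known natural skip.

## ACMG combination

Only combination is in scope: assigning codes to variants is expert
work. Codes carry canonical strengths (PVS very strong; PS strong; PM
moderate; PP supporting; BA stand-alone; BS strong; BP supporting) and
may be adjusted with a recorded reason; the combiner works on effective
strengths, so PM3 upgraded to strong counts as a PS. The combining
rules are transcribed into `data/acmg_rules.json` as minimum-count
patterns per strength tier; matching lets surplus stronger evidence
fill weaker slots, which coincides with the published table on all
canonical-strength sets (verified exhaustively for ≤ 4 pathogenic-side
codes against an independently transcribed oracle). Evidence matching
both sides, or neither, yields `uncertain`.

## Synthetic cohort

The generator emits the stated world the pipeline assumes, not a
tuned-to-pass dataset:

- Background sites: MAF log-uniform on [1e-5, 0.5]; parents in
  Hardy–Weinberg proportions; children by Mendelian transmission;
  depths Poisson(60) with binomial allele split; consequence classes at
  fixed realistic frequencies (40% missense, 25% synonymous, 20%
  non-coding, 15% truncating/splice/in-frame); reference homozygote
  counts Poisson(maf²·60706). Defaults of 50 trios × 5000 sites keep
  the end-to-end runs inside a couple of CPU-minutes; this is an
  exome-scale-down (a real exome carries ~20k variants), which lowers
  absolute candidate counts but not the filter logic being tested.
- The six shipped family specifications reproduce the published
  genotype configurations (parental origins, consequence classes,
  reference allele frequencies, sibling outcomes), with the
  consanguineous family contributing a second trio for its affected
  brother.
- Decoys reproduce the published exclusions: de novo missense in
  *PIGM*/*MPPE1* (recessive-focus lane), biallelic *PIGW*/*PIGS*/*GPLD1*
  genotypes inside the homozygote-exclusion band with ≥ 2 reference
  homozygotes, and an off-panel *SYNGAP1* de novo stop (incidental
  lane). Decoy MAF/homozygote values are representative band members,
  not published figures.
- Gene dropping: founders carry uniquely labelled haplotypes; each
  meiosis applies interference-free Poisson crossovers (mean
  length/100 Mb) at uniform positions; autozygous tracts are intervals
  where the offspring's haplotype labels coalesce. Marker genotypes
  draw founder alleles at per-marker frequencies uniform on
  [0.05, 0.95]; emitted allelic ratios are exact (genotype error
  defaults to 0 so worked examples are deterministic).
- The genome map (GRCh37 lengths, panel genes at fixed approximately
  real loci, *PIGT* on chromosome 20) is synthetic and internally
  consistent; no external resources are downloaded.

What green tests establish: the cascade's selectivity and ordering, the
exactness of the combinatorial statistics, and the statistical recovery
of planted structure under the generator's assumptions. What they do
not: performance on real exome data — real cohorts have linkage
disequilibrium, annotation ambiguity across transcripts, genotyping
error correlated with coverage, and population structure, none of which
the generator models. Cohort-scale observational quantities from the
real study data (per-stratum candidate means, observed sibling F
values, initial candidate-trio counts, per-variant ACMG tallies) are
out of reach without the restricted-access data and are not asserted.

## Numerical and interface conventions

Coordinates are 1-based inclusive as in VCF; BED output converts to
0-based half-open at the writer boundary. Multi-allelic VCF lines are
decomposed per ALT with other alternate alleles recoded as reference;
allele observations are conserved across the decomposition. MAF is
written with 9 significant digits and survives the float32 INFO round
trip to ~1e-7 relative error. X-chromosome PAR boundaries are GRCh37
constants; hemizygous calls are only accepted outside them. All
randomness flows from a single seed through `numpy.random.default_rng`;
report rows and JSON keys are sorted so equal inputs give byte-equal
outputs.
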