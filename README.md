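# gpitrio

Trio-exome prioritization of recessive variants in the
glycosylphosphatidylinositol (GPI) anchor biosynthesis pathway.

Defects in GPI-anchor biogenesis genes (*PGAP3*, *PIGN*, *PIGT*, *PIGO*,
*PIGL* and relatives) cause developmental disorders with epilepsy,
microcephaly and, in several genes, abnormal serum alkaline phosphatase.
Finding these diagnoses in a large cohort of parent–child trios requires
a disciplined filtering cascade: candidate genotypes must fit a Mendelian
inheritance model, be rare in reference populations, alter the protein,
and fall in the pathway gene panel — while common-but-benign biallelic
genotypes (repeatedly seen homozygous in reference cohorts) and de novo
hits in haplosufficient pathway genes are set aside. `gpitrio` implements
that cascade as a tested, reusable library and CLI, together with the
companion analyses used to weigh the survivors:

- **Inheritance classification** per trio: de novo, dominantly inherited
  monoallelic, homozygous or compound-heterozygous biallelic (with
  parental-phase-aware *trans* pairing), and X-linked hemizygous calls.
- **Filter cascade**: MAF thresholds (monoallelic < 0.1%, biallelic < 1%),
  protein-altering consequence, PolyPhen-2 exclusion of inherited benign
  missense, reference-homozygote exclusion in the 0.1–1% MAF band, panel
  membership; per-stage elimination counts and a diagnostic-yield
  (incidence) estimate.
- **Autozygosity mapping**: homozygous-by-descent segments from allelic
  ratios, the observed inbreeding coefficient
  F = (autozygous autosomal length)/(autosomal genome length), the
  pedigree expectation via the recursive kinship coefficient
  (F = φ(father, mother), 1/16 for first-cousin offspring), and
  candidate-gene containment in segments shared between affected sibs.
- **Co-segregation statistic**: under the null, an additional sibling of
  a biallelic proband carries both risk alleles with probability 1/4;
  the per-family probability of the observed sibling genotypes is
  multiplied across informative families (exact rational arithmetic).
- **Exon-skip consequence prediction**: RT-PCR amplicon sizes with and
  without a skipped exon, frame status (length mod 3), and loose-HGVS
  protein notation such as `p.D113fs*2` by translating the modified CDS.
- **ACMG evidence combination**: the published combining rules over
  effective evidence strengths, supporting expert strength adjustments
  (e.g. PM3 moderate → strong) with an audit trail.
- **Synthetic cohorts**: Hardy–Weinberg background trios with Mendelian
  transmission, six shipped family specifications reproducing the
  published biallelic genotype configurations, decoy families that must
  be eliminated at predictable stages, and a gene-dropping simulator
  (Poisson recombination) for consanguineous genomes with known
  autozygous tracts.

## Worked example

```bash
gpitrio simulate --out-dir cohort --seed 1 --trios 50 --sites 5000
gpitrio filter --vcf-dir cohort --ped cohort/cohort.ped \
    --panel cohort/panel.txt --out-dir cohort/out
# -> flagged 7 trios, 11 variants in 5 genes
gpitrio segregate --out cohort/out/segregation.json
# -> combined null probability: 0.026
gpitrio splice --skip-exon 3 --fwd-exon 2 --rev-exon 5 --full-size 280 \
    --out cohort/out/splice.json
# -> 280 bp -> 189 bp, frameshift=True, p.D113fs*2
gpitrio report --in-dir cohort/out --out cohort/summary.json
```

The simulated cohort contains 50 background trios, seven trios from the
six shipped diagnosed-family specifications (one consanguineous family
contributes two affected brothers) and seven decoy trios. The filter
cascade flags exactly the seven planted trios, listing 11 distinct
biallelic candidate variants across the five pathway genes; every decoy
is removed at its designed stage (reference-homozygote exclusion for the
*PIGW*/*PIGS*/*GPLD1* carriers, the recessive-focus lane for the *PIGM*/
*MPPE1* de novo missense calls, and the panel filter — with an incidental
report lane — for an off-panel *SYNGAP1* de novo stop). The co-segregation
product over the four informative families is 27/1024 ≈ 0.026, and with
6 diagnosed families the incidence estimate is `100·6/4125 = 0.15%`.

In Python the same computation is three calls:

```python
from gpitrio.simulate import build_cohort
from gpitrio.filters import run_filter_pipeline

cohort = build_cohort(n_background_trios=50, seed=1, n_sites=5000)
result = run_filter_pipeline(cohort)
print(result.summary()["n_flagged_trios"])   # 7
```

## Acceptance script

`scripts/acceptance.py` recomputes the headline quantities from scratch
by running the package — the combined segregation probability from the
shipped family observations, the skipped-exon amplicon size from the
synthetic transcript model, and the flagged-trio / distinct-variant
counts from a freshly simulated cohort passed through the cascade — and
writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/gpitrio/
  model.py         domain types, config, genome constants
  io.py            VCF/PED/panel/config readers, TSV/BED/JSON writers
  inheritance.py   trio genotype classification, compound-het pairing
  filters.py       the filter cascade and cohort pipeline
  autozygosity.py  ROH calling, inbreeding coefficients, pedigree kinship
  segregation.py   co-segregation null probabilities
  splice.py        exon-skip amplicon and protein consequences
  acmg.py          ACMG evidence combination (+ data/acmg_rules.json)
  simulate.py      synthetic cohorts, planted families, gene dropping
  cli.py           subcommands: simulate filter roh segregate splice acmg report
```

See `docs/methods.md` for the modelling decisions and their rationale.
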