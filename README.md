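# cnphase

Deterministic phasing of normal and CNV-carrying haplotypes within copy
number variant (CNV) regions in nuclear families, from SNP genotyping
array data.

## The problem

CNV callers (QuantiSNP, PennCNV, Fawkes) report, per sample, the total
diploid copy number CN of a genomic segment and per-marker multi-ploid
"CNV genotypes" — allele multisets over the array's two alleles {A, B}
whose size equals CN, e.g. `-` (CN=0), `A`, `AB`, `ABB`, `ABBB`.  These
genotypes mix both homologous chromosomes: they say nothing about which
haplotype carries the deletion or the extra copies, nor which parent a
child's variant came from.  `cnphase` resolves that.  Given genotypes,
CNV calls and a pedigree of nuclear families, it reconstructs for every
family CNV region:

* each parent's pair of haplotypes — *normal* (haploid copy number
  cn = 1) or *CNV-carrying* (cn = 0 deletion; cn = 2, 3 gain) — with the
  full allelic composition of every copy,
* the gamete formation scheme of every child: Mendelian transmission, or
  the simplest non-Mendelian events — de novo deletion, de novo
  duplication (intra- or inter-chromosomal), uniparental isodisomy or
  heterodisomy,
* downstream statistics: transmission rates of CNV-carrying versus
  normal haplotypes with a chi-square test against 50:50 segregation,
  and allelic variability *between* haplotypes and *within* multi-copy
  haplotypes.

## The method

For one region, every member's genotype at every retained marker is an
allele multiset of size equal to that member's region CN.  The engine
enumerates all parental phases — partitions of each parent's per-marker
multisets into two haplotypes under an allowed haploid split (CN=3 →
1+2, CN=4 → 2+2 or 1+3, haploid cn ≤ 3) — and all region-wide gamete
formation schemes per child, and scores each family solution
lexicographically by

```
(number of unexplained member×marker genotypes,  number of non-Mendelian events)
```

All children are evaluated jointly against shared parental phases.
Mendelian scenarios are tried first; non-Mendelian events are admitted
in ascending event count only when Mendelian inheritance cannot explain
the data.  The *complete* set of co-optimal solutions is returned; a
region is *unambiguous* when exactly one remains after collapsing
relabelings that no data could distinguish.  The search is exact: an
independent brute-force enumeration (`brute_force_oracle`) reproduces
the same co-optimal sets on randomized small regions.

Upstream, calls from two callers are intersected per sample (same-type,
≥1 bp overlap), optionally confirmed against an external call set,
filtered (autosomes only, length ≥ 1000 bp, log Bayes Factor ≥ 5) and
converged into family-wise regions (≥3 shared markers when multiple
carrier calls intersect; regions with single-caller raw calls in other
members are excluded).  Markers with no-calls or call confidence < 0.95
in any member, and markers monomorphic across the family, are dropped
before phasing.

## Worked example

```bash
python examples/phase_duplication_family.py
```

phases a trio in which the mother has CN=3 and prints:

```
region T1:1:1000000-1150000: score (0, 0), 1 co-optimal solution(s)
  father hap1 (cn=1): A|A|A|A
  father hap2 (cn=1): B|A|A|A
  mother hap1 (cn=1): B|A|A|B
  mother hap2 (cn=2): AA|AB|BB|AB
  CHILD: paternal mendelian gamete cn=1, maternal mendelian gamete cn=2
  gain haplotype (mother, cn=2): between-informative=True, within-informative=True
```

The unique zero-cost solution gives the mother a normal haplotype
(`B|A|A|B`) and a duplication-carrying haplotype whose two allelic
copies are spelled out per marker (`AA|AB|BB|AB`); `AB` entries mean the
two copies on that single haplotype differ — a polymorphism *within* the
duplication, which is what `within-informative=True` flags.  The child
received the duplication haplotype from the mother by ordinary Mendelian
transmission.

Other examples: `pipeline_from_files.py` (files in → phased regions and
summary out), `denovo_classification.py` (parent-of-origin and
intra/inter typing of de novo events), `transmission_bias.py`
(length-stratified transmission table and the 50:50 test).

## Command line

```bash
cnphase simulate --seed 5 --n-families 20 --out data/
cnphase phase    --genotypes data/genotypes.tsv --calls-a data/calls_quantisnp.tsv \
                 --calls-b data/calls_penncnv.tsv --ped data/families.ped --out phased/
cnphase analyze  --genotypes ... --calls-a ... --calls-b ... --ped ... --out analysis/
cnphase validate --seed 0 --n-regions 200 --out report.json
```

`phase` writes `regions.tsv`, `phasing.tsv` (one row per solution ×
member × haplotype) and `phasing.json`; `analyze` writes
`transmissions.tsv`, `summary.json` and `denovo.tsv`.

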