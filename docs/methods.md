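# Methods

## Data model

A *CNV genotype* at one marker is a multiset over the array alleles
{A, B} whose size equals the individual's diploid copy number (CN,
0–4) of the surrounding region: `-`, `A`, `AB`, `ABB`, `ABBB`, …
Internally every multiset is an allele-count pair `(nA, nB)`, which
makes union, sub-multiset and partition operations integer arithmetic
and gives a canonical A-before-B spelling for free.

A *haplotype* is one homolog's content across the region's retained
markers: a haploid copy number cn ∈ {0, 1, 2, 3} and, per marker, a
multiset of size cn.  cn = 1 is a normal haplotype; cn = 0 a
deletion-carrying and cn ≥ 2 a gain-carrying one.  A parent's *phase*
is an unordered haplotype pair whose per-marker union equals the
parent's observed genotype.  Supported diploid CNs are 0–4 with haploid
cn capped at 3; larger CNs are rejected.

## Inheritance model

Each child receives one gamete from each parent, formed by one
region-wide *event* per (child, parent):

* **Mendelian** — one parental haplotype, unmodified.
* **De novo deletion** — a uniform-cn sub-haplotype of one source
  haplotype (any per-marker sub-multiset; target cn anywhere below the
  source cn).
* **De novo duplication** — the source haplotype plus one extra allele
  copy per marker (more only via `allow_multistep_dup`), drawn from the
  source's own alleles or from the other homolog's, with gamete cn ≤ 3.
  Duplications require a source with cn ≥ 1: a "gain" built on an empty
  haplotype is not a duplication, and its data signature is already
  covered by alternatives from the other haplotype.
* **Uniparental disomy** — a child-level alternative: both gametes come
  from one parent, either two copies of one haplotype (isodisomy) or
  both haplotypes (heterodisomy), and nothing from the other parent.

Events are constant across the region's markers for a given
(child, parent), but may differ between children of the same family.

Duplication typing is derived from content, not from the enumeration
branch: an event is *intra-chromosomal* when every extra allele copy
occurs on the source haplotype and at least one is absent from the
other homolog at some marker; *inter-chromosomal* in the mirrored case;
*ambiguous* otherwise (the two conditions are mutually exclusive).

## Scoring and search

A family solution (two parental phases plus one scheme per child) is
scored lexicographically by `(n_unexplained, n_nonmendelian)`:
unexplained cells are (member, marker) genotypes not reproduced by the
solution, counted per cell; every non-Mendelian gamete counts one
event and a UPD counts one per child (one meiotic error;
`count_upd_as=2` is available).  A child for which no copy-number-
feasible gamete pairing exists at all contributes
`max(n_markers, 1)` unexplained cells and a null scheme — the copy
number itself is the unexplained observation when no markers remain.

The engine exploits a factorization: once a *configuration* — the
haploid split of each parent plus each child's event shape (kind,
source, gamete cn) — is fixed, markers decouple, and the minimal number
of unexplained cells is the sum over markers of local minima over
ordered parental partitions and per-child gamete contents.
Configurations are scanned in ascending event count, so purely
Mendelian scenarios are tried first and the simplest non-Mendelian
explanation wins when Mendelian inheritance cannot explain the data;
the scan stops at the first event level admitting a zero-unexplained
solution, which is provably the lexicographic optimum.  All co-optimal
solutions are then materialized as the product of locally optimal
assignments.  At an unexplained cell the gamete content is fixed to a
deterministic canonical pick instead of being enumerated, so ambiguity
reflects data, not bookkeeping.

Two solutions are *equivalent* when no data could distinguish them:
identical up to swapping a parent's haplotype labels, or differing only
in which source haplotype an event is attributed to while the gamete
content is the same (e.g. a deletion to an empty gamete from either
homolog).  The canonical serialization therefore sorts each phase pair
and keys schemes by (event kind, gamete contents); solutions are
deduplicated and ordered by this key.  A region is *unambiguous* iff
one solution survives.  A configurable budget
(`max_combinations`, default 10⁶ scored combinations) turns
pathological regions into an explicit error rather than a silent
approximation.

`brute_force_oracle` is an independent reference: explicit allele
tuples, index-combination partitioning, exhaustive gamete pairing and a
full cartesian product over children, with no factorization and no
staging.  It is only feasible for small regions (hard cap, refusal
beyond) and is used to validate the engine's co-optimal sets.

The parent of origin of a de novo event is *determined* only when the
two parents' phases differ; with indistinguishable parental haplotypes
the mirrored solution is equally optimal, and region-level reports also
require all co-optimal solutions to agree before naming a parent.

## Upstream filters

* Sample QC (PennCNV array metrics, all inclusive as printed):
  LRR_SD ≤ 0.25, BAF_SD ≤ 0.05, BAF_DRIFT ≤ 0.002, |GCWF| ≤ 0.04.
* Two-caller intersection: same sample, same type (gain/loss), ≥ 1 bp
  overlap; the intersection interval is kept, with cn and LBF from the
  primary caller (a cn discord between agreeing callers is logged).
  Coordinates are 1-based, inclusive.
* External confirmation (optional): same overlap/type rule, internal
  coordinates preserved.
* Call filters: autosomes only; length ≥ 1000 bp; log Bayes Factor ≥ 5
  ("shorter than" and "less than" are strict on the removed side).
* Family-region convergence: overlapping member calls cluster; the
  region interval is the intersection of carrier calls; regions are
  excluded when ≥ 2 carrier calls share an empty interval or fewer than
  3 markers, when a non-carrier member has a raw single-caller call
  overlapping the interval, or when a member has overlapping calls of
  different cn (complex, non-constant CN).  The ≥3-shared-marker rule is
  applied only when an intersection of ≥ 2 carrier calls is taken.
* Marker selection (family-wise): a marker is dropped when any member
  has a no-call or genotype confidence < 0.95 there, when it is
  monomorphic across the family, when it lies outside the interval, or
  when a member's genotype size contradicts its region CN.  A region
  with zero retained markers is kept, flagged `uninformative`, and may
  still phase through copy numbers alone.

## Transmission and variability analytics

Regions are grouped by parental carrier status: A (exactly one carrier
parent), B (both), C (no carrier parent, ≥ 1 carrier child — putative
de novo).  Transmission counting uses only unambiguously phased group-A
regions, one event per locus per child, and only Mendelian gametes from
the carrier parent (a non-Mendelian gamete transmits neither parental
haplotype intact); group-B regions are excluded from the bias analysis.
Note the ascertainment this shares with any such analysis: ambiguously
phased regions are excluded, and ambiguity is correlated with which
haplotype was transmitted.

Lengths are binned half-open with inclusive lower edges:
[0, 10 kb), [10, 30 kb), [30, 100 kb), [100 kb, ∞).  Deviation from
50:50 segregation is tested with Pearson's chi-square with Yates
continuity correction (statistic clamped at zero, so an even split
gives p = 1); the correction reproduces p = 0.011 and p = 0.037 on the
(580, 671) and (70, 98) count pairs where the uncorrected test gives
0.010 and 0.031.  An `corrected=False` switch gives the plain test.
Multiple-testing adjustment is Bonferroni by default, with Holm and
Benjamini–Hochberg available.  The corrected test is slightly
conservative: its exact type-I error at n = 150 events and α = 0.05 is
0.041.

For every gain haplotype (cn ≥ 2) of a phased parent, two flags are
reported: *within*-informative — some marker's tuple on that haplotype
holds both alleles (distinguishable allelic copies inside the gain) —
and *between*-informative — some marker distinguishes the parent's two
haplotypes.  "Distinguishes" requires the marker to be polymorphic in
that parent: a pure dosage difference of one allele (e.g. `A` vs `AA`)
does not separate allelic content and is not counted.

## Synthetic families

The simulator draws nuclear families (1–3 children, weighted 0.7 / 0.2
/ 0.1) and per family a set of CNV regions with 4–12 markers, region
lengths log-uniform on 1.5–400 kb (populating all four length bins),
and a shared B-allele frequency of 0.3 per region (no linkage
disequilibrium model — sufficient to exercise marker informativeness,
not a model of real LD structure).  Carrier configurations reflect
family CNV collections on arrays: 79% single-parent deletion carriers,
11% / 3% single-parent duplication (cn = 2 / cn = 3) carriers, 5%
both-parent regions, 2% with no parental carrier (a de novo event in a
child is then forced, deletions 74%).  Non-Mendelian rates are rare,
as in germline data: per meiosis 0.005 de novo deletion and 0.002 each
intra-/inter-chromosomal duplication; per child 0.001 each iso- and
heterodisomy.  Noise defaults: 2% no-calls, 3% low-confidence cells,
0.5% single-allele genotype errors.  Haplotypes are drawn first, then
gametes per the event model, and observed genotypes are exact multiset
unions before noise — so simulated data satisfies the engine's
conservation invariants by construction.

**Identifiability contract.**  A drawn non-Mendelian event is resampled
(up to 100 attempts) whenever the child's resulting data admits a
Mendelian explanation under *some* parental phase pair — checked with a
direct phase/haplotype enumeration, not the engine's scoring path.
Without this, a parsimony method is *correct* to prefer the coincidental
Mendelian explanation, and "truth recovered" would be ill-posed.  The
contract means recovery results quantify the engine's correctness in
the identifiable regime; they do not measure how often real
non-Mendelian events are masked by coincidental haplotype sharing,
which depends on real allele frequencies and marker density.  Noise is
injected after the truth is fixed and can break the guarantee, as on
real arrays.

Randomness derives from one root seed; per-region streams are derived
by counter, so reordering families does not change a region's draw, and
identical parameters reproduce byte-identical output files.

## Problem sizes used in the self-checks

Oracle-equivalence runs use randomized regions with ≤ 4 markers,
member CN ≤ 4 and elevated event rates so every event kind occurs, with
instances beyond the reference search's cap redrawn (they exceed what an
exhaustive enumeration can score, not what the engine can phase);
500 such regions are compared per run.  Truth recovery uses 1000
noise-free regions under the default study conditions with two-child
families.  The bias-test calibration uses 20 000 replicate datasets of
150 events each, so the Monte Carlo error (~0.0014) is small against
the tested ±0.015 band.

## Known limitations

* No statistical/population phasing, no linkage disequilibrium, no
  recombination within a region, no mosaicism; sex chromosomes are out
  of scope (filtered upstream).
* Multi-step de novo gains are off by default (`allow_multistep_dup`);
  haploid cn > 3 and diploid CN > 4 are rejected outright.
* CN = 2 carriers (a 0 + 2 haplotype pair in a copy-number-polymorphic
  locus) are reachable only via an explicit `cn_splits` override, since
  CN = 2 individuals carry no call; the default split for CN = 2 is
  1 + 1.
* Phased genotypes are derived strictly from the chosen phases and
  schemes; no per-marker genotype re-calling is attempted — a cell no
  scheme can reproduce stays counted as unexplained.
* Exponentially ambiguous regions (many unconstrained heterozygous
  markers) hit the combination budget and error out explicitly rather
  than returning a truncated solution set.
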