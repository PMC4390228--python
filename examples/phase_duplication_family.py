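"""Phase a trio in which the mother carries a duplication haplotype.

The mother has diploid copy number 3 in the region (one normal haplotype
plus one cn=2 duplication-carrying haplotype); the father is a normal
CN=2 individual.  The child's triploid genotypes pin down the maternal
phase, including a heterozygous allelic copy *inside* the duplication
haplotype.
"""

from cnphase import Family, phase_region
from cnphase.model import CnvRegion
from cnphase.family_analysis import allelic_variability

A, B, AB, AA = (1, 0), (0, 1), (1, 1), (2, 0)
AAB, ABB, AAA = (2, 1), (1, 2), (3, 0)

region = CnvRegion(
    family_id="T1",
    chrom="1",
    start=1_000_000,
    end=1_150_000,
    member_cn={"FATHER": 2, "MOTHER": 3, "CHILD": 3},
    marker_ids=("SNP1", "SNP2", "SNP3", "SNP7"),
    marker_pos=(1_000_100, 1_040_000, 1_080_000, 1_120_000),
    genotypes={
        "FATHER": (AB, AA, AA, AA),
        "MOTHER": (AAB, AAB, ABB, ABB),
        "CHILD": (AAA, AAB, ABB, AAB),
    },
    carrier_parents=frozenset({"mother"}),
    carrier_members=frozenset({"MOTHER", "CHILD"}),
)
family = Family("T1", "FATHER", "MOTHER", ("CHILD",))

result = phase_region(region, family)
print(f"region {region.region_id}: score {result.score}, "
      f"{len(result.solutions)} co-optimal solution(s)")
sol = result.solutions[0]
for role, phase in (("father", sol.father_phase), ("mother", sol.mother_phase)):
    for i, hap in enumerate(phase.haps):
        print(f"  {role} hap{i + 1} (cn={hap.cn}): {'|'.join(hap.allele_strings())}")
for cid, (fs, ms) in sol.schemes:
    print(f"  {cid}: paternal {fs.event.value} gamete cn={fs.gametes[0].cn}, "
          f"maternal {ms.event.value} gamete cn={ms.gametes[0].cn}")
for rep in allelic_variability(sol, region.region_id):
    print(f"  gain haplotype ({rep.parent}, cn={rep.hap_cn}): "
          f"between-informative={rep.has_between_informative}, "
          f"within-informative={rep.has_within_informative}")

# The unique solution assigns the mother a normal haplotype and a cn=2
# duplication haplotype; 'within-informative=True' means the duplication
# haplotype itself carries both alleles at some marker (here SNP2/SNP7),
# i.e. its two allelic copies are distinguishable.
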