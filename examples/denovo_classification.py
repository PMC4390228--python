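"""Classify de novo events: parent of origin and intra/inter typing.

Two trios.  In the first, both parents have the same AB genotype and the
child lost one haplotype: the de novo deletion cannot be assigned to a
parental chromosome, so two equally parsimonious solutions are reported.
In the second, the child carries a de novo duplication whose extra allele
copies match one paternal haplotype and differ from the other homolog:
the event is typed intra-chromosomal, on the paternal chromosome.
"""

from cnphase import Event, Family, classify_de_novo, phase_region
from cnphase.model import CnvRegion

A, B, AB = (1, 0), (0, 1), (1, 1)
AAB, ABB = (2, 1), (1, 2)


def show(region, family, title):
    result = phase_region(region, family)
    print(f"{title}: {len(result.solutions)} co-optimal solution(s), "
          f"score {result.score}")
    for sol in result.solutions:
        for cid, scheme in sol.schemes:
            for side in scheme:
                if side.event in (Event.MENDELIAN,) or not side.gametes:
                    continue
                ann = classify_de_novo(sol, side)
                origin = side.parent if ann.parent_of_origin_determined else "undetermined"
                extra = f", {ann.dup_class.value}" if ann.dup_class else ""
                print(f"  child {cid}: {side.event.value} "
                      f"(origin: {origin}{extra})")
    print()


deletion_trio = CnvRegion(
    "T2", "1", 2_000_000, 2_103_000,
    member_cn={"FA": 2, "MO": 2, "CH": 1},
    marker_ids=("rs1",), marker_pos=(2_050_000,),
    genotypes={"FA": (AB,), "MO": (AB,), "CH": (A,)},
    carrier_parents=frozenset(), carrier_members=frozenset({"CH"}),
)
show(deletion_trio, Family("T2", "FA", "MO", ("CH",)),
     "de novo deletion, indistinguishable parents")

duplication_trio = CnvRegion(
    "T3", "2", 3_000_000, 3_167_000,
    member_cn={"FA": 2, "MO": 1, "CH": 3},
    marker_ids=("rs2", "rs3"), marker_pos=(3_050_000, 3_100_000),
    genotypes={"FA": (AB, AB), "MO": (A, B), "CH": (ABB, AAB)},
    carrier_parents=frozenset({"mother"}), carrier_members=frozenset({"MO", "CH"}),
)
show(duplication_trio, Family("T3", "FA", "MO", ("CH",)),
     "de novo duplication, informative parents")

# The first trio prints two solutions with origin 'undetermined'; the
# second prints one solution typed denovo_dup_intra on the father --
# every extra allele copy matches the source haplotype and at least one
# differs from the other homolog.
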