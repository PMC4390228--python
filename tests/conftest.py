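"""Shared fixtures: worked family regions and small on-disk datasets."""

import pytest

from cnphase.model import CnvRegion, Family

# allele count-pair shorthands
A, B = (1, 0), (0, 1)
AA, AB, BB = (2, 0), (1, 1), (0, 2)
AAA, AAB, ABB, BBB = (3, 0), (2, 1), (1, 2), (0, 3)


def make_region(member_cn, genotypes, carrier_parents, carrier_members,
                family_id="FAM", chrom="1", start=100, end=200):
    n = len(next(iter(genotypes.values())))
    return CnvRegion(
        family_id=family_id,
        chrom=chrom,
        start=start,
        end=end,
        member_cn=member_cn,
        marker_ids=tuple(f"m{i + 1}" for i in range(n)),
        marker_pos=tuple(start + 10 * i for i in range(n)),
        genotypes=genotypes,
        carrier_parents=frozenset(carrier_parents),
        carrier_members=frozenset(carrier_members),
    )


@pytest.fixture
def region_builder():
    return make_region


@pytest.fixture
def duplication_family():
    """Father with two normal haplotypes; mother carrying a duplication
    haplotype (cn=2) with a heterozygous allelic copy inside it, transmitted
    to the child (CN=3).  Phasing is unambiguous by design."""
    region = make_region(
        {"FA": 2, "MO": 3, "CH": 3},
        {
            "FA": (AB, AA, AA, AA),
            "MO": (AAB, AAB, ABB, ABB),
            "CH": (AAA, AAB, ABB, AAB),
        },
        {"mother"},
        {"MO", "CH"},
        family_id="DUPFAM",
    )
    family = Family("DUPFAM", "FA", "MO", ("CH",))
    return region, family


@pytest.fixture
def denovo_deletion_trio():
    """Parents with indistinguishable AB genotypes and a child with a
    monoploid genotype: a de novo deletion that cannot be assigned to a
    parental chromosome (two equally parsimonious explanations)."""
    region = make_region(
        {"FA": 2, "MO": 2, "CH": 1},
        {"FA": (AB,), "MO": (AB,), "CH": (A,)},
        set(),
        {"CH"},
        family_id="DELFAM",
    )
    family = Family("DELFAM", "FA", "MO", ("CH",))
    return region, family


@pytest.fixture
def denovo_duplication_trio():
    """Child with a de novo intra-chromosomal duplication of a paternal
    haplotype; parental haplotypes are distinguishable, so the parent of
    origin and the intra-chromosomal mechanism are both determined."""
    region = make_region(
        {"FA": 2, "MO": 1, "CH": 3},
        {"FA": (AB, AB), "MO": (A, B), "CH": (ABB, AAB)},
        {"mother"},
        {"MO", "CH"},
        family_id="DNDUP",
    )
    family = Family("DNDUP", "FA", "MO", ("CH",))
    return region, family


@pytest.fixture
def small_dataset_paths(tmp_path):
    """A small simulated dataset written to disk in the pipeline formats."""
    from cnphase.synthetic_families import (
        SimulationParams,
        simulate_dataset,
        write_dataset,
    )

    params = SimulationParams(seed=11, n_families=6, regions_per_family=2)
    dataset = simulate_dataset(params)
    paths = write_dataset(dataset, tmp_path / "data")
    return paths, dataset
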