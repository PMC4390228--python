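"""Core phasing engine: enumeration, parsimony search, oracle equivalence."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnphase.bruteforce import OracleCapExceeded, brute_force_oracle
from cnphase.model import (
    Event,
    Family,
    Haplotype,
    ParentPhase,
    collapse_equivalent_solutions,
)
from cnphase.phase_engine import (
    BudgetExceededError,
    PhasingConfig,
    classify_de_novo,
    enumerate_gametes,
    enumerate_parent_phases,
    explain_child,
    phase_region,
)
from cnphase.validation import random_small_region, solution_set_keys


def hap(cn, *alleles):
    return Haplotype(cn, tuple(alleles))


A, B, AB, AA, BB = (1, 0), (0, 1), (1, 1), (2, 0), (0, 2)


class TestPhaseEnumeration:
    def test_het_marker_pins_partition_up_to_swap(self):
        phases = enumerate_parent_phases([AB, AA], 2, [(1, 1)])
        assert len(phases) == 1
        keys = {h.counts for h in phases[0].haps}
        assert keys == {(A, A), (B, A)}

    def test_null_genotype_single_degenerate_phase(self):
        phases = enumerate_parent_phases([(0, 0)], 0)
        assert len(phases) == 1
        assert all(h.cn == 0 for h in phases[0].haps)

    def test_triploid_marker_partitions(self):
        phases = enumerate_parent_phases([(2, 1)], 3, [(1, 2)])
        got = {tuple(h.counts for h in p.haps) for p in phases}
        assert got == {((A,), (AB,)), ((B,), (AA,))}

    def test_diploid_cn_above_four_rejected(self):
        with pytest.raises(ValueError):
            enumerate_parent_phases([(5, 0)], 5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=st.integers(0, 4), c1=st.integers(0, 3))
    def test_matches_explicit_allele_list_enumeration(self, a, c1):
        """Count-pair partitioning equals brute-force index-set splitting."""
        b = min(4 - a, 3)
        cn = a + b
        c1 = min(c1, cn)
        c2 = cn - c1
        if c2 > 3:
            return
        phases = enumerate_parent_phases([(a, b)], cn, [(c1, c2)])
        alleles = "A" * a + "B" * b
        expected = set()
        for pick in itertools.combinations(range(cn), c1):
            h1 = "".join(sorted(alleles[i] for i in pick))
            h2 = "".join(sorted(alleles[i] for i in range(cn) if i not in pick))
            expected.add(tuple(sorted([(c1, h1), (c2, h2)])))
        got = {
            tuple(sorted((h.cn, h.allele_strings()[0].replace("-", "")) for h in p.haps))
            for p in phases
        }
        assert got == expected


class TestGameteEnumeration:
    def test_mendelian_gametes_are_the_two_haplotypes(self):
        phase = ParentPhase((hap(1, A), hap(1, B)))
        opts = enumerate_gametes(phase, allow_nonmendelian=False)
        assert [(o.event, o.gamete.counts) for o in opts] == [
            (Event.MENDELIAN, (A,)),
            (Event.MENDELIAN, (B,)),
        ]

    def test_deletions_add_empty_gametes_from_either_source(self):
        phase = ParentPhase((hap(1, A), hap(1, B)))
        opts = enumerate_gametes(phase, allow_nonmendelian=True)
        dels = [o for o in opts if o.event is Event.DENOVO_DELETION]
        assert {(o.gamete.cn, o.source) for o in dels} == {(0, 0), (0, 1)}

    def test_duplication_typing_from_allele_origin(self):
        phase = ParentPhase((hap(1, A), hap(1, B)))
        opts = enumerate_gametes(phase, allow_nonmendelian=True)
        dups = {
            (o.source, o.gamete.counts[0]): o.event
            for o in opts
            if o.event.value.startswith("denovo_dup")
        }
        # extra A onto hap (A): matches source, absent from other homolog
        assert dups[(0, AA)] is Event.DENOVO_DUP_INTRA
        # extra B onto hap (A): only the other homolog carries B
        assert dups[(0, AB)] is Event.DENOVO_DUP_INTER

    def test_gamete_cn_capped_at_three(self):
        phase = ParentPhase((hap(3, (3, 0)), hap(1, A)))
        opts = enumerate_gametes(phase, allow_nonmendelian=True)
        assert all(o.gamete.cn <= 3 for o in opts)
        assert not any(
            o.event.value.startswith("denovo_dup") and o.source == 0 for o in opts
        )


class TestExplainChild:
    def test_biparental_homozygote_unique(self):
        f = ParentPhase((hap(1, A), hap(1, B)))
        m = ParentPhase((hap(1, A), hap(1, B)))
        schemes = explain_child([AA], 2, f, m, allow_nonmendelian=False)
        exact = [s for s, u in schemes if u == 0]
        assert len(exact) == 1
        fs, ms = exact[0]
        assert fs.event is Event.MENDELIAN and fs.gametes[0].counts == (A,)
        assert ms.event is Event.MENDELIAN and ms.gametes[0].counts == (A,)

    def test_inherited_deletion_haplotype(self):
        # father carries a cn=0 haplotype; child (CN=1) received it plus a
        # maternal allele
        f = ParentPhase((hap(0, (0, 0), (0, 0)), hap(1, B, A)))
        m = ParentPhase((hap(1, A, A), hap(1, B, A)))
        schemes = explain_child([B, A], 1, f, m, allow_nonmendelian=False)
        exact = [s for s, u in schemes if u == 0]
        assert len(exact) == 1
        fs, ms = exact[0]
        assert fs.gametes[0].cn == 0 and ms.gametes[0].counts == (B, A)

    def test_denovo_deletion_from_either_parent(self):
        f = ParentPhase((hap(1, A), hap(1, B)))
        m = ParentPhase((hap(1, A), hap(1, B)))
        schemes = explain_child([A], 1, f, m, allow_nonmendelian=True)
        exact = [s for s, u in schemes if u == 0]
        kinds = {
            tuple(side.event for side in s) for s in exact
        }
        assert (Event.DENOVO_DELETION, Event.MENDELIAN) in kinds
        assert (Event.MENDELIAN, Event.DENOVO_DELETION) in kinds


class TestPhaseRegion:
    def test_duplication_family_unambiguous(self, duplication_family):
        region, family = duplication_family
        result = phase_region(region, family)
        assert result.unambiguous and result.score == (0, 0)
        sol = result.solutions[0]
        cns = sorted(h.cn for h in sol.mother_phase.haps)
        assert cns == [1, 2]
        dup_hap = next(h for h in sol.mother_phase.haps if h.cn == 2)
        # the duplication haplotype carries a heterozygous allelic copy
        assert any(a > 0 and b > 0 for a, b in dup_hap.counts)
        # the child received the duplication haplotype from the mother
        _, (fs, ms) = sol.schemes[0]
        assert ms.event is Event.MENDELIAN and ms.gametes[0].cn == 2

    def test_uninformative_region_phases_by_copy_number(self, region_builder):
        # both parents multi-copy carriers, no informative markers: which
        # parent passed the duplication haplotype is undecidable
        region = region_builder(
            {"FA": 3, "MO": 3, "CH": 3},
            {"FA": (), "MO": (), "CH": ()},
            {"father", "mother"}, {"FA", "MO", "CH"},
        )
        region.marker_ids = ()
        region.marker_pos = ()
        family = Family("FAM", "FA", "MO", ("CH",))
        result = phase_region(region, family)
        assert not result.unambiguous and result.score == (0, 0)
        assert len(result.solutions) == 2

    def test_budget_cap_raises(self, duplication_family):
        region, family = duplication_family
        with pytest.raises(BudgetExceededError):
            phase_region(region, family, PhasingConfig(max_combinations=3))

    def test_solution_scores_are_uniform(self, denovo_deletion_trio):
        region, family = denovo_deletion_trio
        result = phase_region(region, family)
        assert all(s.score == result.score for s in result.solutions)


class TestDeNovoClassification:
    def test_mendelian_scheme_rejected(self, duplication_family):
        region, family = duplication_family
        sol = phase_region(region, family).solutions[0]
        _, (fs, _) = sol.schemes[0]
        with pytest.raises(ValueError):
            classify_de_novo(sol, fs)

    def test_undetermined_origin_with_identical_parents(self, denovo_deletion_trio):
        region, family = denovo_deletion_trio
        result = phase_region(region, family)
        assert len(result.solutions) == 2
        for sol in result.solutions:
            for _, scheme in sol.schemes:
                for side in scheme:
                    if side.event is Event.DENOVO_DELETION:
                        ann = classify_de_novo(sol, side)
                        assert not ann.parent_of_origin_determined

    def test_intra_chromosomal_duplication_determined(self, denovo_duplication_trio):
        region, family = denovo_duplication_trio
        result = phase_region(region, family)
        assert result.unambiguous
        sol = result.solutions[0]
        _, (fs, ms) = sol.schemes[0]
        assert fs.event is Event.DENOVO_DUP_INTRA and fs.parent == "father"
        ann = classify_de_novo(sol, fs)
        assert ann.parent_of_origin_determined
        assert ann.dup_class is Event.DENOVO_DUP_INTRA


class TestInvariants:
    def test_conservation_and_truth_membership(self):
        """Parent haplotypes always partition the observed genotypes, and on
        exact (noise-free) regions the child equals its gamete union."""
        from cnphase.synthetic_families import SimulationParams, simulate_family_region

        params = SimulationParams(seed=5).noise_free()
        family = Family("FAM", "FA", "MO", ("CH1", "CH2"))
        for idx in range(40):
            sim = simulate_family_region(params, family, region_index=idx)
            region, truth = sim.phasing_ready()
            result = phase_region(region, family)
            for sol in result.solutions:
                for pid, phase in (("FA", sol.father_phase), ("MO", sol.mother_phase)):
                    for m in range(region.n_markers):
                        assert phase.genotype(m) == region.genotypes[pid][m]
            assert truth.canonical_key() in solution_set_keys(result)

    def test_oracle_equivalence_sample(self):
        config = PhasingConfig()
        done = 0
        attempt = 0
        while done < 60:
            rng = np.random.default_rng([99, 31337, attempt])
            attempt += 1
            region, family = random_small_region(rng)
            try:
                oracle = brute_force_oracle(region, family, config, cap=200_000)
            except OracleCapExceeded:
                continue
            engine = phase_region(region, family, config)
            assert engine.score == oracle.score
            assert solution_set_keys(engine) == solution_set_keys(oracle)
            done += 1

    def test_collapse_is_idempotent(self):
        rng = np.random.default_rng([7, 31337, 3])
        region, family = random_small_region(rng)
        sols = list(phase_region(region, family).solutions)
        once = collapse_equivalent_solutions(sols)
        assert collapse_equivalent_solutions(once) == once
        assert collapse_equivalent_solutions(sols + sols) == once

    def test_added_informative_marker_never_increases_ambiguity(self):
        """Extending a uniquely phased Mendelian region with one more marker
        consistent with its solution keeps it unique."""
        from cnphase.synthetic_families import SimulationParams, simulate_family_region

        params = SimulationParams(
            seed=13, event_rates=(), n_markers_range=(4, 8)
        ).noise_free()
        family = Family("FAM", "FA", "MO", ("CH1",))
        tested = 0
        for idx in range(60):
            sim = simulate_family_region(params, family, region_index=idx)
            region, truth = sim.phasing_ready()
            result = phase_region(region, family)
            if not result.unambiguous:
                continue
            sol = result.solutions[0]
            if any(sch is None for _, sch in sol.schemes):
                continue
            # append a heterozygous marker derived from the unique solution
            ext = _extend_with_marker(region, family, sol)
            if ext is None:
                continue
            assert phase_region(ext, family).unambiguous
            tested += 1
        assert tested >= 10


def _extend_with_marker(region, family, sol):
    """Append one marker whose genotypes follow the solution's haplotypes:
    the father's two haplotypes carry opposite alleles (informative), the
    mother's are monomorphic, so the extension is consistent and cannot
    introduce a new local ambiguity."""
    new_hap_alleles = {
        ("father", 0): (sol.father_phase.haps[0].cn, 0),
        ("father", 1): (0, sol.father_phase.haps[1].cn),
        ("mother", 0): (sol.mother_phase.haps[0].cn, 0),
        ("mother", 1): (sol.mother_phase.haps[1].cn, 0),
    }
    genotypes = {}
    for pid, role in ((family.father_id, "father"), (family.mother_id, "mother")):
        c0 = new_hap_alleles[(role, 0)]
        c1 = new_hap_alleles[(role, 1)]
        genotypes[pid] = region.genotypes[pid] + ((c0[0] + c1[0], c0[1] + c1[1]),)
    for cid in family.child_ids:
        scheme = sol.scheme_for(cid)
        total = (0, 0)
        for side, role in zip(scheme, ("father", "mother")):
            if side.event is not Event.MENDELIAN:
                return None
            src = new_hap_alleles[(role, side.sources[0])]
            total = (total[0] + src[0], total[1] + src[1])
        genotypes[cid] = region.genotypes[cid] + (total,)
    ext = type(region)(
        family_id=region.family_id,
        chrom=region.chrom,
        start=region.start,
        end=region.end + 10,
        member_cn=dict(region.member_cn),
        marker_ids=region.marker_ids + ("m_extra",),
        marker_pos=region.marker_pos + (region.end + 5,),
        genotypes=genotypes,
        carrier_parents=region.carrier_parents,
        carrier_members=region.carrier_members,
    )
    return ext
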