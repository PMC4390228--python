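"""Simulator: determinism, event-rate contracts, noise, round-trips."""

import json

import numpy as np
import pytest

from cnphase.io_regions import parse_cnv_calls, parse_genotype_table, parse_pedigree
from cnphase.model import Event, Family, child_event_count
from cnphase.phase_engine import phase_region
from cnphase.synthetic_families import (
    SimulationParams,
    inject_noise,
    simulate_dataset,
    simulate_family_region,
    write_dataset,
)
from cnphase.validation import solution_set_keys

FAMILY = Family("FAM", "FA", "MO", ("CH1", "CH2"))


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        params = SimulationParams(seed=3, n_families=4, regions_per_family=2)
        p1 = write_dataset(simulate_dataset(params), tmp_path / "a")
        p2 = write_dataset(simulate_dataset(params), tmp_path / "b")
        for key in ("genotypes", "calls_a", "pedigree", "truth"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_region_draw_independent_of_other_regions(self):
        params = SimulationParams(seed=3)
        a = simulate_family_region(params, FAMILY, region_index=5)
        b = simulate_family_region(params, FAMILY, region_index=5)
        assert a.truth.canonical_key() == b.truth.canonical_key()
        assert a.region.genotypes == b.region.genotypes


class TestEventContracts:
    def test_zero_event_rates_all_mendelian(self):
        params = SimulationParams(
            seed=9, event_rates=(),
            carrier_config=(("A_del", 0.6), ("A_dup2", 0.3), ("B_del", 0.1)),
        )
        for idx in range(30):
            sim = simulate_family_region(params, FAMILY, region_index=idx)
            assert sim.truth.n_nonmendelian == 0
            for _, scheme in sim.truth.schemes:
                assert all(s.event is Event.MENDELIAN for s in scheme)

    def test_deletion_rate_one_reduces_child_cn(self):
        params = SimulationParams(
            seed=9,
            event_rates=(("denovo_deletion", 1.0),),
            carrier_config=(("A_del", 1.0),),
        )
        family = Family("FAM", "FA", "MO", ("CH1",))
        sim = simulate_family_region(params, family, region_index=0)
        (cid, (fs, ms)) = sim.truth.schemes[0]
        for side in (fs, ms):
            assert side.event is Event.DENOVO_DELETION
            src_phase = sim.truth.father_phase if side.parent == "father" else sim.truth.mother_phase
            src = src_phase.haps[side.sources[0]]
            gam = side.gametes[0]
            assert gam.cn < src.cn
            assert gam.is_sub_haplotype_of(src)

    def test_forced_de_novo_when_no_parent_carries(self):
        params = SimulationParams(seed=21, carrier_config=(("none", 1.0),))
        sim = simulate_family_region(params, FAMILY, region_index=0)
        assert sim.region.member_cn["FA"] == 2 and sim.region.member_cn["MO"] == 2
        assert any(sim.region.member_cn[c] != 2 for c in ("CH1", "CH2"))
        assert sim.truth.n_nonmendelian == 1

    def test_observed_genotypes_are_truth_unions(self):
        params = SimulationParams(seed=2).noise_free()
        for idx in range(20):
            sim = simulate_family_region(params, FAMILY, region_index=idx)
            sol = sim.truth
            for pid, phase in (("FA", sol.father_phase), ("MO", sol.mother_phase)):
                for m in range(sim.region.n_markers):
                    assert phase.genotype(m) == sim.region.genotypes[pid][m]
            for cid, scheme in sol.schemes:
                gametes = [g for side in scheme for g in side.gametes]
                for m in range(sim.region.n_markers):
                    a = sum(g.counts[m][0] for g in gametes)
                    b = sum(g.counts[m][1] for g in gametes)
                    assert (a, b) == sim.region.genotypes[cid][m]


class TestNoise:
    def test_zero_rates_identity(self):
        params = SimulationParams(seed=4).noise_free()
        sim = simulate_family_region(params, FAMILY, region_index=1)
        noisy = inject_noise(sim, params)
        assert noisy.genotype_rows == sim.genotype_rows

    def test_full_nocall_makes_region_uninformative(self):
        params = SimulationParams(seed=4, nocall_rate=1.0)
        sim = simulate_family_region(params, FAMILY, region_index=1)
        noisy = inject_noise(sim, params)
        assert all(r.is_no_call for r in noisy.genotype_rows)
        region, _ = noisy.phasing_ready()
        assert region.n_markers == 0 and region.flag == "uninformative"

    def test_truth_untouched(self):
        params = SimulationParams(seed=4, nocall_rate=0.5, genotype_error_rate=0.5)
        sim = simulate_family_region(params, FAMILY, region_index=1)
        noisy = inject_noise(sim, params)
        assert noisy.truth is sim.truth


class TestRoundTrip:
    def test_written_files_parse_back(self, small_dataset_paths):
        paths, dataset = small_dataset_paths
        genotypes = parse_genotype_table(paths["genotypes"])
        calls_a = parse_cnv_calls(paths["calls_a"])
        calls_b = parse_cnv_calls(paths["calls_b"])
        families = parse_pedigree(paths["pedigree"])
        assert len(families) == len(dataset.families)
        assert {c.caller for c in calls_a} == {"quantisnp"}
        assert len(calls_a) == len(calls_b)
        by_key = {(r.sample_id, r.marker_id): r for r in genotypes}
        for sim in dataset.regions:
            for row in sim.genotype_rows:
                parsed = by_key[(row.sample_id, row.marker_id)]
                assert parsed.is_no_call == row.is_no_call
                if not row.is_no_call:
                    assert parsed.counts == row.counts

    def test_truth_json_loads(self, small_dataset_paths):
        paths, dataset = small_dataset_paths
        doc = json.loads(paths["truth"].read_text())
        assert len(doc["regions"]) == len(dataset.regions)
        for entry in doc["regions"]:
            assert set(entry) >= {"region_id", "member_cn", "truth"}

    def test_empty_dataset_valid_files(self, tmp_path):
        params = SimulationParams(seed=1, n_families=0)
        paths = write_dataset(simulate_dataset(params), tmp_path)
        assert parse_genotype_table(paths["genotypes"]) == []
        assert parse_cnv_calls(paths["calls_a"]) == []


class TestRecovery:
    def test_noise_free_truth_in_cooptimal(self):
        params = SimulationParams(seed=6).noise_free()
        n_unamb = 0
        for idx in range(60):
            sim = simulate_family_region(params, FAMILY, region_index=idx)
            region, truth = sim.phasing_ready()
            result = phase_region(region, FAMILY)
            assert truth.canonical_key() in solution_set_keys(result)
            if result.unambiguous:
                n_unamb += 1
                assert result.solutions[0].canonical_key() == truth.canonical_key()
        assert n_unamb > 30  # most default-condition regions phase uniquely

    def test_all_group_a_without_events(self):
        from cnphase.family_analysis import assign_group

        params = SimulationParams(
            seed=8, event_rates=(),
            carrier_config=(("A_del", 0.7), ("A_dup2", 0.3),),
        )
        for idx in range(20):
            sim = simulate_family_region(params, FAMILY, region_index=idx)
            assert assign_group(sim.region) == "A"
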