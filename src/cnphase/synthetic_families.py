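"""Seeded simulation of nuclear-family CNV regions with known ground truth.

The generator emulates the data model of family-based SNP-array CNV
genotyping: parental haplotypes with haploid copy numbers 0--3 and
per-marker allele content drawn from a shared B-allele frequency, gametes
formed by Mendelian transmission or rare non-Mendelian events (de novo
deletion/duplication, uniparental iso-/heterodisomy), observed multi-ploid
genotypes as the multiset union of the two transmitted gametes, and CNV
segment calls emitted by two agreeing pseudo-callers.

Identifiability contract: a simulated non-Mendelian event is redrawn
whenever the resulting child data admits a Mendelian explanation under
some parental phase pair, so the simulated truth is always among the
most-parsimonious explanations of the observed (noise-free) data.  Noise
(no-calls, low-confidence cells, allele flips) is injected after the
truth is fixed and can break that guarantee, as it does on real arrays.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_regions import GenotypeTable, select_region_markers
from .model import (
    ChildScheme,
    CnvCall,
    CnvRegion,
    Counts,
    Event,
    Family,
    FamilySolution,
    GameteScheme,
    Haplotype,
    MarkerGenotype,
    ParentPhase,
    child_event_count,
    counts_to_string,
)
from .phase_engine import _classify_dup_extras, enumerate_parent_phases

_MAX_ATTEMPTS = 100


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of the simulated family CNV dataset.

    Carrier configurations mirror the composition of family CNV-region
    collections on genotyping arrays: predominantly single-parent deletion
    carriers, a minority of single-parent duplication carriers, few
    both-parent (copy-number-polymorphism-like) regions and rare regions
    with no parental carrier that surface only through a de novo event in
    a child.  Non-Mendelian event rates are per meiosis (UPD per child)
    and small, as such events are rare in germline data.
    """

    seed: int = 0
    n_families: int = 30
    regions_per_family: int = 3
    children_per_family: tuple[tuple[int, float], ...] = ((1, 0.7), (2, 0.2), (3, 0.1))
    n_markers_range: tuple[int, int] = (4, 12)
    allele_freq: float = 0.3  # B-allele frequency shared across a region
    carrier_config: tuple[tuple[str, float], ...] = (
        ("A_del", 0.79),
        ("A_dup2", 0.11),
        ("A_dup3", 0.03),
        ("B_del", 0.04),
        ("B_mixed", 0.01),
        ("none", 0.02),
    )
    event_rates: tuple[tuple[str, float], ...] = (
        ("denovo_deletion", 0.005),
        ("denovo_dup_intra", 0.002),
        ("denovo_dup_inter", 0.002),
        ("upd_iso", 0.001),
        ("upd_hetero", 0.001),
    )
    length_range_bp: tuple[int, int] = (1_500, 400_000)
    nocall_rate: float = 0.02
    lowconf_rate: float = 0.03
    genotype_error_rate: float = 0.005

    def rate(self, name: str) -> float:
        return dict(self.event_rates).get(name, 0.0)

    def noise_free(self) -> "SimulationParams":
        return replace(
            self, nocall_rate=0.0, lowconf_rate=0.0, genotype_error_rate=0.0
        )


@dataclass
class SimulatedRegion:
    """One simulated family CNV region: observed data plus ground truth."""

    region: CnvRegion  # raw markers, noise-free union genotypes
    family: Family
    truth: FamilySolution  # over all raw markers
    genotype_rows: list[MarkerGenotype]
    calls: list[CnvCall]
    region_index: int

    def phasing_ready(self) -> tuple[CnvRegion, FamilySolution]:
        """Marker-selected region plus the truth projected onto it.

        De novo gain labels are re-derived on the retained marker set,
        since intra/inter typing depends on which informative markers
        survive selection.
        """
        table = GenotypeTable(self.genotype_rows)
        observed = CnvRegion(
            family_id=self.region.family_id,
            chrom=self.region.chrom,
            start=self.region.start,
            end=self.region.end,
            member_cn=dict(self.region.member_cn),
            marker_ids=self.region.marker_ids,
            marker_pos=self.region.marker_pos,
            genotypes={
                sid: tuple(
                    table.get(sid, mid).counts for mid in self.region.marker_ids
                )
                for sid in self.family.members
            },
            carrier_parents=self.region.carrier_parents,
            carrier_members=self.region.carrier_members,
        )
        selected = select_region_markers(observed, table, self.family)
        kept = [self.region.marker_ids.index(m) for m in selected.marker_ids]
        truth = _project_solution(self.truth, kept)
        return selected, truth


def _project_hap(h: Haplotype, idx: Sequence[int]) -> Haplotype:
    return Haplotype(h.cn, tuple(h.counts[i] for i in idx))


def _project_solution(sol: FamilySolution, idx: Sequence[int]) -> FamilySolution:
    def project_phase(phase: ParentPhase) -> ParentPhase:
        return ParentPhase(tuple(_project_hap(h, idx) for h in phase.haps))

    fphase = project_phase(sol.father_phase)
    mphase = project_phase(sol.mother_phase)
    schemes = []
    for cid, scheme in sol.schemes:
        if scheme is None:
            schemes.append((cid, None))
            continue
        new_sides = []
        for side, phase in zip(scheme, (fphase, mphase)):
            gametes = tuple(_project_hap(g, idx) for g in side.gametes)
            event = side.event
            if event in (
                Event.DENOVO_DUP_INTRA,
                Event.DENOVO_DUP_INTER,
                Event.DENOVO_DUP_AMBIG,
            ):
                src = phase.haps[side.sources[0]]
                other = phase.haps[1 - side.sources[0]]
                extras = tuple(
                    (g[0] - s[0], g[1] - s[1])
                    for g, s in zip(gametes[0].counts, src.counts)
                )
                event = _classify_dup_extras(extras, src, other)
            new_sides.append(GameteScheme(side.parent, event, side.sources, gametes))
        schemes.append((cid, (new_sides[0], new_sides[1])))
    return FamilySolution(
        fphase, mphase, tuple(schemes), sol.n_unexplained, sol.n_nonmendelian
    )


# ---------------------------------------------------------------------------
# single-region simulation

_CARRIER_SPLITS = {
    "A_del": ((0, 1), (1, 1)),
    "A_dup2": ((1, 2), (1, 1)),
    "A_dup3": ((1, 3), (1, 1)),
    "B_del": ((0, 1), (0, 1)),
    "B_mixed": ((0, 1), (1, 2)),
    "none": ((1, 1), (1, 1)),
}


def _draw_hap(rng: np.random.Generator, cn: int, n_markers: int, baf: float) -> Haplotype:
    nb = rng.binomial(cn, baf, size=n_markers)
    return Haplotype(cn, tuple((cn - int(b), int(b)) for b in nb))


def _mendelian_explainable(
    child_counts: Sequence[Counts],
    child_cn: int,
    father_counts: Sequence[Counts],
    father_cn: int,
    mother_counts: Sequence[Counts],
    mother_cn: int,
) -> bool:
    """True when some parental hap pair reproduces the child exactly.

    Used for the identifiability contract: the candidate haplotypes are
    all haplotypes appearing in any default-split phase of each parent.
    Only markers polymorphic across the three genotypes are compared,
    matching what survives marker selection.
    """
    poly = [
        m
        for m in range(len(child_counts))
        if sum(g[m][0] for g in (child_counts, father_counts, mother_counts)) > 0
        and sum(g[m][1] for g in (child_counts, father_counts, mother_counts)) > 0
    ]

    def hap_pool(counts, cn):
        pool = set()
        for phase in enumerate_parent_phases([counts[m] for m in poly], cn):
            pool.update(h.key for h in phase.haps)
        return pool

    child_poly = [child_counts[m] for m in poly]
    for fcn, fcounts in hap_pool(father_counts, father_cn):
        for mcn, mcounts in hap_pool(mother_counts, mother_cn):
            if fcn + mcn != child_cn:
                continue
            if all(
                f[0] + g[0] == c[0] and f[1] + g[1] == c[1]
                for f, g, c in zip(fcounts, mcounts, child_poly)
            ):
                return True
    return False


class _Infeasible(Exception):
    pass


def _draw_child_schemes(
    rng: np.random.Generator,
    params: SimulationParams,
    phases: dict[str, ParentPhase],
    forced: Optional[tuple[str, str]] = None,
) -> dict[str, tuple[Event, tuple[int, ...], tuple[Haplotype, ...]]]:
    """Draw region-wide inheritance for one child, per parent role.

    Returns per role (event, sources, gametes); for UPD the disomic role
    carries both gametes and the other role none.  Raises ``_Infeasible``
    when the drawn event cannot be realized (no eligible source haplotype,
    or child diploid CN above 4).
    """
    roles = ("father", "mother")
    out: dict[str, tuple[Event, tuple[int, ...], tuple[Haplotype, ...]]] = {}
    if forced is None:
        u = rng.random()
        p_iso, p_het = params.rate("upd_iso"), params.rate("upd_hetero")
        if u < p_iso or u < p_iso + p_het:
            kind = Event.UPD_ISO if u < p_iso else Event.UPD_HETERO
            disomic = roles[rng.integers(2)]
            haps = phases[disomic].haps
            if kind is Event.UPD_ISO:
                i = int(rng.integers(2))
                sources, gametes = (i, i), (haps[i], haps[i])
            else:
                sources, gametes = (0, 1), haps
            for role in roles:
                out[role] = (
                    (kind, sources, gametes) if role == disomic else (kind, (), ())
                )
            _check_child_cn(out)
            return out
    for role in roles:
        haps = phases[role].haps
        if forced is not None and forced[0] == role:
            event_name = forced[1]
        elif forced is not None:
            event_name = "mendelian"
        else:
            v = rng.random()
            p_del = params.rate("denovo_deletion")
            p_di = params.rate("denovo_dup_intra")
            p_dx = params.rate("denovo_dup_inter")
            if v < p_del:
                event_name = "denovo_deletion"
            elif v < p_del + p_di:
                event_name = "denovo_dup_intra"
            elif v < p_del + p_di + p_dx:
                event_name = "denovo_dup_inter"
            else:
                event_name = "mendelian"
        out[role] = _draw_gamete(rng, haps, event_name)
    _check_child_cn(out)
    return out


def _check_child_cn(out) -> None:
    cn = sum(g.cn for _, _, gametes in out.values() for g in gametes)
    if cn > 4:
        raise _Infeasible("child diploid CN above 4")


def _draw_gamete(rng, haps, event_name):
    if event_name == "mendelian":
        i = int(rng.integers(2))
        return (Event.MENDELIAN, (i,), (haps[i],))
    if event_name == "denovo_deletion":
        eligible = [i for i, h in enumerate(haps) if h.cn >= 1]
        if not eligible:
            raise _Infeasible("no source haplotype for deletion")
        i = int(rng.choice(eligible))
        src = haps[i]
        cn_new = int(rng.integers(src.cn))
        counts = []
        for a, b in src.counts:
            na = int(rng.hypergeometric(a, b, cn_new)) if cn_new else 0
            counts.append((na, cn_new - na))
        return (Event.DENOVO_DELETION, (i,), (Haplotype(cn_new, tuple(counts)),))
    # duplications: one extra allele copy per marker, gamete cn <= 3
    intra = event_name == "denovo_dup_intra"
    eligible = [
        i
        for i, h in enumerate(haps)
        if 1 <= h.cn <= 2 and (intra or haps[1 - i].cn >= 1)
    ]
    if not eligible:
        raise _Infeasible(f"no source haplotype for {event_name}")
    i = int(rng.choice(eligible))
    src, other = haps[i], haps[1 - i]
    donor = src if intra else other
    counts = []
    extras = []
    for m, (a, b) in enumerate(src.counts):
        da, db = donor.counts[m]
        extra_b = int(rng.random() < db / (da + db))
        extras.append((1 - extra_b, extra_b))
        counts.append((a + 1 - extra_b, b + extra_b))
    gamete = Haplotype(src.cn + 1, tuple(counts))
    kind = _classify_dup_extras(tuple(extras), src, other)
    return (kind, (i,), (gamete,))


def simulate_family_region(
    params: SimulationParams,
    family: Family,
    region_index: int = 0,
) -> SimulatedRegion:
    """Simulate one family CNV region with ground-truth phases and schemes.

    Deterministic given (params.seed, region_index); the per-region stream
    is derived by counter, so reordering families leaves each region's
    draw unchanged.  Infeasible draws (including non-identifiable
    non-Mendelian events) are resampled; an error is raised after
    100 attempts.
    """
    rng = np.random.default_rng([params.seed % (2**31), 7919, region_index])
    chrom = str((region_index % 22) + 1)
    base = 1_000_000 + (region_index // 22) * 10_000_000
    lo, hi = params.length_range_bp
    length = int(round(10 ** rng.uniform(math.log10(lo), math.log10(hi))))
    start, end = base, base + length - 1

    for _ in range(_MAX_ATTEMPTS):
        try:
            return _attempt_region(
                rng, params, family, region_index, chrom, start, end
            )
        except _Infeasible:
            continue
    raise RuntimeError(
        f"could not draw a feasible region for {family.family_id} "
        f"after {_MAX_ATTEMPTS} attempts"
    )


def _attempt_region(rng, params, family, region_index, chrom, start, end):
    n_markers = int(rng.integers(params.n_markers_range[0], params.n_markers_range[1] + 1))
    positions = np.sort(rng.choice(np.arange(start, end + 1), size=n_markers, replace=False))
    configs, weights = zip(*params.carrier_config)
    config = str(rng.choice(configs, p=np.asarray(weights) / sum(weights)))
    split_a, split_b = _CARRIER_SPLITS[config]
    if rng.random() < 0.5:
        split_a, split_b = split_b, split_a
    splits = {"father": split_a, "mother": split_b}
    phases = {
        role: ParentPhase(
            (
                _draw_hap(rng, splits[role][0], n_markers, params.allele_freq),
                _draw_hap(rng, splits[role][1], n_markers, params.allele_freq),
            )
        )
        for role in ("father", "mother")
    }
    forced = None
    if config == "none":
        kind = str(
            rng.choice(
                ["denovo_deletion", "denovo_dup_intra", "denovo_dup_inter"],
                p=[0.74, 0.13, 0.13],
            )
        )
        forced_child = str(rng.choice(list(family.child_ids)))
        forced_role = ("father", "mother")[rng.integers(2)]
        forced = (forced_child, forced_role, kind)

    child_schemes: dict[str, ChildScheme] = {}
    child_counts: dict[str, tuple[Counts, ...]] = {}
    child_cn: dict[str, int] = {}
    for cid in family.child_ids:
        f = (forced[1], forced[2]) if forced is not None and forced[0] == cid else None
        drawn = _draw_child_schemes(rng, params, phases, forced=f)
        fs = GameteScheme("father", *drawn["father"])
        ms = GameteScheme("mother", *drawn["mother"])
        child_schemes[cid] = (fs, ms)
        cn = sum(g.cn for side in (fs, ms) for g in side.gametes)
        counts = []
        for m in range(n_markers):
            a = sum(g.counts[m][0] for side in (fs, ms) for g in side.gametes)
            b = sum(g.counts[m][1] for side in (fs, ms) for g in side.gametes)
            counts.append((a, b))
        child_counts[cid] = tuple(counts)
        child_cn[cid] = cn

    father_counts = tuple(phases["father"].genotype(m) for m in range(n_markers))
    mother_counts = tuple(phases["mother"].genotype(m) for m in range(n_markers))
    # identifiability contract: redraw when a simulated non-Mendelian event
    # is mimicked by a Mendelian explanation of the same observed data
    for cid in family.child_ids:
        if child_event_count(child_schemes[cid]) == 0:
            continue
        if _mendelian_explainable(
            child_counts[cid], child_cn[cid],
            father_counts, phases["father"].parent_cn,
            mother_counts, phases["mother"].parent_cn,
        ):
            raise _Infeasible("non-Mendelian event is Mendelian-mimicking")

    n_events = sum(child_event_count(s) for s in child_schemes.values())
    truth = FamilySolution(
        phases["father"],
        phases["mother"],
        tuple((cid, child_schemes[cid]) for cid in family.child_ids),
        0,
        n_events,
    )
    member_cn = {
        family.father_id: phases["father"].parent_cn,
        family.mother_id: phases["mother"].parent_cn,
        **{cid: child_cn[cid] for cid in family.child_ids},
    }
    genotypes = {
        family.father_id: father_counts,
        family.mother_id: mother_counts,
        **child_counts,
    }
    if not any(cn != 2 for cn in member_cn.values()):
        raise _Infeasible("no CNV carrier in drawn region")
    marker_ids = tuple(f"rs{region_index}_{j}" for j in range(n_markers))
    region = CnvRegion(
        family_id=family.family_id,
        chrom=chrom,
        start=start,
        end=end,
        member_cn=member_cn,
        marker_ids=marker_ids,
        marker_pos=tuple(int(p) for p in positions),
        genotypes=genotypes,
        carrier_parents=frozenset(
            role
            for role, pid in (("father", family.father_id), ("mother", family.mother_id))
            if member_cn[pid] != 2
        ),
        carrier_members=frozenset(m for m, cn in member_cn.items() if cn != 2),
    )
    rows = [
        MarkerGenotype(
            sample_id=sid,
            marker_id=marker_ids[m],
            chrom=chrom,
            pos=int(positions[m]),
            counts=genotypes[sid][m],
            is_no_call=False,
            confidence=0.99,
        )
        for sid in family.members
        for m in range(n_markers)
    ]
    calls = [
        CnvCall(
            sample_id=sid,
            chrom=chrom,
            start=start,
            end=end,
            cn=cn,
            lbf=float(np.round(rng.uniform(6, 40), 2)),
            caller="simulated",
            n_markers=n_markers,
        )
        for sid, cn in member_cn.items()
        if cn != 2
    ]
    return SimulatedRegion(region, family, truth, rows, calls, region_index)


def inject_noise(
    sim: SimulatedRegion, params: SimulationParams, rng: Optional[np.random.Generator] = None
) -> SimulatedRegion:
    """Mark cells as no-calls / low-confidence and flip rare allele copies.

    Operates on the observed genotype rows only; the ground truth is left
    untouched.  Deterministic given the passed generator."""
    if rng is None:
        rng = np.random.default_rng([params.seed % (2**31), 104729, sim.region_index])
    new_rows = []
    for row in sim.genotype_rows:
        counts, nc, conf = row.counts, row.is_no_call, row.confidence
        if rng.random() < params.nocall_rate:
            nc = True
        if rng.random() < params.lowconf_rate:
            conf = float(np.round(rng.uniform(0.5, 0.949), 3))
        if not nc and rng.random() < params.genotype_error_rate and sum(counts) > 0:
            a, b = counts
            flip_a = rng.random() < a / (a + b)
            counts = (a - 1, b + 1) if flip_a else (a + 1, b - 1)
        new_rows.append(replace(row, counts=counts, is_no_call=nc, confidence=conf))
    return SimulatedRegion(
        sim.region, sim.family, sim.truth, new_rows, sim.calls, sim.region_index
    )


# ---------------------------------------------------------------------------
# dataset assembly and writing


@dataclass
class SimulatedDataset:
    params: SimulationParams
    families: list[Family]
    regions: list[SimulatedRegion]


def make_families(params: SimulationParams) -> list[Family]:
    rng = np.random.default_rng([params.seed % (2**31), 15485863])
    sizes, weights = zip(*params.children_per_family)
    out = []
    for i in range(params.n_families):
        fid = f"F{i + 1:04d}"
        n_children = int(rng.choice(sizes, p=np.asarray(weights) / sum(weights)))
        out.append(
            Family(
                fid,
                f"{fid}_F",
                f"{fid}_M",
                tuple(f"{fid}_C{j + 1}" for j in range(n_children)),
            )
        )
    return out


def simulate_dataset(params: SimulationParams, with_noise: bool = True) -> SimulatedDataset:
    """Simulate the full dataset: families x regions_per_family regions."""
    families = make_families(params)
    regions = []
    idx = 0
    for family in families:
        for _ in range(params.regions_per_family):
            sim = simulate_family_region(params, family, region_index=idx)
            if with_noise:
                sim = inject_noise(sim, params)
            regions.append(sim)
            idx += 1
    return SimulatedDataset(params, families, regions)


def _solution_to_dict(sol: FamilySolution) -> dict:
    def hap_dict(h: Haplotype) -> dict:
        return {"cn": h.cn, "alleles": list(h.allele_strings())}

    schemes = {}
    for cid, scheme in sol.schemes:
        if scheme is None:
            schemes[cid] = None
            continue
        schemes[cid] = {
            side.parent: {
                "event": side.event.value,
                "sources": list(side.sources),
                "gametes": [hap_dict(g) for g in side.gametes],
            }
            for side in scheme
        }
    return {
        "father_phase": [hap_dict(h) for h in sol.father_phase.haps],
        "mother_phase": [hap_dict(h) for h in sol.mother_phase.haps],
        "schemes": schemes,
        "n_unexplained": sol.n_unexplained,
        "n_nonmendelian": sol.n_nonmendelian,
    }


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write genotype TSV, two agreeing caller TSVs, PED and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "calls_a": outdir / "calls_quantisnp.tsv",
        "calls_b": outdir / "calls_penncnv.tsv",
        "pedigree": outdir / "families.ped",
        "truth": outdir / "truth.json",
    }
    gt_rows = [
        {
            "sample_id": r.sample_id,
            "marker_id": r.marker_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "genotype": r.genotype_string(),
            "confidence": f"{r.confidence:.3f}",
        }
        for sim in dataset.regions
        for r in sim.genotype_rows
    ]
    pd.DataFrame(
        gt_rows,
        columns=["sample_id", "marker_id", "chrom", "pos", "genotype", "confidence"],
    ).to_csv(paths["genotypes"], sep="\t", index=False)
    for key, caller in (("calls_a", "quantisnp"), ("calls_b", "penncnv")):
        call_rows = [
            {
                "sample_id": c.sample_id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "cn": c.cn,
                "lbf": c.lbf,
                "caller": caller,
                "n_markers": c.n_markers,
            }
            for sim in dataset.regions
            for c in sim.calls
        ]
        pd.DataFrame(
            call_rows,
            columns=["sample_id", "chrom", "start", "end", "cn", "lbf", "caller", "n_markers"],
        ).to_csv(paths[key], sep="\t", index=False)
    ped_rows = []
    for fam in dataset.families:
        ped_rows.append([fam.family_id, fam.father_id, "0", "0", "1", "0"])
        ped_rows.append([fam.family_id, fam.mother_id, "0", "0", "2", "0"])
        for j, cid in enumerate(fam.child_ids):
            ped_rows.append(
                [fam.family_id, cid, fam.father_id, fam.mother_id, str(1 + j % 2), "0"]
            )
    pd.DataFrame(ped_rows).to_csv(paths["pedigree"], sep="\t", index=False, header=False)
    truth_doc = {
        "seed": dataset.params.seed,
        "regions": [
            {
                "region_id": sim.region.region_id,
                "family_id": sim.family.family_id,
                "chrom": sim.region.chrom,
                "start": sim.region.start,
                "end": sim.region.end,
                "member_cn": sim.region.member_cn,
                "truth": _solution_to_dict(sim.truth),
            }
            for sim in dataset.regions
        ],
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1, sort_keys=True))
    return paths
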