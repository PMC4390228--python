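"""End-to-end wiring: files in, phased regions and analysis tables out."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from . import io_regions
from .family_analysis import (
    assign_group,
    de_novo_reports,
    summarize_dataset,
    tally_transmissions,
)
from .io_regions import GenotypeTable
from .model import CnvRegion, Family, PhasingResult, counts_to_string
from .phase_engine import BudgetExceededError, PhasingConfig, phase_region

logger = logging.getLogger(__name__)


@dataclass
class RegionOutcome:
    region: CnvRegion
    family: Family
    group: str
    result: Optional[PhasingResult] = None
    error: str = ""


def run_phasing(
    genotype_path,
    calls_a_path,
    calls_b_path,
    pedigree_path,
    external_path=None,
    config: PhasingConfig = PhasingConfig(),
    keep_going: bool = False,
) -> tuple[list[RegionOutcome], list[io_regions.ExcludedRegion]]:
    """Parse, filter, converge and phase every family CNV region.

    Raises :class:`BudgetExceededError` on the first over-budget region
    unless ``keep_going`` is set, in which case the outcome carries the
    error message instead of a result.
    """
    genotypes = GenotypeTable(io_regions.parse_genotype_table(genotype_path))
    calls_a = io_regions.parse_cnv_calls(calls_a_path)
    calls_b = io_regions.parse_cnv_calls(calls_b_path)
    families = io_regions.parse_pedigree(pedigree_path)
    confirmed, raw_index = io_regions.intersect_caller_calls(calls_a, calls_b)
    if external_path is not None:
        external = io_regions.parse_cnv_calls(external_path)
        confirmed = io_regions.confirm_with_external_calls(confirmed, external)
    filtered = io_regions.filter_calls(confirmed)
    logger.info(
        "calls: %d+%d raw, %d confirmed, %d after filters",
        len(calls_a), len(calls_b), len(confirmed), len(filtered),
    )
    regions, excluded = io_regions.converge_family_regions(
        filtered, raw_index, families, genotypes
    )
    fam_by_id = {f.family_id: f for f in families}
    outcomes: list[RegionOutcome] = []
    for region in regions:
        family = fam_by_id[region.family_id]
        ready = io_regions.select_region_markers(region, genotypes, family)
        group = assign_group(ready)
        try:
            result = phase_region(ready, family, config)
            outcomes.append(RegionOutcome(ready, family, group, result=result))
        except BudgetExceededError as exc:
            if not keep_going:
                raise
            logger.warning("%s: %s", ready.region_id, exc)
            outcomes.append(RegionOutcome(ready, family, group, error=str(exc)))
    return outcomes, excluded


def phasing_frame(outcomes: Iterable[RegionOutcome]) -> pd.DataFrame:
    """One row per (solution, member, haplotype) across all phased regions."""
    rows = []
    for oc in outcomes:
        if oc.result is None:
            continue
        region, family, result = oc.region, oc.family, oc.result
        for s_idx, sol in enumerate(result.solutions):
            transmitted: dict[tuple[str, int], list[str]] = {}
            events: dict[tuple[str, int], list[str]] = {}
            for cid, scheme in sol.schemes:
                if scheme is None:
                    continue
                for role_idx, side in enumerate(scheme):
                    role = ("father", "mother")[role_idx]
                    for src in side.sources:
                        transmitted.setdefault((role, src), []).append(cid)
                        events.setdefault((role, src), []).append(side.event.value)
            for role, phase, member in (
                ("father", sol.father_phase, family.father_id),
                ("mother", sol.mother_phase, family.mother_id),
            ):
                for h_idx, hap in enumerate(phase.haps):
                    key = (role, h_idx)
                    rows.append(
                        {
                            "family_id": region.family_id,
                            "region_id": region.region_id,
                            "chrom": region.chrom,
                            "start": region.start,
                            "end": region.end,
                            "solution_idx": s_idx,
                            "n_solutions": len(result.solutions),
                            "member": member,
                            "role": role,
                            "hap_label": f"{role[0].upper()}{h_idx + 1}",
                            "hap_cn": hap.cn,
                            "hap_alleles": ",".join(hap.allele_strings()) or "-",
                            "transmitted_to": ",".join(transmitted.get(key, [])) or "-",
                            "event": ",".join(events.get(key, [])) or "-",
                            "score_unexplained": sol.n_unexplained,
                            "score_nonmendelian": sol.n_nonmendelian,
                        }
                    )
    return pd.DataFrame(rows)


def result_to_dict(oc: RegionOutcome) -> dict:
    from .synthetic_families import _solution_to_dict  # mechanical serializer

    doc = {
        "region_id": oc.region.region_id,
        "family_id": oc.family.family_id,
        "chrom": oc.region.chrom,
        "start": oc.region.start,
        "end": oc.region.end,
        "group": oc.group,
        "member_cn": oc.region.member_cn,
        "n_markers": oc.region.n_markers,
        "flag": oc.region.flag,
    }
    if oc.result is not None:
        doc.update(
            {
                "unambiguous": oc.result.unambiguous,
                "score": list(oc.result.score),
                "solutions": [_solution_to_dict(s) for s in oc.result.solutions],
            }
        )
    else:
        doc["error"] = oc.error
    return doc


def write_phasing_outputs(outcomes, excluded, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "regions": outdir / "regions.tsv",
        "phasing": outdir / "phasing.tsv",
        "phasing_json": outdir / "phasing.json",
    }
    families = {oc.family.family_id: oc.family for oc in outcomes}
    groups = {oc.region.region_id: oc.group for oc in outcomes}
    io_regions.write_regions_tsv(
        [oc.region for oc in outcomes], families, paths["regions"], groups
    )
    phasing_frame(outcomes).to_csv(paths["phasing"], sep="\t", index=False)
    doc = {
        "regions": [result_to_dict(oc) for oc in outcomes],
        "excluded": [e.__dict__ for e in excluded],
    }
    paths["phasing_json"].write_text(json.dumps(doc, indent=1, sort_keys=True))
    return paths


def run_analysis(outcomes: Iterable[RegionOutcome], outdir=None) -> dict:
    """Transmission table, summary and de novo report from phased outcomes."""
    outcomes = [oc for oc in outcomes if oc.result is not None]
    entries = [(oc.region, oc.family, oc.result) for oc in outcomes]
    group_a_unamb = [
        (oc.region, oc.family, oc.result)
        for oc in outcomes
        if oc.group == "A" and oc.result.unambiguous
    ]
    table = tally_transmissions(group_a_unamb)
    summary = summarize_dataset(entries)
    denovo = []
    for region, family, result in entries:
        denovo.extend(de_novo_reports(region, family, result))
    out = {
        "summary": summary,
        "transmissions": table,
        "de_novo": denovo,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_frame().to_csv(outdir / "transmissions.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        pd.DataFrame([r.__dict__ for r in denovo]).to_csv(
            outdir / "denovo.tsv", sep="\t", index=False
        )
    return out
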