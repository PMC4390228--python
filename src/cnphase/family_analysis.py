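"""Post-phasing analytics: region grouping, transmission tables and tests,
allelic variability of copy-number-gain haplotypes, and dataset summaries.

Regions are grouped by parental carrier status (A: one carrier parent,
B: both, C: putative de novo -- no carrier parent but >=1 carrier child).
Transmission counting follows the one-event-per-locus-per-child rule in
unambiguously phased group-A regions only, stratified by CNV type and
length; deviation from the expected 50:50 segregation is tested with a
continuity-corrected Pearson chi-square against equal proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import chi2

from .model import (
    DE_NOVO_EVENTS,
    CnvRegion,
    Event,
    Family,
    FamilySolution,
    Haplotype,
    PhasingResult,
)
from .phase_engine import classify_de_novo

logger = logging.getLogger(__name__)

#: CNV length bins, half-open [low, high) in bp
LENGTH_BINS: tuple[tuple[str, int, float], ...] = (
    ("<10kb", 0, 10_000),
    ("10-30kb", 10_000, 30_000),
    ("30-100kb", 30_000, 100_000),
    (">100kb", 100_000, float("inf")),
)


def length_bin(length_bp: int) -> str:
    """Half-open length bin label (lower edge inclusive)."""
    for label, low, high in LENGTH_BINS:
        if low <= length_bp < high:
            return label
    raise ValueError(f"negative length {length_bp}")


def assign_group(region: CnvRegion) -> str:
    """'A' (one carrier parent), 'B' (both), or 'C' (child carrier only)."""
    n_parents = len(region.carrier_parents)
    if n_parents == 1:
        return "A"
    if n_parents == 2:
        return "B"
    child_carriers = region.carrier_members - region.carrier_parents
    if child_carriers:
        return "C"
    raise ValueError(f"{region.region_id}: no CNV carrier in region")


# ---------------------------------------------------------------------------
# transmission analysis


@dataclass(frozen=True)
class TransmissionRecord:
    """One carrier-parent-to-child transmission in a group-A region."""

    region_id: str
    child_id: str
    carrier_parent: str
    transmitted_cnv: bool  # True when the CNV-carrying haplotype was passed
    cnv_type: str  # 'deletion' | 'duplication'
    cnv_length: int


def _carrier_cnv_type(phase) -> str:
    if any(h.cn > 1 for h in phase.haps):
        return "duplication"
    return "deletion"


def transmission_records(
    region: CnvRegion,
    family: Family,
    result: PhasingResult,
) -> list[TransmissionRecord]:
    """Extract per-child transmission records from one unambiguous group-A
    result.  Only Mendelian gametes from the carrier parent count (a
    non-Mendelian gamete transmits neither parental haplotype intact)."""
    if not result.unambiguous:
        raise ValueError(f"{region.region_id}: ambiguous result not countable")
    if assign_group(region) != "A":
        raise ValueError(f"{region.region_id}: transmission counting is group-A only")
    (carrier_role,) = region.carrier_parents
    sol = result.solutions[0]
    phase = sol.father_phase if carrier_role == "father" else sol.mother_phase
    cnv_type = _carrier_cnv_type(phase)
    records = []
    for cid in family.child_ids:
        scheme = sol.scheme_for(cid)
        if scheme is None:
            continue
        parent_scheme = scheme[0] if carrier_role == "father" else scheme[1]
        if parent_scheme.event is not Event.MENDELIAN:
            logger.info(
                "%s child %s: %s gamete from carrier parent; not counted",
                region.region_id, cid, parent_scheme.event.value,
            )
            continue
        source_hap = phase.haps[parent_scheme.sources[0]]
        records.append(
            TransmissionRecord(
                region_id=region.region_id,
                child_id=cid,
                carrier_parent=carrier_role,
                transmitted_cnv=source_hap.cn != 1,
                cnv_type=cnv_type,
                cnv_length=region.length,
            )
        )
    return records


@dataclass
class TransmissionTable:
    """Counts of CNV-haplotype transmissions by type and length bin."""

    records: list[TransmissionRecord] = field(default_factory=list)

    def counts(self, cnv_type: Optional[str] = None,
               bin_label: Optional[str] = None) -> tuple[int, int]:
        """(n transmitted-CNV, n total) for a type/bin cell; None = margin."""
        n_cnv = n_all = 0
        for r in self.records:
            if cnv_type is not None and r.cnv_type != cnv_type:
                continue
            if bin_label is not None and length_bin(r.cnv_length) != bin_label:
                continue
            n_all += 1
            n_cnv += r.transmitted_cnv
        return n_cnv, n_all

    def to_frame(self, corrected: bool = True,
                 adjust_method: str = "bonferroni") -> pd.DataFrame:
        """Table-style layout: rate and counts per (length bin x CNV type),
        with chi-square p-values against 50:50 and adjusted p-values."""
        rows = []
        bins = [label for label, _, _ in LENGTH_BINS] + ["All"]
        types = ["deletion", "duplication", None]
        for blabel in bins:
            row: dict = {"length_bin": blabel}
            for t in types:
                key = t or "all"
                n_cnv, n_all = self.counts(t, None if blabel == "All" else blabel)
                row[f"{key}_cnv"] = n_cnv
                row[f"{key}_total"] = n_all
                row[f"{key}_rate"] = round(100 * n_cnv / n_all, 1) if n_all else float("nan")
                if n_all:
                    _, p = transmission_bias_test(n_cnv, n_all - n_cnv, corrected)
                    row[f"{key}_p"] = p
                else:
                    row[f"{key}_p"] = float("nan")
            rows.append(row)
        df = pd.DataFrame(rows)
        pcols = [c for c in df.columns if c.endswith("_p")]
        ps, locs = [], []
        for c in pcols:
            for i, p in enumerate(df[c]):
                if p == p:  # not NaN
                    ps.append(p)
                    locs.append((i, c))
        adjusted, significant = multiple_testing_adjust(ps, method=adjust_method)
        for (i, c), padj, sig in zip(locs, adjusted, significant):
            df.loc[i, c.replace("_p", "_p_adj")] = padj
            df.loc[i, c.replace("_p", "_significant")] = bool(sig)
        return df


def tally_transmissions(
    entries: Iterable[tuple[CnvRegion, Family, PhasingResult]]
) -> TransmissionTable:
    """Build the transmission table from unambiguous group-A results."""
    table = TransmissionTable()
    for region, family, result in entries:
        table.records.extend(transmission_records(region, family, result))
    return table


def transmission_bias_test(
    n_cnv: int, n_normal: int, corrected: bool = True
) -> tuple[float, float]:
    """Pearson chi-square of observed (n_cnv, n_normal) against 50:50.

    Yates continuity correction is applied by default; the statistic is
    clamped at zero so a perfect 50:50 split yields p = 1.  Returns
    (statistic, two-sided p).
    """
    total = n_cnv + n_normal
    if total < 1:
        raise ValueError("at least one transmission event required")
    expected = total / 2
    dev = abs(n_cnv - expected)
    if corrected:
        dev = max(dev - 0.5, 0.0)
    stat = 2 * dev * dev / expected
    return stat, float(chi2.sf(stat, df=1))


def multiple_testing_adjust(
    p_values: Sequence[float],
    method: str = "bonferroni",
    alpha: float = 0.05,
) -> tuple[list[float], list[bool]]:
    """Adjust p-values for multiple testing; returns (adjusted, significant).

    Bonferroni by default; 'holm' and 'bh' (Benjamini-Hochberg) are
    available through statsmodels.  Adjusted values are capped at 1.
    """
    p_values = list(p_values)
    if not p_values:
        return [], []
    if method == "bonferroni":
        m = len(p_values)
        adjusted = [min(1.0, p * m) for p in p_values]
        return adjusted, [p < alpha for p in adjusted]
    from statsmodels.stats.multitest import multipletests

    mapped = {"holm": "holm", "bh": "fdr_bh"}
    if method not in mapped:
        raise ValueError(f"unknown adjustment method {method!r}")
    reject, adjusted, _, _ = multipletests(p_values, alpha=alpha, method=mapped[method])
    return list(adjusted), list(reject)


# ---------------------------------------------------------------------------
# allelic variability


@dataclass(frozen=True)
class AllelicVariabilityReport:
    """Informativeness of one copy-number-gain haplotype in one parent."""

    region_id: str
    parent: str
    hap_index: int
    hap_cn: int
    has_between_informative: bool
    has_within_informative: bool


def allelic_variability(
    solution: FamilySolution, region_id: str = ""
) -> list[AllelicVariabilityReport]:
    """Between/within informativeness for every gain haplotype (cn >= 2).

    A marker is *within*-informative when the gain haplotype's tuple there
    holds both alleles (a heterozygous allelic copy inside the haplotype);
    it is *between*-informative when the parent's two haplotypes differ
    there and the marker is polymorphic in that parent (pure dosage of one
    allele does not distinguish allelic content).
    """
    reports = []
    for parent, phase in (
        ("father", solution.father_phase),
        ("mother", solution.mother_phase),
    ):
        h1, h2 = phase.haps
        for idx, hap in enumerate(phase.haps):
            if hap.cn < 2:
                continue
            within = any(a > 0 and b > 0 for a, b in hap.counts)
            between = any(
                c1 != c2 and (c1[0] + c2[0] > 0 and c1[1] + c2[1] > 0)
                for c1, c2 in zip(h1.counts, h2.counts)
            )
            reports.append(
                AllelicVariabilityReport(
                    region_id=region_id,
                    parent=parent,
                    hap_index=idx,
                    hap_cn=hap.cn,
                    has_between_informative=between,
                    has_within_informative=within,
                )
            )
    return reports


# ---------------------------------------------------------------------------
# de novo annotation and dataset summary


@dataclass(frozen=True)
class DeNovoReport:
    region_id: str
    family_id: str
    chrom: str
    start: int
    end: int
    child_id: str
    event: str
    parent_of_origin: str  # 'father' | 'mother' | 'undetermined'
    dup_class: str  # 'intra' | 'inter' | 'ambiguous' | '-'


def de_novo_reports(
    region: CnvRegion, family: Family, result: PhasingResult
) -> list[DeNovoReport]:
    """Aggregate de novo events across the co-optimal set.

    The parent of origin (and the intra/inter typing of gains) is reported
    only when every co-optimal solution agrees on it and the parental
    haplotypes are distinguishable within each solution."""
    per_child: dict[str, list] = {}
    for sol in result.solutions:
        for cid, scheme in sol.schemes:
            if scheme is None:
                continue
            for side in scheme:
                if side.event in DE_NOVO_EVENTS and side.gametes:
                    ann = classify_de_novo(sol, side)
                    per_child.setdefault(cid, []).append((sol, side, ann))
    reports = []
    for cid, hits in per_child.items():
        kinds = {ann.event for _, _, ann in hits}
        event = hits[0][2].event.value if len(kinds) == 1 else "ambiguous"
        parents = {ann.parent for _, _, ann in hits}
        determined = all(ann.parent_of_origin_determined for _, _, ann in hits)
        n_sols_with_hit = len({id(sol) for sol, _, _ in hits})
        if len(parents) == 1 and determined and n_sols_with_hit == len(result.solutions):
            origin = parents.pop()
        else:
            origin = "undetermined"
        dup_classes = {ann.dup_class for _, _, ann in hits if ann.dup_class}
        if len(dup_classes) == 1:
            dup_class = {
                Event.DENOVO_DUP_INTRA: "intra",
                Event.DENOVO_DUP_INTER: "inter",
                Event.DENOVO_DUP_AMBIG: "ambiguous",
            }[dup_classes.pop()]
        elif dup_classes:
            dup_class = "ambiguous"
        else:
            dup_class = "-"
        reports.append(
            DeNovoReport(
                region_id=region.region_id,
                family_id=family.family_id,
                chrom=region.chrom,
                start=region.start,
                end=region.end,
                child_id=cid,
                event=event,
                parent_of_origin=origin,
                dup_class=dup_class,
            )
        )
    return sorted(reports, key=lambda r: (r.region_id, r.child_id))


def summarize_dataset(
    entries: Iterable[tuple[CnvRegion, Family, PhasingResult]]
) -> dict:
    """Phasing-efficiency, de novo and allelic-variability summary.

    Percentages are reported to one decimal.  Gain-haplotype variability is
    counted per (region, parent, haplotype) over unambiguous results.
    """
    entries = list(entries)
    groups: dict[str, list] = {"A": [], "B": [], "C": []}
    for region, family, result in entries:
        groups[assign_group(region)].append((region, family, result))
    summary: dict = {"groups": {}, "all_regions": {}}
    total = unamb_total = 0
    for g, items in groups.items():
        n = len(items)
        n_unamb = sum(1 for _, _, res in items if res.unambiguous)
        total += n
        unamb_total += n_unamb
        summary["groups"][g] = {
            "n_regions": n,
            "n_unambiguous": n_unamb,
            "pct_unambiguous": round(100 * n_unamb / n, 1) if n else None,
        }
    summary["all_regions"] = {
        "n_regions": total,
        "n_unambiguous": unamb_total,
        "pct_unambiguous": round(100 * unamb_total / total, 1) if total else None,
    }
    denovo = []
    for region, family, result in entries:
        denovo.extend(de_novo_reports(region, family, result))
    summary["de_novo"] = [r.__dict__ for r in denovo]
    gain_reports = []
    for region, family, result in entries:
        if not result.unambiguous:
            continue
        gain_reports.extend(allelic_variability(result.solutions[0], region.region_id))
    n_gain = len(gain_reports)
    n_between = sum(r.has_between_informative for r in gain_reports)
    n_within = sum(r.has_within_informative for r in gain_reports)
    summary["gain_haplotypes"] = {
        "n_gain_haplotypes": n_gain,
        "n_between_informative": n_between,
        "n_within_informative": n_within,
        "pct_between_informative": round(100 * n_between / n_gain, 1) if n_gain else None,
        "pct_within_informative": round(100 * n_within / n_gain, 1) if n_gain else None,
    }
    return summary
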