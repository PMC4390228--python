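"""Parsing, filtering and family-wise convergence of CNV calls and genotypes.

Implements the quality pipeline applied upstream of phasing: per-sample
array QC, two-caller intersection of CNV calls, optional confirmation
against an external call set, the autosome / >=1 kb / LBF>=5 call filters,
convergence of member calls into family-wise CNV regions (with the
raw-single-caller exclusion rule), and phasing-ready marker selection.

Coordinates are 1-based and inclusive on both ends; overlap means >=1
shared base pair.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import (
    CnvCall,
    CnvRegion,
    Counts,
    Family,
    MarkerGenotype,
    SampleQC,
    counts_from_string,
)

logger = logging.getLogger(__name__)

#: PennCNV sample-level QC thresholds (all inclusive, as printed)
QC_THRESHOLDS = {"lrr_sd": 0.25, "baf_sd": 0.05, "baf_drift": 0.002, "gcwf": 0.04}
#: minimum call length in bp (calls strictly shorter are removed)
MIN_CALL_LENGTH = 1000
#: minimum log Bayes Factor (calls strictly below are removed)
MIN_LBF = 5.0
#: genotype-call confidence below which a marker is dropped family-wide
MIN_GENOTYPE_CONFIDENCE = 0.95
#: minimum shared markers when >=2 carrier calls are intersected
MIN_SHARED_MARKERS = 3

AUTOSOMES = frozenset(str(i) for i in range(1, 23))


class ParseError(ValueError):
    """A malformed input row, reported with its file line number."""


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


# ---------------------------------------------------------------------------
# parsers

GENOTYPE_COLUMNS = ["sample_id", "marker_id", "chrom", "pos", "genotype", "confidence"]
CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "cn", "lbf", "caller", "n_markers"]
PED_COLUMNS = ["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"]


def parse_genotype_table(path) -> list[MarkerGenotype]:
    """Read a TSV of per-sample per-marker CNV genotypes.

    Genotype strings are multisets over {A, B} of size 0--4 ('-' or empty
    for CN=0), or 'NC' for markers where no call could be made; they are
    canonicalized A-before-B.  Confidence must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        gt = (row.genotype or "").strip()
        is_nc = gt.upper() == "NC"
        if not is_nc and set(gt) - set("AB-"):
            raise ParseError(f"{path} line {idx}: invalid genotype {gt!r}")
        try:
            counts = (0, 0) if is_nc else counts_from_string(gt.replace("-", ""))
        except ValueError as exc:
            raise ParseError(f"{path} line {idx}: {exc}") from None
        try:
            conf = float(row.confidence)
            pos = int(row.pos)
        except (TypeError, ValueError):
            raise ParseError(f"{path} line {idx}: non-numeric pos/confidence") from None
        if not 0.0 <= conf <= 1.0:
            raise ParseError(f"{path} line {idx}: confidence {conf} outside [0,1]")
        records.append(
            MarkerGenotype(
                sample_id=row.sample_id,
                marker_id=row.marker_id,
                chrom=_norm_chrom(row.chrom),
                pos=pos,
                counts=counts,
                is_no_call=is_nc,
                confidence=conf,
            )
        )
    return records


def parse_cnv_calls(path) -> list[CnvCall]:
    """Read a TSV of per-sample CNV segment calls (diploid CN 0,1,3,4)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    calls = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            call = CnvCall(
                sample_id=row.sample_id,
                chrom=_norm_chrom(row.chrom),
                start=int(row.start),
                end=int(row.end),
                cn=int(row.cn),
                lbf=float(row.lbf),
                caller=row.caller,
                n_markers=int(row.n_markers),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path} line {idx}: {exc}") from None
        calls.append(call)
    return calls


def parse_pedigree(path) -> list[Family]:
    """Read a 6-column PED-dialect file into nuclear families.

    Individuals with parent ids '0' are founders.  Each family must be
    strictly nuclear: every child references the same two founder parents
    present in the family; deeper pedigrees are rejected.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str, header=None, comment="#")
    if df.shape[1] != 6:
        raise ParseError(f"{path}: expected 6 columns, got {df.shape[1]}")
    df.columns = PED_COLUMNS
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise ParseError(f"{path}: duplicate individual id {dup!r}")
    families = []
    for fam_id, group in df.groupby("family_id", sort=True):
        ids = set(group["individual_id"])
        children = group[(group["father_id"] != "0") | (group["mother_id"] != "0")]
        founders = group[(group["father_id"] == "0") & (group["mother_id"] == "0")]
        if children.empty:
            logger.warning("family %s has no children; skipped", fam_id)
            continue
        pairs = set(zip(children["father_id"], children["mother_id"]))
        if len(pairs) != 1:
            raise ParseError(f"{path}: family {fam_id} is not a single nuclear family")
        father_id, mother_id = pairs.pop()
        for pid in (father_id, mother_id):
            if pid == "0" or pid not in ids:
                raise ParseError(
                    f"{path}: family {fam_id} child references missing parent {pid!r}"
                )
        if father_id not in set(founders["individual_id"]) or mother_id not in set(
            founders["individual_id"]
        ):
            raise ParseError(
                f"{path}: family {fam_id} spans more than two generations"
            )
        families.append(
            Family(fam_id, father_id, mother_id, tuple(children["individual_id"]))
        )
    return families


# ---------------------------------------------------------------------------
# sample QC


def sample_qc_filter(metrics: Iterable[SampleQC]) -> dict[str, bool]:
    """Pass/fail per sample against the array QC thresholds.

    Pass requires LRR_SD<=0.25, BAF_SD<=0.05, BAF_DRIFT<=0.002 and
    |GCWF|<=0.04 (all inclusive).  Samples with a missing (NaN) metric are
    indeterminate: excluded with a warning.
    """
    out = {}
    for m in metrics:
        values = (m.lrr_sd, m.baf_sd, m.baf_drift, m.gcwf)
        if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in values):
            logger.warning("sample %s: missing QC metric; excluded", m.sample_id)
            out[m.sample_id] = False
            continue
        out[m.sample_id] = (
            m.lrr_sd <= QC_THRESHOLDS["lrr_sd"]
            and m.baf_sd <= QC_THRESHOLDS["baf_sd"]
            and m.baf_drift <= QC_THRESHOLDS["baf_drift"]
            and abs(m.gcwf) <= QC_THRESHOLDS["gcwf"]
        )
    return out


# ---------------------------------------------------------------------------
# call intersection / confirmation / filters


@dataclass
class RawCallIndex:
    """Index of raw per-caller calls, for the single-caller exclusion rule."""

    calls: list[CnvCall] = field(default_factory=list)
    confirmed_keys: set[tuple] = field(default_factory=set)

    def single_caller_calls(self, sample_id: str, chrom: str, start: int, end: int
                            ) -> list[CnvCall]:
        """Raw calls by only one caller overlapping the given interval."""
        out = []
        for c in self.calls:
            key = (c.sample_id, c.chrom, c.start, c.end, c.cn, c.caller)
            if key in self.confirmed_keys:
                continue
            if c.sample_id == sample_id and c.chrom == chrom and c.start <= end and start <= c.end:
                out.append(c)
        return out


def _same_type(a: CnvCall, b: CnvCall) -> bool:
    return a.is_gain == b.is_gain


def intersect_caller_calls(
    calls_a: Iterable[CnvCall], calls_b: Iterable[CnvCall]
) -> tuple[list[CnvCall], RawCallIndex]:
    """Merge two callers' call sets as per-sample same-type intersections.

    For every pair of same-sample calls overlapping by >=1 bp whose types
    agree (both gains or both losses) the coordinate intersection is
    emitted, with cn/LBF taken from the first (primary) caller; a cn
    discord between agreeing callers is logged.  Unmatched calls are
    dropped from the confirmed set but kept in the returned raw-call index
    for the family-region exclusion rule.
    """
    calls_a = list(calls_a)
    calls_b = list(calls_b)
    by_sample_b: dict[tuple, list[CnvCall]] = defaultdict(list)
    for c in calls_b:
        by_sample_b[(c.sample_id, c.chrom)].append(c)
    confirmed = []
    index = RawCallIndex(calls=calls_a + calls_b)
    for a in sorted(calls_a, key=lambda c: (c.sample_id, c.chrom, c.start, c.end, c.cn)):
        for b in by_sample_b.get((a.sample_id, a.chrom), ()):
            if not a.overlaps(b) or not _same_type(a, b):
                continue
            if a.cn != b.cn:
                logger.info(
                    "cn discord for %s %s:%d-%d (%d vs %d); keeping primary caller's",
                    a.sample_id, a.chrom, a.start, a.end, a.cn, b.cn,
                )
            confirmed.append(
                CnvCall(
                    sample_id=a.sample_id,
                    chrom=a.chrom,
                    start=max(a.start, b.start),
                    end=min(a.end, b.end),
                    cn=a.cn,
                    lbf=a.lbf,
                    caller=f"{a.caller}+{b.caller}",
                    n_markers=a.n_markers,
                )
            )
            index.confirmed_keys.add((a.sample_id, a.chrom, a.start, a.end, a.cn, a.caller))
            index.confirmed_keys.add((b.sample_id, b.chrom, b.start, b.end, b.cn, b.caller))
    return confirmed, index


def confirm_with_external_calls(
    confirmed_calls: Iterable[CnvCall], external_calls: Iterable[CnvCall]
) -> list[CnvCall]:
    """Keep calls with a same-sample, same-type, >=1 bp overlapping external
    call; the internal call's coordinates are preserved."""
    by_sample: dict[tuple, list[CnvCall]] = defaultdict(list)
    for c in external_calls:
        by_sample[(c.sample_id, c.chrom)].append(c)
    out = []
    for call in confirmed_calls:
        for ext in by_sample.get((call.sample_id, call.chrom), ()):
            if call.overlaps(ext) and _same_type(call, ext):
                out.append(call)
                break
    return out


def filter_calls(calls: Iterable[CnvCall]) -> list[CnvCall]:
    """Autosomal calls of length >=1000 bp with LBF >=5 (both strict cuts
    on the removed side, per the printed thresholds)."""
    return [
        c
        for c in calls
        if c.chrom in AUTOSOMES and c.length >= MIN_CALL_LENGTH and c.lbf >= MIN_LBF
    ]


# ---------------------------------------------------------------------------
# genotype container


class GenotypeTable:
    """Per-sample per-marker genotypes with positional lookup."""

    def __init__(self, records: Iterable[MarkerGenotype]):
        self._by_sample: dict[str, dict[str, MarkerGenotype]] = defaultdict(dict)
        self._markers: dict[tuple[str, str], int] = {}
        for r in records:
            self._by_sample[r.sample_id][r.marker_id] = r
            self._markers[(r.chrom, r.marker_id)] = r.pos

    def get(self, sample_id: str, marker_id: str) -> Optional[MarkerGenotype]:
        return self._by_sample.get(sample_id, {}).get(marker_id)

    def markers_in(self, chrom: str, start: int, end: int) -> list[tuple[str, int]]:
        """(marker_id, pos) within an interval, ordered by position."""
        hits = [
            (mid, pos)
            for (c, mid), pos in self._markers.items()
            if c == chrom and start <= pos <= end
        ]
        return sorted(hits, key=lambda t: (t[1], t[0]))


# ---------------------------------------------------------------------------
# family-region convergence


@dataclass
class ExcludedRegion:
    family_id: str
    chrom: str
    start: int
    end: int
    reason: str


def converge_family_regions(
    calls: Iterable[CnvCall],
    raw_index: RawCallIndex,
    families: Iterable[Family],
    genotypes: GenotypeTable,
) -> tuple[list[CnvRegion], list[ExcludedRegion]]:
    """Converge filtered confirmed calls into family-wise CNV regions.

    Per family, overlapping member calls are clustered; the region interval
    is the intersection of the carrier calls.  A region is excluded when
    (i) >=2 carrier calls intersect over an empty interval or fewer than 3
    shared markers, (ii) any non-carrier member has a raw single-caller
    call overlapping the interval, or (iii) a member carries overlapping
    calls of different copy number inside the cluster (complex,
    non-constant CN).  Members without a call get region CN 2.
    """
    calls = list(calls)
    regions: list[CnvRegion] = []
    excluded: list[ExcludedRegion] = []
    for family in sorted(families, key=lambda f: f.family_id):
        members = set(family.members)
        fam_calls = [c for c in calls if c.sample_id in members]
        by_chrom: dict[str, list[CnvCall]] = defaultdict(list)
        for c in fam_calls:
            by_chrom[c.chrom].append(c)
        for chrom in sorted(by_chrom):
            for cluster in _overlap_clusters(by_chrom[chrom]):
                _build_region(cluster, chrom, family, raw_index, genotypes,
                              regions, excluded)
    return regions, excluded


def _overlap_clusters(calls: list[CnvCall]) -> list[list[CnvCall]]:
    """Cluster calls transitively by >=1 bp overlap (any member)."""
    calls = sorted(calls, key=lambda c: (c.start, c.end, c.sample_id))
    clusters: list[list[CnvCall]] = []
    cur: list[CnvCall] = []
    cur_end = -1
    for c in calls:
        if cur and c.start > cur_end:
            clusters.append(cur)
            cur = []
            cur_end = -1
        cur.append(c)
        cur_end = max(cur_end, c.end)
    if cur:
        clusters.append(cur)
    return clusters


def _build_region(cluster, chrom, family, raw_index, genotypes, regions, excluded):
    span = (min(c.start for c in cluster), max(c.end for c in cluster))
    per_member: dict[str, list[CnvCall]] = defaultdict(list)
    for c in cluster:
        per_member[c.sample_id].append(c)
    member_cn: dict[str, int] = {}
    for sid, mcalls in per_member.items():
        cns = {c.cn for c in mcalls}
        if len(cns) > 1:
            logger.warning(
                "family %s %s:%d-%d: member %s has calls with CN %s; "
                "complex region excluded", family.family_id, chrom, *span, sid,
                sorted(cns),
            )
            excluded.append(ExcludedRegion(family.family_id, chrom, *span, "complex"))
            return
        member_cn[sid] = cns.pop()
    carriers = sorted(per_member)
    start = max(c.start for c in cluster)
    end = min(c.end for c in cluster)
    if start > end:
        excluded.append(
            ExcludedRegion(family.family_id, chrom, *span, "empty_intersection")
        )
        return
    markers = genotypes.markers_in(chrom, start, end)
    if len(carriers) > 1 and len(markers) < MIN_SHARED_MARKERS:
        excluded.append(
            ExcludedRegion(family.family_id, chrom, start, end, "too_few_shared_markers")
        )
        return
    for sid in family.members:
        if sid in per_member:
            continue
        if raw_index.single_caller_calls(sid, chrom, start, end):
            excluded.append(
                ExcludedRegion(family.family_id, chrom, start, end, "raw_single_caller")
            )
            return
        member_cn[sid] = 2
    carrier_parents = frozenset(
        role
        for role, pid in (("father", family.father_id), ("mother", family.mother_id))
        if pid in per_member
    )
    marker_ids = tuple(m for m, _ in markers)
    marker_pos = tuple(p for _, p in markers)
    gts: dict[str, tuple[Counts, ...]] = {}
    for sid in family.members:
        row = []
        for mid in marker_ids:
            rec = genotypes.get(sid, mid)
            row.append(rec.counts if rec is not None else (0, 0))
        gts[sid] = tuple(row)
    regions.append(
        CnvRegion(
            family_id=family.family_id,
            chrom=chrom,
            start=start,
            end=end,
            member_cn=member_cn,
            marker_ids=marker_ids,
            marker_pos=marker_pos,
            genotypes=gts,
            carrier_parents=carrier_parents,
            carrier_members=frozenset(per_member),
        )
    )


def select_region_markers(region: CnvRegion, genotypes: GenotypeTable,
                          family: Family) -> CnvRegion:
    """Reduce a region to its phasing-ready marker set.

    A marker is dropped when (i) any family member has a no-call or a
    genotype confidence below 0.95 there (one bad member removes the marker
    family-wide), (ii) the union of alleles over all members holds a single
    allele type (monomorphic, uninformative), (iii) it lies outside the
    intersection interval, or (iv) any member's genotype size contradicts
    its region copy number.  Zero remaining markers is allowed: the region
    is flagged 'uninformative' and may still phase via copy numbers alone.
    """
    keep_ids: list[str] = []
    keep_pos: list[int] = []
    keep_idx: list[int] = []
    for i, (mid, pos) in enumerate(zip(region.marker_ids, region.marker_pos)):
        if not region.start <= pos <= region.end:
            continue
        ok = True
        total_a = total_b = 0
        for sid in family.members:
            rec = genotypes.get(sid, mid)
            if rec is None or rec.is_no_call or rec.confidence < MIN_GENOTYPE_CONFIDENCE:
                ok = False
                break
            if rec.size != region.member_cn[sid]:
                ok = False
                break
            total_a += rec.counts[0]
            total_b += rec.counts[1]
        if not ok:
            continue
        if total_a == 0 or total_b == 0:  # monomorphic across the family
            continue
        keep_ids.append(mid)
        keep_pos.append(pos)
        keep_idx.append(i)
    gts = {
        sid: tuple(region.genotypes[sid][i] for i in keep_idx)
        for sid in region.genotypes
    }
    return CnvRegion(
        family_id=region.family_id,
        chrom=region.chrom,
        start=region.start,
        end=region.end,
        member_cn=dict(region.member_cn),
        marker_ids=tuple(keep_ids),
        marker_pos=tuple(keep_pos),
        genotypes=gts,
        carrier_parents=region.carrier_parents,
        carrier_members=region.carrier_members,
        flag="uninformative" if not keep_ids else "",
    )


# ---------------------------------------------------------------------------
# writers


def write_regions_tsv(regions: Sequence[CnvRegion], families: Mapping[str, Family],
                      path, groups: Optional[Mapping[str, str]] = None) -> None:
    """Write the region table (one row per family-converged region)."""
    rows = []
    for r in regions:
        fam = families[r.family_id]
        rows.append(
            {
                "family_id": r.family_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "members": ",".join(fam.members),
                "cns": ",".join(str(r.member_cn[m]) for m in fam.members),
                "n_markers": r.n_markers,
                "carrier_parents": ",".join(sorted(r.carrier_parents)) or "-",
                "group": (groups or {}).get(r.region_id, "-"),
                "flag": r.flag or "-",
            }
        )
    pd.DataFrame(
        rows,
        columns=["family_id", "chrom", "start", "end", "members", "cns",
                 "n_markers", "carrier_parents", "group", "flag"],
    ).to_csv(path, sep="\t", index=False)
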