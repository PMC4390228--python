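"""Core data model for haplotype phasing of CNV regions in nuclear families.

A marker genotype inside a CNV region is a multiset over the two array
alleles {A, B} whose size equals the individual's diploid copy number at
that marker (0--4): ``-``, ``A``, ``AB``, ``ABB``, ``ABBB`` and so on.
Internally every such multiset is stored as an allele-count pair
``(nA, nB)``, which makes multiset union, sub-multiset tests and canonical
ordering plain integer arithmetic.  A haplotype is the per-marker allele
content carried on one homologous chromosome, with a haploid copy number
``cn`` in 0--3 (cn=1 is a normal haplotype, cn=0 a deletion-carrying one,
cn>1 a copy-number-gain-carrying one).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

#: maximum haploid copy number on one haplotype
MAX_HAPLOID_CN = 3
#: maximum diploid copy number (both homologs combined)
MAX_DIPLOID_CN = 4

Counts = tuple[int, int]


def counts_from_string(genotype: str) -> Counts:
    """Parse a canonical {A,B} genotype string ('-' or '' for CN=0)."""
    if genotype in ("-", ""):
        return (0, 0)
    a = genotype.count("A")
    b = genotype.count("B")
    if a + b != len(genotype):
        raise ValueError(f"invalid genotype string {genotype!r}")
    if a + b > MAX_DIPLOID_CN:
        raise ValueError(f"genotype {genotype!r} exceeds diploid CN {MAX_DIPLOID_CN}")
    return (a, b)


def counts_to_string(counts: Counts) -> str:
    a, b = counts
    return "A" * a + "B" * b if a + b else "-"


class Event(str, Enum):
    """Region-wide inheritance event of one gamete (or one child for UPD)."""

    MENDELIAN = "mendelian"
    DENOVO_DELETION = "denovo_deletion"
    DENOVO_DUP_INTRA = "denovo_dup_intra"
    DENOVO_DUP_INTER = "denovo_dup_inter"
    DENOVO_DUP_AMBIG = "denovo_dup_ambig"
    UPD_ISO = "upd_isodisomy"
    UPD_HETERO = "upd_heterodisomy"


DE_NOVO_DUP_EVENTS = frozenset(
    {Event.DENOVO_DUP_INTRA, Event.DENOVO_DUP_INTER, Event.DENOVO_DUP_AMBIG}
)
DE_NOVO_EVENTS = DE_NOVO_DUP_EVENTS | {Event.DENOVO_DELETION}
UPD_EVENTS = frozenset({Event.UPD_ISO, Event.UPD_HETERO})
NON_MENDELIAN_EVENTS = DE_NOVO_EVENTS | UPD_EVENTS


@dataclass(frozen=True)
class Haplotype:
    """Allele content of one homolog across the region's retained markers."""

    cn: int
    counts: tuple[Counts, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.cn <= MAX_HAPLOID_CN:
            raise ValueError(f"haploid cn {self.cn} outside 0..{MAX_HAPLOID_CN}")
        for c in self.counts:
            if c[0] + c[1] != self.cn or c[0] < 0 or c[1] < 0:
                raise ValueError(f"marker counts {c} inconsistent with cn={self.cn}")

    @property
    def key(self) -> tuple:
        return (self.cn, self.counts)

    def allele_strings(self) -> tuple[str, ...]:
        return tuple(counts_to_string(c) for c in self.counts)

    def is_sub_haplotype_of(self, other: "Haplotype") -> bool:
        return self.cn <= other.cn and all(
            sa <= oa and sb <= ob
            for (sa, sb), (oa, ob) in zip(self.counts, other.counts)
        )


def _pair_key(h1: Haplotype, h2: Haplotype) -> tuple:
    return (h1.key, h2.key)


@dataclass(frozen=True)
class ParentPhase:
    """Unordered pair of haplotypes explaining one parent's genotypes."""

    haps: tuple[Haplotype, Haplotype]

    @classmethod
    def from_pair(cls, h1: Haplotype, h2: Haplotype) -> "ParentPhase":
        if h2.key < h1.key:
            h1, h2 = h2, h1
        return cls((h1, h2))

    @property
    def parent_cn(self) -> int:
        return self.haps[0].cn + self.haps[1].cn

    def genotype(self, marker: int) -> Counts:
        a1, b1 = self.haps[0].counts[marker]
        a2, b2 = self.haps[1].counts[marker]
        return (a1 + a2, b1 + b2)

    @property
    def key(self) -> tuple:
        """Order-invariant serialization of the unordered pair."""
        return tuple(sorted(h.key for h in self.haps))


@dataclass(frozen=True)
class GameteScheme:
    """How one parent's haplotypes formed a child's gamete(s), region-wide.

    ``sources`` are indices into the parent's haplotype pair. For uniparental
    disomy the disomic parent carries two gametes (sources ``(i, i)`` for
    isodisomy, ``(0, 1)`` for heterodisomy) while the other parent's scheme
    has no gametes at all.
    """

    parent: str  # 'father' | 'mother'
    event: Event
    sources: tuple[int, ...]
    gametes: tuple[Haplotype, ...]

    def contribution(self, n_markers: int) -> tuple[int, tuple[Counts, ...]]:
        cn = sum(g.cn for g in self.gametes)
        counts = []
        for m in range(n_markers):
            a = sum(g.counts[m][0] for g in self.gametes)
            b = sum(g.counts[m][1] for g in self.gametes)
            counts.append((a, b))
        return cn, tuple(counts)

    def content_key(self) -> tuple:
        """Serialization by observable content only.

        The source haplotype index is deliberately excluded: which homolog
        a de novo event hit is determinable only through the gamete's
        allele content, so solutions differing in an unobservable source
        assignment (e.g. a deletion to an empty gamete from either
        homolog) are one explanation of the data, not two.
        """
        return (self.event.value, tuple(sorted(g.key for g in self.gametes)))


# a child's scheme pair; None means no copy-number-feasible pairing existed
ChildScheme = Optional[tuple[GameteScheme, GameteScheme]]


def child_event_count(scheme: ChildScheme, count_upd_as: int = 1) -> int:
    """Number of non-Mendelian events a child's scheme pair contributes."""
    if scheme is None:
        return 0
    fs, ms = scheme
    if fs.event in UPD_EVENTS or ms.event in UPD_EVENTS:
        return count_upd_as
    n = 0
    if fs.event is not Event.MENDELIAN:
        n += 1
    if ms.event is not Event.MENDELIAN:
        n += 1
    return n


@dataclass(frozen=True)
class FamilySolution:
    """One complete co-optimal explanation of a family's region data."""

    father_phase: ParentPhase
    mother_phase: ParentPhase
    schemes: tuple[tuple[str, ChildScheme], ...]  # (child_id, scheme) in family order
    n_unexplained: int
    n_nonmendelian: int

    @property
    def score(self) -> tuple[int, int]:
        return (self.n_unexplained, self.n_nonmendelian)

    def scheme_for(self, child_id: str) -> ChildScheme:
        for cid, sch in self.schemes:
            if cid == child_id:
                return sch
        raise KeyError(child_id)

    def canonical_key(self) -> tuple:
        """Serialization invariant under within-parent haplotype relabeling.

        Each parent's haplotype pair is put in sorted order and schemes are
        keyed by observable content (event kind and gamete alleles), so
        solutions identical up to hap1/hap2 relabeling or an unobservable
        source-haplotype assignment share one key.
        """
        fkey = tuple(sorted(h.key for h in self.father_phase.haps))
        mkey = tuple(sorted(h.key for h in self.mother_phase.haps))
        skeys = []
        for cid, sch in self.schemes:
            if sch is None:
                skeys.append(("unexplained",))
            else:
                skeys.append((sch[0].content_key(), sch[1].content_key()))
        return (fkey, mkey, tuple(skeys))


@dataclass(frozen=True)
class PhasingResult:
    """All co-optimal family solutions for one region, canonically ordered."""

    region_id: str
    solutions: tuple[FamilySolution, ...]
    score: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.solutions:
            raise ValueError("a phasing result must hold at least one solution")
        for s in self.solutions:
            if s.score != self.score:
                raise ValueError("co-optimal solutions must share one score")

    @property
    def unambiguous(self) -> bool:
        return len(self.solutions) == 1


def collapse_equivalent_solutions(
    solutions: Iterable[FamilySolution],
) -> list[FamilySolution]:
    """Merge solutions identical up to within-parent haplotype relabeling."""
    seen: dict[tuple, FamilySolution] = {}
    for sol in solutions:
        key = sol.canonical_key()
        if key not in seen:
            seen[key] = sol
    return [seen[k] for k in sorted(seen)]


# ---------------------------------------------------------------------------
# observed-data types


@dataclass(frozen=True)
class MarkerGenotype:
    """One sample's observed allele multiset at one marker."""

    sample_id: str
    marker_id: str
    chrom: str
    pos: int
    counts: Counts  # (0, 0) both for CN=0 and for no-calls
    is_no_call: bool
    confidence: float

    @property
    def size(self) -> int:
        return self.counts[0] + self.counts[1]

    def genotype_string(self) -> str:
        return "NC" if self.is_no_call else counts_to_string(self.counts)


@dataclass(frozen=True)
class CnvCall:
    """One caller's CNV segment call for one sample (CN=2 is not a call)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cn: int
    lbf: float
    caller: str
    n_markers: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"call start {self.start} > end {self.end}")
        if self.cn == 2:
            raise ValueError("diploid CN=2 is the normal state, not a CNV call")
        if not 0 <= self.cn <= MAX_DIPLOID_CN:
            raise ValueError(f"diploid CN {self.cn} outside 0..{MAX_DIPLOID_CN}")
        if self.lbf < 0:
            raise ValueError("LBF confidence must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_gain(self) -> bool:
        return self.cn > 2

    def overlaps(self, other: "CnvCall") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class SampleQC:
    """PennCNV per-sample array quality metrics."""

    sample_id: str
    lrr_sd: float
    baf_sd: float
    baf_drift: float
    gcwf: float


@dataclass(frozen=True)
class Family:
    """A nuclear family: two parents and one or more children."""

    family_id: str
    father_id: str
    mother_id: str
    child_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.father_id == self.mother_id:
            raise ValueError("parents must be distinct individuals")
        if not self.child_ids:
            raise ValueError("a nuclear family needs at least one child")
        members = (self.father_id, self.mother_id) + self.child_ids
        if len(set(members)) != len(members):
            raise ValueError("duplicate individual in family")

    @property
    def members(self) -> tuple[str, ...]:
        return (self.father_id, self.mother_id) + self.child_ids


@dataclass
class CnvRegion:
    """A family-converged CNV region ready for phasing.

    ``genotypes`` maps each member to its per-marker count pairs over the
    retained, position-ordered markers; ``member_cn`` holds the region-wide
    diploid copy number per member (2 for members without a call).
    """

    family_id: str
    chrom: str
    start: int
    end: int
    member_cn: dict[str, int]
    marker_ids: tuple[str, ...]
    marker_pos: tuple[int, ...]
    genotypes: dict[str, tuple[Counts, ...]]
    carrier_parents: frozenset[str]  # subset of {'father', 'mother'}
    carrier_members: frozenset[str]
    flag: str = ""

    @property
    def region_id(self) -> str:
        return f"{self.family_id}:{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def validate(self) -> None:
        if not any(cn != 2 for cn in self.member_cn.values()):
            raise ValueError("a CNV region needs at least one non-diploid member")
        for sid, gts in self.genotypes.items():
            cn = self.member_cn[sid]
            for c in gts:
                if c[0] + c[1] != cn:
                    raise ValueError(
                        f"{sid}: genotype size {c[0] + c[1]} != region CN {cn}"
                    )
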