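"""Deterministic phasing of CNV regions in nuclear families.

The engine enumerates, per parent, every partition of the observed
per-marker allele multisets into two haplotypes with an allowed haploid
copy-number split, then every region-wide gamete formation scheme per
child (Mendelian transmission, de novo deletion/duplication, uniparental
iso-/heterodisomy), and returns the complete set of co-optimal family
solutions under the lexicographic parsimony score
``(n_unexplained_genotypes, n_non_mendelian_events)``.

Mendelian-only scenarios are searched first; non-Mendelian events are
enabled only when no zero-unexplained Mendelian solution exists.  Because
a fully Mendelian zero-unexplained solution has the globally minimal score
(0, 0), this staging returns exactly the same co-optimal set as an
unrestricted search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional, Sequence

from .model import (
    MAX_DIPLOID_CN,
    MAX_HAPLOID_CN,
    ChildScheme,
    CnvRegion,
    Counts,
    Event,
    Family,
    FamilySolution,
    GameteScheme,
    Haplotype,
    ParentPhase,
    PhasingResult,
    UPD_EVENTS,
    child_event_count,
    collapse_equivalent_solutions,
)

#: default allowed haploid cn splits per diploid copy number (hap cn capped at 3)
DEFAULT_CN_SPLITS: dict[int, tuple[tuple[int, int], ...]] = {
    0: ((0, 0),),
    1: ((0, 1),),
    2: ((1, 1),),
    3: ((1, 2),),
    4: ((2, 2), (1, 3)),
}


class BudgetExceededError(RuntimeError):
    """Raised when a region's search space exceeds the configured cap."""


@dataclass(frozen=True)
class PhasingConfig:
    """Tunable knobs of the phasing search.

    ``cn_splits`` overrides the allowed (cn1, cn2) haploid splits for a
    diploid CN, e.g. ``{2: ((1, 1), (0, 2))}`` to admit a 0+2 copy-number
    polymorphism carrier.  ``count_upd_as`` sets how many non-Mendelian
    events one uniparental disomy contributes (one meiotic error by
    default).  ``allow_multistep_dup`` admits de novo gains of more than
    one extra copy per marker.
    """

    allow_nonmendelian: bool = True
    cn_splits: Optional[dict[int, tuple[tuple[int, int], ...]]] = None
    max_combinations: int = 1_000_000
    count_upd_as: int = 1
    allow_multistep_dup: bool = False

    def splits_for(self, diploid_cn: int) -> tuple[tuple[int, int], ...]:
        if self.cn_splits and diploid_cn in self.cn_splits:
            return tuple(self.cn_splits[diploid_cn])
        try:
            return DEFAULT_CN_SPLITS[diploid_cn]
        except KeyError:
            raise ValueError(
                f"diploid CN {diploid_cn} unsupported (max {MAX_DIPLOID_CN})"
            ) from None


class GameteOption(NamedTuple):
    gamete: Haplotype
    event: Event
    source: int  # index into the parent's haplotype pair


def _split_counts(genotype: Counts, cn1: int) -> list[tuple[Counts, Counts]]:
    """All ways to draw a sub-multiset of size cn1 from one marker genotype."""
    a, b = genotype
    out = []
    for a1 in range(min(a, cn1) + 1):
        b1 = cn1 - a1
        if 0 <= b1 <= b:
            out.append(((a1, b1), (a - a1, b - b1)))
    return out


def enumerate_parent_phases(
    genotypes: Sequence[Counts],
    parent_cn: int,
    cn_splits: Optional[Iterable[tuple[int, int]]] = None,
) -> list[ParentPhase]:
    """All distinct unordered haplotype pairs partitioning the genotypes.

    ``genotypes`` are the parent's per-marker allele-count pairs, each of
    size ``parent_cn``.  Every allowed (cn1, cn2) split is expanded into
    every per-marker partition of the observed multiset; pairs identical
    under hap1/hap2 swap are collapsed.
    """
    if parent_cn > MAX_DIPLOID_CN:
        raise ValueError(f"diploid CN {parent_cn} unsupported (max {MAX_DIPLOID_CN})")
    for g in genotypes:
        if g[0] + g[1] != parent_cn:
            raise ValueError(f"genotype {g} does not match diploid CN {parent_cn}")
    if cn_splits is None:
        cn_splits = DEFAULT_CN_SPLITS[parent_cn]
    seen: dict[tuple, ParentPhase] = {}
    for cn1, cn2 in cn_splits:
        if cn1 + cn2 != parent_cn:
            raise ValueError(f"split ({cn1},{cn2}) does not sum to CN {parent_cn}")
        if max(cn1, cn2) > MAX_HAPLOID_CN or min(cn1, cn2) < 0:
            raise ValueError(f"split ({cn1},{cn2}) outside haploid cn 0..{MAX_HAPLOID_CN}")
        per_marker = [_split_counts(g, cn1) for g in genotypes]
        for combo in itertools.product(*per_marker):
            h1 = Haplotype(cn1, tuple(c[0] for c in combo))
            h2 = Haplotype(cn2, tuple(c[1] for c in combo))
            phase = ParentPhase.from_pair(h1, h2)
            seen.setdefault(phase.key, phase)
    return [seen[k] for k in sorted(seen)]


def _classify_dup_extras(
    extras: Sequence[Counts], source: Haplotype, other: Haplotype
) -> Event:
    """Type a de novo gain from where its extra allele copies can come from.

    Intra-chromosomal if every extra allele is present on the source
    haplotype and at least one is absent from the other homolog;
    inter-chromosomal in the mirrored case; ambiguous otherwise (including
    when no marker distinguishes the homologs).
    """

    def present(hap: Haplotype, m: int, extra: Counts) -> bool:
        ha, hb = hap.counts[m]
        return (extra[0] == 0 or ha > 0) and (extra[1] == 0 or hb > 0)

    intra_all = all(present(source, m, e) for m, e in enumerate(extras))
    intra_diff = any(not present(other, m, e) for m, e in enumerate(extras))
    inter_all = all(present(other, m, e) for m, e in enumerate(extras))
    inter_diff = any(not present(source, m, e) for m, e in enumerate(extras))
    if intra_all and intra_diff:
        return Event.DENOVO_DUP_INTRA
    if inter_all and inter_diff:
        return Event.DENOVO_DUP_INTER
    return Event.DENOVO_DUP_AMBIG


def enumerate_gametes(
    phase: ParentPhase,
    allow_nonmendelian: bool,
    config: PhasingConfig = PhasingConfig(),
) -> list[GameteOption]:
    """All region-wide gametes one parent phase can form.

    Mendelian gametes are the two haplotypes unmodified.  With
    non-Mendelian events enabled, de novo deletions are every uniform-cn
    sub-haplotype of one source haplotype, and de novo duplications add one
    extra allele copy per marker (more with ``allow_multistep_dup``) drawn
    from the source haplotype's own alleles (intra-chromosomal) or from the
    other homolog's (inter-chromosomal); the gamete cn is capped at 3.
    UPD is handled at the gamete-pairing level, not here.
    """
    n_markers = len(phase.haps[0].counts)
    out: list[GameteOption] = []
    for i, hap in enumerate(phase.haps):
        out.append(GameteOption(hap, Event.MENDELIAN, i))
    if not allow_nonmendelian:
        return out
    for i, hap in enumerate(phase.haps):
        other = phase.haps[1 - i]
        # de novo deletions: any proper uniform-cn sub-haplotype
        for cn2 in range(hap.cn):
            per_marker = [
                [part[0] for part in _split_counts(g, cn2)] for g in hap.counts
            ]
            for combo in itertools.product(*per_marker):
                out.append(
                    GameteOption(Haplotype(cn2, combo), Event.DENOVO_DELETION, i)
                )
        # de novo duplications: source haplotype plus extra copies
        if hap.cn < 1:
            continue
        max_extra = MAX_HAPLOID_CN - hap.cn if config.allow_multistep_dup else 1
        for k in range(1, max_extra + 1):
            if hap.cn + k > MAX_HAPLOID_CN:
                break
            per_marker_extras = []
            for m in range(n_markers):
                allowed_a = hap.counts[m][0] > 0 or other.counts[m][0] > 0
                allowed_b = hap.counts[m][1] > 0 or other.counts[m][1] > 0
                options = [
                    (xa, k - xa)
                    for xa in range(k + 1)
                    if (xa == 0 or allowed_a) and (xa == k or allowed_b)
                ]
                per_marker_extras.append(options)
            for extras in itertools.product(*per_marker_extras):
                counts = tuple(
                    (hap.counts[m][0] + extras[m][0], hap.counts[m][1] + extras[m][1])
                    for m in range(n_markers)
                )
                kind = _classify_dup_extras(extras, hap, other)
                out.append(GameteOption(Haplotype(hap.cn + k, counts), kind, i))
    # deduplicate identical (gamete, event, source) entries
    seen = set()
    unique = []
    for opt in out:
        key = (opt.gamete.key, opt.event, opt.source)
        if key not in seen:
            seen.add(key)
            unique.append(opt)
    return unique


class _Budget:
    __slots__ = ("used", "cap")

    def __init__(self, cap: int) -> None:
        self.used = 0
        self.cap = cap

    def spend(self, n: int, context: str) -> None:
        self.used += n
        if self.used > self.cap:
            raise BudgetExceededError(
                f"search budget of {self.cap} combinations exceeded in {context}; "
                "consider subsampling markers or raising max_combinations"
            )


class _Candidate(NamedTuple):
    scheme: ChildScheme
    u: int  # unexplained (member, marker) cells
    e: int  # non-Mendelian events


def _child_candidates(
    child_counts: Sequence[Counts],
    child_cn: int,
    father_phase: ParentPhase,
    mother_phase: ParentPhase,
    father_gametes: Sequence[GameteOption],
    mother_gametes: Sequence[GameteOption],
    allow_nonmendelian: bool,
    config: PhasingConfig,
    budget: Optional[_Budget] = None,
    context: str = "region",
) -> list[_Candidate]:
    n_markers = len(child_counts)
    cands: list[_Candidate] = []
    by_cn_m: dict[int, list[GameteOption]] = {}
    for opt in mother_gametes:
        by_cn_m.setdefault(opt.gamete.cn, []).append(opt)
    for fopt in father_gametes:
        for mopt in by_cn_m.get(child_cn - fopt.gamete.cn, ()):
            if budget is not None:
                budget.spend(1, context)
            u = 0
            fc, mc = fopt.gamete.counts, mopt.gamete.counts
            for m in range(n_markers):
                if (
                    fc[m][0] + mc[m][0] != child_counts[m][0]
                    or fc[m][1] + mc[m][1] != child_counts[m][1]
                ):
                    u += 1
            e = (fopt.event is not Event.MENDELIAN) + (
                mopt.event is not Event.MENDELIAN
            )
            scheme = (
                GameteScheme("father", fopt.event, (fopt.source,), (fopt.gamete,)),
                GameteScheme("mother", mopt.event, (mopt.source,), (mopt.gamete,)),
            )
            cands.append(_Candidate(scheme, u, e))
    if allow_nonmendelian:
        for role, phase in (("father", father_phase), ("mother", mother_phase)):
            other_role = "mother" if role == "father" else "father"
            pairings: list[tuple[Event, tuple[int, ...], tuple[Haplotype, ...]]] = []
            for i, hap in enumerate(phase.haps):
                pairings.append((Event.UPD_ISO, (i, i), (hap, hap)))
            pairings.append((Event.UPD_HETERO, (0, 1), phase.haps))
            for event, sources, gametes in pairings:
                if sum(g.cn for g in gametes) != child_cn:
                    continue
                if budget is not None:
                    budget.spend(1, context)
                u = 0
                for m in range(n_markers):
                    a = sum(g.counts[m][0] for g in gametes)
                    b = sum(g.counts[m][1] for g in gametes)
                    if (a, b) != child_counts[m]:
                        u += 1
                disomic = GameteScheme(role, event, sources, gametes)
                null_side = GameteScheme(other_role, event, (), ())
                scheme = (
                    (disomic, null_side) if role == "father" else (null_side, disomic)
                )
                cands.append(_Candidate(scheme, u, config.count_upd_as))
    if not cands:
        # no copy-number-feasible pairing: the child is wholly unexplained
        cands.append(_Candidate(None, max(n_markers, 1), 0))
    return cands


def explain_child(
    child_counts: Sequence[Counts],
    child_cn: int,
    father_phase: ParentPhase,
    mother_phase: ParentPhase,
    allow_nonmendelian: bool = True,
    config: PhasingConfig = PhasingConfig(),
) -> list[tuple[ChildScheme, int]]:
    """Every gamete pairing explaining a child, with its unexplained count."""
    fg = enumerate_gametes(father_phase, allow_nonmendelian, config)
    mg = enumerate_gametes(mother_phase, allow_nonmendelian, config)
    cands = _child_candidates(
        child_counts, child_cn, father_phase, mother_phase, fg, mg,
        allow_nonmendelian, config,
    )
    return [(c.scheme, c.u) for c in cands]


# ---------------------------------------------------------------------------
# factorized region search
#
# A region-wide *configuration* fixes the haploid cn split of each parent
# and, per child, the gamete formation shape (event kind, source haplotype
# index and gamete cn per parent, or a UPD variant).  Given a
# configuration, markers decouple: at each marker the local assignment is
# an ordered partition of each parent's observed multiset plus per-child
# gamete contents consistent with the shapes, and the total number of
# unexplained cells is the sum over markers of the local minima.
# Configurations are scanned in ascending non-Mendelian event count, so
# the search stops at the first event level that admits a zero-unexplained
# solution -- Mendelian scenarios first, the simplest non-Mendelian ones
# only when Mendelian inheritance cannot explain the data.


class _SideShape(NamedTuple):
    kind: str  # 'mend' | 'del' | 'dup'
    source: int
    gamete_cn: int


class _ChildShape(NamedTuple):
    kind: str  # 'bi' | 'upd' | 'none'
    father: Optional[_SideShape]
    mother: Optional[_SideShape]
    upd_role: str  # '' | 'father' | 'mother'
    upd_event: Optional[Event]
    upd_sources: tuple[int, ...]
    events: int


def _side_shapes(split: tuple[int, int], allow_nm: bool,
                 config: PhasingConfig) -> list[_SideShape]:
    shapes = [_SideShape("mend", i, split[i]) for i in range(2)]
    if allow_nm:
        for i in range(2):
            for g in range(split[i]):
                shapes.append(_SideShape("del", i, g))
            if split[i] >= 1:
                max_extra = (
                    MAX_HAPLOID_CN - split[i] if config.allow_multistep_dup else 1
                )
                for k in range(1, max_extra + 1):
                    if split[i] + k <= MAX_HAPLOID_CN:
                        shapes.append(_SideShape("dup", i, split[i] + k))
    return shapes


def _child_shapes(split_f, split_m, child_cn, allow_nm, config) -> list[_ChildShape]:
    out = []
    for fs in _side_shapes(split_f, allow_nm, config):
        for ms in _side_shapes(split_m, allow_nm, config):
            if fs.gamete_cn + ms.gamete_cn != child_cn:
                continue
            e = (fs.kind != "mend") + (ms.kind != "mend")
            out.append(_ChildShape("bi", fs, ms, "", None, (), e))
    if allow_nm:
        for role, split in (("father", split_f), ("mother", split_m)):
            for i in range(2):
                if 2 * split[i] == child_cn:
                    out.append(
                        _ChildShape("upd", None, None, role, Event.UPD_ISO,
                                    (i, i), config.count_upd_as)
                    )
            if split[0] + split[1] == child_cn:
                out.append(
                    _ChildShape("upd", None, None, role, Event.UPD_HETERO,
                                (0, 1), config.count_upd_as)
                )
    if not out:
        out.append(_ChildShape("none", None, None, "", None, (), 0))
    return out


def _sub_multisets(counts: Counts, size: int) -> list[Counts]:
    a, b = counts
    return [
        (a1, size - a1)
        for a1 in range(min(a, size) + 1)
        if 0 <= size - a1 <= b
    ]


def _side_contents(shape: _SideShape, comps: tuple[Counts, Counts]) -> list[Counts]:
    """Possible gamete contents of one side at one marker, given the
    parent's ordered partition components there."""
    src = comps[shape.source]
    if shape.kind == "mend":
        return [src]
    if shape.kind == "del":
        return _sub_multisets(src, shape.gamete_cn)
    # dup: extra copies drawn from alleles present on either homolog there
    other = comps[1 - shape.source]
    k = shape.gamete_cn - (src[0] + src[1])
    allowed_a = src[0] > 0 or other[0] > 0
    allowed_b = src[1] > 0 or other[1] > 0
    out = []
    for xa in range(k + 1):
        if (xa > 0 and not allowed_a) or (k - xa > 0 and not allowed_b):
            continue
        out.append((src[0] + xa, src[1] + k - xa))
    return out


def _canonical_side_content(shape: _SideShape, comps) -> Counts:
    """Deterministic content pick for unexplained cells (A-first)."""
    return _side_contents(shape, comps)[-1] if shape.kind != "mend" else comps[shape.source]


def _upd_content(shape: _ChildShape, comps: tuple[Counts, Counts]) -> Counts:
    i, j = shape.upd_sources
    return (comps[i][0] + comps[j][0], comps[i][1] + comps[j][1])


def _explained_at(
    shape: _ChildShape,
    child: Counts,
    fcomps: tuple[Counts, Counts],
    mcomps: tuple[Counts, Counts],
) -> bool:
    if shape.kind == "none":
        return False
    if shape.kind == "upd":
        comps = fcomps if shape.upd_role == "father" else mcomps
        return _upd_content(shape, comps) == child
    for fc in _side_contents(shape.father, fcomps):
        need = (child[0] - fc[0], child[1] - fc[1])
        if need[0] < 0 or need[1] < 0:
            continue
        for mc in _side_contents(shape.mother, mcomps):
            if mc == need:
                return True
    return False


class _Block(NamedTuple):
    split_f: tuple[int, int]
    split_m: tuple[int, int]
    pf_parts: list[list[tuple[Counts, Counts]]]  # per marker, ordered partitions
    pm_parts: list[list[tuple[Counts, Counts]]]
    shapes: list[list[_ChildShape]]  # per child


def _score_config(
    block: _Block,
    combo: tuple[_ChildShape, ...],
    children: list,
    expl_cache: dict,
    budget: _Budget,
    region_id: str,
    abort_above: Optional[int],
) -> Optional[int]:
    """Total unexplained cells for one configuration (None when aborted)."""
    n_markers = len(block.pf_parts)
    u = 0
    for cid_idx, shape in enumerate(combo):
        if shape.kind == "none":
            u += max(n_markers, 1)
    if abort_above is not None and u > abort_above:
        return None
    for m in range(n_markers):
        pairs = len(block.pf_parts[m]) * len(block.pm_parts[m])
        budget.spend(pairs, region_id)
        best_local = None
        for pi in range(pairs):
            miss = 0
            for ci, shape in enumerate(combo):
                if shape.kind == "none":
                    continue
                if not expl_cache[(id(block), ci, shape)][m][pi]:
                    miss += 1
            if best_local is None or miss < best_local:
                best_local = miss
                if miss == 0:
                    break
        u += best_local or 0
        if abort_above is not None and u > abort_above:
            return None
    return u


def _explained_vectors(block: _Block, ci: int, shape: _ChildShape,
                       child_counts) -> list[list[bool]]:
    out = []
    for m, child in enumerate(child_counts):
        row = []
        for fcomps in block.pf_parts[m]:
            for mcomps in block.pm_parts[m]:
                row.append(_explained_at(shape, child, fcomps, mcomps))
        out.append(row)
    return out


def _materialize(
    block: _Block,
    combo: tuple[_ChildShape, ...],
    children: list,
    target_u: int,
    total_e: int,
    expl_cache: dict,
    budget: _Budget,
    region_id: str,
) -> list[FamilySolution]:
    """All solutions of one co-optimal configuration.

    Per marker the locally optimal (partition pair, per-child contents)
    assignments are enumerated; the solution set is their cartesian
    product.  At unexplained cells gamete contents are fixed to a
    deterministic canonical pick rather than enumerated."""
    n_markers = len(block.pf_parts)
    per_marker_choices: list[list[tuple]] = []
    for m in range(n_markers):
        pairs = [
            (fi, mi)
            for fi in range(len(block.pf_parts[m]))
            for mi in range(len(block.pm_parts[m]))
        ]
        miss_by_pair = []
        for pi, (fi, mi) in enumerate(pairs):
            miss = sum(
                1
                for ci, shape in enumerate(combo)
                if shape.kind != "none"
                and not expl_cache[(id(block), ci, shape)][m][pi]
            )
            miss_by_pair.append(miss)
        local_min = min(miss_by_pair)
        choices = []
        for pi, (fi, mi) in enumerate(pairs):
            if miss_by_pair[pi] != local_min:
                continue
            fcomps = block.pf_parts[m][fi]
            mcomps = block.pm_parts[m][mi]
            per_child_opts = []
            for ci, shape in enumerate(combo):
                child = children[ci][1][m]
                opts = _content_options(shape, child, fcomps, mcomps)
                per_child_opts.append(opts)
            n = 1
            for opts in per_child_opts:
                n *= len(opts)
            budget.spend(n, region_id)
            for contents in itertools.product(*per_child_opts):
                choices.append((fcomps, mcomps, contents))
        per_marker_choices.append(choices)
    n_total = 1
    for choices in per_marker_choices:
        n_total *= len(choices)
    budget.spend(n_total, region_id)
    solutions = []
    for assignment in itertools.product(*per_marker_choices):
        solutions.append(
            _assemble_solution(block, combo, children, assignment,
                               target_u, total_e)
        )
    return solutions


def _content_options(shape, child, fcomps, mcomps):
    """(father content, mother content) realizations at one marker; a
    single canonical pick when the cell is unexplained."""
    if shape.kind == "none":
        return [((0, 0), (0, 0))]
    if shape.kind == "upd":
        comps = fcomps if shape.upd_role == "father" else mcomps
        i, j = shape.upd_sources
        return [(comps[i], comps[j])]
    opts = []
    for fc in _side_contents(shape.father, fcomps):
        need = (child[0] - fc[0], child[1] - fc[1])
        if need[0] < 0 or need[1] < 0:
            continue
        for mc in _side_contents(shape.mother, mcomps):
            if mc == need:
                opts.append((fc, mc))
    if not opts:  # unexplained cell: canonical contents
        opts = [
            (
                _canonical_side_content(shape.father, fcomps),
                _canonical_side_content(shape.mother, mcomps),
            )
        ]
    return opts


def _assemble_solution(block, combo, children, assignment, target_u, total_e):
    fh1 = Haplotype(block.split_f[0], tuple(a[0][0] for a in assignment))
    fh2 = Haplotype(block.split_f[1], tuple(a[0][1] for a in assignment))
    mh1 = Haplotype(block.split_m[0], tuple(a[1][0] for a in assignment))
    mh2 = Haplotype(block.split_m[1], tuple(a[1][1] for a in assignment))
    fphase = ParentPhase((fh1, fh2))
    mphase = ParentPhase((mh1, mh2))
    schemes = []
    for ci, (cid, _, _) in enumerate(children):
        shape = combo[ci]
        if shape.kind == "none":
            schemes.append((cid, None))
            continue
        if shape.kind == "upd":
            phase = fphase if shape.upd_role == "father" else mphase
            i, j = shape.upd_sources
            disomic = GameteScheme(
                shape.upd_role, shape.upd_event, shape.upd_sources,
                (phase.haps[i], phase.haps[j]),
            )
            other_role = "mother" if shape.upd_role == "father" else "father"
            null_side = GameteScheme(other_role, shape.upd_event, (), ())
            pair = (disomic, null_side) if shape.upd_role == "father" else (null_side, disomic)
            schemes.append((cid, pair))
            continue
        sides = []
        for role, side_shape, phase in (
            ("father", shape.father, fphase),
            ("mother", shape.mother, mphase),
        ):
            content_idx = 0 if role == "father" else 1
            gamete = Haplotype(
                side_shape.gamete_cn,
                tuple(a[2][ci][content_idx] for a in assignment),
            )
            if side_shape.kind == "mend":
                event = Event.MENDELIAN
            elif side_shape.kind == "del":
                event = Event.DENOVO_DELETION
            else:
                src = phase.haps[side_shape.source]
                other = phase.haps[1 - side_shape.source]
                extras = tuple(
                    (g[0] - s[0], g[1] - s[1])
                    for g, s in zip(gamete.counts, src.counts)
                )
                event = _classify_dup_extras(extras, src, other)
            sides.append(
                GameteScheme(role, event, (side_shape.source,), (gamete,))
            )
        schemes.append((cid, (sides[0], sides[1])))
    return FamilySolution(fphase, mphase, tuple(schemes), target_u, total_e)


def _search(
    region: CnvRegion,
    family: Family,
    config: PhasingConfig,
    allow_nonmendelian: bool,
    budget: _Budget,
) -> tuple[tuple[int, int], list[FamilySolution]]:
    father_cn = region.member_cn[family.father_id]
    mother_cn = region.member_cn[family.mother_id]
    father_gts = region.genotypes[family.father_id]
    mother_gts = region.genotypes[family.mother_id]
    children = [
        (cid, region.genotypes[cid], region.member_cn[cid])
        for cid in family.child_ids
    ]
    blocks: list[_Block] = []
    for sf in config.splits_for(father_cn):
        if max(sf) > MAX_HAPLOID_CN or min(sf) < 0 or sum(sf) != father_cn:
            raise ValueError(f"invalid split {sf} for CN {father_cn}")
        for sm in config.splits_for(mother_cn):
            if max(sm) > MAX_HAPLOID_CN or min(sm) < 0 or sum(sm) != mother_cn:
                raise ValueError(f"invalid split {sm} for CN {mother_cn}")
            pf_parts = [_split_counts(g, sf[0]) for g in father_gts]
            pm_parts = [_split_counts(g, sm[0]) for g in mother_gts]
            shapes = [
                _child_shapes(sf, sm, cn, allow_nonmendelian, config)
                for _, _, cn in children
            ]
            blocks.append(_Block(sf, sm, pf_parts, pm_parts, shapes))

    # explained-vectors cache per (block, child, shape)
    expl_cache: dict = {}
    configs_by_e: dict[int, list[tuple[_Block, tuple[_ChildShape, ...]]]] = {}
    for block in blocks:
        for ci, shapes in enumerate(block.shapes):
            for shape in shapes:
                expl_cache[(id(block), ci, shape)] = _explained_vectors(
                    block, ci, shape, children[ci][1]
                )
        for combo in itertools.product(*block.shapes):
            e = sum(s.events for s in combo)
            configs_by_e.setdefault(e, []).append((block, combo))

    best: Optional[tuple[int, int]] = None
    winners: list[tuple[_Block, tuple[_ChildShape, ...], int]] = []
    for e in sorted(configs_by_e):
        if best is not None and best[0] == 0 and e > best[1]:
            break  # no higher event level can beat a zero-unexplained score
        for block, combo in configs_by_e[e]:
            abort = None if best is None else best[0]
            u = _score_config(
                block, combo, children, expl_cache, budget, region.region_id, abort
            )
            if u is None:
                continue
            score = (u, e)
            if best is None or score < best:
                best = score
                winners = [(block, combo, e)]
            elif score == best:
                winners.append((block, combo, e))
    assert best is not None
    solutions: list[FamilySolution] = []
    for block, combo, e in winners:
        solutions.extend(
            _materialize(
                block, combo, children, best[0], e, expl_cache, budget,
                region.region_id,
            )
        )
    return best, solutions


def phase_region(
    region: CnvRegion,
    family: Family,
    config: PhasingConfig = PhasingConfig(),
) -> PhasingResult:
    """Phase one family-converged CNV region.

    Returns every co-optimal :class:`FamilySolution` under the lexicographic
    score ``(n_unexplained, n_nonmendelian)``, with all children considered
    jointly, equivalence-collapsed and deterministically ordered.
    Mendelian-only scenarios are searched first; non-Mendelian events are
    admitted only when needed, in ascending event count.
    """
    region.validate()
    budget = _Budget(config.max_combinations)
    score, solutions = _search(region, family, config, False, budget)
    if score[0] > 0 and config.allow_nonmendelian:
        budget = _Budget(config.max_combinations)
        score, solutions = _search(region, family, config, True, budget)
    collapsed = collapse_equivalent_solutions(solutions)
    return PhasingResult(region.region_id, tuple(collapsed), score)


@dataclass(frozen=True)
class DeNovoAnnotation:
    """Classification of one de novo scheme within one family solution."""

    event: Event
    parent: str
    parent_of_origin_determined: bool
    dup_class: Optional[Event] = None  # INTRA / INTER / AMBIG for gains


def classify_de_novo(solution: FamilySolution, scheme: GameteScheme) -> DeNovoAnnotation:
    """Annotate a de novo scheme with parent-of-origin and gain typing.

    The parent of origin is reported as determined only when the two
    parents' phases are distinguishable (differ at >=1 marker or in their
    haploid copy-number split); with indistinguishable parental haplotypes
    the mirrored solution is equally optimal and the origin is undetermined.
    Gains are re-typed from the gamete content: intra-chromosomal when every
    extra allele copy matches the source haplotype and differs from the
    other homolog somewhere, inter-chromosomal in the mirrored case,
    ambiguous otherwise.
    """
    from .model import DE_NOVO_EVENTS, DE_NOVO_DUP_EVENTS

    if scheme.event not in DE_NOVO_EVENTS:
        raise ValueError(f"not a de novo scheme: {scheme.event}")
    determined = solution.father_phase.key != solution.mother_phase.key
    dup_class = None
    if scheme.event in DE_NOVO_DUP_EVENTS:
        parent_phase = (
            solution.father_phase if scheme.parent == "father" else solution.mother_phase
        )
        src = parent_phase.haps[scheme.sources[0]]
        other = parent_phase.haps[1 - scheme.sources[0]]
        gamete = scheme.gametes[0]
        extras = tuple(
            (g[0] - s[0], g[1] - s[1]) for g, s in zip(gamete.counts, src.counts)
        )
        dup_class = _classify_dup_extras(extras, src, other)
    return DeNovoAnnotation(scheme.event, scheme.parent, determined, dup_class)


# re-exported here because the oracle validates this module's search
from .bruteforce import brute_force_oracle, OracleCapExceeded  # noqa: E402,F401
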