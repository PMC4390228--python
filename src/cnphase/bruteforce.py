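"""Exhaustive reference search used to validate the phasing engine.

This module deliberately avoids the engine's search machinery: genotypes
are handled as explicit allele tuples, partitions are enumerated by index
combinations, and the lexicographic minimum is taken over *complete*
family assignments (full cartesian product over children) instead of the
engine's per-child decomposition.  It is only suitable for small regions
and refuses instances whose enumeration space exceeds a hard cap.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Optional, Sequence

from .model import (
    MAX_HAPLOID_CN,
    CnvRegion,
    Counts,
    Event,
    Family,
    FamilySolution,
    GameteScheme,
    Haplotype,
    ParentPhase,
    PhasingResult,
    collapse_equivalent_solutions,
)

DEFAULT_ORACLE_CAP = 2_000_000


class OracleCapExceeded(RuntimeError):
    """The instance is too large for exhaustive reference enumeration."""


def _to_tuples(counts_seq: Sequence[Counts]) -> list[tuple[str, ...]]:
    return [("A",) * a + ("B",) * b for a, b in counts_seq]


def _tuple_to_counts(t: tuple[str, ...]) -> Counts:
    return (t.count("A"), t.count("B"))


def _splits_of_tuple(alleles: tuple[str, ...], size1: int) -> list[tuple[tuple, tuple]]:
    """Distinct ways to split an allele tuple into sub-tuples of given sizes."""
    seen = set()
    out = []
    idx = range(len(alleles))
    for pick in itertools.combinations(idx, size1):
        first = tuple(sorted(alleles[i] for i in pick))
        rest = tuple(sorted(alleles[i] for i in idx if i not in pick))
        if (first, rest) not in seen:
            seen.add((first, rest))
            out.append((first, rest))
    return out


def _enumerate_phases_bf(
    genotypes: list[tuple[str, ...]], splits: Sequence[tuple[int, int]]
) -> list[tuple[tuple[tuple, ...], tuple[tuple, ...], int, int]]:
    """All unordered haplotype pairs as (hap1 markers, hap2 markers, cn1, cn2)."""
    seen = set()
    phases = []
    for cn1, cn2 in splits:
        per_marker = [_splits_of_tuple(g, cn1) for g in genotypes]
        for combo in itertools.product(*per_marker):
            h1 = tuple(c[0] for c in combo)
            h2 = tuple(c[1] for c in combo)
            pair = tuple(sorted([(cn1, h1), (cn2, h2)]))
            if pair not in seen:
                seen.add(pair)
                phases.append((pair[0][1], pair[1][1], pair[0][0], pair[1][0]))
    return phases


def _gametes_bf(
    phase: tuple[tuple[tuple, ...], tuple[tuple, ...], int, int],
    allow_nonmendelian: bool,
    multistep: bool,
) -> list[tuple[tuple[tuple, ...], int, Event, int]]:
    """All gametes as (marker tuples, cn, event, source index)."""
    h1, h2, cn1, cn2 = phase
    haps = [(h1, cn1), (h2, cn2)]
    out = []
    seen = set()

    def add(markers, cn, event, src):
        key = (markers, cn, event, src)
        if key not in seen:
            seen.add(key)
            out.append((markers, cn, event, src))

    for i, (h, cn) in enumerate(haps):
        add(h, cn, Event.MENDELIAN, i)
    if not allow_nonmendelian:
        return out
    n_markers = len(h1)
    for i, (h, cn) in enumerate(haps):
        other, other_cn = haps[1 - i]
        for cn_new in range(cn):
            per_marker = [
                sorted({s[0] for s in _splits_of_tuple(m, cn_new)}) for m in h
            ]
            for combo in itertools.product(*per_marker):
                add(tuple(combo), cn_new, Event.DENOVO_DELETION, i)
        if cn < 1:
            continue
        max_extra = (MAX_HAPLOID_CN - cn) if multistep else min(1, MAX_HAPLOID_CN - cn)
        for k in range(1, max_extra + 1):
            per_marker_extra = []
            for m in range(n_markers):
                allowed = sorted(set(h[m]) | set(other[m]))
                per_marker_extra.append(
                    sorted({tuple(sorted(c)) for c in itertools.combinations_with_replacement(allowed, k)})
                )
            for extras in itertools.product(*per_marker_extra):
                markers = tuple(
                    tuple(sorted(h[m] + extras[m])) for m in range(n_markers)
                )
                kind = _classify_bf(extras, h, other)
                add(markers, cn + k, kind, i)
    return out


def _classify_bf(extras, source, other) -> Event:
    def covered(hap, m, extra):
        return all(x in hap[m] for x in set(extra))

    intra_all = all(covered(source, m, e) for m, e in enumerate(extras))
    intra_diff = any(not covered(other, m, e) for m, e in enumerate(extras))
    inter_all = all(covered(other, m, e) for m, e in enumerate(extras))
    inter_diff = any(not covered(source, m, e) for m, e in enumerate(extras))
    if intra_all and intra_diff:
        return Event.DENOVO_DUP_INTRA
    if inter_all and inter_diff:
        return Event.DENOVO_DUP_INTER
    return Event.DENOVO_DUP_AMBIG


def _hap_obj(markers: tuple[tuple, ...], cn: int) -> Haplotype:
    return Haplotype(cn, tuple(_tuple_to_counts(m) for m in markers))


def brute_force_oracle(
    region: CnvRegion,
    family: Family,
    config=None,
    cap: int = DEFAULT_ORACLE_CAP,
) -> PhasingResult:
    """Exhaustively score every phase pair x complete per-child assignment.

    Returns the full co-optimal solution set under the lexicographic
    ``(n_unexplained, n_nonmendelian)`` score, in the same canonical form
    as :func:`cnphase.phase_engine.phase_region`.  Raises
    :class:`OracleCapExceeded` on instances beyond ``cap`` scored
    combinations.
    """
    from .phase_engine import PhasingConfig

    if config is None:
        config = PhasingConfig()
    region.validate()
    father_gts = _to_tuples(region.genotypes[family.father_id])
    mother_gts = _to_tuples(region.genotypes[family.mother_id])
    f_phases = _enumerate_phases_bf(
        father_gts, config.splits_for(region.member_cn[family.father_id])
    )
    m_phases = _enumerate_phases_bf(
        mother_gts, config.splits_for(region.member_cn[family.mother_id])
    )
    children = [
        (cid, _to_tuples(region.genotypes[cid]), region.member_cn[cid])
        for cid in family.child_ids
    ]
    n_markers = region.n_markers
    allow_nm = config.allow_nonmendelian
    spent = 0
    best_score: Optional[tuple[int, int]] = None
    best_solutions: list[FamilySolution] = []

    for pf in f_phases:
        fg = _gametes_bf(pf, allow_nm, config.allow_multistep_dup)
        f_phase_obj = ParentPhase((_hap_obj(pf[0], pf[2]), _hap_obj(pf[1], pf[3])))
        for pm in m_phases:
            mg = _gametes_bf(pm, allow_nm, config.allow_multistep_dup)
            m_phase_obj = ParentPhase((_hap_obj(pm[0], pm[2]), _hap_obj(pm[1], pm[3])))
            per_child: list[list[tuple]] = []
            for cid, c_gts, c_cn in children:
                child_counters = [Counter(g) for g in c_gts]
                cands = []
                for fmarkers, fcn, fev, fsrc in fg:
                    for mmarkers, mcn, mev, msrc in mg:
                        if fcn + mcn != c_cn:
                            continue
                        spent += 1
                        u = sum(
                            1
                            for m in range(n_markers)
                            if Counter(fmarkers[m]) + Counter(mmarkers[m])
                            != child_counters[m]
                        )
                        e = (fev is not Event.MENDELIAN) + (mev is not Event.MENDELIAN)
                        scheme = (
                            GameteScheme("father", fev, (fsrc,), (_hap_obj(fmarkers, fcn),)),
                            GameteScheme("mother", mev, (msrc,), (_hap_obj(mmarkers, mcn),)),
                        )
                        cands.append((scheme, u, e))
                if allow_nm:
                    for role, phase in (("father", pf), ("mother", pm)):
                        haps = [(phase[0], phase[2]), (phase[1], phase[3])]
                        upd_opts = [
                            (Event.UPD_ISO, (0, 0), (haps[0], haps[0])),
                            (Event.UPD_ISO, (1, 1), (haps[1], haps[1])),
                            (Event.UPD_HETERO, (0, 1), (haps[0], haps[1])),
                        ]
                        for ev, sources, pair in upd_opts:
                            if pair[0][1] + pair[1][1] != c_cn:
                                continue
                            spent += 1
                            u = sum(
                                1
                                for m in range(n_markers)
                                if Counter(pair[0][0][m]) + Counter(pair[1][0][m])
                                != child_counters[m]
                            )
                            disomic = GameteScheme(
                                role, ev, sources,
                                (_hap_obj(*pair[0]), _hap_obj(*pair[1])),
                            )
                            null_side = GameteScheme(
                                "mother" if role == "father" else "father", ev, (), ()
                            )
                            scheme = (
                                (disomic, null_side)
                                if role == "father"
                                else (null_side, disomic)
                            )
                            cands.append((scheme, u, config.count_upd_as))
                if not cands:
                    cands.append((None, max(n_markers, 1), 0))
                per_child.append(cands)
                if spent > cap:
                    raise OracleCapExceeded(f"oracle cap {cap} exceeded")
            n_combos = 1
            for cands in per_child:
                n_combos *= len(cands)
            spent += n_combos
            if spent > cap:
                raise OracleCapExceeded(f"oracle cap {cap} exceeded")
            for assignment in itertools.product(*per_child):
                total_u = sum(c[1] for c in assignment)
                total_e = sum(c[2] for c in assignment)
                score = (total_u, total_e)
                if best_score is None or score < best_score:
                    best_score = score
                    best_solutions = []
                if score == best_score:
                    schemes = tuple(
                        (cid, cand[0])
                        for (cid, _, _), cand in zip(children, assignment)
                    )
                    best_solutions.append(
                        FamilySolution(
                            f_phase_obj, m_phase_obj, schemes, score[0], score[1]
                        )
                    )
    assert best_score is not None
    collapsed = collapse_equivalent_solutions(best_solutions)
    return PhasingResult(region.region_id, tuple(collapsed), best_score)
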