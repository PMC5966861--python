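"""Fuzzy equivalence and one-to-one matching of SV call sets.

Two deletion calls are the same event when they have at least 50%
reciprocal overlap; two insertion calls are the same when their breakpoints
lie within ``ins_delta`` bp (default 500).  A matching between two call
sets is resolved one-to-one: all candidate pairs satisfying the equivalence
rule are ranked by quality (higher reciprocal overlap first for span
events, smaller breakpoint distance first for insertions) and accepted
greedily, so no call participates in more than one pair.  Merging a matched
pair averages start and end positions.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace
from typing import Dict, List, Tuple

from intervaltree import IntervalTree

from .errors import ContractError
from .model import DEL, INS, CallSet, MatchConfig, SVCall


def interval_reciprocal_overlap(s1: int, e1: int, s2: int, e2: int) -> float:
    """Reciprocal overlap of two 1-based inclusive intervals on one chromosome.

    Returns ``min(ov / len1, ov / len2)`` with
    ``ov = max(0, min(e1, e2) - max(s1, s2) + 1)``; 0 when disjoint.
    """
    ov = min(e1, e2) - max(s1, s2) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (e1 - s1 + 1), ov / (e2 - s2 + 1))


def reciprocal_overlap(a: SVCall, b: SVCall) -> float:
    """Reciprocal overlap of two calls; 0 on different chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    return interval_reciprocal_overlap(a.start, a.end, b.start, b.end)


def _is_breakpoint_pair(a: SVCall, b: SVCall) -> bool:
    # insertion-style comparison whenever an insertion is involved
    return a.svtype == INS or b.svtype == INS


def calls_match(a: SVCall, b: SVCall, cfg: MatchConfig = MatchConfig()) -> bool:
    """Decide whether two calls represent the same SV under ``cfg``.

    Span events of equal type (DEL vs DEL, INV vs INV, ...) use the
    reciprocal-overlap rule; insertion pairs use breakpoint distance.  With
    ``require_same_type`` disabled, a mixed pair involving an insertion is
    compared by breakpoint distance.
    """
    if a.chrom != b.chrom:
        return False
    if cfg.require_same_type and a.svtype != b.svtype:
        return False
    if _is_breakpoint_pair(a, b):
        return abs(a.start - b.start) <= cfg.ins_delta
    ro = interval_reciprocal_overlap(a.start, a.end, b.start, b.end)
    if cfg.strict_overlap:
        return ro > cfg.min_reciprocal_overlap
    return ro >= cfg.min_reciprocal_overlap


def match_score(a: SVCall, b: SVCall) -> float:
    """Quality of a matched pair: reciprocal-overlap fraction for span
    events (higher is better), breakpoint distance in bp for insertion
    pairs (lower is better)."""
    if _is_breakpoint_pair(a, b):
        return float(abs(a.start - b.start))
    return interval_reciprocal_overlap(a.start, a.end, b.start, b.end)


@dataclass(frozen=True)
class MatchResult:
    """One-to-one matching between call sets A and B.

    ``pairs`` holds (call_a, call_b, score) triples; every call of A appears
    in exactly one of ``pairs`` / ``unmatched_a``, likewise for B.
    """

    pairs: Tuple[Tuple[SVCall, SVCall, float], ...]
    unmatched_a: Tuple[SVCall, ...]
    unmatched_b: Tuple[SVCall, ...]


class CallIndex:
    """Spatial index over one call set for fast candidate lookup."""

    def __init__(self, cs: CallSet, cfg: MatchConfig):
        self.cfg = cfg
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        self._ins: Dict[str, Tuple[List[int], List[SVCall]]] = {}
        for c in cs.calls:
            if c.svtype == INS:
                starts, calls = self._ins.setdefault(c.chrom, ([], []))
                starts.append(c.start)
                calls.append(c)
            else:
                tree = self._trees.setdefault((c.chrom, c.svtype), IntervalTree())
                tree.addi(c.start, c.end + 1, c)
        # CallSet order is canonical, so the bisect lists arrive sorted

    def candidates(self, a: SVCall):
        """Yield calls of the indexed set that match ``a`` under the config."""
        cfg = self.cfg
        if a.svtype == INS:
            entry = self._ins.get(a.chrom)
            if entry is None:
                return
            starts, calls = entry
            lo = bisect_left(starts, a.start - cfg.ins_delta)
            hi = bisect_right(starts, a.start + cfg.ins_delta)
            yield from calls[lo:hi]
        else:
            tree = self._trees.get((a.chrom, a.svtype))
            if tree is None:
                return
            for iv in tree.overlap(a.start, a.end + 1):
                if calls_match(a, iv.data, cfg):
                    yield iv.data

    def has_match(self, a: SVCall) -> bool:
        return next(iter(self.candidates(a)), None) is not None


def _candidate_pairs(A: CallSet, B: CallSet, cfg: MatchConfig):
    if cfg.require_same_type:
        index = CallIndex(B, cfg)
        for a in A.calls:
            for b in index.candidates(a):
                yield a, b
    else:
        # mixed-type matching is rare; fall back to full enumeration
        for a in A.calls:
            for b in B.calls:
                if calls_match(a, b, cfg):
                    yield a, b


def match_callsets(A: CallSet, B: CallSet, cfg: MatchConfig = MatchConfig()) -> MatchResult:
    """Compute the greedy one-to-one matching between two call sets.

    Candidates are ranked best-first — descending reciprocal overlap for
    span events, ascending breakpoint distance for insertions — with ties
    broken deterministically by (chrom, start of A, start of B, id of A,
    id of B), then accepted greedily skipping already-matched members.
    """
    ranked = []
    for a, b in _candidate_pairs(A, B, cfg):
        score = match_score(a, b)
        quality = score if _is_breakpoint_pair(a, b) else -score
        ranked.append(((quality, a.chrom, a.start, b.start, a.id, b.id), a, b, score))
    ranked.sort(key=lambda t: t[0])

    used_a, used_b = set(), set()
    pairs = []
    for _, a, b, score in ranked:
        if a.id in used_a or b.id in used_b:
            continue
        used_a.add(a.id)
        used_b.add(b.id)
        pairs.append((a, b, score))
    unmatched_a = tuple(c for c in A.calls if c.id not in used_a)
    unmatched_b = tuple(c for c in B.calls if c.id not in used_b)
    return MatchResult(tuple(pairs), unmatched_a, unmatched_b)


def merge_pair(a: SVCall, b: SVCall) -> SVCall:
    """Merge two equivalent calls into one, averaging start and end.

    Coordinates are floor-averaged to stay integral.  A merged deletion's
    length is recomputed from the averaged coordinates; a merged insertion
    takes the floor mean of the two inserted lengths.  Support is the max of
    the two (the callers saw the same reads), sources are unioned.
    """
    if a.chrom != b.chrom:
        raise ContractError(f"cannot merge calls on different chromosomes ({a.chrom}, {b.chrom})")
    if a.svtype != b.svtype:
        raise ContractError(f"cannot merge calls of different types ({a.svtype}, {b.svtype})")
    start = (a.start + b.start) // 2
    if a.svtype == INS:
        end = start
        length = (a.length + b.length) // 2
    else:
        end = (a.end + b.end) // 2
        length = end - start + 1
    return SVCall(
        id=a.id,
        chrom=a.chrom,
        start=start,
        end=end,
        svtype=a.svtype,
        length=length,
        support=max(a.support, b.support),
        sources=a.sources | b.sources,
        sample=a.sample,
    )


def _unique_ids(calls):
    seen = set()
    out = []
    for c in calls:
        cid = c.id
        k = 1
        while cid in seen:
            cid = f"{c.id}.{k}"
            k += 1
        if cid != c.id:
            c = replace(c, id=cid)
        seen.add(cid)
        out.append(c)
    return out


def union_callsets(A: CallSet, B: CallSet, cfg: MatchConfig = MatchConfig(),
                   caller: str | None = None) -> CallSet:
    """Sensitive combination: merged calls for every matched pair plus all
    unmatched calls from both sides.  ``|result| = |A| + |B| - #pairs``."""
    res = match_callsets(A, B, cfg)
    merged = [merge_pair(a, b) for a, b, _ in res.pairs]
    calls = _unique_ids(merged + list(res.unmatched_a) + list(res.unmatched_b))
    return CallSet(
        sample=A.sample,
        caller=caller if caller is not None else f"union({A.caller},{B.caller})",
        calls=tuple(calls),
    )


def intersect_callsets(A: CallSet, B: CallSet, cfg: MatchConfig = MatchConfig(),
                       caller: str | None = None) -> CallSet:
    """Stringent combination: exactly the merged calls of matched pairs."""
    res = match_callsets(A, B, cfg)
    calls = _unique_ids(merge_pair(a, b) for a, b, _ in res.pairs)
    return CallSet(
        sample=A.sample,
        caller=caller if caller is not None else f"intersect({A.caller},{B.caller})",
        calls=tuple(calls),
    )
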