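"""Independent brute-force matching oracle.

Re-implements the pair equivalence predicate and the greedy one-to-one
resolution by full candidate enumeration, sharing no code with the package's
indexed implementation.  Used only to cross-check ``match_callsets``.
"""


def _ro(s1, e1, s2, e2):
    ov = min(e1, e2) - max(s1, s2) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (e1 - s1 + 1), ov / (e2 - s2 + 1))


def _same_event(a, b, min_ro, delta):
    if a.chrom != b.chrom or a.svtype != b.svtype:
        return False
    if a.svtype == "INS":
        return abs(a.start - b.start) <= delta
    return _ro(a.start, a.end, b.start, b.end) >= min_ro


def brute_force_pair_ids(A, B, min_ro=0.5, delta=500):
    """All-pairs enumeration + greedy best-first acceptance; returns the set
    of matched (id_a, id_b) tuples."""
    cands = []
    for a in A.calls:
        for b in B.calls:
            if _same_event(a, b, min_ro, delta):
                if a.svtype == "INS":
                    quality = abs(a.start - b.start)
                else:
                    quality = -_ro(a.start, a.end, b.start, b.end)
                cands.append((quality, a.chrom, a.start, b.start, a.id, b.id))
    cands.sort()
    used_a, used_b, pairs = set(), set(), set()
    for _, _, _, _, ia, ib in cands:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.add((ia, ib))
    return pairs
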