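"""Ensemble integration of SV call sets into sensitive and stringent sets.

The three-caller workflow combines a Sniffles call set (SNIF) with the two
complementary PBHoney call sets (SPOT, TAIL):

* sensitive set  = SNIF ∪ (SPOT ∪ TAIL)   — maximizes recall
* stringent set  = SNIF ∩ (SPOT ∪ TAIL)   — maximizes precision

where ∪ / ∩ are the fuzzy union / intersection of :mod:`svmeta.matching`.
Because fuzzy union is not exactly associative, the association order above
is fixed; the generalized k-of-n operator below extends the idea to
arbitrary caller ensembles.
"""

from __future__ import annotations

from functools import reduce
from typing import List, Sequence, Tuple

from .errors import ValidationError
from .matching import CallIndex, intersect_callsets, union_callsets
from .model import CallSet, MatchConfig, filter_by_size, filter_by_support

SENSITIVE_LABEL = "meta-sensitive"
STRINGENT_LABEL = "meta-stringent"


def _check_same_sample(*callsets: CallSet) -> None:
    samples = {cs.sample for cs in callsets}
    if len(samples) > 1:
        raise ValidationError(f"call sets are from different samples: {sorted(samples)}")


def build_sensitive(snif: CallSet, spot: CallSet, tail: CallSet,
                    cfg: MatchConfig = MatchConfig()) -> CallSet:
    """Sensitive (union) call set: SNIF ∪ (SPOT ∪ TAIL), in that order."""
    _check_same_sample(snif, spot, tail)
    inner = union_callsets(spot, tail, cfg)
    return union_callsets(snif, inner, cfg, caller=SENSITIVE_LABEL)


def build_stringent(snif: CallSet, spot: CallSet, tail: CallSet,
                    cfg: MatchConfig = MatchConfig()) -> CallSet:
    """Stringent (intersection) call set: SNIF ∩ (SPOT ∪ TAIL)."""
    _check_same_sample(snif, spot, tail)
    inner = union_callsets(spot, tail, cfg)
    return intersect_callsets(snif, inner, cfg, caller=STRINGENT_LABEL)


def build_generalized(callsets: Sequence[CallSet], cfg: MatchConfig = MatchConfig(),
                      min_callers: int = 2) -> Tuple[CallSet, CallSet]:
    """Generalized ensemble operator for two or more call sets.

    The sensitive set is the left-fold of the fuzzy union over ``callsets``
    in the given order.  The stringent set retains the sensitive calls
    corroborated by at least ``min_callers`` distinct caller labels (each
    merged call carries the union of its contributors in ``sources``).

    Supply at most one call set per SV caller: when one caller was run with
    several aligners, pass only the call set of its best aligner.
    """
    if len(callsets) < 2:
        raise ValidationError("build_generalized needs at least two call sets")
    _check_same_sample(*callsets)
    sensitive = reduce(lambda acc, cs: union_callsets(acc, cs, cfg), callsets)
    sensitive = CallSet(sensitive.sample, SENSITIVE_LABEL, sensitive.calls)
    stringent_calls = tuple(c for c in sensitive.calls if len(c.sources) >= min_callers)
    stringent = CallSet(sensitive.sample, STRINGENT_LABEL, stringent_calls)
    return sensitive, stringent


def build_truthset(initial: CallSet, highcov_sets: List[CallSet],
                   cfg: MatchConfig = MatchConfig(), min_support: int = 20,
                   min_len: int = 200) -> CallSet:
    """Two-step high-confidence truth-set construction.

    Each high-coverage call set is first filtered to calls with read support
    of at least ``min_support`` (default 20, a strict setting appropriate
    for deep coverage).  A call from ``initial`` is retained iff it matches
    at least one call in at least one filtered high-coverage set; retained
    calls keep their original coordinates (no averaging).  Finally calls
    shorter than ``min_len`` (default 200 bp) are removed.
    """
    if not highcov_sets:
        raise ValidationError("at least one high-coverage call set is required")
    filtered = [filter_by_support(hs, min_support) for hs in highcov_sets]
    indexes = [CallIndex(hs, cfg) for hs in filtered]
    kept = tuple(
        c for c in initial.calls if any(ix.has_match(c) for ix in indexes)
    )
    retained = CallSet(initial.sample, "truthset", kept)
    return filter_by_size(retained, min_len)
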