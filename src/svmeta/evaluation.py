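"""Benchmarking against a truth set and trio allele-drop-in evaluation.

A call set is benchmarked against a high-confidence truth set per SV type
(deletions and insertions only), after filtering both sides to calls of at
least 200 bp.  Matching is one-to-one, so TP is a single well-defined
count:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Allele drop-in (ADI) measures trio inconsistency: an offspring call that
matches no call in either parent.  Because de novo SVs are rare, the ADI
rate (events / offspring calls) proxies the combined sequencing and calling
error rate.  No genotypes are used — presence/absence only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import pandas as pd

from .errors import ValidationError
from .matching import CallIndex, match_callsets
from .model import DEL, INS, CallSet, MatchConfig


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class TypeMetrics:
    """Benchmark counts and metrics for one SV type.

    ``precision_defined`` / ``recall_defined`` are False when the
    corresponding denominator was zero; the metric is then reported as 0 so
    results stay plottable without hiding the degeneracy.
    """

    svtype: str
    n_calls: int
    n_truth: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool
    recall_defined: bool


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-type benchmark of a call set against a truth set."""

    per_type: Mapping[str, TypeMetrics]
    config: MatchConfig
    min_len: int
    n_other_calls: int = 0
    n_other_truth: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "svtype": m.svtype, "tp": m.tp, "fp": m.fp, "fn": m.fn,
                "precision": m.precision, "recall": m.recall, "f1": m.f1,
            }
            for m in self.per_type.values()
        ]
        return pd.DataFrame(rows, columns=["svtype", "tp", "fp", "fn",
                                           "precision", "recall", "f1"])

    def to_tsv(self) -> str:
        return self.to_dataframe().to_csv(sep="\t", index=False, float_format="%.6f")


def _metrics_for_type(svtype: str, calls, truth, sample: str,
                      cfg: MatchConfig) -> TypeMetrics:
    cset = CallSet(sample, "calls", tuple(calls))
    tset = CallSet(sample, "truth", tuple(truth))
    res = match_callsets(cset, tset, cfg)
    tp = len(res.pairs)
    fp = len(res.unmatched_a)
    fn = len(res.unmatched_b)
    # one-to-one accounting: both sides must balance
    assert tp + fp == len(cset.calls), "calls-side accounting broken"
    assert tp + fn == len(tset.calls), "truth-side accounting broken"
    p_def = (tp + fp) > 0
    r_def = (tp + fn) > 0
    precision = tp / (tp + fp) if p_def else 0.0
    recall = tp / (tp + fn) if r_def else 0.0
    return TypeMetrics(svtype, len(cset.calls), len(tset.calls), tp, fp, fn,
                       precision, recall, f1_score(precision, recall),
                       p_def, r_def)


def benchmark(calls: CallSet, truth: CallSet, cfg: MatchConfig = MatchConfig(),
              min_len: int = 200) -> BenchmarkResult:
    """Benchmark ``calls`` against ``truth`` for deletions and insertions.

    Both sets are filtered to DEL/INS calls of at least ``min_len`` bp, split
    by type, and matched one-to-one per type.  Other SV types are counted in
    ``n_other_*`` but excluded from the metrics.
    """
    per_type: Dict[str, TypeMetrics] = {}
    for svtype in (DEL, INS):
        c = [x for x in calls.calls if x.svtype == svtype and x.length >= min_len]
        t = [x for x in truth.calls if x.svtype == svtype and x.length >= min_len]
        per_type[svtype] = _metrics_for_type(svtype, c, t, calls.sample, cfg)
    return BenchmarkResult(
        per_type=per_type,
        config=cfg,
        min_len=min_len,
        n_other_calls=sum(1 for x in calls.calls if x.svtype not in (DEL, INS)),
        n_other_truth=sum(1 for x in truth.calls if x.svtype not in (DEL, INS)),
    )


@dataclass(frozen=True)
class TrioTypeResult:
    svtype: str
    offspring_calls: int
    adi_events: int
    adi_rate: float


@dataclass(frozen=True)
class TrioADIResult:
    """Allele-drop-in evaluation of an offspring call set against its parents."""

    per_type: Mapping[str, TrioTypeResult]
    config: MatchConfig

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"svtype": r.svtype, "offspring_calls": r.offspring_calls,
             "adi_events": r.adi_events, "adi_rate": r.adi_rate}
            for r in self.per_type.values()
        ]
        return pd.DataFrame(rows, columns=["svtype", "offspring_calls",
                                           "adi_events", "adi_rate"])

    def to_tsv(self) -> str:
        return self.to_dataframe().to_csv(sep="\t", index=False, float_format="%.6f")


def trio_adi(offspring: CallSet, father: CallSet, mother: CallSet,
             cfg: MatchConfig = MatchConfig()) -> TrioADIResult:
    """Per-type allele-drop-in rate of an offspring call set.

    An offspring call is an ADI event iff it matches no father call and no
    mother call; the two parent comparisons are independent (a call may
    match both parents).  Parent matching is existence-only, not one-to-one:
    a parent call may corroborate several offspring calls.
    """
    father_ix = CallIndex(father, cfg)
    mother_ix = CallIndex(mother, cfg)
    per_type: Dict[str, TrioTypeResult] = {}
    svtypes = sorted({c.svtype for c in offspring.calls})
    for svtype in svtypes:
        calls = [c for c in offspring.calls if c.svtype == svtype]
        events = sum(
            1 for c in calls
            if not father_ix.has_match(c) and not mother_ix.has_match(c)
        )
        rate = events / len(calls) if calls else 0.0
        per_type[svtype] = TrioTypeResult(svtype, len(calls), events, rate)
    return TrioADIResult(per_type, cfg)
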