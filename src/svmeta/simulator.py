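"""Synthetic ground truth and a coverage-dependent SV-caller emulator.

The generator places non-overlapping deletions and single-breakpoint
insertions on a synthetic genome, then emulates noisy caller outputs: the
read support of a heterozygous SV at fold-coverage ``c`` is modelled as
Poisson(c * allele_fraction * type_bias) and the call is emitted when the
support reaches the caller's minimum (2 by default, the sensitive setting
for low-coverage long-read data).  Reported breakpoints are jittered by a
rounded Gaussian, and false positives arrive as a Poisson process uniform
over the genome, independent across callers.

The coverage-titration runner re-enacts a down-sampling experiment
(coverages 2-15X, five replicates each) end to end: emulate every caller,
build the sensitive/stringent ensemble sets, and benchmark everything
against the simulated truth.

All randomness is derived from a single seed through
``numpy.random.SeedSequence([seed, *stage_key])`` so each stage is
independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from bisect import bisect_left, insort
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CapacityError, ValidationError
from .evaluation import benchmark
from .meta import SENSITIVE_LABEL, STRINGENT_LABEL, build_generalized, build_sensitive, build_stringent
from .model import DEL, INS, CallSet, MatchConfig, SVCall

DEFAULT_COVERAGES = (2, 4, 6, 8, 10, 12, 15)


def _stage_rng(seed: int, *tags) -> np.random.Generator:
    """Derive a stage generator from the global seed.

    Stage keys are (seed, crc32(tag) or int tag, ...) fed to SeedSequence,
    a fixed derivation so any stage can be reproduced in isolation.
    """
    entropy = [int(seed)]
    for t in tags:
        entropy.append(zlib.crc32(t.encode()) if isinstance(t, str) else int(t))
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class LengthDist:
    """Truncated log-normal SV length distribution.

    ``median`` is the untruncated median in bp (the log-normal location is
    ``ln(median)``); samples are redrawn until they fall in
    ``[min_len, max_len]``.
    """

    median: float
    sigma: float
    min_len: int = 50
    max_len: int = 100_000

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if size == 0:
            return np.zeros(0, dtype=int)
        out = np.empty(size, dtype=int)
        filled = 0
        while filled < size:
            draw = rng.lognormal(np.log(self.median), self.sigma, size=size - filled)
            draw = np.rint(draw).astype(int)
            keep = draw[(draw >= self.min_len) & (draw <= self.max_len)]
            out[filled:filled + len(keep)] = keep
            filled += len(keep)
        return out


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic truth set.

    Defaults describe a compact but realistic study condition: two 5-Mb
    chromosomes carrying 150 deletions and 150 insertions with log-normal
    lengths (medians 500/400 bp), heterozygous (allele_fraction 0.5), and a
    2-kb exclusion gap between placed SVs so that fuzzy matching against
    the truth is unambiguous.
    """

    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"1": 5_000_000, "2": 5_000_000})
    n_del: int = 150
    n_ins: int = 150
    del_len: LengthDist = LengthDist(500.0, 0.9)
    ins_len: LengthDist = LengthDist(400.0, 0.8)
    allele_fraction: float = 0.5
    min_gap: int = 2_000
    seed: int = 0
    sample: str = "sim"

    def __post_init__(self):
        if not self.chrom_sizes:
            raise ValidationError("chrom_sizes must be non-empty")
        if self.n_del < 0 or self.n_ins < 0:
            raise ValidationError("n_del and n_ins must be >= 0")
        if not (0 < self.allele_fraction <= 1):
            raise ValidationError("allele_fraction must be in (0, 1]")

    @property
    def genome_mb(self) -> float:
        return sum(self.chrom_sizes.values()) / 1e6


@dataclass(frozen=True)
class CallerProfile:
    """Behavioral profile of an emulated SV caller.

    ``type_bias`` multiplies the detection rate per SV type (default 1.0);
    a near-zero insertion bias models callers that are effectively blind to
    insertions.  ``fp_rate`` is false positives per megabase per 10X
    coverage.  ``breakpoint_sd`` is the SD in bp of the reported positions.
    """

    label: str
    min_support: int = 2
    breakpoint_sd: float = 20.0
    fp_rate: float = 0.0
    type_bias: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.min_support < 0 or self.breakpoint_sd < 0 or self.fp_rate < 0:
            raise ValidationError("profile rates must be non-negative")
        for t, v in self.type_bias.items():
            if not (0 < v <= 1):
                raise ValidationError(f"type_bias[{t}] must be in (0, 1], got {v}")

    def bias(self, svtype: str) -> float:
        return self.type_bias.get(svtype, 1.0)


def default_profiles() -> List[CallerProfile]:
    """Three caller archetypes mirroring a long-read ensemble.

    SNIF: strong on deletions, decent on insertions, tight breakpoints.
    SPOT: strong on insertions.
    TAIL: weak on deletions and essentially blind to insertions, the
    complementary clipped-tail detector.  Biases and noise levels are this
    package's modelling choices (see docs/methods.md).
    """
    return [
        CallerProfile("SNIF", min_support=2, breakpoint_sd=10.0, fp_rate=0.5,
                      type_bias={DEL: 1.0, INS: 0.8}),
        CallerProfile("SPOT", min_support=2, breakpoint_sd=20.0, fp_rate=0.5,
                      type_bias={DEL: 0.8, INS: 1.0}),
        CallerProfile("TAIL", min_support=2, breakpoint_sd=30.0, fp_rate=0.2,
                      type_bias={DEL: 0.27, INS: 0.001}),
    ]


class _Placer:
    """Rejection-samples non-overlapping placements with a minimum gap."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator, max_tries: int = 1000):
        self.cfg = cfg
        self.rng = rng
        self.max_tries = max_tries
        self.occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in cfg.chrom_sizes}
        sizes = np.array(list(cfg.chrom_sizes.values()), dtype=float)
        self.chroms = list(cfg.chrom_sizes)
        self.weights = sizes / sizes.sum()

    def _clashes(self, chrom: str, start: int, end: int) -> bool:
        gap = self.cfg.min_gap
        ivs = self.occupied[chrom]
        i = bisect_left(ivs, (start, end))
        for j in (i - 1, i):
            if 0 <= j < len(ivs):
                s, e = ivs[j]
                if start <= e + gap and s <= end + gap:
                    return True
        return False

    def place(self, footprint: int) -> Tuple[str, int]:
        for _ in range(self.max_tries):
            chrom = self.chroms[self.rng.choice(len(self.chroms), p=self.weights)]
            size = self.cfg.chrom_sizes[chrom]
            if size < footprint:
                continue
            start = int(self.rng.integers(1, size - footprint + 2))
            end = start + footprint - 1
            if not self._clashes(chrom, start, end):
                insort(self.occupied[chrom], (start, end))
                return chrom, start
        raise CapacityError(
            f"could not place an SV of {footprint} bp after {self.max_tries} tries; "
            "genome too small or too crowded"
        )


def simulate_truth(cfg: SimConfig) -> CallSet:
    """Generate the synthetic ground-truth call set.

    Deterministic given ``cfg.seed``.  Deletion footprints never overlap
    and keep at least ``cfg.min_gap`` bp from every other placed SV;
    insertion breakpoints respect the same exclusion zone.  Truth calls
    carry ``support = 0`` as a sentinel (read support is a property of a
    caller's observation, not of the truth).
    """
    rng = _stage_rng(cfg.seed, "truth")
    placer = _Placer(cfg, rng)
    del_lens = cfg.del_len.sample(rng, cfg.n_del)
    ins_lens = cfg.ins_len.sample(rng, cfg.n_ins)
    calls = []
    for i, length in enumerate(del_lens):
        chrom, start = placer.place(int(length))
        calls.append(SVCall.deletion(f"truth_del_{i}", chrom, start,
                                     start + int(length) - 1,
                                     support=0, sources=("truth",),
                                     sample=cfg.sample))
    for i, length in enumerate(ins_lens):
        chrom, start = placer.place(1)
        calls.append(SVCall.insertion(f"truth_ins_{i}", chrom, start, int(length),
                                      support=0, sources=("truth",),
                                      sample=cfg.sample))
    return CallSet(cfg.sample, "truth", tuple(calls))


def expected_detection(coverage: float, allele_fraction: float,
                       type_bias: float, min_support: int) -> float:
    """Analytic per-SV detection probability of the emulation model.

    P(X >= min_support) for X ~ Poisson(coverage * allele_fraction *
    type_bias) — the closed-form oracle for :func:`emulate_caller`.
    """
    if min_support < 0:
        raise ValidationError("min_support must be >= 0")
    if min_support == 0:
        return 1.0
    lam = coverage * allele_fraction * type_bias
    return float(stats.poisson.sf(min_support - 1, lam))


def _jitter(rng: np.random.Generator, pos: int, sd: float) -> int:
    if sd == 0:
        return pos
    return max(1, pos + int(round(rng.normal(0.0, sd))))


def emulate_caller(truth: CallSet, profile: CallerProfile, coverage: float,
                   seed: int, allele_fraction: float = 0.5,
                   chrom_sizes: Optional[Mapping[str, int]] = None) -> CallSet:
    """Emulate one caller's output on the given truth at a fold-coverage.

    Each truth SV draws its supporting-read count from
    Poisson(coverage * allele_fraction * type_bias) and is emitted iff the
    count reaches ``profile.min_support``, with breakpoints independently
    jittered by rounded Normal(0, breakpoint_sd).  False positives are added
    as Poisson(fp_rate * genome_Mb * coverage / 10) uniformly placed calls
    whose lengths resample the truth lengths of the same type.

    ``chrom_sizes`` bounds FP placement; when omitted it is inferred from
    the truth extents.
    """
    if coverage <= 0:
        raise ValidationError("coverage must be > 0")
    rng = _stage_rng(seed, "caller", profile.label)
    calls = []
    n = 0
    for t in truth.calls:
        lam = coverage * allele_fraction * profile.bias(t.svtype)
        s = int(rng.poisson(lam))
        if s < profile.min_support:
            continue
        n += 1
        if t.svtype == INS:
            pos = _jitter(rng, t.start, profile.breakpoint_sd)
            calls.append(SVCall.insertion(f"{profile.label.lower()}_{n}", t.chrom, pos,
                                          t.length, support=s,
                                          sources=(profile.label,), sample=t.sample))
        else:
            start = _jitter(rng, t.start, profile.breakpoint_sd)
            end = _jitter(rng, t.end, profile.breakpoint_sd)
            if end < start:
                start, end = end, start
            if t.svtype == DEL:
                calls.append(SVCall.deletion(f"{profile.label.lower()}_{n}", t.chrom,
                                             start, end, support=s,
                                             sources=(profile.label,), sample=t.sample))
            else:
                calls.append(SVCall(f"{profile.label.lower()}_{n}", t.chrom, start, end,
                                    t.svtype, end - start + 1, s,
                                    frozenset((profile.label,)), t.sample))

    if profile.fp_rate > 0:
        if chrom_sizes is None:
            chrom_sizes = {}
            for t in truth.calls:
                chrom_sizes[t.chrom] = max(chrom_sizes.get(t.chrom, 0), t.end + 10_000)
        sizes = np.array(list(chrom_sizes.values()), dtype=float)
        chroms = list(chrom_sizes)
        genome_mb = sizes.sum() / 1e6
        n_fp = int(rng.poisson(profile.fp_rate * genome_mb * coverage / 10.0))
        del_lens = [t.length for t in truth.calls if t.svtype == DEL]
        ins_lens = [t.length for t in truth.calls if t.svtype == INS]
        p_del = len(del_lens) / max(1, len(del_lens) + len(ins_lens))
        for j in range(n_fp):
            svtype = DEL if rng.random() < p_del else INS
            pool = del_lens if svtype == DEL else ins_lens
            length = int(rng.choice(pool)) if pool else 500
            chrom = chroms[rng.choice(len(chroms), p=sizes / sizes.sum())]
            size = int(chrom_sizes[chrom])
            support = profile.min_support + int(rng.poisson(1.0))
            if svtype == DEL:
                start = int(rng.integers(1, max(2, size - length + 1)))
                calls.append(SVCall.deletion(f"{profile.label.lower()}_fp_{j}", chrom,
                                             start, start + length - 1, support=support,
                                             sources=(profile.label,), sample=truth.sample))
            else:
                pos = int(rng.integers(1, size + 1))
                calls.append(SVCall.insertion(f"{profile.label.lower()}_fp_{j}", chrom,
                                              pos, length, support=support,
                                              sources=(profile.label,), sample=truth.sample))

    return CallSet(truth.sample, profile.label, tuple(calls), coverage=coverage)


def _child_seed(seed: int, *key: int) -> int:
    state = np.random.SeedSequence([int(seed), *map(int, key)]).generate_state(1)[0]
    return int(state) % (2 ** 31)


def run_titration(cfg: SimConfig, profiles: Optional[Sequence[CallerProfile]] = None,
                  coverages: Sequence[float] = DEFAULT_COVERAGES,
                  replicates: int = 5, seed: Optional[int] = None,
                  match_cfg: MatchConfig = MatchConfig(),
                  min_len: int = 200) -> pd.DataFrame:
    """Re-enact a coverage titration with replicate emulation runs.

    For every coverage x replicate the three profiles are emulated, the
    sensitive and stringent ensemble sets are built (the literal two-step
    formula when exactly three profiles are given, the generalized >=2-caller
    fold otherwise), and all call sets are benchmarked against the truth.

    Returns a tidy DataFrame with one row per (coverage, replicate,
    callset, svtype) carrying tp/fp/fn and precision/recall/f1.  Fully
    deterministic given ``seed`` (default ``cfg.seed``).
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if profiles is None:
        profiles = default_profiles()
    if seed is None:
        seed = cfg.seed
    truth = simulate_truth(cfg)
    rows = []
    for ci, cov in enumerate(coverages):
        for rep in range(replicates):
            emulated = [
                emulate_caller(truth, p, cov,
                               seed=_child_seed(seed, ci, rep, pi),
                               allele_fraction=cfg.allele_fraction,
                               chrom_sizes=cfg.chrom_sizes)
                for pi, p in enumerate(profiles)
            ]
            if len(emulated) == 3:
                sens = build_sensitive(*emulated, match_cfg)
                strg = build_stringent(*emulated, match_cfg)
            else:
                sens, strg = build_generalized(emulated, match_cfg)
            evaluated = list(zip([p.label for p in profiles], emulated))
            evaluated += [(SENSITIVE_LABEL, sens), (STRINGENT_LABEL, strg)]
            for label, cs in evaluated:
                res = benchmark(cs, truth, match_cfg, min_len=min_len)
                for m in res.per_type.values():
                    rows.append({
                        "coverage": cov, "replicate": rep, "callset": label,
                        "svtype": m.svtype, "tp": m.tp, "fp": m.fp, "fn": m.fn,
                        "precision": m.precision, "recall": m.recall, "f1": m.f1,
                    })
    return pd.DataFrame(rows)


def titration_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD over replicates per (coverage, callset, svtype) cell.

    SD is the sample standard deviation; with a single replicate it is
    reported as 0.
    """
    grouped = table.groupby(["coverage", "callset", "svtype"], sort=True)
    agg = grouped[["precision", "recall", "f1"]].agg(["mean", "std"])
    agg.columns = [f"{metric}_{stat}" for metric, stat in agg.columns]
    return agg.fillna(0.0).reset_index()


def simulate_trio(cfg: SimConfig, private_fraction: float,
                  seed: Optional[int] = None) -> Tuple[CallSet, CallSet, CallSet]:
    """Fabricate a trio from one truth set for allele-drop-in evaluation.

    Every truth call becomes an offspring call.  With probability
    ``private_fraction`` a call is offspring-private (in neither parent —
    a planted ADI event); otherwise it is assigned to the father, the
    mother, or both with equal probability.  Coordinates are copied
    verbatim, so the realized ADI rate of the trio equals the planted
    private fraction up to binomial sampling noise.

    Returns (offspring, father, mother).
    """
    if not (0.0 <= private_fraction <= 1.0):
        raise ValidationError("private_fraction must be in [0, 1]")
    if seed is None:
        seed = cfg.seed
    truth = simulate_truth(cfg)
    rng = _stage_rng(seed, "trio")
    offspring, father, mother = [], [], []
    for t in truth.calls:
        offspring.append(SVCall(t.id, t.chrom, t.start, t.end, t.svtype, t.length,
                                t.support, frozenset(("offspring",)), "offspring"))
        if rng.random() < private_fraction:
            continue
        dest = rng.choice(3)
        parent_call = lambda who: SVCall(t.id, t.chrom, t.start, t.end, t.svtype,
                                         t.length, t.support, frozenset((who,)), who)
        if dest in (0, 2):
            father.append(parent_call("father"))
        if dest in (1, 2):
            mother.append(parent_call("mother"))
    return (CallSet("offspring", "offspring", tuple(offspring)),
            CallSet("father", "father", tuple(father)),
            CallSet("mother", "mother", tuple(mother)))
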