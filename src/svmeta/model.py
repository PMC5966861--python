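"""Core domain types for structural-variant (SV) call sets.

Coordinates are 1-based inclusive throughout (VCF convention); BED readers
and writers convert at the boundary.  A deletion spans ``[start, end]`` with
``length == end - start + 1``.  An insertion is a single-breakpoint event:
``start == end`` is the breakpoint and ``length`` is the inserted-sequence
length.  Other SV types (inversions, duplications, ...) are carried through
I/O and set algebra by exact type-tag matching but are excluded from
benchmark metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional

from .errors import ValidationError

DEL = "DEL"
INS = "INS"


def normalize_chrom(name: str) -> str:
    """Canonicalize a chromosome name by stripping a leading ``chr`` prefix.

    GRCh37-style names ("1", "X") and UCSC-style names ("chr1", "chrX")
    compare equal after normalization; the comparison is case-sensitive
    afterwards.

    >>> normalize_chrom("chr1")
    '1'
    """
    if not isinstance(name, str) or not name:
        raise ValidationError("chromosome name must be a non-empty string")
    stripped = name[3:] if name[:3].lower() == "chr" else name
    if not stripped:
        raise ValidationError(f"chromosome name {name!r} is empty after stripping 'chr'")
    return stripped


@dataclass(frozen=True)
class SVCall:
    """One structural-variant call.

    Parameters
    ----------
    id : str
        Opaque identifier, unique within a :class:`CallSet`.
    chrom : str
        Chromosome name; normalized (``chr`` prefix stripped) on construction.
    start, end : int
        1-based inclusive coordinates.  For insertions ``end == start``.
    svtype : str
        ``"DEL"``, ``"INS"`` or any other tag (``"INV"``, ``"DUP"``, ...).
    length : int
        SV length in bp.  For deletions this equals ``end - start + 1``;
        for insertions it is the inserted-sequence length.
    support : int
        Number of supporting reads (0 when unknown).
    sources : frozenset of str
        Caller labels that produced or corroborated the call; never empty.
    sample : str
        Sample identifier.
    extras : mapping, optional
        Opaque key/value attributes preserved from tolerant readers; ignored
        in comparisons.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    support: int
    sources: frozenset
    sample: str = ""
    extras: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not isinstance(self.sources, frozenset):
            object.__setattr__(self, "sources", frozenset(self.sources))
        if not self.sources:
            raise ValidationError(f"call {self.id!r}: sources must be non-empty")
        if self.start < 1:
            raise ValidationError(f"call {self.id!r}: start must be >= 1, got {self.start}")
        if self.svtype == INS:
            if self.end != self.start:
                raise ValidationError(
                    f"call {self.id!r}: insertion must have end == start "
                    f"(got {self.start}..{self.end})"
                )
        elif self.end < self.start:
            raise ValidationError(
                f"call {self.id!r}: end ({self.end}) < start ({self.start})"
            )
        if self.length < 1:
            raise ValidationError(f"call {self.id!r}: length must be >= 1, got {self.length}")
        if self.svtype == DEL and self.length != self.end - self.start + 1:
            raise ValidationError(
                f"call {self.id!r}: deletion length {self.length} does not match "
                f"span {self.end - self.start + 1}"
            )
        if self.support < 0:
            raise ValidationError(f"call {self.id!r}: support must be >= 0")

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def deletion(cls, id, chrom, start, end, support=0, sources=("unknown",), sample=""):
        """Build a deletion; length is derived from the coordinates."""
        return cls(id, chrom, start, end, DEL, end - start + 1, support,
                   frozenset(sources), sample)

    @classmethod
    def insertion(cls, id, chrom, pos, length, support=0, sources=("unknown",), sample=""):
        """Build a single-breakpoint insertion of the given inserted length."""
        return cls(id, chrom, pos, pos, INS, length, support, frozenset(sources), sample)

    def sort_key(self):
        return (self.chrom, self.start, self.end, self.id)


@dataclass(frozen=True)
class CallSet:
    """An ordered collection of calls from one sample and one caller.

    Calls are kept sorted by (chrom, start, end, id) and ids must be unique
    within the set; both are enforced on construction, so every CallSet is
    canonical.
    """

    sample: str
    caller: str
    calls: tuple = ()
    coverage: Optional[float] = None

    def __post_init__(self):
        ordered = tuple(sorted(self.calls, key=SVCall.sort_key))
        object.__setattr__(self, "calls", ordered)
        ids = [c.id for c in ordered]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate call ids in CallSet: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[SVCall]:
        return iter(self.calls)

    def replace_calls(self, calls) -> "CallSet":
        return replace(self, calls=tuple(calls))


def sort_callset(cs: CallSet) -> CallSet:
    """Return ``cs`` in canonical order (idempotent; CallSets are always sorted)."""
    return replace(cs, calls=cs.calls)


def filter_by_size(cs: CallSet, min_len: int = 200) -> CallSet:
    """Retain calls with ``length >= min_len``.

    The default keeps only SVs of at least 200 bp, the conventional floor
    below which short-read sequencing already detects events reliably and
    long-read precision is poor.  A 200 bp call is kept (the floor excludes
    strictly shorter calls).
    """
    if min_len < 0:
        raise ValidationError("min_len must be >= 0")
    return cs.replace_calls(c for c in cs.calls if c.length >= min_len)


def filter_by_support(cs: CallSet, min_support: int = 2) -> CallSet:
    """Retain calls with ``support >= min_support`` (default 2 reads)."""
    if min_support < 0:
        raise ValidationError("min_support must be >= 0")
    return cs.replace_calls(c for c in cs.calls if c.support >= min_support)


@dataclass(frozen=True)
class MatchConfig:
    """Equivalence thresholds deciding when two SV calls are the same event.

    Deletions (and other span events of equal type) match when their
    reciprocal overlap — the overlap length divided by each call's own
    length, minimum of the two fractions — reaches
    ``min_reciprocal_overlap``.  Insertions match when their breakpoints lie
    within ``ins_delta`` bp; inserted length is deliberately ignored.

    ``strict_overlap`` switches the overlap comparison from ``>=`` (default)
    to ``>`` at the boundary.
    """

    min_reciprocal_overlap: float = 0.5
    ins_delta: int = 500
    require_same_type: bool = True
    strict_overlap: bool = False

    def __post_init__(self):
        if not (0 < self.min_reciprocal_overlap <= 1):
            raise ValidationError(
                f"min_reciprocal_overlap must be in (0, 1], got {self.min_reciprocal_overlap}"
            )
        if self.ins_delta < 0:
            raise ValidationError(f"ins_delta must be >= 0, got {self.ins_delta}")
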