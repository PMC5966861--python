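"""Readers and writers for SV call-set files.

Supported dialects:

``vcf``
    VCF 4.x with INFO keys SVTYPE and SVLEN and/or END (Sniffles-style);
    read support from INFO/RE, then INFO/SUPPORT, then FORMAT/DV of the
    first sample.  Read via cyvcf2.
``bed6sv``
    Six tab-separated columns: chrom, start (0-based), end (exclusive),
    svtype, length, support.  BED coordinate convention; converted to the
    internal 1-based inclusive form on read.
``pbhoney_spots`` / ``pbhoney_tails``
    Four columns: chrom, start (1-based), end (1-based), attributes — a
    semicolon-separated key=value list carrying SVTYPE, SIZE and SUPPORT.
    Unknown keys are preserved as opaque extras.  This column layout is this
    package's documented contract for pre-formatted spot/tail tables, not a
    claim about any caller's native on-disk format.
``annovar_bed``
    Seven columns: chrom, start (1-based), end (1-based), svtype, length,
    support, comma-joined sources — directly usable as an ANNOVAR region
    file (ANNOVAR's avinput is 1-based inclusive, unlike BED).

Lines starting with ``#`` are comments.  All readers accept plain and
gzip-compressed files.  Writers are atomic (write to a temp file, then
rename), so a failed run never leaves a partial primary output.
"""

from __future__ import annotations

import gzip
import logging
import os
from enum import Enum
from pathlib import Path
from typing import IO, Iterator, Optional

from .errors import ParseError, ValidationError
from .model import DEL, INS, CallSet, SVCall

logger = logging.getLogger("svmeta")


class Dialect(str, Enum):
    VCF = "vcf"
    BED6SV = "bed6sv"
    PBHONEY_SPOTS = "pbhoney_spots"
    PBHONEY_TAILS = "pbhoney_tails"
    ANNOVAR_BED = "annovar_bed"


def _open_text(path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


# --------------------------------------------------------------------------- VCF

def _first(value):
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def _vcf_support(variant) -> int:
    for key in ("RE", "SUPPORT"):
        v = _first(variant.INFO.get(key))
        if v is not None:
            return int(v)
    try:
        dv = variant.format("DV")
    except KeyError:
        dv = None
    if dv is not None and len(dv) > 0:
        return int(dv[0][0])
    return 0


def read_vcf(path, sample: str, caller: str) -> CallSet:
    """Read SV records from a VCF file into a CallSet.

    DEL (and other span types): start = POS, end = INFO/END; when END and
    SVLEN disagree, END wins and the length is recomputed from the
    coordinates (a warning is logged) — coordinates are what matching
    consumes.  INS: single breakpoint at POS, length = \\|SVLEN\\|.  Records
    lacking SVTYPE, or lacking both END and SVLEN, are skipped with a
    warning.  SVTYPE values other than DEL/INS are carried through verbatim.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    calls = []
    for i, v in enumerate(vcf, start=1):
        svtype = _first(v.INFO.get("SVTYPE"))
        if svtype is None:
            logger.warning("%s: record %d has no SVTYPE; skipped", path, i)
            continue
        svtype = str(svtype)
        pos = v.POS
        svlen = _first(v.INFO.get("SVLEN"))
        svlen = abs(int(svlen)) if svlen is not None else None
        end_info = _first(v.INFO.get("END"))
        support = _vcf_support(v)
        call_id = v.ID if v.ID not in (None, ".") else f"{caller}_{i}"

        if svtype == INS:
            if svlen is None or svlen < 1:
                logger.warning("%s: INS record %d has no usable SVLEN; skipped", path, i)
                continue
            calls.append(SVCall.insertion(call_id, v.CHROM, pos, svlen,
                                          support=support, sources=(caller,),
                                          sample=sample))
            continue

        if end_info is not None:
            end = int(end_info)
            if svlen is not None and svlen != end - pos + 1:
                logger.warning(
                    "%s: record %d: SVLEN (%d) inconsistent with END-POS span (%d); "
                    "END wins, length recomputed", path, i, svlen, end - pos + 1)
        elif svlen is not None:
            end = pos + svlen - 1
        else:
            logger.warning("%s: record %d has neither END nor SVLEN; skipped", path, i)
            continue
        if end < pos:
            logger.warning("%s: record %d has END < POS; skipped", path, i)
            continue
        length = end - pos + 1
        calls.append(SVCall(call_id, v.CHROM, pos, end, svtype, length,
                            support, frozenset((caller,)), sample))
    return CallSet(sample, caller, tuple(calls))


# --------------------------------------------------------------------------- BED family

def _int_field(path, lineno, name, raw) -> int:
    try:
        return int(raw)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {name}: {raw!r}") from None


def _lines(path) -> Iterator:
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _parse_bed6sv(path, lineno, fields, sample, caller) -> SVCall:
    if len(fields) != 6:
        raise ParseError(path, lineno, f"expected 6 columns, found {len(fields)}")
    chrom, start0, end_x, svtype, length_s, support_s = fields
    start0 = _int_field(path, lineno, "start", start0)
    end_x = _int_field(path, lineno, "end", end_x)
    length = _int_field(path, lineno, "length", length_s)
    support = _int_field(path, lineno, "support", support_s)
    start = start0 + 1  # BED 0-based half-open -> 1-based inclusive
    if svtype == INS:
        return SVCall.insertion(f"{caller}_{lineno}", chrom, start, length,
                                support=support, sources=(caller,), sample=sample)
    end = end_x
    span = end - start + 1
    if svtype == DEL and length != span:
        logger.warning("%s: line %d: length column (%d) != span (%d); span wins",
                       path, lineno, length, span)
    return SVCall(f"{caller}_{lineno}", chrom, start, end, svtype, span,
                  support, frozenset((caller,)), sample)


def _parse_pbhoney(path, lineno, fields, sample, caller) -> SVCall:
    if len(fields) < 4:
        raise ParseError(path, lineno, f"expected >= 4 columns, found {len(fields)}")
    chrom, start_s, end_s = fields[0], fields[1], fields[2]
    start = _int_field(path, lineno, "start", start_s)
    end = _int_field(path, lineno, "end", end_s)
    attrs = {}
    for item in fields[3].split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ParseError(path, lineno, f"malformed attribute {item!r}")
        k, v = item.split("=", 1)
        attrs[k.strip()] = v.strip()
    svtype = attrs.pop("SVTYPE", None)
    if svtype is None:
        raise ParseError(path, lineno, "attribute column lacks SVTYPE")
    size = attrs.pop("SIZE", None)
    if size is None:
        raise ParseError(path, lineno, "attribute column lacks SIZE")
    size = _int_field(path, lineno, "SIZE", size)
    support = _int_field(path, lineno, "SUPPORT", attrs.pop("SUPPORT", 0))
    if svtype == INS:
        return SVCall(f"{caller}_{lineno}", chrom, start, start, INS, size,
                      support, frozenset((caller,)), sample, extras=attrs)
    span = end - start + 1
    if svtype == DEL and size != span:
        logger.warning("%s: line %d: SIZE (%d) != span (%d); span wins",
                       path, lineno, size, span)
    return SVCall(f"{caller}_{lineno}", chrom, start, end, svtype, span,
                  support, frozenset((caller,)), sample, extras=attrs)


def _parse_annovar(path, lineno, fields, sample, caller) -> SVCall:
    if len(fields) != 7:
        raise ParseError(path, lineno, f"expected 7 columns, found {len(fields)}")
    chrom, start_s, end_s, svtype, length_s, support_s, sources_s = fields
    start = _int_field(path, lineno, "start", start_s)
    end = _int_field(path, lineno, "end", end_s)
    length = _int_field(path, lineno, "length", length_s)
    support = _int_field(path, lineno, "support", support_s)
    sources = frozenset(s for s in sources_s.split(",") if s) or frozenset((caller,))
    if svtype == INS:
        return SVCall(f"{caller}_{lineno}", chrom, start, start, INS, length,
                      support, sources, sample)
    return SVCall(f"{caller}_{lineno}", chrom, start, end, svtype,
                  end - start + 1, support, sources, sample)


_BED_PARSERS = {
    Dialect.BED6SV: _parse_bed6sv,
    Dialect.PBHONEY_SPOTS: _parse_pbhoney,
    Dialect.PBHONEY_TAILS: _parse_pbhoney,
    Dialect.ANNOVAR_BED: _parse_annovar,
}


def read_bed_sv(path, dialect: Dialect, sample: str, caller: str) -> CallSet:
    """Read a BED-family SV table in the given dialect into a CallSet."""
    dialect = Dialect(dialect)
    parser = _BED_PARSERS.get(dialect)
    if parser is None:
        raise ValidationError(f"dialect {dialect.value} is not a BED-family dialect")
    calls = [parser(path, lineno, fields, sample, caller)
             for lineno, fields in _lines(path)]
    return CallSet(sample, caller, tuple(calls))


def read_callset(path, dialect: Dialect, sample: str, caller: str) -> CallSet:
    """Read a call set in any supported dialect (dispatches VCF vs BED)."""
    dialect = Dialect(dialect)
    if dialect is Dialect.VCF:
        return read_vcf(path, sample, caller)
    return read_bed_sv(path, dialect, sample, caller)


# --------------------------------------------------------------------------- writers

def _atomic_write(path, text: str) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    if path.suffix == ".gz":
        with gzip.open(tmp, "wt") as fh:
            fh.write(text)
    else:
        with open(tmp, "wt") as fh:
            fh.write(text)
    os.replace(tmp, path)


def write_annovar_bed(cs: CallSet, path) -> None:
    """Write a CallSet as an ANNOVAR-compatible region file (1-based, inclusive).

    Columns: chrom, start, end, svtype, length, support, comma-joined
    sources.  Round-trips through :func:`read_bed_sv` with the
    ``annovar_bed`` dialect up to field equality.
    """
    lines = ["#chrom\tstart\tend\tsvtype\tlength\tsupport\tsources"]
    for c in cs.calls:
        lines.append("\t".join([
            c.chrom, str(c.start), str(c.end), c.svtype, str(c.length),
            str(c.support), ",".join(sorted(c.sources)),
        ]))
    _atomic_write(path, "\n".join(lines) + "\n")


def write_bed6sv(cs: CallSet, path) -> None:
    """Write a CallSet in the ``bed6sv`` dialect (BED 0-based half-open)."""
    lines = ["#chrom\tstart\tend\tsvtype\tlength\tsupport"]
    for c in cs.calls:
        lines.append("\t".join([
            c.chrom, str(c.start - 1), str(c.end), c.svtype, str(c.length),
            str(c.support),
        ]))
    _atomic_write(path, "\n".join(lines) + "\n")


def write_callset(cs: CallSet, path, dialect: Dialect = Dialect.ANNOVAR_BED) -> None:
    dialect = Dialect(dialect)
    if dialect is Dialect.ANNOVAR_BED:
        write_annovar_bed(cs, path)
    elif dialect is Dialect.BED6SV:
        write_bed6sv(cs, path)
    else:
        raise ValidationError(f"no writer for dialect {dialect.value}")
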