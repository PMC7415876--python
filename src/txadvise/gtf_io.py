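"""Transcript models and GTF input/output.

Coordinates are 1-based and inclusive throughout (GTF convention); no
half-open conversion happens anywhere in the public data model.  A
transcript's per-transcript ``cov`` attribute (Scallop and StringTie both
write it) is the confidence score used for threshold sweeps; which
attribute names are tried, and in what order, is configurable.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from .errors import GtfParseError, ValidationError

logger = logging.getLogger(__name__)

#: Attribute names tried, in order, when looking for the confidence score.
DEFAULT_COVERAGE_KEYS = ("cov", "coverage", "FPKM")

_ATTR_RE = re.compile(r'\s*(\w+)\s+"([^"]*)"\s*;?')


@dataclass(frozen=True, order=True)
class Exon:
    """A single exon, 1-based inclusive coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"exon start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    """One transcript model: ordered exons on a chromosome strand.

    ``coverage`` is the assembler's abundance estimate used as the
    confidence score; reference transcripts usually carry ``None``.
    ``strand`` is '+', '-', or '.' (unknown; preserved, never coerced).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon]
    coverage: float | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(
                f"transcript {self.transcript_id}: bad strand {self.strand!r}"
            )
        self.exons = sorted(self.exons)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end + 1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons ({a.start},{a.end}) and "
                    f"({b.start},{b.end}) overlap or touch (introns must have positive length)"
                )
        if self.coverage is not None and self.coverage < 0:
            raise ValidationError(
                f"transcript {self.transcript_id}: negative coverage {self.coverage}"
            )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        """Total exonic length in bases."""
        return sum(len(e) for e in self.exons)

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered intron intervals between consecutive exons.

        Empty for single-exon transcripts.  Each intron is
        ``(prev_exon.end + 1, next_exon.start - 1)``, 1-based inclusive.
        """
        return tuple(
            (a.end + 1, b.start - 1) for a, b in zip(self.exons, self.exons[1:])
        )


def intron_chain(t: Transcript) -> tuple[tuple[int, int], ...]:
    """Splice-junction chain of ``t`` (module-level alias)."""
    return t.intron_chain()


class Transcriptome:
    """A collection of transcripts keyed by id, with a chromosome index.

    Serves both for predictions (transcripts carry coverage) and for the
    reference catalogue (coverage typically absent).
    """

    def __init__(self, transcripts: Iterable[Transcript] = ()) -> None:
        self._transcripts: dict[str, Transcript] = {}
        self._by_chrom: dict[str, list[Transcript]] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: Transcript) -> None:
        if t.transcript_id in self._transcripts:
            raise ValidationError(f"duplicate transcript_id {t.transcript_id!r}")
        self._transcripts[t.transcript_id] = t
        self._by_chrom.setdefault(t.chrom, []).append(t)

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self._transcripts[transcript_id]

    @property
    def transcripts(self) -> dict[str, Transcript]:
        return dict(self._transcripts)

    def by_chrom(self, chrom: str) -> list[Transcript]:
        return list(self._by_chrom.get(chrom, []))

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Transcriptome):
            return NotImplemented
        return self._transcripts == other._transcripts

    def __repr__(self) -> str:
        return f"Transcriptome({len(self)} transcripts, {len(self._by_chrom)} chromosomes)"


def _parse_attributes(attr_col: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    pos = 0
    for m in _ATTR_RE.finditer(attr_col):
        if m.start() != pos:
            break
        attrs[m.group(1)] = m.group(2)
        pos = m.end()
    if not attrs or attr_col[pos:].strip() not in ("", ";"):
        raise GtfParseError(f"line {lineno}: malformed attribute column {attr_col!r}")
    return attrs


def _coerce_coverage(raw: str | None, transcript_id: str) -> float | None:
    if raw is None:
        return None
    try:
        value = float(raw)
    except ValueError:
        logger.warning(
            "transcript %s: unparseable coverage %r treated as absent",
            transcript_id,
            raw,
        )
        return None
    return value


def read_gtf(
    source: str | Path | IO[str],
    coverage_keys: Sequence[str] = DEFAULT_COVERAGE_KEYS,
) -> Transcriptome:
    """Read a GTF file or text stream into a :class:`Transcriptome`.

    Only ``exon`` and ``transcript`` feature rows are consumed; all other
    feature types are ignored.  Exon rows are grouped by ``transcript_id``.
    The coverage score is taken from the first name in ``coverage_keys``
    found on the transcript row or, failing that, on its exon rows.

    Raises :class:`GtfParseError` (naming the line) on malformed rows and
    :class:`ValidationError` on inconsistent transcripts (start > end,
    one id spanning two chromosomes, overlapping exons).
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            return read_gtf(fh, coverage_keys)

    # per transcript: chrom, strand, gene_id, exon list, raw coverage candidates
    exons: dict[str, list[Exon]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    tx_attrs: dict[str, dict[str, str]] = {}
    exon_attrs: dict[str, dict[str, str]] = {}
    order: list[str] = []

    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
            )
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_col = fields
        if feature not in ("exon", "transcript"):
            continue
        attrs = _parse_attributes(attr_col, lineno)
        if "transcript_id" not in attrs or "gene_id" not in attrs:
            raise GtfParseError(
                f"line {lineno}: missing gene_id/transcript_id attribute"
            )
        tid = attrs["transcript_id"]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(
                f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
            ) from None
        if tid in meta:
            prev_chrom, prev_strand, _ = meta[tid]
            if prev_chrom != chrom:
                raise ValidationError(
                    f"line {lineno}: transcript {tid!r} spans chromosomes "
                    f"{prev_chrom!r} and {chrom!r}"
                )
            if prev_strand != strand:
                raise ValidationError(
                    f"line {lineno}: transcript {tid!r} has inconsistent strands"
                )
        else:
            meta[tid] = (chrom, strand, attrs["gene_id"])
            order.append(tid)
        if feature == "exon":
            if start > end:
                raise ValidationError(f"line {lineno}: exon start {start} > end {end}")
            exons.setdefault(tid, []).append(Exon(start, end))
            store = exon_attrs.setdefault(tid, {})
            for k, v in attrs.items():
                store.setdefault(k, v)  # first exon row wins
        else:
            tx_attrs.setdefault(tid, {}).update(attrs)

    out = Transcriptome()
    for tid in order:
        chrom, strand, gene_id = meta[tid]
        if tid not in exons:
            raise ValidationError(f"transcript {tid!r} has a transcript row but no exons")
        raw_cov = None
        for key in coverage_keys:
            if key in tx_attrs.get(tid, {}):
                raw_cov = tx_attrs[tid][key]
                break
            if key in exon_attrs.get(tid, {}):
                raw_cov = exon_attrs[tid][key]
                break
        out.add(
            Transcript(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=exons[tid],
                coverage=_coerce_coverage(raw_cov, tid),
            )
        )
    return out


def write_gtf(t: Transcriptome, sink: str | Path | IO[str]) -> None:
    """Write ``t`` as GTF: one ``transcript`` row plus one ``exon`` row per exon.

    Attributes are ``gene_id``, ``transcript_id`` and, when coverage is
    present, ``cov`` — the dialect both Scallop and StringTie emit.
    ``read_gtf(write_gtf(x))`` reproduces ``x`` exactly.
    """
    if isinstance(sink, (str, Path)):
        with open(sink, "wt") as fh:
            write_gtf(t, fh)
        return

    for tx in t:
        attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
        if tx.coverage is not None:
            attrs += f' cov "{tx.coverage!r}";'
        row = [tx.chrom, "txadvise", "transcript", str(tx.start), str(tx.end),
               ".", tx.strand, ".", attrs]
        sink.write("\t".join(row) + "\n")
        for e in tx.exons:
            row[2:5] = ["exon", str(e.start), str(e.end)]
            sink.write("\t".join(row) + "\n")


def gtf_string(t: Transcriptome) -> str:
    """Render ``t`` as a GTF string (convenience wrapper over write_gtf)."""
    buf = io.StringIO()
    write_gtf(t, buf)
    return buf.getvalue()
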