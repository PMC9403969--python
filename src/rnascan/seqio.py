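"""Transcript FASTA I/O with region-annotated (UTR5/CDS/UTR3) headers.

Headers may be plain identifiers or pipe-delimited records in the style
used by protein-coding transcript FASTA releases, e.g.::

    >ENST00000306434.8|ENSG00000168906.13|OTT...|OTT...|MAT2A-201|MAT2A|3506|UTR5:1-120|CDS:121-1308|UTR3:1309-3506|

Region spans are transcript-local, 1-based and inclusive throughout the
package.  Unknown pipe fields are ignored; absent region fields leave the
corresponding span unset.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Optional, Tuple, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

Span = Tuple[int, int]

_SPAN_RE = re.compile(r"^(UTR5|CDS|UTR3):(\S+)$")

# Accession-like fields that are never gene symbols.
_ACCESSION_RE = re.compile(r"^(ENSG|ENST|OTTHUM|OTT)")


class TranscriptParseError(ValueError):
    """Raised when a FASTA record header carries a malformed region span."""

    def __init__(self, record_id: str, message: str):
        super().__init__(f"record {record_id!r}: {message}")
        self.record_id = record_id


@dataclass(frozen=True)
class Transcript:
    """A transcript sequence with optional 1-based inclusive region spans."""

    transcript_id: str
    sequence: str
    gene_name: str = ""
    utr5: Optional[Span] = None
    cds: Optional[Span] = None
    utr3: Optional[Span] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"transcript {self.transcript_id!r} has empty sequence")
        n = len(self.sequence)
        prev_end = 0
        for name in ("utr5", "cds", "utr3"):
            span = getattr(self, name)
            if span is None:
                continue
            a, b = span
            if not (1 <= a <= b <= n):
                raise ValueError(
                    f"transcript {self.transcript_id!r}: {name} span {a}-{b} "
                    f"outside [1, {n}]"
                )
            if a <= prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: {name} span {a}-{b} "
                    "overlaps or disorders preceding region"
                )
            prev_end = b

    def __len__(self) -> int:
        return len(self.sequence)

    def region_of(self, pos: int) -> Optional[str]:
        """Name of the annotated region containing 1-based ``pos``, if any."""
        for name in ("utr5", "cds", "utr3"):
            span = getattr(self, name)
            if span is not None and span[0] <= pos <= span[1]:
                return name
        return None


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _parse_span(record_id: str, field: str, text: str) -> Span:
    parts = text.split("-")
    if len(parts) != 2:
        raise TranscriptParseError(record_id, f"malformed {field} span {text!r}")
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError:
        raise TranscriptParseError(record_id, f"non-numeric {field} span {text!r}") from None
    if a > b:
        raise TranscriptParseError(record_id, f"{field} span start {a} > end {b}")
    return (a, b)


def _parse_header(header: str) -> tuple[str, str, dict[str, str]]:
    """Split a FASTA header into (transcript_id, gene_name, raw span fields)."""
    fields = [f for f in header.split("|")]
    transcript_id = fields[0].strip()
    spans: dict[str, str] = {}
    gene_name = ""
    for i, field in enumerate(fields[1:], start=1):
        field = field.strip()
        m = _SPAN_RE.match(field)
        if m:
            spans[m.group(1)] = m.group(2)
            continue
        if (
            not gene_name
            and field
            and not field.isdigit()
            and not _ACCESSION_RE.match(field)
        ):
            # First non-accession, non-numeric field without a span prefix.
            # In full pc_transcripts headers this is the transcript name
            # (SYMBOL-NNN); prefer the following bare symbol when present.
            gene_name = field
    # Full-dialect headers carry SYMBOL-NNN then SYMBOL; prefer the bare symbol.
    if gene_name and "-" in gene_name:
        stem = gene_name.rsplit("-", 1)[0]
        for field in fields[1:]:
            if field.strip() == stem:
                gene_name = stem
                break
    return transcript_id, gene_name, spans


def read_transcripts(fasta_source: Union[str, Path, IO[str]]) -> list[Transcript]:
    """Read transcripts from FASTA, parsing region annotations when present.

    DNA alphabet is transliterated to RNA (T -> U); ambiguity codes are kept.
    Record order is preserved.  A malformed span raises
    :class:`TranscriptParseError` naming the offending record.
    """
    records = list(SeqIO.parse(fasta_source, "fasta"))
    if not records:
        logger.warning("no FASTA records found in %s", fasta_source)
        return []
    transcripts: list[Transcript] = []
    for rec in records:
        transcript_id, gene_name, raw_spans = _parse_header(rec.description)
        spans = {
            key.lower(): _parse_span(transcript_id, key, text)
            for key, text in raw_spans.items()
        }
        seq = _to_rna(str(rec.seq))
        if any(c not in "ACGU" for c in set(seq)):
            logger.info(
                "transcript %s contains ambiguity codes; they are kept and "
                "treated as unpairable when folding",
                transcript_id,
            )
        transcripts.append(
            Transcript(
                transcript_id=transcript_id,
                gene_name=gene_name,
                sequence=seq,
                utr5=spans.get("utr5"),
                cds=spans.get("cds"),
                utr3=spans.get("utr3"),
            )
        )
    return transcripts


def _format_header(t: Transcript) -> str:
    fields = [t.transcript_id]
    if t.gene_name:
        fields.append(t.gene_name)
    fields.append(str(len(t.sequence)))
    for key, span in (("UTR5", t.utr5), ("CDS", t.cds), ("UTR3", t.utr3)):
        if span is not None:
            fields.append(f"{key}:{span[0]}-{span[1]}")
    return "|".join(fields) + "|"


def write_transcripts(
    transcripts: Iterable[Transcript],
    destination: Union[str, Path, IO[str]],
    line_width: int = 60,
) -> None:
    """Write transcripts as FASTA with pipe-delimited region headers."""
    own = isinstance(destination, (str, Path))
    handle = open(destination, "w") if own else destination
    try:
        for t in transcripts:
            handle.write(f">{_format_header(t)}\n")
            for i in range(0, len(t.sequence), line_width):
                handle.write(t.sequence[i : i + line_width] + "\n")
    finally:
        if own:
            handle.close()


def filter_by_length(
    transcripts: Iterable[Transcript], min_length: int = 120
) -> tuple[list[Transcript], list[Transcript]]:
    """Partition transcripts into (kept, skipped) by a minimum length.

    Transcripts shorter than ``min_length`` cannot host a single scan
    window and are skipped.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept: list[Transcript] = []
    skipped: list[Transcript] = []
    for t in transcripts:
        (kept if len(t) >= min_length else skipped).append(t)
    return kept, skipped


def write_skipped_report(
    skipped: Iterable[Transcript], destination: Union[str, Path, IO[str]]
) -> None:
    """TSV report (transcript_id, length) of length-filtered transcripts."""
    own = isinstance(destination, (str, Path))
    handle = open(destination, "w") if own else destination
    try:
        handle.write("transcript_id\tlength\n")
        for t in skipped:
            handle.write(f"{t.transcript_id}\t{len(t)}\n")
    finally:
        if own:
            handle.close()
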