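"""Windowed MFE / z-score / p-value / ensemble-diversity scanning.

A fixed-size window slides along the transcript at a fixed step.  Each
window's native sequence is folded to get its MFE and structure; the
sequence is then shuffled (composition-preserving) a configured number
of times and each shuffle is folded to build the null energy
distribution used for the thermodynamic z-score and empirical p-value.
Only full windows are scanned; transcripts shorter than the window must
be filtered out beforehand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np

from rnascan.fold import FoldBackend, get_backend
from rnascan.seqio import Transcript
from rnascan.shuffle import ShuffleConfig, shuffle_sequence, window_rng

logger = logging.getLogger(__name__)

__all__ = [
    "ScanParams",
    "WindowMetrics",
    "zscore",
    "pvalue",
    "scan_transcript",
    "n_windows",
    "per_nt_zavg",
    "write_scan_table",
    "read_scan_table",
    "write_wig",
    "read_wig",
]


@dataclass(frozen=True)
class ScanParams:
    """Scanning configuration (defaults mirror the transcriptome run)."""

    window: int = 120
    step: int = 1
    shuffle: ShuffleConfig = field(default_factory=ShuffleConfig)
    temperature_c: float = 37.0

    def __post_init__(self) -> None:
        if not (1 <= self.step <= self.window):
            raise ValueError("require 1 <= step <= window")


@dataclass(frozen=True)
class WindowMetrics:
    """Per-window scan output; start/end are 1-based inclusive."""

    start: int
    end: int
    native_dg: float
    z: float
    p: float
    ed: float
    sequence: str
    structure: str
    degenerate: bool = False  # sd of the shuffled energies was 0


def zscore(native_dg: float, shuffled_dgs: Sequence[float]) -> float:
    """(native - mean(shuffled)) / sd(shuffled); z = 0 when sd = 0.

    Uses the sample (n-1) standard deviation.  A degenerate null
    (all shuffled energies equal, e.g. a homopolymer window) yields 0 by
    convention rather than an undefined value.
    """
    arr = np.asarray(shuffled_dgs, dtype=float)
    if arr.size < 2:
        raise ValueError("z-score requires at least 2 shuffled energies")
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        return 0.0
    return float((native_dg - arr.mean()) / sd)


def pvalue(native_dg: float, shuffled_dgs: Sequence[float]) -> float:
    """Fraction of shuffled energies at or below the native energy."""
    arr = np.asarray(shuffled_dgs, dtype=float)
    if arr.size < 1:
        raise ValueError("p-value requires at least 1 shuffled energy")
    return float(np.count_nonzero(arr <= native_dg) / arr.size)


def n_windows(length: int, window: int, step: int) -> int:
    if length < window:
        return 0
    return (length - window) // step + 1


def scan_transcript(
    transcript: Transcript,
    params: Optional[ScanParams] = None,
    backend: Optional[FoldBackend] = None,
) -> list[WindowMetrics]:
    """Scan one transcript, returning one :class:`WindowMetrics` per window.

    Windows are ordered by start; reproducibility is guaranteed for a
    fixed (transcript, params, seed) triple because each window draws
    its shuffles from a dedicated RNG stream.
    """
    params = params or ScanParams()
    backend = backend or get_backend()
    seq = transcript.sequence
    if len(seq) < params.window:
        raise ValueError(
            f"transcript {transcript.transcript_id!r} length {len(seq)} is "
            f"shorter than the {params.window}-nt window; filter it out first"
        )
    out: list[WindowMetrics] = []
    for start0 in range(0, len(seq) - params.window + 1, params.step):
        wseq = seq[start0 : start0 + params.window]
        native = backend.mfe_fold(wseq, params.temperature_c)
        ed = backend.ensemble_diversity(wseq, params.temperature_c)
        rng = window_rng(params.shuffle.seed, transcript.transcript_id, start0 + 1)
        shuffled_dgs = np.empty(params.shuffle.n_randomizations)
        for r in range(params.shuffle.n_randomizations):
            rand_seq = shuffle_sequence(wseq, params.shuffle, rng)
            shuffled_dgs[r] = backend.mfe_energy(rand_seq, params.temperature_c)
        sd = float(shuffled_dgs.std(ddof=1)) if shuffled_dgs.size > 1 else 0.0
        degenerate = sd == 0.0
        z = 0.0 if degenerate else zscore(native.delta_g, shuffled_dgs)
        p = 1.0 if degenerate else pvalue(native.delta_g, shuffled_dgs)
        if degenerate:
            logger.debug(
                "window %d of %s has a degenerate shuffle null (sd=0)",
                start0 + 1,
                transcript.transcript_id,
            )
        out.append(
            WindowMetrics(
                start=start0 + 1,
                end=start0 + params.window,
                native_dg=native.delta_g,
                z=z,
                p=p,
                ed=float(ed),
                sequence=wseq,
                structure=native.structure,
                degenerate=degenerate,
            )
        )
    return out


def per_nt_zavg(windows: Iterable[WindowMetrics], transcript_length: int) -> np.ndarray:
    """Mean window z-score over all windows covering each nucleotide.

    Returns a float vector of ``transcript_length`` (index 0 = position 1);
    positions covered by no window are NaN.
    """
    total = np.zeros(transcript_length)
    cover = np.zeros(transcript_length, dtype=int)
    for w in windows:
        if w.end > transcript_length:
            raise ValueError(f"window {w.start}-{w.end} exceeds transcript length")
        total[w.start - 1 : w.end] += w.z
        cover[w.start - 1 : w.end] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(cover > 0, total / np.maximum(cover, 1), np.nan)
    return out


# ---------------------------------------------------------------------------
# Tabular / track output

_SCAN_COLUMNS = ["start", "end", "native_dg", "z", "p", "ed", "sequence", "structure"]


def write_scan_table(windows: Iterable[WindowMetrics], destination: Union[str, Path, IO[str]]) -> None:
    """Tab-separated per-window scan table (one row per window)."""
    own = isinstance(destination, (str, Path))
    handle = open(destination, "w") if own else destination
    try:
        handle.write("\t".join(_SCAN_COLUMNS) + "\n")
        for w in windows:
            handle.write(
                f"{w.start}\t{w.end}\t{w.native_dg:.2f}\t{w.z:.4f}\t{w.p:.2f}\t"
                f"{w.ed:.2f}\t{w.sequence}\t{w.structure}\n"
            )
    finally:
        if own:
            handle.close()


def read_scan_table(source: Union[str, Path, IO[str]]) -> list[WindowMetrics]:
    own = isinstance(source, (str, Path))
    handle = open(source) if own else source
    try:
        header = handle.readline().rstrip("\n").split("\t")
        if header != _SCAN_COLUMNS:
            raise ValueError(f"unexpected scan table header: {header}")
        out = []
        for line in handle:
            if not line.strip():
                continue
            s, e, dg, z, p, ed, seq, db = line.rstrip("\n").split("\t")
            out.append(
                WindowMetrics(
                    start=int(s),
                    end=int(e),
                    native_dg=float(dg),
                    z=float(z),
                    p=float(p),
                    ed=float(ed),
                    sequence=seq,
                    structure=db,
                )
            )
        return out
    finally:
        if own:
            handle.close()


def write_wig(
    values: Sequence[float],
    destination: Union[str, Path, IO[str]],
    chrom: str,
    span_start: int = 1,
) -> None:
    """fixedStep wig track (step 1); NaN values written as ``NA``."""
    own = isinstance(destination, (str, Path))
    handle = open(destination, "w") if own else destination
    try:
        handle.write(f"fixedStep chrom={chrom} start={span_start} step=1\n")
        for v in values:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                handle.write("NA\n")
            else:
                handle.write(f"{v:.4f}\n")
    finally:
        if own:
            handle.close()


def read_wig(source: Union[str, Path, IO[str]]) -> tuple[str, np.ndarray]:
    """Read a single fixedStep wig track; returns (chrom, values with NaN)."""
    own = isinstance(source, (str, Path))
    handle = open(source) if own else source
    try:
        header = handle.readline().split()
        if not header or header[0] != "fixedStep":
            raise ValueError("expected a fixedStep wig header")
        fields = dict(kv.split("=") for kv in header[1:])
        chrom = fields.get("chrom", "")
        values = []
        for line in handle:
            line = line.strip()
            if not line:
                continue
            values.append(np.nan if line == "NA" else float(line))
        return chrom, np.asarray(values)
    finally:
        if own:
            handle.close()
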