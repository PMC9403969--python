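"""End-to-end convenience wrapper: scan -> consensus -> motifs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from rnascan.consensus import (
    FinalPartners,
    Motif,
    accumulate_pairs,
    compute_znorm,
    extract_motifs,
    paired_window_counts,
    resolve_competition,
)
from rnascan.fold import FoldBackend
from rnascan.scan import ScanParams, WindowMetrics, per_nt_zavg, scan_transcript
from rnascan.seqio import Transcript

__all__ = ["TranscriptResult", "analyze_transcript", "fold_from_windows"]


@dataclass
class TranscriptResult:
    transcript: Transcript
    windows: list[WindowMetrics]
    per_nt_z: np.ndarray
    final: FinalPartners
    motifs_m1: list[Motif]
    motifs_m2: list[Motif]


def fold_from_windows(
    transcript: Transcript,
    windows: list[WindowMetrics],
    znorm_denominator: str = "pair",
) -> tuple[np.ndarray, FinalPartners]:
    """Consensus stage alone, from precomputed scan windows."""
    per_nt = per_nt_zavg(windows, len(transcript))
    stats = accumulate_pairs(windows)
    counts = (
        paired_window_counts(windows, len(transcript))
        if znorm_denominator == "nucleotide"
        else None
    )
    compute_znorm(stats, denominator=znorm_denominator, paired_counts=counts)
    final = resolve_competition(stats, len(transcript), per_nt_z=per_nt)
    return per_nt, final


def analyze_transcript(
    transcript: Transcript,
    params: Optional[ScanParams] = None,
    backend: Optional[FoldBackend] = None,
    znorm_denominator: str = "pair",
) -> TranscriptResult:
    """Scan a transcript and build its consensus structure and motifs."""
    windows = scan_transcript(transcript, params, backend)
    per_nt, final = fold_from_windows(transcript, windows, znorm_denominator)
    return TranscriptResult(
        transcript=transcript,
        windows=windows,
        per_nt_z=per_nt,
        final=final,
        motifs_m1=extract_motifs(final, -1.0, transcript.sequence),
        motifs_m2=extract_motifs(final, -2.0, transcript.sequence),
    )
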