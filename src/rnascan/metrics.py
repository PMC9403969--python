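"""Per-transcript and regional aggregation, expression-class summaries,
and covariation-power binning."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from rnascan.consensus import Motif
from rnascan.scan import WindowMetrics
from rnascan.seqio import Transcript

__all__ = [
    "TranscriptMetrics",
    "RegionalZ",
    "PowerBinSummary",
    "transcript_metrics",
    "regional_zavg",
    "motif_region",
    "expression_group_summary",
    "bin_power",
    "read_power_table",
    "read_gene_groups",
    "metrics_to_frame",
]


@dataclass(frozen=True)
class TranscriptMetrics:
    """Whole-transcript aggregates over scan windows and motif counts."""

    transcript_id: str
    length: int
    n_windows: int
    mean_windowed_dg: float
    mean_windowed_z: float
    mean_windowed_ed: float
    pct_windows_z_le_m1: float
    pct_windows_z_le_m2: float
    n_motifs_le_m1: int
    n_motifs_le_m2: int


@dataclass(frozen=True)
class RegionalZ:
    """Per-region means of the per-nucleotide windowed z-average.

    Means are computed only over annotated, window-covered positions;
    regions lacking annotation (or fully uncovered) are NaN with count 0.
    """

    utr5_mean: float
    cds_mean: float
    utr3_mean: float
    utr5_n: int
    cds_n: int
    utr3_n: int


@dataclass(frozen=True)
class PowerBinSummary:
    """Counts of covarying pairs binned by power: [0,0.1), [0.1,0.25), >=0.25."""

    low: int
    mid: int
    high: int

    @property
    def total(self) -> int:
        return self.low + self.mid + self.high


def transcript_metrics(
    windows: Sequence[WindowMetrics],
    motifs_m1: Sequence[Motif],
    motifs_m2: Sequence[Motif],
    transcript: Transcript,
) -> TranscriptMetrics:
    """Arithmetic window means and z-threshold percentages (inclusive <=)."""
    if not windows:
        raise ValueError(
            f"transcript {transcript.transcript_id!r} has no scan windows; "
            "it should have been length-filtered"
        )
    z = np.array([w.z for w in windows])
    return TranscriptMetrics(
        transcript_id=transcript.transcript_id,
        length=len(transcript),
        n_windows=len(windows),
        mean_windowed_dg=float(np.mean([w.native_dg for w in windows])),
        mean_windowed_z=float(z.mean()),
        mean_windowed_ed=float(np.mean([w.ed for w in windows])),
        pct_windows_z_le_m1=float(100.0 * np.count_nonzero(z <= -1) / z.size),
        pct_windows_z_le_m2=float(100.0 * np.count_nonzero(z <= -2) / z.size),
        n_motifs_le_m1=len(motifs_m1),
        n_motifs_le_m2=len(motifs_m2),
    )


def _region_mean(per_nt_z: np.ndarray, span) -> tuple[float, int]:
    if span is None:
        return float("nan"), 0
    a, b = span
    vals = per_nt_z[a - 1 : b]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)


def regional_zavg(per_nt_z: np.ndarray, transcript: Transcript) -> RegionalZ:
    """Mean per-nucleotide z-average within each annotated region span."""
    if transcript.utr5 is None and transcript.cds is None and transcript.utr3 is None:
        raise ValueError(
            f"transcript {transcript.transcript_id!r} has no region annotation"
        )
    if len(per_nt_z) != len(transcript):
        raise ValueError("per-nt z vector length does not match transcript")
    u5, n5 = _region_mean(per_nt_z, transcript.utr5)
    cd, nc = _region_mean(per_nt_z, transcript.cds)
    u3, n3 = _region_mean(per_nt_z, transcript.utr3)
    return RegionalZ(u5, cd, u3, n5, nc, n3)


def motif_region(span: tuple[int, int], transcript: Transcript) -> Optional[str]:
    """Region (utr5/cds/utr3) holding the majority of a motif span.

    Ties break toward the 3' end; None when the transcript is
    unannotated or the span has no overlap with any region.
    """
    a, b = span
    best: Optional[str] = None
    best_overlap = 0
    for name in ("utr5", "cds", "utr3"):
        region = getattr(transcript, name)
        if region is None:
            continue
        overlap = min(b, region[1]) - max(a, region[0]) + 1
        if overlap > 0 and overlap >= best_overlap:
            best, best_overlap = name, overlap
    return best


def metrics_to_frame(metrics: Iterable[TranscriptMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in metrics])


def expression_group_summary(
    metrics_table: pd.DataFrame,
    gene_to_group: Mapping[str, str],
    gene_column: str = "gene_name",
) -> tuple[pd.DataFrame, int]:
    """Per-group means of mean windowed dG and z.

    ``metrics_table`` must carry ``gene_column``, ``mean_windowed_dg`` and
    ``mean_windowed_z``; genes with several analyzed transcripts
    contribute every transcript (transcript-weighted means).  Returns the
    per-group summary and the count of table rows whose gene has no
    group label (excluded from the means).
    """
    required = {gene_column, "mean_windowed_dg", "mean_windowed_z"}
    missing = required - set(metrics_table.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns: {sorted(missing)}")
    table = metrics_table.copy()
    table["group"] = table[gene_column].map(dict(gene_to_group))
    unmatched = int(table["group"].isna().sum())
    matched = table.dropna(subset=["group"])
    summary = (
        matched.groupby("group")
        .agg(
            n_transcripts=("mean_windowed_z", "size"),
            mean_dg=("mean_windowed_dg", "mean"),
            mean_z=("mean_windowed_z", "mean"),
        )
        .reset_index()
    )
    return summary, unmatched


def bin_power(power_records: Iterable[tuple[int, int, float]]) -> PowerBinSummary:
    """Bin covariation power values into [0, 0.1), [0.1, 0.25), [0.25, inf).

    Boundaries are lower-inclusive, so 0.1 lands in the middle bin and
    0.25 in the top bin.
    """
    low = mid = high = 0
    for _i, _j, power in power_records:
        if power < 0:
            raise ValueError(f"negative covariation power {power}")
        if power < 0.1:
            low += 1
        elif power < 0.25:
            mid += 1
        else:
            high += 1
    return PowerBinSummary(low, mid, high)


def read_power_table(source: Union[str, Path, IO[str]]) -> list[tuple[int, int, float]]:
    """Parse an R-scape-style base-pair power table.

    Comment lines (starting with ``#``) are skipped; each data line must
    carry two integer positions followed by a power value in its last
    numeric column.
    """
    own = isinstance(source, (str, Path))
    handle = open(source) if own else source
    records: list[tuple[int, int, float]] = []
    try:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            numeric = []
            for p in parts:
                try:
                    numeric.append(float(p))
                except ValueError:
                    continue
            if len(numeric) < 3:
                raise ValueError(f"cannot parse power record: {line!r}")
            records.append((int(numeric[0]), int(numeric[1]), float(numeric[-1])))
        return records
    finally:
        if own:
            handle.close()


def read_gene_groups(
    source: Union[str, Path, IO[str]],
    gene_column: str = "gene",
    group_column: str = "group",
) -> dict[str, str]:
    """Gene-list TSV reader (columns: gene, group)."""
    df = pd.read_csv(source, sep="\t")
    if gene_column not in df.columns or group_column not in df.columns:
        raise ValueError(
            f"gene list must have columns {gene_column!r} and {group_column!r}"
        )
    return dict(zip(df[gene_column].astype(str), df[group_column].astype(str)))
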