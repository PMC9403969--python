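"""Z-score-weighted consensus base pairing across scan windows.

Base pairs observed in window MFE structures are accumulated in
transcript coordinates.  Each distinct pair carries the number of
windows it occurred in and the sum of those windows' z-scores (Zsum);
normalizing Zsum by window exposure yields Znorm, the ranking metric.
Pairing competition is resolved greedily in ascending Znorm under the
one-partner-per-nucleotide constraint; surviving crossing pairs are
pruned before motif extraction so emitted structures are nested.
Motifs are maximal nested components containing at least one pair at or
below a z-score threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np

from rnascan.fold import dotbracket_to_pairs
from rnascan.scan import WindowMetrics

__all__ = [
    "PairStats",
    "FinalPartners",
    "Motif",
    "accumulate_pairs",
    "paired_window_counts",
    "compute_znorm",
    "resolve_competition",
    "remove_crossings",
    "classify_pairs",
    "zclass",
    "extract_motifs",
    "write_final_partners",
    "write_motifs_gff3",
    "write_motif_ct",
    "write_motif_dbn",
    "write_arc_track",
]


@dataclass
class PairStats:
    """Accumulated statistics for one (i, j) base pair, 1-based, i < j."""

    i: int
    j: int
    n_windows: int = 0
    zsum: float = 0.0
    znorm: Optional[float] = None


@dataclass
class FinalPartners:
    """Consensus pairing after competition resolution.

    ``partner`` is indexed 1..length (entry 0 unused); 0 means unpaired.
    ``annotation`` carries the pair Znorm at paired positions and the
    per-nucleotide windowed z-average at unpaired positions.
    """

    length: int
    partner: np.ndarray
    pair_znorm: dict[tuple[int, int], float] = dataclass_field(default_factory=dict)
    annotation: Optional[np.ndarray] = None

    @property
    def pairs(self) -> list[tuple[int, int]]:
        out = []
        for i in range(1, self.length + 1):
            j = int(self.partner[i])
            if j > i:
                out.append((i, j))
        return out


@dataclass(frozen=True)
class Motif:
    """A maximal nested component of the consensus pairing."""

    start: int
    end: int
    pairs: tuple[tuple[int, int], ...]
    pair_z: tuple[float, ...]
    min_pair_z: float
    sequence: str
    structure: str

    def __len__(self) -> int:
        return self.end - self.start + 1


def accumulate_pairs(windows: Iterable[WindowMetrics]) -> list[PairStats]:
    """Record every base pair occurring in window structures.

    Pairs are mapped to transcript coordinates via the window start.
    Returns one :class:`PairStats` per distinct pair, sorted by (i, j).
    """
    table: dict[tuple[int, int], PairStats] = {}
    for w in windows:
        try:
            local_pairs = dotbracket_to_pairs(w.structure)
        except ValueError as exc:
            raise ValueError(f"window {w.start}-{w.end}: {exc}") from exc
        for a, b in local_pairs:
            key = (w.start + a, w.start + b)
            stats = table.get(key)
            if stats is None:
                stats = table[key] = PairStats(i=key[0], j=key[1])
            stats.n_windows += 1
            stats.zsum += w.z
    return [table[k] for k in sorted(table)]


def paired_window_counts(windows: Iterable[WindowMetrics], length: int) -> np.ndarray:
    """Per-position count of windows in which the nucleotide is paired at all.

    Indexed 1..length (entry 0 unused).  Used by the alternative Znorm
    denominator.
    """
    counts = np.zeros(length + 1, dtype=int)
    for w in windows:
        for a, b in dotbracket_to_pairs(w.structure):
            counts[w.start + a] += 1
            counts[w.start + b] += 1
    return counts


def compute_znorm(
    pair_stats: Sequence[PairStats],
    denominator: str = "pair",
    paired_counts: Optional[np.ndarray] = None,
) -> list[PairStats]:
    """Fill in Znorm = Zsum / exposure for every pair.

    ``denominator='pair'`` (default) divides by the number of windows the
    exact pair occurs in, making Znorm the mean z of its windows.
    ``denominator='nucleotide'`` divides by the mean over both endpoints
    of the number of windows in which the nucleotide is paired to any
    partner (requires ``paired_counts``).
    """
    if denominator not in ("pair", "nucleotide"):
        raise ValueError("denominator must be 'pair' or 'nucleotide'")
    if denominator == "nucleotide" and paired_counts is None:
        raise ValueError("nucleotide denominator requires paired_counts")
    for ps in pair_stats:
        if denominator == "pair":
            denom = ps.n_windows
        else:
            denom = (paired_counts[ps.i] + paired_counts[ps.j]) / 2.0
        ps.znorm = ps.zsum / denom
    return list(pair_stats)


def resolve_competition(
    pair_stats: Sequence[PairStats],
    length: int,
    per_nt_z: Optional[np.ndarray] = None,
) -> FinalPartners:
    """Greedy global selection in ascending Znorm ("competition of 1").

    A pair is accepted iff both endpoints are still unpartnered; ties are
    broken deterministically by (i, j).  When ``per_nt_z`` (0-based
    vector from the scan stage) is given, unpaired positions are
    annotated with it.
    """
    missing = [ps for ps in pair_stats if ps.znorm is None]
    if missing:
        raise ValueError("znorm must be computed before resolving competition")
    partner = np.zeros(length + 1, dtype=int)
    pair_znorm: dict[tuple[int, int], float] = {}
    for ps in sorted(pair_stats, key=lambda p: (p.znorm, p.i, p.j)):
        if partner[ps.i] == 0 and partner[ps.j] == 0:
            partner[ps.i] = ps.j
            partner[ps.j] = ps.i
            pair_znorm[(ps.i, ps.j)] = float(ps.znorm)
    annotation = np.full(length + 1, np.nan)
    if per_nt_z is not None:
        annotation[1:] = np.asarray(per_nt_z, dtype=float)
    for (i, j), z in pair_znorm.items():
        annotation[i] = z
        annotation[j] = z
    return FinalPartners(length=length, partner=partner, pair_znorm=pair_znorm, annotation=annotation)


def _crosses(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = p, q
    return (i < k < j < l) or (k < i < l < j)


def remove_crossings(final: FinalPartners) -> list[tuple[int, int]]:
    """Nested subset of the accepted pairs.

    Crossing (pseudoknot-like) pairs that survive greedy selection are
    resolved by keeping the lower-Znorm pair of each crossing; ties break
    by (i, j).  The pair track itself is left untouched.
    """
    ordered = sorted(final.pair_znorm.items(), key=lambda kv: (kv[1], kv[0]))
    kept: list[tuple[int, int]] = []
    for pair, _z in ordered:
        if all(not _crosses(pair, other) for other in kept):
            kept.append(pair)
    return sorted(kept)


def zclass(z: float) -> str:
    """Z-score class band with inclusive boundaries: <=-2, <=-1, <0, >=0."""
    if z <= -2:
        return "z<=-2"
    if z <= -1:
        return "z<=-1"
    if z < 0:
        return "z<0"
    return "z>=0"


def classify_pairs(final: FinalPartners) -> dict[tuple[int, int], str]:
    """Class band per accepted pair (for arc-track coloring)."""
    return {pair: zclass(z) for pair, z in final.pair_znorm.items()}


def extract_motifs(
    final: FinalPartners,
    threshold_z: float,
    sequence: str,
) -> list[Motif]:
    """Extract maximal nested components with min pair Znorm <= threshold.

    Pairs with Znorm >= 0 never contribute to motifs.  Components run
    from an outermost pair to its partner, including internal unpaired
    stretches; isolated pairs form one-pair motifs.  Motifs are sorted
    by start.
    """
    if len(sequence) != final.length:
        raise ValueError("sequence length does not match final partners")
    nested = [p for p in remove_crossings(final) if final.pair_znorm[p] < 0]
    if not nested:
        return []
    # Outermost pairs: not enclosed by any other kept pair.
    motifs: list[Motif] = []
    for outer in nested:
        if any(q[0] < outer[0] and outer[1] < q[1] for q in nested if q != outer):
            continue
        i0, j0 = outer
        members = [p for p in nested if i0 <= p[0] and p[1] <= j0]
        zs = tuple(final.pair_znorm[p] for p in members)
        min_z = min(zs)
        if min_z > threshold_z:
            continue
        db = []
        paired = {p[0]: p[1] for p in members}
        paired.update({p[1]: p[0] for p in members})
        for pos in range(i0, j0 + 1):
            q = paired.get(pos)
            if q is None:
                db.append(".")
            else:
                db.append("(" if q > pos else ")")
        motifs.append(
            Motif(
                start=i0,
                end=j0,
                pairs=tuple(members),
                pair_z=zs,
                min_pair_z=min_z,
                sequence=sequence[i0 - 1 : j0],
                structure="".join(db),
            )
        )
    return sorted(motifs, key=lambda m: m.start)


# ---------------------------------------------------------------------------
# Writers


def _open(destination, mode="w"):
    own = isinstance(destination, (str, Path))
    return (open(destination, mode) if own else destination), own


def write_final_partners(
    final: FinalPartners, destination: Union[str, Path, IO[str]]
) -> None:
    """TSV: position, partner (0 = unpaired), z annotation, class."""
    handle, own = _open(destination)
    try:
        handle.write("position\tpartner\tz\tclass\n")
        ann = final.annotation
        for i in range(1, final.length + 1):
            z = float(ann[i]) if ann is not None else math.nan
            ztxt = "NA" if math.isnan(z) else f"{z:.4f}"
            cls = zclass(z) if not math.isnan(z) else "NA"
            handle.write(f"{i}\t{int(final.partner[i])}\t{ztxt}\t{cls}\n")
    finally:
        if own:
            handle.close()


def write_motifs_gff3(
    motifs: Iterable[Motif],
    destination: Union[str, Path, IO[str]],
    seqid: str,
    source: str = "rnascan",
) -> None:
    """1-based GFF3 with min_pair_z and class attributes per motif."""
    handle, own = _open(destination)
    try:
        handle.write("##gff-version 3\n")
        for k, m in enumerate(motifs, start=1):
            attrs = (
                f"ID=motif_{k};min_pair_z={m.min_pair_z:.4f};"
                f"zclass={zclass(m.min_pair_z)};n_pairs={len(m.pairs)}"
            )
            handle.write(
                f"{seqid}\t{source}\tRNA_motif\t{m.start}\t{m.end}\t"
                f"{m.min_pair_z:.4f}\t+\t.\t{attrs}\n"
            )
    finally:
        if own:
            handle.close()


def write_motif_ct(
    motif: Motif, destination: Union[str, Path, IO[str]], title: str = ""
) -> None:
    """Standard 6-column CT file for one motif (local coordinates).

    Column 6 keeps the original transcript position.
    """
    handle, own = _open(destination)
    try:
        n = len(motif)
        local = {pos: pos - motif.start + 1 for pos in range(motif.start, motif.end + 1)}
        pairs_both = dict(motif.pairs)
        pairs_both.update({j: i for i, j in motif.pairs})
        handle.write(f"{n} {title or f'motif {motif.start}-{motif.end}'}\n")
        for pos in range(motif.start, motif.end + 1):
            k = local[pos]
            mate = local.get(pairs_both.get(pos, 0), 0)
            base = motif.sequence[k - 1]
            nxt = k + 1 if k < n else 0
            handle.write(f"{k} {base} {k - 1} {nxt} {mate} {pos}\n")
    finally:
        if own:
            handle.close()


def write_motif_dbn(
    motif: Motif, destination: Union[str, Path, IO[str]], title: str = ""
) -> None:
    handle, own = _open(destination)
    try:
        handle.write(f">{title or f'motif {motif.start}-{motif.end}'}\n")
        handle.write(motif.sequence + "\n")
        handle.write(motif.structure + "\n")
    finally:
        if own:
            handle.close()


def write_arc_track(
    final: FinalPartners, destination: Union[str, Path, IO[str]]
) -> None:
    """Base-pair arc track: position_i, position_j, class (TSV)."""
    handle, own = _open(destination)
    try:
        handle.write("position_i\tposition_j\tzclass\n")
        for (i, j), z in sorted(final.pair_znorm.items()):
            handle.write(f"{i}\t{j}\t{zclass(z)}\n")
    finally:
        if own:
            handle.close()
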