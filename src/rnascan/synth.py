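"""Synthetic-data generators with recorded ground truth.

Transcripts are i.i.d. mononucleotide background (matching the
mononucleotide shuffle null, so background windows calibrate to z near
0) with optional planted GC-rich hairpins whose stems are perfect
Watson-Crick complements.  Every planted pair is recorded so recovery
statistics are computed against the record rather than re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping, Optional, Sequence, Union

import numpy as np

from rnascan.roc import ReactivityProfile
from rnascan.seqio import Transcript

__all__ = ["PlantedTranscript", "make_transcript", "make_reactivity", "write_reactivity"]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

DEFAULT_BACKGROUND = {"A": 0.3, "C": 0.2, "G": 0.2, "U": 0.3}


@dataclass(frozen=True)
class PlantedTranscript:
    """A synthetic transcript plus the ground truth planted into it."""

    transcript: Transcript
    motif_spans: tuple[tuple[int, int], ...]
    stem_pairs: tuple[tuple[tuple[int, int], ...], ...]
    background_freqs: tuple[float, float, float, float]  # A, C, G, U
    seed: int


def _draw_background(rng: np.random.Generator, n: int, freqs: Sequence[float]) -> list[str]:
    letters = rng.choice(np.array(list("ACGU")), size=n, p=np.asarray(freqs))
    return list(letters)


def make_transcript(
    length: int = 300,
    n_motifs: int = 1,
    stem_len: int = 10,
    loop_len: int = 5,
    region_layout: Optional[tuple[int, int, int]] = None,
    background_freqs: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    transcript_id: Optional[str] = None,
) -> PlantedTranscript:
    """Generate a transcript with ``n_motifs`` planted GC-rich hairpins.

    ``region_layout`` gives (utr5, cds, utr3) lengths summing to
    ``length``; when omitted the transcript is unannotated.  Motifs are
    placed uniformly at random without overlap; generation is
    deterministic for a fixed seed.
    """
    freqs = dict(background_freqs or DEFAULT_BACKGROUND)
    probs = [freqs.get(b, 0.0) for b in "ACGU"]
    total = sum(probs)
    if total <= 0:
        raise ValueError("background frequencies must sum to a positive value")
    probs = [p / total for p in probs]
    motif_len = 2 * stem_len + loop_len
    if n_motifs < 0 or stem_len < 1 or loop_len < 3:
        raise ValueError("need n_motifs >= 0, stem_len >= 1, loop_len >= 3")
    if n_motifs * motif_len > length:
        raise ValueError("planted motifs do not fit in the requested length")
    if region_layout is not None and sum(region_layout) != length:
        raise ValueError("region_layout lengths must sum to the transcript length")
    rng = np.random.default_rng(seed)
    letters = _draw_background(rng, length, probs)

    # Choose non-overlapping motif start offsets (0-based).
    spans: list[tuple[int, int]] = []
    all_pairs: list[tuple[tuple[int, int], ...]] = []
    attempts = 0
    while len(spans) < n_motifs:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place motifs without overlap")
        s0 = int(rng.integers(0, length - motif_len + 1))
        if any(not (s0 + motif_len <= a - 1 or s0 >= b) for a, b in spans):
            continue
        # GC-rich left arm; right arm is its reverse complement.
        arm = [
            str(rng.choice(list("GC"))) if rng.random() < 0.8 else str(rng.choice(list("AU")))
            for _ in range(stem_len)
        ]
        loop = ["A"] * loop_len
        right = [_COMPLEMENT[b] for b in reversed(arm)]
        letters[s0 : s0 + motif_len] = arm + loop + right
        start1 = s0 + 1
        end1 = s0 + motif_len
        spans.append((start1, end1))
        all_pairs.append(
            tuple((start1 + k, end1 - k) for k in range(stem_len))
        )

    regions: dict[str, Optional[tuple[int, int]]] = {"utr5": None, "cds": None, "utr3": None}
    if region_layout is not None:
        u5, cd, u3 = region_layout
        cursor = 0
        for name, rl in (("utr5", u5), ("cds", cd), ("utr3", u3)):
            if rl > 0:
                regions[name] = (cursor + 1, cursor + rl)
            cursor += rl

    order = np.argsort([s[0] for s in spans])
    transcript = Transcript(
        transcript_id=transcript_id or f"SYNT{seed:08d}.1",
        gene_name="SYN",
        sequence="".join(letters),
        utr5=regions["utr5"],
        cds=regions["cds"],
        utr3=regions["utr3"],
    )
    return PlantedTranscript(
        transcript=transcript,
        motif_spans=tuple(spans[k] for k in order),
        stem_pairs=tuple(all_pairs[k] for k in order),
        background_freqs=tuple(probs),
        seed=seed,
    )


def make_reactivity(
    structure: str,
    noise_sd: float = 0.1,
    seed: int = 0,
    paired_mean: float = 0.1,
    unpaired_mean: float = 0.9,
    probe: str = "synthetic",
) -> ReactivityProfile:
    """Reactivity profile generated from a dot-bracket ground truth.

    Paired positions draw from the low mean, unpaired from the high
    mean, with Gaussian noise truncated at zero.
    """
    balance = 0
    for c in structure:
        if c == "(":
            balance += 1
        elif c == ")":
            balance -= 1
            if balance < 0:
                raise ValueError("unbalanced structure")
        elif c != ".":
            raise ValueError(f"unsupported character {c!r}")
    if balance != 0:
        raise ValueError("unbalanced structure")
    rng = np.random.default_rng(seed)
    means = np.where(
        np.array([c == "." for c in structure]), unpaired_mean, paired_mean
    )
    values = means + rng.normal(0.0, noise_sd, size=len(structure)) if noise_sd > 0 else means.astype(float)
    return ReactivityProfile(values=np.maximum(values, 0.0), probe=probe)


def write_reactivity(
    profile: ReactivityProfile, destination: Union[str, Path, IO[str]]
) -> None:
    """Two-column (position, value) text writer; NaN as NA."""
    own = isinstance(destination, (str, Path))
    handle = open(destination, "w") if own else destination
    try:
        for pos, val in enumerate(profile.values, start=1):
            txt = "NA" if np.isnan(val) else f"{val:.4f}"
            handle.write(f"{pos}\t{txt}\n")
    finally:
        if own:
            handle.close()
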