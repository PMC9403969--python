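"""Composition-preserving sequence randomization for the z-score null.

Two modes are provided: mononucleotide shuffling (a plain permutation,
preserving the letter counts) and dinucleotide shuffling via the
Altschul–Erickson method (a random Euler path on the dinucleotide
multigraph, preserving all 16 dinucleotide counts as well as the first
and last letters).

Per-window random streams are derived deterministically from a global
seed, the transcript identifier and the window start so that results are
reproducible and independent of evaluation order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShuffleConfig",
    "shuffle_mononucleotide",
    "shuffle_dinucleotide",
    "shuffle_sequence",
    "window_rng",
]


@dataclass(frozen=True)
class ShuffleConfig:
    """Randomization settings for the scanning null model."""

    mode: str = "mononucleotide"
    n_randomizations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("mononucleotide", "dinucleotide"):
            raise ValueError(f"unknown shuffle mode {self.mode!r}")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")


def window_rng(seed: int, transcript_id: str, window_start: int) -> np.random.Generator:
    """Deterministic per-window RNG stream.

    The transcript identifier is hashed so that streams do not collide
    across transcripts and do not depend on processing order.
    """
    digest = hashlib.sha256(transcript_id.encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([seed, *words, window_start]))


def shuffle_mononucleotide(sequence: str, rng: np.random.Generator) -> str:
    """Random permutation of the sequence letters."""
    if not sequence:
        raise ValueError("cannot shuffle empty sequence")
    letters = np.frombuffer(sequence.encode(), dtype="S1")
    return b"".join(rng.permutation(letters)).decode()


def _euler_last_edges(
    adjacency: dict[str, list[str]], terminal: str, rng: np.random.Generator
) -> dict[str, str]:
    """Pick a random last-edge per vertex forming an arborescence to ``terminal``.

    Rejection-samples uniformly over candidate edge choices until the chosen
    edges form a tree pointing at the terminal vertex, which is the
    Altschul–Erickson condition for the edge ordering to admit an Euler path.
    """
    vertices = [v for v in adjacency if v != terminal and adjacency[v]]
    while True:
        last = {v: adjacency[v][rng.integers(len(adjacency[v]))] for v in vertices}
        # Every chosen-edge chain must reach the terminal vertex.
        ok = True
        for v in vertices:
            seen = set()
            cur = v
            while cur != terminal:
                if cur in seen or cur not in last:
                    ok = False
                    break
                seen.add(cur)
                cur = last[cur]
            if not ok:
                break
        if ok:
            return last


def shuffle_dinucleotide(sequence: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson dinucleotide shuffle.

    Preserves all dinucleotide counts and the first and last letters.
    """
    if len(sequence) < 2:
        raise ValueError("dinucleotide shuffle requires length >= 2")
    adjacency: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, [])
    terminal = sequence[-1]
    last = _euler_last_edges(adjacency, terminal, rng)
    ordered: dict[str, list[str]] = {}
    for v, edges in adjacency.items():
        edges = list(edges)
        if v in last:
            edges.remove(last[v])
        order = rng.permutation(len(edges))
        shuffled = [edges[k] for k in order]
        if v in last:
            shuffled.append(last[v])
        ordered[v] = shuffled
    # Walk the Euler path consuming edges in the arranged order.
    out = [sequence[0]]
    cursors = {v: 0 for v in ordered}
    cur = sequence[0]
    for _ in range(len(sequence) - 1):
        nxt = ordered[cur][cursors[cur]]
        cursors[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffle_sequence(sequence: str, config: ShuffleConfig, rng: np.random.Generator) -> str:
    """Shuffle according to ``config.mode``."""
    if config.mode == "mononucleotide":
        return shuffle_mononucleotide(sequence, rng)
    return shuffle_dinucleotide(sequence, rng)
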