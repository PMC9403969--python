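"""Folding backend contract: MFE structure/energy and ensemble diversity.

The folding algorithm itself is delegated to a backend behind a small
adapter interface so that engines are swappable:

``builtin``
    A pure-Python/numba nearest-neighbor folder (stacking energies,
    hairpin initiation, flat branch penalty) that ships with the package
    and has no binary dependency.  Its ensemble diversity comes from a
    simplified pair-energy Boltzmann model.  Only 37 degrees C is
    supported.
``vienna``
    ViennaRNA (RNAlib Python bindings), used when installed; full Turner
    parameters and partition function.

Energies are kcal/mol; structures are dot-bracket strings; ensemble
diversity is the Boltzmann mean base-pair distance (>= 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "FoldResult",
    "FoldBackend",
    "BuiltinBackend",
    "ViennaBackend",
    "BackendUnavailableError",
    "get_backend",
    "partners_to_dotbracket",
    "dotbracket_to_pairs",
]


class BackendUnavailableError(RuntimeError):
    """A requested folding backend cannot be loaded."""


@dataclass(frozen=True)
class FoldResult:
    """MFE fold of one sequence."""

    structure: str
    delta_g: float
    ed: Optional[float] = None


def dotbracket_to_pairs(structure: str) -> list[tuple[int, int]]:
    """0-based (i, j) pairs from a dot-bracket string; raises on imbalance."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {idx + 1}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"unsupported dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket: unclosed '('")
    return sorted(pairs)


def partners_to_dotbracket(partner: np.ndarray) -> str:
    """Dot-bracket from a 0-based partner array (-1 = unpaired)."""
    out = []
    for i, j in enumerate(partner):
        if j < 0:
            out.append(".")
        elif j > i:
            out.append("(")
        else:
            out.append(")")
    return "".join(out)


class FoldBackend:
    """Adapter interface; concrete backends implement the four methods."""

    name: str = "abstract"
    version: str = "0"

    def mfe_fold(self, sequence: str, temperature_c: float = 37.0) -> FoldResult:
        raise NotImplementedError

    def mfe_energy(self, sequence: str, temperature_c: float = 37.0) -> float:
        """Energy-only fast path (no traceback)."""
        return self.mfe_fold(sequence, temperature_c).delta_g

    def ensemble_diversity(self, sequence: str, temperature_c: float = 37.0) -> float:
        raise NotImplementedError

    def energy_of_structure(
        self, sequence: str, structure: str, temperature_c: float = 37.0
    ) -> float:
        raise NotImplementedError


class BuiltinBackend(FoldBackend):
    """Self-contained nearest-neighbor folder (numba-accelerated)."""

    name = "builtin"

    def __init__(self) -> None:
        from rnascan.fold import _kernels

        self._k = _kernels
        self.version = "1"

    @staticmethod
    def _check_temperature(temperature_c: float) -> None:
        if abs(temperature_c - 37.0) > 1e-9:
            raise NotImplementedError(
                "the builtin backend has parameters only for 37 C; "
                "install ViennaRNA for other temperatures"
            )

    def mfe_fold(self, sequence: str, temperature_c: float = 37.0) -> FoldResult:
        self._check_temperature(temperature_c)
        if not sequence:
            raise ValueError("cannot fold empty sequence")
        enc = self._k.encode(sequence.upper().replace("T", "U"))
        n = enc.shape[0]
        if n < self._k.MIN_LOOP + 2:
            return FoldResult("." * n, 0.0)
        V, W1 = self._k.fill_mfe(enc)
        energy = min(0.0, W1[0, n - 1])
        partner = self._k.traceback(enc, V, W1)
        return FoldResult(partners_to_dotbracket(partner), float(round(energy, 2)))

    def mfe_energy(self, sequence: str, temperature_c: float = 37.0) -> float:
        self._check_temperature(temperature_c)
        if not sequence:
            raise ValueError("cannot fold empty sequence")
        enc = self._k.encode(sequence.upper().replace("T", "U"))
        n = enc.shape[0]
        if n < self._k.MIN_LOOP + 2:
            return 0.0
        _, W1 = self._k.fill_mfe(enc)
        return float(round(min(0.0, W1[0, n - 1]), 2))

    def ensemble_diversity(self, sequence: str, temperature_c: float = 37.0) -> float:
        self._check_temperature(temperature_c)
        enc = self._k.encode(sequence.upper().replace("T", "U"))
        P = self._k.pair_probabilities(enc)
        return float(np.sum(2.0 * P * (1.0 - P)))

    def energy_of_structure(
        self, sequence: str, structure: str, temperature_c: float = 37.0
    ) -> float:
        self._check_temperature(temperature_c)
        if len(sequence) != len(structure):
            raise ValueError("sequence/structure length mismatch")
        k = self._k
        enc = k.encode(sequence.upper().replace("T", "U"))
        pairs = dotbracket_to_pairs(structure)
        pair_set = set(pairs)
        children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
        # Direct nesting: the tightest enclosing pair is the parent.
        sorted_by_span = sorted(pairs, key=lambda p: p[1] - p[0])
        for p in pairs:
            i, j = p
            parent = None
            for q in sorted_by_span:
                a, b = q
                if a < i and j < b:
                    parent = q
                    break
            if parent is not None:
                children[parent].append(p)
        total = 0.0
        for i, j in pairs:
            pt = k.PAIR_TYPE[enc[i], enc[j]]
            if pt < 0:
                raise ValueError(f"non-canonical pair {i + 1}-{j + 1}")
            kids = children[(i, j)]
            if not kids:
                total += k._hairpin_energy(j - i - 1)
            elif (i + 1, j - 1) in pair_set:
                ptin = k.PAIR_TYPE[enc[i + 1], enc[j - 1]]
                total += k.STACK[pt, ptin]
            else:
                total += k.BRANCH
        return float(round(total, 2))


class ViennaBackend(FoldBackend):
    """ViennaRNA (RNAlib) adapter; optional dependency."""

    name = "vienna"

    def __init__(self) -> None:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - depends on env
            raise BackendUnavailableError(
                "the 'vienna' backend requires the ViennaRNA Python bindings "
                "(package RNA); install ViennaRNA or use backend='builtin'"
            ) from exc
        self._RNA = RNA
        self.version = getattr(RNA, "__version__", "unknown")

    def _fc(self, sequence: str, temperature_c: float):
        md = self._RNA.md()
        md.temperature = temperature_c
        return self._RNA.fold_compound(sequence, md)

    def mfe_fold(self, sequence: str, temperature_c: float = 37.0) -> FoldResult:
        if not sequence:
            raise ValueError("cannot fold empty sequence")
        fc = self._fc(sequence, temperature_c)
        structure, energy = fc.mfe()
        return FoldResult(structure, float(energy))

    def ensemble_diversity(self, sequence: str, temperature_c: float = 37.0) -> float:
        fc = self._fc(sequence, temperature_c)
        fc.pf()
        return float(fc.mean_bp_distance())

    def energy_of_structure(
        self, sequence: str, structure: str, temperature_c: float = 37.0
    ) -> float:
        fc = self._fc(sequence, temperature_c)
        return float(fc.eval_structure(structure))


_BACKENDS = {"builtin": BuiltinBackend, "vienna": ViennaBackend}


def get_backend(name: str = "auto") -> FoldBackend:
    """Instantiate a folding backend.

    ``auto`` prefers ViennaRNA when its bindings are importable and falls
    back to the builtin folder otherwise.
    """
    if name == "auto":
        try:
            return ViennaBackend()
        except BackendUnavailableError:
            return BuiltinBackend()
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ValueError(
            f"unknown backend {name!r}; choose from {sorted(_BACKENDS)} or 'auto'"
        ) from None
    return cls()
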