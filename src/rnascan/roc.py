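"""ROC comparison of structure models (CT files) against chemical-probing
reactivity profiles.

Reactivity thresholds sweep from 0% to 100% in 1% steps; at x% the x% of
applicable positions with the *lowest* reactivity are called paired (low
reactivity implies pairing).  TPR = TP/(TP+FN) and FPR = FP/(FP+TN) are
computed against the pairing status in the CT file, and the area under
the (FPR, TPR) curve is integrated by the trapezoidal rule.  The 0% and
100% endpoints are exactly (0, 0) and (1, 1) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Optional, Union

import numpy as np

__all__ = [
    "ReactivityProfile",
    "RocCurve",
    "read_ct",
    "read_reactivity",
    "call_paired_at_percentile",
    "confusion",
    "roc_curve",
    "top_fraction_mask",
    "single_stranded_share",
    "write_roc_table",
]

MISSING_SENTINELS = (-999.0, -500.0)


@dataclass(frozen=True)
class CtStructure:
    """Parsed CT file: sequence and 1-based partner list (0 = unpaired)."""

    title: str
    sequence: str
    partner: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.sequence)

    def paired_mask(self) -> np.ndarray:
        return np.array([p > 0 for p in self.partner])


@dataclass(frozen=True)
class ReactivityProfile:
    """Per-position reactivities with NaN for missing values."""

    values: np.ndarray
    probe: str = ""
    ac_only: bool = False  # restrict applicability to A/C (DMS convention)

    def __len__(self) -> int:
        return len(self.values)

    def applicable_mask(self, sequence: Optional[str] = None) -> np.ndarray:
        """Positions with a finite value (optionally restricted to A/C)."""
        mask = np.isfinite(self.values)
        if self.ac_only:
            if sequence is None:
                raise ValueError("A/C restriction requires the sequence")
            ac = np.array([c in "AC" for c in sequence.upper().replace("T", "U")])
            mask &= ac
        return mask


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    degenerate: bool = False  # no paired or no unpaired reference positions


def read_ct(source: Union[str, Path, IO[str]]) -> CtStructure:
    """Standard 6-column CT reader (single structure)."""
    own = isinstance(source, (str, Path))
    handle = open(source) if own else source
    try:
        header = handle.readline().split(None, 1)
        if not header:
            raise ValueError("empty CT file")
        n = int(header[0])
        title = header[1].strip() if len(header) > 1 else ""
        seq = []
        partner = []
        for _ in range(n):
            parts = handle.readline().split()
            if len(parts) < 6:
                raise ValueError("truncated CT record")
            seq.append(parts[1])
            partner.append(int(parts[4]))
        return CtStructure(title=title, sequence="".join(seq), partner=tuple(partner))
    finally:
        if own:
            handle.close()


def read_reactivity(
    source: Union[str, Path, IO[str]],
    probe: str = "",
    ac_only: bool = False,
) -> ReactivityProfile:
    """Two-column (position, value) reactivity reader.

    ``NA``, ``nan`` and sentinel values (-999, -500) denote missing data.
    Positions are 1-based and may be sparse; the profile length is the
    largest position seen.
    """
    own = isinstance(source, (str, Path))
    handle = open(source) if own else source
    entries: dict[int, float] = {}
    try:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            pos = int(parts[0])
            raw = parts[1]
            if raw.upper() in ("NA", "NAN"):
                val = np.nan
            else:
                val = float(raw)
                if val in MISSING_SENTINELS:
                    val = np.nan
            entries[pos] = val
    finally:
        if own:
            handle.close()
    if not entries:
        raise ValueError("empty reactivity file")
    n = max(entries)
    values = np.full(n, np.nan)
    for pos, val in entries.items():
        values[pos - 1] = val
    return ReactivityProfile(values=values, probe=probe, ac_only=ac_only)


def _ranked_applicable(profile: ReactivityProfile, sequence: Optional[str]) -> np.ndarray:
    mask = profile.applicable_mask(sequence)
    idx = np.nonzero(mask)[0]
    # Stable sort on value then position: deterministic tie-breaks.
    order = np.lexsort((idx, profile.values[idx]))
    return idx[order]


def call_paired_at_percentile(
    profile: ReactivityProfile,
    x_percent: float,
    sequence: Optional[str] = None,
) -> np.ndarray:
    """Boolean per-position paired call at the x% reactivity threshold.

    The lowest-reactivity x% of applicable positions are called paired;
    inapplicable/missing positions are never called.
    """
    if not (0 <= x_percent <= 100):
        raise ValueError("x_percent must be in [0, 100]")
    ranked = _ranked_applicable(profile, sequence)
    k = int(np.floor(x_percent * ranked.size / 100.0 + 1e-9))
    calls = np.zeros(len(profile), dtype=bool)
    calls[ranked[:k]] = True
    return calls


def confusion(
    ct: CtStructure,
    calls: np.ndarray,
    profile: Optional[ReactivityProfile] = None,
) -> tuple[int, int, int, int]:
    """(tp, fn, fp, tn) over applicable positions.

    TP: paired in CT and called paired; FN: paired in CT, not called;
    FP: unpaired in CT, called; TN: unpaired in CT, not called.
    """
    if len(ct) != len(calls):
        raise ValueError("CT structure and calls have different lengths")
    paired = ct.paired_mask()
    if profile is not None:
        if len(profile) != len(ct):
            raise ValueError("CT structure and profile have different lengths")
        applicable = profile.applicable_mask(ct.sequence)
    else:
        applicable = np.ones(len(ct), dtype=bool)
    tp = int(np.count_nonzero(paired & calls & applicable))
    fn = int(np.count_nonzero(paired & ~calls & applicable))
    fp = int(np.count_nonzero(~paired & calls & applicable))
    tn = int(np.count_nonzero(~paired & ~calls & applicable))
    return tp, fn, fp, tn


def roc_curve(ct: CtStructure, profile: ReactivityProfile) -> RocCurve:
    """Threshold sweep 0..100% in 1% steps with trapezoidal AUC."""
    if len(ct) != len(profile):
        raise ValueError("CT structure and profile have different lengths")
    thresholds = np.arange(101)
    tpr = np.empty(101)
    fpr = np.empty(101)
    degenerate = False
    for t in thresholds:
        calls = call_paired_at_percentile(profile, t, sequence=ct.sequence)
        tp, fn, fp, tn = confusion(ct, calls, profile)
        if tp + fn == 0 or fp + tn == 0:
            degenerate = True
            tpr[t] = np.nan
            fpr[t] = np.nan
            continue
        tpr[t] = tp / (tp + fn)
        fpr[t] = fp / (fp + tn)
    if degenerate:
        auc = float("nan")
    else:
        order = np.argsort(fpr, kind="stable")
        auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc, degenerate=degenerate)


def top_fraction_mask(
    profile: ReactivityProfile,
    fraction: float = 0.20,
    sequence: Optional[str] = None,
) -> np.ndarray:
    """Boolean mask of the highest-reactivity fraction of applicable positions."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    ranked = _ranked_applicable(profile, sequence)
    k = int(np.floor(fraction * ranked.size + 1e-9))
    mask = np.zeros(len(profile), dtype=bool)
    if k > 0:
        mask[ranked[-k:]] = True
    return mask


def single_stranded_share(mask: np.ndarray, structure: Union[CtStructure, str]) -> float:
    """Share of masked positions that are single-stranded in a structure.

    ``structure`` may be a CT structure or a dot-bracket string.
    """
    if isinstance(structure, CtStructure):
        unpaired = ~structure.paired_mask()
    else:
        unpaired = np.array([c == "." for c in structure])
    if len(unpaired) != len(mask):
        raise ValueError("mask and structure have different lengths")
    total = int(np.count_nonzero(mask))
    if total == 0:
        return float("nan")
    return float(np.count_nonzero(mask & unpaired) / total)


def write_roc_table(
    ct: CtStructure,
    profile: ReactivityProfile,
    destination: Union[str, Path, IO[str]],
) -> RocCurve:
    """TSV sweep table (threshold, tp, fn, fp, tn, tpr, fpr) + AUC line."""
    curve = roc_curve(ct, profile)
    own = isinstance(destination, (str, Path))
    handle = open(destination, "w") if own else destination
    try:
        handle.write("threshold\ttp\tfn\tfp\ttn\ttpr\tfpr\n")
        for t in curve.thresholds:
            calls = call_paired_at_percentile(profile, t, sequence=ct.sequence)
            tp, fn, fp, tn = confusion(ct, calls, profile)
            handle.write(
                f"{t}\t{tp}\t{fn}\t{fp}\t{tn}\t{curve.tpr[t]:.4f}\t{curve.fpr[t]:.4f}\n"
            )
        handle.write(f"# auc\t{curve.auc:.4f}\n")
    finally:
        if own:
            handle.close()
    return curve
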