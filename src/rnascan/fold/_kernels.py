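"""Numba kernels for the built-in folding backend.

The minimization model is a lightweight nearest-neighbor scheme
("Nussinov with stacking"): helical stacks draw negative free energy
from a 6x6 pair-type table, hairpin loops pay a size-dependent
initiation penalty, and any pair closing a region that is neither a
stack nor a hairpin (bulges, internal loops, multiloops) pays one flat
branch penalty.  Ensemble quantities use a separate, simpler pair-energy
Boltzmann model evaluated by an inside-outside algorithm.

All energies are kcal/mol at 37 degrees C.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e9
MIN_LOOP = 3
RT37 = 0.0019872 * 310.15  # kcal/mol

# Nucleotide codes: A=0 C=1 G=2 U=3, anything else 4 (unpairable).
_CODE = np.full(256, 4, dtype=np.int8)
for _c, _i in zip(b"ACGU", range(4)):
    _CODE[_c] = _i

# Pair types: CG=0 GC=1 GU=2 UG=3 AU=4 UA=5, -1 if not pairable.
PAIR_TYPE = np.full((5, 5), -1, dtype=np.int8)
PAIR_TYPE[1, 2] = 0  # C-G
PAIR_TYPE[2, 1] = 1  # G-C
PAIR_TYPE[2, 3] = 2  # G-U
PAIR_TYPE[3, 2] = 3  # U-G
PAIR_TYPE[0, 3] = 4  # A-U
PAIR_TYPE[3, 0] = 5  # U-A

# Stacking free energies, outer pair type x inner pair type (kcal/mol).
# Values follow the shape of the Turner nearest-neighbor WC/wobble table.
STACK = np.array(
    [
        # CG     GC     GU     UG     AU     UA
        [-3.3, -2.4, -2.1, -1.4, -2.1, -2.1],  # CG
        [-3.4, -3.3, -2.5, -1.5, -2.2, -2.4],  # GC
        [-2.5, -2.1, -1.4, +0.5, -1.4, -1.3],  # GU
        [-2.1, -1.4, +0.3, -0.5, -0.6, -1.0],  # UG
        [-2.4, -2.1, -1.3, -1.0, -0.9, -1.3],  # AU
        [-2.1, -2.2, -1.4, -0.6, -1.1, -0.9],  # UA
    ]
)

# Hairpin initiation for loop sizes 3..9; larger loops extrapolated
# logarithmically (Jacobson-Stockmayer, 1.75*RT coefficient).
HAIRPIN = np.array([5.4, 5.6, 5.7, 5.4, 6.0, 5.5, 6.4])

# Flat penalty for a pair closing a bulge/internal/multibranch region.
BRANCH = 4.6

# Pair energies for the ensemble (pair-probability) model.
PAIR_ENERGY = np.array([-2.4, -2.4, -0.8, -0.8, -1.1, -1.1])


def encode(sequence: str) -> np.ndarray:
    """Encode an RNA string into nucleotide codes (non-ACGU -> unpairable)."""
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE[raw]


@njit(cache=True)
def _hairpin_energy(loop_size):
    if loop_size < MIN_LOOP:
        return INF
    if loop_size <= 9:
        return HAIRPIN[loop_size - 3]
    return HAIRPIN[6] + 1.75 * RT37 * np.log(loop_size / 9.0)


@njit(cache=True)
def fill_mfe(enc):
    """Fill V (energy given i pairs j) and W1 (best with >= 1 pair)."""
    n = enc.shape[0]
    V = np.full((n, n), INF)
    W1 = np.full((n, n), INF)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            pt = PAIR_TYPE[enc[i], enc[j]]
            if pt >= 0:
                best = _hairpin_energy(j - i - 1)
                ptin = PAIR_TYPE[enc[i + 1], enc[j - 1]]
                if ptin >= 0 and V[i + 1, j - 1] < INF / 2:
                    cand = STACK[pt, ptin] + V[i + 1, j - 1]
                    if cand < best:
                        best = cand
                if W1[i + 1, j - 1] < INF / 2:
                    cand = BRANCH + W1[i + 1, j - 1]
                    if cand < best:
                        best = cand
                V[i, j] = best
            # W1(i,j) = min(W1(i+1,j), min_k V(i,k) + min(0, W1(k+1,j)))
            best1 = W1[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if V[i, k] < INF / 2:
                    tail = 0.0
                    if k + 1 <= j and W1[k + 1, j] < 0.0:
                        tail = W1[k + 1, j]
                    cand = V[i, k] + tail
                    if cand < best1:
                        best1 = cand
            W1[i, j] = best1
    return V, W1


@njit(cache=True)
def traceback(enc, V, W1):
    """Recover the MFE pairing as a partner array (-1 = unpaired)."""
    n = enc.shape[0]
    eps = 1e-6
    partner = np.full(n, -1, dtype=np.int64)
    # Explicit stack of (i, j, which) with which: 0 = W1, 1 = V.
    stack_i = np.empty(2 * n + 4, dtype=np.int64)
    stack_j = np.empty(2 * n + 4, dtype=np.int64)
    stack_m = np.empty(2 * n + 4, dtype=np.int64)
    top = 0
    if n > MIN_LOOP + 1 and W1[0, n - 1] < -eps:
        stack_i[top] = 0
        stack_j[top] = n - 1
        stack_m[top] = 0
        top += 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        which = stack_m[top]
        if which == 1:
            partner[i] = j
            partner[j] = i
            pt = PAIR_TYPE[enc[i], enc[j]]
            ptin = PAIR_TYPE[enc[i + 1], enc[j - 1]]
            if (
                ptin >= 0
                and V[i + 1, j - 1] < INF / 2
                and abs(V[i, j] - (STACK[pt, ptin] + V[i + 1, j - 1])) < eps
            ):
                stack_i[top] = i + 1
                stack_j[top] = j - 1
                stack_m[top] = 1
                top += 1
            elif abs(V[i, j] - _hairpin_energy(j - i - 1)) < eps:
                pass
            else:
                stack_i[top] = i + 1
                stack_j[top] = j - 1
                stack_m[top] = 0
                top += 1
        else:
            # W1 trace: prefer skipping i, then bifurcations in k order.
            if j - i > MIN_LOOP + 1 and abs(W1[i, j] - W1[i + 1, j]) < eps:
                stack_i[top] = i + 1
                stack_j[top] = j
                stack_m[top] = 0
                top += 1
                continue
            for k in range(i + MIN_LOOP + 1, j + 1):
                if V[i, k] >= INF / 2:
                    continue
                tail = 0.0
                push_tail = False
                if k + 1 <= j and W1[k + 1, j] < 0.0:
                    tail = W1[k + 1, j]
                    push_tail = True
                if abs(W1[i, j] - (V[i, k] + tail)) < eps:
                    stack_i[top] = i
                    stack_j[top] = k
                    stack_m[top] = 1
                    top += 1
                    if push_tail:
                        stack_i[top] = k + 1
                        stack_j[top] = j
                        stack_m[top] = 0
                        top += 1
                    break
    return partner


@njit(cache=True)
def pair_probabilities(enc):
    """Base-pair probability matrix under the pair-energy Boltzmann model."""
    n = enc.shape[0]
    P = np.zeros((n, n))
    if n < MIN_LOOP + 2:
        return P
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            pt = PAIR_TYPE[enc[i], enc[j]]
            if pt >= 0:
                w[i, j] = np.exp(-PAIR_ENERGY[pt] / RT37)
    # Inside: Q(i,j) with empty interval = 1.
    Q = np.ones((n + 1, n + 1))
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            total = Q_get(Q, i + 1, j)
            for k in range(i + MIN_LOOP + 1, j + 1):
                if w[i, k] > 0.0:
                    total += w[i, k] * Q_get(Q, i + 1, k - 1) * Q_get(Q, k + 1, j)
            Q[i, j] = total
    Z = Q_get(Q, 0, n - 1)
    # Outside pass.
    O = np.zeros((n, n))
    O[0, n - 1] = 1.0
    for span in range(n - 1, 0, -1):
        for i in range(n - span):
            j = i + span
            o = O[i, j]
            if o == 0.0:
                continue
            if i + 1 <= j:
                O[i + 1, j] += o
            for k in range(i + MIN_LOOP + 1, j + 1):
                if w[i, k] > 0.0:
                    qin = Q_get(Q, i + 1, k - 1)
                    qtail = Q_get(Q, k + 1, j)
                    P[i, k] += o * w[i, k] * qin * qtail
                    if i + 1 <= k - 1:
                        O[i + 1, k - 1] += o * w[i, k] * qtail
                    if k + 1 <= j:
                        O[k + 1, j] += o * w[i, k] * qin
    P /= Z
    return P


@njit(cache=True)
def Q_get(Q, i, j):
    if i > j:
        return 1.0
    return Q[i, j]
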