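"""RNA secondary-structure accessibility for triplex prediction.

Triplex-forming segments of an RNA must be single-stranded, so nucleotides
that are likely base-paired are masked to 'N' before the triplex search.
Pairing probabilities come from a McCaskill-style partition function over
all pseudoknot-free secondary structures with a two-parameter energy
model: every allowed base pair (Watson-Crick plus G:U wobble) carries a
uniform Boltzmann weight ``pair_weight``, and every *stacked* pair — a
pair (i, j) whose neighbour (i+1, j-1) is also paired — earns an
additional factor ``stack_weight``.  A structure :math:`S` with ``p``
pairs and ``s`` stacks therefore has weight

.. math::  W(S) = w^{p} \\, \\sigma^{s}.

The stacking bonus is what lets contiguous helices dominate over the sea
of isolated alternative pairings, mirroring the fact that real helix
stability comes from stacking rather than hydrogen bonding; with
``stack_weight = 1`` the model reduces to a plain per-pair weight.  The
model is exact and fully enumerable — :func:`enumerate_pair_probabilities`
recomputes the same marginals by listing every structure — which is all
the downstream paired/unpaired call at a fixed probability cutoff needs.
Users who want full nearest-neighbour thermodynamics can instead supply an
RNAplfold unpaired-probability track via :func:`triplexmeth.io.read_lunp`
and mask with that.

The inside recursion tracks the region partition function ``Z`` together
with the pair-closed partition function ``Zb``:

.. math::

    Zb(i,j) &= w\\,Z(i+1, j-1) + w(\\sigma - 1)\\,Zb(i+1, j-1) \\\\
    Z(i,j)  &= Z(i, j-1) + \\sum_{k} Z(i, k-1)\\, Zb(k, j)

and a matching exterior recursion yields the probability of every allowed
pair.  All tables are rescaled per nucleotide so kilobase transcripts do
not overflow double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "StructureParams",
    "pair_probabilities",
    "unpaired_profile",
    "mask_paired",
    "enumerate_pair_probabilities",
]

_CODES = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
# Watson-Crick + wobble, as an unordered set of code pairs
_ALLOWED_PAIRS = {(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)}

_ENUM_MAX_LEN = 20  # brute-force enumeration guard


@dataclass(frozen=True)
class StructureParams:
    """Parameters of the accessibility model.

    pairing_cutoff
        A position is called "paired" (and masked) when the probability of
        its most likely partner reaches this value.  This mirrors the
        per-pair semantics of RNAplfold's ``-c`` cutoff rather than a
        threshold on the total unpaired probability.
    min_loop
        Minimum number of unpaired nucleotides enclosed by a hairpin.
    pair_weight
        Boltzmann factor credited to each formed pair.  The default e^-3
        penalises pair formation (about +1.9 kcal/mol at 310 K), playing
        the role of the helix-initiation cost: isolated pairs are rare.
    stack_weight
        Extra Boltzmann factor per stacked pair; the default e^4
        (about -2.5 kcal/mol at 310 K) is what makes contiguous helices
        favourable overall (net e^1 per propagated pair).  Set both
        weights to taste, or ``stack_weight=1`` for the plain per-pair
        model.
    scale
        Per-nucleotide rescaling base for the partition function.  When
        ``None`` it is estimated from a sequence prefix; 1.0 disables
        rescaling (fine up to a couple of hundred nucleotides).
    """

    pairing_cutoff: float = 0.1
    min_loop: int = 3
    pair_weight: float = math.e ** -3
    stack_weight: float = math.e ** 4
    scale: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.pairing_cutoff < 1.0:
            raise ValueError("pairing_cutoff must be in (0, 1)")
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")
        if self.pair_weight <= 0 or self.stack_weight <= 0:
            raise ValueError("pair_weight and stack_weight must be positive")


def _encode(rna: str) -> np.ndarray:
    try:
        return np.array([_CODES[c] for c in rna.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid RNA character {exc.args[0]!r}") from None


def _allowed_matrix(codes: np.ndarray, min_loop: int) -> np.ndarray:
    """Boolean matrix: True where (i, j), i < j, may pair."""
    n = codes.size
    pairable = np.zeros((4, 4), dtype=bool)
    for a, b in _ALLOWED_PAIRS:
        pairable[a, b] = True
    allowed = pairable[codes[:, None], codes[None, :]]
    i = np.arange(n)
    allowed &= (i[None, :] - i[:, None]) > min_loop  # also zeroes i >= j
    return allowed


def _inside(allowed: np.ndarray, w: float, sigma: float, s: float,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Scaled inside tables.

    Returns ``(M, B)`` with ``M[i, e] = Z([i, e)) / s**(e-i)`` and
    ``B[k, j] = Zb(k, j) / s**(j-k+1)`` (zero where (k, j) cannot pair).
    """
    n = allowed.shape[0]
    M = np.ones((n + 1, n + 1))
    B = np.zeros((n, n))
    partners = [np.flatnonzero(allowed[:, j]) for j in range(n)]
    w2 = w / (s * s)
    sig1 = sigma - 1.0
    inv_s = 1.0 / s
    for e in range(1, n + 1):
        j = e - 1
        ks = partners[j]
        if ks.size:
            inner = M[ks + 1, j].copy()
            if j >= 1:
                inner += sig1 * B[ks + 1, j - 1]
            B[ks, j] = w2 * inner
        col = B[:, j]
        for i in range(j, -1, -1):
            total = M[i, j] * inv_s
            if ks.size:
                lo = np.searchsorted(ks, i)
                if lo < ks.size:
                    sel = ks[lo:]
                    total += float(np.dot(M[i, sel], col[sel]))
            M[i, e] = total
    if not (np.isfinite(M).all() and np.isfinite(B).all()):
        raise FloatingPointError(
            "partition function overflowed; supply a larger StructureParams.scale"
        )
    return M, B


def _estimate_scale(allowed: np.ndarray, w: float, sigma: float) -> float:
    """Per-nucleotide growth of Z, estimated on an unscaled prefix."""
    n = allowed.shape[0]
    if n <= 200:
        return 1.0
    m = 150
    M, _ = _inside(allowed[:m, :m], w, sigma, 1.0)
    return float(M[0, m]) ** (1.0 / m)


def pair_probabilities(rna: str, params: StructureParams = StructureParams()) -> np.ndarray:
    """Equilibrium base-pair probability matrix P(i, j) for the sequence.

    P is symmetric with zeros wherever a pair is disallowed or closer than
    ``min_loop``; row sums are the per-position paired probabilities and
    never exceed 1.
    """
    codes = _encode(rna)
    n = codes.size
    if n == 0:
        raise ValueError("empty sequence")
    allowed = _allowed_matrix(codes, params.min_loop)
    w, sigma = params.pair_weight, params.stack_weight
    s = params.scale if params.scale is not None else _estimate_scale(allowed, w, sigma)
    M, B = _inside(allowed, w, sigma, s)

    # Exterior weights O(i, j) for allowed pairs, longest spans first.
    # G[p, j] accumulates sum_q O(p, q) * Zscaled([j+1, q)) over processed
    # enclosing pairs (p, q), turning the exterior recursion into one dot
    # product per pair; the local term credits the stack formed with a
    # directly-adjacent enclosing pair (i-1, j+1).
    O = np.zeros((n, n))
    G = np.zeros((n, n + 1))
    w2 = w / (s * s)
    wsig = w * (sigma - 1.0) / (s * s)
    pair_i, pair_j = np.nonzero(allowed)
    order = np.argsort(pair_j - pair_i)[::-1]
    for idx in order:
        i, j = int(pair_i[idx]), int(pair_j[idx])
        val = M[0, i] * M[j + 1, n]
        if i > 0:
            val += w2 * float(np.dot(M[1:i + 1, i], G[:i, j]))
            if j + 1 < n and allowed[i - 1, j + 1]:
                val += wsig * O[i - 1, j + 1]
        O[i, j] = val
        if j - i >= 2:
            G[i, i + 1:j] += val * M[i + 2:j + 1, j]

    Z = M[0, n]
    P = np.zeros((n, n))
    P[pair_i, pair_j] = B[pair_i, pair_j] * O[pair_i, pair_j] / Z
    P = P + P.T
    return P


def unpaired_profile(P: np.ndarray) -> pd.DataFrame:
    """Per-position profile from a pair-probability matrix.

    ``p_unpaired(i) = 1 - sum_j P(i, j)`` and ``p_paired(i) = max_j P(i, j)``
    (the probability of the most likely single partner, matching the
    masking semantics of :class:`StructureParams.pairing_cutoff`).
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    total = P.sum(axis=1)
    return pd.DataFrame({
        "position": np.arange(n),
        "p_unpaired": np.clip(1.0 - total, 0.0, 1.0),
        "p_paired": P.max(axis=1, initial=0.0),
    })


def mask_paired(rna: str, profile: pd.DataFrame,
                params: StructureParams = StructureParams()) -> str:
    """Replace nucleotides predicted to pair with 'N'.

    Position ``i`` is masked iff ``p_paired(i) >= pairing_cutoff``; all
    other characters (including prior 'N's) pass through unchanged, so the
    operation is idempotent and length-preserving.
    """
    if len(rna) != len(profile):
        raise ValueError(
            f"sequence length {len(rna)} != profile length {len(profile)}"
        )
    p_paired = profile["p_paired"].to_numpy()
    chars = np.array(list(rna))
    chars[p_paired >= params.pairing_cutoff] = "N"
    return "".join(chars)


# ---------------------------------------------------------------------------
# Brute-force reference

def _enumerate_structures(allowed: np.ndarray, i: int, e: int) -> Iterator[tuple]:
    """Yield every pseudoknot-free structure on [i, e) as a tuple of pairs."""
    if e - i <= 0:
        yield ()
        return
    for s in _enumerate_structures(allowed, i + 1, e):
        yield s
    for k in range(i + 1, e):
        if allowed[i, k]:
            for s1 in _enumerate_structures(allowed, i + 1, k):
                for s2 in _enumerate_structures(allowed, k + 1, e):
                    yield ((i, k),) + s1 + s2


def enumerate_pair_probabilities(rna: str,
                                 params: StructureParams = StructureParams()) -> np.ndarray:
    """Exact pair probabilities by explicit enumeration of all structures.

    Each structure is weighted ``pair_weight**n_pairs *
    stack_weight**n_stacks``; independent reference for
    :func:`pair_probabilities`.  Refuses sequences longer than 20 nt to
    guard against combinatorial blow-up.
    """
    codes = _encode(rna)
    n = codes.size
    if n > _ENUM_MAX_LEN:
        raise ValueError(f"enumeration limited to {_ENUM_MAX_LEN} nt (got {n})")
    allowed = _allowed_matrix(codes, params.min_loop)
    w, sigma = params.pair_weight, params.stack_weight
    Z = 0.0
    acc = np.zeros((n, n))
    for structure in _enumerate_structures(allowed, 0, n):
        pairs = set(structure)
        n_stacks = sum(1 for (a, b) in pairs if (a + 1, b - 1) in pairs)
        weight = w ** len(pairs) * sigma ** n_stacks
        Z += weight
        for (a, b) in pairs:
            acc[a, b] += weight
    P = acc / Z
    return P + P.T
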