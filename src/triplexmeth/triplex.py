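"""RNA:DNA triple-helix prediction under canonical Hoogsteen motif rules.

A triplex-forming oligonucleotide (TFO) is a single-stranded RNA segment
that lies in the major groove of duplex DNA and reads the purine strand of
a triplex target site (TTS) via Hoogsteen or reverse-Hoogsteen hydrogen
bonds.  Three canonical motifs are searched:

==== ============ ======================= ==============
code TFO alphabet  triplets (TFO, purine)  orientation
==== ============ ======================= ==============
Y    T, C          T.A:T  C.G:C           parallel
R    G, A          G.G:C  A.A:T           antiparallel
GT   G, T          G.G:C  T.A:T           both
==== ============ ======================= ==============

Orientation is the direction of the TFO relative to the purine strand of
the duplex.  Both duplex strands are examined as the potential purine
strand.  A *hit* is a gap-free TFO/TTS alignment of at least
``min_length`` nucleotides whose mismatch fraction is at most
``max_error_rate``, with at most ``max_consecutive_errors`` mismatches in
a row, and whose TTS purine strand contains at least ``min_guanine_rate``
guanine — the relaxed parameter set used for genome-wide screens.  'N'
(including structure-masked RNA positions) is always an error.  Reported
hits are *maximal*: no other hit with the same motif, orientation, strand
and alignment register strictly contains them.

:func:`brute_force_triplexes` re-derives hits by exhaustive enumeration on
small inputs and serves as the engine's independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TriplexParams",
    "TriplexHit",
    "TRIPLET_RULES",
    "find_tts_tracts",
    "find_triplexes",
    "find_triplexes_one",
    "brute_force_triplexes",
    "hits_to_frame",
]

# (TFO base, duplex purine-strand base) -> legal triplet, per motif/orientation
TRIPLET_RULES: dict[tuple[str, str], frozenset[tuple[str, str]]] = {
    ("Y", "parallel"): frozenset({("T", "A"), ("C", "G")}),
    ("R", "antiparallel"): frozenset({("G", "G"), ("A", "A")}),
    ("GT", "parallel"): frozenset({("G", "G"), ("T", "A")}),
    ("GT", "antiparallel"): frozenset({("G", "G"), ("T", "A")}),
}

_DNA_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_RNA_TO_DNA = str.maketrans("Uu", "Tt")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_BRUTE_MAX_RNA = 30
_BRUTE_MAX_DNA = 60


@dataclass(frozen=True)
class TriplexParams:
    """Search thresholds (defaults follow the relaxed genome-screen set)."""

    min_length: int = 10
    max_error_rate: float = 0.20
    min_guanine_rate: float = 0.70
    max_consecutive_errors: int = 1
    motifs: tuple[str, ...] = ("Y", "R", "GT")
    filter_repeats: bool = False

    def __post_init__(self) -> None:
        if self.min_length < 5:
            raise ValueError("min_length must be >= 5")
        if not 0.0 <= self.max_error_rate <= 1.0:
            raise ValueError("max_error_rate must be in [0, 1]")
        if not 0.0 <= self.min_guanine_rate <= 1.0:
            raise ValueError("min_guanine_rate must be in [0, 1]")
        if self.max_consecutive_errors < 0:
            raise ValueError("max_consecutive_errors must be >= 0")
        bad = set(self.motifs) - {"Y", "R", "GT"}
        if bad:
            raise ValueError(f"unknown motifs: {sorted(bad)}")
        if self.filter_repeats:
            raise ValueError("repeat filtering is not implemented; use filter_repeats=False")

    def configs(self) -> list[tuple[str, str]]:
        out = []
        for motif in self.motifs:
            for m, orientation in TRIPLET_RULES:
                if m == motif:
                    out.append((motif, orientation))
        return out


@dataclass(frozen=True)
class TriplexHit:
    """One TFO <-> TTS match.

    ``strand`` is the duplex strand acting as the purine strand of the
    TTS; coordinates are 0-based half-open, with ``tts_*`` genomic and
    ``rna_*`` transcript-relative.  ``guanine_rate`` is the G fraction of
    the TTS purine strand.
    """

    rna_start: int
    rna_end: int
    tts_chrom: str
    tts_start: int
    tts_end: int
    motif: str
    orientation: str
    strand: str
    n_errors: int
    guanine_rate: float
    region: str | None = field(default=None, compare=True)

    @property
    def length(self) -> int:
        return self.rna_end - self.rna_start

    def sort_key(self) -> tuple:
        return (self.tts_chrom, self.tts_start, self.rna_start, self.motif,
                self.orientation, self.strand, self.tts_end, self.rna_end)


def revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def _encode_rna(rna: str) -> np.ndarray:
    seq = rna.upper().translate(_RNA_TO_DNA)
    try:
        return np.array([_DNA_CODES[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid RNA character {exc.args[0]!r}") from None


def _encode_dna(dna: str) -> np.ndarray:
    try:
        return np.array([_DNA_CODES[c] for c in dna.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid DNA character {exc.args[0]!r}") from None


def _rule_table(motif: str, orientation: str) -> np.ndarray:
    table = np.zeros((5, 5), dtype=bool)
    for r, d in TRIPLET_RULES[(motif, orientation)]:
        table[_DNA_CODES[r], _DNA_CODES[d]] = True
    return table


def _error_ok(n_errors: int, length: int, params: TriplexParams) -> bool:
    return n_errors <= params.max_error_rate * length + 1e-9


def _guanine_ok(n_g: int, length: int, params: TriplexParams) -> bool:
    return n_g >= params.min_guanine_rate * length - 1e-9


def _segments_without_long_error_runs(err: np.ndarray, c: int) -> list[tuple[int, int]]:
    """Maximal intervals containing no run of more than ``c`` errors.

    An interval may overhang a long error run by up to ``c`` positions on
    either side, so adjacent segments can overlap when ``c >= 2``.
    """
    m = err.size
    # maximal error runs longer than c
    padded = np.concatenate(([False], err, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)
    segments: list[tuple[int, int]] = []
    lo = 0
    for s, e in zip(run_starts, run_ends):
        if e - s > c:
            hi = min(s + c, m)
            if hi - lo > 0:
                segments.append((lo, hi))
            lo = max(e - c, 0)
    if m - lo > 0:
        segments.append((lo, m))
    return segments


def _valid_spans(match: np.ndarray, g: np.ndarray, params: TriplexParams) -> list[tuple[int, int]]:
    """All (start, end) spans along one alignment register that satisfy the
    length, error-rate, consecutive-error and guanine-rate constraints."""
    err = ~match
    lmin = params.min_length
    spans: set[tuple[int, int]] = set()
    for lo, hi in _segments_without_long_error_runs(err, params.max_consecutive_errors):
        slen = hi - lo
        if slen < lmin:
            continue
        e_cum = np.concatenate(([0], np.cumsum(err[lo:hi])))
        g_cum = np.concatenate(([0], np.cumsum(g[lo:hi])))
        for length in range(lmin, slen + 1):
            n_err = e_cum[length:] - e_cum[:-length]
            n_g = g_cum[length:] - g_cum[:-length]
            ok = (
                (n_err <= params.max_error_rate * length + 1e-9)
                & (n_g >= params.min_guanine_rate * length - 1e-9)
            )
            for a in np.flatnonzero(ok):
                spans.add((lo + int(a), lo + int(a) + length))
    return sorted(spans)


def _maximal(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Containment-maximal spans (input spans live on one register)."""
    out: list[tuple[int, int]] = []
    max_end = -1
    for a, b in sorted(spans, key=lambda s: (s[0], -s[1])):
        if b > max_end:
            out.append((a, b))
            max_end = b
    return out


def _scan_register(match: np.ndarray, g: np.ndarray, params: TriplexParams) -> list[tuple[int, int]]:
    return _maximal(_valid_spans(match, g, params))


def _min_matches(params: TriplexParams) -> int:
    lmin = params.min_length
    return lmin - int(np.floor(params.max_error_rate * lmin + 1e-9))


def _block_min_matches(params: TriplexParams) -> int:
    """Safe register prefilter threshold.

    Any valid window of length L >= L0 with error rate <= e contains some
    L0-block whose error count is at most floor(E / floor(L/L0)) <=
    floor(2*e*L0), so a register without an L0-window holding at least
    ``L0 - floor(2*e*L0)`` matches cannot host a hit.
    """
    lmin = params.min_length
    return max(1, lmin - int(np.floor(2 * params.max_error_rate * lmin + 1e-9)))


def _min_guanines(params: TriplexParams) -> int:
    return int(np.ceil(params.min_guanine_rate * params.min_length - 1e-9))


def _window_hits(rna_codes: np.ndarray, window: str, chrom: str, offset: int,
                 params: TriplexParams, region: str | None) -> list[TriplexHit]:
    """All maximal hits of the (masked) RNA against one DNA window."""
    hits: list[TriplexHit] = []
    n_rna = rna_codes.size
    W = len(window)
    if n_rna < params.min_length or W < params.min_length:
        return hits
    need_g = _min_guanines(params)
    block_match = _block_min_matches(params)
    g_code = _DNA_CODES["G"]
    for strand in ("+", "-"):
        D = window.upper() if strand == "+" else revcomp(window.upper())
        d_codes = _encode_dna(D)
        if int((d_codes == g_code).sum()) < need_g:
            continue
        for motif, orientation in params.configs():
            # For antiparallel orientation the TFO runs 3'->5' along the
            # purine strand; scanning against the reversed strand turns
            # every register into a parallel one.
            dc = d_codes if orientation == "parallel" else d_codes[::-1]
            table = _rule_table(motif, orientation)
            M = table[rna_codes[:, None], dc[None, :]]
            gflag = dc == g_code
            gcum = np.concatenate(([0], np.cumsum(gflag)))
            # register prefilter: a hit needs an L0-window with enough
            # matches somewhere on its register (see _block_min_matches);
            # registers without one are skipped without extraction
            lmin = params.min_length
            nS0, nS1 = n_rna - lmin + 1, dc.size - lmin + 1
            if nS0 <= 0 or nS1 <= 0:
                continue
            S = np.zeros((nS0, nS1), dtype=np.int16)
            for t in range(lmin):
                S += M[t:t + nS0, t:t + nS1]
            ii, jj = np.nonzero(S >= block_match)
            if ii.size == 0:
                continue
            offsets = np.unique(jj.astype(np.int64) - ii)
            for off in offsets:
                i0 = 0 if off >= 0 else -off
                j0 = off if off >= 0 else 0
                dlen = min(n_rna - i0, dc.size - j0)
                if dlen < params.min_length:
                    continue
                if gcum[j0 + dlen] - gcum[j0] < need_g:
                    continue
                diag = M.diagonal(offset=int(off))
                gdiag = gflag[j0:j0 + dlen]
                for a, b in _scan_register(diag, gdiag, params):
                    L = b - a
                    rs, js = i0 + a, j0 + a
                    seg = slice(js, js + L)
                    n_err = int(L - diag[a:b].sum())
                    n_g = int(gdiag[a:b].sum())
                    # scanned coords -> purine-strand coords
                    if orientation == "parallel":
                        p1, p2 = js, js + L
                    else:
                        p1, p2 = W - (js + L), W - js
                    # purine-strand coords -> reference window coords
                    if strand == "+":
                        w1, w2 = p1, p2
                    else:
                        w1, w2 = W - p2, W - p1
                    hits.append(TriplexHit(
                        rna_start=rs, rna_end=rs + L,
                        tts_chrom=chrom, tts_start=offset + w1, tts_end=offset + w2,
                        motif=motif, orientation=orientation, strand=strand,
                        n_errors=n_err, guanine_rate=n_g / L, region=region,
                    ))
    return hits


def find_triplexes_one(rna: str, dna: str, params: TriplexParams = TriplexParams(),
                       chrom: str = "seq", offset: int = 0,
                       region: str | None = None) -> list[TriplexHit]:
    """Maximal triplex hits between one RNA and one DNA duplex sequence."""
    rna_codes = _encode_rna(rna)
    hits = _window_hits(rna_codes, dna, chrom, offset, params, region)
    return sorted(hits, key=TriplexHit.sort_key)


def find_triplexes(rna_masked: str, windows: pd.DataFrame,
                   params: TriplexParams = TriplexParams()) -> list[TriplexHit]:
    """Search a (masked) RNA against a table of DNA target windows.

    ``windows`` needs columns ``chrom``, ``start`` and ``seq``; a
    ``probe_id`` column, when present, is carried into each hit's
    ``region`` field.  A window is "triplex-positive" when at least one
    hit falls in it.
    """
    rna_codes = _encode_rna(rna_masked)
    if not rna_masked or (rna_codes == _DNA_CODES["N"]).all():
        return []
    hits: list[TriplexHit] = []
    has_id = "probe_id" in windows.columns
    for row in windows.itertuples(index=False):
        region = str(getattr(row, "probe_id")) if has_id else None
        hits.extend(_window_hits(rna_codes, row.seq, row.chrom, int(row.start),
                                 params, region))
    return sorted(hits, key=TriplexHit.sort_key)


# ---------------------------------------------------------------------------
# Candidate TTS tracts

def find_tts_tracts(dna_window: str, params: TriplexParams = TriplexParams()) -> list[tuple[int, int, str]]:
    """Candidate purine tracts able to host a TTS, on either strand.

    Returns ``(start, end, strand)`` intervals in reference-window
    coordinates: maximal stretches whose purine strand (the window itself
    on '+', its complement on '-') has no run of more than
    ``max_consecutive_errors`` non-purines, with enough length and purine
    content to admit a legal hit.  Every hit's TTS is contained in one of
    the reported tracts.
    """
    window = dna_window.upper()
    W = len(window)
    arr = np.frombuffer(window.encode(), dtype="S1")
    tracts: list[tuple[int, int, str]] = []
    min_purines = params.min_length - int(
        np.floor(params.max_error_rate * params.min_length + 1e-9)
    )
    for strand in ("+", "-"):
        if strand == "+":
            purine = (arr == b"A") | (arr == b"G")
        else:
            purine = (arr == b"C") | (arr == b"T")
        for lo, hi in _segments_without_long_error_runs(~purine, params.max_consecutive_errors):
            if hi - lo < params.min_length:
                continue
            if int(purine[lo:hi].sum()) < min_purines:
                continue
            tracts.append((lo, hi, strand))
    tracts.sort()
    return tracts


# ---------------------------------------------------------------------------
# Brute-force oracle

def _register_key(hit: TriplexHit, W: int) -> tuple:
    """Alignment register: hits on the same register can contain each other."""
    # recover purine-strand coordinates of the TTS within the window
    if hit.strand == "+":
        p1, p2 = hit.tts_start, hit.tts_end
    else:
        p1, p2 = W - hit.tts_end, W - hit.tts_start
    if hit.orientation == "parallel":
        diag = hit.rna_start - p1
    else:
        diag = hit.rna_start + p2
    return (hit.motif, hit.orientation, hit.strand, diag)


def brute_force_triplexes(rna: str, dna: str, params: TriplexParams = TriplexParams(),
                          chrom: str = "seq", offset: int = 0,
                          region: str | None = None) -> list[TriplexHit]:
    """Exhaustive reference search over every equal-length substring pair.

    Checks the triplet rules position by position for each candidate
    (RNA substring, DNA substring, motif, orientation, strand), applies
    the error-rate, consecutive-error and guanine filters, and keeps
    containment-maximal hits.  Refuses RNA longer than 30 nt or DNA longer
    than 60 nt.
    """
    if len(rna) > _BRUTE_MAX_RNA or len(dna) > _BRUTE_MAX_DNA:
        raise ValueError(
            f"brute force limited to RNA<={_BRUTE_MAX_RNA}, DNA<={_BRUTE_MAX_DNA}"
        )
    rna_n = rna.upper().translate(_RNA_TO_DNA)
    _encode_rna(rna_n)  # alphabet validation
    _encode_dna(dna.upper())
    W = len(dna)
    candidates: list[TriplexHit] = []
    for strand in ("+", "-"):
        D = dna.upper() if strand == "+" else revcomp(dna.upper())
        for motif, orientation in params.configs():
            rules = TRIPLET_RULES[(motif, orientation)]
            for L in range(params.min_length, min(len(rna_n), W) + 1):
                for i in range(len(rna_n) - L + 1):
                    for j in range(W - L + 1):
                        n_err = 0
                        consec = 0
                        max_consec = 0
                        for t in range(L):
                            r = rna_n[i + t]
                            d = D[j + t] if orientation == "parallel" else D[j + L - 1 - t]
                            if (r, d) in rules:
                                consec = 0
                            else:
                                n_err += 1
                                consec += 1
                                max_consec = max(max_consec, consec)
                        if max_consec > params.max_consecutive_errors:
                            continue
                        if not _error_ok(n_err, L, params):
                            continue
                        n_g = D[j:j + L].count("G")
                        if not _guanine_ok(n_g, L, params):
                            continue
                        p1, p2 = j, j + L
                        if strand == "+":
                            w1, w2 = p1, p2
                        else:
                            w1, w2 = W - p2, W - p1
                        candidates.append(TriplexHit(
                            rna_start=i, rna_end=i + L,
                            tts_chrom=chrom, tts_start=offset + w1, tts_end=offset + w2,
                            motif=motif, orientation=orientation, strand=strand,
                            n_errors=n_err, guanine_rate=n_g / L, region=region,
                        ))
    # containment-maximal reduction per alignment register
    by_register: dict[tuple, list[TriplexHit]] = {}
    for h in candidates:
        by_register.setdefault(_register_key(h, W), []).append(h)
    final: list[TriplexHit] = []
    for group in by_register.values():
        group.sort(key=lambda h: (h.rna_start, -h.rna_end))
        max_end = -1
        for h in group:
            if h.rna_end > max_end:
                final.append(h)
                max_end = h.rna_end
    return sorted(final, key=TriplexHit.sort_key)


def hits_to_frame(hits: Sequence[TriplexHit]) -> pd.DataFrame:
    """Tabulate hits (one row per hit, deterministic column order)."""
    cols = ["rna_start", "rna_end", "tts_chrom", "tts_start", "tts_end",
            "motif", "orientation", "strand", "n_errors", "guanine_rate", "region"]
    return pd.DataFrame([{c: getattr(h, c) for c in cols} for h in hits], columns=cols)
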