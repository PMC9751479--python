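"""Global alignment and reference-anchored projection.

Loci are compared to the reference provirus with an affine-gap global
aligner (Gotoh's algorithm, banded for long sequences) and projected
into reference coordinate space.  The projection — per reference
position, the locus base or a gap, plus an insertion store — replaces a
true multiple alignment: every downstream comparison is either
locus-vs-reference or column-wise over shared reference positions.
Indel calls and per-region annotations are derived from projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import gc_content
from .reference import ReferenceModel

NEG = -(2 ** 30)

# traceback states
_M, _X, _Y = 0, 1, 2


def _encode(seq: str) -> np.ndarray:
    lut = np.full(128, 4, dtype=np.int8)
    for i, ch in enumerate("ACGT"):
        lut[ord(ch)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def global_align(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
    band: int | None = None,
) -> tuple[str, str, int]:
    """Affine-gap global alignment; a gap of length L costs open + L*extend.

    Returns ``(aligned_a, aligned_b, score)``.  Traceback ties are broken
    deterministically (match, then gap-in-a, then gap-in-b).  ``band``
    restricts the search to a corridor of half-width ``band`` around the
    length-scaled diagonal; ``None`` chooses a full (exact) band for
    short inputs and a generous corridor otherwise.  'N' scores as a
    mismatch against everything, including another 'N'.
    """
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    n, m = len(a), len(b)
    if band is None:
        band = max(n, m) if max(n, m) <= 2000 else max(400, abs(n - m) + 400)
    W = min(band, max(n, m))
    WW = 2 * W + 1

    ea, eb = _encode(a), _encode(b)
    go, ge = gap_open, gap_extend

    # center of the band in column space for each row
    centers = np.rint(np.arange(n + 1) * (m / n)).astype(np.int64)
    los = centers - W  # window start (column index of slot 0), may be < 0

    M = np.full(WW, NEG, dtype=np.int64)
    X = np.full(WW, NEG, dtype=np.int64)
    Y = np.full(WW, NEG, dtype=np.int64)
    ptrM = np.zeros((n + 1, WW), dtype=np.int8)
    ptrX = np.zeros((n + 1, WW), dtype=np.int8)
    ptrY = np.zeros((n + 1, WW), dtype=np.int8)

    js0 = los[0] + np.arange(WW)
    valid0 = (js0 >= 0) & (js0 <= m)
    M[valid0 & (js0 == 0)] = 0
    pos = js0 > 0
    Y[valid0 & pos] = go + ge * js0[valid0 & pos]
    ptrY[0, valid0 & pos] = _Y

    def _shift(arr: np.ndarray, off: int) -> np.ndarray:
        """arr indexed so that slot t of the result = arr[t + off]."""
        if off == 0:
            return arr
        out = np.full(WW, NEG, dtype=np.int64)
        src_lo, src_hi = max(0, off), min(WW, WW + off)
        if src_lo < src_hi:
            out[src_lo - off:src_hi - off] = arr[src_lo:src_hi]
        return out

    for i in range(1, n + 1):
        lo = los[i]
        off = lo - los[i - 1]  # slot t here corresponds to prev slot t+off
        js = lo + np.arange(WW)
        valid = (js >= 0) & (js <= m)

        pM_up = _shift(M, off)       # (i-1, j)
        pX_up = _shift(X, off)
        pY_up = _shift(Y, off)
        pM_di = _shift(M, off - 1)   # (i-1, j-1)
        pX_di = _shift(X, off - 1)
        pY_di = _shift(Y, off - 1)

        # X: a[i-1] vs gap, from (i-1, j)
        candX = np.stack([pM_up + go + ge, pX_up + ge, pY_up + go + ge])
        ptrX[i] = np.argmax(candX, axis=0)
        newX = np.max(candX, axis=0)

        # M: a[i-1] vs b[j-1], from (i-1, j-1)
        sub = np.where(
            (eb[np.clip(js - 1, 0, m - 1)] == ea[i - 1])
            & (ea[i - 1] != 4),
            match, mismatch,
        )
        candM = np.stack([pM_di, pX_di, pY_di])
        ptrM[i] = np.argmax(candM, axis=0)
        newM = np.max(candM, axis=0) + sub
        newM[js < 1] = NEG
        newX[js < 0] = NEG

        newM[~valid] = NEG
        newX[~valid] = NEG
        newX[js < 0] = NEG

        # Y: gap vs b[j-1], from (i, j-1).  Y[t] = max_{s<t}(open[s] +
        # (t-s)*ge) with open[s] = max(M[s], X[s]) + go; a prefix-scan:
        # Y[t] - t*ge = running max of (open[s] - s*ge).
        t_idx = np.arange(WW, dtype=np.int64)
        opener = np.maximum(newM, newX) + go - t_idx * ge
        opener[~valid] = NEG
        run = np.maximum.accumulate(opener)
        newY = np.full(WW, NEG, dtype=np.int64)
        newY[1:] = run[:-1] + t_idx[1:] * ge
        newY[~valid] = NEG
        newY[js < 1] = NEG
        newY[newY < NEG // 2] = NEG
        # traceback pointer: fresh open from M/X at t-1, else extension
        rowptrY = np.full(WW, _Y, dtype=np.int8)
        fromM = np.zeros(WW, dtype=bool)
        fromX = np.zeros(WW, dtype=bool)
        fromM[1:] = newY[1:] == newM[:-1] + go + ge
        fromX[1:] = newY[1:] == newX[:-1] + go + ge
        rowptrY[fromX] = _X
        rowptrY[fromM] = _M  # prefer match-state opening on ties
        ptrY[i] = rowptrY

        M, X, Y = newM, newX, newY

    # endpoint (n, m)
    t_end = m - los[n]
    finals = (M[t_end], Y[t_end], X[t_end])
    states = (_M, _Y, _X)
    best = max(range(3), key=lambda k: finals[k])
    score = int(finals[best])
    state = states[best]

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        t = j - los[i]
        if state == _M:
            prev = ptrM[i, t]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == _X:
            prev = ptrX[i, t]
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            prev = ptrY[i, t]
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        if i == 0 and j == 0:
            break
        if i == 0:
            state = _Y
        elif j == 0:
            state = _X
        else:
            state = int(prev)
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score


# ---------------------------------------------------------------------------
# Reference projection


@dataclass
class ReferenceProjection:
    """A locus laid out in reference coordinate space.

    ``cols[r]`` is the locus base aligned to reference position ``r``
    (0-based) or '-' where the locus has no base there; ``insertions``
    maps a reference anchor position r (0-based; the inserted bases sit
    between reference positions r-1 and r... anchored *after* position
    r-1, i.e. before ``r``) to the inserted string.
    """

    ref_len: int
    cols: np.ndarray  # dtype '<U1'
    insertions: dict[int, str] = field(default_factory=dict)
    locus_id: str = ""

    def coverage(self, span: tuple[int, int]) -> float:
        s, e = span
        seg = self.cols[s:e]
        if len(seg) == 0:
            return 0.0
        return float(np.count_nonzero(seg != "-")) / (e - s)

    def column_string(self, span: tuple[int, int]) -> str:
        """Aligned locus bases over a reference span ('-' at gaps)."""
        s, e = span
        return "".join(self.cols[s:e])

    def observed_seq(self, span: tuple[int, int],
                     with_insertions: bool = True) -> str:
        """The locus bases within a reference span, insertions spliced in."""
        s, e = span
        parts: list[str] = []
        for r in range(s, e):
            if with_insertions and r in self.insertions and r > s:
                parts.append(self.insertions[r])
            ch = self.cols[r]
            if ch != "-":
                parts.append(ch)
        if with_insertions and e in self.insertions:
            pass  # insertion after the span's last base belongs downstream
        return "".join(parts)

    @property
    def locus_len(self) -> int:
        matched = int(np.count_nonzero(self.cols != "-"))
        inserted = sum(len(s) for s in self.insertions.values())
        return matched + inserted


def project_locus(
    locus_seq: str,
    reference_seq: str,
    locus_id: str = "",
    band: int | None = None,
    **scoring,
) -> ReferenceProjection:
    """Align a locus to a reference sequence and project it.

    ``band`` defaults to a corridor wide enough for the largest
    structural rearrangement the simulator plants (the env replacement).
    Projection alignments use a stiffer gap-open penalty than the plain
    pairwise default: long novel insertions must stay single events
    rather than being fragmented around chance few-base matches to the
    reference, which is what indel cataloging depends on.
    """
    scoring.setdefault("gap_open", -16)
    if band is None and max(len(locus_seq), len(reference_seq)) > 2000:
        # wide enough for the largest planted rearrangement (env
        # replacement drift), verified against wider bands
        band = max(800, abs(len(locus_seq) - len(reference_seq)) + 600)
    aln_a, aln_b, _ = global_align(locus_seq, reference_seq, band=band,
                                   **scoring)
    cols = np.full(len(reference_seq), "-", dtype="<U1")
    insertions: dict[int, list[str]] = {}
    r = 0
    for ca, cb in zip(aln_a, aln_b):
        if cb == "-":
            insertions.setdefault(r, []).append(ca)
        else:
            if ca != "-":
                cols[r] = ca
            r += 1
    return ReferenceProjection(
        ref_len=len(reference_seq),
        cols=cols,
        insertions={k: "".join(v) for k, v in insertions.items()},
        locus_id=locus_id,
    )


def project_reference(model: ReferenceModel) -> ReferenceProjection:
    """Identity projection of the reference onto itself."""
    seq = model.provirus_seq
    return ReferenceProjection(
        ref_len=len(seq), cols=np.array(list(seq), dtype="<U1"),
        insertions={}, locus_id="reference",
    )


# ---------------------------------------------------------------------------
# Indel calling and region annotation


@dataclass(frozen=True)
class IndelEvent:
    """One insertion or deletion relative to the reference.

    ``ref_start0`` is 0-based on the reference the projection was built
    against (the full provirus for full loci).  For deletions the event
    spans ``[ref_start0, ref_start0 + length)``; for insertions the
    inserted bases sit immediately before reference position
    ``ref_start0``.  ``anchor_internal_1based`` restates the anchor in
    the conventional 1-based internal-sequence coordinates when a model
    is supplied to :func:`call_indels`.
    """

    kind: str  # "insertion" | "deletion"
    ref_start0: int
    length: int
    regions: tuple[str, ...] = ()
    anchor_internal_1based: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad indel kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")


def _containing_regions(model: ReferenceModel | None, start0: int,
                        end0: int) -> tuple[str, ...]:
    if model is None:
        return ()
    out = []
    for name in ("LTR5", *model.regions.keys(), *model.domains.keys(),
                 "LTR3"):
        s, e = model.provirus_span(name)
        if start0 < e and end0 > s:
            out.append(name)
    return tuple(out)


def call_indels(projection: ReferenceProjection,
                model: ReferenceModel | None = None) -> list[IndelEvent]:
    """Maximal gap runs become deletions; insertion-store runs, insertions."""
    events: list[IndelEvent] = []
    gaps = projection.cols == "-"
    r = 0
    n = projection.ref_len
    while r < n:
        if gaps[r]:
            start = r
            while r < n and gaps[r]:
                r += 1
            events.append(IndelEvent(
                kind="deletion", ref_start0=start, length=r - start,
                regions=_containing_regions(model, start, r),
                anchor_internal_1based=(
                    start - model.ltr_len + 1 if model else None),
            ))
        else:
            r += 1
    for anchor, ins in sorted(projection.insertions.items()):
        events.append(IndelEvent(
            kind="insertion", ref_start0=anchor, length=len(ins),
            regions=_containing_regions(model, anchor, anchor + 1),
            anchor_internal_1based=(
                anchor - model.ltr_len + 1 if model else None),
        ))
    events.sort(key=lambda e: (e.ref_start0, e.kind))
    return events


@dataclass(frozen=True)
class RegionAnnotation:
    """Per-region completeness of one locus."""

    locus_id: str
    region_coverage: dict[str, float]
    region_length: dict[str, int]
    region_gc: dict[str, float]
    locus_length: int
    full_length: bool


def annotate_regions(projection: ReferenceProjection, model: ReferenceModel,
                     full_len_threshold: float = 0.8) -> RegionAnnotation:
    """Coverage, observed length and GC per gene; full-length call."""
    cov: dict[str, float] = {}
    length: dict[str, int] = {}
    gc: dict[str, float] = {}
    for name in ("LTR5", "gag", "pro", "pol", "env", "LTR3"):
        span = model.provirus_span(name)
        cov[name] = projection.coverage(span)
        obs = projection.observed_seq(span)
        length[name] = len(obs)
        gc[name] = gc_content(obs)
    full = all(cov[g] >= full_len_threshold
               for g in ("gag", "pro", "pol", "env"))
    return RegionAnnotation(
        locus_id=projection.locus_id,
        region_coverage=cov,
        region_length=length,
        region_gc=gc,
        locus_length=projection.locus_len,
        full_length=full,
    )
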