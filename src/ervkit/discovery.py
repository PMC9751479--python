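"""Locus discovery by exact k-mer seeding, and orthology by flank identity.

Discovery indexes every k-mer of the reference LTR and internal
sequence (both strands) and scans a genome for exact seed matches.
Seeds close together on the same strand are chained into candidate
loci; each seed also implies, through its reference offset, where the
element must start and end in the genome, so locus boundaries are
estimated as the median implied boundary over the (indel-free) LTR
seeds.  Chains are filtered by matched span so that chance seed hits
on locus-free DNA are rejected.

Orthology: two loci in different species are the same insertion if the
host DNA flanking them matches.  Flanks are extracted strand-aware,
screened for a shared seed word, aligned (edit distance), and grouped
by single-linkage when mean flank identity reaches the threshold; a
group's species set determines its category.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from ._seq import revcomp
from .io import GenomicInterval, SequenceRecord
from .reference import ReferenceModel


@dataclass
class LocusHit:
    """One candidate locus found in a genome scan."""

    interval: GenomicInterval
    matched_parts: frozenset[str]   # subset of {LTR5, internal, LTR3}
    score: int                      # matched seed count
    solo_ltr: bool

    def __post_init__(self) -> None:
        has_ltr = bool(self.matched_parts & {"LTR5", "LTR3"})
        assert self.solo_ltr == (has_ltr
                                 and "internal" not in self.matched_parts)


def _index_reference(model: ReferenceModel, k: int) -> dict[str, list]:
    """kmer -> [(part, offset, strand)] for LTR and internal sequences."""
    idx: dict[str, list] = {}
    for part, seq in (("LTR", model.ltr_seq), ("internal",
                                               model.internal_seq)):
        for i in range(len(seq) - k + 1):
            idx.setdefault(seq[i:i + k], []).append((part, i, "+"))
        rc = revcomp(seq)
        for i in range(len(rc) - k + 1):
            # offset recorded on the forward reference
            idx.setdefault(rc[i:i + k], []).append(
                (part, len(seq) - i - k, "-"))
    return idx


def scan_genome(
    genome: SequenceRecord,
    model: ReferenceModel,
    k: int = 16,
    min_internal_len: int = 500,
    min_ltr_span: int = 300,
    min_seeds: int = 3,
    merge_gap: int = 2000,
) -> list[LocusHit]:
    """Find HML2-like loci in one genome by seed-and-extend.

    Returns hits sorted by start coordinate.  A chain is kept when its
    matched internal span reaches ``min_internal_len`` or its matched
    LTR span reaches ``min_ltr_span`` (solo LTRs); isolated chance
    seeds fail both.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if len(model.ltr_seq) < k or len(model.internal_seq) < k:
        raise ValueError("reference shorter than k: degenerate seed space")
    if not genome.seq:
        raise ValueError("empty genome")
    idx = _index_reference(model, k)
    L = model.ltr_len
    M_full = 2 * L + len(model.internal_seq)

    seeds: dict[str, list[tuple[int, str, int]]] = {"+": [], "-": []}
    g = genome.seq
    for i in range(len(g) - k + 1):
        for part, off, strand in idx.get(g[i:i + k], ()):
            seeds[strand].append((i, part, off))

    hits: list[LocusHit] = []
    for strand in "+-":
        ss = sorted(seeds[strand])
        chain: list[tuple[int, str, int]] = []
        for s in ss + [(int(1e18), "end", 0)]:
            if chain and s[0] - chain[-1][0] > merge_gap:
                hit = _chain_to_hit(chain, strand, genome.id, k, L, M_full,
                                    len(model.internal_seq), len(g),
                                    min_internal_len, min_ltr_span,
                                    min_seeds)
                if hit is not None:
                    hits.append(hit)
                chain = []
            if s[1] != "end":
                chain.append(s)
    hits.sort(key=lambda h: h.interval.start)
    merged: list[LocusHit] = []
    for h in hits:  # union overlapping hits, leftmost-start tie-break
        if merged and h.interval.start < merged[-1].interval.end \
                and h.interval.strand == merged[-1].interval.strand:
            prev = merged.pop()
            iv = GenomicInterval(
                prev.interval.contig, prev.interval.start,
                max(prev.interval.end, h.interval.end),
                prev.interval.strand, prev.interval.name)
            parts = prev.matched_parts | h.matched_parts
            merged.append(LocusHit(
                interval=iv, matched_parts=parts,
                score=prev.score + h.score,
                solo_ltr=bool(parts & {"LTR5", "LTR3"})
                and "internal" not in parts))
        else:
            merged.append(h)
    return merged


def _chain_to_hit(chain, strand, contig, k, L, M_full, internal_len,
                  glen, min_internal_len, min_ltr_span, min_seeds):
    if len(chain) < min_seeds:
        return None
    internal_seeds = [(g, off) for g, p, off in chain if p == "internal"]
    ltr_seeds = [(g, off) for g, p, off in chain if p == "LTR"]

    int_span = 0
    if internal_seeds:
        gs = [g for g, _ in internal_seeds]
        int_span = max(gs) + k - min(gs)
    ltr_span = 0
    if ltr_seeds:
        gs = [g for g, _ in ltr_seeds]
        ltr_span = max(gs) + k - min(gs)
        ltr_span = min(ltr_span, 2 * L)  # two LTRs far apart
    if int_span < min_internal_len and ltr_span < min_ltr_span:
        return None

    full = bool(internal_seeds)
    if full:
        centroid = float(np.median([g for g, _ in internal_seeds]))
    else:
        centroid = float(np.median([g for g, _ in ltr_seeds]))

    # Boundaries from the LTR seeds of each side: LTRs carry no indels,
    # so their implied element edges are exact.  Internal seeds are the
    # fallback (exact up to the net indel length).
    left_ltr = [(g, off) for g, off in ltr_seeds if g <= centroid or not full]
    right_ltr = [(g, off) for g, off in ltr_seeds if g > centroid or not full]

    def _median(vals):
        return int(np.median(vals)) if vals else None

    if strand == "+":
        start = _median([g - off for g, off in left_ltr])
        end = _median([g + (L - off) for g, off in right_ltr])
        if start is None:
            start = _median([g - (L + off) for g, off in internal_seeds])
        if end is None:
            end = _median([g + (M_full - L - off)
                           for g, off in internal_seeds])
    else:
        # genome-left is the element's 3' side on the minus strand
        start = _median([g - (L - off - k) for g, off in left_ltr])
        end = _median([g + off + k for g, off in right_ltr])
        if start is None:
            start = _median([g - (M_full - (L + off) - k)
                             for g, off in internal_seeds])
        if end is None:
            end = _median([g + (L + off) + k for g, off in internal_seeds])
    if start is None or end is None:
        return None
    start = max(0, start)
    end = min(glen, end)
    if end <= start:
        return None

    parts = set()
    if internal_seeds:
        parts.add("internal")
    if ltr_seeds:
        if not full:
            parts.add("LTR5")
        else:
            for g, off in ltr_seeds:
                left = g < centroid
                if strand == "+":
                    parts.add("LTR5" if left else "LTR3")
                else:
                    parts.add("LTR3" if left else "LTR5")
    solo = bool(parts & {"LTR5", "LTR3"}) and "internal" not in parts
    iv = GenomicInterval(contig, start, end, strand,
                         f"hit_{contig}_{start}")
    return LocusHit(interval=iv, matched_parts=frozenset(parts),
                    score=len(chain), solo_ltr=solo)


def extract_locus(genome: SequenceRecord, hit: LocusHit) -> str:
    """Element sequence in its own orientation (revcomp on minus strand)."""
    seq = genome.seq[hit.interval.start:hit.interval.end]
    return revcomp(seq) if hit.interval.strand == "-" else seq


# ---------------------------------------------------------------------------
# Orthology


@dataclass
class OrthologyResult:
    categories: dict[tuple[str, int], str]   # (species, hit index) -> category
    groups: list[list[tuple[str, int]]]      # ortholog groups
    unclassifiable: set[tuple[str, int]]


def _flanks(genome: SequenceRecord, hit: LocusHit,
            flank_len: int) -> tuple[str, str] | None:
    s, e = hit.interval.start, hit.interval.end
    if s - flank_len < 0 or e + flank_len > len(genome.seq):
        return None
    left = genome.seq[s - flank_len:s]
    right = genome.seq[e:e + flank_len]
    if hit.interval.strand == "-":
        return revcomp(right), revcomp(left)
    return left, right


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance", mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def classify_orthology(
    hits_by_species: dict[str, list[LocusHit]],
    genomes: dict[str, SequenceRecord],
    flank_len: int = 200,
    min_flank_identity: float = 0.9,
    outgroup: str = "human",
    screen_word: int = 24,
) -> OrthologyResult:
    """Group loci across species by flank identity; assign categories.

    Single-linkage grouping (the symmetric/transitive closure of the
    pairwise relation).  Groups containing the outgroup species are
    ``human_shared``; groups spanning two or more non-outgroup species
    are ``macaque_shared``; singletons are ``species_specific``.  Loci
    whose flanks run off the contig are flagged unclassifiable.
    """
    if len(hits_by_species) < 1:
        raise ValueError("no species provided")
    keys: list[tuple[str, int]] = []
    flanks: dict[tuple[str, int], tuple[str, str]] = {}
    unclassifiable: set[tuple[str, int]] = set()
    for sp, hits in hits_by_species.items():
        for i, h in enumerate(hits):
            key = (sp, i)
            keys.append(key)
            fl = _flanks(genomes[sp], h, flank_len)
            if fl is None:
                unclassifiable.add(key)
            else:
                flanks[key] = fl

    # seed-word screen on upstream flanks
    word_index: dict[str, list[tuple[str, int]]] = {}
    for key, (up, _dn) in flanks.items():
        seen = set()
        for i in range(0, len(up) - screen_word + 1):
            w = up[i:i + screen_word]
            if w not in seen:
                word_index.setdefault(w, []).append(key)
                seen.add(w)

    parent: dict[tuple[str, int], tuple[str, int]] = {
        k: k for k in flanks}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    candidates: set[tuple] = set()
    for _w, ks in word_index.items():
        if len(ks) < 2:
            continue
        for a in ks:
            for b in ks:
                if a < b and a[0] != b[0]:
                    candidates.add((a, b))
    for a, b in sorted(candidates):
        upi = _identity(flanks[a][0], flanks[b][0])
        dni = _identity(flanks[a][1], flanks[b][1])
        if (upi + dni) / 2 >= min_flank_identity:
            union(a, b)

    groups_map: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for kk in flanks:
        groups_map.setdefault(find(kk), []).append(kk)
    groups = sorted(groups_map.values())

    categories: dict[tuple[str, int], str] = {}
    for grp in groups:
        sps = {sp for sp, _ in grp}
        if outgroup in sps and len(sps) > 1:
            cat = "human_shared"
        elif len(sps) > 1:
            cat = "macaque_shared"
        else:
            cat = "species_specific"
        for kk in grp:
            categories[kk] = cat
    for kk in unclassifiable:
        categories[kk] = "unclassifiable"
    return OrthologyResult(categories=categories, groups=groups,
                           unclassifiable=unclassifiable)
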