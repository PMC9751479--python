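"""Residual coding capacity: ORF integrity, domains, protein motifs.

A gene's reading frame is taken from the reference gene start mapped
through the projection; premature stops are counted in the observed
(indel-spliced) gene sequence, and a frameshift is declared when the net
indel length inside the gene is not a multiple of three.  Domain
presence is coverage-based; motif scanning finds the nucleocapsid zinc
knuckle (CX2CX4HX4C, overlapping matches allowed) and the fixed NLS/NES
peptides recorded in the reference model.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import translate
from .align import IndelEvent, ReferenceProjection, call_indels
from .reference import (
    DOMAINS_BY_GENE,
    ReferenceModel,
    ZINC_KNUCKLE_RE,
)


@dataclass(frozen=True)
class MotifMatch:
    motif: str      # zinc_knuckle | NLS | NES
    position: int   # 1-based position in the scanned protein
    matched: str


@dataclass(frozen=True)
class OrfReport:
    gene: str
    present: bool
    coverage: float
    intact: bool
    premature_stops: int
    frameshift: bool
    protein_length: int
    domains_present: tuple[str, ...]
    motif_matches: tuple[MotifMatch, ...]


def scan_motifs(protein: str, model: ReferenceModel | None = None
                ) -> list[MotifMatch]:
    """Scan a protein for zinc knuckles and (if a model is given) NLS/NES."""
    out: list[MotifMatch] = []
    for m in ZINC_KNUCKLE_RE.finditer(protein):
        out.append(MotifMatch("zinc_knuckle", m.start() + 1,
                              protein[m.start():m.start() + 14]))
    if model is not None:
        for name, pep in (("NLS", model.nls_peptide),
                          ("NES", model.nes_peptide)):
            start = 0
            while True:
                i = protein.find(pep, start)
                if i < 0:
                    break
                out.append(MotifMatch(name, i + 1, pep))
                start = i + 1
    out.sort(key=lambda m: m.position)
    return out


def domain_presence(projection: ReferenceProjection, model: ReferenceModel,
                    gene: str, min_cov: float = 0.9) -> tuple[str, ...]:
    """Domains whose reference span is covered at >= min_cov."""
    if gene not in DOMAINS_BY_GENE:
        raise ValueError(f"gene {gene!r} has no domain annotations")
    present = []
    for dom in DOMAINS_BY_GENE[gene]:
        if projection.coverage(model.provirus_span(dom)) >= min_cov:
            present.append(dom)
    return tuple(present)


def _gene_indels(projection: ReferenceProjection, model: ReferenceModel,
                 gene: str) -> list[IndelEvent]:
    s, e = model.provirus_span(gene)
    out = []
    for ev in call_indels(projection):
        if ev.kind == "deletion":
            lo, hi = ev.ref_start0, ev.ref_start0 + ev.length
            if lo < e and hi > s:  # clip to the gene
                clipped = min(hi, e) - max(lo, s)
                out.append(IndelEvent("deletion", max(lo, s), clipped))
        else:
            if s < ev.ref_start0 < e:
                out.append(ev)
    return out


def _observed_frame_seq(projection: ReferenceProjection,
                        model: ReferenceModel, gene: str) -> str:
    """Observed gene sequence starting at the first present in-frame codon."""
    s, e = model.provirus_span(gene)
    # first non-gap reference position congruent to the gene start mod 3
    start = None
    for r in range(s, e):
        if projection.cols[r] != "-" and (r - s) % 3 == 0:
            start = r
            break
    if start is None:
        return ""
    return projection.observed_seq((start, e))


def orf_integrity(projection: ReferenceProjection, model: ReferenceModel,
                  gene: str, min_cov: float = 0.95,
                  domain_min_cov: float = 0.9) -> OrfReport:
    """Assess one gene's residual coding capacity on a projected locus."""
    if gene not in model.regions:
        raise ValueError(f"unknown gene {gene!r}")
    span = model.provirus_span(gene)
    coverage = projection.coverage(span)
    if coverage == 0.0:
        return OrfReport(gene=gene, present=False, coverage=0.0,
                         intact=False, premature_stops=0, frameshift=False,
                         protein_length=0, domains_present=(),
                         motif_matches=())
    indels = _gene_indels(projection, model, gene)
    net = sum(ev.length if ev.kind == "insertion" else -ev.length
              for ev in indels)
    frameshift = (net % 3) != 0

    obs = _observed_frame_seq(projection, model, gene)
    protein = translate(obs)
    stops = protein.count("*")
    plen = protein.index("*") if "*" in protein else len(protein)
    doms = (domain_presence(projection, model, gene, domain_min_cov)
            if gene in DOMAINS_BY_GENE else ())
    motifs = tuple(scan_motifs(protein, model))
    intact = stops == 0 and not frameshift and coverage >= min_cov
    return OrfReport(gene=gene, present=True, coverage=coverage,
                     intact=intact, premature_stops=stops,
                     frameshift=frameshift, protein_length=plen,
                     domains_present=doms, motif_matches=motifs)


def detect_rec(projection: ReferenceProjection, model: ReferenceModel,
               min_cov: float = 0.95) -> dict[str, bool]:
    """Presence of a complete, frame-intact Rec portion with NLS and NES.

    Rec is read in its own frame anchored at the Rec start (codon-aligned
    with env), mirroring the spliced rec message: indels upstream in env
    do not shift it, but indels inside Rec do.
    """
    env_span = model.provirus_span("env")
    if projection.coverage(env_span) == 0.0:
        return {"rec_present": False, "nls": False, "nes": False}
    rec_span = model.provirus_span("Rec")
    cov = projection.coverage(rec_span)
    s, e = rec_span
    net = 0
    for ev in call_indels(projection):
        if ev.kind == "deletion":
            lo, hi = ev.ref_start0, ev.ref_start0 + ev.length
            if lo < e and hi > s:
                net -= min(hi, e) - max(lo, s)
        elif s < ev.ref_start0 < e:
            net += ev.length
    frame_ok = (net % 3) == 0
    rec_present = cov >= min_cov and frame_ok
    if not rec_present:
        return {"rec_present": False, "nls": False, "nes": False}
    protein = translate(projection.observed_seq(rec_span))
    matches = {m.motif for m in scan_motifs(protein, model)}
    return {"rec_present": True, "nls": "NLS" in matches,
            "nes": "NES" in matches}
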