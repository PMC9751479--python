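"""Synthetic HML2 reference-provirus model.

The model mirrors the canonical HML2 prototype layout: a ~8-kb internal
coding region (gag, pro, pol, env, with the genes' published 1-based
coordinates) flanked by two identical LTRs.  The internal sequence is
random DNA constrained so that the gag and env reading frames are
stop-free, the nucleocapsid carries exactly two zinc-knuckle motifs
(CX2CX4HX4C), and the Rec portion of env carries exactly one nuclear
localization signal and one nuclear export signal.  The LTR is generated
CpG-free, reflecting the strong CpG depletion of primate genomic DNA and
making CpG-masked LTR divergence an exact clock on simulated cohorts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from ._rng import substream
from ._seq import (
    encode_peptide,
    gc_content,
    random_dna,
    strip_cpg,
    translate,
)
from .io import from_one_based

LTR_LEN = 968
INTERNAL_LEN = 8000

#: published gene coordinates on the internal sequence, 1-based inclusive
GENE_COORDS_1BASED = {
    "gag": (156, 2297),
    "pro": (2063, 3082),
    "pol": (3037, 5785),
    "env": (5624, 7951),
}

#: protein-domain coordinates, 1-based inclusive, nested in their gene;
#: gag and env domains are in-frame with their gene's reading frame
DOMAIN_COORDS_1BASED = {
    "MA": (156, 575),      # gag matrix, codons 1-140
    "CA": (603, 1505),     # gag capsid, codons 150-450
    "NC": (1953, 2297),    # gag nucleocapsid, codons 600-714
    "RT": (3200, 4199),    # pol reverse transcriptase
    "RH": (4250, 4699),    # pol RNase H
    "IN": (4750, 5699),    # pol integrase
    "SU": (5624, 6913),    # env surface unit, codons 1-430
    "TM": (6941, 7951),    # env transmembrane, codons 440-776
    "Rec": (5801, 6103),   # env accessory-protein portion, codons 60-160
                           # (downstream of the pol overlap)
    "NLS": (5831, 5857),   # inside Rec
    "NES": (5951, 5983),   # inside Rec
}

DOMAINS_BY_GENE = {
    "gag": ("MA", "CA", "NC"),
    "pol": ("RT", "RH", "IN"),
    "env": ("SU", "TM"),
}

#: zinc-knuckle peptide (CX2CX4HX4C) planted twice in NC; gag codon starts
ZINC_KNUCKLE_PEPTIDE = "CAECGKWTHLVNRC"
ZINC_KNUCKLE_CODONS = (620, 660)  # 1-based codon index within gag

NLS_PEPTIDE = "RKQRRSRRK"
NES_PEPTIDE = "LQLPPLERLTL"

ZINC_KNUCKLE_RE = re.compile(r"(?=C..C....H....C)")

#: fixed internal 1-based anchor of the 292-nt type-I env deletion; chosen
#: to overlap the 3' half of Rec so type-I proviruses lose the Rec reading
#: capacity, as type I elements do
TYPE_I_DEL_SPAN_1BASED = (5800, 6091)


@dataclass(frozen=True)
class ReferenceModel:
    """Reference provirus: sequences plus coordinate/motif tables.

    ``regions`` and ``domains`` are 0-based half-open on the internal
    sequence; use :meth:`provirus_span` for full-provirus coordinates.
    """

    internal_seq: str
    ltr_seq: str
    regions: dict[str, tuple[int, int]]
    domains: dict[str, tuple[int, int]]
    nls_peptide: str = NLS_PEPTIDE
    nes_peptide: str = NES_PEPTIDE

    @property
    def ltr_len(self) -> int:
        return len(self.ltr_seq)

    @property
    def provirus_seq(self) -> str:
        return self.ltr_seq + self.internal_seq + self.ltr_seq

    def provirus_span(self, name: str) -> tuple[int, int]:
        """0-based half-open span of a named part on the full provirus."""
        L = self.ltr_len
        if name == "LTR5":
            return (0, L)
        if name == "LTR3":
            return (L + len(self.internal_seq),
                    L + len(self.internal_seq) + L)
        if name in self.regions:
            s, e = self.regions[name]
        elif name in self.domains:
            s, e = self.domains[name]
        else:
            raise KeyError(f"unknown region or domain: {name!r}")
        return (s + L, e + L)

    def gene_seq(self, name: str) -> str:
        s, e = self.regions[name]
        return self.internal_seq[s:e]

    def internal_to_provirus(self, pos0: int) -> int:
        return pos0 + self.ltr_len

    def provirus_to_internal(self, pos0: int) -> int:
        return pos0 - self.ltr_len


def _fix_stops(seq: list[str], start0: int, end0: int) -> None:
    """Rewrite stop codons in the frame starting at start0 (in place)."""
    for i in range(start0, end0 - 2, 3):
        codon = "".join(seq[i:i + 3])
        if codon in ("TAA", "TAG", "TGA"):
            seq[i + 2] = "C"  # TAC=Y / TGC=C: never a stop


def _plant_peptide(seq: list[str], gene_start0: int, codon1: int,
                   peptide: str) -> None:
    nt = encode_peptide(peptide)
    off = gene_start0 + 3 * (codon1 - 1)
    seq[off:off + len(nt)] = list(nt)


def build_reference(seed: int, gc_target: float = 0.41,
                    max_attempts: int = 20) -> ReferenceModel:
    """Construct a reference model deterministically from a seed.

    Retries (bounded) until the frame, motif-count and GC constraints all
    hold; with random DNA the first attempt almost always succeeds.
    """
    regions = {k: from_one_based(*v) for k, v in GENE_COORDS_1BASED.items()}
    domains = {k: from_one_based(*v) for k, v in DOMAIN_COORDS_1BASED.items()}
    rng = substream(seed, "reference")
    for _ in range(max_attempts):
        ltr = strip_cpg(random_dna(rng, LTR_LEN, gc_target), rng)
        internal = list(random_dna(rng, INTERNAL_LEN, gc_target))

        gag_s, gag_e = regions["gag"]
        env_s, env_e = regions["env"]
        for codon1 in ZINC_KNUCKLE_CODONS:
            _plant_peptide(internal, gag_s, codon1, ZINC_KNUCKLE_PEPTIDE)
        rec_s = domains["Rec"][0]
        nls_codon = (domains["NLS"][0] - env_s) // 3 + 1
        nes_codon = (domains["NES"][0] - env_s) // 3 + 1
        _plant_peptide(internal, env_s, nls_codon, NLS_PEPTIDE)
        _plant_peptide(internal, env_s, nes_codon, NES_PEPTIDE)
        # gag/pro, pro/pol and pol/env overlap in different phases, so a
        # fix in one frame can create a stop in another: iterate to a
        # jointly stop-free state
        for _ in range(50):
            for s0, e0 in regions.values():
                _fix_stops(internal, s0, e0)
            if all("*" not in translate("".join(internal[s0:e0]))
                   for s0, e0 in regions.values()):
                break
        internal_str = "".join(internal)

        gag_prot = translate(internal_str[gag_s:gag_e])
        env_prot = translate(internal_str[env_s:env_e])
        model = ReferenceModel(internal_str, ltr, regions, domains)
        ok = (
            all("*" not in translate(internal_str[s0:e0])
                for s0, e0 in regions.values())
            and len(ZINC_KNUCKLE_RE.findall(gag_prot)) == 2
            and gag_prot.count(NLS_PEPTIDE) == 0
            and env_prot.count(NLS_PEPTIDE) == 1
            and env_prot.count(NES_PEPTIDE) == 1
            and abs(gc_content(ltr + internal_str) - gc_target) <= 0.02
        )
        if ok:
            return model
    raise RuntimeError(
        "could not satisfy reference constraints within attempt bound"
    )


def build_mer11a(seed: int, length: int = 1200,
                 gc_target: float = 0.41) -> str:
    """Synthetic MER11A (HML8 LTR) parent sequence for recombination."""
    rng = substream(seed, "mer11a")
    return random_dna(rng, length, gc_target)
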