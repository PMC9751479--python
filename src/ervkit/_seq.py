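"""Small sequence primitives shared across modules."""

from __future__ import annotations

import numpy as np

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = ("TAA", "TAG", "TGA")

#: one representative codon per amino acid, CpG-free within the codon
AA_TO_CODON = {
    "F": "TTT", "L": "CTT", "I": "ATT", "M": "ATG", "V": "GTT",
    "S": "TCT", "P": "CCT", "T": "ACT", "A": "GCT", "Y": "TAT",
    "H": "CAT", "Q": "CAA", "N": "AAT", "K": "AAA", "D": "GAT",
    "E": "GAA", "C": "TGT", "W": "TGG", "R": "AGA", "G": "GGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def translate(seq: str) -> str:
    """Translate in frame 0; incomplete trailing codon is dropped.

    N-containing codons translate to 'X'.
    """
    aas = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        aas.append(CODON_TABLE.get(codon, "X"))
    return "".join(aas)


def encode_peptide(peptide: str) -> str:
    return "".join(AA_TO_CODON[aa] for aa in peptide)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.41) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def strip_cpg(seq: str, rng: np.random.Generator) -> str:
    """Replace the G of every CG dinucleotide until none remain."""
    s = list(seq)
    while True:
        hits = [i for i in range(len(s) - 1) if s[i] == "C" and s[i + 1] == "G"]
        if not hits:
            return "".join(s)
        for i in hits:
            s[i + 1] = rng.choice(["A", "T", "C"])


def seq_to_array(seq: str) -> np.ndarray:
    """Encode A,C,G,T,N,- as uint8 0..5 for vectorized comparison."""
    lut = np.full(128, 5, dtype=np.uint8)
    for i, ch in enumerate("ACGTN-"):
        lut[ord(ch)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
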