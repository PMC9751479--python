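"""Reading and writing the standard formats the pipeline touches.

FASTA goes through Biopython, Newick through scikit-bio; BED6 and the
flat YAML run configuration are handled directly.  All genomic intervals
in this package are 0-based half-open (BED-native); printed retroviral
reference coordinates in the literature are 1-based inclusive and are
converted on load via :func:`from_one_based` / :func:`to_one_based`.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
import skbio

DNA_ALPHABET = frozenset("ACGTN")


class FastaFormatError(ValueError):
    """Raised when a FASTA record violates the DNA alphabet or is empty."""


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named, normalized DNA sequence (uppercase, U converted to T)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise FastaFormatError(
                f"record {self.id!r} contains non-IUPAC-DNA characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig, with strand."""

    contig: str
    start: int
    end: int
    strand: str = "+"
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def normalize_dna(seq: str) -> str:
    """Uppercase and map RNA U to T; validation happens in SequenceRecord."""
    return seq.upper().replace("U", "T")


def from_one_based(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive span to 0-based half-open."""
    return start1 - 1, end1


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open span to 1-based inclusive."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a multi-FASTA file into normalized records, order preserved."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=normalize_dna(str(rec.seq)),
                description=rec.description,
            )
        )
    if not records:
        # distinguish missing file (open() in SeqIO already raised) from
        # a present-but-headerless file
        with open(path) as fh:
            if not fh.read().strip().startswith(">"):
                raise FastaFormatError(f"{path}: not FASTA-formatted")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# BED6


def write_bed(intervals: Sequence[GenomicInterval], path: str | os.PathLike,
              scores: Sequence[int] | None = None) -> None:
    """Write BED6 (0-based half-open), one line per interval."""
    if scores is None:
        scores = [0] * len(intervals)
    with open(path, "w") as fh:
        for iv, score in zip(intervals, scores):
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t"
                f"{iv.strand}\n"
            )


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: fewer than 3 BED columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "+"
            out.append(GenomicInterval(contig, start, end, strand, name))
    return out


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: skbio.TreeNode, path: str | os.PathLike) -> None:
    """Write a tree as Newick; internal node names carry bootstrap support."""
    leaves = [t.name for t in tree.tips()]
    if len(leaves) != len(set(leaves)):
        raise ValueError("duplicate leaf labels in tree")
    tree.write(str(path), format="newick")


def read_newick(path: str | os.PathLike) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")


# ---------------------------------------------------------------------------
# Flat YAML configuration

#: key -> (type, default).  Defaults here are the package-wide study
#: conditions; anything not listed is rejected so runs stay reproducible.
CONFIG_SCHEMA: dict[str, tuple[type, object]] = {
    "species": (list, ["human", "macfas", "rhesus"]),
    "n_human_shared": (int, 12),
    "n_macaque_shared": (int, 46),
    "n_species_specific": (int, 19),
    "specific_species": (str, "macfas"),
    "age_human_shared": (float, 32.4),
    "age_macaque_shared": (float, 15.7),
    "age_species_specific": (float, 5.6),
    "n_solo_ltr": (int, 1),
    "gag_intact_fraction": (float, 0.15),
    "pol_intact_fraction": (float, 0.10),
    "flank_len": (int, 300),
    "shared_flank_len": (int, 200),
    "spacer_len": (int, 2000),
    "gc_target": (float, 0.41),
    "cpg_boost": (float, 1.0),
    "seed": (int, 1),
    # discovery
    "k": (int, 16),
    "min_internal_len": (int, 500),
    "min_ltr_span": (int, 300),
    "min_seeds": (int, 3),
    "merge_gap": (int, 2000),
    "min_flank_identity": (float, 0.9),
    # alignment scoring
    "match": (int, 2),
    "mismatch": (int, -3),
    "gap_open": (int, -5),
    "gap_extend": (int, -2),
    # annotation / coding thresholds
    "full_len_threshold": (float, 0.8),
    "domain_min_cov": (float, 0.9),
    "intact_min_cov": (float, 0.95),
    # recombination
    "sigma": (float, 3.0),
    # phylogeny
    "bootstrap_reps": (int, 500),
    "support_threshold": (float, 70.0),
}


def default_config() -> dict:
    return {k: (v[1].copy() if isinstance(v[1], list) else v[1])
            for k, v in CONFIG_SCHEMA.items()}


def load_config(path: str | os.PathLike | None = None,
                overrides: dict | None = None) -> dict:
    """Load and validate a flat key/value YAML config.

    Unknown keys and ill-typed values are errors, so a run directory's
    serialized config is a complete, unambiguous record of the run.
    """
    cfg = default_config()
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
    if overrides:
        raw.update(overrides)
    for key, value in raw.items():
        if key not in CONFIG_SCHEMA:
            raise ConfigError(f"unknown config key: {key!r}")
        want, _ = CONFIG_SCHEMA[key]
        if want is float and isinstance(value, int):
            value = float(value)
        if not isinstance(value, want):
            raise ConfigError(
                f"config key {key!r}: expected {want.__name__}, "
                f"got {type(value).__name__}"
            )
        cfg[key] = value
    return cfg


def save_config(cfg: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
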