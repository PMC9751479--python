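"""Integration-time estimation from nucleotide divergence.

The molecular clock is the host substitution rate of 0.34 % per
nucleotide per million years: T = D% / 0.34, where D is the p-distance
between two sequences that were identical at integration.  For the
LTR-vs-LTR comparison T is further halved because both LTRs accumulate
mutations independently.  p-distances use pairwise deletion (sites
gapped or ambiguous in either sequence are excluded) and mask
hypermutable CpG dinucleotides: any position that is part of a CG in
either sequence of the pair is excluded from both the site count and
the mismatch count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import ReferenceProjection, global_align
from .reference import ReferenceModel

RATE_PERCENT_PER_MYR = 0.34

METHODS = ("ltr_vs_ltr", "ltr_vs_consensus", "gag_vs_consensus",
           "pol_vs_consensus")


class NoComparableSitesError(ValueError):
    pass


class MethodUnavailableError(ValueError):
    """The locus lacks the parts the requested method needs."""


def _cpg_mask(seq: str) -> np.ndarray:
    """True at positions that are part of a CG dinucleotide in seq."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mask = np.zeros(len(seq), dtype=bool)
    cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    mask[:-1] |= cg
    mask[1:] |= cg
    return mask


def p_distance(a: str, b: str, mask_cpg: bool = False
               ) -> tuple[float, int]:
    """Pairwise-deletion p-distance between two aligned sequences.

    Returns ``(D, sites)``.  Sites gapped or 'N' in either sequence are
    excluded; with ``mask_cpg`` every position belonging to a CG
    dinucleotide in either sequence is excluded too.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    ok = np.ones(len(a), dtype=bool)
    for ch in "-N":
        ok &= (aa != ord(ch)) & (bb != ord(ch))
    if mask_cpg:
        ok &= ~_cpg_mask(a)
        ok &= ~_cpg_mask(b)
    sites = int(np.count_nonzero(ok))
    if sites == 0:
        raise NoComparableSitesError("no comparable sites between sequences")
    mism = int(np.count_nonzero((aa != bb) & ok))
    return mism / sites, sites


@dataclass(frozen=True)
class AgeEstimate:
    """One divergence-based integration-time estimate."""

    method: str
    D: float        # divergence fraction
    sites: int      # compared-site count
    T: float        # million years

    @staticmethod
    def from_divergence(method: str, D: float, sites: int) -> "AgeEstimate":
        T = (D * 100.0) / RATE_PERCENT_PER_MYR
        if method == "ltr_vs_ltr":
            T /= 2.0  # both LTRs mutate independently
        return AgeEstimate(method=method, D=D, sites=sites, T=T)


def age_from_pair(a: str, b: str, method: str,
                  mask_cpg: bool = True) -> AgeEstimate:
    """Date from an aligned pair using the clock formula for ``method``."""
    if method not in METHODS:
        raise ValueError(f"unknown dating method {method!r}")
    D, sites = p_distance(a, b, mask_cpg=mask_cpg)
    return AgeEstimate.from_divergence(method, D, sites)


def estimate_age_from_ltrs(ltr5: str, ltr3: str,
                           mask_cpg: bool = True,
                           **aln_kwargs) -> AgeEstimate:
    """LTR-vs-LTR dating from the two (unaligned) LTR sequences."""
    a, b, _ = global_align(ltr5, ltr3, **aln_kwargs)
    return age_from_pair(a, b, "ltr_vs_ltr", mask_cpg=mask_cpg)


def estimate_age(
    projection: ReferenceProjection,
    model: ReferenceModel,
    method: str,
    consensus: str | None = None,
    mask_cpg: bool = True,
    min_part_coverage: float = 0.5,
) -> AgeEstimate:
    """Date one projected locus by the requested method.

    The projection puts both LTRs (and every gene) into shared reference
    columns, so all comparisons are column-wise and need no re-alignment.
    ``consensus`` (required by the consensus methods) is a sequence over
    the relevant reference span: the LTR span for ``ltr_vs_consensus``,
    the gene span for ``gag_vs_consensus``/``pol_vs_consensus``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown dating method {method!r}")
    ltr5 = projection.column_string(model.provirus_span("LTR5"))
    ltr3 = projection.column_string(model.provirus_span("LTR3"))
    cov5 = sum(c != "-" for c in ltr5) / max(len(ltr5), 1)
    cov3 = sum(c != "-" for c in ltr3) / max(len(ltr3), 1)

    if method == "ltr_vs_ltr":
        if cov5 < min_part_coverage or cov3 < min_part_coverage:
            raise MethodUnavailableError(
                "ltr_vs_ltr requires both LTRs (solo LTR?)")
        return age_from_pair(ltr5, ltr3, method, mask_cpg=mask_cpg)

    if consensus is None:
        raise ValueError(f"{method} requires a consensus sequence")

    if method == "ltr_vs_consensus":
        ests = []
        for ltr, cov in ((ltr5, cov5), (ltr3, cov3)):
            if cov >= min_part_coverage:
                ests.append(age_from_pair(ltr, consensus, method,
                                          mask_cpg=mask_cpg))
        if not ests:
            raise MethodUnavailableError("no LTR present for dating")
        # average the per-LTR estimates
        D = float(np.mean([e.D for e in ests]))
        sites = int(np.mean([e.sites for e in ests]))
        return AgeEstimate.from_divergence(method, D, sites)

    gene = method.split("_")[0]
    part = projection.column_string(model.provirus_span(gene))
    return age_from_pair(part, consensus, method, mask_cpg=mask_cpg)


# ---------------------------------------------------------------------------
# Consensus


def build_consensus(columns: list[str], reference: str | None = None) -> str:
    """Plurality consensus over aligned member strings.

    Per column: the plurality base among non-gap members, ties broken
    toward the reference base when given (else alphabetically); columns
    gapped in more than half the members are emitted as gaps.
    """
    if not columns:
        raise ValueError("empty cluster: cannot build a consensus")
    L = len(columns[0])
    if any(len(c) != L for c in columns):
        raise ValueError("cluster members must share one coordinate space")
    mat = np.array([list(c) for c in columns])
    out: list[str] = []
    n = len(columns)
    for j in range(L):
        col = mat[:, j]
        gaps = int(np.count_nonzero(col == "-"))
        if gaps * 2 > n:
            out.append("-")
            continue
        bases, counts = np.unique(col[col != "-"], return_counts=True)
        best = counts.max()
        tied = sorted(bases[counts == best])
        if len(tied) > 1 and reference is not None and reference[j] in tied:
            out.append(reference[j])
        else:
            out.append(tied[0])
    return "".join(out)


# ---------------------------------------------------------------------------
# Summaries


@dataclass(frozen=True)
class AgeSummary:
    category: str
    n: int
    median: float
    q1: float
    q3: float
    min: float
    max: float


def summarize_ages(estimates: dict[str, list[float]]) -> list[AgeSummary]:
    """Per-category five-number summaries of ages (linear-interpolation
    quartiles, the same convention as numpy's default percentile)."""
    out = []
    for category in sorted(estimates):
        ts = np.asarray(estimates[category], dtype=float)
        if ts.size == 0:
            continue
        out.append(AgeSummary(
            category=category, n=int(ts.size),
            median=float(np.median(ts)),
            q1=float(np.percentile(ts, 25)),
            q3=float(np.percentile(ts, 75)),
            min=float(ts.min()), max=float(ts.max())))
    return out


def summaries_to_frame(summaries: list[AgeSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
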