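"""Simulated primate cohorts with planted HML2 proviruses.

The generator is the package's study-condition oracle: every planted
locus is recorded in a truth table (category, age, env type/variant,
indels, recombination span, solo-LTR status) so each pipeline stage can
be scored against known ground truth.

Model of a locus.  An ancestral provirus (LTR-internal-LTR from the
reference model, with lineage signature indels applied) is inserted with
a 6-nt target-site duplication into neutral flanking DNA.  Each carrier
species' copy then accumulates substitutions independently at
0.34 %/nt/Myr for the locus age T: each LTR copy is mutated at exactly
round(L*0.0034*T) sites, site sets disjoint between the two LTRs and no
site hit twice, so the 5'-3' LTR divergence is 2*0.0034*T up to rounding
and LTR dating is exact by construction.  Substitutions never create CpG
dinucleotides in their own sequence, never fall in planted protein
motifs, and never create stop codons in reading frames the locus is
meant to keep open — emulating the purifying selection and CpG
suppression that make these features recognizable in real genomes.

Signature features (lineage profiles):

* macaque profile: 12-nt deletion at gag 156-167 and 96-nt insertion
  anchored at reference position 745;
* human profile: no deletion; the 96-nt insertion in a minority (27 %)
  of copies;
* env type I (human lineage only): 292-nt deletion overlapping Rec;
* env variant 2: 191-nt insertion in the transmembrane region;
* env variant 3 (macaque only): the env interior — all but short 5'/3'
  stubs — replaced by a contiguous 673-nt stretch of the MER11A parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from ._seq import STOP_CODONS, random_dna, revcomp
from .align import IndelEvent
from .io import GenomicInterval, SequenceRecord
from .reference import (
    DOMAIN_COORDS_1BASED,
    GENE_COORDS_1BASED,
    ReferenceModel,
    TYPE_I_DEL_SPAN_1BASED,
    build_mer11a,
    build_reference,
)

#: host substitution rate: 0.34 % per nucleotide per million years
SUBSTITUTION_RATE = 0.0034

GAG_DEL_SPAN_1BASED = (156, 167)       # recurrent 12-nt macaque deletion
GAG_INS_ANCHOR_1BASED = 745            # 96 novel nt inserted at this anchor
GAG_INS_LEN = 96
HUMAN_GAG_INS_FRACTION = 0.27          # fraction of human copies carrying it
ENV_TM_INS_ANCHOR_1BASED = 7300        # 191-nt variant-2 insertion (in TM)
ENV_TM_INS_LEN = 191
TYPE_I_DEL_LEN = 292
MER11A_SEGMENT_LEN = 673               # variant-3 replacement segment
ENV_STUB_5 = 150                       # env 5' stub kept by variant 3
ENV_STUB_3 = 120                       # env 3' stub kept by variant 3
TSD_LEN = 6                            # target-site duplication

#: fixed per-lineage neutral flank divergence (fractions); chosen to match
#: observed primate genome divergence (~6 % human-macaque, ~1.5 %
#: macaque-macaque pairwise), which is what flank-based orthology calling
#: actually contends with
FLANK_DIVERGENCE = {"human": 0.03, "macfas": 0.0075, "rhesus": 0.0075}

#: env variant mix per category (variant 3 is macaque-only and concentrated
#: in the youngest, species-specific loci)
VARIANT_WEIGHTS = {
    "human_shared": {1: 0.6, 2: 0.4},
    "macaque_shared": {1: 0.45, 2: 0.35, 3: 0.2},
    "species_specific": {1: 0.2, 2: 0.2, 3: 0.6},
}


@dataclass(frozen=True)
class LineageMutationPlan:
    """How substitutions are planted along one lineage."""

    rate: float = SUBSTITUTION_RATE  # substitutions/nt/Myr (fraction)
    cpg_boost: float = 1.0           # >1 adds extra C->T hits at CpG sites

    def __post_init__(self) -> None:
        if self.cpg_boost < 1.0:
            raise ValueError("cpg_boost must be >= 1")


# ---------------------------------------------------------------------------
# Ancestral profile application


@dataclass(frozen=True)
class _Edit:
    kind: str          # 'del' | 'ins' | 'replace'
    start0: int        # on the reference internal sequence
    end0: int          # exclusive; == start0 for pure insertions
    insert: str = ""


class _EditMap:
    """Maps reference-internal positions through a set of edits."""

    def __init__(self, edits: list[_Edit]):
        self.edits = sorted(edits, key=lambda e: e.start0)

    def map(self, p: int) -> int | None:
        """Locus position of reference position p; None if deleted."""
        off = 0
        for e in self.edits:
            if e.kind == "ins":
                if e.start0 <= p:
                    off += len(e.insert)
            else:
                if e.end0 <= p:
                    off += len(e.insert) - (e.end0 - e.start0)
                elif e.start0 <= p < e.end0:
                    return None
        return p + off

    def map_span(self, s: int, e: int) -> tuple[int, int] | None:
        """Image of [s, e); clipped past deleted edges; None if erased."""
        for p in range(s, e):
            ms = self.map(p)
            if ms is not None:
                break
        else:
            return None
        for p in range(e - 1, s - 1, -1):
            me = self.map(p)
            if me is not None:
                return (ms, me + 1)
        return None

    def apply(self, seq: str) -> str:
        out = seq
        for e in sorted(self.edits, key=lambda x: -x.start0):
            out = out[:e.start0] + e.insert + out[e.end0:]
        return out


@dataclass
class AncestralProvirus:
    """A profiled ancestral internal sequence plus its bookkeeping."""

    internal: str
    profile: str
    env_type: str
    env_variant: int
    indels: list[IndelEvent]
    frame_spans: dict[str, tuple[int, int]]   # locus coords, phase 0 at start
    protected: list[tuple[int, int]]          # locus coords, motif spans
    env_span: tuple[int, int] | None          # locus coords of env remnant
    recomb_span: tuple[int, int] | None       # locus coords of MER11A segment


def _fix_stops_in_spans(seq: list[str], spans) -> None:
    for s, e in spans:
        for i in range(s, e - 2, 3):
            if "".join(seq[i:i + 3]) in STOP_CODONS:
                seq[i + 2] = "C"


def apply_signature_profile(
    model: ReferenceModel,
    profile: str,
    env_type: str = "II",
    env_variant: int = 1,
    rng: np.random.Generator | None = None,
    mer11a: str | None = None,
    human_gag_ins: bool | None = None,
    env_stub5: int = ENV_STUB_5,
    env_stub3: int = ENV_STUB_3,
) -> AncestralProvirus:
    """Apply a lineage's signature indels to the reference internal sequence.

    Returns the ancestral (pre-divergence) internal sequence together
    with the planted indel events, the reading-frame spans that remain
    intact (used for stop-avoiding mutation planting), the protected
    motif spans, and — for variant 3 — the MER11A segment coordinates.
    """
    if profile not in ("human", "macaque"):
        raise ValueError(f"unknown profile {profile!r}")
    if env_type not in ("I", "II"):
        raise ValueError(f"unknown env type {env_type!r}")
    if env_variant not in (0, 1, 2, 3):
        raise ValueError(f"unknown env variant {env_variant!r}")
    if env_type == "I" and profile != "human":
        raise ValueError("type I env is restricted to the human lineage")
    if env_variant == 3 and profile != "macaque":
        raise ValueError("variant 3 env is restricted to the macaque lineage")
    if env_variant == 3 and env_type == "I":
        raise ValueError("variant 3 and type I are mutually exclusive")
    if rng is None:
        rng = np.random.default_rng(0)

    edits: list[_Edit] = []
    indels: list[IndelEvent] = []

    def _add_del(start1: int, end1: int, tag_regions) -> None:
        edits.append(_Edit("del", start1 - 1, end1))
        indels.append(IndelEvent(
            kind="deletion", ref_start0=start1 - 1, length=end1 - start1 + 1,
            regions=tag_regions, anchor_internal_1based=start1))

    def _add_ins(anchor1: int, seq: str, tag_regions) -> None:
        edits.append(_Edit("ins", anchor1 - 1, anchor1 - 1, insert=seq))
        indels.append(IndelEvent(
            kind="insertion", ref_start0=anchor1 - 1, length=len(seq),
            regions=tag_regions, anchor_internal_1based=anchor1))

    gag_ins = profile == "macaque" or (
        human_gag_ins if human_gag_ins is not None
        else bool(rng.random() < HUMAN_GAG_INS_FRACTION))
    if profile == "macaque":
        _add_del(*GAG_DEL_SPAN_1BASED, ("gag",))
    if gag_ins:
        _add_ins(GAG_INS_ANCHOR_1BASED, random_dna(rng, GAG_INS_LEN), ("gag",))

    env_s0, env_e0 = model.regions["env"]
    recomb_ref_span = None
    if env_type == "I":
        _add_del(*TYPE_I_DEL_SPAN_1BASED, ("env",))
    if env_variant == 2:
        _add_ins(ENV_TM_INS_ANCHOR_1BASED, random_dna(rng, ENV_TM_INS_LEN),
                 ("env", "TM"))
    elif env_variant == 3:
        if mer11a is None:
            raise ValueError("variant 3 requires the MER11A parent sequence")
        off = int(rng.integers(0, len(mer11a) - MER11A_SEGMENT_LEN + 1))
        segment = mer11a[off:off + MER11A_SEGMENT_LEN]
        rep_s, rep_e = env_s0 + env_stub5, env_e0 - env_stub3
        edits.append(_Edit("replace", rep_s, rep_e, insert=segment))
        recomb_ref_span = (rep_s, rep_e)

    emap = _EditMap(edits)
    internal = emap.apply(model.internal_seq)

    # reading frames that stay open (locus coordinates, phase 0 at start)
    frame_spans: dict[str, tuple[int, int]] = {}
    for gene, (s0, e0) in model.regions.items():
        lo, hi = s0, e0
        if gene == "gag" and profile == "macaque":
            lo = GAG_DEL_SPAN_1BASED[1]  # first ref position after the del
        if gene == "env":
            if env_type == "I":
                hi = TYPE_I_DEL_SPAN_1BASED[0] - 1
            elif env_variant == 2:
                hi = ENV_TM_INS_ANCHOR_1BASED - 1
            elif env_variant == 3:
                hi = env_s0 + env_stub5
        span = emap.map_span(lo, hi)
        if span is not None and span[1] - span[0] >= 3:
            frame_spans[gene] = span

    protected: list[tuple[int, int]] = []
    for name in ("NLS", "NES"):
        s1, e1 = DOMAIN_COORDS_1BASED[name]
        span = emap.map_span(s1 - 1, e1)
        if span is not None and span[1] - span[0] == e1 - s1 + 1:
            protected.append(span)
    from .reference import ZINC_KNUCKLE_CODONS, ZINC_KNUCKLE_PEPTIDE
    gag_s0 = model.regions["gag"][0]
    for codon1 in ZINC_KNUCKLE_CODONS:
        s = gag_s0 + 3 * (codon1 - 1)
        span = emap.map_span(s, s + 3 * len(ZINC_KNUCKLE_PEPTIDE))
        if span is not None:
            protected.append(span)

    # clean stop codons introduced at insertion junctions
    seq = list(internal)
    _fix_stops_in_spans(seq, frame_spans.values())
    internal = "".join(seq)

    recomb_span = None
    if recomb_ref_span is not None:
        # the MER11A segment begins right after the last kept stub base
        seg_start = emap.map(recomb_ref_span[0] - 1) + 1
        recomb_span = (seg_start, seg_start + MER11A_SEGMENT_LEN)

    return AncestralProvirus(
        internal=internal, profile=profile, env_type=env_type,
        env_variant=env_variant, indels=indels, frame_spans=frame_spans,
        protected=protected,
        env_span=emap.map_span(env_s0, env_e0),
        recomb_span=recomb_span,
    )


# ---------------------------------------------------------------------------
# Divergence planting


def _creates_cpg(seq: list[str], pos: int, base: str) -> bool:
    if base == "G" and pos > 0 and seq[pos - 1] == "C":
        return True
    if base == "C" and pos + 1 < len(seq) and seq[pos + 1] == "G":
        return True
    return False


def _creates_stop(seq: list[str], pos: int, base: str, frame_spans) -> bool:
    for s, e in frame_spans:
        if not (s <= pos < e):
            continue
        cs = pos - ((pos - s) % 3)
        if cs + 3 > e:
            continue
        codon = seq[cs:cs + 3]
        codon[pos - cs] = base
        if "".join(codon) in STOP_CODONS:
            return True
    return False


def _mutate_sites(seq: str, n: int, rng: np.random.Generator,
                  frame_spans=(), protected=(), no_cpg: bool = True,
                  max_tries: int = 10000) -> str:
    """Substitute exactly n distinct sites under the planting constraints."""
    s = list(seq)
    banned = np.zeros(len(s), dtype=bool)
    for a, b in protected:
        banned[a:b] = True
    chosen: set[int] = set()
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries + 10 * n:
            raise RuntimeError("could not place requested substitutions")
        pos = int(rng.integers(0, len(s)))
        if pos in chosen or banned[pos]:
            continue
        options = [b for b in "ACGT" if b != s[pos]]
        rng.shuffle(options)
        placed = False
        for b in options:
            if no_cpg and _creates_cpg(s, pos, b):
                continue
            if frame_spans and _creates_stop(s, pos, b, frame_spans):
                continue
            s[pos] = b
            placed = True
            break
        if placed:
            chosen.add(pos)
    return "".join(s)


def _mutate_disjoint_pair(seq: str, n: int, rng: np.random.Generator,
                          no_cpg: bool = True) -> tuple[str, str]:
    """Two copies of seq, each with n substitutions at disjoint sites."""
    L = len(seq)
    if 2 * n > L:
        raise ValueError("divergence saturates")
    sites = rng.choice(L, size=2 * n, replace=False)
    out = []
    for site_set in (sites[:n], sites[n:]):
        s = list(seq)
        for pos in sorted(int(x) for x in site_set):
            options = [b for b in "ACGT" if b != s[pos]]
            rng.shuffle(options)
            for b in options:
                if no_cpg and _creates_cpg(s, pos, b):
                    continue
                s[pos] = b
                break
            else:
                s[pos] = options[0]
        out.append("".join(s))
    return out[0], out[1]


def plant_divergence(
    ltr_seq: str,
    internal_seq: str,
    T: float,
    plan: LineageMutationPlan | None = None,
    seed: int | np.random.Generator = 0,
    frame_spans=(),
    protected=(),
) -> tuple[str, str, str]:
    """Plant T million years of divergence on one proviral copy.

    Each LTR copy receives exactly ``round(L*rate*T)`` substitutions, the
    two site sets disjoint (no coincident or multiple hits), so the
    LTR-LTR p-distance is ``2*rate*T`` up to rounding.  The internal
    region receives ``round(len*rate*T)`` substitutions under the same
    no-multiple-hit rule.  Raises if the requested pairwise LTR
    divergence reaches saturation (``2*rate*T >= 1``).
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    plan = plan or LineageMutationPlan()
    if 2 * plan.rate * T >= 1:
        raise ValueError("divergence saturates: 2*rate*T >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else substream(
        int(seed), "divergence")
    n_ltr = round(len(ltr_seq) * plan.rate * T)
    ltr5, ltr3 = _mutate_disjoint_pair(ltr_seq, n_ltr, rng)
    n_int = round(len(internal_seq) * plan.rate * T)
    internal = _mutate_sites(internal_seq, n_int, rng,
                             frame_spans=frame_spans, protected=protected)
    if plan.cpg_boost > 1.0:
        s = list(internal)
        cpg_c = [i for i in range(len(s) - 1)
                 if s[i] == "C" and s[i + 1] == "G"]
        extra = round(len(cpg_c) * (plan.cpg_boost - 1.0) * plan.rate * T)
        if extra and cpg_c:
            hits = rng.choice(len(cpg_c), size=min(extra, len(cpg_c)),
                              replace=False)
            for h in hits:
                s[cpg_c[int(h)]] = "T"  # methyl-C deamination
            internal = "".join(s)
    return ltr5, ltr3, internal


# ---------------------------------------------------------------------------
# Whole loci


@dataclass
class PlantedLocus:
    """One planted proviral copy (or solo LTR) in one genome."""

    locus_id: str
    species: str
    category: str
    age: float
    env_type: str
    env_variant: int
    solo_ltr: bool
    ltr5: str
    ltr3: str
    internal: str
    indels: list[IndelEvent]
    gag_intact: bool
    pol_intact: bool
    env_intact: bool
    rec_intact: bool
    env_span: tuple[int, int] | None = None
    recomb_span: tuple[int, int] | None = None
    interval: GenomicInterval | None = None
    strand: str = "+"

    @property
    def seq(self) -> str:
        if self.solo_ltr:
            return self.ltr5
        return self.ltr5 + self.internal + self.ltr3


def _plant_stop(internal: list[str], frame_span, window, rng) -> bool:
    """Overwrite one in-frame codon inside window with TAA."""
    s, e = frame_span
    w_lo, w_hi = window
    starts = [i for i in range(s, e - 2, 3) if w_lo <= i and i + 3 <= w_hi]
    if not starts:
        return False
    cs = int(rng.choice(starts))
    internal[cs:cs + 3] = list("TAA")
    return True


def make_locus(
    model: ReferenceModel,
    profile: str = "macaque",
    env_type: str = "II",
    env_variant: int = 1,
    T: float = 10.0,
    seed: int = 1,
    plan: LineageMutationPlan | None = None,
    mer11a: str | None = None,
    solo_ltr: bool = False,
    disrupt_gag: bool = False,
    disrupt_pol: bool = False,
    disrupt_env: bool = False,
    human_gag_ins: bool | None = None,
    locus_id: str = "locus",
    species: str = "macfas",
    category: str = "species_specific",
) -> PlantedLocus:
    """Build one planted locus: profile, then per-copy divergence."""
    rng = substream(seed, f"locus:{locus_id}")
    if solo_ltr:
        n = round(len(model.ltr_seq) * (plan or LineageMutationPlan()).rate
                  * T)
        ltr = _mutate_sites(model.ltr_seq, n, rng)
        return PlantedLocus(
            locus_id=locus_id, species=species, category=category, age=T,
            env_type="II", env_variant=0, solo_ltr=True, ltr5=ltr, ltr3="",
            internal="", indels=[], gag_intact=False, pol_intact=False,
            env_intact=False, rec_intact=False)

    anc = apply_signature_profile(
        model, profile, env_type=env_type, env_variant=env_variant, rng=rng,
        mer11a=mer11a, human_gag_ins=human_gag_ins)
    ltr5, ltr3, internal = plant_divergence(
        model.ltr_seq, anc.internal, T, plan, rng,
        frame_spans=tuple(anc.frame_spans.values()),
        protected=tuple(anc.protected))

    seq = list(internal)
    gag_frame_ok = "gag" in anc.frame_spans
    env_frame_ok = env_variant in (0, 1) and env_type == "II"
    if disrupt_gag and gag_frame_ok:
        dom = DOMAIN_COORDS_1BASED["CA"]
        win = (dom[0] - 1, dom[1])  # CA is upstream of all gag edits' shifts?
        win = _shift_window(anc, win)
        disrupt_gag = _plant_stop(seq, anc.frame_spans["gag"], win, rng)
    if disrupt_pol and "pol" in anc.frame_spans:
        dom = DOMAIN_COORDS_1BASED["RT"]
        win = _shift_window(anc, (dom[0] - 1, dom[1]))
        disrupt_pol = _plant_stop(seq, anc.frame_spans["pol"], win, rng)
    if disrupt_env and env_frame_ok and "env" in anc.frame_spans:
        dom = DOMAIN_COORDS_1BASED["TM"]
        win = _shift_window(anc, (dom[0] - 1, dom[1]))
        disrupt_env = _plant_stop(seq, anc.frame_spans["env"], win, rng)
    internal = "".join(seq)

    return PlantedLocus(
        locus_id=locus_id, species=species, category=category, age=T,
        env_type=env_type, env_variant=env_variant, solo_ltr=False,
        ltr5=ltr5, ltr3=ltr3, internal=internal, indels=list(anc.indels),
        gag_intact=gag_frame_ok and not disrupt_gag,
        pol_intact="pol" in anc.frame_spans and not disrupt_pol,
        env_intact=env_frame_ok and not disrupt_env,
        rec_intact=env_type == "II" and env_variant in (0, 1, 2),
        env_span=anc.env_span, recomb_span=anc.recomb_span)


def _shift_window(anc: AncestralProvirus, win: tuple[int, int]):
    """Map a reference-internal window into ancestral locus coordinates."""
    emap = _EditMap([])  # edits already applied; recompute via indels
    off_events = []
    for ev in anc.indels:
        if ev.kind == "deletion":
            off_events.append(_Edit("del", ev.ref_start0,
                                    ev.ref_start0 + ev.length))
        else:
            off_events.append(_Edit("ins", ev.ref_start0, ev.ref_start0,
                                    insert="N" * ev.length))
    if anc.env_variant == 3 and anc.recomb_span is not None:
        # replacement not in the indel list; approximate via env span shift
        pass
    emap = _EditMap(off_events)
    span = emap.map_span(*win)
    return span if span is not None else win


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class Cohort:
    """A simulated multi-species cohort plus its complete truth table."""

    model: ReferenceModel
    mer11a: str
    genomes: dict[str, SequenceRecord]
    loci: list[PlantedLocus]          # one entry per planted copy
    config: dict

    def truth_by_locus(self) -> dict[str, list[PlantedLocus]]:
        out: dict[str, list[PlantedLocus]] = {}
        for pl in self.loci:
            out.setdefault(pl.locus_id, []).append(pl)
        return out

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lid, copies in self.truth_by_locus().items():
            if copies[0].solo_ltr:
                continue
            counts[copies[0].category] = counts.get(
                copies[0].category, 0) + 1
        return counts

    def extract(self, locus: PlantedLocus) -> str:
        """Pull a planted copy back out of its genome (strand-aware)."""
        iv = locus.interval
        seq = self.genomes[locus.species].seq[iv.start:iv.end]
        return revcomp(seq) if iv.strand == "-" else seq


def _carriers(category: str, species: list[str], specific: str) -> list[str]:
    if category == "human_shared":
        return [s for s in species]
    if category == "macaque_shared":
        return [s for s in species if s != "human"]
    return [specific]


def _sample_variant(category: str, rng: np.random.Generator) -> int:
    weights = VARIANT_WEIGHTS[category]
    ks = sorted(weights)
    ps = np.array([weights[k] for k in ks], dtype=float)
    return int(rng.choice(ks, p=ps / ps.sum()))


def simulate_cohort(config: dict, seed: int | None = None) -> Cohort:
    """Simulate genomes for every configured species, with truth table.

    Each locus is an ancestral provirus shared by its carrier species
    (identical 200-nt flanks and target-site duplication), independently
    mutated per carrier at the locus age.  Loci are embedded in neutral
    spacer DNA on one contig per species; strand is random per copy.
    """
    from .io import default_config
    cfg = dict(default_config())
    cfg.update(config)
    seed = cfg["seed"] if seed is None else seed
    species = list(cfg["species"])
    model = build_reference(seed, cfg["gc_target"])
    mer11a = build_mer11a(seed, gc_target=cfg["gc_target"])
    rng = substream(seed, "cohort")
    plan = LineageMutationPlan(cpg_boost=float(cfg["cpg_boost"]))

    plan_rows = (
        [("human_shared", cfg["age_human_shared"])] * cfg["n_human_shared"]
        + [("macaque_shared", cfg["age_macaque_shared"])]
        * cfg["n_macaque_shared"]
        + [("species_specific", cfg["age_species_specific"])]
        * cfg["n_species_specific"]
    )

    blocks: dict[str, list[tuple[str, PlantedLocus | None, int, int]]] = {
        sp: [] for sp in species}

    def _flank_copy(flank: str, sp: str, rng) -> str:
        n = round(len(flank) * FLANK_DIVERGENCE.get(sp, 0.01))
        return _mutate_sites(flank, n, rng, no_cpg=False)

    all_loci: list[PlantedLocus] = []
    sfl = cfg["shared_flank_len"]
    for idx, (category, age) in enumerate(plan_rows):
        locus_id = f"L{idx:03d}"
        carriers = _carriers(category, species, cfg["specific_species"])
        lflank = random_dna(rng, sfl, cfg["gc_target"])
        rflank = random_dna(rng, sfl, cfg["gc_target"])
        tsd = random_dna(rng, TSD_LEN, cfg["gc_target"])
        variant = _sample_variant(category, rng) if any(
            sp != "human" for sp in carriers) else 0
        gag_ins_human = bool(rng.random() < HUMAN_GAG_INS_FRACTION)
        for sp in carriers:
            profile = "human" if sp == "human" else "macaque"
            child_seed = int(rng.integers(0, 2 ** 31))
            pl = make_locus(
                model, profile=profile, env_type="II",
                env_variant=variant if profile == "macaque" else 0,
                T=float(age), seed=child_seed, plan=plan, mer11a=mer11a,
                disrupt_gag=bool(rng.random() >= cfg.get(
                    "gag_intact_fraction", 0.15)),
                disrupt_pol=bool(rng.random() >= cfg.get(
                    "pol_intact_fraction", 0.10)),
                disrupt_env=True,
                human_gag_ins=gag_ins_human,
                locus_id=locus_id, species=sp, category=category)
            strand = "+" if rng.random() < 0.5 else "-"
            pl.strand = strand
            block = (_flank_copy(lflank, sp, rng) + tsd + pl.seq + tsd
                     + _flank_copy(rflank, sp, rng))
            elem_lo = sfl + TSD_LEN
            elem_hi = elem_lo + len(pl.seq)
            if strand == "-":
                block_rc = revcomp(block)
                elem_lo, elem_hi = len(block) - elem_hi, len(block) - elem_lo
                block = block_rc
            blocks[sp].append((block, pl, elem_lo, elem_hi))
            all_loci.append(pl)

    for j in range(cfg["n_solo_ltr"]):
        sp = cfg["specific_species"]
        locus_id = f"S{j:03d}"
        child_seed = int(rng.integers(0, 2 ** 31))
        pl = make_locus(model, T=float(cfg["age_species_specific"]),
                        seed=child_seed, plan=plan, solo_ltr=True,
                        locus_id=locus_id, species=sp,
                        category="species_specific")
        lflank = random_dna(rng, sfl, cfg["gc_target"])
        rflank = random_dna(rng, sfl, cfg["gc_target"])
        tsd = random_dna(rng, TSD_LEN, cfg["gc_target"])
        strand = "+" if rng.random() < 0.5 else "-"
        pl.strand = strand
        block = lflank + tsd + pl.seq + tsd + rflank
        elem_lo, elem_hi = sfl + TSD_LEN, sfl + TSD_LEN + len(pl.seq)
        if strand == "-":
            elem_lo, elem_hi = len(block) - elem_hi, len(block) - elem_lo
            block = revcomp(block)
        blocks[sp].append((block, pl, elem_lo, elem_hi))
        all_loci.append(pl)

    genomes: dict[str, SequenceRecord] = {}
    for sp in species:
        sp_rng = substream(seed, f"assembly:{sp}")
        order = sp_rng.permutation(len(blocks[sp]))
        parts = [random_dna(sp_rng, cfg["spacer_len"], cfg["gc_target"])]
        pos = cfg["spacer_len"]
        contig = f"{sp}_chr1"
        for bi in order:
            block, pl, lo, hi = blocks[sp][int(bi)]
            if pl is not None:
                pl.interval = GenomicInterval(
                    contig, pos + lo, pos + hi, pl.strand, pl.locus_id)
            parts.append(block)
            pos += len(block)
            spacer = random_dna(sp_rng, cfg["spacer_len"], cfg["gc_target"])
            parts.append(spacer)
            pos += len(spacer)
        genomes[sp] = SequenceRecord(id=contig, seq="".join(parts),
                                     description=f"synthetic {sp} genome")

    return Cohort(model=model, mer11a=mer11a, genomes=genomes,
                  loci=all_loci, config=cfg)
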