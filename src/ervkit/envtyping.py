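"""Env subtype (I/II) and variant (1/2/3) classification.

Rules, in precedence order: a recombination segmentation showing a
MER11A (parent-B) run of at least 300 nt inside env calls variant 3 —
the foreign replacement destroys the other signals' context; otherwise
an insertion of 150-250 nt inside the transmembrane region calls
variant 2; otherwise variant 1.  Independently, a 280-300-nt deletion
at the type-I anchor calls type I (Np9-producing); anything else is
type II (Rec-producing).
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import IndelEvent
from .recombination import Segmentation
from .reference import ReferenceModel, TYPE_I_DEL_SPAN_1BASED

TYPE_I_LEN_WINDOW = (280, 300)
VARIANT2_LEN_WINDOW = (150, 250)
MIN_PARENT_B_RUN = 300
TYPE_I_ANCHOR_TOL = 50  # nt of slack around the type-I deletion anchor


@dataclass(frozen=True)
class EnvCall:
    env_type: str          # I | II | undetermined
    variant: str           # 1 | 2 | 3 | undetermined
    evidence: tuple[str, ...] = ()
    conflict: bool = False


def classify_env(
    indels: list[IndelEvent],
    model: ReferenceModel,
    recomb: Segmentation | None = None,
    env_present: bool = True,
) -> EnvCall:
    """Classify one locus' env from its indel catalog and segmentation.

    ``indels`` are events on the reference provirus (as produced by
    ``call_indels``); only events inside env are considered.
    """
    if not env_present:
        return EnvCall("undetermined", "undetermined")

    env_s, env_e = model.provirus_span("env")
    tm_s, tm_e = model.provirus_span("TM")
    in_env = [ev for ev in indels
              if env_s < ev.ref_start0 + (ev.length if ev.kind == "deletion"
                                          else 0)
              and ev.ref_start0 < env_e]

    evidence: list[str] = []

    # variant, by precedence
    variant = "1"
    b_run = 0
    if recomb is not None:
        b_run = max((e - s for p, s, e in recomb.segments if p == "B"),
                    default=0)
    if recomb is not None and b_run >= MIN_PARENT_B_RUN:
        variant = "3"
        evidence.append(f"parent_B_segment:{b_run}nt")
    else:
        for ev in in_env:
            if (ev.kind == "insertion"
                    and VARIANT2_LEN_WINDOW[0] <= ev.length
                    <= VARIANT2_LEN_WINDOW[1]
                    and tm_s < ev.ref_start0 < tm_e):
                variant = "2"
                evidence.append(f"TM_insertion:{ev.length}nt")
                break

    # type, independent of variant
    anchor0 = model.internal_to_provirus(TYPE_I_DEL_SPAN_1BASED[0] - 1)
    env_type = "II"
    type_i_ev = None
    for ev in in_env:
        if (ev.kind == "deletion"
                and TYPE_I_LEN_WINDOW[0] <= ev.length <= TYPE_I_LEN_WINDOW[1]
                and abs(ev.ref_start0 - anchor0) <= TYPE_I_ANCHOR_TOL):
            env_type = "I"
            type_i_ev = ev
            evidence.append(f"type_I_deletion:{ev.length}nt")
            break

    conflict = variant == "3" and type_i_ev is not None
    if conflict:
        evidence.append("conflict")
    return EnvCall(env_type=env_type, variant=variant,
                   evidence=tuple(evidence), conflict=conflict)
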