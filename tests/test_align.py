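"""Affine-gap alignment vs an exhaustive oracle; projections; indels."""

import numpy as np
import pytest

from ervkit.align import (
    IndelEvent,
    annotate_regions,
    call_indels,
    global_align,
    project_locus,
    project_reference,
)

MATCH, MISMATCH, GO, GE = 2, -3, -5, -2


def exhaustive_best_score(a: str, b: str) -> int:
    """Enumerate every global alignment; affine gap = open + len*extend.

    Plain recursion with no memoization: an oracle independent of the
    banded dynamic program it checks.
    """
    def rec(i, j, prev):
        if i == len(a) and j == len(b):
            return 0
        best = -(10 ** 9)
        if i < len(a) and j < len(b):
            s = MATCH if a[i] == b[j] else MISMATCH
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):
            s = GE + (GO if prev != "X" else 0)
            best = max(best, s + rec(i + 1, j, "X"))
        if j < len(b):
            s = GE + (GO if prev != "Y" else 0)
            best = max(best, s + rec(i, j + 1, "Y"))
        return best

    return rec(0, 0, "M")


class TestGlobalAlign:
    def test_identical(self):
        a, b, s = global_align("ACGT", "ACGT")
        assert (a, b, s) == ("ACGT", "ACGT", 8)

    def test_single_deletion_score(self):
        # three matches minus one opened 1-nt gap: 2*3 - 5 - 2
        _, _, s = global_align("ACGT", "AGT")
        assert s == 2 * 3 - 5 - 2

    def test_symmetry_with_roles_swapped(self):
        a1, b1, s1 = global_align("GATTACA", "GCATGC")
        b2, a2, s2 = global_align("GCATGC", "GATTACA")
        assert s1 == s2
        assert (a1, b1) == (a2, b2)

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        la, lb = rng.integers(1, 8, size=2)
        a = "".join(rng.choice(list("ACGT"), la))
        b = "".join(rng.choice(list("ACGT"), lb))
        _, _, got = global_align(a, b)
        assert got == exhaustive_best_score(a, b)

    def test_aligned_strings_reproduce_score(self):
        rng = np.random.default_rng(99)
        a = "".join(rng.choice(list("ACGT"), 60))
        b = "".join(rng.choice(list("ACGT"), 55))
        aa, bb, s = global_align(a, b)
        assert aa.replace("-", "") == a and bb.replace("-", "") == b
        total, prev = 0, None
        for ca, cb in zip(aa, bb):
            if ca != "-" and cb != "-":
                total += MATCH if ca == cb else MISMATCH
                prev = "M"
            elif cb == "-":
                total += GE + (GO if prev != "X" else 0)
                prev = "X"
            else:
                total += GE + (GO if prev != "Y" else 0)
                prev = "Y"
        assert total == s

    def test_n_mismatches_everything(self):
        _, _, s = global_align("NN", "NN")
        assert s == 2 * MISMATCH

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")


class TestProjection:
    def test_reference_projects_to_identity(self, model):
        proj = project_reference(model)
        assert call_indels(proj) == []
        assert proj.locus_len == len(model.provirus_seq)
        ann = annotate_regions(proj, model)
        assert ann.full_length
        assert all(v == 1.0 for v in ann.region_coverage.values())

    def test_indel_length_conservation(self, projections, model):
        # sum(ins) - sum(del) == locus length - reference length
        for name, proj in projections.items():
            evs = call_indels(proj, model)
            net = sum(e.length if e.kind == "insertion" else -e.length
                      for e in evs)
            assert net == proj.locus_len - proj.ref_len, name

    def test_planted_signature_indels_recovered(self, planted, projections,
                                                model):
        evs = call_indels(projections["macaque_v1"], model)
        big = [(e.kind, e.length, e.anchor_internal_1based)
               for e in evs if e.length >= 3]
        dels = [e for e in big if e[0] == "deletion"]
        inss = [e for e in big if e[0] == "insertion"]
        assert any(ln == 12 and abs(anchor - 156) <= 2
                   for _, ln, anchor in dels)
        assert any(ln == 96 and abs(anchor - 745) <= 2
                   for _, ln, anchor in inss)

    def test_planted_type_i_deletion_recovered(self, projections, model):
        evs = call_indels(projections["human_type1"], model)
        assert any(e.kind == "deletion" and e.length == 292
                   and "env" in e.regions for e in evs)

    def test_indel_recovery_over_seeded_loci(self, model, mer11a):
        # anchors within +-2 nt of the planted positions, lengths exact
        from ervkit.simulate import make_locus
        for seed in (21, 22, 23):
            pl = make_locus(model, profile="macaque", env_variant=1,
                            T=15, seed=seed, mer11a=mer11a)
            proj = project_locus(pl.seq, model.provirus_seq)
            called = {(e.kind, e.length) for e in call_indels(proj, model)
                      if e.length >= 3}
            for truth in pl.indels:
                assert (truth.kind, truth.length) in called

    def test_truncated_locus_not_full_length(self, model):
        # locus cut right after pro: pol and env coverage collapse
        cut = model.internal_to_provirus(model.regions["pro"][1])
        locus = model.provirus_seq[:cut]
        proj = project_locus(locus, model.provirus_seq)
        ann = annotate_regions(proj, model)
        assert ann.region_coverage["gag"] >= 0.99
        assert ann.region_coverage["pol"] < 0.8
        assert ann.region_coverage["env"] < 0.8
        assert not ann.full_length

    def test_region_gc_of_reference(self, model):
        proj = project_reference(model)
        ann = annotate_regions(proj, model)
        from ervkit._seq import gc_content
        assert ann.region_gc["gag"] == pytest.approx(
            gc_content(model.gene_seq("gag")))


class TestIndelEvent:
    def test_validation(self):
        with pytest.raises(ValueError):
            IndelEvent(kind="dup", ref_start0=0, length=5)
        with pytest.raises(ValueError):
            IndelEvent(kind="deletion", ref_start0=0, length=0)
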