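"""Divergence planting, signature profiles, cohort truth-table guarantees."""

import numpy as np
import pytest

from ervkit.simulate import (
    FLANK_DIVERGENCE,
    LineageMutationPlan,
    apply_signature_profile,
    make_locus,
    plant_divergence,
    simulate_cohort,
)


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


class TestPlantDivergence:
    def test_zero_age_leaves_ltrs_identical(self, model):
        l5, l3, internal = plant_divergence(model.ltr_seq,
                                            model.internal_seq, 0, seed=1)
        assert l5 == model.ltr_seq == l3
        assert internal == model.internal_seq

    def test_exact_site_counts_and_disjoint_sets(self, model):
        T, L = 5, len(model.ltr_seq)
        l5, l3, _ = plant_divergence(model.ltr_seq, model.internal_seq,
                                     T, seed=7)
        n = round(L * 0.0034 * T)
        assert hamming(l5, model.ltr_seq) == n
        assert hamming(l3, model.ltr_seq) == n
        # disjoint site sets: pairwise difference is the sum
        assert hamming(l5, l3) == 2 * n == 32

    def test_no_cpg_created_in_ltrs(self, model):
        l5, l3, _ = plant_divergence(model.ltr_seq, model.internal_seq,
                                     30, seed=3)
        assert "CG" not in l5 and "CG" not in l3

    def test_saturation_rejected(self, model):
        with pytest.raises(ValueError, match="saturat"):
            plant_divergence(model.ltr_seq, model.internal_seq, 150, seed=1)

    def test_negative_age_rejected(self, model):
        with pytest.raises(ValueError):
            plant_divergence(model.ltr_seq, model.internal_seq, -1, seed=1)

    def test_cpg_boost_adds_transitions_at_cpg_sites(self, model):
        plan = LineageMutationPlan(cpg_boost=8.0)
        _, _, internal = plant_divergence(model.ltr_seq, model.internal_seq,
                                          10, plan=plan, seed=5)
        _, _, plain = plant_divergence(model.ltr_seq, model.internal_seq,
                                       10, seed=5)
        assert hamming(internal, model.internal_seq) > \
            hamming(plain, model.internal_seq)

    def test_boost_below_one_rejected(self):
        with pytest.raises(ValueError):
            LineageMutationPlan(cpg_boost=0.5)


class TestSignatureProfiles:
    def test_macaque_profile_plants_both_gag_events(self, model):
        anc = apply_signature_profile(model, "macaque",
                                      rng=np.random.default_rng(0))
        kinds = {(e.kind, e.length, e.anchor_internal_1based)
                 for e in anc.indels}
        assert ("deletion", 12, 156) in kinds
        assert ("insertion", 96, 745) in kinds

    def test_human_profile_without_insertion_has_no_indels(self, model):
        anc = apply_signature_profile(model, "human",
                                      rng=np.random.default_rng(0),
                                      human_gag_ins=False)
        assert anc.indels == []

    def test_variant3_records_673_nt_segment(self, model, mer11a):
        anc = apply_signature_profile(model, "macaque", env_variant=3,
                                      rng=np.random.default_rng(0),
                                      mer11a=mer11a)
        s, e = anc.recomb_span
        assert e - s == 673

    @pytest.mark.parametrize("profile,env_type,variant", [
        ("macaque", "I", 1),   # type I is human-only
        ("human", "II", 3),    # variant 3 is macaque-only
    ])
    def test_incompatible_combinations_rejected(self, model, mer11a,
                                                profile, env_type, variant):
        with pytest.raises(ValueError):
            apply_signature_profile(model, profile, env_type=env_type,
                                    env_variant=variant, mer11a=mer11a)

    def test_length_bookkeeping(self, model, mer11a):
        anc = apply_signature_profile(model, "macaque", env_variant=3,
                                      rng=np.random.default_rng(1),
                                      mer11a=mer11a)
        # -12 (gag del) +96 (gag ins) -2058 (env interior) +673 (MER11A)
        assert len(anc.internal) == len(model.internal_seq) - 12 + 96 \
            - 2058 + 673


class TestCohort:
    def test_truth_counts_match_config(self, small_cohort):
        assert small_cohort.category_counts() == {
            "human_shared": 3, "macaque_shared": 4, "species_specific": 3}
        solos = [pl for pl in small_cohort.loci if pl.solo_ltr]
        assert len(solos) == 1
        assert len(solos[0].seq) == len(small_cohort.model.ltr_seq)

    def test_every_planted_interval_round_trips(self, small_cohort):
        for pl in small_cohort.loci:
            assert pl.interval is not None
            assert small_cohort.extract(pl) == pl.seq

    def test_same_seed_is_byte_identical(self, small_cohort):
        from tests.conftest import SMALL_COHORT_CONFIG
        again = simulate_cohort(dict(SMALL_COHORT_CONFIG))
        assert {sp: r.seq for sp, r in again.genomes.items()} == \
            {sp: r.seq for sp, r in small_cohort.genomes.items()}

    def test_different_seed_differs(self, small_cohort):
        from tests.conftest import SMALL_COHORT_CONFIG
        cfg = dict(SMALL_COHORT_CONFIG, seed=6)
        other = simulate_cohort(cfg)
        assert other.genomes["macfas"].seq != \
            small_cohort.genomes["macfas"].seq

    def test_category_is_pure_function_of_species_set(self, small_cohort):
        by_locus = small_cohort.truth_by_locus()
        for copies in by_locus.values():
            species = {c.species for c in copies}
            cat = copies[0].category
            if cat == "human_shared":
                assert "human" in species and len(species) == 3
            elif cat == "macaque_shared":
                assert species == {"macfas", "rhesus"}
            else:
                assert len(species) == 1

    def test_orthologous_copies_share_mutated_flanks(self, small_cohort):
        # flanks around carrier copies diverge only by the per-lineage
        # neutral rates, so cross-species identity stays high
        from ervkit._seq import revcomp
        by_locus = small_cohort.truth_by_locus()
        copies = next(v for v in by_locus.values() if len(v) == 3)
        flanks = {}
        for pl in copies:
            g = small_cohort.genomes[pl.species].seq
            iv = pl.interval
            if iv.strand == "+":
                flanks[pl.species] = g[iv.start - 150:iv.start]
            else:
                flanks[pl.species] = revcomp(g[iv.end:iv.end + 150])
        h, m = flanks["human"], flanks["macfas"]
        div = sum(a != b for a, b in zip(h, m)) / len(h)
        bound = FLANK_DIVERGENCE["human"] + FLANK_DIVERGENCE["macfas"]
        assert div <= bound * 2.5 + 0.02


class TestMakeLocus:
    def test_solo_ltr_is_one_ltr(self, model):
        pl = make_locus(model, solo_ltr=True, T=5, seed=2)
        assert pl.solo_ltr
        assert len(pl.seq) == len(model.ltr_seq)

    def test_truth_flags_reflect_disruptions(self, planted):
        pl = planted["disrupted"]
        assert not pl.gag_intact and not pl.pol_intact and not pl.env_intact
        clean = planted["macaque_v1"]
        assert clean.gag_intact and clean.pol_intact and clean.env_intact

    def test_variant_flags(self, planted):
        assert planted["macaque_v3"].rec_intact is False
        assert planted["macaque_v2"].rec_intact is True
        assert planted["human_type1"].rec_intact is False
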