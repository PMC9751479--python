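"""End-to-end orchestration: simulate -> discover -> orthology ->
annotate -> date -> orf -> env-type -> recomb -> phylo.

Every stage writes a TSV (or FASTA/BED/Newick) into the run directory;
the run config and seed are serialized alongside for provenance, and a
MANIFEST lists the outputs with the stage that produced them.  A stage
failure aborts with a stage-named error, leaving partial outputs and a
MANIFEST marked incomplete.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import dating as dating_mod
from .align import annotate_regions, call_indels, project_locus
from .coding import detect_rec, orf_integrity
from .discovery import classify_orthology, extract_locus, scan_genome
from .envtyping import classify_env
from .io import (
    GenomicInterval,
    SequenceRecord,
    load_config,
    save_config,
    write_bed,
    write_fasta,
    write_newick,
)
from .phylo import bootstrap_support
from .recombination import segment_two_parents
from .reference import GENE_COORDS_1BASED
from .simulate import simulate_cohort


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _truth_frame(cohort) -> pd.DataFrame:
    rows = []
    for pl in cohort.loci:
        iv = pl.interval
        rows.append({
            "locus_id": pl.locus_id, "species": pl.species,
            "category": pl.category, "age": pl.age,
            "env_type": pl.env_type, "env_variant": pl.env_variant,
            "solo_ltr": pl.solo_ltr,
            "contig": iv.contig if iv else "",
            "start": iv.start if iv else -1,
            "end": iv.end if iv else -1,
            "strand": iv.strand if iv else ".",
            "gag_intact": pl.gag_intact, "pol_intact": pl.pol_intact,
            "env_intact": pl.env_intact, "rec_intact": pl.rec_intact,
        })
    return pd.DataFrame(rows)


def run_all(config: dict | None = None, out_dir: str | Path = "erv_run",
            seed: int | None = None) -> Path:
    """Run the whole pipeline on a simulated cohort; returns the run dir."""
    cfg = load_config(overrides=config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    log: list[str] = []
    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    log.append(f"seed\t{cfg['seed']}")
    log.append(f"config_sha1\t{hashlib.sha1(cfg_text.encode()).hexdigest()}")

    def _finish(ok: bool) -> None:
        status = "COMPLETE" if ok else "INCOMPLETE"
        (out / "MANIFEST").write_text(
            "\n".join([f"status\t{status}"] + manifest) + "\n")
        (out / "run.log").write_text("\n".join(log) + "\n")

    stage = "simulate"
    try:
        save_config(cfg, out / "config.yaml")
        manifest.append("config.yaml\tconfig")

        cohort = simulate_cohort(cfg)
        model = cohort.model
        for sp, rec in cohort.genomes.items():
            write_fasta([rec], out / f"genome_{sp}.fa")
            manifest.append(f"genome_{sp}.fa\tsimulate")
        write_fasta([SequenceRecord("HML2_internal", model.internal_seq),
                     SequenceRecord("HML2_LTR5", model.ltr_seq)],
                    out / "reference.fa")
        write_fasta([SequenceRecord("MER11A", cohort.mer11a)],
                    out / "mer11a.fa")
        regions = pd.DataFrame(
            [{"region": g, "start_1based": s, "end_1based": e}
             for g, (s, e) in GENE_COORDS_1BASED.items()])
        regions.to_csv(out / "reference_regions.tsv", sep="\t", index=False)
        truth = _truth_frame(cohort)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        ivs = [pl.interval for pl in cohort.loci if pl.interval]
        write_bed(ivs, out / "planted.bed")
        manifest += ["reference.fa\tsimulate", "mer11a.fa\tsimulate",
                     "reference_regions.tsv\tsimulate", "truth.tsv\tsimulate",
                     "planted.bed\tsimulate"]
        log.append(f"simulate\tplanted={len(cohort.loci)}")

        stage = "discover"
        hits_by_species = {}
        for sp, rec in cohort.genomes.items():
            hits = scan_genome(
                rec, model, k=cfg["k"],
                min_internal_len=cfg["min_internal_len"],
                min_ltr_span=cfg["min_ltr_span"],
                min_seeds=cfg["min_seeds"], merge_gap=cfg["merge_gap"])
            hits_by_species[sp] = hits
            write_bed([h.interval for h in hits], out / f"hits_{sp}.bed",
                      scores=[h.score for h in hits])
            manifest.append(f"hits_{sp}.bed\tdiscover")
            log.append(f"discover\t{sp}\thits={len(hits)}")

        stage = "orthology"
        orth = classify_orthology(
            hits_by_species, cohort.genomes, flank_len=cfg["flank_len"]
            if cfg["flank_len"] <= cfg["shared_flank_len"]
            else cfg["shared_flank_len"],
            min_flank_identity=cfg["min_flank_identity"])
        cat_rows = []
        for sp, hits in hits_by_species.items():
            for i, h in enumerate(hits):
                cat_rows.append({
                    "locus": h.interval.name, "species": sp,
                    "contig": h.interval.contig,
                    "start": h.interval.start, "end": h.interval.end,
                    "strand": h.interval.strand,
                    "solo_ltr": h.solo_ltr,
                    "category": orth.categories[(sp, i)],
                })
        cats = pd.DataFrame(cat_rows)
        cats.to_csv(out / "categories.tsv", sep="\t", index=False)
        manifest.append("categories.tsv\torthology")
        log.append(f"orthology\tgroups={len(orth.groups)}")

        stage = "annotate"
        ref_seq = model.provirus_seq
        projections = {}
        ann_rows, indel_rows = [], []
        for sp, hits in hits_by_species.items():
            for i, h in enumerate(hits):
                name = h.interval.name
                seq = extract_locus(cohort.genomes[sp], h)
                if h.solo_ltr:
                    proj = project_locus(seq, model.ltr_seq, locus_id=name)
                    projections[(sp, i)] = ("solo", proj)
                    continue
                proj = project_locus(seq, ref_seq, locus_id=name)
                projections[(sp, i)] = ("full", proj)
                ann = annotate_regions(proj, model, cfg["full_len_threshold"])
                row = {"locus": name, "species": sp,
                       "length": ann.locus_length,
                       "full_length": ann.full_length}
                for g in ("LTR5", "gag", "pro", "pol", "env", "LTR3"):
                    row[f"{g}_cov"] = round(ann.region_coverage[g], 4)
                    row[f"{g}_gc"] = round(ann.region_gc[g], 4)
                ann_rows.append(row)
                for ev in call_indels(proj, model):
                    if ev.length < 3:
                        continue
                    indel_rows.append({
                        "locus": name, "species": sp, "kind": ev.kind,
                        "ref_start0": ev.ref_start0, "length": ev.length,
                        "anchor_internal_1based": ev.anchor_internal_1based,
                        "regions": ",".join(ev.regions)})
        pd.DataFrame(ann_rows).to_csv(out / "annotations.tsv", sep="\t",
                                      index=False)
        pd.DataFrame(indel_rows).to_csv(out / "indels.tsv", sep="\t",
                                        index=False)
        manifest += ["annotations.tsv\tannotate", "indels.tsv\tannotate"]
        log.append(f"annotate\tloci={len(ann_rows)}")

        stage = "date"
        ltr_span = model.provirus_span("LTR5")
        cons_members = [proj.column_string(ltr_span)
                        for kind, proj in projections.values()
                        if kind == "full"]
        ltr_consensus = (dating_mod.build_consensus(cons_members,
                                                    model.ltr_seq)
                         if len(cons_members) >= 2 else model.ltr_seq)
        age_rows = []
        by_cat: dict[str, list[float]] = {}
        for sp, hits in hits_by_species.items():
            for i, h in enumerate(hits):
                kind, proj = projections[(sp, i)]
                cat = orth.categories[(sp, i)]
                if kind == "solo":
                    est = dating_mod.age_from_pair(
                        "".join(proj.cols), ltr_consensus,
                        "ltr_vs_consensus")
                    ests = [est]
                else:
                    ests = [dating_mod.estimate_age(proj, model,
                                                    "ltr_vs_ltr")]
                    ests.append(dating_mod.estimate_age(
                        proj, model, "ltr_vs_consensus",
                        consensus=ltr_consensus))
                for est in ests:
                    age_rows.append({
                        "locus": h.interval.name, "species": sp,
                        "category": cat, "method": est.method,
                        "D": round(est.D, 6), "sites": est.sites,
                        "T_myr": round(est.T, 3)})
                    if est.method == "ltr_vs_ltr":
                        by_cat.setdefault(cat, []).append(est.T)
        pd.DataFrame(age_rows).to_csv(out / "ages.tsv", sep="\t",
                                      index=False)
        summ = dating_mod.summaries_to_frame(
            dating_mod.summarize_ages(by_cat))
        summ.to_csv(out / "summary.tsv", sep="\t", index=False)
        manifest += ["ages.tsv\tdate", "summary.tsv\tdate"]
        log.append(f"date\testimates={len(age_rows)}")

        stage = "orf"
        orf_rows = []
        for sp, hits in hits_by_species.items():
            for i, h in enumerate(hits):
                kind, proj = projections[(sp, i)]
                if kind == "solo":
                    continue
                for gene in ("gag", "pol", "env"):
                    rep = orf_integrity(proj, model, gene,
                                        min_cov=cfg["intact_min_cov"],
                                        domain_min_cov=cfg["domain_min_cov"])
                    orf_rows.append({
                        "locus": h.interval.name, "species": sp,
                        "gene": gene, "present": rep.present,
                        "coverage": round(rep.coverage, 4),
                        "intact": rep.intact,
                        "premature_stops": rep.premature_stops,
                        "frameshift": rep.frameshift,
                        "protein_aa": rep.protein_length,
                        "domains": ",".join(rep.domains_present),
                        "zinc_knuckles": sum(
                            1 for m in rep.motif_matches
                            if m.motif == "zinc_knuckle")})
        pd.DataFrame(orf_rows).to_csv(out / "orf_report.tsv", sep="\t",
                                      index=False)
        manifest.append("orf_report.tsv\torf")
        log.append(f"orf\trows={len(orf_rows)}")

        stage = "recomb"
        env_span = model.provirus_span("env")
        env_ref = model.gene_seq("env")
        seg_rows = []
        segmentations = {}
        for sp, hits in hits_by_species.items():
            for i, h in enumerate(hits):
                kind, proj = projections[(sp, i)]
                if kind == "solo":
                    continue
                if proj.coverage(env_span) >= 0.7:
                    continue  # env largely intact: no replacement suspected
                query = proj.observed_seq(env_span)
                if len(query) < 300:
                    continue
                seg = segment_two_parents(query, env_ref, cohort.mer11a,
                                          sigma=cfg["sigma"])
                segmentations[(sp, i)] = seg
                for parent, s, e in seg.segments:
                    seg_rows.append({
                        "locus": h.interval.name, "species": sp,
                        "parent": parent, "start": s, "end": e,
                        "length": e - s,
                        "cost": round(seg.total_cost, 2)})
        pd.DataFrame(seg_rows).to_csv(out / "segments.tsv", sep="\t",
                                      index=False)
        manifest.append("segments.tsv\trecomb")
        log.append(f"recomb\tsegmented={len(segmentations)}")

        stage = "env-type"
        env_rows = []
        for sp, hits in hits_by_species.items():
            for i, h in enumerate(hits):
                kind, proj = projections[(sp, i)]
                if kind == "solo":
                    continue
                env_present = proj.coverage(env_span) > 0
                call = classify_env(call_indels(proj, model), model,
                                    recomb=segmentations.get((sp, i)),
                                    env_present=env_present)
                rec = detect_rec(proj, model)
                env_rows.append({
                    "locus": h.interval.name, "species": sp,
                    "env_type": call.env_type, "variant": call.variant,
                    "rec_present": rec["rec_present"],
                    "nls": rec["nls"], "nes": rec["nes"],
                    "evidence": ";".join(call.evidence)})
        pd.DataFrame(env_rows).to_csv(out / "env_calls.tsv", sep="\t",
                                      index=False)
        manifest.append("env_calls.tsv\tenv-type")
        log.append(f"env-type\tcalls={len(env_rows)}")

        stage = "phylo"
        for region in ("env", "full"):
            span = (model.provirus_span(region) if region != "full"
                    else (0, len(ref_seq)))
            seqs = {}
            for sp, hits in hits_by_species.items():
                for i, h in enumerate(hits):
                    kind, proj = projections[(sp, i)]
                    if kind == "solo":
                        continue
                    if proj.coverage(span) >= 0.3:
                        seqs[f"{sp}|{h.interval.name}"] = \
                            proj.column_string(span)
            if len(seqs) >= 4:
                tree = bootstrap_support(seqs,
                                         n_reps=cfg["bootstrap_reps"],
                                         seed=cfg["seed"])
                write_newick(tree, out / f"tree_{region}.nwk")
                manifest.append(f"tree_{region}.nwk\tphylo")
                log.append(f"phylo\t{region}\ttaxa={len(seqs)}")
        _finish(True)
        return out
    except Exception as exc:  # noqa: BLE001 - stage-named abort by contract
        _finish(False)
        raise StageError(stage, exc) from exc
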