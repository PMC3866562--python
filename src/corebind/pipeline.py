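"""End-to-end orchestration of the synthetic study.

``run_pipeline`` simulates a genome, binding evidence, expression data, a
TF pair and motif sequences, then runs every analysis stage in order and
writes plain-text outputs plus a run log of stage counts.  The same
config and seed always produce byte-identical run directories.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import assign, cooccur, core, expression, motif, simulate, targets
from .genome import write_bed, write_chrom_sizes, write_gff_genes
from .simulate import SimConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 1
    high_tier: float = 1.0
    low_tier: float = 25.0
    max_range: int = 10_000
    tss_window: int = 500
    strict_m: float = 1.0
    strict_p: float = 0.01
    moderate_m: float = 0.5
    moderate_p: float = 0.05
    de_tier: str = "strict"
    cooccur_nsamples: int = 200
    motif_threshold: float = 4.0
    enrich_resamples: int = 2000
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.high_tier >= self.low_tier:
            raise ValueError("low (permissive) tier must be numerically above the high tier")
        for name in ("strict_m", "strict_p", "moderate_m", "moderate_p",
                     "motif_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.de_tier not in ("strict", "moderate"):
            raise ValueError("de_tier must be 'strict' or 'moderate'")
        self.sim = (
            self.sim if isinstance(self.sim, SimConfig)
            else SimConfig(**self.sim)
        )
        if self.sim.seed != self.seed:
            self.sim = SimConfig(**{**asdict(self.sim), "seed": self.seed})

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


def _de_thresholds(cfg: PipelineConfig) -> tuple[float, float]:
    if cfg.de_tier == "strict":
        return cfg.strict_m, cfg.strict_p
    return cfg.moderate_m, cfg.moderate_p


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage on fully synthetic inputs; returns the run directory.

    Outputs (all plain text): simulated inputs (GFF3, BEDs, expression
    TSV, FASTA-free sequence TSV is skipped -- sequences are regenerated),
    core BED, gene assignments, feature/TSS/intron reports, normalized
    expression and DE table, target list, enrichment table, co-occurrence
    table, motif report, run log and a metrics JSON with planted-truth
    recovery rates.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    log(f"config: {json.dumps(asdict(cfg), sort_keys=True)}")

    # --- simulate inputs -------------------------------------------------
    stage = "simulate_annotation"
    try:
        ann, genome_seqs = simulate.simulate_annotation(cfg.sim)
        write_gff_genes(ann, out / "genes.gff3")
        write_chrom_sizes(ann.seqspace, out / "chrom.sizes")
        log(f"annotation: {len(ann.genes)} genes on {len(ann.seqspace.chroms)} chromosomes")

        stage = "simulate_binding"
        datasets, bind_truth = simulate.simulate_binding_evidence(cfg.sim, ann)
        for d in datasets:
            write_bed(d, out / f"{d.label}.bed")
            log(f"binding dataset {d.label}: {len(d)} intervals")
        write_bed(bind_truth.sites, out / "true_sites.bed")

        stage = "simulate_expression"
        arrays, expr_truth = simulate.simulate_expression(cfg.sim, ann)
        expression.write_expression_tsv(arrays, out / "expression.tsv")
        log(f"expression: {len(arrays)} arrays x {len(arrays[0].genes)} genes")

        # --- core reconciliation -----------------------------------------
        stage = "core"
        core_set = core.reconcile_core(datasets, cfg.high_tier, cfg.low_tier)
        write_bed(core.core_to_intervals(core_set), out / "core.bed")
        log(f"core: {len(core_set)} reconciled intervals")

        # --- gene assignment ---------------------------------------------
        stage = "assign"
        acfg = assign.AssignmentConfig(max_range=cfg.max_range)
        hits = assign.assign_genes(core_set, ann, acfg)
        pd.DataFrame(
            [
                {"interval_id": h.interval_id, "gene_id": h.gene_id,
                 "mode": h.mode, "distance": h.distance}
                for h in hits
            ]
        ).to_csv(out / "assignments.tsv", sep="\t", index=False)
        bound = assign.bound_genes(hits)
        with open(out / "bound_genes.txt", "w") as fh:
            for g in sorted(bound):
                fh.write(g + "\n")
        log(f"assignment: {len(hits)} hits, {len(bound)} bound genes")

        # --- binding-feature reports ---------------------------------------
        stage = "features"
        feats, summary = core.annotate_location(core_set, ann)
        pd.DataFrame(
            [
                {"interval_id": f.interval_id, "location_class": f.location_class,
                 "genic": f.genic, "host_gene": f.host_gene or ""}
                for f in feats
            ]
        ).to_csv(out / "features.tsv", sep="\t", index=False)
        prof = core.tss_distance_profile(core_set, ann, window=cfg.tss_window)
        pd.DataFrame({"distance": prof.distances}).to_csv(
            out / "tss_distances.tsv", sep="\t", index=False
        )
        intron_rep = core.intron_length_test(core_set, ann)
        with open(out / "reports.tsv", "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"fraction_genic\t{summary['fraction_genic']:.6g}\n")
            fh.write(
                f"fraction_intronic_of_genic\t{summary['fraction_intronic_of_genic']:.6g}\n"
            )
            fh.write(f"tss_within_{cfg.tss_window}bp\t{prof.count_within_window}\n")
            fh.write(f"tss_fraction_within_window\t{prof.fraction_within_window:.6g}\n")
            fh.write(f"median_bound_intron\t{intron_rep.median_bound:.6g}\n")
            fh.write(f"median_unbound_intron\t{intron_rep.median_unbound:.6g}\n")
            fh.write(f"intron_rank_sum_p\t{intron_rep.p_value:.6g}\n")
        log(
            "features: %.1f%% genic, %.1f%% of genic intronic; %d/%d within %d bp of a TSS"
            % (
                100 * summary["fraction_genic"],
                100 * summary["fraction_intronic_of_genic"],
                prof.count_within_window,
                len(prof.distances),
                cfg.tss_window,
            )
        )

        # --- expression normalization and DE -------------------------------
        stage = "normde"
        normed, invariant = expression.normalize_expression(arrays)
        expression.write_expression_tsv(normed, out / "expression_normalized.tsv")
        m_thr, p_thr = _de_thresholds(cfg)
        de = expression.call_de(normed, m_threshold=m_thr, p_threshold=p_thr)
        de.to_csv(out / "de_results.tsv", sep="\t", index=False, float_format="%.6g")
        n_up = int((de["call"] == "up").sum())
        n_down = int((de["call"] == "down").sum())
        log(
            f"expression: {len(invariant)} invariant genes; DE at {cfg.de_tier} tier: "
            f"{n_up} up, {n_down} down"
        )

        # --- targets --------------------------------------------------------
        stage = "targets"
        tgts = targets.define_targets(bound, de, hits)
        pd.DataFrame(
            [
                {"gene_id": t.gene_id, "direction": t.direction, "aveM": t.aveM,
                 "intervals": ";".join(t.supporting_intervals)}
                for t in tgts
            ]
        ).to_csv(out / "targets.tsv", sep="\t", index=False, float_format="%.6g")
        target_ids = {t.gene_id for t in tgts}
        log(f"targets: {len(tgts)} bound-and-DE genes")

        # --- enrichment -----------------------------------------------------
        stage = "enrich"
        universe = {g.gene_id for g in ann.genes}
        term_map = simulate.simulate_term_map(cfg.sim, sorted(universe), target_ids)
        gene_lengths = {g.gene_id: g.end - g.start for g in ann.genes}
        enr = targets.enrich_terms(
            target_ids, term_map, universe, correction="length",
            gene_lengths=gene_lengths, resamples=cfg.enrich_resamples,
            seed=cfg.seed,
        )
        targets.enrichment_frame(enr).to_csv(
            out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
        )
        log(f"enrichment: {len(enr)} terms tested")

        # --- co-occurrence --------------------------------------------------
        stage = "cooccur"
        set_a, set_b, pair_truth = simulate.simulate_tf_pair(cfg.sim, ann.seqspace)
        cc = cooccur.pairwise_cooccur(
            {"tfA": [set_a], "tfB": [set_b]}, ann.seqspace,
            nsamples=cfg.cooccur_nsamples, seed=cfg.seed,
        )
        cc.to_csv(out / "cooccur.tsv", sep="\t", index=False, float_format="%.6g")
        log(f"cooccur: pvalue={cc['pvalue'].iloc[0]:.6g} over {cfg.cooccur_nsamples} resamples")

        # --- motif scanning -------------------------------------------------
        stage = "scan"
        pwm = motif.build_pwm(simulate.default_pwm_counts())
        seqs, seq_truth = simulate.simulate_sequences(cfg.sim, pwm)
        bg = motif.fit_markov1(seqs)
        hits_m = motif.scan_sequences(seqs, pwm, bg, threshold=cfg.motif_threshold)
        pd.DataFrame(
            [
                {"seq_id": h.seq_id, "offset": h.offset, "strand": h.strand,
                 "weight": round(h.weight, 4)}
                for h in hits_m
            ]
        ).to_csv(out / "motif_hits.tsv", sep="\t", index=False)
        seq_with_hit = {h.seq_id for h in hits_m}
        match_fraction = len(seq_with_hit) / len(seqs)
        log(f"motif: {len(seq_with_hit)}/{len(seqs)} sequences with a match "
            f"(fraction {match_fraction:.4f})")

        # --- planted-truth recovery metrics --------------------------------
        stage = "metrics"
        truth_bound = assign.bound_genes(
            assign.assign_genes(bind_truth.sites, ann, acfg)
        )
        truth_de = set(expr_truth.de_direction)
        truth_targets = truth_bound & truth_de
        tp = len(target_ids & truth_targets)
        precision = tp / len(target_ids) if target_ids else float("nan")
        recall = tp / len(truth_targets) if truth_targets else float("nan")
        planted = {s for s, o in seq_truth.motif_offsets.items() if o is not None}
        metrics = {
            "n_core_intervals": len(core_set),
            "n_bound_genes": len(bound),
            "n_de_up": n_up,
            "n_de_down": n_down,
            "n_targets": len(tgts),
            "n_truth_targets": len(truth_targets),
            "target_precision": round(precision, 6),
            "target_recall": round(recall, 6),
            "fraction_genic": round(summary["fraction_genic"], 6),
            "fraction_intronic_of_genic": round(summary["fraction_intronic_of_genic"], 6),
            "tss_fraction_within_window": round(prof.fraction_within_window, 6),
            "motif_match_fraction": round(match_fraction, 6),
            "motif_planted_fraction": round(len(planted) / len(seqs), 6),
            "cooccur_pvalue": float(cc["pvalue"].iloc[0]),
        }
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log(f"metrics: target precision {precision:.3f}, recall {recall:.3f}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return out
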