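"""End-to-end orchestration: simulate (or load) → QC → five estimators →
comparison tables → report bundle.

Every run is a pure function of (inputs, resolved configuration, seed): a
snapshot of the resolved configuration is written next to the outputs, and
rerunning with the same configuration and seed reproduces every numeric
table byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare, freq_estimators, hbd, roh
from .genotypes import QCThresholds, ibs_screen, qc_cascade, qc_log_frame, read_genotypes
from .pedigree import (Pedigree, build_a_matrix, f_ped, read_pedigree_table,
                       trace_ancestors_multi, validate_pedigree)
from .simdata import (SimConfig, gene_drop, simulate_pedigree, write_ped_map,
                      write_pedigree_csv)

log = logging.getLogger("autozyg")


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run."""

    out_dir: str = "autozyg_run"
    seed: int = 1
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    pedigree_file: str | None = None
    ped_file: str | None = None
    map_file: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    roh_params: roh.ROHParams = field(default_factory=roh.ROHParams)
    hbd_n_classes: int = 10
    hbd_error_rate: float = 0.001
    bp_per_morgan: float = 1e8
    pedigree_horizon: int = 5
    min_complete_generations: int = 5
    age_grouping: str = "methods"
    hbd_max_iter: int = 200
    hbd_tol: float = 1e-4
    use_founder_freqs: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig(**kwargs["sim"])
        if "qc" in kwargs:
            kwargs["qc"] = QCThresholds(**kwargs["qc"])
        if "roh_params" in kwargs:
            kwargs["roh_params"] = roh.ROHParams(**kwargs["roh_params"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # plain types for YAML


def run_pipeline(cfg: RunConfig) -> dict[str, object]:
    """Run every stage and write the report bundle to ``cfg.out_dir``.

    Returns the in-memory artefacts (inbreeding table, segment frames,
    comparison tables).  Any stage failure aborts with the stage name; the
    artefacts of completed stages remain on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    artefacts: dict[str, object] = {}
    stage = "setup"
    roh_params = cfg.roh_params
    try:
        stage = "inputs"
        if cfg.simulate:
            sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
            # F_ROH is relative to the genome actually simulated
            roh_params = dataclasses.replace(
                cfg.roh_params,
                genome_length_bp=sim.n_chromosomes * sim.chrom_length_bp)
            ped = simulate_pedigree(sim)
            rng = np.random.default_rng(cfg.seed + 1)
            G, M, truth = gene_drop(ped, sim, rng)
            write_pedigree_csv(ped, out / "pedigree.csv")
            write_ped_map(G, M, out / "genotypes")
            truth.tracts.to_csv(out / "truth_tracts.tsv", sep="\t", index=False)
            truth.autozygous_fraction.rename_axis("individual").to_csv(
                out / "truth_fractions.csv")
            artefacts["truth"] = truth
            founder_freqs = dict(zip(G.marker_ids, truth.founder_freqs))
            raw_rows = read_pedigree_table(out / "pedigree.csv")
        else:
            if not (cfg.pedigree_file and cfg.ped_file and cfg.map_file):
                raise ValueError(
                    "simulation disabled but pedigree_file/ped_file/map_file "
                    "not all provided")
            raw_rows = read_pedigree_table(cfg.pedigree_file)
            G, M = read_genotypes(cfg.ped_file, cfg.map_file)
            founder_freqs = None

        stage = "pedigree-qc"
        ped, ped_report = validate_pedigree(raw_rows)
        ped_report.to_frame().to_csv(out / "qc_pedigree.csv", index=False)

        stage = "genotype-qc"
        G, M, qc_log = qc_cascade(G, M, cfg.qc)
        qc_log_frame(qc_log).to_csv(out / "qc_genotypes.tsv", sep="\t",
                                    index=False)
        ibs = ibs_screen(G, cfg.qc.dup_pi_hat)
        ibs.to_csv(out / "ibs_pairs.csv", index=False)

        genotyped = [i for i in G.individual_ids if i in ped]
        if cfg.use_founder_freqs:
            if founder_freqs is None:
                raise ValueError("founder frequencies requested but only "
                                 "available for simulated runs")
            freqs = np.array([founder_freqs[m] for m in G.marker_ids])
        else:
            freqs = G.allele_freqs()

        stage = "f_ped"
        traced = trace_ancestors_multi(ped, genotyped, cfg.pedigree_horizon)
        A = build_a_matrix(traced)
        A.to_long_frame().to_csv(out / "a_matrix.csv", index=False)
        fped = f_ped(A, traced, genotyped, cfg.min_complete_generations)

        stage = "f_hom"
        fhom = freq_estimators.f_hom(freq_estimators.hom_stats(G, freqs))

        stage = "f_roh"
        segments = roh.detect_roh(G, M, roh_params)
        roh_seg = roh.segments_frame(segments)
        roh_seg.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
        froh = roh.f_roh(segments, G.individual_ids, roh_params)

        stage = "f_hbd"
        model = hbd.HBDModel(n_classes=cfg.hbd_n_classes,
                             error_rate=cfg.hbd_error_rate,
                             bp_per_morgan=cfg.bp_per_morgan)
        results = hbd.fit_hbd(G, M, freqs, model, cfg.hbd_max_iter,
                              cfg.hbd_tol, cfg.age_grouping)
        fhbd = hbd.hbd_table(results)
        hbd_seg = hbd.hbd_segments_frame(results)
        hbd_seg.to_csv(out / "hbd_segments.tsv", sep="\t", index=False)

        stage = "f_grm"
        grm = freq_estimators.vanraden_grm(G, freqs)
        grm.to_long_frame().to_csv(out / "grm.csv", index=False)
        fgrm = freq_estimators.f_grm(grm)

        stage = "assemble"
        table = assemble_inbreeding_table(ped, G.individual_ids, fped, fhom,
                                          froh, fhbd, fgrm)
        if "truth" in artefacts:
            truth = artefacts["truth"]
            table = table.join(truth.autozygous_fraction)
            table = table.join(truth.true_f_ped)
        table.to_csv(out / "inbreeding_table.csv")
        artefacts.update(table=table, roh_segments=roh_seg,
                         hbd_segments=hbd_seg, a_matrix=A, grm=grm)

        stage = "compare"
        summary = compare.summary_table(table)
        summary.to_csv(out / "summary.csv")
        corr = compare.correlation_matrix(table)
        corr.to_csv(out / "correlations.csv")
        reg = compare.regression_table(table)
        reg.to_csv(out / "regressions.csv")
        roh_cols = [c for c in table if c.startswith("f_roh_")]
        part_roh = compare.partition_autozygosity(table, "f_roh", roh_cols)
        part_roh.to_csv(out / "partition_roh.csv")
        age_cols = [c for c in table
                    if c.startswith("f_hbd_") and not c[6:].startswith("R")]
        part_hbd = compare.partition_autozygosity(table, "f_hbd", age_cols)
        part_hbd.to_csv(out / "partition_hbd.csv")
        compare.segment_class_summary(roh_seg).to_csv(
            out / "roh_class_summary.csv")
        compare.segment_class_summary(hbd_seg, "rate_class").to_csv(
            out / "hbd_class_summary.csv")
        trend = compare.birth_year_trend(table, min_cohort=10)
        trend.to_csv(out / "birth_year_medians.csv")
        artefacts.update(summary=summary, correlations=corr, regressions=reg,
                         partition_roh=part_roh, partition_hbd=part_hbd,
                         birth_year_medians=trend)
    except Exception as exc:
        done = sorted(p.name for p in out.iterdir())
        raise RuntimeError(
            f"pipeline stage {stage!r} failed ({exc}); completed artefacts: "
            f"{done}") from exc
    return artefacts


def assemble_inbreeding_table(ped: Pedigree, ids, fped, fhom, froh, fhbd,
                              fgrm) -> pd.DataFrame:
    """One row per genotyped individual, joining all five coefficients with
    birth year and sex from the pedigree."""
    base = pd.DataFrame(index=pd.Index(ids, name="individual"))
    base["birth_year"] = [
        (ped[i].birth_date.year if i in ped and ped[i].birth_date else np.nan)
        for i in ids]
    base["sex"] = [(ped[i].sex if i in ped else "unknown") for i in ids]
    base = base.join(fped.rename("f_ped"))
    base = base.join(fhom.rename("f_hom"))
    base = base.join(froh)
    base = base.join(fhbd)
    base = base.join(fgrm.rename("f_grm"))
    return base
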