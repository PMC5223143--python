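"""Pipeline orchestration and replicate-concordance summaries.

``run_full_analysis`` executes the whole analysis sequence on a simulated
(or pre-written) study bundle: normalization, differential testing of
exon/intron/mark/accessibility counts in the diet and reversal contrasts,
nascent-transcription classification, enhancer-gene proximity enrichment,
persistence classification with diagnostics, motif analyses, and
replicate-concordance summaries.  All outputs are plain TSV/BED/JSON and
the run is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enhancer_activity, motifs as motifs_mod, nascent, synthetic
from .difftest import (
    Contrast,
    CountMatrix,
    estimate_dispersion,
    estimate_size_factors,
    nb_wald_test,
    threshold_results,
)

logger = logging.getLogger("enhrev")

DIO = Contrast("Chow", "HFD")
REV = Contrast("ChowChow", "HFDChow")


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Thresholds and inputs of a full pipeline run.

    Defaults follow the analysis conventions this pipeline reproduces:
    mRNA significance at FDR < 0.05; ongoing-transcription screening at
    exon FDR < 0.01 with 1.5-fold change and an intron FDR grid of
    {0.01, 0.05, 0.1}; region-level screening at p < 0.01 with FDR < 0.1
    confirmation; proximity enrichment within 100 kb of the TSS against
    4 rounds of 200 random genes.
    """

    seed: int = 0
    outdir: str = "enhrev_out"
    sim: synthetic.SimConfig | None = None  # None -> default SimConfig(seed)
    input_dir: str | None = None  # read a written bundle instead of simulating
    mrna_fdr: float = 0.05
    ongoing_exon_fdr: float = 0.01
    ongoing_min_fc: float = 1.5
    intron_fdr_grid: tuple = (0.01, 0.05, 0.1)
    region_p: float = 0.01
    region_fdr: float = 0.1
    window_bp: int = 100_000
    n_random: int = 200
    rounds: int = 4
    motif_score_min: float = 8.0
    motif_n_random_regions: int = 200


def zscore_rows(matrix) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scores (sample sd); constant rows become zeros.

    Returns ``(z, constant_flags)``.  Requires at least 2 columns.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a matrix with >= 2 columns")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mean) / sd, 0.0)
    return z, constant


def replicate_concordance(cm: CountMatrix) -> dict:
    """Pairwise Pearson correlations and 2-component PCA scores per sample.

    Both are computed on log2(size-factor-normalized count + 1).  PCA
    component signs are fixed so the largest-magnitude loading is positive,
    making scores deterministic.
    """
    from sklearn.decomposition import PCA

    if len(cm.sample_ids) < 3:
        raise ValueError("need >= 3 samples")
    sf = estimate_size_factors(cm)
    logx = np.log2(cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    if np.allclose(logx, logx[:, :1]):
        raise ValueError("constant matrix: concordance undefined")

    corr = pd.DataFrame(
        np.corrcoef(logx.T), index=cm.sample_ids, columns=cm.sample_ids
    )

    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(logx.T)
    for k in range(scores.shape[1]):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, k] *= -1
    pca_df = pd.DataFrame(
        scores, index=cm.sample_ids, columns=["PC1", "PC2"]
    )
    return {
        "pearson": corr,
        "pca_scores": pca_df,
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
    }


def _difftest_both(cm: CountMatrix) -> dict[str, pd.DataFrame]:
    sf = estimate_size_factors(cm)
    alpha = estimate_dispersion(cm, sf)
    return {
        "dio": nb_wald_test(cm, sf, alpha, DIO),
        "rev": nb_wald_test(cm, sf, alpha, REV),
    }


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run the full pipeline; write tables and summary.json; return summary.

    Outputs are held in memory and written only after every stage has
    succeeded, so a failed run leaves no partial tables behind.
    """
    t_start = time.time()
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"seed": cfg.seed}
    stage = "setup"

    def log_stage(name: str, **info) -> None:
        logger.info(
            "stage=%s elapsed=%.2fs %s",
            name,
            time.time() - t_start,
            " ".join(f"{k}={v}" for k, v in info.items()),
        )

    try:
        stage = "simulate"
        if cfg.input_dir:
            bundle = synthetic.SimBundle.read(cfg.input_dir)
        else:
            sim_cfg = cfg.sim or synthetic.SimConfig(seed=cfg.seed)
            bundle = synthetic.simulate_study(sim_cfg)
        log_stage(stage, genes=len(bundle.genes), regions=len(bundle.regions))

        stage = "difftest"
        res_exon = _difftest_both(bundle.counts_exon)
        res_intron = _difftest_both(bundle.counts_intron)
        res_k27 = _difftest_both(bundle.counts_k27ac)
        sf_dnase = estimate_size_factors(bundle.counts_dnase)
        alpha_dnase = estimate_dispersion(bundle.counts_dnase, sf_dnase)
        res_dnase = nb_wald_test(bundle.counts_dnase, sf_dnase, alpha_dnase, DIO)
        for name, res in (
            ("exon_dio", res_exon["dio"]),
            ("exon_rev", res_exon["rev"]),
            ("intron_dio", res_intron["dio"]),
            ("intron_rev", res_intron["rev"]),
            ("k27ac_dio", res_k27["dio"]),
            ("k27ac_rev", res_k27["rev"]),
            ("dnase_dio", res_dnase),
        ):
            tables[f"diff_{name}"] = res
        up, down = threshold_results(res_exon["dio"], cfg.mrna_fdr, 1.0)
        summary["genes_up"] = len(up)
        summary["genes_down"] = len(down)
        dn_up, dn_down = threshold_results(res_dnase, cfg.region_fdr, 1.0)
        summary["dnase_regions_changed_fdr"] = len(dn_up) + len(dn_down)
        log_stage(stage, genes_up=len(up), genes_down=len(down))

        stage = "nascent"
        ongoing = nascent.classify_ongoing(
            res_exon["dio"],
            res_intron["dio"],
            cfg.ongoing_exon_fdr,
            cfg.ongoing_min_fc,
            cfg.intron_fdr_grid,
        )
        tables["nascent_calls"] = ongoing.calls
        tables["nascent_fractions"] = ongoing.fractions
        summary["ongoing_fractions"] = {
            f"{row.direction}_at_{row.intron_fdr:g}": (
                None if np.isnan(row.fraction_ongoing) else round(float(row.fraction_ongoing), 6)
            )
            for row in ongoing.fractions.itertuples()
        }
        log_stage(stage)

        stage = "enhancers"
        k27_dio = res_k27["dio"]
        ind_ids, red_ids = threshold_results(k27_dio, cfg.region_fdr, 1.0, p_max=cfg.region_p)
        ind_fdr, red_fdr = threshold_results(k27_dio, cfg.region_fdr, 1.0)
        summary["k27ac_regions_p"] = {"induced": len(ind_ids), "reduced": len(red_ids)}
        summary["k27ac_regions_fdr"] = {
            "induced": len(ind_fdr),
            "reduced": len(red_fdr),
        }
        by_id = {r.id: r for r in bundle.regions}
        from .intervals import RegionSet

        induced_rs = RegionSet([by_id[i] for i in ind_ids], name="induced")
        reduced_rs = RegionSet([by_id[i] for i in red_ids], name="reduced")
        exup, exdown = threshold_results(
            res_exon["dio"], cfg.ongoing_exon_fdr, cfg.ongoing_min_fc
        )
        enrich_rows = []
        summary["proximity"] = {}
        for rs, gene_set, label in (
            (induced_rs, exup, "induced_near_up"),
            (reduced_rs, exdown, "reduced_near_down"),
        ):
            if len(gene_set) == 0 or len(rs) == 0:
                summary["proximity"][label] = None
                continue
            enr = enhancer_activity.proximity_enrichment(
                rs,
                bundle.genes,
                gene_set,
                window_bp=cfg.window_bp,
                n_random=cfg.n_random,
                rounds=cfg.rounds,
                seed=cfg.seed + 1,
                gene_set_name=label,
                region_class=rs.name,
            )
            enrich_rows.append(enr.to_row())
            summary["proximity"][label] = {
                "ratio": None if np.isnan(enr.ratio) else round(enr.ratio, 6),
                "p": round(enr.p, 10),
            }
        if enrich_rows:
            tables["proximity_enrichment"] = pd.DataFrame(enrich_rows)

        persistence = enhancer_activity.classify_persistence(
            k27_dio, res_k27["rev"], cfg.region_p, cfg.region_fdr
        )
        tables["persistence_calls"] = persistence.calls
        summary["persistence_classes"] = persistence.class_counts()
        summary["venn_fdr"] = persistence.venn_fdr
        summary["venn_p"] = persistence.venn_p
        diagnostics = enhancer_activity.persistence_diagnostics(
            persistence, bundle.counts_k27ac
        )
        summary["persistence_diagnostics"] = diagnostics
        log_stage(stage, induced=len(ind_ids), reduced=len(red_ids))

        stage = "motifs"
        pwm = motifs_mod.example_pwm()
        rng = np.random.default_rng(cfg.seed + 2)
        non_induced = [i for i in bundle.regions.ids if i not in set(ind_ids)]
        n_bg = min(cfg.motif_n_random_regions, len(non_induced))
        bg_ids = [non_induced[k] for k in rng.choice(len(non_induced), n_bg, replace=False)]
        if len(ind_ids) >= 2 and n_bg >= 2:
            fg_seqs = [bundle.sequences[i] for i in ind_ids]
            bg_seqs = [bundle.sequences[i] for i in bg_ids]
            fg_frac, bg_frac, p_occ = motifs_mod.occurrence_enrichment(
                fg_seqs, bg_seqs, pwm, cfg.motif_score_min
            )
            strength = motifs_mod.strength_comparison(
                {"induced": fg_seqs, "random_accessible": bg_seqs}, pwm
            )
            summary["motif"] = {
                "fg_frac": round(fg_frac, 6),
                "bg_frac": round(bg_frac, 6),
                "occurrence_p": p_occ,
                "strength_p": strength.pairwise_p[("induced", "random_accessible")],
            }
        else:
            summary["motif"] = None
        log_stage(stage)

        stage = "concordance"
        conc = replicate_concordance(bundle.counts_exon)
        tables["pearson_exon"] = conc["pearson"]
        tables["pca_exon"] = conc["pca_scores"]
        summary["pca_explained_variance_ratio"] = [
            round(float(v), 6) for v in conc["explained_variance_ratio"]
        ]
        log_stage(stage)

        stage = "write"
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.write(out / "bundle")
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log_stage(stage, tables=len(tables))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise StageError(stage, exc) from exc

    return summary
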