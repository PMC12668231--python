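"""End-to-end pipeline: simulate -> quantify -> score -> fit -> translate.

Configuration is a flat mapping (YAML on disk) validated against
:class:`PipelineConfig`; unknown keys are rejected.  All randomness is
derived from the single configured seed, and every output table carries
the config hash and seed in its header, so a rerun with the same config
is bit-identical (timestamps go to the run log only).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, quant, scores, sedmodel, synth, translation

logger = logging.getLogger("sedq")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults give a small but realistic run."""

    out_dir: str = "sedq_run"
    seed: int = 0
    # simulation
    n_genes: int = 2000
    frac_induced: float = 0.05
    n_replicates: int = 2
    mean_total_count: float = 500.0
    phi: float = 50.0
    beta: float = 1e-4
    x: float = 1.0
    mu: float = 0.7
    nu: float = 2e-4
    sigma_g: float = 0.25
    delta_e: float = 1.0
    induction_log2fc: float = 2.0
    exponent_sign: int = 1
    # quantification
    min_count: int = 20
    estimation_mode: str = "MAP"
    # scoring
    window_fraction: float = 0.02
    bin_size: int = 100
    # translation
    simulate_polysome: bool = True
    n_spikes: int = 20
    min_spike_counts: float = 100.0
    # optional external inputs (skip simulation when given)
    counts_path: str | None = None
    annotation_path: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)


def _fit_condition(counts: pd.DataFrame, cfg: PipelineConfig, seed: int):
    """Estimate ratios and pSup per (condition, replicate) experiment."""
    psup_frames, fit_meta = [], []
    for (cond, rep), grp in counts.groupby(["condition", "replicate"], sort=True):
        fit = quant.estimate_mixing_ratios(
            grp, min_count=cfg.min_count, mode=cfg.estimation_mode, seed=seed
        )
        tab = quant.compute_psup(grp, fit)
        psup_frames.append(tab)
        fit_meta.append(
            {
                "condition": cond,
                "replicate": int(rep),
                "a_S": fit.a_S,
                "a_P": fit.a_P,
                "phi": fit.phi,
                "n_genes_used": fit.n_genes_used,
                "mode": fit.estimation_mode,
                "warnings": fit.warnings,
            }
        )
    return pd.concat(psup_frames, ignore_index=True), fit_meta


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a report dict (also written to out_dir)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    # hash the scientific parameters only, so the same analysis rerun into a
    # different directory produces byte-identical outputs
    chash = io.config_hash({k: v for k, v in cfg_dict.items() if k != "out_dir"})
    meta = {"config_hash": chash, "seed": config.seed}
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {"config_hash": chash, "seed": config.seed}
    try:
        logger.info("pipeline start, config hash %s", chash)
        with open(out / "config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(cfg_dict, fh, sort_keys=True)

        # --- stage: inputs (simulate or load) -------------------------------
        master = np.random.default_rng(config.seed)
        seeds = {k: int(master.integers(0, 2**31 - 1))
                 for k in ("annot", "study", "polysome", "quant")}
        if config.counts_path and config.annotation_path:
            counts = io.read_counts_table(config.counts_path)
            annotation = io.read_annotation(config.annotation_path)
            study = None
        else:
            annotation = synth.generate_transcriptome(
                config.n_genes, frac_induced=config.frac_induced, seed=seeds["annot"]
            )
            study = synth.simulate_study(
                annotation,
                beta=config.beta, x=config.x, mu=config.mu, nu=config.nu,
                sigma_g=config.sigma_g, delta_e=config.delta_e,
                induction_log2fc=config.induction_log2fc,
                exponent_sign=config.exponent_sign, phi=config.phi,
                mean_total_count=config.mean_total_count,
                n_replicates=config.n_replicates, seed=seeds["study"],
            )
            counts = study["counts"]
            io.write_table(counts, out / "counts.tsv", meta)
            io.write_table(annotation, out / "annotation.tsv", meta)
            truth = study["truth_control"].table.merge(
                study["truth_stress"].table, on="gene_id",
                suffixes=("_control", "_stress"),
            )
            io.write_table(truth, out / "truth.tsv", meta)
        logger.info("inputs ready: %d genes", annotation["gene_id"].nunique())

        # --- stage: quantify ------------------------------------------------
        psup, fit_meta = _fit_condition(counts, config, seeds["quant"])
        io.write_table(psup, out / "psup.tsv", meta)
        with open(out / "mixing_fits.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump({"fits": fit_meta, **meta}, fh, sort_keys=True)
        report["mixing_fits"] = fit_meta
        logger.info("quantified %d experiments", len(fit_meta))

        # --- stage: score ---------------------------------------------------
        conditions = sorted(psup["condition"].unique())
        control = conditions[0] if "control" not in conditions else "control"
        score_tables = []
        psup_c = psup[psup["condition"] == control]
        prof_c = scores.windowed_length_stats(psup_c, annotation, config.window_fraction)
        for cond in conditions:
            psup_t = psup[psup["condition"] == cond]
            prof_t = scores.windowed_length_stats(psup_t, annotation, config.window_fraction)
            ds = scores.delta_sed(psup_c, psup_t, prof_c)
            es = scores.escape_sed(psup_c, psup_t, prof_c, prof_t)
            rs = scores.sed_score(psup_t, annotation, config.bin_size)
            merged = ds.merge(es, on="gene_id").merge(
                rs[["gene_id", "r_sed"]], on="gene_id"
            )
            merged.insert(1, "condition", cond)
            score_tables.append(merged)
        score_table = pd.concat(score_tables, ignore_index=True)
        io.write_table(score_table, out / "scores.tsv", meta)
        treat = [c for c in conditions if c != control]
        if treat:
            tsc = score_table[score_table["condition"] == treat[0]].merge(
                annotation[["gene_id", "induced"]], on="gene_id"
            )
            report["median_delta_sed"] = float(tsc["delta_sed"].median())
            report["median_e_sed_induced"] = float(
                tsc.loc[tsc["induced"], "e_sed"].median()
            )
            report["condensation_detected"] = report["median_delta_sed"] > 0
        logger.info("scores computed for %d conditions", len(conditions))

        # --- stage: biophysical model fit -----------------------------------
        base = sedmodel.fit_baseline(psup_c, annotation, exponent_sign=config.exponent_sign)
        report["baseline_fit"] = {
            "beta": base.params.beta, "x": base.params.x, "rss": base.rss,
        }
        if treat:
            psup_t = psup[psup["condition"] == treat[0]]
            full = sedmodel.fit_stress(psup_t, annotation, base.params)
            red = sedmodel.fit_stress(psup_t, annotation, base.params,
                                      fit_mu=False, fit_nu=True)
            ftest = sedmodel.nested_f_test(full, red)
            report["stress_fit"] = {
                "mu": full.params.mu, "nu": full.params.nu, "rss": full.rss,
                "F": ftest.F, "p_value": ftest.p_value,
                "df": [ftest.df_num, ftest.df_den],
            }
            pred = pd.DataFrame(
                {
                    "gene_id": annotation["gene_id"],
                    "length_total": annotation["length_total"],
                    "psup_pred_control": sedmodel.predict_psup(
                        annotation["length_total"].to_numpy(float), base.params
                    ),
                    "psup_pred_stress": sedmodel.predict_psup(
                        annotation["length_total"].to_numpy(float), full.params
                    ),
                }
            )
            io.write_table(pred, out / "model_predictions.tsv", meta)
        with open(out / "model_fit.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "baseline": report["baseline_fit"],
                    "stress": report.get("stress_fit"),
                    "exponent_sign": config.exponent_sign,
                    **meta,
                },
                fh, sort_keys=True,
            )
        logger.info("model fit done")

        # --- stage: translation ---------------------------------------------
        if config.simulate_polysome and study is not None:
            # couple occupancy to condensation: condensed transcripts are
            # translationally disengaged (TIIC coupling scenario)
            rng = np.random.default_rng(seeds["polysome"])
            p_stress = study["truth_stress"].table["true_psup"].to_numpy()
            occ = np.clip(p_stress * 0.9 + rng.normal(0, 0.03, p_stress.size), 0, 1)
            tpm = synth.simulate_polysome_tpm(
                annotation, occ, n_spikes=config.n_spikes, seed=seeds["polysome"]
            )
            io.write_table(tpm, out / "polysome_tpm.tsv", meta)
            norm = translation.normalize_to_spikein(tpm, config.min_spike_counts)
            occ_est = translation.ribosome_occupancy(norm)
            assoc = translation.ribosome_association(
                tpm[(tpm["fraction"] == "Bound") & ~tpm["is_spike"]],
                tpm[(tpm["fraction"] == "Total") & ~tpm["is_spike"]],
            )
            trans = occ_est.merge(assoc, on="gene_id")
            io.write_table(trans, out / "translation.tsv", meta)
            joined = trans.merge(
                score_table[score_table["condition"] == (treat[0] if treat else control)],
                on="gene_id",
            ).dropna(subset=["occupancy", "r_sed"])
            rho = float(joined["occupancy"].corr(joined["r_sed"], method="spearman"))
            report["occupancy_rsed_spearman"] = rho
            logger.info("translation metrics done (spearman occ~rSed %.3f)", rho)

        with open(out / "report.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(report, fh, sort_keys=True)
        report["elapsed_s"] = round(time.time() - t0, 2)
        logger.info("pipeline finished in %.1fs", report["elapsed_s"])
        return report
    except Exception:
        logger.exception("pipeline stage failed; partial outputs kept in %s", out)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
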