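"""Umbrella analysis pipeline: PCA -> GWAS -> F_ST -> clines -> dominance.

Mirrors the study design of a two-species hybrid-zone survey: orient
alleles against the parental reference pools, summarize genomic structure
by PCA, scan every trait for structure-corrected associations, scan
differentiation between the parental populations, fit the focal-locus
geographic cline in each sampling epoch, test the change in squared cline
width against neutral diffusion, and estimate per-trait dominance at the
focal locus.  All randomness flows from the single config seed through
named per-stage substreams; every filter reports its count in the run
manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import apply_threshold, score_scan
from .cline import (
    bootstrap_clines,
    site_series_from_genotypes,
    width_change_test,
)
from .dominance import bootstrap_h
from .genotypes import GenotypeMatrix
from .io import (
    orient_alleles,
    read_phenotypes,
    read_transect,
    read_vcf,
    write_json,
    write_site_series,
)
from .popgen import flag_outliers, genomic_pca, wc_fst, windowed_fst

__all__ = ["AnalysisConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AnalysisConfig:
    vcf: str
    phenotypes: str
    transect: str
    traits: list[str] | None = None  # default: every non-id phenotype column
    occidentalis_label: str = "occidentalis"
    townsendi_label: str = "townsendi"
    alpha: float = 1e-5
    n_axes: int = 3
    fst_outlier_threshold: float = 0.6
    window_bp: int = 10_000
    sigma: float = 20.0
    delta_t: float = 3.0
    cline_bootstrap: int = 1000
    dominance_iters: int = 10_000
    focal_locus: int | None = None  # column index; default: top GWAS hit
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _stage(manifest: dict, name: str):
    manifest["stages"].append(name)


def run_pipeline(config: AnalysisConfig, out_dir) -> Path:
    """Run every stage and write results + a machine-readable manifest.

    Returns the output directory.  Any stage failure aborts with a
    :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    seed_cline, seed_dom, _ = [int(s.generate_state(1)[0] % 2**31) for s in seeds]
    manifest: dict = {
        "hzkit_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": [],
        "counts": {},
    }

    stage = "load_inputs"
    try:
        genotypes, n_multiallelic = read_vcf(config.vcf)
        pheno = read_phenotypes(config.phenotypes)
        transect = read_transect(config.transect)
        traits = config.traits or [c for c in pheno.columns if c != "individual_id"]
        missing_cols = [t for t in traits if t not in pheno.columns]
        if missing_cols:
            raise ValueError(f"traits absent from phenotype table: {missing_cols}")
        if "population" not in transect.columns:
            raise ValueError("transect table needs a population column")
        meta = transect.set_index("individual_id")
        keep = [i for i, s in enumerate(genotypes.samples) if s in meta.index]
        if not keep:
            raise ValueError("no overlap between VCF samples and transect table")
        genotypes = genotypes.take_individuals(np.array(keep))
        meta = meta.loc[genotypes.samples].reset_index()
        ph = pheno.set_index("individual_id").reindex(genotypes.samples)
        manifest["counts"]["individuals"] = genotypes.n_individuals
        manifest["counts"]["loci"] = genotypes.n_loci
        manifest["counts"]["multiallelic_skipped"] = n_multiallelic
        _stage(manifest, stage)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    stage = "orient_alleles"
    try:
        labels = meta["population"].to_numpy()
        genotypes, flipped = orient_alleles(
            genotypes, labels, config.occidentalis_label, config.townsendi_label
        )
        manifest["counts"]["loci_flipped"] = int(flipped.sum())
        _stage(manifest, stage)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    stage = "pca"
    try:
        occ_idx = np.flatnonzero(labels == config.occidentalis_label)
        pca = genomic_pca(genotypes, n_axes=max(config.n_axes, 2), occidentalis_index=occ_idx)
        pca_df = pd.DataFrame(
            pca.scores,
            columns=[f"EV{i + 1}" for i in range(pca.scores.shape[1])],
        )
        pca_df.insert(0, "individual_id", genotypes.samples)
        pca_df.to_csv(out / "pca.tsv", sep="\t", index=False)
        write_json(
            {"eigenvalues": pca.eigenvalues, "pct_variance": pca.pct_variance},
            out / "pca.json",
        )
        _stage(manifest, stage)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    stage = "gwas"
    scans = {}
    try:
        for trait in traits:
            scan = score_scan(
                genotypes,
                ph[trait].to_numpy(),
                n_axes=config.n_axes,
                alpha=config.alpha,
            )
            scans[trait] = scan
            cols = ["contig", "pos", "chi2", "p", "chi2_gc", "p_gc", "r2"]
            scan.loci[cols].to_csv(out / f"gwas_{trait}.tsv", sep="\t", index=False)
            hits = apply_threshold(scan, config.alpha)
            write_json(
                {
                    "trait": trait,
                    "lambda": scan.lam,
                    "lambda_method": scan.lambda_method,
                    "n_axes": scan.n_axes_used,
                    "alpha": config.alpha,
                    "bonferroni_bound": hits.bonferroni_bound,
                    "n_loci_tested": hits.n_loci_tested,
                    "n_excluded_mac": scan.n_excluded_mac,
                    "significant": hits.significant[["contig", "pos", "p_gc", "r2"]].to_dict(
                        "records"
                    ),
                },
                out / f"gwas_{trait}.json",
            )
        manifest["counts"]["gwas_excluded_mac"] = {
            t: s.n_excluded_mac for t, s in scans.items()
        }
        _stage(manifest, stage)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    stage = "fst"
    try:
        parental = np.isin(labels, [config.occidentalis_label, config.townsendi_label])
        fst = wc_fst(
            genotypes.take_individuals(parental),
            labels[parental],
            populations=(config.occidentalis_label, config.townsendi_label),
        )
        fst.loci.to_csv(out / "fst.tsv", sep="\t", index=False)
        windows = windowed_fst(fst, window_bp=config.window_bp)
        windows.to_csv(out / "fst_windows.tsv", sep="\t", index=False)
        outliers = flag_outliers(fst, config.fst_outlier_threshold)
        write_json(
            {
                "genome_wide_weighted": fst.genome_wide_weighted,
                "n_loci_skipped": fst.n_skipped,
                "outlier_threshold": config.fst_outlier_threshold,
                "outliers": outliers[["contig", "pos", "theta"]].to_dict("records"),
            },
            out / "fst.json",
        )
        manifest["counts"]["fst_loci_skipped"] = fst.n_skipped
        _stage(manifest, stage)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    stage = "cline"
    try:
        if config.focal_locus is not None:
            focal = config.focal_locus
        else:
            # top corrected hit across traits
            best = min(
                (s.tested()["p_gc"].min(), s.tested()["p_gc"].idxmin())
                for s in scans.values()
            )
            focal = int(best[1])
        series = site_series_from_genotypes(genotypes, transect, focal)
        write_site_series(series, out / "cline_sites.tsv")
        epochs = series.epochs()
        cline_out: dict = {"focal_locus": focal, "epochs": [str(e) for e in epochs]}
        if len(epochs) == 2:
            draws = bootstrap_clines(series, config.cline_bootstrap, seed=seed_cline)
            from .cline import basic_ci

            for e in epochs:
                fit = draws.fits[e]
                cs = np.array([d.center for d in draws.draws[e]])
                ws = np.array([d.width for d in draws.draws[e]])
                lo_w, hi_w = basic_ci(fit.params.width, ws)
                cline_out[f"epoch_{e}"] = {
                    "center": fit.params.center,
                    "width": fit.params.width,
                    "loglik": fit.loglik,
                    "ci95_center": list(basic_ci(fit.params.center, cs)),
                    "ci95_width": [max(lo_w, 0.0), hi_w],
                }
            test = width_change_test(draws, config.sigma, config.delta_t)
            write_json(
                {
                    "delta_w2": test.delta_w2,
                    "ci95": list(test.ci95),
                    "neutral_expectation": test.neutral_expectation,
                    "less_than_neutral": test.less_than_neutral,
                    "includes_zero": test.includes_zero,
                    "n_draws": test.n_draws,
                    "n_failed": draws.n_failed,
                    "sigma": config.sigma,
                    "delta_t": config.delta_t,
                },
                out / "widthtest.json",
            )
            manifest["counts"]["cline_bootstrap_failed"] = draws.n_failed
        else:
            from .cline import fit_cline

            fit = fit_cline(series, bootstrap=config.cline_bootstrap, seed=seed_cline)
            cline_out["single_epoch"] = {
                "center": fit.params.center,
                "width": fit.params.width,
                "loglik": fit.loglik,
                "ci95_center": list(fit.ci95_center) if fit.ci95_center else None,
                "ci95_width": list(fit.ci95_width) if fit.ci95_width else None,
            }
            manifest["counts"]["cline_bootstrap_failed"] = fit.n_bootstrap_failed
        write_json(cline_out, out / "cline.json")
        _stage(manifest, stage)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    stage = "dominance"
    try:
        dom_results = {}
        g_focal = genotypes.dosage[:, focal]
        for i, trait in enumerate(traits):
            hits = apply_threshold(scans[trait], config.alpha)
            if focal not in hits.significant.index:
                continue
            est = bootstrap_h(
                g_focal,
                ph[trait].to_numpy(),
                n_iter=config.dominance_iters,
                seed=seed_dom + i,
            )
            dom_results[trait] = {
                "h": est.h,
                "class_means": est.class_means,
                "class_counts": est.class_counts,
                "ci95": list(est.ci95),
                "n_bootstrap": est.n_bootstrap,
                "n_degenerate": est.n_degenerate,
            }
        write_json(dom_results, out / "dominance.json")
        _stage(manifest, stage)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    write_json(manifest, out / "manifest.json")
    return out
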