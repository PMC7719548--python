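"""Readers and writers for the pipeline's standard formats.

VCF 4.x (biallelic SNP genotypes, GT field) is read with cyvcf2; tables
(phenotypes, transect metadata, site series, scan results) are
tab-delimited UTF-8 with a header row; scalar results are JSON and
scenario/config files YAML.  Internally genotypes are stored as the dosage
of the counted allele; :func:`orient_alleles` flips each locus so the
counted allele is the one commoner in the townsendi reference population.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .cline import ClineParams, SiteSeries
from .genotypes import GenotypeMatrix
from .simulate import SyntheticDataset, TraitSpec, ZoneScenario

__all__ = [
    "read_vcf",
    "write_vcf",
    "orient_alleles",
    "read_phenotypes",
    "read_transect",
    "read_site_series",
    "write_site_series",
    "write_dataset",
    "scenario_to_yaml",
    "scenario_from_yaml",
]


def read_vcf(path) -> tuple[GenotypeMatrix, int]:
    """Load biallelic SNPs from a VCF into a dosage matrix.

    Dosage counts the ALT allele; missing calls become NaN.  Multi-allelic
    and non-SNP records are skipped; the count of skipped records is
    returned alongside the matrix.  A file without genotype (GT) data, or
    with no usable records, is an error.
    """
    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample genotype (GT) columns")
    cols, recs = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        # gts012: 0/1/2 = ALT dosage, 3 = missing
        g = np.asarray(var.gt_types, dtype=float)
        g[g == 3] = np.nan
        cols.append(g)
        recs.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    if not cols:
        raise ValueError(f"{path}: no biallelic SNP records with genotypes found")
    loci = pd.DataFrame(recs, columns=["contig", "pos", "ref", "alt"])
    return GenotypeMatrix(np.column_stack(cols), samples, loci), skipped


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write the dosage matrix as an uncompressed VCF 4.2 with GT only.

    The counted allele is written as ALT, so dosage round-trips through
    :func:`read_vcf`.
    """
    path = Path(path)
    contigs = list(dict.fromkeys(genotypes.loci["contig"]))
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hzkit\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        D = genotypes.dosage
        for j, row in enumerate(genotypes.loci.itertuples(index=False)):
            calls = [
                "./." if np.isnan(D[i, j]) else gt_code[D[i, j]]
                for i in range(genotypes.n_individuals)
            ]
            fh.write(
                f"{row.contig}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def orient_alleles(
    genotypes: GenotypeMatrix,
    population_labels,
    occidentalis: str = "occidentalis",
    townsendi: str = "townsendi",
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Flip loci so the counted allele is commoner in the townsendi pool.

    Returns the re-oriented matrix and the boolean per-locus flip record
    (REF/ALT in the locus table are swapped on flipped loci).  Ties, and
    loci where either pool is entirely missing, are left unflipped with a
    warning.
    """
    labels = np.asarray(population_labels)
    occ = labels == occidentalis
    town = labels == townsendi
    if not occ.any() or not town.any():
        raise ValueError("both reference populations must be non-empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pools -> NaN
        f_occ = np.nanmean(genotypes.dosage[occ], axis=0) / 2.0
        f_town = np.nanmean(genotypes.dosage[town], axis=0) / 2.0
    undecided = np.isnan(f_occ) | np.isnan(f_town) | (f_occ == f_town)
    if undecided.any():
        warnings.warn(
            f"{int(undecided.sum())} loci tied or unpollable between reference "
            "pools; left unflipped",
            stacklevel=2,
        )
    flip = (~undecided) & (f_town < f_occ)
    dosage = genotypes.dosage.copy()
    dosage[:, flip] = 2.0 - dosage[:, flip]
    loci = genotypes.loci.copy()
    ref, alt = loci["ref"].copy(), loci["alt"].copy()
    loci.loc[flip, "ref"] = alt[flip]
    loci.loc[flip, "alt"] = ref[flip]
    return GenotypeMatrix(dosage, list(genotypes.samples), loci), flip


# ---------------------------------------------------------------------------
# tables


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "individual_id" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs an individual_id column")
    return df


def read_transect(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"individual_id", "site_id", "distance_km", "epoch"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: transect table missing columns {sorted(missing)}")
    return df


def read_site_series(path) -> SiteSeries:
    df = pd.read_csv(path, sep="\t")
    kwargs = dict(
        position=df["distance_km"].to_numpy(),
        epoch=df["epoch"].to_numpy(),
        n=df["n"].to_numpy(),
        site_id=df["site_id"].to_numpy() if "site_id" in df else None,
    )
    if "k" in df.columns:
        kwargs["k"] = df["k"].to_numpy()
    elif "value" in df.columns:
        kwargs["value"] = df["value"].to_numpy()
    else:
        raise ValueError(f"{path}: site series needs a k or value column")
    return SiteSeries(**kwargs)


def write_site_series(series: SiteSeries, path) -> None:
    series.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# scenario / dataset round trips


def scenario_to_yaml(scenario: ZoneScenario, path) -> None:
    d = asdict(scenario)
    d["site_positions"] = [float(x) for x in scenario.site_positions]
    d["island_cline"] = {"center": scenario.island_cline.center, "width": scenario.island_cline.width}
    if scenario.island_cline_epoch2 is not None:
        d["island_cline_epoch2"] = {
            "center": scenario.island_cline_epoch2.center,
            "width": scenario.island_cline_epoch2.width,
        }
    d["trait_specs"] = [asdict(t) for t in scenario.trait_specs]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def scenario_from_yaml(path) -> ZoneScenario:
    d = yaml.safe_load(Path(path).read_text())
    d["site_positions"] = np.asarray(d["site_positions"], dtype=float)
    d["island_cline"] = ClineParams(**d["island_cline"])
    if d.get("island_cline_epoch2"):
        d["island_cline_epoch2"] = ClineParams(**d["island_cline_epoch2"])
    d["trait_specs"] = tuple(TraitSpec(**t) for t in d.get("trait_specs", []))
    return ZoneScenario(**d)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict:
    """Write a synthetic dataset as VCF + TSV tables + truth YAML.

    Returns the mapping of logical names to file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "transect": out / "transect.tsv",
        "scenario": out / "truth_scenario.yaml",
        "locus_truth": out / "truth_loci.tsv",
    }
    write_vcf(dataset.genotypes, paths["vcf"])
    dataset.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    dataset.transect.to_csv(paths["transect"], sep="\t", index=False)
    scenario_to_yaml(dataset.truth, paths["scenario"])
    dataset.locus_truth.to_csv(paths["locus_truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
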