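"""Synthetic hybrid-zone data with known ground truth.

The generator emulates the statistical structure of a two-species avian
hybrid zone sampled along a 1-D transect in two epochs:

* a weakly differentiated genomic background (genome-wide Weir-Cockerham
  F_ST near a small target, default 0.03) in which every locus follows a
  wide, shallow cline between its two end-population frequencies;
* a small number of "island" loci nearly fixed for alternative alleles in
  the parental populations, whose frequencies follow a narrow sigmoid cline
  p(x) = (1 + tanh(2 (x - c)/w)) / 2 with per-epoch center and width;
* one causal island locus affecting several continuous plumage-like traits,
  each with its own dominance coefficient h of the O allele and a target
  fraction of trait variance explained;
* genotypes drawn Binomial(2, p(x)) per individual, uniformly random
  missing calls, and fresh individuals in each epoch.

If ``neutral_widening`` is set, the epoch-2 island width obeys the neutral
diffusion law w2^2 = w1^2 + 2 pi sigma^2 delta_t exactly in the generating
parameters; otherwise the island cline keeps its epoch-1 width (the
signature of selection against hybrids).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cline import ClineParams, SiteSeries, cline_value
from .genotypes import GenotypeMatrix
from .popgen import wc_fst

__all__ = [
    "TraitSpec",
    "ZoneScenario",
    "SyntheticDataset",
    "simulate_zone",
    "simulate_allele_counts",
    "default_scenario",
]

# Dominance coefficients and variance-explained targets of the four
# plumage traits controlled by the focal locus (crown/cheek/breast darkening
# and flank streaking), the study conditions this generator reproduces.
DEFAULT_TRAITS = (
    ("crown", 0.810, 0.60),
    ("cheek", 0.908, 0.57),
    ("breast", 0.557, 0.49),
    ("flank", 0.345, 0.59),
)


@dataclass(frozen=True)
class TraitSpec:
    """One continuous trait controlled by the causal locus.

    ``h`` is the dominance coefficient of the O allele (heterozygote mean =
    mean_tt - h * (mean_tt - mean_oo)); ``r2_target`` is the fraction of
    trait variance the locus explains in a reference population with allele
    frequency 1/2 under Hardy-Weinberg genotype proportions.
    """

    name: str
    h: float
    r2_target: float
    mean_oo: float = 0.0
    mean_tt: float = 1.0

    def class_means(self) -> tuple[float, float, float]:
        m_ot = self.mean_tt - self.h * (self.mean_tt - self.mean_oo)
        return (self.mean_oo, m_ot, self.mean_tt)

    def noise_sd(self) -> float:
        """Gaussian noise SD solving r^2(dosage, trait) = r2_target.

        r2 is the squared Pearson correlation with dosage (the scale on
        which variance explained is reported), evaluated at the balanced
        reference population.  Under dominance only the additive part of
        the genetic variance is linear in dosage, which caps the
        attainable r2; an unattainable target is rejected.
        """
        if not 0 < self.r2_target < 1:
            raise ValueError(f"r2_target must be in (0, 1), got {self.r2_target}")
        m = np.array(self.class_means())
        g = np.array([0.0, 1.0, 2.0])
        w = np.array([0.25, 0.5, 0.25])  # HWE at p = 1/2
        vg = float(w @ m**2 - (w @ m) ** 2)  # total genetic variance
        cov = float(w @ (g * m) - (w @ g) * (w @ m))
        va = cov**2 / float(w @ g**2 - (w @ g) ** 2)  # additive part
        noise_var = va / self.r2_target - vg
        if noise_var <= 0:
            raise ValueError(
                f"r2_target={self.r2_target} unattainable: dominance caps the "
                f"dosage-linear r2 at {va / vg:.3f}"
            )
        return float(np.sqrt(noise_var))


@dataclass
class ZoneScenario:
    """Generating parameters of a synthetic two-epoch hybrid zone."""

    site_positions: np.ndarray = field(
        default_factory=lambda: np.arange(1000.0, 1481.0, 20.0)
    )  # km; 25 sites spanning the zone
    n_per_site: int = 12
    n_background_loci: int = 2000
    n_island_loci: int = 1
    causal_locus_index: int = 0  # index among island loci
    background_fst_target: float = 0.03
    island_cline: ClineParams = field(default_factory=lambda: ClineParams(1216.0, 42.0))
    island_cline_epoch2: ClineParams | None = None  # default: derived (see below)
    background_cline_width: float = 112.0  # km, genome-wide cline scale
    sigma: float = 20.0  # dispersal, km per sqrt generation
    delta_t: float = 3.0  # generations between sampling epochs
    neutral_widening: bool = False
    trait_specs: tuple[TraitSpec, ...] = field(
        default_factory=lambda: tuple(TraitSpec(n, h, r2) for n, h, r2 in DEFAULT_TRAITS)
    )
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.site_positions = np.asarray(self.site_positions, dtype=float)
        if self.site_positions.size < 1 or np.any(np.diff(self.site_positions) <= 0):
            raise ValueError("site_positions must be non-empty and strictly increasing")
        for name in ("n_per_site", "n_background_loci", "n_island_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.background_fst_target < 1:
            raise ValueError("background_fst_target must be in [0, 1)")
        if not 0 <= self.causal_locus_index < self.n_island_loci:
            raise ValueError("causal_locus_index must index an island locus")
        if self.sigma <= 0 or self.delta_t <= 0:
            raise ValueError("sigma and delta_t must be positive")
        for t in self.trait_specs:
            t.noise_sd()  # validates r2_target and width conventions

    @property
    def n_sites_per_epoch(self) -> int:
        return int(self.site_positions.size)

    @property
    def neutral_delta_w2(self) -> float:
        return 2.0 * np.pi * self.sigma**2 * self.delta_t

    def epoch_clines(self) -> tuple[ClineParams, ClineParams]:
        """Island cline per epoch; epoch 2 widens neutrally if requested."""
        c1 = self.island_cline
        if self.neutral_widening:
            w2 = float(np.sqrt(c1.width**2 + self.neutral_delta_w2))
            return c1, ClineParams(c1.center, w2)
        if self.island_cline_epoch2 is not None:
            return c1, self.island_cline_epoch2
        return c1, c1


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame  # individual_id + one column per trait
    transect: pd.DataFrame  # individual_id, site_id, distance_km, epoch, population
    truth: ZoneScenario
    locus_truth: pd.DataFrame  # realized per-locus generating parameters

    @property
    def causal_column(self) -> int:
        """Column index of the causal locus in the genotype matrix."""
        return int(np.flatnonzero(self.locus_truth["causal"].to_numpy())[0])

    def epoch_index(self, epoch: int) -> np.ndarray:
        return np.flatnonzero((self.transect["epoch"] == epoch).to_numpy())

    def trait_values(self, name: str) -> np.ndarray:
        return self.phenotypes[name].to_numpy()

    def site_series(self, locus_index: int | None = None) -> SiteSeries:
        from .cline import site_series_from_genotypes

        if locus_index is None:
            locus_index = self.causal_column
        return site_series_from_genotypes(self.genotypes, self.transect, locus_index)


def _calibrate_background_spread(
    target: float, anc: np.ndarray, rng: np.random.Generator, n_pilot_ind: int = 30
) -> float:
    """Scale factor f such that end frequencies p +/- f*sqrt(p(1-p)) yield a
    weighted W&C F_ST near the target, tuned by a short pilot Monte-Carlo."""
    if target == 0:
        return 0.0
    f = float(np.sqrt(target))
    m = anc.size
    labels = np.array(["occ"] * n_pilot_ind + ["town"] * n_pilot_ind)
    for _ in range(3):
        delta = np.clip(f * np.sqrt(anc * (1 - anc)), 0, None)
        p_lo = np.clip(anc - delta, 0.01, 0.99)
        p_hi = np.clip(anc + delta, 0.01, 0.99)
        g1 = rng.binomial(2, p_lo, size=(n_pilot_ind, m)).astype(float)
        g2 = rng.binomial(2, p_hi, size=(n_pilot_ind, m)).astype(float)
        gm = GenotypeMatrix(np.vstack([g1, g2]), [f"p{i}" for i in range(2 * n_pilot_ind)])
        realized = wc_fst(gm, labels).genome_wide_weighted
        if realized <= 0:
            f *= 2.0
            continue
        f *= float(np.sqrt(target / realized))
        f = min(f, 1.0)
    return f


def simulate_zone(scenario: ZoneScenario) -> SyntheticDataset:
    """Draw a full synthetic dataset (both epochs) from a zone scenario."""
    ss = np.random.SeedSequence(scenario.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(5)]
    rng_freq, rng_geno, rng_trait, rng_miss, rng_pilot = rngs

    pos = scenario.site_positions
    n_bg, n_isl = scenario.n_background_loci, scenario.n_island_loci
    cline1, cline2 = scenario.epoch_clines()

    # --- per-locus generating frequencies -------------------------------
    anc = rng_freq.uniform(0.05, 0.95, size=n_bg)
    f = _calibrate_background_spread(scenario.background_fst_target, anc, rng_pilot)
    delta = f * np.sqrt(anc * (1 - anc))
    # which transect end carries the higher frequency is random per locus
    sign = rng_freq.choice([-1.0, 1.0], size=n_bg)
    p_occ = np.clip(anc - sign * delta, 0.01, 0.99)
    p_town = np.clip(anc + sign * delta, 0.01, 0.99)
    bg_shape = ClineParams(cline1.center, scenario.background_cline_width)

    # --- individuals ----------------------------------------------------
    rows = []
    for epoch in (1, 2):
        for s, x in enumerate(pos):
            for i in range(scenario.n_per_site):
                rows.append(
                    {
                        "individual_id": f"e{epoch}_s{s:02d}_i{i:03d}",
                        "site_id": f"s{s:02d}",
                        "distance_km": float(x),
                        "epoch": epoch,
                    }
                )
    transect = pd.DataFrame(rows)
    # parental-population labels from the epoch-1 island cline expectation
    p_exp = np.asarray(cline_value(cline1, transect["distance_km"].to_numpy()))
    transect["population"] = np.where(
        p_exp < 0.1, "occidentalis", np.where(p_exp > 0.9, "townsendi", "admixed")
    )
    n_ind = len(transect)
    x_ind = transect["distance_km"].to_numpy()
    epoch_ind = transect["epoch"].to_numpy()

    # --- per-individual per-locus frequencies ---------------------------
    s_bg = np.asarray(cline_value(bg_shape, x_ind))[:, None]  # (n_ind, 1)
    freq_bg = p_occ[None, :] + (p_town - p_occ)[None, :] * s_bg
    freq_isl = np.empty((n_ind, n_isl))
    for epoch, cl in ((1, cline1), (2, cline2)):
        sel = epoch_ind == epoch
        freq_isl[sel] = np.asarray(cline_value(cl, x_ind[sel]))[:, None]
    freqs = np.hstack([freq_bg, freq_isl])

    geno = rng_geno.binomial(2, freqs).astype(float)

    # --- traits (from the true causal genotype, before masking) ---------
    causal_col = n_bg + scenario.causal_locus_index
    g_causal = geno[:, causal_col].astype(int)
    pheno = {"individual_id": transect["individual_id"]}
    for t in scenario.trait_specs:
        means = np.array(t.class_means())
        pheno[t.name] = means[g_causal] + rng_trait.normal(0, t.noise_sd(), size=n_ind)
    phenotypes = pd.DataFrame(pheno)

    # --- missingness ----------------------------------------------------
    if scenario.missing_rate > 0:
        mask = rng_miss.random(geno.shape) < scenario.missing_rate
        geno[mask] = np.nan

    # --- locus table: background on chr1, island block on chr20 ---------
    loci = pd.DataFrame(
        {
            "contig": ["chr1"] * n_bg + ["chr20"] * n_isl,
            "pos": np.concatenate(
                [
                    1000 * np.arange(1, n_bg + 1),
                    1_900_000 + 1000 * np.arange(1, n_isl + 1),
                ]
            ).astype(int),
            "ref": "G",
            "alt": "C",
        }
    )
    gm = GenotypeMatrix(geno, list(transect["individual_id"]), loci)

    locus_truth = pd.DataFrame(
        {
            "locus": np.arange(n_bg + n_isl),
            "kind": ["background"] * n_bg + ["island"] * n_isl,
            "p_occ": np.concatenate([p_occ, np.zeros(n_isl)]),
            "p_town": np.concatenate([p_town, np.ones(n_isl)]),
            "cline_center": [bg_shape.center] * n_bg + [cline1.center] * n_isl,
            "cline_width_epoch1": [bg_shape.width] * n_bg + [cline1.width] * n_isl,
            "cline_width_epoch2": [bg_shape.width] * n_bg + [cline2.width] * n_isl,
            "causal": [False] * n_bg
            + [i == scenario.causal_locus_index for i in range(n_isl)],
        }
    )
    return SyntheticDataset(
        genotypes=gm,
        phenotypes=phenotypes,
        transect=transect,
        truth=scenario,
        locus_truth=locus_truth,
    )


def simulate_allele_counts(
    params: ClineParams,
    positions,
    n_alleles,
    rng: np.random.Generator,
    epoch=1,
) -> SiteSeries:
    """Binomial site allele counts drawn from a true cline (one epoch)."""
    x = np.asarray(positions, dtype=float)
    n = np.broadcast_to(np.asarray(n_alleles), x.shape).astype(int)
    p = np.asarray(cline_value(params, x))
    k = rng.binomial(n, p)
    return SiteSeries(
        position=x, epoch=np.full(x.shape, epoch), n=n, k=k,
        site_id=np.array([f"s{i:02d}" for i in range(x.size)]),
    )


def default_scenario(seed: int = 0, **overrides) -> ZoneScenario:
    """The default study-condition scenario with a chosen seed."""
    return replace(ZoneScenario(seed=seed), **overrides)
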