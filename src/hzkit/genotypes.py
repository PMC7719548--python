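"""Core genotype container shared by every analysis stage.

Genotypes are stored as the dosage of a counted allele (0, 1, 2) in a dense
float matrix with ``NaN`` marking missing calls.  By convention downstream
modules orient the counted allele to be the one commoner in the *townsendi*
reference population (the "T" allele), so dosage 0 = OO, 1 = OT, 2 = TT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOCUS_COLUMNS = ("contig", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic-loci dosage matrix.

    Parameters
    ----------
    dosage
        Float array of shape ``(n_individuals, n_loci)`` with entries in
        ``{0.0, 1.0, 2.0}`` or ``NaN`` for missing calls.
    samples
        Individual identifiers, one per row.
    loci
        Locus table with columns ``contig, pos, ref, alt`` (``pos`` 1-based).
    """

    dosage: np.ndarray
    samples: list[str]
    loci: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x loci)")
        if len(self.samples) != self.dosage.shape[0]:
            raise ValueError(
                f"{len(self.samples)} sample ids for {self.dosage.shape[0]} rows"
            )
        if self.loci is None:
            self.loci = default_locus_table(self.dosage.shape[1])
        if len(self.loci) != self.dosage.shape[1]:
            raise ValueError(
                f"{len(self.loci)} locus records for {self.dosage.shape[1]} columns"
            )
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.unique(self.dosage[~valid])
            raise ValueError(f"dosage entries must be 0/1/2/NaN; found {bad}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def allele_freq(self) -> np.ndarray:
        """Per-locus frequency of the counted allele among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def minor_allele_count(self) -> np.ndarray:
        """Per-locus minor-allele count over non-missing calls."""
        called = (~np.isnan(self.dosage)).sum(axis=0)
        alt = np.nansum(self.dosage, axis=0)
        return np.minimum(alt, 2 * called - alt)

    def mean_imputed(self) -> np.ndarray:
        """Dosage matrix with missing entries replaced by the locus mean."""
        out = self.dosage.copy()
        mask = np.isnan(out)
        if mask.any():
            with np.errstate(invalid="ignore"):
                mu = np.nanmean(out, axis=0)
            mu = np.where(np.isnan(mu), 0.0, mu)  # all-missing locus -> 0
            out[mask] = np.broadcast_to(mu, out.shape)[mask]
        return out

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosage[index],
            [self.samples[i] for i in index],
            self.loci.reset_index(drop=True),
        )

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosage[:, index],
            list(self.samples),
            self.loci.iloc[index].reset_index(drop=True),
        )


def default_locus_table(n_loci: int, contig: str = "chr1", spacing: int = 1000) -> pd.DataFrame:
    """Placeholder locus table: evenly spaced positions on one contig."""
    return pd.DataFrame(
        {
            "contig": contig,
            "pos": np.arange(1, n_loci + 1) * spacing,
            "ref": "A",
            "alt": "C",
        }
    )
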