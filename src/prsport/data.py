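"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* positions are 1-based base pairs (VCF convention); windows are closed
  intervals in bp;
* every variant carries an explicit effect allele ``a1`` and other allele
  ``a2``; dosages, frequencies, effect sizes and LD correlations are all
  expressed against ``a1``, so signed cross-population LD products are
  well defined;
* dosage matrices are ``samples x variants`` arrays with entries in
  ``[0, 2]`` (hard calls from the simulator are in ``{0, 1, 2}``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantKey",
    "GenotypePanel",
    "SummaryStats",
    "PRSWeights",
    "RecombinationMap",
    "variant_index",
]

#: columns every variant table must carry
VARIANT_COLUMNS = ["chrom", "pos", "id", "a1", "a2"]

#: canonical column order of a summary-statistics table
SUMSTAT_COLUMNS = ["CHR", "POS", "ID", "A1", "A2", "BETA", "SE", "P", "AF", "N"]


@dataclass(frozen=True)
class VariantKey:
    """Identity of a variant: chromosome, 1-based position and allele pair."""

    chrom: str
    pos: int
    a1: str
    a2: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.a1 == self.a2:
            raise ValueError(f"alleles must differ, got {self.a1}/{self.a2}")


def variant_index(df: pd.DataFrame, chrom_col: str = "chrom", pos_col: str = "pos") -> pd.Index:
    """Build a (chrom, pos) MultiIndex used to align tables across modules."""
    return pd.MultiIndex.from_arrays(
        [df[chrom_col].astype(str).to_numpy(), df[pos_col].astype(int).to_numpy()],
        names=["chrom", "pos"],
    )


@dataclass
class GenotypePanel:
    """Samples x variants dosage matrix plus variant and sample metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` array of effect-allele dosages in
        ``[0, 2]``; ``NaN`` marks a missing call.
    variants
        Table with at least ``chrom, pos, id, a1, a2``; simulators add
        per-population truth columns (e.g. ``freq_<pop>``).
    samples
        Table with at least ``sample_id``; may carry ``population``,
        ``admixture`` and covariate columns.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        n, m = self.dosages.shape
        if len(self.variants) != m:
            raise ValueError(f"variant table has {len(self.variants)} rows for {m} columns")
        if len(self.samples) != n:
            raise ValueError(f"sample table has {len(self.samples)} rows for {n} dosage rows")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError(f"{bad} dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # -- basic geometry ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Empirical effect-allele frequency per variant (missing ignored)."""
        freq = self.dosages.mean(axis=0) / 2.0
        if np.isnan(freq).any():
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return freq

    def key_index(self) -> pd.Index:
        return variant_index(self.variants)

    def subset_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx, dtype=int)
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=self.samples.copy(),
        )

    def subset_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx, dtype=int)
        return GenotypePanel(
            dosages=self.dosages[idx, :],
            variants=self.variants.copy(),
            samples=self.samples.iloc[idx].reset_index(drop=True),
        )


@dataclass
class SummaryStats:
    """Marginal GWAS association results for one discovery population."""

    table: pd.DataFrame
    population: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def key_index(self) -> pd.Index:
        return variant_index(self.table, "CHR", "POS")


@dataclass
class PRSWeights:
    """Variant weights produced by clumping + thresholding.

    ``table`` columns: ``CHR, POS, ID, EFFECT_ALLELE, WEIGHT``; ``params``
    records the (p-value, r2, window) tuple that generated the set.
    """

    table: pd.DataFrame
    params: "object | None" = None
    source_population: str = ""

    REQUIRED = ["CHR", "POS", "ID", "EFFECT_ALLELE", "WEIGHT"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"weights table missing columns: {missing}")
        if not np.all(np.isfinite(self.table["WEIGHT"].to_numpy(dtype=float))):
            raise ValueError("non-finite weight")
        keys = list(zip(self.table["CHR"], self.table["POS"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variants in weights")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def key_index(self) -> pd.Index:
        return variant_index(self.table, "CHR", "POS")


@dataclass
class RecombinationMap:
    """Piecewise-linear genetic map: rate is cM/Mb on the interval to the
    right of each position, ``cumulative`` the map value in cM at each
    position (so the cumulative map is exactly piecewise linear)."""

    positions: np.ndarray
    rates: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if not (len(self.positions) == len(self.rates) == len(self.cumulative)):
            raise ValueError("positions, rates and cumulative must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("negative recombination rate")
        if np.any(np.diff(self.cumulative) < -1e-12):
            raise ValueError("cumulative map must be non-decreasing")

    @classmethod
    def from_rates(cls, positions: Iterable[float], rates: Iterable[float]) -> "RecombinationMap":
        """Integrate a piecewise-constant rate (cM/Mb, right-interval
        convention) into a cumulative map starting at 0 cM."""
        pos = np.asarray(list(positions), dtype=float)
        rate = np.asarray(list(rates), dtype=float)
        seg = np.diff(pos) * rate[:-1] / 1e6  # bp * cM/Mb -> cM
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        return cls(pos, rate, cum)

    def interpolate_cumulative(self, pos: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation of the cumulative map; flat beyond the ends."""
        return np.interp(pos, self.positions, self.cumulative)

    @property
    def start(self) -> float:
        return float(self.positions[0])

    @property
    def end(self) -> float:
        return float(self.positions[-1])
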