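"""Synthetic two-population genotype/phenotype generator.

The generator produces every input the transferability analysis consumes —
genotype panels with population-specific allele frequencies and blockwise
LD, causal effects correlated across populations, quantitative and
liability-threshold binary phenotypes, marginal GWAS summary statistics,
an admixture gradient, and piecewise-linear recombination maps — with
enough statistical control that each downstream stage can be checked
against closed-form or brute-force oracles.

LD model
--------
Haplotypes come from a Gaussian copula: within an LD block, a latent
AR(1) Gaussian vector with parameter ``ld_rho`` is thresholded at the
normal quantile of each variant's allele frequency; a genotype is the sum
of two independent haplotypes.  This gives independent control of MAF
(the thresholds) and LD (the latent correlation) — exactly the two
factors the relative-accuracy decomposition isolates — and the implied
genotype correlation for any pair of variants has a closed form via the
bivariate normal CDF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypePanel, RecombinationMap, SummaryStats

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationSpec",
    "ArchitectureSpec",
    "SyntheticDataset",
    "simulate_genotypes",
    "simulate_effects_and_phenotypes",
    "simulate_sumstats",
    "simulate_admixture_gradient",
    "simulate_recomb_map",
]


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Describes one population's panel: sample size, LD blocks, allele
    frequencies, heritability and (for binary traits) prevalence.

    ``ld_rho`` may be a scalar (shared by all blocks) or one value per
    block; each is the latent AR(1) correlation of the Gaussian copula,
    in ``[0, 1)``.
    """

    label: str
    n_samples: int
    block_sizes: list[int]
    freq_vector: np.ndarray
    ld_rho: "float | np.ndarray" = 0.0
    h2: float = 0.5
    prevalence: float = 0.1
    chrom: str = "1"
    spacing_bp: int = 5000

    def __post_init__(self) -> None:
        self.freq_vector = np.asarray(self.freq_vector, dtype=float)
        self.block_sizes = [int(b) for b in self.block_sizes]
        rho = np.asarray(self.ld_rho, dtype=float)
        if rho.ndim == 0:
            rho = np.full(len(self.block_sizes), float(rho))
        self.ld_rho = rho
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if sum(self.block_sizes) != len(self.freq_vector):
            raise ValueError(
                f"block sizes sum to {sum(self.block_sizes)} but "
                f"freq_vector has {len(self.freq_vector)} entries"
            )
        if not np.all(np.isfinite(self.freq_vector)):
            raise ValueError("non-finite allele frequency")
        if np.any((self.freq_vector <= 0.0) | (self.freq_vector >= 1.0)):
            raise ValueError("allele frequencies must lie strictly inside (0, 1)")
        if len(self.ld_rho) != len(self.block_sizes):
            raise ValueError("need one ld_rho per block")
        if np.any((self.ld_rho < 0.0) | (self.ld_rho >= 1.0)):
            raise ValueError("ld_rho must lie in [0, 1)")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")

    @property
    def n_variants(self) -> int:
        return len(self.freq_vector)

    def positions(self) -> np.ndarray:
        return np.arange(1, self.n_variants + 1, dtype=int) * self.spacing_bp


@dataclass
class ArchitectureSpec:
    """Genetic architecture shared by the populations.

    ``rho_b`` is the cross-population correlation of causal effects; the
    scale on which that correlation (and effect equality at ``rho_b = 1``)
    holds is set by ``effect_scale_mode``:

    * ``"standardized"`` — effects are drawn per standardized genotype and
      converted to per-allele units with each population's own ``2p(1-p)``;
    * ``"per_allele"`` — the drawn effects are the per-allele effects
      themselves, identical across populations when ``rho_b = 1``.
    """

    causal_indices: np.ndarray
    rho_b: float = 1.0
    effect_scale_mode: str = "per_allele"

    def __post_init__(self) -> None:
        self.causal_indices = np.asarray(self.causal_indices, dtype=int)
        if len(np.unique(self.causal_indices)) != len(self.causal_indices):
            raise ValueError("causal indices must be unique")
        if np.any(self.causal_indices < 0):
            raise ValueError("causal indices must be non-negative")
        if not -1.0 <= self.rho_b <= 1.0:
            raise ValueError("rho_b must lie in [-1, 1]")
        if self.effect_scale_mode not in ("standardized", "per_allele"):
            raise ValueError(f"unknown effect_scale_mode {self.effect_scale_mode!r}")


@dataclass
class SyntheticDataset:
    """Bundle of everything one simulated study produces."""

    panels: dict[str, GenotypePanel]
    true_effects: dict[str, np.ndarray]
    phenotypes: dict[str, pd.DataFrame]
    sumstats: dict[str, SummaryStats]
    recomb_map: RecombinationMap | None = None
    ref_freqs: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _haplotypes(rng: np.random.Generator, n_hap: int, freqs: np.ndarray,
                block_sizes: list[int], rho: np.ndarray) -> np.ndarray:
    """Threshold a blockwise latent AR(1) Gaussian into 0/1 haplotypes."""
    z = rng.standard_normal((n_hap, len(freqs)))
    start = 0
    for b, size in enumerate(block_sizes):
        r = rho[b]
        if r > 0 and size > 1:
            scale = np.sqrt(1.0 - r * r)
            for j in range(start + 1, start + size):
                z[:, j] = r * z[:, j - 1] + scale * z[:, j]
        start += size
    return (z < stats.norm.ppf(freqs)).astype(np.int8)


def _variant_table(spec: PopulationSpec) -> pd.DataFrame:
    pos = spec.positions()
    return pd.DataFrame({
        "chrom": spec.chrom,
        "pos": pos,
        "id": [f"snp_{spec.chrom}_{p}" for p in pos],
        "a1": "A",
        "a2": "G",
        f"freq_{spec.label}": spec.freq_vector,
    })


def simulate_genotypes(spec: PopulationSpec, seed: int) -> GenotypePanel:
    """Draw a dosage panel for one population under the copula LD model.

    Dosages are in ``{0, 1, 2}``; the empirical allele frequency of each
    variant is binomially concentrated around ``spec.freq_vector`` and the
    within-block genotype correlation equals the thresholded-bivariate-
    normal value implied by ``ld_rho`` (cross-block correlation is zero by
    construction).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    hap = _haplotypes(rng, 2 * spec.n_samples, spec.freq_vector,
                      spec.block_sizes, spec.ld_rho)
    dosages = (hap[: spec.n_samples] + hap[spec.n_samples:]).astype(float)
    samples = pd.DataFrame({
        "sample_id": [f"{spec.label}_{i}" for i in range(spec.n_samples)],
        "population": spec.label,
    })
    return GenotypePanel(dosages=dosages, variants=_variant_table(spec), samples=samples)


def simulate_admixture_gradient(specA: PopulationSpec, specB: PopulationSpec,
                                n: int, seed: int) -> GenotypePanel:
    """Panel of ``n`` admixed individuals along a uniform ancestry gradient.

    Each individual draws an admixture fraction ``alpha ~ Uniform(0, 1)``;
    every LD block of each of their two haplotypes then independently
    comes from population A with probability ``alpha`` (else B), drawn
    from that population's copula — a coarse model of ancestry segments.
    The expected per-variant frequency for individual ``i`` is
    ``alpha_i * p_A + (1 - alpha_i) * p_B``, and LD interpolates between
    the two populations along the gradient.
    """
    if specA.n_variants != specB.n_variants or specA.block_sizes != specB.block_sizes:
        raise ValueError("population specs must share the variant list and block structure")
    rng = np.random.default_rng(seed)
    alpha = rng.uniform(size=n)
    block_cols = np.repeat(np.arange(len(specA.block_sizes)), specA.block_sizes)
    dosages = np.zeros((n, specA.n_variants), dtype=float)
    for _hap in range(2):
        from_a = rng.random((n, len(specA.block_sizes))) < alpha[:, None]
        hapA = _haplotypes(rng, n, specA.freq_vector, specA.block_sizes, specA.ld_rho)
        hapB = _haplotypes(rng, n, specB.freq_vector, specB.block_sizes, specB.ld_rho)
        dosages += np.where(from_a[:, block_cols], hapA, hapB)
    variants = _variant_table(specA)
    variants[f"freq_{specB.label}"] = specB.freq_vector
    samples = pd.DataFrame({
        "sample_id": [f"adm_{i}" for i in range(n)],
        "population": "admixed",
        "admixture": alpha,
    })
    return GenotypePanel(dosages=dosages, variants=variants, samples=samples)


# ---------------------------------------------------------------------------
# effects and phenotypes
# ---------------------------------------------------------------------------

def simulate_effects_and_phenotypes(
    panels: dict[str, GenotypePanel],
    arch: ArchitectureSpec,
    h2_per_pop: dict[str, float],
    prevalence_per_pop: dict[str, float] | None,
    seed: int,
) -> tuple[dict[str, np.ndarray], dict[str, pd.DataFrame]]:
    """Draw correlated causal effects and per-population phenotypes.

    Effects for the first population are N(0, 1) on the scale set by
    ``arch.effect_scale_mode``; every other population's effects have
    correlation ``rho_b`` with them.  Environmental noise is scaled per
    population so the realized genetic variance fraction equals that
    population's ``h2`` exactly in sample (the causal effects themselves
    are never rescaled, so effect equality under ``rho_b = 1`` is
    preserved).  Binary traits threshold the standardized liability at
    the ``1 - prevalence`` normal quantile.

    Returns per-population full-length per-allele effect vectors (zero at
    non-causal variants) and per-population phenotype frames with columns
    ``quantitative``, ``liability``, ``binary`` and ``genetic_value``.
    """
    labels = list(panels)
    first = panels[labels[0]]
    m = first.n_variants
    if np.any(arch.causal_indices >= m):
        raise ValueError("causal index out of range")
    for lab, h2 in h2_per_pop.items():
        if not 0.0 <= h2 <= 1.0:
            raise ValueError(f"h2 for {lab} must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    c = len(arch.causal_indices)
    base = rng.standard_normal(c)
    resid = rng.standard_normal((len(labels), c))

    true_effects: dict[str, np.ndarray] = {}
    phenotypes: dict[str, pd.DataFrame] = {}
    for i, lab in enumerate(labels):
        panel = panels[lab]
        if panel.n_variants != m:
            raise ValueError("all panels must share the variant list")
        if i == 0 or arch.rho_b == 1.0:
            b = base.copy()
        else:
            b = arch.rho_b * base + np.sqrt(1.0 - arch.rho_b ** 2) * resid[i]
        if arch.effect_scale_mode == "standardized":
            freq_col = f"freq_{lab}"
            if freq_col in panel.variants.columns:
                p = panel.variants[freq_col].to_numpy(dtype=float)[arch.causal_indices]
            else:
                p = panel.allele_frequency()[arch.causal_indices]
            beta_allele = b / np.sqrt(2.0 * p * (1.0 - p))
        else:
            beta_allele = b

        g = panel.dosages[:, arch.causal_indices] @ beta_allele
        var_g = float(np.var(g))
        h2 = float(h2_per_pop[lab])
        if h2 == 0.0:
            y = rng.standard_normal(panel.n_samples)
        elif var_g == 0.0:
            raise ValueError(f"degenerate genetic value in population {lab}")
        else:
            noise_sd = np.sqrt(var_g * (1.0 - h2) / h2)
            y = g + noise_sd * rng.standard_normal(panel.n_samples)

        liability = (y - y.mean()) / y.std()
        prev = (prevalence_per_pop or {}).get(lab, 0.1)
        if not 0.0 < prev < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        binary = (liability > stats.norm.ppf(1.0 - prev)).astype(int)

        full = np.zeros(m)
        full[arch.causal_indices] = beta_allele
        true_effects[lab] = full
        phenotypes[lab] = pd.DataFrame({
            "quantitative": y,
            "liability": liability,
            "binary": binary,
            "genetic_value": g,
        })
    return true_effects, phenotypes


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def simulate_sumstats(panel: GenotypePanel, phenotype: np.ndarray,
                      population: str = "", seed: int | None = None,
                      mode: str = "regression",
                      true_effects: np.ndarray | None = None) -> SummaryStats:
    """Marginal GWAS of ``phenotype`` on each variant of ``panel``.

    The default mode runs the actual per-variant simple regressions
    (vectorized), so the estimated effects carry the LD-induced tagging
    the relative-accuracy model's ``r`` terms rely on.  ``mode="analytic"``
    skips the cohort and adds Gaussian sampling noise with the asymptotic
    standard error to supplied true effects — fast, but blind to LD.
    Monomorphic variants are excluded with a logged count.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != panel.n_samples:
        raise ValueError("phenotype length must match panel sample count")
    n = panel.n_samples
    freqs = panel.allele_frequency()

    if mode == "regression":
        G = panel.dosages
        xm = G.mean(axis=0)
        ym = y.mean()
        sxx = np.einsum("ij,ij->j", G, G) - n * xm ** 2
        sxy = (y @ G) - n * xm * ym
        syy = float(np.sum((y - ym) ** 2))
        poly = sxx > 1e-12
        n_drop = int(np.sum(~poly))
        if n_drop:
            logger.info("excluded %d monomorphic variants from summary statistics", n_drop)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(poly, sxy / np.where(poly, sxx, 1.0), np.nan)
            sigma2 = np.maximum(syy - beta ** 2 * sxx, 0.0) / max(n - 2, 1)
            se = np.sqrt(np.where(poly, sigma2 / np.where(poly, sxx, 1.0), np.nan))
            tstat = beta / se
        pval = 2.0 * stats.t.sf(np.abs(tstat), df=max(n - 2, 1))
    elif mode == "analytic":
        if true_effects is None:
            raise ValueError("analytic mode requires true_effects")
        rng = np.random.default_rng(seed)
        pq = freqs * (1.0 - freqs)
        poly = pq > 0
        n_drop = int(np.sum(~poly))
        sigma_y = float(np.std(y))
        se = np.where(poly, sigma_y / np.sqrt(2.0 * pq * n), np.nan)
        beta = np.asarray(true_effects, dtype=float) + rng.standard_normal(panel.n_variants) * se
        pval = 2.0 * stats.norm.sf(np.abs(beta / se))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    table = pd.DataFrame({
        "CHR": panel.variants["chrom"].to_numpy(),
        "POS": panel.variants["pos"].to_numpy(),
        "ID": panel.variants["id"].to_numpy(),
        "A1": panel.variants["a1"].to_numpy(),
        "A2": panel.variants["a2"].to_numpy(),
        "BETA": beta,
        "SE": se,
        "P": pval,
        "AF": freqs,
        "N": n,
    })
    table = table[poly].reset_index(drop=True)
    return SummaryStats(table=table, population=population)


# ---------------------------------------------------------------------------
# recombination maps
# ---------------------------------------------------------------------------

def simulate_recomb_map(length_bp: int, hotspot_positions: list[int],
                        background_rate: float, hotspot_rate: float,
                        seed: int | None = None,
                        hotspot_halfwidth_bp: int = 1000,
                        jitter_sd: float = 0.0) -> RecombinationMap:
    """Piecewise-constant rate map: uniform background with rectangular
    hotspots of half-width ``hotspot_halfwidth_bp`` centered on the given
    positions.  With ``jitter_sd > 0`` the background rate of each segment
    is multiplied by a seeded lognormal factor for realism.  The cumulative
    map is the exact integral of the rate, hence piecewise linear."""
    if background_rate < 0 or hotspot_rate < 0:
        raise ValueError("rates must be non-negative")
    hotspots = list(hotspot_positions)
    if any(b < a for a, b in zip(hotspots, hotspots[1:])):
        raise ValueError("hotspot positions must be sorted")
    bounds = [1.0]
    for h in hotspots:
        bounds += [max(1.0, h - hotspot_halfwidth_bp), min(float(length_bp), h + hotspot_halfwidth_bp)]
    bounds.append(float(length_bp))
    bounds = sorted(set(bounds))
    pos = np.asarray(bounds)
    rate = np.full(len(pos), background_rate, dtype=float)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        rate *= np.exp(rng.normal(0.0, jitter_sd, size=len(pos)))
    for h in hotspots:
        inside = (pos >= h - hotspot_halfwidth_bp) & (pos < h + hotspot_halfwidth_bp)
        rate[inside] = hotspot_rate
    return RecombinationMap.from_rates(pos, rate)
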