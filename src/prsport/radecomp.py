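"""Decomposition of cross-population PRS relative accuracy into LD, MAF
and heritability components.

The expected relative accuracy of a score trained in population 1 and
applied in population 2 is approximated by

    RA = (rho_b^2 h2_pop2 / h2_pop1)
         * ( sum_k  mean_j[r_{kj,pop1} r_{kj,pop2}] * sqrt(p2 q2 / p1 q1)_k
             / sum_k mean_j[r_{kj,pop1}^2] )^2
         * sum_k p1 q1 beta_k^2 / sum_k p2 q2 beta_k^2

where k runs over the M PRS SNPs, j over each SNP's candidate causal
variants (any variant within 100 kb with r^2 > 0.45 in the screening
population; a SNP is always its own candidate), p are effect-allele
frequencies, q = 1 - p, and r are signed dosage correlations computed
against a shared allele orientation.  Constrained versions isolate the
factors: RA_LD+MAF fixes h2 equal and rho_b = 1; RA_LD keeps only the
tagging ratio; RA_MAF treats every PRS SNP as causal.  The share of the
observed loss a model explains is LOA = (1 - RA_model)/(1 - RA_obs) x 100%.

Standard errors come from a SNP-level bootstrap (resampling the M PRS
SNPs with replacement), with normal-approximation 95% CIs (+/- 1.96 SE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypePanel, PRSWeights

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateCausalSet",
    "RAInputs",
    "find_candidate_causals",
    "ra_full",
    "ra_maf",
    "ra_ld",
    "ra_ld_maf",
    "loa",
    "ra_se",
    "RelativeAccuracyModel",
    "RAReport",
]


# ---------------------------------------------------------------------------
# candidate causal variants
# ---------------------------------------------------------------------------

@dataclass
class CandidateCausalSet:
    """Per-PRS-SNP candidate causal variants and their LD summaries.

    ``mean_r2_pop1[k]`` is the mean of r^2 in population 1 between PRS SNP
    k and its candidates; ``mean_cross_r[k]`` the mean of the signed
    product r_pop1 * r_pop2 over the same candidates.
    """

    snp_keys: list[tuple]
    candidates: list[np.ndarray]
    mean_r2_pop1: np.ndarray
    mean_cross_r: np.ndarray

    def __len__(self) -> int:
        return len(self.snp_keys)


def find_candidate_causals(weights: PRSWeights, panel_pop1: GenotypePanel,
                           panel_pop2: GenotypePanel, window_kb: float = 100.0,
                           r2_min: float = 0.45) -> CandidateCausalSet:
    """Screen for candidate causal variants around each PRS SNP.

    Candidates are variants of the shared panel variant set within
    ``window_kb`` of the PRS SNP whose r^2 with it exceeds ``r2_min`` in
    population 1 (the discovery-side reference, whose LD determined what
    the GWAS could tag); the PRS SNP itself is always a candidate.  Both
    panels must carry identically ordered variants under a common allele
    orientation, so the signed product r_pop1 * r_pop2 is well defined.
    PRS SNPs absent from the panels are dropped with a logged count.
    """
    v1 = panel_pop1.variants
    v2 = panel_pop2.variants
    if len(v1) != len(v2) or not (
        (v1["chrom"].to_numpy() == v2["chrom"].to_numpy()).all()
        and (v1["pos"].to_numpy() == v2["pos"].to_numpy()).all()
    ):
        raise ValueError("panels must share an identically ordered variant list")
    keys = {k: j for j, k in enumerate(zip(v1["chrom"].astype(str), v1["pos"].astype(int)))}
    chroms = v1["chrom"].astype(str).to_numpy()
    positions = v1["pos"].to_numpy(dtype=float)
    window_bp = window_kb * 1000.0

    # work in position-sorted, column-contiguous (Fortran) order: each
    # window is then a contiguous slice and the per-SNP correlation a
    # single copy-free matvec
    order = np.lexsort((positions, chroms))
    chroms_s = chroms[order]
    pos_s = positions[order]
    sorted_of = np.empty(len(order), dtype=int)
    sorted_of[order] = np.arange(len(order))

    def _prep(panel):
        Gc = panel.dosages[:, order] - panel.dosages[:, order].mean(axis=0)
        Gc = np.asfortranarray(Gc)
        norm = np.sqrt(np.einsum("ij,ij->j", Gc, Gc))
        return Gc, norm

    Gc1, norm1 = _prep(panel_pop1)
    Gc2, norm2 = _prep(panel_pop2)

    # per-chromosome extents in the sorted order
    chrom_bounds = {}
    for c in pd.unique(chroms_s):
        left = np.searchsorted(chroms_s, c, side="left")
        right = np.searchsorted(chroms_s, c, side="right")
        chrom_bounds[c] = (left, right)

    def corr(Gc, norm, js, sl):
        den = norm[js] * norm[sl]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den > 0, (Gc[:, sl].T @ Gc[:, js]) / np.where(den > 0, den, 1.0), 0.0)

    snp_keys, cand_lists, m_r2, m_cross = [], [], [], []
    n_absent = 0
    for row in weights.table.itertuples(index=False):
        key = (str(row.CHR), int(row.POS))
        j = keys.get(key)
        if j is None:
            n_absent += 1
            continue
        js = int(sorted_of[j])
        cl, cr = chrom_bounds[key[0]]
        lo = cl + np.searchsorted(pos_s[cl:cr], key[1] - window_bp, side="left")
        hi = cl + np.searchsorted(pos_s[cl:cr], key[1] + window_bp, side="right")
        sl = slice(lo, hi)
        r1 = corr(Gc1, norm1, js, sl)
        local = np.arange(lo, hi)
        pass_mask = (r1 ** 2 > r2_min) & (local != js)
        pass_sorted = local[pass_mask]
        r1_pass = r1[pass_mask]
        cand = order[np.concatenate([[js], pass_sorted]).astype(int)]
        r1_all = np.concatenate([[1.0], r1_pass])
        if len(pass_sorted):
            r2_all = np.concatenate([[1.0], corr(Gc2, norm2, js, pass_sorted)])
        else:
            r2_all = np.array([1.0])
        snp_keys.append(key)
        cand_lists.append(cand)
        m_r2.append(float(np.mean(r1_all ** 2)))
        m_cross.append(float(np.mean(r1_all * r2_all)))
    if n_absent:
        logger.info("candidate screen: dropped %d PRS SNPs absent from panels", n_absent)
    return CandidateCausalSet(snp_keys, cand_lists,
                              np.asarray(m_r2), np.asarray(m_cross))


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

@dataclass
class RAInputs:
    """Everything the relative-accuracy equations consume, per PRS SNP."""

    beta: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    h2_pop1: float
    h2_pop2: float
    rho_b: float = 1.0
    mean_r2_pop1: np.ndarray | None = None
    mean_cross_r: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        m = len(self.beta)
        if m < 1:
            raise ValueError("need at least one PRS SNP")
        if len(self.p1) != m or len(self.p2) != m:
            raise ValueError("frequency vectors must match the number of SNPs")
        if np.any((self.p1 <= 0) | (self.p1 >= 1)) or np.any((self.p2 <= 0) | (self.p2 >= 1)):
            raise ValueError("frequencies must lie strictly inside (0, 1); "
                             "exclude monomorphic SNPs upstream")
        if self.h2_pop1 <= 0:
            raise ValueError("h2_pop1 must be positive")
        if self.mean_r2_pop1 is None:
            self.mean_r2_pop1 = np.ones(m)
        if self.mean_cross_r is None:
            self.mean_cross_r = np.ones(m)
        self.mean_r2_pop1 = np.asarray(self.mean_r2_pop1, dtype=float)
        self.mean_cross_r = np.asarray(self.mean_cross_r, dtype=float)

    @property
    def m(self) -> int:
        return len(self.beta)

    def subset(self, idx: np.ndarray) -> "RAInputs":
        return RAInputs(self.beta[idx], self.p1[idx], self.p2[idx],
                        self.h2_pop1, self.h2_pop2, self.rho_b,
                        self.mean_r2_pop1[idx], self.mean_cross_r[idx])

    @classmethod
    def from_data(cls, weights: PRSWeights, panel_pop1: GenotypePanel,
                  panel_pop2: GenotypePanel, h2_pop1: float, h2_pop2: float,
                  rho_b: float = 1.0, window_kb: float = 100.0,
                  r2_min: float = 0.45) -> "RAInputs":
        """Assemble inputs from weights and two LD reference panels:
        candidate screening plus empirical effect-allele frequencies.
        SNPs monomorphic in either panel are excluded with a logged count."""
        cset = find_candidate_causals(weights, panel_pop1, panel_pop2,
                                      window_kb=window_kb, r2_min=r2_min)
        keys = {k: j for j, k in enumerate(zip(
            panel_pop1.variants["chrom"].astype(str),
            panel_pop1.variants["pos"].astype(int)))}
        f1 = panel_pop1.allele_frequency()
        f2 = panel_pop2.allele_frequency()
        wmap = {(str(r.CHR), int(r.POS)): float(r.WEIGHT)
                for r in weights.table.itertuples(index=False)}
        beta, p1, p2, mr2, mcr = [], [], [], [], []
        n_mono = 0
        for i, key in enumerate(cset.snp_keys):
            j = keys[key]
            if not (0.0 < f1[j] < 1.0 and 0.0 < f2[j] < 1.0):
                n_mono += 1
                continue
            beta.append(wmap[key])
            p1.append(f1[j])
            p2.append(f2[j])
            mr2.append(cset.mean_r2_pop1[i])
            mcr.append(cset.mean_cross_r[i])
        if n_mono:
            logger.info("excluded %d PRS SNPs monomorphic in a reference panel", n_mono)
        return cls(np.asarray(beta), np.asarray(p1), np.asarray(p2),
                   h2_pop1, h2_pop2, rho_b, np.asarray(mr2), np.asarray(mcr))


# ---------------------------------------------------------------------------
# the RA equations
# ---------------------------------------------------------------------------

def _freq_ratio(inputs: RAInputs) -> np.ndarray:
    return np.sqrt(inputs.p2 * (1 - inputs.p2) / (inputs.p1 * (1 - inputs.p1)))


def _beta_variance_ratio(inputs: RAInputs) -> float:
    num = float(np.sum(inputs.p1 * (1 - inputs.p1) * inputs.beta ** 2))
    den = float(np.sum(inputs.p2 * (1 - inputs.p2) * inputs.beta ** 2))
    if num == 0.0 or den == 0.0:
        raise ValueError("zero variance sum; all weights zero?")
    return num / den


def ra_full(inputs: RAInputs) -> float:
    """Full model: heritability ratio x squared tagging ratio x
    beta-weighted variance ratio."""
    h_factor = inputs.rho_b ** 2 * inputs.h2_pop2 / inputs.h2_pop1
    return h_factor * ra_ld_maf(inputs)


def ra_ld_maf(inputs: RAInputs) -> float:
    """LD + MAF model: the full equation with h2_pop1 = h2_pop2 and
    rho_b = 1."""
    den = float(np.sum(inputs.mean_r2_pop1))
    if den == 0.0:
        raise ValueError("zero tagging denominator")
    num = float(np.sum(inputs.mean_cross_r * _freq_ratio(inputs)))
    return (num / den) ** 2 * _beta_variance_ratio(inputs)


def ra_ld(inputs: RAInputs) -> float:
    """LD-only model: the tagging ratio with every MAF term (and the h2
    ratio) held at 1."""
    den = float(np.sum(inputs.mean_r2_pop1))
    if den == 0.0:
        raise ValueError("zero tagging denominator")
    return (float(np.sum(inputs.mean_cross_r)) / den) ** 2


def ra_maf(inputs: RAInputs) -> float:
    """MAF-only model: every PRS SNP is taken as causal, removing the LD
    terms; the mean frequency-standard-deviation ratio squared times the
    beta-weighted variance ratio."""
    return (float(np.mean(_freq_ratio(inputs)))) ** 2 * _beta_variance_ratio(inputs)


def loa(ra_predicted: float, ra_obs: float) -> float:
    """Percentage of the observed accuracy loss a predicted RA explains:
    (1 - RA_pred) / (1 - RA_obs) x 100.  Undefined when RA_obs >= 1."""
    if ra_obs >= 1.0:
        raise ValueError("LOA undefined: no observed loss (RA_obs >= 1)")
    return (1.0 - ra_predicted) / (1.0 - ra_obs) * 100.0


_TERMS = {"ra_maf": ra_maf, "ra_ld": ra_ld, "ra_ld_maf": ra_ld_maf, "ra_full": ra_full}


def ra_se(inputs: RAInputs, n_boot: int = 1000, seed: int | None = None,
          method: str = "snp_bootstrap") -> dict[str, float]:
    """Standard error of each predicted RA term from a SNP-level bootstrap
    (resample the M PRS SNPs with replacement)."""
    if method != "snp_bootstrap":
        raise ValueError(f"unknown SE method {method!r}")
    if inputs.m < 10:
        logger.warning("only %d PRS SNPs: bootstrap SEs will be unstable", inputs.m)
    rng = np.random.default_rng(seed)
    draws = {name: np.empty(n_boot) for name in _TERMS}
    for b in range(n_boot):
        idx = rng.integers(0, inputs.m, size=inputs.m)
        sub = inputs.subset(idx)
        for name, fn in _TERMS.items():
            draws[name][b] = fn(sub)
    return {name: float(np.std(v, ddof=1)) for name, v in draws.items()}


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

@dataclass
class RAReport:
    """Fitted relative-accuracy decomposition.

    ``estimates`` maps each term to its point estimate, ``se`` to its
    bootstrap standard error; CIs are estimate +/- 1.96 SE.  When an
    observed RA below 1 is available, ``loa`` holds the percentage of the
    observed loss each model explains.
    """

    estimates: dict[str, float]
    se: dict[str, float]
    ra_obs: float | None = None
    loa: dict[str, float] = field(default_factory=dict)
    n_snps: int = 0

    def ci(self, term: str) -> tuple[float, float]:
        e, s = self.estimates[term], self.se.get(term, np.nan)
        return e - 1.96 * s, e + 1.96 * s

    def summary(self) -> pd.DataFrame:
        rows = []
        for term, est in self.estimates.items():
            lo, hi = self.ci(term)
            rows.append({
                "term": term, "RA": est, "SE": self.se.get(term, np.nan),
                "ci_low": lo, "ci_high": hi,
                "LOA_pct": self.loa.get(term, np.nan),
            })
        if self.ra_obs is not None:
            rows.insert(0, {"term": "ra_obs", "RA": self.ra_obs, "SE": np.nan,
                            "ci_low": np.nan, "ci_high": np.nan, "LOA_pct": np.nan})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {"n_snps": self.n_snps, "ra_obs": self.ra_obs}
        for term, est in self.estimates.items():
            lo, hi = self.ci(term)
            out[term] = {"estimate": est, "se": self.se.get(term, np.nan),
                         "ci_low": lo, "ci_high": hi,
                         "loa_pct": self.loa.get(term)}
        return out


class RelativeAccuracyModel:
    """Statsmodels-flavoured front end: construct from :class:`RAInputs`
    (or via :meth:`from_data`), then :meth:`fit` to obtain a
    :class:`RAReport`."""

    def __init__(self, inputs: RAInputs):
        self.inputs = inputs

    @classmethod
    def from_data(cls, weights: PRSWeights, panel_pop1: GenotypePanel,
                  panel_pop2: GenotypePanel, h2_pop1: float, h2_pop2: float,
                  rho_b: float = 1.0, window_kb: float = 100.0,
                  r2_min: float = 0.45) -> "RelativeAccuracyModel":
        return cls(RAInputs.from_data(weights, panel_pop1, panel_pop2,
                                      h2_pop1, h2_pop2, rho_b,
                                      window_kb=window_kb, r2_min=r2_min))

    def fit(self, ra_obs: float | None = None, n_boot: int = 1000,
            seed: int | None = None) -> RAReport:
        est = {name: fn(self.inputs) for name, fn in _TERMS.items()}
        se = ra_se(self.inputs, n_boot=n_boot, seed=seed) if n_boot else {}
        loa_d = {}
        if ra_obs is not None and ra_obs < 1.0:
            loa_d = {name: loa(v, ra_obs) for name, v in est.items()}
        return RAReport(estimates=est, se=se, ra_obs=ra_obs, loa=loa_d,
                        n_snps=self.inputs.m)
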