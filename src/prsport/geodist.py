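"""Continuous genetic distance between study individuals and a discovery
GWAS sample.

The coordinate system is built in three steps:

1. principal components of a reference panel (SVD of the standardized
   reference genotypes), onto which study individuals are projected with
   an online augmentation-decomposition-Procrustes (OADP) scheme that
   corrects the shrinkage bias of naive projection when variants far
   outnumber reference samples;
2. classical (Torgerson) multidimensional scaling of the Euclidean
   distance matrix between population allele-frequency vectors — this
   embeds populations for which only summary allele frequencies exist
   (the discovery GWAS) in a space of their own;
3. an orthogonal Procrustes fit (scale, rotation, translation; reflection
   allowed by default) mapping the MDS coordinates of the reference
   populations onto their PC centroids; the fitted transform carries the
   GWAS populations into PC space.

Genetic distance is then the Euclidean distance between an individual's
PC point and the mapped GWAS point across the first five dimensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .accuracy import AccuracyResult, incremental_r2, liability_r2
from .data import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "ReferencePCA",
    "project_pcs",
    "mds_from_freqs",
    "procrustes_fit",
    "apply_procrustes",
    "AncestrySpace",
    "build_ancestry_space",
    "map_gwas_points",
    "genetic_distance",
    "GDProfile",
    "binned_accuracy_profile",
]


# ---------------------------------------------------------------------------
# reference PCA and projection
# ---------------------------------------------------------------------------

class ReferencePCA:
    """PCA basis of a reference genotype panel.

    Columns are centered at ``2p`` and scaled by ``sqrt(2p(1-p))`` using
    the reference allele frequencies; monomorphic reference variants are
    excluded (logged).  Reference scores are ``U S`` from the SVD of the
    standardized matrix.
    """

    def __init__(self, reference: GenotypePanel, k: int = 5):
        p = reference.allele_frequency()
        keep = (p > 0) & (p < 1)
        n_mono = int((~keep).sum())
        if n_mono:
            logger.info("PCA: excluded %d monomorphic reference variants", n_mono)
        self.keep = keep
        self.center = 2.0 * p[keep]
        self.scale = np.sqrt(2.0 * p[keep] * (1.0 - p[keep]))
        X = (reference.dosages[:, keep] - self.center) / self.scale
        n = X.shape[0]
        if k > min(X.shape):
            raise ValueError(f"k={k} exceeds the rank bound {min(X.shape)}")
        self.k = k
        self.X = X
        self.gram = X @ X.T
        vals, vecs = np.linalg.eigh(self.gram)
        order = np.argsort(vals)[::-1][:k]
        self.eigvals = np.maximum(vals[order], 0.0)
        self.U = vecs[:, order]
        self.singvals = np.sqrt(self.eigvals)
        if np.any(self.singvals <= 0):
            raise ValueError("k exceeds the rank of the reference panel")
        self.scores = self.U * self.singvals  # n_ref x k
        self.V = X.T @ (self.U / self.singvals)  # loadings, m x k

    def standardize(self, panel: GenotypePanel) -> np.ndarray:
        Y = panel.dosages[:, self.keep]
        if np.isnan(Y).any():
            Y = np.where(np.isnan(Y), self.center, Y)
        return (Y - self.center) / self.scale

    def project_naive(self, panel: GenotypePanel) -> np.ndarray:
        """Direct projection onto the reference loadings; biased toward 0
        when variants far outnumber reference samples."""
        return self.standardize(panel) @ self.V

    def project_oadp(self, panel: GenotypePanel) -> np.ndarray:
        """Shrinkage-adjusted projection: for each study sample, the
        reference spectrum is augmented with that sample, re-decomposed
        (cheap, via the reference Gram matrix), and the augmented
        reference scores are Procrustes-mapped back onto the original
        reference scores; the study sample rides along."""
        from scipy.linalg import eigh as scipy_eigh

        Y = self.standardize(panel)
        n = self.gram.shape[0]
        out = np.empty((Y.shape[0], self.k))
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = self.gram
        for i in range(Y.shape[0]):
            y = Y[i]
            xy = self.X @ y
            A[:n, n] = xy
            A[n, :n] = xy
            A[n, n] = y @ y
            vals, vecs = scipy_eigh(A, subset_by_index=[n + 1 - self.k, n])
            order = np.argsort(vals)[::-1]
            sv = np.sqrt(np.maximum(vals[order], 0.0))
            Q = vecs[:, order] * sv  # (n+1) x k augmented scores
            s, R, t = procrustes_fit(Q[:n], self.scores)
            out[i] = s * (Q[n] @ R) + t
        return out


def project_pcs(study: GenotypePanel, reference: GenotypePanel, k: int = 5,
                method: str = "oadp") -> np.ndarray:
    """Project study individuals onto reference PCs (``method`` in
    {"oadp", "naive"}); returns an ``n_study x k`` coordinate array."""
    pca = ReferencePCA(reference, k=k)
    if method == "oadp":
        return pca.project_oadp(study)
    if method == "naive":
        return pca.project_naive(study)
    raise ValueError(f"unknown projection method {method!r}")


# ---------------------------------------------------------------------------
# classical MDS of allele-frequency rows
# ---------------------------------------------------------------------------

def mds_from_freqs(freq_table: pd.DataFrame | np.ndarray, k: int = 5) -> np.ndarray:
    """Classical (Torgerson) MDS of the pairwise Euclidean distances
    between population allele-frequency rows; returns the top-``k``
    coordinates.  When the configuration is exactly ``k``-dimensional the
    embedded pairwise distances reproduce the input distances."""
    F = np.asarray(freq_table, dtype=float)
    n = F.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} populations, got {n}")
    D2 = cdist(F, F, metric="sqeuclidean")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    lam = np.maximum(vals[order], 0.0)
    coords = vecs[:, order] * np.sqrt(lam)
    # deterministic sign: largest-magnitude loading of each axis positive
    for d in range(k):
        j = np.argmax(np.abs(coords[:, d]))
        if coords[j, d] < 0:
            coords[:, d] = -coords[:, d]
    return coords


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------

def procrustes_fit(source: np.ndarray, target: np.ndarray,
                   allow_reflection: bool = True) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity transform ``x -> s * x @ R + t`` mapping
    ``source`` onto ``target`` (closed-form orthogonal Procrustes).

    ``R`` is orthogonal; with ``allow_reflection=False`` it is constrained
    to a proper rotation (det +1).  Raises on a degenerate source
    configuration (all points identical).
    """
    X = np.asarray(source, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("source and target must have the same shape")
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xm, Y - ym
    normX2 = float(np.sum(Xc * Xc))
    if normX2 == 0.0:
        raise ValueError("degenerate source configuration")
    M = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(M)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        U[:, -1] *= -1
        S = S.copy()
        S[-1] *= -1
        R = U @ Vt
    s = float(np.sum(S)) / normX2
    t = ym - s * (xm @ R)
    return s, R, t


def apply_procrustes(points: np.ndarray, s: float, R: np.ndarray,
                     t: np.ndarray) -> np.ndarray:
    return s * (np.asarray(points, dtype=float) @ R) + t


# ---------------------------------------------------------------------------
# the joint ancestry space
# ---------------------------------------------------------------------------

@dataclass
class AncestrySpace:
    """Joint coordinate system for individuals (PCs) and populations
    (mapped MDS points)."""

    pc_coords: np.ndarray              # study individuals x k
    ref_centroids: pd.DataFrame        # reference population x k
    mds_coords: pd.DataFrame           # (reference + GWAS populations) x k
    scale: float = np.nan
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None
    mapped_gwas: pd.DataFrame | None = None
    fit_residual: float = np.nan

    @property
    def fitted(self) -> bool:
        return self.rotation is not None


def map_gwas_points(space: AncestrySpace,
                    allow_reflection: bool = True) -> pd.DataFrame:
    """Fit the Procrustes transform (reference MDS rows onto reference PC
    centroids) and apply it to every MDS row, including the GWAS
    populations.  Stores the transform and the reference-row residual on
    ``space`` and returns the mapped coordinates."""
    ref_pops = list(space.ref_centroids.index)
    missing = [p for p in ref_pops if p not in space.mds_coords.index]
    if missing:
        raise ValueError(f"MDS table lacks reference populations {missing}")
    src = space.mds_coords.loc[ref_pops].to_numpy()
    tgt = space.ref_centroids.to_numpy()
    s, R, t = procrustes_fit(src, tgt, allow_reflection=allow_reflection)
    mapped = apply_procrustes(space.mds_coords.to_numpy(), s, R, t)
    space.scale, space.rotation, space.translation = s, R, t
    space.fit_residual = float(np.sum((apply_procrustes(src, s, R, t) - tgt) ** 2))
    space.mapped_gwas = pd.DataFrame(mapped, index=space.mds_coords.index,
                                     columns=[f"PC{i + 1}" for i in range(mapped.shape[1])])
    return space.mapped_gwas


def build_ancestry_space(study: GenotypePanel, reference: GenotypePanel,
                         freq_table: pd.DataFrame, k: int = 5,
                         projection: str = "oadp",
                         allow_reflection: bool = True) -> AncestrySpace:
    """Assemble the full ancestry space.

    ``freq_table`` holds one allele-frequency row per population
    (reference populations and discovery-GWAS populations alike) over a
    shared harmonized variant set; reference populations are identified
    by the ``population`` column of ``reference.samples``.
    """
    pca = ReferencePCA(reference, k=k)
    pc_coords = (pca.project_oadp(study) if projection == "oadp"
                 else pca.project_naive(study))
    pops = reference.samples["population"].to_numpy()
    ref_pops = [p for p in pd.unique(pops) if p in freq_table.index]
    if len(ref_pops) < 2:
        raise ValueError("need at least two reference populations present in freq_table")
    centroids = pd.DataFrame(
        np.vstack([pca.scores[pops == p].mean(axis=0) for p in ref_pops]),
        index=ref_pops, columns=[f"PC{i + 1}" for i in range(k)])
    mds = pd.DataFrame(mds_from_freqs(freq_table.to_numpy(), k=k),
                       index=freq_table.index,
                       columns=[f"MDS{i + 1}" for i in range(k)])
    space = AncestrySpace(pc_coords=pc_coords, ref_centroids=centroids, mds_coords=mds)
    map_gwas_points(space, allow_reflection=allow_reflection)
    return space


def genetic_distance(pc_coords: np.ndarray, gwas_point: np.ndarray) -> np.ndarray:
    """Euclidean distance from each individual's PC point to the mapped
    GWAS point across the (first five) shared dimensions."""
    P = np.atleast_2d(np.asarray(pc_coords, dtype=float))
    g = np.asarray(gwas_point, dtype=float).reshape(-1)
    if P.shape[1] != g.shape[0]:
        raise ValueError(f"dimension mismatch: {P.shape[1]} vs {g.shape[0]}")
    return np.sqrt(np.sum((P - g) ** 2, axis=1))


# ---------------------------------------------------------------------------
# binned accuracy profiles
# ---------------------------------------------------------------------------

@dataclass
class GDProfile:
    """Accuracy of a score across equal-sized bins of genetic distance."""

    bin_mean_gd: np.ndarray
    results: list[AccuracyResult]
    bin_n: np.ndarray
    correlation: float
    p_value: float

    @property
    def r2(self) -> np.ndarray:
        return np.array([r.r2_incremental for r in self.results])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean_gd": self.bin_mean_gd,
            "r2_incremental": self.r2,
            "ci_low": [r.ci_low for r in self.results],
            "ci_high": [r.ci_high for r in self.results],
            "n": self.bin_n,
        })

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.bin_mean_gd, self.r2)
        b, a = np.polyfit(self.bin_mean_gd, self.r2, 1)
        xs = np.linspace(self.bin_mean_gd.min(), self.bin_mean_gd.max(), 50)
        ax.plot(xs, a + b * xs, color="C0")
        ax.set_xlabel("genetic distance (bin mean)")
        ax.set_ylabel("incremental $R^2$")
        ax.set_title(f"r = {self.correlation:.2f}, p = {self.p_value:.2g}")
        return ax


def binned_accuracy_profile(gd: np.ndarray, phenotype: np.ndarray, prs: np.ndarray,
                            covariates: np.ndarray | None = None, n_bins: int = 20,
                            binary: bool = False, prevalence: float | None = None,
                            n_boot: int = 0, seed: int | None = None) -> GDProfile:
    """Quantile-bin genetic distance into ``n_bins`` equal-sized bins
    (within one individual), evaluate the score's incremental R-squared in
    each bin, and correlate bin-mean distance with accuracy.

    The correlation and its p-value are computed on the bin-level points,
    matching how such profiles are summarized.  Bins whose phenotype is
    constant are excluded with a log message; if any bin is too small to
    fit the models at all the binning is rejected.
    """
    gd = np.asarray(gd, dtype=float)
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    order = np.argsort(gd, kind="stable")
    chunks = np.array_split(order, n_bins)
    min_needed = 3 + (0 if covariates is None else np.atleast_2d(covariates).shape[1])
    if min(len(c) for c in chunks) < min_needed:
        raise ValueError("bins too small to evaluate accuracy; reduce n_bins")
    means, results, ns = [], [], []
    n_skipped = 0
    for idx in chunks:
        y = np.asarray(phenotype)[idx]
        if np.min(y) == np.max(y):
            n_skipped += 1
            continue
        cov = None if covariates is None else np.asarray(covariates)[idx]
        if binary:
            res = liability_r2(y, prs[idx], cov, prevalence_K=prevalence,
                               n_boot=n_boot, seed=seed)
        else:
            res = incremental_r2(y, prs[idx], cov, n_boot=n_boot, seed=seed)
        means.append(float(gd[idx].mean()))
        results.append(res)
        ns.append(len(idx))
    if n_skipped:
        logger.info("profile: skipped %d bins with constant phenotype", n_skipped)
    if len(results) < 3:
        raise ValueError("fewer than 3 usable bins")
    means = np.asarray(means)
    r2 = np.array([r.r2_incremental for r in results])
    r, p = stats.pearsonr(means, r2)
    return GDProfile(means, results, np.asarray(ns), float(r), float(p))
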