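"""Clumping + thresholding polygenic score construction and scoring.

Clumping is the standard greedy procedure: repeatedly take the most
significant remaining variant passing the p-value threshold as an index
SNP and discard every remaining variant on the same chromosome within
the physical window whose dosage r-squared with it (in the LD reference
panel) exceeds the r2 threshold.  The default tuning grid — p in
{5e-5, 0.01, 0.5}, r2 in {0.1, 0.5}, window in {100, 250} kb — yields
twelve weight sets per discovery population and phenotype.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypePanel, PRSWeights, SummaryStats

logger = logging.getLogger(__name__)

__all__ = ["ClumpParams", "DEFAULT_GRID", "clump", "clump_grid", "score"]


@dataclass(frozen=True)
class ClumpParams:
    """Tuning tuple for one clumping run."""

    p_threshold: float
    r2_threshold: float
    window_kb: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must lie in (0, 1]")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must lie in [0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


#: the study's tuning grid: 3 p-value x 2 r2 x 2 window = 12 scores
DEFAULT_GRID = [
    ClumpParams(p, r2, w)
    for p, r2, w in itertools.product([5e-5, 0.01, 0.5], [0.1, 0.5], [100.0, 250.0])
]


def _dosage_r2(G: np.ndarray, i: int, idx: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage column i and columns idx."""
    x = G[:, i]
    Y = G[:, idx]
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    num = xc @ Yc
    den = np.sqrt((xc @ xc) * np.einsum("ij,ij->j", Yc, Yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return r ** 2


def clump(sumstats: SummaryStats, ld_panel: GenotypePanel,
          params: ClumpParams) -> PRSWeights:
    """Greedy LD clumping of ``sumstats`` against ``ld_panel``.

    ``sumstats`` must already be harmonized to ``ld_panel`` (only variants
    present in the panel are considered; absences are logged).  Ties on
    the p-value are broken toward the smaller (chrom, pos) so the output
    is invariant to input row order.  If nothing passes ``p_threshold``
    an empty weight set is returned with a warning.
    """
    st = sumstats.table
    panel_keys = {k: j for j, k in enumerate(zip(
        ld_panel.variants["chrom"].astype(str), ld_panel.variants["pos"].astype(int)))}
    rows = []
    n_absent = 0
    for irow, row in enumerate(st.itertuples(index=False)):
        key = (str(row.CHR), int(row.POS))
        j = panel_keys.get(key)
        if j is None:
            n_absent += 1
            continue
        rows.append((float(row.P), str(row.CHR), int(row.POS), irow, j))
    if n_absent:
        logger.info("clump: %d summary-statistic variants absent from LD panel", n_absent)

    # sort by (p, chrom, pos): deterministic greedy order
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    candidate = [r for r in rows if r[0] <= params.p_threshold]
    if not candidate:
        logger.warning("clump: no variant passes p <= %g; empty score", params.p_threshold)
        return _weights_from_rows(st, [], params, sumstats.population)

    window_bp = params.window_kb * 1000.0
    alive = {r[4]: r for r in rows}  # all matched variants can be clumped away
    selected: list[tuple] = []
    removed: set[int] = set()
    G = ld_panel.dosages
    chroms = ld_panel.variants["chrom"].astype(str).to_numpy()
    positions = ld_panel.variants["pos"].to_numpy(dtype=float)

    for r in candidate:
        p, chrom, pos, irow, j = r
        if j in removed:
            continue
        selected.append(r)
        removed.add(j)
        near = [jj for jj in alive
                if jj not in removed and chroms[jj] == chrom
                and abs(positions[jj] - pos) <= window_bp]
        if near:
            near = np.asarray(near, dtype=int)
            r2 = _dosage_r2(G, j, near)
            removed.update(int(jj) for jj, v in zip(near, r2) if v > params.r2_threshold)

    selected.sort(key=lambda r: (r[1], r[2]))
    return _weights_from_rows(st, [r[3] for r in selected], params, sumstats.population)


def _weights_from_rows(st: pd.DataFrame, irows: list[int], params: ClumpParams,
                       population: str) -> PRSWeights:
    sub = st.iloc[irows] if irows else st.iloc[:0]
    table = pd.DataFrame({
        "CHR": sub["CHR"].to_numpy(),
        "POS": sub["POS"].to_numpy(),
        "ID": sub["ID"].to_numpy(),
        "EFFECT_ALLELE": sub["A1"].to_numpy(),
        "WEIGHT": sub["BETA"].to_numpy(dtype=float) if len(sub) else np.array([]),
    })
    return PRSWeights(table=table, params=params, source_population=population)


def clump_grid(sumstats: SummaryStats, ld_panel: GenotypePanel,
               grid: list[ClumpParams] | None = None) -> dict[ClumpParams, PRSWeights]:
    """Run ``clump`` over the full tuning grid (default: the 12-score grid)."""
    grid = DEFAULT_GRID if grid is None else grid
    if not grid:
        raise ValueError("empty tuning grid")
    return {params: clump(sumstats, ld_panel, params) for params in grid}


def score(panel: GenotypePanel, weights: PRSWeights) -> np.ndarray:
    """Per-sample polygenic score: sum over weight variants of effect-allele
    dosage times weight.  Missing dosages are mean-imputed at ``2p`` from
    the scoring panel; weight variants absent from the panel are dropped
    with a logged count (all absent is an error)."""
    if len(weights) == 0:
        return np.zeros(panel.n_samples)
    panel_keys = {k: j for j, k in enumerate(zip(
        panel.variants["chrom"].astype(str), panel.variants["pos"].astype(int)))}
    cols, betas = [], []
    n_absent = 0
    for row in weights.table.itertuples(index=False):
        j = panel_keys.get((str(row.CHR), int(row.POS)))
        if j is None:
            n_absent += 1
            continue
        cols.append(j)
        betas.append(float(row.WEIGHT))
    if n_absent:
        logger.info("score: %d weight variants absent from panel", n_absent)
    if not cols:
        raise ValueError("no weight variant present in the scoring panel")
    G = panel.dosages[:, cols]
    if np.isnan(G).any():
        fill = np.nanmean(G, axis=0)  # = 2p of the scoring panel
        G = np.where(np.isnan(G), fill, G)
    return G @ np.asarray(betas)
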