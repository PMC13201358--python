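"""End-to-end orchestration of the transferability analysis.

``run_all`` drives a complete study from a single seeded configuration:
synthetic two-population inputs (a discovery cohort, target cohorts, LD
reference subsamples, an admixture gradient and a recombination map) →
the 12-score clumping grid → within-population score selection →
accuracy per population → relative-accuracy decomposition → genetic-
distance profile → recombination-quartile profile.  Every stage receives
its own child seed derived from the global seed by a fixed counter
scheme, so each stage — and the whole bundle — is reproducible bit for
bit from config + seed alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accuracy import AccuracyResult, incremental_r2, relative_accuracy_observed
from .data import GenotypePanel, PRSWeights
from .formats import write_freq_table, write_recomb_map, write_sumstats, write_weights
from .geodist import binned_accuracy_profile, build_ancestry_space, genetic_distance
from .prs import ClumpParams, clump_grid, score
from .radecomp import RelativeAccuracyModel
from .recomb import quartile_profile
from .synthio import (ArchitectureSpec, PopulationSpec, simulate_admixture_gradient,
                      simulate_effects_and_phenotypes, simulate_genotypes,
                      simulate_recomb_map, simulate_sumstats)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "stage_seed", "select_best_score", "prune_related", "run_all"]

_STAGES = ["freqs", "genotypes", "phenotypes", "ld_subsample", "admixture",
           "recomb_map", "bootstrap", "radecomp", "geodist"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed: global seed spawned through a
    fixed stage counter (stage order is part of the contract)."""
    idx = _STAGES.index(stage)
    child = np.random.SeedSequence(global_seed).spawn(len(_STAGES))[idx]
    return int(child.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Configuration of one synthetic study run."""

    outdir: str = "prsport_run"
    seed: int = 0
    # simulated cohort geometry
    n_variants: int = 400
    block_size: int = 4
    n_discovery: int = 8000
    n_target: int = 4000
    n_admixed: int = 1500
    n_reference: int = 300
    ld_ref_size: int = 10000          # cap on the LD reference subsample
    # population-genetic parameters
    fst: float = 0.1
    ld_rho_pop1: float = 0.8
    ld_rho_pop2: float = 0.3
    h2_pop1: float = 0.4
    h2_pop2: float = 0.4
    rho_b: float = 1.0
    prevalence: float = 0.25
    causal_fraction: float = 0.5
    # analysis parameters
    p_thresholds: list = field(default_factory=lambda: [5e-5, 0.01, 0.5])
    r2_thresholds: list = field(default_factory=lambda: [0.1, 0.5])
    windows_kb: list = field(default_factory=lambda: [100.0, 250.0])
    n_boot: int = 1000
    n_gd_bins: int = 20
    pca_dims: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def grid(self) -> list[ClumpParams]:
        g = [ClumpParams(p, r2, w) for p in self.p_thresholds
             for r2 in self.r2_thresholds for w in self.windows_kb]
        if not g:
            raise ValueError("empty tuning grid")
        return g

    def validate(self) -> None:
        self.grid()
        if self.n_variants % self.block_size:
            raise ValueError("n_variants must be a multiple of block_size")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")


def select_best_score(grid_results: dict[ClumpParams, tuple[PRSWeights, AccuracyResult]]
                      ) -> tuple[PRSWeights, AccuracyResult]:
    """Pick the grid entry maximizing incremental R2 in the tuning
    population; ties break toward the smaller p-threshold, then smaller
    r2 threshold."""
    usable = {p: (w, r) for p, (w, r) in grid_results.items()
              if np.isfinite(r.r2_incremental)}
    if not usable:
        raise ValueError("no usable grid result")
    best = max(usable, key=lambda p: (usable[p][1].r2_incremental,
                                      -p.p_threshold, -p.r2_threshold))
    return usable[best]


def prune_related(kinship: pd.DataFrame, threshold: float = 0.1,
                  seed: int | None = None) -> list:
    """Generic pairwise pruning: from each pair with kinship above the
    threshold, remove one member at random (unless one is already gone).
    ``kinship`` needs columns ``id1, id2, kinship``; returns removed ids."""
    rng = np.random.default_rng(seed)
    removed: set = set()
    for row in kinship.itertuples(index=False):
        if row.kinship <= threshold:
            continue
        if row.id1 in removed or row.id2 in removed:
            continue
        removed.add(row.id1 if rng.random() < 0.5 else row.id2)
    return sorted(removed, key=str)


def _balding_nichols(rng: np.random.Generator, p_anc: np.ndarray, fst: float) -> np.ndarray:
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    return np.clip(rng.beta(a, b), 0.01, 0.99)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; writes TSV/JSON outputs plus a run log
    under ``config.outdir`` and returns the report bundle as a dict."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": asdict(config), "version": __version__}

    # ----- population specs ------------------------------------------------
    rng = np.random.default_rng(stage_seed(config.seed, "freqs"))
    m = config.n_variants
    blocks = [config.block_size] * (m // config.block_size)
    p_anc = rng.uniform(0.1, 0.9, size=m)
    p1 = _balding_nichols(rng, p_anc, config.fst)
    p2 = _balding_nichols(rng, p_anc, config.fst)

    def spec(label, n, freq, rho):
        return PopulationSpec(label=label, n_samples=n, block_sizes=blocks,
                              freq_vector=freq, ld_rho=rho,
                              h2=config.h2_pop1, prevalence=config.prevalence)

    gseed = stage_seed(config.seed, "genotypes")
    discovery = simulate_genotypes(spec("pop1", config.n_discovery, p1,
                                        config.ld_rho_pop1), gseed)
    target1 = simulate_genotypes(spec("pop1", config.n_target, p1,
                                      config.ld_rho_pop1), gseed + 1)
    target2 = simulate_genotypes(spec("pop2", config.n_target, p2,
                                      config.ld_rho_pop2), gseed + 2)

    # LD references: subsamples of the targets, capped at ld_ref_size
    sub_rng = np.random.default_rng(stage_seed(config.seed, "ld_subsample"))
    def ld_ref(panel):
        if panel.n_samples <= config.ld_ref_size:
            return panel
        idx = sub_rng.choice(panel.n_samples, size=config.ld_ref_size, replace=False)
        return panel.subset_samples(idx)
    ld1, ld2 = ld_ref(target1), ld_ref(target2)

    # ----- architecture, phenotypes, GWAS ----------------------------------
    eff_rng = np.random.default_rng(stage_seed(config.seed, "phenotypes"))
    n_causal = max(1, int(round(config.causal_fraction * m)))
    causal = np.sort(eff_rng.choice(m, size=n_causal, replace=False))
    arch = ArchitectureSpec(causal_indices=causal, rho_b=config.rho_b)
    panels = {"discovery": discovery, "pop1": target1, "pop2": target2}
    h2 = {"discovery": config.h2_pop1, "pop1": config.h2_pop1, "pop2": config.h2_pop2}
    prev = {k: config.prevalence for k in panels}
    effects, phenos = simulate_effects_and_phenotypes(
        panels, arch, h2, prev, stage_seed(config.seed, "phenotypes"))
    sumstats = simulate_sumstats(discovery, phenos["discovery"]["quantitative"].to_numpy(),
                                 population="pop1")
    write_sumstats(sumstats, out / "sumstats_pop1.tsv")

    # ----- clumping grid and selection --------------------------------------
    grid_weights = clump_grid(sumstats, ld1, config.grid())
    bundle["n_grid_scores"] = len(grid_weights)
    grid_results = {}
    for params, w in grid_weights.items():
        if len(w) == 0:
            continue
        r = incremental_r2(phenos["pop1"]["quantitative"].to_numpy(),
                           score(target1, w))
        grid_results[params] = (w, r)
    best_weights, best_result = select_best_score(grid_results)
    write_weights(best_weights, out / "weights_best.tsv")
    bundle["best_params"] = {"p_threshold": best_weights.params.p_threshold,
                             "r2_threshold": best_weights.params.r2_threshold,
                             "window_kb": best_weights.params.window_kb}
    bundle["n_prs_snps"] = len(best_weights)

    # ----- accuracy per population ------------------------------------------
    bseed = stage_seed(config.seed, "bootstrap")
    acc = {}
    for lab, panel in (("pop1", target1), ("pop2", target2)):
        acc[lab] = incremental_r2(phenos[lab]["quantitative"].to_numpy(),
                                  score(panel, best_weights),
                                  n_boot=config.n_boot, seed=bseed)
    ra_obs = relative_accuracy_observed(acc["pop2"], acc["pop1"])
    bundle["accuracy"] = {lab: vars(a) for lab, a in acc.items()}
    bundle["ra_obs"] = ra_obs

    # ----- relative-accuracy decomposition -----------------------------------
    model = RelativeAccuracyModel.from_data(best_weights, ld1, ld2,
                                            config.h2_pop1, config.h2_pop2,
                                            rho_b=config.rho_b)
    report = model.fit(ra_obs=ra_obs, n_boot=config.n_boot,
                       seed=stage_seed(config.seed, "radecomp"))
    report.summary().to_csv(out / "ra_report.tsv", sep="\t", index=False)
    bundle["ra_report"] = report.to_dict()

    # ----- genetic distance ---------------------------------------------------
    # the reference panel mimics a multi-population catalogue: the two study
    # populations plus extra populations drawn from the same ancestral
    # frequencies, so the MDS configuration has enough rank for k dimensions
    adm_seed = stage_seed(config.seed, "admixture")
    ref_rng = np.random.default_rng(adm_seed + 10)
    specA = spec("pop1", config.n_reference, p1, config.ld_rho_pop1)
    specB = spec("pop2", config.n_reference, p2, config.ld_rho_pop2)
    ref_specs = {"pop1": specA, "pop2": specB}
    for extra in range(config.pca_dims):
        p_extra = _balding_nichols(ref_rng, p_anc, config.fst)
        ref_specs[f"ref{extra + 1}"] = spec(f"ref{extra + 1}", config.n_reference,
                                            p_extra, config.ld_rho_pop1)
    ref_panels = {lab: simulate_genotypes(s, adm_seed + 1 + i)
                  for i, (lab, s) in enumerate(ref_specs.items())}
    reference = GenotypePanel(
        dosages=np.vstack([pnl.dosages for pnl in ref_panels.values()]),
        variants=next(iter(ref_panels.values())).variants,
        samples=pd.concat([pnl.samples for pnl in ref_panels.values()],
                          ignore_index=True))
    admixed = simulate_admixture_gradient(specA, specB, config.n_admixed, adm_seed)
    freq_table = pd.DataFrame(
        [s.freq_vector for s in ref_specs.values()] + [p1],
        index=list(ref_specs) + ["gwas_pop1"],
        columns=reference.variants["id"])
    write_freq_table(freq_table, out / "ref_freqs.tsv")
    space = build_ancestry_space(admixed, reference, freq_table, k=config.pca_dims)
    gd = genetic_distance(space.pc_coords,
                          space.mapped_gwas.loc["gwas_pop1"].to_numpy())
    beta1 = effects["pop1"]
    g_adm = admixed.dosages @ beta1
    ph_rng = np.random.default_rng(adm_seed + 3)
    noise_sd = np.sqrt(np.var(g_adm) * (1 - config.h2_pop1) / max(config.h2_pop1, 1e-9))
    y_adm = g_adm + noise_sd * ph_rng.standard_normal(len(g_adm))
    profile = binned_accuracy_profile(gd, y_adm, score(admixed, best_weights),
                                      n_bins=config.n_gd_bins)
    profile.to_frame().to_csv(out / "gd_profile.tsv", sep="\t", index=False)
    bundle["gd_correlation"] = profile.correlation
    bundle["gd_p_value"] = profile.p_value

    # ----- recombination quartiles --------------------------------------------
    map_seed = stage_seed(config.seed, "recomb_map")
    length = int(target1.variants["pos"].max()) + 10000
    hotspots = list(range(length // 5, length, length // 5))
    rmap = simulate_recomb_map(length, hotspots, background_rate=1.0,
                               hotspot_rate=20.0, seed=map_seed, jitter_sd=0.3)
    write_recomb_map(rmap, out / "recomb_map.tsv")
    if len(best_weights) >= 8:
        prof = quartile_profile(best_weights, rmap, target2,
                                phenos["pop2"]["quantitative"].to_numpy(),
                                n_boot=config.n_boot, seed=bseed)
        prof.to_csv(out / "recomb_profile.tsv", sep="\t", index=False)
        bundle["recomb_profile"] = prof.to_dict(orient="records")

    with open(out / "run_log.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=float)
    logger.info("run complete: outputs in %s", out)
    return bundle
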