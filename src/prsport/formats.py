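"""Readers and writers for the external formats the pipeline touches.

All tables are plain TSV (gzip-transparent via pandas); genotypes can
additionally round-trip through VCF 4.2 with ``GT`` and ``DS`` fields
(read with :mod:`cyvcf2`).  Positions are 1-based everywhere.  The
``harmonize`` step aligns a summary-statistics table to a genotype
panel's allele orientation — the single place where effect signs and
frequencies may be flipped — so every downstream signed-LD computation
sees a consistent effect allele.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    SUMSTAT_COLUMNS,
    GenotypePanel,
    PRSWeights,
    RecombinationMap,
    SummaryStats,
    variant_index,
)

logger = logging.getLogger(__name__)

__all__ = [
    "write_vcf", "read_vcf",
    "write_dosage_tsv", "read_dosage_tsv", "read_genotypes",
    "write_sumstats", "read_sumstats",
    "write_recomb_map", "read_recomb_map",
    "write_weights", "read_weights",
    "write_freq_table", "read_freq_table",
    "harmonize",
]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _opener(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write hard-call genotypes as a VCF 4.2 with GT and DS fields.

    ``a1`` (the effect allele) is written as ALT, so the VCF dosage of the
    ALT allele equals the panel dosage rounded to a hard call.
    """
    with _opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples["sample_id"].astype(str)) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        D = panel.dosages
        for j, row in panel.variants.iterrows():
            calls = []
            for d in D[:, j]:
                if np.isnan(d):
                    calls.append("./.:.")
                else:
                    calls.append(f"{gt_codes[int(round(d))]}:{d:g}")
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['a2']}\t{row['a1']}"
                     f"\t.\tPASS\t.\tGT:DS\t" + "\t".join(calls) + "\n")


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a VCF into a panel; multi-allelic records are rejected with a
    logged count and duplicate (chrom, pos) keys keep the first record."""
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on junk input
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    rows, dosage_cols = [], []
    n_multi = n_dup = 0
    seen: set[tuple[str, int]] = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        key = (rec.CHROM, rec.POS)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        fmts = rec.FORMAT
        if "DS" in fmts:
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        else:
            gts = np.asarray(rec.genotype.array())[:, :2]
            ds = np.where((gts < 0).any(axis=1), np.nan, gts.clip(min=0).sum(axis=1)).astype(float)
        rows.append({"chrom": rec.CHROM, "pos": rec.POS, "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                     "a1": rec.ALT[0], "a2": rec.REF})
        dosage_cols.append(ds)
    if n_multi:
        logger.info("rejected %d multi-allelic records", n_multi)
    if n_dup:
        logger.info("dropped %d duplicate variant keys", n_dup)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    dosages = np.column_stack(dosage_cols)
    return GenotypePanel(dosages=dosages, variants=pd.DataFrame(rows),
                         samples=pd.DataFrame({"sample_id": sample_ids}))


def write_dosage_tsv(panel: GenotypePanel, path: str | Path) -> None:
    """TSV dosage matrix: variant metadata columns then one column per sample."""
    df = panel.variants[["chrom", "pos", "id", "a1", "a2"]].copy()
    dos = pd.DataFrame(panel.dosages.T, columns=panel.samples["sample_id"].astype(str))
    pd.concat([df.reset_index(drop=True), dos], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypePanel:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"cannot parse dosage TSV {path}: {exc}") from exc
    meta_cols = ["chrom", "pos", "id", "a1", "a2"]
    if df.empty or not set(meta_cols).issubset(df.columns):
        raise ValueError(f"{path} is not a dosage TSV (missing metadata columns)")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    dup = df.duplicated(subset=["chrom", "pos"], keep="first")
    if dup.any():
        logger.info("dropped %d duplicate variant keys", int(dup.sum()))
        df = df[~dup]
    df["chrom"] = df["chrom"].astype(str)
    return GenotypePanel(
        dosages=df[sample_cols].to_numpy(dtype=float).T,
        variants=df[meta_cols].reset_index(drop=True),
        samples=pd.DataFrame({"sample_id": sample_cols}),
    )


def read_genotypes(path: str | Path, format: str = "auto") -> GenotypePanel:
    """Dispatch on ``format`` in {vcf, dosage, auto} (auto by extension)."""
    name = str(path)
    if format == "auto":
        format = "vcf" if ".vcf" in name else "dosage"
    if format == "vcf":
        return read_vcf(path)
    if format == "dosage":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# flat tables
# ---------------------------------------------------------------------------

def write_sumstats(ss: SummaryStats, path: str | Path) -> None:
    ss.table[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path, population: str = "") -> SummaryStats:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"cannot parse summary statistics {path}: {exc}") from exc
    df["CHR"] = df["CHR"].astype(str)
    return SummaryStats(table=df, population=population)


def write_recomb_map(rmap: RecombinationMap, path: str | Path) -> None:
    """HapMap-style three columns: Position(bp), Rate(cM/Mb), Map(cM)."""
    pd.DataFrame({
        "Position(bp)": rmap.positions.astype(int),
        "Rate(cM/Mb)": rmap.rates,
        "Map(cM)": rmap.cumulative,
    }).to_csv(path, sep="\t", index=False)


def read_recomb_map(path: str | Path) -> RecombinationMap:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"cannot parse recombination map {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected three HapMap columns")
    return RecombinationMap(df.iloc[:, 0].to_numpy(dtype=float),
                            df.iloc[:, 1].to_numpy(dtype=float),
                            df.iloc[:, 2].to_numpy(dtype=float))


def write_weights(w: PRSWeights, path: str | Path) -> None:
    w.table[PRSWeights.REQUIRED].to_csv(path, sep="\t", index=False)


def read_weights(path: str | Path, params=None, source_population: str = "") -> PRSWeights:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"cannot parse weights {path}: {exc}") from exc
    df["CHR"] = df["CHR"].astype(str)
    return PRSWeights(table=df, params=params, source_population=source_population)


def write_freq_table(df: pd.DataFrame, path: str | Path) -> None:
    """Population x variant allele-frequency table (populations as rows)."""
    df.to_csv(path, sep="\t", index=True)


def read_freq_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def harmonize(sumstats: SummaryStats, panel: GenotypePanel) -> SummaryStats:
    """Align summary statistics to the panel's effect-allele orientation.

    Variants are matched on (chrom, pos).  Where the panel's a1/a2 are
    swapped relative to the summary statistics, BETA is negated and AF
    complemented; allele pairs that do not match either orientation are
    dropped, as are strand-ambiguous (A/T, C/G) variants.  Drop counts are
    logged.  Raises if no variants survive.  The operation is idempotent.
    """
    st = sumstats.table.copy()
    st_idx = variant_index(st, "CHR", "POS")
    panel_var = panel.variants.set_index(variant_index(panel.variants))
    panel_var = panel_var[~panel_var.index.duplicated()]
    common = st_idx.isin(panel_var.index)
    n_missing = int((~common).sum())
    st = st[common].copy()
    st_idx = st_idx[common]
    if st.empty:
        raise ValueError("no overlapping variants after harmonization")

    pa1 = panel_var.loc[st_idx, "a1"].to_numpy(dtype=object)
    pa2 = panel_var.loc[st_idx, "a2"].to_numpy(dtype=object)
    sa1 = st["A1"].to_numpy(dtype=object)
    sa2 = st["A2"].to_numpy(dtype=object)

    same = (sa1 == pa1) & (sa2 == pa2)
    swapped = (sa1 == pa2) & (sa2 == pa1)
    ambiguous = np.array([(str(x).upper(), str(y).upper()) in _AMBIGUOUS
                          for x, y in zip(sa1, sa2)])
    keep = (same | swapped) & ~ambiguous

    n_mismatch = int((~(same | swapped)).sum())
    n_ambig = int((ambiguous & (same | swapped)).sum())
    if n_missing or n_mismatch or n_ambig:
        logger.info("harmonize: %d absent from panel, %d allele-mismatched, "
                    "%d strand-ambiguous dropped", n_missing, n_mismatch, n_ambig)

    st.loc[swapped, "BETA"] = -st.loc[swapped, "BETA"]
    st.loc[swapped, "AF"] = 1.0 - st.loc[swapped, "AF"]
    st.loc[swapped, ["A1", "A2"]] = st.loc[swapped, ["A2", "A1"]].to_numpy()
    st = st[keep].reset_index(drop=True)
    if st.empty:
        raise ValueError("no overlapping variants after harmonization")
    return SummaryStats(table=st, population=sumstats.population)
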