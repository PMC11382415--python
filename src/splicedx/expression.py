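"""Gene-expression outlier detection, microdeletion scanning, assessability.

Outliers are called per gene x sample from robust z-scores of
log2(size-factor-normalized count + 1): center = median, scale = 1.4826 x
MAD (SD fallback when MAD is zero), two-sided normal p-values, and
Benjamini-Hochberg adjustment across all gene x sample tests. The output
schema (zscore, pvalue, padj, rank) mirrors OUTRIDER's results table so
OUTRIDER output can be imported interchangeably; the denoising autoencoder
itself is out of scope here — the robust z-score is the native detector.

A putative microdeletion is a maximal run of >= ``min_genes`` genomically
consecutive genes all under-expressed in the same sample. Gene-level
assessability for splicing analysis in whole blood is classified from
median TPM: >= 5 assessable by RNA-seq, >= 0.9 by RT-PCR, below that not
assessable in blood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # consistency factor: MAD of a normal = sigma / 1.4826


@dataclass
class ExpressionMatrix:
    """Gene x sample counts with gene coordinates and optional TPM companion.

    ``gene_info`` is indexed by gene id with columns chrom, start, end
    (1-based inclusive); gene length for FPKM-like normalization is
    end - start + 1 unless a ``length`` column is provided.
    """

    counts: pd.DataFrame
    gene_info: pd.DataFrame
    tpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_info.index):
            self.gene_info = self.gene_info.loc[self.counts.index]
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.tpm is not None and self.tpm.shape != self.counts.shape:
            raise ValueError("tpm shape does not match counts")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def gene_lengths(self) -> pd.Series:
        if "length" in self.gene_info.columns:
            return self.gene_info["length"]
        return self.gene_info["end"] - self.gene_info["start"] + 1

    @classmethod
    def from_tsv(cls, counts_path: str, tpm_path: str | None = None) -> "ExpressionMatrix":
        """Read a counts TSV: gene_id, chrom, start, end, then sample columns."""
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        info = df[["chrom", "start", "end"]]
        counts = df.drop(columns=["chrom", "start", "end"])
        tpm = None
        if tpm_path is not None:
            tdf = pd.read_csv(tpm_path, sep="\t", index_col=0)
            tpm = tdf.drop(columns=[c for c in ("chrom", "start", "end") if c in tdf])
            tpm = tpm.loc[counts.index, counts.columns]
        return cls(counts=counts, gene_info=info, tpm=tpm)


@dataclass
class OutlierCall:
    """One significant gene x sample expression outlier."""

    gene: str
    sample: str
    zscore: float
    pvalue: float
    padj: float
    rank: int
    direction: Literal["under", "over"]


@dataclass
class MicrodeletionSignal:
    """A run of consecutive under-expressed genes in one sample."""

    chrom: str
    start: int
    end: int
    sample: str
    genes: list[str]
    n_under: int
    score: float


def filter_low_expression(
    m: ExpressionMatrix, min_fpkm_like: float = 1.0
) -> ExpressionMatrix:
    """Drop genes whose FPKM-like value is below threshold in every sample.

    FPKM-like = count / (gene length in kb x library size in millions). A
    gene is retained if it clears the threshold in at least one sample.
    """
    lengths = m.gene_lengths()
    missing = lengths.isna() | (lengths <= 0)
    if missing.any():
        logger.warning("dropping %d genes with missing/invalid length", int(missing.sum()))
    libsize = m.counts.sum(axis=0) / 1e6
    fpkm = m.counts.div(lengths / 1e3, axis=0).div(libsize, axis=1)
    keep = (fpkm >= min_fpkm_like).any(axis=1) & ~missing
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_low_expression: removed %d / %d genes", dropped, len(keep))
    return ExpressionMatrix(
        counts=m.counts.loc[keep],
        gene_info=m.gene_info.loc[keep],
        tpm=m.tpm.loc[keep] if m.tpm is not None else None,
    )


def size_factors(m: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Falls back to total-count scaling (normalized to geometric mean 1) when
    no gene is nonzero in all samples.
    """
    if len(m.samples) < 2:
        raise ValueError("size factors need >= 2 samples")
    counts = m.counts.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        logger.warning("no gene nonzero in all samples; using total-count scaling")
        totals = counts.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(sf, index=m.samples)
    ref = counts[all_nonzero]
    log_geo_mean = np.mean(np.log(ref), axis=1, keepdims=True)
    sf = np.exp(np.median(np.log(ref) - log_geo_mean, axis=0))
    return pd.Series(sf, index=m.samples)


def _robust_z(log_expr: np.ndarray) -> np.ndarray | None:
    """Per-gene robust z-scores; None when the gene has zero spread."""
    med = np.median(log_expr)
    mad = np.median(np.abs(log_expr - med))
    scale = MAD_SCALE * mad
    if scale == 0:
        sd = np.std(log_expr, ddof=1)
        if sd == 0:
            return None
        scale = sd
    return (log_expr - med) / scale


def outlier_test_frame(m: ExpressionMatrix, sf: pd.Series | None = None) -> pd.DataFrame:
    """Long-format test table: one row per gene x sample.

    Columns: gene, sample, zscore, pvalue, padj, rank, direction, norm_expr.
    ``rank`` is the sample's position among the gene's normalized
    expressions, ascending (1 = lowest expression in the cohort).
    """
    if sf is None:
        sf = size_factors(m)
    norm = m.counts.div(sf, axis=1)
    log_expr = np.log2(norm.to_numpy(dtype=float) + 1.0)
    rows = []
    for gi, gene in enumerate(m.genes):
        z = _robust_z(log_expr[gi])
        if z is None:
            logger.info("gene %s has zero spread; skipped", gene)
            continue
        p = 2.0 * stats.norm.sf(np.abs(z))
        ranks = stats.rankdata(norm.iloc[gi].to_numpy(), method="min")
        for si, sample in enumerate(m.samples):
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "zscore": float(z[si]),
                    "pvalue": float(min(p[si], 1.0)),
                    "rank": int(ranks[si]),
                    "direction": "under" if z[si] < 0 else "over",
                    "norm_expr": float(norm.iloc[gi, si]),
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["padj"] = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")[1]
    else:
        df["padj"] = pd.Series(dtype=float)
    return df


def call_outliers(
    m: ExpressionMatrix, alpha: float = 0.05, sf: pd.Series | None = None
) -> list[OutlierCall]:
    """Significant expression outliers at BH FDR <= ``alpha``."""
    if len(m.samples) < 10:
        logger.warning(
            "outlier calling with %d samples; >= 10 recommended", len(m.samples)
        )
    df = outlier_test_frame(m, sf=sf)
    calls = [
        OutlierCall(
            gene=r.gene,
            sample=r.sample,
            zscore=r.zscore,
            pvalue=r.pvalue,
            padj=r.padj,
            rank=int(r.rank),
            direction=r.direction,
        )
        for r in df.itertuples()
        if r.padj <= alpha
    ]
    calls.sort(key=lambda c: (c.padj, c.gene, c.sample))
    return calls


def readjust_pvalues(test_frame: pd.DataFrame, genes: Iterable[str]) -> pd.DataFrame:
    """Recompute BH adjustment on a gene subset (e.g. disease-gene lists).

    Returns the subset of ``test_frame`` restricted to ``genes`` with a
    fresh ``padj`` column.
    """
    genes = set(genes)
    sub = test_frame[test_frame["gene"].isin(genes)].copy()
    if len(sub):
        sub["padj"] = multipletests(sub["pvalue"].to_numpy(), method="fdr_bh")[1]
    return sub


def scan_microdeletions(
    calls: Sequence[OutlierCall],
    gene_info: pd.DataFrame,
    min_genes: int = 3,
) -> list[MicrodeletionSignal]:
    """Maximal same-sample runs of consecutive under-expressed genes.

    Genes are ordered by (chrom, start) from ``gene_info``; a signal is a
    maximal run of >= ``min_genes`` consecutive genes each carrying an
    under-expression call for the same sample. Runs are maximal, hence
    non-overlapping per sample. Score = mean |z| over the run.
    """
    under: dict[str, dict[str, OutlierCall]] = {}
    for c in calls:
        if c.direction == "under":
            under.setdefault(c.sample, {})[c.gene] = c
    ordered = gene_info.sort_values(["chrom", "start"])
    signals: list[MicrodeletionSignal] = []
    for sample, gene_calls in sorted(under.items()):
        for chrom, sub in ordered.groupby("chrom", sort=True):
            run: list[str] = []

            def flush() -> None:
                if len(run) >= min_genes:
                    zs = [abs(gene_calls[g].zscore) for g in run]
                    signals.append(
                        MicrodeletionSignal(
                            chrom=str(chrom),
                            start=int(sub.loc[run[0], "start"]),
                            end=int(sub.loc[run[-1], "end"]),
                            sample=sample,
                            genes=list(run),
                            n_under=len(run),
                            score=float(np.mean(zs)),
                        )
                    )

            for gene in sub.index:
                if gene in gene_calls:
                    run.append(gene)
                else:
                    flush()
                    run = []
            flush()
    signals.sort(key=lambda s: (s.sample, s.chrom, s.start))
    return signals


def expressed_in_blood(tpm_row: Sequence[float], min_tpm: float = 1.0, min_samples: int = 4) -> bool:
    """True iff TPM > ``min_tpm`` in at least ``min_samples`` samples."""
    vals = np.asarray(tpm_row, dtype=float)
    if vals.size < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {vals.size}")
    return int((vals > min_tpm).sum()) >= min_samples


Assessability = Literal["rnaseq_assessable", "rtpcr_assessable", "not_assessable_in_blood"]


def assessability_class(median_tpm: float) -> Assessability:
    """Whole-blood splicing assessability from median TPM.

    >= 5 assessable by RNA-seq; >= 0.9 by RT-PCR; below 0.9 not assessable
    in blood (both boundaries inclusive).
    """
    if median_tpm < 0:
        raise ValueError("median TPM must be >= 0")
    if median_tpm >= 5.0:
        return "rnaseq_assessable"
    if median_tpm >= 0.9:
        return "rtpcr_assessable"
    return "not_assessable_in_blood"


def read_outrider_results(path: str) -> pd.DataFrame:
    """Adapter: read an OUTRIDER-style results TSV into the native schema.

    Expects columns geneID, sampleID, pValue, padjust, zScore and optionally
    rank/AberrantBySample; returns a frame with the native column names so
    downstream steps (microdeletion scan, subset re-adjustment) work
    unchanged.
    """
    df = pd.read_csv(path, sep="\t")
    colmap = {
        "geneID": "gene",
        "sampleID": "sample",
        "pValue": "pvalue",
        "padjust": "padj",
        "zScore": "zscore",
    }
    out = df.rename(columns=colmap)
    missing = {"gene", "sample", "pvalue", "padj", "zscore"} - set(out.columns)
    if missing:
        raise ValueError(f"OUTRIDER results missing columns: {sorted(missing)}")
    if "direction" not in out.columns:
        out["direction"] = np.where(out["zscore"] < 0, "under", "over")
    return out
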