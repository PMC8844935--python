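"""Differential-expression filtering and classification on FPKM matrices.

The workflow mirrors a deletion-mutant vs wild-type RNA-seq comparison with
three biological replicates per genotype: genes essentially unexpressed in
both genotypes (FPKM < 1 in at least two of three replicates) are excluded;
genes with |log2 fold change| >= 1 at adjusted p <= 0.05 are called up- or
downregulated; and genes with a consistent per-replicate trend that miss the
significance cutoff only through fold-change variability are rescued.

Real datasets should supply an external DE table (from a count-based model
such as DESeq2); the internal Welch-t test on log2(FPKM+1) exists so that
synthetic data can be processed end-to-end without external tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputFormatError

DE_STATUSES = ("up", "down", "unchanged", "filtered", "rescued_up", "rescued_down")


@dataclass
class ExpressionMatrix:
    """Per-gene FPKM values for two genotypes with paired replicates.

    ``wt`` and ``mut`` are gene x replicate frames sharing an index; columns
    are replicate labels in pairing order (replicate i of mut is paired with
    replicate i of wt for the consistency-rescue rule).
    """

    wt: pd.DataFrame
    mut: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.wt.index.equals(self.mut.index):
            raise ValueError("wt and mut must share a gene index")
        if self.wt.shape[1] != self.mut.shape[1]:
            raise ValueError("wt and mut must have the same replicate count")
        if (self.wt.values < 0).any() or (self.mut.values < 0).any():
            raise ValueError("FPKM values must be >= 0")

    @property
    def n_replicates(self) -> int:
        return self.wt.shape[1]

    @property
    def genes(self) -> pd.Index:
        return self.wt.index


def low_expression_filter(
    matrix: ExpressionMatrix, threshold: float = 1.0, min_reps: int = 2
) -> pd.Series:
    """True for genes too lowly expressed to analyse.

    A gene is filtered when FPKM < ``threshold`` in at least ``min_reps``
    replicates in the wild type AND in the mutant (low in one genotype only
    is kept — that is a real expression difference).
    """
    if matrix.n_replicates < min_reps:
        raise ValueError("min_reps exceeds the replicate count")
    low_wt = (matrix.wt < threshold).sum(axis=1) >= min_reps
    low_mut = (matrix.mut < threshold).sum(axis=1) >= min_reps
    out = low_wt & low_mut
    out.name = "filtered"
    return out


def fold_change(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> pd.Series:
    """log2((mean_mut + c) / (mean_wt + c)) per gene."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    lfc = np.log2(
        (matrix.mut.mean(axis=1) + pseudocount) / (matrix.wt.mean(axis=1) + pseudocount)
    )
    lfc.name = "log2fc"
    return lfc


def classify_de(
    records: pd.DataFrame,
    lfc_thresh: float = 1.0,
    padj_thresh: float = 0.05,
) -> pd.Series:
    """up / down / unchanged from (log2fc, padj); thresholds inclusive."""
    lfc = records["log2fc"].astype(float)
    padj = records["padj"].astype(float)
    if ((padj < 0) | (padj > 1)).any():
        raise ValueError("padj must lie in [0, 1]")
    status = pd.Series("unchanged", index=records.index, name="status")
    sig = padj <= padj_thresh
    status[sig & (lfc >= lfc_thresh)] = "up"
    status[sig & (lfc <= -lfc_thresh)] = "down"
    return status


def replicate_pair_ratios(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-replicate-pair log2 ratios, log2((mut_i + c)/(wt_i + c))."""
    return pd.DataFrame(
        np.log2((matrix.mut.values + pseudocount) / (matrix.wt.values + pseudocount)),
        index=matrix.genes,
        columns=[f"pair{i + 1}" for i in range(matrix.n_replicates)],
    )


def consistency_rescue(
    matrix: ExpressionMatrix,
    records: pd.DataFrame,
    lfc_thresh: float = 1.0,
    padj_thresh: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Rescue consistently-trending genes that missed the p-value cutoff.

    A gene with padj > ``padj_thresh`` becomes rescued_up / rescued_down if
    every per-replicate-pair log2 ratio has the same sign and the mean
    |log2 ratio| reaches ``lfc_thresh``.  Already significant genes are
    untouched.
    """
    status = records["status"].copy()
    ratios = replicate_pair_ratios(matrix, pseudocount).loc[records.index]
    candidates = records["padj"].astype(float) > padj_thresh
    all_pos = (ratios.values > 0).all(axis=1)
    all_neg = (ratios.values < 0).all(axis=1)
    strong = np.abs(ratios.values.mean(axis=1)) >= lfc_thresh
    status[candidates & pd.Series(all_pos & strong, index=records.index)] = "rescued_up"
    status[candidates & pd.Series(all_neg & strong, index=records.index)] = "rescued_down"
    return status


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def internal_de_test(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Welch t test on log2(FPKM + c) per gene, BH-adjusted.

    A simplified stand-in for a count-based DE model, intended for
    synthetic data.  Zero-variance degenerate genes resolve to p=1 (equal
    means) or p=0 (different means).
    """
    if matrix.n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    log_wt = np.log2(matrix.wt.values + pseudocount)
    log_mut = np.log2(matrix.mut.values + pseudocount)
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # zero-variance genes trip scipy's precision warning; they are
        # resolved deterministically below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(log_mut, log_wt, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(log_mut.mean(axis=1), log_wt.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return pd.DataFrame(
        {
            "log2fc": fold_change(matrix, pseudocount),
            "pvalue": p,
            "padj": bh_adjust(p),
        },
        index=matrix.genes,
    )


def de_table(
    matrix: ExpressionMatrix,
    external: pd.DataFrame | None = None,
    lfc_thresh: float = 1.0,
    padj_thresh: float = 0.05,
    fpkm_thresh: float = 1.0,
    min_reps: int = 2,
    pseudocount: float = 1.0,
    rescue: bool = True,
) -> pd.DataFrame:
    """Full DE record table: filter, classify, rescue.

    ``external`` (gene_id-indexed log2fc/padj, e.g. from DESeq2) overrides
    the internal test when provided.  The resulting ``status`` column
    partitions genes over {up, down, unchanged, filtered, rescued_up,
    rescued_down}.
    """
    if external is not None:
        records = external.reindex(matrix.genes)[["log2fc", "padj"]].copy()
        records["padj"] = records["padj"].fillna(1.0)
        records["log2fc"] = records["log2fc"].fillna(0.0)
        records["source"] = "external"
    else:
        records = internal_de_test(matrix, pseudocount)
        records["source"] = "internal"
    records["status"] = classify_de(records, lfc_thresh, padj_thresh)
    if rescue:
        records["status"] = consistency_rescue(
            matrix, records, lfc_thresh, padj_thresh, pseudocount
        )
    filtered = low_expression_filter(matrix, fpkm_thresh, min_reps)
    records.loc[filtered, "status"] = "filtered"
    records.index.name = "gene_id"
    return records


# ---------------------------------------------------------------------------
# I/O


def read_expression_tsv(expr_path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    """FPKM matrix (gene_id x sample TSV) plus a sample sheet.

    The sample sheet has columns sample, condition (wt/mut), replicate.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    for col in ("sample", "condition", "replicate"):
        if col not in sheet.columns:
            raise InputFormatError(f"{samples_path}: missing column {col!r}")
    bad = set(sheet["condition"]) - {"wt", "mut"}
    if bad:
        raise InputFormatError(f"{samples_path}: unknown condition(s) {sorted(bad)}")
    parts = {}
    for cond in ("wt", "mut"):
        sub = sheet[sheet["condition"] == cond].sort_values("replicate")
        missing = [s for s in sub["sample"] if s not in expr.columns]
        if missing:
            raise InputFormatError(f"{expr_path}: samples {missing} absent from matrix")
        block = expr[list(sub["sample"])].copy()
        block.columns = [f"rep{r}" for r in sub["replicate"]]
        parts[cond] = block
    return ExpressionMatrix(wt=parts["wt"], mut=parts["mut"])


def read_de_table(path: str | Path) -> pd.DataFrame:
    """External DE table TSV with columns gene_id, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2fc", "padj"):
        if col not in df.columns:
            raise InputFormatError(f"{path}: missing column {col!r}")
    return df.set_index("gene_id")
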