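"""Lightweight differential-expression stage for factorial stress designs.

Covers the steps between a raw count table and the per-condition contrast
tables consumed downstream: detection filtering (reads in >= k of the
replicates), median-of-ratios size factors, normalisation, a documented
stand-in DE test (Welch's t on log2 normalised counts — deliberately not
a negative-binomial GLM; externally computed DE tables, e.g. from DESeq2,
can be supplied instead through :mod:`costress.io_formats`),
Benjamini-Hochberg correction, and a log-PCA sample-similarity check.

Conditions are coded C (control), S (salt), H (hypoxia), HS (combined);
contrasts are always stress vs the control C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CONDITIONS",
    "DEConfig",
    "CountMatrix",
    "filter_min_detected",
    "median_of_ratios",
    "normalize",
    "bh_adjust",
    "naive_contrast",
    "log_pca",
]

CONDITIONS = ("C", "S", "H", "HS")

#: column order of contrast tables produced by :func:`naive_contrast`
CONTRAST_COLUMNS = [
    "gene_id",
    "base_mean",
    "log2fc",
    "pvalue",
    "padj",
    "is_sdeg",
    "is_high",
    "untestable",
]


@dataclass(frozen=True)
class DEConfig:
    """Thresholds of the DE stage.

    min_detected_reps / total_reps
        A gene is kept when some condition group has nonzero counts in at
        least ``min_detected_reps`` of its replicates (default 3 of 4).
    sdeg_alpha
        Adjusted-p cutoff for calling a significant DEG (default 0.01).
    high_lfc_threshold
        |log2FC| above which an sDEG is flagged highly regulated
        (default 2.0).
    pseudocount
        Added before every log2 (default 1.0).
    """

    min_detected_reps: int = 3
    total_reps: int = 4
    sdeg_alpha: float = 0.01
    high_lfc_threshold: float = 2.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (1 <= self.min_detected_reps <= self.total_reps):
            raise ValueError("need 1 <= min_detected_reps <= total_reps")
        if self.sdeg_alpha <= 0 or self.high_lfc_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


@dataclass
class CountMatrix:
    """Gene x sample integer counts with a sample sheet.

    ``counts``: DataFrame indexed by gene id, one column per sample.
    ``samples``: DataFrame indexed by sample id with columns
    ``condition`` (one of C/S/H/HS), ``tissue``, ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicated gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicated sample ids in count matrix")
        if not set(self.counts.columns) <= set(self.samples.index):
            missing = sorted(set(self.counts.columns) - set(self.samples.index))
            raise ValueError(f"samples missing from sample sheet: {missing}")
        for col in ("condition", "tissue", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks required column {col!r}")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition(s) {sorted(bad)}; expected {CONDITIONS}")
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be non-negative integers")

    @property
    def gene_ids(self) -> list:
        return list(self.counts.index)

    def condition_samples(self, condition: str) -> list:
        sheet = self.samples.loc[self.counts.columns]
        return list(sheet.index[sheet["condition"] == condition])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.samples)


def filter_min_detected(cm: CountMatrix, cfg: DEConfig | None = None, scope: str = "condition") -> CountMatrix:
    """Drop genes not detected in enough replicates.

    scope "condition" (default): keep a gene iff in at least one condition
    group it has nonzero counts in >= ``min_detected_reps`` replicates;
    this preserves genes expressed only under one stress.  scope "all"
    requires >= ``min_detected_reps`` nonzero samples over the whole
    matrix (stricter).  Gene order is preserved.
    """
    cfg = cfg or DEConfig()
    nonzero = cm.counts.to_numpy() > 0
    if scope == "all":
        keep = nonzero.sum(axis=1) >= cfg.min_detected_reps
    elif scope == "condition":
        keep = np.zeros(len(cm.counts), dtype=bool)
        for cond in CONDITIONS:
            cols = [cm.counts.columns.get_loc(s) for s in cm.condition_samples(cond)]
            if cols:
                keep |= nonzero[:, cols].sum(axis=1) >= cfg.min_detected_reps
    else:
        raise ValueError(f"scope must be 'condition' or 'all', got {scope!r}")
    if not keep.any():
        raise ValueError("detection filter removed every gene; check counts and min_detected_reps")
    return CountMatrix(cm.counts.loc[keep], cm.samples)


def median_of_ratios(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalisation).

    The reference profile is the per-gene geometric mean across samples,
    computed over genes with strictly positive counts in every sample;
    sample j's factor is the median over those genes of count_gj / ref_g.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    mat = counts.to_numpy(dtype=float)
    allpos = np.all(mat > 0, axis=1)
    if not allpos.any():
        raise ValueError(
            "median-of-ratios needs at least one gene with positive counts in every "
            "sample; consider a pseudocount-based fallback or stricter detection filtering"
        )
    pos = mat[allpos]
    ref = np.exp(np.mean(np.log(pos), axis=1))
    sf = np.median(pos / ref[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize(cm: CountMatrix, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor; returns reals."""
    sf = size_factors.reindex(cm.counts.columns)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    return cm.counts / sf


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def naive_contrast(
    cm: CountMatrix,
    condition: str,
    reference: str = "C",
    cfg: DEConfig | None = None,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Stand-in differential expression of one stress vs the control.

    log2FC is the log2 ratio of group means of normalised counts (plus
    pseudocount); the p-value is Welch's two-sample t-test on
    log2(normalised + pseudocount); padj is BH across genes.  Genes with
    zero counts in both groups get log2FC 0, p 1 and ``untestable``.

    This is an explicit simplification of an NB Wald test and applies no
    fold-change shrinkage; tables from dedicated DE tools are accepted
    downstream in its place.
    """
    cfg = cfg or DEConfig()
    for name, cond in (("condition", condition), ("reference", reference)):
        if len(cm.condition_samples(cond)) < 2:
            raise ValueError(f"{name} group {cond!r} needs at least 2 replicates")
    sf = median_of_ratios(cm) if size_factors is None else size_factors
    norm = normalize(cm, sf)
    a = norm[cm.condition_samples(condition)].to_numpy()
    b = norm[cm.condition_samples(reference)].to_numpy()

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2(mean_a + cfg.pseudocount) - np.log2(mean_b + cfg.pseudocount)
    la, lb = np.log2(a + cfg.pseudocount), np.log2(b + cfg.pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        pvalue = stats.ttest_ind(la, lb, axis=1, equal_var=False).pvalue
    untestable = (a.sum(axis=1) == 0) & (b.sum(axis=1) == 0)
    # constant rows (e.g. all zero in both groups) have no variance: call them null
    pvalue = np.where(np.isfinite(pvalue), pvalue, 1.0)
    pvalue[untestable] = 1.0
    log2fc[untestable] = 0.0
    padj = bh_adjust(pvalue)
    is_sdeg = padj < cfg.sdeg_alpha
    out = pd.DataFrame(
        {
            "gene_id": cm.counts.index.to_numpy(),
            "base_mean": (mean_a + mean_b) / 2.0,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "is_sdeg": is_sdeg,
            "is_high": is_sdeg & (np.abs(log2fc) > cfg.high_lfc_threshold),
            "untestable": untestable,
        },
        columns=CONTRAST_COLUMNS,
    )
    return out


def log_pca(
    cm: CountMatrix,
    size_factors: pd.Series | None = None,
    n_components: int = 2,
    pseudocount: float = 1.0,
):
    """PCA of log2(normalised counts + pseudocount), for sample QC.

    A simple stand-in for a regularised-log transform.  Returns a
    (scores, explained_variance_fractions) pair; scores are per-sample
    coordinates with a deterministic sign convention (the
    largest-magnitude loading of each component is positive).
    """
    n_samples = cm.counts.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > n_samples:
        raise ValueError(f"cannot extract {n_components} components from {n_samples} samples")
    sf = median_of_ratios(cm) if size_factors is None else size_factors
    x = np.log2(normalize(cm, sf).to_numpy().T + pseudocount)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    flip = np.sign(pca.components_[np.arange(n_components), np.argmax(np.abs(pca.components_), axis=1)])
    scores = scores * flip
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=cm.counts.columns, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )
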