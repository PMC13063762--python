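"""Functional-category (MapMan-BIN style) rank-sum enrichment.

For each hierarchical functional BIN, the log2 fold changes of its member
genes are compared against those of all other annotated genes with a
two-sided Wilcoxon rank-sum test (exact when the bin is small and there
are no ties, normal approximation with tie correction otherwise),
followed by Benjamini-Hochberg correction across the tested bins.  A BIN
is "enriched" when its members' expression changes shift away from the
background, in either direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de_lite import bh_adjust

__all__ = ["rollup", "bin_test"]

#: bins at most this large use the exact rank-sum null when tie-free
EXACT_MAX_N_IN = 25

RESULT_COLUMNS = [
    "bin_path",
    "n_in",
    "n_out",
    "statistic",
    "pvalue",
    "padj",
    "direction",
    "median_in",
    "median_out",
]


def rollup(annotation: pd.DataFrame, depth: int) -> pd.DataFrame:
    """Truncate every BIN path to at most ``depth`` dot-separated levels.

    Duplicate gene-bin pairs arising from collapsed leaves are dropped,
    so a gene annotated to two leaves of one subtree counts once at the
    coarser level.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    out = annotation.copy()
    out["bin_path"] = out["bin_path"].map(lambda p: ".".join(p.split(".")[:depth]))
    return out.drop_duplicates(subset=["gene_id", "bin_path"]).reset_index(drop=True)


def _rank_sum_p(inside: np.ndarray, outside: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (= rank-sum) statistic and p-value."""
    combined = np.concatenate([inside, outside])
    exact = len(inside) <= EXACT_MAX_N_IN and len(np.unique(combined)) == len(combined)
    res = stats.mannwhitneyu(
        inside,
        outside,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return float(res.statistic), float(res.pvalue)


def bin_test(
    log2fc: pd.Series,
    annotation: pd.DataFrame,
    min_bin_size: int = 5,
    level: int | None = None,
) -> pd.DataFrame:
    """Per-BIN rank-sum enrichment of log2 fold changes.

    ``log2fc`` is indexed by gene id; ``annotation`` is a long-format
    (gene_id, bin_path) table, possibly with several bins per gene.
    ``level`` truncates the hierarchy before testing (None = as given).
    The background of each bin is every *annotated* gene outside it;
    unannotated genes never enter the test.  Bins with fewer than
    ``min_bin_size`` members or fewer than ``min_bin_size`` background
    genes are skipped; if nothing is testable an error is raised.
    """
    if level is not None:
        annotation = rollup(annotation, level)
    ann = annotation[annotation["gene_id"].isin(log2fc.index)]
    annotated = pd.unique(ann["gene_id"])
    values = log2fc.loc[annotated]
    if values.isna().any():
        raise ValueError("log2fc contains missing values for annotated genes")

    rows = []
    for bin_path, group in ann.groupby("bin_path", sort=True):
        members = pd.unique(group["gene_id"])
        inside = values.loc[members].to_numpy(dtype=float)
        outside = values.drop(index=members).to_numpy(dtype=float)
        if len(inside) < min_bin_size or len(outside) < min_bin_size:
            continue
        stat, p = _rank_sum_p(inside, outside)
        med_in, med_out = float(np.median(inside)), float(np.median(outside))
        rows.append(
            {
                "bin_path": bin_path,
                "n_in": len(inside),
                "n_out": len(outside),
                "statistic": stat,
                "pvalue": p,
                "direction": int(np.sign(med_in - med_out)),
                "median_in": med_in,
                "median_out": med_out,
            }
        )
    if not rows:
        raise ValueError(
            f"no testable bin: every bin has < {min_bin_size} members or background genes"
        )
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out[RESULT_COLUMNS]
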