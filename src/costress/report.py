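"""Summary tables over interaction-classification results.

Mirrors the result structure of a combined-stress study: per gene
universe and tissue the counts and percentages of additive / enhanced /
divergent genes, a per-pathway (BIN-prefix) breakdown, a breakdown by
the sign combination of the single-stress responses, and a scatter-ready
export of observed vs expected log2FC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .interaction_core import LABELS, ClassificationResult

__all__ = ["class_summary", "pathway_summary", "sign_summary", "scatter_table", "plot_scatter"]


def _count_row(table: pd.DataFrame, **keys) -> dict:
    n = len(table)
    row = dict(keys)
    row["n_genes"] = n
    for lab in LABELS:
        c = int((table["label"] == lab).sum())
        row[f"{lab}_n"] = c
        row[f"{lab}_pct"] = 100.0 * c / n if n else np.nan
    return row


def class_summary(results: dict) -> pd.DataFrame:
    """Counts and percentages per (universe, tissue).

    ``results`` maps (universe_name, tissue) -> ClassificationResult.
    Percentages are exact in the returned frame; printing rounds to one
    decimal.
    """
    rows = [
        _count_row(res.table, universe=u, tissue=t, dropped=len(res.dropped))
        for (u, t), res in results.items()
    ]
    return pd.DataFrame(rows)


def pathway_summary(result: ClassificationResult, annotation: pd.DataFrame, depth: int = 1,
                    universe: str = "", tissue: str = "") -> pd.DataFrame:
    """Class breakdown per BIN prefix at the given hierarchy depth."""
    ann = annotation.copy()
    ann["pathway"] = ann["bin_path"].map(lambda p: ".".join(p.split(".")[:depth]))
    merged = result.table.merge(
        ann[["gene_id", "pathway"]].drop_duplicates(), on="gene_id", how="inner"
    )
    rows = [
        _count_row(grp, universe=universe, tissue=tissue, pathway=pw)
        for pw, grp in merged.groupby("pathway", sort=True)
    ]
    return pd.DataFrame(rows)


def sign_summary(result: ClassificationResult, universe: str = "", tissue: str = "") -> pd.DataFrame:
    """Class breakdown per single-stress sign combination."""
    rows = [
        _count_row(grp, universe=universe, tissue=tissue, sign_combination=sc)
        for sc, grp in result.table.groupby("sign_combination", sort=True)
    ]
    return pd.DataFrame(rows)


def scatter_table(result: ClassificationResult) -> pd.DataFrame:
    """Observed-vs-expected export for additive-deviation scatter plots.

    x: back-transformed log2FC of the additive expectation (the sum of
    the single-stress pEX values); y: observed combined-stress log2FC;
    one row per classified gene.
    """
    t = result.table
    return pd.DataFrame(
        {
            "gene_id": t["gene_id"],
            "log2fc_expected_sum": t["log2fc_sum_backtransformed"],
            "log2fc_hs_observed": t["log2fc_hs"],
            "deviation_pex": t["deviation"],
            "label": t["label"],
            "sign_combination": t["sign_combination"],
        }
    )


def plot_scatter(scatter: pd.DataFrame, ax=None, title: str = ""):
    """Observed-vs-expected scatter from an exported scatter table.

    Thin optional helper (needs matplotlib); grey = additive, orange =
    enhanced, violet = divergent, with the additive diagonal in red.
    Renders only from the exported table so figures are reproducible
    from files.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    colors = {"additive": "0.6", "enhanced": "tab:orange", "divergent": "tab:purple"}
    markers = {
        "both_negative": "o",
        "both_positive": "s",
        "H_neg_S_pos": "+",
        "H_pos_S_neg": "x",
        "contains_zero": ".",
    }
    for (label, sc), grp in scatter.groupby(["label", "sign_combination"]):
        ax.scatter(
            grp["log2fc_expected_sum"],
            grp["log2fc_hs_observed"],
            c=colors[label],
            marker=markers[sc],
            s=12,
            linewidths=0.8,
            label=None,
        )
    lim = max(scatter["log2fc_expected_sum"].abs().max(), scatter["log2fc_hs_observed"].abs().max())
    ax.plot([-lim, lim], [-lim, lim], color="tab:red", lw=1, zorder=0)
    ax.set_xlabel("log2FC of the summed single-stress response (H+S)")
    ax.set_ylabel("log2FC under combined stress (HS)")
    if title:
        ax.set_title(title)
    return ax
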