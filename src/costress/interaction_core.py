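"""Additive / enhanced / divergent classification of combined-stress responses.

The statistic compares the transcriptional response to a combined stress
(hypoxia + salt, "HS") with the sum of the two single-stress responses
("H" and "S") on a *percent expression change* (pEX) scale:

1.  log2 fold changes are converted to signed linear fold changes,
    ``FC = 2**log2FC`` for up-regulation and ``FC = -(2**|log2FC|)`` for
    down-regulation, so ``|FC| >= 1`` always and the sign encodes direction.
2.  pEX shifts FC so that "no change" is 0: ``pEX = FC - 1`` for positive
    FC and ``pEX = FC + 1`` for negative FC.  A doubling is +1.0 (+100 %),
    a halving is -1.0.
3.  The additive expectation for the combined stress is the plain sum
    ``pEX_H + pEX_S``.
4.  A gene is *additive* if its observed ``pEX_HS`` lies within a closed
    tolerance band (default +/- 0.5) around the expectation, *enhanced*
    if above the band, and *divergent* if below it.  The rule is
    directional: a jointly down-regulated gene whose combined response is
    even more strongly down-regulated is "divergent" (below the sum),
    not "enhanced".

For scatter plots of observed vs expected log2FC, the expectation is
back-transformed to the log2 scale by the exact inverse of steps 1-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClassifierConfig",
    "InteractionCall",
    "ClassificationResult",
    "signed_fold_change",
    "percent_change",
    "additive_expectation",
    "classify_interaction",
    "backtransform",
    "sign_combination",
    "classify_gene",
    "classify_table",
]

LABELS = ("additive", "enhanced", "divergent")

#: output column order of :func:`classify_table`
TABLE_COLUMNS = [
    "gene_id",
    "log2fc_h",
    "log2fc_s",
    "log2fc_hs",
    "pex_h",
    "pex_s",
    "pex_hs",
    "pex_sum",
    "deviation",
    "label",
    "sign_combination",
    "log2fc_sum_backtransformed",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Parameters of the interaction classifier.

    tolerance
        Half-width of the additive band in pEX units (equivalently in
        linear-FC units, since pEX is FC shifted by one).  Default 0.5.
    mode
        ``"directional"`` (default): enhanced = above the additive sum,
        divergent = below it, exactly as the band is printed.
        ``"magnitude"``: classify on |pEX| so that a stronger response in
        either direction counts as enhanced; provided for exploration,
        never used for the faithful output.
    """

    tolerance: float = 0.5
    mode: str = "directional"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tolerance) and self.tolerance > 0):
            raise ValueError(f"tolerance must be a positive finite number, got {self.tolerance!r}")
        if self.mode not in ("directional", "magnitude"):
            raise ValueError(f"mode must be 'directional' or 'magnitude', got {self.mode!r}")


def _as_finite_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite; got non-finite value(s)")
    return arr


def signed_fold_change(log2fc):
    """Convert log2 fold change(s) to signed linear fold change(s).

    ``2**x`` for ``x >= 0`` and ``-(2**|x|)`` for ``x < 0``; the result
    never falls in the open interval (-1, 1) and equals 1 iff x == 0.
    Accepts scalars or arrays; rejects non-finite input.
    """
    x = _as_finite_array(log2fc, "log2fc")
    fc = np.where(x >= 0, np.exp2(x), -np.exp2(np.abs(x)))
    return fc if fc.ndim else float(fc)


def percent_change(fc):
    """Convert signed fold change(s) to percent expression change (pEX).

    ``fc - 1`` for positive fc, ``fc + 1`` for negative fc, so FC = 2
    maps to +1.0 (+100 %) and FC = -2 to -1.0.  Inputs with |fc| < 1
    violate the signed-FC convention and are rejected.
    """
    arr = _as_finite_array(fc, "fc")
    if np.any(np.abs(arr) < 1):
        bad = np.asarray(arr)[np.abs(np.asarray(arr)) < 1]
        raise ValueError(
            f"signed fold changes must satisfy |fc| >= 1; got {np.atleast_1d(bad)[0]!r}"
        )
    pex = np.where(arr > 0, arr - 1.0, arr + 1.0)
    return pex if pex.ndim else float(pex)


def additive_expectation(pex_h, pex_s):
    """Additive expectation for the combined stress: ``pEX_H + pEX_S``."""
    h = _as_finite_array(pex_h, "pex_h")
    s = _as_finite_array(pex_s, "pex_s")
    out = h + s
    return out if out.ndim else float(out)


def classify_interaction(pex_hs, expectation, cfg: ClassifierConfig | None = None):
    """Label gene(s) additive / enhanced / divergent.

    additive iff ``pex_hs`` lies in the closed interval
    ``[expectation - tol, expectation + tol]``; enhanced strictly above;
    divergent strictly below.  Boundary ties go to additive (closed
    interval, no epsilon fuzz).
    """
    cfg = cfg or ClassifierConfig()
    obs = _as_finite_array(pex_hs, "pex_hs")
    exp = _as_finite_array(expectation, "expectation")
    if cfg.mode == "magnitude":
        obs, exp = np.abs(obs), np.abs(exp)
    dev = obs - exp
    labels = np.where(
        dev > cfg.tolerance, "enhanced", np.where(dev < -cfg.tolerance, "divergent", "additive")
    )
    return labels if labels.ndim else str(labels)


def backtransform(pex):
    """Invert pEX back to a log2 fold change.

    ``FC = pex + 1`` for ``pex >= 0`` else ``pex - 1``, then
    ``sign(FC) * log2|FC|``.  Exact inverse of
    ``percent_change(signed_fold_change(x))`` for every finite x.
    """
    p = _as_finite_array(pex, "pex")
    fc = np.where(p >= 0, p + 1.0, p - 1.0)
    out = np.sign(fc) * np.log2(np.abs(fc))
    return out if out.ndim else float(out)


def sign_combination(log2fc_h, log2fc_s):
    """Categorise the pair of single-stress directions.

    Returns one of ``both_negative``, ``both_positive``, ``H_neg_S_pos``,
    ``H_pos_S_neg``, ``contains_zero`` (the circle / square / + / x
    scatter-symbol categories; zero in either single stress gets its own
    category).  Vectorised.
    """
    h = _as_finite_array(log2fc_h, "log2fc_h")
    s = _as_finite_array(log2fc_s, "log2fc_s")
    out = np.full(np.broadcast(h, s).shape, "contains_zero", dtype=object)
    out[(h < 0) & (s < 0)] = "both_negative"
    out[(h > 0) & (s > 0)] = "both_positive"
    out[(h < 0) & (s > 0)] = "H_neg_S_pos"
    out[(h > 0) & (s < 0)] = "H_pos_S_neg"
    return out if out.ndim else str(out.item())


@dataclass(frozen=True)
class InteractionCall:
    """Full per-gene classification record."""

    gene_id: str
    log2fc_h: float
    log2fc_s: float
    log2fc_hs: float
    pex_h: float
    pex_s: float
    pex_hs: float
    pex_sum: float
    deviation: float
    label: str
    sign_combination: str
    log2fc_sum_backtransformed: float


def classify_gene(
    log2fc_h: float,
    log2fc_s: float,
    log2fc_hs: float,
    cfg: ClassifierConfig | None = None,
    gene_id: str = "",
) -> InteractionCall:
    """Classify a single gene from its three log2 fold changes.

    Scalar composition of the transform chain; the vectorised
    :func:`classify_table` must agree with it gene by gene.
    """
    cfg = cfg or ClassifierConfig()
    for name, v in (("log2fc_h", log2fc_h), ("log2fc_s", log2fc_s), ("log2fc_hs", log2fc_hs)):
        if v is None or not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    pex_h = percent_change(signed_fold_change(log2fc_h))
    pex_s = percent_change(signed_fold_change(log2fc_s))
    pex_hs = percent_change(signed_fold_change(log2fc_hs))
    expect = additive_expectation(pex_h, pex_s)
    label = classify_interaction(pex_hs, expect, cfg)
    return InteractionCall(
        gene_id=gene_id,
        log2fc_h=float(log2fc_h),
        log2fc_s=float(log2fc_s),
        log2fc_hs=float(log2fc_hs),
        pex_h=pex_h,
        pex_s=pex_s,
        pex_hs=pex_hs,
        pex_sum=expect,
        deviation=pex_hs - expect,
        label=label,
        sign_combination=sign_combination(log2fc_h, log2fc_s),
        log2fc_sum_backtransformed=backtransform(expect),
    )


@dataclass
class ClassificationResult:
    """Classification of a gene universe plus bookkeeping.

    ``table`` holds one row per classified gene (columns
    :data:`TABLE_COLUMNS`); ``dropped`` lists universe genes excluded
    because a log2FC was missing from one of the three contrasts.
    """

    table: pd.DataFrame
    dropped: list = field(default_factory=list)

    @property
    def counts(self) -> dict:
        vc = self.table["label"].value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in LABELS}

    @property
    def fractions(self) -> dict:
        n = len(self.table)
        return {lab: (c / n if n else float("nan")) for lab, c in self.counts.items()}


def _lfc_series(contrast: pd.DataFrame, which: str) -> pd.Series:
    if "gene_id" not in contrast.columns or "log2fc" not in contrast.columns:
        raise ValueError(f"contrast_{which} needs 'gene_id' and 'log2fc' columns")
    if contrast["gene_id"].duplicated().any():
        dup = contrast.loc[contrast["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicated gene id {dup!r} in contrast_{which}")
    return contrast.set_index("gene_id")["log2fc"].astype(float)


def classify_table(
    contrast_h: pd.DataFrame,
    contrast_s: pd.DataFrame,
    contrast_hs: pd.DataFrame,
    universe,
    cfg: ClassifierConfig | None = None,
) -> ClassificationResult:
    """Vectorised classification of every gene in ``universe``.

    Each contrast is a DataFrame with at least ``gene_id`` and ``log2fc``
    columns.  Universe genes absent from any contrast, or carrying a
    missing log2FC, are dropped (never imputed) and reported in
    ``ClassificationResult.dropped``.
    """
    cfg = cfg or ClassifierConfig()
    universe = list(universe)
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    if len(set(universe)) != len(universe):
        raise ValueError("duplicated gene ids in universe")

    lfc = pd.DataFrame(
        {
            "log2fc_h": _lfc_series(contrast_h, "h"),
            "log2fc_s": _lfc_series(contrast_s, "s"),
            "log2fc_hs": _lfc_series(contrast_hs, "hs"),
        }
    ).reindex(universe)
    keep = lfc.notna().all(axis=1) & np.isfinite(lfc).all(axis=1)
    dropped = list(lfc.index[~keep])
    lfc = lfc[keep]
    if lfc.empty:
        raise ValueError("no universe gene has a complete set of log2 fold changes")

    h = lfc["log2fc_h"].to_numpy()
    s = lfc["log2fc_s"].to_numpy()
    hs = lfc["log2fc_hs"].to_numpy()
    pex_h = percent_change(signed_fold_change(h))
    pex_s = percent_change(signed_fold_change(s))
    pex_hs = percent_change(signed_fold_change(hs))
    pex_sum = pex_h + pex_s
    table = pd.DataFrame(
        {
            "gene_id": lfc.index.to_numpy(),
            "log2fc_h": h,
            "log2fc_s": s,
            "log2fc_hs": hs,
            "pex_h": pex_h,
            "pex_s": pex_s,
            "pex_hs": pex_hs,
            "pex_sum": pex_sum,
            "deviation": pex_hs - pex_sum,
            "label": classify_interaction(pex_hs, pex_sum, cfg),
            "sign_combination": sign_combination(h, s),
            "log2fc_sum_backtransformed": backtransform(pex_sum),
        },
        columns=TABLE_COLUMNS,
    ).reset_index(drop=True)
    return ClassificationResult(table=table, dropped=dropped)
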