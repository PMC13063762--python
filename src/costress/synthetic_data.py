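"""Synthetic factorial stress experiment with planted interaction classes.

Emulates the design of a combined hypoxia-salt RNA-seq study: per tissue
(shoot and root), 4 conditions (C, S, H, HS) x 4 replicates of
negative-binomial gene counts over ~13,000 genes.  A configurable
fraction of genes responds to each single stress; every
single-stress-responsive gene carries a planted combined-stress class
(additive / enhanced / divergent) constructed directly on the pEX scale,
so the true label of every gene is known by construction and every
downstream stage can be checked for recovery without any download.

What the generator emulates: library-size variation, NB overdispersion,
a lognormal baseline-expression distribution, signed lognormal effect
sizes, and interaction classes at a safety margin from the class
boundaries.  What it does not emulate: gene-gene correlation, per-gene
dispersion trends, isoform structure, or batch effects — recovery on
these data therefore shows correctness of the pipeline's computations,
not robustness to every property of real libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de_lite import CountMatrix
from .interaction_core import backtransform, percent_change, signed_fold_change

__all__ = ["SimulationConfig", "generate_truth", "generate_counts", "simulate_experiment"]

TRUTH_COLUMNS = [
    "gene_id",
    "tissue",
    "log2fc_h",
    "log2fc_s",
    "log2fc_hs",
    "de_h",
    "de_s",
    "de_hs",
    "true_label",
    "bin_path",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Design of the simulated experiment.

    Defaults follow the factorial layout of the emulated study (4
    conditions x 4 replicates per tissue, two tissues, ~13,000 detected
    genes) with effect and noise levels typical of bulk plant RNA-seq:
    ~30 % of genes responding per single stress, signed effects with a
    lognormal magnitude of median 1.5 log2 units (sigma 0.5), NB
    dispersion 0.1, lognormal baseline with median 100 counts, and
    library-size factors drawn uniformly from 0.7-1.4.  Class fractions
    (0.82, 0.09, 0.09) among stress-responsive genes mirror the
    predominantly additive mixtures such experiments report.
    """

    n_genes: int = 13000
    replicates: int = 4
    tissues: tuple = ("shoot", "root")
    fraction_de: float = 0.30
    class_fractions: tuple = (0.82, 0.09, 0.09)
    effect_median_log2: float = 1.5
    effect_sigma_log2: float = 0.5
    tolerance: float = 0.5
    boundary_margin: float = 0.1
    offset_width: float = 2.0
    baseline_median: float = 100.0
    baseline_sigma: float = 1.0
    dispersion: float = 0.1
    libsize_range: tuple = (0.7, 1.4)
    n_bins: int = 50
    bin_depth: int = 2
    shared_truth: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.replicates < 1:
            raise ValueError("n_genes and replicates must be positive")
        if not 0 <= self.fraction_de <= 1:
            raise ValueError("fraction_de must lie in [0, 1]")
        cf = np.asarray(self.class_fractions, dtype=float)
        if cf.size != 3 or np.any(cf < 0) or abs(cf.sum() - 1.0) > 1e-9:
            raise ValueError("class_fractions must be 3 non-negative numbers summing to 1")
        if self.boundary_margin < 0:
            raise ValueError("boundary_margin must be >= 0")
        if self.boundary_margin >= self.tolerance:
            raise ValueError(
                "boundary_margin must be smaller than the tolerance or the additive band is empty"
            )
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def _draw_effects(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Signed single-stress log2FCs: random sign x lognormal magnitude."""
    sign = rng.choice([-1.0, 1.0], size=n)
    mag = rng.lognormal(mean=np.log(cfg.effect_median_log2), sigma=cfg.effect_sigma_log2, size=n)
    return sign * mag


def _plant_hs(
    rng: np.random.Generator,
    pex_sum: np.ndarray,
    labels: np.ndarray,
    cfg: SimulationConfig,
) -> np.ndarray:
    """pEX_HS = pEX_sum + delta, with delta drawn inside the label's band.

    additive: delta in [-tol + margin, tol - margin]; enhanced:
    [tol + margin, tol + margin + width]; divergent: the mirror image.
    The margin keeps planted genes away from the class boundaries so the
    label survives the float round trip exactly.
    """
    tol, m, w = cfg.tolerance, cfg.boundary_margin, cfg.offset_width
    delta = np.empty(len(pex_sum))
    add, enh, div = labels == "additive", labels == "enhanced", labels == "divergent"
    delta[add] = rng.uniform(-tol + m, tol - m, size=add.sum())
    delta[enh] = rng.uniform(tol + m, tol + m + w, size=enh.sum())
    delta[div] = rng.uniform(-tol - m - w, -tol - m, size=div.sum())
    return pex_sum + delta


def _truth_one_tissue(rng: np.random.Generator, tissue: str, cfg: SimulationConfig) -> pd.DataFrame:
    n = cfg.n_genes
    gene_ids = np.array([f"gene_{i:05d}" for i in range(n)])
    de_h = rng.random(n) < cfg.fraction_de
    de_s = rng.random(n) < cfg.fraction_de
    log2fc_h = np.where(de_h, _draw_effects(rng, n, cfg), 0.0)
    log2fc_s = np.where(de_s, _draw_effects(rng, n, cfg), 0.0)

    responsive = de_h | de_s
    labels = np.full(n, "additive", dtype=object)
    labels[responsive] = rng.choice(
        ["additive", "enhanced", "divergent"], size=responsive.sum(), p=cfg.class_fractions
    )
    pex_sum = percent_change(signed_fold_change(log2fc_h)) + percent_change(
        signed_fold_change(log2fc_s)
    )
    pex_hs = np.where(responsive, _plant_hs(rng, pex_sum, labels, cfg), 0.0)
    log2fc_hs = backtransform(pex_hs)

    bins = [
        f"bin{(i % cfg.n_bins) // 10}.bin{i % cfg.n_bins}" if cfg.bin_depth > 1 else f"bin{i % cfg.n_bins}"
        for i in range(n)
    ]
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "tissue": tissue,
            "log2fc_h": log2fc_h,
            "log2fc_s": log2fc_s,
            "log2fc_hs": log2fc_hs,
            "de_h": de_h,
            "de_s": de_s,
            "de_hs": responsive,
            "true_label": labels,
            "bin_path": bins,
        },
        columns=TRUTH_COLUMNS,
    )


def generate_truth(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Planted ground truth: per gene and tissue, the three true log2FCs,
    DE flags, interaction label, and a synthetic BIN path.

    Non-responsive genes have all log2FCs 0 and label "additive"
    (zero deviation).  With ``shared_truth`` the tissues reuse one draw.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    frames = []
    first = None
    for tissue in cfg.tissues:
        if cfg.shared_truth and first is not None:
            t = first.copy()
            t["tissue"] = tissue
        else:
            t = _truth_one_tissue(rng, tissue, cfg)
            if first is None:
                first = t
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with Var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape=shape, scale=np.maximum(mean, 1e-12) / shape)
    return rng.poisson(lam)


def generate_counts(
    truth: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, CountMatrix]:
    """NB count matrices per tissue from a planted truth table.

    Sample mean = baseline x 2^(true log2FC of the sample's condition)
    x library factor; condition C uses log2FC 0; one shared dispersion.
    Returns {tissue: CountMatrix} with complete sample sheets.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    out: dict[str, CountMatrix] = {}
    cond_lfc_col = {"C": None, "S": "log2fc_s", "H": "log2fc_h", "HS": "log2fc_hs"}
    for tissue in cfg.tissues:
        t = truth[truth["tissue"] == tissue].reset_index(drop=True)
        if t.empty:
            raise ValueError(f"truth table has no rows for tissue {tissue!r}")
        n = len(t)
        baseline = rng.lognormal(mean=np.log(cfg.baseline_median), sigma=cfg.baseline_sigma, size=n)
        counts = {}
        sheet = []
        for cond in ("C", "S", "H", "HS"):
            lfc = np.zeros(n) if cond_lfc_col[cond] is None else t[cond_lfc_col[cond]].to_numpy()
            mu_gene = baseline * np.exp2(lfc)
            for rep in range(1, cfg.replicates + 1):
                sample = f"{tissue}_{cond}_{rep}"
                lib = rng.uniform(*cfg.libsize_range)
                counts[sample] = _nb_counts(rng, mu_gene * lib, cfg.dispersion)
                sheet.append(
                    {"sample_id": sample, "condition": cond, "tissue": tissue, "replicate": rep}
                )
        cm = CountMatrix(
            counts=pd.DataFrame(counts, index=t["gene_id"].to_numpy()),
            samples=pd.DataFrame(sheet).set_index("sample_id"),
        )
        out[tissue] = cm
    return out


def simulate_experiment(cfg: SimulationConfig):
    """Convenience wrapper: one seeded run of truth + counts.

    Returns (truth, {tissue: CountMatrix}); fully deterministic in
    cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = generate_truth(cfg, rng)
    matrices = generate_counts(truth, cfg, rng)
    return truth, matrices
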