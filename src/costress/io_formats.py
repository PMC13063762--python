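"""Readers, writers and validation for every table the pipeline touches.

All files are UTF-8 tab-separated with a header row and the gene id in
the first column; missing values are empty fields.  DE tables exported
by DESeq2-style tools (columns ``log2FoldChange`` / ``pvalue`` /
``padj``) are auto-mapped to the internal column names.  Every
validation error names the offending file and rule (and line where it
is known).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .de_lite import CountMatrix, DEConfig
from .interaction_core import ClassifierConfig
from .set_analysis import GeneSet, UniverseSpec

__all__ = [
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_contrast",
    "write_contrast",
    "read_annotation",
    "write_annotation",
    "read_gene_list",
    "write_gene_list",
    "write_table",
    "RunConfig",
    "load_run_config",
]

#: DESeq2-convention column names accepted in external DE tables
DESEQ2_COLUMN_MAP = {
    "log2FoldChange": "log2fc",
    "baseMean": "base_mean",
    "pvalue": "pvalue",
    "padj": "padj",
}


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{path}: file not found")
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: failed to parse as TSV ({exc})") from exc


def _check_unique_genes(df: pd.DataFrame, path, col: str) -> None:
    dup = df[col].duplicated()
    if dup.any():
        # +2: header line plus 1-based numbering
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValueError(f"{path}: line {line}: duplicated gene id {df[col][dup].iloc[0]!r}")


def read_counts(path, sample_sheet_path=None) -> CountMatrix | pd.DataFrame:
    """Read a gene x sample count table (and sample sheet, if given).

    With ``sample_sheet_path`` a validated :class:`CountMatrix` is
    returned; otherwise the raw counts DataFrame indexed by gene id.
    Non-integer or negative counts are rejected.
    """
    df = _read_tsv(path)
    gene_col = df.columns[0]
    _check_unique_genes(df, path, gene_col)
    counts = df.set_index(gene_col)
    counts.index.name = "gene_id"
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError(f"{path}: non-numeric count value present")
    if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
        bad_row = int(np.argwhere((vals < 0) | (vals != np.round(vals)))[0][0])
        raise ValueError(f"{path}: line {bad_row + 2}: counts must be non-negative integers")
    counts = counts.astype(np.int64)
    if sample_sheet_path is None:
        return counts
    return CountMatrix(counts=counts, samples=read_sample_sheet(sample_sheet_path))


def write_counts(cm: CountMatrix | pd.DataFrame, path) -> None:
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = _read_tsv(path)
    need = {"sample_id", "condition", "tissue", "replicate"}
    missing = need - set(sheet.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet lacks column(s) {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample_id")
    return sheet.set_index("sample_id")


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample_id").to_csv(path, sep="\t")


def read_contrast(path, cfg: DEConfig | None = None) -> pd.DataFrame:
    """Read a per-gene DE table (internal or DESeq2 column convention).

    Requires gene id (first column), a log2 fold change and p-value
    columns.  When the sDEG / high-regulation flags are absent they are
    recomputed from ``cfg`` thresholds (default DEConfig).
    """
    df = _read_tsv(path)
    df = df.rename(columns=DESEQ2_COLUMN_MAP)
    gene_col = df.columns[0]
    if gene_col != "gene_id":
        df = df.rename(columns={gene_col: "gene_id"})
    _check_unique_genes(df, path, "gene_id")
    for col in ("log2fc", "pvalue", "padj"):
        if col not in df.columns:
            raise ValueError(f"{path}: DE table lacks required column {col!r}")
        df[col] = pd.to_numeric(df[col], errors="raise")
    bad_p = df["pvalue"].between(0, 1) | df["pvalue"].isna()
    if not bad_p.all():
        line = int(np.flatnonzero(~bad_p.to_numpy())[0]) + 2
        raise ValueError(f"{path}: line {line}: p-value outside [0, 1]")
    cfg = cfg or DEConfig()
    if "is_sdeg" not in df.columns:
        df["is_sdeg"] = df["padj"] < cfg.sdeg_alpha
    else:
        df["is_sdeg"] = df["is_sdeg"].astype(bool)
    if "is_high" not in df.columns:
        df["is_high"] = df["is_sdeg"] & (df["log2fc"].abs() > cfg.high_lfc_threshold)
    else:
        df["is_high"] = df["is_high"].astype(bool)
    return df


def write_contrast(contrast: pd.DataFrame, path) -> None:
    contrast.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    """Read a two-column gene -> BIN-path mapping (long format).

    Multiple rows per gene are allowed (a gene may live in several
    bins); exact duplicate pairs and empty paths are rejected.
    """
    df = _read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation needs two columns (gene_id, bin_path)")
    df = df.rename(columns={df.columns[0]: "gene_id", df.columns[1]: "bin_path"})
    empty = df["bin_path"].isna() | (df["bin_path"].str.strip() == "")
    if empty.any():
        line = int(np.flatnonzero(empty.to_numpy())[0]) + 2
        raise ValueError(f"{path}: line {line}: empty bin path")
    dup = df.duplicated(subset=["gene_id", "bin_path"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValueError(f"{path}: line {line}: duplicated gene-bin pair")
    return df[["gene_id", "bin_path"]]


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[["gene_id", "bin_path"]].to_csv(path, sep="\t", index=False)


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """One gene id per line; '#' starts a comment; blank lines ignored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{path}: file not found")
    members = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        entry = raw.split("#", 1)[0].strip()
        if entry:
            members.append(entry)
    return GeneSet(name=name or path.stem, members=frozenset(members), provenance=str(path))


def write_gene_list(gene_set: GeneSet, path) -> None:
    Path(path).write_text(
        "\n".join(sorted(gene_set.members)) + "\n", encoding="utf-8"
    )


def write_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Generic TSV export used for every derived result table."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


@dataclass
class RunConfig:
    """Parsed run configuration (flat YAML key hierarchy).

    Paths are resolved relative to the config file's directory.  Any
    CLI flag overrides its config key.
    """

    counts: dict = field(default_factory=dict)  # tissue -> path
    sample_sheet: str | None = None
    annotation: str | None = None
    gene_lists: dict = field(default_factory=dict)  # name -> path
    output_dir: str = "costress_out"
    de: DEConfig = field(default_factory=DEConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    universes: list = field(default_factory=lambda: [UniverseSpec(mode="all_hs_sdegs")])
    min_bin_size: int = 5
    bin_level: int | None = None
    seed: int = 0


def load_run_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{path}: config file not found")
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    base = path.parent

    def _resolve(p):
        return str((base / p).resolve()) if p else None

    counts = {t: _resolve(p) for t, p in raw.get("counts", {}).items()}
    gene_lists = {n: _resolve(p) for n, p in raw.get("gene_lists", {}).items()}
    universes = []
    for u in raw.get("universes", [{"mode": "all_hs_sdegs"}]):
        spec = UniverseSpec(
            mode=u["mode"],
            bin_prefix=u.get("bin_prefix"),
            gene_list=tuple(u["gene_list"]) if u.get("gene_list") else None,
            name=u.get("name"),
        )
        universes.append(spec)
    return RunConfig(
        counts=counts,
        sample_sheet=_resolve(raw.get("sample_sheet")),
        annotation=_resolve(raw.get("annotation")),
        gene_lists=gene_lists,
        output_dir=str((base / raw.get("output_dir", "costress_out"))),
        de=DEConfig(**raw.get("de", {})),
        classifier=ClassifierConfig(**raw.get("classifier", {})),
        universes=universes,
        min_bin_size=int(raw.get("min_bin_size", 5)),
        bin_level=raw.get("bin_level"),
        seed=int(raw.get("seed", 0)),
    )
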