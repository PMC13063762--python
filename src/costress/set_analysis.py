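"""Gene-set construction, three-way Venn partitioning, and universe selection.

Builds significant-DEG (sDEG) sets per condition, partitions the S / H /
HS sets into the seven disjoint Venn regions, and resolves the gene
universes over which the interaction classifier runs (all HS sDEGs,
highly regulated HS sDEGs, the uniquely-HS Venn region, a functional-BIN
subtree, or a user-curated list).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import pandas as pd

__all__ = [
    "GeneSet",
    "VennPartition",
    "UniverseSpec",
    "build_sdeg_set",
    "venn_partition",
    "select_universe",
]

UNIVERSE_MODES = ("all_hs_sdegs", "high_hs_sdegs", "unique_hs", "bin_subset", "curated_list")

REGIONS = (
    "S_only",
    "H_only",
    "HS_only",
    "S_H",
    "S_HS",
    "H_HS",
    "S_H_HS",
)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be nonempty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


def build_sdeg_set(
    contrast: pd.DataFrame,
    name: str,
    direction: str = "both",
    require_high: bool = False,
) -> GeneSet:
    """Extract the sDEG set from a flagged contrast table.

    direction "up"/"down" keeps only genes whose log2FC is positive /
    negative; ``require_high`` additionally demands the high-regulation
    flag (|log2FC| above the configured threshold).  An empty result is
    allowed but warned about.
    """
    if direction not in ("both", "up", "down"):
        raise ValueError(f"direction must be both/up/down, got {direction!r}")
    sel = contrast["is_sdeg"].astype(bool)
    if direction == "up":
        sel &= contrast["log2fc"] > 0
    elif direction == "down":
        sel &= contrast["log2fc"] < 0
    if require_high:
        sel &= contrast["is_high"].astype(bool)
    members = frozenset(contrast.loc[sel, "gene_id"])
    if not members:
        warnings.warn(f"gene set {name!r} is empty", stacklevel=2)
    prov = f"direction={direction}, require_high={require_high}"
    return GeneSet(name=name, members=members, provenance=prov)


@dataclass
class VennPartition:
    """The 7 disjoint regions of three gene sets (S, H, HS)."""

    regions: dict = field(default_factory=dict)
    set_names: tuple = ("S", "H", "HS")

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def counts(self) -> dict:
        return {r: len(self.regions[r]) for r in REGIONS}

    def fractions(self) -> dict:
        u = self.union_size
        return {r: (len(self.regions[r]) / u if u else 0.0) for r in REGIONS}

    def reconstruct(self, which: str) -> frozenset:
        """Rebuild one of the input sets from its four regions."""
        out: set = set()
        for region, members in self.regions.items():
            if which in region.split("_"):
                out |= members
        return frozenset(out)

    def to_frame(self, include_members: bool = False) -> pd.DataFrame:
        rows = []
        for region in REGIONS:
            row = {
                "region": region,
                "size": len(self.regions[region]),
                "fraction_of_union": self.fractions()[region],
            }
            if include_members:
                row["members"] = ",".join(sorted(self.regions[region]))
            rows.append(row)
        return pd.DataFrame(rows)


def venn_partition(set_s: GeneSet, set_h: GeneSet, set_hs: GeneSet) -> VennPartition:
    """Partition three sets into the 7 disjoint Venn regions."""
    s, h, hs = set_s.members, set_h.members, set_hs.members
    regions = {
        "S_only": s - h - hs,
        "H_only": h - s - hs,
        "HS_only": hs - s - h,
        "S_H": (s & h) - hs,
        "S_HS": (s & hs) - h,
        "H_HS": (h & hs) - s,
        "S_H_HS": s & h & hs,
    }
    return VennPartition(regions={k: frozenset(v) for k, v in regions.items()})


@dataclass(frozen=True)
class UniverseSpec:
    """Which gene universe to classify.

    mode
        all_hs_sdegs — every HS sDEG; high_hs_sdegs — HS sDEGs with the
        high-regulation flag; unique_hs — the HS-only Venn region;
        bin_subset — genes whose BIN path starts with ``bin_prefix``;
        curated_list — an explicit gene list intersected with the data.
    """

    mode: str
    bin_prefix: str | None = None
    gene_list: tuple | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in UNIVERSE_MODES:
            raise ValueError(f"unknown universe mode {self.mode!r}; expected one of {UNIVERSE_MODES}")
        if self.mode == "bin_subset" and not self.bin_prefix:
            raise ValueError("bin_subset mode requires bin_prefix")
        if self.mode == "curated_list" and not self.gene_list:
            raise ValueError("curated_list mode requires gene_list")
        if self.name is None:
            object.__setattr__(self, "name", self.mode)


def _bin_prefix_match(path: str, prefix: str) -> bool:
    parts, pre = path.split("."), prefix.split(".")
    return parts[: len(pre)] == pre


def select_universe(
    spec: UniverseSpec,
    contrast_hs: pd.DataFrame | None = None,
    partition: VennPartition | None = None,
    annotation: pd.DataFrame | None = None,
    available_genes=None,
) -> frozenset:
    """Resolve a UniverseSpec to a concrete gene-id set.

    ``annotation`` is a long-format (gene_id, bin_path) table;
    ``available_genes`` restricts curated lists to genes present in the
    data (absent genes are warned about, not an error).
    """
    if spec.mode in ("all_hs_sdegs", "high_hs_sdegs"):
        if contrast_hs is None:
            raise ValueError(f"mode {spec.mode} requires the HS contrast table")
        flag = "is_high" if spec.mode == "high_hs_sdegs" else "is_sdeg"
        return frozenset(contrast_hs.loc[contrast_hs[flag].astype(bool), "gene_id"])
    if spec.mode == "unique_hs":
        if partition is None:
            raise ValueError("mode unique_hs requires a Venn partition")
        return partition.regions["HS_only"]
    if spec.mode == "bin_subset":
        if annotation is None:
            raise ValueError("mode bin_subset requires a BIN annotation")
        hit = annotation["bin_path"].map(lambda p: _bin_prefix_match(p, spec.bin_prefix))
        members = frozenset(annotation.loc[hit, "gene_id"])
        if not members:
            raise ValueError(f"BIN prefix {spec.bin_prefix!r} matches no annotated gene")
        return members
    # curated_list
    wanted = frozenset(spec.gene_list)
    if available_genes is None:
        return wanted
    present = wanted & frozenset(available_genes)
    absent = wanted - present
    if absent:
        warnings.warn(
            f"{len(absent)} curated gene(s) absent from the data "
            f"(e.g. {sorted(absent)[:3]})",
            stacklevel=2,
        )
    if not present:
        raise ValueError(f"curated list {spec.name!r} shares no gene with the data")
    return present
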