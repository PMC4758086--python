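"""Site filters producing the analysis-ready SNP subsets.

Four rules, applied in a fixed order for reporting purposes (the surviving
set itself does not depend on the order):

a. drop sites where any pool's depth exceeds ``max_depth_per_pop``
   (excess-coverage guard against collapsed duplicated regions);
b. drop sites whose summed depth over all pools is below ``min_union_depth``;
c. drop sites with fewer than ``min_variant_reads_union`` alternate reads
   summed over pools;
d. drop sites not on a named autosome.

A separate, stricter subset (every pool at depth >= 30) feeds the Fst scan,
reducing the sampling bias of frequency estimates at thin sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import SnpCountTable

DEFAULT_AUTOSOMES = tuple(
    [str(i) for i in range(1, 30)] + [f"chr{i}" for i in range(1, 30)]
)

RULE_ORDER = ("max_depth", "union_depth", "variant_reads", "non_autosome")


@dataclass
class FilterConfig:
    max_depth_per_pop: int = 200
    min_union_depth: int = 60
    min_variant_reads_union: int = 10
    autosomes_only: bool = True
    autosome_names: tuple[str, ...] = DEFAULT_AUTOSOMES
    min_depth_per_pop_for_fst: int = 30
    #: apply the depth cap per pool ("per_pool") or to the union depth ("union")
    depth_cap_mode: str = "per_pool"

    def __post_init__(self):
        for name in (
            "max_depth_per_pop",
            "min_union_depth",
            "min_variant_reads_union",
            "min_depth_per_pop_for_fst",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_union_depth < self.min_variant_reads_union:
            raise ValueError("min_union_depth must be >= min_variant_reads_union")
        if self.depth_cap_mode not in ("per_pool", "union"):
            raise ValueError("depth_cap_mode must be 'per_pool' or 'union'")


@dataclass
class FilterReport:
    n_input: int
    n_output: int
    removed: dict = field(default_factory=dict)

    def __post_init__(self):
        assert self.n_input == self.n_output + sum(self.removed.values())


def apply_site_filters(
    table: SnpCountTable, cfg: FilterConfig | None = None
) -> tuple[SnpCountTable, FilterReport]:
    """Apply the four site filters; removals are attributed to the first
    failing rule in the order max_depth, union_depth, variant_reads,
    non_autosome."""
    cfg = cfg or FilterConfig()
    depth = table.depth().to_numpy()
    union_depth = depth.sum(axis=1)
    alt_union = sum(
        table.frame[f"{n}_alt"].to_numpy() for n in table.pop_names
    ) if table.pop_names else np.zeros(table.n_snps)

    if cfg.depth_cap_mode == "per_pool":
        fail_a = (depth > cfg.max_depth_per_pop).any(axis=1) if cfg.max_depth_per_pop else np.zeros(table.n_snps, bool)
    else:
        fail_a = union_depth > cfg.max_depth_per_pop if cfg.max_depth_per_pop else np.zeros(table.n_snps, bool)
    if cfg.max_depth_per_pop == 0:  # 0 disables the cap
        fail_a = np.zeros(table.n_snps, bool)
    fail_b = union_depth < cfg.min_union_depth
    fail_c = np.asarray(alt_union) < cfg.min_variant_reads_union
    if cfg.autosomes_only:
        fail_d = ~table.frame["chrom"].isin(cfg.autosome_names).to_numpy()
    else:
        fail_d = np.zeros(table.n_snps, bool)

    fails = [fail_a, fail_b, fail_c, fail_d]
    removed = {}
    already = np.zeros(table.n_snps, bool)
    for rule, mask in zip(RULE_ORDER, fails):
        new = mask & ~already
        removed[rule] = int(new.sum())
        already |= mask
    keep = ~already
    out = table.subset(keep)
    report = FilterReport(n_input=table.n_snps, n_output=out.n_snps, removed=removed)
    return out, report


def min_coverage_subset(table: SnpCountTable, min_depth: int = 30) -> SnpCountTable:
    """Keep sites where every population's depth is >= ``min_depth`` (inclusive)."""
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    keep = (table.depth().to_numpy() >= min_depth).all(axis=1)
    return table.subset(keep)
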