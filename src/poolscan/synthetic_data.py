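"""Synthetic pool-seq datasets with known ground truth.

The generator emulates the study design the analysis assumes: six pooled
populations (two highland, four lowland, pool sizes 60/68/45/58/39/60
diploids), biallelic exome SNPs whose ancestral frequencies follow a
truncated neutral site-frequency spectrum calibrated to a mean major-allele
frequency of 0.8619, independent Wright-Fisher drift per population
(Ne = 2749, t = 300 by default, expected Fst ~ 0.053), optional directional
selection on a configurable fraction of loci (favoring the alternate allele
in highland populations only), and a two-stage read-depth model spanning
roughly the 80-160x coverage band of exome pools.

Per locus the draw order is: ancestral frequency -> drift (with selection) ->
pool sampling of 2 x pool-size alleles -> per-pool depth -> alternate reads
binomial at the pool frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_io import PopulationMeta, SnpCountTable, validate_populations
from .highland_scan import ScanResult
from .neutral_null import drift_frequencies

#: the six-population study design (name, group, altitude in m, diploids pooled)
TABLE1_POPULATIONS: tuple[PopulationMeta, ...] = (
    PopulationMeta("BG", "highland", 4700, 60),
    PopulationMeta("RT", "highland", 4500, 68),
    PopulationMeta("CDM", "lowland", 3000, 45),
    PopulationMeta("NJ", "lowland", 1700, 58),
    PopulationMeta("IM", "lowland", 1500, 39),
    PopulationMeta("LN", "lowland", 30, 60),
)

BASES = np.array(list("ACGT"))


def neutral_sfs_sampler(min_freq: float = 0.015) -> Callable:
    """Sampler of ancestral alternate-allele frequencies with density
    proportional to 1/q on [min_freq, 0.5] (folded neutral spectrum with an
    ascertainment floor).  The default floor of 0.015 calibrates the mean
    minor-allele frequency to 0.1381, i.e. mean major-allele frequency
    0.8619."""
    if not 0 < min_freq < 0.5:
        raise ValueError("min_freq must be in (0, 0.5)")

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.random(n)
        return min_freq * (0.5 / min_freq) ** u  # inverse CDF of 1/q

    return sample


@dataclass
class SyntheticConfig:
    populations: tuple[PopulationMeta, ...] = TABLE1_POPULATIONS
    n_loci: int = 57948
    #: ancestral alternate-allele frequency: a float (fixed minor frequency,
    #: e.g. 1 - 0.8619), a callable (rng, n) -> frequencies, or None for the
    #: calibrated neutral-spectrum default
    p0_sampler: float | Callable | None = None
    Ne: int = 2749
    t: int = 300
    selected_fraction: float = 0.0
    #: per-generation selection coefficient favoring the alternate allele in
    #: highland populations only
    s_sel: float = 0.05
    depth_mean: float = 120.0
    #: gamma shape of the per-(pool, locus) depth factor; shape 30 gives a
    #: coverage c.v. of ~0.18, spanning roughly 80-160x at mean 120x
    depth_shape: float = 30.0
    #: pool-based SNP ascertainment: real tables only contain sites that were
    #: called as SNPs from these same pools, so loci whose generated reads
    #: carry fewer than this many alternate reads in the union of all pools
    #: are dropped (they would not have been detected).  1 drops only sites
    #: monomorphic in every pool; 0 keeps everything.  The returned table may
    #: therefore hold fewer than ``n_loci`` records.
    ascertainment_min_alt_reads: int = 10
    n_chromosomes: int = 29
    seed: int = 0

    def __post_init__(self):
        self.populations = validate_populations(self.populations)
        if not 0 <= self.selected_fraction <= 1:
            raise ValueError("selected_fraction must be in [0, 1]")
        if self.s_sel < 0:
            raise ValueError("s_sel must be >= 0")
        if self.depth_mean <= 0 or self.depth_shape <= 0:
            raise ValueError("depth model parameters must be positive")
        if self.ascertainment_min_alt_reads < 0:
            raise ValueError("ascertainment_min_alt_reads must be >= 0")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


@dataclass
class GroundTruth:
    """Per-locus truth aligned with the generated count table.

    ``frame`` columns: chrom, pos, selected, then per population
    ``<pop>_freq`` (post-drift population frequency) and ``<pop>_pool_freq``
    (frequency among the 2 x pool-size sampled alleles actually sequenced).
    """

    frame: pd.DataFrame
    populations: tuple[PopulationMeta, ...]

    @property
    def selected(self) -> np.ndarray:
        return self.frame["selected"].to_numpy(bool)


def _selection_update(q: np.ndarray, s: float) -> np.ndarray:
    """Deterministic one-generation update under genic selection with
    coefficient s favoring the alternate allele: q' = q(1+s) / (1 + q s)."""
    return q * (1 + s) / (1 + q * s)


def generate_dataset(cfg: SyntheticConfig) -> tuple[SnpCountTable, GroundTruth]:
    """Generate a pool-seq count table plus ground truth under ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    pops = cfg.populations
    n_pops, n = len(pops), cfg.n_loci
    highland = np.array([p.group == "highland" for p in pops])

    if cfg.p0_sampler is None:
        q0 = neutral_sfs_sampler()(rng, n)
    elif callable(cfg.p0_sampler):
        q0 = np.asarray(cfg.p0_sampler(rng, n), float)
    else:
        # fixed value: interpreted as a major-allele frequency when > 0.5
        v = float(cfg.p0_sampler)
        q0 = np.full(n, 1 - v if v > 0.5 else v)

    n_sel = int(round(cfg.selected_fraction * n))
    selected = np.zeros(n, bool)
    if n_sel:
        selected[rng.choice(n, size=n_sel, replace=False)] = True

    q = np.tile(q0, (n_pops, 1))
    two_ne = 2 * cfg.Ne
    sel_cols = np.where(selected)[0]
    if cfg.s_sel > 0 and n_sel and highland.any():
        hi_rows = np.where(highland)[0]
        for _ in range(cfg.t):
            block = q[np.ix_(hi_rows, sel_cols)]
            q[np.ix_(hi_rows, sel_cols)] = _selection_update(block, cfg.s_sel)
            q = rng.binomial(two_ne, q) / two_ne
    else:
        q = drift_frequencies(q, cfg.Ne, cfg.t, rng)

    pool_alleles = np.array([2 * p.pool_size_n for p in pops])[:, None]
    q_pool = rng.binomial(np.broadcast_to(pool_alleles, q.shape), q) / pool_alleles
    depth_factor = rng.gamma(cfg.depth_shape, 1.0 / cfg.depth_shape, size=q.shape)
    depth = rng.poisson(cfg.depth_mean * depth_factor)
    alt_reads = rng.binomial(depth, q_pool)
    ref_reads = depth - alt_reads

    chrom, pos = _coordinates(n, cfg.n_chromosomes)
    ref_base_idx = rng.integers(0, 4, size=n)
    alt_base_idx = (ref_base_idx + rng.integers(1, 4, size=n)) % 4

    frame = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": BASES[ref_base_idx],
            "alt": BASES[alt_base_idx],
        }
    )
    truth = pd.DataFrame({"chrom": chrom, "pos": pos, "selected": selected})
    for i, p in enumerate(pops):
        frame[f"{p.name}_ref"] = ref_reads[i]
        frame[f"{p.name}_alt"] = alt_reads[i]
        truth[f"{p.name}_freq"] = q[i]
        truth[f"{p.name}_pool_freq"] = q_pool[i]

    if cfg.ascertainment_min_alt_reads:
        seen = alt_reads.sum(axis=0) >= cfg.ascertainment_min_alt_reads
        frame, truth = frame[seen], truth[seen]

    order = np.lexsort((frame["pos"].to_numpy(), frame["chrom"].to_numpy()))
    frame = frame.iloc[order].reset_index(drop=True)
    truth = truth.iloc[order].reset_index(drop=True)
    return SnpCountTable(frame, pops), GroundTruth(truth, pops)


def _coordinates(n: int, n_chromosomes: int) -> tuple[np.ndarray, np.ndarray]:
    """Spread loci over autosomes named "1".."k", 1-based positions 100 apart."""
    per = math.ceil(n / n_chromosomes)
    chrom_idx = np.arange(n) // per
    within = np.arange(n) % per
    chrom = np.array([str(c + 1) for c in chrom_idx])
    pos = (within + 1) * 100
    return chrom, pos


def truth_frequency_table(truth: GroundTruth, which: str = "pool_freq"):
    """Ground truth as a FrequencyTable (for concordance checks).

    ``which``: "pool_freq" (frequency among the sequenced pool's sampled
    alleles — the analogue of genotyping the pooled animals individually)
    or "freq" (post-drift population frequency).
    """
    from .diversity import FrequencyTable

    if which not in ("pool_freq", "freq"):
        raise ValueError("which must be 'pool_freq' or 'freq'")
    out = truth.frame[["chrom", "pos"]].copy()
    for p in truth.populations:
        out[f"{p.name}_freq"] = truth.frame[f"{p.name}_{which}"]
        out[f"{p.name}_depth"] = 2 * p.pool_size_n
    return FrequencyTable(out, truth.populations)


@dataclass
class ScanEvaluation:
    power: float
    false_positive_rate: float
    n_selected: int
    n_neutral: int
    n_flagged: int


def evaluate_scan(truth: GroundTruth, result: ScanResult) -> ScanEvaluation:
    """Power and false-positive rate of the combined ('common') outlier flag
    against the planted selection labels."""
    tkeys = truth.frame[["chrom", "pos"]].reset_index(drop=True)
    rkeys = result.frame[["chrom", "pos"]].reset_index(drop=True)
    if not tkeys.equals(rkeys):
        raise ValueError("truth and scan result are not aligned on (chrom, pos)")
    sel = truth.selected
    common = result.frame["common"].to_numpy(bool)
    n_sel, n_neu = int(sel.sum()), int((~sel).sum())
    power = float(common[sel].mean()) if n_sel else float("nan")
    fpr = float(common[~sel].mean()) if n_neu else float("nan")
    return ScanEvaluation(
        power=power,
        false_positive_rate=fpr,
        n_selected=n_sel,
        n_neutral=n_neu,
        n_flagged=int(common.sum()),
    )
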