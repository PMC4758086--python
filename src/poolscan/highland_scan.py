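"""Highland-versus-lowland outlier scan: di statistic, chi-square test, FDR,
and the intersection with the global-Fst outliers.

The di statistic standardizes, per SNP, the pairwise Fst between each
highland and each lowland population against that pair's genome-wide mean
and standard deviation, and sums over all highland x lowland pairs (eight in
the 2x4 study design):

    di(k) = sum over pairs (i,j) of [fst_ij(k) - mu_ij] / sigma_ij .

The chi-square test compares pooled allele counts between the combined
highland group (cases) and the combined lowland group (controls) in a 2x2
table per SNP, with Benjamini-Hochberg FDR adjustment over SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import PopulationMeta, SnpCountTable, highland_names, lowland_names
from .diversity import FstTable, estimate_frequencies
from .neutral_null import empirical_top_quantile


@dataclass
class PairMoments:
    """Genome-wide mean and (n-1)-denominator s.d. of pairwise Fst, per pair."""

    pairs: tuple[tuple[str, str], ...]
    mu: np.ndarray
    sigma: np.ndarray
    n_snps: np.ndarray  # defined values per pair

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "highland": [a for a, _ in self.pairs],
                "lowland": [b for _, b in self.pairs],
                "mu": self.mu,
                "sigma": self.sigma,
                "n_snps": self.n_snps,
            }
        )


@dataclass
class ScanThresholds:
    global_fraction: float = 0.025
    di_min: float = 13.5
    q_max: float = 0.01


@dataclass
class ScanResult:
    """Per-SNP scan statistics, outlier flags and overlap counts."""

    frame: pd.DataFrame
    overlap: dict
    global_cutoff: float
    thresholds: ScanThresholds


def _check_pairs(fst: FstTable, populations: Sequence[PopulationMeta]):
    pairs = [(h, l) for h in highland_names(populations) for l in lowland_names(populations)]
    if not pairs:
        raise ValueError("need at least one highland and one lowland population")
    missing = [p for p in pairs if FstTable.pair_column(*p) not in fst.frame.columns]
    if missing:
        raise ValueError(f"pairwise Fst missing for pairs: {missing}")
    return pairs


def pair_moments(fst: FstTable, populations: Sequence[PopulationMeta]) -> PairMoments:
    """Genome-wide moments of pairwise Fst over SNPs with defined values."""
    pairs = _check_pairs(fst, populations)
    mu, sigma, n = [], [], []
    for a, b in pairs:
        vals = fst.pair_values(a, b).to_numpy(float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            raise ValueError(f"pair ({a}, {b}): fewer than 2 defined Fst values")
        sd = float(np.std(vals, ddof=1))
        if sd == 0:
            raise ValueError(
                f"pair ({a}, {b}) has zero Fst variance; exclude this pair"
            )
        mu.append(float(np.mean(vals)))
        sigma.append(sd)
        n.append(len(vals))
    return PairMoments(
        pairs=tuple(pairs), mu=np.array(mu), sigma=np.array(sigma), n_snps=np.array(n)
    )


def di_statistic(
    fst: FstTable, moments: PairMoments, per_highland: bool = False
) -> pd.DataFrame:
    """Per-SNP di over the highland x lowland pairs.

    A pair with undefined Fst at a SNP contributes 0; the number of
    contributing pairs is recorded in ``n_pairs``.  With ``per_highland``
    the classic one-focal-population form is also reported: a ``di_<pop>``
    column per highland population summing only that population's pairs
    (``di`` is the sum of these columns).
    """
    out = fst.frame[["chrom", "pos"]].copy()
    di = np.zeros(len(out))
    n_pairs = np.zeros(len(out), int)
    by_focal: dict[str, np.ndarray] = {}
    for (a, b), mu, sigma in zip(moments.pairs, moments.mu, moments.sigma):
        vals = fst.pair_values(a, b).to_numpy(float)
        ok = ~np.isnan(vals)
        z = np.where(ok, (vals - mu) / sigma, 0.0)
        di += z
        n_pairs += ok.astype(int)
        if per_highland:
            by_focal[a] = by_focal.get(a, np.zeros(len(out))) + z
    out["di"] = di
    out["n_pairs"] = n_pairs
    for name, vals in by_focal.items():
        out[f"di_{name}"] = vals
    return out


def chi2_allele_test(
    counts: SnpCountTable,
    count_mode: str = "effective_alleles",
) -> pd.DataFrame:
    """Per-SNP 2x2 chi-square of allele counts, highland vs lowland group.

    In ``effective_alleles`` mode each population contributes
    round(p_alt * 2 n) alternate alleles out of its 2 n pooled chromosomes,
    so the evidence is capped at the number of sampled chromosomes rather
    than the read depth (raw reads pseudo-replicate chromosomes and inflate
    significance with depth).  ``reads`` mode uses raw read counts.

    Pearson chi-square with 1 df, no continuity correction.  Zero-margin
    tables get chi2 = 0, p = 1 and ``zero_margin`` = True.
    """
    pops = counts.populations
    hi, lo = highland_names(pops), lowland_names(pops)
    if not hi or not lo:
        raise ValueError("need at least one highland and one lowland population")
    if count_mode not in ("effective_alleles", "reads"):
        raise ValueError("count_mode must be 'effective_alleles' or 'reads'")

    if count_mode == "reads":
        alt = {n: counts.frame[f"{n}_alt"].to_numpy(float) for n in counts.pop_names}
        ref = {n: counts.frame[f"{n}_ref"].to_numpy(float) for n in counts.pop_names}
    else:
        freqs = estimate_frequencies(counts)
        size = {p.name: 2 * p.pool_size_n for p in pops}
        alt, ref = {}, {}
        for n in counts.pop_names:
            p = freqs.frame[f"{n}_freq"].to_numpy(float)
            a = np.where(np.isnan(p), 0.0, np.round(p * size[n]))
            tot = np.where(np.isnan(p), 0.0, float(size[n]))
            alt[n], ref[n] = a, tot - a

    a = sum(alt[n] for n in hi)
    b = sum(ref[n] for n in hi)
    c = sum(alt[n] for n in lo)
    d = sum(ref[n] for n in lo)
    N = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    zero = margins == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(zero, 0.0, N * (a * d - b * c) ** 2 / np.where(zero, 1.0, margins))
    p = np.where(zero, 1.0, stats.chi2.sf(chi2, df=1))
    out = counts.frame[["chrom", "pos"]].copy()
    out["chi2"] = chi2
    out["p"] = p
    out["zero_margin"] = zero
    return out


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _aligned(*frames: pd.DataFrame) -> None:
    keys = frames[0][["chrom", "pos"]]
    for f in frames[1:]:
        if not keys.equals(f[["chrom", "pos"]].reset_index(drop=True)):
            raise ValueError("per-SNP tables are not aligned on (chrom, pos)")


def combine_outliers(
    fst: FstTable,
    di: pd.DataFrame,
    chi2: pd.DataFrame,
    thresholds: ScanThresholds | None = None,
) -> ScanResult:
    """Flag outliers per SNP and intersect the two analyses.

    - ``global_outlier``: within the top ``global_fraction`` of the empirical
      global-Fst distribution (ties at the cutoff retained);
    - ``di_outlier``: di strictly greater than ``di_min``;
    - ``chi2_outlier``: BH-adjusted p strictly less than ``q_max``;
    - the high-lowland set is di_outlier AND chi2_outlier;
    - ``common``: global AND high-lowland.

    The overlap dict mirrors a two-set Venn diagram: counts of
    global-only, high-lowland-only, and common SNPs.
    """
    thresholds = thresholds or ScanThresholds()
    _aligned(fst.frame, di, chi2)
    out = fst.frame[["chrom", "pos"]].copy()
    gfst = fst.frame["fst_global"].to_numpy(float)
    out["fst_global"] = gfst
    out["di"] = di["di"].to_numpy(float)
    out["chi2"] = chi2["chi2"].to_numpy(float)
    out["p"] = chi2["p"].to_numpy(float)
    out["q"] = bh_fdr(out["p"].to_numpy())

    top = empirical_top_quantile(gfst, thresholds.global_fraction)
    with np.errstate(invalid="ignore"):
        out["global_outlier"] = ~np.isnan(gfst) & (gfst >= top.cutoff)
        out["di_outlier"] = out["di"].to_numpy() > thresholds.di_min
    out["chi2_outlier"] = out["q"].to_numpy() < thresholds.q_max
    high_lowland = out["di_outlier"] & out["chi2_outlier"]
    out["common"] = out["global_outlier"] & high_lowland
    overlap = {
        "n_global": int(out["global_outlier"].sum()),
        "n_high_lowland": int(high_lowland.sum()),
        "n_common": int(out["common"].sum()),
        "n_global_only": int((out["global_outlier"] & ~high_lowland).sum()),
        "n_high_lowland_only": int((high_lowland & ~out["global_outlier"]).sum()),
    }
    return ScanResult(
        frame=out, overlap=overlap, global_cutoff=top.cutoff, thresholds=thresholds
    )
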