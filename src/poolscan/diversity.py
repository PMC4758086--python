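"""Allele-frequency estimation and diversity / differentiation statistics.

Pool-seq frequencies are read-count ratios: for a pool with ``ref`` and
``alt`` reads at a site, ``p_alt = alt / (ref + alt)``.  Differentiation per
site follows Nei's gene-diversity partition for biallelic loci:

    Hs  = mean over populations of 2 p (1 - p)
    Ht  = 2 pbar (1 - pbar),   pbar = unweighted mean of p
    Fst = (Ht - Hs) / Ht       (undefined when Ht = 0)

Population means are unweighted: read-ratio frequencies are treated as
parametric estimates of the pool frequency, so no sample-size weighting or
small-sample correction is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import PopulationMeta, SnpCountTable, validate_populations


@dataclass
class FrequencyTable:
    """Per-SNP, per-population alternate-allele frequency and depth.

    ``frame`` columns: ``chrom, pos`` then ``<pop>_freq, <pop>_depth``;
    frequency is NaN (missing) where depth is zero.
    """

    frame: pd.DataFrame
    populations: tuple[PopulationMeta, ...]

    def __post_init__(self):
        self.populations = validate_populations(self.populations)
        self.frame = self.frame.reset_index(drop=True)

    @property
    def pop_names(self) -> list[str]:
        return [p.name for p in self.populations]

    @property
    def n_snps(self) -> int:
        return len(self.frame)

    def freq_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """(n_pops, n_snps) array of alt-allele frequencies (NaN = missing)."""
        names = list(names) if names is not None else self.pop_names
        unknown = [n for n in names if n not in self.pop_names]
        if unknown:
            raise ValueError(f"unknown population(s): {unknown}")
        return np.vstack([self.frame[f"{n}_freq"].to_numpy(float) for n in names])

    def keys(self) -> pd.DataFrame:
        return self.frame[["chrom", "pos"]].copy()


@dataclass
class FstTable:
    """Per-SNP Hs, Ht, global Fst and requested pairwise Fst columns."""

    frame: pd.DataFrame
    populations: tuple[PopulationMeta, ...]
    pairs: tuple[tuple[str, str], ...] = ()

    @staticmethod
    def pair_column(a: str, b: str) -> str:
        return f"fst_{a}|{b}"

    def pair_values(self, a: str, b: str) -> pd.Series:
        return self.frame[self.pair_column(a, b)]


@dataclass
class DiversitySummary:
    per_population: pd.DataFrame  # index: population; columns: P, H, n_snps_defined
    mean_fst: float
    mean_Ht: float
    mean_Hs: float
    #: alternative genome-wide Fst: (sum Ht - sum Hs) / sum Ht
    fst_ratio_of_means: float
    n_sites_defined: int


def estimate_frequencies(table: SnpCountTable) -> FrequencyTable:
    """Alt-allele frequency per pool: alt / (ref + alt); NaN when depth 0."""
    out = table.frame[["chrom", "pos"]].copy()
    for name in table.pop_names:
        ref = table.frame[f"{name}_ref"].to_numpy(float)
        alt = table.frame[f"{name}_alt"].to_numpy(float)
        depth = ref + alt
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(depth > 0, alt / np.where(depth > 0, depth, 1.0), np.nan)
        out[f"{name}_freq"] = freq
        out[f"{name}_depth"] = depth.astype(int)
    return FrequencyTable(out, table.populations)


def _nei_components(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Nei components over a (n_pops, n_snps) frequency matrix.

    Sites with fewer than two non-missing populations get NaN throughout.
    """
    freqs = np.atleast_2d(np.asarray(freqs, float))
    n_defined = np.sum(~np.isnan(freqs), axis=0)
    enough = n_defined >= 2
    with np.errstate(invalid="ignore"):
        Hs = np.nanmean(2 * freqs * (1 - freqs), axis=0)
        pbar = np.nanmean(freqs, axis=0)
    Ht = 2 * pbar * (1 - pbar)
    Hs = np.where(enough, Hs, np.nan)
    Ht = np.where(enough, Ht, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(Ht > 0, (Ht - Hs) / np.where(Ht > 0, Ht, 1.0), np.nan)
    return Hs, Ht, fst


def site_fst(freqs: Sequence[float]) -> tuple[float, float, float]:
    """Nei (Hs, Ht, Fst) for one site from per-population alt frequencies.

    Fst is NaN when Ht = 0 (site monomorphic at the mean frequency).
    Raises if fewer than two populations have a defined frequency.
    """
    arr = np.asarray(freqs, float)
    if np.sum(~np.isnan(arr)) < 2:
        raise ValueError("site_fst requires >= 2 non-missing populations")
    Hs, Ht, fst = _nei_components(arr.reshape(-1, 1))
    return float(Hs[0]), float(Ht[0]), float(fst[0])


def fst_table(
    freqs: FrequencyTable,
    pairs: Sequence[tuple[str, str]] = (),
) -> FstTable:
    """Per-SNP global Fst over all populations plus requested pairwise Fst."""
    names = freqs.pop_names
    for a, b in pairs:
        for n in (a, b):
            if n not in names:
                raise ValueError(f"unknown population {n!r} in pair ({a}, {b})")
    mat = freqs.freq_matrix()
    Hs, Ht, fst = _nei_components(mat)
    out = freqs.frame[["chrom", "pos"]].copy()
    out["Hs"] = Hs
    out["Ht"] = Ht
    out["fst_global"] = fst
    for a, b in pairs:
        sub = freqs.freq_matrix([a, b])
        _, _, pf = _nei_components(sub)
        out[FstTable.pair_column(a, b)] = pf
    return FstTable(out, freqs.populations, tuple((a, b) for a, b in pairs))


def highland_lowland_pairs(
    populations: Sequence[PopulationMeta],
) -> list[tuple[str, str]]:
    """All highland x lowland population pairs, in declared order."""
    hi = [p.name for p in populations if p.group == "highland"]
    lo = [p.name for p in populations if p.group == "lowland"]
    return [(h, l) for h in hi for l in lo]


def diversity_summary(
    freqs: FrequencyTable,
    counts: SnpCountTable,
    both_allele_min: int = 1,
) -> DiversitySummary:
    """Per-population polymorphism proportion P and average heterozygosity H,
    plus genome-wide mean Fst / Ht / Hs.

    P counts sites where both alleles have at least ``both_allele_min``
    supporting reads in that pool.  H is the mean over sites with a defined
    frequency of 2 p (1 - p) (symmetric in the allele labeling, so using the
    major-allele frequency is equivalent).  Genome-wide means cover sites
    where the statistic is defined; both the per-site mean Fst and the
    ratio-of-means variant are reported.
    """
    rows = []
    for name in freqs.pop_names:
        ref = counts.frame[f"{name}_ref"].to_numpy(float)
        alt = counts.frame[f"{name}_alt"].to_numpy(float)
        both = (ref >= both_allele_min) & (alt >= both_allele_min)
        P = float(both.mean()) if len(ref) else float("nan")
        p = freqs.frame[f"{name}_freq"].to_numpy(float)
        defined = ~np.isnan(p)
        H = float(np.mean(2 * p[defined] * (1 - p[defined]))) if defined.any() else float("nan")
        rows.append({"population": name, "P": P, "H": H, "n_snps_defined": int(defined.sum())})
    per_pop = pd.DataFrame(rows).set_index("population")

    Hs, Ht, fst = _nei_components(freqs.freq_matrix())
    defined = ~np.isnan(Ht)
    polym = defined & (Ht > 0)
    mean_fst = float(np.nanmean(fst[polym])) if polym.any() else float("nan")
    sHt, sHs = float(np.sum(Ht[polym])), float(np.sum(Hs[polym]))
    return DiversitySummary(
        per_population=per_pop,
        mean_fst=mean_fst,
        mean_Ht=float(np.mean(Ht[defined])) if defined.any() else float("nan"),
        mean_Hs=float(np.mean(Hs[defined])) if defined.any() else float("nan"),
        fst_ratio_of_means=(sHt - sHs) / sHt if sHt > 0 else float("nan"),
        n_sites_defined=int(defined.sum()),
    )


def frequency_concordance(
    estimated: FrequencyTable, truth: FrequencyTable
) -> pd.DataFrame:
    """Product-moment correlation between estimated and true frequencies,
    per population.  Mirrors validating pool-based estimates against
    individual genotyping of the same animals.

    Returns a frame indexed by population with columns ``r``, ``n`` and
    ``degenerate`` (True when either vector is constant; r is NaN there).
    """
    if not estimated.keys().equals(truth.keys()):
        raise ValueError("estimated and truth tables must cover the same SNPs")
    rows = []
    for name in estimated.pop_names:
        if name not in truth.pop_names:
            raise ValueError(f"population {name!r} missing from truth table")
        x = estimated.frame[f"{name}_freq"].to_numpy(float)
        y = truth.frame[f"{name}_freq"].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < 3:
            raise ValueError(f"population {name!r}: fewer than 3 paired values")
        degenerate = bool(np.std(x[ok]) == 0 or np.std(y[ok]) == 0)
        r = float("nan") if degenerate else float(np.corrcoef(x[ok], y[ok])[0, 1])
        rows.append({"population": name, "r": r, "n": n, "degenerate": degenerate})
    return pd.DataFrame(rows).set_index("population")
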