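"""Selectively-neutral Fst null distribution by Wright-Fisher simulation.

A base population segregates a biallelic locus at frequency ``p0`` and is
split into ``s`` subpopulations of equal effective size ``Ne``.  Each
subpopulation drifts independently for ``t`` generations, every generation
resampling 2 Ne genes binomially.  The expected divergence after t
generations is the classic drift result

    Fst(t) = 1 - (1 - 1/(2 Ne))^t .

After drift, a finite sample of alleles is drawn from each subpopulation
(default: the study design's pooled sample sizes) and per-locus Fst is
computed from the sample frequencies, so the null carries the same sampling
variance as the observed data.  Loci monomorphic across all samples have
undefined Fst and are excluded (counted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .diversity import _nei_components

#: 2 x pool size (diploids) for the six study pools — the default post-drift
#: sampling depths (number of alleles drawn per subpopulation).
STUDY_POOL_ALLELES: tuple[int, ...] = (120, 136, 90, 116, 78, 120)


def expected_fst(Ne: int, t: int) -> float:
    """Expected neutral divergence 1 - (1 - 1/(2 Ne))^t."""
    if Ne < 1:
        raise ValueError("Ne must be >= 1")
    if t < 0:
        raise ValueError("t must be >= 0")
    return 1.0 - (1.0 - 1.0 / (2.0 * Ne)) ** t


def solve_generations(Ne: int, target_fst: float) -> int:
    """Smallest integer t with expected_fst(Ne, t) >= target_fst."""
    if not 0 < target_fst < 1:
        raise ValueError("target_fst must be in (0, 1)")
    if Ne < 1:
        raise ValueError("Ne must be >= 1")
    t = math.ceil(math.log1p(-target_fst) / math.log1p(-1.0 / (2 * Ne)) - 1e-12)
    while expected_fst(Ne, t) < target_fst:  # guard against rounding
        t += 1
    while t > 0 and expected_fst(Ne, t - 1) >= target_fst:
        t -= 1
    return t


@dataclass
class NullSimConfig:
    n_subpops: int = 6
    Ne: int = 2749
    t: int = 300
    #: None means "match the observed SNP count" when run inside the pipeline
    n_loci: int | None = 57948
    #: initial frequency of the tracked allele (drift is label-symmetric, so
    #: tracking the major allele at 0.8619 is equivalent to tracking the
    #: minor one at 0.1381); may also be a callable (rng, n) -> frequencies
    p0: float | Callable = 0.8619
    #: post-drift sampling: None (use true subpopulation frequencies), an int
    #: (k alleles per subpopulation), or one k per subpopulation.  Default:
    #: the study's pooled sample sizes in alleles.
    sampling: None | int | Sequence[int] = STUDY_POOL_ALLELES
    seed: int = 0

    def __post_init__(self):
        if self.n_subpops < 2:
            raise ValueError("n_subpops must be >= 2")
        if self.Ne < 1:
            raise ValueError("Ne must be >= 1")
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if self.n_loci is not None and self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if isinstance(self.p0, float) and not 0 < self.p0 < 1:
            raise ValueError("p0 must be in (0, 1)")
        if self.sampling is not None and not isinstance(self.sampling, int):
            self.sampling = tuple(int(k) for k in self.sampling)
            if len(self.sampling) != self.n_subpops:
                raise ValueError(
                    "per-subpopulation sampling needs one value per subpopulation"
                )

    def sampling_depths(self) -> np.ndarray | None:
        if self.sampling is None:
            return None
        if isinstance(self.sampling, int):
            return np.full(self.n_subpops, self.sampling)
        return np.asarray(self.sampling)


@dataclass
class NullDistribution:
    fst: np.ndarray  # defined per-locus values only
    n_excluded: int  # loci monomorphic across all samples (Ht = 0)
    config: NullSimConfig

    def __post_init__(self):
        assert len(self.fst) + self.n_excluded == self.config.n_loci


def drift_frequencies(
    p0: np.ndarray, Ne: int, t: int, rng: np.random.Generator
) -> np.ndarray:
    """Wright-Fisher drift: binomial resampling of 2 Ne genes per generation.

    ``p0`` broadcasts to the output shape (n_subpops, n_loci).
    """
    q = np.array(p0, float, copy=True)
    two_ne = 2 * Ne
    for _ in range(t):
        q = rng.binomial(two_ne, q) / two_ne
    return q


def simulate_null(cfg: NullSimConfig) -> NullDistribution:
    """Simulate the neutral per-locus Fst distribution under ``cfg``."""
    if cfg.n_loci is None:
        raise ValueError("n_loci must be set before simulation")
    rng = np.random.default_rng(cfg.seed)
    if callable(cfg.p0):
        p0 = np.broadcast_to(cfg.p0(rng, cfg.n_loci), (cfg.n_subpops, cfg.n_loci))
    else:
        p0 = np.full((cfg.n_subpops, cfg.n_loci), float(cfg.p0))
    q = drift_frequencies(p0, cfg.Ne, cfg.t, rng)
    depths = cfg.sampling_depths()
    if depths is not None:
        k = depths[:, None]
        q = rng.binomial(np.broadcast_to(k, q.shape), q) / k
    _, Ht, fst = _nei_components(q)
    defined = ~np.isnan(fst)
    return NullDistribution(
        fst=fst[defined], n_excluded=int((~defined).sum()), config=cfg
    )


@dataclass
class ExceedanceReport:
    table: "object"  # pandas DataFrame: threshold, counts and proportions
    max_null: float
    n_observed: int
    n_null: int


def exceedance_report(
    observed: Sequence[float],
    null: NullDistribution | Sequence[float],
    thresholds: Sequence[float],
) -> ExceedanceReport:
    """Counts and proportions strictly above each threshold, observed vs null."""
    import pandas as pd

    obs = np.asarray(observed, float)
    obs = obs[~np.isnan(obs)]
    nul = null.fst if isinstance(null, NullDistribution) else np.asarray(null, float)
    nul = nul[~np.isnan(nul)]
    if len(obs) == 0 or len(nul) == 0:
        raise ValueError("both distributions must be non-empty")
    rows = []
    for thr in thresholds:
        oc, nc = int((obs > thr).sum()), int((nul > thr).sum())
        rows.append(
            {
                "threshold": thr,
                "observed_count": oc,
                "observed_prop": oc / len(obs),
                "null_count": nc,
                "null_prop": nc / len(nul),
            }
        )
    return ExceedanceReport(
        table=pd.DataFrame(rows),
        max_null=float(nul.max()),
        n_observed=len(obs),
        n_null=len(nul),
    )


@dataclass
class TopQuantile:
    cutoff: float
    n_target: int  # ceil(n * fraction)
    n_retained: int  # members >= cutoff (ties at the cutoff all retained)


def empirical_top_quantile(
    values: Sequence[float], fraction: float = 0.025
) -> TopQuantile:
    """Top-``fraction`` members of an empirical distribution.

    The member count is ceil(n * fraction); the cutoff is the smallest
    retained value; ties at the cutoff are all retained (so the retained
    count can exceed the target, reported separately).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    vals = np.asarray(values, float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("values must be non-empty")
    n_target = math.ceil(len(vals) * fraction)
    cutoff = float(np.sort(vals)[len(vals) - n_target])
    return TopQuantile(
        cutoff=cutoff, n_target=n_target, n_retained=int((vals >= cutoff).sum())
    )


def excess_significance(
    observed: Sequence[float], null: NullDistribution | Sequence[float], threshold: float
) -> float:
    """One-sided binomial p-value for the observed exceedance count at the
    null exceedance probability.  A reconstruction of an
    observed-versus-simulated excess test; the exact published test is not
    specified, so this is labeled as such.
    """
    obs = np.asarray(observed, float)
    obs = obs[~np.isnan(obs)]
    nul = null.fst if isinstance(null, NullDistribution) else np.asarray(null, float)
    nul = nul[~np.isnan(nul)]
    p_null = max((nul > threshold).mean(), 1.0 / (len(nul) + 1))
    k = int((obs > threshold).sum())
    return float(stats.binomtest(k, len(obs), p_null, alternative="greater").pvalue)
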