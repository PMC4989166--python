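"""Diversity and differentiation statistics for haplotype data.

Implements the ordered/unordered differentiation pair of Pons & Petit:
G_ST built from haplotype identity alone ("unordered") and N_ST built from
pairwise mutational distances ("ordered"), with unweighted population means
and the harmonic-mean small-sample correction in the total-diversity
estimator.  N_ST exceeding G_ST signals phylogeographic structure, tested by
permuting haplotype labels on the distance matrix (the U-test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .popdata import DistanceMatrix, HaplotypeSet, PopulationTable

__all__ = [
    "DiversityResult",
    "UTestResult",
    "per_population_diversity",
    "differentiation",
    "nst_gst_permutation_test",
    "diversity_vs_latitude",
]


@dataclass(frozen=True)
class DiversityResult:
    h_S: float
    h_T: float
    v_S: float
    v_T: float
    G_ST: float
    N_ST: float
    populations_used: tuple[str, ...]
    defined: bool = True


@dataclass(frozen=True)
class UTestResult:
    n_st_obs: float
    null_mean: float
    null_sd: float
    U: float
    p_value: float
    n_permutations: int


def per_population_diversity(
    h: HaplotypeSet, pops: PopulationTable, d: DistanceMatrix | None = None
) -> pd.DataFrame:
    """Per-population haplotype diversity h and nucleotide diversity pi.

    h uses the unbiased n/(n-1) correction; pi is the mean number of pairwise
    differences per site (recoded events, each indel/inversion = 1), over the
    full alignment length.  Populations of size 1 get h = pi = NaN.
    """
    from .popdata import pairwise_differences

    if d is None:
        d = pairwise_differences(h) if h.n_haplotypes > 1 else None
    L = h.alignment_length
    rows = []
    for pop in h.counts.index:
        c = h.counts.loc[pop].to_numpy(dtype=float)
        n = c.sum()
        if n < 2:
            rows.append((pop, int(n), np.nan, np.nan))
            continue
        p = c / n
        h_pop = (n / (n - 1)) * (1 - np.sum(p**2))
        if d is None:
            pi = 0.0
        else:
            dv = d.values.astype(float)
            pi = (n / (n - 1)) * float(p @ dv @ p) / 2 * 2 / L  # sum_{k<l} 2 p_k p_l d_kl / L
        rows.append((pop, int(n), h_pop, pi))
    out = pd.DataFrame(rows, columns=["population", "n", "h", "pi"])
    coords = pops.coordinates
    out["latitude"] = out["population"].map(coords["latitude"])
    out["longitude"] = out["population"].map(coords["longitude"])
    return out


def _pons_petit(counts: np.ndarray, kernel: np.ndarray) -> tuple[float, float]:
    """Within (v_S) and total (v_T) diversity for an arbitrary distance kernel.

    ``counts``: populations x haplotypes; ``kernel``: haplotype x haplotype
    distances (0/1 identity kernel gives h_S, h_T).  Unweighted means over
    populations; harmonic-mean n in the total correction.
    """
    n_i = counts.sum(axis=1)
    keep = n_i >= 2
    counts = counts[keep]
    n_i = n_i[keep]
    s = counts.shape[0]
    if s < 2:
        raise ValueError("need >=2 populations with n >= 2")
    freqs = counts / n_i[:, None]
    v_i = (n_i / (n_i - 1)) * np.einsum("ik,il,kl->i", freqs, freqs, kernel) / 2.0
    v_S = float(v_i.mean())
    xbar = freqs.mean(axis=0)
    n_harm = s / np.sum(1.0 / n_i)
    v_T = float(xbar @ kernel @ xbar) / 2.0 + v_S / (s * n_harm)
    return v_S, v_T


def differentiation(h: HaplotypeSet, d: DistanceMatrix) -> DiversityResult:
    """h_S, h_T, G_ST (unordered) and v_S, v_T, N_ST (ordered).

    Populations with fewer than 2 individuals are excluded.  A monomorphic
    species (h_T = 0) has undefined differentiation and is flagged.
    """
    counts = h.counts.to_numpy(dtype=float)
    used = tuple(
        p for p, n in zip(h.counts.index, counts.sum(axis=1)) if n >= 2
    )
    identity = 2.0 * (1 - np.eye(h.n_haplotypes))  # /2 inside _pons_petit
    dv = 2.0 * d.values.astype(float)
    h_S, h_T = _pons_petit(counts, identity)
    v_S, v_T = _pons_petit(counts, dv)
    if h_T <= 0:
        return DiversityResult(h_S, h_T, v_S, v_T, np.nan, np.nan, used, defined=False)
    G_ST = (h_T - h_S) / h_T
    N_ST = (v_T - v_S) / v_T if v_T > 0 else np.nan
    return DiversityResult(h_S, h_T, v_S, v_T, G_ST, N_ST, used)


def nst_gst_permutation_test(
    h: HaplotypeSet,
    d: DistanceMatrix,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> UTestResult:
    """Permutation U-test of N_ST against its label-shuffled null.

    Haplotype labels are permuted on the distance matrix (frequencies
    untouched), N_ST recomputed each time; U standardises the observed N_ST
    against the null; one-tailed p with the +1 correction.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    obs = differentiation(h, d)
    if not obs.defined:
        raise ValueError("differentiation undefined (monomorphic data)")
    K = h.n_haplotypes
    counts = h.counts.to_numpy(dtype=float)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(K)
        dp = d.values[np.ix_(perm, perm)].astype(float) * 2.0
        v_S, v_T = _pons_petit(counts, dp)
        null[b] = (v_T - v_S) / v_T if v_T > 0 else np.nan
    null = null[np.isfinite(null)]
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        return UTestResult(obs.N_ST, mean, sd, np.nan, 1.0, n_permutations)
    U = (obs.N_ST - mean) / sd
    p = (1 + int(np.sum(null >= obs.N_ST))) / (len(null) + 1)
    return UTestResult(obs.N_ST, mean, sd, U, p, n_permutations)


def diversity_vs_latitude(per_pop: pd.DataFrame) -> dict:
    """OLS of per-population haplotype diversity on latitude.

    Returns slope, intercept, t and two-sided p for the slope, and R^2.
    Mirrors the leading-edge-expansion test: a significant negative slope
    means diversity declines toward the range margin.
    """
    data = per_pop.dropna(subset=["h", "latitude"])
    if len(data) < 3:
        raise ValueError("need >=3 populations with defined h")
    if data["latitude"].nunique() < 2:
        raise ValueError("zero variance in latitude")
    X = sm.add_constant(data["latitude"].to_numpy(dtype=float))
    fit = sm.OLS(data["h"].to_numpy(dtype=float), X).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "t": float(fit.tvalues[1]),
        "p_value": float(fit.pvalues[1]),
        "r_squared": float(fit.rsquared),
        "n": int(len(data)),
    }
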