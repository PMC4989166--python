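"""Demographic inference from haplotype data.

Neutrality tests (Tajima's D, Fu's F_S) with coalescent-simulation p-values,
the mismatch distribution under the sudden (stepwise) expansion model of
Rogers & Harpending with SSD / raggedness goodness-of-fit by parametric
bootstrap, and conversion of the expansion parameter tau to calendar time via

    T = tau / (2 mu k g)

with mu the substitution rate (substitutions/site/year), k the sequence
length (bp) and g the generation time (years).

The expected mismatch distribution after an expansion at tau mutational time
units ago, from theta0 to theta1, is

    F_j(tau) = F_j(theta1)
             + exp(-tau (theta1+1)/theta1)
               * sum_{i<=j} tau^i/i! [F_{j-i}(theta0) - F_{j-i}(theta1)]

where F_j(theta) = theta^j / (1+theta)^(j+1) is the stationary distribution
(the tau = 0 limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import msprime
import numpy as np
from scipy.optimize import minimize
from scipy.signal import find_peaks

from .popdata import HaplotypeSet, DistanceMatrix, pairwise_differences

__all__ = [
    "NeutralityResult",
    "MismatchFit",
    "DatingInput",
    "ExpansionDate",
    "SuddenExpansionModel",
    "DATING_PRESETS",
    "tajima_d",
    "fu_fs",
    "mismatch_histogram",
    "fit_sudden_expansion",
    "expansion_gof",
    "date_expansion",
    "classify_modality",
    "expected_mismatch",
    "tajima_d_statistic",
    "fu_fs_statistic",
]


# species-specific dating presets: (mu subs/site/year, k bp, g years)
DATING_PRESETS: dict[str, "DatingInput"] = {}


@dataclass(frozen=True)
class NeutralityResult:
    statistic: float
    p_value: float | None
    n: int
    S: int
    pi: float
    n_haplotypes: int | None = None
    defined: bool = True
    tail: str = "lower"


@dataclass(frozen=True)
class DatingInput:
    mu: float  # substitutions / site / year
    k: float  # sites (bp)
    g: float  # generation time (years)

    def __post_init__(self) -> None:
        if min(self.mu, self.k, self.g) <= 0:
            raise ValueError("mu, k, g must be strictly positive")


DATING_PRESETS.update(
    {
        "C_tibetana": DatingInput(0.71e-9, 1826, 25),
        "M_thunbergii": DatingInput(4e-9, 1450, 10),
        "S_superba": DatingInput(0.6e-9, 1399, 8),
    }
)


@dataclass(frozen=True)
class ExpansionDate:
    T: float  # years before present (the formula's output, labelled as printed)
    ci: tuple[float, float] | None
    rounding: str


@dataclass(frozen=True)
class MismatchFit:
    """Observed mismatch histogram with the fitted sudden-expansion model."""

    histogram: np.ndarray
    n: int
    tau: float
    theta0: float
    theta1: float
    ssd: float
    raggedness: float
    modality: str
    p_ssd: float | None = None
    p_rag: float | None = None
    tau_ci: tuple[float, float] | None = None

    @property
    def n_pairs(self) -> int:
        return int(self.histogram.sum())

    def expected(self, n_bins: int | None = None) -> np.ndarray:
        n_bins = n_bins if n_bins is not None else len(self.histogram)
        return expected_mismatch(self.tau, self.theta0, self.theta1, n_bins)

    def summary(self) -> str:
        lines = [
            "Sudden-expansion mismatch fit",
            f"  pairs: {self.n_pairs}  (n = {self.n})",
            f"  tau     = {self.tau:.4f}"
            + (f"  (95% CI {self.tau_ci[0]:.4f}-{self.tau_ci[1]:.4f})" if self.tau_ci else ""),
            f"  theta0  = {self.theta0:.4f}",
            f"  theta1  = {self.theta1:.4f}",
            f"  SSD     = {self.ssd:.5f}" + (f"  (P = {self.p_ssd:.3f})" if self.p_ssd is not None else ""),
            f"  H_Rag   = {self.raggedness:.5f}" + (f"  (P = {self.p_rag:.3f})" if self.p_rag is not None else ""),
            f"  modality: {self.modality}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# core statistics


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajima_d_statistic(S: int, pi: float, n: int) -> float:
    """Tajima's D from segregating sites S and mean pairwise differences pi."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S < 1:
        return np.nan
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    return (pi - S / a1) / math.sqrt(var)


def _ewens_k_distribution(theta: float, n: int) -> np.ndarray:
    """P(K = k | theta, n) for k = 0..n under the Ewens sampling formula."""
    f = np.zeros(n + 1)
    f[1] = 1.0  # n = 1
    for m in range(1, n):
        g = np.zeros(n + 1)
        g[1:] = (m * f[1:] + theta * f[:-1]) / (theta + m)
        f = g
    return f


def fu_fs_statistic(pi: float, k_obs: int, n: int) -> float:
    """Fu's F_S = ln(S'/(1-S')), S' = P(K >= k_obs | theta = pi)."""
    if n < 2 or pi <= 0:
        return np.nan
    probs = _ewens_k_distribution(pi, n)
    s_prime = float(probs[k_obs:].sum())
    if s_prime >= 1 - 1e-15:
        return math.inf
    if s_prime <= 1e-300:
        return -math.inf
    return math.log(s_prime / (1 - s_prime))


# ---------------------------------------------------------------------------
# sample summaries from a haplotype set


def _present(h: HaplotypeSet, populations: list[str] | None):
    counts = h.counts if populations is None else h.counts.loc[populations]
    c = counts.to_numpy(dtype=float).sum(axis=0)
    return c


def _sample_summary(
    h: HaplotypeSet, d: DistanceMatrix | None, populations: list[str] | None
) -> tuple[int, int, float, int]:
    """(n, S, pi_hat, k_obs) for the pooled individuals of the chosen pops."""
    c = _present(h, populations)
    n = int(c.sum())
    present = c > 0
    vecs = h.vectors[present]
    S = 0
    for col in range(vecs.shape[1]):
        states = set(vecs[:, col]) - {"-"}
        if len(states) >= 2:
            S += 1
    if d is None:
        d = pairwise_differences(h)
    dv = d.values.astype(float)
    cp = c[:, None] * c[None, :]
    np.fill_diagonal(cp, c * (c - 1))
    total_pairs = n * (n - 1) / 2
    pi = float((cp * dv).sum() / 2 / total_pairs) if total_pairs > 0 else 0.0
    return n, S, pi, int(present.sum())


# ---------------------------------------------------------------------------
# coalescent simulation machinery (haploid, non-recombining locus)


def _simulate_stationary(n: int, theta: float, seed: int) -> "msprime.TreeSequence":
    return msprime.sim_mutations(
        msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=max(theta, 1e-9), random_seed=max(seed, 1)
        ),
        rate=0.5,
        random_seed=max(seed, 1),
        discrete_genome=False,
    )


def _simulate_expansion(
    n: int, tau: float, theta0: float, theta1: float, seed: int
) -> "msprime.TreeSequence":
    """Sudden size change theta0 -> theta1 at tau mutational units ago.

    Units: mutation rate 0.5 per sequence per generation, so tau equals time
    in generations and theta equals the haploid population size.
    """
    demography = msprime.Demography()
    demography.add_population(initial_size=max(theta1, 1e-9))
    if tau > 0:
        demography.add_population_parameters_change(
            time=tau, initial_size=max(theta0, 1e-9)
        )
    ts = msprime.sim_ancestry(
        samples=n, ploidy=1, demography=demography, random_seed=max(seed, 1)
    )
    return msprime.sim_mutations(
        ts, rate=0.5, random_seed=max(seed, 1), discrete_genome=False
    )


def _ts_summaries(ts) -> tuple[int, float, int, np.ndarray]:
    """(S, pi_hat, k_obs, pairwise difference matrix) of a tree sequence."""
    G = ts.genotype_matrix()  # sites x samples
    n = ts.num_samples
    S = G.shape[0]
    if S == 0:
        return 0, 0.0, 1, np.zeros((n, n), dtype=int)
    D = np.zeros((n, n), dtype=int)
    for s in range(S):
        row = G[s]
        diff = row[:, None] != row[None, :]
        D += diff
    pi = D.sum() / (n * (n - 1))
    k_obs = len({tuple(col) for col in G.T})
    return S, float(pi), k_obs, D


def _hist_from_matrix(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    vals = D[iu]
    return np.bincount(vals.astype(int))


# ---------------------------------------------------------------------------
# public operations


def tajima_d(
    h: HaplotypeSet,
    d: DistanceMatrix | None = None,
    populations: list[str] | None = None,
    n_sims: int = 10_000,
    seed: int | None = None,
    tail: str = "lower",
) -> NeutralityResult:
    """Tajima's D with a coalescent-simulation p-value.

    Simulations are conditioned on theta_hat = S/a1 (fixed-theta convention).
    ``tail='lower'`` reports P(D_sim <= D_obs), the convention of the
    standard software family; 'two_tailed' doubles the smaller tail.
    """
    n, S, pi, _ = _sample_summary(h, d, populations)
    if S == 0:
        return NeutralityResult(np.nan, None, n, S, pi, defined=False)
    D_obs = tajima_d_statistic(S, pi, n)
    p = None
    if n_sims > 0:
        a1, _, _ = _tajima_constants(n)
        theta_hat = S / a1
        rng = np.random.default_rng(seed)
        sims = []
        for _ in range(n_sims):
            ts = _simulate_stationary(n, theta_hat, int(rng.integers(1, 2**31)))
            S_b, pi_b, _, _ = _ts_summaries(ts)
            if S_b >= 1:
                sims.append(tajima_d_statistic(S_b, pi_b, n))
        sims = np.array(sims)
        lower = (1 + np.sum(sims <= D_obs)) / (len(sims) + 1)
        upper = (1 + np.sum(sims >= D_obs)) / (len(sims) + 1)
        p = float(lower if tail == "lower" else min(1.0, 2 * min(lower, upper)))
    return NeutralityResult(float(D_obs), p, n, S, pi, tail=tail)


def fu_fs(
    h: HaplotypeSet,
    d: DistanceMatrix | None = None,
    populations: list[str] | None = None,
    n_sims: int = 1000,
    seed: int | None = None,
) -> NeutralityResult:
    """Fu's F_S with a coalescent-simulation p-value.

    p is the fraction of neutral simulations (theta = pi_hat) with simulated
    F_S <= observed: small values indicate the haplotype excess expected
    after expansion.
    """
    n, S, pi, k_obs = _sample_summary(h, d, populations)
    if pi <= 0 or S == 0:
        return NeutralityResult(np.nan, None, n, S, pi, k_obs, defined=False)
    fs_obs = fu_fs_statistic(pi, k_obs, n)
    p = None
    if n_sims > 0:
        rng = np.random.default_rng(seed)
        sims = []
        for _ in range(n_sims):
            ts = _simulate_stationary(n, pi, int(rng.integers(1, 2**31)))
            S_b, pi_b, k_b, _ = _ts_summaries(ts)
            if pi_b > 0:
                sims.append(fu_fs_statistic(pi_b, k_b, n))
        sims = np.array(sims)
        p = float((1 + np.sum(sims <= fs_obs)) / (len(sims) + 1))
    return NeutralityResult(float(fs_obs), p, n, S, pi, k_obs)


def mismatch_histogram(
    h: HaplotypeSet,
    d: DistanceMatrix | None = None,
    populations: list[str] | None = None,
) -> np.ndarray:
    """Counts of pairwise mutational differences over all individual pairs."""
    c = _present(h, populations)
    n = int(c.sum())
    if n < 2:
        raise ValueError("need >=2 individuals")
    if d is None:
        d = pairwise_differences(h)
    dv = d.values.astype(int)
    hist = np.zeros(int(dv.max()) + 1, dtype=int)
    K = len(c)
    for k in range(K):
        if c[k] >= 2:
            hist[0] += int(c[k] * (c[k] - 1) // 2)
        for l in range(k + 1, K):
            if c[k] and c[l]:
                hist[dv[k, l]] += int(c[k] * c[l])
    return hist


def expected_mismatch(
    tau: float, theta0: float, theta1: float, n_bins: int, tail_pad: int = 20
) -> np.ndarray:
    """Expected relative mismatch frequencies over bins 0..n_bins-1.

    Computed on n_bins + tail_pad bins; mass beyond the last reported bin is
    folded into it, so the returned vector sums to 1 (to truncation error of
    the padded expansion).
    """
    theta0 = max(theta0, 1e-12)
    theta1 = max(theta1, 1e-12)
    m = n_bins + tail_pad
    j = np.arange(m)

    def stationary(theta):
        return np.exp(j * np.log(theta) - (j + 1) * np.log(1 + theta))

    f0, f1 = stationary(theta0), stationary(theta1)
    if tau <= 0:
        out = f0
    else:
        diff = f0 - f1
        log_w = -tau * (theta1 + 1) / theta1 + j * np.log(tau) - [
            math.lgamma(i + 1) for i in j
        ]
        w = np.exp(log_w)
        conv = np.convolve(w, diff)[:m]
        out = f1 + conv
    out = np.clip(out, 0, None)
    res = out[:n_bins].copy()
    res[-1] += out[n_bins:].sum() + max(0.0, 1.0 - out.sum())
    return res


def raggedness(hist: np.ndarray) -> float:
    """Harpending's raggedness over relative frequencies, with a leading
    zero class (d_max+1 squared-step terms)."""
    x = hist / hist.sum()
    xp = np.concatenate([[0.0], x])
    return float(np.sum(np.diff(xp) ** 2))


def _ssd(x: np.ndarray, params: tuple[float, float, float]) -> float:
    e = expected_mismatch(*params, n_bins=len(x))
    return float(np.sum((x - e) ** 2))


def fit_sudden_expansion(
    hist: np.ndarray, n: int, n_starts_extra: int = 0
) -> MismatchFit:
    """Least-squares fit of (tau, theta0, theta1) to the mismatch histogram.

    Minimises the SSD between observed and expected relative frequencies with
    tau, theta0 >= 0 and theta1 >= theta0, by a multistart grid plus
    Nelder-Mead refinement on square-root-transformed parameters.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.sum() <= 0:
        raise ValueError("empty histogram")
    x = hist / hist.sum()
    mean_d = float(np.sum(np.arange(len(x)) * x))

    def objective(z):
        tau = z[0] ** 2
        th0 = z[1] ** 2
        th1 = th0 + z[2] ** 2
        return _ssd(x, (tau, th0, th1))

    starts = [
        (max(mean_d, 0.1), 0.1, 10 * max(mean_d, 1.0)),
        (0.5 * max(mean_d, 0.1), 0.5, 100.0),
        (2.0 * max(mean_d, 0.1), 1.0, 1000.0),
        (0.01, max(mean_d, 0.1), max(mean_d, 0.1)),
    ]
    candidates = []
    for tau0, th00, th10 in starts:
        z0 = [math.sqrt(tau0), math.sqrt(th00), math.sqrt(max(th10 - th00, 1e-6))]
        res = minimize(objective, z0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
        if np.isfinite(res.fun):
            candidates.append(res)
    if not candidates:
        raise RuntimeError("mismatch-model optimisation failed for all starts")
    # the surface has a flat ridge (large tau extinguishes the expansion
    # term); among statistically indistinguishable optima take the smallest tau
    best_fun = min(r.fun for r in candidates)
    tol = best_fun * 0.10 + 1e-12
    best = min((r for r in candidates if r.fun <= best_fun + tol), key=lambda r: r.x[0] ** 2)
    tau = best.x[0] ** 2
    theta0 = best.x[1] ** 2
    theta1 = theta0 + best.x[2] ** 2
    return MismatchFit(
        histogram=hist.astype(int),
        n=n,
        tau=float(tau),
        theta0=float(theta0),
        theta1=float(theta1),
        ssd=float(best.fun),
        raggedness=raggedness(hist),
        modality=classify_modality(hist),
    )


class SuddenExpansionModel:
    """Model-style wrapper around the mismatch-distribution fit.

    ``SuddenExpansionModel(hist, n).fit()`` returns a :class:`MismatchFit`;
    ``fit(gof=True)`` additionally runs the parametric bootstrap.
    """

    def __init__(self, histogram: np.ndarray, n: int):
        self.histogram = np.asarray(histogram)
        self.n = int(n)

    @classmethod
    def from_haplotypes(
        cls, h: HaplotypeSet, d: DistanceMatrix | None = None,
        populations: list[str] | None = None,
    ) -> "SuddenExpansionModel":
        hist = mismatch_histogram(h, d, populations)
        n = int(_present(h, populations).sum())
        return cls(hist, n)

    def fit(self, gof: bool = False, n_boot: int = 1000, seed: int | None = None) -> MismatchFit:
        result = fit_sudden_expansion(self.histogram, self.n)
        if gof:
            result = expansion_gof(result, n_boot=n_boot, seed=seed)
        return result


def expansion_gof(
    fit: MismatchFit, n_boot: int = 1000, seed: int | None = None
) -> MismatchFit:
    """Parametric bootstrap p-values for SSD and raggedness, plus a tau CI.

    Coalescent samples of size n are simulated under the fitted expansion,
    each refit; p = fraction of replicates whose statistic >= observed, and
    the tau CI is the 2.5/97.5 percentile band of replicate tau estimates.
    """
    import warnings

    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap replicates: p-values are coarse")
    rng = np.random.default_rng(seed)
    ssd_b, rag_b, tau_b = [], [], []
    for _ in range(n_boot):
        ts = _simulate_expansion(
            fit.n, fit.tau, fit.theta0, fit.theta1, int(rng.integers(1, 2**31))
        )
        _, _, _, D = _ts_summaries(ts)
        hist = _hist_from_matrix(D)
        try:
            f = fit_sudden_expansion(hist, fit.n)
        except (ValueError, RuntimeError):
            continue
        ssd_b.append(f.ssd)
        rag_b.append(f.raggedness)
        tau_b.append(f.tau)
    ssd_b, rag_b, tau_b = map(np.asarray, (ssd_b, rag_b, tau_b))
    m = len(ssd_b)
    p_ssd = float((1 + np.sum(ssd_b >= fit.ssd)) / (m + 1))
    p_rag = float((1 + np.sum(rag_b >= fit.raggedness)) / (m + 1))
    ci = (float(np.percentile(tau_b, 2.5)), float(np.percentile(tau_b, 97.5)))
    return replace(fit, p_ssd=p_ssd, p_rag=p_rag, tau_ci=ci)


def date_expansion(
    tau: float,
    dating: DatingInput,
    rounding: str = "none",
    tau_ci: tuple[float, float] | None = None,
) -> ExpansionDate:
    """Calendar time of the expansion: T = tau / (2 mu k g).

    ``rounding='paper'`` floors to the nearest hundred years (the convention
    that reproduces the published worked examples); CI endpoints are
    transformed and rounded identically.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if rounding not in ("none", "paper"):
        raise ValueError("rounding must be 'none' or 'paper'")

    def convert(t):
        T = t / (2 * dating.mu * dating.k * dating.g)
        return float(math.floor(T / 100) * 100) if rounding == "paper" else float(T)

    ci = (convert(tau_ci[0]), convert(tau_ci[1])) if tau_ci is not None else None
    return ExpansionDate(convert(tau), ci, rounding)


def classify_modality(hist: np.ndarray, window: int = 3) -> str:
    """Label the smoothed mismatch curve unimodal/bimodal/multimodal.

    A moving average of the relative frequencies is scanned for local maxima
    (boundary peaks count).
    """
    hist = np.asarray(hist, dtype=float)
    if hist.sum() <= 0:
        raise ValueError("empty histogram")
    x = hist / hist.sum()
    if len(x) >= window > 1:
        kernel = np.ones(window) / window
        x = np.convolve(x, kernel, mode="same")
    padded = np.concatenate([[-1.0], x, [-1.0]])
    peaks, _ = find_peaks(padded)
    n_peaks = max(1, len(peaks))
    return {1: "unimodal", 2: "bimodal"}.get(n_peaks, "multimodal")
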