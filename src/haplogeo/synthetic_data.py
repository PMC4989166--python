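"""Synthetic data with known truth for every pipeline stage.

Two generators:

* a structured-coalescent haplotype sampler (island model, optional stepwise
  expansion) producing aligned FASTA + population CSV with a truth record
  carrying theta_true = 2 N_e mu g k, tau_true = 2 mu g k t and the true
  deme assignment, so diversity, differentiation, SAMOVA and expansion-dating
  estimators can be scored against truth;
* a landscape sampler producing spatially autocorrelated environmental
  layers and species occurrences drawn from declared Gaussian niches, with
  the true suitability surfaces and true D/I in the truth record.

The locus is haploid and non-recombining (chloroplast-appropriate); mutation
is finite-sites by default so recurrent hits are possible, with an
infinite-sites switch for clean theory checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .niche import EnvStack, GridSpec, OccurrenceSet, SuitabilityRaster, niche_overlap, write_ascii_grid
from .popdata import Alignment, PopulationTable

__all__ = [
    "CoalescentScenario",
    "LandscapeScenario",
    "simulate_coalescent",
    "simulate_landscape_and_occurrences",
    "write_coalescent_outputs",
    "write_landscape_outputs",
]


@dataclass(frozen=True)
class CoalescentScenario:
    """Island-model sampling design with optional stepwise expansion.

    ``expansion`` is (time in generations ago, growth factor): the per-deme
    size is N_e now and N_e/growth_factor before that time.
    """

    n_per_deme: tuple[int, ...] = (10,)
    N_e: float = 10_000.0
    migration_rate: float = 0.0  # per-generation fraction
    expansion: tuple[float, float] | None = None
    mu: float = 1e-9  # substitutions / site / year
    k: int = 1500  # sites (bp)
    g: float = 10.0  # generation time (years)
    seed: int = 1
    infinite_sites: bool = False

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_deme):
            raise ValueError("every deme needs a positive sample size")
        if self.k < 1 or self.mu < 0 or self.migration_rate < 0:
            raise ValueError("rates must be >= 0 and k >= 1")
        if len(self.n_per_deme) > 1 and self.migration_rate == 0:
            raise ValueError("multi-deme scenarios need migration_rate > 0")

    @property
    def theta_true(self) -> float:
        return 2 * self.N_e * self.mu * self.g * self.k

    @property
    def tau_true(self) -> float:
        if self.expansion is None:
            return 0.0
        return 2 * self.mu * self.g * self.k * self.expansion[0]


def simulate_coalescent(
    sc: CoalescentScenario,
) -> tuple[Alignment, PopulationTable, dict]:
    """Simulate one haploid cpDNA-like sample under the scenario.

    Returns the alignment, the population table (demes on a west-to-east
    axis) and a truth record with theta_true, tau_true and assignments.
    Identical seeds give byte-identical alignments.
    """
    P = len(sc.n_per_deme)
    mu_gen = sc.mu * sc.g  # per site per generation
    if P == 1:
        demography = msprime.Demography()
        demography.add_population(name="pop_0", initial_size=sc.N_e)
    else:
        demography = msprime.Demography.island_model(
            [sc.N_e] * P, migration_rate=sc.migration_rate
        )
    if sc.expansion is not None:
        t_change, factor = sc.expansion
        for pop in demography.populations:
            demography.add_population_parameters_change(
                time=t_change, initial_size=sc.N_e / factor, population=pop.name
            )
        demography.sort_events()
    samples = {f"pop_{i}": n for i, n in enumerate(sc.n_per_deme)}
    ts = msprime.sim_ancestry(
        samples=samples,
        ploidy=1,
        demography=demography,
        sequence_length=sc.k,
        random_seed=sc.seed,
    )
    if sc.infinite_sites:
        ts = msprime.sim_mutations(
            ts, rate=mu_gen, random_seed=sc.seed, model=msprime.BinaryMutationModel(),
            discrete_genome=False,
        )
    else:
        ts = msprime.sim_mutations(
            ts, rate=mu_gen, random_seed=sc.seed, model="jc69", discrete_genome=True
        )

    rng = np.random.default_rng(sc.seed)
    n_total = sum(sc.n_per_deme)
    base = rng.choice(list("ACGT"), size=sc.k)
    seqs = np.tile(base, (n_total, 1))
    if sc.infinite_sites:
        # binary 0/1 alleles on a continuous genome: give each variant its own
        # column (ancestral = background base, derived = a different base)
        for idx, var in enumerate(ts.variants()):
            if idx >= sc.k:
                break  # more segregating sites than columns; vanishingly rare
            col = idx
            derived = "A" if base[col] != "A" else "T"
            seqs[var.genotypes == 1, col] = derived
    else:
        for var in ts.variants():
            col = int(var.site.position)
            alleles = np.array(var.alleles, dtype="<U1")
            seqs[:, col] = alleles[var.genotypes]

    sample_ids = []
    pop_rows = []
    assignment = {}
    i0 = 0
    for p, n in enumerate(sc.n_per_deme):
        pop = f"P{p + 1}"
        lon = 100.0 + 1.5 * p
        lat = 26.0
        for j in range(n):
            sid = f"{pop}_{j + 1}"
            sample_ids.append(sid)
            pop_rows.append((pop, lat, lon, sid))
            assignment[sid] = pop
        i0 += n
    alignment = Alignment(
        tuple(sample_ids),
        tuple("".join(row) for row in seqs),
        ((0, sc.k),),
    )
    pops = PopulationTable(
        pd.DataFrame(pop_rows, columns=["population", "latitude", "longitude", "sample_id"])
    )
    truth = {
        "theta_true": sc.theta_true,
        "tau_true": sc.tau_true,
        "assignment": assignment,
        "mu": sc.mu,
        "k": sc.k,
        "g": sc.g,
        "seed": sc.seed,
        "n_per_deme": list(sc.n_per_deme),
        "migration_rate": sc.migration_rate,
        "expansion": list(sc.expansion) if sc.expansion else None,
    }
    return alignment, pops, truth


def write_coalescent_outputs(
    outdir: str | Path, alignment: Alignment, pops: PopulationTable, truth: dict
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "alignment.fasta"
    with open(fasta, "w") as fh:
        for sid, seq in zip(alignment.sample_ids, alignment.sequences):
            fh.write(f">{sid}\n{seq}\n")
    pop_csv = outdir / "populations.csv"
    pops.table.to_csv(pop_csv, index=False)
    truth_json = outdir / "truth.json"
    truth_json.write_text(json.dumps(truth, indent=1))
    return {"fasta": fasta, "populations": pop_csv, "truth": truth_json}


@dataclass(frozen=True)
class LandscapeScenario:
    """Spatially autocorrelated layers plus declared Gaussian species niches.

    Each niche maps a species name to (optimum vector, width vector) in the
    standardised variable space; occurrences are sampled proportional to the
    true suitability.
    """

    nrows: int = 60
    ncols: int = 60
    n_variables: int = 5
    smoothing_length: float = 6.0  # Gaussian smoothing sigma, cells
    niches: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = field(
        default_factory=lambda: {"speciesA": ((0.0,) * 5, (1.0,) * 5)}
    )
    n_occurrences: int = 100
    seed: int = 1
    cell_size: float = 0.05
    x_origin: float = 100.0
    y_origin: float = 32.0

    def __post_init__(self) -> None:
        if self.n_occurrences < 10:
            raise ValueError("need n_occurrences >= 10")
        for sp, (opt, width) in self.niches.items():
            if len(opt) != self.n_variables or len(width) != self.n_variables:
                raise ValueError(f"niche for {sp} must have {self.n_variables} entries")
            if any(w <= 0 for w in width):
                raise ValueError("niche widths must be positive")


def _true_suitability(stack: EnvStack, opt, width) -> SuitabilityRaster:
    X = np.stack([stack.layers[v] for v in stack.names], axis=-1)
    z2 = ((X - np.asarray(opt)) / np.asarray(width)) ** 2
    s = np.exp(-0.5 * z2.sum(axis=-1))
    s = np.where(stack.mask, s, 0.0)
    return SuitabilityRaster(s / s.max(), stack.mask, stack.grid)


def simulate_landscape_and_occurrences(
    ls: LandscapeScenario,
) -> tuple[EnvStack, dict[str, OccurrenceSet], dict]:
    """Generate the landscape, per-species occurrences and the truth record.

    Truth carries each species' true suitability surface and the analytic
    true (D, I) between every species pair (computed on the true surfaces).
    Identical seeds give identical rasters.
    """
    rng = np.random.default_rng(ls.seed)
    grid = GridSpec(ls.x_origin, ls.y_origin, ls.cell_size, ls.nrows, ls.ncols)
    layers = {}
    for v in range(ls.n_variables):
        field_ = gaussian_filter(
            rng.standard_normal((ls.nrows, ls.ncols)), ls.smoothing_length
        )
        sd = field_.std()
        if sd == 0:
            raise ValueError("degenerate zero-variance environmental field")
        layers[f"BIO_{v + 1}"] = (field_ - field_.mean()) / sd
    mask = np.ones((ls.nrows, ls.ncols), dtype=bool)
    stack = EnvStack(layers, mask, grid)

    true_surfaces = {
        sp: _true_suitability(stack, opt, width) for sp, (opt, width) in ls.niches.items()
    }
    occurrences = {}
    for sp, surf in true_surfaces.items():
        p = surf.values[mask].astype(float)
        p = p / p.sum()
        n_pos = int((p > 0).sum())
        n_draw = min(ls.n_occurrences, n_pos)
        flat_idx = rng.choice(len(p), size=n_draw, replace=False, p=p)
        cells = np.argwhere(mask)[flat_idx]
        lonlat = np.array([grid.center_of(r, c) for r, c in cells])
        occurrences[sp] = OccurrenceSet(sp, lonlat, cells, deduplicated=True)

    species = list(ls.niches)
    true_overlap = {}
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            D, I = niche_overlap(true_surfaces[a], true_surfaces[b])
            true_overlap[f"{a}|{b}"] = {"D": D, "I": I}
    truth = {
        "true_surfaces": true_surfaces,
        "true_overlap": true_overlap,
        "seed": ls.seed,
    }
    return stack, occurrences, truth


def write_landscape_outputs(
    outdir: str | Path, stack: EnvStack, occurrences: dict[str, OccurrenceSet], truth: dict
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, arr in stack.layers.items():
        p = outdir / f"{name}.asc"
        write_ascii_grid(p, np.where(stack.mask, arr, np.nan), stack.grid)
        paths[name] = p
    rows = []
    for sp, occ in occurrences.items():
        for lon, lat in occ.points:
            rows.append((sp, lon, lat))
    occ_csv = outdir / "occurrences.csv"
    pd.DataFrame(rows, columns=["species", "lon", "lat"]).to_csv(occ_csv, index=False)
    paths["occurrences"] = occ_csv
    overlap_json = outdir / "truth_overlap.json"
    overlap_json.write_text(json.dumps(truth["true_overlap"], indent=1))
    paths["truth"] = overlap_json
    return paths
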