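"""Per-species pipeline orchestration and the cross-species report.

A :class:`RunConfig` (TOML-backed) names the input files per species and the
analysis settings; :func:`run_pipeline` runs haplotype collapsing, diversity
and differentiation, SAMOVA, the haplotype network and the demographic
analyses for each species, then assembles a cross-species comparison table
mirroring the mismatch/dating summary layout.  One global seed expands
deterministically into per-stage seeds.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as dv
from . import demography as dm
from . import network as nw
from . import structure as st
from .popdata import (
    collapse_haplotypes,
    pairwise_differences,
    read_alignment,
    read_population_table,
    recode_mutations,
)

logger = logging.getLogger("haplogeo")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class SpeciesConfig:
    name: str
    alignment: Path
    populations: Path
    label_prefix: str = "H"
    inversions: list[tuple[int, int]] = field(default_factory=list)
    dating: dm.DatingInput | None = None


@dataclass
class RunConfig:
    species: list[SpeciesConfig]
    outdir: Path
    seed: int = 0
    n_permutations: int = 1000
    n_bootstraps: int = 1000
    neutrality_sims: int = 1000
    samova_starts: int = 100
    samova_K: tuple[int, int] = (2, 4)
    rounding: str = "paper"
    run_network: bool = True
    run_structure: bool = True
    run_demography: bool = True

    @classmethod
    def from_toml(cls, path: str | Path, outdir: str | Path | None = None) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        gl = raw.get("global", {})
        species = []
        base = Path(path).parent
        for name, section in raw.get("species", {}).items():
            dating = None
            if "dating_preset" in section:
                dating = dm.DATING_PRESETS[section["dating_preset"]]
            elif {"mu", "k", "g"} <= set(section):
                dating = dm.DatingInput(section["mu"], section["k"], section["g"])
            sp = SpeciesConfig(
                name=name,
                alignment=base / section["alignment"],
                populations=base / section["populations"],
                label_prefix=section.get("label_prefix", "H"),
                inversions=[tuple(r) for r in section.get("inversions", [])],
                dating=dating,
            )
            for p in (sp.alignment, sp.populations):
                if not p.exists():
                    raise FileNotFoundError(p)
            species.append(sp)
        cfg = cls(
            species=species,
            outdir=Path(outdir) if outdir else base / gl.get("outdir", "haplogeo_out"),
            seed=int(gl.get("seed", 0)),
        )
        settings = raw.get("settings", {})
        for key in (
            "n_permutations", "n_bootstraps", "neutrality_sims",
            "samova_starts", "rounding",
        ):
            if key in settings:
                setattr(cfg, key, settings[key])
        if "samova_K" in settings:
            cfg.samova_K = tuple(settings["samova_K"])
        return cfg


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _analyse_species(sp: SpeciesConfig, cfg: RunConfig, outdir: Path, seeds: list[int]) -> dict:
    t0 = time.time()
    outdir.mkdir(parents=True, exist_ok=True)
    a = read_alignment(sp.alignment)
    pops = read_population_table(sp.populations)
    m = recode_mutations(a, sp.inversions or None)
    h = collapse_haplotypes(m, pops, label_prefix=sp.label_prefix)
    d = pairwise_differences(h)

    membership = pd.DataFrame(
        sorted(h.membership.items()), columns=["sample_id", "haplotype"]
    )
    membership.to_csv(outdir / "membership.csv", index=False)
    h.counts.to_csv(outdir / "haplotype_counts.csv")
    d.to_frame().to_csv(outdir / "distances.csv")

    report: dict = {
        "species": sp.name,
        "n_individuals": h.n_individuals,
        "n_haplotypes": h.n_haplotypes,
        "n_polymorphic_columns": m.n_sites,
    }

    per_pop = dv.per_population_diversity(h, pops, d)
    per_pop.to_csv(outdir / "perpop_diversity.csv", index=False)
    if not h.monomorphic:
        div = dv.differentiation(h, d)
        u = dv.nst_gst_permutation_test(h, d, cfg.n_permutations, seed=seeds[0])
        report["diversity"] = {
            "h_S": div.h_S, "h_T": div.h_T,
            "G_ST": div.G_ST, "N_ST": div.N_ST,
            "U": u.U, "p_U": u.p_value,
        }
        try:
            report["latitude_regression"] = dv.diversity_vs_latitude(per_pop)
        except ValueError as exc:
            report["latitude_regression"] = {"error": str(exc)}

    if cfg.run_structure and not h.monomorphic and len(pops.populations) >= 4:
        k_lo, k_hi = cfg.samova_K
        k_hi = min(k_hi, len(pops.populations) - 1)
        scan = st.samova_scan(
            h, d, pops, range(k_lo, k_hi + 1),
            n_starts=cfg.samova_starts, seed=seeds[1],
        )
        scan["profile"].to_csv(outdir / "samova_profile.csv", index=False)
        best = scan["results"][scan["suggested_K"]]
        pd.DataFrame(
            sorted(best.grouping.assignment.items()), columns=["population", "group"]
        ).to_csv(outdir / "grouping.csv", index=False)
        G = st.build_contiguity(pops)
        with open(outdir / "adjacency.txt", "w") as fh:
            for x, y in sorted(G.edges):
                fh.write(f"{x}\t{y}\n")
        report["samova"] = {
            "suggested_K": scan["suggested_K"],
            "reliable": scan["reliable"],
            "F_CT": best.F_CT,
        }

    if cfg.run_network and h.n_haplotypes >= 2:
        net = nw.median_joining_network(h)
        net.edge_table().to_csv(outdir / "network_edges.csv", index=False)
        net.node_table().to_csv(outdir / "network_nodes.csv", index=False)
        report["network"] = {
            "n_median_vectors": len(net.median_nodes),
            "total_length": net.total_length(),
        }

    if cfg.run_demography and not h.monomorphic:
        td = dm.tajima_d(h, d, n_sims=cfg.neutrality_sims, seed=seeds[2])
        fs = dm.fu_fs(h, d, n_sims=cfg.neutrality_sims, seed=seeds[3])
        hist = dm.mismatch_histogram(h, d)
        pd.DataFrame({"differences": np.arange(len(hist)), "pairs": hist}).to_csv(
            outdir / "mismatch_histogram.csv", index=False
        )
        fit = dm.SuddenExpansionModel(hist, h.n_individuals).fit(
            gof=True, n_boot=cfg.n_bootstraps, seed=seeds[4]
        )
        demo = {
            "tajima_D": td.statistic, "p_D": td.p_value,
            "fu_FS": fs.statistic, "p_FS": fs.p_value,
            "tau": fit.tau, "tau_ci": fit.tau_ci,
            "theta0": fit.theta0, "theta1": fit.theta1,
            "SSD": fit.ssd, "p_SSD": fit.p_ssd,
            "H_Rag": fit.raggedness, "p_rag": fit.p_rag,
            "modality": fit.modality,
        }
        if sp.dating is not None:
            date = dm.date_expansion(fit.tau, sp.dating, cfg.rounding, fit.tau_ci)
            demo["T_years_bp"] = date.T
            demo["T_ci"] = date.ci
        report["demography"] = demo

    report["wall_time_s"] = round(time.time() - t0, 3)
    (outdir / "report.json").write_text(
        json.dumps(_jsonable(report), indent=1, sort_keys=True)
    )
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured species and write the cross-species comparison."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed, 8 * max(1, len(cfg.species)))
    reports = []
    for i, sp in enumerate(cfg.species):
        logger.info("analysing %s", sp.name)
        rep = _analyse_species(sp, cfg, cfg.outdir / sp.name, seeds[8 * i: 8 * i + 8])
        reports.append(rep)

    rows = []
    for rep in reports:
        demo = rep.get("demography", {})
        div = rep.get("diversity", {})
        rows.append(
            {
                "species": rep["species"],
                "n_haplotypes": rep["n_haplotypes"],
                "h_S": div.get("h_S"), "h_T": div.get("h_T"),
                "G_ST": div.get("G_ST"), "N_ST": div.get("N_ST"),
                "U": div.get("U"), "p_U": div.get("p_U"),
                "tau": demo.get("tau"), "modality": demo.get("modality"),
                "SSD": demo.get("SSD"), "p_SSD": demo.get("p_SSD"),
                "H_Rag": demo.get("H_Rag"), "p_rag": demo.get("p_rag"),
                "T_years_bp": demo.get("T_years_bp"),
            }
        )
    comparison = pd.DataFrame(rows)
    comparison.to_csv(cfg.outdir / "comparison.csv", index=False)
    bundle = {"seed": cfg.seed, "species": _jsonable(reports)}
    (cfg.outdir / "report.json").write_text(
        json.dumps(bundle, indent=1, sort_keys=True)
    )
    return bundle
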