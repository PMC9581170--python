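"""End-to-end orchestration: simulate or ingest a biparental study, build the
bin map, deduce testcross genotypes, compute phenotype statistics, run the
QTL scans on the RIL / testcross / heterosis datasets, classify gene action,
and render a Markdown report.

A run is driven by a single YAML config; every stochastic stage draws from
sub-streams of the one run seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .actions import (
    classify_gene_action,
    compare_environments,
    environment_overlap_summary,
    find_multitrait_regions,
    gene_action_table,
    match_qtl,
    summarize_epistasis_overlap,
)
from .genotypes import MarkerMatrix, bin_markers, deduce_bc1f1_genotypes, filter_markers, summarize_binmap
from .io import read_genotypes, read_phenotypes, write_genotypes, write_phenotypes, write_table
from .phenotypes import (
    broad_sense_heritability,
    filter_restorers,
    heterosis_table,
    hmp_trait_table,
    line_means,
)
from .scan import ScanConfig, call_qtl, permutation_threshold, scan_additive, scan_epistasis
from .sim import (
    ChromosomeSpec,
    EpistasisSpec,
    GeneticMapSpec,
    QTLSpec,
    SimConfig,
    cross_to_bc1f1,
    genetic_values,
    simulate_fertility,
    simulate_phenotypes,
    simulate_ril_genotypes,
)

log = logging.getLogger("heteroqtl")


class ConfigError(ValueError):
    """Invalid run configuration (user error)."""


@dataclass
class RunConfig:
    """Validated run configuration; see ``examples`` in the repo for layout."""

    raw: dict

    def __post_init__(self) -> None:
        if "seed" not in self.raw:
            raise ConfigError("config requires a 'seed'")
        if "orientation" not in self.raw or not isinstance(self.raw["orientation"], dict):
            raise ConfigError("config requires an 'orientation' map (trait -> +1/-1)")
        if ("simulation" in self.raw) == ("inputs" in self.raw):
            raise ConfigError("config requires exactly one of 'simulation' or 'inputs'")
        if "inputs" in self.raw:
            for key in ("genotypes", "map", "phenotypes_ril", "phenotypes_bc1f1"):
                p = self.raw["inputs"].get(key)
                if p is None or not Path(p).exists():
                    raise ConfigError(f"input file for {key!r} missing: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def orientation(self) -> dict[str, int]:
        return {str(k): int(v) for k, v in self.raw["orientation"].items()}

    @property
    def yield_traits(self) -> list[str]:
        return list(self.raw.get("yield_traits", []))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def scan_config(self, design: str) -> ScanConfig:
        kw = dict(self.raw.get("scan", {}))
        kw.pop("permutations", None)
        return ScanConfig(design=design, **kw)

    def epistasis_config(self, design: str) -> ScanConfig:
        kw = dict(self.raw.get("epistasis_scan", {}))
        kw.pop("enabled", None)
        return ScanConfig.for_epistasis(design=design, **kw)


def _sim_objects(cfg: RunConfig):
    sim = cfg.raw["simulation"]
    chroms = [
        ChromosomeSpec(str(c["id"]), float(c["length_cm"]), int(c["n_markers"]))
        for c in sim["chromosomes"]
    ]
    map_spec = GeneticMapSpec(chroms)
    traits = sim["traits"]
    restorer = sim.get("restorer")
    sim_cfg = SimConfig(
        n_lines=int(sim["n_lines"]),
        seed=cfg.seed,
        selfing_generations=int(sim.get("selfing_generations", 7)),
        environments={str(k): float(v) for k, v in sim.get("environments", {"E1": 0.0}).items()},
        replicates=int(sim.get("replicates", 2)),
        trait_means={t: float(spec["mean"]) for t, spec in traits.items()},
        residual_sd={t: spec["residual_sd"] for t, spec in traits.items()},
        restorer=(str(restorer["chrom"]), float(restorer["pos_cm"])) if restorer else None,
        missing_rate=float(sim.get("missing_rate", 0.0)),
    )
    qtl = [
        QTLSpec(
            str(q["chrom"]), float(q["pos_cm"]), str(q["trait"]),
            float(q["a"]), float(q.get("d", 0.0)), q.get("env_multiplier"),
        )
        for q in sim.get("qtl", [])
    ]
    epi = [
        EpistasisSpec(
            (str(e["chrom1"]), float(e["cm1"])),
            (str(e["chrom2"]), float(e["cm2"])),
            str(e["trait"]),
            float(e["aa"]),
        )
        for e in sim.get("epistasis", [])
    ]
    return map_spec, sim_cfg, qtl, epi


def _recurrent_parent_values(
    cfg: RunConfig, sim_cfg: SimConfig | None, qtl, genos: MarkerMatrix | None
) -> dict[str, dict[str, float]]:
    """Recurrent-parent trait values per (trait, env).

    Taken from the config when supplied (the field design evaluates the
    sterile parent through its maintainer near-isogenic line); in simulation
    mode they default to the generating model evaluated at the all-recurrent
    genotype.
    """
    given = cfg.raw.get("recurrent_parent_values")
    if given is not None:
        return {t: {e: float(v) for e, v in envs.items()} for t, envs in given.items()}
    if sim_cfg is None:
        raise ConfigError("recurrent_parent_values is required when loading real data")
    values: dict[str, dict[str, float]] = {}
    rec = MarkerMatrix(
        pd.DataFrame(
            np.zeros((1, genos.n_markers), dtype=np.int16),
            index=["recurrent"],
            columns=genos.marker_ids,
        ),
        genos.marker_map,
    )
    for trait, mu in sim_cfg.trait_means.items():
        values[trait] = {}
        for env, offset in sim_cfg.environments.items():
            gv = float(genetic_values(rec, qtl, trait=trait, env=env).iloc[0])
            values[trait][env] = mu + gv + offset
    return values


def run_pipeline(cfg: RunConfig, out_dir) -> dict[str, Any]:
    """Execute every stage and write all outputs plus a manifest to out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    results: dict[str, Any] = {}

    def stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                log.info("stage %s started", name)

            def __exit__(self_, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    log.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                log.info("stage %s done (%.2fs)", name, timings[name])

        return _T()

    sim_cfg = None
    qtl: list[QTLSpec] = []
    epi: list[EpistasisSpec] = []

    with stage("acquire"):
        if "simulation" in cfg.raw:
            map_spec, sim_cfg, qtl, epi = _sim_objects(cfg)
            rils = simulate_ril_genotypes(map_spec, sim_cfg)
            bc1f1_true = cross_to_bc1f1(rils, sim_cfg)
            pheno_ril = simulate_phenotypes(rils, qtl, epi, sim_cfg, rng_stage="pheno_ril")
            pheno_bc = simulate_phenotypes(bc1f1_true, qtl, epi, sim_cfg, rng_stage="pheno_bc1f1")
            fertility = simulate_fertility(
                rils, sim_cfg.restorer, seed=cfg.seed,
                **cfg.raw["simulation"].get("fertility", {}),
            )
            write_genotypes(rils, out / "ril_genotypes.tsv", out / "marker_map.tsv")
            write_phenotypes(pheno_ril, out / "pheno_ril.csv")
            write_phenotypes(pheno_bc, out / "pheno_bc1f1.csv")
        else:
            paths = cfg.raw["inputs"]
            rils = read_genotypes(paths["genotypes"], paths["map"])
            pheno_ril = read_phenotypes(paths["phenotypes_ril"])
            pheno_bc = read_phenotypes(paths["phenotypes_bc1f1"])
            if "fertility" in paths:
                fert = pd.read_csv(paths["fertility"], index_col=0)
                fertility = fert.iloc[:, 0]
            else:
                fertility = pd.Series(1.0, index=rils.line_ids)
        fertility.rename("fertility").to_csv(out / "fertility.csv", header=True)

    with stage("binmap"):
        filt = cfg.raw.get("filters", {})
        filtered = filter_markers(
            rils,
            maf_min=float(filt.get("maf_min", 0.01)),
            miss_max=float(filt.get("miss_max", 0.2)),
            het_max=filt.get("het_max", 0.1),
        )
        binmap, binned = bin_markers(filtered)
        results["binmap_summary"] = summarize_binmap(binmap)
        bins_out = binmap.bins.copy()
        bins_out["members"] = bins_out["members"].map(lambda ms: ";".join(ms))
        write_table(bins_out, out / "binmap.tsv")
        write_genotypes(binned, out / "binned_genotypes.tsv", out / "binned_map.tsv")

    with stage("deduce_bc1f1"):
        bc_geno = deduce_bc1f1_genotypes(binned)
        write_genotypes(bc_geno, out / "bc1f1_genotypes.tsv", out / "bc1f1_map.tsv")

    with stage("phenotype_stats"):
        traits = sorted(pheno_ril["trait"].unique())
        envs = sorted(pheno_ril["env"].unique())
        rec_values = _recurrent_parent_values(cfg, sim_cfg, qtl, binned)
        het = heterosis_table(pheno_bc, pheno_ril, rec_values)
        write_table(het, out / "heterosis.csv")
        hmp = hmp_trait_table(het)
        h2_rows = []
        for pop, tab in (("RIL", pheno_ril), ("BC1F1", pheno_bc)):
            for trait in traits:
                for env in envs:
                    try:
                        r = broad_sense_heritability(tab, trait, env)
                    except ValueError:
                        continue
                    h2_rows.append(
                        {
                            "population": pop, "trait": trait, "env": env,
                            "h2": r.h2, "sigma2_g": r.sigma2_g, "sigma2_e": r.sigma2_e,
                        }
                    )
        results["heritability"] = pd.DataFrame(h2_rows)
        write_table(results["heritability"], out / "heritability.csv")
        restorers = filter_restorers(fertility)
        results["n_restorers"] = int(len(restorers))

    with stage("scan"):
        perms = int(cfg.raw.get("scan", {}).get("permutations", 0))
        all_calls = []
        datasets = {
            "RIL": (binned, lambda t, e: line_means(pheno_ril, t, e)),
            "BC1F1": (bc_geno, lambda t, e: line_means(pheno_bc, t, e)),
            "HMP": (bc_geno, lambda t, e: line_means(hmp, t, e)),
        }
        scan_rows = []
        for pop, (geno, getter) in datasets.items():
            scfg = cfg.scan_config(pop)
            for trait in traits:
                for env in envs:
                    y = getter(trait, env)
                    if trait in cfg.yield_traits:
                        y = y[y.index.isin(restorers)]
                        if len(y) == 0:
                            continue
                    res = scan_additive(geno, y, scfg)
                    thr = (
                        permutation_threshold(geno, y, scfg, seed=cfg.seed, n_permutations=perms)
                        if perms > 0
                        else scfg.lod_threshold
                    )
                    calls = call_qtl(res, thr, geno.marker_map)
                    calls.insert(0, "trait", trait)
                    calls.insert(1, "env", env)
                    calls.insert(2, "population", pop)
                    all_calls.append(calls)
                    res.insert(0, "trait", trait)
                    res.insert(1, "env", env)
                    res.insert(2, "population", pop)
                    scan_rows.append(res)
        all_calls = [c for c in all_calls if not c.empty] or all_calls[:1]
        results["scans"] = pd.concat(scan_rows, ignore_index=True) if scan_rows else pd.DataFrame()
        results["calls"] = (
            pd.concat(all_calls, ignore_index=True) if all_calls else pd.DataFrame()
        )
        write_table(results["scans"], out / "scan_profiles.tsv")
        write_table(results["calls"], out / "qtl_calls.tsv")

    with stage("epistasis"):
        epi_cfg_raw = cfg.raw.get("epistasis_scan", {})
        epi_frames = []
        if epi_cfg_raw.get("enabled", False):
            for pop, (geno, getter) in datasets.items():
                ecfg = cfg.epistasis_config(pop)
                for trait in traits:
                    for env in envs:
                        y = getter(trait, env)
                        if trait in cfg.yield_traits:
                            y = y[y.index.isin(restorers)]
                        pairs = scan_epistasis(geno, y, ecfg)
                        pairs.insert(0, "trait", trait)
                        pairs.insert(1, "env", env)
                        pairs.insert(2, "population", pop)
                        epi_frames.append(pairs)
        results["epistasis"] = (
            pd.concat(epi_frames, ignore_index=True) if epi_frames else pd.DataFrame()
        )
        write_table(results["epistasis"], out / "eqtl_pairs.tsv")

    with stage("classify"):
        calls = results["calls"]
        clusters_by_env: dict[str, list] = {}
        records = []
        if not calls.empty:
            for env in envs:
                clusters_by_env[env] = match_qtl(calls[calls["env"] == env])
            for env in envs:
                records.extend(classify_gene_action(c) for c in clusters_by_env[env])
        results["gene_actions"] = gene_action_table(records)
        write_table(results["gene_actions"], out / "gene_actions.tsv")
        if len(envs) == 2 and clusters_by_env:
            results["env_comparison"] = compare_environments(clusters_by_env)
            results["env_overlap"] = environment_overlap_summary(results["env_comparison"])
        else:
            results["env_comparison"] = pd.DataFrame()
            results["env_overlap"] = pd.DataFrame()
        write_table(results["env_comparison"], out / "environment_comparison.tsv")
        regions = []
        for env in envs:
            if calls.empty:
                continue
            reg = find_multitrait_regions(calls[calls["env"] == env], cfg.orientation)
            reg.insert(0, "env", env)
            regions.append(reg)
        results["regions"] = (
            pd.concat(regions, ignore_index=True) if regions else pd.DataFrame()
        )
        write_table(results["regions"], out / "multitrait_regions.tsv")

    with stage("report"):
        report = render_report_from_results(cfg, results, pheno_ril, pheno_bc, het, envs, traits)
        (out / "report.md").write_text(report)
        manifest = {
            "package": "heteroqtl",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "timings_s": timings,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    results["manifest"] = manifest
    return results


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _md_table(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    if df.empty:
        return "_(no rows)_\n"
    show = df.copy()
    for c in show.columns:
        if show[c].dtype.kind == "f":
            show[c] = show[c].map(lambda v: floatfmt.format(v) if pd.notna(v) else "")
    header = "| " + " | ".join(map(str, show.columns)) + " |"
    sep = "|" + "|".join(["---"] * len(show.columns)) + "|"
    rows = ["| " + " | ".join(map(str, r)) + " |" for r in show.itertuples(index=False)]
    return "\n".join([header, sep, *rows]) + "\n"


def render_report_from_results(cfg, results, pheno_ril, pheno_bc, het, envs, traits) -> str:
    parts = ["# heteroqtl run report\n"]
    parts.append(f"Seed: {cfg.seed}; config hash: {cfg.config_hash()}\n")

    parts.append("## Bin map\n")
    bs = results.get("binmap_summary")
    if bs:
        parts.append(
            f"{bs['n_bins']} bins spanning {bs['span_cm']:.1f} cM "
            f"(mean spacing {bs['mean_spacing_cm']:.2f} cM, "
            f"mean bin size {bs['mean_bin_size_bp'] / 1e3:.0f} kb)\n"
        )
    else:
        parts.append("_(unavailable)_\n")

    parts.append("## Trait summary\n")
    rows = []
    for pop, tab in (("RIL", pheno_ril), ("BC1F1", pheno_bc)):
        for trait in traits:
            for env in envs:
                lm = line_means(tab, trait, env)
                hmp_mean = (
                    het[(het["trait"] == trait) & (het["env"] == env)]["hmp_pct"].mean()
                    if pop == "BC1F1"
                    else np.nan
                )
                h2tab = results.get("heritability", pd.DataFrame())
                h2 = np.nan
                if not h2tab.empty:
                    hit = h2tab[
                        (h2tab["population"] == pop)
                        & (h2tab["trait"] == trait)
                        & (h2tab["env"] == env)
                    ]
                    if not hit.empty:
                        h2 = float(hit["h2"].iloc[0])
                rows.append(
                    {
                        "population": pop, "trait": trait, "env": env,
                        "mean": lm.mean(), "cv_pct": 100 * lm.std(ddof=1) / lm.mean()
                        if lm.mean() != 0 else np.nan,
                        "H2": h2, "mean_HMP_pct": hmp_mean,
                    }
                )
    parts.append(_md_table(pd.DataFrame(rows)))

    parts.append(f"\nRestorer lines retained for yield scans: {results.get('n_restorers', 'n/a')}\n")

    parts.append("\n## QTL calls by gene action\n")
    ga = results.get("gene_actions", pd.DataFrame())
    if ga.empty:
        parts.append("_(no QTL called)_\n")
    else:
        counts = (
            ga.groupby(["trait", "gene_action"]).size().unstack(fill_value=0).reset_index()
        )
        counts["total"] = counts.drop(columns="trait").sum(axis=1)
        parts.append(_md_table(counts))

    parts.append("\n## Multi-trait regions\n")
    parts.append(_md_table(results.get("regions", pd.DataFrame())))

    parts.append("\n## Environment overlap\n")
    parts.append(_md_table(results.get("env_overlap", pd.DataFrame())))
    comp = results.get("env_comparison", pd.DataFrame())
    if not comp.empty:
        common = comp[comp["status"] == "common"]
        parts.append("\nClusters detected in both environments:\n")
        parts.append(_md_table(common))
    return "\n".join(parts)


def render_report(run_dir) -> str:
    """Regenerate the Markdown report from a completed run directory."""
    run = Path(run_dir)

    def maybe(name, reader=pd.read_csv, **kw):
        p = run / name
        try:
            return reader(p, **kw) if p.exists() else None
        except Exception:
            return None

    parts = ["# heteroqtl run report (re-rendered)\n"]
    for title, fname, sep in (
        ("Heritability", "heritability.csv", ","),
        ("Gene actions", "gene_actions.tsv", "\t"),
        ("Multi-trait regions", "multitrait_regions.tsv", "\t"),
        ("Environment comparison", "environment_comparison.tsv", "\t"),
    ):
        parts.append(f"## {title}\n")
        df = maybe(fname, sep=sep)
        parts.append(_md_table(df) if df is not None else "_(unavailable)_\n")
    text = "\n".join(parts)
    (run / "report.md").write_text(text)
    return text
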