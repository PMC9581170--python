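"""Synthetic biparental populations with the structure of an elite-hybrid
heterosis study: F8 recombinant inbred lines (RILs) from a single-seed-descent
cross, BC1F1 testcrosses of each RIL to the recurrent parent, replicated
phenotypes in multiple environments, and a restorer locus gating testcross
fertility.

The meiosis model places crossovers without interference, so recombination
between positions follows Haldane's map function.  Selfing is simulated
explicitly, one offspring per generation (single-seed descent), which retains
the residual heterozygosity an F8 panel really shows ((1/2)^7 per locus after
seven selfing meioses) instead of forcing fixation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    HET,
    HOM_DONOR,
    HOM_RECURRENT,
    MISSING,
    MarkerMatrix,
    haldane_r_from_cm,
)

#: physical scale of the emulated genome, ~373 Mb over ~2,268 cM
DEFAULT_BP_PER_CM = 165_000.0


@dataclass(frozen=True)
class ChromosomeSpec:
    id: str
    length_cm: float
    n_markers: int

    def __post_init__(self) -> None:
        if self.length_cm < 0:
            raise ValueError(f"chromosome {self.id}: negative length")
        if self.n_markers < 1:
            raise ValueError(f"chromosome {self.id}: need at least one marker")


@dataclass
class GeneticMapSpec:
    """Chromosome lengths and marker placement for the simulated genome.

    Markers are evenly spaced in cM; physical positions follow at
    ``bp_per_cm`` base pairs per centimorgan (strictly increasing even for
    co-located markers).
    """

    chromosomes: Sequence[ChromosomeSpec]
    bp_per_cm: float = DEFAULT_BP_PER_CM

    def marker_table(self) -> pd.DataFrame:
        rows = []
        for ch in self.chromosomes:
            if ch.n_markers == 1:
                cms = np.array([0.0])
            else:
                cms = np.linspace(0.0, ch.length_cm, ch.n_markers)
            bp = np.rint(cms * self.bp_per_cm).astype(np.int64) + 1
            bp = np.maximum.accumulate(bp + np.arange(len(bp)))  # strictly increasing
            for k, (cm, b) in enumerate(zip(cms, bp)):
                rows.append((f"{ch.id}_m{k:04d}", ch.id, float(cm), int(b)))
        df = pd.DataFrame(rows, columns=["marker", "chrom", "cm", "bp"]).set_index("marker")
        return df

    def chromosome_length(self, chrom: str) -> float:
        for ch in self.chromosomes:
            if ch.id == chrom:
                return ch.length_cm
        raise KeyError(f"unknown chromosome {chrom!r}")


@dataclass(frozen=True)
class QTLSpec:
    """A simulated trait locus.

    ``a`` is the additive effect in trait units per donor-allele substitution
    (sign = effect of the donor allele); ``d`` is the heterozygote's deviation
    from the mid-homozygote value.  ``env_multiplier`` optionally scales both
    effects per environment.
    """

    chrom: str
    pos_cm: float
    trait: str
    a: float
    d: float = 0.0
    env_multiplier: Mapping[str, float] | None = None

    def scale(self, env: str) -> float:
        if self.env_multiplier is None:
            return 1.0
        return float(self.env_multiplier.get(env, 1.0))


@dataclass(frozen=True)
class EpistasisSpec:
    """Additive-by-additive interaction between two loci for one trait."""

    locus1: tuple[str, float]
    locus2: tuple[str, float]
    trait: str
    aa: float

    def __post_init__(self) -> None:
        if self.locus1 == self.locus2:
            raise ValueError("epistatic loci must be distinct")


@dataclass
class SimConfig:
    """Study design parameters for one simulated experiment.

    ``selfing_generations`` counts meioses beyond the F1 (7 gives an F8
    panel).  ``residual_sd`` maps trait -> SD, or trait -> {env: SD}.
    ``restorer`` is a (chromosome, cM) locus whose donor allele restores
    testcross pollen fertility, or None.
    """

    n_lines: int
    seed: int
    selfing_generations: int = 7
    environments: Mapping[str, float] = field(default_factory=lambda: {"E1": 0.0})
    replicates: int = 2
    trait_means: Mapping[str, float] = field(default_factory=lambda: {"trait": 0.0})
    residual_sd: Mapping[str, float | Mapping[str, float]] = field(
        default_factory=lambda: {"trait": 1.0}
    )
    restorer: tuple[str, float] | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")
        for t, sd in self.residual_sd.items():
            vals = sd.values() if isinstance(sd, Mapping) else [sd]
            if any(v < 0 for v in vals):
                raise ValueError(f"residual SD for {t} must be >= 0")

    def sd_for(self, trait: str, env: str) -> float:
        sd = self.residual_sd[trait]
        if isinstance(sd, Mapping):
            return float(sd[env])
        return float(sd)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream derived from the run seed."""
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())]))


# ---------------------------------------------------------------------------
# meiosis machinery
# ---------------------------------------------------------------------------

def _gametes(hap: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual from (n, 2, m) haplotypes.

    ``r`` holds the recombination fraction of each adjacent-marker interval;
    intervals recombine independently (no interference).
    """
    n, _, m = hap.shape
    start = rng.integers(0, 2, size=(n, 1), dtype=np.uint8)
    if m > 1:
        switch = (rng.random((n, m - 1)) < r).astype(np.uint8)
        choice = np.bitwise_xor.accumulate(np.concatenate([start, switch], axis=1), axis=1)
    else:
        choice = start
    return hap[np.arange(n)[:, None], choice, np.arange(m)[None, :]]


def simulate_ril_genotypes(map_spec: GeneticMapSpec, config: SimConfig) -> MarkerMatrix:
    """Simulate an F(1 + selfing_generations) RIL panel by single-seed descent.

    Each line starts from the fully heterozygous F1 and is selfed for the
    configured number of generations; each generation unites two independent
    gametes of the current plant.  Residual heterozygosity is retained.
    """
    rng = stage_rng(config.seed, "ril")
    mm = map_spec.marker_table()
    n = config.n_lines
    blocks = []
    for ch in map_spec.chromosomes:
        sub = mm[mm["chrom"] == ch.id]
        r = haldane_r_from_cm(np.diff(sub["cm"].to_numpy()))
        m = len(sub)
        hap = np.empty((n, 2, m), dtype=np.uint8)
        hap[:, 0, :] = 0  # recurrent-parent haplotype
        hap[:, 1, :] = 1  # donor haplotype
        for _ in range(config.selfing_generations):
            g1 = _gametes(hap, r, rng)
            g2 = _gametes(hap, r, rng)
            hap = np.stack([g1, g2], axis=1)
        blocks.append(hap.sum(axis=1).astype(np.int16))  # 0/1/2 = B/het/W
    codes = np.concatenate(blocks, axis=1)
    if config.missing_rate > 0:
        drop = rng.random(codes.shape) < config.missing_rate
        codes[drop] = MISSING
    lines = [f"RIL{i + 1:05d}" for i in range(n)]
    return MarkerMatrix(pd.DataFrame(codes, index=lines, columns=mm.index), mm)


def cross_to_bc1f1(rils: MarkerMatrix, config: SimConfig) -> MarkerMatrix:
    """Testcross each RIL to the recurrent parent (fixed for the recurrent
    allele at every locus).

    The RIL gamete is sampled per locus: homozygous loci transmit their
    allele, residual heterozygous loci transmit either allele with
    probability 1/2.  United with a pure recurrent gamete this yields a
    recurrent homozygote or a heterozygote; missing RIL calls stay missing.
    """
    if rils.n_lines == 0:
        raise ValueError("empty RIL matrix")
    rng = stage_rng(config.seed, "bc1f1")
    g = rils.genotypes.to_numpy()
    donor_gamete = np.zeros_like(g)
    donor_gamete[g == HOM_DONOR] = 1
    het = g == HET
    donor_gamete[het] = rng.integers(0, 2, size=int(het.sum()))
    out = np.where(donor_gamete == 1, HET, HOM_RECURRENT).astype(np.int16)
    out[g == MISSING] = MISSING
    return MarkerMatrix(
        pd.DataFrame(out, index=rils.line_ids, columns=rils.marker_ids),
        rils.marker_map.copy(),
    )


def _nearest_marker(marker_map: pd.DataFrame, chrom: str, pos_cm: float) -> str:
    sub = marker_map[marker_map["chrom"] == chrom]
    if sub.empty:
        raise ValueError(f"chromosome {chrom!r} not on the map")
    lo, hi = sub["cm"].min(), sub["cm"].max()
    if not (lo - 1e-9 <= pos_cm <= hi + 1e-9):
        raise ValueError(f"position {pos_cm} cM outside chromosome {chrom} ({lo}-{hi} cM)")
    return (sub["cm"] - pos_cm).abs().idxmin()


def genetic_values(
    genos: MarkerMatrix,
    qtl: Sequence[QTLSpec],
    epi: Sequence[EpistasisSpec] = (),
    trait: str | None = None,
    env: str | None = None,
) -> pd.Series:
    """Per-line genetic value sum(a*x + d*z) + sum(aa * x_j * x_k).

    x counts donor alleles minus recurrent alleles (-1/0/+1), z indicates the
    heterozygote; missing genotypes contribute 0 (the population mean).
    """
    g = genos.genotypes
    x_all = (g.to_numpy() - 1).astype(float)
    x_all[g.to_numpy() == MISSING] = 0.0
    z_all = (g.to_numpy() == HET).astype(float)
    cols = {m: k for k, m in enumerate(genos.marker_ids)}
    val = np.zeros(genos.n_lines)
    for q in qtl:
        if trait is not None and q.trait != trait:
            continue
        k = cols[_nearest_marker(genos.marker_map, q.chrom, q.pos_cm)]
        s = q.scale(env) if env is not None else 1.0
        val += s * (q.a * x_all[:, k] + q.d * z_all[:, k])
    for e in epi:
        if trait is not None and e.trait != trait:
            continue
        k1 = cols[_nearest_marker(genos.marker_map, *e.locus1)]
        k2 = cols[_nearest_marker(genos.marker_map, *e.locus2)]
        val += e.aa * x_all[:, k1] * x_all[:, k2]
    return pd.Series(val, index=genos.line_ids)


def simulate_phenotypes(
    genos: MarkerMatrix,
    qtl: Sequence[QTLSpec],
    epi: Sequence[EpistasisSpec],
    config: SimConfig,
    rng_stage: str = "pheno",
) -> pd.DataFrame:
    """Replicated long-format phenotypes (line, trait, env, rep, value).

    Each replicate value is mean + genetic value + environment offset +
    Normal(0, residual SD) noise; deterministic for a fixed config seed.
    """
    for q in qtl:
        if q.trait not in config.trait_means:
            raise ValueError(f"QTL trait {q.trait!r} absent from config.trait_means")
    for e in epi:
        if e.trait not in config.trait_means:
            raise ValueError(f"epistasis trait {e.trait!r} absent from config.trait_means")
    rng = stage_rng(config.seed, rng_stage)
    records = []
    n = genos.n_lines
    for trait, mu in config.trait_means.items():
        for env, offset in config.environments.items():
            gv = genetic_values(genos, qtl, epi, trait=trait, env=env).to_numpy()
            sd = config.sd_for(trait, env)
            for rep in range(1, config.replicates + 1):
                noise = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
                vals = mu + gv + offset + noise
                records.append(
                    pd.DataFrame(
                        {
                            "line": genos.line_ids,
                            "trait": trait,
                            "env": env,
                            "rep": rep,
                            "value": vals,
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)


def simulate_fertility(
    genos: MarkerMatrix,
    restorer: tuple[str, float] | None,
    fertile_mean: float = 0.85,
    sterile_mean: float = 0.30,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Testcross pollen fertility per line.

    Lines whose RIL parent carries at least one donor (restorer) allele at
    the restorer locus are drawn around ``fertile_mean`` (> 0.7), the rest
    around ``sterile_mean`` (< 0.7); values are clipped to [0, 1].  With no
    restorer locus all testcrosses are fully fertile.
    """
    if restorer is None:
        return pd.Series(1.0, index=genos.line_ids)
    if not 0.7 < fertile_mean <= 1.0:
        raise ValueError("fertile_mean must lie in (0.7, 1]")
    if not 0.0 <= sterile_mean < 0.7:
        raise ValueError("sterile_mean must lie in [0, 0.7)")
    marker = _nearest_marker(genos.marker_map, *restorer)
    codes = genos.genotypes[marker].to_numpy()
    carrier = (codes == HOM_DONOR) | (codes == HET)
    base = np.where(carrier, fertile_mean, sterile_mean)
    if noise_sd > 0:
        rng = stage_rng(seed, "fertility")
        base = base + rng.normal(0.0, noise_sd, size=len(base))
    return pd.Series(np.clip(base, 0.0, 1.0), index=genos.line_ids)


def residual_sd_for_heritability(
    genos: MarkerMatrix,
    qtl: Sequence[QTLSpec],
    trait: str,
    h2: float,
    replicates: int,
    epi: Sequence[EpistasisSpec] = (),
    env: str | None = None,
) -> float:
    """Residual SD giving a target line-mean broad-sense heritability.

    From the generating model's variance decomposition: with genetic variance
    Vg realized in this panel and r replicates, H2 = Vg / (Vg + Ve/r), so
    Ve = Vg * r * (1 - H2) / H2.
    """
    if not 0 < h2 <= 1:
        raise ValueError("heritability must lie in (0, 1]")
    gv = genetic_values(genos, qtl, epi, trait=trait, env=env)
    vg = float(gv.var(ddof=1))
    if vg == 0:
        raise ValueError("no genetic variance for this trait; heritability target unreachable")
    if h2 == 1:
        return 0.0
    return float(np.sqrt(vg * replicates * (1.0 - h2) / h2))
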