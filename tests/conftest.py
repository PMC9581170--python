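"""Shared fixtures: small simulated panels and hand-built marker matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import heteroqtl as hq


def make_matrix(codes, chroms, cms, bps=None, lines=None, markers=None) -> hq.MarkerMatrix:
    """Hand-build a MarkerMatrix from a nested list of codes (lines x markers)."""
    codes = np.asarray(codes, dtype=np.int16)
    n, p = codes.shape
    markers = markers or [f"m{j}" for j in range(p)]
    lines = lines or [f"L{i}" for i in range(n)]
    bps = bps if bps is not None else [int(c * 250_000) + j + 1 for j, c in enumerate(cms)]
    mm = pd.DataFrame(
        {"chrom": chroms, "cm": [float(c) for c in cms], "bp": bps}, index=markers
    )
    return hq.MarkerMatrix(pd.DataFrame(codes, index=lines, columns=markers), mm)


def strip_heterozygotes(m: hq.MarkerMatrix) -> hq.MarkerMatrix:
    """Replace residual heterozygous calls by recurrent homozygotes so every
    bin is fully informative for the two-homozygote mixture."""
    g = m.genotypes.to_numpy().copy()
    g[g == hq.HET] = hq.HOM_RECURRENT
    return hq.MarkerMatrix(
        pd.DataFrame(g, index=m.line_ids, columns=m.marker_ids), m.marker_map
    )


@pytest.fixture(scope="session")
def five_chrom_map() -> hq.GeneticMapSpec:
    return hq.GeneticMapSpec(
        [hq.ChromosomeSpec(f"chr{i}", 100.0, 41) for i in range(1, 6)]
    )


@pytest.fixture(scope="session")
def calibration_map() -> hq.GeneticMapSpec:
    """200 bins: five chromosomes x 40 markers at 2.5 cM spacing."""
    return hq.GeneticMapSpec(
        [hq.ChromosomeSpec(f"chr{i}", 97.5, 40) for i in range(1, 6)]
    )


@pytest.fixture(scope="session")
def ril_300(calibration_map) -> hq.MarkerMatrix:
    cfg = hq.SimConfig(n_lines=300, seed=20240301)
    return hq.simulate_ril_genotypes(calibration_map, cfg)


@pytest.fixture(scope="session")
def ril_300_informative(ril_300) -> hq.MarkerMatrix:
    return strip_heterozygotes(ril_300)
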