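"""Plain-text interchange formats shared by all stages.

* genotype TSV: lines x markers, first column ``line``, header row of marker
  ids, integer codes {0,1,2,-9};
* map TSV: columns ``marker``, ``chrom``, ``cm``, ``bp``;
* phenotype CSV: long format ``line,trait,env,rep,value``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .genotypes import MarkerMatrix
from .phenotypes import PHENO_COLUMNS, validate_trait_table


def write_genotypes(m: MarkerMatrix, geno_path, map_path) -> None:
    m.genotypes.to_csv(geno_path, sep="\t", index_label="line")
    m.marker_map.to_csv(map_path, sep="\t", index_label="marker")


def read_genotypes(geno_path, map_path) -> MarkerMatrix:
    geno = pd.read_csv(geno_path, sep="\t", index_col="line")
    mm = pd.read_csv(map_path, sep="\t", index_col="marker")
    return MarkerMatrix(geno, mm)


def write_phenotypes(t: pd.DataFrame, path) -> None:
    validate_trait_table(t)[PHENO_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return validate_trait_table(pd.read_csv(path))


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)
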