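"""Phenotype statistics for the heterosis study design: mid-parent heterosis,
hybrid-breakdown ratios, broad-sense heritability, trait correlations, the
restorer-line fertility filter, and the F1-vs-mid-parent t-test.

Phenotypes are long-format tables with columns ``line``, ``trait``, ``env``,
``rep``, ``value`` (one row per replicate measurement).  Environments are
always analyzed separately; a testcross line is keyed by the id of its
paternal RIL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

PHENO_COLUMNS = ["line", "trait", "env", "rep", "value"]

_MP_GUARD = 1e-8


def validate_trait_table(t: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENO_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    if t.duplicated(subset=["line", "trait", "env", "rep"]).any():
        raise ValueError("duplicate (line, trait, env, rep) keys in phenotype table")
    if not np.isfinite(t["value"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite phenotype values")
    return t


def line_means(t: pd.DataFrame, trait: str, env: str) -> pd.Series:
    sub = t[(t["trait"] == trait) & (t["env"] == env)]
    return sub.groupby("line")["value"].mean()


# ---------------------------------------------------------------------------
# heterosis
# ---------------------------------------------------------------------------

def mid_parent_heterosis(f1, p1, p2):
    """Mid-parent heterosis in percent: 100 * (F1 - MP) / MP, MP = (p1+p2)/2.

    Accepts scalars or aligned arrays; raises when |MP| is below 1e-8.
    """
    f1 = np.asarray(f1, dtype=float)
    mp = (np.asarray(p1, dtype=float) + np.asarray(p2, dtype=float)) / 2.0
    if np.any(np.abs(mp) <= _MP_GUARD):
        raise ValueError("mid-parent value is (near) zero; heterosis undefined")
    out = 100.0 * (f1 - mp) / mp
    return float(out) if out.ndim == 0 else out


def hybrid_breakdown_ratio(ril_mean: float, f1_value: float) -> float:
    """Inbred-panel mean as a percentage of the elite F1 hybrid value."""
    if f1_value == 0:
        raise ValueError("F1 value is zero; ratio undefined")
    return 100.0 * ril_mean / f1_value


def heterosis_table(
    bc1f1: pd.DataFrame,
    rils: pd.DataFrame,
    recurrent_values: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Per-testcross mid-parent heterosis from replicated phenotype tables.

    ``recurrent_values[trait][env]`` supplies the recurrent parent's trait
    value (in this design the sterile seed parent is represented by its
    fertile near-isogenic maintainer).  F1 and paternal-RIL values are
    replicate means within environment.  Returns one row per
    (line, trait, env) with F1, the parent values, MP and H_MP percent.
    """
    validate_trait_table(bc1f1)
    validate_trait_table(rils)
    f1 = bc1f1.groupby(["line", "trait", "env"])["value"].mean().rename("f1")
    pril = rils.groupby(["line", "trait", "env"])["value"].mean().rename("p_ril")
    df = pd.concat([f1, pril], axis=1, join="inner").reset_index()
    df["p_recurrent"] = [
        float(recurrent_values[t][e]) for t, e in zip(df["trait"], df["env"])
    ]
    df["mp"] = (df["p_ril"] + df["p_recurrent"]) / 2.0
    bad = df["mp"].abs() <= _MP_GUARD
    if bad.any():
        raise ValueError(f"{int(bad.sum())} testcrosses have (near) zero mid-parent value")
    df["hmp_pct"] = 100.0 * (df["f1"] - df["mp"]) / df["mp"]
    return df


def hmp_trait_table(het: pd.DataFrame) -> pd.DataFrame:
    """Reshape a heterosis table into the long phenotype format (one 'rep')
    so H_MP values can be scanned like any trait."""
    out = het[["line", "trait", "env", "hmp_pct"]].rename(columns={"hmp_pct": "value"})
    out["rep"] = 1
    return out[PHENO_COLUMNS]


# ---------------------------------------------------------------------------
# heritability / correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeritabilityResult:
    trait: str
    env: str
    sigma2_g: float
    sigma2_e: float
    replicates: float
    h2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("H2 outside [0, 1]")


def broad_sense_heritability(t: pd.DataFrame, trait: str, env: str) -> HeritabilityResult:
    """Line-mean broad-sense heritability from a one-way ANOVA across lines.

    sigma2_g = (MS_line - MS_error) / r (truncated at 0), sigma2_e = MS_error,
    H2 = sigma2_g / (sigma2_g + sigma2_e / r) with r the mean replicate count.
    Requires at least two lines and replicated measurements.
    """
    sub = t[(t["trait"] == trait) & (t["env"] == env)]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r} in env {env!r}")
    groups = sub.groupby("line")["value"]
    k = groups.ngroups
    N = len(sub)
    if k < 2:
        raise ValueError("need at least two lines")
    if N <= k:
        raise ValueError("single replicate: residual variance not estimable")
    r = N / k
    grand = sub["value"].mean()
    counts = groups.count()
    means = groups.mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((sub["value"] - means.reindex(sub["line"]).to_numpy()) ** 2).sum())
    ms_line = ss_between / (k - 1)
    ms_err = ss_within / (N - k)
    sigma2_g = max((ms_line - ms_err) / r, 0.0)
    h2 = sigma2_g / (sigma2_g + ms_err / r) if (sigma2_g + ms_err / r) > 0 else 0.0
    return HeritabilityResult(trait, env, sigma2_g, ms_err, r, h2)


def correlate_traits(
    t: pd.DataFrame,
    env: str | tuple[str, str],
    traits: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations of line means with two-sided p-values.

    With a single environment: full trait-by-trait matrix within that
    environment.  With an environment pair: the same-trait between-environment
    correlations on the diagonal (off-diagonal left missing) — the layout used
    when reporting cross-location trait stability.  Constant vectors give NaN.
    """
    validate_trait_table(t)
    if traits is None:
        traits = sorted(t["trait"].unique())
    r_mat = pd.DataFrame(np.nan, index=traits, columns=traits, dtype=float)
    p_mat = r_mat.copy()

    def _corr(x: pd.Series, y: pd.Series):
        common = x.index.intersection(y.index)
        if len(common) < 3:
            raise ValueError("need at least 3 shared lines for a correlation")
        xv, yv = x[common].to_numpy(), y[common].to_numpy()
        if np.std(xv) == 0 or np.std(yv) == 0:
            return np.nan, np.nan
        res = stats.pearsonr(xv, yv)
        return float(res.statistic), float(res.pvalue)

    if isinstance(env, tuple):
        e1, e2 = env
        for trait in traits:
            r_mat.loc[trait, trait], p_mat.loc[trait, trait] = _corr(
                line_means(t, trait, e1), line_means(t, trait, e2)
            )
    else:
        means = {trait: line_means(t, trait, env) for trait in traits}
        for i, ti in enumerate(traits):
            for tj in traits[i:]:
                r, p = _corr(means[ti], means[tj])
                r_mat.loc[ti, tj] = r_mat.loc[tj, ti] = r
                p_mat.loc[ti, tj] = p_mat.loc[tj, ti] = p
    return r_mat, p_mat


# ---------------------------------------------------------------------------
# restorer filter and H_MP significance
# ---------------------------------------------------------------------------

def filter_restorers(fertility: pd.Series, threshold: float = 0.70) -> pd.Index:
    """Lines whose testcross fertility strictly exceeds the threshold.

    These are the RILs deemed to carry the restorer gene; yield scans are
    restricted to them while other traits use the full panel.  Exactly 0.70
    is excluded ("more than 70%" read strictly).
    """
    if ((fertility < 0) | (fertility > 1)).any():
        raise ValueError("fertility values must lie in [0, 1]")
    kept = fertility.index[fertility > threshold]
    if len(kept) == 0:
        warnings.warn(
            "no restorer lines passed the fertility filter; "
            "yield-trait scans will be skipped",
            stacklevel=2,
        )
    return kept


def hmp_significance(f1_values, mid_parent_values) -> tuple[float, float]:
    """Two-sided t-test of F1 replicate values against mid-parent values.

    Returns (t, p).  Identical groups give (0, 1); groups that are both
    constant but different are rejected (no within-group variance to test
    against), as is any group with fewer than two observations.
    """
    a = np.asarray(f1_values, dtype=float)
    b = np.asarray(mid_parent_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    if np.std(a) == 0 and np.std(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)
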