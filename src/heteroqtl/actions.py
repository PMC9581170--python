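"""Cross-population QTL matching and gene-action classification.

A locus mapped in the RIL panel estimates its additive effect a; mapped in
the testcross (BC1F1) panel it estimates a+d; mapped on mid-parent-heterosis
values it reflects the dominance effect d.  Matching detections of the same
trait/environment across the three datasets therefore lets each locus be
classified:

* **A** (additive) — detected in only one of RIL / BC1F1;
* **ID** (incomplete dominant) — dominance ratio |2d/(a+d)| < 1;
* **OD** (overdominant) — |2d/(a+d)| > 1, or detected only in the heterosis
  dataset;
* **UD** (underdominant) — dominance opposing the trait-increasing allele
  (oriented d < 0), overriding ID/OD.

When both the RIL and testcross effects are available, d is derived on the
trait scale as (a+d) - a.  A heterosis-scan effect is in percent units and is
used only for detection and sign, never mixed into the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

POPULATIONS = ("RIL", "BC1F1", "HMP")
CLASSES = ("A", "ID", "OD", "UD")

CALL_COLUMNS = [
    "trait", "env", "population", "chrom", "peak_cm", "lod", "pve", "effect",
    "ci_lo_cm", "ci_hi_cm", "ci_lo_bp", "ci_hi_bp",
]


@dataclass
class QTLCluster:
    """Detections of one locus (same trait and environment) across datasets."""

    trait: str
    env: str
    chrom: str
    members: pd.DataFrame  # rows of CALL_COLUMNS

    @property
    def populations(self) -> frozenset:
        return frozenset(self.members["population"])

    def _effect(self, population: str) -> float | None:
        sub = self.members[self.members["population"] == population]
        if sub.empty:
            return None
        return float(sub.loc[sub["lod"].idxmax(), "effect"])

    @property
    def a_hat(self) -> float | None:
        return self._effect("RIL")

    @property
    def ad_hat(self) -> float | None:
        return self._effect("BC1F1")

    @property
    def hmp_effect(self) -> float | None:
        return self._effect("HMP")

    @property
    def d_hat(self) -> float | None:
        """Dominance on the trait scale when derivable, else the heterosis-scan
        effect (percent scale, flagged by :attr:`d_source`)."""
        if self.a_hat is not None and self.ad_hat is not None:
            return self.ad_hat - self.a_hat
        return self.hmp_effect

    @property
    def d_source(self) -> str | None:
        if self.a_hat is not None and self.ad_hat is not None:
            return "derived"
        if self.hmp_effect is not None:
            return "hmp"
        return None

    @property
    def dominance_ratio(self) -> float | None:
        """|2d/(a+d)| on the trait scale; None when the scales cannot be mixed."""
        if self.d_source != "derived":
            return None
        ad = self.ad_hat
        if ad == 0:
            return np.inf
        return abs(2.0 * self.d_hat / ad)

    @property
    def peak_cm(self) -> float:
        return float(self.members.loc[self.members["lod"].idxmax(), "peak_cm"])

    def interval_cm(self) -> tuple[float, float]:
        return float(self.members["ci_lo_cm"].min()), float(self.members["ci_hi_cm"].max())

    def interval_bp(self) -> tuple[int, int]:
        return int(self.members["ci_lo_bp"].min()), int(self.members["ci_hi_bp"].max())


@dataclass(frozen=True)
class GeneActionRecord:
    cluster: QTLCluster
    gene_action: str

    def __post_init__(self) -> None:
        if self.gene_action not in CLASSES:
            raise ValueError(f"unknown class {self.gene_action!r}")


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _calls_overlap(a, b, peak_tol_cm: float) -> bool:
    if a["chrom"] != b["chrom"]:
        return False
    if abs(a["peak_cm"] - b["peak_cm"]) <= peak_tol_cm:
        return True
    return a["ci_lo_cm"] <= b["ci_hi_cm"] and b["ci_lo_cm"] <= a["ci_hi_cm"]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def match_qtl(calls: pd.DataFrame, peak_tol_cm: float = 5.0) -> list[QTLCluster]:
    """Group same-trait, same-environment calls into loci.

    Calls on one chromosome whose support intervals overlap, or whose peaks
    lie within ``peak_tol_cm``, join the same cluster (transitive closure).
    Clusters are returned in deterministic (trait, env, chrom, peak) order.
    """
    if calls.empty:
        return []
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"calls table lacks columns {missing}")
    clusters: list[QTLCluster] = []
    for (trait, env), sub in calls.groupby(["trait", "env"], sort=True):
        sub = sub.sort_values(["chrom", "peak_cm"]).reset_index(drop=True)
        uf = _UnionFind(len(sub))
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                if _calls_overlap(sub.iloc[i], sub.iloc[j], peak_tol_cm):
                    uf.union(i, j)
        groups: dict[int, list[int]] = {}
        for i in range(len(sub)):
            groups.setdefault(uf.find(i), []).append(i)
        for members in sorted(groups.values(), key=lambda ix: ix[0]):
            rows = sub.iloc[members].reset_index(drop=True)
            clusters.append(QTLCluster(trait, env, rows["chrom"].iloc[0], rows))
    return clusters


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_gene_action(c: QTLCluster) -> GeneActionRecord:
    """Assign one of A / ID / OD / UD to a cluster (exhaustive partition).

    Rules: detection in only RIL or only BC1F1 is additive.  Any cluster
    with evidence of dominance (both RIL and BC1F1, or heterosis plus any
    dataset, or heterosis alone) is rated by the dominance ratio when d is
    derivable on the trait scale (<1 incomplete dominance, >=1 treated as
    incomplete at exactly 1, >1 overdominance) or called overdominant when
    the heterosis scan is the only dominance source; dominance oriented
    against the trait-increasing allele overrides either to underdominant.
    """
    pops = c.populations
    if not pops:
        raise ValueError("cluster has no members")
    if c.members["effect"].isna().all():
        raise ValueError("cluster has no effect estimates")
    if pops in ({"RIL"}, {"BC1F1"}) or pops in (frozenset({"RIL"}), frozenset({"BC1F1"})):
        return GeneActionRecord(c, "A")

    # dominance evidence present
    d = c.d_hat
    if d is None:
        raise ValueError("cluster has no dominance estimate")
    a_ref = c.a_hat if c.a_hat is not None else c.ad_hat
    orient = np.sign(a_ref) if a_ref not in (None, 0) else 1.0
    oriented_d = d * orient

    rho = c.dominance_ratio
    if rho is None:
        klass = "OD"  # heterosis-only dominance evidence
    elif rho <= 1.0:
        klass = "ID"  # ties at exactly 1 fall to incomplete dominance
    else:
        klass = "OD"
    if oriented_d < 0:
        klass = "UD"
    return GeneActionRecord(c, klass)


def gene_action_table(records: list[GeneActionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.cluster
        lo_bp, hi_bp = c.interval_bp()
        rows.append(
            {
                "trait": c.trait,
                "env": c.env,
                "chrom": c.chrom,
                "peak_cm": c.peak_cm,
                "populations": "+".join(sorted(c.populations)),
                "a_hat": c.a_hat,
                "ad_hat": c.ad_hat,
                "d_hat": c.d_hat,
                "d_source": c.d_source,
                "dominance_ratio": c.dominance_ratio,
                "gene_action": r.gene_action,
                "ci_lo_bp": lo_bp,
                "ci_hi_bp": hi_bp,
                "max_lod": float(c.members["lod"].max()),
            }
        )
    cols = [
        "trait", "env", "chrom", "peak_cm", "populations", "a_hat", "ad_hat",
        "d_hat", "d_source", "dominance_ratio", "gene_action",
        "ci_lo_bp", "ci_hi_bp", "max_lod",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# cross-environment and multi-trait comparisons
# ---------------------------------------------------------------------------

def compare_environments(
    clusters_by_env: dict[str, list[QTLCluster]], peak_tol_cm: float = 5.0
) -> pd.DataFrame:
    """Label each cluster common (matched in the other environment for the
    same trait, same matching rule) or environment-specific."""
    envs = list(clusters_by_env)
    if len(envs) != 2:
        raise ValueError("exactly two environments are required")

    def _matches(c: QTLCluster, others: list[QTLCluster]) -> bool:
        lo, hi = c.interval_cm()
        for o in others:
            if o.trait != c.trait or o.chrom != c.chrom:
                continue
            olo, ohi = o.interval_cm()
            if abs(o.peak_cm - c.peak_cm) <= peak_tol_cm or (lo <= ohi and olo <= hi):
                return True
        return False

    rows = []
    for env in envs:
        other = envs[1] if env == envs[0] else envs[0]
        for c in clusters_by_env[env]:
            rows.append(
                {
                    "trait": c.trait,
                    "env": env,
                    "chrom": c.chrom,
                    "peak_cm": c.peak_cm,
                    "status": "common" if _matches(c, clusters_by_env[other]) else "specific",
                }
            )
    return pd.DataFrame(rows, columns=["trait", "env", "chrom", "peak_cm", "status"])


def environment_overlap_summary(comparison: pd.DataFrame) -> pd.DataFrame:
    """Per-trait counts and the proportion of environment-common clusters."""
    rows = []
    for trait, sub in comparison.groupby("trait", sort=True):
        n = len(sub)
        n_common = int((sub["status"] == "common").sum())
        rows.append(
            {
                "trait": trait,
                "n_clusters": n,
                "n_common": n_common,
                "pct_common": 100.0 * n_common / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["trait", "n_clusters", "n_common", "pct_common"])


def find_multitrait_regions(
    calls: pd.DataFrame,
    orientation: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Merge physically overlapping QTL intervals spanning >= 2 distinct traits.

    ``orientation[trait]`` is +1 when a larger trait value is favorable and
    -1 otherwise (default +1).  The favorable-allele direction of each member
    is sign(effect) * orientation; a region is flagged ``same`` when all its
    traits agree after orientation, else ``opposite``.
    """
    if calls.empty:
        return pd.DataFrame(
            columns=["chrom", "start_bp", "end_bp", "traits", "direction", "n_calls"]
        )
    orientation = orientation or {}
    sub = calls.reset_index(drop=True)
    uf = _UnionFind(len(sub))
    for i in range(len(sub)):
        for j in range(i + 1, len(sub)):
            a, b = sub.iloc[i], sub.iloc[j]
            if (
                a["chrom"] == b["chrom"]
                and a["ci_lo_bp"] <= b["ci_hi_bp"]
                and b["ci_lo_bp"] <= a["ci_hi_bp"]
            ):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(sub)):
        groups.setdefault(uf.find(i), []).append(i)
    rows = []
    for members in sorted(groups.values(), key=lambda ix: ix[0]):
        rows_df = sub.iloc[members]
        traits = sorted(rows_df["trait"].unique())
        if len(traits) < 2:
            continue
        dirs = {
            t: set(
                np.sign(rows_df.loc[rows_df["trait"] == t, "effect"])
                * orientation.get(t, 1)
            )
            for t in traits
        }
        flat = {d for s in dirs.values() for d in s if d != 0}
        direction = "same" if len(flat) <= 1 else "opposite"
        rows.append(
            {
                "chrom": rows_df["chrom"].iloc[0],
                "start_bp": int(rows_df["ci_lo_bp"].min()),
                "end_bp": int(rows_df["ci_hi_bp"].max()),
                "traits": "+".join(traits),
                "direction": direction,
                "n_calls": len(rows_df),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "traits", "direction", "n_calls"]
    )


def summarize_epistasis_overlap(
    pairs_a: pd.DataFrame,
    pairs_b: pd.DataFrame,
    grid_step_cm: float = 5.0,
) -> float:
    """Percent of locus pairs common to two epistasis scans.

    Pairs match when both loci agree within one grid step (order-free);
    the denominator is the union of the two pair sets, counting each matched
    pair once: 100 * |common| / (|A| + |B| - |common|).
    """
    if len(pairs_a) == 0 and len(pairs_b) == 0:
        return 0.0
    tol = grid_step_cm + 1e-6
    matched_b: set[int] = set()
    common = 0
    for _, pa in pairs_a.iterrows():
        for k, (_, pb) in enumerate(pairs_b.iterrows()):
            if k in matched_b:
                continue
            if _pair_rows_match(pa, pb, tol):
                matched_b.add(k)
                common += 1
                break
    union = len(pairs_a) + len(pairs_b) - common
    return 100.0 * common / union


def _pair_rows_match(a, b, tol: float) -> bool:
    def loci(p):
        return (
            (p["chrom1"], float(p["cm1"])),
            (p["chrom2"], float(p["cm2"])),
        )

    (a1, a2), (b1, b2) = loci(a), loci(b)

    def close(u, v):
        return u[0] == v[0] and abs(u[1] - v[1]) <= tol

    return (close(a1, b1) and close(a2, b2)) or (close(a1, b2) and close(a2, b1))


def flag_mqtl_involvement(
    epi: pd.DataFrame, calls: pd.DataFrame, tol_cm: float = 5.0
) -> pd.DataFrame:
    """Annotate each epistatic pair with how many of its loci fall inside a
    called main-effect QTL's support interval (0, 1 or 2)."""
    out = epi.copy()

    def _in_mqtl(chrom: str, cm: float) -> bool:
        sub = calls[calls["chrom"] == chrom]
        return bool(
            (
                (sub["ci_lo_cm"] - tol_cm <= cm) & (cm <= sub["ci_hi_cm"] + tol_cm)
            ).any()
        )

    out["n_mqtl_loci"] = [
        int(_in_mqtl(r["chrom1"], r["cm1"])) + int(_in_mqtl(r["chrom2"], r["cm2"]))
        for _, r in epi.iterrows()
    ]
    return out
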