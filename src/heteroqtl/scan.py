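"""Inclusive composite interval mapping (ICIM)-style QTL scans.

The 1-D scan follows the two-step ICIM scheme: (1) stepwise selection of
marker cofactors by forward entry / backward elimination on p-value
thresholds, (2) an interval scan of the cofactor-adjusted phenotype, where at
each position the QTL-class probabilities of every line are computed from the
flanking bins and a two-component normal mixture is maximized by EM.  LOD is
the base-10 log likelihood ratio against a single-normal null.

Designs: ``RIL`` (two homozygote classes, recombination fractions corrected
for the inbreeding accumulated by selfing), ``BC1F1`` (recurrent homozygote
vs heterozygote, genotypes deduced from the paternal RIL so they segregate
with RIL-type linkage), and ``HMP`` (mid-parent heterosis values attached to
the testcross genotypes; effects estimate dominance, units are percent).

The 2-D scan fits, on a coarse grid, a two-locus linear model with both main
effects plus an additive-by-additive interaction and reports pairs whose
interaction LOD clears the epistasis threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import (
    HET,
    HOM_DONOR,
    HOM_RECURRENT,
    MISSING,
    MarkerMatrix,
    haldane_r_from_cm,
    r_to_ril_discordance,
)

DESIGNS = ("RIL", "BC1F1", "HMP")


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    Defaults follow common ICIM practice for dense biparental maps: for the
    1-D scan PIN = 0.001, 1 cM steps and a LOD threshold of 3.0; use
    :meth:`for_epistasis` for the 2-D defaults (PIN = 0.0001, 5 cM grid,
    LOD 5.0).  POUT defaults to twice PIN.
    """

    design: str = "RIL"
    pin: float = 1e-3
    pout: float | None = None
    step_cm: float = 1.0
    lod_threshold: float = 3.0
    n_permutations: int = 1000
    alpha: float = 0.05
    min_pair_sep_cm: float = 20.0
    em_tol: float = 1e-6
    em_max_iter: int = 200

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")
        if not 0 < self.pin < 1:
            raise ValueError("pin must lie in (0, 1)")
        if self.pout is not None and self.pout < self.pin:
            raise ValueError("pout must be >= pin")
        if self.step_cm <= 0:
            raise ValueError("step_cm must be positive")

    @property
    def pout_effective(self) -> float:
        return self.pout if self.pout is not None else min(2 * self.pin, 0.999)

    @classmethod
    def for_epistasis(cls, design: str = "RIL", **kw) -> "ScanConfig":
        defaults = dict(design=design, pin=1e-4, step_cm=5.0, lod_threshold=5.0)
        defaults.update(kw)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# genotype encodings
# ---------------------------------------------------------------------------

def encode_genotypes(m: MarkerMatrix, design: str) -> tuple[np.ndarray, np.ndarray]:
    """Numeric regression scores X and mixture states S for a design.

    X: RIL codes 0/2 -> -1/+1 (het -> 0); testcross designs code the
    heterozygote as 1 against 0 for the recurrent homozygote.  Missing values
    are imputed to the column mean.  S holds the two-class state per line
    (0 = recurrent-type, 1 = donor-type, -1 = uninformative) used for
    interval-scan class probabilities; RIL heterozygotes are uninformative
    for the two-homozygote mixture.
    """
    g = m.genotypes.to_numpy()
    n, p = g.shape
    S = np.full((n, p), -1, dtype=np.int8)
    X = np.zeros((n, p), dtype=float)
    if design == "RIL":
        S[g == HOM_RECURRENT] = 0
        S[g == HOM_DONOR] = 1
        X[g == HOM_RECURRENT] = -1.0
        X[g == HOM_DONOR] = 1.0
        observed = g != MISSING
    elif design in ("BC1F1", "HMP"):
        if np.any(g == HOM_DONOR):
            raise ValueError("testcross data cannot contain donor homozygotes")
        S[g == HOM_RECURRENT] = 0
        S[g == HET] = 1
        X[g == HET] = 1.0
        observed = g != MISSING
    else:
        raise ValueError(f"unknown design {design!r}")
    # mean-impute missing scores
    with np.errstate(invalid="ignore"):
        col_mean = np.where(
            observed.any(axis=0),
            np.where(observed, X, 0.0).sum(axis=0) / observed.sum(axis=0),
            0.0,
        )
    X = np.where(observed, X, col_mean)
    return X, S


# ---------------------------------------------------------------------------
# cofactor selection (ICIM step 1)
# ---------------------------------------------------------------------------

@dataclass
class CofactorModel:
    """Stepwise-selected marker cofactors with their joint-fit coefficients."""

    markers: list[str]
    indices: list[int]
    coef: np.ndarray            # per selected marker, joint fit
    x_centered: np.ndarray      # n x k centered scores of selected markers
    y_mean: float

    def adjust(self, y: np.ndarray, exclude: set[str] = frozenset()) -> np.ndarray:
        """Phenotype minus fitted effects of all cofactors not excluded."""
        keep = [k for k, mk in enumerate(self.markers) if mk not in exclude]
        if not keep:
            return y.copy()
        return y - self.x_centered[:, keep] @ self.coef[keep]


def _stepwise(X: np.ndarray, y: np.ndarray, pin: float, pout: float) -> list[int]:
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    colss = np.maximum((Xc * Xc).sum(axis=0), 1e-30)
    selected: list[int] = []
    Q = np.empty((n, 0))
    resid = yc.copy()
    for _ in range(min(n, p) + 1):
        changed = False
        # forward entry
        if n > len(selected) + 3 and len(selected) < p:
            E = Xc - Q @ (Q.T @ Xc)
            ss = (E * E).sum(axis=0)
            valid = ss > 1e-10 * colss
            valid[selected] = False
            if valid.any():
                rss = float(resid @ resid)
                num = np.zeros(p)
                num[valid] = (E[:, valid].T @ resid) ** 2 / ss[valid]
                df = n - len(selected) - 2
                with np.errstate(divide="ignore", invalid="ignore"):
                    F = num * df / np.maximum(rss - num, 1e-300)
                pvals = np.where(valid, stats.f.sf(F, 1, df), np.inf)
                j = int(np.argmin(pvals))  # ties -> lowest map position
                if pvals[j] <= pin:
                    qv = E[:, j] / np.sqrt(ss[j])
                    Q = np.column_stack([Q, qv])
                    resid = resid - qv * (qv @ resid)
                    selected.append(j)
                    changed = True
        elif n <= len(selected) + 3:
            warnings.warn("cofactor entry stopped: too few lines", stacklevel=2)
        # backward elimination
        while len(selected) > 0:
            Xs = Xc[:, selected]
            beta, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
            res = yc - Xs @ beta
            dfe = n - len(selected) - 1
            if dfe <= 0:
                break
            s2 = float(res @ res) / dfe
            cov = s2 * np.linalg.pinv(Xs.T @ Xs)
            se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
            pvals = 2 * stats.t.sf(np.abs(beta / se), dfe)
            worst = int(np.argmax(pvals))
            if pvals[worst] > pout:
                selected.pop(worst)
                Q, _ = (
                    np.linalg.qr(Xc[:, selected])
                    if selected
                    else (np.empty((n, 0)), None)
                )
                resid = yc - Q @ (Q.T @ yc)
                changed = True
            else:
                break
        if not changed:
            break
    return selected


def select_cofactors(m: MarkerMatrix, y: pd.Series, cfg: ScanConfig) -> CofactorModel:
    """Forward-backward stepwise marker selection (enter at p <= PIN, remove
    at p > POUT); deterministic, ties resolved to the lowest map position."""
    yv = y.loc[m.line_ids].to_numpy(dtype=float)
    X, _ = encode_genotypes(m, cfg.design)
    idx = _stepwise(X, yv, cfg.pin, cfg.pout_effective)
    idx = sorted(idx)
    markers = [m.marker_ids[i] for i in idx]
    Xc = X[:, idx] - X[:, idx].mean(axis=0) if idx else np.empty((len(yv), 0))
    if idx:
        coef, *_ = np.linalg.lstsq(Xc, yv - yv.mean(), rcond=None)
    else:
        coef = np.empty(0)
    return CofactorModel(markers, idx, coef, Xc, float(yv.mean()))


def adjust_phenotype(
    y: pd.Series, model: CofactorModel, exclude_markers=frozenset()
) -> pd.Series:
    """Subtract fitted cofactor effects, keeping any cofactor inside or
    flanking the scanned interval (passed via ``exclude_markers``) intact."""
    adj = model.adjust(y.to_numpy(dtype=float), set(exclude_markers))
    return pd.Series(adj, index=y.index)


# ---------------------------------------------------------------------------
# interval scan (ICIM step 2)
# ---------------------------------------------------------------------------

def _mixture_em(
    W: np.ndarray, Y: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-component equal-variance normal-mixture EM.

    W: (P, n, 2) per-line class priors per scan position; Y: (P, n) adjusted
    phenotypes.  Returns (lod, mu, pve) per position.
    """
    P, n, _ = W.shape
    ybar = Y.mean(axis=1, keepdims=True)
    s0 = np.maximum(((Y - ybar) ** 2).mean(axis=1), 1e-300)
    ll0 = -0.5 * n * (np.log(2 * np.pi * s0) + 1.0)
    wsum = W.sum(axis=1)
    mu = (W * Y[:, :, None]).sum(axis=1) / np.maximum(wsum, 1e-12)
    mu = np.where(wsum < 1e-9, ybar, mu)
    sig2 = s0.copy()
    logW = np.log(np.clip(W, 1e-300, None))
    ll = np.full(P, -np.inf)
    for _ in range(max_iter):
        ll_prev = ll
        diff = Y[:, :, None] - mu[:, None, :]
        logphi = -0.5 * diff**2 / sig2[:, None, None] - 0.5 * np.log(
            2 * np.pi * sig2
        )[:, None, None]
        a = logW + logphi
        amax = a.max(axis=2, keepdims=True)
        lse = amax[..., 0] + np.log(np.exp(a - amax).sum(axis=2))
        ll = lse.sum(axis=1)
        gamma = np.exp(a - lse[:, :, None])
        gsum = gamma.sum(axis=1)
        mu = (gamma * Y[:, :, None]).sum(axis=1) / np.maximum(gsum, 1e-12)
        mu = np.where(gsum < 1e-9, ybar, mu)
        sig2 = (gamma * (Y[:, :, None] - mu[:, None, :]) ** 2).sum(axis=(1, 2)) / n
        sig2 = np.maximum(sig2, 1e-12 * s0)
        if np.all(np.abs(ll - ll_prev) < tol):
            break
    lod = (ll - ll0) / np.log(10.0)
    bad = ~np.isfinite(lod)
    if bad.any():
        warnings.warn(f"skipped {int(bad.sum())} scan positions (non-finite likelihood)")
    lod = np.where(bad, np.nan, np.maximum(lod, 0.0))
    pve = np.clip(100.0 * (1.0 - sig2 / s0), 0.0, 100.0)
    return lod, mu, pve


def _flank_probs(S: np.ndarray, cms: np.ndarray, t: float) -> np.ndarray:
    """P(QTL class | flanking bin states) at position t, per line.

    Transitions between loci use the RIL-panel discordance 2r/(1+2r) of the
    Haldane recombination fraction for the separating distance; uninformative
    flanks contribute nothing, so lines missing at both flanks fall back to
    the 0.5/0.5 design prior.
    """
    n, B = S.shape
    iL = min(max(int(np.searchsorted(cms, t + 1e-9)) - 1, 0), B - 1)
    iR = min(int(np.searchsorted(cms, t - 1e-9)), B - 1)
    flanks = [(iL, abs(t - cms[iL]))]
    if iR != iL:
        flanks.append((iR, abs(cms[iR] - t)))
    f1 = np.ones(n)
    f0 = np.ones(n)
    for i, d in flanks:
        rho = float(r_to_ril_discordance(haldane_r_from_cm(d)))
        s = S[:, i]
        f1 *= np.where(s == 1, 1.0 - rho, np.where(s == 0, rho, 1.0))
        f0 *= np.where(s == 0, 1.0 - rho, np.where(s == 1, rho, 1.0))
    w = np.stack([f0, f1], axis=-1) * 0.5
    return w / w.sum(axis=1, keepdims=True)


def _chromosome_grid(cms: np.ndarray, step: float) -> np.ndarray:
    grid = np.arange(cms[0], cms[-1] + 1e-9, step)
    return np.unique(np.round(np.concatenate([grid, cms]), 6))


def scan_additive(
    m: MarkerMatrix,
    y: pd.Series,
    cfg: ScanConfig,
    cofactors: CofactorModel | None = None,
) -> pd.DataFrame:
    """1-D genome scan; returns one row per position with LOD, the
    donor-allele effect estimate on the design's scale, and PVE (%).

    RIL effects are additive (half the homozygote contrast); testcross
    effects are the heterozygote-vs-recurrent contrast, i.e. a+d for trait
    values and d for mid-parent heterosis values.
    """
    common = m.line_ids.intersection(y.dropna().index)
    if len(common) < 10:
        raise ValueError("fewer than 10 lines shared between genotypes and phenotype")
    msub = m.subset_lines(common)
    yv = y.loc[common]
    if cofactors is None:
        cofactors = select_cofactors(msub, yv, cfg)
    _, S = encode_genotypes(msub, cfg.design)
    mm = msub.marker_map
    out_frames = []
    sel_pos = mm.loc[cofactors.markers] if cofactors.markers else None
    for chrom in msub.chromosomes():
        in_chrom = mm["chrom"] == chrom
        cols = np.flatnonzero(in_chrom.to_numpy())
        cms = mm.loc[in_chrom, "cm"].to_numpy()
        marker_names = list(mm.index[in_chrom])
        grid = _chromosome_grid(cms, cfg.step_cm)
        Sc = S[:, cols]
        W = np.empty((len(grid), len(common), 2))
        Y = np.empty((len(grid), len(common)))
        lefts, rights = [], []
        cache: dict[frozenset, np.ndarray] = {}
        for k, t in enumerate(grid):
            W[k] = _flank_probs(Sc, cms, t)
            iL = min(max(int(np.searchsorted(cms, t + 1e-9)) - 1, 0), len(cms) - 1)
            iR = min(int(np.searchsorted(cms, t - 1e-9)), len(cms) - 1)
            lefts.append(marker_names[iL])
            rights.append(marker_names[iR])
            if sel_pos is not None:
                excl = frozenset(
                    mk
                    for mk, row in sel_pos.iterrows()
                    if row["chrom"] == chrom
                    and cms[iL] - 1e-9 <= row["cm"] <= cms[iR] + 1e-9
                )
            else:
                excl = frozenset()
            if excl not in cache:
                cache[excl] = cofactors.adjust(yv.to_numpy(dtype=float), set(excl))
            Y[k] = cache[excl]
        lod, mu, pve = _mixture_em(W, Y, cfg.em_tol, cfg.em_max_iter)
        effect = mu[:, 1] - mu[:, 0]
        if cfg.design == "RIL":
            effect = effect / 2.0
        out_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "cm": grid,
                    "lod": lod,
                    "effect": effect,
                    "pve": pve,
                    "left_marker": lefts,
                    "right_marker": rights,
                }
            )
        )
    return pd.concat(out_frames, ignore_index=True)


def permutation_threshold(
    m: MarkerMatrix,
    y: pd.Series,
    cfg: ScanConfig,
    seed: int,
    n_permutations: int | None = None,
) -> float:
    """Genome-wide LOD threshold: the (1 - alpha) quantile of the maximum
    LOD over seeded phenotype permutations (cofactors reselected each time)."""
    n_perm = n_permutations if n_permutations is not None else cfg.n_permutations
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    rng = np.random.default_rng(seed)
    common = m.line_ids.intersection(y.dropna().index)
    msub = m.subset_lines(common)
    base = y.loc[common].to_numpy(dtype=float)
    max_lods = np.empty(n_perm)
    for i in range(n_perm):
        yp = pd.Series(rng.permutation(base), index=common)
        res = scan_additive(msub, yp, cfg)
        max_lods[i] = np.nanmax(res["lod"].to_numpy())
    return float(np.quantile(max_lods, 1.0 - cfg.alpha))


def call_qtl(
    scan: pd.DataFrame,
    threshold: float,
    marker_map: pd.DataFrame,
    merge_cm: float = 10.0,
    lod_drop: float = 1.5,
) -> pd.DataFrame:
    """Peaks above threshold with 1.5-LOD support intervals.

    Local maxima closer than ``merge_cm`` collapse to the higher peak; the
    support interval walks out while LOD stays within ``lod_drop`` of the
    peak, clipped to the chromosome, and its physical bounds come from the
    flanking bins' map positions.
    """
    calls = []
    for chrom, sub in scan.groupby("chrom", sort=False):
        sub = sub.sort_values("cm").reset_index(drop=True)
        lod = sub["lod"].to_numpy()
        finite = np.nan_to_num(lod, nan=-1.0)
        peaks = [
            i
            for i in range(len(sub))
            if finite[i] >= threshold
            and (i == 0 or finite[i] >= finite[i - 1])
            and (i == len(sub) - 1 or finite[i] >= finite[i + 1])
        ]
        merged: list[int] = []
        for i in peaks:
            if merged and sub["cm"][i] - sub["cm"][merged[-1]] < merge_cm:
                if finite[i] > finite[merged[-1]]:
                    merged[-1] = i
            else:
                merged.append(i)
        for i in merged:
            lo = i
            while lo > 0 and finite[lo - 1] >= finite[i] - lod_drop:
                lo -= 1
            hi = i
            while hi < len(sub) - 1 and finite[hi + 1] >= finite[i] - lod_drop:
                hi += 1
            calls.append(
                {
                    "chrom": chrom,
                    "peak_cm": float(sub["cm"][i]),
                    "lod": float(lod[i]),
                    "pve": float(sub["pve"][i]),
                    "effect": float(sub["effect"][i]),
                    "ci_lo_cm": float(sub["cm"][lo]),
                    "ci_hi_cm": float(sub["cm"][hi]),
                    "ci_lo_bp": int(marker_map.loc[sub["left_marker"][lo], "bp"]),
                    "ci_hi_bp": int(marker_map.loc[sub["right_marker"][hi], "bp"]),
                }
            )
    cols = [
        "chrom", "peak_cm", "lod", "pve", "effect",
        "ci_lo_cm", "ci_hi_cm", "ci_lo_bp", "ci_hi_bp",
    ]
    return pd.DataFrame(calls, columns=cols)


# ---------------------------------------------------------------------------
# 2-D epistasis scan
# ---------------------------------------------------------------------------

def _expected_scores(
    m: MarkerMatrix, design: str, step: float
) -> tuple[np.ndarray, pd.DataFrame]:
    """Expected donor-dose score at each grid position (columns) per line."""
    _, S = encode_genotypes(m, design)
    mm = m.marker_map
    cols, meta = [], []
    for chrom in m.chromosomes():
        in_chrom = mm["chrom"] == chrom
        idx = np.flatnonzero(in_chrom.to_numpy())
        cms = mm.loc[in_chrom, "cm"].to_numpy()
        grid = np.arange(cms[0], cms[-1] + 1e-9, step)
        for t in grid:
            w = _flank_probs(S[:, idx], cms, float(t))
            score = 2.0 * w[:, 1] - 1.0 if design == "RIL" else w[:, 1]
            cols.append(score)
            meta.append((chrom, float(t)))
    G = np.column_stack(cols)
    return G, pd.DataFrame(meta, columns=["chrom", "cm"])


def scan_epistasis(m: MarkerMatrix, y: pd.Series, cfg: ScanConfig) -> pd.DataFrame:
    """Digenic additive-by-additive scan on a coarse grid.

    For every admissible position pair (all inter-chromosomal pairs;
    intra-chromosomal pairs separated by at least ``min_pair_sep_cm``) the
    full model [1, x1, x2, x1*x2] is tested against the main-effects model on
    cofactor-adjusted phenotypes.  Pairs with interaction LOD >= the
    epistasis threshold survive a one-grid-step non-maximum suppression.
    """
    common = m.line_ids.intersection(y.dropna().index)
    msub = m.subset_lines(common)
    yv = y.loc[common]
    model = select_cofactors(msub, yv, cfg)
    G, meta = _expected_scores(msub, cfg.design, cfg.step_cm)
    n, P = G.shape
    sel_pos = msub.marker_map.loc[model.markers] if model.markers else None
    y_all = model.adjust(yv.to_numpy(dtype=float))
    cache: dict[frozenset, np.ndarray] = {frozenset(): y_all}

    def _adjusted(i: int, j: int) -> np.ndarray:
        if sel_pos is None:
            return y_all
        excl = frozenset(
            mk
            for mk, row in sel_pos.iterrows()
            if any(
                row["chrom"] == meta["chrom"][k]
                and abs(row["cm"] - meta["cm"][k]) <= cfg.step_cm
                for k in (i, j)
            )
        )
        if excl not in cache:
            cache[excl] = model.adjust(yv.to_numpy(dtype=float), set(excl))
        return cache[excl]

    ones = np.ones(n)
    lod_grid = np.full((P, P), -np.inf)
    stats_grid: dict[tuple[int, int], tuple[float, float]] = {}
    chroms = meta["chrom"].to_numpy()
    cms = meta["cm"].to_numpy()
    for i in range(P):
        for j in range(i + 1, P):
            if chroms[i] == chroms[j] and abs(cms[i] - cms[j]) < cfg.min_pair_sep_cm:
                continue
            x1, x2 = G[:, i], G[:, j]
            inter = x1 * x2
            Dr = np.column_stack([ones, x1, x2])
            # degenerate genotype classes: interaction collinear with mains
            br, *_ = np.linalg.lstsq(Dr, inter, rcond=None)
            resid_inter = inter - Dr @ br
            if float(resid_inter @ resid_inter) < 1e-8 * n:
                continue
            ya = _adjusted(i, j)
            b_red, rss_red, *_ = np.linalg.lstsq(Dr, ya, rcond=None)
            Df = np.column_stack([Dr, inter])
            b_full, rss_full, *_ = np.linalg.lstsq(Df, ya, rcond=None)
            rr = float(rss_red[0]) if len(rss_red) else float(((ya - Dr @ b_red) ** 2).sum())
            rf = float(rss_full[0]) if len(rss_full) else float(((ya - Df @ b_full) ** 2).sum())
            if rf <= 0:
                continue
            lod = 0.5 * n * np.log10(rr / rf)
            lod_grid[i, j] = lod_grid[j, i] = lod
            if lod >= cfg.lod_threshold:
                ss0 = float(((ya - ya.mean()) ** 2).sum())
                stats_grid[(i, j)] = (
                    float(b_full[3]),
                    float(100.0 * (1.0 - rf / ss0)) if ss0 > 0 else 0.0,
                )
    cols = ["chrom1", "cm1", "chrom2", "cm2", "lod", "aa", "pve"]
    hits = []
    for (i, j), (aa, pve) in stats_grid.items():
        # report only 2-D local maxima of the LOD surface (one grid step in
        # either locus), so a single interaction yields a single pair
        neigh = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                a, b = i + di, j + dj
                if (di, dj) == (0, 0) or not (0 <= a < P and 0 <= b < P):
                    continue
                if chroms[a] != chroms[i] or chroms[b] != chroms[j]:
                    continue
                neigh.append(lod_grid[a, b])
        if neigh and max(neigh) > lod_grid[i, j] + 1e-9:
            continue
        hits.append(
            {
                "chrom1": chroms[i], "cm1": cms[i],
                "chrom2": chroms[j], "cm2": cms[j],
                "lod": float(lod_grid[i, j]), "aa": aa, "pve": pve,
            }
        )
    if not hits:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(hits).sort_values("lod", ascending=False).reset_index(drop=True)
    kept: list[int] = []
    tol = cfg.step_cm + 1e-6
    for k in range(len(df)):
        row = df.iloc[k]
        if not any(_pairs_match(row, df.iloc[a], tol) for a in kept):
            kept.append(k)
    return df.iloc[kept].reset_index(drop=True)[cols]


def _loci_match(c1, p1, c2, p2, tol) -> bool:
    return c1 == c2 and abs(p1 - p2) <= tol


def _pairs_match(a, b, tol: float) -> bool:
    """Unordered locus-pair match within a grid-step tolerance per locus."""
    direct = _loci_match(a["chrom1"], a["cm1"], b["chrom1"], b["cm1"], tol) and _loci_match(
        a["chrom2"], a["cm2"], b["chrom2"], b["cm2"], tol
    )
    crossed = _loci_match(a["chrom1"], a["cm1"], b["chrom2"], b["cm2"], tol) and _loci_match(
        a["chrom2"], a["cm2"], b["chrom1"], b["cm1"], tol
    )
    return direct or crossed
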