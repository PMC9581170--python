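"""Marker matrices, marker filtering, bin-map construction and BC1F1 deduction.

Genotypes in a biparental (recurrent parent x donor) design are coded

====  =============================================
code  meaning
====  =============================================
0     recurrent-parent homozygote (maintainer-like)
1     heterozygote
2     donor homozygote
-9    missing call
====  =============================================

A :class:`MarkerMatrix` couples a lines-by-markers code matrix with a marker
map (chromosome, genetic position in cM, physical position in bp).  Markers
are kept in map order (chromosome, then cM) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_RECURRENT = 0
HET = 1
HOM_DONOR = 2
MISSING = -9

VALID_CODES = frozenset({HOM_RECURRENT, HET, HOM_DONOR, MISSING})

#: informative co-observed lines required before two markers may be binned
MIN_INFORMATIVE_LINES = 30


class LinkageError(ValueError):
    """Raised when adjacent loci appear unlinked (discordance >= 0.5)."""


@dataclass
class MarkerMatrix:
    """Lines x markers genotype codes plus the marker map.

    Parameters
    ----------
    genotypes
        DataFrame indexed by line id with one integer column per marker.
    marker_map
        DataFrame indexed by marker id with columns ``chrom``, ``cm``, ``bp``,
        sorted by (chrom, cm); must cover exactly the genotype columns.
    """

    genotypes: pd.DataFrame
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = self.genotypes.astype(np.int16)
        if list(self.genotypes.columns) != list(self.marker_map.index):
            # align to map order; every genotype column must be mapped
            missing = set(self.genotypes.columns) - set(self.marker_map.index)
            if missing:
                raise ValueError(f"markers absent from map: {sorted(missing)[:5]} ...")
            self.marker_map = self.marker_map.loc[
                [m for m in self.marker_map.index if m in set(self.genotypes.columns)]
            ]
            self.genotypes = self.genotypes[list(self.marker_map.index)]
        codes = np.unique(self.genotypes.to_numpy())
        bad = set(codes.tolist()) - VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}; allowed {sorted(VALID_CODES)}")

    # -- convenience -----------------------------------------------------
    @property
    def line_ids(self) -> pd.Index:
        return self.genotypes.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.genotypes.columns

    @property
    def n_lines(self) -> int:
        return len(self.genotypes)

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.marker_map["chrom"]))

    def subset_markers(self, markers) -> "MarkerMatrix":
        markers = list(markers)
        return MarkerMatrix(self.genotypes[markers], self.marker_map.loc[markers])

    def subset_lines(self, lines) -> "MarkerMatrix":
        return MarkerMatrix(self.genotypes.loc[list(lines)], self.marker_map)

    def missing_rate(self) -> pd.Series:
        return (self.genotypes == MISSING).mean(axis=0)

    def donor_allele_frequency(self) -> pd.Series:
        """Donor allele frequency per marker on non-missing calls.

        Heterozygotes contribute half an allele count.
        """
        g = self.genotypes.to_numpy()
        obs = g != MISSING
        donor = np.where(obs, (g == HOM_DONOR) + 0.5 * (g == HET), 0.0)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = donor.sum(axis=0) / n_obs
        return pd.Series(freq, index=self.marker_ids)

    def het_frequency(self) -> pd.Series:
        g = self.genotypes.to_numpy()
        obs = g != MISSING
        with np.errstate(invalid="ignore"):
            freq = (g == HET).sum(axis=0) / obs.sum(axis=0)
        return pd.Series(freq, index=self.marker_ids)


@dataclass
class BinMap:
    """Ordered, non-overlapping marker bins per chromosome.

    ``bins`` has one row per bin with columns ``chrom``, ``start_bp``,
    ``end_bp``, ``start_cm``, ``end_cm``, ``representative`` and ``members``
    (tuple of member marker ids); the representative is always a member.
    """

    bins: pd.DataFrame

    def __post_init__(self) -> None:
        for _, row in self.bins.iterrows():
            if row["representative"] not in row["members"]:
                raise ValueError("bin representative is not a member")

    @property
    def n_bins(self) -> int:
        return len(self.bins)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_markers(
    m: MarkerMatrix,
    maf_min: float = 0.01,
    miss_max: float = 0.2,
    het_max: float | None = 0.1,
) -> MarkerMatrix:
    """Drop markers with low minor-allele frequency, high missingness, or
    excess heterozygote frequency.

    Allele frequencies are computed on non-missing calls with heterozygotes
    counting half.  ``het_max`` removes markers whose heterozygote fraction
    exceeds the threshold (pass ``None`` to disable).
    """
    freq = m.donor_allele_frequency()
    maf = np.minimum(freq, 1.0 - freq)
    miss = m.missing_rate()
    keep = (maf >= maf_min) & (miss <= miss_max)
    keep &= freq.notna()
    if het_max is not None:
        keep &= m.het_frequency().fillna(0.0) <= het_max
    kept = [mk for mk in m.marker_ids if keep[mk]]
    if not kept:
        raise ValueError(
            f"all {m.n_markers} markers removed by filters "
            f"(maf_min={maf_min}, miss_max={miss_max}, het_max={het_max})"
        )
    return m.subset_markers(kept)


def _columns_equivalent(a: np.ndarray, b: np.ndarray, min_informative: int) -> bool:
    """True when two genotype columns agree on every co-observed line and at
    least ``min_informative`` lines are co-observed."""
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    if n < min_informative:
        return False
    return bool(np.all(a[both] == b[both]))


def bin_markers(
    m: MarkerMatrix,
    min_informative: int = MIN_INFORMATIVE_LINES,
) -> tuple[BinMap, MarkerMatrix]:
    """Collapse maximal runs of adjacent redundant markers into bins.

    Two adjacent markers are redundant when their genotype vectors agree on
    every line where both are observed (requiring at least ``min_informative``
    co-observed lines).  Each bin is represented by the member with the lowest
    missing rate; ties break to the lowest physical position, which keeps the
    choice deterministic.  Returns the bin map and the matrix reduced to the
    representative columns.
    """
    mm = m.marker_map
    chrom_seq = mm["chrom"].tolist()
    n_runs = 1 + sum(a != b for a, b in zip(chrom_seq, chrom_seq[1:]))
    if n_runs != len(set(chrom_seq)) or any(
        not (mm.loc[sub.index, "cm"].is_monotonic_increasing
             and mm.loc[sub.index, "bp"].is_monotonic_increasing)
        for _, sub in mm.groupby("chrom", sort=False)
    ):
        raise ValueError("markers must be sorted by chromosome and position")
    g = m.genotypes.to_numpy()
    miss = m.missing_rate()

    rows = []
    reps: list[str] = []
    markers = list(mm.index)
    chrom_of = mm["chrom"]
    i = 0
    while i < len(markers):
        j = i + 1
        while (
            j < len(markers)
            and chrom_of.iloc[j] == chrom_of.iloc[i]
            and _columns_equivalent(g[:, j - 1], g[:, j], min_informative)
        ):
            j += 1
        members = tuple(markers[i:j])
        sub = mm.loc[list(members)]
        cand = miss[list(members)]
        best = cand[cand == cand.min()].index
        rep = mm.loc[list(best)].sort_values("bp").index[0]
        rows.append(
            {
                "chrom": chrom_of.iloc[i],
                "start_bp": int(sub["bp"].min()),
                "end_bp": int(sub["bp"].max()),
                "start_cm": float(sub["cm"].min()),
                "end_cm": float(sub["cm"].max()),
                "representative": rep,
                "members": members,
            }
        )
        reps.append(rep)
        i = j
    binmap = BinMap(pd.DataFrame(rows))
    return binmap, m.subset_markers(reps)


def deduce_bc1f1_genotypes(
    rils: MarkerMatrix,
    recurrent_genotype: pd.Series | np.ndarray | None = None,
) -> MarkerMatrix:
    """Deduce testcross (RIL x recurrent parent) genotypes from RIL calls.

    Per locus: a RIL homozygous for the recurrent allele gives a recurrent
    homozygote; a RIL homozygous for the other allele gives a heterozygote; a
    heterozygous or missing RIL call gives a missing hybrid call.  The
    recurrent parent must be homozygous at every locus (default: recurrent
    homozygote, code 0, everywhere).
    """
    if rils.n_lines == 0:
        raise ValueError("empty RIL matrix")
    if recurrent_genotype is None:
        rec = np.full(rils.n_markers, HOM_RECURRENT, dtype=np.int16)
    else:
        rec = np.asarray(
            recurrent_genotype.reindex(rils.marker_ids)
            if isinstance(recurrent_genotype, pd.Series)
            else recurrent_genotype,
            dtype=np.int16,
        )
    if np.any(rec == HET):
        raise ValueError("recurrent parent has heterozygous calls; must be homozygous")
    g = rils.genotypes.to_numpy()
    out = np.full_like(g, MISSING)
    same = (g == rec) & (g != MISSING) & (rec != MISSING)
    opposite = ((g == HOM_RECURRENT) | (g == HOM_DONOR)) & (g != rec) & (rec != MISSING)
    out[same] = np.broadcast_to(rec, g.shape)[same]
    out[opposite] = HET
    return MarkerMatrix(
        pd.DataFrame(out, index=rils.line_ids, columns=rils.marker_ids),
        rils.marker_map.copy(),
    )


def ril_discordance_to_r(R: float | np.ndarray) -> float | np.ndarray:
    """Meiotic recombination fraction from RIL-by-selfing discordance.

    Inverts the Haldane-Waddington relation R = 2r/(1+2r) (F-infinity limit),
    the accepted approximation at F8.
    """
    return R / (2.0 * (1.0 - R))


def r_to_ril_discordance(r: float | np.ndarray) -> float | np.ndarray:
    return 2.0 * r / (1.0 + 2.0 * r)


def haldane_cm_from_r(r: float | np.ndarray) -> float | np.ndarray:
    """Map distance in cM from recombination fraction (Haldane, no interference)."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


def haldane_r_from_cm(d: float | np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d, dtype=float) / 100.0))


def estimate_linkage_map(binned: MarkerMatrix, design: str = "RIL") -> pd.DataFrame:
    """Re-estimate cM positions from adjacent-marker discordance in a RIL panel.

    The observed discordance R between adjacent homozygous calls is converted
    to a meiotic recombination fraction r = R/(2(1-R)) and then to distance by
    Haldane's map function.  Returns a map table with estimated ``cm``.

    Raises :class:`LinkageError` when any adjacent pair shows R >= 0.5.
    """
    if design != "RIL":
        raise ValueError("only the RIL design is supported")
    mm = binned.marker_map
    g = binned.genotypes.to_numpy()
    markers = list(mm.index)
    cm_est = np.zeros(len(markers))
    unlinked: list[tuple[str, str, float]] = []
    pos = 0.0
    for k in range(len(markers)):
        if k == 0 or mm["chrom"].iloc[k] != mm["chrom"].iloc[k - 1]:
            pos = 0.0
        else:
            a, b = g[:, k - 1], g[:, k]
            informative = np.isin(a, (HOM_RECURRENT, HOM_DONOR)) & np.isin(
                b, (HOM_RECURRENT, HOM_DONOR)
            )
            if informative.sum() < 2:
                raise ValueError(
                    f"too few informative lines between {markers[k - 1]} and {markers[k]}"
                )
            R = float(np.mean(a[informative] != b[informative]))
            if R >= 0.5:
                unlinked.append((markers[k - 1], markers[k], R))
                pos += np.inf
            else:
                r = ril_discordance_to_r(R)
                pos += float(haldane_cm_from_r(r))
        cm_est[k] = pos
    if unlinked:
        pairs = ", ".join(f"{a}--{b} (R={R:.3f})" for a, b, R in unlinked)
        raise LinkageError(f"adjacent bins appear unlinked: {pairs}")
    out = mm.copy()
    out["cm"] = cm_est
    return out


def summarize_binmap(b: BinMap) -> dict:
    """Bin count, genetic span, mean neighbour spacing and mean bin size.

    Span is summed per chromosome (last minus first bin position); mean
    spacing is span divided by the number of bins, reported to two decimals —
    the convention used when quoting map density.  A single-bin map reports a
    spacing of 0 by convention.
    """
    if b.n_bins == 0:
        raise ValueError("empty bin map")
    spans = b.bins.groupby("chrom", sort=False).agg(
        lo=("start_cm", "min"), hi=("end_cm", "max")
    )
    span = float((spans["hi"] - spans["lo"]).sum())
    n = b.n_bins
    spacing = 0.0 if n == 1 else round(span / n, 2)
    size_bp = float((b.bins["end_bp"] - b.bins["start_bp"] + 1).mean())
    return {
        "n_bins": n,
        "span_cm": span,
        "mean_spacing_cm": spacing,
        "mean_bin_size_bp": size_bp,
    }


def read_vcf(
    path: str,
    parent_recurrent: str,
    parent_donor: str,
    lines: list[str] | None = None,
) -> MarkerMatrix:
    """Read biallelic SNPs from a VCF into parental codes {0,1,2,-9}.

    Sites where the two named parental samples are not opposite homozygotes
    are skipped.  Genetic positions are seeded from physical positions at
    1 cM per 250 kb and can be re-estimated with :func:`estimate_linkage_map`.
    Requires ``cyvcf2`` (optional dependency).
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(path)
    samples = vcf.samples
    i_rec, i_don = samples.index(parent_recurrent), samples.index(parent_donor)
    idx = (
        list(range(len(samples)))
        if lines is None
        else [samples.index(s) for s in lines]
    )
    names = [samples[i] for i in idx]
    rows, meta = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        gt = np.array([g[:2] for g in v.genotypes])  # allele pairs
        rec, don = gt[i_rec], gt[i_don]
        if set(rec.tolist()) == {-1} or set(don.tolist()) == {-1}:
            continue
        if rec[0] != rec[1] or don[0] != don[1] or rec[0] == don[0]:
            continue
        donor_allele = don[0]
        codes = np.full(len(idx), MISSING, dtype=np.int16)
        sub = gt[idx]
        ok = (sub >= 0).all(axis=1)
        n_donor = (sub == donor_allele).sum(axis=1)
        codes[ok] = n_donor[ok]
        rows.append(codes)
        meta.append((f"{v.CHROM}_{v.POS}", v.CHROM, v.POS))
    if not rows:
        raise ValueError("no informative biallelic sites found in VCF")
    mm = pd.DataFrame(
        [(c, p / 2500.0, p) for _, c, p in meta],
        index=[m for m, _, _ in meta],
        columns=["chrom", "cm", "bp"],
    )
    geno = pd.DataFrame(np.array(rows).T, index=names, columns=mm.index)
    return MarkerMatrix(geno, mm)
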