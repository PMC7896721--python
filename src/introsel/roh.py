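"""Runs of homozygosity: sliding-window caller, the Lencz minimum-SNP
rule, F_ROH with length-class decomposition, and the incidence scan.

The caller emulates the PLINK ``--homozyg`` scanning scheme: a window of
``window_snps`` SNPs slides one SNP at a time over each individual's
chromosome; windows tolerating at most ``max_het_per_window``
heterozygous and ``max_missing_per_window`` missing calls "pass"; each
SNP's hit fraction is the share of passing windows covering it, and
SNPs above ``hit_fraction_threshold`` seed candidate runs that must
then satisfy minimum SNP count, length, density and gap constraints.

F_ROH divides total ROH length by the autosomal genome length (2.45 Gb
for the pig SNP panels this mirrors).  Segments shorter than 5 Mb, 5-10
Mb and over 10 Mb index ancestral, intermediate and recent inbreeding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

LENGTH_CLASSES = ("<5Mb", "5-10Mb", ">10Mb")


def min_roh_snps(alpha: float, n_s: int, n_i: int, het: float) -> int:
    """Lencz minimum SNP count for a false-positive-controlled ROH:

        l = ceil( ln(alpha / (n_s * n_i)) / ln(1 - het) )

    where alpha is the tolerated false-positive ROH rate, n_s the SNPs
    per individual, n_i the number of individuals, and het the mean
    heterozygosity across SNPs.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if not 0 < het < 1:
        raise ValueError("het must be in (0,1)")
    if n_s < 1 or n_i < 1:
        raise ValueError("n_s and n_i must be >= 1")
    return math.ceil(math.log(alpha / (n_s * n_i)) / math.log(1.0 - het))


@dataclass
class ROHParams:
    """Caller thresholds; defaults follow the standard SNP-array recipe."""

    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    min_snps: int | None = None  # Lencz l; computed from the data when None
    min_length_bp: int = 1_000_000
    min_density_bp_per_snp: int = 100_000  # 1 SNP per 100 kb
    max_gap_bp: int = 1_000_000
    hit_fraction_threshold: float = 0.05
    alpha: float = 0.05
    genome_length_bp: float = 2.45e9

    def __post_init__(self) -> None:
        if not 0 < self.hit_fraction_threshold <= 1:
            raise ValueError("hit_fraction_threshold must be in (0,1]")
        for name in ("window_snps", "min_length_bp", "min_density_bp_per_snp",
                     "max_gap_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ROHSet:
    """Called segments, one row per segment.

    Columns: id, chrom, start_bp, end_bp, n_snps, length_bp, class.
    Lengths are 1-based inclusive spans (end - start + 1).
    """

    segments: pd.DataFrame
    min_snps_used: int = 0

    def per_individual(self, ids: list) -> dict:
        by = {i: [] for i in ids}
        for row in self.segments.itertuples():
            by[row.id].append(row)
        return by


def _length_class(length_bp: int) -> str:
    if length_bp < 5_000_000:
        return "<5Mb"
    if length_bp <= 10_000_000:
        return "5-10Mb"
    return ">10Mb"


def call_roh(gm: GenotypeMatrix, params: ROHParams | None = None) -> ROHSet:
    """Detect runs of homozygosity for every individual.

    When ``params.min_snps`` is None the Lencz rule is evaluated with
    het = mean observed heterozygosity over the analysed SNP set.
    """
    p = params or ROHParams()
    d = gm.dosages
    obs = d != MISSING
    het_rate = float(((d == 1) & obs).sum() / max(obs.sum(), 1))
    if p.min_snps is not None:
        l_min = p.min_snps
    else:
        l_min = min_roh_snps(p.alpha, gm.n_snp, gm.n_ind, max(het_rate, 1e-9))

    chroms = gm.snps["chrom"].to_numpy()
    bp = gm.snps["bp"].to_numpy()
    ids = gm.individuals["id"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        n = cols.size
        if n < p.window_snps:
            warnings.warn(f"chromosome {chrom}: {n} SNPs < window, skipped")
            continue
        cbp = bp[cols]
        W = p.window_snps
        n_w = n - W + 1
        lo = np.maximum(0, np.arange(n) - W + 1)
        hi = np.minimum(np.arange(n), n_w - 1)
        denom = (hi - lo + 1).astype(float)
        for i in range(gm.n_ind):
            row = d[i, cols]
            het = (row == 1).astype(np.int32)
            mis = (row == MISSING).astype(np.int32)
            ch = np.concatenate([[0], np.cumsum(het)])
            cmv = np.concatenate([[0], np.cumsum(mis)])
            het_w = ch[W:] - ch[:-W]
            mis_w = cmv[W:] - cmv[:-W]
            ok_w = (het_w <= p.max_het_per_window) & (mis_w <= p.max_missing_per_window)
            cps = np.concatenate([[0], np.cumsum(ok_w.astype(np.int64))])
            hits = cps[hi + 1] - cps[lo]
            cand = (hits / denom) >= p.hit_fraction_threshold
            for s, e in _runs(cand, cbp, p.max_gap_bp):
                seg = _trim_and_check(row, cbp, s, e, l_min, p)
                if seg is not None:
                    s2, e2, n_snps = seg
                    length = int(cbp[e2] - cbp[s2] + 1)
                    rows.append(
                        (ids[i], chrom, int(cbp[s2]), int(cbp[e2]), n_snps,
                         length, _length_class(length))
                    )
    segments = pd.DataFrame(
        rows, columns=["id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp", "class"]
    )
    return ROHSet(segments=segments, min_snps_used=l_min)


def _runs(cand: np.ndarray, cbp: np.ndarray, max_gap: int):
    """Yield (start, end) index pairs of candidate runs, split at bp gaps."""
    idx = np.flatnonzero(cand)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(
        (np.diff(idx) != 1) | (np.diff(cbp[idx]) > max_gap)
    )
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e])


def _trim_and_check(row, cbp, s, e, l_min, p: ROHParams):
    """Trim a candidate run to its outermost homozygous non-missing SNPs
    and re-check every acceptance threshold."""
    hom = (row == 0) | (row == 2)
    while s <= e and not hom[s]:
        s += 1
    while e >= s and not hom[e]:
        e -= 1
    if e < s:
        return None
    n_snps = e - s + 1
    length = int(cbp[e] - cbp[s] + 1)
    if n_snps < l_min:
        return None
    if length < p.min_length_bp:
        return None
    if length / n_snps > p.min_density_bp_per_snp:
        return None
    gaps = np.diff(cbp[s : e + 1])
    if gaps.size and gaps.max() > p.max_gap_bp:
        return None
    return s, e, n_snps


def roh_inbreeding(rs: ROHSet, gm: GenotypeMatrix, genome_length_bp: float = 2.45e9) -> pd.DataFrame:
    """F_ROH per individual: total ROH length / genome length, plus the
    three length-class components (which sum exactly to the total)."""
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    ids = gm.individuals["id"].tolist()
    out = pd.DataFrame(
        0.0,
        index=pd.Index(ids, name="id"),
        columns=["froh", "froh_lt5", "froh_5_10", "froh_gt10"],
    )
    if len(rs.segments):
        col = {"<5Mb": "froh_lt5", "5-10Mb": "froh_5_10", ">10Mb": "froh_gt10"}
        grouped = rs.segments.groupby(["id", "class"])["length_bp"].sum()
        for (iid, cls), total in grouped.items():
            out.loc[iid, col[cls]] += total / genome_length_bp
        out["froh"] = out[["froh_lt5", "froh_5_10", "froh_gt10"]].sum(axis=1)
    return out.reset_index()


def roh_incidence_scan(
    rs: ROHSet, gm: GenotypeMatrix, top_q: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Selection scan from ROH incidence.

    Returns (counts, significant_idx): per-SNP count of individuals
    whose ROH covers the SNP position, and the indices at or above the
    (1 - top_q) empirical quantile (ties included).
    """
    chroms = gm.snps["chrom"].to_numpy()
    bp = gm.snps["bp"].to_numpy()
    counts = np.zeros(gm.n_snp, dtype=np.int64)
    for row in rs.segments.itertuples():
        counts += (chroms == row.chrom) & (bp >= row.start_bp) & (bp <= row.end_bp)
    from .selection import empirical_top

    return counts, empirical_top(counts, q=top_q)
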