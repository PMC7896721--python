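"""Four-population introgression tests on allele frequencies.

All statistics work on the population tree (((P1, P2), P3), O): P1 and
P2 are sister lineages, P3 is the candidate donor, O the outgroup used
to orient alleles.  Per-SNP site patterns are

    ABBA = (1 - p1) * p2 * p3 * (1 - pO)
    BABA = p1 * (1 - p2) * p3 * (1 - pO)

with p the frequency of the derived (outgroup-minor) allele.
Patterson's D = sum(ABBA - BABA) / sum(ABBA + BABA) detects excess
allele sharing between P3 and P2 (D > 0) or P3 and P1 (D < 0); its
standard error comes from a leave-one-out block jackknife over
contiguous genomic blocks.  The windowed f_dM statistic localizes and
sizes the shared fraction; the f3 test (A; B, C) goes negative when
target A is an admixture of sources related to B and C.

Because the input is a SNP array, dxy and pi are per-variant (not
per-bp) averages; absolute values are not comparable to sequence-based
diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix
from .haplotypes import HaplotypePanel


@dataclass
class SitePattern:
    """Per-SNP sample allele frequencies for the four populations.

    ``freqs`` has columns p1, p2, p3, pO (derived-allele frequency,
    polarized so the outgroup-major allele is ancestral), plus n1..nO
    non-missing allele counts, chrom and bp.
    """

    freqs: pd.DataFrame
    pops: dict


def site_patterns(
    gm: GenotypeMatrix, pops: dict[str, str]
) -> SitePattern:
    """Compute per-population derived-allele frequencies for the
    (((P1,P2),P3),O) topology.

    ``pops`` maps the roles "P1","P2","P3","O" to population labels.
    SNPs where any population has no data are dropped.  Polarization
    flips each SNP so the outgroup-major allele counts as ancestral;
    at pO = 0.5 the orientation is left as is.
    """
    for role in ("P1", "P2", "P3", "O"):
        if role not in pops:
            raise ValueError(f"missing role {role}")
    freq = {}
    count = {}
    for role, label in pops.items():
        idx = gm.pop_index(label)
        d = gm.dosages[idx]
        obs = d != MISSING
        n = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[role] = np.where(obs, d, 0).sum(axis=0) / np.where(n > 0, n, np.nan)
        count[role] = n
    ok = np.ones(gm.n_snp, dtype=bool)
    for role in ("P1", "P2", "P3", "O"):
        ok &= count[role] > 0
    flip = freq["O"] > 0.5  # outgroup-major allele becomes the ancestral state
    out = pd.DataFrame(
        {
            "chrom": gm.snps["chrom"].to_numpy(),
            "bp": gm.snps["bp"].to_numpy(),
        }
    )
    for role, col in (("P1", "p1"), ("P2", "p2"), ("P3", "p3"), ("O", "pO")):
        out[col] = np.where(flip, 1 - freq[role], freq[role])
        out["n" + col[1:]] = count[role]
    return SitePattern(freqs=out.loc[ok].reset_index(drop=True), pops=dict(pops))


def _abba_baba(p1, p2, p3, pO):
    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    return abba, baba


@dataclass
class DStatResult:
    d: float
    se: float
    z: float
    p: float
    n_blocks: int
    n_snps: int


def _block_jackknife(num: np.ndarray, den: np.ndarray, blocks: np.ndarray):
    """Ratio-of-sums estimate with leave-one-block-out jackknife SE."""
    total_num, total_den = num.sum(), den.sum()
    if total_den == 0:
        raise ValueError("denominator is zero genome-wide")
    est = total_num / total_den
    uniq = pd.unique(blocks)
    if len(uniq) < 2:
        raise ValueError("need >= 2 jackknife blocks")
    loo = []
    for b in uniq:
        sel = blocks == b
        den_b = total_den - den[sel].sum()
        if den_b == 0:
            continue
        loo.append((total_num - num[sel].sum()) / den_b)
    loo = np.array(loo)
    g = len(loo)
    se = float(np.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum()))
    return float(est), se, g


def _blocks(sp_freqs: pd.DataFrame, block_size_bp: float) -> np.ndarray:
    chrom = sp_freqs["chrom"].astype(str)
    bin_ = (sp_freqs["bp"] // int(block_size_bp)).astype(int).astype(str)
    return (chrom + ":" + bin_).to_numpy()


def d_statistic(sp: SitePattern, block_size_bp: float = 5e6) -> DStatResult:
    """Patterson's D with block-jackknife Z (two-sided normal p)."""
    f = sp.freqs
    abba, baba = _abba_baba(f["p1"], f["p2"], f["p3"], f["pO"])
    num = (abba - baba).to_numpy()
    den = (abba + baba).to_numpy()
    d, se, g = _block_jackknife(num, den, _blocks(f, block_size_bp))
    z = d / se if se > 0 else np.inf * np.sign(d)
    return DStatResult(
        d=d, se=se, z=float(z), p=float(2 * stats.norm.sf(abs(z))),
        n_blocks=g, n_snps=len(f),
    )


@dataclass
class F3Result:
    f3: float
    se: float
    z: float
    significant: bool  # Z < -2: target is admixed
    n_blocks: int
    n_snps: int


def f3_test(
    gm: GenotypeMatrix,
    target: str,
    source_b: str,
    source_c: str,
    block_size_bp: float = 5e6,
) -> F3Result:
    """f3(target; B, C) with the finite-sample correction for the target.

    Per SNP: (a - b)(a - c) - a(1 - a)/(n_A - 1), with a the target's
    sample frequency from n_A sampled alleles; this makes the site term
    unbiased for the population value.  A block-jackknife Z below -2
    indicates the target is admixed between sources related to B and C.
    """
    freqs, counts = {}, {}
    for name in (target, source_b, source_c):
        idx = gm.pop_index(name)
        d = gm.dosages[idx]
        obs = d != MISSING
        n = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[name] = np.where(obs, d, 0).sum(axis=0) / np.where(n > 0, n, np.nan)
        counts[name] = n
    n_a = counts[target]
    if (n_a >= 4).sum() == 0:
        raise ValueError("target population needs >= 2 diploid samples")
    ok = (n_a >= 4) & (counts[source_b] > 0) & (counts[source_c] > 0)
    a, b, c = freqs[target][ok], freqs[source_b][ok], freqs[source_c][ok]
    site = (a - b) * (a - c) - a * (1 - a) / (n_a[ok] - 1)
    blocks = _blocks(gm.snps.loc[ok, ["chrom", "bp"]], block_size_bp)
    num = site
    den = np.ones_like(site)
    f3, se, g = _block_jackknife(num, den, blocks)
    z = f3 / se if se > 0 else np.inf * np.sign(f3)
    return F3Result(
        f3=f3, se=se, z=float(z), significant=bool(z < -2),
        n_blocks=g, n_snps=int(ok.sum()),
    )


# ---------------------------------------------------------------------------
# Sliding windows: f_dM, dxy, pi
# ---------------------------------------------------------------------------


def _fdm_site(p1, p2, p3, pO):
    """Malinsky's f_dM site terms: (numerator, denominator)."""
    num = (1 - p1) * p2 * p3 * (1 - pO) - p1 * (1 - p2) * p3 * (1 - pO)
    pd23 = np.maximum(p2, p3)
    a2, b2 = _abba_baba(p1, pd23, pd23, pO)
    pd13 = np.maximum(p1, p3)
    a1, b1 = _abba_baba(pd13, p2, pd13, pO)
    den = np.where(p2 >= p1, a2 - b2, -(a1 - b1))
    return num, den


def window_scan(
    sp: SitePattern,
    window_snps: int = 10,
    step_snps: int = 2,
    pi_pops: tuple[str, str] = ("P2", "P1"),
    dxy_pairs: tuple[tuple[str, str], ...] = (("P2", "P3"),),
) -> pd.DataFrame:
    """Sliding-window f_dM, dxy and pi along each chromosome.

    Windows hold exactly ``window_snps`` SNPs and step by
    ``step_snps``, never spanning chromosomes.  f_dM is the windowed
    ratio of summed site numerators to denominators and lies in
    [-1, 1]; windows with zero denominator get NaN.  dxy(X,Y) is the
    mean of p_X(1-p_Y) + p_Y(1-p_X); pi uses the unbiased 2p(1-p)
    2n/(2n-1).  Column names: fdm, dxy_X_Y, pi_X.
    """
    f = sp.freqs
    rows = []
    role_col = {"P1": "p1", "P2": "p2", "P3": "p3", "O": "pO"}
    for chrom in pd.unique(f["chrom"]):
        fc = f[f["chrom"] == chrom].reset_index(drop=True)
        if len(fc) < window_snps:
            continue
        num, den = _fdm_site(
            fc["p1"].to_numpy(), fc["p2"].to_numpy(),
            fc["p3"].to_numpy(), fc["pO"].to_numpy(),
        )
        for start in range(0, len(fc) - window_snps + 1, step_snps):
            end = start + window_snps
            w_num, w_den = num[start:end].sum(), den[start:end].sum()
            fdm = w_num / w_den if w_den != 0 else np.nan
            rec = {
                "chrom": chrom,
                "start_idx": start,
                "end_idx": end - 1,
                "start_bp": int(fc["bp"][start]),
                "end_bp": int(fc["bp"][end - 1]),
                "fdm": fdm,
            }
            for x, y in dxy_pairs:
                px = fc[role_col[x]][start:end].to_numpy()
                py = fc[role_col[y]][start:end].to_numpy()
                rec[f"dxy_{x}_{y}"] = float((px * (1 - py) + py * (1 - px)).mean())
            for x in pi_pops:
                px = fc[role_col[x]][start:end].to_numpy()
                nx = fc["n" + role_col[x][1:]][start:end].to_numpy().astype(float)
                rec[f"pi_{x}"] = float(
                    (2 * px * (1 - px) * (nx / np.maximum(nx - 1, 1))).mean()
                )
            rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class WindowSummary:
    windows: pd.DataFrame  # with z, p, significant columns added
    regions: list[tuple]  # merged significant (chrom, start_bp, end_bp)
    genome_fraction_positive: float
    pi_boost: float | None
    fdm_threshold: float


def significant_windows(
    windows: pd.DataFrame,
    p_cut: float = 0.01,
    pi_target: str | None = "P2",
    pi_reference: str | None = "P1",
    positive_only_pi: bool = True,
) -> WindowSummary:
    """Z-transform f_dM over all defined windows, call significance at
    the upper one-sided ``p_cut``, merge significant windows into
    regions, and summarize the introgressed genome fraction and the
    diversity boost.

    ``pi_boost`` = (pi_target - pi_reference) / pi_reference averaged
    over windows with f_dM > 0 (or only significant windows when
    ``positive_only_pi`` is False).
    """
    w = windows.copy()
    ok = w["fdm"].notna()
    mu, sd = w.loc[ok, "fdm"].mean(), w.loc[ok, "fdm"].std(ddof=0)
    if sd == 0:
        # degenerate constant statistic: nothing stands out
        w["z"] = np.where(ok, 0.0, np.nan)
    else:
        w["z"] = (w["fdm"] - mu) / sd
    w["p"] = stats.norm.sf(w["z"])
    w.loc[~ok, ["z", "p"]] = np.nan
    w["significant"] = ok & (w["p"] < p_cut)
    from .selection import merge_regions

    regions = merge_regions(
        [(r.chrom, r.start_bp, r.end_bp) for r in w[w["significant"]].itertuples()]
    )
    frac_pos = float((ok & (w["fdm"] > 0)).sum() / ok.sum())
    pi_boost = None
    if pi_target and pi_reference:
        col_t, col_r = f"pi_{pi_target}", f"pi_{pi_reference}"
        sel = ok & (w["fdm"] > 0) if positive_only_pi else w["significant"]
        if sel.any() and col_t in w and col_r in w:
            mt = w.loc[sel, col_t].mean()
            mr = w.loc[sel, col_r].mean()
            if mr > 0:
                pi_boost = float((mt - mr) / mr)
    thresh = mu + stats.norm.isf(p_cut) * sd
    return WindowSummary(
        windows=w,
        regions=regions,
        genome_fraction_positive=frac_pos,
        pi_boost=pi_boost,
        fdm_threshold=float(thresh),
    )


# ---------------------------------------------------------------------------
# Haplotype frequency tables
# ---------------------------------------------------------------------------


def haplotype_freqs(
    panel: HaplotypePanel, snp_slice: slice | np.ndarray
) -> pd.DataFrame:
    """Distinct haplotype strings over a SNP range with per-population
    counts.

    Returns one row per distinct haplotype with a column per population
    (counts sum to 2n per population) and a ``total`` column; the first
    row is the most frequent haplotype overall.
    """
    if not panel.phased:
        raise ValueError("haplotype tables need phased input")
    sub = panel.haplotypes[:, snp_slice]
    strings = ["".join(map(str, row)) for row in sub]
    pops = np.repeat(panel.individuals["population"].to_numpy(), 2)
    t = pd.crosstab(pd.Series(strings, name="haplotype"), pd.Series(pops, name="population"))
    t["total"] = t.sum(axis=1)
    return t.sort_values("total", ascending=False).reset_index()
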