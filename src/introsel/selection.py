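"""Selection scans: EHH/iHS, EigenGWAS with genomic control, empirical
top-quantile thresholds and multi-method candidate overlap.

iHS (integrated haplotype score) compares how slowly haplotype
homozygosity decays around the ancestral versus the derived allele of a
core SNP: iHS = ln(iHH_A / iHH_D), where iHH integrates the EHH curve
against genetic distance.  Long derived-allele haplotypes (a partial
sweep) push iHS strongly negative.  Raw scores are standardized within
derived-allele-frequency bins so the genome-wide distribution is
approximately standard normal.

EigenGWAS regresses a principal-component score (a synthetic
"differentiation phenotype") on each SNP's dosage; inflation is removed
with genomic control before Bonferroni thresholding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix
from .haplotypes import HaplotypePanel


# ---------------------------------------------------------------------------
# EHH / iHS
# ---------------------------------------------------------------------------


def ehh(
    panel: HaplotypePanel,
    core_snp: int,
    core_allele: int,
    direction: int,
    cutoff: float = 0.05,
    hap_rows: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extended haplotype homozygosity from a core SNP outward.

    EHH(x) = sum_h C(n_h, 2) / C(n_core, 2) over the distinct extended
    haplotypes h carried from the core to x.  ``direction`` is +1
    (towards larger positions) or -1; the walk stops once EHH drops
    below ``cutoff`` or the chromosome ends.  Returns (snp_indices,
    ehh_values), starting at the core where EHH = 1.
    """
    if not panel.phased:
        raise ValueError("EHH requires phased haplotypes")
    haps = panel.haplotypes if hap_rows is None else panel.haplotypes[hap_rows]
    carriers = np.flatnonzero(haps[:, core_snp] == core_allele)
    n = carriers.size
    if n < 2:
        raise ValueError("core allele carried by fewer than 2 haplotypes")
    chroms = panel.snps["chrom"].to_numpy()
    chrom = chroms[core_snp]
    denom = n * (n - 1) / 2

    groups = np.zeros(n, dtype=np.int64)
    idx_out = [core_snp]
    ehh_out = [1.0]
    j = core_snp
    while True:
        j += direction
        if j < 0 or j >= panel.n_snp or chroms[j] != chrom:
            break
        groups = groups * 2 + haps[carriers, j]
        _, groups = np.unique(groups, return_inverse=True)
        sizes = np.bincount(groups)
        val = float((sizes * (sizes - 1) / 2).sum() / denom)
        idx_out.append(j)
        ehh_out.append(val)
        if val < cutoff:
            break
    return np.array(idx_out), np.array(ehh_out)


def _ihh(idx: np.ndarray, vals: np.ndarray, cm: np.ndarray, cutoff: float) -> float:
    """Trapezoid integral of an EHH curve against cM distance from the
    core, truncated at the cutoff."""
    x = np.abs(cm[idx] - cm[idx[0]])
    y = np.clip(vals, 0.0, None)
    keep = vals >= cutoff
    # include the first below-cutoff point so the tail trapezoid counts
    last = np.flatnonzero(~keep)
    stop = last[0] + 1 if last.size else len(vals)
    if stop < 2:
        return 0.0
    return float(np.trapezoid(y[:stop], x[:stop]))


@dataclass
class ScanResult:
    """Per-SNP scan output with raw/standardized statistics."""

    table: pd.DataFrame
    method: str
    extras: dict | None = None


def ihs_scan(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    n_bins: int = 50,
    min_bin_snps: int = 20,
    cutoff: float = 0.05,
    top_q: float = 0.01,
    flank_bp: int = 50_000,
    hap_rows: np.ndarray | None = None,
) -> ScanResult:
    """Genome-wide iHS with within-frequency-bin standardization.

    SNPs without ancestral-allele orientation keep their map
    orientation; their sign is untrusted so they enter the |iHS|
    ranking only (``polarized`` column marks the rest).  Significant
    SNPs are the top ``top_q`` of |standardized iHS|, reported with
    +/- ``flank_bp`` regions.
    """
    haps = panel.haplotypes if hap_rows is None else panel.haplotypes[hap_rows]
    cm = panel.snps["cm"].to_numpy().astype(float)
    if not np.any(cm > 0):
        cm = panel.snps["bp"].to_numpy() / 1e6  # 1 cM/Mb fallback
    anc_flag = (
        panel.snps["ancestral"].to_numpy()
        if "ancestral" in panel.snps.columns
        else np.full(panel.n_snp, -1)
    )
    rows = []
    for k in range(panel.n_snp):
        freq1 = haps[:, k].mean()
        if min(freq1, 1 - freq1) < maf_min:
            continue
        polarized = anc_flag[k] in (0, 1)
        anc_allele = 1 if anc_flag[k] == 1 else 0  # unpolarized: allele1 "kept as is"
        der_allele = 1 - anc_allele
        n1 = int(haps[:, k].sum())
        n_anc = n1 if anc_allele == 1 else haps.shape[0] - n1
        if n_anc < 2 or haps.shape[0] - n_anc < 2:
            continue
        ihh = {}
        skip = False
        for allele, label in ((anc_allele, "anc"), (der_allele, "der")):
            total = 0.0
            for direction in (+1, -1):
                i_idx, i_val = ehh(panel, k, allele, direction, cutoff=cutoff,
                                   hap_rows=hap_rows)
                total += _ihh(i_idx, i_val, cm, cutoff)
            if total <= 0:
                skip = True
                break
            ihh[label] = total
        if skip:
            continue
        daf = 1 - freq1 if der_allele == 0 else freq1
        rows.append((k, float(daf), math.log(ihh["anc"] / ihh["der"]), polarized))
    t = pd.DataFrame(rows, columns=["snp", "daf", "uihs", "polarized"])
    if len(t) == 0:
        return ScanResult(table=t, method="iHS")

    # frequency-bin standardization, merging sparse bins with neighbours
    edges = np.linspace(0, 1, n_bins + 1)
    bin_id = np.clip(np.digitize(t["daf"], edges[1:-1]), 0, n_bins - 1)
    merged = _merge_sparse_bins(bin_id, min_bin_snps)
    z = np.empty(len(t))
    for b in np.unique(merged):
        sel = merged == b
        mu, sd = t.loc[sel, "uihs"].mean(), t.loc[sel, "uihs"].std(ddof=0)
        z[sel] = (t.loc[sel, "uihs"] - mu) / (sd if sd > 0 else 1.0)
    t["std_bin"] = merged
    t["ihs"] = z
    t["abs_ihs"] = np.abs(z)
    sig = empirical_top(t["abs_ihs"].to_numpy(), q=top_q)
    t["significant"] = False
    t.loc[t.index[sig], "significant"] = True
    bp = panel.snps["bp"].to_numpy()
    chroms = panel.snps["chrom"].to_numpy()
    snp_cols = t["snp"].to_numpy()
    t.insert(1, "chrom", chroms[snp_cols])
    t.insert(2, "bp", bp[snp_cols])
    regions = merge_regions(
        [(chroms[s], max(1, bp[s] - flank_bp), bp[s] + flank_bp)
         for s in snp_cols[t["significant"].to_numpy()]]
    )
    return ScanResult(table=t, method="iHS", extras={"regions": regions})


def _merge_sparse_bins(bin_id: np.ndarray, min_count: int) -> np.ndarray:
    """Relabel frequency bins so every label holds >= min_count items,
    merging sparse bins into their left neighbour (rightmost kept)."""
    out = bin_id.copy()
    labels = np.sort(np.unique(out))
    for i, b in enumerate(labels):
        if (out == b).sum() < min_count and i + 1 < len(labels):
            out[out == b] = labels[i + 1]
        elif (out == b).sum() < min_count and i > 0:
            prev = np.sort(np.unique(out[out != b]))
            if prev.size:
                out[out == b] = prev[-1]
    return out


# ---------------------------------------------------------------------------
# EigenGWAS
# ---------------------------------------------------------------------------


def eigengwas(
    gm: GenotypeMatrix,
    evec: np.ndarray,
    genomic_control: bool = True,
    bonferroni: bool = True,
) -> ScanResult:
    """Regress a PC score on each SNP's dosage; chi-square Wald scan.

    With ``genomic_control`` the chi-squares are divided by
    lambda = median(chi2) / 0.4549 before p-values.  Significance is
    p < 0.05 / m (Bonferroni over tested SNPs).
    """
    y = np.asarray(evec, dtype=float)
    if y.shape != (gm.n_ind,):
        raise ValueError("eigenvector length must match individuals")
    x = gm.dosages_float()
    obs = ~np.isnan(x)
    n_k = obs.sum(axis=0).astype(float)
    xs = np.where(obs, x, 0.0)
    sx = xs.sum(axis=0)
    sy = (obs * y[:, None]).sum(axis=0)
    sxx = (xs**2).sum(axis=0)
    syy = (obs * (y**2)[:, None]).sum(axis=0)
    sxy = (xs * y[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = sxx / n_k - (sx / n_k) ** 2
        vy = syy / n_k - (sy / n_k) ** 2
        cov = sxy / n_k - sx * sy / n_k**2
        beta = cov / vx
        r2 = cov**2 / (vx * vy)
        chi2 = r2 / (1 - r2) * (n_k - 2)
    tested = (vx > 0) & (n_k > 2) & np.isfinite(chi2)
    chi2_t = chi2[tested]
    lam = 1.0
    if genomic_control and chi2_t.size:
        lam = float(np.median(chi2_t) / stats.chi2.ppf(0.5, df=1))
        lam = max(lam, 1e-12)
        chi2_t = chi2_t / lam
    p = stats.chi2.sf(chi2_t, df=1)
    m = int(tested.sum())
    thresh = 0.05 / m if bonferroni else 0.05
    t = pd.DataFrame(
        {
            "snp": np.flatnonzero(tested),
            "chrom": gm.snps["chrom"].to_numpy()[tested],
            "bp": gm.snps["bp"].to_numpy()[tested],
            "beta": beta[tested],
            "chi2": chi2_t,
            "p": np.clip(p, np.finfo(float).tiny, 1.0),
            "significant": p < thresh,
        }
    )
    return ScanResult(
        table=t, method="EigenGWAS",
        extras={"lambda_gc": lam, "bonferroni_p": thresh, "m": m},
    )


# ---------------------------------------------------------------------------
# Thresholds and overlap
# ---------------------------------------------------------------------------


def empirical_top(scores: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Indices of scores at or above the (1-q) empirical quantile,
    ties included."""
    scores = np.asarray(scores, dtype=float)
    thresh = np.quantile(scores, 1 - q, method="higher")
    return np.flatnonzero(scores >= thresh)


def merge_regions(regions: list[tuple]) -> list[tuple]:
    """Merge overlapping/adjacent (chrom, start, end) intervals."""
    out = []
    for chrom, start, end in sorted(regions, key=lambda r: (str(r[0]), r[1])):
        if out and out[-1][0] == chrom and start <= out[-1][2] + 1:
            out[-1] = (chrom, out[-1][1], max(end, out[-1][2]))
        else:
            out.append((chrom, start, end))
    return out


def overlap_candidates(
    sets: dict[str, set],
    gm: GenotypeMatrix,
    min_methods: int = 2,
    flank_bp: int = 50_000,
) -> tuple[np.ndarray, list[tuple]]:
    """SNPs flagged by at least ``min_methods`` scans, each reported with
    its +/- ``flank_bp`` window (overlapping windows merged).

    Returns (snp_indices, regions).
    """
    if len(sets) < 2:
        raise ValueError("need at least two method sets")
    counts: dict[int, int] = {}
    for s in sets.values():
        for snp in s:
            counts[snp] = counts.get(snp, 0) + 1
    hits = np.array(sorted(k for k, v in counts.items() if v >= min_methods), dtype=int)
    bp = gm.snps["bp"].to_numpy()
    chroms = gm.snps["chrom"].to_numpy()
    regions = merge_regions(
        [(chroms[s], max(1, int(bp[s]) - flank_bp), int(bp[s]) + flank_bp) for s in hits]
    )
    return hits, regions
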