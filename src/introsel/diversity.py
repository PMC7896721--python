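"""Heterozygosity, LD decay, Sved-equation effective population size,
and the SNP-based method-of-moments inbreeding coefficient.

The Sved (1971) relation links linkage disequilibrium at genetic
distance c Morgans to the effective population size roughly
t = 1/(2c) generations ago:

    Ne_t = (1 / 4c) * (1 / r^2 - 1)

so short-range LD reflects ancient Ne and long-range LD recent Ne.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


def het_stats(gm: GenotypeMatrix, population: str) -> tuple[float, float]:
    """Observed and expected heterozygosity for one population.

    Ho is the mean over SNPs of the observed heterozygote fraction.
    He is the mean of 2p(1-p) * 2n/(2n-1), the unbiased (small-sample
    corrected) expectation, with n the number of non-missing diploid
    calls at the SNP.  Monomorphic SNPs contribute zero to both.
    Returns (Ho, He).
    """
    idx = gm.pop_index(population)
    if idx.size < 2:
        raise ValueError("need >= 2 individuals for heterozygosity")
    d = gm.dosages[idx]
    obs = d != MISSING
    n = obs.sum(axis=0).astype(float)
    ok = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, d, 0).sum(axis=0) / (2 * n)
        ho = ((d == 1) & obs).sum(axis=0) / n
        he = 2 * p * (1 - p) * (2 * n / (2 * n - 1))
    return float(ho[ok].mean()), float(he[ok].mean())


@dataclass
class LDPairs:
    """SNP-pair LD records: chrom, dist_bp, dist_morgan, r2."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"chrom", "dist_bp", "dist_morgan", "r2"}
        if not req <= set(self.table.columns):
            raise ValueError(f"LDPairs table needs columns {req}")


def ld_decay(
    gm: GenotypeMatrix,
    population: str,
    max_dist_bp: int = 10_000_000,
    cm_per_mb_fallback: float = 1.0,
) -> LDPairs:
    """Composite genotypic r^2 for every intra-chromosome SNP pair
    within ``max_dist_bp``.

    r^2 is the squared Pearson correlation of dosages over
    pairwise-complete individuals; the Morgan distance comes from the
    cM map when populated, else bp at ``cm_per_mb_fallback``.
    """
    idx = gm.pop_index(population)
    if idx.size < 10:
        import warnings

        warnings.warn(f"population {population} has {idx.size} < 10 individuals")
    x = gm.dosages[idx].astype(float)
    x[x == MISSING] = np.nan
    chroms = gm.snps["chrom"].to_numpy()
    bp = gm.snps["bp"].to_numpy()
    cm = gm.snps["cm"].to_numpy().astype(float)
    use_map = np.any(cm > 0)

    rows = []
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        xb = x[:, cols]
        # pairwise-complete correlation via masked sums
        obs = ~np.isnan(xb)
        xz = np.where(obs, xb, 0.0)
        n = obs.T.astype(float) @ obs
        s1 = xz.T @ obs
        s2 = (xz**2).T @ obs
        cross = xz.T @ xz
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = cross / n - (s1 / n) * (s1.T / n)
            var_a = s2 / n - (s1 / n) ** 2
            r2 = cov**2 / (var_a * var_a.T)
        ai, bi = np.triu_indices(len(cols), k=1)
        d_bp = bp[cols[bi]] - bp[cols[ai]]
        keep = (d_bp > 0) & (d_bp <= max_dist_bp) & ~np.isnan(r2[ai, bi])
        ai, bi, d_bp = ai[keep], bi[keep], d_bp[keep]
        if use_map:
            d_m = (cm[cols[bi]] - cm[cols[ai]]) / 100.0
        else:
            d_m = d_bp / 1e6 * cm_per_mb_fallback / 100.0
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "dist_bp": d_bp.astype(np.int64),
                    "dist_morgan": d_m,
                    "r2": np.minimum(r2[ai, bi], 1.0),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    if len(table) == 0:
        raise ValueError("no SNP pairs within the distance cutoff")
    return LDPairs(table)


def ld_extent(
    pairs: LDPairs,
    r2_target: float = 0.3,
    n_bins: int = 50,
) -> float:
    """Physical distance (bp) at which binned mean r^2 first decays to
    ``r2_target``, by linear interpolation between bin midpoints.

    Raises ValueError if the binned curve never crosses the target from
    above.
    """
    t = pairs.table
    edges = np.linspace(0, t["dist_bp"].max(), n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(t["dist_bp"], edges[1:-1])
    curve = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            curve[b] = t.loc[sel, "r2"].mean()
    ok = ~np.isnan(curve)
    mids, curve = mids[ok], curve[ok]
    crossings = np.flatnonzero((curve[:-1] > r2_target) & (curve[1:] <= r2_target))
    if crossings.size == 0:
        raise ValueError(f"LD curve never decays through r2={r2_target}")
    j = int(crossings[0]) + 1
    x0, x1, y0, y1 = mids[j - 1], mids[j], curve[j - 1], curve[j]
    return float(x0 + (y0 - r2_target) * (x1 - x0) / (y0 - y1))


@dataclass
class NeEstimate:
    """Sved-equation Ne trajectory: one row per genetic-distance bin."""

    table: pd.DataFrame  # columns: c_morgan, t_gen, r2_mean, ne, n_pairs
    recent_mean: float  # mean Ne over bins with t <= t_max


def estimate_ne(
    pairs: LDPairs,
    t_max: float = 5.0,
    c_range: tuple[float, float] = (0.005, 0.25),
    n_bins: int = 20,
    sample_size_correction: int | None = None,
) -> NeEstimate:
    """Effective population size from LD via Ne_t = (1/4c)(1/r^2 - 1).

    Pairs are binned by Morgan distance over ``c_range``; each bin
    reports Ne at t = 1/(2 c_mean).  ``recent_mean`` averages Ne over
    bins with t <= t_max (i.e. c >= 1/(2 t_max)).  Optionally subtract
    the 1/n sampling floor from mean r^2 first (off by default).
    """
    t = pairs.table
    edges = np.linspace(c_range[0], c_range[1], n_bins + 1)
    rows = []
    for b in range(n_bins):
        sel = (t["dist_morgan"] >= edges[b]) & (t["dist_morgan"] < edges[b + 1])
        if not sel.any():
            continue
        c_bar = float(t.loc[sel, "dist_morgan"].mean())
        r2_bar = float(t.loc[sel, "r2"].mean())
        if sample_size_correction:
            r2_bar = max(r2_bar - 1.0 / sample_size_correction, 1e-12)
        if r2_bar == 0:
            raise ValueError("mean r^2 = 0 in a bin")
        ne = (1.0 / (4.0 * c_bar)) * (1.0 / r2_bar - 1.0)
        rows.append((c_bar, 1.0 / (2.0 * c_bar), r2_bar, max(ne, 0.0), int(sel.sum())))
    table = pd.DataFrame(rows, columns=["c_morgan", "t_gen", "r2_mean", "ne", "n_pairs"])
    recent = table[table["t_gen"] <= t_max]
    recent_mean = float(recent["ne"].mean()) if len(recent) else float("nan")
    return NeEstimate(table=table, recent_mean=recent_mean)


def sved_ne(r2: float, c_morgan: float) -> tuple[float, float]:
    """Point form of the Sved equation: returns (Ne_t, t)."""
    if r2 <= 0:
        raise ValueError("r^2 must be positive")
    return (1.0 / (4.0 * c_morgan)) * (1.0 / r2 - 1.0), 1.0 / (2.0 * c_morgan)


def snp_inbreeding(
    gm: GenotypeMatrix, pruned: np.ndarray | None = None
) -> pd.DataFrame:
    """Method-of-moments SNP-based inbreeding coefficient per individual.

    F = (O_hom - E_hom) / (L - E_hom), where over the individual's
    non-missing pruned SNPs O_hom is the observed homozygote count and
    E_hom = sum_k [1 - 2 p_k (1 - p_k) * 2n/(2n-1)] the Hardy-Weinberg
    expectation; allele frequencies are computed within the
    individual's own population.  Returns columns id, population, F.
    """
    snp_idx = np.arange(gm.n_snp) if pruned is None else np.asarray(pruned)
    if snp_idx.size == 0:
        raise ValueError("empty pruned SNP set")
    pops = gm.individuals["population"].to_numpy()
    rows = []
    for pop in pd.unique(pops):
        idx = gm.pop_index(pop)
        d = gm.dosages[np.ix_(idx, snp_idx)]
        obs = d != MISSING
        n = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, d, 0).sum(axis=0) / (2 * n)
            e_hom_k = 1 - 2 * p * (1 - p) * (2 * n / (2 * n - 1))
        for i_local, i_global in enumerate(idx):
            ok = obs[i_local] & (n >= 2)
            L = int(ok.sum())
            e_hom = float(e_hom_k[ok].sum())
            o_hom = int((d[i_local, ok] != 1).sum())
            if abs(L - e_hom) < 1e-12:
                raise ValueError(f"degenerate F for {gm.individuals['id'][i_global]}")
            rows.append(
                (gm.individuals["id"][i_global], pop, (o_hom - e_hom) / (L - e_hom))
            )
    out = pd.DataFrame(rows, columns=["id", "population", "F"])
    return out.set_index(out["id"]).loc[gm.individuals["id"]].reset_index(drop=True)
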