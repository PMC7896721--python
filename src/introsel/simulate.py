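"""Forward Wright-Fisher simulator with admixture, recombination and truth.

The demographic scenario mirrors the four-population tree
``(((P1, P2), P3), O)`` used throughout the analysis modules: an
ancestral population splits off the outgroup O, then the donor lineage
P3, then the sister pair P1/P2, and a single admixture pulse moves a
fraction ``admix_frac`` of P2's parents to P3 at ``admix_gen``
generations before present.  Simulation is forward in time over standing
ancestral variation (no new mutation), so local donor ancestry is exact
by bookkeeping and is emitted as :class:`TruthTracts`.

The module also provides phenotype simulation under a polygenic model
with configurable heritability and an ROH fixture generator that plants
homozygous segments at known coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .haplotypes import HaplotypePanel

POPS = ("O", "P1", "P2", "P3")


@dataclass
class DemographyParams:
    """Scenario parameters for :func:`simulate_panel`.

    Generations count backwards from the present sample (generation 0).
    ``split_gens`` maps split events to generations before present and
    must satisfy O-split > P3-split > P1/P2-split > ``admix_gen`` >= 0.
    ``recomb_rate`` is in cM/Mb (uniform map).
    """

    n_snps: int = 3600
    n_chrom: int = 3
    chrom_length_bp: int = 50_000_000
    recomb_rate: float = 1.0
    pop_sizes: dict = field(
        default_factory=lambda: {"O": 100, "P1": 100, "P2": 100, "P3": 100}
    )
    split_gens: dict = field(
        default_factory=lambda: {"O": 200, "P3": 120, "P12": 60}
    )
    admix_gen: int = 20
    admix_frac: float = 0.25
    sample_sizes: dict = field(
        default_factory=lambda: {"O": 20, "P1": 30, "P2": 50, "P3": 30}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        g = self.split_gens
        if not (g["O"] > g["P3"] > g["P12"] > self.admix_gen >= 0):
            raise ValueError(
                "require split order O > P3 > P1/P2 > admix_gen >= 0, got "
                f"{g} with admix_gen={self.admix_gen}"
            )
        if not 0.0 <= self.admix_frac <= 1.0:
            raise ValueError("admix_frac outside [0,1]")
        if self.admix_frac > 0 and self.admix_gen < 1:
            raise ValueError("a pulse needs admix_gen >= 1 (generation 0 is the sample)")
        for p in POPS:
            if self.sample_sizes.get(p, 0) > self.pop_sizes[p]:
                raise ValueError(f"sample size exceeds population size for {p}")


@dataclass
class TruthTracts:
    """Ground-truth donor-ancestry intervals per sampled haplotype.

    ``tracts[h]`` lists (chrom, start_bp, end_bp, donor_label) for
    haplotype row ``h`` of the returned panel, non-overlapping and
    sorted; coordinates are 1-based inclusive SNP spans.
    """

    tracts: list
    snps: pd.DataFrame
    individuals: pd.DataFrame
    # allele-1 frequencies of the recipient's native parental pool and the
    # donor pool at the pulse generation: reference panels for supervised
    # ancestry estimation, keys "native" and "donor"
    source_freqs: dict = field(default_factory=dict)

    def donor_fraction(self, population: str | None = None) -> float:
        """Mean fraction of SNPs with donor ancestry over haplotypes
        (of one population if given), computed from tract SNP spans."""
        hap_rows = range(len(self.tracts))
        if population is not None:
            pops = self.individuals["population"].to_numpy()
            ind = np.flatnonzero(pops == population)
            hap_rows = np.concatenate([2 * ind, 2 * ind + 1])
        bp = self.snps["bp"].to_numpy()
        chrom = self.snps["chrom"].to_numpy()
        fracs = []
        for h in hap_rows:
            covered = 0
            for c, s, e, _ in self.tracts[h]:
                covered += int(((chrom == c) & (bp >= s) & (bp <= e)).sum())
            fracs.append(covered / len(self.snps))
        return float(np.mean(fracs)) if fracs else 0.0

    def donor_mask(self) -> np.ndarray:
        """Boolean (n_hap, n_snp) matrix: True where ancestry is donor."""
        bp = self.snps["bp"].to_numpy()
        chrom = self.snps["chrom"].to_numpy()
        mask = np.zeros((len(self.tracts), len(self.snps)), dtype=bool)
        for h, tr in enumerate(self.tracts):
            for c, s, e, _ in tr:
                mask[h] |= (chrom == c) & (bp >= s) & (bp <= e)
        return mask


def _snp_map(dp: DemographyParams, rng: np.random.Generator) -> pd.DataFrame:
    per = np.full(dp.n_chrom, dp.n_snps // dp.n_chrom)
    per[: dp.n_snps % dp.n_chrom] += 1
    frames = []
    for c in range(dp.n_chrom):
        bp = np.array([], dtype=np.int64)
        while bp.size < per[c]:  # collisions are vanishingly rare at array density
            extra = rng.integers(1, dp.chrom_length_bp + 1, size=per[c] - bp.size + 8)
            bp = np.unique(np.concatenate([bp, extra]))
        bp = np.sort(rng.choice(bp, size=per[c], replace=False))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": str(c + 1),
                    "snp_id": [f"snp{c + 1}_{i}" for i in range(per[c])],
                    "cm": bp / 1e6 * dp.recomb_rate,
                    "bp": bp.astype(np.int64),
                    "allele1": "A",
                    "allele2": "B",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class _Pop:
    """Haplotype pool (2N, m) for one population, with optional ancestry labels."""

    __slots__ = ("haps", "anc")

    def __init__(self, haps: np.ndarray, anc: np.ndarray | None = None):
        self.haps = haps
        self.anc = anc


def _gametes_batch(
    pool: _Pop,
    parent_idx: np.ndarray,
    cm: np.ndarray,
    chrom_starts: np.ndarray,
    rng: np.random.Generator,
) -> _Pop:
    """One gamete per parent: crossovers Poisson on the cM map, free
    recombination between chromosomes."""
    n, m = len(parent_idx), pool.haps.shape[1]
    out = np.empty((n, m), dtype=pool.haps.dtype)
    out_anc = None if pool.anc is None else np.empty((n, m), dtype=pool.anc.dtype)
    cm_spans = []
    for c in range(len(chrom_starts) - 1):
        lo, hi = chrom_starts[c], chrom_starts[c + 1]
        cm_spans.append((lo, hi, cm[lo:hi], (cm[hi - 1] - cm[lo]) / 100.0))
    for k, pi in enumerate(parent_idx):
        h0 = pool.haps[2 * pi]
        h1 = pool.haps[2 * pi + 1]
        which = np.empty(m, dtype=bool)
        for lo, hi, cms, morgans in cm_spans:
            n_x = rng.poisson(morgans)
            phase = rng.integers(2)
            if n_x == 0:
                which[lo:hi] = bool(phase)
            else:
                bps = np.sort(rng.uniform(cms[0], cms[-1], n_x))
                which[lo:hi] = ((np.searchsorted(bps, cms) + phase) % 2).astype(bool)
        out[k] = np.where(which, h1, h0)
        if out_anc is not None:
            out_anc[k] = np.where(which, pool.anc[2 * pi + 1], pool.anc[2 * pi])
    return _Pop(out, out_anc)


def _next_generation(
    pools: dict, spec: list, cm: np.ndarray, chrom_starts: np.ndarray, rng: np.random.Generator
) -> dict:
    """spec: list of (child_name, N, [(source_pop, prob), ...])."""
    new = {}
    for name, n_dip, sources in spec:
        labels = [s for s, _ in sources]
        probs = np.array([p for _, p in sources])
        pick = rng.choice(len(labels), size=2 * n_dip, p=probs)
        gams_h = np.empty((2 * n_dip, cm.shape[0]), dtype=np.uint8)
        any_anc = any(pools[s].anc is not None for s in labels)
        gams_a = np.empty((2 * n_dip, cm.shape[0]), dtype=np.int8) if any_anc else None
        for si, s in enumerate(labels):
            rows = np.flatnonzero(pick == si)
            if rows.size == 0:
                continue
            src = pools[s]
            if any_anc and src.anc is None:
                src = _Pop(src.haps, np.zeros_like(src.haps, dtype=np.int8))
            par = rng.integers(src.haps.shape[0] // 2, size=rows.size)
            g = _gametes_batch(src, par, cm, chrom_starts, rng)
            gams_h[rows] = g.haps
            if gams_a is not None:
                gams_a[rows] = g.anc
        new[name] = _Pop(gams_h, gams_a)
    return new


def simulate_panel(
    dp: DemographyParams,
) -> tuple[HaplotypePanel, GenotypeMatrix, TruthTracts]:
    """Simulate the four-population scenario and return phased haplotypes,
    genotypes and exact donor-ancestry truth tracts.

    The root population carries standing variation with allele-1
    frequencies Uniform(0.05, 0.95); splits copy the parental pool into
    independent Wright-Fisher lineages; at ``admix_gen`` each P2 parent
    is drawn from P3 with probability ``admix_frac`` and all genetic
    material inherited through that parent is labelled donor.  The
    ancestral-allele annotation is the root-population major allele.
    """
    rng = np.random.default_rng(dp.seed)
    snps = _snp_map(dp, rng)
    cm = snps["cm"].to_numpy()
    chroms = snps["chrom"].to_numpy()
    chrom_starts = np.concatenate(
        [[0], np.flatnonzero(chroms[1:] != chroms[:-1]) + 1, [len(snps)]]
    )

    p0 = rng.uniform(0.05, 0.95, size=len(snps))
    snps["ancestral"] = np.where(p0 > 0.5, 1, 0).astype(np.int8)

    g = dp.split_gens
    anc_size = int(round(np.mean([dp.pop_sizes[p] for p in POPS])))
    root = _Pop(
        (rng.random((2 * anc_size, len(snps))) < p0).astype(np.uint8)
    )
    pools = {"ANC": root}
    source_freqs: dict = {}

    def wf_spec(names_sizes):
        return [(n, size, [(n, 1.0)]) for n, size in names_sizes]

    for gen in range(g["O"], 0, -1):  # gen = generations before present of the children
        if gen == g["O"]:
            # O splits from the root: both children sample the current root pool
            pools["O"] = pools.pop("ANC")
            pools["ANC12_3"] = pools["O"]
            pools = dict(pools)
        elif gen == g["P3"]:
            pools["P3"] = pools["ANC12_3"]
            pools["ANC12"] = pools.pop("ANC12_3")
        elif gen == g["P12"]:
            pools["P1"] = pools["ANC12"]
            pools["P2"] = pools.pop("ANC12")
        sizes = {
            "O": dp.pop_sizes["O"], "P1": dp.pop_sizes["P1"],
            "P2": dp.pop_sizes["P2"], "P3": dp.pop_sizes["P3"],
            "ANC12_3": anc_size, "ANC12": anc_size,
        }
        spec = wf_spec([(n, sizes[n]) for n in pools])

        if gen == max(dp.admix_gen, 1) and "P2" in pools and "P3" in pools:
            source_freqs = {
                "native": pools["P2"].haps.mean(axis=0),
                "donor": pools["P3"].haps.mean(axis=0),
            }
        if gen == dp.admix_gen and dp.admix_frac > 0:
            # mark donor material: P3 pool gets label 1 for this event
            p3 = pools["P3"]
            pools["P3"] = _Pop(p3.haps, np.ones_like(p3.haps, dtype=np.int8))
            spec = [
                (n, N, src) if n != "P2"
                else ("P2", N, [("P2", 1.0 - dp.admix_frac), ("P3", dp.admix_frac)])
                for n, N, src in spec
            ]
            pools = _next_generation(pools, spec, cm, chrom_starts, rng)
            p3 = pools["P3"]
            pools["P3"] = _Pop(p3.haps, None)  # donor labels only persist in P2
        else:
            pools = _next_generation(pools, spec, cm, chrom_starts, rng)

    # sample the present generation
    hap_rows, anc_rows, meta = [], [], []
    for pop in POPS:
        n_s = dp.sample_sizes.get(pop, 0)
        pool = pools[pop]
        take = rng.choice(pool.haps.shape[0] // 2, size=n_s, replace=False)
        for i, d in enumerate(take):
            hap_rows.append(pool.haps[2 * d])
            hap_rows.append(pool.haps[2 * d + 1])
            if pool.anc is not None:
                anc_rows.extend([pool.anc[2 * d], pool.anc[2 * d + 1]])
            else:
                anc_rows.extend([np.zeros(len(snps), np.int8)] * 2)
            sex = "male" if rng.random() < 0.5 else "female"
            meta.append((f"{pop}_{i:03d}", pop, sex))

    individuals = pd.DataFrame(meta, columns=["id", "population", "sex"])
    panel = HaplotypePanel(
        haplotypes=np.array(hap_rows), snps=snps, individuals=individuals
    )
    gm = panel.to_genotypes()

    bp = snps["bp"].to_numpy()
    tracts = []
    for row in np.array(anc_rows):
        tr = []
        for lo, hi in zip(chrom_starts[:-1], chrom_starts[1:]):
            lab = row[lo:hi]
            edges = np.flatnonzero(np.diff(lab) != 0) + 1
            bounds = np.concatenate([[0], edges, [hi - lo]])
            for s, e in zip(bounds[:-1], bounds[1:]):
                if lab[s] == 1:
                    tr.append(
                        (chroms[lo], int(bp[lo + s]), int(bp[lo + e - 1]), "P3")
                    )
        tracts.append(tr)
    truth = TruthTracts(
        tracts=tracts, snps=snps, individuals=individuals, source_freqs=source_freqs
    )
    return panel, gm, truth


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotype(
    gm: GenotypeMatrix,
    causal: dict[int, float] | None,
    h2: float,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate ``y = sum_k x_k beta_k + g + e`` with polygenic ``g``
    drawn exactly MVN(0, Vg K) from the panel's GRM.

    The total genetic share of variance (causal fixed effects plus
    polygenic) is ``h2``: with the environmental variance fixed at 1
    the genetic variance target is h2/(1-h2), the causal part
    contributes its realized variance, and the polygenic Vg makes up
    the remainder (scaled by the mean GRM diagonal).  ``h2 = 0`` with
    no causal SNPs yields pure standard-normal noise.  Returns a table
    with one row per individual: id, trait, plus covariate columns.
    """
    from .structure import grm_matrix

    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must be in [0,1)")
    causal = causal or {}
    for k in causal:
        if not 0 <= k < gm.n_snp:
            raise IndexError(f"causal SNP index {k} out of range")
    rng = np.random.default_rng(seed)
    n = gm.n_ind
    x = gm.dosages_float()
    col_mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), col_mean, x)

    fixed = np.zeros(n)
    for k, beta in causal.items():
        fixed = fixed + beta * (x[:, k] - x[:, k].mean())
    var_fixed = float(np.var(fixed))
    var_g_target = h2 / (1.0 - h2)  # with Ve = 1
    genetic = fixed
    if h2 > 0 and var_fixed < var_g_target:
        K = grm_matrix(gm)
        kappa = float(np.mean(np.diag(K)))
        w, v = np.linalg.eigh(K)
        w = np.clip(w, 0, None)
        vg = (var_g_target - var_fixed) / kappa
        genetic = fixed + np.sqrt(vg) * (v @ (np.sqrt(w) * rng.standard_normal(n)))
    y = genetic + rng.standard_normal(n)
    out = pd.DataFrame({"id": gm.individuals["id"], "trait": y})
    if covariates is not None:
        out = out.merge(covariates, on="id", how="left")
    return out


# ---------------------------------------------------------------------------
# ROH fixtures
# ---------------------------------------------------------------------------


def plant_roh(
    gm: GenotypeMatrix,
    plan: list[tuple[int, str, int, int]],
    seed: int = 0,
    het_floor: float = 0.3,
) -> tuple[GenotypeMatrix, list[tuple[int, str, int, int]]]:
    """Plant fully homozygous segments at known coordinates.

    ``plan`` lists (individual_index, chrom, start_bp, end_bp).  All
    genotypes are redrawn at Hardy-Weinberg with per-SNP heterozygosity
    at least ``het_floor`` (so no long spurious runs arise), then each
    planted interval is overwritten with homozygous calls.  Returns the
    new matrix and the plan verbatim as truth segments.
    """
    by_ind: dict[int, list] = {}
    for ind, chrom, s, e in plan:
        if not 0 <= ind < gm.n_ind:
            raise IndexError(f"individual index {ind} out of range")
        for c2, s2, e2 in by_ind.get(ind, []):
            if c2 == chrom and s <= e2 and e >= s2:
                raise ValueError(f"overlapping planted intervals for individual {ind}")
        by_ind.setdefault(ind, []).append((chrom, s, e))

    rng = np.random.default_rng(seed)
    # het = 2p(1-p) >= het_floor  <=>  p within [p_lo, 1-p_lo]
    p_lo = 0.5 * (1 - np.sqrt(max(1 - 2 * het_floor, 0.0)))
    p = rng.uniform(p_lo, 1 - p_lo, size=gm.n_snp)
    dos = (
        (rng.random((gm.n_ind, gm.n_snp)) < p).astype(np.int8)
        + (rng.random((gm.n_ind, gm.n_snp)) < p).astype(np.int8)
    )
    bp = gm.snps["bp"].to_numpy()
    chroms = gm.snps["chrom"].to_numpy()
    for ind, chrom, s, e in plan:
        cols = np.flatnonzero((chroms == chrom) & (bp >= s) & (bp <= e))
        hom = 2 * (rng.random(cols.size) < p[cols]).astype(np.int8)
        dos[ind, cols] = hom
    out = GenotypeMatrix(
        dosages=dos, snps=gm.snps.copy(), individuals=gm.individuals.copy()
    )
    return out, list(plan)
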