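"""Population structure: distance matrices, NJ trees, PCA on the GRM,
supervised ancestry proportions, and conservation/family classification.

The conservation classifier implements the mean/SD binning used to
stratify a conserved breed by its native-lineage ancestry proportion:
individuals at or above the mean form the nucleus population, the two
one-SD bands below it are candidate tiers, and individuals more than
two SDs below the mean are flagged for removal from the programme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from skbio.tree import TreeNode

from .genotype_io import MISSING, GenotypeMatrix, ibs_pairwise


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labels."""

    labels: list
    matrix: np.ndarray
    kind: str = "1-IBS"  # or "FST"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(m, 0.0)
        self.matrix = m


def ibs_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """1 - IBS distance between individuals over shared non-missing SNPs."""
    if gm.n_ind < 2:
        raise ValueError("need at least two individuals")
    ibs = ibs_pairwise(gm.dosages)
    if np.isnan(ibs).any():
        raise ValueError("some pair shares no non-missing SNP")
    d = 1.0 - ibs
    d = 0.5 * (d + d.T)  # exact symmetry for downstream NJ
    return DistanceMatrix(labels=gm.individuals["id"].tolist(), matrix=d, kind="1-IBS")


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------


def _wc_components(
    gm: GenotypeMatrix, pops: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Weir-Cockerham variance components a (among populations),
    b (among individuals within populations) and c (within individuals),
    for two or more populations."""
    r = len(pops)
    n = np.zeros((r, gm.n_snp))
    p = np.zeros((r, gm.n_snp))
    h = np.zeros((r, gm.n_snp))
    for i, pop in enumerate(pops):
        idx = gm.pop_index(pop)
        d = gm.dosages[idx]
        obs = d != MISSING
        n[i] = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i] = np.where(obs, d, 0).sum(axis=0) / (2 * n[i])
            h[i] = ((d == 1) & obs).sum(axis=0) / n[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.mean(axis=0)
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    return a, b, c


def wc_fst(
    gm: GenotypeMatrix, pop_a: str, pop_b: str
) -> tuple[float, np.ndarray]:
    """Weir-Cockerham theta between two populations.

    Returns the genome-wide ratio-of-sums estimate and the per-SNP
    theta vector (NaN where undefined; negative values retained).
    """
    for pop in (pop_a, pop_b):
        if len(gm.pop_index(pop)) < 2:
            raise ValueError(f"population {pop} needs >= 2 individuals")
    a, b, c = _wc_components(gm, [pop_a, pop_b])
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = np.where(denom != 0, a / denom, np.nan)
    ok = ~np.isnan(denom) & (denom != 0)
    if not ok.any():
        raise ValueError("FST undefined: no polymorphic SNP in either population")
    genomewide = float(a[ok].sum() / denom[ok].sum())
    return genomewide, per_snp


def fst_matrix(gm: GenotypeMatrix, pops: list[str] | None = None) -> DistanceMatrix:
    """Pairwise genome-wide Weir-Cockerham FST between populations."""
    if pops is None:
        pops = pd.unique(gm.individuals["population"]).tolist()
    m = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            fst, _ = wc_fst(gm, pops[i], pops[j])
            m[i, j] = m[j, i] = max(fst, 0.0)
    return DistanceMatrix(labels=pops, matrix=m, kind="FST")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining; returns an unrooted scikit-bio tree."""
    if len(dm.labels) < 3:
        raise ValueError("NJ needs at least three taxa")
    sk_dm = skbio.DistanceMatrix(dm.matrix, ids=[str(x) for x in dm.labels])
    return skbio.tree.nj(sk_dm)


# ---------------------------------------------------------------------------
# GRM / PCA
# ---------------------------------------------------------------------------


def grm_matrix(gm: GenotypeMatrix, snp_set: np.ndarray | None = None) -> np.ndarray:
    """VanRaden/GCTA genomic relationship matrix.

    G_ij = (1/m) sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k (1 - p_k))
    with frequencies from the full panel; monomorphic SNPs are dropped
    and missing dosages mean-imputed.
    """
    x = gm.dosages_float()
    if snp_set is not None:
        x = x[:, np.asarray(snp_set)]
    p = np.nanmean(x, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs for the GRM")
    x = x[:, poly]
    p = p[poly]
    x = np.where(np.isnan(x), 2 * p, x)
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    return (z @ z.T) / z.shape[1]


def pca_grm(
    gm: GenotypeMatrix, k: int = 10, snp_set: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenpairs of the GRM: (eigenvectors (n, k), eigenvalues (k,)),
    eigenvalues descending."""
    if gm.n_ind < 2:
        raise ValueError("need at least two individuals")
    G = grm_matrix(gm, snp_set)
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)[::-1][:k]
    return v[:, order], w[order]


# ---------------------------------------------------------------------------
# Supervised ancestry
# ---------------------------------------------------------------------------


def supervised_ancestry(
    gm: GenotypeMatrix,
    ref_freqs: dict[str, np.ndarray],
    max_iter: int = 5000,
    tol: float = 1e-9,
    clamp: float = 1e-3,
) -> pd.DataFrame:
    """Per-individual ancestry proportions against fixed reference
    allele frequencies, by EM on the binomial admixture likelihood.

    Each dosage is modelled Binomial(2, sum_l q_l p_lk); the EM update
    is the classic supervised-admixture step on allele responsibilities.
    Returns a DataFrame indexed by individual id with one column per
    lineage; rows sum to 1.
    """
    lineages = list(ref_freqs)
    if len(lineages) < 2:
        raise ValueError("need >= 2 reference lineages")
    P = np.clip(np.array([ref_freqs[l] for l in lineages], dtype=float), clamp, 1 - clamp)
    L, m = P.shape
    if m != gm.n_snp:
        raise ValueError("reference frequencies do not match the SNP map")
    out = np.empty((gm.n_ind, L))
    for i in range(gm.n_ind):
        d = gm.dosages[i].astype(float)
        ok = gm.dosages[i] != MISSING
        d1 = d[ok]
        Pk = P[:, ok]
        q = np.full(L, 1.0 / L)
        for _ in range(max_iter):
            mix1 = q @ Pk          # P(allele = 1)
            mix0 = q @ (1 - Pk)
            r1 = (q[:, None] * Pk) / mix1          # responsibilities, allele 1
            r0 = (q[:, None] * (1 - Pk)) / mix0
            q_new = (r1 @ d1 + r0 @ (2 - d1)) / (2 * d1.size)
            if np.abs(q_new - q).max() < tol:
                q = q_new
                break
            q = q_new
        out[i] = q / q.sum()
    return pd.DataFrame(out, index=gm.individuals["id"], columns=lineages)


# ---------------------------------------------------------------------------
# Conservation classification and families
# ---------------------------------------------------------------------------

GROUPS = ("nucleus", "candidate1", "candidate2", "discard")


@dataclass
class ConservationGrouping:
    """Per-individual conservation tier plus the cutpoints used."""

    assignments: pd.DataFrame  # columns: id, proportion, group, inbreeding_outlier
    mean: float
    sd: float
    cutpoints: dict = field(default_factory=dict)  # {"mean":, "minus1sd":, "minus2sd":}

    def counts(self) -> pd.Series:
        return self.assignments["group"].value_counts().reindex(GROUPS, fill_value=0)


def classify_conservation(
    props: pd.DataFrame,
    lineage: str,
    inbreeding: pd.Series | None = None,
    f_roh: pd.Series | None = None,
    mean: float | None = None,
    sd: float | None = None,
) -> ConservationGrouping:
    """Bin individuals by their ``lineage`` ancestry proportion.

    Cutpoints sit at the mean, mean - 1 SD and mean - 2 SD of the
    proportion (overridable): >= mean -> nucleus; [mean-1sd, mean) ->
    candidate1; [mean-2sd, mean-1sd) -> candidate2; < mean-2sd ->
    discard.  Individuals whose SNP-based F or F_ROH exceeds its own
    mean + 2 SD are flagged as inbreeding outliers.
    """
    x = props[lineage].astype(float)
    mu = float(x.mean()) if mean is None else float(mean)
    sigma = float(x.std(ddof=1)) if sd is None else float(sd)
    if sigma == 0:
        raise ValueError("zero variance in ancestry proportions")
    c1, c2 = mu - sigma, mu - 2 * sigma
    group = np.select(
        [x >= mu, x >= c1, x >= c2], ["nucleus", "candidate1", "candidate2"], "discard"
    )
    outlier = np.zeros(len(x), dtype=bool)
    for series in (inbreeding, f_roh):
        if series is not None:
            s = series.reindex(props.index).astype(float)
            outlier |= (s > s.mean() + 2 * s.std(ddof=1)).to_numpy()
    assignments = pd.DataFrame(
        {
            "id": props.index,
            "proportion": x.to_numpy(),
            "group": group,
            "inbreeding_outlier": outlier,
        }
    )
    return ConservationGrouping(
        assignments=assignments,
        mean=mu,
        sd=sigma,
        cutpoints={"mean": mu, "minus1sd": c1, "minus2sd": c2},
    )


def assign_families(
    tree: TreeNode,
    sex: dict[str, str],
    min_boars: int = 1,
    n_families: int | None = None,
) -> pd.DataFrame:
    """Partition tree leaves into families, each containing at least
    ``min_boars`` males.

    Edges are cut longest-first (ties broken by node name); a cut is
    accepted only if every resulting leaf group keeps >= ``min_boars``
    males.  Cutting stops when ``n_families`` is reached, or when no
    further edge can be cut.  Returns id -> family table.
    """
    import networkx as nx

    leaves = [t.name for t in tree.tips()]
    males = {l for l in leaves if sex.get(l) == "male"}
    if len(males) < min_boars:
        raise ValueError("fewer males than required for a single family")

    g = nx.Graph()
    counter = [0]

    def node_key(node):
        if node.name is None:
            counter[0] += 1
            node.name = f"__internal_{counter[0]}"
        return node.name

    for node in tree.traverse(include_self=True):
        node_key(node)
    for node in tree.traverse(include_self=False):
        g.add_edge(node.parent.name, node.name, length=node.length or 0.0)

    def group_males(component):
        return sum(1 for n in component if n in males)

    edges = sorted(
        g.edges(data=True), key=lambda e: (-e[2]["length"], str(e[0]), str(e[1]))
    )
    cut = nx.Graph(g)
    for u, v, data in edges:
        if n_families is not None and nx.number_connected_components(cut) >= n_families:
            break
        cut.remove_edge(u, v)
        comps = list(nx.connected_components(cut))
        if all(group_males(c) >= min_boars for c in comps):
            continue
        cut.add_edge(u, v, **data)

    rows = []
    for fam_id, comp in enumerate(
        sorted(nx.connected_components(cut), key=lambda c: sorted(c)[0])
    ):
        for n in sorted(comp):
            if n in leaves:
                rows.append((n, fam_id))
    return pd.DataFrame(rows, columns=["id", "family"]).sort_values("id").reset_index(drop=True)
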