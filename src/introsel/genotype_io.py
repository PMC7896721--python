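"""Genotype containers, PLINK binary/text I/O, and the QC pipeline.

The central container is :class:`GenotypeMatrix`: an individuals x SNPs
dosage matrix in {0, 1, 2} with ``MISSING`` (-1) as sentinel, carrying a
per-SNP map (chromosome, bp, cM, alleles, optional ancestral-allele flag)
and per-individual metadata (id, population, sex).  Dosage counts copies
of allele1 (the PLINK A1 allele, conventionally the minor allele).

QC follows the standard SNP-array recipe: duplicate-individual removal by
identity-by-state, minor-allele-frequency and call-rate filtering, and
restriction to mapped autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes (SNP-major): 00=hom A1, 01=missing, 10=het, 11=hom A2.
# Dosage counts A1 alleles, so code -> dosage is 00->2, 10->1, 11->0.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

_SEX_FROM_PLINK = {1: "male", 2: "female"}
_SEX_TO_PLINK = {"male": 1, "female": 2, "unknown": 0}


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with SNP map and individual metadata.

    Attributes
    ----------
    dosages : (n_ind, n_snp) int8 array with values in {0, 1, 2, MISSING}.
    snps : DataFrame with columns chrom (str), snp_id, cm, bp, allele1,
        allele2 and optionally ``ancestral`` (1 if allele1 is ancestral,
        0 if allele2 is, -1 unknown).
    individuals : DataFrame with columns id, population, sex.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if self.dosages.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or MISSING")
        self.snps = self.snps.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)

    @property
    def n_ind(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snp(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def dosages_float(self) -> np.ndarray:
        """Dosages as float with missing -> NaN."""
        x = self.dosages.astype(float)
        x[x == MISSING] = np.nan
        return x

    def pop_index(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(self.individuals["population"].to_numpy() == population)
        if idx.size == 0:
            raise KeyError(f"population {population!r} not present")
        return idx

    def allele_freqs(self, individuals: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP frequency of allele1 over non-missing calls (NaN if none)."""
        d = self.dosages if individuals is None else self.dosages[individuals]
        obs = d != MISSING
        n = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(obs, d, 0).sum(axis=0) / np.where(n > 0, n, np.nan)

    def subset(
        self,
        individuals: np.ndarray | None = None,
        snps: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        ind = np.arange(self.n_ind) if individuals is None else np.asarray(individuals)
        snp = np.arange(self.n_snp) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(ind, snp)].copy(),
            snps=self.snps.iloc[snp].copy(),
            individuals=self.individuals.iloc[ind].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.dosages, other.dosages)
            and self.snps.reset_index(drop=True).equals(other.snps.reset_index(drop=True))
            and self.individuals.reset_index(drop=True).equals(
                other.individuals.reset_index(drop=True)
            )
        )


@dataclass
class QCParams:
    """Thresholds for the QC pipeline (fractions in [0, 1])."""

    maf_min: float = 0.01
    call_rate_min: float = 0.90
    ibs_dup_threshold: float = 0.99
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "ibs_dup_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class QCReport:
    """Per-step removal counts from :func:`apply_qc`."""

    n_ind_in: int = 0
    n_snp_in: int = 0
    removed_dup_individuals: int = 0
    removed_maf_snps: int = 0
    removed_callrate_snps: int = 0
    removed_callrate_individuals: int = 0
    removed_nonautosomal_snps: int = 0
    n_ind_out: int = 0
    n_snp_out: int = 0
    dropped_individual_ids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, v) for k, v in self.__dict__.items() if k != "dropped_individual_ids"],
            columns=["step", "count"],
        )


class EmptyResultError(ValueError):
    """QC removed every SNP or every individual."""


# ---------------------------------------------------------------------------
# PLINK binary (bed/bim/fam) and text (ped/map)
# ---------------------------------------------------------------------------


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK fileset (``prefix.bed/.bim/.fam`` or ``prefix.ped/.map``).

    The binary reader validates the three magic bytes and the SNP-major
    flag and checks that the .bed payload size matches the .bim/.fam row
    counts.  The .fam FID column is used as the population label.
    """
    prefix = Path(prefix)
    if prefix.with_suffix(".bed").exists():
        return _read_bed(prefix)
    if prefix.with_suffix(".ped").exists():
        return _read_ped(prefix)
    raise FileNotFoundError(f"no {prefix}.bed or {prefix}.ped")


def _read_fam(path: Path) -> pd.DataFrame:
    fam = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["fid", "id", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "id": str},
    )
    return pd.DataFrame(
        {
            "id": fam["id"],
            "population": fam["fid"],
            "sex": fam["sex"].map(lambda s: _SEX_FROM_PLINK.get(int(s), "unknown")),
        }
    )


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "bp", "allele1", "allele2"],
        dtype={"chrom": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    bim["cm"] = bim["cm"].astype(float)
    bim["bp"] = bim["bp"].astype(np.int64)
    return bim


def _read_bed(prefix: Path) -> GenotypeMatrix:
    individuals = _read_fam(prefix.with_suffix(".fam"))
    snps = _read_bim(prefix.with_suffix(".bim"))
    n_ind, n_snp = len(individuals), len(snps)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes {raw[:3]!r}")
    bytes_per_snp = (n_ind + 3) // 4
    expected = 3 + bytes_per_snp * n_snp
    if len(raw) != expected:
        raise ValueError(
            f"{prefix}.bed: size {len(raw)} != {expected} expected from "
            f"{n_ind} individuals x {n_snp} SNPs"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_snp, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.zeros((n_snp, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (data >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n_ind]].T
    return GenotypeMatrix(dosages=dosages, snps=snps, individuals=individuals)


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``prefix.bed/.bim/.fam`` (SNP-major bed); lossless round trip."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fam = pd.DataFrame(
        {
            "fid": gm.individuals["population"],
            "id": gm.individuals["id"],
            "father": 0,
            "mother": 0,
            "sex": gm.individuals["sex"].map(lambda s: _SEX_TO_PLINK.get(s, 0)),
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = gm.snps[["chrom", "snp_id", "cm", "bp", "allele1", "allele2"]]
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n_ind, n_snp = gm.n_ind, gm.n_snp
    bytes_per_snp = (n_ind + 3) // 4
    code = np.empty((n_snp, bytes_per_snp * 4), dtype=np.uint8)
    code[:] = 0b11  # pad positions encode hom-A2 (dosage 0), ignored on read
    dos = gm.dosages.T
    lut = np.empty(256, dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        lut[d % 256] = c  # int8 view: MISSING (-1) lands at 255
    code[:, :n_ind] = lut[dos.view(np.uint8)]
    packed = np.zeros((n_snp, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= code[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def _read_ped(prefix: Path) -> GenotypeMatrix:
    mp = pd.read_csv(
        prefix.with_suffix(".map"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "bp"], dtype={"chrom": str, "snp_id": str},
    )
    rows, meta = [], []
    for line in prefix.with_suffix(".ped").read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        fid, iid, _, _, sex = parts[0], parts[1], parts[2], parts[3], parts[4]
        alleles = parts[6:]
        if len(alleles) != 2 * len(mp):
            raise ValueError("ped allele columns inconsistent with map")
        rows.append(alleles)
        meta.append((iid, fid, _SEX_FROM_PLINK.get(int(sex), "unknown")))
    allele_arr = np.array(rows, dtype=object).reshape(len(rows), len(mp), 2)
    a1 = np.empty(len(mp), dtype=object)
    a2 = np.empty(len(mp), dtype=object)
    dosages = np.empty((len(rows), len(mp)), dtype=np.int8)
    for j in range(len(mp)):
        col = allele_arr[:, j, :]
        obs = sorted({a for a in col.ravel() if a != "0"})
        if len(obs) > 2:
            raise ValueError(f"SNP {mp.snp_id[j]}: more than two alleles")
        # A1 = minor allele, matching PLINK recoding
        if len(obs) == 2:
            counts = {a: int((col == a).sum()) for a in obs}
            obs.sort(key=lambda a: (counts[a], a))
        a1[j] = obs[0] if obs else "0"
        a2[j] = obs[1] if len(obs) == 2 else "0"
        missing = (col == "0").any(axis=1)
        dosages[:, j] = np.where(missing, MISSING, (col == a1[j]).sum(axis=1))
    snps = pd.DataFrame(
        {"chrom": mp.chrom, "snp_id": mp.snp_id, "cm": mp.cm.astype(float),
         "bp": mp.bp.astype(np.int64), "allele1": a1, "allele2": a2}
    )
    individuals = pd.DataFrame(meta, columns=["id", "population", "sex"])
    return GenotypeMatrix(dosages=dosages, snps=snps, individuals=individuals)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def ibs_pairwise(dosages: np.ndarray) -> np.ndarray:
    """Pairwise identity-by-state over shared non-missing SNPs.

    IBS(i, j) = mean over SNPs of 1 - |x_i - x_j| / 2.  Returns an
    n x n symmetric matrix with unit diagonal; NaN where a pair shares
    no non-missing SNP.
    """
    x = dosages.astype(float)
    obs = dosages != MISSING
    x[~obs] = 0.0
    obs_f = obs.astype(float)
    n_shared = obs_f @ obs_f.T
    # sum |xi - xj| over shared sites, via the 3x3 genotype table:
    # |xi-xj| = xi + xj - 2*min(xi,xj); use indicator expansion instead.
    diff = np.zeros_like(n_shared)
    for a in (1, 2):
        ga = ((dosages == a) & obs).astype(float)
        for b in range(3):
            if a <= b:
                continue
            gb = ((dosages == b) & obs).astype(float)
            d = ga @ gb.T
            diff += (a - b) * (d + d.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = 1.0 - diff / (2.0 * n_shared)
    np.fill_diagonal(ibs, 1.0)
    return ibs


def apply_qc(gm: GenotypeMatrix, qc: QCParams | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Run the QC pipeline, returning the filtered matrix and a report.

    Steps, in order: (1) duplicate-individual removal at IBS >
    ``ibs_dup_threshold`` keeping the lexicographically smallest id of
    each duplicate cluster, (2) MAF >= ``maf_min``, (3) call rate >=
    ``call_rate_min`` for SNPs then individuals, (4) drop non-autosomal
    or unmapped SNPs.  Raises :class:`EmptyResultError` if nothing
    survives.
    """
    qc = qc or QCParams()
    report = QCReport(n_ind_in=gm.n_ind, n_snp_in=gm.n_snp)

    # (1) IBS duplicates
    ibs = ibs_pairwise(gm.dosages)
    ids = gm.individuals["id"].to_numpy()
    drop: set[int] = set()
    order = np.argsort(ids.astype(str))
    for ii, i in enumerate(order):
        if i in drop:
            continue
        for j in order[ii + 1:]:
            if j in drop:
                continue
            if ibs[i, j] > qc.ibs_dup_threshold:
                drop.add(j)
    keep_ind = np.array([i for i in range(gm.n_ind) if i not in drop])
    report.removed_dup_individuals = len(drop)
    report.dropped_individual_ids = sorted(ids[sorted(drop)].tolist())
    if keep_ind.size == 0:
        raise EmptyResultError("all individuals removed as duplicates")
    gm = gm.subset(individuals=keep_ind)

    # (2) MAF
    p = gm.allele_freqs()
    maf = np.fmin(p, 1 - p)
    keep_snp = np.flatnonzero(~np.isnan(maf) & (maf >= qc.maf_min))
    report.removed_maf_snps = gm.n_snp - keep_snp.size
    if keep_snp.size == 0:
        raise EmptyResultError("all SNPs removed by MAF filter")
    gm = gm.subset(snps=keep_snp)

    # (3) call rate: SNPs first, then individuals
    obs = ~gm.missing_mask()
    snp_cr = obs.mean(axis=0)
    keep_snp = np.flatnonzero(snp_cr >= qc.call_rate_min)
    report.removed_callrate_snps = gm.n_snp - keep_snp.size
    if keep_snp.size == 0:
        raise EmptyResultError("all SNPs removed by call-rate filter")
    gm = gm.subset(snps=keep_snp)
    ind_cr = (~gm.missing_mask()).mean(axis=1)
    keep_ind = np.flatnonzero(ind_cr >= qc.call_rate_min)
    report.removed_callrate_individuals = gm.n_ind - keep_ind.size
    if keep_ind.size == 0:
        raise EmptyResultError("all individuals removed by call-rate filter")
    gm = gm.subset(individuals=keep_ind)

    # (4) autosomes only
    if qc.autosomes_only:
        keep_snp = np.flatnonzero(
            gm.snps["chrom"].map(_is_autosome).to_numpy() & (gm.snps["bp"].to_numpy() > 0)
        )
        report.removed_nonautosomal_snps = gm.n_snp - keep_snp.size
        if keep_snp.size == 0:
            raise EmptyResultError("no autosomal SNPs left")
        gm = gm.subset(snps=keep_snp)

    report.n_ind_out, report.n_snp_out = gm.n_ind, gm.n_snp
    return gm, report


def _is_autosome(chrom: str) -> bool:
    try:
        return int(str(chrom)) > 0
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Composite genotypic r^2: squared Pearson correlation of dosages,
    pairwise-complete over non-missing calls."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step: int = 10,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Greedy windowed LD pruning (PLINK ``--indep-pairwise`` style).

    Within each window of ``window_snps`` consecutive SNPs (never
    crossing chromosomes), for every pair with r^2 > ``r2_max`` the
    later SNP is removed; the window then advances by ``step``.
    Returns the sorted indices of retained SNPs.
    """
    if step > window_snps:
        raise ValueError("step must not exceed window size")
    keep = np.ones(gm.n_snp, dtype=bool)
    chroms = gm.snps["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            window = idx[start : start + window_snps]
            live = [j for j in window if keep[j]]
            for a_pos in range(len(live)):
                a = live[a_pos]
                if not keep[a]:
                    continue
                for b in live[a_pos + 1:]:
                    if not keep[b]:
                        continue
                    r2 = genotype_r2(gm.dosages[:, a], gm.dosages[:, b])
                    if not np.isnan(r2) and r2 > r2_max:
                        keep[b] = False
            if start + window_snps >= len(idx):
                break
            start += step
    return np.flatnonzero(keep)
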