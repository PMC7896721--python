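"""End-to-end orchestration: QC -> diversity -> structure/classification
-> selection scans -> introgression -> association, from one config.

The config either points at a PLINK fileset or asks for a simulated
panel; population roles map the four-taxon tree (((P1,P2),P3),O) onto
population labels, with P2 the admixture target.  All randomness
derives from one root seed.  ``run_all`` returns a nested summary dict
(JSON-serializable) and optionally writes per-stage TSVs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import association, diversity, introgression, roh, selection, structure
from .genotype_io import QCParams, apply_qc, ld_prune, read_plink
from .haplotypes import HaplotypePanel
from .simulate import DemographyParams, simulate_panel, simulate_phenotype


@dataclass
class RunConfig:
    """Study configuration; see the pipeline docstring for semantics."""

    bfile: str | None = None
    simulate: dict = field(default_factory=dict)  # DemographyParams overrides
    roles: dict = field(
        default_factory=lambda: {"P1": "P1", "P2": "P2", "P3": "P3", "O": "O"}
    )
    lineage_refs: tuple = ("P1", "P3")  # native lineage first
    qc: dict = field(default_factory=dict)
    roh_params: dict = field(default_factory=dict)
    phenotype: dict = field(
        default_factory=lambda: {"h2": 0.4, "causal_beta": 0.5}
    )
    window_snps: int = 10
    step_snps: int = 2
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def run_all(cfg: RunConfig) -> dict:
    """Execute the whole workflow; identical config+seed gives identical
    output.  Raises :class:`StageError` naming the failing stage."""
    rng_seeds = np.random.SeedSequence(cfg.seed).generate_state(8)

    # ------------------------------------------------------- input stage
    panel: HaplotypePanel | None = None
    truth = None
    try:
        if cfg.bfile:
            gm = read_plink(cfg.bfile)
        else:
            dp = DemographyParams(**{**cfg.simulate, "seed": int(rng_seeds[0] % 2**31)})
            panel, gm, truth = simulate_panel(dp)
    except Exception as e:  # noqa: BLE001
        raise StageError("input", e) from e

    pops_present = set(gm.individuals["population"])
    missing = [v for v in cfg.roles.values() if v not in pops_present]
    if missing:
        raise StageError("validate", ValueError(f"populations absent: {missing}"))

    summary: dict = {"seed": cfg.seed, "n_ind": gm.n_ind, "n_snp": gm.n_snp}
    p2 = cfg.roles["P2"]

    try:
        gm_qc, qc_report = apply_qc(gm, QCParams(**cfg.qc))
        if panel is not None:
            kept = gm.snps["snp_id"].isin(gm_qc.snps["snp_id"]).to_numpy()
            kept_ind = gm.individuals["id"].isin(gm_qc.individuals["id"]).to_numpy()
            hap_keep = np.repeat(kept_ind, 2)
            panel = HaplotypePanel(
                haplotypes=panel.haplotypes[np.ix_(hap_keep, kept)],
                snps=gm_qc.snps,
                individuals=gm_qc.individuals,
            )
        summary["qc"] = {
            k: v for k, v in asdict(qc_report).items() if k != "dropped_individual_ids"
        }
        gm = gm_qc
    except Exception as e:  # noqa: BLE001
        raise StageError("qc", e) from e

    try:
        het = {
            pop: diversity.het_stats(gm, pop)
            for pop in sorted(pops_present & set(gm.individuals["population"]))
        }
        summary["heterozygosity"] = {
            pop: {"Ho": ho, "He": he} for pop, (ho, he) in het.items()
        }
        pairs = diversity.ld_decay(gm, p2, max_dist_bp=25_000_000)
        ne = diversity.estimate_ne(pairs)
        summary["ne_recent_mean"] = ne.recent_mean
        try:
            summary["ld_extent_r2_0.3_bp"] = diversity.ld_extent(pairs)
        except ValueError:
            summary["ld_extent_r2_0.3_bp"] = None
        pruned = ld_prune(gm)
        fvals = diversity.snp_inbreeding(gm, pruned)
        summary["mean_F"] = {
            pop: float(fvals.loc[fvals["population"] == pop, "F"].mean())
            for pop in het
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("diversity", e) from e

    try:
        roh_overrides = dict(cfg.roh_params)
        if truth is not None and "genome_length_bp" not in roh_overrides:
            # F_ROH denominator = the simulated autosome length
            spans = gm.snps.groupby("chrom")["bp"].max()
            roh_overrides["genome_length_bp"] = float(spans.sum())
        rparams = roh.ROHParams(**roh_overrides)
        rset = roh.call_roh(gm, rparams)
        froh = roh.roh_inbreeding(rset, gm, rparams.genome_length_bp)
        counts, roh_sig = roh.roh_incidence_scan(rset, gm)
        summary["roh"] = {
            "n_segments": int(len(rset.segments)),
            "min_snps_used": rset.min_snps_used,
            "mean_froh": float(froh["froh"].mean()),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("roh", e) from e

    try:
        evec, evals = structure.pca_grm(gm, k=2)
        ref_a, ref_b = cfg.lineage_refs
        if truth is not None and truth.source_freqs:
            # simulated run: use the recorded source-pool frequencies,
            # aligned to the QC-retained SNPs
            kept = truth.snps["snp_id"].isin(gm.snps["snp_id"]).to_numpy()
            refs = {
                ref_a: truth.source_freqs["native"][kept],
                ref_b: truth.source_freqs["donor"][kept],
            }
        else:
            refs = {
                ref_a: gm.allele_freqs(gm.pop_index(ref_a)),
                ref_b: gm.allele_freqs(gm.pop_index(ref_b)),
            }
        target_idx = gm.pop_index(p2)
        props = structure.supervised_ancestry(gm.subset(individuals=target_idx), refs)
        grouping = structure.classify_conservation(
            props, lineage=ref_a,
            inbreeding=fvals.set_index("id")["F"],
            f_roh=froh.set_index("id")["froh"],
        )
        summary["ancestry"] = {
            "mean_native": float(props[ref_a].mean()),
            "sd_native": float(props[ref_a].std(ddof=1)),
            "groups": {k: int(v) for k, v in grouping.counts().items()},
            "cutpoints": grouping.cutpoints,
        }
        dm = structure.ibs_matrix(gm.subset(individuals=target_idx))
        tree = structure.nj_tree(dm)
        sex_map = dict(
            zip(gm.individuals["id"].iloc[target_idx],
                gm.individuals["sex"].iloc[target_idx])
        )
        fams = structure.assign_families(tree, sex_map)
        summary["n_families"] = int(fams["family"].nunique())
    except Exception as e:  # noqa: BLE001
        raise StageError("structure", e) from e

    try:
        scan_sets = {"ROH": set(map(int, roh_sig))}
        eg = selection.eigengwas(gm, evec[:, 0])
        scan_sets["EigenGWAS"] = set(
            eg.table.loc[eg.table["significant"], "snp"].astype(int)
        )
        summary["eigengwas"] = {
            "lambda_gc": eg.extras["lambda_gc"],
            "n_significant": int(eg.table["significant"].sum()),
        }
        if panel is not None:
            ihs = selection.ihs_scan(panel, hap_rows=panel.hap_index(p2))
            if len(ihs.table):
                scan_sets["iHS"] = set(
                    ihs.table.loc[ihs.table["significant"], "snp"].astype(int)
                )
        hits, cand_regions = selection.overlap_candidates(scan_sets, gm)
        summary["candidates"] = {
            "n_overlap_snps": int(hits.size),
            "n_regions": len(cand_regions),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("selection", e) from e

    try:
        sp = introgression.site_patterns(gm, cfg.roles)
        dres = introgression.d_statistic(sp)
        f3res = introgression.f3_test(gm, p2, cfg.roles["P1"], cfg.roles["P3"])
        windows = introgression.window_scan(
            sp, window_snps=cfg.window_snps, step_snps=cfg.step_snps
        )
        wsum = introgression.significant_windows(windows)
        summary["introgression"] = {
            "D": dres.d, "Z_D": dres.z,
            "f3": f3res.f3, "Z_f3": f3res.z,
            "n_significant_windows": int(wsum.windows["significant"].sum()),
            "n_regions": len(wsum.regions),
            "genome_fraction_positive": wsum.genome_fraction_positive,
            "pi_boost": wsum.pi_boost,
            "fdm_threshold": wsum.fdm_threshold,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("introgression", e) from e

    try:
        ph_cfg = cfg.phenotype
        causal_snp = ph_cfg.get("causal_snp")
        if causal_snp is None:
            causal_snp = int(gm.n_snp // 2)
        pheno = simulate_phenotype(
            gm,
            causal={causal_snp: ph_cfg.get("causal_beta", 0.5)},
            h2=ph_cfg.get("h2", 0.4),
            seed=int(rng_seeds[1] % 2**31),
        )
        K = association.grm(gm, pruned)
        window = np.arange(max(0, causal_snp - 10), min(gm.n_snp, causal_snp + 11))
        lmm = association.lmm_assoc(gm, pheno, K, snp_set=window)
        row = lmm.table[lmm.table["snp"] == causal_snp]
        summary["association"] = {
            "delta": lmm.delta,
            "causal_snp": causal_snp,
            "causal_p": float(row["p"].iloc[0]) if len(row) else None,
            "causal_beta": float(row["beta"].iloc[0]) if len(row) else None,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("association", e) from e

    if truth is not None:
        summary["truth"] = {"donor_fraction_P2": truth.donor_fraction(p2)}

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonify)
        rset.segments.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
        froh.to_csv(out / "froh.tsv", sep="\t", index=False)
        fvals.to_csv(out / "snp_inbreeding.tsv", sep="\t", index=False)
        grouping.assignments.to_csv(out / "conservation_groups.tsv", sep="\t", index=False)
        fams.to_csv(out / "families.tsv", sep="\t", index=False)
        eg.table.to_csv(out / "eigengwas.tsv", sep="\t", index=False)
        wsum.windows.to_csv(out / "fdm_windows.tsv", sep="\t", index=False)
        lmm.table.to_csv(out / "association.tsv", sep="\t", index=False)
    return summary


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
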