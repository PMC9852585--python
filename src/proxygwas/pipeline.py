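"""End-to-end orchestration: simulate -> impute -> GWAS -> loci -> replicate.

The run mirrors a proxy-imputation discovery design: a small measured subset
trains sex-stratified imputation models, the imputed traits are scanned at
full-cohort scale (the training subset is excluded from discovery, as the
measured individuals would otherwise enter twice), significant signals are
clumped into quasi-independent loci, screened for novelty, power-screened
for replicability at the replication sample size, and tested in an
independent simulated replication cohort.  A small shared-causal summary
region exercises the colocalisation stage.  Every stage writes a TSV
artifact and one JSON run report; a fixed seed reproduces the report byte
for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import io as pio
from .assoc import preprocess_phenotype, run_gwas
from .imputation import effective_sample_size, impute_cohort
from .loci import annotate_genes, cluster_loci, collate_significant, filter_known
from .multitest import multitest_report
from .replication import select_replicable, test_replication
from .simulate import Cohort, SimulationConfig, simulate_cohort, simulate_replication_cohort, simulate_summary_region

log = logging.getLogger("proxygwas")

__all__ = ["Thresholds", "RunConfig", "PipelineError", "run_pipeline"]


@dataclass
class Thresholds:
    """All fixed analysis constants, overridable per run."""

    alpha_gw: float = 5e-8
    maf_min: float = 0.001
    info_min: float = 0.4
    sd_trim_log: float = 6.0
    sd_trim_int: float = 4.0
    locus_gap: float = 1e6
    gene_flank: float = 5e5
    p_exclude: float = 1e-12
    fdr: float = 0.1
    pp_h4: float = 0.75


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    replicable_p_max: float = 0.05   # expected-P cutoff for the power screen
    composite_indices: bool = True   # derive fat/lean ratio and fat/height^2
    catalogue_path: str | None = None
    gene_table_path: str | None = None
    seed: int | None = None          # overrides simulation.seed when set
    outdir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim = SimulationConfig(**raw.get("simulation", {}))
        thr = Thresholds(**raw.get("thresholds", {}))
        extra = {k: v for k, v in raw.items() if k not in ("simulation", "thresholds")}
        return cls(simulation=sim, thresholds=thr, **extra)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, snapshot: str | None, cause: Exception):
        self.stage = stage
        self.snapshot = snapshot
        super().__init__(f"stage {stage!r} failed ({cause}); config snapshot: {snapshot}")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(type(obj))


def _add_composites(cohort: Cohort) -> list[str]:
    """Fat/lean ratio and fat/height^2 index on the positive scale."""
    df = cohort.table
    added = []
    if {"fat_mass", "lean_mass"}.issubset(df.columns):
        df["fmr"] = df["fat_mass"] / df["lean_mass"]
        added.append("fmr")
    if {"fat_mass", "height"}.issubset(df.columns):
        df["fmi"] = df["fat_mass"] / df["height"] ** 2
        added.append("fmi")
    cohort.target_cols = cohort.target_cols + added
    return added


def _log_cohort(cohort: Cohort) -> Cohort:
    """Natural-log copy of proxies and targets (generative scale)."""
    df = cohort.table.copy()
    for col in cohort.proxy_cols + cohort.target_cols:
        with np.errstate(invalid="ignore", divide="ignore"):
            df[col] = np.log(df[col].to_numpy(dtype=float))
    return dataclasses.replace(cohort, table=df)


def _preprocess_and_scan(raw_values, cohort: Cohort, genotypes, rows, trait,
                         thr: Thresholds):
    """Preprocess one trait on a row subset and run the additive scan."""
    sub = cohort.table.loc[rows]
    pheno = preprocess_phenotype(
        np.asarray(raw_values, dtype=float)[rows],
        sub[cohort.covariate_cols], sub[cohort.sex_col].to_numpy(), trait=trait,
        sd_trim_log=thr.sd_trim_log, sd_trim_int=thr.sd_trim_int)
    gsub = dataclasses.replace(genotypes, dosages=genotypes.dosages[rows])
    table, excluded = run_gwas(gsub, pheno, maf_min=thr.maf_min, info_min=thr.info_min)
    return pheno, table, excluded


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written to disk)."""
    cfg = config
    if cfg.seed is not None:
        cfg.simulation = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    thr = cfg.thresholds
    outdir = pio.ensure_dir(cfg.outdir) if cfg.outdir else None
    snapshot = None
    if outdir:
        snapshot = str(outdir / "config_snapshot.json")
        with open(snapshot, "w") as fh:
            json.dump({"simulation": dataclasses.asdict(cfg.simulation),
                       "thresholds": dataclasses.asdict(thr),
                       "replicable_p_max": cfg.replicable_p_max},
                      fh, default=_json_default, indent=1, sort_keys=True)

    stage = "simulate"
    try:
        cohort, genotypes, truth = simulate_cohort(cfg.simulation)
        log.info("stage=%s seed=%d n=%d m=%d", stage, cfg.simulation.seed,
                 cohort.n, genotypes.n_variants)
        _add_composites(cohort)
        logc = _log_cohort(cohort)
        measured = cohort.measured_mask()
        disc_rows = np.flatnonzero(~measured)   # discovery excludes the training subset
        if outdir:
            pio.write_phenotypes(cohort, outdir / "phenotypes.tsv")

        stage = "impute"
        predictors = cohort.proxy_cols + [c for c in cohort.covariate_cols]
        imputed, models, reports = impute_cohort(logc, cohort.target_cols, predictors)
        acc = {f"{r.trait}:{r.stratum}": {"r": r.r, "r2": r.r2, "n": r.n} for r in reports}
        mean_r2 = float(np.mean([r.r2 for r in reports]))
        n_eff = effective_sample_size(mean_r2, len(disc_rows))
        log.info("stage=impute traits=%d mean_r2=%.3f n_eff=%d",
                 len(cohort.target_cols), mean_r2, n_eff)
        if outdir:
            pio.write_model_store(models, reports, outdir / "imputation_models.tsv")

        stage = "gwas"
        gwas_tables: dict[str, pd.DataFrame] = {}
        pheno_matrix = {}
        for trait in cohort.target_cols:
            vals = np.exp(imputed[f"i_{trait}"].to_numpy(dtype=float))  # back to positive scale
            pheno, table, _ = _preprocess_and_scan(vals, cohort, genotypes,
                                                   disc_rows, trait, thr)
            gwas_tables[trait] = table
            pheno_matrix[trait] = pheno.values
            if outdir:
                table.to_csv(outdir / f"gwas_i_{trait}.tsv", sep="\t", index=False)
        # measured-subset scan of the directly observed targets (power contrast)
        meas_rows = np.flatnonzero(measured)
        gwas_measured: dict[str, pd.DataFrame] = {}
        for trait in cohort.target_cols:
            vals = cohort.table[trait].to_numpy(dtype=float)
            _, table, _ = _preprocess_and_scan(vals, cohort, genotypes,
                                               meas_rows, trait, thr)
            gwas_measured[trait] = table

        stage = "multitest"
        pm = pd.DataFrame(pheno_matrix)
        mt = multitest_report(pm, alpha_gw=thr.alpha_gw)
        log.info("stage=multitest m=%d m_eff=%s threshold=%g", mt.m, mt.m_eff, mt.threshold)

        stage = "loci"
        signals = collate_significant(gwas_tables, mt.threshold)
        loci = cluster_loci(signals, gap=thr.locus_gap)
        catalogue = pd.read_csv(cfg.catalogue_path, sep="\t", dtype={"chrom": str}) \
            if cfg.catalogue_path else None
        loci = filter_known(loci, catalogue=catalogue, reference_assoc=None,
                            p_exclude=thr.p_exclude, window=thr.locus_gap)
        gene_table = pd.read_csv(cfg.gene_table_path, sep="\t", dtype={"chrom": str}) \
            if cfg.gene_table_path else None
        if gene_table is not None:
            for locus in loci:
                annotate_genes(locus, gene_table, flank=thr.gene_flank)
        novel = [l for l in loci if l.novel]
        log.info("stage=loci signals=%d loci=%d novel=%d", len(signals), len(loci), len(novel))
        if outdir:
            pd.DataFrame([{
                "chrom": l.chrom, "start": l.start, "end": l.end,
                "lead_rsid": l.lead_rsid, "lead_trait": l.lead_trait,
                "lead_p": l.lead_p, "n_members": l.n_members, "novel": l.novel,
                "genes": ";".join(l.genes),
            } for l in loci]).to_csv(outdir / "loci.tsv", sep="\t", index=False)

        stage = "replicate"
        leads = pd.DataFrame([{
            "rsid": l.lead_rsid, "trait": l.lead_trait, "chrom": l.chrom,
            "pos": l.lead_pos} for l in novel])
        n_repl = cfg.simulation.n_replication
        repl_summary = None
        replicable = pd.DataFrame()
        if len(leads):
            disc = leads.merge(
                pd.concat([t.assign(trait=name) for name, t in gwas_tables.items()]),
                left_on=["rsid", "trait"], right_on=["rsid", "trait"], how="left")
            disc = disc.rename(columns={"beta1": "beta_disc", "se": "se_disc"})
            replicable = select_replicable(disc, n_repl, cfg.replicable_p_max)
            if len(replicable):
                repl_cohort, repl_geno = simulate_replication_cohort(cfg.simulation, truth)
                _add_composites(repl_cohort)
                repl_rows = np.arange(repl_cohort.n)
                repl_stats = []
                for trait in replicable["trait"].unique():
                    vals = repl_cohort.table[trait].to_numpy(dtype=float)
                    _, table, _ = _preprocess_and_scan(vals, repl_cohort, repl_geno,
                                                       repl_rows, trait, thr)
                    table = table.rename(columns={"beta1": "beta_repl", "se": "se_repl"})
                    table["trait"] = trait
                    repl_stats.append(table[["rsid", "trait", "beta_repl", "se_repl"]])
                repl_stats = pd.concat(repl_stats, ignore_index=True)
                repl_summary = test_replication(replicable, repl_stats,
                                                fdr_level=thr.fdr, on=("rsid", "trait"))
                if outdir:
                    repl_summary.records.to_csv(outdir / "replication.tsv",
                                                sep="\t", index=False)

        stage = "coloc"
        region = simulate_summary_region(50, 3.0, "shared-causal",
                                         seed=cfg.simulation.seed)
        labf_g = coloc_mod.wakefield_log_abf(region.gwas["beta"].to_numpy(),
                                             region.gwas["se"].to_numpy())
        labf_e = coloc_mod.wakefield_log_abf(region.eqtl["beta"].to_numpy(),
                                             region.eqtl["se"].to_numpy())
        cres = coloc_mod.coloc_posteriors(labf_g, labf_e)
        smr_df = coloc_mod.smr_heidi_screen(
            {"demo_region": (region.gwas, region.eqtl, region.ld)})
        if outdir:
            out = pd.DataFrame([{**cres.pp,
                                 "colocalised": cres.pp["H4"] > thr.pp_h4,
                                 **smr_df.iloc[0].to_dict()}])
            out.to_csv(outdir / "coloc.tsv", sep="\t", index=False)

        stage = "report"
        causal = set(truth.causal_ids)

        def _causal_chi2(tables: dict[str, pd.DataFrame]) -> dict:
            best: dict[str, float] = {}
            for table in tables.values():
                sub = table[table["rsid"].isin(causal)]
                for rsid, beta, se in zip(sub["rsid"], sub["beta1"], sub["se"]):
                    chi2 = (beta / se) ** 2
                    best[rsid] = max(chi2, best.get(rsid, 0.0))
            return best

        chi2_full = _causal_chi2(gwas_tables)
        chi2_meas = _causal_chi2(gwas_measured)
        sig_full = len({r for l in loci for r in l.members["rsid"] if r in causal})
        meas_signals = collate_significant(gwas_measured, mt.threshold)
        sig_meas = len(set(meas_signals["rsid"]) & causal) if len(meas_signals) else 0

        report = {
            "seed": cfg.simulation.seed,
            "imputation_accuracy": acc,
            "mean_r2": mean_r2,
            "n_discovery": int(len(disc_rows)),
            "n_effective": n_eff,
            "m_traits": mt.m,
            "m_eff": mt.m_eff,
            "m_eff_used": mt.m_eff_used,
            "gws_threshold": mt.threshold,
            "n_signals": int(len(signals)),
            "n_loci": len(loci),
            "n_novel_loci": len(novel),
            "n_replicable": int(len(replicable)),
            "n_tested": repl_summary.n_tested if repl_summary else 0,
            "n_consistent": repl_summary.n_consistent if repl_summary else 0,
            "n_replicated": repl_summary.n_replicated if repl_summary else 0,
            "sign_test_p": repl_summary.sign_test_p if repl_summary else None,
            "power": {
                "median_chi2_imputed_full": float(np.median(list(chi2_full.values()))) if chi2_full else 0.0,
                "median_chi2_measured_subset": float(np.median(list(chi2_meas.values()))) if chi2_meas else 0.0,
                "causal_loci_significant_imputed": sig_full,
                "causal_variants_significant_measured": sig_meas,
            },
            "coloc_demo": {"pp": cres.pp, "colocalised": cres.pp["H4"] > thr.pp_h4,
                           "smr_p": float(smr_df["smr_p"].iloc[0]),
                           "heidi_p": float(smr_df["heidi_p"].iloc[0])},
        }
        if outdir:
            with open(outdir / "report.json", "w") as fh:
                json.dump(report, fh, default=_json_default, indent=1, sort_keys=True)
        return report
    except Exception as err:  # noqa: BLE001 - re-raised with stage context
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, snapshot, err) from err
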