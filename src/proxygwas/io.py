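"""Plain-text I/O: phenotype/genotype TSVs, a minimal dosage VCF writer,
model stores, truth records and YAML run configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .imputation import AccuracyReport, ImputationModel
from .simulate import Cohort, GenotypeMatrix, PositiveScale, SimulationConfig, TruthRecord

__all__ = [
    "write_phenotypes", "read_phenotypes",
    "write_genotypes", "read_genotypes", "write_vcf",
    "write_truth", "write_model_store", "read_model_store",
    "load_run_config",
]


def write_phenotypes(cohort: Cohort, path) -> None:
    """One row per individual; proxies, covariates and (sparse) targets."""
    cohort.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path, proxy_cols, target_cols, covariate_cols) -> Cohort:
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "measured" not in table.columns:
        table["measured"] = table[target_cols[0]].notna() if target_cols else True
    return Cohort(table=table, proxy_cols=list(proxy_cols),
                  target_cols=list(target_cols), covariate_cols=list(covariate_cols))


def write_genotypes(gmat: GenotypeMatrix, path) -> None:
    """Dosage TSV: a metadata header block (one line per field, '#'-prefixed)
    followed by one dosage column per variant, one row per individual."""
    meta = gmat.variants
    with open(path, "w") as fh:
        for field in ("rsid", "chrom", "pos", "a1", "a0", "eaf", "info"):
            fh.write("#" + field + "\t" + "\t".join(map(str, meta[field])) + "\n")
        np.savetxt(fh, gmat.dosages, fmt="%.3f", delimiter="\t")


def read_genotypes(path) -> GenotypeMatrix:
    meta: dict[str, list] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                name, *vals = line[1:].rstrip("\n").split("\t")
                meta[name] = vals
            else:
                rows.append([float(v) for v in line.split()])
    variants = pd.DataFrame(meta)
    for col in ("pos",):
        variants[col] = variants[col].astype(int)
    for col in ("eaf", "info"):
        variants[col] = variants[col].astype(float)
    return GenotypeMatrix(dosages=np.asarray(rows), variants=variants)


def write_vcf(gmat: GenotypeMatrix, cohort: Cohort, path) -> None:
    """VCFv4.2 with a DS (dosage) FORMAT field, one sample per individual."""
    meta = gmat.variants
    samples = cohort.table[cohort.id_col].tolist()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n')
        for chrom in meta["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, row in meta.iterrows():
            ds = "\t".join(f"{d:.3f}" for d in gmat.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.rsid}\t{row.a0}\t{row.a1}\t.\tPASS\t"
                     f"INFO={row['info']:.4f}\tDS\t{ds}\n")


def write_truth(truth: TruthRecord, path) -> None:
    """JSON snapshot of the ground truth (arrays listed, config echoed)."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (SimulationConfig, PositiveScale)):
            return dataclasses.asdict(obj)
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="list")
        raise TypeError(type(obj))

    payload = dataclasses.asdict(truth)
    payload.pop("factor", None)  # per-individual; large and recomputable
    with open(path, "w") as fh:
        json.dump(payload, fh, default=default, indent=1, sort_keys=True)


def write_model_store(models: list[ImputationModel],
                      reports: list[AccuracyReport], path) -> None:
    """One record per trait x sex: n, intercept, named coefficients, r, R^2."""
    acc = {(r.trait, r.stratum): r for r in reports}
    rows = []
    for m in models:
        rep = acc.get((m.trait, m.stratum))
        row = {"trait": m.trait, "stratum": m.stratum, "n": m.n_train,
               "intercept": m.intercept, "residual_variance": m.residual_variance,
               "r": rep.r if rep else np.nan, "r2": rep.r2 if rep else np.nan}
        row.update({f"beta_{k}": v for k, v in m.coefficients.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_model_store(path) -> list[ImputationModel]:
    df = pd.read_csv(path, sep="\t")
    models = []
    for _, row in df.iterrows():
        coefs = {c[len("beta_"):]: float(row[c]) for c in df.columns if c.startswith("beta_")}
        models.append(ImputationModel(
            trait=row["trait"], stratum=row["stratum"], intercept=float(row["intercept"]),
            coefficients=coefs, residual_variance=float(row["residual_variance"]),
            n_train=int(row["n"])))
    return models


def load_run_config(path) -> dict:
    """YAML run configuration; see docs/methods.md for the schema."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    return cfg


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
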