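"""Phenotype preprocessing and fast per-variant additive association.

The preprocessing cascade runs separately within each sex stratum and then
merges the strata:

1. natural log of the (strictly positive) raw phenotype;
2. removal of values more than 6 SD from the stratum mean;
3. OLS residualisation on the covariate model (categoricals one-hot coded);
4. rank-based inverse normal transformation (Blom offset 3/8);
5. removal of transformed values more than 4 SD from the stratum mean.

Association then regresses the merged analysis phenotype on allelic dosage,
one variant at a time, under an additive model.  Variants failing the
minor-allele-frequency or imputation-info filters are reported separately
rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix

__all__ = [
    "AnalysisPhenotype",
    "inverse_normal_transform",
    "preprocess_phenotype",
    "run_gwas",
    "GWAS_COLUMNS",
]

P_FLOOR = 1e-300

# reason codes for per-row exclusions
REASON_LOG = "log-undefined"
REASON_6SD = "6SD"
REASON_4SD = "4SD"
REASON_MISSING = "missing"


@dataclass
class AnalysisPhenotype:
    """Post-pipeline analysis values with a per-row audit trail."""

    trait: str
    values: np.ndarray            # NaN where excluded
    include: np.ndarray           # bool mask
    reasons: pd.Series            # exclusion reason code per excluded row
    audit: dict[str, int] = field(default_factory=dict)

    @property
    def n_included(self) -> int:
        return int(self.include.sum())


def inverse_normal_transform(values) -> np.ndarray:
    """Map values to standard-normal quantiles by rank (Blom offset).

    transformed_i = Phi^{-1}((rank_i - 3/8) / (n + 1/4)); ties get averaged
    ranks.  All-equal input has no defined ranks and raises ValueError.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D array with at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.all(x == x[0]):
        raise ValueError("all values equal; ranks are degenerate")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


def _one_hot(cov: pd.DataFrame, categorical: list[str]) -> np.ndarray:
    cols = []
    for c in cov.columns:
        if c in categorical:
            dummies = pd.get_dummies(cov[c].astype("category"), drop_first=True)
            cols.append(dummies.to_numpy(dtype=float))
        else:
            cols.append(cov[c].to_numpy(dtype=float)[:, None])
    return np.hstack(cols) if cols else np.empty((len(cov), 0))


def preprocess_phenotype(raw, covariates: pd.DataFrame, sex, trait: str = "",
                         categorical: list[str] | None = None,
                         sd_trim_log: float = 6.0, sd_trim_int: float = 4.0,
                         log_transform: bool = True) -> AnalysisPhenotype:
    """Run the per-sex log / trim / residualise / INT / trim cascade.

    Non-positive raw values are excluded with a reason code rather than
    raising; a rank-deficient covariate design does raise.  SD trims use the
    mean and SD of the currently included values, single pass.
    """
    raw = np.asarray(raw, dtype=float)
    sex = np.asarray(sex)
    n = len(raw)
    if len(covariates) != n or len(sex) != n:
        raise ValueError("raw values, covariates and sex labels must be row-aligned")
    categorical = categorical if categorical is not None else ["batch", "centre"]
    categorical = [c for c in categorical if c in covariates.columns]

    values = np.full(n, np.nan)
    reasons = pd.Series(pd.NA, index=np.arange(n), dtype="string")
    audit = {REASON_MISSING: 0, REASON_LOG: 0, REASON_6SD: 0, REASON_4SD: 0}

    missing = ~np.isfinite(raw)
    missing |= pd.isna(covariates).to_numpy().any(axis=1)
    reasons[missing] = REASON_MISSING
    audit[REASON_MISSING] = int(missing.sum())

    for stratum in pd.unique(sex):
        idx = np.flatnonzero((sex == stratum) & ~missing)
        if len(idx) == 0:
            continue
        x = raw[idx]
        if log_transform:
            bad = x <= 0
            reasons.iloc[idx[bad]] = REASON_LOG
            audit[REASON_LOG] += int(bad.sum())
            idx = idx[~bad]
            x = np.log(raw[idx])
        # 6 SD trim on the (log) scale
        mu, sd = x.mean(), x.std()
        out6 = np.abs(x - mu) > sd_trim_log * sd if sd > 0 else np.zeros(len(x), bool)
        reasons.iloc[idx[out6]] = REASON_6SD
        audit[REASON_6SD] += int(out6.sum())
        idx, x = idx[~out6], x[~out6]
        if len(x) < 2:
            raise ValueError(f"stratum {stratum!r}: fewer than 2 usable values")
        if np.ptp(x) == 0:
            # constant input leaves nothing but float noise after
            # residualisation; the rank transform would be meaningless
            raise ValueError(f"stratum {stratum!r}: all values equal; ranks are degenerate")
        # covariate residualisation
        C = _one_hot(covariates.iloc[idx], categorical)
        X = np.column_stack([np.ones(len(x)), C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"stratum {stratum!r}: covariate design is rank deficient")
        beta, _, _, _ = np.linalg.lstsq(X, x, rcond=None)
        resid = x - X @ beta
        try:
            z = inverse_normal_transform(resid)
        except ValueError as err:
            raise ValueError(f"stratum {stratum!r}: {err}") from err
        # 4 SD trim on the transformed scale
        mu, sd = z.mean(), z.std()
        out4 = np.abs(z - mu) > sd_trim_int * sd if sd > 0 else np.zeros(len(z), bool)
        reasons.iloc[idx[out4]] = REASON_4SD
        audit[REASON_4SD] += int(out4.sum())
        values[idx[~out4]] = z[~out4]

    include = np.isfinite(values)
    return AnalysisPhenotype(trait=trait, values=values, include=include,
                             reasons=reasons, audit=audit)


GWAS_COLUMNS = ["rsid", "chr", "pos", "a1", "a0", "freq1", "info", "n", "beta1", "se", "p"]


def run_gwas(genotypes: GenotypeMatrix, phenotype: AnalysisPhenotype,
             maf_min: float = 0.001, info_min: float = 0.4,
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variant additive association of the analysis phenotype on dosage.

    For each variant, beta = cov(g, y) / var(g), s.e. = sqrt(RSS /
    ((n - 2) * sum (g - mean g)^2)) and a two-sided P value from the t
    distribution with n - 2 df.  Missing dosages are mean-substituted per
    variant.  Returns ``(results, excluded)``; excluded rows carry the filter
    reason (maf, info, or zero-variance).
    """
    mask = phenotype.include
    y = phenotype.values[mask]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 analysed individuals")
    if genotypes.n_individuals != len(mask):
        raise ValueError("genotype rows must align with the phenotype vector")

    g = genotypes.dosages[mask].copy()
    nan_mask = np.isnan(g)
    if nan_mask.any():
        col_means = np.nanmean(g, axis=0)
        g[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])

    meta = genotypes.variants
    freq1 = g.mean(axis=0) / 2.0
    maf = np.minimum(freq1, 1.0 - freq1)
    info = meta["info"].to_numpy(dtype=float)

    gc = g - g.mean(axis=0)
    sxx = np.einsum("ij,ij->j", gc, gc)
    zero_var = sxx <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        yc = y - y.mean()
        sxy = yc @ gc
        beta = sxy / sxx
        rss = float(yc @ yc) - beta * sxy
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / ((n - 2) * sxx))
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.clip(p, P_FLOOR, 1.0)

    keep = (maf >= maf_min) & (info >= info_min) & ~zero_var
    reason = np.where(zero_var, "zero-variance",
                      np.where(maf < maf_min, "maf", np.where(info < info_min, "info", "")))

    results = pd.DataFrame({
        "rsid": meta["rsid"], "chr": meta["chrom"], "pos": meta["pos"],
        "a1": meta["a1"], "a0": meta["a0"], "freq1": freq1, "info": info,
        "n": n, "beta1": beta, "se": se, "p": p,
    })
    excluded = results.loc[~keep, ["rsid", "chr", "pos"]].copy()
    excluded["reason"] = reason[~keep]
    results = results.loc[keep].reset_index(drop=True)[GWAS_COLUMNS]
    return results, excluded.reset_index(drop=True)
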