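"""Synthetic cohorts with a latent adiposity factor and known ground truth.

The generative model mirrors a proxy-phenotype imputation study design:
a large cohort carries cheap proxy phenotypes (anthropometric / bio-impedance
style measures) for everyone, while an expensive imaging-style target
phenotype is observed only in a small "measured" subset.  Proxies and targets
share a latent adiposity factor ``A``; causal variants act partly through the
factor (mediation fraction ``delta``) and partly directly on the target:

    A_i   = sum_k delta_k * b_k * (g_ik - 2 p_k) + c_i' w + N(0, sigma_A^2)
    x_ij  = lambda_j * A_i + N(0, sigma_x^2)                       (proxies)
    y_it  = a_t * A_i + sum_k (1 - delta_k) * b_k * (g_ik - 2 p_k)
            + N(0, sigma_t^2)                                      (targets)

Phenotypes flagged positive-scale are exponentiated, ``Y = exp(mu + s * y)``,
so the natural-log transform of the analysis pipeline recovers the latent
linear scale exactly.  Genotypes are Binomial(2, p) per variant (Hardy-
Weinberg, no LD in cohort mode); linkage disequilibrium exists only in the
summary-statistics region simulator used by the colocalisation module.

Because the model is linear-Gaussian on the latent scale, the imputation
R-squared, the per-variant marginal effects on the target, and the effects
transmitted to the proxy-predicted (imputed) target are all available in
closed form and are returned in a :class:`TruthRecord` for parameter-recovery
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PositiveScale",
    "SimulationConfig",
    "GenotypeMatrix",
    "Cohort",
    "TruthRecord",
    "SummaryRegion",
    "simulate_cohort",
    "simulate_replication_cohort",
    "simulate_summary_region",
]

SEXES = ("F", "M")
_ALLELES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PositiveScale:
    """Map latent values onto a strictly positive measurement scale."""

    enabled: bool = True
    mu: float = 3.0
    s: float = 0.25

    def forward(self, latent: np.ndarray) -> np.ndarray:
        if not self.enabled:
            return latent
        return np.exp(self.mu + self.s * latent)


def _default_covariate_effects() -> dict:
    # weights of covariates on the latent factor; batch enters as an
    # additive per-level shift
    return {
        "age": 0.01,
        "townsend": 0.02,
        "pc1": 0.05,
        "pc2": 0.05,
        "batch": (-0.1, -0.05, 0.0, 0.05, 0.1),
    }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a mid-size discovery design: 20,000 individuals of whom
    1,000 carry the measured target, 500 LD-free variants, five causal
    variants acting fully through the shared factor (delta = 1), and noise
    levels giving a theoretical imputation accuracy of roughly two thirds of
    the target variance.
    """

    n_total: int = 20_000
    n_measured: int = 1_000
    m_variants: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 5
    effect_sizes: Sequence[float] | None = None       # b_k, factor SD units per allele
    mediation_fractions: Sequence[float] | None = None  # delta_k in [0, 1]
    n_proxies: int = 4
    proxy_loadings: Sequence[float] | None = None      # lambda_j
    proxy_noise_sd: float = 0.3
    factor_noise_sd: float = 0.6
    target_noise_sd: float = 0.4
    n_targets: int = 2
    target_loadings: Sequence[float] | None = None     # a_t
    covariate_effects: Mapping[str, object] = field(default_factory=_default_covariate_effects)
    sex_loading_scale: Mapping[str, float] = field(default_factory=lambda: {"F": 1.0, "M": 0.9})
    positive_scale: PositiveScale = field(default_factory=PositiveScale)
    n_replication: int = 1_000
    n_chromosomes: int = 4
    variant_spacing: float = 400_000.0
    seed: int = 0
    generator: str = "PCG64"  # fixed generator algorithm; reproducibility contract

    def __post_init__(self) -> None:
        if self.n_total <= 0 or self.n_measured <= 0:
            raise ValueError("sample counts must be positive")
        if self.n_measured > self.n_total:
            raise ValueError("n_measured cannot exceed n_total")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.m_variants < self.n_causal:
            raise ValueError("more causal variants than variants")
        if self.effect_sizes is None:
            self.effect_sizes = tuple([0.15] * self.n_causal)
        if self.mediation_fractions is None:
            self.mediation_fractions = tuple([1.0] * self.n_causal)
        if len(self.effect_sizes) != self.n_causal or len(self.mediation_fractions) != self.n_causal:
            raise ValueError("effect_sizes / mediation_fractions must have length n_causal")
        if any(d < 0 or d > 1 for d in self.mediation_fractions):
            raise ValueError("mediation fractions must lie in [0, 1]")
        if self.proxy_loadings is None:
            base = (1.0, 0.8, 0.6, 0.4)
            self.proxy_loadings = tuple((base * (self.n_proxies // 4 + 1))[: self.n_proxies])
        if len(self.proxy_loadings) != self.n_proxies:
            raise ValueError("proxy_loadings must have length n_proxies")
        if self.target_loadings is None:
            base = (1.0, 0.7, 0.85, 0.55)
            self.target_loadings = tuple((base * (self.n_targets // 4 + 1))[: self.n_targets])
        if len(self.target_loadings) != self.n_targets:
            raise ValueError("target_loadings must have length n_targets")
        for name, sd in (("proxy_noise_sd", self.proxy_noise_sd),
                         ("factor_noise_sd", self.factor_noise_sd),
                         ("target_noise_sd", self.target_noise_sd)):
            if sd < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.generator != "PCG64":
            raise ValueError("only the PCG64 generator is supported")

    @property
    def proxy_names(self) -> list[str]:
        base = ["height", "weight", "whr", "bia_fat"]
        names = base + [f"proxy_{j}" for j in range(5, self.n_proxies + 1)]
        return names[: self.n_proxies]

    @property
    def target_names(self) -> list[str]:
        base = ["fat_mass", "lean_mass", "android_fat", "gynoid_fat"]
        names = base + [f"target_{t}" for t in range(5, self.n_targets + 1)]
        return names[: self.n_targets]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x variants) plus per-variant metadata.

    ``variants`` columns: rsid, chrom, pos (1-based), a1 (effect allele),
    a0, eaf, info.
    """

    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant metadata length must equal dosage columns")
        if np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class Cohort:
    """Phenotype table plus the column roles the pipeline needs."""

    table: pd.DataFrame
    proxy_cols: list[str]
    target_cols: list[str]
    covariate_cols: list[str]
    sex_col: str = "sex"
    id_col: str = "iid"
    measured_col: str = "measured"

    @property
    def n(self) -> int:
        return len(self.table)

    def measured_mask(self) -> np.ndarray:
        return self.table[self.measured_col].to_numpy(dtype=bool)


@dataclass
class TruthRecord:
    """Analytic ground truth for one simulated architecture."""

    causal_ids: list[str]
    causal_idx: np.ndarray
    effect_sizes: np.ndarray            # b_k
    mediation_fractions: np.ndarray     # delta_k
    causal_freqs: np.ndarray            # p_k at the causal variants
    factor: np.ndarray                  # A_i, aligned with the cohort table
    allele_freqs: np.ndarray            # p_k for all variants
    variants: pd.DataFrame              # metadata shared with replication draws
    # per target name -> per sex -> scalar / array
    r2_theory: dict
    kappa: dict
    var_target_given_cov: dict
    var_imputed_given_cov: dict
    marginal_target: dict               # latent-scale per-allele effect on y_t
    marginal_imputed: dict              # latent-scale effect on the imputed y_t
    config: SimulationConfig = None

    def std_marginal_target(self, target: str, sex: str) -> np.ndarray:
        """Per-allele effect on the variance-standardised (residualised) target."""
        return self.marginal_target[target][sex] / np.sqrt(self.var_target_given_cov[target][sex])

    def std_marginal_imputed(self, target: str, sex: str) -> np.ndarray:
        v = self.var_imputed_given_cov[target][sex]
        if v <= 0:
            return np.zeros_like(self.marginal_imputed[target][sex])
        return self.marginal_imputed[target][sex] / np.sqrt(v)


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64([int(seed), int(stream)]))


def _variant_layout(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = cfg.m_variants
    per_chrom = int(np.ceil(m / cfg.n_chromosomes))
    chroms, positions = [], []
    for c in range(cfg.n_chromosomes):
        k = min(per_chrom, m - c * per_chrom)
        if k <= 0:
            break
        gaps = cfg.variant_spacing * (0.75 + 0.5 * rng.random(k))
        pos = 1_000_000 + np.cumsum(gaps).astype(np.int64)
        chroms.extend([str(c + 1)] * k)
        positions.extend(pos.tolist())
    a1_idx = rng.integers(0, 4, m)
    a0_idx = (a1_idx + rng.integers(1, 4, m)) % 4
    return pd.DataFrame({
        "rsid": [f"rs{100000 + i}" for i in range(m)],
        "chrom": chroms,
        "pos": positions,
        "a1": _ALLELES[a1_idx],
        "a0": _ALLELES[a0_idx],
    })


def _covariate_frame(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame({
        "age": rng.uniform(40, 70, n),
        "townsend": rng.normal(0.0, 1.0, n),
        "batch": rng.integers(1, len(cfg.covariate_effects.get("batch", (0,))) + 1, n),
        "pc1": rng.normal(0.0, 1.0, n),
        "pc2": rng.normal(0.0, 1.0, n),
    })


def _covariate_contribution(cfg: SimulationConfig, cov: pd.DataFrame) -> np.ndarray:
    eff = cfg.covariate_effects
    out = np.zeros(len(cov))
    for name in ("age", "townsend", "pc1", "pc2"):
        out += float(eff.get(name, 0.0)) * cov[name].to_numpy(dtype=float)
    shifts = np.asarray(eff.get("batch", (0.0,)), dtype=float)
    out += shifts[cov["batch"].to_numpy(dtype=int) - 1]
    return out


def _covariate_variance(cfg: SimulationConfig) -> float:
    eff = cfg.covariate_effects
    v = float(eff.get("age", 0.0)) ** 2 * (30.0 ** 2 / 12.0)   # Uniform(40, 70)
    v += float(eff.get("townsend", 0.0)) ** 2
    v += float(eff.get("pc1", 0.0)) ** 2 + float(eff.get("pc2", 0.0)) ** 2
    shifts = np.asarray(eff.get("batch", (0.0,)), dtype=float)
    v += float(np.var(shifts))  # uniform over batch levels
    return v


def _theory(cfg: SimulationConfig, p_causal: np.ndarray) -> dict:
    """Closed-form imputation accuracy and marginal effects, per target and sex."""
    b = np.asarray(cfg.effect_sizes, dtype=float)
    d = np.asarray(cfg.mediation_fractions, dtype=float)
    het = 2.0 * p_causal * (1.0 - p_causal)
    v_G = float(np.sum((d * b) ** 2 * het))
    v_D = float(np.sum(((1.0 - d) * b) ** 2 * het))
    c_GD = float(np.sum(d * (1.0 - d) * b ** 2 * het))
    v_A = v_G + cfg.factor_noise_sd ** 2
    v_cov = _covariate_variance(cfg)
    lam0 = np.asarray(cfg.proxy_loadings, dtype=float)
    sig_x2 = float(cfg.proxy_noise_sd) ** 2

    out = {"r2": {}, "kappa": {}, "var_y_c": {}, "var_imp_c": {},
           "marg_y": {}, "marg_imp": {}}
    for t_name, a_t in zip(cfg.target_names, cfg.target_loadings):
        for key in out:
            out[key].setdefault(t_name, {})
        for sex in SEXES:
            lam = lam0 * float(cfg.sex_loading_scale.get(sex, 1.0))
            u = float(np.sum(lam ** 2)) / sig_x2 if sig_x2 > 0 else np.inf
            s_t = a_t * v_A + c_GD
            if np.isinf(u):
                shrink = 1.0 / v_A if v_A > 0 else 0.0
            else:
                shrink = u / (1.0 + v_A * u)
            explained_x = s_t ** 2 * shrink
            var_y_c = a_t ** 2 * v_A + 2.0 * a_t * c_GD + v_D + cfg.target_noise_sd ** 2
            var_y = a_t ** 2 * v_cov + var_y_c
            kappa = s_t * shrink
            out["r2"][t_name][sex] = (a_t ** 2 * v_cov + explained_x) / var_y
            out["kappa"][t_name][sex] = kappa
            out["var_y_c"][t_name][sex] = var_y_c
            out["var_imp_c"][t_name][sex] = explained_x
            out["marg_y"][t_name][sex] = b * (a_t * d + (1.0 - d))
            out["marg_imp"][t_name][sex] = d * b * kappa
        out["r2"][t_name]["mean"] = float(np.mean([out["r2"][t_name][s] for s in SEXES]))
    return out


def _draw_phenotypes(cfg: SimulationConfig, geno: np.ndarray, p: np.ndarray,
                     causal_idx: np.ndarray, rng: np.random.Generator,
                     n: int, id_prefix: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Shared phenotype draw for discovery and replication cohorts."""
    b = np.asarray(cfg.effect_sizes, dtype=float)
    d = np.asarray(cfg.mediation_fractions, dtype=float)
    g_c = geno[:, causal_idx] - 2.0 * p[causal_idx]
    G = g_c @ (d * b)
    D = g_c @ ((1.0 - d) * b)

    sex = np.where(rng.random(n) < 0.5, "F", "M")
    cov = _covariate_frame(cfg, n, rng)
    A = G + _covariate_contribution(cfg, cov) + rng.normal(0.0, cfg.factor_noise_sd, n)

    lam0 = np.asarray(cfg.proxy_loadings, dtype=float)
    scale = np.where(sex == "F", cfg.sex_loading_scale.get("F", 1.0),
                     cfg.sex_loading_scale.get("M", 1.0))
    proxies = {}
    for j, name in enumerate(cfg.proxy_names):
        latent = lam0[j] * scale * A + rng.normal(0.0, cfg.proxy_noise_sd, n)
        proxies[name] = cfg.positive_scale.forward(latent)
    targets = {}
    for a_t, name in zip(cfg.target_loadings, cfg.target_names):
        latent = a_t * A + D + rng.normal(0.0, cfg.target_noise_sd, n)
        targets[name] = cfg.positive_scale.forward(latent)

    table = pd.DataFrame({"iid": [f"{id_prefix}{i + 1:07d}" for i in range(n)], "sex": sex})
    table = pd.concat([table, cov, pd.DataFrame(proxies), pd.DataFrame(targets)], axis=1)
    return table, A


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GenotypeMatrix, TruthRecord]:
    """Draw a discovery cohort, its genotypes, and the analytic ground truth.

    Deterministic given ``config.seed``; the measured subset (the only rows
    with observed targets) is a simple random sample of size ``n_measured``.
    """
    cfg = config
    rng = _rng(cfg.seed, 0)
    n, m = cfg.n_total, cfg.m_variants

    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], m)
    geno = rng.binomial(2, p, size=(n, m)).astype(float)
    variants = _variant_layout(cfg, rng)
    variants["eaf"] = geno.mean(axis=0) / 2.0
    variants["info"] = rng.beta(20.0, 1.0, m)

    # causal variants evenly spread through the panel so loci stay separable
    causal_idx = np.linspace(0, m - 1, cfg.n_causal + 2)[1:-1].round().astype(int) \
        if cfg.n_causal else np.array([], dtype=int)
    causal_idx = np.unique(causal_idx)
    if len(causal_idx) != cfg.n_causal:  # tiny panels: fall back to first k
        causal_idx = np.arange(cfg.n_causal)

    table, A = _draw_phenotypes(cfg, geno, p, causal_idx, rng, n, "UKS")
    measured = np.zeros(n, dtype=bool)
    measured[rng.choice(n, cfg.n_measured, replace=False)] = True
    table["measured"] = measured
    for t_name in cfg.target_names:
        table.loc[~measured, t_name] = np.nan

    cohort = Cohort(
        table=table,
        proxy_cols=cfg.proxy_names,
        target_cols=cfg.target_names,
        covariate_cols=["age", "townsend", "batch", "pc1", "pc2"],
    )
    gmat = GenotypeMatrix(dosages=geno, variants=variants)

    th = _theory(cfg, p[causal_idx])
    truth = TruthRecord(
        causal_ids=variants["rsid"].iloc[causal_idx].tolist(),
        causal_idx=causal_idx,
        effect_sizes=np.asarray(cfg.effect_sizes, dtype=float),
        mediation_fractions=np.asarray(cfg.mediation_fractions, dtype=float),
        causal_freqs=p[causal_idx],
        factor=A,
        allele_freqs=p,
        variants=variants.copy(),
        r2_theory=th["r2"],
        kappa=th["kappa"],
        var_target_given_cov=th["var_y_c"],
        var_imputed_given_cov=th["var_imp_c"],
        marginal_target=th["marg_y"],
        marginal_imputed=th["marg_imp"],
        config=cfg,
    )
    return cohort, gmat, truth


def simulate_replication_cohort(config: SimulationConfig,
                                truth: TruthRecord) -> tuple[Cohort, GenotypeMatrix]:
    """Independent individuals under the same causal architecture.

    All ``config.n_replication`` individuals carry measured targets, standing
    in for a directly phenotyped replication panel.
    """
    cfg = config
    if cfg.n_replication <= 0:
        raise ValueError("n_replication must be positive")
    rng = _rng(cfg.seed, 1)
    n = cfg.n_replication
    p = truth.allele_freqs
    geno = rng.binomial(2, p, size=(n, len(p))).astype(float)
    variants = truth.variants.copy()
    variants["eaf"] = geno.mean(axis=0) / 2.0

    table, _ = _draw_phenotypes(cfg, geno, p, truth.causal_idx, rng, n, "REP")
    table["measured"] = True
    cohort = Cohort(
        table=table,
        proxy_cols=cfg.proxy_names,
        target_cols=cfg.target_names,
        covariate_cols=["age", "townsend", "batch", "pc1", "pc2"],
    )
    return cohort, GenotypeMatrix(dosages=geno, variants=variants)


@dataclass
class SummaryRegion:
    """Paired GWAS / eQTL summary statistics over one LD region."""

    gwas: pd.DataFrame   # snp, freq, beta, se, z, n
    eqtl: pd.DataFrame
    ld: np.ndarray       # SNP x SNP correlation (r) matrix
    scenario: str
    causal_gwas: int | None
    causal_eqtl: int | None


_SCENARIOS = ("shared-causal", "distinct-causal", "gwas-only", "null")


def simulate_summary_region(n_snps: int, ld_decay: float, scenario: str,
                            n_gwas: int = 100_000, n_eqtl: int = 500,
                            seed: int = 0, z_causal: float = 9.0) -> SummaryRegion:
    """Generate GWAS and eQTL summary statistics over an LD region.

    LD follows an exponential-decay (AR-1 style) correlation, r_ij =
    exp(-|i-j| / ld_decay), which is positive definite for any positive
    decay length.  Observed z-scores are drawn as MVN(R * gamma, R) with a
    point mass ``z_causal`` at the causal SNP(s) of the named scenario, so
    the expected top association comfortably exceeds |z| = 6 in non-null
    scenarios.
    """
    if n_snps < 2:
        raise ValueError("n_snps must be at least 2")
    if ld_decay <= 0:
        raise ValueError("ld_decay must be positive (positive-definite LD)")
    if scenario not in _SCENARIOS:
        raise ValueError(f"scenario must be one of {_SCENARIOS}")
    rng = _rng(seed, 2)

    idx = np.arange(n_snps)
    ld = np.exp(-np.abs(idx[:, None] - idx[None, :]) / float(ld_decay))
    chol = np.linalg.cholesky(ld)
    freq = rng.uniform(0.05, 0.5, n_snps)

    c_g = c_e = None
    if scenario == "shared-causal":
        c_g = c_e = n_snps // 2
    elif scenario == "distinct-causal":
        c_g, c_e = n_snps // 4, (3 * n_snps) // 4
    elif scenario == "gwas-only":
        c_g = n_snps // 2

    def _stats(causal: int | None, n: int) -> pd.DataFrame:
        gamma = np.zeros(n_snps)
        if causal is not None:
            gamma[causal] = z_causal
        z = ld @ gamma + chol @ rng.standard_normal(n_snps)
        se = 1.0 / np.sqrt(2.0 * n * freq * (1.0 - freq))
        return pd.DataFrame({
            "snp": [f"snp_{i + 1}" for i in idx],
            "freq": freq,
            "beta": z * se,
            "se": se,
            "z": z,
            "n": n,
        })

    return SummaryRegion(
        gwas=_stats(c_g, n_gwas),
        eqtl=_stats(c_e, n_eqtl),
        ld=ld,
        scenario=scenario,
        causal_gwas=c_g,
        causal_eqtl=c_e,
    )
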