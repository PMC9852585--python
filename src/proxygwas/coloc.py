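"""Bayesian colocalisation (ABF) and SMR/HEIDI causal-gene statistics.

Colocalisation follows the single-causal-variant enumeration over five
hypotheses: H0 no association, H1/H2 association with one trait only, H3
two distinct causal variants, H4 one shared causal variant.  Per-SNP
evidence is the Wakefield approximate Bayes factor,

    r = W / (se^2 + W),   ln ABF = 0.5 * [ln(1 - r) + r * z^2],

with prior effect variance W = prior_sd^2.  A locus is declared colocalised
when PP(H4) exceeds 0.75.

SMR tests whether a GWAS signal is mediated by gene expression using the
top-eQTL Wald ratio b_xy = b_GWAS / b_eQTL with statistic
T = z_g^2 z_e^2 / (z_g^2 + z_e^2) ~ chi^2_1; HEIDI then asks whether b_xy is
homogeneous across SNPs in moderate LD with the top eQTL — heterogeneity
indicates linkage of distinct causal variants rather than pleiotropy.  The
HEIDI null distribution is an LD-weighted sum of chi-squares, evaluated
numerically by Imhof integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.special import logsumexp

__all__ = [
    "ColocResult", "SmrResult", "HeidiResult",
    "wakefield_log_abf", "coloc_posteriors", "smr_test", "heidi_test",
    "weighted_chi2_sf", "smr_heidi_screen",
]

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


def wakefield_log_abf(beta, se, prior_sd: float = 0.15):
    """Log approximate Bayes factor for a single association estimate."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    W = prior_sd ** 2
    r = W / (se ** 2 + W)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z * z)
    return float(out) if out.ndim == 0 else out


@dataclass
class ColocResult:
    pp: dict[str, float]            # posterior probability per hypothesis
    priors: tuple[float, float, float]
    n_snps: int

    @property
    def colocalised(self) -> bool:
        return self.pp["H4"] > 0.75


def coloc_posteriors(labf1, labf2, p1: float = 1e-4, p2: float = 1e-4,
                     p12: float = 1e-5) -> ColocResult:
    """Posterior probabilities H0..H4 from per-SNP log ABFs of two traits.

    Computed in log space with log-sum-exp:
      H1 ~ p1 * S1,  H2 ~ p2 * S2,  H3 ~ p1 p2 (S1 S2 - S12),
      H4 ~ p12 * S12,  H0 ~ 1,  where S1 = sum e^labf1 etc.
    """
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1:
        raise ValueError("labf vectors must be equal-length 1-D arrays")
    if len(l1) == 0:
        raise ValueError("empty region")
    for p in (p1, p2, p12):
        if not 0 < p < 1:
            raise ValueError("priors must lie in (0, 1)")
    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)
    # log(S1*S2 - S12), guarded against cancellation for single-SNP regions
    diff = ls1 + ls2 + np.log1p(-np.exp(np.minimum(ls12 - ls1 - ls2, 0.0)))
    if not np.isfinite(diff):
        diff = -np.inf
    logs = np.array([
        0.0,
        np.log(p1) + ls1,
        np.log(p2) + ls2,
        np.log(p1) + np.log(p2) + diff,
        np.log(p12) + ls12,
    ])
    pp = np.exp(logs - logsumexp(logs))
    pp /= pp.sum()
    return ColocResult(pp=dict(zip(HYPOTHESES, pp.tolist())),
                       priors=(p1, p2, p12), n_snps=len(l1))


@dataclass
class SmrResult:
    top_index: int
    b_xy: float
    stat: float
    p: float


def smr_test(z_gwas: float, z_eqtl: float, b_gwas: float, b_eqtl: float,
             top_index: int = 0) -> SmrResult:
    """Wald-ratio mediation test: T = z_g^2 z_e^2 / (z_g^2 + z_e^2) ~ chi^2_1."""
    if z_eqtl == 0:
        raise ValueError("z_eqtl must be non-zero")
    if b_eqtl == 0:
        raise ValueError("b_eqtl must be non-zero")
    zg2, ze2 = float(z_gwas) ** 2, float(z_eqtl) ** 2
    T = zg2 * ze2 / (zg2 + ze2)
    return SmrResult(top_index=top_index, b_xy=float(b_gwas) / float(b_eqtl),
                     stat=T, p=float(stats.chi2.sf(T, df=1)))


def weighted_chi2_sf(x: float, weights) -> float:
    """Tail probability P(sum_k w_k chi^2_1 > x) by Imhof numeric inversion."""
    w = np.asarray(weights, dtype=float)
    w = w[w > 1e-10]
    if len(w) == 0:
        return 1.0
    if x <= 0:
        return 1.0

    def phase(u):
        return 0.5 * np.sum(np.arctan(w * u))

    def inv_amp(u):
        return 1.0 / (u * np.exp(0.25 * np.sum(np.log1p((w * u) ** 2))))

    def integrand(u: float) -> float:
        return np.sin(phase(u) - 0.5 * x * u) * inv_amp(u)

    # head: plain adaptive quadrature; tail: sin(phi - omega*u) split into
    # Fourier components with smooth monotone amplitudes, handled by
    # QUADPACK's oscillatory (QAWF) rule so slow 1/u^(1+k/2) decay converges
    omega = 0.5 * x
    head = 64.0
    val, _ = integrate.quad(integrand, 0.0, head, limit=500, epsabs=1e-10, epsrel=1e-10)
    cos_part, _ = integrate.quad(lambda u: np.sin(phase(u)) * inv_amp(u),
                                 head, np.inf, weight="cos", wvar=omega, limlst=200)
    sin_part, _ = integrate.quad(lambda u: np.cos(phase(u)) * inv_amp(u),
                                 head, np.inf, weight="sin", wvar=omega, limlst=200)
    val += cos_part - sin_part
    return float(np.clip(0.5 + val / np.pi, 1e-12, 1.0))


@dataclass
class HeidiResult:
    p: float
    n_snps: int
    tested: bool


def heidi_test(b_gwas, se_gwas, b_eqtl, se_eqtl, ld, top: int,
               r2_window: tuple[float, float] = (0.05, 0.9),
               max_snps: int = 20) -> HeidiResult:
    """Heterogeneity in dependent instruments around the top eQTL.

    SNPs whose r^2 with the top eQTL falls inside ``r2_window`` contribute
    d_i = b_xy(i) - b_xy(top); their joint covariance follows from LD and the
    per-SNP standard errors by the delta method.  The statistic sum z_d^2 is
    referred to its eigenvalue-weighted chi-square null.  Fewer than three
    eligible SNPs yields a no-test result (``tested=False``) rather than a P.
    """
    b_g = np.asarray(b_gwas, dtype=float)
    se_g = np.asarray(se_gwas, dtype=float)
    b_e = np.asarray(b_eqtl, dtype=float)
    se_e = np.asarray(se_eqtl, dtype=float)
    R = np.asarray(ld, dtype=float)
    m = len(b_g)
    if not (len(se_g) == len(b_e) == len(se_e) == m) or R.shape != (m, m):
        raise ValueError("summary vectors and LD matrix must be aligned")

    r2 = R[top] ** 2
    z_e = np.where(se_e > 0, b_e / se_e, 0.0)
    eligible = [i for i in range(m)
                if i != top and r2_window[0] <= r2[i] <= r2_window[1] and b_e[i] != 0]
    eligible.sort(key=lambda i: -abs(z_e[i]))
    eligible = eligible[:max_snps]
    if len(eligible) < 3:
        return HeidiResult(p=float("nan"), n_snps=len(eligible), tested=False)

    idx = [top] + eligible
    bg, sg, be, se_ = b_g[idx], se_g[idx], b_e[idx], se_e[idx]
    Rsub = R[np.ix_(idx, idx)]
    # delta-method covariance of the Wald ratios b_xy = b_g / b_e
    V = (Rsub * np.outer(sg, sg)) / np.outer(be, be) \
        + (np.outer(bg, bg) * Rsub * np.outer(se_, se_)) / np.outer(be ** 2, be ** 2)
    bxy = bg / be
    d = bxy[1:] - bxy[0]
    Vd = V[1:, 1:] - V[1:, [0]] - V[[0], 1:] + V[0, 0]
    sd = np.sqrt(np.diag(Vd))
    if np.any(sd <= 0):
        return HeidiResult(p=float("nan"), n_snps=len(eligible), tested=False)
    z_d = d / sd
    C = Vd / np.outer(sd, sd)
    T = float(np.sum(z_d ** 2))
    weights = np.clip(np.linalg.eigvalsh(C), 0.0, None)
    return HeidiResult(p=weighted_chi2_sf(T, weights), n_snps=len(eligible), tested=True)


def smr_heidi_screen(regions, fdr_level: float = 0.05,
                     heidi_min_p: float = 0.05) -> "pd.DataFrame":
    """Joint SMR + HEIDI decision over a batch of (gwas, eqtl, ld) regions.

    Each region contributes the SMR test at its top eQTL; SMR P values are
    BH-corrected across the batch and a region is flagged pleiotropic when
    the corrected SMR P is below ``fdr_level`` and HEIDI does not reject
    homogeneity (P > ``heidi_min_p`` or no-test).
    """
    import pandas as pd

    from .replication import benjamini_hochberg

    rows = []
    for name, (gwas, eqtl, ld) in regions.items():
        z_e = eqtl["beta"].to_numpy() / eqtl["se"].to_numpy()
        top = int(np.argmax(np.abs(z_e)))
        z_g = gwas["beta"].to_numpy() / gwas["se"].to_numpy()
        smr = smr_test(z_g[top], z_e[top], gwas["beta"].iloc[top], eqtl["beta"].iloc[top], top)
        heidi = heidi_test(gwas["beta"].to_numpy(), gwas["se"].to_numpy(),
                           eqtl["beta"].to_numpy(), eqtl["se"].to_numpy(), ld, top)
        rows.append({"region": name, "top_index": top, "b_xy": smr.b_xy,
                     "smr_stat": smr.stat, "smr_p": smr.p,
                     "heidi_p": heidi.p, "heidi_n": heidi.n_snps,
                     "heidi_tested": heidi.tested})
    df = pd.DataFrame(rows)
    if len(df):
        df["smr_q"] = benjamini_hochberg(df["smr_p"].to_numpy())
        heidi_pass = ~df["heidi_tested"] | (df["heidi_p"] > heidi_min_p)
        df["pleiotropic"] = (df["smr_q"] < fdr_level) & heidi_pass
    return df
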