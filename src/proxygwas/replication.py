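"""Replication power calculation, one-sided FDR replication, and sign test.

For a discovery effect beta on a variance-standardised phenotype, the
standard error expected in a replication panel of N directly measured
individuals is fixed by the effect-allele frequency alone:

    se_repl = 1 / sqrt(2 * N * freq1 * (1 - freq1))

Assuming the replication effect equals the discovery effect, the expected
replication P value is the upper standard-normal tail at |beta / se_repl|;
records whose expected P clears a selection cutoff are "replicable" at that
sample size.  Observed replication is tested one-sided in the discovery
direction, Benjamini-Hochberg corrected across the tested set, and the
overall directional concordance is summarised by an exact binomial sign
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "predicted_replication_se",
    "expected_replication_pvalue",
    "select_replicable",
    "one_sided_replication_pvalue",
    "benjamini_hochberg",
    "sign_test",
    "test_replication",
    "ReplicationSummary",
]


def predicted_replication_se(freq1: float, n_repl: int) -> float:
    """Predicted per-allele s.e. on a variance-1 phenotype at sample size n."""
    freq1 = np.asarray(freq1, dtype=float)
    if np.any((freq1 <= 0) | (freq1 >= 1)):
        raise ValueError("freq1 must lie strictly between 0 and 1")
    if n_repl < 1:
        raise ValueError("n_repl must be at least 1")
    out = 1.0 / np.sqrt(2.0 * n_repl * freq1 * (1.0 - freq1))
    return float(out) if out.ndim == 0 else out


def expected_replication_pvalue(beta_disc: float, se_pred: float) -> float:
    """One-sided expected replication P: upper normal tail at |beta / se|."""
    se_pred = np.asarray(se_pred, dtype=float)
    if np.any(se_pred <= 0):
        raise ValueError("se_pred must be positive")
    out = stats.norm.sf(np.abs(np.asarray(beta_disc, dtype=float)) / se_pred)
    return float(out) if out.ndim == 0 else out


def select_replicable(records: pd.DataFrame, n_repl: int,
                      p_max: float) -> pd.DataFrame:
    """Subset of discovery records expected to replicate at sample size n_repl.

    ``records`` needs columns ``beta_disc`` and ``freq1``; the returned copy
    gains ``se_pred`` and ``p_pred`` columns.
    """
    out = records.copy()
    out["se_pred"] = predicted_replication_se(out["freq1"].to_numpy(), n_repl)
    out["p_pred"] = expected_replication_pvalue(out["beta_disc"].to_numpy(),
                                               out["se_pred"].to_numpy())
    return out[out["p_pred"] < p_max].reset_index(drop=True)


def one_sided_replication_pvalue(beta_disc, beta_repl, se_repl):
    """Upper normal tail at sign(beta_disc) * beta_repl / se_repl.

    Below 0.5 exactly when the replication effect points the discovery way.
    """
    se_repl = np.asarray(se_repl, dtype=float)
    if np.any(se_repl <= 0):
        raise ValueError("se_repl must be positive")
    z = np.sign(np.asarray(beta_disc, dtype=float)) * np.asarray(beta_repl, dtype=float) / se_repl
    out = stats.norm.sf(z)
    return float(out) if out.ndim == 0 else out


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up BH q-values: q_(i) = min_{j >= i} p_(j) * m / j, input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def sign_test(k_consistent: int, n: int) -> float:
    """Exact one-sided binomial tail P(X >= k | n, 1/2)."""
    if not 0 <= k_consistent <= n:
        raise ValueError("need 0 <= k_consistent <= n")
    return float(stats.binom.sf(k_consistent - 1, n, 0.5))


@dataclass
class ReplicationSummary:
    records: pd.DataFrame
    n_tested: int
    n_consistent: int
    n_replicated: int
    sign_test_p: float
    unmatched: list[str]


def test_replication(discovery: pd.DataFrame, replication: pd.DataFrame,
                     fdr_level: float = 0.1,
                     on: tuple[str, ...] = ("rsid",)) -> ReplicationSummary:
    """Joint replication assessment of a discovery record set.

    ``discovery`` needs rsid, beta_disc (and optionally trait); ``replication``
    needs the join keys plus beta_repl, se_repl.  Per record: one-sided P in
    the discovery direction, BH q-value over the tested set, a strict
    direction-consistency flag (zero effects count as inconsistent), and a
    replicated flag (consistent AND q < fdr_level).  Records without a
    replication row are listed as unmatched, never silently dropped.
    """
    on = list(on)
    merged = discovery.merge(replication, on=on, how="left", suffixes=("", "_r"))
    matched = merged["beta_repl"].notna() & merged["se_repl"].notna()
    unmatched = merged.loc[~matched, on[0]].astype(str).tolist()
    rec = merged[matched].copy().reset_index(drop=True)

    if len(rec):
        rec["p_one_sided"] = one_sided_replication_pvalue(
            rec["beta_disc"].to_numpy(), rec["beta_repl"].to_numpy(),
            rec["se_repl"].to_numpy())
        rec["q"] = benjamini_hochberg(rec["p_one_sided"].to_numpy())
        rec["consistent"] = (np.sign(rec["beta_disc"]) == np.sign(rec["beta_repl"])) \
            & (rec["beta_repl"] != 0)
        rec["replicated"] = rec["consistent"] & (rec["q"] < fdr_level)
    else:
        for col in ("p_one_sided", "q"):
            rec[col] = pd.Series(dtype=float)
        for col in ("consistent", "replicated"):
            rec[col] = pd.Series(dtype=bool)

    k = int(rec["consistent"].sum())
    return ReplicationSummary(
        records=rec,
        n_tested=len(rec),
        n_consistent=k,
        n_replicated=int(rec["replicated"].sum()),
        sign_test_p=sign_test(k, len(rec)) if len(rec) else float("nan"),
        unmatched=unmatched,
    )
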