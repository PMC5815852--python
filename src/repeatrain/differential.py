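"""Two-condition differential repeat expression on read proportions.

Counts are compared as proportions of each sample's quantified library.
Unreplicated designs use Kal's Z-test: for counts x₁, x₂ out of libraries
N₁, N₂, with p̂ᵢ = xᵢ/Nᵢ and pooled p₀ = (x₁+x₂)/(N₁+N₂),

    z = (p̂₁ − p̂₂) / sqrt(p₀(1 − p₀)(1/N₁ + 1/N₂)),

two-sided p from the standard normal. Replicated designs use a
Baggerly-style weighted t-test: each group's proportion is estimated by a
precision-weighted mean whose weights combine within-library binomial
variance p(1−p)/N with a method-of-moments between-replicate overdispersion
component (floored at zero); the statistic is
t = (p̂₁ − p̂₂)/sqrt(V̂₁ + V̂₂) with Satterthwaite degrees of freedom. When
both groups show zero estimated overdispersion the statistic reduces to a
pooled two-proportion z.

Raw p-values are corrected with the Benjamini–Hochberg step-up FDR across
all families tested. Fold changes are ratios of mean proportions with a
half-count pseudo-proportion ε = 0.5/median(N) guarding zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class KalTestResult:
    p1: float
    p2: float
    p0: float
    z: float
    p_value: float


@dataclass
class BaggerlyTestResult:
    p1: float
    p2: float
    var1: float
    var2: float
    overdispersion1: float
    overdispersion2: float
    tw: float
    df: float
    p_value: float


def kal_z_test(x1: int, N1: int, x2: int, N2: int) -> KalTestResult:
    """Pooled-variance two-library proportion Z-test (unreplicated designs)."""
    if N1 < 1 or N2 < 1:
        raise ValueError("library sizes must be >= 1")
    if not (0 <= x1 <= N1 and 0 <= x2 <= N2):
        raise ValueError("counts must lie in [0, N]")
    p1, p2 = x1 / N1, x2 / N2
    p0 = (x1 + x2) / (N1 + N2)
    denom = p0 * (1 - p0) * (1 / N1 + 1 / N2)
    if denom <= 0:
        # both libraries all-zero or all-one for this family: no evidence
        return KalTestResult(p1, p2, p0, 0.0, 1.0)
    z = (p1 - p2) / np.sqrt(denom)
    p = float(2 * stats.norm.sf(abs(z)))
    return KalTestResult(p1, p2, p0, float(z), max(min(p, 1.0), np.nextafter(0, 1)))


def _group_estimate(x: np.ndarray, N: np.ndarray, n_iter: int = 20):
    """Weighted proportion, its variance, and the overdispersion estimate."""
    p_s = x / N
    p_hat = x.sum() / N.sum()
    sigma_b2 = 0.0
    for _ in range(n_iter):
        within = np.maximum(p_hat * (1 - p_hat), 1e-300) / N
        # method of moments: between-replicate variance of the p_s beyond binomial
        sigma_b2 = max(0.0, float(np.var(p_s, ddof=1) - within.mean()))
        w = 1.0 / (sigma_b2 + within)
        p_new = float(np.sum(w * p_s) / np.sum(w))
        if abs(p_new - p_hat) < 1e-12:
            p_hat = p_new
            break
        p_hat = p_new
    within = np.maximum(p_hat * (1 - p_hat), 1e-300) / N
    w = 1.0 / (sigma_b2 + within)
    # Var(Σ w p_s / Σ w) with Var(p_s) = σ_b² + p(1−p)/N_s = 1/w_s
    var = float(1.0 / np.sum(w))
    return p_hat, var, sigma_b2


def baggerly_test(x1, N1, x2, N2) -> BaggerlyTestResult:
    """Weighted beta-binomial-style t-test for replicated proportions.

    ``x1, N1`` are arrays of counts and library sizes for the replicates of
    group 1, likewise ``x2, N2``. Requires >= 2 replicates in each group
    (use :func:`kal_z_test` otherwise).
    """
    x1, N1 = np.asarray(x1, float), np.asarray(N1, float)
    x2, N2 = np.asarray(x2, float), np.asarray(N2, float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs >= 2 replicates; use kal_z_test for "
                         "unreplicated designs")
    if (x1 > N1).any() or (x2 > N2).any() or (x1 < 0).any() or (x2 < 0).any():
        raise ValueError("counts must lie in [0, N]")
    p1, v1, s1 = _group_estimate(x1, N1)
    p2, v2, s2 = _group_estimate(x2, N2)
    V = v1 + v2
    if V <= 0:
        return BaggerlyTestResult(p1, p2, v1, v2, s1, s2, 0.0, np.inf, 1.0)
    tw = (p1 - p2) / np.sqrt(V)
    if s1 == 0.0 and s2 == 0.0:
        # purely binomial variance: known-variance regime, normal reference
        df = np.inf
        p = float(2 * stats.norm.sf(abs(tw)))
    else:
        df = V**2 / (v1**2 / (len(x1) - 1) + v2**2 / (len(x2) - 1))
        df = max(df, 1.0)
        p = float(2 * stats.t.sf(abs(tw), df))
    return BaggerlyTestResult(p1, p2, v1, v2, s1, s2, float(tw), float(df),
                              max(min(p, 1.0), np.nextafter(0, 1)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values: q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j, ≤ 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_table(counts: pd.DataFrame, library_sizes: dict[str, int],
                       conditions: dict[str, str]) -> pd.DataFrame:
    """Per-family differential test between control and treated samples.

    ``counts`` is families × samples; ``library_sizes`` maps sample →
    quantified-read total; ``conditions`` maps sample → ``"control"`` or
    ``"treated"``. The Baggerly test is used when both conditions have >= 2
    replicates, Kal's Z on (pooled) single libraries otherwise. Families with
    zero counts in every sample are excluded (logged). Fold change is
    (mean treated proportion + ε)/(mean control proportion + ε) with
    ε = 0.5/median(N).
    """
    samples = list(counts.columns)
    missing = [s for s in samples if s not in conditions or s not in library_sizes]
    if missing:
        raise ValueError(f"samples without condition/library size: {missing}")
    ctrl = [s for s in samples if conditions[s] == "control"]
    trt = [s for s in samples if conditions[s] == "treated"]
    if not ctrl or not trt:
        raise ValueError("need at least one sample per condition")
    N_c = np.array([library_sizes[s] for s in ctrl], dtype=float)
    N_t = np.array([library_sizes[s] for s in trt], dtype=float)
    eps = 0.5 / np.median(np.concatenate([N_c, N_t]))
    use_baggerly = len(ctrl) >= 2 and len(trt) >= 2

    nonzero = counts.sum(axis=1) > 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        logger.info("excluded %d families absent from all samples", n_excluded)

    rows = []
    for family in counts.index[nonzero]:
        x_c = counts.loc[family, ctrl].to_numpy(dtype=float)
        x_t = counts.loc[family, trt].to_numpy(dtype=float)
        mean_c = float(np.mean(x_c / N_c))
        mean_t = float(np.mean(x_t / N_t))
        if use_baggerly:
            res = baggerly_test(x_t, N_t, x_c, N_c)
            test, stat, p = "baggerly", res.tw, res.p_value
        else:
            res = kal_z_test(int(x_t.sum()), int(N_t.sum()),
                             int(x_c.sum()), int(N_c.sum()))
            test, stat, p = "kal_z", res.z, res.p_value
        rows.append({
            "family": family,
            "mean_control_prop": mean_c,
            "mean_treated_prop": mean_t,
            "fold_change": (mean_t + eps) / (mean_c + eps),
            "test": test,
            "statistic": stat,
            "p": p,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values("family", kind="stable").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df
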