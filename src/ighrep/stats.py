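"""Usage-frequency tables and the associated statistical battery.

Pearson chi-square and likelihood-ratio (G) tests come with an optional
Monte Carlo p-value: cell counts are resampled multinomially under the
independence model (row x column margin products over the grand total, total
fixed), and the p-value uses the +1/(reps+1) continuity convention.  The
one-sample proportion test against a background gene frequency is a normal-
approximation z-test with an exact binomial option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hcdr3 import CanonicalClone
from .io import infer_subgroup


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: int | None = None
    p_monte_carlo: float | None = None
    mc_reps: int | None = None
    mc_seed: int | None = None
    method: str = ""


def frequency_table(clones: list[CanonicalClone], level: str = "gene",
                    segment: str = "V", group_by: str | None = None,
                    expanded_only: bool = False) -> pd.DataFrame:
    """Counts of segment usage (rows) by optional grouping column.

    ``level`` is "gene" or "subgroup"; ``segment`` is V, D or J.  The
    returned frame has integer counts plus a ``percent`` column per group
    (1-decimal, column sums 100 up to rounding).
    """
    if level not in ("gene", "subgroup"):
        raise ValueError(f"level must be gene or subgroup, got {level!r}")
    if segment not in ("V", "D", "J"):
        raise ValueError(f"segment must be V, D or J, got {segment!r}")
    pool = [c for c in clones if c.is_expanded] if expanded_only else list(clones)
    if not pool:
        raise ValueError("no clones to tabulate")
    attr = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment]
    sub_attr = {"V": "v_subgroup", "D": "d_subgroup", "J": "j_subgroup"}[segment]

    def category(clone):
        if level == "gene":
            return getattr(clone, attr) or "(none)"
        explicit = getattr(clone, sub_attr)
        call = getattr(clone, attr)
        return explicit or (infer_subgroup(call) if call else "(none)")

    rows = [{"category": category(c),
             "group": getattr(c, group_by) if group_by else "all"} for c in pool]
    df = pd.DataFrame(rows)
    counts = df.pivot_table(index="category", columns="group", aggfunc="size",
                            fill_value=0)
    counts.columns.name = None
    percents = (100.0 * counts / counts.sum(axis=0)).round(1)
    percents.columns = [f"percent_{c}" if group_by else "percent"
                        for c in percents.columns]
    return pd.concat([counts, percents], axis=1)


def _mc_pvalues(observed: np.ndarray, expected: np.ndarray, x2_obs: float,
                g_obs: float, reps: int, seed: int) -> tuple[float, float]:
    """Total-fixed multinomial resampling under the independence model.

    Each simulated table is scored against expected counts rebuilt from its
    own margins (the plug-in statistic), so the simulated statistics follow
    the same null law as the observed one.
    """
    rng = np.random.default_rng(seed)
    n = int(observed.sum())
    r, c = observed.shape
    probs = (expected / n).ravel()
    sims = rng.multinomial(n, probs, size=reps).astype(float).reshape(reps, r, c)
    row = sims.sum(axis=2)
    col = sims.sum(axis=1)
    e_sim = row[:, :, None] * col[:, None, :] / n
    with np.errstate(divide="ignore", invalid="ignore"):
        x2_terms = np.where(e_sim > 0, (sims - e_sim) ** 2 / e_sim, 0.0)
        g_terms = np.where(sims > 0, sims * np.log(sims / e_sim), 0.0)
    x2_sim = x2_terms.sum(axis=(1, 2))
    g_sim = 2.0 * g_terms.sum(axis=(1, 2))
    p_x2 = (1 + int((x2_sim >= x2_obs - 1e-12).sum())) / (reps + 1)
    p_g = (1 + int((g_sim >= g_obs - 1e-12).sum())) / (reps + 1)
    return p_x2, p_g


def chi_square_tests(table, mc_reps: int = 0, seed: int = 0
                     ) -> tuple[TestResult, TestResult]:
    """Pearson X2 and likelihood-ratio G on a contingency table.

    Asymptotic p-values use the chi-square distribution with (r-1)(c-1)
    degrees of freedom; with ``mc_reps`` > 0 a seeded Monte Carlo p-value is
    attached to each.
    """
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    n = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    x2 = float(((observed - expected) ** 2 / expected).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(observed > 0, observed * np.log(observed / expected), 0.0)
    g = float(2.0 * terms.sum())
    pearson = TestResult(statistic=x2, p_value=float(sps.chi2.sf(x2, df)), df=df,
                         method="pearson_chi2")
    lr = TestResult(statistic=g, p_value=float(sps.chi2.sf(g, df)), df=df,
                    method="likelihood_ratio")
    if mc_reps > 0:
        p_x2, p_g = _mc_pvalues(observed, expected, x2, g, mc_reps, seed)
        pearson.p_monte_carlo, pearson.mc_reps, pearson.mc_seed = p_x2, mc_reps, seed
        lr.p_monte_carlo, lr.mc_reps, lr.mc_seed = p_g, mc_reps, seed
    return pearson, lr


def proportion_test(k: int, n: int, p0: float, exact: bool = False) -> TestResult:
    """Two-sided one-sample test of an observed proportion against ``p0``."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if exact:
        res = sps.binomtest(k, n, p0, alternative="two-sided")
        return TestResult(statistic=float(k / n), p_value=float(res.pvalue),
                          method="binomial_exact")
    z = (k / n - p0) / np.sqrt(p0 * (1 - p0) / n)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(statistic=float(z), p_value=float(min(p, 1.0)),
                      method="proportion_z")


def two_sample_t(x, y, welch: bool = False) -> TestResult:
    """Two-sided two-sample t-test (pooled by default, Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        # degenerate: no within-group variance
        equal = np.isclose(x.mean(), y.mean())
        return TestResult(statistic=0.0 if equal else np.inf,
                          p_value=1.0 if equal else 0.0,
                          df=len(x) + len(y) - 2, method="t_degenerate")
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    df = None if welch else len(x) + len(y) - 2
    return TestResult(statistic=float(t), p_value=float(p), df=df,
                      method="welch_t" if welch else "student_t")


def summarize_features(clones: list[CanonicalClone], values: dict[str, float],
                       field: str, expanded_only: bool = False
                       ) -> tuple[float, float | None, int]:
    """Mean, sample SD and n of an HCDR3 feature over canonical clones.

    ``values`` maps cdr3_aa -> feature value (length or pI); rounding follows
    the reporting convention: 1 decimal for length, 2 for pI.
    """
    pool = [c for c in clones if c.is_expanded] if expanded_only else list(clones)
    if not pool:
        raise ValueError("no clones to summarise")
    data = np.array([values[c.cdr3_aa] for c in pool], dtype=float)
    digits = 1 if field == "length" else 2
    mean = round(float(data.mean()), digits)
    sd = round(float(data.std(ddof=1)), digits) if len(data) >= 2 else None
    return mean, sd, len(data)
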