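"""Group-level inference: one-tailed Bonferroni t-tests against the
permutation baseline, two-way repeated-measures ANOVA with Tukey HSD
post-hocs, the Wilcoxon signed-rank test, and signal-detection d'.

The repeated-measures ANOVA uses the classical within-subject sums-of-
squares decomposition for a fully crossed subject x A x B design: each
effect is tested against its own subject-interaction error term
(MS_A / MS_{A x S}, MS_B / MS_{B x S}, MS_{AB} / MS_{AB x S}). Tukey HSD
on a within-subject factor uses that factor's interaction error term,
with the studentized-range distribution for p-values.

The Wilcoxon test enumerates all sign assignments exactly for n <= 12
paired differences (the rating experiment has n = 7) and falls back to
the tie-corrected normal approximation above that; a Z value from the
normal approximation is always reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# one-sample t against the shuffled baseline
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    roi: str
    contrast: str
    t: float
    dof: int
    p_one_tailed: float
    alpha_corrected: float
    significant: bool


def one_sample_t_one_tailed(
    values: np.ndarray,
    baseline: float,
    m_tests: int = 1,
    alpha: float = 0.05,
    roi: str = "",
    contrast: str = "",
) -> GroupTestResult:
    """Upper-tailed one-sample t-test of ``values`` against ``baseline``
    with Bonferroni correction for ``m_tests`` simultaneous tests.

    A zero-variance sample is handled as t = +/-inf with p = 0 (mean
    above baseline) or 1, and t = 0, p = 0.5 when mean equals baseline.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    n = v.size
    sd = v.std(ddof=1)
    diff = v.mean() - baseline
    if sd == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 0.5 if diff == 0 else (0.0 if diff > 0 else 1.0)
    else:
        t = float(diff / (sd / np.sqrt(n)))
        p = float(sps.t.sf(t, n - 1))
    a_corr = alpha / m_tests
    return GroupTestResult(
        roi=roi, contrast=contrast, t=float(t), dof=n - 1,
        p_one_tailed=p, alpha_corrected=a_corr, significant=bool(p <= a_corr),
    )


# ---------------------------------------------------------------------------
# two-way repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaEffect:
    name: str
    ss: float
    df: int
    ms: float
    F: float
    p: float
    error_ss: float
    error_df: int
    error_ms: float


@dataclass
class AnovaTable:
    design: str
    effects: dict[str, AnovaEffect] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.name, "SS": e.ss, "df": e.df, "MS": e.ms,
                    "F": e.F, "p": e.p, "error_df": e.error_df,
                    "error_MS": e.error_ms,
                }
                for e in self.effects.values()
            ]
        )


def rm_anova_two_way(data: np.ndarray, design_label: str = "") -> AnovaTable:
    """Two-way fully-repeated-measures ANOVA on a complete
    subjects x A-levels x B-levels array of cell means."""
    d = np.asarray(data, dtype=float)
    if d.ndim != 3:
        raise ValueError("data must be subjects x A x B")
    if not np.all(np.isfinite(d)):
        raise ValueError("missing cells: the design must be complete")
    n, a, b = d.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")

    grand = d.mean()
    m_s = d.mean(axis=(1, 2))           # subject means
    m_a = d.mean(axis=(0, 2))           # A marginal means
    m_b = d.mean(axis=(0, 1))           # B marginal means
    m_sa = d.mean(axis=2)               # subject x A
    m_sb = d.mean(axis=1)               # subject x B
    m_ab = d.mean(axis=0)               # A x B

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        d
        - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
        + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    table = AnovaTable(design=design_label or f"{a}x{b}")

    def add(name: str, ss: float, df: int, e_ss: float, e_df: int) -> None:
        ms = ss / df
        e_ms = e_ss / e_df
        F = ms / e_ms if e_ms > 0 else (0.0 if ms == 0 else np.inf)
        p = float(sps.f.sf(F, df, e_df)) if np.isfinite(F) else 0.0
        table.effects[name] = AnovaEffect(
            name, float(ss), df, float(ms), float(F), p,
            float(e_ss), e_df, float(e_ms),
        )

    add("A", ss_a, a - 1, ss_as, (a - 1) * (n - 1))
    add("B", ss_b, b - 1, ss_bs, (b - 1) * (n - 1))
    add("AxB", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1))
    return table


# ---------------------------------------------------------------------------
# Tukey HSD on a within-subject factor
# ---------------------------------------------------------------------------

@dataclass
class PosthocResult:
    pair: tuple[int, int]
    mean_difference: float
    q: float
    p: float
    significant: bool


def tukey_hsd(
    marginal_means: np.ndarray,
    error_ms: float,
    error_df: int,
    alpha: float = 0.05,
) -> list[PosthocResult]:
    """Tukey HSD over the levels of one within-subject factor.

    ``marginal_means`` is subjects x levels (already averaged over the
    other factor); ``error_ms``/``error_df`` is the factor's
    subject-interaction error term from the ANOVA, on the scale of
    single observations. q = |diff| / sqrt(error_ms / n_obs_per_mean),
    where each level mean is based on n_subjects * n_other observations
    — pass marginal means computed from the same data as the ANOVA so
    that the implied n matches error_ms / (variance of a level mean).
    """
    m = np.asarray(marginal_means, dtype=float)
    if m.ndim != 2:
        raise ValueError("marginal_means must be subjects x levels")
    n, k = m.shape
    if k < 2:
        return []
    level_means = m.mean(axis=0)
    # each level mean aggregates n subjects; error_ms is per observation
    # on the same aggregation level as the cells that built it
    se = np.sqrt(error_ms / n)
    out: list[PosthocResult] = []
    for i, j in itertools.combinations(range(k), 2):
        diff = level_means[i] - level_means[j]
        q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
        p = (
            float(sps.studentized_range.sf(q, k, error_df))
            if np.isfinite(q)
            else 0.0
        )
        out.append(PosthocResult((i, j), float(diff), float(q), p, bool(p < alpha)))
    return out


def tukey_on_factor(
    data: np.ndarray, table: AnovaTable, factor: str = "A", alpha: float = 0.05
) -> list[PosthocResult]:
    """Tukey HSD for factor A or B of a fitted two-way rm-ANOVA.

    Marginal means are averaged over the other factor, and the error
    term is the factor's subject-interaction MS rescaled to the marginal
    (per-subject-mean) scale by the number of other-factor levels."""
    d = np.asarray(data, dtype=float)
    n, a, b = d.shape
    if factor == "A":
        marg = d.mean(axis=2)
        eff = table.effects["A"]
        scale = b
    elif factor == "B":
        marg = d.mean(axis=1)
        eff = table.effects["B"]
        scale = a
    else:
        raise ValueError("factor must be 'A' or 'B'")
    return tukey_hsd(marg, eff.error_ms / scale, eff.error_df, alpha=alpha)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

EXACT_N_MAX = 12


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, two_tailed: bool = True
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (Z, p).

    Zero differences are discarded. p is exact (full enumeration of the
    2^n sign assignments, ties given average ranks) for n <= 12 and a
    tie-corrected normal approximation with continuity correction
    otherwise. Z always comes from the normal approximation, signed by
    the direction of the rank sum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    # tie correction for the variance of W+
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    cc = 0.5 * np.sign(w_pos - mu)  # continuity correction toward the mean
    z = (w_pos - mu - cc) / sigma if sigma > 0 else 0.0

    if n <= EXACT_N_MAX:
        # exact null distribution of W+ over all sign assignments
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        w_small = min(w_pos, n * (n + 1) / 2.0 - w_pos)
        p_low = np.mean(totals <= w_small + 1e-9)
        p = min(1.0, 2.0 * p_low) if two_tailed else float(
            np.mean(totals >= w_pos - 1e-9)
            if w_pos > mu
            else np.mean(totals <= w_pos + 1e-9)
        )
    else:
        p_one = float(sps.norm.sf(abs(z)))
        p = min(1.0, 2.0 * p_one) if two_tailed else p_one
    return float(z), float(p)


# ---------------------------------------------------------------------------
# d'
# ---------------------------------------------------------------------------

@dataclass
class DPrimeResult:
    d_prime: float
    hit_rate: float
    fa_rate: float
    correction_applied: bool


def dprime(
    hits: int, misses: int, false_alarms: int, correct_rejections: int
) -> DPrimeResult:
    """Signal-detection sensitivity d' = z(hit rate) - z(FA rate).

    When any observed rate is 0 or 1, the log-linear correction is
    applied (0.5 added to every cell, 1 to every denominator) so the
    quantiles stay finite.
    """
    for v in (hits, misses, false_alarms, correct_rejections):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n_sig = hits + misses
    n_noise = false_alarms + correct_rejections
    if n_sig == 0 or n_noise == 0:
        raise ValueError("need both signal and noise trials")
    hr = hits / n_sig
    fa = false_alarms / n_noise
    corrected = hr in (0.0, 1.0) or fa in (0.0, 1.0)
    if corrected:
        hr = (hits + 0.5) / (n_sig + 1)
        fa = (false_alarms + 0.5) / (n_noise + 1)
    d = float(sps.norm.ppf(hr) - sps.norm.ppf(fa))
    return DPrimeResult(d, float(hr), float(fa), corrected)
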