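"""CD4:CD8 odds-ratio scans over TCR features with exact tests and
multiple-testing control.

For each feature value (a V or J gene, a (Vα, Vβ) pair, an integer CDR3
charge or length, or a charge/length pair) the unique clonotypes of the
two lineages form a 2×2 table

    OR = (|C⁺∈T4| · |C⁻∈T8|) / (|C⁻∈T4| · |C⁺∈T8|),

with a two-sided exact hypergeometric p-value, a 95% Woolf CI on the log
odds ratio (Haldane–Anscombe 0.5 correction for zero cells), and either a
Bonferroni adjustment (single-chain scans) or Storey q-values (paired
scans, with a Benjamini–Hochberg fallback for small families).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from statsmodels.stats.multitest import multipletests

from .core import Lineage, Repertoire, Scope, cdr3_charge

SINGLE_FEATURES = ("v_gene", "j_gene", "charge", "length")
PAIR_FEATURES = ("v_pair", "j_pair", "charge_pair", "length_pair")
FeatureType = Literal[
    "v_gene", "j_gene", "v_pair", "j_pair",
    "charge", "charge_pair", "length", "length_pair",
]

# below this total count the exact p is computed in integer arithmetic;
# larger tables use a vectorized float enumeration
_EXACT_INT_MAX_N = 400
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class FeatureCount:
    """2×2 counts for one feature: a = CD4 with, b = CD4 without,
    c = CD8 with, d = CD8 without."""

    feature: object
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")


@dataclass
class AssociationResult:
    feature: object
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    adjusted: float = float("nan")
    significant: bool = False
    adjust_method: str = ""

    @property
    def log_or(self) -> float:
        return math.log(self.odds_ratio) if 0 < self.odds_ratio < math.inf \
            else math.copysign(math.inf, self.odds_ratio - 1)


def exact_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table.  Small tables
    (N ≤ 400) are evaluated in exact integer arithmetic; larger tables use
    a vectorized float enumeration with a relative tie tolerance.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0:
        raise ValueError("empty margin in 2x2 table")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if n <= _EXACT_INT_MAX_N:
        nums = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
        obs = nums[a - lo]
        total = math.comb(n, c1)
        return sum(v for v in nums if v <= obs) / total
    k = np.arange(lo, hi + 1)
    logpmf = stats.hypergeom.logpmf(k, n, c1, r1)
    obs = logpmf[a - lo]
    mask = logpmf <= obs + math.log1p(_TIE_RTOL)
    return float(min(1.0, np.exp(logpmf[mask]).sum()))


def odds_ratio(fc: FeatureCount, ci_level: float = 0.95) -> AssociationResult:
    """Sample odds ratio with Woolf CI and exact two-sided p for one
    feature's 2×2 table."""
    a, b, c, d = fc.a, fc.b, fc.c, fc.d
    if a + b == 0 or c + d == 0:
        raise ValueError("empty lineage margin")
    if b * c == 0:
        orr = math.inf if a * d > 0 else float("nan")
    else:
        orr = (a * d) / (b * c)
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    log_or = math.log(aa * dd / (bb * cc))
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    p = exact_two_sided_p(a, b, c, d)
    return AssociationResult(
        feature=fc.feature, a=a, b=b, c=c, d=d,
        odds_ratio=orr,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p=p,
    )


def _feature_values(rep: Repertoire, feature_type: str) -> pd.Series:
    t = rep.table
    if feature_type in ("v_gene", "j_gene"):
        if rep.scope == Scope.PAIRED:
            raise ValueError(f"{feature_type} scan needs a single-chain repertoire")
        return t["v" if feature_type == "v_gene" else "j"]
    if feature_type in ("charge", "length"):
        if rep.scope == Scope.PAIRED:
            raise ValueError(f"{feature_type} scan needs a single-chain repertoire")
        return t["cdr3"].map(cdr3_charge) if feature_type == "charge" \
            else t["cdr3"].str.len()
    if rep.scope != Scope.PAIRED:
        raise ValueError(f"{feature_type} scan needs a paired repertoire")
    if feature_type == "v_pair":
        return pd.Series(list(zip(t["v_a"], t["v_b"])), index=t.index)
    if feature_type == "j_pair":
        return pd.Series(list(zip(t["j_a"], t["j_b"])), index=t.index)
    if feature_type == "charge_pair":
        return pd.Series(list(zip(t["cdr3_a"].map(cdr3_charge),
                                  t["cdr3_b"].map(cdr3_charge))), index=t.index)
    if feature_type == "length_pair":
        return pd.Series(list(zip(t["cdr3_a"].str.len(),
                                  t["cdr3_b"].str.len())), index=t.index)
    raise ValueError(f"unknown feature type {feature_type!r}")


def _pool_tails(vals4: pd.Series, vals8: pd.Series, min_count: int):
    """Merge sparse extreme integer values into '≤x' / '≥y' tail bins so
    every tail bin holds at least ``min_count`` observations in total."""
    counts = pd.concat([vals4, vals8]).value_counts().sort_index()
    values = counts.index.to_numpy()
    csum = counts.to_numpy().cumsum()
    total = csum[-1]

    lo_cut = hi_cut = None
    # smallest k with cumulative count >= min_count; pool values[0..k] when
    # the bottom value alone is below threshold
    if len(values) > 1 and counts.iloc[0] < min_count:
        k = int(np.searchsorted(csum, min_count))
        k = min(k, len(values) - 1)
        lo_cut = values[k]
    if len(values) > 1 and counts.iloc[-1] < min_count:
        csum_top = total - np.concatenate([[0], csum[:-1]])  # count of >= values[i]
        j = len(values) - 1 - int(np.searchsorted(csum_top[::-1], min_count))
        j = max(j, 0)
        hi_cut = values[j]
    if lo_cut is not None and hi_cut is not None and hi_cut <= lo_cut:
        # degenerate: everything would pool; keep raw values instead
        return vals4, vals8

    def mapper(v):
        if lo_cut is not None and v <= lo_cut:
            return f"<={lo_cut}"
        if hi_cut is not None and v >= hi_cut:
            return f">={hi_cut}"
        return v

    return vals4.map(mapper), vals8.map(mapper)


def enumerate_features(
    cd4: Repertoire,
    cd8: Repertoire,
    feature_type: FeatureType,
    pool_min_count: int = 10,
) -> list[FeatureCount]:
    """One FeatureCount per observed feature value; each unique clonotype
    contributes once.  Sparse integer charge/length values are pooled into
    tail bins."""
    if cd4.scope != cd8.scope:
        raise ValueError("repertoire scopes differ")
    v4 = _feature_values(cd4, feature_type)
    v8 = _feature_values(cd8, feature_type)
    if feature_type in ("charge", "length") and pool_min_count:
        v4, v8 = _pool_tails(v4, v8, pool_min_count)
    n4, n8 = len(v4), len(v8)
    c4 = v4.value_counts()
    c8 = v8.value_counts()
    feats = sorted(set(c4.index) | set(c8.index), key=str)
    out = []
    for f in feats:
        a = int(c4.get(f, 0))
        c = int(c8.get(f, 0))
        out.append(FeatureCount(feature=f, a=a, b=n4 - a, c=c, d=n8 - c))
    return out


def storey_qvalues(pvals: Sequence[float]) -> np.ndarray:
    """Storey q-values with spline-smoothed π₀ over λ ∈ {0, .05, …, .95};
    falls back to Benjamini–Hochberg for families of fewer than 100 tests
    or when the π₀ fit is unstable."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([])
    if m < 100:
        return multipletests(p, method="fdr_bh")[1]
    lambdas = np.arange(0.0, 0.96, 0.05)
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spline = UnivariateSpline(lambdas, pi0_l, k=3)
            pi0 = float(spline(lambdas[-1]))
    except Exception:
        pi0 = float("nan")
    if not np.isfinite(pi0) or pi0 <= 0:
        return multipletests(p, method="fdr_bh")[1]
    pi0 = min(pi0, 1.0)
    order = np.argsort(p)
    q = np.empty(m)
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    return np.clip(q, 0.0, 1.0)


def association_scan(
    cd4: Repertoire,
    cd8: Repertoire,
    feature_type: FeatureType,
    alpha: float = 0.05,
    pool_min_count: int = 10,
) -> list[AssociationResult]:
    """Full odds-ratio scan with multiple-testing control.

    Single-chain feature families use a Bonferroni adjustment across the
    scan; paired families use q-values.  ``significant`` flags adjusted
    values below ``alpha``.
    """
    counts = enumerate_features(cd4, cd8, feature_type, pool_min_count)
    results = [odds_ratio(fc) for fc in counts]
    m = len(results)
    if m == 0:
        return results
    if feature_type in SINGLE_FEATURES:
        for r in results:
            r.adjusted = min(1.0, r.p * m)
            r.adjust_method = "bonferroni"
    else:
        qs = storey_qvalues([r.p for r in results])
        for r, q in zip(results, qs):
            r.adjusted = float(max(q, r.p))
            r.adjust_method = "qvalue"
    for r in results:
        r.significant = bool(r.adjusted < alpha)
    return results


def scan_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"feature": str(r.feature), "a": r.a, "b": r.b, "c": r.c, "d": r.d,
         "odds_ratio": r.odds_ratio, "ci_low": r.ci_low, "ci_high": r.ci_high,
         "p": r.p, "adjusted": r.adjusted, "significant": r.significant,
         "method": r.adjust_method}
        for r in results
    ])


@dataclass
class AAUsageResult:
    amino_acid: str
    mean_ratio: float
    t_stat: float
    p: float
    p_adjusted: float
    n_subjects: int
    zero_variance: bool


def aa_usage_ratio_test(
    cd4_freqs: pd.DataFrame,
    cd8_freqs: pd.DataFrame,
) -> list[AAUsageResult]:
    """Per-amino-acid CD4/CD8 usage ratio across subjects with a one-sample
    t-test of the log-ratio against 0, Bonferroni-adjusted over 20 tests.

    Inputs are subject × amino-acid frequency tables (same index/columns).
    Subjects where an amino acid is absent from the CD8 repertoire are
    excluded for that amino acid, with a warning.
    """
    if len(cd4_freqs) < 2 or len(cd8_freqs) < 2:
        raise ValueError("at least two subjects required")
    common = cd4_freqs.index.intersection(cd8_freqs.index)
    out: list[AAUsageResult] = []
    m = cd4_freqs.shape[1]
    for aa in cd4_freqs.columns:
        f4 = cd4_freqs.loc[common, aa].to_numpy(dtype=float)
        f8 = cd8_freqs.loc[common, aa].to_numpy(dtype=float)
        usable = (f8 > 0) & (f4 > 0)
        if usable.sum() < len(common):
            warnings.warn(
                f"amino acid {aa}: ratio undefined for "
                f"{len(common) - int(usable.sum())} subject(s); excluded")
        f4, f8 = f4[usable], f8[usable]
        if len(f4) < 2:
            out.append(AAUsageResult(aa, float("nan"), float("nan"),
                                     float("nan"), float("nan"),
                                     int(usable.sum()), False))
            continue
        log_ratio = np.log(f4 / f8)
        if np.allclose(log_ratio.std(ddof=1), 0.0):
            p = 1.0 if np.allclose(log_ratio.mean(), 0.0) else 0.0
            out.append(AAUsageResult(aa, float(np.exp(log_ratio.mean())),
                                     float("nan"), p, min(1.0, p * m),
                                     len(f4), True))
            continue
        t, p = stats.ttest_1samp(log_ratio, 0.0)
        out.append(AAUsageResult(aa, float(np.mean(f4 / f8)), float(t),
                                 float(p), min(1.0, float(p) * m),
                                 len(f4), False))
    return out


@dataclass
class StrengthComparison:
    direction: str
    n_single: int
    n_paired: int
    median_single: float
    median_paired: float
    iqr_single: tuple[float, float]
    iqr_paired: tuple[float, float]
    p_value: float
    applicable: bool = True


def strength_comparison(
    single_results: Sequence[AssociationResult],
    paired_results: Sequence[AssociationResult],
    direction: Literal["CD4", "CD8"],
) -> StrengthComparison:
    """Compare |log OR| of significant single-chain vs paired features for
    one bias direction (CD4: OR > 1; CD8: OR < 1) by two-sided rank-sum.

    Features observed in only one lineage (infinite OR) are excluded."""
    def extract(results):
        vals = []
        for r in results:
            if not r.significant or not np.isfinite(r.odds_ratio) or r.odds_ratio <= 0:
                continue
            if direction == "CD4" and r.odds_ratio > 1:
                vals.append(abs(math.log(r.odds_ratio)))
            elif direction == "CD8" and r.odds_ratio < 1:
                vals.append(abs(math.log(r.odds_ratio)))
        return np.asarray(vals)

    s, pr = extract(single_results), extract(paired_results)
    if len(s) == 0 or len(pr) == 0:
        return StrengthComparison(direction, len(s), len(pr),
                                  float("nan"), float("nan"),
                                  (float("nan"),) * 2, (float("nan"),) * 2,
                                  float("nan"), applicable=False)
    p = float(stats.mannwhitneyu(s, pr, alternative="two-sided").pvalue)
    return StrengthComparison(
        direction=direction, n_single=len(s), n_paired=len(pr),
        median_single=float(np.median(s)), median_paired=float(np.median(pr)),
        iqr_single=(float(np.quantile(s, 0.25)), float(np.quantile(s, 0.75))),
        iqr_paired=(float(np.quantile(pr, 0.25)), float(np.quantile(pr, 0.75))),
        p_value=p,
    )
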