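"""CD4/CD8 repertoire sharing: Jaccard overlap, shared-vs-exclusive CDR3
length comparison, and a pluggable generation-probability hook.

Overlap between the unique CD4 and CD8 clonotype sets is quantified with
the Jaccard index J(CD4, CD8) = |CD4 ∩ CD8| / |CD4 ∪ CD8|, computed
separately for the α, β and paired αβ repertoires, pooled and per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
from scipy import stats

from .core import Lineage, Repertoire, Scope


def jaccard(a: Iterable, b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B|.  Errors when both sets are empty."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(sa & sb) / len(union)


@dataclass
class OverlapResult:
    scope: Scope
    jaccard: float
    overlap_percent: float  # shared as % of total unique (union)
    n_shared: int
    n_cd4_only: int
    n_cd8_only: int
    per_subject: dict[str, float] = field(default_factory=dict)


def overlap_summary(cd4: Repertoire, cd8: Repertoire) -> OverlapResult:
    """Pooled and per-subject overlap between two lineage repertoires.

    ``overlap_percent`` uses the union of unique clonotypes as denominator:
    100 · |shared| / |union|.
    """
    if cd4.scope != cd8.scope:
        raise ValueError(f"scope mismatch: {cd4.scope} vs {cd8.scope}")
    a, b = cd4.members, cd8.members
    shared = a & b
    union = a | b
    per_subject: dict[str, float] = {}
    for subject in sorted(cd4.subjects | cd8.subjects):
        sa = cd4.subject_members(subject)
        sb = cd8.subject_members(subject)
        if sa | sb:
            per_subject[subject] = jaccard(sa, sb)
    return OverlapResult(
        scope=cd4.scope,
        jaccard=len(shared) / len(union) if union else float("nan"),
        overlap_percent=100.0 * len(shared) / len(union) if union else float("nan"),
        n_shared=len(shared),
        n_cd4_only=len(a - b),
        n_cd8_only=len(b - a),
        per_subject=per_subject,
    )


def product_rule_gap(alpha_ov: float, beta_ov: float, paired_ov: float) -> float:
    """Signed gap between the observed paired overlap fraction and the
    product of the single-chain overlap fractions (diagnostic for
    independent chain sharing)."""
    for v in (alpha_ov, beta_ov, paired_ov):
        if not 0.0 <= v <= 1.0:
            raise ValueError("overlap fractions must lie in [0, 1]")
    return paired_ov - alpha_ov * beta_ov


@dataclass
class LengthComparison:
    scope: Scope
    n_shared: int
    n_exclusive: int
    mean_shared: float
    mean_exclusive: float
    ci_shared: tuple[float, float]
    ci_exclusive: tuple[float, float]
    p_value: float
    applicable: bool = True
    degenerate_ci: bool = False


def _member_lengths(rep: Repertoire, keys) -> np.ndarray:
    sub = rep.table.loc[list(keys)]
    if rep.scope == Scope.PAIRED:
        return (sub["cdr3_a"].str.len() + sub["cdr3_b"].str.len()).to_numpy()
    return sub["cdr3"].str.len().to_numpy()


def _boot_ci(x: np.ndarray, rng, n_boot: int, level: float) -> tuple[float, float]:
    idx = rng.integers(len(x), size=(n_boot, len(x)))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(means, alpha)), float(np.quantile(means, 1 - alpha)))


def shared_vs_exclusive_lengths(
    cd4: Repertoire,
    cd8: Repertoire,
    n_boot: int = 10_000,
    ci_level: float = 0.99,
    seed: int = 0,
) -> LengthComparison:
    """Compare mean CDR3 lengths of clonotypes shared between lineages
    against clonotypes exclusive to one lineage.

    Paired scope sums the α and β CDR3 lengths per clonotype.  CIs are
    seeded percentile bootstrap intervals of the mean (99% by default);
    the p-value is a two-sided Mann-Whitney U (normal approximation with
    tie correction).
    """
    if len(cd4) == 0 or len(cd8) == 0:
        raise ValueError("both repertoires must be non-empty")
    a, b = cd4.members, cd8.members
    shared_keys = a & b
    rng = np.random.default_rng(seed)
    excl = np.concatenate([
        _member_lengths(cd4, a - b) if a - b else np.array([]),
        _member_lengths(cd8, b - a) if b - a else np.array([]),
    ])
    if not shared_keys:
        return LengthComparison(cd4.scope, 0, len(excl), float("nan"),
                                float(np.mean(excl)) if len(excl) else float("nan"),
                                (float("nan"),) * 2, (float("nan"),) * 2,
                                float("nan"), applicable=False)
    sh = _member_lengths(cd4, shared_keys)
    degenerate = len(sh) < 2 or len(excl) < 2
    ci_sh = _boot_ci(sh, rng, n_boot, ci_level) if len(sh) > 1 else (float(sh[0]),) * 2
    ci_ex = (_boot_ci(excl, rng, n_boot, ci_level) if len(excl) > 1
             else (float(excl[0]),) * 2 if len(excl) else (float("nan"),) * 2)
    if len(excl) and len(sh):
        p = float(stats.mannwhitneyu(sh, excl, alternative="two-sided",
                                     method="asymptotic").pvalue)
    else:
        p = float("nan")
    return LengthComparison(
        scope=cd4.scope, n_shared=len(sh), n_exclusive=len(excl),
        mean_shared=float(sh.mean()),
        mean_exclusive=float(excl.mean()) if len(excl) else float("nan"),
        ci_shared=ci_sh, ci_exclusive=ci_ex, p_value=p,
        degenerate_ci=degenerate,
    )


class PgenDisabledError(RuntimeError):
    """No generation-probability engine configured."""


def pgen_hook(clonotype, engine: Callable[[object], float] | None = None) -> float:
    """Delegate generation-probability computation to an external engine.

    For a paired clonotype — any object with ``alpha`` and ``beta``
    attributes — the paired probability is the product of the per-chain
    probabilities (chains treated as independently generated).  Raises
    :class:`PgenDisabledError` when no engine is supplied.
    """
    if engine is None:
        raise PgenDisabledError(
            "generation-probability computation requires an external engine "
            "(e.g. an OLGA wrapper); none configured")
    try:
        if hasattr(clonotype, "alpha") and hasattr(clonotype, "beta"):
            return float(engine(clonotype.alpha)) * float(engine(clonotype.beta))
        return float(engine(clonotype))
    except PgenDisabledError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pgen engine failed for {clonotype!r}: {exc}") from exc
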