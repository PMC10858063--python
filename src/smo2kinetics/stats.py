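"""Group-level inference for fully within-subject round/leg/training designs.

Implements the classical univariate repeated-measures ANOVA on balanced
complete data: each effect's sum of squares comes from an inclusion-
exclusion decomposition over marginal means, and each effect is tested
against its own subject-by-effect interaction mean square.  No sphericity
correction is applied by default.  Effect sizes are reported as adjusted
partial eta squared (the bias-removing partial-epsilon-squared form,
expressed through F and its degrees of freedom) with the conventional
small / moderate / large bands, and significant omnibus effects are
followed up with Fisher's least-significant-difference pairwise contrasts
(unadjusted t tests on the omnibus error term).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectResult",
    "PairwiseContrast",
    "QQPoints",
    "rm_anova",
    "rm_anova_array",
    "adjusted_partial_eta_squared",
    "classify_effect",
    "fisher_lsd",
    "qq_points",
    "ALPHA",
]

#: significance threshold for omnibus and post-hoc tests
ALPHA = 0.05


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA main effect or interaction."""

    effect: str
    F: float
    df_effect: int
    df_error: int
    p: float
    adj_pes: float
    size_class: str
    ss_effect: float
    ss_error: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass(frozen=True)
class PairwiseContrast:
    """One Fisher-LSD pairwise contrast (unadjusted two-sided t test)."""

    level_a: object
    level_b: object
    mean_diff: float
    t: float
    p: float


@dataclass(frozen=True)
class QQPoints:
    """Normal quantile-quantile pairs for a normality screen (no automated
    accept/reject: intended for plotting or a slope check)."""

    theoretical: np.ndarray
    sample: np.ndarray
    degenerate: bool


def adjusted_partial_eta_squared(F: float, df_effect: int, df_error: int) -> float:
    """Bias-adjusted partial eta squared from F and its degrees of freedom.

    ``adj_pes = df_e (F - 1) / (df_e F + df_err)``, the partial epsilon
    squared: the null expectation of F (=1) is removed before forming the
    variance-explained ratio.  Negative values (F < 1) are clipped to 0,
    matching the convention of reporting 0.00 alongside null-ish effects.
    """
    if df_effect < 1 or df_error < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if F < 0:
        raise ValueError("F must be >= 0")
    return max(0.0, df_effect * (F - 1.0) / (df_effect * F + df_error))


def classify_effect(adj_pes: float) -> str:
    """Size class of an adjusted partial eta squared.

    < 0.01 trivial; 0.01-0.059 small; 0.06-0.137 moderate; >= 0.14 large.
    """
    if adj_pes < 0:
        raise ValueError("effect size must be >= 0")
    if adj_pes < 0.01:
        return "trivial"
    if adj_pes < 0.06:
        return "small"
    if adj_pes < 0.14:
        return "moderate"
    return "large"


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _effect_arrays(data: np.ndarray) -> dict[frozenset, np.ndarray]:
    """Inclusion-exclusion effect arrays for every subset of axes.

    ``data`` has one axis per design factor (axis 0 = subject).  The effect
    array of subset T is the T-marginal mean minus all lower-order effects
    (grand mean included), kept with singleton axes for broadcasting.
    """
    axes = tuple(range(data.ndim))
    effects: dict[frozenset, np.ndarray] = {
        frozenset(): data.mean(axis=axes, keepdims=True)
    }
    for size in range(1, data.ndim + 1):
        for T in combinations(axes, size):
            key = frozenset(T)
            marg = data.mean(axis=tuple(a for a in axes if a not in key), keepdims=True)
            for U, eff in effects.items():
                if U < key:
                    marg = marg - eff
            effects[key] = marg
    return effects


def _subset_ss(effects: dict[frozenset, np.ndarray], shape: tuple[int, ...], T: frozenset) -> float:
    mult = float(np.prod([s for a, s in enumerate(shape) if a not in T]))
    return float(np.sum(effects[T] ** 2) * mult)


def rm_anova_array(data: np.ndarray, factor_names: list[str]) -> list[EffectResult]:
    """RM-ANOVA on a balanced array with axes (subject, factor1, ...).

    Every main effect and interaction of the within-subject factors is
    tested against its own interaction with subject.  Exposed separately
    from the long-table interface so simulation studies can skip the pivot.
    """
    if data.ndim != len(factor_names) + 1:
        raise ValueError("need one array axis per factor plus subjects")
    if data.shape[0] < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 subjects")
    if np.isnan(data).any():
        raise ValueError("design is incomplete (NaN cells)")
    shape = data.shape
    n_subj = shape[0]
    effects = _effect_arrays(data)
    results: list[EffectResult] = []
    factor_axes = list(range(1, data.ndim))
    for size in range(1, len(factor_axes) + 1):
        for A in combinations(factor_axes, size):
            key = frozenset(A)
            ss_eff = _subset_ss(effects, shape, key)
            ss_err = _subset_ss(effects, shape, key | {0})
            df_eff = int(np.prod([shape[a] - 1 for a in A]))
            df_err = df_eff * (n_subj - 1)
            ms_eff = ss_eff / df_eff
            ms_err = ss_err / df_err
            F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
            p = float(sps.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
            adj = adjusted_partial_eta_squared(F if np.isfinite(F) else 1e12, df_eff, df_err)
            results.append(
                EffectResult(
                    effect=":".join(factor_names[a - 1] for a in A),
                    F=float(F),
                    df_effect=df_eff,
                    df_error=df_err,
                    p=p,
                    adj_pes=adj,
                    size_class=classify_effect(adj),
                    ss_effect=ss_eff,
                    ss_error=ss_err,
                )
            )
    return results


def pivot_balanced(
    table: pd.DataFrame, dv: str, subject: str, within: list[str]
) -> tuple[np.ndarray, list[list]]:
    """Pivot a long table to the (subject, factors...) array, enforcing one
    value per cell and complete cases for every subject."""
    counts = table.groupby([subject, *within], observed=True)[dv].count()
    if (counts > 1).any():
        offenders = sorted({idx[0] for idx in counts[counts > 1].index})
        raise ValueError(f"duplicated cells for subjects: {offenders}")
    if (counts < 1).any():
        offenders = sorted({idx[0] for idx in counts[counts < 1].index})
        raise ValueError(f"missing cells for subjects: {offenders}")
    levels = [sorted(table[f].unique()) for f in within]
    subjects = sorted(table[subject].unique())
    expected = len(subjects) * int(np.prod([len(l) for l in levels]))
    if len(table) != expected:
        cells = table.groupby(subject, observed=True)[dv].count()
        per = int(np.prod([len(l) for l in levels]))
        offenders = sorted(cells[cells != per].index.tolist())
        raise ValueError(f"incomplete design for subjects: {offenders}")
    wide = table.set_index([subject, *within])[dv].sort_index()
    data = wide.to_numpy().reshape([len(subjects)] + [len(l) for l in levels])
    return data, [subjects, *levels]


def rm_anova(
    table: pd.DataFrame, dv: str, subject: str, within: list[str]
) -> list[EffectResult]:
    """Repeated-measures ANOVA on a long-format table.

    Parameters
    ----------
    table : DataFrame
        One row per (subject, cell) with the outcome in column ``dv``.
    dv, subject, within
        Column names of the outcome, subject id and within-subject factors.
    """
    data, _ = pivot_balanced(table, dv, subject, within)
    return rm_anova_array(data, within)


def effects_frame(results: list[EffectResult]) -> pd.DataFrame:
    """Tabulate EffectResults (effect, F, dfs, p, adj_pes, class)."""
    return pd.DataFrame(
        {
            "effect": [r.effect for r in results],
            "F": [r.F for r in results],
            "df_effect": [r.df_effect for r in results],
            "df_error": [r.df_error for r in results],
            "p": [r.p for r in results],
            "adj_pes": [r.adj_pes for r in results],
            "size_class": [r.size_class for r in results],
        }
    )


def fisher_lsd(
    cell_means: dict, ms_error: float, df_error: int, n_per_level: int
) -> list[PairwiseContrast]:
    """Fisher's LSD pairwise contrasts after a significant omnibus effect.

    Each pair of level means is compared with an unadjusted two-sided t
    test on the omnibus error mean square: ``t = (m_i - m_j) /
    sqrt(2 ms_error / n)`` on ``df_error`` degrees of freedom.
    """
    if n_per_level < 2:
        raise ValueError("need >= 2 observations per level")
    if ms_error < 0 or df_error < 1:
        raise ValueError("invalid error term")
    se = np.sqrt(2.0 * ms_error / n_per_level)
    out: list[PairwiseContrast] = []
    levels = list(cell_means)
    for a, b in combinations(levels, 2):
        diff = float(cell_means[a] - cell_means[b])
        if se == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        else:
            t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df_error)) if np.isfinite(t) else 0.0
        out.append(PairwiseContrast(a, b, diff, float(t), p))
    return out


def qq_points(values: np.ndarray) -> QQPoints:
    """Normal Q-Q pairs at plotting positions ``(i - 0.5) / n``."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 values for a Q-Q screen")
    positions = (np.arange(1, n + 1) - 0.5) / n
    theo = sps.norm.ppf(positions)
    return QQPoints(theo, x, degenerate=bool(np.all(x == x[0])))
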