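"""Group summaries, pairwise Student's t tests and compact letter displays.

Implements the figure-annotation conventions used throughout the
experiments: means +/- standard error per group and time point, two-sided
two-sample t tests between every pair of groups, and letter codes in which
groups sharing a letter do not differ significantly.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

from .errors import ValidationError


def group_mean_se(values) -> tuple[float, float, int]:
    """Arithmetic mean, standard error (sample SD / sqrt(n)) and n."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 replicates for a mean +/- SE")
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size)), int(x.size)


def t_pvalue(a, b, variant: str = "student", alternative: str = "two-sided") -> float:
    """Two-sample t-test p-value with degenerate zero-variance handling.

    ``variant`` selects pooled-variance Student ("student") or Welch
    ("welch").  When both samples have zero variance the p-value is 1 for
    equal means and 0 for unequal means (perfect separation).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"), alternative=alternative)
    p = float(res.pvalue)
    if np.isnan(p):
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return p


def pairwise_t(groups, variant: str = "student") -> np.ndarray:
    """Symmetric matrix of two-sided pairwise p-values with unit diagonal."""
    k = len(groups)
    p = np.ones((k, k))
    for i, j in combinations(range(k), 2):
        p[i, j] = p[j, i] = t_pvalue(groups[i], groups[j], variant=variant)
    return p


def letter_display(p_matrix, alpha: float = 0.05) -> list[str]:
    """Compact letter display by insert-and-absorb.

    Builds letter sets such that two groups share a letter if and only if
    their pairwise p-value is >= ``alpha``.  Starting from a single set of
    all groups, each significant pair splits every set containing both;
    sets that became subsets of others are absorbed, and redundant sets are
    swept out so the letter count stays minimal.  Ties are broken by group
    input order, so the output is deterministic.
    """
    p = np.asarray(p_matrix, dtype=float)
    n = p.shape[0]
    if p.shape != (n, n):
        raise ValidationError("p_matrix must be square")
    sets: list[frozenset] = [frozenset(range(n))]
    for i, j in combinations(range(n), 2):
        if p[i, j] < alpha:
            new_sets = []
            for s in sets:
                if i in s and j in s:
                    new_sets.extend([s - {i}, s - {j}])
                else:
                    new_sets.append(s)
            # absorb: drop sets contained in another
            sets = [
                s
                for k_, s in enumerate(new_sets)
                if s and not any(s < t or (s == t and k_ > l) for l, t in enumerate(new_sets))
            ]

    nonsig = [(i, j) for i, j in combinations(range(n), 2) if p[i, j] >= alpha]

    def covers(collection):
        if not all(any(g in s for s in collection) for g in range(n)):
            return False
        return all(any(i in s and j in s for s in collection) for i, j in nonsig)

    # sweep: drop sets whose removal keeps the display valid
    changed = True
    while changed:
        changed = False
        for k_ in range(len(sets)):
            trial = sets[:k_] + sets[k_ + 1:]
            if trial and covers(trial):
                sets = trial
                changed = True
                break

    sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return ["".join(alphabet[k_] for k_, s in enumerate(sets) if g in s) for g in range(n)]


def percent_reduction(control_loss: float, treated_loss: float) -> float:
    """Percent reduction 100 * (control - treated) / control."""
    if control_loss <= 0:
        raise ValidationError("control loss must be > 0")
    return 100.0 * (control_loss - treated_loss) / control_loss
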