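"""Two-way ANOVA F statistics and permutation tests for a 2x2 design.

Cumulative outcomes (respired CO2, absolute and relative respired 13C) are
tested for drought, land-use and interaction effects.  With the small
replicate numbers of a mesocosm experiment the F distribution's p-values
are only approximate, so the classical F statistics are reported as effect
sizes and p-values come from a permutation scheme:

* main effects — the tested factor's labels are permuted within levels of
  the other factor (restricted permutation, exact under the null of no
  effect of the tested factor);
* interaction — residuals from the additive main-effects least-squares fit
  are permuted and added back to the fitted values (Freedman-Lane style).

When the number of distinct arrangements is at most ``max_enumeration``
the null distribution is enumerated exactly (identity included,
p = count / total); otherwise ``n_perm`` arrangements are sampled and
p = (1 + count) / (1 + n_perm), which never returns zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def _multiset_permutations(items: list):
    """All distinct permutations of a multiset, lexicographic order."""
    seq = sorted(items)
    n = len(seq)
    while True:
        yield list(seq)
        # next lexicographic permutation
        i = n - 2
        while i >= 0 and seq[i] >= seq[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while seq[j] <= seq[i]:
            j -= 1
        seq[i], seq[j] = seq[j], seq[i]
        seq[i + 1:] = reversed(seq[i + 1:])

TERMS = ("factor_a", "factor_b", "interaction")
MAX_ENUMERATION = 20000


@dataclass(frozen=True)
class AnovaResult:
    term: str
    F: float
    p_classical: float
    p_exact: float
    n_perm: int
    seed: int | None
    enumerated: bool
    degenerate: bool = False


def _tie_tol(f_obs: float) -> float:
    """Tolerance for counting permutation ties (relative for large F)."""
    if not np.isfinite(f_obs):
        return 0.0
    return max(1e-12, 1e-9 * abs(f_obs))


def _codes(labels) -> tuple[np.ndarray, int]:
    _, inv = np.unique(np.asarray(labels), return_inverse=True)
    return inv, int(inv.max()) + 1


def _f_stacked(
    V: np.ndarray, a: np.ndarray, na: int, b: np.ndarray, nb: int
) -> dict[str, np.ndarray]:
    """F statistics for a stack of response vectors (rows of V).

    Balanced (or near-balanced) two-way layout: sums of squares from group
    means, interaction from cell means.  Degenerate residual variance gives
    F = 0 by convention (flagged by the caller).
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    n = V.shape[1]
    cell = a * nb + b
    ncell = na * nb

    def group_ss(codes: np.ndarray, k: int) -> np.ndarray:
        onehot = np.zeros((n, k))
        onehot[np.arange(n), codes] = 1.0
        counts = onehot.sum(axis=0)
        means = (V @ onehot) / counts
        grand = V.mean(axis=1, keepdims=True)
        return np.sum(counts * (means - grand) ** 2, axis=1)

    ss_a = group_ss(a, na)
    ss_b = group_ss(b, nb)
    ss_cells = group_ss(cell, ncell)
    ss_ab = ss_cells - ss_a - ss_b
    grand = V.mean(axis=1, keepdims=True)
    ss_tot = np.sum((V - grand) ** 2, axis=1)
    ss_res = np.maximum(ss_tot - ss_cells, 0.0)

    df = {"factor_a": na - 1, "factor_b": nb - 1,
          "interaction": (na - 1) * (nb - 1)}
    df_res = n - ncell
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom (need >=2 replicates per cell)")
    ms_res = ss_res / df_res
    out = {}
    for term, ss in (("factor_a", ss_a), ("factor_b", ss_b), ("interaction", ss_ab)):
        ms = np.maximum(ss, 0.0) / df[term]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(ms_res > 0, ms / ms_res,
                         np.where(ms > 0, np.inf, 0.0))
        out[term] = F
    return out


def two_way_anova(values, factor_a, factor_b) -> dict[str, AnovaResult]:
    """Classical two-way ANOVA with interaction; F and F-distribution p.

    All-equal responses make every F a 0/0; these are returned as 0 with
    the degenerate flag set.
    """
    y = np.asarray(values, dtype=float)
    a, na = _codes(factor_a)
    b, nb = _codes(factor_b)
    if na < 2 or nb < 2:
        raise ValueError("each factor needs at least two levels")
    fs = _f_stacked(y[None, :], a, na, b, nb)
    n = len(y)
    df_res = n - na * nb
    degenerate = bool(np.ptp(y) == 0)
    results = {}
    dfs = {"factor_a": na - 1, "factor_b": nb - 1, "interaction": (na - 1) * (nb - 1)}
    for term in TERMS:
        F = float(fs[term][0])
        if degenerate:
            F, p = 0.0, 1.0
        elif math.isinf(F):
            p = 0.0
        else:
            p = float(sps.f.sf(F, dfs[term], df_res))
        results[term] = AnovaResult(
            term=term, F=F, p_classical=p, p_exact=math.nan,
            n_perm=0, seed=None, enumerated=False, degenerate=degenerate,
        )
    return results


def _stratified_arrangements(codes: np.ndarray, strata: np.ndarray):
    """All distinct within-stratum arrangements of ``codes`` (generator),
    and their count."""
    stratum_ids = np.unique(strata)
    idx_by_stratum = [np.flatnonzero(strata == s) for s in stratum_ids]
    per = [list(_multiset_permutations(list(codes[idx]))) for idx in idx_by_stratum]
    total = int(np.prod([len(p) for p in per]))

    def gen():
        for combo in itertools.product(*per):
            perm = codes.copy()
            for idx, arrangement in zip(idx_by_stratum, combo):
                perm[idx] = arrangement
            yield perm

    return gen(), total


def _count_stratified(codes: np.ndarray, strata: np.ndarray) -> int:
    total = 1
    for s in np.unique(strata):
        vals = codes[strata == s]
        _, counts = np.unique(vals, return_counts=True)
        total *= math.factorial(len(vals)) // math.prod(
            math.factorial(int(c)) for c in counts)
    return total


def _arrangement_to_y(
    y: np.ndarray, tested: np.ndarray, arrangement: np.ndarray, other: np.ndarray
) -> np.ndarray:
    """Response vector equivalent to relabelling ``tested`` as ``arrangement``.

    Relabelling the tested factor within strata is equivalent to permuting
    the responses within strata (the design stays fixed, which lets the F
    statistics vectorise across permutations).
    """
    out = np.empty_like(y)
    for s in np.unique(other):
        in_s = other == s
        for lev in np.unique(tested[in_s]):
            src = np.flatnonzero(in_s & (tested == lev))
            dst = np.flatnonzero(in_s & (arrangement == lev))
            out[src] = y[dst]
    return out


def _perm_main(
    y: np.ndarray, tested: np.ndarray, n_tested: int,
    other: np.ndarray, n_other: int, which: str,
    n_perm: int, rng: np.random.Generator, max_enum: int,
) -> tuple[float, int, bool]:
    """Restricted-permutation p for one main effect (labels permuted within
    levels of the other factor)."""
    if which == "factor_a":
        def f_stack(Y):
            return _f_stacked(Y, tested, n_tested, other, n_other)["factor_a"]
    else:
        def f_stack(Y):
            return _f_stacked(Y, other, n_other, tested, n_tested)["factor_b"]

    total = _count_stratified(tested, other)
    if total <= max_enum:
        gen, total = _stratified_arrangements(tested, other)
        Y = np.array([_arrangement_to_y(y, tested, arr, other) for arr in gen])
    else:
        Y = np.tile(y, (n_perm, 1))
        for idx in (np.flatnonzero(other == s) for s in np.unique(other)):
            order = np.argsort(rng.random((n_perm, len(idx))), axis=1)
            Y[:, idx] = y[idx][order]
    # observed statistic evaluated inside the same stacked call so the
    # identity arrangement compares bit-identically
    fs = f_stack(np.vstack([Y, y]))
    f_perm, f_obs = fs[:-1], fs[-1]
    count = int(np.sum(f_perm >= f_obs - _tie_tol(f_obs)))
    if total <= max_enum:
        return count / total, total, True
    return (1 + count) / (1 + n_perm), n_perm, False


def _perm_interaction(
    y: np.ndarray, a: np.ndarray, na: int, b: np.ndarray, nb: int,
    n_perm: int, rng: np.random.Generator, max_enum: int,
) -> tuple[float, int, bool]:
    """Residual-permutation p for the interaction term."""
    n = len(y)
    X = np.column_stack([
        np.ones(n),
        *(np.eye(na)[a][:, 1:].T),
        *(np.eye(nb)[b][:, 1:].T),
    ])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted

    n_total = math.factorial(n)
    if n_total <= max_enum:
        perms = np.array(list(itertools.permutations(range(n))))
        enumerated = True
        total = len(perms)
    else:
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        enumerated = False
        total = n_perm
    Y = fitted[None, :] + resid[perms]
    fs = _f_stacked(np.vstack([Y, y]), a, na, b, nb)["interaction"]
    f_perm, f_obs = fs[:-1], fs[-1]
    count = int(np.sum(f_perm >= f_obs - _tie_tol(f_obs)))
    if enumerated:
        return count / total, total, True
    return (1 + count) / (1 + n_perm), n_perm, False


def permutation_anova(
    values, factor_a, factor_b,
    n_perm: int = 5000,
    seed: int = 0,
    max_enumeration: int = MAX_ENUMERATION,
) -> dict[str, AnovaResult]:
    """Permutation two-way ANOVA: classical F, exact/sampled permutation p.

    Reproducible under a fixed seed; full enumeration replaces sampling
    whenever the arrangement count is at most ``max_enumeration``.
    """
    y = np.asarray(values, dtype=float)
    a, na = _codes(factor_a)
    b, nb = _codes(factor_b)
    classical = two_way_anova(y, factor_a, factor_b)
    if classical["factor_a"].degenerate:
        return {
            t: AnovaResult(t, 0.0, 1.0, 1.0, 0, seed, False, degenerate=True)
            for t in TERMS
        }
    rng = np.random.default_rng(seed)
    p_a, n_a, enum_a = _perm_main(y, a, na, b, nb, "factor_a", n_perm, rng, max_enumeration)
    p_b, n_b, enum_b = _perm_main(y, b, nb, a, na, "factor_b", n_perm, rng, max_enumeration)
    p_ab, n_ab, enum_ab = _perm_interaction(y, a, na, b, nb, n_perm, rng, max_enumeration)
    packed = {
        "factor_a": (p_a, n_a, enum_a),
        "factor_b": (p_b, n_b, enum_b),
        "interaction": (p_ab, n_ab, enum_ab),
    }
    return {
        term: AnovaResult(
            term=term, F=classical[term].F, p_classical=classical[term].p_classical,
            p_exact=p, n_perm=np_used, seed=seed, enumerated=enum,
        )
        for term, (p, np_used, enum) in packed.items()
    }
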