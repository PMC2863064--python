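"""Contingency tables and the G² (conditional) independence test.

The G² statistic is the likelihood-ratio test of independence for
discrete variables,

    G² = 2 Σ_i O_i ln(O_i / E_i),

asymptotically chi-square. Expected counts come from the margins of the
observed table: ``E_ij = row_i * col_j / N`` unconditionally, and the
same formula within each stratum of the conditioning variables when a
conditioning set is supplied. Degrees of freedom are

    df = (Cat(A) − 1)(Cat(B) − 1) · ∏_i Cat(C_i),

reduced by the number of empty cells in the observed table and floored
at zero. Category counts use the variables' theoretical ranges (three
genotypes for a SNP, two classes for the disease status), so that
structurally absent categories appear as empty rows/columns and the
empty-cell reduction is well defined.

A test with no degrees of freedom left, or with fewer than
``reliability_factor`` samples per table cell, is flagged unreliable and
never asserts dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset import MISSING, CaseControlDataset

#: Minimum average samples per cell for a test to be considered reliable;
#: the usual heuristic in constraint-based structure learning.
DEFAULT_RELIABILITY_FACTOR = 5.0


@dataclass
class ContingencyCounts:
    """Observed cell counts for (var_a, var_b) within conditioning strata.

    ``counts`` has shape ``(Cat(A), Cat(B), n_strata)`` where
    ``n_strata = ∏ Cat(C_i)`` (a single stratum when the conditioning
    set is empty). Strata are indexed by the mixed-radix code of the
    conditioning variables' values, first conditioning variable most
    significant.
    """

    counts: np.ndarray
    var_a: str
    var_b: str
    cond_vars: list[str]
    cond_cards: list[int]
    n_total: int

    @property
    def n_cells(self) -> int:
        return int(self.counts.size)

    @property
    def n_strata(self) -> int:
        return int(self.counts.shape[2])

    @property
    def n_empty_cells(self) -> int:
        return int((self.counts == 0).sum())


@dataclass
class G2TestResult:
    """Outcome of one G² (conditional) independence test."""

    statistic: float
    df: int
    p_value: float
    dependent: bool
    reliable: bool
    n_empty_cells: int

    def __str__(self) -> str:  # compact form for traces
        return (
            f"G2={self.statistic:.4f} df={self.df} p={self.p_value:.3g}"
            f"{'' if self.reliable else ' (unreliable)'}"
        )


def build_counts(
    data: CaseControlDataset,
    var_a: str,
    var_b: str,
    cond_vars: Sequence[str] = (),
) -> ContingencyCounts:
    """Tabulate joint counts of ``var_a`` × ``var_b`` per conditioning stratum.

    Only samples with no missing value in any involved variable are
    counted (complete-case deletion per test). Category axes span the
    variables' full theoretical ranges, so unobserved categories produce
    empty rows/columns rather than shrinking the table.
    """
    if var_a == var_b:
        raise ValueError("var_a and var_b must differ")
    cond_vars = list(cond_vars)
    if var_a in cond_vars or var_b in cond_vars:
        raise ValueError("a test variable may not appear in the conditioning set")

    a_vals, card_a = data.variable(var_a)
    b_vals, card_b = data.variable(var_b)
    cond_cols, cond_cards = [], []
    for c in cond_vars:
        vals, card = data.variable(c)
        cond_cols.append(vals)
        cond_cards.append(card)

    mask = (a_vals != MISSING) & (b_vals != MISSING)
    for vals in cond_cols:
        mask &= vals != MISSING
    a = a_vals[mask].astype(np.int64)
    b = b_vals[mask].astype(np.int64)

    n_strata = int(np.prod(cond_cards)) if cond_cards else 1
    stratum = np.zeros(a.shape[0], dtype=np.int64)
    for vals, card in zip(cond_cols, cond_cards):
        stratum = stratum * card + vals[mask].astype(np.int64)

    code = (a * card_b + b) * n_strata + stratum
    flat = np.bincount(code, minlength=card_a * card_b * n_strata)
    counts = flat.reshape(card_a, card_b, n_strata)
    return ContingencyCounts(
        counts=counts,
        var_a=var_a,
        var_b=var_b,
        cond_vars=cond_vars,
        cond_cards=cond_cards,
        n_total=int(counts.sum()),
    )


def expected_counts(obs: ContingencyCounts) -> np.ndarray:
    """Expected cell counts under (conditional) independence.

    Within each stratum k: ``E_ijk = row_ik * col_jk / N_k`` from that
    stratum's margins; a stratum with no observations gets expectation 0
    everywhere.
    """
    counts = obs.counts.astype(float)
    row = counts.sum(axis=1, keepdims=True)  # (A, 1, K)
    col = counts.sum(axis=0, keepdims=True)  # (1, B, K)
    tot = counts.sum(axis=(0, 1), keepdims=True)  # (1, 1, K)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = np.where(tot > 0, row * col / np.where(tot > 0, tot, 1.0), 0.0)
    return expected


def g2_statistic(obs: ContingencyCounts) -> float:
    """The G² statistic ``2 Σ O ln(O/E)``; terms with O = 0 contribute 0."""
    o = obs.counts.astype(float)
    e = expected_counts(obs)
    pos = o > 0  # O > 0 forces E > 0 given margin-based expectations
    return float(2.0 * np.sum(o[pos] * np.log(o[pos] / e[pos])))


def degrees_of_freedom(obs: ContingencyCounts) -> int:
    """Degrees of freedom: base df minus the number of empty observed cells.

    Base df is ``(Cat(A)−1)(Cat(B)−1)`` unconditionally, multiplied by
    ``∏ Cat(C_i)`` under conditioning; the result is floored at 0.
    """
    card_a, card_b, n_strata = obs.counts.shape
    base = (card_a - 1) * (card_b - 1) * n_strata
    return max(base - obs.n_empty_cells, 0)


def g2_test_from_counts(
    obs: ContingencyCounts,
    alpha: float,
    reliability_factor: float = DEFAULT_RELIABILITY_FACTOR,
) -> G2TestResult:
    """Run the G² test on a pre-built contingency table."""
    statistic = g2_statistic(obs)
    df = degrees_of_freedom(obs)
    reliable = df >= 1 and obs.n_total >= reliability_factor * obs.n_cells
    if not reliable:
        return G2TestResult(
            statistic=statistic,
            df=df,
            p_value=1.0,
            dependent=False,
            reliable=False,
            n_empty_cells=obs.n_empty_cells,
        )
    p_value = float(stats.chi2.sf(statistic, df))
    return G2TestResult(
        statistic=statistic,
        df=df,
        p_value=p_value,
        dependent=bool(p_value < alpha),
        reliable=True,
        n_empty_cells=obs.n_empty_cells,
    )


def g2_test(
    data: CaseControlDataset,
    var_a: str,
    var_b: str,
    cond_vars: Sequence[str] = (),
    alpha: float = 0.05,
    reliability_factor: float = DEFAULT_RELIABILITY_FACTOR,
) -> G2TestResult:
    """G² (conditional) independence test of ``var_a`` vs ``var_b``.

    The null hypothesis is that the two variables are independent
    (given ``cond_vars``). An unreliable test — no degrees of freedom
    left after the empty-cell reduction, or too few samples per cell —
    reports ``p_value = 1.0`` and never asserts dependence.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    obs = build_counts(data, var_a, var_b, cond_vars)
    return g2_test_from_counts(obs, alpha, reliability_factor)


def counts_from_array(
    table: np.ndarray,
    var_a: str = "A",
    var_b: str = "B",
    cond_cards: Sequence[int] = (),
) -> ContingencyCounts:
    """Wrap a raw count array as :class:`ContingencyCounts`.

    ``table`` may be 2-d ``(Cat(A), Cat(B))`` for an unconditional table
    or 3-d ``(Cat(A), Cat(B), n_strata)``; a 3-d table requires
    ``cond_cards`` whose product equals ``n_strata``.
    """
    arr = np.asarray(table)
    if arr.ndim == 2:
        arr = arr[:, :, None]
        cond_cards = []
    elif arr.ndim != 3:
        raise ValueError("table must be 2-d or 3-d")
    cond_cards = list(cond_cards)
    n_strata = int(np.prod(cond_cards)) if cond_cards else 1
    if arr.shape[2] != n_strata:
        raise ValueError("product of cond_cards must equal the stratum count")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return ContingencyCounts(
        counts=arr.astype(np.int64),
        var_a=var_a,
        var_b=var_b,
        cond_vars=[f"C{i}" for i in range(len(cond_cards))],
        cond_cards=cond_cards,
        n_total=int(arr.sum()),
    )
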