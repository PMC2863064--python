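"""Pre-detection quality-control filters.

Three filters are applied in a fixed order, each seeing the survivors of
the previous one: (1) non-polymorphic SNPs, (2) SNPs with too many
missing genotypes, (3) SNPs out of Hardy-Weinberg equilibrium in the
controls. A SNP is attributed to the first rule that removes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import MISSING, CaseControlDataset, DataError

#: Default missing-genotype tolerance: a SNP with MORE than this many
#: missing calls is removed (strict inequality).
DEFAULT_MAX_MISSING = 5

#: Default HWE significance threshold (controls-only chi-square test).
DEFAULT_HWE_ALPHA = 1e-6


@dataclass
class QCReport:
    """Which SNPs each QC rule removed, and how many survived."""

    removed_nonpolymorphic: list[str] = field(default_factory=list)
    removed_missingness: list[str] = field(default_factory=list)
    removed_hwe: list[str] = field(default_factory=list)
    n_retained: int = 0

    @property
    def n_removed(self) -> int:
        return (
            len(self.removed_nonpolymorphic)
            + len(self.removed_missingness)
            + len(self.removed_hwe)
        )


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Chi-square goodness-of-fit p-value for Hardy-Weinberg equilibrium.

    Observed genotype counts are compared to the HWE expectations
    ``N*(p^2, 2pq, q^2)`` computed from the sample allele frequency, with
    1 degree of freedom (3 cells − 1 − 1 estimated allele frequency).
    Monomorphic input (an allele frequency of 0 or 1) returns 1.0 by
    convention.

    Examples
    --------
    >>> hwe_test(25, 50, 25)
    1.0
    >>> hwe_test(50, 0, 50) < 1e-20
    True
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be nonnegative")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    p = (2 * counts[0] + counts[1]) / (2 * n)  # frequency of allele A
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    statistic = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(statistic, df=1))


def qc_filter(
    dataset: CaseControlDataset,
    max_missing: int = DEFAULT_MAX_MISSING,
    hwe_alpha: float = DEFAULT_HWE_ALPHA,
) -> tuple[CaseControlDataset, QCReport]:
    """Apply the three QC rules and return (filtered dataset, report).

    Rules, in order, each applied to the survivors of the previous one:

    1. non-polymorphic: at most one distinct genotype among non-missing
       calls (an all-missing column counts as non-polymorphic);
    2. missingness: strictly more than ``max_missing`` missing calls;
    3. HWE: :func:`hwe_test` p-value below ``hwe_alpha``, computed on the
       control samples only.

    Retained genotype values are never altered; only columns are dropped.
    Raises :class:`~dassomb.dataset.DataError` if nothing survives.
    """
    report = QCReport()
    g = dataset.genotypes
    controls = dataset.phenotype == 0
    survivors: list[str] = []
    for j, snp in enumerate(dataset.snp_ids):
        col = g[:, j]
        observed = col[col != MISSING]
        if np.unique(observed).size <= 1:
            report.removed_nonpolymorphic.append(snp)
            continue
        if int((col == MISSING).sum()) > max_missing:
            report.removed_missingness.append(snp)
            continue
        ctrl = col[controls]
        ctrl = ctrl[ctrl != MISSING]
        if ctrl.size >= 1:
            n_hom_major = int((ctrl == 0).sum())
            n_het = int((ctrl == 1).sum())
            n_hom_minor = int((ctrl == 2).sum())
            if hwe_test(n_hom_major, n_het, n_hom_minor) < hwe_alpha:
                report.removed_hwe.append(snp)
                continue
        survivors.append(snp)
    report.n_retained = len(survivors)
    if not survivors:
        raise DataError("QC removed every SNP; nothing left to analyze")
    return dataset.select_snps(survivors), report
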