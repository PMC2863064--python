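"""Case-control genotype data model.

Genotypes are coded as minor-allele counts 0/1/2; a missing call is the
sentinel :data:`MISSING` (-1). The disease status (phenotype) is binary:
0 = control, 1 = case. The phenotype is addressed in tests by the
reserved variable id :data:`TARGET`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing genotype call.
MISSING: int = -1

#: Reserved variable id for the disease-status target variable.
TARGET: str = "T"

#: Legal genotype codes (besides MISSING).
GENOTYPE_CODES = (0, 1, 2)

#: Number of genotype categories of a SNP (theoretical range {0,1,2}).
N_GENOTYPE_CATEGORIES = 3

#: Number of phenotype categories (control/case).
N_PHENOTYPE_CATEGORIES = 2


class DataError(ValueError):
    """A dataset violates a structural or coding invariant."""


@dataclass
class CaseControlDataset:
    """Genotype matrix plus binary disease status.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_snps)`` integer matrix with entries in
        ``{0, 1, 2, MISSING}``.
    phenotype
        Length ``n_samples`` vector with entries in ``{0, 1}``.
    snp_ids
        Unique identifiers, one per genotype column.
    sample_ids
        Unique identifiers, one per genotype row.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    _snp_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.snp_ids = list(self.snp_ids)
        self.sample_ids = list(self.sample_ids)
        self.validate()
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`DataError` on any invariant violation."""
        g, y = self.genotypes, self.phenotype
        if g.ndim != 2:
            raise DataError("genotypes must be a 2-d matrix")
        n, m = g.shape
        if y.shape != (n,):
            raise DataError(
                f"phenotype length {y.shape} does not match {n} genotype rows"
            )
        if len(self.snp_ids) != m:
            raise DataError(f"{len(self.snp_ids)} snp_ids for {m} columns")
        if len(self.sample_ids) != n:
            raise DataError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(set(self.snp_ids)) != m:
            raise DataError("snp_ids are not unique")
        if len(set(self.sample_ids)) != n:
            raise DataError("sample_ids are not unique")
        bad = ~np.isin(g, (*GENOTYPE_CODES, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"illegal genotype code {int(g[i, j])} at sample "
                f"{self.sample_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )
        if not np.isin(y, (0, 1)).all():
            raise DataError("phenotype entries must be 0 (control) or 1 (case)")

    def require_both_classes(self) -> None:
        """Raise unless at least one case and one control are present."""
        if not (np.any(self.phenotype == 0) and np.any(self.phenotype == 1)):
            raise DataError("need at least one case and one control")

    # -- accessors -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def snp_column(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def variable(self, var_id: str) -> tuple[np.ndarray, int]:
        """Return (values, number of categories) for a variable id.

        ``TARGET`` maps to the phenotype (2 categories); any SNP id maps
        to its genotype column (3 categories, theoretical range).
        """
        if var_id == TARGET:
            return self.phenotype, N_PHENOTYPE_CATEGORIES
        return (
            self.genotypes[:, self.snp_column(var_id)],
            N_GENOTYPE_CATEGORIES,
        )

    def select_snps(self, keep: list[str]) -> "CaseControlDataset":
        """Dataset restricted to the SNP columns in ``keep`` (order kept)."""
        cols = [self.snp_column(s) for s in keep]
        return CaseControlDataset(
            genotypes=self.genotypes[:, cols].copy(),
            phenotype=self.phenotype.copy(),
            snp_ids=list(keep),
            sample_ids=list(self.sample_ids),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CaseControlDataset):
            return NotImplemented
        return (
            self.snp_ids == other.snp_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
        )
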