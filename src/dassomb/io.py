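"""Readers and writers for case-control genotype files.

Two dialects are supported:

``tabular``
    UTF-8, tab-separated; header ``sample_id<TAB>phenotype<TAB><snp ids...>``;
    genotypes 0/1/2, missing ``NA``; phenotype 0/1.

``pedmap``
    PLINK-style ``.ped`` (FID IID PAT MAT SEX PHENO + one allele pair per
    SNP) with a companion ``.map`` (chrom, snp id, cM, bp). Biallelic SNPs
    only; ``0 0`` is a missing genotype; phenotype 1 = control, 2 = case.
    On read, allele pairs are recoded to minor-allele counts, the minor
    allele being the rarer one in the file's pooled allele counts (ties
    broken lexicographically).
"""

from __future__ import annotations

import os
from collections import Counter
from pathlib import Path

import numpy as np

from .dataset import MISSING, CaseControlDataset, DataError

FORMATS = ("tabular", "pedmap")


class ParseError(ValueError):
    """A file does not parse under the named dialect."""


def read_dataset(path: str | os.PathLike, format: str = "tabular") -> CaseControlDataset:
    """Read a :class:`CaseControlDataset` from ``path``.

    For ``pedmap``, ``path`` is the ``.ped`` file; the ``.map`` file is
    found by swapping the extension.
    """
    _check_format(format)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular":
        return _read_tabular(path)
    return _read_pedmap(path)


def write_dataset(
    dataset: CaseControlDataset, path: str | os.PathLike, format: str = "tabular"
) -> None:
    """Write ``dataset`` to ``path`` in the named dialect.

    Round-trips with :func:`read_dataset` (for ``pedmap``, up to
    allele-letter labeling, and exactly in genotype codes as long as the
    coded minor allele is no more frequent than the major one).
    """
    _check_format(format)
    if dataset.n_snps == 0:
        raise DataError("refusing to write a dataset with no SNPs")
    path = Path(path)
    if format == "tabular":
        _write_tabular(dataset, path)
    else:
        _write_pedmap(dataset, path)


def _check_format(format: str) -> None:
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


# -- tabular dialect -------------------------------------------------------

_GENO_TOKENS = {"0": 0, "1": 1, "2": 2, "NA": MISSING}


def _read_tabular(path: Path) -> CaseControlDataset:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 3 or cols[0] != "sample_id" or cols[1] != "phenotype":
            raise ParseError(
                f"{path}:1: expected header 'sample_id\\tphenotype\\t<snp ids>'"
            )
        snp_ids = cols[2:]
        sample_ids: list[str] = []
        phenos: list[int] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise ParseError(
                    f"{path}:{lineno}: {len(fields)} fields, expected {len(cols)}"
                )
            sample_ids.append(fields[0])
            if fields[1] not in ("0", "1"):
                raise DataError(
                    f"{path}:{lineno}: unknown phenotype code {fields[1]!r}"
                )
            phenos.append(int(fields[1]))
            try:
                rows.append([_GENO_TOKENS[t] for t in fields[2:]])
            except KeyError as exc:
                raise DataError(
                    f"{path}:{lineno}: illegal genotype token {exc.args[0]!r}"
                ) from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return CaseControlDataset(
        genotypes=np.array(rows, dtype=np.int8),
        phenotype=np.array(phenos, dtype=np.int8),
        snp_ids=snp_ids,
        sample_ids=sample_ids,
    )


def _write_tabular(dataset: CaseControlDataset, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tphenotype\t" + "\t".join(dataset.snp_ids) + "\n")
        for i, sid in enumerate(dataset.sample_ids):
            genos = (
                "NA" if g == MISSING else str(int(g))
                for g in dataset.genotypes[i]
            )
            fh.write(
                f"{sid}\t{int(dataset.phenotype[i])}\t" + "\t".join(genos) + "\n"
            )


# -- pedmap dialect --------------------------------------------------------

# Letters used when writing: minor (code-2) allele first so that equal
# pooled frequencies resolve back to the same coding on read.
_MINOR_LETTER, _MAJOR_LETTER = "A", "G"


def _map_path(ped_path: Path) -> Path:
    return ped_path.with_suffix(".map")


def _read_pedmap(ped_path: Path) -> CaseControlDataset:
    map_path = _map_path(ped_path)
    if not map_path.exists():
        raise FileNotFoundError(map_path)
    snp_ids: list[str] = []
    with open(map_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 fields")
            snp_ids.append(fields[1])
    n_snps = len(snp_ids)
    if n_snps == 0:
        raise ParseError(f"{map_path}: no SNPs")

    sample_ids: list[str] = []
    phenos: list[int] = []
    allele_rows: list[list[str]] = []
    with open(ped_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped_path}:{lineno}: {len(fields)} fields, expected "
                    f"{6 + 2 * n_snps} for {n_snps} SNPs"
                )
            sample_ids.append(fields[1])
            if fields[5] == "1":
                phenos.append(0)
            elif fields[5] == "2":
                phenos.append(1)
            else:
                raise DataError(
                    f"{ped_path}:{lineno}: unknown phenotype code {fields[5]!r}"
                )
            allele_rows.append(fields[6:])
    if not allele_rows:
        raise ParseError(f"{ped_path}: no data rows")

    n = len(allele_rows)
    genotypes = np.full((n, n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        pooled: Counter[str] = Counter()
        pairs = [(row[2 * j], row[2 * j + 1]) for row in allele_rows]
        for a1, a2 in pairs:
            if (a1 == "0") != (a2 == "0"):
                raise DataError(
                    f"{ped_path}: half-missing genotype for SNP {snp_ids[j]!r}"
                )
            if a1 != "0":
                pooled[a1] += 1
                pooled[a2] += 1
        alleles = sorted(pooled)
        if len(alleles) > 2:
            raise DataError(
                f"{ped_path}: SNP {snp_ids[j]!r} has more than two alleles"
            )
        if not alleles:
            continue  # all missing; column stays MISSING
        # Minor allele: rarer in pooled counts; lexicographic on tie.
        minor = min(alleles, key=lambda a: (pooled[a], a))
        for i, (a1, a2) in enumerate(pairs):
            if a1 == "0":
                continue
            genotypes[i, j] = (a1 == minor) + (a2 == minor)
    return CaseControlDataset(
        genotypes=genotypes,
        phenotype=np.array(phenos, dtype=np.int8),
        snp_ids=snp_ids,
        sample_ids=sample_ids,
    )


def _write_pedmap(dataset: CaseControlDataset, ped_path: Path) -> None:
    with open(_map_path(ped_path), "w", encoding="utf-8") as fh:
        for j, snp in enumerate(dataset.snp_ids):
            fh.write(f"1 {snp} 0 {j + 1}\n")
    pair = {
        MISSING: "0 0",
        0: f"{_MAJOR_LETTER} {_MAJOR_LETTER}",
        1: f"{_MINOR_LETTER} {_MAJOR_LETTER}",
        2: f"{_MINOR_LETTER} {_MINOR_LETTER}",
    }
    with open(ped_path, "w", encoding="utf-8") as fh:
        for i, sid in enumerate(dataset.sample_ids):
            pheno = 2 if dataset.phenotype[i] == 1 else 1
            alleles = " ".join(pair[int(g)] for g in dataset.genotypes[i])
            fh.write(f"{sid} {sid} 0 0 0 {pheno} {alleles}\n")
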