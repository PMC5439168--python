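"""SNP genotype container, quality control, and VanRaden scaling.

Genotypes are biallelic dosage codes 0/1/2 (count of the allele whose
homozygote is coded 2), with -1 for a missing call.  QC mirrors the usual
PLINK-style sequence: call rate, Hardy-Weinberg equilibrium, then minor
allele frequency, applied in that order so each filter's removal count refers
to the panel surviving the previous one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "SnpQcReport",
    "ScaledGenotypes",
    "allele_frequencies",
    "qc_snps",
    "scale_genotypes",
    "hwe_pvalues",
    "read_genotypes",
    "EmptyPanelWarning",
]


class EmptyPanelWarning(UserWarning):
    """All SNPs were removed by quality control."""


@dataclass
class GenotypeMatrix:
    """Animals x SNPs integer dosage codes with missingness.

    ``codes[i, j]`` is 0, 1 or 2 (copies of the allele coded 2 carried by
    animal ``i`` at SNP ``j``) or ``MISSING`` (-1).
    """

    animal_ids: list[str]
    snp_ids: list[str]
    codes: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.snp_ids)} SNPs"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.codes[i, j]} for animal "
                f"{self.animal_ids[i]!r} at SNP {self.snp_ids[j]!r}"
            )
        self._index = {a: i for i, a in enumerate(self.animal_ids)}

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset_animals(self, animals) -> "GenotypeMatrix":
        rows = [self._index[a] for a in animals]
        return GenotypeMatrix(list(animals), list(self.snp_ids), self.codes[rows])

    def subset_snps(self, keep_mask: np.ndarray) -> "GenotypeMatrix":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return GenotypeMatrix(
            list(self.animal_ids),
            [s for s, k in zip(self.snp_ids, keep_mask) if k],
            self.codes[:, keep_mask],
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.codes, index=self.animal_ids, columns=self.snp_ids)
        df = df.replace(MISSING, pd.NA)
        df.to_csv(path, index_label="animal", na_rep="NA")


@dataclass
class SnpQcReport:
    """Sequential filter accounting for one QC run."""

    n_input: int
    n_removed_callrate: int
    n_removed_hwe: int
    n_removed_maf: int
    surviving_snp_ids: list[str]
    thresholds: tuple[float, float, float]  # (call_rate_min, hwe_p_cutoff, maf_min)

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_snp_ids)

    def __post_init__(self) -> None:
        removed = self.n_removed_callrate + self.n_removed_hwe + self.n_removed_maf
        assert self.n_input == removed + self.n_surviving


@dataclass
class ScaledGenotypes:
    """Column-standardised genotypes W with w_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j))."""

    values: np.ndarray  # animals x SNPs, real
    freqs: np.ndarray  # p_j of the allele coded 2
    animal_ids: list[str]
    snp_ids: list[str]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


def allele_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-SNP frequency of the allele coded 2, from non-missing calls.

    p_j = (sum of codes over non-missing animals) / (2 x non-missing count).
    """
    codes = genotypes.codes
    observed = codes != MISSING
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.argmax(n_obs == 0))
        raise ValueError(
            f"SNP {genotypes.snp_ids[j]!r} has no non-missing calls"
        )
    total = np.where(observed, codes, 0).sum(axis=0)
    return total / (2.0 * n_obs)


def hwe_pvalues(genotypes: GenotypeMatrix) -> np.ndarray:
    """Chi-square (1 df) goodness-of-fit P-values against Hardy-Weinberg
    genotype proportions, computed from non-missing calls per SNP.

    Monomorphic SNPs fit HWE exactly and get P = 1.
    """
    codes = genotypes.codes
    observed = codes != MISSING
    n = observed.sum(axis=0).astype(float)
    n0 = ((codes == 0) & observed).sum(axis=0).astype(float)
    n1 = ((codes == 1) & observed).sum(axis=0).astype(float)
    n2 = ((codes == 2) & observed).sum(axis=0).astype(float)
    p = np.where(n > 0, (n1 + 2 * n2) / (2 * np.maximum(n, 1)), 0.0)
    q = 1.0 - p
    exp = np.stack([n * q**2, n * 2 * p * q, n * p**2])
    obs = np.stack([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
    pvals = stats.chi2.sf(chi2, df=1)
    poly = (p > 0) & (p < 1)
    return np.where(poly, pvals, 1.0)


def qc_snps(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.90,
    hwe_p_cutoff: float = 1e-15,
    maf_min: float = 0.01,
) -> tuple[GenotypeMatrix, SnpQcReport]:
    """Remove SNPs by call rate, then HWE deviation, then minor allele frequency.

    Filters are applied sequentially, each on the survivors of the previous
    stage, and the report counts removals at each stage.  Running QC on its
    own output is a no-op (idempotence).
    """
    if genotypes.n_animals < 1 or genotypes.n_snps < 1:
        raise ValueError("QC needs at least one animal and one SNP")

    codes = genotypes.codes
    call_rate = (codes != MISSING).mean(axis=0)
    pass_cr = call_rate >= call_rate_min
    n_cr = int((~pass_cr).sum())

    stage = genotypes.subset_snps(pass_cr)
    if stage.n_snps:
        pass_hwe = hwe_pvalues(stage) > hwe_p_cutoff
    else:
        pass_hwe = np.zeros(0, dtype=bool)
    n_hwe = int((~pass_hwe).sum())

    stage = stage.subset_snps(pass_hwe)
    if stage.n_snps:
        p = allele_frequencies(stage)
        maf = np.minimum(p, 1.0 - p)
        pass_maf = maf >= maf_min
    else:
        pass_maf = np.zeros(0, dtype=bool)
    n_maf = int((~pass_maf).sum())

    out = stage.subset_snps(pass_maf)
    if out.n_snps == 0:
        warnings.warn(
            "all SNPs removed by quality control", EmptyPanelWarning, stacklevel=2
        )
    report = SnpQcReport(
        n_input=genotypes.n_snps,
        n_removed_callrate=n_cr,
        n_removed_hwe=n_hwe,
        n_removed_maf=n_maf,
        surviving_snp_ids=list(out.snp_ids),
        thresholds=(call_rate_min, hwe_p_cutoff, maf_min),
    )
    return out, report


def scale_genotypes(
    genotypes: GenotypeMatrix, freqs: np.ndarray | None = None
) -> ScaledGenotypes:
    """Centre and scale dosages: w_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)).

    Missing codes are imputed with the column mean 2 p_j, i.e. a scaled value
    of exactly zero, which preserves zero column means.
    """
    if freqs is None:
        freqs = allele_frequencies(genotypes)
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs <= 0) | (freqs >= 1)).any():
        j = int(np.argmax((freqs <= 0) | (freqs >= 1)))
        raise ValueError(
            f"SNP {genotypes.snp_ids[j]!r} is fixed (p={freqs[j]}); "
            "run qc_snps before scaling"
        )
    codes = genotypes.codes.astype(float)
    x = np.where(genotypes.codes == MISSING, 2.0 * freqs, codes)
    w = (x - 2.0 * freqs) / np.sqrt(2.0 * freqs * (1.0 - freqs))
    return ScaledGenotypes(
        values=w,
        freqs=freqs,
        animal_ids=list(genotypes.animal_ids),
        snp_ids=list(genotypes.snp_ids),
    )


# -- readers ---------------------------------------------------------------


def read_genotypes(path) -> GenotypeMatrix:
    """Read genotypes; format picked by extension.

    ``.csv``/``.tsv``
        animals x SNPs table, first column animal id, NA = missing.
    ``.ped`` (with a sibling ``.map``)
        PLINK text pedigree format; the dosage is the count of the
        lexicographically larger allele observed at each SNP, "0 0" = missing.
    """
    path = str(path)
    if path.endswith((".csv", ".tsv")):
        sep = "\t" if path.endswith(".tsv") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        codes = df.to_numpy(dtype=float)
        codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
        return GenotypeMatrix(
            [str(a) for a in df.index], [str(s) for s in df.columns], codes
        )
    if path.endswith(".ped"):
        return _read_plink_ped(path)
    raise ValueError(f"unrecognised genotype file extension: {path}")


def _read_plink_ped(ped_path: str) -> GenotypeMatrix:
    map_path = ped_path[:-4] + ".map"
    snp_ids = [line.split()[1] for line in open(map_path) if line.strip()]
    animals: list[str] = []
    pairs: list[np.ndarray] = []  # per animal: (n_snps, 2) allele strings
    for line in open(ped_path):
        parts = line.split()
        if not parts:
            continue
        animals.append(parts[1])
        alleles = np.array(parts[6:], dtype="U4").reshape(-1, 2)
        if len(alleles) != len(snp_ids):
            raise ValueError(
                f".ped row for {parts[1]!r} has {len(alleles)} SNPs, "
                f".map lists {len(snp_ids)}"
            )
        pairs.append(alleles)
    if not pairs:
        return GenotypeMatrix([], snp_ids, np.zeros((0, len(snp_ids)), dtype=np.int8))
    stacked = np.stack(pairs)  # animals x snps x 2
    codes = np.empty(stacked.shape[:2], dtype=np.int8)
    for j in range(len(snp_ids)):
        col = stacked[:, j, :]
        missing = (col == "0").any(axis=1)
        seen = sorted(set(col[~missing].ravel()))
        # dosage counts the lexicographically larger allele observed at the SNP
        ref = seen[-1] if seen else "0"
        codes[:, j] = np.where(missing, MISSING, (col == ref).sum(axis=1))
    return GenotypeMatrix(animals, snp_ids, codes)
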