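"""Case-control genotype datasets: containers, I/O and quality control.

Genotypes are coded by minor-allele count {0, 1, 2}; missing calls use the
sentinel :data:`MISSING` (-1).  Two plain-text formats are supported: a simple
tab-delimited layout (header row; columns ``sample_id``, ``phenotype``, then
one column per SNP, missing coded ``NA``) and PLINK ``.raw`` recoded output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "QCThresholds",
    "QCReport",
    "load_dataset",
    "write_dataset",
    "quality_control",
]

#: Sentinel for a missing genotype call.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})


class DataError(ValueError):
    """Malformed or invalid genotype data."""


@dataclass
class GenotypeDataset:
    """A samples x SNPs genotype matrix with a binary phenotype.

    Parameters
    ----------
    genotypes
        ``(N, M)`` integer array with entries in ``{0, 1, 2}`` or
        :data:`MISSING`.
    phenotype
        Length-``N`` vector, 0 = control, 1 = case.
    snp_ids, sample_ids
        Unique identifiers; generated (``snp0..``, ``s0..``) when omitted.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise DataError("genotypes must be a 2-D samples x SNPs matrix")
        n, m = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise DataError(
                f"phenotype length {self.phenotype.shape} does not match "
                f"{n} samples"
            )
        if not self.snp_ids:
            self.snp_ids = [f"snp{i}" for i in range(m)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.snp_ids) != m:
            raise DataError("snp_ids length does not match genotype columns")
        if len(self.sample_ids) != n:
            raise DataError("sample_ids length does not match genotype rows")
        if len(set(self.snp_ids)) != m:
            raise DataError("snp_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise DataError("sample_ids must be unique")
        bad = set(np.unique(self.genotypes)) - _VALID_CODES
        if bad:
            raise DataError(f"invalid genotype codes {sorted(bad)}")
        if not set(np.unique(self.phenotype)) <= {0, 1}:
            raise DataError("phenotype values must be 0 (control) or 1 (case)")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    @property
    def has_missing(self) -> bool:
        return bool((self.genotypes == MISSING).any())

    def require_cases_and_controls(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise DataError("analysis requires at least one case and one control")

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: sample_id, phenotype, one column per SNP (NA missing)."""
        df = pd.DataFrame(
            self.genotypes.astype(float), columns=self.snp_ids,
        )
        df[df == MISSING] = np.nan
        df.insert(0, "phenotype", self.phenotype.astype(int))
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass(frozen=True)
class QCThresholds:
    """Quality-control cutoffs; a unit fails on strict `<` comparison."""

    snp_call_rate_min: float = 0.95
    hwe_p_min: float = 1e-4
    maf_min: float = 0.1
    sample_call_rate_min: float = 0.98

    def __post_init__(self) -> None:
        for name in (
            "snp_call_rate_min", "hwe_p_min", "maf_min", "sample_call_rate_min",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Removal log: (identifier, reason) per dropped sample / SNP."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_snps: list[tuple[str, str]] = field(default_factory=list)
    imputed_calls: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", i, r) for i, r in self.removed_samples]
        rows += [("snp", i, r) for i, r in self.removed_snps]
        return pd.DataFrame(rows, columns=["unit", "id", "reason"])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_dataset(path, format: str = "tsv") -> GenotypeDataset:
    """Read a genotype dataset from ``tsv`` or ``plink_raw`` text.

    PLINK ``.raw`` phenotypes coded 1 (control) / 2 (case) are remapped to
    0 / 1.  Missing genotypes (``NA``) map to :data:`MISSING`.
    """
    if format == "tsv":
        return _load_tsv(path)
    if format == "plink_raw":
        return _load_plink_raw(path)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'plink_raw'")


def _parse_genotype_block(df: pd.DataFrame, path) -> np.ndarray:
    geno = df.to_numpy(dtype=float)
    missing = np.isnan(geno)
    geno = np.where(missing, MISSING, geno)
    if not np.all(np.isin(geno, (0.0, 1.0, 2.0, float(MISSING)))):
        bad = sorted(set(geno[~np.isin(geno, (0.0, 1.0, 2.0, float(MISSING)))]))
        raise DataError(f"{path}: invalid genotype values {bad}")
    return geno.astype(np.int8)


def _load_tsv(path) -> GenotypeDataset:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise DataError(f"{path}: {exc}") from exc
    if df.shape[1] < 3 or list(df.columns[:2]) != ["sample_id", "phenotype"]:
        raise DataError(
            f"{path}: expected header 'sample_id<TAB>phenotype<TAB>snp...'"
        )
    # pandas pads short rows with NaN silently; detect ragged rows explicitly
    with open(path) as fh:
        header_len = len(fh.readline().rstrip("\n").split("\t"))
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != header_len:
                raise DataError(f"{path}: line {lineno} has wrong field count")
    pheno = pd.to_numeric(df["phenotype"], errors="coerce")
    if pheno.isna().any() or not set(pheno.unique()) <= {0, 1}:
        raise DataError(f"{path}: phenotype must be coded 0/1")
    geno = _parse_genotype_block(
        df.iloc[:, 2:].apply(pd.to_numeric, errors="raise"), path
    )
    return GenotypeDataset(
        genotypes=geno,
        phenotype=pheno.to_numpy(dtype=np.int8),
        snp_ids=list(df.columns[2:]),
        sample_ids=list(df["sample_id"]),
    )


_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _load_plink_raw(path) -> GenotypeDataset:
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if list(df.columns[: len(_PLINK_META)]) != _PLINK_META:
        raise DataError(f"{path}: missing PLINK .raw header columns {_PLINK_META}")
    pheno = pd.to_numeric(df["PHENOTYPE"], errors="coerce")
    if pheno.isna().any() or not set(pheno.unique()) <= {1, 2}:
        raise DataError(f"{path}: PLINK phenotype must be coded 1 (control) / 2 (case)")
    geno = _parse_genotype_block(
        df.iloc[:, len(_PLINK_META):].apply(pd.to_numeric, errors="raise"), path
    )
    sample_ids = (df["FID"].astype(str) + "_" + df["IID"].astype(str)).tolist()
    return GenotypeDataset(
        genotypes=geno,
        phenotype=(pheno.to_numpy() - 1).astype(np.int8),
        snp_ids=list(df.columns[len(_PLINK_META):]),
        sample_ids=sample_ids,
    )


def write_dataset(dataset: GenotypeDataset, path) -> None:
    """Write the tab-delimited format; inverse of ``load_dataset(..., 'tsv')``."""
    if dataset.n_samples == 0 or dataset.n_snps == 0:
        raise DataError("refusing to write an empty dataset")
    geno = dataset.genotypes.astype(object)
    geno[dataset.genotypes == MISSING] = "NA"
    df = pd.DataFrame(geno, columns=dataset.snp_ids)
    df.insert(0, "phenotype", dataset.phenotype.astype(int))
    df.insert(0, "sample_id", dataset.sample_ids)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def hwe_pvalue(counts: np.ndarray) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg.

    ``counts`` are observed (AA, Aa, aa) genotype counts.  Expected counts
    come from the sample allele frequency; 1 df because the allele frequency
    is estimated from the same counts.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        return 1.0
    q = (counts[1] + 2 * counts[2]) / (2 * n)  # minor-allele frequency
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    ok = expected > 0
    chi2 = float(((counts[ok] - expected[ok]) ** 2 / expected[ok]).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _call_rates(geno: np.ndarray, axis: int) -> np.ndarray:
    return (geno != MISSING).mean(axis=axis)


def _snp_maf(col: np.ndarray) -> float:
    called = col[col != MISSING]
    if called.size == 0:
        return 0.0
    q = called.mean() / 2.0
    return float(min(q, 1.0 - q))


def quality_control(
    dataset: GenotypeDataset,
    thresholds: QCThresholds = QCThresholds(),
    impute: bool = True,
) -> tuple[GenotypeDataset, QCReport]:
    """Filter samples then SNPs by the standard GWAS QC rules.

    Samples are removed first (call rate strictly below
    ``sample_call_rate_min``), then SNPs are removed when, over the retained
    samples, call rate < ``snp_call_rate_min``, Hardy-Weinberg p-value in
    controls < ``hwe_p_min``, or MAF < ``maf_min``.  Boundary values pass.
    Remaining missing calls are median-imputed per SNP when ``impute`` is
    true, so downstream stages see a complete matrix.
    """
    dataset.require_cases_and_controls()
    report = QCReport()
    geno = dataset.genotypes

    sample_ok = _call_rates(geno, axis=1) >= thresholds.sample_call_rate_min
    for idx in np.flatnonzero(~sample_ok):
        report.removed_samples.append((dataset.sample_ids[idx], "call_rate"))
    geno = geno[sample_ok]
    pheno = dataset.phenotype[sample_ok]
    sample_ids = [s for s, ok in zip(dataset.sample_ids, sample_ok) if ok]
    if len(sample_ids) == 0:
        raise DataError("empty after QC: all samples removed")

    controls = geno[pheno == 0]
    snp_ok = np.ones(geno.shape[1], dtype=bool)
    for j in range(geno.shape[1]):
        col = geno[:, j]
        if _call_rates(col, axis=0) < thresholds.snp_call_rate_min:
            snp_ok[j] = False
            report.removed_snps.append((dataset.snp_ids[j], "call_rate"))
            continue
        ctrl = controls[:, j]
        ctrl = ctrl[ctrl != MISSING]
        counts = np.bincount(ctrl, minlength=3)[:3]
        if hwe_pvalue(counts) < thresholds.hwe_p_min:
            snp_ok[j] = False
            report.removed_snps.append((dataset.snp_ids[j], "hwe"))
            continue
        if _snp_maf(col) < thresholds.maf_min:
            snp_ok[j] = False
            report.removed_snps.append((dataset.snp_ids[j], "maf"))

    if not snp_ok.any():
        raise DataError("empty after QC: all SNPs removed")
    geno = geno[:, snp_ok]
    snp_ids = [s for s, ok in zip(dataset.snp_ids, snp_ok) if ok]

    if impute:
        geno = geno.copy()
        for j in range(geno.shape[1]):
            col = geno[:, j]
            miss = col == MISSING
            if miss.any():
                med = int(round(float(np.median(col[~miss]))))
                geno[miss, j] = med
                report.imputed_calls += int(miss.sum())

    out = GenotypeDataset(
        genotypes=geno, phenotype=pheno, snp_ids=snp_ids, sample_ids=sample_ids
    )
    return out, report
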