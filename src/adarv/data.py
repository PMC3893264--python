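"""Genotype/phenotype input, the combined-sample MAF filter, and the
canonical in-memory case-control container.

Genotypes are stored as minor-allele dosages in {0, 1, 2} for diploid
subjects.  Two on-disk layouts are accepted: VCF v4.x plus a tab-separated
phenotype table (``subject_id<TAB>status`` with status in {0, 1}), or a
tab-separated dosage matrix (header row = variant IDs, first column =
subject ID) plus the same phenotype table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("adarv")

__all__ = [
    "CaseControlData",
    "FormatError",
    "InputError",
    "EmptyRegionError",
    "load_genotypes",
    "load_phenotype",
    "maf_filter",
    "write_matrix",
]


class FormatError(ValueError):
    """A genotype or phenotype file could not be parsed."""


class InputError(ValueError):
    """Inputs parse but violate the data contract (e.g. non-binary status)."""


class EmptyRegionError(RuntimeError):
    """No variants remain after filtering; region-level tests are undefined."""


@dataclass(frozen=True)
class CaseControlData:
    """A subject x variant dosage matrix with a binary phenotype.

    Attributes
    ----------
    genotypes : (n_subjects, n_variants) int8 array
        Minor-allele dosages, each entry in {0, 1, 2}.  No missing values:
        subjects with missing genotypes are dropped at load time.
    phenotype : (n_subjects,) int8 array
        1 = case, 0 = control.
    variant_ids : tuple of str
        Unique variant labels, one per column.
    positions : (n_variants,) int array, optional
        Genomic coordinates; informational only.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    variant_ids: tuple
    positions: np.ndarray | None = field(default=None)

    def __post_init__(self):
        g = np.asarray(self.genotypes, dtype=np.int8)
        y = np.asarray(self.phenotype, dtype=np.int8)
        object.__setattr__(self, "genotypes", g)
        object.__setattr__(self, "phenotype", y)
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        if g.ndim != 2:
            raise InputError("genotypes must be a 2-D matrix")
        if y.shape != (g.shape[0],):
            raise InputError("phenotype length must match the number of subjects")
        if g.shape[1] != len(self.variant_ids):
            raise InputError("variant_ids length must match the number of variants")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise InputError("variant_ids must be unique")
        if g.shape[1] < 1:
            raise EmptyRegionError("no variants in region")
        if not np.isin(g, (0, 1, 2)).all():
            raise InputError("dosages must be 0, 1 or 2 with no missing values")
        if not (np.any(y == 1) and np.any(y == 0)):
            raise InputError("need at least one case and one control")
        if not np.isin(y, (0, 1)).all():
            raise InputError("phenotype must be binary 0/1")

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.phenotype == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.phenotype == 0))


def load_phenotype(path) -> "pd.Series":
    """Read a two-column tab-separated phenotype table.

    Columns are subject ID and status (1 = case, 0 = control); a single
    header line is tolerated.  Returns a Series indexed by subject ID.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse phenotype file {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError("phenotype file needs two tab-separated columns")
    df = df.iloc[:, :2]
    # Drop a header line if the status field is not numeric.
    first_status = str(df.iloc[0, 1]).strip()
    try:
        float(first_status)
    except ValueError:
        df = df.iloc[1:]
    if df.empty:
        raise InputError("phenotype file contains no subjects")
    ids = df.iloc[:, 0].astype(str).str.strip()
    try:
        status = df.iloc[:, 1].astype(float)
    except ValueError as exc:
        raise InputError(f"non-numeric phenotype value: {exc}") from exc
    if not status.isin([0.0, 1.0]).all():
        bad = status[~status.isin([0.0, 1.0])].iloc[0]
        raise InputError(f"phenotype must be 0/1; found {bad!r}")
    if ids.duplicated().any():
        raise InputError("duplicate subject IDs in phenotype file")
    return pd.Series(status.astype(np.int8).to_numpy(), index=ids.to_numpy())


def _read_vcf_dosages(path):
    """Parse a VCF into (subject IDs, variant IDs, positions, dosage matrix).

    Multi-allelic records are split into one column per alternate allele;
    the dosage counts copies of that allele.  Missing genotypes are coded -1.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    ids, positions, columns = [], [], []
    for var in vcf:
        gts = np.array([g[:2] for g in var.genotypes], dtype=np.int32)
        for alt_idx, alt in enumerate(var.ALT, start=1):
            dose = (gts == alt_idx).sum(axis=1).astype(np.int8)
            dose[(gts < 0).any(axis=1)] = -1
            base = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
            label = base if len(var.ALT) == 1 else f"{base}:{var.REF}>{alt}"
            ids.append(label)
            positions.append(var.POS)
            columns.append(dose)
    vcf.close()
    if not columns:
        raise EmptyRegionError(f"no variant records in {path}")
    return samples, ids, np.asarray(positions), np.column_stack(columns)


def _read_matrix_dosages(path):
    """Parse the tab-separated dosage-matrix dialect."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot parse dosage matrix {path}: {exc}") from exc
    if df.empty or df.shape[1] < 1:
        raise FormatError("dosage matrix has no variant columns")
    vals = df.to_numpy()
    mat = np.full(vals.shape, -1, dtype=np.int8)
    finite = pd.notna(df).to_numpy()
    mat[finite] = vals[finite].astype(np.int8)
    if not np.isin(mat[finite], (0, 1, 2)).all():
        raise FormatError("dosage matrix entries must be 0, 1, 2 or missing")
    return [str(s) for s in df.index], [str(v) for v in df.columns], None, mat


def load_genotypes(path, phenotype_path, format: str = "vcf") -> CaseControlData:
    """Load genotypes plus phenotype into a :class:`CaseControlData`.

    Subjects are restricted to those present in both files, in
    phenotype-file order.  Subjects carrying any missing genotype are
    dropped (and the count logged), mirroring the usual resequencing
    quality-control step; no imputation is attempted.

    Parameters
    ----------
    path : path to a VCF (``format="vcf"``) or dosage matrix (``format="matrix"``)
    phenotype_path : path to the tab-separated subject/status table
    """
    if format == "vcf":
        samples, vids, positions, mat = _read_vcf_dosages(path)
    elif format == "matrix":
        samples, vids, positions, mat = _read_matrix_dosages(path)
    else:
        raise InputError(f"unknown format {format!r}; expected 'vcf' or 'matrix'")

    pheno = load_phenotype(phenotype_path)
    sample_pos = {s: i for i, s in enumerate(samples)}
    keep_ids = [s for s in pheno.index if s in sample_pos]
    if not keep_ids:
        raise InputError("no overlapping subjects between genotype and phenotype files")
    rows = [sample_pos[s] for s in keep_ids]
    mat = mat[rows]
    y = pheno.loc[keep_ids].to_numpy()

    complete = (mat >= 0).all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d subject(s) with missing genotypes", n_dropped)
        mat, y = mat[complete], y[complete]
    if mat.shape[0] == 0:
        raise InputError("all subjects dropped due to missing genotypes")
    return CaseControlData(mat, y, tuple(vids), positions)


def maf_filter(data: CaseControlData, max_maf: float = 0.05) -> CaseControlData:
    """Keep variants with pooled-sample MAF <= ``max_maf``; re-polarise to minor.

    The minor allele is defined in the combined case+control sample: any
    column whose coded-allele frequency exceeds 0.5 has its dosages flipped
    (g -> 2-g) so that every retained column counts the minor allele, which
    is the convention every downstream formula assumes.  Sites that are
    monomorphic in the sample pass this filter (MAF 0) and are neutralised
    downstream.  The boundary is inclusive: a site at exactly ``max_maf``
    is retained.
    """
    if not 0 < max_maf <= 0.5:
        raise InputError("max_maf must be in (0, 0.5]")
    g = data.genotypes.copy()
    n2 = 2 * data.n_subjects
    freq = g.sum(axis=0) / n2
    flip = freq > 0.5
    if flip.any():
        g[:, flip] = 2 - g[:, flip]
        freq = np.where(flip, 1.0 - freq, freq)
    keep = freq <= max_maf
    if not keep.any():
        raise EmptyRegionError(
            f"all {data.n_variants} variants exceed MAF {max_maf:g} in the pooled sample"
        )
    return replace(
        data,
        genotypes=g[:, keep],
        variant_ids=tuple(v for v, k in zip(data.variant_ids, keep) if k),
        positions=None if data.positions is None else np.asarray(data.positions)[keep],
    )


def pooled_maf(data: CaseControlData) -> np.ndarray:
    """Minor-allele frequency of each variant in the combined sample."""
    return data.genotypes.sum(axis=0) / (2 * data.n_subjects)


def write_matrix(data: CaseControlData, path, phenotype_path=None) -> None:
    """Write the dosage matrix (and optionally the phenotype table) as TSV."""
    subj = [f"S{i+1}" for i in range(data.n_subjects)]
    pd.DataFrame(data.genotypes, index=subj, columns=list(data.variant_ids)).to_csv(
        path, sep="\t", index_label="subject_id"
    )
    if phenotype_path is not None:
        pd.Series(data.phenotype, index=subj).to_csv(
            phenotype_path, sep="\t", header=False
        )
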