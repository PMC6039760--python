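"""Genotype, SNP-map and phenotype I/O, quality control and fixed-effect
pre-adjustment of phenotypes.

Dosage matrices count the alternate (B) allele: 0, 1, 2, with ``MISSING``
(-1) as the sentinel for no-calls.  Supported on-disk dialects:

* VCF (hard GT calls only, biallelic sites only),
* PLINK ``.raw`` (space separated, six meta columns then one column per
  SNP, ``NA`` = missing),
* plain TSV (animals as rows, header row, ``NA`` = missing).

Coordinates are 1-based throughout.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

__all__ = [
    "MISSING",
    "SnpRecord",
    "GenotypeMatrix",
    "PhenotypeTable",
    "read_genotypes",
    "write_genotypes",
    "read_snp_map",
    "write_snp_map",
    "read_phenotypes",
    "write_phenotypes",
    "qc_filter",
    "adjust_phenotypes",
]


@dataclasses.dataclass(frozen=True)
class SnpRecord:
    """One marker: identifier, chromosome and 1-based physical position."""

    snp_id: str
    chrom: str
    pos_bp: int
    allele_ref: str = "A"
    allele_alt: str = "B"

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp} for {self.snp_id}")


@dataclasses.dataclass
class GenotypeMatrix:
    """Animals x SNPs alternate-allele dosage matrix plus its SNP map."""

    animal_ids: list[str]
    snps: list[SnpRecord]
    dosage: np.ndarray  # (n_animals, m_snps) int8, values {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.animal_ids):
            raise ValueError(f"dosage has {n} rows but {len(self.animal_ids)} animal ids")
        if m != len(self.snps):
            raise ValueError(f"dosage has {m} columns but {len(self.snps)} SNP records")
        if len(set(self.animal_ids)) != n:
            raise ValueError("duplicate animal ids")
        if len({s.snp_id for s in self.snps}) != m:
            raise ValueError("duplicate SNP ids")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or MISSING")

    @property
    def n_animals(self) -> int:
        return self.dosage.shape[0]

    @property
    def m_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self) -> dict[str, int]:
        return {s.snp_id: k for k, s in enumerate(self.snps)}

    def allele_freqs(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP (missing calls excluded)."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=0) / 2.0

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.snp_index()
        cols = [idx[s] for s in snp_ids]
        return GenotypeMatrix(
            animal_ids=list(self.animal_ids),
            snps=[self.snps[c] for c in cols],
            dosage=self.dosage[:, cols].copy(),
        )

    def subset_animals(self, animal_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        rows = [pos[a] for a in animal_ids]
        return GenotypeMatrix(
            animal_ids=list(animal_ids),
            snps=list(self.snps),
            dosage=self.dosage[rows].copy(),
        )


@dataclasses.dataclass
class PhenotypeTable:
    """Per-animal trait value plus fixed-effect covariates.

    ``data`` columns: ``animal_id``, ``y_raw``, ``contemporary_group``,
    ``age_days`` and, after :func:`adjust_phenotypes`, ``y_adjusted`` and
    ``y_corrected``.
    """

    data: pd.DataFrame
    fit: dict | None = None  # OLS fit metadata set by adjust_phenotypes

    REQUIRED = ("animal_id", "y_raw", "contemporary_group", "age_days")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if self.data["animal_id"].duplicated().any():
            raise ValueError("duplicate animal ids in phenotype table")
        self.data = self.data.reset_index(drop=True)

    @property
    def animal_ids(self) -> list[str]:
        return self.data["animal_id"].astype(str).tolist()

    @property
    def is_adjusted(self) -> bool:
        return "y_adjusted" in self.data.columns

    def aligned_to(self, g: GenotypeMatrix) -> "PhenotypeTable":
        """Reorder records to match the animal order of a genotype matrix."""
        if set(self.animal_ids) != set(g.animal_ids):
            raise ValueError("phenotype and genotype animal sets differ")
        d = self.data.set_index("animal_id").loc[g.animal_ids].reset_index()
        return PhenotypeTable(d, fit=self.fit)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FORMATS = ("vcf", "plink_raw", "tsv")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".vcf":
        return "vcf"
    if suffix == ".raw":
        return "plink_raw"
    return "tsv"


def read_genotypes(path: str | Path, format: str | None = None,
                   snp_map: list[SnpRecord] | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF, PLINK .raw or TSV.

    ``snp_map`` supplies chromosome/position for the map-less dialects
    (.raw and TSV); without it placeholder coordinates are assigned in
    file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown genotype format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "plink_raw":
        return _read_plink_raw(path, snp_map)
    return _read_tsv(path, snp_map)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animal_ids = list(vcf.samples)
    snps: list[SnpRecord] = []
    rows: list[np.ndarray] = []
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    code = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for var in vcf:
        if len(var.ALT) != 1:
            site = var.ID or f"{var.CHROM}:{var.POS}"
            raise ValueError(f"multi-allelic VCF site rejected: {site}")
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        snps.append(SnpRecord(snp_id, str(var.CHROM), int(var.POS),
                              str(var.REF), str(var.ALT[0])))
        rows.append(code[np.asarray(var.gt_types)])
    if not snps:
        raise ValueError(f"no variant records in {path}")
    dosage = np.stack(rows, axis=1)
    return GenotypeMatrix(animal_ids, snps, dosage)


def _placeholder_map(snp_ids: Sequence[str]) -> list[SnpRecord]:
    return [SnpRecord(s, "0", k + 1) for k, s in enumerate(snp_ids)]


def _apply_map(snp_ids: list[str], snp_map: list[SnpRecord] | None,
               source: str) -> list[SnpRecord]:
    if snp_map is None:
        return _placeholder_map(snp_ids)
    by_id = {r.snp_id: r for r in snp_map}
    try:
        return [by_id[s] for s in snp_ids]
    except KeyError as e:
        raise ValueError(f"SNP {e.args[0]!r} from {source} missing from SNP map") from e


def _read_plink_raw(path: Path, snp_map: list[SnpRecord] | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != meta:
        raise ValueError(f"not a PLINK .raw header in {path}: {list(df.columns[:6])}")
    snp_cols = list(df.columns[6:])
    # .raw columns are "<snp_id>_<counted allele>"
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    animal_ids = df["IID"].tolist()
    vals = df[snp_cols].to_numpy()
    dosage = np.full(vals.shape, MISSING, dtype=np.int8)
    for tok, d in (("0", 0), ("1", 1), ("2", 2)):
        dosage[vals == tok] = d
    unknown = ~np.isin(vals, ["0", "1", "2", "NA"])
    if unknown.any():
        i, j = np.argwhere(unknown)[0]
        raise ValueError(
            f"malformed .raw value {vals[i, j]!r} at line {i + 2}, column {snp_cols[j]}")
    snps = _apply_map(snp_ids, snp_map, str(path))
    if snp_map is None and any("_" in c for c in snp_cols):
        snps = [dataclasses.replace(r, allele_alt=c.rsplit("_", 1)[1])
                for r, c in zip(snps, snp_cols)]
    return GenotypeMatrix(animal_ids, snps, dosage)


def _read_tsv(path: Path, snp_map: list[SnpRecord] | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    snp_ids = list(df.columns)
    vals = df.to_numpy(dtype=float)
    dosage = np.full(vals.shape, MISSING, dtype=np.int8)
    ok = ~np.isnan(vals)
    if not np.isin(vals[ok], [0, 1, 2]).all():
        raise ValueError(f"TSV genotype values outside {{0,1,2,NA}} in {path}")
    dosage[ok] = vals[ok].astype(np.int8)
    snps = _apply_map(snp_ids, snp_map, str(path))
    return GenotypeMatrix(df.index.tolist(), snps, dosage)


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "vcf":
        _write_vcf(g, path)
    elif fmt == "plink_raw":
        _write_plink_raw(g, path)
    elif fmt == "tsv":
        _write_tsv(g, path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    return path


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    chroms = list(dict.fromkeys(s.chrom for s in g.snps))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.animal_ids) + "\n")
        for k, s in enumerate(g.snps):
            calls = "\t".join(gt[int(d)] for d in g.dosage[:, k])
            fh.write(f"{s.chrom}\t{s.pos_bp}\t{s.snp_id}\t{s.allele_ref}\t"
                     f"{s.allele_alt}\t.\t.\t.\tGT\t{calls}\n")


def _write_plink_raw(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        header += [f"{s.snp_id}_{s.allele_alt}" for s in g.snps]
        fh.write(" ".join(header) + "\n")
        for i, aid in enumerate(g.animal_ids):
            row = [aid, aid, "0", "0", "0", "-9"]
            row += ["NA" if d == MISSING else str(int(d)) for d in g.dosage[i]]
            fh.write(" ".join(row) + "\n")


def _write_tsv(g: GenotypeMatrix, path: Path) -> None:
    df = pd.DataFrame(g.dosage.astype(object), index=g.animal_ids, columns=g.snp_ids)
    df[g.dosage == MISSING] = pd.NA
    df.index.name = "animal_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_snp_map(path: str | Path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    cols = {"snp_id", "chrom", "pos_bp"}
    if not cols.issubset(df.columns):
        raise ValueError(f"SNP map must have columns {sorted(cols)}")
    return [
        SnpRecord(
            str(r.snp_id), str(r.chrom), int(r.pos_bp),
            str(getattr(r, "allele_ref", "A")), str(getattr(r, "allele_alt", "B")),
        )
        for r in df.itertuples(index=False)
    ]


def write_snp_map(snps: Sequence[SnpRecord], path: str | Path) -> Path:
    pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snps],
            "chrom": [s.chrom for s in snps],
            "pos_bp": [s.pos_bp for s in snps],
            "allele_ref": [s.allele_ref for s in snps],
            "allele_alt": [s.allele_alt for s in snps],
        }
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "contemporary_group": str})
    return PhenotypeTable(df)


def write_phenotypes(p: PhenotypeTable, path: str | Path) -> Path:
    p.data.to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# QC and phenotype adjustment
# ---------------------------------------------------------------------------

def qc_filter(g: GenotypeMatrix, maf_min: float = 0.01,
              return_reasons: bool = False):
    """Remove SNPs with MAF < ``maf_min`` or any missing call.

    MAF is computed from observed calls only; SNPs at exactly ``maf_min``
    are retained.  Returns ``(filtered, removed_ids)``; with
    ``return_reasons=True`` the second element is a ``{snp_id: reason}``
    dict instead.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")
    freqs = g.allele_freqs()
    maf = np.minimum(freqs, 1.0 - freqs)
    has_missing = (g.dosage == MISSING).any(axis=0)
    reasons: dict[str, str] = {}
    keep = np.ones(g.m_snps, dtype=bool)
    for k, s in enumerate(g.snps):
        why = []
        if has_missing[k]:
            why.append("missing_call")
        if np.isnan(maf[k]) or maf[k] < maf_min:
            why.append(f"maf<{maf_min}")
        if why:
            keep[k] = False
            reasons[s.snp_id] = "+".join(why)
    if not keep.any():
        raise ValueError("QC removed every SNP; downstream analysis undefined")
    filtered = GenotypeMatrix(
        animal_ids=list(g.animal_ids),
        snps=[s for k, s in enumerate(g.snps) if keep[k]],
        dosage=g.dosage[:, keep].copy(),
    )
    if return_reasons:
        return filtered, reasons
    return filtered, list(reasons)


def group_design(groups: Sequence[str], reference: str | None = None) -> tuple[np.ndarray, list[str]]:
    """Treatment-contrast indicator columns for contemporary groups.

    The reference level (first sorted group by default) gets no column.
    """
    levels = sorted(set(map(str, groups)))
    if reference is None:
        reference = levels[0]
    elif reference not in levels:
        raise ValueError(f"reference group {reference!r} not among levels")
    others = [lv for lv in levels if lv != reference]
    garr = np.asarray([str(x) for x in groups])
    cols = np.column_stack([(garr == lv).astype(float) for lv in others]) \
        if others else np.empty((len(garr), 0))
    return cols, others


def adjust_phenotypes(p: PhenotypeTable, reference_group: str | None = None) -> PhenotypeTable:
    """OLS pre-adjustment of the trait for contemporary group and age.

    Fits ``y_raw ~ 1 + group + age_days`` (treatment contrasts, linear
    age) and stores two residual variants: ``y_corrected`` (mean-zero
    residual, the quantity correlated with GEBVs) and ``y_adjusted``
    (residual plus the grand mean, the machine-learning input).
    """
    df = p.data.copy()
    y = df["y_raw"].to_numpy(dtype=float)
    groups = df["contemporary_group"].astype(str)
    counts = groups.value_counts()
    singles = counts[counts == 1].index.tolist()
    if singles:
        warnings.warn(
            f"contemporary groups with a single record: {singles}; "
            "their effects are estimated without pooling", UserWarning)
    gcols, glabels = group_design(groups, reference_group)
    age = df["age_days"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), gcols, age])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    df["y_corrected"] = resid
    df["y_adjusted"] = resid + y.mean()
    fit = {
        "intercept": float(beta[0]),
        "group_effects": dict(zip(glabels, beta[1:-1].tolist())),
        "age_slope": float(beta[-1]),
        "reference_group": reference_group or sorted(set(groups))[0],
    }
    return PhenotypeTable(df, fit=fit)
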