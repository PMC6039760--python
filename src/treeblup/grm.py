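"""VanRaden genomic relationship matrices and their diagnostics.

``GRM = W W' / (2 * sum_k p_k (1 - p_k))`` with ``W_jk = dosage_jk - 2 p_k``
(equivalently the 2-2p / 1-2p / -2p coding with the counted allele as B).
Diagnostics summarise the diagonal, off-diagonal and inverse-diagonal
distributions and screen the diagonal for bimodality (a hidden
sub-population signal).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import MISSING, GenotypeMatrix
from .subset_selection import SnpPanel

__all__ = ["Grm", "GrmDiagnostics", "build_vanraden", "grm_diagnostics",
           "write_grm_tsv", "read_grm_tsv", "write_grm_gcta"]

DEFAULT_RIDGE = 0.01


@dataclasses.dataclass
class Grm:
    """n x n genomic relationship matrix plus construction metadata."""

    animal_ids: list[str]
    matrix: np.ndarray
    m_snps: int
    denominator: float
    allele_freqs: np.ndarray
    ridge_used: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.animal_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM shape does not match animal ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM is not symmetric")
        if self.denominator <= 0:
            raise ValueError("GRM denominator must be positive")

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    def diag(self) -> np.ndarray:
        return np.diag(self.matrix)

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]


def build_vanraden(g: GenotypeMatrix, panel: SnpPanel | None = None,
                   freqs: np.ndarray | None = None) -> Grm:
    """VanRaden GRM from a SNP panel (default: all SNPs).

    ``freqs`` overrides the observed counted-allele frequencies (e.g.,
    from a reference cohort); it must align with the panel's SNP order.
    Monomorphic panel SNPs are dropped with a warning.
    """
    sub = g.subset_snps(panel.snp_ids) if panel is not None else g
    if (sub.dosage == MISSING).any():
        raise ValueError("missing dosage calls; run qc_filter before GRM construction")
    p = sub.allele_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    if len(p) != sub.m_snps:
        raise ValueError(f"got {len(p)} frequencies for {sub.m_snps} SNPs")
    poly = (p > 0) & (p < 1)
    if not poly.all():
        dropped = [s.snp_id for k, s in enumerate(sub.snps) if not poly[k]]
        warnings.warn(f"dropping {len(dropped)} monomorphic panel SNPs", UserWarning)
        sub = sub.subset_snps([s.snp_id for k, s in enumerate(sub.snps) if poly[k]])
        p = p[poly]
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all panel SNPs monomorphic; GRM denominator is zero")
    W = sub.dosage.astype(float) - 2.0 * p
    mat = (W @ W.T) / denom
    mat = 0.5 * (mat + mat.T)
    return Grm(list(sub.animal_ids), mat, sub.m_snps, denom, p)


@dataclasses.dataclass
class GrmDiagnostics:
    diag_mean: float
    diag_sd: float
    diag_min: float
    diag_max: float
    offdiag_mean: float
    offdiag_sd: float
    offdiag_min: float
    offdiag_max: float
    inv_diag_mean: float | None
    inv_diag_sd: float | None
    inv_diag_min: float | None
    inv_diag_max: float | None
    multimodality_flag: bool
    ridge_used: float
    inverse_ok: bool

    def to_series(self) -> pd.Series:
        return pd.Series(dataclasses.asdict(self))


def _bimodality_coefficient(x: np.ndarray) -> float:
    """Sarle's bimodality coefficient; > ~0.555 suggests more than one mode."""
    n = len(x)
    if n < 4 or np.ptp(x) == 0:
        return 0.0
    g1 = stats.skew(x)
    g2 = stats.kurtosis(x)  # excess
    return (g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))


def grm_diagnostics(G: Grm, ridge: float = DEFAULT_RIDGE,
                    bimodality_threshold: float = 0.555) -> GrmDiagnostics:
    """Summary statistics of a GRM and its (possibly ridge-stabilised)
    inverse.

    The inverse is attempted on ``G`` as-is; if that fails (or the matrix
    is numerically singular) ``ridge * I`` is added and the ridge is
    recorded.  Inverse statistics are left unset when both attempts fail.
    """
    d = G.diag()
    o = G.offdiag()
    inv_stats: dict[str, float | None] = dict(inv_diag_mean=None, inv_diag_sd=None,
                                             inv_diag_min=None, inv_diag_max=None)
    ridge_used, inverse_ok = 0.0, False
    mat = G.matrix
    for trial_ridge in (G.ridge_used, ridge if ridge > 0 else None):
        if trial_ridge is None:
            continue
        try:
            M = mat + trial_ridge * np.eye(G.n) if trial_ridge > 0 else mat
            # cholesky doubles as a positive-definiteness check
            c = np.linalg.cholesky(M)
            inv = np.linalg.inv(M)
            cond = np.linalg.cond(M)
            if cond > 1e12:
                raise np.linalg.LinAlgError(f"condition number {cond:.2e}")
            di = np.diag(inv)
            inv_stats = dict(inv_diag_mean=float(di.mean()), inv_diag_sd=float(di.std(ddof=1)),
                             inv_diag_min=float(di.min()), inv_diag_max=float(di.max()))
            ridge_used, inverse_ok = float(trial_ridge), True
            break
        except np.linalg.LinAlgError:
            continue
    if not inverse_ok:
        warnings.warn("GRM inversion failed even with ridge; inverse stats unset",
                      UserWarning)
    return GrmDiagnostics(
        diag_mean=float(d.mean()), diag_sd=float(d.std(ddof=1)),
        diag_min=float(d.min()), diag_max=float(d.max()),
        offdiag_mean=float(o.mean()), offdiag_sd=float(o.std(ddof=1)),
        offdiag_min=float(o.min()), offdiag_max=float(o.max()),
        multimodality_flag=bool(_bimodality_coefficient(d) > bimodality_threshold),
        ridge_used=ridge_used, inverse_ok=inverse_ok, **inv_stats,
    )


def write_grm_tsv(G: Grm, path: str | Path) -> Path:
    df = pd.DataFrame(G.matrix, index=G.animal_ids, columns=G.animal_ids)
    df.index.name = "animal_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    return Path(path)


def read_grm_tsv(path: str | Path) -> Grm:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    mat = df.to_numpy(dtype=float)
    mat = 0.5 * (mat + mat.T)
    p = np.array([0.5])  # frequencies are not stored in the square dialect
    return Grm(ids, mat, m_snps=0, denominator=1.0, allele_freqs=p)


def write_grm_gcta(G: Grm, prefix: str | Path) -> tuple[Path, Path]:
    """GCTA pairwise text dialect: ``<prefix>.grm`` (i j m_used value,
    1-based lower triangle) plus ``<prefix>.id``."""
    prefix = Path(prefix)
    grm_path = prefix.with_suffix(".grm")
    id_path = prefix.with_suffix(".id")
    with open(grm_path, "w") as fh:
        for i in range(G.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{G.m_snps}\t{G.matrix[i, j]:.10g}\n")
    with open(id_path, "w") as fh:
        for a in G.animal_ids:
            fh.write(f"{a}\t{a}\n")
    return grm_path, id_path
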