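"""Synthetic genotype/phenotype cohorts with known additive architecture.

Generates Hardy-Weinberg (or half-sib structured) dosage matrices, draws
additive QTL effects and composes phenotypes with contemporary-group and
age fixed effects, recording the full ground truth for recovery tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_io import GenotypeMatrix, PhenotypeTable, SnpRecord

__all__ = ["SimConfig", "SimTruth", "brahman_like", "simulate_genotypes",
           "simulate_phenotypes", "simulate_cohort"]

_PHENO_STREAM = 104729  # rng substream offset so phenotype draws are independent


@dataclasses.dataclass
class SimConfig:
    """Parameters of one synthetic cohort."""

    n_animals: int = 500
    m_snps: int = 2000
    n_chrom: int = 10
    maf_dist: tuple[float, float] = (1.0, 1.0)  # Beta shapes, truncated to [0.01, 0.5]
    n_qtl: int = 100
    h2_true: float = 0.125
    n_groups: int = 20
    group_sd: float = 10.0
    age_range_days: tuple[int, int] = (323, 509)
    age_slope: float = 0.3  # kg/day
    family_structure: str = "unrelated"  # or "half_sib"
    n_sires: int = 25
    # "normal": N(0,1) effects; "equal": same magnitude, random sign;
    # "equal_var": each QTL contributes equal genetic variance
    qtl_effect_dist: str = "normal"
    qtl_maf_min: float = 0.01  # QTLs drawn among SNPs at or above this MAF
    seed: int = 0
    # presentation-only knobs (do not affect heritability)
    intercept: float = 300.0
    sigma2_p_target: float = 400.0
    ld_block: int = 0  # >0 enables block-LD copying between adjacent loci
    ld_rho: float = 0.0

    def validate(self) -> None:
        if self.n_animals < 2 or self.m_snps < 1:
            raise ValueError("need at least 2 animals and 1 SNP")
        if self.n_qtl > self.m_snps:
            raise ValueError(f"n_qtl={self.n_qtl} exceeds m_snps={self.m_snps}")
        if not 0.0 <= self.h2_true < 1.0:
            raise ValueError(f"h2_true must be in [0, 1), got {self.h2_true}")
        if self.n_qtl == 0 and self.h2_true > 0:
            raise ValueError("n_qtl=0 is incompatible with h2_true > 0")
        if self.family_structure not in ("unrelated", "half_sib"):
            raise ValueError(f"unknown family_structure {self.family_structure!r}")
        if self.family_structure == "half_sib" and self.n_sires < 1:
            raise ValueError("half_sib mode needs n_sires >= 1")
        if self.qtl_effect_dist not in ("normal", "equal", "equal_var"):
            raise ValueError(f"unknown qtl_effect_dist {self.qtl_effect_dist!r}")


@dataclasses.dataclass
class SimTruth:
    """Ground truth behind one simulated phenotype vector."""

    qtl_ids: list[str]
    qtl_effects: np.ndarray          # scaled per-QTL allele substitution effects
    true_breeding_values: np.ndarray  # per animal, genotype order
    h2_realized: float
    fixed_effects_used: dict
    sigma2_a_true: float
    sigma2_e_true: float
    sire_of: np.ndarray | None = None  # family labels in half_sib mode


def brahman_like(seed: int = 42, **overrides) -> SimConfig:
    """Desk-scale stand-in for the study cohorts: 1,000 + 1,000 animals,
    5,000 SNPs, 100 QTLs, 20 contemporary groups, genomic h2 0.125."""
    cfg = SimConfig(n_animals=2000, m_snps=5000, n_qtl=100, n_groups=20,
                    h2_true=0.125, seed=seed)
    return dataclasses.replace(cfg, **overrides)


def _draw_freqs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    a, b = cfg.maf_dist
    p = np.empty(cfg.m_snps)
    todo = np.ones(cfg.m_snps, dtype=bool)
    for _ in range(1000):
        k = int(todo.sum())
        if k == 0:
            break
        draw = rng.beta(a, b, size=k)
        ok = (draw >= 0.01) & (draw <= 0.5)
        idx = np.flatnonzero(todo)
        p[idx[ok]] = draw[ok]
        todo[idx[ok]] = False
    else:
        raise RuntimeError("could not draw allele frequencies in [0.01, 0.5]; "
                           f"check maf_dist={cfg.maf_dist}")
    return p


def _snp_map(cfg: SimConfig, rng: np.random.Generator) -> list[SnpRecord]:
    chrom_of = np.sort(rng.integers(1, cfg.n_chrom + 1, size=cfg.m_snps))
    gaps = rng.integers(1_000, 100_000, size=cfg.m_snps)
    snps: list[SnpRecord] = []
    pos = 0
    last_chrom = None
    for k in range(cfg.m_snps):
        c = int(chrom_of[k])
        pos = int(gaps[k]) if c != last_chrom else pos + int(gaps[k])
        last_chrom = c
        snps.append(SnpRecord(f"snp{k + 1:06d}", str(c), pos))
    return snps


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a dosage matrix under HWE (or half-sib families) at the
    configured allele-frequency distribution; reproducible from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    p = _draw_freqs(cfg, rng)
    snps = _snp_map(cfg, rng)
    n, m = cfg.n_animals, cfg.m_snps
    if cfg.family_structure == "unrelated":
        dosage = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        sire_of = None
    else:
        sires = rng.binomial(2, p, size=(cfg.n_sires, m))
        sire_of = rng.integers(0, cfg.n_sires, size=n)
        paternal = rng.binomial(1, sires[sire_of] / 2.0)
        maternal = rng.binomial(1, p, size=(n, m))
        dosage = (paternal + maternal).astype(np.int8)
    if cfg.ld_block > 1 and cfg.ld_rho > 0:
        # crude block LD: with prob ld_rho copy the previous locus in a block
        copy = rng.random((n, m)) < cfg.ld_rho
        for k in range(1, m):
            if k % cfg.ld_block != 0:
                dosage[copy[:, k], k] = dosage[copy[:, k], k - 1]
    g = GenotypeMatrix([f"A{i + 1:05d}" for i in range(n)], snps, dosage)
    if sire_of is not None:
        g.sire_of = sire_of  # type: ignore[attr-defined]
    return g


def simulate_phenotypes(g: GenotypeMatrix, cfg: SimConfig) -> tuple[PhenotypeTable, SimTruth]:
    """Compose ``y = intercept + group + age_slope*age + u + e`` on top of a
    genotype matrix.

    QTL effects are drawn N(0,1) and rescaled so the *expected* genetic
    variance hits ``h2_true * sigma2_p_target`` (per-realization value is
    recorded in :class:`SimTruth`).
    """
    cfg.validate()
    import pandas as pd

    rng = np.random.default_rng([cfg.seed, _PHENO_STREAM])
    n, m = g.n_animals, g.m_snps
    freqs = g.allele_freqs()
    maf = np.minimum(freqs, 1.0 - freqs)
    eligible = np.flatnonzero(maf >= cfg.qtl_maf_min)
    if cfg.n_qtl > len(eligible):
        raise ValueError(f"only {len(eligible)} SNPs at MAF >= {cfg.qtl_maf_min} "
                         f"for {cfg.n_qtl} QTLs")
    qtl_idx = (np.sort(rng.choice(eligible, size=cfg.n_qtl, replace=False))
               if cfg.n_qtl else np.array([], int))
    raw_effects = rng.standard_normal(cfg.n_qtl)
    if cfg.qtl_effect_dist == "equal":
        raw_effects = np.sign(raw_effects) + (raw_effects == 0)
    elif cfg.qtl_effect_dist == "equal_var" and cfg.n_qtl:
        pq0 = g.allele_freqs()[qtl_idx]
        signs = np.sign(raw_effects) + (raw_effects == 0)
        raw_effects = signs / np.sqrt(np.maximum(2.0 * pq0 * (1.0 - pq0), 1e-12))

    sigma2_a = cfg.h2_true * cfg.sigma2_p_target
    sigma2_e = (1.0 - cfg.h2_true) * cfg.sigma2_p_target
    if cfg.n_qtl and sigma2_a > 0:
        pq = g.allele_freqs()[qtl_idx]
        expected_var = float(np.sum(raw_effects**2 * 2.0 * pq * (1.0 - pq)))
        scale = np.sqrt(sigma2_a / expected_var) if expected_var > 0 else 0.0
    else:
        scale = 0.0
    effects = raw_effects * scale
    if cfg.n_qtl:
        pq = g.allele_freqs()[qtl_idx]
        W = g.dosage[:, qtl_idx].astype(float) - 2.0 * pq
        u = W @ effects
    else:
        u = np.zeros(n)
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=n)

    group_idx = rng.integers(0, cfg.n_groups, size=n)
    group_effects = rng.normal(0.0, cfg.group_sd, size=cfg.n_groups)
    lo, hi = cfg.age_range_days
    age = rng.integers(lo, hi + 1, size=n)
    y = cfg.intercept + group_effects[group_idx] + cfg.age_slope * age + u + e

    var_u, var_e = float(np.var(u)), float(np.var(e))
    h2_real = var_u / (var_u + var_e) if var_u + var_e > 0 else 0.0
    pheno = PhenotypeTable(pd.DataFrame({
        "animal_id": g.animal_ids,
        "y_raw": y,
        "contemporary_group": [f"G{i + 1:02d}" for i in group_idx],
        "age_days": age,
    }))
    truth = SimTruth(
        qtl_ids=[g.snps[k].snp_id for k in qtl_idx],
        qtl_effects=effects,
        true_breeding_values=u,
        h2_realized=h2_real,
        fixed_effects_used={
            "group_effects": {f"G{i + 1:02d}": float(v) for i, v in enumerate(group_effects)},
            "age_slope": cfg.age_slope,
            "intercept": cfg.intercept,
        },
        sigma2_a_true=sigma2_a,
        sigma2_e_true=sigma2_e,
        sire_of=getattr(g, "sire_of", None),
    )
    return pheno, truth


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, PhenotypeTable, SimTruth]:
    """Convenience wrapper: genotypes plus phenotypes in one call."""
    g = simulate_genotypes(cfg)
    p, truth = simulate_phenotypes(g, cfg)
    return g, p, truth
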