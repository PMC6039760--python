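"""Turn importance tables into SNP panels and compare panels.

Panels: top-k by rank, all positive-score SNPs, evenly spaced baselines
(by marker index along genome order, or nearest to an equal-bp grid per
chromosome), and the full panel.  ``overlap_counts`` produces the Venn
region counts for two or three panels.
"""

from __future__ import annotations

import dataclasses
import warnings
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import SnpRecord
from .vim_ranking import VimTable, _genome_order_keys

__all__ = ["SnpPanel", "top_k", "positive_set", "evenly_spaced",
           "all_snps", "overlap_counts"]

_PROVENANCES = ("vim_topk", "vim_positive", "evenly_spaced", "all")


@dataclasses.dataclass
class SnpPanel:
    """A named, ordered subset of SNP ids."""

    name: str
    snp_ids: list[str]
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError(f"duplicate SNP ids in panel {self.name}")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def to_tsv(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            fh.write(f"# panel={self.name} provenance={self.provenance} "
                     f"size={len(self)}\n")
            fh.write("snp_id\n")
            fh.writelines(s + "\n" for s in self.snp_ids)
        return Path(path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SnpPanel":
        name, provenance = Path(path).stem, "all"
        ids: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    meta = dict(tok.split("=", 1) for tok in line[1:].split() if "=" in tok)
                    name = meta.get("panel", name)
                    provenance = meta.get("provenance", provenance)
                elif line and line != "snp_id":
                    ids.append(line)
        return cls(name, ids, provenance)


def top_k(v: VimTable, k: int, name: str | None = None) -> SnpPanel:
    """The k best-ranked SNPs, ordered by rank."""
    m = len(v.snp_ids)
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}], got {k}")
    return SnpPanel(name or f"{v.method}_top{k}", v.top_ids(k), "vim_topk")


def positive_set(v: VimTable, name: str | None = None) -> SnpPanel:
    """All SNPs with strictly positive score, ordered by rank."""
    order = np.argsort(v.ranks)
    ids = [v.snp_ids[i] for i in order if v.scores[i] > 0]
    if not ids:
        warnings.warn(f"no SNP has positive {v.method} score", UserWarning)
    return SnpPanel(name or f"{v.method}_positive", ids, "vim_positive")


def evenly_spaced(snp_map: Sequence[SnpRecord], k: int, by_bp: bool = False,
                  name: str | None = None) -> SnpPanel:
    """Evenly spaced baseline panel over the genome-ordered map.

    Default rule: marker indices ``floor(j*(m-1)/(k-1))`` for
    ``j = 0..k-1`` (first and last SNP always included).  ``by_bp``
    instead picks the marker nearest to each point of an equal-bp grid
    within every chromosome (k split across chromosomes by SNP count).
    """
    m = len(snp_map)
    if not 2 <= k <= m:
        raise ValueError(f"k must be in [2, {m}], got {k}")
    chrom_key, pos_key = _genome_order_keys(snp_map)
    order = np.lexsort((pos_key, chrom_key))
    if not by_bp:
        j = np.arange(k)
        idx = order[(j * (m - 1)) // (k - 1)]
    else:
        idx = []
        chroms = chrom_key[order]
        quota = np.bincount(chroms)  # SNPs per chromosome in map order
        alloc = np.maximum(1, np.round(quota / m * k).astype(int))
        for c in np.unique(chroms):
            rows = order[chroms == c]
            pos = pos_key[rows].astype(float)
            grid = np.linspace(pos.min(), pos.max(), alloc[c])
            nearest = np.unique([int(np.argmin(np.abs(pos - gp))) for gp in grid])
            idx.extend(rows[nearest])
        idx = np.asarray(sorted(set(idx), key=lambda i: (chrom_key[i], pos_key[i])))
    ids = [snp_map[i].snp_id for i in idx]
    return SnpPanel(name or f"even{k}", ids, "evenly_spaced")


def all_snps(snp_map: Sequence[SnpRecord], name: str = "ALL") -> SnpPanel:
    return SnpPanel(name, [s.snp_id for s in snp_map], "all")


def overlap_counts(panels: Sequence[SnpPanel]) -> dict[str, int]:
    """Venn counts for 2 or 3 panels.

    For every '&'-joined panel-name combination the raw intersection size
    is reported (``"A"`` is the panel size, ``"A&B"`` the full pairwise
    intersection), and ``"A&B... (only)"`` counts the exclusive Venn
    region (SNPs in exactly that combination), so the exclusive counts
    sum to the size of the union.
    """
    if len(panels) not in (2, 3):
        raise ValueError("overlap_counts takes 2 or 3 panels")
    names = [p.name for p in panels]
    if len(set(names)) != len(names):
        names = [f"{p.name}#{i}" for i, p in enumerate(panels)]
    sets = {nm: set(p.snp_ids) for nm, p in zip(names, panels)}
    counts: dict[str, int] = {}
    for r in range(1, len(panels) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[nm] for nm in combo))
            outside = set.union(set(), *(sets[nm] for nm in names if nm not in combo))
            counts["&".join(combo)] = len(inside)
            counts["&".join(combo) + " (only)"] = len(inside - outside)
    return counts
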