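"""Genetic maps: per-locus chromosome and centimorgan position.

The map fixes the canonical locus order used throughout the pipeline
(chromosome, then position, ties broken by locus id) and supplies the
inter-locus distances that drive both meiosis in the simulator and the
switch rates of the imputation HMM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "InvalidMapError"]


class InvalidMapError(ValueError):
    """Raised when a genetic map violates its structural invariants."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map.

    Parameters
    ----------
    chromosome
        Integer chromosome label per locus.
    position_cM
        Map position in centimorgans, strictly increasing within a
        chromosome.
    locus_id
        Unique string identifier per locus.
    """

    chromosome: np.ndarray
    position_cM: np.ndarray
    locus_id: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chromosome, dtype=int)
        pos = np.asarray(self.position_cM, dtype=float)
        if chrom.shape != pos.shape or chrom.ndim != 1:
            raise InvalidMapError("chromosome and position arrays must be 1-D and equal length")
        ids = list(self.locus_id) if self.locus_id else [f"snp{i}" for i in range(len(pos))]
        if len(ids) != len(pos):
            raise InvalidMapError("locus_id length does not match number of loci")
        if len(set(ids)) != len(ids):
            raise InvalidMapError("locus ids must be unique")
        # canonical order: chromosome, position, id
        order = np.lexsort((np.array(ids), pos, chrom))
        chrom, pos = chrom[order], pos[order]
        ids = [ids[i] for i in order]
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if len(p) < 2:
                raise InvalidMapError(f"chromosome {c} has fewer than 2 loci")
            if np.any(np.diff(p) <= 0):
                raise InvalidMapError(f"positions not strictly increasing on chromosome {c}")
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_cM", pos)
        object.__setattr__(self, "locus_id", ids)

    @property
    def n_loci(self) -> int:
        return len(self.position_cM)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def chromosome_slice(self, chrom: int) -> slice:
        """Contiguous index range of loci on ``chrom`` (map is sorted)."""
        idx = np.flatnonzero(self.chromosome == chrom)
        if idx.size == 0:
            raise KeyError(f"no loci on chromosome {chrom}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def interval_distances_cM(self, chrom: int) -> np.ndarray:
        """Distances between adjacent loci on a chromosome, in cM."""
        sl = self.chromosome_slice(chrom)
        return np.diff(self.position_cM[sl])

    def subset(self, indices: np.ndarray) -> "GeneticMap":
        indices = np.asarray(indices, dtype=int)
        return GeneticMap(
            chromosome=self.chromosome[indices],
            position_cM=self.position_cM[indices],
            locus_id=[self.locus_id[i] for i in indices],
        )

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def uniform(n_chromosomes: int, loci_per_chromosome: int, spacing_cM: float = 1.0) -> "GeneticMap":
        """Evenly spaced map, ``spacing_cM`` between adjacent loci."""
        chrom = np.repeat(np.arange(1, n_chromosomes + 1), loci_per_chromosome)
        pos = np.tile(np.arange(loci_per_chromosome) * spacing_cM, n_chromosomes)
        return GeneticMap(chrom, pos)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"locus_id": self.locus_id, "chromosome": self.chromosome, "position_cM": self.position_cM}
        )

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "GeneticMap":
        return GeneticMap(
            chromosome=df["chromosome"].to_numpy(),
            position_cM=df["position_cM"].to_numpy(),
            locus_id=[str(x) for x in df["locus_id"]],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path) -> "GeneticMap":
        return GeneticMap.from_frame(pd.read_csv(path, sep="\t"))


def haldane_recombination_fraction(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Map distance (cM) -> recombination fraction, Haldane (no interference)."""
    d = np.asarray(d_cM, dtype=float) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d))
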