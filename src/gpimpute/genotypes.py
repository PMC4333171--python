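"""Genotype containers and file formats.

Genotypes are biallelic SNP codes 0/1/2 counting copies of a designated
allele per locus (after :func:`recode_by_major_allele`, the sample-major
allele). Missing entries are coded ``-1`` internally and ``NA`` on disk.

Two on-disk dialects are supported and round-trip losslessly for codes,
individual ids and positions:

* TSV — tab-separated, header row of locus ids, first column ``individual_id``;
* VCF 4.2 — GT field only, one sample column per individual, where the code
  counts ALT-allele copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gmap import GeneticMap

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "recode_by_major_allele",
]

MISSING: int = -1


class GenotypeParseError(ValueError):
    """Malformed genotype file; carries the offending line number when known."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of 0/1/2 codes with locus metadata.

    ``codes`` is int8 with :data:`MISSING` (-1) for unobserved entries.
    ``loci`` holds at least ``locus_id``, ``chromosome`` and ``position_cM``
    columns, in the matrix column order.
    """

    codes: np.ndarray
    individual_ids: list[str]
    loci: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x loci)")
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype codes outside {{0,1,2,missing}}")
        if len(self.individual_ids) != self.codes.shape[0]:
            raise ValueError("individual_ids length does not match row count")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicated individual ids")
        if len(self.loci) != self.codes.shape[1]:
            raise ValueError("loci metadata length does not match column count")
        if self.loci["locus_id"].duplicated().any():
            raise ValueError("duplicated locus ids")
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    @property
    def locus_ids(self) -> list[str]:
        return [str(x) for x in self.loci["locus_id"]]

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def allele_frequency(self) -> np.ndarray:
        """Per-locus frequency of the counted allele, ignoring missing."""
        codes = np.ma.masked_equal(self.codes, MISSING)
        return np.asarray(codes.mean(axis=0) / 2.0)

    def call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    def subset_loci(self, indices) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            codes=self.codes[:, indices].copy(),
            individual_ids=list(self.individual_ids),
            loci=self.loci.iloc[indices].reset_index(drop=True),
        )

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        index = {iid: i for i, iid in enumerate(self.individual_ids)}
        rows = [index[i] for i in ids]
        return GenotypeMatrix(
            codes=self.codes[rows].copy(), individual_ids=list(ids), loci=self.loci.copy()
        )

    def genetic_map(self) -> GeneticMap:
        return GeneticMap(
            chromosome=self.loci["chromosome"].to_numpy(),
            position_cM=self.loci["position_cM"].to_numpy(),
            locus_id=self.locus_ids,
        )

    def dosage(self, fill: str = "mean") -> np.ndarray:
        """Float copy with missing entries imputed by the locus mean (or 1.0)."""
        x = self.codes.astype(float)
        miss = self.missing_mask()
        if miss.any():
            if fill == "mean":
                col_mean = np.where(miss, np.nan, x).astype(float)
                means = np.nanmean(col_mean, axis=0)
                means = np.where(np.isnan(means), 1.0, means)
            else:
                means = np.full(self.n_loci, 1.0)
            x[miss] = np.broadcast_to(means, x.shape)[miss]
        return x


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def _write_tsv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        np.where(g.codes == MISSING, None, g.codes),
        index=pd.Index(g.individual_ids, name="individual_id"),
        columns=g.locus_ids,
    )
    df.to_csv(path, sep="\t", na_rep="NA")


def _read_tsv(path, loci: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=str)
    codes = np.full(df.shape, MISSING, dtype=np.int8)
    arr = df.to_numpy()
    for v, code in (("0", 0), ("1", 1), ("2", 2)):
        codes[arr == v] = code
    unknown = (~pd.isna(arr)) & ~np.isin(arr, ["0", "1", "2"])
    if unknown.any():
        r, c = np.argwhere(unknown)[0]
        raise GenotypeParseError(
            f"unknown genotype symbol {arr[r, c]!r} at line {r + 2}, column {c + 2}"
        )
    if df.index.duplicated().any():
        raise GenotypeParseError("duplicated individual ids")
    if loci is None:
        loci = pd.DataFrame(
            {
                "locus_id": list(df.columns),
                "chromosome": 1,
                "position_cM": np.arange(df.shape[1], dtype=float),
            }
        )
    return GenotypeMatrix(codes=codes, individual_ids=[str(i) for i in df.index], loci=loci)


# ---------------------------------------------------------------------------
# VCF 4.2 (GT only). The counted allele is written as ALT, so the code equals
# the ALT dosage on both sides of the round trip.
# ---------------------------------------------------------------------------

def _write_vcf(g: GenotypeMatrix, path) -> None:
    chrom = g.loci["chromosome"].to_numpy()
    # positions written in integer "map units" (cM * 1e4) to stay lossless
    pos = np.round(g.loci["position_cM"].to_numpy() * 1e4).astype(np.int64) + 1
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##INFO=<ID=CM,Number=1,Type=Float,Description=\"Map position in cM\">\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for j in range(g.n_loci):
            cm = g.loci["position_cM"].iloc[j]
            row = "\t".join(gt_strings[int(c)] for c in g.codes[:, j])
            fh.write(
                f"{chrom[j]}\t{pos[j]}\t{g.loci['locus_id'].iloc[j]}\tA\tG\t.\t.\tCM={cm:.6g}\tGT\t{row}\n"
            )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids: list[str] = []
    chroms: list[int] = []
    cms: list[float] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        codes = np.empty(len(samples), dtype=np.int8)
        for k, (a, b, *_phase) in enumerate(variant.genotypes):
            if a < 0 or b < 0:
                codes[k] = MISSING
            elif a <= 1 and b <= 1:
                codes[k] = a + b  # "0/1","1/0","0|1" all -> 1
            else:
                raise GenotypeParseError(
                    f"{variant.ID or variant.POS}: non-biallelic allele index in GT"
                )
        cm = variant.INFO.get("CM")
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(int(variant.CHROM))
        cms.append(float(cm) if cm is not None else (variant.POS - 1) / 1e4)
        columns.append(codes)
    vcf.close()
    loci = pd.DataFrame({"locus_id": ids, "chromosome": chroms, "position_cM": cms})
    return GenotypeMatrix(
        codes=np.column_stack(columns) if columns else np.empty((len(samples), 0), np.int8),
        individual_ids=[str(s) for s in samples],
        loci=loci,
    )


def read_genotypes(path, format: str = "tsv", loci: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from ``tsv`` or ``vcf``."""
    if format == "tsv":
        return _read_tsv(path, loci=loci)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path, format: str = "tsv") -> None:
    if format == "tsv":
        _write_tsv(g, path)
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Major-allele recoding
# ---------------------------------------------------------------------------

def recode_by_major_allele(g: GenotypeMatrix) -> tuple[GenotypeMatrix, np.ndarray]:
    """Flip codes so they count the sample-major allele at every locus.

    A locus whose counted-allele frequency is below 0.5 has its codes flipped
    ``c -> 2 - c``. Exact 50/50 ties keep the incoming coding (the allele
    first seen counts). Missing entries are untouched. Returns the recoded
    matrix and the boolean per-locus flip indicator; monomorphic loci are
    legal and come out all-0 or all-2.
    """
    freq = g.allele_frequency()
    flip = freq < 0.5
    codes = g.codes.copy()
    if flip.any():
        cols = codes[:, flip]
        obs = cols != MISSING
        cols[obs] = 2 - cols[obs]
        codes[:, flip] = cols
    loci = g.loci.copy()
    loci["flipped_to_major"] = flip
    return replace(g, codes=codes, loci=loci), flip
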