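"""Simulation of pedigreed outbred populations and complex-trait phenotypes.

The generator emulates a heterogeneous-stock design: a small set of fully
inbred founder strains is crossed and randomly mated for several
generations, and the last generation is organised into full-sib families
whose members share a cage (with an occasional split cage). Meiosis follows
the Haldane model — crossovers in disjoint map intervals are independent,
with recombination fraction ``0.5(1 - exp(-2d))`` for an interval of ``d``
Morgans.

Phenotypes are built from fixed covariate effects (age, gender, month, cage
density), additive / dominance / pairwise-epistatic genetic values at a set
of QTL, a random cage effect and a Gaussian residual. Each genetic component
is rescaled to its target variance exactly, so the realised narrow-sense
heritability matches the requested architecture up to residual sampling
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmap import GeneticMap, InvalidMapError, haldane_recombination_fraction
from .genotypes import GenotypeMatrix

__all__ = [
    "Pedigree",
    "TraitArchitecture",
    "CovariatePlan",
    "PopulationSim",
    "SimulatedStudy",
    "simulate_population",
    "simulate_phenotypes",
    "simulate_study",
    "write_phased_vcf",
]

UNKNOWN_PARENT = ""


@dataclass
class Pedigree:
    """Individual/sire/dam records ordered parents-before-offspring.

    ``table`` columns: individual_id, sire_id, dam_id, generation,
    family_id, cage_id. Founders carry empty parent ids; family and cage
    ids are assigned only in the final (study) generation.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        ids = list(t["individual_id"])
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated individual ids in pedigree")
        seen: set[str] = set()
        for _, row in t.iterrows():
            for parent in (row["sire_id"], row["dam_id"]):
                if parent not in (UNKNOWN_PARENT, None) and not pd.isna(parent):
                    if parent == row["individual_id"]:
                        raise ValueError(f"{parent} is its own parent")
                    if parent not in seen:
                        raise ValueError(
                            f"parent {parent} of {row['individual_id']} does not precede it"
                        )
            seen.add(row["individual_id"])
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["individual_id"])

    def families(self, ids=None) -> pd.Series:
        """family_id indexed by individual_id (NaN outside the study generation)."""
        fam = self.table.set_index("individual_id")["family_id"]
        return fam.loc[list(ids)] if ids is not None else fam

    def parent_indices(self) -> np.ndarray:
        """(n, 2) integer positions of sire and dam, -1 for unknown."""
        pos = {iid: i for i, iid in enumerate(self.ids)}
        out = np.full((len(self), 2), -1, dtype=int)
        for i, (s, d) in enumerate(zip(self.table["sire_id"], self.table["dam_id"])):
            if s not in (UNKNOWN_PARENT, None) and not pd.isna(s):
                out[i, 0] = pos[s]
            if d not in (UNKNOWN_PARENT, None) and not pd.isna(d):
                out[i, 1] = pos[d]
        return out

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @staticmethod
    def read_csv(path) -> "Pedigree":
        t = pd.read_csv(path, dtype={"individual_id": str, "sire_id": str, "dam_id": str})
        t[["sire_id", "dam_id"]] = t[["sire_id", "dam_id"]].fillna(UNKNOWN_PARENT)
        return Pedigree(t)


@dataclass(frozen=True)
class TraitArchitecture:
    """Variance-component targets for a simulated trait (phenotype scale)."""

    n_qtl: int = 30
    additive_variance: float = 1.0
    dominance_variance: float = 0.0
    epistatic_variance: float = 0.0
    cage_variance: float = 0.0
    residual_variance: float = 1.0
    qtl_effect_distribution: str = "normal"  # or "laplace"

    def __post_init__(self) -> None:
        for name in (
            "additive_variance",
            "dominance_variance",
            "epistatic_variance",
            "cage_variance",
            "residual_variance",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be at least 1")

    @property
    def total_variance(self) -> float:
        return (
            self.additive_variance
            + self.dominance_variance
            + self.epistatic_variance
            + self.cage_variance
            + self.residual_variance
        )

    @property
    def heritability(self) -> float:
        return self.additive_variance / self.total_variance


@dataclass(frozen=True)
class CovariatePlan:
    """Fixed-effect covariates attached to every study individual."""

    intercept: float = 20.0
    age_weeks: tuple[int, int] = (6, 10)
    age_effect: float = 0.5
    gender_effect: float = 2.0
    n_months: int = 6
    month_effect_sd: float = 0.5
    density_range: tuple[int, int] = (2, 8)
    density_effect: float = -0.2


@dataclass
class PopulationSim:
    """Pedigree plus phased haplotypes for every simulated individual."""

    pedigree: Pedigree
    haplotypes: np.ndarray  # (n_individuals, n_loci, 2) alleles 0/1
    gmap: GeneticMap

    def study_ids(self) -> list[str]:
        t = self.pedigree.table
        last = t["generation"].max()
        return list(t.loc[t["generation"] == last, "individual_id"])

    def study_haplotypes(self) -> tuple[list[str], np.ndarray]:
        ids = self.study_ids()
        pos = {iid: i for i, iid in enumerate(self.pedigree.ids)}
        rows = [pos[i] for i in ids]
        return ids, self.haplotypes[rows]

    def study_genotypes(self) -> GenotypeMatrix:
        ids, haps = self.study_haplotypes()
        loci = self.gmap.to_frame()[["locus_id", "chromosome", "position_cM"]]
        return GenotypeMatrix(
            codes=haps.sum(axis=2).astype(np.int8), individual_ids=ids, loci=loci
        )


@dataclass
class SimulatedStudy:
    """A simulated population with phenotypes — the unit the pipeline consumes."""

    genotypes: GenotypeMatrix
    haplotypes: np.ndarray  # phased study-generation haplotypes, same row order
    pedigree: Pedigree
    phenotypes: pd.DataFrame  # individual_id, trait, age, gender, month, cage_density, cage_id
    true_breeding_values: np.ndarray
    true_qtl_effects: pd.DataFrame  # locus index + additive effect
    architecture: TraitArchitecture = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _meiosis(parent_haps: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a phased parent, with Haldane recombination."""
    gamete = np.empty(gmap.n_loci, dtype=np.int8)
    for chrom in gmap.chromosomes:
        sl = gmap.chromosome_slice(chrom)
        n = sl.stop - sl.start
        r = haldane_recombination_fraction(gmap.interval_distances_cM(chrom))
        switch = rng.random(n - 1) < r
        which = np.empty(n, dtype=np.int8)
        which[0] = rng.integers(2)
        which[1:] = (which[0] + np.cumsum(switch)) % 2
        sub = parent_haps[sl]
        gamete[sl] = sub[np.arange(n), which]
    return gamete


def simulate_population(
    gmap: GeneticMap,
    n_strains: int = 8,
    n_families: int = 60,
    litter_size: int = 10,
    n_generations: int = 3,
    seed: int = 0,
    n_intermediate: int | None = None,
    founder_allele_freq: float = 0.5,
    split_cage_fraction: float = 0.1,
) -> PopulationSim:
    """Gene-drop a pedigreed population descended from inbred strains.

    Generation 0 holds ``n_strains`` fully homozygous founders (one pair of
    identical gametes each); generations 1..n_generations-1 are produced by
    random mating (sire != dam, no selfing); the final generation consists of
    ``n_families`` full-sib litters of ``litter_size``, with cage assignment
    equal to family except for a ``split_cage_fraction`` of families whose
    litter is split over two cages.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 founder strains")
    if n_generations < 1:
        raise ValueError("need at least 1 generation of offspring")
    if litter_size < 1 or n_families < 1:
        raise ValueError("litter_size and n_families must be positive")
    for chrom in gmap.chromosomes:
        if gmap.chromosome_slice(chrom).stop - gmap.chromosome_slice(chrom).start < 2:
            raise InvalidMapError(f"chromosome {chrom} has fewer than 2 loci")

    rng = np.random.default_rng(seed)
    n_loci = gmap.n_loci
    if n_intermediate is None:
        # enough prospective parents that full-sib families get distinct pairs
        n_intermediate = max(2 * n_families, 4 * n_strains, 48)

    records: list[dict] = []
    haplotypes: list[np.ndarray] = []

    # founders: inbred strains, both gametes identical
    strain_haps = (rng.random((n_strains, n_loci)) < founder_allele_freq).astype(np.int8)
    for s in range(n_strains):
        records.append(
            dict(
                individual_id=f"F{s}",
                sire_id=UNKNOWN_PARENT,
                dam_id=UNKNOWN_PARENT,
                generation=0,
                family_id=np.nan,
                cage_id=np.nan,
            )
        )
        haplotypes.append(np.stack([strain_haps[s], strain_haps[s]], axis=1))

    prev_idx = list(range(n_strains))

    def _offspring(iid, sire_i, dam_i, gen, family, cage):
        records.append(
            dict(
                individual_id=iid,
                sire_id=records[sire_i]["individual_id"],
                dam_id=records[dam_i]["individual_id"],
                generation=gen,
                family_id=family,
                cage_id=cage,
            )
        )
        haplotypes.append(
            np.stack(
                [
                    _meiosis(haplotypes[sire_i], gmap, rng),
                    _meiosis(haplotypes[dam_i], gmap, rng),
                ],
                axis=1,
            )
        )

    for gen in range(1, n_generations):
        new_idx = []
        for k in range(n_intermediate):
            sire_i, dam_i = rng.choice(prev_idx, size=2, replace=False)
            _offspring(f"G{gen}_{k}", sire_i, dam_i, gen, np.nan, np.nan)
            new_idx.append(len(records) - 1)
        prev_idx = new_idx

    # final generation: full-sib families, cage ~ family. Parent pairs are
    # kept distinct across families (disjoint pairs when the parent pool
    # allows, never an identical pair) so families are genuine full-sib
    # groups rather than fragments of one another.
    if len(prev_idx) < 2:
        raise ValueError("not enough parents to form families")
    gen = n_generations
    split = rng.random(n_families) < split_cage_fraction
    if len(prev_idx) >= 2 * n_families:
        perm = rng.permutation(prev_idx)
        parent_pairs = [(int(perm[2 * f]), int(perm[2 * f + 1])) for f in range(n_families)]
    else:
        parent_pairs = []
        used: set[tuple[int, int]] = set()
        for _f in range(n_families):
            for _attempt in range(1000):
                s_i, d_i = (int(v) for v in rng.choice(prev_idx, size=2, replace=False))
                key = (min(s_i, d_i), max(s_i, d_i))
                if key not in used:
                    used.add(key)
                    break
            parent_pairs.append((s_i, d_i))
    for fam in range(n_families):
        sire_i, dam_i = parent_pairs[fam]
        for k in range(litter_size):
            cage = f"c{fam}" if (not split[fam] or k < litter_size // 2) else f"c{fam}b"
            _offspring(f"I{fam}_{k}", sire_i, dam_i, gen, f"fam{fam}", cage)

    table = pd.DataFrame.from_records(records)
    return PopulationSim(
        pedigree=Pedigree(table),
        haplotypes=np.stack(haplotypes, axis=0).transpose(0, 1, 2),
        gmap=gmap,
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _scaled(values: np.ndarray, target_variance: float) -> np.ndarray:
    """Center and rescale to the exact target variance (zeros if target is 0)."""
    v = values - values.mean()
    sd = v.std()
    if target_variance == 0 or sd == 0:
        return np.zeros_like(v)
    return v * np.sqrt(target_variance) / sd


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    architecture: TraitArchitecture,
    covariate_plan: CovariatePlan | None = None,
    seed: int = 0,
    trait_name: str = "trait",
) -> SimulatedStudy:
    """Attach a complex trait with the requested architecture to a population.

    QTL are drawn uniformly from the simulated loci. Additive effects come
    from ``qtl_effect_distribution``; dominance deviations act on
    heterozygotes; epistasis is a sum over random QTL pairs of products of
    centered codes. Genetic and cage components are rescaled to their exact
    target variances; the residual is drawn at its nominal variance.
    """
    plan = covariate_plan or CovariatePlan()
    rng = np.random.default_rng(seed)
    n, p = genotypes.n_individuals, genotypes.n_loci
    arch = architecture
    if arch.n_qtl > p:
        raise ValueError("more QTL requested than available loci")

    qtl = np.sort(rng.choice(p, size=arch.n_qtl, replace=False))
    X = genotypes.codes[:, qtl].astype(float)
    Xc = X - X.mean(axis=0)

    if arch.qtl_effect_distribution == "normal":
        a = rng.standard_normal(arch.n_qtl)
    elif arch.qtl_effect_distribution == "laplace":
        a = rng.laplace(size=arch.n_qtl)
    else:
        raise ValueError(f"unknown effect distribution {arch.qtl_effect_distribution!r}")

    bv = _scaled(Xc @ a, arch.additive_variance)

    d = rng.standard_normal(arch.n_qtl)
    dom = _scaled((X == 1).astype(float) @ d, arch.dominance_variance)

    n_pairs = max(arch.n_qtl // 2, 1)
    pairs = rng.choice(arch.n_qtl, size=(n_pairs, 2))
    e_eff = rng.standard_normal(n_pairs)
    epi = _scaled((Xc[:, pairs[:, 0]] * Xc[:, pairs[:, 1]]) @ e_eff, arch.epistatic_variance)

    # covariates
    age = rng.integers(plan.age_weeks[0], plan.age_weeks[1] + 1, size=n)
    gender = rng.integers(0, 2, size=n)
    month = rng.integers(1, plan.n_months + 1, size=n)
    month_effects = rng.normal(0.0, plan.month_effect_sd, size=plan.n_months)
    density = rng.integers(plan.density_range[0], plan.density_range[1] + 1, size=n)
    fixed = (
        plan.intercept
        + plan.age_effect * age
        + plan.gender_effect * gender
        + month_effects[month - 1]
        + plan.density_effect * density
    )

    cages = pedigree.table.set_index("individual_id").loc[genotypes.individual_ids, "cage_id"]
    cage_levels, cage_idx = np.unique(cages.astype(str), return_inverse=True)
    cage_vals = rng.standard_normal(len(cage_levels))
    cage_component = _scaled(cage_vals[cage_idx], arch.cage_variance)

    resid = rng.normal(0.0, np.sqrt(arch.residual_variance), size=n)

    y = fixed + bv + dom + epi + cage_component + resid
    phen = pd.DataFrame(
        {
            "individual_id": genotypes.individual_ids,
            trait_name: y,
            "age": age,
            "gender": gender,
            "month": month,
            "cage_density": density,
            "cage_id": cages.to_numpy(),
        }
    )
    return SimulatedStudy(
        genotypes=genotypes,
        haplotypes=np.empty((0,)),
        pedigree=pedigree,
        phenotypes=phen,
        true_breeding_values=bv,
        true_qtl_effects=pd.DataFrame({"locus_index": qtl, "additive_effect": a}),
        architecture=arch,
    )


def simulate_study(
    gmap: GeneticMap | None = None,
    architecture: TraitArchitecture | None = None,
    covariate_plan: CovariatePlan | None = None,
    seed: int = 0,
    trait_name: str = "trait",
    **population_kwargs,
) -> SimulatedStudy:
    """One-call study generator: population, genotypes and one trait.

    Defaults give a heterogeneous-stock-like sample of 600 study individuals
    (60 full-sib families of 10, 8 founder strains, 3 generations) on a
    uniform 300-locus map, with a body-weight-like additive architecture
    (h^2 = 0.5).
    """
    gmap = gmap or GeneticMap.uniform(n_chromosomes=5, loci_per_chromosome=60, spacing_cM=1.5)
    arch = architecture or TraitArchitecture(
        n_qtl=30,
        additive_variance=4.0,
        dominance_variance=0.0,
        epistatic_variance=0.0,
        cage_variance=1.6,
        residual_variance=2.4,
    )
    rng = np.random.default_rng(seed)
    pop_seed, phen_seed = rng.integers(2**31, size=2)
    pop = simulate_population(gmap, seed=int(pop_seed), **population_kwargs)
    geno = pop.study_genotypes()
    study = simulate_phenotypes(
        geno, pop.pedigree, arch, covariate_plan, seed=int(phen_seed), trait_name=trait_name
    )
    _, haps = pop.study_haplotypes()
    study.haplotypes = haps
    return study


BW_LIKE = TraitArchitecture(
    n_qtl=30,
    additive_variance=4.0,
    dominance_variance=0.4,
    epistatic_variance=0.4,
    cage_variance=1.6,
    residual_variance=2.4,
)
"""Higher-heritability, mostly additive trait (body-weight-like, h^2 ~ 0.45)."""

BMI_LIKE = TraitArchitecture(
    n_qtl=30,
    additive_variance=0.15,
    dominance_variance=0.05,
    epistatic_variance=0.10,
    cage_variance=0.20,
    residual_variance=0.50,
)
"""Lower-heritability trait with non-additive variance (body-mass-index-like, h^2 = 0.15)."""


def write_phased_vcf(
    haplotypes: np.ndarray, individual_ids: list[str], gmap: GeneticMap, path
) -> None:
    """Write phased haplotypes (n x loci x 2) as a VCF 4.2 with '|' GT."""
    pos = np.round(gmap.position_cM * 1e4).astype(np.int64) + 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Map position in cM">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(individual_ids)
            + "\n"
        )
        for j in range(gmap.n_loci):
            row = "\t".join(f"{haplotypes[i, j, 0]}|{haplotypes[i, j, 1]}" for i in range(len(individual_ids)))
            fh.write(
                f"{gmap.chromosome[j]}\t{pos[j]}\t{gmap.locus_id[j]}\tA\tG\t.\t.\t"
                f"CM={gmap.position_cM[j]:.6g}\tGT\t{row}\n"
            )
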