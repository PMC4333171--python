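"""Family-structured cross-validation and the full prediction experiment.

Two split layouts control the genetic relatedness between training and
testing sets: ``across_families`` assigns whole full-sib families to one
set or the other, while ``within_families`` randomizes the members of each
family between sets. Roughly 2/3 of eligible individuals (those with both
phenotype and genotype) train the models and 1/3 are predicted.

``run_experiment`` orchestrates the factorial study: for each trait,
layout and masking rate it pre-corrects phenotypes, masks the testing set
to a low-density panel, imputes it back from training-set haplotypes (the
reference never includes testing individuals), and evaluates each
prediction model under three genotype conditions — the full panel, the
imputed-to-full panel, and the reduced panel — reporting the predictive
correlation and PMSE per scenario plus an imputation accuracy report.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bl import ChainSettings, fit_bl, predict_bl
from .brann import NetworkArchitecture, predict_brann, train_brann
from .genotypes import GenotypeMatrix, recode_by_major_allele
from .impute import HmmParams, impute, mask_to_panel, score_imputation
from .precorrect import build_numerator_relationship, precorrect_phenotypes
from .qc import QCThresholds, filter_loci, select_equally_spaced
from .rkhs import build_kernels, fit_rkhs, predict_rkhs
from .simulate import BMI_LIKE, BW_LIKE, GeneticMap, Pedigree, TraitArchitecture, simulate_phenotypes, simulate_population

__all__ = [
    "SplitPlan",
    "ExperimentConfig",
    "make_split",
    "predictive_correlation",
    "pmse",
    "run_experiment",
]

LAYOUTS = ("across_families", "within_families")
GENOTYPE_SETS = ("full", "imputed", "reduced")


@dataclass(frozen=True)
class SplitPlan:
    layout: str
    training_ids: tuple[str, ...]
    testing_ids: tuple[str, ...]
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.training_ids) & set(self.testing_ids):
            raise ValueError("training and testing sets overlap")


def make_split(
    pedigree: Pedigree,
    eligible_ids: list[str],
    layout: str,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> SplitPlan:
    """Assign eligible individuals to training/testing under a family layout.

    across_families: whole families are shuffled and accumulated into the
    training set until it reaches the target fraction (no family spans both
    sets; at least one family must land on each side). within_families: each
    family's members are shuffled and round(fraction * size) of them train,
    keeping both sets populated whenever the family has >= 2 members.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    rng = np.random.default_rng(seed)
    fam = pedigree.families(eligible_ids)
    groups: dict[str, list[str]] = {}
    for iid, f in fam.items():
        groups.setdefault(str(f), []).append(iid)
    n_total = len(eligible_ids)
    target = fraction * n_total
    train: list[str] = []
    test: list[str] = []
    if layout == "across_families":
        if len(groups) < 2:
            raise ValueError("across-family layout needs at least 2 families")
        names = list(groups)
        rng.shuffle(names)
        for name in names:
            if not train or len(train) + len(groups[name]) / 2.0 <= target:
                train.extend(groups[name])
            else:
                test.extend(groups[name])
        if not test:  # keep at least one family out
            last = names[-1]
            train = [i for i in train if i not in set(groups[last])]
            test = list(groups[last])
    else:
        for name in sorted(groups):
            members = list(groups[name])
            rng.shuffle(members)
            k = int(round(fraction * len(members)))
            if len(members) >= 2:
                k = min(max(k, 1), len(members) - 1)
            train.extend(members[:k])
            test.extend(members[k:])
    return SplitPlan(
        layout=layout,
        training_ids=tuple(train),
        testing_ids=tuple(test),
        fraction=fraction,
        seed=seed,
    )


def predictive_correlation(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Pearson correlation between predictions and observations (NaN if degenerate)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed) or len(predicted) < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if predicted.std() == 0 or observed.std() == 0:
        return float("nan")
    return float(np.corrcoef(predicted, observed)[0, 1])


def pmse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Prediction mean squared error."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed):
        raise ValueError("length mismatch")
    return float(np.mean((predicted - observed) ** 2))


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """A scaled, fully synthetic rendition of the factorial study design."""

    traits: dict[str, TraitArchitecture] = field(
        default_factory=lambda: {"BW": BW_LIKE, "BMI": BMI_LIKE}
    )
    layouts: tuple[str, ...] = LAYOUTS
    masking_rates: tuple[float, ...] = (0.5, 0.75, 0.9)
    models: tuple[str, ...] = ("BL", "RKHS", "BRANN")
    genotype_sets: tuple[str, ...] = GENOTYPE_SETS
    train_fraction: float = 2.0 / 3.0
    # imputation-accuracy scoring can run on a target subsample when the
    # "imputed" genotype set (which needs every target) is not requested
    max_scoring_targets: int | None = None
    seed: int = 0
    # simulator dimensions (study defaults: 600 individuals x 300 loci)
    n_chromosomes: int = 5
    loci_per_chromosome: int = 60
    spacing_cM: float = 1.5
    n_strains: int = 8
    n_families: int = 60
    litter_size: int = 10
    n_generations: int = 3
    # model settings (test-scale chains; full-scale values go here explicitly)
    chain: ChainSettings = field(default_factory=lambda: ChainSettings(n_iter=4000, burn_in=1000, thin=5))
    brann_epochs: int = 30
    brann_restarts: int = 5
    brann_hidden: int = 5
    hmm: HmmParams = field(default_factory=lambda: HmmParams(max_reference_haplotypes=120))
    qc: QCThresholds = field(default_factory=QCThresholds)


def _counted_allele_haplotypes(haplotypes: np.ndarray, kept: np.ndarray, flipped: np.ndarray) -> np.ndarray:
    """Study haplotypes restricted to QC loci, on the counted-allele scale."""
    h = haplotypes[:, kept, :]
    h = np.where(flipped[None, :, None], 1 - h, h)
    return h


def _fit_model(
    model: str,
    y_train: np.ndarray,
    X_train: np.ndarray,
    cfg: ExperimentConfig,
    seed: int,
):
    """Train one model; return (predict(X_new) closure, diagnostics dict)."""
    settings = ChainSettings(
        n_iter=cfg.chain.n_iter, burn_in=cfg.chain.burn_in, thin=cfg.chain.thin, seed=seed
    )
    if model == "BL":
        post = fit_bl(y_train, X_train, settings=settings)
        return (lambda Xn: predict_bl(post, Xn)), {}
    if model == "RKHS":
        spec = build_kernels(X_train)
        post = fit_rkhs(y_train, spec, settings=settings)
        return (lambda Xn: predict_rkhs(post, Xn)), {}
    if model == "BRANN":
        ens = train_brann(
            X_train,
            y_train,
            arch=NetworkArchitecture(n_inputs=X_train.shape[1], n_hidden=cfg.brann_hidden),
            epochs=cfg.brann_epochs,
            restarts=cfg.brann_restarts,
            seed=seed,
        )
        insample = predictive_correlation(ens.training_predictions, y_train)
        return (lambda Xn: predict_brann(ens, Xn)), {"training_correlation": insample}
    raise ValueError(f"unknown model {model!r}")


def run_experiment(config: ExperimentConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the trait x layout x masking x genotype-set x model factorial.

    Returns ``(results, imputation_report)``: one row per scenario with the
    predictive correlation and PMSE, and one row per (layout, masking rate)
    with imputation accuracy and its error decomposition. Deterministic
    given the config (including its seeds); any scenario failure is
    recorded in the ``status`` column and the run continues.
    """
    cfg = config or ExperimentConfig()
    master = np.random.default_rng(cfg.seed)
    pop_seed, phen_seed, split_seed, model_seed = (int(s) for s in master.integers(2**31, size=4))

    gmap = GeneticMap.uniform(cfg.n_chromosomes, cfg.loci_per_chromosome, cfg.spacing_cM)
    pop = simulate_population(
        gmap,
        n_strains=cfg.n_strains,
        n_families=cfg.n_families,
        litter_size=cfg.litter_size,
        n_generations=cfg.n_generations,
        seed=pop_seed,
    )
    geno_raw = pop.study_genotypes()
    study_ids, haplotypes = pop.study_haplotypes()

    geno_qc, _report = filter_loci(geno_raw, cfg.qc)
    kept = np.array([geno_raw.locus_ids.index(l) for l in geno_qc.locus_ids])
    geno, flipped = recode_by_major_allele(geno_qc)
    haps = _counted_allele_haplotypes(haplotypes, kept, flipped)
    p_full = geno.n_loci

    results: list[dict] = []
    imput_rows: list[dict] = []

    for trait_name, arch in cfg.traits.items():
        trait_seed = (phen_seed + zlib.crc32(trait_name.encode())) % (2**31)
        study = simulate_phenotypes(
            geno, pop.pedigree, arch, seed=trait_seed, trait_name=trait_name
        )
        corrected = precorrect_phenotypes(study.phenotypes, pop.pedigree, trait_name)
        y_star = corrected.as_series()
        eligible = [i for i in geno.individual_ids if i in y_star.index]

        for layout in cfg.layouts:
            split = make_split(pop.pedigree, eligible, layout, cfg.train_fraction, seed=split_seed)
            train_ids, test_ids = list(split.training_ids), list(split.testing_ids)
            y_tr = y_star.loc[train_ids].to_numpy()
            y_te = y_star.loc[test_ids].to_numpy()
            row_of = {iid: i for i, iid in enumerate(geno.individual_ids)}
            X_full = geno.codes.astype(float)
            X_tr_full = X_full[[row_of[i] for i in train_ids]]
            X_te_full = X_full[[row_of[i] for i in test_ids]]
            ref_rows = [study_ids.index(i) for i in train_ids]
            ref_haps = haps[ref_rows].transpose(0, 2, 1).reshape(-1, p_full)

            # full-panel models are shared by the "full" and "imputed"
            # conditions at every masking rate: train them once per layout
            full_models: dict[str, tuple] = {}
            if {"full", "imputed"} & set(cfg.genotype_sets):
                for model in cfg.models:
                    try:
                        full_models[model] = _fit_model(model, y_tr, X_tr_full, cfg, model_seed)
                    except Exception as exc:
                        full_models[model] = (None, {"error": str(exc)})

            def record(rate, gset, model, predictor, extra, Xte):
                row = {
                    "trait": trait_name,
                    "layout": layout,
                    "masking_rate": rate,
                    "genotype_set": gset,
                    "model": model,
                    "n_train": len(train_ids),
                    "n_test": len(test_ids),
                }
                try:
                    if predictor is None:
                        raise RuntimeError(extra.get("error", "model fit failed"))
                    pred = predictor(Xte)
                    row.update(
                        correlation=predictive_correlation(pred, y_te),
                        pmse=pmse(pred, y_te),
                        status="ok",
                        **{k: v for k, v in extra.items() if k != "error"},
                    )
                except Exception as exc:  # scenario fails, run continues
                    row.update(correlation=np.nan, pmse=np.nan, status=f"failed: {exc}")
                results.append(row)

            for rate in cfg.masking_rates:
                n_panel = max(int(round((1.0 - rate) * p_full)), 2)
                panel = select_equally_spaced(p_full, n_panel)
                need_all_targets = "imputed" in cfg.genotype_sets
                scoring_ids = test_ids
                if not need_all_targets and cfg.max_scoring_targets is not None:
                    rng = np.random.default_rng(split_seed + int(rate * 1000))
                    k = min(cfg.max_scoring_targets, len(test_ids))
                    scoring_ids = [test_ids[i] for i in rng.choice(len(test_ids), k, replace=False)]
                masked = mask_to_panel(geno, panel, scoring_ids)
                X_te_imputed = None
                if masked.mask.any():
                    imp = impute(masked, ref_haps, cfg.hmm)
                    accuracy, decomposition = score_imputation(imp, masked.truth)
                    if need_all_targets:
                        imp_rows_idx = [row_of[i] for i in test_ids]
                        X_te_imputed = imp.imputed.codes.astype(float)[imp_rows_idx]
                else:  # degenerate masking rate 0: nothing to impute
                    accuracy, decomposition = np.nan, {}
                    X_te_imputed = X_te_full
                imput_rows.append(
                    {
                        "trait": trait_name,
                        "layout": layout,
                        "masking_rate": rate,
                        "accuracy": accuracy,
                        "n_masked": int(masked.mask.sum()),
                        **{f"error_{k}": v for k, v in decomposition.items()},
                    }
                )
                cols = panel.selected_indices
                for model in cfg.models:
                    if "full" in cfg.genotype_sets:
                        predictor, extra = full_models[model]
                        record(rate, "full", model, predictor, extra, X_te_full)
                    if "imputed" in cfg.genotype_sets:
                        predictor, extra = full_models[model]
                        record(rate, "imputed", model, predictor, extra, X_te_imputed)
                    if "reduced" in cfg.genotype_sets:
                        try:
                            predictor, extra = _fit_model(
                                model, y_tr, X_tr_full[:, cols], cfg, model_seed
                            )
                        except Exception as exc:
                            predictor, extra = None, {"error": str(exc)}
                        record(rate, "reduced", model, predictor, extra, X_te_full[:, cols])
    return pd.DataFrame(results), pd.DataFrame(imput_rows)


def mean_cross_relationship(pedigree: Pedigree, split: SplitPlan) -> float:
    """Mean additive relationship between training and testing individuals."""
    A = build_numerator_relationship(pedigree)
    pos = {iid: i for i, iid in enumerate(pedigree.ids)}
    tr = [pos[i] for i in split.training_ids]
    te = [pos[i] for i in split.testing_ids]
    return float(A[np.ix_(tr, te)].mean())
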