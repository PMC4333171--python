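"""Genotype masking and haplotype-HMM imputation.

Target individuals are reduced to a low-density panel and imputed back to
the full panel with a diploid Li-Stephens model: each target genotype
sequence is modelled as an ordered pair of mosaic copies of reference
haplotypes. Per haplotype, the hidden copied-from index switches between
adjacent loci with probability ``1 - exp(-switch_rate * d_cM)`` (and is
redrawn uniformly at chromosome boundaries), and observed panel genotypes
are emitted through a per-allele error rate ``epsilon``. Posterior genotype
probabilities at every locus come from the forward-backward algorithm over
the K x K haplotype-pair state space; the imputed code is the posterior
mode. The imputer uses reference haplotypes only — pedigree information is
deliberately ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .qc import PanelSelection

__all__ = [
    "HmmParams",
    "MaskedSet",
    "ImputationResult",
    "mask_to_panel",
    "impute",
    "score_imputation",
]

ERROR_CATEGORIES = ("0<->1", "1<->2", "0<->2")


@dataclass(frozen=True)
class HmmParams:
    """Tuning knobs of the Li-Stephens imputer.

    epsilon: per-allele emission error rate (guards zero-probability paths).
    switch_rate_per_cM: haplotype-switch intensity; 0.1/cM gives expected
    mosaic blocks of ~10 cM, a few generations of recombination.
    max_reference_haplotypes: reference subsample cap (seeded) for runtime.
    """

    epsilon: float = 0.01
    switch_rate_per_cM: float = 0.1
    max_reference_haplotypes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.switch_rate_per_cM < 0:
            raise ValueError("switch rate must be non-negative")


@dataclass
class MaskedSet:
    """Targets reduced to a panel, with the hidden truth retained for scoring."""

    observed: GenotypeMatrix  # full-panel shape; non-panel entries of targets MISSING
    mask: np.ndarray  # bool, individuals x loci, True where hidden
    truth: np.ndarray  # codes at masked entries, MISSING elsewhere
    panel: PanelSelection
    target_ids: list[str]

    @property
    def masking_rate(self) -> float:
        return self.panel.masking_rate


@dataclass
class ImputationResult:
    """Imputed full-panel matrix with per-entry genotype posteriors."""

    imputed: GenotypeMatrix
    genotype_posteriors: np.ndarray  # n_targets x n_loci x 3
    target_ids: list[str]
    mask: np.ndarray
    accuracy: float | None = None
    error_decomposition: dict[str, float] = field(default_factory=dict)


def mask_to_panel(
    full: GenotypeMatrix, panel: PanelSelection, target_ids: list[str]
) -> MaskedSet:
    """Hide non-panel genotypes of the target individuals.

    Reference individuals keep all loci; each target keeps only the panel
    loci. The hidden codes are retained (for scoring only) and a
    masking-then-unmasking round trip restores the input exactly.
    """
    if panel.n_full != full.n_loci:
        raise ValueError("panel was built for a different panel size")
    targets = set(target_ids)
    unknown = targets - set(full.individual_ids)
    if unknown:
        raise ValueError(f"target ids not in genotype matrix: {sorted(unknown)[:3]}...")
    target_rows = np.array([iid in targets for iid in full.individual_ids])
    panel_cols = np.zeros(full.n_loci, dtype=bool)
    panel_cols[panel.selected_indices] = True
    mask = target_rows[:, None] & ~panel_cols[None, :]
    codes = full.codes.copy()
    truth = np.full_like(codes, MISSING)
    truth[mask] = codes[mask]
    codes[mask] = MISSING
    observed = GenotypeMatrix(codes=codes, individual_ids=list(full.individual_ids), loci=full.loci.copy())
    return MaskedSet(observed=observed, mask=mask, truth=truth, panel=panel, target_ids=list(target_ids))


def _emission_matrix(epsilon: float) -> np.ndarray:
    """E[true_dosage, observed_code] under independent per-allele errors."""
    e, c = epsilon, 1.0 - epsilon
    return np.array(
        [
            [c * c, 2 * e * c, e * e],
            [e * c, c * c + e * e, e * c],
            [e * e, 2 * e * c, c * c],
        ]
    )


def _switch_probabilities(loci: pd.DataFrame, rate: float) -> np.ndarray:
    """Per-interval haplotype switch probability; 1.0 across chromosomes."""
    chrom = loci["chromosome"].to_numpy()
    pos = loci["position_cM"].to_numpy(dtype=float)
    d = np.diff(pos)
    r = 1.0 - np.exp(-rate * np.maximum(d, 0.0))
    r[chrom[1:] != chrom[:-1]] = 1.0
    return r


def _pair_transition(F: np.ndarray, r: float) -> np.ndarray:
    """Apply the separable pair transition T' F T for T = (1-r)I + (r/K)J."""
    if r == 0.0:
        return F
    K = F.shape[0]
    s = 1.0 - r
    u = r / K
    row = F.sum(axis=1, keepdims=True)  # over second haplotype
    col = F.sum(axis=0, keepdims=True)
    tot = row.sum()
    return s * s * F + s * u * (row + col) + u * u * tot


def _forward_backward_posteriors(
    obs: np.ndarray, H: np.ndarray, r: np.ndarray, Em: np.ndarray
) -> np.ndarray:
    """Genotype posteriors (L x 3) for one target given reference haplotypes H (K x L)."""
    K, L = H.shape
    u = H.astype(float)  # allele-1 indicator per (haplotype, locus)

    def emission_weights(l: int, g: int) -> np.ndarray:
        # W_ab = Em[u_a + u_b, g], written as a quadratic in the indicators
        e0, e1, e2 = Em[0, g], Em[1, g], Em[2, g]
        ul = u[:, l]
        return e0 + (e1 - e0) * (ul[:, None] + ul[None, :]) + (e2 - 2 * e1 + e0) * np.outer(ul, ul)

    alphas = np.empty((L, K, K))
    F = np.full((K, K), 1.0 / (K * K))
    for l in range(L):
        if l > 0:
            F = _pair_transition(F, r[l - 1])
        g = obs[l]
        if g != MISSING:
            F = F * emission_weights(l, g)
        tot = F.sum()
        if tot <= 0:
            raise FloatingPointError(f"zero forward probability at locus {l}")
        F /= tot
        alphas[l] = F
    # backward, collapsing genotype posteriors on the fly
    post = np.empty((L, 3))
    B = np.ones((K, K))
    for l in range(L - 1, -1, -1):
        G = alphas[l] * B
        G /= G.sum()
        ul = u[:, l]
        Gu = G @ ul
        p11 = float(ul @ Gu)
        p00 = float((1.0 - ul) @ (G.sum(axis=1) - Gu))
        post[l] = (p00, max(1.0 - p00 - p11, 0.0), p11)
        if l > 0:
            g = obs[l]
            if g != MISSING:
                B = B * emission_weights(l, g)
            B = _pair_transition(B, r[l - 1])  # T is symmetric: same operator
            B /= B.max()
    return post


def impute(
    masked: MaskedSet,
    reference_haplotypes: np.ndarray,
    params: HmmParams | None = None,
) -> ImputationResult:
    """Impute masked genotypes of every target from reference haplotypes.

    ``reference_haplotypes`` is (n_haplotypes x n_full_loci) with alleles
    0/1 on the counted-allele scale of the genotype codes. Deterministic
    given inputs and ``params.seed`` (used only for reference subsampling).
    """
    params = params or HmmParams()
    Href = np.asarray(reference_haplotypes)
    if Href.ndim != 2 or Href.shape[1] != masked.observed.n_loci:
        raise ValueError("reference haplotypes do not cover the full panel loci")
    if Href.shape[0] < 2:
        raise ValueError("need at least 2 reference haplotypes")
    if Href.shape[0] > params.max_reference_haplotypes:
        rng = np.random.default_rng(params.seed)
        rows = rng.choice(Href.shape[0], size=params.max_reference_haplotypes, replace=False)
        Href = Href[np.sort(rows)]
    Em = _emission_matrix(params.epsilon)
    r = _switch_probabilities(masked.observed.loci, params.switch_rate_per_cM)

    row_of = {iid: i for i, iid in enumerate(masked.observed.individual_ids)}
    L = masked.observed.n_loci
    n_t = len(masked.target_ids)
    posteriors = np.empty((n_t, L, 3))
    imputed_codes = masked.observed.codes.copy()
    for t, iid in enumerate(masked.target_ids):
        i = row_of[iid]
        post = _forward_backward_posteriors(masked.observed.codes[i], Href, r, Em)
        posteriors[t] = post
        calls = post.argmax(axis=1).astype(np.int8)
        hidden = masked.mask[i]
        imputed_codes[i, hidden] = calls[hidden]
    imputed = GenotypeMatrix(
        codes=imputed_codes,
        individual_ids=list(masked.observed.individual_ids),
        loci=masked.observed.loci.copy(),
    )
    return ImputationResult(
        imputed=imputed,
        genotype_posteriors=posteriors,
        target_ids=list(masked.target_ids),
        mask=masked.mask,
    )


def score_imputation(result: ImputationResult, truth: np.ndarray) -> tuple[float, dict[str, float]]:
    """Accuracy at masked entries and the three-way error decomposition.

    Accuracy is the fraction of masked entries whose imputed code equals the
    truth. The decomposition is computed over erroneous entries only —
    proportions of 0<->1, 1<->2 and 0<->2 code switches summing to 1 — and
    is empty when there are no errors. Also fills the corresponding fields
    of ``result``.
    """
    mask = result.mask
    n_masked = int(mask.sum())
    if n_masked == 0:
        raise ValueError("no masked entries to score")
    imput = result.imputed.codes[mask]
    true = truth[mask]
    correct = imput == true
    accuracy = float(correct.mean())
    decomposition: dict[str, float] = {}
    errors = ~correct
    if errors.any():
        lo = np.minimum(imput[errors], true[errors])
        hi = np.maximum(imput[errors], true[errors])
        counts = {
            "0<->1": int(((lo == 0) & (hi == 1)).sum()),
            "1<->2": int(((lo == 1) & (hi == 2)).sum()),
            "0<->2": int(((lo == 0) & (hi == 2)).sum()),
        }
        total = sum(counts.values())
        decomposition = {k: v / total for k, v in counts.items()}
    result.accuracy = accuracy
    result.error_decomposition = decomposition
    return accuracy, decomposition
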