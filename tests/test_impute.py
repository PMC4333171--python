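"""Masking, Li-Stephens imputation and its scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gpimpute.genotypes import MISSING, GenotypeMatrix
from gpimpute.impute import (
    HmmParams,
    ImputationResult,
    _emission_matrix,
    _switch_probabilities,
    impute,
    mask_to_panel,
    score_imputation,
)
from gpimpute.qc import PanelSelection, select_equally_spaced

from conftest import random_genotypes


def _matrix(codes, positions=None):
    codes = np.asarray(codes, dtype=np.int8)
    p = codes.shape[1]
    loci = pd.DataFrame(
        {
            "locus_id": [f"m{j}" for j in range(p)],
            "chromosome": 1,
            "position_cM": positions if positions is not None else np.arange(p, dtype=float),
        }
    )
    return GenotypeMatrix(
        codes=codes, individual_ids=[f"i{k}" for k in range(codes.shape[0])], loci=loci
    )


class TestMasking:
    def test_full_panel_masks_nothing(self):
        rng = np.random.default_rng(0)
        g = random_genotypes(rng, 5, 10)
        masked = mask_to_panel(g, select_equally_spaced(10, 10), ["i0", "i1"])
        assert masked.mask.sum() == 0
        assert masked.masking_rate == 0.0

    def test_masked_count_per_target(self):
        rng = np.random.default_rng(1)
        g = random_genotypes(rng, 6, 20)
        panel = select_equally_spaced(20, 5)
        masked = mask_to_panel(g, panel, ["i2", "i3"])
        # each target hides exactly the non-panel loci
        assert masked.mask[2].sum() == 15
        assert masked.mask[3].sum() == 15
        assert masked.mask[[0, 1, 4, 5]].sum() == 0

    def test_round_trip_restores_matrix(self):
        rng = np.random.default_rng(2)
        g = random_genotypes(rng, 5, 12)
        masked = mask_to_panel(g, select_equally_spaced(12, 3), ["i0"])
        restored = masked.observed.codes.copy()
        restored[masked.mask] = masked.truth[masked.mask]
        np.testing.assert_array_equal(restored, g.codes)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            PanelSelection(selected_indices=np.array([], dtype=int), n_full=5)


def enumeration_posteriors(obs, H, r, Em):
    """Exhaustive-path oracle: sum over every (path1, path2) pair of the
    joint probability, then collapse to genotype posteriors per locus."""
    K, L = H.shape
    posts = np.zeros((L, 3))
    total = 0.0
    for path1 in itertools.product(range(K), repeat=L):
        for path2 in itertools.product(range(K), repeat=L):
            prob = 1.0 / (K * K)
            for l in range(1, L):
                for prev, cur in ((path1[l - 1], path1[l]), (path2[l - 1], path2[l])):
                    p_stay = (1.0 - r[l - 1]) + r[l - 1] / K
                    prob *= p_stay if prev == cur else r[l - 1] / K
            for l in range(L):
                if obs[l] != MISSING:
                    prob *= Em[H[path1[l], l] + H[path2[l], l], obs[l]]
            total += prob
            for l in range(L):
                posts[l, H[path1[l], l] + H[path2[l], l]] += prob
    return posts / total


class TestHmmImputation:
    def test_posteriors_match_exhaustive_enumeration(self):
        H = np.array([[0, 1, 0], [1, 1, 1]], dtype=np.int8)  # 2 haplotypes x 3 loci
        params = HmmParams(epsilon=0.05, switch_rate_per_cM=0.2)
        g = _matrix([[1, MISSING, 2]], positions=[0.0, 2.0, 5.0])
        masked = mask_to_panel(g, select_equally_spaced(3, 2), ["i0"])
        result = impute(masked, H, params)
        Em = _emission_matrix(params.epsilon)
        r = _switch_probabilities(g.loci, params.switch_rate_per_cM)
        oracle = enumeration_posteriors(masked.observed.codes[0], H, r, Em)
        np.testing.assert_allclose(result.genotype_posteriors[0], oracle, atol=1e-10)

    def test_posteriors_sum_to_one_and_call_is_argmax(self, qc_study):
        g = qc_study["genotypes"]
        haps = qc_study["haplotypes"]
        panel = select_equally_spaced(g.n_loci, g.n_loci // 4)
        targets = g.individual_ids[:5]
        ref = haps[20:80].transpose(0, 2, 1).reshape(-1, g.n_loci)
        masked = mask_to_panel(g, panel, targets)
        result = impute(masked, ref, HmmParams(max_reference_haplotypes=60))
        np.testing.assert_allclose(result.genotype_posteriors.sum(axis=2), 1.0, atol=1e-8)
        calls = result.genotype_posteriors.argmax(axis=2)
        for t in range(len(targets)):
            i = g.individual_ids.index(targets[t])
            np.testing.assert_array_equal(
                result.imputed.codes[i][masked.mask[i]], calls[t][masked.mask[i]]
            )

    def test_reference_order_is_irrelevant(self):
        rng = np.random.default_rng(3)
        H = rng.integers(0, 2, size=(6, 8)).astype(np.int8)
        g = _matrix(rng.integers(0, 3, size=(2, 8)))
        masked = mask_to_panel(g, select_equally_spaced(8, 4), ["i1"])
        params = HmmParams()
        a = impute(masked, H, params).genotype_posteriors
        b = impute(masked, H[::-1].copy(), params).genotype_posteriors
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_target_present_in_reference_is_recovered(self):
        # target duplicates a reference homozygote pair: truth is in the panel
        rng = np.random.default_rng(4)
        hap = rng.integers(0, 2, size=20).astype(np.int8)
        other = rng.integers(0, 2, size=(4, 20)).astype(np.int8)
        H = np.vstack([hap, hap, other])
        g = _matrix((2 * hap)[None, :])
        masked = mask_to_panel(g, select_equally_spaced(20, 10), ["i0"])
        result = impute(masked, H, HmmParams(epsilon=1e-4, switch_rate_per_cM=0.01))
        accuracy, _ = score_imputation(result, masked.truth)
        assert accuracy == 1.0

    def test_reference_must_cover_all_loci(self):
        g = _matrix(np.zeros((1, 5)))
        masked = mask_to_panel(g, select_equally_spaced(5, 2), ["i0"])
        with pytest.raises(ValueError):
            impute(masked, np.zeros((4, 3), dtype=np.int8))
        with pytest.raises(ValueError):
            impute(masked, np.zeros((1, 5), dtype=np.int8))


class TestScoring:
    def _result(self, imputed_codes, mask):
        g = _matrix(imputed_codes)
        return ImputationResult(
            imputed=g,
            genotype_posteriors=np.zeros((1, g.n_loci, 3)),
            target_ids=["i0"],
            mask=mask,
        )

    def test_all_correct_has_empty_decomposition(self):
        codes = np.array([[0, 1, 2, 1]], dtype=np.int8)
        mask = np.array([[True, True, True, True]])
        result = self._result(codes, mask)
        accuracy, decomposition = score_imputation(result, codes.copy())
        assert accuracy == 1.0
        assert decomposition == {}

    def test_error_decomposition_counts_switch_types(self):
        truth = np.array([[0, 1, 2, 1, 0, 2, 2, 1, 0, 2]], dtype=np.int8)
        imput = truth.copy()
        imput[0, 0] = 1  # 0 -> 1
        imput[0, 2] = 1  # 2 -> 1
        mask = np.ones_like(truth, dtype=bool)
        accuracy, decomposition = score_imputation(self._result(imput, mask), truth)
        assert accuracy == 0.8
        assert decomposition == {"0<->1": 0.5, "1<->2": 0.5, "0<->2": 0.0}

    def test_random_imputer_scores_one_third_on_balanced_truth(self):
        rng = np.random.default_rng(5)
        n = 10_000
        truth = rng.integers(0, 3, size=(1, n)).astype(np.int8)
        imput = rng.integers(0, 3, size=(1, n)).astype(np.int8)
        mask = np.ones_like(truth, dtype=bool)
        accuracy, _ = score_imputation(self._result(imput, mask), truth)
        assert abs(accuracy - 1.0 / 3.0) < 0.02

    def test_no_masked_entries_is_undefined(self):
        codes = np.array([[0, 1]], dtype=np.int8)
        with pytest.raises(ValueError):
            score_imputation(self._result(codes, np.zeros_like(codes, dtype=bool)), codes)

    def test_posterior_confidence_is_calibrated(self, qc_study):
        """Entries called with max-posterior >= 0.9 are >= 85% correct."""
        g = qc_study["genotypes"]
        haps = qc_study["haplotypes"]
        panel = select_equally_spaced(g.n_loci, g.n_loci // 2)
        targets = g.individual_ids[400:440]
        ref = haps[:200].transpose(0, 2, 1).reshape(-1, g.n_loci)
        masked = mask_to_panel(g, panel, targets)
        result = impute(masked, ref, HmmParams(max_reference_haplotypes=100))
        accuracy, _ = score_imputation(result, masked.truth)
        rows = [g.individual_ids.index(t) for t in targets]
        confident = correct = 0
        for t, i in enumerate(rows):
            post_max = result.genotype_posteriors[t].max(axis=1)
            sel = masked.mask[i] & (post_max >= 0.9)
            confident += sel.sum()
            correct += (result.imputed.codes[i][sel] == masked.truth[i][sel]).sum()
        assert confident > 100
        assert correct / confident >= 0.85
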