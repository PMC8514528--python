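"""Synthetic-cohort generator: determinism, closed-form correlations, PBI."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from traitspace.scoring import score_traits
from traitspace.synthetic import (
    GeneratorError,
    GeneratorParams,
    GroupSpec,
    SubdomainSpec,
    TraitSpec,
    build_schema,
    generate_cohort,
    generate_pbi,
    study_like_params,
    population_correlations,
    population_trait_correlations,
    toy_params,
)


def continuous_items(params):
    """Continuous (pre-discretization) item scores, re-derived from the model.

    Regenerates with noise_sd unchanged but reads the latent scores by
    reversing the equiprobable thresholds is not possible; instead this
    helper re-runs the generator pathway on a copy with a very fine scale
    so discretization is negligible.
    """
    fine = dataclasses.replace(
        params,
        traits=tuple(dataclasses.replace(t, scale=(1, 2001)) for t in params.traits),
    )
    rm, _ = generate_cohort(fine)
    return rm.values.astype(float)


class TestValidation:
    def test_bad_proportions(self):
        with pytest.raises(GeneratorError, match="sum to 1"):
            GeneratorParams(
                traits=(TraitSpec("a", 1, 3),), subject_groups=(GroupSpec(0.5), GroupSpec(0.2))
            )

    def test_bad_loading(self):
        with pytest.raises(GeneratorError, match="loading"):
            GeneratorParams(traits=(TraitSpec("a", 1, 3, loading=1.5),))

    def test_unknown_mix_with(self):
        with pytest.raises(GeneratorError, match="mix_with"):
            GeneratorParams(
                traits=(
                    TraitSpec("a", 1, 3, subdomains=(SubdomainSpec("s", 1, mix_with="ghost"),)),
                )
            )


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        p = toy_params(seed=42)
        rm1, t1 = generate_cohort(p)
        rm2, t2 = generate_cohort(p)
        assert rm1.values.equals(rm2.values)
        assert rm1.metadata.equals(rm2.metadata)
        assert t1.subject_group == t2.subject_group

    def test_different_seed_differs(self):
        rm1, _ = generate_cohort(toy_params(seed=1))
        rm2, _ = generate_cohort(toy_params(seed=2))
        assert not rm1.values.equals(rm2.values)


class TestPopulationCorrelations:
    def test_same_trait_items_r_equals_loading_squared(self):
        lam = 0.6
        p = GeneratorParams(traits=(TraitSpec("a", 1, 4, loading=lam),), n_subjects=10)
        corr = population_correlations(p)
        off = corr.values[np.triu_indices(4, k=1)]
        assert np.allclose(off, lam**2)

    def test_cross_cluster_hand_algebra(self):
        # items in different clusters: r = l1*l2*w*between for unit-variance items
        l1, l2, w, b = 0.8, 0.6, 0.5, -0.4
        p = GeneratorParams(
            traits=(TraitSpec("a", 1, 2, loading=l1), TraitSpec("b", 2, 2, loading=l2)),
            within_cluster_corr=w,
            between_cluster_corr=b,
            n_subjects=10,
        )
        corr = population_correlations(p)
        assert corr.loc["a_q01", "b_q01"] == pytest.approx(l1 * l2 * w * b, abs=1e-12)

    def test_presets_are_psd(self):
        for params in (study_like_params(0), toy_params(0)):
            corr = population_correlations(params)
            assert np.linalg.eigvalsh(corr.values).min() > -1e-8
            assert np.allclose(corr.values, corr.values.T)
            assert np.allclose(np.diag(corr.values), 1.0)

    def test_monte_carlo_convergence(self):
        # sampled correlations of continuous scores converge to the
        # closed form: max abs deviation < 0.05 at n=5000 over 10 seeds
        worst = 0.0
        for seed in range(10):
            p = toy_params(seed=seed, n_subjects=5000)
            X = continuous_items(p)
            sample = np.corrcoef(X.to_numpy(), rowvar=False)
            pop = population_correlations(p).values
            worst = max(worst, np.abs(sample - pop).max())
        assert worst < 0.05

    def test_cross_cluster_sampled_negative(self):
        p = dataclasses.replace(toy_params(seed=3, n_subjects=2000), subject_groups=(GroupSpec(1.0),))
        rm, truth = generate_cohort(p)
        scores = score_traits(rm, build_schema(p)).traits
        r = np.corrcoef(scores.to_numpy(), rowvar=False)
        names = list(scores.columns)
        pop = population_trait_correlations(p)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if j <= i or truth.trait_cluster[a] == truth.trait_cluster[b]:
                    continue
                assert r[i, j] < 0
                # discretization to Likert attenuates; allow for it on top
                # of sampling error
                assert abs(r[i, j] - pop.loc[a, b]) < 0.1

    def test_noiseless_unit_loading_items_identical(self):
        p = GeneratorParams(
            traits=(TraitSpec("a", 1, 3, loading=1.0),), noise_sd=0.0, n_subjects=500, seed=5
        )
        X = continuous_items(p)
        r = np.corrcoef(X.to_numpy(), rowvar=False)
        assert np.allclose(np.abs(r), 1.0, atol=1e-10)

    def test_discretization_preserves_signs(self):
        p = toy_params(seed=7, n_subjects=5000)
        rm, _ = generate_cohort(p)
        sample = np.corrcoef(rm.values.to_numpy(), rowvar=False)
        pop = population_correlations(p).values
        mask = np.abs(pop) > 0.1
        np.fill_diagonal(mask, False)
        assert (np.sign(sample[mask]) == np.sign(pop[mask])).all()


def test_params_yaml_roundtrip(tmp_path):
    from traitspace.synthetic import params_from_yaml, params_to_yaml

    p = study_like_params(seed=5)
    params_to_yaml(p, tmp_path / "preset.yaml")
    back = params_from_yaml(tmp_path / "preset.yaml")
    assert back == p
    rm1, _ = generate_cohort(p)
    rm2, _ = generate_cohort(back)
    assert rm1.values.equals(rm2.values)


class TestGroundTruth:
    def test_labels_consistent(self, default_cohort):
        params, rm, truth, schema = default_cohort
        assert set(truth.trait_cluster.values()) == {1, 2}
        assert sorted(truth.item_cluster) == sorted(rm.items)
        # spectrum subdomain planted in the opposite cluster
        aes = [i for i, s in truth.item_subdomain.items() if s == "AES"]
        assert len(aes) == 7
        assert all(truth.item_cluster[i] == 1 for i in aes)
        assert truth.trait_cluster["SPS"] == 2
        sizes = pd.Series(truth.subject_group).value_counts()
        assert sizes.sort_index().tolist() == [328, 296, 213]

    def test_values_within_scales(self, default_cohort):
        params, rm, truth, schema = default_cohort
        for inst in schema.instruments:
            lo, hi = inst.scale
            block = rm.values[list(inst.item_ids)]
            assert block.min().min() >= lo and block.max().max() <= hi


class TestPBI:
    def test_mother_father_average(self):
        p = toy_params(seed=9, n_subjects=200)
        pbi = generate_pbi(p)
        avg = (pbi["mother_care"] + pbi["father_care"]) / 2
        assert np.allclose(avg, pbi[["mother_care", "father_care"]].mean(axis=1))

    def test_zero_correlation_when_disabled(self):
        p = toy_params(seed=10, n_subjects=5000)
        pbi = generate_pbi(p, care_corr=0.0)
        X = continuous_items(p)
        trait_mean = X.to_numpy().mean(axis=1)
        r = np.corrcoef(pbi["mother_care"], trait_mean)[0, 1]
        assert abs(r) < 0.05

    def test_planted_negative_care_correlation_recovered(self):
        # a near-pure proxy of the negative cluster factor: one trait with
        # cluster coupling 0.99, loading 1, no item noise, fine scale
        p = GeneratorParams(
            traits=(TraitSpec("proxy", 2, 1, loading=1.0, cluster_loading=0.99),),
            noise_sd=0.0,
            n_subjects=5000,
            seed=11,
        )
        proxy = continuous_items(p).iloc[:, 0]
        pbi = generate_pbi(p, care_corr=-0.3)
        r = np.corrcoef(pbi["mother_care"], proxy)[0, 1]
        assert abs(r - (-0.3) * np.sqrt(0.99)) < 0.05
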