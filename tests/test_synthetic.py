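"""Cohort simulator: determinism, separability, monotone views, mixtures."""

import numpy as np
import pytest
from scipy import stats

from sndsubtype import (
    CohortConfig,
    PlatformTransform,
    ReferenceGeneList,
    apply_platform_transform,
    inject_mixture_subtype,
    simulate_cohort,
    simulate_multiplatform_suite,
    snd_transform_matrix,
)
from sndsubtype.errors import ArgumentError
from sndsubtype.synthetic import nearest_centroid_accuracy

from conftest import int_labels


class TestSimulateCohort:
    def test_seed_determinism(self):
        a = simulate_cohort(CohortConfig(seed=5))
        b = simulate_cohort(CohortConfig(seed=5))
        np.testing.assert_array_equal(a.latent.values, b.latent.values)
        c = simulate_cohort(CohortConfig(seed=6))
        assert not np.array_equal(a.latent.values, c.latent.values)

    def test_class_proportions_exact(self):
        cohort = simulate_cohort(CohortConfig(seed=0))
        counts = {c: cohort.labels.labels.count(c) for c in cohort.labels.class_set}
        assert counts == {"C1": 60, "C2": 60, "C3": 60, "C4": 60}

    def test_oracle_separability_at_effect_two(self):
        config = CohortConfig(
            n_samples_per_class={c: 50 for c in ("C1", "C2", "C3", "C4")},
            effect_size=2.0, seed=3,
        )
        cohort = simulate_cohort(config)
        X = cohort.latent.values.T
        y = int_labels(cohort.labels)
        half = len(y) // 2
        rng = np.random.default_rng(0)
        order = rng.permutation(len(y))
        tr, te = order[:half], order[half:]
        assert nearest_centroid_accuracy((X[tr], y[tr]), (X[te], y[te])) >= 0.99

    def test_zero_effect_is_chance_level(self):
        accs = []
        for seed in (1, 2, 3):
            cohort = simulate_cohort(CohortConfig(effect_size=0.0, seed=seed))
            X = cohort.latent.values.T
            y = int_labels(cohort.labels)
            half = len(y) // 2
            order = np.random.default_rng(seed).permutation(len(y))
            accs.append(
                nearest_centroid_accuracy(
                    (X[order[:half]], y[order[:half]]),
                    (X[order[half:]], y[order[half:]]),
                )
            )
        assert abs(np.mean(accs) - 0.25) <= 0.1

    def test_oracle_accuracy_monotone_in_effect_size(self):
        def acc(effect):
            cohort = simulate_cohort(CohortConfig(effect_size=effect, seed=9))
            X = cohort.latent.values.T
            y = int_labels(cohort.labels)
            order = np.random.default_rng(9).permutation(len(y))
            half = len(y) // 2
            return nearest_centroid_accuracy(
                (X[order[:half]], y[order[:half]]),
                (X[order[half:]], y[order[half:]]),
            )

        accs = [acc(e) for e in (0.0, 0.5, 1.0, 2.0)]
        assert all(b >= a - 0.02 for a, b in zip(accs, accs[1:]))
        assert accs[-1] > accs[0]

    def test_signature_genes_outside_universe_rejected(self):
        with pytest.raises(ArgumentError, match="outside"):
            simulate_cohort(
                CohortConfig(class_signatures={"C1": ("nope",)}, seed=0)
            )


class TestPlatformTransforms:
    def test_affine_identity_reproduces_latent(self):
        cohort = simulate_cohort(CohortConfig(seed=1))
        t = PlatformTransform(name="id", kind="affine", params={"a": 1.0, "b": 0.0})
        apply_platform_transform(cohort, t)
        np.testing.assert_array_equal(cohort.views["id"].values,
                                      cohort.latent.values)

    @pytest.mark.parametrize(
        "transform",
        [
            PlatformTransform(name="t", kind="affine", params={"a": 3.3, "b": -7.0}),
            PlatformTransform(name="t", kind="power", params={"p": 2.5, "c": 40.0}),
            PlatformTransform(name="t", kind="logistic", params={"x0": 8.0, "s": 0.5}),
            PlatformTransform(
                name="t", kind="piecewise",
                params={"xs": [0.0, 8.0, 16.0], "ys": [0.0, 1.0, 30.0]},
            ),
        ],
    )
    def test_noise_free_views_have_identical_snd(self, transform):
        """The module's central property: SND(view) == SND(latent), bitwise."""
        cohort = simulate_cohort(CohortConfig(seed=2))
        apply_platform_transform(cohort, transform)
        rgl = ReferenceGeneList(tuple(cohort.latent.gene_ids))
        base = snd_transform_matrix(cohort.latent, rgl)
        view = snd_transform_matrix(cohort.views["t"], rgl)
        np.testing.assert_array_equal(base.values, view.values)

    def test_two_maps_differ_raw_but_agree_in_snd(self):
        cohort = simulate_cohort(CohortConfig(seed=3))
        t1 = PlatformTransform(name="a", kind="affine", params={"a": 2.0, "b": 5.0})
        t2 = PlatformTransform(name="b", kind="logistic", params={"x0": 8.0, "s": 1.0})
        apply_platform_transform(cohort, t1)
        apply_platform_transform(cohort, t2)
        assert not np.allclose(cohort.views["a"].values, cohort.views["b"].values)
        rgl = ReferenceGeneList(tuple(cohort.latent.gene_ids))
        np.testing.assert_array_equal(
            snd_transform_matrix(cohort.views["a"], rgl).values,
            snd_transform_matrix(cohort.views["b"], rgl).values,
        )

    def test_rank_fidelity_degrades_gracefully_with_noise(self):
        def mean_spearman(noise):
            cohort = simulate_cohort(CohortConfig(seed=4))
            t = PlatformTransform(name="t", kind="affine",
                                  params={"a": 1.0, "b": 0.0},
                                  noise_sd=noise, seed=11)
            apply_platform_transform(cohort, t)
            rhos = [
                stats.spearmanr(cohort.latent.values[:, j],
                                cohort.views["t"].values[:, j]).statistic
                for j in range(0, 240, 40)
            ]
            return float(np.mean(rhos))

        low, high = mean_spearman(0.05), mean_spearman(0.5)
        assert low > high
        assert low > 0.99

    def test_non_monotone_parameterizations_rejected(self):
        with pytest.raises(ArgumentError):
            PlatformTransform(name="t", kind="affine", params={"a": -1.0})
        with pytest.raises(ArgumentError):
            PlatformTransform(
                name="t", kind="piecewise",
                params={"xs": [0.0, 1.0], "ys": [1.0, 0.5]},
            )
        with pytest.raises(ArgumentError):
            PlatformTransform(name="t", kind="mystery")


class TestMixtureSubtype:
    def test_mixture_samples_follow_donor_classes(self):
        cohort = simulate_cohort(CohortConfig(seed=5))
        mixed = inject_mixture_subtype(cohort, label="MIX", n=40)
        assert mixed.labels.labels.count("MIX") == 40
        assert mixed.truth_meta["mixture_class"] == "MIX"
        donors = mixed.truth_meta["mixture_donors"]
        assert set(donors.values()) <= {"C1", "C2", "C3", "C4"}
        # a nearest-centroid classifier on the real classes assigns each
        # mixture sample to its own donor far above chance
        X = cohort.latent.values.T
        y = int_labels(cohort.labels)
        classes = sorted(set(cohort.labels.labels))
        mix_ids = [s for s, l in zip(mixed.labels.sample_ids, mixed.labels.labels)
                   if l == "MIX"]
        pos = {s: i for i, s in enumerate(mixed.latent.sample_ids)}
        Xmix = mixed.latent.values.T[[pos[s] for s in mix_ids]]
        centroids = np.stack([X[y == i].mean(axis=0) for i in range(4)])
        d = ((Xmix[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        called = [classes[i] for i in d.argmin(axis=1)]
        agree = np.mean([c == donors[s] for c, s in zip(called, mix_ids)])
        assert agree >= 0.95

    def test_single_donor_mixture_indistinguishable_from_donor(self):
        cohort = simulate_cohort(CohortConfig(seed=6))
        mixed = inject_mixture_subtype(cohort, label="MIX", n=30,
                                       mixing={"C2": 1.0})
        assert set(mixed.truth_meta["mixture_donors"].values()) == {"C2"}

    def test_existing_views_cover_injected_samples(self):
        cohort = simulate_cohort(CohortConfig(seed=7))
        t = PlatformTransform(name="v", kind="affine", params={"a": 2.0, "b": 0.0},
                              noise_sd=0.1, seed=1)
        apply_platform_transform(cohort, t)
        mixed = inject_mixture_subtype(cohort, label="MIX", n=10)
        assert mixed.views["v"].sample_ids == mixed.latent.sample_ids

    def test_bad_arguments_rejected(self):
        cohort = simulate_cohort(CohortConfig(seed=8))
        with pytest.raises(ArgumentError):
            inject_mixture_subtype(cohort, n=0)
        with pytest.raises(ArgumentError):
            inject_mixture_subtype(cohort, n=5, mixing={"C1": 0.4, "C2": 0.4})
        with pytest.raises(ArgumentError):
            inject_mixture_subtype(cohort, n=5, mixing={"C9": 1.0})


class TestSuite:
    def test_views_share_genes_and_samples_with_latent(self):
        suite = simulate_multiplatform_suite(CohortConfig(seed=1), k_platforms=3)
        assert len(suite.views) == 3
        for view in suite.views.values():
            assert view.gene_ids == suite.latent.gene_ids
            assert view.sample_ids == suite.latent.sample_ids

    def test_single_platform_rejected(self):
        with pytest.raises(ArgumentError):
            simulate_multiplatform_suite(CohortConfig(seed=1), k_platforms=1)
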