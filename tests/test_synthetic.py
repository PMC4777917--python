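import numpy as np
import pytest
from dataclasses import replace

import foxgate as fg
from foxgate.synthetic import (CohortSpec, GroupSpec, INSTRUMENT_LIMITS,
                               POPULATIONS, PopulationSpec, SampleSpec,
                               SpecValidationError, default_cohort_spec,
                               default_populations, default_sample_spec,
                               generate_cohort, generate_sample)


class TestSpecValidation:
    def test_weights_must_sum_to_one(self):
        pops = list(default_populations())
        pops[0] = replace(pops[0], weight=pops[0].weight + 0.1)
        with pytest.raises(SpecValidationError, match="sum"):
            SampleSpec(tuple(pops))

    def test_boundary_fraction_bounds(self):
        with pytest.raises(SpecValidationError):
            default_sample_spec(boundary_fraction=1.0)

    def test_n_events_positive(self):
        with pytest.raises(SpecValidationError):
            default_sample_spec(n_events=0)

    def test_covariance_must_be_psd(self):
        bad = np.diag([1.0] * 6)
        bad[0, 1] = bad[1, 0] = 5.0
        with pytest.raises(SpecValidationError, match="PSD"):
            PopulationSpec("debris", 0.1, np.zeros(6), bad)

    def test_effector_must_top_foxp3(self):
        spec = default_sample_spec()
        pops = {p.name: p for p in spec.populations}
        mean = pops["effector_treg"].mean.copy()
        mean[5] = 1.0  # below the FOXP3-low populations
        pops["effector_treg"] = replace(pops["effector_treg"], mean=mean)
        with pytest.raises(SpecValidationError, match="highest FOXP3"):
            SampleSpec(tuple(pops.values()))


class TestGenerateSample:
    def test_labels_align_and_cover(self, default_sample):
        table, labels = default_sample
        assert len(labels) == table.n_events
        assert set(labels) <= set(POPULATIONS)

    def test_determinism(self):
        spec = default_sample_spec(n_events=2000, seed=42)
        t1, l1 = generate_sample(spec)
        t2, l2 = generate_sample(spec)
        assert t1.values.tobytes() == t2.values.tobytes()
        assert np.array_equal(l1, l2)

    def test_effector_count_within_binomial_bound(self):
        spec = default_sample_spec(n_events=10_000, seed=7)
        _, labels = generate_sample(spec)
        n, p = 10_000, 0.02
        bound = 3 * np.sqrt(n * p * (1 - p))
        assert abs((labels == "effector_treg").sum() - n * p) <= bound

    def test_mixture_proportions_converge(self):
        spec = default_sample_spec(n_events=50_000, seed=9)
        _, labels = generate_sample(spec)
        for pop in spec.populations:
            n_hat = (labels == pop.name).sum()
            bound = 3 * np.sqrt(50_000 * pop.weight * (1 - pop.weight))
            assert abs(n_hat - 50_000 * pop.weight) <= bound

    def test_no_clamping_when_not_requested(self):
        spec = default_sample_spec(n_events=5000, seed=3, boundary_fraction=0.0,
                                   debris=0.0)
        table, _ = generate_sample(spec)
        lim = INSTRUMENT_LIMITS["analog"]
        lo_f, hi_f = 10.0 ** lim["fluor_log"][0], 10.0 ** lim["fluor_log"][1]
        scatter = table.values[:, :2]
        fluor = table.values[:, 2:]
        assert not np.any((scatter == lim["scatter"][0])
                          | (scatter == lim["scatter"][1]))
        assert not np.any((fluor == lo_f) | (fluor == hi_f))

    def test_clamped_events_sit_exactly_at_limits(self):
        spec = default_sample_spec(n_events=4000, seed=11, boundary_fraction=0.05)
        table, _ = generate_sample(spec)
        lim = INSTRUMENT_LIMITS["analog"]
        lo_f, hi_f = 10.0 ** lim["fluor_log"][0], 10.0 ** lim["fluor_log"][1]
        at_limit = ((table.values[:, :2] == lim["scatter"][0])
                    | (table.values[:, :2] == lim["scatter"][1])).any(axis=1)
        at_limit |= ((table.values[:, 2:] == lo_f)
                     | (table.values[:, 2:] == hi_f)).any(axis=1)
        assert abs(at_limit.sum() - round(0.05 * 4000)) <= 1
        assert table.metadata["n_clamped"] == round(0.05 * 4000)

    def test_weight_override_renormalizes(self):
        spec = default_sample_spec(effector_treg=0.04)
        total = sum(p.weight for p in spec.populations)
        assert total == pytest.approx(1.0)


class TestGenerateCohort:
    def test_group_sizes_and_statuses(self):
        cs = default_cohort_spec(n_hc=15, n_melanoma=19, n_events=1000, seed=2)
        samples = generate_cohort(cs)
        assert len(samples) == 34
        assert sum(s.status == "HC" for s in samples) == 15
        assert sum(s.status == "melanoma" for s in samples) == 19

    def test_degenerate_weight_distribution(self):
        base = default_sample_spec(n_events=1000)
        cs = CohortSpec((GroupSpec("HC", 4, 0.02, 0.0),), base, seed=1)
        ws = [s.effector_weight for s in generate_cohort(cs)]
        assert all(w == 0.02 for w in ws)

    def test_effector_effect_visible_in_ground_truth(self):
        cs = default_cohort_spec(n_hc=8, n_melanoma=8, hc_effector=0.02,
                                 mel_effector=0.04, n_events=10_000, seed=5)
        samples = generate_cohort(cs)
        med = {}
        for status in ("HC", "melanoma"):
            fracs = [(s.labels == "effector_treg").mean()
                     for s in samples if s.status == status]
            med[status] = np.median(fracs)
        assert med["melanoma"] > med["HC"]

    def test_empty_groups_rejected(self):
        with pytest.raises(SpecValidationError):
            CohortSpec((), default_sample_spec(), seed=0)

    def test_reproducible(self):
        cs = default_cohort_spec(n_hc=2, n_melanoma=2, n_events=500, seed=9)
        a = generate_cohort(cs)
        b = generate_cohort(cs)
        for x, y in zip(a, b):
            assert x.table.values.tobytes() == y.table.values.tobytes()
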