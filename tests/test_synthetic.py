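import numpy as np
import pandas as pd
import pytest

from cscpet.synthetic import (
    COHORT_COLUMNS,
    CohortSpec,
    CompartmentSpec,
    PhantomSpec,
    end_to_end_recovery,
    generate_cohort,
    generate_phantom,
    lognormal_from_median_range,
)


class TestPhantom:
    def test_csc_truth_bookkeeping(self, separated_phantom_spec):
        _, truth = generate_phantom(separated_phantom_spec)
        assert truth.mtv_csc == pytest.approx(14 * 0.064)  # 0.896 cm^3
        assert truth.compartment_indices[-1].shape[0] == 14

    def test_sd_zero_gives_three_distinct_tumor_values(self):
        spec = PhantomSpec(
            shape=(16, 16, 16),
            compartments=(
                CompartmentSpec(3.0, 0.0, 20),
                CompartmentSpec(5.5, 0.0, 10),
                CompartmentSpec(9.0, 0.0, 5),
            ),
            seed=1,
        )
        vol, truth = generate_phantom(spec)
        tumor = np.concatenate(
            [vol.data[tuple(ix.T)] for ix in truth.compartment_indices]
        )
        assert set(np.unique(tumor)) == {3.0, 5.5, 9.0}

    def test_same_seed_reproduces_identical_volume(self, separated_phantom_spec):
        va, _ = generate_phantom(separated_phantom_spec)
        vb, _ = generate_phantom(separated_phantom_spec)
        np.testing.assert_array_equal(va.data, vb.data)

    def test_truth_self_consistent_with_volume(self, separated_phantom_spec):
        vol, truth = generate_phantom(separated_phantom_spec)
        vv = vol.voxel_volume
        suvs = [vol.data[tuple(ix.T)] for ix in truth.compartment_indices]
        avid = [s[s >= truth.threshold] for s in suvs]
        assert truth.mtv == pytest.approx(sum(a.size for a in avid) * vv)
        assert truth.tlg == pytest.approx(sum(a.sum() for a in avid) * vv)
        assert truth.suv_max == pytest.approx(max(s.max() for s in suvs))

    def test_compartments_disjoint(self, separated_phantom_spec):
        _, truth = generate_phantom(separated_phantom_spec)
        all_idx = np.vstack(truth.compartment_indices)
        assert len({tuple(r) for r in all_idx.tolist()}) == all_idx.shape[0]

    def test_oversized_tumor_rejected(self):
        spec = PhantomSpec(
            shape=(4, 4, 4),
            compartments=(
                CompartmentSpec(3.0, 0.1, 30),
                CompartmentSpec(5.5, 0.1, 20),
                CompartmentSpec(9.0, 0.1, 10),
            ),
        )
        with pytest.raises(ValueError, match="capacity|exceed"):
            generate_phantom(spec)

    def test_nonincreasing_means_rejected(self):
        with pytest.raises(ValueError, match="increase"):
            PhantomSpec(
                compartments=(
                    CompartmentSpec(5.0, 0.1, 10),
                    CompartmentSpec(3.0, 0.1, 10),
                    CompartmentSpec(9.0, 0.1, 10),
                )
            )

    def test_random_blob_placement(self):
        spec = PhantomSpec(shape=(40, 40, 40), placement="random-blobs", seed=2)
        vol, truth = generate_phantom(spec)
        assert truth.mtv_csc == pytest.approx(14 * 0.064)
        all_idx = np.vstack(truth.compartment_indices)
        assert len({tuple(r) for r in all_idx.tolist()}) == all_idx.shape[0]


class TestEndToEnd:
    def test_sd_zero_recovers_exactly(self):
        spec = PhantomSpec(
            shape=(16, 16, 16),
            compartments=(
                CompartmentSpec(3.0, 0.0, 20),
                CompartmentSpec(5.5, 0.0, 10),
                CompartmentSpec(9.0, 0.0, 5),
            ),
            seed=4,
        )
        rep = end_to_end_recovery(spec)
        assert rep.mtv_csc_error == 0.0
        assert rep.mtv_error == 0.0
        assert rep.tlg_error == pytest.approx(0.0, abs=1e-10)

    def test_well_separated_within_two_voxel_volumes(self, separated_phantom_spec):
        rep = end_to_end_recovery(separated_phantom_spec)
        assert rep.separable
        assert rep.mtv_csc_error <= 2 * rep.voxel_volume

    def test_overlapping_compartments_flagged_not_asserted(self):
        spec = PhantomSpec(
            shape=(24, 24, 24),
            compartments=(
                CompartmentSpec(4.0, 0.3, 60),
                CompartmentSpec(4.5, 0.3, 40),
                CompartmentSpec(5.0, 0.3, 14),
            ),
            seed=5,
        )
        rep = end_to_end_recovery(spec)
        assert not rep.separable

    def test_compartment_mean_below_threshold_rejected(self):
        spec = PhantomSpec(
            compartments=(
                CompartmentSpec(2.0, 0.1, 20),
                CompartmentSpec(5.5, 0.1, 10),
                CompartmentSpec(9.0, 0.1, 5),
            )
        )
        with pytest.raises(ValueError, match="threshold"):
            end_to_end_recovery(spec)


class TestCohort:
    def test_luminal_never_achieves_pcr_by_default(self):
        cohort = generate_cohort(CohortSpec(seed=0))
        assert cohort.loc[cohort.subtype == "luminal", "pcr"].sum() == 0

    def test_schema_and_sizes(self):
        cohort = generate_cohort(CohortSpec(seed=1))
        assert list(cohort.columns) == COHORT_COLUMNS
        assert len(cohort) == 120
        assert cohort.subtype.value_counts().to_dict() == {
            "HER2-positive": 57, "luminal": 38, "TN": 25
        }

    def test_same_seed_identical_tables(self):
        a = generate_cohort(CohortSpec(seed=6))
        b = generate_cohort(CohortSpec(seed=6))
        pd.testing.assert_frame_equal(a, b)

    def test_pcr_group_median_matches_fitted_lognormal(self):
        mu, sigma = lognormal_from_median_range(0.9, 0.3, 1.7, 22)
        rng = np.random.default_rng(12)
        sample = rng.lognormal(mu, sigma, 10_000)
        assert np.median(sample) == pytest.approx(0.9, abs=0.1)

    def test_lognormal_fit_reproduces_median(self):
        mu, sigma = lognormal_from_median_range(2.8, 0.1, 38.0, 60)
        assert np.exp(mu) == pytest.approx(2.8)
        assert sigma > 0

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            CohortSpec(pcr_rates={"HER2-positive": 1.5, "TN": 0.2, "luminal": 0.0})

    def test_dfs_times_positive_and_events_boolean(self):
        cohort = generate_cohort(CohortSpec(seed=2))
        assert (cohort.dfs_months > 0).all()
        assert cohort.relapse_event.dtype == bool
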