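"""The synthetic-data generators: determinism, structure, effect faithfulness."""

import numpy as np
import pandas as pd
import pytest

from exercog.fnirs import MbllParams, Montage, intensity_to_od, od_to_hemoglobin
from exercog.granger import pairwise_conditional_gc
from exercog.retina import indices_table
from exercog.simulate import (
    NoiseProfile,
    ProfileError,
    VarGroundTruth,
    calibrate_behavior,
    generate_causal_density_cells,
    generate_covariates,
    generate_fnirs_recording,
    generate_study,
    generate_vessel_widths,
    null_profile,
    paper_effects,
)
from exercog.simulate.fnirsgen import StationarityError
from exercog.stroop import summarize_trials, zscore_measures


def behavioral_did(trials, measure, cond="MIC"):
    z = zscore_measures(summarize_trials(trials))
    cell = z.groupby(["condition", "timepoint"])[measure].mean()
    return (
        cell[(cond, "post")] - cell[(cond, "pre")]
        - cell[("SIT", "post")] + cell[("SIT", "pre")]
    )


class TestDeterminismAndStructure:
    def test_identical_seed_bitwise_identical(self, profile):
        a = generate_study(profile, seed=42, conditions=("SIT", "MIC"))
        b = generate_study(profile, seed=42, conditions=("SIT", "MIC"))
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.vessel_widths, b.vessel_widths)
        pd.testing.assert_frame_equal(a.causal_density, b.causal_density)
        c = generate_study(profile, seed=43, conditions=("SIT", "MIC"))
        assert not a.trials["rt_ms"].equals(c.trials["rt_ms"])

    def test_cell_counts_match_design(self, profile):
        ds = generate_study(profile, seed=0)
        assert len(ds.covariates) == 71
        cells = ds.trials.groupby(["subject", "condition", "timepoint"])
        assert len(cells) == 71 * 3 * 2
        resting = ds.causal_density.query("state == 'resting'")
        assert len(resting) == 71 * 3 * 2
        # 6 arterioles + 6 venules per cell
        per_cell = ds.vessel_widths.groupby(
            ["subject", "condition", "timepoint", "vessel_type"]
        ).size()
        assert (per_cell == 6).all()

    def test_congruency_mix_exact(self, profile, covariates71):
        from exercog.simulate import generate_trials

        trials = generate_trials(
            profile, covariates71.head(2), conditions=("SIT",), seed=1
        )
        mix = (
            trials.groupby(["subject", "condition", "timepoint", "block"])
            ["congruency"].value_counts().unstack()
        )
        assert (mix["congruent"] == 18).all()
        assert (mix["incongruent"] == 9).all()
        assert (mix["neutral"] == 9).all()

    def test_rt_window_respected(self, profile):
        ds = generate_study(profile, seed=5, conditions=("SIT",))
        rt = ds.trials["rt_ms"].dropna()
        assert rt.between(200, 3000).all()

    def test_subject_streams_order_independent(self, profile, covariates71):
        """A subject's data do not depend on how many subjects precede it."""
        from exercog.simulate import generate_trials

        big = generate_trials(profile, covariates71.head(4),
                              conditions=("SIT",), seed=3)
        small = generate_trials(profile, covariates71.head(2),
                                conditions=("SIT",), seed=3)
        s2_big = big[big.subject == "S002"].reset_index(drop=True)
        s2_small = small[small.subject == "S002"].reset_index(drop=True)
        pd.testing.assert_frame_equal(s2_big, s2_small)


class TestNullProfile:
    def test_no_injected_differences(self, null_prof):
        dids = {"z_rt": [], "z_er": [], "z_ies": []}
        for seed in range(1, 7):
            ds = generate_study(null_prof, seed=seed, conditions=("SIT", "MIC"))
            for m in dids:
                dids[m].append(behavioral_did(ds.trials, m))
        for m, v in dids.items():
            se = np.std(v) / np.sqrt(len(v))
            assert abs(np.mean(v)) < max(3 * se, 0.02), m


class TestEffectFaithfulness:
    """Monte-Carlo means of empirical contrasts against injected values."""

    N_SEEDS = 100

    @pytest.fixture(scope="class")
    def behavioral_runs(self, profile):
        raws, z_dids = [], {"z_rt": [], "z_er": [], "z_ies": []}
        for seed in range(1, self.N_SEEDS + 1):
            ds = generate_study(profile, seed=seed, conditions=("SIT", "MIC"))
            summ = summarize_trials(ds.trials)
            cell = summ.groupby(["condition", "timepoint"])["er"].mean()
            raws.append(
                cell[("MIC", "post")] - cell[("MIC", "pre")]
                - cell[("SIT", "post")] + cell[("SIT", "pre")]
            )
            z = zscore_measures(summ)
            zc = z.groupby(["condition", "timepoint"])[list(z_dids)].mean()
            did = (
                zc.loc[("MIC", "post")] - zc.loc[("MIC", "pre")]
                - zc.loc[("SIT", "post")] + zc.loc[("SIT", "pre")]
            )
            for m in z_dids:
                z_dids[m].append(did[m])
        return raws, z_dids

    def test_raw_error_rate_shift_exact(self, profile, behavioral_runs):
        raws, _ = behavioral_runs
        calib = calibrate_behavior(profile.behavioral, profile.covariates)
        target = profile.behavioral.dids["MIC"]["er"] * calib.s_er
        se = np.std(raws) / np.sqrt(len(raws))
        assert abs(np.mean(raws) - target) < 3 * se

    @pytest.mark.parametrize("measure", ["z_rt", "z_er", "z_ies"])
    def test_z_scale_contrasts(self, profile, behavioral_runs, measure):
        """z contrasts match the profile up to the finite-pool scale bias.

        Dividing by the empirical pre-pool SD inflates magnitudes by a
        Jensen term of order 1/n_subjects (~2-4% at n=71), so the check
        allows that documented bias on top of the Monte-Carlo error.
        """
        _, z_dids = behavioral_runs
        target = profile.behavioral.dids["MIC"][measure.removeprefix("z_")]
        v = np.asarray(z_dids[measure])
        se = v.std() / np.sqrt(len(v))
        bias_allowance = 0.05 * abs(target)
        assert abs(v.mean() - target) < 3 * se + bias_allowance

    def test_vessel_interaction_faithful(self, profile):
        vals = []
        for seed in range(1, 41):
            cov = generate_covariates(profile, seed=seed)
            w = generate_vessel_widths(profile, cov, seed=seed, design="reduced")
            idx = indices_table(w)
            cell = idx.groupby(["condition", "timepoint"])["crae"].mean()
            vals.append(
                cell[("EX", "post")] - cell[("EX", "pre")]
                - cell[("SIT", "post")] + cell[("SIT", "pre")]
            )
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 4.46) < 3 * se

    def test_causal_density_interaction_faithful(self, profile):
        vals = []
        for seed in range(1, 101):
            cov = generate_covariates(profile, seed=seed)
            cd = generate_causal_density_cells(
                profile, cov, state="resting", seed=seed, design="reduced"
            )
            cell = cd.groupby(["condition", "timepoint"])["causal_density"].mean()
            vals.append(
                cell[("EX", "post")] - cell[("EX", "pre")]
                - cell[("SIT", "post")] + cell[("SIT", "pre")]
            )
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.37) < 3 * se


class TestCalibration:
    def test_calibration_condition_ies_exact(self, profile):
        calib = calibrate_behavior(profile.behavioral, profile.covariates)
        assert calib.implied_z_ies["MIC"] == pytest.approx(
            profile.behavioral.dids["MIC"]["ies"], abs=1e-6
        )

    def test_unattainable_triple_rejected(self, profile):
        from dataclasses import replace

        beh = replace(
            profile.behavioral,
            dids={"MIC": {"rt": -0.13, "er": -0.36, "ies": -0.50}},
        )
        with pytest.raises(ProfileError, match="unattainable"):
            calibrate_behavior(beh, profile.covariates)

    def test_invalid_profile_fields_named(self):
        from exercog.simulate.profiles import BehavioralParams

        with pytest.raises(ProfileError, match="er_mean"):
            BehavioralParams(er_mean=1.5)


class TestFnirsGenerator:
    def _tiny_montage(self):
        return Montage(roi_channels={"a": ["C1"], "b": ["C2"]})

    def test_zero_drive_constant_intensity(self):
        truth = VarGroundTruth(coefs=np.zeros((1, 2, 2)), innovation_sd=0.0)
        rec = generate_fnirs_recording(
            truth, noise=NoiseProfile.silent(), duration_s=60,
            montage=self._tiny_montage(), seed=0,
        )
        assert np.allclose(rec.intensity, rec.intensity[..., :1])

    def test_five_minutes_is_3060_samples(self):
        from exercog.simulate import default_ground_truth

        rec = generate_fnirs_recording(
            default_ground_truth(), noise=NoiseProfile.silent(),
            duration_s=300, seed=1,
        )
        assert rec.n_samples == 3060

    def test_noise_free_inverse_recovers_latent(self):
        from exercog.simulate import default_ground_truth

        rec = generate_fnirs_recording(
            default_ground_truth(), noise=NoiseProfile.silent(),
            duration_s=120, seed=2,
        )
        od = intensity_to_od(rec.intensity)
        hbo, _ = od_to_hemoglobin(od, MbllParams())
        ch = rec.channel_names.index("C10")
        latent = rec.latent_hbo["medial_frontal"].to_numpy()
        got = hbo[ch] - hbo[ch].mean()
        want = latent - latent.mean()
        scale = np.abs(want).max()
        assert np.abs(got - want).max() < 1e-8 * max(scale, 1e-12)

    def test_directed_coupling_recovered_downstream(self):
        coefs = np.array([[[0.3, 0.0], [0.5, 0.3]]])  # x -> y at lag 1
        truth = VarGroundTruth(coefs=coefs, innovation_sd=0.05)
        wins = 0
        for seed in range(5):
            rec = generate_fnirs_recording(
                truth, noise=NoiseProfile.silent(), duration_s=300,
                montage=self._tiny_montage(), seed=seed,
            )
            od = intensity_to_od(rec.intensity)
            hbo, _ = od_to_hemoglobin(od, MbllParams())
            r = pairwise_conditional_gc(hbo.T, order=1)
            wins += r.gc[0, 1] > r.gc[1, 0]
        assert wins == 5

    def test_unstable_truth_rejected(self):
        truth = VarGroundTruth(coefs=np.eye(2)[None] * 1.05, innovation_sd=0.1)
        with pytest.raises(StationarityError):
            generate_fnirs_recording(
                truth, duration_s=60, montage=self._tiny_montage(), seed=0
            )

    def test_aliasing_guard(self):
        truth = VarGroundTruth(coefs=np.zeros((1, 2, 2)), innovation_sd=0.1)
        with pytest.raises(ValueError, match="aliases"):
            generate_fnirs_recording(
                truth, duration_s=60, fs=1.5, montage=self._tiny_montage(),
                seed=0,
            )

    def test_too_short_recording_rejected(self):
        truth = VarGroundTruth(coefs=np.zeros((1, 2, 2)), innovation_sd=0.1)
        with pytest.raises(ValueError, match="60 s"):
            generate_fnirs_recording(
                truth, duration_s=30, montage=self._tiny_montage(), seed=0
            )

    def test_edge_set_from_coefficients(self):
        coefs = np.array([[[0.3, 0.0], [0.5, 0.3]]])
        truth = VarGroundTruth(coefs=coefs, innovation_sd=0.1)
        assert truth.edge_set == {(0, 1)}
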