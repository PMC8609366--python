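"""End-to-end recovery of the planted cohort structure.

These tests run the full chain — simulate, standardize, concatenate, PCA,
variational HMM (3 repetitions, lowest free energy kept), evoked windows,
permutation inference — on a reduced cohort (6 subjects per group,
half-length runs) and check that every planted effect, and no planted null,
is recovered.
"""

import numpy as np
import pandas as pd
import pytest

from ofmri_states import (
    block_significance_profile,
    group_difference_test,
    mixed_anova_interaction,
    rm_anova_frequency,
    select_states,
    subject_evoked,
)
from ofmri_states import permstats as ps
from ofmri_states.evoked import block_windows, run_evoked
from ofmri_states.hmm import match_states
from ofmri_states.synthetic import planted_means_in_standardized_units

PLANTED_5HZ, PLANTED_10HZ = 2, 3
PLANTED_BASELINE = (0, 1)


@pytest.fixture(scope="module")
def recovered(fitted_reduced_cohort):
    """Planted-to-fitted state mapping plus evoked curves for every run."""
    fx = fitted_reduced_cohort
    latent = np.vstack(fx["truth"]["gammas"])
    row, col, corr = match_states(latent, fx["model"].gamma_)
    mapping = dict(zip(row.tolist(), col.tolist()))
    paradigm = fx["spec"].paradigm
    gammas = fx["concat"].split(fx["model"].gamma_)
    run_resp = [run_evoked(block_windows(g, paradigm)) for g in gammas]
    return dict(fx, mapping=mapping, match_corr=corr[row, col], run_resp=run_resp)


def _freq_curves(manifest, run_resp, group, by_session=True):
    keys = ["subject_id", "session"] if by_session else ["subject_id"]
    rows = []
    for _, sub in manifest.groupby(keys):
        if sub.iloc[0]["group"] != group:
            continue
        per = [
            np.median(
                np.stack(
                    [run_resp[manifest.index.get_loc(i)].curves
                     for i in sub.index[sub.freq_hz == f]]
                ),
                axis=0,
            )
            for f in (5, 10, 20)
        ]
        rows.append(np.stack(per))
    return np.stack(rows)


class TestStateRecovery:
    def test_latent_paths_recovered(self, recovered):
        """Matched gamma columns track the planted state paths."""
        assert np.median(recovered["match_corr"]) >= 0.9

    def test_mean_maps_recovered(self, recovered):
        """Back-projected state means correlate with the planted means
        (expressed in the pipeline's standardized units) at r >= 0.9."""
        fx = recovered
        maps = np.stack(
            [
                fx["pca"].backproject_state(m, c)[0]
                for m, c in zip(fx["model"].means_, fx["model"].covariances_)
            ]
        )
        target = planted_means_in_standardized_units(
            fx["gt"], fx["truth"]["gammas"], fx["runs"]
        )
        rs = [
            np.corrcoef(target[kt], maps[kf])[0, 1]
            for kt, kf in fx["mapping"].items()
        ]
        assert np.median(rs) >= 0.9

    def test_pca_kept_half_the_variance(self, recovered):
        pca = recovered["pca"]
        cum = np.cumsum(pca.explained_variance_ratio_)
        m = pca.n_components_
        assert cum[m - 1] >= 0.5
        assert cum[m - 2] < 0.5


class TestFrequencyAnovaRecovery:
    @pytest.fixture(scope="class")
    def anova(self, recovered):
        curves = _freq_curves(recovered["manifest"], recovered["run_resp"], "WT-ChR2")
        return recovered, rm_anova_frequency(
            curves,
            contrasts=(ps.CONTRAST_5HZ, ps.CONTRAST_10HZ, ps.CONTRAST_20HZ,
                       ps.CONTRAST_INCREASING, ps.CONTRAST_DECREASING),
            nperm=1000,
            seed=0,
        )

    def test_5hz_contrast_flags_only_the_5hz_state(self, anova):
        fx, res = anova
        p = res[ps.CONTRAST_5HZ.label].min_p()
        assert p[fx["mapping"][PLANTED_5HZ]] <= 0.05
        assert p[fx["mapping"][PLANTED_10HZ]] > 0.05
        for k in PLANTED_BASELINE:
            assert p[fx["mapping"][k]] > 0.05

    def test_10hz_contrast_flags_only_the_10hz_state(self, anova):
        fx, res = anova
        p = res[ps.CONTRAST_10HZ.label].min_p()
        assert p[fx["mapping"][PLANTED_10HZ]] <= 0.05
        assert p[fx["mapping"][PLANTED_5HZ]] > 0.05

    def test_omnibus_flags_both_tuned_states(self, anova):
        fx, res = anova
        p = res["F"].min_p()
        assert p[fx["mapping"][PLANTED_5HZ]] <= 0.05
        assert p[fx["mapping"][PLANTED_10HZ]] <= 0.05

    def test_control_contrasts_stay_null(self, anova):
        """No 20 Hz-specific response and no monotonic frequency trend was
        planted; the control contrasts must stay non-significant."""
        _, res = anova
        for label in (ps.CONTRAST_20HZ.label, ps.CONTRAST_INCREASING.label,
                      ps.CONTRAST_DECREASING.label):
            assert res[label].p_fwe.min() > 0.05


class TestMixedAnovaRecovery:
    def test_transgenic_tuning_loss_flagged(self, recovered):
        fx = recovered
        A = _freq_curves(fx["manifest"], fx["run_resp"], "WT-ChR2", by_session=False)
        B = _freq_curves(fx["manifest"], fx["run_resp"], "3xTgAD-ChR2", by_session=False)
        res = mixed_anova_interaction(A, B, nperm=1000, seed=0)
        p = res[(ps.CONTRAST_5HZ.label, "A>B")].min_p()
        assert p[fx["mapping"][PLANTED_5HZ]] <= 0.05
        for k in PLANTED_BASELINE:
            assert p[fx["mapping"][k]] > 0.05


class TestGroupDifferenceRecovery:
    def test_evoked_state_separates_active_from_control(self, recovered):
        fx = recovered
        manifest, run_resp = fx["manifest"], fx["run_resp"]
        with pytest.warns(RuntimeWarning):
            s1 = subject_evoked(manifest, run_resp, where=lambda r: r.group == "WT-ChR2")
        with pytest.warns(RuntimeWarning):
            s2 = subject_evoked(manifest, run_resp, where=lambda r: r.group == "WT-mCherry")
        res = group_difference_test(s1, s2, nperm=1000, seed=0)
        p = res.min_p()
        assert p[fx["mapping"][PLANTED_5HZ]] <= 0.05
        for k in PLANTED_BASELINE:
            assert p[fx["mapping"][k]] > 0.05


class TestStateCountSelection:
    @staticmethod
    def _stream(K_true, T, seed, sep=3.0, d=3):
        rng = np.random.default_rng(seed)
        means = rng.standard_normal((K_true, d)) * sep
        A = np.full((K_true, K_true), 0.04 / (K_true - 1))
        np.fill_diagonal(A, 0.96)
        z = np.empty(T, dtype=int)
        z[0] = 0
        for t in range(1, T):
            z[t] = rng.choice(K_true, p=A[z[t - 1]])
        return means[z] + rng.standard_normal((T, d))

    def test_true_state_count_chosen_across_seeds(self):
        """The similarity / free-energy criterion recovers K_true = 4 from
        candidates {2, 4, 8} on at least 8 of 10 seeded streams."""
        hits = 0
        for s in range(10):
            X = self._stream(4, 1500, s)
            report = select_states(
                X, K_list=(2, 4, 8), reps=3, seed=s, max_iter=60, keep_models=False
            )
            hits += report.chosen_K == 4
        assert hits >= 8


class TestBlockProfile:
    def _cohort(self, effect_by_block, n_subj=6, K=2, seed=0):
        """Directly constructed gammas: group 1 has per-block window
        elevation of state 0 given by effect_by_block."""
        from conftest import reduced_paradigm

        p = reduced_paradigm()
        rng = np.random.default_rng(seed)
        manifests, blocks = [], {}
        for gi, grp in enumerate(["G1", "G2"]):
            rows, bss = [], []
            for s in range(n_subj):
                g = np.clip(rng.random((p.n_volumes, K)) * 0.1, 0, 1)
                if gi == 0:
                    for b, onset in enumerate(p.block_onsets()):
                        g[onset : onset + 20, 0] += effect_by_block[b]
                rows.append(
                    dict(subject_id=f"{grp}-s{s}", group=grp, session=1, run=1,
                         freq_hz=5, path="x")
                )
                bss.append(block_windows(g, p))
            manifests.append(pd.DataFrame(rows))
            blocks[grp] = bss
        return manifests[0], blocks["G1"], manifests[1], blocks["G2"]

    def test_identical_groups_rarely_flagged(self):
        m1, b1, m2, b2 = self._cohort(np.zeros(5), seed=1)
        profile, _ = block_significance_profile(m1, b1, m2, b2, n_blocks=5,
                                                nperm=200, seed=0)
        assert profile.mean() <= 0.1

    def test_ramping_effect_flags_later_blocks(self):
        """A gain ramping up across blocks yields more significant later
        blocks than earlier ones (long-scale response amplification)."""
        hits_early, hits_late = 0, 0
        for s in range(5):
            m1, b1, m2, b2 = self._cohort(
                np.array([0.0, 0.0, 0.3, 0.6, 0.6]), seed=10 + s
            )
            profile, _ = block_significance_profile(
                m1, b1, m2, b2, n_blocks=5, nperm=200, seed=s
            )
            hits_early += profile[0, :2].sum()
            hits_late += profile[0, 3:].sum()
        assert hits_late > hits_early

    def test_single_block_matches_direct_test(self):
        from ofmri_states.evoked import single_block_evoked

        m1, b1, m2, b2 = self._cohort(np.array([0.4, 0.0, 0.0, 0.0, 0.0]), seed=2)
        profile, p_all = block_significance_profile(
            m1, b1, m2, b2, n_blocks=5, nperm=200, seed=0
        )
        direct = group_difference_test(
            subject_evoked(m1, single_block_evoked(b1, 0)),
            subject_evoked(m2, single_block_evoked(b2, 0)),
            nperm=200,
            seed=0,
        )
        np.testing.assert_array_equal(p_all[0], direct.p_fwe)
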