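"""Generator contracts: determinism, planted structure, mass balance."""

import io

import numpy as np
import pandas as pd
import pytest

from aeronit import community as comm
from aeronit import kinetics as kin
from aeronit import stats as st
from aeronit import synthetic as syn


class TestGenerateSequences:
    def test_zero_divergence_single_cluster(self):
        spec = syn.CommunitySpec(
            n_samples=1,
            clusters=(syn.ClusterSpec("A", 200, 0.0, (10,)),),
            between_divergence=0.2,
            seed=1,
        )
        records, truth = syn.generate_sequences(spec)
        assert len(records) == 10
        dm = comm.pairwise_distances(records)
        assert np.all(dm.values == 0.0)

    def test_three_clusters_brute_force_separation(self, three_cluster_spec):
        # all-pairs check: within-cluster <= cutoff, cross-cluster > cutoff
        records, truth = syn.generate_sequences(three_cluster_spec)
        cluster_of = dict(zip(truth["seq_id"], truth["cluster"]))
        dm = comm.pairwise_distances(records)
        n = len(dm.ids)
        for i in range(n):
            for j in range(i + 1, n):
                same = cluster_of[dm.ids[i]] == cluster_of[dm.ids[j]]
                if same:
                    assert dm.values[i, j] <= 0.03
                else:
                    assert dm.values[i, j] > 0.03
        table = comm.cluster_otus(dm, records=records)
        assert len(table.otu_ids) == 3

    def test_determinism_byte_identical_fasta(self, three_cluster_spec):
        outputs = []
        for _ in range(2):
            records, _ = syn.generate_sequences(three_cluster_spec)
            buf = io.StringIO()
            comm.write_fasta(records, buf)
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_labels_carry_sample_and_cluster(self, three_cluster_spec):
        records, truth = syn.generate_sequences(three_cluster_spec)
        for rec in records:
            sample, cluster, _ = rec.id.split("|")
            assert rec.sample == sample
        assert set(truth["cluster"]) == {"A", "B", "C"}

    def test_realized_divergence_tracks_spec(self, three_cluster_spec):
        records, truth = syn.generate_sequences(three_cluster_spec)
        cluster_of = dict(zip(truth["seq_id"], truth["cluster"]))
        dm = comm.pairwise_distances(records)
        cross = [
            dm.values[i, j]
            for i in range(len(dm.ids))
            for j in range(i + 1, len(dm.ids))
            if cluster_of[dm.ids[i]] != cluster_of[dm.ids[j]]
        ]
        # centroids differ at ~between_divergence of sites
        assert abs(np.mean(cross) - 0.15) < 0.02

    def test_unseparable_spec_rejected(self):
        with pytest.raises(ValueError, match="separable"):
            syn.CommunitySpec(
                n_samples=1,
                clusters=(
                    syn.ClusterSpec("A", 200, 0.01, (5,)),
                    syn.ClusterSpec("B", 200, 0.01, (5,)),
                ),
                between_divergence=0.04,  # <= 0.03 + 2 * 0.01
                seed=0,
            ).validate_separable()

    def test_wide_within_divergence_rejected(self):
        spec = syn.CommunitySpec(
            n_samples=1,
            clusters=(syn.ClusterSpec("A", 200, 0.10, (5,)),),
            between_divergence=0.5,
            seed=0,
        )
        with pytest.raises(ValueError, match="cutoff"):
            syn.generate_sequences(spec)

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError, match=">= 100"):
            syn.ClusterSpec("A", 50, 0.0, (5,))

    @pytest.mark.parametrize("seed", range(20))
    def test_separability_over_seeds(self, seed):
        spec = syn.CommunitySpec(
            n_samples=1,
            clusters=(
                syn.ClusterSpec("A", 250, 0.008, (6,)),
                syn.ClusterSpec("B", 250, 0.008, (6,)),
                syn.ClusterSpec("C", 250, 0.008, (6,)),
            ),
            between_divergence=0.12,
            seed=seed,
        )
        records, _ = syn.generate_sequences(spec)
        table = comm.cluster_otus(comm.pairwise_distances(records), records=records)
        assert len(table.otu_ids) == 3


class TestGenerateQpcrPlate:
    def test_noiseless_standards_on_line(self, clean_plate_spec):
        plate = syn.generate_qpcr_plate(clean_plate_spec)
        # direct line evaluation with slope -3.3219, intercept 38
        expected = {
            1e7: 14.7467,
            1e6: 18.0686,
            1e5: 21.3905,
            1e4: 24.7124,
            1e3: 28.0343,
        }
        for copies, cq in expected.items():
            got = plate.standards.loc[plate.standards["copies"] == copies, "cq"]
            assert np.allclose(got, cq, atol=1e-4)

    def test_noiseless_unknown_on_line(self, clean_plate_spec):
        plate = syn.generate_qpcr_plate(clean_plate_spec)
        cqs = plate.unknowns.query("sample == 'u1'")["cq"]
        assert np.allclose(cqs, -3.3219 * 5 + 38.0)

    def test_zero_copies_emits_sentinel_not_cq(self):
        spec = syn.QpcrPlateSpec(
            true_slope=-3.3,
            true_intercept=38.0,
            dilution_top=1e7,
            dilution_levels=5,
            unknown_true_copies={"empty": 0.0},
            seed=2,
        )
        plate = syn.generate_qpcr_plate(spec)
        sub = plate.unknowns.query("sample == 'empty'")
        assert sub["no_amplification"].all()
        assert sub["cq"].isna().all()

    def test_noisy_triplicates_reproducible(self):
        spec = syn.QpcrPlateSpec(
            true_slope=-3.3,
            true_intercept=38.0,
            dilution_top=1e7,
            dilution_levels=5,
            unknown_true_copies={"u": 1e4},
            cq_noise_sd=0.2,
            replicates=3,
            seed=99,
        )
        a = syn.generate_qpcr_plate(spec)
        b = syn.generate_qpcr_plate(spec)
        pd.testing.assert_frame_equal(a.standards, b.standards)
        pd.testing.assert_frame_equal(a.unknowns, b.unknowns)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            syn.QpcrPlateSpec(
                true_slope=3.3, true_intercept=38, dilution_top=1e7,
                dilution_levels=5, unknown_true_copies={},
            )
        with pytest.raises(ValueError):
            syn.QpcrPlateSpec(
                true_slope=-3.3, true_intercept=38, dilution_top=1e7,
                dilution_levels=3, unknown_true_copies={},
            )


class TestGenerateIncubation:
    def test_no_cells_flat_series(self):
        spec = syn.IncubationSpec(
            guild_cells={"AOA": 0.0},
            guild_r_in={"AOA": 0.5},
            nh4_start=1.0,
            blank_level=0.3,
        )
        series, truth = syn.generate_incubation(spec)
        assert truth.nnr_max == 0.0
        assert np.allclose(series.nh4_sample, series.nh4_sample[0])
        assert np.all(series.no2_sample == 0)
        assert np.all(series.no3_sample == 0)

    def test_true_nnr_matches_hand_calculation(self, noiseless_incubation_spec):
        # independent unit tracking: cells * r * 14 fg/fmol * 1e-9 ug/fg
        _, truth = syn.generate_incubation(noiseless_incubation_spec)
        expected = (1e5 * 0.5 + 5e3 * 1.0 + 1e3 * 0.5) * 14e-9
        assert truth.nnr_max == pytest.approx(expected, rel=1e-12)

    def test_mass_conservation_every_timepoint(self, noiseless_incubation_spec):
        series, _ = syn.generate_incubation(noiseless_incubation_spec)
        net = kin.net_concentrations(series)
        d_nh4 = net.nh4[0] - net.nh4
        d_nox = (net.no2 + net.no3) - (net.no2[0] + net.no3[0])
        assert np.allclose(d_nh4, d_nox, atol=1e-15)

    def test_round_trip_recovers_truth(self, noiseless_incubation_spec):
        series, truth = syn.generate_incubation(noiseless_incubation_spec)
        net = kin.net_concentrations(series)
        rate = kin.nnr_max(net, q1=series.q1, t=series.t_end, q2=series.q2)
        assert rate.nnr_max == pytest.approx(truth.nnr_max, rel=1e-9)

    def test_excessive_rate_rejected(self):
        spec_kwargs = dict(
            guild_cells={"AOA": 1e9},
            guild_r_in={"AOA": 208.0},
            nh4_start=0.5,
        )
        with pytest.raises(ValueError, match="rate"):
            syn.generate_incubation(syn.IncubationSpec(**spec_kwargs))

    def test_timepoints_validated(self):
        with pytest.raises(ValueError, match="timepoints"):
            syn.IncubationSpec(
                guild_cells={"AOA": 1.0},
                guild_r_in={"AOA": 1.0},
                nh4_start=1.0,
                timepoints=(2, 4, 6),
            )


class TestGenerateEnvTable:
    def _spec(self, sign, noise=0.0, seed=0, n=6):
        return syn.EnvTableSpec(
            n_samples=n,
            factors=("temperature", "pm"),
            planted_links=(("taxonA", "temperature", sign),),
            noise_sd=noise,
            seed=seed,
        )

    def test_positive_link_perfect_rho(self):
        factors, taxa = syn.generate_env_table(self._spec(+1))
        rho = st.spearman_rho(factors["temperature"], taxa["taxonA"])
        assert rho == 1.0

    def test_negative_link_perfect_antirho(self):
        factors, taxa = syn.generate_env_table(self._spec(-1))
        rho = st.spearman_rho(factors["temperature"], taxa["taxonA"])
        assert rho == -1.0

    def test_null_link_uniform_pvalues(self):
        # empirical check over 250 seeds: exact-permutation p under the
        # planted-0 null follows the enumerated discrete null multiset
        from scipy import stats as sps

        from conftest import exact_permutation_null_atoms

        ps = []
        for seed in range(250):
            factors, taxa = syn.generate_env_table(self._spec(0, seed=seed))
            ps.append(
                st.permutation_pvalue(
                    factors["temperature"].to_numpy(), taxa["taxonA"].to_numpy()
                )
            )
        assert sps.ks_2samp(ps, exact_permutation_null_atoms(6)).pvalue > 0.01

    def test_duplicate_factor_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            syn.EnvTableSpec(
                n_samples=6,
                factors=("a", "a"),
                planted_links=(),
            )

    def test_determinism(self):
        a = syn.generate_env_table(self._spec(+1, noise=0.3, seed=4))
        b = syn.generate_env_table(self._spec(+1, noise=0.3, seed=4))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestYamlRoundTrip:
    def test_community_spec_from_yaml(self, tmp_path):
        text = """
n_samples: 2
between_divergence: 0.15
seed: 3
clusters:
  - {label: A, centroid_length: 200, within_divergence: 0.005, abundances: [4, 4]}
  - {label: B, centroid_length: 200, within_divergence: 0.005, abundances: [2, 0]}
"""
        path = tmp_path / "spec.yaml"
        path.write_text(text)
        spec = syn.CommunitySpec.from_yaml(str(path))
        assert spec.n_samples == 2
        records, _ = syn.generate_sequences(spec)
        assert len(records) == 10

    def test_incubation_spec_from_yaml(self, tmp_path):
        text = """
guild_cells: {AOA: 100000.0, AOB: 5000.0}
guild_r_in: {AOA: 0.5, AOB: 1.0}
nh4_start: 1.0
seed: 9
"""
        path = tmp_path / "inc.yaml"
        path.write_text(text)
        spec = syn.IncubationSpec.from_yaml(str(path))
        assert spec.q1 == 0.25 and spec.q2 == 48.0
        assert spec.timepoints == (0, 2, 4, 6, 8, 10, 12, 14, 16)
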