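"""PARS scoring, constraints, metagene/codon profiles, buried bases."""

import numpy as np
import pytest
from scipy import stats

from parsedit import synthio
from parsedit.counts import TrackError
from parsedit.pars import (
    agreement_with_known,
    buried_fraction,
    buried_mask,
    codon_periodicity,
    constraints_from_pars,
    metagene_profile,
    mean_pars_score,
    pars_score,
    relative_pars,
    relative_profile,
    write_constraint_file,
)


class TestScore:
    def test_arithmetic(self):
        prof = pars_score(np.array([7.0]), np.array([1.0]), pseudocount=1.0)
        assert prof.scores[0] == pytest.approx(2.0)  # log2(8/2)

    def test_equal_counts_zero(self, rng):
        v = rng.poisson(10, 50).astype(float)
        assert np.allclose(pars_score(v, v).scores, 0)

    def test_antisymmetric_under_enzyme_swap(self, rng):
        v1, s1 = rng.poisson(8, 100).astype(float), rng.poisson(8, 100).astype(float)
        assert np.allclose(pars_score(v1, s1).scores, -pars_score(s1, v1).scores)

    def test_zero_pseudocount_with_zeros_rejected(self):
        with pytest.raises(TrackError):
            pars_score(np.array([0.0, 1.0]), np.array([1.0, 1.0]), pseudocount=0)

    def test_replicate_mean_is_mean_of_scores(self, rng):
        a = pars_score(rng.poisson(9, 20) + 1.0, rng.poisson(9, 20) + 1.0)
        b = pars_score(rng.poisson(9, 20) + 1.0, rng.poisson(9, 20) + 1.0)
        assert np.allclose(mean_pars_score([a, b]), (a.scores + b.scores) / 2)


class TestRelativeProfile:
    def test_sums_to_one(self, rng):
        assert relative_profile(rng.poisson(5, 30) + 1.0).sum() == pytest.approx(1.0)

    def test_uniform(self):
        assert np.allclose(relative_profile(np.full(20, 7.0)), 1 / 20)

    def test_scale_invariance(self, rng):
        v = rng.poisson(6, 40) + 1.0
        assert np.allclose(relative_profile(v), relative_profile(10 * v))

    def test_relative_pars_matches_profiles(self, rng):
        v1 = rng.poisson(6, 40).astype(float)
        s1 = rng.poisson(6, 40).astype(float)
        want = np.log2(relative_profile(v1 + 1) / relative_profile(s1 + 1))
        assert np.allclose(relative_pars(v1, s1), want)

    def test_zero_region_rejected(self):
        with pytest.raises(TrackError):
            relative_profile(np.zeros(5))


class TestAgreement:
    def test_extremes(self):
        ann = np.array(["DS", "DS", "SS", "SS"])
        v1 = np.array([5.0, 5, 0, 0])
        s1 = np.array([0.0, 0, 5, 5])
        assert agreement_with_known(v1, s1, ann) == 1.0
        assert agreement_with_known(s1, v1, ann) == 0.0

    def test_label_inversion_complements(self, rng):
        ann = np.array(["DS"] * 30 + ["SS"] * 30)
        inv = np.where(ann == "DS", "SS", "DS")
        v1 = rng.poisson(10, 60) + 1.0
        s1 = rng.poisson(10, 60) + 1.0
        a = agreement_with_known(v1, s1, ann)
        assert 0 <= a <= 1
        assert agreement_with_known(v1, s1, inv) == pytest.approx(1 - a)

    def test_simulated_hairpin_exceeds_ninety_percent(self, rng):
        """With V1 strongly double-strand preferring and a half-paired
        molecule, read agreement with the known structure is > 0.9."""
        cfg = synthio.SimulationConfig(v1_ss_rate=0.05, s1_ds_rate=0.05)
        stem, loop = 50, 100
        L = 2 * stem + loop
        seq = ["G"] * stem + ["A"] * loop + ["C"] * stem
        pair_map = np.full(L, -1)
        for k in range(stem):
            pair_map[k], pair_map[L - 1 - k] = L - 1 - k, k
        t = synthio.SyntheticTranscript(
            id="hp", sequence="".join(seq), pair_map=pair_map,
            edit_sites=[], region_labels=np.array(["3UTR"] * L),
        )
        ens = synthio.realize_molecules(t, "control", 10, rng)
        v1 = synthio.simulate_digestion(ens, "V1", 100_000, rng, cfg)
        s1 = synthio.simulate_digestion(ens, "S1", 100_000, rng, cfg)
        ann = np.where(t.baseline_paired(), "DS", "SS")
        assert agreement_with_known(v1, s1, ann) > 0.9


class TestConstraints:
    def test_thresholds(self):
        scores = np.array([0.0, 3.0, -3.0, 2.5, -2.5])
        constraint, _ = constraints_from_pars(scores)
        assert constraint == ".|x.."  # strict > 2.5 and < -2.5

    def test_all_free(self):
        constraint, _ = constraints_from_pars(np.zeros(4))
        assert constraint == "...."

    def test_des_substitution_rules(self):
        seq = "AAAA"
        _, edited = constraints_from_pars(
            np.zeros(4),
            sequence=seq,
            des_substitutions=[(0, 50, 0.5), (1, 150, 0.2), (2, 150, 0.05)],
        )
        # only the site with coverage > 100 AND level > 0.1 is substituted
        assert edited == "AGAA"

    def test_raising_hi_never_adds_ds(self, rng):
        scores = rng.normal(0, 2, 200)
        c1, _ = constraints_from_pars(scores, hi=2.0)
        c2, _ = constraints_from_pars(scores, hi=3.0)
        for a, b in zip(c1, c2):
            assert not (a == "." and b == "|")

    def test_constraint_file(self, tmp_path):
        write_constraint_file("ACGU", ".|x.", tmp_path / "c.txt", name="r1")
        assert (tmp_path / "c.txt").read_text() == ">r1\nACGU\n.|x.\n"


class TestMetagene:
    def test_single_transcript_identity(self):
        v = np.arange(11.0)
        prof = metagene_profile({"t": v}, {"t": 5}, span=5)
        assert np.allclose(prof, v)

    def test_opposite_values_cancel(self):
        v = np.arange(9.0)
        prof = metagene_profile({"a": v, "b": -v}, {"a": 4, "b": 4}, span=4)
        assert np.allclose(prof, 0)

    def test_planted_dip_at_anchor(self, rng):
        values, anchors = {}, {}
        for i in range(30):
            v = rng.normal(1.0, 0.2, 301)
            v[150] -= 3.0
            values[f"t{i}"] = v
            anchors[f"t{i}"] = 150
        prof = metagene_profile(values, anchors, span=100)
        assert np.argmin(prof) == 100  # offset 0

    def test_edge_transcripts_contribute_partially(self):
        prof = metagene_profile({"t": np.ones(5)}, {"t": 1}, span=3)
        assert np.isnan(prof[0]) and np.isnan(prof[1])
        assert prof[2] == 1


class TestCodonPeriodicity:
    def test_constant_profile(self):
        means = codon_periodicity(np.full(30, 2.0), (0, 30))
        assert np.allclose(means, 2.0)

    def test_period_three_recovered(self):
        scores = np.tile([1.0, 5.0, 3.0], 10)
        assert np.allclose(codon_periodicity(scores, (0, 30)), [1, 5, 3])

    def test_trailing_truncated_and_short_rejected(self):
        scores = np.tile([1.0, 5.0, 3.0], 4)
        assert np.allclose(codon_periodicity(scores, (0, 11)), [1, 5, 3])
        with pytest.raises(TrackError):
            codon_periodicity(scores, (0, 2))

    def test_permutation_within_codon_class_invariant(self, rng):
        scores = rng.normal(size=60)
        base = codon_periodicity(scores, (0, 60))
        shuffled = scores.reshape(-1, 3)[rng.permutation(20)].ravel()
        assert np.allclose(codon_periodicity(shuffled, (0, 60)), base)


class TestBuried:
    def test_all_equal_none_buried(self):
        assert buried_fraction(np.full(10, 4.0), np.full(10, 6.0)) == 0

    def test_double_zero_base_buried(self):
        v1 = np.array([5.0, 5, 0, 5])
        s1 = np.array([4.0, 4, 0, 4])
        mask = buried_mask(v1, s1)
        assert list(mask) == [False, False, True, False]

    def test_buried_bases_have_lower_coverage(self, rng):
        """Simulated solvent-buried stretch (low cleavage by both enzymes)
        is recovered, and its coverage ranks below exposed bases."""
        L = 300
        buried = np.zeros(L, dtype=bool)
        buried[100:140] = True
        w = np.where(buried, 0.05, 1.0)
        v1 = rng.multinomial(50_000, w / w.sum()).astype(float)
        s1 = rng.multinomial(50_000, w / w.sum()).astype(float)
        mask = buried_mask(v1, s1)
        assert mask[buried].mean() > 0.9
        cov = v1 + s1
        p = stats.mannwhitneyu(cov[mask], cov[~mask], alternative="less").pvalue
        assert p < 1e-6
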