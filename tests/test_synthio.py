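"""The digestion/editing simulator: construction rules and ground truth."""

import numpy as np
import pytest
from scipy import stats

from parsedit import synthio
from parsedit.pars import pars_score
from parsedit.synthio import (
    InvalidConfigError,
    MoleculeEnsemble,
    SimulationConfig,
    SyntheticTranscript,
    digestion_weights,
    emit_fixtures,
    make_transcriptome,
    realize_molecules,
    simulate_digestion,
    simulate_experiment,
)


class TestConfigValidation:
    def test_arms_must_fit(self):
        with pytest.raises(InvalidConfigError, match="do not fit"):
            SimulationConfig(length_range=(300, 400), arm_length=100)

    def test_enzyme_preferences_enforced(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(v1_ds_rate=0.1, v1_ss_rate=0.5)
        with pytest.raises(InvalidConfigError):
            SimulationConfig(s1_ds_rate=1.0, s1_ss_rate=0.5)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(s1_ds_rate=-0.1)


class TestTranscriptome:
    def test_same_seed_identical(self):
        a, _ = make_transcriptome(SimulationConfig(n_transcripts=5, seed=9))
        b, _ = make_transcriptome(SimulationConfig(n_transcripts=5, seed=9))
        for ta, tb in zip(a, b):
            assert ta.sequence == tb.sequence
            assert np.array_equal(ta.pair_map, tb.pair_map)
            assert ta.edit_sites == tb.edit_sites

    def test_pair_map_symmetric_and_sites_on_a(self, small_experiment):
        for t in small_experiment.transcripts:
            duplex = np.nonzero(t.pair_map >= 0)[0]
            for i in duplex:
                assert t.pair_map[t.pair_map[i]] == i
            for s in t.edit_sites:
                assert t.sequence[s.pos] == "A"
                assert t.sequence[s.partner_pos] == s.partner_base
                assert 0 <= s.level_kd <= s.level_control <= 1

    def test_zero_mismatch_rate_gives_perfect_arms(self):
        cfg = SimulationConfig(n_transcripts=10, mismatch_rate=0.0, seed=3)
        transcripts, truth = make_transcriptome(cfg)
        comp = synthio.COMPLEMENT
        for t in transcripts:
            for i in np.nonzero(t.pair_map >= 0)[0]:
                assert t.sequence[int(t.pair_map[i])] == comp[t.sequence[i]]
            # no A:C mismatches exist, so no stabilizing sites are possible
            assert all(s.partner_base != "C" for s in t.edit_sites)

    def test_realized_mismatch_rate_in_binomial_ci(self):
        cfg = SimulationConfig(n_transcripts=100, mismatch_rate=0.15, seed=8)
        transcripts, _ = make_transcriptome(cfg)
        comp = synthio.COMPLEMENT
        n_mm = n_tot = 0
        for t in transcripts:
            for i in np.nonzero(t.pair_map >= 0)[0]:
                n_tot += 1
                if t.sequence[int(t.pair_map[i])] != comp[t.sequence[i]]:
                    n_mm += 1
        n_tot //= 2  # each arm pair counted from both sides
        n_mm //= 2
        lo, hi = stats.binom.interval(0.99, n_tot, 0.15)
        assert lo <= n_mm <= hi

    def test_truth_covers_every_transcript_once(self, small_experiment):
        ids = [t.id for t in small_experiment.transcripts]
        assert sorted(small_experiment.truth.transcripts) == sorted(ids)
        assert len(set(ids)) == len(ids)


class TestMolecules:
    def _one_site_transcript(self, partner_base, level):
        cfg = SimulationConfig(n_transcripts=30, seed=5)
        transcripts, _ = make_transcriptome(cfg)
        for t in transcripts:
            for k, s in enumerate(t.edit_sites):
                if s.partner_base == partner_base:
                    t.edit_sites[k] = synthio.EditSite(
                        s.pos, s.partner_pos, s.partner_base, level, level
                    )
                    return t, k
        raise AssertionError("fixture lacks a suitable site")

    def test_level_one_ac_site_always_paired(self, rng):
        t, k = self._one_site_transcript("C", 1.0)
        ens = realize_molecules(t, "control", 500, rng)
        p = ens.paired_probability()
        assert p[t.edit_sites[k].pos] == 1.0

    def test_level_one_au_site_never_paired(self, rng):
        t, k = self._one_site_transcript("U", 1.0)
        ens = realize_molecules(t, "control", 500, rng)
        assert ens.paired_probability()[t.edit_sites[k].pos] == 0.0

    def test_edited_fraction_matches_level(self, rng):
        t, k = self._one_site_transcript("U", 0.5)
        ens = realize_molecules(t, "control", 10_000, rng)
        lo, hi = stats.binom.interval(0.99, 10_000, 0.5)
        assert lo <= ens.edited[:, k].sum() <= hi

    def test_au_editing_monotonically_unpairs(self):
        """Raising an A:U site's editing level lowers that base's V1 weight."""
        t, k = self._one_site_transcript("U", 0.5)
        cfg = SimulationConfig()
        pos = t.edit_sites[k].pos
        shares = []
        for frac in (0.0, 0.3, 0.6, 0.9):
            n = 100
            edited = np.zeros((n, len(t.edit_sites)), dtype=bool)
            edited[: int(frac * n), k] = True
            ens = MoleculeEnsemble(transcript=t, condition="control", edited=edited)
            w = digestion_weights(ens, "V1", cfg)
            shares.append(w[pos] / w.sum())
        assert all(a > b for a, b in zip(shares, shares[1:]))


class TestDigestion:
    def test_depth_conserved(self, small_experiment, small_cfg):
        for track in small_experiment.tracks:
            for tid, vec in track.counts.items():
                assert vec.sum() == small_cfg.depth

    def test_rate_extremes(self, rng):
        cfg = SimulationConfig(
            n_transcripts=1, mismatch_rate=0.0, v1_ss_rate=0.0, s1_ds_rate=0.0, seed=1
        )
        transcripts, _ = make_transcriptome(cfg)
        t = transcripts[0]
        ens = realize_molecules(t, "control", 50, rng)
        v1 = simulate_digestion(ens, "V1", 5000, rng, cfg)
        s1 = simulate_digestion(ens, "S1", 5000, rng, cfg)
        paired = t.baseline_paired()
        assert v1[~paired].sum() == 0  # V1 cannot cut single-stranded bases
        assert s1[paired].sum() == 0  # S1 cannot cut the duplex

    def test_invalid_depth(self, small_experiment, rng, small_cfg):
        ens = realize_molecules(small_experiment.transcripts[0], "control", 10, rng)
        with pytest.raises(InvalidConfigError):
            simulate_digestion(ens, "V1", 0, rng, small_cfg)

    def test_uniform_weights_multinomial(self, rng):
        """A fully single-stranded molecule gives uniform S1 weights; the
        drawn counts must be consistent with a uniform multinomial."""
        t = SyntheticTranscript(
            id="flat",
            sequence="A" * 200,
            pair_map=np.full(200, -1),
            edit_sites=[],
            region_labels=np.array(["3UTR"] * 200),
        )
        cfg = SimulationConfig()
        ens = realize_molecules(t, "control", 10, rng)
        counts = simulate_digestion(ens, "S1", 50_000, rng, cfg)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_hairpin_pars_sign(self, rng):
        """Deep digestion of a hairpin: stem scores positive, loop negative."""
        stem, loop = 40, 20
        L = 2 * stem + loop
        seq = list("A" * L)
        pair_map = np.full(L, -1)
        for k in range(stem):
            i, j = k, L - 1 - k
            pair_map[i], pair_map[j] = j, i
            seq[i], seq[j] = "G", "C"
        t = SyntheticTranscript(
            id="hp", sequence="".join(seq), pair_map=pair_map,
            edit_sites=[], region_labels=np.array(["3UTR"] * L),
        )
        cfg = SimulationConfig()
        ens = realize_molecules(t, "control", 10, rng)
        v1 = simulate_digestion(ens, "V1", 100_000, rng, cfg)
        s1 = simulate_digestion(ens, "S1", 100_000, rng, cfg)
        scores = pars_score(v1, s1).scores
        in_stem = pair_map >= 0
        assert scores[in_stem].mean() > 1
        assert scores[~in_stem].mean() < -1


class TestFixtures:
    def test_replicate_layout_and_roundtrip(self, tmp_path):
        from parsedit.counts import load_experiment

        cfg = SimulationConfig(n_transcripts=4, n_replicates=2, seed=6)
        exp = simulate_experiment(cfg)
        manifest = emit_fixtures(exp.transcripts, exp.tracks, exp.truth, tmp_path, cfg=cfg)
        track_files = [k for k in manifest if k.startswith("track_")]
        assert len(track_files) == 8  # 2 conditions x 2 enzymes x 2 replicates
        loaded = load_experiment(tmp_path)
        by_name = {t.meta.name: t for t in loaded}
        for orig in exp.tracks:
            got = by_name[orig.meta.name]
            for tid, vec in orig.counts.items():
                assert np.allclose(got.counts[tid], vec)

    def test_empty_transcript_list(self, tmp_path):
        from parsedit.synthio import TruthTable

        manifest = emit_fixtures([], [], TruthTable(), tmp_path)
        assert manifest["fasta"].exists()
        assert manifest["truth"].read_text().strip() == "{}"
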