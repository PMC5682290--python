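"""Editing levels, differential editing, hyper-edit filter, pairing context."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parsedit import synthio
from parsedit.editing import (
    EditingError,
    call_des,
    call_editing,
    editing_structure_correlation,
    hyper_edit_read_filter,
    level_by_context,
    mismatches_from_alignment,
    pair_context,
    read_pileup,
)
from conftest import make_sam


def _pileup(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "A", "C", "G", "T"])


class TestCallEditing:
    def test_levels_and_ignored_bases(self):
        sites = pd.DataFrame({"chrom": ["t"] * 2, "pos": [5, 9], "strand": ["+"] * 2})
        pile = _pileup([("t", 5, "+", 8, 3, 2, 7), ("t", 9, "+", 4, 0, 0, 0)])
        out = call_editing({"control": pile}, sites)
        # C/T counts do not enter the level
        assert out.loc[0, "level_control"] == pytest.approx(0.2)
        assert out.loc[1, "level_control"] == 0.0

    def test_uncovered_sites_omitted(self):
        sites = pd.DataFrame({"chrom": ["t"], "pos": [99], "strand": ["+"]})
        out = call_editing({"control": _pileup([("t", 5, "+", 8, 0, 2, 0)])}, sites)
        assert out.empty

    def test_strand_required(self):
        with pytest.raises(EditingError):
            call_editing({}, pd.DataFrame({"chrom": ["t"], "pos": [1]}))

    def test_pileup_reader_validates(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tpos\n")
        with pytest.raises(EditingError):
            read_pileup(p)


def fisher_one_sided_oracle(g_c, a_c, g_k, a_k):
    """Hypergeometric tail: P(control G count >= observed | margins)."""
    M = g_c + a_c + g_k + a_k
    n = g_c + g_k
    N = g_c + a_c
    return float(stats.hypergeom.sf(g_c - 1, M, n, N))


class TestCallDes:
    def _sites(self, g_c, a_c, g_k, a_k):
        return pd.DataFrame(
            {
                "chrom": ["t"],
                "pos": [1],
                "strand": ["+"],
                "A_control": [a_c],
                "G_control": [g_c],
                "A_kd": [a_k],
                "G_kd": [g_k],
                "level_control": [g_c / (a_c + g_c)],
                "level_kd": [g_k / (a_k + g_k)],
            }
        )

    def test_strong_drop_is_des(self):
        out = call_des(self._sites(50, 50, 5, 95))
        assert bool(out.loc[0, "is_des"])
        assert out.loc[0, "p"] == pytest.approx(fisher_one_sided_oracle(50, 50, 5, 95), rel=1e-9)

    def test_identical_counts_not_des(self):
        out = call_des(self._sites(20, 80, 20, 80))
        assert not bool(out.loc[0, "is_des"])
        # one-sided exact tail at the observed value is well above alpha
        assert out.loc[0, "p"] > 0.5
        assert out.loc[0, "p"] == pytest.approx(fisher_one_sided_oracle(20, 80, 20, 80), rel=1e-9)

    def test_increase_flagged_as_adar2_candidate(self):
        out = call_des(self._sites(5, 95, 50, 50))
        assert not bool(out.loc[0, "is_des"])
        assert out.loc[0, "direction"] == "higher_in_kd"
        assert bool(out.loc[0, "adar2_candidate"])

    def test_type_one_error_on_null(self, rng):
        """Equal true levels in both conditions: DES rate stays <= nominal."""
        n = 400
        g_c = rng.binomial(60, 0.3, n)
        g_k = rng.binomial(60, 0.3, n)
        sites = pd.DataFrame(
            {
                "chrom": "t",
                "pos": np.arange(n),
                "strand": "+",
                "A_control": 60 - g_c,
                "G_control": g_c,
                "A_kd": 60 - g_k,
                "G_kd": g_k,
                "level_control": g_c / 60,
                "level_kd": g_k / 60,
            }
        )
        out = call_des(sites)
        assert out["is_des"].mean() <= 0.05


class TestHyperEditFilter:
    def test_spec_examples(self):
        ag = [("A", "G", 35)]
        assert hyper_edit_read_filter(100, ag * 6).passes
        assert not hyper_edit_read_filter(100, ag * 4).passes  # 4 < 5% of 100
        # purity: 10/12 ~ 83% <= 90%
        assert not hyper_edit_read_filter(100, ag * 10 + [("C", "T", 35)] * 2).passes

    def test_low_quality_ag_not_counted_for_density(self):
        mm = [("A", "G", 20)] * 6
        assert not hyper_edit_read_filter(100, mm).passes

    def test_missing_quality_rejected(self):
        with pytest.raises(EditingError):
            hyper_edit_read_filter(100, [("A", "G", None)])

    def test_matches_brute_force_recount(self, rng):
        """Filter decisions equal an independent recount on random reads."""
        bases = ["A", "C", "G", "T"]
        for _ in range(200):
            L = int(rng.integers(50, 150))
            n_mm = int(rng.integers(0, 12))
            mm = [
                (bases[rng.integers(4)], bases[rng.integers(4)], int(rng.integers(10, 41)))
                for _ in range(n_mm)
            ]
            got = hyper_edit_read_filter(L, mm)
            n_ag_hq = sum(1 for r, a, q in mm if r == "A" and a == "G" and q >= 30)
            n_ag = sum(1 for r, a, q in mm if r == "A" and a == "G")
            want = n_ag_hq >= 0.05 * L and (len(mm) > 0 and n_ag > 0.9 * len(mm))
            assert got.passes == want

    def test_mismatches_from_alignment(self, tmp_path):
        import pysam

        ref = "ACGTACGTAC"
        sam = make_sam(
            tmp_path / "h.sam",
            {"tx": 10},
            [{"ref": "tx", "pos": 0, "cigar": "10M", "seq": "GCGTACGTGC", "quals": [30] * 10}],
        )
        with pysam.AlignmentFile(str(sam), check_sq=False) as fh:
            read = next(iter(fh))
            mm = mismatches_from_alignment(read, ref)
        assert mm == [("A", "G", 30), ("A", "G", 30)]


class TestPairContext:
    def test_classes(self):
        seq = "AAAC"  # site 0 pairs base 3 (C); site 1 unpaired
        pm = np.array([3, -1, -1, 0])
        classes, _ = pair_context([0], seq, pm)
        assert classes == ["AC"]

    def test_unpaired_is_other_and_non_a_rejected(self):
        seq = "ACAU"
        pm = np.array([3, -1, -1, 0])
        classes = __import__("parsedit.editing", fromlist=["classify_pair_context"]).classify_pair_context(
            [2], seq, pm
        )
        assert classes == ["other"]
        with pytest.raises(EditingError):
            pair_context([1], seq, pm)

    def test_preferential_ac_seeding_detected(self):
        """Simulation seeding edits at A:C mismatches: observed A:C share of
        edited sites exceeds the duplex's A:C availability."""
        cfg = synthio.SimulationConfig(n_transcripts=40, frac_swe=0.6, frac_dswe=0.3, seed=13)
        transcripts, _ = synthio.make_transcriptome(cfg)
        n_ac = n_au = exp_num = exp_den = 0
        pooled_p = []
        for t in transcripts:
            if not t.edit_sites:
                continue
            classes, rep = pair_context([s.pos for s in t.edit_sites], t.sequence, t.pair_map)
            n_ac += classes.count("AC")
            n_au += classes.count("AU")
            exp_num += rep.n_duplex_ac
            exp_den += rep.n_duplex_ac + rep.n_duplex_au
        observed = n_ac / (n_ac + n_au)
        expected = exp_num / exp_den
        assert observed > expected
        p = stats.fisher_exact([[n_ac, n_au], [exp_num, exp_den - exp_num]])[1]
        assert p < 0.01


class TestLevelByContext:
    def _sites(self, ac_levels, au_levels, coverage=50):
        rows = [("AC", lv, coverage) for lv in ac_levels] + [("AU", lv, coverage) for lv in au_levels]
        return pd.DataFrame(rows, columns=["pair_class", "level_control", "coverage"])

    def test_coverage_exactly_five_excluded(self):
        df = self._sites([0.2, 0.3], [0.1, 0.15])
        df.loc[0, "coverage"] = 5  # strict > 5 filter drops this site
        summary, _ = level_by_context(df)
        assert summary.loc["AC", "count"] == 1

    def test_identical_sets_p_one(self):
        summary, p = level_by_context(self._sites([0.2, 0.2], [0.2, 0.2]))
        assert p == 1.0

    def test_true_class_means_recovered(self, rng):
        """Sites simulated at true mean levels 0.16 (A:C) and 0.10 (A:U),
        coverage 100: class means recovered within +/- 0.02."""
        n = 400
        cov = 100
        rows = []
        for klass, mu in (("AC", 0.16), ("AU", 0.10)):
            g = rng.binomial(cov, mu, n)
            rows += [(klass, gi / cov, cov) for gi in g]
        df = pd.DataFrame(rows, columns=["pair_class", "level_control", "coverage"])
        summary, p = level_by_context(df)
        assert summary.loc["AC", "mean"] == pytest.approx(0.16, abs=0.02)
        assert summary.loc["AU", "mean"] == pytest.approx(0.10, abs=0.02)
        assert p < 1e-6

    def test_empty_class_named(self):
        with pytest.raises(EditingError, match="AU"):
            level_by_context(self._sites([0.2], []))


class TestStructureCorrelation:
    def test_perfectly_monotone(self):
        ds = {f"t{i}": i / 20 for i in range(20)}
        lv = {f"t{i}": i / 40 + 0.1 for i in range(20)}
        rho, _ = editing_structure_correlation(ds, lv)
        assert rho == pytest.approx(1.0)

    def test_independent_quantities_near_zero(self, rng):
        ds = {f"t{i}": float(x) for i, x in enumerate(rng.random(100))}
        lv = {f"t{i}": float(x) for i, x in enumerate(rng.random(100))}
        rho, p = editing_structure_correlation(ds, lv)
        assert abs(rho) < 0.25
        assert p > 0.01

    def test_coupled_simulation_positive(self, rng):
        truth = rng.random(100)
        ds = {f"t{i}": float(x + rng.normal(0, 0.2)) for i, x in enumerate(truth)}
        lv = {f"t{i}": float(x + rng.normal(0, 0.2)) for i, x in enumerate(truth)}
        rho, p = editing_structure_correlation(ds, lv)
        assert rho > 0.3 and p < 1e-3

    def test_too_few_or_constant(self):
        with pytest.raises(EditingError):
            editing_structure_correlation({"a": 1.0}, {"a": 2.0})
        ds = {f"t{i}": 0.5 for i in range(12)}
        lv = {f"t{i}": i * 0.01 for i in range(12)}
        with pytest.raises(EditingError):
            editing_structure_correlation(ds, lv)
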