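"""Parameter-recovery benchmarks on synthetic data with known ground truth.

Each function simulates under stated conditions and measures how well the
corresponding estimator recovers the planted truth: editing-level bias, DES
detection sensitivity and null false-positive rate, structure-change (SSC)
sensitivity and false-positive rate, the control-vs-knockdown direction of
the DS/(DS+SS) ratio, the A:C pairing-context excess, and agreement of deep
digestion with a known structure.  The test suite and the acceptance script
both run these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import editing, sschange, strclass, synthio
from .pars import agreement_with_known


@dataclass
class SSCRecovery:
    sensitivity: float
    fpr: float
    n_positive: int
    n_negative: int


def ssc_recovery(
    n_transcripts: int = 200,
    depth: int = 10_000,
    seed: int = 11,
    n_perm: int = 100,
) -> SSCRecovery:
    """SSC calling against the simulator's truth at the 3'UTR region grain."""
    cfg = synthio.SimulationConfig(n_transcripts=n_transcripts, depth=depth, seed=seed)
    exp = synthio.simulate_experiment(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    truth = exp.truth.transcripts
    hits = {True: [0, 0], False: [0, 0]}  # is_positive -> [called, total]
    for t in exp.transcripts:
        lo, hi = t.utr3_interval()
        matrices = {
            enz: sschange.ProfileMatrix(
                t.id,
                exp.track("control", enz, 1).counts[t.id][lo:hi],
                exp.track("control", enz, 2).counts[t.id][lo:hi],
                exp.track("kd", enz, 1).counts[t.id][lo:hi],
                exp.track("kd", enz, 2).counts[t.id][lo:hi],
            )
            for enz in ("V1", "S1")
        }
        res = sschange.analyze_region(t.id, matrices, n_perm, rng)
        key = truth[t.id].is_ssc
        hits[key][0] += res.is_ssc
        hits[key][1] += 1
    return SSCRecovery(
        sensitivity=hits[True][0] / hits[True][1] if hits[True][1] else float("nan"),
        fpr=hits[False][0] / hits[False][1] if hits[False][1] else float("nan"),
        n_positive=hits[True][1],
        n_negative=hits[False][1],
    )


def editing_level_bias(n_sites: int = 1000, coverage: int = 100, seed: int = 1) -> float:
    """Mean (estimate - truth) of the G/(A+G) level estimator."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 102]))
    truth = rng.uniform(0.05, 0.95, n_sites)
    g = rng.binomial(coverage, truth)
    pile = pd.DataFrame(
        {
            "chrom": "t",
            "pos": np.arange(1, n_sites + 1),
            "strand": "+",
            "A": coverage - g,
            "C": 0,
            "G": g,
            "T": 0,
        }
    )
    sites = pile[["chrom", "pos", "strand"]]
    out = editing.call_editing({"control": pile}, sites)
    return float(np.mean(out["level_control"].to_numpy() - truth))


@dataclass
class DESRecovery:
    sensitivity: float
    null_fpr: float
    n_sites: int


def des_recovery(
    n_sites: int = 200,
    coverage: int = 60,
    level_control: float = 0.5,
    level_kd: float = 0.15,
    seed: int = 1,
) -> DESRecovery:
    """DES sensitivity at a planted level drop, and false-positive rate on a
    matched null (equal true levels in both conditions)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 103]))

    def table(lv_c, lv_k):
        g_c = rng.binomial(coverage, lv_c, n_sites)
        g_k = rng.binomial(coverage, lv_k, n_sites)
        return pd.DataFrame(
            {
                "chrom": "t",
                "pos": np.arange(n_sites),
                "strand": "+",
                "A_control": coverage - g_c,
                "G_control": g_c,
                "A_kd": coverage - g_k,
                "G_kd": g_k,
                "level_control": g_c / coverage,
                "level_kd": g_k / coverage,
            }
        )

    effect = editing.call_des(table(level_control, level_kd))
    null = editing.call_des(table(level_control, level_control))
    return DESRecovery(
        sensitivity=float(effect["is_des"].mean()),
        null_fpr=float(null["is_des"].mean()),
        n_sites=n_sites,
    )


@dataclass
class DirectionRecovery:
    wilcoxon_p: float
    frac_control_higher: float
    ac_observed: float
    ac_expected: float
    ac_fisher_p: float
    n_transcripts: int


def direction_recovery(n_transcripts: int = 50, seed: int = 1) -> DirectionRecovery:
    """Net-stabilizing editing (A:C-dominated): the DS/(DS+SS) ratio should
    come out higher in control than knockdown, and edited adenosines should
    sit opposite C more often than duplex base composition predicts."""
    cfg = synthio.SimulationConfig(
        n_transcripts=n_transcripts, frac_swe=0.8, frac_dswe=0.1, seed=seed
    )
    exp = synthio.simulate_experiment(cfg)
    ratios = {"control": {}, "kd": {}}
    for cond in ("control", "kd"):
        for t in exp.transcripts:
            per_rep = []
            for rep in (1, 2):
                v1 = exp.track(cond, "V1", rep).counts[t.id]
                s1 = exp.track(cond, "S1", rep).counts[t.id]
                per_rep.append(strclass.ds_ratio(strclass.classify_bases(v1, s1)).ratio)
            vals = [r for r in per_rep if r is not None]
            if vals:
                ratios[cond][t.id] = float(np.mean(vals))
    cmp = strclass.compare_conditions(ratios["control"], ratios["kd"])

    n_ac = n_au = dup_ac = dup_tot = 0
    for t in exp.transcripts:
        if not t.edit_sites:
            continue
        classes, rep = editing.pair_context([s.pos for s in t.edit_sites], t.sequence, t.pair_map)
        n_ac += classes.count("AC")
        n_au += classes.count("AU")
        dup_ac += rep.n_duplex_ac
        dup_tot += rep.n_duplex_ac + rep.n_duplex_au
    from scipy import stats

    fisher_p = float(
        stats.fisher_exact([[n_ac, n_au], [dup_ac, dup_tot - dup_ac]])[1]
    )
    return DirectionRecovery(
        wilcoxon_p=cmp.wilcoxon_p,
        frac_control_higher=cmp.frac_control_higher,
        ac_observed=n_ac / (n_ac + n_au),
        ac_expected=dup_ac / dup_tot,
        ac_fisher_p=fisher_p,
        n_transcripts=cmp.n,
    )


def known_structure_agreement(depth: int = 100_000, seed: int = 1) -> float:
    """Read agreement with a known structure on a deeply digested molecule
    whose bases are half paired (a long perfect hairpin)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104]))
    cfg = synthio.SimulationConfig()
    stem, loop = 75, 150
    L = 2 * stem + loop
    seq = ["G"] * stem + ["A"] * loop + ["C"] * stem
    pair_map = np.full(L, -1)
    for k in range(stem):
        pair_map[k], pair_map[L - 1 - k] = L - 1 - k, k
    t = synthio.SyntheticTranscript(
        id="control_rna", sequence="".join(seq), pair_map=pair_map,
        edit_sites=[], region_labels=np.array(["3UTR"] * L),
    )
    ens = synthio.realize_molecules(t, "control", 10, rng)
    v1 = synthio.simulate_digestion(ens, "V1", depth, rng, cfg)
    s1 = synthio.simulate_digestion(ens, "S1", depth, rng, cfg)
    ann = np.where(t.baseline_paired(), "DS", "SS")
    return agreement_with_known(v1, s1, ann)


def permutation_null_rejection_rate(
    n_regions: int = 1000, length: int = 50, n_perm: int = 100, seed: int = 1
) -> float:
    """Fraction of i.i.d.-noise regions the shuffle test rejects at 0.05."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 105]))
    hits = 0
    for _ in range(n_regions):
        vecs = tuple(rng.poisson(5, (4, length)).astype(float))
        try:
            hits += sschange.permutation_p(vecs, n_perm=n_perm, rng=rng).p < 0.05
        except sschange.ZeroVarianceError:
            pass
    return hits / n_regions
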