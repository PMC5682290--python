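"""Per-base DS/SS classification and per-transcript stability summaries.

Each base is tested for enrichment of V1 (double-strand) versus S1
(single-strand) read starts against the rest of its transcript with a
two-sided Fisher exact test — the structure-preference-profile construction.
Confident calls are summarized per transcript as the DS/(DS+SS) ratio, the
ratio is compared between control and ADAR1-knockdown conditions, and each
transcript is classed as stabilized-while-edited (SWE: ratio higher in
control) or destabilized-while-edited (DSWE: ratio higher in knockdown).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .counts import ReadStartTrack, TrackError

DS, SS, UNDETERMINED = "DS", "SS", "undetermined"


@dataclass
class BaseCall:
    klass: str
    p: float


@dataclass
class TranscriptStructureSummary:
    transcript_id: str
    condition: str
    n_ds: int
    n_ss: int
    n_undetermined: int
    ratio: float | None  # DS/(DS+SS); None when no confident calls

    @property
    def defined(self) -> bool:
        return self.ratio is not None


@dataclass
class StabilityClass:
    klass: str  # SWE / DSWE / unclassified
    mean_ratio_control: float | None
    mean_ratio_kd: float | None


@lru_cache(maxsize=1 << 20)
def base_fisher_p(v1j: int, s1j: int, v1_total: int, s1_total: int) -> float:
    """Two-sided Fisher exact p for the base-versus-rest 2x2 table
    [[v1j, s1j], [v1_total - v1j, s1_total - s1j]]."""
    table = [[v1j, s1j], [v1_total - v1j, s1_total - s1j]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def classify_bases(v1: np.ndarray, s1: np.ndarray, alpha: float = 0.05) -> list[BaseCall]:
    """Classify every base of one transcript as DS, SS, or undetermined.

    Counts (possibly normalized, hence fractional) are rounded half-to-even
    to integers first.  A base is DS when significantly V1-enriched relative
    to the transcript totals, SS when S1-enriched; low-coverage bases stay
    undetermined.
    """
    v1 = np.rint(np.asarray(v1, dtype=float)).astype(int)
    s1 = np.rint(np.asarray(s1, dtype=float)).astype(int)
    if v1.shape != s1.shape:
        raise TrackError(f"track length mismatch: {v1.shape} vs {s1.shape}")
    v1_total = int(v1.sum())
    s1_total = int(s1.sum())
    if v1_total == 0 or s1_total == 0:
        raise TrackError("zero total read starts in a track; cannot classify")
    calls = []
    for a, b in zip(v1, s1):
        p = base_fisher_p(int(a), int(b), v1_total, s1_total)
        if p <= alpha:
            klass = DS if a / v1_total > b / s1_total else SS
            # exact density ties (equal shares) stay undetermined
            if a / v1_total == b / s1_total:
                klass = UNDETERMINED
        else:
            klass = UNDETERMINED
        calls.append(BaseCall(klass=klass, p=p))
    return calls


def eligible_transcripts(
    tracks: list[ReadStartTrack], min_length: int = 100, min_read_starts: float = 256
) -> set[str]:
    """Transcripts long enough and covered enough for structure calling:
    strictly longer than ``min_length`` bases and strictly more than
    ``min_read_starts`` read starts summed over all given tracks."""
    if not tracks:
        return set()
    ids = set.intersection(*(set(t.counts) for t in tracks))
    out = set()
    for tid in ids:
        length = len(tracks[0].counts[tid])
        total = sum(t.transcript_total(tid) for t in tracks)
        if length > min_length and total > min_read_starts:
            out.add(tid)
    return out


def ds_ratio(calls: list[BaseCall], transcript_id: str = "", condition: str = "") -> TranscriptStructureSummary:
    n_ds = sum(1 for c in calls if c.klass == DS)
    n_ss = sum(1 for c in calls if c.klass == SS)
    n_un = len(calls) - n_ds - n_ss
    ratio = n_ds / (n_ds + n_ss) if (n_ds + n_ss) > 0 else None
    return TranscriptStructureSummary(
        transcript_id=transcript_id,
        condition=condition,
        n_ds=n_ds,
        n_ss=n_ss,
        n_undetermined=n_un,
        ratio=ratio,
    )


@dataclass
class ConditionComparison:
    n: int
    deltas: np.ndarray  # control ratio - kd ratio, per transcript
    wilcoxon_p: float
    frac_control_higher: float


def compare_conditions(
    control: dict[str, float], kd: dict[str, float]
) -> ConditionComparison:
    """Paired comparison of per-transcript DS/(DS+SS) ratios across conditions.

    Uses the two-sided Wilcoxon signed-rank test on matched transcripts; the
    direction summary is the fraction of transcripts with a higher ratio in
    control than in knockdown.
    """
    ids = sorted(set(control) & set(kd))
    if len(ids) < 2:
        raise TrackError(f"need >= 2 matched transcripts, got {len(ids)}")
    c = np.array([control[t] for t in ids], dtype=float)
    k = np.array([kd[t] for t in ids], dtype=float)
    deltas = c - k
    if np.all(deltas == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(c, k, zero_method="wilcox", alternative="two-sided").pvalue)
    return ConditionComparison(
        n=len(ids),
        deltas=deltas,
        wilcoxon_p=p,
        frac_control_higher=float(np.mean(deltas > 0)),
    )


def classify_swe(
    ratios_control: list[float | None], ratios_kd: list[float | None]
) -> StabilityClass:
    """SWE/DSWE from replicate-averaged DS ratios.

    DSWE: mean ratio higher in knockdown than control (the duplex is MORE
    confidently paired when editing is removed, so editing destabilized it).
    SWE is the reverse.  Undefined ratios in a condition, or an exact tie,
    leave the transcript unclassified.
    """
    c = [r for r in ratios_control if r is not None]
    k = [r for r in ratios_kd if r is not None]
    mc = float(np.mean(c)) if c else None
    mk = float(np.mean(k)) if k else None
    if mc is None or mk is None or mc == mk:
        klass = "unclassified"
    elif mk > mc:
        klass = "DSWE"
    else:
        klass = "SWE"
    return StabilityClass(klass=klass, mean_ratio_control=mc, mean_ratio_kd=mk)
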