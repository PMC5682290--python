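"""PARS scores and per-base structural summaries.

The PARS score of base j in transcript i is log2(V1_ij / S1_ij) on normalized
read-start counts: positive scores indicate double-stranded (paired) bases,
negative scores single-stranded ones.  This module also derives relative
(region-normalized) profiles, agreement with a known structure, hard folding
constraints, metagene profiles around anchors, codon-position periodicity,
and the buried-base rule (low cleavage by both enzymes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .counts import TrackError


@dataclass
class ParsProfile:
    scores: np.ndarray
    v1: np.ndarray
    s1: np.ndarray
    pseudocount: float


def pars_score(v1: np.ndarray, s1: np.ndarray, pseudocount: float = 1.0) -> ParsProfile:
    """score[j] = log2((v1[j] + pseudocount) / (s1[j] + pseudocount)).

    The pseudocount keeps the score defined at zero-count bases; swapping the
    enzymes negates the score at every base.
    """
    v1 = np.asarray(v1, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    if v1.shape != s1.shape:
        raise TrackError(f"track length mismatch: {v1.shape} vs {s1.shape}")
    if pseudocount <= 0 and (np.any(v1 == 0) or np.any(s1 == 0)):
        raise TrackError("pseudocount <= 0 with zero counts present")
    return ParsProfile(
        scores=np.log2((v1 + pseudocount) / (s1 + pseudocount)),
        v1=v1,
        s1=s1,
        pseudocount=pseudocount,
    )


def mean_pars_score(profiles: list[ParsProfile]) -> np.ndarray:
    """Replicate-averaged PARS score: mean of per-replicate scores."""
    return np.mean([p.scores for p in profiles], axis=0)


def relative_profile(counts: np.ndarray, region: tuple[int, int] | None = None) -> np.ndarray:
    """Counts normalized to the region total (each vector sums to 1)."""
    counts = np.asarray(counts, dtype=float)
    if region is not None:
        counts = counts[region[0] : region[1]]
    total = counts.sum()
    if total <= 0:
        raise TrackError("region has zero total read starts")
    return counts / total


def relative_pars(
    v1: np.ndarray, s1: np.ndarray, region: tuple[int, int] | None = None, pseudocount: float = 1.0
) -> np.ndarray:
    """log2 ratio of the V1 and S1 relative (region-normalized) profiles.

    Scaling either track by any constant leaves the result unchanged, which is
    what makes profiles from differently sized partitions comparable.
    """
    rv = relative_profile(np.asarray(v1, float) + pseudocount, region)
    rs = relative_profile(np.asarray(s1, float) + pseudocount, region)
    return np.log2(rv / rs)


def agreement_with_known(v1: np.ndarray, s1: np.ndarray, annotation: np.ndarray) -> float:
    """Fraction of reads agreeing with a known structure.

    ``annotation`` holds per-base labels "DS"/"SS"/"unknown".  Agreement is
    (V1 reads on DS bases + S1 reads on SS bases) over all V1+S1 reads on
    annotated bases; ~0.9 on well-behaved probing data.
    """
    annotation = np.asarray(annotation)
    ds = annotation == "DS"
    ss = annotation == "SS"
    if not ds.any() or not ss.any():
        raise TrackError("annotation must contain at least one DS and one SS base")
    v1 = np.asarray(v1, float)
    s1 = np.asarray(s1, float)
    ann = ds | ss
    good = v1[ds].sum() + s1[ss].sum()
    tot = v1[ann].sum() + s1[ann].sum()
    if tot == 0:
        raise TrackError("no reads over annotated bases")
    return float(good / tot)


DS_SYMBOL, SS_SYMBOL, FREE_SYMBOL = "|", "x", "."


def constraints_from_pars(
    scores: np.ndarray,
    hi: float = 2.5,
    lo: float = -2.5,
    sequence: str | None = None,
    des_substitutions: list[tuple[int, float, float]] | None = None,
    min_reads: float = 100.0,
    min_level: float = 0.1,
) -> tuple[str, str | None]:
    """Hard folding constraints from a (replicate-averaged) PARS profile.

    Bases scoring above ``hi`` are forced paired ('|'), below ``lo`` forced
    unpaired ('x'), anything else left free ('.').  When a sequence is given,
    differential editing sites listed as (position, total_reads,
    mean_control_level) with coverage > ``min_reads`` and level > ``min_level``
    are substituted A->G before the sequence is emitted, so the fold reflects
    the inosine-containing molecule.
    """
    if not hi > lo:
        raise TrackError(f"need hi > lo, got {hi} <= {lo}")
    scores = np.asarray(scores, dtype=float)
    symbols = np.full(len(scores), FREE_SYMBOL, dtype="U1")
    symbols[scores > hi] = DS_SYMBOL
    symbols[scores < lo] = SS_SYMBOL
    constraint = "".join(symbols)

    edited = None
    if sequence is not None:
        seq = list(sequence)
        for pos, reads, level in des_substitutions or []:
            if reads > min_reads and level > min_level:
                if seq[pos] not in "Aa":
                    raise TrackError(f"DES substitution at non-A base {seq[pos]!r} (pos {pos})")
                seq[pos] = "G"
        edited = "".join(seq)
    return constraint, edited


def write_constraint_file(sequence: str, constraint: str, path: str | Path, name: str = "region") -> None:
    """Sequence + constraint lines in the dialect folding tools accept."""
    if len(sequence) != len(constraint):
        raise TrackError("sequence and constraint must have equal length")
    Path(path).write_text(f">{name}\n{sequence}\n{constraint}\n")


def metagene_profile(
    values: dict[str, np.ndarray], anchors: dict[str, int], span: int = 150
) -> np.ndarray:
    """Positionwise mean of per-base values at offsets -span..+span around a
    per-transcript anchor (e.g. translation start or stop).  Transcripts
    contribute only the offsets they cover."""
    width = 2 * span + 1
    acc = np.zeros(width)
    n = np.zeros(width)
    for tid, anchor in anchors.items():
        v = np.asarray(values[tid], dtype=float)
        if not 0 <= anchor < len(v):
            raise TrackError(f"anchor {anchor} outside transcript {tid} of length {len(v)}")
        lo = max(0, anchor - span)
        hi = min(len(v), anchor + span + 1)
        sl = v[lo:hi]
        off = lo - (anchor - span)
        acc[off : off + len(sl)] += sl
        n[off : off + len(sl)] += 1
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, acc / np.maximum(n, 1), np.nan)


def codon_periodicity(scores: np.ndarray, cds: tuple[int, int]) -> np.ndarray:
    """Mean score at codon positions 1, 2, 3 within the CDS.

    A trailing partial codon is truncated; structure probing shows a period-3
    signal with the lowest scores at the first codon base.
    """
    start, end = cds
    length = end - start
    if length < 3:
        raise TrackError(f"CDS shorter than one codon: {cds}")
    length -= length % 3
    window = np.asarray(scores, dtype=float)[start : start + length].reshape(-1, 3)
    return window.mean(axis=0)


def buried_mask(v1: np.ndarray, s1: np.ndarray, fraction_of_mean: float = 0.5) -> np.ndarray:
    """Bases cut rarely by BOTH enzymes: count <= fraction_of_mean x the
    transcript's per-base mean for each enzyme separately."""
    v1 = np.asarray(v1, float)
    s1 = np.asarray(s1, float)
    if len(v1) == 0:
        raise TrackError("zero-length transcript")
    return (v1 <= fraction_of_mean * v1.mean()) & (s1 <= fraction_of_mean * s1.mean())


def buried_fraction(v1: np.ndarray, s1: np.ndarray, fraction_of_mean: float = 0.5) -> float:
    m = buried_mask(v1, s1, fraction_of_mean)
    return float(m.mean())
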