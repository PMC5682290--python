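"""Structure-change detection: the CorDiff statistic and its shuffle test.

For a region with two control replicates (c1, c2) and two knockdown
replicates (kd1, kd2) of per-base read-start vectors,

    CorDiff = Cor(c1,c2)^2 + Cor(kd1,kd2)^2 - Cor(c1,kd1)^2 - Cor(c2,kd2)^2

with Pearson correlations: within-condition reproducibility minus
cross-condition similarity.  Large positive values mean the profiles changed
reproducibly between conditions.  Significance comes from an empirical null
built by shuffling the read starts within the region; a region is a
secondary-structure change (SSC) when CorDiff > 0 in both the V1 and S1
libraries and the observed score beats 95% of the shuffles.

The same machinery compares molecules partitioned by their base at an editing
site (G = edited, A = not) within a window around the site, attributing a
structural difference to the edit itself rather than to the knockdown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam


class ZeroVarianceError(ValueError):
    """Pearson correlation undefined: a vector has no variance."""


@dataclass
class ProfileMatrix:
    """Read-start vectors for one region: two replicates per condition."""

    region_id: str
    c1: np.ndarray
    c2: np.ndarray
    kd1: np.ndarray
    kd2: np.ndarray

    def vectors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return self.c1, self.c2, self.kd1, self.kd2


@dataclass
class EnzymeResult:
    cordiff: float
    p: float  # raw shuffle fraction >= observed
    p_add_one: float
    n_perm: int


@dataclass
class SSCResult:
    region_id: str
    per_enzyme: dict[str, EnzymeResult] = field(default_factory=dict)
    is_ssc: bool = False


def _as_float(vs) -> list[np.ndarray]:
    out = [np.asarray(v, dtype=float) for v in vs]
    n = {len(v) for v in out}
    if len(n) != 1:
        raise ValueError(f"vectors have unequal lengths: {sorted(n)}")
    if out[0].size < 3:
        raise ValueError("region too short for correlation (need >= 3 bases)")
    for i, v in enumerate(out):
        if np.ptp(v) == 0:
            raise ZeroVarianceError(f"vector {i} is constant; Pearson correlation undefined")
    return out


def cordiff(c1, c2, kd1, kd2) -> float:
    """The correlation-difference score of four same-length count vectors."""
    c1, c2, kd1, kd2 = _as_float((c1, c2, kd1, kd2))

    def r(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    return r(c1, c2) ** 2 + r(kd1, kd2) ** 2 - r(c1, kd1) ** 2 - r(c2, kd2) ** 2


def _zscore_rows(m: np.ndarray) -> np.ndarray:
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    return (m - mu) / sd


def permutation_p(
    matrix: ProfileMatrix | tuple,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
    coupled: bool = False,
) -> EnzymeResult:
    """Empirical p for CorDiff by within-sample position shuffling.

    Each trial permutes the positions of every sample's vector independently
    (``coupled=True`` applies one shared permutation per trial instead) and
    recomputes CorDiff.  p is the fraction of trials with shuffled CorDiff >=
    the observed value — ties count against significance — and the region is
    significant when p < 0.05, i.e. the observed score beats 95% of trials.
    An add-one corrected p is reported alongside the raw fraction.
    """
    if n_perm < 20:
        import warnings

        warnings.warn(f"n_perm={n_perm} gives coarse p resolution", stacklevel=2)
    rng = rng or np.random.default_rng()
    vecs = matrix.vectors() if isinstance(matrix, ProfileMatrix) else matrix
    c1, c2, kd1, kd2 = _as_float(vecs)
    observed = cordiff(c1, c2, kd1, kd2)

    L = len(c1)
    if coupled:
        perms = np.argsort(rng.random((n_perm, L)), axis=1)
        shuf = [v[perms] for v in (c1, c2, kd1, kd2)]
    else:
        shuf = [rng.permuted(np.broadcast_to(v, (n_perm, L)), axis=1) for v in (c1, c2, kd1, kd2)]
    z = [_zscore_rows(s) for s in shuf]

    def r(a, b):
        return (a * b).mean(axis=1)

    cd = r(z[0], z[1]) ** 2 + r(z[2], z[3]) ** 2 - r(z[0], z[2]) ** 2 - r(z[1], z[3]) ** 2
    n_ge = int(np.sum(cd >= observed))
    return EnzymeResult(
        cordiff=observed,
        p=n_ge / n_perm,
        p_add_one=(n_ge + 1) / (n_perm + 1),
        n_perm=n_perm,
    )


def analyze_region(
    region_id: str,
    per_enzyme_matrices: dict[str, ProfileMatrix],
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> SSCResult:
    """CorDiff + shuffle test for one region in both enzyme libraries."""
    rng = rng or np.random.default_rng()
    res = SSCResult(region_id=region_id)
    for enzyme, matrix in per_enzyme_matrices.items():
        res.per_enzyme[enzyme] = permutation_p(matrix, n_perm=n_perm, rng=rng)
    res.is_ssc = _ssc_flag(res, alpha)
    return res


def _ssc_flag(res: SSCResult, alpha: float) -> bool:
    if set(res.per_enzyme) != {"V1", "S1"}:
        return False
    return all(e.cordiff > 0 and e.p < alpha for e in res.per_enzyme.values())


def call_ssc(results: list[SSCResult], alpha: float = 0.05) -> list[SSCResult]:
    """Flag SSC regions: CorDiff > 0 in both enzymes, shuffle p < alpha in
    both.  Regions missing an enzyme are excluded (flag stays False)."""
    out = []
    for r in results:
        r.is_ssc = _ssc_flag(r, alpha)
        out.append(r)
    return out


def write_ssc_bed(results: list[SSCResult], intervals: dict[str, tuple[str, int, int]], path) -> None:
    """BED of SSC regions with CorDiff and p columns (V1 then S1)."""
    with open(path, "w") as fh:
        for r in results:
            if not r.is_ssc:
                continue
            chrom, start, end = intervals[r.region_id]
            v1, s1 = r.per_enzyme["V1"], r.per_enzyme["S1"]
            fh.write(
                f"{chrom}\t{start}\t{end}\t{r.region_id}\t"
                f"{v1.cordiff:.4g}\t{v1.p:.4g}\t{s1.cordiff:.4g}\t{s1.p:.4g}\n"
            )


# ---------------------------------------------------------------------------
# Edited vs non-edited read partitions
# ---------------------------------------------------------------------------

def partition_reads_by_site(
    alignments: str | pysam.AlignmentFile,
    transcript_id: str,
    site_pos: int,
    window: int = 50,
    min_mapq: int = 10,
) -> tuple[list[int], list[int]]:
    """Split reads covering an editing site by the base they carry there.

    Returns (edited_starts, non_edited_starts): read-start positions (the
    read's 5'-most aligned base) of reads whose query base at ``site_pos`` is
    G (edited — inosine reads as G) or A (non-edited).  Only forward-strand
    reads with starts inside [site_pos - window, site_pos + window] are kept;
    the read start and the edited base lie on the same read by construction.
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True
    edited, non_edited = [], []
    try:
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_reverse:
                continue
            if read.reference_name != transcript_id or read.mapping_quality < min_mapq:
                continue
            start = read.reference_start
            if not (site_pos - window <= start <= site_pos + window):
                continue
            seq = read.query_sequence
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if rpos == site_pos:
                    base = seq[qpos].upper()
                    if base == "G":
                        edited.append(start)
                    elif base == "A":
                        non_edited.append(start)
                    break
    finally:
        if own:
            alignments.close()
    return edited, non_edited


def starts_to_vector(starts: list[int], lo: int, hi: int) -> np.ndarray:
    """Bin read starts into a per-base vector over [lo, hi)."""
    v = np.zeros(hi - lo)
    for s in starts:
        if lo <= s < hi:
            v[s - lo] += 1
    return v


def compare_partitions(
    windows: dict[str, dict[str, np.ndarray]],
    region_id: str = "site",
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
    min_reads: float = 50.0,
    alpha: float = 0.05,
) -> SSCResult | None:
    """CorDiff comparison of edited vs non-edited profiles around a site.

    ``windows[enzyme]`` holds vectors keyed edited_rep1/edited_rep2/
    non_edited_rep1/non_edited_rep2; the edited partition plays the role of
    one condition.  Every partition must carry strictly more than
    ``min_reads`` read starts in the window in every replicate, otherwise the
    site is skipped (returns None).
    """
    rng = rng or np.random.default_rng()
    matrices = {}
    for enzyme, vecs in windows.items():
        needed = ("edited_rep1", "edited_rep2", "non_edited_rep1", "non_edited_rep2")
        if any(k not in vecs for k in needed):
            return None
        if any(vecs[k].sum() <= min_reads for k in needed):
            return None
        matrices[enzyme] = ProfileMatrix(
            region_id=region_id,
            c1=vecs["edited_rep1"],
            c2=vecs["edited_rep2"],
            kd1=vecs["non_edited_rep1"],
            kd2=vecs["non_edited_rep2"],
        )
    try:
        return analyze_region(region_id, matrices, n_perm=n_perm, rng=rng, alpha=alpha)
    except ZeroVarianceError:
        return None
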