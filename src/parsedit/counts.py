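"""Per-base read-start tracks: extraction from alignments, normalization, expression.

PARS-seq probes RNA with two nucleases — RNase V1 (cuts double-stranded RNA)
and S1 (cuts single-stranded RNA) — and sequences from the cleavage points, so
the 5'-most aligned base of each read ("read start") marks a cut site.  Every
downstream statistic in this package consumes per-base read-start count
vectors, one per (condition, enzyme, replicate) sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam

log = logging.getLogger(__name__)

CONDITIONS = ("control", "kd")
ENZYMES = ("V1", "S1")


class TrackError(ValueError):
    pass


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one PARS-seq library."""

    condition: str
    enzyme: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise TrackError(f"condition must be one of {CONDITIONS}: {self.condition!r}")
        if self.enzyme not in ENZYMES:
            raise TrackError(f"enzyme must be one of {ENZYMES}: {self.enzyme!r}")
        if self.replicate < 1:
            raise TrackError(f"replicate must be >= 1: {self.replicate}")

    @property
    def name(self) -> str:
        return f"{self.condition}_{self.enzyme}_rep{self.replicate}"


@dataclass
class ReadStartTrack:
    """Per-base read-start counts for one sample over a set of transcripts.

    ``counts`` maps transcript id to a float vector with one entry per base.
    ``norm_factor`` is the scalar the raw counts were multiplied by (1.0 for
    raw tracks).
    """

    meta: SampleMeta
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    norm_factor: float = 1.0

    def total(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    def transcript_total(self, tid: str) -> float:
        return float(self.counts[tid].sum())

    def scaled(self, factor: float) -> "ReadStartTrack":
        return ReadStartTrack(
            meta=self.meta,
            counts={t: v * factor for t, v in self.counts.items()},
            norm_factor=self.norm_factor * factor,
        )


@dataclass
class TranscriptModel:
    """A transcript model in BED12 terms (0-based, half-open genome coords)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    block_starts: list[int]  # relative to self.start
    block_sizes: list[int]
    thick_start: int | None = None
    thick_end: int | None = None

    @property
    def length(self) -> int:
        return int(sum(self.block_sizes))

    def genome_to_transcript(self, gpos: int) -> int | None:
        """Map a genomic position to transcript coordinates (5'->3').

        Returns None when the position falls outside the exon blocks.
        """
        offset = 0
        tpos = None
        for bs, sz in zip(self.block_starts, self.block_sizes):
            gstart = self.start + bs
            if gstart <= gpos < gstart + sz:
                tpos = offset + (gpos - gstart)
                break
            offset += sz
        if tpos is None:
            return None
        if self.strand == "-":
            tpos = self.length - 1 - tpos
        return tpos

    def cds_interval(self) -> tuple[int, int] | None:
        """CDS as a half-open interval in transcript coordinates, if annotated."""
        if self.thick_start is None or self.thick_end is None:
            return None
        if self.thick_start >= self.thick_end:
            return None
        a = self.genome_to_transcript(self.thick_start)
        b = self.genome_to_transcript(self.thick_end - 1)
        if a is None or b is None:
            return None
        lo, hi = min(a, b), max(a, b)
        return lo, hi + 1


def read_bed12(path: str | Path) -> dict[str, TranscriptModel]:
    """Parse transcript models from a BED12 file."""
    models: dict[str, TranscriptModel] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise TrackError(f"BED12 requires 12 columns, got {len(f)}: {line[:80]}")
        m = TranscriptModel(
            name=f[3],
            chrom=f[0],
            start=int(f[1]),
            end=int(f[2]),
            strand=f[5],
            thick_start=int(f[6]),
            thick_end=int(f[7]),
            block_sizes=[int(x) for x in f[10].rstrip(",").split(",")],
            block_starts=[int(x) for x in f[11].rstrip(",").split(",")],
        )
        models[m.name] = m
    return models


def write_bed12(models: dict[str, TranscriptModel] | list[TranscriptModel], path: str | Path) -> None:
    if isinstance(models, dict):
        models = list(models.values())
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(m.start),
                        str(m.end),
                        m.name,
                        "0",
                        m.strand,
                        str(m.thick_start if m.thick_start is not None else m.start),
                        str(m.thick_end if m.thick_end is not None else m.start),
                        "0",
                        str(len(m.block_sizes)),
                        ",".join(str(s) for s in m.block_sizes) + ",",
                        ",".join(str(s) for s in m.block_starts) + ",",
                    ]
                )
                + "\n"
            )


def _anchor_ok(read: pysam.AlignedSegment, min_anchor: int) -> bool:
    """True when the read's 5' end matches the reference for >= min_anchor
    bases without gaps (no 5' soft clip, leading aligned run long enough)."""
    cig = read.cigartuples
    if not cig:
        return False
    ops = cig if not read.is_reverse else cig[::-1]
    op, length = ops[0]
    # op 0 = M (alignment match); any leading clip/insertion means the 5' end
    # did not match the reference
    return op == 0 and length >= min_anchor


def count_read_starts(
    alignments: str | Path | pysam.AlignmentFile,
    meta: SampleMeta,
    lengths: dict[str, int] | None = None,
    models: dict[str, TranscriptModel] | None = None,
    min_anchor: int = 5,
    min_mapq: int = 10,
) -> ReadStartTrack:
    """Count read starts from a strand-specific alignment file.

    Two input geometries are supported.  Transcript-space (the primary path):
    reads aligned to transcript sequences, ``lengths`` gives transcript
    lengths, and only forward-strand reads are counted because transcripts are
    written 5'->3'.  Genome-space: ``models`` gives BED12 transcript models and
    read positions are projected through the exon blocks; the read orientation
    must match the transcript strand.

    A read is counted only if it is uniquely aligned (MAPQ >= ``min_mapq`` and
    not flagged secondary/supplementary) and its 5' end matches the reference
    for at least ``min_anchor`` bases without gaps.  The count is incremented
    at the 5'-most aligned base, in transcript coordinates.
    """
    if (lengths is None) == (models is None):
        raise TrackError("provide exactly one of lengths= (transcript space) or models= (genome space)")
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True

    chrom_models: dict[str, list[TranscriptModel]] = {}
    if models is not None:
        for m in models.values():
            chrom_models.setdefault(m.chrom, []).append(m)

    counts: dict[str, np.ndarray] = {}
    if lengths is not None:
        counts = {t: np.zeros(n) for t, n in lengths.items()}
    else:
        counts = {m.name: np.zeros(m.length) for m in models.values()}

    skipped_unknown = 0
    try:
        for i, read in enumerate(alignments):
            if read.is_unmapped:
                continue
            if read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if not _anchor_ok(read, min_anchor):
                continue
            ref = read.reference_name
            start5 = read.reference_end - 1 if read.is_reverse else read.reference_start
            if start5 is None:
                raise TrackError(f"malformed alignment record at index {i}")
            if lengths is not None:
                if ref not in counts:
                    skipped_unknown += 1
                    continue
                if read.is_reverse:  # antisense to a 5'->3' transcript sequence
                    continue
                if 0 <= start5 < len(counts[ref]):
                    counts[ref][start5] += 1
            else:
                hit = False
                for m in chrom_models.get(ref, []):
                    if not (m.start <= start5 < m.end):
                        continue
                    want_reverse = m.strand == "-"
                    if read.is_reverse != want_reverse:
                        continue
                    tpos = m.genome_to_transcript(start5)
                    if tpos is not None:
                        counts[m.name][tpos] += 1
                        hit = True
                if not hit:
                    skipped_unknown += 1
    finally:
        if own:
            alignments.close()
    if skipped_unknown:
        log.info("count_read_starts(%s): skipped %d reads outside known transcripts", meta.name, skipped_unknown)
    return ReadStartTrack(meta=meta, counts=counts)


def normalize_tracks(tracks: list[ReadStartTrack]) -> list[ReadStartTrack]:
    """Scale every track by one scalar so all totals equal the mean raw total.

    Equalizing the read-start sums makes V1 and S1 counts directly comparable
    base by base; within-track proportions are untouched.
    """
    if not tracks:
        raise TrackError("no tracks to normalize")
    totals = [t.total() for t in tracks]
    for t, tot in zip(tracks, totals):
        if tot <= 0:
            raise TrackError(f"track {t.meta.name} has zero total read starts")
    target = float(np.mean(totals))
    return [t.scaled(target / tot) for t, tot in zip(tracks, totals)]


def rpkm(count: float, transcript_length: int, library_total: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if transcript_length <= 0:
        raise TrackError(f"transcript length must be positive: {transcript_length}")
    if library_total <= 0:
        raise TrackError(f"library total must be positive: {library_total}")
    return 1e9 * count / (transcript_length * library_total)


def mean_coverage_filter(
    tracks: list[ReadStartTrack],
    region: tuple[str, int, int],
    min_mean_read_starts: float,
) -> bool:
    """True iff the mean read-start total over all samples in the region
    reaches the threshold.  Thresholds of 50/200/1000 reproduce the coverage
    tiers used to stratify 3'UTR exons."""
    tid, start, end = region
    if end <= start:
        raise TrackError(f"empty region {region}")
    sums = []
    for t in tracks:
        if tid not in t.counts:
            raise TrackError(f"transcript {tid!r} missing from track {t.meta.name}")
        vec = t.counts[tid]
        if not (0 <= start and end <= len(vec)):
            raise TrackError(f"region {region} outside transcript of length {len(vec)}")
        sums.append(float(vec[start:end].sum()))
    return float(np.mean(sums)) >= min_mean_read_starts


# ---------------------------------------------------------------------------
# Track file formats: tab track (transcript_id, 0-based position, count) with
# a JSON sidecar holding the sample metadata, and bedGraph export.
# ---------------------------------------------------------------------------

def write_track(track: ReadStartTrack, path: str | Path, lengths: dict[str, int] | None = None) -> None:
    """Write a tab track plus its ``<path>.json`` metadata sidecar.

    Zero positions are omitted from the tab file; ``lengths`` (or the vectors
    themselves) restore them on load.  Counts are written with 6 significant
    digits, which round-trips normalized tracks losslessly at that precision.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for tid in sorted(track.counts):
            vec = track.counts[tid]
            for pos in np.nonzero(vec)[0]:
                fh.write(f"{tid}\t{pos}\t{vec[pos]:.6g}\n")
    sidecar = {
        "condition": track.meta.condition,
        "enzyme": track.meta.enzyme,
        "replicate": track.meta.replicate,
        "norm_factor": track.norm_factor,
        "lengths": {t: int(len(v)) for t, v in track.counts.items()} if lengths is None else lengths,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_track(path: str | Path) -> ReadStartTrack:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    meta = SampleMeta(sidecar["condition"], sidecar["enzyme"], sidecar["replicate"])
    counts = {t: np.zeros(n) for t, n in sidecar["lengths"].items()}
    for line in path.read_text().splitlines():
        tid, pos, val = line.split("\t")
        counts[tid][int(pos)] = float(val)
    return ReadStartTrack(meta=meta, counts=counts, norm_factor=float(sidecar.get("norm_factor", 1.0)))


def load_experiment(directory: str | Path, pattern: str = "track_*.tsv") -> list[ReadStartTrack]:
    """Load every tab track (with sidecar) under a directory."""
    tracks = [read_track(p) for p in sorted(Path(directory).glob(pattern))]
    if not tracks:
        raise TrackError(f"no tracks matching {pattern!r} under {directory}")
    return tracks


def write_bedgraph(track: ReadStartTrack, path: str | Path) -> None:
    """Export a track as bedGraph (0-based half-open runs of equal value)."""
    with open(path, "w") as fh:
        for tid in sorted(track.counts):
            vec = track.counts[tid]
            if len(vec) == 0:
                continue
            edges = np.nonzero(np.diff(vec))[0] + 1
            starts = np.concatenate([[0], edges])
            ends = np.concatenate([edges, [len(vec)]])
            for s, e in zip(starts, ends):
                if vec[s] != 0:
                    fh.write(f"{tid}\t{s}\t{e}\t{vec[s]:.6g}\n")
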