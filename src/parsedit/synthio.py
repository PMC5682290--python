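"""Synthetic transcriptome, editing, and nuclease-digestion simulator.

The generator emulates the structure of a PARS-seq experiment on transcripts
carrying an imperfect inverted-repeat (IR) duplex in their 3'UTR — the
situation created by inverted Alu pairs in human mRNAs.  Each transcript has a
5'UTR, a CDS, and a 3'UTR containing two duplex arms (arm2 is the reverse
complement of arm1 with a configurable mismatch rate).  A-to-I editing sites
sit inside the duplex and act through a binary pairing rule per molecule:

* an A opposite U is paired when unedited and becomes an I:U mismatch
  (unpaired) when edited — editing *destabilizes*;
* an A opposite C is a mismatch (unpaired) when unedited and becomes an I:C
  pair when edited — editing *stabilizes*.

ADAR1 knockdown retains only a fraction (default 0.3, i.e. a ~70% reduction)
of each site's control editing level.  Digestion draws read starts
multinomially with per-base weights set by the enzyme's double-strand and
single-strand cleavage rates, averaged over a molecule ensemble, so the
ground truth for every downstream statistic is known exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .counts import ReadStartTrack, SampleMeta, TranscriptModel, write_bed12, write_track

RNA = "ACGU"
COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the seed fixes every source of randomness.

    Defaults describe a strongly edited IR-duplex region of a few hundred
    bases: 15% arm mismatches, eight editing sites per duplex with control
    levels in [0.3, 0.8], knockdown retaining 30% of the control level, and
    nuclease rates giving ~90% agreement with a known structure.
    """

    n_transcripts: int = 60
    length_range: tuple[int, int] = (350, 500)
    utr5_length: int = 50
    cds_length: int = 150
    arm_length: int = 60
    spacer_length: int = 20
    mismatch_rate: float = 0.15
    frac_mismatch_ac: float = 0.4
    edit_sites_per_duplex: int = 8
    level_control_range: tuple[float, float] = (0.3, 0.8)
    kd_retention: float = 0.3
    frac_swe: float = 0.5
    frac_dswe: float = 0.3
    depth: int = 10_000
    v1_ds_rate: float = 1.0
    v1_ss_rate: float = 0.1
    s1_ds_rate: float = 0.1
    s1_ss_rate: float = 1.0
    n_replicates: int = 2
    n_molecules: int = 400
    site_coverage: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 0:
            raise InvalidConfigError("n_transcripts must be >= 0")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise InvalidConfigError(f"bad length_range {self.length_range}")
        if self.cds_length % 3:
            raise InvalidConfigError("cds_length must be a multiple of 3")
        core = self.utr5_length + self.cds_length + 2 * self.arm_length + self.spacer_length
        if core > lo:
            raise InvalidConfigError(
                f"duplex arms do not fit: need {core} bases, shortest transcript is {lo}"
            )
        for name in ("v1_ds_rate", "v1_ss_rate", "s1_ds_rate", "s1_ss_rate"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if not self.v1_ds_rate > self.v1_ss_rate:
            raise InvalidConfigError("V1 must prefer double-stranded bases (v1_ds_rate > v1_ss_rate)")
        if not self.s1_ss_rate > self.s1_ds_rate:
            raise InvalidConfigError("S1 must prefer single-stranded bases (s1_ss_rate > s1_ds_rate)")
        if not 0 <= self.mismatch_rate <= 1:
            raise InvalidConfigError("mismatch_rate must be in [0, 1]")
        if not 0 <= self.frac_mismatch_ac <= 1:
            raise InvalidConfigError("frac_mismatch_ac must be in [0, 1]")
        if not 0 <= self.kd_retention <= 1:
            raise InvalidConfigError("kd_retention must be in [0, 1]")
        if self.frac_swe + self.frac_dswe > 1 + 1e-12:
            raise InvalidConfigError("frac_swe + frac_dswe must be <= 1")
        a, b = self.level_control_range
        if not (0 <= a <= b <= 1):
            raise InvalidConfigError(f"bad level_control_range {self.level_control_range}")
        if self.depth <= 0:
            raise InvalidConfigError("depth must be positive")
        if self.n_replicates < 1 or self.n_molecules < 1:
            raise InvalidConfigError("n_replicates and n_molecules must be >= 1")

    def rates(self, enzyme: str) -> tuple[float, float]:
        """(double-strand rate, single-strand rate) for an enzyme."""
        if enzyme == "V1":
            return self.v1_ds_rate, self.v1_ss_rate
        if enzyme == "S1":
            return self.s1_ds_rate, self.s1_ss_rate
        raise InvalidConfigError(f"unknown enzyme {enzyme!r}")


@dataclass(frozen=True)
class EditSite:
    """One A-to-I editing site inside the duplex (transcript coordinates)."""

    pos: int
    partner_pos: int
    partner_base: str  # "C" -> stabilizing (I:C), "U" -> destabilizing (I:U)
    level_control: float
    level_kd: float

    @property
    def pair_class(self) -> str:
        return "AC" if self.partner_base == "C" else "AU"


@dataclass
class SyntheticTranscript:
    id: str
    sequence: str
    pair_map: np.ndarray  # partner index per base, -1 outside the duplex
    edit_sites: list[EditSite]
    region_labels: np.ndarray  # per-base: 5UTR / CDS / 3UTR / IR-arm

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds(self) -> tuple[int, int]:
        idx = np.nonzero(self.region_labels == "CDS")[0]
        return int(idx[0]), int(idx[-1]) + 1

    def utr3_interval(self) -> tuple[int, int]:
        """The 3'UTR (including the IR arms) as a half-open interval —
        the exon-grain region for structure-change analysis."""
        idx = np.nonzero((self.region_labels == "3UTR") | (self.region_labels == "IR-arm"))[0]
        return int(idx[0]), int(idx[-1]) + 1

    def baseline_paired(self) -> np.ndarray:
        """Paired state of the unedited molecule: duplex positions whose
        partner base is Watson-Crick complementary."""
        seq = np.frombuffer(self.sequence.encode(), dtype="S1").astype("U1")
        paired = np.zeros(len(self.sequence), dtype=bool)
        duplex = np.nonzero(self.pair_map >= 0)[0]
        for i in duplex:
            j = self.pair_map[i]
            paired[i] = COMPLEMENT[seq[i]] == seq[j]
        return paired


@dataclass
class TranscriptTruth:
    stability_class: str  # SWE / DSWE / none
    is_ssc: bool
    sites: list[EditSite]


@dataclass
class TruthTable:
    transcripts: dict[str, TranscriptTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            tid: {
                "stability_class": t.stability_class,
                "is_ssc": t.is_ssc,
                "sites": [asdict(s) for s in t.sites],
            }
            for tid, t in self.transcripts.items()
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def _make_transcript(tid: str, cfg: SimulationConfig, kind: str, rng: np.random.Generator) -> SyntheticTranscript:
    length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
    seq = list(rng.choice(list(RNA), size=length))

    utr3_start = cfg.utr5_length + cfg.cds_length
    slack = length - utr3_start - (2 * cfg.arm_length + cfg.spacer_length)
    pre = int(rng.integers(0, slack + 1)) if slack > 0 else 0
    a1 = utr3_start + pre  # arm1 start
    a2 = a1 + cfg.arm_length + cfg.spacer_length  # arm2 start

    # arm2 is the reverse complement of arm1 with Bernoulli(mismatch_rate)
    # mismatches; a configured fraction of mismatches are A:C (the editable,
    # stabilizable kind), the rest avoid A:C so the fraction stays controlled.
    arm1 = [seq[a1 + k] for k in range(cfg.arm_length)]
    mism = rng.random(cfg.arm_length) < cfg.mismatch_rate
    # SWE-type duplexes need editable A:C mismatches: force up to the
    # configured site count of the realized mismatches to be A:C, so the
    # stabilizing-editing effect is not availability-limited.
    forced_ac = np.zeros(cfg.arm_length, dtype=bool)
    if kind == "SWE":
        mpos = np.nonzero(mism)[0]
        take = rng.permutation(mpos)[: cfg.edit_sites_per_duplex]
        forced_ac[take] = True
    pair_map = np.full(length, -1, dtype=int)
    for k in range(cfg.arm_length):
        i = a1 + k
        j = a2 + (cfg.arm_length - 1 - k)
        pair_map[i], pair_map[j] = j, i
        if not mism[k]:
            seq[j] = COMPLEMENT[arm1[k]]
        elif forced_ac[k] or rng.random() < cfg.frac_mismatch_ac:
            # A:C mismatch; the A goes on a random side
            if rng.random() < 0.5:
                seq[i], seq[j] = "A", "C"
            else:
                seq[i], seq[j] = "C", "A"
        else:
            b = seq[i]
            choices = [c for c in RNA if c != COMPLEMENT[b] and {b, c} != {"A", "C"}]
            seq[j] = choices[int(rng.integers(len(choices)))]

    labels = np.array(["3UTR"] * length, dtype="U6")
    labels[: cfg.utr5_length] = "5UTR"
    labels[cfg.utr5_length : utr3_start] = "CDS"
    labels[a1 : a1 + cfg.arm_length] = "IR-arm"
    labels[a2 : a2 + cfg.arm_length] = "IR-arm"

    sites: list[EditSite] = []
    if kind in ("SWE", "DSWE"):
        want = "C" if kind == "SWE" else "U"
        candidates = [
            i
            for i in range(length)
            if pair_map[i] >= 0 and seq[i] == "A" and seq[pair_map[i]] == want
        ]
        rng.shuffle(candidates)
        lo, hi = cfg.level_control_range
        for pos in sorted(candidates[: cfg.edit_sites_per_duplex]):
            lvl = float(rng.uniform(lo, hi))
            sites.append(
                EditSite(
                    pos=int(pos),
                    partner_pos=int(pair_map[pos]),
                    partner_base=seq[pair_map[pos]],
                    level_control=lvl,
                    level_kd=lvl * cfg.kd_retention,
                )
            )

    return SyntheticTranscript(
        id=tid,
        sequence="".join(seq),
        pair_map=pair_map,
        edit_sites=sites,
        region_labels=labels,
    )


def make_transcriptome(cfg: SimulationConfig) -> tuple[list[SyntheticTranscript], TruthTable]:
    """Generate the transcript set and its ground-truth table.

    A ``frac_swe`` fraction of transcripts carries A:C sites (editing
    stabilizes the duplex; these are stabilized-while-edited, SWE), a
    ``frac_dswe`` fraction carries A:U sites (destabilized while edited,
    DSWE), and the remainder carries no editing at all (structure identical
    between conditions — the negatives for structure-change calling).
    """
    rng = np.random.default_rng(cfg.seed)
    n_swe = int(round(cfg.frac_swe * cfg.n_transcripts))
    n_dswe = int(round(cfg.frac_dswe * cfg.n_transcripts))
    n_dswe = min(n_dswe, cfg.n_transcripts - n_swe)
    kinds = ["SWE"] * n_swe + ["DSWE"] * n_dswe + ["none"] * (cfg.n_transcripts - n_swe - n_dswe)
    rng.shuffle(kinds)

    transcripts, truth = [], TruthTable()
    for i, kind in enumerate(kinds):
        t = _make_transcript(f"T{i:04d}", cfg, kind, rng)
        effective = [s for s in t.edit_sites if s.level_control > s.level_kd]
        realized_kind = kind if effective else "none"
        transcripts.append(t)
        truth.transcripts[t.id] = TranscriptTruth(
            stability_class=realized_kind,
            is_ssc=bool(effective),
            sites=list(t.edit_sites),
        )
    return transcripts, truth


@dataclass
class MoleculeEnsemble:
    """A finite sample of molecules of one transcript in one condition.

    ``edited`` is an (n_molecules, n_sites) boolean matrix; the pairing state
    of every molecule follows from it through the binary I:C / I:U rule.
    """

    transcript: SyntheticTranscript
    condition: str
    edited: np.ndarray

    @property
    def n_molecules(self) -> int:
        return self.edited.shape[0]

    def paired_probability(self) -> np.ndarray:
        """Per-base fraction of molecules in which the base is paired."""
        t = self.transcript
        p = t.baseline_paired().astype(float)
        for k, site in enumerate(t.edit_sites):
            frac = float(self.edited[:, k].mean()) if self.n_molecules else 0.0
            val = frac if site.partner_base == "C" else 1.0 - frac
            p[site.pos] = val
            p[site.partner_pos] = val
        return p

    def site_g_fraction(self, k: int) -> float:
        return float(self.edited[:, k].mean())


def realize_molecules(
    t: SyntheticTranscript, condition: str, n_molecules: int, rng: np.random.Generator
) -> MoleculeEnsemble:
    """Draw molecules: each site edited independently Bernoulli(level)."""
    if condition not in ("control", "kd"):
        raise InvalidConfigError(f"condition must be control/kd: {condition!r}")
    levels = np.array(
        [s.level_control if condition == "control" else s.level_kd for s in t.edit_sites]
    )
    edited = rng.random((n_molecules, len(t.edit_sites))) < levels
    return MoleculeEnsemble(transcript=t, condition=condition, edited=edited)


def digestion_weights(ensemble: MoleculeEnsemble, enzyme: str, cfg: SimulationConfig) -> np.ndarray:
    ds, ss = cfg.rates(enzyme)
    p = ensemble.paired_probability()
    return ds * p + ss * (1.0 - p)


def simulate_digestion(
    ensemble: MoleculeEnsemble,
    enzyme: str,
    depth: int,
    rng: np.random.Generator,
    cfg: SimulationConfig,
) -> np.ndarray:
    """Draw ``depth`` read starts multinomially with ensemble-mean weights."""
    if depth <= 0:
        raise InvalidConfigError(f"depth must be positive: {depth}")
    w = digestion_weights(ensemble, enzyme, cfg)
    total = w.sum()
    if total == 0:
        return np.zeros(len(w))
    return rng.multinomial(depth, w / total).astype(float)


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    transcripts: list[SyntheticTranscript]
    truth: TruthTable
    tracks: list[ReadStartTrack]

    def track(self, condition: str, enzyme: str, replicate: int) -> ReadStartTrack:
        for t in self.tracks:
            m = t.meta
            if (m.condition, m.enzyme, m.replicate) == (condition, enzyme, replicate):
                return t
        raise KeyError((condition, enzyme, replicate))


def simulate_experiment(cfg: SimulationConfig) -> SimulatedExperiment:
    """Full experiment: transcripts, molecules per condition x replicate, and
    one digestion track per (condition, enzyme, replicate)."""
    transcripts, truth = make_transcriptome(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    tracks = []
    for condition in ("control", "kd"):
        for rep in range(1, cfg.n_replicates + 1):
            ensembles = {t.id: realize_molecules(t, condition, cfg.n_molecules, rng) for t in transcripts}
            for enzyme in ("V1", "S1"):
                counts = {
                    tid: simulate_digestion(ens, enzyme, cfg.depth, rng, cfg)
                    for tid, ens in ensembles.items()
                }
                tracks.append(
                    ReadStartTrack(meta=SampleMeta(condition, enzyme, rep), counts=counts)
                )
    return SimulatedExperiment(config=cfg, transcripts=transcripts, truth=truth, tracks=tracks)


def simulate_pileups(
    transcripts: list[SyntheticTranscript], cfg: SimulationConfig, rng: np.random.Generator
) -> dict[str, list[tuple[str, int, str, int, int, int, int]]]:
    """Per-condition pileup rows (chrom, 1-based pos, strand, A, C, G, T).

    Coverage per site is ``site_coverage`` per replicate, pooled per
    condition; G counts are binomial draws at the site's true level (inosine
    reads as G).
    """
    out: dict[str, list] = {"control": [], "kd": []}
    for t in transcripts:
        for site in t.edit_sites:
            for condition in ("control", "kd"):
                level = site.level_control if condition == "control" else site.level_kd
                cov = cfg.site_coverage * cfg.n_replicates
                g = int(rng.binomial(cov, level))
                out[condition].append((t.id, site.pos + 1, "+", cov - g, 0, g, 0))
    return out


def emit_fixtures(
    transcripts: list[SyntheticTranscript],
    tracks: list[ReadStartTrack],
    truth: TruthTable,
    outdir: str | Path,
    cfg: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, Path]:
    """Write the on-disk experiment: FASTA, BED12 models, per-sample tab
    tracks with JSON sidecars, per-condition pileup tables, and truth JSON.

    Returns a manifest of the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    try:
        fasta = outdir / "transcripts.fa"
        SeqIO.write(
            [SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts],
            str(fasta),
            "fasta",
        )
        manifest["fasta"] = fasta

        bed = outdir / "transcripts.bed"
        models = []
        for t in transcripts:
            cds = t.cds
            models.append(
                TranscriptModel(
                    name=t.id,
                    chrom=t.id,
                    start=0,
                    end=len(t),
                    strand="+",
                    block_starts=[0],
                    block_sizes=[len(t)],
                    thick_start=cds[0],
                    thick_end=cds[1],
                )
            )
        write_bed12(models, bed)
        manifest["bed"] = bed

        lengths = {t.id: len(t) for t in transcripts}
        for track in tracks:
            p = outdir / f"track_{track.meta.name}.tsv"
            write_track(track, p, lengths=lengths)
            manifest[f"track_{track.meta.name}"] = p

        if cfg is not None:
            rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
            pileups = simulate_pileups(transcripts, cfg, rng)
            for condition, rows in pileups.items():
                p = outdir / f"pileup_{condition}.tsv"
                with open(p, "w") as fh:
                    fh.write("chrom\tpos\tstrand\tA\tC\tG\tT\n")
                    for row in rows:
                        fh.write("\t".join(str(x) for x in row) + "\n")
                manifest[f"pileup_{condition}"] = p

        tr = outdir / "truth.json"
        tr.write_text(truth.to_json())
        manifest["truth"] = tr
    except OSError as exc:
        raise OSError(f"failed writing fixtures under {outdir}: {exc}") from exc
    return manifest


def partition_window_tracks(
    t: SyntheticTranscript,
    site_index: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    window: int = 50,
    depth_per_partition: int | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Edited / non-edited read-start vectors around one site (control cells).

    Molecules are partitioned by their edit state at the focal site and each
    partition is digested separately over the window [pos-window, pos+window],
    one pair of vectors per enzyme per replicate.  This mirrors partitioning
    real reads by the base they carry at the site (G = edited, A = not).
    """
    site = t.edit_sites[site_index]
    lo = max(0, site.pos - window)
    hi = min(len(t), site.pos + window + 1)
    depth = depth_per_partition or cfg.depth
    out: dict[str, dict[str, np.ndarray]] = {"V1": {}, "S1": {}}
    for rep in range(1, cfg.n_replicates + 1):
        ens = realize_molecules(t, "control", cfg.n_molecules, rng)
        for label, mask in (("edited", ens.edited[:, site_index]), ("non_edited", ~ens.edited[:, site_index])):
            sub = MoleculeEnsemble(transcript=t, condition="control", edited=ens.edited[mask])
            for enzyme in ("V1", "S1"):
                if sub.n_molecules == 0:
                    vec = np.zeros(hi - lo)
                else:
                    w = digestion_weights(sub, enzyme, cfg)[lo:hi]
                    vec = rng.multinomial(depth, w / w.sum()).astype(float)
                out[enzyme][f"{label}_rep{rep}"] = vec
    return out
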