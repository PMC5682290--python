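import numpy as np
import pytest

from parsedit import synthio


@pytest.fixture(scope="session")
def small_cfg():
    return synthio.SimulationConfig(n_transcripts=20, seed=42)


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    return synthio.simulate_experiment(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_sam(path, lengths, reads):
    """Write a transcript-space SAM file.

    ``reads`` is a list of dicts with keys ref, pos, cigar, flag (default 0),
    mapq (default 60), seq (optional), quals (optional list of ints).
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.get("name", f"read{i}")
            a.flag = r.get("flag", 0)
            a.reference_id = fh.header.references.index(r["ref"])
            a.reference_start = r["pos"]
            a.mapping_quality = r.get("mapq", 60)
            a.cigarstring = r["cigar"]
            qlen = a.infer_query_length()
            a.query_sequence = r.get("seq", "A" * qlen)
            if "quals" in r:
                a.query_qualities = r["quals"]
            fh.write(a)
    return path
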