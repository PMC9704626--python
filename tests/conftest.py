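import numpy as np
import pysam
import pytest

from clonesift.simulate import sam_header
from clonesift.targets import AmpliconTarget, load_bundled_targets


@pytest.fixture(scope="session")
def stat3_targets():
    return load_bundled_targets()


@pytest.fixture(scope="session")
def ex20(stat3_targets):
    return stat3_targets[0]


@pytest.fixture(scope="session")
def ex21(stat3_targets):
    return stat3_targets[1]


@pytest.fixture
def toy_target():
    """Small plus-strand target with a convenient codon layout."""
    # 10 codons starting at protein codon 1, frame 0
    ref = "ATGAGCGAAGGTACCTTTGATCAAAAGTAA"[:30]
    return AmpliconTarget(
        name="toy",
        chrom="chrT",
        start=100,
        end=130,
        ref_seq=ref,
        gene_strand="+",
        codon_offset=1,
        frame_shift=0,
        build_label="toy",
    )


@pytest.fixture
def pair_factory(toy_target):
    """Build aligned read pairs over the toy target with given bases/quals."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [
                {"SN": toy_target.chrom, "LN": 10_000},
                {"SN": "chrOther", "LN": 10_000},
            ],
        }
    )

    def make_pair(name, seq1, quals1, seq2, quals2, start=None, chrom=None):
        start = toy_target.start if start is None else start
        chrom = toy_target.chrom if chrom is None else chrom
        recs = []
        for i, (seq, quals) in enumerate([(seq1, quals1), (seq2, quals2)]):
            rec = pysam.AlignedSegment(header)
            rec.query_name = name
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            rec.reference_name = chrom
            rec.reference_start = start
            rec.cigarstring = f"{len(seq)}M"
            rec.mapping_quality = 60
            rec.is_paired = True
            rec.is_read1 = i == 0
            rec.is_read2 = i == 1
            rec.is_reverse = i == 1
            recs.append(rec)
        return recs[0], recs[1]

    return make_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
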