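"""Construction helpers shared by the test modules."""

import numpy as np

from exocap.lanefilter import MateRecord, ReadPairRecord
from exocap.simulate import seq_to_array


def mate(
    chrom="chr1",
    start=0,
    seq="ACGT" * 19,
    quals=30,
    strand="+",
    mapq=60,
    cigar=None,
):
    bases = seq_to_array(seq)
    if np.isscalar(quals):
        q = np.full(len(bases), int(quals), dtype=np.int64)
    else:
        q = np.asarray(quals, dtype=np.int64)
    return MateRecord(
        chrom=chrom,
        start=start,
        strand=strand,
        cigar=cigar or f"{len(bases)}M",
        bases=bases,
        quals=q,
        mapq=mapq,
    )


def pair(m1, m2, name="p"):
    return ReadPairRecord(name=name, mate1=m1, mate2=m2)
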