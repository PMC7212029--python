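"""RSPO fusion detection from RNA-seq reads.

A fusion is evidenced by reads that span a known breakpoint: the detector
counts reads containing, as an exact substring (on either strand), the
junction window of ``min_overlap`` bases on each side of the breakpoint.
Exact matching is appropriate for the error-free synthetic reads this
pipeline generates; there is no mismatch-tolerant mode.
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

from .cohort import FastqRead
from .errors import ConfigError, FormatError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class JunctionRecord:
    """One known fusion junction: upstream partner sequence followed by the
    RSPO portion, with the 0-based breakpoint offset between them."""

    gene: str  # RSPO2 or RSPO3
    sequence: str
    breakpoint_offset: int

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError("junction sequence must be over {A,C,G,T}")
        if not 0 < self.breakpoint_offset < len(self.sequence):
            raise ValueError("breakpoint_offset must be inside the sequence")


@dataclass
class JunctionLibrary:
    junctions: dict[str, JunctionRecord]

    def __iter__(self):
        return iter(self.junctions)

    def __getitem__(self, fusion_id: str) -> JunctionRecord:
        return self.junctions[fusion_id]

    def window(self, fusion_id: str, min_overlap: int) -> str:
        """The breakpoint-spanning window: min_overlap bases each side."""
        j = self.junctions[fusion_id]
        lo = j.breakpoint_offset - min_overlap
        hi = j.breakpoint_offset + min_overlap
        if lo < 0 or hi > len(j.sequence):
            raise ConfigError(
                f"min_overlap={min_overlap} too large for junction {fusion_id} "
                f"(breakpoint at {j.breakpoint_offset} of {len(j.sequence)})"
            )
        return j.sequence[lo:hi]


@dataclass(frozen=True)
class FusionCall:
    sample_id: str
    fusion_id: str
    gene: str
    supporting_reads: int


def read_junction_fasta(path) -> JunctionLibrary:
    """Load a junction library from FASTA.  Each description must carry
    ``gene=<symbol>`` and ``breakpoint=<0-based offset>`` tags."""
    junctions: dict[str, JunctionRecord] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        tags = dict(
            part.split("=", 1)
            for part in record.description.split()
            if "=" in part
        )
        if "breakpoint" not in tags or "gene" not in tags:
            raise FormatError(
                f"junction {record.id}: description needs gene= and breakpoint= tags"
            )
        junctions[record.id] = JunctionRecord(
            gene=tags["gene"],
            sequence=str(record.seq).upper(),
            breakpoint_offset=int(tags["breakpoint"]),
        )
    return JunctionLibrary(junctions)


def detect_fusions(
    reads: list[FastqRead],
    library: JunctionLibrary,
    min_overlap: int = 10,
    min_supporting_reads: int = 1,
) -> list[FusionCall]:
    """Count breakpoint-spanning reads per junction and emit calls with at
    least ``min_supporting_reads`` support.

    A read supports a junction iff the read or its reverse complement
    contains the junction window as an exact substring; each read counts at
    most once per fusion.  The result is invariant to read order and to
    reverse-complementing any read.
    """
    windows = {fid: library.window(fid, min_overlap) for fid in library}
    calls: list[FusionCall] = []
    sample_id = reads[0].read_id.split("/")[0] if reads else ""
    for fid in sorted(windows):
        window = windows[fid]
        support = 0
        for read in reads:
            seq = read.sequence.upper()
            if window in seq or window in reverse_complement(seq):
                support += 1
        if support >= min_supporting_reads:
            calls.append(
                FusionCall(
                    sample_id=sample_id,
                    fusion_id=fid,
                    gene=library[fid].gene,
                    supporting_reads=support,
                )
            )
    return calls
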