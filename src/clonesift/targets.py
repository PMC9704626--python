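"""Amplicon target definitions.

An :class:`AmpliconTarget` carries everything the pipeline needs to know
about one PCR amplicon: its genomic interval, the reference bases over that
interval, the strand of the gene it covers, and the codon-numbering metadata
required to translate genomic variants into protein-level labels.

Coordinates are 0-based half-open internally; 1-based only in exported
VCF/TSV. The transcript model is supplied entirely by the target metadata
(``codon_offset``, ``frame_shift``, ``gene_strand``) so that annotation
never needs an external database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGT")

#: Name of the bundled target fixture. The sequence in it is SYNTHETIC: the
#: codon positions named in the bundled known-variant table carry the correct
#: STAT3 residues, every other codon is deterministic filler. It is suitable
#: for exercising the pipeline end to end, not for analysing real reads.
BUNDLED_TARGETS = "synthetic_stat3_targets.yaml"


@dataclass(frozen=True)
class AmpliconTarget:
    """One amplicon: interval, reference sequence and codon frame.

    Parameters
    ----------
    name:
        Short label, e.g. ``"STAT3_ex20"``.
    chrom:
        Reference sequence (chromosome) name.
    start, end:
        0-based half-open genomic interval.
    ref_seq:
        Forward-strand reference bases over ``[start, end)``.
    gene_strand:
        ``"+"`` or ``"-"``; strand the coding sequence lies on.
    codon_offset:
        Protein codon number of the first in-frame codon overlapping the
        interval (in transcription order).
    frame_shift:
        Phase (0-2) of the first base of the interval in transcription
        order: 0 means the interval starts on a codon boundary.
    build_label:
        Free-text genome build tag, e.g. ``"GRCh37"``.
    """

    name: str
    chrom: str
    start: int
    end: int
    ref_seq: str
    gene_strand: str
    codon_offset: int
    frame_shift: int
    build_label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval for target {self.name!r}")
        if len(self.ref_seq) != self.end - self.start:
            raise ValueError(
                f"target {self.name!r}: ref_seq length {len(self.ref_seq)} "
                f"!= interval length {self.end - self.start}"
            )
        if not set(self.ref_seq) <= VALID_BASES:
            raise ValueError(f"target {self.name!r}: ref_seq has non-ACGT characters")
        if self.gene_strand not in ("+", "-"):
            raise ValueError("gene_strand must be '+' or '-'")
        if self.frame_shift not in (0, 1, 2):
            raise ValueError("frame_shift must be 0, 1 or 2")
        if self.codon_offset < 1:
            raise ValueError("codon_offset must be >= 1")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def positions(self) -> range:
        return range(self.start, self.end)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def ref_base(self, pos: int) -> str:
        """Forward-strand reference base at genomic position ``pos``."""
        if not self.contains(pos):
            raise ValueError(f"position {pos} outside target {self.name!r}")
        return self.ref_seq[pos - self.start]

    def coding_index(self, pos: int) -> int:
        """Offset of ``pos`` within the interval in transcription order."""
        if not self.contains(pos):
            raise ValueError(f"position {pos} outside target {self.name!r}")
        if self.gene_strand == "+":
            return pos - self.start
        return self.end - 1 - pos

    def coding_seq(self) -> str:
        """Reference bases of the interval in transcription order."""
        if self.gene_strand == "+":
            return self.ref_seq
        return str(Seq(self.ref_seq).reverse_complement())


def load_targets(path: str | Path) -> list[AmpliconTarget]:
    """Load amplicon targets from a YAML definition file.

    Each entry must provide ``name, chrom, start, end, gene_strand,
    codon_offset, frame_shift`` and either an inline ``ref_seq`` or a
    ``fasta`` path (sequence is then taken from ``fasta`` over the
    interval, via pyfaidx).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["targets"] if isinstance(doc, dict) else doc
    targets = []
    for ent in entries:
        ref_seq = ent.get("ref_seq")
        if ref_seq is None:
            import pyfaidx

            fasta = pyfaidx.Fasta(ent["fasta"])
            ref_seq = str(fasta[ent["chrom"]][ent["start"] : ent["end"]]).upper()
        targets.append(
            AmpliconTarget(
                name=ent["name"],
                chrom=ent["chrom"],
                start=int(ent["start"]),
                end=int(ent["end"]),
                ref_seq=str(ref_seq).upper(),
                gene_strand=ent["gene_strand"],
                codon_offset=int(ent["codon_offset"]),
                frame_shift=int(ent.get("frame_shift", 0)),
                build_label=str(ent.get("build_label", "")),
            )
        )
    return targets


def write_targets(targets: Iterable[AmpliconTarget], path: str | Path) -> None:
    doc = {
        "targets": [
            {
                "name": t.name,
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "ref_seq": t.ref_seq,
                "gene_strand": t.gene_strand,
                "codon_offset": t.codon_offset,
                "frame_shift": t.frame_shift,
                "build_label": t.build_label,
            }
            for t in targets
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_bundled_targets() -> list[AmpliconTarget]:
    """Load the bundled synthetic STAT3 SH2-domain exon 20/21 targets."""
    ref = resources.files("clonesift.data").joinpath(BUNDLED_TARGETS)
    with resources.as_file(ref) as path:
        return load_targets(path)
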