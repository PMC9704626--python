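"""Codon mapping, protein-change labels and known-variant lookup.

Variants are given in forward genomic coordinates (as in a VCF); the
amplicon target supplies the transcript model (strand, codon numbering and
frame), so for a minus-strand gene like STAT3 the bases are
reverse-complemented before codon assembly. Consequence classes are
limited to what a short coding amplicon can produce: missense, stop
gained, synonymous, single-codon in-frame deletion/duplication; anything
else is labelled ``complex``.

CADD scores and COSMIC/OMIM identifiers are looked up in a bundled static
table keyed on the protein-change label — they are never computed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .pileup import is_indel_allele
from .targets import AmpliconTarget

MISSENSE = "missense"
STOP_GAINED = "stop_gained"
SYNONYMOUS = "synonymous"
INFRAME_DELETION = "inframe_deletion"
INFRAME_DUPLICATION = "inframe_duplication"
COMPLEX = "complex"

BUNDLED_KNOWN_TABLE = "known_variants_stat3.tsv"

_SUBST_LABEL = re.compile(r"^([A-Z])(\d+)([A-Z*])$")
_INDEL_LABEL = re.compile(r"^([A-Z])(\d+)(del|dup)$")


@dataclass(frozen=True)
class ConsequenceAnnotation:
    protein_change: str
    consequence: str
    known_id: str | None = None
    cadd: float | None = None


@dataclass(frozen=True)
class CodonChange:
    codon_index: int
    ref_codon: str
    alt_codon: str


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _codon_positions(target: AmpliconTarget, codon_index: int) -> list[int]:
    """Coding-order offsets of a codon's three bases within the target."""
    base0 = 3 * (codon_index - target.codon_offset) - target.frame_shift
    offs = [base0, base0 + 1, base0 + 2]
    if offs[0] < 0 or offs[-1] >= len(target):
        raise ValueError(
            f"codon {codon_index} extends beyond target {target.name!r}"
        )
    return offs


def map_to_codon(
    position: int, ref: str, alt: str, target: AmpliconTarget
) -> CodonChange:
    """Map a genomic SNV to its codon change.

    ``position`` is the 0-based genomic coordinate; ``ref``/``alt`` are
    forward-strand bases. For minus-strand genes the codon is assembled
    from the reverse complement of the target interval.
    """
    if is_indel_allele(alt):
        raise ValueError("map_to_codon handles substitutions only")
    if target.ref_base(position) != ref:
        raise ValueError(
            f"reference mismatch at {target.chrom}:{position + 1}: "
            f"target has {target.ref_base(position)!r}, variant says {ref!r}"
        )
    c = target.coding_index(position)
    shifted = c + target.frame_shift
    codon_index = target.codon_offset + shifted // 3
    within = shifted % 3
    coding = target.coding_seq()
    offs = _codon_positions(target, codon_index)
    ref_codon = "".join(coding[o] for o in offs)
    alt_base = alt if target.gene_strand == "+" else alt.translate(_COMPLEMENT)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    return CodonChange(codon_index, ref_codon, alt_codon)


def protein_change(
    ref_codon: str, alt_codon: str, codon_index: int
) -> ConsequenceAnnotation:
    """Translate a codon change into a protein label and consequence class."""
    for codon in (ref_codon, alt_codon):
        if len(codon) != 3 or not set(codon) <= set("ACGT"):
            raise ValueError(f"invalid codon {codon!r}")
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    label = f"{aa_ref}{codon_index}{aa_alt}"
    if aa_alt == "*":
        cons = STOP_GAINED
    elif aa_ref == aa_alt:
        cons = SYNONYMOUS
    else:
        cons = MISSENSE
    return ConsequenceAnnotation(protein_change=label, consequence=cons)


def _annotate_indel(
    position: int, alt: str, target: AmpliconTarget
) -> ConsequenceAnnotation:
    """Label single-codon in-frame deletions and duplications.

    The indel is anchored at ``position`` and affects the bases starting at
    ``position + 1`` (genomic orientation). Only events that remove or
    duplicate exactly one whole codon get an HGVS-style label; everything
    else is ``complex``.
    """
    seq = alt[1:]
    if len(seq) != 3:
        return ConsequenceAnnotation("complex", COMPLEX)
    coding = target.coding_seq()
    minus = target.gene_strand == "-"
    event = str(Seq(seq).reverse_complement()) if minus else seq

    def _codon_of(off: int) -> int:
        return target.codon_offset + (off + target.frame_shift) // 3

    if alt.startswith("-"):
        # deleted genomic span [position+1, position+4) must lie in-target
        if not (target.contains(position + 1) and target.contains(position + 3)):
            return ConsequenceAnnotation("complex", COMPLEX)
        start_off = target.coding_index(position + 3 if minus else position + 1)
        if (start_off + target.frame_shift) % 3 != 0:
            return ConsequenceAnnotation("complex", COMPLEX)
        if coding[start_off : start_off + 3] != event:
            return ConsequenceAnnotation("complex", COMPLEX)
        aa = str(Seq(event).translate())
        return ConsequenceAnnotation(
            f"{aa}{_codon_of(start_off)}del", INFRAME_DELETION
        )

    # insertion between genomic position and position + 1; in coding order
    # the insertion point precedes the base whose coding offset is off_ins
    off_ins = target.coding_index(position) + (0 if minus else 1)
    if (off_ins + target.frame_shift) % 3 != 0:
        return ConsequenceAnnotation("complex", COMPLEX)
    if off_ins >= 3 and coding[off_ins - 3 : off_ins] == event:
        aa = str(Seq(event).translate())
        return ConsequenceAnnotation(
            f"{aa}{_codon_of(off_ins - 3)}dup", INFRAME_DUPLICATION
        )
    if off_ins + 3 <= len(coding) and coding[off_ins : off_ins + 3] == event:
        aa = str(Seq(event).translate())
        return ConsequenceAnnotation(
            f"{aa}{_codon_of(off_ins)}dup", INFRAME_DUPLICATION
        )
    return ConsequenceAnnotation("complex", COMPLEX)


def consequence_from_label(label: str) -> str:
    """Re-derive the consequence class from a protein-change label."""
    if label == "complex":
        return COMPLEX
    m = _INDEL_LABEL.match(label)
    if m:
        return INFRAME_DELETION if m.group(3) == "del" else INFRAME_DUPLICATION
    m = _SUBST_LABEL.match(label)
    if m:
        aa_ref, _, aa_alt = m.groups()
        if aa_alt in ("*", "X"):
            return STOP_GAINED
        return SYNONYMOUS if aa_ref == aa_alt else MISSENSE
    raise ValueError(f"unrecognised protein-change label {label!r}")


class KnownVariantTable:
    """Static lookup of known variants (COSMIC/OMIM id, CADD score)."""

    def __init__(self, table: pd.DataFrame):
        required = {"protein_change", "known_id", "cadd"}
        if not required <= set(table.columns):
            raise ValueError(f"known-variant table needs columns {sorted(required)}")
        self._rows: dict[str, tuple[str | None, float | None]] = {}
        for _, row in table.iterrows():
            known = row["known_id"]
            known = None if pd.isna(known) or known == "" else str(known)
            cadd = None if pd.isna(row["cadd"]) else float(row["cadd"])
            self._rows[str(row["protein_change"])] = (known, cadd)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KnownVariantTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def bundled(cls) -> "KnownVariantTable":
        ref = resources.files("clonesift.data").joinpath(BUNDLED_KNOWN_TABLE)
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def __contains__(self, protein_change: str) -> bool:
        return protein_change in self._rows

    def lookup(self, protein_change: str) -> tuple[str | None, float | None]:
        """Exact-match lookup; returns ``(None, None)`` when absent."""
        return self._rows.get(protein_change, (None, None))


def annotate_variant(
    position: int,
    ref: str,
    alt: str,
    target: AmpliconTarget,
    known: KnownVariantTable | None = None,
) -> ConsequenceAnnotation:
    """Full annotation of one variant on an amplicon target."""
    if is_indel_allele(alt):
        ann = _annotate_indel(position, alt, target)
    else:
        cc = map_to_codon(position, ref, alt, target)
        ann = protein_change(cc.ref_codon, cc.alt_codon, cc.codon_index)
    if known is not None:
        known_id, cadd = known.lookup(ann.protein_change)
        ann = ConsequenceAnnotation(ann.protein_change, ann.consequence, known_id, cadd)
    return ann
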