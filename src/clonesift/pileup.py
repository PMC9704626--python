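"""Dual-strand consensus pileup construction and coverage QC.

Ultra-deep amplicon sequencing with 2x300bp paired-end reads over short
amplicons means the two mates of each read pair cover the same fragment in
full, so every template position is read twice — once per strand. The
pileup layer exploits this: a basecall enters the per-library allele count
table only when the two mates report the *identical* allele and their
combined (summed) Phred quality reaches a threshold (default 60). This
suppresses strand-asymmetric sequencing errors, which dominate raw Illumina
error profiles, and leaves mostly template-level signal (real clones and
PCR artefacts) for the statistical caller to separate.

Indels are accepted under the same rule: the identical left-aligned indel
allele must be present on both mates, and the indel "quality" on each mate
is the minimum of its flanking base qualities. An accepted fragment
contributes exactly one allele per covered position (the indel allele at
its anchor position, in place of the anchor base), so per-position allele
counts always sum to the accepted depth.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .targets import AmpliconTarget

logger = logging.getLogger(__name__)

DEFAULT_MIN_COMBINED_QUAL = 60
DEFAULT_MIN_MAPQ = 1

#: rejection reasons for a read-pair observation
REJECT_DISCORDANT = "discordant"
REJECT_LOW_QUALITY = "low_quality"
REJECT_SINGLE_MATE = "single_mate"


@dataclass(frozen=True)
class ReadPairObservation:
    """One template position as seen by the two mates of a read pair.

    ``base_r1``/``base_r2`` hold either a single base (``A/C/G/T``) or an
    indel allele descriptor anchored at ``position`` (``+SEQ`` insertion
    after the anchor, ``-SEQ`` deletion of SEQ starting right after the
    anchor; left-aligned canonical form). ``None`` means the mate does not
    cover the position. For indel observations the per-mate quality is the
    minimum of the flanking base qualities.
    """

    position: int
    base_r1: str | None
    base_r2: str | None
    qual_r1: int = 0
    qual_r2: int = 0


@dataclass(frozen=True)
class BasecallDecision:
    accepted: bool
    allele: str | None = None
    reason: str | None = None


def accept_basecall(
    obs: ReadPairObservation, min_combined_qual: int = DEFAULT_MIN_COMBINED_QUAL
) -> BasecallDecision:
    """Apply the dual-strand consensus and combined-quality rule.

    Returns the accepted allele iff both mates cover the position, report
    the identical allele, and the sum of their Phred qualities is at least
    ``min_combined_qual``; otherwise a rejection with a reason.
    """
    if obs.qual_r1 < 0 or obs.qual_r2 < 0:
        raise ValueError("Phred qualities must be non-negative")
    if obs.base_r1 is None or obs.base_r2 is None:
        return BasecallDecision(False, None, REJECT_SINGLE_MATE)
    if obs.base_r1 != obs.base_r2:
        return BasecallDecision(False, None, REJECT_DISCORDANT)
    if obs.qual_r1 + obs.qual_r2 < min_combined_qual:
        return BasecallDecision(False, None, REJECT_LOW_QUALITY)
    return BasecallDecision(True, obs.base_r1, None)


def is_indel_allele(allele: str) -> bool:
    return allele.startswith(("+", "-"))


@dataclass
class LibraryPileup:
    """Per-position accepted allele counts for one library in one run."""

    library_id: str
    target: AmpliconTarget
    run_id: str = ""
    donor_id: str = ""
    batch_id: str = ""
    counts: dict[int, dict[str, int]] = field(default_factory=dict)

    def add(self, pos: int, allele: str, n: int = 1) -> None:
        site = self.counts.setdefault(pos, {})
        site[allele] = site.get(allele, 0) + n

    def site_counts(self, pos: int) -> Mapping[str, int]:
        return self.counts.get(pos, {})

    def count(self, pos: int, allele: str) -> int:
        return self.counts.get(pos, {}).get(allele, 0)

    def accepted_depth(self, pos: int) -> int:
        return sum(self.counts.get(pos, {}).values())

    def total_depth(self) -> int:
        return sum(self.accepted_depth(p) for p in self.counts)

    def positions(self) -> list[int]:
        return sorted(self.counts)

    def validate(self) -> None:
        for pos, site in self.counts.items():
            if not self.target.contains(pos):
                raise ValueError(f"position {pos} outside target")
            if any(n < 0 for n in site.values()):
                raise ValueError(f"negative count at {pos}")
            # conservation: accepted_depth is defined as the sum of the
            # allele counts, so it holds by construction; check types only
            if sum(site.values()) != self.accepted_depth(pos):
                raise AssertionError("conservation violated")


def _walk_read(
    read: pysam.AlignedSegment, target: AmpliconTarget
) -> tuple[dict[int, tuple[str, int]], dict[int, tuple[str, int]]]:
    """Extract per-position basecalls and anchored indels from one mate.

    Returns ``(bases, indels)`` where ``bases[pos] = (base, qual)`` and
    ``indels[anchor] = (allele, qual)`` with qual the min flanking base
    quality. Only positions inside the target are kept.
    """
    seq = read.query_sequence
    quals = read.query_qualities
    if seq is None or quals is None:
        raise ValueError(f"read {read.query_name} lacks sequence or qualities")
    bases: dict[int, tuple[str, int]] = {}
    indels: dict[int, tuple[str, int]] = {}
    qpos = 0
    rpos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            for i in range(length):
                p = rpos + i
                if target.contains(p):
                    bases[p] = (seq[qpos + i], int(quals[qpos + i]))
            qpos += length
            rpos += length
        elif op == 1:  # I
            anchor = rpos - 1
            ins = seq[qpos : qpos + length]
            lq = int(quals[qpos - 1]) if qpos > 0 else 0
            rq = int(quals[qpos + length]) if qpos + length < len(quals) else 0
            if target.contains(anchor):
                indels[anchor] = ("+" + ins, min(lq, rq))
            qpos += length
        elif op == 2:  # D
            anchor = rpos - 1
            if target.contains(anchor):
                del_end = min(rpos + length, target.end)
                deleted = target.ref_seq[rpos - target.start : del_end - target.start]
                if len(deleted) == length:
                    lq = int(quals[qpos - 1]) if qpos > 0 else 0
                    rq = int(quals[qpos]) if qpos < len(quals) else 0
                    indels[anchor] = ("-" + deleted, min(lq, rq))
            rpos += length
        elif op == 4:  # S
            qpos += length
        elif op in (3,):  # N
            rpos += length
        elif op in (5, 6):  # H, P
            pass
        else:
            raise ValueError(f"unsupported CIGAR op {op} in read {read.query_name}")
    return bases, indels


def pair_observations(
    r1: pysam.AlignedSegment, r2: pysam.AlignedSegment, target: AmpliconTarget
) -> Iterator[ReadPairObservation]:
    """Yield dual-strand observations for one read pair over the target.

    Indel observations replace the base observation at their anchor: when
    either mate reports an indel at an anchor the fragment is represented
    there by the (possibly discordant) indel observation alone.
    """
    b1, i1 = _walk_read(r1, target)
    b2, i2 = _walk_read(r2, target)
    anchors = set(i1) | set(i2)
    for pos in sorted(set(b1) | set(b2) | anchors):
        if pos in anchors:
            a1 = i1.get(pos)
            a2 = i2.get(pos)
            yield ReadPairObservation(
                pos,
                a1[0] if a1 else None,
                a2[0] if a2 else None,
                a1[1] if a1 else 0,
                a2[1] if a2 else 0,
            )
        else:
            x1 = b1.get(pos)
            x2 = b2.get(pos)
            yield ReadPairObservation(
                pos,
                x1[0] if x1 else None,
                x2[0] if x2 else None,
                x1[1] if x1 else 0,
                x2[1] if x2 else 0,
            )


def build_library_pileup(
    read_pairs: Iterable[tuple[pysam.AlignedSegment, pysam.AlignedSegment]],
    target: AmpliconTarget,
    min_combined_qual: int = DEFAULT_MIN_COMBINED_QUAL,
    *,
    library_id: str = "",
    run_id: str = "",
    donor_id: str = "",
    batch_id: str = "",
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> LibraryPileup:
    """Build the accepted-allele count table for one library and target.

    Pairs on the wrong chromosome are skipped with a warning; unmapped
    mates and mapping quality below ``min_mapq`` skip the pair. Positions
    covered by only one mate never contribute.
    """
    pile = LibraryPileup(
        library_id=library_id,
        target=target,
        run_id=run_id,
        donor_id=donor_id,
        batch_id=batch_id,
    )
    for r1, r2 in read_pairs:
        if r1.is_unmapped or r2.is_unmapped:
            continue
        if r1.mapping_quality < min_mapq or r2.mapping_quality < min_mapq:
            continue
        if r1.reference_name != target.chrom or r2.reference_name != target.chrom:
            warnings.warn(
                f"read pair {r1.query_name} on {r1.reference_name}, "
                f"expected {target.chrom}; skipped"
            )
            continue
        try:
            for obs in pair_observations(r1, r2, target):
                decision = accept_basecall(obs, min_combined_qual)
                if decision.accepted:
                    pile.add(obs.position, decision.allele)
        except ValueError as exc:
            logger.warning("skipping malformed pair %s: %s", r1.query_name, exc)
    return pile


def collect_read_pairs(
    records: Iterable[pysam.AlignedSegment],
) -> Iterator[tuple[pysam.AlignedSegment, pysam.AlignedSegment]]:
    """Group primary alignments into (mate1, mate2) pairs by query name."""
    pending: dict[str, pysam.AlignedSegment] = {}
    for rec in records:
        if rec.is_secondary or rec.is_supplementary:
            continue
        mate = pending.pop(rec.query_name, None)
        if mate is None:
            pending[rec.query_name] = rec
        else:
            r1, r2 = (mate, rec) if mate.is_read1 else (rec, mate)
            yield r1, r2


def pileup_from_sam(
    path: str | Path,
    target: AmpliconTarget,
    min_combined_qual: int = DEFAULT_MIN_COMBINED_QUAL,
    **ids,
) -> LibraryPileup:
    """Build a pileup from a SAM/BAM file of aligned paired-end reads."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return build_library_pileup(
            collect_read_pairs(fh), target, min_combined_qual, **ids
        )


# ---------------------------------------------------------------------------
# coverage QC


@dataclass(frozen=True)
class CoverageQC:
    """Coverage summary for one library across its sequencing runs.

    ``median_depth[(run_id, target_name)]`` is the median accepted depth
    over the target's positions in that run. ``pass_robust`` is true when
    any single run reaches ``d_min``; ``exclude`` is true when every run
    stays below ``d_fail``.
    """

    library_id: str
    median_depth: Mapping[tuple[str, str], float]
    max_depth: float
    pass_robust: bool
    exclude: bool
    d_min: int
    d_fail: int


def coverage_qc(
    pileups: Sequence[LibraryPileup], d_min: int = 25_000, d_fail: int = 1_000
) -> CoverageQC:
    """QC a library: depth must reach ``d_min`` in at least one run."""
    if not pileups:
        raise ValueError("coverage_qc needs at least one pileup")
    library_id = pileups[0].library_id
    medians: dict[tuple[str, str], float] = {}
    for p in pileups:
        depths = [p.accepted_depth(pos) for pos in p.target.positions]
        medians[(p.run_id, p.target.name)] = float(np.median(depths)) if depths else 0.0
    max_depth = max(medians.values())
    return CoverageQC(
        library_id=library_id,
        median_depth=medians,
        max_depth=max_depth,
        pass_robust=max_depth >= d_min,
        exclude=all(v < d_fail for v in medians.values()),
        d_min=d_min,
        d_fail=d_fail,
    )


# ---------------------------------------------------------------------------
# TSV interchange


def pileups_to_frame(pileups: Iterable[LibraryPileup]) -> pd.DataFrame:
    """Long-format counts table; ``pos`` is 1-based in the exported frame."""
    rows = []
    for p in pileups:
        for pos in p.positions():
            depth = p.accepted_depth(pos)
            for allele, n in sorted(p.site_counts(pos).items()):
                rows.append(
                    {
                        "library": p.library_id,
                        "run": p.run_id,
                        "chrom": p.target.chrom,
                        "pos": pos + 1,
                        "allele": allele,
                        "count": n,
                        "depth": depth,
                    }
                )
    return pd.DataFrame(
        rows, columns=["library", "run", "chrom", "pos", "allele", "count", "depth"]
    )


def write_counts_tsv(pileups: Iterable[LibraryPileup], path: str | Path) -> None:
    pileups_to_frame(pileups).to_csv(path, sep="\t", index=False)


def read_counts_tsv(
    path: str | Path,
    targets: Sequence[AmpliconTarget],
    meta: pd.DataFrame | None = None,
) -> list[LibraryPileup]:
    """Rebuild pileups from a counts TSV.

    ``meta``, if given, is a table with columns ``library, donor, batch``
    (and optionally ``run``) used to attach donor and batch identifiers. A
    library sequenced in several batches must be keyed by (library, run)
    in the metadata so each run's counts join their own calling batch.
    """
    df = pd.read_csv(path, sep="\t", dtype={"library": str, "run": str})
    by_target = {t.chrom: [] for t in targets}
    for t in targets:
        by_target[t.chrom].append(t)
    run_map: dict[tuple[str, str], tuple[str, str]] = {}
    lib_map: dict[str, tuple[str, str]] = {}
    if meta is not None:
        for _, row in meta.iterrows():
            val = (str(row["donor"]), str(row["batch"]))
            lib = str(row["library"])
            lib_map.setdefault(lib, val)
            if "run" in meta.columns:
                run_map[(lib, str(row["run"]))] = val
    pileups: dict[tuple[str, str, str], LibraryPileup] = {}
    for (library, run, chrom), grp in df.groupby(["library", "run", "chrom"]):
        for t in by_target.get(chrom, []):
            sub = grp[(grp["pos"] - 1 >= t.start) & (grp["pos"] - 1 < t.end)]
            if sub.empty:
                continue
            donor, batch = run_map.get(
                (str(library), str(run)), lib_map.get(str(library), ("", ""))
            )
            key = (str(library), str(run), t.name)
            pile = pileups.setdefault(
                key,
                LibraryPileup(
                    library_id=str(library),
                    target=t,
                    run_id=str(run),
                    donor_id=donor,
                    batch_id=batch,
                ),
            )
            for _, row in sub.iterrows():
                pile.add(int(row["pos"]) - 1, str(row["allele"]), int(row["count"]))
    return list(pileups.values())
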