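"""Run merging and technical-replicate integration.

Libraries are independent PCR reactions from the same donor DNA; a library
may additionally be sequenced in several batches/runs to increase depth.
This module first collapses run-level passing calls into one call per
library (keeping the deepest run as representative evidence), then
integrates the libraries of each donor into donor-level variants:

* **double-positive** — the full statistical criteria passed independently
  in at least two libraries of the donor (the stringent call set);
* **single-positive** — passed in exactly one library. Donors with a
  single sequenced library can only ever reach single-positive status.

The unit of replication is the library (independent PCR); a variant
passing in two runs of the *same* library never counts as double-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

from .caller import VariantCall

DOUBLE_POSITIVE = "double_positive"
SINGLE_POSITIVE = "single_positive"

VariantKey = tuple[str, int, str, str]  # (chrom, pos0, ref, alt)


@dataclass(frozen=True)
class LibraryCall:
    """A variant with >= 1 run-level passing call in one library."""

    library_id: str
    chrom: str
    position: int
    ref: str
    alt: str
    target_name: str
    best: VariantCall  # call from the deepest run
    runs: tuple[VariantCall, ...] = ()

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class DonorVariant:
    """Donor-level merged variant with its replicate evidence class."""

    donor_id: str
    chrom: str
    position: int
    ref: str
    alt: str
    target_name: str
    evidence_class: str
    supporting_libraries: tuple[str, ...]
    per_library: Mapping[str, tuple[int, int]]  # library -> (n_alt, depth)
    pooled_vaf: float
    n_libraries_tested: int

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.position, self.ref, self.alt)


def merge_runs(calls: Iterable[VariantCall | LibraryCall]) -> list[LibraryCall]:
    """Collapse passing run-level calls of one library into library calls.

    A library-level call exists iff at least one run-level call passed; the
    deepest run's evidence is carried as representative and all runs are
    retained. Accepts already-merged :class:`LibraryCall` objects too, so
    merging is idempotent.
    """
    flat: list[VariantCall] = []
    for item in calls:
        if isinstance(item, LibraryCall):
            flat.extend(item.runs)
        else:
            flat.append(item)
    libraries = {v.candidate.library_id for v in flat}
    if len(libraries) > 1:
        raise ValueError(f"merge_runs expects one library, got {sorted(libraries)}")
    ref_at_pos: dict[tuple[str, int], str] = {}
    groups: dict[VariantKey, list[VariantCall]] = {}
    for v in flat:
        c = v.candidate
        prev = ref_at_pos.setdefault((c.chrom, c.position), c.ref)
        if prev != c.ref:
            raise ValueError(
                f"conflicting reference alleles at {c.chrom}:{c.position + 1} "
                f"({prev!r} vs {c.ref!r}): target definition mismatch"
            )
        if v.passed:
            groups.setdefault((c.chrom, c.position, c.ref, c.alt), []).append(v)
    merged = []
    for key, runs in sorted(groups.items()):
        runs = sorted(runs, key=lambda v: (-v.candidate.depth, v.candidate.run_id))
        best = runs[0]
        merged.append(
            LibraryCall(
                library_id=best.candidate.library_id,
                chrom=key[0],
                position=key[1],
                ref=key[2],
                alt=key[3],
                target_name=best.candidate.target_name,
                best=best,
                runs=tuple(runs),
            )
        )
    return merged


def merge_runs_by_library(calls: Iterable[VariantCall]) -> list[LibraryCall]:
    """Apply :func:`merge_runs` per library over a mixed call list."""
    by_lib: dict[str, list[VariantCall]] = {}
    for v in calls:
        by_lib.setdefault(v.candidate.library_id, []).append(v)
    out: list[LibraryCall] = []
    for lib in sorted(by_lib):
        out.extend(merge_runs(by_lib[lib]))
    return out


def classify_donor_calls(
    library_calls: Iterable[LibraryCall],
    donor_map: Mapping[str, str],
    support_counts: Mapping[tuple[str, VariantKey], tuple[int, int]] | None = None,
    relaxed_min_alt: int | None = None,
) -> list[DonorVariant]:
    """Integrate library-level calls into donor-level variants.

    ``donor_map`` maps every library id to its donor. By default
    double-positivity requires the full statistical criteria to have passed
    independently in two or more libraries of the donor. When
    ``relaxed_min_alt`` is set (with ``support_counts`` providing raw
    ``(n_alt, depth)`` per (library, variant key)), a variant passing in
    one library is upgraded to double-positive if another library of the
    donor merely detects it with at least ``relaxed_min_alt`` accepted
    alternate observations.
    """
    calls = list(library_calls)
    for lc in calls:
        if lc.library_id not in donor_map:
            raise ValueError(f"library {lc.library_id!r} has no donor mapping")
    donor_libraries: dict[str, set[str]] = {}
    for lib, donor in donor_map.items():
        donor_libraries.setdefault(donor, set()).add(lib)

    groups: dict[tuple[str, VariantKey], list[LibraryCall]] = {}
    for lc in calls:
        groups.setdefault((donor_map[lc.library_id], lc.key), []).append(lc)

    out: list[DonorVariant] = []
    for (donor, key), lcs in sorted(groups.items()):
        supporting = sorted({lc.library_id for lc in lcs})
        per_library = {
            lc.library_id: (lc.best.candidate.n_alt, lc.best.candidate.depth)
            for lc in lcs
        }
        n_support = len(supporting)
        if n_support >= 2:
            evidence = DOUBLE_POSITIVE
        else:
            evidence = SINGLE_POSITIVE
            if relaxed_min_alt is not None and support_counts is not None:
                for other in donor_libraries[donor] - set(supporting):
                    n_alt, depth = support_counts.get((other, key), (0, 0))
                    if n_alt >= relaxed_min_alt:
                        evidence = DOUBLE_POSITIVE
                        per_library[other] = (n_alt, depth)
                        break
        pooled_alt = sum(n for n, _ in per_library.values())
        pooled_depth = sum(d for _, d in per_library.values())
        lc0 = lcs[0]
        out.append(
            DonorVariant(
                donor_id=donor,
                chrom=key[0],
                position=key[1],
                ref=key[2],
                alt=key[3],
                target_name=lc0.target_name,
                evidence_class=evidence,
                supporting_libraries=tuple(supporting),
                per_library=per_library,
                pooled_vaf=pooled_alt / pooled_depth if pooled_depth else 0.0,
                n_libraries_tested=len(donor_libraries[donor]),
            )
        )
    return out


@dataclass(frozen=True)
class CallsetSummary:
    """Cohort-level description of a donor callset."""

    n_subjects: int
    n_variants: int
    median_vaf: float | None
    vaf_min: float | None
    vaf_max: float | None
    n_nonsynonymous: int
    n_synonymous: int
    known_fraction: float | None
    n_carriers_multi: int  # donors with >= 2 variants


def summarize_callset(
    donor_variants: Sequence[DonorVariant],
    annotations: Mapping[VariantKey, "object"] | None = None,
) -> CallsetSummary:
    """Summary counts: carriers, VAF distribution, consequence classes.

    ``annotations`` maps variant keys to objects with ``consequence`` and
    ``known_id`` attributes (see :mod:`clonesift.annotate`); without them
    the consequence and known-variant fields are zero / ``None``.
    """
    vafs = [dv.pooled_vaf for dv in donor_variants]
    per_donor: dict[str, int] = {}
    for dv in donor_variants:
        per_donor[dv.donor_id] = per_donor.get(dv.donor_id, 0) + 1
    n_nonsyn = n_syn = n_known = n_annotated = 0
    if annotations:
        for dv in donor_variants:
            ann = annotations.get(dv.key)
            if ann is None:
                continue
            n_annotated += 1
            if getattr(ann, "consequence", None) == "synonymous":
                n_syn += 1
            else:
                n_nonsyn += 1
            if getattr(ann, "known_id", None):
                n_known += 1
    return CallsetSummary(
        n_subjects=len(per_donor),
        n_variants=len(donor_variants),
        median_vaf=median(vafs) if vafs else None,
        vaf_min=min(vafs) if vafs else None,
        vaf_max=max(vafs) if vafs else None,
        n_nonsynonymous=n_nonsyn,
        n_synonymous=n_syn,
        known_fraction=(n_known / n_annotated) if n_annotated else None,
        n_carriers_multi=sum(1 for n in per_donor.values() if n >= 2),
    )
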