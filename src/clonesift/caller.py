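"""Batch-level statistical somatic variant calling.

The caller analyses all sequencing libraries of one library-preparation and
sequencing batch together, because library-preparation artefacts (mostly
PCR) repeat across the libraries of a batch. Every candidate — a
(library, position, non-reference allele) triple with at least
``min_alt_count`` accepted supporting observations — is scored with three
statistics and must pass all of them:

* **Between-sample test** — two-sided Fisher exact test of the library's
  reference/alternate counts against the summed counts of every other
  library in the batch at the same coordinate. Batch-recurrent artefacts
  appear at similar fractions in all libraries and are absorbed here.
* **Within-sample test** — upper-tail binomial test of the alternate count
  against the library's own background rate for that substitution class,
  estimated from all *other* coordinates of the same library. This rejects
  calls from libraries with an overabundance of one substitution type.
* **Log noise ratio (LNR)** — log10 of the observed variant allele
  fraction over the same background rate; calls require LNR above a
  threshold (default 1, i.e. tenfold above noise).

Both p-values are Bonferroni-corrected by the total number of candidates
enumerated in the batch run. Default thresholds (corrected p < 0.001 for
both tests, LNR > 1) are calibrated so that pure-noise technical replicate
libraries produce zero calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom, hypergeom

from .pileup import LibraryPileup

ROLE_PARTICIPANT = "participant"
ROLE_TECHNICAL_REFERENCE = "technical_reference"

#: relative tolerance when deciding which tables are "as extreme" as the
#: observed one in the two-sided Fisher summation (guards float ties)
_FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class CallerThresholds:
    """Pass criteria; p-values are compared after Bonferroni correction."""

    alpha_between: float = 0.001
    alpha_within: float = 0.001
    lnr_min: float = 1.0
    min_alt_count: int = 1

    def __post_init__(self) -> None:
        for a in (self.alpha_between, self.alpha_within):
            if not 0 < a <= 1:
                raise ValueError("alpha must be in (0, 1]")
        if self.lnr_min < 0:
            raise ValueError("lnr_min must be >= 0")


@dataclass(frozen=True)
class CandidateCall:
    """One (library, position, alt allele) candidate with its counts."""

    library_id: str
    batch_id: str
    run_id: str
    target_name: str
    chrom: str
    position: int  # 0-based
    ref: str
    alt: str
    n_alt: int
    n_ref: int
    depth: int

    def __post_init__(self) -> None:
        if self.n_alt < 1:
            raise ValueError("candidate needs n_alt >= 1")
        if self.n_alt + self.n_ref > self.depth:
            raise ValueError("n_alt + n_ref exceeds accepted depth")

    @property
    def vaf(self) -> float:
        return self.n_alt / self.depth


@dataclass(frozen=True)
class CallStatistics:
    p_between_raw: float
    p_between_corr: float
    p_within_raw: float
    p_within_corr: float
    noise_rate: float
    noise_floor: float
    lnr: float
    m_tests: int


@dataclass(frozen=True)
class VariantCall:
    candidate: CandidateCall
    stats: CallStatistics
    passed: bool
    filter: str  # "PASS" or first failed criterion


@dataclass
class BatchPileupSet:
    """All pileups of one batch, one entry per (library, target)."""

    batch_id: str
    libraries: list[LibraryPileup]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len({p.library_id for p in self.libraries}) < 2:
            raise ValueError("a batch needs pileups from at least 2 libraries")
        by_name: dict[str, object] = {}
        for p in self.libraries:
            t = by_name.setdefault(p.target.name, p.target)
            if t != p.target:
                raise ValueError(f"inconsistent definitions for target {p.target.name}")
        for p in self.libraries:
            self.roles.setdefault(p.library_id, ROLE_PARTICIPANT)

    @property
    def library_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.libraries:
            seen.setdefault(p.library_id, None)
        return list(seen)

    def pileups_for_target(self, target_name: str) -> list[LibraryPileup]:
        return [p for p in self.libraries if p.target.name == target_name]

    def pileups_for_library(self, library_id: str) -> list[LibraryPileup]:
        return [p for p in self.libraries if p.library_id == library_id]


# ---------------------------------------------------------------------------
# elementary statistics


def _validate_counts(*counts: int) -> None:
    for x in counts:
        if x < 0:
            raise ValueError("counts must be non-negative")
        if x != int(x):
            raise ValueError("counts must be integers")


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact test p-value for the 2x2 table [[a,b],[c,d]].

    Computed by summing hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed that of the observed
    table. A table with an empty margin carries no information and returns
    p = 1.
    """
    _validate_counts(a, b, c, d)
    total = a + b + c + d
    k_alt = a + c
    n_row = a + b
    if k_alt == 0 or b + d == 0 or n_row == 0 or c + d == 0:
        return 1.0
    lo = max(0, n_row - (total - k_alt))
    hi = min(n_row, k_alt)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, total, k_alt, n_row)
    p_obs = pmf[a - lo]
    p = pmf[pmf <= p_obs * (1 + _FISHER_REL_TOL)].sum()
    return float(min(1.0, p))


def fisher_two_sided_many(tables: Sequence[tuple[int, int, int, int]]) -> np.ndarray:
    """Vectorised :func:`fisher_two_sided` over many 2x2 tables.

    All hypergeometric supports are flattened into one pmf evaluation, so
    scoring the thousands of candidates of a deep batch costs a single
    vectorised scipy call plus segment sums.
    """
    n_tab = len(tables)
    out = np.ones(n_tab)
    los = np.empty(n_tab, dtype=np.int64)
    his = np.empty(n_tab, dtype=np.int64)
    keep = np.zeros(n_tab, dtype=bool)
    arr = np.asarray(tables, dtype=np.int64).reshape(n_tab, 4)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    a, b, c, d = arr.T
    total = a + b + c + d
    k_alt = a + c
    n_row = a + b
    keep = (k_alt > 0) & (b + d > 0) & (n_row > 0) & (c + d > 0)
    los = np.maximum(0, n_row - (total - k_alt))
    his = np.minimum(n_row, k_alt)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return out
    lens = (his[idx] - los[idx] + 1).astype(np.int64)
    starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
    flat_k = np.concatenate([np.arange(los[i], his[i] + 1) for i in idx])
    flat_M = np.repeat(total[idx], lens)
    flat_K = np.repeat(k_alt[idx], lens)
    flat_n = np.repeat(n_row[idx], lens)
    pmf = hypergeom.pmf(flat_k, flat_M, flat_K, flat_n)
    p_obs = pmf[starts + (a[idx] - los[idx])]
    mask = pmf <= np.repeat(p_obs, lens) * (1 + _FISHER_REL_TOL)
    sums = np.add.reduceat(np.where(mask, pmf, 0.0), starts)
    out[idx] = np.minimum(1.0, sums)
    return out


def within_sample_test(
    n_alt: int, depth: int, eps: float, eps_floor: float | None = None
) -> float:
    """Upper-tail binomial p-value: P[Binomial(depth, eps) >= n_alt].

    Only an excess of alternate bases over the background is evidence of a
    clone. A zero rate is replaced by ``eps_floor`` (the rate-resolution
    limit of the data) so the test is always defined.
    """
    if eps < 0 or eps > 1:
        raise ValueError("eps must be in [0, 1]")
    if eps == 0:
        if n_alt == 0:
            return 1.0
        if eps_floor is None:
            raise ValueError("eps = 0 requires an eps_floor")
        eps = eps_floor
    if n_alt == 0:
        return 1.0
    return float(binom.sf(n_alt - 1, depth, eps))


def log_noise_ratio(vaf: float, eps: float, eps_floor: float) -> float:
    """log10 of the observed variant fraction over the background rate."""
    if vaf <= 0:
        raise ValueError("vaf must be positive")
    return math.log10(vaf / max(eps, eps_floor))


def bonferroni(p_raw: float, m_tests: int) -> float:
    """Bonferroni correction: min(1, m_tests * p_raw)."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return min(1.0, m_tests * p_raw)


# ---------------------------------------------------------------------------
# candidate enumeration and scoring


def substitution_class(ref: str, alt: str) -> tuple[str, str]:
    """Noise-pooling class of an alternate allele.

    Substitutions pool by (reference base, alternate base); deletions by
    deleted length, insertions/duplications by inserted length.
    """
    if alt.startswith("-"):
        return ("del", str(len(alt) - 1))
    if alt.startswith("+"):
        return ("ins", str(len(alt) - 1))
    return (ref, alt)


def enumerate_candidates(
    batch: BatchPileupSet, min_alt_count: int = 1
) -> list[CandidateCall]:
    """All (library, position, non-reference allele) candidates of a batch.

    The number of candidates returned defines the Bonferroni divisor for
    the batch run.
    """
    cands: list[CandidateCall] = []
    for p in batch.libraries:
        for pos in p.positions():
            ref = p.target.ref_base(pos)
            site = p.site_counts(pos)
            n_ref = site.get(ref, 0)
            depth = p.accepted_depth(pos)
            for allele in sorted(site):
                if allele == ref:
                    continue
                n = site[allele]
                if n >= min_alt_count:
                    cands.append(
                        CandidateCall(
                            library_id=p.library_id,
                            batch_id=batch.batch_id,
                            run_id=p.run_id,
                            target_name=p.target.name,
                            chrom=p.target.chrom,
                            position=pos,
                            ref=ref,
                            alt=allele,
                            n_alt=n,
                            n_ref=n_ref,
                            depth=depth,
                        )
                    )
    cands.sort(key=lambda c: (c.library_id, c.target_name, c.position, c.alt))
    return cands


def _pooled_other_counts(
    cand: CandidateCall, batch: BatchPileupSet
) -> tuple[int, int]:
    """Summed alt/ref counts of every other library at the candidate site."""
    alt = ref = 0
    found_other = False
    found_self = False
    for p in batch.pileups_for_target(cand.target_name):
        if p.library_id == cand.library_id:
            found_self = True
            continue
        found_other = True
        alt += p.count(cand.position, cand.alt)
        ref += p.count(cand.position, cand.ref)
    if not found_self:
        raise ValueError(f"library {cand.library_id!r} not in batch {batch.batch_id!r}")
    if not found_other:
        raise ValueError("between-sample test needs at least one other library")
    return alt, ref


def between_sample_test(cand: CandidateCall, batch: BatchPileupSet) -> float:
    """Fisher exact test of the candidate library against the pooled rest."""
    o_alt, o_ref = _pooled_other_counts(cand, batch)
    return fisher_two_sided(cand.n_alt, cand.n_ref, o_alt, o_ref)


def within_sample_noise_rate(
    library_pileups: Sequence[LibraryPileup],
    cls: tuple[str, str],
    candidate_site: tuple[str, int],
    excluded_sites: frozenset[tuple[str, int]] = frozenset(),
) -> tuple[float | None, int]:
    """Background rate of a substitution class from other coordinates.

    For a substitution class (X, Y): the summed count of Y at every other
    position whose reference base is X, divided by the summed accepted
    depth at those positions. Indel classes pool matching-length indel
    alleles over all other positions. The candidate's own site and any
    sites in ``excluded_sites`` (putative same-class calls) never
    contribute. Returns ``(rate, eligible_depth)``; rate is ``None`` when
    no eligible position exists.
    """
    num = 0
    den = 0
    is_indel = cls[0] in ("del", "ins")
    for p in library_pileups:
        for pos in p.positions():
            site_key = (p.target.name, pos)
            if site_key == candidate_site or site_key in excluded_sites:
                continue
            ref = p.target.ref_base(pos)
            if not is_indel and ref != cls[0]:
                continue
            den += p.accepted_depth(pos)
            for allele, n in p.site_counts(pos).items():
                if allele == ref:
                    continue
                if substitution_class(ref, allele) == cls:
                    num += n
    if den == 0:
        return None, 0
    return num / den, den


def _site_contribution(
    pileup: LibraryPileup, pos: int, cls: tuple[str, str]
) -> tuple[int, int]:
    """(class count, eligible depth) contributed by one site to a class rate."""
    ref = pileup.target.ref_base(pos)
    is_indel = cls[0] in ("del", "ins")
    if not is_indel and ref != cls[0]:
        return 0, 0
    num = sum(
        n
        for allele, n in pileup.site_counts(pos).items()
        if allele != ref and substitution_class(ref, allele) == cls
    )
    return num, pileup.accepted_depth(pos)


def _class_totals(
    lib_pileups: Mapping[str, Sequence[LibraryPileup]],
) -> dict[tuple[str, tuple[str, str]], tuple[int, int]]:
    """Per-(library, class) summed counts and eligible depths over all sites.

    Per-candidate background rates are obtained by subtracting the
    candidate's own site (and any screened-out sites) from these totals,
    which makes rate estimation O(sites) per library instead of
    O(candidates x sites). Equivalent to :func:`within_sample_noise_rate`.
    """
    totals: dict[tuple[str, tuple[str, str]], list[int]] = {}
    for lid, pileups in lib_pileups.items():
        # depth sums by reference base (substitution classes) and overall
        depth_by_ref: dict[str, int] = {}
        depth_all = 0
        class_nums: dict[tuple[str, str], int] = {}
        indel_nums: dict[tuple[str, str], int] = {}
        for p in pileups:
            for pos in p.positions():
                ref = p.target.ref_base(pos)
                d = p.accepted_depth(pos)
                depth_by_ref[ref] = depth_by_ref.get(ref, 0) + d
                depth_all += d
                for allele, n in p.site_counts(pos).items():
                    if allele == ref:
                        continue
                    cls = substitution_class(ref, allele)
                    if cls[0] in ("del", "ins"):
                        indel_nums[cls] = indel_nums.get(cls, 0) + n
                    else:
                        class_nums[cls] = class_nums.get(cls, 0) + n
        for cls, num in class_nums.items():
            totals[(lid, cls)] = [num, depth_by_ref.get(cls[0], 0)]
        for cls, num in indel_nums.items():
            totals[(lid, cls)] = [num, depth_all]
        # classes with zero observed events still need their depth totals
        for ref_base, d in depth_by_ref.items():
            for alt in "ACGT":
                if alt != ref_base:
                    totals.setdefault((lid, (ref_base, alt)), [0, d])
    return {k: (v[0], v[1]) for k, v in totals.items()}


def call_batch(
    batch: BatchPileupSet, thresholds: CallerThresholds | None = None
) -> list[VariantCall]:
    """Score every candidate of a batch and apply the pass criteria.

    The Bonferroni divisor is the number of enumerated candidates and is
    shared by both tests. Background rates are estimated with a two-pass
    scheme: sites whose same-class candidate survives the between-sample
    screen in the same library are excluded from the rate, so genuine
    clones do not inflate their own background.
    """
    th = thresholds or CallerThresholds()
    cands = enumerate_candidates(batch, th.min_alt_count)
    m = len(cands)
    if m == 0:
        return []

    tables = [(c.n_alt, c.n_ref, *_pooled_other_counts(c, batch)) for c in cands]
    p_between = fisher_two_sided_many(tables)

    # first-pass screen: same-class sites that look like real clones are
    # excluded from the background rate of that class in that library
    excluded: dict[tuple[str, tuple[str, str]], set[tuple[str, int]]] = {}
    for c, pb in zip(cands, p_between):
        if bonferroni(pb, m) < th.alpha_between:
            cls = substitution_class(c.ref, c.alt)
            excluded.setdefault((c.library_id, cls), set()).add(
                (c.target_name, c.position)
            )

    lib_pileups = {lid: batch.pileups_for_library(lid) for lid in batch.library_ids}
    total_depth = {
        lid: sum(p.total_depth() for p in ps) for lid, ps in lib_pileups.items()
    }
    totals = _class_totals(lib_pileups)
    site_index = {
        lid: {(p.target.name, pos): (p, pos) for p in ps for pos in p.positions()}
        for lid, ps in lib_pileups.items()
    }

    calls: list[VariantCall] = []
    for c, pb in zip(cands, p_between):
        cls = substitution_class(c.ref, c.alt)
        num, den = totals.get((c.library_id, cls), (0, 0))
        remove = set(excluded.get((c.library_id, cls), set()))
        remove.add((c.target_name, c.position))
        for site in remove:
            entry = site_index[c.library_id].get(site)
            if entry is None:
                continue
            d_num, d_den = _site_contribution(*entry, cls)
            num -= d_num
            den -= d_den
        eps = num / den if den > 0 else None
        eligible_depth = den
        if eligible_depth > 0:
            floor = 1.0 / eligible_depth
        else:
            floor = 1.0 / max(total_depth[c.library_id], 1)
        eps_val = eps if eps is not None else 0.0
        pw = within_sample_test(c.n_alt, c.depth, eps_val, eps_floor=floor)
        lnr = log_noise_ratio(c.vaf, eps_val, floor)
        stats = CallStatistics(
            p_between_raw=float(pb),
            p_between_corr=bonferroni(float(pb), m),
            p_within_raw=pw,
            p_within_corr=bonferroni(pw, m),
            noise_rate=eps_val,
            noise_floor=floor,
            lnr=lnr,
            m_tests=m,
        )
        if not stats.p_between_corr < th.alpha_between:
            passed, filt = False, "between"
        elif not stats.p_within_corr < th.alpha_within:
            passed, filt = False, "within"
        elif not lnr > th.lnr_min:
            passed, filt = False, "lnr"
        else:
            passed, filt = True, "PASS"
        calls.append(VariantCall(candidate=c, stats=stats, passed=passed, filter=filt))
    return calls


def passing_calls(calls: Iterable[VariantCall]) -> list[VariantCall]:
    return [v for v in calls if v.passed]
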