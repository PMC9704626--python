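"""Synthetic deep-amplicon data with a complete truth ledger.

The generator emulates the data regime of ultra-deep targeted amplicon
sequencing of two short exonic targets: accepted depths of tens of
thousands per position, per-substitution-class background noise around
1e-4, occasional batch-recurrent artefact sites shared by every library of
a batch, and spiked clonal variants at variant allele fractions of
roughly 0.005%-1.5% carried by all libraries of a donor.

Two generation paths are provided. ``simulate_batch_counts`` draws
accepted allele counts directly (Poisson accepted depth, multinomial
allele draw per site) — fast enough to run whole cohorts in property
tests. ``simulate_reads`` emits pre-aligned paired-end SAM-style records
with independent per-mate errors, which is the mechanism the dual-strand
consensus filter exploits: a read-level error rate ``e`` yields concordant
(accepted) errors at only about ``e^2/3`` per class. Every draw is logged
in a :class:`TruthLedger` so tests can recompute any count by brute force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .caller import BatchPileupSet, ROLE_PARTICIPANT, ROLE_TECHNICAL_REFERENCE
from .pileup import LibraryPileup
from .targets import AmpliconTarget

MAX_RATE = 0.05

#: transition partners (the asymmetric part of the default error spectrum)
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class NoiseProfile:
    """Per-substitution-class background error rates.

    ``substitution_rates`` carries the 12 ordered base substitution
    classes; ``site_multipliers`` lets single sites be noisier than their
    class average; ``indel_rates`` is keyed by ('del'|'ins', length).
    Rates apply to *accepted* (dual-strand) observations.
    """

    substitution_rates: Mapping[tuple[str, str], float]
    site_multipliers: Mapping[tuple[str, int], float] = field(default_factory=dict)
    indel_rates: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rate in list(self.substitution_rates.values()) + list(
            self.indel_rates.values()
        ):
            if not 0 <= rate <= MAX_RATE:
                raise ValueError(f"noise rate {rate} outside [0, {MAX_RATE}]")

    @classmethod
    def default(
        cls,
        transition: float = 1.5e-4,
        transversion: float = 5e-5,
        del1: float = 2e-5,
        ins1: float = 1e-5,
    ) -> "NoiseProfile":
        """Asymmetric spectrum: transitions 3x transversions by default."""
        rates = {}
        for x in "ACGT":
            for y in "ACGT":
                if x != y:
                    rates[(x, y)] = transition if (x, y) in _TRANSITIONS else transversion
        indels = {}
        if del1 > 0:
            indels[("del", "1")] = del1
        if ins1 > 0:
            indels[("ins", "1")] = ins1
        return cls(substitution_rates=rates, indel_rates=indels)

    @classmethod
    def zero(cls) -> "NoiseProfile":
        return cls(substitution_rates={}, indel_rates={})

    def substitution_rate(self, target_name: str, pos: int, ref: str, alt: str) -> float:
        base = self.substitution_rates.get((ref, alt), 0.0)
        return base * self.site_multipliers.get((target_name, pos), 1.0)


@dataclass(frozen=True)
class BatchArtefact:
    """A batch-recurrent artefact: present in every library of the batch.

    Per-library fractions are drawn from a Beta distribution with the
    given mean and coefficient of variation; a small CV reflects how
    tightly a library-preparation artefact repeats within its batch.
    """

    target_name: str
    position: int
    alt: str
    mean_fraction: float
    cv: float = 0.1

    def beta_params(self) -> tuple[float, float]:
        m = self.mean_fraction
        sd = self.cv * m
        kappa = m * (1 - m) / sd**2 - 1
        return m * kappa, (1 - m) * kappa


@dataclass(frozen=True)
class SpikedClone:
    """A real clonal variant carried by all libraries of one donor."""

    donor_id: str
    target_name: str
    position: int
    ref: str
    alt: str
    vaf: float

    def __post_init__(self) -> None:
        if not 0 < self.vaf <= 0.015:
            raise ValueError("spiked VAF must lie in (0, 0.015]")


@dataclass(frozen=True)
class LibrarySpec:
    library_id: str
    donor_id: str
    role: str = ROLE_PARTICIPANT


@dataclass
class TruthLedger:
    """Everything needed to recompute the simulated data by brute force."""

    seed: int
    spikes: list[SpikedClone] = field(default_factory=list)
    artefacts: list[BatchArtefact] = field(default_factory=list)
    #: realised per-library artefact fractions: (library, target, pos, alt) -> f
    artefact_fractions: dict[tuple[str, str, int, str], float] = field(
        default_factory=dict
    )
    #: configured alt-allele rate per (library, target, pos, allele)
    expected_rates: dict[tuple[str, str, int, str], float] = field(
        default_factory=dict
    )
    #: read-level path only: per-fragment raw observations
    #: (fragment, pos) -> (base_r1, qual_r1, base_r2, qual_r2)
    observations: dict[tuple[int, int], tuple[str, int, str, int]] = field(
        default_factory=dict
    )
    #: read-level path only: template allele per fragment per spiked site
    template_alleles: dict[tuple[int, int], str] = field(default_factory=dict)


def _site_alt_rates(
    target: AmpliconTarget,
    pos: int,
    library: LibrarySpec,
    noise: NoiseProfile,
    artefact_fracs: Mapping[tuple[str, str, int, str], float],
    spike_map: Mapping[tuple[str, str, int], SpikedClone],
) -> dict[str, float]:
    """Configured alternate-allele rates at one site for one library."""
    ref = target.ref_base(pos)
    rates: dict[str, float] = {}
    for alt in "ACGT":
        if alt == ref:
            continue
        r = noise.substitution_rate(target.name, pos, ref, alt)
        if r > 0:
            rates[alt] = r
    for (cls_kind, cls_len), r in noise.indel_rates.items():
        if r <= 0:
            continue
        length = int(cls_len)
        if cls_kind == "del":
            if pos + length < target.end:
                seq = target.ref_seq[pos + 1 - target.start : pos + 1 + length - target.start]
                rates["-" + seq] = rates.get("-" + seq, 0.0) + r
        else:
            ins = ("A" * length) if ref != "A" else ("C" * length)
            rates["+" + ins] = rates.get("+" + ins, 0.0) + r
    for (lib_id, tname, p, alt), f in artefact_fracs.items():
        if lib_id == library.library_id and tname == target.name and p == pos:
            rates[alt] = rates.get(alt, 0.0) + f
    spike = spike_map.get((library.donor_id, target.name, pos))
    if spike is not None and library.role == ROLE_PARTICIPANT:
        rates[spike.alt] = rates.get(spike.alt, 0.0) + spike.vaf
    return rates


def simulate_batch_counts(
    targets: Sequence[AmpliconTarget],
    libraries: Sequence[LibrarySpec] | int,
    mean_depth: float,
    noise: NoiseProfile | None = None,
    artefacts: Sequence[BatchArtefact] = (),
    spikes: Sequence[SpikedClone] = (),
    seed: int = 0,
    batch_id: str = "batch1",
    run_id: str = "run1",
) -> tuple[BatchPileupSet, TruthLedger]:
    """Draw accepted allele-count pileups for one batch.

    Accepted depth at each position is Poisson around ``mean_depth``; the
    allele split at a site is one multinomial draw over the configured
    alternate-allele rates (noise + artefact + spike), remainder reference.
    Deterministic for a fixed seed.
    """
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    if isinstance(libraries, int):
        libraries = [LibrarySpec(f"lib{i + 1}", f"donor{i + 1}") for i in range(libraries)]
    noise = noise if noise is not None else NoiseProfile.default()
    rng = np.random.default_rng(seed)
    ledger = TruthLedger(seed=seed, spikes=list(spikes), artefacts=list(artefacts))
    tmap = {t.name: t for t in targets}
    for art in artefacts:
        if art.target_name not in tmap:
            raise ValueError(f"artefact target {art.target_name!r} unknown")
        a, b = art.beta_params()
        for lib in libraries:
            frac = float(rng.beta(a, b))
            ledger.artefact_fractions[
                (lib.library_id, art.target_name, art.position, art.alt)
            ] = frac
    spike_map = {(s.donor_id, s.target_name, s.position): s for s in spikes}
    for s in spikes:
        if tmap[s.target_name].ref_base(s.position) != s.ref:
            raise ValueError(f"spike ref mismatch at {s.target_name}:{s.position}")

    pileups: list[LibraryPileup] = []
    roles = {lib.library_id: lib.role for lib in libraries}
    for lib in libraries:
        for target in targets:
            pile = LibraryPileup(
                library_id=lib.library_id,
                target=target,
                run_id=run_id,
                donor_id=lib.donor_id,
                batch_id=batch_id,
            )
            n_pos = len(target)
            depths = rng.poisson(mean_depth, size=n_pos)
            for i, pos in enumerate(target.positions):
                ref = target.ref_base(pos)
                depth = int(depths[i])
                if depth == 0:
                    continue
                rates = _site_alt_rates(
                    target, pos, lib, noise, ledger.artefact_fractions, spike_map
                )
                total = sum(rates.values())
                if total > 1:
                    raise ValueError(
                        f"allele rates sum to {total} > 1 at {target.name}:{pos}"
                    )
                for allele, r in rates.items():
                    ledger.expected_rates[
                        (lib.library_id, target.name, pos, allele)
                    ] = r
                alleles = sorted(rates)
                probs = [rates[a] for a in alleles] + [1 - total]
                draw = rng.multinomial(depth, probs)
                for allele, n in zip(alleles, draw[:-1]):
                    if n:
                        pile.add(pos, allele, int(n))
                if draw[-1]:
                    pile.add(pos, ref, int(draw[-1]))
            pileups.append(pile)
    batch = BatchPileupSet(batch_id=batch_id, libraries=pileups, roles=roles)
    return batch, ledger


# ---------------------------------------------------------------------------
# read-level simulation


@dataclass(frozen=True)
class QualityModel:
    """Per-base Phred qualities: clipped normal draw per base."""

    mean: float = 36.0
    sd: float = 3.0
    lo: int = 2
    hi: int = 40

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        q = rng.normal(self.mean, self.sd, size=n)
        return np.clip(np.rint(q), self.lo, self.hi).astype(int)


def sam_header(targets: Sequence[AmpliconTarget]) -> pysam.AlignmentHeader:
    max_end: dict[str, int] = {}
    for t in targets:
        max_end[t.chrom] = max(max_end.get(t.chrom, 0), t.end)
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": e + 1000} for c, e in sorted(max_end.items())],
        }
    )


def simulate_reads(
    target: AmpliconTarget,
    n_fragments: int,
    quality: QualityModel | None = None,
    template_noise: NoiseProfile | None = None,
    spikes: Sequence[SpikedClone] = (),
    donor_id: str = "donor1",
    seed: int = 0,
    header: pysam.AlignmentHeader | None = None,
) -> tuple[list[tuple[pysam.AlignedSegment, pysam.AlignedSegment]], TruthLedger]:
    """Emit pre-aligned paired-end records over one amplicon target.

    Each fragment spans the whole target (2x300bp mates over a short
    amplicon overlap completely). ``template_noise`` acts at template
    level — both mates carry it, like a PCR artefact or a real clone —
    while per-mate sequencing errors are drawn independently per base with
    probability ``10^(-q/10)`` from that base's quality ``q``. The ledger
    logs every raw observation so acceptance can be recounted externally.
    """
    quality = quality or QualityModel()
    rng = np.random.default_rng(seed)
    ledger = TruthLedger(seed=seed, spikes=list(spikes))
    header = header or sam_header([target])
    L = len(target)
    ref = np.frombuffer(target.ref_seq.encode(), dtype="S1")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    base_idx = {b: i for i, b in enumerate(bases)}
    spike_sites = [
        s for s in spikes if s.target_name == target.name and s.donor_id == donor_id
    ]
    pairs = []
    for frag in range(n_fragments):
        template = ref.copy()
        for s in spike_sites:
            if rng.random() < s.vaf:
                template[s.position - target.start] = s.alt.encode()
                ledger.template_alleles[(frag, s.position)] = s.alt
        if template_noise is not None:
            for i in range(L):
                rb = template[i].decode()
                for alt in "ACGT":
                    if alt == rb:
                        continue
                    r = template_noise.substitution_rate(
                        target.name, target.start + i, rb, alt
                    )
                    if r > 0 and rng.random() < r:
                        template[i] = alt.encode()
                        ledger.template_alleles[(frag, target.start + i)] = alt
                        break
        mates = []
        for _ in range(2):
            quals = quality.draw(rng, L)
            err_p = np.power(10.0, -quals / 10.0)
            errs = rng.random(L) < err_p
            seq = template.copy()
            for i in np.flatnonzero(errs):
                cur = int(base_idx[seq[i]])
                seq[i] = bases[(cur + int(rng.integers(1, 4))) % 4]
            mates.append((seq, quals))
        (s1, q1), (s2, q2) = mates
        for i in range(L):
            ledger.observations[(frag, target.start + i)] = (
                s1[i].decode(),
                int(q1[i]),
                s2[i].decode(),
                int(q2[i]),
            )
        recs = []
        for mate_i, (seq, quals) in enumerate(mates):
            rec = pysam.AlignedSegment(header)
            rec.query_name = f"frag{frag}"
            rec.query_sequence = seq.tobytes().decode()
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            rec.reference_name = target.chrom
            rec.reference_start = target.start
            rec.cigarstring = f"{L}M"
            rec.mapping_quality = 60
            rec.is_paired = True
            rec.is_proper_pair = True
            rec.is_read1 = mate_i == 0
            rec.is_read2 = mate_i == 1
            rec.is_reverse = mate_i == 1
            rec.mate_is_reverse = mate_i == 0
            rec.next_reference_name = target.chrom
            rec.next_reference_start = target.start
            recs.append(rec)
        pairs.append((recs[0], recs[1]))
    return pairs, ledger


def write_sam(
    pairs: Iterable[tuple[pysam.AlignedSegment, pysam.AlignedSegment]],
    header: pysam.AlignmentHeader,
    path,
) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r1, r2 in pairs:
            out.write(r1)
            out.write(r2)


# ---------------------------------------------------------------------------
# replicate-experiment fixture


@dataclass(frozen=True)
class ReplicateExperimentConfig:
    """Study-condition defaults for the cohort fixture.

    Duplicate-library donors mirror the duplicate PCR design; a minority
    of donors have a single library and can only reach single-positive
    status. Each batch carries one technical reference library prepared
    from control DNA. Spiked VAFs are drawn log-uniformly from a range a
    deep 50,000x run detects reliably.
    """

    n_duplicate_donors: int = 6
    n_single_donors: int = 2
    n_spiked_duplicate: int = 4
    n_spiked_single: int = 2
    n_batches: int = 2
    n_rerun_libraries: int = 2
    mean_depth: float = 50_000.0
    vaf_range: tuple[float, float] = (3e-3, 1.2e-2)
    artefacts_per_batch: int = 1
    artefact_fraction: float = 3e-3


@dataclass
class ReplicateExperiment:
    batches: list[BatchPileupSet]
    donor_map: dict[str, str]
    metadata: pd.DataFrame
    donor_metadata: pd.DataFrame
    spikes: list[SpikedClone]
    ledgers: dict[str, TruthLedger]
    config: ReplicateExperimentConfig
    seed: int


def make_replicate_experiment(
    targets: Sequence[AmpliconTarget],
    config: ReplicateExperimentConfig | None = None,
    seed: int = 0,
) -> ReplicateExperiment:
    """Build a ready-to-run cohort fixture with known truth.

    Every spiked variant is carried by *all* libraries of its donor, so on
    this fixture a correctly working pipeline classifies spikes in
    duplicate-library donors as double-positive and spikes in
    single-library donors as single-positive.
    """
    cfg = config or ReplicateExperimentConfig()
    rng = np.random.default_rng(seed)
    noise = NoiseProfile.default()

    libraries: list[LibrarySpec] = []
    donor_map: dict[str, str] = {}
    donors: list[str] = []
    for i in range(cfg.n_duplicate_donors):
        donor = f"donor{i + 1}"
        donors.append(donor)
        for rep in (1, 2):
            lib = f"{donor}_L{rep}"
            libraries.append(LibrarySpec(lib, donor))
            donor_map[lib] = donor
    for i in range(cfg.n_single_donors):
        donor = f"sdonor{i + 1}"
        donors.append(donor)
        lib = f"{donor}_L1"
        libraries.append(LibrarySpec(lib, donor))
        donor_map[lib] = donor

    # spiked clones at distinct sites, one per spiked donor
    spiked_donors = [f"donor{i + 1}" for i in range(cfg.n_spiked_duplicate)] + [
        f"sdonor{i + 1}" for i in range(cfg.n_spiked_single)
    ]
    sites: list[tuple[AmpliconTarget, int]] = [
        (t, pos) for t in targets for pos in t.positions
    ]
    art_positions: set[tuple[str, int]] = set()
    artefacts_by_batch: dict[str, list[BatchArtefact]] = {}
    for b in range(cfg.n_batches):
        arts = []
        for _ in range(cfg.artefacts_per_batch):
            t, pos = sites[int(rng.integers(len(sites)))]
            ref = t.ref_base(pos)
            alt = rng.permuted([a for a in "ACGT" if a != ref])[0]
            arts.append(
                BatchArtefact(t.name, pos, str(alt), cfg.artefact_fraction)
            )
            art_positions.add((t.name, pos))
        artefacts_by_batch[f"batch{b + 1}"] = arts

    spikes: list[SpikedClone] = []
    used: set[tuple[str, int]] = set(art_positions)
    lo, hi = cfg.vaf_range
    for donor in spiked_donors:
        while True:
            t, pos = sites[int(rng.integers(len(sites)))]
            if (t.name, pos) not in used:
                used.add((t.name, pos))
                break
        ref = t.ref_base(pos)
        alt = str(rng.permuted([a for a in "ACGT" if a != ref])[0])
        vaf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        spikes.append(SpikedClone(donor, t.name, pos, ref, alt, vaf))

    # distribute libraries over batches round-robin; each batch gets its
    # own technical reference library
    batch_specs: dict[str, list[LibrarySpec]] = {
        f"batch{b + 1}": [] for b in range(cfg.n_batches)
    }
    for i, lib in enumerate(libraries):
        batch_specs[f"batch{(i % cfg.n_batches) + 1}"].append(lib)
    for b in range(cfg.n_batches):
        ref_lib = LibrarySpec(
            f"ref_B{b + 1}", f"control_pool{b + 1}", ROLE_TECHNICAL_REFERENCE
        )
        batch_specs[f"batch{b + 1}"].append(ref_lib)
        donor_map[ref_lib.library_id] = ref_lib.donor_id

    # a few libraries are re-sequenced in the following batch (deeper data
    # through an extra run, exercising run merging)
    rerun = [lib for lib in libraries[: cfg.n_rerun_libraries]]
    for i, lib in enumerate(rerun):
        other = f"batch{((i + 1) % cfg.n_batches) + 1}"
        batch_specs[other].append(lib)

    batches: list[BatchPileupSet] = []
    ledgers: dict[str, TruthLedger] = {}
    rows = []
    for b in range(cfg.n_batches):
        batch_id = f"batch{b + 1}"
        child_seed = int(rng.integers(0, 2**31 - 1))
        batch, ledger = simulate_batch_counts(
            targets,
            batch_specs[batch_id],
            cfg.mean_depth,
            noise=noise,
            artefacts=artefacts_by_batch[batch_id],
            spikes=spikes,
            seed=child_seed,
            batch_id=batch_id,
            run_id=f"run{b + 1}",
        )
        batches.append(batch)
        ledgers[batch_id] = ledger
        for spec in batch_specs[batch_id]:
            rows.append(
                {
                    "library": spec.library_id,
                    "donor": spec.donor_id,
                    "batch": batch_id,
                    "run": f"run{b + 1}",
                    "role": spec.role,
                }
            )
    metadata = pd.DataFrame(rows)

    donor_rows = []
    for i, donor in enumerate(donors):
        donor_rows.append(
            {
                "donor_id": donor,
                "group": "case" if i % 2 == 0 else "control",
                "sex": "F" if rng.random() < 0.7 else "M",
                "age": float(np.clip(rng.normal(40, 12), 19, 70)),
            }
        )
    donor_metadata = pd.DataFrame(donor_rows)

    return ReplicateExperiment(
        batches=batches,
        donor_map=donor_map,
        metadata=metadata,
        donor_metadata=donor_metadata,
        spikes=spikes,
        ledgers=ledgers,
        config=cfg,
        seed=seed,
    )
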