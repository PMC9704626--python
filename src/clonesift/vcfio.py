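"""Export of scored candidates and donor variants to VCF and TSV.

Internal coordinates are 0-based half-open; VCF and TSV exports are
1-based. Internal indel alleles (``+SEQ`` / ``-SEQ`` anchored at a
position) are converted to standard anchored VCF REF/ALT pairs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .caller import VariantCall
from .pileup import is_indel_allele
from .targets import AmpliconTarget


def vcf_alleles(
    position: int, ref: str, alt: str, target: AmpliconTarget
) -> tuple[int, str, str]:
    """Convert an internal allele pair to VCF (pos0, REF, ALT).

    Substitutions pass through; a deletion ``-SEQ`` anchored at ``position``
    becomes ``REF=anchor+SEQ, ALT=anchor`` and an insertion ``+SEQ``
    becomes ``REF=anchor, ALT=anchor+SEQ``.
    """
    if not is_indel_allele(alt):
        return position, ref, alt
    anchor = target.ref_base(position)
    seq = alt[1:]
    if alt.startswith("-"):
        return position, anchor + seq, anchor
    return position, anchor, anchor + seq


def calls_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    """Full table of scored candidates (one row per candidate)."""
    rows = []
    for v in calls:
        c, s = v.candidate, v.stats
        rows.append(
            {
                "library": c.library_id,
                "batch": c.batch_id,
                "run": c.run_id,
                "target": c.target_name,
                "chrom": c.chrom,
                "pos": c.position + 1,
                "ref": c.ref,
                "alt": c.alt,
                "n_alt": c.n_alt,
                "n_ref": c.n_ref,
                "depth": c.depth,
                "vaf": c.vaf,
                "p_between_raw": s.p_between_raw,
                "p_between_corr": s.p_between_corr,
                "p_within_raw": s.p_within_raw,
                "p_within_corr": s.p_within_corr,
                "eps": s.noise_rate,
                "lnr": s.lnr,
                "m_tests": s.m_tests,
                "filter": v.filter,
                "passed": v.passed,
            }
        )
    return pd.DataFrame(rows)


def calls_from_frame(df: pd.DataFrame) -> list[VariantCall]:
    """Rebuild scored candidates from a :func:`calls_to_frame` table."""
    from .caller import CallStatistics, CandidateCall

    calls = []
    for _, r in df.iterrows():
        cand = CandidateCall(
            library_id=str(r["library"]),
            batch_id=str(r["batch"]),
            run_id=str(r["run"]),
            target_name=str(r["target"]),
            chrom=str(r["chrom"]),
            position=int(r["pos"]) - 1,
            ref=str(r["ref"]),
            alt=str(r["alt"]),
            n_alt=int(r["n_alt"]),
            n_ref=int(r["n_ref"]),
            depth=int(r["depth"]),
        )
        stats = CallStatistics(
            p_between_raw=float(r["p_between_raw"]),
            p_between_corr=float(r["p_between_corr"]),
            p_within_raw=float(r["p_within_raw"]),
            p_within_corr=float(r["p_within_corr"]),
            noise_rate=float(r["eps"]),
            noise_floor=float(r.get("noise_floor", 0.0) or 0.0),
            lnr=float(r["lnr"]),
            m_tests=int(r["m_tests"]),
        )
        calls.append(
            VariantCall(
                candidate=cand,
                stats=stats,
                passed=bool(r["passed"]),
                filter=str(r["filter"]),
            )
        )
    return calls


def donor_variants_to_frame(donor_variants) -> pd.DataFrame:
    """Donor-level variant table with evidence class and pooled VAF."""
    rows = []
    for dv in donor_variants:
        rows.append(
            {
                "donor": dv.donor_id,
                "chrom": dv.chrom,
                "pos": dv.position + 1,
                "ref": dv.ref,
                "alt": dv.alt,
                "target": dv.target_name,
                "evidence_class": dv.evidence_class,
                "supporting_libraries": ",".join(dv.supporting_libraries),
                "n_libraries_tested": dv.n_libraries_tested,
                "pooled_vaf": dv.pooled_vaf,
            }
        )
    return pd.DataFrame(rows)


def _vcf_header(targets: Sequence[AmpliconTarget]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    max_end: dict[str, int] = {}
    for t in targets:
        max_end[t.chrom] = max(max_end.get(t.chrom, 0), t.end)
    for chrom, end in max_end.items():
        header.add_line(f"##contig=<ID={chrom},length={end + 1000}>")
    for id_, desc in [
        ("between", "Between-sample Fisher exact test failed"),
        ("within", "Within-sample binomial noise test failed"),
        ("lnr", "Log noise ratio below threshold"),
    ]:
        header.add_line(f'##FILTER=<ID={id_},Description="{desc}">')
    for id_, num, typ, desc in [
        ("LIB", "1", "String", "Sequencing library"),
        ("BATCH", "1", "String", "Library preparation and sequencing batch"),
        ("RUN", "1", "String", "Sequencing run"),
        ("PB_RAW", "1", "Float", "Between-sample Fisher exact p-value"),
        ("PB_CORR", "1", "Float", "Bonferroni-corrected between-sample p-value"),
        ("PW_RAW", "1", "Float", "Within-sample binomial p-value"),
        ("PW_CORR", "1", "Float", "Bonferroni-corrected within-sample p-value"),
        ("EPS", "1", "Float", "Background noise rate of the substitution class"),
        ("LNR", "1", "Float", "Log10 of VAF over background noise rate"),
        ("MTESTS", "1", "Integer", "Bonferroni divisor (candidates in batch run)"),
        ("DP", "1", "Integer", "Accepted dual-strand depth"),
        ("AD", "R", "Integer", "Accepted observations per allele (ref, alt)"),
        ("VAF", "1", "Float", "Variant allele fraction"),
    ]:
        header.add_line(
            f'##INFO=<ID={id_},Number={num},Type={typ},Description="{desc}">'
        )
    return header


def write_batch_vcf(
    calls: Iterable[VariantCall],
    targets: Sequence[AmpliconTarget],
    path: str | Path,
    passing_only: bool = False,
) -> None:
    """Write scored candidates of one batch to an uncompressed VCF."""
    by_name = {t.name: t for t in targets}
    header = _vcf_header(targets)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in calls:
            if passing_only and not v.passed:
                continue
            c = v.candidate
            pos0, ref, alt = vcf_alleles(
                c.position, c.ref, c.alt, by_name[c.target_name]
            )
            rec = out.new_record(
                contig=c.chrom, start=pos0, alleles=(ref, alt), filter=v.filter
            )
            s = v.stats
            rec.info["LIB"] = c.library_id
            rec.info["BATCH"] = c.batch_id
            rec.info["RUN"] = c.run_id
            rec.info["PB_RAW"] = s.p_between_raw
            rec.info["PB_CORR"] = s.p_between_corr
            rec.info["PW_RAW"] = s.p_within_raw
            rec.info["PW_CORR"] = s.p_within_corr
            rec.info["EPS"] = s.noise_rate
            rec.info["LNR"] = s.lnr
            rec.info["MTESTS"] = s.m_tests
            rec.info["DP"] = c.depth
            rec.info["AD"] = (c.n_ref, c.n_alt)
            rec.info["VAF"] = c.vaf
            out.write(rec)
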