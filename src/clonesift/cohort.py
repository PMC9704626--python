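"""Case/control statistics on donor-level callsets.

Carrier prevalences are compared between groups with the two-sided Fisher
exact test, Bonferroni-corrected by the number of criteria compared
(four: any mutation, two-or-more mutations, known-variant carrier,
other-mutation carrier). Age associations use the classic Student t-test
(pooled variance; Welch available behind a flag), mutation load the
two-sided Mann-Whitney U test with tie correction, and the VAF-age trend
a Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import ConsequenceAnnotation
from .caller import bonferroni, fisher_two_sided
from .replicates import DonorVariant, VariantKey

DEFAULT_N_COMPARISONS = 4

CRITERION_ANY = "any"
CRITERION_GE2 = "ge2"
CRITERION_KNOWN = "known"
CRITERION_OTHER = "other"
CRITERIA = (CRITERION_ANY, CRITERION_GE2, CRITERION_KNOWN, CRITERION_OTHER)

CRITERION_LABELS = {
    CRITERION_ANY: "Any mutation",
    CRITERION_GE2: "Any mutations >=2",
    CRITERION_KNOWN: "Mutation in COSMIC/OMIM",
    CRITERION_OTHER: "Other mutations",
}


@dataclass(frozen=True)
class CohortTable:
    """2x2 carrier contingency table for one criterion.

    ``a``/``b`` are carriers/non-carriers in group 1 (cases), ``c``/``d``
    in group 2 (controls).
    """

    label: str
    a: int
    b: int
    c: int
    d: int
    group1: str = "case"
    group2: str = "control"
    p_raw: float | None = None
    p_corr: float | None = None
    n_comparisons: int | None = None


def _is_carrier(
    n_variants: int,
    n_known: int,
    n_other: int,
    criterion: str,
) -> bool:
    if criterion == CRITERION_ANY:
        return n_variants >= 1
    if criterion == CRITERION_GE2:
        return n_variants >= 2
    if criterion == CRITERION_KNOWN:
        return n_known >= 1
    if criterion == CRITERION_OTHER:
        return n_other >= 1
    raise ValueError(f"unknown criterion {criterion!r}")


def carrier_table(
    donor_variants: Sequence[DonorVariant],
    metadata: pd.DataFrame,
    criterion: str,
    annotations: Mapping[VariantKey, ConsequenceAnnotation] | None = None,
) -> CohortTable:
    """Count carriers per group for one criterion.

    ``metadata`` must have columns ``donor_id`` and ``group`` with groups
    ``case``/``control``; each donor is counted once. The ``known`` and
    ``other`` criteria need ``annotations`` to decide membership of the
    bundled known-variant table.
    """
    if criterion in (CRITERION_KNOWN, CRITERION_OTHER) and annotations is None:
        raise ValueError(f"criterion {criterion!r} requires annotations")
    known_donors = set(metadata["donor_id"].astype(str))
    counts: dict[str, list[int]] = {}
    for dv in donor_variants:
        if dv.donor_id not in known_donors:
            raise ValueError(f"donor {dv.donor_id!r} missing from metadata")
        entry = counts.setdefault(dv.donor_id, [0, 0, 0])
        entry[0] += 1
        if annotations is not None:
            ann = annotations.get(dv.key)
            if ann is not None and ann.known_id:
                entry[1] += 1
            else:
                entry[2] += 1
    carriers = {"case": 0, "control": 0}
    sizes = {"case": 0, "control": 0}
    for _, row in metadata.iterrows():
        group = str(row["group"])
        if group not in sizes:
            raise ValueError(f"group must be case/control, got {group!r}")
        sizes[group] += 1
        n_var, n_known, n_other = counts.get(str(row["donor_id"]), (0, 0, 0))
        if _is_carrier(n_var, n_known, n_other, criterion):
            carriers[group] += 1
    return CohortTable(
        label=CRITERION_LABELS.get(criterion, criterion),
        a=carriers["case"],
        b=sizes["case"] - carriers["case"],
        c=carriers["control"],
        d=sizes["control"] - carriers["control"],
    )


def compare_groups(
    table: CohortTable, n_comparisons: int = DEFAULT_N_COMPARISONS
) -> CohortTable:
    """Attach the Fisher exact p-value and its Bonferroni correction."""
    p_raw = fisher_two_sided(table.a, table.b, table.c, table.d)
    return replace(
        table,
        p_raw=p_raw,
        p_corr=bonferroni(p_raw, n_comparisons),
        n_comparisons=n_comparisons,
    )


@dataclass(frozen=True)
class AgeAssociation:
    mean_carrier: float
    mean_noncarrier: float
    median_carrier: float
    median_noncarrier: float
    p_value: float | None  # None when degenerate


def age_association(
    carrier_ages: Sequence[float],
    noncarrier_ages: Sequence[float],
    welch: bool = False,
) -> AgeAssociation:
    """Two-sample t-test of carrier vs non-carrier age.

    Classic Student (pooled variance) by default; ``welch=True`` drops the
    equal-variance assumption. Degenerate inputs (a single observation or
    zero pooled variance) report the p-value as ``None``.
    """
    x = np.asarray(carrier_ages, dtype=float)
    y = np.asarray(noncarrier_ages, dtype=float)
    if len(x) < 2 or len(y) < 2:
        p = None
    else:
        import warnings

        with warnings.catch_warnings():
            # degenerate (zero-variance) inputs are reported as NA, so the
            # precision warning scipy raises for them is expected
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(x, y, equal_var=not welch)
        p = float(res.pvalue)
        if math.isnan(p):
            p = None
    mk = lambda a, f: float(f(a)) if len(a) else float("nan")
    return AgeAssociation(
        mean_carrier=mk(x, np.mean),
        mean_noncarrier=mk(y, np.mean),
        median_carrier=mk(x, np.median),
        median_noncarrier=mk(y, np.median),
        p_value=p,
    )


#: above this number of distinct group assignments the Mann-Whitney test
#: falls back to the tie-corrected normal approximation
_MWU_EXACT_LIMIT = 200_000


def mutation_load_test(
    case_counts: Sequence[float], control_counts: Sequence[float]
) -> float:
    """Two-sided Mann-Whitney U p-value for per-donor mutation counts.

    Small problems are evaluated exactly (full enumeration of group
    assignments, ties handled by the permutation distribution of U);
    larger ones use the tie-corrected normal approximation.
    """
    x = np.asarray(case_counts, dtype=float)
    y = np.asarray(control_counts, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if math.comb(len(x) + len(y), len(x)) <= _MWU_EXACT_LIMIT:
        method = stats.PermutationMethod(n_resamples=np.inf)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def vaf_age_correlation(
    ages: Sequence[float], vafs: Sequence[float]
) -> tuple[float | None, float | None]:
    """Pearson correlation of donor age with variant allele fraction."""
    x = np.asarray(ages, dtype=float)
    y = np.asarray(vafs, dtype=float)
    if len(x) != len(y):
        raise ValueError("ages and vafs must align")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        return None, None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cohort_report(
    donor_variants: Sequence[DonorVariant],
    metadata: pd.DataFrame,
    annotations: Mapping[VariantKey, ConsequenceAnnotation] | None = None,
    n_comparisons: int = DEFAULT_N_COMPARISONS,
) -> pd.DataFrame:
    """Carrier comparison table over all four criteria."""
    criteria = list(CRITERIA) if annotations is not None else [
        CRITERION_ANY,
        CRITERION_GE2,
    ]
    rows = []
    for crit in criteria:
        tab = compare_groups(
            carrier_table(donor_variants, metadata, crit, annotations), n_comparisons
        )
        rows.append(
            {
                "criterion": tab.label,
                "case_carriers": tab.a,
                "case_total": tab.a + tab.b,
                "control_carriers": tab.c,
                "control_total": tab.c + tab.d,
                "p_raw": tab.p_raw,
                "p_corr": tab.p_corr,
            }
        )
    return pd.DataFrame(rows)
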