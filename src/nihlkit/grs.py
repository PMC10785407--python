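"""Unweighted genetic risk score (GRS) and dose-response estimation.

Per SNP, the risk allele is the allele associated with higher disease odds
(allele-model OR > 1) in the replication cohort.  Each subject's genotype is
coded by its risk-allele count — 0 (homozygous non-risk), 1 (heterozygous),
2 (homozygous risk) — and the GRS is the plain sum of those codes across the
validated SNPs, so with K SNPs the score ranges over 0..2K.

Subjects in ordered GRS bins are compared against the lowest bin by the
2x2 cross-product OR; dose-response is assessed by the Cochran-Armitage
trend test (the one-df chi-square for a linear trend in proportions across
ordered case-control bins).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationResult, GeneticModel, OddsRatio, odds_ratio_woolf
from .cohort import CASE, CONTROL, CohortTable, ContingencyTable2x2

log = logging.getLogger(__name__)

WILD = "wild"
VARIANT = "variant"


def assign_risk_allele(results: Iterable[AssociationResult]) -> str:
    """Pick the risk allele for one SNP from its allele-model crude OR.

    The allele-model table is oriented with exposed = variant allele, so
    OR > 1 names the variant allele as the risk allele and OR < 1 the wild
    allele; an OR of exactly 1 breaks toward the variant allele with a
    warning.  Raises if no allele-model (or additive) result is present.
    """
    by_model = {GeneticModel(r.model): r for r in results}
    r = by_model.get(GeneticModel.ALLELE) or by_model.get(GeneticModel.ADDITIVE)
    if r is None:
        raise ValueError("no allele-model result available for risk-allele assignment")
    or_ = r.or_crude.value if r.or_crude is not None else r.or_adjusted.value
    if or_ == 1.0:
        log.warning("allele-model OR exactly 1 for %s; risk allele set to variant", r.snp_id)
        return VARIANT
    return VARIANT if or_ > 1.0 else WILD


def genotype_risk_code(call: str, risk_allele: str) -> int:
    """Risk-allele count of one genotype call (0, 1 or 2)."""
    call = getattr(call, "value", call)
    if call not in ("AA", "AB", "BB"):
        raise ValueError(f"cannot code missing/invalid call {call!r}")
    dose = {"AA": 0, "AB": 1, "BB": 2}[call]  # variant-allele count
    if risk_allele == VARIANT:
        return dose
    if risk_allele == WILD:
        return 2 - dose
    raise ValueError(f"risk allele must be 'wild' or 'variant', got {risk_allele!r}")


def compute_grs(
    cohort: CohortTable,
    scored_snps: Sequence[str],
    risk_alleles: Mapping[str, str],
    policy: str = "complete",
) -> pd.DataFrame:
    """Per-subject GRS profiles.

    Returns a DataFrame indexed by subject_id with one ``code_<snp>`` column
    per scored SNP, the summed ``grs``, and ``n_missing``.  With the default
    complete-score policy, subjects missing any scored SNP are excluded;
    ``policy="prorate"`` instead rescales the partial sum to the full SNP
    count (flagged in the ``prorated`` column).
    """
    if not scored_snps:
        raise ValueError("scored_snps is empty")
    if policy not in ("complete", "prorate"):
        raise ValueError("policy must be 'complete' or 'prorate'")
    missing_assignment = [s for s in scored_snps if s not in risk_alleles]
    if missing_assignment:
        raise ValueError(f"no risk-allele assignment for {missing_assignment}")

    dose = cohort.dosage_matrix()[list(scored_snps)]
    codes = dose.copy()
    for snp in scored_snps:
        if risk_alleles[snp] == WILD:
            codes[snp] = 2.0 - codes[snp]
        elif risk_alleles[snp] != VARIANT:
            raise ValueError(f"invalid risk allele {risk_alleles[snp]!r} for {snp}")
    n_missing = codes.isna().sum(axis=1)
    out = codes.rename(columns={s: f"code_{s}" for s in scored_snps})
    out["n_missing"] = n_missing.astype(int)
    if policy == "complete":
        out = out[n_missing == 0].copy()
        out["grs"] = codes.loc[out.index].sum(axis=1).astype(int)
        out["prorated"] = False
    else:
        k = len(scored_snps)
        avail = k - n_missing
        out = out[avail > 0].copy()
        partial = codes.loc[out.index].sum(axis=1, skipna=True)
        out["grs"] = (partial * k / avail.loc[out.index]).round().astype(int)
        out["prorated"] = out["n_missing"] > 0
    return out


# --------------------------------------------------------------------------
# binning and dose-response
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GrsBin:
    label: str
    lo: float  # inclusive
    hi: float  # inclusive

    def contains(self, value) -> np.ndarray:
        v = np.asarray(value)
        return (v >= self.lo) & (v <= self.hi)


def default_grs_bins() -> list[GrsBin]:
    """The study's binning: <=5, 6, 7, 8, 9, >=10."""
    return [
        GrsBin("<=5", -math.inf, 5),
        GrsBin("6", 6, 6),
        GrsBin("7", 7, 7),
        GrsBin("8", 8, 8),
        GrsBin("9", 9, 9),
        GrsBin(">=10", 10, math.inf),
    ]


@dataclasses.dataclass
class GrsRiskTable:
    bins: pd.DataFrame            # label, n_cases, n_controls, or, ci_low, ci_high, p
    reference_label: str
    trend_chi2: float
    trend_p: float


def risk_table_from_counts(
    labels: Sequence[str],
    case_counts: Sequence[int],
    control_counts: Sequence[int],
    reference_label: str,
) -> GrsRiskTable:
    """Per-bin ORs against the reference bin, from ordered bin counts.

    The reference row carries OR 1.000 by construction; every other bin is a
    2x2 comparison of that bin against the reference.  The Cochran-Armitage
    trend statistic uses ordinal scores 0..k-1.
    """
    labels = list(labels)
    cases = np.asarray(case_counts, dtype=int)
    controls = np.asarray(control_counts, dtype=int)
    if reference_label not in labels:
        raise ValueError(f"reference bin {reference_label!r} not among labels")
    ref = labels.index(reference_label)
    if cases[ref] + controls[ref] == 0:
        raise ValueError("empty reference bin")
    rows = []
    for i, label in enumerate(labels):
        if i == ref:
            rows.append((label, int(cases[i]), int(controls[i]),
                         1.0, np.nan, np.nan, np.nan))
            continue
        table = ContingencyTable2x2(int(cases[i]), int(controls[i]),
                                    int(cases[ref]), int(controls[ref]))
        orr = odds_ratio_woolf(table)
        rows.append((label, int(cases[i]), int(controls[i]),
                     orr.value, orr.ci_low, orr.ci_high, orr.p))
    bins = pd.DataFrame(rows, columns=["label", "n_cases", "n_controls",
                                       "or", "ci_low", "ci_high", "p"])
    chi2, p = grs_trend_test(cases, controls)
    return GrsRiskTable(bins=bins, reference_label=reference_label,
                        trend_chi2=chi2, trend_p=p)


def grs_risk_table(
    profiles: pd.DataFrame,
    status: pd.Series,
    bins: Sequence[GrsBin] | None = None,
    reference: str = "<=5",
) -> GrsRiskTable:
    """Tally GRS profiles into ordered bins and estimate per-bin ORs.

    ``status`` is the subject status series (indexed like ``profiles``);
    subjects outside case/control are ignored.  Every GRS value must fall in
    exactly one bin.
    """
    bins = list(bins) if bins is not None else default_grs_bins()
    st = status.loc[profiles.index]
    keep = st.isin([CASE, CONTROL])
    grs = profiles.loc[keep, "grs"].to_numpy()
    is_case = (st[keep] == CASE).to_numpy()

    membership = np.stack([b.contains(grs) for b in bins])
    per_subject = membership.sum(axis=0)
    if (per_subject != 1).any():
        bad = sorted(set(grs[per_subject != 1].tolist()))
        raise ValueError(f"GRS values not covered by exactly one bin: {bad}")
    cases = [int((m & is_case).sum()) for m in membership]
    controls = [int((m & ~is_case).sum()) for m in membership]
    return risk_table_from_counts([b.label for b in bins], cases, controls, reference)


def grs_dichotomy(profiles: pd.DataFrame, status: pd.Series, cutoff: int = 6) -> OddsRatio:
    """OR for GRS >= cutoff vs GRS < cutoff (high vs low genetic risk)."""
    st = status.loc[profiles.index]
    keep = st.isin([CASE, CONTROL])
    grs = profiles.loc[keep, "grs"].to_numpy()
    is_case = (st[keep] == CASE).to_numpy()
    high = grs >= cutoff
    if not high.any() or high.all():
        raise ValueError(f"degenerate dichotomy at cutoff {cutoff}: one group is empty")
    table = ContingencyTable2x2(
        int((high & is_case).sum()), int((high & ~is_case).sum()),
        int((~high & is_case).sum()), int((~high & ~is_case).sum()),
    )
    return odds_ratio_woolf(table)


def grs_trend_test(
    case_counts: Sequence[int],
    control_counts: Sequence[int],
    scores: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Cochran-Armitage trend test across ordered case-control bins.

    Scores default to ordinals 0..k-1 (open-ended bins included as
    ordinals).  The statistic is the exact permutation-variance z squared:
    T = sum of scores over cases; under random allocation of the R cases
    among all N subjects, E[T] = R*mean(s) and Var[T] = R(N-R)/(N-1) * var(s)
    with var(s) the population variance of the subject-level scores.
    Returns (chi2 on 1 df, p).
    """
    r = np.asarray(case_counts, dtype=float)
    m = np.asarray(control_counts, dtype=float)
    if len(r) < 3:
        raise ValueError("trend test needs at least 3 ordered bins")
    n = r + m
    s = np.asarray(scores, dtype=float) if scores is not None else np.arange(len(r), dtype=float)
    if len(s) != len(r):
        raise ValueError("scores length mismatch")
    N = n.sum()
    R = r.sum()
    if N == 0 or R == 0 or R == N:
        return 0.0, 1.0
    sbar = (n * s).sum() / N
    svar = (n * (s - sbar) ** 2).sum() / N
    if svar == 0:
        return 0.0, 1.0
    T = (r * s).sum()
    var_T = R * (N - R) / (N - 1) * svar
    chi2 = (T - R * sbar) ** 2 / var_T
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
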