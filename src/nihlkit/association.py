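"""SNP-level QC and five-genetic-model case-control association analysis.

A biallelic genotype can be dichotomized in several ways, each an alternative
hypothesis about how the variant allele acts:

* recessive      — BB vs (AA, AB)
* dominant       — (AB, BB) vs AA
* super_dominant — AB vs (AA, BB) (overdominance)
* homozygote     — BB vs AA, heterozygotes excluded
* additive       — variant-allele dosage 0/1/2 (regression coding)
* allele         — per-allele counting: each subject contributes two alleles

The fixed orientation here is exposed = the variant-containing grouping; the
reciprocal OR is a label swap (``ContingencyTable2x2.swapped``).

Crude effects come from the 2x2 cross-product OR with Woolf (log-scale Wald)
confidence limits; adjusted effects from an in-package Newton-Raphson (IRLS)
logistic regression, whose unadjusted single-predictor fit reproduces the
cross-product OR exactly (a closed-form identity used as a test oracle).
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CASE, CONTROL, CohortTable, ContingencyTable2x2

log = logging.getLogger(__name__)

Z975 = float(stats.norm.ppf(0.975))

DEFAULT_ADJUST = ("age", "years_exposure", "smoking", "drinking")


class GeneticModel(str, enum.Enum):
    RECESSIVE = "recessive"
    DOMINANT = "dominant"
    SUPER_DOMINANT = "super_dominant"
    HOMOZYGOTE = "homozygote"
    ADDITIVE = "additive"
    ALLELE = "allele"


#: the five models reported per SNP in this analysis
DEFAULT_MODELS = (
    GeneticModel.RECESSIVE,
    GeneticModel.DOMINANT,
    GeneticModel.SUPER_DOMINANT,
    GeneticModel.HOMOZYGOTE,
    GeneticModel.ALLELE,
)

EXPOSED = "exposed"
UNEXPOSED = "unexposed"
EXCLUDED = "excluded"


def encode_genetic_model(call: str, model: GeneticModel):
    """Map one genotype call to exposed/unexposed/excluded under a model.

    For the additive model the variant-allele count 0/1/2 is returned
    instead of a binary state; the allele model is handled at allele level
    by :func:`contingency_2x2`, where an AB subject contributes one variant
    and one wild allele.  Missing calls must be filtered by the caller.
    """
    call = getattr(call, "value", call)
    if call not in ("AA", "AB", "BB"):
        raise ValueError(f"cannot encode missing/invalid call {call!r}")
    dose = {"AA": 0, "AB": 1, "BB": 2}[call]
    model = GeneticModel(model)
    if model is GeneticModel.ADDITIVE:
        return dose
    if model is GeneticModel.RECESSIVE:
        return EXPOSED if dose == 2 else UNEXPOSED
    if model is GeneticModel.DOMINANT:
        return EXPOSED if dose >= 1 else UNEXPOSED
    if model is GeneticModel.SUPER_DOMINANT:
        return EXPOSED if dose == 1 else UNEXPOSED
    if model is GeneticModel.HOMOZYGOTE:
        if dose == 1:
            return EXCLUDED
        return EXPOSED if dose == 2 else UNEXPOSED
    if model is GeneticModel.ALLELE:
        # per-allele counting happens in contingency_2x2; per-call the
        # variant-allele count is the natural encoding
        return dose
    raise ValueError(f"unknown model {model}")


# --------------------------------------------------------------------------
# QC
# --------------------------------------------------------------------------

def _cohort_arrays(cohort: CohortTable) -> dict:
    """Per-cohort numpy views cached on the cohort object.

    The cache holds the variant-dosage matrix (NaN = missing), case/control
    masks and numeric covariate columns, so per-SNP-per-model loops avoid
    repeated pandas dispatch.  The cache assumes the cohort is not mutated
    after first use (CohortTable is treated as immutable by the analyses).
    """
    cache = cohort.__dict__.get("_assoc_cache")
    if cache is not None:
        return cache
    dose = cohort.dosage_matrix()
    status = cohort.subjects["status"]
    cache = {
        "snp_pos": {s: j for j, s in enumerate(dose.columns)},
        "dose": dose.to_numpy(dtype=float),
        "is_case": (status == CASE).to_numpy(),
        "is_control": (status == CONTROL).to_numpy(),
        "covariates": {},
    }
    cohort.__dict__["_assoc_cache"] = cache
    return cache


def _covariate_array(cohort: CohortTable, name: str) -> np.ndarray:
    cache = _cohort_arrays(cohort)
    if name not in cache["covariates"]:
        cache["covariates"][name] = pd.to_numeric(
            cohort.subjects[name], errors="coerce").to_numpy(dtype=float)
    return cache["covariates"][name]


def call_rate(cohort: CohortTable, snp_id: str) -> float:
    """Fraction of subjects with a non-missing call for one SNP."""
    if snp_id not in cohort.genotypes.columns:
        raise KeyError(f"unknown SNP {snp_id!r}")
    cache = _cohort_arrays(cohort)
    col = cache["dose"][:, cache["snp_pos"][snp_id]]
    return float(np.isfinite(col).mean())


@dataclasses.dataclass(frozen=True)
class HweResult:
    chi2: float
    p: float
    monomorphic: bool = False


def hwe_test(n_AA: int, n_AB: int, n_BB: int) -> HweResult:
    """Pearson chi-square (1 df) test of Hardy-Weinberg proportions.

    Expected counts come from the estimated allele frequency; a monomorphic
    SNP returns chi2=0, p=1 with a flag.
    """
    n = n_AA + n_AB + n_BB
    if n <= 0:
        raise ValueError("no genotype counts")
    p_wild = (2 * n_AA + n_AB) / (2 * n)
    q = 1.0 - p_wild
    if p_wild == 0.0 or q == 0.0:
        return HweResult(0.0, 1.0, monomorphic=True)
    expected = np.array([p_wild**2, 2 * p_wild * q, q**2]) * n
    observed = np.array([n_AA, n_AB, n_BB], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(chi2, float(stats.chi2.sf(chi2, df=1)))


def genotype_counts(cohort: CohortTable, snp_id: str, status: str | None = None) -> tuple[int, int, int]:
    """(n_AA, n_AB, n_BB) for one SNP, optionally restricted to one status."""
    cache = _cohort_arrays(cohort)
    col = cache["dose"][:, cache["snp_pos"][snp_id]]
    if status is not None:
        mask = {CASE: cache["is_case"], CONTROL: cache["is_control"]}.get(status)
        if mask is None:
            mask = (cohort.subjects["status"] == status).to_numpy()
        col = col[mask]
    col = col[np.isfinite(col)]
    return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())


@dataclasses.dataclass
class QcReport:
    kept: list[str]
    excluded: list[str]
    metrics: pd.DataFrame  # per SNP: call_rate, hwe_chi2_controls, hwe_p_controls, reasons

    def reason(self, snp_id: str) -> str:
        return self.metrics.loc[snp_id, "reasons"]


def qc_filter(
    cohort: CohortTable,
    call_rate_min: float = 0.90,
    hwe_alpha: float = 0.01,
    combine: str = "or",
) -> QcReport:
    """Exclude SNPs failing call-rate or control-group HWE QC.

    HWE is tested in controls only.  With ``combine="or"`` (default) a SNP is
    excluded if it fails *either* filter — the standard QC practice; with
    ``combine="and"`` only if it fails both.  The report records both flags
    per SNP.
    """
    if cohort.n_controls == 0:
        raise ValueError("cohort has no controls; HWE QC undefined")
    if combine not in ("or", "and"):
        raise ValueError("combine must be 'or' or 'and'")
    rows = []
    for snp in cohort.snp_ids:
        cr = call_rate(cohort, snp)
        hwe = hwe_test(*genotype_counts(cohort, snp, status=CONTROL))
        fail_cr = cr < call_rate_min
        fail_hwe = hwe.p < hwe_alpha
        fail = (fail_cr or fail_hwe) if combine == "or" else (fail_cr and fail_hwe)
        reasons = ",".join(r for r, f in (("call_rate", fail_cr), ("hwe", fail_hwe)) if f)
        rows.append((snp, cr, hwe.chi2, hwe.p, fail_cr, fail_hwe, fail, reasons))
    metrics = pd.DataFrame(
        rows,
        columns=["snp_id", "call_rate", "hwe_chi2_controls", "hwe_p_controls",
                 "fail_call_rate", "fail_hwe", "excluded", "reasons"],
    ).set_index("snp_id")
    kept = list(metrics.index[~metrics["excluded"]])
    excluded = list(metrics.index[metrics["excluded"]])
    for snp in excluded:
        log.info("QC excluded %s (%s)", snp, metrics.loc[snp, "reasons"])
    return QcReport(kept=kept, excluded=excluded, metrics=metrics)


# --------------------------------------------------------------------------
# 2x2 machinery
# --------------------------------------------------------------------------

def contingency_2x2(cohort: CohortTable, snp_id: str, model: GeneticModel) -> ContingencyTable2x2:
    """Case/control x exposed/unexposed counts for one SNP under one model.

    Missing calls and model-excluded subjects (AB under the homozygote
    model) are dropped; the allele model counts two alleles per subject.
    """
    model = GeneticModel(model)
    cache = _cohort_arrays(cohort)
    col = cache["dose"][:, cache["snp_pos"][snp_id]]
    keep = np.isfinite(col) & (cache["is_case"] | cache["is_control"])
    dose = col[keep].astype(int)
    is_case = cache["is_case"][keep]

    if model is GeneticModel.ALLELE:
        a = int(dose[is_case].sum())             # variant alleles in cases
        b = int(dose[~is_case].sum())            # variant alleles in controls
        c = int(2 * is_case.sum() - a)           # wild alleles in cases
        d = int(2 * (~is_case).sum() - b)
        return ContingencyTable2x2(a, b, c, d)
    if model is GeneticModel.ADDITIVE:
        raise ValueError("additive model is a regression coding; no 2x2 table")
    if model is GeneticModel.RECESSIVE:
        exposed = dose == 2
    elif model is GeneticModel.DOMINANT:
        exposed = dose >= 1
    elif model is GeneticModel.SUPER_DOMINANT:
        exposed = dose == 1
    elif model is GeneticModel.HOMOZYGOTE:
        keep2 = dose != 1
        dose, is_case = dose[keep2], is_case[keep2]
        exposed = dose == 2
    else:  # pragma: no cover
        raise ValueError(model)
    a = int((exposed & is_case).sum())
    b = int((exposed & ~is_case).sum())
    c = int((~exposed & is_case).sum())
    d = int((~exposed & ~is_case).sum())
    return ContingencyTable2x2(a, b, c, d)


@dataclasses.dataclass(frozen=True)
class OddsRatio:
    value: float
    ci_low: float
    ci_high: float
    p: float
    continuity_corrected: bool = False


def odds_ratio_woolf(table: ContingencyTable2x2, cc: float = 0.5) -> OddsRatio:
    """Cross-product OR with Woolf 95% CI and Wald p-value.

    OR = ad/bc; CI = exp(ln OR +- z * sqrt(1/a+1/b+1/c+1/d)).  If any cell is
    zero, the Haldane-Anscombe correction adds ``cc`` to all four cells and
    the result is flagged.
    """
    if table.n_cases == 0:
        raise ValueError("no cases in table; OR undefined")
    if table.n_controls == 0:
        raise ValueError("no controls in table; OR undefined")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    corrected = False
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + cc, b + cc, c + cc, d + cc
        corrected = True
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ln_or = math.log(or_)
    z = ln_or / se
    return OddsRatio(
        value=or_,
        ci_low=math.exp(ln_or - Z975 * se),
        ci_high=math.exp(ln_or + Z975 * se),
        p=float(2 * stats.norm.sf(abs(z))),
        continuity_corrected=corrected,
    )


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square (1 df) for a 2x2 table; Yates correction optional.

    Warns (via logging) when any expected cell count is below 1.
    """
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if obs.sum() == 0:
        raise ValueError("empty table")
    expected = stats.contingency.expected_freq(obs)
    if (expected < 1).any():
        log.warning("chi-square 2x2: expected cell count < 1")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=yates)
    return float(chi2), float(p)


# --------------------------------------------------------------------------
# logistic regression (Newton-Raphson / IRLS)
# --------------------------------------------------------------------------

@dataclasses.dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    separated: bool
    n_iter: int
    llf: float
    n_obs: int

    def odds_ratios(self) -> pd.DataFrame:
        """exp(coef) with 95% Wald CI per term (exponent capped at +-700)."""
        clip = lambda x: np.exp(np.clip(x, -700, 700))
        or_ = clip(self.params)
        lo = clip(self.params - Z975 * self.bse)
        hi = clip(self.params + Z975 * self.bse)
        return pd.DataFrame({"or": or_, "ci_low": lo, "ci_high": hi, "p": self.pvalues})

    def term_odds_ratio(self, term: str) -> OddsRatio:
        b, s, p = float(self.params[term]), float(self.bse[term]), float(self.pvalues[term])
        e = lambda x: float(np.exp(np.clip(x, -700, 700)))
        return OddsRatio(e(b), e(b - Z975 * s), e(b + Z975 * s), p)


def fit_logistic(
    outcome: np.ndarray | pd.Series,
    design: pd.DataFrame,
    add_constant: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via Newton-Raphson.

    Convergence is declared when the log-likelihood change falls below
    ``tol``.  Perfect separation (a coefficient diverging beyond |15| while
    steps keep growing) yields a flagged non-converged result rather than an
    exception.  A rank-deficient design raises.
    """
    y = np.asarray(outcome, dtype=float)
    X = design.astype(float)
    if add_constant and "const" not in X.columns:
        X = X.copy()
        X.insert(0, "const", 1.0)
    names = list(X.columns)
    return _newton_logistic(y, X.to_numpy(), names, max_iter=max_iter, tol=tol)


def _newton_logistic(
    y: np.ndarray,
    Xm: np.ndarray,
    names: Sequence[str],
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    n, k = Xm.shape
    if n <= k:
        raise ValueError(f"n={n} observations for k={k} parameters")
    if np.linalg.matrix_rank(Xm) < k:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(k)
    ll_old = -np.inf
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(Xm @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        w = mu * (1.0 - mu)
        grad = Xm.T @ (y - mu)
        H = (Xm * w[:, None]).T @ Xm
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        # step-halving if the likelihood would decrease
        new_beta = beta + step
        for _ in range(20):
            eta_n = np.clip(Xm @ new_beta, -30, 30)
            ll_new = float(np.sum(y * eta_n - np.log1p(np.exp(eta_n))))
            if ll_new >= ll - 1e-12:
                break
            new_beta = (beta + new_beta) / 2.0
        beta = new_beta
        if np.any(np.abs(beta) > 15) and np.linalg.norm(step) > 1e-3:
            separated = True
            break
        if abs(ll_new - ll_old) <= tol:
            converged = True
            ll = ll_new
            break
        ll_old = ll_new
        ll = ll_new

    eta = np.clip(Xm @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = (Xm * w[:, None]).T @ Xm
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    if separated:
        converged = False
        log.warning("fit_logistic: possible perfect separation; estimates unreliable")
    return LogisticFit(
        params=pd.Series(beta, index=list(names)),
        bse=pd.Series(se, index=list(names)),
        pvalues=pd.Series(pvals, index=list(names)),
        converged=converged,
        separated=separated,
        n_iter=it,
        llf=float(np.sum(y * eta - np.log1p(np.exp(eta)))),
        n_obs=n,
    )


def adjust_pvalues(pvalues: Sequence[float], method: str = "none") -> np.ndarray:
    """Optional multiple-testing correction: none, bonferroni, or bh."""
    p = np.asarray(pvalues, dtype=float)
    if method == "none":
        return p
    m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# per-SNP association and the two-stage screen
# --------------------------------------------------------------------------

TIER_SIGNIFICANT = "significant"
TIER_MARGINAL = "marginal"
TIER_NULL = "null"


def _tier(p: float, alpha: float = 0.05, alpha_marginal: float = 0.10) -> str:
    if p < alpha:
        return TIER_SIGNIFICANT
    if p < alpha_marginal:
        return TIER_MARGINAL
    return TIER_NULL


@dataclasses.dataclass
class AssociationResult:
    snp_id: str
    model: GeneticModel
    table: ContingencyTable2x2 | None
    or_crude: OddsRatio | None
    or_adjusted: OddsRatio | None
    n_used: int
    hwe_p_controls: float
    call_rate: float
    tier: str
    adjusted_fit_converged: bool = True

    @property
    def p_crude(self) -> float:
        return self.or_crude.p if self.or_crude else float("nan")

    @property
    def p_adjusted(self) -> float:
        return self.or_adjusted.p if self.or_adjusted else float("nan")


def _exposure_column(dose: np.ndarray, model: GeneticModel) -> tuple[np.ndarray, np.ndarray]:
    """(exposure values, keep mask) for subject-level regression.

    The allele model is adjusted at subject level via additive dosage — the
    only coherent way to put covariates on an allele-level comparison.
    """
    model = GeneticModel(model)
    keep = np.ones(len(dose), dtype=bool)
    if model in (GeneticModel.ADDITIVE, GeneticModel.ALLELE):
        return dose.astype(float), keep
    if model is GeneticModel.RECESSIVE:
        return (dose == 2).astype(float), keep
    if model is GeneticModel.DOMINANT:
        return (dose >= 1).astype(float), keep
    if model is GeneticModel.SUPER_DOMINANT:
        return (dose == 1).astype(float), keep
    if model is GeneticModel.HOMOZYGOTE:
        keep = dose != 1
        return (dose == 2).astype(float), keep
    raise ValueError(model)


def snp_association(
    cohort: CohortTable,
    snp_id: str,
    model: GeneticModel,
    adjust_for: Sequence[str] = DEFAULT_ADJUST,
    tier_from: str = "crude",
) -> AssociationResult:
    """Crude (2x2) and covariate-adjusted estimates for one SNP and model.

    Missing genotypes are dropped per SNP; subjects missing an adjustment
    covariate are dropped only from the adjusted fit.  ``tier_from`` selects
    whether the significance tier follows the crude or adjusted p-value.
    """
    model = GeneticModel(model)
    cr = call_rate(cohort, snp_id)
    hwe = hwe_test(*genotype_counts(cohort, snp_id, status=CONTROL))

    if model is GeneticModel.ADDITIVE:
        table = None
        or_crude = None
    else:
        table = contingency_2x2(cohort, snp_id, model)
        or_crude = odds_ratio_woolf(table)

    # subject-level design for the adjusted fit (numpy fast path)
    cache = _cohort_arrays(cohort)
    col = cache["dose"][:, cache["snp_pos"][snp_id]]
    base_keep = np.isfinite(col) & (cache["is_case"] | cache["is_control"])
    dose = col[base_keep].astype(int)
    exposure, keep2 = _exposure_column(dose, model)
    y = cache["is_case"][base_keep][keep2].astype(float)
    columns = [np.ones(keep2.sum()), exposure[keep2]]
    names = ["const", "exposure"]
    for cov in adjust_for:
        columns.append(_covariate_array(cohort, cov)[base_keep][keep2])
        names.append(cov)
    Xm = np.column_stack(columns)
    complete = np.isfinite(Xm).all(axis=1)
    or_adj = None
    converged = True
    if complete.sum() > Xm.shape[1] + 1:
        try:
            fit = _newton_logistic(y[complete], Xm[complete], names)
            converged = fit.converged
            or_adj = fit.term_odds_ratio("exposure")
        except ValueError:
            converged = False

    if model is GeneticModel.ADDITIVE:
        n_used = int(complete.sum())
        p_for_tier = or_adj.p if or_adj else float("nan")
    else:
        n_used = table.n if model is not GeneticModel.ALLELE else table.n // 2
        p_for_tier = {"crude": or_crude.p,
                      "adjusted": (or_adj.p if or_adj else float("nan"))}[tier_from]
    tier = _tier(p_for_tier) if math.isfinite(p_for_tier) else TIER_NULL
    return AssociationResult(
        snp_id=snp_id, model=model, table=table, or_crude=or_crude,
        or_adjusted=or_adj, n_used=n_used, hwe_p_controls=hwe.p,
        call_rate=cr, tier=tier, adjusted_fit_converged=converged,
    )


def association_table(
    cohort: CohortTable,
    snp_ids: Sequence[str],
    models: Sequence[GeneticModel] = DEFAULT_MODELS,
    adjust_for: Sequence[str] = DEFAULT_ADJUST,
) -> pd.DataFrame:
    """Long-format per-SNP, per-model report (one row per SNP x model)."""
    rows = []
    for snp in snp_ids:
        for model in models:
            r = snp_association(cohort, snp, model, adjust_for)
            rows.append({
                "snp_id": snp,
                "gene": cohort.panel.loc[snp, "gene"],
                "model": GeneticModel(model).value,
                "a": r.table.a if r.table else np.nan,
                "b": r.table.b if r.table else np.nan,
                "c": r.table.c if r.table else np.nan,
                "d": r.table.d if r.table else np.nan,
                "n_used": r.n_used,
                "or_crude": r.or_crude.value if r.or_crude else np.nan,
                "ci_low_crude": r.or_crude.ci_low if r.or_crude else np.nan,
                "ci_high_crude": r.or_crude.ci_high if r.or_crude else np.nan,
                "p_crude": r.p_crude,
                "or_adjusted": r.or_adjusted.value if r.or_adjusted else np.nan,
                "ci_low_adjusted": r.or_adjusted.ci_low if r.or_adjusted else np.nan,
                "ci_high_adjusted": r.or_adjusted.ci_high if r.or_adjusted else np.nan,
                "p_adjusted": r.p_adjusted,
                "call_rate": r.call_rate,
                "hwe_p_controls": r.hwe_p_controls,
                "tier": r.tier,
            })
    return pd.DataFrame(rows)


@dataclasses.dataclass
class ScreenResult:
    stage1: dict[str, list[AssociationResult]]
    stage2: dict[str, list[AssociationResult]]
    candidates: list[str]          # SNPs passing stage 1
    validated: list[str]           # SNPs passing both stages
    selection_models: dict[str, list[GeneticModel]]  # models driving stage-2 selection


def two_stage_screen(
    screening: CohortTable,
    replication: CohortTable,
    models: Sequence[GeneticModel] = DEFAULT_MODELS,
    alpha: float = 0.05,
    alpha_marginal: float = 0.10,
    adjust_for: Sequence[str] = DEFAULT_ADJUST,
    snp_ids: Sequence[str] | None = None,
) -> ScreenResult:
    """Screen-then-replicate SNP selection.

    Stage 1 keeps SNPs whose adjusted p is below ``alpha_marginal``
    (significant or marginal) under at least one model; stage 2 keeps, from
    those, SNPs with adjusted p < ``alpha`` under at least one model in the
    independent replication cohort.
    """
    if list(screening.panel.index) != list(replication.panel.index):
        raise ValueError("screening and replication cohorts use different panels")
    snps = list(snp_ids) if snp_ids is not None else screening.snp_ids

    stage1: dict[str, list[AssociationResult]] = {}
    candidates = []
    for snp in snps:
        results = [snp_association(screening, snp, m, adjust_for, tier_from="adjusted")
                   for m in models]
        stage1[snp] = results
        ps = [r.p_adjusted for r in results if math.isfinite(r.p_adjusted)]
        if ps and min(ps) < alpha_marginal:
            candidates.append(snp)
    if not candidates:
        log.warning("two_stage_screen: no SNP passed stage 1")

    stage2: dict[str, list[AssociationResult]] = {}
    validated = []
    selection_models: dict[str, list[GeneticModel]] = {}
    for snp in candidates:
        results = [snp_association(replication, snp, m, adjust_for, tier_from="adjusted")
                   for m in models]
        stage2[snp] = results
        winning = [r.model for r in results
                   if math.isfinite(r.p_adjusted) and r.p_adjusted < alpha]
        if winning:
            validated.append(snp)
            selection_models[snp] = winning
    return ScreenResult(stage1=stage1, stage2=stage2, candidates=candidates,
                        validated=validated, selection_models=selection_models)
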