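"""Synthetic two-stage case-control cohorts for occupational NIHL analyses.

The generator draws a worker population with:

* per-SNP genotypes at configurable minor-allele frequencies, at
  Hardy-Weinberg equilibrium unless an inbreeding-style departure ``f`` is
  requested: P(BB) = q^2 + f q(1-q), P(AB) = 2q(1-q)(1-f),
  P(AA) = p^2 + f p(1-p) with q the variant-allele frequency;
* environmental covariates with the screening-stage moments of the study
  population this package models: age ~ N(48.32, 5.69) years, years of noise
  exposure ~ N(12.24, 5.75) truncated above 3 years, SPL ~ N(85.79, 5.13)
  dB(A) — calibrated so the derived CNE distribution has mean 96.51 and
  SD 5.49 dB(A)·years — plus Bernoulli PPE use, smoking and drinking;
* case status from a logistic disease model over per-SNP genetic-model
  codings, optional gene-gene / gene-environment interaction products, and a
  free intercept;
* case-control accrual by rejection sampling from the population model
  until the requested numbers of cases and controls accrue (odds ratios are
  invariant under this outcome-dependent sampling, so crude ORs converge to
  the specified effect sizes);
* per-SNP genotype masking to missing at 1 - call_rate.

All randomness flows from one integer seed through named substreams, so a
full two-stage study is byte-reproducible from a single number.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .association import GeneticModel
from .cohort import CASE, CONTROL, CohortTable, GENOTYPES, compute_cne

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# effect specification
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Interaction:
    """One multiplicative interaction partner of a SNP effect.

    ``partner`` is either another SNP id (then ``partner_model`` gives its
    indicator coding) or a numeric covariate name (then the indicator is
    value >= ``threshold``); for a boolean covariate the indicator is the
    value itself.
    """

    partner: str
    ln_or: float
    partner_model: GeneticModel | None = None
    threshold: float | None = None


@dataclasses.dataclass(frozen=True)
class EffectSpec:
    snp_id: str
    model: GeneticModel
    ln_or: float
    interactions: tuple[Interaction, ...] = ()


@dataclasses.dataclass(frozen=True)
class CovariateModel:
    """Marginal distributions of the environmental covariates."""

    age_mean: float = 48.32
    age_sd: float = 5.69
    exposure_mean: float = 12.24
    exposure_sd: float = 5.75
    exposure_min: float = 3.0
    spl_mean: float = 85.79   # calibrated: E[CNE] = 96.51 dB(A)·years
    spl_sd: float = 5.13      # calibrated: SD[CNE] = 5.49
    ppe_p: float = 0.70
    smoking_p: float = 0.45
    drinking_p: float = 0.40


@dataclasses.dataclass
class SimulationConfig:
    """Everything needed to draw one case-control cohort."""

    n_cases: int
    n_controls: int
    panel: pd.DataFrame  # index snp_id; columns gene, wild_allele, variant_allele, maf [, hwe_f, call_rate]
    covariates: CovariateModel = dataclasses.field(default_factory=CovariateModel)
    intercept: float = -1.0
    effects: tuple[EffectSpec, ...] = ()
    seed: int = 0
    stage_label: str = ""
    max_draw_factor: int = 2000  # draw budget = factor * (n_cases + n_controls)
    with_audiometry: bool = False

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        for col, default in (("hwe_f", 0.0), ("call_rate", 1.0)):
            if col not in self.panel.columns:
                self.panel = self.panel.copy()
                self.panel[col] = default
        if "maf" not in self.panel.columns:
            raise ValueError("panel must carry a 'maf' column")
        bad = [s for s in self.effects if s.snp_id not in self.panel.index]
        if bad:
            raise ValueError(f"effects reference SNPs not in panel: {[s.snp_id for s in bad]}")

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "panel": self.panel.reset_index().to_dict(orient="list"),
            "covariates": dataclasses.asdict(self.covariates),
            "intercept": self.intercept,
            "effects": [
                {
                    "snp_id": e.snp_id,
                    "model": GeneticModel(e.model).value,
                    "ln_or": e.ln_or,
                    "interactions": [
                        {"partner": i.partner, "ln_or": i.ln_or,
                         "partner_model": (GeneticModel(i.partner_model).value
                                           if i.partner_model else None),
                         "threshold": i.threshold}
                        for i in e.interactions
                    ],
                }
                for e in self.effects
            ],
            "seed": self.seed,
            "stage_label": self.stage_label,
            "max_draw_factor": self.max_draw_factor,
            "with_audiometry": self.with_audiometry,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        panel = pd.DataFrame(d["panel"]).set_index("snp_id")
        effects = tuple(
            EffectSpec(
                snp_id=e["snp_id"],
                model=GeneticModel(e["model"]),
                ln_or=float(e["ln_or"]),
                interactions=tuple(
                    Interaction(
                        partner=i["partner"], ln_or=float(i["ln_or"]),
                        partner_model=(GeneticModel(i["partner_model"])
                                       if i.get("partner_model") else None),
                        threshold=i.get("threshold"),
                    )
                    for i in e.get("interactions", [])
                ),
            )
            for e in d.get("effects", [])
        )
        return cls(
            n_cases=int(d["n_cases"]), n_controls=int(d["n_controls"]),
            panel=panel, covariates=CovariateModel(**d.get("covariates", {})),
            intercept=float(d.get("intercept", -1.0)), effects=effects,
            seed=int(d.get("seed", 0)), stage_label=d.get("stage_label", ""),
            max_draw_factor=int(d.get("max_draw_factor", 2000)),
            with_audiometry=bool(d.get("with_audiometry", False)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# panels and default effects
# --------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


def default_panel(n_snps: int = 60, seed: int = 7_2019) -> pd.DataFrame:
    """A deterministic synthetic candidate panel.

    ``n_snps`` SNPs with rs-style synthetic ids, gene labels cycling through
    plausible NIHL candidate pathway genes, random (but seeded) wild/variant
    alleles, and MAFs uniform on [0.10, 0.45].  The first six SNPs — the
    positions the default planted effects occupy — get fixed common-variant
    MAFs (0.30–0.45), the frequency range of the validated susceptibility
    SNPs these defaults emulate.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i // 2 + 1:02d}" for i in range(n_snps)]
    planted_mafs = (0.40, 0.35, 0.30, 0.45, 0.35, 0.30)
    rows = []
    for i in range(n_snps):
        wild, variant = rng.choice(_BASES, size=2, replace=False)
        maf = float(np.round(rng.uniform(0.10, 0.45), 3))
        if i < len(planted_mafs):
            maf = planted_mafs[i]
        rows.append({
            "snp_id": f"rs9{i + 1:06d}",
            "gene": genes[i],
            "wild_allele": str(wild),
            "variant_allele": str(variant),
            "maf": maf,
        })
    return pd.DataFrame(rows).set_index("snp_id")


def default_effects(panel: pd.DataFrame) -> tuple[EffectSpec, ...]:
    """Six planted effects at the replication-stage crude ORs of the study's
    validated SNPs (recessive 2.261 and 1.861, dominant 1.639 and 1.550,
    recessive 2.659, super-dominant 1.437) — illustrative defaults spread
    over the first six panel SNPs."""
    models_ors = [
        (GeneticModel.RECESSIVE, 2.261),
        (GeneticModel.RECESSIVE, 1.861),
        (GeneticModel.DOMINANT, 1.639),
        (GeneticModel.RECESSIVE, 2.659),
        (GeneticModel.SUPER_DOMINANT, 1.437),
        (GeneticModel.DOMINANT, 1.550),
    ]
    snps = list(panel.index[: len(models_ors)])
    return tuple(
        EffectSpec(snp_id=s, model=m, ln_or=float(np.log(o)))
        for s, (m, o) in zip(snps, models_ors)
    )


# --------------------------------------------------------------------------
# low-level draws
# --------------------------------------------------------------------------

def genotype_probabilities(maf: float, f: float = 0.0) -> np.ndarray:
    """(P(AA), P(AB), P(BB)) under MAF ``maf`` and inbreeding-style ``f``."""
    if not 0 < maf < 1:
        raise ValueError("maf must be in (0, 1)")
    q = maf
    p = 1.0 - q
    probs = np.array([
        p * p + f * p * q,
        2 * p * q * (1 - f),
        q * q + f * p * q,
    ])
    if (probs < -1e-12).any() or abs(probs.sum() - 1) > 1e-9:
        raise ValueError(f"invalid genotype probabilities for maf={maf}, f={f}")
    return np.clip(probs, 0.0, 1.0)


def simulate_dosages(maf: float, f: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Variant-allele dosages 0/1/2 for n subjects."""
    probs = genotype_probabilities(maf, f)
    cum = np.cumsum(probs)
    u = rng.random(n)
    return np.searchsorted(cum, u, side="right").clip(0, 2)


def simulate_genotypes(maf: float, f: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Genotype call strings AA/AB/BB for n subjects."""
    return np.array(GENOTYPES, dtype=object)[simulate_dosages(maf, f, n, rng)]


def _truncated_normal(mean, sd, low, n, rng) -> np.ndarray:
    """Redraw-based truncation (draws > low); exact for sd == 0 above low."""
    if sd == 0:
        if mean <= low:
            raise ValueError("degenerate truncated normal entirely below bound")
        return np.full(n, float(mean))
    out = rng.normal(mean, sd, n)
    for _ in range(1000):
        bad = out <= low
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise RuntimeError("truncated normal rejection did not terminate")


def simulate_covariates(config: SimulationConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Environmental covariates for n subjects (CNE derived from SPL, years)."""
    cm = config.covariates
    age = cm.age_mean + cm.age_sd * rng.standard_normal(n)
    years = _truncated_normal(cm.exposure_mean, cm.exposure_sd, cm.exposure_min, n, rng)
    spl = np.maximum(cm.spl_mean + cm.spl_sd * rng.standard_normal(n), 40.0)
    return pd.DataFrame({
        "age": age,
        "years_exposure": years,
        "spl": spl,
        "cne": compute_cne(spl, years),
        "ppe": rng.random(n) < cm.ppe_p,
        "smoking": rng.random(n) < cm.smoking_p,
        "drinking": rng.random(n) < cm.drinking_p,
    })


def _model_coding(dose: np.ndarray, model: GeneticModel) -> np.ndarray:
    model = GeneticModel(model)
    if model is GeneticModel.RECESSIVE or model is GeneticModel.HOMOZYGOTE:
        return (dose == 2).astype(float)
    if model is GeneticModel.DOMINANT:
        return (dose >= 1).astype(float)
    if model is GeneticModel.SUPER_DOMINANT:
        return (dose == 1).astype(float)
    if model in (GeneticModel.ADDITIVE, GeneticModel.ALLELE):
        return dose.astype(float)
    raise ValueError(model)


def _interaction_indicator(
    inter: Interaction,
    dosages: Mapping[str, np.ndarray],
    covars: pd.DataFrame,
) -> np.ndarray:
    if inter.partner in dosages:
        if inter.partner_model is None:
            raise ValueError(f"interaction with SNP {inter.partner} needs partner_model")
        return _model_coding(dosages[inter.partner], inter.partner_model)
    col = covars[inter.partner]
    if col.dtype == bool:
        return col.to_numpy(dtype=float)
    if inter.threshold is None:
        raise ValueError(f"interaction with numeric covariate {inter.partner!r} needs threshold")
    return (col.to_numpy(dtype=float) >= inter.threshold).astype(float)


def linear_predictor(
    config: SimulationConfig,
    dosages: Mapping[str, np.ndarray],
    covars: pd.DataFrame,
) -> np.ndarray:
    """Log-odds of disease for each subject under the configured model."""
    n = len(covars)
    eta = np.full(n, config.intercept, dtype=float)
    for eff in config.effects:
        coding = _model_coding(dosages[eff.snp_id], eff.model)
        eta += eff.ln_or * coding
        for inter in eff.interactions:
            eta += inter.ln_or * coding * _interaction_indicator(inter, dosages, covars)
    return eta


# --------------------------------------------------------------------------
# audiometry (optional; exercises the classification rule)
# --------------------------------------------------------------------------

def _audiometry_columns(status: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Status-conditional pure-tone thresholds, truncated into the defining
    region of each class so classification is consistent by construction."""
    n = len(status)
    is_case = status == CASE
    cols = {}
    for ear in ("left", "right"):
        for freq in (500, 1000, 2000):
            low = np.where(is_case,
                           np.clip(rng.normal(32, 6, n), 27, 80),
                           np.clip(rng.normal(15, 5, n), -5, 24))
            cols[f"thr_{ear}_{freq}"] = np.round(low, 1)
        for freq in (3000, 4000, 6000):
            high = np.where(is_case,
                            np.clip(rng.normal(55, 8, n), 42, 110),
                            np.clip(rng.normal(27, 6, n), 0, 37))
            cols[f"thr_{ear}_{freq}"] = np.round(high, 1)
    return pd.DataFrame(cols)


# --------------------------------------------------------------------------
# cohort accrual
# --------------------------------------------------------------------------

def simulate_case_control(config: SimulationConfig) -> CohortTable:
    """Draw a cohort with exactly the requested case and control counts.

    Population subjects are generated in batches and assigned disease status
    from the logistic model; accrual continues until both quotas fill, or the
    draw budget (``max_draw_factor`` x cohort size) is exhausted — the latter
    raises with a suggestion to adjust the intercept.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_geno, rng_cov, rng_out, rng_mask, rng_audio = (
        np.random.default_rng(child) for child in ss.spawn(5))

    target = config.n_cases + config.n_controls
    budget = config.max_draw_factor * target
    snps = list(config.panel.index)
    mafs = config.panel["maf"].astype(float)
    fs = config.panel["hwe_f"].astype(float)

    got_cases: list[tuple[pd.DataFrame, np.ndarray]] = []
    kept_doses_cases: list[np.ndarray] = []
    kept_doses_ctrls: list[np.ndarray] = []
    got_ctrls: list[pd.DataFrame] = []
    got_case_cov: list[pd.DataFrame] = []
    n_cases = n_ctrls = drawn = 0
    while n_cases < config.n_cases or n_ctrls < config.n_controls:
        if drawn >= budget:
            raise RuntimeError(
                f"draw budget exhausted ({drawn} draws for {target} subjects); "
                "the intercept is likely too extreme — adjust it toward 0")
        batch = int(min(max(1024, 2 * target), budget - drawn))
        drawn += batch
        dose = np.empty((batch, len(snps)), dtype=np.int8)
        for j, snp in enumerate(snps):
            dose[:, j] = simulate_dosages(mafs[snp], fs[snp], batch, rng_geno)
        covars = simulate_covariates(config, batch, rng_cov)
        dosages = {snp: dose[:, j] for j, snp in enumerate(snps)}
        eta = linear_predictor(config, dosages, covars)
        prob = 1.0 / (1.0 + np.exp(-eta))
        is_case = rng_out.random(batch) < prob

        need_cases = config.n_cases - n_cases
        case_rows = np.flatnonzero(is_case)[:need_cases]
        need_ctrls = config.n_controls - n_ctrls
        ctrl_rows = np.flatnonzero(~is_case)[:need_ctrls]
        if len(case_rows):
            got_case_cov.append(covars.iloc[case_rows])
            kept_doses_cases.append(dose[case_rows])
            n_cases += len(case_rows)
        if len(ctrl_rows):
            got_ctrls.append(covars.iloc[ctrl_rows])
            kept_doses_ctrls.append(dose[ctrl_rows])
            n_ctrls += len(ctrl_rows)

    covars = pd.concat(got_case_cov + got_ctrls, ignore_index=True)
    dose = np.vstack(kept_doses_cases + kept_doses_ctrls)
    status = np.array([CASE] * config.n_cases + [CONTROL] * config.n_controls, dtype=object)

    # genotype strings + per-SNP masking to missing
    geno_cols = {}
    call_rates = config.panel["call_rate"].astype(float)
    for j, snp in enumerate(snps):
        calls = np.array(GENOTYPES, dtype=object)[dose[:, j]]
        cr = call_rates[snp]
        if cr < 1.0:
            miss = rng_mask.random(len(calls)) >= cr
            calls = calls.copy()
            calls[miss] = np.nan
        geno_cols[snp] = calls

    subject_ids = [f"S{i + 1:05d}" for i in range(target)]
    subjects = covars.copy()
    subjects.insert(0, "status", status)
    subjects.index = pd.Index(subject_ids, name="subject_id")
    if config.with_audiometry:
        audio = _audiometry_columns(status, rng_audio)
        audio.index = subjects.index
        subjects = pd.concat([subjects, audio], axis=1)
    genotypes = pd.DataFrame(geno_cols, index=subjects.index)
    panel = config.panel[["gene", "wild_allele", "variant_allele"]].copy()
    return CohortTable(panel=panel, subjects=subjects, genotypes=genotypes,
                       stage_label=config.stage_label)


def generate_two_stage_study(
    config_screen: SimulationConfig,
    config_replicate: SimulationConfig,
) -> tuple[CohortTable, CohortTable]:
    """Two independent cohorts sharing one panel and effect specification."""
    p1 = config_screen.panel[["gene", "wild_allele", "variant_allele", "maf"]]
    p2 = config_replicate.panel[["gene", "wild_allele", "variant_allele", "maf"]]
    if not p1.equals(p2):
        raise ValueError("screening and replication configs must share a panel")
    if config_screen.seed == config_replicate.seed:
        raise ValueError("the two stages must use distinct sub-seeds")
    return simulate_case_control(config_screen), simulate_case_control(config_replicate)


def two_stage_configs(
    master_seed: int,
    panel: pd.DataFrame | None = None,
    effects: tuple[EffectSpec, ...] | None = None,
    n_screen: tuple[int, int] = (83, 83),
    n_replicate: tuple[int, int] = (153, 252),
    intercept: float = -1.0,
    call_rate: float = 1.0,
    **kwargs,
) -> tuple[SimulationConfig, SimulationConfig]:
    """Build the paired stage configs of a two-stage study from one seed.

    Sub-seeds for the two stages are fixed labeled offsets of the master
    seed's stream, so the whole study reproduces from a single integer.
    """
    panel = panel if panel is not None else default_panel()
    if effects is None:
        effects = default_effects(panel)
    seeds = np.random.SeedSequence(master_seed).generate_state(2) % (2**31)
    panel = panel.copy()
    panel["call_rate"] = call_rate
    screen = SimulationConfig(
        n_cases=n_screen[0], n_controls=n_screen[1], panel=panel,
        intercept=intercept, effects=effects, seed=int(seeds[0]),
        stage_label="screening", **kwargs)
    replicate = SimulationConfig(
        n_cases=n_replicate[0], n_controls=n_replicate[1], panel=panel,
        intercept=intercept, effects=effects, seed=int(seeds[1]),
        stage_label="replication", **kwargs)
    return screen, replicate
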