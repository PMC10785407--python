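"""Core domain types and file I/O for occupational NIHL case-control cohorts.

Genotype calls are stored as the strings ``AA`` (homozygous wild), ``AB``
(heterozygous) and ``BB`` (homozygous variant), always oriented relative to
the SNP panel's declared wild allele — never to an external reference such as
VCF REF.  Missing calls are ``NaN`` in genotype tables.

Also houses the derived occupational-audiology quantities:

* CNE — cumulative noise exposure, ``SPL + 10*log10(years)`` in dB(A)·years
  (the equal-energy dose combining sound level and exposure duration);
* BHFTA — binaural high-frequency threshold average over 3000/4000/6000 Hz;
* MTWV — monaural weighted threshold value,
  ``0.9 * mean(500, 1000, 2000 Hz) + 0.1 * (4000 Hz)``;
* the case/control classification rule built on BHFTA and MTWV.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GENOTYPES = ("AA", "AB", "BB")
EARS = ("left", "right")
FREQUENCIES = (500, 1000, 2000, 3000, 4000, 6000)
LOW_FREQS = (500, 1000, 2000)
HIGH_FREQS = (3000, 4000, 6000)

CASE = "case"
CONTROL = "control"
INDETERMINATE = "indeterminate"
STATUSES = (CASE, CONTROL, INDETERMINATE)

#: diagnostic thresholds, dB HL
BHFTA_CASE_MIN = 40.0
MTWV_CASE_MIN = 26.0

# accepted spellings of genotype calls in input tables; anything else is
# treated as missing (with a warning count)
_CALL_SYNONYMS = {
    "AA": "AA", "AB": "AB", "BA": "AB", "BB": "BB",
    "0/0": "AA", "0|0": "AA",
    "0/1": "AB", "1/0": "AB", "0|1": "AB", "1|0": "AB",
    "1/1": "BB", "1|1": "BB",
}
_MISSING_TOKENS = {"./.", ".|.", ".", ""}


class GenotypeCall(str, enum.Enum):
    """A diploid biallelic genotype call relative to the panel's wild allele."""

    AA = "AA"
    AB = "AB"
    BB = "BB"
    MISSING = "MISSING"

    @property
    def variant_dosage(self) -> int:
        if self is GenotypeCall.MISSING:
            raise ValueError("MISSING genotype has no dosage")
        return {"AA": 0, "AB": 1, "BB": 2}[self.value]


@dataclasses.dataclass(frozen=True)
class Dialect:
    """Delimiter/missing-token conventions of the three input tables."""

    sep: str = "\t"
    missing: str = "NA"


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Case/control x exposed/unexposed counts.

    ``a`` cases exposed, ``b`` controls exposed, ``c`` cases unexposed,
    ``d`` controls unexposed.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_controls(self) -> int:
        return self.b + self.d

    def swapped(self) -> "ContingencyTable2x2":
        """Exposed/unexposed labels interchanged (OR -> 1/OR)."""
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


# --------------------------------------------------------------------------
# derived exposure / audiometric quantities
# --------------------------------------------------------------------------

def compute_cne(spl, years_exposure):
    """Cumulative noise exposure in dB(A)·years.

    CNE = SPL + 10*log10(years) = 10*log10(10**(SPL/10) * years): the
    equal-energy dose, so that e.g. a doubling of exposure time adds 3 dB.
    Accepts scalars or arrays; ``years_exposure`` must be positive.
    """
    spl = np.asarray(spl, dtype=float)
    years = np.asarray(years_exposure, dtype=float)
    if np.any(spl <= 0):
        raise ValueError("spl must be positive (dB(A) scale)")
    if np.any(years <= 0):
        raise ValueError("years_exposure must be positive")
    out = spl + 10.0 * np.log10(years)
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass(frozen=True)
class AudiometricProfile:
    """Per-ear pure-tone thresholds (dB HL) at the six diagnostic frequencies.

    ``thresholds`` maps ``(ear, frequency_hz)`` to dB HL; ears are "left" and
    "right".  Thresholds must lie in the audiometric range [-10, 120] dB HL.
    """

    thresholds: Mapping[tuple[str, int], float]

    def __post_init__(self) -> None:
        for (ear, freq), v in self.thresholds.items():
            if ear not in EARS:
                raise ValueError(f"unknown ear {ear!r}")
            if freq not in FREQUENCIES:
                raise ValueError(f"unsupported frequency {freq} Hz")
            if not math.isfinite(v) or v < -10 or v > 120:
                raise ValueError(f"threshold {v!r} at ({ear}, {freq} Hz) out of range")

    def threshold(self, ear: str, freq: int) -> float:
        try:
            return float(self.thresholds[(ear, freq)])
        except KeyError:
            raise KeyError(f"missing threshold for ear={ear!r}, frequency={freq} Hz") from None


def compute_bhfta(audiometry: AudiometricProfile) -> float:
    """Binaural high-frequency threshold average: mean over both ears of the
    3000/4000/6000 Hz thresholds (six values)."""
    vals = [audiometry.threshold(ear, f) for ear in EARS for f in HIGH_FREQS]
    return float(np.mean(vals))


def compute_mtwv(audiometry: AudiometricProfile, ear: str) -> float:
    """Monaural weighted threshold value for one ear:
    0.9 * mean(500, 1000, 2000 Hz) + 0.1 * threshold(4000 Hz)."""
    if ear not in EARS:
        raise ValueError(f"unknown ear {ear!r}")
    low = np.mean([audiometry.threshold(ear, f) for f in LOW_FREQS])
    return float(0.9 * low + 0.1 * audiometry.threshold(ear, 4000))


def classify_hearing_status(audiometry: AudiometricProfile, *, ear_rule: str = "worse") -> str:
    """Classify a profile as case / control / indeterminate.

    Case: BHFTA >= 40 dB and MTWV >= 26 dB; control: BHFTA < 40 and
    MTWV < 26; anything discordant is indeterminate.  The monaural MTWV
    criterion is applied to the worse (larger) ear by default; ``ear_rule``
    may be "worse" or "better".
    """
    bhfta = compute_bhfta(audiometry)
    mtwvs = [compute_mtwv(audiometry, ear) for ear in EARS]
    mtwv = max(mtwvs) if ear_rule == "worse" else min(mtwvs)
    if bhfta >= BHFTA_CASE_MIN and mtwv >= MTWV_CASE_MIN:
        return CASE
    if bhfta < BHFTA_CASE_MIN and mtwv < MTWV_CASE_MIN:
        return CONTROL
    return INDETERMINATE


# --------------------------------------------------------------------------
# cohort container
# --------------------------------------------------------------------------

#: phenotype columns that, when present, are coerced to these dtypes
_PHENO_NUMERIC = ("age", "years_exposure", "spl", "cne")
_PHENO_BOOL = ("ppe", "smoking", "drinking")


@dataclasses.dataclass
class CohortTable:
    """One case-control cohort: SNP panel, subject covariates, genotype calls.

    panel      : DataFrame indexed by snp_id with columns gene, wild_allele,
                 variant_allele and optionally risk_allele ("wild"/"variant").
    subjects   : DataFrame indexed by subject_id; must carry a ``status``
                 column in {case, control, indeterminate}; covariates such as
                 age, sex, years_exposure, spl, cne, ppe, smoking, drinking.
    genotypes  : DataFrame indexed by subject_id, one column per panel SNP,
                 values in {"AA","AB","BB"} or NaN (missing call).
    stage_label: free text, e.g. "screening" or "replication".
    """

    panel: pd.DataFrame
    subjects: pd.DataFrame
    genotypes: pd.DataFrame
    stage_label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if self.panel.index.has_duplicates:
            dups = self.panel.index[self.panel.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate SNP ids in panel: {dups}")
        for col in ("gene", "wild_allele", "variant_allele"):
            if col not in self.panel.columns:
                raise ValueError(f"panel missing required column {col!r}")
        same = self.panel["wild_allele"] == self.panel["variant_allele"]
        if same.any():
            raise ValueError(f"wild and variant allele identical for {list(self.panel.index[same])}")
        if self.subjects.index.has_duplicates:
            dups = self.subjects.index[self.subjects.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dups}")
        if "status" not in self.subjects.columns:
            raise ValueError("subjects table must carry a 'status' column")
        bad = set(self.subjects["status"]) - set(STATUSES)
        if bad:
            raise ValueError(f"invalid status values: {sorted(bad)}")
        if not self.genotypes.index.equals(self.subjects.index):
            only_g = self.genotypes.index.difference(self.subjects.index).tolist()
            only_p = self.subjects.index.difference(self.genotypes.index).tolist()
            raise ValueError(
                "genotype/phenotype subject id mismatch; "
                f"genotypes-only: {only_g[:10]}, phenotypes-only: {only_p[:10]}"
            )
        orphan_snps = self.genotypes.columns.difference(self.panel.index).tolist()
        if orphan_snps:
            raise ValueError(f"genotype columns not in panel: {orphan_snps}")
        valid = self.genotypes.isin(GENOTYPES) | self.genotypes.isna()
        if not valid.all().all():
            bad_cols = valid.columns[~valid.all()].tolist()
            raise ValueError(f"invalid genotype strings in columns {bad_cols}")
        # CNE consistency with SPL and years when all three are present
        cols = set(self.subjects.columns)
        if {"cne", "spl", "years_exposure"} <= cols:
            sub = self.subjects[["cne", "spl", "years_exposure"]].dropna()
            if len(sub):
                expect = compute_cne(sub["spl"].to_numpy(), sub["years_exposure"].to_numpy())
                if not np.allclose(sub["cne"].to_numpy(), expect, atol=1e-6):
                    raise ValueError("cne column inconsistent with spl and years_exposure")

    # -- conveniences ------------------------------------------------------
    @property
    def snp_ids(self) -> list[str]:
        return list(self.panel.index)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_cases(self) -> int:
        return int((self.subjects["status"] == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.subjects["status"] == CONTROL).sum())

    def status_mask(self, status: str) -> np.ndarray:
        return (self.subjects["status"] == status).to_numpy()

    def dosage_matrix(self) -> pd.DataFrame:
        """Variant-allele dosage (0/1/2, NaN if missing) per subject x SNP."""
        mapping = {"AA": 0.0, "AB": 1.0, "BB": 2.0}
        out = self.genotypes.apply(lambda col: col.map(mapping))
        return out.astype(float)

    def subset(self, subject_ids: Iterable[str], stage_label: str | None = None) -> "CohortTable":
        ids = list(subject_ids)
        return CohortTable(
            panel=self.panel.copy(),
            subjects=self.subjects.loc[ids].copy(),
            genotypes=self.genotypes.loc[ids].copy(),
            stage_label=self.stage_label if stage_label is None else stage_label,
        )


# --------------------------------------------------------------------------
# table I/O
# --------------------------------------------------------------------------

def _normalize_call(token, missing_token: str) -> tuple[object, bool]:
    """Return (normalized call or NaN, was_unparseable)."""
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return np.nan, False
    s = str(token).strip()
    if s == missing_token or s in _MISSING_TOKENS:
        return np.nan, False
    if s in _CALL_SYNONYMS:
        return _CALL_SYNONYMS[s], False
    return np.nan, True


def read_panel(panel_path: str | Path, dialect: Dialect = Dialect()) -> pd.DataFrame:
    panel = pd.read_csv(panel_path, sep=dialect.sep, dtype=str)
    required = {"snp_id", "gene", "wild_allele", "variant_allele"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel table missing columns: {sorted(missing)}")
    return panel.set_index("snp_id")


def read_cohort(
    genotype_path: str | Path,
    phenotype_path: str | Path,
    panel_path: str | Path,
    dialect: Dialect = Dialect(),
    stage_label: str = "",
) -> CohortTable:
    """Read the three input tables into a validated :class:`CohortTable`.

    Unparseable genotype strings become missing calls with a logged warning
    count; duplicate subject ids or a genotype/phenotype id mismatch are hard
    errors.
    """
    panel = read_panel(panel_path, dialect)

    pheno = pd.read_csv(phenotype_path, sep=dialect.sep, na_values=[dialect.missing])
    if "subject_id" not in pheno.columns:
        raise ValueError("phenotype table must have a subject_id column")
    if pheno["subject_id"].duplicated().any():
        dups = pheno.loc[pheno["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in phenotype table: {dups}")
    pheno = pheno.set_index("subject_id")
    for col in _PHENO_NUMERIC:
        if col in pheno.columns:
            pheno[col] = pd.to_numeric(pheno[col])
    for col in _PHENO_BOOL:
        if col in pheno.columns:
            pheno[col] = pheno[col].map(
                {True: True, False: False, 1: True, 0: False, "1": True, "0": False,
                 "True": True, "False": False, "yes": True, "no": False}
            ).astype("boolean")

    geno_raw = pd.read_csv(genotype_path, sep=dialect.sep, dtype=str,
                           na_values=[dialect.missing], keep_default_na=False)
    if "subject_id" not in geno_raw.columns:
        raise ValueError("genotype table must have a subject_id column")
    if geno_raw["subject_id"].duplicated().any():
        dups = geno_raw.loc[geno_raw["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in genotype table: {dups}")
    geno_raw = geno_raw.set_index("subject_id")

    if set(geno_raw.index) != set(pheno.index):
        only_g = sorted(set(geno_raw.index) - set(pheno.index))
        only_p = sorted(set(pheno.index) - set(geno_raw.index))
        raise ValueError(
            f"subject id mismatch between tables; genotype-only: {only_g}, phenotype-only: {only_p}"
        )
    geno_raw = geno_raw.loc[pheno.index]

    n_bad = 0
    norm = {}
    for col in geno_raw.columns:
        vals = []
        for tok in geno_raw[col]:
            v, bad = _normalize_call(tok, dialect.missing)
            n_bad += bad
            vals.append(v)
        norm[col] = vals
    genotypes = pd.DataFrame(norm, index=geno_raw.index)
    if n_bad:
        log.warning("%d unparseable genotype strings set to missing", n_bad)

    return CohortTable(panel=panel, subjects=pheno, genotypes=genotypes,
                       stage_label=stage_label)


def write_cohort(
    cohort: CohortTable,
    genotype_path: str | Path,
    phenotype_path: str | Path,
    panel_path: str | Path,
    dialect: Dialect = Dialect(),
) -> None:
    """Write the three tables; inverse of :func:`read_cohort` up to dtypes."""
    cohort.panel.reset_index().rename(columns={"index": "snp_id"}).to_csv(
        panel_path, sep=dialect.sep, index=False, na_rep=dialect.missing)
    pheno = cohort.subjects.reset_index()
    pheno = pheno.rename(columns={pheno.columns[0]: "subject_id"})
    pheno.to_csv(phenotype_path, sep=dialect.sep, index=False, na_rep=dialect.missing)
    geno = cohort.genotypes.reset_index()
    geno = geno.rename(columns={geno.columns[0]: "subject_id"})
    geno.to_csv(genotype_path, sep=dialect.sep, index=False, na_rep=dialect.missing)


# --------------------------------------------------------------------------
# VCF import
# --------------------------------------------------------------------------

def import_vcf(vcf_path: str | Path, panel: pd.DataFrame) -> pd.DataFrame:
    """Import genotype calls for panel SNPs from a VCF 4.x file.

    Diploid GT 0/0 -> AA, 0/1 or 1/0 -> AB, 1/1 -> BB; missing or non-diploid
    GT -> missing.  Calls are re-oriented to the panel's wild allele: if the
    panel declares the VCF REF to be the *variant* allele, homozygote calls
    are flipped.  A multi-allelic site matching a panel SNP is an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    data: dict[str, list] = {}
    for variant in vcf:
        vid = variant.ID
        key = f"{variant.CHROM}:{variant.POS}:{variant.REF}:{','.join(variant.ALT)}"
        snp_id = vid if vid in panel.index else (key if key in panel.index else None)
        if snp_id is None:
            continue
        if len(variant.ALT) != 1:
            raise ValueError(f"multi-allelic site {key} matches panel SNP {snp_id}")
        wild = panel.loc[snp_id, "wild_allele"]
        variant_allele = panel.loc[snp_id, "variant_allele"]
        ref, alt = variant.REF, variant.ALT[0]
        if {ref, alt} != {wild, variant_allele}:
            raise ValueError(
                f"alleles {ref}/{alt} at {snp_id} do not match panel "
                f"{wild}/{variant_allele}")
        flip = ref == variant_allele  # VCF REF is the panel's variant allele
        calls = []
        for gt in variant.genotypes:  # [allele0, allele1, phased]
            alleles = gt[:-1]
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                calls.append(np.nan)
                continue
            dose = sum(alleles)  # ALT dosage
            if flip:
                dose = 2 - dose
            calls.append(GENOTYPES[dose])
        data[snp_id] = calls
    return pd.DataFrame(data, index=pd.Index(samples, name="subject_id"))
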