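#!/usr/bin/env python
"""Genetic risk score analysis on the replication cohort.

Takes the SNPs validated by 02_qc_association.py, assigns each a risk
allele from its replication-stage allele-model odds ratio, sums the 0/1/2
risk-genotype codes into an unweighted GRS per subject, and estimates the
dose-response: per-bin odds ratios against the lowest-GRS reference bin, a
Cochran-Armitage trend test, and the high/low dichotomy OR.

Output: results/grs/grs_risk_table.tsv
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from nihlkit.association import GeneticModel, snp_association
from nihlkit.cohort import read_cohort
from nihlkit.grs import assign_risk_allele, compute_grs, grs_dichotomy, grs_risk_table
from nihlkit.pipeline import _auto_bins


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohorts", type=Path, default=Path("results/cohorts"))
    parser.add_argument("--validated", type=Path,
                        default=Path("results/association/validated_snps.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/grs"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    replication = read_cohort(args.cohorts / "replication_genotypes.tsv",
                              args.cohorts / "replication_phenotypes.tsv",
                              args.cohorts / "replication_panel.tsv",
                              stage_label="replication")
    validated = pd.read_csv(args.validated, sep="\t")["snp_id"].tolist()
    if not validated:
        print("no validated SNPs; GRS analysis skipped")
        return

    risk_alleles = {}
    for snp in validated:
        r = snp_association(replication, snp, GeneticModel.ALLELE, adjust_for=())
        risk_alleles[snp] = assign_risk_allele([r])
        print(f"{snp}: risk allele = {risk_alleles[snp]} "
              f"(allele-model OR {r.or_crude.value:.3f})")

    profiles = compute_grs(replication, validated, risk_alleles)
    status = replication.subjects["status"]
    med = profiles.join(status).groupby("status")["grs"].median()
    print(f"median GRS: cases {med.get('case', float('nan')):.1f}, "
          f"controls {med.get('control', float('nan')):.1f}")

    ref, bins = _auto_bins(profiles)
    table = grs_risk_table(profiles, status, bins=bins, reference=ref)
    out = table.bins.copy()
    out["trend_chi2"], out["trend_p"] = table.trend_chi2, table.trend_p
    out.to_csv(args.out / "grs_risk_table.tsv", sep="\t", index=False,
               float_format="%.6g")
    print(out.to_string(index=False))
    print(f"trend chi2 = {table.trend_chi2:.3f}, p = {table.trend_p:.3g}")

    cutoff = int(ref.strip("<=")) + 1
    dich = grs_dichotomy(profiles, status, cutoff=cutoff)
    print(f"GRS >= {cutoff} vs < {cutoff}: OR {dich.value:.3f} "
          f"({dich.ci_low:.3f}, {dich.ci_high:.3f}), p = {dich.p:.3g}")


if __name__ == "__main__":
    main()
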