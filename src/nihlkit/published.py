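"""Worked-example marginal counts from the two-stage occupational NIHL study
this package models (replication-stage cohort: 153 cases, 252 controls).

Only the published *counts* are stored here; every odds ratio is recomputed
at run time from those counts by the package's own 2x2 machinery, so these
functions double as end-to-end worked examples of the crude-OR arithmetic
behind a GRS risk table and a CART terminal-node risk table.
"""

from __future__ import annotations

import pandas as pd

from .association import odds_ratio_woolf
from .cohort import ContingencyTable2x2
from .grs import GrsRiskTable, risk_table_from_counts

#: GRS bin -> (cases, controls); reference bin "<=5"
GRS_BIN_COUNTS: dict[str, tuple[int, int]] = {
    "<=5": (48, 140),
    "6": (22, 35),
    "7": (31, 32),
    "8": (22, 30),
    "9": (17, 10),
    ">=10": (13, 5),
}

#: high/low GRS split at 6: (cases, controls) per group
GRS_DICHOTOMY_COUNTS: dict[str, tuple[int, int]] = {
    ">=6": (105, 112),
    "<6": (48, 140),
}

#: CART terminal node -> (controls, cases); node 1 is the reference
#: (lowest case fraction).  Combinations paraphrase the published
#: gene-environment tree: splits on GJB2, FAS and PTPRN2 genotypes, age 45,
#: CNE 95 dB(A)·years, PPE use and drinking status.
CART_NODE_COUNTS: dict[int, tuple[int, int]] = {
    1: (87, 26),
    2: (18, 9),
    3: (15, 12),
    4: (63, 22),
    5: (3, 9),
    6: (20, 18),
    7: (31, 23),
    8: (15, 34),
}


def grs_risk_table_from_published_counts() -> GrsRiskTable:
    """Per-bin GRS odds ratios recomputed from the published bin counts."""
    labels = list(GRS_BIN_COUNTS)
    cases = [GRS_BIN_COUNTS[k][0] for k in labels]
    controls = [GRS_BIN_COUNTS[k][1] for k in labels]
    return risk_table_from_counts(labels, cases, controls, reference_label="<=5")


def grs_dichotomy_from_published_counts():
    """OR of high (>=6) vs low (<6) GRS from the published counts."""
    (a, b), (c, d) = GRS_DICHOTOMY_COUNTS[">=6"], GRS_DICHOTOMY_COUNTS["<6"]
    return odds_ratio_woolf(ContingencyTable2x2(a, b, c, d))


def cart_node_ors_from_published_counts(reference: int = 1) -> pd.DataFrame:
    """Terminal-node odds ratios vs the reference node, from published counts."""
    ref_controls, ref_cases = CART_NODE_COUNTS[reference]
    rows = []
    for node, (controls, cases) in CART_NODE_COUNTS.items():
        if node == reference:
            rows.append({"node": node, "n_controls": controls, "n_cases": cases,
                         "or": 1.0, "ci_low": float("nan"), "ci_high": float("nan"),
                         "p": float("nan")})
            continue
        orr = odds_ratio_woolf(ContingencyTable2x2(cases, controls, ref_cases, ref_controls))
        rows.append({"node": node, "n_controls": controls, "n_cases": cases,
                     "or": orr.value, "ci_low": orr.ci_low, "ci_high": orr.ci_high,
                     "p": orr.p})
    return pd.DataFrame(rows).set_index("node")
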