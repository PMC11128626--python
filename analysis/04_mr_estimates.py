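#!/usr/bin/env python
"""Two-sample MR for all three legs of the mediation triangle.

For exposure -> outcome, exposure -> mediator and mediator -> outcome, runs
the five-estimator panel (IVW, MR-Egger, weighted median, simple and weighted
mode) plus the sensitivity suite (Cochran's Q, Egger intercept, leave-one-out,
MR-PRESSO).  Requires 01 and expects the instrument logic of 02.  Writes
results/mr_estimates.tsv and results/mr_sensitivity.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mrmediate.estimators import cochran_q, egger, estimator_panel, mr_presso
from mrmediate.instruments import LDMatrix, load_annotations, select_instruments
from mrmediate.summary_io import harmonize, read_summary_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    data = RESULTS / "data"
    exposure, _ = read_summary_table(data / "exposure.tsv")
    mediator, _ = read_summary_table(data / "mediator.tsv")
    outcome, _ = read_summary_table(data / "outcome.tsv")
    ld = LDMatrix.from_tsv(data / "ld.tsv")
    annotations = load_annotations(data / "annotations.tsv")

    cis = select_instruments(exposure, p_threshold=1e-4, ld=ld, r2_threshold=0.8).instruments
    med_ivs = select_instruments(
        mediator, p_threshold=5e-8, ld=ld, r2_threshold=0.001,
        annotations=annotations,
        blocked_traits=("low-density lipoprotein", "coronary artery disease"),
    ).instruments

    legs = {
        "exposure->outcome": (cis, outcome),
        "exposure->mediator": (cis, mediator),
        "mediator->outcome": (med_ivs, outcome),
    }
    rows, sens = [], {}
    for leg, (ivs, target) in legs.items():
        harm = harmonize(ivs, target).instruments
        for est in estimator_panel(harm, n_boot=2000, seed=args.seed):
            rows.append({"leg": leg, **est.as_dict()})
        q = cochran_q(harm)
        eg = egger(harm)
        pr = mr_presso(harm, n_sim=2000, seed=args.seed) if len(harm) >= 4 else None
        sens[leg] = {
            "cochran_q": {"Q": q.Q, "df": q.df, "pvalue": q.pvalue},
            "egger_intercept": {"value": eg.intercept, "pvalue": eg.intercept_pvalue},
            "mr_presso_global_pvalue": pr.global_pvalue if pr else None,
            "mr_presso_outliers": list(pr.outlier_indices) if pr else None,
        }

    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "mr_estimates.tsv", sep="\t", index=False)
    (RESULTS / "mr_sensitivity.json").write_text(json.dumps(sens, indent=2))

    for leg in legs:
        sub = df[(df["leg"] == leg) & (df["method"] == "IVW")].iloc[0]
        s = sens[leg]
        print(f"{leg}: IVW OR {sub['odds_ratio']:.3f} "
              f"({sub['or_ci_low']:.3f}, {sub['or_ci_high']:.3f}), p {sub['pvalue']:.3g}; "
              f"Q p {s['cochran_q']['pvalue']:.2f}, Egger intercept p "
              f"{s['egger_intercept']['pvalue']:.2f}, PRESSO global p "
              f"{s['mr_presso_global_pvalue'] if s['mr_presso_global_pvalue'] else float('nan'):.2f}")


if __name__ == "__main__":
    main()
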