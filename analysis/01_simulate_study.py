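#!/usr/bin/env python
"""Generate the synthetic study standing in for the real GWAS accessions.

Writes the study-shaped fixture (exposure = cis SGLT2/HbA1c locus, mediator =
venous-thromboembolism-like GWAS with 13 planted genome-wide-significant
variants, outcome = rare cardiac-death-like GWAS) plus its LD matrix,
confounder-annotation table and ground truth under results/data/.
"""

import argparse
import json
from pathlib import Path

from mrmediate.simulate import make_study_shaped_fixture
from mrmediate.summary_io import associations_to_frame

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    out = RESULTS / "data"
    out.mkdir(parents=True, exist_ok=True)
    study = make_study_shaped_fixture(seed=args.seed)

    for name in ("exposure", "mediator", "outcome"):
        frame = associations_to_frame(getattr(study, f"{name}_stats")).rename(
            columns={"variant_id": "SNP", "chromosome": "chr", "position": "pos",
                     "pvalue": "pval", "n": "samplesize"}
        )
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    study.ld.to_tsv(out / "ld.tsv")

    with open(out / "annotations.tsv", "w") as fh:
        fh.write("variant_id\ttrait\n")
        for vid, traits in study.truth["annotations"].items():
            for t in traits:
                fh.write(f"{vid}\t{t}\n")
    (out / "truth.json").write_text(json.dumps(study.truth, indent=2))

    print(f"seed {args.seed}: wrote {len(study.mediator_stats)} variants per trait to {out}")
    print(f"cis instruments planted: {len(study.truth['cis_ids'])}; "
          f"mediator index variants: {len(study.truth['mediator_index_ids'])}; "
          f"satellites in LD: {len(study.truth['mediator_satellite_ids'])}")


if __name__ == "__main__":
    main()
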