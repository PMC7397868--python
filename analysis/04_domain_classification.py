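#!/usr/bin/env python
"""Classify nonclassical RNA-binding domains and compare annotation fractions.

Joins the WCE-normalized enrichment table with the planted annotations,
assigns every abundant nonclassical domain one of the three binding-activity
classes, checks recovery of the planted classes, and computes term-fraction
statistics for the high-activity and underrepresented protein sets.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from ric_activity.domains import classify_domains, select_sets, term_fractions
from ric_activity.tables import (
    read_annotation_table,
    read_id_list,
    read_results,
    write_results,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = read_results(args.out / "enrichment_wce.tsv")
    ann = read_annotation_table(
        args.sim / "annotations.tsv",
        classical_ids=read_id_list(args.sim / "classical_ids.txt"),
        nonclassical_ids=read_id_list(args.sim / "nonclassical_ids.txt"),
    )
    classes = classify_domains(rows, ann)
    write_results(classes, args.out / "domain_classes.tsv")

    expected = read_results(args.sim / "planted_domains.tsv")
    merged = expected.merge(classes, on="pfam_id", how="left")
    recovery = (merged["expected_class"] == merged["klass"]).mean()
    print(f"{len(classes)} domains classified: "
          f"{classes['klass'].value_counts().to_dict()}")
    print(f"planted-class recovery: {100 * recovery:.1f}% of {len(merged)} domains")

    enriched, under = select_sets(rows)
    sets = pd.DataFrame(
        {
            "protein_id": enriched + under,
            "set": ["enriched"] * len(enriched) + ["underrepresented"] * len(under),
        }
    )
    write_results(sets, args.out / "sets.tsv")
    print(f"high-activity set (ratio > 4, P < 0.01): {len(enriched)} proteins; "
          f"underrepresented (ratio < 0.25, P < 0.01): {len(under)}")

    reference = rows["protein_id"].tolist()
    frac_rows = []
    for name, ids in (("enriched", enriched), ("underrepresented", under)):
        if ids:
            comp = term_fractions(ids, reference, "GO:0022626", ann)
            frac_rows.append({"set": name, **dataclasses.asdict(comp)})
            print(
                f"GO:0022626 fraction in {name}: {100 * comp.frac_in_set:.1f}% "
                f"vs {100 * comp.frac_in_reference:.1f}% in the full table"
            )
    write_results(pd.DataFrame(frac_rows), args.out / "term_fractions.tsv")


if __name__ == "__main__":
    main()
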