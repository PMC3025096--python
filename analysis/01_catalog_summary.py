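#!/usr/bin/env python
"""Summarise the full lens phosphosite catalog and validate its rows.

Finds: 73 unique phosphosites on 32 proteins (9 crystallins, 23 others);
serine carries 71.2% of sites, threonine 24.7%, tyrosine 4.1%; exactly one
catalog row (aldolase C, designation Ser-26 against fragment 116-129) is
internally inconsistent and is reported rather than dropped.

Writes results/catalog_summary.json and results/catalog_validation.tsv.
"""

import json
from pathlib import Path

from lensphos import catalog as cat

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    records = cat.load_packaged_catalog("sites")
    summary = cat.summarize(records)
    report = cat.validate_catalog(records)

    out = summary.to_dict()
    out["n_validation_warnings"] = len(report.warnings)
    (OUT / "catalog_summary.json").write_text(json.dumps(out, indent=2) + "\n")
    report.to_frame().to_csv(OUT / "catalog_validation.tsv", sep="\t", index=False)

    print(f"{summary.n_sites} sites on {summary.n_proteins} proteins "
          f"({summary.n_crystallin_proteins} crystallins, {summary.n_other_proteins} others)")
    print(f"residue shares: {summary.residue_percent} (integer: {summary.residue_percent_int})")
    print(f"{len(report.warnings)} inconsistent row(s):")
    for w in report.warnings:
        print(f"  row {w.row} {w.site[0]} {w.site[1]}: {w.message}")


if __name__ == "__main__":
    main()
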