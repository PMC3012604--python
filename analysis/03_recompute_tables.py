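#!/usr/bin/env python
"""Recompute the published key-residue conservation tables.

Replays the conservation arithmetic over the packaged rice/Arabidopsis
residue tables and reports which printed Conserved/Similarity values are
reproduced exactly and which contradict their own printed residues.
"""

from pathlib import Path

from immclass.pipeline import recompute_paper_tables

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for family in ("FKBP", "CYP"):
        rendered, rows, cols = recompute_paper_tables(family)
        (OUT / f"table_{family}_recomputed.tsv").write_text(rendered)
        rows.to_csv(OUT / f"table_{family}_row_audit.tsv", sep="\t")
        cols.to_csv(OUT / f"table_{family}_column_audit.tsv", sep="\t")
        n_flag = int(rows.flag.sum())
        print(
            f"{family}: {len(rows)} rows, {len(rows) - n_flag} printed values "
            f"reproduced, {n_flag} flagged as internally inconsistent:"
        )
        for name, row in rows[rows.flag].iterrows():
            print(
                f"  {name}: printed {row.printed_conserved} vs recomputed "
                f"{row.recomputed_conserved}"
            )


if __name__ == "__main__":
    main()
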