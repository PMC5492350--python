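#!/usr/bin/env python
"""Classify, filter and count the CYP51A1 variant tables.

Loads the two packaged variant tables, recomputes SIFT/PolyPhen-2 threshold
classes from the printed scores, applies the damaging-by-both filter, counts
variants per conserved region, and reports rows whose printed label
disagrees with its own printed score.  Writes results/variant_counts.tsv and
results/variant_qc.tsv.
"""

from pathlib import Path

from cyp51var.variants import (
    consistency_check,
    count_by_region,
    filter_damaging_both,
    load_packaged_table,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    t3 = load_packaged_table("table3_damaging")
    t4 = load_packaged_table("table4_conserved_regions")
    kept = filter_damaging_both(t3)
    print(f"non-active-site table: {len(t3)} records, "
          f"{len(kept)} damaging by both predictors")
    counts = count_by_region(t4)
    print(f"conserved-region table: {len(t4)} missense/nonsense records")
    rows = ["region\tcount"]
    for region, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        print(f"  {region}: {count}")
        rows.append(f"{region}\t{count}")
    out = ROOT / "results" / "variant_counts.tsv"
    out.parent.mkdir(exist_ok=True)
    out.write_text("\n".join(rows) + "\n")

    qc = consistency_check(t3) + consistency_check(t4)
    print(f"\nlabel/score inconsistencies: {len(qc)}")
    qc_rows = ["snp_id\tprotein_change\ttool\tscore\tprinted_label\tcomputed_class"]
    for m in qc:
        print(f"  {m.protein_change} {m.tool}: printed {m.printed_label!r} "
              f"({m.score}) -> computed {m.computed_class}")
        qc_rows.append(f"{m.snp_id}\t{m.protein_change}\t{m.tool}\t{m.score}"
                       f"\t{m.printed_label}\t{m.computed_class}")
    qc_out = ROOT / "results" / "variant_qc.tsv"
    qc_out.write_text("\n".join(qc_rows) + "\n")
    print(f"wrote {out} and {qc_out}")


if __name__ == "__main__":
    main()
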