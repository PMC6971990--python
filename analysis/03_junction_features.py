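#!/usr/bin/env python
"""Characterize splice junctions: novelty and gene-region classes,
donor-acceptor dinucleotide usage, branch points, polypyrimidine tracts,
intron-length statistics and sequence-logo matrices."""

import json
from pathlib import Path

from splicescape import annotation_io, features

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"
CONDITIONS = ("NA", "CS", "CA1", "CA2", "DA")


def main() -> None:
    genome = annotation_io.read_genome(SIM / "genome.fa")
    reference = annotation_io.read_gtf(SIM / "reference.gtf", genome)
    assembled = []
    for cond in CONDITIONS:
        genes = annotation_io.read_gtf(SIM / f"assembled_{cond}.gtf", genome)
        assembled.extend(annotation_io.filter_isoforms(
            genes, reference=reference))

    juncs, incidences = features.collect_junctions(
        reference, assembled, genome)
    feats = features.find_branch_points(juncs, genome)
    usage = features.dinucleotide_usage(juncs, genome)
    stats = features.intron_statistics(feats)
    logos = features.build_logos(feats, genome)

    out = ROOT / "junctions"
    out.mkdir(parents=True, exist_ok=True)
    features.junctions_to_bed(juncs).to_csv(
        out / "junctions.bed", sep="\t", index=False, header=False)
    usage.to_csv(out / "dinucleotide_usage.tsv", sep="\t", index=False)
    stats.pop("histogram").to_csv(out / "intron_length_histogram.tsv",
                                  sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(stats, indent=1,
                                                 sort_keys=True))
    for logo in logos:
        logo.counts.rename_axis("offset").to_csv(
            out / f"logo_{logo.region}.tsv", sep="\t")

    print(f"{len(juncs)} distinct junctions "
          f"({incidences} junction-transcript incidences)")
    for cls in features.NOVELTY_CLASSES:
        print(f"  {cls}: {sum(1 for j in juncs if j.novelty == cls)}")
    print("location classes:",
          {c: sum(1 for j in juncs if j.location == c)
           for c in features.LOCATION_CLASSES})
    print("\ndinucleotide usage (DNA alphabet; GT-AG is the RNA GU-AG):")
    print(usage.to_string(index=False))
    print(f"\nintron length mean {stats['length_mean']:.1f} +/- "
          f"{stats['length_sd']:.1f} nt, median {stats['length_median']:.0f}")
    print(f"branch A to 3'ss offset {stats['bp_offset_3ss_mean']:.1f} +/- "
          f"{stats['bp_offset_3ss_sd']:.1f} nt over "
          f"{stats['n_with_branch']} introns")
    print(f"branch offset from 5'ss vs intron length: "
          f"r = {stats['length_vs_bp5ss_r']:.3f}")
    print(f"\ntables written under {out}")


if __name__ == "__main__":
    main()
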