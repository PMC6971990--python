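#!/usr/bin/env python
"""Project annotated ORFs onto AS isoforms and call premature termination
codons; report truncated-protein lengths and NMD candidacy."""

from pathlib import Path

import pandas as pd

from splicescape import annotation_io, features, orf

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"
CONDITIONS = ("NA", "CS", "CA1", "CA2", "DA")


def main() -> None:
    genome = annotation_io.read_genome(SIM / "genome.fa")
    reference = annotation_io.read_gtf(SIM / "reference.gtf", genome)
    frames = features.reference_cds_frames(reference)

    isoforms = {}
    for cond in CONDITIONS:
        genes = annotation_io.read_gtf(SIM / f"assembled_{cond}.gtf", genome)
        for g in annotation_io.filter_isoforms(genes, reference=reference):
            for t in g.transcripts:
                ref_t = frames.get(g.gene_id)
                if ref_t is None or t.junction_set() == ref_t.junction_set():
                    continue
                isoforms[t.transcript_id] = (t, ref_t)

    rows = []
    for tid, (iso, ref_t) in sorted(isoforms.items()):
        r = orf.scan_orf(iso, ref_t, genome)
        rows.append({
            "transcript_id": tid, "gene_id": iso.gene_id,
            "start_projected": r.start_projected,
            "protein_length_aa": r.protein_length,
            "reference_protein_length_aa": r.reference_protein_length,
            "is_ptc": r.is_ptc, "nmd_candidate": r.nmd_candidate,
            "run_through": r.run_through,
        })
    df = pd.DataFrame(rows)
    out = ROOT / "orf"
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "orf_ptc.tsv", sep="\t", index=False)

    n_ptc = int(df["is_ptc"].sum())
    print(f"{len(df)} AS isoforms scanned; {n_ptc} carry a premature "
          f"termination codon ({100 * n_ptc / max(1, len(df)):.1f}%)")
    trunc = df[df["is_ptc"]]
    if len(trunc):
        ex = trunc.iloc[0]
        print(f"example truncation: {ex.transcript_id} encodes "
              f"{ex.protein_length_aa} aa against the full-length "
              f"{ex.reference_protein_length_aa} aa protein")
    print(f"NMD candidates (stop > 50 nt upstream of the last junction): "
          f"{int(df['nmd_candidate'].sum())}")
    print(f"table written to {out / 'orf_ptc.tsv'}")


if __name__ == "__main__":
    main()
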