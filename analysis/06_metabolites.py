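#!/usr/bin/env python
"""Flag differential metabolites between conditions and correlate AS
transcript expression with metabolite abundances over the time course.

Differential rule: Welch t on log abundances, p < 0.05 and fold change > 2.
Association: Pearson r over condition means; |r| > 0.7 is a strong link.
"""

from pathlib import Path

import pandas as pd

from splicescape import annotation_io, differential, metabolites as mb

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"
CONDITIONS = ("NA", "CS", "CA1", "CA2", "DA")


def main() -> None:
    genome = annotation_io.read_genome(SIM / "genome.fa")
    reference = annotation_io.read_gtf(SIM / "reference.gtf", genome)
    expr = differential.read_expression(SIM / "expression.tsv")
    metab = mb.read_metabolites(SIM / "metabolites.tsv")
    out = ROOT / "metabolites"
    out.mkdir(parents=True, exist_ok=True)

    conds = metab.conditions()
    frames = []
    for cond in conds[1:]:
        table = mb.call_diff_metabolites(metab, (conds[0], cond))
        frames.append(table)
        print(f"{conds[0]} vs {cond}: "
              f"{int(table['is_differential'].sum())} differential "
              f"metabolites of {len(table)}")
    pd.concat(frames, ignore_index=True).to_csv(
        out / "differential_metabolites.tsv", sep="\t", index=False)

    # AS isoforms = assembled transcripts with class code 'j'
    as_transcripts = set()
    for cond in CONDITIONS:
        genes = annotation_io.read_gtf(SIM / f"assembled_{cond}.gtf", genome)
        for g in annotation_io.filter_isoforms(genes, reference=reference):
            as_transcripts.update(t.transcript_id for t in g.transcripts
                                  if t.class_code == "j")
    as_transcripts &= set(expr.values.index)

    pairs = [(t, m) for t in sorted(as_transcripts)
             for m in metab.values.index]
    assoc = mb.correlate(expr, metab, pairs=pairs)
    table = mb.associations_to_frame(assoc)
    table.to_csv(out / "associations.tsv", sep="\t", index=False)

    strong = table[table["is_strong"]]
    print(f"\n{len(table)} transcript-metabolite pairs tested over "
          f"{assoc[0].n_conditions if assoc else 0} shared conditions; "
          f"{len(strong)} strong (|r| > 0.7)")
    for _, row in strong.head(5).iterrows():
        direction = "positively" if row["sign"] == "+" else "negatively"
        print(f"  {row.transcript_id} {direction} correlated with "
              f"{row.metabolite_id} (r = {row.r:+.2f})")
    print(f"tables written under {out}")


if __name__ == "__main__":
    main()
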