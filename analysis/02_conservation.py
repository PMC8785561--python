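#!/usr/bin/env python
"""Score per-column conservation of every component MSA.

Reads results/data/msa_*.fasta, computes Jensen–Shannon conservation
tracks (BLOSUM62 background, Henikoff weights, gap penalty, window 3)
and pairwise identity statistics, and writes per-component track TSVs
plus a summary table under results/conservation/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from sf3bcons.alignment import (
    jsd_track,
    map_reference,
    pairwise_identity,
    read_alignment,
    write_track_tsv,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA, OUT = ROOT / "data", ROOT / "conservation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = json.loads((DATA / "truth.json").read_text())
    rows = []
    for path in sorted(DATA.glob("msa_*.fasta")):
        comp = path.stem.removeprefix("msa_")
        aln = read_alignment(path)
        track = jsd_track(aln)
        ident = pairwise_identity(aln)
        mapping = map_reference(aln, aln.ids[0])
        write_track_tsv(track, OUT / f"track_{comp}.tsv", mapping)
        conserved = set(truth[comp]["conserved_columns"])
        mean_cons = float(
            np.mean([track.windowed_jsd[c - 1] for c in conserved])
        ) if conserved else float("nan")
        mean_var = float(
            np.mean(
                [track.windowed_jsd[c - 1] for c in range(1, track.length + 1)
                 if c not in conserved]
            )
        )
        rows.append(
            (comp, aln.n_records, track.length,
             float(np.mean(track.windowed_jsd)), ident.mean_percent,
             mean_cons, mean_var)
        )
        print(
            f"{comp:8s} mean JSD {np.mean(track.windowed_jsd):.3f} | "
            f"identity {ident.mean_percent:5.1f}% | planted conserved cols score "
            f"{mean_cons:.3f} vs variable {mean_var:.3f}"
        )
    df = pd.DataFrame(
        rows,
        columns=["component", "n_seqs", "alignment_length", "mean_windowed_jsd",
                 "mean_pairwise_identity", "mean_jsd_conserved_cols",
                 "mean_jsd_variable_cols"],
    )
    df.to_csv(OUT / "conservation_summary.tsv", sep="\t", index=False)
    sep = (df["mean_jsd_conserved_cols"] > df["mean_jsd_variable_cols"]).all()
    print(f"planted conserved columns score above variable ones in every "
          f"component: {sep}")
    print(f"done -> {OUT}")


if __name__ == "__main__":
    main()
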