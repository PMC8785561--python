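#!/usr/bin/env python
"""Scan homolog C-terminal tails for proline-rich motifs.

Reads the generated homolog tails, their tail-region table and taxon
labels, scans for the five proline-rich motifs, classifies each homolog
human-like vs yeast-like, and writes hits, classifications and
per-taxon proportions under results/motifs/.
"""

import json
from pathlib import Path

import pandas as pd

from sf3bcons.motifs import CLASS_MOTIF, batch_classify

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA, OUT = ROOT / "data", ROOT / "motifs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    regions = pd.read_csv(DATA / "tail_regions.tsv", sep="\t")
    taxa = pd.read_csv(DATA / "tail_taxa.tsv", sep="\t")
    res = batch_classify(DATA / "sf3b4_homolog_tails.fasta", regions, taxa)

    pd.DataFrame(
        [(h.sequence_id, h.motif, h.start, h.matched) for h in res.hits],
        columns=["sequence_id", "motif", "start", "matched"],
    ).to_csv(OUT / "hits.tsv", sep="\t", index=False)
    res.classifications.to_csv(OUT / "classifications.tsv", sep="\t", index=False)
    res.proportions.to_csv(OUT / "taxon_proportions.tsv", sep="\t")

    counts = res.counts()
    total = len(res.classifications)
    print(f"{total} homologs scanned; class counts: {counts}")
    print("per-taxon human-like (motif) proportion:")
    for taxon, row in res.proportions.iterrows():
        print(f"  {taxon:15s} {row.get(CLASS_MOTIF, 0.0):.2f}")
    truth = json.loads((DATA / "truth.json").read_text())["planted_motif_hits"]
    got = {(h.sequence_id, h.motif, h.start) for h in res.hits}
    want = {tuple(t) for t in truth}
    print(f"planted hits recovered exactly: {got == want}")
    print(f"done -> {OUT}")


if __name__ == "__main__":
    main()
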