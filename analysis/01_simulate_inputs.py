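#!/usr/bin/env python
"""Generate the synthetic study inputs for the SF3b-style analysis.

Creates, under results/data/:
  * one MSA per complex component (7 components, graded numbers of
    planted conserved columns emulating core vs peripheral proteins),
  * two toy multi-chain complex structures (different "species") with
    planted inter-chain contacts, plus a chain map and a residue
    numbering map,
  * a species x component presence/absence table with two planted
    co-occurrence modules,
  * C-terminal-tail homolog sequences with planted proline-rich motifs,
    plus region and taxon tables,
  * an annotated site list on the hub component's reference sequence.

Everything is seeded; truth sidecars record the planted ground truth.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from sf3bcons.structure import write_pdb
from sf3bcons.synthetic import (
    simulate_complex,
    simulate_motif_sequences,
    simulate_msa,
    simulate_profiles,
    write_motif_fasta,
    write_msa_fasta,
    write_profile_tsv,
)

SEED = 2021
OUT = Path(__file__).resolve().parent.parent / "results" / "data"

# component -> (n_seqs, n_cols, n_conserved): core components get more
# planted conserved columns than peripheral ones
COMPONENTS = {
    "SF3b1": (40, 260, 60),
    "SF3b2": (40, 200, 25),
    "SF3b3": (40, 200, 25),
    "SF3b4": (40, 180, 28),
    "SF3b14b": (40, 120, 45),
    "SF3b5": (40, 100, 30),
    "SF3b6": (40, 120, 28),
}

MODULES = {
    "pre_mRNA_binding": ["SF3b1", "SF3b2", "SF3b3", "SF3b4"],
    "core_trio": ["SF3b14b", "SF3b5", "SF3b6"],
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth_sidecar = {}

    print("== component MSAs ==")
    for i, (comp, (n_seqs, n_cols, n_cons)) in enumerate(COMPONENTS.items()):
        t = simulate_msa(n_seqs, n_cols, n_cons, gap_rate=0.05, seed=SEED + i)
        write_msa_fasta(t.alignment, OUT / f"msa_{comp}.fasta")
        truth_sidecar[comp] = {
            "conserved_columns": sorted(t.conserved_columns),
            "n_seqs": n_seqs,
            "n_cols": n_cols,
        }
        print(f"  {comp}: {n_seqs} seqs x {n_cols} cols, {n_cons} conserved planted")

    print("== toy complex structures ==")
    chain_spec = [
        ("SF3b1", "protein", 26), ("SF3b2", "protein", 20),
        ("SF3b14b", "protein", 12), ("SF3b6", "protein", 12),
    ]
    chain_rows, map_rows = [], []
    for k, species in enumerate(["human_like", "yeast_like"]):
        t = simulate_complex(chain_spec, n_contacts=10, seed=SEED + 50 + k)
        t.structure.structure_id = species
        write_pdb(t.structure, OUT / f"complex_{species}.pdb")
        (OUT / f"complex_{species}.contacts.json").write_text(
            json.dumps(t.planted_contacts)
        )
        for ch in t.structure.chains:
            chain_rows.append((species, ch.chain_id, ch.component, ch.molecule_class))
            for res in ch.residues:
                # toy residue numbering == reference numbering
                map_rows.append((species, ch.chain_id, res.number, res.number))
        print(f"  {species}: {len(t.structure.chains)} chains, "
              f"{len(t.planted_contacts)} planted contacts")
    pd.DataFrame(
        chain_rows, columns=["structure_id", "chain_id", "component", "molecule_class"]
    ).to_csv(OUT / "chain_map.tsv", sep="\t", index=False)
    pd.DataFrame(
        map_rows,
        columns=["structure_id", "chain_id", "residue_number", "reference_position"],
    ).to_csv(OUT / "residue_map.tsv", sep="\t", index=False)

    print("== phylogenetic profiles ==")
    pt = simulate_profiles(
        200, MODULES, presence_rate_per_module=[0.8, 0.6],
        noise_rate=0.05, seed=SEED + 70,
    )
    write_profile_tsv(pt.matrix, OUT / "profiles.tsv")
    truth_sidecar["profile_modules"] = MODULES
    print(f"  200 species x {len(pt.matrix.components)} components, noise 0.05")

    print("== motif homologs ==")
    # mixed population: ~64% human-like (motif in the tail), rest yeast-like
    with_motif = simulate_motif_sequences(77, seed=SEED + 80)
    without = simulate_motif_sequences(43, motif_names=[], seed=SEED + 82)
    sequences = dict(with_motif.sequences)
    regions = dict(with_motif.regions)
    for sid, seq in without.sequences.items():
        sequences[f"y{sid}"] = seq
        regions[f"y{sid}"] = without.regions[sid]
    with open(OUT / "sf3b4_homolog_tails.fasta", "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n{seq}\n")
    pd.DataFrame(
        [(sid, s, e) for sid, (s, e) in regions.items()],
        columns=["sequence_id", "start", "end"],
    ).to_csv(OUT / "tail_regions.tsv", sep="\t", index=False)
    rng = np.random.default_rng(SEED + 81)
    taxa = ["Metazoa", "Fungi", "Viridiplantae", "Sar"]
    pd.DataFrame(
        [(sid, taxa[int(rng.integers(len(taxa)))]) for sid in sequences],
        columns=["sequence_id", "taxon"],
    ).to_csv(OUT / "tail_taxa.tsv", sep="\t", index=False)
    truth_sidecar["planted_motif_hits"] = [
        (h.sequence_id, h.motif, h.start) for h in with_motif.planted_hits
    ]
    print(f"  {len(sequences)} homolog tails "
          f"({len(with_motif.sequences)} with planted motifs, "
          f"{len(without.sequences)} without)")

    print("== annotated site list (hub component) ==")
    rng = np.random.default_rng(SEED + 90)
    positions = sorted(rng.choice(np.arange(1, 240), size=30, replace=False))
    pd.DataFrame(
        {"position": positions, "label": [f"site_{p}" for p in positions]}
    ).to_csv(OUT / "sf3b1_sites.tsv", sep="\t", index=False)
    print(f"  30 annotated positions on SF3b1")

    (OUT / "truth.json").write_text(json.dumps(truth_sidecar, indent=2))
    print(f"done -> {OUT}")


if __name__ == "__main__":
    main()
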