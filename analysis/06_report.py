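#!/usr/bin/env python
"""Join conservation tracks with interfaces into the summary reports.

Recomputes tracks from the component MSAs and interfaces from the toy
structures, then writes under results/report/:
  * per-protein summary (mean JSD, identity, % at interface),
  * the owner x partner interface-conservation matrix,
  * overlapping vs non-overlapping interface conservation comparison
    (Mann–Whitney),
  * critical residue pairs (both sides conserved) for the SF3b1/SF3b6
    interface,
  * an annotated-site conservation report for SF3b1,
  * run metadata with every parameter in force.
"""

import json
from pathlib import Path

import pandas as pd

from sf3bcons.alignment import (
    jsd_track,
    map_reference,
    pairwise_identity,
    read_alignment,
)
from sf3bcons.report import (
    critical_pairs,
    interface_conservation_matrix,
    overlap_compare,
    protein_summary,
    site_report,
)
from sf3bcons.structure import (
    classify_overlap,
    find_contacts,
    interface_sets,
    percent_interface,
    read_structure,
    union_interfaces,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA, OUT = ROOT / "data", ROOT / "report"
HUB = "SF3b1"
CRITICAL_PAIR = ("SF3b1", "SF3b6")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    tracks, mappings, alignments, idents = {}, {}, {}, {}
    for path in sorted(DATA.glob("msa_*.fasta")):
        comp = path.stem.removeprefix("msa_")
        aln = read_alignment(path)
        alignments[comp] = aln
        tracks[comp] = jsd_track(aln)
        idents[comp] = pairwise_identity(aln)
        mappings[comp] = map_reference(aln, aln.ids[0])

    chain_map_df = pd.read_csv(DATA / "chain_map.tsv", sep="\t")
    residue_map = pd.read_csv(DATA / "residue_map.tsv", sep="\t")
    structures, per_structure, all_contacts = {}, {}, []
    for species, grp in chain_map_df.groupby("structure_id"):
        cmap = {r.chain_id: (r.component, r.molecule_class)
                for r in grp.itertuples(index=False)}
        st = read_structure(DATA / f"complex_{species}.pdb", cmap, structure_id=species)
        structures[species] = st
        contacts = find_contacts(st)
        all_contacts.extend(contacts)
        per_structure[species] = interface_sets(contacts)
    pairs = sorted({(s.owner, s.partner)
                    for sets in per_structure.values() for s in sets})
    unions = [
        union_interfaces(
            [(sp, s) for sp, sets in per_structure.items() for s in sets
             if (s.owner, s.partner) == pair],
            residue_map,
        )
        for pair in pairs
    ]

    # --- per-protein summaries
    st0 = structures[sorted(structures)[0]]
    in_structure = {c.component for c in st0.chains}
    rows = []
    for comp in sorted(tracks):
        pct = (
            percent_interface(comp, unions, st0.n_residues(comp))
            if comp in in_structure else float("nan")
        )
        s = protein_summary(comp, tracks[comp], idents[comp], pct,
                            alignments[comp].n_records)
        rows.append((comp, round(s.mean_windowed_jsd, 4),
                     round(s.mean_pairwise_identity, 2), s.n_sequences,
                     s.alignment_length,
                     round(s.percent_interface, 2)))
        print(f"{comp:8s} mean JSD {s.mean_windowed_jsd:.3f}, "
              f"identity {s.mean_pairwise_identity:.1f}%, "
              f"interface {s.percent_interface:.1f}%")
    pd.DataFrame(rows, columns=["component", "mean_windowed_jsd",
                                "mean_pairwise_identity", "n_sequences",
                                "alignment_length", "percent_interface"]
                 ).to_csv(OUT / "protein_summary.tsv", sep="\t", index=False)

    # --- interface conservation matrix
    m = interface_conservation_matrix(unions, tracks, mappings)
    m.values.round(4).to_csv(OUT / "interface_matrix.tsv", sep="\t",
                             index_label="owner")
    (OUT / "interface_matrix_support.json").write_text(
        json.dumps({f"{o}|{p}": int(m.support.loc[o, p])
                    for o in m.support.index for p in m.support.columns
                    if m.support.loc[o, p] > 0}, indent=2)
    )
    print(f"interface matrix: {m.values.notna().sum().sum()} defined cells, "
          f"{len(m.unmapped)} unmapped residues")

    # --- overlapping vs non-overlapping conservation (hub component)
    hub_sets = [u for u in unions if u.owner == HUB]
    classes = classify_overlap(HUB, hub_sets)
    mo, mn, p = overlap_compare(tracks[HUB], classes, mappings[HUB])
    (OUT / "overlap_compare.json").write_text(json.dumps({
        "component": HUB,
        "mean_jsd_overlapping": mo,
        "mean_jsd_non_overlapping": mn,
        "mannwhitney_p": p,
        "n_overlapping": sum(v == "overlapping" for v in classes.values()),
        "n_non_overlapping": sum(v == "non_overlapping" for v in classes.values()),
    }, indent=2))
    print(f"{HUB} overlap comparison: overlapping {mo:.3f} vs "
          f"non-overlapping {mn:.3f} (p={p:.3g})")

    # --- critical pairs on the SF3b1/SF3b6 interface
    struct_map = {
        (r.structure_id, r.chain_id, int(r.residue_number), ""):
            int(r.reference_position)
        for r in residue_map.itertuples(index=False)
    }
    pair_contacts = [c for c in all_contacts
                     if {c.component_a, c.component_b} == set(CRITICAL_PAIR)]
    crit = critical_pairs(pair_contacts, tracks, mappings,
                          structure_mappings=struct_map)
    pd.DataFrame(
        [(c.component_a, c.residue_a, round(c.jsd_a, 4),
          c.component_b, c.residue_b, round(c.jsd_b, 4),
          "+".join(c.contact_types)) for c in crit],
        columns=["component_a", "residue_a", "jsd_a",
                 "component_b", "residue_b", "jsd_b", "contact_types"],
    ).to_csv(OUT / "critical_pairs.tsv", sep="\t", index=False)
    print(f"{CRITICAL_PAIR[0]}/{CRITICAL_PAIR[1]}: "
          f"{len({(c.component_a, c.residue_a, c.residue_b) for c in crit})} "
          f"critical residue pairs of {len(pair_contacts)} contact records")

    # --- annotated-site report on the hub component
    sites = pd.read_csv(DATA / "sf3b1_sites.tsv", sep="\t")
    aln = alignments[HUB]
    half = aln.n_records // 2
    groups = {rid: ("metazoa" if i < half else "fungi")
              for i, rid in enumerate(aln.ids)}
    rep = site_report(sites, tracks[HUB], aln, mappings[HUB], groups)
    rep.sites.round(4).to_csv(OUT / "site_report.tsv", sep="\t", index=False)
    print(f"site report: {len(rep.sites)} mapped sites, "
          f"{len(rep.unmapped)} unmapped; fraction with JSD > "
          f"{rep.threshold}: {rep.fraction_above:.2f}")

    (OUT / "run_metadata.json").write_text(json.dumps({
        "jsd_params": tracks[HUB].params,
        "site_threshold": rep.threshold,
        "critical_pair_thresholds": {"high": 0.5, "low": 0.4},
        "overlap_test": "two-sided Mann-Whitney U",
        "structures": sorted(structures),
        "components": sorted(tracks),
    }, indent=2))
    print(f"done -> {OUT}")


if __name__ == "__main__":
    main()
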