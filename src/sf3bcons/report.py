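"""Summary artifacts: per-protein summaries, interface conservation,
overlap comparisons, critical residue pairs and annotated-site reports.

This layer joins the conservation tracks (sequence space) with interface
residue sets (structure space) through per-component reference mappings,
and produces the quantities the analysis reasons about: mean conservation
per protein and per interface, conservation of bifurcated (overlapping)
vs single-partner interface residues, contact pairs whose two sides are
both conserved (candidate critical interactions), and conservation of
externally annotated site lists (e.g. cancer-mutation or drug-binding
positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import (
    AMINO_ACIDS,
    ConservationTrack,
    MultipleAlignment,
    PairwiseIdentity,
    ReferenceMapping,
    henikoff_weights,
)
from .structure import ContactRecord, InterfaceSet, UnionInterface

__all__ = [
    "ProteinSummary",
    "InterfaceConservationMatrix",
    "CriticalPair",
    "SiteReport",
    "protein_summary",
    "interface_conservation_matrix",
    "overlap_compare",
    "critical_pairs",
    "site_report",
]


@dataclass
class ProteinSummary:
    component: str
    mean_windowed_jsd: float
    mean_pairwise_identity: float
    n_sequences: int
    alignment_length: int
    percent_interface: float


def protein_summary(
    component: str,
    track: ConservationTrack,
    identity: PairwiseIdentity,
    pct_interface: float,
    n_sequences: int,
) -> ProteinSummary:
    """Arithmetic per-protein summary; the JSD mean runs over all columns
    (gap-penalized zeros included)."""
    if track.length == 0:
        raise ValueError("empty conservation track")
    return ProteinSummary(
        component=component,
        mean_windowed_jsd=float(np.mean(track.windowed_jsd)),
        mean_pairwise_identity=identity.mean_percent,
        n_sequences=n_sequences,
        alignment_length=track.length,
        percent_interface=pct_interface,
    )


@dataclass
class InterfaceConservationMatrix:
    """Mean windowed JSD of owner-side interface residues, per pair.

    ``values.loc[owner, partner]`` is NaN where no interface exists (an
    empty interface is undefined, not 0).  ``support`` holds the number of
    mapped residues behind each cell; ``unmapped`` lists residues that
    could not be tied to an alignment column.
    """

    values: pd.DataFrame
    support: pd.DataFrame
    unmapped: list[tuple[str, str, int]] = field(default_factory=list)


def interface_conservation_matrix(
    interfaces: Sequence[UnionInterface | InterfaceSet],
    tracks: Mapping[str, ConservationTrack],
    mappings: Mapping[str, ReferenceMapping],
    score: str = "windowed",
) -> InterfaceConservationMatrix:
    """Owner x partner matrix of mean interface conservation.

    Interface residues must be in reference numbering (``UnionInterface``,
    or an ``InterfaceSet`` whose keys already are reference positions).
    RNA partners appear as columns only (they have no track of their own).
    """
    owners = sorted({i.owner for i in interfaces if i.owner in tracks})
    partners = sorted({i.partner for i in interfaces})
    values = pd.DataFrame(np.nan, index=owners, columns=partners)
    support = pd.DataFrame(0, index=owners, columns=partners, dtype=int)
    unmapped: list[tuple[str, str, int]] = []
    for iface in interfaces:
        if iface.owner not in tracks:
            raise KeyError(f"component {iface.owner!r} has no conservation track")
        track = tracks[iface.owner]
        mapping = mappings[iface.owner]
        arr = track.windowed_jsd if score == "windowed" else track.raw_jsd
        scores = []
        for key in iface.residues:
            pos = key if isinstance(key, int) else key[1]
            col = mapping.column_of(pos)
            if col is None:
                unmapped.append((iface.owner, iface.partner, pos))
                continue
            scores.append(arr[col - 1])
        if scores:
            values.loc[iface.owner, iface.partner] = float(np.mean(scores))
            support.loc[iface.owner, iface.partner] = len(scores)
    return InterfaceConservationMatrix(values=values, support=support, unmapped=unmapped)


def overlap_compare(
    track: ConservationTrack,
    classes: Mapping[int, str],
    mapping: ReferenceMapping,
) -> tuple[float, float, float]:
    """Conservation of overlapping vs non-overlapping interface residues.

    ``classes`` maps reference positions to "overlapping" /
    "non_overlapping" (see ``classify_overlap``).  Returns the two group
    means of windowed JSD and a two-sided Mann–Whitney U p-value — exact
    null for group sizes <=20, normal approximation with tie correction
    otherwise; NaN when either group is empty.
    """
    groups: dict[str, list[float]] = {"overlapping": [], "non_overlapping": []}
    for pos, cls in classes.items():
        col = mapping.column_of(pos if isinstance(pos, int) else pos[1])
        if col is None:
            continue
        groups[cls].append(float(track.windowed_jsd[col - 1]))
    over, non = groups["overlapping"], groups["non_overlapping"]
    mean_over = float(np.mean(over)) if over else float("nan")
    mean_non = float(np.mean(non)) if non else float("nan")
    if not over or not non:
        return mean_over, mean_non, float("nan")
    method = "exact" if max(len(over), len(non)) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(over, non, alternative="two-sided", method=method)
    return mean_over, mean_non, float(res.pvalue)


@dataclass(frozen=True)
class CriticalPair:
    component_a: str
    residue_a: int
    jsd_a: float
    component_b: str
    residue_b: int
    jsd_b: float
    contact_types: tuple[str, ...]
    hotspot: bool | None = None


def critical_pairs(
    contacts: Sequence[ContactRecord],
    tracks: Mapping[str, ConservationTrack],
    mappings: Mapping[str, ReferenceMapping],
    structure_mappings: Mapping | None = None,
    high: float = 0.5,
    low: float = 0.4,
    hotspots: Mapping[tuple[str, int], bool] | None = None,
) -> list[CriticalPair]:
    """Contact residue pairs conserved on both sides.

    A pair qualifies when one side's windowed JSD exceeds ``high``
    (strict) and the other side's is at least ``low`` (inclusive) — the
    two-sided core-interface conservation rule.  ``structure_mappings``
    translates structure residue numbering to reference positions, keyed
    ``(structure_id, chain_id, number, icode) -> reference position``;
    when omitted, structure numbering is taken as reference numbering.
    Result is sorted by min JSD descending.
    """

    def ref_pos(rec: ContactRecord, side: str) -> int | None:
        chain = rec.chain_a if side == "a" else rec.chain_b
        num, icode = rec.residue_a if side == "a" else rec.residue_b
        if structure_mappings is None:
            return num
        return structure_mappings.get((rec.structure_id, chain, num, icode))

    pair_types: dict[tuple, set[str]] = {}
    for rec in contacts:
        ra, rb = ref_pos(rec, "a"), ref_pos(rec, "b")
        if ra is None or rb is None:
            continue
        key = (rec.component_a, ra, rec.component_b, rb)
        pair_types.setdefault(key, set()).add(rec.interaction_type)
    out: list[CriticalPair] = []
    for (comp_a, ra, comp_b, rb), types in pair_types.items():
        col_a = mappings[comp_a].column_of(ra)
        col_b = mappings[comp_b].column_of(rb)
        if col_a is None or col_b is None:
            continue
        ja = float(tracks[comp_a].windowed_jsd[col_a - 1])
        jb = float(tracks[comp_b].windowed_jsd[col_b - 1])
        if max(ja, jb) > high and min(ja, jb) >= low:
            hot = None
            if hotspots is not None:
                hot = hotspots.get((comp_a, ra), False) or hotspots.get((comp_b, rb), False)
            out.append(
                CriticalPair(
                    component_a=comp_a, residue_a=ra, jsd_a=ja,
                    component_b=comp_b, residue_b=rb, jsd_b=jb,
                    contact_types=tuple(sorted(types)), hotspot=hot,
                )
            )
    out.sort(key=lambda p: (-min(p.jsd_a, p.jsd_b), p.component_a, p.residue_a, p.residue_b))
    return out


@dataclass
class SiteReport:
    sites: pd.DataFrame  # position, label, column, windowed_jsd + composition cols
    compositions: dict[int, dict[str, dict[str, float]]]  # pos -> group -> residue freqs
    unmapped: list[tuple[int, str]]
    fraction_above: float
    threshold: float


def site_report(
    sites: pd.DataFrame,
    track: ConservationTrack,
    alignment: MultipleAlignment,
    mapping: ReferenceMapping,
    taxon_groups: Mapping[str, str] | None = None,
    threshold: float = 0.4,
    weighted: bool = True,
) -> SiteReport:
    """Conservation readout for an annotated site list.

    ``sites`` needs columns (position, label) in reference numbering.
    Each site resolves to an alignment column with its windowed JSD and a
    per-taxon-group residue composition (sequence-weighted by default);
    unmappable sites are listed, never dropped.  The summary fraction
    counts sites with JSD strictly above ``threshold``.
    """
    taxon_groups = dict(taxon_groups or {})
    weights = (
        henikoff_weights(alignment)
        if weighted
        else np.full(alignment.n_records, 1.0 / alignment.n_records)
    )
    arr = alignment.array()
    group_of = [taxon_groups.get(rid, "all") for rid in alignment.ids]
    rows = []
    comps: dict[int, dict[str, dict[str, float]]] = {}
    unmapped: list[tuple[int, str]] = []
    jsd_values = []
    for r in sites.itertuples(index=False):
        pos, label = int(r.position), str(r.label)
        col = mapping.column_of(pos)
        if col is None:
            unmapped.append((pos, label))
            continue
        j = float(track.windowed_jsd[col - 1])
        jsd_values.append(j)
        by_group: dict[str, dict[str, float]] = {}
        column = arr[:, col - 1]
        for g in sorted(set(group_of)):
            mask = [gg == g for gg in group_of]
            freqs: dict[str, float] = {}
            total = 0.0
            for ch, w, m in zip(column, weights, mask):
                if m and ch in AMINO_ACIDS:
                    freqs[ch] = freqs.get(ch, 0.0) + float(w)
                    total += float(w)
            if total > 0:
                freqs = {k: v / total for k, v in freqs.items()}
            by_group[g] = freqs
        comps[pos] = by_group
        rows.append((pos, label, col, j))
    table = pd.DataFrame(rows, columns=["position", "label", "column", "windowed_jsd"])
    fraction = (
        float(np.mean([j > threshold for j in jsd_values])) if jsd_values else float("nan")
    )
    return SiteReport(
        sites=table,
        compositions=comps,
        unmapped=unmapped,
        fraction_above=fraction,
        threshold=threshold,
    )
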