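"""Proline-rich motif scanning and homolog classification.

The C-terminal tail of the SF3b4 protein carries short proline-rich
motifs (PPRxxP, PPPPP, PxPPxR, PPLP, PPxY; 'x' = any amino acid) in human
and many other eukaryotes, but not in yeast.  Scanning homolog tails for
these literal wildcard patterns splits homologs into human-like (motif
present, or an externally annotated disordered tail) and yeast-like (no
recognizable feature).  Matching is exact and exhaustive: all overlapping
occurrences are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .alignment import AMINO_ACIDS

__all__ = [
    "MotifPattern",
    "MotifHit",
    "HomologClassification",
    "default_motifs",
    "scan",
    "classify",
    "batch_classify",
    "BatchResult",
]

WILDCARD = "x"


@dataclass(frozen=True)
class MotifPattern:
    """A literal amino-acid pattern with 'x' wildcards."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 4:
            raise ValueError(f"pattern {self.pattern!r} shorter than 4")
        literals = [c for c in self.pattern if c != WILDCARD]
        if not literals:
            raise ValueError("pattern needs at least one literal position")
        bad = set(literals) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-amino-acid literals {sorted(bad)} in {self.pattern!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    def matches_at(self, sequence: str, start0: int) -> bool:
        """Position-wise match at 0-based offset ``start0``."""
        if start0 < 0 or start0 + len(self.pattern) > len(sequence):
            return False
        return all(
            p == WILDCARD or p == s
            for p, s in zip(self.pattern, sequence[start0 : start0 + len(self.pattern)])
        )


_DEFAULT_PATTERNS = ["PPRxxP", "PPPPP", "PxPPxR", "PPLP", "PPxY"]


def default_motifs() -> list[MotifPattern]:
    """The five proline-rich protein-interaction motifs screened for."""
    return [MotifPattern(name=p, pattern=p) for p in _DEFAULT_PATTERNS]


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif: str
    start: int  # 1-based, inclusive
    matched: str


def scan(
    sequence: str,
    region: tuple[int, int] | None = None,
    motifs: Sequence[MotifPattern] | None = None,
    sequence_id: str = "",
) -> list[MotifHit]:
    """All overlapping motif occurrences fully inside ``region``.

    ``region`` is 1-based inclusive ``(start, end)``; default is the full
    sequence.  Hits are sorted by (start, motif name).
    """
    sequence = sequence.upper()
    if region is None:
        region = (1, len(sequence))
    start, end = region
    if not (1 <= start <= end <= len(sequence)):
        raise ValueError(
            f"region {region} invalid for sequence of length {len(sequence)}"
        )
    motifs = default_motifs() if motifs is None else list(motifs)
    hits: list[MotifHit] = []
    for m in motifs:
        last_start = end - len(m) + 1
        for pos in range(start, last_start + 1):
            if m.matches_at(sequence, pos - 1):
                hits.append(
                    MotifHit(
                        sequence_id=sequence_id,
                        motif=m.name,
                        start=pos,
                        matched=sequence[pos - 1 : pos - 1 + len(m)],
                    )
                )
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


CLASS_MOTIF = "human_like_motif"
CLASS_DISORDER = "human_like_disorder"
CLASS_YEAST = "yeast_like"
CLASS_UNSCANNED = "unscanned"


@dataclass
class HomologClassification:
    sequence_id: str
    label: str
    hits: list[MotifHit] = field(default_factory=list)
    disorder: bool = False


def classify(
    hits: Sequence[MotifHit],
    disorder: bool = False,
    sequence_id: str | None = None,
) -> HomologClassification:
    """human-like (motif or disorder) vs yeast-like for one homolog."""
    ids = {h.sequence_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits from multiple sequences: {sorted(ids)}")
    sid = sequence_id if sequence_id is not None else (ids.pop() if ids else "")
    if hits:
        label = CLASS_MOTIF
    elif disorder:
        label = CLASS_DISORDER
    else:
        label = CLASS_YEAST
    return HomologClassification(
        sequence_id=sid, label=label, hits=list(hits), disorder=disorder
    )


@dataclass
class BatchResult:
    classifications: pd.DataFrame  # sequence_id, taxon, label, n_hits, note
    proportions: pd.DataFrame  # taxon x class proportions
    hits: list[MotifHit]

    def counts(self) -> dict[str, int]:
        return self.classifications["label"].value_counts().to_dict()


def batch_classify(
    fasta: str | Path | Mapping[str, str],
    regions: pd.DataFrame,
    taxon_labels: pd.DataFrame | None = None,
    disorder_annotations: pd.DataFrame | None = None,
    motifs: Sequence[MotifPattern] | None = None,
    full_sequence: bool = False,
) -> BatchResult:
    """Scan and classify a set of homologs, with per-taxon proportions.

    ``regions`` needs columns (sequence_id, start, end) delimiting the
    C-terminal tail of each homolog; a sequence without a region row — or
    with a region outside its bounds — is reported as unscanned, never
    silently skipped.  ``full_sequence=True`` ignores regions and scans
    whole sequences.  Class counts always reconcile with the input count.
    """
    if isinstance(fasta, (str, Path)):
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    else:
        seqs = {k: v.upper() for k, v in fasta.items()}
    region_of = {
        str(r.sequence_id): (int(r.start), int(r.end))
        for r in regions.itertuples(index=False)
    }
    taxon_of: dict[str, str] = {}
    if taxon_labels is not None:
        taxon_of = {
            str(r.sequence_id): str(r.taxon)
            for r in taxon_labels.itertuples(index=False)
        }
    disorder_of: dict[str, bool] = {}
    if disorder_annotations is not None:
        disorder_of = {
            str(r.sequence_id): bool(r.disorder)
            for r in disorder_annotations.itertuples(index=False)
        }
    rows = []
    all_hits: list[MotifHit] = []
    for sid in seqs:
        seq = seqs[sid]
        note = ""
        if full_sequence:
            region = (1, len(seq))
        elif sid in region_of:
            region = region_of[sid]
        else:
            rows.append((sid, taxon_of.get(sid, "all"), CLASS_UNSCANNED, 0, "no region"))
            continue
        try:
            hits = scan(seq, region, motifs, sequence_id=sid)
        except ValueError as exc:
            rows.append(
                (sid, taxon_of.get(sid, "all"), CLASS_UNSCANNED, 0, f"bad region: {exc}")
            )
            continue
        cls = classify(hits, disorder=disorder_of.get(sid, False), sequence_id=sid)
        all_hits.extend(hits)
        rows.append((sid, taxon_of.get(sid, "all"), cls.label, len(hits), note))
    table = pd.DataFrame(
        rows, columns=["sequence_id", "taxon", "label", "n_hits", "note"]
    )
    props = (
        table.groupby("taxon")["label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        if len(table)
        else pd.DataFrame()
    )
    return BatchResult(classifications=table, proportions=props, hits=all_hits)
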