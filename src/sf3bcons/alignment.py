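"""Multiple sequence alignments and Jensen–Shannon conservation scoring.

A column of a protein alignment evolving under selective pressure has an
amino-acid distribution that differs from the background distribution of
unconstrained positions.  The Jensen–Shannon divergence (JSD) between the
column distribution ``p_c`` and the BLOSUM62 background ``q`` quantifies that
difference on a [0, 1] scale (base-2 logarithms), with higher values meaning
stronger conservation.  The scoring pipeline here follows the widely used
recipe of Capra-style conservation scoring:

* position-based (Henikoff & Henikoff) sequence weights,
* a small pseudocount on the column distribution,
* a multiplicative ``(1 - gap_fraction)`` penalty on gapped columns,
* a sliding-window smoothing that mixes each column's score with the mean
  score of its sequence neighbourhood.

All knobs are explicit keyword parameters of :func:`jsd_track`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "UNKNOWN",
    "AlignmentError",
    "RaggedAlignmentError",
    "DuplicateIdError",
    "EmptyAlignmentError",
    "AlphabetError",
    "MultipleAlignment",
    "ConservationTrack",
    "PairwiseIdentity",
    "ReferenceMapping",
    "read_alignment",
    "henikoff_weights",
    "column_distribution",
    "blosum62_background",
    "js_divergence",
    "jsd_track",
    "pairwise_identity",
    "map_reference",
    "write_track_tsv",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"
UNKNOWN = "X"
_ALPHABET = frozenset(AMINO_ACIDS) | {GAP, UNKNOWN}

# BLOSUM62 marginal amino-acid frequencies (the background distribution the
# BLOSUM62 substitution table was built from), re-ordered to AMINO_ACIDS and
# renormalized so the published 3-decimal values sum to exactly 1.
_BLOSUM62_MARGINALS_RAW = {
    "A": 0.078, "R": 0.051, "N": 0.041, "D": 0.052, "C": 0.024,
    "Q": 0.034, "E": 0.059, "G": 0.083, "H": 0.025, "I": 0.062,
    "L": 0.092, "K": 0.056, "M": 0.024, "F": 0.044, "P": 0.043,
    "S": 0.059, "T": 0.055, "W": 0.014, "Y": 0.034, "V": 0.072,
}


class AlignmentError(ValueError):
    """Base class for alignment validation failures."""


class RaggedAlignmentError(AlignmentError):
    """Sequences of unequal gapped length."""


class DuplicateIdError(AlignmentError):
    """Two records share an identifier."""


class EmptyAlignmentError(AlignmentError):
    """File or record list contains fewer than two sequences."""


class AlphabetError(AlignmentError):
    """A character outside the 20 amino acids, '-', '.' or 'X'."""


class MultipleAlignment:
    """An immutable gapped protein alignment.

    Parameters
    ----------
    records:
        ``(id, gapped_sequence)`` pairs.  Sequences are uppercased and '.'
        gap characters are normalized to '-'.
    taxa:
        Optional mapping from record id to a taxon/group label.
    """

    def __init__(
        self,
        records: Sequence[tuple[str, str]],
        taxa: Mapping[str, str] | None = None,
    ) -> None:
        if len(records) < 2:
            raise EmptyAlignmentError(
                f"an alignment needs >=2 records, got {len(records)}"
            )
        ids = [str(r[0]) for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate record ids: {dupes}")
        seqs = [str(r[1]).upper().replace(".", GAP) for r in records]
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise RaggedAlignmentError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        (length,) = lengths
        if length == 0:
            raise EmptyAlignmentError("zero-length alignment")
        bad = sorted({c for s in seqs for c in s} - _ALPHABET)
        if bad:
            raise AlphabetError(f"characters outside alphabet: {bad}")
        self.ids: tuple[str, ...] = tuple(ids)
        self.sequences: tuple[str, ...] = tuple(seqs)
        self.taxa = dict(taxa) if taxa else {}
        self._array = np.array([list(s) for s in seqs], dtype="U1")
        # every column must carry at least one informative symbol
        known = (self._array != UNKNOWN).any(axis=0)
        if not known.all():
            cols = [int(c) + 1 for c in np.flatnonzero(~known)]
            raise AlignmentError(f"columns entirely 'X': {cols}")

    @property
    def n_records(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return self._array.shape[1]

    def column(self, column: int) -> str:
        """Return column ``column`` (1-based) as a string of characters."""
        if not 1 <= column <= self.length:
            raise IndexError(f"column {column} outside 1..{self.length}")
        return "".join(self._array[:, column - 1])

    def array(self) -> np.ndarray:
        """(n_records, length) character matrix (copy)."""
        return self._array.copy()

    def sequence_of(self, record_id: str) -> str:
        try:
            return self.sequences[self.ids.index(record_id)]
        except ValueError:
            raise KeyError(f"unknown record id {record_id!r}") from None

    def __repr__(self) -> str:  # pragma: no cover
        return f"MultipleAlignment({self.n_records} records x {self.length} cols)"


def read_alignment(path: str | Path, taxa: Mapping[str, str] | None = None) -> MultipleAlignment:
    """Read an aligned FASTA file into a :class:`MultipleAlignment`.

    Lowercase residues are uppercased and '.' gaps normalized to '-'.
    Distinct error classes signal ragged alignments, duplicate ids and
    empty files.
    """
    path = Path(path)
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise EmptyAlignmentError(f"no FASTA records in {path}")
    return MultipleAlignment(records, taxa=taxa)


def henikoff_weights(alignment: MultipleAlignment) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff 1994).

    In each column, a residue type present in the column distributes mass
    ``1 / (r * s)`` to each of the ``s`` sequences carrying it, where ``r``
    is the number of distinct residue types in that column.  Gap and 'X'
    cells contribute nothing.  Per-sequence totals are normalized to sum
    to 1 over the alignment.
    """
    arr = alignment._array
    n = alignment.n_records
    raw = np.zeros(n)
    for c in range(alignment.length):
        col = arr[:, c]
        mask = np.isin(col, list(AMINO_ACIDS))
        if not mask.any():
            continue
        types, inverse, counts = np.unique(
            col[mask], return_inverse=True, return_counts=True
        )
        r = len(types)
        contrib = 1.0 / (r * counts[inverse])
        raw[mask] += contrib
    # a record with no standard residue at all gets a uniform share so
    # weights stay strictly positive
    raw[raw == 0.0] = 1.0 / n
    return raw / raw.sum()


def blosum62_background() -> np.ndarray:
    """BLOSUM62 marginal amino-acid frequencies, ordered as AMINO_ACIDS.

    Embedded constants; normalized to sum to 1 (within 1e-12).
    """
    q = np.array([_BLOSUM62_MARGINALS_RAW[a] for a in AMINO_ACIDS], dtype=float)
    return q / q.sum()


def column_distribution(
    alignment: MultipleAlignment,
    column: int,
    weights: np.ndarray | None = None,
    pseudocount: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Weighted amino-acid distribution and gap fraction of one column.

    'X' cells are excluded from the distribution but are *not* counted as
    gaps.  ``pseudocount`` is added to every amino acid before
    renormalization.  A column with no amino-acid mass (all gaps / 'X')
    yields the uniform distribution; its gap fraction reflects the actual
    weighted share of '-' cells.
    """
    if not 1 <= column <= alignment.length:
        raise IndexError(f"column {column} outside 1..{alignment.length}")
    col = alignment._array[:, column - 1]
    n = alignment.n_records
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights length must equal number of records")
        w = w / w.sum()
    counts = np.zeros(len(AMINO_ACIDS))
    gap_fraction = 0.0
    for ch, wi in zip(col, w):
        if ch == GAP:
            gap_fraction += wi
        elif ch != UNKNOWN:
            counts[AA_INDEX[ch]] += wi
    counts += pseudocount
    total = counts.sum()
    if total <= 0.0:
        p = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    else:
        p = counts / total
    return p, float(gap_fraction)


def _kl(p: np.ndarray, r: np.ndarray) -> float:
    mask = p > 0.0
    return float(np.sum(p[mask] * np.log2(p[mask] / r[mask])))


def js_divergence(p: np.ndarray, q: np.ndarray, lam: float = 0.5) -> float:
    """Jensen–Shannon divergence, base-2 logs, ``0 log 0 = 0``.

    ``JSD = lam * KL(p || r) + (1 - lam) * KL(q || r)`` with
    ``r = lam * p + (1 - lam) * q``.  For ``lam = 0.5`` the value lies in
    [0, 1] and is symmetric in ``p`` and ``q``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"mismatched supports: {p.shape} vs {q.shape}")
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie in (0, 1)")
    for name, d in (("p", p), ("q", q)):
        if (d < 0).any() or abs(d.sum() - 1.0) > 1e-8:
            raise ValueError(f"{name} is not a probability distribution")
    r = lam * p + (1.0 - lam) * q
    return lam * _kl(p, r) + (1.0 - lam) * _kl(q, r)


@dataclass
class ConservationTrack:
    """Per-column conservation scores for one alignment (1-based columns)."""

    raw_jsd: np.ndarray
    windowed_jsd: np.ndarray
    gap_fraction: np.ndarray
    column_distributions: np.ndarray  # (length, 20)
    params: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.raw_jsd)

    def score(self, column: int, kind: str = "windowed") -> float:
        arr = self.windowed_jsd if kind == "windowed" else self.raw_jsd
        return float(arr[column - 1])


def jsd_track(
    alignment: MultipleAlignment,
    *,
    lam: float = 0.5,
    window: int = 3,
    window_weight: float = 0.5,
    pseudocount: float = 1e-7,
    gap_penalty: bool = True,
    use_weights: bool = True,
) -> ConservationTrack:
    """Score every alignment column by Jensen–Shannon divergence.

    ``raw_jsd(c) = JSD(p_c, background) * (1 - gap_fraction(c))`` when
    ``gap_penalty`` is on.  The windowed score mixes each column with the
    mean raw score of up to ``window`` columns on each side (focal column
    excluded, truncated at the alignment edges); a column with no
    neighbours keeps its raw score.
    """
    background = blosum62_background()
    weights = henikoff_weights(alignment) if use_weights else None
    L = alignment.length
    raw = np.zeros(L)
    gaps = np.zeros(L)
    dists = np.zeros((L, len(AMINO_ACIDS)))
    for c in range(1, L + 1):
        p, gf = column_distribution(alignment, c, weights, pseudocount)
        score = js_divergence(p, background, lam)
        if gap_penalty:
            score *= 1.0 - gf
        raw[c - 1] = score
        gaps[c - 1] = gf
        dists[c - 1] = p
    windowed = raw.copy()
    if window > 0 and window_weight > 0.0:
        for i in range(L):
            lo, hi = max(0, i - window), min(L, i + window + 1)
            neigh = np.concatenate([raw[lo:i], raw[i + 1 : hi]])
            if neigh.size:
                windowed[i] = (1.0 - window_weight) * raw[i] + window_weight * neigh.mean()
    return ConservationTrack(
        raw_jsd=raw,
        windowed_jsd=windowed,
        gap_fraction=gaps,
        column_distributions=dists,
        params={
            "lambda": lam,
            "window": window,
            "window_weight": window_weight,
            "pseudocount": pseudocount,
            "gap_penalty": gap_penalty,
            "use_weights": use_weights,
        },
    )


@dataclass
class PairwiseIdentity:
    """Mean and per-pair percent identity of an alignment.

    Identity of a pair is computed over columns where both sequences are
    non-gap; pairs with no co-aligned column are excluded from the mean
    and listed in ``undefined_pairs``.
    """

    mean_percent: float
    pairs: list[tuple[str, str, float]]
    undefined_pairs: list[tuple[str, str]]


def pairwise_identity(alignment: MultipleAlignment) -> PairwiseIdentity:
    """Average pairwise percent identity (alistat / esl-alipid convention)."""
    arr = alignment._array
    ids = alignment.ids
    pairs: list[tuple[str, str, float]] = []
    undefined: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(alignment.n_records), 2):
        a, b = arr[i], arr[j]
        co = (a != GAP) & (b != GAP)
        n_co = int(co.sum())
        if n_co == 0:
            undefined.append((ids[i], ids[j]))
            continue
        n_id = int(((a == b) & co).sum())
        pairs.append((ids[i], ids[j], 100.0 * n_id / n_co))
    mean = float(np.mean([p[2] for p in pairs])) if pairs else float("nan")
    return PairwiseIdentity(mean_percent=mean, pairs=pairs, undefined_pairs=undefined)


@dataclass
class ReferenceMapping:
    """Bijection between a reference sequence's ungapped positions and columns."""

    reference_id: str
    position_to_column: dict[int, int]
    column_to_position: dict[int, int]

    def column_of(self, position: int) -> int | None:
        return self.position_to_column.get(position)

    def position_of(self, column: int) -> int | None:
        return self.column_to_position.get(column)

    @property
    def n_positions(self) -> int:
        return len(self.position_to_column)


def map_reference(alignment: MultipleAlignment, reference_id: str) -> ReferenceMapping:
    """Map the reference record's 1-based ungapped positions to columns."""
    seq = alignment.sequence_of(reference_id)
    pos2col: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(seq, start=1):
        if ch != GAP:
            pos += 1
            pos2col[pos] = col
    return ReferenceMapping(
        reference_id=reference_id,
        position_to_column=pos2col,
        column_to_position={c: p for p, c in pos2col.items()},
    )


def write_track_tsv(
    track: ConservationTrack,
    path: str | Path,
    mapping: ReferenceMapping | None = None,
) -> None:
    """Write a per-column TSV: column, ref_position, raw/windowed JSD, gaps."""
    with open(path, "w") as fh:
        fh.write("column\tref_position\traw_jsd\twindowed_jsd\tgap_fraction\n")
        for c in range(1, track.length + 1):
            ref = mapping.position_of(c) if mapping else None
            fh.write(
                f"{c}\t{'' if ref is None else ref}\t"
                f"{track.raw_jsd[c - 1]:.6f}\t{track.windowed_jsd[c - 1]:.6f}\t"
                f"{track.gap_fraction[c - 1]:.6f}\n"
            )
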