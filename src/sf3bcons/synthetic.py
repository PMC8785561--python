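"""Seeded synthetic inputs with known ground truth.

Every downstream stage of the pipeline (conservation scoring, contact
detection, profile clustering, motif scanning) is exercised end-to-end on
generated data whose truth is recorded alongside:

* MSAs with planted conserved columns (near-point-mass residue
  distributions) among variable columns drawn from the BLOSUM62
  background, with i.i.d. per-cell gaps in variable columns only;
* toy multi-chain complexes of well-separated pseudo-residues with an
  exact list of planted inter-chain contacts and a guaranteed clearance
  margin everywhere else;
* binary species x component presence matrices in which components of
  the same module share one Bernoulli draw per species, plus bit-flip
  noise;
* protein sequences with proline-rich motifs planted at recorded
  positions in an otherwise motif-free background.

All generators take one explicit integer seed and are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, MultipleAlignment, blosum62_background
from .motifs import MotifHit, MotifPattern, default_motifs, scan
from .profiles import ProfileMatrix
from .structure import Atom, Chain, ComplexStructure, Residue

__all__ = [
    "MsaTruth",
    "ComplexTruth",
    "ProfileTruth",
    "MotifTruth",
    "simulate_msa",
    "simulate_complex",
    "simulate_profiles",
    "simulate_motif_sequences",
    "write_msa_fasta",
    "write_profile_tsv",
    "write_motif_fasta",
]

_CONSERVED_MASS = 0.95  # dominant-residue frequency in a conserved column


@dataclass
class MsaTruth:
    alignment: MultipleAlignment
    conserved_columns: set[int]  # 1-based
    gap_columns: set[int]

    def truth_json(self) -> str:
        return json.dumps(
            {
                "conserved_columns": sorted(self.conserved_columns),
                "gap_columns": sorted(self.gap_columns),
            }
        )


def simulate_msa(
    n_seqs: int,
    n_cols: int,
    n_conserved: int,
    gap_rate: float = 0.05,
    seed: int = 0,
) -> MsaTruth:
    """Alignment with ``n_conserved`` planted conserved columns.

    Conserved columns put mass 0.95 on one dominant residue with the
    remaining 5% spread uniformly over the other 19; variable columns are
    i.i.d. BLOSUM62-background draws.  Gaps are inserted per cell at
    ``gap_rate`` in variable columns only.
    """
    if n_seqs < 2 or n_cols < 1:
        raise ValueError("need n_seqs >= 2 and n_cols >= 1")
    if not 0 <= n_conserved <= n_cols:
        raise ValueError("n_conserved must lie in [0, n_cols]")
    if not 0.0 <= gap_rate < 1.0:
        raise ValueError("gap_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    background = blosum62_background()
    aa = np.array(list(AMINO_ACIDS))
    conserved = set()
    if n_conserved:
        conserved = set(
            int(c) + 1 for c in rng.choice(n_cols, size=n_conserved, replace=False)
        )
    cells = np.empty((n_seqs, n_cols), dtype="U1")
    gap_columns: set[int] = set()
    for c in range(1, n_cols + 1):
        if c in conserved:
            # guarantee the realized dominant frequency is >= 0.95: fix the
            # dominant count and scatter the substituted cells uniformly
            dom = aa[rng.integers(len(aa))]
            n_dom = int(np.ceil(_CONSERVED_MASS * n_seqs))
            col = np.full(n_seqs, dom, dtype="U1")
            if n_dom < n_seqs:
                others = np.array([a for a in aa if a != dom])
                subs = rng.choice(n_seqs, size=n_seqs - n_dom, replace=False)
                col[subs] = rng.choice(others, size=n_seqs - n_dom)
            cells[:, c - 1] = col
        else:
            cells[:, c - 1] = rng.choice(aa, size=n_seqs, p=background)
            if gap_rate > 0.0:
                gaps = rng.random(n_seqs) < gap_rate
                if gaps.any():
                    cells[gaps, c - 1] = "-"
                    gap_columns.add(c)
    width = len(str(n_seqs))
    records = [
        (f"seq{i + 1:0{width}d}", "".join(cells[i])) for i in range(n_seqs)
    ]
    return MsaTruth(
        alignment=MultipleAlignment(records),
        conserved_columns=conserved,
        gap_columns=gap_columns,
    )


@dataclass
class ComplexTruth:
    structure: ComplexStructure
    # (chain_a, residue_number_a, chain_b, residue_number_b, distance)
    planted_contacts: list[tuple[str, int, str, int, float]]


_SIDECHAIN_MENU = [
    ("SER", "OG", "O"),
    ("ASP", "OD1", "O"),
    ("LYS", "NZ", "N"),
    ("LEU", "CD1", "C"),
]

_GRID_SPACING = 28.0  # A between pseudo-residues within a chain
_CHAIN_GAP = 80.0  # A between chain bounding boxes
_CLEARANCE = 6.5  # no unplanned inter-chain heavy-atom pair closer than this


def _place_chain(
    chain_id: str,
    component: str,
    mclass: str,
    n_residues: int,
    origin: np.ndarray,
    rng: np.random.Generator,
    sidechains: bool,
) -> Chain:
    side = int(np.ceil(n_residues ** (1.0 / 3.0)))
    chain = Chain(chain_id=chain_id, component=component, molecule_class=mclass)
    for r in range(n_residues):
        i, j, k = r % side, (r // side) % side, r // (side * side)
        ca = origin + _GRID_SPACING * np.array([i, j, k], dtype=float)
        if sidechains and mclass == "protein":
            name, sc_atom, sc_elem = _SIDECHAIN_MENU[
                int(rng.integers(len(_SIDECHAIN_MENU)))
            ]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            atoms = [
                Atom(name="CA", element="C", coord=ca.copy()),
                Atom(name=sc_atom, element=sc_elem, coord=ca + 1.55 * direction),
            ]
        else:
            name = "GLY" if mclass == "protein" else "A"
            atoms = [Atom(name="CA" if mclass == "protein" else "C1'",
                          element="C", coord=ca.copy())]
        chain.residues.append(
            Residue(number=r + 1, insertion_code="", name=name, atoms=atoms)
        )
    return chain


def _min_interchain_gaps(structure: ComplexStructure) -> dict[tuple, float]:
    """Minimum heavy-atom distance for every inter-chain residue pair."""
    out: dict[tuple, float] = {}
    chains = structure.chains
    for ai in range(len(chains)):
        for bi in range(ai + 1, len(chains)):
            for res_a in chains[ai].residues:
                xa = np.array([at.coord for at in res_a.atoms])
                for res_b in chains[bi].residues:
                    xb = np.array([at.coord for at in res_b.atoms])
                    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2).min()
                    out[
                        (chains[ai].chain_id, res_a.number,
                         chains[bi].chain_id, res_b.number)
                    ] = float(d)
    return out


def simulate_complex(
    chain_spec: Sequence[tuple[str, str, int]],
    n_contacts: int,
    seed: int = 0,
    sidechains: bool = False,
    max_retries: int = 20,
) -> ComplexTruth:
    """Toy multi-chain complex with exactly ``n_contacts`` planted contacts.

    ``chain_spec`` lists ``(component_label, molecule_class, n_residues)``
    per chain (chain ids A, B, ...).  Pseudo-residues (single CA, or CA
    plus one side-chain atom with ``sidechains=True``) sit on a wide grid;
    each planted contact moves one "guest" residue next to a "host"
    residue of another chain so the designated atom pair lies at a drawn
    distance in [3.0, 4.9] A.  The construction is verified: planted
    residue pairs are the only inter-chain pairs within 6.5 A; failure
    after ``max_retries`` raises ``RuntimeError``.
    """
    if len(chain_spec) < 2:
        raise ValueError("need at least 2 chains")
    if n_contacts < 0:
        raise ValueError("n_contacts must be >= 0")
    n_pairs_possible = sum(n for _, _, n in chain_spec) // 2
    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        structure = ComplexStructure(structure_id=f"toy_seed{seed}")
        side_max = int(np.ceil(max(n for _, _, n in chain_spec) ** (1.0 / 3.0)))
        extent = side_max * _GRID_SPACING
        for idx, (component, mclass, n_res) in enumerate(chain_spec):
            origin = np.array([idx * (extent + _CHAIN_GAP), 0.0, 0.0])
            structure.chains.append(
                _place_chain(
                    chr(ord("A") + idx), component, mclass, n_res, origin, rng, sidechains
                )
            )
        used: set[tuple[str, int]] = set()
        planted: list[tuple[str, int, str, int, float]] = []
        ok = True
        for _ in range(n_contacts):
            free = [
                (ch, res)
                for ch in structure.chains
                for res in ch.residues
                if (ch.chain_id, res.number) not in used
            ]
            host_pool = [f for f in free]
            rng.shuffle(host_pool)
            pair = None
            for host_chain, host_res in host_pool:
                guests = [
                    (ch, res) for ch, res in free
                    if ch.chain_id != host_chain.chain_id
                ]
                if guests:
                    pair = (host_chain, host_res) + guests[
                        int(rng.integers(len(guests)))
                    ]
                    break
            if pair is None:
                ok = False
                break
            host_chain, host_res, guest_chain, guest_res = pair
            host_atom = host_res.atoms[int(rng.integers(len(host_res.atoms)))]
            guest_atom = guest_res.atoms[int(rng.integers(len(guest_res.atoms)))]
            d = float(rng.uniform(3.0, 4.9))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            target = host_atom.coord + d * direction
            shift = target - guest_atom.coord
            for atom in guest_res.atoms:
                atom.coord = atom.coord + shift
            used.add((host_chain.chain_id, host_res.number))
            used.add((guest_chain.chain_id, guest_res.number))
            a, b = sorted(
                [
                    (host_chain.chain_id, host_res.number),
                    (guest_chain.chain_id, guest_res.number),
                ]
            )
            dist = float(np.linalg.norm(host_atom.coord - guest_atom.coord))
            planted.append((a[0], a[1], b[0], b[1], dist))
        if not ok:
            continue
        gaps = _min_interchain_gaps(structure)
        planted_keys = {(a, ra, b, rb) for a, ra, b, rb, _ in planted}
        valid = all(
            (key in planted_keys) == (d <= 5.0)
            and (key in planted_keys or d > _CLEARANCE)
            for key, d in gaps.items()
        )
        if valid:
            return ComplexTruth(structure=structure, planted_contacts=sorted(planted))
    raise RuntimeError(
        f"could not place {n_contacts} contacts after {max_retries} attempts"
    )


@dataclass
class ProfileTruth:
    matrix: ProfileMatrix
    modules: dict[str, list[str]]
    noise_rate: float


def simulate_profiles(
    n_species: int,
    modules: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    presence_rate_per_module: float | Sequence[float] = 0.7,
    noise_rate: float = 0.05,
    seed: int = 0,
) -> ProfileTruth:
    """Presence/absence matrix with planted co-occurring modules.

    Components in the same module share one Bernoulli(presence rate) draw
    per species; every cell is then flipped independently with
    probability ``noise_rate`` (< 0.5).
    """
    if isinstance(modules, Mapping):
        module_map = {str(k): list(v) for k, v in modules.items()}
    else:
        module_map = {f"module{i + 1}": list(m) for i, m in enumerate(modules)}
    if any(len(m) == 0 for m in module_map.values()):
        raise ValueError("empty module")
    all_comps = [c for m in module_map.values() for c in m]
    if len(set(all_comps)) != len(all_comps):
        raise ValueError("modules must partition distinct component labels")
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must lie in [0, 0.5)")
    names = list(module_map)
    if np.isscalar(presence_rate_per_module):
        rates = {m: float(presence_rate_per_module) for m in names}
    else:
        rates = {m: float(r) for m, r in zip(names, presence_rate_per_module)}
    rng = np.random.default_rng(seed)
    width = len(str(n_species))
    species = [f"sp{i + 1:0{width}d}" for i in range(n_species)]
    data = pd.DataFrame(0, index=species, columns=all_comps, dtype=np.int8)
    for m in names:
        draws = (rng.random(n_species) < rates[m]).astype(np.int8)
        for comp in module_map[m]:
            data[comp] = draws
    if noise_rate > 0.0:
        flips = rng.random(data.shape) < noise_rate
        data = data ^ flips.astype(np.int8)
    return ProfileTruth(
        matrix=ProfileMatrix(data=data),
        modules=module_map,
        noise_rate=float(noise_rate),
    )


@dataclass
class MotifTruth:
    sequences: dict[str, str]
    planted_hits: list[MotifHit]
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)


def _clean_background(
    length: int, motifs: Sequence[MotifPattern], rng: np.random.Generator
) -> str:
    """Uniform-random sequence rejected until free of any default motif."""
    aa = np.array(list(AMINO_ACIDS))
    for _ in range(1000):
        seq = "".join(rng.choice(aa, size=length))
        if not scan(seq, motifs=motifs):
            return seq
    raise RuntimeError("could not draw a motif-free background sequence")


def simulate_motif_sequences(
    n_seqs: int,
    motif_names: Sequence[str] | None = None,
    region: tuple[int, int] | None = None,
    seed: int = 0,
    seq_length: int = 150,
) -> MotifTruth:
    """Sequences with one planted motif each in an otherwise clean background.

    ``motif_names`` selects from the default motif set (empty list plants
    nothing); ``region`` restricts planting (default: the C-terminal
    third, emulating a tail scan).  After planting, each sequence is
    re-scanned and accepted only if the hit set equals the planted set,
    so spurious matches cannot arise.
    """
    all_motifs = {m.name: m for m in default_motifs()}
    if motif_names is None:
        motif_names = list(all_motifs)
    unknown = set(motif_names) - set(all_motifs)
    if unknown:
        raise ValueError(f"unknown motif names {sorted(unknown)}")
    if region is None:
        region = (2 * seq_length // 3 + 1, seq_length)
    start, end = region
    if not (1 <= start <= end <= seq_length):
        raise ValueError(f"region {region} invalid for length {seq_length}")
    rng = np.random.default_rng(seed)
    scan_set = list(all_motifs.values())
    non_p = [a for a in AMINO_ACIDS if a != "P"]
    sequences: dict[str, str] = {}
    planted: list[MotifHit] = []
    regions: dict[str, tuple[int, int]] = {}
    width = len(str(max(n_seqs, 1)))
    for i in range(n_seqs):
        sid = f"hom{i + 1:0{width}d}"
        regions[sid] = region
        if not motif_names:
            sequences[sid] = _clean_background(seq_length, scan_set, rng)
            continue
        motif = all_motifs[motif_names[i % len(motif_names)]]
        for _ in range(200):
            background = _clean_background(seq_length, scan_set, rng)
            pos = int(rng.integers(start, end - len(motif) + 2))
            instance = "".join(
                non_p[int(rng.integers(len(non_p)))] if c == "x" else c
                for c in motif.pattern
            )
            seq = background[: pos - 1] + instance + background[pos - 1 + len(motif):]
            hits = scan(seq, motifs=scan_set, sequence_id=sid)
            if [(h.motif, h.start) for h in hits] == [(motif.name, pos)]:
                sequences[sid] = seq
                planted.extend(hits)
                break
        else:
            raise RuntimeError(f"could not plant motif {motif.name} in {sid}")
    return MotifTruth(sequences=sequences, planted_hits=planted, regions=regions)


# --------------------------------------------------------------------------
# writers


def write_msa_fasta(alignment: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in zip(alignment.ids, alignment.sequences):
            fh.write(f">{rid}\n{seq}\n")


def write_profile_tsv(matrix: ProfileMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="species")


def write_motif_fasta(truth: MotifTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in truth.sequences.items():
            fh.write(f">{sid}\n{seq}\n")
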