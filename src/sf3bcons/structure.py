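"""Multi-chain complex structures, inter-chain contacts and interfaces.

The interface analysis works on cryo-EM/X-ray models of a multi-protein
(and protein–RNA) complex.  Chains are mapped to named components via an
explicit chain map; interface residues are defined geometrically as
residues with at least one qualifying inter-chain heavy-atom contact.
Contact subtypes (hydrogen bond, ionic, hydrophobic) use hydrogen-free
distance criteria, since cryo-EM models rarely include hydrogens:

* generic: any inter-chain heavy-atom pair within 5.0 A,
* hbond: donor-class vs acceptor-class atoms within 3.5 A,
* ionic: Asp/Glu carboxylate vs Lys/Arg/His side-chain nitrogens — or a
  protein charged group vs an RNA phosphate — within 6.0 A,
* hydrophobic: apolar side-chain carbons within 5.0 A.

Interface sets are unioned across structures (different species and
assembly states) through explicit residue-numbering maps, and interface
residues are classified into core/rim by relative solvent accessibility
(Shrake–Rupley SASA against Gly-X-Gly reference maxima).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "ComplexStructure",
    "ContactParams",
    "ContactRecord",
    "InterfaceSet",
    "ResidueEvidence",
    "UnionInterface",
    "CoreRimLabel",
    "MappingConflictError",
    "read_structure",
    "write_pdb",
    "find_contacts",
    "interface_sets",
    "union_interfaces",
    "percent_interface",
    "classify_overlap",
    "sasa",
    "relative_sasa",
    "label_core_rim",
    "core_rim",
    "MAX_SASA",
    "VDW_RADII",
]

ResidueKey = tuple[str, int, str]  # (chain_id, residue number, insertion code)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
_DEFAULT_VDW = 1.70

# Theoretical maximum SASA (A^2) of residue X in a Gly-X-Gly tripeptide
# (Tien et al. 2013), used to normalize per-residue SASA to rSASA %.
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# --- hydrogen-free atom-role tables (simplified, heavy atoms only) ---------

_PROTEIN_DONORS = {
    ("*", "N"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("LYS", "NZ"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("TRP", "NE1"),
    ("ASN", "ND2"), ("GLN", "NE2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("CYS", "SG"),
}
_PROTEIN_ACCEPTORS = {
    ("*", "O"), ("*", "OXT"),
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("MET", "SD"),
}
_RNA_DONORS = {
    ("*", "O2'"),
    ("G", "N1"), ("G", "N2"), ("A", "N6"), ("C", "N4"), ("U", "N3"),
}
_RNA_ACCEPTORS = {
    ("*", "OP1"), ("*", "OP2"), ("*", "O2'"), ("*", "O3'"),
    ("*", "O4'"), ("*", "O5'"),
    ("A", "N1"), ("A", "N3"), ("A", "N7"),
    ("G", "O6"), ("G", "N3"), ("G", "N7"),
    ("C", "O2"), ("C", "N3"),
    ("U", "O2"), ("U", "O4"),
}
_NEGATIVE_GROUP = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}
_POSITIVE_GROUP = {
    ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
_PHOSPHATE = {"P", "OP1", "OP2"}
_APOLAR_CARBONS = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "PRO": {"CB", "CG", "CD"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
}

_RNA_NAMES = {"A", "C", "G", "U", "RA", "RC", "RG", "RU"}


def _in_table(table: set, resname: str, atom: str) -> bool:
    return (resname, atom) in table or ("*", atom) in table


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom

    def distance_to(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.coord - other.coord))


@dataclass
class Residue:
    number: int
    insertion_code: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in residue {self.name}{self.number}")


@dataclass
class Chain:
    chain_id: str
    component: str
    molecule_class: str  # "protein" | "RNA"
    residues: list[Residue] = field(default_factory=list)


@dataclass
class ComplexStructure:
    structure_id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in structure {self.structure_id}")

    def chains_of(self, component: str) -> list[Chain]:
        return [ch for ch in self.chains if ch.component == component]

    def n_residues(self, component: str | None = None) -> int:
        chains = self.chains if component is None else self.chains_of(component)
        return sum(len(ch.residues) for ch in chains)


def read_structure(
    path: str | Path,
    chain_map: Mapping[str, tuple[str, str]],
    structure_id: str | None = None,
) -> ComplexStructure:
    """Read a PDB/mmCIF file, keeping only chains named in ``chain_map``.

    ``chain_map`` maps chain id to ``(component_label, molecule_class)``.
    Hydrogens and waters are dropped; altlocs are resolved to the highest
    occupancy (ties: first encountered).  Unmapped chains are ignored with
    a warning; a chain map naming an absent chain raises ``KeyError``.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    present = {ch.name for ch in model}
    missing = sorted(set(chain_map) - present)
    if missing:
        raise KeyError(f"chain map names absent chains: {missing}")
    unmapped = sorted(present - set(chain_map))
    if unmapped:
        warnings.warn(f"ignoring unmapped chains {unmapped} in {path.name}")
    out = ComplexStructure(structure_id=structure_id or path.stem)
    for gchain in model:
        if gchain.name not in chain_map:
            continue
        component, mclass = chain_map[gchain.name]
        chain = Chain(chain_id=gchain.name, component=component, molecule_class=mclass)
        for gres in gchain:
            if gres.name in _WATER_NAMES:
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in gres:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            if not best:
                continue
            res = Residue(
                number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                name=gres.name.strip(),
                atoms=[
                    Atom(
                        name=a.name,
                        element=a.element.name.upper(),
                        coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    )
                    for a in best.values()
                ],
            )
            chain.residues.append(res)
        seen: set[tuple[int, str]] = set()
        for res in chain.residues:
            key = (res.number, res.insertion_code)
            if key in seen:
                raise ValueError(
                    f"duplicate residue {key} in chain {chain.chain_id} of {path.name}"
                )
            seen.add(key)
        out.chains.append(chain)
    return out


def write_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write a ComplexStructure as a PDB file (occupancy 1.00, B 0.00)."""
    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = 1.0
                ga.b_iso = 0.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass
class ContactParams:
    """Distance criteria (Angstrom) for inter-chain contact detection."""

    generic_cutoff: float = 5.0
    hbond_cutoff: float = 3.5
    ionic_cutoff: float = 6.0
    hydrophobic_cutoff: float = 5.0

    def __post_init__(self) -> None:
        for name in ("generic_cutoff", "hbond_cutoff", "ionic_cutoff", "hydrophobic_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def max_cutoff(self) -> float:
        return max(
            self.generic_cutoff, self.hbond_cutoff,
            self.ionic_cutoff, self.hydrophobic_cutoff,
        )


@dataclass(frozen=True)
class ContactRecord:
    structure_id: str
    chain_a: str
    component_a: str
    residue_a: tuple[int, str]
    residue_name_a: str
    atom_a: str
    chain_b: str
    component_b: str
    residue_b: tuple[int, str]
    residue_name_b: str
    atom_b: str
    distance: float
    interaction_type: str  # hbond | ionic | hydrophobic | generic


def _atom_roles(chain: Chain, res: Residue, atom: Atom) -> dict:
    """Precompute role flags for one atom."""
    if chain.molecule_class == "RNA":
        name = res.name.lstrip("R")  # RA -> A etc.
        return {
            "donor": _in_table(_RNA_DONORS, name, atom.name),
            "acceptor": _in_table(_RNA_ACCEPTORS, name, atom.name),
            "charge": "phos" if atom.name in _PHOSPHATE else None,
            "apolar": False,
        }
    charge = None
    if (res.name, atom.name) in _NEGATIVE_GROUP:
        charge = "neg"
    elif (res.name, atom.name) in _POSITIVE_GROUP:
        charge = "pos"
    return {
        "donor": _in_table(_PROTEIN_DONORS, res.name, atom.name),
        "acceptor": _in_table(_PROTEIN_ACCEPTORS, res.name, atom.name),
        "charge": charge,
        "apolar": atom.element == "C"
        and atom.name in _APOLAR_CARBONS.get(res.name, ()),
    }


def _ionic_pair(ca: str | None, cb: str | None) -> bool:
    if ca is None or cb is None:
        return False
    if {ca, cb} == {"neg", "pos"}:
        return True
    # protein charged group vs RNA phosphate
    return ("phos" in (ca, cb)) and (("pos" in (ca, cb)) or ("neg" in (ca, cb)))


def find_contacts(
    structure: ComplexStructure, params: ContactParams | None = None
) -> list[ContactRecord]:
    """All qualifying inter-chain heavy-atom contacts, one record per type.

    A KD-tree restricts candidate pairs to the largest cutoff in force; the
    result is identical to exhaustive all-pairs search.  Records are sorted
    by (chain_a, residue_a, atom_a, chain_b, residue_b, atom_b, type); the
    a-side is the chain earlier in the structure's chain order.
    """
    params = params or ContactParams()
    if len(structure.chains) < 2:
        raise ValueError("contact detection needs >=2 chains")
    coords, meta = [], []
    chain_rank = {ch.chain_id: i for i, ch in enumerate(structure.chains)}
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                if atom.element == "H":
                    continue
                coords.append(atom.coord)
                meta.append((chain, res, atom, _atom_roles(chain, res, atom)))
    xyz = np.asarray(coords)
    tree = cKDTree(xyz)
    records: list[ContactRecord] = []
    for i, j in tree.query_pairs(params.max_cutoff):
        ch_i, res_i, at_i, roles_i = meta[i]
        ch_j, res_j, at_j, roles_j = meta[j]
        if ch_i.chain_id == ch_j.chain_id:
            continue
        if chain_rank[ch_i.chain_id] > chain_rank[ch_j.chain_id]:
            (ch_i, res_i, at_i, roles_i), (ch_j, res_j, at_j, roles_j) = (
                (ch_j, res_j, at_j, roles_j),
                (ch_i, res_i, at_i, roles_i),
            )
        d = float(np.linalg.norm(
            np.asarray(meta[i][2].coord) - np.asarray(meta[j][2].coord)
        ))
        types = []
        if d <= params.generic_cutoff:
            types.append("generic")
        if d <= params.hbond_cutoff and (
            (roles_i["donor"] and roles_j["acceptor"])
            or (roles_i["acceptor"] and roles_j["donor"])
        ):
            types.append("hbond")
        if d <= params.ionic_cutoff and _ionic_pair(roles_i["charge"], roles_j["charge"]):
            types.append("ionic")
        if d <= params.hydrophobic_cutoff and roles_i["apolar"] and roles_j["apolar"]:
            types.append("hydrophobic")
        for t in types:
            records.append(
                ContactRecord(
                    structure_id=structure.structure_id,
                    chain_a=ch_i.chain_id,
                    component_a=ch_i.component,
                    residue_a=(res_i.number, res_i.insertion_code),
                    residue_name_a=res_i.name,
                    atom_a=at_i.name,
                    chain_b=ch_j.chain_id,
                    component_b=ch_j.component,
                    residue_b=(res_j.number, res_j.insertion_code),
                    residue_name_b=res_j.name,
                    atom_b=at_j.name,
                    distance=d,
                    interaction_type=t,
                )
            )
    records.sort(
        key=lambda r: (
            r.chain_a, r.residue_a, r.atom_a,
            r.chain_b, r.residue_b, r.atom_b, r.interaction_type,
        )
    )
    return records


@dataclass
class ResidueEvidence:
    structures: set[str] = field(default_factory=set)
    interaction_types: set[str] = field(default_factory=set)


@dataclass
class InterfaceSet:
    """Owner-side interface residues of one ordered component pair."""

    owner: str
    partner: str
    residues: dict[ResidueKey, ResidueEvidence] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.residues)


def interface_sets(contacts: Sequence[ContactRecord]) -> list[InterfaceSet]:
    """Two ordered InterfaceSets per touching unordered component pair.

    Each residue appears once per set regardless of contact multiplicity.
    """
    by_pair: dict[tuple[str, str], InterfaceSet] = {}
    for rec in contacts:
        for owner, partner, chain, res in (
            (rec.component_a, rec.component_b, rec.chain_a, rec.residue_a),
            (rec.component_b, rec.component_a, rec.chain_b, rec.residue_b),
        ):
            key = (owner, partner)
            iface = by_pair.setdefault(key, InterfaceSet(owner=owner, partner=partner))
            ev = iface.residues.setdefault((chain,) + res, ResidueEvidence())
            ev.structures.add(rec.structure_id)
            ev.interaction_types.add(rec.interaction_type)
    return [by_pair[k] for k in sorted(by_pair)]


class MappingConflictError(ValueError):
    """One structure residue maps to two different reference positions."""


@dataclass
class UnionInterface:
    """Interface residues in reference numbering, unioned across structures."""

    owner: str
    partner: str
    residues: dict[int, ResidueEvidence] = field(default_factory=dict)
    unmapped: list[tuple[str, ResidueKey]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.residues)


def _mapping_lookup(mapping) -> dict:
    """Normalize a residue-numbering map to {(structure_id, chain, num, icode): ref}."""
    if isinstance(mapping, pd.DataFrame):
        table: dict[tuple, int] = {}
        for row in mapping.itertuples(index=False):
            d = row._asdict()
            key = (
                str(d["structure_id"]),
                str(d["chain_id"]),
                int(d["residue_number"]),
                str(d.get("insertion_code", "") or ""),
            )
            ref = int(d["reference_position"])
            if key in table and table[key] != ref:
                raise MappingConflictError(
                    f"residue {key} maps to both {table[key]} and {ref}"
                )
            table[key] = ref
        return table
    return dict(mapping)


def union_interfaces(
    per_structure_sets: Sequence[tuple[str, InterfaceSet]],
    mapping,
) -> UnionInterface:
    """Union owner-side interface residues across structures.

    Parameters
    ----------
    per_structure_sets:
        ``(structure_id, InterfaceSet)`` pairs; all sets must share the
        same ordered (owner, partner) component pair.
    mapping:
        A DataFrame with columns structure_id, chain_id, residue_number,
        [insertion_code], reference_position — or an equivalent dict keyed
        by ``(structure_id, chain_id, residue_number, insertion_code)``.

    Residues without a mapping row are collected in ``unmapped``, never
    silently dropped.
    """
    if not per_structure_sets:
        raise ValueError("no interface sets to union")
    pairs = {(s.owner, s.partner) for _, s in per_structure_sets}
    if len(pairs) != 1:
        raise ValueError(f"sets span multiple component pairs: {sorted(pairs)}")
    (owner, partner), = pairs
    table = _mapping_lookup(mapping)
    out = UnionInterface(owner=owner, partner=partner)
    for structure_id, iface in per_structure_sets:
        for (chain_id, num, icode), ev in iface.residues.items():
            ref = table.get((structure_id, chain_id, num, icode))
            if ref is None:
                out.unmapped.append((structure_id, (chain_id, num, icode)))
                continue
            tgt = out.residues.setdefault(ref, ResidueEvidence())
            tgt.structures |= ev.structures | {structure_id}
            tgt.interaction_types |= ev.interaction_types
    return out


def percent_interface(
    component: str,
    sets: Sequence[InterfaceSet | UnionInterface],
    denominator: int,
) -> float:
    """Percent of a component's residues at any inter-component interface.

    The numerator is the union over partners of owner-side residues, so a
    residue contacting several partners counts once.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    union: set = set()
    for s in sets:
        if s.owner != component:
            continue
        union |= set(s.residues)
    return 100.0 * len(union) / denominator


def classify_overlap(
    component: str, sets: Sequence[InterfaceSet | UnionInterface]
) -> dict:
    """Label each interface residue overlapping / non_overlapping.

    A residue is overlapping when it appears in owner-side sets for >=2
    distinct partners (bifurcated interactions).
    """
    owned = [s for s in sets if s.owner == component]
    if not owned:
        raise ValueError(f"no interface sets owned by {component!r}")
    partners: dict = {}
    for s in owned:
        for key in s.residues:
            partners.setdefault(key, set()).add(s.partner)
    return {
        key: ("overlapping" if len(p) >= 2 else "non_overlapping")
        for key, p in partners.items()
    }


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n)
    golden = (1.0 + 5.0 ** 0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(
    structure: ComplexStructure,
    chains: Iterable[str] | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> dict[ResidueKey, float]:
    """Per-residue solvent-accessible surface area (Shrake–Rupley), A^2.

    Heavy atoms only, standard van der Waals radii, water probe 1.4 A.
    ``chains`` selects the subset considered present (default: all).
    """
    selected = set(chains) if chains is not None else {c.chain_id for c in structure.chains}
    atoms: list[tuple[ResidueKey, np.ndarray, float]] = []
    for chain in structure.chains:
        if chain.chain_id not in selected:
            continue
        for res in chain.residues:
            key = (chain.chain_id, res.number, res.insertion_code)
            for atom in res.atoms:
                if atom.element == "H":
                    continue
                r = VDW_RADII.get(atom.element, _DEFAULT_VDW)
                atoms.append((key, atom.coord, r))
    if not atoms:
        raise ValueError("empty chain selection")
    xyz = np.array([a[1] for a in atoms])
    radii = np.array([a[2] for a in atoms])
    ext = radii + probe_radius
    points = _sphere_points(n_points)
    tree = cKDTree(xyz)
    areas: dict[ResidueKey, float] = {}
    max_ext = ext.max()
    for idx, (key, center, r) in enumerate(atoms):
        ri = r + probe_radius
        neigh = [
            j for j in tree.query_ball_point(center, ri + max_ext)
            if j != idx and np.linalg.norm(xyz[j] - center) < ri + ext[j]
        ]
        surf = center + ri * points
        if neigh:
            d = np.linalg.norm(surf[:, None, :] - xyz[neigh][None, :, :], axis=2)
            accessible = int((d >= ext[neigh][None, :]).all(axis=1).sum())
        else:
            accessible = n_points
        area = accessible / n_points * 4.0 * np.pi * ri * ri
        areas[key] = areas.get(key, 0.0) + area
    for chain in structure.chains:
        if chain.chain_id in selected:
            for res in chain.residues:
                areas.setdefault((chain.chain_id, res.number, res.insertion_code), 0.0)
    return areas


def _reference_max_sasa(residue_name: str) -> float:
    try:
        return MAX_SASA[residue_name]
    except KeyError:
        warnings.warn(
            f"no reference max SASA for residue type {residue_name!r}; using mean"
        )
        return float(np.mean(list(MAX_SASA.values())))


def relative_sasa(area: float, residue_name: str) -> float:
    """SASA as percent of the residue type's Gly-X-Gly reference maximum."""
    return 100.0 * area / _reference_max_sasa(residue_name)


def label_core_rim(
    rsasa_unbound: float,
    rsasa_bound: float,
    core_max: float = 7.0,
    rim_max: float = 10.0,
) -> str:
    """Core/rim/other label from relative SASA (%) before and after binding.

    Core: surface-exposed when unbound (rSASA > rim_max) and deeply buried
    in the complex (rSASA <= core_max).  Rim: bound rSASA in
    (core_max, rim_max].  Otherwise: other.
    """
    if rsasa_unbound > rim_max and rsasa_bound <= core_max:
        return "core"
    if core_max < rsasa_bound <= rim_max:
        return "rim"
    return "other"


@dataclass
class CoreRimLabel:
    residue: ResidueKey
    residue_name: str
    label: str
    rsasa_unbound: float
    rsasa_bound: float


def core_rim(
    structure: ComplexStructure,
    pair: tuple[str, str],
    *,
    contact_params: ContactParams | None = None,
    core_max: float = 7.0,
    rim_max: float = 10.0,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> list[CoreRimLabel]:
    """Core/rim classification of the owner-side interface of a pair.

    ``pair = (owner, partner)`` component labels.  Unbound rSASA uses the
    owner component's chains alone; bound rSASA uses the chains of both
    components.  Interface residues come from :func:`find_contacts` at the
    parameters in force.
    """
    owner, partner = pair
    owner_chains = [c.chain_id for c in structure.chains_of(owner)]
    partner_chains = [c.chain_id for c in structure.chains_of(partner)]
    if not owner_chains or not partner_chains:
        raise ValueError(f"components {pair} not both present in structure")
    contacts = [
        rec
        for rec in find_contacts(structure, contact_params)
        if {rec.component_a, rec.component_b} == {owner, partner}
    ]
    sets = [s for s in interface_sets(contacts) if s.owner == owner]
    if not sets or not sets[0].residues:
        raise ValueError(f"pair {pair} has no interface residues")
    iface_keys = set(sets[0].residues)
    unbound = sasa(structure, owner_chains, probe_radius, n_points)
    bound = sasa(structure, owner_chains + partner_chains, probe_radius, n_points)
    name_of: dict[ResidueKey, str] = {}
    for cid in owner_chains:
        for res in structure.chain(cid).residues:
            name_of[(cid, res.number, res.insertion_code)] = res.name
    labels = []
    for key in sorted(iface_keys):
        rname = name_of[key]
        ru = relative_sasa(unbound[key], rname)
        rb = relative_sasa(bound[key], rname)
        labels.append(
            CoreRimLabel(
                residue=key,
                residue_name=rname,
                label=label_core_rim(ru, rb, core_max, rim_max),
                rsasa_unbound=ru,
                rsasa_bound=rb,
            )
        )
    return labels
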