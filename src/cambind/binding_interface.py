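"""Intermolecular contacts, salt bridges, anchors and binding-mode spacing.

Calmodulin grips its targets through bulky hydrophobic "anchor" residues of
the peptide buried in the hydrophobic pockets of the two domains; the
one-based spacing between the first and last anchor names the binding-mode
family (1–10, 1–14, 1–16, 1–18 ...).  NOE-observable proximity is
approximated by heavy-atom distance cutoffs: 4.5 Å for side-chain contacts,
4.0 Å between charged-group nitrogens and oxygens for salt bridges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .domain_symmetry import DomainSpec
from .errors import SelectionError
from .structure_io import BACKBONE_ATOMS, Residue, SelectionSpec, chain_residues

CONTACT_CUTOFF = 4.5  # Å, heavy-atom NOE proxy
SALT_BRIDGE_CUTOFF = 4.0  # Å, side-chain N–O
MAJOR_THRESHOLD = 5  # receptor residues contacted for a "major" anchor

HYDROPHOBIC_RESIDUES = frozenset(
    {"ILE", "LEU", "VAL", "PHE", "MET", "TRP", "TYR", "ALA"}
)
BASIC_RESIDUES = frozenset({"ARG", "LYS"})
ACIDIC_RESIDUES = frozenset({"GLU", "ASP"})
BASIC_SIDECHAIN_N = frozenset({"NE", "NH1", "NH2", "NZ"})
ACIDIC_SIDECHAIN_O = frozenset({"OE1", "OE2", "OD1", "OD2"})

ResidueKey = tuple[str, int, str]  # (chain, number, name)


@dataclass(frozen=True)
class ContactRecord:
    peptide_residue: ResidueKey
    receptor_residue: ResidueKey
    min_distance: float
    n_atom_pairs: int


@dataclass(frozen=True)
class SaltBridge:
    basic_residue: ResidueKey
    acidic_residue: ResidueKey
    min_NO_distance: float


@dataclass(frozen=True)
class Anchor:
    residue: ResidueKey
    contact_count: int
    buried_domain: Literal["N-domain", "C-domain", "both"]
    rank: Literal["major", "minor"]


@dataclass(frozen=True)
class AnchorPattern:
    indices: tuple[int, ...]  # one-based, first anchor = 1
    mode_label: str  # "1–K"
    orientation: Literal["parallel", "antiparallel"]


def _key(res: Residue) -> ResidueKey:
    return (res.chain_id, res.seq_number, res.res_name)


def _selected_residues(model: Sequence[Residue], spec: SelectionSpec) -> list[Residue]:
    start, end = spec.residue_range
    return [
        r
        for r in model
        if r.chain_id == spec.chain_id
        and start <= r.seq_number <= end
        and (spec.include_het or not r.het)
    ]


def _heavy_coords(res: Residue, sidechain_only: bool = False) -> np.ndarray:
    atoms = [
        a
        for a in res.atoms
        if not a.is_hydrogen and (not sidechain_only or a.name not in BACKBONE_ATOMS)
    ]
    if not atoms:
        return np.empty((0, 3))
    return np.array([a.coords for a in atoms])


def heavy_atom_contacts(
    model: Sequence[Residue],
    group_a: SelectionSpec,
    group_b: SelectionSpec,
    cutoff: float = CONTACT_CUTOFF,
) -> list[ContactRecord]:
    """Residue pairs with any heavy-atom pair within ``cutoff``.

    One record per (group A residue, group B residue) pair, sorted by the
    group A residue then the group B residue.
    """
    res_a = _selected_residues(model, group_a)
    res_b = _selected_residues(model, group_b)
    keys_a = {(r.chain_id, r.seq_number) for r in res_a}
    if any((r.chain_id, r.seq_number) in keys_a for r in res_b):
        raise SelectionError("contact groups overlap")
    records = []
    for ra in res_a:
        ca = _heavy_coords(ra)
        if not len(ca):
            continue
        tree = cKDTree(ca)
        for rb in res_b:
            cb = _heavy_coords(rb)
            if not len(cb):
                continue
            sparse = tree.sparse_distance_matrix(cKDTree(cb), cutoff)
            if sparse.nnz >= 1:
                records.append(
                    ContactRecord(
                        peptide_residue=_key(ra),
                        receptor_residue=_key(rb),
                        min_distance=float(min(sparse.values())),
                        n_atom_pairs=sparse.nnz,
                    )
                )
    records.sort(key=lambda r: (r.peptide_residue, r.receptor_residue))
    return records


def find_salt_bridges(
    model: Sequence[Residue],
    chain_a: str,
    chain_b: str,
    cutoff: float = SALT_BRIDGE_CUTOFF,
) -> list[SaltBridge]:
    """Arg/Lys ↔ Glu/Asp side-chain N–O pairs across two chains.

    Distances are measured only between the charged-group atoms
    (NE/NH1/NH2/NZ against OE1/OE2/OD1/OD2); one bridge is reported per
    residue pair, with the minimum N–O distance.  Symmetric in chain order.
    """
    if chain_a == chain_b:
        raise SelectionError("salt bridges are intermolecular: chains must differ")
    bridges = []
    for basic_chain, acidic_chain in ((chain_a, chain_b), (chain_b, chain_a)):
        basics = [
            r for r in chain_residues(model, basic_chain) if r.res_name in BASIC_RESIDUES
        ]
        acidics = [
            r for r in chain_residues(model, acidic_chain) if r.res_name in ACIDIC_RESIDUES
        ]
        for rb in basics:
            ncoords = [a.coords for a in rb.atoms if a.name in BASIC_SIDECHAIN_N]
            if not ncoords:
                continue
            for ra in acidics:
                ocoords = [a.coords for a in ra.atoms if a.name in ACIDIC_SIDECHAIN_O]
                if not ocoords:
                    continue
                d = np.linalg.norm(
                    np.asarray(ncoords)[:, None, :] - np.asarray(ocoords)[None, :, :],
                    axis=-1,
                )
                dmin = float(d.min())
                if dmin <= cutoff:
                    bridges.append(
                        SaltBridge(
                            basic_residue=_key(rb),
                            acidic_residue=_key(ra),
                            min_NO_distance=dmin,
                        )
                    )
    bridges.sort(key=lambda b: (b.basic_residue, b.acidic_residue))
    return bridges


def identify_anchors(
    model: Sequence[Residue],
    peptide_spec: SelectionSpec,
    receptor_domains: tuple[DomainSpec, DomainSpec],
    cutoff: float = CONTACT_CUTOFF,
    major_threshold: int = MAJOR_THRESHOLD,
) -> list[Anchor]:
    """Hydrophobic peptide residues buried against hydrophobic receptor pockets.

    A peptide residue qualifies when at least one of its side-chain heavy
    atoms lies within ``cutoff`` of a side-chain heavy atom of a hydrophobic
    (or Met) receptor residue.  ``contact_count`` counts distinct receptor
    residues contacted; anchors reaching ``major_threshold`` rank "major".
    ``buried_domain`` reports which receptor domain owns the contacts.
    """
    peptide = [
        r
        for r in _selected_residues(model, peptide_spec)
        if r.res_name in HYDROPHOBIC_RESIDUES
    ]
    domain_of: dict[tuple[str, int], str] = {}
    receptor: list[Residue] = []
    for dom in receptor_domains:
        lo, hi = dom.residue_range
        for r in model:
            if (
                r.chain_id == dom.chain_id
                and lo <= r.seq_number <= hi
                and not r.het
                and r.res_name in HYDROPHOBIC_RESIDUES
            ):
                receptor.append(r)
                domain_of[(r.chain_id, r.seq_number)] = dom.label
    anchors = []
    for pres in peptide:
        pc = _heavy_coords(pres, sidechain_only=True)
        if not len(pc):
            continue
        touched: set[tuple[str, int]] = set()
        domains: set[str] = set()
        for rres in receptor:
            rc = _heavy_coords(rres, sidechain_only=True)
            if not len(rc):
                continue
            d = np.linalg.norm(pc[:, None, :] - rc[None, :, :], axis=-1)
            if float(d.min()) <= cutoff:
                touched.add((rres.chain_id, rres.seq_number))
                domains.add(domain_of[(rres.chain_id, rres.seq_number)])
        if touched:
            buried = "both" if len(domains) == 2 else domains.pop()
            anchors.append(
                Anchor(
                    residue=_key(pres),
                    contact_count=len(touched),
                    buried_domain=buried,  # type: ignore[arg-type]
                    rank="major" if len(touched) >= major_threshold else "minor",
                )
            )
    anchors.sort(key=lambda a: a.residue[1])
    return anchors


def spacing_pattern(anchors: Sequence[Anchor]) -> AnchorPattern:
    """One-based anchor spacing indices and the "1–K" binding-mode label.

    Orientation follows which domain buries the first (lowest-numbered)
    anchor: the N-domain means the peptide runs parallel (CaMKK-like), the
    C-domain antiparallel (M13-like).
    """
    if not anchors:
        raise ValueError("need at least one anchor")
    chains = {a.residue[0] for a in anchors}
    if len(chains) != 1:
        raise SelectionError(f"anchors span multiple chains: {sorted(chains)}")
    ordered = sorted(anchors, key=lambda a: a.residue[1])
    first = ordered[0].residue[1]
    indices = tuple(a.residue[1] - first + 1 for a in ordered)
    orientation = (
        "parallel" if ordered[0].buried_domain in ("N-domain", "both") else "antiparallel"
    )
    return AnchorPattern(
        indices=indices,
        mode_label=f"1–{indices[-1]}",
        orientation=orientation,  # type: ignore[arg-type]
    )
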