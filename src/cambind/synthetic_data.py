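"""Deterministic synthetic fixtures with known ground truth.

Every geometric and spectroscopic analysis in this package has a generator
here that constructs inputs whose true answer is known by construction:
ideal and kinked α-helices from standard internal coordinates, a toy
wrap-around complex whose two receptor "domains" are related by an exact
screw rotation about the peptide axis, amide shift tables with seeded
perturbation hotspots, two-state CD spectra and power-law size standards.

The receptor domains are deliberately minimal helical bundles, not
EF-hand domains: they exercise the geometry and contact logic, not
calmodulin biology.  All generators are pure functions of their parameters
and a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .biophys_calibration import (
    REF_COIL_222,
    REF_HELIX_222,
    CalibrationPoint,
    CDSpectrum,
)
from .csp_mapping import ShiftTable
from .structure_io import Atom, Residue, StructureEnsemble

# standard peptide internal coordinates (angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
ANGLE_C_CA_CB = 110.1
TORSION_N_C_CA_CB = 122.6  # improper fixing the CB position (L-configuration)
OMEGA = 180.0

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement: position D bonded to c with the
    given bond length, angle b-c-D and torsion a-b-c-D."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), -np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_helix(
    sequence: str,
    phi: float = -57.0,
    psi: float = -47.0,
    chain_id: str = "P",
    start_number: int = 1,
) -> StructureEnsemble:
    """Single-model backbone+CB structure with uniform (φ, ψ).

    The default dihedrals give a canonical α-helix with consecutive CA–CA
    distances of 3.8 Å; any other (φ, ψ) pair builds the corresponding
    regular conformation (e.g. −135/135 for an extended strand).
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have at least 2 residues")
    for letter in sequence:
        if letter.upper() not in THREE_LETTER:
            raise ValueError(f"unknown residue letter {letter!r}")
    n_prev = np.array([0.0, 0.0, 0.0])
    ca_prev = n_prev + BOND_N_CA * np.array([1.0, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c_prev = ca_prev + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues: list[Residue] = []
    backbone = [(n_prev, ca_prev, c_prev)]
    for i in range(1, len(sequence)):
        n_i = _place(backbone[-1][0], backbone[-1][1], backbone[-1][2],
                     BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = _place(backbone[-1][1], backbone[-1][2], n_i,
                      BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _place(backbone[-1][2], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        backbone.append((n_i, ca_i, c_i))
    for i, letter in enumerate(sequence):
        n_i, ca_i, c_i = backbone[i]
        res_name = THREE_LETTER[letter.upper()]
        atoms = [
            Atom("N", "N", n_i),
            Atom("CA", "C", ca_i),
            Atom("C", "C", c_i),
            Atom("O", "O", _place(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)),
        ]
        if res_name != "GLY":
            atoms.append(
                Atom("CB", "C",
                     _place(n_i, c_i, ca_i, BOND_CA_CB, ANGLE_C_CA_CB, TORSION_N_C_CA_CB))
            )
        residues.append(
            Residue(chain_id=chain_id, seq_number=start_number + i,
                    res_name=res_name, atoms=atoms)
        )
    return StructureEnsemble(models=[residues], id="ideal-helix")


def _transform_residues(residues, rotation: np.ndarray, translation: np.ndarray,
                        only_after: int | None = None, chain_id: str | None = None):
    """Rigidly move atoms (optionally only residues numbered > only_after)."""
    out = []
    for res in residues:
        move = (chain_id is None or res.chain_id == chain_id) and (
            only_after is None or res.seq_number > only_after
        )
        if move:
            atoms = [
                Atom(a.name, a.element, rotation @ a.coords + translation)
                for a in res.atoms
            ]
            out.append(Residue(res.chain_id, res.seq_number, res.res_name, atoms, res.het))
        else:
            out.append(res)
    return out


def build_kinked_helix(
    sequence: str,
    split_index: int,
    bend: float,
    chain_id: str = "P",
    start_number: int = 1,
) -> StructureEnsemble:
    """An ideal helix bent by an exact ``bend``° rotation at one residue.

    ``split_index`` is the 1-based position of the hinge residue within the
    sequence.  All residues after the hinge are rotated rigidly about an
    axis through the hinge CA, perpendicular to the helix axis, so the angle
    between the axes of the two flanking segments equals ``bend`` up to the
    axis-fitting error (< 1°).
    """
    if not 2 <= split_index <= len(sequence) - 1:
        raise ValueError("split_index must be strictly inside the sequence")
    if not 0.0 <= bend <= 90.0:
        raise ValueError("bend must be within [0, 90] degrees")
    ens = build_ideal_helix(sequence, chain_id=chain_id, start_number=start_number)
    residues = ens.models[0]
    from .helix_analysis import fit_helix_axis  # deferred: avoids import cycle

    ca = np.array([r.atom("CA").coords for r in residues])
    axis = fit_helix_axis(ca).direction
    hinge_num = start_number + split_index - 1
    hinge_ca = residues[split_index - 1].atom("CA").coords
    # any perpendicular to the helix axis serves as the bend axis
    perp = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    R = Rotation.from_rotvec(np.deg2rad(bend) * perp).as_matrix()
    t = hinge_ca - R @ hinge_ca
    bent = _transform_residues(residues, R, t, only_after=hinge_num, chain_id=chain_id)
    return StructureEnsemble(models=[bent], id="kinked-helix")


@dataclass(frozen=True)
class ToyComplexParams:
    """Construction parameters for the pseudo-C2 wrap-around toy complex."""

    peptide_length: int = 24
    kink_angle: float = 17.0
    kink_position: int = 12  # 1-based hinge position within the peptide
    c2_twist: float = 0.0  # rotation of domain B beyond 180°, degrees
    anchor_positions: tuple[int, ...] = (1, 5, 15, 18)
    noise_sigma: float = 0.0  # Å, per coordinate
    n_models: int = 1
    seed: int = 0
    domain_offset: int = 100  # numbering offset of domain B relative to A

    def __post_init__(self) -> None:
        if not 2 <= self.kink_position <= self.peptide_length - 1:
            raise ValueError("kink_position must be strictly inside the peptide")
        if self.n_models < 1 or self.noise_sigma < 0:
            raise ValueError("need n_models ≥ 1 and noise_sigma ≥ 0")
        if any(not 1 <= p <= self.peptide_length for p in self.anchor_positions):
            raise ValueError("anchor positions must lie within the peptide")


PEPTIDE_CHAIN = "P"
RECEPTOR_CHAIN = "R"
_ANCHOR_NAMES = ("ILE", "PHE", "ILE", "LEU")  # cycled over anchors; ends are major
_SIDECHAIN_NAMES = ("CG", "CG1", "CG2", "CD1", "CD2", "CE1", "CE2", "CZ")


def _build_domain_bundle() -> list[Residue]:
    """A 30-residue antiparallel two-helix bundle (all-Ala), chain R, 1..30."""
    up = build_ideal_helix("A" * 15, chain_id=RECEPTOR_CHAIN, start_number=1)
    down = build_ideal_helix("A" * 15, chain_id=RECEPTOR_CHAIN, start_number=16)
    from .helix_analysis import fit_helix_axis

    residues = []
    for ens, flip, shift in ((up, False, np.zeros(3)), (down, True, np.array([9.0, 0.0, 0.0]))):
        part = ens.models[0]
        ca = np.array([r.atom("CA").coords for r in part])
        ax = fit_helix_axis(ca)
        # canonicalize each helix: axis to ±z, centroid to origin (+ lateral shift)
        target = np.array([0.0, 0.0, -1.0 if flip else 1.0])
        R, _ = Rotation.align_vectors(target.reshape(1, 3), ax.direction.reshape(1, 3))
        Rm = R.as_matrix()
        t = shift - Rm @ ax.centroid
        residues.extend(_transform_residues(part, Rm, t))
    return residues


def make_toy_complex(params: ToyComplexParams) -> StructureEnsemble:
    """Kinked peptide flanked by two screw-related receptor domains.

    Domain A (receptor chain, residues 1–30) sits against the N-terminal
    half of the peptide; domain B (residues 101–130) is an exact copy of A
    transformed by a screw of (180 + c2_twist)° about the fitted peptide
    axis plus a translation along it — so the interdomain CA transform has
    a known rotation by construction.  Hydrophobic anchors at
    ``anchor_positions`` (serine elsewhere) receive engineered receptor
    side-chain atoms exactly 4.0 Å from their CB: six receptor residues for
    the first and last anchor (major), two for the middle ones (minor).
    """
    L = params.peptide_length
    anchors = tuple(sorted(params.anchor_positions))
    seq = list("S" * L)
    one_letter = {"ILE": "I", "PHE": "F", "LEU": "L"}
    for k, pos in enumerate(anchors):
        name = _ANCHOR_NAMES[-1] if pos == anchors[-1] else _ANCHOR_NAMES[k % 2]
        seq[pos - 1] = one_letter[name]
    pep = build_kinked_helix(
        "".join(seq), params.kink_position, params.kink_angle, chain_id=PEPTIDE_CHAIN
    )
    from .helix_analysis import fit_helix_axis

    pep_res = pep.models[0]
    ca = np.array([r.atom("CA").coords for r in pep_res])
    ax = fit_helix_axis(ca)
    Rz, _ = Rotation.align_vectors(np.array([[0.0, 0.0, 1.0]]), ax.direction.reshape(1, 3))
    Rm = Rz.as_matrix()
    pep_res = _transform_residues(pep_res, Rm, -Rm @ ax.centroid)
    half_span = 1.5 * L / 4.0  # ~rise of a quarter of the peptide

    domain_a = _build_domain_bundle()
    # place the bundle against the N-terminal half of the peptide
    domain_a = _transform_residues(
        domain_a, np.eye(3), np.array([12.0, 0.0, -half_span])
    )
    # domain B: exact screw image of A about the peptide (z) axis
    screw_R = Rotation.from_rotvec(
        np.deg2rad(180.0 + params.c2_twist) * np.array([0.0, 0.0, 1.0])
    ).as_matrix()
    screw_t = np.array([0.0, 0.0, 2.0 * half_span])
    domain_b = []
    for res in _transform_residues(domain_a, screw_R, screw_t):
        domain_b.append(
            Residue(res.chain_id, res.seq_number + params.domain_offset,
                    res.res_name, list(res.atoms), res.het)
        )

    # engineer anchor pockets: receptor side-chain atoms exactly 4.0 Å from
    # each anchor CB, on the nearest receptor residues of the matching domain
    def engineer(domain: list[Residue], positions: tuple[int, ...]) -> None:
        for pos in positions:
            anchor_cb = pep_res[pos - 1].atom("CB").coords
            n_pocket = 6 if pos in (anchors[0], anchors[-1]) else 2
            ranked = sorted(
                range(len(domain)),
                key=lambda i: float(
                    np.linalg.norm(domain[i].atom("CB").coords - anchor_cb)
                ),
            )[:n_pocket]
            for i in ranked:
                res = domain[i]
                direction = res.atom("CB").coords - anchor_cb
                direction /= np.linalg.norm(direction)
                used = {a.name for a in res.atoms}
                name = next(n for n in _SIDECHAIN_NAMES if n not in used)
                domain[i] = Residue(
                    res.chain_id, res.seq_number, "LEU",
                    list(res.atoms) + [Atom(name, "C", anchor_cb + 4.0 * direction)],
                    res.het,
                )

    engineer(domain_a, tuple(p for p in anchors if p <= params.kink_position))
    engineer(domain_b, tuple(p for p in anchors if p > params.kink_position))

    base = pep_res + domain_a + domain_b
    rng = np.random.default_rng(params.seed)
    models = []
    for _ in range(params.n_models):
        if params.noise_sigma > 0:
            model = [
                Residue(r.chain_id, r.seq_number, r.res_name,
                        [Atom(a.name, a.element,
                              a.coords + rng.normal(0.0, params.noise_sigma, 3))
                         for a in r.atoms], r.het)
                for r in base
            ]
        else:
            model = base
        models.append(model)
    return StructureEnsemble(models=models, id="toy-complex")


def simulate_shift_tables(
    n_residues: int = 148,
    hotspot_ranges: tuple[tuple[int, int], ...] = ((19, 20), (76, 85)),
    hotspot_scale: float = 6.0,
    background_sd: float = 0.02,
    seed: int = 0,
) -> tuple[ShiftTable, ShiftTable]:
    """Free/bound amide shift tables with localized perturbation hotspots.

    Background perturbations are Gaussian with sd ``background_sd`` in ¹H
    and five times that in ¹⁵N (matching the nitrogen normalization).
    Hotspot residues receive an extra offset of magnitude
    ``hotspot_scale × background_sd`` (¹H; 5× that in ¹⁵N) with random sign,
    so their normalized perturbation sits ``hotspot_scale``-fold above the
    background level by construction.
    """
    for lo, hi in hotspot_ranges:
        if not 1 <= lo <= hi <= n_residues:
            raise ValueError(f"hotspot [{lo}, {hi}] outside 1..{n_residues}")
    rng = np.random.default_rng(seed)
    residues = np.arange(1, n_residues + 1)
    hot = np.zeros(n_residues, dtype=bool)
    for lo, hi in hotspot_ranges:
        hot[lo - 1 : hi] = True
    hn_free = rng.uniform(7.5, 9.3, n_residues)
    n_free = rng.uniform(105.0, 130.0, n_residues)
    d_hn = rng.normal(0.0, background_sd, n_residues)
    d_n = rng.normal(0.0, 5.0 * background_sd, n_residues)
    # hotspot offsets add in the direction of the residue's background
    # deviation, so every hotspot residue's perturbation magnitude exceeds
    # hotspot_scale × the background scale by construction
    d_hn[hot] += np.sign(d_hn[hot]) * hotspot_scale * background_sd
    d_n[hot] += np.sign(d_n[hot]) * 5.0 * hotspot_scale * background_sd
    free = pd.DataFrame(
        {"residue": residues, "res_name": "ALA",
         "delta_HN": hn_free, "delta_N": n_free}
    )
    bound = free.copy()
    bound["delta_HN"] = hn_free + d_hn
    bound["delta_N"] = n_free + d_n
    return (
        ShiftTable(data=free, label="free"),
        ShiftTable(data=bound, label="bound"),
    )


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def helix_basis(wavelengths: np.ndarray) -> np.ndarray:
    """Two-minimum (208/222 nm) α-helix CD basis, Δε(222) = REF_HELIX_222."""
    wl = np.asarray(wavelengths, dtype=float)
    shape = (
        2.2 * _gaussian(wl, 192.0, 6.5)
        - _gaussian(wl, 208.0, 7.5)
        - _gaussian(wl, 222.0, 8.5)
    )
    ref = (
        2.2 * _gaussian(np.array([222.0]), 192.0, 6.5)
        - _gaussian(np.array([222.0]), 208.0, 7.5)
        - _gaussian(np.array([222.0]), 222.0, 8.5)
    )[0]
    return shape * (REF_HELIX_222 / ref)


def coil_basis(wavelengths: np.ndarray) -> np.ndarray:
    """Random-coil CD basis with its minimum near 198 nm, Δε(222) = REF_COIL_222."""
    wl = np.asarray(wavelengths, dtype=float)
    shape = -_gaussian(wl, 198.0, 9.0) + 0.12 * _gaussian(wl, 220.0, 12.0)
    ref = (-_gaussian(np.array([222.0]), 198.0, 9.0)
           + 0.12 * _gaussian(np.array([222.0]), 220.0, 12.0))[0]
    return shape * (REF_COIL_222 / ref)


def simulate_cd_spectrum(
    helix_fraction: float,
    wavelengths: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CDSpectrum:
    """Two-state mixture spectrum f·helix + (1−f)·coil with optional noise."""
    if not 0.0 <= helix_fraction <= 1.0:
        raise ValueError("helix_fraction must be in [0, 1]")
    wl = np.arange(190.0, 251.0) if wavelengths is None else np.asarray(wavelengths, float)
    de = helix_fraction * helix_basis(wl) + (1.0 - helix_fraction) * coil_basis(wl)
    if noise_sd > 0:
        de = de + np.random.default_rng(seed).normal(0.0, noise_sd, len(wl))
    return CDSpectrum(wavelengths=wl, delta_eps=de)


def simulate_dls_standards(
    n_points: int = 6,
    coefficient: float = 4.0,
    exponent: float = 1.5,
    rh_range: tuple[float, float] = (1.5, 7.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[CalibrationPoint]:
    """Power-law size standards M_r = coefficient · R_H^exponent (kDa, nm).

    ``noise_sd`` is lognormal scatter (sd of log10 M_r), emulating the
    deviation of real globular proteins from the ideal power law.
    """
    rng = np.random.default_rng(seed)
    rh = np.geomspace(rh_range[0], rh_range[1], n_points)
    log_mr = np.log10(coefficient) + exponent * np.log10(rh)
    if noise_sd > 0:
        log_mr = log_mr + rng.normal(0.0, noise_sd, n_points)
    return [
        CalibrationPoint(r_h=float(r), m_r=float(10**m), label=f"std{i+1}")
        for i, (r, m) in enumerate(zip(rh, log_mr))
    ]
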