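"""Superposition, fluctuation and torsion geometry.

Least-squares rigid-body fitting (Kabsch), pairwise RMSD matrices,
iterative average structures, per-residue RMSF, the subdomain "propeller"
torsion, side-chain dihedrals with canonical-rotamer enumeration, and
minimum inter-residue side-chain distances.
"""

from __future__ import annotations

import itertools
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model_io import Structure, SubdomainMap, Trajectory

__all__ = [
    "Transform",
    "RotamerState",
    "ContactDistanceSeries",
    "DegenerateSelectionError",
    "ConvergenceError",
    "superpose",
    "apply_transform",
    "pairwise_rmsd_matrix",
    "average_structure",
    "rmsf",
    "dihedral",
    "propeller_angle",
    "CHI_ATOMS",
    "CANONICAL_CHI_STATES",
    "enumerate_rotamers",
    "select_rotamer_max_distance",
    "dihedral_histogram",
    "min_sidechain_distance",
    "residue_dihedral_series",
]


class DegenerateSelectionError(ValueError):
    """Fewer than 3 atoms, or a collinear selection."""


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class Transform:
    """Rigid-body transform x -> R x + t."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1.0e-8:
            raise ValueError(f"rotation determinant {det} != +1")


def apply_transform(transform: Transform, coords: np.ndarray) -> np.ndarray:
    return coords @ transform.rotation.T + transform.translation


def _check_selection(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateSelectionError("need >= 3 atoms to superpose")
    centered = coords - coords.mean(axis=0)
    # rank < 2 means all points lie on one line (or point)
    if np.linalg.matrix_rank(centered, tol=1.0e-8) < 2:
        raise DegenerateSelectionError("selection is collinear")


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[Transform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the optimal transform (Kabsch, proper rotation enforced) and
    the minimized RMSD over the selection. ``selection`` indexes both
    coordinate sets; default is all atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        msel, rsel = mobile[selection], reference[selection]
    else:
        msel, rsel = mobile, reference
    if msel.shape != rsel.shape:
        raise ValueError("selections must be equal length")
    _check_selection(msel)
    _check_selection(rsel)

    mc, rc = msel.mean(axis=0), rsel.mean(axis=0)
    h = (msel - mc).T @ (rsel - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    transform = Transform(rotation=rot, translation=trans)
    moved = apply_transform(transform, msel)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - rsel) ** 2, axis=1))))
    return transform, rmsd


def pairwise_rmsd_matrix(
    structures: Sequence[Structure], selection: np.ndarray | None = None
) -> np.ndarray:
    """Symmetric matrix of pairwise best-fit RMSDs (Å); zero diagonal."""
    n = len(structures)
    if n < 2:
        raise ValueError("need >= 2 structures")
    counts = {len(s) for s in structures}
    if len(counts) != 1:
        raise ValueError("structures differ in atom count")
    coords = [s.coords for s in structures]
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            _, r = superpose(coords[i], coords[j], selection)
            mat[i, j] = mat[j, i] = r
    return mat


def average_structure(
    trajectory: Trajectory,
    selection: np.ndarray | None = None,
    tol: float = 1.0e-6,
    max_iter: int = 100,
) -> Structure:
    """Iteratively fitted mean structure.

    Each round fits every frame to the current mean (over ``selection``,
    default all atoms) and recomputes the all-atom mean, until the RMS
    mean shift drops below ``tol`` Å.
    """
    if trajectory.n_frames < 2:
        raise ValueError("need >= 2 frames")
    frames = trajectory.frames
    mean = frames[0].copy()
    for _ in range(max_iter):
        fitted = np.empty_like(frames)
        for k in range(frames.shape[0]):
            t, _ = superpose(frames[k], mean, selection)
            fitted[k] = apply_transform(t, frames[k])
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            return trajectory.topology.with_coords(mean)
    raise ConvergenceError(f"average structure not converged in {max_iter} iterations")


def rmsf(
    trajectory: Trajectory,
    selection: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
    per_residue: bool = True,
) -> dict[int, float] | np.ndarray:
    """Root mean-square fluctuation about the fitted average structure.

    Every frame is best-fitted to the average structure over
    ``fit_selection`` (default: ``selection``); fluctuations are then
    accumulated for the atoms in ``selection``. With ``per_residue``,
    deviations are pooled over the selection atoms of each residue:
    RMSF_r = sqrt(mean over frames and atoms of squared deviation).
    """
    topo = trajectory.topology
    if selection is None:
        selection = np.arange(len(topo))
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    if fit_selection is None:
        fit_selection = selection
    avg = average_structure(trajectory, fit_selection).coords
    sq = np.zeros(selection.size, dtype=float)
    for k in range(trajectory.n_frames):
        t, _ = superpose(trajectory.frames[k], avg, fit_selection)
        moved = apply_transform(t, trajectory.frames[k])
        sq += np.sum((moved[selection] - avg[selection]) ** 2, axis=1)
    sq /= trajectory.n_frames
    if not per_residue:
        return np.sqrt(sq)
    out: dict[int, list[float]] = {}
    for val, idx in zip(sq, selection):
        out.setdefault(topo.atoms[idx].residue_id, []).append(val)
    return {rid: float(np.sqrt(np.mean(v))) for rid, v in out.items()}


# --------------------------------------------------------------------------
# torsions
# --------------------------------------------------------------------------


def dihedral(p0, p1, p2, p3) -> float:
    """IUPAC-signed torsion angle p0-p1-p2-p3 in degrees, range (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def propeller_angle(
    structure: Structure,
    subdomains: SubdomainMap,
    order: tuple[int, int, int, int] = (2, 1, 3, 4),
    selection: np.ndarray | None = None,
) -> float:
    """Torsion through the four subdomain centroids, degrees.

    Centroids are unweighted means over the selection atoms (default:
    backbone heavy atoms) belonging to each subdomain. ``order`` fixes
    which subdomain supplies each torsion vertex; the default (2,1,3,4)
    runs through the two lobes across the hinge.
    """
    if selection is None:
        selection = structure.backbone_indices()
    coords = structure.coords
    centroids = []
    for sd in order:
        idx = [
            i
            for i in selection
            if structure.atoms[i].residue_id in subdomains
            and subdomains[structure.atoms[i].residue_id] == sd
        ]
        if not idx:
            raise ValueError(f"subdomain {sd} has no selected atoms")
        centroids.append(coords[idx].mean(axis=0))
    return dihedral(*centroids)


# --------------------------------------------------------------------------
# side-chain dihedrals and rotamers
# --------------------------------------------------------------------------

# chi dihedral atom quadruples per residue type (standard definitions)
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# gauche-/gauche+/trans canonical states used for rotamer enumeration
CANONICAL_CHI_STATES: tuple[float, ...] = (-60.0, 60.0, 180.0)


@dataclass(frozen=True)
class RotamerState:
    """Side-chain dihedral angles chi_1..chi_n in degrees, (-180, 180]."""

    chi: tuple[float, ...]

    def __post_init__(self) -> None:
        for c in self.chi:
            if not (-180.0 < c <= 180.0):
                raise ValueError(f"chi {c} outside (-180, 180]")


def enumerate_rotamers(
    residue_type: str, states: Sequence[float] = CANONICAL_CHI_STATES
) -> list[RotamerState]:
    """All combinations of canonical chi states for one residue type.

    Lysine, with four rotatable dihedrals, yields 3**4 = 81 states.
    Glycine/alanine have no rotatable chi: empty list with a warning.
    """
    residue_type = residue_type.upper()
    chis = CHI_ATOMS.get(residue_type, [])
    if not chis:
        _warnings.warn(f"{residue_type} has no rotatable side-chain dihedrals")
        return []
    return [
        RotamerState(chi=combo)
        for combo in itertools.product(states, repeat=len(chis))
    ]


def select_rotamer_max_distance(
    states: Sequence[tuple[RotamerState, Mapping[str, np.ndarray]]],
    probe_atom: str,
    anchor: np.ndarray,
) -> RotamerState:
    """State whose ``probe_atom`` lies farthest from ``anchor``.

    ``states`` pairs each rotamer with its built side-chain coordinates
    (atom name -> position). Ties are broken by lexicographic chi order.
    """
    if not states:
        raise ValueError("no rotamer states supplied")
    anchor = np.asarray(anchor, dtype=float)
    scored = []
    for state, coords in states:
        if probe_atom not in coords:
            raise KeyError(f"state {state.chi} lacks probe atom {probe_atom}")
        d = float(np.linalg.norm(np.asarray(coords[probe_atom]) - anchor))
        scored.append((d, state))
    if all(d < 1.0 for d, _ in scored):
        _warnings.warn("all probe positions within 1 Å of anchor (clash-only)")
    best_d = max(d for d, _ in scored)
    candidates = [s for d, s in scored if abs(d - best_d) < 1.0e-12]
    return min(candidates, key=lambda s: s.chi)


def residue_dihedral_series(
    trajectory: Trajectory, residue_id: int, chi_index: int
) -> np.ndarray:
    """Per-frame chi_{chi_index} (1-based) of one residue, degrees."""
    topo = trajectory.topology
    res_atoms = {
        a.name: i for i, a in enumerate(topo.atoms) if a.residue_id == residue_id
    }
    rname = next(
        a.residue_name for a in topo.atoms if a.residue_id == residue_id
    )
    lookup = "HIS" if rname in ("HSP", "HIP", "3MH", "HIC") else rname
    chis = CHI_ATOMS.get(lookup, [])
    if chi_index < 1 or chi_index > len(chis):
        raise ValueError(f"{rname} {residue_id} has no chi_{chi_index}")
    quad = chis[chi_index - 1]
    try:
        idx = [res_atoms[name] for name in quad]
    except KeyError as exc:
        raise ValueError(
            f"residue {residue_id} missing side-chain atom {exc.args[0]}"
        ) from None
    return np.array(
        [dihedral(*trajectory.frames[k, idx]) for k in range(trajectory.n_frames)]
    )


def dihedral_histogram(
    trajectory: Trajectory,
    residue_id: int,
    chi_indices: Sequence[int],
    bin_width: float = 5.0,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Normalized probability densities of side-chain dihedrals.

    Returns chi_index -> (bin_edges, density) with bins spanning
    (-180, 180]; densities integrate to 1. Angles are wrapped into the
    range so no probability mass is lost at the +-180 boundary.
    """
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    out = {}
    for ci in chi_indices:
        angles = residue_dihedral_series(trajectory, residue_id, ci)
        wrapped = ((angles + 180.0) % 360.0) - 180.0
        # place exact -180 into the last bin (range is open at -180]
        wrapped[wrapped == -180.0] = 180.0
        wrapped = np.clip(wrapped, -180.0 + 1e-12, 180.0)
        hist, _ = np.histogram(wrapped, bins=edges)
        density = hist / (hist.sum() * bin_width)
        out[ci] = (edges, density)
    return out


# --------------------------------------------------------------------------
# inter-residue contacts
# --------------------------------------------------------------------------

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}


@dataclass
class ContactDistanceSeries:
    """Per-frame minimum side-chain atom distance for one residue pair."""

    residue_pair: tuple[int, int]
    values: np.ndarray  # Å, one per frame
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0.0):
            raise ValueError("distances must be positive")
        self.mean = float(self.values.mean())
        self.sd = float(self.values.std())


def min_sidechain_distance(
    trajectory: Trajectory,
    residue_a: int,
    residue_b: int,
    element_filter: str | None = "C",
) -> ContactDistanceSeries:
    """Per-frame minimum distance between two residues' side-chain atoms.

    ``element_filter`` restricts both sides to one element (default
    carbon, matching side-chain packing analyses); ``None`` keeps all
    side-chain heavy atoms.
    """
    topo = trajectory.topology

    def side_idx(rid: int) -> list[int]:
        idx = [
            i
            for i, a in enumerate(topo.atoms)
            if a.residue_id == rid
            and a.name not in _BACKBONE_NAMES
            and not a.element.upper().startswith("H")
            and (element_filter is None or a.element.upper() == element_filter)
        ]
        if not idx:
            raise ValueError(
                f"residue {rid} has no side-chain atoms passing the filter"
            )
        return idx

    ia, ib = side_idx(residue_a), side_idx(residue_b)
    da = trajectory.frames[:, ia, None, :] - trajectory.frames[:, None, ib, :]
    dist = np.linalg.norm(da, axis=-1)  # (n_frames, |ia|, |ib|)
    per_frame = dist.reshape(trajectory.n_frames, -1).min(axis=1)
    return ContactDistanceSeries(residue_pair=(residue_a, residue_b), values=per_frame)
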