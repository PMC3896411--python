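"""Synthetic inputs with known ground truth.

Every input class the analysis pipeline consumes can be generated here
with its expected result computed from closed forms or construction
rules, independent of the analysis code:

* harmonic conformational ensembles with prescribed mode variances
  (closed-form oscillator entropy);
* Gaussian volume series built to a target compressibility (closed-form
  inversion of the fluctuation formula);
* structures with charged groups, secondary-structure labels and
  subdomain assignments at exact separations (bridge counts and
  categories by construction);
* an ATP-like triphosphate fragment with Mg2+ and waters placed to
  requested attack geometries (nucleophile assignment by construction);
* Born ions for the Poisson solver (closed-form solvation energy).

Fixture molecules are built from internal-coordinate templates (ideal
bond lengths and angles), not fetched structures; geometric realism is
limited to what the analyses measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .constants import AMU_KG, ANGSTROM_M, BOLTZMANN_J, COULOMB_KCAL, HBAR_J, KB_KCALMOL
from .model_io import (
    AnnotationConfig,
    AtomRecord,
    Structure,
    TopologyAnnotation,
    Trajectory,
    annotate_topology,
)
from .surface_volume import VolumeSeries

__all__ = [
    "HarmonicEnsembleSpec",
    "gen_harmonic_trajectory",
    "closed_form_internal_entropy",
    "gen_volume_series",
    "place_atom",
    "build_peptide",
    "build_lysine_rotamer",
    "BridgeSpec",
    "InteractionFixtureSpec",
    "gen_interaction_fixture",
    "ActiveSiteSpec",
    "gen_active_site_fixture",
    "gen_born_system",
    "born_closed_form",
    "make_water",
]


# --------------------------------------------------------------------------
# harmonic ensembles
# --------------------------------------------------------------------------


@dataclass
class HarmonicEnsembleSpec:
    """Gaussian ensemble about a reference with prescribed mode variances.

    ``mode_variances`` are eigenvalues of the mass-weighted covariance
    (amu*Å^2), assigned to internal modes only; alternatively
    ``isotropic_variance`` (Å^2) gives every atom the same Cartesian
    variance (in which case external modes are not separated).
    """

    reference: np.ndarray  # (N, 3) Å
    masses: np.ndarray  # (N,) amu
    n_frames: int
    temperature: float = 277.0
    mode_variances: np.ndarray | None = None  # (<= 3N-6,) amu Å^2
    isotropic_variance: float | None = None  # Å^2
    rigid_motion: bool = False  # apply a random rigid move per frame
    seed: int = 0

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if (self.mode_variances is None) == (self.isotropic_variance is None):
            raise ValueError(
                "specify exactly one of mode_variances / isotropic_variance"
            )
        if self.mode_variances is not None:
            self.mode_variances = np.asarray(self.mode_variances, dtype=float)
            if np.any(self.mode_variances <= 0):
                raise ValueError("mode variances must be positive")
            n_int = 3 * len(self.reference) - 6
            if len(self.mode_variances) > n_int:
                raise ValueError(f"at most {n_int} internal modes allowed")
        elif self.isotropic_variance <= 0:
            raise ValueError("isotropic variance must be positive")


def _external_mode_basis(reference: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N, 6) of rigid translations/rotations in
    mass-weighted coordinates."""
    n = len(reference)
    sqrtm = np.sqrt(masses)
    com = (masses[:, None] * reference).sum(axis=0) / masses.sum()
    x = reference - com
    vecs = []
    for d in range(3):  # translations
        v = np.zeros((n, 3))
        v[:, d] = sqrtm
        vecs.append(v.ravel())
    for d in range(3):  # infinitesimal rotations about principal axes
        axis = np.zeros(3)
        axis[d] = 1.0
        v = np.cross(np.broadcast_to(axis, (n, 3)), x) * sqrtm[:, None]
        vecs.append(v.ravel())
    basis = np.column_stack(vecs)
    q, r = np.linalg.qr(basis)
    # drop near-null columns (e.g. linear molecules)
    keep = np.abs(np.diag(r)) > 1.0e-10
    return q[:, keep]


def gen_harmonic_trajectory(
    spec: HarmonicEnsembleSpec,
) -> tuple[Trajectory, float]:
    """Sample the ensemble; return (trajectory, closed-form S_int).

    With ``mode_variances``, sampling happens along an orthonormal set
    of internal modes constructed orthogonal to the six rigid-body
    modes, so a quasi-harmonic analysis that discards the six external
    modes recovers exactly the prescribed spectrum in expectation. The
    closed-form entropy is the quantum oscillator sum over the
    prescribed variances (isotropic specs return the sum over all 3N
    per-coordinate variances m sigma^2).
    """
    rng = np.random.default_rng(spec.seed)
    n = len(spec.reference)
    n_frames = spec.n_frames
    sqrtm = np.sqrt(spec.masses)

    if spec.isotropic_variance is not None:
        sigma = math.sqrt(spec.isotropic_variance)
        disp = rng.normal(0.0, sigma, size=(n_frames, n, 3))
        frames = spec.reference[None, :, :] + disp
        lambdas = np.repeat(spec.masses, 3) * spec.isotropic_variance
    else:
        ext = _external_mode_basis(spec.reference, spec.masses)  # (3N, 6)
        k = len(spec.mode_variances)
        # internal modes: random directions projected off the external space
        raw = rng.standard_normal((3 * n, k))
        raw -= ext @ (ext.T @ raw)
        modes, _ = np.linalg.qr(raw)  # (3N, k), orthonormal, _|_ external
        amps = rng.standard_normal((n_frames, k)) * np.sqrt(spec.mode_variances)
        q = amps @ modes.T  # mass-weighted displacements
        disp = (q.reshape(n_frames, n, 3)) / sqrtm[None, :, None]
        frames = spec.reference[None, :, :] + disp
        lambdas = spec.mode_variances

    if spec.rigid_motion:
        from scipy.spatial.transform import Rotation

        for i in range(n_frames):
            rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            shift = rng.normal(0.0, 5.0, size=3)
            frames[i] = frames[i] @ rot.T + shift

    atoms = [
        AtomRecord(
            serial=i + 1, name="CA", element="C", residue_name="ALA",
            residue_id=i + 1, chain="A", position=spec.reference[i],
        )
        for i in range(n)
    ]
    traj = Trajectory(topology=Structure(atoms=atoms), frames=frames)
    s_int = closed_form_internal_entropy(lambdas, spec.temperature)
    return traj, s_int


def closed_form_internal_entropy(
    mode_variances: np.ndarray, temperature: float
) -> float:
    """Quantum oscillator entropy for modes of variance lambda (amu*Å^2)."""
    lam = np.asarray(mode_variances, dtype=float)
    kbt_int = BOLTZMANN_J * temperature / (AMU_KG * ANGSTROM_M**2)
    omegas = np.sqrt(kbt_int / lam)  # rad/s
    x = HBAR_J * omegas / (BOLTZMANN_J * temperature)
    with np.errstate(over="ignore"):
        term = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return float(KB_KCALMOL * term.sum())


# --------------------------------------------------------------------------
# volume series
# --------------------------------------------------------------------------


def gen_volume_series(
    mean: float,
    target_kappa: float,
    temperature: float,
    n: int,
    seed: int = 0,
) -> VolumeSeries:
    """Gaussian volume series whose fluctuations encode ``target_kappa``.

    Inverts the fluctuation formula: Var(V) = kappa k_B T <V> (unit
    consistent: kappa in GPa^-1, volumes in Å^3), so the estimator
    recovers the target in expectation. Rejects parameter combinations
    where negative volumes would occur with probability > 1e-6.
    """
    if target_kappa <= 0:
        raise ValueError("target_kappa must be positive")
    var = (target_kappa * 1.0e-9) * BOLTZMANN_J * temperature * mean * 1.0e30
    sd = math.sqrt(var)
    if norm.cdf(0.0, loc=mean, scale=sd) > 1.0e-6:
        raise ValueError("variance would produce negative volumes (p > 1e-6)")
    rng = np.random.default_rng(seed)
    values = rng.normal(mean, sd, size=n)
    return VolumeSeries(values=values, temperature=temperature)


# --------------------------------------------------------------------------
# internal-coordinate building blocks
# --------------------------------------------------------------------------


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, torsion: float,
) -> np.ndarray:
    """NeRF placement: position d with |cd|=bond, angle(b,c,d)=angle,
    torsion(a,b,c,d)=torsion (degrees)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ideal backbone geometry
_BB = dict(n_ca=1.458, ca_c=1.525, c_n=1.329, c_o=1.231,
           ang_c_n_ca=121.7, ang_n_ca_c=111.2, ang_ca_c_n=116.2,
           ang_ca_c_o=120.8)


def build_peptide(
    n_residues: int,
    phi: float,
    psi: float,
    residue_name: str = "ALA",
    chain: str = "A",
    first_residue_id: int = 1,
    with_oxt: bool = False,
) -> Structure:
    """Ideal-geometry backbone (N, CA, C, O) at constant (phi, psi).

    Omega is fixed trans (180 deg). Useful for exercising the
    phi/psi-window secondary-structure assigner with canonical helix
    (-57, -47) or strand (-120, 130) angles.
    """
    if n_residues < 1:
        raise ValueError("need >= 1 residue")
    g = _BB
    coords: list[tuple[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([g["n_ca"], 0.0, 0.0])
    c0 = ca0 + np.array(
        [g["ca_c"] * math.cos(math.radians(180 - g["ang_n_ca_c"])),
         g["ca_c"] * math.sin(math.radians(180 - g["ang_n_ca_c"])), 0.0]
    )
    per_res: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, n_residues):
        prev = per_res[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"],
                       g["c_n"], g["ang_ca_c_n"], psi)
        ca = place_atom(prev["CA"], prev["C"], n,
                        g["n_ca"], g["ang_c_n_ca"], 180.0)  # omega trans
        c = place_atom(prev["C"], n, ca, g["ca_c"], g["ang_n_ca_c"], phi)
        per_res.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens (anti to the next N; last residue uses psi+180)
    for i, res in enumerate(per_res):
        if i + 1 < n_residues:
            nxt = per_res[i + 1]["N"]
            res["O"] = place_atom(nxt, res["CA"], res["C"],
                                  g["c_o"], g["ang_ca_c_o"], 180.0)
        else:
            res["O"] = place_atom(res["N"], res["CA"], res["C"],
                                  g["c_o"], g["ang_ca_c_o"], psi + 180.0)
            if with_oxt:
                res["OXT"] = place_atom(res["N"], res["CA"], res["C"],
                                        g["c_o"], g["ang_ca_c_o"], psi)
    atoms: list[AtomRecord] = []
    serial = 1
    for i, res in enumerate(per_res):
        for name in ("N", "CA", "C", "O", "OXT"):
            if name not in res:
                continue
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, element=name[0],
                    residue_name=residue_name, residue_id=first_residue_id + i,
                    chain=chain, position=res[name],
                )
            )
            serial += 1
    return Structure(atoms=atoms)


_LYS_CHAIN = (
    ("CG", 1.53, 111.0), ("CD", 1.53, 111.0), ("CE", 1.53, 111.0),
    ("NZ", 1.49, 111.0),
)


def build_lysine_rotamer(
    n: np.ndarray, ca: np.ndarray, cb: np.ndarray, chi: Sequence[float]
) -> dict[str, np.ndarray]:
    """Side-chain heavy atoms CB..NZ for chi = (chi1..chi4), ideal geometry."""
    if len(chi) != 4:
        raise ValueError("lysine needs 4 chi angles")
    coords = {"CB": np.asarray(cb, dtype=float)}
    prev3 = [np.asarray(n, dtype=float), np.asarray(ca, dtype=float), coords["CB"]]
    for (name, bond, angle), c in zip(_LYS_CHAIN, chi):
        new = place_atom(*prev3, bond, angle, c)
        coords[name] = new
        prev3 = [prev3[1], prev3[2], new]
    return coords


# --------------------------------------------------------------------------
# interaction fixtures
# --------------------------------------------------------------------------


@dataclass
class BridgeSpec:
    """One intended charged contact between two placed residues."""

    positive_id: int
    negative_id: int
    distance: float
    present_frames: Sequence[int] | None = None  # None -> all frames
    atp_letter: str | None = None  # "a"/"b"/"g" when the negative side is ATP


@dataclass
class InteractionFixtureSpec:
    """Declarative placement list with its expected-truth block.

    ``residues`` rows: (residue_id, residue_type, ss_label). Residues
    are laid out on a line with generous spacing; each bridge then
    pins the relevant charged atoms at the requested separation.
    """

    residues: Sequence[tuple[int, str, str]]
    bridges: Sequence[BridgeSpec]
    subdomain_of: dict[int, int]
    n_frames: int = 1
    spacing: float = 12.0
    cutoff: float = 3.2


_CHARGED_ATOM_OF = {"LYS": "NZ", "ARG": "NH1", "ASP": "OD1", "GLU": "OE1"}
_SIDECHAIN_STUBS = {
    "LYS": (("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N")),
    "ARG": (("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"), ("CZ", "C"),
            ("NH1", "N"), ("NH2", "N")),
    "ASP": (("CB", "C"), ("CG", "C"), ("OD1", "O"), ("OD2", "O")),
    "GLU": (("CB", "C"), ("CG", "C"), ("CD", "C"), ("OE1", "O"), ("OE2", "O")),
    "ALA": (("CB", "C"),),
    "GLY": (),
}


def _stub_residue(
    rid: int, rtype: str, origin: np.ndarray, serial0: int, chain: str = "A"
) -> list[AtomRecord]:
    """Minimal residue: backbone cluster + side-chain stub along +y."""
    offsets = {
        "N": (0.0, 0.0, 0.0), "CA": (1.46, 0.0, 0.0),
        "C": (2.2, 1.2, 0.0), "O": (1.8, 2.35, 0.0),
    }
    atoms = []
    s = serial0
    for name, off in offsets.items():
        atoms.append(
            AtomRecord(serial=s, name=name, element=name[0], residue_name=rtype,
                       residue_id=rid, chain=chain,
                       position=origin + np.asarray(off))
        )
        s += 1
    for k, (name, element) in enumerate(_SIDECHAIN_STUBS.get(rtype, ())):
        pos = origin + np.array([1.46, -(1.3 + 1.4 * k), 0.0])
        atoms.append(
            AtomRecord(serial=s, name=name, element=element, residue_name=rtype,
                       residue_id=rid, chain=chain, position=pos)
        )
        s += 1
    return atoms


def _atp_fragment(serial0: int, origin: np.ndarray, residue_id: int = 501
                  ) -> list[AtomRecord]:
    """Triphosphate tail + C5' stub, laid along -z from P-gamma at origin."""
    z = np.array([0.0, 0.0, 1.0])
    pg = origin
    rows = [
        ("PG", "P", pg),
        ("O1G", "O", pg + np.array([1.06, 1.06, 0.0])),
        ("O2G", "O", pg + np.array([1.06, -1.06, 0.0])),
        ("O3G", "O", pg + np.array([-1.06, 0.0, 1.06])),
        ("O3B", "O", pg - 1.55 * z),
        ("PB", "P", pg - 3.10 * z),
        ("O1B", "O", pg - 3.10 * z + np.array([1.5, 0.0, 0.0])),
        ("O2B", "O", pg - 3.10 * z + np.array([-1.5, 0.0, 0.0])),
        ("O3A", "O", pg - 4.65 * z),
        ("PA", "P", pg - 6.20 * z),
        ("O1A", "O", pg - 6.20 * z + np.array([1.5, 0.0, 0.0])),
        ("O2A", "O", pg - 6.20 * z + np.array([-1.5, 0.0, 0.0])),
        ("O5'", "O", pg - 7.75 * z),
        ("C5'", "C", pg - 9.30 * z),
    ]
    return [
        AtomRecord(serial=serial0 + i, name=n, element=e, residue_name="ATP",
                   residue_id=residue_id, chain="A", position=p)
        for i, (n, e, p) in enumerate(rows)
    ]


def gen_interaction_fixture(
    spec: InteractionFixtureSpec,
) -> tuple[Trajectory, TopologyAnnotation, dict]:
    """Build a trajectory realizing the declared bridges; return truth.

    The truth block (expected per-frame bridge count, per-category
    counts, ATP-tag counts, per-pair formation rates) is computed from
    the declarative spec alone. Bridges are broken in non-present frames
    by displacing the positive atom 5 Å away.
    """
    placements: dict[int, np.ndarray] = {}
    atoms: list[AtomRecord] = []
    serial = 1
    rtypes = {rid: rtype for rid, rtype, _ in spec.residues}
    ss_labels = {rid: lab for rid, _, lab in spec.residues}
    needs_atp = any(b.atp_letter is not None for b in spec.bridges)
    for k, (rid, rtype, _) in enumerate(spec.residues):
        origin = np.array([spec.spacing * k, 0.0, 0.0])
        placements[rid] = origin
        res_atoms = _stub_residue(rid, rtype, origin, serial)
        serial += len(res_atoms)
        atoms.extend(res_atoms)
    if needs_atp:
        atp_origin = np.array([-spec.spacing, -20.0, 0.0])
        frag = _atp_fragment(serial, atp_origin)
        serial += len(frag)
        atoms.extend(frag)

    structure = Structure(atoms=atoms)
    index_of = {
        (a.residue_id, a.name): i for i, a in enumerate(structure.atoms)
    }
    atp_letter_atom = {"a": "O1A", "b": "O1B", "g": "O1G"}

    def neg_index(bridge: BridgeSpec) -> int:
        if bridge.atp_letter is not None:
            return index_of[(501, atp_letter_atom[bridge.atp_letter])]
        neg_name = _CHARGED_ATOM_OF[rtypes[bridge.negative_id]]
        return index_of[(bridge.negative_id, neg_name)]

    # pin each positive charged atom out of the template plane so the
    # declared separations are realized without accidental contacts
    coords0 = structure.coords
    by_positive: dict[int, list[BridgeSpec]] = {}
    for bridge in spec.bridges:
        by_positive.setdefault(bridge.positive_id, []).append(bridge)
    for rid, bridges in by_positive.items():
        i = index_of[(rid, _CHARGED_ATOM_OF[rtypes[rid]])]
        if len(bridges) == 1:
            j = neg_index(bridges[0])
            coords0[i] = coords0[j] + np.array([0.0, 0.0, bridges[0].distance])
        elif len(bridges) == 2:
            # point at the two prescribed distances from both negatives
            p1, p2 = coords0[neg_index(bridges[0])], coords0[neg_index(bridges[1])]
            d1, d2 = bridges[0].distance, bridges[1].distance
            span = p2 - p1
            length = float(np.linalg.norm(span))
            a = (d1**2 - d2**2 + length**2) / (2.0 * length)
            h2 = d1**2 - a**2
            if length == 0.0 or h2 < 0.0:
                raise ValueError(
                    f"residue {rid}: distances {d1}/{d2} infeasible for "
                    f"negatives {length:.2f} Å apart"
                )
            e = span / length
            z = np.array([0.0, 0.0, 1.0])
            perp = z - np.dot(z, e) * e
            perp /= np.linalg.norm(perp)
            coords0[i] = p1 + a * e + math.sqrt(h2) * perp
        else:
            raise ValueError(
                f"residue {rid}: at most two bridges per positive residue"
            )

    # clash check across residues
    rid_of = np.array([a.residue_id for a in structure.atoms])
    dmat = np.linalg.norm(coords0[:, None, :] - coords0[None, :, :], axis=-1)
    cross = rid_of[:, None] != rid_of[None, :]
    if np.any(dmat[cross] < 1.0):
        raise ValueError("placement clash: inter-residue atoms within 1 Å")

    frames = np.repeat(coords0[None, :, :], spec.n_frames, axis=0)
    for bridge in spec.bridges:
        if bridge.present_frames is None:
            continue
        if len(by_positive[bridge.positive_id]) > 1:
            raise ValueError(
                "intermittent bridges require a dedicated positive residue"
            )
        i = index_of[(bridge.positive_id, _CHARGED_ATOM_OF[rtypes[bridge.positive_id]])]
        absent = set(range(spec.n_frames)) - set(bridge.present_frames)
        for f in absent:
            frames[f, i] += np.array([0.0, 0.0, 5.0 + bridge.distance])

    structure = structure.with_coords(frames[0])
    ranges = {sd: [] for sd in set(spec.subdomain_of.values())}
    for rid, sd in spec.subdomain_of.items():
        ranges[sd].append((rid, rid))
    config = AnnotationConfig(
        subdomain_ranges={sd: tuple(sp) for sd, sp in ranges.items()},
        ss_labels=ss_labels,
        include_termini=False,
    )
    annotation = annotate_topology(structure, config)
    trajectory = Trajectory(topology=structure, frames=frames)

    # ---- truth block ----
    # Computed from the generator's own placement tables and plain
    # distance arithmetic over the final frame geometry (never through
    # the detection/classification code under test).
    elem: dict[int, int | None] = {}
    counter = 0
    prev_rid, prev_lab = None, "C"
    for rid in sorted(ss_labels):
        lab = ss_labels[rid]
        if lab in "HE":
            if not (prev_lab == lab and prev_rid == rid - 1):
                counter += 1
            elem[rid] = counter
        else:
            elem[rid] = None
        prev_rid, prev_lab = rid, lab

    def category(rid_a: int, rid_b: int) -> str:
        la, lb = ss_labels[rid_a], ss_labels[rid_b]
        if la in "HE" and lb in "HE":
            return "intra_ss" if elem[rid_a] == elem[rid_b] else "inter_ss"
        if la in "HE" or lb in "HE":
            return "ss_loop"
        return "loop_loop"

    pos_table = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
    neg_table = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
    atp_neg = {"O1A": "a", "O2A": "a", "O1B": "b", "O2B": "b",
               "O1G": "g", "O2G": "g", "O3G": "g"}
    one_letter = {"LYS": "K", "ARG": "R"}
    pos_atoms = [
        (rid, name, index_of[(rid, name)])
        for rid, rtype, _ in spec.residues
        for name in pos_table.get(rtype, ())
    ]
    neg_atoms = [
        (rid, name, index_of[(rid, name)], None)
        for rid, rtype, _ in spec.residues
        for name in neg_table.get(rtype, ())
    ]
    if needs_atp:
        neg_atoms += [
            (501, name, index_of[(501, name)], letter)
            for name, letter in atp_neg.items()
        ]

    expected_counts = np.zeros(spec.n_frames)
    expected_categories: dict[str, np.ndarray] = {}
    expected_tags: dict[str, np.ndarray] = {}
    pair_present: dict[tuple[int, int], set[int]] = {}
    for f in range(spec.n_frames):
        for prid, _, pi in pos_atoms:
            for nrid, _, ni, letter in neg_atoms:
                d = float(np.linalg.norm(frames[f, pi] - frames[f, ni]))
                if d > spec.cutoff:
                    continue
                expected_counts[f] += 1
                pair_present.setdefault((prid, nrid), set()).add(f)
                if letter is not None:
                    tag = f"{one_letter[rtypes[prid]]}{prid}-O{letter}"
                    expected_tags.setdefault(
                        tag, np.zeros(spec.n_frames)
                    )[f] += 1
                else:
                    cat = category(prid, nrid)
                    expected_categories.setdefault(
                        cat, np.zeros(spec.n_frames)
                    )[f] += 1
                    sub = (
                        "intra"
                        if spec.subdomain_of[prid] == spec.subdomain_of[nrid]
                        else "inter"
                    )
                    expected_categories.setdefault(
                        sub + "_subdomain", np.zeros(spec.n_frames)
                    )[f] += 1

    truth = {
        "per_frame_total": expected_counts,
        "category_counts": expected_categories,
        "atp_tag_counts": expected_tags,
        "formation_rates": {
            p: len(fr) / spec.n_frames for p, fr in pair_present.items()
        },
    }
    return trajectory, annotation, truth


# --------------------------------------------------------------------------
# active-site fixtures
# --------------------------------------------------------------------------


@dataclass
class ActiveSiteSpec:
    """Waters at requested (theta, d_Nu) around an ATP-like fragment.

    ``mg_pattern``: None (no Mg), "W" (4 shell waters + 2 gamma-O) or
    "Q" (3 shell waters + 2 gamma-O + Gln side-chain O). Shell waters
    are placed on the low-theta side so they never qualify as
    nucleophile candidates.
    """

    waters: Sequence[tuple[float, float]]  # (theta deg, d Å)
    mg_pattern: str | None = None
    theta_min: float = 109.3


def gen_active_site_fixture(
    spec: ActiveSiteSpec,
) -> tuple[Structure, TopologyAnnotation, dict]:
    """Build the fragment + waters; truth names the expected water.

    Truth is derived from the requested (theta, d) values by the
    assignment rule (min d among theta > theta_min, strict), computed
    here from the spec rather than from the analysis code.
    """
    origin = np.zeros(3)
    atoms = _atp_fragment(1, origin)
    serial = len(atoms) + 1
    rid = 601
    u = np.array([0.0, 0.0, -1.0])  # direction P-gamma -> bridging O
    side = np.array([1.0, 0.0, 0.0])
    up = np.array([0.0, 1.0, 0.0])
    water_ids: list[int] = []
    positions: list[np.ndarray] = []
    for k, (theta, d) in enumerate(spec.waters):
        if d <= 0:
            raise ValueError("water distance must be positive")
        az = 2.0 * math.pi * k / max(len(spec.waters), 1)
        perp = math.cos(az) * side + math.sin(az) * up
        t = math.radians(theta)
        pos = origin + d * (math.cos(t) * u + math.sin(t) * perp)
        placed = positions + [a.position for a in atoms]
        for prev in placed:
            if np.linalg.norm(pos - prev) < 1.0:
                raise ValueError("infeasible geometry: water placements clash")
        positions.append(pos)
        atoms.append(
            AtomRecord(serial=serial, name="O", element="O", residue_name="HOH",
                       residue_id=rid, chain="W", position=pos)
        )
        water_ids.append(rid)
        serial += 1
        rid += 1

    if spec.mg_pattern is not None:
        mg_pos = np.array([2.5, 0.0, 0.0])
        atoms.append(
            AtomRecord(serial=serial, name="MG", element="MG",
                       residue_name="MG", residue_id=701, chain="A",
                       position=mg_pos)
        )
        serial += 1
        shell = [np.array([4.6, 0.0, 0.0]), np.array([2.5, 2.1, 0.0]),
                 np.array([2.5, -2.1, 0.0]), np.array([2.5, 0.0, -2.1])]
        n_shell = 4 if spec.mg_pattern == "W" else 3
        for pos in shell[:n_shell]:
            atoms.append(
                AtomRecord(serial=serial, name="O", element="O",
                           residue_name="HOH", residue_id=rid, chain="W",
                           position=pos)
            )
            serial += 1
            rid += 1
        if spec.mg_pattern == "Q":
            atoms.append(
                AtomRecord(serial=serial, name="OE1", element="O",
                           residue_name="GLN", residue_id=137, chain="A",
                           position=np.array([2.5, 0.0, 2.1]))
            )
            serial += 1

    structure = Structure(atoms=atoms)
    config = AnnotationConfig(
        subdomain_ranges={1: ((1, 1000),)}, include_termini=False
    )
    annotation = annotate_topology(structure, config)

    eligible = [
        (d, wid, theta)
        for (theta, d), wid in zip(spec.waters, water_ids)
        if theta > spec.theta_min
    ]
    truth: dict = {"mg_pattern": None, "expected_water": None}
    if eligible:
        d, wid, theta = min(eligible)
        truth["expected_water"] = {"residue": wid, "theta": theta, "d_nu": d}
    if spec.mg_pattern == "W":
        truth["mg_pattern"] = "W-type"
    elif spec.mg_pattern == "Q":
        truth["mg_pattern"] = "Q-type"
    return structure, annotation, truth


# --------------------------------------------------------------------------
# Born systems and waters
# --------------------------------------------------------------------------


def born_closed_form(charge: float, radius: float, eps_out: float,
                     eps_in: float = 1.0) -> float:
    """Born ion solvation free energy, kcal/mol."""
    return (
        -(COULOMB_KCAL / 2.0) * charge**2 * (1.0 / eps_in - 1.0 / eps_out) / radius
    )


def gen_born_system(charge: float, radius: float
                    ) -> tuple[Structure, np.ndarray, np.ndarray]:
    """Single-ion system: (structure, charges, radii)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    atom = AtomRecord(serial=1, name="ION", element="X", residue_name="ION",
                      residue_id=1, chain="A", position=np.zeros(3))
    return (
        Structure(atoms=[atom]),
        np.array([charge]),
        np.array([radius]),
    )


def make_water(
    o_pos: np.ndarray,
    h_toward: np.ndarray | None = None,
    residue_id: int = 801,
    serial0: int = 1,
    bend: float = 0.0,
) -> list[AtomRecord]:
    """Water with one O-H aimed at ``h_toward`` (optionally bent off-axis
    by ``bend`` degrees); second H placed at the 104.5 deg HOH angle."""
    o_pos = np.asarray(o_pos, dtype=float)
    if h_toward is None:
        direction = np.array([1.0, 0.0, 0.0])
    else:
        direction = np.asarray(h_toward, dtype=float) - o_pos
        direction /= np.linalg.norm(direction)
    # an axis perpendicular to the O-H direction
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, direction)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    perp = np.cross(direction, helper)
    perp /= np.linalg.norm(perp)
    b = math.radians(bend)
    h1_dir = math.cos(b) * direction + math.sin(b) * perp
    h1 = o_pos + 0.9572 * h1_dir
    a = math.radians(104.52)
    h2_dir = math.cos(a) * h1_dir - math.sin(a) * perp
    h2 = o_pos + 0.9572 * h2_dir
    return [
        AtomRecord(serial=serial0, name="O", element="O", residue_name="HOH",
                   residue_id=residue_id, chain="W", position=o_pos),
        AtomRecord(serial=serial0 + 1, name="H1", element="H", residue_name="HOH",
                   residue_id=residue_id, chain="W", position=h1),
        AtomRecord(serial=serial0 + 2, name="H2", element="H", residue_name="HOH",
                   residue_id=residue_id, chain="W", position=h2),
    ]
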