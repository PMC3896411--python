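"""ATP active-site geometry: Mg2+ coordination, nucleophilic-water
assignment, and (theta, d_Nu) free-energy surfaces.

The attack geometry of the candidate hydrolytic water is characterized
by the angle theta = O(beta-gamma bridge) - P(gamma) - O(water) and the
distance d_Nu = P(gamma) - O(water). Per frame, the expected
nucleophilic water is the one with minimum d_Nu among waters whose
theta exceeds a threshold (default 109.3 deg, strict). Binned (theta,
d_Nu) occupancies are converted to a free-energy surface
F = -ln(P / P_max) in units of kB T, zero at the occupied minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_io import WATER_NAMES, Structure, TopologyAnnotation

__all__ = [
    "CoordinationState",
    "NucleophilicWaterRecord",
    "FESGrid",
    "mg_coordination",
    "assign_nucleophilic_water",
    "theta_d_free_energy_surface",
    "hydropathy_lookup",
    "KYTE_DOOLITTLE",
    "DEFAULT_MG_CUTOFF",
    "DEFAULT_THETA_MIN",
]

DEFAULT_MG_CUTOFF = 2.6  # Å (typical Mg-O bond ~2.1 Å)
DEFAULT_THETA_MIN = 109.3  # degrees, strict inequality


@dataclass
class CoordinationState:
    """Mg2+ first-shell oxygen counts by ligand class.

    W-type is the dominant crystallographic pattern (4 waters + 2 ATP
    gamma-oxygens); Q-type has a side-chain oxygen replacing one water
    (3 waters + 2 gamma-oxygens + 1 side-chain O).
    """

    water_o: int
    atp_o: dict[str, int]  # phosphate letter -> count
    sidechain_o: int

    @property
    def coordination_number(self) -> int:
        return self.water_o + sum(self.atp_o.values()) + self.sidechain_o

    @property
    def pattern(self) -> str:
        gamma = self.atp_o.get("g", 0)
        if self.water_o == 4 and gamma == 2 and self.sidechain_o == 0 and sum(
            self.atp_o.values()
        ) == 2:
            return "W-type"
        if self.water_o == 3 and gamma == 2 and self.sidechain_o == 1 and sum(
            self.atp_o.values()
        ) == 2:
            return "Q-type"
        return "other"


def mg_coordination(
    coords: np.ndarray | None,
    annotation: TopologyAnnotation,
    cutoff: float = DEFAULT_MG_CUTOFF,
) -> CoordinationState:
    """Classify the oxygens within ``cutoff`` of the single Mg2+."""
    structure = annotation.structure
    if coords is None:
        coords = structure.coords
    coords = np.asarray(coords, dtype=float)
    mg_idx = [
        i for i, a in enumerate(structure.atoms)
        if a.element.upper() == "MG" or a.residue_name == "MG"
    ]
    if len(mg_idx) != 1:
        raise ValueError(f"expected exactly one Mg, found {len(mg_idx)}")
    mg = coords[mg_idx[0]]
    water_o = 0
    sidechain_o = 0
    atp_o: dict[str, int] = {}
    for i, a in enumerate(structure.atoms):
        if a.element.upper() != "O":
            continue
        if np.linalg.norm(coords[i] - mg) > cutoff:
            continue
        if a.residue_name in WATER_NAMES:
            water_o += 1
        elif i in annotation.atp_oxygen_tags:
            for letter in annotation.atp_oxygen_tags[i]:
                atp_o[letter] = atp_o.get(letter, 0) + 1
        elif a.residue_name == "ATP":
            atp_o["?"] = atp_o.get("?", 0) + 1
        elif a.name not in ("O", "OXT"):  # side-chain oxygen
            sidechain_o += 1
    return CoordinationState(water_o=water_o, atp_o=atp_o, sidechain_o=sidechain_o)


@dataclass(frozen=True)
class NucleophilicWaterRecord:
    """Attack geometry of the assigned water in one frame."""

    frame: int
    water_residue: int
    theta: float  # degrees
    d_nu: float  # Å


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def assign_nucleophilic_water(
    coords: np.ndarray | None,
    annotation: TopologyAnnotation,
    theta_min: float = DEFAULT_THETA_MIN,
    frame: int = 0,
) -> NucleophilicWaterRecord | None:
    """Water with minimum d_Nu among those with theta > ``theta_min``.

    theta is measured at P-gamma between the beta-gamma bridging oxygen
    and the water oxygen. Eligibility is strict (theta must exceed the
    threshold); ties in d_Nu break to the lowest water residue id.
    Returns None when no water qualifies.
    """
    structure = annotation.structure
    if coords is None:
        coords = structure.coords
    coords = np.asarray(coords, dtype=float)
    if "g" not in annotation.atp_phosphorus:
        raise ValueError("gamma phosphorus not identified in annotation")
    p_gamma = coords[annotation.atp_phosphorus["g"]]
    bridge = [
        i for i, tag in annotation.atp_oxygen_tags.items() if tag == {"b", "g"}
    ]
    if not bridge:
        raise ValueError("beta-gamma bridging oxygen not found")
    o_beta = coords[bridge[0]]

    best: NucleophilicWaterRecord | None = None
    for i, a in enumerate(structure.atoms):
        if a.residue_name not in WATER_NAMES or a.element.upper() != "O":
            continue
        d = float(np.linalg.norm(coords[i] - p_gamma))
        theta = _angle(o_beta, p_gamma, coords[i])
        if theta <= theta_min:
            continue
        if (
            best is None
            or d < best.d_nu
            or (d == best.d_nu and a.residue_id < best.water_residue)
        ):
            best = NucleophilicWaterRecord(
                frame=frame, water_residue=a.residue_id, theta=theta, d_nu=d
            )
    return best


@dataclass
class FESGrid:
    """Binned (theta, d_Nu) free-energy surface in kB T, min 0."""

    theta_edges: np.ndarray
    d_edges: np.ndarray
    free_energy: np.ndarray  # (n_theta_bins, n_d_bins); NaN marks empty bins

    @property
    def occupied_min(self) -> float:
        return float(np.nanmin(self.free_energy))

    def argmin_bin(self) -> tuple[int, int]:
        flat = np.nanargmin(self.free_energy)
        return tuple(np.unravel_index(flat, self.free_energy.shape))


def theta_d_free_energy_surface(
    records: Sequence[NucleophilicWaterRecord],
    theta_bin: float = 2.0,
    d_bin: float = 0.1,
    theta_range: tuple[float, float] = (90.0, 180.0),
    d_range: tuple[float, float] | None = None,
) -> FESGrid:
    """2-D histogram of records converted to F = -ln(count/max) in kB T.

    Bin widths default to 2 deg x 0.1 Å. Empty bins are NaN; the
    occupied minimum is exactly 0. The surface depends only on count
    ratios, so it is invariant under uniform rescaling of the counts.
    """
    if not records:
        raise ValueError("no records to histogram")
    thetas = np.array([r.theta for r in records])
    ds = np.array([r.d_nu for r in records])
    if d_range is None:
        d_range = (np.floor(ds.min() * 10) / 10, np.ceil(ds.max() * 10) / 10 + d_bin)
    t_edges = np.arange(theta_range[0], theta_range[1] + theta_bin / 2, theta_bin)
    d_edges = np.arange(d_range[0], d_range[1] + d_bin / 2, d_bin)
    counts, _, _ = np.histogram2d(thetas, ds, bins=[t_edges, d_edges])
    fes = np.full_like(counts, np.nan)
    occupied = counts > 0
    fes[occupied] = -np.log(counts[occupied] / counts.max())
    return FESGrid(theta_edges=t_edges, d_edges=d_edges, free_energy=fes)


# Kyte-Doolittle hydropathy scale (three-letter codes)
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def hydropathy_lookup(residue: str) -> float:
    """Kyte-Doolittle hydropathy index of a standard amino acid.

    Accepts one- or three-letter codes; isoleucine (4.5) is the scale
    maximum.
    """
    code = residue.upper()
    if len(code) == 1:
        code = _ONE_TO_THREE.get(code, code)
    try:
        return KYTE_DOOLITTLE[code]
    except KeyError:
        raise KeyError(f"unknown amino acid {residue!r}") from None
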