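"""Rolling-probe surface area and excluded volume; volume-fluctuation
compressibility.

SASA is the area traced by the probe center rolling over the van der
Waals surface, i.e. the exposed area of the union of probe-inflated
atomic spheres; the excluded volume V_ex is the volume enclosed by that
probe-center surface. Atomic radii follow a hybridization/H-count class
table (see :data:`DEFAULT_RADII`); hydrogens do not carry spheres.

The isothermal compressibility is estimated from equilibrium volume
fluctuations, kappa_T = (<V^2> - <V>^2) / (k_B T <V>), reported in
GPa^-1. The estimator accepts any volume series (simulation box or
per-frame excluded volume).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .constants import BOLTZMANN_J
from .model_io import Structure

__all__ = [
    "DEFAULT_RADII",
    "RadiusTable",
    "VolumeSeries",
    "assign_radius_classes",
    "sasa",
    "excluded_volume",
    "isothermal_compressibility",
    "series_stats",
    "DEFAULT_PROBE_RADIUS",
]

DEFAULT_PROBE_RADIUS = 1.4  # Å

# radius classes: hybridization and attached-hydrogen count
DEFAULT_RADII: dict[str, float] = {
    "C_SP3": 2.00,          # aliphatic carbon
    "N_SP3": 2.00,          # e.g. lysine N-zeta
    "S_H": 2.00,            # thiol sulfur
    "C_SP2": 1.70,          # sp2 carbon without hydrogen
    "N_SP2_1H": 1.70,       # sp2 nitrogen with one hydrogen
    "C_SP2_H": 1.85,        # sp2 carbon with hydrogen(s)
    "S": 1.85,              # sulfur without hydrogen
    "N_SP2_2H": 1.80,       # sp2 nitrogen with multiple hydrogens
    "O": 1.40,              # any oxygen
    # extensions beyond the protein table (documented in the methods note)
    "N_SP2": 1.70,          # sp2 nitrogen without hydrogen (Pro N, ring N)
    "P": 1.90,              # phosphate phosphorus
}


@dataclass
class RadiusTable:
    """radius_class -> radius (Å); every radius must be positive."""

    radii: Mapping[str, float]

    def __post_init__(self) -> None:
        for cls, r in self.radii.items():
            if r <= 0:
                raise ValueError(f"class {cls}: radius must be positive, got {r}")

    def __getitem__(self, cls: str) -> float:
        try:
            return self.radii[cls]
        except KeyError:
            raise KeyError(f"no radius for class {cls!r}") from None


DEFAULT_RADIUS_TABLE = RadiusTable(DEFAULT_RADII)


def _cs3(*names: str) -> dict[str, str]:
    return {n: "C_SP3" for n in names}


# atom-name -> radius-class templates, per residue. Backbone atoms are
# shared; unknown heavy atoms raise rather than defaulting.
_BACKBONE_CLASSES = {"N": "N_SP2_1H", "CA": "C_SP3", "C": "C_SP2", "O": "O",
                     "OXT": "O"}

_SIDECHAIN_CLASSES: dict[str, dict[str, str]] = {
    "ALA": _cs3("CB"),
    "ARG": {**_cs3("CB", "CG", "CD"), "NE": "N_SP2_1H", "CZ": "C_SP2",
            "NH1": "N_SP2_2H", "NH2": "N_SP2_2H"},
    "ASN": {**_cs3("CB"), "CG": "C_SP2", "OD1": "O", "ND2": "N_SP2_2H"},
    "ASP": {**_cs3("CB"), "CG": "C_SP2", "OD1": "O", "OD2": "O"},
    "CYS": {**_cs3("CB"), "SG": "S_H"},
    "GLN": {**_cs3("CB", "CG"), "CD": "C_SP2", "OE1": "O", "NE2": "N_SP2_2H"},
    "GLU": {**_cs3("CB", "CG"), "CD": "C_SP2", "OE1": "O", "OE2": "O"},
    "GLY": {},
    "HIS": {**_cs3("CB"), "CG": "C_SP2", "ND1": "N_SP2_1H", "CD2": "C_SP2_H",
            "CE1": "C_SP2_H", "NE2": "N_SP2_1H"},
    "ILE": _cs3("CB", "CG1", "CG2", "CD1"),
    "LEU": _cs3("CB", "CG", "CD1", "CD2"),
    "LYS": {**_cs3("CB", "CG", "CD", "CE"), "NZ": "N_SP3"},
    "MET": {**_cs3("CB", "CG", "CE"), "SD": "S"},
    "PHE": {**_cs3("CB"), "CG": "C_SP2", "CD1": "C_SP2_H", "CD2": "C_SP2_H",
            "CE1": "C_SP2_H", "CE2": "C_SP2_H", "CZ": "C_SP2_H"},
    "PRO": _cs3("CB", "CG", "CD"),
    "SER": {**_cs3("CB"), "OG": "O"},
    "THR": {**_cs3("CB", "CG2"), "OG1": "O"},
    "TRP": {**_cs3("CB"), "CG": "C_SP2", "CD1": "C_SP2_H", "CD2": "C_SP2",
            "NE1": "N_SP2_1H", "CE2": "C_SP2", "CE3": "C_SP2_H",
            "CZ2": "C_SP2_H", "CZ3": "C_SP2_H", "CH2": "C_SP2_H"},
    "TYR": {**_cs3("CB"), "CG": "C_SP2", "CD1": "C_SP2_H", "CD2": "C_SP2_H",
            "CE1": "C_SP2_H", "CE2": "C_SP2_H", "CZ": "C_SP2", "OH": "O"},
    "VAL": _cs3("CB", "CG1", "CG2"),
    "ATP": {
        # adenine
        "N1": "N_SP2", "C2": "C_SP2_H", "N3": "N_SP2", "C4": "C_SP2",
        "C5": "C_SP2", "C6": "C_SP2", "N6": "N_SP2_2H", "N7": "N_SP2",
        "C8": "C_SP2_H", "N9": "N_SP2",
        # ribose
        "C1'": "C_SP3", "C2'": "C_SP3", "C3'": "C_SP3", "C4'": "C_SP3",
        "C5'": "C_SP3", "O2'": "O", "O3'": "O", "O4'": "O", "O5'": "O",
        # triphosphate
        "PA": "P", "PB": "P", "PG": "P",
        "O1A": "O", "O2A": "O", "O3A": "O", "O1B": "O", "O2B": "O",
        "O3B": "O", "O1G": "O", "O2G": "O", "O3G": "O",
    },
}
# protonated/methylated histidine aliases share the His template
for _alias in ("HSP", "HIP", "3MH", "HIC"):
    _SIDECHAIN_CLASSES[_alias] = {
        **_SIDECHAIN_CLASSES["HIS"], "CM": "C_SP3", "C3M": "C_SP3",
    }


def assign_radius_classes(structure: Structure) -> list[str | None]:
    """Radius class per atom; hydrogens map to None (no sphere).

    Raises KeyError for heavy atoms not covered by the residue
    templates, rather than silently defaulting.
    """
    classes: list[str | None] = []
    for a in structure.atoms:
        if a.element.upper().startswith("H"):
            classes.append(None)
            continue
        rname = a.residue_name
        template = _SIDECHAIN_CLASSES.get(rname)
        if template is not None and a.name in template:
            classes.append(template[a.name])
        elif template is not None and a.name in _BACKBONE_CLASSES:
            classes.append(_BACKBONE_CLASSES[a.name])
        elif rname in ("HOH", "WAT", "SOL", "TIP3", "SPC") and a.element.upper() == "O":
            classes.append("O")
        else:
            raise KeyError(
                f"no radius class for atom {a.name!r} of residue {rname!r}"
            )
    return classes


def _spiral_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral lattice on the unit sphere."""
    k = np.arange(n)
    z = (2.0 * k + 1.0) / n - 1.0
    phi = k * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _sphere_setup(structure, radii, probe, classes):
    if classes is None:
        classes = assign_radius_classes(structure)
    keep = [i for i, c in enumerate(classes) if c is not None]
    centers = structure.coords[keep]
    inflated = np.array([radii[classes[i]] + probe for i in keep])
    return centers, inflated


def sasa(
    structure: Structure,
    radii: RadiusTable = DEFAULT_RADIUS_TABLE,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
    classes: list[str | None] | None = None,
) -> float:
    """Solvent-accessible surface area (Å^2).

    Numeric integration over ``n_points`` deterministic spiral-lattice
    points per atom, on spheres of radius r_i + probe; a point counts as
    accessible when it lies outside every other inflated sphere.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    centers, inflated = _sphere_setup(structure, radii, probe, classes)
    unit = _spiral_points(n_points)
    n = len(centers)
    pair_d = cdist(centers, centers)
    total = 0.0
    for i in range(n):
        neighbors = np.flatnonzero(
            (pair_d[i] < inflated[i] + inflated) & (np.arange(n) != i)
        )
        pts = centers[i] + inflated[i] * unit
        if neighbors.size:
            d = cdist(pts, centers[neighbors])
            buried = (d < inflated[neighbors]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        total += 4.0 * np.pi * inflated[i] ** 2 * frac
    return float(total)


def excluded_volume(
    structure: Structure,
    radii: RadiusTable = DEFAULT_RADIUS_TABLE,
    probe: float = DEFAULT_PROBE_RADIUS,
    grid_spacing: float = 0.25,
    classes: list[str | None] | None = None,
) -> float:
    """Volume of the union of probe-inflated atomic spheres (Å^3).

    Grid occupancy with a cell-centroid-in-sphere test; refuses grids
    coarser than 0.5 Å.
    """
    if grid_spacing > 0.5:
        raise ValueError(
            f"grid_spacing {grid_spacing} Å too coarse; must be <= 0.5 Å"
        )
    centers, inflated = _sphere_setup(structure, radii, probe, classes)
    rmax = inflated.max()
    lo = centers.min(axis=0) - rmax - grid_spacing
    hi = centers.max(axis=0) + rmax + grid_spacing
    h = grid_spacing
    axes = [np.arange(lo[d] + h / 2, hi[d], h) for d in range(3)]
    shape = tuple(len(ax) for ax in axes)
    occupied = np.zeros(shape, dtype=bool)
    for c, r in zip(centers, inflated):
        # subbox around this sphere
        sl = []
        for d in range(3):
            i0 = int(np.floor((c[d] - r - lo[d]) / h))
            i1 = int(np.ceil((c[d] + r - lo[d]) / h)) + 1
            sl.append(slice(max(i0, 0), min(i1, shape[d])))
        sub = np.meshgrid(
            axes[0][sl[0]], axes[1][sl[1]], axes[2][sl[2]], indexing="ij"
        )
        d2 = (sub[0] - c[0]) ** 2 + (sub[1] - c[1]) ** 2 + (sub[2] - c[2]) ** 2
        occupied[sl[0], sl[1], sl[2]] |= d2 <= r * r
    return float(occupied.sum()) * h**3


@dataclass
class VolumeSeries:
    """Per-frame volumes (Å^3) at a fixed temperature (K)."""

    values: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("need >= 2 volume samples for fluctuation statistics")
        if np.any(self.values <= 0.0):
            raise ValueError("volumes must be positive")
        if self.temperature <= 0.0:
            raise ValueError("temperature must be positive")


def isothermal_compressibility(series: VolumeSeries) -> float:
    """kappa_T = (<V^2> - <V>^2) / (k_B T <V>), in GPa^-1.

    Averages run over the supplied series (population variance). A
    constant series returns 0.
    """
    v = series.values
    var = float(v.var())  # Å^6, population
    mean = float(v.mean())  # Å^3
    kappa_pa = (var / mean) * 1.0e-30 / (BOLTZMANN_J * series.temperature)
    return kappa_pa * 1.0e9  # GPa^-1


def series_stats(
    values: np.ndarray, window: slice | tuple[int, int] | None = None
) -> tuple[float, float]:
    """Arithmetic mean and population SD over a frame window."""
    values = np.asarray(values, dtype=float)
    if isinstance(window, tuple):
        window = slice(*window)
    if window is not None:
        values = values[window]
    if values.size == 0:
        raise ValueError("empty window")
    return float(values.mean()), float(values.std())
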