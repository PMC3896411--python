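"""Structures, trajectories, scalar series and topology annotation.

This module defines the in-memory containers the rest of the package
operates on and the plain-text interchange formats used to move them
around:

* multi-model PDB (ATOM/HETATM/MODEL/ENDMDL/TER) for structures and
  conformational ensembles, read and written through :mod:`biotite`;
* a TSV frame table (``frame  serial  x  y  z``) as a compact
  alternative trajectory format;
* a TSV scalar table (``frame  volume  total  electrostatic ...``) for
  per-frame volumes and energy terms;
* YAML/JSON run configuration.

Topology annotation marks the atoms that the interaction and active-site
analyses need: charged nitrogens/oxygens (with ATP phosphate oxygens
tagged alpha/beta/gamma by phosphorus connectivity), hydrogen-bond
donors and acceptors, subdomain membership and secondary-structure
labels.

Conventions: coordinates in Å, 1-based PDB residue numbering,
right-handed axes. Insertion codes are rejected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "EnergyTerms",
    "SubdomainMap",
    "TopologyAnnotation",
    "AnnotationConfig",
    "PDBParseError",
    "EmptyInputError",
    "AlignmentError",
    "TopologyError",
    "MappingError",
    "read_pdb",
    "write_pdb",
    "read_frames_tsv",
    "write_frames_tsv",
    "read_scalars_tsv",
    "write_scalars_tsv",
    "load_trajectory",
    "write_trajectory",
    "annotate_topology",
    "load_config",
    "save_config",
    "DEFAULT_SUBDOMAIN_RANGES",
]


class PDBParseError(ValueError):
    """A PDB record could not be parsed; carries the 1-based line number."""


class EmptyInputError(ValueError):
    """An input contained no usable atoms or frames."""


class AlignmentError(ValueError):
    """Frames and per-frame scalars disagree in length or indexing."""


class TopologyError(ValueError):
    """Atom count or identity drifts across frames of one trajectory."""


class MappingError(KeyError):
    """A protein residue falls outside every configured subdomain range."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

WATER_NAMES = {"HOH", "WAT", "TIP3", "SPC", "SOL"}

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # protonated / methylated histidine aliases (post-translationally
    # modified His73 in actin is 3-methyl-histidine, a protonated His)
    "HSP", "HIP", "3MH", "HIC",
}

PROTONATED_HIS = {"HSP", "HIP", "3MH", "HIC"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, position and optional per-atom parameters."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray  # (3,) Å
    radius_class: str | None = None
    partial_charge: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(
                f"atom {self.serial} {self.name}: position must be a finite "
                f"3-vector, got {self.position!r}"
            )
        object.__setattr__(self, "position", pos)
        if self.residue_id < 1:
            raise ValueError(
                f"atom {self.serial}: residue_id must be >= 1 "
                f"(got {self.residue_id})"
            )


@dataclass
class Structure:
    """An ordered collection of atoms, optionally with a box volume (ų)."""

    atoms: list[AtomRecord]
    box_volume: float | None = None

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise EmptyInputError("Structure requires at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serial numbers must be unique")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [replace(a, position=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms=atoms, box_volume=self.box_volume)

    # ---- selections -----------------------------------------------------

    def indices(
        self,
        *,
        atom_names: Iterable[str] | None = None,
        residue_ids: Iterable[int] | None = None,
        residue_names: Iterable[str] | None = None,
        elements: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching every given filter (AND semantics)."""
        mask = np.ones(len(self.atoms), dtype=bool)
        if atom_names is not None:
            names = set(atom_names)
            mask &= np.array([a.name in names for a in self.atoms])
        if residue_ids is not None:
            rids = set(residue_ids)
            mask &= np.array([a.residue_id in rids for a in self.atoms])
        if residue_names is not None:
            rnames = set(residue_names)
            mask &= np.array([a.residue_name in rnames for a in self.atoms])
        if elements is not None:
            els = {e.upper() for e in elements}
            mask &= np.array([a.element.upper() in els for a in self.atoms])
        return np.flatnonzero(mask)

    def backbone_indices(self) -> np.ndarray:
        """Backbone heavy atoms (N, CA, C, O) of protein residues."""
        sel = [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_name in PROTEIN_RESIDUES
            and a.name in ("N", "CA", "C", "O")
        ]
        return np.asarray(sel, dtype=int)

    def protein_residue_ids(self) -> list[int]:
        """Sorted unique residue ids of protein residues."""
        return sorted(
            {a.residue_id for a in self.atoms if a.residue_name in PROTEIN_RESIDUES}
        )


@dataclass
class EnergyTerms:
    """Per-frame solute energy decomposition in kcal/mol."""

    total: float
    electrostatic: float | None = None
    components: dict[str, float] = field(default_factory=dict)
    complete: bool = False

    def __post_init__(self) -> None:
        if self.complete and self.components:
            s = sum(self.components.values())
            if abs(s - self.total) > 1.0e-3:
                raise ValueError(
                    f"components sum to {s}, expected total {self.total} "
                    f"(|diff| > 1e-3 kcal/mol)"
                )


@dataclass
class Trajectory:
    """Frame-invariant topology plus per-frame coordinates and scalars."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3) Å
    volumes: np.ndarray | None = None  # (n_frames,) ų
    energies: list[EnergyTerms] | None = None
    frame_interval: float = 0.5  # ps between stored frames

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise TopologyError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{len(self.topology)}"
            )
        n = self.n_frames
        if self.volumes is not None:
            self.volumes = np.asarray(self.volumes, dtype=float)
            if self.volumes.shape != (n,):
                raise AlignmentError(
                    f"{self.volumes.shape[0] if self.volumes.ndim else 0} "
                    f"volumes for {n} frames"
                )
        if self.energies is not None and len(self.energies) != n:
            raise AlignmentError(f"{len(self.energies)} energy rows for {n} frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, i: int) -> Structure:
        """Topology with the coordinates of frame ``i``."""
        return self.topology.with_coords(self.frames[i])


@dataclass
class SubdomainMap:
    """Total, single-valued map residue_id -> subdomain index (1..4)."""

    mapping: dict[int, int]

    def __getitem__(self, residue_id: int) -> int:
        try:
            return self.mapping[residue_id]
        except KeyError:
            raise MappingError(
                f"residue {residue_id} not assigned to any subdomain"
            ) from None

    def __contains__(self, residue_id: int) -> bool:
        return residue_id in self.mapping

    def centroid_ids(self) -> dict[int, list[int]]:
        """Residue ids grouped per subdomain index."""
        out: dict[int, list[int]] = {}
        for rid, sd in self.mapping.items():
            out.setdefault(sd, []).append(rid)
        return out


# Subdomain residue ranges for the actin fold. The lobes are the standard
# four subdomains of the monomer; boundary residues sit at the hinge
# (141/142 and 336/337) of the propeller motion. Overridable in config.
DEFAULT_SUBDOMAIN_RANGES: dict[int, tuple[tuple[int, int], ...]] = {
    1: ((1, 32), (70, 141), (338, 375)),
    2: ((33, 69),),
    3: ((142, 180), (270, 337)),
    4: ((181, 269),),
}


def subdomain_map_from_ranges(
    residue_ids: Iterable[int],
    ranges: Mapping[int, Sequence[tuple[int, int]]] = DEFAULT_SUBDOMAIN_RANGES,
) -> SubdomainMap:
    """Assign each residue id to the subdomain whose range contains it."""
    mapping: dict[int, int] = {}
    for rid in residue_ids:
        hits = [
            sd
            for sd, spans in ranges.items()
            if any(lo <= rid <= hi for lo, hi in spans)
        ]
        if len(hits) == 0:
            raise MappingError(f"residue {rid} outside all subdomain ranges")
        if len(hits) > 1:
            raise MappingError(f"residue {rid} matched subdomains {hits}")
        mapping[rid] = hits[0]
    return SubdomainMap(mapping)


@dataclass
class TopologyAnnotation:
    """Atoms and labels the interaction/active-site analyses consume.

    ``charged_atoms`` maps atom index (into the structure's atom list) to
    +1/-1. ``atp_oxygen_tags`` maps atom index of each ATP phosphate
    oxygen to the frozenset of phosphate letters ("a"/"b"/"g") of the
    phosphorus atoms it is bonded to; bridging esters carry two letters.
    """

    structure: Structure
    charged_atoms: dict[int, int]
    hbond_donors: list[tuple[int, int]]  # (heavy atom idx, H idx)
    hbond_acceptors: list[int]
    subdomains: SubdomainMap
    ss_labels: dict[int, str]  # residue_id -> H/E/C
    atp_oxygen_tags: dict[int, frozenset[str]] = field(default_factory=dict)
    atp_phosphorus: dict[str, int] = field(default_factory=dict)  # "a"/"b"/"g" -> idx
    warnings: list[str] = field(default_factory=list)

    def charged_positive(self) -> list[int]:
        return [i for i, s in self.charged_atoms.items() if s > 0]

    def charged_negative(self) -> list[int]:
        return [i for i, s in self.charged_atoms.items() if s < 0]


@dataclass
class AnnotationConfig:
    """Knobs for :func:`annotate_topology`."""

    subdomain_ranges: Mapping[int, Sequence[tuple[int, int]]] = field(
        default_factory=lambda: DEFAULT_SUBDOMAIN_RANGES
    )
    ss_labels: Mapping[int, str] | None = None  # external per-residue H/E/C
    protonated_his: frozenset[int] = frozenset()  # residue ids
    acetylated_n_terminus: bool = False
    include_termini: bool = True
    po_bond_cutoff: float = 1.9  # Å, P-O covalent bond detection
    nh_bond_cutoff: float = 1.25  # Å, heavy-atom-to-H bond detection


# --------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# --------------------------------------------------------------------------


def _prevalidate_pdb(path: Path) -> None:
    """Line-level sanity check so errors can report a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}:{lineno}: truncated {rec} record"
                )
            if line[26] != " ":
                raise PDBParseError(
                    f"{path}:{lineno}: insertion code {line[26]!r} not supported"
                )
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"{path}:{lineno}: unparseable {what} coordinate "
                        f"{line[lo:hi]!r}"
                    ) from None


def _atoms_from_array(arr: bst.AtomArray) -> list[AtomRecord]:
    serials = (
        arr.atom_id
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, arr.array_length() + 1)
    )
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(
            AtomRecord(
                serial=int(serials[i]),
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]) or _guess_element(str(arr.atom_name[i])),
                residue_name=str(arr.res_name[i]),
                residue_id=int(arr.res_id[i]),
                chain=str(arr.chain_id[i]) or "A",
                position=arr.coord[i],
            )
        )
    return atoms


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if stripped[:2].upper() in ("MG", "CL", "NA", "FE", "ZN", "CA"):
        return stripped[:2].capitalize()
    return stripped[:1].upper()


def read_pdb(path: str | Path, model_policy: str = "first"):
    """Read a (possibly multi-model) PDB file.

    Parameters
    ----------
    path
        PDB file honoring ATOM/HETATM/MODEL/ENDMDL/TER records. HETATM
        ligands (ATP, MG, HOH) are retained; insertion codes rejected.
    model_policy
        ``"first"`` returns a single :class:`Structure`; ``"all"``
        returns a list, one per model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except PDBParseError:
        raise
    except Exception as exc:  # biotite parse failure without line info
        raise PDBParseError(f"{path}: {exc}") from exc
    if n_models == 0:
        raise EmptyInputError(f"{path}: no models")

    def one(model: int) -> Structure:
        arr = pdb.get_structure(model=model, extra_fields=["atom_id"])
        if arr.array_length() == 0:
            raise EmptyInputError(f"{path}: model {model} has no atoms")
        return Structure(atoms=_atoms_from_array(arr))

    if model_policy == "first":
        return one(1)
    if model_policy == "all":
        return [one(m) for m in range(1, n_models + 1)]
    raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")


def _array_from_structure(structure: Structure) -> bst.AtomArray:
    n = len(structure)
    arr = bst.AtomArray(n)
    arr.coord = structure.coords
    arr.set_annotation(
        "atom_id", np.array([a.serial for a in structure.atoms], dtype=int)
    )
    arr.chain_id = np.array([a.chain for a in structure.atoms])
    arr.res_id = np.array([a.residue_id for a in structure.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element.upper() for a in structure.atoms])
    arr.hetero = np.array(
        [a.residue_name not in PROTEIN_RESIDUES for a in structure.atoms]
    )
    return arr


def write_pdb(structures: Structure | Sequence[Structure], path: str | Path) -> None:
    """Write one structure, or a list as a multi-model PDB."""
    if isinstance(structures, Structure):
        structures = [structures]
    if len(structures) == 0:
        raise EmptyInputError("nothing to write")
    pdb = PDBFile()
    if len(structures) == 1:
        pdb.set_structure(_array_from_structure(structures[0]))
    else:
        ref = structures[0]
        stack = bst.stack([_array_from_structure(s) for s in structures])
        del ref
        pdb.set_structure(stack)
    pdb.write(str(path))


# --------------------------------------------------------------------------
# TSV trajectory / scalar formats
# --------------------------------------------------------------------------


def write_frames_tsv(trajectory: Trajectory, path: str | Path) -> None:
    """Write frames as a TSV table (frame, serial, x, y, z)."""
    serials = np.array([a.serial for a in trajectory.topology.atoms], dtype=int)
    n_frames, n_atoms = trajectory.n_frames, trajectory.n_atoms
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_frames), n_atoms),
            "serial": np.tile(serials, n_frames),
            "x": trajectory.frames[:, :, 0].ravel(),
            "y": trajectory.frames[:, :, 1].ravel(),
            "z": trajectory.frames[:, :, 2].ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_frames_tsv(path: str | Path, topology: Structure) -> np.ndarray:
    """Read a TSV frame table into an (n_frames, n_atoms, 3) array."""
    df = pd.read_csv(path, sep="\t")
    required = {"frame", "serial", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise AlignmentError(
            f"{path}: frame table needs columns {sorted(required)}"
        )
    serials = [a.serial for a in topology.atoms]
    order = {s: i for i, s in enumerate(serials)}
    frame_ids = np.sort(df["frame"].unique())
    n_atoms = len(serials)
    frames = np.empty((len(frame_ids), n_atoms, 3), dtype=float)
    for k, fid in enumerate(frame_ids):
        sub = df[df["frame"] == fid]
        if len(sub) != n_atoms:
            raise TopologyError(
                f"{path}: frame {fid} has {len(sub)} atoms, topology has {n_atoms}"
            )
        idx = np.array([order[s] for s in sub["serial"]])
        frames[k, idx, :] = sub[["x", "y", "z"]].to_numpy()
    return frames


def write_scalars_tsv(
    path: str | Path,
    volumes: np.ndarray | None = None,
    energies: Sequence[EnergyTerms] | None = None,
) -> None:
    """Write per-frame scalars; columns present only when data is."""
    n = len(volumes) if volumes is not None else len(energies or [])
    data: dict[str, list] = {"frame": list(range(n))}
    if volumes is not None:
        data["volume"] = list(np.asarray(volumes, dtype=float))
    if energies is not None:
        data["total"] = [e.total for e in energies]
        if any(e.electrostatic is not None for e in energies):
            data["electrostatic"] = [
                e.electrostatic if e.electrostatic is not None else math.nan
                for e in energies
            ]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_scalars_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "frame" not in df.columns:
        raise AlignmentError(f"{path}: scalar table needs a 'frame' column")
    return df


def load_trajectory(
    structure_path: str | Path,
    frames_path: str | Path,
    scalars_path: str | Path | None = None,
    frame_interval: float = 0.5,
) -> Trajectory:
    """Assemble a trajectory from structure + frames (+ optional scalars).

    ``frames_path`` may be a multi-model PDB or a TSV frame table
    (selected by extension). Scalar rows are matched to frames by frame
    index; a length mismatch is an error.
    """
    topology = read_pdb(structure_path, model_policy="first")
    frames_path = Path(frames_path)
    if frames_path.suffix.lower() in (".tsv", ".txt"):
        frames = read_frames_tsv(frames_path, topology)
    else:
        models = read_pdb(frames_path, model_policy="all")
        counts = {len(m) for m in models}
        if len(counts) != 1:
            raise TopologyError(f"{frames_path}: atom count drifts across models")
        if next(iter(counts)) != len(topology):
            raise TopologyError(
                f"{frames_path}: model atom count differs from topology"
            )
        frames = np.stack([m.coords for m in models])

    volumes = None
    energies = None
    if scalars_path is not None:
        df = read_scalars_tsv(scalars_path)
        if len(df) != frames.shape[0]:
            raise AlignmentError(
                f"{scalars_path}: {len(df)} scalar rows for "
                f"{frames.shape[0]} frames"
            )
        df = df.sort_values("frame")
        if "volume" in df.columns:
            volumes = df["volume"].to_numpy(dtype=float)
        if "total" in df.columns:
            elec = (
                df["electrostatic"].to_numpy(dtype=float)
                if "electrostatic" in df.columns
                else [None] * len(df)
            )
            energies = [
                EnergyTerms(total=float(t), electrostatic=(None if e is None or
                            (isinstance(e, float) and math.isnan(e)) else float(e)))
                for t, e in zip(df["total"].to_numpy(dtype=float), elec)
            ]
    return Trajectory(
        topology=topology,
        frames=frames,
        volumes=volumes,
        energies=energies,
        frame_interval=frame_interval,
    )


def write_trajectory(trajectory: Trajectory, structure_path, frames_path,
                     scalars_path=None) -> None:
    """Inverse of :func:`load_trajectory` (TSV or multi-model PDB frames)."""
    write_pdb(trajectory.topology, structure_path)
    frames_path = Path(frames_path)
    if frames_path.suffix.lower() in (".tsv", ".txt"):
        write_frames_tsv(trajectory, frames_path)
    else:
        write_pdb(
            [trajectory.topology.with_coords(f) for f in trajectory.frames],
            frames_path,
        )
    if scalars_path is not None and (
        trajectory.volumes is not None or trajectory.energies is not None
    ):
        write_scalars_tsv(
            scalars_path, volumes=trajectory.volumes, energies=trajectory.energies
        )


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(config: Mapping, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(dict(config), indent=2))
    else:
        path.write_text(yaml.safe_dump(dict(config)))


# --------------------------------------------------------------------------
# topology annotation
# --------------------------------------------------------------------------

# side-chain atoms carrying formal charge, per residue template
_CHARGED_SIDECHAIN: dict[str, dict[str, int]] = {
    "ASP": {"OD1": -1, "OD2": -1},
    "GLU": {"OE1": -1, "OE2": -1},
    "LYS": {"NZ": +1},
    "ARG": {"NH1": +1, "NH2": +1, "NE": +1},
}
_PROTONATED_HIS_ATOMS = {"ND1": +1, "NE2": +1}


def _bonded_pairs(
    coords: np.ndarray, idx_a: Sequence[int], idx_b: Sequence[int], cutoff: float
) -> list[tuple[int, int]]:
    """(i, j) with i in idx_a, j in idx_b, |r_i - r_j| <= cutoff."""
    if len(idx_a) == 0 or len(idx_b) == 0:
        return []
    da = coords[np.asarray(idx_a)][:, None, :] - coords[np.asarray(idx_b)][None, :, :]
    dist = np.linalg.norm(da, axis=-1)
    out = []
    for ia, i in enumerate(idx_a):
        for jb, j in enumerate(idx_b):
            if i != j and dist[ia, jb] <= cutoff:
                out.append((i, j))
    return out


def _tag_atp_phosphates(
    structure: Structure, cutoff: float
) -> tuple[dict[int, frozenset[str]], dict[str, int]]:
    """Tag ATP phosphate oxygens alpha/beta/gamma by P-O connectivity.

    The alpha phosphorus is the one whose ester oxygen bonds to a carbon
    (O5'); the gamma phosphorus terminates the chain. Each oxygen is
    tagged with the letters of every phosphorus it bonds to, so bridging
    esters carry two letters.
    """
    coords = structure.coords
    atp_idx = [
        i for i, a in enumerate(structure.atoms) if a.residue_name == "ATP"
    ]
    p_idx = [i for i in atp_idx if structure.atoms[i].element.upper() == "P"]
    o_idx = [i for i in atp_idx if structure.atoms[i].element.upper() == "O"]
    c_idx = [i for i in atp_idx if structure.atoms[i].element.upper() == "C"]
    if not p_idx:
        return {}, {}
    po = _bonded_pairs(coords, p_idx, o_idx, cutoff)
    oc = {j for j, _ in _bonded_pairs(coords, o_idx, c_idx, 1.6)}
    o_partners: dict[int, list[int]] = {}
    p_partners: dict[int, list[int]] = {i: [] for i in p_idx}
    for p, o in po:
        o_partners.setdefault(o, []).append(p)
        p_partners[p].append(o)
    # phosphorus adjacency through bridging oxygens
    p_adj: dict[int, set[int]] = {i: set() for i in p_idx}
    for o, ps in o_partners.items():
        if len(ps) == 2:
            p_adj[ps[0]].add(ps[1])
            p_adj[ps[1]].add(ps[0])
    # alpha P: bonded to the ester oxygen that bonds a carbon
    alpha = None
    for p in p_idx:
        if any(o in oc for o in p_partners[p]):
            alpha = p
            break
    if alpha is None:  # fragment without ribose: terminal P with fewest links
        alpha = min(p_idx, key=lambda p: len(p_adj[p]))
    order = [alpha]
    while len(order) < len(p_idx):
        nxt = [p for p in p_adj[order[-1]] if p not in order]
        if not nxt:
            break
        order.append(nxt[0])
    letters = ["a", "b", "g"]
    p_letter = {p: letters[k] for k, p in enumerate(order[:3])}
    tags = {
        o: frozenset(p_letter[p] for p in ps if p in p_letter)
        for o, ps in o_partners.items()
    }
    tags = {o: t for o, t in tags.items() if t}
    return tags, {v: k for k, v in p_letter.items()}


def annotate_topology(
    structure: Structure, config: AnnotationConfig | None = None
) -> TopologyAnnotation:
    """Mark charged atoms, H-bond donors/acceptors, subdomains and ss labels.

    Charged set: Asp/Glu carboxylate oxygens (-1), Lys N-zeta (+1), Arg
    guanidinium nitrogens (+1), nitrogens of protonated histidines (+1;
    via residue alias or ``config.protonated_his``), chain termini (free
    amine N +1 unless acetylated; carboxylate O/OXT -1 when OXT present),
    and ATP phosphate oxygens (-1) tagged alpha/beta/gamma by phosphorus
    connectivity. Unknown residue names are excluded with a warning.
    """
    config = config or AnnotationConfig()
    atoms = structure.atoms
    coords = structure.coords
    warnings: list[str] = []
    charged: dict[int, int] = {}

    known = (
        PROTEIN_RESIDUES | WATER_NAMES | {"ATP", "ADP", "MG", "CA", "K", "CL", "NA"}
    )
    by_residue: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(atoms):
        by_residue.setdefault((a.chain, a.residue_id), []).append(i)
        if a.residue_name not in known:
            msg = f"unknown residue {a.residue_name} {a.residue_id}: excluded"
            if msg not in warnings:
                warnings.append(msg)

    for i, a in enumerate(atoms):
        if a.residue_name not in known:
            continue
        template = _CHARGED_SIDECHAIN.get(a.residue_name, {})
        if a.name in template:
            charged[i] = template[a.name]
        if (
            a.residue_name in PROTONATED_HIS
            or (a.residue_name == "HIS" and a.residue_id in config.protonated_his)
        ) and a.name in _PROTONATED_HIS_ATOMS:
            charged[i] = +1

    # termini of each protein chain
    if config.include_termini:
        protein_by_chain: dict[str, list[int]] = {}
        for i, a in enumerate(atoms):
            if a.residue_name in PROTEIN_RESIDUES:
                protein_by_chain.setdefault(a.chain, []).append(i)
        for chain, idxs in protein_by_chain.items():
            rids = sorted({atoms[i].residue_id for i in idxs})
            first, last = rids[0], rids[-1]
            for i in idxs:
                a = atoms[i]
                if (
                    a.residue_id == first
                    and a.name == "N"
                    and not config.acetylated_n_terminus
                ):
                    charged[i] = +1
            has_oxt = any(
                atoms[i].residue_id == last and atoms[i].name == "OXT" for i in idxs
            )
            if has_oxt:
                for i in idxs:
                    a = atoms[i]
                    if a.residue_id == last and a.name in ("O", "OXT"):
                        charged[i] = -1

    # ATP phosphate oxygens
    atp_tags, atp_p = _tag_atp_phosphates(structure, config.po_bond_cutoff)
    for o, tag in atp_tags.items():
        if len(tag) == 1:  # non-bridging oxygens carry the formal charge
            charged[o] = -1

    # hydrogen-bond donors/acceptors
    heavy_idx = [
        i for i, a in enumerate(atoms) if a.element.upper() in ("N", "O", "S")
    ]
    h_idx = [i for i, a in enumerate(atoms) if a.element.upper() == "H"]
    donors: list[tuple[int, int]] = []
    donor_heavy: set[int] = set()
    for heavy, h in _bonded_pairs(coords, heavy_idx, h_idx, config.nh_bond_cutoff):
        if atoms[heavy].residue_id == atoms[h].residue_id:
            donors.append((heavy, h))
            donor_heavy.add(heavy)
    acceptors = [
        i
        for i in heavy_idx
        if atoms[i].element.upper() == "O"
        or (atoms[i].element.upper() == "N" and i not in donor_heavy)
    ]

    prot_rids = structure.protein_residue_ids()
    subdomains = subdomain_map_from_ranges(prot_rids, config.subdomain_ranges)

    if config.ss_labels is not None:
        ss = {rid: config.ss_labels.get(rid, "C") for rid in prot_rids}
    else:
        ss = {rid: "C" for rid in prot_rids}

    return TopologyAnnotation(
        structure=structure,
        charged_atoms=charged,
        hbond_donors=donors,
        hbond_acceptors=acceptors,
        subdomains=subdomains,
        ss_labels=ss,
        atp_oxygen_tags=atp_tags,
        atp_phosphorus=atp_p,
        warnings=warnings,
    )
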