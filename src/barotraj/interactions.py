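"""Salt-bridge and hydrogen-bond detection, classification, aggregation.

A salt bridge is a charged-nitrogen / charged-oxygen pair within a
distance cutoff (default 3.2 Å, boundary inclusive); several bridges may
link one residue pair. Bridges are classified by the secondary-structure
elements and subdomains of the two residues, with ATP-involved bridges
kept in their own category and tagged by the phosphate oxygen
(alpha/beta/gamma) they involve. Aggregation over frames yields
per-category mean counts +- SD and per-residue-pair formation rates.

The phi/psi-window secondary-structure assigner is a documented,
replaceable fallback; an externally supplied per-residue annotation
always takes precedence.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import dihedral
from .model_io import (
    PROTEIN_RESIDUES,
    WATER_NAMES,
    Structure,
    SubdomainMap,
    TopologyAnnotation,
)

__all__ = [
    "SecondaryStructureProfile",
    "SaltBridgeRecord",
    "HBondRecord",
    "InteractionSummary",
    "assign_secondary_structure",
    "detect_salt_bridges",
    "detect_hbonds",
    "classify_salt_bridges",
    "aggregate_interactions",
    "SS_CATEGORIES",
    "DEFAULT_SALT_BRIDGE_CUTOFF",
]

DEFAULT_SALT_BRIDGE_CUTOFF = 3.2  # Å, inclusive
DEFAULT_HBOND_DISTANCE = 3.0  # Å donor-acceptor heavy atoms
DEFAULT_HBOND_ANGLE = 160.0  # degrees D-H...A

SS_CATEGORIES = ("inter_ss", "ss_loop", "loop_loop", "intra_ss")

# phi/psi windows of the fallback assigner, degrees
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_STRAND_PHI = (-180.0, -40.0)
_STRAND_PSI = ((90.0, 180.0), (-180.0, -170.0))
_MIN_RUN = {"H": 4, "E": 3}


@dataclass
class SecondaryStructureProfile:
    """Per-residue H/E/C labels with element ids grouping contiguous runs."""

    labels: dict[int, str]  # residue_id -> H/E/C
    element_ids: dict[int, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.element_ids:
            self.element_ids = _element_ids(self.labels)


def _element_ids(labels: Mapping[int, str]) -> dict[int, int | None]:
    """Distinct integer per contiguous H or E run; None for coil."""
    out: dict[int, int | None] = {}
    current = 0
    prev_rid: int | None = None
    prev_label = "C"
    for rid in sorted(labels):
        lab = labels[rid]
        if lab in ("H", "E"):
            if not (prev_label == lab and prev_rid == rid - 1):
                current += 1
            out[rid] = current
        else:
            out[rid] = None
        prev_rid, prev_label = rid, lab
    return out


def _in(x: float, lo: float, hi: float) -> bool:
    return lo <= x <= hi


def assign_secondary_structure(
    structure: Structure,
    external: Mapping[int, str] | None = None,
) -> SecondaryStructureProfile:
    """Assign H/E/C per residue from backbone phi/psi windows.

    Helix requires phi in [-100, -30] and psi in [-80, -5] over runs of
    >= 4 residues; strand requires phi in [-180, -40] and psi in
    [90, 180] or [-180, -170] over runs of >= 3. Terminal residues with
    only one defined angle are judged on that angle. Sub-run-length
    stretches and residues missing backbone atoms are coil. When
    ``external`` labels are supplied they are used verbatim.
    """
    rids = structure.protein_residue_ids()
    if external is not None:
        return SecondaryStructureProfile(
            labels={rid: external.get(rid, "C") for rid in rids}
        )
    backbone: dict[int, dict[str, np.ndarray]] = {}
    for a in structure.atoms:
        if a.residue_name in PROTEIN_RESIDUES and a.name in ("N", "CA", "C"):
            backbone.setdefault(a.residue_id, {})[a.name] = a.position

    raw: dict[int, str] = {}
    for rid in rids:
        bb = backbone.get(rid, {})
        if not all(k in bb for k in ("N", "CA", "C")):
            _warnings.warn(f"residue {rid}: missing backbone atom, labeled C")
            raw[rid] = "C"
            continue
        prev = backbone.get(rid - 1)
        nxt = backbone.get(rid + 1)
        phi = (
            dihedral(prev["C"], bb["N"], bb["CA"], bb["C"])
            if prev and "C" in prev
            else None
        )
        psi = (
            dihedral(bb["N"], bb["CA"], bb["C"], nxt["N"])
            if nxt and "N" in nxt
            else None
        )
        if phi is None and psi is None:
            raw[rid] = "C"
            continue
        helix = (phi is None or _in(phi, *_HELIX_PHI)) and (
            psi is None or _in(psi, *_HELIX_PSI)
        )
        strand = (phi is None or _in(phi, *_STRAND_PHI)) and (
            psi is None or any(_in(psi, lo, hi) for lo, hi in _STRAND_PSI)
        )
        raw[rid] = "H" if helix else ("E" if strand else "C")

    # enforce minimum run lengths
    labels = dict(raw)
    runs: list[tuple[str, list[int]]] = []
    for rid in sorted(raw):
        if runs and runs[-1][0] == raw[rid] and runs[-1][1][-1] == rid - 1:
            runs[-1][1].append(rid)
        else:
            runs.append((raw[rid], [rid]))
    for lab, members in runs:
        if lab in _MIN_RUN and len(members) < _MIN_RUN[lab]:
            for rid in members:
                labels[rid] = "C"
    return SecondaryStructureProfile(labels=labels)


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------


@dataclass
class SaltBridgeRecord:
    """One detected charged N...O contact and its classification labels."""

    positive_atom: int  # index into the structure's atom list
    negative_atom: int
    positive_residue: int
    negative_residue: int
    distance: float
    ss_category: str | None = None
    subdomain_category: str | None = None  # "inter" / "intra"
    atp_tag: str | None = None  # e.g. "K18-Oa"; None when ATP not involved

    @property
    def residue_pair(self) -> tuple[int, int]:
        return (self.positive_residue, self.negative_residue)


@dataclass
class HBondRecord:
    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    distance: float  # donor-acceptor heavy atoms, Å
    angle: float  # D-H...A, degrees
    solute_water: bool  # True when exactly one side is water


def detect_salt_bridges(
    coords: np.ndarray | None,
    annotation: TopologyAnnotation,
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
) -> list[SaltBridgeRecord]:
    """All (charged N+, charged O-) pairs within ``cutoff`` (inclusive).

    Every atom pair yields its own record, so a residue pair may
    contribute multiple bridges. ``coords`` defaults to the annotated
    structure's own coordinates.
    """
    structure = annotation.structure
    if coords is None:
        coords = structure.coords
    coords = np.asarray(coords, dtype=float)
    pos_idx = [
        i
        for i in annotation.charged_positive()
        if structure.atoms[i].element.upper() == "N"
    ]
    neg_idx = [
        i
        for i in annotation.charged_negative()
        if structure.atoms[i].element.upper() == "O"
    ]
    records: list[SaltBridgeRecord] = []
    if not pos_idx or not neg_idx:
        return records
    d = np.linalg.norm(
        coords[pos_idx][:, None, :] - coords[neg_idx][None, :, :], axis=-1
    )
    greek = {"a": "a", "b": "b", "g": "g"}
    one_letter = {
        "LYS": "K", "ARG": "R", "HIS": "H", "HSP": "H", "HIP": "H",
        "3MH": "H", "HIC": "H",
    }
    for ii, i in enumerate(pos_idx):
        for jj, j in enumerate(neg_idx):
            dist = float(d[ii, jj])
            if dist <= cutoff:
                ai, aj = structure.atoms[i], structure.atoms[j]
                tag = None
                if j in annotation.atp_oxygen_tags:
                    letters = sorted(annotation.atp_oxygen_tags[j])
                    code = one_letter.get(ai.residue_name, ai.residue_name[0])
                    tag = f"{code}{ai.residue_id}-O{greek.get(letters[0], letters[0])}"
                records.append(
                    SaltBridgeRecord(
                        positive_atom=i,
                        negative_atom=j,
                        positive_residue=ai.residue_id,
                        negative_residue=aj.residue_id,
                        distance=dist,
                        atp_tag=tag,
                    )
                )
    return records


def detect_hbonds(
    coords: np.ndarray | None,
    annotation: TopologyAnnotation,
    criteria: tuple[float, float] = (DEFAULT_HBOND_DISTANCE, DEFAULT_HBOND_ANGLE),
) -> list[HBondRecord]:
    """Geometric hydrogen bonds: D-A distance and D-H...A angle criteria.

    A bond is recorded when the donor/acceptor heavy-atom distance is
    <= ``criteria[0]`` Å and the D-H...A angle is >= ``criteria[1]``
    degrees; donor and acceptor must belong to different residues.
    """
    structure = annotation.structure
    if coords is None:
        coords = structure.coords
    coords = np.asarray(coords, dtype=float)
    d_cut, a_cut = criteria
    records: list[HBondRecord] = []
    acc = np.asarray(annotation.hbond_acceptors, dtype=int)
    if acc.size == 0 or not annotation.hbond_donors:
        return records
    for heavy, h in annotation.hbond_donors:
        da = np.linalg.norm(coords[acc] - coords[heavy], axis=1)
        for j, dist in zip(acc[da <= d_cut], da[da <= d_cut]):
            j = int(j)
            if j == heavy:
                continue
            if (
                structure.atoms[j].residue_id == structure.atoms[heavy].residue_id
                and structure.atoms[j].chain == structure.atoms[heavy].chain
            ):
                continue
            v1 = coords[heavy] - coords[h]
            v2 = coords[j] - coords[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle >= a_cut:
                dw = structure.atoms[heavy].residue_name in WATER_NAMES
                aw = structure.atoms[j].residue_name in WATER_NAMES
                records.append(
                    HBondRecord(
                        donor_atom=heavy,
                        hydrogen_atom=h,
                        acceptor_atom=j,
                        distance=float(dist),
                        angle=angle,
                        solute_water=(dw != aw),
                    )
                )
    return records


# --------------------------------------------------------------------------
# classification and aggregation
# --------------------------------------------------------------------------


def classify_salt_bridges(
    records: Sequence[SaltBridgeRecord],
    ss: SecondaryStructureProfile,
    subdomains: SubdomainMap,
) -> list[SaltBridgeRecord]:
    """Attach secondary-structure and subdomain categories in place.

    ATP-involved bridges keep their atp_tag and bypass both the
    secondary-structure and subdomain categories (they are counted once,
    in the ATP column). For protein-protein bridges: same H/E element ->
    intra_ss; different H/E elements -> inter_ss; one H/E and one coil ->
    ss_loop; both coil -> loop_loop.
    """
    for rec in records:
        if rec.atp_tag is not None:
            rec.ss_category = None
            rec.subdomain_category = None
            continue
        ra, rb = rec.positive_residue, rec.negative_residue
        try:
            la, lb = ss.labels[ra], ss.labels[rb]
        except KeyError as exc:
            raise KeyError(f"residue {exc.args[0]} has no ss label") from None
        ea, eb = ss.element_ids.get(ra), ss.element_ids.get(rb)
        if la in "HE" and lb in "HE":
            rec.ss_category = "intra_ss" if ea == eb else "inter_ss"
        elif la in "HE" or lb in "HE":
            rec.ss_category = "ss_loop"
        else:
            rec.ss_category = "loop_loop"
        rec.subdomain_category = (
            "intra" if subdomains[ra] == subdomains[rb] else "inter"
        )
    return list(records)


@dataclass
class InteractionSummary:
    """Frame-averaged category counts and per-pair formation rates.

    ``category_stats`` holds (mean, SD) per-frame counts for the four
    secondary-structure categories, "atp", "inter_subdomain",
    "intra_subdomain" and "total"; ``atp_tag_stats`` the same per ATP
    contact tag. Both decompositions satisfy
    total = sum(ss categories) + atp = inter + intra + atp.
    """

    n_frames: int
    category_stats: dict[str, tuple[float, float]]
    atp_tag_stats: dict[str, tuple[float, float]]
    formation_rates: dict[tuple[int, int], float]

    def high_formation_pairs(self, threshold: float = 0.5) -> dict:
        """Residue pairs with formation rate above ``threshold``."""
        return {p: r for p, r in self.formation_rates.items() if r > threshold}


def aggregate_interactions(
    per_frame_records: Sequence[Sequence[SaltBridgeRecord]],
    n_frames: int | None = None,
) -> InteractionSummary:
    """Aggregate classified per-frame bridge lists into summary statistics."""
    if n_frames is None:
        n_frames = len(per_frame_records)
    if n_frames < 1:
        raise ValueError("need >= 1 frame")

    cats = list(SS_CATEGORIES) + ["atp", "inter_subdomain", "intra_subdomain",
                                  "total"]
    counts = {c: np.zeros(n_frames) for c in cats}
    tag_counts: dict[str, np.ndarray] = {}
    pair_present: dict[tuple[int, int], np.ndarray] = {}

    for k, frame in enumerate(per_frame_records):
        for rec in frame:
            counts["total"][k] += 1
            if rec.atp_tag is not None:
                counts["atp"][k] += 1
                tag_counts.setdefault(rec.atp_tag, np.zeros(n_frames))[k] += 1
            else:
                if rec.ss_category is None or rec.subdomain_category is None:
                    raise ValueError(
                        "records must be classified before aggregation"
                    )
                counts[rec.ss_category][k] += 1
                counts[rec.subdomain_category + "_subdomain"][k] += 1
            pair_present.setdefault(
                rec.residue_pair, np.zeros(n_frames, dtype=bool)
            )[k] = True

    stats = {c: (float(v.mean()), float(v.std())) for c, v in counts.items()}
    tag_stats = {
        t: (float(v.mean()), float(v.std())) for t, v in tag_counts.items()
    }
    rates = {p: float(v.mean()) for p, v in pair_present.items()}
    return InteractionSummary(
        n_frames=n_frames,
        category_stats=stats,
        atp_tag_stats=tag_stats,
        formation_rates=rates,
    )
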