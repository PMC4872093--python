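"""Protein-DNA contact detection and classification.

Hydrogen-bond contacts are called on a distance-only criterion (donor and
acceptor heavy atoms within a cutoff, default 3.5 Å), matching how
crystallographic interface schematics are usually drawn for structures
solved without hydrogens; an optional donor-H-acceptor proxy angle filter
can be enabled for stricter chemistry.  Water-mediated bridges and
side-chain intercalation into base-stack cavities are detected separately.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import chemistry as chem
from .struct_io import ResidueUnit, StructureModel, TargetFrame, ResidueKey

TSV_COLUMNS = ["enzyme", "chain", "resnum", "resname", "part", "atom",
               "position", "strand", "moiety", "groove", "distance_A",
               "mediation"]


@dataclass(frozen=True)
class ContactRecord:
    enzyme: str
    chain: str
    resnum: int
    resname: str
    part: str            # side chain | main chain
    atom: str
    position: int | None  # target-frame position; None if outside the frame
    strand: str | None
    nuc_atom: str
    moiety: str          # base | sugar | phosphate
    groove: str          # major | minor | n/a
    distance: float      # Å (water-DNA leg for bridged contacts)
    mediation: str       # "direct" or "water:<chain><num>"

    def sort_key(self):
        return (self.position if self.position is not None else 10 ** 6,
                self.resnum, self.atom, self.nuc_atom)


def _protein_polar_atoms(model: StructureModel):
    """(residue, atom, roles) for every protein donor/acceptor heavy atom."""
    out = []
    for res in model.residues("protein"):
        donors = chem.protein_donor_atoms(res.name)
        acceptors = chem.protein_acceptor_atoms(res.name)
        for a in res.atoms:
            is_d, is_a = a.name in donors, a.name in acceptors
            if is_d or is_a:
                out.append((res, a, is_d, is_a))
    return out


def _dna_polar_atoms(model: StructureModel, frame: TargetFrame | None):
    out = []
    for res in model.residues("nucleotide"):
        base = res.base
        if base is None:
            continue
        donors = chem.dna_donor_atoms(base)
        acceptors = chem.dna_acceptor_atoms(base)
        posstrand = frame.position_of(res.key) if frame is not None else None
        for a in res.atoms:
            is_d, is_a = a.name in donors, a.name in acceptors
            if is_d or is_a:
                out.append((res, a, is_d, is_a, posstrand))
    return out


def _part_of(atom_name: str) -> str:
    return "main chain" if atom_name in ("N", "O", "OXT", "C", "CA") else "side chain"


def _make_record(enzyme: str, pres: ResidueUnit, patom, nres: ResidueUnit,
                 natom, posstrand, distance: float, mediation: str) -> ContactRecord:
    pos, strand = posstrand if posstrand is not None else (None, None)
    moiety = chem.moiety_of(natom.name)
    groove = chem.groove_of(nres.base or "", natom.name) if moiety == "base" else "n/a"
    return ContactRecord(enzyme=enzyme, chain=pres.chain_id, resnum=pres.number,
                         resname=pres.name, part=_part_of(patom.name),
                         atom=patom.name, position=pos, strand=strand,
                         nuc_atom=natom.name, moiety=moiety, groove=groove,
                         distance=round(float(distance), 3), mediation=mediation)


def detect_hbond_contacts(model: StructureModel, frame: TargetFrame | None = None,
                          cutoff: float = 3.5, enzyme: str = "",
                          ) -> list[ContactRecord]:
    """All direct protein-DNA donor/acceptor pairs within the cutoff.

    A pair qualifies when the two atoms can take opposite hydrogen-bond
    roles (ambivalent atoms count for either).  Uses a k-d tree over the
    DNA polar atoms; equivalent to the all-pairs scan.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    prot = _protein_polar_atoms(model)
    dna = _dna_polar_atoms(model, frame)
    if not prot or not dna:
        return []
    tree = cKDTree(np.array([a.coords for _, a, _, _, _ in dna]))
    records = []
    for pres, patom, p_d, p_a in prot:
        for j in tree.query_ball_point(patom.coords, cutoff):
            nres, natom, n_d, n_a, posstrand = dna[j]
            if not ((p_d and n_a) or (p_a and n_d)):
                continue
            d = np.linalg.norm(patom.coords - natom.coords)
            if d <= cutoff:
                records.append(_make_record(enzyme, pres, patom, nres, natom,
                                            posstrand, d, "direct"))
    return sorted(set(records), key=ContactRecord.sort_key)


def detect_hbond_contacts_bruteforce(model: StructureModel,
                                     frame: TargetFrame | None = None,
                                     cutoff: float = 3.5, enzyme: str = "",
                                     ) -> list[ContactRecord]:
    """O(n^2) oracle: identical output to :func:`detect_hbond_contacts`."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    records = []
    for pres, patom, p_d, p_a in _protein_polar_atoms(model):
        for nres, natom, n_d, n_a, posstrand in _dna_polar_atoms(model, frame):
            if not ((p_d and n_a) or (p_a and n_d)):
                continue
            d = np.linalg.norm(patom.coords - natom.coords)
            if d <= cutoff:
                records.append(_make_record(enzyme, pres, patom, nres, natom,
                                            posstrand, d, "direct"))
    return sorted(set(records), key=ContactRecord.sort_key)


def detect_water_bridges(model: StructureModel, frame: TargetFrame | None = None,
                         cutoff: float = 3.5, enzyme: str = "",
                         ) -> list[ContactRecord]:
    """Water-mediated protein-base bridges.

    A record is produced for each water whose oxygen lies within the cutoff
    of both a protein donor/acceptor atom and a DNA *base* donor/acceptor
    atom.  The reported distance is the water-base leg.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    waters = [(r, a) for r in model.residues("water") for a in r.atoms
              if a.element == "O"]
    if not waters:
        return []
    prot = _protein_polar_atoms(model)
    dna = [(res, a, d, acc, ps) for res, a, d, acc, ps in _dna_polar_atoms(model, frame)
           if chem.moiety_of(a.name) == "base"]
    records = []
    for wres, watom in waters:
        near_p = [(pres, patom) for pres, patom, _, _ in prot
                  if np.linalg.norm(patom.coords - watom.coords) <= cutoff]
        near_n = [(nres, natom, ps) for nres, natom, _, _, ps in dna
                  if np.linalg.norm(natom.coords - watom.coords) <= cutoff]
        for pres, patom in near_p:
            for nres, natom, ps in near_n:
                d = np.linalg.norm(natom.coords - watom.coords)
                tag = f"water:{wres.chain_id}{wres.number}"
                records.append(_make_record(enzyme, pres, patom, nres, natom,
                                            ps, d, tag))
    return sorted(set(records), key=ContactRecord.sort_key)


# ---------------------------------------------------------------------------
# Intercalation
# ---------------------------------------------------------------------------

def _planar_group(res: ResidueUnit) -> tuple[np.ndarray, np.ndarray] | None:
    names = chem.PLANAR_GROUPS.get(res.name)
    if names is None:
        return None
    pts = res.atom_coords(names)
    if len(pts) < 3:
        return None
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def _base_plane(res: ResidueUnit) -> tuple[np.ndarray, np.ndarray] | None:
    pts = np.array([a.coords for a in res.atoms
                    if chem.moiety_of(a.name) == "base"])
    if len(pts) < 3:
        return None
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def detect_intercalation(model: StructureModel, frame: TargetFrame,
                         centroid_cutoff: float = 4.5,
                         plane_angle_max: float = 30.0,
                         flip_threshold: float = 8.0,
                         ) -> list[tuple[ResidueKey, tuple[int, int]]]:
    """Planar side-chain groups filling a base-stack cavity.

    For each strand, consecutive in-stack bases (flipped bases excluded)
    define the stack steps; a planar group (Arg guanidinium or His / Trp /
    Tyr / Phe ring) is reported when its centroid lies within
    ``centroid_cutoff`` of both flanking base centroids and its plane is
    within ``plane_angle_max`` degrees of the mean flanking base plane.
    """
    from .geometry import detect_flipped_bases
    flipped = {(p, s) for p, s, _ in
               detect_flipped_bases(model, frame,
                                    displacement_threshold=flip_threshold)}
    groups = []
    for res in model.residues("protein"):
        pg = _planar_group(res)
        if pg is not None:
            groups.append((res, pg))
    if not groups:
        return []
    out = []
    for strand, mapping in (("top", frame.top), ("bottom", frame.bottom)):
        stack = []
        for pos in sorted(mapping):
            if (pos, strand) in flipped:
                continue
            plane = _base_plane(model.get_residue(mapping[pos]))
            if plane is not None:
                stack.append((pos, plane))
        for (p1, (c1, n1)), (p2, (c2, n2)) in zip(stack[:-1], stack[1:]):
            mean_normal = n1 + (n2 if np.dot(n1, n2) >= 0 else -n2)
            mean_normal /= np.linalg.norm(mean_normal)
            for res, (gc, gn) in groups:
                if np.linalg.norm(gc - c1) > centroid_cutoff or \
                        np.linalg.norm(gc - c2) > centroid_cutoff:
                    continue
                cosang = abs(float(np.dot(gn, mean_normal)))
                if np.degrees(np.arccos(np.clip(cosang, 0, 1))) < plane_angle_max:
                    out.append((res.key, (p1, p2)))
    return sorted(set(out), key=lambda x: (x[1], x[0]))


# ---------------------------------------------------------------------------
# Schematic table
# ---------------------------------------------------------------------------

def contact_schematic(contacts: list[ContactRecord],
                      frame: TargetFrame | None = None,
                      ) -> tuple[pd.DataFrame, dict]:
    """Tabulate contacts and summarise base-specific vs backbone counts.

    Returns ``(table, per_position_summary)``; the table has one row per
    contact in the fixed TSV column order.
    """
    rows = []
    for c in contacts:
        d = asdict(c)
        d["distance_A"] = d.pop("distance")
        rows.append(d)
    table = pd.DataFrame(rows, columns=TSV_COLUMNS + ["nuc_atom"]) \
        if rows else pd.DataFrame(columns=TSV_COLUMNS + ["nuc_atom"])
    summary: dict[int, dict[str, int]] = {}
    positions = frame.positions() if frame is not None else \
        sorted({c.position for c in contacts if c.position is not None})
    for pos in positions:
        here = [c for c in contacts if c.position == pos]
        summary[pos] = {
            "base_specific": sum(1 for c in here if c.moiety == "base"),
            "backbone": sum(1 for c in here if c.moiety in ("sugar", "phosphate")),
            "water_bridged": sum(1 for c in here if c.mediation != "direct"),
        }
    return table, summary


def write_contacts(contacts: list[ContactRecord], frame: TargetFrame | None,
                   tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    table, summary = contact_schematic(contacts, frame)
    table.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps({str(k): v for k, v in summary.items()}, indent=2,
                       sort_keys=True) + "\n")
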