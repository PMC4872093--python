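"""Coordinate I/O and the target-position frame.

A light hierarchical data model (structure > chain > residue > atom) backed by
``gemmi`` for parsing PDB and mmCIF.  The model keeps author residue
numbering, retains waters, and collapses alternate locations to the
highest-occupancy conformer (ties broken alphabetically by alt-loc id).

The target frame maps duplex nucleotides onto the recognition-sequence
coordinate system used for Type ISP enzymes: the methylated T:A base pair is
position +1, downstream positions are positive, upstream negative, and there
is no position 0 (−1 immediately precedes +1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

from . import chemistry as chem


class StructureError(ValueError):
    """Raised for unparsable files, unknown formats or bad selections."""


class FrameError(ValueError):
    """Raised when a target frame cannot be assigned."""


ResidueKey = tuple[str, int, str]  # (chain id, author number, insertion code)


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    alt_loc: str
    occupancy: float
    coords: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            self.element = _infer_element(self.name)


@dataclass
class ResidueUnit:
    chain_id: str
    number: int
    icode: str
    name: str
    kind: str  # protein | nucleotide | water | other
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_coords(self, names: Iterable[str]) -> np.ndarray:
        """Coordinates of the named atoms that are present, shape (k, 3)."""
        found = [a.coords for a in self.atoms if a.name in set(names)]
        return np.array(found) if found else np.empty((0, 3))

    @property
    def base(self) -> str | None:
        return chem.BASE_OF.get(self.name)


@dataclass
class StructureModel:
    id: str
    chains: dict[str, list[ResidueUnit]]
    source: str = ""
    format: str = ""

    def __iter__(self) -> Iterator[ResidueUnit]:
        for residues in self.chains.values():
            yield from residues

    def residues(self, kind: str | None = None) -> list[ResidueUnit]:
        return [r for r in self if kind is None or r.kind == kind]

    def get_residue(self, key: ResidueKey) -> ResidueUnit:
        chain, number, icode = key
        for r in self.chains.get(chain, []):
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(f"residue {key} not in model {self.id}")

    def chain(self, chain_id: str) -> list[ResidueUnit]:
        if chain_id not in self.chains:
            raise KeyError(f"chain {chain_id!r} not in model {self.id} "
                           f"(has {sorted(self.chains)})")
        return self.chains[chain_id]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for r in self for a in r.atoms])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigid-body transformed deep copy (x' = R x + t)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        chains: dict[str, list[ResidueUnit]] = {}
        for cid, residues in self.chains.items():
            new = []
            for r in residues:
                atoms = [AtomRecord(a.serial, a.name, a.element, a.alt_loc,
                                    a.occupancy, R @ a.coords + t)
                         for a in r.atoms]
                new.append(ResidueUnit(r.chain_id, r.number, r.icode, r.name,
                                       r.kind, atoms))
            chains[cid] = new
        return StructureModel(self.id, chains, self.source, self.format)

    def summary(self) -> dict:
        kinds: dict[str, int] = {}
        for r in self:
            kinds[r.kind] = kinds.get(r.kind, 0) + 1
        return {
            "id": self.id,
            "source": self.source,
            "format": self.format,
            "chains": {c: len(rs) for c, rs in self.chains.items()},
            "n_atoms": self.n_atoms,
            "residue_kinds": kinds,
        }


def residue_kind(name: str) -> str:
    """Deterministic residue classification against the fixed dictionaries."""
    name = name.strip().upper()
    if name in chem.PROTEIN_RESIDUES:
        return "protein"
    if name in chem.NUCLEOTIDE_RESIDUES:
        return "nucleotide"
    if name in chem.WATER_RESIDUES:
        return "water"
    return "other"


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if not stripped:
        raise StructureError("cannot infer element from empty atom name")
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    # two-letter elements that occur in biomolecules
    two = stripped[:2].upper()
    if two in {"FE", "ZN", "MG", "MN", "SE", "NA", "CL", "BR", "CA"} and len(stripped) <= 2:
        return two.capitalize()
    return stripped[0].upper()


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM/HETATM records are represented; waters are retained.  When a
    residue carries alternate locations only the highest-occupancy conformer
    of each atom is kept (ties resolved alphabetically).
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = format.lower()
    if fmt == "auto":
        suffix = path.name.lower()
        if suffix.endswith((".cif", ".mmcif", ".cif.gz")):
            fmt = "mmcif"
        elif suffix.endswith((".pdb", ".ent", ".pdb.gz")):
            fmt = "pdb"
        else:
            raise StructureError(f"cannot infer format from {path.name!r}; "
                                 "pass format='pdb' or 'mmcif'")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"failed to parse {path}: {exc}") from exc

    st.setup_entities()
    model = st[0]
    chains: dict[str, list[ResidueUnit]] = {}
    for ch in model:
        residues = []
        for res in ch:
            icode = res.seqid.icode.strip()
            unit = ResidueUnit(ch.name, res.seqid.num, icode,
                               res.name.strip().upper(), residue_kind(res.name))
            best: dict[str, AtomRecord] = {}
            for at in res:
                rec = AtomRecord(at.serial, at.name, at.element.name,
                                 at.altloc if at.altloc != "\x00" else "",
                                 at.occ, np.array([at.pos.x, at.pos.y, at.pos.z]))
                prev = best.get(at.name)
                if prev is None or (rec.occupancy, _alt_rank(rec.alt_loc)) > \
                        (prev.occupancy, _alt_rank(prev.alt_loc)):
                    best[at.name] = rec
            unit.atoms = list(best.values())
            residues.append(unit)
        if residues:
            chains.setdefault(ch.name, []).extend(residues)
    if not chains:
        raise StructureError(f"{path}: no atoms parsed")
    return StructureModel(st.name or path.stem, chains, str(path), fmt)


def _alt_rank(alt: str) -> float:
    # higher is better; '' beats 'A' beats 'B' ... so negate ordinal
    return 1.0 if alt == "" else -ord(alt)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a fixed-column PDB file."""
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        ch = gemmi.Chain(cid)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.number, r.icode or " ")
            res.het_flag = "A" if r.kind in ("protein", "nucleotide") else "H"
            for a in r.atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.occ = a.occupancy
                at.altloc = a.alt_loc or "\x00"
                at.pos = gemmi.Position(*a.coords)
                res.add_atom(at)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def write_summary(model: StructureModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.summary(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def extract_sequence(model: StructureModel, chain: str) -> tuple[str, list[tuple[int, int]]]:
    """One-letter sequence of a chain ordered by residue number.

    Returns ``(sequence, gaps)`` where ``gaps`` lists ``(last_number,
    next_number)`` pairs across which author numbering jumps by more than
    one.  Non-standard residues are emitted as ``X``; waters are skipped.
    """
    residues = [r for r in model.chain(chain) if r.kind != "water"]
    residues.sort(key=lambda r: (r.number, r.icode))
    seq = []
    gaps = []
    prev = None
    for r in residues:
        if r.kind == "protein":
            seq.append(chem.AA_THREE_TO_ONE.get(r.name, "X"))
        elif r.kind == "nucleotide":
            seq.append(chem.NUC_TO_ONE.get(r.name, "X"))
        else:
            seq.append("X")
        if prev is not None and r.number > prev + 1:
            gaps.append((prev, r.number))
        prev = r.number
    return "".join(seq), gaps


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# Target frame
# ---------------------------------------------------------------------------

def position_run(start: int, n: int) -> list[int]:
    """``n`` consecutive target positions from ``start``, skipping 0."""
    out = []
    p = start
    while len(out) < n:
        if p != 0:
            out.append(p)
        p += 1
    return out


@dataclass
class TargetFrame:
    """Bijection between defined target positions and duplex residues.

    ``top`` and ``bottom`` map position -> residue key.  Position +1 carries
    the methylated adenine on the bottom strand (T:A with T on top).
    """

    top: dict[int, ResidueKey]
    bottom: dict[int, ResidueKey]
    target: str = ""

    def positions(self) -> list[int]:
        return sorted(self.top)

    def position_of(self, key: ResidueKey) -> tuple[int, str] | None:
        for pos, k in self.top.items():
            if k == key:
                return pos, "top"
        for pos, k in self.bottom.items():
            if k == key:
                return pos, "bottom"
        return None

    def residue_at(self, model: StructureModel, pos: int, strand: str = "top") -> ResidueUnit:
        mapping = self.top if strand == "top" else self.bottom
        return model.get_residue(mapping[pos])


def assign_target_frame(model: StructureModel,
                        target: str,
                        anchor: ResidueKey,
                        target_start: int = -1,
                        pairing_cutoff: float = 12.0) -> TargetFrame:
    """Assign recognition-sequence positions to duplex nucleotides.

    Parameters
    ----------
    target:
        Top-strand recognition sequence in IUPAC codes (e.g. ``"CTNGAYG"``),
        whose first letter sits at ``target_start``.
    anchor:
        Residue key of the *top-strand* base at position +1 (the thymine
        paired with the methylated adenine).
    target_start:
        Target position of ``target[0]`` (default −1; no position 0 exists).
    pairing_cutoff:
        Maximum C1'–C1' distance for geometric Watson-Crick partner search;
        partners further than this (e.g. a flipped base) are assigned by
        frame arithmetic on the partner chain numbering.
    """
    try:
        anchor_res = model.get_residue(anchor)
    except KeyError as exc:
        raise FrameError(str(exc)) from exc
    if anchor_res.kind != "nucleotide":
        raise FrameError(f"anchor {anchor} is {anchor_res.kind}, not a nucleotide")

    chain = [r for r in model.chain(anchor_res.chain_id) if r.kind == "nucleotide"]
    chain.sort(key=lambda r: (r.number, r.icode))
    idx = next(i for i, r in enumerate(chain) if r.key == anchor)

    positions = position_run(target_start, len(target))
    if 1 not in positions:
        raise FrameError("target string does not cover position +1")
    anchor_offset = positions.index(1)

    top: dict[int, ResidueKey] = {}
    truncated = []
    for j, pos in enumerate(positions):
        i = idx + (j - anchor_offset)
        if 0 <= i < len(chain):
            top[pos] = chain[i].key
        else:
            truncated.append(pos)
    if truncated:
        warnings.warn(f"target positions {truncated} fall outside the duplex; "
                      "frame truncated", stacklevel=2)

    # check the top strand against the target string
    mismatches = []
    for j, pos in enumerate(positions):
        if pos not in top:
            continue
        allowed = chem.IUPAC_DNA.get(target[j].upper())
        if allowed is None:
            raise FrameError(f"invalid IUPAC code {target[j]!r} in target")
        base = model.get_residue(top[pos]).base
        if base is not None and base not in allowed:
            mismatches.append((pos, base, target[j]))
    if mismatches:
        raise FrameError("top strand conflicts with target string at "
                         + ", ".join(f"{p} ({b} vs {t})" for p, b, t in mismatches))

    bottom = _assign_partners(model, top, anchor_res.chain_id, pairing_cutoff)
    return TargetFrame(top=top, bottom=bottom, target=target.upper())


def find_target(model: StructureModel, target: str,
                target_start: int = -1) -> list[ResidueKey]:
    """Scan nucleotide chains for the top-strand target sequence.

    Returns the residue keys that could anchor position +1 (the residue
    aligned with the target letter at +1), for every IUPAC match on any
    chain read in residue-number order.
    """
    target = target.upper()
    positions = position_run(target_start, len(target))
    anchor_offset = positions.index(1)
    hits = []
    for chain_id in model.chains:
        chain = [r for r in model.chain(chain_id) if r.kind == "nucleotide"]
        chain.sort(key=lambda r: (r.number, r.icode))
        bases = [r.base or "X" for r in chain]
        for i in range(0, len(chain) - len(target) + 1):
            ok = True
            for j, letter in enumerate(target):
                allowed = chem.IUPAC_DNA.get(letter, "")
                if bases[i + j] not in allowed:
                    ok = False
                    break
            if ok:
                hits.append(chain[i + anchor_offset].key)
    return hits


def _assign_partners(model: StructureModel, top: dict[int, ResidueKey],
                     top_chain: str, cutoff: float,
                     wc_cutoff: float = 3.5) -> dict[int, ResidueKey]:
    candidates = [r for r in model.residues("nucleotide")
                  if r.chain_id != top_chain]
    bottom: dict[int, ResidueKey] = {}
    claimed: dict[ResidueKey, tuple[int, float]] = {}
    for pos, key in top.items():
        res = model.get_residue(key)
        pair_atom = chem.PAIRING_ATOM.get(res.base or "", "N1")
        ra = res.atom(pair_atom) or res.atom("N1") or res.atom("N3")
        rc1 = res.atom("C1'")
        best = None
        best_d = np.inf
        for cand in candidates:
            ca = cand.atom(chem.PAIRING_ATOM.get(cand.base or "", "N1")) \
                or cand.atom("N1") or cand.atom("N3")
            cc1 = cand.atom("C1'")
            if ra is None or ca is None:
                continue
            if rc1 is not None and cc1 is not None:
                if np.linalg.norm(rc1.coords - cc1.coords) > cutoff:
                    continue
            d = np.linalg.norm(ra.coords - ca.coords)
            if d < best_d:
                best_d, best = d, cand
        # accept only hydrogen-bonding-range pairing-atom distances; a
        # flipped partner leaves a neighbouring base as spurious nearest
        if best is not None and best_d <= wc_cutoff:
            prev = claimed.get(best.key)
            if prev is None or best_d < prev[1]:
                if prev is not None:
                    bottom.pop(prev[0], None)
                claimed[best.key] = (pos, best_d)
                bottom[pos] = best.key

    # frame arithmetic for unpaired positions (flipped or distorted bases):
    # bottom strand runs anti-parallel, so partner numbering decreases as the
    # position index increases.
    if bottom and len(bottom) < len(top):
        pos_sorted = sorted(top)
        rank = {p: i for i, p in enumerate(pos_sorted)}
        offsets = []
        chain_of = {}
        for p, k in bottom.items():
            offsets.append(k[1] + rank[p])
            chain_of[p] = k[0]
        offset = int(np.median(offsets))
        chain_id = max(set(chain_of.values()),
                       key=list(chain_of.values()).count)
        by_number = {r.number: r for r in model.chain(chain_id)
                     if r.kind == "nucleotide"}
        for p in pos_sorted:
            if p in bottom:
                continue
            want = offset - rank[p]
            if want in by_number:
                bottom[p] = by_number[want].key
    return bottom
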