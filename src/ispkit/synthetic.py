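"""Synthetic fixtures with machine-readable planted ground truth.

Three generator families:

* reduced-atom B-form DNA duplexes (optionally kinked, base-flipped, or
  groove-widened) plus pseudo protein donor/acceptor atoms planted at exact
  distances — the stand-in for a protein-DNA co-crystal;
* multiple sequence alignments with planted conserved columns, covarying
  column pairs and anchor-residue/target-base associations;
* triplex-displacement kinetic traces following the lag-phase model with
  additive Gaussian noise.

The duplex generator is analytic: each base pair carries only the atoms the
downstream geometry and contact stages read (P, C1', glycosidic and
Watson-Crick nitrogens, groove-face atoms), placed on an ideal helix with
3.4 Å rise and 36° twist.  Phosphates sit at radius 8.9 Å with an angular
half-separation of 70° from the base-pair pseudo-dyad, which puts the
closest cross-strand P-P approach across the minor groove at pair offset +3
(width ≈ 5.5 Å) and across the major groove at offset −4 (width ≈ 11.7 Å),
matching canonical B-DNA to a few tenths of an Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from . import chemistry as chem
from .struct_io import AtomRecord, ResidueUnit, StructureModel

RISE = 3.4           # Å per base-pair step
TWIST = 36.0         # degrees per step
P_RADIUS = 8.9       # Å, phosphate radius
P_HALF_ANGLE = 70.0  # degrees, phosphate offset from the pseudo-dyad
C1_CHORD = 10.4      # Å, C1'-C1' distance across a Watson-Crick pair
C1_HALF_ANGLE = 70.0  # degrees, C1' offset from the pseudo-dyad
GLYCO_DIST = 1.5     # Å, C1' -> glycosidic nitrogen along the pair long axis
PAIR_GAP = 2.9       # Å, distance between the two Watson-Crick pairing atoms
GROOVE_OFFSET = 1.6  # Å, lateral offset of groove-face atoms off the long axis
P_P_SUBTRACT = 5.8   # Å, two phosphate radii subtracted from P-P distances

MINOR_REGISTER = range(2, 7)    # cross-strand pair offsets spanning the minor groove
MAJOR_REGISTER = range(-6, -1)  # ... and the major groove


class SpecError(ValueError):
    """Invalid or contradictory generator specification."""


# ---------------------------------------------------------------------------
# Duplex generator
# ---------------------------------------------------------------------------

@dataclass
class DuplexSpec:
    sequence: str                       # top strand, 5'->3'
    rise: float = RISE
    twist: float = TWIST
    kink: tuple[int, float] | None = None        # (step index, angle deg)
    flip: tuple[int, str] | None = None          # (bp index, "top"|"bottom")
    flip_displacement: float = 12.0              # Å from axis after extrusion
    widen: tuple[tuple[int, int], float] | None = None  # ((start, end) incl., added Å)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        if n < 4:
            raise SpecError("duplex needs at least 4 base pairs")
        if any(b not in "ACGT" for b in self.sequence):
            raise SpecError("sequence must be plain ACGT")
        if self.kink is not None:
            step, angle = self.kink
            if not 0 < angle <= 90:
                raise SpecError("kink angle must be in (0, 90] degrees")
            if not 0 < step < n - 1:
                raise SpecError("kink step outside duplex")
        if self.flip is not None:
            pos, strand = self.flip
            if not 0 <= pos < n:
                raise SpecError("flip index outside duplex")
            if strand not in ("top", "bottom"):
                raise SpecError("flip strand must be top or bottom")
            if self.kink is not None and pos in (self.kink[0], self.kink[0] + 1):
                raise SpecError("cannot plant a base flip at a kink step")
        if self.widen is not None:
            (s, e), w = self.widen
            if not (0 <= s <= e < n):
                raise SpecError("widening range outside duplex")
            if w <= 0:
                raise SpecError("widening must be positive")


@dataclass
class DuplexGroundTruth:
    axis_points: np.ndarray             # (n, 3) ideal axis
    axis_dirs: np.ndarray               # (n, 3) local axis direction
    bend_angle: float                   # planted kink angle (0 if none)
    kink_step: int | None
    flipped: list[tuple[int, str, float]]   # (bp index, strand, displacement)
    widen_range: tuple[int, int] | None
    widen_added: float
    minor_width_baseline: float
    major_width_baseline: float


def _register_distance(R: float, mu_deg: float, k: int,
                       rise: float, twist: float) -> float:
    """Cross-strand P-P distance at pair offset k on the ideal helix."""
    da = np.deg2rad(-k * twist + 2 * mu_deg)
    c = 2 * R * abs(np.sin(da / 2))
    dz = -k * rise
    return float(np.hypot(c, dz))


def _groove_minima(R: float, mu_deg: float, rise: float, twist: float) -> tuple[float, float]:
    minor = min(_register_distance(R, mu_deg, k, rise, twist) for k in MINOR_REGISTER)
    major = min(_register_distance(R, mu_deg, k, rise, twist) for k in MAJOR_REGISTER)
    return minor, major


def _solve_widening(added: float, rise: float, twist: float) -> tuple[float, float]:
    """Find local (radius, half-angle) so both groove widths grow by `added`."""
    minor0, major0 = _groove_minima(P_RADIUS, P_HALF_ANGLE, rise, twist)

    def resid(x):
        r, mu = x
        minor, major = _groove_minima(r, mu, rise, twist)
        return [minor - (minor0 + added), major - (major0 + added)]

    sol = least_squares(resid, x0=[P_RADIUS + added, P_HALF_ANGLE],
                        bounds=([P_RADIUS, 30.0], [P_RADIUS + 6 * added + 5, 110.0]))
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise SpecError(f"cannot realise +{added} Å groove widening "
                        f"(residual {sol.fun})")
    return float(sol.x[0]), float(sol.x[1])


_REDUCED_BASE = {
    # base: (major-face atoms, minor-face atoms); glyco/pairing added separately
    "A": (("N7", "N6"), ("N3", "C2")),
    "G": (("N7", "O6"), ("N3", "N2")),
    "T": (("O4", "C7"), ("O2",)),
    "C": (("N4", "C5"), ("O2",)),
}


def make_duplex(spec: DuplexSpec) -> tuple[StructureModel, DuplexGroundTruth]:
    """Build a reduced-atom duplex and return it with its ground truth.

    Top strand is chain ``D`` numbered 1..n in the 5'->3' direction; the
    complementary strand is chain ``E`` numbered n..1 (anti-parallel).
    """
    n = len(spec.sequence)
    h, om = spec.rise, np.deg2rad(spec.twist)

    # per-bp phosphate parameters (widening modifies them locally)
    radius = np.full(n, P_RADIUS)
    half_angle = np.full(n, P_HALF_ANGLE)
    if spec.widen is not None:
        (ws, we), added = spec.widen
        r_w, mu_w = _solve_widening(added, h, spec.twist)
        radius[ws:we + 1] = r_w
        half_angle[ws:we + 1] = mu_w

    # frames along the axis
    origins = np.zeros((n, 3))
    rots = np.zeros((n, 3, 3))
    R = np.eye(3)
    O = np.zeros(3)
    kink_step = spec.kink[0] if spec.kink else None
    for i in range(n):
        origins[i] = O
        rots[i] = R
        Rz = _rot_z(om)
        R = R @ Rz
        if kink_step is not None and i == kink_step:
            R = R @ _rot_x(np.deg2rad(spec.kink[1]))
        O = O + R[:, 2] * h
        # note: translation uses the post-rotation z so the kink tips the arm

    lam = np.deg2rad(C1_HALF_ANGLE)
    rc = C1_CHORD / (2 * np.sin(lam))

    top: list[ResidueUnit] = []
    bottom: list[ResidueUnit] = []
    serial = 1
    flipped_truth: list[tuple[int, str, float]] = []

    for i, base_top in enumerate(spec.sequence):
        base_bot = chem.WATSON_CRICK[base_top]
        Rm, Oi = rots[i], origins[i]
        mu = np.deg2rad(half_angle[i])

        def place(local_xy, z=0.0):
            return Oi + Rm @ np.array([local_xy[0], local_xy[1], z])

        c1_t = place((rc * np.cos(lam), rc * np.sin(lam)))
        c1_b = place((rc * np.cos(lam), -rc * np.sin(lam)))
        p_t = place((radius[i] * np.cos(mu), radius[i] * np.sin(mu)))
        p_b = place((radius[i] * np.cos(mu), -radius[i] * np.sin(mu)))

        u = (c1_b - c1_t) / np.linalg.norm(c1_b - c1_t)  # pair long axis
        minor_dir = Rm[:, 0]          # toward the backbone sector
        major_dir = -Rm[:, 0]

        def base_atoms(c1, sign, base):
            """Atoms of one base: glyco, pairing, groove faces."""
            g = c1 + sign * GLYCO_DIST * u
            pair = c1 + sign * 0.361 * C1_CHORD * u
            centre = 0.5 * (g + pair)
            atoms = {chem.GLYCOSIDIC_ATOM[base]: g, chem.PAIRING_ATOM[base]: pair}
            majors, minors = _REDUCED_BASE[base]
            # groove-face atoms ~2.2 Å apart along the pair long axis,
            # matching the spacing of e.g. purine N7/O6
            for j, name in enumerate(majors):
                atoms[name] = centre + major_dir * GROOVE_OFFSET \
                    + sign * u * (-0.8 + 2.2 * j)
            for j, name in enumerate(minors):
                atoms[name] = centre + minor_dir * GROOVE_OFFSET \
                    + sign * u * (-0.8 + 2.2 * j)
            return atoms

        at_t = {"P": p_t, "C1'": c1_t, **base_atoms(c1_t, +1.0, base_top)}
        at_b = {"P": p_b, "C1'": c1_b, **base_atoms(c1_b, -1.0, base_bot)}

        if spec.flip is not None and spec.flip[0] == i:
            strand = spec.flip[1]
            atoms = at_t if strand == "top" else at_b
            backbone = {"P", "C1'"}
            names = [k for k in atoms if k not in backbone]
            centroid = np.mean([atoms[k] for k in names], axis=0)
            radial = centroid - _nearest_axis_point(centroid, origins, rots)
            radial /= np.linalg.norm(radial)
            shift = radial * (spec.flip_displacement + 2.0)
            for k in names:
                atoms[k] = atoms[k] + shift
            new_centroid = centroid + shift
            disp = float(np.linalg.norm(
                new_centroid - _nearest_axis_point(new_centroid, origins, rots)))
            flipped_truth.append((i, strand, disp))

        res_t = ResidueUnit("D", i + 1, "", "D" + base_top, "nucleotide")
        for name, pos in at_t.items():
            res_t.atoms.append(AtomRecord(serial, name, _element(name), "", 1.0, pos))
            serial += 1
        res_b = ResidueUnit("E", n - i, "", "D" + base_bot, "nucleotide")
        for name, pos in at_b.items():
            res_b.atoms.append(AtomRecord(serial, name, _element(name), "", 1.0, pos))
            serial += 1
        top.append(res_t)
        bottom.append(res_b)

    model = StructureModel("synthetic-duplex",
                           {"D": top, "E": list(reversed(bottom))},
                           source="synthetic", format="generated")
    minor0, major0 = _groove_minima(P_RADIUS, P_HALF_ANGLE, h, spec.twist)
    truth = DuplexGroundTruth(
        axis_points=origins,
        axis_dirs=np.stack([rots[i][:, 2] for i in range(n)]),
        bend_angle=float(spec.kink[1]) if spec.kink else 0.0,
        kink_step=kink_step,
        flipped=flipped_truth,
        widen_range=spec.widen[0] if spec.widen else None,
        widen_added=spec.widen[1] if spec.widen else 0.0,
        minor_width_baseline=minor0 - P_P_SUBTRACT,
        major_width_baseline=major0 - P_P_SUBTRACT,
    )
    return model, truth


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _nearest_axis_point(p: np.ndarray, origins: np.ndarray, rots: np.ndarray) -> np.ndarray:
    """Project p onto the closest local axis segment of the ideal helix."""
    best, best_d = origins[0], np.inf
    for O, R in zip(origins, rots):
        z = R[:, 2]
        proj = O + np.dot(p - O, z) * z
        d = np.linalg.norm(p - proj)
        if d < best_d:
            best_d, best = d, proj
    return best


def _element(atom_name: str) -> str:
    return atom_name.lstrip("0123456789")[0]


# ---------------------------------------------------------------------------
# Planted protein contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactPlant:
    resname: str            # e.g. "LYS"
    resnum: int             # author number of the pseudo residue
    atom: str               # donor/acceptor atom name, e.g. "NZ"
    bp_index: int           # 0-based base-pair index in the duplex
    strand: str             # "top" | "bottom"
    base_atom: str          # DNA atom contacted, e.g. "N7"
    distance: float         # Å
    via_water: float | None = None  # if set, bridge through a water at this Å


def plant_contacts(model: StructureModel, plants: Sequence[ContactPlant],
                   clearance: float = 3.7) -> tuple[StructureModel, list[dict]]:
    """Place pseudo protein residues (and bridging waters) at exact distances.

    Each planted atom is positioned so that its distance to the requested DNA
    atom matches to <0.01 Å while every *other* polar atom stays at least
    ``clearance`` away, so a detector at the default 3.5 Å cutoff sees
    exactly the planted pairs.  Direct plants shorter than 2.4 Å are
    rejected as steric clashes.
    """
    model = model.transformed(np.eye(3), np.zeros(3))  # deep copy
    polar = _polar_atom_coords(model)
    truth: list[dict] = []
    prot: list[ResidueUnit] = []
    waters: list[ResidueUnit] = []
    serial = model.n_atoms + 1
    water_num = 1

    for plant in plants:
        if plant.via_water is None and plant.distance < 2.4:
            raise SpecError(f"planted distance {plant.distance} Å below steric "
                            "minimum of 2.4 Å")
        if plant.via_water is not None and plant.via_water < 2.4:
            raise SpecError("water bridge distance below steric minimum")
        target = _dna_atom(model, plant.bp_index, plant.strand, plant.base_atom)

        if plant.via_water is None:
            pos = _safe_point(target, plant.distance, polar, clearance)
            res = ResidueUnit("P", plant.resnum, "", plant.resname, "protein")
            res.atoms.append(AtomRecord(serial, plant.atom,
                                        _element(plant.atom), "", 1.0, pos))
            serial += 1
            prot.append(res)
            polar.append(pos)
            truth.append({"resname": plant.resname, "resnum": plant.resnum,
                          "atom": plant.atom, "bp_index": plant.bp_index,
                          "strand": plant.strand, "base_atom": plant.base_atom,
                          "distance": plant.distance, "water": None})
        else:
            dw = plant.via_water
            # protein atom beyond direct reach, water on the bisector
            sep = plant.distance if plant.distance > 3.6 else 2 * dw - 0.8
            p_pos = _safe_point(target, sep, polar, clearance)
            mid = 0.5 * (target + p_pos)
            half = 0.5 * sep
            if dw <= half:
                raise SpecError("water distance shorter than half the "
                                "protein-base separation")
            offset = np.sqrt(dw ** 2 - half ** 2)
            others = [p for p in polar if np.linalg.norm(p - target) > 1e-6]
            perp = _perpendicular_safe(p_pos - target, mid, offset, others,
                                       clearance)
            w_pos = mid + perp * offset
            res = ResidueUnit("P", plant.resnum, "", plant.resname, "protein")
            res.atoms.append(AtomRecord(serial, plant.atom,
                                        _element(plant.atom), "", 1.0, p_pos))
            serial += 1
            wat = ResidueUnit("W", water_num, "", "HOH", "water")
            wat.atoms.append(AtomRecord(serial, "O", "O", "", 1.0, w_pos))
            serial += 1
            prot.append(res)
            waters.append(wat)
            polar.extend([p_pos, w_pos])
            truth.append({"resname": plant.resname, "resnum": plant.resnum,
                          "atom": plant.atom, "bp_index": plant.bp_index,
                          "strand": plant.strand, "base_atom": plant.base_atom,
                          "distance": dw, "water": ("W", water_num, "")})
            water_num += 1

    if prot:
        model.chains.setdefault("P", []).extend(prot)
    if waters:
        model.chains.setdefault("W", []).extend(waters)
    return model, truth


def _dna_atom(model: StructureModel, bp_index: int, strand: str, atom: str) -> np.ndarray:
    chain = "D" if strand == "top" else "E"
    n = len(model.chains["D"])
    number = bp_index + 1 if strand == "top" else n - bp_index
    res = model.get_residue((chain, number, ""))
    a = res.atom(atom)
    if a is None:
        raise SpecError(f"atom {atom} absent from {res.name} {chain}{number}")
    return a.coords


def _polar_atom_coords(model: StructureModel) -> list[np.ndarray]:
    out = []
    for r in model:
        for a in r.atoms:
            if a.element in ("N", "O"):
                out.append(a.coords)
    return out


def _sphere_directions(m: int = 72) -> np.ndarray:
    # Fibonacci sphere
    i = np.arange(m) + 0.5
    phi = np.arccos(1 - 2 * i / m)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _safe_point(target: np.ndarray, dist: float,
                polar: list[np.ndarray], clearance: float) -> np.ndarray:
    others = [p for p in polar if np.linalg.norm(p - target) > 1e-6]
    arr = np.array(others) if others else np.empty((0, 3))
    best, best_min = None, -np.inf
    for d in _sphere_directions():
        cand = target + d * dist
        mind = np.min(np.linalg.norm(arr - cand, axis=1)) if len(arr) else np.inf
        if mind > best_min:
            best_min, best = mind, cand
    if best_min < clearance:
        raise SpecError(f"no clash-free placement at {dist} Å "
                        f"(best clearance {best_min:.2f} Å)")
    return best


def _perpendicular_safe(axis: np.ndarray, mid: np.ndarray, offset: float,
                        polar: list[np.ndarray], clearance: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, axis)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    arr = np.array(polar) if polar else np.empty((0, 3))
    best, best_min = e1, -np.inf
    for ang in np.linspace(0, 2 * np.pi, 144, endpoint=False):
        d = np.cos(ang) * e1 + np.sin(ang) * e2
        cand = mid + d * offset
        mind = np.min(np.linalg.norm(arr - cand, axis=1)) if len(arr) else np.inf
        if mind > best_min:
            best_min, best = mind, d
    if best_min < clearance:
        raise SpecError(f"no clash-free water placement "
                        f"(best clearance {best_min:.2f} Å)")
    return best


def plant_planar_group(model: StructureModel, resname: str, resnum: int,
                       centroid: np.ndarray, normal: np.ndarray,
                       radius: float = 1.2) -> StructureModel:
    """Insert a planar pseudo side-chain group (e.g. an Arg guanidinium)
    with the given centroid and plane normal; used to emulate residues
    intercalated into the base stack."""
    model = model.transformed(np.eye(3), np.zeros(3))
    names = chem.PLANAR_GROUPS[resname]
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, normal)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    res = ResidueUnit("P", resnum, "", resname, "protein")
    serial = model.n_atoms + 1
    for j, name in enumerate(names):
        ang = 2 * np.pi * j / len(names)
        pos = centroid + radius * (np.cos(ang) * e1 + np.sin(ang) * e2)
        res.atoms.append(AtomRecord(serial, name, _element(name), "", 1.0, pos))
        serial += 1
    model.chains.setdefault("P", []).append(res)
    return model


# ---------------------------------------------------------------------------
# MSA generator
# ---------------------------------------------------------------------------

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class MsaSpec:
    n_seqs: int
    length: int
    alphabet: str = AA20
    conserved: dict[int, str] = field(default_factory=dict)   # column -> residue
    coupled: list[tuple[int, int, dict[tuple[str, str], float]]] = field(default_factory=list)
    anchors: dict[int, dict[object, str]] = field(default_factory=dict)  # col -> label -> residue
    labels: list[object] | None = None       # per-sequence labels for anchors
    background_rate: float = 1.0             # 1.0 = iid uniform background
    conserved_fidelity: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seqs < 20:
            raise SpecError("need at least 20 sequences for the requested "
                            "conservation fidelity")
        for c in self.conserved:
            if not 0 <= c < self.length:
                raise SpecError(f"conserved column {c} out of range")
        for i, j, table in self.coupled:
            if not (0 <= i < self.length and 0 <= j < self.length) or i == j:
                raise SpecError(f"bad coupled pair ({i}, {j})")
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in table.values()):
                raise SpecError("joint state table is not a distribution")
        planted = list(self.conserved) + [c for i, j, _ in self.coupled
                                          for c in (i, j)]
        if len(planted) != len(set(planted)):
            raise SpecError("conserved/coupled columns overlap")
        for c in self.anchors:
            if not 0 <= c < self.length:
                raise SpecError(f"anchor column {c} out of range")
            if c in planted:
                raise SpecError(f"anchor column {c} collides with another plant")
        if self.anchors and (self.labels is None or len(self.labels) != self.n_seqs):
            raise SpecError("anchor columns require one label per sequence")
        if not 0.95 <= self.conserved_fidelity <= 1.0:
            raise SpecError("conserved fidelity must be >= 0.95")


@dataclass
class MsaGroundTruth:
    conserved: dict[int, str]
    coupled_pairs: list[tuple[int, int]]
    anchors: dict[int, dict[object, str]]
    labels: list[object] | None


def simulate_msa(spec: MsaSpec) -> tuple[list[str], list[str], MsaGroundTruth]:
    """Generate an aligned set of sequences with planted signal columns."""
    rng = np.random.default_rng(spec.seed)
    alpha = np.array(list(spec.alphabet))
    n, L = spec.n_seqs, spec.length

    if spec.background_rate >= 1.0:
        rows = rng.integers(0, len(alpha), size=(n, L))
    else:
        consensus = rng.integers(0, len(alpha), size=L)
        rows = np.tile(consensus, (n, 1))
        mutate = rng.random((n, L)) < spec.background_rate
        rows[mutate] = rng.integers(0, len(alpha), size=int(mutate.sum()))

    index = {a: i for i, a in enumerate(spec.alphabet)}
    for col, res in spec.conserved.items():
        keep = rng.random(n) < spec.conserved_fidelity
        rows[keep, col] = index[res]

    for i, j, table in spec.coupled:
        states = list(table)
        probs = np.array([table[s] for s in states])
        draw = rng.choice(len(states), size=n, p=probs)
        for row, s in enumerate(draw):
            a, b = states[s]
            rows[row, i] = index[a]
            rows[row, j] = index[b]

    for col, mapping in spec.anchors.items():
        for row, label in enumerate(spec.labels or []):
            if label in mapping:
                rows[row, col] = index[mapping[label]]

    seqs = ["".join(alpha[r]) for r in rows]
    ids = [f"seq{i:04d}" for i in range(n)]
    truth = MsaGroundTruth(dict(spec.conserved),
                           [(i, j) for i, j, _ in spec.coupled],
                           {c: dict(m) for c, m in spec.anchors.items()},
                           list(spec.labels) if spec.labels is not None else None)
    return ids, seqs, truth


def write_fasta_alignment(ids: Sequence[str], seqs: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(ids, seqs):
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Kinetic trace generator
# ---------------------------------------------------------------------------

@dataclass
class TraceSpec:
    distances: tuple[float, ...] = (500.0, 1000.0, 1500.0, 2000.0, 2500.0)  # bp
    k_true: float = 226.0      # bp/s, ground-truth stepping rate
    c2: float = 5.0            # s, lag-versus-distance intercept
    m: float = 0.0             # background drift, signal/s
    amplitude: float = 1.0     # exponential amplitude, signal units
    k_exp: float = 0.05        # 1/s, apparent displacement rate constant
    dt: float = 0.1            # s, sampling interval
    duration: float | None = None   # s; default: 2x the largest lag + 5/k_exp
    noise_sd: float = 0.0      # signal units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true <= 0:
            raise SpecError("true rate must be positive")
        if self.k_exp <= 0 or self.dt <= 0:
            raise SpecError("rate constant and sampling interval must be positive")
        if not self.distances:
            raise SpecError("need at least one distance")
        max_lag = max(self.distances) / self.k_true + self.c2
        if self.duration is None:
            self.duration = max_lag * 1.5 + 5.0 / self.k_exp
        if self.duration <= max_lag:
            raise SpecError("duration must exceed the largest lag time")


def lag_model(t: np.ndarray, m: float, amplitude: float, k: float,
              t_app: float) -> np.ndarray:
    """Lag-phase displacement model: linear background before the lag,
    offset exponential after it, continuous at t = t_app."""
    t = np.asarray(t, float)
    c1 = m * t_app
    pre = m * t
    post = amplitude * (1.0 - np.exp(-k * np.clip(t - t_app, 0.0, None))) + c1
    return np.where(t < t_app, pre, post)


def simulate_traces(spec: TraceSpec):
    """One noisy trace per distance; lag times follow T_app = d/k + C2."""
    from .kinetics import KineticTrace  # local import avoids a cycle
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration, spec.dt)
    traces = []
    for d in spec.distances:
        t_app = d / spec.k_true + spec.c2
        y = lag_model(t, spec.m, spec.amplitude, spec.k_exp, t_app)
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=t.shape)
        traces.append(KineticTrace(time=t.copy(), signal=y, distance=d,
                                   label=f"d={d:g}bp", true_t_app=t_app))
    return traces


# ---------------------------------------------------------------------------
# Recognition-code entries
# ---------------------------------------------------------------------------

#: Planted residue/base-pair code used by the synthetic enzyme set.  The
#: layout mirrors the anchor positions that read each target position in the
#: two crystallised enzymes: a lysine/glutamine pair reading C:G at −1, the
#: +3 readers on Loop VI, the +4 readers on Loop IV, +5 on Loop V and the
#: +6 arginines on helix H / Loop V.
DEFAULT_PLANTED_CODE: dict[tuple[int, str], dict[int, str]] = {
    (-1, "C:G"): {1131: "K", 1118: "Q"},
    (3, "G:C"): {1368: "H", 1373: "Q"},
    (3, "A:T"): {1368: "N"},
    (4, "A:T"): {1228: "N"},
    (4, "G:C"): {1226: "K", 1058: "N"},
    (5, "T:A"): {1326: "N", 1329: "R"},
    (5, "C:G"): {1318: "D"},
    (6, "G:C"): {1286: "R"},
    (6, "C:G"): {1327: "R"},
}

#: Residues shown by enzymes that do not read a position (fallback per anchor).
DEFAULT_NONREADER = {1131: "N", 1118: "A", 1368: "S", 1373: "T", 1228: "S",
                     1226: "T", 1058: "G", 1327: "S", 1329: "T", 1318: "G",
                     1286: "L"}


def make_recognition_entries(n_enzymes: int = 11, seed: int = 0,
                             relabel_fraction: float = 0.0,
                             code: dict | None = None,
                             min_cell_support: int = 3):
    """Synthetic enzyme/target entries with a planted recognition code.

    Returns ``(entries, planted_code)`` where each entry carries a target
    over positions −1..+6 and the anchor residues implied by the planted
    code; ``relabel_fraction`` randomises that fraction of anchor residues
    to emulate annotation noise.  Every planted (position, base-pair) cell
    is guaranteed at least ``min_cell_support`` supporting enzymes (three
    by default, so the cell stays above a support-2 reporting floor even
    when one enzyme is held out).
    """
    from .recognition import EnzymeTargetEntry  # local import avoids a cycle
    rng = np.random.default_rng(seed)
    code = dict(DEFAULT_PLANTED_CODE if code is None else code)
    positions = sorted({p for p, _ in code})
    options: dict[int, list[str]] = {}
    for (p, bp) in code:
        options.setdefault(p, []).append(bp)

    anchors = sorted({a for mapping in code.values() for a in mapping})
    assignments: list[dict[int, str]] = []
    for e in range(n_enzymes):
        target: dict[int, str] = {1: "T:A"}
        for p in positions:
            if rng.random() < 0.25:     # this enzyme does not read position p
                continue
            target[p] = options[p][int(rng.integers(len(options[p])))]
        assignments.append(target)

    for p in positions:
        for bp in options[p]:
            supporters = [t for t in assignments if t.get(p) == bp]
            need = min_cell_support - len(supporters)
            for t in assignments:
                if need <= 0:
                    break
                if p not in t:
                    t[p] = bp
                    need -= 1
            for t in assignments:
                if need <= 0:
                    break
                if t.get(p) != bp and \
                        sum(1 for u in assignments
                            if u.get(p) == t.get(p)) > min_cell_support:
                    t[p] = bp
                    need -= 1

    entries = []
    for e, target in enumerate(assignments):
        residues: dict[int, str] = {a: DEFAULT_NONREADER.get(a, "A") for a in anchors}
        for p, bp in target.items():
            if (p, bp) in code:
                for a, res in code[(p, bp)].items():
                    residues[a] = res
        if relabel_fraction > 0:
            for a in anchors:
                if rng.random() < relabel_fraction:
                    residues[a] = AA20[int(rng.integers(len(AA20)))]
        entries.append(EnzymeTargetEntry(name=f"Enz{e:02d}", target=dict(target),
                                         residues=dict(residues)))
    return entries, code
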