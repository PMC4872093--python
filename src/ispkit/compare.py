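"""Structure superposition, inter-domain rotation and sequence identity.

The superposition is the closed-form least-squares rigid-body fit (Kabsch,
via SVD with a proper-rotation determinant correction).  Residue pairing
across homologous proteins uses a global sequence alignment because author
numbering drifts between homologues; same-protein comparisons can pair by
residue number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .struct_io import StructureModel


class ComparisonError(ValueError):
    pass


@dataclass
class Superposition:
    rotation: np.ndarray       # 3x3, det +1
    translation: np.ndarray    # 3-vector, Å
    rmsd: float
    n_atoms: int
    selections: tuple[str, str] = ("", "")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


#: Named residue ranges of the enzyme domains, in LlaGI author numbering.
#: The TRD splits into core, jaw and guide subdomains; LlaBIII equivalents
#: shift by a handful of residues.
LLAGI_DOMAINS = {
    "nuclease": [(1, 165)],
    "mtase": [(868, 1199)],
    "trd": [(1200, 1578)],
    "trd_core": [(1200, 1239), (1297, 1440)],
    "trd_jaw": [(1240, 1296)],
    "trd_guide": [(1440, 1578)],
    "mtase_trd": [(868, 1578)],
}

LLABIII_DOMAINS = {
    "trd": [(1205, 1578)],
    "trd_core": [(1205, 1244), (1291, 1448)],
    "trd_jaw": [(1245, 1288)],
    "trd_guide": [(1448, 1578)],
}


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(\d+)(?:-(\d+))?$")


def parse_selection(text: str) -> tuple[str | None, list[tuple[int, int]]]:
    """Parse a selection like ``"chain A and 1200-1440,1500-1578"``.

    Either part may be omitted; ranges are inclusive.
    """
    chain = None
    ranges: list[tuple[int, int]] = []
    for token in re.split(r"\s+and\s+", text.strip()):
        token = token.strip()
        if not token:
            continue
        if token.lower().startswith("chain"):
            chain = token.split(None, 1)[1].strip()
            continue
        for part in token.split(","):
            m = _RANGE_RE.match(part.strip())
            if not m:
                raise ComparisonError(f"cannot parse selection token {part!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            ranges.append((lo, hi))
    return chain, ranges


def select_atoms(model: StructureModel, selection: str, atom: str = "CA",
                 ) -> dict[int, np.ndarray]:
    """Residue-number -> coordinate map for the selected atoms."""
    chain, ranges = parse_selection(selection)
    chains = [chain] if chain else list(model.chains)
    out: dict[int, np.ndarray] = {}
    for cid in chains:
        for res in model.chain(cid):
            if ranges and not any(lo <= res.number <= hi for lo, hi in ranges):
                continue
            a = res.atom(atom)
            if a is not None:
                out[res.number] = a.coords
    if not out:
        raise ComparisonError(f"selection {selection!r} matched no {atom} atoms")
    return out


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid transform taking ``mobile`` onto ``reference``."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ComparisonError("paired coordinate sets must both be (n, 3)")
    n = len(mobile)
    if n < 3:
        raise ComparisonError("need at least 3 paired atoms")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    P, Q = mobile - mc, reference - rc
    s = np.linalg.svd(P, compute_uv=False)
    if s[1] < 1e-6 * max(s[0], 1.0):
        raise ComparisonError("paired atoms are (nearly) collinear")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def _alignment_pairs(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Index pairs of aligned (non-gap) positions from a global alignment."""
    aligner = _make_aligner()
    aln = aligner.align(seq_a.replace("X", "A"), seq_b.replace("X", "A"))[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def superpose(mobile_model: StructureModel, reference_model: StructureModel,
              mobile_sel: str, reference_sel: str, atom: str = "CA",
              pairing: str = "number") -> Superposition:
    """Superpose selected atoms of one model onto another.

    ``pairing="number"`` pairs by author residue number; ``"alignment"``
    pairs by a global sequence alignment of the selected residues (the
    right choice across homologues, where numbering drifts).
    """
    mob = select_atoms(mobile_model, mobile_sel, atom)
    ref = select_atoms(reference_model, reference_sel, atom)
    if pairing == "number":
        common = sorted(set(mob) & set(ref))
        m = np.array([mob[i] for i in common])
        r = np.array([ref[i] for i in common])
    elif pairing == "alignment":
        mob_nums = sorted(mob)
        ref_nums = sorted(ref)
        chain_m, _ = parse_selection(mobile_sel)
        chain_r, _ = parse_selection(reference_sel)
        seq_m = _selection_sequence(mobile_model, chain_m, mob_nums)
        seq_r = _selection_sequence(reference_model, chain_r, ref_nums)
        pairs = _alignment_pairs(seq_m, seq_r)
        m = np.array([mob[mob_nums[i]] for i, _ in pairs])
        r = np.array([ref[ref_nums[j]] for _, j in pairs])
    else:
        raise ComparisonError(f"unknown pairing mode {pairing!r}")
    sup = kabsch(m, r)
    sup.selections = (mobile_sel, reference_sel)
    return sup


def _selection_sequence(model: StructureModel, chain: str | None,
                        numbers: list[int]) -> str:
    from . import chemistry as chem
    chains = [chain] if chain else list(model.chains)
    by_num = {}
    for cid in chains:
        for res in model.chain(cid):
            if res.kind == "protein":
                by_num[res.number] = chem.AA_THREE_TO_ONE.get(res.name, "X")
    return "".join(by_num.get(n, "X") for n in numbers)


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle of a proper rotation matrix, degrees in [0, 180]."""
    tr = float(np.trace(R))
    return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))


def interdomain_rotation(model_a: StructureModel, model_b: StructureModel,
                         reference_sel_a: str, reference_sel_b: str,
                         mobile_sel_a: str, mobile_sel_b: str,
                         atom: str = "CA", pairing: str = "number") -> float:
    """Relative rotation (degrees) of a mobile domain between two models.

    Model B is first superposed onto model A over the reference domain;
    the residual rotation that then best superposes the mobile domains is
    reported as the inter-domain rotation.
    """
    ref_fit = superpose(model_b, model_a, reference_sel_b, reference_sel_a,
                        atom=atom, pairing=pairing)
    model_b_fit = model_b.transformed(ref_fit.rotation, ref_fit.translation)
    mob_fit = superpose(model_b_fit, model_a, mobile_sel_b, mobile_sel_a,
                        atom=atom, pairing=pairing)
    return rotation_angle(mob_fit.rotation)


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # end gaps are free: homologous constructs often differ by terminal
    # truncations that should not be penalised
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global BLOSUM62 alignment.

    Identity = identical aligned pairs / alignment columns, excluding end
    gaps from the denominator (internal gaps count).  Co-optimal
    alignments can differ between argument orders; the better of the two
    orders is reported, which makes the measure symmetric.
    """
    return max(_identity_one_order(seq_a, seq_b),
               _identity_one_order(seq_b, seq_a))


def _identity_one_order(seq_a: str, seq_b: str) -> float:
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        raise ComparisonError("sequences must be non-empty")
    for s in (seq_a, seq_b):
        bad = set(s) - _AA_ALPHABET
        if bad:
            raise ComparisonError(f"non-amino-acid symbols: {sorted(bad)}")
    aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    # trim end-gap columns
    start = max(len(a) - len(a.lstrip("-")), len(b) - len(b.lstrip("-")))
    end = len(a) - max(len(a) - len(a.rstrip("-")), len(b) - len(b.rstrip("-")))
    core_a, core_b = a[start:end], b[start:end]
    if not core_a:
        return 0.0
    same = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    return 100.0 * same / len(core_a)


def compare_report(model_a: StructureModel, model_b: StructureModel,
                   mobile_sel: str, reference_sel: str,
                   pairing: str = "alignment") -> dict:
    sup = superpose(model_a, model_b, mobile_sel, reference_sel, pairing=pairing)
    return {
        "rmsd_A": round(sup.rmsd, 3),
        "n_atoms": sup.n_atoms,
        "rotation_deg": round(rotation_angle(sup.rotation), 2),
        "rotation_matrix": [[round(x, 6) for x in row] for row in sup.rotation],
        "translation_A": [round(x, 4) for x in sup.translation],
        "selections": list(sup.selections),
    }
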