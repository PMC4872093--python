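"""Residue <-> target-base recognition code across Type ISP homologues.

The enzymes read their targets through a small set of structurally
conserved elements (Loops I-VI and one TRD helix); the residues occupying a
few anchor positions in those elements co-vary with the base pair read at
each target position.  This module maps the anchor positions across an
alignment of homologues, tabulates residue/base-pair associations into a
code table, and predicts target base pairs for an enzyme from its anchor
residues.

Base pairs are oriented top:bottom (``"C:G"`` is a top-strand cytosine) —
which strand a residue reads matters.  The association score for a
(residue, base-pair) cell is the product of the two conditional purities
P(residue | base pair) x P(base pair | residue), computed over enzymes
that specify the position; degenerate target letters contribute
fractional weight to each compatible base pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import chemistry as chem
from .msa import Msa, MsaError


class CodeError(ValueError):
    pass


#: Structural elements that carry the recognition anchors, LlaGI numbering.
#: Loops IV-VI windows are extended a few residues to cover the anchors
#: contributed by homologues whose numbering drifts (e.g. the LlaBIII
#: +4 reader K1231 and the Loop V readers 1318-1321).
DEFAULT_ELEMENTS: dict[str, tuple[int, int]] = {
    "Loop I": (1017, 1027),
    "Loop II": (1053, 1062),
    "Loop III": (1115, 1138),
    "Loop IV": (1223, 1231),
    "Helix H": (1286, 1295),
    "Loop V": (1318, 1331),
    "Loop VI": (1360, 1374),
}

DEFAULT_ANCHORS: tuple[int, ...] = (
    1018, 1021, 1023, 1024, 1055, 1056, 1058, 1118, 1125, 1131,
    1226, 1228, 1231, 1286, 1287, 1318, 1319, 1321, 1326, 1327,
    1329, 1360, 1368, 1372, 1373,
)


@dataclass
class RecognitionAnchors:
    elements: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENTS))
    anchors: tuple[int, ...] = DEFAULT_ANCHORS

    def __post_init__(self) -> None:
        for a in self.anchors:
            homes = [name for name, (lo, hi) in self.elements.items()
                     if lo <= a <= hi]
            if len(homes) != 1:
                raise CodeError(f"anchor {a} lies in {len(homes)} elements "
                                f"({homes}); expected exactly one")

    def element_of(self, anchor: int) -> str:
        for name, (lo, hi) in self.elements.items():
            if lo <= anchor <= hi:
                return name
        raise CodeError(f"anchor {anchor} outside all elements")


# ---------------------------------------------------------------------------
# Enzyme/target entries
# ---------------------------------------------------------------------------

def _expand_letter(letter: str) -> list[tuple[str, float]]:
    """IUPAC top-strand letter -> oriented base pairs with weights."""
    letter = letter.upper()
    if ":" in letter:
        return [(letter, 1.0)]
    bases = chem.IUPAC_DNA.get(letter)
    if bases is None:
        raise CodeError(f"invalid IUPAC letter {letter!r}")
    if letter == "N":
        return []
    w = 1.0 / len(bases)
    return [(f"{b}:{chem.WATSON_CRICK[b]}", w) for b in bases]


@dataclass
class EnzymeTargetEntry:
    """One homologue: its target over positions −1..+6 and anchor residues.

    ``target`` maps target position -> either an oriented base pair
    ("C:G") or a top-strand IUPAC letter; unlisted positions are
    unspecified.  ``residues`` maps anchor (LlaGI numbering) -> one-letter
    residue (None/absent for a gap).
    """
    name: str
    target: dict[int, str]
    residues: dict[int, str | None]

    def weighted_pairs(self, position: int) -> list[tuple[str, float]]:
        if position not in self.target:
            return []
        return _expand_letter(self.target[position])

    @classmethod
    def from_target_string(cls, name: str, target: str,
                           residues: dict[int, str | None],
                           start: int = -1) -> "EnzymeTargetEntry":
        from .struct_io import position_run
        positions = position_run(start, len(target))
        mapping = {p: letter for p, letter in zip(positions, target.upper())
                   if letter != "N"}
        return cls(name=name, target=mapping, residues=dict(residues))


# ---------------------------------------------------------------------------
# Anchor mapping across an alignment
# ---------------------------------------------------------------------------

def map_anchor_residues(msa: Msa, anchors: RecognitionAnchors | None = None,
                        reference_id: str | None = None,
                        ) -> dict[str, dict[int, str | None]]:
    """Residue occupying each anchor position in every aligned sequence.

    The reference row (LlaGI numbering) must be ungapped at the anchor
    columns; other rows report the aligned residue, or None at a gap.
    """
    anchors = anchors or RecognitionAnchors()
    ref = reference_id or msa.ref_id
    if ref is None or ref not in msa.ids:
        raise CodeError(f"reference id {ref!r} not in alignment")
    if not msa.ref_map:
        raise MsaError("alignment has no reference residue map")
    col_of = {num: col for col, num in msa.ref_map.items()}
    out: dict[str, dict[int, str | None]] = {}
    for sid, row in zip(msa.ids, msa.rows):
        res_map: dict[int, str | None] = {}
        for a in anchors.anchors:
            col = col_of.get(a)
            if col is None:
                res_map[a] = None
                continue
            ch = row[col].upper()
            res_map[a] = None if ch in "-." else ch
        out[sid] = res_map
    return out


# ---------------------------------------------------------------------------
# Code derivation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodeEntry:
    position: int
    base_pair: str        # oriented top:bottom
    anchor: int           # LlaGI-numbered anchor position
    residue: str
    score: float          # product of conditional purities, in [0, 1]
    support: int          # number of supporting enzymes
    predicted: bool = False


@dataclass
class CodeTable:
    entries: list[CodeEntry] = field(default_factory=list)

    def at(self, position: int, base_pair: str | None = None) -> list[CodeEntry]:
        return [e for e in self.entries
                if e.position == position
                and (base_pair is None or e.base_pair == base_pair)]

    def add_predicted(self, position: int, base_pair: str, anchor: int,
                      residue: str) -> None:
        """Record a hypothesised (untrained) code entry, flagged predicted."""
        self.entries.append(CodeEntry(position, base_pair, anchor, residue,
                                      score=0.0, support=0, predicted=True))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries],
                            columns=["position", "base_pair", "anchor",
                                     "residue", "score", "support", "predicted"])

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(
                [e.__dict__ for e in self.entries], indent=2) + "\n")


def derive_code(entries: list[EnzymeTargetEntry], threshold: float = 0.8,
                min_support: int = 2) -> CodeTable:
    """Tabulate residue/base-pair associations into a code table.

    For every (position, base pair) observed and every anchor, the
    association score is P(residue | base pair) x P(base pair | residue)
    over the enzymes that specify that position; entries reaching the
    score threshold with at least ``min_support`` supporting enzymes make
    the code.  Order of entries does not matter.
    """
    specified = [e for e in entries if any(e.weighted_pairs(p)
                                           for p in e.target)]
    if len(specified) < 3:
        raise CodeError("need at least 3 entries with specified positions")

    positions = sorted({p for e in entries for p in e.target
                        if e.weighted_pairs(p)})
    anchors = sorted({a for e in entries for a in e.residues})
    table = CodeTable()
    for pos in positions:
        contributors = [(e, e.weighted_pairs(pos)) for e in entries
                        if e.weighted_pairs(pos)]
        for anchor in anchors:
            counts: dict[tuple[str, str], float] = {}
            support: dict[tuple[str, str], int] = {}
            for e, pairs in contributors:
                res = e.residues.get(anchor)
                if res is None:
                    continue
                for bp, w in pairs:
                    counts[(res, bp)] = counts.get((res, bp), 0.0) + w
                    support[(res, bp)] = support.get((res, bp), 0) + 1
            if not counts:
                continue
            by_bp: dict[str, float] = {}
            by_res: dict[str, float] = {}
            for (res, bp), w in counts.items():
                by_bp[bp] = by_bp.get(bp, 0.0) + w
                by_res[res] = by_res.get(res, 0.0) + w
            for (res, bp), w in counts.items():
                score = (w / by_bp[bp]) * (w / by_res[res])
                if score >= threshold and support[(res, bp)] >= min_support:
                    table.entries.append(CodeEntry(pos, bp, anchor, res,
                                                   round(score, 4),
                                                   support[(res, bp)]))
    table.entries.sort(key=lambda e: (e.position, e.base_pair, e.anchor))
    return table


def predict_target(residues: dict[int, str | None], code: CodeTable,
                   ) -> dict[int, tuple[str | None, float]]:
    """Predict the base pair at each coded position from anchor residues.

    Per position, candidate base pairs accumulate the scores of matched
    (trained, non-predicted) code entries; the best-supported pair wins.
    Positions with no match are reported unspecified with zero confidence.
    """
    if not code.entries:
        raise CodeError("empty code table")
    out: dict[int, tuple[str | None, float]] = {}
    for pos in sorted({e.position for e in code.entries}):
        scores: dict[str, float] = {}
        for e in code.at(pos):
            if e.predicted:
                continue
            if residues.get(e.anchor) == e.residue:
                scores[e.base_pair] = scores.get(e.base_pair, 0.0) + e.score
        if scores:
            best = max(scores, key=lambda bp: (scores[bp], bp))
            out[pos] = (best, round(scores[best], 4))
        else:
            out[pos] = (None, 0.0)
    return out


def entries_to_tsv(entries: list[EnzymeTargetEntry], path: str | Path) -> None:
    anchors = sorted({a for e in entries for a in e.residues})
    rows = []
    for e in entries:
        row = {"enzyme": e.name}
        row["target"] = ";".join(f"{p}={e.target[p]}" for p in sorted(e.target))
        for a in anchors:
            row[f"r{a}"] = e.residues.get(a) or "-"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def entries_from_tsv(path: str | Path) -> list[EnzymeTargetEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = []
    for _, row in df.iterrows():
        target: dict[int, str] = {}
        if isinstance(row.get("target"), str) and row["target"]:
            for chunk in row["target"].split(";"):
                p, v = chunk.split("=")
                target[int(p)] = v
        residues = {}
        for col in df.columns:
            if col.startswith("r") and col[1:].isdigit():
                val = row[col]
                residues[int(col[1:])] = None if val in ("-", "", None) else val
        entries.append(EnzymeTargetEntry(row["enzyme"], target, residues))
    return entries
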