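"""DNA duplex deformation geometry.

Quantifies the deformations a target-bound Type ISP enzyme imposes on its
recognition sequence: overall helical-axis bend, widened major and minor
grooves, local unwinding, and extrusion (flipping) of the methylation-target
base out of the stack.

Conventions
-----------
* The helical axis is estimated per base-pair step from windowed
  least-squares line fits through C1' midpoints of Watson-Crick pairs;
  pairs without an intact pairing contact (e.g. a flipped base) are left
  out of the fit.
* Groove widths follow the cross-strand phosphate convention: the shortest
  P-P distance within a groove-specific register window, minus 5.8 Å for
  two phosphate group radii.  The minor-groove register spans pair offsets
  +2..+6 and the major-groove register −6..−2 (the closest approach across
  the major groove lies roughly half a helical turn in the opposite
  direction along the duplex).
* A base counts as flipped when its base-atom centroid lies further than a
  displacement threshold (default 8 Å) from the local axis AND it has no
  Watson-Crick hydrogen bond to its frame partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chemistry as chem
from .struct_io import StructureModel, TargetFrame

MINOR_REGISTER = range(2, 7)
MAJOR_REGISTER = range(-6, -1)
P_P_SUBTRACT = 5.8
END_FLAG_STEPS = 3


class GeometryError(ValueError):
    pass


@dataclass
class DuplexGeometry:
    positions: list[int]
    axis_points: np.ndarray            # (n, 3); NaN rows where undefined
    bend_angle: float | None
    widths: pd.DataFrame               # index position; columns major/minor/defined
    twists: pd.DataFrame               # per-step twist, degrees
    flipped: list[tuple[int, str, float]] = field(default_factory=list)

    def to_summary(self) -> dict:
        return {
            "bend_angle_deg": self.bend_angle,
            "flipped": [{"position": p, "strand": s, "displacement_A": round(d, 2)}
                        for p, s, d in self.flipped],
            "mean_major_width_A": float(np.nanmean(self.widths["major"]))
            if len(self.widths) else None,
            "mean_minor_width_A": float(np.nanmean(self.widths["minor"]))
            if len(self.widths) else None,
        }


# ---------------------------------------------------------------------------
# Pair midpoints and the helical axis
# ---------------------------------------------------------------------------

def _pair_midpoints(model: StructureModel, frame: TargetFrame,
                    pairing_cutoff: float = 6.0) -> tuple[list[int], np.ndarray, np.ndarray]:
    """C1' midpoints per position and a mask of intact Watson-Crick pairs.

    A pair is intact when both pairing atoms exist and lie within
    ``pairing_cutoff`` of each other; broken pairs (flipped or unpaired
    bases) are masked out of axis fitting but keep an interpolated midpoint.
    """
    positions = frame.positions()
    mids = np.full((len(positions), 3), np.nan)
    intact = np.zeros(len(positions), dtype=bool)
    for idx, pos in enumerate(positions):
        try:
            top = frame.residue_at(model, pos, "top")
        except KeyError:
            continue
        bot = None
        if pos in frame.bottom:
            bot = frame.residue_at(model, pos, "bottom")
        t_c1 = top.atom("C1'")
        b_c1 = bot.atom("C1'") if bot is not None else None
        if t_c1 is None or b_c1 is None:
            continue
        mids[idx] = 0.5 * (t_c1.coords + b_c1.coords)
        t_pair = top.atom(chem.PAIRING_ATOM.get(top.base or "", "N1"))
        b_pair = bot.atom(chem.PAIRING_ATOM.get(bot.base or "", "N1"))
        if t_pair is not None and b_pair is not None:
            intact[idx] = np.linalg.norm(t_pair.coords - b_pair.coords) <= pairing_cutoff
    return positions, mids, intact


def _window_directions(mids: np.ndarray, ok: np.ndarray, window: int) -> np.ndarray:
    """Rough local axis direction per step from windowed LS line fits."""
    n = len(mids)
    dirs = np.full((n, 3), np.nan)
    half = window // 2
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, lo + window)
        lo = max(0, hi - window)
        sel = np.arange(lo, hi)[ok[lo:hi]]
        if len(sel) < 3:
            continue
        pts = mids[sel]
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        v = vt[0]
        if np.dot(pts[-1] - pts[0], v) < 0:
            v = -v
        dirs[i] = v
    return dirs


def fit_helical_axis(model: StructureModel, frame: TargetFrame,
                     window: int = 5) -> tuple[list[int], np.ndarray]:
    """Per-step helical axis points from C1' midpoints.

    Windowed least-squares line fits through the midpoints give a local
    axis direction and twist estimate; the rotating (helical) component of
    the midpoints is then cancelled by a three-point stencil whose weights
    annihilate one turn of the estimated twist, leaving points on the
    axis.  Broken pairs (flipped or unpaired bases) are excluded from the
    fits; their axis points, and the duplex ends, are interpolated or
    extrapolated from neighbours.  Rows are NaN where nothing could be
    estimated.
    """
    positions, mids, intact = _pair_midpoints(model, frame)
    n = len(positions)
    if n < 8:
        raise GeometryError("duplex too short for axis fitting (need >= 8 bp)")
    ok = intact & np.all(np.isfinite(mids), axis=1)
    dirs = _window_directions(mids, ok, window)

    # pair long-axis vectors for twist estimation
    vecs = np.full((n, 3), np.nan)
    for idx, pos in enumerate(positions):
        if pos not in frame.top or pos not in frame.bottom:
            continue
        t = model.get_residue(frame.top[pos]).atom("C1'")
        b = model.get_residue(frame.bottom[pos]).atom("C1'")
        if t is not None and b is not None:
            vecs[idx] = b.coords - t.coords

    def step_twist(i: int, axis_dir: np.ndarray) -> float:
        a, b = vecs[i], vecs[i + 1]
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            return np.nan
        a = a - np.dot(a, axis_dir) * axis_dir
        b = b - np.dot(b, axis_dir) * axis_dir
        if np.linalg.norm(a) < 1e-9 or np.linalg.norm(b) < 1e-9:
            return np.nan
        a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
        return float(np.arctan2(np.dot(np.cross(a, b), axis_dir),
                                np.clip(np.dot(a, b), -1, 1)))

    axis = np.full((n, 3), np.nan)
    for i in range(1, n - 1):
        if not (ok[i - 1] and ok[i] and ok[i + 1]):
            continue
        d = dirs[i]
        if not np.all(np.isfinite(d)):
            continue
        twists = [tw for tw in (step_twist(i - 1, d), step_twist(i, d))
                  if np.isfinite(tw)]
        omega = np.mean(twists) if twists else np.deg2rad(36.0)
        omega = float(np.clip(abs(omega), np.deg2rad(18.0), np.deg2rad(60.0)))
        w = 1.0 / (2.0 * (1.0 - np.cos(omega)))
        axis[i] = (1 - 2 * w) * mids[i] + w * (mids[i - 1] + mids[i + 1])
    # refine the twist estimate about the axis tangent and redo the stencil
    for i in range(1, n - 1):
        if not np.all(np.isfinite(axis[max(0, i - 1):i + 2])):
            continue
        tangent = axis[i + 1] - axis[i - 1]
        nt = np.linalg.norm(tangent)
        if nt < 1e-9:
            continue
        tangent /= nt
        twists = [tw for tw in (step_twist(i - 1, tangent), step_twist(i, tangent))
                  if np.isfinite(tw)]
        if not twists:
            continue
        omega = float(np.clip(abs(np.mean(twists)),
                              np.deg2rad(18.0), np.deg2rad(60.0)))
        w = 1.0 / (2.0 * (1.0 - np.cos(omega)))
        axis[i] = (1 - 2 * w) * mids[i] + w * (mids[i - 1] + mids[i + 1])

    # fill gaps by neighbour interpolation, ends by linear extrapolation
    good = np.where(np.all(np.isfinite(axis), axis=1))[0]
    if len(good) >= 2:
        for i in range(n):
            if np.all(np.isfinite(axis[i])):
                continue
            lower = good[good < i]
            upper = good[good > i]
            if len(lower) and len(upper):
                a, b = lower[-1], upper[0]
                f = (i - a) / (b - a)
                axis[i] = (1 - f) * axis[a] + f * axis[b]
            elif len(upper) >= 2:
                a, b = upper[0], upper[1]
                axis[i] = axis[a] + (i - a) / (b - a) * (axis[b] - axis[a])
            elif len(lower) >= 2:
                a, b = lower[-2], lower[-1]
                axis[i] = axis[b] + (i - b) / (b - a) * (axis[b] - axis[a])
    return positions, axis


# ---------------------------------------------------------------------------
# Bend angle
# ---------------------------------------------------------------------------

def _arm_direction(mids: np.ndarray) -> np.ndarray:
    centroid = mids.mean(axis=0)
    _, _, vt = np.linalg.svd(mids - centroid)
    v = vt[0]
    if np.dot(mids[-1] - mids[0], v) < 0:
        v = -v
    return v


def bend_angle(model: StructureModel, frame: TargetFrame,
               upstream: tuple[int, int], downstream: tuple[int, int]) -> float:
    """Angle in degrees between the best-fit axes of two duplex arms.

    ``upstream`` and ``downstream`` are inclusive target-position ranges;
    each arm needs at least 4 steps and the ranges must not overlap.  Arm
    directions are fitted to the helical-axis points of the arm, so arms
    should avoid the 1-2 steps immediately flanking a suspected kink.
    """
    if not (upstream[0] <= upstream[1] and downstream[0] <= downstream[1]):
        raise GeometryError("arm ranges must be (low, high)")
    if upstream[1] >= downstream[0]:
        raise GeometryError("arm ranges overlap or are out of order")
    positions, axis = fit_helical_axis(model, frame)
    pos_arr = np.array(positions)
    arms = []
    for lo, hi in (upstream, downstream):
        sel = (pos_arr >= lo) & (pos_arr <= hi) & \
            np.all(np.isfinite(axis), axis=1)
        if sel.sum() < 5:
            raise GeometryError(f"arm {lo}..{hi} has fewer than 4 usable steps")
        arms.append(_arm_direction(axis[sel]))
    cosang = float(np.clip(np.dot(arms[0], arms[1]), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# Groove widths
# ---------------------------------------------------------------------------

def groove_widths(model: StructureModel, frame: TargetFrame) -> pd.DataFrame:
    """Cross-strand P-P groove widths per top-strand position.

    Width = shortest P(top, i)-P(bottom, i+k) distance within the
    groove-specific register window minus 5.8 Å.  Positions whose register
    window is incomplete, whose phosphates are missing, or that lie within
    3 steps of a duplex end are reported NaN and flagged undefined.
    """
    positions = frame.positions()
    n = len(positions)
    p_top = np.full((n, 3), np.nan)
    p_bot = np.full((n, 3), np.nan)
    for idx, pos in enumerate(positions):
        for mapping, arr in ((frame.top, p_top), (frame.bottom, p_bot)):
            if pos not in mapping:
                continue
            res = model.get_residue(mapping[pos])
            at = res.atom("P")
            if at is not None:
                arr[idx] = at.coords

    rows = []
    for i, pos in enumerate(positions):
        entry = {"position": pos, "major": np.nan, "minor": np.nan,
                 "defined": True}
        near_end = i < END_FLAG_STEPS or i >= n - END_FLAG_STEPS
        for name, register in (("minor", MINOR_REGISTER), ("major", MAJOR_REGISTER)):
            dists = []
            complete = True
            for k in register:
                j = i + k
                if not 0 <= j < n or not np.all(np.isfinite(p_bot[j])) \
                        or not np.all(np.isfinite(p_top[i])):
                    complete = False
                    continue
                dists.append(np.linalg.norm(p_top[i] - p_bot[j]))
            if dists and complete and not near_end:
                entry[name] = min(dists) - P_P_SUBTRACT
        entry["defined"] = bool(np.isfinite(entry["major"]) or np.isfinite(entry["minor"]))
        rows.append(entry)
    return pd.DataFrame(rows).set_index("position")


def groove_widths_bruteforce(model: StructureModel, frame: TargetFrame) -> pd.DataFrame:
    """All-pairs oracle: narrowest cross-strand P-P contact per position.

    Scans every cross-strand phosphate pair; the minimum for a position
    equals the register-based minor-groove value on B-form fixtures (the
    global cross-strand minimum lies in the minor-groove register).
    """
    positions = frame.positions()
    rows = []
    for pos in positions:
        if pos not in frame.top:
            continue
        top = model.get_residue(frame.top[pos])
        pt = top.atom("P")
        if pt is None:
            continue
        best = np.inf
        for q in positions:
            if q not in frame.bottom:
                continue
            bot = model.get_residue(frame.bottom[q])
            pb = bot.atom("P")
            if pb is None:
                continue
            best = min(best, float(np.linalg.norm(pt.coords - pb.coords)))
        rows.append({"position": pos, "narrowest": best - P_P_SUBTRACT})
    return pd.DataFrame(rows).set_index("position")


# ---------------------------------------------------------------------------
# Twist and flipped bases
# ---------------------------------------------------------------------------

def per_step_twist(model: StructureModel, frame: TargetFrame) -> pd.DataFrame:
    """Helical twist per step from the rotation of the C1'-C1' pair vector
    about the local axis direction."""
    positions, mids, intact = _pair_midpoints(model, frame)
    _, axis = fit_helical_axis(model, frame)
    vecs = np.full((len(positions), 3), np.nan)
    for idx, pos in enumerate(positions):
        if pos not in frame.top or pos not in frame.bottom:
            continue
        t = model.get_residue(frame.top[pos]).atom("C1'")
        b = model.get_residue(frame.bottom[pos]).atom("C1'")
        if t is None or b is None:
            continue
        vecs[idx] = b.coords - t.coords
    rows = []
    for i in range(len(positions) - 1):
        if not (np.all(np.isfinite(vecs[i])) and np.all(np.isfinite(vecs[i + 1]))
                and np.all(np.isfinite(axis[i])) and np.all(np.isfinite(axis[i + 1]))):
            continue
        z = axis[i + 1] - axis[i]
        nz = np.linalg.norm(z)
        if nz < 1e-6:
            continue
        z = z / nz
        a = vecs[i] - np.dot(vecs[i], z) * z
        b = vecs[i + 1] - np.dot(vecs[i + 1], z) * z
        if np.linalg.norm(a) < 1e-6 or np.linalg.norm(b) < 1e-6:
            continue
        a /= np.linalg.norm(a)
        b /= np.linalg.norm(b)
        ang = np.degrees(np.arctan2(np.dot(np.cross(a, b), z),
                                    np.clip(np.dot(a, b), -1, 1)))
        rows.append({"step": f"{positions[i]}/{positions[i+1]}",
                     "twist_deg": float(ang)})
    return pd.DataFrame(rows)


def _base_centroid(res) -> np.ndarray | None:
    pts = [a.coords for a in res.atoms if chem.moiety_of(a.name) == "base"]
    if not pts:
        return None
    return np.mean(pts, axis=0)


def detect_flipped_bases(model: StructureModel, frame: TargetFrame,
                         displacement_threshold: float = 8.0,
                         pairing_cutoff: float = 3.5,
                         ) -> list[tuple[int, str, float]]:
    """Flipped-out bases: centroid far from the local axis and no
    Watson-Crick contact with the frame partner.

    Returns ``(position, strand, displacement)`` tuples sorted by position.
    """
    positions, axis = fit_helical_axis(model, frame)
    axis_ok = axis[np.all(np.isfinite(axis), axis=1)]
    out = []
    for pos in positions:
        for strand, mapping, other in (("top", frame.top, frame.bottom),
                                       ("bottom", frame.bottom, frame.top)):
            if pos not in mapping:
                continue
            res = model.get_residue(mapping[pos])
            centroid = _base_centroid(res)
            if centroid is None:
                continue
            disp = _point_to_polyline(centroid, axis_ok)
            if disp <= displacement_threshold:
                continue
            paired = False
            if pos in other:
                partner = model.get_residue(other[pos])
                a = res.atom(chem.PAIRING_ATOM.get(res.base or "", "N1"))
                b = partner.atom(chem.PAIRING_ATOM.get(partner.base or "", "N1"))
                if a is not None and b is not None:
                    paired = np.linalg.norm(a.coords - b.coords) <= pairing_cutoff
            if not paired:
                out.append((pos, strand, float(disp)))
    return sorted(out)


def _point_to_polyline(p: np.ndarray, line: np.ndarray) -> float:
    if len(line) == 0:
        return np.inf
    if len(line) == 1:
        return float(np.linalg.norm(p - line[0]))
    best = np.inf
    for a, b in zip(line[:-1], line[1:]):
        ab = b - a
        denom = np.dot(ab, ab)
        t = np.clip(np.dot(p - a, ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
        best = min(best, float(np.linalg.norm(p - (a + t * ab))))
    return best


def describe_duplex(model: StructureModel, frame: TargetFrame,
                    upstream: tuple[int, int] | None = None,
                    downstream: tuple[int, int] | None = None) -> DuplexGeometry:
    """Convenience bundle of axis, bend, widths, twist and flips."""
    positions, axis = fit_helical_axis(model, frame)
    bend = None
    if upstream is not None and downstream is not None:
        bend = bend_angle(model, frame, upstream, downstream)
    return DuplexGeometry(
        positions=positions,
        axis_points=axis,
        bend_angle=bend,
        widths=groove_widths(model, frame),
        twists=per_step_twist(model, frame),
        flipped=detect_flipped_bases(model, frame),
    )
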