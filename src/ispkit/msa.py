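"""Alignment-based conservation and evolutionary-coupling analysis.

Per-column conservation is relative entropy against BLOSUM62 background
frequencies with Henikoff position-based sequence weighting, reported both
raw and on a rescaled axis (sign-flipped and shifted so the minimum is
exactly zero, the convention used when overlaying conservation with
coupling strengths).

Pairwise couplings are average-product-corrected mutual information
(MI-APC) over weighted joint frequencies with a pseudocount; gaps are a
21st symbol and columns that are mostly gaps are excluded.  The per-residue
coupling strength aggregates each residue's share of the top-L strongest
couplings (L = number of scored columns), a desk-scale rank proxy for the
pseudolikelihood coupling strengths used by large-scale tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO
from scipy.stats import hypergeom


class MsaError(ValueError):
    pass


#: BLOSUM62 background amino-acid frequencies (Robinson & Robinson style
#: composition used when the matrix was built).
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

GAP_CHARS = "-."


@dataclass
class Msa:
    ids: list[str]
    rows: list[str]
    ref_id: str | None = None
    ref_map: dict[int, int] = field(default_factory=dict)  # column -> ref residue number

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise MsaError("alignment rows differ in length")
        if not self.rows:
            raise MsaError("empty alignment")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def array(self) -> np.ndarray:
        return np.array([list(r.upper()) for r in self.rows])

    @classmethod
    def read(cls, path: str | Path, fmt: str = "fasta",
             ref_id: str | None = None, ref_start: int = 1) -> "Msa":
        """Read an aligned FASTA / Clustal / Stockholm file.

        If ``ref_id`` is given, non-gap columns of that row are numbered
        consecutively from ``ref_start`` to build the column -> reference
        residue map.
        """
        aln = AlignIO.read(str(path), fmt)
        ids = [rec.id for rec in aln]
        rows = [str(rec.seq).upper() for rec in aln]
        msa = cls(ids=ids, rows=rows, ref_id=ref_id)
        if ref_id is not None:
            msa.build_ref_map(ref_id, ref_start)
        return msa

    def build_ref_map(self, ref_id: str, ref_start: int = 1) -> None:
        if ref_id not in self.ids:
            raise MsaError(f"reference id {ref_id!r} not in alignment")
        row = self.rows[self.ids.index(ref_id)]
        num = ref_start
        self.ref_id = ref_id
        self.ref_map = {}
        for col, ch in enumerate(row):
            if ch not in GAP_CHARS:
                self.ref_map[col] = num
                num += 1

    def columns_for_ref_range(self, lo: int, hi: int) -> list[int]:
        cols = [c for c, n in self.ref_map.items() if lo <= n <= hi]
        if not cols:
            raise MsaError(f"reference range {lo}-{hi} maps to no columns")
        return sorted(cols)


def henikoff_weights(arr: np.ndarray) -> np.ndarray:
    """Position-based sequence weights, normalised to mean 1."""
    n, L = arr.shape
    w = np.zeros(n)
    for c in range(L):
        col = arr[:, c]
        symbols, inverse, counts = np.unique(col, return_inverse=True,
                                             return_counts=True)
        k = len(symbols)
        w += 1.0 / (k * counts[inverse])
    w *= n / w.sum()
    return w


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

@dataclass
class ConservationProfile:
    raw: np.ndarray          # per-column relative entropy, bits; NaN = undefined
    rescaled: np.ndarray     # (-1 x raw) + offset, min exactly 0
    offset: float
    undefined: list[int]     # all-gap columns

    def to_frame(self, ref_map: dict[int, int] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"column": np.arange(len(self.raw)),
                           "raw_bits": self.raw, "rescaled": self.rescaled})
        if ref_map:
            df["ref_residue"] = [ref_map.get(c) for c in df["column"]]
        return df


def conservation_profile(msa: Msa, gap_policy: str = "ignore",
                         pseudocount: float = 1e-4) -> ConservationProfile:
    """Weighted relative-entropy conservation per column.

    ``gap_policy="ignore"`` drops gaps and renormalises over residues.  The
    rescaled score is the raw score multiplied by −1 and shifted by the
    offset that makes the minimum exactly zero (so the most conserved
    column scores 0 and variability grows positive).
    """
    if msa.n_seqs < 2:
        raise MsaError("need at least 2 sequences")
    if gap_policy != "ignore":
        raise MsaError(f"unknown gap policy {gap_policy!r}")
    arr = msa.array()
    w = henikoff_weights(arr)
    alphabet = sorted({ch for row in arr for ch in row} - set(GAP_CHARS))
    bg = np.array([BLOSUM62_BACKGROUND.get(a, 0.0) for a in alphabet])
    if bg.sum() <= 0:
        bg = np.ones(len(alphabet))
    bg = bg / bg.sum()
    lookup = {a: i for i, a in enumerate(alphabet)}

    raw = np.full(msa.length, np.nan)
    undefined = []
    for c in range(msa.length):
        col = arr[:, c]
        mask = ~np.isin(col, list(GAP_CHARS))
        if not mask.any():
            undefined.append(c)
            continue
        freq = np.full(len(alphabet), pseudocount)
        for ch, wi in zip(col[mask], w[mask]):
            freq[lookup[ch]] += wi
        freq /= freq.sum()
        nz = freq > 0
        raw[c] = float(np.sum(freq[nz] * np.log2(freq[nz] / bg[nz])))
    offset = float(np.nanmax(raw))
    rescaled = -raw + offset
    return ConservationProfile(raw=raw, rescaled=rescaled, offset=offset,
                               undefined=undefined)


# ---------------------------------------------------------------------------
# Coupling (MI-APC)
# ---------------------------------------------------------------------------

@dataclass
class CouplingResult:
    columns: list[int]             # alignment columns scored
    ref_residues: list[int | None]
    mi: np.ndarray                 # raw mutual information, bits
    mi_apc: np.ndarray             # APC-corrected
    ec_strength: np.ndarray        # per-column aggregate of top-L couplings
    excluded: list[int]            # columns dropped for excess gaps

    def strength_by_residue(self) -> dict[int, float]:
        return {r: float(s) for r, s in zip(self.ref_residues, self.ec_strength)
                if r is not None}

    def top_pairs(self, n: int) -> list[tuple[int, int, float]]:
        iu = np.triu_indices(len(self.columns), k=1)
        order = np.argsort(self.mi_apc[iu])[::-1][:n]
        return [(self.columns[iu[0][o]], self.columns[iu[1][o]],
                 float(self.mi_apc[iu][o])) for o in order]


def coupling_matrix(msa: Msa, window: tuple[int, int] | None = None,
                    pseudocount: float = 0.5, max_gap_fraction: float = 0.5,
                    ) -> CouplingResult:
    """MI-APC coupling matrix and per-residue coupling strength.

    ``window`` restricts the calculation to a reference-numbering range
    (requires the alignment's reference map).  Gaps count as an extra
    symbol; columns with more than ``max_gap_fraction`` gaps are excluded.
    ``pseudocount`` is added per joint-frequency cell.
    """
    if window is not None:
        cols = msa.columns_for_ref_range(*window)
    else:
        cols = list(range(msa.length))
    if len(cols) < 2:
        raise MsaError("window maps to fewer than 2 columns")
    if msa.n_seqs < 30:
        raise MsaError("need at least 30 rows for stable pair frequencies")

    arr = msa.array()[:, cols]
    w = henikoff_weights(arr)
    gapfrac = np.isin(arr, list(GAP_CHARS)).mean(axis=0)
    keep = gapfrac <= max_gap_fraction
    excluded = [c for c, k in zip(cols, keep) if not k]
    cols = [c for c, k in zip(cols, keep) if k]
    arr = arr[:, keep]
    n, L = arr.shape
    if L < 2:
        raise MsaError("all columns excluded for gaps")

    symbols = sorted({ch for row in arr for ch in row})
    q = len(symbols)
    lookup = {a: i for i, a in enumerate(symbols)}
    codes = np.vectorize(lookup.get)(arr)

    # weighted one-hot: (n, L*q)
    X = np.zeros((n, L * q))
    rows_idx = np.repeat(np.arange(n), L)
    cols_idx = (np.tile(np.arange(L), n) * q + codes.ravel())
    X[rows_idx, cols_idx] = 1.0
    counts = (X * w[:, None]).T @ X            # (L q, L q) weighted pair counts
    total_w = w.sum()

    mi = np.zeros((L, L))
    for i in range(L):
        Ci = counts[i * q:(i + 1) * q].reshape(q, L, q)  # (q, L, q)
        joint = Ci + pseudocount                          # per-cell pseudocount
        joint_sum = joint.sum(axis=(0, 2))                # per column j
        pj = joint / joint_sum[None, :, None]
        pa = pj.sum(axis=2)                               # (q, L)
        pb = pj.sum(axis=0)                               # (L, q)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = pj / (pa[:, :, None] * pb[None, :, :])
            term = np.where(pj > 0, pj * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
        mi[i] = term.sum(axis=(0, 2))
    mi = 0.5 * (mi + mi.T)
    np.fill_diagonal(mi, 0.0)

    # average product correction
    row_mean = mi.sum(axis=1) / (L - 1)
    overall = mi[np.triu_indices(L, 1)].mean() if L > 1 else 0.0
    apc = np.outer(row_mean, row_mean) / overall if overall > 0 else np.zeros_like(mi)
    mi_apc = mi - apc
    np.fill_diagonal(mi_apc, 0.0)

    # per-residue strength: share of the top-L couplings
    iu = np.triu_indices(L, 1)
    order = np.argsort(mi_apc[iu])[::-1][:L]
    strength = np.zeros(L)
    for o in order:
        i, j = iu[0][o], iu[1][o]
        v = mi_apc[i, j]
        if v > 0:
            strength[i] += v
            strength[j] += v

    ref_res = [msa.ref_map.get(c) for c in cols] if msa.ref_map else [None] * L
    return CouplingResult(columns=cols, ref_residues=ref_res, mi=mi,
                          mi_apc=mi_apc, ec_strength=strength,
                          excluded=excluded)


def pair_mutual_information(col_a, col_b, weights=None,
                            pseudocount: float = 0.0) -> float:
    """Mutual information (bits) between two symbol columns.

    With ``pseudocount=0`` this is the plug-in MI of the empirical joint;
    two perfectly coupled uniform binary columns give exactly 1 bit.
    """
    a = np.asarray(list(col_a))
    b = np.asarray(list(col_b))
    if len(a) != len(b):
        raise MsaError("columns differ in length")
    w = np.ones(len(a)) if weights is None else np.asarray(weights, float)
    sa, ia = np.unique(a, return_inverse=True)
    sb, ib = np.unique(b, return_inverse=True)
    joint = np.full((len(sa), len(sb)), float(pseudocount))
    np.add.at(joint, (ia, ib), w)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])))


# ---------------------------------------------------------------------------
# Selection and enrichment
# ---------------------------------------------------------------------------

def top_fraction(scores: dict[int, float], fraction: float) -> set[int]:
    """The floor(fraction x n) highest-scoring residues.

    Ties at the selection boundary are broken in favour of the lower
    residue number.
    """
    if not scores:
        raise MsaError("no scores supplied")
    if not 0 < fraction <= 1:
        raise MsaError("fraction must be in (0, 1]")
    k = int(np.floor(fraction * len(scores)))
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return {res for res, _ in ranked[:k]}


def contact_enrichment(selected: set[int], contact_residues: set[int],
                       n_total: int) -> dict:
    """Overlap of a selected residue set with known contact residues and
    the hypergeometric tail probability P(X >= overlap)."""
    if not all(1 <= r <= n_total for r in selected | contact_residues):
        raise MsaError("residue indices outside [1, n_total]")
    overlap = len(selected & contact_residues)
    p = float(hypergeom.sf(overlap - 1, n_total, len(contact_residues),
                           len(selected)))
    return {"n_total": n_total, "n_selected": len(selected),
            "n_contacts": len(contact_residues), "overlap": overlap,
            "p_tail": p}


def write_profile_tsv(msa: Msa, profile: ConservationProfile,
                      coupling: CouplingResult | None, path: str | Path) -> None:
    df = profile.to_frame(msa.ref_map or None)
    if coupling is not None:
        strength = {c: s for c, s in zip(coupling.columns, coupling.ec_strength)}
        df["ec_strength"] = [strength.get(c) for c in df["column"]]
        ranks = pd.Series(df["ec_strength"]).rank(ascending=False, method="min")
        df["ec_rank"] = ranks.astype("Int64")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
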