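"""Pentamer-based DNA shape prediction and shape-similarity scoring.

The model predicts four structural features of B-DNA from sequence alone,
using a lookup table over the 512 unique pentanucleotides (unique up to
reverse complement):

* **MGW** — minor groove width (Å) and **ProT** — propeller twist (degrees),
  both base-pair parameters assigned to the central base of the pentamer;
* **Roll** and **HelT** — helix twist (degrees), base-pair-*step* parameters;
  each pentamer carries a value for each of its two central steps.

Sliding the pentamer window over a sequence of length ``L`` defines MGW/ProT
at positions ``2 .. L-3`` (0-based) and Roll/HelT at steps ``1 .. L-3``; the
outermost positions/steps lack the full pentamer context and are reported as
missing (NaN), never silently zero.  Where two pentamer windows both cover a
step, their contributions are averaged, which keeps the profile continuous
and reverse-complement consistent.

Per-protein profiles average the predictions over an aligned set of binding
sites, and profiles are compared with the negative absolute Euclidean
distance, so that 0 means identical shape and more negative means more
different.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import DNA_BASES, all_kmers, canonical, check_acgt, pentamer_index, revcomp
from .matrices import SimilarityMatrix

logger = logging.getLogger(__name__)

#: base-pair parameters (defined per nucleotide position)
BP_PARAMS = ("mgw", "prot")
#: base-pair-step parameters (defined per dinucleotide step)
STEP_PARAMS = ("roll", "helt")
SHAPE_PARAMS = BP_PARAMS + STEP_PARAMS

_TSV_COLUMNS = ("pentamer", "MGW", "ProT", "Roll1", "Roll2", "HelT1", "HelT2")


@dataclass
class ShapeTable:
    """Pentamer -> shape-parameter lookup, mirror-filled over all 1024 ids.

    ``mgw``/``prot`` are length-1024 vectors indexed by pentamer id; ``roll``
    and ``helt`` are (1024, 2) arrays holding the values of the two central
    steps in the pentamer's own 5'->3' orientation.  The reverse complement of
    a pentamer carries the same MGW/ProT and the two step values in swapped
    order, so lookups need no run-time canonicalization.
    """

    mgw: np.ndarray
    prot: np.ndarray
    roll: np.ndarray
    helt: np.ndarray
    n_entries: int = 512

    def __post_init__(self) -> None:
        for name in ("mgw", "prot"):
            v = getattr(self, name)
            if v.shape != (1024,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} vector must be finite with shape (1024,)")
        for name in ("roll", "helt"):
            v = getattr(self, name)
            if v.shape != (1024, 2) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} array must be finite with shape (1024, 2)")
        if np.any(self.mgw <= 0):
            raise ValueError("MGW must be strictly positive for all pentamers")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, records: dict[str, dict]) -> "ShapeTable":
        """Build from ``{pentamer: {mgw, prot, roll: (r1, r2), helt: (h1, h2)}}``.

        Accepts either the canonical-512 form (one entry per revcomp pair) or
        the raw-1024 form; in the latter case revcomp consistency of the
        values is verified (MGW/ProT equal, step values swapped).
        """
        seen = set(records)
        missing = [p for p in all_kmers(5) if p not in seen and revcomp(p) not in seen]
        if missing:
            shown = ", ".join(missing[:10])
            more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
            raise ValueError(f"shape table is missing pentamers: {shown}{more}")

        mgw = np.full(1024, np.nan)
        prot = np.full(1024, np.nan)
        roll = np.full((1024, 2), np.nan)
        helt = np.full((1024, 2), np.nan)

        def _put(p: str, rec: dict) -> None:
            i = pentamer_index(p)
            vals = (
                float(rec["mgw"]),
                float(rec["prot"]),
                float(rec["roll"][0]),
                float(rec["roll"][1]),
                float(rec["helt"][0]),
                float(rec["helt"][1]),
            )
            if not all(np.isfinite(v) for v in vals):
                raise ValueError(f"non-finite shape value for pentamer {p}")
            mgw[i], prot[i] = vals[0], vals[1]
            roll[i] = vals[2], vals[3]
            helt[i] = vals[4], vals[5]

        for p, rec in records.items():
            if len(p) != 5 or any(b not in DNA_BASES for b in p):
                raise ValueError(f"invalid pentamer key: {p!r}")
            _put(p, rec)

        # mirror or verify the reverse complements
        for p in list(records):
            rc = revcomp(p)
            i, j = pentamer_index(p), pentamer_index(rc)
            if rc in records:
                ok = (
                    np.isclose(mgw[i], mgw[j])
                    and np.isclose(prot[i], prot[j])
                    and np.allclose(roll[i], roll[j][::-1])
                    and np.allclose(helt[i], helt[j][::-1])
                )
                if not ok:
                    raise ValueError(
                        f"reverse-complement inconsistency between {p} and {rc}: "
                        "MGW/ProT must match and step values must be swapped"
                    )
            else:
                mgw[j], prot[j] = mgw[i], prot[i]
                roll[j] = roll[i][::-1]
                helt[j] = helt[i][::-1]

        return cls(mgw=mgw, prot=prot, roll=roll, helt=helt, n_entries=512)

    # -- access -------------------------------------------------------------

    def lookup(self, pentamer: str) -> dict:
        check_acgt(pentamer, "pentamer")
        if len(pentamer) != 5:
            raise ValueError("pentamer must have length 5")
        i = pentamer_index(pentamer)
        return {
            "mgw": float(self.mgw[i]),
            "prot": float(self.prot[i]),
            "roll": tuple(self.roll[i]),
            "helt": tuple(self.helt[i]),
        }

    def parameter_range(self, parameter: str) -> tuple[float, float]:
        v = getattr(self, parameter)
        return float(np.min(v)), float(np.max(v))

    def parameter_mean(self, parameter: str) -> float:
        """Unweighted mean over all pentamers (used for flank fill values)."""
        return float(np.mean(getattr(self, parameter)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in sorted({canonical(m) for m in all_kmers(5)}):
            i = pentamer_index(p)
            rows.append(
                (p, self.mgw[i], self.prot[i], *self.roll[i], *self.helt[i])
            )
        return pd.DataFrame(rows, columns=list(_TSV_COLUMNS))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_shape_table(path: str | Path) -> ShapeTable:
    """Read a pentamer shape table from TSV.

    Expected columns: ``pentamer, MGW, ProT, Roll1, Roll2, HelT1, HelT2``
    (case-insensitive).  Both the canonical-512 and the raw-1024 dialect are
    accepted; the loader verifies completeness, finiteness and
    reverse-complement consistency.
    """
    df = pd.read_csv(path, sep="\t")
    colmap = {c.lower(): c for c in df.columns}
    missing_cols = [c for c in _TSV_COLUMNS if c.lower() not in colmap]
    if missing_cols:
        raise ValueError(f"shape table {path} lacks columns: {missing_cols}")
    records = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        p = str(d[colmap["pentamer"]]).upper()
        if p in records:
            raise ValueError(f"duplicate pentamer row: {p}")
        records[p] = {
            "mgw": d[colmap["mgw"]],
            "prot": d[colmap["prot"]],
            "roll": (d[colmap["roll1"]], d[colmap["roll2"]]),
            "helt": (d[colmap["helt1"]], d[colmap["helt2"]]),
        }
    if len(records) not in (512, 1024):
        logger.warning(
            "shape table %s has %d rows (expected 512 canonical or 1024 raw)",
            path,
            len(records),
        )
    return ShapeTable.from_records(records)


# ---------------------------------------------------------------------------
# prediction


def predict_shape(seq: str, table: ShapeTable) -> dict[str, np.ndarray]:
    """Predict the four shape parameters along ``seq``.

    Returns ``{"mgw": (L,), "prot": (L,), "roll": (L-1,), "helt": (L-1,)}``
    with NaN wherever the pentamer context is incomplete: base-pair
    parameters at the two outermost positions on each side, step parameters
    at the outermost step on each side.
    """
    check_acgt(seq, "sequence")
    L = len(seq)
    if L < 5:
        raise ValueError(f"sequence length {L} < 5: no pentamer window fits")

    mgw = np.full(L, np.nan)
    prot = np.full(L, np.nan)
    step_sum = {p: np.zeros(L - 1) for p in STEP_PARAMS}
    step_cnt = np.zeros(L - 1, dtype=int)

    for i in range(2, L - 2):
        idx = pentamer_index(seq[i - 2 : i + 3])
        mgw[i] = table.mgw[idx]
        prot[i] = table.prot[idx]
        # central steps of this pentamer: (i-1, i) and (i, i+1)
        step_sum["roll"][i - 1] += table.roll[idx, 0]
        step_sum["roll"][i] += table.roll[idx, 1]
        step_sum["helt"][i - 1] += table.helt[idx, 0]
        step_sum["helt"][i] += table.helt[idx, 1]
        step_cnt[i - 1] += 1
        step_cnt[i] += 1

    out = {"mgw": mgw, "prot": prot}
    with np.errstate(invalid="ignore"):
        for p in STEP_PARAMS:
            vals = np.full(L - 1, np.nan)
            covered = step_cnt > 0
            vals[covered] = step_sum[p][covered] / step_cnt[covered]
            out[p] = vals
    return out


# ---------------------------------------------------------------------------
# profiles


@dataclass
class ShapeProfile:
    """Per-position average shape over a protein's aligned binding sites."""

    protein_id: str
    length: int
    mgw: np.ndarray
    prot: np.ndarray
    roll: np.ndarray
    helt: np.ndarray
    n_sites: int
    coverage: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in BP_PARAMS:
            if getattr(self, p).shape != (self.length,):
                raise ValueError(f"{p} vector must have length {self.length}")
        for p in STEP_PARAMS:
            if getattr(self, p).shape != (self.length - 1,):
                raise ValueError(f"{p} vector must have length {self.length - 1}")

    def vector(self, parameter: str) -> np.ndarray:
        if parameter not in SHAPE_PARAMS:
            raise KeyError(f"unknown shape parameter {parameter!r}")
        return getattr(self, parameter)

    def validate_against(self, table: ShapeTable) -> None:
        """Check every finite value lies within the table range for its parameter."""
        for p in SHAPE_PARAMS:
            lo, hi = table.parameter_range(p)
            v = self.vector(p)
            fin = v[np.isfinite(v)]
            if fin.size and (fin.min() < lo - 1e-9 or fin.max() > hi + 1e-9):
                raise ValueError(
                    f"profile {self.protein_id}: {p} values escape table range "
                    f"[{lo:.3g}, {hi:.3g}]"
                )


def _iter_placed(sites) -> list[tuple[str, int]]:
    """Normalize site input to ``[(oriented_sequence, frame_offset), ...]``."""
    if hasattr(sites, "iter_placed"):  # BindingSiteSet duck type
        return list(sites.iter_placed())
    out = []
    for s in sites:
        if isinstance(s, str):
            out.append((s, 0))
        else:
            seq, off = s
            out.append((seq, int(off)))
    return out


def average_shape_profile(
    sites, table: ShapeTable, *, frame_width: int | None = None, protein_id: str = ""
) -> ShapeProfile:
    """Average per-position shape over a set of aligned binding sites.

    ``sites`` may be a :class:`shapecov.motifs.BindingSiteSet`, a list of
    equal-width sequences (implicitly at offset 0), or ``(sequence, offset)``
    pairs on a common frame.  The mean at each position is taken over the
    sites that have a *defined* value there; uncovered positions stay NaN.
    """
    placed = _iter_placed(sites)
    if not placed:
        raise ValueError("empty site set: cannot build a shape profile")
    if frame_width is None:
        if hasattr(sites, "frame_width"):
            frame_width = sites.frame_width
        else:
            widths = {len(s) + off for s, off in placed}
            starts = {off for _, off in placed}
            if len(widths) > 1 or min(starts) < 0:
                raise ValueError(
                    "sites have mismatched widths/offsets; pass frame_width explicitly"
                )
            frame_width = max(widths)
    if not protein_id and hasattr(sites, "protein_id"):
        protein_id = sites.protein_id
    W = int(frame_width)

    sums = {p: np.zeros(W if p in BP_PARAMS else W - 1) for p in SHAPE_PARAMS}
    cnts = {p: np.zeros(W if p in BP_PARAMS else W - 1, dtype=int) for p in SHAPE_PARAMS}

    for seq, off in placed:
        pred = predict_shape(seq, table)
        for p in SHAPE_PARAMS:
            v = pred[p]
            # site position j maps to frame position off + j (steps likewise)
            for j, val in enumerate(v):
                col = off + j
                if np.isfinite(val) and 0 <= col < len(sums[p]):
                    sums[p][col] += val
                    cnts[p][col] += 1

    means = {}
    for p in SHAPE_PARAMS:
        m = np.full_like(sums[p], np.nan)
        cov = cnts[p] > 0
        m[cov] = sums[p][cov] / cnts[p][cov]
        means[p] = m

    profile = ShapeProfile(
        protein_id=protein_id,
        length=W,
        mgw=means["mgw"],
        prot=means["prot"],
        roll=means["roll"],
        helt=means["helt"],
        n_sites=len(placed),
        coverage={p: cnts[p] for p in SHAPE_PARAMS},
    )
    profile.validate_against(table)
    return profile


# ---------------------------------------------------------------------------
# similarity


def shape_similarity(profiles: list[ShapeProfile], parameter: str) -> SimilarityMatrix:
    """Pairwise −|Euclidean distance| between one shape parameter's vectors.

    Positions missing in *any* profile are dropped from all of them (the
    number dropped is logged), so every pair is compared over the same
    coordinates.  0 means a perfect match; values are never positive.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles for a similarity matrix")
    vecs = np.vstack([p.vector(parameter) for p in profiles])
    keep = np.all(np.isfinite(vecs), axis=0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "shape_similarity(%s): dropped %d position(s) missing in some profile",
            parameter,
            dropped,
        )
    if not keep.any():
        raise ValueError(f"no position has {parameter} defined in every profile")
    vecs = vecs[:, keep]
    from scipy.spatial.distance import pdist, squareform

    values = -squareform(pdist(vecs, metric="euclidean"))
    labels = [p.protein_id for p in profiles]
    return SimilarityMatrix(
        labels, values, f"shape_{parameter}", meta={"positions_used": int(keep.sum())}
    )
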