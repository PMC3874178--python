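"""Align selected 8-mers to the degenerate homeodomain core and build PFMs.

Homeodomain binding sites from universal protein-binding microarrays arrive
as 8-mers with E-scores in [−0.5, 0.5]; 8-mers with E-score ≥ 0.45 are
conventionally "bound".  The bound 8-mers of one protein are aligned to the
degenerate core consensus NNA(Y/K)N (Y = C/T, K = G/T) on either strand, the
consensus window is anchored at fixed frame columns, and the placed sites are
summarized as a position frequency matrix (PFM).  DNA-sequence similarity
between two proteins is the Pearson correlation of their flattened PFMs.

When an 8-mer matches the consensus at more than one offset/strand, the
placement is disambiguated against a reference PFM if one is supplied;
otherwise a self-contained two-pass scheme is used: pass 1 places the
unambiguous 8-mers and builds a provisional PFM, pass 2 resolves the
ambiguous placements (and the Y-vs-K variant choice) by log-likelihood
against it.  This iterative scheme is a stand-in for disambiguation against
previously published matrices, which requires external data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import DNA_BASES, canonical, check_acgt, matches_pattern, revcomp
from .matrices import SimilarityMatrix

logger = logging.getLogger(__name__)

CORE_PATTERNS = {"NNAYN": "NNAYN", "NNAKN": "NNAKN"}
#: frame column (0-based) where the first consensus position sits; with an
#: 8-wide frame this puts the pattern at frame columns 1–5 (positions 2–6 in
#: the 1-based numbering used in reports)
DEFAULT_ANCHOR = 1
DEFAULT_FRAME_WIDTH = 8
ESCORE_THRESHOLD = 0.45
_PSEUDO = 0.01  # PFM pseudo-frequency for log-likelihood scoring


@dataclass
class Site:
    """One placed binding site in the common frame.

    ``oriented`` is the site sequence in frame orientation (the raw k-mer if
    ``strand`` is '+', its reverse complement if '−'); ``offset`` is the frame
    column of its first base and may be negative (overhanging bases exist but
    fall outside the frame).
    """

    kmer: str
    oriented: str
    strand: str
    offset: int
    escore: float | None = None

    def __post_init__(self) -> None:
        expected = self.kmer if self.strand == "+" else revcomp(self.kmer)
        if self.oriented != expected:
            raise ValueError(
                f"strand/offset round-trip failed for {self.kmer}: "
                f"{self.strand!r} placement should read {expected}"
            )

    def in_frame(self, frame_width: int):
        """(frame_start, subsequence) clipped to [0, frame_width)."""
        lo = max(0, self.offset)
        hi = min(frame_width, self.offset + len(self.oriented))
        return lo, self.oriented[lo - self.offset : hi - self.offset]


@dataclass
class BindingSiteSet:
    protein_id: str
    sites: list[Site]
    frame_width: int = DEFAULT_FRAME_WIDTH
    motif_variant: str = "NNAYN"
    anchor: int = DEFAULT_ANCHOR
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for s in self.sites:
            lo, sub = s.in_frame(self.frame_width)
            if not sub:
                raise ValueError(
                    f"site {s.kmer} at offset {s.offset} falls entirely outside "
                    f"the {self.frame_width}-wide frame"
                )

    def __len__(self) -> int:
        return len(self.sites)

    def iter_placed(self):
        """Yield (oriented sequence, frame offset) pairs, un-clipped.

        Overhanging bases are kept: they provide real pentamer context for
        shape prediction even though they fall outside the frame columns.
        """
        for s in self.sites:
            yield s.oriented, s.offset


@dataclass
class PFM:
    """Column-normalized base frequencies on the alignment frame."""

    protein_id: str
    matrix: np.ndarray  # (frame_width, 4), rows sum to 1
    n_sites: int
    counts: np.ndarray | None = None  # per-column effective site counts

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PFM matrix must be (frame_width, 4)")
        if np.any(self.matrix < 0):
            raise ValueError("PFM entries must be nonnegative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("every PFM column must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def loglik(self, oriented: str, offset: int) -> float:
        """Mean per-column log-likelihood of a placed site under this PFM."""
        total, ncols = 0.0, 0
        for j, b in enumerate(oriented):
            col = offset + j
            if 0 <= col < self.width:
                p = self.matrix[col, DNA_BASES.index(b)]
                total += math.log(p * (1 - 4 * _PSEUDO) + _PSEUDO)
                ncols += 1
        if ncols == 0:
            return -math.inf
        return total / ncols


# ---------------------------------------------------------------------------
# selection


def select_8mers(escore_table, threshold: float = ESCORE_THRESHOLD) -> list[str]:
    """All 8-mers with E-score ≥ threshold, collapsed to one strand representative.

    When both an 8-mer and its reverse complement appear in the table the
    lexicographically smaller sequence represents the pair (it is kept if
    either member passes the threshold).
    """
    best: dict[str, float] = {}
    for kmer, e in dict(escore_table).items():
        kmer = kmer.upper()
        check_acgt(kmer, "8-mer")
        if len(kmer) != 8:
            raise ValueError(f"expected 8-mers, got {kmer!r}")
        rep = canonical(kmer)
        e = float(e)
        if rep not in best or e > best[rep]:
            best[rep] = e
    selected = sorted(rep for rep, e in best.items() if e >= threshold)
    if not selected:
        raise ValueError(
            f"no 8-mer reaches E-score {threshold}; review the threshold or input"
        )
    return selected


# ---------------------------------------------------------------------------
# alignment to the core consensus


def candidate_placements(kmer: str, variant: str, anchor: int = DEFAULT_ANCHOR):
    """All (strand, oriented, offset) placements matching the consensus."""
    pattern = CORE_PATTERNS[variant]
    k = len(pattern)
    out = []
    for strand, oriented in (("+", kmer), ("-", revcomp(kmer))):
        if strand == "-" and oriented == kmer:
            continue  # palindromic k-mer: the two strands are the same placement set
        for w in range(len(kmer) - k + 1):
            if matches_pattern(oriented[w : w + k], pattern):
                out.append((strand, oriented, anchor - w))
    return out


def _pick_placement(cands, ref: PFM | None):
    """Best placement by reference log-likelihood; deterministic tie-break.

    Ties are broken in favour of the leftmost plus-strand placement (callers
    canonicalize k-mers first, so '+' refers to the canonical orientation and
    the choice is strand-symmetric in the original input).
    """
    def sortkey(c):
        strand, _oriented, offset = c
        return (strand != "+", -offset)  # '+' first, then leftmost window (largest offset = smallest w)

    ordered = sorted(cands, key=sortkey)
    if ref is None or len(ordered) == 1:
        return ordered[0]
    scored = [(ref.loglik(o, off), i) for i, (s, o, off) in enumerate(ordered)]
    best = max(scored, key=lambda t: (t[0], -t[1]))
    return ordered[best[1]]


def _place_all(kmers, variant, ref, escores, anchor, frame_width):
    sites, dropped = [], 0
    for kmer in kmers:
        cands = candidate_placements(kmer, variant, anchor)
        if not cands:
            dropped += 1
            continue
        strand, oriented, offset = _pick_placement(cands, ref)
        sites.append(
            Site(
                kmer=kmer,
                oriented=oriented,
                strand=strand,
                offset=offset,
                escore=None if escores is None else escores.get(kmer),
            )
        )
    return sites, dropped


def align_to_consensus(
    kmers,
    motif_variant: str | None = None,
    reference_pfm: PFM | None = None,
    escores=None,
    anchor: int = DEFAULT_ANCHOR,
    frame_width: int = DEFAULT_FRAME_WIDTH,
    protein_id: str = "",
) -> BindingSiteSet:
    """Place 8-mers on the frame so the core consensus sits at fixed columns.

    ``motif_variant`` may be "NNAYN", "NNAKN", or None to let the two-pass
    scheme choose the variant with the higher placement count and total
    log-likelihood.  8-mers matching on neither strand are dropped (counted in
    ``n_dropped``).
    """
    kmers = [canonical(k.upper()) for k in kmers]
    for k in kmers:
        check_acgt(k, "k-mer")
    if escores is not None:
        escores = {canonical(k.upper()): float(v) for k, v in dict(escores).items()}

    variants = [motif_variant] if motif_variant else list(CORE_PATTERNS)
    results = {}
    for variant in variants:
        if reference_pfm is not None:
            sites, dropped = _place_all(
                kmers, variant, reference_pfm, escores, anchor, frame_width
            )
        else:
            # pass 1: unambiguous placements -> provisional PFM
            unambiguous = [
                k for k in kmers if len(candidate_placements(k, variant, anchor)) == 1
            ]
            seed_kmers = unambiguous if unambiguous else kmers
            seed_sites, _ = _place_all(
                seed_kmers, variant, None, escores, anchor, frame_width
            )
            provisional = None
            if seed_sites:
                try:
                    provisional = build_pfm(
                        BindingSiteSet(
                            protein_id or "provisional",
                            seed_sites,
                            frame_width,
                            variant,
                            anchor,
                        )
                    )
                except ValueError:
                    provisional = None
            # pass 2: resolve everything against the provisional PFM
            sites, dropped = _place_all(
                kmers, variant, provisional, escores, anchor, frame_width
            )
        results[variant] = (sites, dropped)

    def variant_score(variant):
        sites, _ = results[variant]
        if not sites:
            return (0, -math.inf)
        try:
            pfm = build_pfm(
                BindingSiteSet(
                    protein_id or "tmp", sites, frame_width, variant, anchor
                )
            )
        except ValueError:
            return (len(sites), -math.inf)
        total = sum(pfm.loglik(s.oriented, s.offset) for s in sites)
        return (len(sites), total / len(sites))

    chosen = max(variants, key=lambda v: (variant_score(v), v == "NNAYN"))
    sites, dropped = results[chosen]
    if not sites:
        raise ValueError(
            "no 8-mer matches the core consensus on either strand "
            f"(tried {', '.join(variants)})"
        )
    if dropped:
        logger.info(
            "align_to_consensus(%s, %s): dropped %d unalignable k-mer(s)",
            protein_id,
            chosen,
            dropped,
        )
    return BindingSiteSet(
        protein_id=protein_id,
        sites=sites,
        frame_width=frame_width,
        motif_variant=chosen,
        anchor=anchor,
        n_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# PFMs


def build_pfm(siteset: BindingSiteSet) -> PFM:
    """Column-normalized base counts over the placed sites.

    Bases outside a site's span contribute nothing to that column; a column
    covered by no site at all means the frame is too wide for the data and is
    an error.
    """
    if not siteset.sites:
        raise ValueError("cannot build a PFM from an empty site set")
    W = siteset.frame_width
    counts = np.zeros((W, 4))
    for s in siteset.sites:
        lo, sub = s.in_frame(W)
        for j, b in enumerate(sub):
            counts[lo + j, DNA_BASES.index(b)] += 1
    coverage = counts.sum(axis=1)
    empty = np.flatnonzero(coverage == 0)
    if empty.size:
        raise ValueError(
            f"frame column(s) {empty.tolist()} have zero coverage: frame too wide"
        )
    matrix = counts / coverage[:, None]
    return PFM(
        protein_id=siteset.protein_id,
        matrix=matrix,
        n_sites=len(siteset.sites),
        counts=coverage,
    )


def pfm_similarity(pfms: list[PFM]) -> SimilarityMatrix:
    """Pearson correlation between flattened PFMs; 1 means identical matrices."""
    if len(pfms) < 2:
        raise ValueError("need at least two PFMs")
    widths = {p.width for p in pfms}
    if len(widths) > 1:
        raise ValueError(f"PFMs have unequal widths: {sorted(widths)}")
    flat = np.vstack([p.matrix.ravel() for p in pfms])
    sd = flat.std(axis=1)
    for p, s in zip(pfms, sd):
        if s == 0:
            raise ValueError(
                f"PFM for {p.protein_id} is uniform: Pearson similarity undefined"
            )
    values = np.corrcoef(flat)
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix([p.protein_id for p in pfms], values, "dna_pfm_pcc")
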