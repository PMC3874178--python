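"""Covariation between protein sequence and binding-site sequence/shape.

Two levels of analysis:

* **Matrix level** — the Pearson correlation between the upper triangles of
  a protein similarity matrix and a DNA sequence/shape similarity matrix,
  with an empirical null built by shuffling the label-to-sequence assignment,
  and a binned variant that equalizes the PFM-score distribution before
  correlating.

* **Position level** — for each (protein alignment column, DNA position)
  pair: an upper-tail cumulative hypergeometric p-value for the co-occurrence
  of basic residues (R/K/H, which can carry a positive charge and read the
  enhanced electrostatic potential of a narrow minor groove) with a narrow
  minor groove call, and a mutual-information score (bits) between the residue
  identity and the binary narrow/not-narrow call.  "Narrow" means a mean MGW
  at or below a threshold (5.12 Å by default, a cohort-average convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrices import SimilarityMatrix
from .protein import GAP, ProteinCohort, SubstitutionMatrix, protein_similarity
from .shape import ShapeProfile

logger = logging.getLogger(__name__)

BASIC_RESIDUES = frozenset("RKH")
NARROW_MGW_THRESHOLD = 5.12  # Å
SENSITIVITY_THRESHOLDS = (4.9, 5.0, 5.1, 5.2)
DEFAULT_BIN_EDGES = (0.0, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
WILCOXON_ALPHA = 5e-5


# ---------------------------------------------------------------------------
# matrix-level correlation


def matrix_pcc(a: SimilarityMatrix, b: SimilarityMatrix) -> dict:
    """Pearson correlation between two similarity matrices' upper triangles.

    The diagonal is excluded (self-similarities are trivially maximal).
    Returns ``{"pcc", "p", "n_pairs"}`` with a two-sided p-value from the
    t-approximation.
    """
    if a.labels != b.labels:
        raise ValueError("similarity matrices must share labels and ordering")
    x, y = a.upper_triangle(), b.upper_triangle()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a similarity triangle: PCC undefined")
    r = stats.pearsonr(x, y)
    return {"pcc": float(r.statistic), "p": float(r.pvalue), "n_pairs": int(x.size)}


@dataclass
class ShuffleNull:
    observed: float
    distribution: np.ndarray
    mean: float
    p_empirical: float
    n_shuffles: int

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.distribution, q))


def shuffle_null(
    cohort: ProteinCohort,
    other: SimilarityMatrix,
    matrix: SubstitutionMatrix,
    n_shuffles: int = 1000,
    seed: int | None = None,
    region: str | None = None,
    protein_sim: SimilarityMatrix | None = None,
) -> ShuffleNull:
    """Empirical null for the matrix-level PCC by shuffling protein identities.

    Each shuffle permutes the label-to-sequence assignment and recomputes the
    protein similarity; because BLOSUM pair scores depend only on the two
    sequences, that recomputation equals conjugating the observed similarity
    matrix by the permutation (``P S P^T``), which is what is evaluated here.
    The empirical two-sided p-value is ``(r + 1) / (n + 1)`` with ``r`` the
    number of null values at least as extreme as the observation.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if protein_sim is None:
        protein_sim = protein_similarity(cohort, matrix, region=region)
    observed = matrix_pcc(protein_sim, other)["pcc"]
    rng = np.random.default_rng(seed)
    n = protein_sim.n
    y = other.upper_triangle()
    iu = np.triu_indices(n, k=1)
    S = protein_sim.values
    null = np.empty(n_shuffles)
    for t in range(n_shuffles):
        perm = rng.permutation(n)
        x = S[np.ix_(perm, perm)][iu]
        ok = np.isfinite(x) & np.isfinite(y)
        null[t] = np.corrcoef(x[ok], y[ok])[0, 1]
    r = int(np.sum(np.abs(null) >= abs(observed)))
    return ShuffleNull(
        observed=observed,
        distribution=null,
        mean=float(null.mean()),
        p_empirical=(r + 1) / (n_shuffles + 1),
        n_shuffles=n_shuffles,
    )


def binned_pcc(
    a: SimilarityMatrix,
    b: SimilarityMatrix,
    bin_edges=DEFAULT_BIN_EDGES,
    n_per_bin: int = 300,
    seed: int | None = None,
) -> dict:
    """Matrix PCC after equalizing the distribution of ``b``'s pair scores.

    Pairs are binned by their value in ``b`` (PFM-score bins by default);
    ``n_per_bin`` pairs are drawn uniformly without replacement from each
    nonempty bin (short bins contribute everything they have) and the PCC is
    computed on the union.  Pairs falling outside every bin are ignored.
    """
    if a.labels != b.labels:
        raise ValueError("similarity matrices must share labels and ordering")
    x, y = a.upper_triangle(), b.upper_triangle()
    edges = np.asarray(bin_edges, dtype=float)
    rng = np.random.default_rng(seed)
    chosen = []
    n_bins_used = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        in_bin = (y >= lo) & ((y <= hi) if last else (y < hi)) & np.isfinite(x)
        idx = np.flatnonzero(in_bin)
        if idx.size == 0:
            continue
        n_bins_used += 1
        if idx.size > n_per_bin:
            idx = rng.choice(idx, size=n_per_bin, replace=False)
        else:
            logger.info(
                "binned_pcc: bin [%g, %g%s takes all %d pairs (< %d requested)",
                lo,
                hi,
                "]" if last else ")",
                idx.size,
                n_per_bin,
            )
        chosen.append(idx)
    if not chosen:
        raise ValueError("all bins are empty on the given binning scale")
    sel = np.concatenate(chosen)
    r = stats.pearsonr(x[sel], y[sel])
    return {
        "pcc": float(r.statistic),
        "p": float(r.pvalue),
        "n_pairs": int(sel.size),
        "n_bins_used": n_bins_used,
    }


# ---------------------------------------------------------------------------
# narrow minor groove calls


@dataclass
class NarrowGrooveCall:
    """Boolean narrow-MGW calls per (protein, DNA position); NaN = undefined."""

    labels: list[str]
    calls: np.ndarray  # (n_proteins, length) of {0.0, 1.0, NaN}
    threshold: float

    @property
    def length(self) -> int:
        return self.calls.shape[1]

    def defined(self) -> np.ndarray:
        return np.isfinite(self.calls)


def call_narrow_minor_groove(
    profiles: list[ShapeProfile], threshold: float = NARROW_MGW_THRESHOLD
) -> NarrowGrooveCall:
    """Call a narrow minor groove wherever the mean MGW is ≤ ``threshold`` Å.

    The call is made on each protein's *average* MGW profile (the same
    feature vector used for shape similarity), with the threshold inclusive.
    """
    mgw = np.vstack([p.mgw for p in profiles])
    calls = np.where(np.isfinite(mgw), (mgw <= threshold).astype(float), np.nan)
    return NarrowGrooveCall(
        labels=[p.protein_id for p in profiles], calls=calls, threshold=threshold
    )


# ---------------------------------------------------------------------------
# position-level maps


@dataclass
class CovariationMaps:
    """(protein column × DNA position) hypergeometric p-values and MI scores."""

    protein_columns: list[int]
    dna_positions: list[int]
    hypergeom_p: np.ndarray | None = None
    neglog10_p: np.ndarray | None = None
    mi: np.ndarray | None = None
    degenerate: np.ndarray | None = None
    narrow_threshold: float = NARROW_MGW_THRESHOLD
    meta: dict = field(default_factory=dict)

    def argmax_cell(self, which: str = "neglog10_p") -> tuple[int, int]:
        """(protein column, DNA position) of the strongest signal."""
        m = getattr(self, which)
        if m is None:
            raise ValueError(f"map {which!r} was not computed")
        flat = np.where(np.isfinite(m), m, -np.inf)
        i, j = np.unravel_index(int(np.argmax(flat)), m.shape)
        return self.protein_columns[i], self.dna_positions[j]


def _check_shared_ids(cohort: ProteinCohort, calls: NarrowGrooveCall) -> None:
    if list(cohort.ids) != list(calls.labels):
        raise ValueError("cohort and narrow-groove calls must share protein ids")


def hypergeom_upper_tail(k: int, N: int, s: int, m: int) -> float:
    """P(K >= k) for the overlap of an s-subset and an m-subset of N items.

    Monotone non-increasing in k at fixed (N, s, m); equals 1 whenever k is
    at or below the guaranteed overlap max(0, s + m - N).
    """
    if not (0 <= s <= N and 0 <= m <= N):
        raise ValueError("need 0 <= s, m <= N")
    return float(stats.hypergeom.sf(k - 1, N, s, m))


def hypergeometric_map(
    cohort: ProteinCohort,
    calls: NarrowGrooveCall,
    basic_set=BASIC_RESIDUES,
) -> CovariationMaps:
    """Upper-tail hypergeometric p-values for basic-residue / narrow-groove overlap.

    For each protein alignment column and DNA position, with ``N`` proteins
    having a defined call at the position, ``s`` of them carrying a basic
    residue at the column, ``m`` with a narrow call, and ``k`` the overlap,
    the p-value is ``P(K >= k)`` under sampling without replacement.  Cells
    with ``s = 0`` or ``m = 0`` are recorded as p = 1 with a degenerate flag.
    """
    _check_shared_ids(cohort, calls)
    basic_set = frozenset(basic_set)
    n_cols, L = cohort.n_columns, calls.length
    pvals = np.ones((n_cols, L))
    degenerate = np.zeros((n_cols, L), dtype=bool)
    is_basic = np.array(
        [[row[c] in basic_set for c in range(n_cols)] for row in cohort.msa]
    )
    defined = calls.defined()
    narrow = calls.calls == 1.0
    for j in range(L):
        dj = defined[:, j]
        N = int(dj.sum())
        if N == 0:
            degenerate[:, j] = True
            continue
        m = int(narrow[dj, j].sum())
        for c in range(n_cols):
            s = int(is_basic[dj, c].sum())
            if s == 0 or m == 0:
                degenerate[c, j] = True
                continue
            k = int((is_basic[:, c] & narrow[:, j] & dj).sum())
            pvals[c, j] = hypergeom_upper_tail(k, N, s, m)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return CovariationMaps(
        protein_columns=list(range(n_cols)),
        dna_positions=list(range(L)),
        hypergeom_p=pvals,
        neglog10_p=-np.log10(pvals),
        degenerate=degenerate,
        narrow_threshold=calls.threshold,
    )


def _mi_bits(joint: np.ndarray) -> float:
    """Plug-in mutual information (bits) from a joint count table."""
    total = joint.sum()
    if total == 0:
        return 0.0
    p = joint / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def mi_map(
    cohort: ProteinCohort,
    calls: NarrowGrooveCall,
    alphabet: str = "full",
) -> CovariationMaps:
    """Mutual information (bits) between residue identity and the groove call.

    ``alphabet="full"`` uses the complete residue alphabet (plus gap) at the
    column; ``alphabet="basic"`` collapses residues to basic/non-basic for
    comparison.  Probabilities are plug-in frequencies; ``0·log 0 ≡ 0``.
    """
    _check_shared_ids(cohort, calls)
    if alphabet not in ("full", "basic"):
        raise ValueError("alphabet must be 'full' or 'basic'")
    n_cols, L = cohort.n_columns, calls.length
    mi = np.zeros((n_cols, L))
    defined = calls.defined()
    narrow = calls.calls == 1.0
    for c in range(n_cols):
        col = cohort.column(c)
        if alphabet == "basic":
            symbols = ["+" if r in BASIC_RESIDUES else "o" for r in col]
        else:
            symbols = col
        levels = sorted(set(symbols))
        sym_idx = np.array([levels.index(s) for s in symbols])
        for j in range(L):
            dj = defined[:, j]
            if not dj.any():
                continue
            joint = np.zeros((len(levels), 2))
            np.add.at(joint, (sym_idx[dj], narrow[dj, j].astype(int)), 1)
            mi[c, j] = _mi_bits(joint)
    return CovariationMaps(
        protein_columns=list(range(n_cols)),
        dna_positions=list(range(L)),
        mi=mi,
        narrow_threshold=calls.threshold,
    )


def covariation_maps(
    cohort: ProteinCohort,
    calls: NarrowGrooveCall,
    basic_set=BASIC_RESIDUES,
    alphabet: str = "full",
) -> CovariationMaps:
    """Both maps on one grid (convenience wrapper)."""
    h = hypergeometric_map(cohort, calls, basic_set)
    m = mi_map(cohort, calls, alphabet)
    h.mi = m.mi
    return h


# ---------------------------------------------------------------------------
# residue-grouped MGW profiles


@dataclass
class GrooveClassProfiles:
    column: int
    classes: dict[str, np.ndarray]  # class -> positionwise mean MGW
    n_members: dict[str, int]
    pvalues: dict[str, np.ndarray]  # basic class vs "other", per position
    significant: dict[str, np.ndarray]  # p < alpha flags
    alpha: float
    tests_skipped: list[str] = field(default_factory=list)


def _nanmean_columns(a: np.ndarray) -> np.ndarray:
    """Column means ignoring NaN; NaN (not a warning) for all-NaN columns."""
    finite = np.isfinite(a)
    cnt = finite.sum(axis=0)
    total = np.where(finite, a, 0.0).sum(axis=0)
    out = np.full(a.shape[1], np.nan)
    np.divide(total, cnt, out=out, where=cnt > 0)
    return out


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small tie-free samples."""
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        return np.nan
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and not ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def groove_profiles_by_residue(
    cohort: ProteinCohort,
    profiles: list[ShapeProfile],
    column: int,
    alpha: float = WILCOXON_ALPHA,
) -> GrooveClassProfiles:
    """Group proteins by the residue class at ``column`` and compare MGW curves.

    Classes are R, K, H and "other" (everything without a positive charge).
    Per position, each basic class with ≥ 2 members is compared against
    "other" with a two-sided Wilcoxon rank-sum test; positions with
    p < ``alpha`` are flagged.
    """
    if list(cohort.ids) != [p.protein_id for p in profiles]:
        raise ValueError("cohort and profiles must list the same proteins in order")
    col = cohort.column(column)
    groups: dict[str, list[int]] = {"R": [], "K": [], "H": [], "other": []}
    for i, r in enumerate(col):
        groups[r if r in ("R", "K", "H") else "other"].append(i)
    mgw = np.vstack([p.mgw for p in profiles])

    classes, n_members = {}, {}
    for name, idx in groups.items():
        if not idx:
            continue
        n_members[name] = len(idx)
        classes[name] = _nanmean_columns(mgw[idx])

    nonempty = [g for g in groups.values() if g]
    if len(nonempty) < 2:
        return GrooveClassProfiles(
            column=column,
            classes=classes,
            n_members=n_members,
            pvalues={},
            significant={},
            alpha=alpha,
            tests_skipped=["single residue class: nothing to compare"],
        )

    L = mgw.shape[1]
    pvalues, significant, skipped = {}, {}, []
    other_idx = groups["other"]
    for name in ("R", "K", "H"):
        idx = groups[name]
        if name not in classes:
            continue
        if len(idx) < 2 or len(other_idx) < 2:
            skipped.append(f"{name}: fewer than 2 members in a compared class")
            continue
        pv = np.full(L, np.nan)
        for j in range(L):
            pv[j] = _ranksum_p(mgw[idx, j], mgw[other_idx, j])
        pvalues[name] = pv
        with np.errstate(invalid="ignore"):
            significant[name] = np.where(np.isfinite(pv), pv < alpha, False)
    return GrooveClassProfiles(
        column=column,
        classes=classes,
        n_members=n_members,
        pvalues=pvalues,
        significant=significant,
        alpha=alpha,
        tests_skipped=skipped,
    )
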