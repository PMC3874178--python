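"""Synthetic cohorts with planted protein/DNA-shape covariation.

The generator emulates the statistical structure the analysis assumes:

* a **synthetic pentamer shape table** with B-DNA-plausible value ranges and
  AT-tract minor-groove narrowing (AT-rich pentamers are narrower, fully
  AT pentamers narrower still), reverse-complement consistent by construction;
* an aligned, gapless **protein cohort** (~60 columns) split into carriers
  and non-carriers of a planted basic residue (arginine by default) at one
  N-terminal-tail column, with a handful of non-basic "subfamily signature"
  columns that separate the two groups imperfectly;
* per-protein **8-mer E-score tables** over all 32,896 revcomp-unique 8-mers
  whose high-scoring members share a degenerate NNA(Y/K)N core, and in which
  carriers' high-scoring 8-mers are drawn toward flanking-base contexts whose
  table MGW at the affected binding-site positions is low.  The shape effect
  flows only through the pentamer model — the table itself is never edited —
  so sequence and shape channels stay separable for ablation experiments.

Latent affinities are rank-transformed onto the PBM E-score scale
[−0.5, 0.5] with a convex transform, so the conventional 0.45 threshold
selects on the order of a few hundred sites per protein, as in real
universal-PBM data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._seq import DNA_BASES, canonical_kmers, revcomp
from .protein import ProteinCohort
from .shape import ShapeTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues eligible for non-carrier planted columns and signature pairs
NON_BASIC_POOL = "ADEGLMNQST"
B_DNA_MGW = 5.8  # Å, reference minor groove width of ideal B-DNA
AT_TRACT_BONUS = 0.5  # extra (dimensionless) narrowing scale for all-AT pentamers
RANK_EXPONENT = 5  # convexity of the rank -> E-score transform


# ---------------------------------------------------------------------------
# synthetic pentamer table


def expected_mean_mgw(at_narrowing: float) -> float:
    """Closed-form mean MGW of the generative rule over all pentamers.

    The rule is ``MGW = 5.8 − at_narrowing · scale(p) + ε`` with
    ``scale(p) = AT_fraction(p) + 0.5·[p is all A/T]`` and zero-mean noise.
    Over the 512 canonical pentamers the AT fraction averages exactly 1/2 and
    16 of 512 are all-AT.
    """
    e_scale = 0.5 + AT_TRACT_BONUS * (16 / 512)
    return B_DNA_MGW - at_narrowing * e_scale


def make_shape_table(seed: int | None = 0, at_narrowing: float = 0.8) -> ShapeTable:
    """Generate a revcomp-consistent synthetic pentamer shape table.

    ``at_narrowing`` (Å per unit AT-scale) controls how strongly AT content
    narrows the minor groove; 0.8 Å keeps all MGW values within a plausible
    4.4–6.1 Å band around the 5.8 Å B-DNA reference.  ProT trends more
    negative and Roll lower with AT content; HelT stays near 34–36°.
    """
    if at_narrowing < 0:
        raise ValueError("at_narrowing must be >= 0")
    rng = np.random.default_rng(seed)
    records: dict[str, dict] = {}
    for p in sorted({canonical_kmer for canonical_kmer in _canonical_pentamers()}):
        at = sum(b in "AT" for b in p) / 5.0
        scale = at + AT_TRACT_BONUS * float(at == 1.0)
        mgw = B_DNA_MGW - at_narrowing * scale + rng.normal(0.0, 0.1)
        prot = -5.0 - 8.0 * at + rng.normal(0.0, 1.0)
        steps = [p[1:3], p[2:4]]  # the two central dinucleotide steps
        roll, helt = [], []
        for s in steps:
            s_at = sum(b in "AT" for b in s) / 2.0
            roll.append(3.0 - 4.0 * s_at + rng.normal(0.0, 0.8))
            helt.append(35.0 - 1.5 * s_at + rng.normal(0.0, 0.5))
        records[p] = {
            "mgw": mgw,
            "prot": prot,
            "roll": tuple(roll),
            "helt": tuple(helt),
        }
    return ShapeTable.from_records(records)


def _canonical_pentamers() -> list[str]:
    from ._seq import all_kmers, canonical

    return sorted({canonical(p) for p in all_kmers(5)})


# ---------------------------------------------------------------------------
# cohort specification


@dataclass
class CovariationSpec:
    """Parameters of the planted covariation experiment.

    ``mgw_shift`` is the targeted MGW reduction (Å, negative = narrowing) of
    carriers' selected binding sites at ``affected_dna_positions`` relative to
    non-carriers; ``shape_effect_weight`` converts that target into the
    latent-affinity reward for low-MGW contexts.  ``shape_localization``
    applies a fraction of that reward as a *penalty* on narrowing at the
    other binding-site positions, mimicking a residue that contacts the minor
    groove at specific positions rather than preferring AT tracts everywhere.
    With ``mgw_shift`` and ``shape_effect_weight`` at 0 the cohort carries no
    shape covariation (the null condition).
    """

    n_proteins: int = 60
    msa_length: int = 60
    tail_column: int = 4  # 0-based MSA column; domain residue 5
    planted_residue_set: tuple[str, ...] = ("R",)
    affected_dna_positions: tuple[int, ...] = (3, 4)  # 0-based frame columns
    mgw_shift: float = -0.5  # Å
    motif_variant: str = "NNAYN"
    escore_noise_sd: float = 0.25
    shape_effect_weight: float = 8.0
    shape_localization: float = 0.5
    seed: int = 0
    carrier_fraction: float = 0.5
    background_mutation_rate: float = 0.30
    signature_fidelity: float = 0.85
    signature_columns: tuple[int, ...] | None = None
    frame_width: int = 8
    anchor: int = 1  # frame column of the first consensus position

    def __post_init__(self) -> None:
        if self.n_proteins < 4:
            raise ValueError("n_proteins must be >= 4")
        if not np.isfinite(self.mgw_shift):
            raise ValueError("mgw_shift must be finite")
        for a in self.affected_dna_positions:
            if not (0 <= a < self.frame_width):
                raise ValueError(
                    f"affected DNA position {a} outside frame [0, {self.frame_width})"
                )
        if not (0 <= self.tail_column < self.msa_length):
            raise ValueError("tail_column outside the MSA")
        if self.motif_variant not in ("NNAYN", "NNAKN"):
            raise ValueError("motif_variant must be NNAYN or NNAKN")

    def resolved_signature_columns(self) -> tuple[int, ...]:
        """Subfamily signature columns: the N-terminal tail plus columns spread
        over the rest of the domain, mirroring how real TF subfamilies differ
        throughout the domain rather than at isolated residues."""
        if self.signature_columns is not None:
            return self.signature_columns
        cols = [c for c in (0, 1, 2, 3, 5, 6) if c != self.tail_column]
        cols += list(range(10, self.msa_length - 1, 4))
        return tuple(c for c in cols if c < self.msa_length and c != self.tail_column)


@dataclass
class SyntheticCohort:
    cohort: ProteinCohort
    escores: pd.DataFrame  # index: canonical 8-mer, one column per protein
    shape_table: ShapeTable
    carriers: list[str]
    spec: CovariationSpec
    manifest: dict = field(default_factory=dict)

    def escore_table(self, protein_id: str) -> dict[str, float]:
        return self.escores[protein_id].to_dict()


# ---------------------------------------------------------------------------
# generation


def _encode_kmers(kmers: list[str]) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int8)
    for i, b in enumerate(DNA_BASES):
        lut[ord(b)] = i
    arr = np.frombuffer("".join(kmers).encode(), dtype=np.uint8).reshape(len(kmers), 8)
    return lut[arr]


def _pentamer_ids(enc: np.ndarray) -> np.ndarray:
    """(n, 4) ids of the pentamers starting at k-mer positions 0..3."""
    out = np.zeros((enc.shape[0], 4), dtype=np.int32)
    for w in range(4):
        ids = np.zeros(enc.shape[0], dtype=np.int32)
        for j in range(5):
            ids = ids * 4 + enc[:, w + j]
        out[:, w] = ids
    return out


def _build_msa(spec: CovariationSpec, rng: np.random.Generator):
    n, L = spec.n_proteins, spec.msa_length
    aa = np.array(list(AMINO_ACIDS))
    consensus = rng.choice(aa, size=L)
    n_carriers = int(round(n * spec.carrier_fraction))
    carrier_mask = np.zeros(n, dtype=bool)
    carrier_mask[rng.permutation(n)[:n_carriers]] = True

    rows = np.tile(consensus, (n, 1))
    mutate = rng.random((n, L)) < spec.background_mutation_rate
    rows[mutate] = rng.choice(aa, size=int(mutate.sum()))

    # subfamily signature columns: imperfectly group-separating, never basic
    pool = list(NON_BASIC_POOL)
    for c in spec.resolved_signature_columns():
        res_a, res_b = rng.choice(pool, size=2, replace=False)
        flip = rng.random(n) > spec.signature_fidelity
        for i in range(n):
            major = res_a if carrier_mask[i] else res_b
            minor = res_b if carrier_mask[i] else res_a
            rows[i, c] = minor if flip[i] else major

    # planted column: carriers get the planted residue, non-carriers never basic
    planted = list(spec.planted_residue_set)
    for i in range(n):
        if carrier_mask[i]:
            rows[i, spec.tail_column] = rng.choice(planted)
        else:
            rows[i, spec.tail_column] = rng.choice(pool)

    ids = [f"HD{i:03d}" for i in range(n)]
    msa = ["".join(r) for r in rows]
    return ids, msa, carrier_mask


def _protein_weights(spec: CovariationSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-protein (frame_width, 4) sequence preference weights.

    Strongly enforces the core consensus (A at the third consensus position,
    the protein's preferred degenerate base at the fourth) and adds weak,
    protein-specific preferences at the remaining positions.
    """
    W = np.zeros((spec.frame_width, 4))
    a0 = spec.anchor
    degen = "CT" if spec.motif_variant == "NNAYN" else "GT"
    pref_y = rng.choice(list(degen))
    other_y = degen.replace(pref_y, "")
    W[a0 + 2, :] = -4.0
    W[a0 + 2, DNA_BASES.index("A")] = 3.0
    W[a0 + 3, :] = -4.0
    W[a0 + 3, DNA_BASES.index(pref_y)] = 2.0
    W[a0 + 3, DNA_BASES.index(other_y)] = 0.5
    for c in (a0, a0 + 1, a0 + 4):
        if 0 <= c < spec.frame_width:
            W[c, rng.integers(4)] = 1.0
    for c in range(spec.frame_width):
        if c not in (a0, a0 + 1, a0 + 2, a0 + 3, a0 + 4):
            W[c, rng.integers(4)] = 0.4
    return W


def make_cohort(
    spec: CovariationSpec, table: ShapeTable | None = None
) -> SyntheticCohort:
    """Generate a cohort with planted residue/MGW covariation.

    Every revcomp-unique 8-mer receives an E-score per protein: a latent
    affinity (core-consensus match + weak flank preferences + carrier shape
    reward + Gaussian noise) is rank-transformed onto [−0.5, 0.5].  Carriers'
    reward for low MGW at the affected positions scales with
    ``shape_effect_weight · |mgw_shift| / 0.5`` and its sign follows
    ``mgw_shift`` (negative = prefer narrow).
    """
    rng = np.random.default_rng(spec.seed)
    if table is None:
        table = make_shape_table(seed=spec.seed, at_narrowing=0.8)
    lo, hi = table.parameter_range("mgw")
    if abs(spec.mgw_shift) > (hi - lo):
        raise ValueError(
            f"mgw_shift {spec.mgw_shift} Å exceeds the table's MGW span "
            f"({hi - lo:.2f} Å): infeasible"
        )

    ids, msa, carrier_mask = _build_msa(spec, rng)
    cohort = ProteinCohort(ids=ids, msa=msa)

    kmers = canonical_kmers(8)
    n_kmers = len(kmers)
    enc_plus = _encode_kmers(kmers)
    enc_minus = _encode_kmers([revcomp(k) for k in kmers])
    pent_plus = _pentamer_ids(enc_plus)
    pent_minus = _pentamer_ids(enc_minus)
    mgw_vec = table.mgw
    mgw_mean = table.parameter_mean("mgw")

    # precompute, per placement (strand, w), the mean MGW at the affected
    # positions and at the remaining (shape-defined) frame positions
    affected = set(spec.affected_dna_positions)
    aff_mgw, rest_mgw = {}, {}
    for s_name, pent in (("+", pent_plus), ("-", pent_minus)):
        for w in range(4):
            acc_a, cnt_a = np.zeros(n_kmers), 0
            acc_r, cnt_r = np.zeros(n_kmers), 0
            for c in range(spec.frame_width):
                start = c + w - spec.anchor - 2  # pentamer start within the k-mer
                if not 0 <= start <= 3:
                    continue
                vals = mgw_vec[pent[:, start]]
                if c in affected:
                    acc_a += vals
                    cnt_a += 1
                else:
                    acc_r += vals
                    cnt_r += 1
            aff_mgw[(s_name, w)] = acc_a / cnt_a if cnt_a else np.full(n_kmers, mgw_mean)
            rest_mgw[(s_name, w)] = acc_r / cnt_r if cnt_r else np.full(n_kmers, mgw_mean)

    scores = np.empty((n_kmers, spec.n_proteins))
    for i in range(spec.n_proteins):
        W = _protein_weights(spec, rng)
        lam = 0.0
        if carrier_mask[i]:
            lam = spec.shape_effect_weight * (-spec.mgw_shift) / 0.5
        best = np.full(n_kmers, -np.inf)
        for s_name, enc in (("+", enc_plus), ("-", enc_minus)):
            for w in range(4):
                c_lo = max(0, spec.anchor - w)
                c_hi = min(spec.frame_width, spec.frame_width + spec.anchor - w)
                sc = np.zeros(n_kmers)
                for c in range(c_lo, c_hi):
                    pos = c + w - spec.anchor
                    sc += W[c, enc[:, pos]]
                if lam != 0.0:
                    sc = sc + lam * (B_DNA_MGW - aff_mgw[(s_name, w)])
                    sc = sc - lam * spec.shape_localization * (
                        B_DNA_MGW - rest_mgw[(s_name, w)]
                    )
                np.maximum(best, sc, out=best)
        latent = best + rng.normal(0.0, spec.escore_noise_sd, n_kmers)
        ranks = np.empty(n_kmers)
        ranks[np.argsort(latent, kind="stable")] = np.arange(n_kmers)
        u = ranks / (n_kmers - 1)
        scores[:, i] = -0.5 + u**RANK_EXPONENT

    escores = pd.DataFrame(scores, index=pd.Index(kmers, name="kmer"), columns=ids)
    carriers = [pid for pid, c in zip(ids, carrier_mask) if c]
    manifest = {
        "spec": asdict(spec),
        "n_kmers": n_kmers,
        "carriers": carriers,
        "generator": "shapecov.simulate.make_cohort",
    }
    return SyntheticCohort(
        cohort=cohort,
        escores=escores,
        shape_table=table,
        carriers=carriers,
        spec=spec,
        manifest=manifest,
    )
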