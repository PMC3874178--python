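"""Pairwise protein-sequence similarity over an MSA with a substitution matrix.

Homeodomains are ~60-residue domains; similarity between two aligned domains
is the sum of BLOSUM45 scores over MSA columns, skipping columns where either
row carries a gap.  Similarity can be restricted to named region windows —
the N-terminal tail (domain residues 1–9) and the recognition helix (47–55)
in engrailed/Hoxa9 numbering — to separate minor-groove shape readout from
major-groove base readout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .matrices import SimilarityMatrix

logger = logging.getLogger(__name__)

GAP = "-"
#: default region windows in 1-based domain-residue numbering (inclusive)
DEFAULT_REGION_RESIDUES = {
    "n_terminal_tail": (1, 9),
    "recognition_helix": (47, 55),
}
#: matrix rows that are not ordinary residues (kept but flagged)
AMBIGUOUS_RESIDUES = frozenset("BZXJUO*")


@dataclass
class SubstitutionMatrix:
    """Symmetric residue substitution scores (e.g. BLOSUM45)."""

    alphabet: str
    scores: dict[tuple[str, str], float]
    name: str = ""
    flagged: frozenset = frozenset()

    def __post_init__(self) -> None:
        for (a, b), s in self.scores.items():
            t = self.scores.get((b, a))
            if t is None or t != s:
                raise ValueError(f"asymmetric substitution score for ({a}, {b})")
        self.flagged = frozenset(r for r in self.alphabet if r in AMBIGUOUS_RESIDUES)

    def score(self, a: str, b: str) -> float:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise KeyError(f"no substitution score for residue pair ({a}, {b})")

    def covers(self, residues) -> bool:
        return all(r in self.alphabet for r in residues)

    @classmethod
    def from_biopython(cls, arr, name: str = "") -> "SubstitutionMatrix":
        alphabet = "".join(arr.alphabet)
        scores = {}
        for a in alphabet:
            for b in alphabet:
                scores[(a, b)] = float(arr[a, b])
        return cls(alphabet=alphabet, scores=scores, name=name)


def load_substitution_matrix(source: str | Path = "BLOSUM45") -> SubstitutionMatrix:
    """Load a substitution matrix from an NCBI flat-format file or by name.

    If ``source`` is an existing file path it is parsed as NCBI flat format;
    otherwise it is treated as the name of a distributed matrix ("BLOSUM45",
    "BLOSUM62", ...).  Asymmetric files are rejected; ambiguity and stop rows
    (B, Z, X, *) are retained but flagged.
    """
    src = Path(str(source))
    if src.exists():
        with open(src) as fh:
            arr = substitution_matrices.read(fh)
        name = src.name
        # NCBI flat files are symmetric by convention; verify before trusting
        for a in arr.alphabet:
            for b in arr.alphabet:
                if arr[a, b] != arr[b, a]:
                    raise ValueError(
                        f"{src}: asymmetric entries for ({a}, {b}): "
                        f"{arr[a, b]} != {arr[b, a]}"
                    )
        return SubstitutionMatrix.from_biopython(arr, name=name)
    if str(source) in substitution_matrices.load():
        return SubstitutionMatrix.from_biopython(
            substitution_matrices.load(str(source)), name=str(source)
        )
    raise FileNotFoundError(f"no such file or known matrix name: {source}")


@dataclass
class ProteinCohort:
    """Aligned protein sequences with named region windows.

    ``regions`` maps a region name to the list of MSA column indices it
    covers (0-based).  ``numbering_map`` maps MSA column -> domain residue
    number (1-based) along the reference row, with None at columns where the
    reference row is gapped.
    """

    ids: list[str]
    msa: list[str]
    regions: dict[str, list[int]] = field(default_factory=dict)
    numbering_map: list[int | None] = field(default_factory=list)
    reference_index: int = 0

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.msa):
            raise ValueError("ids and msa rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("protein ids must be unique")
        lengths = {len(row) for row in self.msa}
        if len(lengths) > 1:
            raise ValueError(f"MSA rows have unequal lengths: {sorted(lengths)}")
        if not self.numbering_map:
            self.numbering_map = self._default_numbering()
        if not self.regions:
            self.regions = self._default_regions()
        L = self.n_columns
        for name, cols in self.regions.items():
            if any(c < 0 or c >= L for c in cols):
                raise ValueError(f"region {name!r} escapes the MSA bounds")
        prev = 0
        for num in self.numbering_map:
            if num is not None:
                if num <= prev:
                    raise ValueError("numbering_map must be strictly increasing")
                prev = num

    @property
    def n_proteins(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.msa[0])

    def _default_numbering(self) -> list[int | None]:
        out: list[int | None] = []
        num = 0
        for ch in self.msa[self.reference_index]:
            if ch == GAP:
                out.append(None)
            else:
                num += 1
                out.append(num)
        return out

    def _default_regions(self) -> dict[str, list[int]]:
        regions = {}
        for name, (lo, hi) in DEFAULT_REGION_RESIDUES.items():
            cols = [
                c
                for c, num in enumerate(self.numbering_map)
                if num is not None and lo <= num <= hi
            ]
            if cols:
                regions[name] = cols
        return regions

    def column(self, c: int) -> list[str]:
        return [row[c] for row in self.msa]

    def residue_number(self, column: int) -> int | None:
        return self.numbering_map[column]

    def column_for_residue(self, residue_number: int) -> int:
        for c, num in enumerate(self.numbering_map):
            if num == residue_number:
                return c
        raise KeyError(f"residue number {residue_number} not in reference numbering")

    @classmethod
    def from_fasta(cls, path: str | Path, **kwargs) -> "ProteinCohort":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        if not ids:
            raise ValueError(f"no sequences found in {path}")
        return cls(ids=ids, msa=rows, **kwargs)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for pid, row in zip(self.ids, self.msa):
                fh.write(f">{pid}\n{row}\n")


def protein_similarity(
    cohort: ProteinCohort,
    matrix: SubstitutionMatrix,
    region: str | None = None,
) -> SimilarityMatrix:
    """Pairwise BLOSUM similarity: sum of scores over shared (ungapped) columns.

    Columns where either row has a gap are skipped per pair; raw sums are
    reported (no length normalization — the downstream Pearson correlation is
    scale-invariant).  If more than 10% of pairs end up with no scorable
    column the computation is aborted.
    """
    if region is not None:
        if region not in cohort.regions:
            raise KeyError(
                f"unknown region {region!r}; defined: {sorted(cohort.regions)}"
            )
        cols = cohort.regions[region]
    else:
        cols = list(range(cohort.n_columns))

    residues = {ch for row in cohort.msa for ch in row if ch != GAP}
    if not matrix.covers(residues):
        missing = sorted(r for r in residues if r not in matrix.alphabet)
        raise ValueError(f"substitution matrix lacks residues: {missing}")

    # integer-encode the selected columns once; score via a lookup table
    alpha = matrix.alphabet + GAP
    index = {ch: i for i, ch in enumerate(alpha)}
    gap_i = index[GAP]
    enc = np.array(
        [[index[row[c]] for c in cols] for row in cohort.msa], dtype=np.int16
    )
    lut = np.zeros((len(alpha), len(alpha)))
    for (a, b), s in matrix.scores.items():
        lut[index[a], index[b]] = s

    n = cohort.n_proteins
    values = np.zeros((n, n))
    n_missing_pairs = 0
    skipped_total = 0
    for i in range(n):
        usable_i = enc[i] != gap_i
        for j in range(i, n):
            usable = usable_i & (enc[j] != gap_i)
            skipped_total += int((~usable).sum())
            if not usable.any():
                values[i, j] = values[j, i] = np.nan
                if i != j:
                    n_missing_pairs += 1
                continue
            s = lut[enc[i][usable], enc[j][usable]].sum()
            values[i, j] = values[j, i] = s

    n_pairs = n * (n - 1) // 2
    if n_pairs and n_missing_pairs / n_pairs > 0.10:
        raise ValueError(
            f"region {region!r}: {n_missing_pairs}/{n_pairs} pairs have no "
            "gap-free column to score"
        )
    if skipped_total:
        logger.info(
            "protein_similarity(region=%s): skipped %d gapped column comparisons",
            region,
            skipped_total,
        )
    return SimilarityMatrix(
        list(cohort.ids),
        values,
        "protein_blosum",
        meta={"region": region, "matrix": matrix.name, "columns": len(cols)},
    )
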