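"""File dialects for the pipeline: E-score TSVs, PFMs, maps, manifests.

All library coordinates are 0-based half-open; every human-facing report uses
1-based positions.  The conversion lives here and nowhere else.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .motifs import PFM
from .shape import BP_PARAMS, STEP_PARAMS, ShapeProfile


def to_report_position(zero_based: int) -> int:
    """Convert an internal 0-based position to the 1-based reporting convention."""
    return zero_based + 1


# -- E-score tables ---------------------------------------------------------


def read_escore_tsv(path: str | Path) -> dict[str, float]:
    """UniPROBE-style export: ``kmer<TAB>escore`` with a header row."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "kmer" not in cols or "escore" not in cols:
        raise ValueError(f"{path}: expected columns 'kmer' and 'escore'")
    return dict(
        zip(df[cols["kmer"]].astype(str).str.upper(), df[cols["escore"]].astype(float))
    )


def write_escore_tsv(table, path: str | Path) -> None:
    items = sorted(dict(table).items())
    with open(path, "w") as fh:
        fh.write("kmer\tescore\n")
        for k, e in items:
            fh.write(f"{k}\t{e:.6f}\n")


def read_aligned_sites(path: str | Path) -> list[str]:
    """Pre-aligned fixed-width binding sites, one per line (B1H-style input)."""
    sites = [ln.strip().upper() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not sites:
        raise ValueError(f"{path}: no sites found")
    widths = {len(s) for s in sites}
    if len(widths) > 1:
        raise ValueError(f"{path}: sites have unequal widths {sorted(widths)}")
    return sites


# -- PFMs -------------------------------------------------------------------


def write_pfm_meme(pfms: list[PFM], path: str | Path) -> None:
    """MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for p in pfms:
            fh.write(f"MOTIF {p.protein_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= {p.n_sites} E= 0\n"
            )
            for row in p.matrix:
                fh.write(" " + " ".join(f"{v:8.6f}" for v in row) + "\n")
            fh.write("\n")


def write_pfm_tabular(pfm: PFM, path: str | Path) -> None:
    df = pd.DataFrame(pfm.matrix, columns=list("ACGT"))
    df.insert(0, "position", [to_report_position(i) for i in range(pfm.width)])
    df.to_csv(path, sep="\t", index=False)


# -- shape profiles ---------------------------------------------------------


def write_profiles_tsv(profiles: list[ShapeProfile], path: str | Path) -> None:
    rows = []
    for prof in profiles:
        for param in BP_PARAMS + STEP_PARAMS:
            for i, v in enumerate(prof.vector(param)):
                if np.isfinite(v):
                    rows.append(
                        (prof.protein_id, to_report_position(i), param, v, prof.n_sites)
                    )
    pd.DataFrame(
        rows, columns=["protein_id", "position", "parameter", "value", "n_sites"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


# -- covariation maps -------------------------------------------------------


def write_map_tsv(maps, which: str, path: str | Path) -> None:
    """Labelled matrix TSV of one statistic (rows: protein columns, 1-based)."""
    m = getattr(maps, which)
    if m is None:
        raise ValueError(f"map {which!r} was not computed")
    df = pd.DataFrame(
        m,
        index=[to_report_position(c) for c in maps.protein_columns],
        columns=[to_report_position(p) for p in maps.dna_positions],
    )
    df.to_csv(path, sep="\t", index_label="protein_position", float_format="%.6g")


def write_map_long(maps, path: str | Path) -> None:
    """Long-format table ``(protein_column, dna_position, statistic, value)``."""
    rows = []
    for name in ("hypergeom_p", "neglog10_p", "mi"):
        m = getattr(maps, name)
        if m is None:
            continue
        for i, c in enumerate(maps.protein_columns):
            for j, p in enumerate(maps.dna_positions):
                rows.append(
                    (to_report_position(c), to_report_position(p), name, m[i, j])
                )
    pd.DataFrame(
        rows, columns=["protein_column", "dna_position", "statistic", "value"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


# -- manifests --------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
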