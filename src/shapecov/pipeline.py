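"""End-to-end orchestration: motifs → shape → similarity → covariation.

:func:`analyze_cohort` is the in-memory workhorse; :func:`run_pipeline` wraps
it with file input/output and a manifest so a run is reproducible from its
configuration alone.  All randomness is funneled through named seeds derived
from the single configuration seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .affinity import featurize, fit_cv, roc_auc
from .covariation import (
    DEFAULT_BIN_EDGES,
    NARROW_MGW_THRESHOLD,
    SENSITIVITY_THRESHOLDS,
    binned_pcc,
    call_narrow_minor_groove,
    covariation_maps,
    groove_profiles_by_residue,
    matrix_pcc,
    shuffle_null,
)
from .motifs import align_to_consensus, build_pfm, pfm_similarity, select_8mers
from .protein import ProteinCohort, load_substitution_matrix, protein_similarity
from .shape import SHAPE_PARAMS, ShapeTable, average_shape_profile, load_shape_table, shape_similarity

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Thresholds default to the conventions of the benchmark: E-score 0.45 for
    bound 8-mers, 5.12 Å for a narrow minor groove (with a 4.9–5.2 Å
    sensitivity list), 1000 shuffles for the null, 10-fold CV × 50 repeats
    for the regression stage.
    """

    proteins_fasta: str | Path | None = None
    escore_dir: str | Path | None = None  # one <protein_id>.tsv per protein
    shape_table_path: str | Path | None = None
    substitution_matrix: str = "BLOSUM45"
    out_dir: str | Path = "shapecov_out"
    escore_threshold: float = 0.45
    narrow_threshold: float = NARROW_MGW_THRESHOLD
    sensitivity_thresholds: tuple[float, ...] = SENSITIVITY_THRESHOLDS
    motif_variant: str | None = None
    n_shuffles: int = 1000
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    n_per_bin: int = 300
    cv_folds: int = 10
    cv_repeats: int = 50
    run_affinity: bool = False
    affinity_subsample: int = 2000
    affinity_max_proteins: int = 4
    seed: int = 0

    def stage_seed(self, name: str) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        order = ("shuffle", "binning", "affinity", "featurize")
        return int(
            np.random.SeedSequence(self.seed).spawn(len(order))[order.index(name)]
            .generate_state(1)[0]
            % (2**31)
        )


@dataclass
class PipelineResult:
    cohort: ProteinCohort
    site_sets: dict
    pfms: list
    profiles: list
    similarity: dict  # metric name -> SimilarityMatrix
    correlations: dict  # metric name -> matrix_pcc dict
    nulls: dict  # metric name -> ShuffleNull
    binned: dict | None
    calls: object
    maps: object
    sensitivity_argmax: dict
    groove_classes: object | None
    affinity: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def analyze_cohort(
    cohort: ProteinCohort,
    escores,
    shape_table: ShapeTable,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full covariation analysis on in-memory inputs.

    ``escores`` maps protein id -> (8-mer -> E-score); a DataFrame with one
    column per protein works too.
    """
    cfg = config or RunConfig()
    if isinstance(escores, pd.DataFrame):
        escores = {pid: escores[pid] for pid in cohort.ids}

    # --- per-protein motif and shape stage
    site_sets, pfms, profiles = {}, [], []
    for pid in cohort.ids:
        table = dict(escores[pid])
        selected = select_8mers(table, threshold=cfg.escore_threshold)
        siteset = align_to_consensus(
            selected,
            motif_variant=cfg.motif_variant,
            escores=table,
            protein_id=pid,
        )
        site_sets[pid] = siteset
        pfms.append(build_pfm(siteset))
        profiles.append(average_shape_profile(siteset, shape_table))

    # --- similarity stage
    submat = load_substitution_matrix(cfg.substitution_matrix)
    similarity = {"dna_pfm_pcc": pfm_similarity(pfms)}
    for param in SHAPE_PARAMS:
        similarity[f"shape_{param}"] = shape_similarity(profiles, param)
    similarity["protein_blosum"] = protein_similarity(cohort, submat)
    for region in cohort.regions:
        similarity[f"protein_blosum[{region}]"] = protein_similarity(
            cohort, submat, region=region
        )

    # --- matrix-level covariation
    dna_metrics = ["dna_pfm_pcc"] + [f"shape_{p}" for p in SHAPE_PARAMS]
    correlations, nulls = {}, {}
    prot_sim = similarity["protein_blosum"]
    shuffle_seed = cfg.stage_seed("shuffle")
    for k, metric in enumerate(dna_metrics):
        correlations[metric] = matrix_pcc(prot_sim, similarity[metric])
        nulls[metric] = shuffle_null(
            cohort,
            similarity[metric],
            submat,
            n_shuffles=cfg.n_shuffles,
            seed=shuffle_seed + k,
            protein_sim=prot_sim,
        )
    for region in cohort.regions:
        for metric in dna_metrics:
            correlations[f"{metric}[{region}]"] = matrix_pcc(
                similarity[f"protein_blosum[{region}]"], similarity[metric]
            )
    binned = binned_pcc(
        prot_sim,
        similarity["dna_pfm_pcc"],
        bin_edges=cfg.bin_edges,
        n_per_bin=cfg.n_per_bin,
        seed=cfg.stage_seed("binning"),
    )

    # --- position-level covariation
    calls = call_narrow_minor_groove(profiles, threshold=cfg.narrow_threshold)
    maps = covariation_maps(cohort, calls)
    sensitivity_argmax = {}
    for thr in cfg.sensitivity_thresholds:
        m = covariation_maps(cohort, call_narrow_minor_groove(profiles, threshold=thr))
        sensitivity_argmax[thr] = {
            "hypergeom": m.argmax_cell("neglog10_p"),
            "mi": m.argmax_cell("mi"),
        }
    top_column = maps.argmax_cell("neglog10_p")[0]
    groove_classes = groove_profiles_by_residue(cohort, profiles, top_column)

    # --- optional affinity stage
    affinity = {}
    if cfg.run_affinity:
        affinity = _affinity_stage(cohort, escores, site_sets, shape_table, cfg)

    return PipelineResult(
        cohort=cohort,
        site_sets=site_sets,
        pfms=pfms,
        profiles=profiles,
        similarity=similarity,
        correlations=correlations,
        nulls=nulls,
        binned=binned,
        calls=calls,
        maps=maps,
        sensitivity_argmax=sensitivity_argmax,
        groove_classes=groove_classes,
        affinity=affinity,
        manifest={"config": asdict(cfg), "n_proteins": cohort.n_proteins},
    )


def _affinity_stage(cohort, escores, site_sets, shape_table, cfg: RunConfig) -> dict:
    """Regression of E-scores for a subset of proteins at a subsampled scale."""
    rng = np.random.default_rng(cfg.stage_seed("affinity"))
    out = {}
    for pid in cohort.ids[: cfg.affinity_max_proteins]:
        table = dict(escores[pid])
        kmers = sorted(table)
        if len(kmers) > cfg.affinity_subsample:
            # keep all selected sites, subsample the rest for class balance
            selected = {s.kmer for s in site_sets[pid].sites}
            rest = [k for k in kmers if k not in selected]
            take = max(0, cfg.affinity_subsample - len(selected))
            kmers = sorted(selected) + sorted(
                rng.choice(rest, size=take, replace=False)
            )
        placements = align_to_consensus(
            kmers, motif_variant=site_sets[pid].motif_variant, protein_id=pid
        )
        feats = featurize(
            [s.kmer for s in placements.sites],
            placements,
            shape_table,
            seed=cfg.stage_seed("featurize"),
            escores=table,
        )
        res = {}
        for variant in ("seq", "seq+shape", "seq+shuffled-shape"):
            cv = fit_cv(
                feats,
                variant=variant,
                folds=cfg.cv_folds,
                repeats=cfg.cv_repeats,
                seed=cfg.stage_seed("affinity"),
                protein_id=pid,
            )
            try:
                cv.auc = roc_auc(
                    cv.predictions, feats.escores, threshold=cfg.escore_threshold
                )["auc"]
            except ValueError:
                cv.auc = None
            res[variant] = cv
        out[pid] = res
    return out


# ---------------------------------------------------------------------------
# file-level entry point


def run_pipeline(config: RunConfig):
    """Load inputs, run :func:`analyze_cohort`, write the result bundle.

    Aborts with the stage name and the offending record on any stage error;
    two runs with the same configuration produce identical numeric outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _require(path, what):
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"[inputs] missing {what}: {path}")

    _require(config.proteins_fasta, "aligned protein FASTA")
    _require(config.shape_table_path, "pentamer shape table")
    _require(config.escore_dir, "E-score directory")

    cohort = ProteinCohort.from_fasta(config.proteins_fasta)
    shape_table = load_shape_table(config.shape_table_path)
    escores = {}
    for pid in cohort.ids:
        path = Path(config.escore_dir) / f"{pid}.tsv"
        _require(path, f"E-score table for {pid}")
        escores[pid] = sio.read_escore_tsv(path)

    result = analyze_cohort(cohort, escores, shape_table, config)
    write_results(result, out)
    return result


def _report_cell(cell: tuple[int, int]) -> list[int]:
    """Internal 0-based (protein column, DNA position) -> 1-based report pair."""
    return [sio.to_report_position(cell[0]), sio.to_report_position(cell[1])]


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, sim in result.similarity.items():
        safe = name.replace("[", ".").replace("]", "")
        sim.to_tsv(out / f"similarity_{safe}.tsv")
    sio.write_pfm_meme(result.pfms, out / "pfms.meme")
    sio.write_profiles_tsv(result.profiles, out / "shape_profiles.tsv")
    sio.write_map_tsv(result.maps, "neglog10_p", out / "map_hypergeom_neglog10p.tsv")
    sio.write_map_tsv(result.maps, "mi", out / "map_mutual_information.tsv")
    sio.write_map_long(result.maps, out / "maps_long.tsv")

    summary = {
        "correlations": {
            k: v for k, v in result.correlations.items()
        },
        "shuffle_null": {
            k: {
                "observed": n.observed,
                "mean": n.mean,
                "p_empirical": n.p_empirical,
                "p99": n.percentile(99),
            }
            for k, n in result.nulls.items()
        },
        "binned_pcc": result.binned,
        "narrow_threshold": result.calls.threshold,
        "hypergeom_argmax": _report_cell(result.maps.argmax_cell("neglog10_p")),
        "mi_argmax": _report_cell(result.maps.argmax_cell("mi")),
        "sensitivity_argmax": {
            str(t): {k: _report_cell(cell) for k, cell in v.items()}
            for t, v in result.sensitivity_argmax.items()
        },
        "affinity": {
            pid: {
                variant: {
                    "r2_mean": cv.r2_mean,
                    "r2_median": cv.r2_median,
                    "auc": cv.auc,
                }
                for variant, cv in res.items()
            }
            for pid, res in result.affinity.items()
        },
    }
    manifest = dict(result.manifest)
    manifest["summary"] = summary
    sio.write_manifest(manifest, out / "manifest.json")
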