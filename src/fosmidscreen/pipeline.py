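"""End-to-end orchestration: generate -> screen -> deconvolve -> confirm ->
bin -> concordance, plus the screening-design arithmetic audit.

A pipeline run is driven by a single YAML config with one section per stage
and a mandatory top-level seed; every stage derives its own child seed from
it, so a run is a pure function of (config, seed).  All intermediate
artifacts are written as delimited text with a manifest, and the run ends
with a plain-text summary report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import binning as tb
from . import concordance as cc
from . import screening as sc
from . import synthetic as syn
from .errors import InvalidParameterError, PipelineError
from .panel import load_family_substrate_map, load_substrate_panel

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class DesignArithmetic:
    """Accounting of the pooled screening design's daily and total throughput."""

    clones_per_assay_plate: int
    clones_per_day: int
    reactions_per_day: int
    total_clones: Optional[int] = None
    total_assays: Optional[int] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def verify_design_arithmetic(
    design: sc.PoolingDesign | None = None,
    total_clones: Optional[int] = None,
    plates_per_pool: int = 16,
    clones_per_plate: int = 95,
    rounds_per_day: int = 8,
    n_substrates: int = 14,
) -> DesignArithmetic:
    """Recompute the design's throughput numbers from its parameters.

    One assay plate pools ``plates_per_pool`` source plates of
    ``clones_per_plate`` clones; repeating the pooling ``rounds_per_day``
    times gives the daily clone throughput, and multiplying by the substrate
    count gives reactions per day.  With a campaign ``total_clones`` the
    total assay count is ``total_clones * n_substrates``.
    """
    if design is not None:
        plates_per_pool = design.plates_per_pool
        clones_per_plate = design.clones_per_plate
        rounds_per_day = design.rounds_per_day
        n_substrates = design.n_substrates
    per_plate = plates_per_pool * clones_per_plate
    per_day = per_plate * rounds_per_day
    return DesignArithmetic(
        clones_per_assay_plate=per_plate,
        clones_per_day=per_day,
        reactions_per_day=per_day * n_substrates,
        total_clones=total_clones,
        total_assays=total_clones * n_substrates if total_clones is not None else None,
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see :meth:`from_dict`)."""

    seed: int
    library: syn.LibraryParams
    noise: syn.NoiseModel
    hit_calling: sc.HitCallingParams
    binning: tb.BinningParams
    esom: tb.EsomParams
    annotation_filter: cc.AnnotationFilter
    n_taxa: int = 2
    taxon_order: int = 3
    taxon_concentration: float = 1.0
    plates_per_pool: int = 16
    clones_per_plate: int = 95
    rounds_per_day: int = 8
    n_substrates: int = 14
    fn_rate: float = 0.0
    fp_rate: float = 0.0
    extract: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any]) -> "PipelineConfig":
        if "seed" not in cfg:
            raise InvalidParameterError("config must define a seed")
        seed = int(cfg["seed"])

        lib_cfg = dict(cfg.get("library", {}))
        n_taxa = int(lib_cfg.pop("n_taxa", 2))
        taxon_order = int(lib_cfg.pop("taxon_order", 3))
        taxon_concentration = float(lib_cfg.pop("taxon_concentration", 1.0))
        if "taxon_mix" not in lib_cfg:
            lib_cfg["taxon_mix"] = {
                f"taxon_{i:02d}": 1.0 / n_taxa for i in range(n_taxa)
            }
        if "insert_size_range" in lib_cfg:
            lib_cfg["insert_size_range"] = tuple(lib_cfg["insert_size_range"])
        lib_cfg.setdefault("n_clones", 1520)
        library = syn.LibraryParams(**lib_cfg)

        noise_cfg = dict(cfg.get("noise", {}))
        noise_cfg.setdefault("seed", seed)
        noise = syn.NoiseModel(**noise_cfg)

        pooling = dict(cfg.get("pooling", {}))
        ann = dict(cfg.get("annotation", {}))
        esom_cfg = dict(cfg.get("esom", {}))
        esom_cfg.setdefault("seed", seed)
        return cls(
            seed=seed,
            library=library,
            noise=noise,
            hit_calling=sc.HitCallingParams(**cfg.get("hit_calling", {})),
            binning=tb.BinningParams(**cfg.get("binning", {})),
            esom=tb.EsomParams(**esom_cfg),
            annotation_filter=cc.AnnotationFilter(
                **{k: v for k, v in ann.items() if k in ("evalue_threshold", "best_hit_only")}
            ),
            n_taxa=len(library.taxon_mix),
            taxon_order=taxon_order,
            taxon_concentration=taxon_concentration,
            plates_per_pool=int(pooling.get("plates_per_pool", 16)),
            clones_per_plate=int(pooling.get("clones_per_plate", 95)),
            rounds_per_day=int(pooling.get("rounds_per_day", 8)),
            n_substrates=int(pooling.get("n_substrates", 14)),
            fn_rate=float(ann.get("fn_rate", 0.0)),
            fp_rate=float(ann.get("fp_rate", 0.0)),
            extract=dict(cfg.get("extract", {})),
            raw=dict(cfg),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls.from_dict(cfg)


def demo_config(seed: int = 0, n_clones: int = 1520, n_taxa: int = 2) -> PipelineConfig:
    """Small two-taxon demonstration configuration."""
    return PipelineConfig.from_dict(
        {
            "seed": seed,
            "library": {"n_clones": n_clones, "n_taxa": n_taxa, "active_gene_rate": 0.05},
            "annotation": {"fn_rate": 0.0, "fp_rate": 0.0},
        }
    )


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------


def _write(df: pd.DataFrame, path: Path, **kw) -> str:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, **kw)
    return path.name


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage on synthetic data and write a report bundle.

    Returns a dict with the in-memory results (summary, assignments,
    concordance, design arithmetic).  Identical config and seed give
    byte-identical output files.  On stage failure a
    :class:`~fosmidscreen.errors.PipelineError` is raised naming the stage;
    artifacts written so far stay on disk with the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}, "files": {}}
    results: dict[str, Any] = {}
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(rng.integers(2**31))
        for name in ("taxa", "library", "readings", "expansion", "rescreen", "annotations")
    }

    def run_stage(name, fn):
        logger.info("stage %s (seed %s)", name, config.seed)
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            manifest["stages"][name] = "failed"
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = "ok"
        return out

    panel = load_substrate_panel()
    family_map = load_family_substrate_map()

    # --- generation -------------------------------------------------------
    def gen():
        models = syn.random_taxon_models(
            len(config.library.taxon_mix),
            stage_seeds["taxa"],
            order=config.taxon_order,
            concentration=config.taxon_concentration,
        )
        models = [
            syn.TaxonModel(t, config.taxon_order, m.transition_weights)
            for t, m in zip(sorted(config.library.taxon_mix), models)
        ]
        lib = syn.build_library(config.library, models, family_map, stage_seeds["library"])
        lib.to_fasta(outdir / "library.fasta")
        _write(lib.truth_table(), outdir / "truth.tsv", index=False)
        return lib

    library = run_stage("generate", gen)
    results["library"] = library

    # --- pooled screening -------------------------------------------------
    def screen():
        design = sc.build_pooling_design(
            len(library.clones),
            clone_ids=library.clone_ids(),
            plates_per_pool=config.plates_per_pool,
            clones_per_plate=config.clones_per_plate,
            rounds_per_day=config.rounds_per_day,
            n_substrates=config.n_substrates,
        )
        noise = syn.NoiseModel(**{**config.noise.__dict__, "seed": stage_seeds["readings"]})
        readings = syn.simulate_readings(library, design, noise, panel=panel)
        _write(readings, outdir / "pooled_readings.tsv", index=False)
        hits = sc.call_hits(readings, config.hit_calling)
        _write(hits.thresholds, outdir / "pooled_thresholds.tsv", index=False)
        _write(hits.wells, outdir / "pooled_hits.tsv", index=False)
        candidates = sc.deconvolve(hits, design)
        cand_out = candidates.copy()
        if not cand_out.empty:
            cand_out["substrates"] = cand_out["substrates"].map(";".join)
        _write(cand_out, outdir / "candidates.tsv", index=False)
        return design, candidates

    design, candidates = run_stage("screen", screen)

    # --- confirmation -----------------------------------------------------
    def confirm():
        clone_ids = candidates["clone_id"].tolist() if not candidates.empty else []
        if not clone_ids:
            return sc.ActivityProfile()
        noise = config.noise
        readings, layout = syn.simulate_individual_readings(
            library, clone_ids, noise, panel=panel, seed=stage_seeds["expansion"]
        )
        _write(readings, outdir / "expansion_readings.tsv", index=False)
        rescreen, _ = syn.simulate_individual_readings(
            library, clone_ids, noise, panel=panel, seed=stage_seeds["rescreen"]
        )
        tags = dict(zip(candidates["clone_id"], candidates["substrates"]))
        profile = sc.confirm_clones(
            readings, layout, config.hit_calling, rescreen, candidate_substrates=tags
        )
        _write(profile.to_frame(), outdir / "confirmations.tsv", index=False)
        return profile

    profile = run_stage("confirm", confirm)
    results["profile"] = profile

    summary = run_stage(
        "tally",
        lambda: sc.tally(profile, len(library.clones), panel, config.n_substrates),
    )
    results["summary"] = summary

    # --- binning (confirmed clones only, mirroring the real workflow) ----
    def bin_stage():
        confirmed = profile.positive_clones()
        seqs = {c.clone_id: c.insert_seq for c in library.clones if c.clone_id in set(confirmed)}
        if len(seqs) < 2:
            return None
        result = tb.bin_clones(seqs, config.binning, config.esom, config.extract)
        _write(result.assignments, outdir / "bin_assignments.tsv", index=False)
        umx = pd.DataFrame(result.umatrix)
        _write(umx, outdir / "umatrix.tsv", header=False, index=False)
        return result

    binres = run_stage("bin", bin_stage)
    results["binning"] = binres

    # --- concordance ------------------------------------------------------
    def concord():
        annotations = syn.synthesize_annotations(
            library, config.fn_rate, config.fp_rate, stage_seeds["annotations"]
        )
        _write(annotations, outdir / "annotations.tsv", index=False)
        kept = cc.filter_annotations(annotations, config.annotation_filter)
        universe = sorted(profile.activities)
        predicted = cc.predict_activities(kept, family_map, clone_ids=universe)
        predicted = {c: predicted[c] for c in universe}
        matrix = cc.classify_concordance(
            predicted, profile.activities, list(panel["substrate"])
        )
        _write(matrix, outdir / "concordance.tsv")
        summary_cc = cc.summarize_concordance(matrix) if not matrix.empty else None
        if summary_cc is not None:
            _write(summary_cc, outdir / "concordance_summary.tsv")
        if binres is not None and not matrix.empty:
            traits, counts = cc.bin_trait_table(binres.assignments, matrix)
            _write(traits, outdir / "bin_traits.tsv")
            _write(counts, outdir / "bin_trait_counts.tsv", index=False)
        return matrix, summary_cc

    matrix, cc_summary = run_stage("concordance", concord)
    results["concordance"] = matrix

    # --- design arithmetic + report --------------------------------------
    arithmetic = verify_design_arithmetic(design, total_clones=len(library.clones))
    results["design_arithmetic"] = arithmetic

    ari = None
    if binres is not None:
        from sklearn.metrics import adjusted_rand_score

        truth = {c.clone_id: c.true_taxon for c in library.clones}
        assigned = binres.assignments
        ari = float(
            adjusted_rand_score(
                [truth[c] for c in assigned["clone_id"]], assigned["bin"]
            )
        )
    results["bin_ari"] = ari

    lines = [
        "fosmidscreen pipeline report",
        f"seed: {config.seed}",
        "",
        "[design arithmetic]",
        *(f"{k}: {v}" for k, v in arithmetic.to_dict().items()),
        "",
        "[screen]",
        f"clones screened: {summary.n_clones_screened}",
        f"assays: {summary.n_assays}",
        f"positive assays: {summary.n_positive_assays}",
        f"unique positive clones: {summary.n_unique_positive_clones}",
        f"multi-substrate clones: {summary.n_multi_substrate_clones}",
        f"average positive rate (%): {summary.average_positive_rate:.4f}",
        "",
        "[binning]",
        f"clones binned: {0 if binres is None else len(binres.assignments)}",
        f"bins: {0 if binres is None else len(binres.partition.bin_ids)}",
        f"ARI vs true taxa: {'n/a' if ari is None else f'{ari:.4f}'}",
        "",
        "[concordance]",
    ]
    if cc_summary is not None:
        concordant = cc_summary["fully_concordant"].sum()
        lines.append(f"fully concordant substrates: {int(concordant)}/{len(cc_summary)}")
        both = int(cc_summary["both"].sum())
        pred_only = int(cc_summary["predicted_only"].sum())
        conf_only = int(cc_summary["confirmed_only"].sum())
        lines += [
            f"both: {both}",
            f"predicted only: {pred_only}",
            f"confirmed only: {conf_only}",
        ]
    report = "\n".join(lines) + "\n"
    (outdir / "summary.txt").write_text(report)
    results["report"] = report

    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results
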