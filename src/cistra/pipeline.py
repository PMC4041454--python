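"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` composes the stages in analysis order (peaks ->
concordance -> annotation -> differential expression -> core sets ->
integration -> survival).  Runs are deterministic given the config and
master seed; every serialized output carries the config hash, and a
manifest records versions, seeds and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

import cistra
from cistra import annotation as ann
from cistra import expression as expr
from cistra import integration as integ
from cistra import survival as surv
from cistra.enrichment import GenomeSpec
from cistra.intervals import read_bed, write_bed, pairwise_overlap_matrix
from cistra.synthetic import (
    SyntheticSpec,
    child_seeds,
    gen_expression,
    gen_genome,
    gen_overlapping_peakset,
    gen_peakset,
    gen_survival,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "DataError", "run_pipeline", "simulate"]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or missing input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Validated run configuration; mirrors the plain ``key: value`` file."""

    peaks: list[str] = field(default_factory=list)
    genome: dict[str, int] = field(default_factory=dict)
    annotation: str | None = None
    expression: str | None = None
    groups: str | None = None
    clinical: str | None = None
    panel: str | None = None
    oe_group: str = "OE"
    kd_group: str = "KD"
    control_group: str = "control"
    score_column: str = "score"
    windows: list[int] = field(
        default_factory=lambda: list(ann.DEFAULT_WINDOWS)
    )
    de_threshold: float = 0.05
    integrative_threshold: float = 0.1
    n_perm: int = 199
    seed: int = 0
    out_dir: str = "cistra_out"

    def __post_init__(self) -> None:
        for name in ("de_threshold", "integrative_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0,1), got {v}")
        w = [int(x) for x in self.windows]
        if any(x <= 0 for x in w) or w != sorted(w):
            raise ConfigError(f"windows must be positive ascending, got {w}")
        self.windows = w
        if self.n_perm < 99:
            raise ConfigError(f"n_perm must be >= 99, got {self.n_perm}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config must be a key: value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, index=False) -> None:
    with path.open("w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise DataError(f"config does not provide {what}")
    p = Path(path)
    if not p.exists():
        raise DataError(f"{what} file not found: {p}")
    return p


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; returns the report bundle dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    counts: dict[str, object] = {}
    report: dict = {"config_hash": cfg_hash}
    stage = "setup"
    try:
        # ---- stage: peaks
        stage = "peaks"
        peak_sets = []
        for p in config.peaks:
            peak_sets.append(read_bed(_require(p, "peak BED")))
        counts["peak_sets"] = {s.name: len(s) for s in peak_sets}
        genome = GenomeSpec(config.genome) if config.genome else None

        genes = None
        if config.annotation:
            stage = "annotation"
            genes = ann.load_gene_annotation(_require(config.annotation, "annotation"))
            counts["genes"] = len(genes)

        # ---- stage: concordance
        if len(peak_sets) >= 2 and genome is not None and genes is not None:
            stage = "concordance"
            report["concordance"] = integ.cistrome_concordance_report(
                peak_sets,
                genes,
                genome,
                windows=config.windows,
                n_perm=config.n_perm,
                seed=config.seed,
                out_dir=out / "concordance",
            )
            counts["pairwise_comparisons"] = len(report["concordance"]["pairwise"])
        elif len(peak_sets) >= 2:
            stage = "concordance"
            report["overlap_matrix"] = pairwise_overlap_matrix(peak_sets)

        # ---- stage: peak-to-gene assignment
        assignments = None
        if peak_sets and genes is not None:
            stage = "assignment"
            max_w = max(config.windows)
            assignments = ann.assign_peaks_to_genes(peak_sets[0], genes, max_w)
            counts["assignments"] = len(assignments)
            df = pd.DataFrame(
                {
                    "chrom": [a.peak.chrom for a in assignments],
                    "start": [a.peak.start for a in assignments],
                    "end": [a.peak.end for a in assignments],
                    "gene_id": [a.gene_id for a in assignments],
                    "distance": [a.distance for a in assignments],
                    "window": [a.window for a in assignments],
                }
            )
            _write_tsv(df, out / "assignments.tsv", cfg_hash)

        # ---- stage: differential expression
        core = None
        de_oe = de_kd = None
        if config.expression:
            stage = "differential_expression"
            mat = expr.read_expression_tsv(
                _require(config.expression, "expression matrix"),
                _require(config.groups, "sample groups") if config.groups else None,
            )
            mat = expr.quantile_normalize(mat)
            de_oe = expr.differential_expression(
                mat, config.control_group, config.oe_group, config.de_threshold
            )
            de_kd = expr.differential_expression(
                mat, config.control_group, config.kd_group, config.de_threshold
            )
            core = expr.core_regulated_set(
                de_oe, de_kd, config.integrative_threshold
            )
            counts["genes_tested"] = len(de_oe)
            counts["core_regulated"] = len(core)
            for label, res in (("oe", de_oe), ("kd", de_kd)):
                df = pd.DataFrame(
                    {
                        "gene_id": [r.gene_id for r in res],
                        "log_fc": [r.log_fc for r in res],
                        "p": [r.p for r in res],
                        "adj_p": [r.adj_p for r in res],
                        "direction": [r.direction for r in res],
                    }
                )
                _write_tsv(df, out / f"de_{label}.tsv", cfg_hash)
            expr.write_gene_set(core, out / "core_regulated_set.txt")
            report["core_set"] = core

        # ---- stage: integration
        if assignments is not None and core is not None and len(core) > 0:
            stage = "integration"
            records, frac = integ.integrate_binding_expression(
                assignments, core, window=config.windows[1]
                if len(config.windows) > 1 else config.windows[0],
                window_ladder=config.windows,
            )
            counts["core_fraction_bound"] = frac
            df = pd.DataFrame(
                [
                    {
                        "gene_id": r.gene_id,
                        "nearest_distance": r.nearest_distance,
                        **{f"bound_lt_{w}": r.bound_within[w] for w in sorted(r.bound_within)},
                    }
                    for r in records
                ]
            )
            _write_tsv(df, out / "integrated_genes.tsv", cfg_hash)
            report["fraction_bound"] = frac
            if config.panel:
                panel = expr.read_gene_set(_require(config.panel, "gene panel"))
                check = integ.panel_regulation_check(
                    panel,
                    assignments,
                    de_oe,
                    de_kd,
                    window=25_000 if 25_000 in config.windows else max(config.windows),
                    threshold=config.integrative_threshold,
                )
                counts["panel_regulated"] = f"{check.n_regulated}/{check.n_panel}"
                df = pd.DataFrame(
                    [{"gene_id": g, **flags} for g, flags in check.per_gene.items()]
                )
                _write_tsv(df, out / "panel_check.tsv", cfg_hash)
                report["panel_check"] = check

        # ---- stage: survival
        if config.clinical:
            stage = "survival"
            records = surv.read_clinical_tsv(_require(config.clinical, "clinical table"))
            col = config.score_column
            missing = [r.subject_id for r in records if col not in r.covariates]
            if missing:
                raise DataError(
                    f"clinical table lacks score column {col!r} for "
                    f"{len(missing)} subject(s)"
                )
            values = [r.covariates[col] for r in records]
            cut, labels = surv.dichotomize_first_quartile(values)
            low = [r for r, lab in zip(records, labels) if lab == "low"]
            high = [r for r, lab in zip(records, labels) if lab == "high"]
            km_all: dict[str, surv.KMCurve] = {}
            for label, grp in (("low", low), ("high", high)):
                if grp:
                    km = surv.km_estimate(grp)
                    km_all[label] = km
                    surv.write_km_tsv(km, out / f"km_{label}.tsv")
            survival_summary: dict = {
                "quartile_cut": cut,
                "n_low": len(low),
                "n_high": len(high),
            }
            if low and high and any(r.event for r in records):
                chi2, p = surv.logrank_test(low, high)
                survival_summary["logrank_chi2"] = chi2
                survival_summary["logrank_p"] = p
                for r in records:
                    r.covariates  # mappings are shared; build cox input below
                cox_records = [
                    surv.SurvivalRecord(
                        r.subject_id,
                        r.time,
                        r.event,
                        {**r.covariates, "high_score": 1.0 if lab == "high" else 0.0},
                    )
                    for r, lab in zip(records, labels)
                ]
                cox = surv.cox_ph(cox_records, ["high_score"])
                survival_summary["cox_coef"] = float(cox.coef[0])
                survival_summary["cox_hr"] = float(cox.hazard_ratios[0])
                survival_summary["cox_wald_p"] = float(cox.wald_p[0])
            counts["clinical_subjects"] = len(records)
            report["survival"] = survival_summary
            with (out / "survival_summary.json").open("w") as fh:
                json.dump(
                    {"config_hash": cfg_hash, **survival_summary}, fh, indent=2
                )
            _maybe_plot_km(km_all, out / "km_curves.png")

        # ---- manifest
        stage = "manifest"
        manifest = {
            "version": cistra.__version__,
            "config_hash": cfg_hash,
            "config": asdict(config),
            "seed": config.seed,
            "counts": counts,
        }
        with (out / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2)
        report["counts"] = counts
        report["manifest"] = manifest
        return report
    except (ConfigError, DataError):
        raise
    except (ValueError, LookupError, OSError) as exc:
        raise DataError(f"stage {stage!r} failed: {exc}") from exc


def _maybe_plot_km(curves: dict[str, "surv.KMCurve"], path: Path) -> None:
    """Basic KM PNG export; failures are logged, never fatal."""
    if not curves:
        return
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for label, km in curves.items():
            t = [0.0, *km.times.tolist()]
            s = [1.0, *km.survival.tolist()]
            ax.step(t, s, where="post", label=label)
            if km.times.size:
                ax.fill_between(
                    km.times, km.ci_low, km.ci_high, step="post", alpha=0.2
                )
        ax.set_xlabel("time (months)")
        ax.set_ylabel("recurrence-free fraction")
        ax.set_ylim(0, 1.02)
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
    except Exception as exc:  # pragma: no cover - plotting is best-effort
        logger.warning("KM plot failed: %s", exc)


# ---------------------------------------------------------------------------
# Simulation entry point


def simulate(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Write a full synthetic input directory readable by ``run_pipeline``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, genes = gen_genome(spec)
    peaks_a = gen_peakset(genome, genes, spec, name="peaks_a")
    seeds = child_seeds(spec.seed)
    overlap_seed = int(seeds["overlap"].generate_state(1)[0])
    peaks_b = gen_overlapping_peakset(
        peaks_a,
        spec.overlap_fraction,
        genome,
        seed=overlap_seed,
        peak_length_dist=spec.peak_length_dist,
        name="peaks_b",
    )
    matrix, planted = gen_expression(genes, spec)
    scores, records = gen_survival(max(10, 2 * spec.n_genes // 3), spec)

    write_bed(peaks_a, out / "peaks_a.bed")
    write_bed(peaks_b, out / "peaks_b.bed")
    ann.write_gene_annotation(genes, out / "annotation.tsv")
    expr.write_expression_tsv(matrix, out / "expression.tsv", out / "groups.tsv")
    clin = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "time_months": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "score": [r.covariates["score"] for r in records],
        }
    )
    clin.to_csv(out / "clinical.tsv", sep="\t", index=False)
    manifest = {
        "spec": spec.to_dict(),
        "planted_de_genes": planted,
        "files": [
            "peaks_a.bed",
            "peaks_b.bed",
            "annotation.tsv",
            "expression.tsv",
            "groups.tsv",
            "clinical.tsv",
        ],
    }
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
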