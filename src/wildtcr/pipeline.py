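"""End-to-end pipeline: simulate/ingest -> QC -> diversity -> power law ->
sharing -> covariate models, as a configured, logged, reproducible run.

A single master seed drives every stage through derived sub-seeds, so
re-running with the same config and inputs reproduces every output file
byte-identically.  Each stage writes tidy TSVs into the output directory and
the run ends with a JSON manifest (config echo, per-stage row counts,
package version).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .diversity import diversity_table, qc_cohort
from .models import (
    emm_contrasts,
    emm_slopes,
    fit_diversity_model,
    fit_richness_model,
    fit_sharing_model,
)
from .powerlaw import fit_and_classify
from .repertoire_io import (
    RECEPTOR_TYPES,
    MouseMetadata,
    Repertoire,
    apply_record_filters,
    collapse_to_aa,
    read_clonotype_table,
    read_metadata,
    read_repertoire,
)
from .seeds import derive_seed
from .sharing import (
    build_pair_table,
    linkage_to_newick,
    dendrogram_order,
    pairwise_shared,
    pcoa,
    public_clonotypes,
    sharing_percentage,
    sharing_to_dissimilarity,
)
from .simulate import SimulationConfig, simulate_cohort

__all__ = [
    "PipelineConfig",
    "PipelineConfigError",
    "PipelineStageError",
    "validate_config",
    "run_pipeline",
]

logger = logging.getLogger("wildtcr")


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration; ``errors`` lists every violation."""

    def __init__(self, errors: List[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML or JSON on disk)."""

    out_dir: str = "wildtcr_run"
    input_dir: Optional[str] = None
    simulate: Optional[SimulationConfig] = None
    qc_threshold: int = 5000
    gof_n_sim: int = 500
    public_threshold: float = 0.75
    powerlaw_p_cutoffs: Tuple[float, float] = (0.05, 0.1)
    master_seed: int = 0
    site_filter: Optional[str] = None
    dialect: str = "airr"
    dissimilarity_form: str = "rescaled"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d


def validate_config(source) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a dict or a YAML/JSON file.

    Every field is type- and range-checked; all violations are collected and
    reported together in a :class:`PipelineConfigError`, not just the first.
    Missing fields take their defaults (QC threshold 5000 molecules, 500 GoF
    simulations, public threshold 0.75, p cutoffs 0.05/0.1).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(raw, dict):
            raise PipelineConfigError([f"config file {source} is not a mapping"])
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        raise PipelineConfigError([f"unsupported config source {type(source)}"])

    errors: List[str] = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    for key in unknown:
        errors.append(f"unknown config field {key!r}")
        raw.pop(key)

    sim = raw.get("simulate")
    if sim is not None and not isinstance(sim, SimulationConfig):
        try:
            raw["simulate"] = SimulationConfig.from_dict(sim)
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate block invalid: {exc}")
            raw.pop("simulate", None)
    if "powerlaw_p_cutoffs" in raw and raw["powerlaw_p_cutoffs"] is not None:
        raw["powerlaw_p_cutoffs"] = tuple(raw["powerlaw_p_cutoffs"])

    try:
        cfg = PipelineConfig(**raw)
    except TypeError as exc:
        raise PipelineConfigError(errors + [str(exc)]) from None

    if cfg.input_dir is None and cfg.simulate is None:
        errors.append("one of input_dir or simulate block is required")
    if cfg.input_dir is not None and cfg.simulate is not None:
        errors.append("input_dir and simulate block are mutually exclusive")
    if cfg.qc_threshold < 1:
        errors.append(f"qc_threshold must be positive, got {cfg.qc_threshold}")
    if cfg.gof_n_sim < 1:
        errors.append(f"gof_n_sim must be positive, got {cfg.gof_n_sim}")
    if not 0.0 < cfg.public_threshold <= 1.0:
        errors.append(
            f"public_threshold must be in (0, 1], got {cfg.public_threshold}"
        )
    lo, hi = cfg.powerlaw_p_cutoffs
    if not 0.0 <= lo < hi <= 1.0:
        errors.append(f"powerlaw_p_cutoffs must be ordered within [0, 1], "
                      f"got {cfg.powerlaw_p_cutoffs}")
    if cfg.master_seed < 0:
        errors.append(f"master_seed must be non-negative, got {cfg.master_seed}")
    if cfg.dialect not in ("airr", "simple_tsv"):
        errors.append(f"unknown dialect {cfg.dialect!r}")
    if cfg.dissimilarity_form not in ("rescaled", "relative"):
        errors.append(f"unknown dissimilarity_form {cfg.dissimilarity_form!r}")
    if errors:
        raise PipelineConfigError(errors)
    return cfg


_FILE_RE = re.compile(r"^(?P<mouse>.+)_(?P<subset>CD[48])_(?P<chain>alpha|beta)\.tsv$")


def _ingest(config: PipelineConfig):
    """Load a cohort from disk: metadata.tsv plus one clonotype table per
    (mouse, subset, chain), named ``<mouse>_<subset>_<chain>.tsv``.

    Nucleotide-level tables (non-empty junction column) are filtered for
    productive CDR3s and collapsed to amino-acid clonotypes; amino-acid
    tables are taken as already collapsed.
    """
    in_dir = Path(config.input_dir)
    metadata = read_metadata(in_dir / "metadata.tsv")
    repertoires: Dict[Tuple[str, str], Repertoire] = {}
    exclusions: Dict[str, int] = {}
    for path in sorted(in_dir.glob("*.tsv")):
        m = _FILE_RE.match(path.name)
        if not m:
            continue
        mouse, subset, chain = m.group("mouse", "subset", "chain")
        records = read_clonotype_table(path, dialect=config.dialect)
        if any(r.has_cdr3 for r in records):
            kept, report = apply_record_filters(records)
            for reason, count in report.items():
                exclusions[reason] = exclusions.get(reason, 0) + count
            rep = collapse_to_aa(kept, mouse, subset, chain)
        else:
            rep = read_repertoire(path, mouse, subset, chain,
                                  dialect=config.dialect, level="amino_acid")
        repertoires[(mouse, rep.receptor_type)] = rep
    return metadata, repertoires, exclusions


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return decorator


@_stage("powerlaw")
def _stage_powerlaw(repertoires, config) -> pd.DataFrame:
    rows = []
    for (mouse_id, rt), rep in sorted(repertoires.items()):
        seed = derive_seed(config.master_seed, mouse_id, rt, "gof")
        counts = list(rep.clones.values())
        try:
            fit = fit_and_classify(counts, n_sim=config.gof_n_sim, seed=seed)
        except ValueError as exc:
            logger.warning("power-law fit skipped for %s %s: %s",
                           mouse_id, rt, exc)
            continue
        rows.append({
            "mouse_id": mouse_id, "receptor_type": rt, "alpha": fit.alpha,
            "xmin": fit.xmin, "ks_stat": fit.ks_stat, "n_tail": fit.n_tail,
            "p_value": fit.p_value, "classification": fit.classification,
            "n_sim": config.gof_n_sim, "seed": seed,
        })
    return pd.DataFrame(rows)


@_stage("sharing")
def _stage_sharing(repertoires, metadata, config, out_dir) -> pd.DataFrame:
    pair_tables = []
    for rt in RECEPTOR_TYPES:
        n_mice = sum(1 for (_, r) in repertoires if r == rt)
        if n_mice < 2:
            logger.warning("sharing skipped for %s (<2 mice)", rt)
            continue
        S = pairwise_shared(repertoires, rt, seed=config.master_seed)
        S.frame().to_csv(out_dir / f"sharing_{rt}.tsv", sep="\t")
        public, fraction = public_clonotypes(S.key_sets,
                                             threshold=config.public_threshold)
        _write_tsv(public, out_dir / f"public_{rt}.tsv")
        d = sharing_to_dissimilarity(S, form=config.dissimilarity_form)
        order, Z = dendrogram_order(d)
        (out_dir / f"dendrogram_{rt}.nwk").write_text(
            linkage_to_newick(Z, S.mouse_ids) + "\n")
        res = pcoa(d)
        coords = pd.DataFrame(
            res.coordinates, index=S.mouse_ids,
            columns=[f"PCo{i + 1}" for i in range(res.coordinates.shape[1])],
        )
        coords.to_csv(out_dir / f"pcoa_{rt}.tsv", sep="\t")
        pairs = build_pair_table(S, metadata, site_filter=config.site_filter)
        pair_tables.append(pairs)
        logger.info("sharing %s: %d mice, mean sharing %.2f%%, %d public "
                    "(%.3f%% of unique)", rt, n_mice, sharing_percentage(S),
                    len(public), 100 * fraction)
    return (pd.concat(pair_tables, ignore_index=True)
            if pair_tables else pd.DataFrame())


@_stage("models")
def _stage_models(div_tbl, pairs, metadata, out_dir) -> Dict[str, int]:
    counts = {}
    meta_ids = {m.mouse_id for m in metadata}

    def dump(result, stem):
        result.coefficients.reset_index().pipe(_write_tsv, out_dir / f"{stem}.tsv")
        if "receptor_type" in result.factors:
            contrasts = emm_contrasts(result, "receptor_type")
            pd.DataFrame([dataclasses.asdict(c) for c in contrasts]).pipe(
                _write_tsv, out_dir / f"{stem}_emm.tsv")
        counts[stem] = len(result.coefficients)

    if not div_tbl.empty:
        dump(fit_richness_model(div_tbl, _meta_frame(metadata)), "model_richness")
        dump(fit_diversity_model(div_tbl, _meta_frame(metadata), "shannon"),
             "model_shannon")
        dump(fit_diversity_model(div_tbl, _meta_frame(metadata), "simpson_log"),
             "model_simpson")
    if not pairs.empty and pairs["receptor_type"].nunique() >= 2 \
            and len(pairs) >= 10:
        sharing_model = fit_sharing_model(pairs)
        dump(sharing_model, "model_sharing")
        for cov in ("age_diff", "age_sum"):
            slopes = emm_slopes(sharing_model, cov, "receptor_type")
            _write_tsv(slopes, out_dir / f"model_sharing_slopes_{cov}.tsv")
    return counts


def _meta_frame(metadata: List[MouseMetadata]) -> pd.DataFrame:
    return pd.DataFrame([{"mouse_id": m.mouse_id, "sex": m.sex, "age": m.age,
                          "site": m.site, "cohort": m.cohort}
                         for m in metadata])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)
               for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    logger.setLevel(logging.INFO)
    manifest = {"version": __version__, "config": config.to_dict(), "stages": {}}
    try:
        # --- ingest or simulate -------------------------------------------
        if config.simulate is not None:
            try:
                cohort = simulate_cohort(config.simulate)
                metadata, repertoires = cohort.metadata, cohort.repertoires
                exclusions: Dict[str, int] = {}
            except Exception as exc:
                raise PipelineStageError("simulate", exc) from exc
        else:
            try:
                metadata, repertoires, exclusions = _ingest(config)
            except Exception as exc:
                raise PipelineStageError("ingest", exc) from exc
        _meta_frame(metadata).pipe(_write_tsv, out_dir / "metadata.tsv")
        manifest["stages"]["input"] = {
            "n_mice": len(metadata),
            "n_repertoires": len(repertoires),
            "record_exclusions": exclusions,
        }
        logger.info("input: %d mice, %d repertoires", len(metadata),
                    len(repertoires))

        # --- QC ------------------------------------------------------------
        try:
            kept, decisions = qc_cohort(repertoires, threshold=config.qc_threshold)
        except Exception as exc:
            raise PipelineStageError("qc", exc) from exc
        qc_df = pd.DataFrame([dataclasses.asdict(d) for d in decisions])
        _write_tsv(qc_df, out_dir / "qc_decisions.tsv")
        analysable = sorted({mid for (mid, _) in kept})
        manifest["stages"]["qc"] = {
            "n_pairs_checked": len(decisions),
            "n_pairs_kept": int(sum(d.keep for d in decisions)),
            "n_mice_analysable": len(analysable),
        }
        logger.info("qc: %d/%d subset pairs kept, %d analysable mice",
                    sum(d.keep for d in decisions), len(decisions),
                    len(analysable))
        if not kept:
            logger.warning("no repertoires passed QC; nothing to analyse")
            manifest["stages"]["result"] = "zero analysable mice"
            _write_manifest(manifest, out_dir)
            return manifest

        # --- diversity ------------------------------------------------------
        try:
            div_tbl = diversity_table(kept, seed=config.master_seed)
        except Exception as exc:
            raise PipelineStageError("diversity", exc) from exc
        _write_tsv(div_tbl, out_dir / "diversity.tsv")
        manifest["stages"]["diversity"] = {"n_rows": len(div_tbl)}

        # --- power law ------------------------------------------------------
        pl_tbl = _stage_powerlaw(kept, config)
        _write_tsv(pl_tbl, out_dir / "powerlaw.tsv")
        manifest["stages"]["powerlaw"] = {
            "n_rows": len(pl_tbl),
            "classifications": (pl_tbl["classification"].value_counts()
                                .to_dict() if not pl_tbl.empty else {}),
        }

        # --- sharing --------------------------------------------------------
        pairs = _stage_sharing(kept, metadata, config, out_dir)
        if not pairs.empty:
            _write_tsv(pairs, out_dir / "pairs.tsv")
        manifest["stages"]["sharing"] = {"n_pair_rows": len(pairs)}

        # --- models ---------------------------------------------------------
        model_counts = _stage_models(div_tbl, pairs, metadata, out_dir)
        manifest["stages"]["models"] = model_counts

        _write_manifest(manifest, out_dir)
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with (out_dir / "manifest.json").open("w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")
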