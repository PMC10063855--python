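"""End-to-end pipeline: data -> preprocess -> stability x2 -> signature ->
enrichment -> network, from a single YAML config with one global seed.

Every stage writes its own files into the output bundle, so each is re-runnable
standalone on the previous stage's outputs.  The global seed deterministically
derives one independent seed per stage (via numpy SeedSequence keyed on a
stage index), so re-running an identical config reproduces every non-timing
output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .matrix import ExpressionMatrix, read_annotation_tsv, read_expression_matrix
from .preprocess import differential_expression, preprocess_cohort
from .stability import StabilityConfig, rank_genes, stability_select
from .signature import (common_genes, evaluate_curve, incremental_sets,
                        select_optimal)
from .enrich import ora, pathway_gene_counts, read_gmt, set_overlap_edges, write_gmt
from .network import find_hubs, node_table, read_sif, write_sif
from .synth import (CohortSpec, SyntheticTruth, generate_gene_sets,
                    generate_network, generate_paired_cohorts, write_cohort)

_STAGES = ("data", "preprocess", "stability_a", "stability_b", "signature",
           "enrich", "network")


def derive_stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence(global_seed, stage index)."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ----------------------------------------------------------------- config
_COHORT_SPEC_KEYS = {"n_cases", "n_controls", "n_genes", "n_informative",
                     "effect_size", "noise_sd", "n_batches", "batch_shift_sd"}

_DEFAULTS: dict = {
    "seed": None,  # mandatory
    "cohorts": {
        "mode": "synth",
        "synth": {
            "shared_informative": 30,
            "a": {"n_cases": 70, "n_controls": 26, "n_genes": 5000,
                  "n_informative": 50, "effect_size": 1.0, "noise_sd": 0.5,
                  "n_batches": 1, "batch_shift_sd": 0.0},
            "b": {"n_cases": 96, "n_controls": 65, "n_genes": 5000,
                  "n_informative": 50, "effect_size": 1.0, "noise_sd": 0.5,
                  "n_batches": 1, "batch_shift_sd": 0.0},
        },
        "files": {
            "a": {"expression": None, "labels": None, "annotation": None},
            "b": {"expression": None, "labels": None, "annotation": None},
        },
    },
    "preprocess": {"quantile": True, "batch": True},
    "stability": {"n_boot": 100, "score_threshold": 0.6,
                  "penalty_strength": 0.08, "stratified": True},
    "signature": {"top_k": 1500, "step": 10, "explicit_sizes": None,
                  "l2_strength": 1.0, "ci_resamples": 2000},
    "enrich": {"gmt": None, "n_synth_sets": 20},
    "network": {"sif": None, "min_degree": 10},
}


@dataclass
class RunConfig:
    """Validated, defaults-filled pipeline configuration."""

    data: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return self.data["seed"]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" +
                         "\n".join(f"  - {e}" for e in errors))


def _merge(defaults, given, path, errors):
    """Recursively fill defaults, rejecting unknown keys; collects all errors."""
    if not isinstance(given, dict):
        errors.append(f"{path or 'config'}: expected a mapping")
        return defaults
    out = {}
    for key, dval in defaults.items():
        here = f"{path}.{key}" if path else key
        if key in given:
            gval = given[key]
            if isinstance(dval, dict):
                out[key] = _merge(dval, gval, here, errors)
            else:
                out[key] = gval
        else:
            out[key] = json.loads(json.dumps(dval)) if isinstance(dval, dict) else dval
    for key in given:
        if key not in defaults:
            errors.append(f"{path or 'config'}: unknown key {key!r}")
    return out


def _type_check(cfg: dict, errors: list[str]) -> None:
    if cfg.get("seed") is None:
        errors.append("seed: mandatory and must be an integer")
    elif not isinstance(cfg["seed"], int) or isinstance(cfg["seed"], bool):
        errors.append(f"seed: expected integer, got {type(cfg['seed']).__name__}")
    mode = cfg["cohorts"]["mode"]
    if mode not in ("synth", "files"):
        errors.append(f"cohorts.mode: must be 'synth' or 'files', got {mode!r}")
    if mode == "files":
        for c in ("a", "b"):
            for key in ("expression", "labels"):
                p = cfg["cohorts"]["files"][c][key]
                if p is None:
                    errors.append(f"cohorts.files.{c}.{key}: required in files mode")
                elif not Path(p).exists():
                    errors.append(f"cohorts.files.{c}.{key}: file not found: {p}")
    for key, lo in (("n_boot", 1), ("score_threshold", 0), ("penalty_strength", 0)):
        v = cfg["stability"][key]
        if not isinstance(v, (int, float)) or v <= (0 if lo == 0 else lo - 1):
            errors.append(f"stability.{key}: must be a number >= {lo}")
    if cfg["signature"]["top_k"] < 1:
        errors.append("signature.top_k: must be >= 1")
    for key in ("gmt",):
        p = cfg["enrich"][key]
        if p is not None and not Path(p).exists():
            errors.append(f"enrich.{key}: file not found: {p}")
    p = cfg["network"]["sif"]
    if p is not None and not Path(p).exists():
        errors.append(f"network.sif: file not found: {p}")


def normalize_config(raw: dict) -> RunConfig:
    """Fill defaults, reject unknown keys, and type-check; all errors at once."""
    errors: list[str] = []
    merged = _merge(_DEFAULTS, raw, "", errors)
    if not errors:
        _type_check(merged, errors)
    if errors:
        raise ConfigError(errors)
    return RunConfig(data=merged)


def validate_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return normalize_config(raw)


# ----------------------------------------------------------------- logging
class JsonLogger:
    """Line-delimited JSON event log (no timestamps: byte-reproducible)."""

    def __init__(self, path: Path):
        self.path = path
        self.events: list[dict] = []
        self._fh = open(path, "w")

    def log(self, stage: str, level: str, message: str, **extra) -> None:
        event = {"stage": stage, "level": level, "message": message, **extra}
        self.events.append(event)
        self._fh.write(json.dumps(event, sort_keys=True) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


# ----------------------------------------------------------------- pipeline
def _load_cohorts(cfg: RunConfig, out: Path, logger: JsonLogger):
    mode = cfg["cohorts"]["mode"]
    seed = derive_stage_seed(cfg.seed, "data")
    if mode == "synth":
        s = cfg["cohorts"]["synth"]
        spec_a = CohortSpec(**s["a"], seed=seed)
        spec_b = CohortSpec(**s["b"], seed=seed + 1)
        (ma, ta), (mb, tb) = generate_paired_cohorts(spec_a, spec_b,
                                                     s["shared_informative"])
        write_cohort(ma, ta, out, prefix="cohort_a")
        write_cohort(mb, tb, out, prefix="cohort_b")
        logger.log("data", "info", "synthetic cohorts generated",
                   n_genes=s["a"]["n_genes"],
                   shared_informative=s["shared_informative"])
        return ma, mb, ta, tb
    f = cfg["cohorts"]["files"]
    ms = []
    for c in ("a", "b"):
        m = read_expression_matrix(f[c]["expression"], f[c]["labels"])
        if f[c]["annotation"]:
            annot = read_annotation_tsv(f[c]["annotation"])
            m.meta["annotation"] = dict(zip(annot["probe_id"], annot["gene_id"]))
        else:
            m.level = "gene"  # unannotated input is taken as gene-level
            m.values.index.name = "gene_id"
        ms.append(m)
    logger.log("data", "info", "cohorts loaded from files")
    return ms[0], ms[1], None, None


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns the manifest dict (also written as JSON).

    Any stage failure re-raises with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = JsonLogger(out / "run_log.jsonl")
    timings: dict[str, float] = {}
    stage = "data"
    try:
        t0 = time.perf_counter()
        ma, mb, truth_a, truth_b = _load_cohorts(cfg, out, logger)
        timings[stage] = time.perf_counter() - t0

        stage = "preprocess"
        t0 = time.perf_counter()
        pp = cfg["preprocess"]
        ga = preprocess_cohort(ma, quantile=pp["quantile"], batch=pp["batch"])
        gb = preprocess_cohort(mb, quantile=pp["quantile"], batch=pp["batch"])
        for name, g in (("a", ga), ("b", gb)):
            de = differential_expression(g)
            de.write_csv(out / f"de_{name}.csv")
            n_sig = len(de.significant())
            logger.log("preprocess", "info",
                       f"cohort {name}: {g.n_features} genes, "
                       f"{n_sig} DE at q<0.05", cohort=name, n_de=n_sig)
        timings[stage] = time.perf_counter() - t0

        ranked = {}
        for name, g in (("a", ga), ("b", gb)):
            stage = f"stability_{name}"
            t0 = time.perf_counter()
            scfg = StabilityConfig(**cfg["stability"],
                                   seed=derive_stage_seed(cfg.seed, stage))
            res = stability_select(g, scfg)
            res.write_csv(out / f"stability_{name}.csv")
            (out / f"stability_{name}_manifest.json").write_text(
                json.dumps(res.manifest(), indent=1, sort_keys=True) + "\n")
            ranked[name] = rank_genes(res)
            logger.log(stage, "info",
                       f"{res.manifest()['n_passing']} genes pass threshold",
                       n_skipped=res.n_skipped)
            timings[stage] = time.perf_counter() - t0

        stage = "signature"
        t0 = time.perf_counter()
        sg = cfg["signature"]
        common = common_genes(ranked["a"], ranked["b"], top_k=sg["top_k"])
        common.table.to_csv(out / "common_genes.csv")
        logger.log(stage, "info", f"{len(common)} genes common to both top-k",
                   top_k=sg["top_k"])
        if len(common) == 0:
            raise RuntimeError("no common genes between cohorts' top-k lists")
        sets = incremental_sets(common, step=sg["step"],
                                explicit_sizes=sg["explicit_sizes"])
        sig_seed = derive_stage_seed(cfg.seed, "signature")
        curves = []
        for name, g in (("a", ga), ("b", gb)):
            curve = evaluate_curve(g, sets, cohort=name,
                                   l2_strength=sg["l2_strength"],
                                   n_resample=sg["ci_resamples"],
                                   seed=sig_seed)
            curves.append(curve)
        curve_table = pd.concat([c.table for c in curves], ignore_index=True)
        curve_table.to_csv(out / "signature_curve.csv", index=False,
                           float_format="%.6g")
        # optimum: size maximizing mean AUROC across the two cohorts
        mean_curve = curve_table.groupby("size")["auroc"].mean()
        optimum = int(mean_curve.index[np.argmax(mean_curve.to_numpy())])
        per_cohort_opt = {c.table["cohort"].iloc[0]: select_optimal(c)
                          for c in curves}
        signature_genes = curves[0].gene_lists[optimum]
        (out / "optimal_signature.json").write_text(json.dumps({
            "optimal_size": optimum,
            "per_cohort_optimal_size": per_cohort_opt,
            "genes": signature_genes,
        }, indent=1, sort_keys=True) + "\n")
        for size, genes in curves[0].gene_lists.items():
            (out / f"signature_{size:04d}.txt").write_text("\n".join(genes) + "\n")
        logger.log(stage, "info", f"optimal signature size {optimum}")
        timings[stage] = time.perf_counter() - t0

        stage = "enrich"
        t0 = time.perf_counter()
        universe = sorted(set(ga.feature_ids) & set(gb.feature_ids))
        gmt_path = cfg["enrich"]["gmt"]
        if gmt_path is not None:
            gsc = read_gmt(gmt_path)
        elif cfg["cohorts"]["mode"] == "synth":
            planted = (sorted(set(truth_a.informative_genes) &
                              set(truth_b.informative_genes))
                       or sorted(truth_a.informative_genes))
            gsc = generate_gene_sets(universe,
                                     n_sets=cfg["enrich"]["n_synth_sets"],
                                     size_range=(10, min(200, len(universe))),
                                     planted_set=planted,
                                     seed=derive_stage_seed(cfg.seed, "enrich"))
            write_gmt(gsc, out / "gene_sets.gmt")
        else:
            gsc = None
            logger.log(stage, "info", "no GMT supplied; enrichment skipped")
        if gsc is not None:
            enrichment = ora(signature_genes, universe, gsc)
            enrichment.to_csv(out / "enrichment.csv", index=False,
                              float_format="%.6g")
            counts = pathway_gene_counts(signature_genes, gsc)
            counts.to_csv(out / "pathway_gene_counts.csv", index=False)
            edges = set_overlap_edges(gsc)
            edges.to_csv(out / "set_overlap_edges.csv", index=False,
                         float_format="%.6g")
            logger.log(stage, "info",
                       f"{int((enrichment['fdr'] < 0.05).sum())} sets at FDR<0.05")
        timings[stage] = time.perf_counter() - t0

        stage = "network"
        t0 = time.perf_counter()
        sif_path = cfg["network"]["sif"]
        if sif_path is not None:
            graph = read_sif(sif_path)
        elif cfg["cohorts"]["mode"] == "synth":
            planted_hubs = signature_genes[:3]
            graph = generate_network(universe, planted_hubs,
                                     hub_degree=cfg["network"]["min_degree"] + 2,
                                     background_degree_mean=1.0,
                                     seed=derive_stage_seed(cfg.seed, "network"))
            write_sif(graph, out / "network.sif")
        else:
            graph = None
            logger.log(stage, "info", "no SIF supplied; network stage skipped")
        if graph is not None:
            hubs = find_hubs(graph, min_degree=cfg["network"]["min_degree"])
            node_table(graph, min_degree=cfg["network"]["min_degree"]).to_csv(
                out / "network_nodes.csv", index=False)
            (out / "hubs.txt").write_text("\n".join(hubs) + ("\n" if hubs else ""))
            logger.log(stage, "info", f"{len(hubs)} hub genes")
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        logger.log(stage, "error", str(exc))
        logger.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    logger.close()

    manifest = {
        "package_version": __version__,
        "config": cfg.data,
        "config_hash": cfg.config_hash(),
        "stage_seeds": {s: derive_stage_seed(cfg.seed, s) for s in _STAGES},
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
        "warnings": [e for e in logger.events if e["level"] == "warning"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True) + "\n")
    return manifest


def bundle_checksums(out_dir: str | Path,
                     exclude: tuple[str, ...] = ("manifest.json",)) -> dict[str, str]:
    """SHA256 of every bundle file except the (timing-bearing) manifest —
    the determinism contract's comparison surface."""
    out = Path(out_dir)
    sums = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name not in exclude:
            sums[str(p.relative_to(out))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return sums
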