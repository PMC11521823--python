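"""End-to-end orchestration: config validation, hierarchical seeding,
structured logging and a reproducibility manifest.

A run executes synth (optional) -> preprocess -> markers -> integrate ->
response -> health from one YAML/JSON config.  The master seed
deterministically derives one sub-seed per stage (so skipping a stage never
shifts another stage's randomness), every stage logs its parameter snapshot,
and the manifest records checksums of all written artifacts: re-running the
same config and seed reproduces all checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import health as H
from . import integrate as I
from . import markers as M
from . import preprocess as P
from . import response as R
from . import synth as S
from .datamodel import (OmicsBlock, ParticipantSheet, SampleSheet,
                        ValidationError, build_paired_design, logger,
                        read_block, write_block, write_results)

STAGES = ("synth", "preprocess", "markers", "integrate", "response", "health")

_DEFAULTS: dict[str, object] = {
    # inputs (either synth: true or paths per block)
    "synth": True,
    "inputs": {},
    # stage parameters; printed-value defaults
    "nmar_threshold": 0.75,
    "nmar_percentile": 0.01,
    "mar_sd": 0.5,
    "alpha": 0.05,
    "vip_threshold": 1.0,
    "n_components": 2,
    "snf_K": None,
    "snf_mu": 0.5,
    "snf_t": 20,
    "correlation_threshold": 0.7,
    "trend_tol": 0.25,
    "level": 0.95,
    "max_missing": 10,
    "min_paired": 9,
    "seed": 0,
    "out": "results",
    "synth_config": {},
}

_RANGES = {
    "nmar_threshold": (0.0, 1.0), "nmar_percentile": (0.0, 1.0),
    "alpha": (0.0, 1.0), "level": (0.0, 1.0),
    "correlation_threshold": (0.0, 1.0), "trend_tol": (0.0, 1.0),
}


@dataclass
class RunConfig:
    options: dict = field(default_factory=lambda: dict(_DEFAULTS))

    def __getitem__(self, key):
        return self.options[key]


def validate_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config; unknown keys are an error."""
    options = {k: (dict(v) if isinstance(v, dict) else v)
               for k, v in _DEFAULTS.items()}
    loaded = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
    if overrides:
        loaded.update(overrides)
    for key, value in loaded.items():
        if key not in _DEFAULTS:
            raise ValidationError(f"unknown config key {key!r}")
        options[key] = value
    for key, (lo, hi) in _RANGES.items():
        v = options[key]
        if v is not None and not lo <= float(v) <= hi:
            raise ValidationError(f"{key}={v} out of range [{lo},{hi}]")
    for name, p in (options.get("inputs") or {}).items():
        if not Path(p).exists():
            raise ValidationError(f"input path for {name!r} does not exist: {p}")
    return RunConfig(options)


def stage_seed(master: int, stage: str) -> int:
    """Per-stage sub-seed derived deterministically from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seeds: dict[str, int] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    wall_clock: dict[str, float] = field(default_factory=dict)
    completed: list[str] = field(default_factory=list)


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES
                 ) -> RunManifest:
    """Execute the requested stages; any stage failure aborts with a
    stage-named error, and the manifest records partial completion."""
    from . import __version__
    out = Path(config["out"])
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.options, sort_keys=True, default=str)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        package_version=__version__)
    master = int(config["seed"])
    state: dict[str, object] = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        seed = stage_seed(master, stage)
        manifest.seeds[stage] = seed
        logger.info("stage %s: seed=%d", stage, seed)
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, seed, out, state, manifest)
        except Exception as exc:
            _write_manifest(manifest, out)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.wall_clock[stage] = round(time.perf_counter() - t0, 3)
        manifest.completed.append(stage)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: RunManifest, out: Path) -> None:
    payload = dataclasses.asdict(manifest)
    (out / "manifest.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _record(manifest: RunManifest, path: Path) -> None:
    manifest.checksums[path.name] = _sha256(path)


def _stage_synth(config, seed, out, state, manifest) -> None:
    sc = dict(config["synth_config"] or {})
    sc.setdefault("seed", seed)
    scfg = S.SynthConfig(**sc)
    blocks, sheet, participants, truth = S.generate_cohort(scfg)
    state.update(blocks=blocks, sheet=sheet, participants=participants,
                 truth=truth)
    sheet.to_csv(out / "sample_sheet.csv")
    participants.to_csv(out / "participants.csv")
    for name, block in blocks.items():
        write_block(block, out / f"{name}.tsv", out / f"{name}_meta.tsv")
        _record(manifest, out / f"{name}.tsv")
    write_results({"planted": truth.planted,
                   "cluster": truth.cluster,
                   "trend_shape": truth.trend_shape},
                  out / "truth.json")
    for p in ("sample_sheet.csv", "participants.csv", "truth.json"):
        _record(manifest, out / p)


def _load_inputs(config, state) -> None:
    if "blocks" in state:
        return
    inputs = config["inputs"]
    sheet = SampleSheet.from_csv(inputs["sample_sheet"])
    participants = ParticipantSheet.from_csv(inputs["participants"])
    blocks = {name: read_block(inputs[name], inputs.get(f"{name}_meta"), sheet)
              for name in S.BLOCKS}
    state.update(blocks=blocks, sheet=sheet, participants=participants)


def _stage_preprocess(config, seed, out, state, manifest) -> None:
    _load_inputs(config, state)
    sheet = state["sheet"]
    design = build_paired_design(sheet)
    state["design"] = design
    params = P.ImputationParams(nmar_threshold=config["nmar_threshold"],
                                nmar_percentile=config["nmar_percentile"],
                                mar_sd=config["mar_sd"], seed=seed)
    processed = {}
    for name, block in state["blocks"].items():
        kind = "protein" if name == "plasma" else "ptm"
        res = P.preprocess_block(block, sheet, design, params, kind,
                                 max_missing=config["max_missing"],
                                 min_paired=config["min_paired"])
        processed[name] = res
        final = res.get("relative_abundance", res["adjusted"])
        write_block(final, out / f"{name}_processed.tsv")
        _record(manifest, out / f"{name}_processed.tsv")
    state["processed"] = processed


def _analysis_block(state, name) -> OmicsBlock:
    res = state["processed"][name]
    return res.get("relative_abundance", res["adjusted"])


def _stage_markers(config, seed, out, state, manifest) -> None:
    design = state["design"]
    records = {}
    for name in S.BLOCKS:
        block = _analysis_block(state, name)
        mode = "lfc" if name == "plasma" else "delta_pp"
        recs = M.discover_markers(block, design, mode=mode,
                                  alpha=config["alpha"],
                                  vip_threshold=config["vip_threshold"],
                                  n_components=config["n_components"],
                                  sample_type=name)
        records[name] = recs
        frame = M.records_frame(recs)
        frame.to_csv(out / f"markers_{name}.tsv", sep="\t")
        write_results(recs, out / f"markers_{name}.json")
        _record(manifest, out / f"markers_{name}.tsv")
    state["markers"] = records


def _stage_integrate(config, seed, out, state, manifest) -> None:
    design = state["design"]
    changes = {name: I.participant_change_matrix(
        _analysis_block(state, name), design, sample_type=name)
        for name in S.BLOCKS}
    selected = {name: [r.feature for r in state["markers"][name] if r.selected]
                for name in S.BLOCKS}
    affinities = []
    for name in ("buccal", "pbmc"):
        feats = selected[name] or list(changes[name].columns)
        ch = changes[name][feats]
        K = config["snf_K"] or max(2, ch.shape[0] // 3)
        affinities.append(I.build_affinity(ch, K=K, mu=config["snf_mu"]))
    fused = I.snf_fuse(affinities, K=config["snf_K"], t=config["snf_t"])
    labels, diag = I.spectral_cluster(fused, seed=seed)
    fused.matrix.to_csv(out / "fused_affinity.tsv", sep="\t")
    write_results({"labels": labels, "diagnostics": {k: v for k, v in
                                                     diag.items() if k != "eigenvalues"}},
                  out / "clusters.json")

    ptm_changes = pd.concat(
        [changes[n][selected[n] or list(changes[n].columns)]
         for n in ("buccal", "pbmc")], axis=1)
    prot_changes = changes["plasma"][selected["plasma"]
                                     or list(changes["plasma"].columns)]
    edges = I.change_correlation_network(ptm_changes, prot_changes,
                                         config["correlation_threshold"])
    edges.to_graphml(out / "network.graphml")
    coph = I.cophenetic_compare(ptm_changes, prot_changes)
    write_results({"cophenetic_correlation": coph}, out / "cophenetic.json")
    for p in ("fused_affinity.tsv", "clusters.json", "network.graphml",
              "cophenetic.json"):
        _record(manifest, out / p)
    state.update(changes=changes, fused=fused, cluster_labels=labels,
                 edges=edges, cophenetic=coph, selected=selected)


def _stage_response(config, seed, out, state, manifest) -> None:
    participants = state["participants"]
    adjusted = R.baseline_adjust(participants)
    fit, labels = R.gmm_categories(adjusted, seed=seed)
    trends = {}
    pt = participants.table.set_index("participant_id")
    for name in S.BLOCKS:
        feats = state["selected"][name] or list(state["changes"][name].columns)
        eff = state["changes"][name][feats]
        perf = pt.loc[eff.index.intersection(pt.index), "performance"]
        trends[name] = R.classify_trends(eff.loc[perf.index], perf,
                                         R.PERFORMANCE_ORDER,
                                         tol=config["trend_tol"])
    write_results({"gmm_k": fit.k, "bic": fit.bic_trace,
                   "labels": labels,
                   "trends": {n: t["trend"] for n, t in trends.items()}},
                  out / "response.json")
    _record(manifest, out / "response.json")
    state.update(gmm=fit, performance_labels=labels, trends=trends)


def _stage_health(config, seed, out, state, manifest) -> None:
    design = state["design"]
    participants = state["participants"]
    pt = participants.table.set_index("participant_id")
    all_scores, d_vectors = [], {}
    for name in S.BLOCKS:
        block = _analysis_block(state, name)
        pairs = [p for p in design.pairs_for(name)
                 if p.bt_sample in block.values.columns]
        idx = [p.participant_id for p in pairs]
        bt = block.values[[p.bt_sample for p in pairs]].T.set_axis(idx)
        at = block.values[[p.at_sample for p in pairs]].T.set_axis(idx)
        for comp, healthy in S.HEALTHY_CATEGORIES.items():
            labels = pt.loc[idx, comp]
            if labels.nunique() < 2:
                logger.warning("%s/%s: single lifestyle category, skipped",
                               name, comp)
                continue
            hmap = H.fit_health_map(bt, labels, lifestyle_component=comp,
                                    sample_type=name,
                                    healthy_category=healthy,
                                    n_components=config["n_components"])
            H.project_at(hmap, at)
            d_vectors[(name, comp)] = hmap.d_bt_at
            try:
                ranges = H.healthy_range(hmap, at, labels, reference=at,
                                         level=config["level"],
                                         vip_threshold=config["vip_threshold"])
            except ValidationError as exc:
                logger.warning("%s/%s: %s", name, comp, exc)
                continue
            if not ranges:
                continue
            sc = H.score_cohort(bt, at, ranges, reference=at)
            sc["sample_type"] = name
            sc["lifestyle"] = comp
            all_scores.append(sc)
    scores = (pd.concat(all_scores, ignore_index=True)
              if all_scores else pd.DataFrame())
    kendall = {}
    for comp in S.HEALTHY_CATEGORIES:
        cols = {st: d_vectors[(st, comp)] for st in S.BLOCKS
                if (st, comp) in d_vectors}
        if len(cols) >= 2:
            tab = pd.DataFrame(cols).dropna()
            if len(tab) >= 3:
                W, chi2, df, p = H.kendalls_w(tab)
                kendall[comp] = {"W": W, "chi2": chi2, "df": df, "p": p}
    tests = H.compare_bt_at(scores) if len(scores) else pd.DataFrame()
    write_results({"kendall": kendall}, out / "kendall.json")
    if len(scores):
        scores.to_csv(out / "health_scores.tsv", sep="\t", index=False)
        tests.to_csv(out / "health_tests.tsv", sep="\t", index=False)
        _record(manifest, out / "health_scores.tsv")
    _record(manifest, out / "kendall.json")
    state.update(health_scores=scores, health_tests=tests, kendall=kendall,
                 d_vectors=d_vectors)


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "preprocess": _stage_preprocess,
    "markers": _stage_markers,
    "integrate": _stage_integrate,
    "response": _stage_response,
    "health": _stage_health,
}
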