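"""End-to-end orchestration: simulate/load → SQI → diversity → network →
Mantel/Procrustes → JSON report.

A pipeline run is configured by one nested dict (typically loaded from
YAML/JSON), validated and default-filled by :func:`validate_config`, and
executed by :func:`run_pipeline`. Runs are deterministic for a fixed global
seed: each stage draws from its own seed derived by a fixed per-stage
offset, so enabling or disabling one stage never reshuffles another's
randomness.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import association, diversity, network, simulate, soil_quality
from . import io as rio
from .errors import ConfigError

logger = logging.getLogger("rhizoq")

__all__ = ["validate_config", "run_pipeline", "stage_seed"]

# fixed per-stage offsets: inserting a stage never changes the others' seeds
_STAGE_OFFSETS = {
    "simulate": 1,
    "sqi": 2,
    "diversity": 3,
    "network": 4,
    "mantel": 5,
    "procrustes": 6,
}

_SCHEMA: dict[str, dict[str, Any]] = {
    "seed": 0,
    "simulate": {"enabled": True},  # extra keys forwarded to SyntheticConfig
    "inputs": {"indicators": None, "counts": None, "taxonomy": None},
    "sqi": {
        "enabled": True,
        "variant": "unit",
        "bounds_scope": "replicates",
        "weights": "factor",
    },
    "diversity": {"enabled": True, "log_base": None},
    "network": {
        "enabled": True,
        "method": "spearman",
        "r_min": 0.6,
        "p_max": 0.01,
        "min_abundance": 0.01,
        "keep_isolates": False,
    },
    "mantel": {"enabled": True, "method": "pearson", "n_perm": 999},
    "procrustes": {"enabled": True, "n_perm": 999, "k": 2},
}

_SIMULATE_KEYS = {
    "enabled", "n_species", "doses", "n_replicates", "n_taxa", "seq_depth",
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed by a fixed offset."""
    if stage not in _STAGE_OFFSETS:
        raise ConfigError(f"unknown stage {stage!r}")
    return (int(global_seed) * 1009 + _STAGE_OFFSETS[stage]) % (2**31)


def _suggest(key: str, known) -> str:
    close = difflib.get_close_matches(key, list(known), n=1)
    return f"; did you mean {close[0]!r}?" if close else ""


def validate_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    """Normalize a pipeline config: fill defaults, reject unknown keys.

    Exactly one of the ``simulate`` block (enabled) or the ``inputs`` block
    (paths) must be active.
    """
    if not config:
        raise ConfigError(
            "empty config; required top-level keys: "
            + ", ".join(sorted(_SCHEMA))
        )
    out: dict[str, Any] = {}
    for key in config:
        if key not in _SCHEMA:
            raise ConfigError(f"unknown config key {key!r}{_suggest(key, _SCHEMA)}")
    out["seed"] = int(config.get("seed", _SCHEMA["seed"]))
    for block, defaults in _SCHEMA.items():
        if block == "seed":
            continue
        given = dict(config.get(block) or {})
        known = _SIMULATE_KEYS if block == "simulate" else set(defaults)
        for key in given:
            if key not in known:
                raise ConfigError(
                    f"unknown key {key!r} in block {block!r}"
                    f"{_suggest(key, known)}"
                )
        merged = {**defaults, **given}
        out[block] = merged
    has_inputs = any(out["inputs"].get(k) for k in ("indicators", "counts"))
    explicit_simulate = (config.get("simulate") or {}).get("enabled") is True
    simulating = bool(out["simulate"].get("enabled", True))
    if has_inputs and not explicit_simulate:
        out["simulate"]["enabled"] = False
        simulating = False
    if simulating == has_inputs:
        raise ConfigError(
            "exactly one of the simulate block or the inputs block must be "
            "active"
        )
    return out


def _config_hash(config: Mapping[str, Any]) -> str:
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _load_or_simulate(config):
    seed = config["seed"]
    if config["simulate"]["enabled"]:
        kwargs = {
            k: v for k, v in config["simulate"].items() if k != "enabled"
        }
        syn = simulate.SyntheticConfig(
            seed=stage_seed(seed, "simulate"), **kwargs
        )
        indicators, counts, taxonomy, truth = simulate.generate_experiment(syn)
        return indicators, counts, taxonomy, truth
    paths = config["inputs"]
    indicators = (
        rio.read_indicator_table(paths["indicators"])
        if paths.get("indicators") else None
    )
    counts = rio.read_count_table(paths["counts"]) if paths.get("counts") else None
    taxonomy = (
        rio.read_taxonomy(paths["taxonomy"]) if paths.get("taxonomy") else None
    )
    return indicators, counts, taxonomy, None


def _species_of(index: pd.Index, table: rio.IndicatorTable | None):
    if table is None:
        return {}
    return dict(table.data["species"])


def run_pipeline(
    config: Mapping[str, Any], out_dir: str | Path | None = None
) -> dict[str, Any]:
    """Execute the enabled stages in dependency order; return the report.

    When ``out_dir`` is given, writes the generated/loaded tables, the
    per-species network GraphML files and ``report.json`` there. Identical
    config + seed gives byte-identical reports.
    """
    config = validate_config(config)
    seed = config["seed"]
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    indicators, counts, taxonomy, truth = _load_or_simulate(config)
    report: dict[str, Any] = {
        "seed": seed,
        "config": config,
        "config_hash": _config_hash(config),
        "sqi": None,
        "diversity": None,
        "network": None,
        "mantel": None,
        "procrustes": None,
    }
    if out_path is not None and truth is not None:
        rio.write_indicator_table(indicators, out_path / "indicators.tsv")
        rio.write_count_table(counts, out_path / "counts.tsv")
        rio.write_taxonomy(taxonomy, out_path / "taxonomy.tsv")
        (out_path / "truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True, default=str) + "\n"
        )

    species_groups: dict[str, list[str]] = {}
    if indicators is not None:
        for sid, sp in indicators.data["species"].items():
            species_groups.setdefault(str(sp), []).append(sid)
    elif counts is not None:
        species_groups = {"all": counts.sample_ids}

    if config["sqi"]["enabled"] and indicators is not None:
        block = {}
        for sp, sids in species_groups.items():
            sub = indicators.subset(sids)
            weights = None
            if config["sqi"]["weights"] == "uniform":
                k = len(sub.indicators)
                weights = pd.Series(1.0 / k, index=sub.indicators)
            result = soil_quality.evaluate_soil_quality(
                sub,
                variant=config["sqi"]["variant"],
                bounds_scope=config["sqi"]["bounds_scope"],
                weights=weights,
            )
            kmo, chi2, pval = soil_quality.kmo_bartlett(sub)
            block[sp] = {
                "sqi": result.scores.round(6).to_dict(),
                "level": result.levels.to_dict(),
                "weights": result.weights.round(6).to_dict(),
                "kmo": round(kmo, 6),
                "bartlett_chi2": round(chi2, 6),
                "bartlett_p": round(pval, 9),
            }
            logger.info("sqi[%s]: %s", sp, block[sp]["sqi"])
        report["sqi"] = block

    if config["diversity"]["enabled"] and counts is not None:
        table = diversity.alpha_diversity_table(
            counts, log_base=config["diversity"]["log_base"]
        )
        report["diversity"] = {
            sid: {k: round(float(v), 6) for k, v in row.items()}
            for sid, row in table.iterrows()
        }

    if config["network"]["enabled"] and counts is not None:
        ncfg = config["network"]
        block = {}
        for sp, sids in species_groups.items():
            sub = rio.CountTable(counts.data.loc[sids].copy())
            filtered = network.abundance_filter(sub, ncfg["min_abundance"])
            r, p = network.correlation_matrix(filtered, method=ncfg["method"])
            net = network.build_network(
                r, p,
                taxonomy=taxonomy,
                r_min=ncfg["r_min"],
                p_max=ncfg["p_max"],
                mean_abundance=filtered.relative_abundance().mean(axis=0),
                keep_isolates=ncfg["keep_isolates"],
            )
            topo = network.topology(net) if net.n_nodes else None
            block[sp] = topo.as_dict() if topo else {"nodes": 0, "edges": 0}
            if out_path is not None:
                rio.write_network(
                    net, out_path / f"network_{sp}.graphml", "graphml"
                )
        report["network"] = block

    if (
        (config["mantel"]["enabled"] or config["procrustes"]["enabled"])
        and counts is not None
        and indicators is not None
    ):
        mantel_block: dict[str, Any] = {}
        proc_block: dict[str, Any] = {}
        for sp, sids in species_groups.items():
            sub_counts = rio.CountTable(counts.data.loc[sids].copy())
            sub_ind = indicators.subset(sids)
            d_comm = association.bray_curtis(sub_counts)
            d_env = association.env_distance(sub_ind)
            if config["mantel"]["enabled"]:
                res = association.mantel(
                    d_comm, d_env,
                    method=config["mantel"]["method"],
                    n_perm=config["mantel"]["n_perm"],
                    seed=stage_seed(seed, "mantel"),
                )
                mantel_block[sp] = {
                    "r": round(res.r, 6), "p": res.p,
                    "n_perm": res.n_perm, "method": res.method,
                }
            if config["procrustes"]["enabled"]:
                k = config["procrustes"]["k"]
                x = association.pcoa(d_comm, k=k).to_numpy()
                y = association.pcoa(d_env, k=k).to_numpy()
                res = association.procrustes_test(
                    x, y,
                    n_perm=config["procrustes"]["n_perm"],
                    seed=stage_seed(seed, "procrustes"),
                )
                proc_block[sp] = {
                    "m2": round(res.m2, 6), "r": round(res.r, 6),
                    "p": res.p, "n_perm": res.n_perm,
                }
        if config["mantel"]["enabled"]:
            report["mantel"] = mantel_block
        if config["procrustes"]["enabled"]:
            report["procrustes"] = proc_block

    if out_path is not None:
        rio.write_report(report, out_path / "report.json")
    return report
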