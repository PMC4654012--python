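"""End-to-end study orchestration: index -> QC -> map -> quantify -> DE -> enrichment.

A study compares each stress library against one control library, with the
control as library 1, so positive log2 ratios mean up-regulation under
stress.  All result surfaces are TSV tables plus a machine-readable JSON run
log (versions, seed, thresholds).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .detest import call_de
from .simulate import (
    SimConfig,
    catg_gene_ids,
    make_de_truth,
    make_fixtures,
    make_transcriptome,
    simulate_library,
)
from .enrichment import TermMap, enrich  # noqa: F401  (TermMap re-used by run_synthetic_study)
from .expression import ExpressionTable, quantify, saturation_curve
from .index import Transcript, build_virtual_index, index_summary
from .mapping import map_tags, mapping_summary, unambiguous_assignments
from .qc import QCStats, TagLibrary, clean_library


@dataclass
class RunConfig:
    """Study design and thresholds for run_study()."""

    reference: Sequence[Transcript]
    libraries: Dict[str, TagLibrary]  # condition label -> raw library
    control: str
    fdr_max: float = 0.001
    min_abs_log2: float = 1.0
    enrichment_p_max: float = 0.05
    enrichment_q_max: Optional[float] = 0.05
    seed: int = 0
    saturation_points: int = 10
    term_map: Optional[TermMap] = None
    out_dir: Optional[Path] = None

    def __post_init__(self):
        if self.control not in self.libraries:
            raise ValueError(f"control {self.control!r} not among libraries")
        if self.fdr_max <= 0 or self.min_abs_log2 < 0:
            raise ValueError("thresholds must be positive")


def _qc_stats_frame(stats: QCStats) -> pd.DataFrame:
    rows = [
        ("raw", stats.raw_distinct, stats.raw_total),
        ("tags_containing_N", *stats.n_with_N),
        ("adaptors", *stats.n_adaptor),
        ("low_complexity", *stats.n_low_complexity),
        ("copy_num_lt_2", *stats.n_singleton),
        ("clean", stats.clean_distinct, stats.clean_total),
    ]
    for t, (d, tot) in stats.copy_buckets.items():
        rows.append((f"copy_num_gt_{t}", d, tot))
    return pd.DataFrame(rows, columns=["category", "distinct", "total"])


def run_study(config: RunConfig) -> Dict[str, object]:
    """Run the full tag-profiling analysis for a multi-condition design.

    Returns a bundle of DataFrames keyed by stage; if ``config.out_dir`` is
    set, every table is also written as TSV together with a JSON run log.
    """
    try:
        index = build_virtual_index(config.reference)
    except Exception as e:  # pragma: no cover - re-raise with stage context
        raise RuntimeError(f"stage 'index' failed: {e}") from e

    bundle: Dict[str, object] = {
        "index_summary": pd.DataFrame([index_summary(index)]),
    }

    clean_libs: Dict[str, TagLibrary] = {}
    expr: Dict[str, ExpressionTable] = {}
    for cond, raw in config.libraries.items():
        try:
            clean, stats = clean_library(raw)
            clean_libs[cond] = clean
            bundle[f"qc_{cond}"] = _qc_stats_frame(stats)
            table = map_tags(clean, index)
            bundle[f"mapping_{cond}"] = mapping_summary(table)
            expr[cond] = quantify(unambiguous_assignments(table), clean, index)
            bundle[f"expression_{cond}"] = expr[cond].data
            total = clean.total_tags
            if total:
                step = max(total // config.saturation_points, 1)
                grid = list(range(0, total + 1, step))
                if grid[-1] != total:
                    grid.append(total)
                bundle[f"saturation_{cond}"] = saturation_curve(
                    clean, index, grid, config.seed
                ).data
        except Exception as e:
            raise RuntimeError(f"stage 'library:{cond}' failed: {e}") from e

    de_sets: Dict[str, set] = {}
    stress = [c for c in config.libraries if c != config.control]
    for cond in stress:
        try:
            de = call_de(
                expr[config.control], expr[cond], config.fdr_max, config.min_abs_log2
            )
            de = de.sort_values("fdr", kind="mergesort")
            bundle[f"de_{cond}_vs_{config.control}"] = de
            called = de[de["call"] != "not_de"]
            de_sets[cond] = set(called.index)
            bundle[f"de_counts_{cond}"] = pd.DataFrame(
                [
                    (
                        cond,
                        int((de["call"] == "up").sum()),
                        int((de["call"] == "down").sum()),
                        int((de["call"] == "not_de").sum()),
                    )
                ],
                columns=["condition", "up", "down", "not_de"],
            )
            if config.term_map is not None and len(called):
                background = set(de.index[de["tested"]])
                bundle[f"enrichment_{cond}"] = enrich(
                    de_sets[cond] & background,
                    background,
                    config.term_map,
                    config.enrichment_p_max,
                    config.enrichment_q_max,
                )
        except Exception as e:
            raise RuntimeError(f"stage 'de:{cond}' failed: {e}") from e

    if len(stress) >= 2:
        shared = set.intersection(*(de_sets[c] for c in stress)) if de_sets else set()
        bundle["de_intersection"] = pd.DataFrame(
            sorted(shared), columns=["gene_id"]
        )

    log = {
        "package": "dgetag",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "control": config.control,
        "conditions": list(config.libraries),
        "thresholds": {
            "fdr_max": config.fdr_max,
            "min_abs_log2": config.min_abs_log2,
            "enrichment_p_max": config.enrichment_p_max,
            "enrichment_q_max": config.enrichment_q_max,
        },
    }
    bundle["run_log"] = log

    bundle["_expression"] = expr
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, value in bundle.items():
            if isinstance(value, pd.DataFrame):
                value.to_csv(out / f"{key}.tsv", sep="\t")
        (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return bundle


def run_synthetic_study(
    sim_config: SimConfig,
    de_gene_sets: Optional[Dict[str, Sequence[str]]] = None,
    with_fixtures: bool = False,
    **run_kwargs,
):
    """Generate a seeded synthetic study and push it through the full pipeline.

    Returns ``(bundle, truth, extras)`` where ``extras`` holds the
    transcriptome and (if requested) the annotation/Ct fixtures.
    """
    transcripts = make_transcriptome(sim_config)
    truth = make_de_truth(sim_config, catg_gene_ids(transcripts), de_gene_sets)
    libraries = {
        cond: simulate_library(transcripts, truth, cond, sim_config)[0]
        for cond in sim_config.conditions
    }
    extras: Dict[str, object] = {"transcripts": transcripts}
    term_map = None
    if with_fixtures:
        term_rows, ct_table = make_fixtures(truth, sim_config)
        extras["term_map_frame"] = term_rows
        extras["ct_table"] = ct_table
        term_map = TermMap.from_pairs(
            term_rows[["term_id", "term_name", "gene_id"]].itertuples(index=False)
        )
    config = RunConfig(
        reference=transcripts,
        libraries=libraries,
        control=sim_config.control,
        seed=sim_config.seed,
        term_map=term_map,
        **run_kwargs,
    )
    return run_study(config), truth, extras
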