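"""Simulation-study driver: dataset generation, calling and scoring.

Bundles the steps of a benchmark run - draw fusion specs, build chimeric
transcripts, simulate fusion + background reads, call fusions, score with
the per-partner breakpoint tolerance - so that tests, examples and the
acceptance script share one code path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import simulate as sim
from .pipeline import CallResult, PipelineConfig, Resources, call_fusions
from .refdb import TranscriptDB


def truth_frame(specs: Sequence[sim.FusionSpec]) -> pd.DataFrame:
    """Truth table as a DataFrame (1-based coordinates, one row per isoform)."""
    rows = []
    for s in specs:
        d = dataclasses.asdict(s)
        d["pos_5p"] = s.pos_5p + 1
        d["pos_3p"] = s.pos_3p + 1
        rows.append({k: d[k] for k in sim.TRUTH_COLUMNS})
    return pd.DataFrame(rows, columns=sim.TRUTH_COLUMNS)


def simulate_dataset(
    db: TranscriptDB,
    seed: int,
    n_per_class: int = 20,
    background_pairs: int = 25_000,
    params: Optional[sim.SimReadParams] = None,
) -> Tuple[sim.SimulatedPairs, pd.DataFrame, List[sim.FusionSpec]]:
    """One benchmark dataset: fusion reads at their assigned coverage plus
    background reads, with the matching truth table."""
    params = params or sim.SimReadParams(seed=seed)
    rng = np.random.default_rng(seed)
    specs = sim.generate_fusion_annotations(db, n_per_class=n_per_class, seed=seed)
    transcripts = sim.build_fusion_transcripts(specs, db)
    by_iso = {(s.fusion_id, str(s.isoform)): s.coverage for s in specs}
    covs = {k: by_iso[tuple(k.split("|")[:2])] for k in transcripts}
    reads = sim.simulate_reads(transcripts, covs, params, rng=rng)
    bg = sim.add_background_reads(db, params, background_pairs, rng=rng)
    return sim.merge_pairs(reads, bg), truth_frame(specs), specs


def predictions_frame(result: CallResult, passing_only: bool = True) -> pd.DataFrame:
    from .report import REPORT_COLUMNS

    recs = [
        dataclasses.asdict(r)
        for r in result.records
        if not passing_only or r.filter_status == "PASS"
    ]
    return pd.DataFrame(recs, columns=REPORT_COLUMNS)


@dataclass
class DatasetOutcome:
    seed: int
    n_pairs: int
    evaluation: sim.EvalResult
    result: CallResult


def run_study(
    db: TranscriptDB,
    resources: Resources,
    seeds: Sequence[int],
    config: Optional[PipelineConfig] = None,
    n_per_class: int = 20,
    background_pairs: int = 25_000,
    tol: int = 20,
) -> List[DatasetOutcome]:
    """Run the full benchmark over several seeded datasets."""
    config = config or PipelineConfig()
    out: List[DatasetOutcome] = []
    for seed in seeds:
        params = sim.SimReadParams(seed=seed, strandedness=config.strandedness)
        pairs, truth, _specs = simulate_dataset(
            db, seed, n_per_class=n_per_class, background_pairs=background_pairs,
            params=params,
        )
        result = call_fusions(pairs.names, pairs.reads1, pairs.reads2, resources, config)
        ev = sim.evaluate_predictions(truth, predictions_frame(result), tol=tol)
        out.append(DatasetOutcome(seed=seed, n_pairs=len(pairs.names), evaluation=ev,
                                  result=result))
    return out


def summarize(outcomes: Sequence[DatasetOutcome]) -> Dict[str, float]:
    recalls = [o.evaluation.recall for o in outcomes]
    precisions = [o.evaluation.precision for o in outcomes if o.evaluation.precision is not None]
    summary = {
        "mean_recall": float(np.mean(recalls)) if recalls else 0.0,
        "mean_precision": float(np.mean(precisions)) if precisions else float("nan"),
    }
    classes = sorted({c for o in outcomes for c in o.evaluation.per_class_recall})
    for c in classes:
        vals = [o.evaluation.per_class_recall.get(c, 0.0) for o in outcomes]
        summary[f"class{c}_recall"] = float(np.mean(vals))
    return summary
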