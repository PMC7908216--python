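"""End-to-end cohort analysis: score -> pattern -> indexes -> evaluation."""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .indexes import classify_responder, compute_index_panel
from .model import InputError, PatientRecord, VIEWS
from .pattern import classify_pattern
from .scoring import DEFAULT_CUTOFF, ScoringConfig, compute_rspi
from .stats import TwoByTwo, diagnostics, logistic_univariate, roc


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    The defaults encode the published constants of the method: the 70 %
    ejection-phase window inside :class:`ScoringConfig`, the >=7-point
    high-RSPI cutoff, and the >=15 % LVESV-reduction responder rule
    (applied inside :func:`rspi.indexes.classify_responder`).
    """

    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    cutoff: int = DEFAULT_CUTOFF
    haldane: bool = False
    include_two_chamber_pattern: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cutoff <= 12:
            raise InputError("cutoff must be in 0..12")


def patient_table(patients: Sequence[PatientRecord],
                  config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Per-patient results: component bits, RSPI, pattern, indexes, response."""
    config = config or RunConfig()
    if not patients:
        raise InputError("no patients")
    rows = []
    for p in patients:
        res = compute_rspi(p, config.scoring, cutoff=config.cutoff)
        pat = classify_pattern(
            p, config.scoring,
            include_two_chamber=config.include_two_chamber_pattern)
        panel = compute_index_panel(p)
        responder, delta = classify_responder(p.lvesv_base, p.lvesv_fu)
        row = {"patient_id": p.id, "rspi_total": res.total,
               "high_rspi": res.high, "pattern": pat.label,
               "responder": responder, "delta_lvesv_pct": delta,
               "lvdft_rr": panel.lvdft_rr, "ivmd": panel.ivmd,
               "max_time_delay": panel.max_time_delay,
               "opposing_wall_delay": panel.opposing_wall_delay,
               "yu_index": panel.yu_index,
               "septal_flash": panel.septal_flash}
        for view in VIEWS:
            cv = res.per_view[view]
            for i, bit in enumerate(cv.bits, start=1):
                row[f"{view}_c{i}"] = bit
            row[f"{view}_points"] = cv.points
            row[f"{view}_assessable"] = cv.assessable
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_summary(table: pd.DataFrame,
                   config: Optional[RunConfig] = None) -> dict:
    """Cohort diagnostics of high RSPI against volumetric CRT response."""
    config = config or RunConfig()
    scores = table["rspi_total"].to_numpy()
    labels = table["responder"].to_numpy(dtype=bool)
    two = TwoByTwo.from_cohort(scores, labels, config.cutoff)
    diag = diagnostics(two, haldane=config.haldane)
    out = {"n": int(len(table)),
           "cutoff": config.cutoff,
           "table": {"tp": two.tp, "fp": two.fp, "fn": two.fn, "tn": two.tn},
           "diagnostics": _jsonable(asdict(diag))}
    if 0 < labels.sum() < len(labels):
        r = roc(scores, labels)
        out["roc"] = {"auc": r.auc, "optimal_cutoff": r.optimal_cutoff,
                      "points": [list(p) for p in r.points]}
        fit = logistic_univariate((scores >= config.cutoff).astype(float),
                                  labels)
        out["logistic_high_rspi"] = _jsonable(asdict(fit))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def run_pipeline(patients: Sequence[PatientRecord],
                 config: Optional[RunConfig] = None) -> dict:
    """Full report bundle: the per-patient table and the cohort summary."""
    config = config or RunConfig()
    table = patient_table(patients, config)
    return {"patients": table, "summary": cohort_summary(table, config)}
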