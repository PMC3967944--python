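"""Rate-dependence index B_RD, RRD/FRD/NRD classification, consensus ranks.

B_RD compares a parameter's standardized sensitivity at slow pacing (B_slow)
with its rescaled sensitivity at fast pacing (B_fast):

* same sign:      B_RD = |B_slow| - |B_fast|
  (positive: larger effect at slow pacing -> reverse rate dependent)
* opposite signs: B_RD = -(|B_slow| + |B_fast|) = -|B_slow - B_fast|
  (always negative: such a parameter can be perturbed to lengthen the APD
  at fast but not at slow pacing, so it is grouped with the FRD set)

Zeros count as "same sign".  Classification: B_RD > threshold -> RRD,
B_RD < -threshold -> FRD, otherwise NRD.  The analysis threshold is 0.01;
heat-map style displays conventionally use a stricter 0.03.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 0.01
DISPLAY_THRESHOLD = 0.03

CLASSES = ("RRD", "FRD", "NRD")


def compute_brd(b_slow: float, b_fast: float) -> float:
    """Rate-dependence index from slow and (rescaled) fast sensitivities."""
    b_slow = float(b_slow)
    b_fast = float(b_fast)
    if not (np.isfinite(b_slow) and np.isfinite(b_fast)):
        raise ValueError("sensitivities must be finite")
    if b_slow * b_fast >= 0.0:  # zero handled as same sign
        return abs(b_slow) - abs(b_fast)
    return -(abs(b_slow) + abs(b_fast))


def classify(b_rd: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    if b_rd > threshold:
        return "RRD"
    if b_rd < -threshold:
        return "FRD"
    return "NRD"


@dataclass(frozen=True)
class RateDependenceEntry:
    parameter: str
    b_slow: float
    b_fast: float  # rescaled
    b_rd: float
    klass: str
    rank: float  # normalized within-model rank; 1.0 = most FRD


def build_table(
    parameter_names: list[str],
    b_slow: np.ndarray,
    b_fast_scaled: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[RateDependenceEntry]:
    """Per-parameter B_RD table with classes and normalized ranks.

    Ranks run 1..P from the highest B_RD (most RRD) to the lowest (most
    FRD), normalized by P, so the most FRD parameter gets rank 1.0.  Ties
    are broken by registry order (stable sort).
    """
    b_slow = np.asarray(b_slow, dtype=float)
    b_fast_scaled = np.asarray(b_fast_scaled, dtype=float)
    if not (len(parameter_names) == len(b_slow) == len(b_fast_scaled)):
        raise ValueError("length mismatch")
    brd = np.array([compute_brd(s, f) for s, f in zip(b_slow, b_fast_scaled)])
    order = np.argsort(-brd, kind="stable")  # descending B_RD, registry-stable ties
    p = len(brd)
    rank = np.empty(p)
    rank[order] = (np.arange(p) + 1) / p
    return [
        RateDependenceEntry(
            parameter=parameter_names[i],
            b_slow=float(b_slow[i]),
            b_fast=float(b_fast_scaled[i]),
            b_rd=float(brd[i]),
            klass=classify(brd[i], threshold),
            rank=float(rank[i]),
        )
        for i in range(p)
    ]


def table_frame(entries: list[RateDependenceEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "B_slow": [e.b_slow for e in entries],
            "B_fast_scaled": [e.b_fast for e in entries],
            "B_RD": [e.b_rd for e in entries],
            "class": [e.klass for e in entries],
            "rank": [e.rank for e in entries],
        }
    ).set_index("parameter")


def percent_frd(
    entries: list[RateDependenceEntry], threshold: float = DEFAULT_THRESHOLD
) -> float:
    """Percentage of parameters classified FRD at ``threshold``."""
    if not entries:
        raise ValueError("empty entry list")
    n_frd = sum(1 for e in entries if classify(e.b_rd, threshold) == "FRD")
    return 100.0 * n_frd / len(entries)


def consensus_rank(
    tables: dict[str, list[RateDependenceEntry]],
    name_map: dict[str, dict[str, str]] | None = None,
) -> pd.DataFrame:
    """Average normalized rank of each (shared) parameter across models.

    ``name_map`` maps model id -> {model-local name: shared name}; absent
    entries keep their local names.  Parameters present in no model are
    simply absent from the output.  Returns a frame indexed by shared name
    with columns ``average_rank`` (in (0, 1]; ~1 = consistently FRD) and
    ``n_models``.
    """
    if not tables:
        raise ValueError("need at least one model table")
    acc: dict[str, list[float]] = {}
    for model_id, entries in tables.items():
        local_map = (name_map or {}).get(model_id, {})
        for e in entries:
            shared = local_map.get(e.parameter, e.parameter)
            acc.setdefault(shared, []).append(e.rank)
    frame = pd.DataFrame(
        {
            "average_rank": {k: float(np.mean(v)) for k, v in acc.items()},
            "n_models": {k: len(v) for k, v in acc.items()},
        }
    )
    frame.index.name = "parameter"
    return frame.sort_values("average_rank")


def heatmap_matrix(
    tables: dict[str, list[RateDependenceEntry]],
    parameters: list[str],
    threshold: float = DISPLAY_THRESHOLD,
) -> pd.DataFrame:
    """Class matrix (parameter x model) at the display threshold.

    Cells hold "RRD"/"FRD"/"NRD", or "" for parameters a model lacks.
    """
    data = {}
    for model_id, entries in tables.items():
        by_name = {e.parameter: e for e in entries}
        data[model_id] = [
            classify(by_name[p].b_rd, threshold) if p in by_name else ""
            for p in parameters
        ]
    return pd.DataFrame(data, index=pd.Index(parameters, name="parameter"))
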