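"""Trial-log readers/writers, run configuration, and report reproduction.

All simulated agents, synthetic participants and (optionally ingested)
real data share one flat CSV trial-log schema::

    id,experiment,mapping,curriculum,block,trial,phase,color,shape,
    truth_x,truth_y,resp_x,resp_y,points

with coordinates in px, arena-centered, y increasing upward.  A single
analysis path then serves every data source.

:func:`reproduce_stats` recomputes the study-level statistics whose
inputs are printed count tables (generalizer contingency tables, the
structural trial counts, and the exclusion totals), giving a fast
end-to-end check that the statistical machinery reproduces the reference
values exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .cohort_stats import ContingencyTable2x2, chi_square_2x2
from .task_env import (
    ARENA_RADIUS_PX,
    Arena,
    Cue,
    N_BLOCKS,
    N_TEST_TRIALS_PER_BLOCK,
    N_TRAIN_TRIALS_PER_BLOCK,
    TrialRecord,
)

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "RunConfig",
    "REFERENCE_CHI_SQUARE_TABLES",
    "REFERENCE_EXCLUSIONS_PER_CONDITION",
    "REFERENCE_COHORT_SIZE",
    "write_trial_log",
    "read_trial_log",
    "records_to_frame",
    "reproduce_stats",
]

logger = logging.getLogger(__name__)

TRIAL_LOG_COLUMNS = [
    "id",
    "experiment",
    "mapping",
    "curriculum",
    "block",
    "trial",
    "phase",
    "color",
    "shape",
    "truth_x",
    "truth_y",
    "resp_x",
    "resp_y",
    "points",
]


@dataclass(frozen=True)
class RunConfig:
    """Reproducible description of one simulation/analysis run."""

    experiment: int = 1
    mapping: str = "grid"
    condition: str = "aligned"
    agent: str = "hebbian"
    n_agents: int = 20
    seed: int = 0
    sigma: float = 20.0
    lattice_step: float = 2.0
    n_resamples: int = 10_000
    arena_radius: float = ARENA_RADIUS_PX
    output_dir: str = "results"
    agent_hyperparams: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        """Short stable hash embedded in every output for provenance."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Trial logs
# ---------------------------------------------------------------------------

def records_to_frame(
    records: Iterable[TrialRecord],
    experiment: int = 1,
    mapping: str = "grid",
    curriculum: str = "aligned",
) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.participant_id,
                "experiment": experiment,
                "mapping": mapping,
                "curriculum": curriculum,
                "block": r.block,
                "trial": r.trial_in_block,
                "phase": r.phase,
                "color": r.cue.color_level,
                "shape": r.cue.shape_level,
                "truth_x": r.truth[0],
                "truth_y": r.truth[1],
                "resp_x": r.response[0] if r.response else None,
                "resp_y": r.response[1] if r.response else None,
                "points": r.points,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def write_trial_log(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def read_trial_log(
    path: str | Path, arena: Optional[Arena] = None
) -> list[TrialRecord]:
    """Read and validate a trial-log CSV into :class:`TrialRecord` objects.

    Malformed rows are reported with their line numbers; responses
    outside the arena load with a validation warning (they are clamped
    downstream by the likelihood code, not here).
    """
    arena = arena or Arena()
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in TRIAL_LOG_COLUMNS]
    if missing or extra:
        raise ValueError(
            f"trial log schema mismatch: missing columns {missing}, "
            f"unexpected columns {extra}"
        )
    records: list[TrialRecord] = []
    n_outside = 0
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            response = None
            points = None
            if pd.notna(row["resp_x"]) and pd.notna(row["resp_y"]):
                response = (float(row["resp_x"]), float(row["resp_y"]))
                if not arena.contains(*response):
                    n_outside += 1
            if pd.notna(row["points"]):
                points = int(row["points"])
            records.append(
                TrialRecord(
                    participant_id=str(row["id"]),
                    block=int(row["block"]),
                    trial_in_block=int(row["trial"]),
                    phase=str(row["phase"]),  # type: ignore[arg-type]
                    cue=Cue(int(row["color"]), int(row["shape"])),
                    truth=(float(row["truth_x"]), float(row["truth_y"])),
                    response=response,
                    points=points,
                )
            )
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"malformed trial-log row at line {line}: {exc}") from exc
    if n_outside:
        logger.warning("%d response(s) outside the arena in %s", n_outside, path)
    return records


# ---------------------------------------------------------------------------
# Reference statistics from printed count tables
# ---------------------------------------------------------------------------

#: Generalizer-count comparisons whose inputs are reported count tables:
#: (name, (k1, n1, k2, n2), reference chi-square to one decimal).
REFERENCE_CHI_SQUARE_TABLES: tuple[tuple[str, tuple[int, int, int, int], float], ...] = (
    ("human_grid_aligned_vs_misaligned", (47, 63, 21, 61), 20.2),
    ("human_polar_aligned_vs_misaligned", (49, 58, 39, 56), 3.6),
    ("human_grid_blocked_vs_interleaved", (47, 58, 36, 60), 6.3),
    ("human_polar_blocked_vs_interleaved", (57, 62, 48, 60), 3.6),
    ("hebbian_grid_aligned_vs_misaligned", (52, 63, 32, 61), 12.8),
    ("hebbian_polar_aligned_vs_misaligned", (52, 58, 8, 56), 64.9),
    ("unilateral_attribution_human_vs_matched", (277, 478, 75, 478), 183.5),
)

#: Reported exclusion counts per condition (grid a/m/b/i, then polar).
REFERENCE_EXCLUSIONS_PER_CONDITION: tuple[int, ...] = (13, 16, 15, 16, 19, 19, 16, 13)

#: Participants entering the policy-sequence analysis.
REFERENCE_COHORT_SIZE: int = 478


def reproduce_stats(config: Optional[RunConfig] = None) -> dict:
    """Recompute all count-based reference statistics and structural counts.

    Returns a report dict with, per chi-square, the input table, the
    recomputed statistic and p-value, and whether it matches the
    reference value to one decimal; plus the structural counts implied
    by the block design.
    """
    config = config or RunConfig()
    chi_rows = []
    for name, (k1, n1, k2, n2), ref in REFERENCE_CHI_SQUARE_TABLES:
        stat, p = chi_square_2x2(ContingencyTable2x2.from_successes(k1, n1, k2, n2))
        chi_rows.append(
            {
                "name": name,
                "counts": [k1, n1, k2, n2],
                "chi_square": round(stat, 6),
                "p_value": float(f"{p:.6g}"),
                "reference": ref,
                "matches_reference": round(stat, 1) == ref,
            }
        )
    structural = {
        "train_trials_per_session": N_TRAIN_TRIALS_PER_BLOCK * N_BLOCKS,
        "test_trials_per_session": N_TEST_TRIALS_PER_BLOCK * N_BLOCKS,
        "cohort_test_responses": REFERENCE_COHORT_SIZE
        * N_TEST_TRIALS_PER_BLOCK
        * N_BLOCKS,
        "total_exclusions": sum(REFERENCE_EXCLUSIONS_PER_CONDITION),
    }
    return {
        "config_hash": config.config_hash(),
        "chi_square": chi_rows,
        "structural_counts": structural,
        "all_chi_square_match": all(r["matches_reference"] for r in chi_rows),
    }
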