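"""CTMD scoring: per-ligand replica c(t) series -> one stability score.

The CTMD score of a ligand pose is the minimum, over a few short
independent well-tempered metadynamics replicas, of the terminal value of
the c(t) estimator.  A stable pose traps the walker so tempered bias piles
up locally and c(t) climbs; an unstable pose lets the walker escape early,
leaving a low c(t).  Taking the minimum over replicas makes the score
conservative: one early escape is enough to mark a pose unstable.  Higher
score = more stable pose = predicted binder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ct import CtSeries, Grid, ct_series
from .metad import HillList, ThermoParams

__all__ = ["ReplicaSet", "LigandScore", "terminal_ct", "ctmd_score", "rank_ligands"]

#: replicas per ligand in the standard protocol
DEFAULT_N_REPLICAS = 3


@dataclass
class ReplicaSet:
    """Independent metadynamics replicas of one ligand pose."""

    ligand_id: str
    replicas: list  # HillList or CtSeries entries

    def __post_init__(self) -> None:
        if len(self.replicas) < 1:
            raise ValueError("need at least one replica")

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)


@dataclass(frozen=True)
class LigandScore:
    ligand_id: str
    score: float
    per_replica_terminal_ct: tuple[float, ...]


def terminal_ct(series: CtSeries) -> float:
    """The c(t) value at the final time point of a series."""
    return series.terminal


def ctmd_score(
    rep: ReplicaSet,
    grid: Grid | None = None,
    thermo: ThermoParams | None = None,
    stride: float | None = None,
) -> LigandScore:
    """Score = min over replicas of the terminal c(t).

    Replicas given as HillLists are converted to c(t) series on ``grid``;
    replicas given as CtSeries are used directly.  An empty HillList scores
    zero (no bias ever deposited, so c(t) = 0 throughout).
    """
    terminals = []
    for i, rep_i in enumerate(rep.replicas):
        try:
            if isinstance(rep_i, CtSeries):
                terminals.append(terminal_ct(rep_i))
            else:
                hills: HillList = rep_i
                if grid is None:
                    raise ValueError("grid required to evaluate c(t) from hills")
                th = thermo if thermo is not None else hills.thermo
                if not len(hills):
                    terminals.append(0.0)
                    continue
                st = stride if stride is not None else max(float(hills.times[-1]) / 50.0, 1e-12)
                terminals.append(terminal_ct(ct_series(hills, st, grid, th)))
        except Exception as exc:
            raise RuntimeError(
                f"c(t) evaluation failed for ligand {rep.ligand_id!r} replica {i}: {exc}"
            ) from exc
    return LigandScore(rep.ligand_id, min(terminals), tuple(terminals))


def rank_ligands(scores: list[LigandScore]) -> pd.DataFrame:
    """Deterministic ranking: score descending, ties by ligand_id ascending.

    Returns a DataFrame with columns rank (1-based), ligand_id, score.
    """
    if not scores:
        raise ValueError("no scores to rank")
    ids = [s.ligand_id for s in scores]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ligand_id(s): {dupes}")
    ordered = sorted(scores, key=lambda s: (-s.score, s.ligand_id))
    return pd.DataFrame(
        {
            "rank": range(1, len(ordered) + 1),
            "ligand_id": [s.ligand_id for s in ordered],
            "score": [s.score for s in ordered],
        }
    )
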