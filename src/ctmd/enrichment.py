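"""Early-enrichment evaluation: labels, enrichment factors, BEDROC,
and the binder-subsampling protocol.

A screen is a table of (ligand_id, score, label) rows, label in
{"binder", "nonbinder"}; higher score means ranked earlier.  The
enrichment factor at a selection threshold of xx% is

    EF_xx = (hits in top xx% / (xx% * N)) / (n_binders / N)

i.e. the hit density in the selected head of the ranking relative to the
base hit rate; values above 1 beat random selection.  Selection membership
uses ceil(xx% * N) rows, while the denominator keeps the exact fractional
xx% * N.

BEDROC (Boltzmann-enhanced discrimination of ROC, Truchon & Bailly 2007)
exponentially downweights late ranks, so it rewards putting actives at the
very top; alpha sets how early "early" is (alpha = 20 concentrates ~80% of
the weight in the top ~8%).

The subsampling protocol repeatedly draws k binders with replacement while
keeping the full non-binder set, recomputing EF and BEDROC each time, to
emulate realistic (low) hit rates and yield percentile confidence bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScreenTable",
    "EnrichmentResult",
    "classify_by_pki",
    "hit_rate",
    "ef_at",
    "bedroc",
    "subsample_enrichment",
]

BINDER = "binder"
NONBINDER = "nonbinder"
EXCLUDED = "excluded"

_COLUMNS = ["ligand_id", "score", "label"]


@dataclass(frozen=True)
class EnrichmentResult:
    """EF at one selection threshold."""

    xx: float
    ef: float
    n_selected: int
    hits_in_selection: int


def ScreenTable(records) -> pd.DataFrame:
    """Normalize records into a screen DataFrame (ligand_id, score, label).

    Accepts a DataFrame with those columns or an iterable of
    (ligand_id, score, label) tuples.  Labels must be 'binder'/'nonbinder'.
    """
    if isinstance(records, pd.DataFrame):
        df = records.loc[:, _COLUMNS].copy()
    else:
        df = pd.DataFrame(list(records), columns=_COLUMNS)
    bad = set(df["label"]) - {BINDER, NONBINDER}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    df["score"] = df["score"].astype(float)
    return df.reset_index(drop=True)


def classify_by_pki(pki: float, lower: float = 5.0, upper: float = 6.0) -> str:
    """Label a compound from its pKi with an ambiguity band.

    pKi below ``lower`` -> nonbinder; above ``upper`` -> binder; the band in
    between is 'excluded' so borderline affinities never contaminate either
    class.
    """
    if not math.isfinite(pki):
        raise ValueError(f"non-finite pKi: {pki}")
    if lower > upper:
        raise ValueError("lower threshold must not exceed upper")
    if pki < lower:
        return NONBINDER
    if pki > upper:
        return BINDER
    return EXCLUDED


def hit_rate(table: pd.DataFrame) -> float:
    """Fraction of binders in the library (the EF100 normalization)."""
    n = len(table)
    if n == 0:
        raise ValueError("empty screen table")
    return float((table["label"] == BINDER).sum()) / n


def _ranked(table: pd.DataFrame) -> pd.DataFrame:
    """Deterministic ranking: score desc, ligand_id asc, then replicate
    index asc if present (subsample duplicates)."""
    by = ["score", "ligand_id"]
    ascending = [False, True]
    if "replicate" in table.columns:
        by.append("replicate")
        ascending.append(True)
    return table.sort_values(by, ascending=ascending, kind="mergesort").reset_index(drop=True)


def ef_at(table: pd.DataFrame, xx: float) -> EnrichmentResult:
    """Enrichment factor at the top xx% of the ranking.

    Counts hits among the top ceil(xx% * N) rows but divides by the exact
    fractional selection size xx% * N, normalized by the base hit rate.
    EF at xx=100 is identically 1.
    """
    if not (0 < xx <= 100):
        raise ValueError("xx must be in (0, 100]")
    n = len(table)
    if n == 0:
        raise ValueError("empty screen table")
    n_binders = int((table["label"] == BINDER).sum())
    if n_binders == 0:
        raise ValueError("EF undefined: no binders in table")
    frac = xx / 100.0 * n
    n_sel = math.ceil(frac - 1e-12)  # guard float fuzz at exact integers
    ranked = _ranked(table)
    hits = int((ranked["label"].iloc[:n_sel] == BINDER).sum())
    ef = (hits / frac) / (n_binders / n)
    return EnrichmentResult(xx=xx, ef=float(ef), n_selected=n_sel, hits_in_selection=hits)


def bedroc(table: pd.DataFrame, alpha: float) -> float:
    """BEDROC with early-recognition parameter alpha.

    RIE is the mean over actives of exp(-alpha * r_i / N) divided by its
    expectation under a uniformly random ranking; BEDROC maps RIE onto
    ~[0, 1] via

        BEDROC = RIE * Ra sinh(a/2) / (cosh(a/2) - cosh(a/2 - a Ra))
                 + 1 / (1 - exp(a (1 - Ra)))

    with Ra = n_actives / N.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    n_total = len(table)
    if n_total == 0:
        raise ValueError("empty screen table")
    ranked = _ranked(table)
    ranks = np.flatnonzero((ranked["label"] == BINDER).to_numpy()) + 1  # 1-based
    n_act = ranks.size
    if n_act == 0:
        raise ValueError("BEDROC undefined: no actives in table")

    a = float(alpha)
    big_n = float(n_total)
    ra = n_act / big_n
    mean_exp = float(np.mean(np.exp(-a * ranks / big_n)))
    uniform_mean = (1.0 / big_n) * (1.0 - math.exp(-a)) / (math.exp(a / big_n) - 1.0)
    rie = mean_exp / uniform_mean
    scale = ra * math.sinh(a / 2.0) / (math.cosh(a / 2.0) - math.cosh(a / 2.0 - a * ra))
    offset = 1.0 / (1.0 - math.exp(a * (1.0 - ra)))
    return float(rie * scale + offset)


def subsample_enrichment(
    table: pd.DataFrame,
    k: int = 5,
    n_repeats: int = 200,
    xx_list=(10.0, 20.0, 30.0),
    alpha_list=(20.0,),
    seed: int = 0,
) -> pd.DataFrame:
    """Binder subsampling with replacement, holding the non-binder set fixed.

    Each repeat draws ``k`` binder rows with replacement (duplicates kept
    as distinct rows sharing a score), keeps every non-binder, and computes
    EF at each threshold in ``xx_list`` plus BEDROC at each alpha in
    ``alpha_list``.  Returns a summary DataFrame with one row per metric:
    columns metric, param, mean, median, ci_lo, ci_hi (2.5/97.5 percentile
    across repeats).  Fully deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    binders = table[table["label"] == BINDER].reset_index(drop=True)
    nonbinders = table[table["label"] == NONBINDER].reset_index(drop=True)
    if len(binders) == 0:
        raise ValueError("no binders to subsample")

    rng = np.random.default_rng(seed)
    values: dict[tuple[str, float], list[float]] = {
        **{("EF", xx): [] for xx in xx_list},
        **{("BEDROC", a): [] for a in alpha_list},
    }
    for _ in range(n_repeats):
        idx = rng.integers(0, len(binders), size=k)
        picked = binders.iloc[idx].reset_index(drop=True)
        sub = pd.concat([picked, nonbinders], ignore_index=True)
        sub["replicate"] = range(len(sub))
        for xx in xx_list:
            values[("EF", xx)].append(ef_at(sub, xx).ef)
        for a in alpha_list:
            values[("BEDROC", a)].append(bedroc(sub, a))

    rows = []
    for (metric, param), vals in values.items():
        arr = np.asarray(vals)
        rows.append(
            {
                "metric": metric,
                "param": param,
                "mean": float(arr.mean()),
                "median": float(np.median(arr)),
                "ci_lo": float(np.percentile(arr, 2.5)),
                "ci_hi": float(np.percentile(arr, 97.5)),
            }
        )
    return pd.DataFrame(rows)
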