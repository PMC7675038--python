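"""Enrichment factors, hit calling, replicate concordance and synergy.

The default enrichment factor compares a combination's count with the uniform
expectation over the full CodeA x CodeB grid:

    EF_i = c_i / (TCs / N) = c_i * N / TCs,      N = |A| * |B|

so the grid mean of EF is exactly 1 whenever TCs > 0, and EF is invariant to
rescaling all counts.  An unselected-library baseline is available as an
option: EF_i = (c_i / TCs) / ((c0_i + pi) / (TCs0 + pi * N)) with pseudocount
pi guarding unsampled reference cells.

Dual-pharmacophore (2+1) synergy compares the same combination's EF in
single-pharmacophore (SP) and dual-pharmacophore (DP) selections through the
ratio EF_dp / max(EF_sp, 1); the floor stops sub-background SP values from
inflating the ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .decode import CountMatrix

logger = logging.getLogger("deldeck")

SYNERGY_CLASSES = ("synergistic", "independent", "sp-only", "background")

# default decision thresholds; chosen so that published-scale exemplars
# (SP 3 -> DP 22 and SP 3 -> DP 1119 synergistic; EF ~112 in both modes
# independent) classify as narrated
DEFAULT_RATIO_MIN = 5.0
DEFAULT_EF_DP_MIN = 10.0
DEFAULT_EF_MIN = 10.0
DEFAULT_COUNT_MIN = 3
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class EnrichmentTable:
    """Per-combination counts and enrichment factors for one selection."""

    table: pd.DataFrame  # columns: code_a, code_b, count, ef
    baseline_mode: str  # "uniform" | "library"
    target: str = ""
    mode: str = "SP"
    replicate_id: int = 0

    def __post_init__(self) -> None:
        required = {"code_a", "code_b", "count", "ef"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"EnrichmentTable missing columns {sorted(missing)}")
        if (self.table["ef"] < 0).any():
            raise ValueError("negative enrichment factor")

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def grid_key(self) -> frozenset:
        return frozenset(zip(self.table["code_a"], self.table["code_b"]))


def enrichment_factors(
    matrix: CountMatrix,
    baseline: str = "uniform",
    reference: Optional[CountMatrix] = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    target: str = "",
    mode: str = "SP",
    replicate_id: int = 0,
) -> EnrichmentTable:
    """Compute per-combination enrichment factors over the full grid.

    `baseline="uniform"` needs no reference; `baseline="library"` normalises
    against an unselected-library CountMatrix on the same grid.
    """
    if matrix.tcs == 0:
        raise ValueError("cannot compute enrichment factors: TCs = 0")
    df = matrix.to_frame(drop_zero=False)
    n_cells = matrix.grid_size
    if baseline == "uniform":
        df["ef"] = df["count"] * n_cells / matrix.tcs
    elif baseline == "library":
        if reference is None:
            raise ValueError("library baseline requires an unselected reference matrix")
        if reference.a_ids != matrix.a_ids or reference.b_ids != matrix.b_ids:
            raise ValueError("reference matrix grid does not match")
        ref = reference.to_frame(drop_zero=False)
        sel_freq = df["count"] / matrix.tcs
        ref_freq = (ref["count"] + pseudocount) / (reference.tcs + pseudocount * n_cells)
        df["ef"] = (sel_freq / ref_freq).to_numpy()
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    return EnrichmentTable(
        table=df, baseline_mode=baseline, target=target, mode=mode, replicate_id=replicate_id
    )


def call_hits(
    table: EnrichmentTable,
    ef_min: float = DEFAULT_EF_MIN,
    count_min: int = DEFAULT_COUNT_MIN,
) -> pd.DataFrame:
    """Rows with ef >= ef_min and count >= count_min, ranked by EF descending.

    Ties break lexicographically on (code_a, code_b) so the ranking is stable.
    """
    if ef_min < 0 or count_min < 0:
        raise ValueError("thresholds must be >= 0")
    df = table.table
    hits = df[(df["ef"] >= ef_min) & (df["count"] >= count_min)].copy()
    hits = hits.sort_values(
        ["ef", "code_a", "code_b"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    hits.insert(0, "rank", np.arange(1, len(hits) + 1))
    return hits


def replicate_concordance(
    tables: Sequence[EnrichmentTable],
    ef_min: float = DEFAULT_EF_MIN,
    count_min: int = DEFAULT_COUNT_MIN,
) -> pd.DataFrame:
    """Consensus hits: combinations passing thresholds in ALL replicates.

    Reports per-combination minimum and median EF across replicates, ranked
    by minimum EF descending.
    """
    if len(tables) < 2:
        raise ValueError(f"replicate concordance needs >= 2 tables, got {len(tables)}")
    key = tables[0].grid_key()
    for t in tables[1:]:
        if t.grid_key() != key:
            raise ValueError("replicate tables are not on the same grid")
    hit_sets = []
    efs: dict[tuple[str, str], list[float]] = {}
    for t in tables:
        hits = call_hits(t, ef_min, count_min)
        pairs = set(zip(hits["code_a"], hits["code_b"]))
        hit_sets.append(pairs)
        for _, row in hits.iterrows():
            efs.setdefault((row["code_a"], row["code_b"]), []).append(float(row["ef"]))
    consensus = set.intersection(*hit_sets)
    rows = [
        {
            "code_a": a,
            "code_b": b,
            "n_replicates": len(tables),
            "ef_min": min(efs[(a, b)]),
            "ef_median": float(np.median(efs[(a, b)])),
        }
        for a, b in consensus
    ]
    out = pd.DataFrame(rows, columns=["code_a", "code_b", "n_replicates", "ef_min", "ef_median"])
    return out.sort_values(
        ["ef_min", "code_a", "code_b"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# SP vs DP synergy
# ---------------------------------------------------------------------------

def classify_synergy(
    ef_sp: float,
    ef_dp: float,
    ratio_min: float = DEFAULT_RATIO_MIN,
    ef_dp_min: float = DEFAULT_EF_DP_MIN,
) -> tuple[float, str]:
    """Classify one combination from its SP and DP enrichment factors.

    Returns (synergy_ratio, class) with ratio = ef_dp / max(ef_sp, 1) and
    mutually exclusive classes:

    - ``synergistic``: ratio >= ratio_min and ef_dp >= ef_dp_min
    - ``independent``: both EFs >= ef_dp_min but ratio < ratio_min
    - ``sp-only``: ef_sp >= ef_dp_min while ef_dp < ef_dp_min
    - ``background``: everything else
    """
    ratio = ef_dp / max(ef_sp, 1.0)
    if ratio >= ratio_min and ef_dp >= ef_dp_min:
        cls = "synergistic"
    elif ef_sp >= ef_dp_min and ef_dp >= ef_dp_min and ratio < ratio_min:
        cls = "independent"
    elif ef_sp >= ef_dp_min and ef_dp < ef_dp_min:
        cls = "sp-only"
    else:
        cls = "background"
    return ratio, cls


@dataclass
class SynergyReport:
    """Paired SP/DP enrichment comparison for affinity-maturation calls."""

    table: pd.DataFrame  # code_a, code_b, ef_sp, ef_dp, synergy_ratio, classification
    hit_label: str = ""

    def hits(self, classification: str = "synergistic") -> pd.DataFrame:
        df = self.table[self.table["classification"] == classification]
        return df.sort_values(
            ["synergy_ratio", "code_a", "code_b"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def synergy_analysis(
    sp: EnrichmentTable,
    dp: EnrichmentTable,
    ratio_min: float = DEFAULT_RATIO_MIN,
    ef_dp_min: float = DEFAULT_EF_DP_MIN,
    hit_label: str = "",
) -> SynergyReport:
    """Join SP and DP enrichment tables and classify every combination."""
    if sp.grid_key() != dp.grid_key():
        raise ValueError("SP and DP tables are not on the same grid")
    merged = sp.table.merge(
        dp.table, on=["code_a", "code_b"], suffixes=("_sp", "_dp"), validate="one_to_one"
    )
    ef_sp = merged["ef_sp"].to_numpy()
    ef_dp = merged["ef_dp"].to_numpy()
    ratio = ef_dp / np.maximum(ef_sp, 1.0)
    cls = np.full(len(merged), "background", dtype=object)
    cls[(ef_sp >= ef_dp_min) & (ef_dp < ef_dp_min)] = "sp-only"
    cls[(ef_sp >= ef_dp_min) & (ef_dp >= ef_dp_min) & (ratio < ratio_min)] = "independent"
    cls[(ratio >= ratio_min) & (ef_dp >= ef_dp_min)] = "synergistic"
    out = pd.DataFrame(
        {
            "code_a": merged["code_a"],
            "code_b": merged["code_b"],
            "count_sp": merged["count_sp"],
            "count_dp": merged["count_dp"],
            "ef_sp": ef_sp,
            "ef_dp": ef_dp,
            "synergy_ratio": ratio,
            "classification": cls,
        }
    )
    label = hit_label or getattr(dp, "target", "")
    logger.info(
        "synergy analysis: %s",
        out["classification"].value_counts().to_dict(),
    )
    return SynergyReport(table=out, hit_label=label)
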