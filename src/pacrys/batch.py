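"""All-vs-all comparison driver with multi-process parallelism.

Comparison pairs are embarrassingly parallel: the pair list is split into
contiguous blocks, each worker process compares its block independently, and
the merged table is sorted by pair index — so the result is identical
regardless of worker count.  Self-pairs are included by default as a built-in
sanity check (they must come out at RMSD_N ≈ 0).
"""

from __future__ import annotations

import multiprocessing as mp
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ComparisonResult, PacParams, compare_crystals

__all__ = ["ComparisonTable", "all_vs_all", "comparison_row"]

_COLUMNS = [
    "name_a", "name_b", "rmsd_n", "rg_a", "rg_b", "rg_average",
    "asphericity_a", "asphericity_b", "anisotropy_a", "anisotropy_b",
    "n", "linkage", "rmsd_1", "rmsd_3",
]


def comparison_row(name_a: str, name_b: str, result: ComparisonResult,
                   params: PacParams) -> dict:
    """Flatten one comparison result into a table row."""
    return {
        "name_a": name_a,
        "name_b": name_b,
        "rmsd_n": result.rmsd_n,
        "rg_a": result.cluster_metrics_1.rg,
        "rg_b": result.cluster_metrics_2.rg,
        "rg_average": result.rg_average,
        "asphericity_a": result.cluster_metrics_1.asphericity,
        "asphericity_b": result.cluster_metrics_2.asphericity,
        "anisotropy_a": result.cluster_metrics_1.anisotropy,
        "anisotropy_b": result.cluster_metrics_2.anisotropy,
        "n": params.n,
        "linkage": params.linkage,
        "rmsd_1": result.trace["rmsd_1"],
        "rmsd_3": result.trace["rmsd_3"],
    }


@dataclass
class ComparisonTable:
    """Result table of an all-vs-all run."""

    frame: pd.DataFrame

    def to_tsv(self, path=None) -> str | None:
        """Tab-separated text with a commented header and fixed 6-decimal
        formatting, so identical runs produce byte-identical files."""
        lines = ["# " + "\t".join(_COLUMNS)]
        for _, row in self.frame.iterrows():
            cells = []
            for col in _COLUMNS:
                val = row[col]
                if isinstance(val, float):
                    cells.append(f"{val:.6f}")
                else:
                    cells.append(str(val))
            lines.append("\t".join(cells))
        text = "\n".join(lines) + "\n"
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def _compare_block(args) -> list:
    crystals, params, block = args
    rows = []
    for i, j in block:
        try:
            result = compare_crystals(crystals[i], crystals[j], params)
        except Exception as exc:  # surface the failing pair
            raise RuntimeError(
                f"comparison failed for pair ({crystals[i].name}, {crystals[j].name}): {exc}"
            ) from exc
        rows.append(comparison_row(crystals[i].name, crystals[j].name, result, params))
    return rows


def all_vs_all(crystals, params: PacParams | None = None, workers: int = 1,
               include_self: bool = True) -> ComparisonTable:
    """Compare every unique pair of crystals (self-pairs optional).

    ``workers`` > 1 distributes contiguous blocks of the pair list over a
    process pool; the merged table is bit-identical to the single-worker run.
    """
    if len(crystals) < 2:
        raise ValueError("need at least two crystals")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    params = params or PacParams()

    pairs = [(i, j) for i in range(len(crystals))
             for j in range(i if include_self else i + 1, len(crystals))
             if include_self or i != j]

    if workers == 1:
        rows = _compare_block((crystals, params, pairs))
    else:
        workers = min(workers, len(pairs))
        bounds = np.linspace(0, len(pairs), workers + 1).astype(int)
        blocks = [(crystals, params, pairs[bounds[k]:bounds[k + 1]])
                  for k in range(workers)]
        ctx = mp.get_context("fork" if "fork" in mp.get_all_start_methods() else "spawn")
        with ctx.Pool(workers) as pool:
            rows = [row for block_rows in pool.map(_compare_block, blocks)
                    for row in block_rows]

    frame = pd.DataFrame(rows, columns=_COLUMNS)
    frame = frame.sort_values(["name_a", "name_b"], kind="stable").reset_index(drop=True)
    return ComparisonTable(frame=frame)
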