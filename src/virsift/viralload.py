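"""Viral-load quantification across pooled RNA-seq libraries.

The abundance measure is RPKM (reads per kilobase of genome per million
mapped reads) computed from filtered read-pair counts, divided by the number
of individuals pooled in the library, then ln(x+1)-transformed for display.
Values below the detection floor (default 0.001, applied on the transformed
scale) are classified as virus-free. Queens and workers are compared with
classical paired t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, DegenerateTestError, InputError

DETECTION_FLOOR = 0.001


@dataclass
class LoadRecord:
    """Viral load of one virus in one library."""

    library_id: str
    virus_id: str
    pair_count: int
    total_mapped: int
    rpkm: float
    rpkm_per_ind: float
    ln1p: float
    detected: bool


def rpkm(read_count: int, genome_len_bp: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of genome per million mapped reads."""
    if genome_len_bp <= 0 or total_mapped_reads <= 0:
        raise InputError("genome length and total mapped reads must be positive")
    if read_count < 0:
        raise InputError("read count must be non-negative")
    return read_count * 1e9 / (genome_len_bp * total_mapped_reads)


def per_individual(value: float, n_individuals: int) -> float:
    """Scale a library-level RPKM to a single pooled individual."""
    if n_individuals < 1:
        raise InputError("n_individuals must be >= 1")
    return value / n_individuals


def classify_detection(values, floor: float = DETECTION_FLOOR):
    """Detection mask on ln(x+1)-scale values: detected iff value >= floor."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise InputError("transformed load values must be non-negative")
    return arr >= floor


def make_load_record(
    library_id: str,
    virus_id: str,
    pair_count: int,
    genome_len_bp: int,
    total_mapped: int,
    n_individuals: int,
    floor: float = DETECTION_FLOOR,
) -> LoadRecord:
    """Assemble the full RPKM → per-individual → ln(x+1) → detection chain."""
    r = rpkm(pair_count, genome_len_bp, total_mapped)
    ri = per_individual(r, n_individuals)
    ln1p = math.log1p(ri)
    return LoadRecord(
        library_id=library_id,
        virus_id=virus_id,
        pair_count=pair_count,
        total_mapped=total_mapped,
        rpkm=r,
        rpkm_per_ind=ri,
        ln1p=ln1p,
        detected=bool(ln1p >= floor),
    )


def load_table(records: Sequence[LoadRecord]) -> pd.DataFrame:
    """Long-format table of load records."""
    return pd.DataFrame(
        {
            "library_id": [r.library_id for r in records],
            "virus_id": [r.virus_id for r in records],
            "pair_count": [r.pair_count for r in records],
            "total_mapped": [r.total_mapped for r in records],
            "rpkm": [r.rpkm for r in records],
            "rpkm_per_ind": [r.rpkm_per_ind for r in records],
            "ln1p": [r.ln1p for r in records],
            "detected": [r.detected for r in records],
        }
    )


def heatmap_matrix(
    records: Sequence[LoadRecord],
    row_order: Sequence[str],
    col_order: Sequence[str],
) -> pd.DataFrame:
    """ln(x+1) matrix with libraries as rows and viruses as columns.

    Every (library, virus) cell must be present exactly once.
    """
    seen: dict[tuple[str, str], float] = {}
    for r in records:
        key = (r.library_id, r.virus_id)
        if key in seen:
            raise ConsistencyError(f"duplicate load record for {key}")
        seen[key] = r.ln1p
    data = np.empty((len(row_order), len(col_order)))
    for i, lib in enumerate(row_order):
        for j, vir in enumerate(col_order):
            if (lib, vir) not in seen:
                raise ConsistencyError(f"missing load record for ({lib!r}, {vir!r})")
            data[i, j] = seen[(lib, vir)]
    return pd.DataFrame(data, index=list(row_order), columns=list(col_order))


def paired_caste_test(
    queen_values: Sequence[float], worker_values: Sequence[float]
) -> tuple[float, int, float]:
    """Paired t-test of queen vs. worker viral loads: (t, df, two-sided p)."""
    q = np.asarray(queen_values, dtype=float)
    w = np.asarray(worker_values, dtype=float)
    if q.shape != w.shape:
        raise InputError("queen and worker vectors must be the same length")
    n = q.size
    if n < 2:
        raise DegenerateTestError("paired t-test needs at least two pairs")
    if np.var(q - w, ddof=1) == 0:
        raise DegenerateTestError("zero variance of paired differences")
    res = stats.ttest_rel(q, w)
    return float(res.statistic), n - 1, float(res.pvalue)


def plot_heatmap(matrix: pd.DataFrame, path, floor: float = DETECTION_FLOOR) -> None:
    """Render the ln(x+1) load matrix as a heat-map image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1.2 + 0.6 * matrix.shape[1], 1.0 + 0.35 * matrix.shape[0])
    )
    shown = matrix.where(matrix >= floor)
    im = ax.imshow(shown.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    fig.colorbar(im, ax=ax, label="ln(RPKM per individual + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
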