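"""Agreement statistics between two methods' species tables.

Two pipelines applied to the same samples rarely produce identical
tables; what matters is whether they rank species abundances the same
way (Kendall tau-b, tie-corrected), agree on presence/absence (Cohen's
kappa, chance-corrected), and recover similar community structure
(Bray-Curtis dissimilarity).  ``median_agreement`` runs these per sample
across a grid of minimum-read thresholds and aggregation levels and
reports medians, the summary the per-sample statistics are reduced to.
A three-way overlap count supports validation against an independent
species checklist.

Per-sample vectors are laid over the union of species detected anywhere
by either method, with absences as zeros.  Samples whose statistic is
undefined (all-tied vectors for tau-b, chance agreement of 1 for kappa)
return NaN and are excluded from medians with a logged count.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis
from sklearn.metrics import cohen_kappa_score

from .pipeline import SampleTable, aggregate, apply_min_reads

__all__ = [
    "kendall_tau_b",
    "cohen_kappa",
    "bray_curtis",
    "bray_curtis_matrix",
    "median_agreement",
    "richness_correlation",
    "overlap_counts",
]

DEFAULT_MIN_READS_GRID = (0, 5, 10, 25, 50, 75, 100)


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Kendall rank correlation between two count vectors.

    ``tau_b = (P - Q) / sqrt((P + Q + T_x)(P + Q + T_y))`` over all pairs,
    with ties counted on each side.  Returns NaN (undefined) for vectors
    shorter than 2 or entirely tied on either side.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def cohen_kappa(pres_a: Sequence[bool], pres_b: Sequence[bool]) -> float:
    """Chance-corrected presence/absence agreement, ``(p_o - p_e)/(1 - p_e)``.

    Expected agreement ``p_e`` comes from the 2x2 marginals.  Returns NaN
    when ``p_e = 1`` (both vectors constant and equal — agreement is
    indistinguishable from chance).
    """
    a = np.asarray(pres_a, dtype=bool)
    b = np.asarray(pres_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size == 0:
        raise ValueError("empty presence vectors")
    pa, pb = a.mean(), b.mean()
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        return float("nan")
    return float(cohen_kappa_score(a, b, labels=[False, True]))


def bray_curtis(counts_a: Sequence[float], counts_b: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity ``1 - 2 sum(min) / (sum a + sum b)`` in [0, 1].

    NaN (undefined) when both vectors are all-zero.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("count vectors must be non-negative")
    if a.sum() == 0 and b.sum() == 0:
        return float("nan")
    return float(braycurtis(a, b))


def bray_curtis_matrix(table: SampleTable, level: str = "filter") -> pd.DataFrame:
    """Square Bray-Curtis dissimilarity matrix between samples at a level."""
    wide = aggregate(table, level).wide()
    ids = list(wide.index)
    mat = np.zeros((len(ids), len(ids)))
    vals = wide.to_numpy(dtype=float)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            mat[i, j] = mat[j, i] = bray_curtis(vals[i], vals[j])
    return pd.DataFrame(mat, index=ids, columns=ids)


def _paired_vectors(
    ta: SampleTable, tb: SampleTable
) -> tuple[list[str], list[str], pd.DataFrame, pd.DataFrame]:
    shared = sorted(set(ta.sample_ids) & set(tb.sample_ids))
    if not shared:
        raise ValueError("the two tables share no samples")
    universe = sorted(set(ta.species) | set(tb.species))
    wa = ta.wide().reindex(index=shared, columns=universe, fill_value=0).fillna(0)
    wb = tb.wide().reindex(index=shared, columns=universe, fill_value=0).fillna(0)
    return shared, universe, wa, wb


def median_agreement(
    table_a: SampleTable,
    table_b: SampleTable,
    level: str = "filter",
    min_reads_grid: Iterable[int] = DEFAULT_MIN_READS_GRID,
) -> pd.DataFrame:
    """Median per-sample tau-b and kappa across a min-read threshold grid.

    For each grid value the filter is applied to both tables at the
    replicate level, both are aggregated to ``level``, and one tau-b
    (counts) and one kappa (presence/absence) are computed per shared
    sample.  One report row per grid value with medians, ranges, and the
    number of samples where each statistic was undefined (excluded from
    the median).
    """
    rows = []
    for g in min_reads_grid:
        ta = aggregate(apply_min_reads(table_a, g), level)
        tb = aggregate(apply_min_reads(table_b, g), level)
        shared, universe, wa, wb = _paired_vectors(ta, tb)
        taus, kappas = [], []
        for s in shared:
            if not universe:  # nothing detected by either method
                taus.append(float("nan"))
                kappas.append(float("nan"))
                continue
            a = wa.loc[s].to_numpy(dtype=float)
            b = wb.loc[s].to_numpy(dtype=float)
            taus.append(kendall_tau_b(a, b))
            kappas.append(cohen_kappa(a > 0, b > 0))
        taus = np.asarray(taus)
        kappas = np.asarray(kappas)
        rows.append(
            {
                "min_reads": g,
                "n_samples": len(shared),
                "tau_median": float(np.nanmedian(taus)) if np.isfinite(taus).any() else float("nan"),
                "tau_min": float(np.nanmin(taus)) if np.isfinite(taus).any() else float("nan"),
                "tau_max": float(np.nanmax(taus)) if np.isfinite(taus).any() else float("nan"),
                "tau_undefined": int(np.isnan(taus).sum()),
                "kappa_median": float(np.nanmedian(kappas)) if np.isfinite(kappas).any() else float("nan"),
                "kappa_min": float(np.nanmin(kappas)) if np.isfinite(kappas).any() else float("nan"),
                "kappa_max": float(np.nanmax(kappas)) if np.isfinite(kappas).any() else float("nan"),
                "kappa_undefined": int(np.isnan(kappas).sum()),
            }
        )
    return pd.DataFrame(rows)


def richness_correlation(
    table_a: SampleTable, table_b: SampleTable, level: str = "replicate"
) -> float:
    """Pearson correlation of per-sample species richness between methods."""
    ta = aggregate(table_a, level)
    tb = aggregate(table_b, level)
    shared, _, wa, wb = _paired_vectors(ta, tb)
    ra = (wa.to_numpy() > 0).sum(axis=1)
    rb = (wb.to_numpy() > 0).sum(axis=1)
    if len(shared) < 2 or ra.std() == 0 or rb.std() == 0:
        return float("nan")
    return float(stats.pearsonr(ra, rb).statistic)


def overlap_counts(
    set_a: Iterable[str], set_b: Iterable[str], set_c: Iterable[str]
) -> dict[str, int]:
    """Counts of the seven Venn regions of three species sets.

    Keys: ``a_only, b_only, c_only, ab, ac, bc, abc`` (each region
    exclusive of the deeper intersections); region sums reproduce the set
    sizes by inclusion-exclusion.
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab": len((a & b) - abc),
        "ac": len((a & c) - abc),
        "bc": len((b & c) - abc),
        "abc": len(abc),
    }
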