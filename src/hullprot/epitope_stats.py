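"""Layer-coverage statistics and group comparisons for epitope analysis.

For one protein with a hull decomposition and epitope labels:

* ``CREPI_k``  — epitopes at level k / all epitopes;
* ``CREXP_k``  — exposed residues at level k / all exposed residues;
* ``PROP_k``   — epitopes at level k / residues at level k;

and the cumulate analogues over levels ≤ k.  Cross-protein curves are
unweighted means over proteins (a per-residue pool would let large antigens
dominate).  Group comparisons use the Wilcoxon rank-sum (Mann–Whitney U)
test, exact for small untied samples; depth-vs-RSA association is summarised
as the mean per-protein Pearson correlation.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .hull_peeling import HullDecomposition
from .structure_model import EpitopeAnnotation, ResidueKey

__all__ = [
    "LayerStats",
    "ComparisonResult",
    "layer_stats",
    "average_layer_stats",
    "k0_distribution",
    "rank_sum_test",
    "per_protein_pcc",
    "read_s1_table",
    "s1_summary",
]


@dataclasses.dataclass
class LayerStats:
    """Per-layer and cumulate coverage fractions for one protein.

    Arrays are indexed by layer ``k-1`` (length ``n_levels``).  ``crepi`` is
    all-NaN when the protein has no epitopes.
    """

    crepi: np.ndarray
    crexp: np.ndarray
    prop: np.ndarray
    crepi_cum: np.ndarray
    crexp_cum: np.ndarray
    prop_cum: np.ndarray
    n_epitopes: int
    n_exposed: int
    n_levels: int

    def at(self, k: int, cumulate: bool = False) -> Tuple[float, float, float]:
        """(CREPI, CREXP, PROP) at layer k; cumulate values clamp beyond
        ``n_levels`` (the hull is exhausted), per-layer values are 0 there."""
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > self.n_levels:
            if cumulate:
                return (self.crepi_cum[-1], self.crexp_cum[-1], self.prop_cum[-1])
            return (0.0 if self.n_epitopes else float("nan"), 0.0, 0.0)
        i = k - 1
        if cumulate:
            return (self.crepi_cum[i], self.crexp_cum[i], self.prop_cum[i])
        return (self.crepi[i], self.crexp[i], self.prop[i])


@dataclasses.dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    alternative: str
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n_x: int
    n_y: int


def layer_stats(decomp: HullDecomposition, labels: EpitopeAnnotation) -> LayerStats:
    """Count epitope and exposed-residue coverage per hull layer."""
    n_levels = decomp.n_levels
    levels = np.array(list(decomp.residue_level.values()), dtype=int)
    is_epi = np.array(
        [labels.is_epitope(k) for k in decomp.residue_level], dtype=bool
    )
    n_exposed = len(levels)
    n_epitopes = int(is_epi.sum())

    residues_at = np.bincount(levels, minlength=n_levels + 1)[1:]
    epis_at = np.bincount(levels[is_epi], minlength=n_levels + 1)[1:]

    with np.errstate(invalid="ignore", divide="ignore"):
        crepi = epis_at / n_epitopes if n_epitopes else np.full(n_levels, np.nan)
        crexp = residues_at / n_exposed
        prop = np.where(residues_at > 0, epis_at / np.maximum(residues_at, 1), 0.0)
        res_cum = np.cumsum(residues_at)
        epi_cum = np.cumsum(epis_at)
        crepi_cum = epi_cum / n_epitopes if n_epitopes else np.full(n_levels, np.nan)
        crexp_cum = res_cum / n_exposed
        prop_cum = np.where(res_cum > 0, epi_cum / np.maximum(res_cum, 1), 0.0)

    return LayerStats(
        crepi=np.asarray(crepi, dtype=float),
        crexp=crexp.astype(float),
        prop=prop.astype(float),
        crepi_cum=np.asarray(crepi_cum, dtype=float),
        crexp_cum=crexp_cum.astype(float),
        prop_cum=prop_cum.astype(float),
        n_epitopes=n_epitopes,
        n_exposed=n_exposed,
        n_levels=n_levels,
    )


def average_layer_stats(
    stats_list: Sequence[LayerStats],
    k_max: int,
    cumulate: bool = False,
) -> pd.DataFrame:
    """Unweighted cross-protein mean curves over k = 1..k_max.

    Proteins without epitopes are excluded from the CREPI and PROP averages
    (their coverage ratios are undefined); layers beyond a protein's own
    ``n_levels`` contribute 0 to its per-layer values and the exhausted-hull
    value to its cumulate ones.
    """
    if not stats_list:
        raise ValueError("empty cohort")
    rows = []
    for k in range(1, k_max + 1):
        crepis, crexps, props = [], [], []
        for st in stats_list:
            crepi, crexp, prop = st.at(k, cumulate=cumulate)
            crexps.append(crexp)
            if st.n_epitopes > 0:
                crepis.append(crepi)
                props.append(prop)
        rows.append(
            {
                "k": k,
                "crepi": float(np.mean(crepis)) if crepis else float("nan"),
                "crexp": float(np.mean(crexps)),
                "prop": float(np.mean(props)) if props else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("k")


def k0_distribution(k0_values: Iterable[int]) -> Tuple[Dict[int, int], Dict[int, float]]:
    """Histogram of per-protein K₀ plus cumulative fractions P(K₀ ≤ k)."""
    values = list(k0_values)
    if not values:
        raise ValueError("no K0 values")
    hist = dict(sorted(Counter(values).items()))
    n = len(values)
    cum: Dict[int, float] = {}
    running = 0
    for k in range(1, max(values) + 1):
        running += hist.get(k, 0)
        cum[k] = running / n
    return hist, cum


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> ComparisonResult:
    """Wilcoxon rank-sum (Mann–Whitney U) comparison of two samples.

    Exact enumeration for small untied samples; normal approximation with tie
    correction otherwise.  Two identical constant samples give p = 1 with a
    warning instead of an undefined statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")

    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        warnings.warn("all values identical across both samples; p = 1")
        return ComparisonResult(
            statistic=len(x) * len(y) / 2.0,
            p_value=1.0,
            alternative=alternative,
            mean_x=float(x.mean()), mean_y=float(y.mean()),
            sd_x=0.0, sd_y=0.0, n_x=len(x), n_y=len(y),
        )

    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(x), len(y)) <= 50
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        mean_x=float(x.mean()), mean_y=float(y.mean()),
        sd_x=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        sd_y=float(y.std(ddof=1)) if len(y) > 1 else 0.0,
        n_x=len(x), n_y=len(y),
    )


def per_protein_pcc(
    feature: Mapping[ResidueKey, float],
    rsa: Mapping[ResidueKey, float],
    grouping: Mapping[ResidueKey, str],
) -> Tuple[float, float, int]:
    """Mean ± SD of the within-protein Pearson correlation feature vs RSA.

    ``grouping`` maps each residue to its protein id.  Proteins with fewer
    than 3 paired residues or zero variance in either column are skipped.
    Returns (mean, sd, n_proteins_used).
    """
    by_protein: Dict[str, List[Tuple[float, float]]] = {}
    for key, fval in feature.items():
        if key in rsa and key in grouping:
            rval = rsa[key]
            if np.isfinite(fval) and np.isfinite(rval):
                by_protein.setdefault(grouping[key], []).append((fval, rval))
    pccs = []
    for pid, pairs in by_protein.items():
        if len(pairs) < 3:
            continue
        f, r = np.array(pairs).T
        if f.std() == 0.0 or r.std() == 0.0:
            continue
        pccs.append(float(stats.pearsonr(f, r).statistic))
    if not pccs:
        raise ValueError("no protein had enough paired residues with variance")
    arr = np.array(pccs)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd, len(arr)


# ---------------------------------------------------------------------------
# S1-style residue feature tables (per-residue RSA + depth values per class)

_S1_COLUMN_ALIASES = {
    "label": ("label", "class", "type", "epitope"),
    "rsa": ("rsa",),
    "chakravarty": ("chakravarty", "chakravarty depth", "depth", "residue depth"),
    "dpx": ("dpx",),
    "hseau": ("hseau",),
    "hsead": ("hsead",),
    "hsebu": ("hsebu",),
    "hsebd": ("hsebd",),
    "hsd": ("hsd", "half space depth"),
}


def read_s1_table(path: str | Path) -> pd.DataFrame:
    """Read a per-residue feature table (XLSX or TSV/CSV) with one row per
    exposed residue, a class column (epitope / non-epitope) and RSA/depth
    columns.  Column headers are matched case-insensitively against common
    aliases; the class column is normalised to a boolean ``epitope`` column.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    rename: Dict[str, str] = {}
    for canonical, aliases in _S1_COLUMN_ALIASES.items():
        for col in df.columns:
            if str(col).strip().lower() in aliases:
                rename[col] = canonical
                break
    df = df.rename(columns=rename)
    if "label" not in df.columns or "rsa" not in df.columns:
        raise ValueError(f"{path}: could not locate the class and RSA columns")
    lab = df["label"].astype(str).str.strip().str.lower()
    df["epitope"] = lab.isin(("epitope", "e", "1", "true", "yes"))
    return df


def s1_summary(df: pd.DataFrame) -> Dict[str, object]:
    """Class counts, per-class mean/SD of each feature column, the maximum
    epitope Chakravarty depth, and one-sided rank-sum p-values (epitope depth
    < non-epitope depth; epitope RSA > non-epitope RSA)."""
    epi = df[df["epitope"]]
    non = df[~df["epitope"]]
    out: Dict[str, object] = {
        "n_epitopes": int(len(epi)),
        "n_non_epitopes": int(len(non)),
    }
    for col in ("rsa", "chakravarty", "dpx", "hseau", "hsead", "hsebu", "hsebd", "hsd"):
        if col not in df.columns:
            continue
        out[f"{col}_epitope_mean"] = float(epi[col].mean())
        out[f"{col}_epitope_sd"] = float(epi[col].std(ddof=1))
        out[f"{col}_non_epitope_mean"] = float(non[col].mean())
        out[f"{col}_non_epitope_sd"] = float(non[col].std(ddof=1))
        alt = "greater" if col == "rsa" else "less"
        res = rank_sum_test(epi[col].to_numpy(), non[col].to_numpy(), alternative=alt)
        out[f"{col}_p_value"] = res.p_value
        out[f"{col}_alternative"] = alt
    if "chakravarty" in df.columns:
        out["max_epitope_chakravarty"] = float(epi["chakravarty"].max())
    return out
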