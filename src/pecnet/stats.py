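"""Group statistics: normality/homogeneity gates, Kruskal-Wallis with
Bonferroni post hocs, edge-wise one-way ANOVA with Bonferroni over edges,
and the 68 -> 7 region grouping used for reporting edge counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Desikan-Killiany parcellation, one hemisphere (34 regions), in the
#: conventional alphabetical order; the 68-ROI list is left then right.
DK34 = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal", "frontalpole", "insula",
]

#: Seven reporting groups: four lobes plus posterior cingulate, anterior
#: cingulate and insula.
SEVEN_GROUPS = ["frontal", "temporal", "parietal", "occipital",
                "PCC", "ACC", "insula"]

_REGION_TO_GROUP = {
    "bankssts": "temporal", "caudalanteriorcingulate": "ACC",
    "caudalmiddlefrontal": "frontal", "cuneus": "occipital",
    "entorhinal": "temporal", "fusiform": "temporal",
    "inferiorparietal": "parietal", "inferiortemporal": "temporal",
    "isthmuscingulate": "PCC", "lateraloccipital": "occipital",
    "lateralorbitofrontal": "frontal", "lingual": "occipital",
    "medialorbitofrontal": "frontal", "middletemporal": "temporal",
    "parahippocampal": "temporal", "paracentral": "frontal",
    "parsopercularis": "frontal", "parsorbitalis": "frontal",
    "parstriangularis": "frontal", "pericalcarine": "occipital",
    "postcentral": "parietal", "posteriorcingulate": "PCC",
    "precentral": "frontal", "precuneus": "parietal",
    "rostralanteriorcingulate": "ACC", "rostralmiddlefrontal": "frontal",
    "superiorfrontal": "frontal", "superiorparietal": "parietal",
    "superiortemporal": "temporal", "supramarginal": "parietal",
    "temporalpole": "temporal", "transversetemporal": "temporal",
    "frontalpole": "frontal", "insula": "insula",
}


def dk68_to_7() -> np.ndarray:
    """Index (0..6 into SEVEN_GROUPS) for each of the 68 DK ROIs (lh then rh)."""
    idx = [SEVEN_GROUPS.index(_REGION_TO_GROUP[r]) for r in DK34]
    return np.array(idx + idx, dtype=int)


@dataclass
class StatResult:
    """One omnibus test with Bonferroni-corrected pairwise post hocs."""

    test: str
    statistic: float
    p_raw: float
    p_corrected: float
    post_hoc: dict[tuple[str, str], float] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_raw) and self.p_corrected < self.p_raw - 1e-15:
            raise ValueError("corrected p below raw p")


def _split(values: np.ndarray, group: np.ndarray):
    labels = pd.unique(pd.Series(group))
    return labels, [np.asarray(values)[np.asarray(group) == g] for g in labels]


def normality_and_homogeneity(values: np.ndarray, group: np.ndarray,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk per group per feature plus Levene across groups.

    Returns one row per feature with the minimum Shapiro p across groups,
    the Levene p, and a `parametric` gate that is True only when no group
    rejects normality.  Constant features are flagged non-parametric.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if values.ndim != 2 or values.shape[0] != len(np.asarray(group)):
        raise ValueError("values must be (subjects, features)")
    labels, _ = _split(values[:, 0], group)
    if any((np.asarray(group) == g).sum() < 3 for g in labels):
        raise ValueError("need >= 3 observations per group")
    rows = []
    for f in range(values.shape[1]):
        col = values[:, f]
        _, groups = _split(col, group)
        if np.ptp(col) == 0:
            rows.append({"feature": f, "shapiro_p_min": np.nan,
                         "levene_p": np.nan, "parametric": False})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw = [sps.shapiro(g).pvalue if np.ptp(g) > 0 else np.nan
                  for g in groups]
            lev = sps.levene(*groups, center="median").pvalue
        sw_min = np.nanmin(sw) if not np.all(np.isnan(sw)) else np.nan
        parametric = bool(np.isfinite(sw_min) and sw_min > alpha)
        rows.append({"feature": f, "shapiro_p_min": sw_min,
                     "levene_p": lev, "parametric": parametric})
    return pd.DataFrame(rows)


def kruskal_wallis_with_posthoc(values: np.ndarray,
                                group: np.ndarray) -> StatResult:
    """Tie-corrected Kruskal-Wallis H plus Dunn-style pairwise rank-sum
    post hocs, Bonferroni-corrected by the number of group pairs."""
    labels, groups = _split(values, group)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(np.asarray(values, dtype=float)) == 0:
        return StatResult("kruskal", 0.0, 1.0, 1.0)
    h, p = sps.kruskal(*groups)
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    post = {}
    for i, j in pairs:
        if np.ptp(np.concatenate([groups[i], groups[j]])) == 0:
            pp = 1.0
        else:
            pp = sps.mannwhitneyu(groups[i], groups[j],
                                  alternative="two-sided").pvalue
        post[(str(labels[i]), str(labels[j]))] = min(1.0, pp * len(pairs))
    return StatResult("kruskal", float(h), float(p), float(p), post_hoc=post)


def anova_edgewise(values: np.ndarray, group: np.ndarray,
                   alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA per edge column with Bonferroni over all edges.

    Returns per-edge F, raw and corrected p, the significance mask at the
    corrected alpha, and a flag for degenerate edges whose within-group
    variance is zero while group means differ (infinite F, reported
    significant).
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    labels = pd.unique(pd.Series(group))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    parts = [values[group == g] for g in labels]
    n_edges = values.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*parts, axis=0)
    f = np.atleast_1d(np.asarray(f, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    gmeans = np.stack([part.mean(axis=0) for part in parts])
    within = np.stack([part.var(axis=0) for part in parts]).sum(axis=0)
    degenerate = (within == 0) & (np.ptp(gmeans, axis=0) > 0)
    p = np.where(degenerate, 0.0, p)
    f = np.where(degenerate, np.inf, f)
    all_const = (within == 0) & (np.ptp(gmeans, axis=0) == 0)
    p = np.where(all_const, 1.0, p)
    f = np.where(all_const, 0.0, f)
    p_corr = np.minimum(1.0, p * n_edges)
    return pd.DataFrame({
        "edge": np.arange(n_edges), "F": f, "p_raw": p,
        "p_corrected": p_corr, "significant": p_corr < alpha,
        "degenerate": degenerate,
    })


def roi_group_summary(edge_mask: np.ndarray, mapping: np.ndarray | None = None,
                      n_groups: int | None = None) -> np.ndarray:
    """Count significant edges per coarse region pair.

    edge_mask is an N x N boolean matrix (or upper-triangle vector for
    N=68); mapping assigns each of the N ROIs to one of the coarse groups
    (default: the 68 -> 7 DK lobe mapping).  Returns a symmetric count
    matrix whose upper triangle plus diagonal sums to the number of
    significant edges.
    """
    if mapping is None:
        mapping = dk68_to_7()
    mapping = np.asarray(mapping, dtype=int)
    n_rois = mapping.size
    if np.any(mapping < 0):
        raise ValueError("mapping must cover all ROIs with non-negative indices")
    edge_mask = np.asarray(edge_mask)
    if edge_mask.ndim == 1:
        full = np.zeros((n_rois, n_rois), dtype=bool)
        iu = np.triu_indices(n_rois, k=1)
        if edge_mask.size != iu[0].size:
            raise ValueError("upper-triangle mask length mismatch")
        full[iu] = edge_mask.astype(bool)
        edge_mask = full | full.T
    if edge_mask.shape != (n_rois, n_rois):
        raise ValueError("edge mask does not match the mapping size")
    k = int(n_groups if n_groups is not None else mapping.max() + 1)
    counts = np.zeros((k, k), dtype=int)
    ii, jj = np.triu_indices(n_rois, k=1)
    for a, b in zip(ii[edge_mask[ii, jj]], jj[edge_mask[ii, jj]]):
        ga, gb = sorted((mapping[a], mapping[b]))
        counts[ga, gb] += 1
    return counts + np.triu(counts, k=1).T


def metrics_table(records: list[dict]) -> pd.DataFrame:
    """Assemble the per-subject, per-band network-metric table."""
    return pd.DataFrame.from_records(records, columns=[
        "subject", "group", "band", "CC", "L", "sigma",
        "Eglobal", "Elocal", "unreachable_fraction"])
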