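"""Exometabolite utilization profiling from targeted LC-MS peak tables.

The pipeline turns a feature x sample table of peak heights/areas into
per-isolate metabolite utilization profiles:

1. ``blank_subtract`` removes extraction-blank background per metabolite;
2. ``normalize`` rescales each metabolite so the *maximum* value over the
   uninoculated-control samples is 100 percent;
3. ``fold_change`` computes log2 of mean isolate abundance over mean control
   abundance (with an abundance floor so fully depleted metabolites stay
   finite);
4. ``depletion_test`` calls each metabolite-isolate cell depleted, produced
   or unchanged by a two-sided Wilcoxon rank-sum test against the control
   samples.

The rank-sum test uses the *normal approximation without continuity
correction*. This is deliberate and load-bearing at triplicate scale: with
n=3 vs 3 and complete separation the approximation gives two-sided
p ~ 0.0495 (< 0.05) whereas the exact permutation distribution cannot go
below 0.10, so significance calls at n=3 are only attainable - and only
reproducible - under the approximation.

Clustering of utilization profiles uses Bray-Curtis dissimilarity, which is
defined for non-negative abundances only; it therefore operates on the mean
normalized (0-100) profiles while the log2 fold-change matrix is what gets
displayed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

ROLE_CONTROL = "uninoculated_control"
ROLE_BLANK = "extraction_blank"

CALL_DEPLETED = "depleted"
CALL_PRODUCED = "produced"
CALL_UNCHANGED = "unchanged"


@dataclass
class PeakTable:
    """Non-negative feature x sample abundance matrix with sample annotations.

    ``data`` rows are metabolites, columns are sample ids. ``samples`` is
    indexed by sample id with columns ``role`` (an isolate label, or one of
    the reserved roles above), ``isolate`` and ``replicate``. ``quant_type``
    optionally records per-feature whether the value is a peak height or
    area.
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    quant_type: pd.Series | None = None

    def __post_init__(self):
        if (self.data.to_numpy() < 0).any():
            raise ValueError("peak abundances must be non-negative")
        missing = set(self.data.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)}")
        if "role" not in self.samples.columns:
            raise ValueError("sample annotations need a 'role' column")

    def columns_with_role(self, role: str) -> list[str]:
        ann = self.samples.loc[list(self.data.columns)]
        return list(ann.index[ann["role"] == role])

    @property
    def control_columns(self) -> list[str]:
        return self.columns_with_role(ROLE_CONTROL)

    @property
    def blank_columns(self) -> list[str]:
        return self.columns_with_role(ROLE_BLANK)

    @property
    def isolate_columns(self) -> dict[str, list[str]]:
        """Mapping isolate label -> its culture sample columns."""
        ann = self.samples.loc[list(self.data.columns)]
        cultures = ann[~ann["role"].isin([ROLE_CONTROL, ROLE_BLANK])]
        key = "isolate" if "isolate" in cultures.columns else "role"
        out: dict[str, list[str]] = {}
        for sid, label in cultures[key].items():
            out.setdefault(str(label), []).append(sid)
        return out


@dataclass
class NormalizedTable:
    """Percent-of-control-maximum table; same layout as :class:`PeakTable`.

    ``masked`` flags metabolites whose control maximum was zero - they have
    no normalization reference and are excluded downstream rather than
    silently divided.
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    masked: pd.Series
    quant_type: pd.Series | None = None

    columns_with_role = PeakTable.columns_with_role
    control_columns = PeakTable.control_columns
    blank_columns = PeakTable.blank_columns
    isolate_columns = PeakTable.isolate_columns


@dataclass
class FoldChangeMatrix:
    """Metabolite x isolate log2(mean isolate / mean control) with mask."""

    log2: pd.DataFrame
    masked: pd.DataFrame
    floor: float

    @property
    def isolates(self) -> list[str]:
        return list(self.log2.columns)


@dataclass
class UtilizationCallSet:
    """Depleted/produced/unchanged calls with the underlying test results."""

    calls: pd.DataFrame
    pvalues: pd.DataFrame
    statistic: pd.DataFrame
    alpha: float
    adjusted: bool = False

    def counts(self, direction: str) -> pd.Series:
        """Per-isolate count of metabolites with the given call."""
        return (self.calls == direction).sum(axis=0)


def blank_subtract(table: PeakTable) -> PeakTable:
    """Subtract the per-metabolite extraction-blank mean from all samples.

    Negative results are clipped to zero; blank samples are dropped from the
    output. A table without blanks is returned unchanged with a warning.
    """
    blanks = table.blank_columns
    if not blanks:
        warnings.warn("no extraction-blank samples; blank subtraction skipped")
        return table
    background = table.data[blanks].mean(axis=1)
    keep = [c for c in table.data.columns if c not in blanks]
    data = table.data[keep].sub(background, axis=0).clip(lower=0.0)
    return PeakTable(
        data=data, samples=table.samples.loc[keep].copy(), quant_type=table.quant_type
    )


def blank_ratio_filter(table: PeakTable, ratio: float = 10.0) -> PeakTable:
    """Drop features whose signal is not ``ratio`` x above blank background.

    A feature is kept when its maximum non-blank abundance is at least
    ``ratio`` times its maximum blank abundance (features absent from the
    blanks are always kept). Removals are reported via a warning so they are
    never silent.
    """
    blanks = table.blank_columns
    if not blanks:
        return table
    non_blank = [c for c in table.data.columns if c not in blanks]
    blank_max = table.data[blanks].max(axis=1)
    signal_max = table.data[non_blank].max(axis=1)
    keep = (blank_max <= 0) | (signal_max >= ratio * blank_max)
    removed = list(table.data.index[~keep])
    if removed:
        warnings.warn(f"blank-ratio filter removed {len(removed)} features: {removed}")
    qt = table.quant_type[keep] if table.quant_type is not None else None
    return PeakTable(data=table.data.loc[keep], samples=table.samples.copy(), quant_type=qt)


def normalize(table: PeakTable) -> NormalizedTable:
    """Rescale each metabolite to percent of its control-sample maximum.

    After normalization the maximum over uninoculated-control samples is
    exactly 100 for every unmasked metabolite. Metabolites whose control
    maximum is zero are masked, not divided.
    """
    controls = table.control_columns
    if not controls:
        raise ValueError("normalization requires at least one uninoculated-control sample")
    control_max = table.data[controls].max(axis=1)
    masked = control_max <= 0
    scale = control_max.where(~masked, 1.0)
    data = table.data.div(scale, axis=0) * 100.0
    data[masked] = table.data[masked]  # leave masked rows untouched
    return NormalizedTable(
        data=data, samples=table.samples.copy(), masked=masked, quant_type=table.quant_type
    )


def resolve_quant_type(table: PeakTable, prefer: str = "height") -> PeakTable:
    """Collapse duplicate metabolite ids measured as both height and area.

    When a metabolite id appears once per quant type, the preferred type
    (height by default) wins and the other row is dropped.
    """
    if table.quant_type is None or not table.data.index.duplicated().any():
        return table
    order = {prefer: 0}
    rank = table.quant_type.map(lambda q: order.get(q, 1))
    chosen: dict = {}
    for pos, (mid, r) in enumerate(zip(table.data.index, rank)):
        if mid not in chosen or r < chosen[mid][0]:
            chosen[mid] = (r, pos)
    idx = sorted(pos for _, pos in chosen.values())
    return PeakTable(
        data=table.data.iloc[idx],
        samples=table.samples.copy(),
        quant_type=table.quant_type.iloc[idx],
    )


def _mean_profiles(norm: NormalizedTable) -> tuple[pd.DataFrame, pd.Series]:
    """Mean normalized abundance per isolate and over controls (unmasked rows)."""
    data = norm.data.loc[~norm.masked]
    control_mean = data[norm.control_columns].mean(axis=1)
    iso_means = {
        iso: data[cols].mean(axis=1) for iso, cols in norm.isolate_columns.items()
    }
    return pd.DataFrame(iso_means), control_mean


def fold_change(norm: NormalizedTable, floor: float | None = None) -> FoldChangeMatrix:
    """log2(mean isolate / mean control) per metabolite and isolate.

    ``floor`` (default: half the smallest nonzero normalized value in the
    table) is applied to both means before the log so that completely
    depleted metabolites give a large negative, finite fold change.
    """
    iso_means, control_mean = _mean_profiles(norm)
    if iso_means.empty:
        raise ValueError("no isolate culture samples in table")
    if floor is None:
        vals = norm.data.loc[~norm.masked].to_numpy()
        positive = vals[vals > 0]
        floor = float(positive.min()) / 2.0 if positive.size else 1.0
    log2 = np.log2(iso_means.clip(lower=floor).div(control_mean.clip(lower=floor), axis=0))
    # exact zeros where the means are equal (avoid -0.0 / rounding artifacts)
    equal = iso_means.sub(control_mean, axis=0).abs().le(1e-12)
    log2 = log2.where(~equal, 0.0)
    masked = pd.DataFrame(False, index=log2.index, columns=log2.columns)
    return FoldChangeMatrix(log2=log2, masked=masked, floor=floor)


def ranksum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum via the normal approximation.

    Midranks for ties, no continuity correction, no tie correction to the
    variance - the classical large-sample form. Matches
    ``scipy.stats.ranksums`` exactly (that equivalence is pinned in the test
    suite).
    """
    z = _ranksum_z_many(x[None, :], y[None, :])[0]
    return float(z), float(2 * stats.norm.sf(abs(z)))


def _ranksum_z_many(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized rank-sum z over rows of (m, n1) x and (m, n2) y."""
    n1, n2 = x.shape[1], y.shape[1]
    combined = np.concatenate([x, y], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    s = ranks[:, :n1].sum(axis=1)
    expected = n1 * (n1 + n2 + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return (s - expected) / sd


def depletion_test(
    norm: NormalizedTable,
    alpha: float = 0.05,
    min_replicates: int = 2,
    adjust: str | None = None,
) -> UtilizationCallSet:
    """Call each metabolite depleted/produced/unchanged per isolate.

    Two-sided rank-sum (normal approximation, see module docs) of the
    isolate's replicate values against the uninoculated-control samples;
    direction comes from the sign of the mean difference. Metabolites are
    masked (NaN call) for isolates with fewer than ``min_replicates``
    replicates or when the metabolite had no normalization reference.

    ``adjust='bh'`` optionally applies Benjamini-Hochberg correction per
    isolate before calling; the default is raw p < alpha.
    """
    controls = norm.control_columns
    if len(controls) < min_replicates:
        raise ValueError(f"need >= {min_replicates} control samples, got {len(controls)}")
    iso_cols = norm.isolate_columns
    if not iso_cols:
        raise ValueError("no isolate culture samples in table")
    metabolites = norm.data.index
    unmasked = ~norm.masked
    ctrl = norm.data[controls].to_numpy(float)

    calls = pd.DataFrame(np.nan, index=metabolites, columns=list(iso_cols), dtype=object)
    pvals = pd.DataFrame(np.nan, index=metabolites, columns=list(iso_cols), dtype=float)
    zstat = pd.DataFrame(np.nan, index=metabolites, columns=list(iso_cols), dtype=float)

    for iso, cols in iso_cols.items():
        if len(cols) < min_replicates:
            warnings.warn(f"isolate {iso!r} masked: fewer than {min_replicates} replicates")
            continue
        x = norm.data[cols].to_numpy(float)
        z = _ranksum_z_many(x, ctrl)
        p = 2 * stats.norm.sf(np.abs(z))
        p_eff = p.copy()
        if adjust == "bh":
            ok = unmasked.to_numpy()
            p_eff[ok] = multipletests(p[ok], method="fdr_bh")[1]
        diff = x.mean(axis=1) - ctrl.mean(axis=1)
        call = np.where(
            (p_eff < alpha) & (diff < 0), CALL_DEPLETED,
            np.where((p_eff < alpha) & (diff > 0), CALL_PRODUCED, CALL_UNCHANGED),
        )
        mask = unmasked.to_numpy()
        calls.loc[mask, iso] = call[mask]
        pvals.loc[mask, iso] = (p_eff if adjust == "bh" else p)[mask]
        zstat.loc[mask, iso] = z[mask]
    return UtilizationCallSet(
        calls=calls, pvalues=pvals, statistic=zstat, alpha=alpha, adjusted=adjust == "bh"
    )


def count_significant(calls: UtilizationCallSet, direction: str = CALL_DEPLETED) -> pd.Series:
    """Per-isolate count of metabolites with the given call."""
    if direction not in (CALL_DEPLETED, CALL_PRODUCED, CALL_UNCHANGED):
        raise ValueError(f"unknown direction {direction!r}")
    return calls.counts(direction)


# ---------------------------------------------------------------------------
# clustering

@dataclass
class ClusterResult:
    """Bray-Curtis dissimilarities with an agglomerative dendrogram."""

    distance: pd.DataFrame = field(repr=False)
    linkage: np.ndarray = field(repr=False)
    leaf_order: list[str] = field(default_factory=list)
    newick: str = ""
    method: str = "average"
    metric: str = "braycurtis"


def isolate_mean_profiles(norm: NormalizedTable) -> pd.DataFrame:
    """Metabolite x isolate matrix of mean normalized abundances (non-negative)."""
    iso_means, _ = _mean_profiles(norm)
    return iso_means


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({build(tree.left, tree.dist)},{build(tree.right, tree.dist)});"


def cluster_profiles(
    matrix: pd.DataFrame, metric: str = "braycurtis", method: str = "average"
) -> ClusterResult:
    """Hierarchically cluster isolate columns of an abundance matrix.

    Bray-Curtis requires non-negative input, so this operates on mean
    normalized abundances (0-100), not on log2 fold changes; passing a
    matrix with negative entries raises with a pointer to the normalized
    input. Ties in the linkage are broken deterministically by scipy's
    ordering, so the leaf order is reproducible.
    """
    if metric == "braycurtis" and (matrix.to_numpy() < 0).any():
        raise ValueError(
            "Bray-Curtis needs non-negative input; cluster the mean normalized "
            "abundances (isolate_mean_profiles), not the log2 fold-change matrix"
        )
    labels = list(matrix.columns)
    if len(labels) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    condensed = pdist(matrix.to_numpy(float).T, metric=metric)
    Z = hierarchy.linkage(condensed, method=method)
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    dist = pd.DataFrame(squareform(condensed), index=labels, columns=labels)
    return ClusterResult(
        distance=dist,
        linkage=Z,
        leaf_order=order,
        newick=_linkage_to_newick(Z, labels),
        method=method,
        metric=metric,
    )


# ---------------------------------------------------------------------------
# IO

def read_peak_table(peaks_path, samples_path) -> PeakTable:
    """Read a peak TSV (first column metabolite id, optional quant_type
    column, remaining columns samples) and a sample-annotation TSV."""
    df = pd.read_csv(peaks_path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{peaks_path}: expected metabolite id column plus sample columns")
    df = df.set_index(df.columns[0])
    quant = None
    if "quant_type" in df.columns:
        quant = df.pop("quant_type")
    try:
        data = df.astype(float)
    except ValueError as e:
        raise ValueError(f"{peaks_path}: non-numeric abundance value ({e})") from e
    bad = data.index[data.lt(0).any(axis=1)]
    if len(bad):
        raise ValueError(f"{peaks_path}: negative abundances in rows {list(bad)}")
    samples = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
    missing = {"role"} - set(samples.columns)
    if missing:
        raise ValueError(f"{samples_path}: missing columns {sorted(missing)}")
    return PeakTable(data=data, samples=samples, quant_type=quant)


def write_calls(calls: UtilizationCallSet, fc: FoldChangeMatrix, path) -> None:
    """Long-format calls TSV: metabolite, isolate, call, p, fold change."""
    long = (
        calls.calls.stack(future_stack=True)
        .rename("call")
        .to_frame()
        .join(calls.pvalues.stack(future_stack=True).rename("p"))
        .join(fc.log2.stack(future_stack=True).rename("log2_fc"))
        .reset_index(names=["metabolite", "isolate"])
    )
    long.to_csv(path, sep="\t", index=False)
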