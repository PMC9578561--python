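"""Phenotypic barcodes, hierarchical clustering, and potency comparisons.

Each chemical concentration gets a binary "phenotypic barcode" over the
direction-split outcome measures: a cell is active when the pooled median
normalized response (continuous) or pooled incidence (binary) lies strictly
beyond the measure's benchmark response.  Barcodes are filtered to rows and
columns with at least one active cell (concentrations with 100% lethality
are dropped first to focus on sublethal effects) and clustered with Jaccard
("binary") distance and Ward's ward.D2 linkage.  Chemical-level summaries
link chemicals to endpoint classes and compare potency rankings with
Spearman correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

from . import schema as sc
from .bmc import ConcentrationResponse, BMCResult


@dataclass
class PhenotypicBarcode:
    """Binary activity matrix: rows chemical x concentration, columns measures."""

    matrix: pd.DataFrame  # bool; index "chemical@conc", columns measure labels
    lethal_rows: list[str] = field(default_factory=list)

    def copy(self) -> "PhenotypicBarcode":
        return PhenotypicBarcode(self.matrix.copy(), list(self.lethal_rows))


def binarize(responses: dict[sc.OutcomeMeasure, ConcentrationResponse],
             bmr_table: dict[sc.OutcomeMeasure, float],
             chemical: str) -> PhenotypicBarcode:
    """Barcode one chemical: active iff pooled summary strictly exceeds BMR.

    The pooled summary at each concentration is the median of all worms
    combined across replicates (continuous) or the control-adjusted pooled
    incidence in percent (binary); values exactly at the BMR are inactive.
    Note this per-concentration call ignores concentration-response shape on
    purpose — it is a pattern descriptor, not hit identification.
    """
    cells: dict[str, dict[str, bool]] = {}
    lethal_rows: set[str] = set()
    for measure, cr in responses.items():
        bmr = bmr_table.get(measure)
        if bmr is None:
            raise KeyError(f"no BMR for outcome measure {measure.label}")
        for j, c in enumerate(cr.concentrations):
            row = f"{chemical}@{c:g}"
            raw = cr.samples[j]
            if cr.kind == "binary":
                rate = float(np.mean(raw))
                summary = max(0.0, rate - cr.control_rate) * 100.0
                if measure.endpoint == "lethality" and rate >= 1.0:
                    lethal_rows.add(row)
            else:
                vals = raw[np.isfinite(raw)]
                if vals.size == 0:
                    continue
                summary = float(np.median(vals))
                if cr.direction == "-":
                    summary = -summary
            cells.setdefault(row, {})[measure.label] = summary > bmr
    mat = pd.DataFrame(cells).T.fillna(False).astype(bool)
    mat = mat.sort_index()
    return PhenotypicBarcode(mat, sorted(lethal_rows))


def filter_barcode(barcode: PhenotypicBarcode) -> PhenotypicBarcode:
    """Drop fully-lethal rows, then all-inactive rows and columns.

    Idempotent; never creates activity.  Row removal precedes column removal
    so a column active only in a removed lethal row is itself removed.
    """
    mat = barcode.matrix.drop(index=[r for r in barcode.lethal_rows
                                     if r in barcode.matrix.index])
    while True:
        rows = mat.index[mat.any(axis=1)]
        mat = mat.loc[rows]
        cols = mat.columns[mat.any(axis=0)]
        mat = mat[cols]
        if len(rows) == len(mat.index) and len(cols) == len(mat.columns):
            break
    return PhenotypicBarcode(mat, list(barcode.lethal_rows))


def binary_distance(row_a, row_b) -> float:
    """Jaccard dissimilarity of two binary vectors (1 - |A∩B| / |A∪B|).

    Two all-inactive rows have distance 0 (they are pre-filtered in the
    clustering pipeline).
    """
    a = np.asarray(row_a, dtype=bool)
    b = np.asarray(row_b, dtype=bool)
    union = np.sum(a | b)
    if union == 0:
        return 0.0
    return 1.0 - np.sum(a & b) / union


def jaccard_condensed(matrix: np.ndarray) -> np.ndarray:
    """Condensed pairwise Jaccard dissimilarity matrix."""
    m = np.asarray(matrix, dtype=bool)
    n = m.shape[0]
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        inter = (m[i] & m[i + 1:]).sum(axis=1)
        union = (m[i] | m[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(union > 0, 1.0 - inter / np.maximum(union, 1), 0.0)
        out[k:k + n - 1 - i] = d
        k += n - 1 - i
    return out


@dataclass
class ClusterResult:
    """Ward (ward.D2) dendrogram and a k-cluster cut of the barcode rows."""

    linkage: np.ndarray          # scipy linkage matrix; heights on distance scale
    labels: np.ndarray           # canonical 1..k labels per retained row
    row_ids: list[str]
    k: int

    def assignments(self) -> pd.Series:
        return pd.Series(self.labels, index=self.row_ids, name="cluster")


def _canonical_labels(raw_labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by order of first appearance (row order)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw_labels)
    for i, lab in enumerate(raw_labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def ward_cluster(barcode: PhenotypicBarcode, k: int = 6) -> ClusterResult:
    """Agglomerative Ward clustering (ward.D2 variant) of barcode rows.

    Distances are Jaccard dissimilarities; the Ward criterion squares them
    internally and merge heights are reported on the distance scale, the
    ward.D2 convention.  Binary barcodes produce many tied distances, and
    agglomeration under ties depends on row order, so rows are first put in
    a canonical order (by barcode content, then row id); the resulting
    partition is therefore invariant to input row order, with labels
    canonicalized by first appearance.
    """
    mat = barcode.matrix
    n = len(mat)
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    order = sorted(range(n),
                   key=lambda i: (tuple(mat.iloc[i]), str(mat.index[i])))
    mat = mat.iloc[order]
    dist = jaccard_condensed(mat.to_numpy())
    Z = hierarchy.linkage(dist, method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(Z, _canonical_labels(raw), list(mat.index), k)


def endpoint_class_links(results: list[BMCResult],
                         measures: list[sc.OutcomeMeasure],
                         chemical: str,
                         class_map: dict[str, str] = sc.ENDPOINT_CLASSES
                         ) -> pd.DataFrame:
    """Chemical-to-endpoint-class link table.

    A link exists when any member outcome measure of the class has an active
    BMC on day 7 or day 12 at any tested concentration.  ``results`` and
    ``measures`` are parallel lists for one chemical/worm type.
    """
    if len(results) != len(measures):
        raise ValueError("results and measures must be parallel")
    linked: set[str] = set()
    for res, m in zip(results, measures):
        if res.active:
            linked.add(class_map[m.endpoint])
    return pd.DataFrame(
        [(chemical, cls) for cls in sorted(linked)],
        columns=["chemical", "endpoint_class"],
    )


def spearman_rho(ranks_a: np.ndarray, ranks_b: np.ndarray) -> float:
    """Spearman rho from two rank vectors (Pearson correlation of ranks)."""
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        return math.nan
    return float((a * b).sum() / denom)


def _exact_permutation_p(ranks_a: np.ndarray, ranks_b: np.ndarray,
                         rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (n <= 9)."""
    n = len(ranks_a)
    perms = np.array(list(itertools.permutations(range(n))))
    b_perm = np.asarray(ranks_b, dtype=float)[perms]  # (n!, n)
    a = np.asarray(ranks_a, dtype=float)
    a_c = a - a.mean()
    b_c = b_perm - b_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((a_c ** 2).sum() * (b_c ** 2).sum(axis=1))
    rhos = (b_c @ a_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def rank_and_correlate(potency_a: dict[str, float],
                       potency_b: dict[str, float]) -> dict:
    """Rank two potency maps (lowest concentration = rank 1) and correlate.

    Returns ranks per chemical, Spearman rho, and a two-sided p-value —
    exact by permutation for n <= 9, asymptotic otherwise.
    """
    if set(potency_a) != set(potency_b) or not potency_a:
        raise ValueError("potency maps must cover the same non-empty chemical set")
    chems = sorted(potency_a)
    va = np.array([potency_a[c] for c in chems], dtype=float)
    vb = np.array([potency_b[c] for c in chems], dtype=float)
    if not (np.isfinite(va).all() and np.isfinite(vb).all()):
        raise ValueError("potency values must be finite")
    ra = stats.rankdata(va)  # average ranks on ties; rank 1 = most potent
    rb = stats.rankdata(vb)
    rho = spearman_rho(ra, rb)
    n = len(chems)
    if n <= 9:
        p = _exact_permutation_p(ra, rb, rho)
    else:
        p = float(stats.spearmanr(va, vb).pvalue)
    return {
        "chemicals": chems,
        "ranks_a": ra.tolist(),
        "ranks_b": rb.tolist(),
        "spearman_rho": rho,
        "p_value": p,
    }
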