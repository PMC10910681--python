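"""Cell-type concordance between identified proteins and scRNAseq clusters.

The cluster-median expression matrix (genes x labeled clusters, labels of
the form ``"<number> <description>"``) is first simplified by merging runs
of consecutive clusters that share a description, keeping the highest median
per gene.  For each merged cell type we then ask what fraction of the cell
surface genes it expresses were also identified by glycocapture, and flag
cell types whose fraction is anomalously high or low with the ROUT outlier
test (robust regression followed by an FDR-controlled residual scan,
Motulsky & Brown's recipe) at Q = 0.1% by default.  Signature genes --
genes detected in exactly one merged cell type -- give a complementary
coverage-independent view of cell-type specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import ClusterExpression


@dataclass
class MergedClusters:
    """Cluster matrix after collapsing consecutive same-description runs."""

    descriptions: list[str]
    genes: list[str]
    values: np.ndarray  # genes x merged clusters
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def column(self, description: str) -> np.ndarray:
        try:
            j = self.descriptions.index(description)
        except ValueError:
            raise KeyError(f"unknown merged cluster {description!r}") from None
        return self.values[:, j]


@dataclass
class ROUTResult:
    values: np.ndarray
    q: float
    robust_center: float
    rsdr: float
    outlier_flags: np.ndarray  # boolean, aligned with values
    directions: dict[int, str]  # index of flagged value -> "high"/"low"

    def flagged(self) -> list[int]:
        return sorted(self.directions)


def parse_cluster_label(label: str) -> tuple[str, str]:
    """Split ``"<number> <description>"`` into (number token, description)."""
    parts = label.split(None, 1)
    if len(parts) != 2 or not parts[0].isdigit():
        raise ValueError(f"unparsable cluster label {label!r}")
    return parts[0], parts[1]


def merge_clusters(expr: ClusterExpression) -> MergedClusters:
    """Collapse consecutive clusters with the same description (max per gene).

    Non-consecutive repeats of a description stay separate; a repeated
    merged name is disambiguated with an ``#<n>`` suffix so columns remain
    addressable by name.
    """
    runs: list[tuple[str, list[int], list[str]]] = []
    for j, label in enumerate(expr.clusters):
        _, desc = parse_cluster_label(label)
        if runs and runs[-1][0] == desc:
            runs[-1][1].append(j)
            runs[-1][2].append(label)
        else:
            runs.append((desc, [j], [label]))
    seen: dict[str, int] = {}
    names, provenance = [], {}
    values = np.empty((len(expr.genes), len(runs)))
    for k, (desc, cols, labels) in enumerate(runs):
        seen[desc] = seen.get(desc, 0) + 1
        name = desc if seen[desc] == 1 else f"{desc} #{seen[desc]}"
        names.append(name)
        provenance[name] = labels
        values[:, k] = expr.values[:, cols].max(axis=1)
    return MergedClusters(
        descriptions=names, genes=list(expr.genes), values=values, provenance=provenance
    )


def detected_genes(
    merged: MergedClusters, cluster: str, threshold: float = 0.0
) -> set[str]:
    """Genes with median expression strictly above threshold in one cell type."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    col = merged.column(cluster)
    return {g for g, v in zip(merged.genes, col) if v > threshold}


def percent_identified(
    merged: MergedClusters,
    surface_genes: set[str],
    identified: set[str],
    threshold: float = 0.0,
) -> dict[str, float]:
    """Per cell type: % of detected surface genes also identified by glycocapture.

    Cell types with no detected surface genes report NaN (undefined) and are
    excluded from downstream outlier testing.
    """
    out = {}
    for desc in merged.descriptions:
        det_surface = detected_genes(merged, desc, threshold) & surface_genes
        if not det_surface:
            out[desc] = float("nan")
        else:
            out[desc] = 100.0 * len(det_surface & identified) / len(det_surface)
    return out


def _robust_constant_fit(values: np.ndarray, n_params: int = 1) -> tuple[float, float]:
    """Lorentzian-loss location estimate and RSDR for a constant model.

    The robust standard deviation of residuals (RSDR) is the 68.27th
    percentile of absolute residuals with an N/(N-K) small-sample correction.
    The location minimises sum(log(1 + (r/RSDR)^2)); location and scale are
    iterated to a fixed point starting from the median/MAD-free percentile
    estimate.
    """
    n = len(values)

    def rsdr_at(center: float) -> float:
        res = np.abs(values - center)
        return float(np.percentile(res, 68.27)) * n / (n - n_params)

    center = float(np.median(values))
    scale = rsdr_at(center)
    for _ in range(100):
        if scale == 0:
            break

        def merit(c: float) -> float:
            return float(np.sum(np.log1p(((values - c) / scale) ** 2)))

        lo, hi = values.min(), values.max()
        res = optimize.minimize_scalar(merit, bounds=(lo, hi), method="bounded")
        new_center = float(res.x)
        new_scale = rsdr_at(new_center)
        if abs(new_center - center) <= 1e-10 * max(1.0, abs(center)) and math.isclose(
            new_scale, scale, rel_tol=1e-10, abs_tol=1e-300
        ):
            center, scale = new_center, new_scale
            break
        center, scale = new_center, new_scale
    return center, rsdr_at(center)


def rout_outliers(
    values: Sequence[float],
    q: float = 0.001,
    max_fraction: float = 0.3,
    n_params: int = 1,
) -> ROUTResult:
    """Flag outliers among values by the ROUT method at FDR level ``q``.

    A robust constant model is fit with Lorentzian loss; residuals scaled by
    the RSDR are treated as t statistics with N-K degrees of freedom, and the
    points with the largest absolute residuals are flagged by the FDR
    stepping rule: with residuals ranked descending, the largest k such that
    P_(i) < q*i/N for i = k is flagged together with all larger residuals.
    At most ``max_fraction`` of the points are ever tested.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4 or not np.isfinite(arr).all():
        raise ValueError("ROUT needs at least 4 finite values")
    if not 0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    n = arr.size
    center, rsdr = _robust_constant_fit(arr, n_params=n_params)
    residuals = arr - center
    flags = np.zeros(n, dtype=bool)
    directions: dict[int, str] = {}
    if not np.allclose(arr, arr[0]):
        df = n - n_params
        abs_res = np.abs(residuals)
        order = np.argsort(-abs_res, kind="stable")
        n_test = max(1, int(math.floor(max_fraction * n)))
        if rsdr == 0:
            pvals = np.where(abs_res[order] > 0, 0.0, 1.0)
        else:
            pvals = 2.0 * stats.t.sf(abs_res[order] / rsdr, df)
        k_flag = 0
        for i in range(n_test):
            if pvals[i] < q * (i + 1) / n:
                k_flag = i + 1
        for idx in order[:k_flag]:
            flags[idx] = True
            directions[int(idx)] = "high" if residuals[idx] > 0 else "low"
    return ROUTResult(
        values=arr,
        q=q,
        robust_center=center,
        rsdr=rsdr,
        outlier_flags=flags,
        directions=directions,
    )


def signature_genes(
    merged: MergedClusters, threshold: float = 0.0
) -> dict[str, str]:
    """Genes detected (expression > threshold) in exactly one merged cell type."""
    detected = merged.values > threshold
    n_types = detected.sum(axis=1)
    out = {}
    for i in np.flatnonzero(n_types == 1):
        j = int(np.argmax(detected[i]))
        out[merged.genes[i]] = merged.descriptions[j]
    return out


def signature_fraction(
    signatures: Mapping[str, str], identified: set[str]
) -> dict[str, float]:
    """Per cell type: % of all identified signature genes that belong to it.

    Fractions sum to 100 across cell types with at least one identified
    signature gene; cell types with none report 0.
    """
    hits = {g: c for g, c in signatures.items() if g in identified}
    clusters = sorted(set(signatures.values()))
    if not hits:
        warnings.warn("no identified signature genes; fractions undefined", stacklevel=2)
        return {c: float("nan") for c in clusters}
    out = {c: 0.0 for c in clusters}
    for c in hits.values():
        out[c] += 100.0 / len(hits)
    return out


def signature_fraction_difference(
    signatures: Mapping[str, str], identified_a: set[str], identified_b: set[str]
) -> dict[str, float]:
    """Per-cell-type difference of signature fractions between two datasets."""
    fa = signature_fraction(signatures, identified_a)
    fb = signature_fraction(signatures, identified_b)
    return {c: fa[c] - fb[c] for c in fa}


def surface_detected_fraction(
    merged: MergedClusters, surface_genes: set[str], threshold: float = 0.0
) -> dict[str, float]:
    """Per cell type: % of detected genes that encode cell surface proteins."""
    if not (merged.values > threshold).any():
        raise ValueError("no gene detected in any cell type")
    out = {}
    for desc in merged.descriptions:
        det = detected_genes(merged, desc, threshold)
        out[desc] = 100.0 * len(det & surface_genes) / len(det) if det else float("nan")
    return out


def cell_type_summary(
    merged: MergedClusters,
    surface_genes: set[str],
    identified: set[str],
    q: float = 0.001,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-cell-type detection/identification table with ROUT outlier flags.

    Cell types with undefined percentages (no detected surface genes) are
    excluded from the ROUT sample rather than imputed.
    """
    percents = percent_identified(merged, surface_genes, identified, threshold)
    rows = []
    for desc in merged.descriptions:
        det = detected_genes(merged, desc, threshold)
        det_surface = det & surface_genes
        rows.append(
            {
                "cluster": desc,
                "n_detected": len(det),
                "n_surface_detected": len(det_surface),
                "n_identified": len(det_surface & identified),
                "percent": percents[desc],
                "outlier_flag": False,
                "direction": "",
            }
        )
    df = pd.DataFrame(rows)
    defined = df.index[df["percent"].notna()]
    if len(defined) >= 4:
        result = rout_outliers(df.loc[defined, "percent"].to_numpy(), q=q)
        for pos, idx in enumerate(defined):
            if result.outlier_flags[pos]:
                df.loc[idx, "outlier_flag"] = True
                df.loc[idx, "direction"] = result.directions[pos]
    return df
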