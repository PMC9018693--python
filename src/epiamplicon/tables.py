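"""Sample x epiallele count tables and their downstream summaries.

The central container is :class:`EpialleleCountTable`: rows are samples,
columns are binary methylation profiles (epialleles) over the amplicon's k
CpG sites. The conceptual column space is all 2^k profiles in lexicographic
order; storage keeps only observed columns (absent = 0). From the table we
derive epiallele-class distributions (class = number of methylated CpGs,
regardless of position), mean and per-CpG methylation, rarefied tables at a
common depth, and sample ordination (PCoA on Bray-Curtis distances by
default, plain PCA on frequencies as an alternative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa

from .amplicon import AmpliconSpec
from .calling import ReadCall
from .simulate import SampleMeta


def all_epialleles(k: int) -> list[str]:
    """All 2^k binary profiles in lexicographic order (leftmost = 5' CpG)."""
    return [format(code, f"0{k}b") for code in range(2 ** k)]


@dataclass(frozen=True)
class EpialleleCountTable:
    """Samples x epiallele counts with sample metadata.

    ``counts`` is a pandas DataFrame indexed by sample_id whose columns are
    the *observed* epiallele strings (sorted lexicographically); absent
    profiles count 0. ``meta`` carries tissue/stage/replicate per sample.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    k: int
    rarefied_depth: int | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if any(len(c) != self.k or set(c) - {"0", "1"}
               for c in self.counts.columns):
            raise ValueError(f"columns must be binary strings of length {self.k}")
        row_sums = self.counts.sum(axis=1)
        if (row_sums == 0).any():
            raise ValueError("retained samples must have positive row sums")
        if self.rarefied_depth is not None and not (
            row_sums == self.rarefied_depth
        ).all():
            raise ValueError("rarefied rows must all sum to rarefied_depth")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    def row_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def dense(self) -> pd.DataFrame:
        """Counts over the full 2^k lexicographic column space."""
        return self.counts.reindex(columns=all_epialleles(self.k),
                                   fill_value=0)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")

    def to_biom_json(self, path: str | Path, table_id: str = "epialleles") -> None:
        """Write BIOM v1.0 sparse-JSON (rows = epialleles, columns = samples)."""
        dense = self.counts
        data = []
        for j, sid in enumerate(dense.index):
            row = dense.loc[sid]
            for i, allele in enumerate(dense.columns):
                v = int(row.iloc[i])
                if v:
                    data.append([i, j, v])
        doc = {
            "id": table_id,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "epiamplicon",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [len(dense.columns), len(dense.index)],
            "rows": [{"id": a, "metadata": None} for a in dense.columns],
            "columns": [
                {"id": s, "metadata": self.meta.loc[s].to_dict()
                 if s in self.meta.index else None}
                for s in dense.index
            ],
            "data": data,
        }
        Path(path).write_text(json.dumps(doc))


def build_count_table(
    calls_by_sample: dict[str, Sequence[ReadCall]],
    spec: AmpliconSpec,
    meta: Iterable[SampleMeta] | None = None,
) -> EpialleleCountTable:
    """Tabulate retained read calls into a sample x epiallele count table.

    Samples with zero retained (called) reads are dropped with a warning
    attribute in the metadata rather than raising.
    """
    k = spec.n_cpgs
    rows = {}
    for sample_id, calls in calls_by_sample.items():
        counter: dict[str, int] = {}
        for call in calls:
            if call.epiallele is None:
                continue
            if len(call.epiallele) != k:
                raise ValueError("epiallele length mismatch with amplicon")
            counter[call.epiallele] = counter.get(call.epiallele, 0) + 1
        if counter:
            rows[sample_id] = counter
        else:
            import warnings

            warnings.warn(
                f"sample {sample_id!r} has no retained reads; dropped",
                stacklevel=2,
            )
    counts = (
        pd.DataFrame.from_dict(rows, orient="index")
        .fillna(0)
        .astype(int)
    )
    counts = counts.reindex(sorted(counts.columns), axis=1)
    counts = counts.loc[list(rows)]
    meta_df = _meta_frame(meta, counts.index)
    return EpialleleCountTable(counts=counts, meta=meta_df, k=k)


def _meta_frame(meta, sample_ids) -> pd.DataFrame:
    if meta is None:
        return pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    records = {
        m.sample_id: {"tissue": m.tissue, "stage": m.stage,
                      "replicate": m.replicate}
        for m in meta
    }
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "sample_id"
    return df.reindex(sample_ids)


def rarefy(
    table: EpialleleCountTable, depth: int, seed: int
) -> EpialleleCountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped (reported through
    the returned table's smaller index). Subsampling a row is a draw from
    the multivariate hypergeometric distribution over its epiallele
    counts, so expected frequencies are preserved. Deterministic given
    ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    keep = table.row_sums() >= depth
    sub = table.counts.loc[keep.index[keep]]
    out = np.empty_like(sub.values)
    for i in range(sub.shape[0]):
        out[i] = rng.multivariate_hypergeometric(sub.values[i], depth)
    counts = pd.DataFrame(out, index=sub.index, columns=sub.columns)
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    if counts.empty:
        raise ValueError("no sample reaches the requested depth")
    return EpialleleCountTable(
        counts=counts,
        meta=table.meta.reindex(counts.index),
        k=table.k,
        rarefied_depth=depth,
    )


def class_distribution(table: EpialleleCountTable) -> pd.DataFrame:
    """Per-sample proportions over epiallele classes 0..k.

    The class of an epiallele is its number of methylated CpGs (Hamming
    weight), regardless of which positions carry them.
    """
    weights = np.array([c.count("1") for c in table.counts.columns])
    props = np.zeros((table.counts.shape[0], table.k + 1))
    vals = table.frequencies().values
    for cls in range(table.k + 1):
        props[:, cls] = vals[:, weights == cls].sum(axis=1)
    return pd.DataFrame(
        props,
        index=table.counts.index,
        columns=[f"{c}-Meth" for c in range(table.k + 1)],
    )


def mean_methylation(table: EpialleleCountTable) -> pd.Series:
    """Per-sample mean methylation fraction (average over molecules and CpGs)."""
    weights = np.array([c.count("1") for c in table.counts.columns])
    num = table.counts.values @ weights
    den = table.row_sums().values * table.k
    return pd.Series(num / den, index=table.counts.index, name="mean_methylation")


def per_cpg_methylation(
    table: EpialleleCountTable, spec: AmpliconSpec | None = None
) -> pd.DataFrame:
    """Samples x CpG methylation fractions.

    Columns are TSS-relative CpG labels when ``spec`` is given, else CpG
    indices 0..k-1. The across-CpG mean of this matrix equals
    :func:`mean_methylation` exactly.
    """
    bits = np.array(
        [[int(b) for b in col] for col in table.counts.columns]
    )  # columns x k
    num = table.counts.values @ bits
    den = table.row_sums().values[:, None]
    cols = (
        [str(lbl) for lbl in spec.cpg_labels]
        if spec is not None
        else [str(i) for i in range(table.k)]
    )
    return pd.DataFrame(num / den, index=table.counts.index, columns=cols)


@dataclass(frozen=True)
class OrdinationResult:
    """Sample coordinates with per-axis variance-explained fractions."""

    coordinates: pd.DataFrame  # samples x axes ("PC1", "PC2", ...)
    proportion_explained: np.ndarray
    metric: str
    method: str

    def __post_init__(self) -> None:
        pe = np.asarray(self.proportion_explained, dtype=float)
        if (pe < -1e-12).any() or pe.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must lie in [0,1], sum <= 1")
        if (np.diff(pe) > 1e-12).any():
            raise ValueError("variance fractions must be non-increasing")


def distance_matrix(
    table: EpialleleCountTable, metric: str = "braycurtis"
) -> pd.DataFrame:
    """Pairwise sample distances on epiallele profiles.

    ``braycurtis`` acts on counts (rarefy first so depths are equal);
    ``euclidean`` acts on relative frequencies.
    """
    if metric == "braycurtis":
        data = table.counts.values.astype(float)
        d = pdist(data, metric="braycurtis")
    elif metric == "euclidean":
        d = pdist(table.frequencies().values, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(
        squareform(d), index=table.counts.index, columns=table.counts.index
    )


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


def ordinate(
    table: EpialleleCountTable,
    metric: str = "braycurtis",
    method: str = "pcoa",
    n_axes: int = 2,
) -> OrdinationResult:
    """Ordinate samples by their epiallele distributions.

    ``pcoa`` eigen-decomposes the double-centred squared-distance matrix
    (principal coordinates); ``pca`` eigen-decomposes the covariance of
    the frequency rows. Axis signs are fixed by making the
    largest-magnitude coordinate on each axis positive. Degenerate input
    (all samples identical) yields zero coordinates and zero variance
    fractions.
    """
    n = table.counts.shape[0]
    if n < 3:
        raise ValueError("ordination requires at least 3 samples")
    index = table.counts.index
    if method == "pcoa":
        dm = distance_matrix(table, metric=metric)
        if np.allclose(dm.values, 0):
            coords = np.zeros((n, n_axes))
            pe = np.zeros(n_axes)
        else:
            res = pcoa(DistanceMatrix(dm.values, ids=list(dm.index)),
                       number_of_dimensions=min(n_axes, n - 1))
            coords = res.samples.values[:, :n_axes]
            pe = res.proportion_explained.values[:n_axes]
            if coords.shape[1] < n_axes:
                pad = n_axes - coords.shape[1]
                coords = np.hstack([coords, np.zeros((n, pad))])
                pe = np.concatenate([pe, np.zeros(pad)])
    elif method == "pca":
        X = table.frequencies().values
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / max(n - 1, 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0, None)
        evecs = evecs[:, order]
        total = evals.sum()
        coords = (Xc @ evecs)[:, :n_axes]
        pe = (evals / total if total > 0 else np.zeros_like(evals))[:n_axes]
        if coords.shape[1] < n_axes:
            pad = n_axes - coords.shape[1]
            coords = np.hstack([coords, np.zeros((n, pad))])
            pe = np.concatenate([pe, np.zeros(pad)])
        metric = "euclidean-on-frequencies"
    else:
        raise ValueError(f"unknown method {method!r}")
    coords = _fix_signs(np.asarray(coords, dtype=float))
    pe = np.clip(np.asarray(pe, dtype=float), 0, None)
    cols = [f"PC{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=index, columns=cols),
        proportion_explained=pe,
        metric=metric,
        method=method,
    )


def conversion_transition_matrix(
    k: int, failure_rate: float, inappropriate_rate: float = 0.0
) -> np.ndarray:
    """2^k x 2^k map from true to observed epiallele probabilities.

    Incomplete bisulfite conversion flips a true-unmethylated CpG to an
    observed '1' with probability ``failure_rate``; inappropriate
    conversion flips a true-methylated CpG to '0' with probability
    ``inappropriate_rate``. Sites are independent, so the joint transition
    is the k-fold Kronecker product of the per-site 2x2 matrix. Column
    index = true profile, row index = observed profile, both in the
    lexicographic bit order used throughout.
    """
    eps, delta = failure_rate, inappropriate_rate
    site = np.array([[1 - eps, delta], [eps, 1 - delta]])
    full = np.ones((1, 1))
    for _ in range(k):
        full = np.kron(full, site)
    return full


def correct_conversion_bias(
    freqs: pd.Series,
    failure_rate: float,
    inappropriate_rate: float = 0.0,
    k: int | None = None,
) -> pd.Series:
    """Invert the per-site conversion-error process on observed frequencies.

    ``freqs`` holds observed epiallele frequencies (index = binary
    strings); ``failure_rate`` is the per-site miscall rate of unmethylated
    CpGs, estimable from the unmethylated spike-in as 1 - conversion
    efficiency. Returns the deconvolved frequency estimate over the full
    2^k space, clipped at zero and renormalised. Only a small, well-
    conditioned correction is intended (rates of a few percent).
    """
    k = k if k is not None else len(freqs.index[0])
    order = all_epialleles(k)
    obs = freqs.reindex(order, fill_value=0.0).values.astype(float)
    T = conversion_transition_matrix(k, failure_rate, inappropriate_rate)
    est = np.linalg.solve(T, obs)
    est = np.clip(est, 0.0, None)
    total = est.sum()
    if total <= 0:
        raise ValueError("correction produced an empty distribution")
    return pd.Series(est / total, index=order)


def expected_uniform_class_proportion(k: int, cls: int) -> float:
    """Class proportion under a uniform distribution over all 2^k profiles."""
    return comb(k, cls) / 2 ** k


def group_separation(
    ordination: OrdinationResult, groups: pd.Series
) -> dict[str, float]:
    """Between-centroid vs within-group spread on the first two axes.

    Returns the distance between the two group centroids and the maximum
    within-group point-to-centroid distance; separation holds when
    ``between > max_within``.
    """
    labels = groups.reindex(ordination.coordinates.index)
    uniq = labels.unique()
    if len(uniq) != 2:
        raise ValueError("group_separation expects exactly 2 groups")
    pts = ordination.coordinates.iloc[:, :2].values
    cents = {}
    max_within = 0.0
    for g in uniq:
        sel = pts[(labels == g).values]
        c = sel.mean(axis=0)
        cents[g] = c
        max_within = max(
            max_within, float(np.linalg.norm(sel - c, axis=1).max())
        )
    between = float(np.linalg.norm(cents[uniq[0]] - cents[uniq[1]]))
    return {"between_centroids": between, "max_within": max_within}
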