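"""Cell/tissue-specificity expression indexes and the star-coordinate projection.

Given a genes x samples matrix of non-negative, pre-normalized expression
levels, each index scores how dominantly (or specifically) a gene is expressed
in one focal sample. Four of them build per-sample ranked gene lists for the
downstream gene-set tests:

``ED``
    expression differential — observed expression minus the expression
    expected if the gene followed the per-sample library totals,
    ``ED = x_i − Σx · s_i/Σs``. Full-spectrum (signed) and sums to zero over
    samples for every gene.
``PEM``
    preferential expression measure, ``log10`` of the expression-enrichment
    ratio ``EE = (x_i/Σx)/(s_i/Σs)``.
``SPM``
    specificity measure, ``x_i²/Σx²`` — in [0, 1], sums to one per gene.
``START``
    star-coordinate projection: samples become evenly spaced axes of a 2-D
    star plot (axis order from hierarchical clustering of the samples), each
    gene's expression vector is projected to a point P, and its score for a
    sample is the scalar projection of OP onto that sample's axis.

Three reference summaries are also provided: the specificity index ``tau``,
the entropy score ``Hg`` (both per-gene, no focal sample) and the raw ``EE``
ratio. They are reported for comparison only and are not gene-list builders
in the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ExpressionMatrix",
    "RankedGeneList",
    "StarLayout",
    "ProjectedPoint",
    "LIST_METHODS",
    "SUMMARY_METHODS",
    "ed_scores",
    "pem_scores",
    "spm_scores",
    "ee_scores",
    "tau_scores",
    "hg_scores",
    "build_star_layout",
    "start_project",
    "start_vo",
    "start_scores",
    "compute_index",
]

#: methods that produce one ranked gene list per focal sample
LIST_METHODS = ("ed", "pem", "spm", "ee", "start")
#: per-gene summaries across samples (no focal sample)
SUMMARY_METHODS = ("tau", "hg")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of non-negative finite expression levels."""

    values: np.ndarray
    gene_ids: pd.Index
    sample_ids: pd.Index

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        genes = pd.Index(self.gene_ids).astype(str)
        samples = pd.Index(self.sample_ids).astype(str)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        if v.ndim != 2 or v.shape != (len(genes), len(samples)):
            raise ValueError("values shape does not match gene/sample ids")
        if len(samples) < 2:
            raise ValueError("at least two samples are required")
        if not genes.is_unique or not samples.is_unique:
            raise ValueError("gene and sample ids must be unique")
        if not np.all(np.isfinite(v)):
            raise ValueError("expression values must be finite")
        if np.any(v < 0):
            raise ValueError("expression values must be non-negative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), df.index, df.columns)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        from .io import read_expression

        return cls.from_frame(read_expression(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        """Per-sample totals s_i; zero totals are a hard error."""
        s = self.values.sum(axis=0)
        if np.any(s <= 0):
            bad = list(self.sample_ids[np.asarray(s <= 0)])
            raise ValueError(f"zero total expression in sample(s) {bad}")
        return s


@dataclass(frozen=True)
class RankedGeneList:
    """Per-sample gene-list: one real-valued rank score per gene.

    Larger score = more dominantly/specifically expressed in the focal sample
    (for ED/PEM/SPM/START; EE follows the same orientation).
    """

    sample_id: str
    method: str
    scores: pd.Series

    def to_tsv(self, path) -> None:
        from .io import write_gene_list

        write_gene_list(self.scores, path)


# ---------------------------------------------------------------------------
# index computations
# ---------------------------------------------------------------------------

def _zero_row_warn(mask: np.ndarray, what: str) -> None:
    if mask.any():
        warnings.warn(
            f"{int(mask.sum())} all-zero gene row(s): {what} defined as 0",
            RuntimeWarning,
            stacklevel=3,
        )


def ed_scores(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Expression differential: observed minus expected under sample totals."""
    s = matrix.sample_totals()
    expected = np.outer(matrix.values.sum(axis=1), s / s.sum())
    return pd.DataFrame(matrix.values - expected, index=matrix.gene_ids,
                        columns=matrix.sample_ids)


def ee_scores(matrix: ExpressionMatrix, pseudo: float = 0.0) -> pd.DataFrame:
    """Expression-enrichment ratio EE = (x_i/Σx) / (s_i/Σs).

    ``pseudo`` is added to each expression value before forming the gene-side
    ratio so that downstream logs stay finite on matrices containing zeros;
    the sample totals s_i are taken from the raw values.
    """
    s = matrix.sample_totals()
    x = matrix.values + pseudo
    row = x.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        ee = (x / row) / (s / s.sum())
    zero_rows = ~np.isfinite(ee).all(axis=1)
    if zero_rows.any():
        _zero_row_warn(zero_rows, "EE")
        ee[zero_rows] = 0.0
    return pd.DataFrame(ee, index=matrix.gene_ids, columns=matrix.sample_ids)


def pem_scores(matrix: ExpressionMatrix, pseudo: float = 1e-3) -> pd.DataFrame:
    """Preferential expression measure, PEM = log10(EE).

    With the default pseudo-expression the score is finite on zero-containing
    matrices; with ``pseudo=0`` on strictly positive data it is exactly
    ``log10`` of :func:`ee_scores`.
    """
    ee = ee_scores(matrix, pseudo=pseudo).to_numpy()
    with np.errstate(divide="ignore"):
        pem = np.log10(ee)
    return pd.DataFrame(pem, index=matrix.gene_ids, columns=matrix.sample_ids)


def spm_scores(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Specificity measure SPM = x_i² / Σx² (in [0, 1], sums to 1 per gene)."""
    sq = matrix.values ** 2
    denom = sq.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    _zero_row_warn(zero, "SPM")
    with np.errstate(invalid="ignore"):
        spm = np.where(denom > 0, sq / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.DataFrame(spm, index=matrix.gene_ids, columns=matrix.sample_ids)


def tau_scores(matrix: ExpressionMatrix) -> pd.Series:
    """Specificity index tau = Σ(1 − x_i/max x)/(n−1); 0 uniform, 1 single-sample."""
    v = matrix.values
    mx = v.max(axis=1, keepdims=True)
    zero = mx[:, 0] == 0
    _zero_row_warn(zero, "tau")
    with np.errstate(invalid="ignore"):
        ratio = np.where(mx > 0, v / np.where(mx > 0, mx, 1.0), 1.0)
    tau = (1.0 - ratio).sum(axis=1) / (matrix.n_samples - 1)
    tau[zero] = 0.0
    return pd.Series(tau, index=matrix.gene_ids, name="tau")


def hg_scores(matrix: ExpressionMatrix) -> pd.Series:
    """Entropy score Hg = −Σ p·log2 p with p = x_i/Σx (0·log0 ≡ 0).

    log2(n) for a uniform gene, 0 for single-sample expression. Reported raw:
    small Hg = specific, i.e. the orientation is inverted relative to the
    other indexes.
    """
    v = matrix.values
    row = v.sum(axis=1, keepdims=True)
    zero = row[:, 0] == 0
    _zero_row_warn(zero, "Hg")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(row > 0, v / np.where(row > 0, row, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    hg = -plogp.sum(axis=1)
    hg[zero] = 0.0
    return pd.Series(hg, index=matrix.gene_ids, name="hg")


# ---------------------------------------------------------------------------
# star-coordinate projection (START)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StarLayout:
    """Axis arrangement of the star plot: sample order, angles, origin."""

    axis_order: tuple[str, ...]
    angles: np.ndarray  # strictly increasing in [0, 2π), one per position
    origin: tuple[float, float] = (0.0, 0.0)

    def angle_of(self, sample_id: str) -> float:
        try:
            return float(self.angles[self.axis_order.index(sample_id)])
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in layout") from None


@dataclass(frozen=True)
class ProjectedPoint:
    """A gene's 2-D star-plot position P and the angle δ of vector OP."""

    gene_id: str
    px: float
    py: float
    delta: float = field(init=False)
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        d = np.arctan2(self.py - self.origin[1], self.px - self.origin[0])
        object.__setattr__(self, "delta", float(np.mod(d, 2.0 * np.pi)))


def build_star_layout(matrix: ExpressionMatrix) -> StarLayout:
    """Order sample axes by hierarchical clustering of expression profiles.

    Distance is 1 − Pearson correlation between sample columns, average
    linkage; the dendrogram leaf order becomes the axis order, with angles
    evenly spaced over [0, 2π). Constant sample profiles make the correlation
    undefined, in which case the input order is kept with a warning.
    """
    n = matrix.n_samples
    angles = 2.0 * np.pi * np.arange(n) / n
    order = list(range(n))
    stds = matrix.values.std(axis=0)
    if np.any(stds == 0):
        warnings.warn(
            "constant sample profile(s): star layout falls back to input order",
            RuntimeWarning,
            stacklevel=2,
        )
    else:
        corr = np.corrcoef(matrix.values, rowvar=False)
        dist = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        order = list(leaves_list(z))
    axis_order = tuple(str(matrix.sample_ids[i]) for i in order)
    return StarLayout(axis_order=axis_order, angles=angles)


def start_project(gene_values: np.ndarray, layout: StarLayout,
                  gene_id: str = "") -> ProjectedPoint:
    """Project one gene's per-sample vector D (ordered as layout.axis_order)."""
    d = np.asarray(gene_values, dtype=float)
    if d.shape != layout.angles.shape:
        raise ValueError("gene vector length does not match layout")
    if not np.all(np.isfinite(d)):
        raise ValueError("gene vector must be finite")
    px = layout.origin[0] + float(d @ np.cos(layout.angles))
    py = layout.origin[1] + float(d @ np.sin(layout.angles))
    return ProjectedPoint(gene_id=gene_id, px=px, py=py, origin=layout.origin)


def start_vo(point: ProjectedPoint, target_angle: float) -> float:
    """Scalar projection of OP onto the target sample's axis (the VO length)."""
    ox, oy = point.origin
    r = float(np.hypot(point.px - ox, point.py - oy))
    return r * float(np.cos(target_angle - point.delta))


def start_scores(matrix: ExpressionMatrix, layout: StarLayout | None = None,
                 normalize: bool = False) -> pd.DataFrame:
    """START rank scores for every gene against every sample axis.

    ``normalize`` rescales each gene's vector to unit sum before projection
    (off by default; raw expression lengths are used).
    """
    if layout is None:
        layout = build_star_layout(matrix)
    cols = [list(matrix.sample_ids).index(s) for s in layout.axis_order]
    d = matrix.values[:, cols]
    if normalize:
        row = d.sum(axis=1, keepdims=True)
        d = np.divide(d, row, out=np.zeros_like(d), where=row > 0)
    px = d @ np.cos(layout.angles) + layout.origin[0]
    py = d @ np.sin(layout.angles) + layout.origin[1]
    # VO = |OP| cos(θ−δ) = P·(cos θ, sin θ) for origin (0,0)
    rx, ry = px - layout.origin[0], py - layout.origin[1]
    vo = np.outer(rx, np.cos(layout.angles)) + np.outer(ry, np.sin(layout.angles))
    out = pd.DataFrame(vo, index=matrix.gene_ids, columns=list(layout.axis_order))
    return out[list(matrix.sample_ids)]


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def compute_index(matrix: ExpressionMatrix, method: str,
                  sample: str | None = None, pseudo: float = 1e-3,
                  layout: StarLayout | None = None,
                  normalize: bool = False):
    """Compute one index.

    For the per-sample methods (``ed``, ``pem``, ``spm``, ``ee``, ``start``)
    a focal ``sample`` is required and a :class:`RankedGeneList` is returned;
    for the per-gene summaries (``tau``, ``hg``) a :class:`pandas.Series` of
    per-gene scores is returned and ``sample`` must be None.
    """
    method = method.lower()
    if method in SUMMARY_METHODS:
        if sample is not None:
            raise ValueError(f"{method} is a per-gene summary; no focal sample")
        return {"tau": tau_scores, "hg": hg_scores}[method](matrix)
    if method not in LIST_METHODS:
        raise ValueError(f"unknown index method {method!r}")
    if sample is None:
        raise ValueError(f"{method} requires a focal sample")
    sample = str(sample)
    if sample not in matrix.sample_ids:
        raise KeyError(f"sample {sample!r} not in matrix")
    if method == "ed":
        full = ed_scores(matrix)
    elif method == "pem":
        full = pem_scores(matrix, pseudo=pseudo)
    elif method == "spm":
        full = spm_scores(matrix)
    elif method == "ee":
        full = ee_scores(matrix, pseudo=pseudo)
    else:
        full = start_scores(matrix, layout=layout, normalize=normalize)
    return RankedGeneList(sample_id=sample, method=method, scores=full[sample])
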