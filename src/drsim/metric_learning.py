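"""Supervised similarity learning: PCA + Fisher LDA + class references.

The trained model is a linear map applied to any signature ``x``::

    TR = L' P' (x - mu)

where ``mu`` is the per-gene training mean, ``P`` holds orthonormal
principal-component loadings (dimensionality reduction), and ``L`` is the
Fisher discriminant projection learned from the compound labels.  LDA
maximizes between-class over within-class scatter, so in the projected
space replicates of one compound sit close together while different
compounds separate.  Each compound is then summarized by its *transformed
median reference* (TMR): the componentwise median of its transformed
replicates.  Queries are matched to TMRs by cosine similarity.

For repositioning, training in ``reversed`` mode negates the reference
signatures first, so a high learned similarity means the compound is
expected to *revert* the query phenotype.  The ``use_lda=False`` ablation
sets ``L`` to the identity, scoring in plain PCA space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.linalg

from .errors import (
    CompatibilityError,
    DegenerateInputError,
    DegenerateSeparationError,
    IntegrityError,
    ParameterError,
    ShapeError,
    ValidationError,
)
from .io import SampleAnnotation, SignatureMatrix
from .preprocess import filter_min_replicates

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "1"

__all__ = [
    "TrainingConfig",
    "DrSimModel",
    "fit_pca",
    "fit_lda",
    "compute_tmr",
    "train",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of model training.

    ``component_selection`` picks the PCA dimensionality when
    ``n_components`` is not given explicitly:

    * ``"parallel"`` (default) — Horn's parallel analysis: keep only the
      components whose eigenvalue exceeds the largest eigenvalue observed
      after independently permuting each gene's values across samples.
      With many more genes than samples a fixed variance fraction retains
      mostly noise components and the downstream discriminant analysis
      overfits them; the permutation noise floor retains only components
      carrying structure.
    * ``"variance"`` — smallest count whose cumulative explained-variance
      ratio reaches ``variance_fraction``.

    ``shrinkage`` regularizes the pooled within-class scatter as
    ``S_w + shrinkage * (trace(S_w)/p) * I`` — LINCS-style classes are
    small, so ``S_w`` is easily ill-conditioned.
    """

    n_components: int | None = None
    component_selection: str = "parallel"
    variance_fraction: float = 0.95
    shrinkage: float = 1e-4
    use_lda: bool = True
    min_replicates: int = 2
    parallel_draws: int = 3
    parallel_seed: int = 0

    def __post_init__(self) -> None:
        if self.component_selection not in ("parallel", "variance"):
            raise ParameterError(
                f"component_selection must be 'parallel' or 'variance', "
                f"got {self.component_selection!r}"
            )


@dataclass
class DrSimModel:
    """Trained similarity model: linear map plus per-compound references."""

    gene_ids: list[str]
    mean: np.ndarray  # (genes,)
    P: np.ndarray  # (genes, p), orthonormal columns
    L: np.ndarray  # (p, q), unit-norm columns
    class_labels: list[str]
    tmr: np.ndarray  # (q, C)
    mode: str  # "forward" | "reversed"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("forward", "reversed"):
            raise ValidationError(f"mode must be 'forward' or 'reversed', got {self.mode!r}")
        if self.tmr.shape != (self.L.shape[1], len(self.class_labels)):
            raise ValidationError(
                f"tmr shape {self.tmr.shape} does not match (q={self.L.shape[1]}, "
                f"C={len(self.class_labels)})"
            )
        if not np.allclose(self.P.T @ self.P, np.eye(self.P.shape[1]), atol=1e-8):
            raise ValidationError("P columns are not orthonormal")

    @property
    def n_components(self) -> int:
        return self.P.shape[1]

    @property
    def n_discriminants(self) -> int:
        return self.L.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Apply ``L' P' (x - mu)`` to a vector or a (genes, k) matrix."""
        x = np.asarray(x, dtype=np.float64)
        if x.shape[0] != len(self.gene_ids):
            raise ShapeError(
                f"input has {x.shape[0]} genes, model expects {len(self.gene_ids)}"
            )
        centered = x - (self.mean if x.ndim == 1 else self.mean[:, None])
        return self.L.T @ (self.P.T @ centered)


def _fix_signs(M: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Eigenvectors are defined only up to sign; fixing it makes training
    deterministic and serialization reproducible.
    """
    M = M.copy()
    for j in range(M.shape[1]):
        i = int(np.argmax(np.abs(M[:, j])))
        if M[i, j] < 0:
            M[:, j] = -M[:, j]
    return M


def fit_pca(
    X: SignatureMatrix | np.ndarray,
    n_components: int | None = None,
    variance_fraction: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components of a genes x samples matrix.

    Returns ``(mu, P, explained_variance_ratios)`` where ``mu`` is the
    per-gene mean, ``P`` the orthonormal loadings ordered by decreasing
    eigenvalue of the sample covariance, and the ratios are each
    eigenvalue's share of the total variance.
    """
    values = X.values if isinstance(X, SignatureMatrix) else np.asarray(X, dtype=np.float64)
    n = values.shape[1]
    if n < 2:
        raise DegenerateInputError(f"PCA needs at least 2 samples, got {n}")
    if n_components is None and not 0 < variance_fraction <= 1:
        raise ParameterError(
            f"variance_fraction must be in (0, 1], got {variance_fraction}"
        )
    max_rank = min(values.shape[0], n - 1)
    if n_components is not None and not 1 <= n_components <= max_rank:
        raise ParameterError(
            f"n_components must be in [1, {max_rank}], got {n_components}"
        )
    mu = values.mean(axis=1)
    centered = values - mu[:, None]
    # SVD of the centered data is the eigendecomposition of the covariance.
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / (n - 1)
    total = eigvals.sum()
    ratios = eigvals / total if total > 0 else np.zeros_like(eigvals)
    if n_components is not None:
        p = n_components
    else:
        p = int(np.searchsorted(np.cumsum(ratios), variance_fraction - 1e-12) + 1)
        p = min(p, max_rank)
    P = _fix_signs(U[:, :p])
    return mu, P, ratios[:max_rank]


def select_components_parallel(
    values: np.ndarray, n_draws: int = 3, seed: int = 0
) -> int:
    """Number of principal components above the permutation noise floor.

    Horn's parallel analysis: each gene's values are permuted across
    samples independently (destroying covariance while keeping marginals),
    and the threshold is the largest top eigenvalue over ``n_draws``
    permuted datasets.  Components of the real data with eigenvalues above
    the threshold are retained; at least one component is always kept.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.shape[1]
    if n < 2:
        raise DegenerateInputError(f"parallel analysis needs >= 2 samples, got {n}")
    rng = np.random.default_rng(seed)
    threshold = 0.0
    for _ in range(n_draws):
        perm = rng.permuted(values, axis=1)
        perm = perm - perm.mean(axis=1, keepdims=True)
        top = np.linalg.svd(perm, compute_uv=False)[0]
        threshold = max(threshold, float(top) ** 2 / (n - 1))
    centered = values - values.mean(axis=1, keepdims=True)
    eigvals = np.linalg.svd(centered, compute_uv=False) ** 2 / (n - 1)
    return max(1, int(np.count_nonzero(eigvals > threshold)))


def _scatter_matrices(
    Z: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pooled within-class and size-weighted between-class scatter of (p, n) data."""
    classes = sorted(set(labels.tolist()))
    p = Z.shape[0]
    grand = Z.mean(axis=1)
    S_w = np.zeros((p, p))
    S_b = np.zeros((p, p))
    for c in classes:
        Zc = Z[:, labels == c]
        if Zc.shape[1] < 2:
            raise ValidationError(
                f"class {c!r} has {Zc.shape[1]} sample(s); LDA needs >= 2 per class"
            )
        mc = Zc.mean(axis=1)
        D = Zc - mc[:, None]
        S_w += D @ D.T
        d = (mc - grand)[:, None]
        S_b += Zc.shape[1] * (d @ d.T)
    return S_w, S_b, classes


def fit_lda(Z: np.ndarray, labels, shrinkage: float = 1e-4) -> np.ndarray:
    """Fisher discriminant directions of PCA-projected samples.

    Solves the generalized eigenproblem ``S_b v = lambda S_w v`` with the
    within-class scatter shrunk toward a scaled identity, keeps the top
    ``q <= C - 1`` eigenvectors with eigenvalue above 1e-10, and returns
    them as unit-norm, sign-fixed columns.
    """
    Z = np.asarray(Z, dtype=np.float64)
    labels = np.asarray([str(v) for v in labels])
    if Z.shape[1] != labels.shape[0]:
        raise ShapeError(f"{Z.shape[1]} samples but {labels.shape[0]} labels")
    if shrinkage < 0:
        raise ParameterError(f"shrinkage must be >= 0, got {shrinkage}")
    S_w, S_b, classes = _scatter_matrices(Z, labels)
    if len(classes) < 2:
        raise DegenerateInputError("LDA needs at least 2 classes")
    p = Z.shape[0]
    tr = np.trace(S_w)
    reg = shrinkage * (tr / p if tr > 0 else 1.0)
    S_w_reg = S_w + reg * np.eye(p)
    eigvals, eigvecs = scipy.linalg.eigh(S_b, S_w_reg)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    q_max = len(classes) - 1
    keep = [j for j in range(min(q_max, p)) if eigvals[j] > 1e-10]
    if not keep:
        raise DegenerateSeparationError(
            "all discriminant eigenvalues are numerically zero"
        )
    L = eigvecs[:, keep]
    L = L / np.linalg.norm(L, axis=0)
    return _fix_signs(L)


def compute_tmr(TR: np.ndarray, labels) -> tuple[np.ndarray, list[str]]:
    """Componentwise median of each class's transformed replicates.

    Returns ``(tmr, class_labels)`` with classes in sorted label order;
    column ``c`` of ``tmr`` is the median reference of class ``c``.
    """
    TR = np.asarray(TR, dtype=np.float64)
    labels = np.asarray([str(v) for v in labels])
    if TR.shape[1] != labels.shape[0]:
        raise ShapeError(f"{TR.shape[1]} columns but {labels.shape[0]} labels")
    if not np.all(np.isfinite(TR)):
        raise ValidationError("transformed references contain non-finite values")
    classes = sorted(set(labels.tolist()))
    tmr = np.column_stack([np.median(TR[:, labels == c], axis=1) for c in classes])
    return tmr, classes


def train(
    X: SignatureMatrix,
    annotations: list[SampleAnnotation],
    config: TrainingConfig | None = None,
    mode: str = "forward",
) -> DrSimModel:
    """Fit the full pipeline: (optional negation) -> PCA -> LDA -> TMR."""
    config = config or TrainingConfig()
    if mode not in ("forward", "reversed"):
        raise ParameterError(f"mode must be 'forward' or 'reversed', got {mode!r}")
    if config.use_lda:
        X, annotations = filter_min_replicates(X, annotations, max(2, config.min_replicates))
    by_id = {a.sample_id: a for a in annotations}
    missing = [s for s in X.sample_ids if s not in by_id]
    if missing:
        raise ValidationError(f"annotations missing for samples: {missing[:5]}")
    labels = np.asarray([by_id[s].compound for s in X.sample_ids])

    values = -X.values if mode == "reversed" else X.values
    n_components = config.n_components
    if n_components is None and config.component_selection == "parallel":
        n_components = min(
            select_components_parallel(values, config.parallel_draws, config.parallel_seed),
            min(values.shape[0], values.shape[1] - 1),
        )
    mu, P, ratios = fit_pca(values, n_components, config.variance_fraction)
    Z = P.T @ (values - mu[:, None])
    if config.use_lda:
        L = fit_lda(Z, labels, config.shrinkage)
    else:
        L = np.eye(P.shape[1])
    TR = L.T @ Z
    tmr, classes = compute_tmr(TR, labels)
    hyper = asdict(config)
    hyper["explained_variance_fraction_achieved"] = float(
        ratios[: P.shape[1]].sum()
    )
    return DrSimModel(
        gene_ids=list(X.gene_ids),
        mean=mu,
        P=P,
        L=L,
        class_labels=classes,
        tmr=tmr,
        mode=mode,
        hyperparameters=hyper,
    )


def _write_matrix(path: Path, M: np.ndarray, row_labels, col_labels) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(col_labels) + "\n")
        for label, row in zip(row_labels, np.atleast_2d(M)):
            fh.write(label + "\t" + "\t".join(repr(v) for v in row.tolist()) + "\n")


def _read_matrix(path: Path) -> np.ndarray:
    if not path.exists():
        raise IntegrityError(f"model file missing: {path}")
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    rows = [[float(v) for v in ln.split("\t")[1:]] for ln in lines[1:] if ln]
    return np.asarray(rows, dtype=np.float64)


def save_model(model: DrSimModel, out_dir) -> None:
    """Persist a model as a directory of TSV matrices plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "n_genes": len(model.gene_ids),
        "p": model.n_components,
        "q": model.n_discriminants,
        "class_labels": model.class_labels,
        "mode": model.mode,
        "hyperparameters": model.hyperparameters,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    pcs = [f"PC{j + 1}" for j in range(model.n_components)]
    lds = [f"LD{j + 1}" for j in range(model.n_discriminants)]
    _write_matrix(out / "mu.tsv", model.mean[:, None], model.gene_ids, ["mu"])
    _write_matrix(out / "P.tsv", model.P, model.gene_ids, pcs)
    _write_matrix(out / "L.tsv", model.L, pcs, lds)
    _write_matrix(out / "tmr.tsv", model.tmr, lds, model.class_labels)


def load_model(in_dir) -> DrSimModel:
    """Load a model directory written by :func:`save_model`."""
    src = Path(in_dir)
    manifest_path = src / "manifest.json"
    if not manifest_path.exists():
        raise IntegrityError(f"model manifest missing: {manifest_path}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    if manifest.get("format_version") != MODEL_FORMAT_VERSION:
        raise CompatibilityError(
            f"unsupported model format version {manifest.get('format_version')!r} "
            f"(expected {MODEL_FORMAT_VERSION!r})"
        )
    mu = _read_matrix(src / "mu.tsv")[:, 0]
    P = _read_matrix(src / "P.tsv")
    L = _read_matrix(src / "L.tsv")
    tmr = _read_matrix(src / "tmr.tsv")
    with open(src / "P.tsv", encoding="utf-8") as fh:
        gene_ids = [ln.split("\t", 1)[0] for ln in fh.read().splitlines()[1:] if ln]
    checks = [
        (P.shape == (manifest["n_genes"], manifest["p"]), "P.tsv", P.shape),
        (L.shape == (manifest["p"], manifest["q"]), "L.tsv", L.shape),
        (tmr.shape == (manifest["q"], len(manifest["class_labels"])), "tmr.tsv", tmr.shape),
        (mu.shape == (manifest["n_genes"],), "mu.tsv", mu.shape),
    ]
    for ok, name, shape in checks:
        if not ok:
            raise IntegrityError(f"{name} shape {shape} inconsistent with manifest")
    return DrSimModel(
        gene_ids=gene_ids,
        mean=mu,
        P=P,
        L=L,
        class_labels=list(manifest["class_labels"]),
        tmr=tmr,
        mode=manifest["mode"],
        hyperparameters=manifest.get("hyperparameters", {}),
    )
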