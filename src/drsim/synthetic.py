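"""LINCS-like synthetic signature collections with known ground truth.

The generator emulates the structure of a compound-perturbation resource:
many compounds x replicates (dosage variants) x cell lines x treatment
durations, with class-structured latent signal plus Gaussian noise.

Generative model (all draws from one seeded generator):

* each MOA class k has a latent direction ``m_k ~ N(0, I)`` in
  ``latent_dim`` dimensions; compounds are assigned to MOA classes
  round-robin;
* compound j's latent centroid is ``tau * (m_moa(j) + 0.3 * N(0, I))`` —
  compounds of one MOA are similar but not identical;
* each (cell line, time point) condition adds a latent offset
  ``~ N(0, (tau/2)^2 I)``, so conditions shift the whole distribution and
  condition-wise splitting matters;
* dosage only rescales the centroid by a factor in [0.8, 1.2] — a weak
  effect, mirroring the observation that dosage barely moves signature
  distributions — so dosage variants behave as replicates;
* latent vectors are embedded into gene space by a fixed random
  orthonormal map (QR of a Gaussian matrix), preserving latent geometry,
  and i.i.d. ``N(0, sigma^2)`` gene noise is added.

``tau / sigma`` is therefore the class separability; the defaults
(15 compounds x 20 replicates, 1000 genes, tau/sigma = 5) give a
well-separated single-subset collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ParameterError, ValidationError
from .io import SampleAnnotation, SignatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_reference_collection",
    "simulate_disease_query",
    "stratified_split",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic collection.

    ``class_effect_size`` (tau) scales compound centroids and condition
    offsets; ``noise_sd`` (sigma) is the per-gene noise level; their ratio
    sets class separability.  ``tau = 0`` produces pure noise (no class
    signal).

    ``n_moa_classes=None`` (the default) gives every compound its own
    mechanism.  Grouping compounds into shared MOA classes
    (``n_moa_classes < n_compounds``) correlates their centroids at ~0.95
    and makes compound-level recovery intrinsically harder: the
    within-MOA differences carry little variance and, with far more genes
    than samples, fall below what unsupervised PCA can detect.
    """

    n_genes: int = 1000
    n_compounds: int = 15
    replicates_per_compound: int = 20
    n_moa_classes: int | None = None  # default: every compound its own MOA
    cell_lines: tuple[str, ...] = ("MCF7",)
    time_points: tuple[int, ...] = (24,)
    latent_dim: int = 10
    class_effect_size: float = 5.0
    noise_sd: float = 1.0
    dosage_levels: tuple[str, ...] = ("1uM", "10uM")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_moa_classes is None:
            object.__setattr__(self, "n_moa_classes", self.n_compounds)
        if self.n_moa_classes > self.n_compounds:
            raise ParameterError("n_moa_classes must be <= n_compounds")
        if self.latent_dim > self.n_genes:
            raise ParameterError("latent_dim must be <= n_genes")
        if self.class_effect_size < 0:
            raise ParameterError("class_effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        if self.n_compounds < 1 or self.replicates_per_compound < 1:
            raise ParameterError("need at least one compound and one replicate")
        if not self.cell_lines or not self.time_points or not self.dosage_levels:
            raise ParameterError("cell_lines, time_points, dosage_levels must be non-empty")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated collection."""

    config: SimulationConfig
    compound_of_sample: dict[str, str]
    moa_of_compound: dict[str, str]
    latent_centroids: dict[str, np.ndarray]
    embedding: np.ndarray  # (n_genes, latent_dim), orthonormal columns

    def gene_centroid(self, compound: str) -> np.ndarray:
        """A compound's noise-free signature in gene space."""
        if compound not in self.latent_centroids:
            raise ValidationError(f"unknown compound {compound!r}")
        return self.embedding @ self.latent_centroids[compound]

    def to_json_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "compound_of_sample": self.compound_of_sample,
            "moa_of_compound": self.moa_of_compound,
        }


def simulate_reference_collection(
    config: SimulationConfig,
) -> tuple[SignatureMatrix, list[SampleAnnotation], SyntheticTruth]:
    """Draw a full reference collection; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    tau, sigma = config.class_effect_size, config.noise_sd

    # fixed orthonormal embedding of the latent space into gene space
    G = rng.normal(size=(config.n_genes, config.latent_dim))
    embedding, _ = np.linalg.qr(G)

    moa_dirs = rng.normal(size=(config.n_moa_classes, config.latent_dim))
    compounds = [f"C{j + 1:03d}" for j in range(config.n_compounds)]
    moa_of = {c: f"MOA{(j % config.n_moa_classes) + 1}" for j, c in enumerate(compounds)}
    centroids = {
        c: tau
        * (moa_dirs[j % config.n_moa_classes] + 0.3 * rng.normal(size=config.latent_dim))
        for j, c in enumerate(compounds)
    }

    conditions = [(cl, tp) for cl in config.cell_lines for tp in config.time_points]
    offsets = {
        cond: rng.normal(scale=tau / 2 if tau > 0 else 0.0, size=config.latent_dim)
        if tau > 0
        else np.zeros(config.latent_dim)
        for cond in conditions
    }
    n_levels = len(config.dosage_levels)
    dose_scale = (
        np.linspace(0.8, 1.2, n_levels) if n_levels > 1 else np.array([1.0])
    )

    sample_ids: list[str] = []
    annotations: list[SampleAnnotation] = []
    columns: list[np.ndarray] = []
    compound_of_sample: dict[str, str] = {}
    for cell_line, time_point in conditions:
        offset = offsets[(cell_line, time_point)]
        for c in compounds:
            for r in range(config.replicates_per_compound):
                dose_idx = r % n_levels
                latent = dose_scale[dose_idx] * centroids[c] + offset
                signal = embedding @ latent
                noise = rng.normal(scale=sigma, size=config.n_genes)
                sid = f"{c}_{cell_line}_{time_point}h_{config.dosage_levels[dose_idx]}_r{r + 1:02d}"
                sample_ids.append(sid)
                columns.append(signal + noise)
                compound_of_sample[sid] = c
                annotations.append(
                    SampleAnnotation(
                        sample_id=sid,
                        compound=c,
                        cell_line=cell_line,
                        time_point=time_point,
                        dosage=config.dosage_levels[dose_idx],
                    )
                )
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    matrix = SignatureMatrix(gene_ids, sample_ids, np.column_stack(columns))
    truth = SyntheticTruth(config, compound_of_sample, moa_of, centroids, embedding)
    return matrix, annotations, truth


def simulate_disease_query(
    truth: SyntheticTruth,
    target_compound: str,
    direction: str = "reverse",
    noise_sd: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """A disease-style query tied to one compound's signature.

    ``direction="induce"`` returns the compound's gene-space centroid plus
    noise (a phenotype the compound induces); ``"reverse"`` returns its
    negation plus noise (a phenotype the compound should revert — the
    repositioning use case).
    """
    if direction not in ("induce", "reverse"):
        raise ParameterError(f"direction must be 'induce' or 'reverse', got {direction!r}")
    rng = np.random.default_rng(seed)
    sigma = truth.config.noise_sd if noise_sd is None else noise_sd
    centroid = truth.gene_centroid(target_compound)
    sign = 1.0 if direction == "induce" else -1.0
    return sign * centroid + rng.normal(scale=sigma, size=centroid.shape[0])


def stratified_split(
    annotations: list[SampleAnnotation],
    ratio: float = 0.3,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Per-compound query/reference split at ``ratio`` query fraction.

    Every compound with >= 2 replicates is represented on both sides;
    single-replicate compounds go to the reference side with a warning.
    Deterministic for a fixed seed.
    """
    if not 0 < ratio < 1:
        raise ParameterError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    by_compound: dict[str, list[str]] = {}
    for a in annotations:
        by_compound.setdefault(a.compound, []).append(a.sample_id)
    query_ids: list[str] = []
    reference_ids: list[str] = []
    for compound in sorted(by_compound):
        ids = sorted(by_compound[compound])
        if len(ids) < 2:
            logger.warning(
                "stratified_split: compound %s has a single replicate; kept as reference",
                compound,
            )
            reference_ids.extend(ids)
            continue
        perm = rng.permutation(len(ids))
        n_query = int(np.clip(round(ratio * len(ids)), 1, len(ids) - 1))
        query_ids.extend(ids[i] for i in perm[:n_query])
        reference_ids.extend(ids[i] for i in perm[n_query:])
    return query_ids, reference_ids
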