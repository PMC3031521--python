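"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators produce, reproducibly from a single integer seed:

* a gold-standard catalog of positive / negative / unknown proteins,
* binary predictor calls that are conditionally independent given the label,
  each predictor characterised by a (sensitivity, specificity) operating
  point — the published operating points of the fourteen genome-scale
  predictors are provided as :data:`DEFAULT_PREDICTOR_PROFILES`,
* expression datasets in which positives load on a shared latent factor so
  that co-expression carries localization signal,
* a planted-partition interaction network whose modules carry coherent
  function annotations.

All generators are pure functions of (config, seed): the master seed is
expanded into per-generator substreams via :class:`numpy.random.SeedSequence`
so each generator can be re-run independently with identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_model import (
    AnnotationMap,
    ExpressionDataset,
    FeatureMatrix,
    InteractionNetwork,
    Label,
    ProteinCatalog,
    ValidationError,
)

__all__ = [
    "PredictorProfile",
    "ExpressionConfig",
    "NetworkConfig",
    "SynthConfig",
    "DEFAULT_PREDICTOR_PROFILES",
    "generate_gold_standard",
    "generate_predictor_calls",
    "generate_expression",
    "generate_pin",
]


@dataclass(frozen=True)
class PredictorProfile:
    """Operating point of one binary predictor."""

    predictor_id: str
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.predictor_id}: {name}={v} outside [0,1]")


#: Published operating points (sensitivity, specificity) of the fourteen
#: genome-scale predictors, s1..s14, evaluated on the 806/1,464 gold standard.
DEFAULT_PREDICTOR_PROFILES: tuple[PredictorProfile, ...] = (
    PredictorProfile("s1", 0.5087, 0.8443),   # MitoProtII
    PredictorProfile("s2", 0.4926, 0.8969),   # iPSORT
    PredictorProfile("s3", 0.4194, 0.9570),   # TargetP
    PredictorProfile("s4", 0.3710, 0.8668),   # SubLoc
    PredictorProfile("s5", 0.3201, 0.9884),   # Predotar
    PredictorProfile("s6", 0.2519, 0.9693),   # Pfam-domain (MitoPred)
    PredictorProfile("s7", 0.2754, 0.9467),   # LOCtree
    PredictorProfile("s8", 0.1886, 0.9898),   # WoLF PSORT
    PredictorProfile("s9", 0.3623, 0.9440),   # MultiLoc
    PredictorProfile("s10", 0.3040, 0.8969),  # ancestral-homolog transfer
    PredictorProfile("s11", 0.3263, 0.9809),  # human mito orthologs
    PredictorProfile("s12", 0.2940, 0.9843),  # mouse mito orthologs
    PredictorProfile("s13", 0.3189, 0.9816),  # yeast mito orthologs
    PredictorProfile("s14", 0.5409, 0.9836),  # N50 coexpression
)


@dataclass(frozen=True)
class ExpressionConfig:
    """Latent-factor expression model.

    Each dataset has one latent factor; positives load on it with strength
    ``rho`` (the expected pairwise correlation among positives), everything
    else is i.i.d. Gaussian noise scaled by ``noise_sd``.
    """

    n_datasets: int = 24
    n_samples: int = 43
    rho: float = 0.8
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValidationError(f"rho={self.rho} outside [0,1)")
        if self.n_datasets < 1 or self.n_samples < 2:
            raise ValidationError("need >=1 dataset and >=2 samples")


@dataclass(frozen=True)
class NetworkConfig:
    """Planted-partition interaction network with annotated modules."""

    n_modules: int = 8
    module_size: int = 25
    p_within: float = 0.9
    p_background: float = 0.005
    coherence: float = 0.9
    frac_unannotated: float = 0.1
    n_background_terms: int = 20
    level: int = 4

    def __post_init__(self) -> None:
        for name in ("p_within", "p_background", "coherence", "frac_unannotated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0,1]")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the motivating study: 806 gold-standard positives, 1,464
    negatives, predictor operating points from the published evaluation, and
    24 expression datasets.
    """

    n_pos: int = 806
    n_neg: int = 1464
    n_unknown: int = 0
    profiles: tuple[PredictorProfile, ...] = DEFAULT_PREDICTOR_PROFILES
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg, self.n_unknown) < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_pos + self.n_neg + self.n_unknown == 0:
            raise ValidationError("catalog must contain at least one protein")


_STREAMS = ("gold", "calls", "expression", "network")


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of the master seed (order-independent)."""
    idx = _STREAMS.index(name)
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[idx])


def generate_gold_standard(config: SynthConfig) -> ProteinCatalog:
    """Catalog with exactly n_pos / n_neg / n_unknown labelled proteins.

    Label order is shuffled so downstream code cannot rely on block layout.
    """
    rng = _substream(config.seed, "gold")
    n = config.n_pos + config.n_neg + config.n_unknown
    labels = (
        [Label.POSITIVE] * config.n_pos
        + [Label.NEGATIVE] * config.n_neg
        + [Label.UNKNOWN] * config.n_unknown
    )
    order = rng.permutation(n)
    width = len(str(n))
    entries = [
        (f"P{i:0{width}d}", labels[order[i]], "synthetic")
        for i in range(n)
    ]
    return ProteinCatalog(entries)


def generate_predictor_calls(
    catalog: ProteinCatalog,
    profiles: tuple[PredictorProfile, ...] = DEFAULT_PREDICTOR_PROFILES,
    seed: int = 0,
    coupling: float = 0.0,
) -> FeatureMatrix:
    """Conditionally independent binary calls given the label.

    For each protein and predictor independently, call = 1 with probability
    ``sensitivity`` if the protein is positive and ``1 - specificity``
    otherwise (unknowns behave as negatives, emulating a predominantly
    non-mitochondrial background).

    ``coupling`` > 0 violates conditional independence on purpose: a standard
    normal per-protein "difficulty" shifts every predictor's call probability
    on the logit scale by ``coupling`` times that value, inducing positive
    pairwise correlation between predictors within a class.  Used to probe
    robustness of the naive Bayes assumption; the default 0 matches it.
    """
    if not profiles:
        raise ValidationError("profiles must be non-empty")
    rng = _substream(seed, "calls")
    pos = catalog.positives
    is_pos = np.array([pid in pos for pid in catalog.protein_ids])
    n = len(catalog)
    probs = np.empty((n, len(profiles)))
    for j, prof in enumerate(profiles):
        probs[:, j] = np.where(is_pos, prof.sensitivity, 1.0 - prof.specificity)
    if coupling > 0.0:
        z = rng.standard_normal(n)[:, None]
        with np.errstate(divide="ignore", over="ignore"):
            logit = np.log(probs) - np.log1p(-probs)
            probs = 1.0 / (1.0 + np.exp(-(logit + coupling * z)))
        probs = np.nan_to_num(probs, nan=0.0)  # degenerate 0/1 probs stay hard
    calls = (rng.random((n, len(profiles))) < probs).astype(float)
    return FeatureMatrix(
        list(catalog.protein_ids), [p.predictor_id for p in profiles], calls
    )


def generate_expression(
    catalog: ProteinCatalog, config: SynthConfig
) -> list[ExpressionDataset]:
    """Latent-factor expression: positives correlate, the rest is noise.

    Writing f_d for the dataset-d factor, a positive gene's profile is
    sqrt(rho)*f_d + sqrt(1-rho)*eps so that any two positives have expected
    sample correlation rho; negatives and unknowns are pure noise.  The whole
    matrix is scaled by ``noise_sd``.
    """
    ec = config.expression
    rng = _substream(config.seed, "expression")
    pos = catalog.positives
    is_pos = np.array([pid in pos for pid in catalog.protein_ids])
    n = len(catalog)
    datasets = []
    for d in range(ec.n_datasets):
        factor = rng.standard_normal(ec.n_samples)
        noise = rng.standard_normal((n, ec.n_samples))
        values = noise.copy()
        values[is_pos] = (
            np.sqrt(ec.rho) * factor[None, :]
            + np.sqrt(1.0 - ec.rho) * noise[is_pos]
        )
        datasets.append(
            ExpressionDataset(
                dataset_id=f"ds{d:02d}",
                gene_ids=list(catalog.protein_ids),
                samples=[f"sample{s:03d}" for s in range(ec.n_samples)],
                values=values * ec.noise_sd,
            )
        )
    return datasets


def generate_pin(
    catalog: ProteinCatalog, config: SynthConfig
) -> tuple[InteractionNetwork, AnnotationMap]:
    """Planted-partition network with function-coherent modules.

    Modules of ``module_size`` proteins are carved from a seed-shuffled
    ordering of the catalog; within-module pairs connect with ``p_within``,
    all other pairs with ``p_background``.  Each module owns a dominant term;
    members are annotated with it with probability ``coherence`` and with a
    random background term otherwise.  Off-module proteins get a random
    background term.  A fraction ``frac_unannotated`` of proteins is left
    unannotated.
    """
    nc = config.network
    rng = _substream(config.seed, "network")
    ids = list(catalog.protein_ids)
    n = len(ids)
    if nc.n_modules * nc.module_size > n:
        raise ValidationError(
            f"{nc.n_modules} modules x {nc.module_size} exceeds catalog size {n}"
        )
    order = rng.permutation(n)
    module_of = np.full(n, -1)
    for m in range(nc.n_modules):
        members = order[m * nc.module_size : (m + 1) * nc.module_size]
        module_of[members] = m

    # edges: module pairs at p_within, every other pair at p_background
    edges: list[tuple[str, str]] = []
    iu, ju = np.triu_indices(n, k=1)
    same = module_of[iu] == module_of[ju]
    within = same & (module_of[iu] >= 0)
    p = np.where(within, nc.p_within, nc.p_background)
    keep = rng.random(len(iu)) < p
    for a, b in zip(iu[keep], ju[keep]):
        edges.append((ids[a], ids[b]))
    net = InteractionNetwork(ids, edges)

    terms = [f"GO:M{m:04d}" for m in range(nc.n_modules)] + [
        f"GO:B{t:04d}" for t in range(nc.n_background_terms)
    ]
    background = terms[nc.n_modules :]
    records = set()
    unannotated = rng.random(n) < nc.frac_unannotated
    for i in range(n):
        if unannotated[i]:
            continue
        m = module_of[i]
        if m >= 0 and rng.random() < nc.coherence:
            term = terms[m]
        else:
            term = background[rng.integers(len(background))]
        records.add((ids[i], term, nc.level))
    return net, AnnotationMap(frozenset(records))
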